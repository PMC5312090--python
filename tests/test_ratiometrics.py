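import numpy as np
import pandas as pd
import pytest

import hypoximap as hm
from hypoximap.ratiometrics import COLUMNS, render_legend

from conftest import SYNTH_SEG_PARAMS


def table_from_ratios(ratios, specimen_id="s", refs=None):
    n = len(ratios)
    refs = refs if refs is not None else np.full(n, 100.0)
    ratios = np.asarray(ratios, dtype=float)
    df = pd.DataFrame(
        {
            "blob_id": np.arange(1, n + 1),
            "section": np.zeros(n, dtype=int),
            "centroid_row": np.zeros(n),
            "centroid_col": np.zeros(n),
            "area": np.full(n, 10),
            "mean_reference": refs,
            "mean_sensor": refs * ratios,
            "ratio": ratios,
            "normalized_ratio": ratios,
            "region": ["unassigned"] * n,
            "valid": [True] * n,
        },
        columns=COLUMNS,
    )
    return hm.BlobTable(records=df, specimen_id=specimen_id)


def single_blob_stack(sensor_vals, reference_vals):
    h = len(sensor_vals)
    lab = np.zeros((1, h, 3), dtype=np.int32)
    lab[0, :, 1] = 1
    sen = np.zeros((1, h, 3))
    ref = np.zeros((1, h, 3))
    sen[0, :, 1] = sensor_vals
    ref[0, :, 1] = reference_vals
    stack = hm.Stack({"sensor": sen, "reference": ref}, 1, 1)
    return hm.LabelMask(lab), stack


class TestMeasureBlobs:
    def test_constant_blob_means_and_ratio(self):
        mask, stack = single_blob_stack([50.0] * 100, [100.0] * 100)
        table = hm.measure_blobs(mask, stack)
        rec = table.records.iloc[0]
        assert rec["mean_sensor"] == 50 and rec["mean_reference"] == 100
        assert rec["ratio"] == pytest.approx(0.5)
        assert rec["area"] == 100

    def test_identical_channels_give_unit_ratios(self, default_specimen_run):
        stack, _, _, mask, _ = default_specimen_run
        same = hm.Stack(
            {"sensor": stack.channel("reference"), "reference": stack.channel("reference")},
            stack.spacing_xy, stack.spacing_z,
        )
        table = hm.measure_blobs(mask, same)
        np.testing.assert_allclose(table.finite_ratios(), 1.0)

    def test_three_pixel_blob_hand_arithmetic(self):
        mask, stack = single_blob_stack([10.0, 20.0, 30.0], [20.0, 20.0, 20.0])
        rec = hm.measure_blobs(mask, stack).records.iloc[0]
        assert rec["mean_sensor"] == pytest.approx(20.0)
        assert rec["mean_reference"] == pytest.approx(20.0)
        assert rec["ratio"] == pytest.approx(1.0)

    def test_zero_reference_blob_flagged_and_excluded(self, caplog):
        mask, stack = single_blob_stack([5.0, 5.0], [0.0, 0.0])
        with caplog.at_level("WARNING"):
            table = hm.measure_blobs(mask, stack)
        assert not table.records["valid"].iloc[0]
        assert table.finite_ratios().size == 0
        assert any("zero reference" in r.message for r in caplog.records)

    def test_measurement_uses_raw_channels(self, default_specimen_run):
        """Different segmentation params, same mask: identical intensity means."""
        stack, _, _, mask, table = default_specimen_run
        again = hm.measure_blobs(mask, stack)
        np.testing.assert_array_equal(
            table.records["mean_sensor"], again.records["mean_sensor"]
        )

    def test_dimension_mismatch_rejected(self):
        mask, _ = single_blob_stack([1.0], [1.0])
        stack = hm.Stack({"sensor": np.ones((2, 5, 5)), "reference": np.ones((2, 5, 5))}, 1, 1)
        with pytest.raises(ValueError, match="does not match"):
            hm.measure_blobs(mask, stack)


class TestRatiometricInvariance:
    def test_scaling_both_channels_preserves_ratios(self, default_specimen_run):
        stack, _, _, mask, table = default_specimen_run
        scaled = stack.scaled({"sensor": 3.0, "reference": 3.0})
        t2 = hm.measure_blobs(mask, scaled)
        np.testing.assert_allclose(
            t2.finite_ratios(), table.finite_ratios(), rtol=0, atol=1e-9
        )

    def test_scaling_sensor_scales_ratios_exactly(self, default_specimen_run):
        stack, _, _, mask, table = default_specimen_run
        t3 = hm.measure_blobs(mask, stack.scaled({"sensor": 3.0}))
        np.testing.assert_allclose(t3.finite_ratios(), 3.0 * table.finite_ratios(), rtol=1e-12)


class TestNormalizePerSpecimen:
    def test_factor_is_arithmetic_mean(self):
        table = hm.normalize_per_specimen(table_from_ratios([2.0, 4.0, 6.0]))
        np.testing.assert_allclose(
            np.sort(table.records["normalized_ratio"]), [0.5, 1.0, 1.5]
        )
        assert table.normalization == {"scheme": "per_specimen", "factor": 4.0}

    def test_equal_ratios_normalize_to_one(self):
        table = hm.normalize_per_specimen(table_from_ratios([3.3] * 5))
        np.testing.assert_allclose(table.records["normalized_ratio"], 1.0)

    def test_mean_normalized_is_one(self, rng):
        ratios = rng.lognormal(0, 0.4, size=257)
        table = hm.normalize_per_specimen(table_from_ratios(ratios))
        assert abs(table.records["normalized_ratio"].mean() - 1.0) < 1e-9

    def test_idempotent_after_one_application(self, rng):
        table = hm.normalize_per_specimen(table_from_ratios(rng.lognormal(0, 0.3, 50)))
        refactored = hm.normalize_per_specimen(
            table_from_ratios(table.records["normalized_ratio"].to_numpy())
        )
        assert refactored.normalization["factor"] == pytest.approx(1.0, abs=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            hm.normalize_per_specimen(table_from_ratios([]))


class TestNormalizeToReferenceCondition:
    def test_single_pooled_factor(self):
        normoxic = table_from_ratios([0.7, 0.9], specimen_id="n1")  # pooled mean 0.8
        hypoxic = table_from_ratios([1.2, 1.2], specimen_id="h1")
        out = hm.normalize_to_reference_condition([normoxic, hypoxic], {"n1"})
        h = [t for t in out if t.specimen_id == "h1"][0]
        np.testing.assert_allclose(h.records["normalized_ratio"], 1.5)

    def test_reference_pool_normalizes_to_one(self, rng):
        tabs = [
            table_from_ratios(rng.lognormal(0, 0.2, 40), specimen_id=f"n{i}")
            for i in range(3)
        ]
        out = hm.normalize_to_reference_condition(tabs, {"n0", "n1", "n2"})
        pooled = np.concatenate([t.records["normalized_ratio"].to_numpy() for t in out])
        assert pooled.mean() == pytest.approx(1.0, abs=1e-9)

    def test_condition_recovery_with_ground_truth(self):
        """Three O2 conditions with true mean ratios 1.4/1.0/0.7 x reference."""
        tables = []
        for base, (cond, true_mean, n) in enumerate(
            (("hx", 1.4, 3), ("nx", 1.0, 3), ("ox", 0.7, 3))
        ):
            for i in range(n):
                params = hm.SynthParams(
                    n_nuclei=60, n_sections=2, height=160, width=160,
                    regions=(hm.RegionSpec("embryo", (0.0, 1.0), true_mean),),
                    seed=1000 * base + i,
                )
                stack, _, _ = hm.generate_specimen(params)
                mask = hm.segment_nuclei(stack, "reference", SYNTH_SEG_PARAMS)
                tables.append(
                    hm.measure_blobs(mask, stack, specimen_id=f"{cond}{i}")
                )
        ref_ids = {t.specimen_id for t in tables if t.specimen_id.startswith("nx")}
        out = hm.normalize_to_reference_condition(tables, ref_ids)
        for cond, expected in (("hx", 1.4), ("nx", 1.0), ("ox", 0.7)):
            means = [
                t.records.loc[t.records["valid"], "normalized_ratio"].mean()
                for t in out if t.specimen_id.startswith(cond)
            ]
            assert np.mean(means) == pytest.approx(expected, rel=0.05)

    def test_empty_reference_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            hm.normalize_to_reference_condition([table_from_ratios([1.0])], set())


class TestHeatmap:
    def _setup(self, values, lo=0.0, hi=2.0):
        n = len(values)
        lab = np.zeros((1, 4, 4 * n), dtype=np.int32)
        for i in range(n):
            lab[0, 1:3, 4 * i + 1 : 4 * i + 3] = i + 1
        mask = hm.LabelMask(lab)
        table = table_from_ratios(values)
        return mask, table, hm.render_heatmap(mask, table, value_range=(lo, hi))

    def test_end_colors_at_range_bounds(self):
        mask, table, rgb = self._setup([0.0, 2.0])
        colors = hm.ratiometrics._lut_colors("coolwarm")
        np.testing.assert_array_equal(rgb[0, 1, 1], colors[0])
        np.testing.assert_array_equal(rgb[0, 1, 5], colors[-1])

    def test_out_of_range_clamped(self, caplog):
        with caplog.at_level("INFO"):
            mask, table, rgb = self._setup([-5.0, 7.0])
        colors = hm.ratiometrics._lut_colors("coolwarm")
        np.testing.assert_array_equal(rgb[0, 1, 1], colors[0])
        np.testing.assert_array_equal(rgb[0, 1, 5], colors[-1])
        assert any("clamped" in r.message for r in caplog.records)

    def test_background_stays_black(self):
        _, _, rgb = self._setup([1.0])
        assert rgb[0, 0, 0].tolist() == [0, 0, 0]

    def test_invalid_range_rejected(self):
        mask, table, _ = self._setup([1.0])
        with pytest.raises(ValueError):
            hm.render_heatmap(mask, table, value_range=(2.0, 2.0))
        with pytest.raises(ValueError):
            render_legend((1.0, 1.0))

    def test_legend_spans_lut(self):
        leg = render_legend((0.0, 2.0), size=(8, 64))
        assert leg.shape == (8, 64, 3)
        assert not np.array_equal(leg[:, 0], leg[:, -1])
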