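"""Regional analysis: assign nuclei to anatomical regions, build ratio
frequency distributions, and compare regions or compartments.

Region comparisons are reported on two bases: pooling nuclei across
specimens (large effective n, as in per-nucleus frequency histograms) and
per-specimen means (one value per specimen, robust to pseudo-replication).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .image_io import RegionMask
from .ratiometrics import BlobTable

__all__ = [
    "SummaryStats",
    "RegionSummary",
    "TestResult",
    "assign_regions",
    "ratio_histogram",
    "mann_whitney_u",
    "t_test",
    "compartment_ratio",
    "normalize_compartment_ratios",
    "summarize_regions",
    "write_summary",
]

log = logging.getLogger(__name__)


def assign_regions(table: BlobTable, region_mask: RegionMask, stack_shape=None) -> BlobTable:
    """Assign each blob the region name at its centroid voxel.

    Centroids falling on label 0 are ``"unassigned"``.
    """
    if stack_shape is not None and tuple(stack_shape) != region_mask.shape:
        raise ValueError(
            f"region mask shape {region_mask.shape} does not match stack shape {tuple(stack_shape)}"
        )
    df = table.records.copy()
    if len(df):
        secs = df["section"].to_numpy(dtype=int)
        if secs.max(initial=0) >= region_mask.shape[0]:
            raise ValueError("blob section index exceeds region mask depth")
        rows = np.clip(np.round(df["centroid_row"].to_numpy()).astype(int), 0, region_mask.shape[1] - 1)
        cols = np.clip(np.round(df["centroid_col"].to_numpy()).astype(int), 0, region_mask.shape[2] - 1)
        labels = region_mask.labels[secs, rows, cols]
        names = np.array(
            [region_mask.names.get(int(l), RegionMask.UNASSIGNED) if l else RegionMask.UNASSIGNED
             for l in labels],
            dtype=object,
        )
        df["region"] = names
    from dataclasses import replace

    return replace(table, records=df)


def ratio_histogram(table: BlobTable, region: str, bin_edges: np.ndarray) -> np.ndarray:
    """Frequency counts of normalized ratios per bin.

    Bins are half-open ``[edge_i, edge_{i+1})`` with the last bin closed —
    a value exactly on an interior edge counts to the right-hand bin.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly ascending with at least two values")
    values = table.region_values(region)
    if values.size == 0:
        raise ValueError(f"no records in region {region!r}")
    counts, _ = np.histogram(values, bins=edges)
    return counts


def mann_whitney_u(sample_a, sample_b, sidedness: str = "two_sided") -> tuple[float, float]:
    """Mann–Whitney U with midrank ties.

    The p-value is exact (full enumeration of rank assignments) when the
    combined sample size is at most 12 and there are no ties; otherwise the
    normal approximation with tie and continuity corrections is used.
    Returns ``(U_a, p)`` where ``U_a`` is the statistic of the first sample.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    if sidedness != "two_sided":
        raise ValueError("only two_sided tests are supported")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def t_test(sample_a, sample_b, variant: str = "student") -> tuple[float, float]:
    """Two-sided two-sample t-test (pooled-variance Student or Welch)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two values")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero variance in both samples")
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)


def compartment_ratio(sensor_image: np.ndarray, roi_a: np.ndarray, roi_p: np.ndarray) -> float:
    """Posterior/anterior ratio of mean sensor intensities.

    ``roi_a`` and ``roi_p`` are boolean pixel masks of the anterior
    (control) and posterior (experimental) compartment ROIs; same-size
    ROIs are recommended.
    """
    img = np.asarray(sensor_image, dtype=float)
    roi_a = np.asarray(roi_a, dtype=bool)
    roi_p = np.asarray(roi_p, dtype=bool)
    if not roi_a.any() or not roi_p.any():
        raise ValueError("ROIs must be non-empty")
    mean_a = float(img[roi_a].mean())
    mean_p = float(img[roi_p].mean())
    if mean_a == 0:
        raise ValueError("anterior ROI mean is zero")
    return mean_p / mean_a


def normalize_compartment_ratios(ratios: dict[str, list], control: str) -> dict[str, np.ndarray]:
    """Divide each genotype's compartment ratios by the control genotype's mean."""
    if control not in ratios or len(ratios[control]) == 0:
        raise ValueError(f"control genotype {control!r} missing or empty")
    factor = float(np.mean(np.asarray(ratios[control], dtype=float)))
    return {g: np.asarray(v, dtype=float) / factor for g, v in ratios.items()}


@dataclass
class RegionSummary:
    n_blobs: int
    mean_normalized_ratio: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    specimen_means: dict[str, float] = field(default_factory=dict)


@dataclass
class TestResult:
    region_a: str
    region_b: str
    test: str  # mann_whitney_u | t_test
    basis: str  # pooled | per_specimen
    statistic: float
    p_value: float
    sidedness: str = "two_sided"


@dataclass
class SummaryStats:
    """Per-region summaries and two-sample comparisons."""

    per_region: dict[str, RegionSummary]
    tests: list[TestResult]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": name, "n_blobs": s.n_blobs, "mean_normalized_ratio": s.mean_normalized_ratio}
            for name, s in self.per_region.items()
        ]
        return pd.DataFrame(rows)

    def report(self) -> str:
        lines = ["Region summary", "=============="]
        for name, s in self.per_region.items():
            lines.append(f"{name}: n={s.n_blobs}, mean normalized ratio={s.mean_normalized_ratio:.4f}")
            edges = ", ".join(f"{e:.3g}" for e in s.hist_edges)
            counts = ", ".join(str(int(c)) for c in s.hist_counts)
            lines.append(f"  histogram edges: [{edges}]")
            lines.append(f"  histogram counts: [{counts}]")
            for spec, m in s.specimen_means.items():
                lines.append(f"  specimen {spec}: mean={m:.4f}")
        if self.tests:
            lines += ["", "Two-sample tests", "----------------"]
            for t in self.tests:
                lines.append(
                    f"{t.region_a} vs {t.region_b} [{t.test}, {t.basis}]: "
                    f"statistic={t.statistic:.4g}, p={t.p_value:.4g} ({t.sidedness})"
                )
        return "\n".join(lines) + "\n"


def _pooled_values(tables: list[BlobTable], region: str) -> np.ndarray:
    vals = [t.region_values(region) for t in tables]
    vals = [v for v in vals if v.size]
    return np.concatenate(vals) if vals else np.array([])


def summarize_regions(
    tables: BlobTable | list[BlobTable],
    bin_edges: np.ndarray | None = None,
    n_bins: int = 20,
) -> SummaryStats:
    """Summarise normalized ratios per region and compare every region pair.

    For each pair both the Mann–Whitney U test and the Student t-test are
    run, each on the pooled per-nucleus values and (when at least two
    specimens contribute to both regions) on per-specimen means.
    """
    if isinstance(tables, BlobTable):
        tables = [tables]
    regions = sorted(
        {r for t in tables for r in t.records.loc[t.records["valid"], "region"].unique()}
    )
    regions = [r for r in regions if _pooled_values(tables, r).size > 0]
    if not regions:
        raise ValueError("no regions with finite ratios to summarise")
    all_vals = np.concatenate([_pooled_values(tables, r) for r in regions])
    if bin_edges is None:
        lo, hi = float(all_vals.min()), float(all_vals.max())
        span = (hi - lo) or 1.0
        bin_edges = np.linspace(lo - 1e-9 * span, hi + 1e-9 * span, n_bins + 1)
    bin_edges = np.asarray(bin_edges, dtype=float)

    per_region: dict[str, RegionSummary] = {}
    for r in regions:
        vals = _pooled_values(tables, r)
        counts, _ = np.histogram(vals, bins=bin_edges)
        spec_means = {
            t.specimen_id: float(np.mean(t.region_values(r)))
            for t in tables
            if t.region_values(r).size
        }
        per_region[r] = RegionSummary(
            n_blobs=int(vals.size),
            mean_normalized_ratio=float(vals.mean()),
            hist_edges=bin_edges,
            hist_counts=counts,
            specimen_means=spec_means,
        )

    tests: list[TestResult] = []
    for i, ra in enumerate(regions):
        for rb in regions[i + 1 :]:
            va, vb = _pooled_values(tables, ra), _pooled_values(tables, rb)
            u, p = mann_whitney_u(va, vb)
            tests.append(TestResult(ra, rb, "mann_whitney_u", "pooled", u, p))
            if va.size >= 2 and vb.size >= 2:
                t, p = t_test(va, vb, "student")
                tests.append(TestResult(ra, rb, "t_test", "pooled", t, p))
            ma = list(per_region[ra].specimen_means.values())
            mb = list(per_region[rb].specimen_means.values())
            if len(ma) >= 2 and len(mb) >= 2:
                u, p = mann_whitney_u(ma, mb)
                tests.append(TestResult(ra, rb, "mann_whitney_u", "per_specimen", u, p))
                t, p = t_test(ma, mb, "student")
                tests.append(TestResult(ra, rb, "t_test", "per_specimen", t, p))
    return SummaryStats(per_region=per_region, tests=tests)


def write_summary(stats_obj: SummaryStats, csv_path, report_path=None) -> None:
    """Write the per-region table as CSV and (optionally) the text report."""
    stats_obj.to_frame().to_csv(csv_path, index=False)
    if report_path is not None:
        with open(report_path, "w") as fh:
            fh.write(stats_obj.report())
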