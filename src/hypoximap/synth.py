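"""Synthetic two-channel specimens with known ground truth.

The generator emulates the image structure the ratiometric workflow sees: a
nuclear reference channel of bright disks (one nucleus cross-section per
disk) over a dim, optionally tilted background, and a sensor channel tied
multiplicatively to each nucleus's reference signal through its region's
true ratio — exactly the design assumption of a ratiometric reporter, where
the sensor/reference ratio depends only on the O₂-dependent turnover of the
sensor. Per-nucleus brightness is lognormal; cell-to-cell ratio jitter is
lognormal; noise is Poisson (photon shot) plus additive Gaussian (read),
applied independently per channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .image_io import RegionMask, Stack

__all__ = [
    "RegionSpec",
    "NoiseParams",
    "SynthParams",
    "GroundTruth",
    "generate_specimen",
    "generate_two_region_brain",
    "generate_tube_phantom",
    "score_detection",
    "match_blobs_to_truth",
]


@dataclass(frozen=True)
class RegionSpec:
    """A lateral image region with its own true sensor/reference ratio.

    ``col_span`` is the (lo, hi) fractional column extent of the region;
    ``n_nuclei`` fixes the nucleus count placed in it (None = allocate a
    share of the specimen total proportional to region width).
    """

    name: str
    col_span: tuple[float, float]
    true_ratio: float
    n_nuclei: int | None = None

    def __post_init__(self) -> None:
        if self.true_ratio <= 0:
            raise ValueError("true_ratio must be positive")
        lo, hi = self.col_span
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("col_span must be an increasing pair within [0, 1]")


@dataclass(frozen=True)
class NoiseParams:
    """Poisson-Gaussian noise model.

    ``poisson_gain`` is the intensity units per detected photon (0 disables
    shot noise); ``gaussian_sigma`` the additive read-noise s.d. in
    intensity units (0 disables).
    """

    poisson_gain: float = 1.0
    gaussian_sigma: float = 5.0


@dataclass(frozen=True)
class SynthParams:
    """Study conditions of a synthetic specimen.

    Defaults describe a scaled-down brain-hemisphere-like specimen: 8
    sections of 192×192 px, 200 nuclei of radius 4-6 px, reference
    intensity 3000 (lognormal sigma 0.2, emulating expression variability)
    over a background of 100 with a mild lateral gradient, nucleus/background
    contrast well above 5:1.
    """

    n_sections: int = 8
    height: int = 192
    width: int = 192
    n_nuclei: int = 200
    nucleus_radius_range: tuple[float, float] = (4.0, 6.0)
    regions: tuple[RegionSpec, ...] = (RegionSpec("specimen", (0.0, 1.0), 1.0),)
    reference_intensity: tuple[float, float] = (3000.0, 0.2)  # mean, lognormal sigma
    background: tuple[float, float] = (100.0, 20.0)  # constant, linear gradient amplitude
    noise: NoiseParams = field(default_factory=NoiseParams)
    ratio_jitter_sigma: float = 0.05
    spacing_xy: float = 0.5
    spacing_z: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleus_radius_range[0] < 2:
            raise ValueError("nucleus radii must be at least 2 px")
        if self.nucleus_radius_range[0] > self.nucleus_radius_range[1]:
            raise ValueError("invalid nucleus_radius_range")


@dataclass
class GroundTruth:
    """One row per generated nucleus: position, radius, region, true ratio."""

    nuclei: pd.DataFrame  # nucleus_id, section, row, col, radius, region, true_ratio, ref_intensity

    def __len__(self) -> int:
        return len(self.nuclei)


_MAX_ATTEMPTS_PER_NUCLEUS = 2000


def _allocate_counts(params: SynthParams) -> list[int]:
    explicit = [r.n_nuclei for r in params.regions]
    if all(n is not None for n in explicit):
        return [int(n) for n in explicit]  # type: ignore[arg-type]
    widths = np.array([hi - lo for (lo, hi) in (r.col_span for r in params.regions)])
    shares = widths / widths.sum()
    counts = np.floor(shares * params.n_nuclei).astype(int)
    for i in np.argsort(-(shares * params.n_nuclei - counts))[: params.n_nuclei - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def _place_nuclei(params: SynthParams, rng: np.random.Generator) -> pd.DataFrame:
    """Rejection-sample non-overlapping disk centers (per section)."""
    r_lo, r_hi = params.nucleus_radius_range
    margin_edge = 2.0
    rows: list[dict] = []
    placed: dict[int, list[tuple[float, float, float]]] = {s: [] for s in range(params.n_sections)}
    counts = _allocate_counts(params)
    nid = 1
    for region, n_region in zip(params.regions, counts):
        c_lo = region.col_span[0] * params.width
        c_hi = region.col_span[1] * params.width
        for _ in range(n_region):
            radius = float(rng.uniform(r_lo, r_hi))
            ok = False
            for _ in range(_MAX_ATTEMPTS_PER_NUCLEUS):
                s = int(rng.integers(0, params.n_sections))
                row = float(rng.uniform(radius + margin_edge, params.height - radius - margin_edge))
                col = float(rng.uniform(
                    max(c_lo + radius + margin_edge, radius + margin_edge),
                    min(c_hi - radius - margin_edge, params.width - radius - margin_edge),
                ))
                # minimum center distance = sum of radii + 1 within a section
                if all(
                    (row - r0) ** 2 + (col - c0) ** 2 >= (radius + rad0 + 1.0) ** 2
                    for r0, c0, rad0 in placed[s]
                ):
                    ok = True
                    break
            if not ok:
                raise RuntimeError(
                    f"could not place nucleus {nid} without overlap after "
                    f"{_MAX_ATTEMPTS_PER_NUCLEUS} attempts; reduce n_nuclei or enlarge the image"
                )
            placed[s].append((row, col, radius))
            ratio = region.true_ratio * float(
                rng.lognormal(mean=0.0, sigma=params.ratio_jitter_sigma)
            ) if params.ratio_jitter_sigma > 0 else region.true_ratio
            mean_i, sigma_i = params.reference_intensity
            intensity = float(mean_i * rng.lognormal(mean=0.0, sigma=sigma_i)) if sigma_i > 0 else mean_i
            rows.append(
                {
                    "nucleus_id": nid,
                    "section": s,
                    "row": row,
                    "col": col,
                    "radius": radius,
                    "region": region.name,
                    "true_ratio": ratio,
                    "ref_intensity": intensity,
                }
            )
            nid += 1
    return pd.DataFrame(rows)


def _region_mask(params: SynthParams) -> RegionMask:
    labels = np.zeros((params.n_sections, params.height, params.width), dtype=np.int32)
    names: dict[int, str] = {}
    for i, region in enumerate(params.regions, start=1):
        lo = int(round(region.col_span[0] * params.width))
        hi = int(round(region.col_span[1] * params.width))
        labels[:, :, lo:hi] = i
        names[i] = region.name
    return RegionMask(labels, names)


def generate_specimen(params: SynthParams | None = None) -> tuple[Stack, RegionMask, GroundTruth]:
    """Generate a synthetic two-channel stack, its region mask and ground truth.

    Deterministic for a fixed ``params.seed``. With noise disabled and zero
    background, the measured ratio of every perfectly segmented nucleus
    equals its true ratio exactly (sensor = reference × ratio pixelwise).
    """
    params = params or SynthParams()
    rng = np.random.default_rng(params.seed)
    nuclei = _place_nuclei(params, rng)

    shape = (params.n_sections, params.height, params.width)
    signal_ref = np.zeros(shape, dtype=np.float64)
    signal_sen = np.zeros(shape, dtype=np.float64)
    yy, xx = np.mgrid[0 : params.height, 0 : params.width].astype(np.float64)
    for rec in nuclei.itertuples():
        disk = (yy - rec.row) ** 2 + (xx - rec.col) ** 2 <= rec.radius**2
        signal_ref[rec.section][disk] += rec.ref_intensity
        signal_sen[rec.section][disk] += rec.ref_intensity * rec.true_ratio

    bg_const, bg_grad = params.background
    background = bg_const + bg_grad * (xx / max(params.width - 1, 1))
    ref = signal_ref + background
    sen = signal_sen + background

    noise = params.noise
    for img in (ref, sen):
        if noise.poisson_gain > 0:
            img[:] = rng.poisson(img / noise.poisson_gain) * noise.poisson_gain
        if noise.gaussian_sigma > 0:
            img += rng.normal(0.0, noise.gaussian_sigma, size=img.shape)
        np.clip(img, 0.0, None, out=img)

    stack = Stack(
        {"reference": ref, "sensor": sen},
        spacing_xy=params.spacing_xy,
        spacing_z=params.spacing_z,
    )
    return stack, _region_mask(params), GroundTruth(nuclei)


def generate_two_region_brain(
    true_ratio_a: float = 0.83,
    true_ratio_b: float = 1.11,
    n_per_region: int = 200,
    seed: int = 0,
    n_sections: int = 10,
    height: int = 160,
    width: int = 224,
    **overrides,
) -> tuple[Stack, RegionMask, GroundTruth]:
    """Two lateral regions mimicking the central brain (medial, densely
    tracheolated, low ratio) and optic lobe (lateral, sparsely tracheolated,
    high ratio) of a larval brain hemisphere."""
    regions = (
        RegionSpec("CB", (0.0, 0.5), true_ratio_a, n_nuclei=n_per_region),
        RegionSpec("OL", (0.5, 1.0), true_ratio_b, n_nuclei=n_per_region),
    )
    params = SynthParams(
        n_sections=n_sections,
        height=height,
        width=width,
        n_nuclei=2 * n_per_region,
        regions=regions,
        seed=seed,
        **overrides,
    )
    return generate_specimen(params)


def generate_tube_phantom(
    shape: str,
    radius: float | None = None,
    length: float | None = None,
    side: float | None = None,
    spacing_xy: float = 1.0,
    spacing_z: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Voxelized solid (sphere, cube or cylinder) plus its analytic area.

    Sizes are in µm; the voxelization respects the anisotropic spacing so
    the same physical solid can be generated on different grids. The
    smallest dimension must span at least 8 voxels.
    """
    sp = np.array([spacing_z, spacing_xy, spacing_xy])
    if shape == "sphere":
        if radius is None:
            raise ValueError("sphere needs a radius")
        if np.any(radius / sp < 4):
            raise ValueError("degenerate size: sphere must span at least 8 voxels")
        half = np.ceil(radius / sp).astype(int) + 3
        z, y, x = np.mgrid[-half[0]:half[0] + 1, -half[1]:half[1] + 1, -half[2]:half[2] + 1]
        mask = (z * sp[0]) ** 2 + (y * sp[1]) ** 2 + (x * sp[2]) ** 2 <= radius**2
        return mask, 4.0 * math.pi * radius**2
    if shape == "cube":
        if side is None:
            raise ValueError("cube needs a side")
        if np.any(side / sp < 8):
            raise ValueError("degenerate size: cube must span at least 8 voxels")
        n = np.ceil(side / sp).astype(int)
        padded = n + 8
        mask = np.zeros(padded, dtype=bool)
        # odd trimming keeps the cube centred; exact voxel count n_i per axis
        starts = (padded - n) // 2
        mask[starts[0]:starts[0] + n[0], starts[1]:starts[1] + n[1], starts[2]:starts[2] + n[2]] = True
        sides = n * sp  # realised physical side lengths
        area = 2.0 * (sides[0] * sides[1] + sides[0] * sides[2] + sides[1] * sides[2])
        return mask, float(area)
    if shape == "cylinder":
        if radius is None or length is None:
            raise ValueError("cylinder needs radius and length")
        if radius / spacing_xy < 4 or length / spacing_z < 8:
            raise ValueError("degenerate size: cylinder must span at least 8 voxels")
        n_z = int(round(length / spacing_z))
        half = int(np.ceil(radius / spacing_xy)) + 3
        z, y, x = np.mgrid[0:n_z + 8, -half:half + 1, -half:half + 1]
        mask = ((y * spacing_xy) ** 2 + (x * spacing_xy) ** 2 <= radius**2) & (z >= 4) & (z < 4 + n_z)
        real_length = n_z * spacing_z
        return mask, float(2 * math.pi * radius * real_length + 2 * math.pi * radius**2)
    raise ValueError(f"unknown phantom shape {shape!r}")


def score_detection(
    truth: GroundTruth,
    blob_table,
    max_center_distance: float | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Match detected blobs to ground-truth nuclei; return (recall, precision, matches).

    A blob matches a nucleus when it lies in the nucleus's section and its
    centroid is within the nucleus radius (or ``max_center_distance``) of
    the true center; matching is greedy, nearest first, one-to-one.
    """
    gt = truth.nuclei
    det = blob_table.records
    pairs: list[tuple[float, int, int]] = []
    for sec in sorted(set(gt["section"]) | set(det["section"])):
        g = gt[gt["section"] == sec]
        d = det[det["section"] == sec]
        if not len(g) or not len(d):
            continue
        dr = d["centroid_row"].to_numpy()[:, None] - g["row"].to_numpy()[None, :]
        dc = d["centroid_col"].to_numpy()[:, None] - g["col"].to_numpy()[None, :]
        dist = np.hypot(dr, dc)
        limit = (
            np.full(len(g), max_center_distance)
            if max_center_distance is not None
            else g["radius"].to_numpy()
        )
        di, gi = np.nonzero(dist <= limit[None, :])
        for a, b in zip(di, gi):
            pairs.append((float(dist[a, b]), int(d.index[a]), int(g.index[b])))
    pairs.sort()
    used_d: set[int] = set()
    used_g: set[int] = set()
    matches = []
    for dist_v, di, gi in pairs:
        if di in used_d or gi in used_g:
            continue
        used_d.add(di)
        used_g.add(gi)
        matches.append(
            {
                "blob_id": int(det.loc[di, "blob_id"]),
                "nucleus_id": int(gt.loc[gi, "nucleus_id"]),
                "distance": dist_v,
                "true_ratio": float(gt.loc[gi, "true_ratio"]),
                "region": gt.loc[gi, "region"],
            }
        )
    n_match = len(matches)
    recall = n_match / len(gt) if len(gt) else 1.0
    precision = n_match / len(det) if len(det) else 1.0
    return recall, precision, pd.DataFrame(matches)


def match_blobs_to_truth(truth: GroundTruth, blob_table) -> pd.DataFrame:
    """Blob records joined with their matched ground-truth nuclei."""
    _, _, matches = score_detection(truth, blob_table)
    return matches.merge(blob_table.records, on="blob_id", how="left")


def write_ground_truth(truth: GroundTruth, path) -> None:
    truth.nuclei.to_csv(path, index=False)


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth(pd.read_csv(path))
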