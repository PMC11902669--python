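"""Spatial-tuning analysis of network units.

The pipeline is the standard one from the rodent grid-cell literature:

1. ratemap — mean activation per spatial bin over the arena (default 32x32);
2. spatial autocorrelogram (SAC) — Pearson correlation between the ratemap
   and every integer (dx, dy) shift of itself, over the bins where both
   copies are defined;
3. gridness — mask the SAC to an annulus that excludes the central peak,
   rotate the annulus by 30/60/90/120/150 degrees, and score
   min(r60, r120) - max(r30, r90, r150); a hexagonal field keeps its
   structure under 60-degree rotations and loses it under 30/90/150, so
   large positive scores mean grid-like tuning.  The outer annulus radius is
   swept and the best score reported;
4. head-direction resultant length and border score complete the unit
   classification (grid-like / border-like / hd-like / untuned).

Units with activations clipped below zero are treated as silent; linear-layer
activations can be negative, and only the non-negative part is meaningful as
a firing-rate analogue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .arena import wrap_angle

__all__ = [
    "Ratemap",
    "SpatialAutocorrelogram",
    "GridnessResult",
    "TuningReport",
    "AnalysisError",
    "compute_ratemap",
    "autocorrelogram",
    "gridness",
    "hd_tuning",
    "border_score",
    "rank_units",
    "plot_unit_grid",
    "GRIDNESS_ANGLES",
]

GRIDNESS_ANGLES = (30, 60, 90, 120, 150)


class AnalysisError(ValueError):
    """Input does not support the requested analysis."""


@dataclass
class Ratemap:
    """Mean activation per spatial bin; NaN marks unvisited bins."""

    values: np.ndarray  # (bins, bins), NaN where occupancy == 0
    occupancy: np.ndarray  # (bins, bins) sample counts
    extent: float  # arena half-width (m)

    @property
    def bins(self) -> int:
        return self.values.shape[0]

    @property
    def bin_width(self) -> float:
        return 2.0 * self.extent / self.bins


@dataclass
class SpatialAutocorrelogram:
    values: np.ndarray  # (2B-1, 2B-1) Pearson coefficients, NaN where invalid
    valid_mask: np.ndarray  # same shape, bool

    @property
    def center(self) -> tuple[int, int]:
        return (self.values.shape[0] // 2, self.values.shape[1] // 2)


@dataclass
class GridnessResult:
    score: float
    rotation_correlations: dict[int, float]
    inner_radius: int
    outer_radius: int


@dataclass
class TuningReport:
    table: pd.DataFrame  # one row per unit, sorted by descending gridness
    thresholds: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def compute_ratemap(
    positions: np.ndarray,
    activations: np.ndarray,
    bins: int = 32,
    extent: float = 3.2,
) -> Ratemap:
    """Bin positions over [-extent, extent]^2 and average the activations."""
    positions = np.asarray(positions, float)
    activations = np.asarray(activations, float)
    if positions.size == 0:
        raise AnalysisError("no samples to bin")
    edges = np.linspace(-extent, extent, bins + 1)
    # index [iy, ix] so the map renders with y as rows
    occ, _, _ = np.histogram2d(positions[:, 1], positions[:, 0], bins=(edges, edges))
    tot, _, _ = np.histogram2d(
        positions[:, 1], positions[:, 0], bins=(edges, edges), weights=activations
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(occ > 0, tot / np.maximum(occ, 1), np.nan)
    return Ratemap(values, occ.astype(int), extent)


def autocorrelogram(
    ratemap: Ratemap, min_overlap: int = 20, crop_circle: bool = True
) -> SpatialAutocorrelogram:
    """Pearson correlation of the ratemap with all integer shifts of itself.

    Shifts whose overlap region has fewer than ``min_overlap`` visited bins,
    or where either copy is constant over the overlap, are masked invalid.
    All shift correlations are computed at once from six cross-correlation
    maps of the masked ratemap (counts, sums, sums of squares and products).

    With ``crop_circle`` the ratemap is first restricted to the inscribed
    disk.  On the full square the per-shift overlap windows are rectangles
    whose shape depends on the shift *direction*, which imprints a spurious
    four-fold symmetry on the correlogram (a perfectly radial field would
    correlate better with its 90-degree rotation than with any other); disk
    overlaps depend on the shift magnitude only, removing the bias.
    """
    values = ratemap.values
    if crop_circle:
        b = ratemap.bins
        centers = -ratemap.extent + (np.arange(b) + 0.5) * ratemap.bin_width
        rr = centers[None, :] ** 2 + centers[:, None] ** 2
        values = np.where(rr <= ratemap.extent**2, values, np.nan)
    a = np.nan_to_num(values, nan=0.0)
    m = np.isfinite(values).astype(float)
    if m.sum() < min_overlap:
        raise AnalysisError("too few visited bins for an autocorrelogram")

    corr = lambda u, v: signal.correlate(u, v, mode="full", method="auto")
    n = corr(m, m)
    sx = corr(a, m)
    sy = corr(m, a)
    sxy = corr(a, a)
    sxx = corr(a * a, m)
    syy = corr(m, a * a)

    n_r = np.round(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        var_x = n * sxx - sx * sx
        var_y = n * syy - sy * sy
        denom = np.sqrt(np.clip(var_x, 0, None) * np.clip(var_y, 0, None))
        values = cov / denom
    valid = (n_r >= min_overlap) & (denom > 1e-10 * np.maximum(n_r, 1))
    values = np.where(valid, np.clip(values, -1.0, 1.0), np.nan)
    if not valid.any():
        raise AnalysisError("autocorrelogram undefined everywhere (constant map?)")
    return SpatialAutocorrelogram(values, valid)


def _radial_distances(shape: tuple[int, int]) -> np.ndarray:
    cy, cx = shape[0] // 2, shape[1] // 2
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return np.hypot(yy - cy, xx - cx)


def _rotate_nan(values: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate about the map centre with bilinear interpolation.

    NaNs (invalid bins) poison any output bin whose interpolation stencil
    touches them, so masked data never leaks into the correlations.
    """
    cy, cx = values.shape[0] // 2, values.shape[1] // 2
    theta = np.deg2rad(angle_deg)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    yy, xx = np.mgrid[: values.shape[0], : values.shape[1]]
    y0, x0 = yy - cy, xx - cx
    # source coordinates: rotate backwards
    ys = cos_t * y0 - sin_t * x0 + cy
    xs = sin_t * y0 + cos_t * x0 + cx
    return ndimage.map_coordinates(
        values, [ys, xs], order=1, mode="constant", cval=np.nan
    )


def gridness(
    sac: SpatialAutocorrelogram,
    min_annulus_bins: int = 20,
    outer_radius_factor: float = 2.5,
) -> GridnessResult:
    """Hexagonality score of a spatial autocorrelogram.

    The central peak is excised by an inner radius set to the first radius at
    which the angularly averaged correlation drops below zero; the outer
    radius is swept from inner + 2 bins up to ``outer_radius_factor`` times
    the inner radius (clipped to the map edge) and the best (maximum) score
    over the sweep is reported, together with the rotation correlations at
    that radius.  The cap keeps the annulus around the first ring of
    correlogram peaks — the structure the score is meant to probe; far-field
    rings can realign in phase under rotation and award spuriously positive
    scores to plainly non-hexagonal (e.g. banded) patterns.
    """
    vals = sac.values
    center = sac.center
    if not np.isfinite(vals[center]):
        raise AnalysisError("autocorrelogram centre is undefined")
    rho = _radial_distances(vals.shape)
    max_radius = min(center)

    inner = None
    for r in range(1, max_radius):
        ring = vals[(rho >= r) & (rho < r + 1)]
        ring = ring[np.isfinite(ring)]
        if ring.size and ring.mean() < 0.0:
            inner = r
            break
    if inner is None or inner + 2 > max_radius:
        raise AnalysisError("central peak fills the autocorrelogram; no annulus")
    outer_hi = min(max_radius, max(inner + 2, int(round(outer_radius_factor * inner))))

    rotated = {ang: _rotate_nan(vals, ang) for ang in GRIDNESS_ANGLES}
    best: GridnessResult | None = None
    for outer in range(inner + 2, outer_hi + 1):
        ann = (rho > inner) & (rho <= outer)
        base = vals[ann]
        corrs: dict[int, float] = {}
        ok = True
        for ang, rot in rotated.items():
            other = rot[ann]
            good = np.isfinite(base) & np.isfinite(other)
            if good.sum() < min_annulus_bins:
                ok = False
                break
            b, o = base[good], other[good]
            bc, oc = b - b.mean(), o - o.mean()
            denom = np.sqrt((bc * bc).sum() * (oc * oc).sum())
            if denom <= 0:
                ok = False
                break
            corrs[ang] = float((bc * oc).sum() / denom)
        if not ok:
            continue
        score = min(corrs[60], corrs[120]) - max(corrs[30], corrs[90], corrs[150])
        if best is None or score > best.score:
            best = GridnessResult(float(score), corrs, inner, outer)
    if best is None:
        raise AnalysisError("no annulus with enough valid bins")
    return best


def hd_tuning(
    headings: np.ndarray,
    activations: np.ndarray,
    n_angle_bins: int = 36,
) -> tuple[float, float]:
    """Directional tuning strength of one unit.

    Builds an ``n_angle_bins``-bin tuning curve of mean activation versus
    heading (negative activations clipped to zero), then returns the length
    of the activation-weighted circular resultant vector (0 = untuned,
    1 = all mass in one direction) and the preferred angle in radians.
    """
    headings = np.asarray(headings, float)
    activations = np.clip(np.asarray(activations, float), 0.0, None)
    if headings.size == 0:
        raise AnalysisError("no samples")
    edges = np.linspace(-np.pi, np.pi, n_angle_bins + 1)
    idx = np.clip(np.digitize(headings, edges) - 1, 0, n_angle_bins - 1)
    sums = np.bincount(idx, weights=activations, minlength=n_angle_bins)
    counts = np.bincount(idx, minlength=n_angle_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        curve = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    total = curve.sum()
    if total <= 0:
        raise AnalysisError("unit is silent at every heading; tuning undefined")
    centers = (edges[:-1] + edges[1:]) / 2
    resultant = np.sum(curve * np.exp(1j * centers)) / total
    return float(np.abs(resultant)), float(wrap_angle(np.angle(resultant)))


def border_score(ratemap: Ratemap, wall_band: float = 0.4) -> float:
    """Contrast of wall-adjacent versus interior activation, in [-1, 1].

    Bins whose centre lies within ``wall_band`` metres of any wall form the
    wall region; the score is (wall mean - interior mean) / (wall mean +
    interior mean) on activations clipped at zero.  1 means all activity is
    at the walls, 0 none in particular, negative values central activity.
    """
    b = ratemap.bins
    centers = -ratemap.extent + (np.arange(b) + 0.5) * ratemap.bin_width
    dist_x = ratemap.extent - np.abs(centers)
    wall = (dist_x[None, :] <= wall_band) | (dist_x[:, None] <= wall_band)
    visited = np.isfinite(ratemap.values)
    vals = np.clip(np.nan_to_num(ratemap.values, nan=0.0), 0.0, None)
    n_wall = (wall & visited).sum()
    n_int = (~wall & visited).sum()
    if n_wall == 0 or n_int == 0:
        raise AnalysisError("one region has no visited bins; border score undefined")
    mean_wall = vals[wall & visited].mean()
    mean_int = vals[~wall & visited].mean()
    total = mean_wall + mean_int
    if total <= 0:
        return 0.0
    return float((mean_wall - mean_int) / total)


DEFAULT_THRESHOLDS = {"grid": 0.37, "hd": 0.5, "border": 0.5}


def rank_units(
    positions: np.ndarray,
    headings: np.ndarray,
    activations: np.ndarray,
    bins: int = 32,
    extent: float = 3.2,
    thresholds: dict | None = None,
    wall_band: float = 0.4,
) -> tuple[TuningReport, list[Ratemap], list[SpatialAutocorrelogram | None]]:
    """Score every unit and classify it by its strongest tuning.

    ``activations`` is (n_samples, n_units).  Returns the report (sorted by
    descending gridness, NaN last) plus the per-unit ratemaps and SACs in
    original unit order, for plotting.  Units whose SAC or annulus cannot be
    formed get NaN gridness and can only be tagged border/hd/untuned.
    """
    thresholds = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    activations = np.asarray(activations, float)
    n_units = activations.shape[1]
    rows = []
    ratemaps: list[Ratemap] = []
    sacs: list[SpatialAutocorrelogram | None] = []
    for u in range(n_units):
        act = activations[:, u]
        rm = compute_ratemap(positions, act, bins=bins, extent=extent)
        ratemaps.append(rm)
        g = np.nan
        inner = outer = -1
        sac = None
        try:
            sac = autocorrelogram(rm)
            res = gridness(sac)
            g, inner, outer = res.score, res.inner_radius, res.outer_radius
        except AnalysisError:
            pass
        sacs.append(sac)
        try:
            rl, pref = hd_tuning(headings, act)
        except AnalysisError:
            rl, pref = np.nan, np.nan
        try:
            bs = border_score(rm, wall_band=wall_band)
        except AnalysisError:
            bs = np.nan
        if np.isfinite(g) and g > thresholds["grid"]:
            tag = "grid-like"
        elif np.isfinite(bs) and bs > thresholds["border"]:
            tag = "border-like"
        elif np.isfinite(rl) and rl > thresholds["hd"]:
            tag = "hd-like"
        else:
            tag = "untuned"
        rows.append(
            {
                "unit": u,
                "gridness": g,
                "inner_radius": inner,
                "outer_radius": outer,
                "hd_resultant": rl,
                "hd_preferred_angle": pref,
                "border_score": bs,
                "tag": tag,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        "gridness", ascending=False, na_position="last", kind="mergesort"
    )
    report = TuningReport(
        table.reset_index(drop=True),
        thresholds=thresholds,
        config={"bins": bins, "extent": extent, "wall_band": wall_band},
    )
    return report, ratemaps, sacs


def plot_unit_grid(
    maps: list[np.ndarray],
    scores: list[float],
    path: str | Path,
    n_cols: int = 8,
    cmap: str = "jet",
) -> None:
    """Panel grid of per-unit maps with the score in parentheses."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(maps)
    n_cols = min(n_cols, max(n, 1))
    n_rows = (n + n_cols - 1) // n_cols
    fig, axes = plt.subplots(
        n_rows, n_cols, figsize=(1.6 * n_cols, 1.8 * n_rows), squeeze=False
    )
    for k, ax in enumerate(axes.ravel()):
        ax.set_axis_off()
        if k >= n:
            continue
        ax.imshow(maps[k], origin="lower", cmap=cmap, interpolation="nearest")
        ax.set_title(f"({scores[k]:.2f})", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
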