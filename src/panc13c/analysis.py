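"""Metabolite-ratio endpoints and group statistics.

The diagnostic readout is the [1-13C]alanine / [1-13C]lactate signal ratio
over a region of interest encompassing the pancreas, which falls with
disease progression.  This module turns metabolite maps into ratio maps and
ROI ratio reports, summarises longitudinal change as percent decreases,
quantifies repeatability as a coefficient of variation, and compares groups
by one-way ANOVA with Tukey's post hoc test, falling back to Kruskal-Wallis
with Dunn's post hoc test when the parametric assumptions fail their
screens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .recon import MetaboliteMaps

__all__ = [
    "ROI",
    "RatioReport",
    "LongitudinalSeries",
    "PercentChangeReport",
    "GroupComparison",
    "ratio_map",
    "roi_ratio",
    "percent_change",
    "coefficient_of_variation",
    "group_compare",
]


@dataclass(frozen=True)
class ROI:
    """A set of voxel coordinates on the reconstructed grid."""

    voxels: tuple[tuple[int, int], ...]
    label: str = "pancreas"

    def __post_init__(self) -> None:
        if len(self.voxels) == 0:
            raise ValueError("ROI must contain at least one voxel")

    @classmethod
    def from_mask(cls, mask: np.ndarray, label: str = "pancreas") -> "ROI":
        ys, xs = np.nonzero(mask)
        return cls(voxels=tuple(zip(ys.tolist(), xs.tolist())), label=label)

    def indices(self) -> tuple[np.ndarray, np.ndarray]:
        arr = np.asarray(self.voxels)
        return arr[:, 0], arr[:, 1]


@dataclass(frozen=True)
class RatioReport:
    """ROI metabolite signal ratios (dimensionless)."""

    ala_lac: float
    lac_ala: float
    ala_pyr: float
    lac_pyr: float
    roi_label: str
    n_voxels: int
    aggregation: str


@dataclass(frozen=True)
class LongitudinalSeries:
    """Ratio measurements of one subject over time (months)."""

    subject_id: str
    timepoints: tuple[float, ...]
    ratios: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.timepoints) != len(self.ratios):
            raise ValueError("timepoints and ratios must have equal length")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if any(r < 0 for r in self.ratios):
            raise ValueError("ratios must be >= 0")


@dataclass(frozen=True)
class PercentChangeReport:
    """Percent decreases of a longitudinal ratio series.

    Positive values are decreases, negative values increases.  ``undefined``
    flags intervals whose early ratio was zero.
    """

    consecutive: tuple[float, ...]  # between adjacent timepoints
    from_first: tuple[float, ...]  # first timepoint to each later one
    undefined: tuple[bool, ...]  # per consecutive interval


@dataclass(frozen=True)
class GroupComparison:
    """Result of a multi-group comparison with post hoc pairs."""

    method: str  # 'anova_tukey' or 'kruskal_dunn'
    statistic: float
    p_value: float
    posthoc: pd.DataFrame  # columns: group1, group2, p_value
    shapiro_p: dict[str, float]
    levene_p: float


def ratio_map(
    maps: MetaboliteMaps,
    numerator: str,
    denominator: str,
    mask_threshold: float = 0.05,
) -> np.ndarray:
    """Voxelwise numerator / denominator map, masked on pyruvate signal.

    Voxels where either the denominator map or the pyruvate map falls below
    ``mask_threshold`` times the maximal pyruvate signal are set to NaN
    (following the display convention of scaling signals to the maximal
    pyruvate signal, with a floor that suppresses noise-dominated ratios).
    """
    if not 0.0 <= mask_threshold < 1.0:
        raise ValueError("mask_threshold must lie in [0, 1)")
    for name in (numerator, denominator, "pyruvate"):
        if name not in maps.maps:
            raise ValueError(f"metabolite {name!r} missing from maps")
    num = maps.maps[numerator]
    den = maps.maps[denominator]
    pyr = maps.maps["pyruvate"]
    floor = mask_threshold * float(pyr.max())
    valid = (den > floor) & (pyr > floor)
    out = np.full(num.shape, np.nan)
    out[valid] = num[valid] / den[valid]
    return out


def roi_ratio(
    maps: MetaboliteMaps,
    roi: ROI,
    aggregation: str = "ratio_of_sums",
    mask_threshold: float = 0.05,
) -> RatioReport:
    """Metabolite signal ratios over a region of interest.

    ``ratio_of_sums`` divides the summed numerator signal over the ROI by the
    summed denominator signal (the default); ``mean_of_ratios`` averages the
    voxelwise ratio over unmasked ROI voxels.  Both conventions agree for a
    single voxel and for uniform maps.
    """
    if aggregation not in ("ratio_of_sums", "mean_of_ratios"):
        raise ValueError("aggregation must be 'ratio_of_sums' or 'mean_of_ratios'")
    shape = next(iter(maps.maps.values())).shape
    ys, xs = roi.indices()
    if ys.min() < 0 or xs.min() < 0 or ys.max() >= shape[0] or xs.max() >= shape[1]:
        raise ValueError("ROI extends outside the map bounds")

    def pair(numerator: str, denominator: str) -> float:
        if aggregation == "ratio_of_sums":
            num = float(maps.maps[numerator][ys, xs].sum())
            den = float(maps.maps[denominator][ys, xs].sum())
            if den <= 0:
                raise ValueError(
                    f"insufficient {denominator} signal in ROI {roi.label!r}"
                )
            return num / den
        rmap = ratio_map(maps, numerator, denominator, mask_threshold)
        vals = rmap[ys, xs]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"ROI {roi.label!r} is entirely masked; insufficient signal")
        return float(vals.mean())

    ala_lac = pair("alanine", "lactate")
    return RatioReport(
        ala_lac=ala_lac,
        lac_ala=1.0 / ala_lac if ala_lac > 0 else float("inf"),
        ala_pyr=pair("alanine", "pyruvate"),
        lac_pyr=pair("lactate", "pyruvate"),
        roi_label=roi.label,
        n_voxels=len(roi.voxels),
        aggregation=aggregation,
    )


def percent_change(series: LongitudinalSeries) -> PercentChangeReport:
    """Percent decrease of the ratio between timepoints.

    For an early ratio r_e and a later ratio r_l the decrease is
    100 * (r_e - r_l) / r_e; negative values indicate increases.  Reported
    for consecutive timepoint pairs and from the first timepoint to each
    later one.
    """
    r = series.ratios
    if len(r) < 2:
        raise ValueError("need at least 2 timepoints")

    def change(early: float, late: float) -> tuple[float, bool]:
        if early == 0:
            return float("nan"), True
        return 100.0 * (early - late) / early, False

    consecutive, undefined = zip(*(change(a, b) for a, b in zip(r, r[1:])))
    from_first = tuple(change(r[0], late)[0] for late in r[1:])
    return PercentChangeReport(
        consecutive=tuple(consecutive),
        from_first=from_first,
        undefined=tuple(undefined),
    )


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample coefficient of variation, percent: 100 * sd / mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("mean is zero; CV undefined")
    return float(100.0 * arr.std(ddof=1) / mean)


def _dunn_posthoc(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based post hoc test with tie correction.

    Pairwise z statistics on mean ranks of the pooled sample, two-sided
    normal p values with a Bonferroni adjustment over all pairs (the
    convention of the usual implementations of Dunn's test).
    """
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    start = 0
    for g in names:
        n = groups[g].size
        mean_rank[g] = float(ranks[start : start + n].mean())
        start += n
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for i, g1 in enumerate(names):
        for g2 in names[i + 1 :]:
            se = np.sqrt(var_base * (1.0 / groups[g1].size + 1.0 / groups[g2].size))
            z = (mean_rank[g1] - mean_rank[g2]) / se if se > 0 else 0.0
            p = min(1.0, 2.0 * stats.norm.sf(abs(z)) * m)
            rows.append({"group1": g1, "group2": g2, "statistic": z, "p_value": p})
    return pd.DataFrame(rows)


def group_compare(
    groups: Mapping[str, Iterable[float]],
    alpha_screen: float = 0.05,
) -> GroupComparison:
    """Compare groups by ANOVA/Tukey or Kruskal-Wallis/Dunn.

    The parametric branch runs when every group passes a Shapiro-Wilk
    normality screen and Levene's equal-variance test at ``alpha_screen``;
    otherwise the rank-based branch runs.  The branch taken is recorded in
    ``method``.
    """
    arrays = {k: np.asarray(list(v), dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")

    shapiro_p: dict[str, float] = {}
    for name, arr in arrays.items():
        if np.ptp(arr) == 0:
            shapiro_p[name] = 1.0  # degenerate constant group: screen passes
        else:
            shapiro_p[name] = float(stats.shapiro(arr).pvalue)
    values = list(arrays.values())
    if all(np.ptp(v) == 0 for v in values):
        levene_p = 1.0
    else:
        levene_p = float(stats.levene(*values).pvalue)

    parametric = all(p > alpha_screen for p in shapiro_p.values()) and (
        levene_p > alpha_screen
    )
    names = list(arrays)
    if parametric:
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            # constant identical groups are legal input and resolved below
            warnings.simplefilter("ignore")
            stat, p = stats.f_oneway(*values)
            res = stats.tukey_hsd(*values)
        rows = []
        for i, g1 in enumerate(names):
            for j, g2 in enumerate(names):
                if j <= i:
                    continue
                rows.append(
                    {
                        "group1": g1,
                        "group2": g2,
                        "statistic": float(res.statistic[i, j]),
                        "p_value": float(res.pvalue[i, j]),
                    }
                )
        posthoc = pd.DataFrame(rows)
        method = "anova_tukey"
    else:
        stat, p = stats.kruskal(*values)
        posthoc = _dunn_posthoc(arrays)
        method = "kruskal_dunn"
    if np.isnan(p):  # identical constant groups: no evidence of difference
        stat, p = 0.0, 1.0
    return GroupComparison(
        method=method,
        statistic=float(stat),
        p_value=float(p),
        posthoc=posthoc,
        shapiro_p=shapiro_p,
        levene_p=levene_p,
    )
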