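"""Group-level aggregation and per-scale comparison of anisotropy curves.

Groups of images (tissue categories, calibration ensembles) are compared the
way multiscale anisotropy studies present them: a per-scale median Fa curve
per group, and a per-scale two-sided Wilcoxon rank-sum (Mann-Whitney) test
between two groups' per-image Fa values, plotted against the 0.05 line.
P-values are raw by default; Benjamini-Hochberg adjustment is available as an
extra column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .anisotropy import AnisotropyCurve, _common_scales

__all__ = [
    "GroupCurves",
    "median_curve",
    "pairwise_scale_test",
    "crossover_scale",
]

#: combined sample size at or below which the exact rank-sum null is used
EXACT_RANKSUM_MAX_N = 30


@dataclass(frozen=True)
class GroupCurves:
    """A labelled ensemble of anisotropy curves on one common ladder."""

    group_label: str
    curves: List[AnisotropyCurve]

    def __post_init__(self) -> None:
        if len(self.curves) < 1:
            raise ValueError("a group needs at least one curve")
        _common_scales(self.curves)

    @property
    def scales_px(self) -> np.ndarray:
        return self.curves[0].scales_px

    @property
    def scales_um(self) -> Optional[np.ndarray]:
        return self.curves[0].scales_um

    def fa_matrix(self) -> np.ndarray:
        """(n_curves, n_scales) Fa values; nan marks missing scales."""
        return np.vstack([c.fa for c in self.curves])


def median_curve(group: GroupCurves) -> pd.DataFrame:
    """Per-scale median Fa over curves with a value at that scale."""
    fa = group.fa_matrix()
    n = np.sum(np.isfinite(fa), axis=0)
    med = np.full(fa.shape[1], np.nan)
    has = n > 0
    med[has] = np.nanmedian(fa[:, has], axis=0)
    um = group.scales_um
    return pd.DataFrame(
        {
            "group": group.group_label,
            "scale_px": group.scales_px,
            "scale_um": um if um is not None else np.nan,
            "median_fa": med,
            "n": n,
        }
    )


def _ranksum_two_sided(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution when the combined sample is small and tie-free;
    otherwise the tie-corrected normal approximation with a continuity
    correction (clamped at z = 0, so identical samples give p = 1).
    """
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        return float("nan")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if not has_ties and combined.size <= EXACT_RANKSUM_MAX_N:
        return float(sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
    ranks = sps.rankdata(combined)
    n1, n2 = x.size, y.size
    u1 = np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    tie_factor = sps.tiecorrect(ranks)
    if tie_factor == 0:  # every observation identical
        return 1.0
    sigma = np.sqrt(tie_factor * n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = max(abs(u1 - mu) - 0.5, 0.0) / sigma
    return float(min(1.0, 2.0 * sps.norm.sf(z)))


def pairwise_scale_test(a: GroupCurves, b: GroupCurves, bh: bool = False) -> pd.DataFrame:
    """Per-scale two-sided rank-sum comparison of two groups' Fa values."""
    if len(a.curves) < 3 or len(b.curves) < 3:
        raise ValueError("need at least 3 curves per group")
    if a.scales_px.shape != b.scales_px.shape or not np.allclose(a.scales_px, b.scales_px):
        raise ValueError("groups are not on a common ladder")
    fa_a = a.fa_matrix()
    fa_b = b.fa_matrix()
    p = np.array([_ranksum_two_sided(fa_a[:, j], fa_b[:, j]) for j in range(fa_a.shape[1])])
    um = a.scales_um
    out = pd.DataFrame(
        {
            "scale_px": a.scales_px,
            "scale_um": um if um is not None else np.nan,
            "p_raw": p,
        }
    )
    if bh:
        finite = np.isfinite(p)
        p_bh = np.full_like(p, np.nan)
        if finite.any():
            p_bh[finite] = sps.false_discovery_control(p[finite], method="bh")
        out["p_bh"] = p_bh
    return out


def crossover_scale(
    median_a: Sequence[float] | np.ndarray,
    median_b: Sequence[float] | np.ndarray,
    scales: Sequence[float] | np.ndarray,
) -> Optional[float]:
    """Smallest scale where the ordering of two median curves reverses.

    Returns the geometric mean of the two ladder scales bracketing the first
    sign change of ``median_a - median_b`` (or the scale itself if the
    difference is exactly zero there); ``None`` when the ordering never
    changes.  Units follow ``scales``.
    """
    a = np.asarray(median_a, dtype=np.float64)
    b = np.asarray(median_b, dtype=np.float64)
    s = np.asarray(scales, dtype=np.float64)
    if not (a.shape == b.shape == s.shape):
        raise ValueError("median curves and scales must share a shape")
    diff = a - b
    ok = np.isfinite(diff)
    diff, s = diff[ok], s[ok]
    for j in range(diff.size):
        if diff[j] == 0.0:
            return float(s[j])
        if j + 1 < diff.size and diff[j] * diff[j + 1] < 0:
            return float(np.sqrt(s[j] * s[j + 1]))
    return None
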