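"""Angle PDFs, the anisotropy factor Fa, and multiscale Fa curves.

The direction statistics of the WTMM points at one scale are summarized by a
histogram-based probability density ``P_a(A)`` of the gradient angles on the
full circle [-pi, pi).  The anisotropy factor is the L1 distance between that
density and the flat (isotropic) density 1/(2*pi):

    Fa = sum_i |P_a(A_i) - 1/(2*pi)| * dA,     dA = 2*pi / n_bins,

summed over the ``n_bins`` bins that tile the circle exactly once.  Fa = 0
for a perfectly flat PDF (pure isotropy); for a density concentrated in a
single bin Fa = 2*(1 - 1/n_bins), so the theoretical supremum is 2.

Binning is either *fixed* (a constant bin count, conventionally 64) or
*variable*: the bin count at each scale is chosen so that a fixed number of
samples (default 100) lands in each bin on average, which stabilizes the
noise floor of Fa across scales where maxima counts differ by orders of
magnitude.

Module-level analyses: per-image multiscale Fa curves, the central-crop
(edge-effect) variant, per-scale coefficient of variation across an image
ensemble, and normalization of curves by an isotropic reference (the
per-scale median Fa of a white-noise ensemble).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.fft

from .fields import ScalarField
from .maxima import detect_wtmm_mask, label_chains
from .transform import ScaleLadder, gaussian_derivative_transform

__all__ = [
    "BinningPolicy",
    "AnglePDF",
    "AnisotropyCurve",
    "NoMaximaError",
    "ISOTROPIC_DENSITY",
    "build_angle_pdf",
    "anisotropy_factor",
    "angles_by_scale",
    "curve_from_angles",
    "multiscale_curve",
    "central_crop_curve",
    "coefficient_of_variation",
    "reference_median",
    "normalize_by_reference",
]

ISOTROPIC_DENSITY = 1.0 / (2.0 * np.pi)


class NoMaximaError(ValueError):
    """Raised when an angle PDF is requested for an empty angle set."""


@dataclass(frozen=True)
class BinningPolicy:
    """How WTMM angles are histogrammed at each scale.

    mode
        ``"fixed"``: always ``n_bins`` bins.  ``"variable"``: the bin count
        is ``max(min_bins, floor(n_samples / samples_per_bin))`` so each bin
        holds ~``samples_per_bin`` samples.
    unit
        ``"point"`` bins one angle per WTMM point (default); ``"chain_mean"``
        bins one circular-mean angle per maxima chain (sensitivity mode).
    """

    mode: str = "variable"
    n_bins: int = 64
    samples_per_bin: int = 100
    min_bins: int = 4
    unit: str = "point"

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "variable"):
            raise ValueError(f"mode must be 'fixed' or 'variable', got {self.mode!r}")
        if self.unit not in ("point", "chain_mean"):
            raise ValueError(f"unit must be 'point' or 'chain_mean', got {self.unit!r}")
        if self.n_bins < 2 or self.samples_per_bin < 1 or self.min_bins < 2:
            raise ValueError("need n_bins >= 2, samples_per_bin >= 1, min_bins >= 2")

    def bins_for(self, n_samples: int) -> int:
        if self.mode == "fixed":
            return self.n_bins
        return max(self.min_bins, n_samples // self.samples_per_bin)


@dataclass(frozen=True)
class AnglePDF:
    """Histogram density of WTMM angles at one scale.

    Bins are half-open ``[A_i, A_i + dA)`` with ``A_0 = -pi`` and
    ``dA = 2*pi/n_bins``; densities integrate to 1 over the circle.
    """

    scale: float
    n_bins: int
    bin_width: float
    left_edges: np.ndarray
    density: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        total = float(np.sum(self.density) * self.bin_width)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"density does not integrate to 1 (got {total!r})")
        if np.any(self.density < 0):
            raise ValueError("negative density")


def build_angle_pdf(
    angles: Sequence[float] | np.ndarray,
    policy: BinningPolicy,
    scale: float = float("nan"),
) -> AnglePDF:
    """Bin angles in [-pi, pi) into a normalized density under ``policy``."""
    a = np.asarray(angles, dtype=np.float64).ravel()
    if a.size == 0:
        raise NoMaximaError(f"no angles to bin at scale {scale:g}")
    if np.any(a < -np.pi) or np.any(a >= np.pi):
        raise ValueError("angles must lie in [-pi, pi)")
    n_bins = policy.bins_for(a.size)
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(a, bins=edges)
    bin_width = 2.0 * np.pi / n_bins
    density = counts / (a.size * bin_width)
    return AnglePDF(
        scale=float(scale),
        n_bins=n_bins,
        bin_width=bin_width,
        left_edges=edges[:-1],
        density=density,
        n_samples=int(a.size),
    )


def anisotropy_factor(pdf: AnglePDF) -> float:
    """L1 deviation of the angle PDF from the flat density 1/(2*pi)."""
    return float(np.sum(np.abs(pdf.density - ISOTROPIC_DENSITY)) * pdf.bin_width)


@dataclass(frozen=True)
class AnisotropyCurve:
    """Per-scale anisotropy factors for one image.

    Scales with no detected maxima carry ``fa = nan`` and ``n_samples = 0``;
    they are excluded from ensemble aggregates, never imputed.
    """

    image_id: str
    policy: BinningPolicy
    scales_px: np.ndarray
    fa: np.ndarray
    n_samples: np.ndarray
    n_bins: np.ndarray
    scales_um: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        s = np.asarray(self.scales_px, dtype=np.float64)
        if np.any(np.diff(s) <= 0):
            raise ValueError("scales must be strictly increasing")
        fa = np.asarray(self.fa, dtype=np.float64)
        ok = np.isfinite(fa)
        if np.any(fa[ok] < 0) or np.any(fa[ok] >= 2):
            raise ValueError("Fa out of [0, 2)")

    def __len__(self) -> int:
        return self.scales_px.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "image_id": self.image_id,
                "scale_px": self.scales_px,
                "scale_um": self.scales_um if self.scales_um is not None else np.nan,
                "n_maxima": self.n_samples,
                "n_bins": self.n_bins,
                "fa": self.fa,
            }
        )
        return df


def angles_by_scale(
    image: ScalarField,
    ladder: ScaleLadder,
    unit: str = "point",
    crop: Optional[int] = None,
) -> List[np.ndarray]:
    """WTMM angle sets for every ladder scale (the expensive pipeline stage).

    Runs transform -> maxima detection at each scale on the full image.  With
    ``crop`` set, only maxima inside the centered ``crop x crop`` window are
    kept (chains straddling the window are truncated); the transform itself
    still sees the full image, so boundary contamination stays outside the
    window.  With ``unit="chain_mean"`` each maxima chain contributes the
    circular mean of its point angles instead of one angle per point.
    """
    ladder.validate_for(image.side)
    if crop is not None and crop >= image.side:
        raise ValueError(f"crop {crop} must be smaller than the image side {image.side}")
    image_rfft = scipy.fft.rfft2(image.values)
    window = None
    if crop is not None:
        off = (image.side - crop) // 2
        window = np.zeros(image.values.shape, dtype=bool)
        window[off:off + crop, off:off + crop] = True
    out: List[np.ndarray] = []
    for scale in ladder.scales:
        field = gaussian_derivative_transform(image, scale, image_rfft=image_rfft)
        mask = detect_wtmm_mask(field)
        if window is not None:
            mask &= window
        if unit == "chain_mean":
            labels, n = label_chains(mask)
            if n == 0:
                out.append(np.empty(0))
                continue
            ang = field.argument[mask]
            lab = labels[mask]
            sin_sum = np.bincount(lab, weights=np.sin(ang), minlength=n + 1)[1:]
            cos_sum = np.bincount(lab, weights=np.cos(ang), minlength=n + 1)[1:]
            mean = np.arctan2(sin_sum, cos_sum)
            mean[mean == np.pi] = -np.pi
            out.append(mean)
        else:
            out.append(field.argument[mask])
    return out


def curve_from_angles(
    angle_sets: Sequence[np.ndarray],
    ladder: ScaleLadder,
    policy: BinningPolicy,
    image_id: str = "",
) -> AnisotropyCurve:
    """Assemble an Fa curve from precomputed per-scale angle sets."""
    n_scales = len(ladder)
    if len(angle_sets) != n_scales:
        raise ValueError("angle_sets length must match the ladder")
    fa = np.full(n_scales, np.nan)
    n_samples = np.zeros(n_scales, dtype=np.int64)
    n_bins = np.zeros(n_scales, dtype=np.int64)
    for i, (scale, angles) in enumerate(zip(ladder.scales, angle_sets)):
        try:
            pdf = build_angle_pdf(angles, policy, scale)
        except NoMaximaError:
            warnings.warn(f"no maxima at scale {scale:g} px ({image_id or 'image'}); Fa left missing")
            continue
        fa[i] = anisotropy_factor(pdf)
        n_samples[i] = pdf.n_samples
        n_bins[i] = pdf.n_bins
    return AnisotropyCurve(
        image_id=image_id,
        policy=policy,
        scales_px=ladder.scales.copy(),
        fa=fa,
        n_samples=n_samples,
        n_bins=n_bins,
        scales_um=None if ladder.scales_um is None else ladder.scales_um.copy(),
    )


def multiscale_curve(
    image: ScalarField,
    ladder: ScaleLadder,
    policy: BinningPolicy,
    image_id: str = "",
) -> AnisotropyCurve:
    """Full per-image pipeline: transform -> detect -> bin -> Fa at each scale."""
    sets = angles_by_scale(image, ladder, unit=policy.unit)
    return curve_from_angles(sets, ladder, policy, image_id=image_id)


def central_crop_curve(
    large_image: ScalarField,
    ladder: ScaleLadder,
    policy: BinningPolicy,
    crop: int,
    image_id: str = "",
) -> AnisotropyCurve:
    """Edge-robust Fa curve: analyze the full image, bin only central maxima."""
    sets = angles_by_scale(large_image, ladder, unit=policy.unit, crop=crop)
    return curve_from_angles(sets, ladder, policy, image_id=image_id)


def _common_scales(curves: Sequence[AnisotropyCurve]) -> np.ndarray:
    ref = curves[0].scales_px
    for c in curves[1:]:
        if c.scales_px.shape != ref.shape or not np.allclose(c.scales_px, ref):
            raise ValueError("curves are not on a common scale ladder")
    return ref


def coefficient_of_variation(curves: Sequence[AnisotropyCurve]) -> pd.DataFrame:
    """Per-scale CV = sample SD / mean of Fa across an ensemble of curves."""
    if len(curves) < 3:
        raise ValueError("need at least 3 curves for a coefficient of variation")
    scales = _common_scales(curves)
    fa = np.vstack([c.fa for c in curves])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(fa, axis=0)
        sd = np.nanstd(fa, axis=0, ddof=1)
    return pd.DataFrame({"scale_px": scales, "mean_fa": mean, "sd_fa": sd, "cv": sd / mean})


def reference_median(curves: Sequence[AnisotropyCurve]) -> np.ndarray:
    """Per-scale median Fa across an isotropic reference ensemble."""
    _common_scales(curves)
    fa = np.vstack([c.fa for c in curves])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmedian(fa, axis=0)


def normalize_by_reference(
    curve: AnisotropyCurve,
    reference: np.ndarray | Iterable[float],
    mode: str = "ratio",
) -> AnisotropyCurve:
    """Normalize a curve by a per-scale isotropic reference Fa.

    ``mode="ratio"`` (default) divides; ``mode="difference"`` subtracts.  The
    reference must be strictly positive at every scale in ratio mode.
    """
    ref = np.asarray(list(reference) if not isinstance(reference, np.ndarray) else reference,
                     dtype=np.float64)
    if ref.shape != curve.scales_px.shape:
        raise ValueError("reference and curve are not on a common ladder")
    if mode == "ratio":
        if np.any(~np.isfinite(ref)) or np.any(ref <= 0):
            raise ValueError("reference Fa must be finite and > 0 to normalize by ratio")
        fa = curve.fa / ref
    elif mode == "difference":
        fa = curve.fa - ref
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    # normalized values live on a different scale; bypass the raw-Fa range check
    out = replace(curve)
    object.__setattr__(out, "fa", fa)
    return out
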