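"""Synthetic calibration and fixture fields.

Isotropic, scale-invariant random surfaces are the numerical controls of the
anisotropy method: white noise (flat power spectrum) and fractional Brownian
surfaces (power spectrum ``|k|**-(2H+2)``), both synthesized by the Fourier
filtering method — shape the spectrum of Gaussian white noise by a power-law
amplitude and invert the transform.  An oriented sinusoidal grating is
provided as a known-anisotropic positive control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "FieldSpec",
    "ScalarField",
    "generate_field",
    "generate_white_noise",
    "generate_brownian_surface",
    "generate_oriented_stripes",
]

FIELD_KINDS = ("white_noise", "brownian_surface", "oriented_stripes")


@dataclass(frozen=True)
class ScalarField:
    """A square, single-channel intensity raster.

    Parameters
    ----------
    values
        2D float array, ``side x side``.  Row index is y (downward), column
        index is x (rightward).
    pixel_size_um
        Physical pixel spacing in micrometres, or ``None`` for dimensionless
        analysis.
    """

    values: np.ndarray
    pixel_size_um: Optional[float] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"field must be a square 2D raster, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("field contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def side(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class FieldSpec:
    """Recipe for a synthetic field; identical specs yield bit-identical rasters.

    ``hurst`` applies only to Brownian surfaces (roughness exponent H in
    (0, 1); H = 0.5 is the ordinary Brownian surface).  ``orientation_deg``
    and ``wavelength`` apply only to oriented stripes; the seed then sets the
    random phase of the grating so replicate fixtures are not identical
    images.
    """

    side_length: int
    kind: str
    hurst: Optional[float] = None
    orientation_deg: Optional[float] = None
    wavelength: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.side_length
        if n < 64 or (n & (n - 1)) != 0:
            raise ValueError(f"side_length must be a power of two >= 64, got {n}")
        if self.kind not in FIELD_KINDS:
            raise ValueError(f"unknown field kind {self.kind!r}; expected one of {FIELD_KINDS}")
        if self.kind == "brownian_surface":
            h = 0.5 if self.hurst is None else float(self.hurst)
            if not 0.0 < h < 1.0:
                raise ValueError(f"hurst must lie in (0, 1), got {h}")
            object.__setattr__(self, "hurst", h)
        if self.kind == "oriented_stripes":
            if self.wavelength is None or self.orientation_deg is None:
                raise ValueError("oriented_stripes requires orientation_deg and wavelength")
            if self.wavelength < 4:
                raise ValueError(f"stripe wavelength must be >= 4 px, got {self.wavelength}")


def _require_kind(spec: FieldSpec, kind: str) -> None:
    if spec.kind != kind:
        raise ValueError(f"spec.kind is {spec.kind!r}, expected {kind!r}")


def generate_white_noise(spec: FieldSpec) -> ScalarField:
    """i.i.d. standard-normal pixels (flat power spectrum)."""
    _require_kind(spec, "white_noise")
    rng = np.random.default_rng(spec.seed)
    values = rng.standard_normal((spec.side_length, spec.side_length))
    return ScalarField(values)


def generate_brownian_surface(spec: FieldSpec) -> ScalarField:
    """Fractional Brownian surface by Fourier filtering.

    Gaussian white noise is transformed, its spectrum multiplied by the
    power-law amplitude ``|k|**-(H+1)`` (power spectrum ``|k|**-(2H+2)``),
    the zero-frequency coefficient set to zero to remove the divergent mean,
    and the inverse transform taken.  Filtering the spectrum of a *real*
    noise field keeps the spectrum Hermitian, so the inverse transform is
    real to machine precision.
    """
    _require_kind(spec, "brownian_surface")
    n = spec.side_length
    h = spec.hurst if spec.hurst is not None else 0.5
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal((n, n))
    freq = np.fft.fftfreq(n)
    kr = np.hypot(freq[:, None], freq[None, :])
    with np.errstate(divide="ignore"):
        amplitude = np.where(kr > 0, kr ** -(h + 1.0), 0.0)
    spectrum = np.fft.fft2(noise) * amplitude
    values = np.fft.ifft2(spectrum).real
    return ScalarField(values)


def generate_oriented_stripes(spec: FieldSpec) -> ScalarField:
    """Sinusoidal grating: a strongly anisotropic positive-control fixture.

    Intensity is constant along the stripe direction ``orientation_deg``
    (measured so that 0 deg stripes are constant within each row) and varies
    sinusoidally with period ``wavelength`` across it.  The requested wave
    vector is snapped to the nearest integer frequency pair of the raster so
    the grating is *exactly* periodic: otherwise the wrap discontinuity at
    the domain boundary injects broadband power that swamps the grating at
    analysis scales larger than the wavelength.  The seed draws the grating
    phase, giving independent replicates with identical anisotropy.

    A grating carries directional signal only up to scales where the Gaussian
    attenuation exp(-(2*pi*a/wavelength)**2 / 2) stays above the synthesis
    noise floor (~1e-16); probe it at scales up to roughly its wavelength.
    """
    _require_kind(spec, "oriented_stripes")
    n = spec.side_length
    theta = np.deg2rad(spec.orientation_deg)
    # nearest on-grid wave vector (cycles per raster), in (col, row) order
    p = round(n * np.sin(theta) / spec.wavelength)
    q = round(n * np.cos(theta) / spec.wavelength)
    if p == 0 and q == 0:  # wavelength longer than the raster: lowest mode
        p, q = (1, 0) if abs(np.sin(theta)) >= abs(np.cos(theta)) else (0, 1)
    rng = np.random.default_rng(spec.seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    y = np.arange(n, dtype=np.float64)[:, None]  # row
    x = np.arange(n, dtype=np.float64)[None, :]  # column
    values = np.sin(2.0 * np.pi * (p * x + q * y) / n + phase)
    return ScalarField(values)


_GENERATORS = {
    "white_noise": generate_white_noise,
    "brownian_surface": generate_brownian_surface,
    "oriented_stripes": generate_oriented_stripes,
}


def generate_field(spec: FieldSpec) -> ScalarField:
    """Dispatch on ``spec.kind``."""
    return _GENERATORS[spec.kind](spec)
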