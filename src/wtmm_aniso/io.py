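"""Image I/O, run configuration, and the batch pipeline.

Images are read verbatim: single-channel TIFF or PNG, integer or float,
cast to float64 with **no** rescaling — the anisotropy method is invariant to
affine intensity changes, so any preprocessing must be an explicit upstream
step.  Multi-channel or non-square inputs are rejected rather than silently
coerced.

``run_pipeline`` drives the full analysis for a config describing labelled
image groups (on disk or synthetic), a scale ladder, a binning policy and an
isotropic reference, writing per-image curves, group medians, pairwise
p-value tracks, the reference table and a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import zlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from . import __version__
from .anisotropy import (
    AnisotropyCurve,
    BinningPolicy,
    multiscale_curve,
    normalize_by_reference,
    reference_median,
)
from .fields import FieldSpec, ScalarField, generate_field
from .stats import GroupCurves, median_curve, pairwise_scale_test
from .transform import ScaleLadder, make_scale_ladder

__all__ = [
    "read_image",
    "write_field_tiff",
    "write_field_png",
    "write_spec_sidecar",
    "RunConfig",
    "load_config",
    "run_pipeline",
]

log = logging.getLogger("wtmm_aniso")

_ALLOWED_DTYPES = ("uint8", "uint16", "int16", "int32", "float32", "float64")


def read_image(path: str | Path, pixel_size_um: Optional[float] = None) -> ScalarField:
    """Read a single-channel square TIFF/PNG as a float64 ScalarField."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        with Image.open(path) as im:
            arr = np.asarray(im)
    else:
        raise ValueError(f"{path}: unsupported format {suffix!r} (expected TIFF or PNG)")
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single channel, got shape {arr.shape}")
    if arr.dtype.name not in _ALLOWED_DTYPES:
        raise ValueError(f"{path}: unsupported bit depth {arr.dtype}")
    if arr.shape[0] != arr.shape[1]:
        raise ValueError(f"{path}: image must be square, got {arr.shape}")
    return ScalarField(arr.astype(np.float64), pixel_size_um=pixel_size_um)


def write_field_tiff(field: ScalarField, path: str | Path, dtype=np.float32) -> Path:
    """Write the raster as a float TIFF (32-bit by default)."""
    path = Path(path)
    tifffile.imwrite(path, field.values.astype(dtype))
    return path


def write_field_png(field: ScalarField, path: str | Path) -> Path:
    """Write a 16-bit PNG after affine rescale to the full dynamic range."""
    path = Path(path)
    v = field.values
    lo, hi = float(v.min()), float(v.max())
    scaled = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
    arr = np.round(scaled * 65535.0).astype(np.uint16)
    Image.fromarray(arr).save(path)
    return path


def write_spec_sidecar(spec: FieldSpec, path: str | Path) -> Path:
    """JSON sidecar recording the full synthesis recipe next to an image."""
    path = Path(path)
    path.write_text(json.dumps(dataclasses.asdict(spec), indent=2) + "\n")
    return path


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class GroupSpec:
    """One labelled input group: image paths, or a synthetic ensemble recipe."""

    label: str
    paths: List[str] = dc_field(default_factory=list)
    synthetic: Optional[Dict[str, Any]] = None  # kind, n, side_length, [hurst, ...]

    def __post_init__(self) -> None:
        if bool(self.paths) == (self.synthetic is not None):
            raise ValueError(f"group {self.label!r}: give either paths or a synthetic recipe")


@dataclass
class RunConfig:
    groups: List[GroupSpec]
    out_dir: str
    seed: int = 0
    min_scale: float = 7.0
    max_scale: float = 210.0
    n_scales: int = 50
    pixel_size_um: Optional[float] = None
    binning_mode: str = "variable"
    n_bins: int = 64
    samples_per_bin: int = 100
    min_bins: int = 4
    binning_unit: str = "point"
    # isotropic reference: generated white noise (default) or loaded table
    reference_source: str = "generate"   # "generate" | "load" | "none"
    reference_n: int = 30
    reference_side: int = 512
    reference_path: Optional[str] = None
    normalize_mode: str = "ratio"

    def ladder(self) -> ScaleLadder:
        return make_scale_ladder(self.min_scale, self.max_scale, self.n_scales, self.pixel_size_um)

    def policy(self) -> BinningPolicy:
        return BinningPolicy(
            mode=self.binning_mode,
            n_bins=self.n_bins,
            samples_per_bin=self.samples_per_bin,
            min_bins=self.min_bins,
            unit=self.binning_unit,
        )

    def validate(self) -> None:
        for g in self.groups:
            for p in g.paths:
                if not Path(p).exists():
                    raise FileNotFoundError(f"group {g.label!r}: missing input image {p}")
        if self.reference_source == "load":
            if not self.reference_path or not Path(self.reference_path).exists():
                raise FileNotFoundError(f"reference table not found: {self.reference_path}")


def load_config(path: str | Path, **overrides: Any) -> RunConfig:
    """Load a RunConfig from YAML or TOML; keyword overrides win."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(path.read_text())
    elif path.suffix.lower() == ".toml":
        import tomllib

        raw = tomllib.loads(path.read_text())
    else:
        raise ValueError(f"unsupported config format: {path.suffix}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    groups = [GroupSpec(**g) for g in raw.pop("groups")]
    return RunConfig(groups=groups, **raw)


# ---------------------------------------------------------------------------
# pipeline


def _derived_seeds(seed: int, n: int, tag: str) -> List[int]:
    """Deterministic per-image seeds below 2**31, namespaced by a tag."""
    ss = np.random.SeedSequence([seed, zlib.crc32(tag.encode()) % (2**31)])
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def _synthetic_fields(recipe: Dict[str, Any], seed: int, label: str) -> List[tuple[str, ScalarField]]:
    n = int(recipe.get("n", 1))
    seeds = _derived_seeds(seed, n, label)
    out = []
    for i, s in enumerate(seeds):
        spec = FieldSpec(
            side_length=int(recipe.get("side_length", 512)),
            kind=recipe["kind"],
            hurst=recipe.get("hurst"),
            orientation_deg=recipe.get("orientation_deg"),
            wavelength=recipe.get("wavelength"),
            seed=s,
        )
        out.append((f"{label}_{i:03d}", generate_field(spec)))
    return out


def run_pipeline(config: RunConfig) -> Dict[str, Any]:
    """Run the full batch analysis; returns a summary with output paths."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ladder = config.ladder()
    policy = config.policy()
    skipped: List[str] = []

    # isotropic reference
    reference: Optional[np.ndarray] = None
    if config.reference_source == "generate":
        log.info("generating white-noise reference ensemble (n=%d)", config.reference_n)
        ref_recipe = {"kind": "white_noise", "n": config.reference_n,
                      "side_length": config.reference_side}
        ref_curves = [
            multiscale_curve(fieldd, ladder, policy, image_id=name)
            for name, fieldd in _synthetic_fields(ref_recipe, config.seed, "__reference__")
        ]
        reference = reference_median(ref_curves)
    elif config.reference_source == "load":
        ref_df = pd.read_csv(config.reference_path)
        if not np.allclose(ref_df["scale_px"].to_numpy(), ladder.scales):
            raise ValueError("loaded reference table is not on the configured ladder")
        reference = ref_df["median_fa"].to_numpy()

    # per-image curves per group
    groups: Dict[str, GroupCurves] = {}
    for g in config.groups:
        curves: List[AnisotropyCurve] = []
        if g.synthetic is not None:
            for name, fieldd in _synthetic_fields(g.synthetic, config.seed, g.label):
                curves.append(multiscale_curve(fieldd, ladder, policy, image_id=name))
        else:
            for p in g.paths:
                try:
                    img = read_image(p, pixel_size_um=config.pixel_size_um)
                except Exception as exc:  # logged skip, nonzero summary flag
                    log.warning("skipping unreadable image %s: %s", p, exc)
                    skipped.append(str(p))
                    continue
                curves.append(multiscale_curve(img, ladder, policy, image_id=Path(p).stem))
        if not curves:
            raise ValueError(f"group {g.label!r} produced no curves")
        groups[g.label] = GroupCurves(g.label, curves)

    # tables
    curve_rows = []
    for label, grp in groups.items():
        for c in grp.curves:
            df = c.to_frame()
            df.insert(0, "group", label)
            if reference is not None:
                df["fa_normalized"] = normalize_by_reference(
                    c, reference, mode=config.normalize_mode
                ).fa
            curve_rows.append(df)
    curves_df = pd.concat(curve_rows, ignore_index=True)
    medians_df = pd.concat([median_curve(grp) for grp in groups.values()], ignore_index=True)

    ptrack_frames = []
    for (la, ga), (lb, gb) in itertools.combinations(groups.items(), 2):
        if len(ga.curves) >= 3 and len(gb.curves) >= 3:
            pt = pairwise_scale_test(ga, gb)
            pt.insert(0, "pair", f"{la}_vs_{lb}")
            ptrack_frames.append(pt)

    paths = {"curves": out_dir / "curves.csv", "medians": out_dir / "medians.csv",
             "manifest": out_dir / "manifest.json"}
    curves_df.to_csv(paths["curves"], index=False)
    medians_df.to_csv(paths["medians"], index=False)
    if ptrack_frames:
        paths["ptracks"] = out_dir / "ptracks.csv"
        pd.concat(ptrack_frames, ignore_index=True).to_csv(paths["ptracks"], index=False)
    if reference is not None:
        paths["reference"] = out_dir / "reference.csv"
        pd.DataFrame({"scale_px": ladder.scales, "median_fa": reference}).to_csv(
            paths["reference"], index=False
        )

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            **{k: v for k, v in dataclasses.asdict(config).items() if k != "groups"},
            "groups": [dataclasses.asdict(g) for g in config.groups],
        },
        "counts": {label: len(grp.curves) for label, grp in groups.items()},
        "skipped": skipped,
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return {"paths": {k: str(v) for k, v in paths.items()}, "skipped": skipped,
            "n_groups": len(groups)}
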