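"""File formats and run configuration.

On-disk conventions:

* DWI: 4-D NIfTI-1 (RAS-positive affine) with FSL-style sibling gradient
  files — ``<stem>.bval`` (one row of b-values) and ``<stem>.bvec`` (three
  rows of x/y/z components).
* Ground-truth / fitted tensor fields: NIfTI-1 with 6 volumes in the order
  Dxx, Dyy, Dzz, Dxy, Dxz, Dyz.
* Cohorts: CSV with header
  ``id,group,age_years,duration_months,frequency_per_day,alps_true``
  (plus ``alps_measured`` once the pipeline has run); missing covariates
  are empty fields.
* Run configuration: a single YAML file mirroring the phantom, acquisition,
  ROI and cohort dataclasses; a serialized copy is written into every
  output directory.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .cohort import (ALPS_BOUNDS, CohortConfig, GroupConfig, Marginal,
                     Subject, default_cohort_config)
from .containers import DWIVolume, TensorField
from .errors import ConfigError, FormatError
from .gradients import GradientTable
from .phantom import PhantomSpec, Region

COHORT_COLUMNS = [
    "id", "group", "age_years", "duration_months", "frequency_per_day",
    "alps_true",
]

_UNIT_TOL = 1e-6


# ---------------------------------------------------------------- gradients

def write_gradient_table(gtab: GradientTable, bval_path, bvec_path) -> None:
    """Write FSL-style text files: b-values in one row, bvecs in three."""
    Path(bval_path).write_text(
        " ".join(f"{b:.6g}" for b in gtab.bvals) + "\n")
    rows = [" ".join(f"{v:.9f}" for v in gtab.bvecs[:, ax]) for ax in range(3)]
    Path(bvec_path).write_text("\n".join(rows) + "\n")


def read_gradient_table(bval_path, bvec_path) -> GradientTable:
    """Read FSL-style bval/bvec files; non-unit b > 0 columns are
    renormalized with a warning."""
    bvals = np.loadtxt(bval_path, ndmin=1)
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T  # FSL files are 3 rows x n columns
    if bvecs.ndim != 2 or bvecs.shape[1] != 3:
        raise FormatError(f"bvec file {bvec_path} is not 3 x n")
    if bvals.shape[0] != bvecs.shape[0]:
        raise FormatError(
            f"{bvals.shape[0]} b-values but {bvecs.shape[0]} bvec columns"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    bad = (bvals > 0) & (np.abs(norms - 1.0) > _UNIT_TOL)
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} non-unit gradient vectors renormalized"
        )
        bvecs[bad] /= norms[bad, None]
    return GradientTable(bvals, bvecs)


# --------------------------------------------------------------------- DWI

def _gradient_siblings(path: Path) -> tuple[Path, Path]:
    stem = path.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return path.parent / f"{stem}.bval", path.parent / f"{stem}.bvec"


def write_dwi(dwi: DWIVolume, path) -> None:
    """Write a 4-D NIfTI plus sibling ``.bval``/``.bvec`` files."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(dwi.data, dtype=np.float32), dwi.affine)
    img.header.set_zooms(dwi.voxel_size + (1.0,))
    nib.save(img, str(path))
    bval_path, bvec_path = _gradient_siblings(path)
    write_gradient_table(dwi.gtab, bval_path, bvec_path)


def read_dwi(path, bval_path=None, bvec_path=None) -> DWIVolume:
    """Read a 4-D NIfTI DWI with its gradient table.

    Gradient files default to the NIfTI's siblings. Raises
    :class:`FormatError` when the volume count disagrees with the gradient
    table.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"{path} is not a 4-D DWI (shape {data.shape})")
    if bval_path is None or bvec_path is None:
        default_bval, default_bvec = _gradient_siblings(path)
        bval_path = bval_path or default_bval
        bvec_path = bvec_path or default_bvec
    gtab = read_gradient_table(bval_path, bvec_path)
    if data.shape[-1] != len(gtab):
        raise FormatError(
            f"{data.shape[-1]} volumes in {path} but {len(gtab)} gradient entries"
        )
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DWIVolume(data, gtab, voxel_size, img.affine)


# ------------------------------------------------------------ tensor fields

def write_tensor_field(field: TensorField, path) -> None:
    """NIfTI with 6 volumes: Dxx, Dyy, Dzz, Dxy, Dxz, Dyz."""
    img = nib.Nifti1Image(np.asarray(field.data, dtype=np.float64), field.affine)
    img.header.set_zooms(field.voxel_size + (1.0,))
    img.header["descrip"] = b"tensor: Dxx Dyy Dzz Dxy Dxz Dyz"
    nib.save(img, str(path))


def read_tensor_field(path) -> TensorField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[-1] != 6:
        raise FormatError(
            f"{path} is not a 6-component tensor image (shape {data.shape})"
        )
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return TensorField(data, voxel_size, img.affine)


# ---------------------------------------------------------------- cohorts

def cohort_to_dataframe(subjects: list[Subject]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        row = {
            "id": s.id, "group": s.group, "age_years": s.age,
            "duration_months": s.duration, "frequency_per_day": s.frequency,
            "alps_true": s.alps_true,
        }
        if s.alps_measured is not None:
            row["alps_measured"] = s.alps_measured
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_csv(subjects: list[Subject], path) -> None:
    cohort_to_dataframe(subjects).to_csv(path, index=False, float_format="%.10g")


def read_cohort_csv(path) -> list[Subject]:
    """Read a cohort table; raises :class:`FormatError` with the missing
    column names if the schema is wrong."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"cohort file {path} is missing columns: {', '.join(missing)} "
            f"(expected header {','.join(COHORT_COLUMNS)})"
        )
    subjects = []
    for _, row in df.iterrows():
        subjects.append(Subject(
            id=str(row["id"]), group=str(row["group"]),
            age=float(row["age_years"]),
            duration=None if pd.isna(row["duration_months"]) else float(row["duration_months"]),
            frequency=None if pd.isna(row["frequency_per_day"]) else float(row["frequency_per_day"]),
            alps_true=float(row["alps_true"]),
            alps_measured=(float(row["alps_measured"])
                           if "alps_measured" in df.columns and not pd.isna(row["alps_measured"])
                           else None),
        ))
    return subjects


# ------------------------------------------------------------ run config

@dataclass(frozen=True)
class AcquisitionConfig:
    """DWI acquisition scheme and noise level of the simulated scan."""

    n_directions: int = 30
    b: float = 1000.0
    n_b0: int = 1
    s0: float = 1000.0
    snr: Optional[float] = 30.0


@dataclass(frozen=True)
class RunConfig:
    """Everything a full experiment run depends on, besides the seed."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    cohort: CohortConfig = field(default_factory=default_cohort_config)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    roi_diameter: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.roi_diameter <= 0:
            raise ConfigError("roi_diameter must be > 0")


def default_run_config(seed: int = 0) -> RunConfig:
    return RunConfig(cohort=default_cohort_config(seed), seed=seed)


def _marginal_to_dict(m: Optional[Marginal]) -> Optional[dict]:
    if m is None:
        return None
    d = {"mean": m.mean, "sd": m.sd}
    if np.isfinite(m.lower):
        d["lower"] = m.lower
    if np.isfinite(m.upper):
        d["upper"] = m.upper
    return d


def _marginal_from_dict(d: Optional[dict], what: str) -> Optional[Marginal]:
    if d is None:
        return None
    try:
        return Marginal(
            mean=float(d["mean"]), sd=float(d["sd"]),
            lower=float(d.get("lower", -np.inf)),
            upper=float(d.get("upper", np.inf)),
        )
    except KeyError as exc:
        raise ConfigError(f"{what}: marginal needs 'mean' and 'sd' ({exc})") from exc


def _group_to_dict(g: GroupConfig) -> dict:
    return {
        "n": g.n,
        "alps": _marginal_to_dict(g.alps),
        "age": _marginal_to_dict(g.age),
        "duration": _marginal_to_dict(g.duration),
        "frequency": _marginal_to_dict(g.frequency),
        "r_alps_age": g.r_alps_age,
        "r_alps_duration": g.r_alps_duration,
        "r_alps_frequency": g.r_alps_frequency,
    }


def _group_from_dict(d: dict, what: str) -> GroupConfig:
    try:
        return GroupConfig(
            n=int(d["n"]),
            alps=_marginal_from_dict(d["alps"], f"{what}.alps"),
            age=_marginal_from_dict(d["age"], f"{what}.age"),
            duration=_marginal_from_dict(d.get("duration"), f"{what}.duration"),
            frequency=_marginal_from_dict(d.get("frequency"), f"{what}.frequency"),
            r_alps_age=float(d.get("r_alps_age", 0.0)),
            r_alps_duration=float(d.get("r_alps_duration", 0.0)),
            r_alps_frequency=float(d.get("r_alps_frequency", 0.0)),
        )
    except KeyError as exc:
        raise ConfigError(f"{what}: missing required key {exc}") from exc


def _region_from_dict(d: dict, name: str, axis: int) -> Region:
    try:
        return Region(name, tuple(int(v) for v in d["lo"]),
                      tuple(int(v) for v in d["hi"]), fiber_axis=axis)
    except KeyError as exc:
        raise ConfigError(f"phantom.{name}: missing key {exc}") from exc


def config_to_dict(cfg: RunConfig) -> dict:
    p = cfg.phantom
    return {
        "phantom": {
            "grid_shape": list(p.grid_shape),
            "voxel_size": list(p.voxel_size),
            "projection": {"lo": list(p.projection.lo), "hi": list(p.projection.hi)},
            "association": {"lo": list(p.association.lo), "hi": list(p.association.hi)},
            "subcortical": {"lo": list(p.subcortical.lo), "hi": list(p.subcortical.hi)},
            "d_parallel": p.d_parallel,
            "d_perp": p.d_perp,
            "d_background": p.d_background,
        },
        "acquisition": {
            "n_directions": cfg.acquisition.n_directions,
            "b": cfg.acquisition.b,
            "n_b0": cfg.acquisition.n_b0,
            "s0": cfg.acquisition.s0,
            "snr": cfg.acquisition.snr,
        },
        "roi_diameter": cfg.roi_diameter,
        "seed": cfg.seed,
        "cohort": {
            "cae": _group_to_dict(cfg.cohort.cae),
            "hc": _group_to_dict(cfg.cohort.hc),
        },
    }


def config_from_dict(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a YAML mapping")
    defaults = default_run_config()
    pd_ = raw.get("phantom", {})
    dp = defaults.phantom
    phantom = PhantomSpec(
        grid_shape=tuple(int(v) for v in pd_.get("grid_shape", dp.grid_shape)),
        voxel_size=tuple(float(v) for v in pd_.get("voxel_size", dp.voxel_size)),
        projection=(_region_from_dict(pd_["projection"], "projection", 2)
                    if "projection" in pd_ else dp.projection),
        association=(_region_from_dict(pd_["association"], "association", 1)
                     if "association" in pd_ else dp.association),
        subcortical=(_region_from_dict(pd_["subcortical"], "subcortical", 0)
                     if "subcortical" in pd_ else dp.subcortical),
        d_parallel=float(pd_.get("d_parallel", dp.d_parallel)),
        d_perp=float(pd_.get("d_perp", dp.d_perp)),
        d_background=float(pd_.get("d_background", dp.d_background)),
    )
    ad = raw.get("acquisition", {})
    da = defaults.acquisition
    snr = ad.get("snr", da.snr)
    acquisition = AcquisitionConfig(
        n_directions=int(ad.get("n_directions", da.n_directions)),
        b=float(ad.get("b", da.b)),
        n_b0=int(ad.get("n_b0", da.n_b0)),
        s0=float(ad.get("s0", da.s0)),
        snr=None if snr in (None, "none") else float(snr),
    )
    cd = raw.get("cohort", {})
    cohort = CohortConfig(
        cae=(_group_from_dict(cd["cae"], "cohort.cae")
             if "cae" in cd else defaults.cohort.cae),
        hc=(_group_from_dict(cd["hc"], "cohort.hc")
            if "hc" in cd else defaults.cohort.hc),
        seed=int(raw.get("seed", defaults.seed)),
    )
    return RunConfig(
        phantom=phantom, cohort=cohort, acquisition=acquisition,
        roi_diameter=float(raw.get("roi_diameter", defaults.roi_diameter)),
        seed=int(raw.get("seed", defaults.seed)),
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    return config_from_dict(raw)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(cfg), sort_keys=True)
    )


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the canonical YAML serialization."""
    canonical = yaml.safe_dump(config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
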