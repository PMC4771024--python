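"""Synthetic cohorts, ratings, cortical surfaces and ROI volumes.

No participant data are distributed with this package, so every downstream
stage is exercised on simulated data with the statistical structure the
analyses assume:

* a cohort of adults (default n=18, ages 18-40) with a latent per-subject
  discriminability alpha_s > 0 governing how well structure levels are told
  apart;
* trial-level ordinal ratings from a latent-logistic model, u = alpha_s * z
  + logistic noise cut at fixed thresholds — by construction the fitted
  proportional-odds model is correctly specified with true per-subject
  log-odds slope alpha_s;
* per-vertex thickness maps on a shared icosphere mesh: baseline + age
  slope + spatially smoothed Gaussian noise + optional planted clusters
  whose thickness scales with the subject's sensitivity;
* subcortical-style ROI volumes (8 structures x 2 hemispheres) with ICV
  scaling and optional sensitivity effects.

All simulators are deterministic given (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import trimesh

from .errors import ValidationError
from .surface_stats import (
    SurfaceModel,
    default_mesh,
    geodesic_distances,
    smooth_maps,
    write_mesh,
    write_scalar_map,
)

# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

#: Structure scores of the three conditions in the rating simulator.
DEFAULT_STRUCTURE_SCORES: dict[str, float] = {"low": 0.0, "mid": 1.0, "high": 2.0}
#: Latent-scale cut-points mapping u to the 7 rating categories.  Spaced by
#: the median subject's condition step (alpha_median * 1) so that the three
#: condition means fall mid-bin for an average subject.
DEFAULT_CUTPOINTS: tuple[float, ...] = (-1.5, 0.0, 1.5, 3.0, 4.5, 6.0)


def simulate_cohort(
    n: int = 18,
    seed: int | None = None,
    *,
    age_range: tuple[float, float] = (18.0, 40.0),
    alpha_median: float = 1.5,
    alpha_sigma: float = 0.5,
    icv_mean: float = 1.5e6,
    icv_sd: float = 1.5e5,
) -> pd.DataFrame:
    """Simulate a cohort table.

    Ages are uniform over ``age_range``; the latent discriminability
    ``alpha_s`` is log-normal with the given median and log-scale spread
    (``alpha_sigma = 0`` collapses every subject onto the median); ICV is
    Gaussian in mm^3; sex is a balanced binary code.
    """
    if n < 2:
        raise ValidationError("cohort needs at least 2 subjects")
    if alpha_median <= 0:
        raise ValidationError("alpha_median must be positive")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(age_range[0], age_range[1], n)
    alpha = alpha_median * np.exp(alpha_sigma * rng.standard_normal(n))
    icv = rng.normal(icv_mean, icv_sd, n)
    sex = rng.permutation(np.arange(n) % 2)
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:02d}" for i in range(n)],
            "age": ages,
            "sex": sex,
            "icv": icv,
            "discrimination": alpha,
        }
    )


# ---------------------------------------------------------------------------
# Ratings
# ---------------------------------------------------------------------------


@dataclass
class RatingDesign:
    """Trial counts and generative scores of the rating simulator."""

    trials_per_condition: int = 21
    categories: tuple[str, ...] = ("speech",)
    structure_scores: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STRUCTURE_SCORES)
    )
    cutpoints: tuple[float, ...] = DEFAULT_CUTPOINTS
    #: multiplies alpha_s for non-speech categories, emulating the weaker
    #: discriminability of unfamiliar sound classes (1.0 = same as speech)
    category_scale: dict[str, float] = field(default_factory=dict)


def simulate_ratings(
    cohort: pd.DataFrame,
    design: RatingDesign | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate trial-level ordinal ratings (1..J) for every subject.

    Latent utility u = alpha_s * z(condition) + eps with standard-logistic
    eps; the rating is the ordinal category of u under the design's fixed
    cut-points.  The proportional-odds assumption holds exactly, with true
    per-subject log-odds slope alpha_s per unit of structure score.
    """
    design = design or RatingDesign()
    cuts = np.asarray(design.cutpoints, dtype=float)
    if np.any(np.diff(cuts) <= 0):
        raise ValidationError("cutpoints must be strictly increasing")
    rng = np.random.default_rng(seed)
    rows = []
    for _, subj in cohort.iterrows():
        for category in design.categories:
            scale = design.category_scale.get(category, 1.0)
            alpha = float(subj["discrimination"]) * scale
            for condition, z in design.structure_scores.items():
                eps = rng.logistic(size=design.trials_per_condition)
                u = alpha * z + eps
                rating = np.searchsorted(cuts, u) + 1
                for trial, r in enumerate(rating):
                    rows.append(
                        {
                            "subject_id": subj["subject_id"],
                            "category": category,
                            "condition": condition,
                            "trial_index": trial,
                            "rating": int(r),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Surface study
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedCluster:
    """A planted thickness-behavior effect: geodesic disc around a vertex."""

    vertex: int
    radius_mm: float
    slope: float  # mm of thickness per unit of sensitivity


def simulate_surface_study(
    cohort: pd.DataFrame,
    mesh: trimesh.Trimesh | None = None,
    effect_spec: Sequence[PlantedCluster] = (),
    seed: int | None = None,
    *,
    sensitivity: np.ndarray | None = None,
    baseline_mm: float = 2.5,
    age_slope: float = -0.01,
    noise_sd: float = 0.1,
    noise_fwhm_mm: float = 12.0,
) -> SurfaceModel:
    """Simulate per-subject thickness maps on a shared mesh.

    thickness(s, v) = baseline + age_slope * (age_s - mean age)
                      + slope_c * sensitivity_s   inside each planted disc
                      + spatially smoothed Gaussian noise (sd ``noise_sd``
                        after smoothing to ``noise_fwhm_mm`` coherence).

    ``sensitivity`` defaults to the cohort's latent discriminability; pass
    the estimated per-subject Wald index to couple the simulation to the
    behavioral pipeline instead.
    """
    mesh = mesh if mesh is not None else default_mesh()
    n_vert = len(mesh.vertices)
    n_subj = len(cohort)
    if sensitivity is None:
        sensitivity = cohort["discrimination"].to_numpy(dtype=float)
    sensitivity = np.asarray(sensitivity, dtype=float)
    if sensitivity.size != n_subj:
        raise ValidationError("one sensitivity value per subject required")
    for spec in effect_spec:
        if not 0 <= spec.vertex < n_vert:
            raise ValidationError(f"planted vertex {spec.vertex} outside mesh (n={n_vert})")
    rng = np.random.default_rng(seed)
    ages = cohort["age"].to_numpy(dtype=float)
    thickness = np.full((n_subj, n_vert), baseline_mm)
    thickness += age_slope * (ages - ages.mean())[:, None]
    if effect_spec:
        dists = geodesic_distances(mesh, [spec.vertex for spec in effect_spec])
        for spec, d in zip(effect_spec, dists):
            inside = d <= spec.radius_mm
            thickness[:, inside] += spec.slope * sensitivity[:, None]
    if noise_sd > 0:
        noise = rng.standard_normal((n_subj, n_vert))
        if noise_fwhm_mm > 0:
            noise = smooth_maps(noise, mesh, noise_fwhm_mm)
            noise /= noise.std(axis=1, keepdims=True)  # restore unit sd
        thickness += noise_sd * noise
    covariates = cohort[["subject_id", "age", "sex", "icv"]].copy()
    covariates["sensitivity"] = sensitivity
    return SurfaceModel(mesh=mesh, thickness=thickness, covariates=covariates)


# ---------------------------------------------------------------------------
# ROI volumes
# ---------------------------------------------------------------------------

#: Typical per-hemisphere volumes (mm^3) of the eight subcortical-style
#: structures the ROI analysis enumerates.
ROI_BASELINES_MM3: dict[str, float] = {
    "thalamus": 7500.0,
    "caudate": 3800.0,
    "putamen": 5000.0,
    "pallidum": 1800.0,
    "hippocampus": 4200.0,
    "amygdala": 1700.0,
    "accumbens": 600.0,
    "cerebellum": 140000.0,
}
HEMISPHERES: tuple[str, str] = ("lh", "rh")


@dataclass(frozen=True)
class PlantedROIEffect:
    roi_name: str
    hemisphere: str
    slope: float  # mm^3 of volume per unit of sensitivity


def simulate_roi_volumes(
    cohort: pd.DataFrame,
    effect_spec: Sequence[PlantedROIEffect] = (),
    seed: int | None = None,
    *,
    sensitivity: np.ndarray | None = None,
    icv_scaling: float = 1.0,
    noise_frac: float = 0.05,
) -> pd.DataFrame:
    """Simulate an ROI volume table (8 structures x 2 hemispheres/subject).

    volume = baseline * (1 + icv_scaling * (icv/icv_mean - 1))
             + slope * sensitivity  for planted effects
             + Gaussian noise with sd = noise_frac * baseline.
    """
    rng = np.random.default_rng(seed)
    if sensitivity is None:
        sensitivity = cohort["discrimination"].to_numpy(dtype=float)
    sensitivity = np.asarray(sensitivity, dtype=float)
    icv = cohort["icv"].to_numpy(dtype=float)
    icv_rel = icv / icv.mean() - 1.0
    effects = {(e.roi_name, e.hemisphere): e.slope for e in effect_spec}
    for name, hemi in effects:
        if name not in ROI_BASELINES_MM3 or hemi not in HEMISPHERES:
            raise ValidationError(f"unknown ROI {(name, hemi)!r}")
    rows = []
    for i, sid in enumerate(cohort["subject_id"]):
        for name, base in ROI_BASELINES_MM3.items():
            for hemi in HEMISPHERES:
                value = base * (1.0 + icv_scaling * icv_rel[i])
                value += effects.get((name, hemi), 0.0) * sensitivity[i]
                value += rng.normal(0.0, noise_frac * base)
                rows.append(
                    {
                        "subject_id": sid,
                        "roi_name": name,
                        "hemisphere": hemi,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_table_tsv(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_table_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_surface_study(
    model: SurfaceModel, out_dir: str | Path, scalar_format: str = "curv"
) -> dict[str, Path]:
    """Write the mesh (FreeSurfer + PLY), covariates TSV and per-subject maps."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["mesh_fs"] = write_mesh(model.mesh, out_dir / "mesh.surf")
    paths["mesh_ply"] = write_mesh(model.mesh, out_dir / "mesh.ply")
    paths["covariates"] = write_table_tsv(model.covariates, out_dir / "covariates.tsv")
    ext = ".gii" if scalar_format == "gifti" else ".curv"
    for i, sid in enumerate(model.covariates["subject_id"]):
        paths[f"thickness_{sid}"] = write_scalar_map(
            model.thickness[i], out_dir / f"{sid}_thickness{ext}"
        )
    return paths


def read_surface_study(in_dir: str | Path) -> SurfaceModel:
    from .surface_stats import read_mesh, read_scalar_map

    in_dir = Path(in_dir)
    mesh = read_mesh(in_dir / "mesh.surf")
    covariates = read_table_tsv(in_dir / "covariates.tsv")
    maps = []
    for sid in covariates["subject_id"]:
        for ext in (".curv", ".gii"):
            path = in_dir / f"{sid}_thickness{ext}"
            if path.exists():
                maps.append(read_scalar_map(path))
                break
        else:
            raise ValidationError(f"no thickness map found for subject {sid!r}")
    return SurfaceModel(mesh=mesh, thickness=np.vstack(maps), covariates=covariates)
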