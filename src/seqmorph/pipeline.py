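"""End-to-end pipeline orchestration, configuration and run manifests.

A single declarative configuration (YAML-serializable dataclass tree) drives
the whole chain: stimulus generation -> behavioral simulation -> group
ordinal regression -> per-subject sensitivity indices -> surface simulation,
smoothing, vertex-wise regression and cluster correction -> ROI regression
with FDR.  Every stochastic stage has an explicit seed; a rerun with the
same config reproduces all numeric outputs.  Each run directory carries a
manifest (package version, config, seeds, SHA-256 of every declared output).

Units and conventions, project-wide: millimetres, 0-based vertex ids,
closed entropy-window intervals.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import SeqmorphError, ValidationError
from . import markov_design, ordinal_inference, roi_stats, surface_stats, synthetic_data

log = logging.getLogger("seqmorph")


def configure_logging(verbosity: int = 0) -> None:
    """0 = warnings, 1 = info, 2 = debug; negative silences everything."""
    level = logging.WARNING
    if verbosity >= 2:
        level = logging.DEBUG
    elif verbosity == 1:
        level = logging.INFO
    elif verbosity < 0:
        level = logging.CRITICAL
    logging.basicConfig(format="%(asctime)s %(name)s %(levelname)s %(message)s")
    log.setLevel(level)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class StimulusConfig:
    n_per_level: int = 21
    category: str = "speech"
    seed: int = 11
    me_windows: dict = field(
        default_factory=lambda: {k: list(v) for k, v in markov_design.DEFAULT_ME_WINDOWS.items()}
    )
    render_audio: bool = False


@dataclass
class BehaviorConfig:
    n_subjects: int = 18
    trials_per_condition: int = 21
    cohort_seed: int = 21
    ratings_seed: int = 22
    alpha_median: float = 1.5
    alpha_sigma: float = 0.5


@dataclass
class SurfaceConfig:
    seed: int = 31
    mesh_subdivisions: int = 4
    mesh_radius_mm: float = 50.0
    fwhm_mm: float = 10.0
    vertex_p: float = 0.05
    n_mc: int = 1000
    mc_seed: int = 32
    noise_sd: float = 0.1
    planted: list = field(default_factory=list)  # [vertex, radius_mm, slope] triples


@dataclass
class ROIConfig:
    seed: int = 41
    q: float = 0.05
    planted: list = field(default_factory=list)  # [roi_name, hemisphere, slope]


@dataclass
class PipelineConfig:
    """Declarative configuration of one reproducible pipeline run."""

    stimuli: StimulusConfig = field(default_factory=StimulusConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    surface: SurfaceConfig = field(default_factory=SurfaceConfig)
    roi: ROIConfig = field(default_factory=ROIConfig)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sections = {
            "stimuli": StimulusConfig,
            "behavior": BehaviorConfig,
            "surface": SurfaceConfig,
            "roi": ROIConfig,
        }
        kwargs = {}
        for name, section_cls in sections.items():
            data = raw.get(name, {})
            known = {f.name for f in dataclasses.fields(section_cls)}
            unknown = set(data) - known
            if unknown:
                raise ValidationError(f"unknown {name} config keys: {sorted(unknown)}")
            kwargs[name] = section_cls(**data)
        return cls(**kwargs)

    @classmethod
    def with_seed(cls, seed: int, **overrides) -> "PipelineConfig":
        """Derive all stage seeds from one master seed (kept below 2^31)."""
        ss = np.random.SeedSequence(seed).spawn(6)
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
        cfg = cls(**overrides)
        cfg.stimuli.seed = seeds[0]
        cfg.behavior.cohort_seed = seeds[1]
        cfg.behavior.ratings_seed = seeds[2]
        cfg.surface.seed = seeds[3]
        cfg.surface.mc_seed = seeds[4]
        cfg.roi.seed = seeds[5]
        return cfg


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except SeqmorphError:
                raise
            except Exception as exc:  # pragma: no cover - defensive
                raise SeqmorphError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the full analysis chain into ``out_dir``; returns the run dir.

    Stages: generate stimuli -> simulate cohort/ratings -> group ordinal
    regression -> sensitivity indices -> surface study (smooth, vertex-wise
    regression, cluster correction) -> ROI regression with FDR.  A manifest
    with checksums of every declared output and a JSON summary are written
    last.  Any stage failure aborts with the stage name; outputs of earlier
    stages are left in place.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def declare(key: str, path: Path) -> Path:
        outputs[key] = path
        return path

    config.to_yaml(declare("config", out_dir / "config.yaml"))

    # --- stimuli ---------------------------------------------------------
    design = markov_design.StimulusDesign(
        n_per_level=config.stimuli.n_per_level,
        category=config.stimuli.category,
        me_windows={k: tuple(v) for k, v in config.stimuli.me_windows.items()},
    )
    seqs = _stage("stimuli")(markov_design.generate_stimulus_set)(design, config.stimuli.seed)
    markov_design.write_sequences_tsv(seqs, declare("sequences", out_dir / "sequences.tsv"))
    summary_stim = markov_design.stimulus_set_summary(seqs)
    summary_stim.to_csv(
        declare("stimulus_summary", out_dir / "stimulus_summary.tsv"), sep="\t", index=False
    )
    if config.stimuli.render_audio:
        markov_design.render_audio(seqs, out_dir / "audio")

    # --- behavior --------------------------------------------------------
    cohort = _stage("cohort")(synthetic_data.simulate_cohort)(
        config.behavior.n_subjects,
        config.behavior.cohort_seed,
        alpha_median=config.behavior.alpha_median,
        alpha_sigma=config.behavior.alpha_sigma,
    )
    synthetic_data.write_table_tsv(cohort, declare("cohort", out_dir / "cohort.tsv"))
    ratings = _stage("ratings")(synthetic_data.simulate_ratings)(
        cohort,
        synthetic_data.RatingDesign(trials_per_condition=config.behavior.trials_per_condition),
        config.behavior.ratings_seed,
    )
    synthetic_data.write_table_tsv(ratings, declare("ratings", out_dir / "ratings.tsv"))

    # trial-level fit: averaging 21 clean simulated trials per condition
    # separates the aggregated table, so the trial-level entry point is the
    # pipeline default (both are exposed by fit_group_rmolr)
    _, contrast_table = _stage("group_rmolr")(ordinal_inference.fit_group_rmolr)(
        ratings, config.stimuli.category, aggregated=False
    )
    contrast_table.to_csv(
        declare("group_model", out_dir / "group_model.tsv"), sep="\t", index=False
    )
    reliability = ordinal_inference.split_half_reliability(ratings)
    reliability.to_csv(
        declare("reliability", out_dir / "split_half.tsv"), sep="\t", index=False
    )

    indices = _stage("sensitivity")(ordinal_inference.sensitivity_indices)(
        ratings, config.stimuli.category
    )
    synthetic_data.write_table_tsv(
        indices, declare("sensitivity", out_dir / "sensitivity_index.tsv")
    )
    valid = indices[indices["valid"]]
    if len(valid) < len(indices):
        log.warning(
            "excluding %d subject(s) with degenerate sensitivity fits",
            len(indices) - len(valid),
        )
    cohort_valid = cohort[cohort["subject_id"].isin(valid["subject_id"])].reset_index(drop=True)
    sens = valid.set_index("subject_id").loc[cohort_valid["subject_id"], "wald_chi2"].to_numpy()

    # --- surface ---------------------------------------------------------
    mesh = surface_stats.default_mesh(
        config.surface.mesh_subdivisions, config.surface.mesh_radius_mm
    )
    planted = [synthetic_data.PlantedCluster(int(v), float(r), float(s))
               for v, r, s in config.surface.planted]
    model = _stage("surface_sim")(synthetic_data.simulate_surface_study)(
        cohort_valid,
        mesh,
        planted,
        config.surface.seed,
        sensitivity=sens,
        noise_sd=config.surface.noise_sd,
    )
    model = _stage("smoothing")(surface_stats.smooth_model)(model, config.surface.fwhm_mm)
    vertex_results = _stage("vertexwise")(surface_stats.vertexwise_regression)(model)
    surface_stats.write_scalar_map(
        vertex_results["t"].to_numpy(), declare("t_map", out_dir / "sensitivity_t.curv")
    )
    clusters = _stage("cluster_correct")(surface_stats.cluster_correct)(
        model,
        vertex_p=config.surface.vertex_p,
        n_mc=config.surface.n_mc,
        seed=config.surface.mc_seed,
    )
    ctable = surface_stats.cluster_table(clusters, mesh)
    ctable.to_csv(declare("clusters", out_dir / "clusters.tsv"), sep="\t", index=False)

    # --- ROI -------------------------------------------------------------
    roi_effects = [synthetic_data.PlantedROIEffect(str(n), str(h), float(s))
                   for n, h, s in config.roi.planted]
    roi_table = _stage("roi_sim")(synthetic_data.simulate_roi_volumes)(
        cohort_valid, roi_effects, config.roi.seed, sensitivity=sens
    )
    synthetic_data.write_table_tsv(roi_table, declare("roi_table", out_dir / "roi_volumes.tsv"))
    covariates = cohort_valid.copy()
    covariates["sensitivity"] = sens
    roi_results = _stage("roi_regress")(roi_stats.roi_analysis)(
        roi_table, covariates, mode="volume", q=config.roi.q
    )
    roi_results.to_csv(declare("roi_results", out_dir / "roi_results.tsv"), sep="\t", index=False)

    # --- summary + manifest ---------------------------------------------
    summary = {
        "n_sequences": len(seqs),
        "stimulus_me_means": {
            row["condition"]: round(float(row["empirical_me_mean"]), 4)
            for _, row in summary_stim.iterrows()
        },
        "n_subjects": int(len(cohort)),
        "n_valid_sensitivity": int(len(valid)),
        "group_omnibus_wald": float(
            contrast_table.loc[contrast_table["contrast"] == "omnibus", "wald_chi2"].iloc[0]
        ),
        "n_clusters": int(len(ctable)),
        "n_significant_clusters": int(ctable["significant"].sum()) if len(ctable) else 0,
        "n_roi_discoveries": int(roi_results["significant"].sum()),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    declare("summary", out_dir / "summary.json")

    manifest = {
        "package": "seqmorph",
        "version": __version__,
        "seeds": {
            "stimuli": config.stimuli.seed,
            "cohort": config.behavior.cohort_seed,
            "ratings": config.behavior.ratings_seed,
            "surface": config.surface.seed,
            "monte_carlo": config.surface.mc_seed,
            "roi": config.roi.seed,
        },
        "outputs": {
            key: {"path": str(p.relative_to(out_dir)), "sha256": _sha256(p)}
            for key, p in outputs.items()
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline complete: %s", out_dir)
    return out_dir


def validate_manifest(run_dir: str | Path) -> bool:
    """Re-hash every declared output and compare with the manifest."""
    run_dir = Path(run_dir)
    manifest = json.loads((run_dir / "manifest.json").read_text())
    for entry in manifest["outputs"].values():
        path = run_dir / entry["path"]
        if not path.exists() or _sha256(path) != entry["sha256"]:
            return False
    return True
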