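"""End-to-end pipeline driver.

Runs the stages ``simulate -> cluster -> fit -> assess -> curves -> project
-> summarize`` over a directory of plain-text artifacts, so any stage can be
re-run from the outputs of the previous ones.  All randomness flows from one
root seed: stage ``i`` uses ``SeedSequence([seed, i])`` (per-OTU fits add the
OTU's position), and every stage writes a manifest recording the config hash
and the seeds actually used.  Re-running a stage with the same config
produces byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .assessment import (
    AssessmentRecord,
    apply_exclusion,
    assessment_table,
    cor_expl,
    cor_pred,
    importance_gbm,
    importance_shuffle,
    make_split_plan,
)
from .community import change_summary, curves_frame, project_sites, response_curve, stack_profiles
from .containers import OtuTable
from .models import ModelSpec, OffsetSpec, fit_model, model_from_json, model_to_json
from .otu import cluster_zotus, filter_low_count_zotus, filter_low_prevalence_otus
from .scenarios import apply_scenarios, default_shift_triple, estimate_mean_slope, shift_triple_from_slope
from .schema import default_schema
from . import synthetic

STAGES = ("simulate", "cluster", "fit", "assess", "curves", "project", "summarize")


@dataclass
class PipelineConfig:
    """Validated configuration; defaults carry the protocol constants."""

    output_dir: str = "soilsdm_run"
    seed: int = 0
    # simulate
    n_train_sites: int = 255
    n_proj_sites: int = 229
    n_otus: int = 60
    zotus_per_otu: int = 3
    dispersion: float = 1.0
    # cluster
    cutoffs: tuple[float, ...] = (20.0, 40.0, 60.0)
    primary_cutoff: float = 40.0
    min_total: int = 100
    min_sites: int = 21
    # models
    engine: str = "gam"
    family: str = "negbin"
    n_trees: int = 2000
    interaction_depth: int = 3
    shrinkage: float = 0.01
    basis_df: int = 10
    # assessment
    split_repeats: int = 10
    calibration_fraction: float = 0.8
    exclusion_threshold: float = 0.2
    n_perms: int = 10
    # scenarios
    ph_shift: float = 0.3
    toc_shift: float = 3.2
    base_year: int = 2013
    target_year: int = 2060
    shifts_from_resurvey: bool = False
    # curves / summaries
    n_grid: int = 100
    curve_variables: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        errors = []
        if self.engine not in ("gam", "gbm"):
            errors.append(f"engine: unknown engine {self.engine!r}")
        if self.family not in ("poisson", "negbin"):
            errors.append(f"family: unknown family {self.family!r}")
        if self.engine == "gbm" and self.family == "negbin":
            errors.append("family: the negative-binomial family is not available for gbm")
        if self.primary_cutoff not in tuple(self.cutoffs):
            errors.append(f"primary_cutoff: {self.primary_cutoff} not among cutoffs {self.cutoffs}")
        for key in ("n_train_sites", "n_proj_sites", "n_otus", "zotus_per_otu", "split_repeats"):
            if getattr(self, key) < 1:
                errors.append(f"{key}: must be positive")
        if not 0 < self.calibration_fraction < 1:
            errors.append("calibration_fraction: must be in (0, 1)")
        if self.dispersion <= 0:
            errors.append("dispersion: must be positive")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))

    def model_spec(self) -> ModelSpec:
        return ModelSpec(
            engine=self.engine,
            family=self.family if self.engine == "gam" else "poisson",
            basis_df=self.basis_df,
            n_trees=self.n_trees,
            interaction_depth=self.interaction_depth,
            shrinkage=self.shrinkage,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"invalid configuration: unknown keys {unknown}")
        for key in ("cutoffs", "curve_variables"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cutoffs"] = list(self.cutoffs)
        if self.curve_variables is not None:
            d["curve_variables"] = list(self.curve_variables)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def stage_seed(root_seed: int, stage: str) -> int:
    """Per-stage child seed, kept below 2**31."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([root_seed, idx]).generate_state(1)[0] & 0x7FFFFFFF)


class MissingArtifactError(FileNotFoundError):
    pass


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"missing artifact {path.name} (run the {producer!r} stage first)"
        )
    return path


def _write_manifest(out: Path, stage: str, config: PipelineConfig, seeds: dict) -> None:
    from . import __version__

    sio.write_json(
        {
            "stage": stage,
            "config": config.to_dict(),
            "config_digest": config.digest(),
            "seeds": seeds,
            "version": __version__,
        },
        out / f"manifest_{stage}.json",
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def run_simulate(config: PipelineConfig, out: Path) -> None:
    seed = stage_seed(config.seed, "simulate")
    schema = default_schema()
    ds = synthetic.generate_dataset(
        n_sites=config.n_train_sites,
        n_otus=config.n_otus,
        dispersion=config.dispersion,
        seed=seed,
        schema=schema,
    )
    env_proj = synthetic.generate_projection_env(schema, config.n_proj_sites, seed=seed + 10)
    climate_future = synthetic.generate_future_climate(env_proj, seed=seed + 11)
    zotus, members = synthetic.generate_zotu_table(ds.counts, config.zotus_per_otu, seed=seed + 12)
    records, sim = synthetic.generate_family_similarity(members, seed=seed + 13)
    dt = config.target_year - config.base_year
    resurvey = pd.concat(
        [
            synthetic.generate_resurvey_pairs(
                config.ph_shift / dt, 0.05, seed=seed + 14, variable="pH"
            ),
            synthetic.generate_resurvey_pairs(
                config.toc_shift / dt, 0.5, seed=seed + 15, variable="TOC",
                value_range=(1.0, 40.0),
            ),
        ],
        ignore_index=True,
    )

    sio.write_env_csv(ds.env, out / "env_train.csv")
    sio.write_env_csv(env_proj, out / "env_proj.csv")
    sio.write_env_csv(climate_future, out / "climate_future.csv")
    sio.write_zotu_table(
        zotus, out / "zotu.counts.tsv", out / "zotu.taxonomy.tsv", out / "zotu.lib.tsv"
    )
    sio.write_similarity_tsv(sim, out / "similarity.tsv")
    sio.write_fasta(records, out / "sequences.fasta")
    resurvey.to_csv(out / "resurvey.csv", index=False)
    sio.write_json(
        {
            "optimum": ds.truth.optimum.to_dict(),
            "breadth": ds.truth.breadth.to_dict(),
            "baseline": ds.truth.baseline.to_dict(),
            "dispersion": ds.dispersion,
        },
        out / "truth.json",
    )
    _write_manifest(out, "simulate", config, {"simulate": seed})


def run_cluster(config: PipelineConfig, out: Path) -> None:
    zotus = sio.read_zotu_table(
        _require(out / "zotu.counts.tsv", "simulate"),
        _require(out / "zotu.taxonomy.tsv", "simulate"),
        _require(out / "zotu.lib.tsv", "simulate"),
    )
    sim = sio.read_similarity_tsv(_require(out / "similarity.tsv", "simulate"))
    zotus = filter_low_count_zotus(zotus, min_total=config.min_total)
    sim_kept = _subset_similarity(sim, zotus.zotu_ids)
    for cutoff in config.cutoffs:
        otus = cluster_zotus(zotus, sim_kept, cutoff)
        sio.write_otu_table(otus, out / f"otu_cl{cutoff:g}")
    _write_manifest(out, "cluster", config, {})


def _subset_similarity(sim, keep_ids):
    from .containers import SimilarityScores

    keep = [i for i, x in enumerate(sim.ids) if x in set(keep_ids)]
    ids = tuple(sim.ids[i] for i in keep)
    return SimilarityScores(ids=ids, sim=sim.sim[np.ix_(keep, keep)])


def _load_primary_otus(config: PipelineConfig, out: Path) -> OtuTable:
    prefix = out / f"otu_cl{config.primary_cutoff:g}"
    _require(prefix.with_suffix(".counts.tsv"), "cluster")
    otus = sio.read_otu_table(prefix)
    return filter_low_prevalence_otus(otus, min_sites=config.min_sites)


def run_fit(config: PipelineConfig, out: Path) -> None:
    seed = stage_seed(config.seed, "fit")
    otus = _load_primary_otus(config, out)
    env = sio.read_env_csv(_require(out / "env_train.csv", "simulate"), default_schema())
    offset = OffsetSpec.per_site(otus.library_sizes)
    spec = config.model_spec()
    with open(out / "models.jsonl", "w") as fh:
        for i, otu in enumerate(otus.otu_ids):
            model = fit_model(
                otus.counts.loc[otu], env, offset, spec, seed=seed + i, otu_id=otu
            )
            fh.write(model_to_json(model) + "\n")
    _write_manifest(out, "fit", config, {"fit": seed})


def _load_models(out: Path) -> dict:
    path = _require(out / "models.jsonl", "fit")
    models = {}
    with open(path) as fh:
        for line in fh:
            m = model_from_json(line)
            models[m.otu_id] = m
    return models


def run_assess(config: PipelineConfig, out: Path) -> None:
    seed = stage_seed(config.seed, "assess")
    otus = _load_primary_otus(config, out)
    env = sio.read_env_csv(_require(out / "env_train.csv", "simulate"), default_schema())
    offset = OffsetSpec.per_site(otus.library_sizes)
    models = _load_models(out)
    spec = config.model_spec()
    plan = make_split_plan(
        env.index, seed=seed, n_repeats=config.split_repeats,
        calibration_fraction=config.calibration_fraction,
    )
    records = []
    for i, (otu, model) in enumerate(models.items()):
        obs = otus.counts.loc[otu]
        ce = cor_expl(obs, model.fitted)
        tuning = None
        if spec.engine == "gam":
            tuning = {"alpha_smooth": model.alpha_smooth, "nb_alpha": model.nb_alpha}
        cp = cor_pred(obs, env, offset, spec, plan, seed=seed + i, fixed_tuning=tuning)
        if spec.engine == "gbm":
            imp = importance_gbm(model)
        else:
            imp = importance_shuffle(
                model, env, obs, offset, n_perms=config.n_perms, seed=seed + 1000 + i
            )
        records.append(
            AssessmentRecord(
                otu_id=otu, engine=spec.engine, family=spec.family,
                cor_expl=ce, cor_pred=cp, importance=imp,
            )
        )
    retained, _ = apply_exclusion(records, threshold=config.exclusion_threshold)
    assessment_table(records).to_csv(out / "assessment.tsv", sep="\t", index=False)
    sio.write_json(
        {
            "retained": [r.otu_id for r in retained],
            "plan": {
                "seed": plan.seed,
                "repeats": [[list(c), list(e)] for c, e in plan.repeats],
            },
        },
        out / "retained.json",
    )
    _write_manifest(out, "assess", config, {"assess": seed})


def _retained_models(config: PipelineConfig, out: Path) -> dict:
    models = _load_models(out)
    retained = sio.read_json(_require(out / "retained.json", "assess"))["retained"]
    return {k: models[k] for k in retained}


def run_curves(config: PipelineConfig, out: Path) -> None:
    otus = _load_primary_otus(config, out)
    env = sio.read_env_csv(_require(out / "env_train.csv", "simulate"), default_schema())
    models = _retained_models(config, out)
    offset = OffsetSpec.fixed_median(otus.library_sizes)
    variables = config.curve_variables or tuple(default_schema().names)
    curves = [
        response_curve(m, env, v, offset, n_grid=config.n_grid)
        for m in models.values()
        for v in variables
    ]
    curves_frame(curves).to_csv(out / "curves.tsv", sep="\t", index=False)
    profiles = []
    for v in variables:
        sub = [c for c in curves if c.variable == v]
        grid = sub[0].grid
        abund = pd.DataFrame(
            [c.abundance for c in sub],
            index=[c.otu_id for c in sub],
            columns=[f"{v}={g:.6g}" for g in grid],
        )
        prof = stack_profiles(abund, otus.phylum)
        frame = pd.DataFrame(
            {
                "variable": v,
                "grid_value": grid,
                "prop_above_median": prof.prop_above_median.to_numpy(),
                "shannon": prof.shannon.to_numpy(),
            }
        )
        profiles.append(frame)
    pd.concat(profiles, ignore_index=True).to_csv(out / "gradient_profiles.tsv", sep="\t", index=False)
    _write_manifest(out, "curves", config, {})


def _scenario_grid(config: PipelineConfig, out: Path):
    env_train = sio.read_env_csv(_require(out / "env_train.csv", "simulate"), default_schema())
    env_proj = sio.read_env_csv(_require(out / "env_proj.csv", "simulate"), default_schema())
    climate_future = sio.read_env_csv(_require(out / "climate_future.csv", "simulate"))
    if config.shifts_from_resurvey:
        resurvey = pd.read_csv(_require(out / "resurvey.csv", "simulate"))
        ph = shift_triple_from_slope(
            estimate_mean_slope(resurvey, "pH"), config.base_year, "pH", config.target_year
        )
        toc = shift_triple_from_slope(
            estimate_mean_slope(resurvey, "TOC"), config.base_year, "TOC", config.target_year
        )
    else:
        from .scenarios import ScenarioShift

        ph = (
            ScenarioShift("pH", "inc", config.ph_shift),
            ScenarioShift("pH", "now", 0.0),
            ScenarioShift("pH", "dec", -config.ph_shift),
        )
        toc = (
            ScenarioShift("TOC", "inc", config.toc_shift),
            ScenarioShift("TOC", "now", 0.0),
            ScenarioShift("TOC", "dec", -config.toc_shift),
        )
    grid = apply_scenarios(env_proj, climate_future, ph, toc, env_training=env_train)
    return env_proj, grid


def run_project(config: PipelineConfig, out: Path) -> None:
    otus = _load_primary_otus(config, out)
    models = _retained_models(config, out)
    offset = OffsetSpec.fixed_median(otus.library_sizes)
    env_proj, grid = _scenario_grid(config, out)
    current = project_sites(models, env_proj, offset)
    current.to_csv(out / "proj_current.tsv", sep="\t", index_label="otu")
    for name, tab in grid.tables.items():
        sio.write_env_csv(tab, out / f"scenario_{name}.csv")
        grid.flags[name].to_csv(out / f"flags_{name}.csv", index_label="site")
        project_sites(models, tab, offset).to_csv(
            out / f"proj_{name}.tsv", sep="\t", index_label="otu"
        )
    _write_manifest(out, "project", config, {})


def run_summarize(config: PipelineConfig, out: Path) -> None:
    otus = _load_primary_otus(config, out)
    current = pd.read_csv(_require(out / "proj_current.tsv", "project"), sep="\t", index_col=0)
    _, grid = _scenario_grid(config, out)
    frames = []
    for name in grid.names:
        future = pd.read_csv(_require(out / f"proj_{name}.tsv", "project"), sep="\t", index_col=0)
        flags = pd.read_csv(out / f"flags_{name}.csv", index_col=0)["any"]
        cs = change_summary(current, future, otus.phylum, analog_flags=flags)
        frame = cs.frame()
        frame.insert(0, "scenario", name)
        frame.insert(1, "site", frame.index)
        frames.append(frame.reset_index(drop=True))
    summary = pd.concat(frames, ignore_index=True)
    summary.to_csv(out / "summary_all.tsv", sep="\t", index=False)
    summary[summary["analog"]].to_csv(out / "summary_analog.tsv", sep="\t", index=False)
    _write_manifest(out, "summarize", config, {})


_STAGE_FUNCS = {
    "simulate": run_simulate,
    "cluster": run_cluster,
    "fit": run_fit,
    "assess": run_assess,
    "curves": run_curves,
    "project": run_project,
    "summarize": run_summarize,
}


def run_pipeline(config: PipelineConfig, stages=None) -> Path:
    """Run the requested stages (all by default) in dependency order."""
    stages = list(stages) if stages else list(STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        if stage in stages:
            _STAGE_FUNCS[stage](config, out)
    return out


__all__ = [
    "MissingArtifactError",
    "PipelineConfig",
    "STAGES",
    "run_pipeline",
    "stage_seed",
]
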