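"""End-to-end pipeline orchestration with deterministic seeding and
stage caching.

Stage order: simulate (or load user tables) -> preprocess -> univariate
-> pca -> classify -> survive.  Each stage writes delimited-text outputs
into ``outdir/<stage>/`` along with a hash of its effective
configuration; when a stage's hash is unchanged on a rerun, its outputs
are reused instead of recomputed.  A run manifest lists every emitted
file with a SHA-256 checksum, so two runs with the same config and seed
are verifiably bit-identical.

The survival stage consumes exactly the consensus components produced
by the classification stage; if the consensus is empty the stage is
skipped with an explicit notice and the run still succeeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import pathway_pca as ppca
from .data import (
    AnalysisConfig,
    CohortMetadata,
    ValidationError,
    read_cohort,
    write_results,
)
from .preprocess import preprocess
from .simulate import EffectConfig, generate_cohort, truth_report, write_cohort
from .survival import fit_cox, km_stratify, survival_report
from .univariate import run_univariate

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "univariate", "pca", "classify", "survive")

CONFIG_SCHEMA_VERSION = 1

# Per-stage seed offsets fanned out from the master seed.
SEED_OFFSETS = {"simulate": 0, "classify": 500_000}


@dataclass
class SimulateConfig:
    n_per_group: tuple[int, ...] = (30, 26, 45, 33, 32)
    n_subpathways: int = 91
    n_metabolites: int = 842
    effects: EffectConfig = field(default_factory=EffectConfig)


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "results/run"
    simulate: SimulateConfig | None = field(default_factory=SimulateConfig)
    inputs: dict | None = None  # {"abundance":..., "pathways":..., "metadata":...}
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        version = raw.pop("schema_version", CONFIG_SCHEMA_VERSION)
        if version != CONFIG_SCHEMA_VERSION:
            raise ValidationError(f"unsupported config schema version {version}")
        known = {"seed", "outdir", "simulate", "inputs", "analysis"}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        sim = None
        if raw.get("simulate") is not None:
            s = dict(raw["simulate"])
            eff = EffectConfig(**s.pop("effects", {}))
            if "n_per_group" in s:
                s["n_per_group"] = tuple(s["n_per_group"])
            sim = SimulateConfig(effects=eff, **s)
        inputs = raw.get("inputs")
        if sim is None and inputs is None:
            raise ValidationError("config must provide either simulate or inputs")
        analysis = AnalysisConfig.from_dict(raw.get("analysis", {}))
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            outdir=str(raw.get("outdir", "results/run")),
            simulate=sim,
            inputs=inputs,
            analysis=analysis,
        )
        # classification randomness flows from the master seed
        cfg.analysis.random_seed = cfg.seed + SEED_OFFSETS["classify"]
        return cfg

    def snapshot(self) -> dict:
        return {
            "schema_version": CONFIG_SCHEMA_VERSION,
            "seed": self.seed,
            "outdir": self.outdir,
            "simulate": None if self.simulate is None else asdict(self.simulate),
            "inputs": self.inputs,
            "analysis": asdict(self.analysis),
        }


@dataclass
class PipelineRun:
    config_snapshot: dict
    master_seed: int
    stage_seconds: dict[str, float]
    manifest: dict[str, str]  # relative path -> sha256
    outdir: Path
    skipped: list[str]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()


def _stage_cached(stage_dir: Path, stage_hash: str, files: list[str]) -> bool:
    marker = stage_dir / ".stage_hash"
    if not marker.exists() or marker.read_text().strip() != stage_hash:
        return False
    return all((stage_dir / f).exists() for f in files)


def _mark_stage(stage_dir: Path, stage_hash: str) -> None:
    (stage_dir / ".stage_hash").write_text(stage_hash + "\n")


def run_pipeline(
    config: PipelineConfig | str | Path, stop_after: str | None = None
) -> PipelineRun:
    """Execute the pipeline from a config object or YAML path.

    ``stop_after`` names a stage after which to stop (outputs of later
    stages are untouched); the default runs everything.
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ValidationError(f"unknown stage {stop_after!r}")
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    snapshot = config.snapshot()
    timings: dict[str, float] = {}
    skipped: list[str] = []
    acfg = config.analysis

    def timed(name):
        class _T:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()

            def __exit__(self_inner, *exc):
                timings[name] = round(time.perf_counter() - self_inner.t0, 3)

        return _T()

    # ---------------- simulate / load ----------------
    sim_dir = outdir / "simulate"
    sim_dir.mkdir(exist_ok=True)
    with timed("simulate"):
        if config.simulate is not None:
            sim_hash = _stage_hash({"simulate": asdict(config.simulate),
                                    "seed": config.seed})
            files = ["abundance.csv", "pathways.csv", "metadata.csv",
                     "truth_effects.csv", "truth_severity.csv"]
            if not _stage_cached(sim_dir, sim_hash, files):
                s = config.simulate
                matrix, pmap, meta, truth = generate_cohort(
                    n_per_group=s.n_per_group,
                    n_subpathways=s.n_subpathways,
                    n_metabolites=s.n_metabolites,
                    effects=s.effects,
                    seed=config.seed + SEED_OFFSETS["simulate"],
                )
                write_cohort(matrix, pmap, meta, truth, sim_dir)
                _mark_stage(sim_dir, sim_hash)
            paths = {k: sim_dir / f"{k}.csv"
                     for k in ("abundance", "pathways", "metadata")}
        else:
            paths = {k: Path(v) for k, v in config.inputs.items()
                     if k in ("abundance", "pathways", "metadata")}
            for k in ("abundance", "pathways", "metadata"):
                if k not in paths or not paths[k].exists():
                    raise ValidationError(f"missing input table: {k}")
        matrix, pmap, meta = read_cohort(
            paths["abundance"], paths["pathways"], paths["metadata"]
        )

    if stop_after == "simulate":
        return _finish(outdir, snapshot, config.seed, timings, skipped)

    # ---------------- preprocess ----------------
    pre_dir = outdir / "preprocess"
    pre_dir.mkdir(exist_ok=True)
    with timed("preprocess"):
        pre = preprocess(matrix, pmap, acfg)
        write_results(
            {
                "preprocess_report": pre.report.to_frame(),
                "half_minimums": pre.report.half_minimums.rename("half_minimum")
                .rename_axis("metabolite")
                .reset_index(),
            },
            pre_dir,
        )
        pre.scaled.values.to_csv(pre_dir / "scaled_matrix.csv", index_label="participant")

    if stop_after == "preprocess":
        return _finish(outdir, snapshot, config.seed, timings, skipped)

    # ---------------- univariate ----------------
    uni_dir = outdir / "univariate"
    uni_dir.mkdir(exist_ok=True)
    with timed("univariate"):
        uni = run_univariate(pre, meta, acfg)
        write_results({"univariate": uni.table}, uni_dir)

    if stop_after == "univariate":
        return _finish(outdir, snapshot, config.seed, timings, skipped)

    # ---------------- pca ----------------
    pca_dir = outdir / "pca"
    pca_dir.mkdir(exist_ok=True)
    with timed("pca"):
        locals_ = ppca.fit_local_pcas(pre.scaled, pre.pathway_map, acfg)
        sub_table, sig_subs = ppca.subpathway_group_tests(
            locals_, meta, fdr_threshold=acfg.fdr_threshold, fdr_method=acfg.fdr_method
        )
        gmodel = ppca.global_pca(
            locals_,
            retention=acfg.global_retention,
            fixed_k=acfg.global_fixed_k,
            kaiser_threshold=acfg.kaiser_threshold,
            standardize=acfg.standardize_local_scores,
        )
        eig_rows = [
            {"subpathway": sub, "n_metabolites": len(m.metabolite_ids),
             "n_retained": m.n_retained,
             "eigenvalues": ";".join(f"{v:.10g}" for v in m.eigenvalues)}
            for sub, m in locals_.items()
        ]
        write_results(
            {
                "local_eigenvalues": pd.DataFrame(eig_rows),
                "subpathway_tests": sub_table,
                "significant_subpathways": pd.DataFrame(
                    {"subpathway": sig_subs}
                ),
                "global_eigenvalues": pd.DataFrame(
                    {"component": [f"G{k+1}" for k in range(len(gmodel.eigenvalues))],
                     "eigenvalue": gmodel.eigenvalues}
                ),
            },
            pca_dir,
        )
        gmodel.scores.to_csv(pca_dir / "global_scores.csv", index_label="participant")

    if stop_after == "pca":
        return _finish(outdir, snapshot, config.seed, timings, skipped)

    # ---------------- classify ----------------
    clf_dir = outdir / "classify"
    clf_dir.mkdir(exist_ok=True)
    with timed("classify"):
        clf_hash = _stage_hash(
            {"analysis": asdict(acfg), "seed": config.seed,
             "scores": _sha256(pca_dir / "global_scores.csv")}
        )
        files = ["accuracy_matrix.csv", "pair_selections.csv", "consensus.csv"]
        if _stage_cached(clf_dir, clf_hash, files):
            consensus = (
                pd.read_csv(clf_dir / "consensus.csv")["component"].astype(str).tolist()
            )
        else:
            results, matrix_acc = clf.run_pairwise_suite(gmodel, meta, acfg)
            consensus = clf.consensus_component(results)
            sel_rows = []
            for (a, b), res in results.items():
                for rep, (accv, sel) in enumerate(
                    zip(res.rep_accuracies, res.rep_selected)
                ):
                    sel_rows.append(
                        {"group_a": a, "group_b": b, "repetition": rep,
                         "accuracy": accv,
                         "selected": ";".join(sorted(sel)),
                         "consensus": ";".join(sorted(res.consensus))}
                    )
            write_results(
                {
                    "accuracy_matrix": matrix_acc.rename_axis("group").reset_index(),
                    "pair_selections": pd.DataFrame(sel_rows),
                    "consensus": pd.DataFrame({"component": consensus}),
                },
                clf_dir,
            )
            _mark_stage(clf_dir, clf_hash)

    if stop_after == "classify":
        return _finish(outdir, snapshot, config.seed, timings, skipped)

    # ---------------- survive ----------------
    surv_dir = outdir / "survive"
    surv_dir.mkdir(exist_ok=True)
    with timed("survive"):
        if not consensus:
            logger.warning(
                "consensus component set is empty; survival stage skipped"
            )
            skipped.append("survive")
            (surv_dir / "SKIPPED.txt").write_text(
                "survival stage skipped: empty consensus component set\n"
            )
        else:
            tables: dict[str, pd.DataFrame] = {}
            for comp in consensus:
                scores = gmodel.scores[comp]
                fit = fit_cox(scores, meta)
                strata = km_stratify(
                    (scores.loc[meta.patient_ids]
                     - scores.loc[meta.patient_ids].mean())
                    / scores.loc[meta.patient_ids].std(ddof=1),
                    meta,
                    z_cut=acfg.km_z_cut,
                )
                rep = survival_report(fit, strata)
                for name, tab in rep.items():
                    tables[f"{comp}_{name}"] = tab
            write_results(tables, surv_dir)

    return _finish(outdir, snapshot, config.seed, timings, skipped)


def _finish(
    outdir: Path,
    snapshot: dict,
    seed: int,
    timings: dict[str, float],
    skipped: list[str],
) -> PipelineRun:
    """Checksum every emitted file and write the run manifest."""
    manifest: dict[str, str] = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name not in (".stage_hash", "manifest.json"):
            manifest[str(path.relative_to(outdir))] = _sha256(path)
    run = PipelineRun(
        config_snapshot=snapshot,
        master_seed=seed,
        stage_seconds=timings,
        manifest=manifest,
        outdir=outdir,
        skipped=skipped,
    )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(
            {
                "config": snapshot,
                "master_seed": seed,
                "skipped_stages": skipped,
                "files": manifest,
            },
            fh,
            indent=2,
            sort_keys=True,
            default=str,
        )
        fh.write("\n")
    return run
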