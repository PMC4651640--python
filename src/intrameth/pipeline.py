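"""End-to-end orchestration: simulate/load -> measures -> classify ->
RBFE -> stump ranking -> enrichment, with a machine-readable run report.

A single master seed fans out deterministically to per-stage seeds
(stage-name CRC offsets), so any stage can be rerun in isolation and
reproduce its part of a full run exactly.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from intrameth import io as imio
from intrameth import synthetic
from intrameth.classify import ModelSpec, nested_cv_evaluate
from intrameth.enrichment import curves_to_frame, enrich_collection
from intrameth.measures import (
    MEASURES,
    compute_measure_matrix,
    kendall_concordance,
    split_columns,
)
from intrameth.rbfe import run_rbfe, stump_rank

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (master_seed + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Everything one pipeline run needs, YAML-loadable."""

    seed: int
    out_dir: str
    # either simulate-block parameters ...
    simulate: dict[str, Any] | None = None
    # ... or paths to the four inputs
    beta_path: str | None = None
    manifest_path: str | None = None
    samplesheet_path: str | None = None
    gmt_path: str | None = None

    measures: tuple[str, ...] = MEASURES
    models: tuple[str, ...] = ("l1_logistic", "random_forest")
    n_folds: int = 5
    rf_trees: int = 1000
    rf_depth: int = 3
    rbfe_base: str = "l1_logistic"
    rbfe_batch_size: int | None = None
    rbfe_measure: str | None = None  # None -> all features
    stump_measure: str = "MEAN"
    stump_error_cutoff: float = 0.10
    enrichment_threshold: float = 0.01
    induced_class: str | None = None
    run_rbfe_stage: bool = True
    run_enrichment_stage: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        unknown = set(self.measures) - set(MEASURES)
        if unknown:
            raise ValueError(f"unknown measure name(s): {sorted(unknown)}")
        if self.stump_measure not in MEASURES:
            raise ValueError(f"unknown stump_measure {self.stump_measure!r}")
        for thr in (self.stump_error_cutoff, self.enrichment_threshold):
            if not 0.0 < thr < 1.0:
                raise ValueError("thresholds must be in (0, 1)")
        if self.simulate is None:
            for p in (self.beta_path, self.manifest_path, self.samplesheet_path):
                if p is None:
                    raise ValueError("either a simulate block or all input paths")
                if not Path(p).exists():
                    raise FileNotFoundError(p)
            if self.gmt_path is not None and not Path(self.gmt_path).exists():
                raise FileNotFoundError(self.gmt_path)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("measures", "models"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _simulate_stage(cfg: RunConfig, out: Path) -> tuple[Path, Path, Path, Path | None]:
    """Generate inputs from the simulate block; returns the four paths."""
    sim = dict(cfg.simulate or {})
    seed = stage_seed(cfg.seed, "simulate")
    rng_seed = sim.get("seed", seed)
    manifest = synthetic.generate_manifest(
        n_genes=sim.get("n_genes", 200),
        probes_per_gene=tuple(sim.get("probes_per_gene", (5, 20))),
        coordinate_spacing=tuple(sim.get("coordinate_spacing", (50, 500))),
        seed=rng_seed,
    )
    genes = list(dict.fromkeys(manifest["gene"]))
    effects = []
    planted: list[str] = []
    import numpy as np

    pick_rng = np.random.default_rng(rng_seed + 1)
    for eff in sim.get("effects", []):
        n_targets = int(eff.get("n_targets", 0))
        targets = eff.get("target_genes")
        if targets is None:
            available = [g for g in genes if g not in set(planted)]
            targets = sorted(
                pick_rng.choice(available, size=n_targets, replace=False).tolist()
            )
        effects.append(
            synthetic.EffectSpec(
                target_genes=tuple(targets),
                measure=eff["measure"],
                effect_size=float(eff["effect_size"]),
                noise_sd=float(eff.get("noise_sd", sim.get("noise_sd", 0.05))),
            )
        )
        planted.extend(targets)
    data = synthetic.generate_betas(
        manifest,
        n_class0=sim.get("n_class0", 31),
        n_class1=sim.get("n_class1", 35),
        effects=effects,
        noise_sd=sim.get("noise_sd", 0.05),
        seed=rng_seed + 2,
    )
    simdir = out / "simulated"
    simdir.mkdir(parents=True, exist_ok=True)
    beta_path = simdir / "betas.tsv"
    manifest_path = simdir / "manifest.csv"
    sheet_path = simdir / "samplesheet.csv"
    imio.write_betas(data.betas, beta_path)
    imio.write_manifest(manifest, manifest_path)
    imio.write_samplesheet(data.labels, sheet_path)
    (simdir / "planted_genes.txt").write_text("".join(g + "\n" for g in planted))

    gmt_path: Path | None = None
    gs = sim.get("gene_sets")
    if gs:
        default_size = min(40, max(4, len(genes) // 4), 2 * max(len(planted), 2))
        sets = synthetic.generate_gene_sets(
            manifest,
            planted_genes=planted,
            n_sets=gs.get("n_sets", 1),
            overlap_fraction=gs.get("overlap_fraction", 0.5),
            set_size=gs.get("set_size", default_size),
            seed=rng_seed + 3,
        )
        gmt_path = simdir / "gene_sets.gmt"
        imio.write_gene_sets(sets, gmt_path)
    return beta_path, manifest_path, sheet_path, gmt_path


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute every stage; write all artifacts; return the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "seed": config.seed,
        "stages": {},
    }

    def _timed(stage: str):
        t0 = time.perf_counter()

        def done(**extra):
            report["stages"][stage] = {
                "seconds": round(time.perf_counter() - t0, 3),
                **extra,
            }

        return done

    # --- inputs
    done = _timed("inputs")
    if config.simulate is not None:
        beta_path, manifest_path, sheet_path, gmt_path = _simulate_stage(config, out)
    else:
        beta_path = Path(config.beta_path)
        manifest_path = Path(config.manifest_path)
        sheet_path = Path(config.samplesheet_path)
        gmt_path = Path(config.gmt_path) if config.gmt_path else None
    dataset = imio.load_dataset(beta_path, manifest_path, sheet_path)
    done(n_probes=int(dataset.betas.shape[0]), n_samples=int(dataset.betas.shape[1]))

    # --- measures + concordance
    done = _timed("measures")
    matrix = compute_measure_matrix(dataset, config.measures)
    imio.write_measure_matrix(matrix, out / "measures.tsv")
    if set(config.measures) == set(MEASURES):
        kendall = kendall_concordance(matrix)
        kendall.to_csv(out / "kendall.csv", index_label="sample_id")
        done(n_features=int(matrix.shape[1]),
             kendall_significant=int(kendall["significant"].sum()))
    else:
        done(n_features=int(matrix.shape[1]))

    info = split_columns(matrix.columns)
    by_measure = {
        m: matrix.loc[:, (info["measure"] == m).to_numpy()]
        for m in config.measures
    }

    # --- classification per measure and on all features
    done = _timed("classify")
    rows = []
    for family in config.models:
        spec = ModelSpec(
            family=family,
            n_trees=config.rf_trees,
            max_depth=config.rf_depth,
            seed=stage_seed(config.seed, "classify"),
        )
        tables = {**by_measure, "all": matrix}
        for name, sub in tables.items():
            rep = nested_cv_evaluate(
                sub,
                dataset.labels,
                spec,
                n_outer=config.n_folds,
                seed=stage_seed(config.seed, f"classify:{family}:{name}"),
                induced_class=config.induced_class,
            )
            rows.append({"model": family, "features": name, **rep.as_dict()})
    classification = pd.DataFrame(rows)
    classification.to_csv(out / "classification.csv", index=False)
    done(n_rows=len(rows))

    # --- RBFE
    if config.run_rbfe_stage:
        done = _timed("rbfe")
        rbfe_matrix = (
            by_measure[config.rbfe_measure] if config.rbfe_measure else matrix
        )
        spec = ModelSpec(
            family=config.rbfe_base,
            n_trees=config.rf_trees,
            max_depth=config.rf_depth,
            seed=stage_seed(config.seed, "rbfe"),
        )
        trace = run_rbfe(
            rbfe_matrix,
            dataset.labels,
            spec,
            batch_size=config.rbfe_batch_size,
            seed=stage_seed(config.seed, "rbfe"),
            n_folds=config.n_folds,
            induced_class=config.induced_class,
        )
        trace.to_frame().to_csv(out / "rbfe_trace.csv", index=False)
        with open(out / "rbfe_batches.txt", "w") as fh:
            for i, batch in enumerate(trace.batches):
                for feat in batch:
                    fh.write(f"{i}\t{feat}\n")
        done(n_iterations=len(trace.iterations))

    # --- stump ranking
    done = _timed("rank")
    ranking = stump_rank(
        by_measure[config.stump_measure],
        dataset.labels,
        error_cutoff=config.stump_error_cutoff,
        folds=config.n_folds,
        seed=stage_seed(config.seed, "rank"),
    )
    ranking.to_csv(out / "stump_ranking.csv")
    done(n_retained=int(ranking["retained"].sum()))

    # --- enrichment
    if config.run_enrichment_stage and gmt_path is not None:
        done = _timed("enrich")
        gene_sets = imio.load_gene_sets(gmt_path)
        universe = sorted(set(ranking["gene"]))
        # scan only the genes whose stump error clears the cutoff; the
        # universe stays the full filtered gene pool
        ranked_genes = ranking.loc[ranking["retained"], "gene"].tolist()
        curves = enrich_collection(
            ranked_genes,
            gene_sets,
            universe,
            threshold=config.enrichment_threshold,
        )
        curves_to_frame(curves).to_csv(out / "enrichment.csv", index=False)
        done(
            n_sets=len(curves),
            rejected_sets=sorted(
                name for name, c in curves.items() if c.any_rejected
            ),
        )

    report["artifacts"] = sorted(p.name for p in out.iterdir() if p.is_file())
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
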