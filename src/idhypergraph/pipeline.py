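"""End-to-end orchestration: deviation -> hyperedges -> clustering ->
evaluation, with frozen-config reproducibility and a replication mode that
reuses discovery parameters on a second cohort.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._errors import SchemaError
from .community import ModularityParams, hmll
from .config import RunConfig, config_hash, freeze_config
from .deviation import FeatureTable, deviation_matrix, read_feature_table
from .evaluation import metrics_table, pairwise_svm_cv, subtype_profile
from .hypergraph import merge_duplicates, write_hypergraph
from .hyperedges import build_id_hypergraph, fit_report
from .synthetic import simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "run_replication", "write_table"]


def write_table(
    df: pd.DataFrame, path: Path, seed: int, cfg_hash: str, note: str | None = None
) -> None:
    """CSV with a provenance header comment (version, seed, config hash)."""
    with open(path, "w") as fh:
        fh.write(f"# idhypergraph v{__version__} seed={seed} config={cfg_hash}\n")
        if note:
            fh.write(f"# {note}\n")
        df.to_csv(fh, index=False)


def _load_inputs(cfg: RunConfig) -> FeatureTable:
    if cfg.features is None:
        raise SchemaError("config paths.features is required")
    table = read_feature_table(cfg.features, cfg.phenotype)
    if cfg.phenotype is None:
        raise SchemaError("config paths.phenotype is required (group labels)")
    return table

def run_pipeline(
    cfg: RunConfig,
    table: FeatureTable | None = None,
    fixed_modularity: ModularityParams | None = None,
    fixed_lambdas: tuple[float, float] | None = None,
) -> dict:
    """Execute every stage and write the artifact bundle to output_dir.

    ``fixed_modularity``/``fixed_lambdas`` implement replication mode: when
    given, the elastic-net grid search and the modularity-parameter
    estimation are skipped and the supplied discovery values are reused.

    While running, an ``INCOMPLETE`` marker sits in the output directory; it
    is removed on success, so its presence flags partial artifacts and names
    the stage that failed.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "INCOMPLETE"
    stage = "setup"
    try:
        marker.write_text(f"pipeline running (stage: {stage})\n")
        result = _run_stages(cfg, table, fixed_modularity, fixed_lambdas, out)
    except Exception as exc:
        stage = getattr(exc, "_pipeline_stage", stage)
        marker.write_text(f"pipeline aborted during stage '{stage}': {exc}\n")
        raise
    marker.unlink(missing_ok=True)
    return result


class _StageTracker:
    """Attaches the current stage name to any escaping exception."""

    def __init__(self) -> None:
        self.name = "setup"

    def __call__(self, name: str) -> "_StageTracker":
        self.name = name
        logger.info("stage: %s", name)
        return self

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not hasattr(exc, "_pipeline_stage"):
            exc._pipeline_stage = self.name
            exc.add_note(f"pipeline stage: {self.name}")
        return False


def _run_stages(
    cfg: RunConfig,
    table: FeatureTable | None,
    fixed_modularity: ModularityParams | None,
    fixed_lambdas: tuple[float, float] | None,
    out: Path,
) -> dict:
    t0 = time.time()
    frozen = freeze_config(cfg)
    chash = config_hash(frozen)
    track = _StageTracker()
    with track("load-inputs"):
        if table is None:
            table = _load_inputs(cfg)

    cases = table.cases()
    controls = table.controls()
    if cases.n_subjects < 3 or controls.n_subjects < 2:
        raise SchemaError(
            f"need >=3 cases and >=2 controls, got {cases.n_subjects}/{controls.n_subjects}"
        )
    with track("deviation"):
        logger.info("deviation: %d cases x %d controls", cases.n_subjects, controls.n_subjects)
        dev = deviation_matrix(
            cases,
            controls,
            zscore_against_controls=cfg.deviation.zscore_against_controls,
            correlation_distance=cfg.deviation.correlation_distance,
        )
        dev_path = out / "deviation_matrix.csv"
        with open(dev_path, "w") as fh:
            fh.write(f"# idhypergraph v{__version__} seed={cfg.seed} config={chash}\n")
            pd.DataFrame(dev.X, index=dev.row_ids, columns=dev.col_ids).to_csv(
                fh, index_label="subject_id"
            )

    with track("hyperedges"):
        en_cfg = cfg.elastic_net
        if fixed_lambdas is not None:
            en_cfg = dataclasses.replace(
                en_cfg,
                lambda1_grid=(fixed_lambdas[0],),
                lambda2_grid=(fixed_lambdas[1],),
            )
        logger.info("elastic-net fits for %d centroids", cases.n_subjects)
        G, fits = build_id_hypergraph(dev, en_cfg, return_fits=True)
        G = merge_duplicates(G)
        write_hypergraph(G, out / "hypergraph.txt")
        write_table(fit_report(fits), out / "hyperedge_fits.csv", cfg.seed, chash)

    with track("clustering"):
        cl_cfg = cfg.hmll
        if fixed_modularity is not None:
            cl_cfg = dataclasses.replace(cl_cfg, params=fixed_modularity)
        logger.info("clustering %d vertices, %d hyperedges", G.n_vertices, G.n_hyperedges)
        part = hmll(G, cl_cfg)
    part_df = pd.DataFrame(
        {"subject_id": dev.row_ids, "subtype": part.one_based()}
    )
    write_table(part_df, out / "partition.csv", cfg.seed, chash)
    with open(out / "partition.json", "w") as fh:
        json.dump(
            {
                "labels": part.one_based().tolist(),
                "subject_ids": dev.row_ids,
                "Q": part.quality,
                "params": {
                    "beta": {str(k): v for k, v in part.params.beta.items()},
                    "gamma": {str(k): v for k, v in part.params.gamma.items()},
                },
                "seed": cfg.seed,
                "restart": part.meta.get("restart"),
            },
            fh,
            indent=2,
        )
    logger.info("clustering found %d subtypes (Q=%.6g)", part.n_clusters, part.quality)

    eval_error = None
    with track("evaluation"):
        try:
            pair_metrics, avg = pairwise_svm_cv(cases, part, cfg.svm)
            write_table(
                metrics_table(pair_metrics, avg),
                out / "svm_metrics.csv",
                cfg.seed,
                chash,
                note="positive class per pair = lower-numbered subtype",
            )
        except Exception as exc:  # a 1-cluster partition has no pairs
            eval_error = str(exc)
            pair_metrics, avg = [], None
            logger.warning("pairwise SVM skipped: %s", exc)

    with track("stats"):
        profiles = subtype_profile(
            cases,
            part,
            controls,
            covariates=cfg.stats.covariates,
            q_threshold=cfg.stats.q_threshold,
        )
        for s, df in profiles.items():
            write_table(df, out / f"difference_map_subtype{s+1}.csv", cfg.seed, chash)

    # freeze the effective config, including everything replication reuses
    frozen["replication"] = {
        "lambda1": float(np.median([f.chosen_lambda1 for f in fits])),
        "lambda2": float(np.median([f.chosen_lambda2 for f in fits])),
        "modularity_params": {
            "beta": {str(k): v for k, v in part.params.beta.items()},
            "gamma": {str(k): v for k, v in part.params.gamma.items()},
        },
        "n_subtypes": int(part.n_clusters),
    }
    with open(out / "frozen_config.yaml", "w") as fh:
        yaml.safe_dump(frozen, fh, sort_keys=True)
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return {
        "deviation": dev,
        "hypergraph": G,
        "partition": part,
        "fits": fits,
        "pair_metrics": pair_metrics,
        "avg_metrics": avg,
        "profiles": profiles,
        "frozen_config": frozen,
        "eval_error": eval_error,
        "output_dir": out,
    }


def run_replication(cfg: RunConfig, frozen_discovery: dict, table: FeatureTable | None = None) -> dict:
    """Re-run the pipeline on a second cohort reusing discovery parameters.

    The discovery frozen config supplies the elastic-net penalties and the
    modularity parameters, so no lambda grid search and no (beta, gamma)
    re-estimation happens here.
    """
    rep = frozen_discovery.get("replication") or {}
    if not rep:
        raise SchemaError("discovery frozen config carries no 'replication' block")
    params = ModularityParams(
        beta={int(k): float(v) for k, v in rep["modularity_params"]["beta"].items()},
        gamma={int(k): float(v) for k, v in rep["modularity_params"]["gamma"].items()},
    )
    return run_pipeline(
        cfg,
        table=table,
        fixed_modularity=params,
        fixed_lambdas=(float(rep["lambda1"]), float(rep["lambda2"])),
    )


def simulate_to_dir(cfg: RunConfig, out_dir) -> dict:
    """Run the cohort simulator and write feature/phenotype/truth CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, truth = simulate_cohort(cfg.simulate)
    frozen = freeze_config(cfg)
    chash = config_hash(frozen)
    feat = pd.DataFrame(table.values, columns=table.feature_names)
    feat.insert(0, "subject_id", table.subject_ids)
    write_table(feat, out / "features.csv", cfg.seed, chash)
    pheno = pd.DataFrame(
        {
            "id": table.subject_ids,
            "group": table.group,
            "age": table.covariates["age"],
            "site": table.covariates["site"],
        }
    )
    write_table(pheno, out / "phenotype.csv", cfg.seed, chash)
    truth_df = pd.DataFrame(
        {
            "id": [s for s, g in zip(table.subject_ids, table.group) if g == "case"],
            "subtype": truth + 1,
        }
    )
    write_table(truth_df, out / "truth.csv", cfg.seed, chash)
    return {"table": table, "truth": truth, "output_dir": out}
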