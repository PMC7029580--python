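"""End-to-end orchestration: simulate-or-read -> QC -> normalize ->
classify -> cluster -> markers -> enrich -> states -> diffcorr.

Every run writes flat TSV/JSON stage outputs plus the resolved
configuration and a log of per-stage nucleus and gene tallies into the run
directory; identical configuration and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import cluster as _cluster
from . import diffcorr as _diffcorr
from . import enrich as _enrich
from . import markers as _markers
from . import normalize as _normalize
from . import qc as _qc
from . import states as _states
from .io import read_10x, write_10x
from .qc import QCThresholds
from .sim import SimConfig, generate_cohort

logger = logging.getLogger("snanno")

STAGES = (
    "input",
    "nucleus_qc",
    "gene_filter",
    "doublet",
    "normalize",
    "identity",
    "embed",
    "precluster",
    "enrich_classes",
    "resolve",
    "subcluster",
    "markers",
    "states",
    "diffcorr",
)


@dataclass
class PipelineConfig:
    """Run configuration; unset simulate/input combinations are rejected."""

    input_path: str | None = None  # 10x directory; None => simulate
    genesets_path: str | None = None  # GMT with the six class marker lists
    sim: SimConfig = field(default_factory=SimConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    ambiguity_rho: float = 1.0
    quick_min_size: int = 50
    perplexity: float | None = None  # default: n/10 capped below (n-1)/3
    k_snn: int = 6
    embed_method: str = "tsne"
    mixed_delta: float = 0.1
    subcluster_classes: tuple[str, ...] = ("Astrocyte",)
    k_consensus: dict = field(default_factory=lambda: {"Astrocyte": 4})
    marker_p_max: float = 0.05
    n_perm: int = 100
    n_pairs: int = 1000
    doublet_n_sim: int = 5000
    seed: int = 0

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute the full pipeline; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    seeds = _seeds(config.seed)

    try:
        with open(outdir / "resolved_config.yaml", "w") as fh:
            yaml.safe_dump(config.resolved(), fh, sort_keys=True)

        truth = None
        if config.input_path is None:
            cfg = dataclasses.replace(config.sim, seed=seeds[0])
            adata, truth = generate_cohort(cfg)
            _write_tsv(truth, outdir / "truth.tsv")
            write_10x(adata, outdir / "simulated_counts")
        else:
            adata = read_10x(config.input_path)
        logger.info("stage=input nuclei=%d genes=%d", adata.n_obs, adata.n_vars)

        logs = []
        adata, log1 = _qc.filter_nuclei_qc(adata, config.qc)
        logs.append(log1)
        logger.info("stage=nucleus_qc nuclei=%d genes=%d", adata.n_obs, adata.n_vars)

        adata, log2 = _qc.filter_genes(adata, config.qc)
        logs.append(log2)
        logger.info("stage=gene_filter nuclei=%d genes=%d", adata.n_obs, adata.n_vars)

        adata, log3, _scores = _qc.flag_doublets(
            adata, config.qc, n_sim=config.doublet_n_sim, seed=seeds[1]
        )
        logs.append(log3)
        logger.info("stage=doublet nuclei=%d genes=%d", adata.n_obs, adata.n_vars)

        if config.genesets_path is not None:
            from .io import read_gmt

            marker_sets = read_gmt(config.genesets_path)
        else:
            marker_sets = adata.uns.get("class_marker_sets")
        if marker_sets is None:
            raise RuntimeError(
                "no class marker sets available; provide a GMT file via "
                "genesets_path or adata.uns['class_marker_sets']"
            )

        # identity scores on raw counts (detection-based, normalization-free)
        scores = _classify.identity_scores(adata, marker_sets)
        assignments = _classify.assign_class(
            scores,
            _classify.AmbiguityRule(rho=config.ambiguity_rho),
            identity_min=config.qc.identity_min,
        )
        low_q = ~assignments["quality_pass"]
        for bc in assignments.index[low_q]:
            logs.append(
                pd.DataFrame(
                    [(bc, "nucleus", "identity", "identity_score<min")],
                    columns=list(_qc.LOG_COLUMNS),
                )
            )
        adata = adata[~low_q.to_numpy()].copy()
        scores = scores.loc[adata.obs_names]
        assignments = assignments.loc[adata.obs_names]
        logger.info("stage=identity nuclei=%d genes=%d", adata.n_obs, adata.n_vars)

        log_expr, factors, notes = _normalize.normalize_counts(
            adata, min_size=config.quick_min_size
        )
        for note in notes:
            logger.warning("normalize: %s", note)
        _write_tsv(
            log_expr.obs[["size_factor"]], outdir / "size_factors.tsv"
        )
        logger.info("stage=normalize nuclei=%d genes=%d", adata.n_obs, adata.n_vars)

        n = log_expr.n_obs
        perp = config.perplexity
        if perp is None:
            perp = max(5.0, min(n / 10.0, (n - 1) / 3.0 - 1.0))
        coords = _cluster.embed(
            log_expr, method=config.embed_method, perplexity=perp, seed=seeds[2]
        )
        coord_df = pd.DataFrame(
            coords, index=log_expr.obs_names, columns=["dim1", "dim2"][: coords.shape[1]]
        )
        _write_tsv(coord_df, outdir / "embedding.tsv")
        logger.info("stage=embed nuclei=%d perplexity=%g", n, perp)

        pre = _cluster.snn_precluster(coords, k_snn=config.k_snn, seed=seeds[3])
        preclusters = pd.Series(pre.astype(str), index=log_expr.obs_names, name="precluster")
        logger.info("stage=precluster nuclei=%d preclusters=%d", n, preclusters.nunique())

        # class-level enrichment of precluster mean profiles; identity-score
        # means stand in when there are too few preclusters for ranks
        means = _enrich.cluster_mean_profiles(log_expr, preclusters)
        if means.shape[1] >= 3:
            enr = _enrich.gsva_scores(means, marker_sets).T  # cluster x class
        else:
            enr = scores.groupby(preclusters).mean()
        _write_tsv(enr, outdir / "precluster_enrichment.tsv")
        mixed = _classify.flag_mixed(enr, delta=config.mixed_delta)
        resolved = _classify.resolve_mixed_preclusters(preclusters, mixed, assignments)
        per_cluster_class, master = _classify.master_classes(
            resolved["cluster"], assignments
        )
        cluster_table = resolved.copy()
        cluster_table["master_class"] = master
        logger.info(
            "stage=resolve mixed=%d clusters=%d", int(mixed.sum()), resolved["cluster"].nunique()
        )

        profile_out = scores.copy()
        profile_out[assignments.columns] = assignments
        _write_tsv(profile_out, outdir / "identity_profiles.tsv")

        sub_results = {}
        for cls in config.subcluster_classes:
            in_cls = (master == cls).to_numpy()
            k = int(config.k_consensus.get(cls, 4))
            if in_cls.sum() < 5 * k:
                logger.warning("subcluster: %s has %d nuclei < 5k; skipped", cls, in_cls.sum())
                continue
            res = _cluster.consensus_subcluster(
                log_expr[in_cls], k=k, seed=seeds[4]
            )
            sub = pd.Series(
                res.labels.astype(str), index=log_expr.obs_names[in_cls], name="subcluster"
            )
            sub_results[cls] = (res, sub)
            cluster_table.loc[sub.index, "subcluster"] = cls + "_" + sub
            logger.info(
                "stage=subcluster class=%s k=%d silhouettes=%s",
                cls,
                k,
                {c: round(v, 3) for c, v in res.silhouette.items()},
            )
        _write_tsv(cluster_table, outdir / "clusters.tsv")

        for cls, (res, sub) in sub_results.items():
            sub_expr = log_expr[sub.index]
            rec = _markers.auroc_markers(
                sub_expr, sub.to_numpy(), p_max=config.marker_p_max
            )
            _write_tsv(rec, outdir / f"markers_auroc_{cls}.tsv", index=False)
            if min(np.bincount(pd.factorize(sub)[0])) >= 3:
                tables = _markers.pairwise_t_markers(sub_expr, sub.to_numpy())
                ranked = _markers.ranked_marker_list(tables)
                _write_tsv(
                    _markers.marker_table_export(ranked),
                    outdir / f"markers_ranked_{cls}.tsv",
                    index=False,
                )
        logger.info("stage=markers classes=%s", list(sub_results))

        astro = master == "Astrocyte"
        summary: dict = {
            "n_nuclei": int(adata.n_obs),
            "n_genes": int(adata.n_vars),
            "n_astrocytes": int(astro.sum()),
            "master_class_counts": master.value_counts().to_dict(),
            "subcluster_silhouette": {
                cls: {str(c): round(v, 6) for c, v in res.silhouette.items()}
                for cls, (res, _sub) in sub_results.items()
            },
        }
        if astro.any():
            astro_expr = log_expr[astro.to_numpy()]
            have_sentinels = all(
                g in astro_expr.var_names for g in _states.SENTINEL_GENES
            )
            if have_sentinels:
                calls = _states.classify_state_matrix(astro_expr)
                cond = astro_expr.obs["condition"]
                comp = _states.state_composition(calls, cond, warn_empty=False)
                _write_tsv(
                    pd.DataFrame({"state": calls}), outdir / "states.tsv"
                )
                _write_tsv(comp, outdir / "state_composition.tsv")
                comp.to_json(outdir / "state_composition.json", orient="index")
                if "Astrocyte" in sub_results:
                    cross = _states.cluster_state_crosstab(
                        calls, sub_results["Astrocyte"][1]
                    )
                    _write_tsv(cross, outdir / "cluster_state_crosstab.tsv")
                summary["state_composition"] = comp.round(6).to_dict(orient="index")
                logger.info("stage=states astrocytes=%d", int(astro.sum()))

            if astro.sum() >= 8:
                keep = _diffcorr.filter_top_mean(astro_expr, 0.95)
                dc = _diffcorr.differential_correlation(
                    astro_expr[:, keep],
                    astro_expr.obs["condition"].to_numpy(),
                    n_perm=config.n_perm,
                    n_pairs=config.n_pairs,
                    seed=seeds[5],
                )
                _write_tsv(dc, outdir / "diffcorr.tsv", index=False)
                summary["n_diffcorr_pairs"] = int(len(dc))
                summary["n_diffcorr_significant"] = int((dc["p_adjusted"] < 0.05).sum())
                logger.info("stage=diffcorr pairs=%d", len(dc))

        exclusions = (
            pd.concat(logs, ignore_index=True) if logs else pd.DataFrame(columns=list(_qc.LOG_COLUMNS))
        )
        _write_tsv(exclusions, outdir / "exclusions.tsv", index=False)

        if truth is not None:
            kept_truth = truth.loc[master.index]
            acc = float((kept_truth["true_class"] == master).mean())
            summary["master_class_accuracy"] = acc
            logger.info("truth: master-class accuracy %.4f", acc)

        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        return outdir
    except Exception as exc:  # annotate which stage died, then re-raise
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
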