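"""End-to-end driver: simulate -> transform -> factorize -> classify ->
importance -> enrich -> trajectory.

Every stage writes its artifacts under the output directory; a manifest
records package/library versions, the global seed and its per-stage
fan-out, and all parameters; ``pipeline.log`` records each stage's inputs,
outputs and duration. Any stage error aborts with the stage name attached.
"""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import enrichment as enr
from . import io as pio
from . import outcomes as om
from . import trajectories as tj
from .containers import ACUTE_TIMEPOINTS
from .factorization import PatternNMF, filter_genes, log_transform
from .simulate import SyntheticCohortConfig, generate_cohort, generate_gene_sets

# fixed per-stage seed offsets so stages can be rerun independently
STAGE_SEED_OFFSETS = {
    "simulate": 0,
    "factorize": 101,
    "importance": 202,
    "enrich": 303,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def run_pipeline(config: "pio.PipelineConfig", outdir) -> Path:
    """Execute the full analysis; returns the output directory."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    log = open(log_path, "w")
    t0 = time.time()

    def _log(msg: str) -> None:
        log.write(f"[{time.time() - t0:9.2f}s] {msg}\n")
        log.flush()

    _log(f"pipeline start, global seed {config.seed}")

    def _stage(name):
        class _Ctx:
            def __enter__(self_):
                self_.t = time.time()
                _log(f"stage {name}: start")
                return self_

            def __exit__(self_, exc_type, exc, tb):
                if exc is not None:
                    _log(f"stage {name}: FAILED: {exc}")
                    log.close()
                    raise PipelineError(name, str(exc)) from exc
                _log(f"stage {name}: done in {time.time() - self_.t:.2f}s")
                return False
        return _Ctx()

    with _stage("simulate"):
        if config.simulate:
            sim_cfg = SyntheticCohortConfig(
                n_genes=config.n_genes,
                seed=config.seed + STAGE_SEED_OFFSETS["simulate"])
            expr_raw, meta, truth = generate_cohort(sim_cfg)
            gene_sets = generate_gene_sets(
                truth, top_n=config.set_size, n_random_controls=5,
                seed=sim_cfg.seed)
            pio.write_expression_tsv(expr_raw, outdir / "expression.tsv")
            pio.write_metadata_csv(meta, outdir / "metadata.csv")
            pio.write_ground_truth(truth, sim_cfg, outdir / "ground_truth")
            pio.write_gmt(gene_sets, outdir / "gene_sets.gmt")
            _log(f"simulated {expr_raw.shape[0]} genes x "
                 f"{expr_raw.shape[1]} samples")
        else:
            expr_raw = pio.read_expression_tsv(config.expression)
            meta = pio.read_metadata_csv(config.metadata)
            gene_sets = pio.read_gmt(config.gene_sets) if config.gene_sets else []
            _log(f"loaded {expr_raw.shape[0]} genes x "
                 f"{expr_raw.shape[1]} samples from {config.expression}")

    with _stage("transform"):
        expr = log_transform(expr_raw, pseudocount=config.pseudocount)
        expr = filter_genes(expr)
        _log(f"log2(TPM+{config.pseudocount:g}); {expr.shape[0]} genes kept")

    with _stage("factorize"):
        sparsity = None if config.sparsity < 0 else (config.sparsity,) * 2
        model = PatternNMF(expr, K=config.k, sparsity=sparsity,
                           tol=config.tol, max_iter=config.max_iter,
                           n_restarts=config.n_restarts)
        fact = model.fit(seed=config.seed + STAGE_SEED_OFFSETS["factorize"])
        pio.write_factorization(fact, outdir / "factorization")
        _log(f"K={config.k}, reconstruction error "
             f"{fact.reconstruction_error():.4f}, converged={fact.converged}")

    with _stage("classify"):
        table = om.auroc_table(fact.P, meta, timepoints=ACUTE_TIMEPOINTS)
        classes = om.classify_patterns(table, threshold=config.threshold)
        out = table.copy()
        out["class"] = classes
        out.index.name = "pattern"
        pio.write_table_tsv(out, outdir / "auroc_classes.tsv")
        _log("pattern classes: " + ", ".join(
            f"{k}={v}" for k, v in classes.value_counts().items()))

    with _stage("importance"):
        P_scaled = om.scale_patterns(fact.P)
        known, n_subjects = om.filter_known_outcome(meta)
        at_tp = known[known["timepoint"] == config.model_timepoint]
        at_tp = at_tp[at_tp["sample_id"].isin(P_scaled.columns)]
        P0 = P_scaled[at_tp["sample_id"]].T
        P0.index = at_tp["subject_id"].to_numpy()
        labels = (at_tp["outcome"] == "died").to_numpy(dtype=int)
        imp = om.rf_importance_pipeline(
            P0, labels, seed=config.seed + STAGE_SEED_OFFSETS["importance"],
            n_resplits=config.n_resplits, n_folds=config.n_folds,
            n_repeats=config.n_repeats, n_trees=config.n_trees)
        imp_out = imp.table.copy()
        imp_out.index.name = "pattern"
        pio.write_table_tsv(imp_out, outdir / "importance.tsv")
        ors = om.pattern_odds_ratios(P0, labels)
        pio.write_table_tsv(ors, outdir / "odds_ratios.tsv")
        _log(f"{n_subjects} known-outcome subjects; "
             f"{len(at_tp)} at {config.model_timepoint}; "
             f"held-out AUROC {imp.heldout_auroc.mean():.3f}")

    with _stage("enrich"):
        seed_e = config.seed + STAGE_SEED_OFFSETS["enrich"]
        bg = enr.background_rank_model(
            n_genes=fact.A.shape[0], set_size=config.set_size,
            iterations=config.iterations, n_patterns=config.k, seed=seed_e)
        rows = []
        rankings = {k: fact.rank_genes(k) for k in range(1, config.k + 1)}
        for gs in gene_sets:
            best = None
            for k in range(1, config.k + 1):
                try:
                    total, ranks, absent = enr.cumulative_rank_statistic(
                        rankings[k], gs)
                except enr.EnrichmentError:
                    continue
                if best is None or total < best[1]:
                    best = (k, total, ranks, absent)
            if best is None:
                continue
            k, total, ranks, absent = best
            # exact KS of the set's ranks against a uniform background draw
            n_genes = fact.A.shape[0]
            m = min(10_000 // max(len(ranks), 1), n_genes)
            rng = np.random.default_rng(seed_e + k)
            bg_sample = rng.choice(n_genes, size=m, replace=False) + 1
            d, p, tag = enr.ks_exact_two_sample(ranks.to_numpy(), bg_sample)
            rows.append({
                "set": gs.name, "best_pattern": fact.P.index[k - 1],
                "summed_rank": total, "n_present": len(ranks),
                "n_absent": len(absent),
                "background_mean_sum": bg.mean_sum * len(ranks) / config.set_size,
                "ks_D": d, "ks_p": p, "ks_method": tag,
            })
        enr_table = pd.DataFrame(rows)
        pio.write_table_tsv(enr_table, outdir / "gene_set_enrichment.tsv",
                            index=False)
        _log(f"background mean summed rank {bg.mean_sum:.1f} "
             f"({config.iterations} iterations x {config.k} patterns); "
             f"{len(rows)} gene sets scored")

    with _stage("trajectory"):
        top2 = imp.ordered_patterns[:2]
        traj = tj.group_mean_trajectory(fact.P, meta, axes=tuple(top2),
                                        groups=("survived", "died"))
        pio.write_table_tsv(traj.means, outdir / "trajectory.tsv", index=False)
        disp = pd.DataFrame([
            {"group": g, "net_displacement": tj.net_displacement(traj, g)}
            for g in ("survived", "died")])
        pio.write_table_tsv(disp, outdir / "net_displacement.tsv", index=False)
        paths = tj.subject_paths(fact.P, meta, axes=tuple(top2))
        path_rows = []
        for subj, df in paths.items():
            for _, r in df.iterrows():
                path_rows.append({"subject_id": subj, **r.to_dict()})
        pio.write_table_tsv(pd.DataFrame(path_rows),
                            outdir / "subject_paths.tsv", index=False)
        per_subj, per_group = tj.recovery_index(fact.P.loc[top2[0]], meta)
        pio.write_table_tsv(per_group, outdir / "recovery_index.tsv",
                            index=False)
        _log(f"trajectory axes {top2}; "
             f"displacement survived={disp['net_displacement'][0]:.3f} "
             f"died={disp['net_displacement'][1]:.3f}")

    manifest = {
        "sepsispatterns_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        **{f"seed_{k}": config.seed + v for k, v in STAGE_SEED_OFFSETS.items()},
        **{f"param_{k}": v for k, v in config.to_dict().items()},
    }
    pio.write_manifest(manifest, outdir / "manifest.txt")
    _log("pipeline complete")
    log.close()
    return outdir
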