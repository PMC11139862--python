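"""Synthetic longitudinal sepsis cohorts with known latent structure.

The generator emulates the shape of an observational sepsis study: healthy
donors plus sepsis subjects sampled at enrolment (0 h) through 12 months,
with death/dropout missingness. Expression is built from known non-negative
amplitude (``A_true``, genes x K) and pattern (``P_true``, K x samples)
matrices so every downstream stage — factorization, projection, outcome
modelling, enrichment, trajectories — can be tested against ground truth.

Temporal model per sepsis subject and pattern k::

    w(t) = w_healthy_k + (w_acute - w_healthy_k) * exp(-t / tau_k)   survivors
    w(t) = w_acute                                                    non-survivors

so survivors relax exponentially toward the healthy-donor mean while
non-survivors stay at their enrolment level; non-survivors contribute no
samples after 72 h. Prognostic patterns shift the enrolment (acute) mean of
non-survivors; dynamic patterns separate the groups only through the
decay-vs-plateau divergence at later timepoints; null patterns ignore
outcome entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import (
    CANONICAL_TIMEPOINTS,
    TIMEPOINT_HOURS,
    ExpressionMatrix,
    GeneSet,
    GroundTruth,
    validate_metadata,
)


class ConfigError(ValueError):
    """Inconsistent synthetic-cohort configuration."""


# Per-timepoint sample retention derived from the study's printed
# per-timepoint subject counts (survivors out of 63, non-survivors out of 54).
DEFAULT_RETENTION_SURVIVED = {
    "0h": 60 / 63, "6h": 58 / 63, "24h": 52 / 63, "48h": 42 / 63,
    "72h": 35 / 63, "28d": 41 / 63, "6m": 25 / 63, "12m": 14 / 63,
}
DEFAULT_RETENTION_DIED = {
    "0h": 48 / 54, "6h": 51 / 54, "24h": 42 / 54, "48h": 34 / 54, "72h": 22 / 54,
}


@dataclass
class SyntheticCohortConfig:
    """Configuration of :func:`generate_cohort`.

    Defaults mirror the study shape: 120 sepsis subjects with 28-day outcome
    counts (63 survived, 54 died, 3 unknown) plus 42 healthy donors, eight
    collection timepoints, 2,000 genes.
    """

    n_sepsis_subjects: int = 120
    n_healthy: int = 42
    outcome_counts: tuple[int, int, int] = (63, 54, 3)
    timepoints: tuple[str, ...] = CANONICAL_TIMEPOINTS
    n_genes: int = 2000
    K_true: int = 6
    #: per-pattern class: prognostic | dynamic | null (cycled if shorter than K_true)
    pattern_classes: tuple[str, ...] = ("prognostic", "dynamic", "null")
    effect_size: float = 1.5
    healthy_mean: float = 1.0
    acute_mean: float = 3.0
    subject_sd: float = 0.5
    #: recovery time constant, hours
    tau_hours: float = 48.0
    amplitude_sparsity: float = 0.7
    noise_kind: str = "lognormal"  # lognormal | poisson | none
    noise_sigma: float = 0.2
    poisson_depth: float = 50.0
    dropout: bool = True
    retention_survived: dict = field(
        default_factory=lambda: dict(DEFAULT_RETENTION_SURVIVED))
    retention_died: dict = field(
        default_factory=lambda: dict(DEFAULT_RETENTION_DIED))
    seed: int = 0

    def validate(self) -> None:
        s, d, u = self.outcome_counts
        if min(s, d, u) < 0 or s + d + u != self.n_sepsis_subjects:
            raise ConfigError(
                f"outcome_counts {self.outcome_counts} do not sum to "
                f"n_sepsis_subjects={self.n_sepsis_subjects}"
            )
        if not (1 <= self.K_true <= self.n_genes):
            raise ConfigError(
                f"K_true={self.K_true} must lie in [1, n_genes={self.n_genes}]"
            )
        unknown = set(self.timepoints) - set(CANONICAL_TIMEPOINTS)
        if unknown:
            raise ConfigError(f"non-canonical timepoints {sorted(unknown)}")
        order = {t: i for i, t in enumerate(CANONICAL_TIMEPOINTS)}
        idx = [order[t] for t in self.timepoints]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ConfigError("timepoints must be unique and in canonical order")
        if self.noise_kind not in ("lognormal", "poisson", "none"):
            raise ConfigError(f"unknown noise_kind {self.noise_kind!r}")
        if not 0 <= self.amplitude_sparsity < 1:
            raise ConfigError("amplitude_sparsity must be in [0, 1)")


def _pattern_classes(config: SyntheticCohortConfig) -> list[str]:
    classes = []
    for k in range(config.K_true):
        c = config.pattern_classes[k % len(config.pattern_classes)]
        if c not in ("prognostic", "dynamic", "null"):
            raise ConfigError(f"unknown pattern class {c!r}")
        classes.append(c)
    return classes


def _draw_amplitude(config: SyntheticCohortConfig, rng: np.random.Generator,
                    gene_ids: list[str]) -> pd.DataFrame:
    A = rng.exponential(scale=1.0, size=(config.n_genes, config.K_true))
    # per-pattern sparsity mask mimicking sparse NMF structure
    mask = rng.random((config.n_genes, config.K_true)) >= config.amplitude_sparsity
    A = A * mask
    cols = [f"pattern_{k + 1}" for k in range(config.K_true)]
    return pd.DataFrame(A, index=gene_ids, columns=cols)


def generate_cohort(
    config: SyntheticCohortConfig | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Simulate a longitudinal cohort with known factorization.

    Returns the TPM-scale expression matrix (genes x samples), the per-sample
    metadata table and the :class:`GroundTruth` holding ``A_true``,
    ``P_true`` and the outcome wiring. Deterministic in ``config.seed``.
    """
    config = config or SyntheticCohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    A_true = _draw_amplitude(config, rng, gene_ids)
    classes = _pattern_classes(config)

    n_surv, n_died, n_unk = config.outcome_counts
    outcomes = (["survived"] * n_surv + ["died"] * n_died + ["unknown"] * n_unk)
    subjects = [f"SEP{i + 1:03d}" for i in range(config.n_sepsis_subjects)]
    healthy_subjects = [f"HC{i + 1:03d}" for i in range(config.n_healthy)]

    K = config.K_true
    h = np.full(K, config.healthy_mean)
    acute_base = np.full(K, config.acute_mean)

    # per-subject acute level; prognostic patterns shift non-survivors upward
    acute_levels = {}
    for subj, out in zip(subjects, outcomes):
        mu = acute_base.copy()
        if out == "died":
            for k, cls in enumerate(classes):
                if cls == "prognostic":
                    mu[k] += config.effect_size * config.subject_sd
        w = rng.normal(mu, config.subject_sd)
        acute_levels[subj] = np.clip(w, 0.0, None)

    # sample retention: which (subject, timepoint) pairs exist
    rows = []
    weights = []
    for subj, out in zip(subjects, outcomes):
        retention = (config.retention_died if out == "died"
                     else config.retention_survived)
        w_acute = acute_levels[subj]
        for tp in config.timepoints:
            hours = TIMEPOINT_HOURS[tp]
            if out == "died" and hours > 72:
                continue  # non-survivors never sampled after 72 h
            if config.dropout:
                p_keep = retention.get(tp, 0.0)
                if rng.random() >= p_keep:
                    continue
            if out == "died":
                w_t = w_acute.copy()
            else:  # survivors and unknowns relax toward the healthy mean
                decay = np.exp(-hours / config.tau_hours)
                w_t = h + (w_acute - h) * decay
            for k, cls in enumerate(classes):
                if cls == "null":
                    # outcome-independent: sits at the subject's acute level
                    # regardless of outcome or time
                    w_t[k] = w_acute[k]
            rows.append((f"{subj}_{tp}", subj, tp, hours, "sepsis", out))
            weights.append(np.clip(w_t, 0.0, None))

    for subj in healthy_subjects:
        w = np.clip(rng.normal(h, config.subject_sd), 0.0, None)
        rows.append((f"{subj}_0h", subj, "0h", 0.0, "healthy", "not_applicable"))
        weights.append(w)

    P = np.column_stack(weights) if weights else np.zeros((K, 0))
    sample_ids = [r[0] for r in rows]
    P_true = pd.DataFrame(P, index=A_true.columns, columns=sample_ids)

    clean = A_true.to_numpy() @ P
    if config.noise_kind == "lognormal" and config.noise_sigma > 0:
        noisy = clean * np.exp(
            rng.normal(0.0, config.noise_sigma, size=clean.shape))
    elif config.noise_kind == "poisson":
        noisy = rng.poisson(clean * config.poisson_depth) / config.poisson_depth
        noisy = noisy.astype(float)
    else:
        noisy = clean
    expr = ExpressionMatrix(
        pd.DataFrame(noisy, index=gene_ids, columns=sample_ids),
        transform_tag="raw_tpm",
    )

    ages = np.round(np.clip(rng.normal(50, 15, size=len(subjects)), 18, 90))
    sexes = rng.choice(["F", "M"], size=len(subjects))
    h_ages = np.round(np.clip(rng.normal(40, 12, size=len(healthy_subjects)), 18, 90))
    h_sexes = rng.choice(["F", "M"], size=len(healthy_subjects))
    age_of = dict(zip(subjects, ages)) | dict(zip(healthy_subjects, h_ages))
    sex_of = dict(zip(subjects, sexes)) | dict(zip(healthy_subjects, h_sexes))

    meta = pd.DataFrame(
        rows, columns=["sample_id", "subject_id", "timepoint", "hours",
                       "group", "outcome"])
    meta["age"] = meta["subject_id"].map(age_of)
    meta["sex"] = meta["subject_id"].map(sex_of)
    meta = validate_metadata(meta)

    outcome_effects = {
        k: {"class": cls,
            "effect_size": config.effect_size if cls != "null" else 0.0}
        for k, cls in enumerate(classes)
    }
    truth = GroundTruth(
        A_true=A_true, P_true=P_true, outcome_effects=outcome_effects,
        noise_model={"kind": config.noise_kind, "sigma": config.noise_sigma,
                     "poisson_depth": config.poisson_depth},
        seed=config.seed,
    )
    return expr, meta, truth


def generate_target_cells(
    truth: GroundTruth,
    cell_type_loadings: dict[str, np.ndarray],
    n_cells_per_type: int,
    seed: int,
    jitter_sd: float = 0.05,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Toy annotated single-cell-like target whose types load on known patterns.

    Each cell of type ``t`` has expected expression ``A_true @ (loading_t +
    jitter)`` with non-negative per-cell jitter truncation; the annotation
    table assigns each cell its type. With ``jitter_sd=0`` all cells of a
    type are identical.
    """
    K = truth.n_patterns
    for name, load in cell_type_loadings.items():
        load = np.asarray(load, dtype=float)
        if load.shape != (K,):
            raise ValueError(
                f"loading for cell type {name!r} has length {load.size}, "
                f"expected K_true={K}"
            )
        if (load < 0).any():
            raise ValueError(f"loading for cell type {name!r} has negative entries")
    rng = np.random.default_rng(seed)
    A = truth.A_true.to_numpy()
    cols, ids, types = [], [], []
    for name in cell_type_loadings:  # insertion order, deterministic
        load = np.asarray(cell_type_loadings[name], dtype=float)
        for i in range(n_cells_per_type):
            w = np.clip(load + rng.normal(0.0, jitter_sd, size=K), 0.0, None)
            cols.append(A @ w)
            ids.append(f"{name}_cell{i + 1}")
            types.append(name)
    values = (np.column_stack(cols) if cols
              else np.zeros((A.shape[0], 0)))
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=truth.A_true.index, columns=ids),
        transform_tag="raw_tpm",
    )
    annot = pd.DataFrame({"cell_id": ids, "cell_type": types})
    return expr, annot


def generate_gene_sets(
    truth: GroundTruth,
    top_n: int = 20,
    n_random_controls: int = 5,
    seed: int = 0,
) -> list[GeneSet]:
    """Gene-set fixtures: one "true" top-``top_n``-amplitude set per pattern
    plus uniformly drawn control sets of the same size.

    Ties in amplitude break lexicographically on gene id, matching the
    amplitude ranking convention used downstream.
    """
    if top_n <= 0:
        raise ValueError(f"top_n must be positive, got {top_n}")
    n_genes = truth.A_true.shape[0]
    if top_n > n_genes:
        raise ValueError(f"top_n={top_n} exceeds n_genes={n_genes}")
    rng = np.random.default_rng(seed)
    sets: list[GeneSet] = []
    for k, pat in enumerate(truth.A_true.columns):
        col = truth.A_true[pat]
        order = sorted(zip(-col.to_numpy(), col.index))
        genes = tuple(g for _, g in order[:top_n])
        sets.append(GeneSet(name=f"true_{pat}",
                            genes=genes,
                            description=f"top {top_n} amplitude genes, {pat}"))
    all_genes = np.asarray(truth.A_true.index)
    for j in range(n_random_controls):
        pick = rng.choice(n_genes, size=top_n, replace=False)
        sets.append(GeneSet(
            name=f"control_{j + 1}",
            genes=tuple(all_genes[np.sort(pick)]),
            description="uniform random control set"))
    return sets


def config_manifest(config: SyntheticCohortConfig) -> dict:
    """Flat manifest of generator settings for provenance files."""
    d = asdict(config)
    d["timepoints"] = ",".join(config.timepoints)
    d["pattern_classes"] = ",".join(config.pattern_classes)
    d["outcome_counts"] = ",".join(map(str, config.outcome_counts))
    d["retention_survived"] = ";".join(
        f"{k}={v:.6g}" for k, v in config.retention_survived.items())
    d["retention_died"] = ";".join(
        f"{k}={v:.6g}" for k, v in config.retention_died.items())
    return d
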