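"""Two-stage outlier-exclusion procedure and retraining-based evaluation.

Stage 1 trains an ensemble of sparse nets on the *entire* cohort and scores
the same samples (test-on-train, deliberately): a model pushed to separate
the observed classes assigns low scores to labeled cases whose genetics look
control-like, and high scores to labeled controls that look case-like.
Mean ensemble scores and per-run misclassification counts drive exclusion
quotas set by external epidemiology — disease prevalence for the control
pool (expected undiagnosed cases) and literature misdiagnosis rates for the
case pool (broad- vs narrow-definition diagnosis).

Stage 2 retrains on the filtered cohort with conventional stratified
train/validation/test splits and compares AUC distributions against the
unfiltered baseline with an unpaired two-sample t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .association import EncodedMatrix, TopologyMap
from .network import TrainConfig, build_model, forward, prepare_inputs, train

__all__ = [
    "FilterSpec",
    "EvaluationResult",
    "derive_seeds",
    "ensemble_scores",
    "exclusion_quota",
    "select_exclusions",
    "filter_cohort",
    "stratified_split",
    "compute_auc",
    "evaluate_model",
    "compare_auc",
]


def derive_seeds(master_seed: int, n: int, stream: int = 0) -> list[int]:
    """Deterministic per-run seeds below 2**31 from one master seed.

    ``stream`` separates independent consumers (ensemble runs, evaluation
    repeats, splits) so each is individually reproducible.
    """
    state = np.random.SeedSequence([int(master_seed), int(stream)]).generate_state(n)
    return [int(s % (2**31)) for s in state]


@dataclass(frozen=True)
class FilterSpec:
    """Exclusion quotas expressed as rates on the observed pools.

    Defaults carry the epidemiology used throughout: prevalence 0.34 % for
    controls; misdiagnosis 6 % (broad) or 19 % (narrow) for cases.  In
    narrow mode a case is only *eligible* for exclusion when it was
    misclassified in at least half of the ensemble runs.  Explicit count
    overrides replace the rate-derived quotas when given.
    """

    control_rate: float = 0.0034
    case_rate: float = 0.19
    mode: str = "narrow"
    quota_override_controls: int | None = None
    quota_override_cases: int | None = None

    def __post_init__(self):
        if self.mode not in ("broad", "narrow"):
            raise ValueError("mode must be 'broad' or 'narrow'")
        for r in (self.control_rate, self.case_rate):
            if not (0 <= r <= 1):
                raise ValueError("rates must be in [0, 1]")


def exclusion_quota(rate: float, pool_size: int, override: int | None = None) -> int:
    """floor(rate x pool size), or an explicit override count."""
    if override is not None:
        if override > pool_size:
            raise ValueError("override exceeds pool size")
        return int(override)
    if not (0 <= rate <= 1):
        raise ValueError("rate must be in [0, 1]")
    return math.floor(rate * pool_size)


def ensemble_scores(
    encoded,
    labels,
    topology: TopologyMap,
    n_runs: int = 10,
    config: TrainConfig | None = None,
    master_seed: int = 0,
    sample_ids=None,
) -> pd.DataFrame:
    """Stage-1 score table: mean test-on-train score per sample over an ensemble.

    Trains ``n_runs`` independently seeded models on all samples and
    predicts on all samples; a run misclassifies a sample when its score
    falls on the wrong side of 0.5 (scores >= 0.5 read as *case*).
    Returns columns sample_id, label, mean_score, n_runs,
    misclassified_count.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    config = config or TrainConfig()
    y = np.asarray(labels)
    if isinstance(encoded, EncodedMatrix):
        sample_ids = sample_ids or list(encoded.sample_ids)
        X = prepare_inputs(encoded, config.fill)
    else:
        X = np.asarray(encoded, float)
        if sample_ids is None:
            sample_ids = [f"S{i:05d}" for i in range(X.shape[0])]
    seeds = derive_seeds(master_seed, n_runs, stream=1)
    total = np.zeros(X.shape[0])
    miscls = np.zeros(X.shape[0], dtype=int)
    for run, seed in enumerate(seeds):
        run_cfg = TrainConfig(
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            max_epochs=config.max_epochs,
            early_stopping=False,
            patience=config.patience,
            seed=seed,
            gene_activation=config.gene_activation,
            l1_variant=config.l1_variant,
            init_scale=config.init_scale,
            fill=config.fill,
        )
        try:
            params, _ = train(build_model(topology, run_cfg), X, y, run_cfg)
        except Exception as err:  # noqa: BLE001 - annotate which run failed
            raise RuntimeError(f"ensemble run {run} failed: {err}") from err
        scores = forward(params, X, run_cfg.gene_activation)
        total += scores
        predicted_case = scores >= 0.5
        miscls += (predicted_case != (y == 1)).astype(int)
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "label": y.astype(int),
            "mean_score": total / n_runs,
            "n_runs": n_runs,
            "misclassified_count": miscls,
        }
    )


def select_exclusions(score_table: pd.DataFrame, spec: FilterSpec):
    """Pick the samples to exclude from each pool.

    Controls: the quota-many highest mean scores.  Cases: the quota-many
    lowest mean scores; in narrow mode only cases misclassified in at least
    half the runs are eligible, and a short eligible list triggers a warning
    rather than an error.  Ties break on sample_id, so the selection is
    deterministic.  Returns (excluded_controls, excluded_cases, warnings).
    """
    warnings: list[str] = []
    controls = score_table[score_table["label"] == 0]
    cases = score_table[score_table["label"] == 1]
    q_ctrl = exclusion_quota(spec.control_rate, len(controls), spec.quota_override_controls)
    q_case = exclusion_quota(spec.case_rate, len(cases), spec.quota_override_cases)

    ctrl_sorted = controls.sort_values(
        ["mean_score", "sample_id"], ascending=[False, True], kind="mergesort"
    )
    excluded_controls = ctrl_sorted["sample_id"].head(q_ctrl).tolist()

    eligible = cases
    if spec.mode == "narrow":
        half = math.ceil(int(cases["n_runs"].iloc[0]) / 2) if len(cases) else 0
        eligible = cases[cases["misclassified_count"] >= half]
        if len(eligible) < q_case:
            warnings.append(
                f"narrow mode: only {len(eligible)} eligible cases for a quota of {q_case}"
            )
    case_sorted = eligible.sort_values(
        ["mean_score", "sample_id"], ascending=[True, True], kind="mergesort"
    )
    excluded_cases = case_sorted["sample_id"].head(q_case).tolist()
    return excluded_controls, excluded_cases, warnings


def filter_cohort(encoded: EncodedMatrix, labels, excluded_ids):
    """Drop the excluded samples; the variant set is untouched."""
    excluded = set(excluded_ids)
    unknown = excluded - set(encoded.sample_ids)
    if unknown:
        raise ValueError(f"unknown sample ids in exclusion list: {sorted(unknown)}")
    keep = [i for i, s in enumerate(encoded.sample_ids) if s not in excluded]
    return encoded.subset_samples(keep), np.asarray(labels)[keep]


def stratified_split(labels, fractions=(0.6, 0.2, 0.2), seed: int = 0):
    """Class-stratified train/validation/test partition by largest remainder.

    Each class is fully shuffled, then allocated to the three sets so the
    per-class counts match the fractions to within rounding; the three
    index arrays are disjoint and exhaustive.
    """
    fr = np.asarray(fractions, float)
    if fr.size != 3 or not math.isclose(fr.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("fractions must be three numbers summing to 1")
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    parts = [[], [], []]
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        n = idx.size
        base = np.floor(fr * n).astype(int)
        rem = fr * n - base
        for _ in range(n - base.sum()):
            j = int(np.argmax(rem))
            base[j] += 1
            rem[j] = -1
        if (base == 0).any():
            raise ValueError(f"class {cls} too small for a three-way split")
        bounds = np.cumsum(base)
        parts[0].append(idx[: bounds[0]])
        parts[1].append(idx[bounds[0] : bounds[1]])
        parts[2].append(idx[bounds[1] :])
    return tuple(np.sort(np.concatenate(p)) for p in parts)


def compute_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half."""
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("AUC needs both classes")
    return float(roc_auc_score(y, np.asarray(scores, float)))


@dataclass
class EvaluationResult:
    """Per-repeat validation/test AUCs of retrained models plus summaries."""

    val_aucs: list[float]
    test_aucs: list[float]

    @property
    def n_repeats(self) -> int:
        return len(self.test_aucs)

    def summary(self) -> dict:
        out = {}
        for name, vals in (("validation", self.val_aucs), ("test", self.test_aucs)):
            arr = np.asarray(vals, float)
            out[name] = {
                "mean_auc": float(arr.mean()),
                "sd_auc": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                "max_auc": float(arr.max()),
            }
        out["n_repeats"] = self.n_repeats
        return out


def evaluate_model(
    encoded,
    labels,
    topology: TopologyMap,
    n_repeats: int = 30,
    config: TrainConfig | None = None,
    master_seed: int = 0,
    fractions=(0.6, 0.2, 0.2),
) -> EvaluationResult:
    """Stage-2 performance estimate: repeated stratified retraining.

    Each repeat draws a fresh fully randomized stratified split, trains
    with early stopping on the validation loss, and records validation and
    test AUC.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    config = config or TrainConfig(early_stopping=True)
    y = np.asarray(labels)
    X = prepare_inputs(encoded, config.fill) if isinstance(encoded, EncodedMatrix) else np.asarray(encoded, float)
    split_seeds = derive_seeds(master_seed, n_repeats, stream=2)
    train_seeds = derive_seeds(master_seed, n_repeats, stream=3)
    val_aucs, test_aucs = [], []
    for split_seed, train_seed in zip(split_seeds, train_seeds):
        tr, va, te = stratified_split(y, fractions, seed=split_seed)
        run_cfg = TrainConfig(
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            max_epochs=config.max_epochs,
            early_stopping=True,
            patience=config.patience,
            seed=train_seed,
            gene_activation=config.gene_activation,
            l1_variant=config.l1_variant,
            init_scale=config.init_scale,
            fill=config.fill,
        )
        params, _ = train(
            build_model(topology, run_cfg), X[tr], y[tr], run_cfg,
            validation=(X[va], y[va]),
        )
        val_aucs.append(compute_auc(forward(params, X[va], run_cfg.gene_activation), y[va]))
        test_aucs.append(compute_auc(forward(params, X[te], run_cfg.gene_activation), y[te]))
    return EvaluationResult(val_aucs=val_aucs, test_aucs=test_aucs)


def compare_auc(aucs_a, aucs_b):
    """Two-tailed unpaired pooled-variance t-test between two AUC lists.

    Returns (t, df, p) with df = n_a + n_b - 2.  Degenerate zero-variance
    input with equal means yields (0, df, 1); zero variance with unequal
    means is flagged with an error since the statistic is undefined.
    """
    a = np.asarray(aucs_a, float)
    b = np.asarray(aucs_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each AUC list needs at least two values")
    df = a.size + b.size - 2
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if pooled == 0.0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), df, float(p)
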