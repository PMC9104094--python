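"""Reciprocal distribution modelling: presence/pseudo-absence ensembles.

Workflow per dataset (native, P1, P2): draw pseudo-absences at five times
the presence count, split 75/25 stratified, fit three learners (boosted
trees, random forest, and a MaxEnt-style L1-regularized logistic model on
linear + quadratic features), score held-out AUC, binarize each run's
prediction at its own max-sensitivity+specificity threshold, and take a
strict-majority vote of the 30 binary maps as the ensemble consensus.
Projecting each range's ensemble onto the other range and overlaying the
two consensus maps yields the four-category invasion-risk map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import FunctionTransformer, StandardScaler

from .containers import EnvLayerStack, OccurrenceSet

__all__ = [
    "ALGORITHMS",
    "SdmRun",
    "EnsembleResult",
    "RiskMap",
    "sample_pseudo_absences",
    "fit_sdm",
    "auc",
    "max_sss_threshold",
    "run_ensemble",
    "project_ensemble",
    "presence_coverage",
    "risk_overlay",
]

log = logging.getLogger("nichedyn")

ALGORITHMS = ("boosted_trees", "random_forest", "maxent_like")


@dataclass
class SdmRun:
    """One fitted model repetition: scorer, held-out AUC, threshold, map."""

    algorithm: str
    repetition: int
    auc: float
    threshold: float
    binary_map: np.ndarray
    seed: int
    scorer: object = field(repr=False, default=None)


@dataclass
class EnsembleResult:
    runs: list[SdmRun]
    consensus_binary: np.ndarray
    agreement_count: np.ndarray
    dataset: str
    stack: EnvLayerStack = field(repr=False, default=None)

    @property
    def run_table(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"algorithm": r.algorithm, "repetition": r.repetition,
             "auc": r.auc, "threshold": r.threshold}
            for r in self.runs
        ])


@dataclass
class RiskMap:
    """Risk overlay categories: 0 neither, 1 invasive-only, 2 native-only, 3 both."""

    categories: np.ndarray
    shares: dict[str, float]
    valid_mask: np.ndarray

    CODES = {"neither": 0, "invasive_only": 1, "native_only": 2, "both": 3}


def sample_pseudo_absences(stack: EnvLayerStack, presences: OccurrenceSet,
                           ratio: int = 5, seed: int = 0) -> pd.DataFrame:
    """Uniform sample of ratio x n_presences valid cells holding no presence.

    Returns a frame with columns x, y (cell centres) plus the stack's
    environmental values; sampling is without replacement.
    """
    if ratio < 1:
        raise ValueError("pseudo-absence ratio must be at least 1")
    row, col = stack.cell_of(presences.data["x"], presences.data["y"])
    nr, nc = stack.shape
    inside = (row >= 0) & (row < nr) & (col >= 0) & (col < nc)
    occupied = np.zeros((nr, nc), dtype=bool)
    occupied[row[inside], col[inside]] = True
    candidates = np.argwhere(stack.valid_mask & ~occupied)
    n_needed = ratio * len(presences)
    if len(candidates) < n_needed:
        raise ValueError(
            f"only {len(candidates)} free valid cells for {n_needed} pseudo-absences")
    rng = np.random.default_rng(seed)
    chosen = candidates[rng.choice(len(candidates), size=n_needed, replace=False)]
    x, y = stack.cell_center(chosen[:, 0], chosen[:, 1])
    out = pd.DataFrame({"x": x, "y": y})
    for i, name in enumerate(stack.layer_names):
        out[name] = stack.values[i, chosen[:, 0], chosen[:, 1]]
    return out


def _quadratic(X):
    return np.hstack([X, X ** 2])


def fit_sdm(algorithm: str, train_table: pd.DataFrame, seed: int = 0):
    """Fit one presence / pseudo-absence learner; returns a [0, 1] scorer.

    ``train_table`` holds the environmental columns plus a 0/1 ``label``
    column. ``maxent_like`` is a MaxEnt-style surrogate: an L1-regularized
    presence-vs-background logistic model over linear and quadratic
    features; the interface is pluggable so a true maximum-entropy
    implementation can be swapped in.
    """
    y = train_table["label"].to_numpy()
    X = train_table.drop(columns="label").to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if algorithm == "boosted_trees":
        model = GradientBoostingClassifier(random_state=seed)
    elif algorithm == "random_forest":
        model = RandomForestClassifier(n_estimators=100, random_state=seed)
    elif algorithm == "maxent_like":
        model = Pipeline([
            ("quad", FunctionTransformer(_quadratic)),
            ("scale", StandardScaler()),
            ("logit", LogisticRegression(l1_ratio=1.0, C=1.0, max_iter=1000,
                                         solver="liblinear", random_state=seed)),
        ])
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    model.fit(X, y)

    def scorer(env_values: np.ndarray) -> np.ndarray:
        return model.predict_proba(np.asarray(env_values, float))[:, 1]

    return scorer


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties count 1/2."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def max_sss_threshold(scores, labels) -> float:
    """Score cut-off maximizing sensitivity + specificity (TSS-maximizing).

    Candidates are midpoints of consecutive sorted unique scores; a cell
    scoring at or above the threshold is predicted present. Ties resolve
    to the lowest maximizing threshold (favouring sensitivity). If every
    score is identical the degenerate threshold is returned with a warning.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("threshold selection needs both classes")
    uniq = np.unique(scores)
    if len(uniq) == 1:
        warnings.warn("all scores identical: degenerate threshold", stacklevel=2)
        return float(uniq[0])
    candidates = 0.5 * (uniq[:-1] + uniq[1:])
    n_pos, n_neg = labels.sum(), len(labels) - labels.sum()
    best_t, best_v = None, -np.inf
    for t in candidates:
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        if sens + spec > best_v + 1e-12:
            best_t, best_v = t, sens + spec
    return float(best_t)


def _stack_scores(scorer, stack: EnvLayerStack) -> np.ndarray:
    vals = stack.values[:, stack.valid_mask].T
    return scorer(vals)


def _binary_map(scorer, stack: EnvLayerStack, threshold: float) -> np.ndarray:
    out = np.zeros(stack.shape, dtype=bool)
    out[stack.valid_mask] = _stack_scores(scorer, stack) >= threshold
    return out


def run_ensemble(stack: EnvLayerStack, presences: OccurrenceSet,
                 algorithms=ALGORITHMS, reps: int = 10,
                 train_fraction: float = 0.75, ratio: int = 5,
                 seed: int = 0, dataset: str = "") -> EnsembleResult:
    """Fit the full reps x algorithms ensemble and take the majority vote.

    Pseudo-absences are redrawn for every repetition; the 75/25 split is
    stratified so train and test preserve the presence:absence ratio; each
    run is binarized with its own training-score threshold. A consensus
    cell is presence only when strictly more than half of the runs agree.
    Individual run failures are collected; the ensemble raises if more
    than 10% of runs fail.
    """
    from .io import extract_env_at_points

    if len(presences) < 8:
        raise ValueError("need at least 8 presences")
    pres_env = extract_env_at_points(stack, presences)
    rng = np.random.default_rng(seed)
    runs: list[SdmRun] = []
    failures: list[str] = []
    for rep in range(reps):
        pa_seed = int(rng.integers(2 ** 31 - 1))
        pa = sample_pseudo_absences(stack, presences, ratio, pa_seed)
        table = pd.concat([
            pres_env.assign(label=1),
            pa[stack.layer_names].assign(label=0),
        ], ignore_index=True)
        split_seed = int(rng.integers(2 ** 31 - 1))
        train, test = train_test_split(
            table, train_size=train_fraction, stratify=table["label"],
            random_state=split_seed)
        for algo in algorithms:
            fit_seed = int(rng.integers(2 ** 31 - 1))
            try:
                scorer = fit_sdm(algo, train, fit_seed)
                X_train = train.drop(columns="label").to_numpy(float)
                X_test = test.drop(columns="label").to_numpy(float)
                thr = max_sss_threshold(scorer(X_train), train["label"])
                test_auc = auc(scorer(X_test), test["label"])
                runs.append(SdmRun(algo, rep, test_auc, thr,
                                   _binary_map(scorer, stack, thr),
                                   fit_seed, scorer))
            except Exception as exc:  # per-run failures are tolerated up to 10%
                failures.append(f"{algo} rep {rep}: {exc}")
    n_total = reps * len(algorithms)
    if failures and len(failures) > 0.1 * n_total:
        raise RuntimeError(f"{len(failures)}/{n_total} ensemble runs failed: "
                           + "; ".join(failures[:3]))
    for msg in failures:
        log.warning("ensemble run failed: %s", msg)
    agreement = np.sum([r.binary_map for r in runs], axis=0).astype(int)
    consensus = agreement > len(runs) / 2  # strict majority; ties are absence
    return EnsembleResult(runs, consensus, agreement, dataset, stack)


def project_ensemble(ensemble: EnsembleResult,
                     other_stack: EnvLayerStack) -> np.ndarray:
    """Project every run (with its own threshold) onto another range.

    The target stack must carry identical layer names in identical order.
    Returns the strict-majority consensus on the other range's grid.
    """
    if other_stack.layer_names != ensemble.stack.layer_names:
        raise ValueError("layer names/order mismatch between ranges")
    maps = [_binary_map(r.scorer, other_stack, r.threshold)
            for r in ensemble.runs]
    agreement = np.sum(maps, axis=0)
    return agreement > len(maps) / 2


def presence_coverage(consensus: np.ndarray, stack: EnvLayerStack,
                      presences: OccurrenceSet) -> float:
    """Fraction of presence records whose cell is predicted present."""
    row, col = stack.cell_of(presences.data["x"], presences.data["y"])
    nr, nc = stack.shape
    inside = (row >= 0) & (row < nr) & (col >= 0) & (col < nc)
    if not inside.any():
        raise ValueError("no presence inside the projected extent")
    return float(consensus[row[inside], col[inside]].mean())


def risk_overlay(native_consensus: np.ndarray, invasive_consensus: np.ndarray,
                 valid_mask: np.ndarray | None = None) -> RiskMap:
    """Four-category risk map from the two consensus predictions.

    High-risk areas are the cells predicted by both models or by either
    one alone; low-risk cells are predicted by neither. Area shares are
    fractions of valid cells and sum to 1.
    """
    if native_consensus.shape != invasive_consensus.shape:
        raise ValueError("consensus grids must share a shape")
    if valid_mask is None:
        valid_mask = np.ones(native_consensus.shape, dtype=bool)
    cats = np.zeros(native_consensus.shape, dtype=int)
    cats[invasive_consensus & ~native_consensus] = RiskMap.CODES["invasive_only"]
    cats[native_consensus & ~invasive_consensus] = RiskMap.CODES["native_only"]
    cats[native_consensus & invasive_consensus] = RiskMap.CODES["both"]
    n = valid_mask.sum()
    shares = {name: float((cats[valid_mask] == code).sum() / n)
              for name, code in RiskMap.CODES.items()}
    return RiskMap(cats, shares, valid_mask)
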