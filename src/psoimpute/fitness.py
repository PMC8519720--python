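"""Two-objective fitness: how much does imputation disturb classification?

For a candidate chain assignment the evaluator (a) scores a classifier on
the intact observational block (cross-validated baseline panel), then (b)
repeatedly amputes the block under the resolved missingness profile,
imputes it with the candidate's algorithms, re-scores the classifier, and
records the absolute differences in sensitivity and specificity.  The mean
pair over repeats is the particle's fitness — lower means the imputation
better preserves the classification behaviour of the complete data.

Each repeat re-draws both the amputation and the cross-validation folds
from its own seed, so fitness is a deterministic function of (data,
profile, assignment, seed schedule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .data import ChainOrder, Dataset, chain_order, encode_matrix
from .errors import ConfigurationError, DataError
from .mechanism import MissingnessProfile, ampute
from .pool import AlgorithmSpec, ChainAssignment, fit_predict, get_spec, impute_chain

logger = logging.getLogger(__name__)

#: Classifier used inside the fitness loop unless configured otherwise:
#: logistic regression (discrete pool row 17) — cheap and deterministic.
DEFAULT_CLASSIFIER_INDEX = 17


@dataclass
class MetricPanel:
    """Binary classification panel on the percent scale.

    ``degenerate`` flags that at least one ratio had a zero denominator and
    was reported as 0.
    """

    sensitivity: float
    specificity: float
    accuracy: float
    ppv_pos: float
    ppv_neg: float
    f_measure: float
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "ppv_pos": self.ppv_pos,
            "ppv_neg": self.ppv_neg,
            "f_measure": self.f_measure,
        }


@dataclass
class FitnessResult:
    """Mean absolute sensitivity/specificity shifts over the repeats."""

    d_sensitivity: float
    d_specificity: float
    n_repeats: int
    per_repeat: list[tuple[float, float]]

    @property
    def objectives(self) -> tuple[float, float]:
        return (self.d_sensitivity, self.d_specificity)


def _safe_ratio(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return 100.0 * num / den, False


def metric_panel(truth, predicted, positive) -> MetricPanel:
    """Confusion-table panel for binary labels, percent scale."""
    truth = np.asarray(truth, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if len(truth) != len(predicted) or len(truth) == 0:
        raise DataError("truth and predicted must have equal nonzero length")
    labels = set(truth.tolist()) | set(predicted.tolist())
    if len(labels) > 2:
        raise DataError(f"unsupported target: more than two labels {sorted(map(str, labels))}")
    pos_t = truth == positive
    pos_p = predicted == positive
    tp = int((pos_t & pos_p).sum())
    fn = int((pos_t & ~pos_p).sum())
    fp = int((~pos_t & pos_p).sum())
    tn = int((~pos_t & ~pos_p).sum())
    sens, d1 = _safe_ratio(tp, tp + fn)
    spec, d2 = _safe_ratio(tn, tn + fp)
    acc, d3 = _safe_ratio(tp + tn, tp + tn + fp + fn)
    ppv_p, d4 = _safe_ratio(tp, tp + fp)
    ppv_n, d5 = _safe_ratio(tn, tn + fn)
    if sens + ppv_p > 0:
        f = 2 * sens * ppv_p / (sens + ppv_p)
        d6 = False
    else:
        f, d6 = 0.0, True
    return MetricPanel(sens, spec, acc, ppv_p, ppv_n, f,
                       degenerate=any([d1, d2, d3, d4, d5, d6]))


# -- cross-validated classification panel --------------------------------------


def _cv_predictions(X: np.ndarray, y: np.ndarray, classifier: AlgorithmSpec,
                    seed: int, n_splits: int = 5) -> np.ndarray:
    """Pooled out-of-fold predictions under (stratified where possible) CV."""
    from sklearn.model_selection import KFold, StratifiedKFold

    _, counts = np.unique(y.astype(str), return_counts=True)
    k = int(min(n_splits, counts.min()))
    out = np.empty(len(y), dtype=object)
    if k >= 2:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2 ** 31))
        folds = splitter.split(X, y.astype(str))
    else:
        k2 = min(2, len(y) - 1)
        splitter = KFold(n_splits=max(2, k2), shuffle=True, random_state=seed % (2 ** 31))
        folds = splitter.split(X)
    for train_idx, test_idx in folds:
        preds = fit_predict(classifier, X[train_idx], y[train_idx], X[test_idx], seed=seed)
        out[test_idx] = preds
    return out


def classification_panel(ds: Dataset, classifier: AlgorithmSpec, seed: int,
                         positive=None, n_splits: int = 5) -> MetricPanel:
    """Cross-validated panel of ``classifier`` on a fully observed dataset.

    Features are the numeric-encoded independent variables; the positive
    class defaults to the lexicographically last observed dependent level.
    """
    dep = ds.dependent.name
    if not ds.mask.to_numpy().all():
        raise DataError("classification panel requires a fully observed dataset")
    levels = ds.observed_levels(dep)
    if len(levels) < 2:
        raise DataError("dependent variable needs at least 2 observed levels")
    if positive is None:
        positive = levels[-1]
    X = encode_matrix(ds, [v.name for v in ds.independents])
    y = ds.values[dep].to_numpy(object)
    preds = _cv_predictions(X, y, classifier, seed, n_splits=n_splits)
    return metric_panel(y, preds, positive)


# -- imputers pluggable into the fitness loop ----------------------------------


def chain_imputer(amputed: Dataset, assignment: ChainAssignment, seed: int) -> Dataset:
    """Default imputer: the chained per-variable algorithm executor."""
    return impute_chain(amputed, assignment, seed=seed)


def make_oracle_imputer(original: Dataset) -> Callable[[Dataset, ChainAssignment, int], Dataset]:
    """Imputer that restores every amputed cell from the intact original —
    the ideal-recovery reference, which must score fitness exactly (0, 0)."""

    def _impute(amputed: Dataset, assignment: ChainAssignment, seed: int) -> Dataset:
        out = amputed.copy()
        miss = ~out.mask.to_numpy()
        for r, c in zip(*np.nonzero(miss)):
            name = out.var_names[c]
            out.values.at[r, name] = original.values.at[r, name]
            out.mask.at[r, name] = True
        return Dataset(out.values, out.mask, out.schema)

    return _impute


def make_noise_imputer(scale: float = 3.0) -> Callable[[Dataset, ChainAssignment, int], Dataset]:
    """Imputer that fills amputed cells with pure noise — a corruption
    reference expected to score worse than faithful imputation."""

    def _impute(amputed: Dataset, assignment: ChainAssignment, seed: int) -> Dataset:
        rng = np.random.default_rng(seed)
        out = amputed.copy()
        miss = ~out.mask.to_numpy()
        for r, c in zip(*np.nonzero(miss)):
            name = out.var_names[c]
            var = out.var(name)
            if var.vtype == "continuous":
                out.values.at[r, name] = float(rng.normal(scale=scale))
            else:
                levels = out.observed_levels(name)
                out.values.at[r, name] = levels[int(rng.integers(len(levels)))]
            out.mask.at[r, name] = True
        return Dataset(out.values, out.mask, out.schema)

    return _impute


# -- the evaluator -------------------------------------------------------------


class FitnessEvaluator:
    """Caches per-assignment fitness over a fixed observational block.

    With the per-repeat seeds fixed at construction, fitness depends only on
    the decoded assignment, so results are memoized by pool-index tuple —
    particles that decode identically share one evaluation.
    """

    def __init__(
        self,
        observational: Dataset,
        profile: MissingnessProfile,
        order: ChainOrder | None = None,
        classifier: AlgorithmSpec | None = None,
        n_repeats: int = 100,
        seed: int = 0,
        positive=None,
        imputer: Callable[[Dataset, ChainAssignment, int], Dataset] | None = None,
    ):
        if n_repeats < 1:
            raise ConfigurationError("n_repeats must be >= 1")
        if not observational.mask.to_numpy().all():
            raise DataError("the observational block must be fully observed")
        self.observational = observational
        self.profile = profile
        self.order = order if order is not None else ChainOrder(tuple(profile.per_var_fraction))
        self.classifier = classifier or get_spec("discrete", DEFAULT_CLASSIFIER_INDEX)
        self.n_repeats = n_repeats
        self.seed = int(seed) % (2 ** 31)
        self.positive = positive
        self.imputer = imputer or chain_imputer
        self._cache: dict[tuple[int, ...], FitnessResult] = {}
        self._acc_cache: dict[tuple[int, ...], float] = {}
        self._baseline_cache: dict[int, MetricPanel] = {}
        self.baseline = classification_panel(
            observational, self.classifier, seed=self.seed, positive=positive
        )
        if self.baseline.degenerate and self.baseline.accuracy == 0:
            raise ConfigurationError("classifier degenerate on the baseline data")

    def _baseline_panel(self, rep_seed: int) -> MetricPanel:
        """Intact-data panel under the same fold draw as the repeat.

        Pairing the two evaluation modes on one fold split makes the
        difference attributable to the imputation alone; with an ideal
        imputation the two panels are identical and the difference is an
        exact zero.
        """
        if rep_seed not in self._baseline_cache:
            self._baseline_cache[rep_seed] = classification_panel(
                self.observational, self.classifier, seed=rep_seed,
                positive=self.positive)
        return self._baseline_cache[rep_seed]

    # fitness -----------------------------------------------------------------

    def evaluate(self, assignment: ChainAssignment) -> FitnessResult:
        key = assignment.index_tuple()
        if key in self._cache:
            return self._cache[key]
        per_repeat: list[tuple[float, float]] = []
        for r in range(self.n_repeats):
            rep_seed = self.seed + 1 + r
            amputed = ampute(self.observational, self.profile, seed=rep_seed)
            imputed = self.imputer(amputed, assignment, rep_seed)
            panel = classification_panel(imputed, self.classifier, seed=rep_seed,
                                         positive=self.positive)
            base = self._baseline_panel(rep_seed)
            per_repeat.append((
                abs(panel.sensitivity - base.sensitivity),
                abs(panel.specificity - base.specificity),
            ))
        result = FitnessResult(
            d_sensitivity=float(np.mean([d[0] for d in per_repeat])),
            d_specificity=float(np.mean([d[1] for d in per_repeat])),
            n_repeats=self.n_repeats,
            per_repeat=per_repeat,
        )
        self._cache[key] = result
        return result

    def __call__(self, assignment: ChainAssignment) -> tuple[float, float]:
        return self.evaluate(assignment).objectives

    # accuracy re-scoring for the final selection ------------------------------

    def accuracy(self, assignment: ChainAssignment) -> float:
        """Classification accuracy after a fresh amputation/imputation draw
        (a seed outside the fitness schedule, so the re-score is not
        optimistically tied to the search draws)."""
        key = assignment.index_tuple()
        if key in self._acc_cache:
            return self._acc_cache[key]
        fresh = self.seed + 999_983
        amputed = ampute(self.observational, self.profile, seed=fresh)
        imputed = self.imputer(amputed, assignment, fresh)
        panel = classification_panel(imputed, self.classifier, seed=fresh,
                                     positive=self.positive)
        self._acc_cache[key] = panel.accuracy
        return panel.accuracy


def fitness(
    assignment: ChainAssignment,
    observational: Dataset,
    profile: MissingnessProfile,
    classifier: AlgorithmSpec | None = None,
    n_repeats: int = 100,
    seed: int = 0,
) -> FitnessResult:
    """One-shot fitness of a single assignment (see :class:`FitnessEvaluator`)."""
    ev = FitnessEvaluator(observational, profile, order=assignment.order,
                          classifier=classifier, n_repeats=n_repeats, seed=seed)
    return ev.evaluate(assignment)
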