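"""Prediction-algorithm pools and the chained imputation executor.

Two fixed registries — 18 discrete-target algorithms and 9 continuous-target
algorithms — sit behind a single ``fit_predict`` contract, all realized with
scikit-learn estimators.  The chain executor imputes the missing variables
in order: position *i* is predicted from the already-completed variables
``x_1..x_{i-1}``; position 1, which has no predecessor, is predicted from
the next chain variable (or, for a single-variable chain, from the
least-missing other independent variable).

Hyperparameter conventions where the registry names a family only:

* "RBF = c" is read as the kernel width gamma of exp(-gamma ||u - v||^2).
* SVM-polynomial uses degree 3; SVM-quadratic degree 2.
* The feed-forward network has one hidden layer of width
  ceil((n_inputs + n_outputs) / 2), trained for up to 500 epochs with a
  seeded initialization.
* The discrete tree is an entropy-criterion CART stand-in for C4.5 (no rule
  post-pruning); the continuous tree uses variance reduction.

Inputs to distance/margin-based learners (SVM, k-NN, ANN, logistic, SVR,
linear regression) are z-scored from the training rows; tree and
naive-Bayes families are fit on raw codes.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data import ChainOrder, Dataset, VariableSchema, encode_column, missing_fraction
from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

_DISCRETE_ROWS: list[tuple[str, dict]] = [
    ("svm-linear", {}),
    ("svm-quadratic", {"degree": 2}),
    ("svm-polynomial", {"degree": 3}),
    ("svm-rbf", {"gamma": 5.0}),
    ("svm-rbf", {"gamma": 2.0}),
    ("svm-rbf", {"gamma": 1.0}),
    ("svm-rbf", {"gamma": 0.5}),
    ("svm-rbf", {"gamma": 0.2}),
    ("svm-rbf", {"gamma": 0.1}),
    ("knn", {"k": 1}),
    ("knn", {"k": 3}),
    ("knn", {"k": 5}),
    ("knn", {"k": 7}),
    ("knn", {"k": 9}),
    ("tree-entropy", {}),
    ("ann", {}),
    ("logistic", {}),
    ("naive-bayes", {}),
]

_CONTINUOUS_ROWS: list[tuple[str, dict]] = [
    ("svr", {}),
    ("knn", {"k": 1}),
    ("knn", {"k": 3}),
    ("knn", {"k": 5}),
    ("knn", {"k": 7}),
    ("knn", {"k": 9}),
    ("cart", {}),
    ("ann", {}),
    ("multiple-regression", {}),
]

#: Families fit on z-scored inputs.
_STANDARDIZED = {"svm-linear", "svm-quadratic", "svm-polynomial", "svm-rbf",
                 "knn", "ann", "logistic", "svr", "multiple-regression"}

REGRESSION_FAMILIES = {"multiple-regression", "svr"}


@dataclass(frozen=True)
class AlgorithmSpec:
    """One registry row: 1-based index, family name, target type, hyperparameters."""

    index: int
    family: str
    vtype: str
    hyper: tuple[tuple[str, object], ...] = ()

    @property
    def hyper_dict(self) -> dict:
        return dict(self.hyper)

    @property
    def label(self) -> str:
        if self.family == "knn":
            return f"{self.hyper_dict['k']}-NN"
        if self.family == "svm-rbf":
            return f"SVM-RBF={self.hyper_dict['gamma']:g}"
        return self.family


def registry(vtype: str) -> list[AlgorithmSpec]:
    """The fixed algorithm pool for one target type, in table row order."""
    if vtype == "discrete":
        rows = _DISCRETE_ROWS
    elif vtype == "continuous":
        rows = _CONTINUOUS_ROWS
    else:
        raise ConfigurationError(f"unknown vtype {vtype!r}")
    return [
        AlgorithmSpec(i + 1, family, vtype, tuple(sorted(h.items())))
        for i, (family, h) in enumerate(rows)
    ]


def get_spec(vtype: str, index: int) -> AlgorithmSpec:
    pool = registry(vtype)
    if not (1 <= index <= len(pool)):
        raise ConfigurationError(f"index {index} outside the {vtype} pool 1..{len(pool)}")
    return pool[index - 1]


def registry_json() -> list[dict]:
    """Serializable registry listing (for documentation / CLI overrides)."""
    return [
        {"vtype": s.vtype, "index": s.index, "family": s.family,
         "label": s.label, "hyper": s.hyper_dict}
        for vt in ("discrete", "continuous") for s in registry(vt)
    ]


# -- estimator construction ----------------------------------------------------


def _make_estimator(spec: AlgorithmSpec, n_rows: int, n_classes: int, seed: int):
    from sklearn.linear_model import LinearRegression, LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
    from sklearn.neural_network import MLPClassifier, MLPRegressor
    from sklearn.svm import SVC, SVR
    from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

    h = spec.hyper_dict
    fam = spec.family
    discrete = spec.vtype == "discrete"
    if fam == "knn":
        k = h["k"]
        if k > n_rows - 1:
            k = max(1, n_rows - 1)
            logger.info("k-NN: reducing k to %d (only %d training rows)", k, n_rows)
        cls = KNeighborsClassifier if discrete else KNeighborsRegressor
        return cls(n_neighbors=k)
    if fam == "svm-linear":
        return SVC(kernel="linear", decision_function_shape="ovr")
    if fam in ("svm-quadratic", "svm-polynomial"):
        return SVC(kernel="poly", degree=h["degree"], gamma="scale", coef0=1.0)
    if fam == "svm-rbf":
        return SVC(kernel="rbf", gamma=h["gamma"])
    if fam == "svr":
        return SVR(kernel="rbf", gamma="scale")
    if fam == "tree-entropy":
        return DecisionTreeClassifier(criterion="entropy", random_state=seed)
    if fam == "cart":
        return DecisionTreeRegressor(criterion="squared_error", random_state=seed)
    if fam == "ann":
        n_out = n_classes if discrete else 1
        width = max(2, math.ceil((1 + n_out) / 2) + 1)  # refined below with n_features
        cls = MLPClassifier if discrete else MLPRegressor
        return cls(hidden_layer_sizes=(width,), max_iter=500, random_state=seed)
    if fam == "logistic":
        return LogisticRegression(max_iter=1000)
    if fam == "naive-bayes":
        return GaussianNB()
    if fam == "multiple-regression":
        return LinearRegression()
    raise ConfigurationError(f"unknown family {fam!r}")


def fit_predict(
    spec: AlgorithmSpec,
    train_X: np.ndarray,
    train_y: np.ndarray,
    query_X: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Train ``spec``'s estimator and predict one value per query row.

    Degenerate training targets (a single observed level, or zero variance
    for continuous targets) fall back to a constant predictor.  Discrete
    predictions can only be levels present in the training target.
    """
    train_X = np.asarray(train_X, dtype=float)
    query_X = np.asarray(query_X, dtype=float)
    if train_X.ndim == 1:
        train_X = train_X[:, None]
    if query_X.ndim == 1:
        query_X = query_X[:, None]
    if np.isnan(train_X).any() or np.isnan(query_X).any():
        raise DataError("fit_predict inputs must not contain missing cells")
    train_y = np.asarray(train_y)
    n_rows = len(train_X)
    if n_rows == 0:
        raise DataError("empty training set")

    discrete = spec.vtype == "discrete"
    levels = np.unique(train_y)
    if discrete and len(levels) < 2:
        logger.info("%s: single training level, constant predictor", spec.label)
        return np.full(len(query_X), levels[0] if len(levels) else np.nan, dtype=object)
    if not discrete:
        yf = train_y.astype(float)
        if np.ptp(yf) == 0:
            logger.info("%s: zero-variance target, constant predictor", spec.label)
            return np.full(len(query_X), yf[0])

    if spec.family in _STANDARDIZED:
        mu = train_X.mean(axis=0)
        sd = train_X.std(axis=0)
        sd[sd == 0] = 1.0
        train_X = (train_X - mu) / sd
        query_X = (query_X - mu) / sd

    est = _make_estimator(spec, n_rows, len(levels), seed)
    if spec.family == "ann":
        width = max(2, math.ceil((train_X.shape[1] + (len(levels) if discrete else 1)) / 2))
        est.set_params(hidden_layer_sizes=(width,))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if discrete:
            est.fit(train_X, train_y.astype(str) if train_y.dtype == object else train_y)
            pred = est.predict(query_X)
            if train_y.dtype == object:
                # map back from the string view to the original objects
                back = {str(v): v for v in train_y}
                pred = np.asarray([back[p] for p in pred], dtype=object)
            return pred
        est.fit(train_X, train_y.astype(float))
        return est.predict(query_X).astype(float)


# -- chain assignment and executor ---------------------------------------------


@dataclass(frozen=True)
class ChainAssignment:
    """Ordered (variable, algorithm) pairs realizing the imputation chain."""

    entries: tuple[tuple[str, AlgorithmSpec], ...]
    order: ChainOrder

    def __post_init__(self) -> None:
        if tuple(v for v, _ in self.entries) != self.order.ordered_vars:
            raise ConfigurationError("assignment entries must follow the chain order")

    def spec_for(self, var: str) -> AlgorithmSpec:
        for name, spec in self.entries:
            if name == var:
                return spec
        raise ConfigurationError(f"no assignment entry for {var!r}")

    def index_tuple(self) -> tuple[int, ...]:
        return tuple(spec.index for _, spec in self.entries)

    def to_json(self) -> list[dict]:
        return [
            {"variable": v, "vtype": s.vtype, "index": s.index, "algorithm": s.label}
            for v, s in self.entries
        ]


def make_assignment(order: ChainOrder, schema: Sequence[VariableSchema],
                    indices: Sequence[int]) -> ChainAssignment:
    """Build an assignment from pool indices (one per chain variable)."""
    smap = {v.name: v for v in schema}
    if len(indices) != len(order):
        raise ConfigurationError("one pool index per chain variable required")
    entries = []
    for name, idx in zip(order, indices):
        spec = get_spec(smap[name].vtype, idx)
        entries.append((name, spec))
    return ChainAssignment(tuple(entries), order)


def _partner_variable(ds: Dataset, order: ChainOrder) -> str:
    """Predictor for chain position 1: the next chain variable, or the
    least-missing other independent variable for a single-variable chain."""
    if len(order) >= 2:
        return order.ordered_vars[1]
    first = order.ordered_vars[0]
    others = [
        (missing_fraction(ds, v.name), i, v.name)
        for i, v in enumerate(ds.independents) if v.name != first
    ]
    if not others:
        raise DataError("no partner variable available for a single-variable chain")
    return min(others)[2]


def _mean_mode_fill(ds: Dataset, name: str, column: np.ndarray) -> np.ndarray:
    """Fill NaNs in an encoded column with the observed mean (continuous)
    or modal code (discrete)."""
    out = column.copy()
    nan = np.isnan(out)
    if not nan.any():
        return out
    obs = out[~nan]
    if len(obs) == 0:
        raise DataError(f"column {name!r} has no observed values to fall back on")
    if ds.var(name).vtype == "continuous":
        fill = float(obs.mean())
    else:
        vals, counts = np.unique(obs, return_counts=True)
        fill = float(vals[np.argmax(counts)])
    out[nan] = fill
    return out


def impute_chain(ds: Dataset, assignment: ChainAssignment, seed: int = 0) -> Dataset:
    """Impute every chain variable in order under ``assignment``.

    Observed cells are never overwritten; the output has no missing cell in
    any chain variable.  Training for position *i* uses the rows where the
    variable is observed; its predictors are the previously completed chain
    variables (position 1 uses the designated partner variable, with
    mean/mode fill of any still-missing partner cell at query time only).
    """
    out = ds.copy()
    order = assignment.order
    if len(order) == 0:
        return out
    completed: list[str] = []
    for pos, (name, spec) in enumerate(assignment.entries):
        var = ds.var(name)
        if spec.vtype != var.vtype:
            raise ConfigurationError(f"{spec.label} ({spec.vtype}) assigned to {name!r} ({var.vtype})")
        if pos == 0:
            predictors = [_partner_variable(ds, order)]
        else:
            predictors = list(completed)
        train_rows = np.flatnonzero(out.mask[name].to_numpy())
        query_rows = np.flatnonzero(~out.mask[name].to_numpy())
        if len(query_rows) == 0:
            completed.append(name)
            continue
        X_full = np.column_stack([
            _mean_mode_fill(out, p, encode_column(out, p)) for p in predictors
        ]) if predictors else np.empty((out.n_records, 0))
        y_train = out.values[name].to_numpy(object)[train_rows]
        use_fallback = X_full.shape[1] == 0 or len(train_rows) == 0
        if use_fallback:
            logger.warning("chain variable %r: empty predictor set, mean/mode fallback", name)
            filled = _mean_mode_fill(out, name, encode_column(out, name))
            if var.vtype == "continuous":
                preds = filled[query_rows]
            else:
                levels = out.observed_levels(name)
                preds = np.asarray([levels[int(filled[i])] for i in query_rows], dtype=object)
        else:
            if var.vtype == "continuous":
                y_train = y_train.astype(float)
            preds = fit_predict(spec, X_full[train_rows], y_train, X_full[query_rows],
                                seed=seed + pos)
        for r, v in zip(query_rows, preds):
            out.values.at[r, name] = v
            out.mask.at[r, name] = True
        completed.append(name)
    return Dataset(out.values, out.mask, out.schema)
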