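"""Comparison imputers and the benchmarking harness.

Five standard single-imputation baselines — listwise deletion, mean/mode,
multivariate-normal EM, chained equations (MICE), and an iterative
random-forest imputer in the missForest style — plus a harness that imputes
a dataset with each requested method (including the swarm-selected chain)
and scores a downstream classifier under tenfold or 70/30 evaluation,
averaging the metric panels over repeated runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._em import conditional_fill, em_mvnorm
from .data import Dataset, encode_column, missing_fraction
from .errors import ConfigurationError, DataError, DegenerateInputError
from .fitness import AlgorithmSpec, MetricPanel, _cv_predictions, metric_panel
from .pool import get_spec

logger = logging.getLogger(__name__)

METHOD_LABELS = {
    "deletion": "Delete missing",
    "mean": "Mean algorithm",
    "em": "Expectation maximization",
    "mice": "MICE algorithm",
    "missforest": "missForest algorithm",
    "proposed": "Proposed algorithm",
}
DEFAULT_METHODS = tuple(METHOD_LABELS)


# -- simple imputers -----------------------------------------------------------


def impute_deletion(ds: Dataset) -> Dataset:
    """Listwise deletion: drop records with any missing independent cell."""
    cols = [v.name for v in ds.independents]
    keep = ds.mask[cols].to_numpy().all(axis=1) & ds.mask[ds.dependent.name].to_numpy()
    if not keep.any():
        raise DegenerateInputError("listwise deletion removes every record")
    return Dataset(ds.values[keep].copy(), ds.mask[keep].copy(), ds.schema)


def _column_mode(ds: Dataset, name: str):
    observed = ds.values[name][ds.mask[name]].tolist()
    levels = ds.observed_levels(name)
    counts = {lvl: 0 for lvl in levels}
    for v in observed:
        counts[v] += 1
    return max(levels, key=lambda l: (counts[l], ))  # ties: first in level order


def impute_mean(ds: Dataset) -> Dataset:
    """Mean fill for continuous columns, modal level for discrete ones."""
    out = ds.copy()
    for var in ds.schema:
        missing = np.flatnonzero(~out.mask[var.name].to_numpy())
        if len(missing) == 0:
            continue
        observed = out.values[var.name][out.mask[var.name]]
        if len(observed) == 0:
            raise ConfigurationError(
                f"column {var.name!r} is fully missing; drop it before imputing"
            )
        fill = float(observed.astype(float).mean()) if var.vtype == "continuous" \
            else _column_mode(out, var.name)
        for r in missing:
            out.values.at[r, var.name] = fill
            out.mask.at[r, var.name] = True
    return Dataset(out.values, out.mask, out.schema)


def impute_em(ds: Dataset, tol: float = 1e-6, max_iter: int = 500,
              return_info: bool = False):
    """Multivariate-normal EM completion of the continuous block.

    Missing continuous cells become conditional expectations given the
    row's observed continuous values under the EM-estimated N(mu, Sigma);
    discrete cells are mode-filled.  Deterministic.
    """
    cont = [v.name for v in ds.schema if v.vtype == "continuous"]
    out = ds.copy()
    n_iter = 0
    converged = True
    cont_missing = any((~ds.mask[c]).any() for c in cont)
    if cont and cont_missing:
        X = np.column_stack([encode_column(ds, c) for c in cont])
        est = em_mvnorm(X, tol=tol, max_iter=max_iter)
        n_iter, converged = est.n_iter, est.converged
        if not converged:
            logger.warning("EM did not converge in %d iterations; using last iterate", max_iter)
        filled = conditional_fill(X, est.mean, est.cov)
        for j, name in enumerate(cont):
            rows = np.flatnonzero(~out.mask[name].to_numpy())
            for r in rows:
                out.values.at[r, name] = float(filled[r, j])
                out.mask.at[r, name] = True
    for var in ds.schema:
        if var.vtype == "discrete" and (~out.mask[var.name]).any():
            mode = _column_mode(out, var.name)
            for r in np.flatnonzero(~out.mask[var.name].to_numpy()):
                out.values.at[r, var.name] = mode
                out.mask.at[r, var.name] = True
    result = Dataset(out.values, out.mask, out.schema)
    if return_info:
        return result, {"n_iter": n_iter, "converged": converged}
    return result


# -- MICE ----------------------------------------------------------------------


def _design_matrix(ds: Dataset, exclude: str) -> np.ndarray:
    cols = [n for n in ds.var_names if n != exclude]
    return np.column_stack([encode_column(ds, c) for c in cols])


def impute_mice(ds: Dataset, n_iterations: int = 10, seed: int = 0) -> Dataset:
    """Chained-equation single imputation.

    Mean/mode initialization, then ``n_iterations`` sweeps; each incomplete
    variable is regressed on all other variables over its originally
    observed rows (linear model for continuous targets, multinomial
    logistic for discrete) and its missing cells are re-drawn from the
    fitted predictive distribution.  Seeded and deterministic.
    """
    from sklearn.linear_model import LinearRegression, LogisticRegression, Ridge

    rng = np.random.default_rng(int(seed) % (2 ** 31))
    incomplete = [v for v in ds.schema if (~ds.mask[v.name]).any()]
    if not incomplete:
        return ds.copy()
    orig_mask = {v.name: ds.mask[v.name].to_numpy().copy() for v in ds.schema}
    work = impute_mean(ds)
    for _ in range(n_iterations):
        for var in incomplete:
            name = var.name
            obs_rows = np.flatnonzero(orig_mask[name])
            mis_rows = np.flatnonzero(~orig_mask[name])
            X = _design_matrix(work, name)
            if var.vtype == "continuous":
                y = work.values[name].to_numpy(float)
                model = LinearRegression()
                try:
                    model.fit(X[obs_rows], y[obs_rows])
                except np.linalg.LinAlgError:
                    logger.warning("MICE: singular design for %r, ridge fallback", name)
                    model = Ridge(alpha=1e-6).fit(X[obs_rows], y[obs_rows])
                resid = y[obs_rows] - model.predict(X[obs_rows])
                dof = max(1, len(obs_rows) - X.shape[1] - 1)
                sigma = float(np.sqrt((resid ** 2).sum() / dof))
                draws = model.predict(X[mis_rows]) + rng.normal(scale=sigma, size=len(mis_rows))
                for r, v in zip(mis_rows, draws):
                    work.values.at[r, name] = float(v)
            else:
                y = work.values[name].to_numpy(object)[obs_rows]
                levels = sorted(set(y.tolist()), key=str)
                if len(levels) < 2:
                    for r in mis_rows:
                        work.values.at[r, name] = levels[0]
                    continue
                model = LogisticRegression(max_iter=500)  # l2 penalty guards separation
                ymap = {lvl: i for i, lvl in enumerate(levels)}
                model.fit(X[obs_rows], [ymap[v] for v in y])
                proba = model.predict_proba(X[mis_rows])
                for r, p in zip(mis_rows, proba):
                    work.values.at[r, name] = levels[int(rng.choice(len(levels), p=p))]
    return Dataset(work.values, work.mask, work.schema)


# -- missForest-style imputer --------------------------------------------------


def _rf_fit_predict(vtype: str, X_train, y_train, X_query, seed: int,
                    n_estimators: int) -> np.ndarray:
    """Random-forest fit/predict used by the missForest loop (patchable in tests)."""
    from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

    if vtype == "continuous":
        rf = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
        rf.fit(X_train, np.asarray(y_train, dtype=float))
        return rf.predict(X_query)
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    levels = sorted(set(np.asarray(y_train, dtype=object).tolist()), key=str)
    if len(levels) < 2:
        return np.asarray([levels[0]] * len(X_query), dtype=object)
    ymap = {lvl: i for i, lvl in enumerate(levels)}
    rf.fit(X_train, [ymap[v] for v in np.asarray(y_train, dtype=object)])
    return np.asarray([levels[int(i)] for i in rf.predict(X_query)], dtype=object)


def impute_missforest(ds: Dataset, max_iter: int = 10, seed: int = 0,
                      n_estimators: int = 100, return_info: bool = False):
    """Iterative random-forest imputation with a self-stopping criterion.

    Variables are revisited in ascending-missingness order; iteration stops
    the first time the difference criterion between successive imputations
    (normalized squared change for continuous cells plus disagreement
    proportion for discrete cells) increases, returning the previous
    iterate.
    """
    incomplete = sorted(
        (v for v in ds.schema if (~ds.mask[v.name]).any()),
        key=lambda v: (missing_fraction(ds, v.name), ds.var_names.index(v.name)),
    )
    if not incomplete:
        out = ds.copy()
        return (out, {"n_accepted": 0, "criteria": []}) if return_info else out
    orig_mask = {v.name: ds.mask[v.name].to_numpy().copy() for v in ds.schema}
    work = impute_mean(ds)
    prev = work.copy()
    criteria: list[float] = []
    n_accepted = 0
    for it in range(1, max_iter + 1):
        for var in incomplete:
            name = var.name
            obs_rows = np.flatnonzero(orig_mask[name])
            mis_rows = np.flatnonzero(~orig_mask[name])
            X = _design_matrix(work, name)
            y_obs = work.values[name].to_numpy(object)[obs_rows]
            preds = _rf_fit_predict(var.vtype, X[obs_rows], y_obs, X[mis_rows],
                                    seed=seed + it, n_estimators=n_estimators)
            for r, v in zip(mis_rows, preds):
                work.values.at[r, name] = float(v) if var.vtype == "continuous" else v
        crit = _difference_criterion(prev, work, orig_mask, incomplete)
        if criteria and crit > criteria[-1]:
            criteria.append(crit)
            work = prev  # revert: the previous iterate is the accepted one
            break
        criteria.append(crit)
        n_accepted = it
        prev = work.copy()
    result = Dataset(work.values, work.mask, work.schema)
    if return_info:
        return result, {"n_accepted": n_accepted, "criteria": criteria}
    return result


def _difference_criterion(prev: Dataset, new: Dataset, orig_mask: dict,
                          incomplete) -> float:
    num_c = den_c = 0.0
    dis = tot_d = 0
    for var in incomplete:
        mis = np.flatnonzero(~orig_mask[var.name])
        a = new.values[var.name].iloc[mis].to_numpy(object)
        b = prev.values[var.name].iloc[mis].to_numpy(object)
        if var.vtype == "continuous":
            a, b = a.astype(float), b.astype(float)
            num_c += float(((a - b) ** 2).sum())
            den_c += float((a ** 2).sum())
        else:
            dis += int((a != b).sum())
            tot_d += len(a)
    crit = 0.0
    if den_c > 0:
        crit += num_c / den_c
    if tot_d > 0:
        crit += dis / tot_d
    return crit


# -- benchmark harness ---------------------------------------------------------


@dataclass
class BenchmarkReport:
    """Mean metric panels per method; ``None`` marks a not-evaluable method."""

    rows: dict[str, MetricPanel | None]
    protocol: str
    n_runs: int
    dataset_tag: str = ""
    notes: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "protocol": self.protocol,
            "n_runs": self.n_runs,
            "dataset_tag": self.dataset_tag,
            "rows": {
                METHOD_LABELS.get(k, k): (p.as_dict() if p is not None else None)
                for k, p in self.rows.items()
            },
            "notes": self.notes,
        }
        return json.dumps(payload, indent=2)

    def to_text(self) -> str:
        cols = ["sensitivity", "specificity", "accuracy", "ppv_pos", "ppv_neg", "f_measure"]
        header = ["Algorithm name", "Sensitivity (%)", "Specificity (%)", "Accuracy (%)",
                  "PPV+ (%)", "PPV- (%)", "F-measure (%)"]
        lines = ["\t".join(header)]
        for k, p in self.rows.items():
            label = METHOD_LABELS.get(k, k)
            if p is None:
                lines.append(f"{label}\t" + "\t".join(["n/a"] * 6))
            else:
                d = p.as_dict()
                lines.append(label + "\t" + "\t".join(f"{d[c]:.2f}" for c in cols))
        return "\n".join(lines)


def _evaluate_imputed(imputed: Dataset, protocol: str, n_runs: int,
                      classifier: AlgorithmSpec, seed: int, positive=None) -> MetricPanel:
    from sklearn.model_selection import train_test_split

    from .data import encode_matrix

    dep = imputed.dependent.name
    levels = imputed.observed_levels(dep)
    if len(levels) < 2:
        raise DataError("dependent variable needs >= 2 levels for evaluation")
    if positive is None:
        positive = levels[-1]
    X = encode_matrix(imputed, [v.name for v in imputed.independents])
    y = imputed.values[dep].to_numpy(object)
    panels = []
    for run in range(n_runs):
        run_seed = (seed + run) % (2 ** 31)
        if protocol == "tenfold":
            preds = _cv_predictions(X, y, classifier, seed=run_seed, n_splits=10)
            panels.append(metric_panel(y, preds, positive))
        elif protocol == "split_70_30":
            idx = np.arange(len(y))
            strat = y.astype(str)
            try:
                tr, te = train_test_split(idx, test_size=0.3, random_state=run_seed,
                                          stratify=strat)
            except ValueError:
                tr, te = train_test_split(idx, test_size=0.3, random_state=run_seed)
            from .pool import fit_predict
            preds = fit_predict(classifier, X[tr], y[tr], X[te], seed=run_seed)
            panels.append(metric_panel(y[te], preds, positive))
        else:
            raise ConfigurationError(f"unknown protocol {protocol!r}")
    mean = {k: float(np.mean([p.as_dict()[k] for p in panels])) for k in panels[0].as_dict()}
    return MetricPanel(**mean, degenerate=any(p.degenerate for p in panels))


def benchmark(
    ds: Dataset,
    methods: Sequence[str] = DEFAULT_METHODS,
    protocol: str = "tenfold",
    n_runs: int = 100,
    classifier: AlgorithmSpec | None = None,
    seed: int = 0,
    proposed_options: dict | None = None,
    dataset_tag: str = "",
) -> BenchmarkReport:
    """Impute ``ds`` with each method and score the downstream classifier.

    ``proposed_options`` are forwarded to the full swarm pipeline for the
    "proposed" method.  A method whose imputation degenerates (e.g. deletion
    leaving too few records for the protocol) is marked not-evaluable.
    """
    if not methods:
        raise ConfigurationError("methods list must be non-empty")
    classifier = classifier or get_spec("discrete", 17)
    rows: dict[str, MetricPanel | None] = {}
    notes: dict[str, str] = {}
    min_records = 20 if protocol == "tenfold" else 10
    for method in methods:
        try:
            if method == "deletion":
                imputed = impute_deletion(ds)
            elif method == "mean":
                imputed = impute_mean(ds)
            elif method == "em":
                imputed = impute_em(ds)
            elif method == "mice":
                imputed = impute_mice(ds, seed=seed)
            elif method == "missforest":
                imputed = impute_missforest(ds, seed=seed)
            elif method == "proposed":
                from .pipeline import impute_with_mopso
                imputed = impute_with_mopso(ds, seed=seed, **(proposed_options or {})).imputed
            else:
                raise ConfigurationError(f"unknown method {method!r}")
            if imputed.n_records < min_records:
                raise DegenerateInputError(
                    f"{imputed.n_records} records left, need >= {min_records} for {protocol}"
                )
            rows[method] = _evaluate_imputed(imputed, protocol, n_runs, classifier, seed)
        except (DataError, DegenerateInputError) as exc:
            logger.warning("method %r not evaluable: %s", method, exc)
            rows[method] = None
            notes[method] = str(exc)
    return BenchmarkReport(rows=rows, protocol=protocol, n_runs=n_runs,
                           dataset_tag=dataset_tag, notes=notes)
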