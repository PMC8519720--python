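"""Missingness mechanisms: detection, resolution policy and simulation.

Covers four pieces of the pipeline front end:

* **Little's MCAR test** — a chi-square test comparing pattern-wise means of
  the continuous block against EM-estimated grand means.  Rejection argues
  against the missing-completely-at-random hypothesis.
* **Mechanism resolution** — MCAR when the test fails to reject; otherwise a
  user-declared mechanism when available; otherwise MNAR (the conservative
  default for clinical data).
* **Amputation** — mechanism-faithful deletion of cells from a fully
  observed block, hitting each requested per-variable fraction exactly.
* **MICE bootstrap** — when fewer than half of the records are fully
  observed, the least-incomplete records are completed by chained-equation
  imputation and promoted into the observational block.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._em import em_mvnorm
from .data import Dataset, chain_order, encode_column, missing_fraction, split_observational
from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

MECHANISMS = ("MCAR", "MAR", "MNAR")


@dataclass
class LittleTestResult:
    """Little's MCAR chi-square test outcome.

    ``applicable`` is False when the test is vacuous (a single missingness
    pattern, or fewer than two continuous variables); such data are treated
    as MCAR-consistent.
    """

    statistic: float
    df: int
    p_value: float
    n_patterns: int
    applicable: bool = True


@dataclass
class MissingnessProfile:
    """Resolved missingness description used to drive amputation."""

    per_var_fraction: dict[str, float]
    patterns: list[tuple[tuple[bool, ...], int]]
    mechanism: str
    mar_driver: dict[str, str] | None = None
    mnar_tail: str = "upper"

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ConfigurationError(f"unknown mechanism {self.mechanism!r}")
        if any(not (0 <= f <= 1) for f in self.per_var_fraction.values()):
            raise ConfigurationError("missing fractions must lie in [0, 1]")
        if (self.mechanism == "MAR") != (self.mar_driver is not None):
            raise ConfigurationError("mar_driver must be given exactly when mechanism is MAR")
        if self.mnar_tail not in ("upper", "lower", "both"):
            raise ConfigurationError(f"unknown mnar_tail {self.mnar_tail!r}")


def missingness_patterns(ds: Dataset) -> list[tuple[tuple[bool, ...], int]]:
    """Distinct rows of the missingness indicator R (True = missing) with counts."""
    R = ~ds.mask.to_numpy()
    counts: dict[tuple, int] = {}
    for row in R:
        key = tuple(row.tolist())
        counts[key] = counts.get(key, 0) + 1
    return sorted(counts.items())


# -- Little's MCAR test --------------------------------------------------------


def _little_statistic(X: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> tuple[float, int, int]:
    """Pattern-sum statistic d2 = sum_j k_j (ybar_j - mu_[j])' Sigma_[j]^-1 (ybar_j - mu_[j]).

    Returns (statistic, df, n_patterns) where df = (sum_j p_j) - p over
    patterns with at least one observed variable.
    """
    observed = ~np.isnan(X)
    p = X.shape[1]
    groups: dict[tuple, list[int]] = {}
    for i, row in enumerate(observed):
        groups.setdefault(tuple(row.tolist()), []).append(i)
    stat = 0.0
    sum_pj = 0
    n_patterns = 0
    for pat, idx in groups.items():
        o = np.asarray(pat, dtype=bool)
        if not o.any():
            continue
        n_patterns += 1
        sum_pj += int(o.sum())
        ybar = X[np.ix_(idx, np.flatnonzero(o))].mean(axis=0)
        diff = ybar - mu[o]
        s_oo = sigma[np.ix_(o, o)]
        try:
            sol = np.linalg.solve(s_oo, diff)
        except np.linalg.LinAlgError:
            raise DataError(
                "singular restricted covariance in Little's test; drop collinear columns"
            ) from None
        stat += len(idx) * float(diff @ sol)
    return stat, sum_pj - p, n_patterns


def little_mcar_test(ds: Dataset, tol: float = 1e-6, max_iter: int = 500) -> LittleTestResult:
    """Little's MCAR test on the dataset's continuous block.

    Discrete variables are excluded: the test's multivariate-normal EM
    estimates are undefined for nominal data.  With a single missingness
    pattern (e.g. fully observed data) the test is vacuous and a
    not-applicable result with p = 1 is returned.
    """
    cont = [v.name for v in ds.independents if v.vtype == "continuous"]
    if len(cont) < 2:
        return LittleTestResult(0.0, 0, 1.0, 1, applicable=False)
    X = np.column_stack([encode_column(ds, c) for c in cont])
    patterns = {tuple(row.tolist()) for row in ~np.isnan(X)}
    if len(patterns) < 2:
        return LittleTestResult(0.0, 0, 1.0, len(patterns), applicable=False)
    est = em_mvnorm(X, tol=tol, max_iter=max_iter)
    stat, df, n_patterns = _little_statistic(X, est.mean, est.cov)
    if df <= 0:
        return LittleTestResult(stat, df, 1.0, n_patterns, applicable=False)
    p_value = float(stats.chi2.sf(stat, df))
    return LittleTestResult(float(stat), int(df), p_value, n_patterns)


# -- mechanism resolution ------------------------------------------------------


def resolve_mechanism(
    ds: Dataset,
    test: LittleTestResult,
    declared: str | None = None,
    mar_driver: dict[str, str] | None = None,
    alpha: float = 0.05,
    mnar_tail: str = "upper",
) -> MissingnessProfile:
    """Decide the working mechanism and collect the missingness profile.

    MCAR when the test fails to reject at ``alpha`` (or is not applicable);
    otherwise the declared mechanism when one is supplied; otherwise MNAR.
    """
    if not (0 < alpha < 1):
        raise ConfigurationError("alpha must lie in (0, 1)")
    if declared is not None:
        declared = declared.upper()
        if declared not in MECHANISMS:
            raise ConfigurationError(f"unknown declared mechanism {declared!r}")
        if declared == "MAR" and not mar_driver:
            raise ConfigurationError("declared MAR requires a mar_driver map")
    fractions = {
        name: missing_fraction(ds, name)
        for name in chain_order(ds)
    }
    if (not test.applicable) or test.p_value >= alpha:
        mech = "MCAR"
    elif declared is not None:
        mech = declared
    else:
        mech = "MNAR"
    return MissingnessProfile(
        per_var_fraction=fractions,
        patterns=missingness_patterns(ds),
        mechanism=mech,
        mar_driver=mar_driver if mech == "MAR" else None,
        mnar_tail=mnar_tail,
    )


# -- amputation ----------------------------------------------------------------


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def ampute(ds: Dataset, profile: MissingnessProfile, seed: int) -> Dataset:
    """Delete cells from a fully observed block under ``profile``.

    For each profiled variable exactly ``round(fraction * n)`` cells are
    masked: uniformly at random (MCAR), with logistic weights on the
    standardized driver covariate (MAR), or at the most extreme values of
    the variable itself (MNAR; tail configurable).  Deterministic under a
    fixed seed; the dependent variable is never touched.
    """
    rng = np.random.default_rng(seed)
    out = ds.copy()
    dep = ds.dependent.name
    n = ds.n_records
    for name, frac in profile.per_var_fraction.items():
        if frac > 1:
            raise ConfigurationError(f"fraction {frac} > 1 for {name!r}")
        if ds.var(name).role == "dependent" or name == dep:
            raise ConfigurationError("amputation must not target the dependent variable")
        m = _round_half_up(frac * n)
        if m == 0:
            continue
        observed_rows = np.flatnonzero(out.mask[name].to_numpy())
        if m > len(observed_rows):
            raise ConfigurationError(f"cannot mask {m} cells in {name!r}: only {len(observed_rows)} observed")
        if profile.mechanism == "MCAR":
            hit = rng.choice(observed_rows, size=m, replace=False)
        elif profile.mechanism == "MAR":
            driver = (profile.mar_driver or {}).get(name)
            if driver is None:
                raise ConfigurationError(f"no MAR driver configured for {name!r}")
            if driver not in ds.var_names:
                raise ConfigurationError(f"MAR driver {driver!r} is not a dataset variable")
            dvals = encode_column(ds, driver)[observed_rows]
            if np.isnan(dvals).any():
                raise ConfigurationError(f"MAR driver {driver!r} has missing cells")
            sd = dvals.std()
            z = (dvals - dvals.mean()) / (sd if sd > 0 else 1.0)
            w = 1.0 / (1.0 + np.exp(-z))
            hit = rng.choice(observed_rows, size=m, replace=False, p=w / w.sum())
        else:  # MNAR: extreme values of the variable itself
            vals = encode_column(ds, name)[observed_rows]
            order = np.argsort(vals, kind="stable")
            if profile.mnar_tail == "upper":
                pick = order[-m:]
            elif profile.mnar_tail == "lower":
                pick = order[:m]
            else:
                lo = m // 2
                pick = np.concatenate([order[:lo], order[-(m - lo):]])
            hit = observed_rows[pick]
        out.mask.loc[hit, name] = False
        out.values.loc[hit, name] = np.nan
    return Dataset(out.values, out.mask, out.schema)


# -- MICE bootstrap of the observational block ---------------------------------


def mice_bootstrap(
    ds: Dataset,
    target_fraction: float = 0.5,
    seed: int = 0,
    n_iterations: int = 10,
) -> Dataset:
    """Promote just enough records into the observational block.

    When fewer than ``target_fraction`` of records are fully observed, the
    incomplete records with the fewest missing cells are completed by
    chained-equation imputation and marked observed; everything else is
    untouched.  A no-op when the observational fraction already meets the
    target.
    """
    from .baselines import impute_mice  # local import: baselines builds on data only

    complete = ds.complete_row_mask()
    n = ds.n_records
    n_complete = int(complete.sum())
    need = math.ceil(target_fraction * n) - n_complete
    if need <= 0:
        return ds
    miss_counts = (~ds.mask.to_numpy()).sum(axis=1)
    candidates = [i for i in np.argsort(miss_counts, kind="stable") if not complete[i]]
    promote = candidates[:need]
    logger.info("MICE bootstrap: promoting %d of %d incomplete records", len(promote), n - n_complete)
    filled = impute_mice(ds, n_iterations=n_iterations, seed=seed)
    out = ds.copy()
    for i in promote:
        for name in ds.var_names:
            if not out.mask.at[i, name]:
                out.values.at[i, name] = filled.values.at[i, name]
                out.mask.at[i, name] = True
    return Dataset(out.values, out.mask, out.schema)
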