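"""End-to-end orchestration: from an incomplete table to an imputed one.

The stages, in order: exclude records missing the dependent variable; drop
independent variables above the missingness threshold; split into
observational (fully observed) and incomplete records, topping the
observational block up by chained-equation imputation when it holds less
than half the data; resolve the missing-data mechanism (Little's MCAR
test, user declaration, MNAR default); run the multiobjective swarm over
per-variable algorithm assignments, scoring each candidate by how little
simulated amputation + imputation disturbs classification; re-score the
Pareto front for accuracy and select; finally run the selected chain on
the real missing cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .data import (ChainOrder, Dataset, chain_order, drop_high_missing,
                   drop_missing_dependent, split_observational)
from .errors import DataError
from .fitness import FitnessEvaluator
from .mechanism import (LittleTestResult, MissingnessProfile, little_mcar_test,
                        mice_bootstrap, resolve_mechanism)
from .mopso import MopsoResult, SwarmConfig, final_select, optimize
from .pool import AlgorithmSpec, ChainAssignment, get_spec, impute_chain

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    imputed: Dataset
    assignment: ChainAssignment | None
    profile: MissingnessProfile | None
    little: LittleTestResult | None
    mopso: MopsoResult | None
    selected_accuracy: float | None
    order: ChainOrder


def impute_with_mopso(
    ds: Dataset,
    drop_threshold: float = 0.5,
    declared_mechanism: str | None = None,
    mar_driver: dict[str, str] | None = None,
    alpha: float = 0.05,
    mnar_tail: str = "upper",
    swarm: SwarmConfig | None = None,
    classifier: AlgorithmSpec | None = None,
    n_repeats: int = 100,
    observational_target: float = 0.5,
    seed: int = 0,
) -> PipelineResult:
    """Run the full selection-and-imputation pipeline on ``ds``.

    Every stochastic stage derives its stream from ``seed``, so a fixed
    seed reproduces the assignment and the imputed table exactly.
    """
    ds = drop_missing_dependent(ds)
    if ds.n_records == 0:
        raise DataError("no records with an observed dependent value")
    ds = drop_high_missing(ds, drop_threshold)
    order = chain_order(ds)
    if len(order) == 0:
        logger.info("no missing data in independent variables: imputation is a no-op")
        return PipelineResult(ds.copy(), None, None, None, None, None, order)

    observational, _ = split_observational(ds)
    if observational.n_records < observational_target * ds.n_records:
        logger.info("observational block %.0f%% < target %.0f%%: MICE bootstrap",
                    100 * observational.n_records / ds.n_records,
                    100 * observational_target)
        ds = mice_bootstrap(ds, target_fraction=observational_target, seed=seed)
        observational, _ = split_observational(ds)

    little = little_mcar_test(ds)
    profile = resolve_mechanism(ds, little, declared=declared_mechanism,
                                mar_driver=mar_driver, alpha=alpha, mnar_tail=mnar_tail)
    logger.info("resolved mechanism: %s (Little p=%.4g, %d patterns)",
                profile.mechanism, little.p_value, little.n_patterns)

    swarm = swarm or SwarmConfig(seed=seed)
    evaluator = FitnessEvaluator(
        observational, profile, order=order, classifier=classifier,
        n_repeats=n_repeats, seed=seed,
    )
    result = optimize(evaluator, order, ds.schema, swarm)
    assignment, accuracy = final_select(result.archive, evaluator.accuracy,
                                        order, ds.schema, seed=seed)
    logger.info("selected assignment %s (re-scored accuracy %.2f%%)",
                assignment.index_tuple(), accuracy)
    imputed = impute_chain(ds, assignment, seed=seed)
    return PipelineResult(imputed, assignment, profile, little, result, accuracy, order)
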