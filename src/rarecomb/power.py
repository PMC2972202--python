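"""Replicate-level type-I error and power study driver.

Per-gene haplotype pools, hundreds of simulated case-control (or
quantitative-trait) replicates each analyzed with a permutation test, and
power averaged over pools at a fixed significance level, all at a
configurable scale. The full-scale profile is 13 pools x 500
simulations x 500 permutations; the default desk-scale profile is 3 pools x
200 simulations x 199 permutations (with B chosen so (B+1) * alpha is an
integer and p = alpha is exactly attainable under the add-one estimator).

Per-replicate seeds are spawned from the master seed through
``numpy.random.SeedSequence`` counters, so any single replicate can be
re-run in isolation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

from .association import (
    AssociationTest,
    CastTest,
    CmcTest,
    CombinedTest,
    ModelSetTest,
    StepUpTest,
)
from .core_data import PhenotypeVector
from .permutation import PermutationConfig, permutation_pvalue
from .simulate import (
    DiseaseModel,
    HaplotypePool,
    ScenarioConfig,
    calibrate_intercept,
    sample_case_control,
    sample_quantitative,
    scenario_betas,
)

logger = logging.getLogger(__name__)

__all__ = ["PowerResult", "run_power_study", "make_test"]


@dataclass
class PowerResult:
    """Empirical rejection rate of one method under one scenario."""

    method: str
    scenario: int
    effect: float
    n_replicates: int
    rejections: int
    power: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_counts(
        cls, method: str, scenario: int, effect: float, rejections: int, n: int
    ) -> "PowerResult":
        ci = binomtest(rejections, n).proportion_ci(0.95, method="exact")
        return cls(
            method=method,
            scenario=scenario,
            effect=effect,
            n_replicates=n,
            rejections=rejections,
            power=rejections / n,
            ci_low=float(ci.low),
            ci_high=float(ci.high),
        )


def make_test(
    name: str,
    *,
    cutoff: float = 0.01,
    weights: str = "constant",
    signed: bool = False,
    groups: list[str] | None = None,
    annotations=None,
) -> AssociationTest:
    """Build a named association test from configuration keys.

    Names: "cast", "fixed" (threshold burden with configurable weights and
    sign), "all-maf", "functional", "step", "cmc".
    """
    signs = "signed" if signed else "unsigned"
    if name == "cast":
        return CastTest(cutoff)
    if name == "fixed":
        return ModelSetTest(weights=weights, signs=signs, inclusion=cutoff)
    if name == "all-maf":
        return ModelSetTest(weights=weights, signs=signs, inclusion="all_maf")
    if name == "functional":
        return ModelSetTest(
            weights=weights,
            signs=signs,
            inclusion="functional",
            annotations=annotations,
            groups=groups or ["nonsynonymous"],
        )
    if name == "step":
        w_model = "maf_weighted" if weights == "maf_weighted" else "constant"
        return StepUpTest(w_model=w_model, s_model=signs)
    if name == "cmc":
        return CmcTest(cutoff)
    raise ValueError(f"unknown test name {name!r}")


def _simulate_replicate(
    pool: HaplotypePool,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    beta0_cache: dict,
):
    beta = scenario_betas(pool, cfg, rng)
    if cfg.trait == "dichotomous":
        key = (id(pool), beta.tobytes())
        if key not in beta0_cache:
            beta0_cache[key] = calibrate_intercept(pool, beta, cfg.prevalence)
        model = DiseaseModel(
            beta=beta,
            beta0=beta0_cache[key],
            link="logit",
            prevalence_target=cfg.prevalence,
        )
        return sample_case_control(
            pool, model, cfg.n_cases, cfg.n_controls, seed=rng
        )
    return sample_quantitative(pool, beta, cfg.n_quantitative, seed=rng)


def run_power_study(
    pools: list[HaplotypePool],
    scenarios: list[ScenarioConfig],
    methods: dict[str, AssociationTest],
    n_sims: int = 200,
    B: int = 199,
    alpha: float = 0.05,
    seed: int | None = None,
    adaptive: bool = False,
) -> list[PowerResult]:
    """Empirical power of each method under each scenario, averaged over pools.

    For every (pool, scenario) pair, ``n_sims`` independent datasets are
    simulated and every method is applied to each dataset; permutation tests
    use B permutations (rejection iff p <= alpha), the asymptotic CMC
    comparator uses its chi-squared p-value directly. Counts are pooled
    across haplotype pools, the analogue of averaging power over genes.
    Method/trait incompatibilities (CMC on a continuous trait) are skipped
    with a warning. Fully reproducible under the master seed.
    """
    if n_sims < 1 or B < 1 or not (0.0 < alpha <= 1.0):
        raise ValueError("need n_sims >= 1, B >= 1, alpha in (0, 1]")
    root = np.random.SeedSequence(seed)
    results: list[PowerResult] = []
    for cfg in scenarios:
        counts: dict[str, int] = {}
        totals: dict[str, int] = {}
        skipped = set()
        beta0_cache: dict = {}
        for pool_idx, pool in enumerate(pools):
            # a callable lets annotation-bound methods rebind per pool
            pool_methods = methods(pool) if callable(methods) else methods
            for name in pool_methods:
                counts.setdefault(name, 0)
                totals.setdefault(name, 0)
            for sim in range(n_sims):
                ss = np.random.SeedSequence(
                    entropy=root.entropy,
                    spawn_key=(cfg.scenario, pool_idx, sim),
                )
                child = ss.generate_state(2)
                rng = np.random.default_rng(ss)
                G, Y = _simulate_replicate(pool, cfg, rng, beta0_cache)
                for name, test in pool_methods.items():
                    if test.asymptotic and not Y.is_dichotomous:
                        if name not in skipped:
                            logger.warning(
                                "%s incompatible with continuous trait; "
                                "skipping",
                                name,
                            )
                            skipped.add(name)
                        continue
                    if test.asymptotic:
                        res = test.statistic(G, Y)
                        pval = res.p_value
                        if pval is None or math.isnan(pval):
                            continue  # non-converged fit, excluded
                    else:
                        pcfg = PermutationConfig(
                            B=B,
                            seed=int(child[0] % (2**31)),
                            adaptive=adaptive,
                        )
                        pval = permutation_pvalue(test, G, Y, pcfg).p_value
                    totals[name] += 1
                    if pval <= alpha:
                        counts[name] += 1
            logger.info(
                "scenario %d pool %d/%d done", cfg.scenario, pool_idx + 1,
                len(pools),
            )
        for name in totals:
            if totals[name] == 0:
                continue
            results.append(
                PowerResult.from_counts(
                    name, cfg.scenario, cfg.effect, counts[name], totals[name]
                )
            )
    return results


def results_to_tsv(results: list[PowerResult], path) -> None:
    import pandas as pd

    pd.DataFrame([r.__dict__ for r in results]).to_csv(
        path, sep="\t", index=False
    )
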