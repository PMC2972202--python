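"""Haplotype-pool population model and disease/trait simulation.

No suitable public deep-resequencing dataset exists for exercising these
tests (the motivating setting is candidate-gene panels such as the coding
regions of one-carbon folate pathway genes sequenced in a few hundred
individuals), so this module provides a synthetic stand-in: a
:class:`HaplotypePool` of binary haplotypes with random simplex frequencies
whose variant frequency spectrum is heavily rare (by default ~85% of
variants below MAF 0.01, typical of deep resequencing), three partially
concordant functional-call algorithms (default pairwise agreement 0.6),
and a continuous deleteriousness score in [0, 1] with 0 most deleterious,
in the style of the SIFT tolerance index.

Individuals are formed by drawing two haplotypes independently from the pool
(Hardy-Weinberg random mating). Disease status follows a logistic model
logit P(D=1|G) = beta0 + sum_j beta_j G_j whose intercept is calibrated so
the population prevalence hits a target (0.01 by default); quantitative
traits are Normal(G beta, 1). Five generative scenarios map an effect size
onto per-variant beta:

1. constant log-odds for every rare functional variant below a cutoff;
2. as 1 but with the cutoff redrawn per replicate from the observed MAFs
   below 0.05 (unknown causal frequency);
3. effect proportional to predicted deleteriousness, beta_j =
   log(OR) (1 - score_j), capped so no variant contributes more than the
   odds ratio;
4. rare and common functional variants with a lambda-controlled decay
   (lambda small => only the rarest variants matter);
5. a random split of rare functional variants into deleterious (+log OR)
   and protective (-log OR) sets by total allele frequency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .core_data import (
    ALGORITHMS,
    GenotypeMatrix,
    PhenotypeVector,
    VariantAnnotation,
)
from .weights import functional_group_mask

__all__ = [
    "HaplotypePool",
    "DiseaseModel",
    "ScenarioConfig",
    "generate_haplotype_pool",
    "scenario_betas",
    "calibrate_intercept",
    "sample_case_control",
    "sample_quantitative",
]

#: Score below which an algorithm's latent truth calls a variant deleterious
#: (the conventional SIFT intolerance cutoff).
DELETERIOUS_SCORE_CUTOFF = 0.05


@dataclass(eq=False)
class HaplotypePool:
    """A population of haplotypes with frequencies and variant annotations."""

    haplotypes: np.ndarray  # (H, p) 0/1 minor-allele indicators
    frequencies: np.ndarray  # (H,) sums to 1
    annotations: list[VariantAnnotation]
    variant_ids: list[str]

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be an (H, p) matrix")
        if self.frequencies.shape != (self.haplotypes.shape[0],):
            raise ValueError("one frequency per haplotype required")
        if np.any(self.frequencies < 0) or abs(self.frequencies.sum() - 1) > 1e-12:
            raise ValueError("frequencies must be >= 0 and sum to 1")
        if len(self.annotations) != self.haplotypes.shape[1]:
            raise ValueError("one annotation per variant required")
        if np.any(self.pop_maf > 0.5 + 1e-12):
            raise ValueError("pool MAFs must be <= 0.5")

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def pop_maf(self) -> np.ndarray:
        """Population minor-allele frequency implied by the pool."""
        return self.frequencies @ self.haplotypes

    def sample_genotypes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n individuals as sums of two independent haplotypes."""
        idx = rng.choice(self.n_haplotypes, size=(n, 2), p=self.frequencies)
        return (
            self.haplotypes[idx[:, 0]] + self.haplotypes[idx[:, 1]]
        ).astype(np.int8)

    def to_json(self, path) -> None:
        payload = {
            "variant_ids": self.variant_ids,
            "haplotypes": self.haplotypes.tolist(),
            "frequencies": self.frequencies.tolist(),
            "annotations": [
                {
                    "variant_id": a.variant_id,
                    "calls": a.calls,
                    "score": a.score,
                }
                for a in self.annotations
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "HaplotypePool":
        with open(path) as fh:
            payload = json.load(fh)
        annotations = [
            VariantAnnotation(
                variant_id=a["variant_id"], calls=a["calls"], score=a["score"]
            )
            for a in payload["annotations"]
        ]
        return cls(
            haplotypes=np.array(payload["haplotypes"], dtype=np.int8),
            frequencies=np.array(payload["frequencies"]),
            annotations=annotations,
            variant_ids=list(payload["variant_ids"]),
        )


@dataclass
class DiseaseModel:
    """First-stage trait model: link(E[Y|G]) = beta0 + sum_j beta_j G_j."""

    beta: np.ndarray
    beta0: float = 0.0
    link: str = "logit"  # "logit" (dichotomous) | "identity" (continuous)
    prevalence_target: float | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=np.float64)
        if self.link not in ("logit", "identity"):
            raise ValueError("link must be 'logit' or 'identity'")


@dataclass
class ScenarioConfig:
    """Configuration of one generative scenario.

    ``effect`` is an odds ratio (>= 1) for dichotomous traits or a mean
    difference per dosage for continuous traits. ``functional_group`` names
    which annotation set defines "functional"; by default the generating
    algorithm's deleterious calls (algoA, playing a SIFT-like role), except
    scenario 3 which spreads the effect over all scored (nonsynonymous)
    variants, and scenario 4 where a second algorithm (algoB, PMUT-like)
    is used to enlarge the common-variant set.
    """

    scenario: int
    effect: float = 2.0
    cutoff: float = 0.01
    lam: float = 0.01  # scenario 4 rare-vs-common decay
    deleterious_fraction: float = 0.5  # scenario 5 split
    trait: str = "dichotomous"
    n_cases: int = 1000
    n_controls: int = 1000
    n_quantitative: int = 2000
    prevalence: float = 0.01
    functional_group: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2, 3, 4, 5):
            raise ValueError("scenario must be 1..5")
        if self.trait == "dichotomous" and self.effect < 1.0:
            raise ValueError("odds ratio must be >= 1")
        if not (0.0 < self.cutoff <= 0.5):
            raise ValueError("cutoff must lie in (0, 0.5]")
        if not (0.0 <= self.deleterious_fraction <= 1.0):
            raise ValueError("deleterious_fraction must lie in [0, 1]")
        if self.functional_group is None:
            self.functional_group = {
                3: "nonsynonymous",
                4: "algoB_deleterious",
            }.get(self.scenario, "algoA_deleterious")

    @property
    def log_effect(self) -> float:
        return float(np.log(self.effect)) if self.trait == "dichotomous" else float(self.effect)


# ---------------------------------------------------------------------------
# pool generation
# ---------------------------------------------------------------------------


def _agreement_accuracy(concordance: float) -> float:
    """Observer accuracy a with pairwise agreement a^2 + (1-a)^2 = concordance."""
    if not (0.5 <= concordance <= 1.0):
        raise ValueError(
            "pairwise concordance must lie in [0.5, 1] for conditionally "
            "independent annotation algorithms"
        )
    return 0.5 * (1.0 + np.sqrt(2.0 * concordance - 1.0))


def generate_haplotype_pool(
    p: int = 48,
    H: int = 256,
    spectrum: str = "rare_heavy",
    concordance: float = 0.6,
    nonsynonymous_fraction: float = 0.30,
    deleterious_truth_rate: float = 0.40,
    rare_fraction: float = 0.85,
    seed: int | np.random.Generator | None = None,
) -> HaplotypePool:
    """Generate a synthetic haplotype pool with a rare-heavy spectrum.

    Target MAFs are drawn log-uniformly, ``rare_fraction`` of them below
    0.01 and the remainder between 0.01 and 0.35. Haplotype frequencies come
    from a symmetric Dirichlet(1) simplex draw; each variant is placed on a
    random haplotype subset whose total frequency approaches (never exceeds)
    its target, so the realized spectrum stays rare-heavy. Nonsynonymous
    variants receive a deleteriousness score (mixture: deleterious scores
    uniform on [0, 0.05), tolerated uniform on [0.05, 1]) and three noisy
    binary calls of the latent score-derived truth, tuned so every pair of
    algorithms agrees with probability ``concordance``. Deterministic under
    seed.
    """
    if spectrum != "rare_heavy":
        raise ValueError(f"unknown spectrum {spectrum!r}")
    if p < 1 or H < 4:
        raise ValueError("need p >= 1 variants and H >= 4 haplotypes")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    freqs = rng.dirichlet(np.ones(H))
    is_rare = rng.random(p) < rare_fraction
    target = np.where(
        is_rare,
        np.exp(rng.uniform(np.log(2e-4), np.log(0.01), size=p)),
        np.exp(rng.uniform(np.log(0.01), np.log(0.35), size=p)),
    )

    hap = np.zeros((H, p), dtype=np.int8)
    order_min = int(np.argmin(freqs))
    for j in range(p):
        perm = rng.permutation(H)
        cum = 0.0
        carriers = []
        for h in perm:
            if cum + freqs[h] <= target[j]:
                carriers.append(h)
                cum += freqs[h]
        if not carriers:
            carriers = [order_min]  # force at least one carrier haplotype
        hap[carriers, j] = 1

    nonsyn = rng.random(p) < nonsynonymous_fraction
    accuracy = _agreement_accuracy(concordance)
    annotations: list[VariantAnnotation] = []
    variant_ids = [f"v{j + 1}" for j in range(p)]
    for j in range(p):
        if not nonsyn[j]:
            annotations.append(
                VariantAnnotation(
                    variant_id=variant_ids[j],
                    calls={a: "synonymous" for a in ALGORITHMS},
                    score=None,
                )
            )
            continue
        if rng.random() < deleterious_truth_rate:
            score = rng.uniform(0.0, DELETERIOUS_SCORE_CUTOFF)
        else:
            score = rng.uniform(DELETERIOUS_SCORE_CUTOFF, 1.0)
        truth = score < DELETERIOUS_SCORE_CUTOFF
        calls = {}
        for a in ALGORITHMS:
            agrees = rng.random() < accuracy
            deleterious = truth if agrees else not truth
            calls[a] = "deleterious" if deleterious else "tolerated"
        annotations.append(
            VariantAnnotation(
                variant_id=variant_ids[j], calls=calls, score=float(score)
            )
        )

    return HaplotypePool(
        haplotypes=hap,
        frequencies=freqs,
        annotations=annotations,
        variant_ids=variant_ids,
    )


# ---------------------------------------------------------------------------
# scenario effect vectors
# ---------------------------------------------------------------------------


def scenario_betas(
    pool: HaplotypePool,
    cfg: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-variant effect vector for one replicate of the given scenario.

    Scenarios 2 and 5 involve per-replicate randomness (the drawn cutoff and
    the deleterious/protective split); pass the replicate's generator for
    reproducibility. Every |beta_j| is capped at the log effect so no single
    allele contributes more than the nominal odds ratio / mean difference.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    maf = pool.pop_maf
    functional = functional_group_mask(pool.annotations, cfg.functional_group)
    if not functional.any():
        raise ValueError(
            f"pool has no variants in group {cfg.functional_group!r}"
        )
    b = cfg.log_effect
    beta = np.zeros(pool.n_variants)

    if cfg.scenario in (1, 2):
        cutoff = cfg.cutoff
        if cfg.scenario == 2:
            candidates = np.unique(maf[(maf > 0) & (maf < 0.05)])
            if candidates.size == 0:
                raise ValueError("no observed MAFs below 0.05 to draw from")
            cutoff = float(rng.choice(candidates))
        beta[functional & (maf > 0) & (maf <= cutoff)] = b
    elif cfg.scenario == 3:
        scores = np.array(
            [a.score if a.score is not None else 1.0 for a in pool.annotations]
        )
        beta[functional] = b * (1.0 - scores[functional])
    elif cfg.scenario == 4:
        active = functional & (maf > 0)
        if not active.any():
            raise ValueError("no polymorphic functional variants")
        lam = cfg.lam
        maf_min = maf[active].min()
        decay = (lam + maf_min) / (lam + maf[active])
        beta[active] = b * decay
    elif cfg.scenario == 5:
        rare = functional & (maf > 0) & (maf <= cfg.cutoff)
        idx = np.where(rare)[0]
        if idx.size == 0:
            raise ValueError("no rare functional variants for scenario 5")
        total = maf[idx].sum()
        target = cfg.deleterious_fraction * total
        order = rng.permutation(idx)
        cum = 0.0
        deleterious = np.zeros(pool.n_variants, dtype=bool)
        for j in order:
            if cum < target:
                deleterious[j] = True
                cum += maf[j]
        if cfg.deleterious_fraction >= 1.0:
            deleterious[idx] = True
        beta[idx] = np.where(deleterious[idx], b, -b)

    np.clip(beta, -abs(b), abs(b), out=beta)
    return beta


# ---------------------------------------------------------------------------
# prevalence calibration and sampling
# ---------------------------------------------------------------------------

_MAX_EXACT_PAIRS = 1_000_000


def calibrate_intercept(
    pool: HaplotypePool,
    beta: np.ndarray,
    K: float,
    rng: np.random.Generator | None = None,
    mc_samples: int = 200_000,
) -> float:
    """Solve for beta0 so the population prevalence under the logistic model
    equals K.

    When the number of haplotype pairs H^2 is enumerable the expectation
    E[expit(beta0 + G beta)] is computed exactly over the Hardy-Weinberg
    pair distribution and the unique root found by bracketing; otherwise a
    fixed Monte-Carlo genotype sample stands in for the expectation.
    """
    if not (0.0 < K < 1.0):
        raise ValueError("prevalence must lie in (0, 1)")
    beta = np.asarray(beta, dtype=float)
    x = pool.haplotypes.astype(float) @ beta  # per-haplotype dose
    if pool.n_haplotypes**2 <= _MAX_EXACT_PAIRS:
        pair_dose = x[:, None] + x[None, :]
        pair_w = pool.frequencies[:, None] * pool.frequencies[None, :]

        def prevalence(b0: float) -> float:
            return float(np.sum(pair_w * expit(b0 + pair_dose))) - K

    else:
        rng = rng if rng is not None else np.random.default_rng(0)
        dose = pool.sample_genotypes(mc_samples, rng).astype(float) @ beta

        def prevalence(b0: float) -> float:
            return float(np.mean(expit(b0 + dose))) - K

    lo, hi = float(logit(K)) - abs(beta).sum() * 2 - 50.0, float(logit(K)) + 50.0
    if prevalence(lo) > 0 or prevalence(hi) < 0:
        raise ValueError("target prevalence not achievable for this model")
    return float(brentq(prevalence, lo, hi, xtol=1e-12))


def sample_case_control(
    pool: HaplotypePool,
    model: DiseaseModel,
    n_cases: int,
    n_controls: int,
    seed: int | np.random.Generator | None = None,
    max_draws: int = 50_000_000,
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Rejection-sample a case-control study from the calibrated model.

    Each individual is two independent haplotype draws; disease status is
    Bernoulli(expit(beta0 + G beta)); sampling continues until both strata
    are filled. When beta is identically zero the disease is independent of
    the genotype, so cases and controls share the population genotype
    distribution exactly and are drawn directly without rejection.
    Phenotype order is cases first, then controls.
    """
    if model.link != "logit":
        raise ValueError("case-control sampling requires the logit link")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    p = pool.n_variants
    if not np.any(model.beta):
        dos = pool.sample_genotypes(n_cases + n_controls, rng)
        y = np.concatenate([np.ones(n_cases), np.zeros(n_controls)])
        return (
            GenotypeMatrix.from_dosages(dos, pool.variant_ids),
            PhenotypeVector(values=y, trait_type="dichotomous"),
        )

    K = (
        model.prevalence_target
        if model.prevalence_target is not None
        else float(expit(model.beta0))
    )
    need_cases, need_controls = n_cases, n_controls
    got_cases: list[np.ndarray] = []
    got_controls: list[np.ndarray] = []
    drawn = 0
    while need_cases > 0 or need_controls > 0:
        batch = int(
            min(
                max(
                    need_cases / max(K, 1e-6),
                    need_controls / max(1.0 - K, 1e-6),
                )
                * 1.3
                + 100,
                2_000_000,
            )
        )
        drawn += batch
        if drawn > max_draws:
            raise RuntimeError(
                "rejection-sampling budget exceeded; reduce the sample size "
                "or raise the target prevalence"
            )
        dos = pool.sample_genotypes(batch, rng)
        prob = expit(model.beta0 + dos.astype(float) @ model.beta)
        disease = rng.random(batch) < prob
        if need_cases > 0:
            take = dos[disease][:need_cases]
            got_cases.append(take)
            need_cases -= take.shape[0]
        if need_controls > 0:
            take = dos[~disease][:need_controls]
            got_controls.append(take)
            need_controls -= take.shape[0]
    dosages = np.vstack(got_cases + got_controls)
    y = np.concatenate([np.ones(n_cases), np.zeros(n_controls)])
    return (
        GenotypeMatrix.from_dosages(dosages, pool.variant_ids),
        PhenotypeVector(values=y, trait_type="dichotomous"),
    )


def sample_quantitative(
    pool: HaplotypePool,
    beta: np.ndarray,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Sample n individuals with Y ~ Normal(G beta, 1)."""
    if n < 2:
        raise ValueError("need at least two individuals")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    dos = pool.sample_genotypes(n, rng)
    y = dos.astype(float) @ np.asarray(beta, dtype=float) + rng.standard_normal(n)
    return (
        GenotypeMatrix.from_dosages(dos, pool.variant_ids),
        PhenotypeVector(values=y, trait_type="continuous"),
    )
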