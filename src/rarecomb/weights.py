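"""Variant weight models: continuous weight w, direction s, inclusion gamma.

Each aggregation model assigns every variant j a multiplicative coefficient
w_j * s_j * gamma_j: a strictly positive continuous weight (constant, or
Madsen-Browning inverse standard deviation under control-estimated allele
frequency), a direction in {+1, -1} (all-deleterious, or estimated from the
case/control frequency difference resp. the trait covariance), and a 0/1
inclusion indicator (hard MAF threshold, every observed MAF threshold, or
functional-annotation groups). A ModelSet is the indexed family of such
assignments that the association test maximizes over; the step-up search in
:mod:`rarecomb.association` plays the same role without enumerating a set.

Sign and Madsen-Browning weight depend on the phenotype, so they must be
re-estimated inside every permutation; model-set builders therefore separate
the phenotype-independent inclusion structure from the per-phenotype (w, s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_data import (
    ALGORITHMS,
    GenotypeMatrix,
    PhenotypeVector,
    VariantAnnotation,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "ModelSet",
    "FUNCTIONAL_GROUPS",
    "constant_weights",
    "madsen_browning_weights",
    "sign_variants",
    "maf_threshold_inclusion",
    "all_maf_model_set",
    "functional_model_set",
    "functional_group_mask",
    "build_model_set",
]

#: Names of the supported functional inclusion groups.
FUNCTIONAL_GROUPS = (
    "nonsynonymous",
    "algoA_deleterious",
    "algoB_deleterious",
    "algoC_deleterious",
)


@dataclass(eq=False)
class ModelSpec:
    """One concrete (w, s, gamma) assignment over p variants."""

    w: np.ndarray
    s: np.ndarray
    gamma: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        self.s = np.asarray(self.s, dtype=np.float64)
        self.gamma = np.asarray(self.gamma, dtype=np.float64)
        if not (self.w.shape == self.s.shape == self.gamma.shape):
            raise ValueError("w, s, gamma must have identical shape")
        if not np.all(np.isfinite(self.w)) or np.any(self.w <= 0):
            raise ValueError("weights must be finite and strictly positive")
        if not np.isin(self.s, (-1.0, 1.0)).all():
            raise ValueError("signs must be +1 or -1")
        if not np.isin(self.gamma, (0.0, 1.0)).all():
            raise ValueError("gamma must be 0 or 1")

    @property
    def coefficients(self) -> np.ndarray:
        """Per-variant multiplicative coefficient w_j * s_j * gamma_j."""
        return self.w * self.s * self.gamma

    @property
    def is_empty(self) -> bool:
        return not self.gamma.any()


@dataclass(eq=False)
class ModelSet:
    """An ordered family of ModelSpecs to maximize the score statistic over."""

    specs: list[ModelSpec]
    generator: str = "fixed"

    def __post_init__(self) -> None:
        if not self.specs:
            raise ValueError("a ModelSet must contain at least one model")
        labels = [m.label for m in self.specs]
        if len(set(labels)) != len(labels):
            raise ValueError("model labels must be unique within a set")

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)

    @classmethod
    def union(cls, *sets: "ModelSet") -> "ModelSet":
        """Concatenate several sets ("best of" across approaches)."""
        specs: list[ModelSpec] = []
        seen: set[str] = set()
        for s in sets:
            for m in s.specs:
                label = m.label
                while label in seen:
                    label += "'"
                seen.add(label)
                if label != m.label:
                    m = ModelSpec(m.w, m.s, m.gamma, label)
                specs.append(m)
        return cls(specs=specs, generator="union")


# ---------------------------------------------------------------------------
# w: continuous weights
# ---------------------------------------------------------------------------


def constant_weights(p: int) -> np.ndarray:
    """Unit weights: the aggregated score is the plain (signed) dosage sum."""
    if p < 1:
        raise ValueError("need at least one variant")
    return np.ones(p)


def madsen_browning_weights(
    G: GenotypeMatrix, Y: PhenotypeVector
) -> np.ndarray:
    """Inverse-standard-deviation weights from reference allele frequencies.

    For a dichotomous trait the allele frequency of variant j is estimated in
    the controls with pseudocounts, q_j = (m_j + 1) / (2 n_ref + 2) where m_j
    is the control minor-allele count; for a continuous trait all subjects
    serve as the reference. The weight is w_j = 1 / sqrt(n q_j (1 - q_j))
    with n the total sample size. The pseudocount keeps every weight finite
    even for variants unseen in the reference group.
    """
    n = G.n_individuals
    if Y.is_dichotomous:
        ref = ~Y.case_mask()
        n_ref = int(ref.sum())
        if n_ref == 0:
            raise ValueError("Madsen-Browning weights need at least 1 control")
        m = G.dosages[ref].sum(axis=0)
    else:
        n_ref = n
        m = G.dosages.sum(axis=0)
    q = (m + 1.0) / (2.0 * n_ref + 2.0)
    return 1.0 / np.sqrt(n * q * (1.0 - q))


# ---------------------------------------------------------------------------
# s: direction
# ---------------------------------------------------------------------------


def sign_variants(G: GenotypeMatrix, Y: PhenotypeVector) -> np.ndarray:
    """Estimate per-variant effect direction from the data.

    Dichotomous: +1 where the minor allele is more frequent in cases than in
    controls (putatively deleterious), -1 where less frequent (protective),
    +1 on an exact tie so the signed test reduces to the unsigned one when
    there is no information. Continuous: the sign of cov(Y, G_j), +1 at zero.
    """
    if Y.is_dichotomous:
        cases = Y.case_mask()
        f_case = G.dosages[cases].mean(axis=0)
        f_ctrl = G.dosages[~cases].mean(axis=0)
        return np.where(f_case >= f_ctrl, 1.0, -1.0)
    yc = Y.values - Y.values.mean()
    cov = yc @ G.centered_dosages()
    return np.where(cov >= 0, 1.0, -1.0)


# ---------------------------------------------------------------------------
# gamma: inclusion
# ---------------------------------------------------------------------------


def maf_threshold_inclusion(maf: np.ndarray, cutoff: float) -> np.ndarray:
    """Hard MAF threshold: gamma_j = 1 iff 0 < maf_j <= cutoff.

    Monomorphic variants are always excluded; the boundary is inclusive. An
    all-zero gamma is allowed (the downstream statistic is defined as 0).
    """
    maf = np.asarray(maf, dtype=float)
    if not (0.0 < cutoff <= 0.5):
        raise ValueError("cutoff must lie in (0, 0.5]")
    return ((maf > 0) & (maf <= cutoff)).astype(np.float64)


def all_maf_model_set(
    maf: np.ndarray, base: ModelSpec | None = None
) -> ModelSet:
    """One model per unique observed nonzero MAF, thresholds ascending.

    Testing every observed allele frequency is equivalent to running the hard
    threshold test at each element of the set of unique sample MAFs. ``base``
    supplies (w, s); defaults to constant unsigned.
    """
    maf = np.asarray(maf, dtype=float)
    thresholds = np.unique(maf[maf > 0])
    if thresholds.size == 0:
        raise ValueError("all-MAF set needs at least one polymorphic variant")
    p = maf.shape[0]
    w = base.w if base is not None else constant_weights(p)
    s = base.s if base is not None else np.ones(p)
    specs = [
        ModelSpec(w, s, maf_threshold_inclusion(maf, t), f"maf<={t:.8g}")
        for t in thresholds
    ]
    return ModelSet(specs=specs, generator="all_maf")


def functional_group_mask(
    annotations: list[VariantAnnotation], group: str
) -> np.ndarray:
    """Boolean membership of each variant in a functional group.

    "nonsynonymous" covers every protein-altering variant regardless of the
    deleterious/tolerated verdicts; "<algo>_deleterious" restricts to the
    variants that algorithm calls deleterious.
    """
    if group == "nonsynonymous":
        return np.array([a.is_nonsynonymous for a in annotations])
    if group.endswith("_deleterious"):
        algo = group[: -len("_deleterious")]
        if algo in ALGORITHMS:
            return np.array([a.deleterious_by(algo) for a in annotations])
    raise ValueError(f"unknown functional group {group!r}")


def functional_model_set(
    G: GenotypeMatrix,
    annotations: list[VariantAnnotation],
    groups: list[str],
    maf_sets: float | str = "all_maf",
    base: ModelSpec | None = None,
) -> ModelSet:
    """Cartesian product of functional groups and MAF thresholds.

    ``maf_sets`` is either a fixed cutoff or "all_maf" (every unique observed
    MAF). gamma_j = 1 iff the variant is in the group, polymorphic, and at or
    below the threshold. Empty intersections are dropped with a warning;
    raising only happens when nothing at all survives.
    """
    if not groups:
        raise ValueError("at least one functional group is required")
    for g in groups:
        if g not in FUNCTIONAL_GROUPS:
            raise ValueError(
                f"unknown group {g!r}; allowed: {list(FUNCTIONAL_GROUPS)}"
            )
    maf = G.maf
    if maf_sets == "all_maf":
        thresholds = list(np.unique(maf[maf > 0]))
    else:
        thresholds = [float(maf_sets)]
    p = G.n_variants
    w = base.w if base is not None else constant_weights(p)
    s = base.s if base is not None else np.ones(p)
    specs = []
    for g in groups:
        member = functional_group_mask(annotations, g)
        for t in thresholds:
            gamma = maf_threshold_inclusion(maf, t) * member
            if not gamma.any():
                logger.warning(
                    "dropping empty model: group=%s threshold=%.6g", g, t
                )
                continue
            specs.append(ModelSpec(w, s, gamma, f"{g},maf<={t:.8g}"))
    if not specs:
        raise ValueError("all functional-group models are empty")
    return ModelSet(specs=specs, generator="functional")


# ---------------------------------------------------------------------------
# composite builder
# ---------------------------------------------------------------------------


def build_model_set(
    G: GenotypeMatrix,
    Y: PhenotypeVector,
    *,
    weights: str = "constant",
    signs: str = "unsigned",
    inclusion: float | str = 0.01,
    annotations: list[VariantAnnotation] | None = None,
    groups: list[str] | None = None,
) -> ModelSet:
    """Assemble a model set from configuration keys.

    weights: "constant" | "maf_weighted" | "both"; signs: "unsigned" |
    "signed"; inclusion: a fixed MAF cutoff, "all_maf", or "functional"
    (requires annotations and groups). Because w and s may depend on the
    phenotype, callers re-invoke this inside each permutation.
    """
    p = G.n_variants
    if weights == "constant":
        w_options = [("C", constant_weights(p))]
    elif weights == "maf_weighted":
        w_options = [("W", madsen_browning_weights(G, Y))]
    elif weights == "both":
        w_options = [
            ("C", constant_weights(p)),
            ("W", madsen_browning_weights(G, Y)),
        ]
    else:
        raise ValueError(f"unknown weights option {weights!r}")
    if signs == "unsigned":
        s = np.ones(p)
    elif signs == "signed":
        s = sign_variants(G, Y)
    else:
        raise ValueError(f"unknown signs option {signs!r}")

    sets = []
    for wl, w in w_options:
        base = ModelSpec(w, s, np.ones(p), f"{wl},{signs}")
        if inclusion == "all_maf":
            sub = all_maf_model_set(G.maf, base)
        elif inclusion == "functional":
            if annotations is None or not groups:
                raise ValueError(
                    "functional inclusion requires annotations and groups"
                )
            sub = functional_model_set(G, annotations, groups, "all_maf", base)
        else:
            gamma = maf_threshold_inclusion(G.maf, float(inclusion))
            sub = ModelSet(
                [ModelSpec(w, s, gamma, f"maf<={float(inclusion):g}")],
                generator="fixed",
            )
        relabeled = [
            ModelSpec(m.w, m.s, m.gamma, f"{wl},{signs},{m.label}")
            for m in sub.specs
        ]
        sets.append(ModelSet(relabeled, generator=sub.generator))
    return sets[0] if len(sets) == 1 else ModelSet.union(*sets)
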