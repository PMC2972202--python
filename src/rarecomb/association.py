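"""Score statistics over aggregated variants, model-set maximization,
step-up greedy selection, and the CAST / CMC comparators.

For a model with coefficients c_j = w_j s_j gamma_j the per-individual
aggregated score is S_i = sum_j c_j G_ij, and the test statistic is the
classical score statistic

    T = U^2 / (sigma2_Y * V_S),   U = sum_i (Y_i - Ybar) S_i,
    sigma2_Y = (1/n) sum_i (Y_i - Ybar)^2,   V_S = sum_i (S_i - Sbar)^2,

which is chi-squared with one degree of freedom under the null for a fixed
model, and identical to the score test of a logistic (or linear) regression
of Y on S with the intercept profiled out. Degenerate inputs (constant S or
constant Y) score 0 rather than erroring, so model sets with empty groups
stay well-defined under maximization.

When several models are searched — a ModelSet maximum or the step-up greedy
subset search — the final statistic is the maximum over models, and its
p-value must come from re-running the entire search on permuted phenotypes
(:mod:`rarecomb.permutation`).

Implementation note: maximization and step-up evaluate U and V_S as linear
and quadratic forms in c using the cached centered Gram matrix of the
genotypes, so a full step-up pass costs O(steps * p) array work after one
O(n p) mat-vec per phenotype. The definitional route through
:func:`aggregate_score` + :func:`score_statistic` is kept public and the
test suite asserts the two routes agree.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_data import GenotypeMatrix, PhenotypeVector, VariantAnnotation
from . import weights as wmod
from .weights import ModelSet, ModelSpec

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "aggregate_score",
    "score_statistic",
    "max_over_models",
    "step_up",
    "cast_test",
    "cmc_test",
    "AssociationTest",
    "StepUpTest",
    "ModelSetTest",
    "CastTest",
    "CmcTest",
    "CombinedTest",
]

_EPS = 1e-12


@dataclass
class TestResult:
    """Outcome of one association procedure on one dataset."""

    __test__ = False  # not a pytest class, despite the name

    statistic: float
    best_model: str
    selected_variants: list[str]
    method: str
    p_value: float | None = None
    n_permutations: int = 0
    df: int | None = None  # only for asymptotic comparators (CMC)


# ---------------------------------------------------------------------------
# definitional operations
# ---------------------------------------------------------------------------


def aggregate_score(G: GenotypeMatrix, m: ModelSpec) -> np.ndarray:
    """Per-individual weighted burden S_i = sum_j w_j s_j gamma_j G_ij."""
    c = m.coefficients
    if c.shape[0] != G.n_variants:
        raise ValueError("model dimension does not match genotype columns")
    return G.dosages @ c


def score_statistic(S: np.ndarray, Y: PhenotypeVector) -> float:
    """One-degree-of-freedom score statistic of Y on the aggregated score S."""
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if n < 2:
        raise ValueError("need at least two individuals")
    yc = Y.values - Y.values.mean()
    sigma2 = float(yc @ yc) / n
    sc = S - S.mean()
    v = float(sc @ sc)
    if sigma2 <= _EPS or v <= _EPS:
        return 0.0
    u = float(yc @ S)
    return u * u / (sigma2 * v)


# ---------------------------------------------------------------------------
# fast quadratic-form internals
# ---------------------------------------------------------------------------


def _phenotype_parts(G: GenotypeMatrix, Y: PhenotypeVector):
    """(u_raw, sigma2): per-variant centered cross-products and ML variance."""
    yc = Y.values - Y.values.mean()
    sigma2 = float(yc @ yc) / yc.shape[0]
    # Gc^T yc == G^T yc because yc is centered
    u_raw = G.dosages.T.astype(np.float64) @ yc
    return u_raw, sigma2


def _model_statistic_fast(
    c: np.ndarray, u_raw: np.ndarray, Q: np.ndarray, sigma2: float
) -> float:
    u = float(c @ u_raw)
    v = float(c @ Q @ c)
    if sigma2 <= _EPS or v <= _EPS:
        return 0.0
    return u * u / (sigma2 * v)


def max_over_models(
    G: GenotypeMatrix, Y: PhenotypeVector, M: ModelSet
) -> TestResult:
    """Maximum score statistic over a model set; first label wins ties."""
    u_raw, sigma2 = _phenotype_parts(G, Y)
    Q = G.centered_gram()
    best_t, best_m = -np.inf, None
    for m in M:
        t = _model_statistic_fast(m.coefficients, u_raw, Q, sigma2)
        if t > best_t:
            best_t, best_m = t, m
    selected = [
        v for v, g in zip(G.variant_ids, best_m.gamma) if g > 0
    ]
    return TestResult(
        statistic=float(best_t),
        best_model=best_m.label,
        selected_variants=selected,
        method=f"max[{M.generator}]",
    )


def step_up(
    G: GenotypeMatrix,
    Y: PhenotypeVector,
    w_model: str = "constant",
    s_model: str = "unsigned",
) -> TestResult:
    """Greedy forward search for the best aggregated group of variants.

    Starts from the best single-variant statistic and repeatedly adds the
    variant giving the largest statistic for the enlarged group, stopping as
    soon as the best addition fails to strictly increase the statistic (a
    plateau terminates). Weights and signs are computed once from the full
    data and applied marginally; ties break to the lowest variant index.
    Worst case O(p^2) statistic evaluations.
    """
    p = G.n_variants
    if w_model == "constant":
        w = wmod.constant_weights(p)
    elif w_model == "maf_weighted":
        w = wmod.madsen_browning_weights(G, Y)
    else:
        raise ValueError(f"unknown w_model {w_model!r}")
    if s_model == "unsigned":
        s = np.ones(p)
    elif s_model == "signed":
        s = wmod.sign_variants(G, Y)
    else:
        raise ValueError(f"unknown s_model {s_model!r}")
    c = w * s

    u_raw, sigma2 = _phenotype_parts(G, Y)
    Q = G.centered_gram()
    u = c * u_raw
    diag = c * c * np.diag(Q)
    eligible = (G.maf > 0) & (diag > _EPS)
    if not eligible.any() or sigma2 <= _EPS:
        return TestResult(0.0, "step-up(empty)", [], f"step_up[{w_model},{s_model}]")

    with np.errstate(divide="ignore", invalid="ignore"):
        t_uni = np.where(eligible, u * u / (sigma2 * diag), -np.inf)
    j0 = int(np.argmax(t_uni))
    selected = [j0]
    in_model = np.zeros(p, dtype=bool)
    in_model[j0] = True
    U = float(u[j0])
    V = float(diag[j0])
    qA = c * Q[:, j0] * c[j0]  # qA_k = sum_{j in model} c_k Q_kj c_j
    t_cur = float(t_uni[j0])

    while True:
        cand = eligible & ~in_model
        if not cand.any():
            break
        U_new = U + u
        V_new = V + diag + 2.0 * qA
        with np.errstate(divide="ignore", invalid="ignore"):
            t_new = np.where(
                cand & (V_new > _EPS), U_new * U_new / (sigma2 * V_new), -np.inf
            )
        k = int(np.argmax(t_new))
        if not t_new[k] > t_cur:
            break
        selected.append(k)
        in_model[k] = True
        U = float(U_new[k])
        V = float(V_new[k])
        qA = qA + c * Q[:, k] * c[k]
        t_cur = float(t_new[k])

    ids = [G.variant_ids[j] for j in selected]
    return TestResult(
        statistic=t_cur,
        best_model=f"step-up(k={len(selected)})",
        selected_variants=ids,
        method=f"step_up[{w_model},{s_model}]",
    )


def cast_test(
    G: GenotypeMatrix, Y: PhenotypeVector, cutoff: float = 0.01
) -> TestResult:
    """Dosage-sum burden test at a hard MAF cutoff.

    Constant weights, unsigned, one fixed threshold: the CAST idea, except
    summing minor-allele dosages rather than an any-mutation indicator.
    """
    p = G.n_variants
    gamma = wmod.maf_threshold_inclusion(G.maf, cutoff)
    m = ModelSpec(
        wmod.constant_weights(p), np.ones(p), gamma, f"C,unsigned,maf<={cutoff:g}"
    )
    res = max_over_models(G, Y, ModelSet([m], generator="fixed"))
    res.method = f"cast[maf<={cutoff:g}]"
    return res


def cmc_test(
    G: GenotypeMatrix, Y: PhenotypeVector, cutoff: float = 0.01
) -> TestResult:
    """Combined multivariate and collapsing logistic likelihood-ratio test.

    Rare variants (0 < maf <= cutoff) are collapsed into one any-rare-variant
    indicator; each common variant keeps its own dosage term. The LRT against
    the intercept-only logistic model is chi-squared with 1 + #common degrees
    of freedom (collinear columns dropped with a warning). Asymptotic only —
    this comparator is never permuted.
    """
    import statsmodels.api as sm

    if not Y.is_dichotomous:
        raise ValueError("CMC requires a dichotomous trait")
    if G.n_variants < 1:
        raise ValueError("CMC requires at least one variant")
    maf = G.maf
    rare = (maf > 0) & (maf <= cutoff)
    common = maf > cutoff
    cols, names = [], []
    if rare.any():
        cols.append((G.dosages[:, rare].sum(axis=1) > 0).astype(float))
        names.append("rare_collapsed")
    for j in np.where(common)[0]:
        cols.append(G.dosages[:, j].astype(float))
        names.append(G.variant_ids[j])
    if not cols:
        return TestResult(0.0, "cmc(empty)", [], f"cmc[maf<={cutoff:g}]",
                          p_value=1.0, df=0)
    X = np.column_stack(cols)
    # drop constant and collinear columns
    keep: list[int] = []
    for j in range(X.shape[1]):
        sub = X[:, keep + [j]]
        subc = sub - sub.mean(axis=0)
        if np.linalg.matrix_rank(subc) > len(keep):
            keep.append(j)
        else:
            logger.warning("CMC: dropping collinear column %s", names[j])
    X = X[:, keep]
    names = [names[j] for j in keep]
    y = Y.values
    design = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", False):
            raise RuntimeError("logistic fit did not converge")
        llf = fit.llf
    except Exception as exc:  # separation / non-convergence
        logger.warning("CMC fit failed (%s); reporting NA", exc)
        return TestResult(
            float("nan"), "cmc(NA)", names, f"cmc[maf<={cutoff:g}]",
            p_value=float("nan"), df=len(names),
        )
    pbar = y.mean()
    ll0 = y.sum() * np.log(pbar) + (len(y) - y.sum()) * np.log(1 - pbar)
    lrt = max(0.0, 2.0 * (llf - ll0))
    df = X.shape[1]
    pval = float(stats.chi2.sf(lrt, df))
    return TestResult(
        statistic=float(lrt),
        best_model=f"cmc(df={df})",
        selected_variants=names,
        method=f"cmc[maf<={cutoff:g}]",
        p_value=pval,
        df=df,
    )


# ---------------------------------------------------------------------------
# procedure objects (closures for the permutation engine)
# ---------------------------------------------------------------------------


class AssociationTest:
    """A deterministic procedure mapping (G, Y) to a TestResult.

    Subclasses re-estimate any phenotype-dependent quantities (signs,
    Madsen-Browning weights, step-up selection) on every call, which is what
    makes permutation of the full procedure valid.
    """

    name: str = "test"
    asymptotic: bool = False  # True => p-value available without permutation

    def statistic(self, G: GenotypeMatrix, Y: PhenotypeVector) -> TestResult:
        raise NotImplementedError

    def __call__(self, G: GenotypeMatrix, Y: PhenotypeVector) -> TestResult:
        return self.statistic(G, Y)


class StepUpTest(AssociationTest):
    def __init__(self, w_model: str = "constant", s_model: str = "unsigned"):
        self.w_model = w_model
        self.s_model = s_model
        self.name = f"step[{w_model},{s_model}]"

    def statistic(self, G, Y):
        return step_up(G, Y, self.w_model, self.s_model)


class ModelSetTest(AssociationTest):
    """Max-over-models test built from configuration keys.

    The inclusion structure is phenotype-independent, but weights/signs may
    not be, so the set is rebuilt from (G, Y) on every call.
    """

    def __init__(
        self,
        *,
        weights: str = "constant",
        signs: str = "unsigned",
        inclusion: float | str = 0.01,
        annotations: list[VariantAnnotation] | None = None,
        groups: list[str] | None = None,
    ):
        self.kwargs = dict(
            weights=weights,
            signs=signs,
            inclusion=inclusion,
            annotations=annotations,
            groups=groups,
        )
        wl = {"constant": "C", "maf_weighted": "W", "both": "B"}[weights]
        self.name = f"{wl},{signs},{inclusion}"

    def statistic(self, G, Y):
        M = wmod.build_model_set(G, Y, **self.kwargs)
        res = max_over_models(G, Y, M)
        res.method = self.name
        return res


class CastTest(AssociationTest):
    def __init__(self, cutoff: float = 0.01):
        self.cutoff = cutoff
        self.name = f"cast[maf<={cutoff:g}]"

    def statistic(self, G, Y):
        return cast_test(G, Y, self.cutoff)


class CmcTest(AssociationTest):
    asymptotic = True

    def __init__(self, cutoff: float = 0.01):
        self.cutoff = cutoff
        self.name = f"cmc[maf<={cutoff:g}]"

    def statistic(self, G, Y):
        return cmc_test(G, Y, self.cutoff)


class CombinedTest(AssociationTest):
    """Best-of union across procedures (e.g. model sets plus step-up)."""

    def __init__(self, tests: list[AssociationTest], name: str = "union"):
        if not tests:
            raise ValueError("CombinedTest needs at least one procedure")
        self.tests = tests
        self.name = name

    def statistic(self, G, Y):
        results = [t.statistic(G, Y) for t in self.tests]
        best = max(range(len(results)), key=lambda i: results[i].statistic)
        res = results[best]
        return TestResult(
            statistic=res.statistic,
            best_model=f"{self.tests[best].name}:{res.best_model}",
            selected_variants=res.selected_variants,
            method=self.name,
        )
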