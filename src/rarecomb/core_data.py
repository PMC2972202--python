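"""Data containers and I/O for genotypes, phenotypes and variant annotations.

The central object is :class:`GenotypeMatrix`, an n_individuals x n_variants
matrix of minor-allele dosages (0/1/2) with per-variant sample minor-allele
frequencies. Dosages are always oriented to the minor allele: if the coded
allele has sample frequency above 0.5 the coding is flipped (2 - dosage) and
the flip is recorded, so ``maf`` is guaranteed to lie in [0, 0.5].

Genotypes travel as a plain TSV dialect (header row of variant ids, one
individual per row) or, as a convenience, as biallelic GT-only VCF.
Phenotypes are a single column (dichotomous 0/1 or continuous). Annotations
carry per-algorithm functional calls plus a continuous deleteriousness score
in [0, 1] (0 = most deleterious, in the style of the SIFT tolerance index).

Missing genotypes are rejected rather than imputed: silent imputation would
change the test statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ALGORITHMS",
    "CALL_TOKENS",
    "GenotypeMatrix",
    "PhenotypeVector",
    "VariantAnnotation",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_annotations",
    "write_annotations",
]

#: Names of the three (partially concordant) functional-prediction algorithms.
ALGORITHMS = ("algoA", "algoB", "algoC")

#: Allowed functional-call tokens in annotation tables.
CALL_TOKENS = frozenset(
    {"deleterious", "tolerated", "nonsynonymous_only", "synonymous"}
)


@dataclass(eq=False)
class GenotypeMatrix:
    """Minor-allele dosage matrix with per-variant metadata.

    Attributes
    ----------
    dosages : ndarray of shape (n_individuals, n_variants)
        Minor-allele counts, each entry in {0, 1, 2}.
    variant_ids : list of str
        Unique variant labels, one per column.
    maf : ndarray of shape (n_variants,)
        Sample minor-allele frequency, ``dosages.sum(0) / (2 n)``; <= 0.5.
    flipped : ndarray of bool
        True where the input coding was flipped to reach minor-allele
        orientation.
    """

    dosages: np.ndarray
    variant_ids: list[str]
    maf: np.ndarray
    flipped: np.ndarray = field(default=None, repr=False)

    # lazy caches used by the association fast path
    _centered: np.ndarray = field(default=None, init=False, repr=False)
    _gram: np.ndarray = field(default=None, init=False, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosages must be 0, 1 or 2 (no missing genotypes)")
        self.variant_ids = [str(v) for v in self.variant_ids]
        if len(self.variant_ids) != self.dosages.shape[1]:
            raise ValueError("variant_ids length does not match dosage columns")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("variant_ids must be unique")
        self.maf = np.asarray(self.maf, dtype=float)
        if self.maf.shape != (self.dosages.shape[1],):
            raise ValueError("maf length does not match dosage columns")
        if np.any(self.maf > 0.5 + 1e-12):
            raise ValueError("maf must be <= 0.5 (minor-allele orientation)")
        if self.flipped is None:
            self.flipped = np.zeros(self.dosages.shape[1], dtype=bool)

    @classmethod
    def from_dosages(
        cls, dosages: np.ndarray, variant_ids: list[str]
    ) -> "GenotypeMatrix":
        """Build a matrix from raw 0/1/2 dosages, orienting to the minor allele."""
        dosages = np.asarray(dosages)
        if not np.isin(dosages, (0, 1, 2)).all():
            raise ValueError("dosages must be 0, 1 or 2 (no missing genotypes)")
        n = dosages.shape[0]
        freq = dosages.sum(axis=0) / (2.0 * n)
        flip = freq > 0.5
        if flip.any():
            dosages = dosages.copy()
            dosages[:, flip] = 2 - dosages[:, flip]
        maf = dosages.sum(axis=0) / (2.0 * n)
        return cls(
            dosages=dosages.astype(np.int8),
            variant_ids=list(variant_ids),
            maf=maf,
            flipped=flip,
        )

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def centered_dosages(self) -> np.ndarray:
        """Column-centered float copy of the dosages (cached)."""
        if self._centered is None:
            d = self.dosages.astype(np.float64)
            self._centered = d - d.mean(axis=0)
        return self._centered

    def centered_gram(self) -> np.ndarray:
        """p x p Gram matrix of the centered dosages (cached).

        Entry (j, k) is sum_i (G_ij - mean_j)(G_ik - mean_k); the diagonal is
        the per-variant centered sum of squares. Phenotype-independent, so it
        can be reused across permutations.
        """
        if self._gram is None:
            gc = self.centered_dosages()
            self._gram = gc.T @ gc
        return self._gram


@dataclass(eq=False)
class PhenotypeVector:
    """Phenotype values, dichotomous (0/1 case-control) or continuous."""

    values: np.ndarray
    trait_type: str  # "dichotomous" | "continuous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("phenotype values must be a 1-D vector")
        if self.trait_type not in ("dichotomous", "continuous"):
            raise ValueError("trait_type must be 'dichotomous' or 'continuous'")
        if self.trait_type == "dichotomous":
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise ValueError("dichotomous phenotype values must be 0 or 1")
            if len(np.unique(self.values)) < 2:
                raise ValueError(
                    "dichotomous phenotype must contain both cases and controls"
                )

    @classmethod
    def from_values(
        cls, values, trait_type: str | None = None
    ) -> "PhenotypeVector":
        """Build a phenotype, auto-detecting the trait type unless overridden.

        All values in {0, 1} are taken as dichotomous; anything else is
        continuous. An explicit ``trait_type`` always wins.
        """
        values = np.asarray(values, dtype=np.float64)
        if trait_type is None:
            trait_type = (
                "dichotomous"
                if np.isin(values, (0.0, 1.0)).all()
                else "continuous"
            )
        return cls(values=values, trait_type=trait_type)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def is_dichotomous(self) -> bool:
        return self.trait_type == "dichotomous"

    def case_mask(self) -> np.ndarray:
        if not self.is_dichotomous:
            raise ValueError("case/control split requires a dichotomous trait")
        return self.values == 1.0


@dataclass
class VariantAnnotation:
    """Functional annotation of a single variant.

    ``calls`` maps each algorithm name to one of the tokens in
    :data:`CALL_TOKENS`. Deleterious/tolerated calls are only meaningful for
    nonsynonymous variants; synonymous variants carry the "synonymous" token
    for every algorithm and no deleteriousness score.
    """

    variant_id: str
    calls: dict[str, str]
    score: float | None = None

    def __post_init__(self) -> None:
        for algo, call in self.calls.items():
            if call not in CALL_TOKENS:
                raise ValueError(
                    f"unknown call token {call!r} for {algo} on "
                    f"{self.variant_id}; allowed: {sorted(CALL_TOKENS)}"
                )
        syn = [c == "synonymous" for c in self.calls.values()]
        if any(syn) and not all(syn):
            raise ValueError(
                f"{self.variant_id}: synonymous status must agree across "
                "algorithms (it is a property of the substitution)"
            )
        if self.is_nonsynonymous:
            if self.score is None or not (0.0 <= self.score <= 1.0):
                raise ValueError(
                    f"{self.variant_id}: nonsynonymous variants need a "
                    "deleteriousness score in [0, 1]"
                )
        elif self.score is not None:
            raise ValueError(
                f"{self.variant_id}: synonymous variants carry no score"
            )

    @property
    def is_nonsynonymous(self) -> bool:
        return any(c != "synonymous" for c in self.calls.values())

    def deleterious_by(self, algorithm: str) -> bool:
        return self.calls.get(algorithm) == "deleterious"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_genotypes(path, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from TSV (canonical) or biallelic VCF.

    The TSV dialect has a header row of variant ids and one row of integer
    dosages per individual. VCF reading is GT-only and biallelic-only; a
    multi-allelic record or a missing genotype raises, naming the record.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        if df.isna().any().any():
            raise ValueError(f"{path}: missing genotype values are not allowed")
        values = df.to_numpy()
        if not np.equal(np.mod(values, 1), 0).all():
            raise ValueError(f"{path}: dosages must be integers")
        return GenotypeMatrix.from_dosages(
            values.astype(np.int64), list(df.columns)
        )
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF  # optional dependency, imported on demand

    ids, columns = [], []
    for variant in VCF(str(path)):
        if len(variant.ALT) != 1:
            raise ValueError(
                f"non-biallelic record {variant.CHROM}:{variant.POS} "
                f"(ALT={variant.ALT})"
            )
        dos = []
        for gt in variant.genotypes:
            a = gt[:-1]  # trailing element is phasing
            if len(a) != 2 or -1 in a:
                raise ValueError(
                    f"missing or non-diploid genotype at "
                    f"{variant.CHROM}:{variant.POS}"
                )
            dos.append(a[0] + a[1])
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        ids.append(vid)
        columns.append(dos)
    if not columns:
        raise ValueError(f"{path}: no variant records")
    return GenotypeMatrix.from_dosages(np.array(columns).T, ids)


def write_genotypes(G: GenotypeMatrix, path) -> None:
    """Write the canonical TSV dialect (round-trips exactly)."""
    pd.DataFrame(G.dosages, columns=G.variant_ids).to_csv(
        path, sep="\t", index=False
    )


def read_phenotypes(
    path, trait_type: str | None = None, n_expected: int | None = None
) -> PhenotypeVector:
    """Read a phenotype vector: one value per line, or (id, value) TSV."""
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] == 2:
        values = df.iloc[:, 1].to_numpy(dtype=float)
    elif df.shape[1] == 1:
        values = df.iloc[:, 0].to_numpy(dtype=float)
    else:
        raise ValueError(f"{path}: expected 1 or 2 columns")
    if n_expected is not None and len(values) != n_expected:
        raise ValueError(
            f"{path}: {len(values)} phenotypes but {n_expected} individuals"
        )
    return PhenotypeVector.from_values(values, trait_type)


def write_phenotypes(Y: PhenotypeVector, path) -> None:
    fmt = "%d" if Y.is_dichotomous else "%.17g"
    np.savetxt(path, Y.values, fmt=fmt)


def read_annotations(path) -> list[VariantAnnotation]:
    """Read an annotation TSV: variant_id, algoA, algoB, algoC, score.

    A '.' in the score column means absent (synonymous variant).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["variant_id", *ALGORITHMS, "score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        score = getattr(row, "score")
        score = None if score in (".", "", None) or score != score else float(score)
        out.append(
            VariantAnnotation(
                variant_id=row.variant_id,
                calls={a: getattr(row, a) for a in ALGORITHMS},
                score=score,
            )
        )
    return out


def write_annotations(annotations: list[VariantAnnotation], path) -> None:
    rows = [
        {
            "variant_id": a.variant_id,
            **{algo: a.calls[algo] for algo in ALGORITHMS},
            "score": "." if a.score is None else f"{a.score:.6g}",
        }
        for a in annotations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def align_annotations(
    annotations: list[VariantAnnotation], G: GenotypeMatrix
) -> list[VariantAnnotation]:
    """Order annotations to match the genotype columns; error on absent ids."""
    by_id = {a.variant_id: a for a in annotations}
    missing = [v for v in G.variant_ids if v not in by_id]
    if missing:
        raise KeyError(
            f"annotations missing for genotype variants: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    unknown = set(by_id) - set(G.variant_ids)
    if unknown:
        raise KeyError(
            f"annotated variants absent from genotypes: {sorted(unknown)[:5]}"
        )
    return [by_id[v] for v in G.variant_ids]
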