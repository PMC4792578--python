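"""Within-sample relative expression orderings (REOs).

The primitive of everything in this package is the comparison of two genes'
expression values inside a single sample.  Gene pairs whose ordering is
conserved across almost all normal-tissue samples ("stable pairs") define a
reference ordering; tumour samples are then characterised by which of those
orderings they reverse.  Because only within-sample ranks are consumed, every
result in this module is invariant under per-sample monotone transforms of
the expression values.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import binom

__all__ = [
    "Relation",
    "GenePair",
    "ExpressionMatrix",
    "StablePairSet",
    "ConsistencyResult",
    "ReversalMatrix",
    "pairwise_reo",
    "find_stable_pairs",
    "intersect_stable_pairs",
    "binomial_consistency_test",
    "log_binomial_tail",
    "reversal_status",
]


class Relation(enum.Enum):
    """Outcome of comparing two expression values within one sample."""

    GREATER = ">"
    LESS = "<"
    TIE = "="


@dataclass(frozen=True, order=True)
class GenePair:
    """Directed gene pair: ``gene_a`` is expressed above ``gene_b`` in the
    reference (normal-tissue) ordering."""

    gene_a: str
    gene_b: str

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"degenerate pair ({self.gene_a!r}, {self.gene_b!r})")

    @property
    def unordered(self) -> tuple[str, str]:
        a, b = self.gene_a, self.gene_b
        return (a, b) if a <= b else (b, a)

    def reversed(self) -> "GenePair":
        return GenePair(self.gene_b, self.gene_a)


class ExpressionMatrix:
    """Gene x sample matrix of log2 expression values.

    Parameters
    ----------
    gene_ids, sample_ids:
        Unique string identifiers for rows and columns.
    values:
        Real-valued array of shape ``(len(gene_ids), len(sample_ids))`` with
        no missing entries.
    """

    def __init__(
        self,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        values: np.ndarray,
    ) -> None:
        gene_ids = [str(g) for g in gene_ids]
        sample_ids = [str(s) for s in sample_ids]
        values = np.asarray(values, dtype=float)
        if values.shape != (len(gene_ids), len(sample_ids)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(gene_ids)} genes x {len(sample_ids)} samples"
            )
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("gene ids are not unique")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("sample ids are not unique")
        if np.isnan(values).any():
            raise ValueError("expression matrix contains missing values")
        self.gene_ids = gene_ids
        self.sample_ids = sample_ids
        self.values = values
        self._gene_index = {g: i for i, g in enumerate(gene_ids)}
        self._sample_index = {s: j for j, s in enumerate(sample_ids)}

    # -- basic access ------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self._gene_index[gene]]
        except KeyError:
            raise KeyError(f"gene {gene!r} not present in matrix") from None

    def gene_indices(self, genes: Iterable[str]) -> np.ndarray:
        missing = [g for g in genes if g not in self._gene_index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return np.array([self._gene_index[g] for g in genes], dtype=np.intp)

    def sample_column(self, sample: str) -> dict[str, float]:
        j = self._sample_index[sample]
        return dict(zip(self.gene_ids, self.values[:, j]))

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_indices(genes)
        return ExpressionMatrix(list(genes), self.sample_ids, self.values[idx])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self._sample_index]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing}")
        idx = np.array([self._sample_index[s] for s in samples], dtype=np.intp)
        return ExpressionMatrix(self.gene_ids, list(samples), self.values[:, idx])

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path, impute: bool = False) -> "ExpressionMatrix":
        """Load a TSV whose first column is ``gene_id``.

        Missing values are rejected unless ``impute`` is set, in which case
        each gene's missing entries are replaced by that gene's median.
        """
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy(dtype=float)
        if np.isnan(values).any():
            if not impute:
                raise ValueError(
                    f"{path}: matrix contains missing values "
                    "(pass impute=True for per-gene median imputation)"
                )
            med = np.nanmedian(values, axis=1, keepdims=True)
            if np.isnan(med).any():
                raise ValueError(f"{path}: some genes have no observed values")
            values = np.where(np.isnan(values), med, values)
        return cls(df.index.astype(str).tolist(), df.columns.astype(str).tolist(), values)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")


@dataclass
class StablePairSet:
    """Directed gene pairs conserved in a normal-tissue cohort.

    ``direction`` is implicit: for every stored pair, gene_a exceeds gene_b
    in at least ``support`` of the ``n_normal`` reference samples.
    """

    gene_a: np.ndarray
    gene_b: np.ndarray
    support: np.ndarray
    n_normal: int
    threshold: float

    def __post_init__(self) -> None:
        self.gene_a = np.asarray(self.gene_a, dtype=object)
        self.gene_b = np.asarray(self.gene_b, dtype=object)
        self.support = np.asarray(self.support, dtype=float)
        if not (len(self.gene_a) == len(self.gene_b) == len(self.support)):
            raise ValueError("pair arrays have inconsistent lengths")
        seen: set[tuple[str, str]] = set()
        for a, b in zip(self.gene_a, self.gene_b):
            if a == b:
                raise ValueError(f"degenerate pair ({a!r}, {b!r})")
            key = (a, b) if a <= b else (b, a)
            if key in seen:
                raise ValueError(f"pair on genes {key} listed more than once")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.gene_a)

    def __iter__(self):
        for a, b in zip(self.gene_a, self.gene_b):
            yield GenePair(a, b)

    @property
    def pairs(self) -> list[GenePair]:
        return list(self)

    def direction_map(self) -> dict[tuple[str, str], tuple[str, str]]:
        """Map unordered gene pair -> stored (higher, lower) orientation."""
        out = {}
        for a, b in zip(self.gene_a, self.gene_b):
            key = (a, b) if a <= b else (b, a)
            out[key] = (a, b)
        return out

    def genes(self) -> set[str]:
        return set(self.gene_a) | set(self.gene_b)

    def restrict_to_genes(self, genes: set[str]) -> "StablePairSet":
        mask = np.fromiter(
            (a in genes and b in genes for a, b in zip(self.gene_a, self.gene_b)),
            dtype=bool,
            count=len(self),
        )
        return StablePairSet(
            self.gene_a[mask], self.gene_b[mask], self.support[mask],
            self.n_normal, self.threshold,
        )

    @classmethod
    def from_pairs(
        cls,
        pairs: Sequence[GenePair],
        support: Sequence[float] | None = None,
        n_normal: int = 0,
        threshold: float = 0.99,
    ) -> "StablePairSet":
        if support is None:
            support = np.ones(len(pairs))
        return cls(
            np.array([p.gene_a for p in pairs], dtype=object),
            np.array([p.gene_b for p in pairs], dtype=object),
            np.asarray(support, dtype=float),
            n_normal,
            threshold,
        )

    # TSV round-trip: columns gene_a, gene_b, support; direction = a > b.
    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {"gene_a": self.gene_a, "gene_b": self.gene_b, "support": self.support}
        )
        with open(path, "w") as fh:
            fh.write(f"# n_normal={self.n_normal}\tthreshold={self.threshold!r}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "StablePairSet":
        n_normal, threshold = 0, 0.99
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for tok in first[1:].split():
                    key, _, val = tok.partition("=")
                    if key == "n_normal":
                        n_normal = int(val)
                    elif key == "threshold":
                        threshold = float(val)
                df = pd.read_csv(fh, sep="\t", dtype={"gene_a": str, "gene_b": str})
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t", dtype={"gene_a": str, "gene_b": str})
        return cls(
            df["gene_a"].to_numpy(dtype=object),
            df["gene_b"].to_numpy(dtype=object),
            df["support"].to_numpy(dtype=float),
            n_normal,
            threshold,
        )


@dataclass
class ConsistencyResult:
    """Cross-cohort agreement of overlapping stable pairs.

    ``score`` is k/n and is ``None`` when no pairs overlap; ``p`` is the
    upper-tail probability of observing at least ``k`` agreements among ``n``
    fair coin flips.
    """

    n: int
    k: int
    score: float | None
    p: float


@dataclass
class ReversalMatrix:
    """Binary pair x sample indicator: 1 = sample reverses the reference REO."""

    pairs: list[GenePair]
    sample_ids: list[str]
    status: np.ndarray  # uint8, shape (len(pairs), len(sample_ids))

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=np.uint8)
        if self.status.shape != (len(self.pairs), len(self.sample_ids)):
            raise ValueError("status shape does not match pairs x samples")
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("reversal statuses must be 0/1")
        self._pair_index = {p: i for i, p in enumerate(self.pairs)}

    def row(self, pair: GenePair) -> np.ndarray:
        try:
            return self.status[self._pair_index[pair]]
        except KeyError:
            raise KeyError(f"pair {pair} not present in reversal matrix") from None

    def subset_pairs(self, pairs: Sequence[GenePair]) -> "ReversalMatrix":
        idx = []
        for p in pairs:
            if p not in self._pair_index:
                raise KeyError(f"pair {p} not present in reversal matrix")
            idx.append(self._pair_index[p])
        return ReversalMatrix(list(pairs), self.sample_ids, self.status[idx])


# ---------------------------------------------------------------------------
# operations


def pairwise_reo(sample_expression: Mapping[str, float], gene_a: str, gene_b: str) -> Relation:
    """Compare two genes inside one sample."""
    for g in (gene_a, gene_b):
        if g not in sample_expression:
            raise KeyError(f"gene {g!r} not present in sample expression map")
    va, vb = sample_expression[gene_a], sample_expression[gene_b]
    if va > vb:
        return Relation.GREATER
    if va < vb:
        return Relation.LESS
    return Relation.TIE


def _effective_count_threshold(threshold: float, n: int) -> float:
    # "more than threshold*n" with a snap to integer so that e.g. 0.99*100
    # behaves as exactly 99 despite binary-float rounding.
    t = threshold * n
    if abs(t - round(t)) < 1e-9:
        t = float(round(t))
    return t


def find_stable_pairs(
    normal: ExpressionMatrix,
    threshold: float = 0.99,
    gene_universe: set[str] | None = None,
) -> StablePairSet:
    """Identify gene pairs whose ordering holds in more than ``threshold`` of
    normal samples.

    The inequality is strict on both levels: a sample supports (A, B) only if
    A's value strictly exceeds B's (ties count against stability), and a pair
    is kept only if its supporting count strictly exceeds ``threshold * n``.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0.5, 1], got {threshold}")
    mat = normal
    if gene_universe is not None:
        keep = [g for g in normal.gene_ids if g in gene_universe]
        mat = normal.subset_genes(keep)
    if mat.n_genes == 0 or mat.n_samples < 2:
        raise ValueError("need at least one gene and two normal samples")

    v = mat.values
    g, n = v.shape
    # greater[i, j] = #samples with gene i strictly above gene j
    greater = np.zeros((g, g), dtype=np.int64)
    # chunk over samples to bound the g*g temporaries
    chunk = max(1, int(2e7 // (g * g)) or 1)
    for s0 in range(0, n, chunk):
        block = v[:, s0 : s0 + chunk]  # g x c
        greater += (block[:, None, :] > block[None, :, :]).sum(axis=2)

    t = _effective_count_threshold(threshold, n)
    ia, ja = np.nonzero(greater > t)
    order = np.lexsort((ja, ia))
    ia, ja = ia[order], ja[order]
    genes = np.array(mat.gene_ids, dtype=object)
    return StablePairSet(
        genes[ia], genes[ja], greater[ia, ja] / n, n_normal=n, threshold=threshold
    )


def log_binomial_tail(n: int, k: int) -> float:
    """Natural log of P(X >= k) for X ~ Binomial(n, 1/2).

    Evaluated in log space so the tail is finite even when the probability
    underflows double precision (e.g. n in the tens of millions with k near n).
    """
    if n < 0 or k < 0 or k > n:
        raise ValueError(f"require 0 <= k <= n, got n={n}, k={k}")
    if k == 0:
        return 0.0
    p = binom.sf(k - 1, n, 0.5)
    if p > 0.0:
        return float(math.log(p))
    # deep tail: sum log-space terms from k outward until they stop mattering
    log_half_n = n * math.log(0.5)
    window = 1024
    while True:
        hi = min(n, k + window)
        i = np.arange(k, hi + 1)
        logterms = gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1) + log_half_n
        if hi == n or logterms[-1] < logterms.max() - 60.0:
            return float(logsumexp(logterms))
        window *= 8


def binomial_consistency_test(n: int, k: int) -> float:
    """Exact upper-tail probability P(X >= k), X ~ Binomial(n, 1/2).

    Returns 0.0 only when the true tail is below the smallest positive
    double; use :func:`log_binomial_tail` to keep the magnitude.
    """
    lp = log_binomial_tail(n, k)
    return float(math.exp(lp)) if lp > -745.0 else 0.0


def intersect_stable_pairs(
    set1: StablePairSet, set2: StablePairSet
) -> tuple[StablePairSet, ConsistencyResult]:
    """Overlap two stable-pair sets on unordered gene pairs and test direction
    agreement against a fair-coin null."""
    d1 = set1.direction_map()
    d2 = set2.direction_map()
    sup1 = {}
    for (a, b, s) in zip(set1.gene_a, set1.gene_b, set1.support):
        sup1[(a, b) if a <= b else (b, a)] = s
    sup2 = {}
    for (a, b, s) in zip(set2.gene_a, set2.gene_b, set2.support):
        sup2[(a, b) if a <= b else (b, a)] = s

    overlap = sorted(set(d1) & set(d2))
    n = len(overlap)
    ga, gb, sup = [], [], []
    k = 0
    for key in overlap:
        if d1[key] == d2[key]:
            k += 1
            a, b = d1[key]
            ga.append(a)
            gb.append(b)
            sup.append(min(sup1[key], sup2[key]))
    consistent = StablePairSet(
        np.array(ga, dtype=object),
        np.array(gb, dtype=object),
        np.array(sup, dtype=float),
        n_normal=min(set1.n_normal, set2.n_normal),
        threshold=max(set1.threshold, set2.threshold),
    )
    p = binomial_consistency_test(n, k) if n > 0 else 1.0
    score = (k / n) if n > 0 else None
    return consistent, ConsistencyResult(n=n, k=k, score=score, p=p)


def reversal_status(tumor: ExpressionMatrix, pairs: Sequence[GenePair]) -> ReversalMatrix:
    """Score each sample 1 for pairs whose ordering strictly opposes the
    reference direction (ties score 0)."""
    pairs = list(pairs)
    if not pairs:
        return ReversalMatrix([], tumor.sample_ids, np.zeros((0, tumor.n_samples), np.uint8))
    ia = tumor.gene_indices([p.gene_a for p in pairs])
    ib = tumor.gene_indices([p.gene_b for p in pairs])
    status = (tumor.values[ib] > tumor.values[ia]).astype(np.uint8)
    return ReversalMatrix(pairs, list(tumor.sample_ids), status)
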