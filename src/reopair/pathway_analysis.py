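"""Per-sample pathway disruption and survival-relevant pathway screening.

A pathway's disruption index in a sample is the fraction of that pathway's
stable intra-pathway gene pairs whose ordering the sample reverses.  Indexes
are screened against recurrence-free survival with univariate Cox models, and
the surviving pathways are reduced to a correlated "core" via a Spearman
network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .reo_core import ExpressionMatrix, GenePair, StablePairSet, reversal_status
from .survival_stats import SurvivalTable, CoxResult, bh_fdr, cox_univariate

__all__ = [
    "PathwayCollection",
    "DisruptionMatrix",
    "read_gmt",
    "pathway_stable_pairs",
    "disruption_index",
    "compute_disruption_matrix",
    "screen_rfs_pathways",
    "core_pathway_network",
]


class PathwayCollection:
    """Named gene sets (GMT semantics): unique names, non-empty deduplicated sets."""

    def __init__(self, sets: Mapping[str, Sequence[str]], source: str = "") -> None:
        self._sets: dict[str, set[str]] = {}
        for name, genes in sets.items():
            genes = {str(g) for g in genes}
            if not genes:
                raise ValueError(f"pathway {name!r} has an empty gene set")
            if name in self._sets:
                raise ValueError(f"duplicate pathway name {name!r}")
            self._sets[name] = genes
        self.source = source

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> set[str]:
        return self._sets[name]

    def items(self):
        return self._sets.items()

    def names(self) -> list[str]:
        return list(self._sets)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for s in self._sets.values():
            out |= s
        return out

    @classmethod
    def from_gmt(cls, path) -> "PathwayCollection":
        return read_gmt(path)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, genes in self._sets.items():
                fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


def read_gmt(path) -> PathwayCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene...`` per line."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            sets[name] = [g for g in fields[2:] if g]
    return PathwayCollection(sets, source=str(path))


@dataclass
class DisruptionMatrix:
    """Pathway x sample disruption fractions.

    Only pathways with at least one stable intra-pathway pair appear;
    ``n_pairs`` records how many pairs back each row.
    """

    pathway_names: list[str]
    sample_ids: list[str]
    values: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if self.values.shape != (len(self.pathway_names), len(self.sample_ids)):
            raise ValueError("values shape mismatch")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("disruption indexes must lie in [0, 1]")
        if np.any(self.n_pairs < 1):
            raise ValueError("pathways without stable pairs must be absent, not zero")
        self._row = {n: i for i, n in enumerate(self.pathway_names)}

    def row(self, name: str) -> np.ndarray:
        return self.values[self._row[name]]

    def subset(self, names: Sequence[str]) -> "DisruptionMatrix":
        idx = [self._row[n] for n in names]
        return DisruptionMatrix(
            list(names), self.sample_ids, self.values[idx], self.n_pairs[idx]
        )

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.pathway_names, columns=self.sample_ids)
        df.insert(0, "n_pairs", self.n_pairs)
        df.index.name = "pathway"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DisruptionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        n_pairs = df.pop("n_pairs").to_numpy(dtype=int)
        return cls(
            df.index.astype(str).tolist(),
            df.columns.astype(str).tolist(),
            df.to_numpy(dtype=float),
            n_pairs,
        )


# ---------------------------------------------------------------------------


def pathway_stable_pairs(
    pathways: PathwayCollection, stable: StablePairSet
) -> dict[str, list[GenePair]]:
    """For each pathway, the stable pairs with both genes annotated to it."""
    out: dict[str, list[GenePair]] = {}
    ga, gb = stable.gene_a, stable.gene_b
    for name, genes in pathways.items():
        mask = np.fromiter(
            (a in genes and b in genes for a, b in zip(ga, gb)),
            dtype=bool,
            count=len(stable),
        )
        out[name] = [GenePair(a, b) for a, b in zip(ga[mask], gb[mask])]
    return out


def disruption_index(tumor: ExpressionMatrix, pathway_pairs: Sequence[GenePair]) -> np.ndarray:
    """Per-sample fraction of the given stable pairs that are reversed."""
    if len(pathway_pairs) == 0:
        raise ValueError("disruption index undefined for zero stable pairs")
    rev = reversal_status(tumor, pathway_pairs)
    return rev.status.mean(axis=0)


def compute_disruption_matrix(
    tumor: ExpressionMatrix,
    pathways: PathwayCollection,
    stable: StablePairSet,
    min_pairs: int = 1,
) -> DisruptionMatrix:
    """Disruption indexes for every pathway with >= ``min_pairs`` stable pairs."""
    ppairs = pathway_stable_pairs(pathways, stable)
    names, rows, counts = [], [], []
    for name, pairs in ppairs.items():
        if len(pairs) < max(1, min_pairs):
            continue
        names.append(name)
        rows.append(disruption_index(tumor, pairs))
        counts.append(len(pairs))
    values = np.vstack(rows) if rows else np.zeros((0, tumor.n_samples))
    return DisruptionMatrix(names, list(tumor.sample_ids), values, np.array(counts, int))


def screen_rfs_pathways(
    dis: DisruptionMatrix,
    surv: SurvivalTable,
    fdr: float = 0.05,
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Univariate Cox screen of disruption indexes against survival.

    Returns one row per tested pathway with hr/ci/p/q and a ``selected``
    flag (BH-FDR < ``fdr``).  Constant or non-convergent indexes are skipped
    with a warning.
    """
    if dis.sample_ids != list(surv.sample_ids):
        surv = surv.align_to(dis.sample_ids)
    rows = []
    for i, name in enumerate(dis.pathway_names):
        if dis.n_pairs[i] < min_pairs:
            continue
        x = dis.values[i]
        if np.ptp(x) == 0:
            warnings.warn(f"pathway {name!r}: constant disruption index, skipped")
            continue
        res = cox_univariate(x, surv)
        if not res.converged or not np.isfinite(res.p_wald):
            warnings.warn(f"pathway {name!r}: Cox fit did not converge, skipped")
            continue
        rows.append((name, res, int(dis.n_pairs[i])))
    if not rows:
        return pd.DataFrame(
            columns=["pathway", "coef", "hr", "ci_low", "ci_high", "p", "q", "n_pairs", "selected"]
        )
    q = bh_fdr([r.p_wald for _, r, _ in rows])
    df = pd.DataFrame(
        {
            "pathway": [n for n, _, _ in rows],
            "coef": [r.coef for _, r, _ in rows],
            "hr": [r.hr for _, r, _ in rows],
            "ci_low": [r.ci_low for _, r, _ in rows],
            "ci_high": [r.ci_high for _, r, _ in rows],
            "p": [r.p_wald for _, r, _ in rows],
            "q": q,
            "n_pairs": [np_ for _, _, np_ in rows],
        }
    )
    df["selected"] = df["q"] < fdr
    return df


def core_pathway_network(
    dis: DisruptionMatrix,
    rho_min: float = 0.6,
    fdr: float = 0.05,
) -> tuple[set[str], list[tuple[str, str, float]]]:
    """Extract the correlated core of survival-relevant pathways.

    Edges join pathway pairs whose Spearman correlation is strictly above
    ``rho_min`` and significant at BH-FDR < ``fdr`` (family = all pathway
    pairs).  The core is the largest connected component containing at least
    one edge; ties between equal-sized components go to the component with
    the lexicographically smallest member.
    """
    names = dis.pathway_names
    m = len(names)
    if m < 2:
        raise ValueError("need at least two pathways")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho_mat, p_mat = stats.spearmanr(dis.values.T)
    if m == 2:  # spearmanr returns scalars for two variables
        rho_mat = np.array([[1.0, rho_mat], [rho_mat, 1.0]])
        p_mat = np.array([[0.0, p_mat], [p_mat, 0.0]])
    iu, ju = np.triu_indices(m, k=1)
    pvals = p_mat[iu, ju]
    finite = np.isfinite(pvals)
    q = np.full(len(pvals), np.nan)
    if finite.any():
        q[finite] = bh_fdr(pvals[finite])
    graph = nx.Graph()
    graph.add_nodes_from(names)
    edges = []
    for idx in range(len(iu)):
        rho = rho_mat[iu[idx], ju[idx]]
        if finite[idx] and q[idx] < fdr and rho > rho_min:
            a, b = names[iu[idx]], names[ju[idx]]
            graph.add_edge(a, b, rho=float(rho))
            edges.append((a, b, float(rho)))
    comps = [c for c in nx.connected_components(graph) if len(c) > 1]
    if not comps:
        return set(), []
    comps.sort(key=lambda c: (-len(c), min(c)))
    core = set(comps[0])
    core_edges = [(a, b, r) for a, b, r in edges if a in core and b in core]
    return core, core_edges
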