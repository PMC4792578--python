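"""Gene-pair signature discovery.

Candidate pairs are intra-core-pathway stable pairs whose reversal is
associated with worse survival (univariate Cox, BH-FDR, hazard ratio > 1).
The signature itself is selected greedily: starting from the single pair
with the best concordance index, pairs are added while the C-index of the
zero-reversal classification keeps improving.

Classification rule: a sample is *favorable* iff none of the signature pairs
is reversed in it; any reversal makes it *unfavorable*.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .reo_core import ExpressionMatrix, GenePair, ReversalMatrix, StablePairSet, reversal_status
from .pathway_analysis import (
    PathwayCollection,
    compute_disruption_matrix,
    core_pathway_network,
    pathway_stable_pairs,
    screen_rfs_pathways,
)
from .survival_stats import CoxResult, SurvivalTable, bh_fdr, cox_univariate, harrell_c

__all__ = [
    "Signature",
    "CandidatePair",
    "PipelineError",
    "DiscoveryParams",
    "screen_candidate_pairs",
    "classify_by_signature",
    "forward_stepwise_select",
    "discover_signature",
]


class PipelineError(RuntimeError):
    """Raised when a discovery stage cannot proceed; carries the stage name."""

    def __init__(self, stage: str, message: str, no_signal: bool = False) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.no_signal = no_signal


@dataclass
class Signature:
    """An ordered gene-pair signature with the zero-reversal rule."""

    name: str
    pairs: list[GenePair]
    labels: tuple[str, str] = ("low-risk", "high-risk")  # (favorable, unfavorable)
    provenance: dict = field(default_factory=dict)
    directions_known: bool = True

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("signature must contain at least one pair")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("signature contains duplicate pairs")

    def genes(self) -> set[str]:
        return {g for p in self.pairs for g in (p.gene_a, p.gene_b)}

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "labels": list(self.labels),
            "directions_known": self.directions_known,
            "pairs": [
                {"gene_a": p.gene_a, "gene_b": p.gene_b, "direction": "a>b"}
                for p in self.pairs
            ],
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "Signature":
        return cls(
            name=d["name"],
            pairs=[GenePair(p["gene_a"], p["gene_b"]) for p in d["pairs"]],
            labels=tuple(d.get("labels", ("low-risk", "high-risk"))),
            provenance=d.get("provenance", {}),
            directions_known=bool(d.get("directions_known", True)),
        )

    @classmethod
    def from_json(cls, path) -> "Signature":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"gene_a": [p.gene_a for p in self.pairs],
             "gene_b": [p.gene_b for p in self.pairs]}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class CandidatePair:
    pair: GenePair
    cox: CoxResult
    q: float


@dataclass
class DiscoveryParams:
    fdr_pathway: float = 0.05
    rho_min: float = 0.6
    fdr_pair: float = 0.10
    min_pathway_pairs: int = 5


def screen_candidate_pairs(
    core_pairs: Sequence[GenePair],
    tumor: ExpressionMatrix,
    surv: SurvivalTable,
    fdr: float = 0.10,
) -> list[CandidatePair]:
    """Cox screen of pair reversal statuses against survival.

    BH-FDR is computed across all tested pairs first; retained candidates
    additionally require hazard ratio > 1 (reversal = worse outcome).  Pairs
    with constant reversal status are not tested.
    """
    core_pairs = list(dict.fromkeys(core_pairs))
    if not core_pairs:
        raise ValueError("empty candidate pair list")
    if tumor.sample_ids != list(surv.sample_ids):
        surv = surv.align_to(tumor.sample_ids)
    rev = reversal_status(tumor, core_pairs)
    tested: list[tuple[GenePair, CoxResult]] = []
    for pair, row in zip(rev.pairs, rev.status):
        if row.min() == row.max():
            continue
        res = cox_univariate(row.astype(float), surv)
        if not res.converged or not np.isfinite(res.p_wald):
            continue
        tested.append((pair, res))
    if not tested:
        return []
    q = bh_fdr([r.p_wald for _, r in tested])
    out = [
        CandidatePair(pair, res, float(qi))
        for (pair, res), qi in zip(tested, q)
        if qi < fdr and res.hr > 1.0
    ]
    out.sort(key=lambda c: (c.q, c.cox.p_wald, c.pair))
    return out


def classify_by_signature(rev: ReversalMatrix, signature: Signature) -> np.ndarray:
    """Label each sample: favorable iff all signature-pair statuses are 0."""
    if not signature.directions_known:
        raise ValueError(
            f"signature {signature.name!r} has unbound pair directions; "
            "bind them against a normal-tissue stable-pair set first"
        )
    sub = rev.subset_pairs(signature.pairs)
    unfavorable = sub.status.any(axis=0)
    fav, unfav = signature.labels
    return np.where(unfavorable, unfav, fav)


def _binary_c(status_any: np.ndarray, surv: SurvivalTable) -> float:
    return harrell_c(status_any.astype(float), surv).c


def forward_stepwise_select(
    candidates: Sequence[CandidatePair],
    rev: ReversalMatrix,
    surv: SurvivalTable,
    eps: float = 1e-10,
) -> tuple[Signature, list[tuple[int, GenePair, float]]]:
    """Greedy C-index maximisation of the zero-reversal classification.

    The seed is the single pair with the largest C (ties: larger hazard
    ratio, then lexicographic pair).  Pairs are added one at a time while the
    best addition improves C by more than ``eps``.  Returns the signature and
    the step trace [(step, pair, c)].
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate pairs to select from")
    if rev.sample_ids != list(surv.sample_ids):
        surv = surv.align_to(rev.sample_ids)
    status = {c.pair: rev.row(c.pair) for c in candidates}

    # seed tie-break: max C, then max HR, then lexicographically smallest pair
    scored = [(_binary_c(status[c.pair], surv), c) for c in candidates]
    top = max(s for s, _ in scored)
    pool = [c for s, c in scored if s == top]
    top_hr = max(c.cox.hr for c in pool)
    pool = [c for c in pool if c.cox.hr == top_hr]
    seed = min(pool, key=lambda c: (c.pair.gene_a, c.pair.gene_b))
    best_c = top

    selected = [seed]
    current = status[seed.pair].copy().astype(bool)
    trace = [(0, seed.pair, best_c)]
    remaining = [c for c in candidates if c.pair != seed.pair]
    step = 0
    while remaining:
        step += 1
        trial = []
        for c in remaining:
            combined = current | status[c.pair].astype(bool)
            if combined.min() == combined.max():
                continue  # saturated classification carries no ordering
            trial.append((_binary_c(combined, surv), c))
        if not trial:
            break
        top = max(s for s, _ in trial)
        if top <= best_c + eps:
            break
        pool = [c for s, c in trial if s == top]
        top_hr = max(c.cox.hr for c in pool)
        pool = [c for c in pool if c.cox.hr == top_hr]
        chosen = min(pool, key=lambda c: (c.pair.gene_a, c.pair.gene_b))
        selected.append(chosen)
        current |= status[chosen.pair].astype(bool)
        best_c = top
        trace.append((step, chosen.pair, best_c))
        remaining = [c for c in remaining if c.pair != chosen.pair]

    sig = Signature(
        name="discovered",
        pairs=[c.pair for c in selected],
        provenance={"c_index": best_c, "n_candidates": len(candidates)},
    )
    return sig, trace


def discover_signature(
    tumor: ExpressionMatrix,
    surv: SurvivalTable,
    stable: StablePairSet,
    pathways: PathwayCollection,
    params: DiscoveryParams | None = None,
    labels: tuple[str, str] = ("low-risk", "high-risk"),
    name: str = "discovered",
) -> Signature:
    """Full discovery chain: pathway disruption -> survival screen -> core
    network -> pair screen -> greedy selection.  Deterministic given inputs."""
    params = params or DiscoveryParams()
    surv = surv.align_to(tumor.sample_ids)

    dis = compute_disruption_matrix(tumor, pathways, stable, min_pairs=1)
    if len(dis.pathway_names) == 0:
        raise PipelineError("disruption", "no pathway has stable intra-pathway pairs")

    screen = screen_rfs_pathways(dis, surv, fdr=params.fdr_pathway,
                                 min_pairs=params.min_pathway_pairs)
    selected = screen.loc[screen["selected"], "pathway"].tolist()
    if len(selected) == 0:
        raise PipelineError("pathway_screen", "no survival-relevant pathways",
                            no_signal=True)
    if len(selected) < 2:
        raise PipelineError("core_network",
                            "fewer than two survival-relevant pathways",
                            no_signal=True)

    core, _edges = core_pathway_network(dis.subset(selected),
                                        rho_min=params.rho_min, fdr=params.fdr_pathway)
    if not core:
        raise PipelineError("core_network", "no correlated pathway core",
                            no_signal=True)

    ppairs = pathway_stable_pairs(pathways, stable)
    core_pairs = list(dict.fromkeys(p for name_ in sorted(core) for p in ppairs[name_]))
    if not core_pairs:
        raise PipelineError("candidate_screen", "core pathways have no stable pairs")

    candidates = screen_candidate_pairs(core_pairs, tumor, surv, fdr=params.fdr_pair)
    if not candidates:
        raise PipelineError("candidate_screen",
                            "no pair reversal is associated with poor survival",
                            no_signal=True)

    rev = reversal_status(tumor, [c.pair for c in candidates])
    sig, trace = forward_stepwise_select(candidates, rev, surv)
    sig.name = name
    sig.labels = labels
    sig.provenance.update(
        {
            "fdr_pathway": params.fdr_pathway,
            "rho_min": params.rho_min,
            "fdr_pair": params.fdr_pair,
            "n_core_pathways": len(core),
            "n_candidates": len(candidates),
            "n_samples": len(surv),
            "trace": [(s, p.gene_a, p.gene_b, c) for s, p, c in trace],
        }
    )
    return sig
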