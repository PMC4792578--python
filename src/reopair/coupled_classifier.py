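"""Sequential application of two gene-pair signatures.

Stage one flags patients whose recurrence risk is low without adjuvant
therapy (no reversed pair of the recurrence-risk signature).  The remaining
high-risk patients are split by the second signature into a predicted
therapy-benefit group (no reversed pair) and a non-benefit group.  The same
two-stage logic drives coupled discovery: the second signature is discovered
only on samples the first signature calls high-risk.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .reo_core import ExpressionMatrix, GenePair, ReversalMatrix, StablePairSet, reversal_status
from .pathway_analysis import PathwayCollection
from .signature_discovery import (
    DiscoveryParams,
    PipelineError,
    Signature,
    classify_by_signature,
    discover_signature,
)
from .survival_stats import SurvivalTable, cox_univariate, km_curve, km_logrank

__all__ = [
    "ThreeGroupLabel",
    "stratify",
    "discover_coupled",
    "evaluate_groups",
    "load_published_signature",
    "bind_directions",
]


class ThreeGroupLabel(str, enum.Enum):
    DRUG_FREE_LOW_RISK = "drug_free_low_risk"
    TAMOXIFEN_BENEFIT = "tamoxifen_benefit"
    TAMOXIFEN_NON_BENEFIT = "tamoxifen_non_benefit"


def stratify(
    rev_drug_free: ReversalMatrix, rev_benefit: ReversalMatrix
) -> list[ThreeGroupLabel]:
    """Three-way stratification from the two signatures' reversal matrices.

    Low-risk (no reversed recurrence-risk pair) wins outright; among the
    rest, no reversed benefit pair means predicted treatment benefit.
    """
    if rev_drug_free.sample_ids != rev_benefit.sample_ids:
        raise ValueError("the two reversal matrices cover different samples")
    risk_unfav = rev_drug_free.status.any(axis=0)
    benefit_fav = ~rev_benefit.status.any(axis=0)
    labels = []
    for high_risk, benefit in zip(risk_unfav, benefit_fav):
        if not high_risk:
            labels.append(ThreeGroupLabel.DRUG_FREE_LOW_RISK)
        elif benefit:
            labels.append(ThreeGroupLabel.TAMOXIFEN_BENEFIT)
        else:
            labels.append(ThreeGroupLabel.TAMOXIFEN_NON_BENEFIT)
    return labels


def discover_coupled(
    drug_free_cohort: tuple[ExpressionMatrix, SurvivalTable],
    treated_cohort: tuple[ExpressionMatrix, SurvivalTable],
    stable: StablePairSet,
    pathways: PathwayCollection,
    params: DiscoveryParams | None = None,
    min_stage2: int = 40,
) -> tuple[Signature, Signature, list[str]]:
    """Two-stage discovery.

    Stage 1 learns a recurrence-risk signature on the untreated cohort.
    Stage 2 classifies the treated cohort with it, keeps the high-risk
    subset, and learns a benefit signature there.  Returns both signatures
    and the stage-2 sample ids.
    """
    expr1, surv1 = drug_free_cohort
    expr2, surv2 = treated_cohort
    sig1 = discover_signature(
        expr1, surv1, stable, pathways, params,
        labels=("low-risk", "high-risk"), name="recurrence_risk",
    )
    rev2 = reversal_status(expr2, sig1.pairs)
    grp = classify_by_signature(rev2, sig1)
    high_ids = [s for s, g in zip(expr2.sample_ids, grp) if g == sig1.labels[1]]
    if len(high_ids) == 0:
        raise PipelineError("stage2_subset", "empty discovery subset: "
                            "stage-1 signature flags no high-risk samples")
    if len(high_ids) < min_stage2:
        raise PipelineError(
            "stage2_subset",
            f"stage-2 discovery subset has {len(high_ids)} samples (< {min_stage2})",
        )
    sig2 = discover_signature(
        expr2.subset_samples(high_ids),
        surv2.align_to(high_ids),
        stable,
        pathways,
        params,
        labels=("benefit", "non-benefit"),
        name="treatment_benefit",
    )
    return sig1, sig2, high_ids


def evaluate_groups(
    labels: Sequence[ThreeGroupLabel],
    surv: SurvivalTable,
    treated: Sequence[int],
) -> dict:
    """Survival report for a three-group stratification.

    Per-group KM curves, pairwise log-rank tests, and within each group the
    treated-vs-untreated Cox hazard ratio.  Contrasts that are not estimable
    (no events, single arm, single sample) are flagged rather than raised.
    """
    labels = np.asarray([ThreeGroupLabel(l) for l in labels], dtype=object)
    treated = np.asarray(treated, dtype=int)
    if not (len(labels) == len(surv) == len(treated)):
        raise ValueError("labels, survival table and treatment vector misaligned")

    report: dict = {"groups": {}, "pairwise_logrank": {}, "treatment_effects": {}}
    def _mask(lab):
        # numpy stringifies an Enum scalar before comparing, so == on the
        # object array silently yields all-False; compare explicitly
        return np.array([l == lab for l in labels], dtype=bool)

    for lab in ThreeGroupLabel:
        mask = _mask(lab)
        report["groups"][lab.value] = {
            "n": int(mask.sum()),
            "n_events": int(surv.event[mask].sum()),
            "km": km_curve(surv.time[mask], surv.event[mask]) if mask.any() else None,
        }
    pairs = [
        (ThreeGroupLabel.DRUG_FREE_LOW_RISK, ThreeGroupLabel.TAMOXIFEN_BENEFIT),
        (ThreeGroupLabel.DRUG_FREE_LOW_RISK, ThreeGroupLabel.TAMOXIFEN_NON_BENEFIT),
        (ThreeGroupLabel.TAMOXIFEN_BENEFIT, ThreeGroupLabel.TAMOXIFEN_NON_BENEFIT),
    ]
    for a, b in pairs:
        key = f"{a.value}_vs_{b.value}"
        mask = _mask(a) | _mask(b)
        sub_labels = labels[mask]
        if len({l for l in sub_labels}) < 2 or mask.sum() < 3:
            report["pairwise_logrank"][key] = {"estimable": False}
            continue
        sub = SurvivalTable(
            [surv.sample_ids[i] for i in np.nonzero(mask)[0]],
            surv.time[mask], surv.event[mask],
        )
        try:
            res = km_logrank([l.value for l in sub_labels], sub)
            report["pairwise_logrank"][key] = {
                "estimable": True, "chi2": res["chi2"], "p": res["p"],
            }
        except ValueError:
            report["pairwise_logrank"][key] = {"estimable": False}
    for lab in ThreeGroupLabel:
        mask = _mask(lab)
        entry: dict = {"estimable": False}
        if mask.sum() >= 2:
            tr = treated[mask]
            sub = SurvivalTable(
                [surv.sample_ids[i] for i in np.nonzero(mask)[0]],
                surv.time[mask], surv.event[mask],
            )
            if 0 < tr.sum() < len(tr) and sub.n_events >= 2:
                try:
                    cox = cox_univariate(tr.astype(float), sub)
                    lr = km_logrank(tr, sub)
                    entry = {
                        "estimable": True,
                        "hr": cox.hr, "ci_low": cox.ci_low, "ci_high": cox.ci_high,
                        "p_wald": cox.p_wald, "logrank_p": lr["p"],
                        "n_treated": int(tr.sum()), "n_untreated": int(len(tr) - tr.sum()),
                    }
                except ValueError:
                    pass
        report["treatment_effects"][lab.value] = entry
    return report


# ---------------------------------------------------------------------------
# bundled reference signatures (ER+ breast cancer, Entrez gene ids)
#
# The published tables list which genes form each pair but not which gene of
# a pair sits higher in normal tissue, so the fixtures load with
# directions_known=False and must be bound to a user-supplied stable-pair
# set before they can classify anything.

_PUBLISHED = {
    "drug_free": {
        "labels": ("low-risk", "high-risk"),
        "pairs": [
            ("55182", "RNF220", "27338", "UBE2S"),
            ("6124", "RPL4", "3315", "HSPB1"),
            ("7327", "UBE2G2", "51588", "PIAS4"),
            ("22794", "CASC3", "23658", "LSM5"),
            ("6205", "RPS11", "9861", "PSMD6"),
            ("896", "CCND3", "983", "CDK1"),
            ("5689", "PSMB1", "27338", "UBE2S"),
            ("1021", "CDK6", "990", "CDC6"),
            ("5707", "PSMD1", "27338", "UBE2S"),
        ],
    },
    "benefit": {
        "labels": ("benefit", "non-benefit"),
        "pairs": [
            ("1843", "DUSP1", "983", "CDK1"),
            ("8440", "NCK2", "983", "CDK1"),
            ("2908", "NR3C1", "58", "ACTA1"),
            ("2625", "GATA3", "581", "BAX"),
            ("1845", "DUSP3", "7204", "TRIO"),
            ("8878", "SQSTM1", "835", "CASP2"),
            ("8660", "IRS2", "5153", "PDE1B"),
            ("6196", "RPS6KA2", "30849", "PIK3R4"),
            ("1997", "ELF1", "983", "CDK1"),
            ("9146", "HGS", "983", "CDK1"),
        ],
    },
}


def load_published_signature(name: str) -> Signature:
    """Load a bundled reference signature ("drug_free": 9 pairs,
    "benefit": 10 pairs).  Pair directions are unbound; see
    :func:`bind_directions`."""
    if name not in _PUBLISHED:
        raise KeyError(f"unknown signature {name!r}; choose from {sorted(_PUBLISHED)}")
    entry = _PUBLISHED[name]
    pairs = [GenePair(a, b) for a, _, b, _ in entry["pairs"]]
    symbols = {a: sa for a, sa, b, sb in entry["pairs"]}
    symbols.update({b: sb for a, sa, b, sb in entry["pairs"]})
    return Signature(
        name=name,
        pairs=pairs,
        labels=entry["labels"],
        provenance={"source": "published", "gene_symbols": symbols},
        directions_known=False,
    )


def bind_directions(signature: Signature, stable: StablePairSet) -> Signature:
    """Orient a direction-unbound signature against a normal-tissue
    stable-pair set; errors if any pair is absent from it."""
    dmap = stable.direction_map()
    bound = []
    missing = []
    for p in signature.pairs:
        key = p.unordered
        if key not in dmap:
            missing.append(key)
        else:
            a, b = dmap[key]
            bound.append(GenePair(a, b))
    if missing:
        raise ValueError(
            f"cannot bind {signature.name!r}: pairs absent from the "
            f"stable-pair set: {missing}"
        )
    return Signature(
        name=signature.name,
        pairs=bound,
        labels=signature.labels,
        provenance={**signature.provenance, "directions_bound": True},
        directions_known=True,
    )
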