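"""Synthetic cohorts with the structure the pipeline assumes.

Normal samples share one consensus expression ordering plus Gaussian noise,
so well-separated gene pairs are stable across almost all samples.  Tumour
samples start from the same consensus; designated ("planted") pairs have
their two genes' values swapped with a per-sample Bernoulli probability,
which flips the pair's ordering without touching marginal distributions.
Recurrence times are exponential with hazard multiplied by a planted hazard
ratio per reversed prognostic pair, and by a treatment hazard ratio for
treated samples inside the planted benefit stratum (samples whose benefit
pair keeps its normal ordering).  Every artifact draws from its own RNG
stream derived from the master seed, so adding one artifact never perturbs
another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .reo_core import ExpressionMatrix, GenePair
from .pathway_analysis import PathwayCollection
from .survival_stats import SurvivalTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_normal",
    "simulate_tumor",
    "simulate_pathways",
    "simulate_cohort",
    "write_cohort",
]

# fixed RNG stream offsets (one stream per artifact)
_STREAM_CONSENSUS = 0
_STREAM_NORMAL = 1
_STREAM_TUMOR = 2
_STREAM_SURVIVAL = 3
_STREAM_PATHWAYS = 4


@dataclass
class SimulationConfig:
    n_genes: int = 500
    n_normal: int = 150
    n_tumor: int = 300
    noise_sd: float = 0.5
    n_pathways: int = 30
    pathway_size_min: int = 10
    pathway_size_max: int = 40
    n_signal_pathways: int = 3
    n_planted_pairs: int = 3
    reversal_prob: float = 0.3
    prognostic_hr: float = 4.0
    benefit_pair: bool = False
    benefit_reversal_prob: float = 0.4
    treatment_hr: float = 0.4
    baseline_hazard: float = 0.01  # per month
    censor_rate: float = 0.3
    treated_fraction: float = 0.5
    seed: int = 0
    cohort_id: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_normal", "n_tumor", "n_pathways",
                     "pathway_size_min", "pathway_size_max",
                     "n_signal_pathways", "n_planted_pairs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("reversal_prob", "benefit_reversal_prob",
                     "censor_rate", "treated_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("noise_sd", "prognostic_hr", "treatment_hr", "baseline_hazard"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.pathway_size_max < self.pathway_size_min:
            raise ValueError("pathway_size_max < pathway_size_min")
        if self.pathway_size_max > self.n_genes:
            raise ValueError("pathway size exceeds number of genes")
        needed = 2 * self.n_planted_pairs + (2 if self.benefit_pair else 0)
        if needed > self.n_genes:
            raise ValueError("planted genes exceed n_genes")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class GroundTruth:
    """Generator-side truth for recovery tests."""

    consensus: dict[str, float]
    planted_pairs: list[GenePair]
    planted_hr: float
    reversal_prob: float
    benefit_pair: GenePair | None = None
    treatment_hr: float | None = None
    reversal_states: np.ndarray | None = None  # planted pairs x tumor samples
    benefit_reversed: np.ndarray | None = None
    benefit_member: np.ndarray | None = None
    treated: np.ndarray | None = None
    tumor_sample_ids: list[str] = field(default_factory=list)
    pathway_overlap: dict = field(default_factory=dict)

    def to_manifest(self) -> dict:
        return {
            "planted_pairs": [[p.gene_a, p.gene_b] for p in self.planted_pairs],
            "planted_hr": self.planted_hr,
            "reversal_prob": self.reversal_prob,
            "benefit_pair": (
                [self.benefit_pair.gene_a, self.benefit_pair.gene_b]
                if self.benefit_pair else None
            ),
            "treatment_hr": self.treatment_hr,
            "tumor_sample_ids": self.tumor_sample_ids,
            "reversal_states": (
                self.reversal_states.tolist() if self.reversal_states is not None else None
            ),
            "benefit_member": (
                self.benefit_member.tolist() if self.benefit_member is not None else None
            ),
            "treated": self.treated.tolist() if self.treated is not None else None,
            "pathway_overlap": self.pathway_overlap,
        }


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(n)]


def _consensus_and_pairs(config: SimulationConfig):
    """Consensus expression plus planted pairs in reserved bands.

    Non-planted genes draw uniform consensus values on [2, 14].  Each planted
    pair occupies its own band above that range: the two genes sit a fixed
    gap apart with guard margins so that (a) the pair is stable in normals
    with overwhelming probability and (b) swapping the two genes' values in a
    tumour flips that pair's ordering and no other stable pair's.
    """
    rng = np.random.default_rng([config.seed, _STREAM_CONSENSUS])
    genes = _gene_ids(config.n_genes)
    mu = rng.uniform(2.0, 14.0, size=config.n_genes)
    n_pairs = config.n_planted_pairs + (1 if config.benefit_pair else 0)
    gap = 7.0 * config.noise_sd
    margin = 4.0 * config.noise_sd
    chosen = rng.choice(config.n_genes, size=2 * n_pairs, replace=False)
    pairs = []
    base = 14.0 + margin
    for i in range(n_pairs):
        lo_val = base + i * (gap + 2.0 * margin)
        hi_val = lo_val + gap
        hi_idx, lo_idx = chosen[2 * i], chosen[2 * i + 1]
        mu[hi_idx] = hi_val
        mu[lo_idx] = lo_val
        pairs.append(GenePair(genes[hi_idx], genes[lo_idx]))
    planted = pairs[: config.n_planted_pairs]
    benefit = pairs[config.n_planted_pairs] if config.benefit_pair else None
    return genes, mu, planted, benefit


def simulate_normal(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Normal-tissue cohort: consensus + iid Gaussian noise."""
    genes, mu, planted, benefit = _consensus_and_pairs(config)
    rng = np.random.default_rng([config.seed, _STREAM_NORMAL])
    values = mu[:, None] + rng.normal(0.0, config.noise_sd, (config.n_genes, config.n_normal))
    samples = [f"n{i:04d}" for i in range(config.n_normal)]
    truth = GroundTruth(
        consensus=dict(zip(genes, mu)),
        planted_pairs=planted,
        planted_hr=config.prognostic_hr,
        reversal_prob=config.reversal_prob,
        benefit_pair=benefit,
        treatment_hr=config.treatment_hr if config.benefit_pair else None,
    )
    return ExpressionMatrix(genes, samples, values), truth


def _calibrate_censor_tmax(event_times: np.ndarray, censor_rate: float) -> float:
    """Uniform-censoring horizon T with mean P(C < t_i) = censor_rate,
    solved by bisection on the drawn event times."""

    def frac(tmax: float) -> float:
        return float(np.minimum(event_times / tmax, 1.0).mean())

    lo, hi = 1e-6, float(event_times.max()) * 2 + 1e-6
    while frac(hi) > censor_rate:
        hi *= 2.0
        if hi > 1e12:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > censor_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_tumor(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[ExpressionMatrix, SurvivalTable, GroundTruth]:
    """Tumour cohort with planted reversals driving an exponential hazard."""
    genes = list(truth.consensus)
    mu = np.array([truth.consensus[g] for g in genes])
    gidx = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng([config.seed, config.cohort_id, _STREAM_TUMOR])
    n = config.n_tumor
    values = mu[:, None] + rng.normal(0.0, config.noise_sd, (config.n_genes, n))

    all_pairs = list(truth.planted_pairs)
    probs = [config.reversal_prob] * len(truth.planted_pairs)
    if truth.benefit_pair is not None:
        all_pairs.append(truth.benefit_pair)
        probs.append(config.benefit_reversal_prob)
    states = np.zeros((len(all_pairs), n), dtype=np.uint8)
    for r, (pair, prob) in enumerate(zip(all_pairs, probs)):
        flip = rng.random(n) < prob
        ia, ib = gidx[pair.gene_a], gidx[pair.gene_b]
        va = values[ia, flip].copy()
        values[ia, flip] = values[ib, flip]
        values[ib, flip] = va
        states[r] = flip

    n_prog = len(truth.planted_pairs)
    prog_states = states[:n_prog]
    benefit_reversed = (
        states[n_prog] if truth.benefit_pair is not None else np.zeros(n, np.uint8)
    )
    benefit_member = benefit_reversed == 0

    srng = np.random.default_rng([config.seed, config.cohort_id, _STREAM_SURVIVAL])
    treated = (srng.random(n) < config.treated_fraction).astype(int)
    hazard = config.baseline_hazard * config.prognostic_hr ** prog_states.sum(axis=0)
    if truth.benefit_pair is not None:
        hazard = hazard * np.where(
            (treated == 1) & benefit_member, config.treatment_hr, 1.0
        )
    event_times = srng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        tmax = _calibrate_censor_tmax(event_times, config.censor_rate)
        censor_times = srng.uniform(0.0, tmax, n)
        time = np.minimum(event_times, censor_times)
        event = (event_times <= censor_times).astype(int)
    else:
        time, event = event_times, np.ones(n, dtype=int)
    time = np.maximum(time, 1e-6)

    samples = [f"c{config.cohort_id}t{i:04d}" for i in range(n)]
    expr = ExpressionMatrix(genes, samples, values)
    surv = SurvivalTable(
        samples, time, event,
        covariates=pd.DataFrame({"treated": treated}),
    )
    out = dataclasses.replace(
        truth,
        reversal_states=prog_states,
        benefit_reversed=benefit_reversed,
        benefit_member=benefit_member,
        treated=treated,
        tumor_sample_ids=samples,
    )
    return expr, surv, out


def simulate_pathways(config: SimulationConfig, truth: GroundTruth) -> PathwayCollection:
    """Random gene sets plus designated signal pathways that co-annotate all
    planted pairs (different filler genes per signal pathway)."""
    rng = np.random.default_rng([config.seed, _STREAM_PATHWAYS])
    genes = np.array(list(truth.consensus), dtype=object)
    planted_genes = [g for p in truth.planted_pairs for g in (p.gene_a, p.gene_b)]
    if truth.benefit_pair is not None:
        planted_genes += [truth.benefit_pair.gene_a, truth.benefit_pair.gene_b]
    planted_genes = list(dict.fromkeys(planted_genes))
    others = np.array([g for g in genes if g not in set(planted_genes)], dtype=object)

    sets: dict[str, list[str]] = {}
    n_signal = min(config.n_signal_pathways, config.n_pathways)
    for i in range(n_signal):
        size = int(rng.integers(config.pathway_size_min, config.pathway_size_max + 1))
        n_fill = max(0, size - len(planted_genes))
        fillers = rng.choice(others, size=min(n_fill, len(others)), replace=False)
        sets[f"SIGNAL_PW{i:03d}"] = planted_genes + fillers.tolist()
    for i in range(config.n_pathways - n_signal):
        size = int(rng.integers(config.pathway_size_min, config.pathway_size_max + 1))
        members = rng.choice(others, size=min(size, len(others)), replace=False)
        sets[f"RANDOM_PW{i:03d}"] = members.tolist()

    # overlap bookkeeping for the manifest (disjointness is not enforced)
    names = list(sets)
    overlaps = 0
    for i in range(len(names)):
        si = set(sets[names[i]])
        for j in range(i + 1, len(names)):
            if si & set(sets[names[j]]):
                overlaps += 1
    truth.pathway_overlap = {
        "n_pathways": len(names),
        "n_overlapping_set_pairs": overlaps,
    }
    return PathwayCollection(sets, source="simulated")


def simulate_cohort(config: SimulationConfig):
    """Convenience: normal + tumour + pathways + ground truth in one call."""
    normal, truth = simulate_normal(config)
    tumor, surv, truth = simulate_tumor(config, truth)
    pathways = simulate_pathways(config, truth)
    return {
        "normal": normal,
        "tumor": tumor,
        "survival": surv,
        "pathways": pathways,
        "truth": truth,
    }


def write_cohort(config: SimulationConfig, outdir) -> None:
    """Write matrix/clinical TSVs, a GMT file and ground_truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config)
    cohort["normal"].to_tsv(outdir / "normal.tsv")
    cohort["tumor"].to_tsv(outdir / "tumor.tsv")
    cohort["survival"].to_tsv(outdir / "clinical.tsv")
    cohort["pathways"].to_gmt(outdir / "pathways.gmt")
    config.to_yaml(outdir / "config.yaml")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(cohort["truth"].to_manifest(), fh, indent=2)
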