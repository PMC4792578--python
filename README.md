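# reopair

Rank-based gene-pair survival signatures built on within-sample relative
expression orderings (REOs). Because only the ordering of two genes *inside
one sample* is consumed, every classification is invariant to per-sample
monotone normalisation and robust to batch effects, and samples from
different datasets can be pooled without renormalisation.

The package implements the full pipeline:

1. **Stable pairs** (`reo_core`) — gene pairs whose ordering holds in more
   than a threshold fraction (default 99%, strict) of normal-tissue samples;
   cross-cohort intersection with an exact log-space binomial consistency
   test; tumour reversal matrices.
2. **Survival primitives** (`survival_stats`) — Cox proportional hazards
   (Efron ties, Newton–Raphson), Kaplan–Meier + log-rank, Harrell's C-index
   by pair enumeration, Benjamini–Hochberg FDR, Spearman tests (exact
   permutation p for n ≤ 10), and a two-cohort DEG direction-concordance
   check.
3. **Pathway disruption** (`pathway_analysis`) — per-sample fraction of a
   pathway's stable pairs that are reversed; univariate Cox screening of
   disruption indexes against recurrence-free survival; extraction of the
   correlated "core" pathway set via a Spearman network (edges rho > 0.6,
   FDR < 5%; core = largest connected component).
4. **Signature discovery** (`signature_discovery`) — Cox screening of pair
   reversals (FDR < 10%, HR > 1) followed by forward-stepwise C-index
   maximisation under the zero-reversal rule: a sample is favorable iff none
   of the signature pairs is reversed.
5. **Coupled classification** (`coupled_classifier`) — sequential
   application of a recurrence-risk signature and a treatment-benefit
   signature to produce three groups (drug-free low-risk / benefit /
   non-benefit); two-stage coupled discovery; bundled published 9-pair and
   10-pair ER+ breast-cancer signatures (directions unbound — bind against a
   normal-tissue stable-pair set before classifying).
6. **Simulation** (`synthetic_data`) — fully reproducible cohorts with a
   consensus normal ordering, planted reversible pairs driving an
   exponential hazard, a planted treatment-benefit stratum, pathway GMTs and
   a ground-truth manifest for recovery tests.

## Command line

```bash
reopair simulate --config sim.yaml --outdir data/       # or defaults + --seed
reopair stable-pairs --normal data/normal.tsv -o pairs.tsv
reopair consistency --set1 a.tsv --set2 b.tsv
reopair disrupt --tumor data/tumor.tsv --stable pairs.tsv \
        --gmt data/pathways.gmt -o dis.tsv
reopair screen-pathways --dis dis.tsv --clinical data/clinical.tsv -o core.txt
reopair discover --tumor data/tumor.tsv --clinical data/clinical.tsv \
        --stable pairs.tsv --gmt data/pathways.gmt -o sig.json
reopair classify --tumor data/tumor.tsv --sig1 sig.json [--sig2 sig2.json] \
        -o labels.tsv
reopair discover-coupled --tumor1 ut.tsv --clinical1 c1.tsv \
        --tumor2 tt.tsv --clinical2 c2.tsv --stable pairs.tsv \
        --gmt pathways.gmt -o sigs/
reopair survdiff --clinical data/clinical.tsv --groups labels.tsv
reopair cox --clinical data/clinical.tsv --risk labels.tsv --covariates treated
```

Exit code 3 from `discover`/`discover-coupled`/`screen-pathways` signals a
clean "no signal" outcome (nothing survives the screens), distinct from
usage or data errors.

## File formats

- Expression matrix: TSV, first column `gene_id`, one column per sample,
  log2 scale, no missing values (optional per-gene median imputation).
- Clinical table: TSV with `sample_id`, `time_months`, `event` plus optional
  covariates (`age`, `grade`, `size_cm`, `node`, `treated`).
- Stable pairs: TSV `gene_a`, `gene_b`, `support` (direction = a > b).
- Gene sets: standard GMT.
- Signatures: JSON (`name`, `labels`, `pairs`, `provenance`).

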