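# engraftment

Quantification of fecal-microbiota-transplant (FMT) engraftment from 16S
amplicon (ASV) count tables, for microbiome researchers studying humanized
gnotobiotic mouse models: how much of a donor community actually colonizes a
recipient, how consistently it does so across recipients, and how the
recipient host environment reshapes it.

## What it computes

All analyses run on depth-scaled log10 abundances. A raw count *c* in a
sample of total depth *T* is normalized as

    y = log10( c / T * D̄ + 1 )

where *D̄* is the arithmetic mean sequencing depth over the samples in the
analysis; rescaling to a common depth before the +1 pseudo-count gives the
pseudo-count a comparable effect across samples, and a zero count maps to
exactly 0.

On this scale the package provides:

- **Transfer efficiency** — Pearson *r* of normalized ASV abundances between
  an FMT input and each recipient, summarized as mean ± SD over pairs; at
  ASV, genus or phylum level, optionally stratified by phylum.
- **Engraftment consistency** — mean pairwise *r* among recipients of one
  group (low values = high mouse-to-mouse variability).
- **Transfer-fate classification** — every ASV labelled transferred,
  non-transferring (in the input, absent in the recipient) or newly detected
  in vivo, with abundance histograms of the failing classes.
- **Community ecology** — Shannon diversity (nats), Bray–Curtis
  dissimilarity, PCoA (negative eigenvalues reported, not hidden), one-way
  PERMANOVA with permutation *p*-values.
- **Differential abundance** — pairwise Wilcoxon rank-sum tests at a chosen
  rank with a 10% prevalence filter applied *before* testing and
  Benjamini–Hochberg FDR within each comparison.
- **A synthetic engraftment simulator** — donor communities, a logistic
  abundance-dependent engraftment bottleneck, inflammation-dependent
  reassembly (pathobiont blooms, suppressed protective taxa, noisier
  recipients), serial passage and multinomial sequencing, with full ground
  truth for every recipient. Calibrated scenario constants are versioned in
  `src/engraftment/scenarios/`.

## Worked example

```python
import engraftment as eg

human   = eg.simulate_study("human_to_mouse", seed=1)
adapted = eg.simulate_study("mouse_adapted",  seed=1)

eff_h = eg.between_group_efficiency(human.bundle,   "HM_input",   "HM->WT")
eff_m = eg.between_group_efficiency(adapted.bundle, "NIMM_input", "NIMM-g2->WT")
print(f"human -> mouse: r = {eff_h.mean_r:.3f} +/- {eff_h.sd_r:.3f}")
print(f"passage:        r = {eff_m.mean_r:.3f} +/- {eff_m.sd_r:.3f}")
```

prints

```
human -> mouse: r = 0.318 +/- 0.047
passage:        r = 0.853 +/- 0.030
```

— the human-to-mouse bottleneck leaves input and recipient communities only
weakly correlated, while an already mouse-adapted community passages almost
faithfully. On the same simulated study, PERMANOVA of the recipient groups
(inflamed vs non-inflamed host) gives `R2 = 0.43, p = 0.001`
(`examples/community_analysis.py`): the host environment explains a large
fraction of the compositional variance among recipients.

The `examples/` directory has one short script per capability
(`transfer_efficiency.py`, `classify_fates.py`, `community_analysis.py`,
`differential_abundance.py`, `full_pipeline.py`); each builds a small
simulated input, runs one analysis and explains its printed numbers.

## Command line

A thin CLI (`engraft`) wraps the library for shell use on QIIME2-style TSV
exports (`counts.tsv`, `taxonomy.tsv`, `metadata.tsv`):

```bash
engraft simulate --scenario human_to_mouse --seed 7 --out-dir sim/
engraft efficiency --counts sim/counts.tsv --taxonomy sim/taxonomy.tsv \
    --metadata sim/metadata.tsv --input-group HM_input \
    --recipient-group "HM->WT" --out eff.tsv
engraft run --config study.yaml --out-dir results/
```

`engraft run` executes the whole battery from one YAML config and writes a
`report.json` whose config hash, seed and per-file checksums make the run
byte-for-byte reproducible.

## Input formats

- `counts.tsv` — features × samples, first column `feature_id`, integer
  cells (BIOM 1.0 JSON also readable).
- `taxonomy.tsv` — `feature_id<TAB>lineage`, semicolon-delimited ranks with
  optional Silva `d__/p__/…` prefixes.
- `metadata.tsv` — `sample_id, group, role, host_genotype, transplant_event,
  generation, replicate_kind`.
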