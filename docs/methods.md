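# Methods

## Normalization

Counts are transformed to `log10(c/T · D̄ + 1)` with `T` the sample's depth
and `D̄` the arithmetic mean depth. Two properties motivate the form: a zero
count maps to exactly 0, and rescaling each sample to the common depth `D̄`
before adding the pseudo-count gives the +1 the same relative weight in
shallow and deep samples. `D̄` is recomputed over exactly the samples
entering each analysis (and recorded in every output), because subsetting
changes the depth mixture; an explicit `depth_scope` freezes it when a fixed
reference is wanted. The arithmetic (not geometric) mean is used — "average
depth" with no qualifier. Rank-collapsed analyses collapse counts first and
normalize the collapsed table, so genus/phylum values are self-contained
rather than sums of log-transformed ASVs.

## Transfer efficiency and consistency

Transfer efficiency is the Pearson product–moment correlation of normalized
abundances between an input profile and a recipient sample; engraftment
consistency is the same statistic over all k(k−1)/2 unordered pairs within a
recipient group. Summaries are mean ± SD over pairs.

Zero handling is the one genuinely open choice. ASVs absent from *both*
members of a pair carry no information about transfer yet mechanically pull
*r* toward +1 (they sit at the origin of the scatter). The default policy
`drop_joint_zeros` removes them; `keep_all` is provided to measure the
sensitivity of any result to this choice, and the policy used is recorded in
every result object. A pair is declared undefined (an error, never a silent
NaN) when fewer than 3 features survive filtering or a retained vector is
constant.

Input technical replicates are averaged on the normalized scale into a
single profile by default (`per_replicate` keeps them separate; conclusions
should not depend on the mode, and both are recorded). Presence is raw count
≥ 1 — a single read counts as detected, with no abundance floor.

Transfer-fate labels partition the ASV universe: `transferred` (present in
input and recipient), `non_transferring` (input only), `newly_detected`
(recipient only), `absent_both`. Classification is per-recipient by default
because transfer fate is a per-mouse event; a `group_mean` mode supports
figure-style summaries. Histograms of the failing classes use 0.5-log10-unit
bins anchored at 0 (presentational; recorded in the output).

Phylum-stratified efficiency subsets the ASV-level normalized vectors by
phylum (including an `Unclassified` stratum) rather than collapsing counts,
so a stratum's *r* measures how its member ASVs transfer. Strata failing the
3-feature/variance precondition are flagged not-estimable, never dropped.

## Diversity, ordination, PERMANOVA

Shannon entropy uses natural log (nats) on raw proportions. Bray–Curtis is
`Σ|a−b| / Σ(a+b)`; the default ordination computes it on log10-normalized
abundances, which up-weights sub-dominant taxa relative to raw proportions
(a Euclidean-on-log alternative is exposed since no single metric is
canonical). PCoA double-centers `−½D²`, takes the symmetric
eigendecomposition, builds coordinates from positive eigenvalues only and
reports negative eigenvalues untouched — no Lingoes/Cailliez correction, so
metricity violations stay visible. Axis signs are fixed by making the
largest-magnitude coordinate positive, for deterministic output.

PERMANOVA is one-way: pseudo-F from within/between sums of squared
distances, `R² = 1 − SS_within/SS_total`, and `p = (1 + #{F_perm ≥ F_obs}) /
(1 + n_perm)` so p is never 0 (minimum 1/(n_perm+1)); default 999
permutations from a recorded seed, with an exhaustive-enumeration mode for
small n where the exact permutation distribution is enumerable.

## Differential abundance

For each unordered group pair: collapse to the tested rank, restrict to the
pair's samples, drop taxa present in fewer than 10% of those samples
(*strictly* fewer — exactly 10% is retained), run a two-sided Wilcoxon
rank-sum test per retained taxon on relative abundances, BH-adjust within
that pair's taxon family, and flag q < 0.1. The prevalence filter runs
*before* testing, so excluded taxa never enter the BH family; the BH family
is per-pair (not pooled across pairs) because significant-taxon counts are
reported per comparison. The rank-sum statistic uses midranks for ties;
p-values are exact by enumeration of all C(n_a+n_b, n_a) splits for
n_a+n_b ≤ 12, otherwise a normal approximation with tie-corrected variance
and 0.5 continuity correction. When every observation is identical the test
is degenerate and p = 1 by convention. Note the approximation is only
guaranteed within 0.02 of the exact p for groups of ≥ 5 (worst case 0.017 at
5×5 by enumeration; up to 0.088 at 2×2), which is why `auto` mode uses exact
enumeration whenever feasible.

## The simulator

The generator reproduces the statistical structure the analyses assume, with
ground truth attached to every recipient. Its stages, and the defaults of
the `human_to_mouse` scenario (all calibrated constants are versioned in
`scenarios/*.cfg`):

- **Donor**: S = 400 ASVs, proportions from a normalized log-normal with
  shape σ = 2.0 (heavy-tailed, a handful of dominant taxa and a long rare
  tail), partitioned into five named phyla plus an unclassified block with
  nested genus labels. Input slurries are sequenced as 3 technical
  multinomial replicates.
- **Bottleneck**: ASV i engrafts with probability
  `π_i = logistic(α + β·log10 p_i)` (α = 1.5, β = 0.9), so rare taxa fail
  most and moderately abundant taxa still fail often. Masks are marginally
  Bernoulli(π_i) but correlated across recipients of one event through a
  Gaussian copula (ρ = 0.9; 0.6 in the inflamed host): most transfer
  failures are taxon–host properties, not per-mouse accidents, which is what
  makes within-group consistency meaningfully positive. A uniform or
  per-phylum override replaces the logistic for parameter-recovery designs.
- **Reassembly**: retained taxa are reweighted by a per-ASV fitness factor
  drawn once per transplantation event (log-normal, σ = 2.5) plus
  per-recipient log-normal noise (σ = 0.9; 1.5 inflamed). The inflamed mode
  suppresses a designated protective set (Blautia/Lachnoclostridium/
  Faecalibacterium/Roseburia blocks, ×0.08) and blooms a pathobiont set
  (Proteobacteria + Enterococcus, ×15 with per-ASV-per-recipient log-normal
  spread σ = 1.5) — which pathobiont expands, and how far, varies mouse to
  mouse, producing the lower diversity and higher recipient-to-recipient
  variability of the inflamed phenotype.
- **Influx**: Poisson(λ = 4) novel taxa per recipient at ~10⁻³ relative
  abundance, modelling taxa undetected in the input that appear in vivo
  (sub-detection expansion, sequence change and contamination are
  observationally identical and not distinguished).
- **Passage**: the next generation engrafts the arithmetic-mean pool of the
  previous recipients' true proportions with uniform retention ρ = 0.95 and
  reduced noise (σ_fitness = 0.6, σ_host = 0.5) — near-faithful
  mouse-to-mouse transfer.
- **Sequencing**: multinomial reads at log-normally distributed depth
  (mean 5×10⁴ recipients, 2×10⁵ input replicates; the deeper inputs keep the
  input detection limit well below the recipients'). All randomness flows
  from one study seed through named substreams; a (scenario, seed) pair is
  bit-identical across runs and platforms.

Scenarios: `human_to_mouse` (WT + inflamed KO arms from one donor),
`mouse_adapted` (generation-1 cage pooled, re-sequenced and passaged),
`two_event` (two independent transplantation events per arm, for event-level
clustering contrasts) and `null` (16 exchangeable recipients split 8/8, a
true null for permutation-test calibration).

What the simulator does *not* emulate: taxon–taxon ecological interactions
(no Lotka–Volterra dynamics), chimeras/denoising artefacts at read level,
longitudinal within-mouse dynamics, or real phylogenetic structure in the
taxonomy. Passing tests therefore certify the statistical machinery and its
calibration under the stated generative assumptions, not biological fidelity
of any particular real dataset.

## Problem sizes and numerical choices

Default simulated studies use 400 ASVs, 8 recipients/group and 5×10⁴ reads —
large enough for stable r estimates, small enough that the full test suite
runs in well under a minute per heavy check. Calibration checks use 199–999
permutations with the +1 p-value convention; eigenvalue positivity uses a
relative 1e-9 tolerance; PCoA sign convention and fixed 6-decimal TSV
formatting make pipeline runs byte-identical. The pipeline report
deliberately excludes wall-clock timestamps (they are logged to the console
instead) so that identical config + seed yields identical output bytes; the
config hash, package version, seed and per-file checksums in `report.json`
suffice to re-execute a run exactly.

## Known limitations

- Pearson r on log abundances is sensitive to the zero-handling policy;
  both policies are first-class precisely because the "right" choice is
  context-dependent.
- The PERMANOVA is one-way only; no multi-factor designs, strata, or
  dispersion (PERMDISP) test.
- Bray–Curtis and Euclidean are the only ordination metrics; no UniFrac
  (no tree in scope).
- The rank-sum normal approximation degrades below 5 samples/group (see
  above); exact enumeration covers those sizes.
- Genus/phylum analyses inherit whatever misannotation the input taxonomy
  carries; unclassified ASVs are pooled into one feature per rank.
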