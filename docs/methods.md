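# Methods

## Repertoire diversity

Clonotypes are keyed by the TCR-β CDR3 amino-acid sequence; nucleotide
variants encoding the same CDR3β are merged at import, and frequencies are
always recomputed from counts (any frequency column in an input file is
ignored).  For frequencies `F_i` over `n` clonotypes:

* Shannon entropy (bits): `H = −Σ F_i log2(F_i)`; 0 for a monoclonal
  sample, `log2 n` for a perfectly even one.
* Clonality: `1 − (−Σ F_i log10(F_i)) / log10(n)`, i.e. one minus the
  Pielou evenness.  The ratio cancels the logarithm base, so the log10
  form equals the natural-log form to machine precision (tested to
  1e-12).  Clonality is undefined at `n = 1` (the denominator vanishes)
  and the package raises rather than returning a sentinel: silently
  mapping a degenerate repertoire to 1.0 would hide upstream problems.

Zero-frequency clonotypes are dropped before either statistic, which
implements the `0·log 0 = 0` convention.

A caution on invariants: merging any two clonotypes can only decrease
entropy (concavity), but it can *decrease* clonality as well, because the
`log10 n` normalizer shrinks with `n` (e.g. `{0.4, 0.2, 0.4}` merged to
`{0.6, 0.4}` drops from 0.0398 to 0.0290).  Merging the two *largest*
clonotypes is the monotone operation, and that is the property the test
suite asserts.

## Expansion calling across the coculture

For every clonotype observed at day 14 of the neuron–PBMC coculture the
caller forms `fold = F_day14 / F_exvivo_effective`, where the effective
ex vivo frequency is the measured one or, for clonotypes undetected
ex vivo, the maximal theoretical frequency `1 / input_cell_count` (one
cell among the CD8+ T cells used as sequencing input; 10⁵ input cells give
a 0.001% floor).  Defaults, all configurable through `PipelineConfig`:

| parameter | default | meaning |
|---|---|---|
| `fold_threshold` | 9 | expanded ⇔ fold ≥ 9 (inclusive; the source texts vary between "> 9" and "≥ 9-fold" and the inclusive reading accompanies the findings) |
| `day14_freq_floor` | 0.005 | reportable ⇔ expanded and day-14 frequency > 0.5% |
| `control_fold_ceiling` | 2 | non-expanded control ⇔ fold < 2 |
| `day7_exponential_ratio` | 2 | "exponential" second-week growth ⇔ F_day14/F_day7 ≥ 2 (no published value; 2 marks at least a doubling in the second week) |

The reporting floor is kept separate from the expanded flag because the
two criteria serve different purposes (statistical expansion vs. practical
selectability for TCR cloning).  Calls are sorted by descending day-14
frequency with lexicographic tie-break, so output tables are
deterministic.

## Single-cell QC, linkage and candidate selection

Cell filters (in fixed order, first failing reason recorded): exactly one
productive TRB chain; ≤ 10% mitochondrial reads (boundary passes); ≥ 100
detected genes.  Multiple productive TRA chains do not disqualify a cell.
Gene filter afterwards: detected in ≥ 10 kept cells.  When `pct_mito` is
absent it can be derived from the counts matrix as the percentage of
counts on genes with the `MT-` prefix.

Profiles are donor-scoped `(donor, CDR3β)` pairs; cells lacking a cluster
label are excluded from both numerator and denominator of the cluster
fractions (clustering is an upstream input here, and its gaps should be
visible, not smoothed over).  A clonotype is *ex vivo expanded* when it has
≥ 2 cells.  Candidate selection in a target cluster requires ≥ 10 cells in
the cluster (inclusive) and > 60% of the clonotype's cells there (strict).
Cohort summaries report exact integer counts, per-donor means to one
decimal and percentages to one decimal; VDJ mapping-rate means are
unweighted arithmetic means over samples, to two decimals.

## Reporter reactivity

Per TCR and condition, replicates (the assay runs duplicates) are averaged
and the mock-transfection mean subtracted, floored at zero; the mock maps
to 0 by construction, which makes all adjusted signals invariant to adding
a constant to every replicate.  Thresholding applies to these adjusted
means (no per-replicate test — duplicates are too few), default 5000 RLU:

* `neuron_reactive` (default): stimulated-neuron signal > 5000 **and**
  HLA-blocked signal ≤ 5000, so the verdict is demonstrably TCR/HLA
  mediated.  A permissive mode drops the block requirement.  Note the
  composite rule is intentionally not monotone in the threshold (raising
  it loosens the block condition); threshold monotonicity holds for the
  positivity rule alone.
* `pbmc_positive` reuses the 5000 cutoff; `pbmc_lower_than_neurons`
  records the weaker-than-neurons pattern.  Absent conditions leave the
  flags unset (`None`), never false.
* TransAct (anti-CD3/CD28) is the transfection control: adjusted signal
  ≥ 5000 required when present; when absent the QC state is unknown and
  treated as pass, with a logged warning.

## Expression statistics

Normalization: `ln(1 + count · scale / library_size)` with scale 10⁴.
TCR segment genes (prefixes TRAV/TRAJ/TRAC/TRBV/TRBD/TRBJ/TRBC) are
removed before DE so clonotype identity cannot masquerade as phenotype.
Genes enter the test when expressed in ≥ 10% of cells of at least one
group.  P-values: two-sided Wilcoxon rank-sum, exact enumeration when both
groups have ≤ 25 cells and values are tie-free, otherwise the normal
approximation with tie and continuity corrections (within 0.02 of exact on
tie-free fixtures at sizes 8–25).  The reported fold-change is
`log2((mean(expm1 x₁)+1) / (mean(expm1 x₂)+1))` — means on the
back-transformed scale with pseudocount 1; exact parity with any external
toolkit's fold-change is a non-goal, the formula is the contract.
Significance: BH-adjusted p < 0.05 and |log2FC| > 0.5.

BH adjustment is the standard step-up; the useful invariants are
determinism, monotonicity along sorted raw p-values, being a fixed point
of the step-up monotonization, and rejection-set equivalence with the raw
step-up rule.  (Literal idempotence — re-running BH on adjusted values —
does not hold for any step-up procedure, since the n/k factor applies
again.)

Pseudobulk sums raw counts per donor (integer arithmetic, mass conserved
exactly) and scales each donor column to 10⁶ (per-million values).
Donor-level differential testing is a rank test on per-million values — a
deliberate simplification of a negative-binomial GLM, adequate for
single-digit donor cohorts, and flagged in the output header.

The exact signed-rank test enumerates all 2ⁿ sign assignments of the
mid-ranked |differences| (zero differences dropped, n ≤ 20) and doubles
the smaller inclusive tail, capped at 1 — the convention of R's
`wilcox.test` exact path.  For a uniformly signed sample of 6 pairs this
gives 0.03125 two-sided (the corresponding one-sided value is 0.015625;
reports that quote ~0.0156 for such data are one-sided).

## Synthetic data: what it emulates, and what it does not

* `simulate_repertoire`: clone probabilities ∝ rank^(−α) (default α = 2),
  multinomially sampled at the sequencing depth.  Two parameters suffice
  to reproduce the "few large clones, long rare tail" shape; α = 2 yields
  a strongly clonal sample (top clone ≈ 60%), smaller α gives more even
  repertoires.  CDR3β strings are random unique C…F-framed amino-acid
  strings of length 10–20 — no V/J grammar, since no operation depends on
  sequence content beyond identity.
* `simulate_coculture`: planted reactive clones are drawn among clones
  with ex vivo frequency < 0.01% (the rare-precursor regime); their mass
  is multiplied by the weekly growth factor (default 20) with multinomial
  resampling at day 7 and day 14, so the day-14 fold is ≈ growth² under
  deep sampling and the ≥ 9 threshold is cleanly separable from noise.
  Growth acts on the day-7 *empirical* frequencies, so week-one sampling
  noise propagates, as it would in a real culture.
* `simulate_cell_dataset` (defaults: 3 AgD + 7 Ri-AIE donors, 30
  clonotypes/donor, 16 clusters): cluster memberships are
  Dirichlet-multinomial.  Planted target-cluster clonotypes use a
  concentration putting 0.92 expected mass on the target cluster
  (strength 150) and carry 25–60 cells; background clonotypes use a
  symmetric Dirichlet (strength 5 per cluster) with 1 + geometric cell
  counts capped at 100, so their expected target-cluster occupancy stays
  below the selection threshold.  Each QC field independently fails its
  filter in 2% of cells.
* `simulate_counts`: negative-binomial counts (dispersion 0.5) with
  lognormal baseline means (log-mean 0, log-sd 1); planted genes scale
  the second group's mean by 2^log2FC, half up, half down.
* `simulate_luminescence`: reactive TCRs emit lognormal signal of median
  20 000 RLU above background on stimulated neurons (background median
  500, log-sd 0.25), collapsing to background under HLA block; 85% of
  reactive TCRs also respond to PBMCs at median 8000.  Mock and TransAct
  conditions are always present, duplicates per condition.

All draws flow from one top-level seed through named substreams
(`SeedSequence([seed, crc32(name)])`), so outputs are byte-identical per
seed and adding a generator does not perturb existing fixtures.

Passing the recovery tests on these data shows the *decision logic* is
correct under the stated noise models; it does not certify performance on
real data, which additionally carry ambient RNA, doublets, batch effects,
V(D)J annotation errors and plate effects that the generators deliberately
omit.

## Problem sizes and numerical choices

The test and acceptance runs use 3000-clonotype repertoires at depth 10⁵,
10-donor cell cohorts (~1700 cells), 2000-gene × 1000-cell count matrices
and 30–48-TCR plates — miniature but in-regime versions of the study's
scales, chosen so the full suite completes in well under a minute of
compute per battery.  Frequency sums are checked to 1e-9; clonality is
clamped to [0, 1] against round-off; exact enumeration switches on at
≤ 25 cells per group (rank-sum) and ≤ 20 pairs (signed-rank); ties use
mid-ranks with the variance tie-correction.  Floats round-trip through
TSV/CSV via `float_precision="round_trip"`.

## Known limitations

* No clustering, integration, ambient-RNA correction or cluster
  annotation: cluster labels are inputs.
* No negative-binomial GLM for donor-level DE; no pathway enrichment.
* Reporter calls use a fixed threshold on duplicate means — no plate
  normalization or dose–response modeling.
* Clonotype identity is CDR3β amino acid only by default (an optional
  strict mode could add V-gene identity; bulk/single-cell joinability was
  prioritized).
* The cluster-fraction denominator counts only cells with cluster labels;
  cohort totals are donor-scoped (identical CDR3β in two donors counts
  twice).
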