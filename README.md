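# clonoreact

Clonotype-level identification and characterization of neuron-reactive
CD8+ T cells, as a tested, reusable Python pipeline.

Autoreactive CD8+ T cells that recognize neurons circulate at very low
frequency; one way to find them is to coculture a donor's PBMCs with
autologous stem-cell-derived neurons for 14 days and look for T-cell
clonotypes that expand, then validate the cloned TCRs in an NFAT-luciferase
reporter assay and profile the corresponding cells by single-cell
RNA/VDJ sequencing. `clonoreact` implements the computational side of that
workflow for immunologists working with bulk TCR-β repertoires, 10x-style
single-cell VDJ/GEX outputs and plate-reader luminescence:

1. **Repertoire diversity and expansion calling** (`repertoire_metrics`).
   Shannon entropy `H = −Σᵢ Fᵢ log₂ Fᵢ` and clonality
   `1 − (−Σᵢ Fᵢ log₁₀ Fᵢ)/log₁₀ n` over clonotype frequencies `Fᵢ`.
   A day-14 clonotype is *expanded* when its frequency is ≥ 9-fold its
   ex vivo frequency, and *reportable* when it additionally exceeds 0.5%
   of the day-14 repertoire.  Clonotypes undetected ex vivo receive the
   maximal theoretical frequency `1 / (input CD8+ T cells)`, giving the
   assay a detection floor of 0.001% at 10⁵ input cells.  Clonotypes whose
   fold-change stays below 2 serve as non-expanded controls.
2. **Single-cell linkage and candidate selection** (`clonotype_linker`).
   Cells pass QC with exactly one productive TCR-β chain, ≤ 10%
   mitochondrial reads and ≥ 100 genes; genes must be detected in ≥ 10
   kept cells.  Clonotypes are keyed by the CDR3β amino-acid sequence, so
   bulk and single-cell tables are joinable.  A clonotype becomes a
   reactivity-testing candidate when ≥ 10 of its cells sit in the target
   expression cluster and > 60% of its cells reside there.
3. **Reporter reactivity calling** (`reactivity_caller`).  Replicate
   luminescence means are background-adjusted against the mock
   transfection; a TCR is neuron-reactive when the adjusted signal on
   cytokine-stimulated neurons exceeds 5000 RLU and collapses under
   HLA class I blockade.  PBMC cross-reactivity reuses the same threshold.
4. **Phenotype statistics** (`phenotype_stats`).  Cell-level two-sided
   Wilcoxon rank-sum DE on log-normalized counts (TCR segment genes
   removed), Benjamini–Hochberg FDR 0.05 with an average log₂
   fold-change cutoff 0.5; pseudobulk aggregation with per-million
   normalization for donor-level views; exact enumeration tests for
   small-n comparisons.
5. **Synthetic data with planted truth** (`synth`).  Power-law
   repertoires under multinomial sampling, multiplicative weekly clone
   growth, Dirichlet-multinomial cluster memberships, negative-binomial
   counts with planted log-fold-changes and lognormal reporter signals —
   so every stage runs and is benchmarked without any download.

## Worked example

Simulate a coculture timecourse in which 5 rare clones (< 0.01% ex vivo)
grow 20-fold per week, then call expansions:

```python
from clonoreact import (simulate_repertoire, simulate_coculture,
                        call_expansions, repertoire_summary, Timepoint)

base = simulate_repertoire(3000, 100_000, seed=7, input_cell_count=100_000)
tc, truth = simulate_coculture(base, n_reactive=5, seed=7, growth_factor=20.0)

for tp in (Timepoint.ex_vivo, Timepoint.day14):
    s = repertoire_summary(tc.samples[tp])
    print(f"{tp.value:8s} n={s.n_clonotypes:4d}  H={s.shannon_entropy_bits:.3f} bits"
          f"  clonality={s.clonality:.3f}")

reportable = [c for c in call_expansions(tc) if c.reportable]
print(f"{len(reportable)} reportable expansion(s)")
for c in reportable:
    print(f"  {c.cdr3b_aa:22s} day14={100*c.freq_day14:5.2f}%  fold={c.fold_change:8.1f}")
```

prints

```
ex_vivo  n= 415  H=2.354 bits  clonality=0.729
day14    n= 287  H=2.613 bits  clonality=0.680
3 reportable expansion(s)
  CPIFTKVVPYIITIFPFPF    day14= 1.64%  fold=   409.7
  CMKQECDKTTKRMIHSALF    day14= 1.62%  fold=   404.2
  CFEENLASDKILMF         day14= 0.51%  fold=   506.0
```

All three reported clonotypes are planted reactive clones (the other two
planted clones stayed below the 0.5% reporting floor at this depth); their
400–500× fold-changes dwarf the ≥ 9 threshold, while no neutral clone is
called.  `n` is the number of detected clonotypes, `H` the Shannon
entropy, and clonality rises as the repertoire concentrates.

The same analyses are available from the shell:

```bash
clonoreact simulate all --seed 7 --outdir fixtures/
clonoreact qc      --cells fixtures/cells.tsv -o qc.tsv
clonoreact select  --cells fixtures/cells.tsv --cluster 1 -o selected.tsv
clonoreact expand  --exvivo fixtures/repertoire_ex_vivo.tsv \
                   --day14 fixtures/repertoire_day14.tsv \
                   --input-cells 100000 -o expansions.tsv
clonoreact react   --lum fixtures/plate.csv -o reactivity.tsv
clonoreact de      --counts fixtures/counts --labels fixtures/counts_labels.tsv \
                   --group1 Ri_AIE --group2 AgD -o de.tsv
```

Every output TSV starts with a comment line recording the tool version and
a hash of the active configuration.

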