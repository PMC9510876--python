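# cardiosplice

A tissue-specificity and splicing-regulation screen for cardiac
RNA-binding proteins, with fully synthetic, seed-reproducible data
generators for every stage.

## Scientific problem

Alternative splicing in the heart is controlled by a small set of
splicing factors; losing one (as with RBM20) can cause dilated
cardiomyopathy. Finding new cardiac splicing regulators among the
hundreds of mRNA-binding proteins (mRBPs) requires a multi-stage
screen:

1. **Tissue specificity.** For each gene, a heart-specificity score
   (HSS) summarizes left-ventricle enrichment against all non-heart
   tissues:

   HSS(g) = mean over non-heart tissues t of
   (x(g, heart) + ε) / (x(g, t) + ε),

   with a small pseudocount ε to stabilize lowly expressed genes.
   Genes with HSS ≥ 3 are heart-enriched.
2. **Disease regulation.** Heart-enriched candidates whose expression
   differs between failing and non-failing myocardium (median-of-ratios
   normalized counts, two-sample pooled-variance t-test) become
   screen hits.
3. **Target identification.** RIP-seq enrichment (case IP vs control
   IP fold change and t-test on jointly normalized counts) yields the
   factor's bound transcripts.
4. **Splicing consequence.** Exon-level PSI (percent spliced in) from
   junction and coverage counts over flattened exonic parts, compared
   between conditions (ΔPSI), identifies the transcripts that are both
   bound and differentially spliced — the factor's direct splicing
   targets.
5. **Mechanism.** A UWAA (U-[A/U]-A-A) motif scanner and a
   motif-ablating mutagenesis helper support minigene design around
   candidate exons, e.g. retained introns.

The package implements each stage, plus GTF flattening into disjoint
exonic parts (DEXSeq-style counting bins), exon–factor expression
correlation profiling, and planted-truth simulators that make the whole
screen testable end to end without any external data.

## Worked example

Score a toy two-gene expression matrix:

```python
import pandas as pd
from cardiosplice.hss import compute_hss

matrix = pd.DataFrame(
    {"heart_left_ventricle": [80.0, 5.0], "liver": [8.0, 5.0],
     "lung": [10.0, 4.0], "brain_cortex": [6.0, 6.0]},
    index=["RBM20", "GAPDH"],
)
for r in compute_hss(matrix, "heart_left_ventricle"):
    print(r.gene_id, round(r.hss, 3))
```

prints

```
RBM20 10.432
GAPDH 1.028
```

Run the full screen on a simulated cohort with planted truth:

```python
from cardiosplice.pipeline import PipelineConfig, run_screen, simulate_screen_inputs

inputs, truth = simulate_screen_inputs(7)
result = run_screen(inputs, PipelineConfig(seed=7))
top = result.top_candidate
print(top.gene_id, round(top.hss, 2), round(top.fold_change, 3), f"{top.p_value:.2e}")
print(len(result.bound_spliced), result.bound_spliced == set(truth.bound_spliced_genes))
dp = max(result.delta_psi, key=lambda r: abs(r.delta_psi))
print(dp.part_id, round(dp.delta_psi, 3), f"{dp.p_value:.2e}")
```

prints

```
FACTOR1 7.79 1.887 3.51e-07
25 True
sgene_ret:002 0.415 3.07e-08
```

The planted factor tops the candidate list (heart-enriched, 1.89-fold
up-regulated), all 25 planted bound-and-spliced genes are recovered
exactly, and the strongest splicing change is the planted retained
intron.

The same pipeline is available on the command line:

```bash
cardiosplice screen --seed 7 --out-dir screen_out/
cardiosplice simulate --seed 2 --out-dir sim/
cardiosplice hss --matrix sim/tissue_rpkm.tsv --out hss.tsv
```

## Testing

```bash
python -m pytest -q tests/
```

The suite (~180 tests, <1 min) checks every module against independent
oracles: a per-base brute-force segmentation for GTF flattening, a
hand-computed pooled t-statistic for the differential tests, pydeseq2
for median-of-ratios size factors, and an exhaustive 4-mer scan for the
motif scanner. `tests/test_acceptance.py` runs the study-level
benchmarks (recovery and calibration at full problem sizes).

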