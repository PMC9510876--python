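# Methods

This note records the statistical models, conventions and parameter
defaults used by `cardiosplice`, and what the synthetic generators do
and do not emulate.

## Heart-specificity score (HSS)

For gene g with expression x(g, t) across a tissue panel containing a
designated heart column,

HSS(g) = (1 / |T|) · Σ_{t ∈ T} (x(g, heart) + ε) / (x(g, t) + ε),

where T is the set of non-heart tissues and ε = 0.01 by default. The
score is the mean of heart-over-other ratios, so a gene expressed
uniformly scores ≈ 1 and a gene expressed k-fold higher in heart over a
uniform background scores exactly k (ε = 0). The enrichment call is
HSS ≥ 3, inclusive. An alternative `mean_background` mode (heart over
the mean of the others) is provided; the ratio-mean is the default
because it rewards consistent enrichment across all tissues rather
than enrichment against an average that a single outlier tissue can
inflate. Validation against a second heart region (atrial appendage)
uses the Spearman correlation of the two scores.

## Annotation flattening

Overlapping transcripts of a gene are flattened into disjoint *exonic
parts*: the elementary intervals induced by the sorted set of all exon
boundaries, keeping those covered by at least one transcript. Each
part carries the exact set of supporting transcripts; it is flagged
`is_alternative` when that set is a proper subset of the gene's
transcripts. Part ids are `geneID:NNN` with a 1-based, zero-padded
index ascending along the genome. Internally all coordinates are
0-based half-open; GTF (1-based inclusive) is converted at the parser
boundary. Flattening refuses to mix contigs or strands within a gene.

## Differential expression

Counts are normalized by median-of-ratios size factors (geometric-mean
pseudo-reference over genes positive in all samples), then each gene is
tested with a two-sample Student's t-test with pooled variance.
Fold changes use a 0.5 pseudocount only when a group mean is zero.
Genes with zero pooled variance are flagged degenerate and excluded
from candidate calls instead of receiving an artificial P-value.
Candidate nomination intersects the HSS call (enriched) with the DE
call (P below threshold), sorted by P then |log2 fold change|. The
qPCR helper computes relative expression as 2^−ΔCt.

## PSI estimation

For an exonic part p and sample s:

- **Inclusion evidence**: read coverage assigned to p plus junction
  reads abutting p (junction end equals part start, or junction start
  equals part end).
- **Exclusion evidence**: junction reads spanning p, i.e. junctions
  with start ≤ p.start and end ≥ p.end. Containment is inclusive of
  boundary equality so that the splice junction of a retained intron —
  which coincides exactly with the intronic part — counts as exclusion;
  the abutting and spanning classes remain disjoint because an abutting
  junction has exactly one boundary outside the part.
- PSI = inclusion / (inclusion + exclusion); undefined (NaN) when both
  are zero.

Two modes are supported. `raw` treats counts as event counts and is
exact for the simulator's output; `length-normalized` divides inclusion
by (L_part + L_read − 1) and exclusion by (L_read − 1), the standard
correction when inclusion is measured in positional read coverage.
ΔPSI per part is tested case vs control with the same pooled t-test;
parts with too few defined values per group are reported as skipped
with a reason rather than silently dropped. A retention index helper
summarizes isoform triplets (large/middle, large/small,
large/(large+middle+small)).

## RIP enrichment

Case-IP and control-IP count matrices are jointly normalized
(median-of-ratios across all IP samples) and each feature is tested by
fold change and pooled t-test. A feature is *bound* when P < 0.05 and
fold change > 1. Gene-level calls collapse features by the prefix of
`gene:part` ids (any bound feature ⇒ bound gene). The
bound-and-spliced set intersects bound genes with genes carrying a
significant ΔPSI part, with a per-chromosome summary table.

## Exon–factor correlation

Per-part expression is correlated with a factor's expression across
samples (Pearson on log2(x+1) by default; Spearman and identity
transform available). Zero-variance parts yield NaN, never 0. Profile
comparison between two factors reports mean/max absolute r and the
argmax part within a part-index region.

## Motif scanning and mutagenesis

The UWAA element (U-[A/U]-A-A after T→U mapping) is scanned at every
position, counting overlapping matches; N never matches. Mutagenesis
ablates selected motifs by replacing the two A's at motif positions
3–4 with C,G (falling back to C,C / G,C / G,G if a substitution would
create a new motif), then verifies by full rescan that the selected
motifs are gone and no new motif arose.

## Synthetic data generators

All generators take a single integer seed driving one
`numpy.random.Generator`; identical configurations produce
byte-identical outputs.

- **Tissue matrix**: log-normal baseline per gene (median 5, log-sd 1
  by default) times per-cell log-normal noise, over a 53-tissue panel
  with one left-ventricle and one atrial-appendage column; planted
  genes have their heart columns multiplied by an enrichment factor.
- **Splice counts**: per part and sample, an event total n ~
  Poisson(depth) (optionally Gamma-Poisson overdispersed), split
  inclusion ~ Binomial(n, ψ); inclusion becomes part coverage and
  exclusion becomes the skipping junction between the flanking parts.
  Junction rows are emitted even at count 0 so all samples share a
  junction grid. Cassette-exon and intron-retention gene templates are
  provided.
- **RIP counts**: Poisson with per-feature mean library_size /
  n_features; bound features have case-IP means multiplied by the
  binding factor. Realistic panels must contain a majority of unbound
  background features — median-of-ratios normalization assumes most
  features are unchanged and will absorb the enrichment otherwise.
- **Motif sequences**: uniform ACGU backgrounds with motifs planted at
  chosen positions; spurious background motifs are removed by rejection
  (replacing bases inside unplanned hits with C/G).
- **End-to-end fixture** (`simulate_screen_inputs`): 300 background
  genes plus one planted factor (enrichment 8, fold change 1.9), 40
  splice genes of which 25 are bound-and-spliced (ΔPSI 0.3, RIP factor
  8) including one retained intron (ΔPSI 0.4), and a 240-feature RIP
  panel with 200 unbound background features.

These sizes are the package's own desk-scale choices: large enough for
stable rankings and calibration estimates, small enough that the full
validation battery runs in about a minute.

## Validation battery

`cardiosplice.validation` (used by both `tests/test_acceptance.py` and
`scripts/acceptance.py`) measures:

- exact HSS on noise-free input and exact planted-set recovery at
  threshold 3 over 20 seeds (1000 genes, 50 planted, factor 8,
  log-noise 0.2);
- flattening equivalence to a per-base brute-force segmentation on 200
  random genes;
- DE null false-positive rate (1000 Poisson genes, 4 vs 4) and the
  closed-form worked example t = −3.674, P ≈ 0.021;
- PSI recovery error at depth 10⁴, ΔPSI = 0.3 power at depth 1000, and
  the ΔPSI null false-positive rate on 1000 null parts;
- 20-seed end-to-end screen recovery (factor ranked first; exact
  bound-and-spliced set);
- motif scanner equality with the exhaustive scan up to length 10⁴ and
  zero residual hits after mutate-all on 100 random constructions.

## Limitations

- The t-tests assume approximate normality of (normalized) counts and
  proportions; no multiple-testing correction is applied, so screen
  calls at nominal P < 0.05 carry the expected false-positive load.
  In the end-to-end benchmark the only observed failure mode (~1% of
  seeds) is one null gene jointly passing the RIP and ΔPSI tests.
- The simulators use Poisson/Binomial sampling without positional read
  modeling, GC or mappability effects; they test estimator identities
  and calibration, not aligner behavior.
- PSI length normalization assumes uniform read start positions and a
  single read length.
- Real-cohort quantities (multi-tissue consortium scores, patient
  RIP-seq target counts) require the corresponding external datasets
  and are out of scope for the packaged validation, which is entirely
  synthetic.
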