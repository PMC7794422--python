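# Methods

## Problem and model

A SNAIL-family repressor bound at E-box enhancers can silence a
differentiation program two ways: directly, by occupying regulatory elements
of a gene, or indirectly, through a directly repressed intermediate (e.g. a
master transcription factor) whose reactivation drives downstream genes.
ChIP-seq alone cannot separate the two, and nearest-gene assignment of
peaks is unreliable at enhancer distances. The model adopted here uses
topologically associated domains (TADs) as the linkage constraint: enhancer
action is assumed to stay within the TAD, so a knockdown-upregulated gene
whose TAD contains a high-confidence repressor peak is called a **direct**
target, one whose TAD is peak-free is **indirect**, and a gene whose TSS
falls in a boundary gap between TADs is **excluded** (reported, never
silently dropped). TADs are consumed as intervals; no contact-map processing
is performed.

"High-confidence" peaks are consensus peaks: maximal regions where at least
*k* of *n* cell lines' peak calls cover a base (each set pre-merged so one
experiment contributes depth ≤ 1). The depth-≥k region is the reproducible
minimal choice for "shared between cell lines"; a union-of-contributors mode
is available when the broader native extent is wanted. Co-occupancy of two
factors uses a ≥1 bp single-peak overlap by default, counted from the first
argument's side — the Venn convention is stated rather than assumed because
merged-event counting gives different totals.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| consensus `k` / `n` | 2 of 3 | experiments | reproducibility in ≥2 cell lines |
| `min_overlap` | 1 | bp | any-overlap co-occupancy |
| stitch `max_gap` | 12 500 | bp | ROSE stitching default |
| `tss_exclusion` | ±2 500 | bp | removes promoter-proximal peaks (full containment only) |
| profile `flank` | 2 000 | bp | composite window half-width |
| track `bin_size` | 10 (library) / 25 (simulator) | bp | resolution vs. memory |
| `l2fc_min`, `fdr_max` | 0, 0.05 | — | strict inequalities; boundary genes excluded reproducibly |
| GSEA `weight_p` | 1 | — | score-weighted running sum |
| `n_perm` | 1000 | permutations | resolution of the nominal p (floor 1/n_perm) |

## Normalization

Signal tracks carry explicit units: `raw` counts, `RPM`
(reads per million mapped), or `RRPM` (reference-adjusted RPM). The RRPM
scale is `(1e6 / total_mapped_reads) × (reference_spikein / spikein_reads)`
with the cohort-minimum spike-in count as the default reference, mirroring
exogenous-chromatin (e.g. Drosophila H2Av) spike-in practice: a sample that
recovers more spike-in chromatin is scaled down. The reference anchor is
defined at the sample's library scale, so resequencing the same library
c-fold deeper — raw bins, total reads, spike-in reads and the matched
anchor all ×c — leaves the RRPM track bit-for-bit unchanged; this is the
depth-invariance the test suite asserts. Condition differences (knockdown
minus control) are computed only on like-normalized tracks and returned as a
separate signed `DeltaTrack`, preventing sequencing-depth artifacts from
masquerading as biology.

Composite profiles use an odd offset grid — the bin containing each center
sits at offset 0 with `flank/bin` bins each side — so the profile of a
mirror-symmetric track is exactly mirror-symmetric. Centers nearer than the
flank to a chromosome edge are zero-padded and counted. Heatmap matrices
sort rows by the per-row total of a separate sort track, descending, ties by
genomic coordinate (stable).

## Enrichment statistic

For a preranked list of N genes the running sum increments at set members by
`|score|^p` normalized to the in-set total and decrements at non-members by
`1/(N − N_hits)`; the enrichment score is the maximum signed deviation, with
the positive extreme preferred when the two extremes tie within 1e-9 (exact
ties occur in real arithmetic and would otherwise be broken by float noise).
The null is gene-set relabeling — the pipeline consumes preranked lists, so
phenotype permutation is not applicable. NES divides the observed ES by the
mean |ES| of same-sign permutations; the nominal p is the same-sign
permutation tail, floored at 1/n_perm. With a single gene set the reported
FDR q is the nominal p; with several sets q uses GSEA-style pooling of
per-set-normalized null NES values. FWER is not computed.

## E-box module

CANNTG is closed under reverse complement, so single-strand scanning finds
every site; subtypes (the NN dinucleotide) map pairwise under reverse
complement. Enrichment against background regions is a per-region
presence/absence binomial upper tail with the background rate floored at
`1/(bg_total+1)` — a deliberate simplification of de novo motif discovery
with matched backgrounds, adequate for ranking subtypes but not for
absolute motif p-values. A hit-count Poisson mode would be the next step for
long regions where presence saturates.

## Synthetic study

The generator plants the statistical structure the pipeline is meant to
detect, at a desk scale where every stage runs in seconds: 3 chromosomes ×
2 Mb, 30 TADs (10% boundary-gap fraction), 10 genes per TAD, 300 repressor
and 600 activator master peaks observed across 3 cell lines with
per-line inclusion probability 0.8, and gene classes 30 direct / 100
indirect / 170 null. Sixty percent of repressor peaks get an activator peak
planted within ±200 bp (the co-bound class); 20 activator sites carry
10-fold signal as planted super enhancers. Each direct gene's TAD receives a
repressor master forced into ≥2 cell lines; TADs hosting indirect genes are
kept entirely repressor-free — these two invariants are asserted at
generation time. Tracks are triangular bumps over Poisson background
(rate 0.25/bin); knockdown and treatment conditions scale repressor bumps by
0.2 and raise activator bumps 1.8-fold at co-bound peaks only. Per-factor
noise is drawn from one stream re-seeded identically per condition, so
conditions differ only through planted effects (a knockdown factor of 1
gives byte-identical tracks). DE tables draw planted-up genes from
Normal(3, 0.5) log2FC in both cell lines and both contrasts and null genes
from Normal(0, 0.5), with p-values from the corresponding z-scores and BH
FDR; a mean of 3 log2 units reflects the multi-fold induction typical of
myogenic differentiation genes on repressor loss. DE tables are generated
directly rather than through a count model because DE testing is an input
to, not a product of, this pipeline.

What passing these tests shows — and does not. The fixture exercises the
integration logic exactly (coordinate arithmetic, normalization algebra,
classification set logic, statistic definitions) with known truth. It does
not emulate GC or mappability bias, fragment-length effects, copy-number
variation, antibody efficiency differences, or genes whose TSS-containing
TAD differs from the TAD of their functional enhancer; recovery rates on the
fixture are therefore upper bounds, not predictions of performance on real
data.

## Numerical and design choices

- Coordinates 0-based half-open everywhere; strand ignored for peaks;
  touching intervals merge at `min_gap = 0`.
- Hockey-stick slope uses the forward difference with a strict `>` at the
  boundary and first crossing wins (a centered-difference "tangent" variant
  is available); an exactly linear scaled curve yields zero supers. All-equal
  signals give an infinite cutoff; fewer than 3 regions are all typical.
- Region scores are background-subtracted then floored at 0 per region.
- Peak-to-state assignment: maximal bp overlap, ties by the segmentation's
  priority order; unassigned peaks appear in a footer count, not the table.
- Gene anchor = TSS, peak anchor = midpoint (half-open containment, so an
  anchor on a TAD start is inside); a full-interval-overlap mode exists.
- Degenerate inputs fail loudly with the offending line or gene named:
  inverted BED coordinates, overlapping segments or TADs, unknown gene ids,
  raw-unit deltas, unit or grid mismatches, zero spike-in under RRPM.
- All pipeline randomness flows from one config seed; reports echo the full
  parameter set and reruns are byte-identical apart from the runtime field.

## Known limitations

- The TAD constraint inherits the TAD caller's boundaries; genes regulated
  across boundaries are misclassified by construction.
- Consensus regions are depth-defined, so a consensus peak can be narrower
  than any contributing native peak.
- The binomial E-box test ignores sequence composition matching.
- Pearson p-values assume bivariate normality; with n < 3 they are refused
  rather than approximated.
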