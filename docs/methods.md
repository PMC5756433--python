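# Methods

This note documents the models, procedures, parameter choices and known
limitations of the package, in the order the pipeline runs.

## Coordinates and formats

All coordinates are 0-based half-open (BED convention) internally; GFF3/GTF
(1-based inclusive) is converted at the file boundary and nowhere else. When
a gene has several isoforms the canonical transcript is the one with the
longest exonic span, ties broken by lexicographically smallest transcript id;
the intron set of the analysis is the canonical transcript's. Methylation is
consumed as a per-cytosine table of methylated fraction plus supporting read
count; a cytosine with count 0 is *missing*, not 0.0 — treating unobserved
positions as unmethylated would bias every downstream profile toward 0.

## Event calling

An intron is **retained (IR)** when per-base RNA-seq coverage is ≥ 1 at every
base and **excised (IE)** when it is 0 at every base. This is a deliberately
strict trichotomy: introns with partial coverage are evidence for neither
class and contribute no event. "Exonic read depth ≥ 20" is implemented as
the mean over the canonical transcript's exonic bases (a per-flanking-exon
variant is available via `per_exon=True`); the event-calling threshold is
monotone by construction, so raising it can only remove events.

First introns are flagged and excluded from all comparative statistics: the
promoter DHS of an expressed gene typically overlaps the first intron, which
would otherwise masquerade as an IR-specific accessibility signal. For the
same reason IE events are matched to IR events by relative position within
the gene — relative position is the intron midpoint offset divided by the
gene's genomic span, reflected on the minus strand so 0 is always
TSS-proximal; the matching tolerance defaults to 0.1 (events within 10% of
gene length of some IR event are eligible).

Strand handling: an event's `exon5`/`exon3` follow transcript orientation,
and all window extraction downstream (`part_sequence`,
`CoverageTrack.slice_oriented`) reverses genomic slices for minus-strand
events, so "5' of the hexamer" always means transcript-upstream.

## DHS statistics

DHS content is the fraction of events whose full span (exon5 start through
exon3 end — the same three-part window the bin profiles display) intersects
at least one peak by ≥ 1 bp; the IR/IE difference is tested two-sided by
Fisher's exact test with the probability-mass rule (sum of hypergeometric
probabilities ≤ the observed table's — R's default, via scipy). Bin
profiles length-normalize each part into 10 bins; a part shorter than the
bin count contributes its whole-part overlap to every bin. The per-event
coverage comparison uses the Mann–Whitney U test: exact by enumeration of
labelings when both groups have ≤ 8 observations (ties through midranks),
otherwise the normal approximation with continuity and tie correction.

Gene-level coverage profiles group genes as first-intron-IR > IR-elsewhere >
no-IR (one group per gene, first-intron priority), cover −1000 bp to
+5000 bp around the TSS strand-aware, and average only over genes that reach
a given position.

## The footprint HMM

For each hexamer and event part, every occurrence contributes a 206-slot
window (100 bp upstream, the 6 hexamer bases, 100 bp downstream, transcript
orientation). Windows never cross part boundaries — slots beyond the
boundary are flagged absent so flanking-segment composition cannot bias the
profile — and when a part contains several instances the one with the lowest
mean raw coverage over its 6 bases is kept (mean over the hexamer is the
narrowest reading of "lowest coverage"). Profiles are the position-wise mean
over present slots, divided by the scalar C_train (the training set's mean
background coverage). Division by a scalar rather than z-scoring keeps
profiles non-negative and makes the score a coverage ratio. A hexamer needs
≥ 10 occurrences in a (part, class) combination to be scored; rarer hexamers
are reported as unscored rather than scored from noise.

The decoder is a 13-state left-to-right continuous HMM with Gaussian
emissions on standardized coverage: the core chain BG1 → DN → FP → UP → BG2
models leading background, the descending edge, the protected footprint, the
ascending edge and trailing background; two optional secondary blocks
(DNu/FPu/UPu/BGu between BG1 and DN; BGd/DNd/FPd/UPd between UP and BG2)
absorb tandem secondary footprints up- or downstream of the primary one.
Every state has a self-loop; the topology is otherwise acyclic and decoding
starts in BG1. This is the minimal wiring consistent with a primary dip
flanked by optional secondary dips; the exact published wiring of the
13 states is not recoverable, so ours is a documented design choice.

Training is supervised maximum likelihood from labelled profiles: emission
mean/variance per state from labelled positions (variance floored at 1e-3),
transitions from labelled bigrams with add-one smoothing over the allowed
edges only, C_train from background-labelled positions. A secondary state
with no labelled positions borrows its core counterpart's emission; a core
state with none is an error. Optional Baum–Welch refinement (≤ 50
iterations, log-likelihood tolerance 1e-6) re-estimates emissions and
transitions while keeping topology zeros fixed; it is off by default because
the supervised fit is already consistent and refinement can drift emission
semantics.

Decoding is Viterbi over present slots, with transitions composed across
absent-slot gaps by matrix powers (posterior decoding was considered and not
used: the score needs a single state assignment per position). The score is

    S = −log(C_FP / C_BG)

with C_FP the mean standardized coverage over positions decoded as the
primary FP state and C_BG the mean over background-state positions. The log
is natural; the calling thresholds S ≥ 0.30 (single-species) and S ≥ 0.20
(cross-species) are interpreted in the same units, and a `log_base` option
rescales if another convention is wanted. If no position decodes as primary
FP, S = 0; if C_FP = 0, S is capped at 10. A footprint call additionally
requires the primary FP state to cover at least one of the 6 hexamer slots —
a dip elsewhere in the window is not a footprint *of this hexamer*.

## Enrichment, conservation, multi-set overlap

Hexamer enrichment counts event-level presence/absence of the hexamer in a
part's sequence (not occurrence counts), one Fisher test per hexamer, with
Benjamini–Hochberg adjustment within each (part × direction) family of 4096
tests. Conservation of two species' hexamer sets is the hypergeometric upper
tail P[X ≥ k] over the 4096-hexamer universe. The simultaneous overlap of
m ≥ 2 sets uses the exact distribution of the intersection of independent
uniform random subsets of a finite population, computed by iterated
hypergeometric mixing: conditional on the running intersection having s
elements, intersecting the next subset of size n gives a
Hypergeometric(N, s, n) count. This reduces exactly to the hypergeometric
test at m = 2 and is validated against exhaustive enumeration and Monte
Carlo in the test suite.

## Motifs

The clustering metric assigns distance 0 to hexamers sharing any contiguous
4-mer and the Levenshtein edit distance otherwise; clustering is complete-
linkage agglomeration with deterministic tie-breaking (smallest
lexicographic member pair first), cut at merge height 4 — with integer
distances in 0..6 a "depth of 4" reads most naturally as a height threshold;
ties in the integer metric are why the agglomerator is implemented
in-package rather than delegated (scipy's linkage is used as an independent
cross-check on jittered, unique distances). Consensus strings align members
ungapped to the cluster medoid over offsets −5..+5 (hexamers are too short
for gapped alignment to add anything); a column reports its top base at
frequency ≥ 0.75, the top two as (X/Y) when they jointly reach 0.75, and x
otherwise, with terminal x trimmed. The 0.75 thresholds are this package's
choice of "clear consensus". Positional preferences histogram the relative
position of each event's lowest-coverage occurrence into 20 bins on [0, 1].

PWM information content is IC_j = 2 + Σ_b p_bj log2 p_bj (bits, uniform
background). A PWM matches a hexamer when the hexamer equals the consensus
substring at some offset *and* the 6 covered columns carry ≥ 50% of the
motif's total IC; among qualifying offsets the maximal covered-IC one is
reported.

## The synthetic-data generator

The generator emulates, at desk scale, the statistical structure the
analysis assumes: genes with 2–3 introns (exons 150–300 bp, introns
100–250 bp by default) separated by ≥ 1500 bp spacers on one contig, uniform
ACGT sequence, random strand per gene; exonic coverage Poisson(30) redrawn
until the gene clears the depth-20 filter; IR introns Poisson(15) with zeros
raised to 1 (full coverage by construction), IE introns zero, ambiguous
introns covered over one contiguous half; DNase cuts Poisson(20)/base with a
10× promoter peak over TSS±200 (always accompanied by a promoter DHS, so the
first-intron exclusion always has something to exclude) and DHS peaks of
5× background planted in the 3' exon of non-first IR/IE events with
configurable probabilities (0.30/0.05 by default, mirroring the IR ≫ IE
pattern the analysis detects); methylation Beta-distributed per cytosine
with class/region shapes (IR 3' exon Beta(2,8) vs IE Beta(5,5) by default,
read counts Poisson(10), count 0 missing).

Footprints are planted as *multiplicative* rate dips (rate × δ over the
hexamer ± halfwidth) so the dip factor is scale-free and maps directly onto
the ratio form of S. Planted hexamer sequences are written at non-overlapping
sites, and accidental occurrences of planted hexamers inside event parts are
mutated away (`scrub_chance_occurrences`, default on): the sequence is
uniform *except* at planted sites, so each planted hexamer's occurrence set
coincides with its truth table. Without scrubbing, chance occurrences dilute
the averaged dip toward background and the planted/unplanted distinction
blurs — a real-data effect, but one that makes planted truth unrecoverable
by construction rather than by method failure.

One RNG seeded once drives the whole dataset, with sub-generators drawn in a
fixed order, so a config is byte-reproducible (tested on written files).

The reference HMM used to generate labelled training profiles has background
mean 1.0, primary dip 0.35, edges 0.65 — and *shallower secondary* blocks
(0.55/0.80). Generating secondary footprints shallower than the primary one
makes the decoder reserve the primary FP state for the deep hexamer-centered
dip instead of spending it on an incidental shoulder; biologically, tandem
secondary sites protected less strongly than the profiled site are the
plausible reading. `background_coverage` scales training profiles onto the
raw coverage scale of the data to be decoded (20 for the default generator).

### What the generator does not emulate

Sequencing-read structure (everything is per-base counts), DNase cut-site
sequence bias, nucleosome positioning, isoform mixtures and partial
retention levels, correlated noise along the genome, and realistic genome
composition (the sequence is uniform, so hexamer background frequencies are
flat at ~L/4096 per part). Passing tests therefore demonstrate that the
implementation recovers planted structure under the stated noise model —
not that the biological conclusions hold on any particular real dataset.

### A note on planted-hexamer "shadows"

Inserting a fixed hexamer into random sequence necessarily elevates the
frequency of overlapping hexamers (junction k-mers sharing a 4- or 5-mer
with the insert). These shadows are genuinely enriched in the generated
sequence, and the enrichment stage correctly reports them. Truth-recovery
checks therefore classify a significant hexamer as a *statistical* false
positive only when it shares no 4-mer with any planted hexamer — the same
"same element" notion the clustering metric encodes. Control hexamers for
footprint checks are drawn unrelated to planted ones for the same reason.

## Problem sizes and numerical choices

The test suite and the acceptance script run the pipeline at desk scale:
60–250 genes for most stages, a 200-gene genome with 20 planted hexamers and
100 controls for footprint recovery, ~1100 genes (one non-first intron each)
for the DHS-content comparison at ~500 events per class, 500 labelled
profiles for HMM training, and 10^5 Monte-Carlo draws for the multi-set
oracle. Exact tests switch to approximations only where stated (Mann-Whitney
above n = 8 per group). Variance floor 1e-3 on emissions; PWM columns must
sum to 1 within 1e-3 (renormalized with a warning beyond 1e-6); BH inputs
must lie in (0, 1]. Degenerate inputs have defined behaviour throughout:
zero-margin tables give p = 1, empty event classes raise, parts shorter than
the bin count use the whole-part rule, and hexamers below the occurrence
floor are reported unscored.

## Known limitations

- Only annotated introns of the canonical transcript are classified; novel
  splice-graph-derived events are out of scope.
- The binary IR/IE call discards retention-level information (no PIR/IR
  ratio estimation).
- The 13-state wiring and the Gaussian emission family are design choices;
  alternatives (posterior decoding, heavier-tailed emissions) were not
  explored beyond exposing Viterbi as the single decoder.
- The hypergeometric conservation test treats the two species' hexamer sets
  as uniform random subsets of the 4096 universe, ignoring sequence
  composition biases shared between species.
- Peak calling is consumed, not performed: DHS peaks arrive as BED.
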