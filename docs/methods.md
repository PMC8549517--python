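# Methods

This note documents the models and numerical choices behind
`bravointegrate`: what the synthetic-data generator simulates, how the
chimera filters and junction conventions are defined, how events are
quantified, and how the statistical components are calibrated.

## The generative model (`synthdata`)

A simulated experiment consists of a host contig, a wasp contig with
planted proviral segments, a set of HIM-mediated integrations of
excised circles into the host, and single-end reads from both genomes.

**Segment geometry.** Each proviral segment is
`DRJ + A + [J2 + spacer + J1] + B + DRJ` with two byte-identical DRJ
copies (default 20 bp), interior arms A of 350–550 bp and B of
250–450 bp, and — on the `him_fraction` of segments that carry a HIM —
35-bp J2 and J1 motifs separated by a spacer drawn uniformly from
41–73 bp. The J motif lengths and spacer range give HIMs of
111–143 bp, bracketing the canonical ~121-bp motif. J1 and J2 are
*conserved*: the same motif sequence is planted in every segment, as
in real bracoviruses, which makes short junction-spanning read
portions genuinely multi-mapping (see "ambiguity" below). The arms are
kept longer than one read so junction reads always align contiguously
on the wasp genome. Base composition is uniform (configurable GC),
which makes the (1/4)^k microhomology null analytic.

**Excision and integration.** Circle excision collapses the two DRJs
into one; circles are reported linearized from the retained DRJ
(`5'DRJ → 3'DRJ` orientation), so the circle is `drj_length` shorter
than the segment. Integration linearizes the circle by cuts at fixed
canonical positions — by default the J1 start and the J2 end, so
exactly the spacer is deleted and `inserted = circle − spacer` for
every event; the cut offsets inside the motifs are configurable but
single-valued per segment, matching the observation that
no-microhomology junctions recur at one exact position. Orientation is
± with equal probability.

**Microhomology is a property of the host target site, not of the
cut.** For a requested microhomology of m bp the generator rewrites
the host reference so that the m bases after the insertion point equal
the insert's first m bases and the m bases before it equal the
insert's last m bases, then forces the (m+1)-th base on each side to
differ. Spacer boundary bases are constrained at genome-construction
time to differ from the adjacent motif bases, so the wasp-side
alignment cannot extend into the lost spacer and the doubly-aligned
overlap measured downstream equals m on both junctions. The default
microhomology distribution is uniform on 0–5 bp.

**Reads.** For each source (the integrated host, the wasp genome, and
optionally free circles at per-circle depths), `round(depth × length /
read_length)` reads of fixed length (default 150 bp) start at uniform
positions on a uniform strand. Substitutions occur at `error_rate` per
base (default 0.1 %); a `pcr_dup_rate` fraction of reads (default 2 %)
is then duplicated byte-for-byte under fresh identifiers. Indels,
quality profiles and paired-end structure are not modeled — the
chimera analysis treats reads as independent single ends. All
randomness derives from one `numpy` generator seeded by
`SimConfig.seed`; identical seeds give byte-identical datasets.

**What passing tests do and do not show.** The generator reproduces
the *structural* signal (junction geometry, microhomology, duplicate
fragments, depth proportionality) on uniform-composition genomes
without repeats other than the planted motifs. Real genomes add
transposable elements, low-complexity tracts, indel errors and mapping
biases that the round-trip results here do not speak to; the filters
and conventions are identical, but real-data precision depends on the
aligner and genome quality.

## Alignment

The pipeline consumes 12-column tabular alignments (query, subject,
identity, length, mismatches, gap opens, query start/end, subject
start/end, e-value, bitscore). Any aligner emitting that dialect
works; `align.run_blastn` wraps the NCBI binary for real genomes. For
simulated data the built-in `ReferenceIndex` aligner is used: 12-mer
indexing of the reference, query seeds every 4 bp (guaranteeing a seed
in any exact region ≥ 16 bp, the smallest side the filters accept),
gapless X-drop extension (match +1, mismatch −3, drop 9) trimmed to
the maximum-score ends. Since simulated reads contain substitutions
only, gapless extension is complete; the test suite cross-checks best
hits against `blastn` on a shared fixture. Like BLAST's X-drop
extension, the aligner can extend through an isolated mismatch when
enough matching bases follow, so observed junction overlaps can
occasionally exceed the engineered microhomology; the junction-position
uncertainty is always bounded by the observed overlap.

## Chimera classification

For each read with alignments on both genomes, one best hit per genome
is chosen (bitscore, then identity, then subject id, then subject
start — fully deterministic). A read is discarded as *ambiguous* when
any distinct-location hit comes within 16 bitscore (~8 matching bases)
of the best hit on either genome: conserved J1/J2/HIM/DRJ copies make
short read portions multi-mapping, and a wrong motif copy can even
out-score the true one by a few chance bases of extension across the
junction, so a clear margin is required rather than an exact tie. The
margin costs only reads whose diagnostic flank is shorter than ~8 bp;
at 30× depth every junction retains many unambiguous reads.

The read-coordinate intervals of the two best hits decompose the read
into wasp-only, host-only, doubly-aligned (overlap = microhomology),
inserted (gap between the intervals) and flanking unaligned bases —
five counts that always sum to the read length. Filters: (i) wasp-only
≥ 16 and host-only ≥ 16; (ii) unaligned + inserted < 10 % of the read
length (strict); (iii) overlap ≤ 20; (iv) inserted ≤ 5. Rejections are
logged with the failing filter.

**Junction conventions.** `junction_on_wasp` is the wasp alignment end
coordinate on the junction side *regardless of overlap*, so a k-bp
microhomology shifts the apparent wasp junction by up to k. The host
breakpoint is normalized to the last host base before the insertion,
so with zero overlap the J1-side and J2-side junctions of one
integration report the same host position. PCR duplicates — chimeras
identical in junction coordinates, orientation and subject-interval
boundaries on both genomes (identical sequenced fragments) — collapse
to one representative; boundary identity as the duplicate definition
is a design choice of this package.

## Quantification

An integration event is one unique (segment, host contig, breakpoint,
orientation, junction class); support is the number of deduplicated
chimeras. By default only J1/J2-class junctions are counted (the
parsimonious choice); a flag includes all categories. Normalizations:
`IPMH = IEs / (host-mapped reads / 10^6)` and `IEs per genome =
(IPMH / read length) × genome size in Mbp`; genome size is derived
from the assembly, reported in Mbp to keep the formula literal.
Round-trip scoring matches a called event to a truth event when
segment, contig and orientation agree and the positional difference is
within the observed junction uncertainty (the overlap, or the inserted
length for error-shifted junctions); events with neither must match
exactly.

The BUSCO-exon baseline (`expected_outside_him`) scales the chimera
count observed on single-copy exons by each circle's length × depth
product to give the count expected if circles behaved like ordinary
wasp sequence.

## Junction regions and the microhomology null

Junctions are histogrammed along each circle; inside the HIM, each of
the two modes is delineated as the argmax position (always retained)
extended while flanking positions hold ≥ 2 reads. The two regions are
ordered (J2, J1) along the circle and their gap tracks the deleted
spacer. Per-sample regions can be intersected for pooled reporting.

The null model draws reads as concatenations of a random circle
substring and a random host substring, each ≥ 28 bp, summing to the
read length. Each read is realigned to its sources by exact maximal
extension — which, for error-free substrings, is precisely what any
local aligner reports — and pushed through the *production*
`classify_chimera`, so the expected microhomology distribution is
measured by the identical code path as the observed one. For uniform
composition the overlap is the sum of two geometric(3/4) variables:
P(K = k) = (k+1)(3/4)²(1/4)^k, and the one-sided junction-base match
frequency is 1/4 (1/16 for two bases). Observed and expected
distributions are compared after rescaling the expected counts to the
observed total; upper-tail classes are pooled to expected ≥ 5 for the
chi-square statistic.

## Spatial randomness

Each contig is tiled with full fixed-width windows (default 100 kb)
from its start; the remainder (and contigs shorter than one window) is
excluded but its length and any events on it are accounted, so window
counts plus excluded events always sum to the total. The test
estimates λ as the mean count, computes the chi-square over occupancy
classes with the upper tail pooled to expected ≥ 5, and calibrates the
p-value by parametric bootstrap (default 199 Poisson resamples at the
estimated rate, the statistic recomputed identically). A plain
chi-square reference is anticonservative here — the rate is estimated
from ungrouped counts (Chernoff–Lehmann) — while re-fitting the rate
to the grouped classes destroys power against concentrated
integrations; the bootstrap keeps the published statistic and the
nominal level. The "maximum plausible count" is the largest occupancy
with ≥ 0.5 expected windows. All-zero counts are flagged as
degenerate, not tested.

## Duplication annotation

`search_motifs` runs the built-in aligner with motifs as queries on
both strands, reporting forward-strand coordinates. A HIM hit is a
*half-HIM* when ≥ 80 % of its aligned motif interval lies on one side
of the motif midpoint and ≤ 20 % on the other; full-length HIM hits
(intact segments) straddle the midpoint and never qualify. An Hdp is a
pair of opposite half-HIM hits bounding a region with the J1 half
outermost (mirrored on the minus strand), no DRJ hit within ±10 bp of
either extremity, and — when junction queries are supplied — junction
hits overlapping both half-hits. The retained circle DRJ *inside* the
duplication is expected and allowed; only terminal DRJs disqualify,
since they mark an ordinary proviral segment. An Rdp is a
segment-homologous region (merged segment-query hits) containing
exactly one internal DRJ hit, with neither terminal DRJs nor terminal
half-HIMs. The ±10 bp slack absorbs alignment-end fuzziness.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `read_length` | 150 bp | read size; all side/fraction filters scale from it |
| `min_side` | 16 bp | minimum genome-exclusive bases per side (filter i) |
| `max_unaligned_frac` | 0.10 | strict bound on unaligned fraction (filter ii) |
| `max_overlap` | 20 bp | doubly-aligned cap = microhomology cap (filter iii) |
| `max_insert` | 5 bp | non-templated insertion cap (filter iv) |
| `min_support` | 2 reads | J-region extension threshold |
| `null_min_side` | 28 bp | minimum side length in the random-chimera null |
| `window_size` | 100 kb | spatial-test window width |
| `drj_length` | 20 bp | simulated DRJ size |
| `spacer_length` | 41–73 bp | per-segment spacer, lost upon integration |
| `depth_host`, `depth_wasp` | 30× | fold coverage per genome |
| `error_rate` | 0.001 | per-base substitution probability |
| `pcr_dup_rate` | 0.02 | fraction of reads duplicated exactly |
| ambiguity margin | 16 bitscore | required lead of the best hit over distinct locations |

## Problem sizes used in the test suite

The reference synthetic experiment is 16 HIM segments (~60-kb wasp
contig), 200 integrations on a 300-kb host contig, 30× depth on both
genomes — about 110,000 reads realigned per run — with microhomologies
of 0–5 bp; it is run once without and once with sequencing errors. The
microhomology null uses 10⁵ simulated reads; the spatial-test
calibration uses 1,000 null replicates of 5,000 windows at λ = 0.7
with 199 bootstrap resamples each; the depth–IE correlation experiment
uses five segments at relative circle abundances 1:2:4:8:16 with
proportional integration counts.

## Known limitations

* No indels, structural errors, quality-score models or paired-end
  rescue; reads are independent single ends.
* Non-HIM integration is detected (junctions classified `outside_HIM`)
  but not simulated, so its recovery is untested.
* The duplication caller assumes motif queries that match their copies
  closely (≥ 80 % identity); deeply diverged duplications would need
  relaxed search thresholds.
* The built-in aligner is for desk-scale genomes (the k-mer index is
  an in-memory dict); use the BLAST wrapper for real assemblies.
* With all J1/J2 motifs identical across segments, reads whose
  diagnostic flank is ≤ ~8 bp beyond the motif are unassignable by
  construction and are dropped as ambiguous rather than guessed.
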