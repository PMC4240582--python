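# Methods

## Problem and scope

`p53peaks` implements a ChIP-seq analysis pipeline for mapping
transcription-factor binding sites (built around p53) and characterizing
their genomic landscape: nucleotide-resolution coverage from mapped tags,
peak calling with a dual confidence filter against an Input (pre-IP
chromatin) control, scanning for p53 response elements around peak maxima,
annotation of peaks against genes/TSSs/CpG islands/repeats under fixed
distance rules, cross-dataset comparison, and Monte-Carlo random-location
controls.  Read mapping, de-novo motif discovery and pathway annotation are
out of scope; the pipeline consumes mapped tags (chrom, 0-based position,
strand) and annotation tables.

All coordinates are 0-based half-open internally.  1-based fully-closed
dialects (RepeatMasker `.out`, browser-exported gene tables) are converted at
the parser boundary via a config switch, so the same physical feature always
yields the same interval.

## Coverage and candidate peaks

Each distinct uniquely-mapped tag (36 nt by default) is extended to the
average chromatin fragment size, 700 bp (`fragment_size`): a + tag at `pos`
covers `[pos, pos+700)`, a − tag covers `[pos+36−700, pos+36)`, truncated at
chromosome ends.  Duplicate (chrom, pos, strand) tags are removed before
coverage is built, mirroring the use of distinct reads in real libraries.

Candidate peaks are maximal runs of coverage at or above a threshold.  The
default threshold rule is Poisson: per chromosome, the smallest height `h`
with upper-tail probability `P(X ≥ h) < q` for `X ~ Poisson(λ = mean
coverage)`, with `q = 1e−4`.  Runs separated by fewer than 200 bp
(`merge_gap`) are merged; the peak maximum is the leftmost position attaining
the run's highest coverage, a deterministic tie-break.  A fixed-height rule
is available for controlled tests.

## The dual confidence filter

A candidate peak becomes high-confidence only if it passes **both** of two
independent tests at the 99% level and is not matched by a symmetric Input
peak.  The two tests are this package's own construction (the statistical
internals of such filters are rarely published in full); they are isolated
behind a narrow interface so alternatives can be swapped in:

1. **Enrichment test** (`conf_enrichment`).  Let `k` be the effective ChIP
   fragment count in the peak region (coverage mass divided by fragment
   size), `k′` the Input count plus a +1 pseudo-count (which avoids
   degenerate certainty in Input deserts).  Under no enrichment, `k` given
   `k+k′` is binomial with success probability `N_chip/(N_chip+N_input)`
   (library-size scaling).  The reported confidence is `1 − P(X ≥ k)`.

2. **Background-percentile test** (`conf_background`).  The empirical
   percentile of the peak's ChIP height among the maxima of `n = 1000`
   seeded random windows of the same width drawn from the Input track
   (chromosomes weighted by usable length).  This asks whether the Input
   background anywhere produces fluctuations as tall as the peak.

3. **Symmetric-Input disqualifier.**  A ChIP peak with an Input peak whose
   maximum lies within 100 bp and whose library-scaled height ratio
   (ChIP/Input) is ≤ 2 is disqualified regardless of its scores: such peaks
   track chromatin biases rather than immunoprecipitation.  Input peaks are
   called with the identical rule as ChIP peaks.

## Response-element scanning

A p53 response element is two `RRRCWWGYYY` decamer half-sites separated by a
0–13 bp unscored spacer.  A base matching its degenerate class scores that
position's weight, else 0; a site's score is percent of the maximal score and
sites ≥ 75% are reported.  The default weight table `[1,1,1,3,2,2,3,1,1,1]`
(max 16 per half-site) emphasizes the invariant C4/G7 core and central WW;
the published p53MH matrix is not reproduced here, so this fully-specified
table stands in, and the model is pluggable from a 10-row TSV.  Whether the
original "75%" is percent-of-max or an internally normalized score is not
recoverable; percent-of-max is used.

Because the consensus is class-wise its own reverse complement and the weight
table is palindromic, scores are exactly strand-symmetric (property-tested);
the scanner therefore scans the forward strand once and reports calls
unstranded.  Scanning runs in 2 kb windows centered on peak maxima; only
calls whose site midpoint lies within ±100 nt of the maximum are reported
per peak, with the full in-window distance table available for
site-enrichment histograms.

## Annotation rules

All associations are pure functions of the peak maximum (a single base):

- **Gene proximity**: within 20 kb upstream of the TSS, inside the gene, or
  up to 5 kb past the TES; peaks are classed as near none/single/multiple
  genes by the count of qualifying transcripts.
- **Genic bins** (12 categories + unassigned): strand-oriented distance to
  the TSS decides the five upstream and three downstream bins; exon/intron 1/
  intron >1 apply only beyond 5 kb downstream of the TSS (the distance rule
  wins closer in), and positions ≤ 5 kb past the TES map to the TES bin.
  When several genes qualify, the gene with the nearest TSS wins, so each
  peak lands in exactly one bin (the alternative — double-counting a peak for
  every nearby gene — is noted but not used).
- **CpG islands**: maximum within island boundaries extended by 350 nt (half
  the average fragment size), half-open after extension.
- **Repeats**: maximum strictly inside element boundaries; with nested
  elements the shortest (most specific) wins — a deterministic tie-break.
- **TSS profile**: counts of all TSSs at signed distances within ±5 kb of
  each maximum, in 200 bp bins.
- **Chromosome density**: Gaussian-kernel density over maxima, peak-height
  weighted, normalized per chromosome and scaled per Mb.  Bandwidth (2 Mb)
  and grid (100 kb) defaults are design choices; the density integrates to
  ~1 when kernel mass stays inside the chromosome.

The Monte-Carlo control draws points uniformly (chromosomes proportional to
length), extends each to a fragment-sized interval, and resamples points
whose fragment would overhang an edge.  The control size 6,789 matches the
largest experimental dataset it stands in for.

The interval index is an `intervaltree` wrapper with build-time slop
extension; its contract (point containment, equivalent to a linear scan,
order-stable) is enforced by randomized oracle tests.

## Cross-dataset comparison

Set-vs-set overlap uses the validated cluster rule generalized to peaks: A's
maximum within B's region extended by 350 nt.  Pairing is one-to-one,
greedily by smallest maximum-to-maximum distance, which gives a well-defined
common-set size.  PET clusters are handled by rank (PETn+ = clusters with at
least n overlapping paired-end-tag fragments, so sets are nested); a cluster
is "identified" if any peak maximum falls within 350 nt of its boundaries.
Common-site heights are normalized to percent of each set's highest peak
before computing the squared Pearson correlation (Pearson, matching the
linear presentation of such comparisons; the normalization is affine and
leaves R² unchanged, which is itself a test).

## Synthetic data: what it emulates, and what it does not

The generator's defaults define the study conditions used throughout the
tests: 2 chromosomes × 2.5 Mb; 150 non-overlapping genes with 3–8 exons;
CpG islands at 60% of promoters; repeat composition {SINE 10%, LINE 20%,
LTR 8%, Satellite 2%, Simple 2%, Low-complexity 2%} placed disjointly with
class-typical element lengths to within ±1% of target; 200 planted perfect
consensus sites with 8× local enrichment, at least 3 kb apart; ChIP and
Input libraries of 214,000 tags each, giving ~30× mean fragment coverage.

Tags are drawn from a piecewise-constant intensity.  The Input bias
{Satellite ×2.5, SINE ×0.6, LINE ×0.6, LTR ×0.6} reproduces the qualitative
Input-vs-random deviations seen in real chromatin (satellite
over-representation, SINE/LINE/LTR under-representation).  ChIP uses the
same biased base intensity multiplied by the enrichment factor in a
fragment-sized window around each planted site; fragment ends emit the tag
5′ position on a random strand, so + tags flank sites from the left and −
tags from the right as in real libraries.

Scenario presets encode the cell-line contrasts: `hct116_like` plants 30% of
sites inside LINE elements (none at CGIs), `imr90_like` plants 30% at CGIs,
12% in low-complexity repeats and 6% in LINEs, and `null` plants nothing.
Context counts are apportioned deterministically (largest remainder), so the
realized mix always matches the weights.  Accounting for random/CGI-context
sites that coincidentally fall in LINE bp (~20% of the genome), the expected
LINE fractions are 0.44 vs 0.224 — a designed ratio of ≈2 — and the CGI
fractions ~0.03 vs ~0.30.

Not modeled: sequencing errors, mappability, GC-dependent amplification,
fragment-length variation, real repeat sequence content (repeats are random
sequence with annotated coordinates), or chromatin-state structure beyond
the class-wise bias.  Passing tests therefore demonstrate the correctness
and calibration of the *pipeline logic* under a faithful statistical
abstraction, not performance on real libraries.

## Numerical choices and degenerate inputs

- Poisson thresholds are exact smallest-h searches, not approximations.
- Leftmost-argmax tie-breaks make peak maxima deterministic; fixed seeds make
  the background test and all simulations byte-reproducible.
- Empty tracks yield empty peak sets; empty peak sets report NA fractions;
  scanning sequences shorter than 20 bp yields no calls; windows at
  chromosome edges are truncated and logged.
- Background sampling requires ≥100 windows; the +1 Input pseudo-count keeps
  the enrichment test defined over coverage deserts.

## Problem sizes

The default synthetic scale (5 Mb, ~200 planted sites, ~430 k tags per run)
was chosen so a full scenario runs in seconds on one core while leaving
enough events for confidence-interval-based assertions: with ~200
high-confidence peaks per scenario, the LINE-fraction ratio has a standard
error of ~0.3, and the 6,789-point random control resolves the genomic
repeat fraction to ±0.6% (1σ).

## Known limitations

- The two confidence tests are reasoned stand-ins for an unpublished filter;
  their calibration is verified on the null scenario (≤ ~2% of candidates
  pass both tests at 99%), not against any external implementation.
- The seq-vs-seq overlap criterion (maximum within region + 350 nt,
  one-to-one nearest pairing) is declared, not claimed identical to the
  criterion behind the published common-peak count.
- Genic-bin assignment single-assigns each peak via the nearest TSS; studies
  that double-count peaks near multiple genes will differ at gene-dense loci.
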