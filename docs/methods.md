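# Methods

`iespipe` analyses programmed DNA elimination in ciliates of the
*Paramecium* type: during development of the somatic macronucleus (MAC)
from a germline (MIC) genome copy, tens of thousands of internal
eliminated sequences (IESs) are excised precisely at TA dinucleotides.
Knockdowns of chromatin remodeling factors perturb this process in two
measurable ways — IESs are retained, and excision shifts to alternative
TA boundaries.  The package quantifies both from sequencing-style
inputs and ships a synthetic-data generator so that every estimator can
be validated against known ground truth.

## Coordinate model and excision semantics

All coordinates are 0-based, half-open; GFF3 I/O converts to and from
1-based inclusive.  An IES is recorded by the positions of the T of its
left and right flanking TA (`left_ta`, `right_ta`).  Excision removes
`[left_ta, right_ta)`, so exactly one TA — by our convention the right
one — survives at the somatic junction.  Which TA is "kept" is not
observable (the two conventions produce identical somatic sequence);
the choice only fixes the arithmetic of alternative-boundary offsets,
so it is applied globally and stated here.  The IES length reported
everywhere is `excised_len = right_ta - left_ta`, which includes
exactly one TA; this makes the 26–28 bp first length peak and the
34–44 bp forbidden band internally consistent.  Sequences are handled
case-insensitively and non-ACGT characters are rejected at load with
an error naming the offending record.

## Synthetic data generator

The generator (`iespipe.simulate`) emulates the data classes of a
genome-editing knockdown experiment.  Its defaults are the package's
study conditions; everything is configurable through `SimConfig`.

**Genome.**  Uniform random ACGT scaffolds; IESs placed without
overlap by distributing the free slack uniformly among the gaps.  Each
IES gets TA boundaries, a 5 bp terminal inverted repeat
(head `TA+NNN`, tail its reverse complement), one planted internal TA
at the midpoint (≥ 3 bp from either boundary), and planted external
TAs 8 bp outside each boundary, so alternative boundary candidates
always exist.  The minimum spacing between IESs (160 bp by default)
exceeds `molecule_flank + anchor_k + min_anchor`, which guarantees that
the molecule window of one IES contains no junction context of its
neighbours — without this, reads from one IES's window masquerade as
retention evidence for the next IES and bias its score upward.

**Length model.**  IES lengths are drawn from a discretized mixture:
one third of the mass at the 27 bp first peak (spanning 26–28 bp), a
depleted tooth at 37 bp carrying the forbidden-band weight (0.01), and
a geometric comb (decay 0.85 per tooth, sd 1.0 bp) at
48 + 10.5·k bp out to ~200 bp.  These defaults reproduce the
qualitative anatomy of the natural spectrum: a dominant first peak,
a near-empty 34–44 bp band (sampled fraction ≈ 0.01), monotone decline,
and a visible 10/11 bp periodicity.

**Excision outcomes.**  Per IES copy: retained with probability ρ,
otherwise alternative with probability α, otherwise exact — so outcome
frequencies converge to (ρ, (1−ρ)α, (1−ρ)(1−α)).  Alternative boundary
pairs are drawn from the candidate set (below) with probability
proportional to `alt_decay^(|dL|+|dR|)` (default decay 0.6).  The
geometric kernel is a stated assumption: it concentrates events near
the reference boundaries, matching the observed dominance of
boundary-sharing ("partial") classes; no generative model for wrong-TA
choice is available to calibrate against.

**Reads.**  Single-end, uniform start positions, optional per-base
substitution errors.  The per-molecule read count is Poisson with mean
`depth · (L − read_len + 1) / read_len`, i.e. every valid start
position carries the same expected rate regardless of molecule length.
This coverage-uniform law matters: under the naive `depth · L /
read_len` law, longer (retained) molecules receive proportionally
fewer junction-spanning reads per placement, which biases retention
scores down by up to ~0.03 at ρ = 0.5 at these molecule sizes.  For
molecules much longer than a read the two laws coincide.  Read ids
carry molecule provenance for parameter-recovery tests.

**Nucleosome fragments.**  Lengths Normal(146, 15) truncated at
≥ 100 bp, uniform placement, with rejection sampling weighted by the
density multiplier of the overlapped IES (largest-overlap IES decides;
background weight 1).  A multiplier of 0 removes all fragments
touching that IES.

**Small RNAs.**  Configurable `(length, label, source, count)` classes
drawn as exact substrings of vector, MAC, or IES sequence sets.  Class
length bounds for scan-RNA-like and IES-RNA-like species are labels,
not hard-coded biology.

All randomness flows from one seed through deterministically spawned
child generators; every emitted file is byte-reproducible.

What the generator does **not** emulate: paired-end reads, indels, PCR
duplicates, the ~800n polyploidy of the developing MAC, MNase bias,
correlated retention across IESs, and length- or age-dependent
retention (a hook for length-dependent ρ exists but has no default
functional form).  Passing tests therefore demonstrate correctness of
the estimators under this model, not robustness to every artifact of
real libraries.

## Junction detection

For every IES the library holds two retention junctions (germline
sequence spanning each TA boundary with `anchor_k` = 25 bases of
context per side), one exact-excision junction (the somatic sequence
across the excision point), and one junction per candidate alternative
boundary pair.  Candidates are all TA pairs `(left', right')` with
`left'` within `window_W` = 20 bp upstream of the left boundary
through the IES, `right'` symmetrically, excised length ≥ 2 bp, pair ≠
reference, and excised interval overlapping the reference interval.

**Indistinguishable variants.**  Overlapping or repeated TA sites make
distinct boundary pairs yield byte-identical excision products — e.g.
excising `[a, b)` versus `[a+2, b+2)` across a TATA produces the same
molecule, and some candidate products equal the exact product.  No
read can separate these.  Candidates are therefore grouped by their
local product sequence over a fixed germline window
(`anchor_k + window_W` beyond the reference boundaries); each group is
represented by its lexicographically smallest pair, and groups whose
product equals the exact product are dropped.  The generator draws
from the same canonical set, so logged ground truth is always
recoverable in principle.

**Assignment.**  A read (or its reverse complement) is compared
against junction strings by Hamming distance over the best placement,
requiring `min_anchor` = 10 matched-region bases on each side of the
junction point; it is assigned to the unique variant with distance ≤
`max_mismatch` (default 1).  Placement search uses an exact-seed
index: any qualifying placement with ≤ d mismatches over ≥ 2·min_anchor
overlap contains an exact run of ≥ (2·min_anchor − d)/(d+1) bases, so
seed lookup plus masked verification is equivalent to the exhaustive
sliding scan (property-tested against one).  Ties across different
IESs are ambiguous; ties across categories of one IES resolve by the
priority exact > alternative > retention, then lexicographic variant
id — the priority matters because reads that span an alternative
junction with few bases on one side can also partially match a
retention junction of the same IES.

**Counting.**  Per IES: `n_plus` (distinct reads on either retention
junction), per-boundary tallies `n_plus_left`/`n_plus_right` (a read
spanning both boundaries of a short IES counts in both), `n_minus`
(exact-excision reads), and per-variant alternative counts.  Duplicate
read ids count once; counting is order-invariant.

## Retention scores

`IRS = IES+ / (IES+ + IES−)`.  The IES+ entering the score is the
boundary-averaged retention evidence `(n_plus_left + n_plus_right)/2`:
a retained molecule exposes two junctions where an excised molecule
exposes one, so the combined distinct-read count estimates 2ρ/(1+ρ)
rather than ρ.  With the boundary average the estimator is unbiased
under the simulation model (|bias| < 0.01 over 200 replicates at
per-boundary depth 30; strata ρ ∈ {0.1, 0.5, 0.9} recovered within
0.003 in the shipped acceptance run).  Scores with fewer than
`min_cov` = 5 informative reads are undefined and propagate as
explicit NaN markers, never as 0 (0 means confidently excised).  The
coverage floor is not an observed constant of the assay but an
exposed, reported analysis choice.  Cross-sample comparison uses
Pearson correlation with pairwise exclusion of undefined scores plus
an ordinary-least-squares fit; retention grouping uses IRS ≥ 0.2 as
"high" (boundary inclusive).

## Alternative-excision taxonomy and rates

With signed offsets `dL = left' − left`, `dR = right' − right`, the
five classes are: partial_internal (one offset zero, the other
inward), partial_external (one zero, the other outward), internal
(dL > 0 ∧ dR < 0), external (dL < 0 ∧ dR > 0), and overlap (both
nonzero, same sign).  The overlap requirement is evaluated on the
excised intervals; non-overlapping pairs are "detached" and excluded
from the five-class tally.  The per-IES alternative percentage is
`100 · alt / (alt + exact)` over excision-supporting reads — retention
reads are not in the denominator, because the quantity is the error
rate *among excisions*; including retention reads would conflate the
two knockdown phenotypes.  A `legacy` estimator mode reproduces the
caveat of skipping IESs whose mapped excision reads are all
alternative (undefined instead of 100 %), quantifying how that
convention underestimates the mean.  Class shares are reported both
read-weighted and variant-weighted.

## Length spectra

Peak bands are closed integer intervals: `[26, 33]` (peak 1, anchored
by the dominant 26–28 bp class), `[34, 44]` (forbidden), then bands
with boundaries at `floor(44 + 10.5k)` — troughs of the 10.5 bp comb —
with the last band open-ended; lengths below 26 bp are "sub-minimal".
"Forbidden" is its own label rather than "peak 2".  Histograms use
1 bp bins.  Origin attribution maps each forbidden-length alternative
event to the peak band of its *reference* IES length and reports the
read-weighted distribution.

**Periodicity.**  The integer histogram is mean-detrended and its
autocorrelation evaluated at lags 5–20.  For a 10.5 bp comb the second
harmonic (lag 21) aligns the teeth exactly while the fundamental
splits over lags 10 and 11, so a plain argmax reports the harmonic
shoulder at lag 20 for any realistic tooth width.  The fundamental is
therefore read out with standard subharmonic suppression: the
smallest-lag local maximum reaching at least half the global maximum.
Confidence uses harmonic support — the mean of the normalized
autocorrelation at the chosen lag and its strongest second harmonic
(lags 2p−1..2p+1): a genuine comb reinforces its harmonic
(score ≈ 0.25 for the default generator) while a chance peak in white
noise does not (≤ 0.17 observed); the default threshold is 0.2.
Estimates need ≥ 200 lengths spanning ≥ 3 bands, else they are
undefined.

## Nucleosome densities

`density_i = (coverage_bases_i / excised_len_i) / (total_frag_bases /
genome_len)` — per-base fragment coverage of the IES relative to
genome-average per-base coverage, counted by base overlap rather than
fragment midpoint (robust when ~146 bp fragments rival IES lengths).
Uniform tiling gives density 1.0 everywhere and the measure is
invariant to library size.  Normalization is to the genome average
rather than local flanks: it is a single, exactly testable convention.
Differences are experiment minus control per IES, summarized by mean
and spread, and stratified by retention (IRS ≥ 0.2 high) crossed with
length (≥ 200 bp long), both boundaries inclusive.  The metagene
profile rescales each IES body to a fixed bin count with fixed-width
flank bins.  Dyad-level nucleosome positioning is deliberately out of
scope — at these read lengths old- and new-MAC molecules are not
separable and positions cannot be called reliably; densities are the
supported statistic.

## Small RNA accounting

Reads are classified by exact substring match (either strand) against
the feeding-vector sequence, annotated IES sequences (germline-only),
and the somatic genome, with priority vector > IES > MAC resolving
multi-target matches; everything else is unmatched, and reads outside
15–35 nt are dropped with a tally so totals are conserved.
MAC-matching abundances are normalized against the MAC-matching 23 nt
siRNA class.  Off-target prediction finds all maximal exact shared
windows ≥ 23 nt between a transcript and either strand of an RNAi
construct (no mismatches); each window of length w supports
w − 22 distinct siRNAs.

## Pipeline and problem sizes

`run_pipeline` chains simulate → detect → count → score → classify →
spectra → densities → sRNA, writes plain-text artifacts
(FASTA/GFF3/FASTQ/BED/TSV) plus a JSON summary, and is byte-
deterministic given the seed; every TSV carries the config hash and
seed.  The feeding-vector stand-in used by the demo pipeline is a
synthetic fixed-seed sequence, not the real plasmid.  Validation runs
use a few hundred IESs on tens-of-kilobase scaffolds with ~15–60
molecule copies per IES — sizes at which every recovery check has
comfortable statistical power while a full run stays in the
seconds-to-minutes range; all of them scale up linearly via
`SimConfig`.

## Known limitations

* Indels and structural errors in reads are not modeled and not
  tolerated by the Hamming matcher.
* Ambiguity across IESs is resolved by discarding (counted), not by
  fractional assignment.
* The alternative-boundary kernel and the length mixture are stated
  synthetic assumptions, not fitted models; analyses that depend on
  their exact shape (e.g. class-share magnitudes) are qualitative.
* Per-IES retention is simulated independently across IESs; real
  knockdowns show correlated, age- and length-structured retention.
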