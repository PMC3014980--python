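# Methods

## Scope and model

`junctioneer` analyzes finished, Sanger-scale sequences of a duplicated
locus: two or more allele/haplotype sequences of the same chromosomal
region, optionally with feature annotations, a user-supplied TE library,
and 3' RACE clone reads.  The underlying model of locus evolution is the
one that tandem gene arrays in plants exhibit: an array of near-identical
units (period in the 5–13 kb range in the motivating system) modified by
TE insertion (with 2–12 bp TSDs), abortive excision → double-strand break →
exonucleolytic resection → NHEJ repair with 1–2 filler fragments copied
from within ~100 bp of the break ends on either strand, unequal crossover
at short exact anchors, and background SNP/indel divergence of 0.2–5%.
Each mechanism is detected from its junction signature alone; no
probabilistic scoring is attempted (Non-goal: short-read SV calling).

## Alignment

Alleles of one locus are typically >99% identical, so the pipeline uses
exact dynamics where affordable and a conservative anchor heuristic where
not:

* **Scoring.** match +1, mismatch −2, affine gap cost `gap_open +
  k·gap_extend` = `4 + k` for a gap of length k.  The paper-scale
  comparisons this package reconstructs do not state alignment parameters;
  these are fixed package defaults, and identity catalogs are insensitive
  to them at <1% divergence.
* **Exact mode** (inputs ≤ 20 kb): Gotoh DP via Biopython's C
  `PairwiseAligner`.
* **Anchored mode** (longer inputs, or forced): unique shared 15-mers are
  chained by longest increasing subsequence on the second coordinate,
  co-diagonal overlapping anchors are merged, and every inter-anchor region
  is closed with the same exact DP (regions whose DP matrix would exceed
  ~3·10⁷ cells are left as paired deletion+insertion; at locus-scale
  identity this does not occur).  A pair sharing no unique 15-mer returns
  an explicit `unalignable` signal rather than an exception.
* **Representation.** An alignment is an ordered list of gapless aligned
  segments; inter-segment gaps are the indel events.  SNPs are mismatch
  columns, one indel event per maximal gap run (lengths reported
  separately), and identity is computed over *all* alignment columns
  including gaps — the "consensus sequence" denominator used when alleles
  are described as, e.g., 99.8% identical.

Equivalence of the anchored path with exact DP (score and full catalog) is
enforced in tests against an independently written full-matrix numpy Gotoh
oracle on random pairs ≤ 2 kb at 0.5–5% divergence.

## Junction calling and canonical placement

Alignment gaps become `Junction` objects (deleted reference interval,
inserted alternate string, flanking contexts).  Two normalizations matter:

* Gap runs separated by fewer than 10 matched bases merge into one variant
  region — affine DP freely aligns fragments of a filler insertion against
  deleted reference sequence, fragmenting one biological junction.
* Boundaries are re-derived by maximal exact prefix/suffix matching over
  the span between the midpoints of the flanking anchor blocks, preferring
  the 5' (prefix) side on overlap.  This is needed because aligning k
  insert bases against k deleted bases costs at most the 2k gap-extension
  columns it saves, so the DP systematically absorbs junction bases into
  adjacent match blocks; exact re-derivation restores the canonical
  placement that offsets ("27 bp downstream") are measured from.  For a
  tandem-duplication insertion, whose placement is inherently ambiguous
  along the repeat, the rule lands on the 3' copy boundary deterministically.

## Detectors

* **TSD**: the longest exact direct repeat (2–20 bp) abutting both element
  ends; maximal by construction (extending one base breaks it).  Windows
  containing `N` never match, here and in every exact-match search.
* **Filler decomposition**: greedy maximal-prefix left-to-right; each
  fragment must occur exactly (either strand) within W = 100 bp of either
  deletion endpoint (donors observed in the motivating system lie 21–59 bp
  away); fragments shorter than 4 bp (the smallest attributed fragment in
  that system) remain unexplained remainder.  Donor ties break to the
  nearest occurrence, then downstream, then + strand — stated explicitly
  because 4-mers recur by chance.  The strand-adjusted concatenation of
  fragments plus remainder always reconstructs the insertion exactly.
* **Tandem arrays**: candidate periods come from repeated 16-mer spacings;
  for each period p the match profile `m[i] = (s[i] == s[i+p])` is scanned
  for runs seeded by ≥16-bp exact cores (a chance core has probability
  4⁻¹⁶ per position) and bridged across ≤50 bp interruptions, with
  adjacent-copy identity ≥98% by default.  The homology run extends past
  the last full copy by exactly the crossover anchor length, so
  `anchor_len = run_len − (n_copies − 1)·p`; edge SNPs can trim a run by up
  to one core length per side, which the run-length threshold tolerates.
  Harmonic calls (period 2p covering the same span) are suppressed in
  favor of the fundamental period.
* **Flanking repeats**: longest near-exact (≥95%) direct repeat pair
  immediately bracketing an insertion, scanned longest-first; misphased
  longer candidates in a tandem context score ~25% identity and cannot
  pre-empt the true length.
* **Classifier precedence** (deterministic): TE insertion (library match
  ≥80% identity over ≥80% of entry length, either strand, plus a TSD) →
  tandem duplication (insertion ≥98% identical to same-length adjacent
  reference) → NHEJ filler (deletion whose insertion is ≥50% explained) →
  unequal-crossover deletion (clean deletion with ≥4 bp endpoint
  microhomology or a flanking-repeat pair) → unclassified, which is a
  valid outcome.  Confidence is `strong` when the decisive evidence exceeds
  its threshold by at least twofold.

## Recombination breakpoints

For a parent–parent–recombinant trio, both parents are aligned to the
recombinant; informative sites are columns where the parents differ and the
recombinant matches exactly one.  The breakpoint interval is the widest
consistent bracketing — (position of the last site supporting the first
parent, position of the first site supporting the second].  All sites
supporting one parent yields "no crossover"; more than one switch returns
every switch interval with a multi-switch flag.

## Poly(A) mapping

Reads are trimmed by enumerating suffix cut points and taking the longest
suffix that starts with A, is ≥8 bp, and contains ≤10% non-A (Sanger-
quality clones).  The templated insert is matched ungapped with ≤1 mismatch
per 50 nt; multi-locus ties are rejected as ambiguous.  The cleavage
position is the last templated base, then extended 3' while reference
bases match the trimmed tail in order (`max3`, default).  This rule serves
two purposes: genomic A-runs after the cleavage site make the position
inherently ambiguous (the most-3' consistent position is reported, a
configurable choice — `min5` reports the most-5'), and tolerant trimming
can strip templated bases from an A-rich 3' end, which tail-sequence
matching re-assigns.  Positions are reported 1-based after the stop codon.
Fractions are computed over all accepted reads and sum to exactly 100
before min-count filtering; sites occurring fewer than `min_count = 2`
times (the "plotted only when they occurred more than once" convention)
are suppressed from reports but retained in totals.  Feature overlap is
labeled with LTR > TE > other precedence.

## Simulator

A single `numpy.random.Generator` keyed by the config seed drives all
randomness; a fixed seed gives byte-identical output, and replaying the
ordered truth-log records on the ancestor reproduces the derived allele
byte-for-byte.  Defaults mirror the study conditions: 11 array copies of a
12-kb unit, TSDs 2–12 bp, resection geometric with mean 300 bp (the
memoryless minimal assumption — only outcomes, not length distributions,
are observable), filler window 100 bp with 1–2 fragments of uniform(4, 15)
bp on Bernoulli(½) strands, 8-bp crossover anchors, and a default 18-site
cleavage distribution spanning positions 141–329 with a 36% modal site at
301.  Simulated RACE reads carry uniform(10, 30) untemplated A-tails;
cleavage positions are canonicalized under the maximal-extension rule
before logging so that exact recovery is well defined.

What the generator does *not* emulate: sequencing error beyond the tail
model, heterozygosity, nested/fragmented TE families, gene conversion
tracts, or indel divergence between array copies (copy divergence is
SNP-only, keeping array periods exact).  Passing tests therefore
demonstrate correctness of the detectors under the stated mechanisms, not
robustness to assembly artifacts.

## Evaluation harnesses and problem sizes

Round-trip rates are computed on many independent single-event loci
(1.5–3 kb carriers, one event each) rather than one monolithic locus, so
500 mixed events evaluate in seconds and each recovery is attributable:

* TSD length and duplication period: exact recovery required (100%).
  Clean-settings insertion sites are those whose flanking context cannot
  extend the duplication by chance (resampled during generation; the
  detector's maximality makes a chance-extended context a different, also
  correct, answer).
* Filler attribution: the detector receives the logged junction and must
  re-identify each fragment's donor *locus* — same side and strand, donor
  intervals overlapping by ≥half a fragment length.  Junction placement is
  ambiguous up to shared edge bases, so raw offset equality is not the
  meaningful criterion; chance donors of 4-bp fragments bound the
  achievable rate, hence the ≥90% floor.  End-to-end recall through
  alignment and classification is reported separately
  (`nhej_event_recall`): very short inserts inside large deletions can be
  absorbed by legitimate alignment ambiguity.
* Breakpoint containment: crossovers between 1%-diverged haplotypes of a
  3-copy array; the reported interval must contain the logged crossover in
  every replicate where informative sites exist on both sides.
* Poly(A): 500 reads from the default 18-site multinomial; all canonical
  positions must be recovered exactly and per-site fractions must fall
  within binomial 95% CIs of the drawn distribution.

The two canonical junction reconstructions (a single 9-bp filler at +27 bp
with 203-bp flanking repeats produced by a less-than-one-unit deletion in
a tandem array; a two-fragment 13-bp filler with donors 59 bp downstream
and 21 bp upstream plus an 8-bp-anchored 1,269-bp duplication) are built
by seeded generators that assert the uniqueness constraints the
architecture requires — e.g., no spurious donor occurrence nearer than the
planted one, and boundary bases that do not extend by chance.  These
constraints define the architectures; they are not tuned to detector
output.  A known discrepancy in the source material for the downstream
donor distance (59 vs 55 bp) is resolved in favor of the running-text
value (59).

## Numerical and degenerate-input choices

Empty sequences are alignment errors; unalignable pairs are signals.
Fractions use double precision with an explicit 1e-9 conservation
tolerance in tests.  `N` bases are accepted in input but excluded from all
exact-match windows.  Thresholds are constructor/CLI parameters
everywhere; the values quoted above are the defaults.  Internal
coordinates are 0-based half-open; GenBank (1-based inclusive) and
figure-style positions ("nt after the stop codon", 1-based) are converted
at the I/O boundary only.

## Known limitations

Anchored alignment assumes collinearity; inversions and translocations are
out of scope.  The tandem-array detector assumes SNP-level (not indel)
divergence between copies at a fixed period.  The classifier's precedence
is sharp: a TE insertion whose TSD was eroded classifies as unclassified
rather than guessing.  Accession-based catalogs (the deposited GenBank
records) require a one-time download via `scripts/fetch_accessions.py`;
no test depends on them.
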