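# Methods

This note documents the models, conventions and numerical choices behind
`virusscout`, in the order the pipeline runs.

## Sequence model and alphabets

All sequences are stored internally in the uppercase DNA alphabet
{A,C,G,T,N}; RNA input (U) is converted to T on parsing. Base-bias tables
are reported in the RNA alphabet (U labels), because the biological
signatures they describe (1U, 10A) are conventionally stated for RNA.
N is legal in references, is never emitted by the simulator, and behaves
as "matches nothing" during mapping — an N aligned to anything, including
another N, counts as a mismatch. k-mers containing N are excluded from
assembly, and N read bases contribute nothing to curation pileups or base
frequency matrices.

## Adapter trimming

The 3′ adapter is located as the lowest-error semi-global occurrence:
every start position where the adapter overlaps the read's 3′ end by at
least `min_overlap` (default 3) is scored by mismatch fraction within the
overlap, and the occurrence with the lowest fraction wins, ties going to
the earliest start (the longest adapter match). Defaults
`max_error_rate = 0.1` and `min_overlap = 3` are common small-RNA
practice. Qualities are ignored during trimming. Reads shorter than
`min_len` after trimming are discarded; curation keeps the window
[18, 35] by default while analysis tables restrict to [18, 31]
(keep-wide-filter-late). Trim decisions are cached per distinct sequence,
which makes deep libraries (dominated by duplicate sRNAs) cheap.

## Assembly

Canonical-k-mer de Bruijn graph, k = 17 (odd k forbids palindromic
k-mers, so a k-mer and its reverse complement always collapse to one
node). Only strict unitigs are reported: a path never extends through a
node whose out-degree (in the walk direction) or whose successor's
in-degree differs from 1. There is no tip clipping or bubble popping —
sRNA contigs are short, and the downstream homology search tolerates
fragmentation; this is a deliberate simplification relative to
fuller assemblers, traded for determinism (output is invariant to read
order and to reverse-complementing any subset of reads; contigs are
emitted in canonical orientation, sorted by length then lexicographically).

The automatic coverage cutoff is half the length-weighted median of
preliminary unitig mean k-mer coverage — a testable stand-in for the
expected-coverage heuristics of de Bruijn assemblers. Libraries whose
weighted median coverage is below 2 get cutoff 0.0 so that shallow
fixtures are not silently emptied. Contigs below the cutoff or shorter
than `min_contig_len` (default 50) are removed.

## Homology search and detection statistics

Seeding is megablast-like: a (query, subject, strand) pair is considered
only when it shares at least one exact word of `word_size` (default 17);
the query's reverse complement is scanned for the minus strand. Each
seeded pair is then extended with Biopython's `PairwiseAligner` in local
mode under +1/−2 match/mismatch and BLAST-convention affine gaps (a
length-L gap costs 5 + 2L, mapped to open −7 / extend −2 in Biopython's
convention). The aligner returns the optimal local alignment of the pair,
which dominates any x-drop-truncated extension; the `x_drop` parameter is
accepted for interface parity but has no effect. One best hit is reported
per (query, subject, strand) — distinct secondary HSPs on the same pair
are not enumerated, which leaves subject ranking unaffected at desk scale
since fragmented queries arrive as separate contigs.

Scores use Karlin–Altschul statistics with λ = 1.28, k = 0.46 (the
+1/−2 parameters): bitscore S′ = (λS − ln k)/ln 2 and
E = k·m·n·e^(−λS) with m the query length and n the total database
length. No effective-search-space length adjustment is applied, a
documented divergence from NCBI BLAST; bit-exact agreement with NCBI
tools is not a contract — cutoff behaviour (E ≤ 10⁻⁴ for discovery,
≤ 10⁻³ for scaffolding) and ranking are. Detection sums bitscores per
subject; the ranked table is the primary output, and a configurable
minimum summed bitscore (default 50) backs the optional boolean
"library is positive" call.

## Guided scaffolding and curation

Contigs are placed at their hit subject-coordinates (reverse-complemented
for minus-strand hits). Overlaps resolve to the hit with the higher
bitscore, ties to the lexicographically smaller contig id. Uncovered
positions keep the guide base, emitted lowercase — a full-length sequence
with a case-encoded and separately serialized provenance mask, rather
than N-filled gaps, so downstream mapping works immediately and
guide-derived spans stay auditable. Gapped hits are re-aligned globally
against their guide segment to recover a per-position column map;
contig insertions are dropped and deletions keep the guide base
(substitution-only scaffolding, consistent with the ungapped mapper).

Curation is a single majority-vote pass over the read pileup: at every
position with coverage ≥ `min_cov` (default 5) where the most frequent
read base differs from the scaffold base with frequency ≥ `min_frac`
(default 0.5), the base is replaced and logged. These two knobs are the
explicit, configurable automation of what is traditionally a manual SNP
inspection. One pass only, no re-mapping — mirrors a
single round of manual review and keeps the operation deterministic and
(in practice) idempotent. Note the coverage gate's consequence: mutation
clusters denser than the mapping mismatch budget (e.g. three
substitutions inside one 25-nt read span at two allowed mismatches) shed
the reads that span them, can drop local pileup below `min_cov`, and then
remain uncorrected by design.

## Mapping

Ungapped (Hamming) alignment of full-length reads on both strands with
m ∈ {0,1,2} mismatches — small-RNA reads are 18–31 nt and the
profiling conventions are mismatch-count interfaces, so indels are out of
scope. Full sensitivity is guaranteed by pigeonhole seeding: the read is
cut into m+1 disjoint seeds of length ⌊L/(m+1)⌋; any placement with ≤ m
mismatches contains at least one error-free seed, every seed match is
verified exactly, and the result provably equals a sliding-window scan
(property-tested against one). `best_stratum` reporting (the default)
keeps only placements at the read's minimal mismatch count;
`n_placements` counts that stratum and backs the default multi-mapping
weight of 1/n_placements per alignment ("unique" policy; a weight-1
"all" policy is available and recorded in every report, since the
upstream tools' policy is unstated). Placement lists are cached per
distinct read sequence.

## Profiling

RPM = weighted mapped count × 10⁶ / curated library size; the curated
(post trim + size filter) denominator makes libraries comparable and a
raw-read denominator is available by flag. Coverage maps add each
alignment's weight to every covered position per strand (span mode, the
readmap convention); a 5′-position-only mode exists for positional
fingerprint plots. The conservation identity Σ_position coverage =
Σ_(len,strand) count × len holds exactly under identical weighting and is
asserted in tests. The contamination check maps the curated library onto
a donor-cell marker sequence at ≤1 mismatch and flags the library at
marker RPM ≥ 0.2 (the default operating threshold; the boundary is
inclusive by default and configurable to strict-above).

## Fingerprinting

Base frequency matrices are computed per strand over a size class
(piRNA class 26–29 nt; the siRNA class is fixed at 20 nt), with position
1 at each read's own 5′ end on either strand and rows beyond a read's
length receiving no contribution. u1 is the position-1 U fraction of
antisense reads (primary signature at ≥ 0.5 by default), a10 the
position-10 A fraction of sense reads in responder orientation.

The distance histogram pairs every plus-strand alignment (5′ at s) with
every minus-strand alignment (5′ at a, plus-strand coordinates) of the
size class that overlaps it by ≥ 1 nt, adding the product of the two
alignment weights to bin d = a − s for 1 ≤ d ≤ D (default D = 30). All
overlapping pairs are counted (the pair-inclusion rule of the reference
analytics is not recoverable, so the inclusive rule is fixed
project-wide and stated in report headers); under this convention the
canonical 10-nt 5′ overlap of secondary biogenesis falls at d = 9. The
ping-pong score is a z-score of bin 9 against the empirical null of all
other bins (sample SD; defined as +∞ when the other bins are constant
and bin 9 exceeds them). Signature calls: primary = u1 ≥ 0.5;
ping-pong = modal bin 9 with z ≥ 3; secondary = ping-pong plus
a10 ≥ 0.5. All thresholds are configurable.

## Simulator

The simulator emulates a persistently infecting positive-sense RNA virus
in an insect sRNA library. Defaults, chosen once as the study
conditions: genome 6,500 nt at GC 0.45 with a 1,250-nt 3′-coterminal
subgenomic region; viral reads split 70% siRNA / 15% primary piRNA /
15% ping-pong (matching a persistently infected cell line in which
roughly a quarter of viral reads are piRNA-sized); siRNA length 20 nt
with a 0.6 sense fraction;
piRNA lengths 26–29 weighted {0.20, 0.40, 0.25, 0.15} (peak at 27 nt);
primary u1 bias 0.9 and sense fraction 0.3; positional hotspots as ×3
sampling weight on the 5′-terminal 500 nt and on the subgenomic region;
transposon component 2% as fully ping-pong pairs from a simulated 2-kb
element; host background from a simulated 20-kb transcript pool;
substitution error rate 10⁻³ per base; 21-nt 3′ adapter ligated and reads
emitted at a 36-cycle sequencer length.

Two constructions matter for verification. First, `u1_bias` is the exact
probability that a primary piRNA read starts with U: with probability
u1_bias the locus is drawn from 5′-U-compatible positions and otherwise
from the complement, so the parameter itself is the recovery target.
Second, ping-pong pairs are geometric: the antisense initiator's 5′ end
sits on a genomic A (hence reads start with U), and the sense responder's
5′ end is placed 9 nt upstream in plus-strand coordinates — the
canonical 10-nt 5′ overlap — which forces responder position 10 to be A
without any base editing, so error-free reads still map at zero
mismatches. A single seeded NumPy generator drives all draws; identical
parameters and seed give byte-identical FASTQ.

What the simulator does not model: ligation and PCR biases, quality-score
structure, indels, real host transcriptomes, and genuine viral
quasispecies structure. Passing recovery tests therefore demonstrates
correctness of the pipeline's computations under the stated statistical
model, not robustness to every artefact of real libraries.

## Problem sizes and tolerances

Statistical recovery tests run at the sizes stated in their docstrings —
e.g. RPM recovery at 10⁶ reads for design fractions 10⁻³ and 10⁻²,
u1 recovery at 2,000 reads, ping-pong geometry at 5,000 pairs — with
acceptance bands of 3 binomial standard errors throughout. Oracle
equivalence checks (mapper vs sliding-window scan, aligner vs quadratic
Gotoh DP, histogram vs O(n²) pair enumeration) are exact. Floating-point
identities (RPM linearity, coverage conservation) are asserted at
relative tolerances ≤ 10⁻¹². Determinism checks compare output files
byte for byte.

## Known limitations

- Single best hit per (query, subject, strand); no masking/dusting; no
  protein-space search.
- Substitution-only everywhere downstream of assembly (no indel calling
  during curation).
- The automatic coverage cutoff is a reconstruction of "automatic", not
  a reimplementation of any specific assembler's heuristic; contig counts
  on real data should be treated as approximate.
- The pipeline is single-threaded; stage outputs are plain files and the
  orchestration is deterministic by construction.
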