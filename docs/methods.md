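# Methods

This note documents the models, rules and numerical choices implemented
in `minitag`, in the order the pipeline applies them.

## Tagged primer scheme

Four fixed core primers define the two markers: 27F
(`AGAGTTTGATCMTGGCTCAG`, the M is IUPAC A/C) and 1492R
(`GGTTACCTTGTTACGACTT`) for the bacterial 16S rRNA gene; ITS1F
(`TCCGTAGGTGAACCTGCGG`) and ITS4 (`TCCTCCGCTTATTGATATGC`) for the fungal
ITS region. A round-1 tagged primer is `tag1 + core` with a 24 bp
sample tag; a round-2 primer prepends a further 26 bp tag
(`tag2 + tag1 + core`), so every round-2 primer contains its round-1
primer as an exact suffix — the nested-PCR structure the demultiplexer
must disambiguate. Full round-1 primer lengths are 44/43 nt (16S F/R)
and 43/44 nt (ITS F/R); round-2 adds 26 nt.

Tag sequences are generated, not transcribed from a published list
(none is available). The generator draws uniform random ACGT strings
and accepts a candidate only if: GC content lies in [0.40, 0.60];
homopolymer runs are ≤ 3; it contains no exact 12-mer from any core
primer or its reverse complement; and its edit distance to every
previously accepted tag is at least 8 (24-mers) or 9 (26-mers). The
distance floor is the demultiplexing safety margin: converting one tag
into a better match for another tag's library requires ≥ 8 coordinated
errors, far outside what the per-read error model produces over 24
bases. Generation is rejection sampling with a bounded retry budget and
is deterministic given its seed. One tag pair is assigned per sample
and reused on the forward and reverse primers of that sample's
libraries; classification only requires that the two ends of a read
agree on one library, which this satisfies while minimising the number
of distinct tags.

The default experimental design expands to 80 libraries: 38 DNA
extracts (36 soil samples from twelve containers over two time points,
plus two leaf samples) templating 16S round-1, and a 14-sample subset
(single-sampled containers and leaves) templating 16S round-2 and both
ITS rounds — 52 round-1 and 28 round-2 libraries in total. Expansion is
a pure function of its config.

## Primer alignment

Local alignment uses match +1, mismatch −2, and affine gaps with open 2
and extend 1 (a gap of length *g* costs 2 + *g*) — blastn-like
parameters appropriate for short, high-identity matches. IUPAC codes in
primers match any of their bases at full match score; N in a read
matches nothing. `smith_waterman` is exact full dynamic programming
(numpy row recurrence; the within-row gap pass is resolved exactly with
a prefix-maximum, valid for affine costs); traceback yields start/end
coordinates on both sequences and the per-column composition, from
which primer coverage = aligned primer bases / primer length.

For pools, aligning all ~160 tagged primers against every read would be
wasteful, so demultiplexing screens candidates hierarchically: the four
core primers (both orientations) are located in each 150 bp end zone
with bounded-edit-distance edlib searches (≤ 6 edits); a core hit fixes
marker, orientation and strand, and the region adjacent to the core is
ranked against every library's tag block by anchored edit distance.
The few best tag candidates (within +3 edits of the best, at most 5,
and below 40 % of the tag length) are then rescored with the exact
Smith–Waterman routine, which is what produces the reported hits. Any
candidate that could win on alignment score survives this screen by a
wide margin (the tag distance floor is 8), so the screen changes
nothing about which hit wins — only how much work is done per read
(~4 ms against the full 80-library sheet).

## Demultiplexing rules

A read is assigned to a library when all of the following hold,
evaluated in order:

1. **Length window.** The full (untrimmed) read length must fall in a
   marker window — 16S 1200–1700 bp, ITS 600–900 bp, bounds inclusive,
   windows validated as disjoint. Reads outside every window are
   `length_fail`; the winning marker's window is re-checked after the
   primers are identified.
2. **Coverage.** Only primer hits covering ≥ 90 % of the primer are
   used; the boundary is inclusive (40/44 aligned bases = 0.909 passes,
   39/44 = 0.886 fails). This rule is also what separates PCR rounds: a
   round-2 primer aligned to a round-1 read covers at most 44/70 ≈ 0.63
   of itself and is discarded.
3. **Terminal anchoring.** A chosen head hit must begin within 12 bases
   of the read's 5′ end, a tail hit must end within 12 bases of the 3′
   end. Amplicon reads are primer-terminal, and this is what prevents
   the round-1 primer nested *inside* a round-2 read (whose hit starts
   ~26 bases in) from capturing the read when noise clips the round-2
   primer below 90 % coverage. Twelve bases tolerates the indel drift
   of the error model with a large margin while excluding the 26-base
   offset decisively.
4. **Both ends, one library.** The top-scoring coverage-passing hit in
   the first and last 150 bases must name the forward and reverse
   primer of the same library on opposite strands (`barcode_mismatch`
   otherwise — this is also how tag-swapped chimeras surface). Ties
   break by higher coverage, then lexicographic primer name, so output
   is deterministic.
5. **Ambiguity guard.** If a coverage-*failing* hit at either end
   outscores the chosen hit and names a different library, the read is
   discarded as `coverage_fail` rather than assigned on weaker
   evidence. On a genuine round-1 read the nested round-2 primer aligns
   only its round-1 suffix and cannot strictly outscore, so the guard
   never fires there.

The insert strictly between the two primer alignments is trimmed out
and reverse-complemented to insert-forward orientation when the read
came off the minus strand. Every read receives exactly one status
(assigned, no_forward_hit, no_reverse_hit, barcode_mismatch,
length_fail, coverage_fail); statuses always sum to the input count.
Rules 3 and 5 are the package's own additions to the coverage/both-ends
scheme: without them, measured cross-library assignment at 9 % error is
~1 % (all round-1/round-2 confusions within a sample); with them it is
zero across every pool simulated in the test suite, at the price of a
slightly higher unassigned fraction. Base qualities are ignored
throughout.

## Taxonomy by thresholded LCA

Trimmed inserts are searched against a marker reference set with
`blastn` (megablast, 12-column tabular output); any external tool
emitting the same dialect can substitute. Per read, multiple HSPs
against one reference collapse to the best one. A read is assignable
when its top bitscore is ≥ 100 (inclusive); the candidate set is every
hit with bitscore ≥ 0.995 × top (inclusive), and the assignment is the
deepest lineage that is a prefix of all candidate lineages. The
100-bit floor applies to the top hit only: candidates below 100 bits
but within 99.5 % of the top are retained. The relative rule is
scale-free; the absolute floor inherits blastn's Karlin–Altschul
parameters (the package's own `bitscore` uses λ = 0.625, K = 0.41, the
gapped defaults for its +1/−2 scoring, and is used for primer-hit
scores only). Raising the relative threshold t can only shrink the
candidate set, so assignment depth is monotone non-decreasing in t.

Each distinct assigned lineage string is one OTU; identical terminal
names under different parents remain distinct. Reads assigned exactly
at the root are kept as a `root` placeholder taxon so conservation
accounting stays intact, and are removed by the kingdom filter.

## Community statistics

Filters apply in a fixed order: kingdom first (keep taxa whose
root-most rank is Bacteria for 16S, Fungi for ITS), then minimum count
(keep taxa with ≥ 2 reads summed over all samples of the marker; a
per-sample variant exists behind a flag). The order matters — the two
filters do not commute — and the pooled reading of the ≥ 2-read rule is
used because the filter is defined against marker-wide totals.

Per sample: N is the demultiplexed read count; OTU the number of
retained taxa with ≥ 1 read in the sample; Ns their summed counts
(Ns ≤ N always); Ns/ng divides by the library's input mass (default
0.49 ng); S = −Σ pᵢ ln pᵢ (natural log, the convention of the usual R
vegan default); R = 1 / max pᵢ. Samples with no retained reads report
S and R as missing. Bray–Curtis dissimilarities are computed with
scipy's `braycurtis` metric; pairs involving an all-zero sample are
missing, and the matrix is exported for external ordination and
clustering tools (NMDS/bootstrap clustering are out of scope). A
phylum-level roll-up aggregates lineages at rank 2 and conserves column
sums.

## Simulator

The simulator emulates the study's setting at toy scale with full
ground truth.

*References.* For each marker, a root sequence is drawn and evolved
along a random taxonomy tree (default depth 6 below the kingdom, 1–3
children per node, 3 % substitutions per branch), so taxa sharing
lineage share sequence identity — which is what gives the LCA stage
non-trivial candidate sets. Leaf insert lengths are uniform over
1150–1500 nt (16S) and 520–750 nt (ITS), chosen so that a full tagged
read (insert + 87 bp of round-1 primers or 139 bp of round-2 primers)
always lands inside its marker's demux length window.

*Communities.* `raw` soil draws a symmetric Dirichlet(5) over all taxa
(even, diverse); `sterilized` soil keeps 1–3 surviving taxa at 5 %
relative yield (autoclaved soil contains almost no DNA); and
`post_treatment` mixes a Dirichlet(0.3) draw with a 50 % share for one
dominant taxon (a skewed, lower-diversity community).

*Reads.* Each read is `fwd_primer + insert + revcomp(rev_primer)` with
degenerate primer positions resolved randomly, flipped to the minus
strand with probability 1/2, then corrupted with i.i.d. per-base
substitutions, insertions and deletions (3 % each by default, a
nanopore-like 9 % total for the study's era; expected read length is
clean length × (1 + ins − del)). An optional chimera fraction swaps the
reverse-side primer with another library of the same marker and round.
Everything is deterministic given (config, seed); the pipeline splits
one top-level seed per stage.

The error model is deliberately i.i.d. — no homopolymer-conditioned
errors, no quality-score realism (constant placeholder qualities), no
signal-level artefacts, and chimeras are tag swaps rather than
mid-insert joins. Passing tests therefore demonstrate the correctness
of the decision rules and accounting under calibrated noise, not
performance on real flow-cell data, where error clustering would shift
the unassigned fraction (though not the zero-cross-assignment margin,
which is set by the tag distance floor).

## Problem sizes and verification

The test suite and `scripts/acceptance.py` run the pipeline at sizes
chosen to make the checked properties statistically decisive on one
CPU: 20-library pools of 1000 error-free and 5000 noisy reads for
demultiplexing accuracy and conservation; 1000 random hit sets against
a 40-taxon reference tree for LCA-oracle agreement; and 3 samples ×
2000 error-free reads for community recovery, where the multinomial
sampling error of the Shannon index (≈ (k−1)/2n bias, small variance)
sits well inside the 0.05 acceptance band. Oracles are implemented
independently of the code paths they check: plain-Python
Smith–Waterman for the aligner, Wagner–Fischer for tag distances,
all-pairs common prefixes for the LCA, and double-loop sums for
Bray–Curtis.

## Known limitations

- Concatemers (> 2 primer occurrences) are classified by the two
  terminal end-zone hits only.
- Sequencing-adapter trimming is out of scope; reads are assumed
  primer-terminal, and the 12-base anchoring would reject reads with
  long untrimmed adapters.
- The absolute 100-bit floor presumes blastn-scale bitscores; hit
  tables from aligners with other scoring scales need a rescaled floor.
- Reference databases are synthetic stand-ins; no public 16S/ITS
  database is bundled or downloaded.
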