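# Methods

## Scope and data model

mirpipe implements the computational arc of a homology-based plant miRNA
study: raw reads → clean unique tags → known-miRNA families → novel
hairpin candidates → predicted targets → validation primers. The central
container is the *tag* — a unique RNA sequence with its redundant read
count — and every expression figure downstream is a sum of tag counts.
Internally all sequences are RNA (T→U on input); files are written in the
DNA alphabet where a sequencer or primer vendor would expect it.

## Read cleaning

Reads failing a mean-Phred ≥ 20 gate are "low quality" and excluded from
the 100 % baseline. The five contaminant categories are mutually
exclusive and checked in fixed precedence (3′-adapter-null, insert-null,
5′-adapter contaminant, shorter-than-18 nt, poly-A); the first matching
rule wins, which makes the category counts partition the high-quality
total by construction — an invariant asserted in the tests. Adapter
detection is a seed search (8 nt, ≤ 1 substitution, leftmost hit wins);
the poly-A rule fires at A-fraction ≥ 0.9 of the insert, tolerant of one
or two sequencing errors in an A-tail. Inserts longer than 30 nt are
excluded but reported outside the five categories, which have no such
row. An empty 3′-adapter string switches the stage into pre-trimmed mode
(the read *is* the insert), which makes cleaning idempotent on its own
output. Percentages are reported against the high-quality count, two
decimals, half-up.

## Known-miRNA assignment

The aligner is a global (end-to-end) dynamic programme with unit costs
for substitutions and gaps, terminal gaps included; "up to three
mismatches or free gaps" is read as one combined edit budget of 3, the
interpretation consistent with published per-hit statistics that cap
gaps at 3 (truly free gaps would not). Optimal alignments are selected
lexicographically by (cost, −matches, gaps), so ties resolve toward more
matches, then fewer gaps, deterministically. Each tag takes its best
database hit (minimum cost; ties to the entry with larger exact-match
usage, then the lexicographically smaller name). Families are keyed by
the miR-number token of the best hit's name; a small alias map
(miR157→miR156, miR165→miR166) reproduces the convention of databases
that annotate those numerals as one family. Family expression sums the
counts of every tag that aligns within the same budget to the family
representative (the highest-count member), each tag contributing to at
most one family. Conservation is a threshold on a species × family
presence table: ≥ 9 species (configurable) → conserved; non-conserved
families split into "defined" (numeral present in the table) and
"undefined".

## RNA folding

The fold search space is restricted to single-stem, multibranch-free
nested structures: one ladder of pairs with bulges and internal loops
around a terminal hairpin loop of ≥ 3 nt. Every accepted precursor is a
single hairpin, so nothing is lost, and the restriction keeps the DP
small enough to verify exhaustively: the test suite enumerates *all*
single-stem structures of short sequences and checks the DP optimum
energy exactly, under both the thermodynamic and the unit model.

The energy model is a compact nearest-neighbour table shipped as TSV
resources: stacking energies for adjacent pairs over {AU, UA, CG, GC,
GU, UG}, symmetric under strand reversal and all negative; hairpin,
bulge and internal-loop penalties tabulated to size 6–8 and extrapolated
logarithmically (1.08·ln(n/base) kcal/mol). Interior loops are capped at
30 nt total — the standard cap in secondary-structure prediction — and
an optional flat per-pair bonus supports the unit test model (−1 per
pair, zero elsewhere), under which the DP's pair count equals a
Nussinov-style maximum-pairing recursion restricted to the same
single-stem space. The DP kernel is JIT-compiled with numba; ties break
toward fewer pairs, then the first optimal transition in a fixed scan
order, so folding is deterministic. Typical synthetic precursors of
80–350 nt land in the −20 to −110 kcal/mol range reported for plant
pre-miRNAs; no claim is made of numerically reproducing any external
folder's values, which depend on unpublished internals.

Duplex (miRNA/target) energies reuse the stacking table over an
ungapped, antiparallel, full-length pairing, plus a +0.5 kcal/mol
penalty per interior mismatch; the perfect complement is provably the
minimum over equal-length sites, so the energy ratio used by the target
rules is well defined and equals 100 % exactly for perfect sites.

The stated precursor scale (78–349 nt) is documented, not enforced: the
folder accepts any sequence length, since the oracle tests and the
worked examples exercise it far below precursor scale.

## Novel miRNA discovery

Unassigned tags are exact-mapped to both genome strands; tags hitting
more than 20 loci are treated as repeat-derived and skipped. Around each
locus two windows are excised (tag near the 5′ end with a 250-nt distal
flank, and the mirror; both clipped at contig ends) so a mature on
either hairpin arm is covered — window geometry is pipeline plumbing,
chosen to span the 78–349 nt precursor range. Each window containing
the tag exactly once is folded and scored against all five criteria,
with *every* failure recorded: (ii) the mature must not straddle the
terminal loop (the arm call); (iii) the star span is derived
structurally from the mature's pairing partners offset for 2-nt 3′
overhangs on both strands and must fit inside the window without
overlapping the mature; (iv) the mature itself must hold ≥ 16 pairs and
no unpaired run > 4 nt may touch mature or star (the star's own 2-nt
terminal overhang is exempt); (v) MFE ≤ −20 kcal/mol, boundary
inclusive. min_pairs = 16 and max_bulge = 4 quantify "no large internal
loops or bulges" and are config keys. One candidate is kept per genomic
region: a perfect-stem hairpin matches its own mature on the star arm
of the opposite strand, and terminal isomiR variants re-map inside the
same precursor, so overlapping loci (within one flank length) collapse
onto the call from the highest-count tag. Accepted candidates are named
`col-miRN<k>-<arm>` in order of decreasing count. Expression sums tags
whose middle region (beyond 3 nt from each end) matches the mature
exactly, anchored by that middle core, with total flank differences
within 3 nt per end — terminal variants count, internal edits never do.

## Target prediction

Duplexes are ungapped: the rules are positional and reported site spans
always equal miRNA length, matching how such tables print coordinates.
Positions are 1-based from the miRNA 5′ end. The literal statements of
rule iii (no mismatches in 2–12) and rule v (≤ 2.5 mismatches in 1–12)
conflict — read literally, rule v could never bind. The shipped
resolution: rule iii forbids *full* mismatches in 2–12 while G:U
wobbles are tolerated there under rule v's 2.5 cap; a
`strict_five_prime` mode applies the literal reading. Rule iv (10–11)
is intolerant of G:U by default, since wobble tolerance there is
unstated and the cleavage site deserves the conservative reading. Rule
ii counts contiguous *full* mismatches only. Overlapping passing
windows of one miRNA on one transcript collapse to the best (lowest
score, then lowest energy, then leftmost). The cleavage position
between miRNA positions 10–11 is emitted as metadata only.

## Primer design

The stem-loop RT primer is a constant 44-nt scaffold (the widely used
universal backbone; configurable) plus the DNA reverse complement of the
mature's last 6 nt — 50 nt total. The forward primer is the DNA form of
the first 15 nt behind a 5′ extension; the extension is deterministic
alternating G/C (a seeded-random mode exists) grown until the
nearest-neighbour Tm reaches 60 °C, for reproducibility where a
"random GC-rich" tail is the bench convention. Tm uses the SantaLucia
unified parameters (via Biopython) at 250 nM primer with PCR-buffer
salt expressed as a monovalent equivalent, Na_eq = 50 + 120·√3 ≈ 258 mM
(50 mM monovalent + 3 mM Mg²⁺), with the 0.368·(N−1)·ln[Na_eq] entropy
correction; an independent hand recomputation from the same published
constants is the test oracle. The expected amplicon is
extension + miRNA + backbone; 19–24 nt matures with ordinary
composition land inside the 60–70 bp assay window, and extreme AT-only
matures (which need long extensions) trigger a warning with the
computed size rather than an error. The universal reverse primer is a
configurable 5′ sub-span of the backbone (default its first 16 nt);
its exact span does not change the amplicon length, which is set by the
construct's ends.

## Synthetic data

The generator plants everything the pipeline is supposed to find.
Tag lengths follow a 13-point law over 18–30 nt with the mode at 21 nt
(42.19 %), then 24 nt (22.95 %) and 20 nt (14.25 %), 92.69 % of mass in
20–24 nt — the shape reported for real plant libraries. Counts are
discretised log-normal (μ = 3, σ = 1.5 on the log scale) to mimic the
observed 1-to-millions dynamic range, allocated multinomially over
matures at the configured depth (50,000 by default), each mature
guaranteed at least one read. Contaminants are drawn binomially at
fractions matching a ~98.9 %-clean library. Conforming hairpins are
perfect stems (pad + mature + extension against the full reverse
complement around a 10–20 nt loop), which forces all five criteria by
construction; spoilers violate a designated criterion (mature across
the loop, a 6-nt bulge opposite the mature, or a sparse weak stem) and
are labelled with the intended violation — the fold may reject them on
a different criterion first, so tests assert rejection, not the failing
label. The background genome is AU-rich (0.32/0.18/0.18/0.32) to keep
spurious stems rare; chance hairpins still occur at a low rate, bounded
in tests at ≤ 1 accepted per 100 kb. Planted inserts are rejection-
sampled away from fuzzy adapter-seed matches and poly-A runs so the
cleaning truth is exact. Target sites are perfect complements
(compliant) or single-rule violators built by forcing pair states at
chosen positions; violations of rules iv and v are realised as G:U
wobbles and are skipped for miRNAs whose composition cannot produce
them.

What the generator does not emulate: sequencing errors beyond terminal
isomiR trims, quality-score variation (constant Q40), multi-chromosome
genomes, genuine ncRNA-derived reads, imperfect (bulged) real
precursor stems, and UTR/CDS structure in transcripts. Passing the
planted-truth suite therefore demonstrates the pipeline's logic, not
its robustness to noisy real libraries.

## Problem sizes and numerics

Default test-scale conditions: 50,000 reads, a 100-kb genome with 10
hairpins, 20 database matures, 10 transcripts of 800 nt with 10
compliant sites — the full pipeline runs in seconds, and the oracle
suites (exhaustive folding ≤ 18 nt, 1,000 alignment pairs, 10,000
duplex configurations) complete within the ordinary pytest run. Energy
comparisons use a 1e-9 tie epsilon inside the DP and 1e-6 in oracle
assertions; report percentages round half-up to two decimals; all
generator randomness flows from a single integer seed through
numpy's Generator, so every artefact is byte-reproducible.

## Known limitations

Exclusion-set filtering is exact substring/equality matching, not
BLAST-style local alignment. The known-assignment stage is
quadratic in (tags × database) and meant for collapsed tag sets, not
raw reads. The folding model's absolute energies are a compact
approximation — adequate for thresholding and ordering hairpins, not
for quantitative thermodynamics. Multi-locus matures are capped rather
than fractionally assigned. GO/KEGG analysis is out of scope; only a
generic annotation join summary is provided.
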