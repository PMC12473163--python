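# Methods

This note documents the statistical definitions, models and design
choices behind `markerscreen`, in the spirit of a package vignette: what
is computed, under which conventions, and what the tests do and do not
establish.

## Conventions

All intervals are 0-based and half-open internally; conversion to the
1-based inclusive conventions of GenBank feature tables, NEXUS charsets
and RAxML partition files happens only at the format boundary. The gap
character `-`, the supermatrix pad `?`, and every IUPAC ambiguity code
(including `N`) are missing data in every statistic. Treating ambiguity
codes like gaps extends the usual gaps-as-missing rule to ambiguous
Sanger base calls, which is where these data typically come from. Taxon
ids match exactly after whitespace normalisation; there is no fuzzy
matching.

## Informativeness statistics

Published marker-screening tables rarely state how their counts were
tallied, so the definitions here are chosen to be reproducible and close
to how a human scores an alignment by eye; absolute agreement with any
particular published table is not expected, but the definitions are
stated precisely so discrepancies are interpretable.

**Indel events.** A candidate event is a maximal run of `-` in one row.
Runs with identical (start, end) in several rows are pooled into a single
event carried by all of them — simple indel coding in the
Simmons–Ochoterena sense; overlapping but unequal runs remain separate
events. Leading and trailing runs are excluded by default
(`include_terminal=False`) because ragged Sanger read ends are missing
sequence, not indels. `indel_bp` sums the lengths of distinct events, not
per-row gap characters.

**Substitutions.** Per column, the consensus is the most frequent
unambiguous base, ties broken alphabetically. Every distinct
non-consensus base present contributes exactly one substitution,
classified as a transition if the pair is {A,G} or {C,T}, otherwise a
transversion. This counts derived states, not pairwise differences, so a
column with three states contributes two substitutions. Under low
divergence each true mutation event produces one counted substitution;
under saturation the count is a lower bound on events (overprinting), a
bias the simulator tests assert directionally.

**Microsatellites.** A locus is a maximal perfect tandem array of a
primitive motif (1–6 bp, not itself a power of a shorter motif) whose
repeat count meets a per-motif-length threshold. Defaults are 10 (mono),
6 (di), 4 (tri) and 3 (tetra–hexa) repeats — ordinary screening-tool
territory, exposed in configuration and not a claim about any specific
web tool. Motifs are reported in canonical (lexicographically smallest)
rotation; overlapping arrays resolve in favour of the longer one.
Per-row arrays are mapped through gaps into alignment coordinates, and
arrays from different rows merge into one counted locus when their
intervals overlap and their canonical motifs agree — a union count per
alignment, which is one of the two plausible readings of published
"microsatellite loci" columns (the other being per-sequence sums).

**PIS and clade diagnostics.** A parsimony-informative site has ≥ 2
distinct unambiguous states each in ≥ 2 rows. A clade-diagnostic site
(mode `fixed_difference`) is a PIS where every scored ingroup row shares
one state that is absent from every scored row outside the clade; mode
`strict` additionally requires the complement monomorphic. Both modes
are always computed, because "sites common to all taxa in a clade" does
not by itself pin down the complement's condition; columns where either
side has fewer than two scored rows are skipped.

## Region harvesting

The built-in catalogue lists the 43 chloroplast intergenic spacers and 6
introns classically screened in Lamiaceae plastomes. Spacer extraction
takes the sequence strictly between the two nearest annotated copies of
the flank genes, reverse-complementing when needed so the first-named
gene is upstream; the pair of copies minimising spacer length is used
(plastome inverted repeats duplicate tRNAs), and exact ties demand
explicit disambiguation rather than guessing. One catalogue entry
(`trnK-matK-trnK`) names the same flank gene twice and is handled as the
region between the two nearest copies/exon parts of that gene. Gene-name
matching strips tRNA anticodon decorations (`trnK-UUU` → `trnK`) because
annotation dialects vary between records. Overlapping or adjacent flanks
yield a flagged zero-length result, not an error. Intron extraction
returns the sequence between consecutive exon parts of a same-strand
joined gene annotation; trans-spliced (mixed-strand) locations are
rejected as out of scope.

Homologous copies are aligned with a deterministic center-star scheme:
each sequence is globally aligned (affine gaps; defaults +1 match, −1
mismatch, −4 open, −1 extend via Biopython's `PairwiseAligner`) to the
longest input, and the pairwise alignments are merged by gap-column
insertion. For screen-scale loci (< ~5 kb, few sequences, easily
alignable regions) this is adequate and self-contained; pre-aligned
FASTA can be supplied instead wherever an alignment is accepted. No
claim is made that the defaults reproduce any GUI aligner.

Because the screening literature does not fix how "highest variability"
is quantified, the screen reports both raw counts and per-kb rates; the
ranking score is `w_subs × substitutions/kb + w_ssr × SSR count`
(defaults 1, 1), descending, ties broken by locus name so the order is
total and stable.

## Supermatrix

Concatenation takes the union taxon set in first-appearance order;
taxon × locus blocks absent from the input are filled with `?` rather
than `-`, distinguishing absent data from inferred gaps while both map
to missing in statistics. Offsets are recorded per locus and exported as
NEXUS charsets and RAxML-style `DNA, locus = start-end` lines.
Total length is the sum of block lengths, invariant under block
permutation, and per-block statistics are unchanged by padding — both
asserted as tests.

## Distance trees

The K2P distance uses pairwise deletion (only columns where both rows
carry unambiguous bases), matching the `?`-padded supermatrix. Saturated
pairs where a log argument leaves (0, 1] are flagged infinite rather
than silently clamped, and NJ refuses matrices containing them, naming
the offending pairs. NJ is the canonical Q-criterion agglomeration with
two numerical policies: ties on Q break by the lexicographically
smallest leaf labels under the candidate pair (full determinism), and
negative branch lengths are clamped to zero with the deficit moved to
the sister branch (preserving path lengths). Bootstrap resamples columns
with replacement from one seeded generator; support is the percentage of
replicates whose NJ tree contains each original split. NJ rather than
ML/Bayesian inference is deliberate: the tree stage exists to verify
two-lineage structure on synthetic data at desk scale, and the package
emits ready-to-run inputs for external ML/BI tools rather than wrapping
them. Robinson–Foulds distance is computed from normalised split sets
and cross-checked against dendropy in the test suite.

## Simulator

Sequences evolve along a user-supplied rooted tree. Substitutions are
Poisson per branch with rate `sub_rate × length × branch length`; each
event picks a uniform site and is a transition with probability
κ/(κ+2) — the K2P allocation under equal base frequencies (κ = 2 r
reproduces a target transition:transversion count ratio r). Indels are
Poisson with geometric lengths; insertions register new columns in a
global column order, so the emitted alignment is exact by construction
and no realigner is involved — separating alignment error from counting
error in every recovery test. Deleted root columns remain alignment
columns; columns inserted and later lost everywhere are dropped. SSR
arrays are planted in the root at evenly spaced positions with breaker
bases enforcing maximality, and mutate by symmetric single-motif-unit
steps per branch with a configured probability. `forced_branch_subs`
pins an exact number of substitutions at distinct sites onto named
branches — the mechanism for planting clade-diagnostic fixed
differences, exact when background rates are zero.

Every event is logged per branch; `replay_locus` re-derives all leaves
from the root plus the log alone, and the suite asserts byte-for-byte
identity.

**Study-scale regime.** `make_screening_fixture` generates nine loci (seven
plastid spacers, ITS, ETS) on a 16-taxon two-clade tree (7 + 8 taxa plus
one distant outgroup), with lengths 703/903/1002/710/611/424/1057/702/408
bp and per-locus event-count targets in the tens of substitutions, 10–22
indels and 8–41 SSR arrays — the regime of a real screening table.
Targets convert to rates by dividing by total tree length × locus
length. This regime is deletion-only (`insertion_prob = 0`) and SSR
steps are off by default so every fixture locus's true alignment length
equals its configured length exactly, which is what makes the
5410/1110/6520-nt concatenation identities testable; both switches are
available for configs that want growing alignments.

**What the simulator does not emulate:** alignment uncertainty (the true
alignment is given), rate heterogeneity among sites, GTR-class
asymmetries, coalescent processes or introgression. Passing recovery
tests therefore demonstrates that the statistics are computed correctly
and calibrated against a known generating process — not that any real
data set will be free of alignment or model error.

## Problem sizes and numerics

The shipped suites use alignments up to 20 × 200 for oracle equivalence
(500 instances), 200 additive matrices of ≤ 8 taxa for NJ exactness,
50 seeded two-clade runs × 100 bootstrap replicates for split recovery,
and 100 nine-locus replicates for the ±50% calibration band — sizes
chosen so the whole suite runs in about a minute on one core while
keeping binomial noise well inside the asserted tolerances. K2P is
evaluated to 1e−9 against the closed form on a (P, Q) grid. All
stochastic tests fix seeds; hypothesis properties run derandomised.

## Known limitations

* Center-star alignment is not optimal multiple alignment; for
  divergent or heavily gapped loci, supply an external alignment.
* The substitution tally is consensus-based, not model-based; it
  undercounts at saturation and does not reconstruct ancestral states.
* SSR detection covers perfect repeats only; compound and interrupted
  microsatellites are out of scope.
* Bootstrap support uses the NJ engine throughout; it is a recovery
  check, not a substitute for ML/Bayesian support values.
* GenBank parsing captures gene/tRNA/rRNA/CDS/exon/intron features only
  and rejects trans-spliced locations (relevant to *rps12*).
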