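import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markerscreen.informativeness import (
    DEFAULT_SSR_THRESHOLDS,
    canonical_rotation,
    count_pis,
    count_ssr_loci,
    count_substitutions,
    find_indels,
    find_ssr,
    is_primitive,
    report,
)
from markerscreen.seq_core import LocusAlignment, Sequence

from conftest import make_alignment, random_alignment
from _oracles import brute_indels, brute_pis, brute_ssr, brute_substitutions


class TestIndels:
    def test_shared_identical_run_is_one_event(self, toy_alignment):
        events = find_indels(toy_alignment)
        assert len(events) == 1
        (e,) = events
        assert (e.start, e.end, e.length) == (2, 4, 2)
        assert e.carriers == frozenset({"r1", "r3"})

    def test_different_columns_are_separate_events(self):
        aln = make_alignment({"a": "A-CGT", "b": "AC-GT"})
        events = find_indels(aln)
        assert [(e.start, e.end) for e in events] == [(1, 2), (2, 3)]

    def test_gap_free_alignment(self):
        assert find_indels(make_alignment({"a": "ACGT", "b": "ACGT"})) == []

    def test_terminal_runs_excluded_by_default(self):
        aln = make_alignment({"a": "--CGT", "b": "ACG--", "c": "ACGTT"})
        assert find_indels(aln) == []
        assert len(find_indels(aln, include_terminal=True)) == 2


class TestSubstitutions:
    @pytest.mark.parametrize(
        "rows,expected",
        [
            ({"a": "A", "b": "A", "c": "G", "d": "G"}, (1, 0)),  # tie -> A, 1 ti
            ({"a": "A", "b": "C", "c": "G"}, (1, 1)),  # A cons; C tv, G ti
            ({"a": "T", "b": "T", "c": "T"}, (0, 0)),  # invariant
            ({"a": "A-", "b": "AN", "c": "A?"}, (0, 0)),  # missing only
        ],
    )
    def test_consensus_tally(self, rows, expected):
        assert count_substitutions(make_alignment(rows)) == expected


class TestSsr:
    def test_dinucleotide_array(self):
        loci = find_ssr("ATATATATATATAT")
        assert [(l.motif, l.repeats, l.start, l.end) for l in loci] == [
            ("AT", 7, 0, 14)
        ]

    def test_below_threshold(self):
        assert find_ssr("ATATAT") == []

    def test_mononucleotide_threshold_boundary(self):
        assert [(l.motif, l.repeats) for l in find_ssr("A" * 10)] == [("A", 10)]
        assert find_ssr("A" * 9) == []

    def test_canonical_rotation_reported(self):
        loci = find_ssr("C" + "TA" * 7 + "C")
        assert [l.motif for l in loci] == ["AT"]

    def test_non_primitive_motif_reported_once_under_shortest(self):
        loci = find_ssr("G" + "AT" * 8 + "G")
        assert len(loci) == 1 and loci[0].motif == "AT"

    def test_unknown_characters_break_arrays(self):
        assert find_ssr("AAAAA" + "N" + "AAAAA") == []

    def test_helpers(self):
        assert canonical_rotation("TA") == "AT"
        assert is_primitive("AT") and not is_primitive("ATAT")


class TestSsrMerge:
    def test_same_array_homologous_positions_merges(self):
        row = "G" + "AT" * 7 + "G"
        aln = make_alignment({"a": row, "b": row})
        count, loci = count_ssr_loci(aln)
        assert count == 1 and len(loci) == 2

    def test_different_motifs_or_positions_stay_separate(self):
        a = "AT" * 7 + "G" * 3 + "AG" * 6 + "C" * 3
        b = "AT" * 7 + "G" * 3 + "C" * 15
        aln = make_alignment({"a": a, "b": b})
        count, _ = count_ssr_loci(aln)
        # shared (AT)7 merges; (AG)6 in a and C15 in b are separate
        assert count == 3

    def test_gap_mapping_keeps_homology(self):
        # same array, one row interrupted by an upstream gap
        a = "--" + "AT" * 7 + "GG"
        b = "CC" + "AT" * 7 + "GG"
        count, loci = count_ssr_loci(make_alignment({"a": a, "b": b}))
        assert count == 1
        assert {(l.start, l.end) for l in loci} == {(2, 16)}

    def test_ssr_free_alignment(self):
        assert count_ssr_loci(make_alignment({"a": "ACGT", "b": "ACGT"}))[0] == 0


class TestPis:
    def test_example_alignment(self):
        aln = make_alignment(
            {"a": "ACGT", "b": "ACGT", "c": "GCGT", "d": "GCGA"}
        )
        count, sites = count_pis(aln)
        assert (count, sites) == (1, [0])

    def test_identical_rows(self):
        assert count_pis(make_alignment({"a": "ACGT", "b": "ACGT"}))[0] == 0

    def test_singleton_with_gap_not_informative(self):
        aln = make_alignment({"a": "A", "b": "A", "c": "G", "d": "-"})
        assert count_pis(aln)[0] == 0


class TestReport:
    def test_constructed_fixture(self):
        ssr = "AT" * 7
        rows = {
            "a": "CCGG" + ssr + "TTAAC",
            "b": "CC--" + ssr + "TTAAC",
            "c": "CC--" + ssr + "TTAGC",
        }
        rep = report(make_alignment(rows))
        assert rep.n_indels == 1 and rep.indel_bp == 2
        assert (rep.transitions, rep.transversions) == (1, 0)
        assert rep.n_ssr == 1
        assert rep.length == len(rows["a"])

    def test_invariant_alignment_all_zero(self):
        row = "ACGGTCATTCGAGCTAACGG"  # no tandem structure
        rep = report(make_alignment({"a": row, "b": row}))
        assert (rep.n_indels, rep.substitutions, rep.n_ssr, rep.n_pis) == (0, 0, 0, 0)

    def test_length_passthrough(self):
        aln = make_alignment({"a": "A" * 703, "b": "A" * 703})
        assert report(aln).length == 703


class TestOracleEquivalence:
    """Production implementations vs naive definition-scans."""

    def test_random_alignments_match_oracles(self, rng):
        for _ in range(60):
            n_taxa = int(rng.integers(2, 12))
            n_cols = int(rng.integers(10, 120))
            aln = random_alignment(rng, n_taxa, n_cols, gap_frac=0.15)
            assert count_pis(aln)[1] == brute_pis(aln)
            assert count_substitutions(aln) == brute_substitutions(aln)
            got = [
                (e.start, e.end, e.carriers) for e in find_indels(aln)
            ]
            assert got == brute_indels(aln)

    def test_ssr_matches_bruteforce_on_repeat_rich_strings(self, rng):
        motifs = ["A", "AT", "AG", "AAT", "ACGT", "C"]
        for _ in range(150):
            parts = []
            for _ in range(int(rng.integers(1, 6))):
                m = motifs[int(rng.integers(0, len(motifs)))]
                reps = int(rng.integers(1, 14))
                parts.append(m * reps)
                parts.append(
                    "".join("ACGT"[i] for i in rng.integers(0, 4, size=int(rng.integers(0, 4))))
                )
            s = "".join(parts)
            if not s:
                continue
            got = [(l.start, l.end, l.motif, l.repeats) for l in find_ssr(s)]
            assert got == brute_ssr(s, DEFAULT_SSR_THRESHOLDS), s


@st.composite
def alignments(draw):
    n_taxa = draw(st.integers(2, 8))
    n_cols = draw(st.integers(1, 40))
    rows = [
        draw(
            st.text(alphabet="ACGT-N", min_size=n_cols, max_size=n_cols).filter(
                lambda s: set(s) - set("-N")
            )
        )
        for _ in range(n_taxa)
    ]
    return make_alignment({f"t{i}": r for i, r in enumerate(rows)})


class TestProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(alignments(), st.randoms(use_true_random=False))
    def test_counts_invariant_under_row_permutation(self, aln, rnd):
        rows = list(aln.rows)
        rnd.shuffle(rows)
        shuffled = LocusAlignment(aln.locus_name, tuple(rows))
        assert count_substitutions(shuffled) == count_substitutions(aln)
        assert count_pis(shuffled)[0] == count_pis(aln)[0]
        assert len(find_indels(shuffled)) == len(find_indels(aln))
        assert count_ssr_loci(shuffled)[0] == count_ssr_loci(aln)[0]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(alignments())
    def test_adding_consensus_row_monotone(self, aln):
        """A gap-free consensus row changes no event counts; PIS never drops."""
        consensus = []
        for col in range(aln.length):
            column = [r.residues[col] for r in aln.rows if r.residues[col] in "ACGT"]
            if column:
                best = sorted(set(column), key=lambda b: (-column.count(b), b))[0]
            else:
                best = "A"
            consensus.append(best)
        extra = Sequence("consensus_row", "".join(consensus))
        grown = LocusAlignment(aln.locus_name, aln.rows + (extra,))
        assert len(find_indels(grown)) == len(find_indels(aln))
        assert count_substitutions(grown) == count_substitutions(aln)
        assert count_pis(grown)[0] >= count_pis(aln)[0]
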