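"""Per-locus marker-informativeness statistics.

For one aligned locus this module computes the screening statistics used to
rank candidate phylogenetic markers: aligned length, indel events and total
indel bp, substitutions split into transitions and transversions,
microsatellite (SSR) loci, and parsimony-informative sites (PIS).

Definitions (documented because published marker tables rarely state them):

* An **indel event** is a maximal run of ``-`` in one row; runs with
  identical column coordinates in several rows are one event carried by all
  of them (simple indel coding).  Leading/trailing runs are excluded by
  default — ragged Sanger read ends are missing sequence, not indels.
* **Substitutions** are counted per column against the column consensus
  (most frequent unambiguous base, ties broken alphabetically); every
  distinct non-consensus base present contributes one substitution,
  classified as a transition for A<->G / C<->T and a transversion otherwise.
* An **SSR locus** is a maximal perfect tandem array of a primitive 1-6 bp
  motif meeting a per-motif-length repeat threshold; arrays at homologous
  positions with the same canonical motif are merged across rows.
* A **PIS** is a column with >= 2 distinct unambiguous bases each present in
  >= 2 rows; gaps and ambiguity codes are missing data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .seq_core import DNA_BASES, GAP_CHAR, LocusAlignment, PAD_CHAR, Sequence

#: Default minimum repeat counts per motif length 1..6.
DEFAULT_SSR_THRESHOLDS: dict[int, int] = {1: 10, 2: 6, 3: 4, 4: 3, 5: 3, 6: 3}

_GAP_RUN = re.compile(r"-+")

# Base encoding for vectorised column statistics: A,C,G,T -> 0..3, missing -> 4.
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(DNA_BASES):
    _CODE[ord(_b)] = _i
MISSING_CODE = 4


def encode_alignment(aln: LocusAlignment) -> np.ndarray:
    """Encode rows x columns as uint8 (A,C,G,T -> 0..3; anything else 4)."""
    flat = np.frombuffer(
        "".join(row.residues for row in aln.rows).encode("ascii"), dtype=np.uint8
    )
    return _CODE[flat].reshape(len(aln.rows), aln.length)


@dataclass(frozen=True)
class IndelEvent:
    """One gap event in alignment coordinates (0-based, half-open)."""

    start: int
    end: int
    carriers: frozenset[str]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("indel event must have width >= 1")
        if not self.carriers:
            raise ValueError("indel event must have carriers")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SsrLocus:
    """A perfect tandem repeat array in one row, in alignment coordinates."""

    motif: str
    repeats: int
    start: int
    end: int
    carrier: str

    @property
    def array_length(self) -> int:
        return self.repeats * len(self.motif)


@dataclass(frozen=True)
class InformativenessReport:
    """Screening statistics for one locus (one table row per locus)."""

    locus_name: str
    length: int
    n_indels: int
    indel_bp: int
    transitions: int
    transversions: int
    n_ssr: int
    n_pis: int

    @property
    def substitutions(self) -> int:
        return self.transitions + self.transversions

    def per_kb(self, count: int) -> float:
        return 1000.0 * count / self.length

    def as_dict(self) -> dict:
        return {
            "locus": self.locus_name,
            "length": self.length,
            "n_indels": self.n_indels,
            "indel_bp": self.indel_bp,
            "transitions": self.transitions,
            "transversions": self.transversions,
            "substitutions": self.substitutions,
            "n_ssr": self.n_ssr,
            "n_pis": self.n_pis,
            "subs_per_kb": self.per_kb(self.substitutions),
            "indels_per_kb": self.per_kb(self.n_indels),
            "pis_per_kb": self.per_kb(self.n_pis),
        }


# ---------------------------------------------------------------------------
# Indels


def find_indels(
    aln: LocusAlignment, include_terminal: bool = False
) -> list[IndelEvent]:
    """Locate gap events; identical-coordinate runs collapse to one event."""
    by_span: dict[tuple[int, int], set[str]] = {}
    for row in aln.rows:
        for m in _GAP_RUN.finditer(row.residues):
            span = m.span()
            if not include_terminal and (span[0] == 0 or span[1] == aln.length):
                continue
            by_span.setdefault(span, set()).add(row.id)
    return [
        IndelEvent(start, end, frozenset(carriers))
        for (start, end), carriers in sorted(by_span.items())
    ]


def indel_bp(events: list[IndelEvent]) -> int:
    return sum(e.length for e in events)


# ---------------------------------------------------------------------------
# Substitutions


def count_substitutions(aln: LocusAlignment) -> tuple[int, int]:
    """Count (transitions, transversions) with consensus-based tallying.

    A <-> G and C <-> T are transitions; base codes 0..3 map A,C,G,T so two
    distinct bases are a transition exactly when their codes share parity.
    """
    arr = encode_alignment(aln)
    counts = np.stack([(arr == s).sum(axis=0) for s in range(4)])  # 4 x L
    present = counts > 0
    variable = present.sum(axis=0) >= 2
    if not variable.any():
        return 0, 0
    consensus = counts.argmax(axis=0)  # ties -> lowest code = alphabetical
    ti = tv = 0
    for s in range(4):
        hit = variable & present[s] & (consensus != s)
        same_parity = (consensus % 2) == (s % 2)
        ti += int((hit & same_parity).sum())
        tv += int((hit & ~same_parity).sum())
    return ti, tv


# ---------------------------------------------------------------------------
# Microsatellites


def canonical_rotation(motif: str) -> str:
    """Lexicographically smallest rotation of *motif*."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def is_primitive(motif: str) -> bool:
    """True when *motif* is not a tandem power of a shorter motif."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def _raw_tandem_arrays(
    seq: str, thresholds: dict[int, int]
) -> list[tuple[int, int, str, int]]:
    """All maximal perfect tandem arrays meeting thresholds.

    Returns (start, end, motif, repeats) tuples on the ungapped sequence.
    Unknown characters (anything outside ACGT) break arrays.
    """
    n = len(seq)
    valid = [c in DNA_BASES for c in seq]
    out = []
    for mlen, min_rep in sorted(thresholds.items()):
        i = 0
        while i + mlen <= n:
            motif = seq[i : i + mlen]
            if not all(valid[i : i + mlen]) or not is_primitive(motif):
                i += 1
                continue
            j = i + mlen
            while j < n and valid[j] and seq[j] == seq[j - mlen]:
                j += 1
            repeats = (j - i) // mlen
            if repeats >= min_rep:
                out.append((i, i + repeats * mlen, motif, repeats))
                i = j - mlen + 1  # skip shifted copies of the same run
            else:
                i += 1
    return out


def find_ssr(
    seq: Sequence | str, thresholds: dict[int, int] | None = None
) -> list[SsrLocus]:
    """Find perfect SSR arrays in one (degapped) sequence.

    Overlapping arrays are resolved in favour of the longer one; motifs are
    reported in canonical rotation.  Coordinates are on the degapped
    sequence; :func:`count_ssr_loci` maps them through gaps.
    """
    thresholds = thresholds or DEFAULT_SSR_THRESHOLDS
    if isinstance(seq, Sequence):
        carrier, residues = seq.id, seq.degapped()
    else:
        carrier, residues = "", seq.upper().replace(GAP_CHAR, "").replace(PAD_CHAR, "")
    raw = _raw_tandem_arrays(residues, thresholds)
    # longer array wins on overlap; deterministic tie-break
    raw.sort(key=lambda a: (-(a[1] - a[0]), a[0], len(a[2])))
    chosen: list[tuple[int, int, str, int]] = []
    for cand in raw:
        if all(cand[1] <= c[0] or cand[0] >= c[1] for c in chosen):
            chosen.append(cand)
    chosen.sort()
    return [
        SsrLocus(canonical_rotation(motif), reps, start, end, carrier)
        for start, end, motif, reps in chosen
    ]


def count_ssr_loci(
    aln: LocusAlignment, thresholds: dict[int, int] | None = None
) -> tuple[int, list[SsrLocus]]:
    """Count merged SSR loci across an alignment.

    Per-row arrays are mapped to alignment coordinates; arrays from
    different rows merge into one locus when their alignment intervals
    overlap and their canonical motifs are identical.
    """
    per_row: list[SsrLocus] = []
    for row in aln.rows:
        degap_to_col = [
            i for i, c in enumerate(row.residues) if c not in (GAP_CHAR, PAD_CHAR)
        ]
        for locus in find_ssr(row, thresholds):
            per_row.append(
                SsrLocus(
                    locus.motif,
                    locus.repeats,
                    degap_to_col[locus.start],
                    degap_to_col[locus.end - 1] + 1,
                    row.id,
                )
            )
    # merge chain-overlapping same-motif loci
    per_row.sort(key=lambda s: (s.motif, s.start, s.end, s.carrier))
    n_merged = 0
    current_motif, current_end = None, -1
    for locus in per_row:
        if locus.motif != current_motif or locus.start >= current_end:
            n_merged += 1
            current_motif, current_end = locus.motif, locus.end
        else:
            current_end = max(current_end, locus.end)
    return n_merged, per_row


# ---------------------------------------------------------------------------
# Parsimony-informative sites


def count_pis(aln: LocusAlignment) -> tuple[int, list[int]]:
    """Count parsimony-informative columns and return their indices."""
    arr = encode_alignment(aln)
    counts = np.stack([(arr == s).sum(axis=0) for s in range(4)])
    informative = (counts >= 2).sum(axis=0) >= 2
    sites = np.nonzero(informative)[0].tolist()
    return len(sites), sites


# ---------------------------------------------------------------------------
# Assembly


def report(
    aln: LocusAlignment,
    ssr_thresholds: dict[int, int] | None = None,
    include_terminal_gaps: bool = False,
) -> InformativenessReport:
    """Assemble the full per-locus informativeness record."""
    events = find_indels(aln, include_terminal=include_terminal_gaps)
    ti, tv = count_substitutions(aln)
    n_ssr, _ = count_ssr_loci(aln, ssr_thresholds)
    n_pis, _ = count_pis(aln)
    return InformativenessReport(
        locus_name=aln.locus_name,
        length=aln.length,
        n_indels=len(events),
        indel_bp=indel_bp(events),
        transitions=ti,
        transversions=tv,
        n_ssr=n_ssr,
        n_pis=n_pis,
    )
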