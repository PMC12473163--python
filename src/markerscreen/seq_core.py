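"""Core domain types and file I/O for sequences, alignments, genomes and trees.

Conventions used throughout the package:

* **Coordinates** — every interval is 0-based, half-open ``[start, end)``.
  Conversion to the 1-based inclusive conventions of GenBank feature tables
  and NEXUS charsets happens only inside the readers/writers in this module.
* **Missing data** — the gap character ``-``, the supermatrix pad character
  ``?``, and all IUPAC ambiguity codes (including ``N``) are treated as
  missing in every downstream statistic.  This extends the gaps-as-missing
  convention to ambiguous Sanger base calls.
* **Taxon ids** — exact string match after whitespace normalisation
  (leading/trailing stripped, internal runs collapsed to single spaces).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Unambiguous bases; everything else in VALID_CHARS is missing data.
DNA_BASES = "ACGT"
AMBIGUITY_CODES = "RYSWKMBDHVN"
GAP_CHAR = "-"
PAD_CHAR = "?"
VALID_CHARS = frozenset(DNA_BASES + AMBIGUITY_CODES + GAP_CHAR + PAD_CHAR)
MISSING_CHARS = frozenset(AMBIGUITY_CODES + GAP_CHAR + PAD_CHAR)

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-?", "TGCAYRSWMKVHDBN-?")


class FormatError(ValueError):
    """A file did not conform to the expected format."""


def normalise_taxon_id(label: str) -> str:
    return re.sub(r"\s+", " ", label.strip())


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Sequence:
    """A named DNA sequence; residues normalised to upper case."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "id", normalise_taxon_id(self.id))
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: residues must be non-empty")
        bad = set(self.residues) - VALID_CHARS
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: invalid characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def degapped(self) -> str:
        """Residues with gap and pad characters removed."""
        return self.residues.replace(GAP_CHAR, "").replace(PAD_CHAR, "")

    def reverse_complement(self) -> "Sequence":
        return Sequence(self.id, reverse_complement(self.residues), self.description)


@dataclass(frozen=True)
class LocusAlignment:
    """An aligned set of sequences for one locus.

    All rows share the same length; alignment columns are addressed with
    0-based, half-open intervals.
    """

    locus_name: str
    rows: tuple[Sequence, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(self.rows))
        if not self.rows:
            raise ValueError(f"alignment {self.locus_name!r}: no rows")
        length = len(self.rows[0])
        for row in self.rows:
            if len(row) != length:
                raise ValueError(
                    f"alignment {self.locus_name!r}: row {row.id!r} has length "
                    f"{len(row)}, expected {length}"
                )
        ids = [row.id for row in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(
                f"alignment {self.locus_name!r}: duplicate taxon ids {dupes!r}"
            )
        if length < 1:
            raise ValueError(f"alignment {self.locus_name!r}: zero columns")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(row.id for row in self.rows)

    def row(self, taxon: str) -> Sequence:
        for r in self.rows:
            if r.id == taxon:
                return r
        raise KeyError(taxon)

    def column(self, index: int) -> str:
        return "".join(row.residues[index] for row in self.rows)


@dataclass(frozen=True)
class GenomeFeature:
    """One annotated feature; multi-exon genes carry several parts."""

    feature_type: str
    gene_name: str
    parts: tuple[tuple[int, int], ...]
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for start, end in self.parts:
            if not 0 <= start < end:
                raise ValueError(f"bad feature interval [{start}, {end})")
        if self.feature_type in ("gene", "tRNA") and not self.gene_name:
            raise ValueError(f"{self.feature_type} feature without a gene name")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.parts)

    @property
    def end(self) -> int:
        return max(e for _, e in self.parts)


@dataclass(frozen=True)
class GenomeRecord:
    """An annotated genome (e.g. a plastome) with gene-level features."""

    id: str
    residues: str
    features: tuple[GenomeFeature, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        object.__setattr__(self, "features", tuple(self.features))
        n = len(self.residues)
        for feat in self.features:
            if feat.end > n:
                raise ValueError(
                    f"feature {feat.gene_name!r} extends past sequence end "
                    f"({feat.end} > {n})"
                )

    def reverse_complement(self) -> "GenomeRecord":
        n = len(self.residues)
        feats = tuple(
            GenomeFeature(
                f.feature_type,
                f.gene_name,
                tuple(sorted((n - e, n - s) for s, e in f.parts)),
                "+" if f.strand == "-" else "-",
            )
            for f in self.features
        )
        return GenomeRecord(self.id, reverse_complement(self.residues), feats)


@dataclass(frozen=True)
class CladePartition:
    """A named bipartition of the matrix taxa; the complement is implicit."""

    name: str
    ingroup: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "ingroup", frozenset(normalise_taxon_id(t) for t in self.ingroup)
        )
        if not self.ingroup:
            raise ValueError(f"partition {self.name!r}: empty ingroup")

    def complement(self, taxa: Iterable[str]) -> frozenset[str]:
        comp = frozenset(taxa) - self.ingroup
        if not comp:
            raise ValueError(
                f"partition {self.name!r}: ingroup must be a strict subset of taxa"
            )
        return comp


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read a (possibly aligned) multi-FASTA file.

    Residues are upper-cased; gap characters are preserved.  Duplicate ids
    and malformed headers raise :class:`FormatError` naming the line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(
                    f"{path}: line {lineno}: expected FASTA header, got {line[:30]!r}"
                )
            break
        else:
            raise FormatError(f"{path}: empty FASTA file")
    seqs: list[Sequence] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        seq = Sequence(record.id, str(record.seq), record.description)
        if seq.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {seq.id!r}")
        seen.add(seq.id)
        seqs.append(seq)
    if not seqs:
        raise FormatError(f"{path}: no FASTA records")
    return seqs


def write_fasta(seqs: Iterable[Sequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id.replace(" ", "_"), description="")
        for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_alignment(path: str | Path, locus_name: str | None = None) -> LocusAlignment:
    """Read an aligned FASTA file as a :class:`LocusAlignment`."""
    name = locus_name or Path(path).stem
    return LocusAlignment(name, tuple(read_fasta(path)))


# ---------------------------------------------------------------------------
# GenBank


class CompoundLocationError(FormatError):
    """Raised for trans-spliced (mixed-strand) feature locations."""


_CAPTURED_FEATURES = ("gene", "tRNA", "rRNA", "CDS", "intron", "exon")


def read_genbank(path: str | Path) -> GenomeRecord:
    """Read an annotated GenBank flat file into a :class:`GenomeRecord`.

    Feature intervals are converted from GenBank's 1-based inclusive
    convention to 0-based half-open (Biopython already does this).
    Same-strand joined locations are kept as ordered parts, so spliced
    genes retain their exon structure; mixed-strand (trans-spliced)
    locations are rejected.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    residues = str(record.seq)
    if not residues or set(residues) == {"N"}:
        raise FormatError(f"{path}: record has no ORIGIN sequence")
    features: list[GenomeFeature] = []
    for feat in record.features:
        if feat.type not in _CAPTURED_FEATURES:
            continue
        gene = (
            feat.qualifiers.get("gene", [""])[0]
            or feat.qualifiers.get("locus_tag", [""])[0]
        )
        strands = {part.strand for part in feat.location.parts}
        if len(strands) > 1:
            raise CompoundLocationError(
                f"{path}: trans-spliced location for {gene or feat.type!r} "
                "is not supported"
            )
        strand = "-" if strands.pop() == -1 else "+"
        parts = tuple(
            sorted((int(part.start), int(part.end)) for part in feat.location.parts)
        )
        if feat.type in ("gene", "tRNA") and not gene:
            continue  # unnamed gene-level features cannot be matched anyway
        features.append(GenomeFeature(feat.type, gene, parts, strand))
    return GenomeRecord(record.id or record.name, residues, tuple(features))


# ---------------------------------------------------------------------------
# NEXUS with charsets

_NEXUS_ILLEGAL = re.compile(r"[\s()\[\]{}/\\,;:=*'\"`+<>-]")


def _nexus_label(label: str) -> str:
    if _NEXUS_ILLEGAL.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_nexus_matrix(alignments: TypingSequence[LocusAlignment], path: str | Path) -> None:
    """Write a concatenated NEXUS matrix with one charset per locus.

    All alignments must share an identical taxon set (pad first with the
    supermatrix module if they do not).  Charsets use NEXUS's 1-based
    inclusive convention.
    """
    alignments = list(alignments)
    if not alignments:
        raise ValueError("no alignments to write")
    taxa = list(alignments[0].taxa)
    taxon_set = set(taxa)
    for aln in alignments[1:]:
        if set(aln.taxa) != taxon_set:
            missing = sorted(taxon_set.symmetric_difference(aln.taxa))
            raise ValueError(
                f"taxon sets differ at locus {aln.locus_name!r}; "
                f"unshared taxa: {missing}"
            )
    names = [a.locus_name for a in alignments]
    if len(set(names)) != len(names):
        raise ValueError("duplicate locus names")
    total = sum(a.length for a in alignments)
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={len(taxa)} NCHAR={total};",
        "    FORMAT DATATYPE=DNA MISSING=? GAP=-;",
        "    MATRIX",
    ]
    width = max(len(_nexus_label(t)) for t in taxa) + 2
    for taxon in taxa:
        row = "".join(a.row(taxon).residues for a in alignments)
        lines.append(f"    {_nexus_label(taxon):<{width}}{row}")
    lines += ["    ;", "END;", "BEGIN SETS;"]
    offset = 0
    for aln in alignments:
        start, end = offset + 1, offset + aln.length  # 1-based inclusive
        lines.append(f"    CHARSET {_nexus_label(aln.locus_name)} = {start}-{end};")
        offset = end
    lines += ["END;", ""]
    Path(path).write_text("\n".join(lines))


_CHARSET_RE = re.compile(
    r"CHARSET\s+(?:'([^']+)'|(\S+))\s*=\s*(\d+)\s*-\s*(\d+)\s*;", re.IGNORECASE
)
_MATRIX_ROW_RE = re.compile(r"^\s*(?:'([^']+)'|(\S+))\s+(\S+)\s*$")


def read_nexus_matrix(path: str | Path) -> list[LocusAlignment]:
    """Read a NEXUS matrix written by :func:`write_nexus_matrix`.

    Returns one :class:`LocusAlignment` per charset, reconstructing the
    0-based half-open locus spans from the file's 1-based inclusive ones.
    """
    text = Path(path).read_text()
    if not text.lstrip().upper().startswith("#NEXUS"):
        raise FormatError(f"{path}: not a NEXUS file")
    matrix_match = re.search(r"MATRIX(.*?);", text, re.DOTALL | re.IGNORECASE)
    if not matrix_match:
        raise FormatError(f"{path}: no MATRIX block")
    rows: list[tuple[str, str]] = []
    for line in matrix_match.group(1).splitlines():
        if not line.strip():
            continue
        m = _MATRIX_ROW_RE.match(line)
        if not m:
            raise FormatError(f"{path}: unparseable matrix row {line!r}")
        rows.append(((m.group(1) or m.group(2)).replace("''", "'"), m.group(3)))
    charsets = [
        ((m.group(1) or m.group(2)).replace("''", "'"), int(m.group(3)) - 1, int(m.group(4)))
        for m in _CHARSET_RE.finditer(text)
    ]
    if not charsets:
        total = len(rows[0][1])
        charsets = [(Path(path).stem, 0, total)]
    alignments = []
    for name, start, end in charsets:
        alignments.append(
            LocusAlignment(
                name, tuple(Sequence(t, seq[start:end]) for t, seq in rows)
            )
        )
    return alignments


# ---------------------------------------------------------------------------
# Newick trees (dendropy-backed)


def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse a newick tree from a path or a literal newick string.

    Internal-node labels are kept as node labels; the common convention of
    storing bootstrap/posterior support as internal labels is preserved.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("(")
    ):
        data = Path(source).read_text()
    else:
        data = source
    try:
        return dendropy.Tree.get(
            data=data,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise FormatError(f"newick parse error: {exc}") from exc


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Serialise a tree to newick; writes to *path* when given."""
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip() + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
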