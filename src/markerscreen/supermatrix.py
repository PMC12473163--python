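"""Locus ranking and supermatrix assembly.

Selected loci are concatenated over the union taxon set into a partitioned
matrix; taxa absent from a locus are padded with ``?`` (absent data) rather
than ``-`` (an inferred gap), and both count as missing in every statistic.
Export writers emit relaxed PHYLIP, a RAxML-style partition file and NEXUS
with charsets for hand-off to external ML/BI tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .informativeness import InformativenessReport
from .seq_core import LocusAlignment, PAD_CHAR, Sequence, write_nexus_matrix


@dataclass(frozen=True)
class LocusRanking:
    """Deterministic ordering of loci by informativeness score."""

    table: pd.DataFrame  # columns: locus, subs_per_kb, n_ssr, score, rank

    @property
    def ordered_loci(self) -> list[str]:
        return self.table["locus"].tolist()

    def top(self, k: int) -> list[str]:
        return self.ordered_loci[:k]


def rank_loci(
    reports: list[InformativenessReport],
    weight_subs: float = 1.0,
    weight_ssr: float = 1.0,
) -> LocusRanking:
    """Rank loci by weighted substitutions/kb + SSR count, descending.

    Ties break lexicographically by locus name so the order is a total
    order regardless of input order.
    """
    if not reports:
        raise ValueError("rank_loci needs at least one report")
    rows = []
    for r in reports:
        subs_per_kb = r.per_kb(r.substitutions)
        rows.append(
            {
                "locus": r.locus_name,
                "subs_per_kb": subs_per_kb,
                "indels_per_kb": r.per_kb(r.n_indels),
                "pis_per_kb": r.per_kb(r.n_pis),
                "n_ssr": r.n_ssr,
                "score": weight_subs * subs_per_kb + weight_ssr * r.n_ssr,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["score", "locus"], ascending=[False, True], kind="mergesort"
    )
    table["rank"] = range(1, len(table) + 1)
    return LocusRanking(table.reset_index(drop=True))


@dataclass(frozen=True)
class Supermatrix:
    """Concatenation of per-locus alignments over the union taxon set."""

    taxa: tuple[str, ...]
    blocks: tuple[tuple[str, LocusAlignment], ...]
    offsets: tuple[tuple[str, int, int], ...]  # (locus, start, end) 0-based half-open

    @property
    def total_length(self) -> int:
        return sum(aln.length for _, aln in self.blocks)

    def row(self, taxon: str) -> str:
        parts = []
        for _, aln in self.blocks:
            if taxon in aln.taxa:
                parts.append(aln.row(taxon).residues)
            else:
                parts.append(PAD_CHAR * aln.length)
        return "".join(parts)

    def to_alignment(self, name: str = "supermatrix") -> LocusAlignment:
        return LocusAlignment(
            name, tuple(Sequence(t, self.row(t)) for t in self.taxa)
        )

    def padded_blocks(self) -> list[LocusAlignment]:
        """Per-locus alignments padded to the full taxon set with '?' rows."""
        out = []
        for locus, aln in self.blocks:
            rows = []
            for t in self.taxa:
                if t in aln.taxa:
                    rows.append(aln.row(t))
                else:
                    rows.append(Sequence(t, PAD_CHAR * aln.length))
            out.append(LocusAlignment(locus, tuple(rows)))
        return out


def concatenate(alignments: list[LocusAlignment]) -> Supermatrix:
    """Concatenate loci; taxa missing from a locus are padded with '?'.

    Taxon order is first-appearance order across the input loci; block
    order is the input order; offsets record each locus's 0-based
    half-open span in the concatenation.
    """
    if not alignments:
        raise ValueError("nothing to concatenate")
    names = [a.locus_name for a in alignments]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate locus names: {dupes}")
    taxa: list[str] = []
    for aln in alignments:
        for t in aln.taxa:
            if t not in taxa:
                taxa.append(t)
    offsets = []
    pos = 0
    for aln in alignments:
        offsets.append((aln.locus_name, pos, pos + aln.length))
        pos += aln.length
    return Supermatrix(tuple(taxa), tuple((a.locus_name, a) for a in alignments), tuple(offsets))


def write_phylip(sm: Supermatrix, path: str | Path) -> None:
    """Relaxed PHYLIP: 'name sequence' per line, names space-free."""
    lines = [f" {len(sm.taxa)} {sm.total_length}"]
    for taxon in sm.taxa:
        lines.append(f"{taxon.replace(' ', '_')}  {sm.row(taxon)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_raxml_partitions(sm: Supermatrix, path: str | Path) -> None:
    """RAxML partition file: 'DNA, locus = start-end' (1-based inclusive)."""
    lines = [
        f"DNA, {locus.replace(' ', '_')} = {start + 1}-{end}"
        for locus, start, end in sm.offsets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def export_for_inference(sm: Supermatrix, outdir: str | Path) -> dict[str, Path]:
    """Write PHYLIP + RAxML partitions + NEXUS charsets under *outdir*.

    All-missing rows are retained (external tools decide how to treat
    them); the NEXUS charset spans round-trip to the supermatrix offsets.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "phylip": outdir / "supermatrix.phy",
        "partitions": outdir / "supermatrix.partitions",
        "nexus": outdir / "supermatrix.nex",
    }
    write_phylip(sm, paths["phylip"])
    write_raxml_partitions(sm, paths["partitions"])
    write_nexus_matrix(sm.padded_blocks(), paths["nexus"])
    return paths
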