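"""In-silico harvesting of candidate plastid regions from annotated genomes.

The screening approach: given a handful of annotated plastomes from related
species, extract every named intergenic spacer and intron from a fixed
catalogue, align the homologous copies, and score each region's
informativeness to pick markers worth sequencing.  The built-in catalogue
covers the 43 intergenic spacers and 6 introns classically screened in
Lamiaceae plastomes.

Gene-name matching strips tRNA anticodon suffixes ("trnK-UUU" matches
"trnK") because annotation dialects differ between GenBank records; the
display name keeps whatever the catalogue says.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner

from .informativeness import InformativenessReport, report
from .seq_core import GenomeRecord, LocusAlignment, Sequence, reverse_complement

logger = logging.getLogger(__name__)

_ANTICODON = re.compile(r"^(trn[A-Za-z])[-^]?\(?[ACGUT]{3}\)?\^?$", re.IGNORECASE)


def normalise_gene_name(name: str) -> str:
    """Strip anticodon decorations: 'trnK-UUU', 'trnK^UUU^' -> 'trnK'."""
    name = name.strip().strip("*")
    m = _ANTICODON.match(name)
    if m:
        return m.group(1)
    return name


@dataclass(frozen=True)
class RegionSpec:
    """One catalogued region: an intergenic spacer or an intron."""

    name: str
    kind: str  # 'spacer' | 'intron'
    flank_genes: tuple[str, str] = ()
    host_gene: str = ""
    intron_ordinal: int = 0

    def __post_init__(self) -> None:
        if self.kind == "spacer":
            if len(self.flank_genes) != 2:
                raise ValueError(f"spacer {self.name!r} needs two flank genes")
            # Equal flank names are allowed for the special case of a region
            # spanning two copies/exons of the same gene (e.g. trnK-matK-trnK).
        elif self.kind == "intron":
            if not self.host_gene or self.intron_ordinal < 1:
                raise ValueError(
                    f"intron {self.name!r} needs a host gene and ordinal >= 1"
                )
        else:
            raise ValueError(f"kind must be 'spacer' or 'intron', got {self.kind!r}")


@dataclass(frozen=True)
class RegionCatalogue:
    regions: tuple[RegionSpec, ...]

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate region names in catalogue")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def get(self, name: str) -> RegionSpec:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]


_SPACERS = [
    ("accD-psaI", "accD", "psaI"),
    ("atpB-rbcL", "atpB", "rbcL"),
    ("rpl32-trnL", "rpl32", "trnL-UAG"),
    ("atpF-atpH", "atpF", "atpH"),
    ("atpI-atpH", "atpI", "atpH"),
    ("trnL-trnF", "trnL-UAA", "trnF-GAA"),
    ("ccsA-ndhD", "ccsA", "ndhD"),
    ("clpP-psbB", "clpP", "psbB"),
    ("ndhC-trnV", "ndhC", "trnV-UAC"),
    ("ndhE-ndhI", "ndhE", "ndhI"),
    ("petA-psbJ", "petA", "psbJ"),
    ("petB-petD", "petB", "petD"),
    ("petL-psaJ", "petL", "psaJ"),
    ("petN-psbM", "petN", "psbM"),
    ("psaA-ycf3", "psaA", "ycf3"),
    ("psaC-ndhE", "psaC", "ndhE"),
    ("psaI-ycf4", "psaI", "ycf4"),
    ("psaJ-rpl20", "psaJ", "rpl20"),
    ("psbA-trnH", "psbA", "trnH-GUG"),
    ("psbK-trnS", "psbK", "trnS-UGA"),
    ("rbcL-accD", "rbcL", "accD"),
    ("rpl20-rps12", "rpl20", "rps12"),
    ("rpl23-psbA", "rpl23", "psbA"),
    ("rps3-rps19", "rps3", "rps19"),
    ("rps4-trnT", "rps4", "trnT-UGU"),
    ("rps16-trnQ", "rps16", "trnQ-UUG"),
    ("rps15-ycf1", "rps15", "ycf1"),
    ("rps16-trnK", "rps16", "trnK-UUU"),
    ("rrn23-trnA", "rrn23", "trnA-UGC"),
    ("trnC-trnD", "trnC-GCA", "trnD-GUC"),
    ("trnD-trnT", "trnD-GUC", "trnT-GGU"),
    ("trnF-ndhJ", "trnF-GAA", "ndhJ"),
    ("trnF-psbA", "trnF-GAA", "psbA"),
    ("trnG-atpA", "trnG-UCC", "atpA"),
    ("trnH-trnK", "trnH-GUG", "trnK-UUU"),
    ("trnK-matK-trnK", "trnK-UUU", "trnK-UUU"),
    ("trnK-trnQ", "trnK-UUU", "trnQ-UUG"),
    ("trnL-rpl32", "trnL-UAG", "rpl32"),
    ("trnQ-psbK", "trnQ-UUG", "psbK"),
    ("trnS-psbZ", "trnS-UGA", "psbZ"),
    ("trnT-psbC", "trnT-GGU", "psbC"),
    ("ycf3-trnS", "ycf3", "trnS-GCU"),
    ("ycf4-ycf10", "ycf4", "ycf10"),
]

_INTRONS = [
    ("atpF intron", "atpF", 1),
    ("clpP intron 1", "clpP", 1),
    ("clpP intron 2", "clpP", 2),
    ("rpoC1 intron", "rpoC1", 1),
    ("trnV intron", "trnV-UAC", 1),
    ("ycf3 intron 1", "ycf3", 1),
]


def builtin_catalogue() -> RegionCatalogue:
    """The packaged 49-region catalogue: 43 spacers + 6 introns."""
    regions = [
        RegionSpec(name, "spacer", flank_genes=(a, b)) for name, a, b in _SPACERS
    ] + [
        RegionSpec(name, "intron", host_gene=g, intron_ordinal=k)
        for name, g, k in _INTRONS
    ]
    return RegionCatalogue(tuple(regions))


# ---------------------------------------------------------------------------
# Extraction


class RegionExtractionError(ValueError):
    pass


def _gene_copies(genome: GenomeRecord, gene: str):
    """All features matching a (normalised) gene name, best type first."""
    want = normalise_gene_name(gene).lower()
    hits = [
        f
        for f in genome.features
        if normalise_gene_name(f.gene_name).lower() == want
        and f.feature_type in ("gene", "tRNA", "rRNA", "CDS")
    ]
    # prefer gene-level features when both gene and CDS/tRNA are annotated
    gene_level = [f for f in hits if f.feature_type == "gene"]
    return gene_level or hits


def extract_region(genome: GenomeRecord, spec: RegionSpec) -> Sequence:
    """Extract one catalogued region from an annotated genome.

    Spacers: the sequence strictly between the two nearest annotated
    copies of the flank genes, reverse-complemented when needed so the
    first-named flank is upstream on the forward strand of the returned
    sequence.  A zero-length spacer (overlapping/adjacent flanks) is
    returned as a flagged empty result rather than an error.  Introns:
    the sequence between consecutive exon parts of the host gene.
    """
    if spec.kind == "intron":
        return _extract_intron(genome, spec)
    gene_a, gene_b = spec.flank_genes
    copies_a = _gene_copies(genome, gene_a)
    copies_b = _gene_copies(genome, gene_b)
    for gene, copies in ((gene_a, copies_a), (gene_b, copies_b)):
        if not copies:
            raise RegionExtractionError(
                f"{genome.id}: gene not annotated: {gene!r} (region {spec.name})"
            )
    same_gene = normalise_gene_name(gene_a) == normalise_gene_name(gene_b)
    if same_gene and len(copies_a) < 2:
        raise RegionExtractionError(
            f"{genome.id}: region {spec.name} needs two copies of "
            f"{gene_a!r}, found {len(copies_a)}"
        )
    candidates = []
    for fa in copies_a:
        for fb in copies_b:
            if fa is fb:
                continue
            if fa.end <= fb.start:
                candidates.append((fb.start - fa.end, fa.end, fb.start, False, fa, fb))
            elif fb.end <= fa.start:
                candidates.append((fa.start - fb.end, fb.end, fa.start, True, fa, fb))
            else:  # overlapping flanks: zero-length spacer
                candidates.append((0, fa.end, fa.end, False, fa, fb))
    if not candidates:
        raise RegionExtractionError(
            f"{genome.id}: no usable flank pair for region {spec.name}"
        )
    candidates.sort(key=lambda c: c[0])
    best = candidates[0]
    ties = [c for c in candidates[1:] if c[0] == best[0] and (c[1], c[2]) != (best[1], best[2])]
    if ties:
        raise RegionExtractionError(
            f"{genome.id}: region {spec.name}: multiple equally-near flank "
            "copies; disambiguate with explicit coordinates"
        )
    gap, start, end, a_is_downstream, fa, _ = best
    if gap == 0:
        logger.warning(
            "%s: region %s has a zero-length spacer (flanks adjacent/overlapping)",
            genome.id,
            spec.name,
        )
        return Sequence(genome.id, "N", f"{spec.name} [empty spacer]")
    residues = genome.residues[start:end]
    if a_is_downstream:
        # first-named flank lies after the second in genome coordinates:
        # flip so it is upstream on '+' in the returned sequence
        residues = reverse_complement(residues)
    return Sequence(genome.id, residues, spec.name)


def _extract_intron(genome: GenomeRecord, spec: RegionSpec) -> Sequence:
    copies = _gene_copies(genome, spec.host_gene)
    multi = [f for f in copies if len(f.parts) > spec.intron_ordinal]
    if not multi:
        # gene-level annotations are often single-span; fall back to CDS/exon parts
        want = normalise_gene_name(spec.host_gene).lower()
        multi = [
            f
            for f in genome.features
            if normalise_gene_name(f.gene_name).lower() == want
            and len(f.parts) > spec.intron_ordinal
        ]
    if not multi:
        raise RegionExtractionError(
            f"{genome.id}: no multi-exon annotation for {spec.host_gene!r} "
            f"(region {spec.name})"
        )
    feat = multi[0]
    parts = feat.parts
    if feat.strand == "-":
        # part order along the gene runs right-to-left on the genome
        k = len(parts) - spec.intron_ordinal
        start, end = parts[k - 1][1], parts[k][0]
        return Sequence(genome.id, reverse_complement(genome.residues[start:end]), spec.name)
    start = parts[spec.intron_ordinal - 1][1]
    end = parts[spec.intron_ordinal][0]
    return Sequence(genome.id, genome.residues[start:end], spec.name)


# ---------------------------------------------------------------------------
# Center-star multiple alignment


def align_homologs(
    seqs: list[Sequence],
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
    locus_name: str | None = None,
    max_len: int = 5000,
) -> LocusAlignment:
    """Deterministic center-star multiple alignment with affine gaps.

    Each sequence is globally aligned to the longest input (the center)
    and the pairwise alignments are merged by inserting gap columns.
    Deterministic for a fixed input order and scoring parameters.  Input
    gaps are stripped first.  Intended for screen-scale loci (< ~5 kb).
    """
    if len(seqs) < 2:
        raise ValueError("alignment needs >= 2 sequences")
    degapped = [Sequence(s.id, s.degapped() or "", s.description) for s in seqs]
    for s in degapped:
        if len(s.residues) > max_len:
            raise ValueError(f"sequence {s.id!r} exceeds {max_len} bp screen scale")
    center_idx = max(range(len(degapped)), key=lambda i: len(degapped[i].residues))
    center = degapped[center_idx]

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend

    master: list[str] = list(center.residues)  # center row, gaps accrue
    rows: dict[str, list[str]] = {center.id: master}
    order = [s.id for s in degapped]

    for s in degapped:
        if s.id == center.id:
            continue
        aln = aligner.align(center.residues, s.residues)[0]
        pair_c, pair_s = str(aln[0]), str(aln[1])
        new_row: list[str] = []
        i = 0  # column in current master
        j = 0  # column in pairwise alignment
        while j < len(pair_c):
            if pair_c[j] == "-":
                # insertion in s relative to the center: new column everywhere
                for row in rows.values():
                    row.insert(i, "-")
                new_row.append(pair_s[j])
                i += 1
                j += 1
            elif i < len(master) and master[i] == "-":
                new_row.append("-")
                i += 1
            else:
                new_row.append(pair_s[j])
                i += 1
                j += 1
        while i < len(master):  # trailing master gap columns
            new_row.append("-")
            i += 1
        rows[s.id] = new_row

    name = locus_name or (seqs[0].description or "locus")
    return LocusAlignment(
        name, tuple(Sequence(t, "".join(rows[t])) for t in order)
    )


# ---------------------------------------------------------------------------
# Screening


@dataclass(frozen=True)
class ScreenResult:
    spec: RegionSpec
    report: InformativenessReport | None
    partial: bool
    errors: tuple[str, ...] = ()
    alignment: LocusAlignment | None = None


def screen_regions(
    genomes: list[GenomeRecord],
    catalogue: RegionCatalogue | None = None,
    ssr_thresholds: dict[int, int] | None = None,
    aligner_params: dict | None = None,
) -> list[ScreenResult]:
    """Extract, align and score every catalogued region across genomes.

    Regions missing from some (but not all-but-one) genomes are scored on
    the remaining copies and flagged partial; per-region failures are
    collected, never fatal.  Results are sorted by ranking score
    (substitutions/kb + SSR count, descending; ties by name).
    """
    if len(genomes) < 2:
        raise ValueError("screening needs >= 2 genomes")
    catalogue = catalogue or builtin_catalogue()
    aligner_params = aligner_params or {}
    results: list[ScreenResult] = []
    for spec in catalogue:
        seqs, errors = [], []
        for genome in genomes:
            try:
                seq = extract_region(genome, spec)
            except RegionExtractionError as exc:
                errors.append(str(exc))
                continue
            if seq.degapped() and set(seq.degapped()) != {"N"}:
                seqs.append(seq)
            else:
                errors.append(f"{genome.id}: empty spacer for {spec.name}")
        if len(seqs) < 2:
            results.append(ScreenResult(spec, None, True, tuple(errors)))
            continue
        try:
            aln = align_homologs(seqs, locus_name=spec.name, **aligner_params)
            rep = report(aln, ssr_thresholds=ssr_thresholds)
        except ValueError as exc:
            results.append(ScreenResult(spec, None, True, tuple(errors) + (str(exc),)))
            continue
        results.append(
            ScreenResult(spec, rep, len(seqs) < len(genomes), tuple(errors), aln)
        )

    def sort_key(res: ScreenResult):
        if res.report is None:
            return (1, 0.0, res.spec.name)
        score = res.report.per_kb(res.report.substitutions) + res.report.n_ssr
        return (0, -score, res.spec.name)

    return sorted(results, key=sort_key)
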