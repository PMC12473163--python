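"""Clade-diagnostic parsimony-informative sites.

Counts, per locus, the PIS columns that separate a named clade (e.g. the
Acinos/Ziziphora lineage) from the rest of the matrix.  Two criteria are
computed because published per-region tallies rarely state which was used:

* ``fixed_difference`` — the column is a PIS, every non-missing ingroup row
  carries one state ``x``, and ``x`` is absent from every non-missing row
  outside the clade.  The complement may be polymorphic.
* ``strict`` — additionally requires the complement monomorphic for a
  single state ``y != x``.

Gaps, pads and ambiguity codes are missing data; rows missing at a column
are ignored, and columns where either side retains fewer than two scored
rows are skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seq_core import CladePartition, DNA_BASES, LocusAlignment
from .informativeness import MISSING_CODE, encode_alignment

logger = logging.getLogger(__name__)

MODES = ("fixed_difference", "strict")


@dataclass(frozen=True)
class DiagnosticSite:
    """One clade-diagnostic alignment column."""

    column: int
    clade_state: str
    other_states: tuple[str, ...]
    strict: bool


def clade_pis(
    aln: LocusAlignment,
    partition: CladePartition,
    mode: str = "fixed_difference",
) -> tuple[int, list[DiagnosticSite]]:
    """Count PIS columns diagnostic of *partition*'s ingroup.

    Returns the count and the located sites.  ``mode`` selects the
    criterion described in the module docstring.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    taxa = aln.taxa
    unknown = partition.ingroup - set(taxa)
    if unknown:
        raise ValueError(
            f"partition {partition.name!r} references unknown taxa: {sorted(unknown)}"
        )
    in_mask = np.array([t in partition.ingroup for t in taxa])
    if in_mask.sum() < 2 or (~in_mask).sum() < 2:
        raise ValueError(
            f"partition {partition.name!r}: need >= 2 taxa on each side"
        )
    arr = encode_alignment(aln)
    ingroup, outgroup = arr[in_mask], arr[~in_mask]
    counts = np.stack([(arr == s).sum(axis=0) for s in range(4)])
    is_pis = (counts >= 2).sum(axis=0) >= 2

    sites: list[DiagnosticSite] = []
    for col in np.nonzero(is_pis)[0]:
        in_states = set(ingroup[:, col][ingroup[:, col] != MISSING_CODE].tolist())
        out_states = set(outgroup[:, col][outgroup[:, col] != MISSING_CODE].tolist())
        if len(in_states) != 1 or len(out_states) < 1:
            continue
        if np.sum(ingroup[:, col] != MISSING_CODE) < 2:
            continue
        if np.sum(outgroup[:, col] != MISSING_CODE) < 2:
            continue
        (x,) = in_states
        if x in out_states:
            continue
        strict = len(out_states) == 1
        if mode == "strict" and not strict:
            continue
        sites.append(
            DiagnosticSite(
                column=int(col),
                clade_state=DNA_BASES[x],
                other_states=tuple(DNA_BASES[s] for s in sorted(out_states)),
                strict=strict,
            )
        )
    return len(sites), sites


def clade_pis_table(
    alignments: list[LocusAlignment],
    partition: CladePartition,
    mode: str = "both",
) -> pd.DataFrame:
    """Per-locus table of clade-diagnostic site counts.

    With ``mode="both"`` the table carries one column per criterion.  Loci
    with zero diagnostic sites are marked ``none_detected`` (mirroring how
    marker studies flag regions with no sites common to the whole clade).
    Undersized partitions are skipped with a warning rather than crashing.
    """
    modes = list(MODES) if mode == "both" else [mode]
    rows = []
    for aln in alignments:
        row: dict = {"locus": aln.locus_name}
        try:
            for m in modes:
                count, sites = clade_pis(aln, partition, m)
                row[f"n_{m}"] = count
                row[f"sites_{m}"] = ",".join(str(s.column) for s in sites)
        except ValueError as exc:
            logger.warning("skipping locus %s: %s", aln.locus_name, exc)
            continue
        row["none_detected"] = all(row[f"n_{m}"] == 0 for m in modes)
        rows.append(row)
    return pd.DataFrame(rows)
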