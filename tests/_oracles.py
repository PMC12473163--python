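"""Independent brute-force oracles, written from the definitions.

These deliberately share no code with the package: column statistics are
naive per-column scans, SSR detection enumerates every candidate substring
array.  They exist to cross-check the production implementations.
"""

from markerscreen.seq_core import LocusAlignment

BASES = set("ACGT")


def brute_pis(aln: LocusAlignment) -> list[int]:
    """Columns with >= 2 distinct unambiguous states each in >= 2 rows."""
    sites = []
    for col in range(aln.length):
        column = [row.residues[col] for row in aln.rows]
        tallies = {}
        for c in column:
            if c in BASES:
                tallies[c] = tallies.get(c, 0) + 1
        if sum(1 for v in tallies.values() if v >= 2) >= 2:
            sites.append(col)
    return sites


def brute_substitutions(aln: LocusAlignment) -> tuple[int, int]:
    """Consensus-based per-column tally, transitions vs transversions."""
    ti = tv = 0
    for col in range(aln.length):
        tallies = {}
        for row in aln.rows:
            c = row.residues[col]
            if c in BASES:
                tallies[c] = tallies.get(c, 0) + 1
        if len(tallies) < 2:
            continue
        consensus = sorted(tallies, key=lambda b: (-tallies[b], b))[0]
        for state in tallies:
            if state == consensus:
                continue
            if {state, consensus} in ({"A", "G"}, {"C", "T"}):
                ti += 1
            else:
                tv += 1
    return ti, tv


def brute_indels(aln: LocusAlignment, include_terminal=False):
    """Gap events as (start, end, carriers) with identical-span pooling."""
    events = {}
    for row in aln.rows:
        col = 0
        while col < aln.length:
            if row.residues[col] == "-":
                start = col
                while col < aln.length and row.residues[col] == "-":
                    col += 1
                if include_terminal or (start != 0 and col != aln.length):
                    events.setdefault((start, col), set()).add(row.id)
            else:
                col += 1
    return sorted(
        (start, end, frozenset(carriers))
        for (start, end), carriers in events.items()
    )


def brute_ssr(seq: str, thresholds: dict[int, int]):
    """Enumerate every maximal perfect tandem array, then apply the rules.

    Returns (start, end, canonical_motif, repeats) on the degapped string,
    non-primitive motifs dropped, overlaps resolved in favour of length.
    """
    seq = seq.replace("-", "").replace("?", "")
    n = len(seq)
    found = set()
    for mlen, min_rep in thresholds.items():
        for start in range(n - mlen + 1):
            motif = seq[start : start + mlen]
            if not set(motif) <= BASES:
                continue
            # primitive check
            if any(
                mlen % d == 0 and motif == motif[:d] * (mlen // d)
                for d in range(1, mlen)
            ):
                continue
            end = start + mlen
            while end < n and seq[end] == seq[end - mlen]:
                end += 1
            reps = (end - start) // mlen
            end = start + reps * mlen
            if reps < min_rep:
                continue
            # maximality: discard arrays that are shifted suffixes of a
            # longer array with the same motif period
            if start >= mlen and seq[start - mlen : start] == motif:
                continue
            if start >= 1 and seq[start - 1] == seq[start + mlen - 1]:
                continue
            canon = min(motif[i:] + motif[:i] for i in range(mlen))
            found.add((start, start + reps * mlen, canon, reps))
    chosen = []
    for cand in sorted(found, key=lambda a: (-(a[1] - a[0]), a[0], len(a[2]))):
        if all(cand[1] <= c[0] or cand[0] >= c[1] for c in chosen):
            chosen.append(cand)
    return sorted(chosen)
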