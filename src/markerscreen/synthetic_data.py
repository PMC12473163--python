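"""Sequence simulator with ground truth for recovery tests.

Generates per-locus alignments with the statistical structure the marker
screen assumes: a rooted tree with two diverged clades, locus-specific
substitution rates with a transition/transversion bias (K2P process),
indel events with geometric lengths, and planted microsatellite arrays
undergoing stepwise repeat-number mutation.

Insertions and deletions are tracked natively through a global column
registry, so the emitted alignment is the *true* alignment — no realigner
is involved, which separates alignment error from counting error in
recovery tests.  Every event is logged per branch and locus; replaying
the log from the root reproduces each leaf byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .seq_core import LocusAlignment, Sequence
from .informativeness import DEFAULT_SSR_THRESHOLDS

BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class SsrSeed:
    """A microsatellite array planted in the root sequence."""

    motif: str
    repeats: int

    @property
    def array_length(self) -> int:
        return len(self.motif) * self.repeats


@dataclass(frozen=True)
class LocusConfig:
    """Evolutionary regime for one simulated locus.

    Rates are per site per unit branch length; ``kappa`` is the
    transition/transversion *rate* ratio (a substitution is a transition
    with probability kappa / (kappa + 2), the K2P allocation for equal
    base frequencies).  ``forced_branch_subs`` pins an exact number of
    substitutions (at distinct sites) onto named branches — the mechanism
    for planting clade-diagnostic fixed differences.
    """

    name: str
    length: int
    sub_rate: float = 0.0
    kappa: float = 2.0
    indel_rate: float = 0.0
    indel_mean_len: float = 3.0
    insertion_prob: float = 0.5  # fraction of indel events that insert
    ssr_seeds: tuple[SsrSeed, ...] = ()
    ssr_step_prob: float = 0.0
    forced_branch_subs: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.length < 50:
            raise ValueError(f"locus {self.name!r}: length must be >= 50")
        if self.sub_rate < 0 or self.indel_rate < 0 or self.ssr_step_prob < 0:
            raise ValueError(f"locus {self.name!r}: rates must be >= 0")
        if self.kappa <= 0:
            raise ValueError(f"locus {self.name!r}: kappa must be > 0")


@dataclass(frozen=True)
class SimConfig:
    tree: str  # newick with branch lengths; internal labels name branches
    loci: tuple[LocusConfig, ...]
    seed: int = 0


# ---------------------------------------------------------------------------
# Ground truth


@dataclass(frozen=True)
class SubEvent:
    branch: str
    col: int
    from_base: str
    to_base: str
    forced: bool = False

    @property
    def is_transition(self) -> bool:
        return _TRANSITION[self.from_base] == self.to_base


@dataclass(frozen=True)
class IndelTruthEvent:
    branch: str
    kind: str  # 'ins' | 'del'
    cols: tuple[int, ...]
    bases: tuple[str, ...]  # inserted or deleted bases, in column order
    from_ssr: bool = False


@dataclass(frozen=True)
class BranchLog:
    branch: str
    indels: tuple[IndelTruthEvent, ...]
    subs: tuple[SubEvent, ...]


@dataclass(frozen=True)
class LocusTruth:
    """Everything needed to replay and audit one simulated locus."""

    name: str
    root: tuple[tuple[int, str], ...]  # (column id, base) in order
    column_order: tuple[int, ...]  # all columns ever created, global order
    kept_columns: tuple[int, ...]  # columns present in the emitted alignment
    logs: tuple[BranchLog, ...]  # preorder branch traversal
    alignment: LocusAlignment

    @property
    def n_indel_events(self) -> int:
        return sum(len(log.indels) for log in self.logs)

    @property
    def n_substitutions(self) -> int:
        return sum(len(log.subs) for log in self.logs)

    @property
    def n_forced_subs(self) -> int:
        return sum(1 for log in self.logs for s in log.subs if s.forced)

    def column_position(self, col: int) -> int | None:
        """Final alignment index of a column id, or None if dropped."""
        try:
            return self.kept_columns.index(col)
        except ValueError:
            return None


@dataclass(frozen=True)
class SimTruth:
    tree: str
    loci: tuple[LocusTruth, ...]
    config: SimConfig

    def locus(self, name: str) -> LocusTruth:
        for lt in self.loci:
            if lt.name == name:
                return lt
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Simulation core


def _branch_id(node: dendropy.Node, counter: dict) -> str:
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    counter["n"] += 1
    return f"node{counter['n']}"


class _LocusSim:
    """Mutable simulation state for one locus."""

    def __init__(self, cfg: LocusConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.next_col = cfg.length
        root = [BASES[i] for i in rng.integers(0, 4, size=cfg.length)]
        self.ssr_arrays_root: list[list[int]] = []
        self._plant_ssr(root)
        self.global_order: list[int] = list(range(cfg.length))
        self.order_key: dict[int, float] = {c: float(c) for c in self.global_order}
        self.root_state: dict[int, str] = dict(enumerate(root))

    def _plant_ssr(self, root: list[str]) -> None:
        seeds = self.cfg.ssr_seeds
        if not seeds:
            return
        L = self.cfg.length
        segment = L // len(seeds)
        for i, seed in enumerate(seeds):
            alen = seed.array_length
            if alen + 2 > segment:
                raise ValueError(
                    f"locus {self.cfg.name!r}: SSR seeds too dense to plant"
                )
            start = i * segment + (segment - alen) // 2
            array = (seed.motif * seed.repeats)[:alen]
            root[start : start + alen] = list(array)
            # breaker bases so the planted array is exactly maximal
            if start > 0:
                left_ext = seed.motif[-1]
                if root[start - 1] == left_ext:
                    root[start - 1] = next(b for b in BASES if b != left_ext)
            end = start + alen
            if end < L:
                right_ext = seed.motif[alen % len(seed.motif)]
                if root[end] == right_ext:
                    root[end] = next(b for b in BASES if b != right_ext)
            self.ssr_arrays_root.append(list(range(start, end)))

    # -- ordering helpers --------------------------------------------------

    def _ordered_cols(self, state: dict[int, str]) -> list[int]:
        return sorted(state, key=self.order_key.get)

    def _new_cols(self, k: int, after: int | None) -> list[int]:
        """Register k new columns in the global order, after column *after*."""
        ids = list(range(self.next_col, self.next_col + k))
        self.next_col += k
        if after is None:
            pos = 0
        else:
            pos = self.global_order.index(after) + 1
        self.global_order[pos:pos] = ids
        # rebuild order keys (simulation scale keeps this cheap)
        self.order_key = {c: float(i) for i, c in enumerate(self.global_order)}
        return ids

    # -- per-branch evolution ----------------------------------------------

    def evolve(
        self,
        state: dict[int, str],
        arrays: list[list[int]],
        blen: float,
        branch: str,
    ) -> tuple[dict[int, str], list[list[int]], BranchLog]:
        cfg, rng = self.cfg, self.rng
        state = dict(state)
        arrays = [list(a) for a in arrays]
        indel_events: list[IndelTruthEvent] = []
        sub_events: list[SubEvent] = []

        # indels
        n_indel = rng.poisson(cfg.indel_rate * len(state) * blen) if cfg.indel_rate else 0
        for _ in range(n_indel):
            cols = self._ordered_cols(state)
            if len(cols) < 2:
                break
            length = min(int(rng.geometric(1.0 / cfg.indel_mean_len)), len(cols) - 1)
            if rng.random() >= cfg.insertion_prob:  # deletion
                start = int(rng.integers(0, len(cols) - length + 1))
                run = cols[start : start + length]
                bases = tuple(state[c] for c in run)
                for c in run:
                    del state[c]
                for arr in arrays:
                    arr[:] = [c for c in arr if c not in run]
                indel_events.append(
                    IndelTruthEvent(branch, "del", tuple(run), bases)
                )
            else:  # insertion
                a = int(rng.integers(0, len(cols) + 1))
                anchor = cols[a - 1] if a > 0 else None
                new = self._new_cols(length, anchor)
                bases = tuple(BASES[i] for i in rng.integers(0, 4, size=length))
                for c, b in zip(new, bases):
                    state[c] = b
                indel_events.append(
                    IndelTruthEvent(branch, "ins", tuple(new), bases)
                )

        # SSR repeat-number steps (symmetric single-step model)
        if cfg.ssr_step_prob:
            for arr_idx, arr in enumerate(arrays):
                live = [c for c in arr if c in state]
                motif = cfg.ssr_seeds[arr_idx].motif
                d = len(motif)
                if len(live) < 2 * d or rng.random() >= cfg.ssr_step_prob:
                    continue
                if rng.random() < 0.5 and len(live) >= 3 * d:  # contraction
                    run = live[-d:]
                    bases = tuple(state[c] for c in run)
                    for c in run:
                        del state[c]
                    arr[:] = [c for c in arr if c not in run]
                    indel_events.append(
                        IndelTruthEvent(branch, "del", tuple(run), bases, from_ssr=True)
                    )
                else:  # expansion: duplicate the last motif unit
                    unit = live[-d:]
                    bases = tuple(state[c] for c in unit)
                    new = self._new_cols(d, unit[-1])
                    for c, b in zip(new, bases):
                        state[c] = b
                    arr.extend(new)
                    indel_events.append(
                        IndelTruthEvent(branch, "ins", tuple(new), bases, from_ssr=True)
                    )

        # substitutions: forced (distinct sites) then background
        cols = self._ordered_cols(state)
        p_ti = cfg.kappa / (cfg.kappa + 2.0)
        forced = dict(cfg.forced_branch_subs).get(branch, 0)
        if forced:
            if forced > len(cols):
                raise ValueError(
                    f"locus {cfg.name!r}: cannot force {forced} substitutions "
                    f"on branch {branch!r} with {len(cols)} sites"
                )
            sites = rng.choice(len(cols), size=forced, replace=False)
            for s in sorted(int(x) for x in sites):
                c = cols[s]
                state[c] = self._substitute(state[c], p_ti)
                sub_events.append(
                    SubEvent(branch, c, self._last_from, state[c], forced=True)
                )
        n_sub = rng.poisson(cfg.sub_rate * len(cols) * blen) if cfg.sub_rate else 0
        for _ in range(n_sub):
            c = cols[int(rng.integers(0, len(cols)))]
            state[c] = self._substitute(state[c], p_ti)
            sub_events.append(SubEvent(branch, c, self._last_from, state[c]))

        return state, arrays, BranchLog(branch, tuple(indel_events), tuple(sub_events))

    def _substitute(self, base: str, p_ti: float) -> str:
        self._last_from = base
        if self.rng.random() < p_ti:
            return _TRANSITION[base]
        tv = _TRANSVERSIONS[base]
        return tv[int(self.rng.integers(0, 2))]


def simulate(config: SimConfig) -> tuple[list[LocusAlignment], SimTruth]:
    """Run the simulator; returns true alignments and the event log."""
    tree = dendropy.Tree.get(
        data=config.tree,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(set(leaves)) != len(leaves):
        raise ValueError("tree leaf labels must be unique")
    rng = np.random.default_rng(config.seed)
    alignments: list[LocusAlignment] = []
    truths: list[LocusTruth] = []
    for cfg in config.loci:
        sim = _LocusSim(cfg, rng)
        counter = {"n": 0}
        node_state: dict[int, tuple[dict, list]] = {
            id(tree.seed_node): (sim.root_state, sim.ssr_arrays_root)
        }
        logs: list[BranchLog] = []
        leaf_rows: dict[str, dict[int, str]] = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                if node.is_leaf():
                    raise ValueError("tree must have >= 2 leaves")
                continue
            parent_state, parent_arrays = node_state[id(node.parent_node)]
            blen = node.edge.length or 0.0
            branch = _branch_id(node, counter)
            state, arrays, log = sim.evolve(parent_state, parent_arrays, blen, branch)
            logs.append(log)
            if node.is_leaf():
                leaf_rows[node.taxon.label] = state
            else:
                node_state[id(node)] = (state, arrays)
        # Root columns are kept unconditionally (a column deleted in every
        # leaf is still a real alignment column); inserted columns are kept
        # only while at least one leaf carries them.
        kept = [
            c
            for c in sim.global_order
            if c in sim.root_state or any(c in row for row in leaf_rows.values())
        ]
        rows = tuple(
            Sequence(taxon, "".join(leaf_rows[taxon].get(c, "-") for c in kept))
            for taxon in leaves
        )
        aln = LocusAlignment(cfg.name, rows)
        alignments.append(aln)
        truths.append(
            LocusTruth(
                name=cfg.name,
                root=tuple(sorted(sim.root_state.items())),
                column_order=tuple(sim.global_order),
                kept_columns=tuple(kept),
                logs=tuple(logs),
                alignment=aln,
            )
        )
    return alignments, SimTruth(config.tree, tuple(truths), config)


# ---------------------------------------------------------------------------
# Replay (independent audit of the event log)


def replay_locus(truth: LocusTruth, tree_newick: str) -> dict[str, str]:
    """Re-derive every leaf row from the root and the event log alone.

    Uses only the logged events and the global column order — not the
    simulator's internal state — so it serves as the replay-identity
    oracle for the invariant that the log fully determines the leaves.
    """
    tree = dendropy.Tree.get(
        data=tree_newick,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    logs = {log.branch: log for log in truth.logs}
    counter = {"n": 0}
    states: dict[int, dict[int, str]] = {id(tree.seed_node): dict(truth.root)}
    leaf_rows: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        branch = _branch_id(node, counter)
        state = dict(states[id(node.parent_node)])
        log = logs[branch]
        for ev in log.indels:
            if ev.kind == "del":
                for c in ev.cols:
                    del state[c]
            else:
                for c, b in zip(ev.cols, ev.bases):
                    state[c] = b
        for ev in log.subs:
            assert state[ev.col] == ev.from_base, "replay mismatch"
            state[ev.col] = ev.to_base
        if node.is_leaf():
            leaf_rows[node.taxon.label] = "".join(
                state.get(c, "-") for c in truth.kept_columns
            )
        else:
            states[id(node)] = state
    return leaf_rows


# ---------------------------------------------------------------------------
# Study-scale fixture: nine loci at screening-table rates


#: (name, aligned length, indel events, indel bp, transitions,
#:  transversions, SSR arrays) — the regime of a published screening table
#: for seven plastid spacers plus ITS and ETS; used as generator defaults.
SCREENING_REGIMES: tuple[tuple[str, int, int, int, int, int, int], ...] = (
    ("trnS-psbK", 703, 21, 90, 11, 19, 13),
    ("trnL-rpl32", 903, 16, 91, 27, 34, 34),
    ("rps16-trnQ", 1002, 22, 206, 21, 31, 41),
    ("rps16-trnK", 710, 15, 67, 19, 23, 18),
    ("rps15-ycf1", 611, 12, 144, 24, 12, 19),
    ("psbA-trnH", 424, 10, 61, 13, 21, 13),
    ("petN-psbM", 1057, 19, 47, 21, 17, 25),
    ("ITS", 702, 15, 21, 77, 47, 17),
    ("ETS", 408, 16, 24, 138, 68, 8),
)

PLASTID_LOCI = tuple(r[0] for r in SCREENING_REGIMES[:7])
NUCLEAR_LOCI = tuple(r[0] for r in SCREENING_REGIMES[7:])

#: Two-clade study tree: 7 taxa in an Acinos/Ziziphora-like clade, 8 in a
#: Clinopodium-like clade, one distant outgroup.  Branch lengths in
#: arbitrary time units; per-locus rates are per site per unit time.
CLADE_A_TAXA = tuple(f"Acinos_{i}" for i in range(1, 7)) + ("Ziziphora",)
CLADE_B_TAXA = tuple(f"Clinopodium_{i}" for i in range(1, 9))
OUTGROUP_TAXON = "Micromeria"


def _clade(
    names: tuple[str, ...], tip: float, internal: float, label: str, stem: float
) -> str:
    sub = f"{names[0]}:{tip}"
    for nm in names[1:-1]:
        sub = f"({sub},{nm}:{tip}):{internal}"
    return f"({sub},{names[-1]}:{tip}){label}:{stem}"


def two_clade_tree(
    stem: float = 0.5, tip: float = 0.3, internal: float = 0.15
) -> str:
    """Newick for the default two-clade study tree.

    The clade stems carry labels ``cladeA``/``cladeB`` so configs can pin
    forced substitutions onto the branch separating the clades.
    """
    a = _clade(CLADE_A_TAXA, tip, internal, "cladeA", stem)
    b = _clade(CLADE_B_TAXA, tip, internal, "cladeB", stem)
    return f"({a},{b},{OUTGROUP_TAXON}:{2 * stem});"


def tree_length(newick: str) -> float:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return sum(e.length or 0.0 for e in tree.preorder_edge_iter())


_SSR_MOTIFS = ("AT", "AG", "CT", "AAT", "AC", "AAG")


def screening_config(seed: int, ssr_step_prob: float = 0.0) -> SimConfig:
    """Nine-locus configuration at screening-table-like rates.

    Event-count targets (substitutions, indels, SSR arrays) are converted
    to per-site rates by dividing by total tree length x locus length, so
    the *expected* event counts equal the regime targets.  The regime is
    deletion-only (``insertion_prob=0``) so the true alignment length of
    every fixture locus equals its configured length exactly; SSR
    repeat-number mutation is off by default for the same reason and can
    be enabled via ``ssr_step_prob``.
    """
    tree = two_clade_tree()
    T = tree_length(tree)
    loci = []
    for name, L, n_ind, ind_bp, ti, tv, n_ssr in SCREENING_REGIMES:
        kappa = 2.0 * ti / tv
        motif_cycle = [_SSR_MOTIFS[i % len(_SSR_MOTIFS)] for i in range(n_ssr)]
        seeds = tuple(
            SsrSeed(m, DEFAULT_SSR_THRESHOLDS[len(m)] + 1) for m in motif_cycle
        )
        loci.append(
            LocusConfig(
                name=name,
                length=L,
                sub_rate=(ti + tv) / (T * L),
                kappa=kappa,
                indel_rate=n_ind / (T * L),
                indel_mean_len=ind_bp / n_ind,
                insertion_prob=0.0,
                ssr_seeds=seeds,
                ssr_step_prob=ssr_step_prob,
            )
        )
    return SimConfig(tree=tree, loci=tuple(loci), seed=seed)


def expected_counts(config: SimConfig) -> dict[str, dict[str, float]]:
    """Analytic expected event counts per locus under *config*."""
    T = tree_length(config.tree)
    tree = dendropy.Tree.get(data=config.tree, schema="newick")
    n_branches = sum(1 for n in tree.preorder_node_iter() if n.parent_node is not None)
    out = {}
    for cfg in config.loci:
        forced = sum(k for _, k in cfg.forced_branch_subs)
        out[cfg.name] = {
            "substitutions": cfg.sub_rate * cfg.length * T + forced,
            "indels": cfg.indel_rate * cfg.length * T
            + len(cfg.ssr_seeds) * n_branches * cfg.ssr_step_prob,
            "ssr": float(len(cfg.ssr_seeds)),
            "ti_tv_ratio": cfg.kappa / 2.0,
        }
    return out


def make_screening_fixture(seed: int) -> tuple[list[LocusAlignment], SimTruth]:
    """Generate the nine-locus study-scale fixture with its ground truth."""
    return simulate(screening_config(seed))


# ---------------------------------------------------------------------------
# Recovery summary


def truth_compare(truth: SimTruth, reports, clade_table=None):
    """Tabulate true vs detected statistics per locus.

    *reports* maps locus name -> InformativenessReport (or is an iterable
    of reports); *clade_table* is the optional per-locus diagnostic-site
    table whose ``n_fixed_difference`` column is compared with the number
    of forced stem substitutions.
    """
    import pandas as pd

    if not isinstance(reports, dict):
        reports = {r.locus_name: r for r in reports}
    rows = []
    for lt in truth.loci:
        if lt.name not in reports:
            raise ValueError(f"no report for simulated locus {lt.name!r}")
        rep = reports[lt.name]
        cfg = next(c for c in truth.config.loci if c.name == lt.name)
        row = {
            "locus": lt.name,
            "true_indel_events": lt.n_indel_events,
            "detected_indels": rep.n_indels,
            "true_substitutions": lt.n_substitutions,
            "detected_substitutions": rep.substitutions,
            "true_ssr": len(cfg.ssr_seeds),
            "detected_ssr": rep.n_ssr,
            "true_forced_subs": lt.n_forced_subs,
        }
        if clade_table is not None and "locus" in clade_table:
            hit = clade_table[clade_table["locus"] == lt.name]
            row["detected_fixed_differences"] = (
                int(hit["n_fixed_difference"].iloc[0]) if len(hit) else 0
            )
        rows.append(row)
    return pd.DataFrame(rows)
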