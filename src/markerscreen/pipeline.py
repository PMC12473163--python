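"""End-to-end pipeline: loci -> stats -> diagnose -> rank -> concat -> tree.

A run is described by one YAML-able config dict; every stage writes plain
TSV/FASTA/newick artifacts under a single output directory and the run
manifest records inputs, outputs (with content hashes), the seed and the
package version, so identical configs reproduce identical hashes for the
deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clade_diagnostics import clade_pis_table
from .informativeness import report
from .region_harvest import builtin_catalogue, screen_regions
from .seq_core import CladePartition, LocusAlignment, read_alignment, read_genbank, write_fasta, write_newick
from .supermatrix import concatenate, export_for_inference, rank_loci
from .synthetic_data import SimConfig, LocusConfig, SsrSeed, simulate, screening_config
from .tree_lite import bootstrap_support

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration (pre-flight validation failure)."""


_KNOWN_KEYS = {
    "seed",
    "simulate",
    "input",
    "ssr_thresholds",
    "clades",
    "diagnose",
    "rank",
    "concat",
    "tree",
    "harvest",
}


def validate_config(config: dict) -> None:
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "simulate" not in config and "input" not in config and "harvest" not in config:
        raise ConfigError("config needs one of: simulate, input, harvest")
    if "diagnose" in config:
        diag = config["diagnose"]
        name = diag.get("partition")
        clades = config.get("clades") or {}
        if name is not None and name not in clades:
            raise ConfigError(
                f"diagnose.partition {name!r} not defined under 'clades'"
            )
    thresholds = config.get("ssr_thresholds")
    if thresholds is not None:
        bad = [k for k in thresholds if int(k) not in range(1, 7)]
        if bad:
            raise ConfigError(f"ssr_thresholds keys must be 1..6, got {bad}")


def parse_clades_file(path: str | Path) -> dict[str, list[str]]:
    """Plain-text clade sets: '>name' headers, one taxon id per line."""
    sets: dict[str, list[str]] = {}
    current = Path(path).stem
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            current = line[1:].strip()
            sets.setdefault(current, [])
        else:
            sets.setdefault(current, []).append(line)
    return {k: v for k, v in sets.items() if v}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _sim_config_from_dict(spec: dict, seed: int) -> SimConfig:
    if spec.get("screening_regime"):
        return screening_config(seed)
    loci = []
    for item in spec["loci"]:
        item = dict(item)
        seeds = tuple(
            SsrSeed(s["motif"], int(s["repeats"])) for s in item.pop("ssr_seeds", [])
        )
        forced = tuple(
            (str(b), int(k)) for b, k in item.pop("forced_branch_subs", {}).items()
        )
        loci.append(LocusConfig(ssr_seeds=seeds, forced_branch_subs=forced, **item))
    return SimConfig(tree=spec["tree"], loci=tuple(loci), seed=seed)


def _load_loci(config: dict, outdir: Path, manifest: dict) -> list[LocusAlignment]:
    seed = int(config.get("seed", 0))
    if "simulate" in config:
        sim_config = _sim_config_from_dict(config["simulate"], seed)
        alignments, truth = simulate(sim_config)
        loci_dir = outdir / "loci"
        loci_dir.mkdir(parents=True, exist_ok=True)
        outputs = []
        for aln in alignments:
            path = loci_dir / f"{aln.locus_name.replace(' ', '_')}.fasta"
            write_fasta(aln.rows, path)
            outputs.append(path)
        tree_path = outdir / "true_tree.nwk"
        tree_path.write_text(sim_config.tree + "\n")
        outputs.append(tree_path)
        _record(manifest, "simulate", outputs, {"seed": seed})
        return alignments
    if "harvest" in config:
        genomes = [read_genbank(p) for p in config["harvest"]["genomes"]]
        results = screen_regions(genomes, builtin_catalogue())
        rows = []
        for res in results:
            row = {"region": res.spec.name, "kind": res.spec.kind, "partial": res.partial}
            if res.report:
                row.update(res.report.as_dict())
            rows.append(row)
        screen_path = outdir / "screen.tsv"
        pd.DataFrame(rows).to_csv(screen_path, sep="\t", index=False)
        _record(manifest, "harvest", [screen_path], {"n_genomes": len(genomes)})
        # scored regional alignments feed the downstream stages directly
        return [res.alignment for res in results if res.alignment is not None]
    alignments = [read_alignment(p) for p in config["input"]["loci"]]
    _record(manifest, "input", [], {"n_loci": len(alignments)})
    return alignments


def _record(manifest: dict, stage: str, outputs: list[Path], extra: dict | None = None) -> None:
    manifest["stages"].append(
        {
            "stage": stage,
            "outputs": {str(p): _sha256(Path(p)) for p in outputs},
            "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
            **(extra or {}),
        }
    )


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the configured stages in order; returns the run manifest."""
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "stages": [],
    }
    thresholds = (
        {int(k): int(v) for k, v in config["ssr_thresholds"].items()}
        if config.get("ssr_thresholds")
        else None
    )

    alignments = _load_loci(config, outdir, manifest)

    # stats
    reports = [report(aln, ssr_thresholds=thresholds) for aln in alignments]
    stats_path = outdir / "stats.tsv"
    pd.DataFrame([r.as_dict() for r in reports]).to_csv(stats_path, sep="\t", index=False)
    _record(manifest, "stats", [stats_path])

    # diagnose
    if "diagnose" in config:
        name = config["diagnose"]["partition"]
        partition = CladePartition(name, frozenset(config["clades"][name]))
        table = clade_pis_table(alignments, partition, mode="both")
        diag_path = outdir / "diagnostics.tsv"
        table.to_csv(diag_path, sep="\t", index=False)
        _record(manifest, "diagnose", [diag_path], {"partition": name})

    # rank
    rank_cfg = config.get("rank", {})
    ranking = rank_loci(
        reports,
        weight_subs=float(rank_cfg.get("weight_subs", 1.0)),
        weight_ssr=float(rank_cfg.get("weight_ssr", 1.0)),
    )
    rank_path = outdir / "ranking.tsv"
    ranking.table.to_csv(rank_path, sep="\t", index=False)
    _record(manifest, "rank", [rank_path])

    # concat (+ optional top-k selection or explicit pinned loci)
    concat_cfg = config.get("concat", {})
    selected = alignments
    if "loci" in concat_cfg:
        wanted = list(concat_cfg["loci"])
        by_name = {a.locus_name: a for a in alignments}
        missing = [w for w in wanted if w not in by_name]
        if missing:
            raise ConfigError(f"concat.loci names not present: {missing}")
        selected = [by_name[w] for w in wanted]
    elif "top" in concat_cfg:
        keep = set(ranking.top(int(concat_cfg["top"])))
        selected = [a for a in alignments if a.locus_name in keep]
    sm = concatenate(selected)
    export_paths = export_for_inference(sm, outdir / "supermatrix")
    _record(
        manifest,
        "concat",
        list(export_paths.values()),
        {"total_length": sm.total_length, "n_loci": len(selected)},
    )

    # tree
    if "tree" in config:
        tree_cfg = config["tree"]
        tree, support = bootstrap_support(
            sm,
            model=tree_cfg.get("model", "k2p"),
            n_reps=int(tree_cfg.get("bootstrap", 100)),
            seed=int(tree_cfg.get("seed", seed)),
            outgroup=tree_cfg.get("outgroup"),
        )
        tree_path = outdir / "nj_tree.nwk"
        write_newick(tree, tree_path)
        _record(
            manifest,
            "tree",
            [tree_path],
            {"n_reps": int(tree_cfg.get("bootstrap", 100))},
        )

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def load_config(path: str | Path) -> dict:
    config = yaml.safe_load(Path(path).read_text())
    if not isinstance(config, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    return config
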