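"""End-to-end orchestration: reconcile many gene families, then classify.

``run_reconcile`` draws R replicate reconciliations per family (seeded per
family so adding a family never changes the others' replicates), writes a
self-contained JSON archive plus a per-node support TSV, and records a
manifest tying every output to the inputs and configuration.
``run_classify`` turns the archives into per-family origin calls and a
group summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
import random
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

from . import __version__ as _version
from .aggregate import aggregate, support_report
from .origin import classify_origin, calls_tsv, markdown_report, summarize
from .reconcile import (
    CostScheme,
    DTLReconciler,
    PRESETS,
    Reconciliation,
    check_temporal_feasibility,
)
from .trees import default_leafmap, midpoint_root, read_trees, read_tsv_map, write_newick

__all__ = ["RunConfig", "family_seed", "run_reconcile", "run_classify"]

log = logging.getLogger("dtlrec")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline settings; ``cost_preset`` is NOTUNG, RANGER or a custom triple."""

    cost_preset: Union[str, CostScheme] = "RANGER"
    replicates: int = 100
    seed: int = 0
    focal_groups: tuple[str, ...] = ()
    feasibility_filter: bool = False  # drop temporally infeasible replicates
    root_method: str = "none"  # "none" | "midpoint" (applied to gene trees)

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if isinstance(self.cost_preset, str) and self.cost_preset.upper() not in PRESETS:
            raise ValueError(f"unknown cost preset {self.cost_preset!r}")
        if self.root_method not in ("none", "midpoint"):
            raise ValueError("root_method must be 'none' or 'midpoint'")

    @property
    def costs(self) -> CostScheme:
        if isinstance(self.cost_preset, CostScheme):
            return self.cost_preset
        return PRESETS[self.cost_preset.upper()]

    def to_json_dict(self) -> dict:
        c = self.costs
        name = self.cost_preset if isinstance(self.cost_preset, str) else "custom"
        return {
            "cost_preset": name,
            "costs": {"D": c.dup_cost, "T": c.transfer_cost, "L": c.loss_cost},
            "replicates": self.replicates,
            "seed": self.seed,
            "focal_groups": list(self.focal_groups),
            "feasibility_filter": self.feasibility_filter,
            "root_method": self.root_method,
        }


def family_seed(master_seed: int, family: str) -> int:
    """Stable per-family seed: master seed XOR CRC32 of the family name."""
    return (master_seed ^ zlib.crc32(family.encode("utf-8"))) % (2**31)


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True), encoding="utf-8")


def run_reconcile(
    species_file,
    gene_files: dict[str, Path] | Sequence[Path],
    leafmap_file,
    config: RunConfig,
    outdir,
) -> dict:
    """Reconcile every family; returns the manifest dict (also written).

    Per family the archive holds the gene/species Newicks, the leaf map,
    the optimal cost, the exact optimum count, R sampled replicates and
    the fraction that is temporally feasible.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    species = read_trees(species_file)[0]
    if isinstance(gene_files, dict):
        items = sorted(gene_files.items())
    else:
        items = sorted((Path(p).stem, Path(p)) for p in gene_files)
    file_map = read_tsv_map(leafmap_file) if leafmap_file else None

    manifest: dict = {
        "tool": "dtlrec",
        "version": _version,
        "config": config.to_json_dict(),
        "inputs": {
            "species": _digest(species_file),
            "leafmap": _digest(leafmap_file) if leafmap_file else None,
            "families": {name: _digest(path) for name, path in items},
        },
        "families": {},
    }
    for name, path in items:
        gene = read_trees(path)[0]
        if config.root_method == "midpoint":
            gene = midpoint_root(gene)
        leafmap = dict(file_map) if file_map is not None else default_leafmap(gene)
        missing = [l for l in gene.leaf_labels() if l not in leafmap]
        if missing:
            raise ValueError(f"family {name!r}: unmapped gene leaves {missing[:5]}")
        leafmap = {l: leafmap[l] for l in gene.leaf_labels()}
        engine = DTLReconciler(gene, species, leafmap, config.costs)
        rng = random.Random(family_seed(config.seed, name))
        reps = [engine.sample(rng) for _ in range(config.replicates)]
        feasible = [check_temporal_feasibility(r)[0] for r in reps]
        frac = sum(feasible) / len(feasible)
        kept = reps
        if config.feasibility_filter:
            kept = [r for r, ok in zip(reps, feasible) if ok] or reps
        archive = {
            "family": name,
            "gene_newick": write_newick(gene),
            "species_newick": write_newick(species),
            "leafmap": leafmap,
            "optimal_cost": engine.optimal_cost,
            "optimum_count": str(engine.count),
            "feasible_fraction": frac,
            "replicates": [r.to_json_dict() for r in kept],
        }
        _json_dump(archive, out / f"{name}.replicates.json")
        (out / f"{name}.support.tsv").write_text(
            support_report(aggregate(kept)), encoding="utf-8"
        )
        manifest["families"][name] = {
            "optimal_cost": engine.optimal_cost,
            "optimum_count": str(engine.count),
            "feasible_fraction": frac,
            "replicates_kept": len(kept),
        }
        log.info("family %s: cost=%.3f count=%s feasible=%.2f",
                 name, engine.optimal_cost, engine.count, frac)
    _json_dump(manifest, out / "manifest.json")
    return manifest


def _load_archive(path: Path):
    d = json.loads(Path(path).read_text(encoding="utf-8"))
    from .trees import parse_newick

    gene = parse_newick(d["gene_newick"])
    species = parse_newick(d["species_newick"])
    reps = [
        Reconciliation.from_json_dict(r, gene, species)
        for r in d["replicates"]
    ]
    # share one index pair across replicates
    if reps:
        gidx, sidx = reps[0].gidx, reps[0].sidx
        for r in reps[1:]:
            r.gidx, r.sidx = gidx, sidx
    return d["family"], gene, species, d["leafmap"], reps


def run_classify(run_dir, groups_file, focal_group: str, outdir=None) -> dict:
    """Per-family origin calls + group summary from a reconcile run.

    Writes ``calls.<group>.tsv``, ``summary.<group>.json`` and
    ``report.<group>.md`` next to the archives (or under ``outdir``).
    """
    run = Path(run_dir)
    out = Path(outdir) if outdir else run
    out.mkdir(parents=True, exist_ok=True)
    groups = read_tsv_map(groups_file)
    if focal_group not in set(groups.values()):
        raise ValueError(f"focal group {focal_group!r} absent from {groups_file}")
    calls = []
    for path in sorted(run.glob("*.replicates.json")):
        family, gene, species, leafmap, reps = _load_archive(path)
        call = classify_origin(gene, species, leafmap, groups, focal_group,
                               reps, family=family)
        calls.append(call)
        log.info("family %s: %s donor=%s support=%.2f",
                 family, call.verdict, call.donor_group or "-", call.support)
    summary = summarize(calls, focal_group)
    tag = focal_group.replace("/", "_")
    (out / f"calls.{tag}.tsv").write_text(calls_tsv(calls), encoding="utf-8")
    _json_dump(summary.to_json_dict(), out / f"summary.{tag}.json")
    (out / f"report.{tag}.md").write_text(markdown_report(summary), encoding="utf-8")
    return summary.to_json_dict()
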