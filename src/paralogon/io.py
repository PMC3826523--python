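"""Readers/writers for the interchange formats and the run-all driver.

All tables are UTF-8 tab-separated text with a header row; ``#`` lines
are comments.  Writers emit deterministic row order so outputs are
diffable; identical configurations (including the seed) give
byte-identical artifacts.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

from . import simulate as sim
from .ancestral import AncestralContent, LossPlacement, SubtypeLineage
from .assembly import AncestralUnit, ParalogonGroup, TranslocationCall
from .blocks import ChromosomeBlock, FamilyProfile
from .dating import DuplicationCall, FamilyVerdict
from .loci import (LocusTable, read_chromosome_lengths, read_locus_table,
                   write_locus_table)
from .model import ParalogonModel, ParalogonResults
from .trees import GeneTree, SpeciesTree

log = logging.getLogger(__name__)


def read_newick(path, kind: str = "gene") -> Union[SpeciesTree, GeneTree]:
    """Read a rooted Newick tree; ``kind`` selects the wrapper type."""
    if kind == "species":
        return SpeciesTree.read(path)
    if kind == "gene":
        return GeneTree.read(path)
    raise ValueError(f"kind must be 'species' or 'gene', got {kind!r}")


def read_gene_trees(directory) -> Dict[str, GeneTree]:
    """One Newick file per family: ``<family>.nwk`` (``/`` encoded as ``%2F``)."""
    trees: Dict[str, GeneTree] = {}
    for name in sorted(os.listdir(directory)):
        if not name.endswith(".nwk"):
            continue
        family = name[:-4].replace("%2F", "/")
        trees[family] = GeneTree.read(Path(directory) / name)
    return trees


def write_gene_trees(trees: Mapping[str, GeneTree], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for family in sorted(trees):
        safe = family.replace("/", "%2F")
        trees[family].write(directory / f"{safe}.nwk")


def _write_rows(path, header: Sequence[str], rows) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for row in rows:
            writer.writerow(row)


def write_blocks(blocks: Sequence[ChromosomeBlock], path) -> None:
    _write_rows(path,
                ["block_id", "species", "chromosome", "start", "end",
                 "anchors"],
                ([b.block_id, b.species, b.chromosome, b.start, b.end,
                  ",".join(b.anchor_ids)] for b in blocks))


def write_profile(profile: FamilyProfile, path) -> None:
    rows = []
    for family in profile.families():
        for block_id in sorted(profile[family]):
            rows.append([family, block_id, profile[family][block_id]])
    _write_rows(path, ["family", "block_id", "members"], rows)


def write_calls(calls: Mapping[str, Sequence[DuplicationCall]], path) -> None:
    rows = []
    for family in sorted(calls):
        for c in calls[family]:
            rows.append([family, c.node_id, c.species_node, c.window,
                         ",".join(c.candidate_windows)])
    _write_rows(path,
                ["family", "node_id", "species_node", "window", "candidates"],
                rows)


def write_verdicts(verdicts: Mapping[str, FamilyVerdict], path) -> None:
    rows = []
    for family in sorted(verdicts):
        v = verdicts[family]
        rows.append([family, ",".join(v.per_tree), v.aggregate,
                     str(v.undated_consistent).lower()])
    _write_rows(path, ["family", "per_tree", "aggregate",
                       "undated_consistent"], rows)


def write_groups(groups: Sequence[ParalogonGroup], path) -> None:
    rows = []
    for g in groups:
        support = ",".join(f"{a}~{b}:{w}" for a, b, w in g.support)
        rows.append([g.group_id, len(g.block_ids), ",".join(g.block_ids),
                     support])
    _write_rows(path, ["group_id", "n_blocks", "blocks", "support"], rows)


def write_units(units: Mapping[str, Sequence[AncestralUnit]], path) -> None:
    rows = []
    for group_id in sorted(units):
        for u in units[group_id]:
            rows.append([group_id, u.unit_id, ",".join(u.block_ids),
                         u.outgroup_chromosome or "",
                         str(u.merged).lower(), str(u.flagged).lower()])
    _write_rows(path, ["group_id", "unit_id", "blocks",
                       "outgroup_chromosome", "merged", "flagged"], rows)


def write_translocations(calls: Sequence[TranslocationCall], path) -> None:
    _write_rows(path,
                ["species", "chromosome", "loci", "source_unit",
                 "dominant_unit", "timing"],
                ([c.species, c.chromosome, ",".join(c.locus_ids),
                  c.source_unit, c.dominant_unit, c.timing] for c in calls))


def write_lineages(lineages: Sequence[SubtypeLineage], path) -> None:
    _write_rows(path,
                ["lineage_id", "family", "subtype", "origin_node",
                 "origin_window", "members", "species", "flagged_members"],
                ([l.lineage_id, l.family, l.subtype, l.origin_node,
                  l.origin_window, ",".join(l.members),
                  ",".join(l.species), ",".join(l.flagged_members)]
                 for l in sorted(lineages, key=lambda l: l.lineage_id)))


def write_content(content: AncestralContent, path) -> None:
    rows = []
    for node in content.nodes():
        for (family, subtype), n in sorted(content.counts[node].items()):
            rows.append([node, family, subtype, n])
    _write_rows(path, ["node", "family", "subtype", "count"], rows)


def write_losses(losses: Sequence[LossPlacement], path) -> None:
    _write_rows(path,
                ["lineage_id", "family", "branch", "n_equally_parsimonious",
                 "alternatives", "uncertain"],
                ([l.lineage_id, l.family, l.branch, l.n_equally_parsimonious,
                  ",".join(l.alternatives), str(l.uncertain).lower()]
                 for l in losses))


def write_synteny_matrix(table: LocusTable, families: Sequence[str],
                         path) -> None:
    """Families x species matrix of chromosome:count placements."""
    species = table.species
    rows = []
    for family in sorted(families):
        row = [family]
        for sp in species:
            tally: Dict[str, int] = {}
            for locus in table.filter(species=sp, family=family):
                tally[locus.chromosome] = tally.get(locus.chromosome, 0) + 1
            row.append(";".join(f"{c}:{n}" for c, n in sorted(tally.items())))
        rows.append(row)
    _write_rows(path, ["family"] + species, rows)


# ---------------------------------------------------------------------------
# Run configuration and the end-to-end driver
# ---------------------------------------------------------------------------

_INT_KEYS = {"seed", "min_blocks", "min_support", "min_run", "nni_noise",
             "max_translocations", "max_family_members"}
_FLOAT_KEYS = {"window_mb", "collapse_below", "loss_rate", "local_dup_rate",
               "translocation_rate"}


@dataclass
class RunConfig:
    """Flat key=value run configuration; CLI flags override file values."""

    scenario: str = "opsin"          # opsin | random | load
    seed: int = 1
    out_dir: str = "paralogon-out"
    loci: Optional[str] = None
    chromosome_lengths: Optional[str] = None
    species_tree: Optional[str] = None
    gene_trees: Optional[str] = None
    focal_species: Optional[str] = None
    fission_outgroup: Optional[str] = None
    rearrangement_outgroup: Optional[str] = None
    anchor_families: Optional[List[str]] = None
    window_mb: float = 5.0
    min_blocks: int = 2
    min_support: int = 2
    min_run: int = 2
    max_family_members: int = 200
    collapse_below: Optional[float] = None
    rhol_origin: str = "3R"
    loss_rate: float = 0.0
    local_dup_rate: float = 0.0
    translocation_rate: float = 0.0
    max_translocations: Optional[int] = None
    nni_noise: int = 0

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        values: Dict[str, object] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}: bad config line {line!r}")
                key, raw = (part.strip() for part in line.split("=", 1))
                if key not in cls.__dataclass_fields__:
                    raise ValueError(f"{path}: unknown config key {key!r}")
                if key == "anchor_families":
                    values[key] = [f.strip() for f in raw.split(",")]
                elif key in _INT_KEYS:
                    values[key] = int(raw)
                elif key in _FLOAT_KEYS:
                    values[key] = float(raw)
                else:
                    values[key] = raw
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)  # type: ignore[arg-type]

    def validate(self) -> None:
        if self.scenario not in ("opsin", "random", "load"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "load":
            for key in ("loci", "species_tree", "gene_trees"):
                path = getattr(self, key)
                if path is None or not os.path.exists(path):
                    raise FileNotFoundError(
                        f"config {key!r}: missing path {path!r}")


def run_all(config: RunConfig) -> ParalogonResults:
    """simulate-or-load -> blocks -> select -> date -> paralogon -> reconstruct.

    Every stage's inputs and outputs are written under ``config.out_dir``;
    a failing stage aborts with its name while earlier artifacts are kept.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run-all: scenario=%s seed=%d out=%s",
             config.scenario, config.seed, out)

    stage = "input"
    try:
        if config.scenario == "opsin":
            dataset = sim.simulate_opsin_paralogon(config.rhol_origin)
        elif config.scenario == "random":
            dataset = sim.simulate_random(sim.SimConfig(
                seed=config.seed,
                loss_rate=config.loss_rate,
                local_dup_rate=config.local_dup_rate,
                translocation_rate=config.translocation_rate,
                max_translocations=config.max_translocations,
                nni_noise=config.nni_noise,
            ))
        else:
            dataset = None

        if dataset is not None:
            table = dataset.locus_table
            gene_trees: Mapping[str, GeneTree] = dataset.gene_trees
            stree = dataset.species_tree
            write_locus_table(table, out / "loci.tsv")
            write_gene_trees(gene_trees, out / "gene_trees")
            stree.write(out / "species_tree.nwk")
            sim.write_event_log(dataset.event_log, out / "events.tsv",
                                out / "ancestral_genome.tsv")
            anchor_families = (config.anchor_families
                               or list(sim.MAIN_FAMILIES))
            focal = config.focal_species or "human"
            fission_out = config.fission_outgroup or "chicken"
            rearr_out = config.rearrangement_outgroup or "gar"
        else:
            table = read_locus_table(config.loci, config.chromosome_lengths)
            stree = SpeciesTree.read(config.species_tree)
            gene_trees = read_gene_trees(config.gene_trees)
            anchor_families = config.anchor_families
            focal = config.focal_species
            fission_out = config.fission_outgroup
            rearr_out = config.rearrangement_outgroup

        stage = "model"
        model = ParalogonModel(
            table, gene_trees, stree,
            anchor_families=anchor_families,
            focal_species=focal,
            fission_outgroup=fission_out,
            rearrangement_outgroup=rearr_out,
            window=int(config.window_mb * 1_000_000),
            min_blocks=config.min_blocks,
            min_support=config.min_support,
            min_run=config.min_run,
            max_family_members=config.max_family_members,
            collapse_below=config.collapse_below,
        )
        stage = "fit"
        results = model.fit()

        stage = "report"
        write_blocks(results.blocks, out / "blocks.tsv")
        for family, profile in results.profiles.items():
            safe = family.replace("/", "%2F")
            write_profile(profile, out / f"profile_{safe}.tsv")
        _write_rows(out / "selected_families.tsv", ["family"],
                    ([f] for f in results.selected_families))
        write_calls(results.calls, out / "calls.tsv")
        write_verdicts(results.verdicts, out / "verdicts.tsv")
        write_groups(results.groups, out / "groups.tsv")
        write_units(results.units, out / "units.tsv")
        write_translocations(results.translocations,
                             out / "translocations.tsv")
        write_lineages(results.lineages, out / "lineages.tsv")
        write_content(results.content, out / "content.tsv")
        write_losses(results.losses, out / "losses.tsv")
        write_synteny_matrix(
            table,
            sorted(set(results.selected_families)
                   | set(model.anchor_families)),
            out / "synteny_matrix.tsv")
        with open(out / "summary.txt", "w") as fh:
            fh.write(results.summary() + "\n")
        with open(out / "run_log.txt", "w") as fh:
            fh.write(f"scenario={config.scenario}\nseed={config.seed}\n")
            for key in ("window_mb", "min_blocks", "min_support", "min_run",
                        "loss_rate", "local_dup_rate", "translocation_rate",
                        "nni_noise", "rhol_origin"):
                fh.write(f"{key}={getattr(config, key)}\n")
        return results
    except Exception as exc:
        raise RuntimeError(f"run-all failed in stage {stage!r}: {exc}") from exc
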