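"""Genome-evolution simulator producing locus tables, congruent gene trees
and a ground-truth event log.

The simulator replays an ordered event log over a species tree.  Genomes
are ordered gene lists per chromosome; a whole-genome duplication doubles
every chromosome preserving gene order, speciation copies the genome into
both daughter lineages, and losses, local (tandem) duplications,
retrotranspositions (intron-less dispersed copies), translocations of
contiguous runs, and chromosome fissions edit it in place.  A full
genealogy is tracked so that the true gene tree of every family — with
each internal node labeled by the event that generated it — falls out of
the replay, ready for reconciliation-based dating to be tested against.

``script_opsin_paralogon`` encodes the inferred history of the visual-opsin
paralogon: a single ancestral chromosome carrying linked opsin, GNAT,
GNAI, OT/VP-R and CACNA1-L genes (plus two neighbor families and an
unlinked decoy family), two pre-2R local duplications (SWS/LWS and
V1-OTR/V2), quadruplication in 2R, the stem losses leaving 5 opsins /
3 GNAT / 3 GNAI / 6 OT/VP-R / 4 CACNA1-L, the rhodopsin
retrotransposition on the ray-finned stem, 3R with its selective
retentions, post-3R tandem expansions (RH2, OTR, V2A), two post-3R
translocations between paralogous teleost blocks, and the chromosome
fission in the human lineage that split one paralogon block in two.

Coordinates are synthetic: genes are 10 kb long, spaced 2 Mb apart,
except tandem copies which sit 30 kb from their neighbor, so that local
duplicates fall well inside a 1 Mb clustering gap and distinct genes
well outside it.
"""

from __future__ import annotations

import csv
import itertools
import logging
import random
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import dendropy

from .loci import GeneLocus, LocusTable
from .trees import GeneTree, SpeciesTree, window_of_label

log = logging.getLogger(__name__)

GENE_LENGTH = 10_000
SPACING = 2_000_000
TANDEM_GAP = 30_000
OFFSET = 1_000_000

EVENT_TYPES = {
    "wgd", "local_duplication", "retrotransposition", "loss",
    "translocation", "fission",
}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class EvoEvent:
    event_type: str
    branch: str                 # child-end node name of the species-tree branch
    order_index: int
    params: Tuple[Tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")

    def param(self, key: str, default=None) -> Optional[str]:
        for k, v in self.params:
            if k == key:
                return v
        return default

    def describe(self) -> str:
        kv = ";".join(f"{k}={v}" for k, v in self.params)
        return f"{self.event_type}@{self.branch}#{self.order_index}[{kv}]"


def _ev(event_type: str, branch: str, order_index: int, **params) -> EvoEvent:
    return EvoEvent(
        event_type, branch, order_index,
        tuple((k, str(v)) for k, v in params.items()),
    )


@dataclass(frozen=True)
class AncestralLocus:
    lineage_id: str
    family: str
    tandem_prev: bool = False


@dataclass
class EventLog:
    """Ordered event list plus the ancestral chromosome content."""

    ancestral_genome: Dict[str, List[AncestralLocus]]
    events: List[EvoEvent] = field(default_factory=list)
    subtype_names: Dict[str, str] = field(default_factory=dict)

    def events_on(self, branch: str) -> List[EvoEvent]:
        evs = [e for e in self.events if e.branch == branch]
        evs.sort(key=lambda e: e.order_index)
        seen = set()
        for e in evs:
            if e.order_index in seen:
                raise SimulationError(
                    f"duplicate order_index on branch {branch!r}: {e.describe()}"
                )
            seen.add(e.order_index)
        return evs


# ---------------------------------------------------------------------------
# Replay engine
# ---------------------------------------------------------------------------


class _GNode:
    __slots__ = ("kind", "at", "event_key", "children", "tip")

    def __init__(self) -> None:
        self.kind: Optional[str] = None
        self.at: Optional[str] = None
        self.event_key: Optional[str] = None
        self.children: List["_GNode"] = []
        self.tip: Optional[Tuple[str, str]] = None


class _Copy:
    __slots__ = ("lineage_id", "family", "has_introns", "tandem_prev", "unit",
                 "gnode")

    def __init__(self, lineage_id, family, has_introns, tandem_prev, unit,
                 gnode) -> None:
        self.lineage_id = lineage_id
        self.family = family
        self.has_introns = has_introns
        self.tandem_prev = tandem_prev
        self.unit = unit
        self.gnode = gnode


Genome = Dict[str, List[_Copy]]


@dataclass
class SimulatedDataset:
    """Extant loci, true gene trees and ground truth from one replay."""

    species_tree: SpeciesTree
    locus_table: LocusTable
    gene_trees: Dict[str, GeneTree]
    event_log: EventLog
    duplication_truth: Dict[str, Dict[str, str]]   # family -> node_id -> event key
    node_kinds: Dict[str, Dict[str, str]]          # family -> node_id -> kind
    locus_lineage: Dict[str, str]                  # locus_id -> lineage_id
    locus_unit: Dict[str, str]                     # locus_id -> ancestral unit
    snapshots: Dict[str, List[Tuple[str, str, str, bool, bool]]]
    perturbed_trees: Optional[Dict[str, GeneTree]] = None

    def snapshot_counts(self, name: str) -> Dict[str, int]:
        """Family -> locus count in the named ancestral genome snapshot."""
        counts: Dict[str, int] = {}
        for _chrom, _lid, family, _tp, _hi in self.snapshots[name]:
            counts[family] = counts.get(family, 0) + 1
        return counts

    def snapshot_table(self, name: str) -> LocusTable:
        """The named snapshot as a LocusTable (species = snapshot name)."""
        table = LocusTable()
        pos: Dict[str, int] = {}
        for chrom, lid, family, tandem_prev, has_introns in self.snapshots[name]:
            start = pos.get(chrom)
            start = (OFFSET if start is None
                     else start + GENE_LENGTH + (TANDEM_GAP if tandem_prev
                                                 else SPACING))
            pos[chrom] = start
            table.add(GeneLocus(
                locus_id=f"{name}_{lid}", species=name, family=family,
                subtype=self.event_log.subtype_names.get(lid, "unassigned"),
                chromosome=chrom, start=start, end=start + GENE_LENGTH,
                strand="+", has_introns=has_introns,
            ))
        return table


class _Engine:
    def __init__(self, stree: SpeciesTree, log_: EventLog) -> None:
        self.stree = stree
        self.log = log_
        self.snapshots: Dict[str, List[Tuple[str, str, str, bool, bool]]] = {}
        self.family_roots: Dict[str, _GNode] = {}
        self.loci: List[GeneLocus] = []
        self.lengths: Dict[Tuple[str, str], int] = {}
        self.locus_lineage: Dict[str, str] = {}
        self.locus_unit: Dict[str, str] = {}
        windows = stree.windows
        self.unit_window = (
            min(windows, key=lambda w: stree.depth(windows[w])) if windows
            else None
        )
        self.root_genome: Genome = {}
        for chrom, spec in log_.ancestral_genome.items():
            copies = []
            for anc in spec:
                gnode = _GNode()
                if anc.family in self.family_roots:
                    raise SimulationError(
                        f"family {anc.family!r} has two ancestral loci; "
                        "one ancestral locus per family is required"
                    )
                self.family_roots[anc.family] = gnode
                copies.append(_Copy(anc.lineage_id, anc.family, True,
                                    anc.tandem_prev, chrom, gnode))
            self.root_genome[chrom] = copies

    # -- event application -------------------------------------------------

    def _find(self, genome: Genome, lineage_id: str, event: EvoEvent):
        for chrom, copies in genome.items():
            for i, copy in enumerate(copies):
                if copy.lineage_id == lineage_id:
                    return chrom, i
        raise SimulationError(
            f"event {event.describe()} targets lineage {lineage_id!r} "
            "which is not alive in this genome"
        )

    def _snapshot(self, genome: Genome, name: str) -> None:
        self.snapshots[name] = [
            (chrom, c.lineage_id, c.family, c.tandem_prev, c.has_introns)
            for chrom, copies in genome.items()
            for c in copies
        ]

    def apply_event(self, genome: Genome, event: EvoEvent) -> None:
        kind = event.event_type
        if kind == "wgd":
            label = event.param("label")
            placed = self.stree.placements.get(label)
            if placed is None or self.stree.name_of(placed) != event.branch:
                raise SimulationError(
                    f"event {event.describe()}: WGD label {label!r} is not "
                    f"placed on this branch of the species tree"
                )
            window = window_of_label(label)
            key = f"pre-{label}"
            self._snapshot(genome, key)
            self.snapshots.setdefault(f"pre-{window}", self.snapshots[key])
            new_chroms: List[Tuple[str, List[_Copy]]] = []
            for chrom in list(genome):
                new_chrom = f"{chrom}.{label}"
                fresh: List[_Copy] = []
                for i, copy in enumerate(genome[chrom]):
                    g_a, g_b = _GNode(), _GNode()
                    copy.gnode.kind = "duplication"
                    copy.gnode.at = event.branch
                    copy.gnode.event_key = f"wgd:{label}"
                    copy.gnode.children = [g_a, g_b]
                    dup_id = f"{copy.lineage_id}.{label}"
                    unit_a, unit_b = copy.unit, copy.unit
                    if window == self.unit_window:
                        unit_a, unit_b = chrom, new_chrom
                    genome[chrom][i] = _Copy(
                        copy.lineage_id, copy.family, copy.has_introns,
                        copy.tandem_prev, unit_a, g_a,
                    )
                    fresh.append(_Copy(
                        dup_id, copy.family, copy.has_introns,
                        copy.tandem_prev, unit_b, g_b,
                    ))
                new_chroms.append((new_chrom, fresh))
            for name, copies in new_chroms:
                genome[name] = copies
        elif kind == "loss":
            chrom, i = self._find(genome, event.param("lineage"), event)
            copy = genome[chrom].pop(i)
            copy.gnode.kind = "lost"
            if i < len(genome[chrom]):
                genome[chrom][i].tandem_prev = (
                    genome[chrom][i].tandem_prev and copy.tandem_prev
                )
        elif kind in ("local_duplication", "retrotransposition"):
            lineage = event.param("lineage")
            new_id = event.param("new_id") or f"{lineage}.X{event.order_index}"
            chrom, i = self._find(genome, lineage, event)
            parent = genome[chrom][i]
            g_a, g_b = _GNode(), _GNode()
            parent.gnode.kind = "duplication"
            parent.gnode.at = event.branch
            parent.gnode.event_key = f"{kind}:{event.branch}:{event.order_index}"
            parent.gnode.children = [g_a, g_b]
            kept = _Copy(parent.lineage_id, parent.family, parent.has_introns,
                         parent.tandem_prev, parent.unit, g_a)
            genome[chrom][i] = kept
            if kind == "local_duplication":
                fresh = _Copy(new_id, parent.family, parent.has_introns,
                              True, parent.unit, g_b)
                genome[chrom].insert(i + 1, fresh)
            else:
                dest = event.param("dest_chromosome") or chrom
                fresh = _Copy(new_id, parent.family, False, False,
                              parent.unit, g_b)
                genome.setdefault(dest, []).append(fresh)
        elif kind == "translocation":
            chrom = event.param("chromosome")
            dest = event.param("dest_chromosome")
            start = int(event.param("start_index"))
            length = int(event.param("length"))
            dest_index = int(event.param("dest_index"))
            if chrom not in genome or dest not in genome or chrom == dest:
                raise SimulationError(
                    f"event {event.describe()}: bad chromosomes"
                )
            src = genome[chrom]
            if not (0 <= start and start + length <= len(src) and length >= 1):
                raise SimulationError(
                    f"event {event.describe()}: run outside chromosome"
                )
            moved = src[start:start + length]
            del src[start:start + length]
            if start < len(src):
                src[start].tandem_prev = False
            moved[0].tandem_prev = False
            tgt = genome[dest]
            if not (0 <= dest_index <= len(tgt)):
                raise SimulationError(
                    f"event {event.describe()}: bad destination index"
                )
            tgt[dest_index:dest_index] = moved
            after = dest_index + length
            if after < len(tgt):
                tgt[after].tandem_prev = False
        elif kind == "fission":
            chrom = event.param("chromosome")
            bp = int(event.param("breakpoint_index"))
            if chrom not in genome or not (1 <= bp < len(genome[chrom])):
                raise SimulationError(
                    f"event {event.describe()}: bad fission breakpoint"
                )
            name_p = event.param("name_p") or f"{chrom}-p"
            name_q = event.param("name_q") or f"{chrom}-q"
            copies = genome.pop(chrom)
            left, right = copies[:bp], copies[bp:]
            right[0].tandem_prev = False
            genome[name_p] = left
            genome[name_q] = right
        else:  # pragma: no cover - guarded by EvoEvent validation
            raise SimulationError(f"unhandled event type {kind!r}")

    # -- traversal ---------------------------------------------------------

    def run(
        self,
        branch_events: Callable[[str, Genome], Iterable[EvoEvent]],
    ) -> None:
        self._recurse(self.stree.tree.seed_node, self.root_genome,
                      branch_events)

    def _recurse(self, node, genome: Genome, branch_events) -> None:
        name = self.stree.name_of(node)
        self._snapshot(genome, name)
        if node.is_leaf():
            self._finalize_tip(name, genome)
            return
        for copy_list in genome.values():
            for copy in copy_list:
                copy.gnode.kind = "speciation"
                copy.gnode.at = name
        for child in node.child_nodes():
            child_name = self.stree.name_of(child)
            child_genome: Genome = {}
            for chrom, copies in genome.items():
                fresh = []
                for copy in copies:
                    g = _GNode()
                    copy.gnode.children.append(g)
                    fresh.append(_Copy(copy.lineage_id, copy.family,
                                       copy.has_introns, copy.tandem_prev,
                                       copy.unit, g))
                child_genome[chrom] = fresh
            for event in branch_events(child_name, child_genome):
                self.apply_event(child_genome, event)
            self._recurse(child, child_genome, branch_events)

    def _finalize_tip(self, species: str, genome: Genome) -> None:
        for chrom, copies in genome.items():
            start = None
            for copy in copies:
                start = (OFFSET if start is None
                         else start + GENE_LENGTH
                         + (TANDEM_GAP if copy.tandem_prev else SPACING))
                locus_id = f"{species}_{copy.lineage_id}"
                copy.gnode.kind = "leaf"
                copy.gnode.tip = (species, locus_id)
                self.loci.append(GeneLocus(
                    locus_id=locus_id, species=species, family=copy.family,
                    subtype=self.log.subtype_names.get(
                        copy.lineage_id, "unassigned"),
                    chromosome=chrom, start=start, end=start + GENE_LENGTH,
                    strand="+", has_introns=copy.has_introns,
                ))
                self.locus_lineage[locus_id] = copy.lineage_id
                self.locus_unit[locus_id] = copy.unit
            if start is not None:
                self.lengths[(species, chrom)] = start + GENE_LENGTH + OFFSET

    # -- gene-tree extraction ----------------------------------------------

    def build_dataset(self) -> SimulatedDataset:
        table = LocusTable(chromosome_lengths=self.lengths)
        for locus in self.loci:
            table.add(locus)
        gene_trees: Dict[str, GeneTree] = {}
        dup_truth: Dict[str, Dict[str, str]] = {}
        kinds: Dict[str, Dict[str, str]] = {}
        for family in sorted(self.family_roots):
            meta: Dict[int, Tuple[str, Optional[str]]] = {}
            pruned = self._prune(self.family_roots[family], meta)
            if pruned is None:
                log.info("family %r left no extant loci", family)
                continue
            taxa = dendropy.TaxonNamespace()
            tree = dendropy.Tree(taxon_namespace=taxa)
            tree.seed_node = self._to_dendropy(pruned, taxa, meta)
            tree.is_rooted = True
            gtree = GeneTree(tree)
            gene_trees[family] = gtree
            dup_truth[family] = {}
            kinds[family] = {}
            for node in tree.preorder_node_iter():
                entry = meta.get(id(node))
                if entry is None:
                    continue
                kind, event_key = entry
                nid = gtree.id_of(node)
                kinds[family][nid] = kind
                if kind == "duplication":
                    dup_truth[family][nid] = event_key  # type: ignore[index]
        return SimulatedDataset(
            species_tree=self.stree,
            locus_table=table,
            gene_trees=gene_trees,
            event_log=self.log,
            duplication_truth=dup_truth,
            node_kinds=kinds,
            locus_lineage=self.locus_lineage,
            locus_unit=self.locus_unit,
            snapshots=self.snapshots,
        )

    def _prune(self, gnode: _GNode, sink) -> Optional[_GNode]:
        if gnode.kind == "leaf":
            return gnode
        if gnode.kind == "lost" or gnode.kind is None:
            return None
        kept = [p for c in gnode.children if (p := self._prune(c, sink))]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        out = _GNode()
        out.kind = gnode.kind
        out.at = gnode.at
        out.event_key = gnode.event_key
        out.children = kept
        return out

    def _to_dendropy(self, gnode: _GNode, taxa, meta) -> dendropy.Node:
        node = dendropy.Node()
        if gnode.kind == "leaf":
            species, locus_id = gnode.tip  # type: ignore[misc]
            node.taxon = taxa.require_taxon(label=f"{species}|{locus_id}")
        else:
            meta[id(node)] = (gnode.kind, gnode.event_key or gnode.at)
            for child in gnode.children:
                node.add_child(self._to_dendropy(child, taxa, meta))
        return node


def replay(log_: EventLog, stree: SpeciesTree) -> SimulatedDataset:
    """Deterministically replay an event log over the species tree."""
    engine = _Engine(stree, log_)
    engine.run(lambda branch, genome: log_.events_on(branch))
    return engine.build_dataset()


# ---------------------------------------------------------------------------
# The scripted visual-opsin paralogon scenario
# ---------------------------------------------------------------------------

OPSIN_SCENARIO_NEWICK = (
    "(tunicate,((coelacanth,(chicken,human)Amniota)Sarcopterygii,"
    "(gar,(zebrafish,stickleback)Teleostei[wgd=3R])Actinopterygii)"
    "Gnathostomata[wgd=2R-1][wgd=2R-2])Olfactores;"
)

# post-2R paralogon units (chromosome names produced by the replay)
UNIT_A = "anc1"                 # SWS1 / GNAT3-GNAI1 / V1A-V2C / CACNA1C
UNIT_B = "anc1.2R-1"            # RH1  / GNAT1-GNAI2 / OTR-V2B / CACNA1D
UNIT_C = "anc1.2R-2"            # RH2  / GNAT2-GNAI3 / V1B     / CACNA1S
UNIT_D = "anc1.2R-1.2R-2"       # SWS2-LWS / V2A / CACNA1F
OPSIN_SCENARIO_UNITS = (UNIT_A, UNIT_B, UNIT_C, UNIT_D)

MAIN_FAMILIES = ("opsin", "GNAT", "GNAI", "OT/VP-R", "CACNA1-L")
NEIGHBOR_FAMILIES = ("ATP2B", "CAMK1")
DECOY_FAMILY = "TLR"

_SUBTYPES = {
    "ops": "SWS1", "ops.2R-1": "RH1", "ops.2R-2": "RH2",
    "ops.2R-1.2R-2": "SWS2", "ops.Lgar": "SWS1",
    "rh1r": "RH1", "rh1r.3R": "RH1", "rh1r.Lzf": "RH1",
    "rh2b": "RH2", "rh2c": "RH2", "rh2d": "RH2",
    "lws.2R-1.2R-2": "LWS",
    "gnat": "GNAT3", "gnat.2R-1": "GNAT1", "gnat.2R-2": "GNAT2",
    "gnai": "GNAI1", "gnai.3R": "GNAI1",
    "gnai.2R-1": "GNAI2", "gnai.2R-1.3R": "GNAI2", "gnai.2R-2": "GNAI3",
    "ovr": "V1A", "ovr.3R": "V1A", "ovr.2R-1": "OTR", "otr2": "OTR",
    "ovr.2R-2": "V1B",
    "v2": "V2C", "v2.2R-1": "V2B", "v2.2R-1.2R-2": "V2A", "v2a2": "V2A",
    "cacna": "CACNA1C", "cacna.3R": "CACNA1C",
    "cacna.2R-1": "CACNA1D", "cacna.2R-1.3R": "CACNA1D",
    "cacna.2R-2": "CACNA1S",
    "cacna.2R-1.2R-2": "CACNA1F", "cacna.2R-1.2R-2.3R": "CACNA1F",
}


def opsin_species_tree() -> SpeciesTree:
    return SpeciesTree.from_newick(OPSIN_SCENARIO_NEWICK)


def opsin_ancestral_genome() -> Dict[str, List[AncestralLocus]]:
    return {
        "anc1": [
            AncestralLocus("ops", "opsin"),
            AncestralLocus("gnat", "GNAT"),
            AncestralLocus("gnai", "GNAI", tandem_prev=True),
            AncestralLocus("ovr", "OT/VP-R"),
            AncestralLocus("cacna", "CACNA1-L"),
            AncestralLocus("atp", "ATP2B"),
            AncestralLocus("camk", "CAMK1"),
        ],
        "anc2": [AncestralLocus("tlr", DECOY_FAMILY)],
    }


# lineages alive when 3R strikes (used to script the post-3R losses)
_AT_3R = (
    # unit A (lws lost post-2R)
    ["ops", "gnat", "gnai", "ovr", "v2", "cacna", "atp", "camk"]
    # unit B (+ the retrotransposed rhodopsin)
    + [f"{x}.2R-1" for x in ("ops", "gnat", "gnai", "ovr", "v2", "cacna",
                             "atp", "camk")] + ["rh1r"]
    # unit C (V1B lost on the ray-finned stem, V2 copy lost post-2R)
    + [f"{x}.2R-2" for x in ("ops", "gnat", "gnai", "cacna", "atp", "camk")]
    # unit D (GNAT/GNAI pair and the V1-side copy lost post-2R)
    + [f"{x}.2R-1.2R-2" for x in ("ops", "lws", "v2", "cacna", "atp", "camk")]
    # decoy chromosome quartet
    + ["tlr", "tlr.2R-1", "tlr.2R-2", "tlr.2R-1.2R-2"]
)

_3R_RETAINED = (
    "gnai.3R",                 # GNAI1 ohnolog pair
    "gnai.2R-1.3R",            # GNAI2 ohnolog pair
    "ovr.3R",                  # V1Aa / V1Ab
    "cacna.2R-1.3R",           # CACNA1D pair
    "cacna.3R",                # CACNA1C pair
    "cacna.2R-1.2R-2.3R",      # CACNA1F pair
    "rh1r.3R",                 # rho / rhol
)


def script_opsin_paralogon(rhol_origin: str = "3R") -> EventLog:
    """Deterministic event list for the visual-opsin paralogon history.

    ``rhol_origin`` selects the origin of the second intron-less teleost
    rhodopsin: ``"3R"`` (retained 3R ohnolog of the retrogene, the
    scenario considered most likely) or ``"local"`` (a lineage-specific
    duplication in the zebrafish lineage, the alternative that cannot be
    excluded without more positional data).
    """
    if rhol_origin not in ("3R", "local"):
        raise ValueError("rhol_origin must be '3R' or 'local'")
    events: List[EvoEvent] = []
    order = itertools.count()

    def on(branch: str, etype: str, **params) -> None:
        events.append(_ev(etype, branch, next(order), **params))

    # vertebrate stem: pre-2R local duplications, then the two doublings,
    # then the stem losses that leave the six-family ancestral repertoire
    on("Gnathostomata", "local_duplication", lineage="ops", new_id="lws")
    on("Gnathostomata", "local_duplication", lineage="ovr", new_id="v2")
    on("Gnathostomata", "wgd", label="2R-1")
    on("Gnathostomata", "wgd", label="2R-2")
    for lost in ("lws", "lws.2R-1", "lws.2R-2",          # 3 of 4 LWS copies
                 "gnat.2R-1.2R-2", "gnai.2R-1.2R-2",     # one GNAT/GNAI pair
                 "ovr.2R-1.2R-2", "v2.2R-2"):            # 8 -> 6 OT/VP-Rs
        on("Gnathostomata", "loss", lineage=lost)

    # ray-finned stem: V1B loss; rhodopsin retrotransposition before the
    # gar/teleost split (intron-less copy at the far end of its chromosome)
    on("Actinopterygii", "loss", lineage="ovr.2R-2")
    on("Actinopterygii", "retrotransposition", lineage="ops.2R-1",
       new_id="rh1r")

    # gar lineage: the tandem SWS1 pair
    on("gar", "local_duplication", lineage="ops", new_id="ops.Lgar")

    # teleost stem: 3R, selective retention, post-3R tandem duplications
    # and two translocations between paralogous blocks
    on("Teleostei", "wgd", label="3R")
    retained = set(_3R_RETAINED)
    if rhol_origin == "local":
        retained.discard("rh1r.3R")
    for lineage in _AT_3R:
        dup = f"{lineage}.3R"
        if dup not in retained:
            on("Teleostei", "loss", lineage=dup)
    on("Teleostei", "translocation", chromosome=UNIT_C, start_index=1,
       length=2, dest_chromosome=UNIT_B, dest_index=1)
    on("Teleostei", "translocation", chromosome=UNIT_D, start_index=4,
       length=2, dest_chromosome=UNIT_C, dest_index=0)
    on("Teleostei", "local_duplication", lineage="ovr.2R-1", new_id="otr2")
    on("Teleostei", "local_duplication", lineage="v2.2R-1.2R-2",
       new_id="v2a2")

    # zebrafish lineage: RH2 tandem quadruplication
    on("zebrafish", "local_duplication", lineage="ops.2R-2", new_id="rh2b")
    on("zebrafish", "local_duplication", lineage="rh2b", new_id="rh2c")
    on("zebrafish", "local_duplication", lineage="rh2c", new_id="rh2d")
    if rhol_origin == "local":
        on("zebrafish", "local_duplication", lineage="rh1r",
           new_id="rh1r.Lzf")

    # stickleback lineage lacks the second intron-less rhodopsin
    if rhol_origin == "3R":
        on("stickleback", "loss", lineage="rh1r.3R")

    # human lineage: fission of the SWS1/V1A block into two chromosomes
    on("human", "fission", chromosome=UNIT_A, breakpoint_index=3,
       name_p="anc1-p", name_q="anc1-q")

    return EventLog(
        ancestral_genome=opsin_ancestral_genome(),
        events=events,
        subtype_names=dict(_SUBTYPES),
    )


def simulate_opsin_paralogon(rhol_origin: str = "3R") -> SimulatedDataset:
    return replay(script_opsin_paralogon(rhol_origin), opsin_species_tree())


# ---------------------------------------------------------------------------
# Stochastic mode
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Conditions for a stochastic genome-evolution simulation.

    Rates are per-branch probabilities: loss and local duplication per
    locus present at the start of a branch (losses are drawn before the
    branch's WGDs, so a locus lost on a WGD branch loses both prospective
    copies), translocation per branch.  Translocations are restricted by
    default to branches at or below the most recent WGD, emulating the
    observation that the large rearrangements of these regions are
    teleost-specific.  ``seed`` is mandatory.
    """

    seed: int
    species_tree: SpeciesTree = field(default_factory=opsin_species_tree)
    ancestral_genome: Dict[str, List[AncestralLocus]] = field(
        default_factory=opsin_ancestral_genome)
    subtype_names: Dict[str, str] = field(default_factory=dict)
    loss_rate: float = 0.0
    local_dup_rate: float = 0.0
    translocation_rate: float = 0.0
    max_translocations: Optional[int] = None
    translocation_branches: Optional[Sequence[str]] = None
    nni_noise: int = 0

    def __post_init__(self) -> None:
        for name in ("loss_rate", "local_dup_rate", "translocation_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.translocation_branches is None:
            stree = self.species_tree
            if stree.windows:
                last = max(stree.windows.values(), key=stree.depth)
                self.translocation_branches = sorted(
                    stree.name_of(n)
                    for n in stree.tree.preorder_node_iter()
                    if stree.is_ancestor_or_equal(last, n)
                )
            else:
                self.translocation_branches = sorted(
                    stree.name_of(n)
                    for n in stree.tree.preorder_node_iter()
                    if n.parent_node is not None
                )


def simulate_random(config: SimConfig) -> SimulatedDataset:
    """Draw per-branch events from the configured rates and replay them.

    The drawn events are recorded in the returned dataset's event log, so
    an identical (seed, config) pair reproduces the dataset exactly and
    the log itself can be replayed deterministically.
    """
    rng = random.Random(config.seed)
    stree = config.species_tree
    log_ = EventLog(
        ancestral_genome=config.ancestral_genome,
        events=[],
        subtype_names=dict(config.subtype_names),
    )
    engine = _Engine(stree, log_)
    wgd_by_branch: Dict[str, List[str]] = {}
    for node in stree.tree.preorder_node_iter():
        labels = stree.wgd_labels.get(id(node))
        if labels:
            wgd_by_branch[stree.name_of(node)] = list(labels)
    counters = {"local": itertools.count(1), "transloc": 0}
    transloc_branches = set(config.translocation_branches or ())

    def branch_events(branch: str, genome: Genome) -> Iterable[EvoEvent]:
        order = itertools.count()

        def emit(etype: str, **params) -> EvoEvent:
            event = _ev(etype, branch, next(order), **params)
            log_.events.append(event)
            return event

        # losses on the loci present at the start of the branch
        for chrom in list(genome):
            for copy in list(genome[chrom]):
                if rng.random() < config.loss_rate:
                    engine.apply_event(genome, emit("loss",
                                                    lineage=copy.lineage_id))
        for label in wgd_by_branch.get(branch, ()):
            engine.apply_event(genome, emit("wgd", label=label))
        if config.local_dup_rate > 0:
            for chrom in list(genome):
                for copy in list(genome[chrom]):
                    if rng.random() < config.local_dup_rate:
                        new_id = (f"{copy.lineage_id}"
                                  f".L{next(counters['local'])}")
                        engine.apply_event(genome, emit(
                            "local_duplication",
                            lineage=copy.lineage_id, new_id=new_id))
        if (
            config.translocation_rate > 0
            and branch in transloc_branches
            and (config.max_translocations is None
                 or counters["transloc"] < config.max_translocations)
            and rng.random() < config.translocation_rate
        ):
            sources = sorted(c for c, copies in genome.items()
                             if len(copies) >= 3)
            if sources:
                src = rng.choice(sources)
                start = rng.randrange(len(genome[src]) - 1)
                run_units = {c.unit for c in genome[src][start:start + 2]}
                # move between paralogous regions: the destination must
                # belong to a different ancestral unit than the moved run
                dests = sorted(
                    c for c, copies in genome.items()
                    if c != src and copies
                    and {cp.unit for cp in copies}.isdisjoint(run_units)
                )
                if dests:
                    dest = rng.choice(dests)
                    dest_index = rng.randrange(len(genome[dest]) + 1)
                    engine.apply_event(genome, emit(
                        "translocation", chromosome=src, start_index=start,
                        length=2, dest_chromosome=dest,
                        dest_index=dest_index))
                    counters["transloc"] += 1
        return ()

    engine.run(branch_events)
    dataset = engine.build_dataset()
    if config.nni_noise > 0:
        perturbed = {}
        for k, (family, gtree) in enumerate(sorted(dataset.gene_trees.items())):
            perturbed[family] = perturb_tree(
                gtree, config.nni_noise, seed=(config.seed * 1009 + k) % (2**31)
            )
        dataset.perturbed_trees = perturbed
    return dataset


# ---------------------------------------------------------------------------
# Tree perturbation (topological noise)
# ---------------------------------------------------------------------------


def perturb_tree(gtree: GeneTree, n_nni: int, seed: int) -> GeneTree:
    """Apply ``n_nni`` random nearest-neighbor interchanges.

    Models the topological disagreement between alternative tree
    inferences (e.g. NJ versus ML) while preserving the tip set.
    """
    if n_nni < 0:
        raise ValueError("n_nni must be >= 0")
    out = gtree.copy()
    if n_nni == 0:
        return out
    if len(out.tip_locus_ids) < 4:
        raise ValueError("NNI needs a tree with at least 4 tips")
    rng = random.Random(seed)
    root = None
    for _ in range(n_nni):
        tree = out.tree
        root = tree.seed_node
        edges = []
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None or node.is_leaf():
                continue
            if len(node.child_nodes()) < 2:
                continue
            if parent is root and len(root.child_nodes()) == 2:
                # the root edge is internal (in the unrooted sense) only
                # when the sibling subtree is itself internal; a swap with
                # the sibling as a whole would leave the topology unchanged
                sibling = next(c for c in root.child_nodes() if c is not node)
                if not sibling.is_leaf():
                    edges.append(node)
            else:
                edges.append(node)
        if not edges:
            break
        edges.sort(key=out.id_of)
        v = rng.choice(edges)
        parent = v.parent_node
        a = rng.choice(sorted(v.child_nodes(), key=out.id_of))
        if parent is root and len(root.child_nodes()) == 2:
            sibling = next(c for c in root.child_nodes() if c is not v)
            c = rng.choice(sorted(sibling.child_nodes(), key=out.id_of))
            sibling.remove_child(c)
            v.remove_child(a)
            sibling.add_child(a)
            v.add_child(c)
        else:
            siblings = [ch for ch in parent.child_nodes() if ch is not v]
            s = rng.choice(sorted(siblings, key=out.id_of))
            parent.remove_child(s)
            v.remove_child(a)
            parent.add_child(a)
            v.add_child(s)
        out = GeneTree(tree)
    return out


# ---------------------------------------------------------------------------
# Event-log serialization (tab-separated text)
# ---------------------------------------------------------------------------


def _subtypes_path(genome_path):
    from pathlib import Path

    p = Path(genome_path)
    return p.with_name(p.stem + "_subtypes" + p.suffix)


def write_event_log(log_: EventLog, events_path, genome_path,
                    subtypes_path=None) -> None:
    if subtypes_path is None:
        subtypes_path = _subtypes_path(genome_path)
    with open(subtypes_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["lineage_id", "subtype"])
        for lid in sorted(log_.subtype_names):
            writer.writerow([lid, log_.subtype_names[lid]])
    with open(events_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["event_type", "branch", "order_index", "params"])
        for e in log_.events:
            writer.writerow([
                e.event_type, e.branch, e.order_index,
                ";".join(f"{k}={v}" for k, v in e.params),
            ])
    with open(genome_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["chromosome", "position", "lineage_id", "family",
                         "tandem_prev", "subtype"])
        for chrom, spec in log_.ancestral_genome.items():
            for pos, anc in enumerate(spec):
                writer.writerow([
                    chrom, pos, anc.lineage_id, anc.family,
                    str(anc.tandem_prev).lower(),
                    log_.subtype_names.get(anc.lineage_id, "unassigned"),
                ])


def read_event_log(events_path, genome_path,
                   subtypes_path=None) -> EventLog:
    import os

    genome: Dict[str, List[AncestralLocus]] = {}
    subtypes: Dict[str, str] = {}
    if subtypes_path is None:
        subtypes_path = _subtypes_path(genome_path)
    if os.path.exists(subtypes_path):
        with open(subtypes_path, newline="") as fh:
            rows = [r for r in csv.reader(fh, delimiter="\t")
                    if r and not r[0].startswith("#")]
        for row in rows[1:]:
            subtypes[row[0]] = row[1]
    with open(genome_path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t")
                if r and not r[0].startswith("#")]
    header = rows[0]
    idx = {c: header.index(c) for c in header}
    for row in rows[1:]:
        anc = AncestralLocus(
            lineage_id=row[idx["lineage_id"]],
            family=row[idx["family"]],
            tandem_prev=row[idx["tandem_prev"]] == "true",
        )
        genome.setdefault(row[idx["chromosome"]], []).append(anc)
        subtype = row[idx["subtype"]]
        if subtype != "unassigned":
            subtypes[anc.lineage_id] = subtype
    events: List[EvoEvent] = []
    with open(events_path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t")
                if r and not r[0].startswith("#")]
    header = rows[0]
    idx = {c: header.index(c) for c in header}
    for row in rows[1:]:
        params = tuple(
            tuple(kv.split("=", 1))
            for kv in row[idx["params"]].split(";")
            if kv
        )
        events.append(EvoEvent(
            event_type=row[idx["event_type"]],
            branch=row[idx["branch"]],
            order_index=int(row[idx["order_index"]]),
            params=params,  # type: ignore[arg-type]
        ))
    return EventLog(ancestral_genome=genome, events=events,
                    subtype_names=subtypes)
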