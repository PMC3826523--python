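"""Gene locus tables and elementary repertoire queries.

Coordinates are 0-based, half-open, in base pairs.  Positions published
only at Mb precision are treated as point anchors (``end = start + 1``).
A "local duplicate" cluster is a run of same-species, same-chromosome,
same-subtype loci whose consecutive members lie within ``max_gap`` of
each other — the tandem copies that arise from small-scale duplication,
as opposed to the dispersed copies produced by whole-genome duplication.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

log = logging.getLogger(__name__)

STRANDS = {"+", "-", "?"}

LOCUS_COLUMNS = [
    "species",
    "locus_id",
    "family",
    "subtype",
    "chromosome",
    "start",
    "end",
    "strand",
    "has_introns",
]


@dataclass(frozen=True)
class GeneLocus:
    """A single gene placement on a chromosome of one species."""

    locus_id: str
    species: str
    family: str
    subtype: str
    chromosome: str
    start: int
    end: int
    strand: str = "?"
    has_introns: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"locus {self.locus_id!r}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"locus {self.locus_id!r}: bad strand {self.strand!r}")
        # Subtype strings are free-form but case-normalized on ingest.
        object.__setattr__(self, "subtype", self.subtype.upper())

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and self.end > start

    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


class LocusTable:
    """A collection of :class:`GeneLocus` with optional chromosome lengths.

    ``chromosome_lengths`` maps ``(species, chromosome)`` to length in bp;
    when a length is known every locus on that chromosome must fit on it.
    """

    def __init__(
        self,
        loci: Iterable[GeneLocus] = (),
        chromosome_lengths: Optional[Dict[Tuple[str, str], int]] = None,
    ) -> None:
        self._loci: List[GeneLocus] = []
        self._by_id: Dict[str, GeneLocus] = {}
        self.chromosome_lengths: Dict[Tuple[str, str], int] = dict(
            chromosome_lengths or {}
        )
        for locus in loci:
            self.add(locus)

    def add(self, locus: GeneLocus) -> None:
        if locus.locus_id in self._by_id:
            raise ValueError(f"duplicate locus_id {locus.locus_id!r}")
        length = self.chromosome_lengths.get((locus.species, locus.chromosome))
        if length is not None and locus.end > length:
            raise ValueError(
                f"locus {locus.locus_id!r} ends at {locus.end} beyond "
                f"chromosome length {length}"
            )
        self._loci.append(locus)
        self._by_id[locus.locus_id] = locus

    def __len__(self) -> int:
        return len(self._loci)

    def __iter__(self) -> Iterator[GeneLocus]:
        return iter(self._loci)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._by_id

    def get(self, locus_id: str) -> GeneLocus:
        return self._by_id[locus_id]

    @property
    def species(self) -> List[str]:
        return sorted({l.species for l in self._loci})

    @property
    def families(self) -> List[str]:
        return sorted({l.family for l in self._loci})

    def filter(
        self,
        species: Optional[str] = None,
        family: Optional[str] = None,
        chromosome: Optional[str] = None,
        subtype: Optional[str] = None,
    ) -> "LocusTable":
        out = LocusTable(chromosome_lengths=self.chromosome_lengths)
        for l in self._loci:
            if species is not None and l.species != species:
                continue
            if family is not None and l.family != family:
                continue
            if chromosome is not None and l.chromosome != chromosome:
                continue
            if subtype is not None and l.subtype != subtype.upper():
                continue
            out.add(l)
        return out

    def sorted_loci(self) -> List[GeneLocus]:
        """Loci in deterministic (species, chromosome, start, locus_id) order."""
        return sorted(
            self._loci, key=lambda l: (l.species, l.chromosome, l.start, l.locus_id)
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {c: getattr(l, c) for c in LOCUS_COLUMNS}
                for l in self.sorted_loci()
            ],
            columns=LOCUS_COLUMNS,
        )


@dataclass(frozen=True)
class LocalCluster:
    """A maximal run of >= 2 tandem same-subtype copies."""

    species: str
    chromosome: str
    family: str
    subtype: str
    locus_ids: Tuple[str, ...]

    def __len__(self) -> int:
        return len(self.locus_ids)


def count_repertoire(
    table: LocusTable,
    species: Optional[str] = None,
    family: Optional[str] = None,
) -> Dict[Tuple[str, str, str], int]:
    """Count loci per (species, family, subtype), optionally filtered.

    Unknown filter values yield an empty result (logged), not an error.
    """
    if species is not None and species not in table.species:
        log.info("count_repertoire: species %r not in table", species)
    if family is not None and family not in table.families:
        log.info("count_repertoire: family %r not in table", family)
    counts: Dict[Tuple[str, str, str], int] = {}
    for l in table:
        if species is not None and l.species != species:
            continue
        if family is not None and l.family != family:
            continue
        key = (l.species, l.family, l.subtype)
        counts[key] = counts.get(key, 0) + 1
    return counts


def find_local_duplicates(table: LocusTable, max_gap: int = 1_000_000) -> List[LocalCluster]:
    """Cluster tandem same-subtype copies.

    Consecutive loci (ordered by start) belong to one cluster when the gap
    between them, ``max(0, next.start - prev.end)``, is at most ``max_gap``.
    Only clusters with >= 2 members are reported; clusters are disjoint and
    the result is invariant to input order.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be > 0")
    groups: Dict[Tuple[str, str, str, str], List[GeneLocus]] = {}
    for l in table:
        groups.setdefault((l.species, l.chromosome, l.family, l.subtype), []).append(l)
    clusters: List[LocalCluster] = []
    for (species, chrom, fam, subtype), loci in sorted(groups.items()):
        loci.sort(key=lambda l: (l.start, l.locus_id))
        run: List[GeneLocus] = [loci[0]]
        for prev, nxt in zip(loci, loci[1:]):
            gap = max(0, nxt.start - prev.end)
            if gap <= max_gap:
                run.append(nxt)
            else:
                if len(run) >= 2:
                    clusters.append(
                        LocalCluster(species, chrom, fam, subtype,
                                     tuple(l.locus_id for l in run))
                    )
                run = [nxt]
        if len(run) >= 2:
            clusters.append(
                LocalCluster(species, chrom, fam, subtype,
                             tuple(l.locus_id for l in run))
            )
    return clusters


def paired_adjacency(
    table: LocusTable,
    family_a: str,
    family_b: str,
    max_gap: int = 1_000_000,
) -> Dict[str, List[Tuple[str, str]]]:
    """Pair nearby loci of two families per species (greedy nearest-first).

    Two loci are candidate partners when they share a chromosome and their
    anchor distance ``|a.start - b.start|`` is at most ``max_gap``.  Each
    locus enters at most one pair; candidates are consumed nearest-first,
    ties resolved toward the smaller start coordinate.  Returns a map
    species -> list of (locus_a_id, locus_b_id) pairs.
    """
    families = set(table.families)
    for fam in (family_a, family_b):
        if fam not in families:
            log.info("paired_adjacency: family %r absent from table", fam)
            return {}
    out: Dict[str, List[Tuple[str, str]]] = {}
    for species in table.species:
        locs_a = list(table.filter(species=species, family=family_a))
        locs_b = list(table.filter(species=species, family=family_b))
        candidates = []
        for a in locs_a:
            for b in locs_b:
                if a.chromosome != b.chromosome:
                    continue
                dist = abs(a.start - b.start)
                if dist <= max_gap:
                    candidates.append(
                        (dist, min(a.start, b.start), a.locus_id, b.locus_id)
                    )
        candidates.sort()
        used_a: set = set()
        used_b: set = set()
        pairs: List[Tuple[str, str]] = []
        for _dist, _pos, aid, bid in candidates:
            if aid in used_a or bid in used_b:
                continue
            used_a.add(aid)
            used_b.add(bid)
            pairs.append((aid, bid))
        if pairs:
            out[species] = sorted(pairs)
    return out


# ---------------------------------------------------------------------------
# Tab-separated interchange format
# ---------------------------------------------------------------------------

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def _parse_bool(text: str, where: str) -> bool:
    low = text.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValueError(f"{where}: cannot parse boolean {text!r}")


def read_locus_table(path, lengths_path=None) -> LocusTable:
    """Read a locus table from tab-separated text.

    The header must contain exactly the columns
    ``species locus_id family subtype chromosome start end strand has_introns``.
    Lines starting with ``#`` are comments.  Rows violating the coordinate
    invariants are rejected with their row number.
    """
    lengths: Dict[Tuple[str, str], int] = {}
    if lengths_path is not None:
        lengths = read_chromosome_lengths(lengths_path)
    table = LocusTable(chromosome_lengths=lengths)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t")
                if r and not r[0].startswith("#")]
    if not rows:
        raise ValueError(f"{path}: empty locus table (missing header)")
    header = [c.strip() for c in rows[0]]
    missing = [c for c in LOCUS_COLUMNS if c not in header]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    idx = {c: header.index(c) for c in LOCUS_COLUMNS}
    for rownum, row in enumerate(rows[1:], start=2):
        try:
            locus = GeneLocus(
                locus_id=row[idx["locus_id"]].strip(),
                species=row[idx["species"]].strip(),
                family=row[idx["family"]].strip(),
                subtype=row[idx["subtype"]].strip(),
                chromosome=row[idx["chromosome"]].strip(),
                start=int(row[idx["start"]]),
                end=int(row[idx["end"]]),
                strand=row[idx["strand"]].strip(),
                has_introns=_parse_bool(row[idx["has_introns"]], f"row {rownum}"),
            )
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: row {rownum}: {exc}") from exc
        table.add(locus)
    return table


def write_locus_table(table: LocusTable, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(LOCUS_COLUMNS)
        for l in table.sorted_loci():
            writer.writerow(
                [l.species, l.locus_id, l.family, l.subtype, l.chromosome,
                 l.start, l.end, l.strand, str(l.has_introns).lower()]
            )


def load_visual_opsin_table() -> LocusTable:
    """The curated cross-species visual opsin locus table shipped with the
    package (point anchors at published Mb precision)."""
    from importlib.resources import files

    path = files("paralogon.data") / "visual_opsin_loci.tsv"
    return read_locus_table(str(path))


def read_chromosome_lengths(path) -> Dict[Tuple[str, str], int]:
    """Read a species/chromosome/length tab-separated table."""
    lengths: Dict[Tuple[str, str], int] = {}
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t")
                if r and not r[0].startswith("#")]
    if not rows:
        return lengths
    header = [c.strip() for c in rows[0]]
    for col in ("species", "chromosome", "length"):
        if col not in header:
            raise ValueError(f"{path}: missing column {col!r}")
    si, ci, li = (header.index(c) for c in ("species", "chromosome", "length"))
    for row in rows[1:]:
        lengths[(row[si].strip(), row[ci].strip())] = int(row[li])
    return lengths
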