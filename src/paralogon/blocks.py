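"""Chromosome blocks around anchor genes and neighboring-family selection.

A block is the +-window interval around an anchor gene, clipped to the
chromosome when its length is known.  Families are profiled by how many
distinct blocks carry at least one member; families reaching the
``min_blocks`` co-occurrence threshold are the candidate neighbors of the
anchors, and selections from several anchor sets can be pooled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .loci import GeneLocus, LocusTable

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 5_000_000  # +- 5 Mb around each anchor


@dataclass(frozen=True)
class ChromosomeBlock:
    block_id: str
    species: str
    chromosome: str
    start: int
    end: int
    anchor_ids: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"block {self.block_id!r}: start must be < end")

    def contains(self, locus: GeneLocus) -> bool:
        return (
            locus.species == self.species
            and locus.chromosome == self.chromosome
            and locus.overlaps(self.start, self.end)
        )


class FamilyProfile:
    """family -> block_id -> member locus count."""

    def __init__(self) -> None:
        self.counts: Dict[str, Dict[str, int]] = {}

    def add(self, family: str, block_id: str) -> None:
        self.counts.setdefault(family, {})[block_id] = (
            self.counts.get(family, {}).get(block_id, 0) + 1
        )

    def families(self) -> List[str]:
        return sorted(self.counts)

    def block_count(self, family: str) -> int:
        return len(self.counts.get(family, {}))

    def member_count(self, family: str) -> int:
        return sum(self.counts.get(family, {}).values())

    def __getitem__(self, family: str) -> Dict[str, int]:
        return self.counts[family]

    def __contains__(self, family: str) -> bool:
        return family in self.counts


def define_blocks(
    anchors: Sequence[GeneLocus],
    window: int,
    table: LocusTable,
    merge: bool = True,
) -> List[ChromosomeBlock]:
    """Build ``[start - window, end + window)`` blocks around anchors.

    Blocks are clipped to ``[0, chromosome length)`` when the length is
    known (otherwise a warning is logged and the block is only clipped at
    zero).  With ``merge`` (default) overlapping same-chromosome blocks
    are unioned and credited to all contributing anchors; ``merge=False``
    keeps one block per anchor for within-chromosome paralogy questions.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if not anchors:
        return []
    species = {a.species for a in anchors}
    if len(species) > 1:
        raise ValueError(f"anchors span several species: {sorted(species)}")
    raw: List[Tuple[str, int, int, Tuple[str, ...]]] = []
    for anchor in anchors:
        start = max(0, anchor.start - window)
        end = anchor.end + window
        length = table.chromosome_lengths.get((anchor.species, anchor.chromosome))
        if length is None:
            log.warning(
                "no chromosome length for (%s, %s); block around %s left unclipped",
                anchor.species, anchor.chromosome, anchor.locus_id,
            )
        else:
            end = min(end, length)
        raw.append((anchor.chromosome, start, end, (anchor.locus_id,)))

    if merge:
        merged: List[Tuple[str, int, int, Tuple[str, ...]]] = []
        for chrom, start, end, ids in sorted(raw):
            if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
                pchrom, pstart, pend, pids = merged[-1]
                merged[-1] = (pchrom, pstart, max(pend, end), pids + ids)
            else:
                merged.append((chrom, start, end, ids))
        raw = merged
    else:
        raw.sort()

    sp = next(iter(species))
    blocks = []
    for k, (chrom, start, end, ids) in enumerate(raw):
        blocks.append(
            ChromosomeBlock(
                block_id=f"{sp}:{chrom}:{k}",
                species=sp,
                chromosome=chrom,
                start=start,
                end=end,
                anchor_ids=tuple(sorted(ids)),
            )
        )
    return blocks


def profile_families(
    blocks: Sequence[ChromosomeBlock], table: LocusTable
) -> FamilyProfile:
    """Assign loci to overlapping blocks and tally families per block."""
    if not blocks:
        raise ValueError("profile_families requires at least one block")
    profile = FamilyProfile()
    for locus in table.sorted_loci():
        for block in blocks:
            if block.contains(locus):
                profile.add(locus.family, block.block_id)
    return profile


def select_families(
    profile: FamilyProfile,
    min_blocks: int = 2,
    max_members: Optional[int] = 200,
) -> List[str]:
    """Families with members on at least ``min_blocks`` distinct blocks.

    Multiple members in one block count once toward the threshold.  Very
    large families (more than ``max_members`` assigned members) are
    excluded, mirroring the exclusion of families too large for reliable
    phylogenetic treatment; pass ``max_members=None`` to keep all.
    """
    if min_blocks < 2:
        raise ValueError("min_blocks must be >= 2")
    out = []
    for family in profile.families():
        if profile.block_count(family) < min_blocks:
            continue
        if max_members is not None and profile.member_count(family) > max_members:
            log.info("family %r excluded: %d members > max_members=%d",
                     family, profile.member_count(family), max_members)
            continue
        out.append(family)
    return sorted(out)


def pool_selections(selections: Iterable[Sequence[str]]) -> List[str]:
    """Sorted set union of several family selections."""
    pooled: set = set()
    for sel in selections:
        pooled.update(sel)
    return sorted(pooled)


def assign_loci_to_blocks(
    blocks: Sequence[ChromosomeBlock], table: LocusTable
) -> Dict[str, List[GeneLocus]]:
    """block_id -> loci overlapping the block (deterministic order)."""
    out: Dict[str, List[GeneLocus]] = {b.block_id: [] for b in blocks}
    for locus in table.sorted_loci():
        for block in blocks:
            if block.contains(locus):
                out[block.block_id].append(locus)
    return out
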