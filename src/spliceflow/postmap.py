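"""Post-mapping classification: unique vs multi-maps, and mate rescue.

A read is unique when exactly one placement survives at its best mismatch
stratum across ALL references — genome and junctions combined — after
collapsing placements with identical genomic projection.  A read placed
uniquely in the genome and also uniquely at a distinct junction locus is
therefore a multi-map (often the signature of a processed pseudogene).

For paired ends, a multi-mapping mate of a uniquely mapped read can be
rescued: among its placements on the unique mate's chromosome with consistent
orientation, the one closest to the unique mate is chosen and flagged.
Insert size is deliberately not used — introns stretch the genomic distance
between mates unpredictably.  Rescued mates stay flagged rather than being
promoted to unique; downstream quantification only counts them on request.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .core import AlignmentRecord, MappingSummary

UNIQUE = "unique"
MULTI = "multi"


@dataclass
class ClassifiedAlignment:
    """A read's surviving placements plus its uniqueness call."""

    read_id: str
    mate_index: int
    uniqueness: str  # unique | multi
    records: List[AlignmentRecord]
    rescue_flag: str = "none"  # none | mate_rescued
    rescued_record: Optional[AlignmentRecord] = None

    @property
    def key(self) -> Tuple[str, int]:
        return (self.read_id, self.mate_index)

    @property
    def primary(self) -> AlignmentRecord:
        """The single placement for unique reads; the rescued placement for
        rescued multi-maps; otherwise the first placement."""
        if self.rescued_record is not None:
            return self.rescued_record
        return self.records[0]


def classify_uniqueness(
    grouped: Dict[Tuple[str, int], List[AlignmentRecord]]
) -> Dict[Tuple[str, int], ClassifiedAlignment]:
    """Classify each read from its full placement list.

    Placements are reduced to the best mismatch stratum (fewer mismatches at
    equal effective length is better) and collapsed by genomic projection;
    one survivor means unique, two or more mean multi.  Idempotent.
    """
    out = {}
    for (read_id, mate_index), records in grouped.items():
        if not records:
            continue
        best_len = max(r.effective_read_length for r in records)
        at_len = [r for r in records if r.effective_read_length == best_len]
        best_mm = min(r.mismatches for r in at_len)
        dedup = {}
        for r in at_len:
            if r.mismatches == best_mm:
                dedup.setdefault(r.projection, r)
        survivors = sorted(dedup.values(), key=lambda r: (r.chrom, r.start))
        out[(read_id, mate_index)] = ClassifiedAlignment(
            read_id=read_id,
            mate_index=mate_index,
            uniqueness=UNIQUE if len(survivors) == 1 else MULTI,
            records=survivors,
        )
    return out


def _mate_distance(a: AlignmentRecord, b: AlignmentRecord) -> int:
    """Gap between the inner ends of two mates (0 if they overlap)."""
    if a.end <= b.start:
        return b.start - a.end
    if b.end <= a.start:
        return a.start - b.end
    return 0


def _orientation_consistent(unique_rec: AlignmentRecord, cand: AlignmentRecord) -> bool:
    """FR layout: mates on opposite strands."""
    return unique_rec.strand != cand.strand


def rescue_mates(
    classified: Dict[Tuple[str, int], ClassifiedAlignment],
    require_orientation: bool = True,
) -> Dict[Tuple[str, int], ClassifiedAlignment]:
    """Rescue multi-mapping mates of uniquely mapping paired reads, in place.

    For a (unique U, multi M) pair, the placement of M on U's chromosome with
    the smallest inner-end gap to U (ties broken toward the smaller
    coordinate) is selected and M flagged ``mate_rescued``.  M's uniqueness is
    unchanged, no placements are invented, and pairs without a placement on
    U's chromosome are left alone.  Running twice equals running once.
    """
    by_stem: Dict[str, dict] = {}
    for (read_id, mate_index), ca in classified.items():
        if mate_index in (1, 2):
            by_stem.setdefault(read_id, {})[mate_index] = ca
    for stem, mates in by_stem.items():
        if len(mates) != 2:
            continue
        for u_idx, m_idx in ((1, 2), (2, 1)):
            u, m = mates[u_idx], mates[m_idx]
            if u.uniqueness != UNIQUE or m.uniqueness != MULTI:
                continue
            anchor = u.records[0]
            cands = [
                r
                for r in m.records
                if r.chrom == anchor.chrom
                and (not require_orientation or _orientation_consistent(anchor, r))
            ]
            if not cands:
                continue
            cands.sort(key=lambda r: (_mate_distance(anchor, r), r.start))
            m.rescue_flag = "mate_rescued"
            m.rescued_record = cands[0]
    return classified


def unique_records(
    classified: Dict[Tuple[str, int], ClassifiedAlignment],
    use_rescued: bool = False,
) -> List[AlignmentRecord]:
    """The one placement per read that feeds quantification: unique reads
    always; rescued mates only when ``use_rescued``."""
    out = []
    for ca in classified.values():
        if ca.uniqueness == UNIQUE:
            out.append(ca.records[0])
        elif use_rescued and ca.rescue_flag == "mate_rescued":
            out.append(ca.rescued_record)
    return out


def classification_summary(
    classified: Dict[Tuple[str, int], ClassifiedAlignment], total_reads: int
) -> MappingSummary:
    unique = sum(1 for c in classified.values() if c.uniqueness == UNIQUE)
    multi = len(classified) - unique
    return MappingSummary(
        total_reads=total_reads,
        mapped_unique=unique,
        mapped_multi=multi,
        unmapped=total_reads - len(classified),
    )
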