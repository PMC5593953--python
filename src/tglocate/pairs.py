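"""Pair-level evidence classes over the composite genome+vector reference.

Each fragment is assigned exactly one class. The two classes that carry
insertion-site information operationalize "read maps both to the genome
and to the vector": a *chimeric pair* has one mate uniquely on the genome
and the other uniquely on the vector (the junction lies in the
unsequenced part of the fragment), while a *split junction* read crosses
the junction itself, its soft-clipped tail re-aligning uniquely to the
other contig class and pinning the breakpoint to the base.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .genome import VECTOR_CONTIG
from .mapper import AlignmentRecord, MapParams, SeedIndex, align_read, align_reads_batch
from .simulate import ReadPairs


class PairClass(enum.Enum):
    GENOME_CONCORDANT = "GENOME_CONCORDANT"
    VECTOR_INTERNAL = "VECTOR_INTERNAL"
    CHIMERIC_GENOME_VECTOR = "CHIMERIC_GENOME_VECTOR"
    SPLIT_JUNCTION = "SPLIT_JUNCTION"
    DISCORDANT_GENOME = "DISCORDANT_GENOME"
    UNMAPPED = "UNMAPPED"


@dataclass(frozen=True)
class SplitHit:
    """A junction observed inside a single read.

    ``genome_pos`` is the wild-type coordinate of the junction under the
    left-breakpoint convention (first base after the last genome base on
    the 'L' side; alignment start on the 'R' side). ``side`` says which
    side of the junction the genome-aligned part occupies.
    """

    qname: str
    mate: int
    genome_contig: str
    genome_pos: int
    side: str  # 'L': genome part left of junction; 'R': right
    vector_interval: tuple[int, int]
    vector_strand: str


@dataclass
class PairAlignment:
    """Both mates' placements plus the pair-level class and split evidence."""

    qname: str
    recs1: list[AlignmentRecord]
    recs2: list[AlignmentRecord]
    pair_class: PairClass
    splits: list[SplitHit] = field(default_factory=list)

    @property
    def best1(self) -> AlignmentRecord | None:
        return self.recs1[0] if self.recs1 else None

    @property
    def best2(self) -> AlignmentRecord | None:
        return self.recs2[0] if self.recs2 else None


def _is_vector(rec: AlignmentRecord) -> bool:
    return rec.contig == VECTOR_CONTIG


def _find_splits(
    rec: AlignmentRecord, index: SeedIndex, params: MapParams
) -> list[SplitHit]:
    """Re-align qualifying soft-clips of a unique record to the other
    contig class; each confirmed re-alignment is one split observation."""
    hits: list[SplitHit] = []
    primary_on_vector = _is_vector(rec)
    for clip_side in ("5", "3"):
        clip_len = rec.clip5 if clip_side == "5" else rec.clip3
        if clip_len < params.min_clip:
            continue
        clipped = rec.seq[: rec.clip5] if clip_side == "5" else rec.seq[rec.clip5 + rec.aligned_len :]
        sub = align_read(clipped, index, params, qname=rec.qname, mate=rec.mate)
        if not sub or not sub[0].unique:
            continue
        r2 = sub[0]
        if _is_vector(r2) == primary_on_vector:
            continue  # must land on the other contig class
        if r2.aligned_len < params.min_clip:
            continue
        if primary_on_vector:
            # the re-aligned clip is the genome part; the junction sits at
            # the clip boundary, i.e. at the genome part's end adjacent to
            # the vector part
            genome = r2
            if clip_side == "5":
                # genome part 5' of the vector part in read orientation
                side = "L" if genome.strand == "+" else "R"
            else:
                side = "R" if genome.strand == "+" else "L"
            pos = genome.end if side == "L" else genome.pos
            vec_iv = (rec.pos, rec.end)
            vec_strand = rec.strand
            contig = genome.contig
        else:
            # primary record is the genome part; clip boundary is the breakpoint
            side = "R" if clip_side == "5" else "L"
            pos = rec.pos if side == "R" else rec.end
            vec_iv = (r2.pos, r2.end)
            vec_strand = r2.strand
            contig = rec.contig
        hits.append(
            SplitHit(
                qname=rec.qname,
                mate=rec.mate,
                genome_contig=contig,
                genome_pos=int(pos),
                side=side,
                vector_interval=vec_iv,
                vector_strand=vec_strand,
            )
        )
    return hits


def classify_pair(
    recs1: list[AlignmentRecord],
    recs2: list[AlignmentRecord],
    index: SeedIndex,
    params: MapParams = MapParams(),
) -> tuple[PairClass, list[SplitHit]]:
    """Assign the fragment's evidence class and collect split observations.

    Precedence: CHIMERIC_GENOME_VECTOR, SPLIT_JUNCTION, GENOME_CONCORDANT,
    VECTOR_INTERNAL, DISCORDANT_GENOME, UNMAPPED. Split observations are
    also harvested from chimeric pairs (a chimeric fragment's genome mate
    may itself cross the junction); they refine breakpoints downstream.
    """
    b1 = recs1[0] if recs1 and recs1[0].unique else None
    b2 = recs2[0] if recs2 and recs2[0].unique else None

    splits: list[SplitHit] = []
    for rec in (b1, b2):
        if rec is not None and max(rec.clip5, rec.clip3) >= params.min_clip:
            splits.extend(_find_splits(rec, index, params))

    if b1 is not None and b2 is not None and _is_vector(b1) != _is_vector(b2):
        return PairClass.CHIMERIC_GENOME_VECTOR, splits
    if splits:
        return PairClass.SPLIT_JUNCTION, splits
    if b1 is None or b2 is None:
        return PairClass.UNMAPPED, splits
    if _is_vector(b1) and _is_vector(b2):
        return PairClass.VECTOR_INTERNAL, splits
    # both uniquely on the genome
    if b1.contig == b2.contig and b1.strand != b2.strand:
        plus, minus = (b1, b2) if b1.strand == "+" else (b2, b1)
        insert = minus.end - plus.pos
        lo, hi = params.insert_bounds
        if plus.pos <= minus.pos and lo <= insert <= hi:
            return PairClass.GENOME_CONCORDANT, splits
    return PairClass.DISCORDANT_GENOME, splits


def align_pairs(
    reads: ReadPairs,
    index: SeedIndex,
    params: MapParams = MapParams(),
) -> list[PairAlignment]:
    """Align both mates of every pair and classify each fragment."""
    if len(reads.r1) != len(reads.r2):
        raise ValueError("mate count mismatch")
    res1 = align_reads_batch(reads.r1, index, params, qnames=reads.names, mate=1)
    res2 = align_reads_batch(reads.r2, index, params, qnames=reads.names, mate=2)
    out: list[PairAlignment] = []
    for name, r1, r2 in zip(reads.names, res1, res2):
        cls, splits = classify_pair(r1, r2, index, params)
        out.append(PairAlignment(qname=name, recs1=r1, recs2=r2, pair_class=cls, splits=splits))
    return out


def class_counts(pairs: list[PairAlignment]) -> dict[str, int]:
    counts = {c.value: 0 for c in PairClass}
    for p in pairs:
        counts[p.pair_class.value] += 1
    return counts


def deletion_spanning_gaps(
    pairs: list[PairAlignment], params: MapParams = MapParams()
) -> list[tuple[int, int]]:
    """Inner gaps of discordant same-contig pairs with stretched inserts.

    A fragment spanning a deletion maps with an implied insert longer than
    the concordant range; its inner gap ``(left mate end, right mate
    start)`` brackets the deleted interval. Used to corroborate
    depth-based deletion calls.
    """
    out: list[tuple[int, int]] = []
    _, hi = params.insert_bounds
    for p in pairs:
        if p.pair_class is not PairClass.DISCORDANT_GENOME:
            continue
        b1, b2 = p.best1, p.best2
        if b1.contig != b2.contig or b1.strand == b2.strand:
            continue
        plus, minus = (b1, b2) if b1.strand == "+" else (b2, b1)
        if plus.pos > minus.pos:
            continue
        if minus.end - plus.pos > hi and minus.pos > plus.end:
            out.append((plus.end, minus.pos))
    return out


def unique_records(pairs: list[PairAlignment]) -> list[AlignmentRecord]:
    """All uniquely-placed mate records, the substrate for depth profiles."""
    recs = []
    for p in pairs:
        for rs in (p.recs1, p.recs2):
            if rs and rs[0].unique:
                recs.append(rs[0])
    return recs
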