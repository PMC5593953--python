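"""SAM text serialization of pair alignments (via pysam).

Minimal dialect: @HD/@SQ/@PG header, the 11 mandatory columns, NM and AS
tags. Uniqueness is encoded in MAPQ (60 unique, 0 otherwise), matching
common aligner practice. Coordinates are converted between the package's
0-based half-open convention and SAM's 1-based.
"""

from __future__ import annotations

from pathlib import Path

import pysam

from .mapper import AlignmentRecord
from .pairs import PairAlignment

MAPQ_UNIQUE = 60


def _header(contigs: dict[str, int]) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in contigs.items()],
        "PG": [{"ID": "tglocate", "PN": "tglocate"}],
    }


def _to_segment(
    rec: AlignmentRecord | None,
    mate_rec: AlignmentRecord | None,
    mate: int,
    header: pysam.AlignmentHeader,
    qname: str,
) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = qname
    flag = 0x1 | (0x40 if mate == 1 else 0x80)
    if rec is None:
        flag |= 0x4
    else:
        if rec.strand == "-":
            flag |= 0x10
    if mate_rec is None:
        flag |= 0x8
    elif mate_rec.strand == "-":
        flag |= 0x20
    seg.flag = flag
    if rec is not None:
        seg.reference_name = rec.contig
        seg.reference_start = rec.pos
        seg.mapping_quality = MAPQ_UNIQUE if rec.unique else 0
        seg.cigarstring = rec.cigar
        seg.query_sequence = rec.seq
        seg.set_tag("NM", rec.nm)
        seg.set_tag("AS", rec.score)
    if mate_rec is not None:
        seg.next_reference_name = mate_rec.contig
        seg.next_reference_start = mate_rec.pos
    return seg


def write_sam(
    pairs: list[PairAlignment], contigs: dict[str, int], path: str | Path
) -> None:
    """Write the best placement of each mate (one line per mate)."""
    header = pysam.AlignmentHeader.from_dict(_header(contigs))
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for p in pairs:
            b1, b2 = p.best1, p.best2
            fh.write(_to_segment(b1, b2, 1, header, p.qname))
            fh.write(_to_segment(b2, b1, 2, header, p.qname))


def read_sam(path: str | Path) -> list[tuple[AlignmentRecord | None, AlignmentRecord | None]]:
    """Read mate-paired records back; inverse of :func:`write_sam`.

    Returns one ``(mate1, mate2)`` tuple per fragment, in file order.
    Unmapped mates come back as None.
    """
    by_name: dict[str, list[AlignmentRecord | None]] = {}
    order: list[str] = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for seg in fh:
            mate = 1 if (seg.flag & 0x40) else 2
            if seg.query_name not in by_name:
                by_name[seg.query_name] = [None, None]
                order.append(seg.query_name)
            if seg.is_unmapped:
                continue
            clip5 = clip3 = 0
            aligned = 0
            if seg.cigartuples:
                for i, (op, ln) in enumerate(seg.cigartuples):
                    if op == 4:  # S
                        if i == 0:
                            clip5 = ln
                        else:
                            clip3 = ln
                    elif op == 0:  # M
                        aligned += ln
            rec = AlignmentRecord(
                qname=seg.query_name,
                mate=mate,
                contig=seg.reference_name,
                pos=seg.reference_start,
                strand="-" if seg.is_reverse else "+",
                clip5=clip5,
                clip3=clip3,
                nm=int(seg.get_tag("NM")) if seg.has_tag("NM") else 0,
                score=int(seg.get_tag("AS")) if seg.has_tag("AS") else aligned,
                unique=seg.mapping_quality >= MAPQ_UNIQUE,
                seq=seg.query_sequence or "",
            )
            by_name[seg.query_name][mate - 1] = rec
    return [tuple(by_name[name]) for name in order]
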