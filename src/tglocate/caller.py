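"""Insertion-site calling from chimeric/split evidence, and transgene
copy number from relative depth.

Chimeric pairs localize a junction to within a fragment length; split
reads pin it to the base. Evidence is clustered along the genome by
single linkage and clusters with enough support become insertion calls
under a left-breakpoint convention (the call coordinate is the first
wild-type base after the junction's left side).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter
from pathlib import Path

import numpy as np

from .depth import DepthProfile
from .genome import VECTOR_CONTIG
from .pairs import PairAlignment, PairClass


@dataclass(frozen=True)
class JunctionEvidence:
    """One junction observation: a chimeric pair or a split read."""

    kind: str  # 'chimeric_pair' | 'split_read'
    contig: str
    genome_pos: int
    side: str  # 'L' | 'R'
    vector_interval: tuple[int, int]
    vector_strand: str
    qname: str


@dataclass
class InsertionCall:
    """A genome<->vector junction cluster passing the support threshold."""

    contig: str
    breakpoint_lo: int
    breakpoint_hi: int
    vector_interval: tuple[int, int]
    vector_orientation: str
    n_split: int
    n_pairs: int

    @property
    def support(self) -> int:
        return self.n_split + self.n_pairs

    @property
    def resolution(self) -> str:
        return "base_pair" if self.n_split >= 1 else "interval"

    @property
    def breakpoint(self) -> int:
        return (self.breakpoint_lo + self.breakpoint_hi) // 2


@dataclass(frozen=True)
class CopyNumberEstimate:
    """Transgene copies per diploid genome from the vector:genome depth ratio."""

    vector_mean_depth: float
    genome_mean_depth: float
    copies_per_diploid: float


def collect_evidence(pairs: list[PairAlignment]) -> list[JunctionEvidence]:
    """One item per chimeric pair plus one per confirmed split read.

    For a chimeric pair the genome mate's junction-proximal coordinate is
    used: its 3' end for a ``+`` mate (junction to the right, side 'L'),
    its 5' start for a ``-`` mate (side 'R').
    """
    out: list[JunctionEvidence] = []
    for p in pairs:
        if p.pair_class is PairClass.CHIMERIC_GENOME_VECTOR:
            b1, b2 = p.best1, p.best2
            genome, vector = (b1, b2) if b2.contig == VECTOR_CONTIG else (b2, b1)
            if genome.strand == "+":
                side, pos = "L", genome.end
            else:
                side, pos = "R", genome.pos
            out.append(
                JunctionEvidence(
                    kind="chimeric_pair",
                    contig=genome.contig,
                    genome_pos=int(pos),
                    side=side,
                    vector_interval=(vector.pos, vector.end),
                    vector_strand=vector.strand,
                    qname=p.qname,
                )
            )
        if p.pair_class in (PairClass.CHIMERIC_GENOME_VECTOR, PairClass.SPLIT_JUNCTION):
            for s in p.splits:
                out.append(
                    JunctionEvidence(
                        kind="split_read",
                        contig=s.genome_contig,
                        genome_pos=s.genome_pos,
                        side=s.side,
                        vector_interval=s.vector_interval,
                        vector_strand=s.vector_strand,
                        qname=s.qname,
                    )
                )
    out.sort(key=lambda e: (e.contig, e.genome_pos, e.kind, e.qname))
    return out


def cluster_evidence(
    evidence: list[JunctionEvidence], window: int = 1100
) -> list[list[JunctionEvidence]]:
    """Single-linkage clustering along the genome: an item joins a cluster
    when it is within ``window`` bases of the cluster's last member."""
    clusters: list[list[JunctionEvidence]] = []
    for ev in sorted(evidence, key=lambda e: (e.contig, e.genome_pos, e.qname)):
        if (
            clusters
            and clusters[-1][-1].contig == ev.contig
            and ev.genome_pos - clusters[-1][-1].genome_pos <= window
        ):
            clusters[-1].append(ev)
        else:
            clusters.append([ev])
    return clusters


def call_insertions(
    clusters: list[list[JunctionEvidence]], min_support: int = 3
) -> list[InsertionCall]:
    """Turn supported clusters into breakpoint calls.

    With split reads the breakpoint is their modal coordinate (base-pair
    resolution); otherwise the interval is bounded by the innermost
    left-side and right-side chimeric-pair coordinates, falling back to
    the evidence span when only one side was observed.
    """
    calls: list[InsertionCall] = []
    for cluster in clusters:
        n_split = sum(1 for e in cluster if e.kind == "split_read")
        n_pairs = sum(1 for e in cluster if e.kind == "chimeric_pair")
        if n_split + n_pairs < min_support:
            continue
        if n_split:
            positions = Counter(
                e.genome_pos for e in cluster if e.kind == "split_read"
            )
            bp = positions.most_common(1)[0][0]
            lo = hi = int(bp)
        else:
            lefts = [e.genome_pos for e in cluster if e.side == "L"]
            rights = [e.genome_pos for e in cluster if e.side == "R"]
            if lefts and rights:
                lo, hi = max(lefts), min(rights)
                if lo > hi:  # noisy outer coordinates crossed; fall back to span
                    lo, hi = min(hi, lo), max(hi, lo)
            else:
                pos = [e.genome_pos for e in cluster]
                lo, hi = min(pos), max(pos)
        v_lo = min(e.vector_interval[0] for e in cluster)
        v_hi = max(e.vector_interval[1] for e in cluster)
        orient = Counter(e.vector_strand for e in cluster).most_common(1)[0][0]
        calls.append(
            InsertionCall(
                contig=cluster[0].contig,
                breakpoint_lo=int(lo),
                breakpoint_hi=int(hi),
                vector_interval=(int(v_lo), int(v_hi)),
                vector_orientation=orient,
                n_split=n_split,
                n_pairs=n_pairs,
            )
        )
    return calls


def estimate_transgene_copies(
    vector_profile: DepthProfile,
    genome_profile: DepthProfile,
) -> CopyNumberEstimate:
    """copies_per_diploid = 2 x (mean vector depth / mean genome depth).

    The genome mean is taken over unmasked windows (deletions and
    insertion flanks are expected to be masked by the caller of
    :func:`tglocate.depth.compute_depth`); the vector mean is over the
    whole vector contig. A heterozygote with an n-copy concatemer gives
    ~n, a homozygote ~2n, plus a fractional contribution from the short
    sub-site fragment over its interval.
    """
    unmasked = genome_profile.raw[~genome_profile.masked]
    genome_mean = float(unmasked.mean()) if unmasked.size else 0.0
    if genome_mean == 0:
        raise ValueError("undefined copy number: genome mean depth is 0")
    vector_mean = float(vector_profile.raw.mean())
    return CopyNumberEstimate(
        vector_mean_depth=vector_mean,
        genome_mean_depth=genome_mean,
        copies_per_diploid=2.0 * vector_mean / genome_mean,
    )


def write_vcf(
    calls: list[InsertionCall],
    contigs: dict[str, int],
    path: str | Path,
    min_support: int,
    window: int,
) -> None:
    """VCF 4.2 breakend records for each genome->vector junction."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=tglocate\n")
        fh.write(f"##tglocate_min_support={min_support}\n")
        fh.write(f"##tglocate_cluster_window={window}\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=NSPLIT,Number=1,Type=Integer,Description="Split-read support">\n')
        fh.write('##INFO=<ID=NPAIR,Number=1,Type=Integer,Description="Chimeric-pair support">\n')
        fh.write('##INFO=<ID=RES,Number=1,Type=String,Description="Breakpoint resolution">\n')
        fh.write('##INFO=<ID=CIPOS,Number=2,Type=Integer,Description="Breakpoint interval">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, c in enumerate(calls, 1):
            pos1 = c.breakpoint + 1  # VCF is 1-based
            v_lo = c.vector_interval[0] + 1
            alt = f"N[{VECTOR_CONTIG}:{v_lo}[" if c.vector_orientation == "+" else f"N]{VECTOR_CONTIG}:{v_lo}]"
            ci = f"{c.breakpoint_lo - c.breakpoint},{c.breakpoint_hi - c.breakpoint}"
            fh.write(
                f"{c.contig}\t{pos1}\tbnd_{i}\tN\t{alt}\t.\tPASS\t"
                f"SVTYPE=BND;NSPLIT={c.n_split};NPAIR={c.n_pairs};RES={c.resolution};CIPOS={ci}\n"
            )


def write_insertion_tsv(calls: list[InsertionCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "contig\tbreakpoint_lo\tbreakpoint_hi\tvector_lo\tvector_hi\t"
            "orientation\tn_split\tn_pairs\tresolution\n"
        )
        for c in calls:
            fh.write(
                f"{c.contig}\t{c.breakpoint_lo}\t{c.breakpoint_hi}\t"
                f"{c.vector_interval[0]}\t{c.vector_interval[1]}\t"
                f"{c.vector_orientation}\t{c.n_split}\t{c.n_pairs}\t{c.resolution}\n"
            )
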