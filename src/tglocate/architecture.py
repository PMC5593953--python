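"""The transgene insertion architecture and its application to a genome.

The model is a single complex integration locus with two sub-sites:

* ``Ins1`` — a short fragment of the vector (517 b by default) deposited
  ~100 kb upstream of the first coding gene analog;
* ``Ins2`` — a head-to-tail concatemer of full vector copies deposited
  ~250 kb downstream of the two-gene cluster;

plus three deletions of wild-type sequence associated with the insertion,
the largest of which (100 kb) removes a non-expressed gene analog
(``ak_analog``). Real-genome distances are multiplied by a ``scale``
factor so that the whole architecture fits on a desk-scale contig while
preserving its topology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import GeneModel, ReferenceGenome, VectorConstruct, random_dna, revcomp

# Unscaled (real-genome) layout constants, in bases. The two offsets and the
# largest deletion length are the architecture's load-bearing distances; the
# rest position the gene analogs and the two smaller deletions relative to
# the sub-sites.
LEFT_FLANK = 200_000
GENE_LENGTH = 30_000
INTERGENE_GAP = 20_000
SMALL_DEL_1 = (-60_000, -40_000)  # relative to Ins1
SMALL_DEL_2 = (40_000, 60_000)  # relative to Ins2
LARGE_DEL = (100_000, 200_000)  # relative to Ins2
AK_GENE = (130_000, 160_000)  # relative to Ins2, inside LARGE_DEL
RIGHT_FLANK = 200_000


class ArchitectureError(ValueError):
    """Raised when an insertion architecture cannot be realized."""


@dataclass(frozen=True)
class InsertionArchitecture:
    """Parameters of the two-sub-site insertion locus.

    Distances (``ins1_offset``, ``ins2_offset``, deletion coordinates above)
    are stated in real-genome bases and multiplied by ``scale`` when the
    layout is realized; the default ``scale=0.05`` maps 250 kb / 100 kb /
    100 kb to 12.5 kb / 5 kb / 5 kb.
    """

    scale: float = 0.05
    ins1_offset: int = 100_000
    ins2_offset: int = 250_000
    ins2_copies: int = 5
    ins2_orientations: str | None = None
    include_ins1: bool = True
    include_deletions: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.scale <= 1):
            raise ArchitectureError(f"scale must be in (0, 1], got {self.scale}")
        if self.ins2_copies < 1:
            raise ArchitectureError("ins2_copies must be >= 1")
        if self.ins2_orientations is not None:
            if len(self.ins2_orientations) != self.ins2_copies:
                raise ArchitectureError("ins2_orientations length must equal ins2_copies")
            if set(self.ins2_orientations) - set("+-"):
                raise ArchitectureError("orientations must be over {+,-}")

    @property
    def orientations(self) -> str:
        return self.ins2_orientations or "+" * self.ins2_copies

    def _s(self, x: float) -> int:
        # scale and snap to a 100 b grid for tidy coordinates
        return int(round(x * self.scale / 100.0)) * 100

    def layout(self, contig_length: int, contig: str = "chr1") -> "Layout":
        """Realize the architecture on a contig of ``contig_length`` bases."""
        s = self._s
        ins1_pos = s(LEFT_FLANK)
        d_start = ins1_pos + s(self.ins1_offset)
        tfap2d = GeneModel("tfap2d_analog", contig, d_start, d_start + s(GENE_LENGTH), "-")
        b_start = tfap2d.end + s(INTERGENE_GAP)
        tfap2b = GeneModel("tfap2b_analog", contig, b_start, b_start + s(GENE_LENGTH), "+")
        ins2_pos = tfap2b.end + s(self.ins2_offset)
        ak = GeneModel("ak_analog", contig, ins2_pos + s(AK_GENE[0]), ins2_pos + s(AK_GENE[1]), "+")
        deletions: list[tuple[int, int]] = []
        if self.include_deletions:
            deletions = [
                (ins1_pos + s(SMALL_DEL_1[0]), ins1_pos + s(SMALL_DEL_1[1])),
                (ins2_pos + s(SMALL_DEL_2[0]), ins2_pos + s(SMALL_DEL_2[1])),
                (ins2_pos + s(LARGE_DEL[0]), ins2_pos + s(LARGE_DEL[1])),
            ]
        span = ins2_pos + s(LARGE_DEL[1]) + s(RIGHT_FLANK)
        if span > contig_length:
            raise ArchitectureError(
                f"architecture span {span} b (Ins2 at {ins2_pos} + largest deletion "
                f"+ flank) exceeds contig length {contig_length} b; "
                f"reduce scale={self.scale} or enlarge the contig"
            )
        lay = Layout(
            contig=contig,
            contig_length=contig_length,
            ins1_pos=ins1_pos,
            ins2_pos=ins2_pos,
            genes=[tfap2d, tfap2b, ak],
            deletions=deletions,
            architecture=self,
        )
        lay.validate()
        return lay


@dataclass
class Layout:
    """Scaled wild-type coordinates of every architectural feature."""

    contig: str
    contig_length: int
    ins1_pos: int
    ins2_pos: int
    genes: list[GeneModel]
    deletions: list[tuple[int, int]]
    architecture: InsertionArchitecture

    def validate(self) -> None:
        ivs = sorted(self.deletions)
        for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
            if b1 > a2:
                raise ArchitectureError(f"deletions overlap: [{a1},{b1}) and [{a2},{b2})")
        for a, b in ivs:
            if not (0 <= a < b <= self.contig_length):
                raise ArchitectureError(f"deletion [{a},{b}) outside contig")
            for p, name in ((self.ins1_pos, "Ins1"), (self.ins2_pos, "Ins2")):
                if a <= p < b:
                    raise ArchitectureError(f"{name} point {p} inside deletion [{a},{b})")
        if self.deletions:
            la, lb = max(self.deletions, key=lambda iv: iv[1] - iv[0])
            ak = next(g for g in self.genes if g.name == "ak_analog")
            if not (la <= ak.start and ak.end <= lb):
                raise ArchitectureError("largest deletion must contain ak_analog")

    @property
    def largest_deletion(self) -> tuple[int, int]:
        return max(self.deletions, key=lambda iv: iv[1] - iv[0])


def build_wt_reference(
    contig_length: int,
    architecture: InsertionArchitecture,
    seed: int | np.random.Generator = 0,
    contig: str = "chr1",
) -> ReferenceGenome:
    """Seeded uniform-random wild-type contig with the gene analogs placed.

    The annotation coordinates depend only on the architecture (not the
    seed), so different seeds give different sequence over identical
    layouts.
    """
    lay = architecture.layout(contig_length, contig)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return ReferenceGenome(
        contigs={contig: random_dna(contig_length, rng)},
        annotations=list(lay.genes),
    )


@dataclass
class JunctionTruth:
    """One insertion sub-site: its wild-type position and vector payload.

    ``homology`` is the micro-homology interval ``(back, fwd)``: the
    junction can be placed anywhere in ``[wt_pos - back, wt_pos + fwd]``
    without changing the transgenic sequence, because the inserted
    sequence coincidentally matches the flanking reference there. A
    breakpoint call inside this interval is exact by construction.
    """

    name: str
    wt_pos: int  # insertion is between wt_pos-1 and wt_pos (left-breakpoint = wt_pos)
    vector_interval: tuple[int, int]
    orientations: str
    copies: int
    homology: tuple[int, int] = (0, 0)

    def breakpoint_error(self, called_pos: int) -> int:
        """Distance from a called breakpoint to the homology interval."""
        lo = self.wt_pos - self.homology[0]
        hi = self.wt_pos + self.homology[1]
        return max(0, lo - called_pos, called_pos - hi)


@dataclass
class Liftover:
    """Piecewise-affine map between wild-type and transgenic coordinates.

    Stored as the kept wild-type segments ``[wt_start, wt_end)`` and the
    transgenic offset of each; a bijection outside deleted/inserted
    segments.
    """

    wt_starts: list[int]
    wt_ends: list[int]
    tg_starts: list[int]

    def wt_to_tg(self, pos: int) -> int | None:
        i = np.searchsorted(self.wt_starts, pos, side="right") - 1
        if i < 0 or pos >= self.wt_ends[i]:
            return None
        return self.tg_starts[i] + (pos - self.wt_starts[i])

    def tg_to_wt(self, pos: int) -> int | None:
        for ws, we, ts in zip(self.wt_starts, self.wt_ends, self.tg_starts):
            if ts <= pos < ts + (we - ws):
                return ws + (pos - ts)
        return None


@dataclass
class TruthSet:
    """Machine-readable ground truth emitted by the simulator.

    Consumed only by tests and truth-comparison tooling; the callers never
    see it.
    """

    contig: str
    ins1: JunctionTruth | None
    ins2: JunctionTruth
    deletions: list[tuple[int, int]]
    liftover: Liftover
    wt_length: int
    tg_length: int
    scale: float

    @property
    def junction_positions(self) -> list[int]:
        pos = [self.ins2.wt_pos]
        if self.ins1 is not None:
            pos.insert(0, self.ins1.wt_pos)
        return pos

    def to_json(self, path: str | Path) -> None:
        def jt(j: JunctionTruth | None):
            if j is None:
                return None
            return {
                "name": j.name,
                "wt_pos": j.wt_pos,
                "vector_interval": list(j.vector_interval),
                "orientations": j.orientations,
                "copies": j.copies,
                "homology": list(j.homology),
            }

        payload = {
            "contig": self.contig,
            "ins1": jt(self.ins1),
            "ins2": jt(self.ins2),
            "deletions": [list(d) for d in self.deletions],
            "liftover": {
                "wt_starts": self.liftover.wt_starts,
                "wt_ends": self.liftover.wt_ends,
                "tg_starts": self.liftover.tg_starts,
            },
            "wt_length": self.wt_length,
            "tg_length": self.tg_length,
            "scale": self.scale,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        d = json.loads(Path(path).read_text())

        def jt(x):
            if x is None:
                return None
            return JunctionTruth(
                x["name"],
                x["wt_pos"],
                tuple(x["vector_interval"]),
                x["orientations"],
                x["copies"],
                tuple(x.get("homology", (0, 0))),
            )

        return cls(
            contig=d["contig"],
            ins1=jt(d["ins1"]),
            ins2=jt(d["ins2"]),
            deletions=[tuple(x) for x in d["deletions"]],
            liftover=Liftover(**d["liftover"]),
            wt_length=d["wt_length"],
            tg_length=d["tg_length"],
            scale=d["scale"],
        )


def apply_architecture(
    ref: ReferenceGenome,
    vector: VectorConstruct,
    architecture: InsertionArchitecture,
    contig: str = "chr1",
) -> tuple[str, TruthSet]:
    """Build the transgenic haplotype and its truth set.

    Walks the wild-type contig left to right, excising each deletion and
    depositing the Ins1 fragment and the Ins2 concatemer at their scaled
    positions. Satisfies the length identity
    ``|tg| = |wt| - sum(deletions) + copies * |vector| + |ins1_fragment|``.
    """
    wt = ref.contigs[contig]
    lay = architecture.layout(len(wt), contig)

    concatemer = "".join(
        vector.sequence if o == "+" else revcomp(vector.sequence)
        for o in architecture.orientations
    )
    events: list[tuple[int, int, str]] = [(a, b, "") for a, b in lay.deletions]
    if architecture.include_ins1:
        events.append((lay.ins1_pos, lay.ins1_pos, vector.ins1_sequence))
    events.append((lay.ins2_pos, lay.ins2_pos, concatemer))
    events.sort()

    pieces: list[str] = []
    wt_starts: list[int] = []
    wt_ends: list[int] = []
    tg_starts: list[int] = []
    cur = 0
    tg_len = 0
    for a, b, ins in events:
        if a < cur:
            raise ArchitectureError("overlapping architecture events")
        seg = wt[cur:a]
        pieces.append(seg)
        wt_starts.append(cur)
        wt_ends.append(a)
        tg_starts.append(tg_len)
        tg_len += len(seg)
        pieces.append(ins)
        tg_len += len(ins)
        cur = b
    seg = wt[cur:]
    pieces.append(seg)
    wt_starts.append(cur)
    wt_ends.append(len(wt))
    tg_starts.append(tg_len)
    tg_len += len(seg)

    tg = "".join(pieces)
    assert len(tg) == tg_len

    def _homology(pos: int, insert: str) -> tuple[int, int]:
        # bases the junction can shift without changing the haplotype:
        # forward while the insert's head matches the reference after pos,
        # backward while its tail matches the reference before pos
        fwd = 0
        while fwd < len(insert) and pos + fwd < len(wt) and insert[fwd] == wt[pos + fwd]:
            fwd += 1
        back = 0
        while back < len(insert) and pos - back - 1 >= 0 and insert[-1 - back] == wt[pos - back - 1]:
            back += 1
        return (back, fwd)

    ins1 = None
    if architecture.include_ins1:
        ins1 = JunctionTruth(
            "Ins1",
            lay.ins1_pos,
            vector.ins1_fragment,
            "+",
            1,
            homology=_homology(lay.ins1_pos, vector.ins1_sequence),
        )
    ins2 = JunctionTruth(
        "Ins2",
        lay.ins2_pos,
        (0, len(vector)),
        architecture.orientations,
        architecture.ins2_copies,
        homology=_homology(lay.ins2_pos, concatemer),
    )
    truth = TruthSet(
        contig=contig,
        ins1=ins1,
        ins2=ins2,
        deletions=list(lay.deletions),
        liftover=Liftover(wt_starts, wt_ends, tg_starts),
        wt_length=len(wt),
        tg_length=len(tg),
        scale=architecture.scale,
    )
    return tg, truth
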