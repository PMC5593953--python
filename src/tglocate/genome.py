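"""Reference sequences, gene annotations and the transgene construct.

All intervals are 0-based, half-open ``[start, end)``; strands are ``"+"``
or ``"-"``. Sequences are plain upper-case ``str`` over the DNA alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA = "ACGT"
VECTOR_CONTIG = "vector"

_COMPLEMENT = str.maketrans("ACGTacgtN", "TGCAtgcaN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(length: int, rng: np.random.Generator) -> str:
    """Uniform random DNA string of ``length`` bases."""
    return "".join(np.array(list(DNA))[rng.integers(0, 4, size=length)])


@dataclass(frozen=True)
class GeneModel:
    """A gene analog placed on the synthetic contig."""

    name: str
    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad gene interval {self.name}: [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class VectorConstruct:
    """The transgenic cloning vector: a ~7 kb cassette.

    ``ins1_fragment`` is the sub-interval of the vector that is deposited
    on its own at the small insertion sub-site (517 b by default); the
    full-length vector forms the concatemer at the large sub-site.
    """

    sequence: str
    name: str = VECTOR_CONTIG
    ins1_fragment: tuple[int, int] = (3000, 3517)

    def __post_init__(self) -> None:
        lo, hi = self.ins1_fragment
        if not (0 <= lo < hi <= len(self.sequence)):
            raise ValueError(
                f"ins1_fragment [{lo}, {hi}) outside vector of length {len(self.sequence)}"
            )
        if set(self.sequence) - set(DNA):
            raise ValueError("vector sequence must be over {A,C,G,T}")

    @classmethod
    def random(
        cls,
        length: int = 7000,
        ins1_fragment: tuple[int, int] | None = None,
        seed: int | np.random.Generator = 0,
    ) -> "VectorConstruct":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        if ins1_fragment is None:
            start = min(3000, max(0, length - 517))
            ins1_fragment = (start, start + min(517, length))
        return cls(sequence=random_dna(length, rng), ins1_fragment=ins1_fragment)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def ins1_sequence(self) -> str:
        lo, hi = self.ins1_fragment
        return self.sequence[lo:hi]


@dataclass
class ReferenceGenome:
    """Named contigs plus gene annotations.

    The composite reference used for mapping is a ``ReferenceGenome`` whose
    contigs include both the genomic contig and the ``vector`` contig.
    """

    contigs: dict[str, str]
    annotations: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        for gene in self.annotations:
            if gene.contig not in self.contigs:
                raise ValueError(f"gene {gene.name} on unknown contig {gene.contig}")
            if gene.end > len(self.contigs[gene.contig]):
                raise ValueError(f"gene {gene.name} outside contig {gene.contig}")

    def with_vector(self, vector: VectorConstruct) -> "ReferenceGenome":
        """Composite reference: genome contigs plus the vector contig."""
        contigs = dict(self.contigs)
        contigs[vector.name] = vector.sequence
        return ReferenceGenome(contigs=contigs, annotations=list(self.annotations))

    def gene(self, name: str) -> GeneModel:
        for g in self.annotations:
            if g.name == name:
                return g
        raise KeyError(name)

    # ------------------------------------------------------------------ I/O

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in self.contigs.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        contigs = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
        }
        if not contigs:
            raise ValueError(f"no sequences in {path}")
        return cls(contigs=contigs)

    def to_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, seq in self.contigs.items():
                fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
            for g in self.annotations:
                fh.write(
                    f"{g.contig}\ttglocate\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.name};Name={g.name}\n"
                )


def write_fasta(contigs: Iterable[tuple[str, str]], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs]
    SeqIO.write(records, str(path), "fasta")
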