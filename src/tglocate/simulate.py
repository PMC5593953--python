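"""Paired-end read simulation and F2 breeding-colony simulation.

The read simulator emulates a PCR-free short-insert Illumina library:
150 b paired-end reads from ~550 b fragments, substitution errors only.
Fragments are drawn uniformly from the diploid genome of an animal of the
requested genotype (WT, HET or HOM for the transgenic haplotype), so the
vector contig of a homozygote is covered at ``ins2_copies`` times the
haploid-pair genome depth.

Read names carry truth tags with the grammar
``frag<NNNNNNN>:<hap>:<contig>:<start>:<end>:<strand>`` where ``hap`` is
``wt`` or ``tg`` and ``start``/``end`` are the fragment's 0-based
half-open coordinates on that haplotype. The tags exist for tests and
truth comparison only; the mapper and callers never parse them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

from .genome import revcomp
from .segregation import TransmissionTable

QUAL_CHAR = "I"  # constant Q40; the simulator's error model is flat


class Genotype(enum.Enum):
    WT = "WT"
    HET = "HET"
    HOM = "HOM"


@dataclass(frozen=True)
class ReadSimParams:
    """Sequencing-library parameters.

    ``depth`` is the target depth of the diploid genome (total sequenced
    bases / wild-type contig length).
    """

    read_length: int = 150
    insert_mean: int = 550
    insert_sd: int = 60
    error_rate: float = 0.002
    depth: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length > self.insert_mean:
            raise ValueError("read_length must be <= insert_mean")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")


@dataclass
class ReadPairs:
    """In-memory paired reads; serializable as two Phred+33 FASTQ files."""

    names: list[str]
    r1: list[str]
    r2: list[str]
    read_length: int

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[tuple[str, str, str]]:
        return iter(zip(self.names, self.r1, self.r2))

    def write_fastq(self, path1: str | Path, path2: str | Path) -> None:
        q = QUAL_CHAR * self.read_length
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for name, s1, s2 in self:
                f1.write(f"@{name}/1\n{s1}\n+\n{q[: len(s1)]}\n")
                f2.write(f"@{name}/2\n{s2}\n+\n{q[: len(s2)]}\n")

    @classmethod
    def from_fastq(cls, path1: str | Path, path2: str | Path) -> "ReadPairs":
        from Bio import SeqIO

        def load(path):
            names, seqs = [], []
            for rec in SeqIO.parse(str(path), "fastq"):
                name = rec.id
                if name.endswith("/1") or name.endswith("/2"):
                    name = name[:-2]
                names.append(name)
                seqs.append(str(rec.seq).upper())
            return names, seqs

        n1, s1 = load(path1)
        n2, s2 = load(path2)
        if len(n1) != len(n2):
            raise ValueError(f"mate count mismatch: {len(n1)} vs {len(n2)}")
        for a, b in zip(n1, n2):
            if a != b:
                raise ValueError(f"mate name mismatch: {a!r} vs {b!r}")
        rl = max((len(s) for s in s1), default=0)
        return cls(names=n1, r1=s1, r2=s2, read_length=rl)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _apply_errors(seqs: list[str], error_rate: float, rng: np.random.Generator) -> list[str]:
    if error_rate == 0:
        return seqs
    lengths = np.array([len(s) for s in seqs])
    n_err = rng.binomial(lengths, error_rate)
    out = seqs
    for i in np.nonzero(n_err)[0]:
        arr = bytearray(seqs[i], "ascii")
        pos = rng.choice(len(arr), size=n_err[i], replace=False)
        for p in pos:
            # substitute with one of the three other bases
            old = arr[p]
            choices = [b for b in _BASES if b != old]
            arr[p] = choices[rng.integers(0, len(choices))]
        out[i] = arr.decode("ascii")
    return out


def simulate_reads(
    wt_haplotype: str,
    tg_haplotype: str | None,
    genotype: Genotype,
    params: ReadSimParams,
    contig: str = "chr1",
) -> ReadPairs:
    """Draw seeded paired-end reads from the diploid genome of one animal.

    Fragment lengths are Normal(insert_mean, insert_sd) truncated below at
    the read length; HET animals contribute each haplotype with
    probability 1/2 per fragment.
    """
    if genotype is not Genotype.WT and tg_haplotype is None:
        raise ValueError(f"genotype {genotype.value} requires a transgenic haplotype")
    rng = np.random.default_rng(params.seed)
    rl = params.read_length
    n_pairs = int(round(params.depth * len(wt_haplotype) / (2 * rl)))

    if genotype is Genotype.WT:
        hap_idx = np.zeros(n_pairs, dtype=np.int8)
    elif genotype is Genotype.HOM:
        hap_idx = np.ones(n_pairs, dtype=np.int8)
    else:
        # fragments are sampled in proportion to DNA mass, so the longer
        # (insertion-bearing) haplotype contributes proportionally more
        # fragments and per-base coverage stays equal across haplotypes
        p_tg = len(tg_haplotype) / (len(wt_haplotype) + len(tg_haplotype))
        hap_idx = (rng.random(n_pairs) < p_tg).astype(np.int8)

    haps = [wt_haplotype, tg_haplotype or ""]
    hap_lens = np.array([len(h) for h in haps])
    frag_len = np.rint(rng.normal(params.insert_mean, params.insert_sd, size=n_pairs)).astype(int)
    frag_len = np.clip(frag_len, rl, hap_lens[hap_idx])
    max_start = hap_lens[hap_idx] - frag_len
    starts = rng.integers(0, max_start + 1)
    strands = rng.integers(0, 2, size=n_pairs)

    names: list[str] = []
    r1: list[str] = []
    r2: list[str] = []
    hap_tag = ("wt", "tg")
    for i in range(n_pairs):
        h = haps[hap_idx[i]]
        s = int(starts[i])
        e = s + int(frag_len[i])
        fwd = h[s : s + rl]
        rev = revcomp(h[e - rl : e])
        if strands[i] == 0:
            a, b, st = fwd, rev, "+"
        else:
            a, b, st = rev, fwd, "-"
        names.append(f"frag{i:07d}:{hap_tag[hap_idx[i]]}:{contig}:{s}:{e}:{st}")
        r1.append(a)
        r2.append(b)

    r1 = _apply_errors(r1, params.error_rate, rng)
    r2 = _apply_errors(r2, params.error_rate, rng)
    return ReadPairs(names=names, r1=r1, r2=r2, read_length=rl)


def simulate_colony(
    n_offspring: int,
    penetrance: float,
    seed: int | np.random.Generator = 0,
    label: str = "simulated",
) -> TransmissionTable:
    """One het x het cross: 1:2:1 genotypes, glaucoma only in homozygotes.

    Each offspring's genotype is Multinomial(1/4 WT, 1/2 HET, 1/4 HOM);
    a homozygote is glaucomatous with probability ``penetrance``. The
    returned table pools non-glaucomatous heterozygotes and homozygotes as
    transgene-positive normals, mirroring a presence/absence PCR assay
    that cannot distinguish zygosity.
    """
    if n_offspring <= 0:
        raise ValueError("n_offspring must be > 0")
    if not (0 <= penetrance <= 1):
        raise ValueError("penetrance must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_wt, n_het, n_hom = rng.multinomial(n_offspring, [0.25, 0.5, 0.25])
    n_glau = rng.binomial(n_hom, penetrance)
    return TransmissionTable(
        label=label,
        n_neg=int(n_wt),
        n_pos_normal=int(n_het + n_hom - n_glau),
        n_pos_glaucoma=int(n_glau),
    )
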