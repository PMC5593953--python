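"""Minimal seed-and-extend read mapper over a composite reference.

The index stores every k-mer of the forward strand of each contig
(including the ``vector`` contig); queries probe both orientations of the
read. Seed hits vote for a diagonal (placement offset) and each candidate
placement is verified by ungapped extension: the maximum-scoring
contiguous segment (match +1, mismatch -3) of the read against the
reference, which naturally soft-clips read ends that overhang a junction
or a contig end. A placement is *unique* when no other candidate locus
comes within a configured score margin; only unique placements feed the
insertion caller, mirroring a uniquely-mapped-reads filter.

Gapped alignment is deliberately out of scope: the simulator's error
model is substitution-only and external alignments can be ingested as
SAM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome import ReferenceGenome, revcomp

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A=0,C=1,G=2,T=3; 255 for non-ACGT)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class MapParams:
    """Mapper and pair-classification parameters."""

    k: int = 21
    seed_step: int = 10
    margin: int = 2  # score units separating best from second-best for uniqueness
    max_mismatch_rate: float = 0.1
    min_aligned: int = 30
    mismatch_penalty: int = 3
    max_seed_hits: int = 128  # repeat filter: seeds with more hits are skipped
    max_keep: int = 4
    insert_mean: int = 550
    insert_sd: int = 60
    insert_sd_mult: float = 4.0  # concordant insert range = mean +/- mult * sd
    min_clip: int = 20  # minimum soft-clip length considered split-read evidence

    def __post_init__(self) -> None:
        if not (11 <= self.k <= 31):
            raise ValueError(f"k must be in [11, 31], got {self.k}")

    @property
    def insert_bounds(self) -> tuple[int, int]:
        lo = self.insert_mean - self.insert_sd_mult * self.insert_sd
        hi = self.insert_mean + self.insert_sd_mult * self.insert_sd
        return (max(0, int(lo)), int(hi))


@dataclass
class AlignmentRecord:
    """One placement of one mate on the composite reference.

    ``seq`` is stored in reference-forward orientation (already
    reverse-complemented for ``-`` strand placements, as in SAM). ``clip5``
    and ``clip3`` count soft-clipped bases at the reference-forward 5' and
    3' ends; ``clip5 + aligned_len + clip3 == len(seq)``.
    """

    __slots__ = ("qname", "mate", "contig", "pos", "strand", "clip5", "clip3", "nm", "score", "unique", "seq")

    qname: str
    mate: int
    contig: str
    pos: int
    strand: str
    clip5: int
    clip3: int
    nm: int
    score: int
    unique: bool
    seq: str

    @property
    def read_length(self) -> int:
        return len(self.seq)

    @property
    def aligned_len(self) -> int:
        return len(self.seq) - self.clip5 - self.clip3

    @property
    def end(self) -> int:
        return self.pos + self.aligned_len

    @property
    def cigar(self) -> str:
        parts = []
        if self.clip5:
            parts.append(f"{self.clip5}S")
        parts.append(f"{self.aligned_len}M")
        if self.clip3:
            parts.append(f"{self.clip3}S")
        return "".join(parts)


class SeedIndex:
    """Sorted k-mer index over all contigs of a composite reference."""

    def __init__(self, contigs: dict[str, str], k: int = 21):
        if not (11 <= k <= 31):
            raise ValueError(f"k must be in [11, 31], got {k}")
        if not contigs:
            raise ValueError("empty reference")
        self.k = k
        self.names: list[str] = list(contigs)
        self.codes: list[np.ndarray] = [encode(contigs[n]) for n in self.names]
        self.lengths = np.array([len(c) for c in self.codes], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(self.lengths)])
        self.global_codes = (
            np.concatenate(self.codes) if self.codes else np.empty(0, np.uint8)
        )
        self._powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)

        hashes, positions, cids = [], [], []
        for ci, codes in enumerate(self.codes):
            if len(codes) < k:
                continue
            win = np.lib.stride_tricks.sliding_window_view(codes, k)
            bad = np.cumsum(np.concatenate([[0], (codes > 3).astype(np.int64)]))
            valid = (bad[k:] - bad[:-k]) == 0
            h = win.astype(np.int64) @ self._powers
            idx = np.flatnonzero(valid)
            hashes.append(h[idx])
            positions.append(idx.astype(np.int64))
            cids.append(np.full(idx.size, ci, dtype=np.int16))
        if hashes:
            h = np.concatenate(hashes)
            order = np.argsort(h, kind="stable")
            self.sorted_hash = h[order]
            self.sorted_pos = np.concatenate(positions)[order]
            self.sorted_cid = np.concatenate(cids)[order]
        else:
            self.sorted_hash = np.empty(0, np.int64)
            self.sorted_pos = np.empty(0, np.int64)
            self.sorted_cid = np.empty(0, np.int16)

    @classmethod
    def from_reference(cls, ref: ReferenceGenome, k: int = 21) -> "SeedIndex":
        return cls(ref.contigs, k=k)

    @property
    def n_positions(self) -> int:
        return int(self.sorted_hash.size)

    def contig_id(self, name: str) -> int:
        return self.names.index(name)

    def lookup(self, h: int) -> tuple[int, int]:
        lo = int(np.searchsorted(self.sorted_hash, h, side="left"))
        hi = int(np.searchsorted(self.sorted_hash, h, side="right"))
        return lo, hi


def _seed_offsets(read_len: int, k: int, step: int) -> list[int]:
    offs = list(range(0, read_len - k + 1, step))
    if offs and offs[-1] != read_len - k:
        offs.append(read_len - k)
    return offs


def _extend(
    codes: np.ndarray,
    strand: int,
    cid: int,
    diag: int,
    index: SeedIndex,
    params: MapParams,
) -> tuple | None:
    """Ungapped extension of one candidate diagonal.

    Returns ``(cid, pos, strand, clip5, clip3, nm, score)`` for the
    maximum-scoring contiguous segment, or None if it fails the length or
    mismatch-rate filters.
    """
    L = codes.size
    clen = int(index.lengths[cid])
    i0 = max(0, -diag)
    i1 = min(L, clen - diag)
    if i1 - i0 < params.min_aligned:
        return None
    ref_slice = index.codes[cid][diag + i0 : diag + i1]
    m = codes[i0:i1] == ref_slice
    v = np.where(m, 1, -params.mismatch_penalty).astype(np.int64)
    s = np.cumsum(v)
    prefix = np.concatenate([[0], s])
    prev_min = np.minimum.accumulate(prefix[:-1])
    end_scores = s - prev_min
    e_rel = int(np.argmax(end_scores))
    score = int(end_scores[e_rel])
    b_rel = e_rel + 1
    a_rel = int(np.argmin(prefix[:b_rel]))
    aligned = b_rel - a_rel
    if aligned < params.min_aligned:
        return None
    nm = int(np.count_nonzero(~m[a_rel:b_rel]))
    if nm > params.max_mismatch_rate * aligned:
        return None
    a = i0 + a_rel
    b = i0 + b_rel
    return (cid, diag + a, strand, a, L - b, nm, score)


def _materialize(
    qname: str,
    mate: int,
    oriented: Sequence[str],
    placements: list[tuple],
    index: SeedIndex,
    params: MapParams,
) -> list[AlignmentRecord]:
    """Rank placements, set the uniqueness flag, build records."""
    if not placements:
        return []
    placements.sort(key=lambda t: (-t[6], t[0], t[1], t[2]))
    best = placements[0][6]
    second = placements[1][6] if len(placements) > 1 else None
    unique = second is None or best - second >= params.margin
    out = []
    for cid, pos, strand, clip5, clip3, nm, score in placements[: params.max_keep]:
        out.append(
            AlignmentRecord(
                qname=qname,
                mate=mate,
                contig=index.names[cid],
                pos=int(pos),
                strand="+-"[strand],
                clip5=int(clip5),
                clip3=int(clip3),
                nm=int(nm),
                score=int(score),
                unique=False,
                seq=oriented[strand],
            )
        )
    out[0].unique = unique
    return out


def align_read(
    seq: str,
    index: SeedIndex,
    params: MapParams = MapParams(),
    qname: str = "read",
    mate: int = 1,
) -> list[AlignmentRecord]:
    """Align one read; returns best-scoring placements (possibly empty)."""
    seq = seq.upper()
    if len(seq) < index.k:
        return []
    oriented = [seq, revcomp(seq)]
    coded = [encode(s) for s in oriented]
    cands: set[tuple[int, int, int]] = set()
    for strand in (0, 1):
        codes = coded[strand]
        for off in _seed_offsets(len(seq), index.k, params.seed_step):
            win = codes[off : off + index.k]
            if (win > 3).any():
                continue
            h = int(win.astype(np.int64) @ index._powers)
            lo, hi = index.lookup(h)
            if hi - lo > params.max_seed_hits:
                continue
            for j in range(lo, hi):
                cands.add(
                    (strand, int(index.sorted_cid[j]), int(index.sorted_pos[j]) - off)
                )
    placements = []
    seen = set()
    for strand, cid, diag in sorted(cands):
        r = _extend(coded[strand], strand, cid, diag, index, params)
        if r is None:
            continue
        key = (r[0], r[1], r[2])  # same final placement can arise from shifted diagonals
        if key in seen:
            continue
        seen.add(key)
        placements.append(r)
    return _materialize(qname, mate, oriented, placements, index, params)


def _expand_ranges(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expand [lo_i, hi_i) ranges into (owner_index, flat_position) arrays."""
    counts = hi - lo
    keep = np.flatnonzero(counts > 0)
    counts = counts[keep]
    owners = np.repeat(keep, counts)
    total = int(counts.sum())
    # flat positions: lo[owner] + within-range offset
    starts = np.repeat(lo[keep], counts)
    csum = np.concatenate([[0], np.cumsum(counts)])
    within = np.arange(total) - np.repeat(csum[:-1], counts)
    return owners, starts + within


def align_reads_batch(
    seqs: Sequence[str],
    index: SeedIndex,
    params: MapParams = MapParams(),
    qnames: Sequence[str] | None = None,
    mate: int = 1,
) -> list[list[AlignmentRecord]]:
    """Vectorized alignment of many same-length reads.

    Candidate placements that fit entirely inside a contig are verified by
    a single vectorized full-length mismatch count; candidates that fail
    (junction-spanning reads, contig-edge reads, high-error reads) fall
    back to the per-read extension used by :func:`align_read`. Results are
    identical to mapping each read with :func:`align_read` up to ties
    broken by score ordering.
    """
    n = len(seqs)
    if qnames is None:
        qnames = [f"read{i}" for i in range(n)]
    results: list[list[AlignmentRecord]] = [[] for _ in range(n)]
    if n == 0:
        return results

    lengths = np.array([len(s) for s in seqs])
    L = int(np.bincount(lengths).argmax()) if n else 0
    uniform = np.flatnonzero(lengths == L)
    odd = np.flatnonzero(lengths != L)
    for i in odd:
        results[i] = align_read(seqs[i], index, params, qnames[i], mate)
    if uniform.size == 0 or L < index.k:
        for i in uniform:
            results[i] = align_read(seqs[i], index, params, qnames[i], mate)
        return results

    mat = np.empty((uniform.size, L), dtype=np.uint8)
    for row, i in enumerate(uniform):
        mat[row] = encode(seqs[i])
    dirty = np.flatnonzero((mat > 3).any(axis=1))
    for row in dirty:
        i = uniform[row]
        results[i] = align_read(seqs[i], index, params, qnames[i], mate)
    clean = np.setdiff1d(np.arange(uniform.size), dirty, assume_unique=True)
    if clean.size == 0:
        return results
    mat = mat[clean]
    rows = uniform[clean]  # original read index per matrix row
    m = mat.shape[0]
    mats = [mat, (3 - mat)[:, ::-1]]  # forward, reverse-complement

    offs = _seed_offsets(L, index.k, params.seed_step)
    cand_codes: list[np.ndarray] = []
    ncontig = len(index.names)
    # int64 packing: (row * 2 + strand) * ncontig + cid, then diagonal
    for strand in (0, 1):
        cmat = mats[strand]
        for off in offs:
            h = cmat[:, off : off + index.k].astype(np.int64) @ index._powers
            lo = np.searchsorted(index.sorted_hash, h, side="left")
            hi = np.searchsorted(index.sorted_hash, h, side="right")
            hi = np.where(hi - lo > params.max_seed_hits, lo, hi)
            owners, flat = _expand_ranges(lo, hi)
            if owners.size == 0:
                continue
            diag = index.sorted_pos[flat] - off
            cid = index.sorted_cid[flat].astype(np.int64)
            code = ((owners * 2 + strand) * ncontig + cid) * (2 * L + int(index.lengths.max())) + (
                diag + L
            )
            cand_codes.append(code)
    if not cand_codes:
        return results
    codes_u = np.unique(np.concatenate(cand_codes))
    span = 2 * L + int(index.lengths.max())
    diag = (codes_u % span) - L
    rest = codes_u // span
    cid = rest % ncontig
    rest //= ncontig
    strand = rest % 2
    row = rest // 2

    # fast path: perfect full-length in-contig placements (provably the
    # ungapped-extension optimum); everything else goes through the same
    # per-candidate extension align_read uses, so both paths agree exactly
    in_bounds = (diag >= 0) & (diag + L <= index.lengths[cid])
    fast = np.flatnonzero(in_bounds)
    chunk = 200_000
    accept_parts = []
    for c0 in range(0, fast.size, chunk):
        sel = fast[c0 : c0 + chunk]
        base = index.offsets[cid[sel]] + diag[sel]
        gathered = index.global_codes[base[:, None] + np.arange(L)]
        # pick the right orientation rows
        reads = np.empty_like(gathered)
        f = strand[sel] == 0
        reads[f] = mat[row[sel][f]]
        reads[~f] = mats[1][row[sel][~f]]
        nm = (gathered != reads).sum(axis=1)
        ok = nm == 0
        k_sel = sel[ok]
        accept_parts.append(
            np.stack(
                [
                    row[k_sel],
                    cid[k_sel],
                    diag[k_sel],
                    strand[k_sel],
                    nm[ok],
                ]
            )
        )
    slow = np.flatnonzero(~in_bounds)
    if accept_parts:
        acc = np.concatenate(accept_parts, axis=1)
        accepted_codes = set(
            zip(acc[0].tolist(), acc[3].tolist(), acc[1].tolist(), acc[2].tolist())
        )
    else:
        acc = np.empty((5, 0), dtype=np.int64)
        accepted_codes = set()
    # in-bounds candidates that failed the full-length check also go to the
    # slow path: they may still yield a clipped alignment
    fast_set = {
        (int(r), int(st), int(ci), int(dg))
        for r, st, ci, dg in zip(row[fast], strand[fast], cid[fast], diag[fast])
    }
    retry = [t for t in fast_set if t not in accepted_codes]
    slow_tuples = [
        (int(row[i]), int(strand[i]), int(cid[i]), int(diag[i])) for i in slow
    ] + retry

    # assemble per-read placement lists
    per_read: dict[int, list[tuple]] = {}
    r_arr, c_arr, d_arr, s_arr, nm_arr = acc
    score_arr = L - (1 + params.mismatch_penalty) * nm_arr
    for i in range(r_arr.size):
        per_read.setdefault(int(r_arr[i]), []).append(
            (
                int(c_arr[i]),
                int(d_arr[i]),
                int(s_arr[i]),
                0,
                0,
                int(nm_arr[i]),
                int(score_arr[i]),
            )
        )
    slow_cache: dict[int, list[np.ndarray]] = {}
    for r, st, ci, dg in slow_tuples:
        coded = slow_cache.get(r)
        if coded is None:
            coded = [mat[r], mats[1][r]]
            slow_cache[r] = coded
        res = _extend(coded[st], st, ci, dg, index, params)
        if res is not None:
            # drop duplicates of an already-accepted full-length placement
            per_read.setdefault(r, []).append(res)

    for r, placements in per_read.items():
        # dedup placements that converged to the same locus
        seen: set[tuple[int, int, int]] = set()
        uniq = []
        for p in placements:
            key = (p[0], p[1], p[2])
            if key not in seen:
                seen.add(key)
                uniq.append(p)
        i = int(rows[r])
        oriented = (seqs[i].upper(), revcomp(seqs[i].upper()))
        results[i] = _materialize(qnames[i], mate, oriented, uniq, index, params)
    return results


def exhaustive_best_placements(
    seq: str, contigs: dict[str, str], mismatch_penalty: int = 3
) -> list[tuple[str, int, str, int]]:
    """Brute-force oracle: score a full-length ungapped placement of the
    read at every position of every contig and strand; return the list of
    ``(contig, pos, strand, score)`` attaining the maximum.

    Only full-length placements are scored (no clipping), so it is an
    oracle for reads drawn entirely from the reference. Intended for tiny
    references in tests.
    """
    seq = seq.upper()
    L = len(seq)
    best_score = None
    best: list[tuple[str, int, str, int]] = []
    for name, ref in contigs.items():
        refc = encode(ref)
        if refc.size < L:
            continue
        win = np.lib.stride_tricks.sliding_window_view(refc, L)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            codes = encode(s)
            nm = (win != codes).sum(axis=1)
            scores = L - (1 + mismatch_penalty) * nm
            top = int(scores.max())
            if best_score is None or top > best_score:
                best_score = top
                best = []
            if top == best_score:
                for p in np.flatnonzero(scores == top):
                    best.append((name, int(p), strand, top))
    return best
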