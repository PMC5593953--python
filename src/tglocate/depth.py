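"""Windowed read-depth profiles, deletion calling and locus genotyping.

Depth is the quantitative substrate for the copy-number readout: a
hemizygous deletion halves normalized depth (~0.5), a homozygous deletion
removes it (~0), and the 2/1/0-copy genotype of a locus is the rounded
doubled mean normalized depth — the sequencing analog of a categorical
copy-number assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import GeneModel
from .mapper import AlignmentRecord


@dataclass
class DepthProfile:
    """Per-window and per-base depth over one contig.

    ``raw`` is aligned-base count per window divided by the window's true
    width (the final window may be partial); ``norm`` is ``raw`` divided
    by the median raw depth of unmasked windows, so the unmasked median of
    ``norm`` is 1 by construction.
    """

    contig: str
    length: int
    window: int
    starts: np.ndarray
    widths: np.ndarray
    raw: np.ndarray
    coverage: np.ndarray  # per-base aligned-read depth
    start_counts: np.ndarray  # per-base count of alignment starts
    end_counts: np.ndarray  # per-base count of alignment ends (exclusive coord)
    masked: np.ndarray  # per-window bool; excluded from normalization/calling
    norm_factor: float
    norm: np.ndarray

    @property
    def n_windows(self) -> int:
        return int(self.starts.size)

    def mean_norm(self, start: int, end: int) -> float:
        """Mean normalized per-base depth over an interval."""
        if self.norm_factor == 0:
            raise ValueError("undefined depth: normalization factor is 0")
        start = max(0, start)
        end = min(self.length, end)
        if end <= start:
            raise ValueError(f"empty interval [{start}, {end})")
        return float(self.coverage[start:end].mean() / self.norm_factor)


@dataclass
class DeletionCall:
    """A contiguous depth-loss segment with inferred zygosity."""

    contig: str
    start: int
    end: int
    zygosity: str  # 'hom' | 'het'
    mean_norm_depth: float
    n_windows: int
    n_span_pairs: int = 0  # discordant pairs whose stretched insert brackets the call
    edge_support: tuple[int, int] = (0, 0)  # clipped reads pinning each edge
    genes: list[tuple[str, float]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LocusGenotype:
    """Integer copy number of a locus and the genotype class it implies."""

    locus: str
    copies: int  # in {0, 1, 2}
    genotype: str  # 'WT' (2), 'HET' (1), 'HOM' (0)
    mean_norm_depth: float


_COPY_TO_GENOTYPE = {2: "WT", 1: "HET", 0: "HOM"}


def _mask_windows(
    starts: np.ndarray, widths: np.ndarray, intervals: list[tuple[int, int]]
) -> np.ndarray:
    masked = np.zeros(starts.size, dtype=bool)
    ends = starts + widths
    for a, b in intervals:
        masked |= (starts < b) & (ends > a)
    return masked


def compute_depth(
    records: list[AlignmentRecord],
    contig: str,
    contig_length: int,
    window: int = 200,
    mask_intervals: list[tuple[int, int]] | None = None,
    edge_mask: int = 0,
) -> DepthProfile:
    """Aligned-base depth per window from uniquely mapped records.

    ``mask_intervals`` (e.g. insertion flanks) and ``edge_mask`` bases at
    each contig end are excluded from the normalization median and from
    downstream deletion calling; their depth is still computed.
    """
    if contig_length <= 0:
        raise ValueError("contig_length must be > 0")
    on_contig = [r for r in records if r.contig == contig]
    diff = np.zeros(contig_length + 1, dtype=np.int64)
    start_counts = np.zeros(contig_length, dtype=np.int32)
    end_counts = np.zeros(contig_length, dtype=np.int32)
    if on_contig:
        pos = np.array([r.pos for r in on_contig])
        ends = np.array([min(r.end, contig_length) for r in on_contig])
        np.add.at(diff, pos, 1)
        np.add.at(diff, ends, -1)
        np.add.at(start_counts, pos, 1)
        np.add.at(end_counts, np.minimum(ends, contig_length - 1), 1)
    coverage = np.cumsum(diff[:-1])

    starts = np.arange(0, contig_length, window)
    widths = np.minimum(window, contig_length - starts)
    csum = np.concatenate([[0], np.cumsum(coverage)])
    raw = (csum[np.minimum(starts + widths, contig_length)] - csum[starts]) / widths

    intervals = list(mask_intervals or [])
    if edge_mask > 0:
        intervals += [(0, edge_mask), (contig_length - edge_mask, contig_length)]
    masked = _mask_windows(starts, widths, intervals)
    unmasked = raw[~masked]
    norm_factor = float(np.median(unmasked)) if unmasked.size else 0.0
    norm = raw / norm_factor if norm_factor > 0 else np.zeros_like(raw)
    return DepthProfile(
        contig=contig,
        length=contig_length,
        window=window,
        starts=starts,
        widths=widths,
        raw=raw,
        coverage=coverage,
        start_counts=start_counts,
        end_counts=end_counts,
        masked=masked,
        norm_factor=norm_factor,
        norm=norm,
    )


def _refine_edge(
    profile: DepthProfile,
    guess: int,
    core_norm: float,
    left: bool,
    bound: int | None = None,
) -> tuple[int, int]:
    """Move a window-granular deletion edge to the per-base junction.

    Reads crossing an excision junction are soft-clipped at the deletion
    edge, so alignment ends (left edge) or starts (right edge) pile up on
    the breakpoint base (smeared a few bases inward by chance matches
    beyond the junction; piles are aggregated over that range).

    When a spanning-pair ``bound`` is available (the innermost mate
    coordinate of fragments bracketing the deletion) it already sits
    within a few tens of bases of the junction, so the refinement reduces
    to finding the clip pile-up next to it, falling back to the bound
    itself. Without pair evidence the edge comes from pile-ups ranked by
    a two-level changepoint fit of the per-base coverage (diploid
    baseline outside, core depth inside), with the pure fit as the last
    resort. Returns ``(position, pile_support)``.
    """

    def _agg(counts: np.ndarray) -> np.ndarray:
        conv = np.convolve(counts, np.ones(3), mode="full")
        # left edge: ends smear forward from the junction ->
        # agg[x] = counts[x..x+2]; right edge: starts smear backward ->
        # agg[x] = counts[x-2..x]
        return conv[2 : 2 + counts.size] if left else conv[: counts.size]

    pile_src = profile.end_counts if left else profile.start_counts

    if bound is not None:
        # junction-local search: the innermost spanning-mate coordinate is
        # at most one read spacing outside the junction (and a few bases
        # inside it when the alignment absorbed chance-matching bases)
        lo = max(0, bound - 8 if left else bound - 48)
        hi = min(profile.length, bound + 48 if left else bound + 8)
        if hi - lo < 4:
            return min(max(bound, 0), profile.length), 0
        agg = _agg(pile_src[lo:hi].astype(float))
        best = int(np.argmax(agg))
        if agg[best] >= 2:
            return lo + best, int(agg[best])
        return min(max(bound, 0), profile.length), 0

    w = profile.window
    # runs may start/end a couple of noisy windows away from the true edge,
    # so search further inward than outward
    lo = max(0, guess - w if left else guess - 3 * w)
    hi = min(profile.length, guess + 3 * w if left else guess + w)
    if hi - lo < 4:
        return guess, 0
    agg = _agg(pile_src[lo:hi].astype(float))
    cov = profile.coverage[lo:hi].astype(float)
    base = profile.norm_factor
    core = core_norm * profile.norm_factor
    # SSE(p) differences: moving the breakpoint right by one base swaps one
    # residual between the two levels
    if left:
        delta = (cov - base) ** 2 - (cov - core) ** 2
    else:
        delta = (cov - core) ** 2 - (cov - base) ** 2
    sse = np.concatenate([[0.0], np.cumsum(delta)])[: hi - lo]
    for thresh in (3, 2):
        cand = np.flatnonzero(agg >= thresh)
        if cand.size:
            pick = int(cand[np.argmin(sse[cand])])
            return lo + pick, int(agg[pick])
    return lo + int(np.argmin(sse)), 0


def call_deletions(
    profile: DepthProfile,
    hom_max: float = 0.2,
    het_band: tuple[float, float] = (0.3, 0.7),
    min_windows: int = 3,
    min_z: float = 5.0,
    refine: bool = True,
    spanning_gaps: list[tuple[int, int]] | None = None,
    min_span_pairs: int = 2,
) -> list[DeletionCall]:
    """Maximal runs of low-depth windows become deletion calls.

    A run is >= ``min_windows`` consecutive unmasked windows with
    normalized depth below the heterozygous band's upper edge; its
    zygosity comes from the run mean (below the hom/het midpoint ->
    homozygous, within the band -> heterozygous). To suppress chance dips
    of the sampling noise, a run must additionally sit at least ``min_z``
    robust standard deviations (1.4826 x MAD of unmasked window depths)
    below the diploid baseline. Edges are refined to per-base resolution
    when ``refine`` is set.

    ``spanning_gaps`` are the inner gaps ``(left_mate_end, right_mate_start)``
    of discordant pairs with stretched inserts; they are orthogonal
    corroboration for hemizygous calls, whose ~0.5x depth signal noise can
    imitate: a het call is kept only when ``min_span_pairs`` such gaps
    bracket it. Homozygous calls (near-zero depth) need no corroboration.
    """
    het_lo, het_hi = het_band
    candidate = (~profile.masked) & (profile.norm < het_hi)
    # bridge windows sit between the het band and baseline; they may not seed
    # a run but do connect adjacent runs (noise can push one interior window
    # of a true deletion just above the band edge)
    bridge_max = (het_hi + 1.0) / 2.0
    bridge = (~profile.masked) & (profile.norm < bridge_max)
    calls: list[DeletionCall] = []
    idx = np.flatnonzero(candidate)
    if idx.size == 0:
        return calls
    unmasked = profile.norm[~profile.masked]
    sd = 1.4826 * float(np.median(np.abs(unmasked - 1.0))) if unmasked.size else 0.0
    gaps = np.diff(idx)
    joined = np.ones(gaps.size, dtype=bool)
    for j, g in enumerate(gaps):
        joined[j] = g <= 3 and bool(bridge[idx[j] + 1 : idx[j + 1]].all())
    breaks = np.flatnonzero(~joined)
    run_bounds = zip(
        np.concatenate([[0], breaks + 1]), np.concatenate([breaks, [idx.size - 1]])
    )
    hom_cut = (hom_max + het_lo) / 2.0
    for a, b in run_bounds:
        wi = np.arange(idx[a], idx[b] + 1)
        wi = wi[~profile.masked[wi]]
        if wi.size < min_windows:
            continue
        start = int(profile.starts[wi[0]])
        end = int(profile.starts[wi[-1]] + profile.widths[wi[-1]])
        core = float(profile.norm[wi].mean())
        if sd > 0 and (1.0 - core) < min_z * sd / np.sqrt(wi.size):
            continue
        zyg = "hom" if core < hom_cut else "het"
        # a fragment spanning the excised segment maps with its inner gap
        # containing the whole deletion, hence the run's center
        center = (start + end) // 2
        gaps = [(a, b) for a, b in (spanning_gaps or []) if a <= center <= b]
        n_span = len(gaps)
        gl = max((a for a, _ in gaps), default=None)
        gr = min((b for _, b in gaps), default=None)
        sup_l = sup_r = 0
        if refine:
            start, sup_l = _refine_edge(profile, start, core, left=True, bound=gl)
            end, sup_r = _refine_edge(profile, end, core, left=False, bound=gr)
            if end <= start:
                start = int(profile.starts[wi[0]])
                end = int(profile.starts[wi[-1]] + profile.widths[wi[-1]])
        if zyg == "het" and spanning_gaps is not None and n_span < min_span_pairs:
            continue
        calls.append(
            DeletionCall(
                contig=profile.contig,
                start=start,
                end=end,
                zygosity=zyg,
                mean_norm_depth=core,
                n_windows=int(wi.size),
                n_span_pairs=n_span,
                edge_support=(sup_l, sup_r),
            )
        )
    return calls


def genotype_locus_copy_number(profile: DepthProfile, locus: GeneModel) -> LocusGenotype:
    """Round the doubled mean normalized depth over the locus to {0,1,2}."""
    if locus.contig != profile.contig:
        raise ValueError(f"locus {locus.name} is on {locus.contig}, profile on {profile.contig}")
    w0 = locus.start // profile.window
    w1 = min((locus.end - 1) // profile.window + 1, profile.n_windows)
    if bool(profile.masked[w0:w1].all()):
        raise ValueError(f"locus {locus.name} is fully masked; genotype undefined")
    mean = profile.mean_norm(locus.start, locus.end)
    copies = int(np.clip(round(2.0 * mean), 0, 2))
    return LocusGenotype(
        locus=locus.name,
        copies=copies,
        genotype=_COPY_TO_GENOTYPE[copies],
        mean_norm_depth=mean,
    )


def annotate_overlaps(
    calls: list[DeletionCall], genes: list[GeneModel]
) -> list[DeletionCall]:
    """Attach ``(gene, overlap_fraction_of_gene)`` pairs to each call."""
    for call in calls:
        call.genes = []
        for g in genes:
            if g.contig != call.contig:
                continue
            ov = min(call.end, g.end) - max(call.start, g.start)
            if ov > 0:
                call.genes.append((g.name, ov / g.length))
    return calls


def write_bed(calls: list[DeletionCall], path: str | Path) -> None:
    """Deletion calls as BED (0-based half-open) with zygosity and depth."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tzygosity\tmean_norm_depth\tgenes\n")
        for i, c in enumerate(calls, 1):
            genes = ",".join(f"{n}:{f:.2f}" for n, f in c.genes) or "."
            fh.write(
                f"{c.contig}\t{c.start}\t{c.end}\tdel{i}\t{c.zygosity}\t"
                f"{c.mean_norm_depth:.3f}\t{genes}\n"
            )
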