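"""Asymmetry calling for paired single-cell ATAC peak sets.

Two signals distinguish a symmetric from an asymmetric division at the
chromatin level:

* the ratio of mapped-read-adjusted peak counts (peaks per million
  mapped reads) between the daughters — a measure of global chromatin
  accessibility, and
* positional sharing of peaks, tested against a chromosome-controlled
  reshuffling null: each peak of one daughter is re-placed uniformly at
  random within its own chromosome (length and per-chromosome counts
  preserved) and the overlap with the other daughter re-measured.

A pair is asymmetric when the observed overlap is NOT significantly
above the random null (the daughters do not share positions) AND the
adjusted peak-count ratio exceeds a cutoff (default 2).  In an
asymmetric pair the daughter with fewer peaks (lower accessibility) is
the stem cell; symmetric pairs keep two stem daughters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PeakSet",
    "GenomeDef",
    "AtacPairCall",
    "AtacPairCaller",
    "adjusted_peak_count",
    "pair_ratio",
    "overlap_count",
    "reshuffle_null",
    "call_pair",
    "peaks_to_genes",
]


@dataclass(frozen=True)
class GenomeDef:
    """Chromosome name -> length (bp)."""

    sizes: dict[str, int]

    def __post_init__(self):
        if not self.sizes:
            raise ValueError("empty genome definition")
        for name, length in self.sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name}: non-positive length")


@dataclass(frozen=True)
class PeakSet:
    """ATAC peaks of one daughter cell, 0-based half-open coordinates."""

    cell_id: str
    pair_id: str
    slot: str
    intervals: tuple[tuple[str, int, int], ...]
    mapped_reads: int

    def __post_init__(self):
        if self.mapped_reads <= 0:
            raise ValueError("mapped_reads must be positive")
        for chrom, start, end in self.intervals:
            if start < 0 or start >= end:
                raise ValueError(f"bad interval {chrom}:{start}-{end}")

    @property
    def n_peaks(self) -> int:
        return len(self.intervals)

    def by_chromosome(self) -> dict[str, np.ndarray]:
        """Sorted (n, 2) start/end arrays per chromosome."""
        out: dict[str, list] = {}
        for chrom, s, e in self.intervals:
            out.setdefault(chrom, []).append((s, e))
        return {c: np.array(sorted(v), dtype=np.int64) for c, v in out.items()}


@dataclass
class AtacPairCall:
    pair_id: str
    adjusted_ratio: float
    observed_overlap: int
    null_mean_overlap: float
    empirical_p: float
    call: str  # "asymmetric" | "symmetric"
    roles: dict[str, str]  # cell_id -> "stem" | "progenitor"
    observed_overlap_ba: int = 0
    ratio_infinite: bool = False


def adjusted_peak_count(ps: PeakSet) -> float:
    """Peaks per million mapped reads."""
    return 1e6 * ps.n_peaks / ps.mapped_reads


def pair_ratio(a: PeakSet, b: PeakSet) -> tuple[float, str, bool]:
    """Oriented adjusted peak-count ratio >= 1.

    Returns (ratio, cell_id of the higher-count daughter, infinite_flag);
    a zero-peak daughter yields an infinite ratio with the flag set.
    """
    ca, cb = adjusted_peak_count(a), adjusted_peak_count(b)
    hi_cell = a.cell_id if ca >= cb else b.cell_id
    lo = min(ca, cb)
    hi = max(ca, cb)
    if lo == 0:
        return math.inf, hi_cell, True
    return hi / lo, hi_cell, False


def _merge(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge sorted intervals into disjoint (starts, ends)."""
    starts, ends = [], []
    cur_s, cur_e = int(arr[0, 0]), int(arr[0, 1])
    for s, e in arr[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, int(e))
        else:
            starts.append(cur_s)
            ends.append(cur_e)
            cur_s, cur_e = int(s), int(e)
    starts.append(cur_s)
    ends.append(cur_e)
    return np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64)


def _count_overlapping(query: np.ndarray, ref_starts: np.ndarray,
                       ref_ends: np.ndarray, min_overlap: int) -> int:
    """Number of query intervals overlapping the merged reference by at
    least ``min_overlap`` bp (vectorized sweep via binary search)."""
    if len(query) == 0 or len(ref_starts) == 0:
        return 0
    qs, qe = query[:, 0], query[:, 1]
    # candidate merged interval: the last one starting before the query end
    idx = np.searchsorted(ref_starts, qe - min_overlap, side="right") - 1
    valid = idx >= 0
    ov = np.zeros(len(qs), dtype=bool)
    if valid.any():
        i = idx[valid]
        # overlap length with candidate; merged intervals are disjoint so a
        # query overlapping any reference overlaps the candidate or one
        # further left only if it also spans; spanning is covered because
        # merged intervals are separated by gaps and the candidate is the
        # rightmost starting at or before the query end.
        lo = np.maximum(qs[valid], ref_starts[i])
        hi = np.minimum(qe[valid], ref_ends[i])
        left_ov = hi - lo >= min_overlap
        # a long query can also overlap the *previous* merged interval
        prev = i - 1
        has_prev = prev >= 0
        prev_ov = np.zeros(valid.sum(), dtype=bool)
        if has_prev.any():
            lo2 = np.maximum(qs[valid][has_prev], ref_starts[prev[has_prev]])
            hi2 = np.minimum(qe[valid][has_prev], ref_ends[prev[has_prev]])
            prev_ov[has_prev] = hi2 - lo2 >= min_overlap
        # queries spanning multiple merged intervals necessarily overlap the
        # candidate fully, so candidate+previous checks suffice
        ov[valid] = left_ov | prev_ov
    return int(ov.sum())


def overlap_count(a: PeakSet, b: PeakSet, min_overlap: int = 1) -> tuple[int, int]:
    """(number of a-peaks overlapping any b-peak, and the reverse).

    Chromosomes present in only one set contribute zero.
    """
    a_by, b_by = a.by_chromosome(), b.by_chromosome()
    ab = ba = 0
    for chrom in set(a_by) & set(b_by):
        bs, be = _merge(b_by[chrom])
        ab += _count_overlapping(a_by[chrom], bs, be, min_overlap)
        as_, ae = _merge(a_by[chrom])
        ba += _count_overlapping(b_by[chrom], as_, ae, min_overlap)
    return ab, ba


def reshuffle_null(a: PeakSet, b: PeakSet, genome: GenomeDef,
                   n_iter: int = 1000, seed: int | np.random.Generator = 0,
                   min_overlap: int = 1) -> dict:
    """Chromosome-controlled reshuffling null for positional sharing.

    Each iteration independently re-places every peak of ``b`` uniformly
    within its own chromosome, preserving peak length and per-chromosome
    peak count (overlaps within the shuffled set are allowed), and
    counts shuffled-b peaks overlapping ``a``.  The empirical p is the
    smoothed fraction of iterations with overlap >= observed — small
    when the daughters share positions far beyond chance.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for chrom, s, e in b.intervals:
        if chrom not in genome.sizes:
            raise ValueError(f"chromosome {chrom} missing from genome definition")
        if e - s > genome.sizes[chrom]:
            raise ValueError(f"peak {chrom}:{s}-{e} longer than its chromosome")
    a_by = a.by_chromosome()
    merged = {c: _merge(v) for c, v in a_by.items()}
    # observed: b-peaks overlapping a
    observed = 0
    for chrom, arr in b.by_chromosome().items():
        if chrom in merged:
            observed += _count_overlapping(arr, *merged[chrom], min_overlap)
    null = np.zeros(n_iter, dtype=np.int64)
    for chrom, arr in b.by_chromosome().items():
        if chrom not in merged:
            continue
        lengths = arr[:, 1] - arr[:, 0]
        L = genome.sizes[chrom]
        max_start = L - lengths  # inclusive upper bound for each peak
        # (n_iter, n_peaks) random placements, vectorized overlap test
        starts = (rng.random((n_iter, len(lengths))) * (max_start + 1)).astype(np.int64)
        ends = starts + lengths
        rs, re = merged[chrom]
        idx = np.searchsorted(rs, ends - min_overlap, side="right") - 1
        valid = idx >= 0
        i = np.clip(idx, 0, None)
        lo = np.maximum(starts, rs[i])
        hi = np.minimum(ends, re[i])
        ov = valid & (hi - lo >= min_overlap)
        prev = np.clip(idx - 1, 0, None)
        lo2 = np.maximum(starts, rs[prev])
        hi2 = np.minimum(ends, re[prev])
        ov |= (idx - 1 >= 0) & (hi2 - lo2 >= min_overlap)
        null += ov.sum(axis=1)
    p = (int((null >= observed).sum()) + 1) / (n_iter + 1)
    return {"observed": int(observed), "null": null,
            "null_mean": float(null.mean()), "empirical_p": float(p)}


class AtacPairCaller:
    """Asymmetry caller for paired daughter peak sets.

    Parameters
    ----------
    ratio_cutoff : float
        Adjusted peak-count ratio above which the accessibility
        difference supports asymmetry.
    alpha : float
        Significance level for the reshuffling overlap test.
    n_iter : int
        Reshuffling iterations.
    min_peaks : int
        Minimum peaks per cell for the reshuffling test to be
        meaningful; pairs below it are unscorable.
    low_tail : bool
        Alternative operationalization flag: when True, asymmetry
        additionally requires the observed overlap to be significantly
        BELOW the null rather than merely not above it.
    """

    def __init__(self, ratio_cutoff: float = 2.0, alpha: float = 0.05,
                 n_iter: int = 1000, min_peaks: int = 50,
                 min_overlap: int = 1, low_tail: bool = False,
                 random_state: int = 0):
        self.ratio_cutoff = ratio_cutoff
        self.alpha = alpha
        self.n_iter = n_iter
        self.min_peaks = min_peaks
        self.min_overlap = min_overlap
        self.low_tail = low_tail
        self.random_state = random_state

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in
                ("ratio_cutoff", "alpha", "n_iter", "min_peaks",
                 "min_overlap", "low_tail", "random_state")}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def call(self, a: PeakSet, b: PeakSet, genome: GenomeDef,
             rng: np.random.Generator | None = None) -> AtacPairCall:
        if a.n_peaks < self.min_peaks or b.n_peaks < self.min_peaks:
            raise ValueError(
                f"pair {a.pair_id}: fewer than {self.min_peaks} peaks in a "
                "daughter; insufficient for the reshuffling test")
        if rng is None:
            rng = np.random.default_rng(self.random_state)
        ratio, hi_cell, infinite = pair_ratio(a, b)
        res = reshuffle_null(a, b, genome, n_iter=self.n_iter, seed=rng,
                             min_overlap=self.min_overlap)
        if self.low_tail:
            n_low = int((res["null"] <= res["observed"]).sum())
            p_low = (n_low + 1) / (self.n_iter + 1)
            no_sharing = p_low < self.alpha
        else:
            no_sharing = res["empirical_p"] >= self.alpha
        asym = no_sharing and ratio > self.ratio_cutoff
        if asym:
            roles = {c.cell_id: ("progenitor" if c.cell_id == hi_cell else "stem")
                     for c in (a, b)}
        else:
            roles = {a.cell_id: "stem", b.cell_id: "stem"}
        ab, ba = overlap_count(a, b, self.min_overlap)
        return AtacPairCall(
            pair_id=a.pair_id, adjusted_ratio=ratio,
            observed_overlap=res["observed"], null_mean_overlap=res["null_mean"],
            empirical_p=res["empirical_p"],
            call="asymmetric" if asym else "symmetric", roles=roles,
            observed_overlap_ba=ba, ratio_infinite=infinite)

    def fit(self, pairs: list[tuple[PeakSet, PeakSet]], genome: GenomeDef):
        """Call every pair in a cohort; fitted attributes hold results."""
        rng = np.random.default_rng(self.random_state)
        self.calls_ = []
        self.unscorable_ = []
        for a, b in pairs:
            try:
                self.calls_.append(self.call(a, b, genome, rng=rng))
            except ValueError as err:
                self.unscorable_.append({"pair_id": a.pair_id, "reason": str(err)})
        n = len(self.calls_)
        self.fraction_asymmetric_ = (
            sum(c.call == "asymmetric" for c in self.calls_) / n if n else float("nan"))
        return self


def call_pair(a: PeakSet, b: PeakSet, genome: GenomeDef,
              ratio_cutoff: float = 2.0, alpha: float = 0.05,
              **kwargs) -> AtacPairCall:
    return AtacPairCaller(ratio_cutoff=ratio_cutoff, alpha=alpha,
                          **kwargs).call(a, b, genome)


def peaks_to_genes(ps: PeakSet, tss_table, window: int = 1000) -> frozenset[str]:
    """Genes whose TSS lies within ``window`` bp of any peak.

    ``tss_table`` is an iterable of (gene, chromosome, position, strand)
    or a DataFrame with those columns.  Peaks on chromosomes absent from
    the TSS table simply contribute nothing; TSS rows on chromosomes
    absent from the peak set likewise.
    """
    import pandas as pd

    if isinstance(tss_table, pd.DataFrame):
        rows = tss_table[["gene", "chromosome", "position", "strand"]].itertuples(index=False)
    else:
        rows = tss_table
    by_chrom = ps.by_chromosome()
    genes = set()
    tss_by_chrom: dict[str, list] = {}
    for gene, chrom, pos, strand in rows:
        tss_by_chrom.setdefault(chrom, []).append((int(pos), gene))
    for chrom, entries in tss_by_chrom.items():
        if chrom not in by_chrom:
            continue
        arr = by_chrom[chrom]
        starts, ends = arr[:, 0], arr[:, 1]
        for pos, gene in entries:
            # distance from the TSS to the closest point of each peak
            dist = np.maximum(starts - pos, 0) + np.maximum(pos - (ends - 1), 0)
            if (dist <= window).any():
                genes.add(gene)
    return frozenset(genes)
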