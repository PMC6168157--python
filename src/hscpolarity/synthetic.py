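"""Seeded synthetic-data generators for every pipeline stage.

Each generator emulates one modality of the paired-daughter study with
controllable ground truth, so the whole analysis stack is testable
without any external download:

* imaging: per-pair fluorescence signal volumes with a planted
  asymmetric fraction (asymmetric pairs below the 1:4 amount ratio),
* transplants: longitudinal chimerism series with planted stem /
  progenitor daughters and division outcomes,
* transcriptomes: log-normal expression with planted shared (or
  sign-flipped / independent) fold-change programs per pair,
* ATAC: shared peak backbones plus private peaks with planted
  positional-sharing fractions and adjusted count ratios,
* niche: Poisson background centroids in 500x500x50 μm fields with
  planted doublets/triplets inside the adjacency radius,
* transition-model observations (via
  :func:`hscpolarity.transition.simulate_observations`).

One master seed deterministically spawns per-modality child generators
(fixed order: imaging, chimerism, expression, peaksets, centroids,
transition) so any modality can be regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atac import GenomeDef, PeakSet
from .imaging import DaughterPairSignal
from .niche import CentroidSet
from .transcriptome import ExpressionMatrix
from .transition import ConditionObservation, TransitionParams, simulate_observations
from .transplant import ChimerismRecord, ChimerismSeries

__all__ = [
    "ScenarioConfig",
    "modality_rng",
    "gen_imaging_pairs",
    "gen_chimerism",
    "gen_expression",
    "gen_peaksets",
    "gen_centroids",
    "gen_transition_observations",
    "default_genome",
]

_MODALITIES = ("imaging", "chimerism", "expression", "peaksets",
               "centroids", "transition")

WEEKS = (4, 12, 16, 24)


def default_genome() -> GenomeDef:
    """Small synthetic genome (3 chromosomes of 10 Mb) for fast shuffles."""
    return GenomeDef({"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000})


@dataclass(frozen=True)
class ScenarioConfig:
    """Ground-truth knobs of a full synthetic study."""

    master_seed: int = 0
    # transition model
    d_a: float = 0.96
    d_s: float = 0.82
    polar_fractions: tuple[float, ...] = (1.0, 0.75, 0.35, 0.0)
    pairs_per_condition: int = 5000
    # imaging
    n_imaging_pairs: int = 200
    imaging_asym_fraction: float = 0.8
    imaging_condition: str = "young"
    # chimerism
    n_transplant_pairs: int = 100
    outcome_fractions: tuple[float, float, float] = (0.5, 0.275, 0.225)  # Asym, SymS, SymD
    chimerism_noise: float = 0.0  # log-sd multiplicative jitter on donor %
    # expression
    n_genes: int = 1000
    n_expression_pairs: int = 10
    n_signal_genes: int = 60
    signal_log2fc: float = 2.0
    expression_noise_sd: float = 0.2
    shared_signal_fraction: float = 1.0
    concordant_fraction: float = 0.5
    # peak sets
    n_atac_pairs: int = 10
    peaks_per_cell: int = 300
    peak_length: int = 300
    atac_sharing: float = 0.9
    atac_count_ratio: float = 1.0
    atac_asym_fraction: float = 0.0
    mapped_reads: int = 10_000_000
    # centroids
    n_centroids: int = 400
    planted_cluster_fraction: float = 0.34
    points_per_field: int = 8
    centroid_group: str = "aged"

    def __post_init__(self):
        for name in ("d_a", "d_s", "imaging_asym_fraction", "chimerism_noise",
                     "shared_signal_fraction", "concordant_fraction",
                     "atac_sharing", "atac_asym_fraction",
                     "planted_cluster_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1 and name != "chimerism_noise":
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(sum(self.outcome_fractions) - 1.0) > 1e-9:
            raise ValueError("outcome_fractions must sum to 1")


def modality_rng(master_seed: int, modality: str) -> np.random.Generator:
    """Child generator for one modality, spawned deterministically from
    the master seed."""
    if modality not in _MODALITIES:
        raise KeyError(f"unknown modality {modality!r}; one of {_MODALITIES}")
    children = np.random.SeedSequence(master_seed).spawn(len(_MODALITIES))
    return np.random.default_rng(children[_MODALITIES.index(modality)])


# --------------------------------------------------------------------------
# imaging


def gen_imaging_pairs(cfg: ScenarioConfig) -> tuple[list[DaughterPairSignal], list[str]]:
    """Signal-volume pairs with a planted asymmetric fraction.

    Asymmetric pairs draw their lower/higher amount ratio from a Beta
    scaled into (0, 0.25) (strictly inside the 1:4 rule), symmetric
    pairs from a Beta scaled into (0.3, 1.0).
    """
    rng = modality_rng(cfg.master_seed, "imaging")
    pairs, truth = [], []
    for i in range(cfg.n_imaging_pairs):
        asym = rng.random() < cfg.imaging_asym_fraction
        if asym:
            ratio = 0.24 * rng.beta(2.0, 2.0)
        else:
            ratio = 0.30 + 0.70 * rng.beta(2.0, 2.0)
        hi = float(rng.lognormal(mean=math.log(100.0), sigma=0.4))
        lo = ratio * hi
        a, b = (hi, lo) if rng.random() < 0.5 else (lo, hi)
        pairs.append(DaughterPairSignal(
            pair_id=f"img{i:04d}", condition=cfg.imaging_condition,
            marker="Cdc42", volume_a=a, volume_b=b, phase="telophase"))
        truth.append("asymmetric" if asym else "symmetric")
    return pairs, truth


# --------------------------------------------------------------------------
# chimerism


def _stem_record(rng, week, noise) -> ChimerismRecord:
    donor = float(np.clip(rng.lognormal(math.log(15.0), 0.5 + noise), 0.5, 95.0))
    shares = rng.dirichlet([4.0, 3.0, 4.0]) * 100.0
    shares = np.clip(shares, 1.0, None)
    return ChimerismRecord(week=week, donor_percent=donor,
                           b_percent=float(shares[0]), t_percent=float(shares[1]),
                           myeloid_percent=float(shares[2]))


def _progenitor_record(rng, week, noise, mode: str) -> ChimerismRecord:
    if mode == "low_engraft":
        donor = float(np.clip(rng.uniform(0.0, 0.05) *
                              math.exp(noise * rng.normal()), 0.0, 0.09))
        shares = rng.dirichlet([4.0, 3.0, 4.0]) * 100.0
        return ChimerismRecord(week=week, donor_percent=donor,
                               b_percent=float(shares[0]),
                               t_percent=float(shares[1]),
                               myeloid_percent=float(shares[2]))
    # engrafted but missing one lineage (lineage-restricted progenitor)
    donor = float(np.clip(rng.lognormal(math.log(5.0), 0.5 + noise), 0.3, 95.0))
    shares = rng.dirichlet([5.0, 5.0]) * 100.0
    missing = rng.integers(3)
    vals = [0.0, 0.0, 0.0]
    j = 0
    for k in range(3):
        if k != missing:
            vals[k] = float(max(shares[j], 1.0))
            j += 1
    return ChimerismRecord(week=week, donor_percent=donor, b_percent=vals[0],
                           t_percent=vals[1], myeloid_percent=vals[2])


def gen_chimerism(cfg: ScenarioConfig) -> tuple[list[ChimerismSeries], pd.DataFrame]:
    """Chimerism series per transplanted daughter with planted outcomes.

    Stem daughters engraft multilineage well above the 0.1% cutoff;
    progenitor daughters either stay below it or miss one lineage.
    ``chimerism_noise`` widens the log-spread of donor percentages.
    """
    rng = modality_rng(cfg.master_seed, "chimerism")
    labels = ["Asym", "SymS", "SymD"]
    outcomes = rng.choice(3, size=cfg.n_transplant_pairs,
                          p=list(cfg.outcome_fractions))
    series, rows = [], []
    for i, oc in enumerate(outcomes):
        outcome = labels[oc]
        if outcome == "SymS":
            calls = ("S", "S")
        elif outcome == "SymD":
            calls = ("P", "P")
        else:
            calls = ("S", "P") if rng.random() < 0.5 else ("P", "S")
        pid = f"tp{i:04d}"
        for slot, call in zip("AB", calls):
            if call == "S":
                recs = tuple(_stem_record(rng, w, cfg.chimerism_noise) for w in WEEKS)
            else:
                mode = "low_engraft" if rng.random() < 0.5 else "missing_lineage"
                recs = tuple(_progenitor_record(rng, w, cfg.chimerism_noise, mode)
                             for w in WEEKS)
            series.append(ChimerismSeries(
                mouse_id=f"{pid}{slot}", pair_id=pid, daughter_slot=slot,
                condition="young", records=recs))
        rows.append({"pair_id": pid, "call_a": calls[0], "call_b": calls[1],
                     "outcome": outcome})
    return series, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# expression


def gen_expression(cfg: ScenarioConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Cells x genes matrix with pair structure and planted concordance.

    Every cell starts from a common log-normal gene baseline with
    multiplicative log-normal noise.  Each pair receives a planted
    fold-change program over ``n_signal_genes`` randomly chosen genes;
    concordant pairs share a fraction ``shared_signal_fraction`` of the
    program between daughters (rest independent), discordant pairs give
    daughter B the sign-flipped program.
    """
    rng = modality_rng(cfg.master_seed, "expression")
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    baseline = rng.lognormal(mean=3.0, sigma=1.0, size=cfg.n_genes)
    cols, meta_rows = {}, []
    truth = []
    for i in range(cfg.n_expression_pairs):
        pid = f"rna{i:04d}"
        concordant = rng.random() < cfg.concordant_fraction
        idx = rng.choice(cfg.n_genes, size=cfg.n_signal_genes, replace=False)
        signs = rng.choice([-1.0, 1.0], size=cfg.n_signal_genes)
        fold_a = np.zeros(cfg.n_genes)
        fold_a[idx] = signs * cfg.signal_log2fc
        fold_b = np.zeros(cfg.n_genes)
        if concordant:
            shared = rng.random(cfg.n_signal_genes) < cfg.shared_signal_fraction
            fold_b[idx[shared]] = signs[shared] * cfg.signal_log2fc
            own = idx[~shared]
            fold_b[own] = rng.choice([-1.0, 1.0], size=len(own)) * cfg.signal_log2fc
        else:
            fold_b[idx] = -signs * cfg.signal_log2fc
        for slot, fold in zip("AB", (fold_a, fold_b)):
            noise = rng.normal(0.0, cfg.expression_noise_sd, size=cfg.n_genes)
            cell = f"{pid}{slot}"
            cols[cell] = baseline * 2.0 ** (fold + noise)
            meta_rows.append({"cell": cell, "pair_id": pid, "slot": slot,
                              "condition": "young"})
        truth.append({"pair_id": pid,
                      "truth": "concordant" if concordant else "discordant"})
    values = pd.DataFrame(cols, index=genes)
    metadata = pd.DataFrame(meta_rows).set_index("cell")
    return ExpressionMatrix(values=values, metadata=metadata), pd.DataFrame(truth)


# --------------------------------------------------------------------------
# peak sets


def _draw_peaks(rng, genome: GenomeDef, n: int, length: int) -> list[tuple[str, int, int]]:
    chroms = list(genome.sizes)
    sizes = np.array([genome.sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    which = rng.choice(len(chroms), size=n, p=probs)
    out = []
    for ci in which:
        L = genome.sizes[chroms[ci]]
        s = int(rng.integers(0, L - length))
        out.append((chroms[ci], s, s + length))
    return out


def gen_peaksets(cfg: ScenarioConfig, genome: GenomeDef | None = None
                 ) -> tuple[list[tuple[PeakSet, PeakSet]], pd.DataFrame]:
    """Paired peak sets with planted sharing and adjusted count ratio.

    Symmetric pairs share ``atac_sharing`` of their positions at ratio
    ~1; asymmetric pairs have ratio ``atac_count_ratio`` (via peak
    counts at equal mapped reads) and no planted sharing.
    """
    rng = modality_rng(cfg.master_seed, "peaksets")
    if genome is None:
        genome = default_genome()
    pairs, rows = [], []
    for i in range(cfg.n_atac_pairs):
        pid = f"atac{i:04d}"
        asym = rng.random() < cfg.atac_asym_fraction
        n = cfg.peaks_per_cell
        if asym:
            n_hi = int(round(n * max(cfg.atac_count_ratio, 1.0)))
            iv_a = _draw_peaks(rng, genome, n_hi, cfg.peak_length)
            iv_b = _draw_peaks(rng, genome, n, cfg.peak_length)
        else:
            n_shared = int(round(n * cfg.atac_sharing))
            backbone = _draw_peaks(rng, genome, n_shared, cfg.peak_length)
            iv_a = backbone + _draw_peaks(rng, genome, n - n_shared, cfg.peak_length)
            iv_b = backbone + _draw_peaks(rng, genome, n - n_shared, cfg.peak_length)
        a = PeakSet(cell_id=f"{pid}A", pair_id=pid, slot="A",
                    intervals=tuple(sorted(iv_a)), mapped_reads=cfg.mapped_reads)
        b = PeakSet(cell_id=f"{pid}B", pair_id=pid, slot="B",
                    intervals=tuple(sorted(iv_b)), mapped_reads=cfg.mapped_reads)
        pairs.append((a, b))
        rows.append({"pair_id": pid,
                     "truth": "asymmetric" if asym else "symmetric"})
    return pairs, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# centroids


FIELD_DIMS = np.array([500.0, 500.0, 50.0])  # μm


def gen_centroids(cfg: ScenarioConfig) -> tuple[list[CentroidSet], float]:
    """Centroid fields with a planted clustered fraction.

    Points are spread over enough 500x500x50 μm fields to keep the
    background density HSC-realistically low; the planted fraction of
    points is placed in doublets/triplets with partner distances of
    6-15 μm (strictly inside the 19 μm adjacency radius).
    """
    rng = modality_rng(cfg.master_seed, "centroids")
    n_clustered_target = int(round(cfg.n_centroids * cfg.planted_cluster_fraction))
    n_fields = max(1, int(math.ceil(cfg.n_centroids / cfg.points_per_field)))
    field_pts: list[list[np.ndarray]] = [[] for _ in range(n_fields)]
    placed_clustered = 0
    placed_total = 0
    # planted groups of 2-3 points
    while placed_clustered < n_clustered_target and placed_total < cfg.n_centroids:
        size = 3 if (n_clustered_target - placed_clustered >= 3 and
                     rng.random() < 0.3) else 2
        size = min(size, cfg.n_centroids - placed_total,
                   n_clustered_target - placed_clustered)
        if size < 2:
            break
        f = int(rng.integers(n_fields))
        anchor = rng.random(3) * (FIELD_DIMS - 40.0) + 20.0
        group = [anchor]
        for _ in range(size - 1):
            while True:
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                p = anchor + direction * rng.uniform(6.0, 15.0)
                if (p >= 0).all() and (p <= FIELD_DIMS).all():
                    group.append(p)
                    break
        field_pts[f].extend(group)
        placed_clustered += size
        placed_total += size
    # Poisson-like background, one uniform point at a time
    while placed_total < cfg.n_centroids:
        f = int(rng.integers(n_fields))
        field_pts[f].append(rng.random(3) * FIELD_DIMS)
        placed_total += 1
    out = [CentroidSet(points=np.array(pts), group=cfg.centroid_group,
                       field_id=f"field{f:03d}")
           for f, pts in enumerate(field_pts) if len(pts) >= 1]
    truth_fraction = placed_clustered / placed_total if placed_total else 0.0
    return out, truth_fraction


# --------------------------------------------------------------------------
# transition observations


def gen_transition_observations(cfg: ScenarioConfig) -> list[ConditionObservation]:
    rng = modality_rng(cfg.master_seed, "transition")
    design = [(p, cfg.pairs_per_condition) for p in cfg.polar_fractions]
    return simulate_observations(TransitionParams(cfg.d_a, cfg.d_s), design,
                                 seed=rng)
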