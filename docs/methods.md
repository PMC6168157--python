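# Methods

`hscpolarity` re-implements, as a tested library, the quantitative
machinery of a paired-daughter study of hematopoietic stem cell (HSC)
division: a mechanistic model in which the spatial polarity of Cdc42
determines whether a division is asymmetric, plus the rule-based and
statistical scoring used on imaging, single-daughter transplantation,
scRNA-seq, scATAC-seq and whole-mount niche-imaging data. This note
documents the models, the numerical choices, and what the synthetic
data do and do not establish.

## The mechanistic division model (`model_core`)

### Fate dynamics

Total Cdc42 concentration in a cell follows a one-dimensional ODE with
basal production, autoregulatory (positive-feedback) production and
first-order turnover:

    dc/dt = α + β c^n / (K^n + c^n) − k_c c ,    n = 2.

For suitable parameters this system is bistable: a low stable state
(progenitor identity), a high stable state (HSC identity), and an
unstable state between them (the separatrix). The shipped defaults are
calibrated by solving the three fixed-point conditions for the fixed
points {1, 2, 4} with k_c = 1, which has the exact solution
α = 4/7, β = 45/7, K = √14. The calibration targets encode three
qualitative constraints: autoregulation-driven bistability, a
separatrix at concentration 2 (daughters starting below 2 become
progenitors, above 2 remain HSCs), and a high/low state ratio of 4
bracketing the roughly two-fold Cdc42 difference observed between
daughter cells. `calibrate_bistable` exposes the calibration for other
fixed-point choices.

Active (GTP-bound) Cdc42 is treated as a fast cycling equilibrium,
`c_act = c · k₊/(k₊ + k₋)` with k₋ = 1, so the activation constant k₊
alone sets the active fraction. H4K16 acetylation is co-integrated as a
reporter, `d(ac)/dt = k_a/(1 + γ c_act) − δ_a ac` (active Cdc42
inhibits acetylation), and never feeds back on fate.

### Polarity and division

Cdc42 on the cell outline is a wrapped normal on [−π, π) whose variance
σ² increases affinely with the active fraction between `SIGMA2_MIN`
(fully polar) and `SIGMA2_MAX = 25` (indistinguishable from uniform
after wrapping; σ² = ∞ selects the exact uniform limit). Division is a
random plane through the centre: a uniform cut angle splits the circle
into two half-arcs, each daughter inherits the wrapped-normal mass on
its arc, and — with equal daughter volumes — starts at concentration
`2 · share · c_mother`. A simulated division is called asymmetric by the
same 1:4 rule used for imaged pairs (min/max share ≤ 0.25).

`SIGMA2_MIN` is set to 0.002 rad². The value is fixed by the geometry of
the uniform-cut construction: the fraction of cuts producing an
intermediate split (share between 1/4 and 3/4, hence two HSC daughters
from a polar mother) is ≈ 4·0.674·σ/2π, so σ must satisfy
σ ≲ 0.05 rad for a polar population to reproduce the model's target
behaviour — almost exclusively asymmetric divisions with a close-to-1:1
HSC:progenitor daughter ratio. Larger "polar" variances (σ ≳ 0.3)
yield a visibly inflated HSC excess (ratio ≈ 1.3) and only ~84%
asymmetric divisions, contradicting that target.

### Population simulation

`simulate_population` draws one log-normal k₊ per mother (activity
heterogeneity), maps it to σ², draws a uniform cut, partitions, and
relaxes both daughters (LSODA, absolute/relative tolerance 1e-8,
convergence within 1e-4 of a stable state, t_max = 500). A mother is
classified polar when σ² ≤ 1 rad² (config-exposed). Young-like and
aged-like pools are parameterized by the target polar fractions (0.75
and 0.32 respectively, literature-derived stand-ins exposed in config);
`kplus_lognormal_mu` inverts the activity→variance chain at the polar
threshold so that the requested fraction of cells classifies polar
(log-sd 0.5). The RNG order per cell is documented and fixed: k₊ draw,
then cut angle. Non-convergent relaxations are counted, not fatal.

`bifurcation_scan` tabulates fixed points over a k_c grid (the bistable
window is where three roots exist) and `pseudo_potential` integrates
U(c) = −∫f dc by cumulative trapezoid, anchored U = 0 at the grid
start, so stable states appear as valleys and the separatrix as the
hill between them.

## Transition-model MLE (`transition`)

In a condition with polar fraction p, the probability of an asymmetric
division is `p·d_a + (1−p)·(1−d_s)` where d_a is the probability that a
polar HSC divides asymmetrically and d_s the probability that an apolar
HSC divides symmetrically. Counts of asymmetric divisions per condition
are binomial; `TransitionMLE` maximizes the summed log-likelihood over
[0, 1]² (101×101 grid seed, then clipped Nelder–Mead, log-likelihood
tolerance 1e-9). Polar fractions are plug-in inputs, not estimated.
Confidence intervals are profile-likelihood at the χ²₁ cutoff; a
parameter whose profile is flat across [0, 1] (e.g. all conditions
share one polar fraction) is flagged non-identifiable and reported with
the trivial interval. The example configuration uses polar fractions
young 0.75 / aged 0.32 / Wnt5a-treated young 0.35 / CASIN-treated aged
0.70 as documented literature stand-ins.

## Imaged pairs (`imaging`)

For each telophase or late-anaphase daughter pair the percent
difference is `100·(higher − lower)/higher` of the marker signal
volumes. A pair is asymmetric when the difference is ≥ 75%, boundary
inclusive — equivalently when the lower/higher amount ratio is ≤ 1/4.
The two published phrasings of this rule conflict (percent difference
vs "ratio ≤ 75%"); the 1:4 reading is adopted because it is
arithmetically explicit, and the alternative (lower/higher ≤ 0.75) is
available behind `legend_ratio_rule=True` for sensitivity analysis.
Condition contrasts use Pearson chi-squared on the 2×2 asymmetric/
symmetric table without continuity correction.

## Transplanted daughters (`transplant`)

A daughter is a stem cell (S) when week-24 peripheral-blood donor
chimerism exceeds 0.1% and all three lineages (B, T, myeloid) are
detected among donor cells; otherwise a progenitor (P). The lineage
detection floor is unstated upstream and defaults to 0.1% (mirroring
the engraftment cutoff and typical flow detection limits;
config-exposed). Recipients without a week-24 record are unscorable and
excluded with counts; "not engrafted" annotations force P but are
flagged distinctly. Division outcome: S+S = SymS (symmetric
self-renewal), P+P = SymD (symmetric differentiation), otherwise Asym.
A mother is a "true HSC" when at least one daughter scored S — pooled
and per-condition fractions are both reported since either averaging
basis is defensible.

## Paired transcriptomes (`transcriptome`)

Per-gene log2 fold changes compare each daughter to the cohort mean
profile (pseudocount 1). Per-cell significant genes come from a z-test
of the cell's log abundance against a reference distribution that
excludes the tested cell and its pair partner, with Student-t tails
(df = reference size − 1) and Benjamini–Hochberg correction, both at
0.05. Excluding the partner is deliberate: a concordant sibling carries
the same program, and leaving it in the reference inflates the null SD
for precisely the genes under test. This z-test replaces an upstream
self-organizing-map metagene pipeline that is out of scope here; the
downstream statistics are unchanged.

Pair concordance uses the quadrant count ratio over the union of the
daughters' significant genes: QCR = (n_I + n_III − n_II − n_IV)/total,
where quadrants I/III hold genes moving the same direction in both
daughters. Genes with an exactly zero fold change in either daughter
are excluded. Significance is assessed two ways: chi-squared of
concordant vs discordant counts against 50/50, and a permutation test
that reassigns daughter-B fold changes across genes (10,000 draws,
add-one smoothed, tail in the direction of the observed QCR sign; full
enumeration replaces sampling automatically for ≤ 8 genes). A pair is
concordant when QCR > 0 and the permutation p < 0.05; an empty union is
degenerate and reported concordant-by-convention with a flag.

Signature enrichment is upper-tail hypergeometric against a universe of
all genes passing the expression filter (the published universe is
unstated, so the run's filtered gene list is used), BH-adjusted across
signatures at 0.05. Signatures are user-supplied GMT input. Daughter
agreement at the signature level compares the two binary significance
patterns; the statistic is the mismatch count (zero for identical
patterns) with an exact binomial(n, 1/2) tail p — a textbook chi-squared
on (match, mismatch) counts would not vanish for identical patterns,
so the distance form is used. Arm-level directional sets take a pair of
condition arms expected to behave alike, keep genes changing
significantly (plain p < 0.05, per-gene one-sample t of the condition's
cells against the grand mean) in the same direction in both conditions
of an arm, and report the Venn partition between arms per direction.

## Paired ATAC (`atac`)

Peak counts are normalized to peaks per million mapped reads; the pair
ratio is max/min of the adjusted counts with the orientation recorded
(a zero-peak daughter gives an infinite ratio with a flag). Overlap
counting merges one set per chromosome and sweeps the other with a
binary search (O(n log n); equivalent to brute force on every tested
instance, minimum overlap 1 bp, BED-style half-open coordinates).

The positional-sharing null re-places every peak of one daughter
uniformly within its own chromosome, preserving peak length and
per-chromosome counts (within-set overlap after placement is allowed —
matching chromosome-controlled shuffle semantics), and recomputes the
overlap; the empirical p is the smoothed fraction of ≥-observed
iterations over 1,000 draws. Small p therefore means the daughters
share positions far beyond chance. A pair is asymmetric when the
observed overlap is NOT significantly above the null (p ≥ 0.05) AND the
adjusted ratio exceeds 2; this "no significant sharing" direction is
the only one consistent with the null being tested (identical positions
⇒ small p ⇒ symmetric), and a stricter low-tail variant is exposed as a
flag. Roles: in an asymmetric pair the lower-count (less accessible)
daughter is the stem cell; symmetric pairs keep two stem daughters.
Pairs with fewer than 50 peaks in either daughter (config; the
published floor is not printed) are unscorable. Peak-to-gene assignment
for signature reuse is a ±1 kb TSS window (replacing an external
annotation tool; motif analysis is out of scope).

## Niche clustering (`niche`)

Within each imaged field (500×500×50 μm; no cross-field distances),
nearest-neighbour distances are 3D Euclidean via a k-d tree. Two HSCs
are adjacent when their centroid distance is strictly below 19 μm
(7 + 7 + 5 μm: two maximal HSC radii plus one minimal intervening
marrow-cell radius); clusters are connected components of the adjacency
graph and the clustered fraction is the share of cells in components of
≥ 2. Distance histograms use half-open lower-inclusive 20 μm bins. A
precomputed nearest-neighbour-distance table is accepted directly for
datasets shipping distances rather than coordinates.

## Synthetic data (`synthetic`)

One master seed spawns per-modality child streams (fixed order:
imaging, chimerism, expression, peaksets, centroids, transition) via
`numpy` seed sequences, so every modality is independently
bit-reproducible. Defaults mirror the study conditions: transition
truth d_a = 0.96 / d_s = 0.82 with the four-condition polar-fraction
design (1.0, 0.75, 0.35, 0.0) at 5,000 pairs per condition for
recovery runs; a planted 80% asymmetric imaging fraction over 200
pairs; 100 transplant pairs at outcome mix Asym/SymS/SymD =
0.50/0.275/0.225 (chosen so the pooled true-HSC mother fraction is
77.5%); 400 centroids with a planted 34% clustered fraction at 8
points per field (HSC-realistic sparsity keeps chance clustering below
~2%); and a 3×10 Mb genome for fast shuffling.

What the generators do NOT emulate: count-based scRNA noise (expression
is log-normal with planted log-fold programs), fragment-level ATAC
structure (peaks are placed uniformly, not at regulatory elements),
chimerism kinetics between time points (records are drawn per week
independently), or imaging segmentation error. Passing recovery tests
therefore shows that the scoring rules invert the planted generative
process at realistic sizes and noise — not that they are robust to
every artefact of real data.

## Problem sizes and numerical settings

Population acceptance runs use 1,000 mothers (2,000 daughter
relaxations, ~10 s); transition recovery uses 20 replicate fits at
4×5,000 pairs; permutation defaults are 10,000 (QCR) and 1,000
(reshuffling), reduced in unit tests where only correctness, not
resolution, is probed. Root finding brackets sign changes on a
4,001-point grid bounded by (α+β)/k_c (production is bounded, so no
root can exceed it) and refines by Brent to 1e-12. Degenerate inputs
are first-class: both-zero imaging volumes, zero-peak daughters, empty
significant-gene unions, singleton centroid fields and all-flat
signature patterns each have a defined, flagged behaviour rather than
an exception where the quantity is still well-defined.

## Known limitations

* The ODE's functional form and rate constants are a calibrated
  stand-in satisfying the printed qualitative constraints; absolute
  time and concentration units are arbitrary.
* Polar fractions for the four conditions and the aged/young k₊
  distributions are literature-derived defaults, not fitted quantities.
* The QCR permutation scheme (gene-axis reassignment of one daughter's
  fold changes) is one of several exchangeable nulls; the choice is
  config-visible and validated against full enumeration on small
  instances.
* Cluster membership uses the distance rule only; no visual
  "no-intervening-cell" criterion is applied.
* Accession-bound results (real scRNA/scATAC daughter-pair fractions)
  require the deposited data; the package ships the machinery and
  property-level validation, not those numbers.
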