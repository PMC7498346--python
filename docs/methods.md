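# Methods

This note documents the models, parameter choices and numerical conventions
behind painttools, and what the simulation-based tests do and do not
demonstrate.

## Duplex thermodynamics

Melting temperatures use the unified DNA/DNA nearest-neighbor parameter set
(ten stack ΔH°/ΔS° pairs, terminal A·T / G·C initiation terms, a symmetry
entropy for self-complementary strands). The entropy receives the monovalent
salt correction ΔS° += 0.368 · (N−1) · ln[Na⁺], and

  T_m(K) = 1000 · ΔH° / (ΔS° + R ln(C_T / x)),

with x = 4 for non-self-complementary duplexes (x = 1 otherwise) and C_T the
total strand concentration. Defaults: Na⁺ 50 mM, Mg²⁺ 0, 25 °C assay
temperature, C_T 0.25 μM (a common vendor convention; exposed in
`HybridizationConditions`). Mg²⁺, when nonzero, is folded into an equivalent
sodium concentration as Na_eq = Na + 120·√Mg (mM). Reported ΔS is
salt-corrected, and ΔG37 = ΔH − 310.15·ΔS/1000 always holds within rounding.
The implementation agrees with Biopython's `Tm_NN` (DNA_NN3 table, salt
correction 5) to numerical precision for non-palindromic sequences, which the
test suite uses as an independent cross-check; degenerate IUPAC bases are
rejected rather than enumerated.

LNA substitutions are handled two ways. *Approximate* mode adds a configurable
per-base T_m increment for each locked position (A 2.4, C 3.1, G 2.7, T 2.2 °C
— screening-grade values shipped in `data/nn_dna.yaml`, constrained
non-negative so that adding an LNA never lowers the approximate T_m).
*Refined* mode perturbs the stack parameters of each stack whose 5′ base is
locked (ΔΔH/ΔΔS from the same config) and falls back to the additive increment
for positions without a table entry; the mode actually used is recorded in
every result. These tables are configuration, not constants: they should be
recalibrated against a thermodynamic reference if quantitative LNA T_m
accuracy matters. No equivalence with any commercial analyzer is claimed.

## Structure screens

The self-dimer screen scans every ungapped antiparallel alignment of the
sequence against itself, scores Watson–Crick complementary runs of ≥ 2 bp by
their stack ΔG37 sum (all runs in an alignment contribute) and returns the
most stable alignment; ΔG is never positive, with 0 meaning no pairing. The
hairpin screen scans all single stems (length ≥ 2, loop ≥ 3) and adds a flat
loop penalty (+3.0 kcal/mol, configurable). Both are screening-grade ranking
scores — exhaustive within their model class and verified against brute-force
enumeration — not partition-function folding; multiloops, bulges and
RNA-containing hybrids are out of scope.

## Probe design pipeline

All contiguous 19–22 nt windows of the reverse-complemented target are
scored; the longest window with DNA-only T_m under the 60 °C ceiling wins,
with lower T_m preferred within a length (the ceiling applies before LNA
placement). When no window qualifies, the minimum-T_m window proceeds with a
warning rather than a hard failure. LNA placement enumerates position subsets
of the requested size exhaustively (streamed; C(22,8) ≈ 3.2 × 10⁵), rejecting
runs of > 4 consecutive locked bases and ≥ 3 consecutive locked G/C bases
(which over-stabilize and promote aggregation). The 200 highest
approximate-T_m placements are assembled with the linker and docking strand,
screened (self-dimer floor −9.0 kcal/mol, hairpin floor −3.0 kcal/mol,
configurable), ranked by refined backbone T_m and cut to the top 10 per
docking strand. Because the ΔG screens see only the assembled sequence — LNA
positions do not alter it — they act per docking strand as a gate; a docking
strand can therefore legitimately return an empty list (with a warning) for a
given target. Ties break on backbone start, then mask order, making reruns
byte-identical. `design()` uses a vectorized equivalent of the streamed
enumeration for speed; a unit test pins the two paths to each other. LNA
positions are confined to the backbone, since only the backbone hybridizes
the target.

The shipped docking library (`data/docking_strands_synthetic.yaml`) is
synthetic: six orthogonal 9-mers generated once (self/cross complementary
runs ≤ 3 bp, balanced GC, no homopolymer runs) under the P-series naming
convention. It exists so the pipeline runs out of the box; real experiments
should supply their published docking sequences by path.

## Localization processing

Tables carry frame, x/y (nm), photons and optional precision, plus frame time
(default 0.1 s), pixel size (159 nm — a 3.18 μm pick is 20 pixels) and frame
count (default 20 000). The photon filter keeps 420–10 000 inclusive on both
ends. Drift correction averages each fiducial's displacement from its start,
means across fiducials (≥ 1 track covering ≥ 50 % of frames required),
smooths with a centered 200-frame moving average (suppressing few-nm
localization noise while following slow mechanical drift) and re-anchors the
smoothed track to zero at frame 0 — referencing the raw first-frame
localization would bake its noise in as a constant offset of several nm.
Channel registration is translation-only (mean pairwise fiducial
displacement, the least-squares solution); affine distortion is out of scope.
Pick membership and the photon window are boundary-inclusive. Rendering is a
plain 2-D histogram (default 16 nm bins) that conserves counts.

## qPAINT

Localizations within a pick are linked into binding events; gaps of up to
`ignore_gap` dark frames (default 1, covering single missed detections) are
bridged. The dark time between events ending in frame e and starting in frame
s is (s − e − 1) frames — a one-frame gap is one dark frame; this off-by-one
convention shifts every estimate and is therefore fixed here explicitly. With
per-site influx ξ = k_on·c, the pooled dark time over n independent sites is
exponential with mean 1/(nξ) provided τ_bright ≪ τ_dark (comfortably true at
sub-nanomolar imager concentrations, ξ ~ 10⁻³ s⁻¹), giving n = 1/(ξ·τ_dark).
τ_dark comes from the sample mean (≥ 5 dark times) or a least-squares fit of
the empirical CDF to 1 − exp(−t/τ) (≥ 20 dark times); both are reported.
Background subtraction clamps at zero; the 5.12-site default is
configuration, measured per experiment with a scrambled probe. TP10M
normalization (reads × 10⁷ / total genome-matched reads) is provided for
comparing imaging counts with sequencing abundances.

## Colocalization

DBSCAN is delegated to scikit-learn with labels canonicalized by smallest
member index (0 = noise), so the labelling is stable under point permutation;
tests verify equivalence with an independent density-reachability expansion.
The degree-of-colocalization score correlates, per point, the same-channel
and cross-channel *annulus* densities (ΔN/Δ(r²)) over radii step..R_max
(10 nm steps to 2500 nm) by Spearman rank. Annulus gradients, not cumulative
N(r)/r² profiles, are essential: cumulative profiles share geometric
structure (edge attenuation, the common rise-then-plateau shape) that
produces null medians of +0.2–0.35 for completely independent channels,
whereas annulus counts are independent under the null (median ≈ 0.04 in
tests). Identical channels score exactly 1 (coincident zero-distance
cross-channel points are treated as self); channels separated beyond R_max
have constant (all-zero) cross profiles and score 0 by convention. The
colocalized fraction applies a 0.4 threshold by default.

## Simulator

Each docking site is an alternating renewal process: dark dwells
Exponential(1/ξ), bright dwells Exponential(τ_bright) with τ_bright = 0.5 s —
unstated by typical experiments' reporting, chosen so τ_bright ≪ τ_dark holds
in the qPAINT validity regime at the concentrations used here. Bright
intervals are rasterized to frames by the rule "bright in frame f if the
interval covers ≥ 50 % of the frame", which makes event durations
reproducible; each bright frame yields one localization at the site position
plus Gaussian noise (8 nm) plus cumulative linear drift. Photons are
lognormal (median 2000, σ_log 0.5) so the 420–10 000 filter sees realistic
tails. Sites are placed in a tight cluster or uniformly in a circle;
multi-region scenes require disjoint circles and record per-region truth.
Fiducials are localized every frame with their own noise. Everything is
deterministic under the seed.

Two consequences of these choices are worth knowing. First, bright events
shorter than half a frame produce no localization; at τ_bright = 0.5 s and
0.1 s frames ~12 % of events vanish, inflating dark times and biasing
recovered site counts ~10–12 % low — the same detection-efficiency bias real
acquisitions have. Second, completed dark dwells near the end of a finite
track are biased short by right-censoring (~10 % for τ_dark = 200 s in a
2000 s track); dwell-statistics tests therefore pool gaps starting in the
first half of the acquisition. At n = 1 true site, a 20 000-frame acquisition
yields only ~14 dark times, so single-seed estimates carry ~28 % sampling
error regardless of estimator; recovery there is meaningful only in the
median over many seeds.

What passing simulation tests show: the kinetics, linking, dark-time and
counting machinery are internally consistent and recover known ground truth
at realistic rates. What they do not show: robustness to spatially overlapping
PSFs, non-exponential photophysics, imager depletion, sample distortion
between exchange rounds, or detection thresholds of a real localization
pipeline — none of which the simulator models.

## Problem sizes in tests

The default suite runs the full acceptance battery: 100-target design sweep,
50 seeds × five site counts for recovery, 200 random sequences against the
structure oracles, 50 point sets against the DBSCAN oracle; it completes in a
few minutes on one CPU. The acceptance script uses 20 seeds per site count
and 30 design targets, reporting each problem size alongside the value.
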