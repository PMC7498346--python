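# painttools

Probe design and quantification tools for DNA-PAINT imaging of small RNAs
(21–24 nt miRNAs, siRNAs and phasiRNAs), plus a blink-kinetics simulator and a
colocalization module so the whole pipeline can be validated without
microscope data.

Small RNAs are too short for multi-probe FISH: each molecule is detected by a
single hybrid probe consisting of a locked-nucleic-acid (LNA) **backbone**
complementary to the target, a short **linker** (`tattcgt`), and a
**docking strand** whose dye-labelled reverse complement (the *imager strand*)
binds transiently during imaging. Each binding event is one localized blink;
the kinetics of those blinks count the molecules.

## What the package computes

**Probe design** (`painttools.thermo`, `painttools.probe_design`). Duplex
stability uses the unified nearest-neighbor model: stack sums of ΔH°/ΔS° with
duplex-initiation terms, a monovalent-salt entropy correction
ΔS → ΔS + 0.368 (N−1) ln[Na⁺], and T_m = 1000 ΔH / (ΔS + R ln(C_T/4)) − 273.15.
The designer reverse-complements the target, picks the longest 19–22 nt window
with T_m < 60 °C (lowest T_m preferred), exhaustively places `n_lna` LNA bases
(default 8; 5–9 allowed, no run > 4, no ≥ 3 consecutive LNA G/C), shortlists
the 200 placements with the highest additive LNA T_m, appends linker + docking
strand, screens every full sequence for self-dimers and hairpins (stack-sum
ΔG37), and reports the top 10 surviving candidates per docking strand with
imager-strand ordering info.

**qPAINT quantification** (`painttools.locs`, `painttools.qpaint`).
Localization tables (CSV or Picasso-style HDF5) are photon-filtered
(420–10 000, inclusive), drift-corrected from fiducial tracks, and restricted
to circular picks (default 3.18 μm). Blinks are linked into binding events;
the *dark times* between events are exponential with mean 1/(n ξ), where
ξ = k_on · c is the per-site influx rate (k_on = 1.5 × 10⁶ M⁻¹ s⁻¹), so the
site count is **n = 1 / (ξ · τ_dark)**, with τ_dark from the sample mean or an
exponential-CDF fit, minus a scrambled-probe background (default 5.12 sites).

**Colocalization** (`painttools.coloc`). DBSCAN (eps 200 nm, minPts 3) and
per-point degree-of-colocalization: Spearman rank correlation of same- versus
cross-channel annulus densities over a radius ladder (step 10 nm, R_max
2500 nm), with the fraction of points scoring ≥ 0.4 reported.

**Simulation** (`painttools.sim`). Two-state imager binding per docking site
(exponential dark/bright dwells), frame rasterization, Gaussian localization
noise, lognormal photons, fiducial tracks with drift — all with ground truth
attached and deterministic under a seed.

## Worked example

Design probes for a 24-nt target and quantify a simulated acquisition:

```bash
$ printf ">mir_demo\nUUAGCCAAGGAUGACUUGCCGGUU\n" > demo.fa
$ painttools design --fasta demo.fa --docking P1 --out probes.tsv
wrote 10 probes to probes.tsv
$ head -2 probes.tsv | cut -f3-8
rank  full_sequence                                   backbone                lna_positions        tm_approx_C  tm_refined_C
1     +C+CGG+CAAGT+CAT+C+CTTGG+CTA+AtattcgtACATACACG  CCGGCAAGTCATCCTTGGCTAA  0,1,4,9,12,13,18,21  83.11        77.90
```

The rank-1 probe uses the 22-nt backbone window (DNA-only T_m 59.0 °C, under
the 60 °C ceiling), eight `+N`-marked LNA positions that raise the refined T_m
to 77.9 °C, the `tattcgt` linker, and docking strand P1 whose imager strand
(`CGTGTATGT`) is listed for ordering. The shipped docking library is a
synthetic orthogonal P-series; replace it with your lab's sequences via
`--docking-config`.

```bash
$ painttools simulate --n-sites 10 --conc-nm 5 --seed 7 --out locs.csv
wrote 804 localizations to locs.csv
$ painttools quantify --locs locs.csv --picks picks.yml --conc-nm 5 --background 0 --out q.tsv
$ cut -f5,6,9 q.tsv
n_dark  mean_dark_s  n_sites_raw
128     14.7578125   9.03476266101994
```

At c = 5 nM the influx rate is ξ = 1.5 × 10⁶ × 5 × 10⁻⁹ = 7.5 × 10⁻³ s⁻¹; the
128 observed dark times average 14.76 s, so 1/(ξ · τ_dark) ≈ 9.03 binding
sites against a ground truth of 10 — within the expected recovery error
(short bright events below half a camera frame go undetected, biasing counts
~10 % low).

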