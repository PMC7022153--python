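# fcdev

Analysis of how functional brain connectivity (FC) reorganises during
adolescence, built for accelerated-longitudinal resting-state fMRI cohorts
(subjects spanning ages 14–26 y, each scanned 1–3 times). The package is a
library: you import it from Python, and `examples/` contains one short
narrative script per capability.

## The analysis

For each scan, FC is the Pearson correlation between regional BOLD time
series (optionally wavelet-bandpassed to ~0.025–0.111 Hz). Head motion is
quantified by framewise displacement (FD); scans with mean FD > 0.3 mm or
max FD > 1.3 mm are excluded, residual contamination is diagnosed with
QC-FC (the per-edge correlation of FC with mean FD across scans, and its
dependence on inter-regional distance) and removed by regressing FC on
mean FD.

Each edge's trajectory is then fitted with a linear mixed-effects model

    FC_is = β0 + β_age (age_is − 14) + β_sex sex_i + β_site site_i + u_i + ε_is

with a subject random intercept u_i (REML, profiled over the variance
ratio). The fit is summarised by **FC14** = predicted connectivity at age
14 and **ΔFC14−26** = 12 · β_age, the total change over the 14–26 window.

The **maturational index (MI)** of a region is the Spearman correlation,
across that region's incident edges, between FC14 and ΔFC14−26:

    MI_i = ρ( FC14_{i·}, ΔFC14−26_{i·} )

MI > 0 marks a *conservative* mode (edges already strong at 14 strengthen
further); MI < 0 a *disruptive* mode (weak edges strengthen, strong edges
weaken). Significance of cortical map statistics uses a **spin test**:
random rotations of the spherical coordinate system (mirrored across
hemispheres) generate permutations that preserve spatial contiguity and
bilateral symmetry. The MI map is finally colocated with a battery of
per-region annotation maps (Spearman ρ, spin p, Benjamini–Hochberg FDR
over the declared battery) and profiled across categorical atlas classes.

A first-class synthetic-cohort generator plants per-edge trajectories with
known per-region MI, distance-dependent motion confounds, and annotation
maps with controlled spatial coupling to the true MI map, so the entire
pipeline is testable against exact ground truth.

## Worked example

```bash
python examples/03_growth_and_mi.py
```

prints, for a 150-subject synthetic cohort with 40 regions and planted
MI targets of ±0.6:

```
global mean FC trend: +0.0009 FC/y (p=0.308, reml fit on 260 scans / 150 subjects)
maturational index: 20 conservative, 20 disruptive regions; 14 significant at spin-FDR q<0.05
recovery of planted MI: Spearman 0.973, sign agreement 100%
```

The global mean trend is weak (as planted: region couplings are balanced
±0.6 so mean change is near zero), the MI map splits regions into the two
developmental modes, and the estimated MI map recovers the planted one
almost perfectly at this noise level. `examples/06_full_pipeline.py` runs
the whole chain from simulation to colocation and writes a report bundle
(TSV tables + JSON provenance) that reproduces byte-for-byte under a
fixed seed.

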