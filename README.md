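# panc13c

Hyperpolarised [1-¹³C]pyruvate metabolic imaging of pancreatic disease
progression: simulation, reconstruction and analysis.

## The problem

Pancreatic ductal adenocarcinoma evolves through graded precursor lesions
(PanIN).  Detecting the transition from low-grade to high-grade
preneoplasia non-invasively would let high-risk patients be offered surgery
while the disease is still curable.  After an intravenous bolus of
hyperpolarised [1-¹³C]pyruvate, the ¹³C label exchanges into the endogenous
lactate and alanine pools through lactate dehydrogenase (LDH) and alanine
aminotransferase (ALT).  As disease progresses, LDH activity and the
lactate pool rise while ALT activity falls, so the
**[1-¹³C]alanine / [1-¹³C]lactate signal ratio** measured by ¹³C
chemical-shift imaging (CSI) over the pancreas decreases stage by stage —
from healthy pancreas, through pancreatitis and low-grade then high-grade
murine PanIN (KC mice at 2, 4 and 9 months), to tumour.

This package implements that experiment end to end, for people who want to
study the method itself: pulse-sequence-faithful simulation of the raw
k-space CSI data from digital phantoms whose voxels carry stage-specific
metabolic parameters, the exact reconstruction chain used on the real data,
the ratio/ROI/statistics analysis, and the cell-free homogenate
isotope-exchange computation that validates the in-vivo ratios.

## The model

Longitudinal magnetization of the pyruvate (P), lactate (L) and alanine (A)
pools follows a three-pool linear exchange system with T1 loss and a
rectangular bolus b(t):

    dP/dt = -(k_PL + k_PA + 1/T1) P + k_LP L + k_AP A + b(t)
    dL/dt =  k_PL P - (k_LP + 1/T1) L
    dA/dt =  k_PA P - (k_AP + 1/T1) A

Each excitation at flip angle α reads out M·sin α and costs the
longitudinal pools a factor cos α.  Rate constants derive from measured
enzyme activities and pool sizes by mass-action exchange flux,
J_lac = κ·LDH·[lac] and J_ala = κ·ALT·[ala] (so k_LP = κ·LDH,
k_PL = κ·LDH·L/P), giving a short-time label partition
ala*/lac* ≈ (ALT·A)/(LDH·L).  The acquisition is the in-vivo protocol:
32×32 matrix, 40×40 mm FOV, TR 30 ms, flip 5°, 6 kHz spectral width,
centre-out phase encoding, start 20 s after injection.  Reconstruction is
the processing chain applied to the real data: cosine k-space apodization,
zero-filling to 128×128, 20 Hz exponential line broadening, zero-filling to
1024 spectral points, Fourier transformation, per-voxel zero-order phase
correction, median baseline correction and peak integration over fixed
frequency windows.

The homogenate module implements the cell-free assay arithmetic: simulate
¹³C label incorporation from [3-¹³C]pyruvate into tissue-matched alanine
and lactate pools, fit a line to the initial five points of each labelling
curve, convert the tube-frame slope to a tissue-frame rate
(slope × sample volume / wet weight), and integrate the exchange law
forward 20 s with the tissue pool sizes to predict the in-vivo label
partition.

## Worked example

`examples/03_stage_ordering.py` runs the full imaging chain for four
disease stages:

```
control      ROI ala/lac = 0.2487
kc_4mo       ROI ala/lac = 0.0763
kc_9mo       ROI ala/lac = 0.0278
tumour_pda   ROI ala/lac = 0.0129

strictly decreasing with disease progression: yes
decrease from 4 to 9 months: 64%
```

Each line is the alanine/lactate signal ratio over a pancreatic region of
interest, computed from simulated raw k-space data through the full
reconstruction.  The ratio falls strictly with disease stage — healthy
pancreas keeps a high alanine partition (active ALT, small lactate pool);
tumour-bearing tissue converts almost all label to lactate.  Absolute
values depend on a calibration constant that cannot be fixed from the
reported tissue data (see `docs/methods.md`); the ordering and the relative
separations are the reproducible content.

`examples/04_homogenate_assay.py` prints the matching cell-free chain:

```
stage            rate_ala   rate_lac   ala*20s   lac*20s     ratio
control           0.00540    0.13041    0.1048    1.2619   0.08303
pancreatitis      0.00415    0.08641    0.0801    0.9783   0.08190
kc_4mo            0.00202    0.19321    0.0397    1.5896   0.02496
kc_9mo            0.00126    0.30159    0.0249    3.2178   0.00772
tumour_pda        0.00007    0.39901    0.0014    5.0861   0.00027
```

Rates are dilution-corrected initial rates (μmol/s/g tissue); the last
column is the predicted 20-s in-vivo alanine/lactate label partition, again
strictly decreasing across the five stages.

The other examples cover single-examination simulation + reconstruction
(`02`), the stage profiles and rate constants (`01`), and repeatability /
group statistics (`05`).

## Command line

A thin CLI wraps the same workflows for file-based use:

```bash
panc13c simulate  --config sim.yaml   --out raw.h5 --seed 1
panc13c recon     --in raw.h5 --config recon.yaml --out maps/
panc13c analyze   --maps maps/ --roi roi.json --out report.json
panc13c homogenate --config assay.yaml --out kinetics.csv
```

Raw CSI data live in an HDF5 container (`/fids` complex ky×kx×t, `/acq`
attributes, `/seed`); metabolite maps are written as NIfTI volumes with a
JSON provenance sidecar.

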