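"""The cell-free homogenate isotope-exchange computation.

For each disease stage: simulate 13C label incorporation from
[3-13C]pyruvate into alanine and lactate in a tissue homogenate (unlabelled
pools added at tissue-matched concentrations), fit the initial five points
of each labelling curve, correct for the dilution of the tissue in the NMR
tube, and extrapolate the exchange to the label partition an in-vivo
measurement would see 20 s after injection.
"""

from panc13c import run_homogenate_study

stages = ["control", "pancreatitis", "kc_4mo", "kc_9mo", "tumour_pda"]
print(f"{'stage':14s} {'rate_ala':>10s} {'rate_lac':>10s} {'ala*20s':>9s} "
      f"{'lac*20s':>9s} {'ratio':>9s}")
ratios = []
for stage in stages:
    res = run_homogenate_study(stage)
    p = res.prediction
    ratios.append(p.ala_lac_label_ratio)
    print(
        f"{stage:14s} {res.rate_ala_tissue:10.5f} {res.rate_lac_tissue:10.5f} "
        f"{p.labelled_alanine_20s:9.4f} {p.labelled_lactate_20s:9.4f} "
        f"{p.ala_lac_label_ratio:9.5f}"
    )
assert all(a > b for a, b in zip(ratios, ratios[1:]))
print(
    "\nRates in umol/s/g tissue; labelled amounts in umol/g at 20 s."
    "\nThe predicted 20-s ala/lac label partition falls strictly across the"
    "\nfive stages, mirroring the in-vivo imaging ratio."
)
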