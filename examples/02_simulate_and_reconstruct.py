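"""Simulate one hyperpolarised-pyruvate CSI examination and reconstruct it.

Builds a phantom with a 9-month (high-grade mPanIN) pancreas, simulates the
32x32 chemical-shift-imaging acquisition (TR 30 ms, 5 degree flip, 6 kHz
spectral width, centre-out encoding, starting 20 s after injection),
reconstructs metabolite maps with the cosine-apodise / 20 Hz line-broaden /
zero-fill / Fourier / phase / baseline / peak-integration chain, and
reports the pancreatic ROI signal ratios.
"""

import numpy as np

from panc13c import run_imaging_study

res = run_imaging_study("kc_9mo", seed=1)

print("raw k-space data:", res.dataset.fids.shape, "(ky, kx, t)")
maps = res.maps.maps
print("reconstructed maps:", {k: v.shape for k, v in maps.items()})
ys, xs = res.roi.indices()
print(f"pancreas ROI: {res.report.n_voxels} voxels on the 128x128 grid")
for name in ("pyruvate", "lactate", "alanine"):
    print(f"  ROI {name:9s} integral: {maps[name][ys, xs].sum():12.1f} (a.u.)")
rep = res.report
print(f"\nROI ala/lac = {rep.ala_lac:.4f}   lac/pyr = {rep.lac_pyr:.4f}   "
      f"ala/pyr = {rep.ala_pyr:.4f}")
print(
    "\nThe ala/lac signal ratio is the diagnostic endpoint: a 9-month"
    "\npancreas (abundant high-grade mPanIN) sits far below a healthy one."
)
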