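"""Disease-stage metabolic profiles and the exchange rates they imply.

Prints the tissue-extract parameters (pool sizes, enzyme activities) for
each stage of disease progression, and the apparent label-exchange rate
constants of the three-pool model derived from them.  The ALT-driven
alanine rate falls and the LDH-driven lactate rate rises with progression:
this is the contrast the imaging experiment reads out.
"""

from panc13c import Stage, activities_to_rates, stage_profile

print(f"{'stage':20s} {'ala':>6s} {'lac':>6s} {'LDH':>8s} {'ALT':>6s} "
      f"{'k_pl':>9s} {'k_pa':>9s} {'k_pa/k_pl':>10s}")
for stage in Stage:
    p = stage_profile(stage)
    r = activities_to_rates(p)
    print(
        f"{stage.value:20s} {p.alanine_conc:6.2f} {p.lactate_conc:6.2f} "
        f"{p.ldh_activity:8.2f} {p.alt_activity:6.2f} "
        f"{r.k_pl:9.5f} {r.k_pa:9.6f} {r.k_pa / r.k_pl:10.5f}"
    )
print(
    "\nPools in umol/g wet tissue, activities in mU/mg protein, rates in 1/s."
    "\nk_pa/k_pl is the short-time alanine:lactate label partition; it falls"
    "\nby ~3 orders of magnitude from healthy pancreas to tumour."
)
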