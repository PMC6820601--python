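"""Simulate the wheat-like breeding programme.

Runs the desk-scale recurrent-selection programme (crosses among inbred
parents, doubled-haploid progeny, headrow selection into a preliminary
yield trial) and reports how selection erodes genetic variance, which is
why the realized plot heritability of the recorded cohort sits well below
the nominal 0.25 anchor.
"""

import numpy as np

from fieldspatial import ProgrammeConfig, run_programme

config = ProgrammeConfig()  # desk scale: 50 crosses x 40 DH, 200-line PYT
state = run_programme(config, seed=42)[0]

print(f"recorded year: {state.year}  (after {config.burn_in_years} burn-in cycles)")
print(f"PYT cohort: {state.pyt.n} doubled-haploid lines")
print(f"prediction cohort (genotyped, unphenotyped): {state.prediction.n} lines")
print(f"heterozygosity of DH lines: {state.pyt.heterozygosity().max():.0f} (exactly 0)")
print()
print(f"base genetic variance (year-1 cohort):   {state.sigma2_g_base:.2f}")
print(f"genetic variance among PYT entrants:     {state.realized_sigma2_g:.3f}")
print(f"plot residual variance (h2 anchor 0.25): {state.sigma2_e:.2f}")
print(f"realized plot heritability:              {state.realized_h2_plot:.3f}")
print()
print(
    "selection gain: PYT mean breeding value "
    f"{state.pyt_tbv.mean():.2f} vs prediction-cohort mean "
    f"{state.prediction_tbv.mean():.2f} (new unselected crosses)"
)
# the drop from 0.25 to the realized value reflects genetic variance spent
# by 10 cycles of selection and drift, with the residual variance anchored
# at the base cohort -- the same mechanism that operates in the full-scale
# programme
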