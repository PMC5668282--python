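"""Locate the peak mortality-risk month with the sinusoid covariate scan.

Replaces the winter/summer dichotomy with x1 = cos(2*pi*(M - M_max)/12)
and refits the Cox model for every candidate peak month M_max; the
coefficient-maximizing month is the data's preferred peak of seasonal
mortality risk.
"""

import math

import hlseason as h
from hlseason import survival as sv

config = h.SimConfig(n_cases=30_000, seed=7,
                     seasonal_log_hr=math.log(1.15), mortality_peak_month=11)
cases = h.simulate_registry(config)
design = sv.encode_covariates(cases, horizon_months=36)
scan = sv.scan_peak_month(design, [c.month_dx for c in cases])

print(scan.grid_frame().round(3).to_string(index=False))
print(f"\nbest peak-risk month: {scan.best_m_max} (injected truth: 11)")
print("Note the built-in antisymmetry: the hazard ratio for any peak month")
print("times the one six months later equals 1, and their p-values match —")
print("the covariate simply flips sign.")
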