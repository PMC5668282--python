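"""Standardized monthly incidence and the cosinor seasonality fit.

Uses the packaged monthly Hodgkin-lymphoma diagnosis counts (SEER-18,
1973–2012, 41,405 cases) — the only real registry data the package ships.
"""

import hlseason as h

counts = h.seer_hl_monthly_counts()
table = h.incidence_from_counts(counts)
print(table.to_frame().to_string(index=False))

fit = h.fit_cosinor(table.normalized_incidence)
print(f"\namplitude       : {fit.amplitude:.3f}")
print(f"peak month      : {fit.peak_month} (trough {fit.trough_month})")
print(f"peak vs trough  : +{h.peak_trough_percent(fit):.1f}% "
      f"[{200 * fit.amplitude_ci[0]:.1f}, {200 * fit.amplitude_ci[1]:.1f}]")
print(f"seasonality p   : {fit.seasonality_p:.2g}")
print("\nThe fitted cosine says incidence peaks around March and dips around")
print("September, the peak exceeding the trough by about 15% of the average")
print("month's incidence; the tiny p-value rejects a flat (aseasonal) model.")
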