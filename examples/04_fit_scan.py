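"""Scan membrane capacitance and time constant, then pick the best fit.

Runs a small 2-D grid over C_m and tau_m (realized as g_L = C_m/tau_m)
around the wild-type fixture, simulates each combination at a reduced
size, and selects the combination whose median peak burst frequency is
closest to a target value, mimicking how model parameters are matched
to a recorded culture's burst frequency.
"""

import meaburst as mb
from meaburst.experiments import run_fit_scan, scaled_config, select_top_fit

wt = mb.genotype_fixture("WT").params
scan = run_fit_scan(
    cm_values=[70.0, 80.0, 90.0],
    tau_m_values=[16.0, 20.0, 24.0],
    base_params=wt,
    config=scaled_config(),
    seeds=(0, 1),
)
print(scan.summary().to_string(index=False))

target = 0.30  # Hz, e.g. the median peak of a recorded WT culture
best = select_top_fit(scan, target_peak=target)
print(f"\nbest fit for a {target} Hz culture: C_m={best['C_m']:.0f} pF, "
      f"tau_m={best['tau_m']:.0f} ms "
      f"(median peak {best['median_peak_hz']:.3f} Hz, "
      f"|diff| {best['abs_diff']:.3f} Hz)")
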