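"""Grid search used to calibrate the genotype parameter fixtures.

No numeric AdIF parameters are published for the cell lines this package
models, so the fixtures in ``meaburst.synth`` are versioned calibration
constants. This script reproduces the search: it scans spike-triggered
adaptation b and adaptation time constant tau_w around the wild-type
operating point, simulates each combination at the scaled profile over
three seeds, and reports the population peak burst frequency, so the
three genotypes can be placed on the adaptation axis with the ordering
NULL < WT < L124W and stable sub-1 Hz peaks.

Run:  python scripts/calibrate_fixtures.py [--fast]
"""

import argparse
import sys

import numpy as np

import meaburst as mb
from meaburst.experiments import (
    DEFAULT_W_EXT,
    AnalysisSettings,
    scaled_config,
    simulate_and_analyze,
)


def main() -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("--fast", action="store_true", help="single seed, coarse grid")
    ap.add_argument("--duration", type=float, default=90.0)
    args = ap.parse_args()

    wt = mb.genotype_fixture("WT").params
    seeds = (0,) if args.fast else (0, 1, 2)
    b_grid = [150.0, 250.0, 400.0] if args.fast else [120.0, 180.0, 250.0, 330.0, 400.0]
    tw_grid = [1300.0, 2400.0] if args.fast else [1000.0, 1300.0, 1800.0, 2400.0]

    print(f"# operating point: w_e={wt.w_e} nS, w_ext={DEFAULT_W_EXT} nS, "
          f"a={wt.a} nS, scaled profile ({args.duration:.0f} s)")
    print("b_pA\ttau_w_ms\tmedian_peak_hz\tseed_peaks")
    from dataclasses import replace

    for b in b_grid:
        for tw in tw_grid:
            params = replace(wt, b=b, tau_w=tw)
            peaks = []
            for seed in seeds:
                cfg = scaled_config(seed=seed, duration=args.duration)
                res = simulate_and_analyze(params, cfg, AnalysisSettings())
                peaks.append(np.nan if res.excluded else res.frequency)
            med = np.nanmedian(peaks) if not np.all(np.isnan(peaks)) else np.nan
            print(f"{b:.0f}\t{tw:.0f}\t{med:.3f}\t{np.round(peaks, 3).tolist()}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
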