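#!/usr/bin/env python
"""Preprocess and analyze every session of the simulated cohort.

For each session: band-pass + notch filtering, automated channel rating,
spherical-spline interpolation to the combined 128-site montage, common
average reference, then the three analyses — alpha band power in a centered
resting-state window, averaged blink overlays, and the VEP with its global
field power (GFPt) peaks. Writes one row per session to
results/session_analyses.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from capcompare.pipeline import PipelineConfig, analyze_cohort
from capcompare.synthdata import simulate_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 11
N_SUBJECTS = 10


def main() -> None:
    config = PipelineConfig.desk_scale(n_subjects=N_SUBJECTS, seed=SEED)
    cohort = simulate_cohort(config.simulation)
    pairs = analyze_cohort(cohort, config)

    rows = []
    for gel, dry in pairs:
        for a in (gel, dry):
            n_bad = sum(
                1 for ratings in a.ratings.values() for r in ratings
                if r.verdict.value == "bad"
            )
            rows.append(
                {
                    "subject": a.subject_id,
                    "cap": a.cap_type.value,
                    "layout": a.layout_kind.value,
                    "alpha_peak_freq_hz": a.alpha_closed.peak_freq,
                    "alpha_power_closed": a.alpha_power_scalar,
                    "alpha_power_open": float(a.alpha_open.mean_power.mean()),
                    "n75_latency_ms": a.vep_peaks["N75"].latency,
                    "n75_gfp_uv": a.vep_peaks["N75"].amplitude,
                    "p100_latency_ms": a.vep_peaks["P100"].latency,
                    "p100_gfp_uv": a.vep_peaks["P100"].amplitude,
                    "n_bad_ratings": n_bad,
                }
            )
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "session_analyses.csv", index=False)

    print(table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
    print(f"\nalpha peak recovered at "
          f"{table['alpha_peak_freq_hz'].mean():.2f} Hz on average (configured: 10 Hz)")
    print(f"wrote {RESULTS / 'session_analyses.csv'}")


if __name__ == "__main__":
    main()
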