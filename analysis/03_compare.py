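#!/usr/bin/env python
"""Gel-vs-dry comparison over the analyzed cohort.

Computes channel reliability per cap, impedance and metadata grand averages,
per-subject agreement metrics (Pearson r, RMSD) for the blink overlays, the
eyes-closed PSD and the VEP, and the distributional tests (Lilliefors KS,
Mann-Whitney U). Writes the full report bundle under results/report/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from capcompare.pipeline import PipelineConfig, run_study

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 11
N_SUBJECTS = 10


def main() -> None:
    config = PipelineConfig.desk_scale(n_subjects=N_SUBJECTS, seed=SEED)
    _, _, report = run_study(config)

    out = RESULTS / "report"
    report.write(out)

    meta = report.sections["metadata_summary"]
    print(f"prep time: dry/gel ratio {meta['prep_time_ratio']}, "
          f"reduction {meta['prep_time_reduction_pct']}%")
    for cap, aggs in report.sections["reliability"]["grand"].items():
        print(f"channel reliability [{cap}]: "
              + ", ".join(f"{k} {100 * v:.1f}%" for k, v in aggs.items()))
    imp = report.sections["impedance"].groupby("cap")["grand_mean"].first()
    print(f"impedance grand mean: gel {imp['gel']:.0f} kOhm, dry {imp['dry']:.0f} kOhm")
    for cap, comps in report.sections["vep_grand_average"].items():
        line = ", ".join(
            f"{name} {v['amplitude_uV']:.2f} uV @ {v['latency_ms']:.0f} ms"
            for name, v in comps.items()
        )
        print(f"grand-average GFPt [{cap}]: {line}")
    print(report.sections["comparison_summary"].to_string(index=False))
    rejected = [
        name for name, entry in report.sections["test_results"].items()
        if entry["mann_whitney_u"]["decision"] == "reject"
    ]
    print("U tests rejecting equality at 0.05:", rejected or "none")
    print(f"wrote report bundle to {out}")


if __name__ == "__main__":
    main()
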