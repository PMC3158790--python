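"""SCN flip-flop alignment on synthetic paired traces.

Generates paired SCN/SWA traces driven by a known switching schedule,
detects the SCN threshold crossings and the SWA towards/away turning
points, scores their temporal alignment, and demonstrates the binning
artefact by which a sharp sub-bin SCN peak straddling a bin edge fails to
reach the threshold.  Writes results/scn_alignment.json.
"""

import json
from pathlib import Path

import numpy as np

from ntpsleep.flipflop import (
    ThresholdCurve,
    align_events,
    bin_trace,
    detect_crossings,
    detect_state_transitions,
)
from ntpsleep.io import write_activity_trace
from ntpsleep.synthetic import generate_scn_swa

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    switches = np.arange(930.0, 7200.0, 900.0)
    rates = []
    for seed in range(10):
        scn, swa, threshold = generate_scn_swa(switches, 7200.0,
                                               noise_sigma=5.0, seed=seed)
        crossings = detect_crossings(
            scn, ThresholdCurve.constant(threshold, scn.values.size))
        transitions = detect_state_transitions(swa)
        report = align_events(crossings, transitions, tolerance=scn.bin_width)
        rates.append(report.rate)
        if seed == 0:
            write_activity_trace(scn, RESULTS / "scn_trace.csv")
            write_activity_trace(swa, RESULTS / "swa_trace.csv")
            first = report

    # binning artefact: sharp peak on a bin edge vs centered in a bin
    t = np.arange(0, 1200, 1.0)
    straddling = np.full(t.size, 40.0)
    straddling[570:630] += np.bartlett(60) * 80.0
    centered = np.full(t.size, 40.0)
    centered[540:600] += np.bartlett(60) * 80.0
    n_strad = len(detect_crossings(bin_trace(t, straddling, 60.0),
                                   ThresholdCurve.constant(70.0, 20)))
    n_cent = len(detect_crossings(bin_trace(t, centered, 60.0),
                                  ThresholdCurve.constant(70.0, 20)))

    out = {
        "schedule_switches": switches.tolist(),
        "first_seed_matched": first.matched,
        "first_seed_total": first.total,
        "mean_match_rate_pct": float(np.mean(rates)),
        "binning_demo_crossings_straddling": n_strad,
        "binning_demo_crossings_centered": n_cent,
    }
    (RESULTS / "scn_alignment.json").write_text(json.dumps(out, indent=2) + "\n")
    print(f"seed 0: {first.matched}/{first.total} SWA transitions matched by "
          f"SCN threshold crossings")
    print(f"mean match rate over 10 seeds at noise sigma 5: "
          f"{np.mean(rates):.1f}%")
    print(f"binning demo: straddling peak -> {n_strad} crossings, "
          f"centered peak -> {n_cent} crossings")


if __name__ == "__main__":
    main()
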