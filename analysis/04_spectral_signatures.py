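#!/usr/bin/env python
"""1/f spectral signatures and antiphase coupling of the congruence series.

Smoothed periodograms of the sliding congruence probabilities, pooled
power-law slopes below 0.1 cycles/trial, and the cross-spectral phase and
squared coherence between stimulus- and history-congruence fluctuations.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from bimodal_inference import congruence as cg
from bimodal_inference import spectral as sp
from bimodal_inference.simulate import SimulationConfig, simulate_cohort


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--n-agents", type=int, default=200)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    sim = simulate_cohort(SimulationConfig(n_agents=args.n_agents, seed=args.seed))
    profiles = []
    for s in sim.cohort:
        c = cg.congruence_series(s)
        profiles.append(sp.spectral_profile(c.p_stim, c.p_hist,
                                            subject_id=s.subject_id, group_id=s.group_id))
    pd.concat([p.to_frame() for p in profiles], ignore_index=True).to_csv(
        args.out / "spectral_profiles.csv", index=False)

    summary = {}
    for which, label in (("stim", "stimulus"), ("hist", "history")):
        res = sp.powerlaw_exponent(profiles, which=which)
        summary[f"beta_{which}"] = res
        print(f"{label}-congruence 1/f slope below 0.1 cycles/trial: "
              f"beta = {res['beta']:.3f} +/- {res['beta_se']:.3f}")

    from bimodal_inference.cohortstats import phase_histogram_mode
    bands = [sp.band_summary(p) for p in profiles]
    phases = np.array([b[0] for b in bands])
    coh = 100 * np.mean([b[1] for b in bands])
    mode_phase = phase_histogram_mode(phases)
    summary["band_phase_histogram_mode_rad"] = mode_phase
    summary["band_mean_sq_coherence_pct"] = coh
    print(f"band-mean phase histogram peaks at {mode_phase / np.pi:.2f} pi "
          f"(antiphase = 1.00 pi); mean squared coherence {coh:.2f}%")
    (args.out / "spectral_summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
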