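"""Simulate annotated RR streams and look at their serial structure.

Generates one record per rhythm class and prints the statistics that
distinguish them on a Lorenz scattergram: sinus rhythm has strongly
autocorrelated RR intervals (tight diagonal attractor), AF is serially
uncorrelated with a high CV (diffuse fan), and premature beats break the
correlation with short-long interval pairs (off-diagonal lobes) without
being AF.
"""

import numpy as np

from lorenzaf import (BeatClass, SimulationConfig, inject_ectopy, rr_series,
                      simulate_af, simulate_paroxysmal, simulate_sinus)


def lag1(x):
    x = np.asarray(x) - np.mean(x)
    return float(np.dot(x[:-1], x[1:]) / np.dot(x, x))


cfg = SimulationConfig(duration_s=900.0)  # 15-minute records

sinus = simulate_sinus(cfg, seed=1)
ectopic = inject_ectopy(sinus, cfg.pvc_rate_per_min,
                        cfg.prematurity_fraction, seed=2)
ectopic.record_id = "sinus+pvc"
af = simulate_af(cfg, seed=3)
parox = simulate_paroxysmal(cfg, seed=4)

for rec in (sinus, ectopic, af, parox):
    rr = rr_series(rec)
    af_frac = np.mean([l is BeatClass.AF for l in rec.beat_labels])
    print(f"{rec.record_id:12s} truth={rec.record_truth.value:14s} "
          f"beats={len(rec):5d} mean_rr={rr.intervals.mean():.3f}s "
          f"cv={rr.intervals.std() / rr.intervals.mean():.3f} "
          f"lag1_autocorr={lag1(rr.intervals):+.3f} af_beat_frac={af_frac:.2f}")

print("\nPure sinus rhythm is strongly autocorrelated; AF is uncorrelated"
      "\nwith a much larger CV; premature beats also destroy lag-1"
      "\ncorrelation but stay non-AF — the image classifier has to separate"
      f"\nthese cases. The paroxysmal record has {len(parox.episodes)} "
      "alternating episodes.")
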