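#!/usr/bin/env python
"""Simulate one synthetic joint fUS-Neuropixels session per region preset
and store them as HDF5 under scratch/sessions/.

Each session carries the full study structure: 143 x 128 Power-Doppler
frames at 5 Hz, 34-s trials (10 s baseline / 4 s stimulus / 20 s post), six
stimulus contrasts, Poisson spiking on 100-um depth bins along the true
probe trajectory, and a Doppler field produced by the spatiotemporal forward
model with the region's calibration slope and gamma kernel.

Sessions are heavyweight binary artifacts, so they live under scratch/
(regenerable from the seeds echoed below); the downstream scripts re-derive
everything from them.
"""

from pathlib import Path

import fusnpx
from fusnpx.synthetic import save_session

OUT = Path("scratch/sessions")
N_TRIALS = 20
BASE_SEED = 20_260_919

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    for i, (region, make) in enumerate(sorted(fusnpx.config.REGION_CONFIGS.items())):
        seed = BASE_SEED + i
        session = fusnpx.gen_session(make(n_trials=N_TRIALS), seed=seed)
        path = OUT / f"{region.lower()}_seed{seed}.h5"
        save_session(session, path)
        gt = session.ground_truth
        print(
            f"{region}: seed={seed} slope={gt.slope_amp} basal={gt.basal_rate_hz} "
            f"gamma_peak={gt.gamma.time_to_peak_s:.2f}s -> {path}"
        )
    print("done; run 02_analyze_sessions.py next")
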