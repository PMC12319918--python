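#!/usr/bin/env python
"""Probe-tip localization robustness under strong Doppler noise.

Twenty replicate sessions are simulated with per-frame voxel noise equal to
half the evoked-response peak; each is aligned by Monte-Carlo candidate
search from an initial estimate displaced by (2, -2) voxels and +0.05 slope.
The table written to results/alignment_robustness.csv records the selected
tip error per replicate; the summary line reports the fraction recovered
within one voxel (see docs/methods.md for why this fraction saturates below
1 — lateral localization through the hemodynamic point-spread function is
information-limited).
"""

from pathlib import Path

import fusnpx

OUT = Path("results")

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    df = fusnpx.alignment_recovery(
        region="SC", n_replicates=20, base_seed=1, n_candidates=10_000
    )
    df.to_csv(OUT / "alignment_robustness.csv", index=False, float_format="%.6g")
    within1 = (df.tip_err_vox <= 1).mean()
    print(df.to_string(index=False))
    print(
        f"tip recovered within 1 voxel in {within1:.0%} of replicates "
        f"(median error {df.tip_err_vox.median():.1f} voxels)"
    )
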