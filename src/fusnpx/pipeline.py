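"""Multi-session orchestration: simulate -> analyze -> aggregate -> report.

``run_all`` executes the whole analysis for a configured set of regions and
sessions, writing tidy CSV results, a group-statistics JSON and a manifest
(config hash, seeds, output hashes) so that a run is fully reproducible from
its config and seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .experiments import recovery_batch, summarize_batch
from .metrics import drop_outliers, group_compare

__all__ = ["RunConfig", "run_all", "report"]

log = logging.getLogger("fusnpx")

GROUP_METRICS = [
    "slope",
    "r2_amp",
    "tf_time_to_peak_s",
    "tf_fwhm_s",
    "spatial_r",
    "spatial_dfwhm_mm",
]


@dataclass(frozen=True)
class RunConfig:
    """Serialized settings that fully determine every output artifact."""

    regions: dict[str, int] = field(
        default_factory=lambda: {"SC": 12, "LGN": 9, "V1": 9}
    )
    n_trials: int = 20
    n_candidates: int = 2000
    base_seed: int = 1
    out_dir: str = "results/pipeline"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> Path:
    """Run every stage for every configured region; returns the results dir.

    Re-running with an identical config produces byte-identical CSV/JSON
    outputs. Sessions failing the inclusion filter are kept in the session
    table but listed separately in ``exclusions.csv`` and dropped from the
    group statistics.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for ri, (region, n_sessions) in enumerate(sorted(config.regions.items())):
        log.info(
            "region %s: %d sessions (base seed %d)",
            region,
            n_sessions,
            config.base_seed + ri,
        )
        results = recovery_batch(
            region=region,
            n_sessions=n_sessions,
            base_seed=config.base_seed * 7 + ri,
            n_trials=config.n_trials,
            n_candidates=config.n_candidates,
        )
        frames.append(summarize_batch(results))
    table = pd.concat(frames, ignore_index=True)
    sessions_csv = out / "sessions.csv"
    table.to_csv(sessions_csv, index=False, float_format="%.6g")

    excl = table[~table["included"]][["region", "seed", "exclusion_reason"]]
    exclusions_csv = out / "exclusions.csv"
    excl.to_csv(exclusions_csv, index=False)

    kept = table[table["included"]]
    stats: dict[str, dict] = {}
    regions = sorted(kept["region"].unique())
    for metric in GROUP_METRICS:
        entry: dict[str, object] = {}
        for a in range(len(regions)):
            for b in range(a + 1, len(regions)):
                ga = kept.loc[kept["region"] == regions[a], metric].to_numpy()
                gb = kept.loc[kept["region"] == regions[b], metric].to_numpy()
                if len(ga) >= 2 and len(gb) >= 2:
                    t, p = group_compare(
                        {regions[a]: ga, regions[b]: gb}, test="t"
                    )
                    entry[f"t_{regions[a]}_vs_{regions[b]}"] = {"t": t, "p": p}
        groups = {
            r: kept.loc[kept["region"] == r, metric].to_numpy() for r in regions
        }
        if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
            h, p = group_compare(groups, test="kruskal")
            entry["kruskal"] = {"H": h, "p": p}
        stats[metric] = entry
    group_json = out / "group_stats.json"
    group_json.write_text(json.dumps(stats, indent=2, sort_keys=True))

    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "outputs": {
            p.name: _sha256_file(p)
            for p in (sessions_csv, exclusions_csv, group_json)
        },
        "n_sessions": int(len(table)),
        "n_included": int(table["included"].sum()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def report(results_dir, make_plots: bool = False) -> pd.DataFrame:
    """Aggregate per-region summary of a ``run_all`` output directory.

    For each region and metric: mean, sd (reported missing for a single
    session, not zero), median and first/third quartiles (linear
    interpolation). Optionally writes simple figures (transfer-function
    coefficients cannot be re-plotted from the tidy table; figures cover the
    distribution metrics). FWHM-type collections have the mean + 2 sd
    outlier rule applied before aggregation.
    """
    results_dir = Path(results_dir)
    table = pd.read_csv(results_dir / "sessions.csv")
    if table.empty:
        raise ValueError("empty results table")
    kept = table[table["included"]]
    rows = []
    for region, grp in kept.groupby("region"):
        for metric in GROUP_METRICS:
            vals = grp[metric].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if metric.endswith("fwhm_s") or metric.endswith("fwhm_mm"):
                vals = drop_outliers(vals)
            if len(vals) == 0:
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])  # linear interpolation
            rows.append(
                {
                    "region": region,
                    "metric": metric,
                    "n": len(vals),
                    "mean": vals.mean(),
                    "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                    "q1": q1,
                    "median": med,
                    "q3": q3,
                }
            )
    summary = pd.DataFrame(rows)
    summary.to_csv(results_dir / "summary.csv", index=False, float_format="%.6g")
    if make_plots:
        _write_plots(kept, results_dir)
    return summary


def _write_plots(kept: pd.DataFrame, results_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(GROUP_METRICS), figsize=(3 * len(GROUP_METRICS), 3))
    for ax, metric in zip(np.atleast_1d(axes), GROUP_METRICS):
        data = [
            grp[metric].dropna().to_numpy() for _, grp in kept.groupby("region")
        ]
        labels = [r for r, _ in kept.groupby("region")]
        if all(len(d) for d in data):
            ax.violinplot(data, showmedians=True)
            ax.set_xticks(range(1, len(labels) + 1), labels)
        ax.set_title(metric, fontsize=8)
    fig.tight_layout()
    fig.savefig(results_dir / "group_metrics.png", dpi=120)
    plt.close(fig)
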