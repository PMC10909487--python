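"""End-to-end workflow: growth table → lag scan → bootstrap → diagnostics.

``run_full_analysis`` ties the stages together the way the field analysis is
run: estimate per-animal growth rates, scan candidate lags with the pooled
fixed-slope regression, bootstrap the growth rates for percentile intervals,
compute per-individual fractionation intercepts at the best lag, and write
tables, a JSON summary, a two-panel diagnostic figure (r² vs lag; hair vs
environment scatter with the unit-slope line) and a run manifest.

Output files are written atomically (write to a temp name, then rename) so a
failed run never leaves a partial file behind.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .estimators import (
    LagBootstrap,
    LagScanEstimator,
    per_individual_intercepts,
)
from .growth import GrowthRateRecord, growth_rate_table, printed_summary, summarize_rates
from .io import HairRecord, IsoScape, Trajectory, read_hair_records, read_isoscape, read_trajectories

__all__ = ["RunConfig", "run_full_analysis", "atomic_write_text"]

log = logging.getLogger("isolag")


@dataclass
class RunConfig:
    """Paths and parameters for one full analysis run."""

    hair_path: str
    segments_path: str
    trajectory_path: str
    isoscape_path: str
    outdir: str
    lag_start: float = 0.0
    lag_stop: float = 160.0
    lag_step: float = 10.0
    B: int = 5000
    seed: int | None = None
    slope: float = 1.0
    percentiles: tuple[float, float] = (2.5, 97.5)
    rate_mean: float | None = None  # default: estimated from the hair records
    rate_sd: float | None = None

    def __post_init__(self) -> None:
        if self.lag_step <= 0:
            raise ValueError("lag_step must be positive")
        if self.lag_stop < self.lag_start:
            raise ValueError("lag_stop must be >= lag_start")
        if self.B < 1:
            raise ValueError("B must be >= 1")

    @property
    def lag_grid(self) -> list[float]:
        grid = []
        lag = self.lag_start
        while lag <= self.lag_stop + 1e-9:
            grid.append(round(lag, 9))
            lag += self.lag_step
        return grid

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "percentiles" in d:
            d["percentiles"] = tuple(d["percentiles"])
        return cls(**d)


def atomic_write_text(path: Path, text: str) -> None:
    """Write via a temporary file and rename; never leaves partial output."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage named."""

    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
            log.info("stage %s: done", name)
            return False

    return _Ctx()


def run_full_analysis(
    config: RunConfig,
    hairs: Mapping[str, HairRecord] | None = None,
    trajs: Mapping[str, Trajectory] | None = None,
    scape: IsoScape | None = None,
) -> dict:
    """Run every stage and write all artifacts to ``config.outdir``.

    In-memory inputs may be passed directly (e.g. a simulated cohort);
    otherwise they are read from the configured paths.  Returns a result
    bundle with the growth table, scan result, bootstrap summary and
    per-individual intercepts.  Reruns with the same config and seed produce
    identical JSON outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with _stage("read-inputs"):
        if hairs is None:
            hairs = read_hair_records(config.hair_path, config.segments_path)
        if trajs is None:
            trajs = read_trajectories(config.trajectory_path)
        if scape is None:
            scape = read_isoscape(config.isoscape_path)

    with _stage("growth-rates"):
        table = growth_rate_table(hairs)
        records = [GrowthRateRecord.from_hair(h) for h in hairs.values()]
        cohort_summary = summarize_rates(records)
        printed = printed_summary(records)
        table_path = outdir / "growth_rates.csv"
        atomic_write_text(table_path, table.to_csv(index=False))

    segmented = {a: h for a, h in hairs.items() if h.segments is not None}
    if not segmented:
        raise RuntimeError("stage 'lag-scan' failed: no hair records carry segment values")

    with _stage("lag-scan"):
        scan = LagScanEstimator(lag_grid=config.lag_grid, slope=config.slope).fit(
            segmented, trajs, scape
        )
        atomic_write_text(outdir / "lag_scan.csv", scan.result_.to_frame().to_csv(index=False))
        observations = scan.observations_(segmented, trajs, scape)
        n_dropped = sum(h.n_segments for h in segmented.values()) - len(observations)
        log.info("lag scan: best lag %.0f d, %d observations, %d segments dropped",
                 scan.best_lag_, len(observations), n_dropped)

    with _stage("bootstrap"):
        boot = LagBootstrap(
            B=config.B,
            seed=config.seed,
            rate_mean=config.rate_mean,
            rate_sd=config.rate_sd,
            lag_grid=config.lag_grid,
            slope=config.slope,
            percentiles=config.percentiles,
        ).fit(segmented, trajs, scape)
        atomic_write_text(
            outdir / "bootstrap_replicates.csv",
            boot.replicates_.to_csv(index=False, float_format="%.6f"),
        )

    with _stage("per-individual"):
        if len(segmented) >= 2:
            intercepts, intercept_sd = per_individual_intercepts(
                observations, slope=config.slope
            )
        else:
            intercepts, intercept_sd = pd.Series(dtype=float), float("nan")

    with _stage("figure"):
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
        ax1.plot(scan.result_.lags, scan.result_.r2, "o-", color="black")
        ax1.axvline(scan.best_lag_, color="firebrick", ls="--",
                    label=f"best lag {scan.best_lag_:.0f} d")
        ax1.set_xlabel("lag (days)")
        ax1.set_ylabel(r"$r^2$")
        ax1.legend(frameon=False)
        env = [o.env_d34S for o in observations]
        hair = [o.hair_d34S for o in observations]
        ax2.scatter(env, hair, s=12, alpha=0.6, color="steelblue")
        if env:
            lo, hi = min(env), max(env)
            ax2.plot([lo, hi],
                     [config.slope * lo + scan.intercept_,
                      config.slope * hi + scan.intercept_],
                     color="firebrick",
                     label=f"slope {config.slope:g}, intercept {scan.intercept_:.2f}")
            ax2.legend(frameon=False)
        ax2.set_xlabel(r"environment $\delta^{34}$S (‰)")
        ax2.set_ylabel(r"hair $\delta^{34}$S (‰)")
        fig.tight_layout()
        fig.savefig(outdir / "lag_fit.png", dpi=120)
        plt.close(fig)

    summary = {
        "growth_rates": {
            "n_animals": len(records),
            "mean_mm_per_day": cohort_summary.mean,
            "sd_mm_per_day": cohort_summary.sd,
            "min_mm_per_day": cohort_summary.min,
            "max_mm_per_day": cohort_summary.max,
            "printed_style": dataclasses.asdict(printed),
        },
        "lag_scan": {
            "best_lag_days": scan.best_lag_,
            "r2_at_best": scan.r2_,
            "intercept_at_best_permil": scan.intercept_,
            "n_observations": len(observations),
            "n_segments_dropped": n_dropped,
        },
        "bootstrap": boot.summary_.to_dict(),
        "per_individual": {
            "intercepts_permil": {str(k): float(v) for k, v in intercepts.items()},
            "intercept_sd_permil": intercept_sd,
        },
    }
    atomic_write_text(outdir / "summary.json",
                      json.dumps(summary, indent=2, sort_keys=True) + "\n")
    manifest = {
        "config": {
            **{k: v for k, v in dataclasses.asdict(config).items()},
            "lag_grid": config.lag_grid,
        },
        "outputs": sorted(
            p.name for p in outdir.iterdir() if not p.name.startswith(".")
        ),
    }
    atomic_write_text(outdir / "run_manifest.json",
                      json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return {
        "growth_table": table,
        "scan": scan.result_,
        "bootstrap": boot.summary_,
        "per_individual_intercepts": intercepts,
        "per_individual_sd": intercept_sd,
        "summary": summary,
    }
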