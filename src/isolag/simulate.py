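"""Synthetic isoscapes, trajectories and hair-isotope series with known truth.

The generator emulates the statistical structure the lag analysis assumes for
a Serengeti-like system:

* a gridded δ³⁴S surface with a dominant north–south gradient plus smooth
  spatial noise, clipped to a plausible range;
* migratory animals oscillating annually along the gradient (one full
  north–south cycle per 365-day year) and residents confined to a small home
  range;
* tail hair growing at an animal-specific rate drawn from the cohort
  distribution, sectioned into 8 mm segments, each segment's δ³⁴S being the
  mean environmental value over its growth window shifted ``true_lag_days``
  into the past, plus a diet–hair fractionation offset, grass-level noise per
  GPS fix and analytical noise per segment.

Everything is a pure function of the configuration (including its seed), so
regenerating with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .growth import segment_bounds_ns
from .io import (
    SEGMENT_LENGTH_MM,
    HairRecord,
    IsoScape,
    Trajectory,
    parse_date,
    write_hair_records,
    write_isoscape,
    write_trajectories,
)

__all__ = [
    "SimConfig",
    "Cohort",
    "simulate_isoscape",
    "simulate_trajectory",
    "simulate_hair",
    "simulate_cohort",
    "make_fixture_cohort",
]

_DAY_NS = 86_400_000_000_000

#: months counted as dry season (5 months, June-October) in the simulated year
DRY_MONTHS = (6, 7, 8, 9, 10)
#: months counted as wet season (December-April)
WET_MONTHS = (12, 1, 2, 3, 4)
#: lactation runs from calving in February to weaning in September
LACTATION_MONTHS = (2, 3, 4, 5, 6, 7, 8)


@dataclass
class SimConfig:
    """Study conditions for a synthetic cohort.

    Defaults describe the system the estimator targets: hair growing at
    0.511 ± 0.062 mm/day sectioned into 8 mm segments, grass δ³⁴S varying
    site-to-site with SD 1.21‰, analytical repeatability 0.65‰, a landscape
    gradient inside −5…30‰, daily GPS fixes, and an 80-day (on-grid)
    ingestion-to-deposition lag with a 2.1‰ diet–hair fractionation.
    """

    seed: int = 0
    n_migratory: int = 5
    n_resident: int = 6
    movement_mode: Literal["both", "migratory", "resident"] = "both"
    true_lag_days: float = 80.0
    true_fractionation_permil: float = 2.1
    fractionation_sd_permil: float = 0.0  # animal-level spread of the offset
    rate_mean: float = 0.511  # mm/day
    rate_sd: float = 0.062
    grass_sd_permil: float = 1.21  # site-level δ³⁴S SD, applied per fix
    analytical_sd_permil: float = 0.65  # per-segment measurement SD
    isoscape_range: tuple[float, float] = (-5.0, 30.0)
    duration_days: int = 420  # shave to collection, ~14 months as in the field
    fix_interval_days: float = 1.0
    start_date: str = "2016-06-01"
    warmup_days: float | None = None  # GPS coverage before the shave date

    # isoscape grid: 120 km x 240 km at 2 km cells, values in per mil
    ncols: int = 60
    nrows: int = 120
    cell_size: float = 2000.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    gradient_south_permil: float = 13.0  # grass values measured in the field
    gradient_north_permil: float = 2.0
    isoscape_noise_sd: float = 1.5
    isoscape_noise_scale_cells: float = 8.0

    migration_amplitude_frac: float = 0.42  # fraction of the grid height
    track_jitter_sd_m: float = 800.0
    resident_radius_m: float = 4000.0

    def __post_init__(self) -> None:
        if self.rate_sd < 0 or self.grass_sd_permil < 0 or self.analytical_sd_permil < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.true_lag_days < 0:
            raise ValueError("true lag must be non-negative")
        min_dur = self.true_lag_days + SEGMENT_LENGTH_MM / max(self.rate_mean, 1e-9)
        if self.duration_days < min_dur:
            raise ValueError(
                f"duration_days must cover the lag plus one segment (~{min_dur:.0f} d)"
            )

    @property
    def warmup(self) -> float:
        if self.warmup_days is not None:
            return self.warmup_days
        return self.true_lag_days + 40.0

    @property
    def width(self) -> float:
        return self.ncols * self.cell_size

    @property
    def height(self) -> float:
        return self.nrows * self.cell_size

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "isoscape_range" in d:
            d["isoscape_range"] = tuple(d["isoscape_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["isoscape_range"] = list(d["isoscape_range"])
        return d


@dataclass
class Cohort:
    """A simulated cohort plus its ground truth."""

    config: SimConfig
    scape: IsoScape
    trajectories: dict[str, Trajectory]
    hairs: dict[str, HairRecord]
    truth: dict


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def simulate_isoscape(config: SimConfig,
                      rng: np.random.Generator | None = None) -> IsoScape:
    """Smooth δ³⁴S field: linear north–south gradient + low-frequency noise.

    Row 0 is the northern edge.  With ``isoscape_noise_sd = 0`` the field is
    a pure monotone gradient along y; values are clipped to
    ``config.isoscape_range``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    # cell-centre y as fraction of height (1 = north edge), row 0 = north
    fy = (np.arange(config.nrows)[::-1] + 0.5) / config.nrows
    base = config.gradient_south_permil + fy * (
        config.gradient_north_permil - config.gradient_south_permil
    )
    grid = np.tile(base[:, None], (1, config.ncols))
    if config.isoscape_noise_sd > 0:
        white = rng.standard_normal((config.nrows, config.ncols))
        noise = gaussian_filter(white, sigma=config.isoscape_noise_scale_cells)
        sd = noise.std()
        if sd > 0:
            grid = grid + noise * (config.isoscape_noise_sd / sd)
    grid = np.clip(grid, *config.isoscape_range)
    return IsoScape(grid=grid, origin_x=config.origin_x, origin_y=config.origin_y,
                    cell_size=config.cell_size)


def _times(config: SimConfig) -> tuple[pd.DatetimeIndex, np.ndarray]:
    """Fix timestamps from warmup start to collection, and days since shave."""
    start = pd.Timestamp(parse_date(config.start_date))
    n = int(np.floor((config.duration_days + config.warmup) / config.fix_interval_days)) + 1
    t_days = np.arange(n) * config.fix_interval_days - config.warmup
    times = start + pd.to_timedelta(np.round(t_days * _DAY_NS).astype(np.int64), unit="ns")
    return pd.DatetimeIndex(times), t_days


def _ou(rng: np.random.Generator, n: int, dt: float, tau: float, sd: float) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck noise (mean 0, SD ``sd``, timescale ``tau`` d)."""
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    a = np.exp(-dt / tau)
    innov_sd = sd * np.sqrt(1 - a * a)
    shocks = rng.normal(0.0, innov_sd, size=n - 1) if n > 1 else np.empty(0)
    for i in range(1, n):
        x[i] = a * x[i - 1] + shocks[i - 1]
    return x


def simulate_trajectory(config: SimConfig, animal_id: str,
                        mode: Literal["migratory", "resident"],
                        rng: np.random.Generator) -> Trajectory:
    """One GPS track covering ``[shave − warmup, collection]``.

    Migrants follow a sinusoidal annual north–south oscillation spanning the
    isotopic gradient, with small OU jitter in both axes; residents perform a
    mean-reverting walk hard-clipped to a disc around their home centre.
    """
    times, t_days = _times(config)
    n = len(t_days)
    dt = config.fix_interval_days
    margin = 2 * config.cell_size

    if mode == "migratory":
        y_mid = config.origin_y + config.height / 2
        amp = config.migration_amplitude_frac * config.height
        phase = rng.uniform(0, 2 * np.pi)
        y = y_mid + amp * np.sin(2 * np.pi * t_days / 365.0 + phase)
        y = y + _ou(rng, n, dt, tau=5.0, sd=config.track_jitter_sd_m)
        x_mid = config.origin_x + config.width / 2
        x = x_mid + _ou(rng, n, dt, tau=30.0, sd=config.width / 8)
    else:
        home_x = config.origin_x + rng.uniform(
            config.resident_radius_m + margin,
            config.width - config.resident_radius_m - margin,
        )
        home_y = config.origin_y + rng.uniform(
            config.resident_radius_m + margin,
            config.height - config.resident_radius_m - margin,
        )
        dx = _ou(rng, n, dt, tau=3.0, sd=config.resident_radius_m / 2.5)
        dy = _ou(rng, n, dt, tau=3.0, sd=config.resident_radius_m / 2.5)
        r = np.hypot(dx, dy)
        over = r > config.resident_radius_m
        scale = np.where(over, config.resident_radius_m / np.where(r > 0, r, 1.0), 1.0)
        x = home_x + dx * scale
        y = home_y + dy * scale

    x = np.clip(x, config.origin_x + margin, config.origin_x + config.width - margin)
    y = np.clip(y, config.origin_y + margin, config.origin_y + config.height - margin)
    return Trajectory(animal_id=animal_id, times=times, x=x, y=y)


def _days_in_months(start: date, end: date, months: tuple[int, ...]) -> int:
    d = pd.date_range(start, end, inclusive="left")
    return int(d.month.isin(months).sum())


def simulate_hair(config: SimConfig, traj: Trajectory, scape: IsoScape,
                  rng: np.random.Generator,
                  fractionation: float | None = None) -> tuple[HairRecord, dict]:
    """Grow and section one hair; returns the record and its ground truth.

    The animal's growth rate is drawn from ``Normal(rate_mean, rate_sd)``
    truncated to positive values; hair length is the grown length rounded
    down to a whole number of 8 mm segments.  Segment i's δ³⁴S is the mean
    over GPS fixes in its window shifted ``true_lag_days`` earlier of
    (isoscape value + grass noise), plus the fractionation offset and one
    analytical noise draw.
    """
    rate = rng.normal(config.rate_mean, config.rate_sd)
    while rate <= 0:
        rate = rng.normal(config.rate_mean, config.rate_sd)
    if fractionation is None:
        fractionation = config.true_fractionation_permil + (
            rng.normal(0.0, config.fractionation_sd_permil)
            if config.fractionation_sd_permil > 0
            else 0.0
        )

    start = parse_date(config.start_date)
    end = start + timedelta(days=config.duration_days)
    n_seg = int(np.floor(rate * config.duration_days / SEGMENT_LENGTH_MM))
    if n_seg < 1:
        raise ValueError("growth period too short to grow a full segment")
    length = n_seg * SEGMENT_LENGTH_MM

    end_ns = pd.Timestamp(end).value
    starts, ends = segment_bounds_ns(end_ns, n_seg, rate, config.true_lag_days)
    times_ns = traj.times.asi8
    if starts[-1] < times_ns[0]:
        short = (times_ns[0] - starts[-1]) / _DAY_NS
        raise ValueError(
            f"{traj.animal_id}: GPS record starts {short:.1f} d too late for the "
            f"lag-shifted distal segment; increase warmup_days"
        )

    clean = scape.sample(traj.x, traj.y)
    noisy = clean + (
        rng.normal(0.0, config.grass_sd_permil, size=clean.size)
        if config.grass_sd_permil > 0
        else 0.0
    )
    i = np.searchsorted(times_ns, starts, side="left")
    j = np.searchsorted(times_ns, ends, side="left")
    values = np.empty(n_seg)
    for k in range(n_seg):
        window_vals = noisy[i[k]:j[k]]
        window_vals = window_vals[np.isfinite(window_vals)]
        if window_vals.size == 0:
            raise ValueError(
                f"{traj.animal_id}: segment {k} has no usable fixes in simulation"
            )
        values[k] = window_vals.mean() + fractionation
    if config.analytical_sd_permil > 0:
        values = values + rng.normal(0.0, config.analytical_sd_permil, size=n_seg)

    record = HairRecord(
        animal_id=traj.animal_id,
        start_date=start,
        end_date=end,
        length_mm=length,
        segments=values,
        days_dry=float(_days_in_months(start, end, DRY_MONTHS)),
        days_wet=float(_days_in_months(start, end, WET_MONTHS)),
        days_lactating=(
            float(_days_in_months(start, end, LACTATION_MONTHS))
            if rng.uniform() < 0.6
            else 0.0
        ),
    )
    truth = {"rate_mm_per_day": float(rate), "fractionation_permil": float(fractionation)}
    return record, truth


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate the full study: isoscape, one track and one hair per animal.

    Default cohort is 5 migratory plus 6 resident animals, matching the
    field design the analysis was built for.  Animal ids are ``M01..`` and
    ``R01..``; all randomness derives from ``config.seed``.
    """
    root = np.random.SeedSequence([int(config.seed), 0])
    ss_scape, ss_animals = root.spawn(2)
    scape = simulate_isoscape(config, np.random.default_rng(ss_scape))

    plan: list[tuple[str, str]] = []
    if config.movement_mode in ("both", "migratory"):
        plan += [(f"M{k + 1:02d}", "migratory") for k in range(config.n_migratory)]
    if config.movement_mode in ("both", "resident"):
        plan += [(f"R{k + 1:02d}", "resident") for k in range(config.n_resident)]
    if not plan:
        raise ValueError("empty cohort")

    trajs: dict[str, Trajectory] = {}
    hairs: dict[str, HairRecord] = {}
    per_animal: dict[str, dict] = {}
    for (animal_id, mode), ss in zip(plan, ss_animals.spawn(len(plan))):
        rng = np.random.default_rng(ss)
        traj = simulate_trajectory(config, animal_id, mode, rng)
        hair, truth = simulate_hair(config, traj, scape, rng)
        trajs[animal_id] = traj
        hairs[animal_id] = hair
        per_animal[animal_id] = {**truth, "mode": mode}

    truth = {
        "true_lag_days": config.true_lag_days,
        "true_fractionation_permil": config.true_fractionation_permil,
        "rate_mean": config.rate_mean,
        "rate_sd": config.rate_sd,
        "animals": per_animal,
    }
    return Cohort(config=config, scape=scape, trajectories=trajs, hairs=hairs,
                  truth=truth)


def make_fixture_cohort(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated cohort to disk as plain-text files.

    Emits ``trajectories.csv``, ``hair.csv``, ``segments.csv``,
    ``isoscape.asc`` and ``truth.json``; regenerating with the same config is
    byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config)
    paths = {
        "trajectories": outdir / "trajectories.csv",
        "hair": outdir / "hair.csv",
        "segments": outdir / "segments.csv",
        "isoscape": outdir / "isoscape.asc",
        "truth": outdir / "truth.json",
    }
    write_trajectories(cohort.trajectories, paths["trajectories"])
    write_hair_records(cohort.hairs, paths["hair"], paths["segments"])
    write_isoscape(cohort.scape, paths["isoscape"])
    payload = {"config": cohort.config.to_dict(), "truth": cohort.truth}
    paths["truth"].write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return paths
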