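"""Forward simulator of tiller growth and the study's two measurement instruments.

Each tiller carries a ladder of phytomers whose total length follows a
logistic time course; successive phytomers are one phyllochron apart.  An
explicit 1-D height model (stacked internodes, sheath tubes, blades) turns
the hidden trajectories into what a ruler can see: daily distances from
each emerged tip to the next older visible ligule, censored before tip
emergence and rounded to the measurement resolution.  A destructive
dissection snapshot provides blade/sheath/internode lengths at harvest.

The defaults emulate the study design: a 2x2 nitrogen x VPD factorial, two
growth chambers per treatment, eight tillers per chamber, daily
observations on days 24-37 and dissection on day 37.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .growth_model import (
    PartitionThresholds,
    SigmoidCurve,
    invert_sigmoid,
    partition_components,
)

__all__ = [
    "TreatmentSpec",
    "GeneratorConfig",
    "PhytomerTrajectory",
    "simulate_tiller",
    "emulate_observations",
    "emulate_dissection",
    "generate_experiment",
    "default_config",
    "round_to_resolution",
]

#: Fraction of final length at which a phytomer is called fully expanded.
MATURITY_FRACTION = 0.99


@dataclass(frozen=True)
class TreatmentSpec:
    """One cell of the N x VPD factorial with its parameter overrides.

    ``tiller_count`` is the plant-level number of tillers reported for the
    treatment; tillering is not simulated mechanistically, the count enters
    summaries as a per-treatment constant.
    """

    n_level: str
    vpd_level: str
    phyllochron: float = 2.3
    plateau_scale: float = 1.0
    tiller_count: float = 21.0

    @property
    def name(self) -> str:
        return f"{self.n_level}{self.vpd_level}"


def _default_treatments() -> tuple[TreatmentSpec, ...]:
    # Phyllochron and tiller counts per treatment cell; high N at low VPD
    # also increases final phytomer length by 8 %.
    return (
        TreatmentSpec("N1", "V1", phyllochron=2.4, tiller_count=19.7),
        TreatmentSpec("N1", "V2", phyllochron=2.4, tiller_count=17.6),
        TreatmentSpec("N2", "V1", phyllochron=2.1, plateau_scale=1.08, tiller_count=24.0),
        TreatmentSpec("N2", "V2", phyllochron=2.4, tiller_count=21.7),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the forward simulator.

    Time is in days after seed imbibition, lengths in mm.  The complete
    time course of a phytomer's fraction of final length is the logistic
    with midpoint ``timecourse_x0`` and scale ``timecourse_b`` on a clock
    whose zero (``initiation`` clock of rank n, at
    ``n * phyllochron + start_offset``) nominally coincides with tip
    emergence; actual emergence is decided by the height model.

    ``tube_fraction`` is the effective height of the sheath tube enclosing
    a young phytomer, as a fraction of the tube-forming phytomer's final
    length.  Its default is calibrated so that tips emerge at ~26-27 % of
    final length, as observed.
    """

    phyllochron: float = 2.3
    timecourse_x0: float = 1.82
    timecourse_b: float = 1.81
    plateau_length: float = 100.0
    decline_start_rank: int = 8
    decline_per_rank: float = 0.04
    rank_min: int = 1
    rank_max: int = 22
    thresholds: PartitionThresholds = field(default_factory=PartitionThresholds)
    tube_fraction: float = 0.241
    length_cv: float = 0.10
    tiller_size_share: float = 0.8
    timing_sd: float = 0.2
    measurement_resolution: float = 0.5
    window_start: int = 24
    window_end: int = 37
    dissection_day: int = 37
    min_dissect_length: float = 4.0
    start_offset: float = -4.5
    seed: int = 0
    treatments: tuple[TreatmentSpec, ...] = field(default_factory=_default_treatments)
    chambers_per_treatment: int = 2
    tillers_per_chamber: int = 8

    def __post_init__(self) -> None:
        if self.phyllochron <= 0 or self.plateau_length <= 0:
            raise ValueError("phyllochron and plateau_length must be positive")
        if self.timecourse_b <= 0 or self.tube_fraction <= 0:
            raise ValueError("timecourse_b and tube_fraction must be positive")
        if self.measurement_resolution <= 0:
            raise ValueError("measurement_resolution must be positive")
        if not (self.rank_min >= 1 and self.rank_max > self.rank_min):
            raise ValueError("need rank_min >= 1 and rank_max > rank_min")
        if self.window_end < self.window_start:
            raise ValueError("observation window is empty")
        # final lengths must stay positive across the simulated ranks
        worst = 1.0 - self.decline_per_rank * (self.rank_max - self.decline_start_rank)
        if worst <= 0:
            raise ValueError("rank decline drives final lengths non-positive")

    @property
    def n_tillers(self) -> int:
        return (
            len(self.treatments)
            * self.chambers_per_treatment
            * self.tillers_per_chamber
        )

    def timecourse(self) -> SigmoidCurve:
        return SigmoidCurve(1.0, self.timecourse_x0, self.timecourse_b)

    def without_noise(self) -> "GeneratorConfig":
        """Copy with length and timing noise switched off."""
        return replace(self, length_cv=0.0, timing_sd=0.0)

    def rank_profile(self, ranks) -> np.ndarray:
        """Expected final length by rank: plateau, then linear decline."""
        r = np.asarray(ranks, dtype=float)
        drop = np.maximum(r - self.decline_start_rank, 0.0) * self.decline_per_rank
        return self.plateau_length * (1.0 - drop)


@dataclass
class PhytomerTrajectory:
    """Ground truth for one phytomer: parameters, events and daily series."""

    rank: int
    final_length: float
    initiation_time: float  # clock zero of the logistic time course
    tube_length: float  # height of this phytomer's sheath tube when complete
    true_emergence_day: float
    true_cessation_day: float
    days: np.ndarray
    total: np.ndarray
    blade: np.ndarray
    sheath: np.ndarray
    internode: np.ndarray

    def fraction_at(self, t, curve: SigmoidCurve):
        return curve(np.asarray(t, dtype=float) - self.initiation_time)


def round_to_resolution(x, resolution: float):
    """Round half-up to the nearest multiple of ``resolution``."""
    return np.floor(np.asarray(x, dtype=float) / resolution + 0.5) * resolution


class _TillerKinetics:
    """Vectorized evaluation of one tiller's lengths and heights."""

    def __init__(self, config: GeneratorConfig, treatment: TreatmentSpec, rng):
        self.config = config
        self.treatment = treatment
        self.ranks = np.arange(config.rank_min, config.rank_max + 1)
        n = self.ranks.size

        jitter = (
            rng.normal(0.0, config.timing_sd, size=n) if config.timing_sd > 0 else 0.0
        )
        self.offsets = (
            self.ranks * treatment.phyllochron + config.start_offset + jitter
        )

        base = config.rank_profile(self.ranks) * treatment.plateau_scale
        if config.length_cv > 0:
            # size heterogeneity is mostly a tiller-level property (a big
            # plant has uniformly big phytomers); the remainder is an
            # independent per-phytomer residual.  The split keeps the
            # total CV at length_cv.
            var = math.log(1.0 + config.length_cv**2)
            s_tiller = math.sqrt(config.tiller_size_share * var)
            s_rank = math.sqrt((1.0 - config.tiller_size_share) * var)
            tiller_factor = rng.lognormal(mean=-0.5 * s_tiller**2, sigma=s_tiller)
            noise = tiller_factor * rng.lognormal(
                mean=-0.5 * s_rank**2, sigma=s_rank, size=n
            )
        else:
            noise = 1.0
        self.final_lengths = base * noise
        self.tube_lengths = config.tube_fraction * self.final_lengths
        self.curve = config.timecourse()
        # a ligule becomes visible once its sheath has ceased elongating
        self.visible_from = self.offsets + invert_sigmoid(
            self.curve, config.thresholds.internode_onset * MATURITY_FRACTION
        )

    def fractions(self, t) -> np.ndarray:
        """Fraction of final length, ranks x times.

        Elongation terminates when the logistic reaches the maturity
        fraction (99 % of its asymptote): the curve is rescaled so the
        final length is attained exactly there and growth is flat after.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        raw = self.curve(t[None, :] - self.offsets[:, None])
        return np.minimum(raw / MATURITY_FRACTION, 1.0)

    def component_lengths(self, t):
        f = self.fractions(t)
        blade_f, sheath_f, inter_f = partition_components(f, self.config.thresholds)
        lp = self.final_lengths[:, None]
        return blade_f * lp, sheath_f * lp, inter_f * lp

    def heights(self, t):
        """Node, ligule and tip heights (mm above tiller base), ranks x times.

        Node of rank j sits on the stacked internodes of ranks <= j; the
        ligule (top of the sheath tube) sits ``tube_length`` above the node
        once visible; the blade tip sits at node + sheath + blade.
        """
        blade, sheath, inter = self.component_lengths(t)
        node = np.cumsum(inter, axis=0)
        ligule = node + self.tube_lengths[:, None]
        tip = node + sheath + blade
        t = np.atleast_1d(np.asarray(t, dtype=float))
        visible = t[None, :] >= self.visible_from[:, None]
        return node, ligule, tip, visible

    def barrier(self, t):
        """Height of the highest visible ligule below each rank.

        The first simulated rank emerges from the base (height 0); any
        later rank stays censored (-inf barrier is never crossed downward,
        so we mark it unemergeable) until an older ligule is visible.
        """
        _, ligule, tip, visible = self.heights(t)
        lig = np.where(visible, ligule, -np.inf)
        barrier = np.full_like(lig, -np.inf)
        barrier[1:] = np.maximum.accumulate(lig, axis=0)[:-1]
        barrier[0] = 0.0
        return barrier, tip

    def reference_ligule(self, t_scalar: float, rank: int):
        """(rank, height) of the next older visible ligule, or (0, 0.0)."""
        _, ligule, _, visible = self.heights([t_scalar])
        idx = np.nonzero((self.ranks < rank) & visible[:, 0])[0]
        if idx.size == 0:
            return 0, 0.0
        heights = ligule[idx, 0]
        j = idx[np.argmax(heights)]
        return int(self.ranks[j]), float(heights.max())

    def emergence_days(self, t_grid: np.ndarray) -> np.ndarray:
        """First time each tip exceeds the highest visible older ligule."""
        barrier, tip = self.barrier(t_grid)
        above = (tip > barrier) & np.isfinite(barrier)
        out = np.full(self.ranks.size, np.nan)
        for i in range(self.ranks.size):
            hits = np.nonzero(above[i])[0]
            if hits.size == 0:
                continue
            k = hits[0]
            if k == 0 or not np.isfinite(barrier[i, k - 1]):
                out[i] = t_grid[k]
                continue
            # linear refinement between the bracketing grid points
            g0 = tip[i, k - 1] - barrier[i, k - 1]
            g1 = tip[i, k] - barrier[i, k]
            w = -g0 / (g1 - g0) if g1 != g0 else 0.0
            out[i] = t_grid[k - 1] + w * (t_grid[k] - t_grid[k - 1])
        return out


def simulate_tiller(
    config: GeneratorConfig,
    rng: np.random.Generator,
    treatment: TreatmentSpec | None = None,
    grid_step: float = 0.01,
) -> list[PhytomerTrajectory]:
    """Simulate one tiller and return per-phytomer ground-truth trajectories."""
    treatment = treatment or config.treatments[0]
    kin = _TillerKinetics(config, treatment, rng)

    t0 = min(float(kin.offsets.min()) - 5.0, 0.0)
    t1 = config.dissection_day + 1.0
    grid = np.arange(t0, t1 + grid_step, grid_step)
    emergence = kin.emergence_days(grid)
    cessation = kin.offsets + invert_sigmoid(kin.curve, MATURITY_FRACTION)

    days = np.arange(config.window_start, config.window_end + 1, dtype=float)
    blade, sheath, inter = kin.component_lengths(days)
    total = blade + sheath + inter

    out = []
    for i, rank in enumerate(kin.ranks):
        out.append(
            PhytomerTrajectory(
                rank=int(rank),
                final_length=float(kin.final_lengths[i]),
                initiation_time=float(kin.offsets[i]),
                tube_length=float(kin.tube_lengths[i]),
                true_emergence_day=float(emergence[i]),
                true_cessation_day=float(cessation[i]),
                days=days.copy(),
                total=total[i].copy(),
                blade=blade[i].copy(),
                sheath=sheath[i].copy(),
                internode=inter[i].copy(),
            )
        )
    out[0]._kinetics = kin  # kept for the measurement emulators
    return out


def _kinetics_of(trajectories: Sequence[PhytomerTrajectory]) -> _TillerKinetics:
    if not trajectories:
        raise ValueError("empty trajectory list")
    kin = getattr(trajectories[0], "_kinetics", None)
    if kin is None:
        raise ValueError("trajectories were not produced by simulate_tiller")
    return kin


def emulate_observations(
    trajectories: Sequence[PhytomerTrajectory],
    config: GeneratorConfig,
    tiller_id: str = "t0",
    treatment: TreatmentSpec | None = None,
    chamber: int = 1,
) -> pd.DataFrame:
    """Daily ruler records: tip to next older visible ligule, rounded.

    One record per emerged rank per observation day.  The reported
    distance is tip height minus the height of the highest visible older
    ligule (the tiller base when none exists), rounded half-up to the
    measurement resolution.
    """
    kin = _kinetics_of(trajectories)
    treatment = treatment or kin.treatment
    emergence = {tr.rank: tr.true_emergence_day for tr in trajectories}
    visible_from = dict(zip(kin.ranks.tolist(), kin.visible_from.tolist()))

    rows = []
    for day in range(config.window_start, config.window_end + 1):
        _, ligule, tip, visible = kin.heights([float(day)])
        for i, rank in enumerate(kin.ranks):
            em = emergence.get(int(rank), np.nan)
            if not np.isfinite(em) or em > day:
                continue
            ref_rank, ref_height = kin.reference_ligule(float(day), int(rank))
            raw = tip[i, 0] - ref_height
            dist = float(
                round_to_resolution(max(raw, 0.0), config.measurement_resolution)
            )
            rows.append(
                {
                    "treatment": treatment.name,
                    "n_level": treatment.n_level,
                    "vpd_level": treatment.vpd_level,
                    "chamber": chamber,
                    "tiller_id": tiller_id,
                    "day": day,
                    "rank": int(rank),
                    "distance": dist,
                    "reference_ligule_rank": ref_rank,
                    "own_ligule_visible": bool(day >= visible_from[int(rank)]),
                }
            )
    return pd.DataFrame(rows)


def emulate_dissection(
    trajectories: Sequence[PhytomerTrajectory],
    day: float,
    config: GeneratorConfig,
    tiller_id: str = "t0",
    treatment: TreatmentSpec | None = None,
    chamber: int = 1,
) -> pd.DataFrame:
    """Destructive harvest snapshot: component lengths per phytomer.

    Components are rounded to the measurement resolution; phytomer length
    is the sum of the rounded components.  Phytomers at or below
    ``min_dissect_length`` are dropped (shoot apex and primordia).
    """
    if not (config.window_start <= day <= config.dissection_day + 1e-9):
        raise ValueError(f"dissection day {day} outside the simulated range")
    kin = _kinetics_of(trajectories)
    treatment = treatment or kin.treatment
    blade, sheath, inter = kin.component_lengths([float(day)])
    f = kin.fractions([float(day)])[:, 0]
    res = config.measurement_resolution
    rows = []
    for i, rank in enumerate(kin.ranks):
        b = float(round_to_resolution(blade[i, 0], res))
        s = float(round_to_resolution(sheath[i, 0], res))
        n = float(round_to_resolution(inter[i, 0], res))
        total = b + s + n
        if total <= config.min_dissect_length:
            continue
        rows.append(
            {
                "treatment": treatment.name,
                "n_level": treatment.n_level,
                "vpd_level": treatment.vpd_level,
                "chamber": chamber,
                "tiller_id": tiller_id,
                "rank": int(rank),
                "blade": b,
                "sheath": s,
                "internode": n,
                "phytomer_length": total,
                "maturity": "mature" if f[i] >= 1.0 - 1e-9 else "immature",
            }
        )
    return pd.DataFrame(rows)


def _truth_frame(
    trajectories, tiller_id, treatment, chamber, tiller_count
) -> pd.DataFrame:
    rows = []
    for tr in trajectories:
        rows.append(
            {
                "treatment": treatment.name,
                "n_level": treatment.n_level,
                "vpd_level": treatment.vpd_level,
                "chamber": chamber,
                "tiller_id": tiller_id,
                "rank": tr.rank,
                "final_length": tr.final_length,
                "initiation_day": tr.initiation_time,
                "true_emergence_day": tr.true_emergence_day,
                "true_cessation_day": tr.true_cessation_day,
                "tube_length": tr.tube_length,
                "phyllochron": treatment.phyllochron,
                "tiller_count": tiller_count,
            }
        )
    return pd.DataFrame(rows)


def generate_experiment(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the full factorial experiment.

    Returns (observations, dissection, truth) tables.  Reproducible: the
    same config (including seed) yields identical tables.
    """
    seed_seq = np.random.SeedSequence(config.seed)
    streams = seed_seq.spawn(config.n_tillers)

    obs_parts, diss_parts, truth_parts = [], [], []
    k = 0
    for treatment in config.treatments:
        for chamber_idx in range(config.chambers_per_treatment):
            chamber = f"{treatment.name}-ch{chamber_idx + 1}"
            for plant in range(config.tillers_per_chamber):
                tiller_id = f"{treatment.name}-c{chamber_idx + 1}-p{plant + 1}"
                rng = np.random.default_rng(streams[k])
                k += 1
                trajs = simulate_tiller(config, rng, treatment)
                obs_parts.append(
                    emulate_observations(trajs, config, tiller_id, treatment, chamber)
                )
                diss_parts.append(
                    emulate_dissection(
                        trajs,
                        config.dissection_day,
                        config,
                        tiller_id,
                        treatment,
                        chamber,
                    )
                )
                truth_parts.append(
                    _truth_frame(
                        trajs, tiller_id, treatment, chamber, treatment.tiller_count
                    )
                )

    obs = pd.concat(obs_parts, ignore_index=True)
    diss = pd.concat(diss_parts, ignore_index=True)
    truth = pd.concat(truth_parts, ignore_index=True)
    return obs, diss, truth


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """The study-sized default: 4 treatments x 2 chambers x 8 tillers."""
    return GeneratorConfig(seed=seed, **overrides)
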