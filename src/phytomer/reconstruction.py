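"""Reconstruction of phytomer development from ruler and dissection tables.

The analysis chain mirrors how the greenhouse data were processed:

1. tip-emergence days, corrected for the lag between emergence and the
   first daily observation (first distance / initial elongation rate);
2. per-tiller phyllochron from consecutive emergence days;
3. cessation of elongation from stagnating distances;
4. final lengths of still-growing phytomers extrapolated per tiller from
   the mature length-vs-rank relationship;
5. normalization to fraction of final length, f_L = La / Lp;
6. the visible time course rebuilt backwards from the measured final
   length, and ages of unemerged phytomers assigned by anchoring one
   immature phytomer (60-80 % of final length) on the fitted visible
   curve and stepping down in whole phyllochrons;
7. within- and between-phytomer coordination tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth_model import SigmoidCurve, invert_sigmoid

logger = logging.getLogger(__name__)

__all__ = [
    "estimate_emergence",
    "compute_phyllochron",
    "detect_full_expansion",
    "predict_final_length",
    "predict_final_lengths",
    "fraction_of_final",
    "build_visible_timecourse",
    "assign_invisible_ages",
    "build_coordination_tables",
    "ReconstructionResult",
    "reconstruct",
]


def fraction_of_final(actual_length, predicted_final_length):
    """f_L = La / Lp, the normalized state of a phytomer or component."""
    lp = np.asarray(predicted_final_length, dtype=float)
    if np.any(lp <= 0):
        raise ValueError("predicted final length must be positive")
    la = np.asarray(actual_length, dtype=float)
    out = la / lp
    return float(out) if out.ndim == 0 else out


def estimate_emergence(
    observations: pd.DataFrame,
    resolution: float = 0.5,
    rate_increments: int = 1,
) -> pd.DataFrame:
    """Estimate tip-emergence days from the daily distance records.

    The tip of a phytomer may have emerged between two daily visits; the
    lag is estimated as first distance divided by the elongation rate just
    after emergence (the first one-day increment, or the mean of the first
    ``rate_increments``).  Ranks already present on the first day of a
    tiller's record are censored (their emergence was not witnessed) and
    are excluded.  Non-positive rates are flagged and excluded downstream.
    """
    rows = []
    for tiller_id, tdf in observations.groupby("tiller_id", sort=False):
        window_start = int(tdf["day"].min())
        for rank, g in tdf.groupby("rank", sort=True):
            g = g.sort_values("day")
            days = g["day"].to_numpy(dtype=float)
            dist = g["distance"].to_numpy(dtype=float)
            first_day, first_dist = days[0], dist[0]
            if first_day <= window_start:
                continue  # censored: emerged before monitoring started
            if len(days) < 3:
                continue
            ref = g["reference_ligule_rank"].to_numpy()
            # rate just following emergence: the first usable one-day
            # increment(s); an increment spanning a reference-ligule switch
            # is skipped (elongation in the quasi-linear early phase makes
            # the next-day increment an equivalent measure)
            rate = np.nan
            incs = []
            for i in range(min(4, len(days) - 1)):
                if days[i + 1] == days[i] + 1 and ref[i + 1] == ref[i]:
                    incs.append(dist[i + 1] - dist[i])
                    if len(incs) >= rate_increments:
                        break
            if incs:
                rate = float(np.mean(incs))
            # a zero first distance pins emergence to the observation day
            flagged = first_dist > 0 and (not np.isfinite(rate) or rate <= 0)
            lag = 0.0 if first_dist == 0 else (first_dist / rate if not flagged else np.nan)
            if flagged:
                logger.warning(
                    "tiller %s rank %s: non-positive initial elongation rate, "
                    "emergence not estimated",
                    tiller_id,
                    rank,
                )
            rows.append(
                {
                    "tiller_id": tiller_id,
                    "treatment": g["treatment"].iloc[0],
                    "rank": int(rank),
                    "first_observation_day": first_day,
                    "first_distance": first_dist,
                    "rate": rate,
                    "lag": lag,
                    "emergence_day": first_day - lag if not flagged else np.nan,
                    "flagged": flagged,
                }
            )
    return pd.DataFrame(rows)


def compute_phyllochron(
    events: pd.DataFrame,
    rank_window: tuple[int, int] = (7, 16),
    strict: bool = True,
) -> pd.DataFrame:
    """Per-tiller phyllochron: mean spacing of consecutive emergence days.

    Uses estimated emergence days of ranks inside ``rank_window``; a gap in
    the rank sequence contributes its per-rank average.  At least two
    usable events per tiller are required; with ``strict=False`` such
    tillers are skipped with a warning instead of raising.
    """
    if events.empty:
        raise ValueError("no emergence events")
    lo, hi = rank_window
    rows = []
    for tiller_id, g in events.groupby("tiller_id", sort=False):
        g = g[(~g["flagged"]) & g["rank"].between(lo, hi)].sort_values("rank")
        if len(g) < 2:
            msg = (
                f"tiller {tiller_id}: need >= 2 emergence events in ranks "
                f"{lo}-{hi} to compute a phyllochron"
            )
            if strict:
                raise ValueError(msg)
            logger.warning(msg)
            continue
        ranks = g["rank"].to_numpy(dtype=float)
        days = g["emergence_day"].to_numpy(dtype=float)
        per_rank = np.diff(days) / np.diff(ranks)
        rows.append(
            {
                "tiller_id": tiller_id,
                "treatment": g["treatment"].iloc[0],
                "phyllochron": float(np.mean(per_rank)),
                "n_intervals": len(per_rank),
            }
        )
    return pd.DataFrame(rows)


def detect_full_expansion(
    observations: pd.DataFrame,
    resolution: float = 0.5,
    k: int = 2,
) -> pd.DataFrame:
    """Find, per (tiller, rank), the day elongation ceased.

    A phytomer is mature from the first day after which the daily distance
    changes stay strictly below one resolution step for ``k`` consecutive
    days.  Series that are still changing at the end of the record are
    flagged immature (no cessation day).
    """
    rows = []
    for (tiller_id, rank), g in observations.groupby(
        ["tiller_id", "rank"], sort=False
    ):
        g = g.sort_values("day")
        days = g["day"].to_numpy(dtype=float)
        dist = g["distance"].to_numpy(dtype=float)
        cessation = np.nan
        n_inc = len(days) - 1
        for i in range(n_inc - k + 1):
            flat = all(
                days[i + j + 1] == days[i + j] + 1
                and abs(dist[i + j + 1] - dist[i + j]) < resolution
                for j in range(k)
            )
            if flat:
                cessation = days[i]
                break
        rows.append(
            {
                "tiller_id": tiller_id,
                "treatment": g["treatment"].iloc[0],
                "rank": int(rank),
                "cessation_day": cessation,
                "mature": bool(np.isfinite(cessation)),
            }
        )
    return pd.DataFrame(rows)


def predict_final_length(
    dissection_tiller: pd.DataFrame,
    target_rank: int,
    min_rank: int = 8,
) -> float:
    """Extrapolate one tiller's final length vs rank line to ``target_rank``.

    An ordinary least-squares line is fitted to the mature phytomers of
    that same tiller with rank >= ``min_rank``.
    """
    mature = dissection_tiller[
        (dissection_tiller["maturity"] == "mature")
        & (dissection_tiller["rank"] >= min_rank)
    ]
    if len(mature) < 3:
        raise ValueError(
            f"need >= 3 mature phytomers at ranks >= {min_rank}, got {len(mature)}"
        )
    slope, intercept = np.polyfit(
        mature["rank"].to_numpy(dtype=float),
        mature["phytomer_length"].to_numpy(dtype=float),
        1,
    )
    lp = slope * target_rank + intercept
    if lp <= 0:
        raise ValueError(f"non-positive predicted final length at rank {target_rank}")
    return float(lp)


def predict_final_lengths(dissection: pd.DataFrame, min_rank: int = 8) -> pd.DataFrame:
    """Add a predicted-final-length column ``Lp`` to the dissection table.

    Mature phytomers keep their measured final length; immature ones get
    the per-tiller OLS extrapolation.  Tillers where the line cannot be
    fitted are dropped with a warning.
    """
    parts = []
    for tiller_id, g in dissection.groupby("tiller_id", sort=False):
        g = g.copy()
        try:
            lp = np.where(
                g["maturity"] == "mature",
                g["phytomer_length"],
                [
                    predict_final_length(g, int(r), min_rank=min_rank)
                    for r in g["rank"]
                ],
            )
        except ValueError as exc:
            logger.warning("tiller %s skipped: %s", tiller_id, exc)
            continue
        g["Lp"] = lp
        g["f_L"] = g["phytomer_length"] / g["Lp"]
        parts.append(g)
    if not parts:
        raise ValueError("no tiller had enough mature phytomers for extrapolation")
    return pd.concat(parts, ignore_index=True)


def _elongation_increments(days, dist, ref) -> np.ndarray:
    """Daily elongation from distance differences.

    Differences are only meaningful while the reference ligule is
    unchanged; increments across a reference switch (a younger ligule
    became the highest visible one) are filled by linear interpolation of
    the neighbouring increments.
    """
    inc = np.diff(dist)
    valid = np.array(
        [
            days[i + 1] == days[i] + 1 and ref[i + 1] == ref[i]
            for i in range(len(days) - 1)
        ]
    )
    if not valid.all():
        if not valid.any():
            raise ValueError("no usable same-reference increments")
        idx = np.arange(len(inc), dtype=float)
        inc = inc.astype(float)
        inc[~valid] = np.interp(idx[~valid], idx[valid], inc[valid])
        logger.warning(
            "interpolated %d elongation increment(s) across reference switches "
            "or daily gaps",
            int((~valid).sum()),
        )
    return inc


def build_visible_timecourse(
    observations: pd.DataFrame,
    dissection: pd.DataFrame,
    events: pd.DataFrame,
    cessation: pd.DataFrame,
    ranks: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """(age, f_L) points for phytomers monitored from emergence to cessation.

    The actual length on each day is reconstructed backwards from the
    measured final length (dissection) by subtracting the daily elongation
    increments; the age axis is days after the lag-corrected emergence.
    ``ranks=None`` uses every rank with complete in-window coverage.
    """
    ev = events[~events["flagged"]].set_index(["tiller_id", "rank"])
    ce = cessation[cessation["mature"]].set_index(["tiller_id", "rank"])
    final = dissection.set_index(["tiller_id", "rank"])

    rows = []
    for (tiller_id, rank), g in observations.groupby(
        ["tiller_id", "rank"], sort=False
    ):
        if ranks is not None and int(rank) not in ranks:
            continue
        key = (tiller_id, int(rank))
        if key not in ev.index or key not in ce.index or key not in final.index:
            continue
        emergence_day = float(ev.loc[key, "emergence_day"])
        cease_day = float(ce.loc[key, "cessation_day"])
        lf = float(final.loc[key, "phytomer_length"])

        g = g.sort_values("day")
        days = g["day"].to_numpy(dtype=float)
        dist = g["distance"].to_numpy(dtype=float)
        ref = g["reference_ligule_rank"].to_numpy()
        keep = days <= cease_day
        days, dist, ref = days[keep], dist[keep], ref[keep]
        if len(days) < 3:
            continue
        inc = _elongation_increments(days, dist, ref)
        # telescope backwards from the final length at cessation
        la = np.empty_like(days)
        la[-1] = lf
        for i in range(len(days) - 2, -1, -1):
            la[i] = la[i + 1] - inc[i]
        for d, l in zip(days, la):
            rows.append(
                {
                    "treatment": g["treatment"].iloc[0],
                    "tiller_id": tiller_id,
                    "rank": int(rank),
                    "day": d,
                    "age": d - emergence_day,
                    "f_L": l / lf,
                    "phase": "visible",
                }
            )
    return pd.DataFrame(rows)


def assign_invisible_ages(
    dissection_with_lp: pd.DataFrame,
    visible_curves: dict[str, SigmoidCurve] | SigmoidCurve,
    phyllochrons: pd.DataFrame | float,
    anchor_window: tuple[float, float] = (0.60, 0.80),
) -> pd.DataFrame:
    """(age, f_L) points for immature phytomers, dated by phyllochron offsets.

    Per tiller, the oldest immature phytomer inside ``anchor_window``
    (typically the second oldest immature one) is placed on the fitted
    visible curve of its treatment; each younger phytomer is one
    phyllochron younger per rank.  Tillers without an anchor candidate are
    skipped with a warning.
    """
    lo, hi = anchor_window
    if isinstance(phyllochrons, pd.DataFrame):
        phy_map = phyllochrons.set_index("tiller_id")["phyllochron"].to_dict()
    else:
        phy_map = None

    rows = []
    for tiller_id, g in dissection_with_lp.groupby("tiller_id", sort=False):
        imm = g[g["maturity"] == "immature"].sort_values("rank")
        if imm.empty:
            continue
        cand = imm[imm["f_L"].between(lo, hi)]
        if cand.empty:
            logger.warning(
                "tiller %s: no immature phytomer in the %g-%g anchor window; skipped",
                tiller_id,
                lo,
                hi,
            )
            continue
        # the candidate nearest the window centre; picking the oldest one
        # instead preferentially selects older phytomers whose noisy f_L
        # dipped below the upper bound and biases the assigned ages young
        anchor = cand.iloc[int((cand["f_L"] - 0.5 * (lo + hi)).abs().argmin())]
        treatment = g["treatment"].iloc[0]
        if isinstance(visible_curves, dict):
            curve = visible_curves.get(treatment)
            if curve is None:
                logger.warning(
                    "tiller %s: no visible-phase curve for treatment %s; skipped",
                    tiller_id,
                    treatment,
                )
                continue
        else:
            curve = visible_curves
        anchor_age = invert_sigmoid(curve, float(anchor["f_L"]))
        phy = phy_map.get(tiller_id) if phy_map is not None else float(phyllochrons)
        if phy is None or not np.isfinite(phy):
            logger.warning("tiller %s: no phyllochron estimate; skipped", tiller_id)
            continue
        younger = imm[imm["rank"] >= anchor["rank"]]
        for _, rec in younger.iterrows():
            age = anchor_age - (rec["rank"] - anchor["rank"]) * phy
            rows.append(
                {
                    "treatment": treatment,
                    "tiller_id": tiller_id,
                    "rank": int(rec["rank"]),
                    "day": np.nan,
                    "age": float(age),
                    "f_L": float(rec["f_L"]),
                    "phase": "initial",
                }
            )
    return pd.DataFrame(rows)


def build_coordination_tables(
    dissection_with_lp: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within- and between-phytomer coordination tables.

    Within: per dissected phytomer, component contributions (blade, sheath,
    internode, each / Lp) against f_L.  Between: (f_L of P_n, f_L of
    P_{n+1}) for adjacent rank pairs whose younger member is immature,
    ordered older -> younger.
    """
    d = dissection_with_lp
    within = pd.DataFrame(
        {
            "treatment": d["treatment"],
            "tiller_id": d["tiller_id"],
            "rank": d["rank"],
            "f_L": d["f_L"],
            "blade_fraction": d["blade"] / d["Lp"],
            "sheath_fraction": d["sheath"] / d["Lp"],
            "internode_fraction": d["internode"] / d["Lp"],
        }
    )

    rows = []
    for tiller_id, g in d.groupby("tiller_id", sort=False):
        g = g.sort_values("rank").set_index("rank")
        for rank in g.index:
            if rank + 1 not in g.index:
                continue
            younger = g.loc[rank + 1]
            if younger["maturity"] != "immature":
                continue
            rows.append(
                {
                    "treatment": g.loc[rank, "treatment"],
                    "tiller_id": tiller_id,
                    "rank_older": int(rank),
                    "f_older": float(g.loc[rank, "f_L"]),
                    "f_younger": float(younger["f_L"]),
                }
            )
    return within, pd.DataFrame(rows)


@dataclass
class ReconstructionResult:
    """Bundle of every table the reconstruction pipeline produces."""

    events: pd.DataFrame
    phyllochron: pd.DataFrame
    cessation: pd.DataFrame
    dissection: pd.DataFrame  # with Lp and f_L columns
    timecourse: pd.DataFrame  # visible + initial phases
    within: pd.DataFrame
    between: pd.DataFrame
    visible_fits: dict = field(default_factory=dict)
    complete_fit: object | None = None


def reconstruct(
    observations: pd.DataFrame,
    dissection: pd.DataFrame,
    resolution: float = 0.5,
    rank_window: tuple[int, int] = (7, 16),
    monitored_ranks: tuple[int, ...] | None = None,
    anchor_window: tuple[float, float] = (0.60, 0.80),
    min_fit_rank: int = 8,
) -> ReconstructionResult:
    """Run the full analysis chain on an observation + dissection table pair.

    Fits the per-treatment visible curves (needed for the invisible-phase
    age assignment) and the pooled complete time course.
    """
    from .fitting import fit_sigmoid2

    events = estimate_emergence(observations, resolution=resolution)
    phyllo = compute_phyllochron(events, rank_window=rank_window, strict=False)
    cess = detect_full_expansion(observations, resolution=resolution)
    diss = predict_final_lengths(dissection, min_rank=min_fit_rank)
    visible = build_visible_timecourse(
        observations, dissection, events, cess, ranks=monitored_ranks
    )
    if visible.empty:
        raise ValueError("no phytomer was monitored from emergence to cessation")

    visible_fits = {
        treatment: fit_sigmoid2(g["age"].to_numpy(), g["f_L"].to_numpy())
        for treatment, g in visible.groupby("treatment")
    }
    curves = {t: fr.curve for t, fr in visible_fits.items()}

    initial = assign_invisible_ages(
        diss, curves, phyllo, anchor_window=anchor_window
    )
    timecourse = pd.concat([visible, initial], ignore_index=True)
    complete_fit = fit_sigmoid2(
        timecourse["age"].to_numpy(), timecourse["f_L"].to_numpy()
    )
    within, between = build_coordination_tables(diss)
    return ReconstructionResult(
        events=events,
        phyllochron=phyllo,
        cessation=cess,
        dissection=diss,
        timecourse=timecourse,
        within=within,
        between=between,
        visible_fits=visible_fits,
        complete_fit=complete_fit,
    )
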