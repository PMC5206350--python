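"""Per-treatment descriptive statistics of growth and development.

Produces the treatment-table layout of the study (mean +/- SE per N x VPD
cell, n = 16 tillers), grand means across the four cells, and the percent
effects of one factor averaged over (or conditioned on) the other.  The
published treatment table is included as input data so that the derived
quantities can be recomputed from it.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "PUBLISHED_TABLE1",
    "published_table1",
    "round_half_up",
    "summarize_tillers",
    "treatment_means",
    "grand_mean",
    "percent_effect",
]

#: Published per-treatment means and standard errors (n = 16 tillers).
#: Cells keyed (N level, VPD level).
PUBLISHED_TABLE1: dict[str, dict[tuple[str, str], tuple[float, float]]] = {
    "n_visibly_growing": {
        ("N1", "V1"): (3.6, 0.1),
        ("N1", "V2"): (3.8, 0.1),
        ("N2", "V1"): (4.2, 0.1),
        ("N2", "V2"): (3.8, 0.1),
    },
    "n_phytomers": {
        ("N1", "V1"): (13.4, 0.2),
        ("N1", "V2"): (13.3, 0.2),
        ("N2", "V1"): (14.5, 0.2),
        ("N2", "V2"): (13.7, 0.2),
    },
    "phyllochron": {
        ("N1", "V1"): (2.4, 0.1),
        ("N1", "V2"): (2.4, 0.0),
        ("N2", "V1"): (2.1, 0.0),
        ("N2", "V2"): (2.4, 0.1),
    },
    "visible_growth_duration": {
        ("N1", "V1"): (11.0, 0.5),
        ("N1", "V2"): (11.8, 0.2),
        ("N2", "V1"): (10.6, 0.2),
        ("N2", "V2"): (10.6, 0.3),
    },
    "n_tillers": {
        ("N1", "V1"): (19.7, 1.8),
        ("N1", "V2"): (17.6, 1.0),
        ("N2", "V1"): (24.0, 1.1),
        ("N2", "V2"): (21.7, 1.6),
    },
}


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero (12.5 % -> 13 %), as printed.

    Values are snapped to 9 decimals first so that binary-float noise
    (e.g. 12.499999999999993 for an exact ratio of 12.5) does not flip a
    tie the wrong way.
    """
    factor = 10.0**decimals
    scaled = round(abs(x) * factor, 9)
    return math.copysign(math.floor(scaled + 0.5) / factor, x)


def published_table1() -> pd.DataFrame:
    """The published treatment table in tidy form."""
    rows = []
    for parameter, cells in PUBLISHED_TABLE1.items():
        for (n_level, vpd_level), (mean, se) in cells.items():
            rows.append(
                {
                    "parameter": parameter,
                    "treatment": f"{n_level}{vpd_level}",
                    "n_level": n_level,
                    "vpd_level": vpd_level,
                    "mean": mean,
                    "se": se,
                    "n": 16,
                }
            )
    return pd.DataFrame(rows)


def summarize_tillers(
    recon,
    observations: pd.DataFrame,
    truth: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row of growth parameters per tiller.

    ``phyllochron`` and ``visible_growth_duration`` are per-tiller means
    over the ranks they could be measured on; ``n_visibly_growing`` and
    ``n_phytomers`` are means of the daily counts over the observation
    window.  ``n_tillers`` (plant-level tiller count) is taken from the
    truth table when given, since tillering is not reconstructed.
    """
    cess = recon.cessation.set_index(["tiller_id", "rank"])

    rows = []
    for tiller_id, g in observations.groupby("tiller_id", sort=False):
        treatment = g["treatment"].iloc[0]
        daily = g.groupby("day")["rank"]
        n_phytomers = float(daily.count().mean())

        def growing(day_ranks):
            day = day_ranks.name
            count = 0
            for rank in day_ranks:
                key = (tiller_id, rank)
                if key in cess.index:
                    c = cess.loc[key]
                    if (not c["mature"]) or day < c["cessation_day"]:
                        count += 1
            return count

        n_growing = float(daily.apply(growing).mean())

        ev = recon.events
        ev = ev[(ev["tiller_id"] == tiller_id) & (~ev["flagged"])]
        durations = []
        for _, e in ev.iterrows():
            key = (tiller_id, e["rank"])
            if key in cess.index and cess.loc[key, "mature"]:
                durations.append(cess.loc[key, "cessation_day"] - e["emergence_day"])
        duration = float(np.mean(durations)) if durations else np.nan

        phy = recon.phyllochron
        phy = phy.loc[phy["tiller_id"] == tiller_id, "phyllochron"]
        phyllochron = float(phy.iloc[0]) if len(phy) else np.nan

        diss = recon.dissection
        mature = diss[(diss["tiller_id"] == tiller_id) & (diss["maturity"] == "mature")]
        mean_final = float(mature["phytomer_length"].mean()) if len(mature) else np.nan

        n_tillers = np.nan
        if truth is not None:
            t = truth.loc[truth["tiller_id"] == tiller_id, "tiller_count"]
            if len(t):
                n_tillers = float(t.iloc[0])

        rows.append(
            {
                "treatment": treatment,
                "n_level": g["n_level"].iloc[0] if "n_level" in g else treatment[:2],
                "vpd_level": g["vpd_level"].iloc[0] if "vpd_level" in g else treatment[2:],
                "chamber": g["chamber"].iloc[0] if "chamber" in g else "",
                "tiller_id": tiller_id,
                "phyllochron": phyllochron,
                "visible_growth_duration": duration,
                "n_visibly_growing": n_growing,
                "n_phytomers": n_phytomers,
                "n_tillers": n_tillers,
                "mean_final_phytomer_length": mean_final,
            }
        )
    return pd.DataFrame(rows)


_PARAMETERS = (
    "phyllochron",
    "visible_growth_duration",
    "n_visibly_growing",
    "n_phytomers",
    "n_tillers",
    "mean_final_phytomer_length",
)


def treatment_means(summaries: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SE of each parameter per treatment cell, tidy layout."""
    rows = []
    for (treatment, n_level, vpd_level), g in summaries.groupby(
        ["treatment", "n_level", "vpd_level"]
    ):
        if len(g) < 2:
            raise ValueError(f"treatment {treatment}: need >= 2 tillers")
        for parameter in _PARAMETERS:
            if parameter not in g:
                continue
            vals = g[parameter].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            rows.append(
                {
                    "parameter": parameter,
                    "treatment": treatment,
                    "n_level": n_level,
                    "vpd_level": vpd_level,
                    "mean": float(vals.mean()),
                    "se": float(vals.std(ddof=1) / np.sqrt(vals.size))
                    if vals.size > 1
                    else 0.0,
                    "n": int(vals.size),
                }
            )
    return pd.DataFrame(rows)


def _cells(table: pd.DataFrame, parameter: str) -> pd.DataFrame:
    cells = table[table["parameter"] == parameter]
    if cells.empty:
        raise KeyError(f"parameter {parameter!r} not in table")
    return cells


def grand_mean(table: pd.DataFrame, parameter: str) -> float:
    """Unweighted mean of the treatment-cell means."""
    return float(_cells(table, parameter)["mean"].mean())


def percent_effect(
    table: pd.DataFrame,
    parameter: str,
    factor: str = "N",
    conditioning: str | None = None,
) -> float:
    """Percent change from the low to the high level of ``factor``.

    Cell means are averaged over the other factor, or restricted to a
    stated level of it (``conditioning``, e.g. ``"V1"``).  Positive values
    mean the high level increases the parameter.  Returned unrounded;
    apply :func:`round_half_up` for reporting.
    """
    cells = _cells(table, parameter)
    col, other = ("n_level", "vpd_level") if factor.upper() == "N" else ("vpd_level", "n_level")
    if conditioning is not None:
        cells = cells[cells[other] == conditioning]
        if cells.empty:
            raise ValueError(f"no cells at {other} == {conditioning!r}")
    levels = sorted(cells[col].unique())
    if len(levels) != 2:
        raise ValueError(f"need both levels of {factor}, found {levels}")
    low = cells.loc[cells[col] == levels[0], "mean"].mean()
    high = cells.loc[cells[col] == levels[1], "mean"].mean()
    if low == 0:
        raise ZeroDivisionError("low-level mean is zero")
    return float(100.0 * (high - low) / low)
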