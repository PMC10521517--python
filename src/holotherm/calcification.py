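"""Buoyant-weight calcification rates.

Skeletal growth is measured non-destructively by weighing fragments
under water; the daily mass increment is normalized to the *initial*
skeletal surface area:

    rate = (BW_final − BW_initial) / A_initial × (1 / days) × 100

The ×100 factor is kept literally, so rates are on a
(g · cm⁻² · d⁻¹) × 100 scale; negative rates (dissolution) are allowed.
The day-0 area is used for every interval — later-day areas, if present,
are ignored for rate computation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["calcification_rate", "interval_rates"]


def calcification_rate(bw_initial, bw_final, a_initial, days):
    """Daily areal skeletal growth on the percent-scaled buoyant-weight basis.

    Accepts scalars or aligned arrays.  Raises ``ValueError`` for
    non-positive area or interval length.
    """
    a_initial = np.asarray(a_initial, dtype=float)
    days = np.asarray(days, dtype=float)
    if (a_initial <= 0).any():
        raise ValueError("initial surface area must be > 0")
    if (days <= 0).any():
        raise ValueError("interval length must be > 0 days")
    rate = (np.asarray(bw_final, float) - np.asarray(bw_initial, float)) \
        / a_initial * (1.0 / days) * 100.0
    return rate if rate.ndim else float(rate)


def interval_rates(weights: pd.DataFrame,
                   intervals: list[tuple[int, int]] = ((0, 7), (7, 14)),
                   ) -> pd.DataFrame:
    """One rate per fragment per interval from weekly buoyant weights.

    The day-0 surface area of each fragment is used for all intervals.
    Fragments missing a weight at an interval endpoint are skipped for
    that interval with a warning.

    Returns a DataFrame [fragment_id, day_start, day_end, rate].
    """
    if weights.empty:
        return pd.DataFrame(columns=["fragment_id", "day_start", "day_end", "rate"])
    wide = weights.pivot_table(index="fragment_id", columns="day",
                               values="buoyant_weight_g", aggfunc="first")
    area0 = (weights[weights["day"] == 0]
             .set_index("fragment_id")["surface_area_cm2"])
    rows, skipped = [], 0
    for fid in wide.index:
        if fid not in area0.index:
            logger.warning("fragment %s has no day-0 area; skipped", fid)
            continue
        a = float(area0.loc[fid])
        for start, end in intervals:
            if start not in wide.columns or end not in wide.columns \
                    or np.isnan(wide.loc[fid].get(start, np.nan)) \
                    or np.isnan(wide.loc[fid].get(end, np.nan)):
                skipped += 1
                continue
            rate = calcification_rate(wide.loc[fid, start], wide.loc[fid, end],
                                      a, end - start)
            rows.append((fid, int(start), int(end), float(rate)))
    if skipped:
        logger.warning("%d fragment-interval(s) missing an endpoint weight; "
                       "skipped", skipped)
    return pd.DataFrame(rows, columns=["fragment_id", "day_start", "day_end",
                                       "rate"])
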