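"""Areal symbiont density and fate-tracked bleaching rates.

Symbiodiniaceae are counted on a hemocytometer from an airbrushed tissue
slurry; the replicate-mean chamber count converts to an areal density

    density = mean(count) / V_chamber × dilution × V_slurry / area

in cells·cm⁻².  The chamber volume defaults to the standard Neubauer
large-square grid (0.1 µL = 1e-4 mL) and is configurable for other
counting rules.

Bleaching rates come from the fate-tracked census: at a given day the
rate is the percentage of bleached fragments among *all the remaining*
fragments — those not yet removed for destructive assays.  Fragments
scored (healthy or bleached) on their own removal day still count that
day; 'removed' rows exclude them from later denominators.  Densities are
computed identically for healthy and bleached fragments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .experiment_core import IntegrityError, design_with_arm

__all__ = ["areal_density", "bleaching_rate", "bleaching_rate_table",
           "DEFAULT_CHAMBER_VOLUME_ML"]

DEFAULT_CHAMBER_VOLUME_ML = 1e-4


def areal_density(counts: pd.DataFrame,
                  chamber_volume_ml: float = DEFAULT_CHAMBER_VOLUME_ML,
                  ) -> pd.DataFrame:
    """Cells per cm² from replicate hemocytometer counts.

    All replicates of one fragment-day must share dilution, slurry volume
    and area; inconsistent metadata raises :class:`IntegrityError`.

    Returns a DataFrame [fragment_id, day, density].
    """
    if counts.empty:
        return pd.DataFrame(columns=["fragment_id", "day", "density"])
    meta_cols = ["dilution_factor", "slurry_volume_ml", "surface_area_cm2"]
    nun = counts.groupby(["fragment_id", "day"])[meta_cols].nunique()
    bad = nun[(nun > 1).any(axis=1)]
    if not bad.empty:
        raise IntegrityError(
            f"inconsistent count metadata across replicates for {list(bad.index)}")
    grp = counts.groupby(["fragment_id", "day"], as_index=False).agg(
        mean_count=("chamber_count", "mean"),
        dilution=("dilution_factor", "first"),
        slurry=("slurry_volume_ml", "first"),
        area=("surface_area_cm2", "first"))
    grp["density"] = (grp["mean_count"] / chamber_volume_ml
                      * grp["dilution"] * grp["slurry"] / grp["area"])
    return grp[["fragment_id", "day", "density"]]


def bleaching_rate(census: pd.DataFrame, design: pd.DataFrame,
                   holobiont: str, arm: str, day: int) -> float:
    """Percent bleached among remaining fragments of one group at one day.

    Remaining = fragments of the holobiont × arm whose status at ``day``
    is not 'removed' (removal at an earlier sampling day drops a fragment
    from the denominator; bleached fragments remain in it).
    """
    d = design_with_arm(design)
    ids = d.loc[(d["holobiont"] == holobiont) & (d["arm"] == arm), "fragment_id"]
    rows = census[(census["fragment_id"].isin(set(ids))) & (census["day"] == day)]
    present = rows[rows["status"] != "removed"]
    if present.empty:
        raise ValueError(f"no remaining fragments for {holobiont}/{arm} "
                         f"at day {day}; bleaching rate undefined")
    return 100.0 * float((present["status"] == "bleached").sum()) / len(present)


def bleaching_rate_table(census: pd.DataFrame, design: pd.DataFrame,
                         ) -> pd.DataFrame:
    """Bleaching rate for every holobiont × arm × census day."""
    d = design_with_arm(design)
    out = []
    days = sorted(census["day"].unique())
    for (hb, arm), _ in d.groupby(["holobiont", "arm"]):
        for day in days:
            try:
                rate = bleaching_rate(census, design, hb, arm, int(day))
            except ValueError:
                rate = np.nan
            out.append((hb, arm, int(day), rate))
    return pd.DataFrame(out, columns=["holobiont", "arm", "day", "bleaching_rate"])
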