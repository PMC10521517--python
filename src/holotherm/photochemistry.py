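"""Quantum yields, excitation pressure over PSII, and ΔQm.

Chlorophyll-*a* fluorometry yields two quantities per fragment and day:
the maximum quantum yield of photosystem II after dark adaptation
(Fv/Fm) and the effective quantum yield under illumination (ΔF/Fm′).
The maximum excitation pressure over PSII is

    Qm = 1 − (ΔF/Fm′) / (Fv/Fm),

a dimensionless index of how much of the photosystem's capacity is
closed under ambient light: 0 when light and dark yields coincide, 1
when the effective yield collapses.  The thermal-adjustment metric ΔQm
subtracts the control arm's mean Qm from the heated arm's, per
holobiont, isolating the temperature effect from the diurnal baseline.

Replicates are averaged at the measurement level before the ratio is
formed (triplicate readings exist to suppress instrument noise, not
biological variation).  Negative Qm values — light yield exceeding the
dark yield — are retained and flagged rather than truncated, to avoid
biasing group means.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .experiment_core import design_with_arm

logger = logging.getLogger(__name__)

__all__ = ["pair_yields", "compute_qm", "compute_delta_qm"]


def pair_yields(pam: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate-average PAM records and pair dark with light per day.

    Parameters
    ----------
    pam : DataFrame with columns fragment_id, day, phase, replicate, yield.

    Returns
    -------
    pairs : DataFrame [fragment_id, day, fv_fm, df_fm_prime]
        One row per fragment-day on which *both* phases were measured.
    skipped : DataFrame [fragment_id, day, phase]
        Fragment-days with only one phase present (warned, not fatal).
    """
    if pam.empty:
        cols = ["fragment_id", "day", "fv_fm", "df_fm_prime"]
        return (pd.DataFrame(columns=cols),
                pd.DataFrame(columns=["fragment_id", "day", "phase"]))
    means = (pam.groupby(["fragment_id", "day", "phase"], as_index=False)["yield"]
             .mean())
    wide = means.pivot_table(index=["fragment_id", "day"], columns="phase",
                             values="yield", aggfunc="first")
    for phase in ("dark", "light"):
        if phase not in wide.columns:
            wide[phase] = np.nan
    unpaired = wide[wide["dark"].isna() | wide["light"].isna()]
    skipped_rows = []
    for (fid, day), row in unpaired.iterrows():
        present = "dark" if not np.isnan(row["dark"]) else "light"
        skipped_rows.append((fid, int(day), present))
    if skipped_rows:
        logger.warning("%d fragment-day(s) had only one PAM phase; skipped",
                       len(skipped_rows))
    pairs = (wide.dropna(subset=["dark", "light"])
             .reset_index()
             .rename(columns={"dark": "fv_fm", "light": "df_fm_prime"})
             [["fragment_id", "day", "fv_fm", "df_fm_prime"]])
    pairs.columns.name = None
    skipped = pd.DataFrame(skipped_rows, columns=["fragment_id", "day", "phase"])
    return pairs, skipped


def compute_qm(pairs: pd.DataFrame) -> pd.DataFrame:
    """Excitation pressure Qm = 1 − (ΔF/Fm′)/(Fv/Fm) per fragment-day.

    Pairs with Fv/Fm = 0 have undefined Qm and are excluded with a
    warning.  Negative Qm (light yield above dark yield) is kept and
    flagged in the ``negative`` column.
    """
    if pairs.empty:
        return pd.DataFrame(columns=["fragment_id", "day", "qm", "negative"])
    undefined = pairs["fv_fm"] <= 0
    if undefined.any():
        logger.warning("%d pair(s) with Fv/Fm = 0 excluded (undefined Qm)",
                       int(undefined.sum()))
    ok = pairs.loc[~undefined].copy()
    ok["qm"] = 1.0 - ok["df_fm_prime"] / ok["fv_fm"]
    ok["negative"] = ok["qm"] < 0
    return ok[["fragment_id", "day", "qm", "negative"]].reset_index(drop=True)


def compute_delta_qm(qm: pd.DataFrame, design: pd.DataFrame,
                     pooling: str = "overall") -> pd.DataFrame:
    """Heated-minus-control mean Qm per holobiont.

    ``pooling="overall"`` averages each fragment's Qm over the stress
    window (days ≥ 1) first, then contrasts arm means; ``"per_day"``
    contrasts arms day by day.  The standard error combines the two arm
    SEs in quadrature.

    Raises ``ValueError`` naming the holobiont if either arm is absent.
    """
    if pooling not in ("overall", "per_day"):
        raise ValueError(f"unknown pooling '{pooling}'")
    merged = qm.merge(design_with_arm(design)[["fragment_id", "holobiont", "arm"]],
                      on="fragment_id", how="left")
    if merged["arm"].isna().any():
        bad = merged.loc[merged["arm"].isna(), "fragment_id"].unique()[:5]
        raise ValueError(f"Qm records not in design: {list(bad)}")
    out = []
    for hb, grp in merged.groupby("holobiont"):
        arms = set(grp["arm"])
        if arms != {"control", "heat"}:
            raise ValueError(f"holobiont {hb}: missing arm(s) "
                             f"{sorted({'control', 'heat'} - arms)}")
        if pooling == "overall":
            window = grp[grp["day"] >= 1]
            per_frag = (window.groupby(["fragment_id", "arm"], as_index=False)["qm"]
                        .mean())
            stats = per_frag.groupby("arm")["qm"].agg(["mean", "sem"])
            out.append((hb, "overall",
                        stats.loc["heat", "mean"] - stats.loc["control", "mean"],
                        float(np.hypot(stats.loc["heat", "sem"],
                                       stats.loc["control", "sem"]))))
        else:
            for day, dgrp in grp.groupby("day"):
                if set(dgrp["arm"]) != {"control", "heat"}:
                    continue
                stats = dgrp.groupby("arm")["qm"].agg(["mean", "sem"])
                out.append((hb, int(day),
                            stats.loc["heat", "mean"] - stats.loc["control", "mean"],
                            float(np.hypot(stats.loc["heat", "sem"],
                                           stats.loc["control", "sem"]))))
    return pd.DataFrame(out, columns=["holobiont", "day", "delta_qm", "se"])
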