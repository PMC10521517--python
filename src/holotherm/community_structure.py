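"""Symbiont community quantification: D/C ratios, shuffling index,
clone-library matrices, zero-adjusted Bray–Curtis, NMDS and clustering.

qPCR with genus-specific primers yields threshold cycles CT_C and CT_D;
the Durusdinium-to-Cladocopium cell ratio follows the ΔCT model

    D/C = 2^−(CT_D − CT_C).

A primer with no detected replicate is assigned the detection-limit CT
(default 40 cycles) and the ratio flagged as censored; a fragment-day
where both primers fail is skipped.  The shuffling index maps the
Durusdinium proportion p_D = D/C / (1 + D/C) affinely onto [−1, +1]
(−1 = complete Cladocopium dominance, +1 = complete Durusdinium
dominance):

    index = 2·p_D − 1.

Clone-library composition is analyzed on a samples × ITS2-type count
matrix with a constant "dummy species" column (value 1) appended, so the
Bray–Curtis dissimilarity of two empty samples is defined (zero-adjusted
Bray–Curtis).  Ordination is non-metric MDS minimizing Kruskal stress-1;
grouping cuts a complete-linkage dendrogram at 1 − similarity/100.

No copy-number correction between genera is applied to the ΔCT ratio;
it is a cell-ratio proxy, not an absolute quantification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .experiment_core import design_with_arm

logger = logging.getLogger(__name__)

__all__ = [
    "dc_ratio",
    "shuffling_index",
    "dc_trajectory",
    "community_matrix",
    "zero_adjusted_bray_curtis",
    "nmds",
    "complete_linkage_groups",
    "OrdinationResult",
]

DEFAULT_CT_LIMIT = 40.0


def dc_ratio(qpcr: pd.DataFrame, ct_limit: float = DEFAULT_CT_LIMIT,
             ) -> pd.DataFrame:
    """Durusdinium/Cladocopium ratio per fragment-day from triplicate CTs.

    The CT per primer is the mean over detected replicates; a fully
    non-detect primer is censored at ``ct_limit``.  Fragment-days with
    both primers non-detect are skipped with a warning.

    Returns [fragment_id, day, dc, log10_dc, censored].
    """
    if qpcr.empty:
        return pd.DataFrame(columns=["fragment_id", "day", "dc", "log10_dc",
                                     "censored"])
    rows, skipped = [], 0
    for (fid, day), grp in qpcr.groupby(["fragment_id", "day"]):
        cts = {}
        censored = False
        for primer in ("C", "D"):
            vals = pd.to_numeric(
                grp.loc[grp["primer"] == primer, "ct"], errors="coerce").dropna()
            if len(vals):
                cts[primer] = float(vals.mean())
            else:
                cts[primer] = float(ct_limit)
                censored = True
        if censored and all(
            pd.to_numeric(grp.loc[grp["primer"] == p, "ct"],
                          errors="coerce").dropna().empty
            for p in ("C", "D")
        ):
            skipped += 1
            continue
        dc = 2.0 ** (-(cts["D"] - cts["C"]))
        rows.append((fid, int(day), dc, float(np.log10(dc)), censored))
    if skipped:
        logger.warning("%d fragment-day(s) non-detect on both primers; skipped",
                       skipped)
    return pd.DataFrame(rows, columns=["fragment_id", "day", "dc", "log10_dc",
                                       "censored"])


def shuffling_index(dc):
    """Affine map of the Durusdinium proportion onto [−1, +1].

    With p_D = dc/(1+dc): index = 2·p_D − 1.  Strictly increasing in dc;
    −1 only at dc = 0 and +1 only in the limit dc → ∞.
    """
    dc = np.asarray(dc, dtype=float)
    if (dc < 0).any():
        raise ValueError("D/C ratio must be >= 0")
    idx = 2.0 * dc / (1.0 + dc) - 1.0
    return idx if idx.ndim else float(idx)


def dc_trajectory(ratios: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """OLS regression of log₁₀(D/C) on day, per holobiont × arm.

    Returns slope, intercept, the 95 % CI of the slope, its p-value, and
    the total log₁₀ change over the observed window.  Requires ≥ 2 time
    points per group.
    """
    import statsmodels.api as sm

    merged = ratios.merge(
        design_with_arm(design)[["fragment_id", "holobiont", "arm"]],
        on="fragment_id", how="left")
    out = []
    for (hb, arm), grp in merged.groupby(["holobiont", "arm"]):
        days = np.sort(grp["day"].unique())
        if len(days) < 2:
            raise ValueError(f"{hb}/{arm}: need >= 2 time points for a "
                             "log10 D/C trajectory")
        x = sm.add_constant(grp["day"].to_numpy(dtype=float))
        fit = sm.OLS(grp["log10_dc"].to_numpy(), x).fit()
        lo, hi = map(float, fit.conf_int(alpha=0.05)[1])
        span = float(days[-1] - days[0])
        out.append((hb, arm, float(fit.params[1]), float(fit.params[0]),
                    lo, hi, float(fit.pvalues[1]), float(fit.params[1]) * span))
    return pd.DataFrame(out, columns=["holobiont", "arm", "slope", "intercept",
                                      "ci_low", "ci_high", "p_value",
                                      "log10_change"])


#: ITS2 types assembled into each dominant metahaplotype
METAHAPLOTYPES = {
    "C42-C1-C1b-C1c": ("C42", "C1", "C1b", "C1c"),
    "D1-D4-D6": ("D1", "D4", "D6"),
}


def community_matrix(clones: pd.DataFrame, level: str = "type",
                     relative: bool = False) -> pd.DataFrame:
    """Samples × abundance matrix from clone libraries.

    ``level="type"`` keeps one column per ITS2 type (raw assignment
    scores, used for dominance shares); ``level="metahaplotype"`` pools
    types into their co-occurring metahaplotypes (the unit the ordination
    works at — individual libraries of a handful of clones are too sparse
    to compare type by type).  ``relative=True`` row-normalizes to
    relative abundance.  One row per fragment × stage.
    """
    if clones.empty:
        return pd.DataFrame()
    mat = clones.pivot_table(index=["fragment_id", "stage"],
                             columns="its2_type", values="clone_count",
                             aggfunc="sum", fill_value=0)
    mat.index = [f"{fid}:{stage}" for fid, stage in mat.index]
    mat.columns.name = None
    if level == "metahaplotype":
        cols = {}
        assigned = set()
        for meta, types in METAHAPLOTYPES.items():
            members = [t for t in types if t in mat.columns]
            if members:
                cols[meta] = mat[members].sum(axis=1)
                assigned.update(members)
        for t in mat.columns:
            if t not in assigned:
                cols[t] = mat[t]
        mat = pd.DataFrame(cols, index=mat.index)
    elif level != "type":
        raise ValueError(f"unknown level '{level}'")
    if relative:
        totals = mat.sum(axis=1).replace(0, 1.0)
        mat = mat.div(totals, axis=0)
    return mat


def zero_adjusted_bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Bray–Curtis dissimilarity after appending a constant dummy column.

    The dummy species (value 1 in every sample) keeps the dissimilarity
    of two all-zero samples at 0 instead of 0/0, and bounds the range to
    [0, 1).  Negative abundances are a domain error.
    """
    if (matrix.to_numpy(dtype=float) < 0).any():
        raise ValueError("abundances must be >= 0")
    adj = matrix.copy().astype(float)
    adj["__dummy__"] = 1.0
    d = pdist(adj.to_numpy(), metric="braycurtis")
    return pd.DataFrame(squareform(d), index=matrix.index, columns=matrix.index)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame   # samples × 2
    stress: float               # Kruskal stress-1
    groups: pd.Series | None = None


def _check_dissimilarity(d: pd.DataFrame) -> np.ndarray:
    arr = np.asarray(d, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-12):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    return arr


def nmds(d: pd.DataFrame, dims: int = 2, restarts: int = 20,
         seed: int = 0) -> OrdinationResult:
    """Non-metric MDS (Kruskal stress-1, isotonic regression).

    Best configuration of ``restarts`` random starts; a fixed seed gives
    identical coordinates on repeat runs.
    """
    arr = _check_dissimilarity(d)
    index = d.index if isinstance(d, pd.DataFrame) else pd.RangeIndex(len(arr))
    mds = MDS(n_components=dims, metric_mds=False, dissimilarity="precomputed",
              n_init=restarts, random_state=int(seed), max_iter=500,
              eps=1e-9, normalized_stress=True)
    coords = mds.fit_transform(arr)
    cols = [f"nmds{i+1}" for i in range(dims)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=index, columns=cols),
        stress=float(mds.stress_))


def complete_linkage_groups(d: pd.DataFrame, similarity_cut: float = 90.0,
                            ) -> pd.Series:
    """Complete-linkage clusters cut at dissimilarity 1 − cut/100.

    ``similarity_cut`` is a percent in (0, 100).  Returns integer labels
    indexed like the input matrix.
    """
    if not 0 < similarity_cut < 100:
        raise ValueError("similarity cut must be inside (0, 100) percent")
    arr = _check_dissimilarity(d)
    index = d.index if isinstance(d, pd.DataFrame) else pd.RangeIndex(len(arr))
    if len(arr) == 1:
        return pd.Series([1], index=index, name="group")
    z = linkage(squareform(arr, checks=False), method="complete")
    labels = fcluster(z, t=1.0 - similarity_cut / 100.0, criterion="distance")
    return pd.Series(labels, index=index, name="group")
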