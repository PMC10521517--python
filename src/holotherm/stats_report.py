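"""Supporting inference layer: assumption checks, ANOVA with Tukey post
hoc, Kruskal–Wallis fallback, mixed-effects screening, and the
consolidated metrics report with a trait PCA.

This module wraps standard routines (scipy, statsmodels, scikit-learn);
the bespoke science lives in the upstream stages.  Tukey's pairwise test
runs only after a significant omnibus test, and groups are routed to
Kruskal–Wallis when Shapiro–Wilk normality or Levene homogeneity fails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "assumption_checks",
    "omnibus_and_posthoc",
    "mixed_effects_screen",
    "build_report",
    "GroupComparison",
    "MetricsReport",
]

ALPHA = 0.05


@dataclass
class GroupComparison:
    metric: str
    factors: list[str]
    test: str                      # anova | kruskal | three_way_anova
    statistic: float
    p_value: float
    significant: bool
    posthoc: pd.DataFrame | None = None   # pairwise Tukey flags, if run
    routing: dict = field(default_factory=dict)


def assumption_checks(values_by_group: dict[str, np.ndarray],
                      alpha: float = ALPHA) -> dict:
    """Shapiro–Wilk per group and pooled Levene; returns the routing verdict.

    Groups with fewer than 3 values get the verdict "insufficient" and
    force nonparametric routing.  A constant group makes homogeneity
    undefined (flagged, routed nonparametric).
    """
    normality = {}
    insufficient = False
    for name, vals in values_by_group.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 3:
            normality[name] = "insufficient"
            insufficient = True
        elif np.ptp(vals) == 0:
            normality[name] = "constant"
        else:
            p = sps.shapiro(vals).pvalue
            normality[name] = "pass" if p >= alpha else "fail"
    groups = [np.asarray(v, float) for v in values_by_group.values()]
    if len(groups) < 2:
        homogeneity = "not_applicable"
    elif any(len(g) < 2 for g in groups) or any(np.ptp(g) == 0 for g in groups):
        homogeneity = "undefined"
    else:
        homogeneity = ("pass" if sps.levene(*groups).pvalue >= alpha else "fail")
    parametric = (not insufficient
                  and all(v == "pass" for v in normality.values())
                  and homogeneity in ("pass", "not_applicable"))
    return {"normality": normality, "homogeneity": homogeneity,
            "route": "parametric" if parametric else "nonparametric"}


def omnibus_and_posthoc(table: pd.DataFrame, value: str, factors: list[str],
                        alpha: float = ALPHA,
                        force_parametric: bool = False) -> GroupComparison:
    """One-way or three-way ANOVA with Tukey HSD, or Kruskal–Wallis.

    With one factor the test is routed by :func:`assumption_checks`
    (unless ``force_parametric``); with several factors a type-II
    factorial ANOVA is fitted and the full-interaction cell grid must be
    non-empty.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    for f in factors:
        if table[f].nunique() < 2:
            raise ValueError(f"factor '{f}' has fewer than 2 levels")

    if len(factors) == 1:
        factor = factors[0]
        groups = {str(k): g[value].to_numpy()
                  for k, g in table.groupby(factor)}
        routing = assumption_checks(groups, alpha)
        route = "parametric" if force_parametric else routing["route"]
        if route == "parametric":
            stat, p = sps.f_oneway(*groups.values())
            test = "anova"
        else:
            stat, p = sps.kruskal(*groups.values())
            test = "kruskal"
        sig = bool(p < alpha)
        posthoc = None
        if sig and len(groups) > 2:
            tk = pairwise_tukeyhsd(table[value].to_numpy(),
                                   table[factor].astype(str).to_numpy(),
                                   alpha=alpha)
            posthoc = pd.DataFrame(tk.summary().data[1:],
                                   columns=tk.summary().data[0])
        return GroupComparison(value, factors, test, float(stat), float(p),
                               sig, posthoc, routing)

    # factorial ANOVA: every cell of the full cross must be populated
    cells = table.groupby(factors, observed=True).size()
    full = np.prod([table[f].nunique() for f in factors])
    if len(cells) < full:
        have = set(cells.index)
        levels = [table[f].unique() for f in factors]
        from itertools import product
        missing = [c for c in product(*levels) if c not in have]
        raise ValueError(f"empty cell(s) in the factorial design: {missing[:5]}")
    rhs = " * ".join(f"C({f})" for f in factors)
    fit = smf.ols(f"{value} ~ {rhs}", data=table).fit()
    aov = sm.stats.anova_lm(fit, typ=2)
    main = aov.loc[[f"C({f})" for f in factors]]
    stat = float(main["F"].max())
    p = float(main["PR(>F)"].min())
    sig = bool(p < alpha)
    posthoc = None
    if sig:
        combo = table[factors].astype(str).agg(":".join, axis=1)
        tk = pairwise_tukeyhsd(table[value].to_numpy(), combo.to_numpy(),
                               alpha=alpha)
        posthoc = pd.DataFrame(tk.summary().data[1:],
                               columns=tk.summary().data[0])
    return GroupComparison(value, factors, "three_way_anova", stat, p, sig,
                           posthoc, {"anova_table": aov})


def mixed_effects_screen(table: pd.DataFrame, value: str,
                         fixed: list[str], random: list[str],
                         alpha: float = ALPHA) -> dict:
    """Gaussian mixed model: fixed-effect tests plus random variance shares.

    Fit with ``statsmodels`` MixedLM using variance components for each
    random factor.  A singular fit (a variance component at the zero
    boundary) is reported as a boundary estimate, not an error.  The
    "negligible" verdict per random factor is a variance share below 5 %
    of the total.
    """
    import statsmodels.formula.api as smf

    for r in random:
        if table[r].nunique() < 2:
            raise ValueError(f"random factor '{r}' has fewer than 2 levels")
    data = table.copy()
    data["_one_"] = 1
    rhs = " + ".join(f"C({f})" for f in fixed) if fixed else "1"
    vc = {r: f"0 + C({r})" for r in random}
    model = smf.mixedlm(f"{value} ~ {rhs}", data=data, groups="_one_",
                        vc_formula=vc)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    resid_var = float(fit.scale)
    vc_names = list(getattr(model.exog_vc, "names", vc))
    vcs = {name: max(float(v), 0.0)
           for name, v in zip(vc_names, np.atleast_1d(fit.vcomp))}
    total = resid_var + sum(vcs.values())
    shares = {k: v / total for k, v in vcs.items()}
    fixed_tests = {}
    for name, coef, p in zip(fit.params.index, fit.params, fit.pvalues):
        if name in ("Intercept",) or name in vc:
            continue
        fixed_tests[name] = {"estimate": float(coef), "p_value": float(p)}
    verdicts = {k: ("negligible" if s < 0.05 else "substantial")
                for k, s in shares.items()}
    return {"fixed": fixed_tests, "variance_shares": shares,
            "residual_variance": resid_var, "random_verdicts": verdicts,
            "converged": bool(fit.converged)}


# ---------------------------------------------------------------------
# consolidated report
# ---------------------------------------------------------------------

TRAITS = ("fv_fm", "df_fm_prime", "density", "calcification",
          "carbon_fixation", "carbon_translocation", "log10_dc")


@dataclass
class MetricsReport:
    traits: pd.DataFrame                      # per holobiont × arm × tank
    pca_scores: pd.DataFrame | None
    pca_loadings: pd.DataFrame | None
    explained_variance_ratio: list | None
    comparisons: list[GroupComparison]
    gaps: list[str]
    tables: dict = field(default_factory=dict)


def build_report(assay, alpha: float = ALPHA, nmds_seed: int = 0,
                 ) -> MetricsReport:
    """Run every stage on an AssaySet and consolidate the derived metrics.

    Traits are aggregated per holobiont × arm × tank (the unit at which
    all seven traits coexist), z-scored, and summarized by PCA.  Stages
    whose input table is empty are recorded as gaps rather than failures.
    """
    from sklearn.decomposition import PCA

    from . import calcification as calc
    from . import census as census_mod
    from . import community_structure as comm
    from . import isotope_tracing as iso
    from . import photochemistry as photo
    from .experiment_core import design_with_arm

    design = design_with_arm(assay.design)
    frag_meta = design[["fragment_id", "holobiont", "arm", "tank"]]
    gaps, tables = [], {}
    pieces = []

    def _tankwise(df, value, name):
        merged = df.merge(frag_meta, on="fragment_id", how="left")
        agg = (merged.groupby(["holobiont", "arm", "tank"])[value]
               .mean().rename(name))
        pieces.append(agg)

    if assay.pam.empty:
        gaps.append("photochemistry")
    else:
        pairs, _ = photo.pair_yields(assay.pam)
        last = pairs["day"].max()
        end = pairs[pairs["day"] == last]
        _tankwise(end, "fv_fm", "fv_fm")
        _tankwise(end, "df_fm_prime", "df_fm_prime")
        tables["delta_qm"] = photo.compute_delta_qm(
            photo.compute_qm(pairs), assay.design, pooling="overall")

    if assay.counts.empty:
        gaps.append("census")
    else:
        dens = census_mod.areal_density(assay.counts)
        _tankwise(dens[dens["day"] == dens["day"].max()], "density", "density")
        tables["bleaching"] = census_mod.bleaching_rate_table(
            assay.census, assay.design) if not assay.census.empty else None

    if assay.weights.empty:
        gaps.append("calcification")
    else:
        rates = calc.interval_rates(assay.weights)
        _tankwise(rates, "rate", "calcification")
        tables["calcification_rates"] = rates

    if assay.isotopes.empty:
        gaps.append("isotope_tracing")
    else:
        meta = assay.metadata
        up = iso.tracer_uptake(
            assay.isotopes, assay.design,
            incubation_hours=float(meta.get("incubation_hours", 24.0)),
            tracer_umol=float(meta.get("tracer_umol", 70.0)),
            tracer_atom_percent=float(meta.get("tracer_atom_percent", 99.0)),
            ambient_dic_umol=float(meta.get("ambient_dic_umol", 2000.0)))
        valid = up[up["valid"]]
        wide = valid.pivot_table(index="fragment_id", columns="fraction",
                                 values="uptake", aggfunc="first")
        wide = wide.dropna()
        if not wide.empty:
            fix = (wide["host"] + wide["symbiont"]).rename("carbon_fixation")
            tl = (wide["host"] / (wide["host"] + wide["symbiont"])
                  ).rename("carbon_translocation")
            frame = pd.concat([fix, tl], axis=1).reset_index()
            _tankwise(frame, "carbon_fixation", "carbon_fixation")
            _tankwise(frame, "carbon_translocation", "carbon_translocation")
        tables["translocation"] = iso.summarize_translocation(up)

    if assay.qpcr.empty:
        gaps.append("community_structure")
    else:
        ct_limit = float(assay.metadata.get("ct_limit", 40.0))
        ratios = comm.dc_ratio(assay.qpcr, ct_limit=ct_limit)
        _tankwise(ratios[ratios["day"] == ratios["day"].max()],
                  "log10_dc", "log10_dc")
        tables["dc_trajectory"] = comm.dc_trajectory(ratios, assay.design)
        if not assay.clones.empty:
            mat = comm.community_matrix(assay.clones, level="metahaplotype",
                                        relative=True)
            d = comm.zero_adjusted_bray_curtis(mat)
            ord_ = comm.nmds(d, seed=nmds_seed)
            ord_.groups = comm.complete_linkage_groups(d, 90.0)
            tables["ordination"] = ord_

    traits = pd.concat(pieces, axis=1) if pieces else pd.DataFrame()
    comparisons: list[GroupComparison] = []
    if not traits.empty:
        flat = traits.reset_index()
        for col in traits.columns:
            sub = flat.dropna(subset=[col])
            for hb, grp in sub.groupby("holobiont"):
                if grp["arm"].nunique() == 2 and len(grp) >= 4:
                    cmp_ = omnibus_and_posthoc(grp, col, ["arm"], alpha=alpha)
                    cmp_.metric = f"{col}[{hb}]"
                    comparisons.append(cmp_)

    pca_scores = pca_loadings = None
    evr = None
    complete = traits.dropna(axis=1, how="all").dropna()
    if complete.shape[0] >= 3 and complete.shape[1] >= 2:
        z = (complete - complete.mean()) / complete.std(ddof=0).replace(0, 1.0)
        n_comp = min(2, z.shape[1])
        pca = PCA(n_components=n_comp)
        scores = pca.fit_transform(z.to_numpy())
        pca_scores = pd.DataFrame(scores, index=complete.index,
                                  columns=[f"PC{i+1}" for i in range(n_comp)])
        pca_loadings = pd.DataFrame(pca.components_.T, index=complete.columns,
                                    columns=[f"PC{i+1}" for i in range(n_comp)])
        evr = [float(v) for v in pca.explained_variance_ratio_]
    else:
        gaps.append("pca")

    return MetricsReport(traits=traits.reset_index(), pca_scores=pca_scores,
                         pca_loadings=pca_loadings,
                         explained_variance_ratio=evr,
                         comparisons=comparisons, gaps=gaps, tables=tables)
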