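"""Seeded generator of synthetic assay tables for the two-holobiont design.

The generator emulates the laboratory experiment end to end: per holobiont
(PdC, PdD) three colonies of ~40 ramets are spread over six 80-L tanks
(three control at 26 °C, three heated at 32 °C), fate-tracked for 14 days
with sampling at days 0/7/14 and daily PAM fluorometry.  Effect sizes are
encoded per holobiont × arm in :class:`EffectBlock`; the ``paper_default``
preset carries the study's reported effects (77 % day-14 Fv/Fm decrease and
98 % symbiont-density decline in heated PdC, 40 %/50 % calcification
reductions, 26.7 %/83.3 % cumulative bleaching, a −7 → −4 drift in
log₁₀ D/C, and a 71 % control-temperature calcification advantage of PdC
over PdD), while ``null_effect`` switches every treatment effect off for
type-I-error calibration.

Mechanistic choices (documented in docs/methods.md):

* PAM trajectories are piecewise-linear in day between arm-specific
  endpoints, with a multiplicative per-fragment effect (which leaves the
  excitation-pressure ratio invariant) plus additive replicate noise
  truncated to [0, 1].
* Bleaching is an absorbing per-fragment state drawn as a first-passage
  process matching the block's cumulative probabilities.
* qPCR CTs are derived from a latent per-fragment log₁₀ D/C value via the
  2^−ΔCT model, with technical-triplicate noise; CTs above the detection
  limit are stored as non-detects (empty cells).
* Labeled δ¹³C values are back-computed from per-fragment fixation and
  translocation rates through the same atom-percent bookkeeping the
  analysis stage uses; unlabeled controls sit at the natural baseline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .experiment_core import (
    ARMS,
    AssaySet,
    CONTROL_TEMPERATURE,
    HEAT_TEMPERATURE,
    HOLOBIONTS,
    empty_table,
    make_fragment_id,
)
from .isotope_tracing import atom_percent, delta_from_atom_percent, dic_atom_percent

__all__ = [
    "EffectBlock",
    "NoiseConfig",
    "GeneratorConfig",
    "paper_default_config",
    "null_effect_config",
    "generate",
    "generate_worked_microexample",
]

#: ITS2 types scored in clone libraries, per dominant genus
CLONE_TYPES = {
    "PdC": (("C42", 0.55), ("C1", 0.25), ("C1b", 0.12), ("C1c", 0.08)),
    "PdD": (("D1", 0.60), ("D4", 0.25), ("D6", 0.15)),
}


@dataclass(frozen=True)
class EffectBlock:
    """Target effect sizes for one holobiont × temperature arm.

    Multipliers are relative to the arm's own day-0 / control level; a
    multiplier of 1.0 means no treatment effect.  ``qm_offset_day14`` is
    the day-14 elevation of excitation pressure Qm over the control
    level (the daily offset ramps linearly from 0 at day 0).
    """

    fvfm_baseline: float = 0.65
    fvfm_day14_multiplier: float = 1.0
    light_yield_baseline: float = 0.45
    qm_offset_day14: float = 0.0
    density_baseline: float = 1.5e6          # cells / cm²
    density_day7_multiplier: float = 1.0
    density_day14_multiplier: float = 1.0
    calcification_baseline: float = 0.060    # Eq-2 scale: (g cm⁻² d⁻¹) × 100
    calcification_day7_multiplier: float = 1.0
    calcification_day14_multiplier: float = 1.0
    bleach_prob_day7: float = 0.0
    bleach_prob_day14: float = 0.0
    log10_dc_start: float = -7.0
    log10_dc_end: float = -7.0
    carbon_fixation_rate: float = 2.0e-4     # tracer C per tissue C per hour
    translocation_fraction: float = 0.30
    natural_delta13c: float = -15.0          # ‰ vs VPDB

    def __post_init__(self):
        if min(self.fvfm_day14_multiplier, self.density_day7_multiplier,
               self.density_day14_multiplier, self.calcification_day7_multiplier,
               self.calcification_day14_multiplier) < 0:
            raise ValueError("effect multipliers must be >= 0")
        if not 0 <= self.bleach_prob_day7 <= self.bleach_prob_day14 <= 1:
            raise ValueError("cumulative bleaching probability must be "
                             "non-decreasing and in [0, 1]")
        if not np.isfinite(self.log10_dc_start) or not np.isfinite(self.log10_dc_end):
            raise ValueError("log10 D/C endpoints must be finite")


@dataclass(frozen=True)
class NoiseConfig:
    """Measurement / biological noise standard deviations per assay."""

    pam_replicate_sd: float = 0.02     # additive, on a single yield reading
    pam_fragment_sd: float = 0.03      # multiplicative, shared by both phases
    weight_sd_g: float = 0.0005        # buoyant-weight reading error
    growth_cv: float = 0.10            # per-fragment calcification heterogeneity
    density_log_sd: float = 0.15       # per-fragment lognormal density scatter
    ct_replicate_sd: float = 0.15      # qPCR technical-triplicate SD (cycles)
    dc_log10_sd: float = 0.30          # per-fragment log10 D/C scatter
    delta13c_sd: float = 0.3           # IRMS reproducibility (‰)
    uptake_cv: float = 0.20            # per-fragment carbon-fixation scatter
    translocation_sd: float = 0.03     # per-fragment translocation scatter
    tank_sd: float = 0.0               # multiplicative random tank effect
    colony_sd: float = 0.0             # multiplicative random colony effect

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"noise SD '{f.name}' must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    preset: str = "custom"
    seed: int = 0
    n_colonies: int = 3
    n_tanks_per_arm: int = 3
    n_fragments_per_colony: int = 40
    duration_days: int = 14
    sampling_days: tuple[int, ...] = (0, 7, 14)
    n_pam_per_arm: int = 9             # fate-tracked photochem/weight ramets
    n_census_per_arm_day: int = 6      # destructively sampled per sampling day
    n_isotope_labeled_per_arm: int = 6
    n_isotope_controls_per_arm: int = 3
    clones_min: int = 6
    clones_max: int = 12
    qpcr_base_ct: float = 14.5         # CT of the (abundant) dominant genus
    ct_limit: float = 40.0
    tracer_umol: float = 70.0
    tracer_atom_percent: float = 99.0
    ambient_dic_umol: float = 2000.0
    incubation_hours: float = 24.0
    effect_table: dict = field(default_factory=dict)  # (holobiont, arm) -> EffectBlock
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def __post_init__(self):
        for name in ("n_colonies", "n_tanks_per_arm", "n_fragments_per_colony",
                     "duration_days", "n_pam_per_arm", "n_census_per_arm_day"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def block(self, holobiont: str, arm: str) -> EffectBlock:
        return self.effect_table[(holobiont, arm)]


def _paper_effect_table() -> dict:
    """Effect blocks encoding the study's reported effect sizes."""
    pdc_calc = 0.060
    pdd_calc = pdc_calc / 1.71          # PdC control calcifies 71 % faster
    pdc = dict(density_baseline=1.5e6, calcification_baseline=pdc_calc,
               carbon_fixation_rate=4.0e-4, translocation_fraction=0.45)
    pdd = dict(density_baseline=2.5e6, calcification_baseline=pdd_calc,
               carbon_fixation_rate=2.0e-4, translocation_fraction=0.30)
    # daily Qm offsets ramp linearly 0 → day-14 value; the pooled (day 1–14)
    # mean of such a ramp is mean(1..14)/14 = 7.5/14 of the endpoint, so the
    # endpoint is chosen to make the pooled ΔQm equal the target value.
    pool = 7.5 / 14.0
    return {
        ("PdC", "control"): EffectBlock(
            log10_dc_start=-7.0, log10_dc_end=-6.8, **pdc),
        ("PdC", "heat"): EffectBlock(
            fvfm_day14_multiplier=0.23,          # 77 % day-14 Fv/Fm decrease
            qm_offset_day14=0.17 / pool,         # pooled ΔQm 0.17
            density_day7_multiplier=0.30,
            density_day14_multiplier=0.02,       # 98 % density decline
            calcification_day7_multiplier=0.60,  # 40 % reduction, day 7
            calcification_day14_multiplier=0.50, # 50 % reduction, day 14
            bleach_prob_day7=0.267,
            bleach_prob_day14=0.833,
            log10_dc_start=-7.0, log10_dc_end=-4.0,   # 1000-fold D/C rise
            **{**pdc, "carbon_fixation_rate": 1.0e-4}),
        ("PdD", "control"): EffectBlock(
            log10_dc_start=6.0, log10_dc_end=5.2, **pdd),
        ("PdD", "heat"): EffectBlock(
            qm_offset_day14=0.02 / pool,         # pooled ΔQm 0.02
            log10_dc_start=6.0, log10_dc_end=6.3, **pdd),
    }


def paper_default_config(seed: int) -> GeneratorConfig:
    """The preset that encodes the study's design and effect sizes."""
    return GeneratorConfig(preset="paper_default", seed=int(seed),
                           effect_table=_paper_effect_table())


def null_effect_config(seed: int) -> GeneratorConfig:
    """All treatment effects off — both arms identical in expectation."""
    table = {}
    for (hb, arm), block in _paper_effect_table().items():
        table[(hb, arm)] = replace(
            block,
            fvfm_day14_multiplier=1.0, qm_offset_day14=0.0,
            density_day7_multiplier=1.0, density_day14_multiplier=1.0,
            calcification_day7_multiplier=1.0, calcification_day14_multiplier=1.0,
            bleach_prob_day7=0.0, bleach_prob_day14=0.0,
            log10_dc_end=block.log10_dc_start,
            carbon_fixation_rate=table.get((hb, "control"), block).carbon_fixation_rate
            if arm == "heat" else block.carbon_fixation_rate,
        )
    return GeneratorConfig(preset="null_effect", seed=int(seed), effect_table=table)


def config_from_preset(preset: str, seed: int) -> GeneratorConfig:
    if preset == "paper_default":
        return paper_default_config(seed)
    if preset == "null_effect":
        return null_effect_config(seed)
    raise ValueError(f"unknown preset '{preset}' (use paper_default or null_effect)")


# ---------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------

def _lerp(a: float, b: float, frac) -> np.ndarray:
    return a + (b - a) * np.asarray(frac, dtype=float)


def _day_multiplier(day, m7: float, m14: float) -> np.ndarray:
    """Piecewise-linear multiplier through (0, 1), (7, m7), (14, m14)."""
    day = np.asarray(day, dtype=float)
    return np.where(day <= 7, _lerp(1.0, m7, day / 7.0),
                    _lerp(m7, m14, (day - 7.0) / 7.0))


class _Design:
    """Fragment bookkeeping for one generated experiment."""

    def __init__(self, config: GeneratorConfig, rng: np.random.Generator):
        rows = []
        n_tanks = 2 * config.n_tanks_per_arm
        for hb in HOLOBIONTS:
            for colony in range(1, config.n_colonies + 1):
                tanks = np.tile(np.arange(1, n_tanks + 1),
                                -(-config.n_fragments_per_colony // n_tanks))
                tanks = tanks[: config.n_fragments_per_colony]
                for idx, tank in enumerate(tanks, start=1):
                    arm = "control" if tank <= config.n_tanks_per_arm else "heat"
                    temp = CONTROL_TEMPERATURE if arm == "control" else HEAT_TEMPERATURE
                    rows.append((make_fragment_id(hb, colony, tank, idx),
                                 hb, colony, int(tank), temp, arm))
        self.frame = pd.DataFrame(
            rows, columns=["fragment_id", "holobiont", "colony", "tank",
                           "temperature", "arm"])
        self.config = config
        self.roles = self._assign_roles(rng)
        # random tank / colony effects (multiplicative, shared across assays)
        noise = config.noise
        self.tank_eff = {
            (hb, t): np.exp(rng.normal(0.0, noise.tank_sd)) if noise.tank_sd else 1.0
            for hb in HOLOBIONTS for t in range(1, n_tanks + 1)}
        self.colony_eff = {
            (hb, c): np.exp(rng.normal(0.0, noise.colony_sd)) if noise.colony_sd else 1.0
            for hb in HOLOBIONTS for c in range(1, config.n_colonies + 1)}

    def _assign_roles(self, rng: np.random.Generator) -> dict:
        """Pick which fragments serve which assay, per holobiont × arm.

        PAM/weight ramets are fate-tracked for the full 14 days; census
        (count + community) ramets are destructively sampled at one
        sampling day; isotope ramets are sacrificed at day 14.
        """
        cfg = self.config
        roles: dict[str, dict] = {}
        for (hb, arm), grp in self.frame.groupby(["holobiont", "arm"]):
            ids = grp["fragment_id"].to_numpy()
            perm = rng.permutation(len(ids))
            ids = ids[perm]
            k = 0
            pam = ids[k:k + cfg.n_pam_per_arm]; k += cfg.n_pam_per_arm
            census = {}
            for day in cfg.sampling_days:
                census[day] = ids[k:k + cfg.n_census_per_arm_day]
                k += cfg.n_census_per_arm_day
            iso = ids[k:k + cfg.n_isotope_labeled_per_arm]
            k += cfg.n_isotope_labeled_per_arm
            iso_ctl = ids[k:k + cfg.n_isotope_controls_per_arm]
            k += cfg.n_isotope_controls_per_arm
            if k > len(ids):
                raise ValueError("not enough fragments per arm for the assay roles")
            roles[(hb, arm)] = {"pam": pam, "census": census,
                                "isotope": iso, "isotope_control": iso_ctl}
        return roles

    def effect(self, fragment_rows: pd.DataFrame) -> np.ndarray:
        """Combined tank × colony multiplicative effect per row."""
        return np.array([
            self.tank_eff[(hb, t)] * self.colony_eff[(hb, c)]
            for hb, t, c in zip(fragment_rows["holobiont"],
                                fragment_rows["tank"], fragment_rows["colony"])])


def generate(config: GeneratorConfig) -> AssaySet:
    """Produce a complete, validated :class:`AssaySet` from ``config``.

    Identical configs yield identical tables (single seeded RNG, fixed
    draw order).
    """
    if not config.effect_table:
        raise ValueError("config.effect_table is empty; build the config via "
                         "paper_default_config / null_effect_config")
    rng = np.random.default_rng(config.seed)
    design = _Design(config, rng)
    frame = design.frame.set_index("fragment_id", drop=False)
    noise = config.noise

    bleach_u = {fid: rng.uniform() for fid in frame["fragment_id"]}

    pam = _gen_pam(config, design, frame, rng)
    weights = _gen_weights(config, design, frame, rng)
    counts = _gen_counts(config, design, frame, rng)
    census = _gen_census(config, design, frame, bleach_u)
    qpcr = _gen_qpcr(config, design, frame, rng)
    isotopes = _gen_isotopes(config, design, frame, rng)
    clones = _gen_clones(config, design, frame, rng)

    metadata = {
        "preset": config.preset,
        "seed": int(config.seed),
        "units": {"mass": "g", "area": "cm2", "density": "cells/cm2",
                  "delta13c": "permil vs VPDB", "ct": "cycles"},
        "incubation_hours": config.incubation_hours,
        "tracer_umol": config.tracer_umol,
        "tracer_atom_percent": config.tracer_atom_percent,
        "ambient_dic_umol": config.ambient_dic_umol,
        "ct_limit": config.ct_limit,
    }
    out = AssaySet(
        design=design.frame[["fragment_id", "holobiont", "colony", "tank",
                             "temperature"]].copy(),
        pam=pam, weights=weights, counts=counts, census=census,
        qpcr=qpcr, isotopes=isotopes, clones=clones, metadata=metadata)
    return out.validate()


def _gen_pam(config, design, frame, rng) -> pd.DataFrame:
    noise = config.noise
    rows = []
    days = np.arange(config.duration_days + 1)
    for (hb, arm), roles in design.roles.items():
        block = config.block(hb, arm)
        ctl = config.block(hb, "control")
        qm_control = 1.0 - ctl.light_yield_baseline / ctl.fvfm_baseline
        fvfm_mult = _lerp(1.0, block.fvfm_day14_multiplier,
                          days / config.duration_days)
        qm = qm_control + block.qm_offset_day14 * days / config.duration_days
        dark_mean = block.fvfm_baseline * fvfm_mult
        light_mean = dark_mean * (1.0 - qm)
        for fid in roles["pam"]:
            eff = design.effect(frame.loc[[fid]])[0]
            frag = 1.0 + rng.normal(0.0, noise.pam_fragment_sd)
            scale = max(frag * eff, 0.05)   # multiplicative: leaves Qm intact
            for d in days:
                for phase, mean in (("dark", dark_mean[d]), ("light", light_mean[d])):
                    reps = mean * scale + rng.normal(0.0, noise.pam_replicate_sd, 3)
                    reps = np.clip(reps, 0.0, 1.0)
                    for r, y in enumerate(reps, start=1):
                        rows.append((fid, int(d), phase, r, float(y)))
    return pd.DataFrame(rows, columns=["fragment_id", "day", "phase",
                                       "replicate", "yield"])


def _gen_weights(config, design, frame, rng) -> pd.DataFrame:
    noise = config.noise
    rows = []
    for (hb, arm), roles in design.roles.items():
        block = config.block(hb, arm)
        for fid in roles["pam"]:
            eff = design.effect(frame.loc[[fid]])[0]
            area = max(rng.normal(5.0, 0.5), 1.0)
            bw = max(rng.normal(1.2, 0.1), 0.3)
            frag = np.exp(rng.normal(0.0, noise.growth_cv))
            rate = block.calcification_baseline * frag * eff
            true = {0: bw}
            true[7] = true[0] + rate * block.calcification_day7_multiplier * area * 7 / 100.0
            true[14] = true[7] + rate * block.calcification_day14_multiplier * area * 7 / 100.0
            for day in (0, 7, 14):
                if day > config.duration_days:
                    continue
                obs = true[day] + rng.normal(0.0, noise.weight_sd_g)
                rows.append((fid, day, float(obs), float(area)))
    return pd.DataFrame(rows, columns=["fragment_id", "day",
                                       "buoyant_weight_g", "surface_area_cm2"])


_CHAMBER_VOLUME_ML = 1e-4   # standard hemocytometer large-square grid


def _gen_counts(config, design, frame, rng) -> pd.DataFrame:
    noise = config.noise
    rows = []
    for (hb, arm), roles in design.roles.items():
        block = config.block(hb, arm)
        for day, ids in roles["census"].items():
            mult = float(_day_multiplier(day, block.density_day7_multiplier,
                                         block.density_day14_multiplier))
            for fid in ids:
                eff = design.effect(frame.loc[[fid]])[0]
                area = max(rng.normal(5.0, 0.5), 1.0)
                dens = block.density_baseline * mult * eff * np.exp(
                    rng.normal(0.0, noise.density_log_sd))
                slurry = 5.0
                raw = dens * area * _CHAMBER_VOLUME_ML / slurry
                dilution = max(1.0, float(round(raw / 50.0)))  # aim ~50 cells
                lam = raw / dilution
                for r in range(1, 4):
                    c = int(rng.poisson(lam))
                    rows.append((fid, int(day), c, dilution, slurry,
                                 float(area), r))
    return pd.DataFrame(rows, columns=["fragment_id", "day", "chamber_count",
                                       "dilution_factor", "slurry_volume_ml",
                                       "surface_area_cm2", "replicate"])


def _gen_census(config, design, frame, bleach_u) -> pd.DataFrame:
    """Fate-tracked status of every fragment at each sampling day.

    A fragment destructively sampled at day d is scored at d and recorded
    as 'removed' at later sampling days, so bleaching-rate denominators
    ("all the remaining fragments") are exercised.  Bleaching is absorbing.
    """
    removal_day = {}
    for (hb, arm), roles in design.roles.items():
        for day, ids in roles["census"].items():
            for fid in ids:
                removal_day[fid] = day
        last = config.sampling_days[-1]
        for fid in np.concatenate([roles["isotope"], roles["isotope_control"]]):
            removal_day[fid] = last
    rows = []
    for fid, hb, arm in zip(frame["fragment_id"], frame["holobiont"], frame["arm"]):
        block = config.block(hb, arm)
        u = bleach_u[fid]
        for day in config.sampling_days:
            if fid in removal_day and day > removal_day[fid]:
                status = "removed"
            else:
                p = 0.0 if day == 0 else (
                    block.bleach_prob_day7 if day <= 7 else block.bleach_prob_day14)
                status = "bleached" if u < p else "healthy"
            rows.append((fid, int(day), status))
    return pd.DataFrame(rows, columns=["fragment_id", "day", "status"])


def _gen_qpcr(config, design, frame, rng) -> pd.DataFrame:
    noise = config.noise
    rows = []
    for (hb, arm), roles in design.roles.items():
        block = config.block(hb, arm)
        for day, ids in roles["census"].items():
            frac = day / config.duration_days
            for fid in ids:
                l10 = float(_lerp(block.log10_dc_start, block.log10_dc_end, frac)
                            + rng.normal(0.0, noise.dc_log10_sd))
                dc = 10.0 ** l10
                p_d = dc / (1.0 + dc)
                ct_c = config.qpcr_base_ct - np.log2(1.0 - p_d)
                ct_d = config.qpcr_base_ct - np.log2(p_d)
                for primer, ct_true in (("C", ct_c), ("D", ct_d)):
                    for r in range(1, 4):
                        ct = ct_true + rng.normal(0.0, noise.ct_replicate_sd)
                        val = np.nan if ct > config.ct_limit else float(ct)
                        rows.append((fid, int(day), primer, r, val))
    return pd.DataFrame(rows, columns=["fragment_id", "day", "primer",
                                       "replicate", "ct"])


def _gen_isotopes(config, design, frame, rng) -> pd.DataFrame:
    noise = config.noise
    a_dic = dic_atom_percent(config.tracer_umol, config.tracer_atom_percent,
                             config.ambient_dic_umol)
    rows = []
    for (hb, arm), roles in design.roles.items():
        block = config.block(hb, arm)
        a_nat = atom_percent(block.natural_delta13c)
        for fid in roles["isotope"]:
            u_tot = block.carbon_fixation_rate * np.exp(
                rng.normal(0.0, noise.uptake_cv))
            tf = float(np.clip(block.translocation_fraction
                               + rng.normal(0.0, noise.translocation_sd),
                               0.02, 0.98))
            for fraction, u in (("host", tf * u_tot), ("symbiont", (1 - tf) * u_tot)):
                a_s = a_nat + u * config.incubation_hours * (a_dic - a_nat)
                delta = delta_from_atom_percent(a_s) + rng.normal(0.0, noise.delta13c_sd)
                oc = max(rng.normal(800.0, 100.0), 50.0)
                rows.append((fid, fraction, 1, float(delta), float(oc)))
        for fid in roles["isotope_control"]:
            for fraction in ("host", "symbiont"):
                delta = block.natural_delta13c + rng.normal(0.0, noise.delta13c_sd)
                oc = max(rng.normal(800.0, 100.0), 50.0)
                rows.append((fid, fraction, 0, float(delta), float(oc)))
    return pd.DataFrame(rows, columns=["fragment_id", "fraction", "labeled",
                                       "delta13c_permil", "organic_carbon_ug"])


def _gen_clones(config, design, frame, rng) -> pd.DataFrame:
    """ITS2 clone libraries: pretreatment (control-arm day-0 ramets) and
    experiment-end (day-14 ramets, both arms).

    Libraries contain dominant-genus types only: the background genus
    sits at a relative abundance of ≤ 1e-4 (the qPCR-scale D/C ratios),
    far below the detection floor of a 6–12-clone Sanger library, so its
    expected clone count rounds to zero in every sample.
    """
    rows = []
    last = config.sampling_days[-1]
    for (hb, arm), roles in design.roles.items():
        types, props = zip(*CLONE_TYPES[hb])
        props = np.asarray(props) / np.sum(props)
        samples = []
        if arm == "control":
            samples += [(fid, "pretreatment") for fid in roles["census"][0]]
        samples += [(fid, "end") for fid in roles["census"][last]]
        for fid, stage in samples:
            n = int(rng.integers(config.clones_min, config.clones_max + 1))
            dom = rng.multinomial(n, props)
            for t, c in zip(types, dom):
                if c > 0:
                    rows.append((fid, stage, t, int(c)))
    return pd.DataFrame(rows, columns=["fragment_id", "stage", "its2_type",
                                       "clone_count"])


# ---------------------------------------------------------------------
# worked micro-example
# ---------------------------------------------------------------------

def generate_worked_microexample() -> AssaySet:
    """A tiny noise-free fixture with hand-computable expected metrics.

    Two PdC fragments (one per arm), two time points.  Downstream values:
    control Qm = 1 − 0.30/0.60 = 0.5; heated Qm = 1 − 0.20/0.50 = 0.6;
    ΔQm = 0.1.  Control calcification rate over days 0–7 equals
    (1.014 − 1.000)/10 × (1/7) × 100 = 0.02.  The qPCR pair CT_C = 20,
    CT_D = 30 gives D/C = 2⁻¹⁰.  Hemocytometer counts {50, 48, 52} at
    dilution 10, 5 mL slurry, 5 cm² give 5.0e6 cells/cm².
    """
    ctl = make_fragment_id("PdC", 1, 1, 1)
    hot = make_fragment_id("PdC", 1, 4, 2)
    design = pd.DataFrame({
        "fragment_id": [ctl, hot], "holobiont": ["PdC", "PdC"],
        "colony": [1, 1], "tank": [1, 4],
        "temperature": [CONTROL_TEMPERATURE, HEAT_TEMPERATURE]})
    pam = pd.DataFrame(
        [(ctl, 0, "dark", 1, 0.60), (ctl, 0, "light", 1, 0.30),
         (hot, 0, "dark", 1, 0.50), (hot, 0, "light", 1, 0.20)],
        columns=["fragment_id", "day", "phase", "replicate", "yield"])
    weights = pd.DataFrame(
        [(ctl, 0, 1.000, 10.0), (ctl, 7, 1.014, 10.0),
         (hot, 0, 1.000, 10.0), (hot, 7, 1.007, 10.0)],
        columns=["fragment_id", "day", "buoyant_weight_g", "surface_area_cm2"])
    counts = pd.DataFrame(
        [(ctl, 0, c, 10.0, 5.0, 5.0, r) for r, c in enumerate((50, 48, 52), 1)],
        columns=["fragment_id", "day", "chamber_count", "dilution_factor",
                 "slurry_volume_ml", "surface_area_cm2", "replicate"])
    census = pd.DataFrame(
        [(ctl, 0, "healthy"), (ctl, 7, "healthy"),
         (hot, 0, "healthy"), (hot, 7, "bleached")],
        columns=["fragment_id", "day", "status"])
    qpcr = pd.DataFrame(
        [(ctl, 0, "C", r, 20.0) for r in (1, 2, 3)]
        + [(ctl, 0, "D", r, 30.0) for r in (1, 2, 3)],
        columns=["fragment_id", "day", "primer", "replicate", "ct"])
    # labeled values back-computed from a 0.01 h⁻¹ uptake in each fraction
    a_dic = dic_atom_percent(70.0, 99.0, 2000.0)
    a_nat = atom_percent(-15.0)
    a_lab = a_nat + 0.01 * 24.0 * (a_dic - a_nat)
    d_lab = delta_from_atom_percent(a_lab)
    isotopes = pd.DataFrame(
        [(ctl, "host", 1, d_lab, 800.0), (ctl, "symbiont", 1, d_lab, 800.0),
         (hot, "host", 0, -15.0, 800.0), (hot, "symbiont", 0, -15.0, 800.0)],
        columns=["fragment_id", "fraction", "labeled", "delta13c_permil",
                 "organic_carbon_ug"])
    clones = pd.DataFrame(
        [(ctl, "pretreatment", "C42", 5), (ctl, "pretreatment", "C1", 3),
         (ctl, "end", "C42", 5), (ctl, "end", "C1", 3),
         (hot, "end", "C42", 6), (hot, "end", "C1", 2)],
        columns=["fragment_id", "stage", "its2_type", "clone_count"])
    meta = {"preset": "worked_microexample", "seed": 0,
            "incubation_hours": 24.0, "tracer_umol": 70.0,
            "tracer_atom_percent": 99.0, "ambient_dic_umol": 2000.0,
            "ct_limit": 40.0}
    return AssaySet(design=design, pam=pam, weights=weights, counts=counts,
                    census=census, qpcr=qpcr, isotopes=isotopes, clones=clones,
                    metadata=meta).validate()
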