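# Methods

## The experiment being modeled

Two holobionts of the same coral host — PdC (*Pocillopora damicornis*
with *Cladocopium* symbionts of metahaplotype C42-C1-C1b-C1c) and PdD
(the same host with *Durusdinium* D1-D4-D6) — are each represented by
three parental colonies cut into ~40 ramets and spread over six tanks,
three at 26 °C (control) and three at 32 °C (heat), for a 14-day stress
window.  Assays attach to ramet subsets the way a wet lab would allocate
them: 9 ramets per holobiont × arm are fate-tracked for daily PAM
fluorometry and weekly buoyant weights; 6 per arm are destructively
sampled at each of days 0/7/14 for hemocytometer counts, qPCR and clone
libraries (the same homogenate, so the same ramets); 6 labeled plus 3
unlabeled ramets per arm feed the day-14 ¹³C incubation.  All tables are
long CSVs keyed by a composite `holobiont-colony-tank-index` fragment id.

## Derived metrics

**Excitation pressure.**  Qm = 1 − (ΔF/Fm′)/(Fv/Fm) from
replicate-averaged dark and light yields.  Replicates are averaged at the
measurement level *before* the ratio (triplicate readings exist to
suppress instrument noise); Qm-then-mean would propagate the ratio's
nonlinearity into the replicate noise.  Negative Qm (light above dark
yield) is retained and flagged — truncation would bias group means
upward.  ΔQm subtracts the control-arm mean from the heated-arm mean per
holobiont; "overall" pooling averages each fragment over days 1–14 first
and combines the two arm standard errors in quadrature.  Both pooling
modes (overall, per-day) are exposed because the single printed ΔQm value
per holobiont does not pin down the window; pooled days 1–14 is the
default.

**Calcification.**  rate = (BW_f − BW_i)/A_initial × (1/days) × 100,
taken literally from the buoyant-weight formulation, so the unit is
(g · cm⁻² · d⁻¹) × 100; no aragonite-density conversion is applied.  The
day-0 area is used for every interval, which gives the exact additivity
rate(0→14) = (7·rate(0→7) + 7·rate(7→14))/14.

**Census.**  Areal density = mean chamber count / chamber volume ×
dilution × slurry volume / area.  The chamber volume defaults to the
Neubauer large-square 0.1 µL (1e-4 mL) and is configurable, since
counting rules differ.  The bleaching rate at a day is bleached /
(all remaining) × 100, where "remaining" excludes ramets destructively
sampled at *earlier* days; a ramet scored on its own sampling day still
counts.  Bleached status is absorbing (fate-tracking reports no
reversals).

**Isotopes.**  δ¹³C → atom% via R = R_VPDB(1 + δ/1000),
atom% = 100R/(1+R), R_VPDB = 0.0112372.  Uptake per tissue C per hour is
(a_s − a_n)/(a_DIC − a_n)/t, the classical tracer mixing form; a_n is the
tank-matched unlabeled control (holobiont-wide mean as fallback), and
a_DIC mixes the 70 µmol L⁻¹ 99-atom% spike into a configurable ambient
DIC pool (default 2000 µmol L⁻¹ at natural abundance — the ambient
concentration is not part of the assay record, so it is an analysis
parameter).  Samples not enriched above their natural baseline are
invalid and carry no value.  The per-hour basis is a unit choice
(incubations are 24 h); multiply by the incubation length for
per-incubation rates.

**Community.**  D/C = 2^−(CT_D−CT_C) with CT per primer the mean of
detected technical replicates.  A fully non-detect primer is substituted
with the detection-limit CT (default 40 cycles) and the ratio flagged
censored — necessary because a D/C of 10⁻⁷ places the rare-genus CT near
or past any plausible limit; no between-genus copy-number correction is
applied (a documented limitation: the ratio is a cell-ratio proxy).  The
shuffling index is 2·p_D − 1, the unique affine map of the Durusdinium
proportion onto [−1, +1] with −1 = pure *Cladocopium* and +1 = pure
*Durusdinium*.  Clone libraries pivot to a samples × ITS2-type count
matrix; for ordination the types are pooled into their metahaplotypes and
row-normalized, because individual libraries of 6–12 Sanger clones carry
multinomial noise of ~0.2–0.3 Bray–Curtis units at type level — at that
granularity no 90 %-similarity grouping could ever form, whereas the
metahaplotype profile is what the libraries actually resolve.  The
zero-adjusted Bray–Curtis appends a constant dummy column (value 1)
before computing the dissimilarity, keeping empty-vs-empty comparisons at
0 and the range inside [0, 1).  Bray–Curtis is not metric; triangle
violations are possible and are not asserted against.  NMDS minimizes
Kruskal stress-1 by isotonic-regression SMACOF (scikit-learn), best of 20
random starts under a fixed seed; grouping cuts a complete-linkage
dendrogram at dissimilarity 1 − similarity/100.

**Statistics.**  Shapiro–Wilk per group and Levene across groups route
each one-way comparison to ANOVA (with Tukey HSD only after a significant
omnibus) or Kruskal–Wallis; factorial designs use type-II ANOVA and
require a full cell grid.  The mixed-model screen is a Gaussian
identity-link MixedLM with variance components for tank and colony; the
family is configurable in principle but Gaussian is the default since all
screened traits are continuous.  Because profile confidence intervals for
variance components are not exposed, the "negligible random factor"
verdict is a variance share below 5 % of the total; boundary (singular)
fits are reported as such, not errors.  The trait PCA z-scores seven
trait means (Fv/Fm, ΔF/Fm′, density, calcification, carbon fixation,
carbon translocation, log₁₀ D/C) aggregated per holobiont × arm × tank —
the finest unit on which all seven coexist — before extracting two
components.

## The synthetic-data generator

The generator is first-class, tested code; its `paper_default` preset
*is* the study condition set.  Encoded effects (per holobiont × arm):

| parameter | PdC heat | PdC ctrl | PdD heat | PdD ctrl |
|---|---|---|---|---|
| Fv/Fm day-14 multiplier | 0.23 | 1 | 1 | 1 |
| Qm day-14 offset | 0.3173 | 0 | 0.0373 | 0 |
| density day-14 multiplier | 0.02 | 1 | 1 | 1 |
| calcification multipliers (d7, d14) | 0.60, 0.50 | 1, 1 | 1, 1 | 1, 1 |
| cumulative bleach prob (d7, d14) | 0.267, 0.833 | 0 | 0 | 0 |
| log₁₀ D/C (d0 → d14) | −7 → −4 | −7 → −6.8 | 6 → 6.3 | 6 → 5.2 |
| fixation rate (h⁻¹), translocation | 1e-4, 0.45 | 4e-4, 0.45 | 2e-4, 0.30 | 2e-4, 0.30 |

The Qm day-14 offsets are the pooled ΔQm targets (0.17, 0.02) divided by
the mean of a linear 0→1 ramp over days 1–14 (7.5/14), so the pooled
estimator recovers them exactly in expectation.  The control
calcification baselines are set 1.71:1 (PdC:PdD); PdD's density baseline
(2.5e6 cells cm⁻²) exceeds PdC's (1.5e6).  The control-PdD log₁₀ D/C
endpoint (−0.8 over 14 d) is sized so its decline is reliably detectable
at the design's replication (n = 6 × 3 days), matching the reported
significance of that drift; the control-PdC drift (+0.2) stays
non-significant at the same replication.

Mechanisms: PAM trajectories are piecewise-linear in day (the real data
show diurnal oscillation, but no functional form is available; linearity
keeps every estimator's expectation analytic), with a multiplicative
per-fragment effect shared by both phases — so fragment identity never
biases Qm — plus additive replicate noise (SD 0.02) truncated to [0, 1].
Bleaching is a per-fragment first-passage draw against the cumulative
probabilities, absorbing by construction, independent of which ramets are
destructively sampled.  Hemocytometer counts are Poisson draws whose
dilution is chosen adaptively to target ~50 cells per chamber, as a
counting protocol would.  qPCR CTs come from a latent per-fragment
log₁₀ D/C (fragment SD 0.30) through CT_genus = base − log₂(p_genus)
with replicate SD 0.15 cycles (typical instrument precision; not stated
by the source study); the base CT (14.5) puts the rare-genus CT just
inside the detection window at D/C = 10⁻⁷, so the censoring path is
exercised occasionally but does not dominate.  Labeled δ¹³C values are
back-computed through the same atom-percent bookkeeping the analysis
uses (fragment-level fixation CV 20 %, translocation SD 0.03,
measurement SD 0.3 ‰ — the stated IRMS reproducibility); the natural
baseline defaults to −15 ‰, a typical coral-tissue value, and is a
config knob.  Clone libraries draw 6–12 clones per sample multinomially
over the dominant genus's type frequencies only: the background genus
(≤ 10⁻⁴ relative abundance) is below the detection floor of libraries
this small, so its expected clone count rounds to zero — consistent with
the generator's dominance invariant (> 99 % in every sample) and with no
ITS2 types being shared between the two holobionts.  Random tank and
colony effects default to zero (the study reported none) but are
injectable for mixed-model calibration.

What the generator does **not** emulate: diurnal PAM oscillation shape,
mechanistic photophysiology (electron transport, ROS), symbiont
switching (acquisition of new genera), intra-genus type dynamics within
libraries, tank micro-environments, or fragment mortality other than
destructive sampling.  Passing recovery tests therefore demonstrates
estimator correctness under the encoded effect structure and realistic
noise, not fidelity to any particular real data set.

## Numerical and testing choices

Determinism: one `numpy` Generator seeded from the config with a fixed
draw order, so identical configs give byte-identical tables; NMDS uses a
seeded best-of-20 restart.  Degenerate inputs: zero Fv/Fm pairs are
excluded with a warning; both-primer non-detects are skipped; all-invalid
isotope groups are marked absent; constant-total uptake groups report no
slope.  Equality of AssaySets compares key-sorted tables within an
absolute tolerance (1e-9 after full-precision `%.17g` CSV round-trip).

Monte-Carlo tests compare ensemble means to encoded effects within 3
Monte-Carlo standard errors: 20 seeds for effect recovery, 50 for
bleaching rates, 200 null-preset datasets for type-I calibration (whole
suite ≈ 30 s on one CPU).  The acceptance script uses 100-seed ensembles
(50 for bleaching) — the fold-scale D/C change is the noisiest statistic
(~4 % relative SE at that size) — and derives child seeds from the
command-line seed via `SeedSequence`.

## Known limitations

* The ΔCT D/C ratio carries no rDNA copy-number correction; absolute
  proportions inherit that bias.
* The per-hour uptake unit is a convention; only ratios between groups
  are interpretation-safe.
* The Fig-style 90 %-similarity grouping is meaningful only on the
  metahaplotype-level relative matrix; type-level clone counts are too
  sparse for it.
* Mixed-model variance-share verdicts use a pragmatic 5 % threshold, not
  a profile-likelihood interval.
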