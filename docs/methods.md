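# Methods

## Problem and scope

`pulmoquant` quantifies pulmonary fibrosis in the mouse from retrospectively
gated micro-CT. Each subject scan consists of two independently reconstructed
3D volumes in Hounsfield units (HU) — end-inspiration (P01) and end-expiration
(P02) — with lung masks distinguishing the right lung (label 1) and the left
lung (label 2). The package computes densitometric parameters and biomarkers
per region (whole / left / right lung), runs the longitudinal three-arm group
analysis of a bleomycin treatment study, and correlates imaging with Ashcroft
histology. Lung segmentation itself is out of scope: the mask is taken as
authoritative.

## Densitometry

Per region and phase, with `N` the voxel count and `v` the voxel cell volume
(default (0.05 mm)³):

* lung volume `V = N · v`
* mean lung attenuation `MLA = Σ HU / N`
* air volume from inspiration `Air = V_P01 · MLA_P01 / (−1000 HU)` and
  functional residual capacity `FRC = V_P02 · MLA_P02 / (−1000 HU)`
* `Tissue = V_P02 − FRC`, tidal volume `TV = Air − FRC`,
  `%Gas_phase = 100 · air_volume / V` (algebraically `−MLA/10`)

Aeration compartments use the preclinical HU windows: normo-aerated
[−860, −435], hypo-aerated (−435, −121), non-aerated [−121, 121]. The bracket
notation is honored literally, so a voxel at exactly −435 HU is normo and one
at −121 HU is non. Voxels outside all three windows (hyper-aerated below −860,
dense above 121) form an explicit fourth class, `other`; the denominator of
every compartment percentage is the full region voxel count, so the four
percentages sum to 100 and the three conventional ones need not. Compartments
are reported from P02 by default (configurable to P01), since expiratory
densitometry is the conventional morphological readout.

Numerical choices: HU data are stored and round-tripped as float32; means are
accumulated in float64. Air and FRC can be negative when MLA > 0 (severe
consolidation); they are flagged, never clipped, so the conservation
identities `Tissue + FRC = V_P02` and `TV = Air − FRC` remain exact. HU values
outside [−1000, 3000] are retained (clamping would bias MLA) but counted and
logged. Histograms use half-open bins of default width 10 HU, last bin closed.
Anisotropic voxel headers are rejected unless explicitly accepted, in which
case the cell volume is the product of the three spacings.

## Synthetic phantom

The phantom generator provides exact ground truth in place of scan data. A
soft-tissue body ellipsoid (~40 HU) contains two ellipsoidal lobes; the left
lobe is scaled so that it holds a configurable fraction of total lung volume,
default 1/3 as in the mouse. Lung voxels are ranked by a lesion-propensity
score — a smooth Gaussian random field (smoothing length `min(shape)/12`
voxels, unit variance over the lung) plus an apical gradient
(`lesion_apical_bias`, default 1) and a left-lobe offset (`lesion_left_bias`,
default 0; 1 in the bleomycin arms) — and the top-scoring fraction becomes
non-aerated, the next hypo-aerated, then normo-aerated, any remainder
hyper-aerated. Realized class counts therefore match the requested fractions
to integer rounding, and ground truth is read from the assigned labels, not
re-estimated.

HU values are drawn per compartment from Gaussians truncated to the
compartment's own window (means −647.5 / −278 / 0 / −930 HU, sd 50 HU; a
0.5 HU margin keeps draws off the open hypo endpoints). Truncation makes the
ground-truth fractions exact by construction; an untruncated switch exists to
study boundary leakage, which at sd = 50 HU stays within ±2 percentage
points. With sd = 0 every voxel sits exactly at its compartment mean and all
biomarkers are recovered bit-exactly through the file round-trip.

Inspiration (P01) is derived from expiration (P02) by one binary dilation of
each lobe (recruited voxels get normo-aerated HU) and an `inspiration_air_gain`
(default 100 HU) subtracted from aerated voxels, floored at −1000 HU. This
guarantees a coherent subject with positive tidal volume; real gated
acquisitions reconstruct the phases independently, which the phantom does not
emulate. Other features deliberately not modelled: airway trees, cardiac
motion, reconstruction artifacts, vessels, and lesion shapes beyond the
smooth random field (lesion morphology is a free parameter, not fitted to
data). Passing tests therefore demonstrate correctness of the computational
pipeline on idealized anatomy, not segmentation robustness on real scans.

Cohorts follow the three-arm design (SAL n=4, BLM n=7, BLM+NINT n=12; days
7/14/21). Per-arm compartment trajectories default to the representative
percentages of the bleomycin study (SAL 81.4/18.6/0 constant; BLM
73.8/24.7/1.5 → 22.7/38.4/38.9; BLM+NINT 57.7/36.1/6.2 → 48.7/39.1/12.2;
day 14 is the midpoint). Total lung volume swells ×1.15 on day 7 in both
challenged arms (acute inflammation) and recedes to ×1.05 (BLM) / ×1.02
(BLM+NINT) by day 21. Subject-level random effects are log-normal: sd 0.15 on
the hypo/non target fractions (constant within subject across days) and
sd 0.05 on lung size. Each subject-day stream is seeded by hashing
(cohort seed, subject id, day), making regeneration order-independent.

## Group statistics

Biomarkers are normalized by the pooled SAL mean over all subjects and all
three days per (region, biomarker), so the normalized control mean is 1;
%Non is exempt and reported as an absolute percentage (it is ~0 in healthy
lungs and the pooled mean would be degenerate). Normalization is
scale-equivariant by construction.

The longitudinal analysis is an ordinary two-way ANOVA (group × day, day
categorical, no repeated-measures structure — per-subject values enter
directly). Within-group day-21 vs day-7 contrasts use the pooled residual
error of the fit and are Šidák-adjusted over the groups tested. Per-day
many-to-one contrasts against BLM use Dunnett's procedure via the
equicoordinate multivariate-t distribution (randomized-QMC integration with a
pinned rng for reproducibility); the adjusted p is floored at the analytic
per-comparison pooled-t p, which it dominates mathematically, to absorb
integration error at extreme statistics. Group summaries report mean ± SEM.
Missing design cells degrade to the available contrasts with a recorded
warning rather than aborting.

Percent inhibition/recovery at day 21 is `100 · (mean_NINT − mean_BLM) /
mean_BLM` — negative for parameters the treatment reduces (inhibition),
positive for parameters it restores (recovery). An alternative convention,
`100 · (NINT − BLM) / (SAL − BLM)` (fraction of the disease effect removed),
is available behind a flag.

Paired left-vs-right lobe comparisons test the per-subject differences for
normality (Shapiro–Wilk, α = 0.05): paired t when normal, Wilcoxon
signed-rank otherwise, with the test used reported. All-zero differences are
the degenerate "no difference" case (p = 1); nonzero constant differences are
flagged as zero-variance rather than assigned a p-value. At least 3 complete
pairs are required.

### Calibration checks and their problem sizes

Null calibration generates cohorts with no systematic left/right difference:
zero apical and zero left bias, so lesion placement is decided by the
stationary noise field alone. (An apical gradient is not a valid null here —
the lobes span different cranio-caudal extents, so it induces a geometric
left/right asymmetry.) The acceptance checks run 2500 such single-arm,
single-day cohorts (n = 7) at 32³; the paired-test rejection rate at α = 0.05
is required to sit in [0.03, 0.07]. Power/direction is checked on 100
default left-biased cohorts of the largest arm (BLM+NINT, n = 12, day 21) at
48³, requiring correct-sign rejection in ≥ 90% of seeds. The ground-truth
recovery check runs the full 23-subject × 3-day cohort at 64³. These sizes
are the package's default evaluation scales; phantoms are resolution-scaled
versions of the 512³ acquisitions the instrument produces.

## Histology

Ashcroft field scores (ordinal 0–8) are aggregated per lobe and for the whole
lung by pooling fields (the score is defined per field, so pooling — not
averaging of lobe means — is the natural whole-lung aggregate). Severity
classes: no/mild 0–3, moderate exactly 4, severe ≥ 5; class frequencies are
percentages of fields and always sum to 100. Imaging–histology association
uses Spearman rank correlation (average ranks on ties, two-sided p) between
each biomarker and the mean score across subjects at day 21; entries with
p ≥ 0.05 are masked in the reported table but retained in the raw output.

The synthetic score generator (used when no slide scores exist, always
labelled synthetic in its output) maps a lobe's ground-truth %Non through the
saturating curve `8 · x / (x + 12)` to an expected score and draws 12 integer
field scores per lobe from a rounded, clipped normal (sd 1.2) around it. The
half-saturation constant 12 places a %Non of ~39 (severe disease) near score
6 and leaves healthy lungs at 0; it is a documented choice, not a fit.

## Orchestration and reproducibility

`run_study` executes phantom generation (or manifest ingestion) →
biomarkers → group statistics → histology as one run described by a
serializable `RunConfig`. A config hash (excluding the output directory,
which cannot affect the numbers) heads every output table, and a run manifest
records config, hash, seed and outputs. Equal configs and seeds produce
byte-identical tables. The `demo` subcommand runs the full default cohort at
32³ end to end in a few seconds.

## Known limitations

* The phantom's ellipsoidal anatomy and truncated-Gaussian HU model make
  ground truth exact but understate real-scan difficulty (partial volume,
  vessels, motion, segmentation error).
* The paired-test power guarantee is stated for the n = 12 arm; at n = 7 with
  severe day-21 disease, saturation of the left lobe interacts with the
  subject-level %Non random effect and power sits near, not safely above,
  0.90.
* The ANOVA ignores the within-subject correlation across days; with the
  small arm sizes of this design a repeated-measures or mixed model would
  need structure the study table does not demand.
* Ashcroft scores are ordinal; means and normal-theory comparisons on them
  follow field convention rather than strict measurement theory.
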