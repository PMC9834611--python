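# Methods

## Model structure

`vinpbpk` implements a whole-body physiologically based pharmacokinetic
(PBPK) model of vinblastine with nine tissue regions: a central well-mixed
blood pool, lung, bone marrow, kidney, liver, gut, slowly perfused and
rapidly perfused lumps, and a brain compartment split into tissue (97% of
brain volume) and vascular (3%) sub-volumes. All tissue densities are taken
as 1 kg/L, so a tissue's volume in litres equals its weight in kilograms.

Every tissue except the brain is flow-limited (well-stirred): the venous
concentration leaving tissue T is the free concentration `CVT` obtained from
the saturable tubulin-binding relation

    CT = CVT * (PC_T + BC_T / (KD + CVT))

where `CT` is the total tissue concentration (nM), `PC_T` the
tissue-to-plasma partition coefficient, `BC_T` the tissue tubulin binding
capacity (nmol/kg, numerically nM at unit density) and `KD` the
vinblastine-tubulin dissociation constant (196.08 nM). The unique
non-negative root of the equivalent quadratic

    PC x^2 + (PC*KD + BC - CT) x - CT*KD = 0

is evaluated in closed form with the cancellation-safe branch
(`2*CT*KD / (b + sqrt(b^2 + 4*PC*CT*KD))` when `b >= 0`), verified against a
fixed-point iteration oracle to 1e-8 relative over nine decades of
concentration. This nonlinearity is the model's central mechanism: at the
micromolar free concentrations reached in the first minutes after a bolus
the binding sites saturate, and as concentrations fall the apparent tissue
partition rises toward `PC + BC/KD`, producing the long tissue retention
characteristic of vinca alkaloids.

The blood-brain barrier is permeability-limited. The brain vascular
sub-volume exchanges with arterial blood by flow (`QCNS`), and with brain
tissue through a permeability-surface-area product (`PSA`, default
0.379 ml/h, the value calibrated to Mdr1a/b(-/-) mouse brain data; the
companion text value 0.376 is accepted via configuration). ABCB1
(P-glycoprotein) pumps free brain-tissue drug back to the vascular space
with Michaelis-Menten kinetics (`sf_CNS * V_CNS * Vmax_ABCB1 * C/(Km + C)`).
Gut and kidney carry the same saturable efflux scaled by relative ABCB1
expression (gut 0.14, kidney 0.78), routed to the feces and urine sinks
respectively (intestinal secretion, tubular secretion). The liver's ABCB1
efflux is the biliary route and is represented once, by the biliary
clearance term, scaled by the hepatic expression factor 0.28 in wild-type,
dog and human parameter sets; the Mdr1a/b(-/-) scenario replaces it with
the knockout biliary kinetics (Vmax 23.35 nmol/L/h, Km 0.0152 pmol/L as
printed, i.e. effectively concentration-independent transport attributed to
Mrp2/Abcc2) and zeroes `Vmax_ABCB1` everywhere.

Elimination comprises saturable hepatic metabolism
(`V_LIV * Vmax_met * C/(Km_met + C)`), saturable biliary transport, and
glomerular filtration (`GFR_fraction * Q_kidney * CA`, GFR fraction 0.11).
By default all three are driven by the central blood concentration and
drawn from the blood pool. This was a genuinely open design point: the
mass-balance equations can also be read with the hepatic terms driven by
the liver venous free concentration and drawn from the liver compartment
(`elimination_driving="liver_free"` implements that reading). We made
blood-driving the default because the liver receives only 2-4.6% of cardiac
output in the parameter tables, so liver-supply-limited metabolism caps
whole-body clearance an order of magnitude below what the published
simulated serum exposures require, whereas blood-driven elimination
reproduces them; the filtration equation is unambiguously blood-driven.

The lung is not assigned weight/flow fractions in the physiology table but
has a tubulin binding capacity, so it rides the central blood path: a
flow-limited compartment carrying total cardiac output with PC 1.0, its
volume (reference values: 0.73/0.89/0.76 %BW for mouse/dog/human) carved
out of the rapidly perfused lump so total tissue volume never exceeds body
weight. `include_lung=False` removes it. Partition coefficients are printed
only for gut, kidney, liver, bone marrow, CNS and blood; lung and the
perfusion lumps default to PC 1.0.

## Parameters and units

Internal units are nmol, litres, hours, nM. Doses in mg/kg are converted
with the vinblastine free-base molecular weight 811.0 g/mol. Canine per-BSA
doses use `BSA = 0.101 * BW^(2/3)` m^2. Cardiac output defaults to the
allometric relationship `QC = 14.1 * BW^0.75` L/h (0.235 L/min/kg^0.75),
which gives 0.89 L/h for a 25 g mouse, 158 L/h for a 25 kg dog and 341 L/h
for a 70 kg human — all mid-physiologic; both the (coefficient, exponent)
pair and a direct per-species cardiac output are configurable. Default body
weights are 0.025 kg (mouse, not printed in the source tables), 25 kg
(dog) and 70 kg (human); study-specific weights (43 and 59 kg) are used for
the human study presets. Hematocrit and plasma protein binding are stored
for provenance but do not enter the fluxes (serum is equated with the blood
pool, PC_blood = 1); an optional free-fraction multiplier `fu` (default 1)
can scale the PSA, metabolic and filtration driving concentrations.

## Numerics

The bolus is an initial condition in the blood pool, not an impulse
forcing. The system is stiff immediately post-bolus (binding saturation
relaxes on a seconds scale in the mouse), so integration uses LSODA with
rtol 1e-8 and atol 1e-10 nmol. Output defaults to a log-spaced grid
(first point ~0.4 s) so that linear-log trapezoidal AUCs are grid-
insensitive: refining from 100 to 1000 output points changes AUCs by less
than 0.1%. Mass balance (compartments + cumulative sinks vs dose) holds to
machine precision and is asserted at 0.1% in tests. Free-concentration
root-finding clamps exactly to zero at zero tissue concentration.

## Noncompartmental analysis

AUC uses the linear-log trapezoidal rule: log trapezoid
`(C1-C2)*dt/ln(C1/C2)` on declining positive segments (exact for
mono-exponential decay), linear trapezoid on flat/rising segments or where
an endpoint is zero. Interval endpoints falling between samples are
interpolated consistently with the segment rule (log-linear inside a
declining segment), which makes AUC exactly additive over adjacent
intervals. Terminal half-life is ordinary least squares of ln C on t over
the last `min_points` (default 3) positive samples after the observed
maximum; a non-negative slope yields an undefined result with the reason
"terminal phase not achieved" (the knockout brain behaves this way), never
an exception. An adaptive best-r^2 window and extrapolation to infinity
(`+ C_last/k`) are optional.

A protocol point that matters for reproducing published values: reported
simulated NCA quantities are evaluated on the originating study's
observation schedule (mouse: 0.083-6 h destructive design; dog: 5 min-24 h
clinical draws; human: a standard sparse 0.083-24 h schedule), with AUC
accumulated from the first scheduled sample. An IV bolus into the mouse's
~1.2 ml blood pool produces a ~50 uM central spike that decays within
seconds; a measured profile whose first sample is at 5 minutes cannot
contain it, and including it (dense-grid AUC from t=0) inflates the mouse
serum AUC by ~70% relative to the like-for-like value. The human study
sampling horizons are not recorded in our sources; we evaluate both human
presets over 0-24 h, matching the canine definition.

## Calibration

`fit_model` wraps bounded trust-region nonlinear least squares
(`scipy.optimize.least_squares`) around the simulator; free parameters are
addressed by dotted paths (e.g. `drug.PC.kidney`), and pooled residuals are
computed on the log scale by default because tissue concentrations span
more than two orders of magnitude (a linear-scale option with 1/y and
1/y^2 weighting is retained). Model variants are compared by
`AIC = n ln(SSR/n) + 2k` and `BIC = n ln(SSR/n) + k ln(n)` on the same
residuals. Microsomal Michaelis-Menten fits flag non-identifiable designs
(substrate range far below the fitted Km). IVIVE scaling converts a
microsomal velocity (ng/ml/min at a stated protein concentration) to a
liver-volume-referenced Vmax via mg microsomal protein per g liver
(46 mouse, 55 dog) and the molecular weight.

Seeded recovery studies define the calibration acceptance surface: fitting
synthetic noisy data generated at the published values recovers PC_kidney
(3.73) within 15% at 6 times x 3 replicates with 5% noise, PSA (0.379
ml/h) within 25%, and the ABCB1 pair (928.8 nmol/L/h, 6.41 nmol/L) within
two-fold at the mouse sampling density with 15% noise.

## Monte Carlo virtual populations

Virtual subjects draw selected parameters from lognormal distributions with
median at the base value and log-SD 0.2 (per-parameter overrides allowed).
The default varied set is body weight, the cardiac-output coefficient, the
five calibrated partition coefficients, Vmax_met, Km_met, Vmax_ABCB1 and
PSA — the sources describe varying "physiologic and biochemical parameters"
without an explicit list, so this set is an explicit, editable stand-in.
Rank correlation is imposed by Iman-Conover rank reordering against a
correlated multivariate-normal reference; the default correlation is the
identity, and non-positive-semidefinite matrices are rejected with a
nearest-PSD suggestion. Populations are summarized by pointwise
min/max/mean/SD envelopes and per-subject NCA; per-subject doses are
mg/kg x the subject's sampled body weight. All sampling is reproducible
from a single integer seed.

## Synthetic data generator

The fixtures module emulates the structure of the validation datasets:
destructive mouse sampling (three independent animals per time point, six
times over 0.083-6 h), longitudinal clinical schedules for dog and human,
and technical-doublet microsomal velocity tables. Noise is multiplicative
lognormal (default CV 0.15 for tissues, 0.10 for serum, consistent with
typical bioanalytical accuracy bounds), mean-unbiased by construction;
values below an LLOQ-like floor (1 ng/ml ~ 1.23 nM) are flagged as
censored but retained so LLOQ policies can be exercised downstream. The
generator captures sampling structure and assay noise only — it does not
emulate between-animal physiologic variability, enterohepatic
recirculation, metabolite interference or chromatographic artifacts, so
passing recovery tests demonstrate estimator correctness under the stated
noise model, not robustness to structural model error in real data.

## Reproduction status and known limitations

With the shipped defaults the package reproduces, on the study-schedule NCA
protocol: mouse wild-type serum AUC(0-6h) within ~5%, knockout serum AUC
within ~3%, wild-type brain AUC within ~6%, the ~10-fold knockout/wild-type
brain exposure contrast, the canine Monte Carlo mean AUC(0-24h) within
~26%, and the human terminal half-life within ~5-10%.

Four published values are not reproduced by the printed parameter set under
any equation reading we could construct, and the corresponding checks are
intentionally left failing rather than fitted: (1) the mouse serum terminal
half-life (published 2.09 h vs ~0.8-1.0 h here) — the slowest washout pool
the printed volumes/flows admit is the liver, with a time constant near
1.5 h, and the published AUC/half-life pair jointly implies a mouse
distribution volume of ~0.9 L, 36x the animal's volume; (2) the knockout
brain AUC overshoot (+28%), a knock-on of the faster serum decline
(front-loaded exposure raises time-integrated brain uptake at matched serum
AUC); (3) the mouse kidney (and gut, bone marrow) AUCs, whose published
tissue:serum ratios (~60 for kidney) exceed the flow-limited-equilibrium
ceiling `PC + BC/KD` (~11) by ~5x; (4) the human mean AUCs, which at the
shared dog/human clearance parameters imply either ~2.5x the canine
clearance per liver volume or an AUC horizon of ~6-8 h rather than the
24 h used here. The canine mean terminal half-life (published 10.15 h)
comes out ~30% low for the same clearance-parameter reasons.

Not modeled: the 4-deacetylvinblastine metabolite, enterohepatic
recirculation, oral absorption, multi-dose regimens, hematocrit
partitioning, and covariate (age/sex/organ-function) models.

## Problem sizes

Default runs use 300-400 log-spaced output points per simulation and
100-subject virtual populations; recovery tests use 150-point grids with
the 18-point mouse destructive design. A single mouse simulation takes
~1 s and a 100-subject canine population ~20 s on one core.
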