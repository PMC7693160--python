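# Methods

This note documents the models implemented in `flupbpk`, their default
parameterization, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## Solubility models

Flurbiprofen is a monoprotic weak acid (MW 244.3 g/mol, pKa 4.05,
logP 3.99). Total aqueous solubility is the Henderson-Hasselbalch sum of
neutral and ionized species, S(pH) = S₀·(1 + 10^(pH−pKa)) with
S₀ = 18.1 µg/mL fixed to the minimum measured buffer solubility. (The
frequently printed form S_i = S₀·10^(pH−pKa) is the ionized contribution
alone; equilibrium measurements report the total, and the fit treats them
as such.)

In bile-salt media the total is the four-term sum

    S_tot = BS·S₀/C_H2O·K_neutral + S₀ + BS·S_i/C_H2O·K_ion + S_i

evaluated in mol/L with C_H2O = 55.5 mol/L (pure-water molarity) and
converted back to µg/mL. Because the micellar terms are mole-fraction-like,
a single molar basis is required for the partition coefficients to be
meaningful; the shipped defaults are logK_m:w = 5.36 (neutral) and 2.56
(ionized).

**Fitting.** Both fits minimize the squared-residual sum weighted by the
reciprocal of the predicted value with a Nelder-Mead simplex (deterministic
multi-start for the two-parameter micellar fit); predictions are formed via
clipped log-ratios so high-pH evaluations cannot overflow. Confidence
intervals use a 1000-replicate relative-residual bootstrap with a fixed
seed. Identifiability caveat: at 3 mM bile salt the ionized micellar term
is <1% of total solubility for logK_m:w,ion ≲ 2.5, so that coefficient is
intrinsically poorly determined — fits warn when no micellar excess is
present, and its CI should be expected to be wide.

## Dissolution (in vitro)

Spherical-particle dissolution follows the diffusion layer model per size
bin; the boundary-layer thickness defaults to h_eff = min(a, 30 µm) (the
standard thin-film rule; a Ranz-Marshall Sherwood-number mode is available
in `boundary_layer_thickness`). The lumped scalar S_DLM absorbs all
hydrodynamic and wetting effects, so fitted values are conditional on both
the h_eff model and the assumed particle size distribution — transplanting
an S_DLM between tools or PSDs changes its meaning.

The surface pH of the dissolving acid is obtained from a quasi-equilibrium
interfacial flux balance: the acid anion leaving the saturated surface is
balanced by protons diffusing out plus hydroxide and buffer base diffusing
in (diffusivities 9.3×10⁻⁵, 5.3×10⁻⁵, 8×10⁻⁶ cm²/s for H⁺, OH⁻, buffer),
solved by bracketing root-finding to machine tolerance. S_surface is the
total solubility evaluated at the surface pH with the medium's bile salt.
The correction matters most in weakly buffered media (FaSSIF V3 Level I,
buffer capacity 5.6 mmol/L/ΔpH) and is negligible in 50 mM compendial
phosphate.

Experiments are integrated piecewise between sampling/stage events
(LSODA): stage switches add the new medium volume and swap the medium
(the two-stage pH shift is applied instantaneously at the measured final
pH rather than titrating NaOH as chemistry); each sampling removes 5 mL of
bulk solution and the withdrawn mass is added back when percent dissolved
is reported. First-order disintegration (rate k_d after lag T_lag) gates
the release of solid from an undisintegrated reservoir in one-stage mode;
in serial-dilution (two-stage) mode the gate is off, since gastric-stage
dissolution already represents the disintegrated state. Particles released
after disintegration adopt the bin's current radius state — an
approximation that slightly accelerates late-released particles; it is
mass-conserving and below fitting noise for the k_d range of interest.
Time is carried in hours internally and reported in minutes.

S_DLM fitting uses equally weighted least squares (Nelder-Mead in log10
parameter space), reports R² and optional bootstrap CIs.

## Oral absorption

The fasted gut is nine well-mixed segments with first-order transit:
stomach 0.25 h (gastric emptying), small intestine partitioned
0.26/0.90/0.70/0.55/0.40/0.30/0.19 h (total ≈3.3 h), colon 12 h. Default
segmental pH rises 1.5 → 6.0–7.4 → 6.8 (colon), bile salts fall
0.08 mM (stomach) → 3.5–0.8 mM (SI) → 0 (colon), fluid volumes total
≈220 mL. Dissolution in each segment uses the same DLM against the bulk
segmental solubility (pH + bile salt); no surface-pH correction is applied
in vivo, where the correction's in-vitro rationale (fixed bulk pH, defined
buffer) does not transfer cleanly and the intestinal S_DLM already embeds
the in-vitro surface-pH treatment used during fitting. Dissolved drug
permeates at k_a = 2·P_eff/r per segment (cylindrical surface-to-volume),
stomach excluded, colon de-rated by an absorptive-area scalar of 0.2.
Oral solutions start fully dissolved in the stomach.

**Particle size.** The default formulation is a 5-bin lognormal PSD with
volume-median radius 7 µm and geometric SD 2.0. The median was chosen so
that, with h_eff = min(a, 30 µm), the fitted dissolution scalars map onto
their observed intestinal release times (S_DLM = 0.125 ↔ ≈85% in minutes;
S_DLM = 0.0018 ↔ ≈85% in about an hour at jejunal solubility); the
polydispersity represents milled drug substance. This coupling is the
reason S_DLM values must never be reinterpreted under a different PSD.
With a monodisperse 15–25 µm assumption the same scalars would predict
release times tens of times longer than measured.

**Radius bookkeeping.** Each size bin carries one shared squared-radius
state advanced at the solid-mass-weighted mean shrink rate across
segments (particles in transit are not tracked individually). The
per-mass dissolution coefficient is smoothly capped at 50 h⁻¹ — on the
minutes timescale this is "instantaneous" while keeping the a→0
singularity integrable — and the saturation driving force (S−C) is
ε-smoothed (ε = 10⁻³·S) so the solver does not chatter at the saturation
fixed point. Mass balance (absorbed + luminal + fecal = dose) holds to
better than 10⁻⁶ relative in the test suite.

## Whole-body PBPK

Thirteen flow-limited tissues plus venous/arterial blood with the lung in
series; reference physiology is a 70 kg adult male (plasma 3.1 L, cardiac
output ≈321 L/h, liver 1.65 kg with 21.6 + 64.9 L/h arterial/portal
inflow). Tissue:plasma partitioning uses the Rodgers-Rowland
composition-based method for acids,

    Kpu = f_EW + (X/Y)·f_IW + (P·f_NL + (0.3P+0.7)·f_NP)/Y
          + Ka_alb·AR·f_EW,

with intracellular pH 7.0, plasma pH 7.4, the vegetable-oil logP scale for
adipose neutral lipid, and the albumin association constant back-computed
from plasma fu = 0.01. Albumin is treated as confined to extracellular
water (tissue albumin = plasma ratio AR × f_EW); with whole-tissue AR
values instead, the predicted V_ss for this very highly bound acid rises
from 0.063 to 0.124 L/kg, far above the ≈0.07–0.1 L/kg range established
for flurbiprofen, which is the empirical basis for the extracellular
restriction. The empirical Kp scalar 0.7 multiplies all tissue Kp during
simulation only; reported Method-2 V_ss is pre-scalar. With B:P = 0.55 and
hematocrit 0.45 the erythrocyte partition is zero.

**Clearance.** Hepatic elimination is well-stirred: CL_h =
Q_li·fu_B·CLint/(Q_li + fu_B·CLint) with fu_B = fu/(B:P). CLint sums
CYP2C9 (ISEF 0.3 × V_max/(K_m+Cu) × abundance, recombinant-enzyme units),
UGT2B7 + UGT1A9 (per mg microsomal protein, ISEF 1), and an unassigned
microsomal pathway (7.88 µL/min/mg), all scaled by MPPGL 40 mg/g × liver
weight. Michaelis-Menten saturation is retained (clinically negligible at
≤300 mg: unbound liver concentrations stay ≪ K_m). Renal clearance
(0.066 L/h) acts on total plasma concentration, consistent with the ≈5%
urinary share of total elimination; an unbound-referenced interpretation
would make it a 0.05% pathway and was rejected on that ground.
Genotypes: heterozygotes use one lumped enzyme with the wild-type K_m and
V_max scaled by the clinically observed clearance ratios (0.73, 0.605);
2\*/2\* and 3\*/3\* use their measured recombinant kinetics; 2\*/3\*
(unmeasured) lumps the homozygote means.

**CYP2C9 abundance calibration.** The hepatic abundance default
(54 pmol/mg) is the value at which the published pair {additional
microsomal CLint = 7.88 µL/min/mg ⇔ f_m,CYP2C9 = 0.71} is self-consistent
under this reference physiology — i.e. the same retrograde calculation the
source workflow performs, run once against this package's system
parameters. It sits inside the published human range (≈30–100 pmol/mg).
`retrograde_clint` exposes the calculation for any target f_m.

**Numerics.** LSODA with rtol 10⁻⁶ / atol 10⁻⁹ by default (rtol 10⁻⁵ for
100-subject population runs; the two agree to four significant figures on
every reported metric). Output on a 1-minute grid; AUC by trapezoid with
λ_z log-linear extrapolation from the terminal points; whole-body mass
balance is checked on every simulation.

## Interactions

Perpetrator exposure is an exact closed-form one-compartment superposition
(fluconazole defaults: CL/F 0.77 L/h, V/F 49 L, k_a 1.5 h⁻¹, fu 0.89,
MW 306.3). In dynamic mode the unbound hepatic-inlet concentration
(systemic plus k_a·A_gut/Q_portal absorption term) drives competitive
inhibition 1/(1+I_u/K_i) of CYP2C9 CLint, tabulated once per scenario and
interpolated inside the ODE; static mode uses the window-average unbound
concentration. K_i values are study-context-specific inputs (11/17/23 µM
by genotype for the 50 mg studies; 14.3, 20.3, 29.9, 10 µM elsewhere).
Rifampicin induction is a steady-state fold on CYP2C9 V_max reached with
an enzyme-turnover half-life of 36 h; the default fold 1.83 was fixed once
from the closed-form linear relation AUC-ratio = 1/(1−f_m+f_m·F) at the
predicted induction AUC ratio 0.63 with f_m = 0.71, because no induction
parameters are published for the library compound. DDI ratios are
AUC_last (to the common last time) and Cmax with/without perpetrator on
matched grids.

## Pharmacodynamics

dCe/dt = k_eo(Cp − Ce) links total plasma concentration to the effect
site (exact piecewise update for linearly interpolated Cp — no additional
discretization error). Response is inhibitory E_max with E_max fixed at 1
(full suppression attainable; only IC₅₀ and k_eo are published) and
baseline 100%: TPEP endpoint k_eo 0.56 h⁻¹ (43% CV), IC₅₀ 25.8 mg/L
(21% CV); pain-rating 0.89 h⁻¹ (24%), 27.6 mg/L (10%). AUCE is defined as
the area between baseline and response over 0–24 h (the operational
definition is not standardized; both the window and the
baseline-deficit-vs-under-curve choice are arguments to `pd_metrics`, and
genotype AUCE ratios move by several percent under alternatives).
T_80%initial is the first return above 80% of baseline after the response
nadir, 0 with a flag if the response never drops that far.

## Virtual populations and synthetic data

Subjects draw weight/age uniformly within study ranges (organ volumes,
flows, blood/liver mass scale linearly with weight), CYP2C9 genotype
multinomially (Caucasian 0.65/0.20/0.10/0.025/0.02/0.005 for
1\*/1\* … 3\*/3\*; Chinese 0.975/0/0.0249/0/0/0.0001), and log-normal
variability: 30% CV on CYP2C9 abundance, 15% on volumes/flows/GI transit,
25% on luminal bile salts, 0.2-pH-unit jitter truncated to physiological
bounds. Each subject owns an RNG stream spawned as (master seed, index),
so populations are bit-reproducible and stable under resizing. Korean
study designs are simulated with the Chinese frequency table (closest
available population).

The synthetic generators produce (a) noisy percent-dissolved curves
(multiplicative Gaussian, clipped to [0,100]), (b) per-subject plasma
profiles with proportional residual error, (c) response-time profiles —
the fixtures for the fitting and evaluation machinery. They emulate
sampling noise and between-subject variability but **not** the features
that make real flurbiprofen data hard: double-peak absorption profiles,
food effects, enantiomer-specific disposition, assay LLOQ censoring, or
model misspecification. Green parameter-recovery and evaluation tests
therefore demonstrate internal consistency of the workflow, not fidelity
to any particular clinical dataset.

## Known limitations

- Single effective permeability for all segments; no gut-wall metabolism
  (fraction escaping gut metabolism = 1), no transporters, no
  enterohepatic recycling, no fed state, no modified-release forms.
- Linear-kinetics consequence: between the fastest and slowest intestinal
  dissolution scalars the model reproduces the ≈20% Cmax decrease and the
  ≈30–45 min tmax shift, but AUC_inf falls only ≈1–2% because absorption
  remains ≈99% complete — an AUC decrease of ≈20% is arithmetically
  incompatible with near-complete absorption in a linear model, and the
  package makes that explicit rather than reproducing it.
- Racemate treated as one species (the enantiomers differ clinically);
  the 4-OH metabolite is not tracked.
- Tissue-composition and population system parameters are published
  literature values, not any proprietary database; absolute exposure
  predictions (e.g. Cmax ≈ 18 mg/L for 100 mg at the reference subject)
  run ≈20–40% above typical observed means, while clearance ratios,
  interaction ratios and genotype contrasts — the quantities the workflow
  is designed around — are insensitive to that scale.
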