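# Methods

## Model structure

The model describes an isolated cardiac mitochondrion suspended in a
well-stirred buffer. Three compartments are resolved: the matrix, the
intermembrane space (IMS), and the extra-mitochondrial buffer. Matrix and
IMS species are integrated as amounts (nmol per mg protein) because both
water volumes are dynamic; buffer species are molar concentrations whose
rates scale with the mitochondrial load (mg protein per mL). The outer
membrane is modeled as freely permeable: every IMS metabolite and cation
relaxes to its buffer counterpart with a first-order permeation constant
(k_OM = 150 µL/min/mg, relaxation time below a second), and chelators
(EGTA/EDTA) are present at equal totals on both sides.

The 73 states decompose as 65 ODEs (25 matrix: 20 metabolites + the five
cation contents H⁺, K⁺, Na⁺, Mg²⁺, Ca²⁺; 20 IMS: 15 metabolites + 5
cations; 19 buffer: 15 metabolites + 4 cations, buffer pH being clamped;
and ΔΨ), five conservation-derived species (matrix ATP, GTP, NADH,
ubiquinol, reduced cytochrome c, each pool total minus the free partner),
and three algebraic states:

* **V_mtx** solves the osmotic balance: total osmotically active matrix
  content (metabolites, nucleotide/cofactor pool totals, cations, Cl⁻ and
  an impermeant-osmolyte constant) divided by the buffer osmolarity. Ideal
  van't Hoff behaviour is assumed (osmotic coefficients of 1), so doubling
  buffer osmolarity at fixed content exactly halves the volume.
* **V_ims** is the fixed total mitochondrial water (2.6 µL/mg) minus
  V_mtx, so swelling of the matrix reciprocally shrinks the IMS.
* **Cl⁻_mtx** closes matrix electroneutrality: cation charge minus
  metabolite anion charge (nominal integer charges per species; pool
  members expressed through the conserved totals) minus a fixed impermeant
  charge. The impermeant osmolyte and charge constants are calibrated once
  so that a canonical condensed matrix at 290 mOsm sits at the reference
  volume of 0.65 µL/mg with ~15 mM Cl⁻.

This K⁺-salt/Cl⁻/osmotic chain is what converts electrophoretic K⁺ uptake
into swelling.

Matrix and IMS pH use a linear buffering-capacity mapping from a
titratable-proton content state (β_H = 22 mM per pH unit, anchored at
pH 7.2), rather than a full proton binding polynomial over all matrix
buffers; the IMS proton content additionally relaxes to the clamped buffer
pH through the outer-membrane term. The DAE is reduced to an ODE by
index-1 elimination (conservation, volumes, Cl⁻ evaluated inside the
right-hand side) and integrated with SciPy's stiff BDF method (LSODA and
Radau as fallbacks), default tolerances 10⁻³ relative with per-state
absolute tolerances, and stricter settings available for sensitivity work.

## Rate laws

All 34 fluxes are reversible and thermodynamically balanced: each is zero
exactly when its mass-action ratio — including explicit proton terms and
the n·F·ΔΨ work of any translocated charge — equals its apparent
equilibrium constant. Scalar matrix enzymes use a convenience-kinetics
backbone (substrate saturation numerator times a (1 − Q/K_eq) driving
factor) with the documented regulation: saturable free-Ca²⁺ activation of
the three dehydrogenases (PDH, IDH, αKGDH), proton and ATP/ADP control of
PDH, ADP activation of IDH/αKGDH, OAA inhibition of SDH, and the saturable
Pi-activation mechanisms of MDH and complex III. Proton stoichiometries of
the scalar reactions are derived from the nominal charge ledger, so every
reaction conserves charge by construction.

The electron-transport complexes use bilinear redox driving terms with
standard free energies referenced to 1 M H⁺ (so the proton concentrations
appear explicitly), charge stoichiometries of 4/2/4 per two electrons
(10 charges per NADH), and a symmetric kinetic voltage partition
exp(α n u) (α = 0.10) that slows turnover against a large potential
without moving the equilibrium point. The F₁F₀ synthase translocates
n = 8/3 charges per ATP and saturates through a driving-term denominator,
reversing to ATP hydrolysis when the proton-motive force cannot support
the matrix phosphorylation potential. The ANT exchanges free (unchelated)
ATP⁴⁻/ADP³⁻ with the potential partitioned between the export and import
translocation steps (θ = 0.5) and modulating the ATP site occupancies,
which keeps |J| ≤ V_max. The Ca²⁺ uniporter is a GHK-type flux (z = 2)
with competitive Mg²⁺ inhibition of the single Ca²⁺ site; the Na⁺/Ca²⁺
exchanger couples 3 Na⁺ per Ca²⁺ with a matrix-Ca²⁺ activation mechanism;
the Na⁺/H⁺ exchanger carries a second-order proton regulation. K⁺
electrodiffusion (leak and the MgATP-inhibited mKATP channel, with MgADP
antagonism and an endogenous-inhibition coupling zeroed by diazoxide) uses
a symmetric Eyring barrier; the K⁺/H⁺ exchanger is activated linearly by
swelling above the resting volume (stretch activation), which is the
mechanism that makes it an effective volume controller. A protocol-scoped
high-activity variant replaces it for the Pi-titration data set, rapidly
equilibrating [K⁺]ₓ[H⁺]ᵢ/[K⁺]ᵢ[H⁺]ₓ.

Pharmacology is parameter surgery: oligomycin zeroes the F₁F₀ activity,
diazoxide zeroes the endogenous mKATP inhibition coupling, 5-HD zeroes the
mKATP conductance.

## Parameters and provenance

The shipped parameter file carries one record per constant with units and
a provenance tier: tier 3 is the 42-member whole-model adjustable set
(the tabulated values, at the 25 °C reference); tier 1 constants come from
kinetic literature; tier 2 marks structural constants of this
reconstruction. The functional forms follow the mechanism families these
processes are standardly modeled with (two-site electrogenic carrier for
the ANT, constant-field flux for the uniporter and leaks, hexa-uni
ping-pong-style product inhibition for the dehydrogenase chain) under
Haldane constraints, and a small number of tier-2 normalization constants (the ETS turnover scale, the pump voltage
partition α, the ANT potential split θ, the mKHE stretch-activation offset
and slope, the F₁F₀/PIC saturation scales) were calibrated so the model
reproduces the qualitatively and quantitatively described K⁺-cycle and
energization behaviour of the source experiments: minutes-scale swelling
to ~1.4/1.1/2.3 µL/mg under the ATP+oligomycin / ATP+ADP / no-ATP
conditions, an ATP-energized resting potential near −112 mV, and
Pi-monotone respiration. The tier-3 adjustable values were never
altered during this calibration.

Temperature corrections use the enzyme's activation energy (Arrhenius,
valid over 4–37 °C) where one is compiled, otherwise a standard Q₁₀ of
2.25; equilibrium constants are used at their 25 °C reference values.
Ion speciation solves the coupled binding-polynomial mass balances for
free K⁺, Na⁺, Mg²⁺ and Ca²⁺ (damped fixed point, 10⁻¹² relative
tolerance, bisection fallback), with a clamp mode that fixes a stated
free concentration (used for the 550 nM free-Ca²⁺ buffers) and implies
the corresponding total. Dissociation constants (25 °C, ionic strength
≈ 0.1 M) ship as a versioned table; no further ionic-strength activity
model is applied.

## Protocols and initialization

Each experiment replica standardizes its starting point from a canonical
condensed, fully oxidized, de-energized matrix composition. The
"equilibrated" initialization modes simulate the pre-incubation buffer to
a steady state (30 min cap; 6 min for the energized mode, matching the
minutes-scale pre-incubations — the true asymptote of an ATP-energized
suspension would be ATP exhaustion); "non-equilibrated" modes pre-incubate
for 30 s. The Pi-depletion pre-treatment of the titration protocol is
implemented as: initialize in the presence of ATP, empty the phosphate
pools, and re-equilibrate briefly (the source describes no exact
depletion recipe, so this surgery is versioned in the protocol file).
Interventions are applied as stop-modify-restart events rather than
discontinuous forcing. Steady-state detection requires the relative state
velocity to fall below 10⁻⁶ s⁻¹.

The five buffer recipes (compositions, clamped pH, temperature,
osmolarity, load) ship as versioned YAML files. Mitochondrial loads are
1, 3.5, 2, 0.1 and 0.1 mg/mL; the 3.5 mg/mL value reproduces the
load-inference arithmetic from the reported 1430 nmol/mg malate content,
and the osmolarity scan sets buffer [K⁺] to half the stated osmolarity
with adenylate kinase disabled (no divalent cation in that medium).
TPP⁺/TPMP⁺/DMO probes are tracer-level and not modeled.

## Calibration toolkit

The objective is the weighted least-squares form summed over data sets
with curve- and point-averaging: f = Σ_k (1/M_k) Σ_j (1/N_jk) Σ_i
((y−Y)/σ)²; missing standard deviations are imputed as a 7.5% relative
error (the midpoint of the 5–10% convention). Failed simulations score a
finite 10⁶ penalty so annealing can traverse pathological regions.

Local sensitivity coefficients are the absolute normalized first-order
responses |∂y/∂p · p/y| averaged over all 73 states, five equally spaced
time points and the replayed conditions, approximated by centered finite
differences with a 1% relative perturbation at tightened solver
tolerances; where |y| falls below the state's absolute tolerance the
normalization is floored there and the entry is flagged below-resolution.

Fitting is simulated annealing (log-normal single-parameter moves,
Metropolis acceptance, geometric cooling) followed by a Nelder–Mead
polish in log-parameter space, deterministic for a given seed and
serial by default.

## Synthetic data

The packaged synthetic curves are isolated pyruvate-dehydrogenase
titrations (rate versus pyruvate and versus NAD⁺) simulated from the
shipped parameters with 5% multiplicative Gaussian noise — the isolated
rate-curve setting used for tier-2 constants. They emulate assay-style
initial-rate data (saturating co-substrates, zero products, full
activation) and deliberately contain none of the whole-organelle
couplings (ΔΨ, volume, speciation), so parameter-recovery tests on them
demonstrate the estimator machinery, not identifiability of the full
model.

## Problem sizes and numerical choices

Default test and acceptance runs use desk-scale sizes chosen as the
smallest that reach the relevant plateaus: swelling runs of 15–20
simulated minutes (plateaus form within ~5), titrations of 2–4 phosphate
levels, two-minute Ca²⁺-loading runs, and sensitivity replays of 0.5–1
simulated minute of the heavy-load TCA protocol at 10⁻⁴ relative
tolerance. Concentrations are clipped at zero inside the right-hand side
to guard against solver overshoot; exponentials are capped well inside
floating-point range; the mKHE stretch activation is smoothed over
0.05 µL/mg around its offset so the right-hand side stays continuously
differentiable.

## Known limitations

* The rate-expression forms are reconstructions, so the tabulated activities do
  not pin down absolute respiration magnitudes; simulated
  MVO₂ runs several-fold low while all monotone trends (Pi control,
  Na⁺-dependence of matrix Ca²⁺, swelling order) are preserved. This
  depresses the computed Ca²⁺-cycle share of the ETS proton flux (~1.6%,
  where realistic respiration rates would give well under 1%) and the
  hexokinase sensitivity ranking.
* Rapid-mode Ca²⁺ uptake, Na⁺-independent Ca²⁺ efflux, β-oxidation,
  oxygen depletion and outer-membrane permeability regulation are outside
  scope, as in the source model.
* The tricarboxylate carrier is a passive exchange process and fumarate
  is not a dicarboxylate-carrier substrate, with the known consequences
  for citrate/isocitrate accumulation and malate oxidation.
* State-3 redox trends of the Pi titration (%NADH rising with Pi) are
  only partially reproduced; the simulated state-3 %NADH declines
  slightly with Pi. The steady α-ketoglutarate-versus-malate titration
  rises steeply from the malate-free baseline but is not monotone across
  the full malate range, and the osmolarity scan over-swells at high
  osmolarity (the K⁺ channel is fully de-inhibited in that
  nucleotide-free medium).
* Matrix pH rests on an effective buffering capacity, not a mechanistic
  buffer inventory; Cl⁻ is an electroneutrality closure with no carrier.
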