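# Methods

## Model equations

Each architecture is a compartment graph over a fish of total volume
`V = Σ V_i` (mL). For a tissue `i` with perfusion `Q_i` (mL/s) and
tissue:water partition coefficient `P_i`, exchange with blood is
flow-limited: the tissue receives its afferent blood at the upstream
effluent concentration and returns effluent at the locally equilibrated
concentration `C_i / P_i`,

    V_i dC_i/dt = Σ_in Q_e C_src/P_src  -  (Σ_out Q_e) C_i/P_i  -  sink_i(C_i) V_i.

Partitioning uses a linear lipid/water mixing rule, `P_i = f_lipid,i Kow +
f_water,i`, with the octanol–water ratio `Kow = 10^logKow` as the lipid
surrogate. Arterial and venous blood are pinned to `P = 1`: with no data to
characterise chemical binding to blood components, blood is assumed not to
accumulate chemical (the plasma-binding constant `kd_plasma` is carried on
`ChemicalDescriptor` but inert).

Sinks are first-order by default: hepatic metabolism `k_met C_liver` (in the
1C model, whole-body `k_met C`), and excretion `k_exc C_other` in the 6C
"other" tissue. Saturable metabolism replaces `k_met C` with
`vmax C / (km + C)`; in the regime `C << km` the two coincide, and the
simulated 7C dynamics under the two kinetics agree within 1% whenever
`km >= 100x` the peak concentration (asserted in the test-suite), which is
why the linear form — and with it the exact inversion — is the default.

### Gill exchange

The gills are an instantaneous-equilibrium interface, not a state variable.
Transfer is limited by both carriers — the water stream delivers at most
`Q_w` (mL/s) and the blood stream carries away at most `Q_c` — so the
exchange conductance is their series (harmonic) combination scaled by the
assimilation factor `AF` (7C only; `AF = 1` otherwise):

    G = AF / (1/Q_w + 1/Q_c),        net uptake = G (C_env - C_ven),

added to the arterial blood. The single-compartment fish has no explicit
blood, so `G = Q_w` referenced to the body's own effluent `C/P`. This form
guarantees three properties that a purely ventilation-referenced flux
violates when `Q_w > Q_c` (the usual situation in fish): uptake never
exceeds what the water delivers; post-gill (arterial) blood never overshoots
equilibrium with the water (`s_blood <= 1`); and steady-state concentrations
decrease monotonically as the metabolic rate increases. The assimilation
factor is applied symmetrically to uptake and elimination — it scales the
conductance, not one direction of the flux.

### Steady states and inversion

With first-order kinetics the system is `dC/dt = A C + b C_env`, assembled
exactly from the graph; all eigenvalues of `A` have negative real part. The
steady state is the linear solve `C_ss = -A^{-1} b C_env`, so each
compartment carries a dimensionless, exposure-independent response
coefficient `s_i = (-A^{-1} b)_i` and the whole-body coefficient is the
volume-weighted mean (blood included; blood has `P = 1`, so including it is
conservative). Exposure reconstruction inverts one scalar relation,
`PEC = C_obs / s_obs`. The inversion is computed from the same linear system
as the forward model rather than from transcribed closed forms — one code
path, no transcription errors — and the forward simulator serves as the
independent round-trip oracle in the tests (worst relative error ~1e-15
over 200 random chemical/observable/structure combinations).

Steady states can also be obtained by integration. Rather than judging
convergence visually from long time series, a trajectory is declared
converged at the first time the maximum relative change over a trailing
one-hour window drops below 1e-8, after which integration continues several
multiples of that detection time before the state is reported (the window
criterion alone can leave a few-1e-6 residual for the slowest systems).

### Numerics

Integration uses `scipy.integrate.solve_ivp`'s BDF method (stiff-capable,
implicit) at rtol 1e-8 / atol 1e-12, with the analytic Jacobian for
first-order kinetics and log-spaced output (200 points per decade by
default) so that half-lives spanning 1e2–1e6 s interpolate accurately.
Relaxation decays under first-order kinetics are propagated in closed form
through an eigendecomposition of `A` — exact for a linear system, so no
integration error accumulates over four decades of time — with crossing
times bracketed on a log grid and refined by `brentq` to 1e-12; the BDF
route remains available (`method="integrate"`) and the two agree to ~1e-3
relative in the tests. Saturable kinetics always integrate numerically.

## Relaxation protocol

Hold `c_env` until steady state (linear solve), step to `c_env (1+delta)`,
re-equilibrate (linear solve; both equilibrations are exact to avoid
compounding solver error), then step back and integrate the decay. The
half-life of an observable is the first time it falls halfway from the
perturbed to the baseline steady state. `delta = 0.10` by default —
"slightly increased" made concrete — and by linearity the first-order
half-life is delta-independent (verified within 0.5% for delta in
{0.05, 0.10, 0.20}). Relaxations that have not crossed by 1e8 s are
reported as censored, never silently truncated.

## Population variability

Body parameters (volumes, tissue flows, cardiac output, respiratory flow,
body mass) are drawn independently log-normally around the reference value
with geometric standard deviation `gsd`; the arithmetic mean of each draw
equals its base value (`mu_log = ln(base) - sigma^2/2`, `sigma = ln(gsd)`;
geometric mean-matching is available via config). Tissue flows are rescaled
after sampling so they sum to the drawn cardiac output, keeping every draw a
valid physiology. Chemical parameters never vary. The default
`gsd = sqrt(2)` keeps draws almost always within two-fold of the reference,
consistent with the modest population spread the ensemble time series are
meant to emulate. Sampling is seeded and bit-reproducible.

## Fixtures and synthetic data

The default physiologies describe a 0.65 g adult female zebrafish-scale
fish: `Q_c = 9.5e-4 mL/s`, `Q_w = 2.57e-3 mL/s` (ventilation ≈ 2.7×
perfusion), gill assimilation factor 0.8, gonads lipid-rich (f_lipid 0.10)
and poorly perfused (2% of cardiac output), muscle-dominated "poorly
perfused tissue" holding ~79% of body volume. Values not printed in the
primary literature are flagged `assumed` in the fixtures' provenance
column. The 6C "other" compartment is the exact volume-weighted merge of
the 7C richly+poorly perfused tissues, and the 1C body composition is the
exact volume-weighted whole-fish composition (blood as water); this makes
all three models agree exactly in the zero-clearance limit, so differences
between them isolate clearance handling and architecture rather than bulk
partitioning. Preset chemicals carry their literature log Kow values
(diazinon 3.81; 1,2-dichloroethane 1.48) and an assumed clearance
`k_met = 1e-4 /s`, the geometric midpoint of the grid scan range
`[1e-7, 1e-1] /s`, with `k_exc = 0` (clearance treated as hepatic).

The synthetic assay table emulates the *structure* of a high-throughput
estrogenicity screen joined to whole-organism effect data: 36 chemicals,
AC10s log-uniform over 1e-3..10 uM, log Kow uniform over 0.5..6.5, k_met
log-uniform over 1e-6..1e-3 /s, and LOECs tied to AC10s by
`loec = ac10 * 10^eta`, `eta ~ N(1, 1)` (LOECs scatter around ~10x the
AC10). It reproduces none of the real chemicals' identities or values, so
analyses built on it exercise the machinery and the qualitative
model-comparison logic, not the study's absolute numbers: passing tests
show the pipeline's internal consistency, not agreement with any measured
dataset.

## Point-of-departure rationale

For a logistic concentration-response in log-concentration, the tangent at
the inflection point (response 1/2, slope 1/4) meets the lower asymptote
two log-units below the midpoint, where the response is `1/(1+e^2) ≈ 0.119`
— about 12%, just above the 10% defining the AC10. This closed form is the
justification for treating AC10s as point-of-departure surrogates in the
IVIVE comparison.

## Statistics

Under-prediction counts (PEC < LOEC) are tested against a fair-coin null
with an exact two-sided binomial test by integer tail enumeration — no
normal approximation; ties count as not-below and are reported. Ratio
comparisons between models use log10(PEC/LOEC) with Welch's t-test by
default (the pooled test is available via config) and Gaussian kernel
density estimates with a Silverman-type bandwidth. Prediction-ratio grids
tabulate `log10(PEC_a/PEC_b)` over log10 k_met in [-7, -1] and log10 Kow in
[0, 8] (50×50) at a 10 uM whole-body concentration; by linearity the grid
is independent of that concentration (asserted to 1e-9).

## Structural-variant analysis

Collapsing the 6C gonads into "other" leaves the arterial, venous, brain
and liver response coefficients exactly unchanged *when the merged tissues
carry no sink*: a passive tissue's effluent equals the arterial
concentration regardless of its size or partitioning, so the merge is
invisible to the rest of the graph. With `k_exc > 0` the identity breaks,
because the venous-return coefficient `Q^2/(Q + k V P)` is not additive
under a merge; the default chemicals have `k_exc = 0`, so the invariance
holds to machine precision here.

Rewiring the gonads to drain through the liver sends their effluent through
a metabolising organ. The liver's own steady state rises (its inflow grows),
but the venous return strictly falls — `Q^2/(Q+kVP)` is strictly
subadditive in `Q` — so the arterial blood, brain and venous blood all
settle *below* the original model, for every positive parameter draw tested
(100/100). Consequently the rewired rTK *over*-estimates the exposure for
blood-side observables. The literature this analysis mirrors reports the
opposite direction (all four compartments higher, hence rTK
under-estimation); within the flow-limited, mass-conserving family of
models implemented here that direction is provably unattainable, and the
corresponding acceptance test is left failing rather than weakened. The
same cap on hepatic clearance — loss from the liver can never exceed its
perfusion-limited delivery, while non-metabolising tissues store chemical in
proportion to Kow — also means the multicompartment models always retain
more chemical per unit exposure than the 1C model (whose clearance acts on
the entire well-mixed burden). Both prediction-ratio grids are therefore
everywhere negative: the reported over-estimation pocket of the 7-compartment
model at jointly high k_met and Kow does not occur in this formulation, and
that assertion is likewise left failing by design.

## Known limitations

- Constant (or piecewise-constant) aqueous exposure only; no dietary or
  dermal routes, no growth or temperature scaling, no mixtures.
- The exact inversion requires first-order kinetics; saturable metabolism
  makes reconstruction non-unique and is supported for forward simulation
  only.
- Parameter values are plausible and internally consistent but partly
  assumed; absolute concentrations should be read as illustrative, while
  ratios, orderings and structural comparisons are the intended outputs.
- Population sampling is independent per parameter (no correlation
  structure) and there are no formal global sensitivity indices.
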