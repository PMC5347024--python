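# Methods

## Evolutionary dynamics

The tumor is a finite set of genotypes on an acquisition lattice: every
modeled clone carries the EGFR-L858R founder alteration, and each directed
edge adds exactly one further alteration (BRAF-V600E, EGFR-T790M, MET
amplification) at a per-day rate μ. Acquisition is irreversible, and the
graph is acyclic by construction. With a therapy *u* held constant, cell
counts follow the linear system dx/dt = A(u)x with

- A_ii = g_i(d_u) − Σ μ_out(i) — net growth minus mutational outflow,
- A_ji = μ_{i→j} for each edge i → j.

Columns of A sum to the growth rates, so mutation moves cells between
compartments without creating or destroying them; the off-diagonal entries
are nonnegative (Metzler), so nonnegative initial counts stay nonnegative.
Counts are continuous and deterministic — no branching-process noise and no
extinction cutoff (one can be imposed downstream by thresholding a
trajectory). Within a treatment segment the system is time-invariant, so the
simulator evaluates the exact closed form x(t) = e^{A(t−t₀)}x(t₀) at every
output time; negative floating-point dust (≲10⁻¹⁸ relative) is clipped to
zero. Death is not modeled separately: g is the *net* growth rate.

Units: days, micromolar, cells. Default initial population 5 000 cells
(the seeding density of a 96-well growth assay).

## Pharmacodynamics

Each (clone, environment, therapy) carries a four-parameter Hill curve on
the net growth rate as a function of the EGFR TKI concentration *d*:

    g(d) = g_min + (g₀ − g_min)/(1 + (d/EC50)^h),  g_min ≤ g₀, EC50 > 0, h > 0.

g₀ is the drug-free rate, g_min the saturating-TKI asymptote (negative =
net kill). The partner drug of a combination is dosed at a fixed panel
concentration, so its effect is absorbed into the per-therapy parameters
rather than modeled as a second dose axis — combinations are fitted (or
specified) per clone per combination. The HGF flag of the environment is
fixed for a whole simulation; MET-amplified genotypes are MET-activated in
either environment.

## Calibration

Two stages, each independently testable:

1. **Rates.** For one (clone, environment, therapy, dose) condition, the
   net rate is the least-squares slope of ln(count) against time across all
   replicates (`scipy.stats.linregress`), exact for noiseless exponential
   data. Single end-point viability ratios are converted via
   ln(treated/untreated)/t plus the untreated rate and flagged
   endpoint-derived.
2. **Hill fit.** Bounded nonlinear least squares over (g₀, δ = g₀ − g_min ≥ 0,
   log EC50, h), which encodes g_min ≤ g₀ exactly; h ∈ [0.2, 5],
   EC50 ∈ [10⁻⁴, 10³] μM. Five deterministic seeded starts; best residual
   wins, ties broken by the smaller EC50. Requires ≥ 4 dose levels
   including dose 0.

With 4 time points × 6 replicates and 5% lognormal replicate noise, the
slope's ±2·SE interval has nominal coverage P(|t₂₂| ≤ 2) ≈ 94.2% (the SE is
estimated, so the t — not normal — reference applies); the test suite
verifies the Monte-Carlo coverage against that t-based value.

## Evolutionary stability

The stability of a subclone under a therapy is the maximum real eigenvalue
of A(u) restricted to the set of genotypes reachable from it (itself
included). Reachability is a plain breadth-first search; because the
restricted matrix is triangular in topological order, the stability also
equals max over reachable j of (g_j(d) − μ_out(j)), and the package
computes both, asserting agreement to 10⁻¹⁰ in tests. Negative stability
for every initially present subclone means the whole population decays
exponentially; positive stability of any present subclone identifies the
branch that will drive progression. The sign convention at exactly zero is
conservative: 0 is reported as "boundary" and treated as not stabilized.

The minimum stabilizing TKI concentration is found by bisection on the dose
(partner doses fixed) to 10⁻⁴ μM within default bounds [0, 100] μM — far
above every panel dose, so "infeasible" means no biologically reachable
dose stabilizes the population. Monotonicity of every Hill curve makes the
bisection target unique up to tolerance.

## Scheduling

`ControlProblem` fixes the total horizon T (default 30 days), the switching
horizon τ ∈ {30, 15, 10, 5, 3, 1} by default (final segment truncated when
τ ∤ T), the therapy panel, and the objective. The receding-horizon solver
is greedy per segment, matching a per-horizon minimization: simulate every
panel therapy τ days ahead, keep the one with the smallest total population
at segment end, advance, repeat. Ties go to panel declaration order, so
results are reproducible bit-for-bit from the config. The default objective
is the end-of-segment total; an integrated-load mode (Simpson quadrature of
the total) is available but not default, because end-of-horizon totals are
what the scenario comparisons report.

Two exhaustive solvers audit the greedy path: `solve_constrained_switching`
searches all schedules with ≤ k switches on a switch-time grid (ties: fewer
switches, then lexicographic panel order) — the clinically constrained
variant; `enumerate_global_optimum` evaluates every assignment
(|panel|^segments, guarded at 10⁶) and is used in tests to bound the greedy
solution. All solvers share cached per-segment matrix exponentials, and the
returned trajectory is always re-simulated through the dynamics module, so
the reported final total cannot drift from what the schedule actually does.

## Robustness

Dose-reduction sweeps re-simulate a schedule optimized at *nominal* dose
with every segment's TKI concentration scaled by (1 − p), p on a grid
(default 0–0.9 step 0.05); partner drugs stay at panel dose. Re-optimizing
under the reduced dose is deliberately not the default — the question is
how a committed strategy degrades. Outcomes classify the day-30/day-0 fold
change: response < 0.7, progression > 1.2, otherwise stable, strict
inequalities. Because reducing the dose only raises diagonal entries of a
Metzler matrix, every clone count — hence the fold change — is
nondecreasing in p; the sweep asserts this and the maximum tolerated
reduction is therefore a boundary located to one grid step.

The switching-benefit table solves the receding-horizon problem per
scenario and horizon, records fold changes, normalizes by the constant
(τ = T) strategy, and sums fold changes across horizons per scenario; no
monotonicity in τ is asserted (it is not a theorem).

## Synthetic data and the shipped parameter table

`generate_synthetic_assay` produces exponential growth at the model rate
per condition with multiplicative lognormal replicate noise
(count = x₀ e^{gt}·e^{σz}); σ = 0 reproduces the model exactly. It emulates
seeded-well growth assays: no saturation/confluence effects, no pipetting
covariance between wells, no plate-edge effects — parameter-recovery tests
therefore certify the estimation machinery, not robustness to those
real-assay artifacts. `generate_synthetic_pharmacodynamics` draws bounded
random Hill parameters (g₀ ∈ [0.05, 0.3], g_min ∈ [−0.3, 0.1] with
g_min ≤ g₀, EC50 ∈ [0.05, 2] μM, h ∈ [0.5, 3]) with an optional
resistance-motif mode in which T790M defeats erlotinib-based combinations,
V600E requires a BRAF/MEK inhibitor and METamp requires crizotinib
(g_min clamped ≥ 0 for uncovered pairs).

The built-in scenarios ship with `reference_pharmacodynamics`, a
**synthetic rule-based stand-in** rather than measured fits: a clone is
killable by a combination only if the EGFR axis is blocked (erlotinib fails
against T790M; afatinib does not) and every active bypass is covered
(V600E by vemurafenib or trametinib; MET activation by crizotinib, or by
trametinib only in MAPK-rewired clones carrying V600E or T790M, since
MET-activated founder cells also signal through PI3K/AKT). Covered clones
get g_min = −0.45/day (≈36%/day loss — a strong but realistic targeted-kill
rate, and necessarily larger in magnitude than the HGF-boosted drug-free
growth of +0.32/day, without which no switching schedule could ever achieve
a net response), EC50 = 0.15 μM, h = 1.5; uncovered clones are essentially
insensitive (g_min = g₀ − 0.02). Drug-free rates start at 0.30/day for the
founder, minus 0.01/day per extra alteration, plus 0.02/day under MET
activation. Replace this table with measured parameters via the scenario
config (`pharmacodynamics:` block) for quantitative predictions.

In-vitro scenario lattices span only {V600E, T790M}: MET activation there
is environmental (HGF in the medium), not genomic, so MET-amplified
genotypes appear only in the patient scenario's eight-node lattice.

## Numerical choices and limitations

- Matrix exponentials are evaluated per output time relative to the segment
  start (`scipy.linalg.expm`), so within-segment error is at machine level;
  the audit against an independent adaptive integrator sits near 10⁻¹².
- Overflowing populations raise an explicit error naming the simulated time
  rather than propagating NaNs.
- Problem sizes used by the test suite and the reproduction script — ≤ 8
  genotypes, 30-day horizons, 50–200 randomized audit instances, 500
  calibration seeds — keep full runs in the seconds-to-minutes range while
  exercising every code path at the stated tolerances.
- Not modeled: pharmacokinetic within-segment concentration dynamics,
  stochastic extinction of small subclones, spatial structure and
  microenvironment, toxicity constraints beyond fixed panel doses, and
  drug-interaction surfaces (Bliss/Loewe); mutation rates are constant per
  edge and irreversible.
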