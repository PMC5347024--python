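# tumorsched

Receding-horizon polytherapy scheduling for heterogeneous, evolving
EGFR-mutant lung adenocarcinoma.

Targeted therapy in EGFR-mutant (L858R) lung adenocarcinoma routinely fails
because the tumor is not one clone: rare subpopulations carrying BRAF-V600E,
the EGFR-T790M gatekeeper mutation, or MET activation (amplification, or HGF
stimulation that phenocopies it) survive the EGFR inhibitor and expand. No
single two-drug combination covers every subclone at clinically feasible
doses, but *switching* between combinations on a schedule — sometimes while
the bulk tumor is still shrinking — can suppress each subpopulation in turn.
This package is for computational and translational researchers who want to
explore such switching strategies quantitatively.

## Model

Subclones live on an acquisition lattice rooted at the L858R founder; each
directed edge adds one alteration at a small rate μ (default 10⁻⁶/day).
Under a therapy *u*, the vector *x* of cell counts per genotype evolves as

    dx/dt = A(u) x,
    A_ii = g_i(d_u) − Σ_j μ_{i→j},    A_ji = μ_{i→j}  (i → j an edge),

where the net growth rate of clone *i* follows a four-parameter Hill curve
in the EGFR TKI concentration *d* of the therapy (partner-drug effects are
absorbed into the per-therapy parameters):

    g(d) = g_min + (g_0 − g_min) / (1 + (d/EC50)^h).

*A(u)* is Metzler (nonnegative off-diagonal), so trajectories stay
nonnegative, and it is triangular in topological order, so its eigenvalues
are the diagonal entries. On top of this model the package provides:

- **Calibration** — net growth rates as log-linear slopes of assay counts,
  then bounded nonlinear least squares for (g₀, g_min, EC50, h).
- **Evolutionary stability** — for each initially present subclone, the
  maximum eigenvalue of *A(u)* restricted to the genotypes reachable from
  it: positive means that branch can drive progression. Also the minimum
  TKI concentration (bisection) at which every branch decays.
- **Scheduling** — a greedy receding-horizon solver that, every switching
  horizon τ, picks the panel combination minimizing the total population at
  the segment end; plus an exhaustive ≤ *k*-switch solver and a
  full-enumeration audit oracle.
- **Robustness** — fold-change outcomes (response < 0.7, progression > 1.2)
  under EGFR TKI dose reductions, and switching-benefit tables across
  horizons.

Built-in scenarios cover a patient-derived pre-treatment composition
(94% L858R / 6% +V600E / 0.01% each of three MET-amplified variants, 1 μM
erlotinib) and two in-vitro mixtures (89/10/1 HGF-treated and 90/10) with
the six-combination panel: 1.5 μM erlotinib or 0.5 μM afatinib plus 0.5 μM
crizotinib, 0.5 μM trametinib, or 5 μM vemurafenib. The shipped
dose-response table is a synthetic, rule-based stand-in encoding the
qualitative pharmacology of these alterations (see `docs/methods.md`);
supply measured parameters through a scenario config for quantitative work.

## Worked example

```python
from tumorsched import ControlProblem, get_scenario, solve_receding_horizon

scenario = get_scenario("invitro_heterogeneous_hgf")
x0 = scenario.initial_state()
for tau in (30, 15, 5):
    problem = ControlProblem(T=30, tau=tau, panel=scenario.panel)
    sol = solve_receding_horizon(x0, problem, scenario.pds, scenario.graph)
    plan = " -> ".join(f"{t.name}({d:g}d)" for t, d in sol.schedule.segments)
    print(f"tau={tau:>2}d  fold change {sol.fold_change:8.3f}   {plan}")
```

prints

```
tau=30d  fold change  815.846   ERL+CRI(30d)
tau=15d  fold change    0.222   ERL+CRI(15d) -> AFA+TRA(15d)
tau= 5d  fold change    0.222   ERL+CRI(5d) -> AFA+TRA(5d) -> ERL+CRI(5d) -> AFA+TRA(5d) -> ERL+CRI(5d) -> AFA+TRA(5d)
```

The 89/10/1 HGF-treated mixture progresses ~800-fold in 30 days on the best
*constant* combination (erlotinib+crizotinib kills the L858R bulk but not
the V600E and T790M subclones), while any schedule that alternates to
afatinib+trametinib shrinks the population to 22% of baseline — the
switching happens while the bulk tumor is still responding. The same
machinery is available from the shell:

```sh
tumorsched schedule --scenario invitro_heterogeneous_hgf --switch-horizon 15
tumorsched stability --scenario invitro_heterogeneous_hgf --therapy AFA+TRA
tumorsched robustness --scenario invitro_simple
```

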