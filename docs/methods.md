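# Methods

## Model and assumptions

The chain `X(t)` lives on the tree of finite monomer words over `d`
types. Transition rates are tip-local and type-homogeneous: attachment
of type `i` at rate `k_i^+` from every state, detachment of a terminal
type-`i` monomer at rate `k_i^-`. There are no interior edits, no
sequence-dependent (template) rates, and a single growing polymer — the
model is deliberately the minimal null model of copolymer growth. Exit
rates are bounded by `sum k^+ + max k^-`, so the chain is non-explosive
and the embedded jump chain `Z_n` is well defined.

All monomer indices are 0-based in code; labels (`M1..Md` by default)
carry the 1-based presentation. The empty polymer is the sentinel `ROOT`
object (never an integer); tip arrays use `-1` for the root.

## Theory computations

**Regime.** `alpha = sum_i k_i^+/k_i^-` is computed directly; it equals
the spectral radius of the rank-one cone-type matrix `A = (k_j^+/k_i^-)`,
which the validation suite confirms by an eigenvalue computation.
Because floating-point inputs make exact criticality undecidable, the
classification declares `alpha = 1` within an absolute
`boundary_tolerance` (default `1e-9`) and logs a warning in that band.

**Escape rate.** `m` solves `g(m) = sum_r k_r^+/(m + k_r^-) = 1`. `g` is
strictly decreasing with `g(0) = alpha > 1` and `g(sum k^+) < 1`, so
`(0, sum k^+]` always brackets the root. We use Brent's method
(derivative-free, bracketed — robustness over speed) followed by two
Newton polish steps, which leaves the residual `g(m) - 1` at machine
precision; all downstream quantities inherit this accuracy. The `tol`
parameter (default `1e-12` relative) only loosens the pre-polish
bracket. For `d <= 4` the defining equation is polynomial and solvable
in radicals; the `d = 2` radical formulas are implemented as an
independent cross-check path (`d2_closed_form`), never as the primary
path, since radicals are unavailable for `d >= 5`.

**Derived identities.** Two facts used in tests are algebraic
consequences of the formulas rather than primary definitions, and are
labelled as derived wherever they appear: `v = m` (substituting
`sigma_bar_r = k_r^+/(m + k_r^-)` collapses the velocity formula to
`m g(m) = m`), and "every row of the boundary transition matrix `V`
equals `sigma_bar`" (via the reduction `V_ij = F_j k_j^+/k_j^-`). The
implementation of `V` evaluates the unreduced three-factor product so
the reduction remains a testable identity.

**Degenerate branches.** `d2_closed_form` switches to the
equal-detachment formula `sigma_bar_i = k_i^+/(k_1^+ + k_2^+)` when
`|k_1^- - k_2^-| < 1e-12 * max(k^-)`, avoiding catastrophic cancellation
in the radical formula's vanishing denominator. Transient-only
quantities are represented as explicitly absent (`None`, with a
fail-fast `require` accessor) outside the transient regime — never NaN,
so a regime mistake surfaces as an exception rather than silent
propagation.

## Simulation

The simulator is the exact SSA: an `Exp(1)` variate scaled by the
current exit rate gives the holding time, a single uniform selects the
move from the embedded-chain step distribution. Each event consumes
exactly these two variates in fixed order from one
`numpy.random.default_rng(seed)` stream per trajectory, making event
lists bitwise reproducible across refactors; determinism is part of the
tested contract. Trajectories store only the event list (time, move);
levels, tips, per-type counts and compositions are reconstructed by
replaying the tip stack, so memory is `O(events)` and horizons of order
`10^5`–`10^6` events are routine. Observables use left-continuous step
interpolation: the state at time `t` is the state after the last event
at or before `t`, and the composition at the root is the zero vector by
convention.

The Monte-Carlo validation estimators (first-return, escape rate) use a
separate tight-loop walker with buffered uniforms (one per embedded
step); they are independent estimators, not the trajectory simulator,
so the two-variate stream contract does not apply to them.

## Boundary extraction

Last-exit times are not stopping times, so a finite window can only
approximate the boundary process: a level occupied late in the window
might still be revisited afterwards. The extractor returns levels `0`
through `max attained level - safety_margin` (default margin 10). Each
crossing of a level is undone later with probability at most
`max_i F_i`, so the disagreement probability on the returned range
decays geometrically in the margin; near criticality (`F_i` close to 1)
a larger margin or a longer run past the window of interest is the
appropriate remedy, and the showcase run does the latter. Within the
window the returned records are exact last exits: `e_k` is strictly
increasing, the path never returns to level `<= k` after `e_k`, and
consecutive boundary states satisfy the prefix property — all asserted
structurally in tests. Cone-visit counts `chi_i(n)` count states
`Z_0..Z_n` by tip type, with the initial root state counted in the root
tally, so the counts partition `n + 1`.

## Validation oracles

* *Truncated balance*: enumerate all states to a depth (refused above
  2×10^6 states), check the CTMC balance equations of the product-form
  measure at every interior state; the identity is algebraic, so the
  relative residual must sit at machine precision in every regime.
* *Detailed balance*: build the recursive reversible measure of the
  embedded chain edge-by-edge and check symmetry on every in-truncation
  edge.
* *Monte-Carlo first return*: censored excursions from a length-1 state;
  censoring at level `L` counts as no return, biasing the estimate
  downward and making it nondecreasing in `L`. The default cap
  `L = max(50, ceil(20/(alpha - 1)))` grows near criticality, where
  excursions above a level are long.
* *Monte-Carlo escape rate*: the fraction of root excursions that reach
  `L` before returning estimates the never-return probability; scaled by
  `sum k^+` this estimates `m`, an empirical check of the escape-rate
  interpretation that no core computation relies on.

Statistical checks are framed as `|estimate - theory| <= 3 SE` with
recorded seeds. A 3-SE check on a single seeded path fails by pure
chance a few percent of the time, so stochastic checks follow a
two-stage rule: a failed first attempt is rerun once with a fresh fixed
seed and must then pass. Standard errors for single-path functionals
(embedded speed, cone-visit fractions, root occupancy) come from batch
means over 20 blocks, which absorbs short-range serial correlation;
replicate-mean checks use the replicate standard deviation.

## Problem sizes and what the tests show

The statistical tests run at: 20 replicates × horizon 1000 and one
100,000-step embedded path for the strongly transient set
(`alpha = 6`); horizon 20,000 for the positive-recurrent root-occupancy
check and for the near-critical showcase run; 20,000 Monte-Carlo
replicates per estimator; enumeration to depth 8 at `d = 2`. These sizes
put the 3-SE bands at roughly the percent level, which is tight enough
to catch rate-arithmetic or replay errors while remaining quick to run.
The showcase horizon of 20,000 is an order of magnitude shorter than
the longest runs one might do for figures; at `alpha ≈ 1.0185` the
composition then still fluctuates at the few-percent level, which is why
its acceptance band is 0.05 rather than a multiple of a standard error.

Everything the simulator emulates is the model itself, so passing tests
validate the mathematics and the implementation, not the biological
realism of tip-only, context-free kinetics: real copolymerization
(e.g. templated replication) has sequence-dependent rates that this
model deliberately omits.

## Known limitations

* Near criticality, mixing is slow: finite-horizon composition and
  boundary statistics converge at rates that degrade as `alpha -> 1`,
  and the Monte-Carlo level caps grow correspondingly.
* The boundary extractor's finite-window error is controlled only
  probabilistically (geometric in the margin), not certified per path.
* The bivariate boundary/visit-count transition kernels have no closed
  form and are not implemented; their limit consequences (the cone-visit
  fraction law) are validated statistically instead.
* No approximate acceleration (tau-leaping) is provided; the exact SSA
  is the point.
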