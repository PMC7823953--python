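# Methods

## The estimation problem

Each subject *i* contributes a vector of timed concentration observations
$Y_i$ whose conditional density $p(Y_i\mid\theta)$ is fully specified by a
pharmacokinetic forward model and a residual-error model. The subject-level
parameter vectors $\theta_i$ are i.i.d. draws from an unknown mixing
distribution $F$ on a compact box $\Theta \subset \mathbb{R}^Q$. The
nonparametric maximum-likelihood (NPML) estimate maximises

$$L(F) = \prod_{i=1}^N \int_\Theta p(Y_i \mid \theta)\, dF(\theta)$$

over *all* probability distributions on $\Theta$ — no distributional shape
is assumed. By the Lindsay/Mallet convexity results the maximiser is
discrete with at most $N$ support points, which turns the problem into
finding locations $\phi_k \in \Theta$ and simplex weights $\lambda_k$
maximising $\ell(\lambda,\phi)=\sum_i \log \sum_k \lambda_k\, p(Y_i\mid\phi_k)$.
The package alternates two sub-solvers until the likelihood stabilises:

1. **weights for fixed locations** — a convex problem solved by a
   primal-dual interior-point method (`npag.pdip`);
2. **better locations** — an adaptive-grid search that perturbs surviving
   support points and prunes negligible ones (`npag.adaptive`).

All coupling between the pharmacology and the optimiser flows through the
$N \times K$ matrix $\Psi_{ik} = p(Y_i \mid \phi_k)$.

## Scaled likelihood matrix

With 11 observations per subject, raw densities sit far below double
underflow for most grid points, so each $\Psi$ row is stored divided by its
maximum with the log constant kept alongside (`PsiMatrix.row_scale`). The
optimal weights are invariant to positive per-row rescaling; the constants
are added back to every reported log-likelihood. Entries more than ~700
nats below their row maximum become exact zeros — they are irrecoverable in
double precision and carry no weight anyway. A subject whose row is zero
*everywhere* (log-density $-\infty$ at every grid point) aborts the fit
with an error naming the subject, since no reweighting can explain it.

## Weight solver

The simplex-constrained problem is solved through the equivalent
unnormalised program $\min_{\lambda \ge 0}\; N\mathbf{1}^\top\lambda -
\sum_i \log(\Psi\lambda)_i$, whose minimiser automatically sums to one.
Its KKT conditions, divided by $N$, are exactly Lindsay's first-order
characterisation: $g_k = \frac1N \sum_i \Psi_{ik}/(\Psi\lambda)_i \le 1$
with equality on the support. The solver follows the central path
$\lambda_k z_k = \mu$ with a damped Newton method:

- Newton system reduced to size $\min(K, N)$ — for expanded grids
  ($K \gg N$) the Woodbury identity turns the $K\times K$ system into an
  $N\times N$ positive-definite solve, keeping per-iteration cost
  $O(NK\cdot\min(N,K))$;
- $\mu$ cut by a factor 10 per iteration; fraction-to-boundary damping with
  factor 0.99995; an additional backtracking line search keeps the primal
  merit monotone (the "relaxed Newton" safeguard);
- iteration cap 100, certificate tolerance $10^{-10}$ on the Lindsay
  residual $\max\big(\max_k g_k - 1,\; \max_{\lambda_k > \text{tol}} (1 - g_k)\big)$.

Interior-point iterates approach the boundary only asymptotically, so a
**fixed-active-set Newton polish** runs after the interior phase: support
candidates (weights above $10^{-9}$ of the maximum) are refined by damped
Newton steps at $\mu = 0$, retiring any candidate squeezed into the
boundary. This reliably lands the certificate at $10^{-10}$–$10^{-13}$ in
double precision. The solve whose residual is smallest is returned; if the
certificate is still not met the solver raises, carrying the last iterate.
Inside the outer loop a stalled solve with residual $\le 10^{-6}$ is
accepted and iteration continues — a robustness valve that leaves the final
reported residual honest.

Two identical $\Psi$ columns make the optimum non-unique in $\lambda$
(only the column *sums* are determined); the solver returns an arbitrary
split and downstream condensation or the minimum-distance gate removes
near-duplicates. This is documented behaviour, not corrected.

## Adaptive grid

Per cycle, with perturbation fraction `eps` (initially 0.2):

1. solve weights on the expanded grid;
2. **condense**: keep points with $\lambda_k > \max_k\lambda_k \cdot
   \Delta_\lambda$ ($\Delta_\lambda = 10^{-3}$); the maximum-weight point
   always survives;
3. re-solve on the survivors — this second solve defines the cycle's
   log-likelihood and, at exit, the final estimate (the condensed-grid
   $\Psi$ is obtained by column selection, never recomputed);
4. **expand**: for each survivor and each dimension append
   $\phi \pm \text{eps}\,(b_d - a_d)\,e_d$ when inside the box and at
   normalised-$L_1$ distance $\ge \Delta_D = 10^{-4}$ from every point
   already accepted. Acceptance is order-dependent (earlier daughters can
   block later ones); the literal ordering is kept for determinism and
   compatibility with the published procedure.

When a cycle improves the log-likelihood by at most $\Delta_L = 10^{-4}$,
`eps` is halved. Once `eps` reaches the floor $\Delta_e = 10^{-4}$
(boundary case `eps == delta_e` counts as "precision reached"), the
current estimate is accepted if its log-likelihood moved by at most
$\Delta_F = 10^{-2}$ since the previous acceptance test; otherwise `eps`
resets to 0.2 and the search continues. Log-likelihood bookkeeping is
initialised with sentinels ($-10^{30}$, $10^{30}$) that any first cycle
beats. The loop contains no randomness: identical inputs produce
bit-identical traces.

`max_cycles` defaults to 1000. This is a deliberate desk-scale budget
choice: the two-level stopping test is conservative and, on the reference
problem class, typically fires only after thousands of cycles, long after
the mixture has stabilised (in our 100-subject replication the Ke marginal
is unchanged between cycle 1000 and formal convergence at cycle ~3000,
with the log-likelihood still creeping in the third significant digit). A
run that hits the cap returns the last condensed estimate flagged
`converged=False`; callers wanting the formal certificate raise the cap.
`max_cycles=0` returns the weight solve of the initial grid unchanged.

Forward-model predictions are memoised per (dosing regimen, parameter
vector) across cycles — survivors and repeated daughter positions then
cost nothing, which is the dominant saving at production sizes.

## Initial grids

The default space-filling start is the Faure sequence in base $b$ = the
smallest prime $\ge Q$: point $j$ applies powers of the Pascal matrix mod
$b$ to the base-$b$ digits of the integer index before the radical
inverse. Indexing starts at 1 and the first $b^4 - 1$ terms are skipped by
default (the usual burn-in; set `skip=0` for the raw sequence, whose 1-D
case is the van der Corput sequence 0.5, 0.25, 0.75, …). Points are
affinely mapped onto $\Theta$ and are strictly interior. The customary
sizes 2129, 5003, 10007, 20011, 40009, 80021 are provided as the
`FAURE_LADDER` presets; any size is allowed. Seeded uniform grids and
support files from previous runs are drop-in alternatives.

## Forward model

The built-in model is the linear three-compartment system with first-order
absorption (depot $x_1$), central elimination and peripheral exchange:

$$\dot x_1 = -K_a x_1,\quad
  \dot x_2 = K_a x_1 - (K_e + K_{cp}) x_2 + K_{pc} x_3 + r(t),\quad
  \dot x_3 = K_{cp} x_2 - K_{pc} x_3,$$

output $y = x_2 / V$. Between dose events the system has constant
coefficients and constant forcing, so the analytic path propagates the
exact matrix exponential of the augmented $4\times4$ matrix
$\begin{psmallmatrix}A & u\\ 0 & 0\end{psmallmatrix}$ — this absorbs the
zero-order infusion forcing and needs no special-casing when $A$ is
singular (zero rate constants) or has coincident eigenvalues (the
$K_a = K_e$ Bateman degeneracy). Boluses are instantaneous state jumps; an
observation exactly at an event time sees the post-event state, and an
observation at an infusion stop sees the continuous state with the
infusion integrated over its half-open window $[t_0, t_0 + d)$. The
analytic path is vectorised over parameter batches (one batched
exponential per event segment per observation time).

An independent ODE path drives LSODA piecewise at rtol $10^{-8}$ / atol
$10^{-10}$ and exists purely as a cross-check oracle; the two paths agree
to $10^{-6}$ relative on the reference dosing across the parameter box.
User models plug in through `PKModelSpec` (a batch `predict` callable plus
parameter names).

## Residual-error models

The residual SD combines the assay-error polynomial $\alpha = c_0 + c_1 f
+ c_2 f^2 + c_3 f^3$ with a variance factor $\gamma$: polynomial only
($\sigma=\alpha$), multiplicative ($\gamma\alpha$), additive
($\sqrt{\alpha^2+\gamma^2}$), constant ($\gamma$). By default $\alpha$ is
evaluated at the model prediction; evaluating it at the observed value is
available as an opt-in stabilisation for $c_0 = 0$ polynomials, with the
caveat that it leaves strict maximum-likelihood territory. $\sigma \le 0$
anywhere is a hard configuration error naming the observation — silent
clamping would hide miscalibrated coefficients. Multiple outputs are
treated as independent with per-output coefficient sets. The staged
workflow (`fit_staged` / `[[stages]]` in the CLI config) runs successive
fits with decreasing error magnitude, warm-starting each from the previous
support — the standard model-development strategy when the assay error is
not known up front.

## Simulator

`default_spec()` encodes the reference study design exactly: 300 subjects;
$V, K_a, K_{cp}, K_{pc}$ normal with means (1.2, 0.8, 2.0, 0.2) and 25%
CV (SD = CV × mean); $K_e$ the bimodal mixture $0.2\,N(0.5, 10\%\,\text{CV})
+ 0.8\,N(1.5, 10\%\,\text{CV})$; a 2000 mg bolus into the depot at
$t=5$ h over a 500 mg/h infusion into the central compartment on
$(0,16)$ h; 11 sampling times (0.25, 1.0, 4.98, 5.25, 5.5, 6.0, 7.0, 8.5,
10.0, 13.0, 16.0); additive $N(0, 5.5^2)$ assay noise; search box
$K_a\in(0.01,2.0)$, $V\in(0.01,2.5)$, $K_e\in(0.0001,2.0)$,
$K_{cp}\in(0.0,4.0)$, $K_{pc}\in(0.0001,2.0)$.

Draws outside the box are redrawn rather than clamped — clamping would put
spurious mass exactly on the boundary, whereas the NPML support must live
inside $\Theta$; redraw counts are reported (`truth.attrs["n_resampled"]`,
well under 1% under the defaults). One RNG stream is consumed in
subject-major order (mixture component, parameters in domain order, noise
vector), so a seed fully determines the dataset.

What the simulator does **not** emulate: covariates, inter-occasion
variability, below-quantification-limit censoring, missed samples, or
between-subject differences in dosing/sampling schedules. Passing tests
therefore demonstrate correct recovery under the stated design — clean
regimens, known error magnitude, a correctly specified structural model —
not robustness to the messiness of real clinical datasets.

## Diagnostics

The directional derivative $D(\theta,F) = \sum_i p(Y_i\mid\theta)/
p(Y_i\mid F) - N$ is computed in log space (log ratios capped at ~700 nats
so grossly sub-optimal estimates give huge finite values rather than
overflow). $F$ is the global NPML optimum iff $\max_\Theta D = 0$, and
$\max(D,0)$ bounds the log-likelihood shortfall. `optimality_check` runs
bounded L-BFGS-B ascents from the support points plus seeded uniform
starts (50 by default; the choice of optimiser is ours — any bounded
multistart search fits the contract). Empirical-Bayes posteriors are
$w_k \propto \lambda_k p(Y_i\mid\phi_k)$, normalised in log space;
population predictions average per-point profiles under $\lambda$;
Bayesian predictions evaluate the model at the posterior-mean parameter
vector. Marginal summaries are weighted histograms at user-chosen bin
counts (no canonical binning is claimed).

## Problem sizes used in the shipped checks

The acceptance script and test suite run the study at desk scale, a
package choice keeping the full pipeline inside routine CI budgets:
generator checks at the full 300 subjects; the bimodality-recovery fit at
100 subjects from a 5003-point Faure start under the default controls
(including the 1000-cycle budget discussed above); and the support-bound
fit at 300 subjects from a 2129-point start under a 50-cycle budget — the
support bound is a structural property enforced by condensation and
interior-point sparsity from the first cycle on, so a short run measures
it as well as a long one. The reported quantities (minor-mode mass and
location of the $K_e$ marginal, support counts, moments) are stable well
before the cycle budgets bind.

## Known limitations

- The semiparametric mode in which $\gamma$ is itself optimised is out of
  scope; $\gamma$ is fixed per fit (or per stage).
- No censored observations, covariate models, or inter-occasion
  variability.
- `expand` is order-dependent by construction; a different daughter
  ordering can yield slightly different (equally valid) grids.
- The support-count bound ($\le N$) is a property of the exact optimum;
  the solver enforces it through condensation and the interior-point
  sparsity, not as a hard constraint, and near-duplicate support pairs
  can transiently both carry weight within a cycle.
- Weight non-uniqueness under exactly duplicated $\Psi$ columns is
  resolved arbitrarily.
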