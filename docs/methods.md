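# Methods

## Model

A gene regulatory network over binary genes `X_1 … X_n` is modeled as a
Boolean network with perturbation (BNp): a deterministic update
`X(t+1) = F(X(t))` followed by independent per-gene flips with probability
`p`.  States are encoded as decimals with `X_1` the most significant bit.
The chain's transition probability matrix (TPM) is
`P[i, j] = (1-p)^(n-d) p^d`, `d` the Hamming distance between `j` and
`F(i)`; for `p > 0` every entry is positive, so the chain is ergodic with a
unique stationary distribution.  Two rule representations are supported:
per-gene truth tables, and a signed regulatory matrix under the
majority-vote rule (on ties a gene holds its value, which makes every gene
implicitly self-regulating — its own current value is part of its regulator
context).

Equivalently, the network is a set of conditional probability matrices
(CPMs): for gene `i` with `k_i` regulators, a `2^k_i x 2` matrix of
`Pr[X_i = 0/1 | regulator context]`.  The TPM factorizes as the product of
per-gene CPM entries; extraction from a TPM sums row mass over destination
states and averages over source states sharing a regulator context (an
unweighted average; a stationary-distribution-weighted variant would be easy
to add but the unweighted rule is the one used throughout).

## Uncertainty and robust control

Unknown conditional probabilities `theta = Pr[X_i = 0 | context]` carry
independent conjugate Beta(alpha, beta) priors (default Beta(1, 1),
uniform).  Observing a state trajectory adds event counts to the
hyperparameters.  The *effective TPM* (ETPM) replaces each unknown entry by
its posterior mean; because the parameters are independent and enter the
gene-wise product linearly, the ETPM is exactly the prior mean of the
uncertain TPM (verified in tests against Monte-Carlo averages).

Intervention flips a control gene (action `c = 1` substitutes the flipped
state's TPM row).  Costs default to 5 per transition into an undesirable
state plus 1 per applied action (6/5/1/0), discount `zeta = 0.2`.  The
intrinsically Bayesian robust (IBR) stationary policy is obtained by value
iteration on the ETPM; the optimal policy for a known network is the special
case of an empty uncertainty class.  Value iteration starts from `J = 0`
(fixed for reproducibility of the truncated protocol), breaks action ties
toward no intervention, and runs either a fixed number of sweeps (the
benchmark protocol uses I = 4) or to a sup-norm residual below 1e-12.
Exact policy evaluation solves `(I - zeta P_mu) J = r_mu`.

## MFPT approximation

Splitting the states into desirable (D) and undesirable (U) blocks, the
hitting-time vectors solve `(I - P_DD) K_DU = e` and `(I - P_UU) K_UD = e`
(dense LU; singular blocks are reported, not regularized).  The MFPT policy
acts from a desirable state when flipping the control gene increases the
time to U by more than `Delta` (default 0.3), and from an undesirable state
when it shortens the time back to D by more than `Delta`.  When the flipped
partner lies in the opposite block, the comparison uses the full
hitting-time vector to the relevant target set, which is zero on the target
itself — this extension is an interpretation (the block-restricted vectors
do not define the comparison in that case) and preserves the reach-quickly /
leave-quickly reading.  Applied to the ETPM, the MFPT policy is a cheap
stand-in for the IBR policy *inside experimental design only*; any policy
actually deployed or evaluated is the value-iteration IBR policy.

## Experiment selection (MOCU)

The mean objective cost of uncertainty (MOCU) is the prior-expected excess
cost of the robust policy over the model-specific optimal policy.  An
experiment reveals one unknown parameter exactly; experiments are ranked by
the expected cost of the robust policy remaining after conditioning on the
outcome (terms independent of the candidate drop from the ranking, so the
remaining-MOCU order equals this expected-cost order).  Two scoring routes:

* **optimal** — value iteration on the conditioned ETPM, evaluated exactly
  by the linear solve (the outcome expectation is of a cost on the ETPM, so
  exact evaluation simply removes estimator variance);
* **mfpt** — the MFPT policy of the conditioned ETPM, costed by discounted
  rollouts (default 500 trajectories, horizon 6).

The outcome expectation over `theta'_i ~ Beta(alpha_i, beta_i)` uses, by
default, the marginal's quantile midpoints (a midpoint rule on the Beta
CDF, default M = 20 points) rather than raw Monte-Carlo draws.  Score
differences between candidate experiments are frequently of order 1e-4 —
far below raw Monte-Carlo noise at any affordable M — and the midpoint rule
removes that noise at identical cost; against a 400-point reference ranking
it reproduced the top choice on every diagnostic instance where raw draws
managed half.  Raw sampling remains available (`stratified=False`).  M
itself is a free parameter of the method; 20 balances the T x M policy
solves against ranking fidelity.

A caution on a tempting "information never hurts" shortcut: the expected
post-experiment cost *measured on the conditioned ETPMs* can exceed the
unconditioned robust cost on the unconditioned ETPM, because the optimal
value is not concave in the transition matrix; quadrature on 2-gene
instances shows violations of order 0.05.  The inequality that does hold —
and that the tests assert — is the model-space form: on every realized
model, the conditioned-optimal policy is pointwise no worse than the
unconditioned robust policy, so the expected remaining MOCU never exceeds
the current MOCU.

## Evaluation protocol and pairing

Determining a parameter is scored on the *true* network: condition the
class on the revealed value, solve the IBR policy (I = 4), and average the
discounted cost of 10,000 horizon-6 rollouts from uniform initial states.
Evaluation rollout seeds depend only on (network, truth set, parameter), so
every selection strategy is compared on identical evaluation noise; in
sequential designs all strategies additionally share per-step evaluation
seeds, making the first and last points of the cost curves coincide
exactly.  For curve-shape analyses an exact-evaluation mode replaces the
rollout average with the infinite-horizon linear solve — zero variance, and
with `zeta = 0.2` the horizon-6 truncation error is about 1e-4, negligible
against the effects measured.

## Synthetic-data conditions

The generator draws, per gene, `k = 2` distinct regulators uniformly
(self-regulation allowed), a truth-table bias from Beta(mean 0.5, variance
1e-4) (shape parameters 1249.5 each), and i.i.d. Bernoulli(bias) outputs;
`p = 0.01`.  Benchmarks use `n = 6`, control gene `X_6`, undesirable states
`{X_1 = 0, X_2 = 0}`, `T = 5` unknown rows drawn uniformly, truth values
drawn from the prior, and optionally a length-L trajectory from the true
network to sharpen the priors before design.  What this emulates — and what
it does not: truth tables with near-unbiased outputs and a uniform truth
prior produce dynamics far noisier than curated biological models, and real
regulatory data would arrive as noisy expression time series rather than
exact state observations.  Passing benchmarks therefore demonstrate the
estimator and selection machinery under the stated stochastic conditions,
not biological fidelity.

Realized costs vary enormously across generated networks (std ~1.0,
heavy-tailed by networks whose dynamics dwell in U), so benchmark *levels*
carry a seed-to-seed standard error of roughly `1.0 / sqrt(#networks)`;
paired comparisons between selection strategies on shared instances are far
tighter and are the meaningful output at reduced scale.  Default scales:
the test suite runs 60 networks x 30 truth sets (tables) and 15 x 3 / 3 x 2
(6- and 9-gene sequential curves); the acceptance script runs 200 networks x 10 truth sets
(network count dominates the level variance).
The full 100 x 100 x 10,000 protocol is a configuration change
(`BenchmarkConfig(n_networks=100, n_truth_sets=100)`) and runs overnight.

## Fixtures

The 9-gene mutated mammalian cell-cycle network (p27 null) ships as truth
tables; CycD is an extracellular input modeled as a held bit (the BNp
perturbation supplies its switching).  The 6-node TP53 pathway
(DNA-DSBs, MDM2, TP53, WIP1, CHK2, ATM) uses the majority-vote rule; the
shipped regulatory matrix is a synthetic reconstruction of the published
pathway diagram (activations: DSB->ATM, ATM->CHK2, ATM/CHK2->TP53,
TP53->WIP1, TP53/WIP1->MDM2; suppressions: WIP1 -| ATM/CHK2/TP53,
MDM2 -| TP53, ATM -| MDM2) and can be overridden with any 6x6 signed
matrix.  Undesirable states are those with DNA damage present, MDM2 up and
TP53 down (decimal 48–55).

## Known limitations

* Single control gene and binary actions (the interface generalizes, the
  experiments do not).
* Stationary policies only; no hyperstate / non-stationary Bayesian control.
* Independent Beta priors per CPM row; no correlated or Dirichlet priors.
* Experiment outcomes are exact determinations of a parameter, not noisy
  measurements.
* The exhaustive-enumeration and quadrature oracles used in tests are
  feasible only for 1–2-gene instances; larger networks are checked by
  statistical agreement, not exactness.
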