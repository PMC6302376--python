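# grndesign

Objective-based experimental design for Markovian gene regulatory networks
under stationary control.

## The problem

Therapeutic intervention in a gene regulatory network is a control problem:
a network of `n` binary genes evolves as a Markov chain on its `2^n`
expression states, some states correspond to a pathological phenotype, and
a controller may flip a designated gene each step to steer the chain away
from them.  When the network model is known, the optimal stationary policy
minimizes the expected infinite-horizon discounted cost

```
J_mu(x0) = E[ sum_t  zeta^t  r(X(t), X(t+1), mu(X(t))) | X(0)=x0 ]
```

and is found from Bellman's equation by value iteration.  In practice some
of the regulatory conditional probabilities `theta = Pr[X_i | regulators]`
are unknown.  This package:

* represents networks as Boolean networks with perturbation (BNp) or,
  equivalently, per-gene conditional probability matrices (CPMs), and
  converts between CPMs and the transition probability matrix (TPM);
* models unknown conditional probabilities with conjugate Beta priors,
  updated by observed state trajectories;
* derives the **intrinsically Bayesian robust (IBR)** policy — the policy
  optimal on average over the uncertainty — by value iteration on the
  **effective TPM** (the prior mean of the uncertain TPM);
* ranks candidate experiments (each reveals one unknown probability) by
  the expected intervention cost remaining after the experiment, the
  **mean-objective-cost-of-uncertainty (MOCU)** criterion: perform first
  the experiment whose outcome leaves the cheapest robust control;
* provides a **mean-first-passage-time (MFPT)** approximation of the IBR
  policy that makes the design step cheap on larger networks (the deployed
  policy is always the exact IBR policy);
* ships the 9-gene mutated mammalian cell-cycle network and a 6-node TP53
  pathway model as fixtures, plus the random synthetic-network generator
  and the full benchmark harness.

Intended users: computational biologists and control theorists studying
intervention and experiment prioritization in probabilistic Boolean
network models.

## Worked example

Rank three unknown regulatory probabilities in the TP53 pathway model by
how much determining each would improve robust control of ATM:

```python
import numpy as np
from grndesign import (
    build_tp53, bnp_tpm, cpms_from_tpm, UncertaintyClass, ControlProblem,
    undesirable_states, DesignConfig, select_experiment, effective_tpm,
    value_iteration, expected_cost,
)

net = build_tp53()                      # 6-node TP53 pathway BNp, p = 0.01
P = bnp_tpm(net)
cpms = cpms_from_tpm(P, net.regulators)

unknowns = [(2, 5), (5, 1), (1, 3)]     # (gene index, CPM row)
unc = UncertaintyClass.uniform(unknowns)

problem = ControlProblem(
    n_genes=6, control_gene=5,          # intervene on ATM
    undesirable=undesirable_states(6, {0: 1, 1: 1, 2: 0}),
    zeta=0.2,
)

report = select_experiment(cpms, unc, problem, DesignConfig(), rng=0)
for i, score in sorted(report.scores.items()):
    g, r = unknowns[i]
    print(f"experiment {i} (gene {net.gene_names[g]}, context row {r}): "
          f"expected remaining cost {score:.4f}")
print("selected experiment:", report.selected)

ibr = value_iteration(effective_tpm(cpms, unc), problem, iterations=None)
print(f"robust policy cost on the effective TPM: "
      f"{expected_cost(effective_tpm(cpms, unc), ibr, problem):.4f}")
print("states where the robust policy flips ATM:",
      np.flatnonzero(ibr.actions).tolist())
```

Output:

```
experiment 0 (gene TP53, context row 5): expected remaining cost 0.8434
experiment 1 (gene ATM, context row 1): expected remaining cost 0.8427
experiment 2 (gene MDM2, context row 3): expected remaining cost 0.8417
selected experiment: 2
robust policy cost on the effective TPM: 0.8427
states where the robust policy flips ATM: [36, 38, 40, 44, 46, 48, 50, 56, 62]
```

Undesirable states here are those with DNA damage present, MDM2 up and
TP53 down (decimals 48–55).  Scores are expected discounted intervention
costs after conditioning on each experiment's outcome — lower is better —
so measuring the MDM2 conditional probability is the most valuable first
experiment, and the robust policy's cost (0.8427) upper-bounds what any of
the three experiments is expected to leave behind.  The shipped TP53
regulatory matrix is a reconstruction of the published pathway diagram and
can be overridden (`build_tp53(R)`).

A command-line interface mirrors the library (`grn net`, `grn cpm`,
`grn unc`, `grn control`, `grn mfpt`, `grn design`, `grn bench`); run
`grn --help`.

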