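"""End-to-end simulation workflow: priors -> data -> design -> robust policy.

One reproducible run on a single network: load or generate a BNp, hide a set
of conditional probabilities behind Beta priors, optionally sharpen the
priors with an observed trajectory, run sequential MOCU-based design for a
budget of experiments, and write the resulting policies, costs, and a
manifest tying every artifact to the seed and inputs that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .control import ControlProblem, value_iteration
from .cpm_uncertainty import UncertaintyClass, cpms_from_tpm, effective_tpm, update_posteriors
from .design import DesignConfig, sequential_design
from .io import load_network, load_trajectory, load_uncertainty, save_policy, parse_state_set
from .networks import bnp_tpm, random_bnp, simulate_tpm, undesirable_states


@dataclass
class RunConfig:
    """Configuration for :func:`run`.

    Either ``network`` (a network JSON path) or the generator parameters
    (``n_genes``/``k``/``p``) define the true network.  ``uncertainty`` may
    name a YAML file; otherwise ``n_unknown`` positions are drawn uniformly.
    ``trajectory`` may name a TSV file; otherwise a length-``L`` trajectory is
    simulated from the true network.  True values for the unknown entries are
    drawn from the prior (the simulation stand-in for performing the actual
    experiments).
    """

    out_dir: str = "run_out"
    seed: int = 0
    network: str | None = None
    n_genes: int = 6
    k: int = 2
    p: float = 0.01
    uncertainty: str | None = None
    n_unknown: int = 5
    trajectory: str | None = None
    L: int = 0
    control_gene: int = 5
    zeta: float = 0.2
    undesirable: str | None = None  # state-set spec; default {X1=0, X2=0}
    method: str = "optimal"
    design_samples: int = 20
    vi_iterations: int = 4
    delta: float = 0.3
    budget: int | None = None
    eval_n: int = 10_000
    horizon: int = 6


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the workflow; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    ss = dict(zip(("network", "positions", "truth", "trajectory", "design"), root.spawn(5)))
    input_hashes = {}

    if config.network:
        net = load_network(config.network)
        input_hashes["network"] = _sha256(config.network)
    else:
        net = random_bnp(config.n_genes, config.k, p=config.p,
                         rng=np.random.default_rng(ss["network"]))
    P_model = bnp_tpm(net)
    cpms = cpms_from_tpm(P_model, net.regulators)

    if config.uncertainty:
        unc = load_uncertainty(config.uncertainty)
        input_hashes["uncertainty"] = _sha256(config.uncertainty)
    else:
        rng = np.random.default_rng(ss["positions"])
        flat = [(g, r) for g, tab in enumerate(cpms.tables) for r in range(tab.shape[0])]
        idx = rng.choice(len(flat), size=config.n_unknown, replace=False)
        unc = UncertaintyClass.uniform([flat[i] for i in idx])

    # Simulation stand-in for the experiments: the assumed true values are
    # prior draws, and the "true network" plugs them into the model CPMs.
    truth_rng = np.random.default_rng(ss["truth"])
    truths = unc.sample_theta(truth_rng)
    from .cpm_uncertainty import realize_cpms, tpm_from_cpms

    true_P = tpm_from_cpms(realize_cpms(cpms, unc, truths))

    if config.trajectory:
        traj = load_trajectory(config.trajectory, n=net.n)
        input_hashes["trajectory"] = _sha256(config.trajectory)
        unc = update_posteriors(unc, traj, cpms.regulators)
    elif config.L > 0:
        traj = simulate_tpm(true_P, config.L, np.random.default_rng(ss["trajectory"]))
        unc = update_posteriors(unc, traj, cpms.regulators)

    U = (parse_state_set(config.undesirable) if config.undesirable
         else undesirable_states(net.n, {0: 0, 1: 0}))
    problem = ControlProblem(
        n_genes=net.n, control_gene=config.control_gene, undesirable=U, zeta=config.zeta
    )
    d_cfg = DesignConfig(
        method="mfpt" if config.method == "mfpt" else "optimal",
        n_samples=config.design_samples,
        vi_iterations=config.vi_iterations,
        delta=config.delta,
    )

    budget = unc.num_uncertain if config.budget is None else config.budget
    design_rng = np.random.default_rng(ss["design"])
    eval_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss["design"].spawn(budget + 1)]
    report = sequential_design(
        true_P, cpms, unc, truths, problem, d_cfg, budget=budget,
        eval_n=config.eval_n, eval_horizon=config.horizon,
        rng=design_rng, eval_seeds=eval_seeds,
    )

    # Final robust policy for the post-design uncertainty class.
    final_unc = unc
    for i in report.selections:
        final_unc = final_unc.condition_on(i, float(truths[i]))
    final_policy = value_iteration(
        effective_tpm(cpms, final_unc), problem, iterations=config.vi_iterations
    )
    save_policy(out / "ibr_policy.json", final_policy)
    (out / "design_report.json").write_text(json.dumps(
        {"selections": [int(i) for i in report.selections],
         "step_costs": [float(c) for c in report.step_costs]}, indent=1) + "\n")

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "sub_streams": {k: list(map(int, v.spawn_key)) for k, v in ss.items()},
        "eval_seeds": eval_seeds,
        "config": asdict(config),
        "input_hashes": input_hashes,
        "unknown_positions": [[p.gene, p.row] for p in unc.params],
        "selections": [int(i) for i in report.selections],
        "step_costs": [float(c) for c in report.step_costs],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
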