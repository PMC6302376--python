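"""Mean first passage times and the MFPT approximate control policy.

Partitioning the TPM by the desirable/undesirable phenotype blocks, the
vectors of expected hitting times satisfy the linear systems
``K_DU = e + P_DD K_DU`` and ``K_UD = e + P_UU K_UD``.  The MFPT stationary
policy intervenes when flipping the control gene changes the relevant hitting
time by more than a threshold ``Delta``: from a desirable state it acts if the
flip pushes the exit time to the undesirable set up by more than ``Delta``;
from an undesirable state it acts if the flip pulls the return time to the
desirable set down by more than ``Delta``.

Applied to the effective TPM of an uncertainty class, the same construction
gives a cheap approximation of the IBR policy used inside experimental design
(the policy finally deployed is always the value-iteration IBR policy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .control import ControlProblem, Policy
from .networks import flip_state

__all__ = ["MfptResult", "mfpt_vectors", "hitting_times", "mfpt_policy", "approx_ibr_policy"]


@dataclass(frozen=True)
class MfptResult:
    """Hitting-time vectors between phenotype blocks (units: steps)."""

    K_DU: np.ndarray  # from each desirable state to the undesirable set
    K_UD: np.ndarray  # from each undesirable state to the desirable set
    desirable: np.ndarray
    undesirable: np.ndarray


def _block_hitting(P: np.ndarray, inside: np.ndarray, label: str) -> np.ndarray:
    """Solve (I - P[inside, inside]) K = e, validating against absorbing subsets."""
    sub = P[np.ix_(inside, inside)]
    m = sub.shape[0]
    A = np.eye(m) - sub
    try:
        K = np.linalg.solve(A, np.ones(m))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular hitting-time system for block {label}; states {inside.tolist()} "
            f"contain an absorbing subset"
        ) from exc
    if not np.isfinite(K).all() or K.min() < 1.0 - 1e-9:
        trapped = inside[np.flatnonzero(~np.isfinite(K) | (K < 1.0 - 1e-9))]
        raise np.linalg.LinAlgError(
            f"invalid hitting times for block {label}; check states {trapped.tolist()}"
        )
    return K


def mfpt_vectors(P: np.ndarray, desirable: np.ndarray, undesirable: np.ndarray) -> MfptResult:
    """Mean first passage times from each block to the opposite one."""
    P = np.asarray(P, dtype=np.float64)
    D = np.unique(np.asarray(desirable, dtype=np.int64))
    U = np.unique(np.asarray(undesirable, dtype=np.int64))
    S = P.shape[0]
    if D.size == 0 or U.size == 0:
        raise ValueError("both phenotype blocks must be nonempty")
    if np.intersect1d(D, U).size or D.size + U.size != S:
        raise ValueError("desirable/undesirable must partition the state space")
    return MfptResult(
        K_DU=_block_hitting(P, D, "D"),
        K_UD=_block_hitting(P, U, "U"),
        desirable=D,
        undesirable=U,
    )


def hitting_times(P: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Expected steps to first reach ``target`` from every state (0 on the target).

    Restricted to the complement of the target this is the block hitting-time
    vector; extending it by zeros on the target makes the flip comparisons of
    the MFPT policy well defined even when the flipped state crosses blocks.
    """
    P = np.asarray(P, dtype=np.float64)
    S = P.shape[0]
    target = np.unique(np.asarray(target, dtype=np.int64))
    outside = np.setdiff1d(np.arange(S), target)
    h = np.zeros(S)
    if outside.size:
        h[outside] = _block_hitting(P, outside, "complement")
    return h


def mfpt_policy(
    P: np.ndarray,
    problem: ControlProblem,
    delta: float = 0.3,
) -> Policy:
    """The MFPT stationary control policy with threshold ``delta``.

    Hitting times are computed from the *uncontrolled* TPM; the policy then
    compares each state with its control-gene-flipped partner.
    """
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    S = problem.n_states
    states = np.arange(S)
    U = problem.undesirable
    D = problem.desirable
    h_to_U = hitting_times(P, U)
    h_to_D = hitting_times(P, D)
    flipped = flip_state(states, problem.control_gene, problem.n_genes)
    actions = np.zeros(S, dtype=np.int64)
    # Desirable: act when flipping buys more than delta extra steps away from U.
    actions[D] = (h_to_U[flipped[D]] - h_to_U[D] > delta).astype(np.int64)
    # Undesirable: act when flipping gets back to D more than delta steps sooner.
    actions[U] = (h_to_D[U] - h_to_D[flipped[U]] > delta).astype(np.int64)
    return Policy(actions=actions)


def approx_ibr_policy(etpm: np.ndarray, problem: ControlProblem, delta: float = 0.3) -> Policy:
    """MFPT approximation of the IBR policy: the MFPT policy of the effective TPM."""
    return mfpt_policy(etpm, problem, delta=delta)
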