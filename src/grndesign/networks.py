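"""Boolean networks with perturbation (BNp) and their Markov-chain representation.

A BNp over genes ``X_1, ..., X_n`` evolves by a deterministic update
``X(t+1) = F(X(t))`` except that, independently each step, every gene may be
flipped with a small perturbation probability ``p``.  The resulting state
sequence is an ergodic Markov chain on the ``2**n`` gene activity profiles
(GAPs), encoded as decimal states with ``X_1`` as the most significant bit.

Two rule representations are supported: explicit per-gene truth tables, and a
signed regulatory matrix ``R`` under the majority-vote rule (a gene turns on
when its weighted regulator sum is positive, off when negative, and holds its
value on a tie).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "BooleanNetwork",
    "encode_state",
    "decode_state",
    "gene_bit",
    "context_index",
    "flip_state",
    "next_state",
    "next_state_majority",
    "transition_map",
    "bnp_tpm",
    "random_bnp",
    "beta_shapes_from_moments",
    "build_cell_cycle",
    "build_tp53",
    "TP53_DEFAULT_R",
    "TP53_GENES",
    "steady_state",
    "simulate_tpm",
    "undesirable_states",
]


class ConfigurationError(ValueError):
    """Raised for structurally invalid networks or rule definitions."""


# ---------------------------------------------------------------------------
# State encoding: decimal state s in {0, ..., 2^n - 1}, X_1 = MSB.
# ---------------------------------------------------------------------------

def encode_state(bits: Sequence[int]) -> int:
    """Encode a binary gene activity profile (X_1 first) as a decimal state."""
    s = 0
    for b in bits:
        s = (s << 1) | int(b)
    return s


def decode_state(s: int, n: int) -> np.ndarray:
    """Decode a decimal state into the length-``n`` binary GAP (X_1 first)."""
    return np.array([(int(s) >> (n - 1 - i)) & 1 for i in range(n)], dtype=np.int64)


def gene_bit(s, gene: int, n: int):
    """Value of gene ``gene`` (0-based) in state ``s``; works element-wise on arrays."""
    return (s >> (n - 1 - gene)) & 1


def context_index(s, regulators: Sequence[int], n: int):
    """Decimal value of the regulator vector of a gene, extracted from state ``s``.

    The regulator ordering is the one stored in the network (ascending gene
    index), with the first regulator as the most significant bit — the same
    convention used for full states.  Works element-wise on state arrays.
    """
    c = 0
    for g in regulators:
        c = (c << 1) | gene_bit(s, g, n)
    return c


def flip_state(s, gene: int, n: int):
    """State(s) with the value of ``gene`` flipped."""
    return s ^ (1 << (n - 1 - gene))


# ---------------------------------------------------------------------------
# Network container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BooleanNetwork:
    """A Boolean network with perturbation.

    Parameters
    ----------
    gene_names
        Identifier per gene.
    regulators
        Per gene, the ordered (ascending) tuple of 0-based regulator indices.
    truth_tables
        Per gene, a binary array of length ``2**k_i`` giving the update output
        for each regulator context; ``None`` for majority-vote networks.
    majority_matrix
        Signed ``n x n`` regulatory matrix with entries in {-1, 0, 1} for
        majority-vote networks (entry ``R[i, j]`` is the influence of gene j on
        gene i); ``None`` for truth-table networks.
    p
        Per-gene perturbation probability in [0, 1).
    """

    gene_names: tuple[str, ...]
    regulators: tuple[tuple[int, ...], ...]
    truth_tables: tuple[np.ndarray, ...] | None = None
    majority_matrix: np.ndarray | None = None
    p: float = 0.01

    def __post_init__(self) -> None:
        n = len(self.gene_names)
        if len(self.regulators) != n:
            raise ConfigurationError("regulator list must have one entry per gene")
        if not 0.0 <= self.p < 1.0:
            raise ValueError(f"perturbation probability must be in [0, 1), got {self.p}")
        for i, regs in enumerate(self.regulators):
            if len(set(regs)) != len(regs):
                raise ConfigurationError(f"gene {i}: duplicate regulators {regs}")
            if any(not 0 <= g < n for g in regs):
                raise ConfigurationError(f"gene {i}: regulator index out of range in {regs}")
        if (self.truth_tables is None) == (self.majority_matrix is None):
            raise ConfigurationError("exactly one of truth_tables / majority_matrix required")
        if self.truth_tables is not None:
            if len(self.truth_tables) != n:
                raise ConfigurationError("need one truth table per gene")
            for i, tt in enumerate(self.truth_tables):
                if len(tt) != 2 ** len(self.regulators[i]):
                    raise ConfigurationError(
                        f"gene {i}: truth table length {len(tt)} != 2^{len(self.regulators[i])}"
                    )
                if not np.isin(np.asarray(tt), (0, 1)).all():
                    raise ConfigurationError(f"gene {i}: truth table outputs must be binary")
        else:
            R = np.asarray(self.majority_matrix)
            if R.shape != (n, n):
                raise ConfigurationError(f"majority matrix must be {n}x{n}, got {R.shape}")
            if not np.isin(R, (-1, 0, 1)).all():
                raise ConfigurationError("majority matrix entries must be in {-1, 0, 1}")

    @property
    def n(self) -> int:
        return len(self.gene_names)

    @property
    def n_states(self) -> int:
        return 2 ** self.n

    @classmethod
    def from_truth_tables(
        cls,
        regulators: Sequence[Sequence[int]],
        truth_tables: Sequence[Sequence[int]],
        p: float = 0.01,
        gene_names: Sequence[str] | None = None,
    ) -> "BooleanNetwork":
        n = len(regulators)
        names = tuple(gene_names) if gene_names is not None else tuple(f"X{i+1}" for i in range(n))
        return cls(
            gene_names=names,
            regulators=tuple(tuple(int(g) for g in regs) for regs in regulators),
            truth_tables=tuple(np.asarray(tt, dtype=np.int64) for tt in truth_tables),
            p=p,
        )

    @classmethod
    def from_majority(
        cls,
        R: np.ndarray,
        p: float = 0.01,
        gene_names: Sequence[str] | None = None,
    ) -> "BooleanNetwork":
        """Build a majority-vote network from a signed regulatory matrix.

        The stored regulator set of gene ``i`` is the set of genes with nonzero
        influence on it plus gene ``i`` itself, because the tie rule makes every
        update depend on the gene's own current value (the all-off context
        always ties).
        """
        R = np.asarray(R, dtype=np.int64)
        n = R.shape[0]
        names = tuple(gene_names) if gene_names is not None else tuple(f"X{i+1}" for i in range(n))
        regs = tuple(
            tuple(sorted(set(np.flatnonzero(R[i]).tolist()) | {i})) for i in range(n)
        )
        return cls(gene_names=names, regulators=regs, majority_matrix=R, p=p)


# ---------------------------------------------------------------------------
# Deterministic updates
# ---------------------------------------------------------------------------

def next_state_majority(R: np.ndarray, s: int) -> int:
    """One deterministic majority-vote step from decimal state ``s``.

    Gene i becomes 1 if ``sum_j R[i, j] * X_j > 0``, 0 if negative, and keeps
    its current value on a tie.
    """
    R = np.asarray(R)
    n = R.shape[0]
    bits = decode_state(s, n)
    score = R @ bits
    new = np.where(score > 0, 1, np.where(score < 0, 0, bits))
    return encode_state(new)


def next_state(net: BooleanNetwork, s: int) -> int:
    """One deterministic update step ``F(s)`` of the network."""
    if net.truth_tables is not None:
        bits = [
            int(net.truth_tables[i][context_index(s, net.regulators[i], net.n)])
            for i in range(net.n)
        ]
        return encode_state(bits)
    return next_state_majority(net.majority_matrix, s)


def transition_map(net: BooleanNetwork) -> np.ndarray:
    """Vector ``F`` with ``F[s]`` the deterministic successor of every state."""
    n, S = net.n, net.n_states
    states = np.arange(S)
    if net.truth_tables is not None:
        nxt = np.zeros(S, dtype=np.int64)
        for i in range(n):
            ctx = context_index(states, net.regulators[i], n)
            bit = np.asarray(net.truth_tables[i])[ctx]
            nxt |= bit << (n - 1 - i)
        return nxt
    return np.array([next_state_majority(net.majority_matrix, s) for s in states])


# ---------------------------------------------------------------------------
# Transition probability matrix and chain utilities
# ---------------------------------------------------------------------------

def bnp_tpm(net: BooleanNetwork) -> np.ndarray:
    """Transition probability matrix of the BNp.

    ``P[i, j] = (1 - p)**(n - d) * p**d`` where ``d`` is the Hamming distance
    between ``j`` and the deterministic successor ``F(i)``: the next state is
    ``F(X(t))`` perturbed gene-wise by independent Bernoulli(p) flips, so the
    no-flip branch has probability ``(1 - p)**n`` and any nonzero flip pattern
    gamma occurs with probability ``p**|gamma| (1 - p)**(n - |gamma|)``.  Rows
    sum to one by the binomial theorem.
    """
    n, p = net.n, net.p
    F = transition_map(net)
    d = np.bitwise_count(np.arange(net.n_states)[np.newaxis, :] ^ F[:, np.newaxis])
    return (1.0 - p) ** (n - d) * p ** d.astype(np.float64)


def steady_state(P: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Stationary distribution pi with ``pi^T P = pi^T``.

    Solves the linear system with the normalization constraint substituted for
    one balance equation.  Raises ``np.linalg.LinAlgError`` when the chain does
    not have a unique stationary distribution (reducible chain).
    """
    P = np.asarray(P, dtype=np.float64)
    S = P.shape[0]
    A = P.T - np.eye(S)
    A[-1, :] = 1.0
    b = np.zeros(S)
    b[-1] = 1.0
    try:
        pi = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rare path
        raise np.linalg.LinAlgError(f"chain appears reducible: {exc}") from exc
    resid = np.max(np.abs(pi @ P - pi))
    if resid > tol or pi.min() < -tol or not np.isfinite(pi).all():
        raise np.linalg.LinAlgError(
            f"no unique stationary distribution (residual {resid:.2e}, "
            f"min component {pi.min():.2e}); is the chain irreducible?"
        )
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def simulate_tpm(
    P: np.ndarray,
    steps: int,
    rng: np.random.Generator,
    init: int | None = None,
) -> np.ndarray:
    """Sample a trajectory of ``steps`` transitions from TPM ``P``.

    Returns the ``steps + 1`` visited decimal states.  The initial state is
    drawn uniformly unless given.
    """
    P = np.asarray(P)
    S = P.shape[0]
    cum = np.cumsum(P, axis=1)
    s = int(rng.integers(S)) if init is None else int(init)
    out = np.empty(steps + 1, dtype=np.int64)
    out[0] = s
    for t in range(steps):
        u = rng.random()
        s = int(np.searchsorted(cum[s], u, side="right"))
        if s >= S:  # guard against cumulative rounding
            s = S - 1
        out[t + 1] = s
    return out


def undesirable_states(n: int, fixed: dict[int, int]) -> np.ndarray:
    """All decimal states whose genes take the values in ``fixed`` (0-based index -> bit)."""
    states = np.arange(2 ** n)
    mask = np.ones(2 ** n, dtype=bool)
    for gene, bit in fixed.items():
        mask &= gene_bit(states, gene, n) == bit
    return states[mask]


# ---------------------------------------------------------------------------
# Random synthetic networks
# ---------------------------------------------------------------------------

def beta_shapes_from_moments(mean: float, var: float) -> tuple[float, float]:
    """Beta shape parameters (alpha, beta) with the given mean and variance."""
    if not 0 < mean < 1:
        raise ValueError("mean must be in (0, 1)")
    if not 0 < var < mean * (1 - mean):
        raise ValueError(f"variance must be in (0, {mean * (1 - mean)})")
    nu = mean * (1 - mean) / var - 1.0
    return mean * nu, (1 - mean) * nu


def random_bnp(
    n: int = 6,
    k: int = 2,
    bias_mean: float = 0.5,
    bias_var: float = 1e-4,
    p: float = 0.01,
    rng: np.random.Generator | int | None = None,
) -> BooleanNetwork:
    """Generate a random BNp under the synthetic-network protocol.

    Each gene receives ``k`` distinct regulators drawn uniformly from all genes
    (self-regulation allowed).  A per-gene bias — the probability that the
    Boolean function outputs 1 — is drawn from a Beta distribution with the
    given mean and variance (defaults: mean 0.5, variance 1e-4), and each
    truth-table entry is an independent Bernoulli(bias) draw.
    """
    if k >= n:
        raise ValueError(f"need k < n distinct regulators per gene (k={k}, n={n})")
    if k < 1:
        raise ValueError("each gene needs at least one regulator")
    rng = np.random.default_rng(rng)
    a, b = beta_shapes_from_moments(bias_mean, bias_var)
    regulators = []
    tables = []
    for _ in range(n):
        regs = np.sort(rng.choice(n, size=k, replace=False))
        bias = rng.beta(a, b)
        tt = (rng.random(2 ** k) < bias).astype(np.int64)
        regulators.append(tuple(int(g) for g in regs))
        tables.append(tt)
    return BooleanNetwork.from_truth_tables(regulators, tables, p=p)


# ---------------------------------------------------------------------------
# Fixtures: mutated mammalian cell cycle, TP53 pathway
# ---------------------------------------------------------------------------

def _table_from_function(fn: Callable[..., int], regs: Sequence[int]) -> np.ndarray:
    """Enumerate a truth table over regulator contexts (first regulator = MSB)."""
    k = len(regs)
    tt = np.zeros(2 ** k, dtype=np.int64)
    for ctx in range(2 ** k):
        bits = {regs[m]: (ctx >> (k - 1 - m)) & 1 for m in range(k)}
        tt[ctx] = int(bool(fn(bits)))
    return tt


def build_cell_cycle(p: float = 0.01) -> BooleanNetwork:
    """The 9-gene mutated mammalian cell-cycle Boolean network (p27 knocked out).

    Gene order: CycD, Rb, E2F, CycE, Cdc20, Cdh1, UbcH10, CycB, CycA
    (X_1 ... X_9).  CycD is an extracellular signal with no Boolean function;
    it is modeled as holding its value, with the BNp perturbation providing
    stochastic switching of the growth signal.
    """
    names = ("CycD", "Rb", "E2F", "CycE", "Cdc20", "Cdh1", "UbcH10", "CycB", "CycA")
    # 0-based gene indices: CycD=0, Rb=1, E2F=2, CycE=3, Cdc20=4, Cdh1=5,
    # UbcH10=6, CycB=7, CycA=8.
    defs: list[tuple[tuple[int, ...], Callable[[dict], int]]] = [
        ((0,), lambda b: b[0]),  # CycD: held extracellular input
        ((0, 3, 7, 8), lambda b: (not b[0]) and (not b[3]) and (not b[8]) and (not b[7])),  # Rb
        ((1, 7, 8), lambda b: (not b[1]) and (not b[8]) and (not b[7])),  # E2F
        ((1, 2), lambda b: b[2] and (not b[1])),  # CycE
        ((7,), lambda b: b[7]),  # Cdc20
        ((4, 7, 8), lambda b: ((not b[8]) and (not b[7])) or b[4]),  # Cdh1
        ((4, 5, 6, 7, 8), lambda b: (not b[5]) or (b[5] and b[6] and (b[4] or b[8] or b[7]))),  # UbcH10
        ((4, 5), lambda b: (not b[4]) and (not b[5])),  # CycB
        (
            (1, 2, 4, 5, 6, 8),
            lambda b: (b[2] and (not b[1]) and (not b[4]) and ((not b[5]) and (not b[6])))
            or (b[8] and (not b[1]) and (not b[4]) and (not (b[5] and b[6]))),
        ),  # CycA
    ]
    regulators = [regs for regs, _ in defs]
    tables = [_table_from_function(fn, regs) for regs, fn in defs]
    return BooleanNetwork.from_truth_tables(regulators, tables, p=p, gene_names=names)


TP53_GENES = ("DNA_DSBs", "MDM2", "TP53", "WIP1", "CHK2", "ATM")

#: Default signed regulatory matrix for the 6-node TP53 pathway model.
#: Synthetic reconstruction from the literature model this fixture emulates
#: (DSB activates ATM; WIP1 suppresses ATM and CHK2; ATM activates CHK2;
#: ATM and CHK2 activate TP53 while MDM2 and WIP1 suppress it; TP53 activates
#: WIP1; TP53 and WIP1 activate MDM2 while ATM suppresses it).  Override by
#: passing your own matrix to :func:`build_tp53`.
TP53_DEFAULT_R = np.array(
    [
        #  DSB MDM2 TP53 WIP1 CHK2 ATM
        [0, 0, 0, 0, 0, 0],      # DNA DSBs: external signal (held on ties)
        [0, 0, 1, 1, 0, -1],     # MDM2
        [0, -1, 0, -1, 1, 1],    # TP53
        [0, 0, 1, 0, 0, 0],      # WIP1
        [0, 0, 0, -1, 0, 1],     # CHK2
        [1, 0, 0, -1, 0, 0],     # ATM
    ],
    dtype=np.int64,
)


def build_tp53(R: np.ndarray | None = None, p: float = 0.01) -> BooleanNetwork:
    """The 6-node TP53 pathway BNp under the majority-vote rule.

    Genes X_1..X_6 are DNA_DSBs, MDM2, TP53, WIP1, CHK2, ATM.  ``R`` is the
    signed regulatory matrix (``R[i, j] = +1/-1`` for an activating/suppressive
    relation from gene j to gene i); the shipped default is a synthetic
    reconstruction of the published pathway diagram and can be overridden.
    """
    R = TP53_DEFAULT_R if R is None else np.asarray(R, dtype=np.int64)
    if R.shape != (6, 6):
        raise ConfigurationError(f"TP53 regulatory matrix must be 6x6, got {R.shape}")
    return BooleanNetwork.from_majority(R, p=p, gene_names=TP53_GENES)
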