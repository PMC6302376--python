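"""Conditional probability matrices and Beta uncertainty over unknown entries.

A Markovian regulatory network factorizes gene-wise: gene ``X_i`` with ``k_i``
regulators is described by a conditional probability matrix (CPM) of shape
``2**k_i x 2`` whose row ``j`` holds ``(Pr[X_i=0 | context j], Pr[X_i=1 |
context j])``.  The TPM entry for a transition ``i -> j`` is the product over
genes of the matching CPM entries.

Unknown conditional probabilities are modeled with independent conjugate
Beta priors on ``theta = Pr[X_i = 0 | context]`` (one degree of freedom per
row).  Observing a state trajectory adds simple event counts to the Beta
hyperparameters, and the *effective* TPM — the prior (or posterior) mean of
the uncertain TPM — is obtained by plugging posterior means into the product.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .networks import ConfigurationError, context_index, gene_bit

__all__ = [
    "CPMSet",
    "UncertainParam",
    "UncertaintyClass",
    "tpm_from_cpms",
    "cpms_from_tpm",
    "update_posteriors",
    "effective_tpm",
    "realize_cpms",
]


@dataclass(frozen=True)
class CPMSet:
    """Per-gene conditional probability matrices plus the regulator lists."""

    tables: tuple[np.ndarray, ...]
    regulators: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if len(self.tables) != len(self.regulators):
            raise ConfigurationError("need one CPM per regulator list")
        for i, (tab, regs) in enumerate(zip(self.tables, self.regulators)):
            if tab.shape != (2 ** len(regs), 2):
                raise ConfigurationError(
                    f"gene {i}: CPM shape {tab.shape} != (2^{len(regs)}, 2)"
                )
            if tab.min() < -1e-12 or tab.max() > 1 + 1e-12:
                raise ConfigurationError(f"gene {i}: CPM entries outside [0, 1]")
            if np.abs(tab.sum(axis=1) - 1.0).max() > 1e-10:
                raise ConfigurationError(f"gene {i}: CPM rows must sum to 1")

    @property
    def n(self) -> int:
        return len(self.tables)

    def copy_tables(self) -> list[np.ndarray]:
        return [t.copy() for t in self.tables]

    def with_entry(self, gene: int, row: int, prob_zero: float) -> "CPMSet":
        """A copy with row ``row`` of gene ``gene`` set to ``(theta, 1 - theta)``."""
        tables = self.copy_tables()
        tables[gene][row] = (prob_zero, 1.0 - prob_zero)
        return CPMSet(tuple(tables), self.regulators)


def tpm_from_cpms(cpms: CPMSet) -> np.ndarray:
    """Assemble the TPM from per-gene CPMs.

    ``P[i, j] = prod_k C_k[context_k(i), bit_k(j)]`` by conditional
    independence of the genes given the full source state.
    """
    n = cpms.n
    S = 2 ** n
    states = np.arange(S)
    P = np.ones((S, S))
    for k in range(n):
        ctx = context_index(states, cpms.regulators[k], n)
        bits = gene_bit(states, k, n)
        P *= cpms.tables[k][np.asarray(ctx)[:, None], np.asarray(bits)[None, :]]
    return P


def cpms_from_tpm(P: np.ndarray, regulators: Sequence[Sequence[int]]) -> CPMSet:
    """Extract per-gene CPMs from a TPM.

    For gene ``X_i`` and regulator context ``j``, ``C[j, 0]`` is the total mass
    that rows with that context place on destination states with ``X_i = 0``;
    when several source states share the context, the values are averaged.
    """
    P = np.asarray(P, dtype=np.float64)
    S = P.shape[0]
    n = len(regulators)
    if S != 2 ** n:
        raise ConfigurationError(f"TPM size {S} does not match {n} genes")
    states = np.arange(S)
    tables = []
    for i, regs in enumerate(regulators):
        k = len(regs)
        dest_zero = gene_bit(states, i, n) == 0
        mass0 = P[:, dest_zero].sum(axis=1)
        mass1 = P[:, ~dest_zero].sum(axis=1)
        ctx = np.asarray(context_index(states, regs, n))
        tab = np.zeros((2 ** k, 2))
        for j in range(2 ** k):
            sel = ctx == j
            if not sel.any():  # unreachable for full state spaces; guard anyway
                raise ConfigurationError(f"gene {i}: context {j} never occurs")
            tab[j, 0] = mass0[sel].mean()
            tab[j, 1] = mass1[sel].mean()
        tables.append(tab)
    return CPMSet(tuple(tables), tuple(tuple(int(g) for g in regs) for regs in regulators))


# ---------------------------------------------------------------------------
# Uncertainty class
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UncertainParam:
    """One unknown conditional probability ``theta = Pr[X_gene = 0 | context row]``.

    ``alpha`` counts (pseudo-)observations of ``X_gene = 0`` in the context and
    ``beta`` of ``X_gene = 1``.  Once an experiment reveals the true value it is
    stored in ``value`` and the parameter no longer contributes uncertainty.
    """

    gene: int
    row: int
    alpha: float
    beta: float
    value: float | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError(f"Beta shapes must be positive, got ({self.alpha}, {self.beta})")
        if self.value is not None and not 0.0 <= self.value <= 1.0:
            raise ValueError(f"revealed value must be in [0, 1], got {self.value}")

    @property
    def revealed(self) -> bool:
        return self.value is not None

    @property
    def posterior_mean(self) -> float:
        """Beta posterior mean ``alpha / (alpha + beta)``."""
        return self.alpha / (self.alpha + self.beta)

    @property
    def plug_in(self) -> float:
        """Value used when building the effective TPM: revealed value or posterior mean."""
        return self.value if self.value is not None else self.posterior_mean


@dataclass(frozen=True)
class UncertaintyClass:
    """Independent Beta-distributed unknown conditional probabilities."""

    params: tuple[UncertainParam, ...]

    def __post_init__(self) -> None:
        seen = set()
        for p in self.params:
            key = (p.gene, p.row)
            if key in seen:
                raise ConfigurationError(f"duplicate uncertain parameter at {key}")
            seen.add(key)

    @classmethod
    def uniform(cls, positions: Sequence[tuple[int, int]]) -> "UncertaintyClass":
        """Beta(1, 1) (uniform) priors at the given (gene, CPM row) positions."""
        return cls(tuple(UncertainParam(g, r, 1.0, 1.0) for g, r in positions))

    def __len__(self) -> int:
        return len(self.params)

    @property
    def free_indices(self) -> tuple[int, ...]:
        """Indices of parameters that are still uncertain (not revealed)."""
        return tuple(i for i, p in enumerate(self.params) if not p.revealed)

    @property
    def num_uncertain(self) -> int:
        return len(self.free_indices)

    def condition_on(self, index: int, value: float) -> "UncertaintyClass":
        """Remove parameter ``index`` from the uncertainty by fixing it to ``value``."""
        if not 0 <= index < len(self.params):
            raise IndexError(f"parameter index {index} out of range")
        params = list(self.params)
        params[index] = replace(params[index], value=float(value))
        return UncertaintyClass(tuple(params))

    def sample_theta(self, rng: np.random.Generator) -> np.ndarray:
        """Draw a full realization: revealed values as-is, free ones from their Beta."""
        out = np.empty(len(self.params))
        for i, p in enumerate(self.params):
            out[i] = p.value if p.revealed else rng.beta(p.alpha, p.beta)
        return out


def update_posteriors(
    unc: UncertaintyClass,
    trajectory: Sequence[int],
    regulators: Sequence[Sequence[int]],
    n: int | None = None,
) -> UncertaintyClass:
    """Conjugate posterior update from an observed state trajectory.

    For each unrevealed parameter at (gene i, context j), alpha gains one count
    per transition whose source state shows context j and whose destination has
    ``X_i = 0``; beta gains the ``X_i = 1`` counts.
    """
    traj = np.asarray(trajectory, dtype=np.int64)
    n = len(regulators) if n is None else n
    if traj.size and (traj.min() < 0 or traj.max() >= 2 ** n):
        bad = int(np.flatnonzero((traj < 0) | (traj >= 2 ** n))[0])
        raise ValueError(f"trajectory state out of range at position {bad}: {traj[bad]}")
    if traj.size < 2:
        return unc
    src, dst = traj[:-1], traj[1:]
    params = list(unc.params)
    for idx, p in enumerate(params):
        if p.revealed:
            continue
        ctx = np.asarray(context_index(src, regulators[p.gene], n))
        match = ctx == p.row
        zeros = gene_bit(dst, p.gene, n) == 0
        a_add = int(np.sum(match & zeros))
        b_add = int(np.sum(match & ~zeros))
        params[idx] = replace(p, alpha=p.alpha + a_add, beta=p.beta + b_add)
    return UncertaintyClass(tuple(params))


def effective_tpm(cpms: CPMSet, unc: UncertaintyClass) -> np.ndarray:
    """The effective TPM: expectation of the uncertain TPM under the prior.

    Because the unknown parameters are independent and enter the gene-wise
    product linearly, the expectation passes inside the product: each unknown
    CPM row is replaced by its Beta posterior mean (or revealed value) and the
    TPM is assembled as usual.  Known entries are used as-is.
    """
    tables = cpms.copy_tables()
    for p in unc.params:
        if p.gene >= cpms.n or p.row >= tables[p.gene].shape[0]:
            raise ConfigurationError(
                f"uncertain parameter (gene {p.gene}, row {p.row}) outside the CPM set"
            )
        v = p.plug_in
        tables[p.gene][p.row] = (v, 1.0 - v)
    return tpm_from_cpms(CPMSet(tuple(tables), cpms.regulators))


def realize_cpms(cpms: CPMSet, unc: UncertaintyClass, theta: Sequence[float]) -> CPMSet:
    """Plug a concrete realization ``theta`` (aligned with ``unc.params``) into the CPMs."""
    theta = np.asarray(theta, dtype=np.float64)
    if theta.shape != (len(unc.params),):
        raise ValueError("theta must have one value per uncertain parameter")
    tables = cpms.copy_tables()
    for p, v in zip(unc.params, theta):
        tables[p.gene][p.row] = (v, 1.0 - v)
    return CPMSet(tuple(tables), cpms.regulators)
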