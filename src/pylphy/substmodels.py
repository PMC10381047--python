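"""Instantaneous rate matrices and transition probabilities.

All constructors return a :class:`RateMatrix` normalized so that the
expected number of substitutions per site per unit time is one
(``-sum_i pi_i Q_ii = 1``), which makes clock rates directly interpretable
as substitutions per site per time unit.  Every model here is
time-reversible, so ``pi_i Q_ij = pi_j Q_ji``.

Models:

* :func:`jukes_cantor` — 4-state, equal frequencies and exchange rates.
* :func:`hky` — transitions (A<->G, C<->T) scaled by ``kappa`` relative to
  transversions, arbitrary base frequencies.
* :func:`gtr` — general time-reversible model with 6 relative rates in the
  order (AC, AG, AT, CG, CT, GT).
* :func:`gt16` — 16-state model over phased diploid genotypes (AA, AC, ...,
  TT; AC and CA distinct).  Genotypes differing at exactly one allele
  exchange at the corresponding nucleotide GTR rate times the target
  genotype frequency; simultaneous changes at both alleles are forbidden
  (rate 0).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm as _scipy_expm

from .errors import InvalidParameter

__all__ = [
    "NUCLEOTIDES",
    "GENOTYPES",
    "RateMatrix",
    "jukes_cantor",
    "hky",
    "gtr",
    "gt16",
    "transition_probs",
]

NUCLEOTIDES = ("A", "C", "G", "T")
#: Phased diploid genotypes, row-major over (maternal, paternal) alleles.
GENOTYPES = tuple(a + b for a in NUCLEOTIDES for b in NUCLEOTIDES)

# index pairs for the canonical 6-rate order (AC, AG, AT, CG, CT, GT)
_PAIR_ORDER = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


class RateMatrix:
    """A normalized reversible CTMC rate matrix with its stationary
    frequencies."""

    def __init__(self, states, Q, pi, name: str = "custom"):
        self.states = tuple(states)
        self.Q = np.asarray(Q, dtype=float)
        self.pi = np.asarray(pi, dtype=float)
        self.name = name
        k = len(self.states)
        if self.Q.shape != (k, k) or self.pi.shape != (k,):
            raise InvalidParameter("rate matrix dimensions inconsistent with states")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def expected_rate(self) -> float:
        """Expected substitutions per unit time: -sum_i pi_i Q_ii."""
        return float(-np.dot(self.pi, np.diag(self.Q)))

    def __eq__(self, other):
        return (
            isinstance(other, RateMatrix)
            and self.states == other.states
            and np.allclose(self.Q, other.Q, atol=1e-12)
            and np.allclose(self.pi, other.pi, atol=1e-12)
        )

    def __repr__(self):
        return f"RateMatrix({self.name}, {self.n_states} states)"


def _finalize(states, Q, pi, name) -> RateMatrix:
    """Fill the diagonal, normalize to one expected substitution per unit
    time, and wrap."""
    Q = Q.copy()
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -np.dot(pi, np.diag(Q))
    if mean_rate <= 0:
        raise InvalidParameter(f"{name}: degenerate rate matrix (zero total rate)")
    return RateMatrix(states, Q / mean_rate, pi, name)


def _check_simplex(freq, k, name):
    freq = np.asarray(freq, dtype=float)
    if freq.shape != (k,):
        raise InvalidParameter(f"{name}: freq must have length {k}, got {freq.shape}")
    if np.any(freq < 0):
        raise InvalidParameter(f"{name}: freq entries must be >= 0")
    if abs(freq.sum() - 1.0) > 1e-8:
        raise InvalidParameter(f"{name}: freq must sum to 1, got {freq.sum()}")
    return freq


def jukes_cantor() -> RateMatrix:
    """Jukes-Cantor model: equal frequencies, equal exchange rates."""
    pi = np.full(4, 0.25)
    Q = np.ones((4, 4))
    return _finalize(NUCLEOTIDES, Q, pi, "JC")


def hky(kappa: float, freq) -> RateMatrix:
    """HKY model: transition/transversion ratio ``kappa``."""
    if kappa <= 0:
        raise InvalidParameter(f"hky: kappa must be > 0, got {kappa}")
    pi = _check_simplex(freq, 4, "hky")
    Q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            rate = kappa if (i, j) in transitions else 1.0
            Q[i, j] = rate * pi[j]
    return _finalize(NUCLEOTIDES, Q, pi, "HKY")


def gtr(rates, freq) -> RateMatrix:
    """General time-reversible model; ``rates`` ordered (AC, AG, AT, CG, CT, GT)."""
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (6,):
        raise InvalidParameter(f"gtr: rates must have length 6, got {rates.shape}")
    if np.any(rates <= 0):
        raise InvalidParameter("gtr: rates must be > 0")
    pi = _check_simplex(freq, 4, "gtr")
    Q = np.zeros((4, 4))
    for r, (i, j) in zip(rates, _PAIR_ORDER):
        Q[i, j] = r * pi[j]
        Q[j, i] = r * pi[i]
    return _finalize(NUCLEOTIDES, Q, pi, "GTR")


def gt16(rates, freq) -> RateMatrix:
    """GT16 model on phased diploid genotypes.

    ``rates`` are the 6 nucleotide exchangeabilities (AC, AG, AT, CG, CT,
    GT); ``freq`` is a 16-simplex over genotypes in :data:`GENOTYPES` order.
    A change affects one allele at a time, at the nucleotide rate for that
    allele pair times the frequency of the *target genotype*.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (6,):
        raise InvalidParameter(f"gt16: rates must have length 6, got {rates.shape}")
    if np.any(rates <= 0):
        raise InvalidParameter("gt16: rates must be > 0")
    pi = _check_simplex(freq, 16, "gt16")
    R = np.zeros((4, 4))  # symmetric nucleotide exchangeability lookup
    for r, (i, j) in zip(rates, _PAIR_ORDER):
        R[i, j] = R[j, i] = r
    Q = np.zeros((16, 16))
    for g in range(16):
        a, b = divmod(g, 4)
        for h in range(16):
            c, d = divmod(h, 4)
            if a == c and b != d:  # paternal allele changes
                Q[g, h] = R[b, d] * pi[h]
            elif b == d and a != c:  # maternal allele changes
                Q[g, h] = R[a, c] * pi[h]
    return _finalize(GENOTYPES, Q, pi, "GT16")


def transition_probs(model: RateMatrix, t: float) -> np.ndarray:
    """Transition probability matrix ``P = exp(Q t)``.

    Uses an eigendecomposition of the symmetrized reversible form
    ``diag(sqrt(pi)) Q diag(1/sqrt(pi))`` when all frequencies are positive,
    falling back to a general matrix exponential otherwise.
    """
    if t < 0:
        raise InvalidParameter(f"time must be >= 0, got {t}")
    if np.all(model.pi > 0):
        sq = np.sqrt(model.pi)
        B = (sq[:, None] * model.Q) / sq[None, :]
        B = 0.5 * (B + B.T)  # enforce exact symmetry
        w, V = np.linalg.eigh(B)
        P = (V * np.exp(w * t)) @ V.T
        P = P / sq[:, None] * sq[None, :]
    else:
        P = _scipy_expm(model.Q * t)
    P = np.clip(P, 0.0, 1.0)
    P /= P.sum(axis=1, keepdims=True)
    return P
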