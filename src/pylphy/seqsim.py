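"""Sequence simulation along time trees.

:func:`phylo_ctmc` simulates a multiple sequence alignment down a
:class:`~pylphy.trees.TimeTree` under a CTMC substitution model and a
molecular clock.  Root states are drawn IID from the stationary frequencies
``pi``; along each branch every site evolves independently with transition
matrix ``P = exp(Q * rate * duration)``, where the rate is the strict-clock
rate ``mu`` or the branch's own rate under a relaxed clock.  One transition
matrix is computed per branch (not per site).

:func:`gt16_error` applies the single-cell observation channel to a phased
genotype alignment: with probability ``delta`` one allele of the genotype
drops out (allelic dropout, the cell is read as a homozygote of the
retained allele, chosen uniformly), and independently every surviving
allele is mis-read to one of the three other nucleotides with total
probability ``epsilon``.  The induced 16 x 16 channel matrix is
row-stochastic and is exposed via :func:`gt16_error_matrix` for testing
against empirical observation frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameter, RateLengthMismatch
from .substmodels import GENOTYPES, NUCLEOTIDES, RateMatrix, transition_probs
from .trees import Taxa, TimeTree

__all__ = [
    "DataType",
    "NUCLEOTIDE",
    "PHASED_GENOTYPE",
    "Alignment",
    "ClockSpec",
    "phylo_ctmc",
    "assign_branch_rates",
    "gt16_error",
    "gt16_error_matrix",
    "partition_by_codon",
]


@dataclass(frozen=True)
class DataType:
    name: str
    symbols: tuple

    @property
    def n_states(self) -> int:
        return len(self.symbols)


NUCLEOTIDE = DataType("nucleotide", NUCLEOTIDES)
PHASED_GENOTYPE = DataType("phasedGenotype", GENOTYPES)


class Alignment:
    """taxa x sites matrix of state indices over a declared data type."""

    def __init__(self, taxa: Taxa, states, datatype: DataType = NUCLEOTIDE):
        self.taxa = taxa
        self.states = np.asarray(states, dtype=np.int16)
        self.datatype = datatype
        if self.states.ndim != 2 or self.states.shape[0] != len(taxa):
            raise InvalidParameter(
                f"states matrix {self.states.shape} does not match {len(taxa)} taxa"
            )
        if self.states.size and (
            self.states.min() < 0 or self.states.max() >= datatype.n_states
        ):
            raise InvalidParameter(f"state index out of range for {datatype.name}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def L(self) -> int:
        return self.states.shape[1]

    def nchar(self) -> int:
        return self.L

    def sequence(self, i: int) -> str:
        return "".join(self.datatype.symbols[s] for s in self.states[i])

    def sequences(self) -> dict:
        return {name: self.sequence(i) for i, name in enumerate(self.taxa.names)}

    def __eq__(self, other):
        return (
            isinstance(other, Alignment)
            and self.datatype.name == other.datatype.name
            and self.taxa.names == other.taxa.names
            and np.array_equal(self.states, other.states)
        )

    def __repr__(self):
        return f"Alignment({self.n_taxa} x {self.L}, {self.datatype.name})"


@dataclass
class ClockSpec:
    """Molecular clock: strict (one rate ``mu``) or relaxed (one positive
    rate per branch, in the tree's canonical branch order)."""

    mode: str = "strict"  # "strict" | "relaxed"
    mu: float = 1.0
    branch_rates: np.ndarray | None = field(default=None)

    def __post_init__(self):
        if self.mode not in ("strict", "relaxed"):
            raise InvalidParameter(f"unknown clock mode {self.mode!r}")
        if self.mode == "strict" and self.mu <= 0:
            raise InvalidParameter(f"clock rate mu must be > 0, got {self.mu}")
        if self.mode == "relaxed":
            if self.branch_rates is None:
                raise InvalidParameter("relaxed clock requires branch rates")
            self.branch_rates = np.asarray(self.branch_rates, dtype=float)
            if np.any(self.branch_rates <= 0):
                raise InvalidParameter("branch rates must be > 0")


def assign_branch_rates(tree: TimeTree, rates) -> ClockSpec:
    """Deterministically assign the i-th rate to the i-th branch in the
    canonical branch order (post-order, children sorted by smallest
    descendant leaf label)."""
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    if rates.size != tree.n_branches:
        raise RateLengthMismatch(
            f"tree has {tree.n_branches} branches but {rates.size} rates given"
        )
    return ClockSpec(mode="relaxed", branch_rates=rates)


def phylo_ctmc(
    tree: TimeTree,
    Q: RateMatrix,
    L: int,
    clock: ClockSpec | None = None,
    datatype: DataType | None = None,
    rng: np.random.Generator | None = None,
) -> Alignment:
    """Simulate an alignment of ``L`` sites on ``tree`` under model ``Q``."""
    L = int(L)
    if L < 1:
        raise InvalidParameter(f"L must be >= 1, got {L}")
    if tree.n_leaves < 2:
        raise InvalidParameter("tree must have >= 2 leaves")
    if clock is None:
        clock = ClockSpec()
    if datatype is None:
        datatype = PHASED_GENOTYPE if Q.n_states == 16 else NUCLEOTIDE
    if datatype.n_states != Q.n_states:
        raise InvalidParameter(
            f"data type {datatype.name} has {datatype.n_states} states but Q has {Q.n_states}"
        )
    if rng is None:
        rng = np.random.default_rng()

    if clock.mode == "relaxed":
        branches = tree.canonical_branches()
        if clock.branch_rates.size != len(branches):
            raise RateLengthMismatch(
                f"tree has {len(branches)} branches but "
                f"{clock.branch_rates.size} rates given"
            )
        rate_of = {id(node): r for node, r in zip(branches, clock.branch_rates)}
    else:
        rate_of = None

    states: dict[int, np.ndarray] = {}
    root_state = _draw_categorical(np.tile(Q.pi, (L, 1)), rng)
    states[id(tree.root)] = root_state

    # preorder: parents are always simulated before children
    for node in tree.nodes():
        for child in node.children:
            duration = node.age - child.age
            rate = clock.mu if rate_of is None else rate_of[id(child)]
            P = transition_probs(Q, rate * duration)
            parent_states = states[id(node)]
            states[id(child)] = _draw_categorical(P[parent_states], rng)

    leaves = {str(n.label): n for n in tree.leaves()}
    if tree.taxa is not None and set(tree.taxa.names) == set(leaves):
        taxa = tree.taxa
        order = [leaves[name] for name in taxa.names]
    else:
        order = tree.leaves()
        taxa = Taxa([str(n.label) for n in order], [n.age for n in order])
    matrix = np.vstack([states[id(n)] for n in order])
    return Alignment(taxa, matrix, datatype)


def _draw_categorical(P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-wise categorical draw: P is (m, k), one draw per row."""
    cum = np.cumsum(P, axis=1)
    u = rng.random(P.shape[0])
    return (u[:, None] < cum).argmax(axis=1).astype(np.int16)


# ---------------------------------------------------------------------------
# GT16 single-cell observation channel
# ---------------------------------------------------------------------------


def _misread_prob(x: int, y: int, epsilon: float) -> float:
    return 1.0 - epsilon if x == y else epsilon / 3.0


def gt16_error_matrix(epsilon: float, delta: float) -> np.ndarray:
    """The 16 x 16 observation matrix: entry (g, h) is the probability of
    reading genotype ``h`` from true genotype ``g``.

    Built by enumerating allele outcomes: dropout (probability ``delta``)
    keeps one allele uniformly and reports its (possibly mis-read)
    homozygote; otherwise both alleles are mis-read independently.
    """
    if not (0.0 <= epsilon <= 1.0):
        raise InvalidParameter(f"epsilon must be in [0, 1], got {epsilon}")
    if not (0.0 <= delta <= 1.0):
        raise InvalidParameter(f"delta must be in [0, 1], got {delta}")
    E = np.zeros((16, 16))
    for g in range(16):
        a, b = divmod(g, 4)
        for h in range(16):
            c, d = divmod(h, 4)
            p = (1.0 - delta) * _misread_prob(a, c, epsilon) * _misread_prob(b, d, epsilon)
            if c == d:
                p += delta * 0.5 * (
                    _misread_prob(a, c, epsilon) + _misread_prob(b, c, epsilon)
                )
            E[g, h] = p
    return E


def apply_channel(states: np.ndarray, channel: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Map true states through a row-stochastic channel using pre-drawn
    uniforms ``u`` (same shape as ``states``): a memoryless per-cell
    operation, so any site-wise slicing with matching ``u`` slices commutes
    with whole-alignment application."""
    cum = np.cumsum(channel, axis=1)
    return (u[..., None] < cum[states]).argmax(axis=-1).astype(np.int16)


def gt16_error(
    alignment: Alignment,
    epsilon: float,
    delta: float,
    rng: np.random.Generator,
) -> Alignment:
    """Apply the GT16 single-cell error channel to a phased-genotype
    alignment, returning the observed noisy alignment."""
    if alignment.datatype.name != "phasedGenotype":
        raise InvalidParameter(
            f"gt16 error model requires a phased-genotype alignment, got {alignment.datatype.name}"
        )
    channel = gt16_error_matrix(epsilon, delta)
    u = rng.random(alignment.states.shape)
    observed = apply_channel(alignment.states, channel, u)
    return Alignment(alignment.taxa, observed, alignment.datatype)


def partition_by_codon(source: Alignment) -> list[Alignment]:
    """Split an alignment into three alignments holding codon positions 1,
    2 and 3 (reading frame starting at the first site)."""
    if source.L < 3:
        raise InvalidParameter(f"need >= 3 sites to partition by codon, got {source.L}")
    return [
        Alignment(source.taxa, source.states[:, pos::3], source.datatype)
        for pos in range(3)
    ]
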