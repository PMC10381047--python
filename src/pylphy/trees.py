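"""Time trees and generative tree priors.

A :class:`TimeTree` is a rooted binary tree whose nodes carry ages measured
in time before the present (age 0.0 = now).  Tips may be sampled serially
(heterochronous tips with positive ages) and may carry deme labels when the
tree was generated under a structured process.

Implemented tree priors:

* :func:`coalescent` — constant-population-size Kingman coalescent,
  generalized to serially sampled tips: while ``k`` lineages are active they
  coalesce at rate ``k(k-1)/(2*theta)``, and lineages enter the active set
  at their sampling ages.
* :func:`structured_coalescent` — multi-deme coalescent with migration,
  simulated with a Gillespie event loop; the deme in which each coalescence
  occurs is recorded on the internal node.
* :func:`skyline_coalescent` — piecewise-constant population size changing
  at coalescent events; ``groupSizes`` counts intervals from the tips.
* :func:`yule` — pure-birth tree on ``n`` extant tips, generated backward
  with interval durations Exp(k*lambda) while k lineages remain (equivalent
  to observing the forward birth process during its n-lineage sojourn).
* :func:`birth_death` — reconstructed birth-death tree conditioned on ``n``
  extant tips (optionally also on the root age), using the conditioned
  reconstructed process: internal node ages are drawn from their known
  closed-form density and attached to a uniformly chosen ranked topology.
* :func:`birth_death_serial` — forward birth-death simulation from a fixed
  root age with through-time sampling of extinct lineages (rate ``psi``)
  and Bernoulli(``rho``) sampling of extant tips.
"""

from __future__ import annotations

import numpy as np

from .errors import (
    InvalidParameter,
    LengthMismatch,
    GroupSizeMismatch,
    NonConvergence,
    SimulationFailed,
    TooFewTaxa,
)

__all__ = [
    "Taxa",
    "TreeNode",
    "TimeTree",
    "MigrationMatrix",
    "coalescent",
    "structured_coalescent",
    "skyline_coalescent",
    "yule",
    "birth_death",
    "birth_death_serial",
    "migration_matrix",
]

_EVENT_CAP = 1_000_000


class Taxa:
    """A set of named samples with ages (time before present) and optional
    deme labels."""

    def __init__(self, names, ages=None, demes=None):
        self.names = [str(n) for n in names]
        if len(set(self.names)) != len(self.names):
            raise InvalidParameter("taxon names must be unique")
        if ages is None:
            ages = [0.0] * len(self.names)
        self.ages = [float(a) for a in ages]
        if len(self.ages) != len(self.names):
            raise LengthMismatch(
                f"{len(self.names)} names but {len(self.ages)} ages"
            )
        if any(a < 0 for a in self.ages):
            raise InvalidParameter("taxon ages must be >= 0")
        if demes is not None:
            demes = [str(d) for d in demes]
            if len(demes) != len(self.names):
                raise LengthMismatch(
                    f"{len(self.names)} names but {len(demes)} deme labels"
                )
        self.demes = demes

    @classmethod
    def contemporaneous(cls, n: int) -> "Taxa":
        return cls([str(i + 1) for i in range(int(n))])

    def __len__(self) -> int:
        return len(self.names)

    @classmethod
    def coerce(cls, value) -> "Taxa":
        """Accept a Taxa object or a bare vector of names (ages all 0)."""
        if isinstance(value, cls):
            return value
        return cls([str(x) for x in np.atleast_1d(value)])

    def __eq__(self, other):
        return (
            isinstance(other, Taxa)
            and self.names == other.names
            and self.ages == other.ages
            and self.demes == other.demes
        )

    def __repr__(self):
        return f"Taxa(n={len(self)})"


class TreeNode:
    __slots__ = ("label", "age", "children", "parent", "deme")

    def __init__(self, age, label=None, children=(), deme=None):
        self.age = float(age)
        self.label = label
        self.children = list(children)
        self.parent = None
        self.deme = deme
        for c in self.children:
            c.parent = self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)


class TimeTree:
    """Rooted binary time tree."""

    def __init__(self, root: TreeNode, taxa: Taxa | None = None):
        self.root = root
        self.taxa = taxa

    # -- traversal --------------------------------------------------------
    def nodes(self):
        """All nodes, preorder."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self):
        return [n for n in self.nodes() if n.is_leaf]

    def internal_nodes(self):
        return [n for n in self.nodes() if not n.is_leaf]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    @property
    def n_branches(self) -> int:
        """Number of branches: one per non-root node (2n-2 for binary)."""
        return sum(1 for n in self.nodes()) - 1

    @property
    def root_age(self) -> float:
        return self.root.age

    def oldest_tip_age(self) -> float:
        return max(n.age for n in self.leaves())

    def total_branch_length(self) -> float:
        return sum(n.parent.age - n.age for n in self.nodes() if n.parent is not None)

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        return all(abs(n.age) <= tol for n in self.leaves())

    def validate(self) -> None:
        """Check structural invariants; raises InvalidParameter on violation."""
        for node in self.nodes():
            for child in node.children:
                if child.age > node.age + 1e-12:
                    raise InvalidParameter(
                        f"child age {child.age} exceeds parent age {node.age}"
                    )
        n = self.n_leaves
        if len(self.internal_nodes()) != n - 1:
            raise InvalidParameter("tree is not strictly binary")

    def canonical_branches(self):
        """Non-root nodes in the canonical order used for branch-rate
        assignment: post-order, children visited in order of their smallest
        descendant leaf label."""
        order: list[TreeNode] = []

        def smallest_leaf(node) -> str:
            if node.is_leaf:
                return str(node.label)
            return min(smallest_leaf(c) for c in node.children)

        def walk(node):
            for child in sorted(node.children, key=smallest_leaf):
                walk(child)
            if node.parent is not None:
                order.append(node)

        walk(self.root)
        return order

    # -- serialization ----------------------------------------------------
    def to_newick(self, include_demes: bool = False, precision: int = 17) -> str:
        def fmt(x: float) -> str:
            return f"{x:.{precision}g}"

        def label_of(node) -> str:
            lab = "" if node.label is None else str(node.label)
            if any(ch in lab for ch in " (),:;[]'\t\n"):
                lab = "'" + lab.replace("'", "''") + "'"
            if include_demes and node.deme is not None:
                lab += f"[&deme={node.deme}]"
            return lab

        def render(node) -> str:
            if node.is_leaf:
                core = label_of(node)
            else:
                core = "(" + ",".join(render(c) for c in node.children) + ")" + label_of(node)
            if node.parent is None:
                return core
            return core + ":" + fmt(node.parent.age - node.age)

        return render(self.root) + ";"

    def __repr__(self):
        return f"TimeTree(n_leaves={self.n_leaves}, root_age={self.root_age:.4g})"


def _tips_from_taxa(taxa: Taxa) -> list[TreeNode]:
    tips = []
    for i, name in enumerate(taxa.names):
        deme = taxa.demes[i] if taxa.demes is not None else None
        tips.append(TreeNode(taxa.ages[i], label=name, deme=deme))
    return tips


def _join(a: TreeNode, b: TreeNode, age: float, deme=None) -> TreeNode:
    return TreeNode(age, children=(a, b), deme=deme)


# ---------------------------------------------------------------------------
# Coalescent family
# ---------------------------------------------------------------------------


def coalescent(theta: float, taxa: Taxa, rng: np.random.Generator) -> TimeTree:
    """Serially sampled constant-population-size coalescent."""
    if theta <= 0:
        raise InvalidParameter(f"theta must be > 0, got {theta}")
    return _serial_coalescent(taxa, rng, theta_of_interval=lambda j: theta)


def skyline_coalescent(theta, group_sizes, taxa: Taxa, rng: np.random.Generator) -> TimeTree:
    """Coalescent with piecewise-constant population size.

    ``group_sizes[g]`` is the number of consecutive coalescent intervals
    (counted from the tips) that share population size ``theta[g]``.
    """
    theta = [float(t) for t in np.atleast_1d(theta)]
    group_sizes = [int(g) for g in np.atleast_1d(group_sizes)]
    if len(theta) != len(group_sizes):
        raise GroupSizeMismatch(
            f"{len(theta)} theta values but {len(group_sizes)} group sizes"
        )
    if any(g < 1 for g in group_sizes):
        raise GroupSizeMismatch("group sizes must be positive integers")
    if any(t <= 0 for t in theta):
        raise InvalidParameter("theta entries must be > 0")
    n = len(taxa)
    if sum(group_sizes) != n - 1:
        raise GroupSizeMismatch(
            f"group sizes sum to {sum(group_sizes)} but {n} taxa imply {n - 1} intervals"
        )
    # interval j (1-based from the tips) -> theta of its group
    per_interval: list[float] = []
    for t, g in zip(theta, group_sizes):
        per_interval.extend([t] * g)

    return _serial_coalescent(taxa, rng, theta_of_interval=lambda j: per_interval[j - 1])


def _serial_coalescent(taxa: Taxa, rng, theta_of_interval) -> TimeTree:
    """Shared event loop: coalesce active lineages at rate k(k-1)/(2 theta),
    activating tips at their sampling ages; theta may depend on the index of
    the coalescent interval (1-based, counted from the tips)."""
    if len(taxa) < 2:
        raise TooFewTaxa(f"coalescent needs >= 2 taxa, got {len(taxa)}")
    tips = _tips_from_taxa(taxa)
    pending = sorted(tips, key=lambda n: n.age)
    t = pending[0].age
    active: list[TreeNode] = []
    while pending and pending[0].age <= t:
        active.append(pending.pop(0))
    n_coal = 0
    while active or pending:
        if len(active) + len(pending) == 1:
            break
        k = len(active)
        if k >= 2:
            theta = theta_of_interval(n_coal + 1)
            rate = k * (k - 1) / (2.0 * theta)
            wait = rng.exponential(1.0 / rate)
            t_next = t + wait
        else:
            t_next = np.inf
        if pending and pending[0].age <= t_next:
            t = pending[0].age
            while pending and pending[0].age <= t:
                active.append(pending.pop(0))
            continue
        t = t_next
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        for node in sorted((i, j), reverse=True):
            active.pop(node)
        active.append(_join(a, b, t))
        n_coal += 1
    tree = TimeTree(active[0], taxa)
    return tree


class MigrationMatrix:
    """K x K matrix: diagonal = per-deme population sizes theta, off-diagonal
    = migration rates (backwards in time, from row deme to column deme)."""

    def __init__(self, matrix, deme_names=None):
        M = np.asarray(matrix, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1] or M.shape[0] < 1:
            raise InvalidParameter("migration matrix must be square, K >= 1")
        if np.any(np.diag(M) <= 0):
            raise InvalidParameter("diagonal (population sizes) must be > 0")
        off = M[~np.eye(M.shape[0], dtype=bool)]
        if np.any(off < 0):
            raise InvalidParameter("migration rates must be >= 0")
        self.matrix = M
        self.K = M.shape[0]
        self.deme_names = (
            [str(d) for d in deme_names] if deme_names is not None else [str(i) for i in range(self.K)]
        )

    @property
    def thetas(self):
        return np.diag(self.matrix)

    def __eq__(self, other):
        return isinstance(other, MigrationMatrix) and np.array_equal(self.matrix, other.matrix)


def migration_matrix(theta, m) -> MigrationMatrix:
    """Assemble a migration matrix from a K-vector of population sizes and a
    (K^2 - K)-vector of migration rates filled row-major, skipping the
    diagonal."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    m = np.atleast_1d(np.asarray(m, dtype=float))
    K = theta.size
    if K < 1:
        raise InvalidParameter("migrationMatrix needs >= 1 deme")
    if m.size != K * K - K:
        raise LengthMismatch(
            f"K={K} demes require {K * K - K} migration rates, got {m.size}"
        )
    M = np.zeros((K, K))
    idx = 0
    for i in range(K):
        for j in range(K):
            if i == j:
                M[i, j] = theta[i]
            else:
                M[i, j] = m[idx]
                idx += 1
    return MigrationMatrix(M)


def structured_coalescent(M: MigrationMatrix, taxa: Taxa, rng: np.random.Generator) -> TimeTree:
    """Multi-deme coalescent with migration (Gillespie event loop).

    Within deme ``i`` lineages coalesce at rate ``k_i (k_i - 1) / (2 theta_i)``;
    each lineage in deme ``i`` migrates to deme ``j`` at rate ``m_ij``.
    Internal nodes are labelled with the deme where the coalescence occurred.
    """
    if len(taxa) < 2:
        raise TooFewTaxa(f"structured coalescent needs >= 2 taxa, got {len(taxa)}")
    if taxa.demes is None:
        raise InvalidParameter("structured coalescent requires taxa with deme labels")
    name_to_idx = {d: i for i, d in enumerate(M.deme_names)}
    unique = sorted(set(taxa.demes))
    if not all(d in name_to_idx for d in unique):
        # matrix rows carry default names: map the script's deme labels onto
        # rows in sorted order (e.g. "A","B" -> rows 0,1)
        if len(unique) > M.K:
            raise InvalidParameter(
                f"{len(unique)} distinct taxon demes but only {M.K} demes in the matrix"
            )
        name_to_idx = {d: i for i, d in enumerate(unique)}
        deme_labels = unique + [str(i) for i in range(len(unique), M.K)]
    else:
        deme_labels = M.deme_names

    tips = _tips_from_taxa(taxa)
    pending = sorted(tips, key=lambda n: n.age)
    t = pending[0].age
    active: list[TreeNode] = []
    deme_of: dict[int, int] = {}

    def activate(upto: float):
        nonlocal t
        t = upto
        while pending and pending[0].age <= t:
            node = pending.pop(0)
            deme_of[id(node)] = name_to_idx[node.deme]
            active.append(node)

    activate(t)
    thetas = M.thetas
    events = 0
    while len(active) + len(pending) > 1:
        events += 1
        if events > _EVENT_CAP:
            raise NonConvergence(
                "structured coalescent exceeded event budget (zero migration "
                "with lineages stranded in separate demes?)"
            )
        counts = np.zeros(M.K, dtype=int)
        for node in active:
            counts[deme_of[id(node)]] += 1
        coal_rates = counts * (counts - 1) / (2.0 * thetas)
        mig_rates = counts[:, None] * M.matrix
        np.fill_diagonal(mig_rates, 0.0)
        total = coal_rates.sum() + mig_rates.sum()
        if total <= 0:
            if pending:
                activate(pending[0].age)
                continue
            raise NonConvergence(
                "no events possible: zero migration with lineages in separate demes"
            )
        wait = rng.exponential(1.0 / total)
        if pending and pending[0].age <= t + wait:
            activate(pending[0].age)
            continue
        t = t + wait
        u = rng.random() * total
        acc = 0.0
        chosen = None
        for i in range(M.K):
            acc += coal_rates[i]
            if u < acc:
                chosen = ("coal", i)
                break
        if chosen is None:
            for i in range(M.K):
                for j in range(M.K):
                    if i == j:
                        continue
                    acc += mig_rates[i, j]
                    if u < acc:
                        chosen = ("mig", i, j)
                        break
                if chosen:
                    break
        if chosen is None:  # numerical edge: last event
            i = int(np.argmax(coal_rates))
            chosen = ("coal", i)
        if chosen[0] == "coal":
            deme = chosen[1]
            members = [n for n in active if deme_of[id(n)] == deme]
            pick = rng.choice(len(members), size=2, replace=False)
            a, b = members[pick[0]], members[pick[1]]
            active.remove(a)
            active.remove(b)
            parent = _join(a, b, t, deme=deme_labels[deme])
            deme_of[id(parent)] = deme
            active.append(parent)
        else:
            _, i, j = chosen
            members = [n for n in active if deme_of[id(n)] == i]
            mover = members[int(rng.integers(len(members)))]
            deme_of[id(mover)] = j
    return TimeTree(active[0], taxa)


# ---------------------------------------------------------------------------
# Birth-death family
# ---------------------------------------------------------------------------


def yule(lam: float, n: int, rng: np.random.Generator) -> TimeTree:
    """Pure-birth tree on ``n`` contemporaneous tips."""
    if lam <= 0:
        raise InvalidParameter(f"lambda must be > 0, got {lam}")
    n = int(n)
    if n < 2:
        raise InvalidParameter(f"n must be >= 2, got {n}")
    active = _tips_from_taxa(Taxa.contemporaneous(n))
    t = 0.0
    for k in range(n, 1, -1):
        t += rng.exponential(1.0 / (k * lam))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        for idx in sorted((i, j), reverse=True):
            active.pop(idx)
        active.append(_join(a, b, t))
    return TimeTree(active[0], Taxa.contemporaneous(n))


def _bd_g(s, lam, mu):
    r = lam - mu
    e = np.exp(-r * s)
    return (1.0 - e) / (lam - mu * e)


def _bd_g_inv(y, lam, mu):
    """Inverse of _bd_g: the age s with g(s) = y."""
    r = lam - mu
    e = (1.0 - y * lam) / (1.0 - y * mu) if mu > 0 else 1.0 - y * lam
    return -np.log(e) / r


def _assemble_from_ages(ages, n, rng) -> TimeTree:
    """Uniform ranked topology: join two uniformly chosen lineages at each
    internal-node age, youngest first."""
    active = _tips_from_taxa(Taxa.contemporaneous(n))
    for age in sorted(ages):
        k = len(active)
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        for idx in sorted((i, j), reverse=True):
            active.pop(idx)
        active.append(_join(a, b, age))
    return TimeTree(active[0], Taxa.contemporaneous(n))


def birth_death(lam: float, mu: float, n: int, root_age: float | None = None,
                rng: np.random.Generator | None = None) -> TimeTree:
    """Reconstructed birth-death tree conditioned on ``n`` extant tips.

    Uses the conditioned reconstructed process: given the root age ``t``,
    the ``n - 2`` non-root internal node ages are IID with CDF
    ``g(s)/g(t)`` where ``g(s) = (1 - exp(-(lam-mu) s)) / (lam - mu exp(-(lam-mu) s))``.
    When ``root_age`` is not given, the root age itself is drawn from its
    marginal under a uniform prior on the time of origin, via the transform
    ``u ~ Beta(n-1, 2)``, ``t = g^{-1}(u / lam)``.
    """
    if not (lam > mu >= 0):
        raise InvalidParameter(f"birth-death requires lambda > mu >= 0, got {lam}, {mu}")
    n = int(n)
    if n < 2:
        raise InvalidParameter(f"n must be >= 2, got {n}")
    if root_age is not None and root_age <= 0:
        raise InvalidParameter(f"rootAge must be > 0, got {root_age}")
    if rng is None:
        rng = np.random.default_rng()
    if root_age is None:
        u = rng.beta(n - 1, 2)
        root_age = float(_bd_g_inv(u / lam, lam, mu))
    gt = _bd_g(root_age, lam, mu)
    inner = _bd_g_inv(rng.uniform(size=n - 2) * gt, lam, mu) if n > 2 else np.empty(0)
    ages = list(np.atleast_1d(inner)) + [root_age]
    return _assemble_from_ages(ages, n, rng)


def birth_death_serial(lam: float, mu: float, rho: float, psi: float,
                       root_age: float, rng: np.random.Generator,
                       max_retries: int = 100) -> TimeTree:
    """Serially sampled birth-death tree, simulated forward from a root split
    at ``root_age``.

    Lineages give birth at rate ``lam``, die at rate ``mu``, and are sampled
    (and removed) through time at rate ``psi``; lineages surviving to the
    present are sampled with probability ``rho``.  The returned tree is
    pruned to the sampled tips; its root is their most recent common
    ancestor.  A simulation yielding fewer than two samples is a legitimate
    failure outcome and is retried up to ``max_retries`` times before
    :class:`~pylphy.errors.SimulationFailed` is raised.
    """
    if lam <= 0:
        raise InvalidParameter(f"lambda must be > 0, got {lam}")
    if mu < 0 or psi < 0:
        raise InvalidParameter("mu and psi must be >= 0")
    if not (0 < rho <= 1):
        raise InvalidParameter(f"rho must be in (0, 1], got {rho}")
    if root_age <= 0:
        raise InvalidParameter(f"rootAge must be > 0, got {root_age}")

    total = lam + mu + psi
    counter = [0]

    def simulate(age: float) -> TreeNode | None:
        t = age
        while True:
            counter[0] += 1
            if counter[0] > _EVENT_CAP:
                raise SimulationFailed("serial birth-death exceeded event budget")
            t_next = t - rng.exponential(1.0 / total)
            if t_next <= 0:
                return TreeNode(0.0) if rng.random() < rho else None
            u = rng.random() * total
            if u < mu:
                return None
            if u < mu + psi:
                return TreeNode(t_next)  # sampled (and removed) extinct lineage
            # birth: both daughter lineages continue independently; a
            # degree-2 node (one sampled daughter) is pruned away
            left = simulate(t_next)
            right = simulate(t_next)
            if left is not None and right is not None:
                return _join(left, right, t_next)
            return left if left is not None else right

    for _ in range(max_retries):
        counter[0] = 0
        left = simulate(root_age)
        right = simulate(root_age)
        if left is not None and right is not None:
            root = _join(left, right, root_age)
        else:
            root = left if left is not None else right
        if root is None or root.is_leaf:
            continue
        tips = [n for n in TimeTree(root).leaves()]
        if len(tips) < 2:
            continue
        for i, tip in enumerate(tips):
            tip.label = str(i + 1)
        names = [t.label for t in tips]
        ages = [t.age for t in tips]
        return TimeTree(root, Taxa(names, ages))
    raise SimulationFailed(
        f"no simulation with >= 2 sampled tips in {max_retries} attempts"
    )
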