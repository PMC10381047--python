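"""Tree priors: structural invariants, closed-form means, model nestings,
and independent brute-force simulator oracles."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from pylphy import (
    GroupSizeMismatch,
    InvalidParameter,
    LengthMismatch,
    NonConvergence,
    SimulationFailed,
    Taxa,
    TooFewTaxa,
    birth_death,
    birth_death_serial,
    coalescent,
    migration_matrix,
    parse_newick,
    skyline_coalescent,
    structured_coalescent,
    yule,
)
from pylphy.trees import MigrationMatrix, TimeTree


def rng_for(seed):
    return np.random.default_rng(seed)


def heights(simulate, reps, seed):
    rng = rng_for(seed)
    return np.array([simulate(rng).root_age for _ in range(reps)])


class TestCoalescent:
    @pytest.mark.parametrize("n", [2, 5, 10])
    def test_mean_root_height_closed_form(self, n):
        """E[root height] = 2 theta (1 - 1/n) for the Kingman coalescent."""
        reps = 10_000
        h = heights(lambda rng: coalescent(1.0, Taxa.contemporaneous(n), rng), reps, seed=n)
        expected = 2.0 * (1.0 - 1.0 / n)
        se = h.std(ddof=1) / np.sqrt(reps)
        assert abs(h.mean() - expected) < 4 * se

    def test_serial_tips_keep_their_ages(self):
        taxa = Taxa(["a", "b", "c", "d"], [0.0, 1.0, 2.0, 3.0])
        tree = coalescent(0.5, taxa, rng_for(1))
        tree.validate()
        assert tree.oldest_tip_age() == 3.0
        assert tree.root_age > 3.0
        assert {n.label: n.age for n in tree.leaves()} == {
            "a": 0.0, "b": 1.0, "c": 2.0, "d": 3.0,
        }

    def test_tree_shape_invariants(self):
        tree = coalescent(1.0, Taxa.contemporaneous(10), rng_for(3))
        tree.validate()
        assert tree.n_leaves == 10
        assert len(tree.internal_nodes()) == 9
        assert tree.n_branches == 18
        assert tree.is_ultrametric()

    def test_parameter_validation(self):
        with pytest.raises(InvalidParameter):
            coalescent(0.0, Taxa.contemporaneous(4), rng_for(0))
        with pytest.raises(TooFewTaxa):
            coalescent(1.0, Taxa(["only"]), rng_for(0))


class TestMigrationMatrix:
    def test_row_major_placement(self):
        M = migration_matrix([0.1, 0.2], [1.0, 2.0])
        assert np.array_equal(M.matrix, [[0.1, 1.0], [2.0, 0.2]])

    def test_k_demes_need_k2_minus_k_rates(self):
        migration_matrix([0.1, 0.2], [1.0, 2.0])  # K=2 -> 2 rates
        migration_matrix([0.1, 0.2, 0.3], [1.0] * 6)  # K=3 -> 6 rates
        with pytest.raises(LengthMismatch):
            migration_matrix([0.1, 0.2, 0.3], [1.0, 2.0])

    def test_invalid_entries(self):
        with pytest.raises(InvalidParameter):
            MigrationMatrix([[0.0, 1.0], [1.0, 0.5]])  # zero population size
        with pytest.raises(InvalidParameter):
            MigrationMatrix([[0.5, -1.0], [1.0, 0.5]])  # negative migration


class TestStructuredCoalescent:
    def test_internal_nodes_carry_demes(self):
        M = migration_matrix([0.1, 0.1], [1.0, 1.0])
        taxa = Taxa(["a1", "a2", "b1", "b2"], demes=["A", "A", "B", "B"])
        tree = structured_coalescent(M, taxa, rng_for(5))
        tree.validate()
        assert all(n.deme in ("A", "B") for n in tree.internal_nodes())
        assert tree.n_leaves == 4

    def test_single_deme_reduces_to_kingman(self):
        """K=1 structured coalescent root heights are distributed like the
        plain coalescent (two-sample KS)."""
        reps = 5_000
        M = MigrationMatrix([[0.7]])
        taxa = Taxa.contemporaneous(5)
        taxa_d = Taxa([str(i + 1) for i in range(5)], demes=["0"] * 5)
        h_struct = heights(lambda rng: structured_coalescent(M, taxa_d, rng), reps, 11)
        h_plain = heights(lambda rng: coalescent(0.7, taxa, rng), reps, 12)
        assert ks_2samp(h_struct, h_plain).pvalue > 0.01

    def test_fast_migration_approaches_pooled_panmixis(self):
        """With strong symmetric migration and per-deme size theta, the
        process approaches a panmictic coalescent with pooled size K*theta."""
        reps = 600
        M = migration_matrix([0.5, 0.5], [50.0, 50.0])
        taxa = Taxa(["a1", "a2", "b1", "b2"], demes=["A", "A", "B", "B"])
        h = heights(lambda rng: structured_coalescent(M, taxa, rng), reps, 21)
        expected = 2.0 * 1.0 * (1 - 0.25)  # pooled theta = 1, n = 4
        se = h.std(ddof=1) / np.sqrt(reps)
        assert abs(h.mean() - expected) < max(5 * se, 0.1 * expected)

    def test_zero_migration_split_demes_is_nonconvergent(self):
        M = migration_matrix([0.5, 0.5], [0.0, 0.0])
        taxa = Taxa(["a", "b"], demes=["A", "B"])
        with pytest.raises(NonConvergence):
            structured_coalescent(M, taxa, rng_for(0))


class TestSkylineCoalescent:
    def test_eleven_taxa_ten_intervals(self):
        tree = skyline_coalescent(
            [0.1, 0.2, 0.3, 0.4], [4, 3, 2, 1], Taxa.contemporaneous(11), rng_for(2)
        )
        tree.validate()
        assert len(tree.internal_nodes()) == 10

    def test_group_sizes_must_sum_to_n_minus_1(self):
        with pytest.raises(GroupSizeMismatch):
            skyline_coalescent(
                [0.1, 0.2, 0.3], [4, 3, 2], Taxa.contemporaneous(11), rng_for(0)
            )

    def test_theta_groupsize_length_mismatch(self):
        with pytest.raises(GroupSizeMismatch):
            skyline_coalescent([0.1, 0.2], [4, 3, 2, 1], Taxa.contemporaneous(11), rng_for(0))

    def test_single_group_reduces_to_constant_coalescent(self):
        reps = 5_000
        taxa = Taxa.contemporaneous(6)
        h_sky = heights(
            lambda rng: skyline_coalescent([0.4], [5], taxa, rng), reps, 31
        )
        h_const = heights(lambda rng: coalescent(0.4, taxa, rng), reps, 32)
        assert ks_2samp(h_sky, h_const).pvalue > 0.01

    def test_interval_thetas_affect_expected_depths(self):
        """With a huge ancestral theta the root is much older than with a
        small one (sanity check that groups count from the tips)."""
        reps = 400
        taxa = Taxa.contemporaneous(5)
        h_small = heights(
            lambda rng: skyline_coalescent([0.1, 0.1], [3, 1], taxa, rng), reps, 41
        )
        h_big = heights(
            lambda rng: skyline_coalescent([0.1, 10.0], [3, 1], taxa, rng), reps, 42
        )
        assert h_big.mean() > 5 * h_small.mean()


def yule_forward_oracle(lam, n, rng):
    """Independent pure-birth simulator: per-lineage exponential clocks,
    forward in time, observed during the n-lineage sojourn."""
    times = [0.0]
    t = 0.0
    k = 1
    node_times = []
    while k < n:
        # each of k lineages splits at rate lam -> next split Exp(k*lam)
        t += rng.exponential(1.0 / (k * lam))
        node_times.append(t)
        k += 1
    # observe at a memoryless stopping point during the n-lineage sojourn
    t_obs = t + rng.exponential(1.0 / (n * lam))
    return t_obs - node_times[0]  # root height


class TestYule:
    def test_shape(self):
        tree = yule(1.0, 5, rng_for(0))
        tree.validate()
        assert len(tree.internal_nodes()) == 4
        assert tree.n_branches == 8
        assert tree.is_ultrametric()

    def test_root_height_matches_forward_oracle(self):
        reps = 5_000
        h = heights(lambda rng: yule(1.0, 4, rng), reps, 51)
        rng = rng_for(52)
        h_oracle = np.array([yule_forward_oracle(1.0, 4, rng) for _ in range(reps)])
        assert ks_2samp(h, h_oracle).pvalue > 0.01

    def test_time_rescaling(self):
        """Doubling lambda halves node ages in distribution."""
        reps = 4_000
        h1 = heights(lambda rng: yule(1.0, 6, rng), reps, 61)
        h2 = heights(lambda rng: yule(2.0, 6, rng), reps, 62)
        assert ks_2samp(h1, 2.0 * h2).pvalue > 0.01

    def test_validation(self):
        with pytest.raises(InvalidParameter):
            yule(0.0, 5, rng_for(0))
        with pytest.raises(InvalidParameter):
            yule(1.0, 1, rng_for(0))


def bd_forward_rejection_oracle(lam, mu, n, root_age, rng, max_tries=100_000):
    """Brute-force reconstructed birth-death simulator: forward simulation
    from a root split at root_age, rejecting unless exactly n tips survive
    and both root children leave survivors; returns sorted internal node
    ages of the reconstructed tree."""
    for _ in range(max_tries):
        # lineage: (birth_age, [child_lineages] or None if dead leaf)
        split_ages = []

        def grow(age, splits):
            t = age
            while True:
                w = rng.exponential(1.0 / (lam + mu))
                t -= w
                if t <= 0:
                    return 1  # survived to present
                if rng.random() < mu / (lam + mu):
                    return 0  # died
                left = grow(t, splits)
                right_splits = []
                right = grow(t, right_splits)
                if left and right:
                    splits.append(t)
                    splits.extend(right_splits)
                    return left + right
                if right:
                    splits.extend(right_splits)
                    return right
                if left:
                    return left
                return 0

        left_splits, right_splits = [], []
        nl = grow(root_age, left_splits)
        nr = grow(root_age, right_splits)
        if nl >= 1 and nr >= 1 and nl + nr == n:
            return np.sort(np.array(left_splits + right_splits + [root_age]))
    raise RuntimeError("rejection oracle failed")


class TestBirthDeath:
    def test_validation(self):
        with pytest.raises(InvalidParameter):
            birth_death(1.0, 1.0, 5, rng=rng_for(0))  # mu >= lambda
        with pytest.raises(InvalidParameter):
            birth_death(1.0, 2.0, 5, rng=rng_for(0))

    def test_fixed_root_age_conditioning(self):
        tree = birth_death(2.0, 1.0, 2, root_age=1.0, rng=rng_for(0))
        assert tree.root_age == 1.0
        assert all(leaf.age == 0.0 for leaf in tree.leaves())

    def test_branch_count(self):
        tree = birth_death(2.0, 1.0, 10, rng=rng_for(1))
        tree.validate()
        assert tree.n_branches == 18

    def test_mu_zero_reduces_to_yule(self):
        """Nesting: birth-death with mu = 0 equals the Yule process (KS on
        root heights; the two samplers are algorithmically unrelated)."""
        reps = 5_000
        h_bd = heights(lambda rng: birth_death(1.0, 0.0, 5, rng=rng), reps, 71)
        h_yule = heights(lambda rng: yule(1.0, 5, rng), reps, 72)
        assert ks_2samp(h_bd, h_yule).pvalue > 0.01

    def test_node_ages_match_rejection_oracle(self):
        """Given the root age, non-root node ages follow the conditioned
        density g(s)/g(t); cross-checked against a brute-force forward
        simulator with rejection."""
        reps = 800
        root_age = 1.0
        rng = rng_for(81)
        mine = np.concatenate([
            np.sort([n.age for n in birth_death(1.5, 0.5, 4, root_age, rng).internal_nodes()])[:-1]
            for _ in range(reps)
        ])
        rng2 = rng_for(82)
        oracle = np.concatenate([
            bd_forward_rejection_oracle(1.5, 0.5, 4, root_age, rng2)[:-1]
            for _ in range(reps)
        ])
        assert ks_2samp(mine, oracle).pvalue > 0.01


def bdss_count_oracle(lam, mu, rho, psi, root_age, rng):
    """Population-level Gillespie simulator counting sampled lineages only."""
    k = 2  # lineages at the root split
    t = root_age
    sampled = 0
    while k > 0:
        total = k * (lam + mu + psi)
        t -= rng.exponential(1.0 / total)
        if t <= 0:
            break
        u = rng.random() * (lam + mu + psi)
        if u < lam:
            k += 1
        elif u < lam + mu:
            k -= 1
        else:
            k -= 1
            sampled += 1
    if k > 0:
        sampled += rng.binomial(k, rho)
    return sampled


class TestBirthDeathSerial:
    def test_yule_like_reduction(self):
        """psi=0, rho=1, mu=0: every tip is extant (age 0)."""
        tree = birth_death_serial(1.5, 0.0, 1.0, 0.0, 2.0, rng_for(0))
        tree.validate()
        assert all(leaf.age == 0.0 for leaf in tree.leaves())

    def test_serial_samples_have_positive_ages(self):
        """With psi > 0, ancient (psi-sampled) tips appear."""
        found = False
        for seed in range(20):
            tree = birth_death_serial(2.0, 1.0, 0.5, 1.0, 3.0, rng_for(100 + seed))
            if any(leaf.age > 0 for leaf in tree.leaves()):
                found = True
                break
        assert found

    def test_validation(self):
        rng = rng_for(0)
        for bad in [
            lambda: birth_death_serial(0.0, 0.5, 0.5, 0.5, 1.0, rng),
            lambda: birth_death_serial(1.0, -0.1, 0.5, 0.5, 1.0, rng),
            lambda: birth_death_serial(1.0, 0.5, 0.0, 0.5, 1.0, rng),
            lambda: birth_death_serial(1.0, 0.5, 1.5, 0.5, 1.0, rng),
            lambda: birth_death_serial(1.0, 0.5, 0.5, 0.5, 0.0, rng),
        ]:
            with pytest.raises(InvalidParameter):
                bad()

    def test_retry_budget_exhaustion(self):
        # death rate huge relative to sampling: almost never >= 2 samples
        with pytest.raises(SimulationFailed):
            birth_death_serial(0.1, 5.0, 0.01, 0.0, 0.5, rng_for(3), max_retries=5)

    def test_tip_count_distribution_matches_oracle(self):
        """Sampled-tip counts (conditional on >= 2) match a brute-force
        event-by-event population simulator."""
        reps = 2_000
        params = dict(lam=1.5, mu=0.5, rho=0.5, psi=0.5, root_age=1.0)
        rng = rng_for(91)
        mine = []
        for _ in range(reps):
            try:
                tree = birth_death_serial(
                    params["lam"], params["mu"], params["rho"], params["psi"],
                    params["root_age"], rng, max_retries=1,
                )
                mine.append(tree.n_leaves)
            except SimulationFailed:
                continue
        rng2 = rng_for(92)
        oracle = [
            c for c in (
                bdss_count_oracle(
                    params["lam"], params["mu"], params["rho"], params["psi"],
                    params["root_age"], rng2,
                )
                for _ in range(reps)
            ) if c >= 2
        ]
        assert ks_2samp(np.array(mine), np.array(oracle)).pvalue > 0.01


class TestNewickRoundTrip:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_topology_and_ages_survive(self, seed):
        taxa = Taxa(["a", "b", "c", "d", "e"], [0.0, 0.5, 0.0, 1.5, 3.0])
        tree = coalescent(0.8, taxa, rng_for(seed))
        back = parse_newick(tree.to_newick())
        # identical topology (compare at display precision: converting ages
        # to branch lengths and back may shift the last ulp)
        assert back.to_newick(precision=9) == tree.to_newick(precision=9)
        ages = {n.label: n.age for n in tree.leaves()}
        back_ages = {n.label: n.age for n in back.leaves()}
        assert all(abs(ages[k] - back_ages[k]) < 1e-12 for k in ages)
        assert abs(back.root_age - tree.root_age) < 1e-12

    def test_cross_check_against_dendropy(self):
        import dendropy

        tree = coalescent(1.0, Taxa.contemporaneous(6), rng_for(9))
        newick = tree.to_newick()
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        # total tree length and tip set agree
        assert dtree.length() == pytest.approx(tree.total_branch_length(), abs=1e-9)
        assert {t.label for t in dtree.taxon_namespace} == set(tree.taxa.names)

    def test_two_taxon_branch_lengths(self):
        from pylphy.trees import TreeNode

        root = TreeNode(1.0, children=(TreeNode(0.0, label="a"), TreeNode(0.0, label="b")))
        assert TimeTree(root).to_newick() == "(a:1,b:1);"

    def test_serial_branch_lengths(self):
        from pylphy.trees import TreeNode

        root = TreeNode(2.0, children=(TreeNode(0.0, label="a"), TreeNode(1.0, label="b")))
        assert TimeTree(root).to_newick() == "(a:2,b:1);"
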