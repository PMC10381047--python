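"""Graph engine: node taxonomy, clamping, sampling determinism,
vectorization, DOT export."""

import numpy as np
import pytest

import pylphy
from pylphy import (
    BroadcastError,
    DuplicateDefinition,
    RateMatrix,
    ShapeMismatch,
    TypeMismatch,
    UnknownGenerator,
    UnknownVariable,
    build_graph,
    clamp,
    export_dot,
    sample,
    vectorize,
)
from pylphy.parser import parse_script
from pylphy.seqsim import Alignment


def build(source, registry):
    return build_graph(parse_script(source), registry)


class TestBuild:
    def test_example1_node_taxonomy(self, registry):
        model = build(pylphy.example_source("example1.lphy"), registry)
        kinds = {name: node.kind for name, node in model.nodes.items()}
        assert kinds["L"] == "constant"
        assert kinds["taxa"] == "constant"
        assert kinds["Q"] == "deterministic"
        assert {n for n, k in kinds.items() if k == "stochastic"} == {"Θ", "ψ", "D"}

    def test_example3_stochastic_nodes(self, registry):
        model = build(pylphy.example_source("example3.lphy"), registry)
        stochastic = {n.name for n in model.by_kind("stochastic")}
        assert {"π", "rates", "Θ", "ψ", "A", "E", "delta", "epsilon"} <= stochastic

    def test_use_before_definition(self, registry):
        with pytest.raises(UnknownVariable):
            build("x = hky(kappa=k, freq=p);", registry)

    def test_unknown_generator(self, registry):
        with pytest.raises(UnknownGenerator):
            build("x ~ NoSuchDistribution(a=1.0);", registry)

    def test_duplicate_definition_in_block(self, registry):
        with pytest.raises(DuplicateDefinition):
            build("x = 1; x = 2;", registry)

    def test_operator_kind_mismatch(self, registry):
        with pytest.raises(TypeMismatch):
            build("x = Normal(mean=0.0, sd=1.0);", registry)  # '=' on a distribution
        with pytest.raises(TypeMismatch):
            build("x ~ jukesCantor();", registry)  # '~' on a function

    def test_classification_follows_operator(self, registry):
        model = build("a = 2; b = a * 3; c ~ Exp(mean=1.0);", registry)
        assert model.nodes["a"].kind == "constant"
        assert model.nodes["b"].kind == "deterministic"  # depends on a
        assert model.nodes["c"].kind == "stochastic"


class TestSampling:
    def test_constants_only_model(self, registry):
        model = build("a = 2; b = [1.0, 2.0];", registry)
        values = sample(model, seed=123)
        assert values["a"] == 2
        assert np.array_equal(values["b"], [1.0, 2.0])

    def test_same_seed_identical_assignment(self, run_example):
        _, v1 = run_example("example1.lphy", seed=11)
        _, v2 = run_example("example1.lphy", seed=11)
        assert v1["Θ"] == v2["Θ"]
        assert v1["ψ"].to_newick() == v2["ψ"].to_newick()
        assert np.array_equal(v1["D"].states, v2["D"].states)

    def test_different_seeds_differ(self, run_example):
        _, v1 = run_example("example1.lphy", seed=1)
        _, v2 = run_example("example1.lphy", seed=2)
        assert v1["Θ"] != v2["Θ"]

    def test_unrelated_node_does_not_perturb_streams(self, registry):
        """Per-node random streams: inserting an unrelated variable leaves
        other nodes' draws untouched."""
        v1 = sample(build("x ~ Normal(mean=0.0, sd=1.0);", registry), seed=5)
        v2 = sample(
            build("y ~ Exp(mean=2.0); x ~ Normal(mean=0.0, sd=1.0);", registry), seed=5
        )
        assert v1["x"] == v2["x"]

    def test_range_evaluation(self, registry):
        values = sample(build("c = 1:5; s = 5:5;", registry), seed=0)
        assert list(values["c"]) == [1, 2, 3, 4, 5]
        assert list(values["s"]) == [5]

    def test_arithmetic(self, registry):
        values = sample(build("a = 3; b = a * 2 + 1; c = -b / 2.0;", registry), seed=0)
        assert values["b"] == 7 and values["c"] == -3.5


class TestClamping:
    def _clamped_model(self, registry, tmp_path, model_block):
        aln = Alignment(
            pylphy.Taxa(["a", "b", "c"]),
            np.array([[0, 1, 2, 3, 0, 1], [1, 1, 2, 3, 0, 0], [2, 1, 2, 3, 0, 1]]),
        )
        pylphy.write_fasta(aln, tmp_path / "obs.fasta")
        source = (
            f'data {{ D = readFasta(file="{tmp_path / "obs.fasta"}"); '
            "t = D.taxa(); L = D.nchar(); }"
            f" model {{ {model_block} }}"
        )
        return clamp(build(source, registry))

    def test_clamped_value_fixed_across_seeds(self, registry, tmp_path):
        model = self._clamped_model(
            registry,
            tmp_path,
            "ψ ~ Coalescent(theta=1.0, taxa=t); D ~ PhyloCTMC(tree=ψ, Q=jukesCantor(), L=L);",
        )
        assert model.nodes["D"].observed
        v1, v2 = sample(model, 1), sample(model, 2)
        assert np.array_equal(v1["D"].states, v2["D"].states)
        assert v1["ψ"].to_newick() != v2["ψ"].to_newick()  # tree still sampled

    def test_no_collision_is_noop(self, registry):
        model = clamp(build("x ~ Exp(mean=1.0);", registry))
        assert not model.nodes["x"].observed

    def test_site_count_mismatch(self, registry, tmp_path):
        model = self._clamped_model(
            registry,
            tmp_path,
            "ψ ~ Coalescent(theta=1.0, taxa=t); D ~ PhyloCTMC(tree=ψ, Q=jukesCantor(), L=9999);",
        )
        with pytest.raises(ShapeMismatch):
            sample(model, 1)

    def test_taxon_count_mismatch(self, registry, tmp_path):
        model = self._clamped_model(
            registry,
            tmp_path,
            "ψ ~ Coalescent(theta=1.0, n=2); D ~ PhyloCTMC(tree=ψ, Q=jukesCantor(), L=L);",
        )
        with pytest.raises(ShapeMismatch):
            sample(model, 1)


class TestVectorize:
    def _rngs(self, seed=0):
        return lambda i: np.random.default_rng([seed, i])

    def test_dirichlet_replicates_gives_matrix(self, registry):
        spec = registry.resolve("Dirichlet", {"conc"})
        out = vectorize(
            spec, {"conc": np.full(4, 2.0), "replicates": 3}, self._rngs()
        )
        assert out.shape == (3, 4)
        assert np.allclose(out.sum(axis=1), 1.0)

    def test_lognormal_replicates_gives_vector(self, registry):
        spec = registry.resolve("LogNormal", {"meanlog", "sdlog"})
        out = vectorize(
            spec, {"meanlog": 1.0, "sdlog": 0.5, "replicates": 3}, self._rngs()
        )
        assert out.shape == (3,) and np.all(out > 0)

    def test_replicates_one_is_length_one_vector(self, registry):
        spec = registry.resolve("LogNormal", {"meanlog", "sdlog"})
        out = vectorize(
            spec, {"meanlog": 0.0, "sdlog": 1.0, "replicates": 1}, self._rngs()
        )
        assert out.shape == (1,)

    def test_hky_broadcast_over_vector_args(self, registry):
        spec = registry.resolve("hky", {"kappa", "freq"})
        kappas = np.array([1.0, 2.0, 4.0])
        freqs = np.tile([0.25, 0.25, 0.25, 0.25], (3, 1))
        out = vectorize(spec, {"kappa": kappas, "freq": freqs}, self._rngs())
        assert isinstance(out, list) and len(out) == 3
        assert all(isinstance(Q, RateMatrix) for Q in out)

    def test_broadcast_equals_elementwise(self, registry):
        """Vectorization equivalence: broadcast f(x) == [f(x_i)] exactly."""
        spec = registry.resolve("hky", {"kappa", "freq"})
        kappas = np.array([1.5, 3.0])
        freqs = np.array([[0.1, 0.2, 0.3, 0.4], [0.4, 0.3, 0.2, 0.1]])
        out = vectorize(spec, {"kappa": kappas, "freq": freqs}, self._rngs())
        for i, Q in enumerate(out):
            assert Q == pylphy.hky(kappas[i], freqs[i])

    def test_unequal_major_dimensions_rejected(self, registry):
        spec = registry.resolve("hky", {"kappa", "freq"})
        with pytest.raises(BroadcastError):
            vectorize(
                spec,
                {"kappa": np.array([1.0, 2.0, 3.0]),
                 "freq": np.tile([0.25] * 4, (2, 1))},
                self._rngs(),
            )

    def test_replicates_with_broadcast_rejected(self, registry):
        spec = registry.resolve("hky", {"kappa", "freq"})
        with pytest.raises(BroadcastError):
            vectorize(
                spec,
                {"kappa": np.array([1.0, 2.0]),
                 "freq": np.array([0.25] * 4), "replicates": 2},
                self._rngs(),
            )

    def test_vectorization_script_shapes(self, run_example):
        _, values = run_example("vectorization.lphy")
        assert values["κ"].shape == (3,)
        assert values["π"].shape == (3, 4)
        assert len(values["Q"]) == 3


class TestDotExport:
    def test_example1_shapes(self, registry, run_example):
        model, _ = run_example("example1.lphy")
        dot = export_dot(model)
        assert '"Q" [shape=diamond]' in dot
        for name in ("Θ", "ψ", "D"):
            assert f'"{name}" [shape=ellipse]' in dot
        assert "shape=box" in dot  # constants present
        assert '"Θ" -> "ψ"' in dot

    def test_hide_constants(self, registry, run_example):
        model, _ = run_example("example1.lphy")
        dot = export_dot(model, hide_constants=True)
        assert "shape=box" not in dot
        assert '"Q"' in dot

    def test_empty_model(self, registry):
        dot = export_dot(build("", registry))
        assert dot.startswith("digraph") and dot.rstrip().endswith("}")

    def test_observed_nodes_filled(self, registry, run_example):
        model, _ = run_example("example2.lphy")
        dot = export_dot(model)
        assert "style=filled" in dot
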