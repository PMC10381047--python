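"""The built-in generator library.

:func:`default_registry` assembles the standard generative distributions
(parametric families, tree priors, PhyloCTMC, the GT16 error model),
deterministic functions (rate-matrix constructors, ``taxa``,
``migrationMatrix``, file readers) and methods (``.taxa()``, ``.nchar()``,
``.codonPartitions()``) into a fresh :class:`~pylphy.registry.GeneratorRegistry`.

Each entry carries the metadata the rest of the system needs: argument
types (driving type checking and implicit vectorization), a narrative verb
phrase plus per-argument noun phrases (driving natural-language model
descriptions), and citation keys into the bibliography.
"""

from __future__ import annotations

import numpy as np

from . import distributions as dists
from . import formats, seqsim, substmodels, trees
from .errors import ShapeMismatch
from .registry import GeneratorRegistry, GeneratorSpec, MethodSpec, ParamSpec

__all__ = ["default_registry"]


def _p(name, kind, desc="", required=True, default=None):
    return ParamSpec(name, kind, required=required, default=default, description=desc)


def _num(v) -> float:
    return float(v)


# -- parametric distributions ------------------------------------------------


def _make_dist_spec(name, cls, params, template, argmap=None):
    argmap = argmap or {}

    def func(values, rng):
        kwargs = {argmap.get(k, k): v for k, v in values.items()}
        return cls(**kwargs).sample_one(rng)

    return GeneratorSpec(
        name=name, kind="generative", params=params, func=func, template=template,
        returns="random variable",
    )


def _parametric_specs():
    yield _make_dist_spec(
        "Uniform", dists.Uniform,
        [_p("lower", "number", "lower bound"), _p("upper", "number", "upper bound")],
        "has a uniform prior",
    )
    yield _make_dist_spec(
        "Normal", dists.Normal,
        [_p("mean", "number", "mean"), _p("sd", "number", "standard deviation")],
        "has a normal prior",
    )
    yield _make_dist_spec(
        "LogNormal", dists.LogNormal,
        [_p("meanlog", "number", "mean in log space"),
         _p("sdlog", "number", "standard deviation in log space")],
        "has a log-normal prior",
    )
    yield _make_dist_spec(
        "Gamma", dists.Gamma,
        [_p("shape", "number", "shape"), _p("scale", "number", "scale")],
        "has a gamma prior",
    )
    yield _make_dist_spec(
        "Exp", dists.Exp, [_p("mean", "number", "mean")], "has an exponential prior",
    )
    yield _make_dist_spec(
        "Beta", dists.Beta,
        [_p("alpha", "number", "alpha"), _p("beta", "number", "beta")],
        "has a Beta distribution prior",
    )
    yield _make_dist_spec(
        "Dirichlet", dists.Dirichlet,
        [_p("conc", "number_vector", "concentration")],
        "have a Dirichlet distribution prior",
    )


# -- tree priors --------------------------------------------------------------


def _tree_specs():
    def coalescent_taxa(v, rng):
        return trees.coalescent(_num(v["theta"]), trees.Taxa.coerce(v["taxa"]), rng)

    def coalescent_n(v, rng):
        return trees.coalescent(_num(v["theta"]), trees.Taxa.contemporaneous(v["n"]), rng)

    yield GeneratorSpec(
        "Coalescent", "generative",
        [_p("theta", "number", "coalescent parameter"), _p("taxa", "taxa", "taxa")],
        coalescent_taxa,
        returns="phylogenetic time tree",
        citations=("kingman1982", "rodrigo1999"),
        template="is assumed to come from a Kingman's coalescent tree prior",
    )
    yield GeneratorSpec(
        "Coalescent", "generative",
        [_p("theta", "number", "coalescent parameter"), _p("n", "int", "n")],
        coalescent_n,
        returns="phylogenetic time tree",
        citations=("kingman1982",),
        template="is assumed to come from a Kingman's coalescent tree prior",
    )
    yield GeneratorSpec(
        "StructuredCoalescent", "generative",
        [_p("M", "migrationmatrix", "migration matrix"), _p("taxa", "taxa", "taxa")],
        lambda v, rng: trees.structured_coalescent(v["M"], trees.Taxa.coerce(v["taxa"]), rng),
        returns="gene tree",
        citations=("hudson1990", "notohara1990"),
        template="is assumed to come from a structured coalescent process",
    )
    yield GeneratorSpec(
        "SkylineCoalescent", "generative",
        [_p("theta", "number_vector", "population sizes"),
         _p("groupSizes", "int_vector", "group sizes"),
         _p("taxa", "taxa", "taxa")],
        lambda v, rng: trees.skyline_coalescent(v["theta"], v["groupSizes"], trees.Taxa.coerce(v["taxa"]), rng),
        returns="phylogenetic time tree",
        citations=("pybus2000",),
        template="is assumed to come from a skyline coalescent tree prior",
    )
    yield GeneratorSpec(
        "Yule", "generative",
        [_p("lambda", "number", "birth rate"), _p("n", "int", "n")],
        lambda v, rng: trees.yule(_num(v["lambda"]), v["n"], rng),
        returns="phylogenetic time tree",
        citations=("yule1925",),
        template="is assumed to come from a Yule tree prior",
    )
    yield GeneratorSpec(
        "BirthDeath", "generative",
        [_p("lambda", "number", "birth rate"), _p("mu", "number", "death rate"),
         _p("n", "int", "n"),
         _p("rootAge", "number", "root age", required=False)],
        lambda v, rng: trees.birth_death(
            _num(v["lambda"]), _num(v["mu"]), v["n"], v.get("rootAge"), rng
        ),
        returns="phylogenetic time tree",
        citations=("gernhard2008",),
        template="is assumed to come from a birth-death tree prior",
    )
    yield GeneratorSpec(
        "BirthDeathSerialSampling", "generative",
        [_p("lambda", "number", "birth rate"), _p("mu", "number", "death rate"),
         _p("rho", "number", "extant sampling probability"),
         _p("psi", "number", "extinct sampling rate"),
         _p("rootAge", "number", "root age")],
        lambda v, rng: trees.birth_death_serial(
            _num(v["lambda"]), _num(v["mu"]), _num(v["rho"]), _num(v["psi"]),
            _num(v["rootAge"]), rng,
        ),
        returns="phylogenetic time tree",
        citations=("stadler2010",),
        template="is assumed to come from a serially sampled birth-death tree prior",
    )


# -- substitution models -------------------------------------------------------


def _subst_specs():
    yield GeneratorSpec(
        "jukesCantor", "function", [],
        lambda v, rng: substmodels.jukes_cantor(),
        returns="instantaneous rate matrix",
        citations=("jukescantor1969",),
        template="is the instantaneous rate matrix of the Jukes-Cantor model",
    )
    yield GeneratorSpec(
        "hky", "function",
        [_p("kappa", "number", "kappa"), _p("freq", "simplex", "base frequencies")],
        lambda v, rng: substmodels.hky(_num(v["kappa"]), v["freq"]),
        returns="instantaneous rate matrix",
        citations=("hky1985",),
        template="is the instantaneous rate matrix of the HKY model",
    )
    yield GeneratorSpec(
        "gtr", "function",
        [_p("rates", "number_vector", "relative rates"),
         _p("freq", "simplex", "base frequencies")],
        lambda v, rng: substmodels.gtr(v["rates"], v["freq"]),
        returns="instantaneous rate matrix",
        citations=("tavare1986",),
        template="is the general time-reversible rate matrix",
    )
    yield GeneratorSpec(
        "gt16", "function",
        [_p("rates", "number_vector", "relative rates"),
         _p("freq", "simplex", "base frequencies")],
        lambda v, rng: substmodels.gt16(v["rates"], v["freq"]),
        returns="instantaneous rate matrix",
        citations=("kozlov2022",),
        template="is the general time-reversible rate matrix on phased genotypes",
    )
    yield GeneratorSpec(
        "phasedGenotype", "function", [],
        lambda v, rng: seqsim.PHASED_GENOTYPE,
        returns="phased genotype data type",
        template="is the phased genotype data type",
    )
    yield GeneratorSpec(
        "nucleotides", "function", [],
        lambda v, rng: seqsim.NUCLEOTIDE,
        returns="nucleotide data type",
        template="is the nucleotide data type",
    )


# -- sequence simulation -------------------------------------------------------


def _phylo_ctmc(v, rng):
    tree = v["tree"]
    if "branchRates" in v and v["branchRates"] is not None:
        clock = seqsim.assign_branch_rates(tree, v["branchRates"])
    else:
        clock = seqsim.ClockSpec(mu=_num(v.get("mu", 1.0)))
    return seqsim.phylo_ctmc(tree, v["Q"], v["L"], clock, v.get("dataType"), rng)


def _validate_observed_alignment(observed, argvalues):
    trees_arg = argvalues.get("tree")
    L = argvalues.get("L")
    L_list = list(np.atleast_1d(L)) if L is not None else None

    def check_one(aln, L_i, tree):
        if not isinstance(aln, seqsim.Alignment):
            raise ShapeMismatch(f"observed value is {type(aln).__name__}, not an alignment")
        if tree is not None and aln.n_taxa != tree.n_leaves:
            raise ShapeMismatch(
                f"observed alignment has {aln.n_taxa} taxa but the tree has "
                f"{tree.n_leaves} leaves"
            )
        if L_i is not None and aln.L != int(L_i):
            raise ShapeMismatch(
                f"observed alignment has {aln.L} sites but L = {int(L_i)}"
            )

    if isinstance(observed, (list, tuple)):
        if L_list is not None and len(L_list) not in (1, len(observed)):
            raise ShapeMismatch(
                f"{len(observed)} observed alignments but {len(L_list)} lengths"
            )
        for i, aln in enumerate(observed):
            L_i = L_list[i % len(L_list)] if L_list is not None else None
            check_one(aln, L_i, trees_arg)
    else:
        check_one(observed, L_list[0] if L_list else None, trees_arg)


def _seqsim_specs():
    yield GeneratorSpec(
        "PhyloCTMC", "generative",
        [_p("tree", "tree", "phylogenetic time tree"),
         _p("Q", "ratematrix", "instantaneous rate matrix"),
         _p("L", "int", "alignment length"),
         _p("mu", "number", "clock rate", required=False),
         _p("branchRates", "number_vector", "branch rates", required=False),
         _p("dataType", "datatype", "data type used for simulations", required=False)],
        _phylo_ctmc,
        returns="alignment",
        citations=("felsenstein1981",),
        template="is assumed to have evolved under a phylogenetic continuous time Markov process",
        validate_observed=_validate_observed_alignment,
    )
    yield GeneratorSpec(
        "ErrorModel", "generative",
        [_p("alignment", "alignment", "genotype alignment"),
         _p("epsilon", "number", "sequencing and amplification error probability"),
         _p("delta", "number", "allelic dropout probability")],
        lambda v, rng: seqsim.gt16_error(v["alignment"], _num(v["epsilon"]), _num(v["delta"]), rng),
        returns="alignment",
        citations=("kozlov2022",),
        template="has an error model",
        validate_observed=lambda obs, args: _validate_observed_alignment(
            obs, {"L": args["alignment"].L if isinstance(args.get("alignment"), seqsim.Alignment) else None}
        ),
    )


# -- deterministic helpers -----------------------------------------------------


def _taxa_func(v, rng):
    names = [str(n) for n in np.atleast_1d(v["names"])]
    ages = v.get("ages")
    demes = v.get("demes")
    demes = [str(d) for d in np.atleast_1d(demes)] if demes is not None else None
    return trees.Taxa(names, ages, demes)


def _helper_specs():
    yield GeneratorSpec(
        "taxa", "function",
        [_p("names", "string_vector", "names"),
         _p("ages", "number_vector", "ages", required=False),
         _p("demes", "string_vector", "demes", required=False)],
        _taxa_func,
        returns="set of taxa",
        template="is the set of taxa",
    )
    yield GeneratorSpec(
        "migrationMatrix", "function",
        [_p("theta", "number_vector", "population sizes"),
         _p("m", "number_vector", "migration rates")],
        lambda v, rng: trees.migration_matrix(v["theta"], v["m"]),
        returns="migration matrix",
        template="is the migration matrix",
    )
    yield GeneratorSpec(
        "readNexus", "function",
        [_p("file", "string", "file")],
        lambda v, rng: formats.read_alignment(v["file"], format="nexus"),
        returns="alignment",
        template="is read from the NEXUS file",
    )
    yield GeneratorSpec(
        "readFasta", "function",
        [_p("file", "string", "file")],
        lambda v, rng: formats.read_alignment(v["file"], format="fasta"),
        returns="alignment",
        template="is read from the FASTA file",
    )
    yield GeneratorSpec(
        "rep", "function",
        [_p("element", "number", "element"), _p("times", "int", "times")],
        lambda v, rng: np.full(int(v["times"]), float(v["element"])),
        returns="vector",
        template="is a repeated vector",
    )
    yield GeneratorSpec(
        "length", "function",
        [_p("x", "any", "value")],
        lambda v, rng: int(len(v["x"])),
        returns="length",
        template="is the length",
    )


def _method_specs():
    yield MethodSpec(
        "alignment", "taxa",
        lambda target, v: target.taxa,
        returns="set of taxa",
    )
    yield MethodSpec(
        "alignment", "nchar",
        lambda target, v: int(target.L),
        returns="number of sites",
    )
    yield MethodSpec(
        "alignment", "codonPartitions",
        lambda target, v: seqsim.partition_by_codon(target),
        returns="codon position partitions",
    )
    yield MethodSpec(
        "taxa", "length",
        lambda target, v: len(target),
        returns="number of taxa",
    )
    yield MethodSpec(
        "tree", "taxa",
        lambda target, v: target.taxa,
        returns="set of taxa",
    )


def default_registry() -> GeneratorRegistry:
    """A registry pre-loaded with the standard generator library."""
    registry = GeneratorRegistry()
    for group in (
        _parametric_specs(),
        _tree_specs(),
        _subst_specs(),
        _seqsim_specs(),
        _helper_specs(),
    ):
        for spec in group:
            registry.register(spec)
    for mspec in _method_specs():
        registry.register_method(mspec)
    return registry
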