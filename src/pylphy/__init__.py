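"""pylphy: an interpreter and forward simulator for LPhy model scripts.

LPhy is a concise, declarative specification language for Bayesian
phylogenetic models: a script names every random variable, draws each from
a generative distribution with ``~``, computes deterministic quantities
with ``=``, and groups observed data into a ``data`` block that clamps the
matching model-block variables.  This package parses such scripts, builds
the corresponding probabilistic graphical model, simulates data from it,
and renders the model as Graphviz DOT and as a natural-language methods
narrative with citations.

Typical use::

    import pylphy

    model, values = pylphy.run_script(pylphy.example_source("example1.lphy"), seed=1)
    print(values["D"])            # a simulated 10 x 200 nucleotide alignment
    print(pylphy.generate_narrative(model))
"""

from importlib import resources as _resources
from pathlib import Path

from .errors import (  # noqa: F401
    BroadcastError,
    DuplicateDefinition,
    FormatError,
    GraphError,
    GroupSizeMismatch,
    InvalidParameter,
    LengthMismatch,
    LPhyError,
    NonConvergence,
    ParseError,
    RateLengthMismatch,
    ShapeMismatch,
    SimulationFailed,
    TooFewTaxa,
    TypeMismatch,
    UnknownGenerator,
    UnknownVariable,
)
from .parser import ScriptAST, Statement, parse_expression, parse_script, unparse  # noqa: F401
from .graph import (  # noqa: F401
    GraphicalModel,
    PGMNode,
    build_graph,
    clamp,
    export_dot,
    sample,
    vectorize,
)
from .registry import GeneratorRegistry, GeneratorSpec, MethodSpec, ParamSpec  # noqa: F401
from .stdlib import default_registry  # noqa: F401
from .narrative import (  # noqa: F401
    BIBLIOGRAPHY,
    citation_record,
    export_latex,
    generate_narrative,
)
from .trees import (  # noqa: F401
    MigrationMatrix,
    Taxa,
    TimeTree,
    birth_death,
    birth_death_serial,
    coalescent,
    migration_matrix,
    skyline_coalescent,
    structured_coalescent,
    yule,
)
from .substmodels import (  # noqa: F401
    GENOTYPES,
    NUCLEOTIDES,
    RateMatrix,
    gt16,
    gtr,
    hky,
    jukes_cantor,
    transition_probs,
)
from .seqsim import (  # noqa: F401
    Alignment,
    ClockSpec,
    DataType,
    NUCLEOTIDE,
    PHASED_GENOTYPE,
    assign_branch_rates,
    gt16_error,
    gt16_error_matrix,
    partition_by_codon,
    phylo_ctmc,
)
from .formats import (  # noqa: F401
    parse_newick,
    read_alignment,
    read_tree,
    write_fasta,
    write_nexus,
    write_trace,
    write_tree,
)

from . import synthdata  # noqa: F401,E402

__version__ = "0.1.0"


def run_script(source: str, seed: int = 0, registry: GeneratorRegistry | None = None):
    """Parse, build, clamp and sample a script in one call.

    Returns ``(model, assignment)``: the graphical model and the full
    name -> value assignment produced with the given seed.
    """
    if registry is None:
        registry = default_registry()
    ast = parse_script(source)
    model = clamp(build_graph(ast, registry))
    return model, sample(model, seed)


def example_path(name: str) -> Path:
    """Filesystem path of one of the bundled example scripts."""
    return Path(str(_resources.files("pylphy") / "scripts" / name))


def example_source(name: str) -> str:
    """Source text of one of the bundled example scripts."""
    return (_resources.files("pylphy") / "scripts" / name).read_text()


def list_examples() -> list:
    """Names of the bundled example scripts."""
    return sorted(
        p.name for p in (_resources.files("pylphy") / "scripts").iterdir()
        if p.name.endswith(".lphy")
    )
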