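"""Natural-language model narratives.

:func:`generate_narrative` renders a graphical model as the paragraph of
prose a methods section would contain: one sentence per non-constant node,
data first and priors last (each node is described after the node it
generates has been introduced), with constants inlined verbatim as the
modeller wrote them and a citation for every generator with a published
source.

Sentence text is assembled from per-generator templates (a verb phrase on
the :class:`~pylphy.registry.GeneratorSpec` plus a noun phrase per
argument), so extensions registering new generators automatically carry
their own narrative text.
"""

from __future__ import annotations

from . import parser as ast
from .graph import GraphicalModel, PGMNode, export_dot
from .registry import GeneratorRegistry

__all__ = [
    "BIBLIOGRAPHY",
    "citation_record",
    "generate_narrative",
    "export_latex",
]

#: key -> (short author-year citation, full reference)
BIBLIOGRAPHY: dict[str, tuple[str, str]] = {
    "kingman1982": (
        "Kingman 1982",
        "Kingman, J.F.C. (1982). The coalescent. Stochastic Processes and "
        "their Applications, 13(3), 235-248.",
    ),
    "rodrigo1999": (
        "Rodrigo & Felsenstein 1999",
        "Rodrigo, A.G. & Felsenstein, J. (1999). Coalescent approaches to HIV "
        "population genetics. In The Evolution of HIV, Johns Hopkins University Press.",
    ),
    "hudson1990": (
        "Hudson 1990",
        "Hudson, R.R. (1990). Gene genealogies and the coalescent process. "
        "Oxford Surveys in Evolutionary Biology, 7, 1-44.",
    ),
    "notohara1990": (
        "Notohara 1990",
        "Notohara, M. (1990). The coalescent and the genealogical process in "
        "geographically structured population. Journal of Mathematical Biology, 29, 59-75.",
    ),
    "pybus2000": (
        "Pybus, Rambaut & Harvey 2000",
        "Pybus, O.G., Rambaut, A. & Harvey, P.H. (2000). An integrated framework "
        "for the inference of viral population history from reconstructed "
        "genealogies. Genetics, 155(3), 1429-1437.",
    ),
    "yule1925": (
        "Yule 1925",
        "Yule, G.U. (1925). A mathematical theory of evolution, based on the "
        "conclusions of Dr. J.C. Willis. Philosophical Transactions of the Royal "
        "Society B, 213, 21-87.",
    ),
    "gernhard2008": (
        "Gernhard 2008",
        "Gernhard, T. (2008). The conditioned reconstructed process. Journal of "
        "Theoretical Biology, 253(4), 769-778.",
    ),
    "stadler2010": (
        "Stadler 2010",
        "Stadler, T. (2010). Sampling-through-time in birth-death trees. "
        "Journal of Theoretical Biology, 267(3), 396-404.",
    ),
    "jukescantor1969": (
        "Jukes & Cantor 1969",
        "Jukes, T.H. & Cantor, C.R. (1969). Evolution of protein molecules. In "
        "Mammalian Protein Metabolism, Academic Press, 21-132.",
    ),
    "hky1985": (
        "Hasegawa, Kishino & Yano 1985",
        "Hasegawa, M., Kishino, H. & Yano, T. (1985). Dating of the human-ape "
        "splitting by a molecular clock of mitochondrial DNA. Journal of "
        "Molecular Evolution, 22(2), 160-174.",
    ),
    "tavare1986": (
        "Tavaré 1986",
        "Tavaré, S. (1986). Some probabilistic and statistical problems in the "
        "analysis of DNA sequences. Lectures on Mathematics in the Life "
        "Sciences, 17, 57-86.",
    ),
    "kozlov2022": (
        "Kozlov et al. 2022",
        "Kozlov, A., Alves, J.M., Stamatakis, A. & Posada, D. (2022). CellPhy: "
        "accurate and fast probabilistic inference of single-cell phylogenies "
        "from scDNA-seq data. Genome Biology, 23, 37.",
    ),
    "felsenstein1981": (
        "Felsenstein 1981",
        "Felsenstein, J. (1981). Evolutionary trees from DNA sequences: a "
        "maximum likelihood approach. Journal of Molecular Evolution, 17(6), 368-376.",
    ),
    "drummond2006": (
        "Drummond et al. 2006",
        "Drummond, A.J., Ho, S.Y.W., Phillips, M.J. & Rambaut, A. (2006). "
        "Relaxed phylogenetics and dating with confidence. PLoS Biology, 4(5), e88.",
    ),
}


def citation_record(registry: GeneratorRegistry) -> dict:
    """Generator name -> tuple of reference keys (the citation record)."""
    record: dict[str, tuple] = {}
    for name in registry.names():
        keys: list[str] = []
        for spec in registry.overloads(name):
            for key in spec.citations:
                if key not in keys:
                    keys.append(key)
        if keys:
            record[name] = tuple(keys)
    return record


# ---------------------------------------------------------------------------
# Sentence assembly
# ---------------------------------------------------------------------------

_VOWELISH = set("aeiou") | {"n", "m", "f", "h", "l", "r", "s", "x"}


def _article(desc: str) -> str:
    first = desc.split()[0].lower()
    if first[0] in "aeiou":
        return "an"
    if len(first) == 1 and first in _VOWELISH:
        return "an"  # letters pronounced with a leading vowel ("an n of 16")
    return "a"


def _narrative_order(model: GraphicalModel) -> list:
    """Depth-first preorder from the sink nodes (last-declared first),
    visiting parents in argument order: the data node comes first, the
    priors that generated it follow."""
    order: list[PGMNode] = []
    seen: set[str] = set()

    def visit(node: PGMNode):
        if node.name in seen:
            return
        seen.add(node.name)
        order.append(node)
        for parent in node.parents:
            if parent in model.nodes:
                visit(model.nodes[parent])

    for sink in reversed(model.sink_nodes()):
        visit(sink)
    for node in model.order:  # anything unreachable from a sink
        visit(node)
    return order


def _subject_description(model: GraphicalModel, node: PGMNode) -> str:
    """A node is named after the role it plays for its first consumer
    ("coalescent parameter" for the theta argument of the coalescent);
    nodes nothing consumes fall back to their generator's return
    description."""
    for consumer in model.order:
        if consumer.generator is None or not isinstance(consumer.rhs, ast.GeneratorCall):
            continue
        for argname, expr in consumer.rhs.args:
            if isinstance(expr, ast.VariableRef) and expr.name == node.name:
                p = consumer.generator.param(argname)
                if p is not None and p.description:
                    return p.description
    if node.generator is not None and node.generator.returns:
        return node.generator.returns
    return "parameter"


def _render_value(model: GraphicalModel, expr) -> str:
    """Literal text for a constant-valued expression, echoing the script's
    own spelling of numbers."""
    if isinstance(expr, ast.VariableRef):
        target = model.nodes.get(expr.name)
        if target is not None and target.kind == "constant":
            return _render_value(model, target.rhs)
        return expr.name
    return ast.unparse(expr)


def _clause(model: GraphicalModel, spec, argname: str, expr) -> str:
    p = spec.param(argname) if spec is not None else None
    desc = p.description if p is not None and p.description else argname
    if isinstance(expr, ast.VariableRef):
        target = model.nodes.get(expr.name)
        if target is not None and target.kind != "constant":
            return f"{desc}, {expr.name}"
        return f"{_article(desc)} {desc} of {_render_value(model, expr)}"
    if isinstance(expr, (ast.GeneratorCall, ast.MethodCall)):
        return f"the {desc}"
    return f"{_article(desc)} {desc} of {ast.unparse(expr)}"


def _join_clauses(clauses: list) -> str:
    if not clauses:
        return ""
    if len(clauses) == 1:
        return " with " + clauses[0]
    return " with " + ", ".join(clauses[:-1]) + " and " + clauses[-1]


def _sentence(model: GraphicalModel, node: PGMNode, cite) -> str:
    desc = _subject_description(model, node)
    subject = f"The {desc}, {node.name}"
    if node.generator is not None and isinstance(node.rhs, ast.GeneratorCall):
        spec = node.generator
        verb = spec.template or (
            "is generated by " + spec.name if spec.kind == "generative" else "is computed by " + spec.name
        )
        citation = cite(spec.citations)
        clauses = [
            _clause(model, spec, argname, expr) for argname, expr in node.rhs.args
        ]
        body = f"{subject} {verb}{citation}{_join_clauses(clauses)}."
    else:
        body = f"{subject} is given by {ast.unparse(node.rhs)}."
    if node.observed:
        body += f" The value of {node.name} is observed (clamped to the data)."
    return body


def generate_narrative(model: GraphicalModel, format: str = "markdown") -> str:
    """One sentence per stochastic and deterministic node, in data-first
    order; deterministic given the model (no sampling involved)."""
    if format == "latex":
        def cite(keys):
            return "".join(f"~\\cite{{{k}}}" for k in keys)
    else:
        def cite(keys):
            shorts = [BIBLIOGRAPHY[k][0] for k in keys if k in BIBLIOGRAPHY]
            return " (" + "; ".join(shorts) + ")" if shorts else ""

    sentences = [
        _sentence(model, node, cite)
        for node in _narrative_order(model)
        if node.kind != "constant"
    ]
    return " ".join(sentences)


def cited_keys(model: GraphicalModel) -> list:
    """Reference keys cited by the model's generators, de-duplicated, in
    narrative order."""
    keys: list[str] = []
    for node in _narrative_order(model):
        if node.generator is None:
            continue
        for key in node.generator.citations:
            if key not in keys:
                keys.append(key)
    return keys


def export_latex(model: GraphicalModel) -> str:
    """A compilable LaTeX document: the narrative paragraph, a figure block
    embedding the DOT-rendered PGM, and a bibliography of the cited
    references (each exactly once)."""
    narrative = generate_narrative(model, format="latex")
    keys = cited_keys(model)
    bib_items = "\n".join(
        f"\\bibitem{{{k}}} {BIBLIOGRAPHY[k][1]}" for k in keys if k in BIBLIOGRAPHY
    )
    dot = export_dot(model, hide_constants=True)
    dot_comment = "\n".join("% " + line for line in dot.splitlines())
    return f"""\\documentclass{{article}}
\\usepackage{{graphicx}}
\\begin{{document}}

\\section*{{Model description}}

{narrative}

\\begin{{figure}}[ht]
\\centering
% Render the probabilistic graphical model with Graphviz, e.g.:
%   dot -Tpdf model-pgm.dot -o model-pgm.pdf
% The DOT source is reproduced below.
{dot_comment}
\\fbox{{\\texttt{{PGM: see model-pgm.dot}}}}
\\caption{{Probabilistic graphical model (constants hidden).}}
\\end{{figure}}

\\begin{{thebibliography}}{{99}}
{bib_items}
\\end{{thebibliography}}

\\end{{document}}
"""
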