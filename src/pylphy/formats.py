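"""Readers and writers for the standard phylogenetic interchange formats.

Alignments are read with Biopython (FASTA via ``SeqIO``, NEXUS via
``Bio.Nexus`` so that charset blocks are surfaced); trees are written as
Newick with branch lengths in time units (parent age minus child age) and
optional ``[&deme=...]`` comments, and read back with a small reader whose
output is cross-checked against dendropy in the test suite.

Tip dates: taxon names ending in ``_YYYY`` (a four-digit year) are treated
as dated samples; ages are computed as ``max year - year`` so the youngest
sample has age 0.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .errors import FormatError
from .seqsim import NUCLEOTIDE, PHASED_GENOTYPE, Alignment, DataType
from .trees import Taxa, TimeTree, TreeNode

__all__ = [
    "read_alignment",
    "write_fasta",
    "write_nexus",
    "write_tree",
    "read_tree",
    "parse_newick",
    "write_trace",
]

_YEAR_SUFFIX = re.compile(r"^(?P<stem>.+)_(?P<year>\d{4})$")


def _ages_from_names(names: list) -> list | None:
    """Decode the ``name_YYYY`` tip-date convention; None when not all
    names carry a year suffix."""
    years = []
    for name in names:
        m = _YEAR_SUFFIX.match(name)
        if m is None:
            return None
        years.append(int(m.group("year")))
    latest = max(years)
    return [float(latest - y) for y in years]


def _states_from_string(seq: str, datatype: DataType, name: str) -> list:
    index = {s: i for i, s in enumerate(datatype.symbols)}
    if datatype.name == "phasedGenotype":
        if len(seq) % 2:
            raise FormatError(
                f"phased genotype sequence for {name!r} has odd length {len(seq)}"
            )
        tokens = [seq[i : i + 2] for i in range(0, len(seq), 2)]
    else:
        tokens = list(seq)
    states = []
    for tok in tokens:
        if tok.upper() not in index:
            raise FormatError(f"invalid state {tok!r} in sequence {name!r}")
        states.append(index[tok.upper()])
    return states


def _alignment_from_pairs(pairs, datatype: DataType, charsets=None) -> Alignment:
    names = [name for name, _ in pairs]
    if len(set(names)) != len(names):
        raise FormatError("duplicate taxon names in alignment")
    lengths = {len(seq) for _, seq in pairs}
    if len(lengths) != 1:
        raise FormatError(f"sequences have unequal lengths: {sorted(lengths)}")
    states = [_states_from_string(seq, datatype, name) for name, seq in pairs]
    ages = _ages_from_names(names)
    taxa = Taxa(names, ages)
    aln = Alignment(taxa, np.asarray(states, dtype=np.int16), datatype)
    aln.charsets = dict(charsets or {})
    return aln


def read_alignment(path, format: str | None = None, datatype: DataType = NUCLEOTIDE) -> Alignment:
    """Read a NEXUS or FASTA alignment.

    The format is inferred from the file extension unless given.  NEXUS
    charset blocks are surfaced on the returned alignment's ``charsets``
    attribute (name -> 0-based site indices); tip ages are decoded from
    ``name_YYYY`` suffixes when every taxon carries one.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format is None:
        format = "nexus" if path.suffix.lower() in (".nex", ".nexus", ".nxs") else "fasta"
    format = format.lower()
    if format == "fasta":
        return _read_fasta(path, datatype)
    if format == "nexus":
        return _read_nexus(path, datatype)
    raise FormatError(f"unsupported alignment format {format!r}")


def _read_fasta(path, datatype) -> Alignment:
    from Bio import SeqIO

    pairs = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            pairs.append((rec.id, str(rec.seq)))
    except Exception as exc:
        raise FormatError(f"cannot parse FASTA {path}: {exc}") from exc
    if not pairs:
        raise FormatError(f"no sequences in {path}")
    return _alignment_from_pairs(pairs, datatype)


def _read_nexus(path, datatype) -> Alignment:
    from Bio.Nexus import Nexus

    try:
        nx = Nexus.Nexus(str(path))
    except Exception as exc:
        raise FormatError(f"cannot parse NEXUS {path}: {exc}") from exc
    if not nx.matrix:
        raise FormatError(f"no character matrix in {path}")
    pairs = [(name, str(nx.matrix[name])) for name in nx.taxlabels if name in nx.matrix]
    charsets = {name: sorted(sites) for name, sites in (nx.charsets or {}).items()}
    return _alignment_from_pairs(pairs, datatype, charsets)


def write_fasta(alignment: Alignment, path) -> None:
    with open(path, "w") as fh:
        for i, name in enumerate(alignment.taxa.names):
            fh.write(f">{name}\n{alignment.sequence(i)}\n")


def write_nexus(alignment: Alignment, path, charsets: dict | None = None) -> None:
    """Write a NEXUS alignment.  Phased genotypes are written as two-letter
    state codes (datatype=standard), nucleotides as datatype=dna."""
    dt = alignment.datatype
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN TAXA;\n")
        fh.write(f"    DIMENSIONS NTAX={alignment.n_taxa};\n    TAXLABELS\n")
        for name in alignment.taxa.names:
            fh.write(f"        {name}\n")
        fh.write("    ;\nEND;\n\nBEGIN CHARACTERS;\n")
        fh.write(f"    DIMENSIONS NCHAR={alignment.L};\n")
        if dt.name == "phasedGenotype":
            fh.write("    FORMAT DATATYPE=STANDARD SYMBOLS=\"ACGT\";\n")
            fh.write("    [phased genotypes: two nucleotide symbols per site]\n")
        else:
            fh.write("    FORMAT DATATYPE=DNA GAP=- MISSING=?;\n")
        fh.write("    MATRIX\n")
        width = max(len(n) for n in alignment.taxa.names) + 2
        for i, name in enumerate(alignment.taxa.names):
            fh.write(f"        {name:<{width}}{alignment.sequence(i)}\n")
        fh.write("    ;\nEND;\n")
        if charsets:
            fh.write("\nBEGIN ASSUMPTIONS;\n")
            for name, spec in charsets.items():
                fh.write(f"    charset {name} = {spec};\n")
            fh.write("END;\n")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def write_tree(tree: TimeTree, path=None, include_demes: bool = True) -> str:
    """Serialize a tree as Newick (branch lengths = parent age - child age);
    returns the text and optionally writes it to ``path``."""
    text = tree.to_newick(include_demes=include_demes)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


_NEWICK_TOKEN = re.compile(r"\(|\)|,|;|:[^,():;\[\]]+|\[&[^\]]*\]|'(?:[^']|'')*'|[^,():;\[\]]+")


def parse_newick(text: str) -> TimeTree:
    """Parse Newick text into a :class:`TimeTree`.

    Branch lengths are interpreted as time; node ages are reconstructed so
    the most distant tip from the root has age 0.  ``[&deme=...]`` comments
    become deme labels.
    """
    tokens = _NEWICK_TOKEN.findall(text.strip())
    if not tokens or tokens[-1] != ";":
        raise FormatError("Newick text must end with ';'", text[:80])
    pos = 0
    blen_of: dict[int, float] = {}

    def parse_clade() -> tuple:
        """Returns (node, branch_length_to_parent)."""
        nonlocal pos
        node = TreeNode(0.0)
        if tokens[pos] == "(":
            pos += 1
            while True:
                child, blen = parse_clade()
                blen_of[id(child)] = blen
                node.add_child(child)
                if tokens[pos] == ",":
                    pos += 1
                    continue
                break
            if tokens[pos] != ")":
                raise FormatError("unbalanced parentheses in Newick")
            pos += 1
        # optional label, comment, branch length
        label = None
        blen = 0.0
        while pos < len(tokens) and tokens[pos] not in (",", ")", ";"):
            tok = tokens[pos]
            if tok.startswith(":"):
                try:
                    blen = float(tok[1:])
                except ValueError as exc:
                    raise FormatError(f"bad branch length {tok[1:]!r}") from exc
            elif tok.startswith("[&"):
                m = re.search(r"deme=([^,\]]+)", tok)
                if m:
                    node.deme = m.group(1)
            elif tok.startswith("'"):
                label = tok[1:-1].replace("''", "'")
            else:
                label = tok
            pos += 1
        node.label = label
        return node, blen

    root, _ = parse_clade()
    if tokens[pos] != ";":
        raise FormatError("trailing content after Newick tree")

    # convert depths (via stored branch lengths) to ages
    depths: dict[int, float] = {id(root): 0.0}
    maxdepth = 0.0
    stack = [root]
    order = []
    while stack:
        node = stack.pop()
        order.append(node)
        for child in node.children:
            depths[id(child)] = depths[id(node)] + blen_of.get(id(child), 0.0)
            maxdepth = max(maxdepth, depths[id(child)])
            stack.append(child)
    for node in order:
        node.age = maxdepth - depths[id(node)]
    leaves = [n for n in order if n.is_leaf]
    for i, leaf in enumerate(leaves):
        if leaf.label is None:
            leaf.label = str(i + 1)
    taxa = Taxa(
        [str(n.label) for n in leaves],
        [n.age for n in leaves],
        [n.deme for n in leaves] if all(n.deme is not None for n in leaves) else None,
    )
    return TimeTree(root, taxa)


def read_tree(path) -> TimeTree:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    return parse_newick(path.read_text())


# ---------------------------------------------------------------------------
# Parameter trace
# ---------------------------------------------------------------------------


def _trace_columns(name: str, value) -> list:
    """Flatten a node value into (column, number) pairs; vector entries get
    ``.i`` suffixes.  Non-numeric values yield no columns."""
    if isinstance(value, (bool,)):
        return []
    if isinstance(value, (int, float, np.integer, np.floating)):
        return [(name, float(value))]
    if isinstance(value, np.ndarray) and value.dtype.kind in "if":
        flat = value.reshape(-1)
        return [(f"{name}.{i + 1}", float(v)) for i, v in enumerate(flat)]
    return []


def write_trace(assignments: list, path) -> list:
    """Write a tab-delimited trace: one row per replicate assignment, one
    column per scalar quantity.  Returns the column names."""
    if not assignments:
        raise ValueError("no assignments to trace")
    columns = [c for name, value in assignments[0].items() for c, _ in _trace_columns(name, value)]
    with open(path, "w") as fh:
        fh.write("\t".join(["replicate"] + columns) + "\n")
        for rep, assignment in enumerate(assignments):
            cells = {c: v for name, value in assignment.items() for c, v in _trace_columns(name, value)}
            if set(cells) != set(columns):
                raise ValueError("trace column set differs across replicates")
            fh.write(
                "\t".join([str(rep)] + [repr(cells[c]) for c in columns]) + "\n"
            )
    return columns
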