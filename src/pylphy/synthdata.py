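"""Synthetic alignment fixtures.

Real serially sampled virus alignments (such as the classic respiratory
syncytial virus subgroup A G-protein set: 129 sequences sampled between
1956 and 2002, with codon structure) cannot be redistributed here, so
:func:`write_rsva_like_nexus` simulates a stand-in with the same shape:
129 dated taxa spanning 1956-2002, a codon-structured protein-coding
length, sequences evolved under an HKY model on a serially sampled
coalescent tree with a realistic per-year clock rate.  The output is a
plain NEXUS file whose taxon names carry the ``name_YYYY`` tip-date
convention.

This is synthetic data for exercising the interpreter's data-clamping
path; it reproduces the dataset's dimensions, not its biology.
"""

from __future__ import annotations

import numpy as np

from .formats import write_nexus
from .seqsim import ClockSpec, phylo_ctmc
from .substmodels import hky
from .trees import Taxa, coalescent

__all__ = ["rsva_like_alignment", "write_rsva_like_nexus"]


def rsva_like_alignment(
    n_taxa: int = 129,
    n_sites: int = 630,
    first_year: int = 1956,
    last_year: int = 2002,
    theta: float = 30.0,
    kappa: float = 8.0,
    clock_rate: float = 2e-3,
    seed: int = 20260101,
):
    """Simulate the synthetic stand-in alignment (see module docstring).

    theta is in years (coalescent time scale of a seasonal virus),
    clock_rate in substitutions/site/year.
    """
    if n_sites % 3:
        raise ValueError("n_sites must be a multiple of 3 (codon structure)")
    rng = np.random.default_rng(seed % (2**31))
    years = np.sort(rng.integers(first_year, last_year + 1, size=n_taxa))
    years[0], years[-1] = first_year, last_year
    names = [f"virus{i + 1:03d}_{y}" for i, y in enumerate(years)]
    ages = [float(years.max() - y) for y in years]
    taxa = Taxa(names, ages)
    tree = coalescent(theta, taxa, rng)
    freq = np.array([0.35, 0.18, 0.22, 0.25])  # A-rich, like many RNA viruses
    Q = hky(kappa, freq)
    return phylo_ctmc(tree, Q, n_sites, ClockSpec(mu=clock_rate), rng=rng)


def write_rsva_like_nexus(path, **kwargs) -> None:
    """Write the synthetic dated alignment as NEXUS (``name_YYYY`` taxon
    names carry the tip dates)."""
    write_nexus(rsva_like_alignment(**kwargs), path)
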