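# pylphy

An interpreter and forward simulator for **LPhy**, the concise,
declarative model-specification language for Bayesian phylogenetics.

Phylogenetic analyses combine tree priors, substitution models, molecular
clocks and error models into hierarchies that are hard to report precisely
in prose and hard to reproduce from prose. LPhy addresses this by making
the model itself a small, readable script: every random variable is drawn
from a generative distribution with `~`, deterministic quantities are
computed with `=`, and observed data placed in a `data` block *clamps* the
equally named model variables, turning a simulator into the specification
of an inference problem. `pylphy` is for modellers who want to simulate
from such models, validate simulators against closed forms, and generate
publication-ready model descriptions — without a GUI or an MCMC engine.

## What it does

Given a `.lphy` script, `pylphy`

1. **parses** it (case-sensitive; Unicode identifiers such as `Θ`, `ψ`,
   `κ`; no control flow — repetition is expressed by vectorization);
2. **builds the probabilistic graphical model** — constant nodes
   (squares), deterministic nodes (diamonds), stochastic nodes (circles) —
   resolving generator overloads and type-checking arguments;
3. **clamps** model-block stochastic nodes to equally named data-block
   values;
4. **samples** every unobserved node in dependency order, with one
   name-keyed random stream per node so results are reproducible and
   insensitive to unrelated model edits;
5. **renders** the model as Graphviz DOT and as a natural-language
   narrative with citations (Markdown or LaTeX).

The generator library covers the parametric families (uniform, normal,
log-normal, gamma, exponential, beta, Dirichlet), tree priors (serially
sampled coalescent, structured coalescent with migration, skyline
coalescent, Yule, birth–death, serially sampled birth–death),
substitution models (JC, HKY, GTR, and the 16-state GT16 model on phased
diploid genotypes), strict and relaxed molecular clocks over `PhyloCTMC`,
and the GT16 single-cell error model (amplification/sequencing error ε,
allelic dropout δ).

Any generator is vectorized two ways: `replicates=k` stacks k IID draws
on a new major dimension, and passing a length-k vector where a scalar is
expected broadcasts the generator element-wise:

```
κ ~ LogNormal(meanlog=1.0, sdlog=0.5, replicates=3);
π ~ Dirichlet(conc=[2.0, 2.0, 2.0, 2.0], replicates=3);
Q = hky(kappa=κ, freq=π);   // three rate matrices
```

## Worked example

The bundled 10-taxon script (`example1.lphy`):

```
data {
  L = 200;
  taxa = 1:10;
}
model {
  Θ ~ LogNormal(meanlog=3.0, sdlog=1.0);
  ψ ~ Coalescent(theta=Θ, taxa=taxa);
  Q = jukesCantor();
  D ~ PhyloCTMC(tree=ψ, Q=Q, L=L);
}
```

```python
import pylphy
model, values = pylphy.run_script(pylphy.example_source("example1.lphy"), seed=1)
```

prints (via `examples/01_simulate_coalescent_jc.py`):

```
node kinds: {'L': 'constant', 'taxa': 'constant', 'Θ': 'stochastic',
             'ψ': 'stochastic', 'Q': 'deterministic', 'D': 'stochastic'}
sampled population size Θ = 37.535
tree root age            = 116.763
alignment                = 10 taxa x 200 sites
```

`Θ` is the coalescent population size drawn from its log-normal prior;
the tree's root age is on the coalescent time scale set by `Θ` (root
height has expectation `2Θ(1 − 1/n)`); `D` is the 10 × 200 nucleotide
alignment simulated down the tree under the Jukes–Cantor CTMC.
`pylphy.generate_narrative(model)` turns the same graph into a
methods-section paragraph, e.g. *"The coalescent parameter, Θ has a
log-normal prior with a mean in log space of 3.0 and a standard deviation
in log space of 1.0."*

The `examples/` directory holds one short script per capability:
simulation, data clamping on a dated virus alignment, single-cell GT16
simulation with the error channel, tree priors, vectorization, and
DOT/LaTeX export.

## Command line

```bash
pylphy validate model.lphy             # parse + type-check (exit 2 on errors)
pylphy simulate model.lphy --seed 1 --reps 10 --outdir out/
pylphy narrate  model.lphy --latex -o methods.tex
pylphy graph    model.lphy --hide-constants -o model.dot
echo 'b ~ Normal(mean=0.0, sd=1.0);' | pylphy validate -   # console mode
```

`simulate` writes FASTA/NEXUS alignments and Newick trees per replicate,
a tab-delimited parameter trace, the narrative and the DOT graph; equal
seeds give byte-identical output.

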