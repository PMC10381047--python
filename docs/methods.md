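# Methods

This note records the models implemented by `pylphy`, the conventions
chosen where the language leaves room, and the numerical and design
decisions a maintainer would want to know. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Language semantics

A script is a sequence of `;`-terminated statements, optionally grouped
into `data { }` and `model { }` blocks; bare statements outside any block
are treated as model statements so console snippets work unchanged.
`lhs = rhs` defines a constant (no variables or calls on the right) or a
deterministic node; `lhs ~ Generator(...)` defines a stochastic node. All
generator arguments are named; positional arguments are a parse error, as
are the control-flow keywords `for`, `while`, `if` — repetition belongs
to vectorization, not loops. Identifiers are case-sensitive and may be
any Unicode letter sequence; Greek names (`Θ`, `theta`) are distinct from
their ASCII spellings, with no aliasing. `//` starts a line comment;
block comments are not supported. Numeric literals are integers unless
they contain `.` or an exponent; `-5` parses as unary minus on `5`.
Redefining a variable within a block, including re-`=`-defining a
data-block name in the model block, is rejected; the single sanctioned
collision is a model-block `~` statement sharing a data-block name, which
is the data-clamping idiom.

Generator resolution is Java-overload style: among registered signatures
of a name, the one whose required arguments are all supplied and whose
parameter set covers the supplied names is chosen (ties go to the fewest
unfilled optionals). Type checking of argument *values* happens during
evaluation, when vectorization can be taken into account.

### Vectorization

Two mechanisms, deliberately not composable:

* `replicates=k` invokes the generator k times IID and stacks the results
  on a new major dimension (`replicates=1` yields a length-1 vector, not
  a scalar).
* An argument declared scalar that receives a length-k vector (or a
  vector-valued argument receiving a k-row matrix, or an object-valued
  argument receiving a list of k objects) broadcasts the generator
  element-wise. All broadcast arguments must share the major dimension k;
  there is no R-style recycling, because silent length mismatches are a
  classic source of model bugs.
* `replicates` combined with broadcast arguments is rejected as
  ambiguous (is the result k×k or k?).

Results are stacked as a numpy array when elements are homogeneous
numeric, otherwise as a list (e.g. a list of rate matrices).

### Sampling and reproducibility

Statement order is an evaluation order (use-before-definition is a build
error, so the graph is topologically sorted by construction). Each
stochastic node draws from a dedicated `numpy` PCG64 stream seeded by
`(root seed, sha256(node name), replicate index)`. Consequences: equal
seeds give bitwise-identical assignments, and inserting an unrelated
statement does not perturb any other node's draws — useful when comparing
model variants. Clamped (observed) nodes never consume random numbers;
their dimensions are checked against the generator's output shape when
the graph is sampled, so a 10-taxon alignment clamped onto a 9-leaf tree
raises a shape error rather than silently conditioning on nonsense.

## Parametric distributions

Parameterizations follow the language's conventions: `LogNormal` takes
the log-space mean and standard deviation, `Exp` takes its **mean** (not
rate), `Gamma` shape/scale, `Beta` alpha/beta, `Dirichlet` a
concentration vector. Validation is eager (`sd > 0`, `lower < upper`,
concentrations strictly positive; a degenerate `Uniform(1,1)` is
rejected). Log-densities delegate to `scipy.stats` and return −∞ outside
the support; sampling uses the node's own `numpy.random.Generator`.

## Tree priors

Trees are rooted, binary, time-calibrated: node ages in time units before
the present, tips optionally serial (age > 0). An n-leaf tree has n−1
internal nodes and 2n−2 branches; all simulators are checked against
these invariants and, where available, closed forms.

* **Coalescent** (constant θ, serially sampled): active lineages coalesce
  at rate k(k−1)/(2θ); a tip enters the active set when simulation time
  reaches its age. Waiting times are re-drawn at activation boundaries,
  which is exact for exponentials. E[root height] = 2θ(1−1/n) for
  contemporaneous tips is reproduced within 4 standard errors at 10⁴
  replicates in the suite.
* **Skyline coalescent**: identical event loop, but the population size
  for the j-th coalescent interval (counting from the tips) is the θ of
  the group containing j; `groupSizes` must sum to n−1. Group 1 applies
  to the tip-most intervals.
* **Structured coalescent**: Gillespie competition between within-deme
  coalescence (rate kᵢ(kᵢ−1)/(2θᵢ)) and per-lineage migration (rate m_ij,
  backwards in time). The migration matrix stores θ on the diagonal and
  the (K²−K) migration rates row-major off the diagonal. Internal nodes
  record the deme where the coalescence happened. A hard cap of 10⁶
  events guards the zero-migration/split-demes pathology, which is
  reported as non-convergence rather than a hang. K=1 is allowed and
  reduces to the plain coalescent (verified by a KS test).
* **Yule(λ, n)**: defined as the pure-birth process observed during its
  n-lineage sojourn, i.e. backward interval durations Exp(kλ) while k
  lineages remain, joining uniform pairs. This is the memoryless-stopping
  convention; it makes doubling λ exactly halve all ages.
* **BirthDeath(λ, μ, n[, rootAge])**: the conditioned reconstructed
  process with λ > μ ≥ 0. With g(s) = (1−e^{−rs})/(λ−μe^{−rs}), r = λ−μ:
  given the root age t, the n−2 non-root internal ages are IID with CDF
  g(s)/g(t) (sampled by the closed-form inverse); without a root age, the
  root is drawn from its marginal under a uniform prior on the origin
  time via u ~ Beta(n−1, 2), t = g⁻¹(u/λ) — a transform derived from the
  joint density of the speciation ages (the Beta(n−1,2) form follows by
  the substitution u = λg(t)). Ages are attached to a uniformly chosen
  ranked topology (join two uniform lineages at each age, youngest
  first). Two independent cross-checks live in the suite: at μ=0 the
  construction matches the algorithmically unrelated Yule sampler (KS),
  and given the root age the inner-age distribution matches a brute-force
  forward simulator with rejection on the tip count.
* **BirthDeathSerialSampling(λ, μ, ρ, ψ, rootAge)**: forward simulation
  from a root split at `rootAge`; each lineage births at λ, dies at μ,
  and is ψ-sampled (sampled and removed, becoming a dated tip); extant
  lineages are kept with probability ρ. The returned tree is pruned to
  sampled tips (root = their MRCA). Fewer than two samples is a
  legitimate outcome; the generator retries up to 100 times before
  raising a simulation failure. Sampled-tip counts are cross-checked
  against an independent population-level Gillespie simulator.

Conditioning conventions (on n, with optional root-age conditioning; no
survival-conditioned origin process) were an open design choice; they
were selected because they simulate exactly without rejection and nest
cleanly (μ=0 ⇒ Yule), and they are stated here rather than hidden in
code.

## Substitution models

All constructors return a reversible rate matrix normalized to **one
expected substitution per site per unit time** (−Σπᵢqᵢᵢ = 1), so clock
rates are substitutions/site/time — the convention of the major Bayesian
phylogenetic engines. JC, HKY (transitions A↔G, C↔T scaled by κ) and GTR
(rates ordered AC, AG, AT, CG, CT, GT; q_ij ∝ rate·π_j) are standard.

**GT16** acts on the 16 phased diploid genotypes ordered row-major over
(maternal, paternal) alleles A,C,G,T — AA, AC, …, TT, with AC ≠ CA. A
rate connects genotypes differing at exactly one allele and equals the
corresponding nucleotide exchangeability times the **target genotype
frequency**; double-allele changes have rate zero. Each genotype
therefore has 6 neighbors (96 nonzero off-diagonals), and detailed
balance holds with respect to the genotype frequencies. Whether the
target-genotype or target-allele frequency multiplies the rate was an
open point; the target-genotype form is used because it makes the
supplied 16-simplex the exact stationary distribution, which is what the
Dirichlet prior on π is meant to parameterize.

Transition probabilities use the eigendecomposition of the symmetrized
form D^{1/2}QD^{−1/2} (symmetric for reversible Q with positive π),
falling back to `scipy.linalg.expm` when frequencies contain zeros. The
result is clipped to [0,1] and row-renormalized to absorb last-ulp
negatives. The suite checks Chapman–Kolmogorov (10⁻¹⁰), agreement with a
scaled-series exponential oracle (10⁻⁹), and the JC closed form
P(same,t) = ¼ + ¾e^{−4t/3} (10⁻¹⁰).

## Sequence simulation and clocks

`PhyloCTMC` draws root states IID from π and evolves each site
independently down the tree; one transition matrix is computed per branch
(not per site), which changes nothing distributionally and keeps 200-site
desk simulations instant. The branch-specific rate is the strict-clock
`mu` (default 1.0) or, for a relaxed clock, the branch's entry in a
supplied rate vector. Rates map to branches in a canonical order —
post-order with children visited by smallest descendant leaf label — so
rate assignment is deterministic and reproducible; a 16-leaf tree
requires exactly 30 rates.

### GT16 error channel

The observation model for single-cell genotypes applies, per cell
independently: with probability δ, allelic dropout — one allele
(uniformly chosen) is retained and the cell is read as its homozygote;
independently, every surviving allele is mis-read to each of the three
other nucleotides with probability ε/3. The induced 16×16 channel matrix
is built by enumerating allele outcomes; it is row-stochastic, equals the
identity at ε=δ=0, and maps everything to homozygotes at δ=1. The
enumeration is isolated in one function (`gt16_error_matrix`) so an
alternative published parameterization can be swapped in; empirical
observation frequencies are tested against the enumerated matrix at 10⁵
cells.

### Codon partitioning

`partition_by_codon` assumes the reading frame starts at site 1 and
splits sites 1,4,7,…/2,5,8,…/3,6,9,… into three alignments (sizes (4,3,3)
for L=10); interleaving them back by original index recovers the source.
No frame detection is attempted.

## Synthetic dated-virus fixture

The data-clamping example needs a serially sampled, codon-structured
alignment of realistic size. `pylphy.synthdata` simulates a stand-in with
the shape of the classic RSV-A G-protein set: 129 taxa with `name_YYYY`
tip dates spanning 1956–2002, 630 sites (210 codons), evolved under
HKY(κ=8) with A-rich frequencies on a serial coalescent tree with θ = 30
years and a clock of 2×10⁻³ substitutions/site/year — parameter scales
typical of seasonal RNA viruses. It reproduces the dimensions, dated-tip
structure and rough diversity of such data, **not** its biology: there is
no codon-position rate heterogeneity, no selection, no recombination, and
the tree prior is the same family the model block assumes. Tests passing
on it demonstrate the interpreter's clamping/partitioning machinery, not
fidelity to real RSV sequences.

## Tip dates and I/O conventions

Taxon names ending `_YYYY` are treated as dated samples; ages are
`max(year) − year`, so the youngest tip has age 0. Newick branch lengths
are ages differences (time units), serialized at 17 significant digits so
parse→write round-trips are exact to the double; deme labels travel as
`[&deme=...]` comments. NEXUS reading goes through Biopython (charset
blocks surfaced as 0-based site indices); NEXUS writing is a small
purpose-built writer because phased genotypes need two symbols per site,
which standard writers do not emit. The per-replicate trace is
tab-delimited with vector nodes expanded as `name.1, name.2, …`.

## Problem sizes and tolerances

Monte-Carlo checks use sizes chosen to make a 4-standard-error band
decisive while keeping the whole suite under ~15 s on one core: 10⁴
replicates for coalescent root-height means, 4–5×10³ for KS equivalences
(p > 0.01 with fixed seeds), 10⁵ sites/cells for the JC pairwise and GT16
channel frequencies, 800 accepted replicates for the rejection-sampled
birth–death oracle. Exact identities (model nestings, normalization,
detailed balance) are asserted at 10⁻¹²–10⁻¹⁰.

## Known limitations

No inference: the package simulates and describes models; it emits no
engine configuration and runs no MCMC. No fossilized birth–death prior,
no codon or amino-acid substitution models, no site-rate heterogeneity,
no indels, no ancestral-state output. Method-call syntax (`D.taxa()`)
supports a small implementation-defined set (`taxa`, `nchar`,
`codonPartitions`, `length`). Nested generator calls inside expressions
are restricted to deterministic functions; a generative distribution must
be the entire right-hand side of a `~` statement.
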