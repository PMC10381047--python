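"""Sample each tree prior and print summary statistics.

Shows the five generative tree distributions: constant coalescent (serial
tips), skyline coalescent, structured coalescent with migration, Yule and
birth-death.
"""

import numpy as np

from pylphy import (
    Taxa, birth_death, coalescent, migration_matrix, skyline_coalescent,
    structured_coalescent, yule,
)

rng = np.random.default_rng(42)

serial = coalescent(0.5, Taxa(["a", "b", "c", "d"], [0.0, 1.0, 2.0, 3.0]), rng)
print(f"serial coalescent : root {serial.root_age:.2f}, oldest tip {serial.oldest_tip_age():.1f}")

sky = skyline_coalescent([0.1, 0.2, 0.3, 0.4], [4, 3, 2, 1], Taxa.contemporaneous(11), rng)
print(f"skyline           : {len(sky.internal_nodes())} coalescent intervals (11 taxa)")

M = migration_matrix([0.1, 0.1], [1.0, 1.0])
taxa = Taxa(["a1", "a2", "b1", "b2"], demes=["A", "A", "B", "B"])
g = structured_coalescent(M, taxa, rng)
demes = [n.deme for n in g.internal_nodes()]
print(f"structured        : coalescences in demes {demes}")

y = yule(1.0, 5, rng)
print(f"yule (n=5)        : {y.n_branches} branches, root {y.root_age:.2f}")

bd = birth_death(2.0, 1.0, 10, rng=rng)
print(f"birth-death (n=10): root {bd.root_age:.2f}, ultrametric={bd.is_ultrametric()}")
# Branch counts are always 2n-2; serial/psi-sampled tips have positive ages.
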