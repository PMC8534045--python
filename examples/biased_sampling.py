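"""Bias sampling toward a helical conformation for part of a segment.

A per-residue Gaussian centered on helical dihedrals (-58, -47) with
sigma 10 degrees is mixed into the data distribution with weight 0.99 for
residues 1-15 and 0.80 for residues 16-20 — the recipe for modeling a
single-alpha-helix region whose C-terminus frays.  The script prints how
often sampled torsions fall in the helical basin with and without bias.
"""

import numpy as np

from coilgen import BiasSpec, Mode, ModeContext, assign_torsions, sequence_densities
from coilgen.ndrd import RamachandranGrid

SEQUENCE = "AKLDELRRQIEELSAKNARLKE"  # 22-residue helical segment

grids = {
    key: RamachandranGrid(bins, key)
    for key, bins in sequence_densities(SEQUENCE).items()
}
biases = {
    i: BiasSpec(i, -58.0, -47.0, 10.0, 0.99 if i <= 15 else 0.80)
    for i in range(1, len(SEQUENCE) + 1)
}


def helical_fraction(context: ModeContext, n_chains: int = 200) -> float:
    rng = np.random.default_rng(7)
    hits = total = 0
    for _ in range(n_chains):
        for phi, psi in assign_torsions(SEQUENCE, context, rng):
            hits += (-100.0 <= phi <= -30.0) and (-70.0 <= psi <= -10.0)
            total += 1
    return hits / total


plain = helical_fraction(ModeContext(Mode.TRIPLET, grids))
biased = helical_fraction(ModeContext(Mode.WEIGHTED_TRIPLET, grids, biases))
print(f"helical-basin fraction, unbiased TRIPLET:  {plain:.3f}")
print(f"helical-basin fraction, weighted bias:     {biased:.3f}")
# With weight 0.99 nearly every draw comes from the user Gaussian, so the
# biased fraction approaches 1 while the unbiased one reflects the coil
# library's own alpha-region propensity.
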