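# coilgen

Conformer-pool generation for intrinsically disordered protein segments
from neighbor-dependent backbone dihedral distributions.

Ensemble models of intrinsically disordered regions (IDRs) are usually
obtained by selection: a large pool of candidate conformers is generated
first, and a sub-ensemble matching experimental data (chemical shifts,
RDCs, J-couplings, SAXS) is then picked by a downstream tool such as
CoNSEnsX+ or BME. The quality of the final model is capped by the quality
of the pool, so the pool generator should sample the coil region of the
conformational space efficiently and evenly. `coilgen` builds such pools:
it is a library plus a thin command-line tool for structural biologists who
need tens of thousands of realistic coil conformers of a given sequence.

## Model

Each residue's backbone dihedrals (φ, ψ) are drawn from residue-specific,
neighbor-dependent Ramachandran distributions: 72 × 72 probability tables
over 5° × 5° bins, conditioned on the identity of the left (N-terminal)
or right (C-terminal) sequence neighbor, with marginal ("ALL") tables per
central residue. The published Dunbrack-lab coil libraries (TCBIG or
Coil-only flavors) are read directly; a synthetic generator with
analytically known densities stands in for testing and self-contained runs.

Building modes:

- **LEFT / RIGHT** — sample from the table conditioned on one neighbor.
- **TRIPLET** — combine both neighbors in log space against the marginals,

  p<sub>triplet</sub> ∝ exp( ln p<sub>cl</sub> + ln p<sub>rg</sub> − ln p<sub>lall</sub> − ln p<sub>rall</sub> ),

  renormalized over all bins.
- **WEIGHTED_\*** — mix a per-residue user Gaussian p<sub>u</sub>
  (center φ₀, ψ₀; width σ; weight w ∈ [0, 1]) into the data distribution:
  p = w·p<sub>u</sub> + (1 − w)·p<sub>d</sub>. This encodes a priori local
  preferences such as transient helices.

Draws are inverse-transform ("roulette-wheel"): the cumulative
distribution runs in a fixed bin order from (−180, −180) to (+175, +175),
normalized to end at exactly 1, and a uniform variate picks the first bin
whose cumulative value exceeds it.

The pipeline then: (1) builds an extended starting chain at φ = −65°,
ψ = +135°; (2) assigns the sampled torsions and constructs all backbone
atoms (N, CA, C, O, CB) by natural-extension-reference-frame (NeRF)
placement with fixed Engh–Huber-style geometry and trans peptide bonds;
(3) rejects chains with CA–CA contacts < 4 Å between non-sequential
residues (optionally attempting an "unknotting" repair: perturb φ/ψ of the
residue midway between the clashing pair by ±δ, trying all sign
combinations); (4) optionally invokes external side-chain packing and
energy-minimization tools through subprocess hooks; (5) applies an
all-atom van-der-Waals overlap screen; and (6) writes each accepted
conformer as `<base>min_<k>.pdb`, retrying failed slots up to a per-slot
trial limit.

## Worked example

```sh
python examples/generate_pool.py
```

```
accepted 20/20 structures in 51 trials
  rejected (CA clash): 16
  rejected (atom clash): 15
first file: pool_min_1.pdb
```

20 conformers of a 35-residue disordered segment were accepted after 51
trials: 16 sampled chains folded back onto themselves (CA–CA < 4 Å) and 15
passed the CA screen but carried atomic overlaps ≥ 0.6 Å; each rejection
triggered a fresh resampling of the whole chain. Biasing part of a
sequence toward a helix (`examples/biased_sampling.py`) shows the weighted
mixture at work:

```
helical-basin fraction, unbiased TRIPLET:  0.253
helical-basin fraction, weighted bias:     0.941
```

With a weight-0.99 Gaussian at (−58, −47), σ = 10°, almost every draw lands
in the helical basin; unbiased sampling reflects the coil library's own
α-region propensity. `examples/clash_repair.py` demonstrates the
unknotting heuristic repairing a kinked 16-mer by shifting one residue's
φ and ψ by +30° each.

The same pipeline is available from the shell:

```sh
coilgen --sequence SLRVKFSRSAEPPAYQQGQNQ --n 100 --mode TRIPLET \
        --ndrd-dir tables/ --base pool_ --out-dir out/ --seed 7
```

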