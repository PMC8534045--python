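# Methods

## Sampling model

Backbone conformations are sampled residue by residue from discretized
Ramachandran distributions: 72 × 72 tables of bin probabilities over
5° × 5° (φ, ψ) cells, labelled by their left edge from −180° to +175°,
with the half-open convention [edge, edge + 5°). Tables are conditioned
on the central residue and on the identity of one sequence neighbor
(left = N-terminal side, right = C-terminal side); marginal tables
("ALL") average over the neighbor. Cis-proline is accepted as a distinct
central-residue type when present in a table file, but generation uses the
trans tables by default (`CPR` keys are loadable; cis geometry is not
built).

All tables are renormalized to unit sum at load time, and every table must
supply all 5184 bins (a missing bin is a parse error naming the key).
Probabilities are floored at 1e−12 before any logarithm so that empty bins
cannot produce −∞; the floor perturbs normalized probabilities far below
every tolerance used here.

The TRIPLET combination follows the log-space form

    p ∝ exp( ln p_cl + ln p_rg − ln p_lall − ln p_rall ),

renormalized after exponentiation. Note that this divides by *both*
marginals; when a conditional table equals its marginal the ratios cancel
bin-wise and the combination is exactly uniform — the combination keeps
only the information the neighbors add. Terminal residues lack one
neighbor: they fall back to the marginal table on the missing side, and in
TRIPLET mode the first residue degrades to RIGHT and the last to LEFT.

Weighted modes mix a per-residue isotropic wrapped Gaussian (single σ for
both axes, wrap sum truncated at ±2 turns — ample for σ ≤ 60°) into the
data distribution as p = w·p_u + (1 − w)·p_d. Because the mixture is
linear, mixing densities and then cumulating is identical to mixing
cumulatives; w = 0 and w = 1 reduce exactly to the data-only and user-only
samplers.

Draws are inverse-transform: bins are flattened φ-major starting at
(−180, −180) and ending at (+175, +175), the cumulative sum is divided by
its total and its last entry forced to exactly 1.0, and a uniform variate
u selects the first bin whose cumulative value strictly exceeds u. The
emitted angle is the bin's left edge, so all sampled torsions are
multiples of 5°; the optional external minimization hook exists to relax
this grid constraint. One seeded generator per run consumes exactly one
variate per residue in residue order, which makes whole runs reproducible
and byte-identical with hooks disabled.

## Discretization of analytic densities

Synthetic tables assign each bin the analytic density at the bin center
(midpoint rule), so the most probable bin is always the one containing a
Gaussian's center. The evaluation point is nudged 1e−9° toward the left
edge, which resolves the degenerate case of a center lying exactly on a
bin edge in favor of the containing bin (per the half-open convention)
while perturbing probabilities by only ~1e−13 relative.

## Backbone construction

Chains are built atom by atom with the natural-extension reference frame
construction. Geometry constants (Å, degrees): N–CA 1.458, CA–C 1.525,
C–N 1.329, C=O 1.231, CA–CB 1.521; N–CA–C 111.0, CA–C–N 116.2,
C–N–CA 121.7, CA–C–O 120.8, C–CA–CB 110.1; ω = 180° (trans) for every
peptide bond including prolines. These are fixed single-conformation
values of the Engh–Huber type, chosen for bit-reproducibility; a
downstream force-field minimization is the intended way to relax them. CB
is placed with a torsion constant chosen so the improper dihedral
N–CA–C–CB measures −122.6°, i.e. L-amino acids; glycine gets no CB, and no
hydrogens or further side-chain atoms are built. The first residue sits in
a canonical frame (N at the origin, CA on +x, C in the xy half-plane), so
identical inputs give identical coordinates to the last bit.

Torsion measurement uses the standard IUPAC sign convention (verified
against an independent implementation in tests) and inverts the builder to
well below 1e−4°. φ of the first and ψ of the last residue are undefined
(NaN on measurement); the sampled ψ of the last residue still orients its
carbonyl oxygen.

## Clash screens

* CA screen: any residue pair with |i − j| > 1 and CA–CA distance strictly
  below 4.0 Å is a clash (a 4.00 Å pair is not). Pair search uses a k-d
  tree; tests compare against a naive all-pairs scan.
* Discontinuity: |i − j| ≤ 3 with CA–CA distance strictly above 20 Å flags
  corrupted coordinates; a correctly built chain with fixed bond geometry
  cannot trigger it.
* All-atom screen: overlap(i, j) = r_vdw(i) + r_vdw(j) − d(i, j) is a
  clash when ≥ 0.6 Å and the atoms are more than 4 covalent bonds apart
  (both thresholds configurable; these defaults emulate the documented
  defaults of the commonly used GUI clash checker). The radius set is
  Bondi (1964): C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å, shipped as a
  versioned constant. Without hydrogens and side chains the screen is an
  approximation by construction.

## Clash repair ("unknotting")

Clashes whose endpoints lie within one residue of another clash's
endpoints are merged into segments; each segment keeps its closest pair
(i, j). The adjustable residue is ⌊(i + j)/2⌋ (floor on ties); its φ and ψ
enter the plan, ψ only for proline. If the total torsion count exceeds the
budget (`max_unknot_torsions`, 0 = disabled) the structure is dropped
without any attempt. Otherwise all 2^k assignments of {+δ, −δ} are applied
in lexicographic order (+ before −), each candidate is rebuilt and
CA-screened, and the first clash-free candidate is accepted; the all-atom
screen still runs afterwards in the pipeline. The accepted structure
differs from the input only at the planned torsions, by exactly ±δ.
Defaults: δ = 30°, budget 0 (repair off — resampling is usually cheaper
for segments under ~75 residues).

## Pipeline accounting

Each of the n output slots performs up to `tries_per_structure` trials
(default 30), so a run executes at most n × tries trials; an always
failing input consumes exactly that bound. Every trial is recorded with
the stage reached and a rejection reason (CA clash, unknot fail,
sidechain fail, minimization fail, atom clash); reason counts always sum
to trials minus acceptances. External side-chain packing and minimization
are subprocess adapters with `{in}`/`{out}` command templates, disabled by
default; a nonzero exit, missing output, or a log lacking the configured
success marker fails the trial, never the run. Temporary hook files are
removed unless `keep_temp` is set.

## Synthetic coil library

The synthetic table generator emulates a coil library restricted to
non-helix/non-strand secondary structure. Per central residue the
marginal is a three-basin mixture — polyproline II (−65, 145, σ 12°),
extended β (−125, 140, σ 15°) and α-region turns (−63, −38, σ 10°) with
base weights 0.37/0.35/0.28 — plus a 0.5% uniform pedestal that keeps all
bins strictly positive (the role Dirichlet smoothing plays in real
libraries, and what keeps the log floor inert). Basin centers and weights
are jittered deterministically per key (CRC32-seeded, ±4° / ±5%), so
different residues and neighbors get genuinely different tables.

Neighbor-conditioned tables are derived from the marginal m as
normalize(m^1.5 · t_key), where t_key is a wide (σ 80°) Gaussian tilt to
the 0.3 power: conditioning on a neighbor sharpens the marginal and leans
it slightly. This reproduces the statistical structure real libraries
have (marginals are averages of conditionals; conditionals carry more
information), and it makes the TRIPLET combination analytically recover
m·t_l·t_r — a coil-like density — instead of collapsing to uniform, which
is what happens when conditional and marginal tables are (near-)identical.

What the generator does **not** emulate: residue-type-specific basin
shapes (glycine's mirrored map, proline's restricted φ), correlations
beyond nearest neighbors, and the detailed bin-level texture of real
Dirichlet-smoothed tables. Tests passing on synthetic tables therefore
validate the machinery (parsing, combination, sampling, construction,
screening) — not the biophysical accuracy of any particular published
library.

## Problem sizes and defaults

Test and example runs use a 55-residue segment (a disordered-receptor-tail
length) with pools of up to 50 conformers, and 2 × 10⁵ draws for the
sampling-fidelity check; these sizes exercise every code path while
keeping the suite quick. Run defaults: 10 structures, TRIPLET mode,
TCBIG flavor, 30 tries per slot, hooks off, repair off. The per-slot
retry bound is n × tries trials in the worst case.

## Known limitations

* No cis-proline geometry; ω is always 180°.
* The all-atom screen sees only backbone atoms plus CB; with side chains
  packed externally the screen underestimates overlap.
* Left-edge angle emission quantizes torsions to 5°; use the minimization
  hook when continuous geometry matters.
* The unknotting heuristic is strictly discrete and local; it cannot
  resolve clashes requiring coordinated multi-residue motion.
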