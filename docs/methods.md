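# Methods

`stepfold` implements the computational chain used to ask whether a
non-canonical residue substitution destabilizes a folded protein:
discrete molecular dynamics (DMD) over step potentials, replica-exchange
sampling, WHAM melting analysis, trajectory analytics (RMSD/RMSF/correlated
motions), a backbone-dependent rotamer-library builder for non-canonical
side chains, and a repacking-Monte-Carlo ΔΔG estimator. Everything runs at
desk scale on synthetic systems whose answers are known or constructible,
so each stage can be validated against an oracle.

## Units and conventions

Reduced units throughout the simulation layer: length in Å, energy in
kcal/mol, mass in amu, k_B = 1 (temperature therefore carries energy
units). One reduced time unit is √(amu·Å²/(kcal/mol)) ≈ 48.9 fs; the 50 ps
exchange interval of the reference protocol corresponds to ≈ 1023 reduced
time units, and is configurable. Reduced temperatures convert to Kelvin
via k_B = 0.0019872 kcal/(mol·K) — the conversion is indicative only,
since simulation temperatures do not directly equate to physical ones.
Coordinates are Å; residue numbering is the 1-based author numbering of
the input PDB; internal atom indices are 0-based and contiguous.

## Step-potential force field

Every interaction is a `StepPotential`: an infinite hard core, a ladder of
constant-energy shells, and exactly zero energy beyond the outermost
radius. Bonded terms (bond lengths, 1-3 and 1-4 distances, disulfide,
metal-ligand and regenerated peptide links) are *bounded* wells — infinite
walls on both sides — built around the current geometry with fractional
tolerances (bonds 2 %, 1-3 5 %, 1-4 10 % by default; the source protocol
does not state its tolerances, these are DMD-conventional values).
Continuous potentials are discretized into n equal-width shells between the
hard core (where the potential first drops below a 100 kcal/mol cap) and a
cutoff, each shell carrying the mean of the continuous form over the shell;
the sup-norm discretization error decreases monotonically with the number
of shells on the Lennard-Jones test. Default hard cores are 0.8 × the sum
of the elements' van-der-Waals radii. Disulfides are detected at S–S
< 2.5 Å, metal–ligand links at metal–N/O < 2.8 Å; metals are constrained
to their ligands because unligated metal sites are not meaningful in a
square-well model.

An implicit-solvation profile (e.g. a Lazaridis–Karplus-style effective
energy) can be supplied as sampled values and discretized the same way; no
solvation parameter set ships with the package, because the Gō surrogate
below carries the folding physics at this scale.

## Event-driven dynamics

Between events particles move ballistically. An event is a pair reaching a
wall of its step potential; the pair receives an impulse along the line of
centers: it crosses when the radial kinetic energy in the pair frame
exceeds the step height ΔU (total energy conserved exactly, the radial
relative speed mapping to √(v² − 2ΔU/μ)), and reflects elastically
otherwise. Momentum is conserved identically at every event. The engine
keeps one next-event prediction per pair and rescans the affected pairs
after each event; simultaneous events resolve in pair-index order, which
makes runs bit-reproducible for a fixed seed. The hot loop is compiled
with numba; the first call in a session pays a one-time compilation cost.

Temperature control is an Andersen thermostat: at Poisson-distributed
times (default rate 0.1 per particle per time unit) one particle's
velocity is redrawn from the Maxwell–Boltzmann distribution. With the
thermostat off, total energy drifts by less than 1e−7 kcal/mol over 10⁴
events (floating-point only); with it on, the mean kinetic energy per
degree of freedom converges to T/2.

## The Gō-model study system

The folding workhorse is a one-bead-per-residue Gō model: residue pairs
with |i−j| ≥ 3 within 7.5 Å in the reference structure get a square well
of depth −ε spanning [0.9, 1.1] × the native distance; all other
non-bonded pairs are hard spheres (bead radius 2 Å). Chain connectivity
enters as bond wells only. This last choice is deliberate: 1-3 (and
especially 1-4) distance wells drain the unfolded state's entropy so
thoroughly that the chain cannot melt anywhere near the working
temperature window — with them in place the transition sits above T ≈ 1.0
even for shallow wells, far outside the 0.48–0.71 ladder.

Two fold templates ship: a two-strand hairpin (strand spacing 3.4 Å,
strand separation 4.8 Å, ±0.8 Å zigzag; 25 native contacts at n = 20) and
an α-helix-like spiral. A small seeded jitter (σ = 0.05 Å) breaks lattice
degeneracies; generation retries with an offset seed if the jitter creates
an overlap.

The default well depth is ε = 0.6 kcal/mol. This value was calibrated at
design time so that the hairpin's cooperative transition sits mid-ladder:
direct C_V(T) = var(E)/T² scans show the collapse of the native contact
network between T ≈ 0.55 and 0.70, and the WHAM major peak lands at
T_m ≈ 0.6, comfortably inside the sampled 0.48–0.71 range, where the
density of states is well constrained. Deeper wells (ε ≳ 1) push melting
above the ladder top, where any WHAM peak position is extrapolation noise.
T_m increases monotonically with ε (tested by doubling ε under a fixed
ladder and seed).

### The modified ("BMAA-like") variant

`make_modified_variant` swells one bead by Δr (default 0.3 Å), gives it a
formal +1 charge annotation, and shallows every native well involving the
site by a factor (1 − Δε), default Δε = 0.9 — the modified side chain
nearly abolishes its native packing interactions. The default site is the
maximum-contact-degree bead nearest the quarter-chain position: a strand
core site away from the floppy termini and turn. Consequences, each the
toy-scale analogue of a destabilization signature:

* the ground-state energy rises by Δε·ε·(site contact degree), so the
  low-temperature modal potential energy is strictly higher than wild
  type;
* the major C_V peak shifts to lower temperature;
* the modified bead's RMSF increases (≈ +0.5 Å at T = 0.25).

Two systematic findings from the calibration study are worth recording.
First, swelling dominates weakening if Δr is large: at Δr ≥ 0.7 Å the
enlarged hard core sterically cages the site and its neighbours (their
RMSF *drops*), and at Δr = 1.0 Å the core overlaps a native contact
outright — which is why the default swelling is modest and why a staged
relaxation (`staged_equilibration`: a short descending-temperature
annealing schedule) is provided for post-substitution strain. Second, the
flexibility gain concentrates on the modified bead itself; in a
distance-well model the neighbours are pinned by their own contacts and
inherit almost nothing.

## Replica exchange and WHAM

Replicas run at the 16-rung ladder 0.48, 0.495, …, 0.71 (overridable);
neighbouring rungs attempt to exchange temperatures every interval with
Metropolis probability min(1, exp[(1/T_i − 1/T_j)(E_i − E_j)]) (T_i < T_j),
alternating even/odd pairs. Velocities rescale by √(T_new/T_old) on
acceptance. One RNG stream per replica plus a swap stream, all derived
from the master seed, keep runs reproducible without cross-replica
coupling. The swap rule satisfies detailed balance analytically, and
in practice the per-rung energy distributions from a two-rung exchange run
are indistinguishable (KS distance < 0.08 at ~10⁴ frames) from
single-temperature runs.

WHAM iterates the self-consistency equations in log space (free-energy
tolerance 1e−7, max 10⁵ iterations) over shared-bin histograms
(Freedman–Diaconis width on the pooled sample by default; histograms whose
supports do not connect raise an error rather than silently extrapolate).
C_V(T) = (⟨E²⟩−⟨E⟩²)/T² follows from the recovered density of states with
log-sum-exp stabilization; melting events are local C_V maxima with
prominence ≥ 10 % of the global maximum (enough to separate minor
pre-melting shoulders from noise on the toys), the global maximum being
the major transition. On a two-level system with g₁/g₀ = 50 and ΔE = 2 the
pipeline recovers ln(g₁/g₀) within sampling error and the Schottky peak
temperature within 1 % of the closed form.

Single-temperature potential-energy histograms discard a configurable
leading fraction (default 20 %) as equilibration and report the modal bin
center.

## Trajectory analytics

Superposition is Kabsch via SVD with the determinant correction (proper
rotations only). RMSF superposes every frame onto an iterated mean
structure (2 rounds) and reports per-bead fluctuation; the correlated-
motion map is the isotropic normalized covariance
C_ij = ⟨Δr_i·Δr_j⟩/√(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) with zero-variance rows flagged,
and difference maps subtract element-wise with an exactly zero diagonal.
Full 3×3 covariance blocks and PCA are out of scope.

Because per-run RMSF estimates of a marginally stable toy mix slowly
(run-to-run dispersion ~0.85 Å that does not shrink with run length —
long-lived conformational macrostates), the variant-flexibility check
averages 8 independent replicate runs per seed before applying a one-sided
sign test over 5 paired seeds (pass at ≥ 4/5). Dynamics comparisons run at
T = 0.25, well below the toy's T_m, where the native cage dominates.

## Rotamer libraries for non-canonical residues

The builder follows the staggered-seed protocol: a regular φ/ψ grid (10°
increments → 36 × 36 = 1296 bins), a χ scan at 30° increments inside each
bin, assignment of each grid point to the nearest staggered seed
(+60°/180°/−60° per χ, ties shared equally), and per-seed
Boltzmann-weighted circular means, circular standard deviations
(√(−2 ln R̄)) and probabilities, normalized per bin. The quantum-chemical
torsional surface of the original protocol is replaced by a pluggable
`energy_fn(φ, ψ, χ…)`; a smooth threefold-barrier toy surface for the
BMAA side chain is the shipped default. The Boltzmann temperature for
probabilities is k_BT = 0.5917 kcal/mol (298 K); probabilities are
normalized within each φ/ψ bin (the library-construction convention).
A post-processing mode overwrites χ standard deviations and attaches a
reference energy from a packaged lysine table — shipped as a constructed
synthetic stand-in (`data/lysine_reference_synthetic.txt`), not values
extracted from any published library.

BMAA itself is a residue template: serine's backbone plus the
Cβ–Nγ(H)–Cγ(methyl) side chain, protonated secondary amine, net +1, two χ
torsions; geometry uses standard bond lengths (Cβ–N and N–C 1.47 Å) and
tetrahedral angles, since no optimized geometry is published.

## ΔΔG by repacking Monte Carlo

The estimator follows the 20 × 20 × 20 replicate protocol: 20 independent
rounds, each taking the best of 20 independent repacking simulations of 20
Metropolis steps (k_BT = 0.6 kcal/mol) for both the wild-type and the
mutant structure over the same local shell (residues within 8 Å of the
site), ΔΔG = best mutant energy − best wild-type energy per round, and the
report is mean ± SD over rounds. Positive values mean destabilization.
Rounds are seed-exchangeable (permuting round seeds permutes the per-round
values only). The energy model is the same step-potential machinery
evaluated statically: element-typed discretized Lennard-Jones (uniform
well depth 0.15 kcal/mol, σ from vdW radii, 6 shells to 8 Å) plus a
screened charge term (Coulomb / 10ε_r) for charged pairs; 1-2/1-3/1-4
pairs are excluded; hard-core clashes score a large finite penalty
(10³ kcal/mol) so the Markov chain remains well-behaved. Flexible-backbone
mode adds cumulative φ/ψ pivots at the site (Gaussian σ = 3°, clamped to
±10°), applied as rotations of the side chain about the N–Cα and Cα–C
axes — a local approximation of small backbone moves.

The packed-core validation fixture is constructed, not simulated: a
GLY-SER-GLY peptide with obstacle atoms placed 2.5 Å beyond the serine Oγ
of the +60° and 180° rotamers, leaving the −60° channel open. A one-arm
side chain escapes through the channel (ΔΔG ≈ 0); a head branched at
~120° on Cβ cannot orient both arms away and clashes in every rotamer
(ΔΔG strongly positive). On this fixture the Metropolis search reproduces
the exhaustive rotamer-enumeration minimum to < 0.01 kcal/mol at 200
steps, identity substitutions give 0 ± 0.1, and the bulky + charged
template is strictly more destabilizing than a conservative same-charge
one — the qualitative pattern of a sterically demanding non-canonical
substitution versus a lysine control. No attempt is made to reproduce
absolute ΔΔG values of any published table; those depend on a proprietary
force-field parameterization.

## What the synthetic systems do and do not show

The generators emulate: two-state folding thermodynamics with known
partition functions; cooperative melting of a small native-contact
network; the energetic and dynamic signature of a single destabilizing
modification; steric selection among side-chain rotamers in a crowded
pocket. They do not emulate: real protein topology (no attempt at any
specific protein's fold, metal sites or dimer interface), hydrogen-bond
directionality (no reaction algorithm), solvation thermodynamics, or
sequence-dependent backbone statistics. Passing tests therefore validate
the *machinery* — event handling, estimators, statistics — not the
biological magnitude of any destabilization; quantitative melting shifts
and ΔΔG values at protein scale are out of scope by design.

## Problem sizes

Defaults were chosen so every workflow runs in minutes on one CPU: 20-bead
peptides, 16-replica REMD segments of a few thousand reduced time units,
10⁵-sample oracles, repacking protocols of a few hundred energy
evaluations. All sizes are config values and scale up transparently.
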