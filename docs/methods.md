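# Methods

This note records the models, conventions and deliberate choices behind the
package, in the spirit of a methods section: what is computed, under which
assumptions, and what the synthetic benchmarks do and do not demonstrate.

## Geometric hydrogen-bond criterion

A donor–acceptor pair is hydrogen-bonded in a frame when the heavy-atom
distance is strictly below `d_max` (default 3.5 Å) and, in explicit-hydrogen
mode, at least one donor hydrogen gives a donor–hydrogen–acceptor angle
strictly above `theta_min` (default 120°), measured at the hydrogen vertex.
Both cutoffs are strict comparisons.  Crystal structures normally lack
hydrogens, so `distance_only` mode (distance test alone) is the sensible
default for static structures; trajectories from simulation topologies carry
hydrogens and use the full criterion.  Distance-only detection is by
construction a superset of explicit detection at equal `d_max`.

Donor/acceptor assignment comes from a built-in chemistry dictionary covering
the 20 amino acids (backbone amide N donates except proline; carbonyl O
accepts; side-chain polar atoms as usual — e.g. Ser OG donates and accepts,
Arg NE/NH1/NH2 donate, Asp OD1/OD2 accept), the four ribonucleotides
(2′-OH donates and accepts; O3′/O4′/O5′ and the phosphate OP1/OP2 accept;
base donors/acceptors per nucleobase) and water (donor with two hydrogens,
acceptor).  Atoms of unknown residues are skipped with a warning rather than
guessed.  Water–solute bonds are evaluated in both donor directions and
either direction qualifies; this symmetric treatment is used throughout the
bridge analyses.

Neighbour search uses a k-d tree at radius `d_max`.  The tree is an
implementation detail: a property test asserts bitwise agreement with the
exhaustive O(n²) evaluation, so any accelerator must be exact.  When a
trajectory carries an orthorhombic box, distances and hydrogen geometry are
minimum-imaged; there is no periodic treatment by default.

## Water bridges and residence statistics

A bridge site is a set of solute atoms.  Its per-frame occupant is the water
satisfying the H-bond criterion with *every* site atom simultaneously; if
several qualify, the smallest sum of heavy-atom distances wins, with exact
ties going to the lower water index (deterministic).  From the occupant
series:

* **occupancy** — occupied frames / total frames × 100 (raw series, no gap
  forgiveness);
* **binding events** — maximal runs of the same water identity.  An
  interruption (vacancy or different occupant) shorter than
  `gap_tolerance_ps` is absorbed if and only if the same water resumes;
  absorbed gap frames count toward the event's duration (span from first to
  last occupied frame), which makes the maximum binding time non-decreasing
  in the tolerance.  A different water's brief visit that gets absorbed does
  not additionally count as an event of its own, so the event count is
  non-increasing in the tolerance.  The default tolerance is 0 ps (strict);
  because the appropriate forgiveness is system-dependent, the CLI site
  report prints a 0/10/50 ps sensitivity line instead of committing to one.
* **long residency** — a site whose maximum binding time reaches 1 ns, an
  order of magnitude above typical surface-water exchange (~50–500 ps).

Bridge discovery enumerates *pairs* of polar solute atoms (optionally
restricted to cross-partition pairs, e.g. protein × RNA) whose pairwise
bridge occupancy reaches a threshold.  Larger sites are intentionally not
inferred automatically — which atoms constitute "one site" is a judgement
call — and are instead declared by the user and scored with the same
machinery.

Waters are classified per frame into three groups: *bridging* (H-bonded to
two or more solute atoms), *first shell* (within 3.5 Å of a solute heavy
atom but not bridging) and *bulk*.  Salt bridges are classified as *direct*
(any cation–anion heavy-atom distance ≤ 3.5 Å), *water-mediated* (a single
water H-bonds both sides) or *separated*.

## Density grids

After Kabsch superposition of every frame onto frame 0 (default fit
selection: protein backbone N/CA/C; the choice of fitting frame shifts peak
positions slightly and is exposed as an option rather than fixed), water
oxygens are histogrammed into cubic voxels of edge 0.5 Å (volume 0.125 Å³)
over the solute bounding box padded by 5 Å.  Voxel intervals are half-open
`[low, high)` so boundary hits are assigned deterministically.  Counts are
converted to fold-over-bulk by dividing by `n_frames × voxel_volume ×
0.0334 Å⁻³`, the number density of pure water at ambient conditions — a
fixed constant so that "n-fold over bulk" is reproducible.  Peaks are
26-neighbourhood local maxima above a fold threshold (default 2).  A water
pinned in one voxel for every frame therefore has fold-over-bulk
1/(0.125 × 0.0334) ≈ 239.5, a convenient closed-form check.  Maps export as
OpenDX scalar fields with the last (z) index varying fastest, the order
PyMOL, VMD and APBS expect.

## Crystal consensus sites

The copies of an asymmetric unit are superposed onto the first chain over
their common residues/atoms (backbone = N, CA, C, O; termini present in only
one copy are excluded).  Waters are assigned to the nearest protein chain
(deposited waters belong to the asymmetric unit, not a chain), carried into
the reference frame by their chain's transform, and clustered greedily:
seeds in decreasing order of neighbour count within the cutoff, members join
the nearest centroid within the cutoff, centroids updated; the ordering rule
makes the result deterministic and invariant to chain relabelling.  The
cluster cutoff defaults to 1.2 Å — below half a water–water contact
distance, so distinct adjacent sites cannot merge — and is exposed as a
flag, since published presence calls rarely state a numeric criterion and
any reproduction is cutoff-sensitive.  A site's presence count is the number
of distinct source chains among its members; coordination labels list polar
protein atoms within 3.5 Å of each member water, and the site label keeps
the atoms shared by a majority of member chains.

Chain-vs-chain and ensemble-vs-model comparisons use the same common-atom
mapping and report post-superposition RMSDs (mean over distinct pairs);
a per-chain residue-number offset map reconciles structures with different
numbering.

## Kinetics and affinity energetics

Association traces follow A(t) = A∞(1 − e^(−k_obs·t)) with k_obs = k_on·C +
k_off; dissociation follows a pure exponential decay.  The "global" fit is
decomposed into per-trace nonlinear fits (rate seeded from the half-rise
time) plus a weighted linear regression of k_obs on concentration (weights =
inverse squared rate standard errors); k_on is the slope, k_off comes from
the dissociation decay, K_D = k_off/k_on.  Instrument software implements
the global objective internally; this standard decomposition is our stated
interpretation, not a claim of identity.  ΔΔG = RT·ln(K_D,mut/K_D,wt) with
R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹ and T = 298.15 K by default (measurements at
25 °C), positive when the mutant binds more weakly; the definition is
antisymmetric and additive over chains of comparisons.

## Synthetic data: what it emulates, and what it does not

The generators produce every input with exact ground truth and no physics:

* **Toy solute** — a template-built peptide chain (side chains toward −y,
  including a solvent-exposed serine) with a parallel RNA strand close
  enough for protein–RNA bridges; atom names are standard so the chemistry
  dictionary applies.  Geometry is sane (bonded neighbours 0.9–1.8 Å) but
  not physical.
* **Bridge trajectories** — a pool of waters takes turns occupying a planted
  site for exponentially distributed dwells (identity exchange each run);
  vacancy lengths are tuned, deterministically per seed, to hit a target
  occupancy within 2 points.  The planted water is placed ~2.8 Å from every
  site atom with hydrogens aimed at the acceptors, and the geometry is
  re-checked against the package's own criterion at generation time.
  Off-duty and bulk waters are re-drawn uniformly every frame (≥ 2.4 Å from
  the solute, ≥ 4 Å from planted sites) — i.e. infinitely fast bulk
  exchange.
* **Crystal assemblies** — rigid copies of the toy protein with shared water
  sites planted in exactly k copies.  Jitter parameters are RMS positional
  displacements (per-coordinate σ/√3), the way crystallographic coordinate
  error is quoted; at 0.3 Å RMS the 1.2 Å cluster cutoff recovers presence
  counts exactly.
* **Kinetics traces** — closed-form exponentials at the 26–200 nM
  concentration grid with multiplicative Gaussian noise.

Because solute atoms are static, bulk waters uncorrelated between frames and
dwell times exactly exponential, passing these benchmarks demonstrates the
*bookkeeping* — criterion evaluation, occupant tracking, event statistics,
clustering, fitting — not robustness to conformational dynamics, drifting
superpositions, or correlated solvent motion found in real trajectories.
Occupancies of real interface bridges additionally require microsecond-scale
sampling that is far outside desk-scale reproduction.

## Problem sizes

Default benchmark sizes were chosen so the whole suite runs in well under a
minute of CPU: residency recovery uses five 50 000-frame trajectories
(dt = 10 ps, τ = 2 ns, ~1000 events pooled — mean dwell recovered to a few
percent), oracle-equivalence checks use ≤ 50-atom frames and 50-frame
trajectories, and density/uniformity checks use a few hundred frames.

## Crystal-side conventions

Waters are recognised by residue names HOH/WAT/SOL/TIP3; monatomic ions are
excluded from water analyses.  Alternate locations other than blank/A are
dropped.  Symmetry expansion applies the named space group's operators plus
all ±1 lattice translations (27 cells), sufficient for contact counting;
alternative origin choices are not explored.  The refinement-water filter
keeps waters whose nearest protein distance lies in [2.0, 4.0] Å and whose
B-factor is ≤ 50 Å² — deletion of *high*-B waters, following standard
refinement practice.  First-shell counts take distinct water oxygens
(symmetry images counted once each) within 3.5 Å of a chain's heavy atoms;
each chain's count is independent, so a water touching two chains counts for
both.

## Known limitations

* Orthorhombic minimum-image only; no triclinic boxes.
* Single-water bridges only; chained two-water bridges are out of scope.
* mmCIF is not parsed; anisotropic B-factors are ignored.
* The kinetics model has no mass-transport or surface-depletion terms.
* Density maps are raw histograms — no Gaussian smoothing, no symmetry
  averaging.
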