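# hydration

Hydration-site analysis for protein and protein–RNA systems: geometric
hydrogen-bond detection, water-bridge occupancy and residence-time statistics
on MD trajectories, water density grids, consensus hydration sites across
crystallographically independent copies, and binding-kinetics affinity
arithmetic for hydration-site mutants.

## Who this is for

Structured water is a first-class part of biomolecular interfaces: a single
water simultaneously hydrogen-bonded to two or more solute atoms (a *water
bridge*) can staple protein loops together or mediate protein–RNA contacts,
and its removal by mutation measurably changes binding affinity.  This
package provides the analysis chain needed to find and quantify such sites
from the two standard sources of evidence — crystallographic water positions
replicated across the copies of an asymmetric unit, and explicit-solvent MD
trajectories — and to convert wild-type/mutant dissociation constants into
binding free-energy penalties.

## The core definitions

* **H-bond criterion** — a hydrogen bond is present when the donor/acceptor
  heavy-atom distance is `< 3.5 Å` and the donor–hydrogen–acceptor angle is
  `> 120°` (distance-only mode for hydrogen-free crystal structures).
* **Bridge occupancy** — the percentage of trajectory frames in which one
  water satisfies the criterion with *every* atom of a declared site
  simultaneously ("fully formed").
* **Binding time** — the contiguous duration a single water identity occupies
  a site; maximum binding time distinguishes long-residency sites (≥ ~1 ns)
  from ordinary surface hydration (~50–500 ps).
* **Density map** — after rigid superposition, water-oxygen occurrences are
  counted in 0.5 Å voxels (0.125 Å³) and normalised by bulk water density
  (0.0334 Å⁻³); local maxima above a fold-over-bulk threshold are hydration
  sites.
* **Crystal consensus** — the independent copies in an asymmetric unit are
  superposed (Kabsch), their waters pooled in a common frame and clustered
  (1.2 Å cutoff); the number of copies contributing to a cluster is the
  site's presence count, and nearby polar atoms give the `S155(OG)`-style
  coordination label.
* **Affinity energetics** — K_D = k_off / k_on from single-exponential
  association/dissociation fits, and ΔΔG = RT·ln(K_D,mut / K_D,wt)
  (R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹, default T = 298.15 K).

## Worked example

Generate a synthetic trajectory with one planted water bridge (exponential
dwell times, 80 % target occupancy) and analyse it:

```sh
$ hydra simulate bridge --seed 3 --frames 1000 --out demo
$ hydra bridges demo/topology.pdb demo/traj.txt --min-occ 30
site         occupancy_pct  n_events  max_binding_ns  mean_binding_ns
S1(O)/G2(O)  78.2           15        1.280           0.521
```

The discovered pair is exactly the planted site: backbone carbonyls of
residues 1 and 2 share one water in 78.2 % of frames (target 80 ± 2), split
into 15 binding events whose longest lasts 1.28 ns — a long-residency site by
the ≥ 1 ns yardstick.  The ground truth written to `demo/ground_truth.json`
lets you check the per-frame occupant identity.

The mutant affinity arithmetic, with measured dissociation constants as
input:

```sh
$ hydra ddg --kd-wt 1.33e-9 --kd-mut 10.5e-9
factor        7.89
ddg_kcal_mol  1.224
$ hydra ddg --kd-wt 1.33e-9 --kd-mut 3.75e-9
factor        2.82
ddg_kcal_mol  0.614
```

A 7.9-fold affinity loss corresponds to a ~1.2 kcal/mol binding penalty, a
2.8-fold loss to ~0.6 kcal/mol — the cost of deleting a serine-coordinated
interface water, in the two cases these numbers come from.

Other entry points: `hydra site` (declared multi-atom sites with a gap-
tolerance sensitivity line), `hydra density` (OpenDX maps + peak lists),
`hydra xtal-consensus` (per-copy presence table), `hydra rmsd`,
`hydra fit-kinetics`, `hydra shell-count`, `hydra filter-waters`.

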