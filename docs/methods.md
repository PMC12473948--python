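# Methods

## Scope and model

`octagg` analyses the aggregation state of aromatic solutes in an n-octanol
box and its consequence for the apparent octanol–air partition coefficient.
It does not run molecular dynamics: its inputs are either trajectories
produced elsewhere (GRO/XYZ/PDB) or its own synthetic configurations, and
its outputs are aggregate censuses and corrected log K_OA estimates.

## Composition arithmetic

The apparent saturated octanol solubility is S_O = S_W · 10^(log K_OW),
which follows from K_OW = S_O/S_W at three-phase distribution equilibrium.
Concentrations map to molecule counts through the molarity of pure
n-octanol, 6.344 mol/L (density 0.8262 g/cm³, molar mass 130.23 g/mol): a
concentration c in a box of n octanol molecules corresponds to
round(c/6.344·n) solutes, with half-up rounding. This single constant,
with an ideal-dilution assumption (the dilute solute does not change the
solvent volume), reproduces every reference box ratio we test against,
including the 61:4000 equal-concentration box; it is exposed as a parameter
rather than hard-coded into call sites. One reference value is knowingly
off in its third significant figure (PCN-5's tabulated S_O, 9.67×10⁻²,
versus 9.64×10⁻² from the rounded K_OW); the tabulated value was evidently
derived from an unrounded K_OW, so solubility agreement for that chemical
is asserted at two significant figures only.

Display rounding follows the conventions of the printed tables this work
mirrors: concentrations to 3 decimals, percentages to 1 decimal, log K_OA
to 2 decimals, always half-up (commercial) rounding — the mean 7.645 must
print as 7.65, which banker's rounding would not produce.

## Stacked-pair recognition

A pair of molecules is a π-stacked contact when its centroid distance
(minimum image, orthorhombic box) is below a conformer-specific cutoff:

| conformer            | cutoff | geometric gate                          |
|----------------------|--------|-----------------------------------------|
| face-to-face         | 3.8 Å  | interplanar angle γ ≤ 50°, offset < 1 Å |
| offset face-to-face  | 3.9 Å  | γ ≤ 50°, lateral offset ≥ 1 Å           |
| edge-to-face         | 5.0 Å  | γ > 50°                                 |

γ is the angle between the two molecules' best-fit aromatic-plane normals
(least-squares plane over the union of each molecule's ring atoms; normals
are sign-free, so γ is folded to [0°, 90°]). The lateral offset is the
component of the centroid–centroid vector perpendicular to the mean normal.
The distance cutoffs are the recognition rule proper; whether the original
analysis applied explicit angle tests alongside them is not documented, so
the angle/offset subdivision here is a reconstruction following common
stacking-geometry conventions, and both thresholds (50°, 1.0 Å) are
configurable. The decision tree makes conformer assignment unambiguous; the
effective precedence when a geometry sits near a boundary is most-specific
first (face-to-face, then offset, then edge-to-face).

Two distance modes exist. The default tests whole-molecule centroids (the
literal recognition rule). `ring-pair` mode tests every ring–ring pair and
lets the closest qualifying pair decide — more defensible for elongated
multi-ring solutes whose molecular centroid can sit far from either ring —
but it is not the default because it changes the operational meaning of the
cutoffs. Molecule centroids are unweighted (geometric) means by default,
after unwrapping each molecule to the periodic image of its first atom;
mass weighting is available.

Aggregates are connected components of the contact graph; a cluster of k
molecules contributes 100·k·n_k/N to the size-k percentage. Sizes ≥ 4 are
pooled as "polymer" for display with exact sizes retained in the raw
counts. Because each displayed category is rounded to 0.1, a census's
percentages sum to 100 within 0.05 per nonzero category (≤ 0.2 in the worst
four-category case).

## Equilibrium detection and pair traces

`detect_equilibrium` reports the earliest checkpoint from which every
species percentage stays within a tolerance band (default 5 percentage
points) for the remainder of the series, requiring at least `window`
points; a single transient excursion therefore delays the detected onset
past itself, matching how such tables are read. `pair_distance_trace`
reports a pair's per-frame centroid distance and the fraction of frames
below each cutoff, a proxy for bound-state occupancy in a dynamic
aggregation/segregation equilibrium.

Hydrogen bonds use the standard geometric criterion (H···A ≤ 3.5 Å,
D–H···A ≥ 130°) under minimum image; the counter exists because H-bonding
is the competing association channel one must rule out (aromatic systems
show only one or two such bonds, leaving π-stacking as the driver).

## K_OA layer

log K_OA = −ΔG_OA/(2.303·R·T) with R = 8.314 J mol⁻¹ K⁻¹ and T defaulting
to 298.15 K. The literal 2.303 (rather than ln 10 = 2.302585…) is kept for
consistency with the conventional form; the discrepancy is below 0.01%.
ΔG values are accepted in kJ/mol or kcal/mol (×4.184) with an explicit unit
tag; kJ/mol is canonical internally.

The combination of per-species free energies into an apparent coefficient
is not uniquely fixed by the source material, so two estimators ship and
the estimate records which was used:

* **fraction-weighted-log** (default): Σ_s f_s·log K_OA(ΔG_s per molecule).
  An s-mer's ΔG_OA is divided by s unless its entry is flagged
  `per_molecule` — whether published dimer free energies refer to the dimer
  or to each constituent is often ambiguous, and double counting is the
  costlier error.
* **monomer-fraction**: log K_OA,monomer − log10(f_monomer), the
  thermodynamic correction for a condensed phase whose total burden
  includes aggregates while the gas phase exchanges only monomers.

Both are monotone increasing in the aggregate fraction whenever the dimer
is more favorable per molecule than the monomer, which is the mechanism by
which concentration raises the apparent K_OA; `concentration_profile` flags
any violation of that expected monotonicity across a dilution ladder.

## Synthetic data

The generators define the test conditions; they are not tuned per test.

*Template.* Every synthetic molecule is a rigid planar C6 hexagon with
1.40 Å edges. Conformer geometry, not chemistry, is what the census needs;
using one template for all five chemicals is deliberate.

*Planted conformations.* Clusters are placed by rejection sampling: a
random center and orientation per cluster, members stacked along the plane
normal at the requested spacing (3.5 Å for the parallel conformers, with a
1.2 Å lateral slide for offset stacks; 4.5 Å with alternating perpendicular
orientations for edge-to-face), and every inter-cluster/monomer centroid
pair kept beyond a 6 Å separation — comfortably outside the widest (5.0 Å)
cutoff, so the planted partition is the unique detectable one. Box edges of
40 Å (≤ 35 molecules) and 50 Å (61 molecules) keep rejection sampling fast;
placement failure raises with advice rather than looping forever.

*Equilibrium trajectories.* Each frame is an independent placement of the
same cluster multiset (aggregates appear in different places), while a
slot-to-molecule permutation, advanced by seeded cross-cluster swaps,
changes which molecules occupy the clusters. Cluster count is conserved
exactly, membership is not — the dynamic-equilibrium signature. With
`exchange_rate=0` membership freezes while positions still move.

*What this does and does not show.* Passing census tests on planted data
demonstrates that the detector recovers a known ground truth under periodic
boundaries, including at the exact reported cluster inventories; it says
nothing about whether a force field would produce those inventories, and no
such claim is made. Real trajectories add thermal disorder, solvent, and
conformational flexibility that the rigid-template generator deliberately
omits.

*Metropolis simulator.* Point particles with a hard core (σ = 3.4 Å, an
aromatic contact distance) and a square attractive well to 5.0 Å (the
edge-to-face cutoff) in a 40 Å periodic cube, sampled by single-particle
displacements (uniform within ±1 Å) accepted with min(1, e^(−ΔU/k_BT)),
k_B T = 0.5925 kcal/mol at 298.15 K. Well depths map from the five π–π
stacking energies as ε = 0.10·|E|, giving ε/k_BT ≈ 1.6–1.9 so association
stays reversible at desk scale; full-strength energies would freeze
aggregates and leave no equilibrium to measure. Runs are 300 sweeps with
the first half discarded as burn-in — pilot traces of the aggregate
fraction equilibrate well within that. The census here uses a single
distance cutoff equal to the well range (point particles carry no plane).
This toy reproduces the two qualitative trends of interest — aggregate
fraction rising with particle count at fixed volume and with well depth at
fixed count — and is validated in its ε = 0 limit against direct rejection
sampling of hard-sphere configurations. Because two of the five mapped well
depths differ by only ~1%, trend tests across the ladder use a rank
correlation plus endpoint significance over 20 seeds rather than demanding
a strict total order of sample means, which that spacing cannot
statistically support.

## Numerical choices and degenerate inputs

Minimum-image wrapping maps each displacement component to [−L/2, L/2);
plane fitting uses the SVD of centered ring coordinates and rejects
collinear rings; checkpoint matching takes the nearest frame and logs the
time delta, erroring only outside the trajectory span; empty frames,
zero-molecule censuses, non-positive temperatures, triclinic boxes and
decreasing frame times are all rejected with specific errors. All
randomness flows through seeded `numpy` generators; identical seeds give
bit-identical outputs.

## Known limitations

* The reference estimated-log K_OA column cannot be recomputed (the
  underlying per-species ΔG_OA values are unpublished) and is carried as
  metadata only.
* One published equal-concentration census row (PCN-5, 60.0/40.0) is
  inconsistent with its own stated cluster count (12 dimers among 61
  molecules gives 60.7/39.3); comparisons treat that row as a documented
  discrepancy rather than a target.
* The published equilibrium grid contains two single-checkpoint excursions;
  a generator that conserves cluster count reproduces the stationary rows
  only.
* Molecule grouping is declarative; no bond perception is attempted, and
  binary trajectory formats (XTC/TRR/DCD) are out of scope.
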