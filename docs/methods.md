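# Methods

## Geometric model

All interdomain descriptors treat the three globular domains (N-SH2, C-SH2,
PTP) as quasi-rigid bodies identified by author residue numbering. Default
boundaries are N-SH2 3–104, C-SH2 112–216, PTP 221–524 — conventional SHP2
ranges; they are configuration data, not constants, because different
constructs and structures resolve different termini. Residue numbering is
never remapped.

Frames are superposed on the closed reference over the Cα atoms of the
alignment domain (PTP by default) before any reference-relative measurement.
Superposition is the SVD Kabsch solution restricted to proper rotations
(det +1 via the sign-corrected diagonal); only residues present in both
structures are used, so partially resolved structures still align. Cα-only
superposition makes the alignment indifferent to side-chain substitutions
between variants.

**N-SH2 rotation angle.** The angle at the C-SH2 pivot between (a) the vector
to the reference's N-SH2 anchor and (b) the vector to the frame's N-SH2
anchor, after alignment. The anchor and pivot are Cα centroids of the
respective domains. A centroid is used because it is representative of
rigid-body position and insensitive to missing side chains; any selection can
be substituted through the config. The pivot is taken from the *aligned
frame* (the C-SH2 domain rides on the PTP face and moves modestly between
states); for the reference measured against itself the choice is immaterial
and the angle is exactly 0°.

**C-SH2 rotation angle.** The angle between a Cα→Cα vector on the frame's
C-SH2 domain and a Cα→Cα vector on the reference's PTP domain, after
alignment. The default pairs span each domain's sequence extremes
(C-SH2: Cα 112→216; PTP: Cα 221→524).
The intended construction is a vector pair that is nearly parallel in the
auto-inhibited state, so the closed-state angle is small and growth of the
angle reports C-SH2 rotation; because suitable pairs depend on the specific
reference structure, the pair is shipped as overridable configuration and
validated in this repository only on synthetic closed references, where the
construction guarantees the parallelism property.

**Tandem-SH2 dihedral.** Standard signed four-point dihedral over the ordered
quadruple Cα L43 – Cα R111 – Cα R220 – Cα L149 (the two SH2 centers-of-mass
proxies and the two linker anchors), computed with the atan2 formulation
x = n₁·n₂, y = (n₁×n₂)·b̂₂, range (−180°, 180°]. The atan2 form is exact for
the sign convention in which the dihedral is positive for a right-handed
twist looking down the central bond, and is well conditioned near 0° and
180° where the arccos form loses precision. The sign flips under mirror
inversion, which the tests assert.

**Salt bridges.** The contact variable for a basic/acidic residue pair is the
minimum over all side-chain N (NE/NH1/NH2, NZ) × carboxylate O (OE1/OE2,
OD1/OD2) distances. Occupancy is the fraction of frames with minimum
distance ≤ 4.0 Å, the standard heavy-atom salt-bridge criterion; a single
cutoff (no hysteresis/dual-cutoff smoothing) is used, which slightly inflates
apparent transition counts for distances hovering at the cutoff but leaves
occupancies unbiased. Joint occupancy is the frame-wise AND. Missing side
chains (alanine substitutions, unresolved density) raise a typed error
carrying the residue identity; trajectory passes convert these to flagged
NaN frames and log them rather than aborting.

**SASA.** Shrake–Rupley point sampling: each atom's sphere of radius
r_vdW + r_probe carries a deterministic golden-spiral lattice of n points; a
point is accessible if outside every neighbor's probe-expanded sphere.
Defaults: Bondi radii, probe 1.4 Å, 960 points (relative error ≲ 0.5% on an
isolated sphere, verified against the closed form in tests), hydrogens
excluded, side-chain scope for the residue-139 burial question. The whole
frame buries; only the target residue's atoms are integrated, which keeps
per-frame cost proportional to residue size.

## Energetic model

Catalytic efficiency k_cat/K_M is the activity measure. Replicates are
averaged **geometrically**: mutational effects compose multiplicatively, so
the natural scale is logarithmic (an arithmetic-mean mode exists for
cross-checking). Fold changes are ratios of geometric means with the log-SE
propagated from per-group SEMs of log efficiency.

A double-mutant cycle over (background, +mut1, +mut2, +both) gives

    Ω = (v_bg · v_12) / (v_1 · v_2),    ΔΔG_int = −RT ln Ω

with R = 1.9872 × 10⁻³ kcal/(mol·K) and T = 298.15 K by default (the assay
temperature is configurable; ΔΔG scales linearly in T so the choice does not
affect signs or Ω). The cycle validator requires exact closure of the
substitution sets, and the result is invariant under exchanging the singles
and under rescaling all activities by a common constant (unit independence) —
both asserted as identities in the tests. ln Ω equals the deviation of the
double mutant's log fold change from the sum of the singles', which is the
operational meaning of coupling.

Welch's unequal-variance t test is applied to log efficiencies by default
(ratio-scale data); star annotations follow the usual convention
(* p<0.05, ** p<0.01, *** p<0.001). Michaelis–Menten fits use trust-region
nonlinear least squares with non-negativity bounds and a data-driven start
(v_max from the rate maximum, K_M from the concentration median); when all
concentrations fall below K_M/5 the hyperbola is unidentifiable and the fit
falls back to the origin-constrained linear regime whose slope estimates
k_cat·[E]/K_M, reporting efficiency only with a span flag. Melt temperatures
come from a four-parameter Boltzmann sigmoid (midpoint = T_m), initialized
from the smoothed-derivative peak; the derivative-maximum estimate (Savitzky–
Golay smoothing, parabolic peak refinement) is available as a cross-check.
A curve is rejected as transition-free when its derivative peak does not
exceed 5× the median derivative magnitude, or when the signal range is
numerically flat.

## Synthetic data: what it emulates and what it does not

The generators produce the study conditions for every pipeline stage with
known ground truth, recorded in JSON sidecars (PCG64 generator, seed and all
truth values included); downstream recovery tests read truth only from
sidecars.

* **Rigid trajectories.** Three pseudo-domains of Cα-like atoms (≥ 4
  non-coplanar each, centroids > 20 Å apart) carry the real anchor residue
  numbers (4, 5, 32, 43, 111, 138, 139, 149, 220) so descriptor configs
  transfer unchanged to real structures. The moving domain rotates by a
  scripted per-frame angle about an axis through the C-SH2 pivot chosen
  perpendicular to the pivot→anchor vector, so the scripted angle is exactly
  what the rotation descriptor measures. Scripted contacts place carboxylate
  oxygens at 2.8 Å (bound) or 8.0 Å (unbound) from the partner NE along the
  side-chain direction; with two concurrent schedules OE1 serves Arg4 and
  OE2 serves Arg5, with the two arginines built pointing apart so the pairs
  stay independent. Isotropic Gaussian coordinate noise (default 0.2 Å, a
  magnitude typical of heavy-atom thermal fluctuation) is added last.
* **Kinetics.** Rates follow the Michaelis–Menten law (defaults k_cat 10 s⁻¹,
  K_M 100 µM, [E] 0.05 µM) over a log-spaced K_M/50–10·K_M concentration
  range, with multiplicative lognormal noise (sdlog 0.05).
* **Melt curves.** Four-parameter sigmoid (T_m 55 °C, width 1.5 °C) sampled
  every 0.5 °C from 25–95 °C with additive Gaussian noise (2% of amplitude).
* **Variant panel.** `REFERENCE_RELATIVE_EFFICIENCIES` is a synthetic
  reconstruction of the SHP2 variant panel's relative efficiencies from its
  reported fold changes (7× E139D activation; 2.1×/18.7× E139D effects in
  R5A/R4A backgrounds; 4.3×/41.9× R5A reductions; 3.2× E139A reduction in
  R4A; 1.8× enhancement of the E139A effect by R5A; 7.1× D139A inactivation;
  >100× E76K). The reported set is over-determined: the two directly
  constrained R4A-background effects (18.7×, 3.2×) bound the derived
  D139A-in-R4A ratio to ≈ 59.8, whereas 61.2 is reported; the reconstruction
  honors the direct single-background effects and leaves that derived ratio
  at its implied value, with the discrepancy asserted openly in the test
  suite rather than absorbed. Free parameters not pinned by any ratio (R4A
  at 1.5×, E76K at 110×, WT absolute efficiency 10³ M⁻¹s⁻¹) are set once to
  representative values; only ratios are ever compared.

Passing these tests demonstrates that the descriptors and estimators recover
known rigid-body motion, contact schedules, and generative parameters under
idealized noise. It does not demonstrate force-field realism, conformational
sampling, correlated atomic fluctuations, or any statistical property of real
MD ensembles — the generators make no attempt to mimic those.

## Numerical choices

* Angles via atan2(‖v₁×v₂‖, v₁·v₂) (never arccos); degrees everywhere;
  distances Å, areas Å².
* Kabsch requires ≥ 3 points with centered rank ≥ 2; collinear sets raise a
  conditioning error.
* Alternate locations: highest occupancy wins, ties broken by altloc label
  order — deterministic parsing.
* Frames with missing descriptor atoms yield NaN, are excluded from summary
  statistics, counted in `n_missing`, and logged with the frame index.
* Medians use the midpoint convention for even counts.
* TSV output carries 6 significant digits; reports contain no timestamps, so
  identical config + inputs reproduce byte-identical outputs (a config
  content hash ties every report to its exact settings).
* Binary trajectory round-trips are exact only to format precision (DCD/XTC
  store float32; PDB stores 3 decimals).

## Problem sizes

The test suite and the results script run at deliberately small scale chosen
to exercise every code path with tight tolerances: toy systems of 12 residues
per domain, trajectories of 50–200 frames, 100-member recovery ensembles for
kinetics and melt fits, 960-point SASA spheres. The full suite completes in a
few seconds on one CPU.

## Known limitations

* The C-SH2 rotation vector pair and the exact N-SH2 anchor construction are
  configuration, not canon; analyses of real structures should record the
  config hash alongside results.
* Occupancy uses a single inclusive cutoff; kinetic on/off statistics are out
  of scope.
* No structure repair, hydrogen placement, enhanced-sampling analysis,
  free-energy estimation, or conformational clustering.
* The ±0.05 agreement of reconstructed panel ratios is a property of the
  reconstruction, not an independent re-measurement of the underlying
  replicate data, which this repository does not contain.
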