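# domainmotion

Quantitative descriptors of interdomain motion in multi-domain phosphatases,
paired with double-mutant-cycle energetics for the salt-bridge networks that
stabilize those motions.

## The problem

SHP2 (*PTPN11*) is a tyrosine phosphatase with two phosphotyrosine-binding SH2
domains (N-SH2, C-SH2) and a catalytic PTP domain. In the auto-inhibited state
the N-SH2 domain blocks the PTP active site; activation displaces it. Open
states are not a single structure but an ensemble: the crystallographic open
state differs from modeled open states in where the N-SH2 domain sits relative
to the C-SH2/PTP core, and pathogenic mutations such as E139D can stabilize
one member of that ensemble through salt bridges between the C-SH2 residue
139 and arginines (Arg4/Arg5) at the N-SH2 N-terminus.

This package computes, over crystal structures and MD trajectories, the
geometric descriptors that distinguish these states, and analyzes the variant
biochemistry (catalytic efficiencies, thermal stability, pull-downs) that
tests whether specific residue pairs are energetically coupled.

## Descriptors

With all frames superposed on the PTP domain Cα atoms (Kabsch, proper
rotations only):

- **N-SH2 rotation angle** — the angle at the C-SH2 pivot centroid between
  the N-SH2 anchor centroid in the auto-inhibited reference and in the frame;
  0° for the closed state, > 120° for crystallographic open states.
- **C-SH2 rotation angle** — the angle between a C-SH2 Cα vector and a PTP
  Cα vector that are nearly parallel in the closed state.
- **Tandem-SH2 dihedral** — signed four-point dihedral over
  Cα L43 – Cα R111 – Cα R220 – Cα L149, reporting relative SH2 orientation.
- **Salt-bridge descriptors** — minimum side-chain N···O distance between a
  basic residue (NE/NH1/NH2 or NZ) and an acidic residue (OE1/OE2 or
  OD1/OD2); occupancy = fraction of frames with distance ≤ 4.0 Å; joint
  occupancy for concurrent pairs.
- **Cα pair distance** — e.g. Arg32–Arg138, the phosphotyrosine-pocket
  separation that constrains bis-phosphorylated ligand binding.
- **Residue SASA** — Shrake–Rupley solvent accessibility (Bondi radii, 1.4 Å
  probe, 960 sphere points), side-chain scope by default.

## Energetics

Catalytic efficiencies (k_cat/K_M) are fit from initial-rate data, averaged
geometrically over replicates, and compared as fold changes. A double-mutant
cycle over WT, two single mutants, and the double quantifies coupling:

    Ω = (v_WT · v_12) / (v_1 · v_2),        ΔΔG_int = −RT ln Ω

Ω = 1 when the substitutions act independently. Welch's unequal-variance
t test (on log efficiencies) assesses pairwise significance; DSF melt curves
yield T_m via a Boltzmann-sigmoid midpoint or smoothed-derivative maximum;
co-IP band intensities are double-normalized (IP/TCL, then to wild type).

## Worked example

Generate a synthetic trajectory whose ground truth is known — the
pseudo-N-SH2 domain sweeps 0→90° about the C-SH2 pivot while an Arg4–Glu139
contact is scripted at 30% occupancy, with 0.2 Å coordinate noise — then
recover both signals:

```python
import numpy as np
from domainmotion import synthetic as syn
from domainmotion.geometry import (
    ionpair_occupancy, min_sidechain_contact_distance, nsh2_rotation_angle, summarize,
)

spec = syn.GeneratorSpec(seed=1, n_frames=100, coordinate_noise_sd=0.2)
model, partition = syn.make_toy_multidomain(spec)
schedule = syn.default_rotation_schedule(model, partition, np.linspace(0, 90, 100))
contact = syn.ContactSchedule(flags=np.arange(100) < 30)
stream, truth = syn.make_rigid_trajectory(model, partition, schedule, contact, spec)

rot = summarize([nsh2_rotation_angle(f, model, partition) for f in stream],
                "nsh2_rotation", "degrees")
dist = [min_sidechain_contact_distance(f, 4, 139) for f in stream]
print(f"N-SH2 rotation median: {rot.median:.2f} deg")
print(f"Arg4-139 occupancy:    {ionpair_occupancy(dist, 4.0):.2f}")
```

```
N-SH2 rotation median: 44.10 deg
Arg4-139 occupancy:    0.30
```

The recovered median tracks the scheduled 45° midpoint to within the noise,
and the occupancy equals the scripted 0.30 exactly. A mutant cycle on the
bundled synthetic variant panel:

```python
from domainmotion.pipeline import run_cycles
table = syn.synthetic_activity_table(n_replicates=3)
cycle = run_cycles(table, [("WT", "R5A", "E139D", "R5A+E139D")])["cycles"][0]
print({k: round(v, 2) for k, v in cycle["fold_changes"].items()})
print(f"omega = {cycle['omega']:.3f}, "
      f"ddG_int = {cycle['delta_delta_g_interaction_kcal_mol']:+.3f} kcal/mol")
```

```
{'R5A/WT': 0.78, 'E139D/WT': 7.0, 'R5A+E139D/WT': 1.63, 'R5A+E139D/R5A': 2.1,
 'R5A+E139D/E139D': 0.23}
omega = 0.300, ddG_int = +0.713 kcal/mol
```

E139D activates 7-fold, but only 2.1-fold in the R5A background: Ω < 1 means
the two positions are coupled — removing Arg5 costs the E139D-stabilized
state about 0.7 kcal/mol of its advantage.

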