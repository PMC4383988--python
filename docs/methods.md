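# Methods

`quatsym` characterizes the quaternary structure of protein complexes: it
reports subunit stoichiometry, detects the rotational point group (Cn, Dn,
T, O, I) or helical symmetry of a biological assembly, distinguishes strict
symmetry from pseudo-symmetry, and emits the symmetry axes for display.
This note records the model, the algorithms, the tunable parameters, and the
design choices that were genuinely open.

## Background and model

A deposited crystal structure contains the asymmetric unit; the
biologically functional complex (the *biological assembly*) is obtained by
applying stored rigid-body operators to its chains. A complex is modeled as
a set of subunits, each reduced to its Cα trace — one point per residue —
which is the standard reduced representation for rigid-body superposition.

A *symmetry operation* of the assembly is a proper rigid motion
(rotation R, translation t; x′ = R·x + t, column-vector convention,
ångströms) together with a permutation of the subunits such that moving
every subunit and relabeling by the permutation reproduces the assembly to
within a Cα RMSD threshold. The accepted operations form a group under
composition; classifying that group against the finite rotation groups —
cyclic C*n* (order n), dihedral D*n* (2n), tetrahedral T (12), octahedral O
(24), icosahedral I (60) — yields the symmetry label. Open-ended
(filament-like) assemblies are instead tested for invariance under a screw
operation: rotation by a *twist* angle plus a *rise* translation along one
axis per subunit step.

Symmetry may relate identical subunits or merely homologous ones
(*pseudo-symmetry*). The distinction is made by sequence clustering: chains
are grouped at 95% identity for strict symmetry (absorbing point mutants
and minor sequence variation) and at 30% for pseudo-symmetry (grouping
homologs). Only chains with at least 20 Cα-bearing residues take part.

## Pipeline

1. **Parse and expand** (`structure_io`). mmCIF and legacy PDB files are
   read with gemmi; protein chains are kept as Cα traces (first model wins;
   highest-occupancy alternate conformer, ties to the first encountered;
   modified residues map to their parent one-letter code, unknowns to 'X';
   chains without any Cα are dropped with a warning). Assembly operators
   (`_pdbx_struct_assembly_gen`/`_pdbx_struct_oper_list` or REMARK 350
   BIOMT) are expanded into explicit subunit copies; when absent, the
   asymmetric unit is analyzed as-is.

2. **Cluster** (`seqcluster`). Pairwise identity comes from global
   Needleman–Wunsch/Gotoh alignment with affine gaps (match +1, mismatch 0,
   gap open −10 for the first gapped residue, −0.5 per further residue).
   Percent identity is matches divided by alignment columns *excluding
   terminal-gap columns*, so truncated constructs still reach 100%. End
   gaps are penalized in the alignment itself: with this identity-oriented
   scoring, free end gaps would let an ungapped frame shift outscore a true
   internal deletion and corrupt the residue correspondence. The argument
   pair is put in canonical order before aligning so identity(a,b) equals
   identity(b,a) exactly even when co-optimal alignments differ.
   Clustering is greedy: the longest unassigned chain (ties by chain id)
   seeds a cluster and captures every remaining chain with identity ≥
   threshold to the seed. This deterministic representative-based scheme is
   our stand-in for archive-scale clustering tools whose exact parameters
   are not part of the method.

3. **Enumerate operations** (`symmetry.enumerate_operations`). A reference
   subunit is taken from the largest cluster. For each same-cluster partner,
   the pairwise all-Cα superposition of reference onto partner seeds a
   candidate transform (sequence-aligned residue pairs for homologous
   subunits). The candidate then alternates two steps until convergence
   (RMSD improvement < 1e-4 Å or 20 iterations): (a) map every subunit to
   its nearest centroid under the transform, restricted to its own cluster
   (Hungarian assignment, so the mapping is a bijection that respects
   cluster membership); (b) refit the transform by Kabsch superposition over
   all mapped Cα pairs. Operations with RMSD below the cutoff (7 Å) are
   accepted; the identity is always included; finally the accepted set is
   completed under composition (composed permutations are re-scored and
   admitted if they pass), which recovers group elements not reachable from
   the reference pairing. This gives O(N) seeds instead of N! permutations;
   for assemblies of ≤ 6 subunits the result is verified in the test suite
   against an exhaustive permutation search. When a subunit is asymmetric
   (guaranteed for the synthetic generator, typical for real domains) each
   group element maps the reference to a distinct partner, so the seed set
   covers the group and closure is a safety net.

4. **Classify** (`symmetry.classify_point_group`). Each accepted rotation is
   decomposed into axis and angle (angle from arccos((tr R − 1)/2), axis
   from the rotation vector, sign canonicalized to positive z, ties broken
   by y then x). The *fold* of a rotation is the smallest n ≥ 2 whose angle
   grid 2πk/n contains the angle within min(angle_tol, π/(n(n+1))). The cap
   at half the separation between consecutive fold grids matters: with a
   flat tolerance of 0.1 rad, a 36° rotation (10-fold) also sits within
   tolerance of the 9-fold grid and a smallest-n rule would return 9.
   Axes are merged when parallel within angle_tol. Decision rules: one
   distinct axis → C_N; an n-fold principal axis with n perpendicular
   2-folds at order 2n → D_n (three mutually perpendicular 2-folds at order
   4 → D2); orders 12/24/60 with the tetrahedral {four 3-folds, three
   2-folds} / octahedral {three 4-folds, four 3-folds, six 2-folds} /
   icosahedral {six 5-folds, ten 3-folds, fifteen 2-folds} axis patterns →
   T/O/I; anything else falls back to the largest internally consistent
   cyclic subgroup with a warning.

5. **Helical** (`symmetry.detect_helical`), attempted when the point-group
   path returns C1 (or a cyclic group, to guard against mixed cases).
   Subunits of the largest cluster are ordered along the dominant principal
   component of their centroids; the consecutive-neighbor mapping i → i+1 is
   refined by all-Cα Kabsch superposition into a single screw operation,
   then decomposed: the axis is the rotation axis (or the translation
   direction for twist ≈ 0), rise is the translation component along it,
   twist the rotation angle in degrees, with the axis oriented so rise ≥ 0.
   The ordering is recomputed once along the recovered axis if it changed.
   Helical symmetry is reported when the screw RMSD is below the cutoff,
   |rise| ≥ helical_rise_min, and the squared screw maps subunit i onto
   i+2 within the cutoff (propagation across ≥ 3 subunits); a closed ring
   has rise ≈ 0 and is rejected here, staying cyclic.

6. **Verdict** (`symmetry.detect_symmetry`). Stoichiometry letters are
   assigned to clusters by descending size (ties by representative id);
   counts of 1 are implicit ("A", "ABC", "A2B2"). One analyzed subunit →
   monomer; several subunits in one cluster → homomer; several clusters →
   heteromer. The mode label is "symmetric" when the strict (95%) threshold
   already produces the non-trivial group, "pseudo-symmetric" when only the
   30% threshold does (checked by comparing the two partitions), and
   "asymmetric" for C1. max_rmsd is the maximum over accepted non-identity
   operations. Detection involves no randomness: a fixed input always gives
   a bit-identical result.

7. **Standard orientation** (`symmetry.standard_orientation`). The
   highest-fold (or helical) axis is rotated onto +z; when perpendicular
   axes exist (dihedral and cubic groups) the highest-fold perpendicular
   axis is brought onto +x; the complex centroid moves to the origin. For
   the cubic groups this places the 4-fold (O), 5-fold (I) or 3-fold (T)
   vertical, the customary display convention for these polyhedra. The
   choice among equivalent axes prefers the one already closest to the
   target direction, which makes re-orientation of an already-oriented
   complex the identity.

## Parameters

| Parameter | Default | Units | Role |
|---|---|---|---|
| `rmsd_cutoff` | 7.0 | Å | accept a candidate operation; separates symmetric/pseudo-symmetric from asymmetric |
| `identity_threshold_symmetry` | 95 | % | clustering for strict symmetry |
| `identity_threshold_pseudo` | 30 | % | clustering for pseudo-symmetry |
| `min_residues` | 20 | residues | minimum Cα count for a chain to be analyzed |
| `angle_tol` | 0.1 | rad | axis merging; cap on fold snapping (see above) |
| `max_fold` | 60 | — | highest cyclic fold considered (icosahedral order) |
| `helical_rise_min` | 1.0 | Å | minimum rise per step to call a screw helical rather than cyclic |
| `max_iter` / `converge_tol` | 20 / 1e-4 | — / Å | iteration cap and RMSD-improvement stop for refinement |

The 7 Å cutoff is deliberately permissive: it tolerates conformational
variability between subunits while still rejecting genuinely misplaced
ones; the same value governs strict and pseudo modes.

## Synthetic assemblies

The generator (`synthetic`) is the test bed for the whole pipeline.
Subunits are persistent random walks with exact 3.8 Å Cα–Cα steps — the
backbone spacing of real chains — with a construction guarantee of
asymmetry (the trace superposed onto its own reversal must exceed 5 Å RMSD,
re-derived deterministically from the seed otherwise), so no spurious
internal 2-folds contaminate the operation count. Copies are placed by the
exact operator sets of the requested group (Cn/Dn built directly; T/O/I
generated once by closing two generators under multiplication in the
standard orientation with 2-folds along coordinate axes, validated against
the expected group order), at a generic off-axis position (default radius
20 Å) so the orbit is free. Helices apply the screw operator k times to
subunit k. Noise is i.i.d. isotropic Gaussian per coordinate — the simplest
model with a predictable RMSD relationship (an operation's RMSD grows like
σ√2 for independent copies). Sequence divergence for pseudo-symmetry tests
mutates each copy independently at a rate chosen so *pairwise* identities
land near the requested target (per-copy identity 100·√(t/100)). Everything
derives from a single integer seed; identical specs produce byte-identical
assemblies.

What the generator does not emulate: real side chains and packing,
correlated (domain-level) motions, missing residues and disordered loops,
crystallographic interface ambiguity, and quasi-equivalence in viral
capsids. Passing tests therefore demonstrate the correctness of the
geometry and decision logic, not robustness to every artifact of
experimental structures; the 7 Å cutoff and sequence-alignment-based
correspondence are the mechanisms expected to absorb those artifacts, and
they are exercised here only through Gaussian noise and sequence mutation.

## Numerical choices and degenerate inputs

- Superposition is Kabsch via SVD with the determinant sign-corrected, so a
  reflection is never returned even for near-planar point sets; the test
  suite cross-checks against an independent quaternion-eigenvalue
  implementation at 1e-8.
- Fewer than 3 points is an error; collinear point sets are flagged with a
  warning but still return the least-squares transform.
- Assemblies with fewer than 2 analyzable subunits short-circuit to C1;
  an assembly with no analyzable protein subunits reports category "none"
  rather than raising.
- Ties in greedy clustering, stoichiometry lettering, axis ordering and
  orientation are all broken lexicographically so results are reproducible
  across runs and platforms.
- Per-pair residue correspondences are cached per subunit pair during
  enumeration; identical sequences short-circuit to the 1:1 map.

## Known limitations

- The candidate search assumes subunits are internally asymmetric; a
  subunit with a near-perfect internal 2-fold could make a group element
  unreachable from reference pairings alone (closure mitigates but cannot
  always recover it).
- Helical detection orders subunits by a principal component of the
  centroids; extremely short, wide helices (axial extent smaller than the
  radius) may be mis-ordered and fall back to C1.
- Pseudo-symmetry relies on sequence alignment; homologs below ~20%
  identity align poorly and their correspondence degrades before the 30%
  clustering threshold is reached.
- Quasi-symmetry of viral capsids (T-numbers), internal (intra-chain)
  symmetry and interface-based assembly prediction are out of scope.
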