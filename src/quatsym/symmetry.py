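"""Quaternary-structure symmetry detection.

The pipeline characterizes a biological assembly in four stages:

1. chains are clustered by sequence identity — 95% for strict symmetry
   (identical subunits up to minor variation), 30% for pseudo-symmetry
   (homologous subunits);
2. candidate symmetry operations are enumerated by superposing a reference
   subunit onto each same-cluster partner, establishing the induced subunit
   mapping by cluster-respecting nearest-centroid assignment, and refining
   the transform over all mapped Cα atoms to convergence;
3. an operation is accepted when its all-Cα RMSD is below the cutoff
   (7 Å by default) and the accepted set is closed under composition;
4. the rotation parts are decomposed into axes and folds and matched against
   the finite rotation point groups Cn, Dn, T (order 12), O (24), I (60);
   open (filament-like) arrangements are tested for helical (screw)
   symmetry instead.

Detection involves no randomness: results are bit-reproducible for a fixed
input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation

from .seqcluster import ClusterSet, cluster_chains
from .structure_io import Assembly, Chain
from .superpose import (
    AxisAngle,
    RigidTransform,
    axis_angle_matrix,
    canonical_axis,
    residue_correspondence,
    rotation_parameters,
    superpose_kabsch,
)

logger = logging.getLogger(__name__)


@dataclass
class Config:
    """Tunables of the detection pipeline (Å, %, radians)."""

    rmsd_cutoff: float = 7.0
    identity_threshold_symmetry: float = 95.0
    identity_threshold_pseudo: float = 30.0
    min_residues: int = 20
    angle_tol: float = 0.1
    max_fold: int = 60
    helical_rise_min: float = 1.0
    max_iter: int = 20
    converge_tol: float = 1e-4

    def __post_init__(self):
        if self.rmsd_cutoff <= 0:
            raise ValueError("rmsd_cutoff must be positive")
        for thr in (self.identity_threshold_symmetry, self.identity_threshold_pseudo):
            if not 0.0 < thr <= 100.0:
                raise ValueError("identity thresholds must be in (0, 100]")


@dataclass
class SymmetryOperation:
    """One accepted rigid operation and the subunit permutation it induces."""

    transform: RigidTransform
    permutation: dict[str, str]
    rmsd: float

    def is_identity(self) -> bool:
        return all(a == b for a, b in self.permutation.items())


@dataclass
class Stoichiometry:
    """Subunit composition: 'A5' = homopentamer, 'A2B2' = heterotetramer."""

    composition: str
    counts: dict[str, int]
    category: str  # monomer | homomer | heteromer | none


@dataclass
class HelicalParams:
    axis: np.ndarray
    rise: float       # Å per subunit step along the axis
    twist: float      # degrees per subunit step
    n_subunits: int
    rmsd: float = 0.0


@dataclass
class SymmetryResult:
    entry_id: str
    assembly_id: str
    stoichiometry: Stoichiometry
    group_label: str                  # C1, Cn, Dn, T, O, I, H
    axes: list[AxisAngle]
    operations: list[SymmetryOperation]
    max_rmsd: float
    mode: str                         # symmetric | pseudo-symmetric | asymmetric
    helical: HelicalParams | None = None
    excluded_subunits: list[str] = field(default_factory=list)
    center: np.ndarray | None = None

    @property
    def order(self) -> int:
        return len(self.operations)


def compute_stoichiometry(assembly: Assembly, clusters: ClusterSet) -> Stoichiometry:
    """Canonical composition string and monomer/homomer/heteromer category.

    Cluster letters are assigned by descending subunit count, ties by
    representative id; a count of 1 is left implicit ('ABC', not 'A1B1C1').
    """
    sizes = [
        (len(members), rep)
        for members, rep in zip(clusters.clusters, clusters.representatives)
    ]
    if not sizes:
        return Stoichiometry("", {}, "none")
    sizes.sort(key=lambda x: (-x[0], x[1]))
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    counts: dict[str, int] = {}
    parts = []
    for i, (n, _rep) in enumerate(sizes):
        letter = letters[i] if i < 26 else letters[i // 26 - 1] + letters[i % 26]
        counts[letter] = n
        parts.append(f"{letter}{n}" if n > 1 else letter)
    total = sum(counts.values())
    if total == 1:
        category = "monomer"
    elif len(counts) == 1:
        category = "homomer"
    else:
        category = "heteromer"
    return Stoichiometry("".join(parts), counts, category)


class _OperationSearch:
    """Shared state for enumerating cluster-respecting symmetry operations."""

    def __init__(self, assembly: Assembly, clusters: ClusterSet, config: Config):
        self.config = config
        sub_map = assembly.subunit_map()
        self.ids = [m for members in clusters.clusters for m in members]
        self.chains: dict[str, Chain] = {i: sub_map[i] for i in self.ids}
        self.cluster_index = clusters.as_index_map()
        self.cluster_members = [list(members) for members in clusters.clusters]
        self.centroids = {i: self.chains[i].centroid for i in self.ids}
        self._corr_cache: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}

    def correspondence(self, a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
        key = (a, b)
        if key not in self._corr_cache:
            pairs = residue_correspondence(self.chains[a], self.chains[b])
            ia = np.array([p[0] for p in pairs], dtype=int)
            ib = np.array([p[1] for p in pairs], dtype=int)
            self._corr_cache[key] = (ia, ib)
        return self._corr_cache[key]

    def assign(self, transform: RigidTransform) -> dict[str, str] | None:
        """Cluster-respecting nearest-centroid mapping under a transform."""
        perm: dict[str, str] = {}
        for members in self.cluster_members:
            moved = np.array([transform.apply(self.centroids[m]) for m in members])
            targets = np.array([self.centroids[m] for m in members])
            cost = np.linalg.norm(moved[:, None, :] - targets[None, :, :], axis=2)
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                perm[members[r]] = members[c]
        return perm

    def stack(self, perm: dict[str, str]) -> tuple[np.ndarray, np.ndarray] | None:
        """Concatenated (moving, fixed) Cα pairs induced by a permutation."""
        mov, fix = [], []
        for a in self.ids:
            b = perm[a]
            ia, ib = self.correspondence(a, b)
            if len(ia) == 0:
                return None
            mov.append(self.chains[a].ca_coords[ia])
            fix.append(self.chains[b].ca_coords[ib])
        return np.vstack(mov), np.vstack(fix)

    def score(self, perm: dict[str, str]) -> tuple[RigidTransform, float] | None:
        stacked = self.stack(perm)
        if stacked is None or len(stacked[0]) < 3:
            return None
        return superpose_kabsch(*stacked)

    def refine(self, transform: RigidTransform):
        """Alternate mapping update and all-Cα refit until convergence."""
        prev_rmsd = np.inf
        perm = None
        result = None
        for _ in range(self.config.max_iter):
            new_perm = self.assign(transform)
            scored = self.score(new_perm)
            if scored is None:
                return None
            transform, rmsd = scored
            if new_perm == perm and prev_rmsd - rmsd < self.config.converge_tol:
                return transform, rmsd, new_perm
            perm, prev_rmsd, result = new_perm, rmsd, (transform, rmsd, new_perm)
        return result


def enumerate_operations(
    assembly: Assembly, clusters: ClusterSet, config: Config | None = None
) -> list[SymmetryOperation]:
    """All symmetry operations passing the RMSD cutoff, identity included.

    Candidates are seeded by superposing one reference subunit (from the
    largest cluster) onto every same-cluster partner — O(N) seeds instead of
    N! permutations; the accepted set is then completed under composition so
    group elements not reachable from the reference pairing are recovered.
    """
    config = config or Config()
    search = _OperationSearch(assembly, clusters, config)
    if not search.ids:
        return []

    identity_perm = {i: i for i in search.ids}
    accepted: dict[tuple, SymmetryOperation] = {}

    def perm_key(perm: dict[str, str]) -> tuple:
        return tuple(perm[i] for i in search.ids)

    def admit(transform: RigidTransform, rmsd: float, perm: dict[str, str]):
        key = perm_key(perm)
        if rmsd < config.rmsd_cutoff and (
            key not in accepted or rmsd < accepted[key].rmsd
        ):
            accepted[key] = SymmetryOperation(transform, dict(perm), rmsd)

    admit(RigidTransform.identity(), 0.0, identity_perm)

    ref_cluster = max(search.cluster_members, key=len)
    ref = ref_cluster[0]
    for partner in ref_cluster:
        if partner == ref:
            continue
        ia, ib = search.correspondence(ref, partner)
        if len(ia) < 3:
            continue
        seed, _ = superpose_kabsch(
            search.chains[ref].ca_coords[ia], search.chains[partner].ca_coords[ib]
        )
        refined = search.refine(seed)
        if refined is not None:
            admit(*refined)

    # closure under composition: compose permutations, re-score, admit
    for _ in range(8):
        added = False
        ops = list(accepted.values())
        for p in ops:
            for q in ops:
                comp = {i: p.permutation[q.permutation[i]] for i in search.ids}
                key = perm_key(comp)
                if key in accepted:
                    continue
                scored = search.score(comp)
                if scored is not None:
                    transform, rmsd = scored
                    if rmsd < config.rmsd_cutoff:
                        admit(transform, rmsd, comp)
                        added = True
        if not added:
            break

    # deterministic order: identity first, then by permutation key
    result = sorted(
        accepted.values(), key=lambda op: (not op.is_identity(), perm_key(op.permutation))
    )
    return result


def _group_axes(
    operations: list[SymmetryOperation], config: Config
) -> list[tuple[np.ndarray, int, int]]:
    """Distinct rotation axes as (axis, max fold, #ops); identity excluded."""
    axes: list[list] = []  # [axis accumulator vector, max fold, count]
    merge_cos = np.cos(config.angle_tol)
    for op in operations:
        aa = rotation_parameters(op.transform, config.angle_tol, config.max_fold)
        if aa.fold is None:
            continue
        for entry in axes:
            ref = canonical_axis(entry[0])
            if abs(float(np.dot(ref, aa.axis))) >= merge_cos:
                entry[0] = entry[0] + aa.axis * np.sign(np.dot(ref, aa.axis))
                entry[1] = max(entry[1], aa.fold)
                entry[2] += 1
                break
        else:
            axes.append([aa.axis.copy(), aa.fold, 1])
    out = [(canonical_axis(v), fold, count) for v, fold, count in axes]
    out.sort(key=lambda e: (-e[1], tuple(-np.round(e[0], 6))))
    return out


def classify_point_group(
    operations: list[SymmetryOperation], config: Config | None = None
) -> tuple[str, list[AxisAngle]]:
    """Match a closed set of accepted operations to a rotation point group.

    Decision rules on the order N and the distinct rotation axes:
    N=1 → C1; a single axis → C_N; an n-fold principal axis plus n
    perpendicular 2-folds with N=2n → D_n; N=12/24/60 with the tetrahedral /
    octahedral / icosahedral axis patterns → T / O / I; anything else falls
    back to the largest internally consistent cyclic or dihedral subgroup.
    """
    config = config or Config()
    N = len(operations)
    axes = _group_axes(operations, config)
    if N <= 1 or not axes:
        return "C1", []

    def axis_angles(entries):
        return [AxisAngle(a, 2.0 * np.pi / f, f) for a, f, _ in entries]

    n_axes = len(axes)
    fold_census: dict[int, int] = {}
    for _, fold, _ in axes:
        fold_census[fold] = fold_census.get(fold, 0) + 1

    if n_axes == 1:
        fold = axes[0][1]
        if fold == N:
            return f"C{N}", axis_angles(axes)
        logger.warning("cyclic axis fold %d inconsistent with order %d", fold, N)
        return f"C{fold}", axis_angles(axes)

    if N == 12 and fold_census.get(3) == 4 and fold_census.get(2) == 3:
        return "T", axis_angles(axes)
    if N == 24 and fold_census.get(4) == 3 and fold_census.get(3) == 4 \
            and fold_census.get(2) == 6:
        return "O", axis_angles(axes)
    if N == 60 and fold_census.get(5) == 6 and fold_census.get(3) == 10 \
            and fold_census.get(2) == 15:
        return "I", axis_angles(axes)

    # dihedral: principal n-fold + n perpendicular 2-folds, order 2n
    principal_axis, principal_fold, _ = axes[0]
    if N == 2 * principal_fold:
        perpendicular = [
            e for e in axes[1:]
            if e[1] == 2 and abs(float(np.dot(principal_axis, e[0]))) < np.sin(config.angle_tol) + 0.05
        ]
        if len(perpendicular) == principal_fold:
            return f"D{principal_fold}", axis_angles([axes[0]] + perpendicular)
    # D2: three mutually perpendicular 2-folds, any one may serve as principal
    if N == 4 and fold_census.get(2) == 3 and n_axes == 3:
        return "D2", axis_angles(axes)

    # fallback: largest cyclic subgroup on a single axis
    best_axis = max(axes, key=lambda e: (e[2], e[1]))
    order = best_axis[2] + 1
    logger.warning(
        "operation set of order %d matches no point group exactly; "
        "reporting largest cyclic subgroup C%d", N, order
    )
    if order == 1:
        return "C1", []
    return f"C{order}", axis_angles([best_axis])


def detect_helical(
    assembly: Assembly, clusters: ClusterSet, config: Config | None = None
) -> HelicalParams | None:
    """Best screw operation mapping consecutive subunits; None when unmet.

    Subunits of the largest cluster are ordered along the dominant direction
    of their centroids; the consecutive-neighbor mapping i→i+1 is refined by
    all-Cα superposition and decomposed into axis, twist (degrees) and rise
    (Å along the axis). Helical symmetry is reported when the RMSD is below
    the cutoff, |rise| reaches ``helical_rise_min`` (separating true screws
    from closed rings), and the operation propagates across at least three
    subunits within the cutoff.
    """
    config = config or Config()
    sub_map = assembly.subunit_map()
    members = max(clusters.clusters, key=len, default=[])
    if len(members) < 3:
        return None
    chains = [sub_map[m] for m in members]

    def ordered(axis_guess: np.ndarray) -> list[Chain]:
        proj = [float(np.dot(c.centroid, axis_guess)) for c in chains]
        return [c for _, c in sorted(zip(proj, chains), key=lambda t: t[0])]

    centroids = np.array([c.centroid for c in chains])
    centered = centroids - centroids.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis_guess = vt[0]

    chain_order = ordered(axis_guess)
    for _ in range(2):
        mov, fix = [], []
        for a, b in zip(chain_order[:-1], chain_order[1:]):
            pairs = residue_correspondence(a, b)
            if len(pairs) < 3:
                return None
            ia = [p[0] for p in pairs]
            ib = [p[1] for p in pairs]
            mov.append(a.ca_coords[ia])
            fix.append(b.ca_coords[ib])
        transform, rmsd = superpose_kabsch(np.vstack(mov), np.vstack(fix))

        R, t = transform.rotation, transform.translation
        angle = float(np.linalg.norm(Rotation.from_matrix(R).as_rotvec()))
        if angle < 1e-6:
            tn = np.linalg.norm(t)
            if tn < 1e-9:
                return None
            axis, twist = t / tn, 0.0
        else:
            rotvec = Rotation.from_matrix(R).as_rotvec()
            axis = rotvec / angle
            twist = np.rad2deg(angle)
        rise = float(np.dot(t, axis))
        if rise < 0:
            axis, twist, rise = -axis, -twist, -rise

        reordered = ordered(axis)
        if [c.chain_id for c in reordered] == [c.chain_id for c in chain_order]:
            break
        chain_order = reordered

    if rmsd >= config.rmsd_cutoff or abs(rise) < config.helical_rise_min:
        return None

    # propagation: the screw applied twice must map subunit i onto i+2
    sq = transform.compose(transform)
    devs = []
    for a, b in zip(chain_order[:-2], chain_order[2:]):
        pairs = residue_correspondence(a, b)
        if len(pairs) < 3:
            return None
        ia = [p[0] for p in pairs]
        ib = [p[1] for p in pairs]
        d = sq.apply(a.ca_coords[ia]) - b.ca_coords[ib]
        devs.append(float(np.sqrt((d * d).sum() / len(d))))
    if not devs or max(devs) >= config.rmsd_cutoff:
        return None

    return HelicalParams(axis, rise, twist, len(chain_order), rmsd)


def detect_symmetry(
    assembly: Assembly, config: Config | None = None, mode: str = "symmetric"
) -> SymmetryResult:
    """Full characterization of one assembly at the chosen identity threshold.

    ``mode="symmetric"`` clusters chains at the strict (95%) identity
    threshold; ``mode="pseudo"`` at the homology (30%) threshold, allowing
    symmetry that relates homologous but non-identical subunits. The result
    is labeled "symmetric" when the strict threshold already yields the
    non-trivial group, "pseudo-symmetric" when only the homology threshold
    does, and "asymmetric" (C1) otherwise.
    """
    config = config or Config()
    if mode not in ("symmetric", "pseudo"):
        raise ValueError("mode must be 'symmetric' or 'pseudo'")
    threshold = (
        config.identity_threshold_symmetry
        if mode == "symmetric"
        else config.identity_threshold_pseudo
    )
    clusters = cluster_chains(assembly.subunits, threshold, config.min_residues)
    analyzed = {m for members in clusters.clusters for m in members}
    excluded = [s.chain_id for s in assembly.subunits if s.chain_id not in analyzed]
    stoich = compute_stoichiometry(assembly, clusters)

    center = None
    if analyzed:
        sub_map = assembly.subunit_map()
        allca = np.vstack([sub_map[i].ca_coords for i in sorted(analyzed)])
        center = allca.mean(axis=0)

    if len(analyzed) < 2:
        mode_label = "asymmetric"
        ops = (
            [SymmetryOperation(RigidTransform.identity(), {i: i for i in analyzed}, 0.0)]
            if analyzed
            else []
        )
        return SymmetryResult(
            assembly.entry_id, assembly.assembly_id, stoich, "C1", [], ops,
            0.0, mode_label, None, excluded, center,
        )

    ops = enumerate_operations(assembly, clusters, config)
    label, axes = classify_point_group(ops, config)

    helical = None
    if label == "C1" or label.startswith("C"):
        helical = detect_helical(assembly, clusters, config)
        if helical is not None and label == "C1":
            label = "H"
            axes = [AxisAngle(canonical_axis(helical.axis), 0.0, None)]
        elif helical is not None:
            # a closed ring with large rise cannot occur; cyclic wins
            helical = None

    non_identity = [op for op in ops if not op.is_identity()]
    max_rmsd = max((op.rmsd for op in non_identity), default=0.0)
    if label == "H" and helical is not None:
        max_rmsd = max(max_rmsd, helical.rmsd)

    nontrivial = label not in ("C1",)
    if not nontrivial:
        mode_label = "asymmetric"
    elif mode == "symmetric":
        mode_label = "symmetric"
    else:
        strict = cluster_chains(
            assembly.subunits, config.identity_threshold_symmetry, config.min_residues
        )
        same_partition = sorted(map(sorted, strict.clusters)) == sorted(
            map(sorted, clusters.clusters)
        )
        mode_label = "symmetric" if same_partition else "pseudo-symmetric"

    return SymmetryResult(
        assembly.entry_id, assembly.assembly_id, stoich, label, axes, ops,
        max_rmsd, mode_label, helical, excluded, center,
    )


def standard_orientation(result: SymmetryResult) -> RigidTransform:
    """Transform placing the complex in its standard display orientation.

    The principal (highest-fold, or helical) axis is rotated onto +z; when a
    perpendicular axis exists (dihedral and cubic groups) the
    highest-fold perpendicular axis is brought onto +x; the symmetry center
    moves to the origin. Deterministic for a given result, and the identity
    for a complex already in standard orientation.
    """
    if result.group_label == "C1":
        raise ValueError("no standard orientation for an asymmetric (C1) complex")
    if result.helical is not None:
        axes = [AxisAngle(canonical_axis(result.helical.axis), 0.0, 1)]
    else:
        axes = result.axes
    if not axes:
        raise ValueError("result carries no axes")

    z = np.array([0.0, 0.0, 1.0])
    x = np.array([1.0, 0.0, 0.0])
    top_fold = max(a.fold or 1 for a in axes)
    candidates = [a.axis for a in axes if (a.fold or 1) == top_fold]
    primary = max(candidates, key=lambda v: (round(float(np.dot(v, z)), 9),
                                             round(float(np.dot(v, x)), 9)))

    cross = np.cross(primary, z)
    s = np.linalg.norm(cross)
    c = float(np.dot(primary, z))
    if s < 1e-12:
        R1 = np.eye(3) if c > 0 else axis_angle_matrix(x, np.pi)
    else:
        R1 = axis_angle_matrix(cross / s, float(np.arctan2(s, c)))

    R = R1
    perp = [
        a for a in axes
        if abs(float(np.dot(a.axis, primary))) < 0.05 and (a.fold or 1) >= 2
    ]
    if perp:
        best_fold = max(a.fold or 1 for a in perp)
        vs = []
        for a in perp:
            if (a.fold or 1) != best_fold:
                continue
            v = R1 @ a.axis
            if float(np.dot(v, x)) < 0 or (
                abs(float(np.dot(v, x))) < 1e-12 and v[1] < 0
            ):
                v = -v
            vs.append(v)
        v = max(vs, key=lambda w: (round(float(np.dot(w, x)), 9), round(w[1], 9)))
        phi = float(np.arctan2(v[1], v[0]))
        R = axis_angle_matrix(z, -phi) @ R1

    center = result.center if result.center is not None else np.zeros(3)
    return RigidTransform(R, -R @ center)
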