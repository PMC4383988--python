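"""Independent reference implementations used only to check the package.

Each oracle takes a deliberately different route from the implementation it
verifies: quaternion-eigenvalue superposition instead of SVD Kabsch, an
explicit Gotoh dynamic program instead of Biopython's aligner, exhaustive
permutation search instead of seeded candidate enumeration, and a
centroid-based screw fit instead of all-Cα refinement.
"""

from __future__ import annotations

import itertools

import numpy as np


def quaternion_superpose(moving, fixed):
    """Optimal proper rigid superposition via Horn's quaternion method.

    Returns (R, t, rmsd) such that R @ m + t best fits f.
    """
    m = np.asarray(moving, float)
    f = np.asarray(fixed, float)
    mc, fc = m.mean(0), f.mean(0)
    mm, ff = m - mc, f - fc
    S = mm.T @ ff
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    w, v = np.linalg.eigh(K)
    q = v[:, np.argmax(w)]  # (w, x, y, z)
    qw, qx, qy, qz = q
    R = np.array([
        [1 - 2 * (qy * qy + qz * qz), 2 * (qx * qy - qz * qw), 2 * (qx * qz + qy * qw)],
        [2 * (qx * qy + qz * qw), 1 - 2 * (qx * qx + qz * qz), 2 * (qy * qz - qx * qw)],
        [2 * (qx * qz - qy * qw), 2 * (qy * qz + qx * qw), 1 - 2 * (qx * qx + qy * qy)],
    ])
    t = fc - R @ mc
    diff = mm @ R.T - ff
    rmsd = float(np.sqrt((diff * diff).sum() / len(m)))
    return R, t, rmsd


def gotoh_align(a: str, b: str, match=1.0, mismatch=0.0, gap_open=-10.0,
                gap_extend=-0.5):
    """Affine-gap global alignment (Gotoh DP), end gaps penalized.

    gap_open is the score of the first residue of a gap; gap_extend of each
    subsequent one. Returns (score, gapped_a, gapped_b).
    """
    n, m = len(a), len(b)
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b: consumes a
    Y = np.full((n + 1, m + 1), NEG)  # gap in a: consumes b
    bpM, bpX, bpY = {}, {}, {}
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
        bpX[(i, 0)] = "X" if i > 1 else "M"
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
        bpY[(0, j)] = "Y" if j > 1 else "M"
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            opts = {"M": M[i - 1, j - 1], "X": X[i - 1, j - 1], "Y": Y[i - 1, j - 1]}
            best = max(opts, key=lambda k: opts[k])
            M[i, j] = opts[best] + s
            bpM[(i, j)] = best

            opts = {"M": M[i - 1, j] + gap_open, "Y": Y[i - 1, j] + gap_open,
                    "X": X[i - 1, j] + gap_extend}
            best = max(opts, key=lambda k: opts[k])
            X[i, j] = opts[best]
            bpX[(i, j)] = best

            opts = {"M": M[i, j - 1] + gap_open, "X": X[i, j - 1] + gap_open,
                    "Y": Y[i, j - 1] + gap_extend}
            best = max(opts, key=lambda k: opts[k])
            Y[i, j] = opts[best]
            bpY[(i, j)] = best

    finals = {"M": M[n, m], "X": X[n, m], "Y": Y[n, m]}
    state = max(finals, key=lambda k: finals[k])
    score = finals[state]
    i, j = n, m
    ga, gb = [], []
    while i > 0 or j > 0:
        if state == "M":
            prev = bpM[(i, j)]
            ga.append(a[i - 1]); gb.append(b[j - 1])
            i -= 1; j -= 1; state = prev
        elif state == "X":
            prev = bpX[(i, j)]
            ga.append(a[i - 1]); gb.append("-")
            i -= 1; state = prev
        else:
            prev = bpY[(i, j)]
            ga.append("-"); gb.append(b[j - 1])
            j -= 1; state = prev
    return float(score), "".join(reversed(ga)), "".join(reversed(gb))


def identity_from_gapped(ga: str, gb: str) -> float:
    """Percent identity over columns excluding terminal-gap columns."""
    start = 0
    while start < len(ga) and (ga[start] == "-" or gb[start] == "-"):
        start += 1
    end = len(ga)
    while end > start and (ga[end - 1] == "-" or gb[end - 1] == "-"):
        end -= 1
    cols = end - start
    if cols <= 0:
        return 0.0
    matches = sum(1 for x, y in zip(ga[start:end], gb[start:end]) if x == y and x != "-")
    return 100.0 * matches / cols


def cluster_respecting_permutations(clusters: list[list[str]]):
    """All bijections mapping every cluster onto itself."""
    per_cluster = []
    for members in clusters:
        per_cluster.append(
            [dict(zip(members, p)) for p in itertools.permutations(members)]
        )
    for combo in itertools.product(*per_cluster):
        perm = {}
        for d in combo:
            perm.update(d)
        yield perm


def exhaustive_operations(assembly, clusters: list[list[str]], cutoff: float):
    """Brute-force accepted symmetry operations for small assemblies.

    Assumes same-cluster subunits have equal residue counts (true for the
    synthetic generator), so the residue correspondence is the trivial 1:1
    map and no sequence alignment is needed. Returns {perm_key: rmsd} for
    every cluster-respecting permutation whose concatenated-Cα quaternion
    superposition passes the cutoff.
    """
    sub = assembly.subunit_map()
    ids = [m for members in clusters for m in members]
    accepted = {}
    for perm in cluster_respecting_permutations(clusters):
        mov = np.vstack([sub[i].ca_coords for i in ids])
        fix = np.vstack([sub[perm[i]].ca_coords for i in ids])
        _, _, rmsd = quaternion_superpose(mov, fix)
        if rmsd < cutoff:
            accepted[tuple(perm[i] for i in ids)] = rmsd
    return ids, accepted


def screw_fit_centroids(centroids):
    """Least-squares screw from consecutive centroid displacements.

    Returns (axis, rise, twist_degrees); the axis is oriented so rise >= 0.
    """
    c = np.asarray(centroids, float)
    R, t, _ = quaternion_superpose(c[:-1], c[1:])
    w, v = np.linalg.eig(R)
    k = int(np.argmin(np.abs(w - 1.0)))
    axis = np.real(v[:, k])
    axis /= np.linalg.norm(axis)
    cos_angle = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = float(np.arccos(cos_angle))
    # fix the rotation sense relative to the axis
    probe = np.array([1.0, 0.2, 0.3])
    probe -= axis * (probe @ axis)
    rotated = R @ probe
    if float(np.dot(np.cross(probe, rotated), axis)) < 0:
        axis = -axis
    rise = float(np.dot(t, axis))
    if rise < 0:
        axis, angle, rise = -axis, -angle, -rise
    return axis, rise, float(np.rad2deg(angle))


def bin_rotation_angles(matrices, max_fold=60, tol=0.1):
    """Fold of each rotation by snapping its trace angle to a 2π/n grid."""
    folds = []
    for R in matrices:
        angle = float(np.arccos(np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)))
        if angle <= tol / 2:
            folds.append(None)
            continue
        for n in range(2, max_fold + 1):
            k = round(angle * n / (2 * np.pi))
            if k >= 1 and abs(angle - 2 * np.pi * k / n) <= tol:
                folds.append(n)
                break
        else:
            folds.append(-1)
    return folds
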