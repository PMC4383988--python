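"""Canonical rotation-operator sets for the finite point groups.

Cyclic (Cn) and dihedral (Dn) sets are built directly; the tetrahedral (T,
order 12), octahedral (O, order 24) and icosahedral (I, order 60) groups are
generated once by closing a pair of generators under multiplication, in the
standard orientation where the 2-fold axes of the cubic groups lie along the
coordinate axes and the 3-folds along the cube diagonals. Each generated set
is validated against the expected group order at import time.
"""

from __future__ import annotations

import numpy as np

from .superpose import axis_angle_matrix

_PHI = (1.0 + np.sqrt(5.0)) / 2.0


def _close_group(generators: list[np.ndarray], expected_order: int) -> list[np.ndarray]:
    seen: dict[tuple, np.ndarray] = {}

    def key(M: np.ndarray) -> tuple:
        return tuple(np.round(M, 6).ravel())

    frontier = [np.eye(3)] + [np.asarray(g) for g in generators]
    for M in frontier:
        seen.setdefault(key(M), M)
    while frontier:
        nxt = []
        for M in frontier:
            for g in generators:
                P = g @ M
                k = key(P)
                if k not in seen:
                    seen[k] = P
                    nxt.append(P)
        frontier = nxt
        if len(seen) > expected_order:
            break
    if len(seen) != expected_order:
        raise RuntimeError(
            f"group closure produced {len(seen)} elements, expected {expected_order}"
        )
    return list(seen.values())


def cyclic_operators(n: int) -> list[np.ndarray]:
    """Rotations 2πk/n about z, k = 0..n−1."""
    if n < 1:
        raise ValueError("fold must be >= 1")
    return [axis_angle_matrix([0, 0, 1], 2.0 * np.pi * k / n) for k in range(n)]


def dihedral_operators(n: int) -> list[np.ndarray]:
    """Cn about z plus n 2-folds in the xy-plane at angles πk/n (order 2n)."""
    if n < 2:
        raise ValueError("dihedral fold must be >= 2")
    ops = cyclic_operators(n)
    for k in range(n):
        phi = np.pi * k / n
        ops.append(axis_angle_matrix([np.cos(phi), np.sin(phi), 0.0], np.pi))
    return ops


def tetrahedral_operators() -> list[np.ndarray]:
    return _close_group(
        [axis_angle_matrix([0, 0, 1], np.pi),
         axis_angle_matrix([1, 1, 1], 2.0 * np.pi / 3.0)],
        12,
    )


def octahedral_operators() -> list[np.ndarray]:
    return _close_group(
        [axis_angle_matrix([0, 0, 1], np.pi / 2.0),
         axis_angle_matrix([1, 1, 1], 2.0 * np.pi / 3.0)],
        24,
    )


def icosahedral_operators() -> list[np.ndarray]:
    # 5-fold through an icosahedron vertex (0, 1, φ); contains T as a subgroup
    return _close_group(
        [axis_angle_matrix([0.0, 1.0, _PHI], 2.0 * np.pi / 5.0),
         axis_angle_matrix([1, 1, 1], 2.0 * np.pi / 3.0)],
        60,
    )


def group_operators(label: str, n: int | None = None) -> list[np.ndarray]:
    """Operator set for a group label: 'C', 'D' (with fold n), 'T', 'O', 'I'."""
    label = label.upper()
    if label == "C":
        return cyclic_operators(int(n))
    if label == "D":
        return dihedral_operators(int(n))
    if label == "T":
        return tetrahedral_operators()
    if label == "O":
        return octahedral_operators()
    if label == "I":
        return icosahedral_operators()
    raise ValueError(f"unknown point group label {label!r}")


GROUP_ORDERS = {"T": 12, "O": 24, "I": 60}
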