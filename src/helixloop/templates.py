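"""Idealized planar base templates in the standard base-pair frame.

Each template maps atom names to coordinates (Angstrom) of a planar,
regular-polygon idealization of the base ring system, expressed in the
base-pair reference frame of a strand-I base: the base plane is the
frame's xy-plane (z = 0), the ring sits on the +y side of the origin and
the Watson-Crick edge faces the paired base across the origin.  Templates
carry the glycosidic nitrogen, all ring atoms and a C1' marker plus an
idealized backbone P marker (the only out-of-plane atom).

These are synthetic idealized geometries (aromatic bond length 1.39 A,
regular hexagon/pentagon rings), not crystallographic standards: the
package uses them as a self-consistent substrate for embedding atoms into
frames and re-fitting frames from atoms, where only the rigid-body
relationship matters.

A strand-II base in the same pair uses the same template after a
180-degree rotation about the frame x axis (y -> -y, z -> -z), the
standard flip that brings the antiparallel partner into the shared frame
convention.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BASE_TEMPLATES", "WC_PARTNER", "flip_strand_ii"]

_SIDE = 1.39  # aromatic bond length, A

WC_PARTNER = {"A": "T", "T": "A", "G": "C", "C": "G", "U": "A"}

_PYRIMIDINE_RING = ["N1", "C2", "N3", "C4", "C5", "C6"]
_PURINE_SIX_RING = ["N1", "C2", "N3", "C4", "C5", "C6"]
_PURINE_FIVE_RING = ["C4", "C5", "N7", "C8", "N9"]  # fused on the C4-C5 edge


def _hexagon(center: np.ndarray, start_angle_deg: float) -> dict[str, np.ndarray]:
    """Regular hexagon in the xy-plane; vertex 0 at ``start_angle_deg``."""
    r = _SIDE  # circumradius of a regular hexagon equals its side
    pts = {}
    for k in range(6):
        a = np.radians(start_angle_deg + 60.0 * k)
        pts[k] = center + r * np.array([np.cos(a), np.sin(a), 0.0])
    return pts


def _pentagon_on_edge(p1: np.ndarray, p2: np.ndarray, outward: np.ndarray):
    """The three remaining vertices of a regular pentagon built on the
    edge p1->p2, on the side indicated by ``outward``."""
    side = np.linalg.norm(p2 - p1)
    apothem = side / (2.0 * np.tan(np.pi / 5.0))
    circum = side / (2.0 * np.sin(np.pi / 5.0))
    mid = 0.5 * (p1 + p2)
    edge_dir = (p2 - p1) / side
    normal = outward - np.dot(outward, edge_dir) * edge_dir
    normal = normal / np.linalg.norm(normal)
    center = mid + apothem * normal
    # pentagon vertices at 72-degree spacing starting from p1
    a0 = np.arctan2(p1[1] - center[1], p1[0] - center[0])
    a2 = np.arctan2(p2[1] - center[1], p2[0] - center[0])
    # walk from p2 away from p1 (three new vertices)
    step = np.radians(72.0)
    delta = (a2 - a0) % (2.0 * np.pi)
    direction = 1.0 if np.isclose(delta, step, atol=1e-6) else -1.0
    out = []
    for k in range(1, 4):
        a = a2 + direction * step * k
        out.append(center + circum * np.array([np.cos(a), np.sin(a), 0.0]))
    return out


def _build_pyrimidine() -> dict[str, np.ndarray]:
    # ring center on the +y side; glycosidic N1 at the top of the ring
    center = np.array([0.0, 2.0, 0.0])
    hexa = _hexagon(center, start_angle_deg=90.0)
    atoms = {name: hexa[k] for k, name in enumerate(_PYRIMIDINE_RING)}
    n1 = atoms["N1"]
    c1p = n1 + 1.48 * (n1 - center) / np.linalg.norm(n1 - center)
    atoms["C1'"] = c1p
    atoms["P"] = c1p + np.array([0.8, 1.6, 1.6])
    return atoms


def _build_purine() -> dict[str, np.ndarray]:
    center = np.array([0.0, 2.0, 0.0])
    hexa = _hexagon(center, start_angle_deg=-90.0)
    atoms = {name: hexa[k] for k, name in enumerate(_PURINE_SIX_RING)}
    p1, p2 = atoms["C4"], atoms["C5"]
    outward = 0.5 * (p1 + p2) - center
    n7, c8, n9 = _pentagon_on_edge(p1, p2, outward)
    atoms["N7"], atoms["C8"], atoms["N9"] = n7, c8, n9
    n9v = atoms["N9"]
    five_center = (atoms["C4"] + atoms["C5"] + n7 + c8 + n9v) / 5.0
    c1p = n9v + 1.48 * (n9v - five_center) / np.linalg.norm(n9v - five_center)
    atoms["C1'"] = c1p
    atoms["P"] = c1p + np.array([0.8, 1.6, 1.6])
    return atoms


_PURINE = _build_purine()
_PYRIMIDINE = _build_pyrimidine()

BASE_TEMPLATES: dict[str, dict[str, np.ndarray]] = {
    "A": dict(_PURINE),
    "G": dict(_PURINE),
    "C": dict(_PYRIMIDINE),
    "T": dict(_PYRIMIDINE),
    "U": dict(_PYRIMIDINE),
}

_FLIP = np.diag([1.0, -1.0, -1.0])


def flip_strand_ii(template: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Apply the strand-II flip (180 degrees about the frame x axis)."""
    return {name: _FLIP @ xyz for name, xyz in template.items()}
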