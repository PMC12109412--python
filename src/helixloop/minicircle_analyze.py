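"""Topology and bending analysis of closed duplex paths.

Implements the twist-writhe-linking-number bookkeeping of closed duplex
circles (Lk = Tw + Wr, White's theorem), per-bp curvature and bend-
direction (register) profiles, and detection/typing of kinks from helical
parameter time series.

Writhe uses the exact closed-form Gauss double integral over segment
pairs of the origin polygon (the Klenin-Langowski method).  Twist is the
ribbon twist of the bp x axes about the path tangent, computed with
parallel transport across each vertex; with this definition the discrete
Calugareanu-White identity Lk = Tw + Wr holds to numerical precision for
any closed path, and for the uniform planar builder circle Tw equals the
construction twist exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .helix_analyze import ParameterTable
from .helix_build import DuplexPath

__all__ = [
    "TopologyResult",
    "KinkCall",
    "writhe",
    "gauss_linking_number",
    "ribbon_twist",
    "linking_number",
    "curvature_profile",
    "mean_curvature_profile",
    "register_profile",
    "detect_kinks",
]


def _pairwise_solid_angles(p1, p2, p3, p4) -> np.ndarray:
    """Signed solid-angle contributions Omega*/(4 pi) for batches of
    segment pairs (p1->p2, p3->p4), per Klenin & Langowski method 1a.

    All inputs broadcast to (..., 3); degenerate pairs (any coplanar
    tetrahedron face) contribute exactly zero."""
    r13 = p3 - p1
    r14 = p4 - p1
    r23 = p3 - p2
    r24 = p4 - p2
    n1 = np.cross(r13, r14)
    n2 = np.cross(r14, r24)
    n3 = np.cross(r24, r23)
    n4 = np.cross(r23, r13)
    normals = np.stack([n1, n2, n3, n4])
    norms = np.linalg.norm(normals, axis=-1, keepdims=True)
    ok = (norms[..., 0] > 1e-14).all(axis=0)
    normals = np.where(norms > 1e-300, normals / np.maximum(norms, 1e-300), 0.0)
    n1, n2, n3, n4 = normals
    omega = (
        np.arcsin(np.clip(np.sum(n1 * n2, axis=-1), -1.0, 1.0))
        + np.arcsin(np.clip(np.sum(n2 * n3, axis=-1), -1.0, 1.0))
        + np.arcsin(np.clip(np.sum(n3 * n4, axis=-1), -1.0, 1.0))
        + np.arcsin(np.clip(np.sum(n4 * n1, axis=-1), -1.0, 1.0))
    )
    sign = np.sign(np.sum(np.cross(p4 - p3, p2 - p1) * r13, axis=-1))
    return np.where(ok, omega * sign / (4.0 * np.pi), 0.0)


def writhe(origins: np.ndarray, closed: bool = True) -> float:
    """Writhe of a closed polygon via the exact Gauss double integral.

    ``origins`` is an (N, 3) array of vertices of a closed,
    non-self-intersecting polygon (the closing edge from the last vertex
    to the first is implicit).  Adjacent segments contribute zero.
    """
    if not closed:
        raise ValueError("writhe is defined for closed paths only")
    pts = np.asarray(origins, dtype=float)
    n = len(pts)
    if n < 3:
        raise ValueError("polygon needs >= 3 vertices")
    starts = pts
    ends = np.roll(pts, -1, axis=0)
    omega = _pairwise_solid_angles(
        starts[:, None, :], ends[:, None, :], starts[None, :, :], ends[None, :, :]
    )
    # zero out self and adjacent pairs (shared vertices), then sum i < j
    idx = np.arange(n)
    adjacent = (np.abs(idx[:, None] - idx[None, :]) <= 1) | (
        np.abs(idx[:, None] - idx[None, :]) == n - 1
    )
    omega = np.where(adjacent, 0.0, omega)
    return float(np.sum(np.triu(omega, k=1)) * 2.0)


def gauss_linking_number(curve1: np.ndarray, curve2: np.ndarray) -> float:
    """Gauss linking integral of two disjoint closed polygons."""
    c1 = np.asarray(curve1, dtype=float)
    c2 = np.asarray(curve2, dtype=float)
    e1 = np.roll(c1, -1, axis=0)
    e2 = np.roll(c2, -1, axis=0)
    omega = _pairwise_solid_angles(
        c1[:, None, :], e1[:, None, :], c2[None, :, :], e2[None, :, :]
    )
    return float(omega.sum())


def _tangents(origins: np.ndarray) -> np.ndarray:
    segs = np.roll(origins, -1, axis=0) - origins
    return segs / np.linalg.norm(segs, axis=1, keepdims=True)


def _transport(u: np.ndarray, t_from: np.ndarray, t_to: np.ndarray) -> np.ndarray:
    """Parallel transport (minimal rotation) of u from tangent t_from to
    t_to (the double-reflection-free rotation about t_from x t_to)."""
    axis = np.cross(t_from, t_to)
    s = np.linalg.norm(axis)
    c = float(t_from @ t_to)
    if s < 1e-14:
        return u.copy()
    axis = axis / s
    angle = np.arctan2(s, c)
    return (
        u * np.cos(angle)
        + np.cross(axis, u) * np.sin(angle)
        + axis * (axis @ u) * (1.0 - np.cos(angle))
    )


def ribbon_twist(path: DuplexPath) -> float:
    """Twist (turns) of the bp x-axis ribbon about the path tangent.

    For each segment the material vector is frame k's x axis
    orthogonalized against the segment tangent; between consecutive
    segments the vector is parallel-transported across the vertex and the
    residual rotation about the new tangent is the local twist increment.
    """
    if not path.closed:
        raise ValueError("ribbon twist is defined for closed paths only")
    origins = path.origins
    tangents = _tangents(origins)
    n = len(origins)
    us = []
    for k in range(n):
        u = path.frames[k].x
        u = u - (u @ tangents[k]) * tangents[k]
        nu = np.linalg.norm(u)
        if nu < 1e-12:
            raise ValueError(f"bp {k + 1} x axis parallel to the tangent")
        us.append(u / nu)
    total = 0.0
    for k in range(n):
        k1 = (k + 1) % n
        u_t = _transport(us[k], tangents[k], tangents[k1])
        s = float(np.cross(u_t, us[k1]) @ tangents[k1])
        c = float(u_t @ us[k1])
        total += np.arctan2(s, c)
    return total / (2.0 * np.pi)


@dataclass(frozen=True)
class TopologyResult:
    """Twist, writhe and linking number of a closed duplex path.

    ``Tw`` and ``Wr`` are in turns; ``Lk`` is the nearest integer to
    Tw + Wr with the rounding residual reported separately."""

    Tw: float
    Wr: float

    @property
    def Lk_real(self) -> float:
        return self.Tw + self.Wr

    @property
    def Lk(self) -> int:
        return int(round(self.Lk_real))

    @property
    def residual(self) -> float:
        return self.Lk_real - self.Lk


def linking_number(path: DuplexPath) -> TopologyResult:
    """Linking number of a closed duplex path as Tw + Wr.

    Tw sums the cyclic per-step twist of the bp x-axis ribbon about the
    path tangent (see :func:`ribbon_twist`); Wr is the writhe of the
    origin polygon.  Raises on open paths.
    """
    if not path.closed:
        raise ValueError("linking number is defined for closed paths only")
    return TopologyResult(Tw=ribbon_twist(path), Wr=writhe(path.origins))


def curvature_profile(path: DuplexPath, window: int = 1) -> np.ndarray:
    """Per-bp curvature (degrees per step) of a closed path.

    The curvature at bp k is the angle between the average incoming and
    outgoing tangents over ``window`` segments on each side.  For an
    ideal planar circle of N bp this is the regular-polygon exterior
    angle 360/N at every bp.
    """
    if not path.closed:
        raise ValueError("curvature profile requires a closed path")
    origins = path.origins
    n = len(origins)
    if window < 1 or 2 * window > n - 1:
        raise ValueError("window must satisfy 1 <= window <= (n-1)/2")
    tangents = _tangents(origins)
    out = np.empty(n)
    for k in range(n):
        t_in = np.sum([tangents[(k - w) % n] for w in range(1, window + 1)], axis=0)
        t_out = np.sum([tangents[(k + w - 1) % n] for w in range(1, window + 1)], axis=0)
        t_in /= np.linalg.norm(t_in)
        t_out /= np.linalg.norm(t_out)
        out[k] = np.degrees(
            np.arctan2(np.linalg.norm(np.cross(t_in, t_out)), float(t_in @ t_out))
        )
    return out


def mean_curvature_profile(paths: list[DuplexPath], window: int = 1) -> np.ndarray:
    """Time-averaged per-bp curvature over an ensemble of closed paths."""
    return np.mean([curvature_profile(p, window=window) for p in paths], axis=0)


def register_profile(
    path: DuplexPath,
    smooth_window: int = 3,
    min_curvature: float = 0.5,
) -> np.ndarray:
    """Per-bp register angle in (-180, 180] of a closed path.

    The register is the direction of local bending expressed in the bp
    frame: the discrete Frenet normal (the perpendicular change of the
    tangent, smoothed over ``smooth_window`` steps) is projected onto the
    bp x/y plane and reported as atan2(b_x, b_y) degrees.  By this
    convention a bp whose major groove (the -x side) faces the bend
    center reads -90 degrees (bending into the major groove) and one
    whose minor groove faces the center reads +90 degrees.  Base pairs
    whose local curvature is below ``min_curvature`` degrees/step have no
    defined bend direction and get NaN.
    """
    if not path.closed:
        raise ValueError("register profile requires a closed path")
    origins = path.origins
    n = len(origins)
    tangents = _tangents(origins)
    curv = curvature_profile(path)
    half = max(smooth_window // 2, 1)
    out = np.full(n, np.nan)
    for k in range(n):
        if curv[k] < min_curvature:
            continue
        t_in = np.sum([tangents[(k - w) % n] for w in range(1, half + 1)], axis=0)
        t_out = np.sum([tangents[(k + w - 1) % n] for w in range(1, half + 1)], axis=0)
        t_in /= np.linalg.norm(t_in)
        t_out /= np.linalg.norm(t_out)
        bend = t_out - t_in
        t_mean = t_in + t_out
        t_mean /= np.linalg.norm(t_mean)
        bend = bend - (bend @ t_mean) * t_mean
        nb = np.linalg.norm(bend)
        if nb < 1e-12:
            continue
        bend /= nb
        frame = path.frames[k]
        out[k] = np.degrees(np.arctan2(float(bend @ frame.x), float(bend @ frame.y)))
    return out


@dataclass(frozen=True)
class KinkCall:
    """A detected kink: contiguous 1-based step range, type (I or II) and
    the evidence behind the call."""

    step_range: tuple[int, ...]
    kink_type: str  # "I" | "II"
    min_roll: float
    max_propeller: float
    broken_pair: bool
    snapshot_span: tuple[int, int]


def _longest_run(mask: np.ndarray) -> tuple[int, int, int]:
    """(length, start, end) of the longest True run in a boolean array."""
    best = (0, -1, -1)
    run = 0
    start = 0
    for i, v in enumerate(mask):
        if v:
            if run == 0:
                start = i
            run += 1
            if run > best[0]:
                best = (run, start, i)
        else:
            run = 0
    return best


def detect_kinks(
    table: ParameterTable,
    roll_threshold: float = -30.0,
    propeller_threshold: float = 30.0,
    min_frames: int = 100,
) -> list[KinkCall]:
    """Detect and type kinks from roll/propeller time series.

    A step is kinked when its roll stays below ``roll_threshold``
    (degrees) for a contiguous dwell of at least ``min_frames`` snapshots.
    Adjacent kinked steps merge into one call.  A call is type II when it
    spans >= 2 steps or shows disrupted pairing (a broken-pair flag, or
    median propeller above ``propeller_threshold`` at the spanned base
    pairs during the dwell); a single-step call with intact pairing is
    type I.  Detection is monotone in the thresholds: loosening
    ``roll_threshold`` upward or ``min_frames`` downward never un-flags a
    step.
    """
    try:
        roll = table.series("step", "roll")
    except KeyError as exc:
        raise ValueError("parameter table lacks a roll series") from exc
    has_intra = any(p == ("bp", "propeller") for p in table.parameters())
    prop = table.series("bp", "propeller") if has_intra else None
    if prop is None:
        raise ValueError("parameter table lacks a propeller series")
    broken = (
        table.series("bp", "broken")
        if any(p == ("bp", "broken") for p in table.parameters())
        else None
    )

    flagged: dict[int, tuple[int, int]] = {}
    for step in roll.columns:
        mask = (roll[step] < roll_threshold).to_numpy()
        length, start, end = _longest_run(mask)
        if length >= min_frames:
            flagged[int(step)] = (start, end)

    calls: list[KinkCall] = []
    steps_sorted = sorted(flagged)
    i = 0
    while i < len(steps_sorted):
        j = i
        while j + 1 < len(steps_sorted) and steps_sorted[j + 1] == steps_sorted[j] + 1:
            j += 1
        group = steps_sorted[i : j + 1]
        spans = [flagged[s] for s in group]
        span = (min(s for s, _ in spans), max(e for _, e in spans))
        bps = sorted({b for s in group for b in (s, s + 1) if b in prop.columns})
        window = prop.loc[span[0] : span[1], bps]
        max_prop = float(window.median(axis=0).max())
        any_broken = False
        if broken is not None:
            bcols = [b for b in bps if b in broken.columns]
            if bcols:
                any_broken = bool(
                    (broken.loc[span[0] : span[1], bcols].mean(axis=0) > 0.5).any()
                )
        # type II requires a multi-step signature or disrupted pairing;
        # a single sharply rolled step with intact pairing is type I
        kink_type = "II" if len(group) >= 2 or any_broken else "I"
        roll_window = roll.loc[span[0] : span[1], group]
        calls.append(
            KinkCall(
                step_range=tuple(group),
                kink_type=kink_type,
                min_roll=float(roll_window.min().min()),
                max_propeller=max_prop,
                broken_pair=any_broken,
                snapshot_span=span,
            )
        )
        i = j + 1
    return calls
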