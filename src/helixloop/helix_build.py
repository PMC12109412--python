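"""Construction of idealized duplex geometries.

A duplex is represented as an ordered path of base-pair reference frames
(:class:`BpFrame`): an origin plus a right-handed orthonormal triad with
x toward the major groove, y toward the strand-I backbone and z along the
local helix advance (the standard base-pair frame convention).  Builders
provided here:

* :func:`straight_duplex` — repeated application of a rigid-body step
  generator (the exact inverse of the parameter extraction in
  :mod:`helixloop.helix_analyze`);
* :func:`helical_duplex` — a regular helix around a fixed global axis
  with prescribed helical parameters (x/y displacement, inclination, tip);
* :func:`minicircle` — a planar closed circle with the total twist
  distributed uniformly over the cyclic steps, i.e. a torsionally defined
  starting structure at a chosen linking number;
* :func:`embed_atoms` — placement of idealized base atom templates into
  each frame for PDB export.

Angles are degrees and lengths are Angstrom throughout.  The step
generator composes the three step rotations as a single rotation vector
(tilt, roll, twist) about the mid-step frame axes, so that rebuilding a
path from extracted parameters is exact to machine precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .templates import BASE_TEMPLATES, WC_PARTNER, flip_strand_ii

__all__ = [
    "BpFrame",
    "DuplexPath",
    "StepParams",
    "IntraBpParams",
    "Atom",
    "AtomicModel",
    "FORM_STEPS",
    "straight_duplex",
    "helical_duplex",
    "minicircle",
    "embed_atoms",
    "advance_frame",
    "mid_frame",
    "sample_trajectory",
    "KinkSpec",
    "SyntheticEnsemble",
    "deform_out_of_plane",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class BpFrame:
    """Base-pair reference frame: origin (A) + orthonormal triad.

    ``triad`` columns are the x, y, z axes expressed in lab coordinates.
    """

    origin: np.ndarray
    triad: np.ndarray
    bp_id: int = 1
    identity: str = "G·C"

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "triad", np.asarray(self.triad, dtype=float))
        if self.origin.shape != (3,) or self.triad.shape != (3, 3):
            raise ValueError("origin must be a 3-vector and triad a 3x3 matrix")
        err = np.abs(self.triad.T @ self.triad - np.eye(3)).max()
        if err > _ORTHO_TOL:
            raise ValueError(f"triad not orthonormal (max deviation {err:.2e})")
        if np.linalg.det(self.triad) < 0:
            raise ValueError("triad must be right-handed (det +1)")

    @property
    def x(self) -> np.ndarray:
        return self.triad[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.triad[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.triad[:, 2]


@dataclass(frozen=True)
class DuplexPath:
    """Ordered base-pair frames of one duplex, open or closed.

    For a closed path, step parameters are defined cyclically (the step
    from the last frame back to the first is a regular step).
    """

    frames: tuple[BpFrame, ...]
    closed: bool = False
    form_tag: str = "custom"

    def __post_init__(self) -> None:
        n_min = 3 if self.closed else 2
        if len(self.frames) < n_min:
            raise ValueError(
                f"{'closed' if self.closed else 'open'} path needs >= {n_min} frames"
            )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def origins(self) -> np.ndarray:
        return np.array([f.origin for f in self.frames])

    @property
    def triads(self) -> np.ndarray:
        return np.array([f.triad for f in self.frames])

    def steps(self) -> list[tuple[BpFrame, BpFrame]]:
        pairs = list(zip(self.frames[:-1], self.frames[1:]))
        if self.closed:
            pairs.append((self.frames[-1], self.frames[0]))
        return pairs


@dataclass(frozen=True)
class StepParams:
    """The six rigid-body base-pair step parameters."""

    shift: float = 0.0
    slide: float = 0.0
    rise: float = 3.4
    tilt: float = 0.0
    roll: float = 0.0
    twist: float = 36.0

    def translation(self) -> np.ndarray:
        return np.array([self.shift, self.slide, self.rise])

    def rotation_deg(self) -> np.ndarray:
        return np.array([self.tilt, self.roll, self.twist])

    @classmethod
    def from_arrays(cls, translation, rotation_deg) -> "StepParams":
        sh, sl, ri = translation
        ti, ro, tw = rotation_deg
        return cls(shift=sh, slide=sl, rise=ri, tilt=ti, roll=ro, twist=tw)


@dataclass(frozen=True)
class IntraBpParams:
    """The six intra-base-pair parameters (base II relative to base I)."""

    shear: float = 0.0
    stretch: float = 0.0
    stagger: float = 0.0
    buckle: float = 0.0
    propeller: float = 0.0
    opening: float = 0.0

    def translation(self) -> np.ndarray:
        return np.array([self.shear, self.stretch, self.stagger])

    def rotation_deg(self) -> np.ndarray:
        return np.array([self.buckle, self.propeller, self.opening])


# Idealized fiber-like defaults.  B-form for DNA; an A-like parameter set
# for the RNA-DNA hybrid (lower twist, shorter rise, positive roll),
# consistent with the hybrid sitting between B-DNA and A-RNA.
FORM_STEPS: dict[str, StepParams] = {
    "B": StepParams(rise=3.4, twist=36.0),
    "A": StepParams(rise=2.8, twist=32.7, roll=8.0),
    "hybrid": StepParams(rise=2.8, twist=32.0, roll=6.0),
}


def _rotvec_matrix(rot_deg: np.ndarray) -> np.ndarray:
    return Rotation.from_rotvec(np.radians(rot_deg)).as_matrix()


def mid_frame(triad_i: np.ndarray, triad_j: np.ndarray) -> np.ndarray:
    """The mid-frame between two triads: triad_i rotated halfway toward
    triad_j along the geodesic (half the rotation vector)."""
    r = Rotation.from_matrix(triad_i.T @ triad_j)
    half = Rotation.from_rotvec(r.as_rotvec() / 2.0).as_matrix()
    return triad_i @ half


def advance_frame(frame: BpFrame, step: StepParams, bp_id: int | None = None,
                  identity: str = "G·C") -> BpFrame:
    """Generate the next bp frame by one rigid-body step.

    The rotation is applied as a single rotation vector (tilt, roll,
    twist) about the mid-step frame axes; the translation (shift, slide,
    rise) is expressed in the mid-step frame.
    """
    rot = step.rotation_deg()
    t1 = frame.triad
    tm = t1 @ _rotvec_matrix(rot / 2.0)
    t2 = t1 @ _rotvec_matrix(rot)
    o2 = frame.origin + tm @ step.translation()
    return BpFrame(
        origin=o2,
        triad=t2,
        bp_id=frame.bp_id + 1 if bp_id is None else bp_id,
        identity=identity,
    )


def _identities(sequence: str | None, n_bp: int) -> list[str]:
    if sequence is None:
        return ["G·C"] * n_bp
    if len(sequence) != n_bp:
        raise ValueError(f"sequence length {len(sequence)} != n_bp {n_bp}")
    seq = sequence.upper()
    bad = set(seq) - set(WC_PARTNER)
    if bad:
        raise ValueError(f"unknown residues in sequence: {sorted(bad)}")
    return [f"{b}·{WC_PARTNER[b]}" for b in seq]


def straight_duplex(
    n_bp: int,
    step: StepParams | None = None,
    sequence: str | None = None,
    form: str | None = None,
) -> DuplexPath:
    """Uniform open duplex from repeated application of one step.

    Provide either explicit ``step`` parameters or a named ``form``
    ("B", "A", "hybrid"); defaults to B-form.
    """
    if n_bp < 2:
        raise ValueError("straight duplex needs n_bp >= 2")
    if step is None:
        step = FORM_STEPS[form or "B"]
    if step.rise <= 0:
        raise ValueError("rise must be positive")
    idents = _identities(sequence, n_bp)
    frames = [BpFrame(origin=np.zeros(3), triad=np.eye(3), bp_id=1, identity=idents[0])]
    for k in range(1, n_bp):
        frames.append(advance_frame(frames[-1], step, identity=idents[k]))
    return DuplexPath(frames=tuple(frames), closed=False,
                      form_tag=form or "custom")


def helical_duplex(
    n_bp: int,
    h_twist: float = 36.0,
    h_rise: float = 3.4,
    xdisp: float = 0.0,
    ydisp: float = 0.0,
    inclination: float = 0.0,
    tip: float = 0.0,
    sequence: str | None = None,
) -> DuplexPath:
    """Regular helix around the global z axis with prescribed helical
    parameters: bp k sits at azimuth k*h_twist, height k*h_rise, displaced
    by (xdisp, ydisp) in its own frame from the axis, its triad tilted by
    (inclination about bp x', tip about bp y') relative to the axis."""
    if n_bp < 2:
        raise ValueError("helical duplex needs n_bp >= 2")
    if h_rise <= 0:
        raise ValueError("h_rise must be positive")
    idents = _identities(sequence, n_bp)
    tilt_rot = (
        Rotation.from_euler("y", tip, degrees=True)
        * Rotation.from_euler("x", inclination, degrees=True)
    ).as_matrix()
    disp = tilt_rot @ np.array([xdisp, ydisp, 0.0])
    frames = []
    for k in range(n_bp):
        az = Rotation.from_euler("z", k * h_twist, degrees=True).as_matrix()
        triad = az @ tilt_rot
        origin = np.array([0.0, 0.0, k * h_rise]) + az @ disp
        frames.append(BpFrame(origin=origin, triad=triad, bp_id=k + 1,
                              identity=idents[k]))
    return DuplexPath(frames=tuple(frames), closed=False, form_tag="custom")


def minicircle(
    n_bp: int,
    turns: int,
    rise: float = 3.4,
    sequence: str | None = None,
    x_toward_center: bool = True,
) -> DuplexPath:
    """Planar closed minicircle with uniform twist at a target linking
    number.

    Origins are equally spaced on a circle of radius n_bp*rise/(2*pi) in
    the xy-plane; each local z is the tangent; the bp x axis starts in the
    circle plane pointing at (or away from, with ``x_toward_center=False``)
    the center, then accumulates a uniform twist of 360*turns/n_bp degrees
    per step about the local tangent.  Because ``turns`` is an integer the
    cyclic step from frame N back to frame 1 is identical to every other
    step (exact closure).
    """
    if n_bp < 3:
        raise ValueError("minicircle needs n_bp >= 3")
    if turns < 1:
        raise ValueError("turns must be >= 1")
    per_step_twist = 360.0 * turns / n_bp
    if per_step_twist > 60.0:
        warnings.warn(
            f"per-step twist {per_step_twist:.1f} deg exceeds 60 deg: "
            "unphysically overwound circle",
            stacklevel=2,
        )
    idents = _identities(sequence, n_bp)
    radius = n_bp * rise / (2.0 * np.pi)
    frames = []
    for k in range(n_bp):
        alpha = 2.0 * np.pi * k / n_bp
        radial = np.array([np.cos(alpha), np.sin(alpha), 0.0])
        tangent = np.array([-np.sin(alpha), np.cos(alpha), 0.0])
        origin = radius * radial
        x0 = -radial if x_toward_center else radial
        twist_angle = np.radians(per_step_twist) * k
        x_axis = Rotation.from_rotvec(twist_angle * tangent).apply(x0)
        y_axis = np.cross(tangent, x_axis)
        triad = np.column_stack([x_axis, y_axis, tangent])
        frames.append(BpFrame(origin=origin, triad=triad, bp_id=k + 1,
                              identity=idents[k]))
    return DuplexPath(frames=tuple(frames), closed=True, form_tag="custom")


# ---------------------------------------------------------------------------
# Atom embedding

@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: np.ndarray
    resname: str
    resseq: int
    chain: str


@dataclass(frozen=True)
class AtomicModel:
    """One all-atom snapshot: two antiparallel strands, chains A and B."""

    atoms: tuple[Atom, ...]

    def coordinates(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms])


_DNA_RESNAMES = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}
_RNA_RESNAMES = {"A": "A", "C": "C", "G": "G", "U": "U"}


def _resname(base: str, kind: str) -> str:
    return _DNA_RESNAMES[base] if kind == "DNA" else _RNA_RESNAMES[base]


def embed_atoms(
    path: DuplexPath,
    sequence: str,
    kind1: str = "DNA",
    kind2: str = "DNA",
) -> AtomicModel:
    """Place idealized base atom templates by each frame's rigid
    transform.

    ``sequence`` is the strand-I sequence 5'->3' (one residue per frame);
    strand II carries the Watson-Crick complement.  Strand-I atoms are the
    template transformed by the bp frame; strand-II atoms additionally get
    the 180-degree flip about the bp x axis that maps the strand-II base
    into the shared frame convention.  Strand II residues are numbered
    5'->3' along strand II (reverse of strand I).
    """
    if len(sequence) != len(path):
        raise ValueError(
            f"sequence length {len(sequence)} != number of frames {len(path)}"
        )
    seq1 = sequence.upper()
    if kind2 == "RNA":
        partner = {"A": "U", "T": "A", "U": "A", "G": "C", "C": "G"}
    else:
        partner = {"A": "T", "T": "A", "U": "A", "G": "C", "C": "G"}
    n = len(path)
    atoms: list[Atom] = []
    for i, frame in enumerate(path.frames):
        base1 = seq1[i]
        base2 = partner[base1]
        tpl1 = BASE_TEMPLATES[base1]
        tpl2 = flip_strand_ii(BASE_TEMPLATES[base2])
        for name, local in tpl1.items():
            atoms.append(
                Atom(
                    name=name,
                    element=name.strip()[0],
                    xyz=frame.origin + frame.triad @ local,
                    resname=_resname(base1, kind1),
                    resseq=i + 1,
                    chain="A",
                )
            )
        for name, local in tpl2.items():
            atoms.append(
                Atom(
                    name=name,
                    element=name.strip()[0],
                    xyz=frame.origin + frame.triad @ local,
                    resname=_resname(base2, kind2),
                    resseq=n - i,
                    chain="B",
                )
            )
    return AtomicModel(atoms=tuple(atoms))


# ---------------------------------------------------------------------------
# Synthetic conformational ensembles

@dataclass(frozen=True)
class KinkSpec:
    """Perturbation injected at a contiguous run of steps in every
    snapshot: a roll offset at the steps, a propeller offset at the base
    pairs they span, and optionally a disrupted (broken) pair signature
    injected as a large opening angle."""

    steps: tuple[int, ...]  # 1-based step indices
    roll: float = -60.0
    propeller: float = 0.0
    broken: bool = False


@dataclass(frozen=True)
class SyntheticEnsemble:
    """A synthetic conformational ensemble: per-snapshot bp-frame paths
    plus the per-strand base frames they were generated from."""

    snapshots: tuple[DuplexPath, ...]
    strand_frames: tuple[tuple[tuple[BpFrame, ...], tuple[BpFrame, ...]], ...]


def _base_frames_from_intra(
    bp_frame: BpFrame, intra: IntraBpParams
) -> tuple[BpFrame, BpFrame]:
    """Split a bp frame into strand-I / strand-II base frames realizing
    the given intra-bp parameters (strand-II frame already in the flipped
    convention), with the bp frame as their mid-frame."""
    v = intra.rotation_deg()
    w = intra.translation()
    t_i = bp_frame.triad @ _rotvec_matrix(-v / 2.0)
    t_ii = bp_frame.triad @ _rotvec_matrix(v / 2.0)
    o_i = bp_frame.origin - bp_frame.triad @ (w / 2.0)
    o_ii = bp_frame.origin + bp_frame.triad @ (w / 2.0)
    f_i = BpFrame(origin=o_i, triad=t_i, bp_id=bp_frame.bp_id, identity=bp_frame.identity)
    f_ii = BpFrame(origin=o_ii, triad=t_ii, bp_id=bp_frame.bp_id, identity=bp_frame.identity)
    return f_i, f_ii


def sample_trajectory(
    n_bp: int,
    n_snapshots: int,
    step_means: StepParams | None = None,
    step_sds: StepParams | None = None,
    intra_means: IntraBpParams | None = None,
    intra_sds: IntraBpParams | None = None,
    kinks: tuple[KinkSpec, ...] = (),
    rng: np.random.Generator | int | None = None,
) -> SyntheticEnsemble:
    """Generate a duplex conformational ensemble with prescribed mean
    helical parameters, independent Gaussian fluctuations per step/bp and
    per snapshot, and optional injected kinks.

    Emulates the statistical structure of an equilibrated trajectory of a
    torsionally relaxed duplex (independent Gaussian excursions of each
    parameter); it does not model inter-step correlations or sequence
    dependence.
    """
    rng = np.random.default_rng(rng)
    step_means = step_means or FORM_STEPS["B"]
    step_sds = step_sds or StepParams(0.3, 0.3, 0.2, 3.0, 5.0, 4.0)
    intra_means = intra_means or IntraBpParams()
    intra_sds = intra_sds or IntraBpParams(0.2, 0.1, 0.3, 5.0, 6.0, 3.0)

    kink_roll = np.zeros(n_bp - 1)
    kink_prop = np.zeros(n_bp)
    kink_open = np.zeros(n_bp)
    for spec in kinks:
        for s in spec.steps:
            if not 1 <= s <= n_bp - 1:
                raise ValueError(f"kink step {s} outside 1..{n_bp - 1}")
            kink_roll[s - 1] += spec.roll
            # a step s spans base pairs s and s+1
            kink_prop[s - 1] += spec.propeller
            kink_prop[s] += spec.propeller
            if spec.broken:
                kink_open[s - 1] = 120.0
                kink_open[s] = 120.0

    mean_t = step_means.translation()
    mean_r = step_means.rotation_deg()
    sd_t = step_sds.translation()
    sd_r = step_sds.rotation_deg()
    imean_t = intra_means.translation()
    imean_r = intra_means.rotation_deg()
    isd_t = intra_sds.translation()
    isd_r = intra_sds.rotation_deg()

    snapshots = []
    strand_frames = []
    for _ in range(n_snapshots):
        frames = [BpFrame(origin=np.zeros(3), triad=np.eye(3), bp_id=1)]
        for k in range(n_bp - 1):
            rot = rng.normal(mean_r, sd_r)
            rot[1] += kink_roll[k]
            trans = rng.normal(mean_t, sd_t)
            step = StepParams.from_arrays(trans, rot)
            frames.append(advance_frame(frames[-1], step))
        path = DuplexPath(frames=tuple(frames), closed=False)

        per_strand: list[tuple[BpFrame, BpFrame]] = []
        for k, bpf in enumerate(frames):
            irot = rng.normal(imean_r, isd_r)
            irot[1] += kink_prop[k]
            irot[2] += kink_open[k]
            itrans = rng.normal(imean_t, isd_t)
            per_strand.append(
                _base_frames_from_intra(
                    bpf, IntraBpParams(*itrans, *irot)
                )
            )
        snapshots.append(path)
        strand_frames.append(
            (tuple(f for f, _ in per_strand), tuple(f for _, f in per_strand))
        )
    return SyntheticEnsemble(
        snapshots=tuple(snapshots), strand_frames=tuple(strand_frames)
    )


def deform_out_of_plane(
    path: DuplexPath,
    amplitude: float,
    n_modes: int = 3,
    rng: np.random.Generator | int | None = None,
) -> DuplexPath:
    """Smoothly deform a closed path out of its plane (no strand passage
    for moderate amplitudes), preserving the material twist of the bp x
    axes about the path: each frame's x axis is re-orthogonalized against
    the new tangent by the minimal rotation taking the old tangent to the
    new one, which does not add or remove twist."""
    if not path.closed:
        raise ValueError("deform_out_of_plane requires a closed path")
    rng = np.random.default_rng(rng)
    n = len(path)
    theta = 2.0 * np.pi * np.arange(n) / n
    dz = np.zeros(n)
    for m in range(1, n_modes + 1):
        a, b = rng.normal(0.0, amplitude, 2)
        dz += a * np.sin(m * theta) + b * np.cos(m * theta)
    origins = path.origins + np.column_stack([np.zeros(n), np.zeros(n), dz])

    new_frames = []
    for k, frame in enumerate(path.frames):
        t_old = frame.z
        t_new = origins[(k + 1) % n] - origins[k - 1]
        t_new = t_new / np.linalg.norm(t_new)
        axis = np.cross(t_old, t_new)
        s = np.linalg.norm(axis)
        c = float(np.dot(t_old, t_new))
        if s < 1e-12:
            rot = np.eye(3)
        else:
            rot = Rotation.from_rotvec(axis / s * np.arctan2(s, c)).as_matrix()
        x_new = rot @ frame.x
        x_new -= np.dot(x_new, t_new) * t_new
        x_new /= np.linalg.norm(x_new)
        y_new = np.cross(t_new, x_new)
        new_frames.append(
            BpFrame(
                origin=origins[k],
                triad=np.column_stack([x_new, y_new, t_new]),
                bp_id=frame.bp_id,
                identity=frame.identity,
            )
        )
    return DuplexPath(frames=tuple(new_frames), closed=True, form_tag=path.form_tag)
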