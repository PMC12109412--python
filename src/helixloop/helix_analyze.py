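"""Extraction of helical parameters from frames and coordinates.

Implements the analysis side of the frame algebra in
:mod:`helixloop.helix_build`:

* :func:`fit_base_frame` — least-squares rigid superposition of an
  idealized base template onto observed base atoms (quaternion-free
  Kabsch/SVD with a proper-rotation constraint), yielding the base
  reference frame;
* :func:`bp_parameters` — the six intra-base-pair parameters (shear,
  stretch, stagger, buckle, propeller, opening) from two paired base
  frames (strand II pre-flipped);
* :func:`step_parameters` — the six base-pair step parameters (shift,
  slide, rise, tilt, roll, twist) from consecutive bp frames;
* :func:`axis_and_helical_params` — local helical axis from the screw
  decomposition of each step transform, and the derived axis parameters
  (Xdisp, Ydisp, inclination, tip) and helical parameters (H-rise,
  H-twist) per bp;
* :func:`parameter_series` / :func:`fluctuation_summary` — parameter
  tables over conformational ensembles and the mean/SD fluctuation
  statistics (with 10-block uncertainty estimates) used to compare two
  constructs.

All rotational decompositions use the mid-frame rotation-vector scheme:
the rotation between two triads is expressed as a single rotation vector
whose components along the mid-frame x, y, z axes are the three angular
parameters.  This scheme is the exact inverse of the builders' step
generator; absolute values can differ from curvilinear-axis programs by
small systematic offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .helix_build import BpFrame, DuplexPath, IntraBpParams, StepParams, mid_frame

__all__ = [
    "FrameFit",
    "BpParameterResult",
    "ParameterTable",
    "FluctuationSummary",
    "fit_base_frame",
    "bp_parameters",
    "step_parameters",
    "step_screw_axis",
    "axis_and_helical_params",
    "parameter_series",
    "fluctuation_summary",
]

INTER_PARAMS = ("shift", "slide", "rise", "tilt", "roll", "twist")
INTRA_PARAMS = ("shear", "stretch", "stagger", "buckle", "propeller", "opening")
AXIS_PARAMS = ("Xdisp", "Ydisp", "inclination", "tip", "H-rise", "H-twist")


@dataclass(frozen=True)
class FrameFit:
    """A fitted base reference frame plus the superposition RMSD."""

    frame: BpFrame
    rmsd: float


def fit_base_frame(
    atoms: dict[str, np.ndarray],
    template: dict[str, np.ndarray],
    bp_id: int = 1,
    identity: str = "G·C",
) -> FrameFit:
    """Fit a base reference frame by rigid superposition of ``template``
    onto ``atoms`` (matched by atom name).

    Solves for the proper rotation R (det +1) and translation t
    minimizing sum ||obs - (R tpl + t)||^2 by SVD of the covariance
    matrix.  The returned frame has triad R and origin t — i.e. the
    template's own frame carried onto the observed base.

    Raises ``ValueError`` when fewer than 3 matched atoms exist, the
    matched template atoms are collinear, or the optimum is a reflection
    (the proper-rotation optimum is qualitatively worse than the improper
    one).
    """
    names = [n for n in template if n in atoms]
    if len(names) < 3:
        raise ValueError(f"need >= 3 matched atoms, got {len(names)}")
    obs = np.array([np.asarray(atoms[n], dtype=float) for n in names])
    tpl = np.array([template[n] for n in names])

    obs_c = obs - obs.mean(axis=0)
    tpl_c = tpl - tpl.mean(axis=0)
    if np.linalg.matrix_rank(tpl_c, tol=1e-8) < 2:
        raise ValueError("template atoms are collinear; frame is undetermined")

    h = tpl_c.T @ obs_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d < 0 and s[-1] > 1e-6 * s[0]:
        raise ValueError(
            "optimal superposition is a reflection; observed base is "
            "mirror-inverted relative to the template"
        )
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = obs.mean(axis=0) - rot @ tpl.mean(axis=0)
    fitted = (rot @ tpl.T).T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - obs) ** 2, axis=1))))
    frame = BpFrame(origin=trans, triad=rot, bp_id=bp_id, identity=identity)
    return FrameFit(frame=frame, rmsd=rmsd)


def _midframe_decomposition(
    frame_i: BpFrame, frame_j: BpFrame
) -> tuple[np.ndarray, np.ndarray, float]:
    """Rotation vector (degrees, mid-frame components) and displacement
    (mid-frame components) from frame_i to frame_j, plus the rotation
    angle magnitude in degrees."""
    r = Rotation.from_matrix(frame_i.triad.T @ frame_j.triad)
    rotvec_deg = np.degrees(r.as_rotvec())
    tm = mid_frame(frame_i.triad, frame_j.triad)
    disp = tm.T @ (frame_j.origin - frame_i.origin)
    return rotvec_deg, disp, float(np.linalg.norm(rotvec_deg))


@dataclass(frozen=True)
class BpParameterResult:
    params: IntraBpParams
    broken: bool


def bp_parameters(frame_i: BpFrame, frame_ii: BpFrame) -> BpParameterResult:
    """Intra-base-pair parameters between two paired base frames.

    ``frame_ii`` must already be in the flipped strand-II convention.
    The rotation from frame I to frame II, decomposed about the mid-frame
    axes, gives (buckle, propeller, opening); the origin displacement in
    the mid-frame gives (shear, stretch, stagger).  A rotation angle of
    90 degrees or more marks the pair as broken (disrupted pairing),
    which feeds kink typing.
    """
    rotvec, disp, angle = _midframe_decomposition(frame_i, frame_ii)
    params = IntraBpParams(
        shear=disp[0],
        stretch=disp[1],
        stagger=disp[2],
        buckle=rotvec[0],
        propeller=rotvec[1],
        opening=rotvec[2],
    )
    return BpParameterResult(params=params, broken=angle >= 90.0)


def step_parameters(bp_frame_i: BpFrame, bp_frame_j: BpFrame) -> StepParams:
    """Base-pair step parameters between consecutive bp frames.

    Exact inverse of :func:`helixloop.helix_build.advance_frame`.
    """
    rotvec, disp, _ = _midframe_decomposition(bp_frame_i, bp_frame_j)
    return StepParams(
        shift=disp[0],
        slide=disp[1],
        rise=disp[2],
        tilt=rotvec[0],
        roll=rotvec[1],
        twist=rotvec[2],
    )


def step_screw_axis(
    bp_frame_i: BpFrame, bp_frame_j: BpFrame
) -> tuple[np.ndarray, np.ndarray, float, float, bool]:
    """Screw decomposition of the lab-frame step transform.

    Returns ``(axis, point, h_twist_deg, h_rise, flagged)``: the unit
    axis direction, a point on the axis (the one closest to the origin's
    perpendicular plane), the rotation about and advance along the axis.
    For a near-zero step rotation the axis degenerates to the translation
    direction and the result is flagged.
    """
    r_lab = bp_frame_j.triad @ bp_frame_i.triad.T
    rot = Rotation.from_matrix(r_lab)
    rotvec = rot.as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    d = bp_frame_j.origin - r_lab @ bp_frame_i.origin
    if angle < 1e-9:
        axis = d / np.linalg.norm(d) if np.linalg.norm(d) > 0 else np.array([0.0, 0.0, 1.0])
        return axis, bp_frame_i.origin.copy(), np.degrees(angle), float(d @ axis), True
    axis = rotvec / angle
    h_rise = float(d @ axis)
    # points p on the axis satisfy (I - R) p = d_perp
    d_perp = d - h_rise * axis
    m = np.vstack([np.eye(3) - r_lab, axis[None, :]])
    b = np.concatenate([d_perp, [0.0]])
    point, *_ = np.linalg.lstsq(m, b, rcond=None)
    return axis, point, float(np.degrees(angle)), h_rise, False


def axis_and_helical_params(path: DuplexPath, window: int = 1) -> pd.DataFrame:
    """Axis parameters (Xdisp, Ydisp, inclination, tip) and helical
    parameters (H-rise, H-twist) per base pair.

    The local helical axis at bp i averages the screw axes of the steps
    within ``window`` steps of i.  Xdisp/Ydisp are the components of the
    bp origin's offset from the axis along the bp x and y axes;
    inclination and tip describe the axis direction in bp coordinates
    (rotation of the bp normal about the bp x and y axes respectively);
    H-twist and H-rise are the screw rotation/advance.  Rows where the
    step rotation was degenerate (straight translation) are flagged.
    """
    n = len(path)
    if n < 3:
        raise ValueError("need >= 3 bp frames to define a local helical axis")
    if window < 1:
        raise ValueError("window must be >= 1")
    steps = path.steps()
    screws = [step_screw_axis(a, b) for a, b in steps]

    rows = []
    n_steps = len(steps)
    for i in range(n):
        if path.closed:
            step_ids = [(i - 1 + k) % n_steps for k in range(-(window - 1), window + 1)]
        else:
            lo = max(0, i - window)
            hi = min(n_steps, i + window)
            step_ids = list(range(lo, hi))
        axes = np.array([screws[j][0] for j in step_ids])
        # keep directions consistent before averaging
        ref = axes[0]
        axes = np.where((axes @ ref)[:, None] < 0, -axes, axes)
        axis = axes.mean(axis=0)
        axis /= np.linalg.norm(axis)
        points = np.array([screws[j][1] for j in step_ids])
        point = points.mean(axis=0)
        h_twist = float(np.mean([screws[j][2] for j in step_ids]))
        h_rise = float(np.mean([screws[j][3] for j in step_ids]))
        flagged = any(screws[j][4] for j in step_ids)

        frame = path.frames[i]
        rel = frame.origin - point
        offset = rel - (rel @ axis) * axis
        u = frame.triad.T @ axis  # axis direction in bp coordinates
        inclination = float(np.degrees(np.arctan2(u[1], u[2])))
        tip = float(np.degrees(np.arctan2(-u[0], np.hypot(u[1], u[2]))))
        rows.append(
            {
                "bp": i + 1,
                "Xdisp": float(offset @ frame.x),
                "Ydisp": float(offset @ frame.y),
                "inclination": inclination,
                "tip": tip,
                "H-rise": h_rise,
                "H-twist": h_twist,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)


def _wrap_angles(df: pd.DataFrame) -> pd.DataFrame:
    return df


@dataclass(frozen=True)
class ParameterTable:
    """Tidy per-snapshot, per-step/bp helical parameter records.

    ``data`` columns: ``snapshot`` (0-based, post-discard), ``kind``
    ("step" | "bp" | "axis"), ``index`` (1-based step or bp id),
    ``parameter``, ``value``.  Broken-pair flags appear as parameter
    ``"broken"`` with value 0/1.  Angles are degrees in (-180, 180],
    lengths Angstrom.
    """

    data: pd.DataFrame
    n_snapshots: int

    def series(self, kind: str, parameter: str) -> pd.DataFrame:
        """Wide snapshot x index matrix for one parameter."""
        sub = self.data[(self.data["kind"] == kind) & (self.data["parameter"] == parameter)]
        if sub.empty:
            raise KeyError(f"no records for kind={kind!r} parameter={parameter!r}")
        return sub.pivot(index="snapshot", columns="index", values="value")

    def parameters(self) -> list[tuple[str, str]]:
        return sorted(
            {(k, p) for k, p in zip(self.data["kind"], self.data["parameter"])}
        )


def parameter_series(
    snapshots: list[DuplexPath],
    strand_frames: list[tuple[tuple[BpFrame, ...], tuple[BpFrame, ...]]] | None = None,
    discard: float = 1.0 / 3.0,
    axis: bool = True,
) -> ParameterTable:
    """Full parameter table over an ordered trajectory of duplex paths.

    ``discard`` is the equilibration fraction removed from the front of
    the trajectory (default one third).  ``strand_frames``, when given,
    supplies per-snapshot (strand-I frames, flipped strand-II frames)
    from which intra-bp parameters and broken-pair flags are computed.
    """
    if not snapshots:
        raise ValueError("empty trajectory")
    n_bp = len(snapshots[0])
    if any(len(s) != n_bp for s in snapshots):
        raise ValueError("snapshots have inconsistent bp counts")
    if not 0.0 <= discard < 1.0:
        raise ValueError("discard fraction must be in [0, 1)")
    start = int(round(discard * len(snapshots)))
    kept = snapshots[start:]
    kept_strands = strand_frames[start:] if strand_frames is not None else None
    if kept_strands is not None and len(strand_frames) != len(snapshots):
        raise ValueError("strand_frames length must match snapshots")

    records = []
    for s_idx, path in enumerate(kept):
        for k, (fi, fj) in enumerate(path.steps()):
            sp = step_parameters(fi, fj)
            for name, value in zip(INTER_PARAMS, (*sp.translation(), *sp.rotation_deg())):
                records.append((s_idx, "step", k + 1, name, float(value)))
        if axis and n_bp >= 3:
            adf = axis_and_helical_params(path)
            for _, row in adf.iterrows():
                for name in AXIS_PARAMS:
                    records.append((s_idx, "axis", int(row["bp"]), name, float(row[name])))
        if kept_strands is not None:
            frames_i, frames_ii = kept_strands[s_idx]
            for k, (fi, fii) in enumerate(zip(frames_i, frames_ii)):
                res = bp_parameters(fi, fii)
                vals = (*res.params.translation(), *res.params.rotation_deg())
                for name, value in zip(INTRA_PARAMS, vals):
                    records.append((s_idx, "bp", k + 1, name, float(value)))
                records.append((s_idx, "bp", k + 1, "broken", float(res.broken)))
    data = pd.DataFrame(
        records, columns=["snapshot", "kind", "index", "parameter", "value"]
    )
    return ParameterTable(data=data, n_snapshots=len(kept))


@dataclass(frozen=True)
class FluctuationSummary:
    """Per-parameter fluctuation statistics of a target ensemble against
    a reference ensemble.

    ``table`` columns: kind, parameter, mean/sd for target and reference
    (maximum-likelihood Gaussian fit, i.e. sample mean and SD pooled over
    steps/bps and snapshots), ``delta_sd`` = sd_target - sd_reference, the
    block-estimate standard error of each SD from ``n_blocks`` equal time
    blocks, ``se_delta_sd`` combining both, and a ``degenerate`` flag for
    constant series.
    """

    table: pd.DataFrame
    n_blocks: int
    blocks_available: bool


def _pooled_stats(
    table: ParameterTable, kind: str, parameter: str, n_blocks: int
) -> tuple[float, float, float, bool]:
    wide = table.series(kind, parameter)
    values = wide.to_numpy().ravel()
    mean = float(values.mean())
    sd = float(values.std(ddof=0))
    if table.n_snapshots >= n_blocks:
        blocks = np.array_split(wide.to_numpy(), n_blocks, axis=0)
        block_sds = np.array([b.std(ddof=0) for b in blocks])
        se_sd = float(block_sds.std(ddof=1) / np.sqrt(n_blocks))
    else:
        se_sd = np.nan
    return mean, sd, se_sd, sd <= 1e-9


def fluctuation_summary(
    table: ParameterTable,
    reference: ParameterTable,
    n_blocks: int = 10,
) -> FluctuationSummary:
    """Compare per-parameter fluctuations of two ensembles.

    Both tables must cover the same (kind, parameter) set.  SD
    uncertainties come from SDs recomputed in ``n_blocks`` equal time
    blocks; when either ensemble has fewer snapshots than blocks the
    block analysis is unavailable and the errors are NaN.
    """
    params = [p for p in table.parameters() if p[1] != "broken"]
    ref_params = [p for p in reference.parameters() if p[1] != "broken"]
    if set(params) != set(ref_params):
        raise ValueError("tables cover different parameter sets")
    rows = []
    blocks_ok = table.n_snapshots >= n_blocks and reference.n_snapshots >= n_blocks
    for kind, name in params:
        m_t, sd_t, se_t, deg_t = _pooled_stats(table, kind, name, n_blocks)
        m_r, sd_r, se_r, deg_r = _pooled_stats(reference, kind, name, n_blocks)
        se_delta = (
            float(np.sqrt(se_t**2 + se_r**2))
            if blocks_ok and not (np.isnan(se_t) or np.isnan(se_r))
            else np.nan
        )
        rows.append(
            {
                "kind": kind,
                "parameter": name,
                "mean": m_t,
                "sd": sd_t,
                "mean_ref": m_r,
                "sd_ref": sd_r,
                "delta_sd": sd_t - sd_r,
                "se_sd": se_t,
                "se_sd_ref": se_r,
                "se_delta_sd": se_delta,
                "degenerate": deg_t or deg_r,
            }
        )
    return FluctuationSummary(
        table=pd.DataFrame(rows), n_blocks=n_blocks, blocks_available=blocks_ok
    )
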