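"""Per-frame core behavioural features from worm skeletons.

Every feature here is a time series over the frames of one trajectory
(NaN on invalid frames): morphology (length, widths, area, best-fit-ellipse
axes, quirkiness), posture (segment curvature, eigenworm amplitudes),
velocities (signed segment speeds, angular velocities, velocities of one
body point relative to another) and path descriptors (path curvature,
coverage, dispersion).  Motion state (forward / backward / paused) is
classified from the signed midbody speed.

Conventions that the underlying study leaves open are documented in
docs/methods.md: body segments are equal fifths of the skeleton points,
segment curvature is the mean pointwise curvature over the segment, and
the dorsoventral sign is applied only when the ventral side is annotated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .io import WormTrajectory

SEGMENT_NAMES = ("head", "neck", "midbody", "hips", "tail")
POINT_ANCHORS = ("head_tip", "head_base", "tail_base", "tail_tip")

#: default analysis parameters (windows in seconds, thresholds in body lengths/s)
DEFAULT_PARAMS = {
    "velocity_window": 0.5,
    "path_window": 1.0,
    "coverage_window": 10.0,
    "coverage_cell_um": 50.0,
    "fwd_threshold_bl": 0.05,
    "pause_threshold_bl": 0.01,
    "min_bout_duration": 0.5,
    "n_eigenworms": 7,
}


@dataclass
class CoreSeries:
    """One per-frame feature series.

    ``signed`` marks series whose sign is meaningful (speed direction,
    bend direction); ``dorsoventral`` marks the subset whose sign depends on
    knowing which side of the worm is ventral.
    """

    name: str
    values: np.ndarray
    units: str
    signed: bool = False
    dorsoventral: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class MotionStateSeries:
    """Per-frame locomotion state: forward, backward, paused or undefined."""

    states: np.ndarray  # array of strings

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype="<U9")

    def fraction(self, state: str) -> float:
        defined = self.states != "undefined"
        if not defined.any():
            return np.nan
        return float(np.mean(self.states[defined] == state))


@dataclass
class BodySegmentMap:
    """Partition of the P skeleton points into five contiguous fifths.

    When P is not divisible by five the midbody gets the smallest share so
    the map stays symmetric about the body centre (head/tail first, then
    neck/hips).  ``head_base`` is the single boundary point between the head
    and neck fifths, ``tail_base`` the boundary between hips and tail.
    """

    n_points: int
    ranges: dict[str, range] = field(init=False)
    head_base: int = field(init=False)
    tail_base: int = field(init=False)

    def __post_init__(self) -> None:
        p = self.n_points
        if p < 5:
            raise ValueError("need at least 5 skeleton points")
        sizes = {name: p // 5 for name in SEGMENT_NAMES}
        for name in ("head", "tail", "neck", "hips", "midbody")[: p % 5]:
            sizes[name] += 1
        start = 0
        self.ranges = {}
        for name in SEGMENT_NAMES:
            self.ranges[name] = range(start, start + sizes[name])
            start += sizes[name]
        assert start == p
        self.head_base = self.ranges["neck"].start
        self.tail_base = self.ranges["tail"].start

    def indices(self, segment: str) -> np.ndarray:
        return np.asarray(self.ranges[segment])

    def anchor_positions(self, skeleton: np.ndarray) -> dict[str, np.ndarray]:
        """(T, 2) position per named anchor: tips/bases are points, segments
        and ``body`` are centroids."""
        out = {
            "head_tip": skeleton[:, 0],
            "tail_tip": skeleton[:, -1],
            "head_base": skeleton[:, self.head_base],
            "tail_base": skeleton[:, self.tail_base],
            "body": skeleton.mean(axis=1),
        }
        for name in SEGMENT_NAMES:
            out[name] = skeleton[:, self.indices(name)].mean(axis=1)
        return out


def _valid_mask(traj: WormTrajectory) -> np.ndarray:
    return np.asarray(traj.frame_valid, dtype=bool)


def _nan_like(traj: WormTrajectory) -> np.ndarray:
    return np.full(traj.n_frames, np.nan)


# ---------------------------------------------------------------------------
# morphology


def compute_length(traj: WormTrajectory) -> CoreSeries:
    """Arc length of the skeleton: sum of consecutive point distances (um)."""
    seg = np.linalg.norm(np.diff(traj.skeleton, axis=1), axis=2)
    values = seg.sum(axis=1)
    values[~_valid_mask(traj)] = np.nan
    return CoreSeries("length", values, "um")


def compute_area(traj: WormTrajectory) -> CoreSeries:
    """Plan-view body area: width profile integrated along the midline (um^2)."""
    if traj.widths is None:
        return CoreSeries("area", _nan_like(traj), "um^2")
    seg = np.linalg.norm(np.diff(traj.skeleton, axis=1), axis=2)
    s = np.concatenate([np.zeros((traj.n_frames, 1)), np.cumsum(seg, axis=1)], axis=1)
    values = np.trapezoid(traj.widths, s, axis=1)
    values[~_valid_mask(traj)] = np.nan
    return CoreSeries("area", values, "um^2")


def compute_widths(traj: WormTrajectory, segmap: BodySegmentMap) -> dict[str, CoreSeries]:
    """Mean body width per segment plus the width at the head-base point (um)."""
    out: dict[str, CoreSeries] = {}
    invalid = ~_valid_mask(traj)
    for name in SEGMENT_NAMES + ("head_base",):
        if traj.widths is None:
            values = _nan_like(traj)
        elif name == "head_base":
            values = traj.widths[:, segmap.head_base].copy()
        else:
            values = traj.widths[:, segmap.indices(name)].mean(axis=1)
        values[invalid] = np.nan
        out[name] = CoreSeries(f"width_{name}", values, "um")
    return out


def compute_axes_and_quirkiness(traj: WormTrajectory) -> dict[str, CoreSeries]:
    """Best-fit-ellipse axes from the second moments of the skeleton points.

    Axis lengths follow the solid-ellipse convention (full axis = 4 sqrt(
    eigenvalue of the point covariance)); quirkiness is the eccentricity
    sqrt(1 - minor^2 / major^2), 0 for a circle and 1 for a line.
    """
    T = traj.n_frames
    major = np.full(T, np.nan)
    minor = np.full(T, np.nan)
    quirk = np.full(T, np.nan)
    valid = _valid_mask(traj)
    pts = traj.skeleton
    centred = pts - pts.mean(axis=1, keepdims=True)
    # per-frame 2x2 covariance eigenvalues in closed form
    xx = np.mean(centred[:, :, 0] ** 2, axis=1)
    yy = np.mean(centred[:, :, 1] ** 2, axis=1)
    xy = np.mean(centred[:, :, 0] * centred[:, :, 1], axis=1)
    tr, det = xx + yy, xx * yy - xy**2
    disc = np.sqrt(np.maximum(tr**2 / 4 - det, 0.0))
    lam1 = tr / 2 + disc
    lam2 = np.maximum(tr / 2 - disc, 0.0)
    ok = valid & (lam1 > 0)
    major[ok] = 4.0 * np.sqrt(lam1[ok])
    minor[ok] = 4.0 * np.sqrt(lam2[ok])
    quirk[ok] = np.sqrt(1.0 - lam2[ok] / lam1[ok])
    return {
        "major_axis": CoreSeries("major_axis", major, "um"),
        "minor_axis": CoreSeries("minor_axis", minor, "um"),
        "quirkiness": CoreSeries("quirkiness", quirk, ""),
    }


# ---------------------------------------------------------------------------
# curvature


def _smooth_window(n_points: int) -> int:
    """Savitzky-Golay window spanning roughly 1/12 of the body."""
    w = max(5, int(round(n_points / 12)))
    return w + 1 if w % 2 == 0 else w


def pointwise_curvature(skeleton_frame: np.ndarray) -> np.ndarray:
    """Signed curvature (1/um) at every skeleton point of one frame.

    Tangent angles come from locally smoothed coordinates and are
    differenced with respect to arc length; the geometric sign is positive
    for counterclockwise bending in the coordinate frame.
    """
    p = skeleton_frame.shape[0]
    if not np.isfinite(skeleton_frame).all():
        return np.full(p, np.nan)
    w = _smooth_window(p)
    x = savgol_filter(skeleton_frame[:, 0], w, polyorder=3)
    y = savgol_filter(skeleton_frame[:, 1], w, polyorder=3)
    ds = np.hypot(np.diff(x), np.diff(y))
    if np.any(ds <= 0):
        return np.full(p, np.nan)
    s = np.concatenate([[0.0], np.cumsum(ds)])
    dx = np.gradient(x, s)
    dy = np.gradient(y, s)
    phi = np.unwrap(np.arctan2(dy, dx))
    return np.gradient(phi, s)


def _dv_sign(traj: WormTrajectory) -> float:
    # positive = ventral bend; the geometric (counterclockwise) sign is kept
    # when the ventral side is the worm's left and flipped when right
    return -1.0 if traj.ventral_side == "right" else 1.0


def compute_curvature(
    traj: WormTrajectory, segmap: BodySegmentMap
) -> dict[str, CoreSeries]:
    """Mean signed curvature per body segment (1/um)."""
    T = traj.n_frames
    curv = np.full((T, traj.n_points), np.nan)
    for t in np.flatnonzero(_valid_mask(traj)):
        curv[t] = pointwise_curvature(traj.skeleton[t])
    curv *= _dv_sign(traj)
    out = {}
    for name in SEGMENT_NAMES:
        values = curv[:, segmap.indices(name)].mean(axis=1)
        out[name] = CoreSeries(
            f"curvature_{name}", values, "1/um", signed=True, dorsoventral=True
        )
    return out


# ---------------------------------------------------------------------------
# velocities


def _window_frames(traj: WormTrajectory, window: float) -> int:
    return max(1, int(round(window * traj.fps / 2)))


def _central_diff(values: np.ndarray, times: np.ndarray, h: int) -> np.ndarray:
    """Central difference over +-h frames; NaN at the edges."""
    out = np.full(values.shape, np.nan)
    if values.shape[0] <= 2 * h:
        return out
    num = values[2 * h :] - values[: -2 * h]
    den = times[2 * h :] - times[: -2 * h]
    if values.ndim == 2:
        den = den[:, None]
    out[h:-h] = num / den
    return out


def _position_derivative(
    traj: WormTrajectory, pos: np.ndarray, h: int
) -> np.ndarray:
    """(T, 2) velocity of a point track; NaN where either endpoint is invalid."""
    vel = _central_diff(pos, traj.timestamps, h)
    valid = _valid_mask(traj)
    ok = np.zeros(traj.n_frames, dtype=bool)
    if traj.n_frames > 2 * h:
        ok[h:-h] = valid[2 * h :] & valid[: -2 * h]
    vel[~ok] = np.nan
    return vel


def _mean_tangent_angle(traj: WormTrajectory, indices: np.ndarray) -> np.ndarray:
    """Orientation (rad) of the mean tangent of a run of skeleton points."""
    lo, hi = indices.min(), indices.max()
    if hi == lo:
        hi = min(lo + 1, traj.n_points - 1)
    vec = traj.skeleton[:, lo:hi + 1][:, -1] - traj.skeleton[:, lo:hi + 1][:, 0]
    ang = np.arctan2(vec[:, 1], vec[:, 0])
    return ang


def _unwrap_with_nan(ang: np.ndarray) -> np.ndarray:
    out = np.full_like(ang, np.nan)
    ok = np.isfinite(ang)
    if ok.sum() >= 2:
        out[ok] = np.unwrap(ang[ok])
    return out


def compute_velocity(
    traj: WormTrajectory, segmap: BodySegmentMap, window: float = 0.5
) -> dict[str, CoreSeries]:
    """Signed speed and angular velocity at each segment and both tips.

    Speed is the displacement of the anchor over the window divided by
    elapsed time, signed positive when motion is head-ward (aligned with the
    tail-to-head body axis).  Angular velocity is the rotation rate of the
    anchor's local tangent direction.
    """
    h = _window_frames(traj, window)
    anchors = segmap.anchor_positions(traj.skeleton)
    # tail-to-head body axis per frame
    axis = traj.skeleton[:, 0] - traj.skeleton[:, -1]
    norm = np.linalg.norm(axis, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        axis = axis / norm
    out: dict[str, CoreSeries] = {}
    for name in SEGMENT_NAMES + ("head_tip", "tail_tip"):
        vel = _position_derivative(traj, anchors[name], h)
        speed = np.linalg.norm(vel, axis=1)
        sign = np.sign(np.sum(vel * axis, axis=1))
        sign[sign == 0] = 1.0
        out[f"speed_{name}"] = CoreSeries(
            f"speed_{name}", speed * sign, "um/s", signed=True
        )
    for name in SEGMENT_NAMES + ("head_tip", "tail_tip"):
        if name == "head_tip":
            idx = np.arange(0, 2)
        elif name == "tail_tip":
            idx = np.arange(traj.n_points - 2, traj.n_points)
        else:
            idx = segmap.indices(name)
        ang = _unwrap_with_nan(_mean_tangent_angle(traj, idx))
        ang[~_valid_mask(traj)] = np.nan
        omega = _central_diff(ang, traj.timestamps, h)
        out[f"angular_velocity_{name}"] = CoreSeries(
            f"angular_velocity_{name}", omega, "rad/s", signed=True, dorsoventral=True
        )
    return out


def compute_relative_velocity(
    traj: WormTrajectory,
    segmap: BodySegmentMap,
    moving: str,
    reference: str,
    window: float = 0.5,
) -> dict[str, CoreSeries]:
    """Radial and angular velocity of ``moving`` in the frame of ``reference``.

    Radial velocity (um/s) is the rate of change of the distance between the
    two anchors (positive = moving away); angular velocity (rad/s) is the
    rate of change of the bearing of the moving anchor about the reference.
    """
    h = _window_frames(traj, window)
    anchors = segmap.anchor_positions(traj.skeleton)
    rel = anchors[moving] - anchors[reference]
    dist = np.linalg.norm(rel, axis=1)
    dist[dist < 1e-9] = np.nan  # coincident anchors: bearing undefined
    bearing = _unwrap_with_nan(np.arctan2(rel[:, 1], rel[:, 0]))
    valid = _valid_mask(traj)
    dist[~valid] = np.nan
    bearing[~valid] = np.nan
    radial = _central_diff(dist, traj.timestamps, h)
    angular = _central_diff(bearing, traj.timestamps, h)
    stem = f"relative_to_{reference}"
    return {
        "radial": CoreSeries(
            f"{stem}_radial_velocity_{moving}", radial, "um/s", signed=True
        ),
        "angular": CoreSeries(
            f"{stem}_angular_velocity_{moving}",
            angular,
            "rad/s",
            signed=True,
            dorsoventral=True,
        ),
    }


#: the 12 (reference, moving) anchor pairs of the default inventory
RELATIVE_VELOCITY_PAIRS = (
    ("body", "head_tip"),
    ("body", "head_base"),
    ("body", "neck"),
    ("body", "hips"),
    ("body", "tail_base"),
    ("body", "tail_tip"),
    ("head_base", "head_tip"),
    ("neck", "head_tip"),
    ("midbody", "head_tip"),
    ("midbody", "tail_tip"),
    ("hips", "tail_tip"),
    ("tail_base", "tail_tip"),
)


# ---------------------------------------------------------------------------
# motion state


def _runs(labels: np.ndarray) -> list[tuple[int, int, str]]:
    """(start, stop, label) runs of equal consecutive labels."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((start, i, labels[start]))
            start = i
    return runs


def classify_motion_state(
    speed: CoreSeries,
    fps: float,
    fwd_threshold: float,
    pause_threshold: float,
    min_duration: float = 0.5,
) -> MotionStateSeries:
    """Forward / backward / paused classification of a signed speed series.

    Thresholds are in um/s (callers working in body lengths per second
    convert first).  Between ``pause_threshold`` and ``fwd_threshold`` lies a
    hysteresis band that keeps the previous state; bouts shorter than
    ``min_duration`` are merged into their neighbours.
    """
    v = np.asarray(speed.values, dtype=float).copy()
    n = v.size
    # light smoothing over the bout timescale
    w = max(1, int(round(min_duration * fps / 2)) * 2 + 1)
    if w > 1 and n >= w:
        kernel = np.ones(w) / w
        finite = np.isfinite(v)
        vs = np.where(finite, v, 0.0)
        norm = np.convolve(finite.astype(float), kernel, mode="same")
        sm = np.convolve(vs, kernel, mode="same")
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(norm > 0.5, sm / np.maximum(norm, 1e-12), np.nan)
    labels = np.full(n, "undefined", dtype="<U9")
    defined = np.isfinite(v)
    labels[defined & (v > fwd_threshold)] = "forward"
    labels[defined & (v < -fwd_threshold)] = "backward"
    labels[defined & (np.abs(v) < pause_threshold)] = "paused"
    hyst = defined & (labels == "undefined")
    # hysteresis: carry the previous decided state through the band
    last = None
    for i in range(n):
        if hyst[i]:
            if last is not None:
                labels[i] = last
        elif labels[i] != "undefined":
            last = labels[i]
    # leading band frames inherit the first decided state
    first = next((l for l in labels if l != "undefined"), None)
    for i in range(n):
        if hyst[i] and labels[i] == "undefined" and first is not None:
            labels[i] = first
        elif labels[i] != "undefined":
            break
    # merge short bouts into the preceding (else following) neighbour
    min_frames = max(1, int(round(min_duration * fps)))
    changed = True
    while changed:
        changed = False
        runs = [r for r in _runs(labels) if r[2] != "undefined"]
        for k, (start, stop, lab) in enumerate(runs):
            if stop - start < min_frames and len(runs) > 1:
                if k > 0:
                    labels[start:stop] = runs[k - 1][2]
                else:
                    labels[start:stop] = runs[k + 1][2]
                changed = True
                break
    return MotionStateSeries(labels)


# ---------------------------------------------------------------------------
# eigenworms


def default_eigenworm_basis(n_points: int = 48, n_modes: int = 7) -> np.ndarray:
    """Synthetic orthonormal postural basis (n_modes x n_points).

    Orthonormalized sinusoids of increasing spatial frequency over the body
    coordinate, standing in for an experimentally derived eigenworm basis.
    The published basis can be supplied instead via a CSV of tangent-angle
    loadings (rows = modes).  Modes are mean-free, like any basis derived
    from mean-subtracted tangent-angle profiles.
    """
    x = (np.arange(n_points) + 0.5) / n_points
    cols = np.stack([np.sin(np.pi * (k + 1) * x) for k in range(n_modes)], axis=1)
    cols -= cols.mean(axis=0, keepdims=True)
    q, r = np.linalg.qr(cols)
    # fix the sign so each mode starts positive
    signs = np.sign(r.diagonal())
    signs[signs == 0] = 1.0
    return (q * signs).T


def load_eigenworm_basis(path) -> np.ndarray:
    basis = np.loadtxt(path, delimiter=",", ndmin=2)
    if basis.ndim != 2:
        raise ValueError("eigenworm basis must be a 2-D CSV (modes x points)")
    return basis


def tangent_angles(skeleton: np.ndarray) -> np.ndarray:
    """(T, P-1) tangent angle profile of each frame."""
    d = np.diff(skeleton, axis=1)
    return np.arctan2(d[:, :, 1], d[:, :, 0])


def compute_eigen_projections(
    traj: WormTrajectory, basis: np.ndarray | None = None
) -> list[CoreSeries]:
    """Amplitudes of the mean-subtracted tangent-angle profile on each mode."""
    if basis is None:
        basis = default_eigenworm_basis(traj.n_points - 1)
    basis = np.asarray(basis, dtype=float)
    theta = tangent_angles(traj.skeleton)
    if theta.shape[1] != basis.shape[1]:
        if basis.shape[1] < 2:
            raise ValueError(
                f"eigenworm basis has {basis.shape[1]} points; "
                f"trajectory provides {theta.shape[1]} tangent angles"
            )
        src = np.linspace(0.0, 1.0, theta.shape[1])
        dst = np.linspace(0.0, 1.0, basis.shape[1])
        theta = np.stack([np.interp(dst, src, row) for row in theta])
        # resampling changes the norm; keep projections comparable
        theta *= np.sqrt(theta.shape[1] / len(src))
    theta = np.unwrap(theta, axis=1)
    theta = theta - np.nanmean(theta, axis=1, keepdims=True)
    amps = theta @ basis.T * _dv_sign(traj)
    amps[~_valid_mask(traj)] = np.nan
    return [
        CoreSeries(
            f"eigen_projection_{k + 1}",
            amps[:, k],
            "",
            signed=True,
            dorsoventral=True,
        )
        for k in range(basis.shape[0])
    ]


# ---------------------------------------------------------------------------
# path


def _moving_average(values: np.ndarray, w: int) -> np.ndarray:
    t = values.shape[0]
    w = min(w, t if t % 2 else t - 1)  # largest odd window that fits
    if w <= 1:
        return values
    kernel = np.ones(w) / w
    out = values.copy()
    for j in range(values.shape[1]):
        col = values[:, j]
        finite = np.isfinite(col)
        sm = np.convolve(np.where(finite, col, 0.0), kernel, mode="same")
        norm = np.convolve(finite.astype(float), kernel, mode="same")
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, j] = np.where(norm > 0, sm / np.maximum(norm, 1e-12), np.nan)
    return out


def compute_path_features(
    traj: WormTrajectory,
    segmap: BodySegmentMap,
    window: float = 1.0,
    coverage_window: float = 10.0,
    cell_size: float = 50.0,
    stationary_speed: float = 2.0,
) -> dict[str, CoreSeries]:
    """Path curvature of the smoothed centroid track plus windowed coverage
    and dispersion.

    Path curvature (1/um) is undefined (NaN) where the centroid moves slower
    than ``stationary_speed`` um/s.  Coverage is the area (um^2) of distinct
    ``cell_size`` grid cells visited by an anchor within non-overlapping
    ``coverage_window`` windows; dispersion is the radius of gyration (um) of
    the centroid positions within each window.  Both are step-wise series so
    they can be summarized like any other per-frame feature.
    """
    T = traj.n_frames
    valid = _valid_mask(traj)
    anchors = segmap.anchor_positions(traj.skeleton)
    centroid = anchors["body"].copy()
    centroid[~valid] = np.nan
    w = max(1, int(round(window * traj.fps)) | 1)
    sm = _moving_average(centroid, w)
    h = _window_frames(traj, window)
    vel = _central_diff(sm, traj.timestamps, h)
    acc = _central_diff(vel, traj.timestamps, h)
    speed = np.linalg.norm(vel, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa = (vel[:, 0] * acc[:, 1] - vel[:, 1] * acc[:, 0]) / speed**3
    kappa[~np.isfinite(speed) | (speed < stationary_speed)] = np.nan
    out = {
        "path_curvature": CoreSeries(
            "path_curvature", kappa, "1/um", signed=True, dorsoventral=True
        )
    }

    win_frames = max(1, int(round(coverage_window * traj.fps)))
    starts = np.arange(0, T, win_frames)

    def _stepwise(fn) -> np.ndarray:
        vals = np.full(T, np.nan)
        for s in starts:
            e = min(s + win_frames, T)
            vals[s:e] = fn(s, e)
        return vals

    for name in SEGMENT_NAMES + ("body",):
        pos = anchors[name]

        def _coverage(s: int, e: int, pos=pos) -> float:
            pts = pos[s:e][valid[s:e]]
            if len(pts) == 0:
                return np.nan
            cells = np.unique(np.floor(pts / cell_size), axis=0)
            return len(cells) * cell_size**2

        out[f"path_coverage_{name}"] = CoreSeries(
            f"path_coverage_{name}", _stepwise(_coverage), "um^2"
        )

    def _dispersion(s: int, e: int) -> float:
        pts = centroid[s:e][valid[s:e]]
        if len(pts) == 0:
            return np.nan
        return float(np.sqrt(np.mean(np.sum((pts - pts.mean(axis=0)) ** 2, axis=1))))

    out["dispersion"] = CoreSeries("dispersion", _stepwise(_dispersion), "um")
    return out
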