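"""Occlusal-plane reorientation and dental metric extraction.

Metrics are measured in the mid-sagittal plane of each incisor after the
volume has been rotated so the best-fit plane through the molar cusps is
horizontal.  Landmark operators (documented choices, overridable by
supplying landmarks explicitly):

* alveolus edge - intersection of the incisor outline with the alveolar
  bone level, on the labial (larger-y) side; the bone level is the top of
  the bone mask adjacent to the incisor;
* tip and gnaw ridge - the two strongest curvature corners on the erupted
  outline, the tip being the one nearer the labial end; corner positions
  are refined by intersecting line fits on either flank so that contour
  smoothing does not shorten the measured paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure

from .imagecore import Volume
from .register import apply_transform
from .transforms import RigidTransform, from_matrix

SURFACES = ("labial", "lingual", "occlusal")


@dataclass(frozen=True)
class Plane:
    point: tuple[float, float, float]
    normal: tuple[float, float, float]

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or norm == 0:
            raise ValueError("plane normal must be nonzero")
        object.__setattr__(self, "normal", tuple(n / norm))
        object.__setattr__(self, "point", tuple(float(p) for p in self.point))

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, dtype=float) - np.asarray(self.point)) @ np.asarray(
            self.normal
        )


@dataclass
class SagittalProfile:
    """Ordered outline of one incisor's erupted crown in its mid-sagittal plane.

    ``points`` is an (N, 2) array of (y, z) mm coordinates running from the
    labial alveolus edge over the tip and gnaw ridge to the lingual
    alveolus edge.  ``landmarks`` maps landmark names to point indices.
    """

    side: str
    points: np.ndarray
    landmarks: dict
    slice_x_mm: float = 0.0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 2:
            raise ValueError("profile needs at least 2 planar points")
        order = [self.landmarks.get(k) for k in
                 ("alveolus_edge", "tip", "gnaw_ridge", "lingual_alveolus_edge")
                 if self.landmarks.get(k) is not None]
        if order != sorted(order):
            raise ValueError(f"landmark indices out of order: {self.landmarks}")

    def arc_length(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def to_dict(self) -> dict:
        return {
            "side": self.side,
            "points_mm": self.points.tolist(),
            "landmarks": {k: int(v) for k, v in self.landmarks.items()},
            "slice_x_mm": self.slice_x_mm,
        }


@dataclass(frozen=True)
class IncisorMetrics:
    side: str
    labial_mm: float
    lingual_mm: float | None = None
    occlusal_mm: float | None = None
    occlusal_angle_deg: float | None = None
    timepoint: str = "baseline"

    def __post_init__(self):
        for name in ("labial_mm", "lingual_mm", "occlusal_mm"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CheekToothHeight:
    tooth_label: str
    side: str
    height_mm: float
    timepoint: str = "baseline"

    def __post_init__(self):
        if self.height_mm < -1e-9:
            raise ValueError("height must be >= 0")


# ---------------------------------------------------------------------------
# Occlusal plane
# ---------------------------------------------------------------------------


def fit_occlusal_plane(points: np.ndarray) -> Plane:
    """Total-least-squares plane through 3D points, normal oriented dorsally."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValueError("need at least 3 three-dimensional points")
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid)
    if len(pts) > 2 and s[1] < 1e-9 * max(s[0], 1e-300):
        raise ValueError("points are collinear: plane is degenerate")
    normal = vt[2]
    if normal[2] < 0:
        normal = -normal
    elif normal[2] == 0:
        raise ValueError("degenerate occlusal plane is vertical")
    return Plane(tuple(centroid), tuple(normal))


def molar_cusp_points(tooth_mask: Volume, n_incisors: int = 2,
                      min_volume_mm3: float = 0.5) -> np.ndarray:
    """One cusp point per molar: centroid of each molar's top voxel layer.

    Molar components are all tooth components except the ``n_incisors``
    largest (the incisors dominate by volume in both species); speckle
    components below ``min_volume_mm3`` (stray noise voxels) are ignored.
    """
    labels, n, counts, _, _ = _component_stats(tooth_mask)
    if n <= n_incisors:
        raise ValueError(f"expected molars besides {n_incisors} incisors, found {n} components")
    counts = counts.copy()
    counts[0] = 0
    min_voxels = max(2, int(np.ceil(min_volume_mm3 / tooth_mask.voxel_volume())))
    incisor_labels = set(np.argsort(counts)[::-1][:n_incisors])
    pts = []
    for lab in range(1, n + 1):
        if lab in incisor_labels or counts[lab] < min_voxels:
            continue
        idx = np.argwhere(labels == lab)
        top = idx[:, 2].max()
        layer = idx[idx[:, 2] == top]
        center = layer.mean(axis=0)
        pts.append(tooth_mask.index_to_physical(center))
    return np.asarray(pts)


def occlusal_rotation(plane: Plane, tol_deg: float = 0.05) -> RigidTransform:
    """Rotation mapping the plane normal to +z about the plane point.

    Identity if the plane is already horizontal within ``tol_deg``.
    """
    n = np.asarray(plane.normal)
    z = np.array([0.0, 0.0, 1.0])
    cosang = float(np.clip(n @ z, -1.0, 1.0))
    angle = np.arccos(cosang)
    if np.degrees(angle) < tol_deg:
        return RigidTransform(center_mm=plane.point)
    axis = np.cross(n, z)
    axis = axis / np.linalg.norm(axis)
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
    return from_matrix(rot, (0.0, 0.0, 0.0), center=plane.point)


def reorient_to_occlusal(volume: Volume, plane: Plane,
                         interpolation: str = "linear",
                         tol_deg: float = 0.05):
    """Rotate so the occlusal plane normal maps to +z, about the plane point.

    Returns ``(reoriented Volume, RigidTransform used)``.  If the plane is
    horizontal within ``tol_deg`` the identity is returned unresampled.
    """
    t = occlusal_rotation(plane, tol_deg)
    if t.is_identity:
        return volume.copy(), t
    return apply_transform(volume, t, volume, interpolation=interpolation), t


# ---------------------------------------------------------------------------
# Sagittal profile
# ---------------------------------------------------------------------------


def _component_stats(tooth_mask: Volume):
    """Label the tooth mask; per-label voxel counts and x/y centroids.

    Vectorized with bincount: noisy masks can carry thousands of speckle
    labels and any per-label full-volume scan is quadratic.
    """
    labels, n = ndimage.label(
        np.asarray(tooth_mask.data) > 0, structure=ndimage.generate_binary_structure(3, 1)
    )
    xs = tooth_mask.axis_coords(0)
    ys = tooth_mask.axis_coords(1)
    counts = np.zeros(n + 1, dtype=np.int64)
    xsum = np.zeros(n + 1)
    ysum = np.zeros(n + 1)
    # slab-wise accumulation keeps memory flat on large grids
    for i in range(labels.shape[0]):
        c = np.bincount(labels[i].ravel(), minlength=n + 1)
        counts += c
        xsum += c * xs[i]
    for j in range(labels.shape[1]):
        c = np.bincount(labels[:, j].ravel(), minlength=n + 1)
        ysum += c * ys[j]
    with np.errstate(invalid="ignore"):
        cx = xsum / counts
        cy = ysum / counts
    return labels, n, counts, cx, cy


def _incisor_component(tooth_mask: Volume, side: str) -> np.ndarray:
    labels, n, counts, cx, _ = _component_stats(tooth_mask)
    if n == 0:
        raise ValueError(f"no tooth components found for side {side!r}")
    want = -1 if side == "left" else 1
    on_side = np.where(np.sign(cx[1:]) == want)[0] + 1
    if len(on_side) == 0:
        raise ValueError(f"no incisor component found on the {side} side")
    best = on_side[np.argmax(counts[on_side])]
    if counts[best] < 8:
        raise ValueError(f"no incisor component found on the {side} side")
    return labels == best


def _alveolus_level(bone_mask: Volume, component: np.ndarray) -> float:
    """Top of the bulk bone adjacent to the incisor, as a physical z (mm).

    The bone mask is eroded by one voxel first: partial-volume voxels in
    resampled scans threshold into a one-voxel bone shell wrapping the
    erupted crown, which must not drag the alveolus level up to the tip.
    The erosion offset is compensated in the returned level.
    """
    struct = ndimage.generate_binary_structure(3, 1)
    bulk = ndimage.binary_erosion(np.asarray(bone_mask.data) > 0, struct, border_value=0)
    near = ndimage.binary_dilation(component, struct, iterations=3)
    adjacent = bulk & near
    if not adjacent.any():
        raise ValueError("no bone adjacent to the incisor: cannot place alveolus edge")
    top = int(np.argwhere(adjacent)[:, 2].max())
    return bone_mask.origin[2] + bone_mask.spacing[2] * (top + 1.5)


def _turning_angles(pts: np.ndarray, k: int) -> np.ndarray:
    """Absolute turning angle at each vertex over a +/-k window (rad)."""
    n = len(pts)
    ang = np.zeros(n)
    for i in range(k, n - k):
        v1 = pts[i] - pts[i - k]
        v2 = pts[i + k] - pts[i]
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 == 0 or n2 == 0:
            continue
        c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
        ang[i] = np.arccos(c)
    return ang


def _fit_line(pts: np.ndarray):
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[0]


def _line_intersection(p1, d1, p2, d2) -> np.ndarray:
    a = np.array([[d1[0], -d2[0]], [d1[1], -d2[1]]])
    if abs(np.linalg.det(a)) < 1e-12:
        return (p1 + p2) / 2
    s, _ = np.linalg.solve(a, p2 - p1)
    return p1 + s * d1


def _refine_corner(chain: np.ndarray, i: int, k: int) -> np.ndarray:
    """Corner apex as intersection of line fits on the two flanks."""
    lo = max(0, i - 3 * k)
    hi = min(len(chain), i + 3 * k + 1)
    before = chain[lo:max(lo + 2, i - k + 1)]
    after = chain[min(i + k, hi - 2):hi]
    if len(before) < 2 or len(after) < 2:
        return chain[i]
    p1, d1 = _fit_line(before)
    p2, d2 = _fit_line(after)
    apex = _line_intersection(p1, d1, p2, d2)
    if np.linalg.norm(apex - chain[i]) > 4 * k * np.linalg.norm(chain[1] - chain[0]):
        return chain[i]  # near-parallel flanks: keep the raw vertex
    return apex


class _IncrementalLine:
    """Total-least-squares 2D line with O(1) point insertion."""

    def __init__(self):
        self.n = 0
        self.sx = self.sy = self.sxx = self.sxy = self.syy = 0.0

    def add(self, p) -> None:
        x, y = float(p[0]), float(p[1])
        self.n += 1
        self.sx += x
        self.sy += y
        self.sxx += x * x
        self.sxy += x * y
        self.syy += y * y

    def line(self):
        mx, my = self.sx / self.n, self.sy / self.n
        cxx = self.sxx / self.n - mx * mx
        cxy = self.sxy / self.n - mx * my
        cyy = self.syy / self.n - my * my
        # principal eigenvector of the 2x2 covariance
        tr, det = cxx + cyy, cxx * cyy - cxy * cxy
        lam = tr / 2 + np.sqrt(max(tr * tr / 4 - det, 0.0))
        d = np.array([cxy, lam - cxx])
        norm = np.linalg.norm(d)
        if norm < 1e-14:
            d = np.array([1.0, 0.0]) if cxx >= cyy else np.array([0.0, 1.0])
        else:
            d = d / norm
        return np.array([mx, my]), d


def _locate_ridge(chain: np.ndarray, arc: np.ndarray, i_tip: int, step: float):
    """Gnaw ridge = departure of the contour from the occlusal facet line.

    The facet is straight from the tip to the ridge while the lingual
    surface curves away at a finite (possibly shallow) dihedral, so the
    ridge is found as the first sustained deviation from the facet line
    fit and then refined as the intersection of the facet line with a
    line fit on the lingual flank.  More robust than curvature maxima for
    shallow facet-to-lingual angles.
    """
    s_tip = arc[i_tip]
    after = arc - s_tip
    # window bounds scale with the contour step (~1 voxel): the slice
    # smoothing rounds corners over ~3 sigma voxels, which must be skipped
    seed_lo, seed_hi = 4 * step, 10 * step
    seed = np.where((after >= seed_lo) & (after <= seed_hi))[0]
    if len(seed) < 3:
        raise ValueError("occlusal facet too short to fit past the tip")

    # grow the facet line point by point (incremental total-least-squares);
    # the breakpoint is 3 consecutive residuals beyond tolerance
    fit = _IncrementalLine()
    for idx in seed:
        fit.add(chain[idx])
    p0, d0 = fit.line()
    seed_resid = [abs(d0[0] * (chain[i][1] - p0[1]) - d0[1] * (chain[i][0] - p0[0]))
                  for i in seed]
    tol = max(3.0 * float(np.sqrt(np.mean(np.square(seed_resid)))), 0.5 * step)
    # freeze the fit once it spans enough arc so a shallow dihedral cannot
    # rotate the line into the lingual surface as points are absorbed
    freeze_span = max(2.5, 20 * step)
    run = None
    violations: list[int] = []
    for idx in range(seed[-1] + 1, len(chain)):
        p0, d0 = fit.line()
        r = abs(d0[0] * (chain[idx][1] - p0[1]) - d0[1] * (chain[idx][0] - p0[0]))
        if r > tol:
            violations.append(idx)
            if len(violations) == 3:
                run = violations[0]
                break
        else:
            frozen = arc[idx] - arc[seed[0]] >= freeze_span
            if not frozen:
                for v_idx in violations:
                    fit.add(chain[v_idx])
                fit.add(chain[idx])
            violations = []
    if run is None:
        raise ValueError("no gnaw ridge found: contour never leaves the facet line")
    p1, d1 = fit.line()

    # iterate: long facet refit + tight lingual flank window, re-intersect
    s_ridge = arc[run]
    ridge_pt = chain[run]
    for _ in range(3):
        facet_sel = (after >= seed_lo) & (arc <= s_ridge - max(0.3, 3 * step))
        if facet_sel.sum() >= 3:
            p1, d1 = _fit_line(chain[facet_sel])
        flank_sel = np.zeros(len(chain), dtype=bool)
        for lo, hi in ((0.2, 0.8), (2 * step, 0.8 + 4 * step), (0.0, 1.6)):
            flank_sel = (arc >= s_ridge + lo) & (arc <= s_ridge + hi)
            if flank_sel.sum() >= 3:
                break
        if flank_sel.sum() < 3:
            break
        cand = _facet_flank_crossing(chain[flank_sel], p1, d1, ridge_pt)
        if cand is None or np.linalg.norm(cand - ridge_pt) > 2.0:
            break
        ridge_pt = cand
        s_ridge = arc[int(np.argmin(np.linalg.norm(chain - ridge_pt, axis=1)))]
    i_ridge = int(np.argmin(np.linalg.norm(chain - ridge_pt, axis=1)))
    if i_ridge <= i_tip:
        raise ValueError("gnaw ridge localization failed (landmark ordering)")
    if np.dot(d1, chain[i_tip] - ridge_pt) < 0:
        d1 = -d1
    return i_ridge, ridge_pt, d1


def _facet_flank_crossing(flank: np.ndarray, p1: np.ndarray, d1: np.ndarray,
                          near: np.ndarray) -> np.ndarray | None:
    """Where the lingual flank curve meets the facet line.

    The flank is fit as a quadratic in facet-aligned coordinates so its
    curvature does not bias the crossing (a straight secant fit lands
    systematically past the true corner); the root nearest ``near`` wins.
    Falls back to a line fit for degenerate quadratics.
    """
    p2, d2 = _fit_line(flank)
    if abs(d1[0] * d2[1] - d1[1] * d2[0]) < np.sin(np.deg2rad(2.0)):
        linear = None
    else:
        linear = _line_intersection(p1, d1, p2, d2)
    n1 = np.array([-d1[1], d1[0]])
    u = (flank - p1) @ d1
    v = (flank - p1) @ n1
    if linear is not None and len(flank) >= 4 and np.ptp(u) > 1e-9:
        coeffs = np.polyfit(u, v, 2)
        roots = np.roots(coeffs)
        roots = roots[np.isreal(roots)].real
        if len(roots):
            u_near = (near - p1) @ d1
            u0 = roots[np.argmin(np.abs(roots - u_near))]
            quad = p1 + u0 * d1
            # accept the curvature correction only as a small refinement
            # of the secant estimate; a stray root means a bad fit
            if np.linalg.norm(quad - linear) < 0.3:
                return quad
    return linear


def _erupted_chain(contour: np.ndarray, z_level: float) -> np.ndarray:
    """Longest above-plane chain, endpoints interpolated onto the plane."""
    z = contour[:, 1] - z_level
    n = len(contour)
    above = z > 0
    if not above.any():
        raise ValueError("incisor outline has no erupted part above the alveolus level")
    if above.all():
        raise ValueError("incisor outline never crosses the alveolus level")
    start = int(np.argmin(above))
    order = np.roll(np.arange(n), -start)
    pts, up, zz = contour[order], above[order], z[order]
    chains = []
    i = 0
    while i < n:
        if up[i]:
            j = i
            while j < n and up[j]:
                j += 1
            chains.append((i, j))  # pts[i:j] above plane
            i = j
        else:
            i += 1
    def chain_pts(i, j):
        seg = pts[i:j]
        # entry crossing between i-1 and i
        a, b = pts[i - 1], pts[i]
        f = (z_level - a[1]) / (b[1] - a[1])
        entry = a + f * (b - a)
        c, d = pts[j - 1], pts[(j) % n]
        f = (z_level - c[1]) / (d[1] - c[1])
        exit_ = c + f * (d - c)
        return np.vstack([entry, seg, exit_])
    best = max(chains, key=lambda ij: _polyline_length(chain_pts(*ij)))
    return chain_pts(*best)


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _smooth_chain(chain: np.ndarray, sigma_pts: float = 2.0) -> np.ndarray:
    """Suppress marching-squares staircase ripple along the open chain.

    Coordinates are Gaussian-filtered along arc length with the endpoints
    (exact plane crossings) pinned; the residual shortening bias on the
    smooth arcs is O(sigma^2 / R^2) per unit length, far below a voxel.
    """
    if len(chain) < 7:
        return chain
    sm = np.column_stack([
        ndimage.gaussian_filter1d(chain[:, i], sigma_pts, mode="nearest")
        for i in range(2)
    ])
    sm[0], sm[-1] = chain[0], chain[-1]
    return sm


def extract_sagittal_profile(
    tooth_mask: Volume,
    side: str,
    bone_mask: Volume,
    smooth_sigma_vox: float = 1.2,
    corner_window_mm: float = 0.35,
    alveolus_z_mm: float | None = None,
) -> SagittalProfile:
    """Mid-sagittal outline of one incisor with landmark indices.

    The slice passes through the incisor component centroid (normal along
    the left-right axis); the binary slice is Gaussian-smoothed and the
    0.5-level contour extracted at sub-voxel resolution.
    """
    comp = _incisor_component(tooth_mask, side)
    z_alv = alveolus_z_mm if alveolus_z_mm is not None else _alveolus_level(bone_mask, comp)
    ci = int(round(np.argwhere(comp)[:, 0].mean()))
    slice2d = comp[ci].astype(float)
    if smooth_sigma_vox > 0:
        slice2d = ndimage.gaussian_filter(slice2d, smooth_sigma_vox)
    slice2d = np.pad(slice2d, 1)
    contours = skmeasure.find_contours(slice2d, 0.5)
    if not contours:
        raise ValueError(f"no incisor outline found on the {side} side")
    contour = max(contours, key=len) - 1.0  # undo padding
    sy, sz = tooth_mask.spacing[1], tooth_mask.spacing[2]
    oy, oz = tooth_mask.origin[1], tooth_mask.origin[2]
    contour_mm = np.column_stack([oy + contour[:, 0] * sy, oz + contour[:, 1] * sz])
    if np.allclose(contour_mm[0], contour_mm[-1]):
        contour_mm = contour_mm[:-1]

    chain = _erupted_chain(contour_mm, z_alv)
    # orient labial (larger y) end first
    if chain[0, 0] < chain[-1, 0]:
        chain = chain[::-1]
    chain = _smooth_chain(chain)

    step = float(np.median(np.linalg.norm(np.diff(chain, axis=0), axis=1)))
    k = max(3, int(round(corner_window_mm / max(step, 1e-9))))
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(chain, axis=0), axis=1))])
    if arc[-1] < 6 * k * step:
        raise ValueError(f"erupted outline on the {side} side is too short for landmarks")
    ang = _turning_angles(chain, k)
    interior = (arc > 2 * k * step) & (arc < arc[-1] - 2 * k * step)
    cand = np.where(interior, ang, -1.0)
    i_tip = int(np.argmax(cand))
    if cand[i_tip] < np.deg2rad(20):
        raise ValueError(f"no incisal tip corner found on the {side} side")
    i_ridge, ridge_pt, facet_dir = _locate_ridge(chain, arc, i_tip, step)
    tip_pt = _refine_corner(chain, i_tip, k)

    parts = [
        chain[: max(1, i_tip - k)],
        tip_pt[None],
        chain[i_tip + k: max(i_tip + k + 1, i_ridge - 1)],
        ridge_pt[None],
        chain[i_ridge + 1:],
    ]
    pts = np.vstack(parts)
    idx_tip = len(parts[0])
    idx_ridge = idx_tip + 1 + len(parts[2])
    landmarks = {
        "alveolus_edge": 0,
        "tip": idx_tip,
        "gnaw_ridge": idx_ridge,
        "lingual_alveolus_edge": len(pts) - 1,
    }
    x_mm = tooth_mask.origin[0] + ci * tooth_mask.spacing[0]
    return SagittalProfile(side, pts, landmarks, x_mm)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

_SURFACE_SPANS = {
    "labial": ("alveolus_edge", "tip"),
    "occlusal": ("tip", "gnaw_ridge"),
    "lingual": ("gnaw_ridge", "lingual_alveolus_edge"),
}


def path_length(profile: SagittalProfile, from_landmark: str | None = None,
                to_landmark: str | None = None, surface: str = "labial") -> float:
    """Polyline arc length (mm) along the named surface between landmarks."""
    if surface not in SURFACES:
        raise ValueError(f"surface {surface!r} not in {SURFACES}")
    default_from, default_to = _SURFACE_SPANS[surface]
    from_landmark = from_landmark or default_from
    to_landmark = to_landmark or default_to
    for name in (from_landmark, to_landmark):
        if name not in profile.landmarks:
            raise ValueError(f"profile has no landmark {name!r}")
    arc = profile.arc_length()
    a, b = profile.landmarks[from_landmark], profile.landmarks[to_landmark]
    return float(abs(arc[b] - arc[a]))


def occlusal_angle(profile: SagittalProfile, trim: float = 0.1) -> float:
    """Signed angle (deg) between the occlusal facet line and the horizontal.

    The facet is the ridge-to-tip contour with ``trim`` of the path length
    dropped at each end; positive when the tip is dorsal to the ridge.
    """
    i_tip, i_ridge = profile.landmarks["tip"], profile.landmarks["gnaw_ridge"]
    pts = profile.points[i_tip: i_ridge + 1]
    if len(pts) < 3:
        raise ValueError("occlusal facet has fewer than 3 points")
    if len(pts) > 6 and trim > 0:
        arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        keep = (arc >= trim * arc[-1]) & (arc <= (1 - trim) * arc[-1])
        if keep.sum() >= 3:
            pts = pts[keep]
    _, d = _fit_line(pts)
    tip = profile.points[i_tip]
    ridge = profile.points[i_ridge]
    if np.dot(d, tip - ridge) < 0:
        d = -d
    return float(np.degrees(np.arctan2(d[1], abs(d[0]))))


def measure_incisor(tooth_mask: Volume, bone_mask: Volume, side: str,
                    species: str = "rat", timepoint: str = "baseline",
                    **profile_kwargs) -> IncisorMetrics:
    """Full per-side incisor metric set for one reoriented volume."""
    profile = extract_sagittal_profile(tooth_mask, side, bone_mask, **profile_kwargs)
    labial = path_length(profile, surface="labial")
    if species == "rat":
        return IncisorMetrics(
            side,
            labial_mm=labial,
            lingual_mm=path_length(profile, surface="lingual"),
            occlusal_mm=path_length(profile, surface="occlusal"),
            occlusal_angle_deg=occlusal_angle(profile),
            timepoint=timepoint,
        )
    # rabbit: lingual/occlusal path lengths deliberately not reported
    return IncisorMetrics(
        side, labial_mm=labial, occlusal_angle_deg=occlusal_angle(profile),
        timepoint=timepoint,
    )


def cheek_tooth_height(tooth_mask: Volume, bone_mask: Volume, tooth_label: str | int,
                       side: str, timepoint: str = "baseline") -> CheekToothHeight:
    """Vertical distance from the adjacent alveolus edge to the highest cusp.

    Cheek teeth are numbered #2.. from the incisor backwards (descending y).
    """
    label_no = int(str(tooth_label).lstrip("#"))
    labels, n, counts, cx, cy = _component_stats(tooth_mask)
    want = -1 if side == "left" else 1
    min_voxels = max(2, int(np.ceil(0.5 / tooth_mask.voxel_volume())))
    keep = [lab for lab in range(1, n + 1)
            if counts[lab] >= min_voxels and np.sign(cx[lab]) == want]
    if not keep:
        raise ValueError(f"no teeth found on the {side} side")
    keep.sort(key=lambda lab: -counts[lab])
    molars = keep[1:]  # drop the incisor (largest component)
    if not molars:
        raise ValueError(f"no cheek teeth found on the {side} side")
    molars.sort(key=lambda lab: -cy[lab])
    pos = label_no - 2
    if pos < 0 or pos >= len(molars):
        raise ValueError(
            f"tooth #{label_no} not found on the {side} side ({len(molars)} cheek teeth)"
        )
    lab = molars[pos]
    idx = np.argwhere(labels == lab)
    sz = tooth_mask.spacing[2]
    cusp_z = tooth_mask.origin[2] + idx[:, 2].max() * sz + sz / 2
    comp = labels == lab
    near = ndimage.binary_dilation(
        comp, structure=ndimage.generate_binary_structure(3, 1), iterations=2
    )
    adjacent = (np.asarray(bone_mask.data) > 0) & near
    if not adjacent.any():
        raise ValueError(f"no alveolar bone adjacent to tooth #{label_no}")
    alv_z = bone_mask.origin[2] + np.argwhere(adjacent)[:, 2].max() * sz + sz / 2
    return CheekToothHeight(f"#{label_no}", side, float(cusp_z - alv_z), timepoint)
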