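"""Paired hemi-mandible voxel phantoms with analytically known geometry.

Each hemi-mandible is built in a sagittal working frame shared by both
sides (mirrored about the symphysis plane x = 0):

* the incisor is a tube of radius ``r`` around a planar circular arc of
  radius ``R`` centered at (y, z) = (0, 0) in the plane x = +/- x_s;
* a flat alveolus plane z = z_alv separates erupted crown from bone;
* the erupted tip is cut by a planar bevel whose facet runs from the
  gnaw ridge (on the inner/lingual arc) to the tip (on the outer/labial
  arc);
* cheek teeth are rectangular crowns with coplanar occlusal tops and
  per-tooth alveolar collar heights;
* body and ramus are boxes; surgical defect modes carve analytic regions
  out of the ramus or body.

All ground-truth metrics are closed-form functions of the arc parameters
(never of the voxelization).  Intensities: background 0, bone 800, teeth
1000 (arbitrary units); the documented binarization thresholds are
``BONE_THRESHOLD`` = 500 (bone + teeth) and ``TOOTH_THRESHOLD`` = 900
(teeth only).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq

from .imagecore import Volume
from .transforms import RigidTransform

BACKGROUND = 0.0
BONE_INTENSITY = 800.0
TOOTH_INTENSITY = 1000.0
BONE_THRESHOLD = 500.0
TOOTH_THRESHOLD = 900.0
DYNAMIC_RANGE = TOOTH_INTENSITY - BACKGROUND

#: capture-range cap for pose perturbations (documented contract)
MAX_POSE_DEG = 10.0
MAX_POSE_MM = 5.0

SIDES = ("left", "right")
DEFECT_TYPES = ("none", "CSD", "ID", "CRO_narrow", "CRO_wide", "BODY")


# ---------------------------------------------------------------------------
# Incisor arc geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IncisorSpec:
    """Planar-arc incisor descriptor.

    The bevel geometry is fully determined by the three erupted path
    lengths: ``labial_mm`` along the outer arc (alveolus edge -> tip),
    ``lingual_mm`` along the inner arc (alveolus edge -> gnaw ridge) and
    ``occlusal_mm`` as the straight facet chord (gnaw ridge -> tip).
    ``crown_extra_mm`` lengthens the labial crown (overgrowth).
    """

    centerline_radius_mm: float
    tube_radius_mm: float
    labial_mm: float
    lingual_mm: float
    occlusal_mm: float
    crown_extra_mm: float = 0.0

    def __post_init__(self):
        if self.tube_radius_mm <= 0 or self.centerline_radius_mm <= self.tube_radius_mm:
            raise ValueError("need 0 < tube radius < centerline radius")
        if min(self.labial_mm, self.lingual_mm, self.occlusal_mm) <= 0:
            raise ValueError("path-length targets must be positive")
        if self.crown_extra_mm < 0:
            raise ValueError("crown_extra_mm must be >= 0")


@dataclass(frozen=True)
class ArcSolution:
    """Solved arc angles (radians) plus derived analytic quantities."""

    R: float
    r: float
    phi_alv_outer: float  # labial alveolus edge, on outer arc
    phi_alv_inner: float  # lingual alveolus edge, on inner arc
    phi_ridge: float      # gnaw ridge, on inner arc
    phi_tip: float        # tip, on outer arc
    labial_mm: float
    lingual_mm: float
    occlusal_mm: float

    @property
    def outer(self) -> float:
        return self.R + self.r

    @property
    def inner(self) -> float:
        return self.R - self.r

    @property
    def z_alveolus(self) -> float:
        return self.outer * np.sin(self.phi_alv_outer)

    def point_outer(self, phi: float) -> np.ndarray:
        return self.outer * np.array([np.cos(phi), np.sin(phi)])

    def point_inner(self, phi: float) -> np.ndarray:
        return self.inner * np.array([np.cos(phi), np.sin(phi)])

    @property
    def tip(self) -> np.ndarray:
        """(y, z) of the incisal tip."""
        return self.point_outer(self.phi_tip)

    @property
    def ridge(self) -> np.ndarray:
        """(y, z) of the gnaw ridge."""
        return self.point_inner(self.phi_ridge)

    @property
    def occlusal_angle_deg(self) -> float:
        """Signed facet angle vs. horizontal; positive = tip dorsal to ridge."""
        dy, dz = self.tip - self.ridge
        return float(np.degrees(np.arctan2(dz, abs(dy))))

    @property
    def bevel_angle_deg(self) -> float:
        """Angle between the facet and the outer-arc tangent at the tip."""
        tangent = np.array([-np.sin(self.phi_tip), np.cos(self.phi_tip)])
        facet = self.ridge - self.tip
        facet = facet / np.linalg.norm(facet)
        cosb = np.clip(abs(np.dot(tangent, facet)), -1, 1)
        return float(np.degrees(np.arccos(cosb)))


def solve_arc(spec: IncisorSpec) -> ArcSolution:
    """Solve the four arc angles matching the three erupted path lengths.

    Closed-form pieces: the facet chord fixes the angular gap
    ``phi_tip - phi_ridge``; the alveolus plane couples the outer and
    inner crossing angles; the labial/lingual lengths fix the remaining
    spans.  A 1D root solve in the labial crossing angle ties it together.
    """
    R, r = spec.centerline_radius_mm, spec.tube_radius_mm
    a = spec.labial_mm
    b, c = spec.lingual_mm, spec.occlusal_mm
    ro, ri = R + r, R - r
    cos_delta = (ro**2 + ri**2 - c**2) / (2 * ro * ri)
    if not -1 < cos_delta < 1:
        raise ValueError(f"occlusal length {c} mm is not realizable at R={R}, r={r}")
    delta = np.arccos(cos_delta)

    def gap(phi_o):
        s = ro * np.sin(phi_o) / ri
        if s >= 1:
            return np.nan
        return (phi_o + a / ro) - (np.arcsin(s) + b / ri) - delta

    phi_max = np.arcsin(ri / ro) - 1e-9
    grid = np.linspace(1e-6, phi_max, 512)
    vals = np.array([gap(p) for p in grid])
    ok = np.isfinite(vals)
    grid, vals = grid[ok], vals[ok]
    crossings = np.where(np.diff(np.sign(vals)) != 0)[0]
    if len(crossings) == 0:
        raise ValueError(
            f"incisor targets (labial={a}, lingual={b}, occlusal={c}) mm are "
            f"not realizable on an arc with R={R}, r={r} mm"
        )
    i = crossings[0]
    phi_o = brentq(gap, grid[i], grid[i + 1])
    phi_i = np.arcsin(ro * np.sin(phi_o) / ri)
    phi_r = phi_i + b / ri
    phi_t = phi_o + a / ro
    # overgrowth slides the bevel outward along the arc: the alveolus
    # crossings and the facet chord stay fixed, the whole erupted crown
    # lengthens (labial by exactly crown_extra_mm)
    shift = spec.crown_extra_mm / ro
    phi_t += shift
    phi_r += shift
    if phi_t >= np.pi - phi_o - 1e-6:
        raise ValueError("erupted crown wraps past the alveolus plane")
    sol = ArcSolution(
        R, r, phi_o, phi_i, phi_r, phi_t,
        a + spec.crown_extra_mm, b + spec.crown_extra_mm * ri / ro, c,
    )
    assert phi_o < phi_i < phi_r < phi_t
    return sol


# ---------------------------------------------------------------------------
# Phantom specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MolarRow:
    """Cheek-tooth row: boxes with coplanar occlusal tops."""

    positions_y_mm: tuple[float, ...]      # box centers along y
    heights_mm: tuple[float, ...]          # per-tooth alveolus-to-cusp height
    width_y_mm: float = 1.6
    width_x_mm: float = 2.0
    root_depth_mm: float = 1.5
    collar_margin_mm: float = 0.3

    def __post_init__(self):
        if len(self.positions_y_mm) != len(self.heights_mm):
            raise ValueError("positions and heights must have equal length")
        if any(h < 0 for h in self.heights_mm):
            raise ValueError("crown heights must be >= 0")


@dataclass(frozen=True)
class Layout:
    """Box layout of one hemi-mandible in the shared sagittal frame."""

    slab_width_mm: float        # x thickness of the hemi-mandible
    body_y_mm: tuple[float, float]
    body_z_min_mm: float
    ramus_y_mm: tuple[float, float]
    ramus_z_top_mm: float
    margin_mm: float = 0.6


@dataclass(frozen=True)
class PhantomSpec:
    species: str
    voxel_mm: tuple[float, float, float]
    incisors: dict                      # side -> IncisorSpec
    molars: dict                        # side -> MolarRow
    layout: Layout
    symphysis_gap_mm: float = 1.0
    noise_sd: float = 0.0               # fraction of dynamic range
    seed: int = 0

    def __post_init__(self):
        v = np.asarray(self.voxel_mm, dtype=float)
        if v.shape == ():
            v = np.repeat(v, 3)
        if np.any(v <= 0):
            raise ValueError("voxel_mm must be positive")
        object.__setattr__(self, "voxel_mm", tuple(float(x) for x in v))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.symphysis_gap_mm <= 0:
            raise ValueError("symphysis_gap_mm must be positive")
        for side in SIDES:
            inc = self.incisors[side]
            if max(self.voxel_mm) > inc.tube_radius_mm:
                raise ValueError(
                    f"voxel size {max(self.voxel_mm)} mm exceeds incisor tube "
                    f"radius {inc.tube_radius_mm} mm: geometry unresolvable"
                )

    def arc(self, side: str) -> ArcSolution:
        return solve_arc(self.incisors[side])

    def incisor_center_x(self, side: str) -> float:
        s = -1.0 if side == "left" else 1.0
        return s * (self.symphysis_gap_mm / 2 + self.incisors[side].tube_radius_mm + 0.3)


@dataclass(frozen=True)
class DefectSpec:
    type: str = "none"
    side: str = "left"
    size_mm: tuple[float, ...] | None = None
    center_mm: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.type not in DEFECT_TYPES:
            raise ValueError(f"defect type {self.type!r} not in {DEFECT_TYPES}")
        if self.side not in SIDES:
            raise ValueError(f"side {self.side!r} not in {SIDES}")


@dataclass
class GroundTruth:
    """Analytic per-side metrics and construction metadata."""

    labial_mm: dict
    lingual_mm: dict
    occlusal_mm: dict
    occlusal_angle_deg: dict
    cheek_heights_mm: dict          # side -> tuple
    alveolus_z_mm: float
    defect_type: str
    defect_side: str | None
    defect_removed_mm3: float
    pose: RigidTransform | None = None

    def metric(self, name: str, side: str) -> float:
        return getattr(self, name)[side]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pose"] = self.pose.to_dict() if self.pose is not None else None
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# Species presets
# ---------------------------------------------------------------------------


def rat_spec(
    voxel_mm: float = 0.046,
    noise_sd: float = 0.0,
    seed: int = 0,
    crown_extra_mm: dict | None = None,
) -> PhantomSpec:
    """Rat preset: erupted path lengths at the published baseline scale."""
    extra = {"left": 0.0, "right": 0.0, **(crown_extra_mm or {})}
    inc = {
        side: IncisorSpec(
            centerline_radius_mm=14.0,
            tube_radius_mm=1.0,
            labial_mm=12.66,
            lingual_mm=1.67,
            occlusal_mm=5.85,
            crown_extra_mm=extra[side],
        )
        for side in SIDES
    }
    molars = {
        side: MolarRow(positions_y_mm=(-3.4, -5.2, -7.0), heights_mm=(2.5, 2.5, 2.5))
        for side in SIDES
    }
    layout = Layout(
        slab_width_mm=6.0,
        body_y_mm=(-10.0, 16.0),
        body_z_min_mm=-4.0,
        ramus_y_mm=(-18.0, -8.0),
        ramus_z_top_mm=18.6,
    )
    return PhantomSpec("rat", (voxel_mm,) * 3, inc, molars, layout, 1.0, noise_sd, seed)


def rabbit_spec(
    voxel_mm: float = 0.09,
    noise_sd: float = 0.0,
    seed: int = 0,
    crown_extra_mm: dict | None = None,
    cheek_heights_mm: dict | None = None,
) -> PhantomSpec:
    """Rabbit preset (default scan voxel 0.09 mm; low-resolution scans use 0.18)."""
    extra = {"left": 0.0, "right": 0.0, **(crown_extra_mm or {})}
    inc = {
        side: IncisorSpec(
            centerline_radius_mm=12.0,
            tube_radius_mm=1.2,
            labial_mm=11.5,
            lingual_mm=2.0,
            occlusal_mm=4.0,
            crown_extra_mm=extra[side],
        )
        for side in SIDES
    }
    heights = {"left": (5.3, 3.4, 4.1, 3.0), "right": (5.3, 3.4, 4.1, 3.0)}
    if cheek_heights_mm:
        heights.update({k: tuple(v) for k, v in cheek_heights_mm.items()})
    molars = {
        side: MolarRow(positions_y_mm=(-1.6, -3.8, -6.0, -8.2), heights_mm=heights[side])
        for side in SIDES
    }
    layout = Layout(
        slab_width_mm=8.0,
        body_y_mm=(-12.0, 15.0),
        body_z_min_mm=10.51 - 13.0,   # 13 mm body height below the alveolus plane
        ramus_y_mm=(-24.0, -10.0),
        ramus_z_top_mm=10.51 + 16.0,
    )
    return PhantomSpec("rabbit", (voxel_mm,) * 3, inc, molars, layout, 1.4, noise_sd, seed)


PRESETS = {"rat": rat_spec, "rabbit": rabbit_spec}


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def _grid(spec: PhantomSpec):
    """Physical voxel-center coordinate vectors covering the phantom."""
    lay = spec.layout
    arcs = [spec.arc(s) for s in SIDES]
    m = lay.margin_mm
    x_max = spec.symphysis_gap_mm / 2 + lay.slab_width_mm + m
    y_min = lay.ramus_y_mm[0] - m
    y_max = max(a.outer + a.r for a in arcs) + m + 1.0
    z_top = max(
        max(lay.ramus_z_top_mm, a.z_alveolus + max(spec.molars[s].heights_mm))
        for a, s in zip(arcs, SIDES)
    )
    z_max = max(z_top, max(a.outer for a in arcs)) + m
    z_min = lay.body_z_min_mm - m
    vx, vy, vz = spec.voxel_mm
    # x centers mirror-symmetric about the symphysis plane so both sides
    # rasterize identically
    half = np.arange(vx / 2, x_max, vx)
    xs = np.concatenate([-half[::-1], half])
    ys = np.arange(y_min, y_max + vy / 2, vy)
    zs = np.arange(z_min, z_max + vz / 2, vz)
    return xs, ys, zs


def _box_mask(xs, ys, zs, x_rng, y_rng, z_rng):
    bx = (xs >= x_rng[0]) & (xs < x_rng[1])
    by = (ys >= y_rng[0]) & (ys < y_rng[1])
    bz = (zs >= z_rng[0]) & (zs < z_rng[1])
    return bx[:, None, None] & by[None, :, None] & bz[None, None, :]


def _incisor_mask(xs, ys, zs, arc: ArcSolution, x_center: float) -> np.ndarray:
    """Rasterize the beveled arc tube, slab-by-slab along x for memory."""
    yy = ys[:, None]
    zz = zs[None, :]
    rho = np.hypot(yy, zz)
    phi = np.arctan2(zz, yy)
    in_span = (phi >= 0.0) & (phi <= arc.phi_tip + arc.r / arc.R)
    # bevel half-space: keep material on the proximal side of the facet line
    tip, ridge = arc.tip, arc.ridge
    facet = ridge - tip
    facet = facet / np.linalg.norm(facet)
    normal = np.array([-facet[1], facet[0]])
    mid_phi = 0.5 * (arc.phi_alv_outer + arc.phi_tip)
    probe = arc.point_outer(mid_phi) * (1 - 1e-6)
    if np.dot(probe - tip, normal) > 0:
        normal = -normal
    keep = ((yy - tip[0]) * normal[0] + (zz - tip[1]) * normal[1]) <= 0.0
    planar = in_span & keep
    radial2 = (rho - arc.R) ** 2
    out = np.zeros((len(xs), len(ys), len(zs)), dtype=bool)
    r2 = arc.r**2
    for i, x in enumerate(xs):
        dx2 = (x - x_center) ** 2
        if dx2 > r2:
            continue
        out[i] = planar & (radial2 <= r2 - dx2)
    return out


def _molar_boxes(spec: PhantomSpec, side: str):
    """Per-tooth (x_rng, y_rng, crown_z_rng, collar_z_top) boxes."""
    arc = spec.arc(side)
    row = spec.molars[side]
    s = -1.0 if side == "left" else 1.0
    # molar row sits lateral of the incisor tube so tooth components stay apart
    x_mid = s * (spec.symphysis_gap_mm / 2 + 0.75 * spec.layout.slab_width_mm)
    x_rng = sorted((x_mid - row.width_x_mm / 2, x_mid + row.width_x_mm / 2))
    z_alv = arc.z_alveolus
    z_occ = z_alv + max(row.heights_mm)
    boxes = []
    for y0, h in zip(row.positions_y_mm, row.heights_mm):
        y_rng = (y0 - row.width_y_mm / 2, y0 + row.width_y_mm / 2)
        crown_z = (z_alv - row.root_depth_mm, z_occ)
        boxes.append((tuple(x_rng), y_rng, crown_z, z_occ - h))
    return boxes, z_occ


def rasterize(spec: PhantomSpec):
    """Build (grayscale Volume, bone mask, tooth mask) from the spec."""
    xs, ys, zs = _grid(spec)
    shape = (len(xs), len(ys), len(zs))
    tooth = np.zeros(shape, dtype=bool)
    bone = np.zeros(shape, dtype=bool)
    lay = spec.layout
    g2 = spec.symphysis_gap_mm / 2
    for side in SIDES:
        s = -1.0 if side == "left" else 1.0
        arc = spec.arc(side)
        x_rng = tuple(sorted((s * g2, s * (g2 + lay.slab_width_mm))))
        bone |= _box_mask(xs, ys, zs, x_rng, lay.body_y_mm, (lay.body_z_min_mm, arc.z_alveolus))
        bone |= _box_mask(xs, ys, zs, x_rng, lay.ramus_y_mm, (lay.body_z_min_mm, lay.ramus_z_top_mm))
        tooth |= _incisor_mask(xs, ys, zs, arc, spec.incisor_center_x(side))
        boxes, _ = _molar_boxes(spec, side)
        row = spec.molars[side]
        for bx, by, bz, collar_top in boxes:
            tooth |= _box_mask(xs, ys, zs, bx, by, bz)
            if collar_top > arc.z_alveolus + 1e-9:
                cm = row.collar_margin_mm
                cx = (bx[0] - cm, bx[1] + cm)
                cy = (by[0] - cm, by[1] + cm)
                bone |= _box_mask(xs, ys, zs, cx, cy, (arc.z_alveolus, collar_top))
    bone &= ~tooth
    data = np.zeros(shape, dtype=np.float32)
    data[bone] = BONE_INTENSITY
    data[tooth] = TOOTH_INTENSITY
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd * DYNAMIC_RANGE, shape).astype(
            np.float32
        )
    origin = (float(xs[0]), float(ys[0]), float(zs[0]))
    vol = Volume(data, spec.voxel_mm, origin)
    bone_vol = Volume(bone.astype(np.uint8), spec.voxel_mm, origin)
    tooth_vol = Volume(tooth.astype(np.uint8), spec.voxel_mm, origin)
    return vol, bone_vol, tooth_vol


# ---------------------------------------------------------------------------
# Defects
# ---------------------------------------------------------------------------


def default_defect_geometry(spec: PhantomSpec, defect: DefectSpec):
    """Resolve a defect into (kind, params, analytic removed bone volume mm^3).

    kind is ``"sphere"`` (center, radius) or ``"box"`` ((x,y,z) ranges).
    Removed volumes are exact because the default placements lie fully
    inside bone and clear of the teeth.
    """
    lay = spec.layout
    s = -1.0 if defect.side == "left" else 1.0
    g2 = spec.symphysis_gap_mm / 2
    x_rng = tuple(sorted((s * g2, s * (g2 + lay.slab_width_mm))))
    x_mid = s * (g2 + lay.slab_width_mm / 2)
    w = lay.slab_width_mm
    arc = spec.arc(defect.side)
    y_ram = lay.ramus_y_mm
    y_mid = 0.5 * (y_ram[0] + y_ram[1])
    z_lo, z_hi = lay.body_z_min_mm, lay.ramus_z_top_mm
    rat = spec.species == "rat"

    if defect.type == "none":
        return None, None, 0.0
    if defect.type == "CSD":
        d = (defect.size_mm or ((5.0,) if rat else (8.0, 8.0)))
        if rat or len(d) == 1:
            radius = d[0] / 2
            center = (x_mid, y_mid, 0.5 * (z_lo + z_hi))
            return "sphere", (center, radius), 4.0 / 3.0 * np.pi * radius**3
        dy, dz = d
        zc = 0.5 * (z_lo + z_hi)
        box = (x_rng, (y_mid - dy / 2, y_mid + dy / 2), (zc - dz / 2, zc + dz / 2))
        return "box", box, dy * dz * w
    if defect.type in ("ID", "CRO_narrow", "CRO_wide"):
        dy, dz = defect.size_mm or ((5.0, 9.0) if rat else (6.0, 23.0))
        box = (x_rng, (y_mid - dy / 2, y_mid + dy / 2), (z_lo, z_lo + dz))
        removed = dy * dz * w
        if defect.type == "ID":
            return "box", box, removed
        gap = 1.0 if defect.type == "CRO_narrow" else 3.0
        # the cut starts 0.1 mm below the ID top so no bone ledge survives;
        # the overlap removes no extra bone, so it is excluded from the total
        cut = (x_rng, (y_mid - gap / 2, y_mid + gap / 2), (z_lo + dz - 0.1, z_hi))
        removed += gap * (z_hi - (z_lo + dz)) * w
        return "multibox", (box, cut), removed
    if defect.type == "BODY":
        dy, dz = defect.size_mm or (12.0, 10.0)
        yc = float(np.mean(spec.molars[defect.side].positions_y_mm))
        yc = max(yc, lay.body_y_mm[0] + dy / 2 + 0.2)  # keep inside the body
        box = (x_rng, (yc - dy / 2, yc + dy / 2), (lay.body_z_min_mm, lay.body_z_min_mm + dz))
        return "box", box, dy * dz * w
    raise ValueError(defect.type)


def _geometry_mask(volume: Volume, kind, params) -> np.ndarray:
    xs = volume.axis_coords(0)
    ys = volume.axis_coords(1)
    zs = volume.axis_coords(2)
    if kind == "sphere":
        (cx, cy, cz), radius = params
        d2 = (
            (xs - cx)[:, None, None] ** 2
            + (ys - cy)[None, :, None] ** 2
            + (zs - cz)[None, None, :] ** 2
        )
        return d2 <= radius**2
    if kind == "box":
        return _box_mask(xs, ys, zs, *params)
    if kind == "multibox":
        m = np.zeros(volume.shape, dtype=bool)
        for box in params:
            m |= _box_mask(xs, ys, zs, *box)
        return m
    raise ValueError(kind)


def apply_defect(volume: Volume, mask: Volume, defect: DefectSpec, spec: PhantomSpec | None = None,
                 geometry=None):
    """Carve a defect out of ``volume``; returns (volume, removed mm^3, components).

    ``geometry`` may be an explicit ``(kind, params)`` pair; otherwise the
    preset placement from ``spec`` is used.  The removed volume is the
    physical volume of bone-mask voxels cleared; the component count is
    the number of 6-connected bone components on the defect side.
    """
    if defect.type == "none":
        side_mask = _side_bone(mask, defect.side)
        _, n = _label_count(side_mask)
        return volume.copy(), 0.0, n
    if geometry is None:
        if spec is None:
            raise ValueError("need a PhantomSpec (or explicit geometry) to place the defect")
        kind, params, _ = default_defect_geometry(spec, defect)
    else:
        kind, params = geometry
    region = _geometry_mask(volume, kind, params)
    bone = np.asarray(mask.data) > 0
    removed = float(np.count_nonzero(region & bone)) * volume.voxel_volume()
    out = np.asarray(volume.data).copy()
    out[region] = BACKGROUND
    new_mask = bone & ~region
    side_mask = Volume(new_mask.astype(np.uint8), mask.spacing, mask.origin)
    _, n = _label_count(_side_bone(side_mask, defect.side))
    return Volume(out, volume.spacing, volume.origin), removed, n


def _side_bone(mask: Volume, side: str) -> np.ndarray:
    xs = mask.axis_coords(0)
    sel = xs < 0 if side == "left" else xs > 0
    return np.asarray(mask.data)[sel] > 0


def _label_count(binary: np.ndarray) -> tuple[np.ndarray, int]:
    labels, n = ndimage.label(binary, structure=ndimage.generate_binary_structure(3, 1))
    return labels, int(n)


# ---------------------------------------------------------------------------
# Pose perturbation
# ---------------------------------------------------------------------------


def random_pose(seed: int, max_deg: float = 4.0, max_mm: float = 2.5,
                center=(0.0, 0.0, 0.0)) -> RigidTransform:
    """Seeded random rigid pose within the documented capture range."""
    if max_deg > MAX_POSE_DEG or max_mm > MAX_POSE_MM:
        raise ValueError(
            f"pose perturbation capped at {MAX_POSE_DEG} deg / {MAX_POSE_MM} mm"
        )
    rng = np.random.default_rng(seed)
    ang = rng.uniform(-max_deg, max_deg, 3)
    tr = rng.uniform(-max_mm, max_mm, 3)
    return RigidTransform(tuple(ang), tuple(tr), tuple(center))


def perturb_pose(volume: Volume, transform: RigidTransform | None = None,
                 seed: int | None = None, interpolation: str = "linear") -> Volume:
    """Resample ``volume`` under a rigid pose (simulated repositioning).

    With ``transform=None`` a random pose is drawn from ``seed``.
    Interpolation is linear by default (``"nearest"`` for masks);
    out-of-field voxels are set to background.
    """
    from .register import apply_transform

    if transform is None:
        if seed is None:
            raise ValueError("need a transform or a seed")
        center = tuple(
            o + s * (n - 1) / 2 for o, s, n in zip(volume.origin, volume.spacing, volume.shape)
        )
        transform = random_pose(seed, center=center)
    if np.any(np.abs(transform.angles_deg) > MAX_POSE_DEG) or np.any(
        np.abs(transform.translation_mm) > MAX_POSE_MM
    ):
        raise ValueError(
            f"pose perturbation capped at {MAX_POSE_DEG} deg / {MAX_POSE_MM} mm"
        )
    return apply_transform(volume, transform, volume, interpolation=interpolation)


# ---------------------------------------------------------------------------
# make_phantom
# ---------------------------------------------------------------------------


def make_phantom(spec: PhantomSpec, defect: DefectSpec | None = None,
                 pose: RigidTransform | None = None):
    """Generate a paired hemi-mandible phantom.

    Returns ``(Volume, GroundTruth)``.  The ground truth is computed in
    closed form from the spec (never from the voxelization); the applied
    pose and analytic removed defect volume are recorded.
    """
    defect = defect or DefectSpec("none")
    vol, bone, tooth = rasterize(spec)
    removed = 0.0
    if defect.type != "none":
        vol, removed_meas, _ = apply_defect(vol, bone, defect, spec)
        _, _, removed = default_defect_geometry(spec, defect)
    if pose is not None:
        vol = perturb_pose(vol, pose)
    arcs = {s: spec.arc(s) for s in SIDES}
    gt = GroundTruth(
        labial_mm={s: arcs[s].labial_mm for s in SIDES},
        lingual_mm={s: arcs[s].lingual_mm for s in SIDES},
        occlusal_mm={s: arcs[s].occlusal_mm for s in SIDES},
        occlusal_angle_deg={s: arcs[s].occlusal_angle_deg for s in SIDES},
        cheek_heights_mm={s: tuple(spec.molars[s].heights_mm) for s in SIDES},
        alveolus_z_mm=float(arcs["left"].z_alveolus),
        defect_type=defect.type,
        defect_side=defect.side if defect.type != "none" else None,
        defect_removed_mm3=removed,
        pose=pose,
    )
    return vol, gt


# ---------------------------------------------------------------------------
# Parametric cohort simulator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricParams:
    """Normal model for one metric: animal means and left-right splits."""

    mean: float
    between_sd: float
    diff_sd: float
    defect_effect: float = 0.0   # additive shift on the defect side post-defect
    units: str = "mm"

    def __post_init__(self):
        if self.between_sd < 0 or self.diff_sd < 0:
            raise ValueError("SDs must be >= 0")


#: published baseline scales; left-right difference SDs are free knobs
#: (the between-animal/within-animal split is not printed).
RAT_COHORT_METRICS = {
    "labial": MetricParams(12.66, 0.59, 0.6),
    "lingual": MetricParams(1.67, 0.25, 0.2),
    "occlusal": MetricParams(5.85, 0.51, 0.4),
}
RABBIT_COHORT_METRICS = {
    "labial": MetricParams(11.5, 1.1, 0.6),
    "occlusal_angle": MetricParams(30.0, 3.0, 1.2, units="deg"),
}


@dataclass(frozen=True)
class CohortParams:
    metrics: dict               # name -> MetricParams
    n_animals: int = 8
    timepoints: tuple[str, ...] = ("baseline",)
    defect_side: str = "left"
    species: str = "rat"
    seed: int = 0

    def __post_init__(self):
        if self.n_animals < 2:
            raise ValueError("need n >= 2 animals")


def simulate_cohort(params: CohortParams) -> pd.DataFrame:
    """Draw a tidy metric table: per animal, side, timepoint and metric.

    left = animal mean + d/2 and right = animal mean - d/2 with
    d ~ N(0, diff_sd) redrawn per timepoint; the defect effect is added
    to the defect side at every post-baseline timepoint.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    for name, mp in params.metrics.items():
        animal_means = rng.normal(mp.mean, mp.between_sd, params.n_animals)
        for tp in params.timepoints:
            diffs = rng.normal(0.0, mp.diff_sd, params.n_animals)
            for a in range(params.n_animals):
                left = animal_means[a] + diffs[a] / 2
                right = animal_means[a] - diffs[a] / 2
                if tp != "baseline" and mp.defect_effect != 0.0:
                    if params.defect_side == "left":
                        left += mp.defect_effect
                    else:
                        right += mp.defect_effect
                rows.append((f"{params.species}{a + 1:02d}", params.species, "left", tp, name, left, mp.units))
                rows.append((f"{params.species}{a + 1:02d}", params.species, "right", tp, name, right, mp.units))
    return pd.DataFrame(
        rows, columns=["animal_id", "species", "side", "timepoint", "metric", "value", "units"]
    )
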