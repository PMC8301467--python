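"""Rigid co-registration by mutual-information maximization.

The similarity uses every overlapping voxel (no landmarks): intensities of
the fixed grid and of the moving volume resampled under the candidate
transform are binned into a joint histogram, and mutual information in
bits is maximized over the 6 rigid parameters with the Nelder-Mead
simplex.  Defaults: 64 bins, min-max intensity normalization, linear
interpolation of moving intensities, rotation center at the fixed-volume
grid center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

from .imagecore import Volume
from .transforms import RigidTransform


@dataclass
class JointHistogram:
    counts: np.ndarray
    fixed_range: tuple[float, float]
    moving_range: tuple[float, float]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or np.any(self.counts < 0):
            raise ValueError("counts must be a nonnegative 2D grid")

    @property
    def n_samples(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class RegistrationOptions:
    #: 32 bins keep the joint histogram well populated on small volumes;
    #: raise for large, high-dynamic-range scans
    bins: int = 32
    interpolation: str = "linear"     # or "nearest"
    #: subsampling factor: the optimizer draws fixed.size / sample_step^3
    #: seeded random sample positions (continuous, not a voxel lattice --
    #: lattice strides alias against the transform and make MI ragged)
    sample_step: int = 3
    #: pre-smoothing of both volumes (voxels); smooths interpolation-induced
    #: local maxima of the MI landscape
    smooth_sigma_vox: float = 0.7
    max_iter: int = 500
    simplex_tol: float = 1e-2         # normalized-parameter simplex size
    starts: int = 1                   # 1 = identity only; extra starts jittered
    jitter_deg: float = 5.0
    jitter_mm: float = 2.5
    seed: int = 0
    #: initial simplex scale in (deg, mm) around each start
    step_deg: float = 1.0
    step_mm: float = 0.5


def _resample_moving(fixed: Volume, moving: Volume, t: RigidTransform,
                     interpolation: str, step: int):
    """Moving intensities at fixed-grid voxel centers mapped through t^-1.

    Returns (fixed values, moving values, inside mask) for the strided grid.
    """
    order = 1 if interpolation == "linear" else 0
    idx = np.indices([int(np.ceil(n / step)) for n in fixed.shape], dtype=float)
    idx = idx.reshape(3, -1).T * step
    pts_fixed = fixed.index_to_physical(idx)
    pts_moving = t.invert().apply(pts_fixed)
    mov_idx = moving.physical_to_index(pts_moving)
    upper = np.asarray(moving.shape) - 1
    inside = np.all((mov_idx >= 0) & (mov_idx <= upper), axis=1)
    vals = ndimage.map_coordinates(
        np.asarray(moving.data, dtype=float), mov_idx.T, order=order, mode="constant",
        cval=np.nan, prefilter=False,
    )
    fvals = np.asarray(fixed.data, dtype=float)[
        tuple(idx.astype(int)[:, i] for i in range(3))
    ]
    inside &= np.isfinite(vals)
    return fvals[inside], vals[inside], inside


def joint_histogram(fixed: Volume, moving: Volume, t: RigidTransform | None = None,
                    bins: int = 64, interpolation: str = "linear",
                    sample_step: int = 1) -> JointHistogram:
    """Joint intensity histogram over the overlap of fixed and transformed moving."""
    if bins < 2:
        raise ValueError("need at least 2 bins")
    t = t or RigidTransform()
    fvals, mvals, _ = _resample_moving(fixed, moving, t, interpolation, sample_step)
    if fvals.size == 0:
        raise ValueError(
            "empty overlap between fixed and moving volumes: transform outside capture range"
        )
    frange = (float(np.min(fixed.data)), float(np.max(fixed.data)))
    mrange = (float(np.min(moving.data)), float(np.max(moving.data)))
    frange = (frange[0], frange[1] if frange[1] > frange[0] else frange[0] + 1.0)
    mrange = (mrange[0], mrange[1] if mrange[1] > mrange[0] else mrange[0] + 1.0)
    counts, _, _ = np.histogram2d(fvals, mvals, bins=bins, range=[frange, mrange])
    return JointHistogram(counts, frange, mrange)


def mutual_information(h: JointHistogram) -> float:
    """MI in bits: sum p(i,j) log2[p(i,j) / (p(i) p(j))]; 0-count terms drop."""
    n = h.n_samples
    if n <= 0:
        raise ValueError("histogram is empty")
    p = h.counts / n
    pi = p.sum(axis=1, keepdims=True)
    pj = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (pi @ pj)[nz])))


def entropy_bits(marginal: np.ndarray) -> float:
    p = np.asarray(marginal, dtype=float)
    p = p / p.sum()
    nz = p > 0
    return float(-np.sum(p[nz] * np.log2(p[nz])))


def mi_between(fixed: Volume, moving: Volume, t: RigidTransform | None = None,
               opts: RegistrationOptions = RegistrationOptions()) -> float:
    h = joint_histogram(fixed, moving, t, opts.bins, opts.interpolation, opts.sample_step)
    return mutual_information(h)


class _SampledMI:
    """MI objective over a fixed, seeded set of continuous sample points."""

    def __init__(self, fixed: Volume, moving: Volume, opts: RegistrationOptions):
        rng = np.random.default_rng(opts.seed)
        n = max(10_000, fixed.data.size // opts.sample_step**3)
        lo = np.asarray(fixed.origin)
        hi = lo + (np.asarray(fixed.shape) - 1) * np.asarray(fixed.spacing)
        self.points = rng.uniform(lo, hi, size=(min(n, fixed.data.size), 3))
        fidx = ((self.points - lo) / np.asarray(fixed.spacing)).T
        self.fixed_values = ndimage.map_coordinates(
            np.asarray(fixed.data, dtype=float), fidx, order=1, prefilter=False
        )
        self.moving = np.asarray(moving.data, dtype=float)
        self.moving_origin = np.asarray(moving.origin)
        self.moving_spacing = np.asarray(moving.spacing)
        self.moving_upper = np.asarray(moving.shape) - 1
        self.bins = opts.bins
        self.order = 1 if opts.interpolation == "linear" else 0
        self.fixed_range = _span(fixed.data)
        self.moving_range = _span(moving.data)

    def __call__(self, t: RigidTransform) -> float:
        mov_pts = t.invert().apply(self.points)
        idx = (mov_pts - self.moving_origin) / self.moving_spacing
        inside = np.all((idx >= 0) & (idx <= self.moving_upper), axis=1)
        if not inside.any():
            return 0.0
        vals = ndimage.map_coordinates(
            self.moving, idx[inside].T, order=self.order, prefilter=False
        )
        counts, _, _ = np.histogram2d(
            self.fixed_values[inside], vals, bins=self.bins,
            range=[self.fixed_range, self.moving_range],
        )
        return mutual_information(JointHistogram(counts, self.fixed_range, self.moving_range))


def _span(data) -> tuple[float, float]:
    lo, hi = float(np.min(data)), float(np.max(data))
    return (lo, hi if hi > lo else lo + 1.0)


def register_rigid(fixed: Volume, moving: Volume,
                   init: RigidTransform | None = None,
                   opts: RegistrationOptions = RegistrationOptions()):
    """Nelder-Mead maximization of MI over the 6 rigid parameters.

    Returns ``(transform, final_mi_bits, trace, converged)``; the trace is
    the per-iteration best-vertex MI (monotone non-decreasing).  With
    ``opts.starts > 1``, jittered restarts are run from seeded offsets and
    the best MI wins (ties broken by smaller parameter norm).
    Deterministic given ``init`` and ``opts``.
    """
    if np.ptp(fixed.data) == 0 or np.ptp(moving.data) == 0:
        raise ValueError("cannot register constant volumes")
    if opts.smooth_sigma_vox > 0:
        fixed = Volume(
            ndimage.gaussian_filter(np.asarray(fixed.data, dtype=float), opts.smooth_sigma_vox),
            fixed.spacing, fixed.origin,
        )
        moving = Volume(
            ndimage.gaussian_filter(np.asarray(moving.data, dtype=float), opts.smooth_sigma_vox),
            moving.spacing, moving.origin,
        )
    center = tuple(
        o + s * (n - 1) / 2 for o, s, n in zip(fixed.origin, fixed.spacing, fixed.shape)
    )
    init = init or RigidTransform(center_mm=center)
    scale = np.array([opts.step_deg] * 3 + [opts.step_mm] * 3)
    objective = _SampledMI(fixed, moving, opts)

    def neg_mi(p):
        return -objective(RigidTransform(tuple(p[:3]), tuple(p[3:]), center))

    p_init = np.array(list(init.angles_deg) + list(init.translation_mm))
    rng = np.random.default_rng(opts.seed)
    starts = [p_init]
    for _ in range(max(0, opts.starts - 1)):
        jitter = np.concatenate([
            rng.uniform(-opts.jitter_deg, opts.jitter_deg, 3),
            rng.uniform(-opts.jitter_mm, opts.jitter_mm, 3),
        ])
        starts.append(p_init + jitter)

    best = None
    trace_best = None
    for p0 in starts:
        trace: list[float] = []

        def record(pk):
            trace.append(-neg_mi(pk))

        # restart the simplex at full scale around the incumbent until MI
        # stops improving: a collapsed simplex can stall a voxel short of
        # the optimum, and a fresh simplex hops it out
        res = None
        pk, fk = np.asarray(p0, dtype=float), np.inf
        for _ in range(4):
            simplex = np.vstack([pk] + [pk + scale * e for e in np.eye(6)])
            res_k = minimize(
                neg_mi, pk, method="Nelder-Mead", callback=record,
                options={
                    "maxiter": opts.max_iter,
                    "xatol": opts.simplex_tol * float(np.min(scale)),
                    "fatol": 1e-9,
                    "initial_simplex": simplex,
                },
            )
            if res is None or res_k.fun < res.fun:
                res = res_k
            if fk - res_k.fun < 1e-4:
                break
            pk, fk = res_k.x, res_k.fun
        mi = -res.fun
        cand = (mi, -float(np.linalg.norm(res.x / scale)), res)
        if best is None or cand[:2] > best[:2]:
            best = cand
            trace_best = np.maximum.accumulate(trace) if trace else [mi]
    res = best[2]
    t = RigidTransform(tuple(res.x[:3]), tuple(res.x[3:]), center)
    converged = bool(res.success)
    return t, float(best[0]), list(trace_best), converged


def apply_transform(volume: Volume, t: RigidTransform, reference: Volume,
                    interpolation: str = "linear", background: float = 0.0) -> Volume:
    """Resample ``volume`` onto the reference grid under ``t``.

    ``t`` maps volume (moving) physical coordinates into the reference
    (fixed) frame; output voxel x gets ``volume(t^-1(x))``.  Out-of-field
    voxels are set to ``background``.
    """
    if t.is_identity and reference.shape == volume.shape \
            and reference.spacing == volume.spacing and reference.origin == volume.origin:
        return volume.copy()
    order = 1 if interpolation == "linear" else 0
    a, b = t.invert().as_affine()
    s_ref = np.diag(reference.spacing)
    s_vol_inv = np.diag(1.0 / np.asarray(volume.spacing))
    # moving index = S_vol^-1 (A (S_ref i + o_ref) + b - o_vol)
    m = s_vol_inv @ a @ s_ref
    off = s_vol_inv @ (a @ np.asarray(reference.origin) + b - np.asarray(volume.origin))
    data = ndimage.affine_transform(
        np.asarray(volume.data, dtype=float), m, offset=off,
        output_shape=reference.shape, order=order, mode="constant", cval=background,
        prefilter=False,
    )
    if np.issubdtype(np.asarray(volume.data).dtype, np.integer) and order == 0:
        data = data.astype(np.asarray(volume.data).dtype)
    return Volume(data, reference.spacing, reference.origin)
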