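"""Per-material path lengths from subsampled sources to subsampled detectors.

Rays run from every focal-spot subsample to the center of every subsampled
detector element at every angular subsample of every view.  Path lengths per
material are exact voxel-traversal (Siddon-style) intersection lengths, not
interpolation samples, so analytic chord oracles hold to one-voxel accuracy.
Rotation is realized by rotating the source/detector about the z-axis; the
phantom stays fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .config import FocalSpot, ScannerGeometry, SubsamplingScheme
from .phantoms import VoxelPhantom

__all__ = ["ThicknessMaps", "trace_thickness_maps",
           "rebin_detector_subsamples", "block_average", "ray_endpoints"]


@dataclass
class ThicknessMaps:
    """Intersection lengths T in mm.

    ``data`` has axes ``(material, focal_subsample, angular_subsample, view,
    row_subsample, channel_subsample)``; the two detector axes are the
    subsampled grid (``n_rows*M``, ``n_channels*M``).
    """

    data: np.ndarray
    materials: tuple[str, ...]
    scheme: SubsamplingScheme
    view_angles_rad: np.ndarray
    geometry: ScannerGeometry

    def __post_init__(self):
        if self.data.ndim != 6:
            raise ValueError("thickness maps must be 6-D")
        if not np.isfinite(self.data).all():
            raise RuntimeError("non-finite value in thickness maps")


@njit(cache=True)
def _trace_kernel(p0, p1, origin, vox, labels, out):  # pragma: no cover
    """Accumulate per-material path lengths for each ray.

    p0, p1: (n, 3) ray endpoints in (x, y, z) mm; origin: low grid corner
    (x, y, z); vox: (dx, dy, dz); labels: (nz, ny, nx); out: (n_mat, n).
    """
    nz, ny, nx = labels.shape
    eps = 1e-12
    for r in range(p0.shape[0]):
        x0 = p0[r, 0]; y0 = p0[r, 1]; z0 = p0[r, 2]
        dx = p1[r, 0] - x0; dy = p1[r, 1] - y0; dz = p1[r, 2] - z0
        length = np.sqrt(dx * dx + dy * dy + dz * dz)
        if length <= 0.0:
            continue
        tmin = 0.0
        tmax = 1.0
        ok = True
        # slab clipping against the grid box
        for ax in range(3):
            if ax == 0:
                p = x0; d = dx; o = origin[0]; ext = nx * vox[0]
            elif ax == 1:
                p = y0; d = dy; o = origin[1]; ext = ny * vox[1]
            else:
                p = z0; d = dz; o = origin[2]; ext = nz * vox[2]
            if abs(d) < eps:
                if p < o or p > o + ext:
                    ok = False
                    break
            else:
                t1 = (o - p) / d
                t2 = (o + ext - p) / d
                if t1 > t2:
                    t1, t2 = t2, t1
                if t1 > tmin:
                    tmin = t1
                if t2 < tmax:
                    tmax = t2
        if not ok or tmin >= tmax:
            continue
        t = tmin
        # entry voxel from a point just inside
        tprobe = tmin + 1e-9 * (tmax - tmin)
        ix = int((x0 + tprobe * dx - origin[0]) / vox[0])
        iy = int((y0 + tprobe * dy - origin[1]) / vox[1])
        iz = int((z0 + tprobe * dz - origin[2]) / vox[2])
        if ix < 0: ix = 0
        if iy < 0: iy = 0
        if iz < 0: iz = 0
        if ix > nx - 1: ix = nx - 1
        if iy > ny - 1: iy = ny - 1
        if iz > nz - 1: iz = nz - 1
        # next crossing parameter and parameter step per axis
        big = 1e300
        if abs(dx) < eps:
            tx = big; dtx = big; sx = 0
        else:
            sx = 1 if dx > 0 else -1
            nxt = ix + 1 if dx > 0 else ix
            tx = (origin[0] + nxt * vox[0] - x0) / dx
            dtx = vox[0] / abs(dx)
        if abs(dy) < eps:
            ty = big; dty = big; sy = 0
        else:
            sy = 1 if dy > 0 else -1
            nxt = iy + 1 if dy > 0 else iy
            ty = (origin[1] + nxt * vox[1] - y0) / dy
            dty = vox[1] / abs(dy)
        if abs(dz) < eps:
            tz = big; dtz = big; sz = 0
        else:
            sz = 1 if dz > 0 else -1
            nxt = iz + 1 if dz > 0 else iz
            tz = (origin[2] + nxt * vox[2] - z0) / dz
            dtz = vox[2] / abs(dz)
        while t < tmax - eps:
            tnext = tx
            if ty < tnext:
                tnext = ty
            if tz < tnext:
                tnext = tz
            if tnext > tmax:
                tnext = tmax
            seg = (tnext - t) * length
            if seg > 0.0:
                m = labels[iz, iy, ix]
                out[m, r] += seg
            t = tnext
            if t >= tmax - eps:
                break
            stop = False
            if tx <= tnext + eps:
                ix += sx
                tx += dtx
                if ix < 0 or ix >= nx:
                    stop = True
            if ty <= tnext + eps:
                iy += sy
                ty += dty
                if iy < 0 or iy >= ny:
                    stop = True
            if tz <= tnext + eps:
                iz += sz
                tz += dtz
                if iz < 0 or iz >= nz:
                    stop = True
            if stop:
                break


def ray_endpoints(geometry: ScannerGeometry, focal: FocalSpot,
                  scheme: SubsamplingScheme, view_angle_rad: float):
    """Ray endpoints for one view.

    Returns ``(p0, p1)`` of shape ``(L*L, K, n_rows*M, n_channels*M, 3)``:
    focal-spot subsample positions and subsampled detector-element centers,
    in the lab frame (x, y, z) in mm.

    Focal subsamples sit on an L x L uniform grid centered on the nominal
    source point (width tangential in-plane, length axial).  The K angular
    subsamples sit at the centers of K equal sub-intervals of the view
    window.  Channel subsamples follow the equiangular curved detector;
    row subsamples are equally spaced in z.
    """
    L, K, M = scheme.L, scheme.K, scheme.M
    g = geometry
    span = g.view_angular_span_rad
    beta = view_angle_rad + ((np.arange(K) + 0.5) / K - 0.5) * span  # (K,)

    # subsampled detector coordinates
    ns_ch = g.n_channels * M
    gamma = (np.arange(ns_ch) - (ns_ch - 1) / 2.0) * (g.channel_angular_pitch_rad / M)
    ns_row = g.n_rows * M
    zdet = (np.arange(ns_row) - (ns_row - 1) / 2.0) * (g.row_pitch_mm / M)

    # focal-spot subsample offsets: (L*L,) tangential u and axial w
    off = (np.arange(L) + 0.5) / L - 0.5
    u = (off * focal.width_mm)[:, None].repeat(L, 1).ravel()
    w = (off * focal.length_mm)[None, :].repeat(L, 0).ravel()

    cosb, sinb = np.cos(beta), np.sin(beta)  # (K,)
    S = g.source_to_isocenter_mm * np.stack([cosb, sinb, np.zeros(K)], -1)
    d0 = np.stack([-cosb, -sinb, np.zeros(K)], -1)      # central-ray direction
    that = np.stack([-sinb, cosb, np.zeros(K)], -1)     # tangential unit

    # sources: (L2, K, 3)
    p0 = (S[None] + u[:, None, None] * that[None]
          + w[:, None, None] * np.array([0.0, 0.0, 1.0]))

    # detector points: (K, ns_row, ns_ch, 3)
    cg, sg = np.cos(gamma), np.sin(gamma)  # (ns_ch,)
    ux = d0[:, None, 0] * cg[None] - d0[:, None, 1] * sg[None]    # (K, ns_ch)
    uy = d0[:, None, 0] * sg[None] + d0[:, None, 1] * cg[None]
    Px = S[:, 0, None] + g.source_to_detector_mm * ux             # (K, ns_ch)
    Py = S[:, 1, None] + g.source_to_detector_mm * uy
    p1 = np.empty((K, ns_row, ns_ch, 3))
    p1[..., 0] = Px[:, None, :]
    p1[..., 1] = Py[:, None, :]
    p1[..., 2] = zdet[None, :, None]

    p0_full = np.broadcast_to(p0[:, :, None, None, :],
                              (L * L, K, ns_row, ns_ch, 3))
    p1_full = np.broadcast_to(p1[None], (L * L, K, ns_row, ns_ch, 3))
    return p0_full, p1_full


def trace_thickness_maps(phantom: VoxelPhantom, geometry: ScannerGeometry,
                         focal: FocalSpot, scheme: SubsamplingScheme,
                         views_rad: np.ndarray) -> ThicknessMaps:
    """Trace the phantom for every view in ``views_rad``.

    Returns per-material intersection lengths on the full subsample grid.
    For long view lists call this in batches and stream the results; memory
    scales with ``L^2 * K * M^2 * n_rows * n_channels * len(views)``.
    """
    if phantom.labels.size == 0:
        raise ValueError("zero-size phantom")
    views = np.atleast_1d(np.asarray(views_rad, dtype=float))
    L, K, M = scheme.L, scheme.K, scheme.M
    n_mat = len(phantom.materials)
    ns_row, ns_ch = geometry.n_rows * M, geometry.n_channels * M
    out = np.zeros((n_mat, L * L, K, len(views), ns_row, ns_ch),
                   dtype=np.float32)
    origin = phantom.grid_origin_mm()
    dz, dy, dx = phantom.voxel_size_mm
    vox = np.array([dx, dy, dz])
    labels = phantom.labels
    for v, ang in enumerate(views):
        p0, p1 = ray_endpoints(geometry, focal, scheme, ang)
        n = p0.size // 3
        buf = np.zeros((n_mat, n))
        _trace_kernel(np.ascontiguousarray(p0.reshape(n, 3)),
                      np.ascontiguousarray(p1.reshape(n, 3)),
                      origin, vox, labels, buf)
        out[:, :, :, v] = buf.reshape(n_mat, L * L, K, ns_row, ns_ch)
    if not np.isfinite(out).all():
        raise RuntimeError("non-finite path length produced by the ray tracer")
    return ThicknessMaps(out, phantom.materials, scheme, views, geometry)


def block_average(arr: np.ndarray, factor: int) -> np.ndarray:
    """Block-average the last two axes by ``factor`` (shape must divide)."""
    if factor == 1:
        return arr
    *lead, ny, nx = arr.shape
    if ny % factor or nx % factor:
        raise ValueError(f"detector axes {(ny, nx)} not divisible by {factor}")
    a = arr.reshape(*lead, ny // factor, factor, nx // factor, factor)
    return a.mean(axis=(-3, -1))


def rebin_detector_subsamples(maps: ThicknessMaps, m_lo: int) -> ThicknessMaps:
    """Rebin detector subsamples from the traced M down to ``m_lo``.

    Block-averages (M/m_lo)^2 subsamples per target element; used when the
    tracing is run at a higher detector subsampling than the rest of the
    pipeline (thin-wire phantoms).
    """
    m_hi = maps.scheme.M
    if m_hi % m_lo:
        raise ValueError(f"M={m_hi} not divisible by target M={m_lo}")
    data = block_average(maps.data, m_hi // m_lo)
    scheme = SubsamplingScheme(maps.scheme.L, maps.scheme.K, m_lo)
    return ThicknessMaps(np.ascontiguousarray(data, dtype=np.float32),
                         maps.materials, scheme, maps.view_angles_rad,
                         maps.geometry)
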