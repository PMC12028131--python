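"""Standardized vertebra coordinate frame and 2D length measurements.

Every measurement is taken in a vertebra-local frame built from anatomy:
the superior endplate plane of the vertebral body defines the SI axis,
the line joining the pedicle centroids defines RL (orthogonalized
against SI), and AP = SI x RL completes a right-handed triad anchored at
the body centroid.  Ten named lengths are then read off analytic mesh
cross-sections (plane-mesh intersections, not voxel counts) for
sub-voxel accuracy:

* anterior / posterior body heights in the midsagittal plane,
* body width (RL) and length (AP) in axial planes inset 2 mm from each
  endplate,
* width and height of each pedicle in the narrowest cross-section plane
  along its screw-like trajectory (the mask's principal axis; the
  narrowest plane minimizes cross-sectional area),
* the longest straight center line of the spinous process over a sweep
  of oblique near-axial planes rotated about RL.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import trimesh

from .volio import LabelVolume, VoxelVolume

__all__ = [
    "VertebraFrame",
    "MorphometryRecord",
    "MEASUREMENT_FIELDS",
    "fit_endplate_plane",
    "build_frame",
    "body_heights",
    "body_width_length",
    "pedicle_dimensions",
    "spinous_length",
    "measure_vertebra",
]

MEASUREMENT_FIELDS = (
    "body_height_anterior",
    "body_height_posterior",
    "body_width_superior",
    "body_width_inferior",
    "body_length_superior",
    "body_length_inferior",
    "pedicle_width_L",
    "pedicle_height_L",
    "pedicle_width_R",
    "pedicle_height_R",
    "spinous_length",
)


@dataclass
class VertebraFrame:
    """Orthonormal vertebra-local frame: origin at the body centroid."""

    origin: np.ndarray
    SI: np.ndarray
    RL: np.ndarray
    AP: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        for name in ("SI", "RL", "AP"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v / np.linalg.norm(v))
        dots = [abs(self.SI @ self.RL), abs(self.SI @ self.AP), abs(self.RL @ self.AP)]
        if max(dots) > 1e-9:
            raise ValueError(f"frame axes are not orthonormal: |dot| up to {max(dots):.2e}")


@dataclass
class MorphometryRecord:
    """The named 2D length measurements of one vertebra, in mm.

    Fields left ``None`` were not measurable (e.g. a missing part label);
    they are flagged as absent rather than fabricated.
    """

    name: str = ""
    body_height_anterior: float | None = None
    body_height_posterior: float | None = None
    body_width_superior: float | None = None
    body_width_inferior: float | None = None
    body_length_superior: float | None = None
    body_length_inferior: float | None = None
    pedicle_width_L: float | None = None
    pedicle_height_L: float | None = None
    pedicle_width_R: float | None = None
    pedicle_height_R: float | None = None
    spinous_length: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MorphometryRecord":
        return cls(**{k: d.get(k) for k in ("name",) + MEASUREMENT_FIELDS})

    def present_fields(self) -> dict[str, float]:
        out = {}
        for k in MEASUREMENT_FIELDS:
            v = getattr(self, k)
            if v is not None:
                out[k] = float(v)
        return out


# ---------------------------------------------------------------------------
# Cross-section helpers: plane/mesh intersection segments, no loop ordering
# needed — chords and areas are computed directly from unordered segments.

def _section_2d(
    mesh: trimesh.Trimesh, origin: np.ndarray, e1: np.ndarray, e2: np.ndarray
) -> np.ndarray | None:
    """Intersection segments of the plane spanned by (e1, e2) through origin,
    projected to that in-plane basis.  Returns (n, 2, 2) or None if empty."""
    normal = np.cross(e1, e2)
    segs = trimesh.intersections.mesh_plane(mesh, plane_normal=normal, plane_origin=origin)
    if len(segs) == 0:
        return None
    rel = segs - origin
    return np.stack([rel @ e1, rel @ e2], axis=-1)


def _chords(segs2d: np.ndarray, a_samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Extent of the section along the second in-plane axis at each first-axis
    sample: min/max crossing of the vertical line a = a_i (nan if no crossing)."""
    a1 = segs2d[:, 0, 0][:, None]
    a2 = segs2d[:, 1, 0][:, None]
    b1 = segs2d[:, 0, 1][:, None]
    b2 = segs2d[:, 1, 1][:, None]
    a0 = np.asarray(a_samples)[None, :]
    da = a2 - a1
    crosses = ((a1 - a0) * (a2 - a0) <= 0) & (np.abs(da) > 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.clip((a0 - a1) / da, 0.0, 1.0)
    b = b1 + t * (b2 - b1)
    lo = np.where(crosses, b, np.inf).min(axis=0)
    hi = np.where(crosses, b, -np.inf).max(axis=0)
    lo[~np.isfinite(lo)] = np.nan
    hi[~np.isfinite(hi)] = np.nan
    return lo, hi


def _section_area(segs2d: np.ndarray, n_samples: int = 80) -> float:
    """Cross-section area by chord integration (valid for sections whose
    vertical extent is a single interval, true for the convex-ish parts)."""
    amin = segs2d[..., 0].min()
    amax = segs2d[..., 0].max()
    if amax - amin < 1e-9:
        return 0.0
    a = np.linspace(amin, amax, n_samples)
    lo, hi = _chords(segs2d, a)
    widths = np.nan_to_num(hi - lo, nan=0.0)
    return float(np.trapezoid(widths, a))


def _mask_points(mask: VoxelVolume) -> np.ndarray:
    idx = np.argwhere(mask.data > 0)
    if len(idx) == 0:
        raise ValueError("mask is empty")
    return mask.index_to_world(idx)


def _mesh_of(mask: VoxelVolume) -> trimesh.Trimesh:
    from .surfdist import extract_mesh

    return extract_mesh(mask).to_trimesh()


# ---------------------------------------------------------------------------
# Frame construction

def _endplate_points(body_mask: VoxelVolume, superior: bool) -> np.ndarray:
    """Boundary voxels of one endplate: the outermost body voxel of each
    (RL, AP) column, restricted to the extreme 15% of the body's SI extent."""
    data = body_mask.data > 0
    if not data.any():
        raise ValueError("body mask is empty")
    nz = data.any(axis=2)
    ii, jj = np.nonzero(nz)
    if superior:
        kk = data.shape[2] - 1 - np.argmax(data[ii, jj, ::-1], axis=1)
    else:
        kk = np.argmax(data[ii, jj, :], axis=1)
    k_occ = np.argwhere(data.any(axis=(0, 1)))
    extent = max(int(k_occ.max() - k_occ.min()), 1)
    if superior:
        keep = kk >= kk.max() - 0.15 * extent
    else:
        keep = kk <= kk.min() + 0.15 * extent
    return body_mask.index_to_world(np.column_stack([ii[keep], jj[keep], kk[keep]]))


def fit_endplate_plane(body_mask: VoxelVolume) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through the superior endplate of the vertebral body.

    Candidate points are the topmost body voxel of each (RL, AP) column,
    restricted to the top 15% of the body's SI extent; the plane is fit as
    z = a x + b y + c and the normal oriented superiorly.
    """
    pts = _endplate_points(body_mask, superior=True)
    if len(pts) < 3:
        raise ValueError("too few endplate points to fit a plane")
    # trimmed re-fitting: at larger scan tilts the top-voxel set also picks
    # up the downhill lateral wall, which sits well below the endplate plane
    keep = np.ones(len(pts), dtype=bool)
    coef = None
    for _ in range(4):
        sel = pts[keep]
        A = np.column_stack([sel[:, 0], sel[:, 1], np.ones(len(sel))])
        coef, _, rank, _ = np.linalg.lstsq(A, sel[:, 2], rcond=None)
        if rank < 3:
            raise ValueError("degenerate endplate point set (collinear)")
        resid = pts[:, 2] - (pts[:, 0] * coef[0] + pts[:, 1] * coef[1] + coef[2])
        med = np.median(resid)
        sigma = 1.4826 * np.median(np.abs(resid - med))
        tol = 3.0 * max(sigma, 0.5 * min(body_mask.spacing))
        new_keep = np.abs(resid - med) <= tol
        if new_keep.sum() < 3 or (new_keep == keep).all():
            break
        keep = new_keep
    normal = np.array([-coef[0], -coef[1], 1.0])
    normal /= np.linalg.norm(normal)
    return pts[keep].mean(axis=0), normal


def build_frame(
    body_mask: VoxelVolume,
    pedicle_L_mask: VoxelVolume,
    pedicle_R_mask: VoxelVolume,
) -> VertebraFrame:
    """Anatomy-derived frame: SI from the endplate normal, RL from the
    left-to-right pedicle centroid line (orthogonalized against SI),
    AP = SI x RL, origin at the body centroid."""
    _, SI = fit_endplate_plane(body_mask)
    cl = _mask_points(pedicle_L_mask).mean(axis=0)
    cr = _mask_points(pedicle_R_mask).mean(axis=0)
    raw = cr - cl
    norm = np.linalg.norm(raw)
    if norm < 1e-6:
        raise ValueError("pedicle centroids coincide; cannot define the RL axis")
    raw /= norm
    if abs(raw @ SI) > np.sin(np.deg2rad(60.0)):
        raise ValueError("pedicle line is nearly parallel to SI; anatomy implausible")
    RL = raw - (raw @ SI) * SI
    RL /= np.linalg.norm(RL)
    AP = np.cross(SI, RL)
    origin = _mask_points(body_mask).mean(axis=0)
    return VertebraFrame(origin=origin, SI=SI, RL=RL, AP=AP)


# ---------------------------------------------------------------------------
# Measurements

_BAND_FRACTION = 0.10  # extreme-AP band for anterior/posterior heights
_ENDPLATE_INSET = 2.0  # mm, axial planes inset from the endplates
_N_BAND_SAMPLES = 15


def _body_heights_mesh(frame: VertebraFrame, body: trimesh.Trimesh) -> tuple[float, float]:
    segs = _section_2d(body, frame.origin, frame.AP, frame.SI)
    if segs is None:
        raise ValueError("midsagittal plane misses the vertebral body")
    umin, umax = segs[..., 0].min(), segs[..., 0].max()
    span = umax - umin
    # midpoint sampling keeps the tangent corners of the section out of the bands
    offsets = (np.arange(_N_BAND_SAMPLES) + 0.5) / _N_BAND_SAMPLES * _BAND_FRACTION * span
    heights = []
    for band in (umax - offsets, umin + offsets):  # anterior, posterior
        lo, hi = _chords(segs, band)
        ext = hi - lo
        ext = ext[np.isfinite(ext)]
        if len(ext) == 0:
            raise ValueError("empty height band in the midsagittal section")
        # the longest chord in the band is the wall height; shorter chords in
        # the band belong to the rounded corner region of the section
        heights.append(float(ext.max()))
    return heights[0], heights[1]


def body_heights(frame: VertebraFrame, body_mask: VoxelVolume) -> tuple[float, float]:
    """Anterior and posterior vertebral body heights (mm) in the midsagittal
    plane, averaged over the extreme 10% AP bands."""
    return _body_heights_mesh(frame, _mesh_of(body_mask))


def _body_width_length_mesh(
    frame: VertebraFrame, mask: VoxelVolume, body: trimesh.Trimesh
) -> tuple[float, float, float, float]:
    # station each axial plane 2 mm inside the endplate surface, measured
    # where the endplate crosses the SI axis: robust both to endplates
    # oblique to SI (which would clip a plane referenced to the extreme
    # vertex) and to domed surfaces such as a ball phantom
    def axis_level(superior: bool) -> float:
        rel = _endplate_points(mask, superior) - frame.origin
        s = rel @ frame.SI
        radius = np.linalg.norm(rel - s[:, None] * frame.SI, axis=1)
        central = radius <= np.percentile(radius, 10)
        return float(s[central].mean())

    out = []
    for station in (
        axis_level(superior=True) - _ENDPLATE_INSET,
        axis_level(superior=False) + _ENDPLATE_INSET,
    ):
        origin = frame.origin + station * frame.SI
        segs = _section_2d(body, origin, frame.RL, frame.AP)
        if segs is None:
            raise ValueError("endplate-offset axial plane misses the vertebral body")
        # centroid of the section, then chords through it along RL and AP
        ca = 0.5 * (segs[..., 0].min() + segs[..., 0].max())
        cb = 0.5 * (segs[..., 1].min() + segs[..., 1].max())
        lo, hi = _chords(segs, np.array([ca]))
        length = float(hi[0] - lo[0])
        swapped = segs[:, :, ::-1]
        lo, hi = _chords(swapped, np.array([cb]))
        width = float(hi[0] - lo[0])
        out.extend([width, length])
    return out[0], out[2], out[1], out[3]  # width_sup, width_inf, length_sup, length_inf


def body_width_length(
    frame: VertebraFrame, body_mask: VoxelVolume
) -> tuple[float, float, float, float]:
    """(width_sup, length_sup, width_inf, length_inf): RL and AP chords of the
    body cross-section in axial planes inset 2 mm from each endplate."""
    ws, wi, ls, li = _body_width_length_mesh(frame, body_mask, _mesh_of(body_mask))
    return ws, ls, wi, li


def _section_centroid(segs2d: np.ndarray, n_samples: int = 40) -> tuple[float, float, float]:
    """(area, cx, cy) of a section by chord integration."""
    amin, amax = segs2d[..., 0].min(), segs2d[..., 0].max()
    if amax - amin < 1e-9:
        return 0.0, amin, float(segs2d[..., 1].mean())
    a = np.linspace(amin, amax, n_samples)
    lo, hi = _chords(segs2d, a)
    w = np.nan_to_num(hi - lo, nan=0.0)
    mid = np.nan_to_num(0.5 * (hi + lo), nan=0.0)
    area = np.trapezoid(w, a)
    if area <= 0:
        return 0.0, float(a.mean()), float(mid.mean())
    cx = np.trapezoid(w * a, a) / area
    cy = np.trapezoid(w * mid, a) / area
    return float(area), float(cx), float(cy)


def _principal_axis(pts: np.ndarray) -> np.ndarray:
    cov = np.cov((pts - pts.mean(axis=0)).T)
    evals, evecs = np.linalg.eigh(cov)
    return evecs[:, np.argmax(evals)]


def _pedicle_sections(mesh, centroid, traj, e1, e2, step):
    t = (mesh.vertices - centroid) @ traj
    tmin, tmax = t.min(), t.max()
    span = tmax - tmin
    stations = np.arange(tmin + 0.1 * span, tmax - 0.1 * span + 1e-9, step)
    out = []
    for s in stations:
        segs = _section_2d(mesh, centroid + s * traj, e1, e2)
        if segs is not None:
            out.append((s, segs))
    return out, 0.5 * (tmin + tmax)


def _pedicle_dimensions_mesh(
    frame: VertebraFrame,
    mask: VoxelVolume,
    mesh: trimesh.Trimesh,
) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    pts = _mask_points(mask)
    idx = np.argwhere(mask.data > 0)
    if len(pts) < 3 or (idx.max(axis=0) - idx.min(axis=0) + 1).min() < 3:
        raise ValueError("pedicle too thin to sample")
    centroid = pts.mean(axis=0)
    traj = _principal_axis(pts)
    if traj @ frame.AP < 0:
        traj = -traj  # orient posterior -> anterior
    step = 0.5 * min(mask.spacing)

    def in_plane_basis(axis):
        e1 = frame.RL - (frame.RL @ axis) * axis
        e1 /= np.linalg.norm(e1)
        return e1, np.cross(axis, e1)

    # Refine the trajectory through the section centroids: complete
    # cross-sections of a straight canal are centered on its axis, so a
    # robust line fit through them undoes the bias that the flaring
    # body/lamina junctions impose on the raw second-moment axis.
    e1, e2 = in_plane_basis(traj)
    sections, _ = _pedicle_sections(mesh, centroid, traj, e1, e2, step)
    if len(sections) >= 5:
        cents = []
        for s, segs in sections:
            _, cx, cy = _section_centroid(segs)
            cents.append(centroid + s * traj + cx * e1 + cy * e2)
        cents = np.asarray(cents)
        axis = _principal_axis(cents)
        resid = np.linalg.norm(
            (cents - cents.mean(axis=0))
            - ((cents - cents.mean(axis=0)) @ axis)[:, None] * axis,
            axis=1,
        )
        keep = resid <= max(3.0 * np.median(resid), 0.5 * step)
        if keep.sum() >= 5:
            axis = _principal_axis(cents[keep])
        traj = axis if axis @ frame.AP >= 0 else -axis

    e1, e2 = in_plane_basis(traj)
    sections, mid = _pedicle_sections(mesh, centroid, traj, e1, e2, step)
    if not sections:
        raise ValueError("no valid cross-section plane found along the pedicle")
    areas = np.array([_section_area(segs) for _, segs in sections])
    smooth = np.convolve(areas, np.ones(3) / 3, mode="same") if len(areas) >= 3 else areas

    # the narrowest *complete* cross-section is an interior minimum of the
    # area profile; edge minima belong to the flaring junction cuts
    interior = np.zeros(len(areas), dtype=bool)
    if len(areas) >= 3:
        interior[1:-1] = (smooth[1:-1] <= smooth[:-2]) & (smooth[1:-1] <= smooth[2:])
    candidates = np.nonzero(interior)[0]
    if len(candidates) == 0:
        candidates = np.arange(len(areas))
    key = [(round(areas[i], 9), abs(sections[i][0] - mid)) for i in candidates]
    best = candidates[int(np.argmin(np.array(key, dtype=object)[:, 0]))]
    # ties broken toward mid-pedicle
    tied = [i for i in candidates if abs(areas[i] - areas[best]) < 1e-9]
    best = min(tied, key=lambda i: abs(sections[i][0] - mid))

    segs = sections[best][1]
    width = float(segs[..., 0].max() - segs[..., 0].min())
    height = float(segs[..., 1].max() - segs[..., 1].min())
    return width, height, (centroid, traj)


def pedicle_dimensions(
    frame: VertebraFrame, pedicle_mask: VoxelVolume, side: str = ""
) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    """Width (RL-like) and height of the narrowest pedicle cross-section.

    The trajectory is the principal second-moment axis of the pedicle mask
    (the screw-like axis); planes orthogonal to it are swept over the middle
    80% of its extent at half-voxel steps and the minimum-area plane is
    selected.  Returns (width, height, (point, direction)) with the
    trajectory line through the pedicle centroid.
    """
    return _pedicle_dimensions_mesh(frame, pedicle_mask, _mesh_of(pedicle_mask))


_SWEEP_DEG = np.arange(-45.0, 45.0 + 0.5, 1.0)


def _spinous_length_mesh(
    frame: VertebraFrame, mask: VoxelVolume, mesh: trimesh.Trimesh
) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    centroid = _mask_points(mask).mean(axis=0)
    step = 0.5 * min(mask.spacing)
    best_len = -np.inf
    best_plane = None
    for theta in np.deg2rad(_SWEEP_DEG):
        u = -np.cos(theta) * frame.AP - np.sin(theta) * frame.SI  # posterior-caudal
        segs = _section_2d(mesh, centroid, u, frame.RL)
        if segs is None:
            continue
        amin, amax = segs[..., 0].min(), segs[..., 0].max()
        n = max(int((amax - amin) / step), 8)
        a = np.linspace(amin, amax, n)
        lo, hi = _chords(segs, a)
        ok = np.isfinite(lo)
        if ok.sum() < 2:
            continue
        mid = 0.5 * (lo + hi)
        a_ok, m_ok = a[ok], mid[ok]
        span = float(np.hypot(a_ok[-1] - a_ok[0], m_ok[-1] - m_ok[0]))
        if span > best_len:
            best_len = span
            best_plane = (centroid, np.cross(u, frame.RL))
    if best_plane is None:
        raise ValueError("no plane in the sweep intersects the spinous process")
    return best_len, best_plane


def spinous_length(
    frame: VertebraFrame, spinous_mask: VoxelVolume
) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Longest straight center line of the spinous process.

    Near-axial planes through the spinous centroid are swept about the RL
    axis over +/-45 degrees in 1-degree steps; in each plane the center
    line is the locus of RL-chord midpoints and its straight-line span is
    the candidate length.  Returns (length, (plane point, plane normal)).
    """
    return _spinous_length_mesh(frame, spinous_mask, _mesh_of(spinous_mask))


# ---------------------------------------------------------------------------
# Full-record assembly

def measure_vertebra(instance) -> MorphometryRecord:
    """All ten measurements of a part-labeled vertebra instance.

    ``instance`` needs ``name``, ``mask`` and ``parts`` attributes (see the
    labeling module).  Missing parts leave the affected fields ``None``;
    a missing body or missing pedicle pair makes the frame impossible and
    raises instead.
    """
    parts: LabelVolume | None = getattr(instance, "parts", None)
    if parts is None:
        raise ValueError("instance carries no part labels")

    def part_mask(name: str) -> VoxelVolume | None:
        try:
            m = parts.mask_of(name)
        except KeyError:
            return None
        return m if m.data.any() else None

    body = part_mask("body")
    ped_l = part_mask("pedicle_L")
    ped_r = part_mask("pedicle_R")
    if body is None or ped_l is None or ped_r is None:
        raise ValueError("body and both pedicles are required to build the frame")

    frame = build_frame(body, ped_l, ped_r)
    rec = MorphometryRecord(name=getattr(instance, "name", "") or "")

    body_mesh = _mesh_of(body)
    rec.body_height_anterior, rec.body_height_posterior = _body_heights_mesh(frame, body_mesh)
    ws, wi, ls, li = _body_width_length_mesh(frame, body, body_mesh)
    rec.body_width_superior, rec.body_width_inferior = ws, wi
    rec.body_length_superior, rec.body_length_inferior = ls, li

    for side, mask in (("L", ped_l), ("R", ped_r)):
        w, h, _ = _pedicle_dimensions_mesh(frame, mask, _mesh_of(mask))
        setattr(rec, f"pedicle_width_{side}", w)
        setattr(rec, f"pedicle_height_{side}", h)

    spin = part_mask("spinous")
    if spin is not None:
        rec.spinous_length = _spinous_length_mesh(frame, spin, _mesh_of(spin))[0]
    return rec
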