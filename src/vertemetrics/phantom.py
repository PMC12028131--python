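"""Parametric vertebra/spine phantoms with analytically known morphometry.

Since paired patient CT / synthetic-CT scans are not publicly available,
validation runs on digital phantoms: each vertebra is a union of simple
solids — an elliptic-cylinder body with a tilted superior endplate (the
anterior/posterior height difference is a wedge cut of the top plane),
two elliptic-cylinder pedicles with a cosine mid-length constriction, a
lamina slab, a stadium-profile spinous process and two transverse-process
bars — rasterized by the voxel-center rule on a regular mm grid.

Every quantity the morphometry module measures is a closed-form function
of the :class:`PhantomSpec` alone, independent of pose and voxel spacing,
so parameter-recovery error can be scored exactly.  A separate
degradation model (signed boundary shift, spatially correlated surface
noise, pre-threshold blur) stands in for the sub-millimeter boundary
error of a synthetic-CT reconstruction.

Geometry is built in the canonical world frame: +x subject right (RL),
+y anterior (AP), +z superior (SI); the rigid ``pose`` is applied last.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .morphometry import MorphometryRecord
from .volio import LabelVolume, VoxelVolume

__all__ = [
    "Pose",
    "PhantomSpec",
    "DegradationSpec",
    "PART_IDS",
    "PART_NAMES",
    "rasterize_phantom",
    "rasterize_spine",
    "degrade",
    "ground_truth_measurements",
    "sample_spec",
    "ball_mask",
    "save_phantom",
]

# Anatomical part vocabulary.  Label overlap precedence (highest wins):
# body > pedicles > spinous > lamina > transverse.  The spinous process
# outranks the lamina so that its full stadium solid — whose base is
# anchored inside the lamina for connectivity — stays measurable end to end.
PART_IDS = {
    "body": 1,
    "pedicle_L": 2,
    "pedicle_R": 3,
    "lamina": 4,
    "spinous": 5,
    "transverse_L": 6,
    "transverse_R": 7,
    "sacrum": 8,
}
PART_NAMES = {v: k for k, v in PART_IDS.items()}
_PAINT_ORDER = ["transverse_L", "transverse_R", "lamina", "spinous", "pedicle_L", "pedicle_R", "body"]


@dataclass(frozen=True)
class Pose:
    """Rigid transform: intrinsic x-y-z Euler rotation (deg) then translation (mm)."""

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return pts @ self.matrix.T + np.asarray(self.translation)

    def invert(self, pts: np.ndarray) -> np.ndarray:
        return (pts - np.asarray(self.translation)) @ self.matrix


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one vertebra (all lengths in mm).

    ``pedicle_width``/``pedicle_height`` are the nominal (end) cross-section
    extents of each pedicle; the waist of the cosine constriction scales
    both by ``pedicle_constriction``, and that constricted section is what
    the ground-truth record reports.
    """

    name: str = "L4"
    body_height_anterior: float = 27.0
    body_height_posterior: float = 29.0
    body_width: float = 42.0
    body_length: float = 32.0
    pedicle_width: float = 9.0
    pedicle_height: float = 13.0
    pedicle_constriction: float = 0.8
    pedicle_length: float = 14.0
    pedicle_cant_deg: float = 10.0
    spinous_length: float = 32.0
    spinous_tilt_deg: float = 15.0
    spinous_height: float = 10.0
    transverse_length: float = 25.0
    lamina_thickness: float = 6.0
    pose: Pose = field(default_factory=Pose)
    seed: int = 0

    def validate(self) -> None:
        lengths = {
            k: getattr(self, k)
            for k in (
                "body_height_anterior",
                "body_height_posterior",
                "body_width",
                "body_length",
                "pedicle_width",
                "pedicle_height",
                "pedicle_length",
                "spinous_length",
                "spinous_tilt_deg",
                "spinous_height",
                "transverse_length",
                "lamina_thickness",
            )
        }
        lengths.pop("spinous_tilt_deg")
        bad = {k: v for k, v in lengths.items() if v <= 0}
        if bad:
            raise ValueError(f"all lengths must be positive: {bad}")
        if not (0.0 < self.pedicle_constriction <= 1.0):
            raise ValueError("pedicle_constriction must lie in (0, 1]")
        if self.spinous_length <= self.spinous_height:
            raise ValueError("spinous_length must exceed spinous_height (stadium profile)")
        # left/right pedicles must stay clear of each other at every station
        clearance = 2 * self._pedicle_offset_x() - self.pedicle_width
        if clearance <= 0.5:
            raise ValueError(
                f"left/right pedicles overlap (clearance {clearance:.2f} mm); "
                "reduce pedicle_width or widen the body"
            )

    def _pedicle_offset_x(self) -> float:
        return 0.30 * self.body_width

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        pose = d.pop("pose", None)
        if pose is not None:
            pose = Pose(tuple(pose["rotation_deg"]), tuple(pose["translation"]))
        return cls(**d, pose=pose or Pose())


@dataclass(frozen=True)
class DegradationSpec:
    """Surface-error model standing in for synthetic-CT reconstruction error.

    ``boundary_shift_mm`` dilates (positive) or erodes (negative) the bone
    surface uniformly; ``noise_amplitude_mm`` adds a zero-mean displacement
    field with spatial correlation length ``noise_correlation_mm``;
    ``smoothing_mm`` is a Gaussian pre-threshold blur.  The all-zero spec is
    the identity, voxel for voxel.
    """

    boundary_shift_mm: float = 0.0
    noise_amplitude_mm: float = 0.0
    noise_correlation_mm: float = 3.0
    smoothing_mm: float = 0.0
    seed: int = 0

    def is_identity(self) -> bool:
        return (
            self.boundary_shift_mm == 0.0
            and self.noise_amplitude_mm == 0.0
            and self.smoothing_mm == 0.0
        )


# ---------------------------------------------------------------------------
# Solid construction

Solid = tuple[str, Callable[[np.ndarray], np.ndarray], np.ndarray]  # (part, inside(pts), local bbox)


def _box_bbox(lo, hi) -> np.ndarray:
    return np.array([lo, hi], dtype=float)


def _vertebra_solids(spec: PhantomSpec) -> list[Solid]:
    ha, hp = spec.body_height_anterior, spec.body_height_posterior
    W, L = spec.body_width, spec.body_length
    hbar = 0.5 * (ha + hp)
    wedge = (ha - hp) / L  # slope of the superior endplate along +y

    def body_inside(p: np.ndarray) -> np.ndarray:
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        in_ellipse = (x / (W / 2)) ** 2 + (y / (L / 2)) ** 2 <= 1.0
        z_top = hbar / 2 + wedge * y
        return in_ellipse & (z >= -hbar / 2) & (z <= z_top)

    body_bbox = _box_bbox(
        [-W / 2, -L / 2, -hbar / 2], [W / 2, L / 2, hbar / 2 + abs(ha - hp) / 2]
    )
    solids: list[Solid] = [("body", body_inside, body_bbox)]

    # pedicles: elliptic cylinders from the posterior body, diverging
    # laterally by the cant angle, waist scaled by the constriction factor
    w, h = spec.pedicle_width, spec.pedicle_height
    c = spec.pedicle_constriction
    Lp = spec.pedicle_length
    cant = np.deg2rad(spec.pedicle_cant_deg)
    xp = spec._pedicle_offset_x()
    y_att = -0.75 * (L / 2)

    def make_pedicle(s: float):
        p0 = np.array([s * xp, y_att, 0.0])
        d = np.array([s * np.sin(cant), -np.cos(cant), 0.0])
        e_w = np.array([d[1], -d[0], 0.0])
        e_w /= np.linalg.norm(e_w)

        def inside(p: np.ndarray) -> np.ndarray:
            q = p - p0
            t = q @ d
            ok = (t >= 0) & (t <= Lp)
            scale = 1.0 - (1.0 - c) * np.sin(np.pi * np.clip(t, 0, Lp) / Lp) ** 2
            u = q @ e_w
            v = q[:, 2]
            au = (w / 2) * scale
            av = (h / 2) * scale
            return ok & ((u / au) ** 2 + (v / av) ** 2 <= 1.0)

        p1 = p0 + Lp * d
        lo = np.minimum(p0, p1) - [w / 2, w / 2, h / 2]
        hi = np.maximum(p0, p1) + [w / 2, w / 2, h / 2]
        return inside, _box_bbox(lo, hi)

    for side, s in (("pedicle_L", -1.0), ("pedicle_R", +1.0)):
        fn, bb = make_pedicle(s)
        solids.append((side, fn, bb))

    # lamina: posterior slab bridging the pedicle ends
    T = spec.lamina_thickness
    y_f = y_att - Lp * np.cos(cant) + 1.0  # 1 mm overlap with the pedicle ends
    xl = xp + Lp * np.sin(cant) + w / 2

    def lamina_inside(p: np.ndarray) -> np.ndarray:
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        return (np.abs(x) <= xl) & (y <= y_f) & (y >= y_f - T) & (np.abs(z) <= h / 2)

    solids.append(("lamina", lamina_inside, _box_bbox([-xl, y_f - T, -h / 2], [xl, y_f, h / 2])))

    # spinous process: extruded stadium whose tip-to-tip axial span equals
    # spinous_length; the base cap is anchored mid-lamina for connectivity
    S = spec.spinous_length
    r = spec.spinous_height / 2
    tau = np.deg2rad(spec.spinous_tilt_deg)
    ds = np.array([0.0, -np.cos(tau), -np.sin(tau)])
    A = np.array([0.0, y_f - T / 2, 0.0]) + r * ds  # tip of base cap sits at y_f - T/2
    seg = S - 2 * r
    B = A + seg * ds
    half_w = spec.lamina_thickness / 2

    def spinous_inside(p: np.ndarray) -> np.ndarray:
        q = p - A
        t = np.clip(q @ ds, 0.0, seg)
        close = A + t[:, None] * ds
        dd = p - close
        return (np.abs(p[:, 0]) <= half_w) & (dd[:, 1] ** 2 + dd[:, 2] ** 2 <= r**2)

    lo = np.minimum(A, B) - [half_w, r, r]
    hi = np.maximum(A, B) + [half_w, r, r]
    solids.append(("spinous", spinous_inside, _box_bbox(lo, hi)))

    # transverse processes: lateral bars at lamina level
    TL = spec.transverse_length
    x0 = xl - 2.0

    def make_transverse(s: float):
        def inside(p: np.ndarray) -> np.ndarray:
            x, y, z = p[:, 0], p[:, 1], p[:, 2]
            return (
                (s * x >= x0)
                & (s * x <= x0 + TL)
                & (y <= y_f)
                & (y >= y_f - T)
                & (np.abs(z) <= 4.0)
            )

        lo = [min(s * x0, s * (x0 + TL)), y_f - T, -4.0]
        hi = [max(s * x0, s * (x0 + TL)), y_f, 4.0]
        return inside, _box_bbox(lo, hi)

    for side, s in (("transverse_L", -1.0), ("transverse_R", +1.0)):
        fn, bb = make_transverse(s)
        solids.append((side, fn, bb))

    return solids


def _sacrum_solids(extents: tuple[float, float, float], z_base: float) -> list[Solid]:
    """Sacrum stand-in: a wide elliptic cylinder, the inferior reference blob."""
    W, L, H = extents

    def inside(p: np.ndarray) -> np.ndarray:
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        return ((x / (W / 2)) ** 2 + (y / (L / 2)) ** 2 <= 1.0) & (z >= z_base) & (z <= z_base + H)

    return [("sacrum", inside, _box_bbox([-W / 2, -L / 2, z_base], [W / 2, L / 2, z_base + H]))]


# ---------------------------------------------------------------------------
# Rasterization

def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in np.broadcast_to(np.asarray(spacing, dtype=float), (3,)))
    if any(not (0.1 < s <= 2.0) for s in spacing):
        raise ValueError(f"voxel spacing must lie in (0.1, 2.0] mm, got {spacing}")
    return spacing


def _posed_bbox(bbox: np.ndarray, pose: Pose) -> np.ndarray:
    corners = np.array(np.meshgrid(*bbox.T, indexing="ij")).reshape(3, -1).T
    world = pose.apply(corners)
    return np.array([world.min(axis=0), world.max(axis=0)])


def _rasterize(
    solids: list[tuple[str, Callable, np.ndarray, Pose]],
    spacing: tuple[float, float, float],
    margin: float = 3.0,
) -> LabelVolume:
    sp = np.asarray(spacing)
    boxes = np.array([_posed_bbox(bb, pose) for _, _, bb, pose in solids])
    lo = boxes[:, 0, :].min(axis=0) - margin
    hi = boxes[:, 1, :].max(axis=0) + margin
    shape = np.ceil((hi - lo) / sp).astype(int) + 1
    origin = lo

    labels = np.zeros(tuple(shape), dtype=np.int16)
    order = {name: i for i, name in enumerate(_PAINT_ORDER)}
    order["sacrum"] = -1  # painted first, never overlaps vertebrae anyway
    for part, inside, bb, pose in sorted(solids, key=lambda s: order[s[0]]):
        wbb = _posed_bbox(bb, pose)
        i_lo = np.maximum(np.floor((wbb[0] - origin) / sp).astype(int) - 1, 0)
        i_hi = np.minimum(np.ceil((wbb[1] - origin) / sp).astype(int) + 1, shape - 1)
        if (i_hi < i_lo).any():
            continue
        axes = [origin[k] + sp[k] * np.arange(i_lo[k], i_hi[k] + 1) for k in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        mask = inside(pose.invert(pts)).reshape(gx.shape)
        sub = labels[i_lo[0] : i_hi[0] + 1, i_lo[1] : i_hi[1] + 1, i_lo[2] : i_hi[2] + 1]
        sub[mask] = PART_IDS[part]

    table = {PART_IDS[p]: p for p in {s[0] for s in solids}}
    return LabelVolume(labels, tuple(sp), tuple(origin), labels=table)


def rasterize_phantom(
    spec: PhantomSpec, spacing=0.5
) -> tuple[VoxelVolume, LabelVolume]:
    """Voxel-center rasterization of one vertebra.

    Returns the binary bone volume and the part label volume on the same
    grid; every bone voxel carries exactly one part label.
    """
    spacing = _check_spacing(spacing)
    spec.validate()
    solids = [(p, fn, bb, spec.pose) for p, fn, bb in _vertebra_solids(spec)]
    parts = _rasterize(solids, spacing)
    bone = VoxelVolume((parts.data > 0).astype(np.uint8), parts.spacing, parts.origin)
    return bone, parts


def rasterize_spine(
    specs: Sequence[PhantomSpec],
    sacrum: tuple[float, float, float] = (90.0, 55.0, 32.0),
    spacing=1.0,
    gap: float = 4.0,
) -> tuple[VoxelVolume, LabelVolume, list[MorphometryRecord]]:
    """Stack a sacrum and a list of vertebrae into one labeled column.

    The sacrum is the inferior-most component; vertebrae are stacked
    superiorly in list order with ``gap`` mm of clearance between the posed
    solids of consecutive levels, so connected components stay separate.
    """
    spacing = _check_spacing(spacing)
    if len(specs) == 0:
        raise ValueError("at least one vertebra spec is required")
    if gap <= max(spacing):
        raise ValueError(f"inter-vertebral gap {gap} mm must exceed the voxel spacing")

    solids: list[tuple[str, Callable, np.ndarray, Pose]] = []
    z_top = sacrum[2]
    for part, fn, bb in _sacrum_solids(sacrum, 0.0):
        solids.append((part, fn, bb, Pose()))

    truth: list[MorphometryRecord] = []
    for spec in specs:
        spec.validate()
        vsolids = _vertebra_solids(spec)
        # full z-extent of this vertebra under its own pose
        boxes = np.array([_posed_bbox(bb, spec.pose) for _, _, bb in vsolids])
        zmin, zmax = boxes[:, 0, 2].min(), boxes[:, 1, 2].max()
        dz = z_top + gap - zmin
        shift = Pose(
            spec.pose.rotation_deg,
            tuple(np.asarray(spec.pose.translation) + [0.0, 0.0, dz]),
        )
        solids.extend((p, fn, bb, shift) for p, fn, bb in vsolids)
        z_top = zmax + dz
        truth.append(ground_truth_measurements(spec))

    parts = _rasterize(solids, spacing)
    bone = VoxelVolume((parts.data > 0).astype(np.uint8), parts.spacing, parts.origin)

    n_comp = ndimage.label(bone.data, structure=np.ones((3, 3, 3)))[1]
    if n_comp != len(specs) + 1:
        raise ValueError(
            f"expected {len(specs) + 1} connected components (sacrum + vertebrae) "
            f"but found {n_comp}; the inter-vertebral gap of {gap} mm is too small "
            "for this spacing/pose combination"
        )
    return bone, parts, truth


def ground_truth_measurements(spec: PhantomSpec) -> MorphometryRecord:
    """Closed-form morphometry of the phantom; pose- and spacing-independent."""
    spec.validate()
    c = spec.pedicle_constriction
    return MorphometryRecord(
        name=spec.name,
        body_height_anterior=spec.body_height_anterior,
        body_height_posterior=spec.body_height_posterior,
        body_width_superior=spec.body_width,
        body_width_inferior=spec.body_width,
        body_length_superior=spec.body_length,
        body_length_inferior=spec.body_length,
        pedicle_width_L=c * spec.pedicle_width,
        pedicle_height_L=c * spec.pedicle_height,
        pedicle_width_R=c * spec.pedicle_width,
        pedicle_height_R=c * spec.pedicle_height,
        spinous_length=spec.spinous_length,
    )


# ---------------------------------------------------------------------------
# Degradation

def degrade(volume: VoxelVolume, d: DegradationSpec) -> VoxelVolume:
    """Simulate reconstruction error on a binary volume.

    Order of effects: Gaussian blur, uniform signed boundary shift,
    spatially correlated zero-mean surface displacement, re-threshold at
    0.5.  An all-zero spec returns the input voxel-for-voxel.  The boundary
    displacement is evaluated against the exact marching-cubes iso-surface,
    so sub-voxel shifts move the expected surface by the requested amount.
    """
    if not volume.is_binary():
        raise ValueError("degrade expects a binary volume")
    if d.is_identity():
        return volume.with_data(volume.data.copy())

    from .surfdist import extract_mesh, point_to_surface

    sp = np.asarray(volume.spacing)
    data = volume.data.astype(np.float32)
    if d.smoothing_mm > 0:
        data = ndimage.gaussian_filter(data, sigma=d.smoothing_mm / sp)
    base = data >= 0.5
    if not base.any():
        raise ValueError("degradation erased the volume before displacement")
    base_vol = volume.with_data(base.astype(np.uint8))

    # coarse signed distance to the iso-surface: voxel-center EDT shifted by
    # half a voxel (the marching-cubes boundary sits between voxel centers)
    h = float(sp.mean())
    inside = ndimage.distance_transform_edt(base, sampling=sp)
    outside = ndimage.distance_transform_edt(~base, sampling=sp)
    d_corr = np.where(base, -(inside - h / 2), outside - h / 2)

    threshold = np.full(volume.shape, d.boundary_shift_mm)
    if d.noise_amplitude_mm > 0:
        rng = np.random.default_rng(d.seed)
        white = rng.standard_normal(volume.shape)
        corr = ndimage.gaussian_filter(white, sigma=d.noise_correlation_mm / sp)
        corr /= corr.std()
        threshold = threshold + d.noise_amplitude_mm * corr

    out = d_corr <= threshold
    # the coarse decision can only be wrong within ~a voxel of the displaced
    # boundary; refine that band against the exact iso-surface distance
    band = np.abs(d_corr - threshold) <= 0.9 * sp.max()
    idx = np.argwhere(band)
    if len(idx):
        mesh = extract_mesh(base_vol)
        pts = base_vol.index_to_world(idx)
        exact = point_to_surface(pts, mesh)
        d_signed = np.where(base[tuple(idx.T)], -exact, exact)
        out[tuple(idx.T)] = d_signed <= threshold[tuple(idx.T)]
    if not out.any():
        raise ValueError("degradation erased the volume")
    return volume.with_data(out.astype(np.uint8))


# ---------------------------------------------------------------------------
# Cohort sampling and convenience

def sample_spec(rng: np.random.Generator, name: str = "L4", tilt_deg: float = 0.0) -> PhantomSpec:
    """Draw a plausible lumbar vertebra spec from the study-like parameter ranges.

    Body heights span 22-34 mm, widths 35-50 mm, nominal pedicle widths
    8-12 mm with constriction 0.72-0.92 (so constricted widths span roughly
    6-11 mm) and spinous lengths 25-40 mm.  ``tilt_deg`` bounds a uniform
    random rotation about each axis.
    """
    hbar = rng.uniform(23.0, 33.0)
    dh = rng.uniform(-1.5, 1.5)
    rot = tuple(rng.uniform(-tilt_deg, tilt_deg, 3)) if tilt_deg else (0.0, 0.0, 0.0)
    return PhantomSpec(
        name=name,
        body_height_anterior=hbar + dh,
        body_height_posterior=hbar - dh,
        body_width=rng.uniform(35.0, 50.0),
        body_length=rng.uniform(28.0, 36.0),
        pedicle_width=rng.uniform(8.0, 12.0),
        pedicle_height=rng.uniform(11.0, 15.0),
        pedicle_constriction=rng.uniform(0.72, 0.92),
        pedicle_length=rng.uniform(12.0, 16.0),
        pedicle_cant_deg=rng.uniform(5.0, 15.0),
        spinous_length=rng.uniform(25.0, 40.0),
        spinous_tilt_deg=rng.uniform(5.0, 22.0),
        transverse_length=rng.uniform(20.0, 30.0),
        lamina_thickness=rng.uniform(5.0, 7.0),
        pose=Pose(rotation_deg=rot),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def ball_mask(radius: float, spacing=0.5, margin: float = 3.0) -> VoxelVolume:
    """Binary ball phantom used by the metric calibration checks."""
    spacing = _check_spacing(spacing)
    sp = np.asarray(spacing)
    lo = -radius - margin
    n = np.ceil((2 * (radius + margin)) / sp).astype(int) + 1
    axes = [lo + sp[k] * np.arange(n[k]) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    data = (gx**2 + gy**2 + gz**2 <= radius**2).astype(np.uint8)
    return VoxelVolume(data, tuple(sp), (lo, lo, lo))


def save_phantom(
    spec: PhantomSpec, spacing, out_dir: str | Path
) -> dict[str, Path]:
    """Rasterize and write bone/parts NIfTI volumes plus spec and truth JSON."""
    from .volio import write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bone, parts = rasterize_phantom(spec, spacing)
    truth = ground_truth_measurements(spec)
    paths = {
        "bone": write_volume(bone, out / f"{spec.name}_bone.nii.gz"),
        "parts": write_volume(parts, out / f"{spec.name}_parts.nii.gz"),
    }
    spec_path = out / f"{spec.name}_spec.json"
    spec_path.write_text(spec.to_json())
    truth_path = out / f"{spec.name}_truth.json"
    truth_path.write_text(json.dumps(truth.to_dict(), indent=1))
    paths["spec"] = spec_path
    paths["truth"] = truth_path
    return paths
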