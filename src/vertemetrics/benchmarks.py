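"""Self-contained validation experiments on the phantom suite.

Each function regenerates its inputs from a seed, runs the pipeline
operation under test, and returns the measured quantities.  They back
both the acceptance test suite and ``scripts/acceptance.py``; problem
sizes are chosen so the whole battery runs in minutes on one CPU (see
the methods note).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import phantom as ph
from .labeling import name_vertebrae, split_instances
from .morphometry import MEASUREMENT_FIELDS
from .pipeline import RunConfig, measure_labeled, run_cohort
from .surfdist import (
    extract_mesh,
    point_to_surface,
    point_to_surface_bruteforce,
    surface_rmse,
)
from .volio import SurfaceMesh

__all__ = [
    "metric_identity",
    "metric_asymmetry",
    "concentric_sphere_rmse",
    "bruteforce_agreement",
    "degradation_calibration",
    "morphometry_recovery",
    "pose_invariance",
    "labeling_accuracy",
    "cohort_regime",
]


def _phantom_meshes(seed: int, n: int, spacing: float = 1.0) -> list[SurfaceMesh]:
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        spec = ph.sample_spec(rng)
        bone, _ = ph.rasterize_phantom(spec, spacing)
        out.append(extract_mesh(bone))
    return out


def metric_identity(seed: int = 0, n: int = 5) -> float:
    """Max rmse(A -> A) over n distinct phantom meshes (should be ~0)."""
    return max(surface_rmse(m, m).rmse for m in _phantom_meshes(seed, n))


def metric_asymmetry(seed: int = 0) -> tuple[float, float]:
    """(rmse(sub -> full), rmse(full -> sub)) for a superior-half crop.

    Every point of the cropped mesh lies on the full surface, so the first
    value vanishes while the second stays large — the directionality of
    the metric.
    """
    mesh = _phantom_meshes(seed, 1)[0]
    z = mesh.vertices[:, 2]
    keep_v = z > np.median(z)
    keep_f = keep_v[mesh.faces].all(axis=1)
    sub_faces = mesh.faces[keep_f]
    used = np.unique(sub_faces)
    remap = np.zeros(len(mesh.vertices), dtype=np.int64)
    remap[used] = np.arange(len(used))
    sub = SurfaceMesh(mesh.vertices[used], remap[sub_faces])
    return surface_rmse(sub, mesh).rmse, surface_rmse(mesh, sub).rmse


def concentric_sphere_rmse(spacing: float = 0.5) -> float:
    """rmse between meshed balls of radius 20 and 21 mm (closed form: 1.0)."""
    m20 = extract_mesh(ph.ball_mask(20.0, spacing))
    m21 = extract_mesh(ph.ball_mask(21.0, spacing))
    return surface_rmse(m20, m21).rmse


def bruteforce_agreement(seed: int = 0, n_points: int = 120) -> float:
    """Max |accelerated - brute force| point-to-surface distance, in mm."""
    rng = np.random.default_rng(seed)
    mesh = extract_mesh(ph.ball_mask(5.0, 1.0))  # a few hundred triangles
    pts = rng.uniform(-9.0, 9.0, (n_points, 3))
    return float(
        np.abs(point_to_surface(pts, mesh) - point_to_surface_bruteforce(pts, mesh)).max()
    )


def degradation_calibration(
    shifts=(0.25, 0.5, 1.0), radius: float = 20.0, spacing: float = 0.5
) -> dict[float, float]:
    """rmse(degraded -> original) of a ball under pure boundary shifts."""
    ball = ph.ball_mask(radius, spacing)
    ref = extract_mesh(ball)
    out = {}
    for s in shifts:
        deg = ph.degrade(ball, ph.DegradationSpec(boundary_shift_mm=s))
        out[s] = surface_rmse(extract_mesh(deg), ref).rmse
    return out


def morphometry_recovery(
    seed: int = 0, n: int = 20, spacing: float = 0.5
) -> dict[str, float]:
    """Median |measured - analytic truth| per field over a random spec grid."""
    rng = np.random.default_rng(seed)
    errs: dict[str, list[float]] = {k: [] for k in MEASUREMENT_FIELDS}
    for i in range(n):
        spec = ph.sample_spec(rng, name=f"L{i % 5 + 1}")
        bone, parts = ph.rasterize_phantom(spec, spacing)
        rec = measure_labeled(bone, parts, spec.name)
        truth = ph.ground_truth_measurements(spec)
        for k, v in rec.present_fields().items():
            errs[k].append(abs(v - getattr(truth, k)))
    return {k: float(np.median(v)) for k, v in errs.items() if v}


def pose_invariance(
    seed: int = 0, n_poses: int = 10, spacing: float = 0.5, max_rot_deg: float = 25.0
) -> dict[str, float]:
    """Max |measurement(posed) - measurement(identity pose)| per field."""
    rng = np.random.default_rng(seed)
    spec0 = ph.PhantomSpec()
    bone, parts = ph.rasterize_phantom(spec0, spacing)
    base = measure_labeled(bone, parts, spec0.name).present_fields()
    worst = {k: 0.0 for k in base}
    for _ in range(n_poses):
        pose = ph.Pose(
            rotation_deg=tuple(rng.uniform(-max_rot_deg, max_rot_deg, 3)),
            translation=tuple(rng.uniform(-8.0, 8.0, 3)),
        )
        spec = dataclasses.replace(spec0, pose=pose)
        b, p = ph.rasterize_phantom(spec, spacing)
        rec = measure_labeled(b, p, spec.name).present_fields()
        for k in worst:
            worst[k] = max(worst[k], abs(rec[k] - base[k]))
    return worst


def labeling_accuracy(seed: int = 0, n_spines: int = 20, spacing: float = 1.25) -> float:
    """Fraction of randomly tilted sacrum+L5..L1 phantoms named perfectly."""
    rng = np.random.default_rng(seed)
    expected = ["sacrum", "L5", "L4", "L3", "L2", "L1"]
    good = 0
    for _ in range(n_spines):
        specs = [ph.sample_spec(rng, name=n, tilt_deg=15.0) for n in expected[1:]]
        bone, _, _ = ph.rasterize_spine(specs, spacing=spacing)
        named = name_vertebrae(split_instances(bone))
        good += [v.name for v in named] == expected
    return good / n_spines


def cohort_regime(seed: int = 0, n: int = 20, spacing: float = 0.5) -> dict:
    """Full pipeline on a degraded cohort; returns the summary report dict."""
    cfg = RunConfig(
        seed=seed, n_phantoms=n, spacing=spacing, noise_amplitude_mm=0.5
    )
    return run_cohort(cfg)
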