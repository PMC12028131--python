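"""Vertebra frame construction and the ten 2D measurements."""

import dataclasses

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from vertemetrics import morphometry as mm
from vertemetrics import phantom as ph
from vertemetrics.pipeline import measure_labeled
from vertemetrics.volio import VoxelVolume


def cylinder_mask(radius=15.0, height=30.0, spacing=1.0, tilt_deg=0.0, wedge_deg=0.0):
    """Elliptic cylinder with optionally tilted top plane, optionally rotated
    about the RL axis — a body-like solid with a known endplate normal."""
    n = int(2 * (radius + height) / spacing)
    ax = (np.arange(n) - n / 2) * spacing
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    if tilt_deg:
        R = Rotation.from_euler("x", tilt_deg, degrees=True).as_matrix()
        pts = np.stack([x, y, z], axis=-1) @ R  # rotate sampling points back
        x, y, z = pts[..., 0], pts[..., 1], pts[..., 2]
    top = height / 2 + np.tan(np.deg2rad(wedge_deg)) * y
    data = ((x**2 + y**2 <= radius**2) & (z >= -height / 2) & (z <= top)).astype(np.uint8)
    return VoxelVolume(data, (spacing,) * 3, (-n / 2 * spacing,) * 3)


def angle_deg(u, v):
    return np.degrees(np.arccos(np.clip(abs(np.dot(u, v)), -1.0, 1.0)))


# --- endplate plane --------------------------------------------------------

def test_endplate_flat_top():
    _, n = mm.fit_endplate_plane(cylinder_mask())
    assert angle_deg(n, [0, 0, 1]) <= 1.0
    assert n[2] > 0  # oriented superiorly


def test_endplate_recovers_known_tilt():
    _, n = mm.fit_endplate_plane(cylinder_mask(tilt_deg=10.0))
    expect = Rotation.from_euler("x", 10.0, degrees=True).as_matrix() @ [0, 0, 1]
    assert angle_deg(n, expect) <= 1.0


def test_endplate_wedge_normal():
    """A 5 deg wedge on the top plane tilts the fitted normal by the wedge angle."""
    _, n = mm.fit_endplate_plane(cylinder_mask(wedge_deg=5.0, spacing=0.5))
    assert angle_deg(n, [0, 0, 1]) == pytest.approx(5.0, abs=1.0)


def test_endplate_empty_mask_rejected():
    with pytest.raises(ValueError):
        mm.fit_endplate_plane(VoxelVolume(np.zeros((3, 3, 3), np.uint8), (1, 1, 1)))


# --- frame -----------------------------------------------------------------

def parts_of(parts):
    return (
        parts.mask_of("body"),
        parts.mask_of("pedicle_L"),
        parts.mask_of("pedicle_R"),
    )


def test_frame_axes_of_untilted_phantom(phantom_1mm, default_spec):
    _, parts = phantom_1mm
    frame = mm.build_frame(*parts_of(parts))
    wedge = np.arctan2(
        default_spec.body_height_anterior - default_spec.body_height_posterior,
        default_spec.body_length,
    )
    expect_si = np.array([0.0, -np.sin(wedge), np.cos(wedge)])
    assert angle_deg(frame.SI, expect_si) <= 1.5
    assert angle_deg(frame.RL, [1, 0, 0]) <= 1.5
    assert frame.RL[0] > 0 and frame.AP[1] > 0  # right / anterior orientation


def test_frame_equivariant_under_rotation(default_spec):
    rot = (12.0, -8.0, 17.0)
    posed = dataclasses.replace(default_spec, pose=ph.Pose(rot))
    _, parts = ph.rasterize_phantom(posed, 1.0)
    _, parts0 = ph.rasterize_phantom(default_spec, 1.0)
    f0 = mm.build_frame(*parts_of(parts0))
    f1 = mm.build_frame(*parts_of(parts))
    R = ph.Pose(rot).matrix
    for ax in ("SI", "RL", "AP"):
        assert angle_deg(getattr(f1, ax), R @ getattr(f0, ax)) <= 1.5


def test_frame_pedicle_swap_antisymmetry(phantom_1mm):
    _, parts = phantom_1mm
    body, pl, pr = parts_of(parts)
    f = mm.build_frame(body, pl, pr)
    g = mm.build_frame(body, pr, pl)
    np.testing.assert_allclose(g.RL, -f.RL, atol=1e-9)
    np.testing.assert_allclose(g.AP, -f.AP, atol=1e-9)
    np.testing.assert_allclose(g.SI, f.SI, atol=1e-9)


def test_frame_orthonormal(phantom_1mm):
    _, parts = phantom_1mm
    f = mm.build_frame(*parts_of(parts))
    for a, b in ((f.SI, f.RL), (f.SI, f.AP), (f.RL, f.AP)):
        assert abs(np.dot(a, b)) < 1e-9
    np.testing.assert_allclose(np.cross(f.SI, f.RL), f.AP, atol=1e-9)


# --- body measurements -----------------------------------------------------

def test_body_heights_match_generator(phantom_1mm, default_spec):
    _, parts = phantom_1mm
    body = parts.mask_of("body")
    frame = mm.build_frame(*parts_of(parts))
    ha, hp = mm.body_heights(frame, body)
    assert ha == pytest.approx(default_spec.body_height_anterior, abs=2.0)
    assert hp == pytest.approx(default_spec.body_height_posterior, abs=2.0)


def test_body_heights_uniform_cylinder():
    mask = cylinder_mask(radius=18.0, height=30.0)
    frame = mm.VertebraFrame(
        origin=np.zeros(3), SI=[0, 0, 1.0], RL=[1.0, 0, 0], AP=[0, 1.0, 0]
    )
    ha, hp = mm.body_heights(frame, mask)
    assert ha == pytest.approx(30.0, abs=2.0)
    assert hp == pytest.approx(30.0, abs=2.0)


def test_body_width_length_match_generator(phantom_1mm, default_spec):
    _, parts = phantom_1mm
    frame = mm.build_frame(*parts_of(parts))
    ws, ls, wi, li = mm.body_width_length(frame, parts.mask_of("body"))
    assert ws == pytest.approx(default_spec.body_width, abs=2.0)
    assert wi == pytest.approx(default_spec.body_width, abs=2.0)
    assert ls == pytest.approx(default_spec.body_length, abs=2.0)
    assert li == pytest.approx(default_spec.body_length, abs=2.0)


def test_body_width_sphere_chord_closed_form():
    """Planes inset 2 mm from the poles of a ball cut chords of known size."""
    r = 15.0
    mask = ph.ball_mask(r, 0.5)
    frame = mm.VertebraFrame(
        origin=np.zeros(3), SI=[0, 0, 1.0], RL=[1.0, 0, 0], AP=[0, 1.0, 0]
    )
    ws, ls, wi, li = mm.body_width_length(frame, mask)
    chord = 2 * np.sqrt(r**2 - (r - 2.0) ** 2)
    for v in (ws, ls, wi, li):
        assert v == pytest.approx(chord, abs=1.5)


# --- pedicles --------------------------------------------------------------

def test_pedicle_uniform_cylinder_dimensions():
    """A constant elliptic cylinder measures its nominal width/height in any plane."""
    spacing = 0.5
    n = 60
    ax = (np.arange(n) - n / 2) * spacing
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    data = (((x / 4.0) ** 2 + (z / 5.0) ** 2 <= 1.0) & (np.abs(y) <= 10)).astype(np.uint8)
    mask = VoxelVolume(data, (spacing,) * 3, (ax[0],) * 3)
    frame = mm.VertebraFrame(
        origin=np.zeros(3), SI=[0, 0, 1.0], RL=[1.0, 0, 0], AP=[0, 1.0, 0]
    )
    w, h, (_, traj) = mm.pedicle_dimensions(frame, mask)
    assert w == pytest.approx(8.0, abs=1.0)
    assert h == pytest.approx(10.0, abs=1.0)
    assert angle_deg(traj, [0, 1, 0]) <= 3.0


def test_pedicle_constricted_waist(phantom_half_mm, default_spec):
    _, parts = phantom_half_mm
    frame = mm.build_frame(*parts_of(parts))
    truth_w = default_spec.pedicle_width * default_spec.pedicle_constriction
    truth_h = default_spec.pedicle_height * default_spec.pedicle_constriction
    for side in ("pedicle_L", "pedicle_R"):
        w, h, _ = mm.pedicle_dimensions(frame, parts.mask_of(side))
        assert w == pytest.approx(truth_w, abs=1.0)
        assert h == pytest.approx(truth_h, abs=1.0)


def test_pedicle_trajectory_recovers_cant(phantom_half_mm, default_spec):
    _, parts = phantom_half_mm
    frame = mm.build_frame(*parts_of(parts))
    cant = np.deg2rad(default_spec.pedicle_cant_deg)
    for side, s in (("pedicle_L", -1.0), ("pedicle_R", +1.0)):
        _, _, (_, traj) = mm.pedicle_dimensions(frame, parts.mask_of(side))
        gen = np.array([s * np.sin(cant), -np.cos(cant), 0.0])
        assert angle_deg(traj, gen) <= 3.0


def test_pedicle_too_thin_rejected():
    data = np.zeros((20, 20, 20), np.uint8)
    data[5:15, 5:15, 10] = 1  # a one-voxel-thick sheet
    frame = mm.VertebraFrame(
        origin=np.zeros(3), SI=[0, 0, 1.0], RL=[1.0, 0, 0], AP=[0, 1.0, 0]
    )
    with pytest.raises(ValueError):
        mm.pedicle_dimensions(frame, VoxelVolume(data, (1, 1, 1)))


# --- spinous process -------------------------------------------------------

@pytest.mark.parametrize("tilt", [0.0, 20.0])
def test_spinous_length_recovers_generator(tilt):
    spec = ph.PhantomSpec(spinous_length=35.0, spinous_tilt_deg=max(tilt, 0.01))
    _, parts = ph.rasterize_phantom(spec, 1.0)
    frame = mm.build_frame(*parts_of(parts))
    length, (point, normal) = mm.spinous_length(frame, parts.mask_of("spinous"))
    assert length == pytest.approx(35.0, abs=2.0)


def test_spinous_plane_angle_tracks_tilt():
    spec = ph.PhantomSpec(spinous_length=35.0, spinous_tilt_deg=20.0)
    _, parts = ph.rasterize_phantom(spec, 0.5)
    frame = mm.build_frame(*parts_of(parts))
    _, (point, normal) = mm.spinous_length(frame, parts.mask_of("spinous"))
    # plane normal should stay orthogonal to the generative spinous axis
    tau = np.deg2rad(20.0)
    axis = np.array([0.0, -np.cos(tau), -np.sin(tau)])
    assert abs(np.dot(normal / np.linalg.norm(normal), axis)) <= np.sin(np.deg2rad(4.0))


# --- full record -----------------------------------------------------------

def test_measure_vertebra_matches_truth(phantom_1mm, default_spec):
    bone, parts = phantom_1mm
    rec = measure_labeled(bone, parts, default_spec.name)
    truth = ph.ground_truth_measurements(default_spec)
    for k, v in rec.present_fields().items():
        assert v == pytest.approx(getattr(truth, k), abs=2.0), k


def test_missing_spinous_gives_partial_record(phantom_1mm, default_spec):
    from vertemetrics.labeling import VertebraInstance
    from vertemetrics.volio import LabelVolume

    bone, parts = phantom_1mm
    data = parts.data.copy()
    data[data == ph.PART_IDS["spinous"]] = 0
    stripped = LabelVolume(
        data, parts.spacing, parts.origin,
        labels={k: v for k, v in parts.labels.items() if v != "spinous"},
    )
    mask = bone.with_data((data > 0).astype(np.uint8))
    rec = mm.measure_vertebra(VertebraInstance("L4", mask, stripped))
    assert rec.spinous_length is None
    assert rec.body_height_anterior is not None
    assert rec.pedicle_width_L is not None


def test_missing_body_rejected(phantom_1mm):
    from vertemetrics.labeling import VertebraInstance
    from vertemetrics.volio import LabelVolume

    bone, parts = phantom_1mm
    data = parts.data.copy()
    data[data == ph.PART_IDS["body"]] = 0
    stripped = LabelVolume(
        data, parts.spacing, parts.origin,
        labels={k: v for k, v in parts.labels.items() if v != "body"},
    )
    with pytest.raises(ValueError):
        mm.measure_vertebra(VertebraInstance("L4", bone, stripped))


def test_degraded_phantom_still_measurable(phantom_1mm, default_spec):
    from vertemetrics.pipeline import transfer_parts

    bone, parts = phantom_1mm
    deg = ph.degrade(bone, ph.DegradationSpec(noise_amplitude_mm=0.5, seed=9))
    rec = measure_labeled(deg, transfer_parts(parts, deg), default_spec.name)
    truth = ph.ground_truth_measurements(default_spec)
    for k, v in rec.present_fields().items():
        assert v == pytest.approx(getattr(truth, k), abs=2.0 + 1.0), k
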