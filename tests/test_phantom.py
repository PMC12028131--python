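"""Phantom generator: rasterization, ground truth, degradation."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from vertemetrics import phantom as ph
from vertemetrics.phantom import DegradationSpec, PhantomSpec, Pose


def brute_force_ellipse_extent(width, length, spacing):
    """Oracle: RL extent of voxel centers inside the body footprint ellipse."""
    a, b = width / 2, length / 2
    xs = np.arange(-a - 2, a + 2, spacing)
    inside = np.abs(xs) <= a  # extent along y=0 row
    return xs[inside].max() - xs[inside].min()


def test_body_rl_extent_matches_ellipse_oracle(phantom_1mm, default_spec):
    _, parts = phantom_1mm
    body = parts.mask_of("body")
    idx = np.argwhere(body.data > 0)
    xs = body.index_to_world(idx)[:, 0]
    measured = xs.max() - xs.min()
    oracle = brute_force_ellipse_extent(default_spec.body_width, default_spec.body_length, 1.0)
    assert measured == pytest.approx(oracle, abs=1.0)
    assert measured == pytest.approx(default_spec.body_width, abs=1.0)


def test_rasterization_deterministic(default_spec):
    b1, p1 = ph.rasterize_phantom(default_spec, 1.0)
    b2, p2 = ph.rasterize_phantom(default_spec, 1.0)
    assert (b1.data == b2.data).all()
    assert (p1.data == p2.data).all()
    assert b1.origin == b2.origin


def test_posed_rasterization_is_congruent(default_spec):
    """Rotating the solid before rasterization preserves its voxel volume."""
    posed = dataclasses.replace(default_spec, pose=Pose((0.0, 0.0, 30.0)))
    n0 = int(ph.rasterize_phantom(default_spec, 1.0)[0].data.sum())
    n1 = int(ph.rasterize_phantom(posed, 1.0)[0].data.sum())
    assert abs(n1 - n0) / n0 < 0.02


def test_part_partition_property(phantom_1mm):
    bone, parts = phantom_1mm
    assert ((parts.data > 0) == (bone.data > 0)).all()
    assert set(np.unique(parts.data)) == set(range(8))  # background + 7 parts


def test_vertebra_is_one_connected_component(phantom_1mm):
    bone, _ = phantom_1mm
    assert ndimage.label(bone.data, structure=np.ones((3, 3, 3)))[1] == 1


def test_volume_converges_with_spacing(default_spec):
    """Rasterized body volume approaches the analytic solid volume as the
    grid refines."""
    spec = default_spec
    analytic = (
        np.pi
        * (spec.body_width / 2)
        * (spec.body_length / 2)
        * 0.5
        * (spec.body_height_anterior + spec.body_height_posterior)
    )
    errs = []
    for spacing in (1.0, 0.5):
        _, parts = ph.rasterize_phantom(spec, spacing)
        vol = parts.mask_of("body").data.sum() * spacing**3
        errs.append(abs(vol - analytic) / analytic)
    assert errs[1] <= max(errs[0], 0.005)
    assert errs[1] < 0.02


@pytest.mark.parametrize("spacing", [0.05, 2.5])
def test_spacing_out_of_range(default_spec, spacing):
    with pytest.raises(ValueError):
        ph.rasterize_phantom(default_spec, spacing)


def test_overlapping_pedicles_rejected():
    spec = PhantomSpec(body_width=18.0, pedicle_width=12.0)
    with pytest.raises(ValueError, match="pedicle"):
        ph.rasterize_phantom(spec, 1.0)


# --- spine -----------------------------------------------------------------

def test_spine_component_count(spine_specs):
    bone, parts, truth = ph.rasterize_spine(spine_specs, spacing=1.25)
    n = ndimage.label(bone.data, structure=np.ones((3, 3, 3)))[1]
    assert n == 6  # sacrum + 5 vertebrae
    assert len(truth) == 5
    assert truth[0].body_height_anterior == spine_specs[0].body_height_anterior


def test_spine_two_vertebrae_three_components(spine_specs):
    bone, _, _ = ph.rasterize_spine(spine_specs[:2], spacing=1.0, gap=3.0)
    assert ndimage.label(bone.data, structure=np.ones((3, 3, 3)))[1] == 3


def test_spine_empty_list_rejected():
    with pytest.raises(ValueError):
        ph.rasterize_spine([])


def test_spine_gap_too_small_rejected(spine_specs):
    with pytest.raises(ValueError, match="gap"):
        ph.rasterize_spine(spine_specs[:2], spacing=1.0, gap=0.5)


# --- ground truth ----------------------------------------------------------

def test_ground_truth_passthrough():
    rec = ph.ground_truth_measurements(PhantomSpec(body_height_anterior=28.0))
    assert rec.body_height_anterior == 28.0


def test_ground_truth_constriction_product():
    rec = ph.ground_truth_measurements(
        PhantomSpec(pedicle_width=9.0, pedicle_constriction=0.8)
    )
    assert rec.pedicle_width_L == pytest.approx(7.2)
    assert rec.pedicle_width_R == pytest.approx(7.2)


def test_ground_truth_pose_independent(default_spec):
    posed = dataclasses.replace(
        default_spec, pose=Pose((10.0, -5.0, 20.0), (4.0, 1.0, -2.0))
    )
    assert ph.ground_truth_measurements(default_spec) == ph.ground_truth_measurements(posed)


def test_constricted_waist_is_minimal_cross_section(default_spec):
    """Brute-force oracle: the narrowest transverse slab of the rasterized
    pedicle matches nominal width x constriction."""
    _, parts = ph.rasterize_phantom(default_spec, 0.5)
    ped = parts.mask_of("pedicle_R")
    idx = np.argwhere(ped.data > 0)
    pts = ped.index_to_world(idx)
    cant = np.deg2rad(default_spec.pedicle_cant_deg)
    axis = np.array([np.sin(cant), -np.cos(cant), 0.0])
    t = pts @ axis
    e_w = np.array([axis[1], -axis[0], 0.0])
    widths = []
    for tc in np.arange(t.min() + 2, t.max() - 2, 0.25):
        sel = np.abs(t - tc) <= 0.4
        if sel.sum() > 10:
            u = pts[sel] @ e_w
            widths.append(u.max() - u.min())
    truth = default_spec.pedicle_width * default_spec.pedicle_constriction
    assert min(widths) == pytest.approx(truth, abs=1.0)


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        PhantomSpec(body_width=-1.0).validate()
    with pytest.raises(ValueError):
        PhantomSpec(pedicle_constriction=0.0).validate()
    with pytest.raises(ValueError):
        PhantomSpec(pedicle_constriction=1.2).validate()


def test_spec_json_round_trip(default_spec):
    posed = dataclasses.replace(default_spec, pose=Pose((1.0, 2.0, 3.0), (4.0, 5.0, 6.0)))
    assert PhantomSpec.from_json(posed.to_json()) == posed


# --- degradation -----------------------------------------------------------

def test_zero_degradation_is_identity(phantom_1mm):
    bone, _ = phantom_1mm
    out = ph.degrade(bone, DegradationSpec())
    assert (out.data == bone.data).all()
    assert out.spacing == bone.spacing and out.origin == bone.origin


def test_degrade_requires_binary(ball_10mm):
    bad = ball_10mm.with_data(ball_10mm.data * 0.5)
    with pytest.raises(ValueError):
        ph.degrade(bad, DegradationSpec(boundary_shift_mm=1.0))


def test_boundary_shift_changes_volume_monotonically(ball_10mm):
    volumes = []
    for s in (-1.0, 0.0, 1.0):
        out = ph.degrade(ball_10mm, DegradationSpec(boundary_shift_mm=s))
        volumes.append(out.data.sum())
    assert volumes[0] < volumes[1] < volumes[2]


def test_noise_monotone_in_amplitude(ball_10mm):
    """Same seed, larger amplitude => no smaller surface error."""
    from vertemetrics.surfdist import extract_mesh, surface_rmse

    ref = extract_mesh(ball_10mm)
    for seed in range(3):
        rmses = []
        for amp in (0.4, 0.8):
            out = ph.degrade(
                ball_10mm, DegradationSpec(noise_amplitude_mm=amp, seed=seed)
            )
            rmses.append(surface_rmse(extract_mesh(out), ref).rmse)
        assert rmses[1] >= rmses[0]


def test_degradation_keeps_grid(ball_10mm):
    out = ph.degrade(ball_10mm, DegradationSpec(boundary_shift_mm=0.7, seed=1))
    assert out.same_grid(ball_10mm)
    assert out.is_binary()
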