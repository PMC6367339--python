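"""Generator: truth tables, rendering, time-lapse and section fixtures."""

import math

import numpy as np
import pytest
from scipy import ndimage

from myonuc import (
    SyntheticFiberSpec,
    generate_fiber,
    generate_section,
    generate_timelapse,
    render_stack,
)
from myonuc.simulate import (
    expected_mean_sinus,
    render_fiber_mask,
    sample_orientation_angles,
)


def test_zero_density_gives_empty_fiber():
    spec = SyntheticFiberSpec(nuclei_per_100um=0.0, seed=0)
    nuclei, geometry = generate_fiber(spec)
    assert nuclei == []
    assert geometry.csa == pytest.approx(math.pi * 30 * 20)


def test_seed_determinism_bit_identical():
    spec = SyntheticFiberSpec(seed=42)
    a, _ = generate_fiber(spec)
    b, _ = generate_fiber(spec)
    assert [(n.centroid, n.angle_deg) for n in a] == [(n.centroid, n.angle_deg) for n in b]
    stack_a = render_stack(a, spec.geometry(), spec)
    stack_b = render_stack(b, spec.geometry(), spec)
    np.testing.assert_array_equal(stack_a.intensities, stack_b.intensities)


def test_poisson_count_law_monte_carlo():
    """With min_spacing=0 the count is Poisson(density x length / 100)."""
    spec = SyntheticFiberSpec(
        fiber_length=400.0, nuclei_per_100um=6.0, min_spacing=0.0
    )
    n_rep = 500
    counts = [
        len(generate_fiber(spec, rng=np.random.default_rng(s))[0])
        for s in range(n_rep)
    ]
    lam = 24.0
    se = math.sqrt(lam / n_rep)
    assert abs(np.mean(counts) - lam) < 3 * se


def test_centroids_inside_envelope_and_hard_core():
    spec = SyntheticFiberSpec(seed=11)
    nuclei, _ = generate_fiber(spec)
    pts = np.array([n.centroid for n in nuclei])
    assert np.all((pts[:, 0] >= 0) & (pts[:, 0] <= spec.fiber_length))
    r = (pts[:, 1] / (spec.width_w / 2)) ** 2 + (pts[:, 2] / (spec.thickness_t / 2)) ** 2
    assert np.all(r <= 1.0 + 1e-12)
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    assert d.min() >= spec.min_spacing


def test_incompatible_density_and_spacing_raises():
    spec = SyntheticFiberSpec(
        fiber_length=100.0, nuclei_per_100um=50.0, min_spacing=30.0, seed=0
    )
    with pytest.raises(RuntimeError, match="incompatible"):
        generate_fiber(spec)


def test_orientation_law_uniform_and_concentrated(rng):
    uni = sample_orientation_angles(20000, 0.0, rng)
    assert np.all((uni >= 0) & (uni < 180))
    # uniform law: mean sinus = 2/pi
    assert np.mean(np.sin(np.radians(uni))) == pytest.approx(2 / math.pi, abs=0.01)
    conc = sample_orientation_angles(20000, 4.0, rng)
    m = np.mean(np.sin(np.radians(conc)))
    assert m < 2 / math.pi  # concentration toward alignment lowers the sinus
    assert m == pytest.approx(expected_mean_sinus(4.0), abs=0.01)


def test_render_centroid_matches_truth(small_spec):
    """Intensity-weighted centroid of a clean single-ellipsoid stack."""
    spec = SyntheticFiberSpec(
        fiber_length=40, width_w=30, thickness_t=24, nuclei_per_100um=0,
        noise_model="none", psf_sigma=0.0, seed=0,
    )
    from myonuc.simulate import GroundTruthNucleus

    truth = [GroundTruthNucleus(0, (20.0, 5.0, -3.0), (6.0, 2.5, 2.0), 30.0)]
    stack = render_stack(truth, spec.geometry(), spec)
    img = stack.intensities
    zz, yy, xx = np.nonzero(img)
    w = img[zz, yy, xx]
    dx, dy, dz = stack.voxel_size
    x0, y0, z0 = stack.origin
    cx = np.average(x0 + (xx + 0.5) * dx, weights=w)
    cy = np.average(y0 + (yy + 0.5) * dy, weights=w)
    cz = np.average(z0 + (zz + 0.5) * dz, weights=w)
    assert abs(cx - 20.0) < 0.5 * dx
    assert abs(cy - 5.0) < 0.5 * dy
    assert abs(cz - (-3.0)) < 0.5 * dz


def test_two_separated_nuclei_give_two_components():
    spec = SyntheticFiberSpec(
        fiber_length=80, width_w=30, thickness_t=24, nuclei_per_100um=0,
        noise_model="none", seed=0,
    )
    from myonuc.simulate import GroundTruthNucleus

    sep = 4 * 6.0  # 4 x max semi-axis
    truth = [
        GroundTruthNucleus(0, (20.0, 0.0, 0.0), (6.0, 2.5, 2.0), 0.0),
        GroundTruthNucleus(1, (20.0 + sep, 0.0, 0.0), (6.0, 2.5, 2.0), 0.0),
    ]
    stack = render_stack(truth, spec.geometry(), spec)
    half_max = stack.intensities.max() / 2
    _, n = ndimage.label(stack.intensities > half_max, structure=np.ones((3, 3, 3)))
    assert n == 2


def test_empty_truth_renders_pure_background(small_spec):
    stack = render_stack([], small_spec.geometry(), small_spec)
    assert stack.intensities.max() == 0.0


def test_fiber_mask_csa_matches_ellipse(small_spec):
    mask = render_fiber_mask(small_spec)
    mid = mask.intensities[:, :, mask.intensities.shape[2] // 2]
    dx, dy, _ = mask.voxel_size
    csa = mid.sum() * dx * dy
    expected = math.pi * (small_spec.width_w / 2) * (small_spec.thickness_t / 2)
    assert csa == pytest.approx(expected, rel=0.05)


def test_regular_placement_is_even():
    spec = SyntheticFiberSpec(
        fiber_length=400, nuclei_per_100um=5, axial_placement="regular", seed=0
    )
    nuclei, _ = generate_fiber(spec)
    x = np.array([n.centroid[0] for n in nuclei])
    assert len(x) == 20
    assert np.allclose(np.diff(x), 20.0)


@pytest.mark.parametrize(
    "model,expected_disp",
    [("stationary", 0.0), (("drift", 0.05), 1.0)],
)
def test_timelapse_truth_displacements(model, expected_disp):
    _, truth = generate_timelapse(5, model, 20.0, 1440.0, seed=3)
    assert truth.frame.nunique() == 73  # every 20 min over 24 h
    for _, tr in truth.groupby("track_id"):
        pos = tr.sort_values("frame")[["x_um", "y_um"]].to_numpy()
        disp = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        np.testing.assert_allclose(disp, expected_disp, atol=1e-9)


def test_timelapse_frame_count_and_validation():
    movie, truth = generate_timelapse(3, "stationary", 30.0, 100.0, seed=0)
    assert movie.shape[0] == 4  # floor(100/30) + 1
    with pytest.raises(ValueError):
        generate_timelapse(3, "stationary", 0.0, 100.0, seed=0)


def test_section_point_counts_and_adjacency():
    fibers, points = generate_section(2000, 1.0, seed=5)
    assert len(points) == 20
    # points sit just outside their host fibre membrane
    host = fibers.set_index("fiber_id").loc[points.fiber_id]
    d = np.hypot(points.x_um.to_numpy() - host.x_um.to_numpy(),
                 points.y_um.to_numpy() - host.y_um.to_numpy())
    np.testing.assert_allclose(d, host.radius_um.to_numpy() + 1.0, atol=1e-9)
    _, empty = generate_section(100, 0.0, seed=5)
    assert len(empty) == 0


def test_spec_validation():
    with pytest.raises(ValueError):
        SyntheticFiberSpec(fiber_length=-1)
    with pytest.raises(ValueError):
        SyntheticFiberSpec(nuclei_per_100um=-1)
    with pytest.raises(ValueError):
        SyntheticFiberSpec(voxel_size=(0.5, 0.5, 0.0))
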