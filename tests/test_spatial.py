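"""NN distances, slice-based MND and the orientation-sinus distribution."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.integrate import quad
from scipy.stats import poisson

from myonuc import (
    SyntheticFiberSpec,
    generate_fiber,
    myonuclear_domain,
    nearest_neighbour,
    sinus_distribution,
)


def brute_force_nn(pts):
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


class TestNearestNeighbour:
    def test_three_four_five(self):
        res = nearest_neighbour([(0, 0, 0), (3, 4, 0)])
        np.testing.assert_allclose(res.nn_distances, [5.0, 5.0])
        assert res.nn_mean == 5.0

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            pts = rng.uniform(0, 100, size=(rng.integers(2, 25), 3))
            res = nearest_neighbour(pts)
            np.testing.assert_allclose(res.nn_distances, brute_force_nn(pts))

    @settings(derandomize=True, max_examples=50)
    @given(
        arrays(float, st.tuples(st.integers(2, 12), st.just(3)),
               elements=st.floats(-100, 100, allow_nan=False, width=32))
    )
    def test_brute_force_equality_property(self, pts):
        import warnings

        with warnings.catch_warnings():
            # duplicated points legitimately trigger the coincidence warning
            warnings.simplefilter("ignore", UserWarning)
            res = nearest_neighbour(pts)
        np.testing.assert_allclose(res.nn_distances, brute_force_nn(pts),
                                   rtol=1e-9, atol=1e-9)
        assert np.all(res.nn_distances >= 0)

    def test_fewer_than_two_is_undefined(self):
        res = nearest_neighbour(np.empty((0, 3)))
        assert not res.defined and math.isnan(res.nn_mean)
        res1 = nearest_neighbour([(1.0, 2.0, 3.0)])
        assert not res1.defined

    def test_duplicate_centroids_warn(self):
        with pytest.warns(UserWarning, match="coincident"):
            res = nearest_neighbour([(0, 0, 0), (0, 0, 0), (9, 0, 0)])
        assert res.nn_distances.min() == 0.0

    def test_rigid_motion_invariance_and_scaling(self, rng):
        pts = rng.uniform(0, 50, size=(15, 3))
        base = nearest_neighbour(pts).nn_mean
        # translation
        assert nearest_neighbour(pts + 17.3).nn_mean == pytest.approx(base)
        # rotation about z
        th = 0.7
        rot = np.array([[math.cos(th), -math.sin(th), 0],
                        [math.sin(th), math.cos(th), 0], [0, 0, 1]])
        assert nearest_neighbour(pts @ rot.T).nn_mean == pytest.approx(base)
        # linear scaling
        assert nearest_neighbour(pts * 2.5).nn_mean == pytest.approx(2.5 * base)

    def test_nn_mean_increases_with_min_spacing(self):
        means = []
        for spacing in (0.0, 10.0, 20.0):
            vals = []
            for seed in range(15):
                spec = SyntheticFiberSpec(min_spacing=spacing, seed=seed)
                nuclei, _ = generate_fiber(spec)
                pts = np.array([n.centroid for n in nuclei])
                vals.append(nearest_neighbour(pts).nn_mean)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestMyonuclearDomain:
    def test_uniform_one_nucleus_per_slice(self):
        x = np.arange(10, 375, 20.0)  # one nucleus centred in every slice
        res = myonuclear_domain(x, csa=1000.0)
        full = res.slices[res.slices.volume_um3 == 20000.0]
        assert np.allclose(full.mnd_um3, 20000.0)
        assert res.n_empty_slices == 0
        # 18 full slices + the 15 µm partial remainder
        assert len(res.slices) == 19
        assert res.slices.volume_um3.iloc[-1] == pytest.approx(15000.0)

    def test_two_nuclei_halve_the_domain(self):
        res = myonuclear_domain([5.0, 15.0], csa=1000.0, segment_length=20.0)
        assert res.mnd_mean == pytest.approx(10000.0)

    def test_adding_a_nucleus_strictly_decreases_slice_mnd(self):
        one = myonuclear_domain([5.0], csa=1000.0, segment_length=20.0)
        two = myonuclear_domain([5.0, 7.0], csa=1000.0, segment_length=20.0)
        assert two.mnd_mean < one.mnd_mean

    def test_empty_slices_excluded_and_counted(self):
        res = myonuclear_domain([10.0], csa=1000.0, segment_length=100.0,
                                include_partial=False)
        assert res.n_empty_slices == 4
        assert res.mnd_mean == pytest.approx(20000.0)

    def test_partial_slice_configurable(self):
        res = myonuclear_domain([370.0], csa=1000.0)
        assert res.slices.volume_um3.iloc[-1] == pytest.approx(15000.0)
        dropped = myonuclear_domain([370.0], csa=1000.0, include_partial=False)
        assert len(dropped.slices) == 18

    def test_segment_longer_than_fiber_rejected(self):
        with pytest.raises(ValueError, match="exceeds fibre length"):
            myonuclear_domain([10.0], csa=1000.0, fiber_length=300.0)

    def test_no_occupied_slices_is_undefined(self):
        res = myonuclear_domain([], csa=1000.0, segment_length=40.0)
        assert not res.defined and math.isnan(res.mnd_mean)

    def test_poisson_placement_matches_conditional_expectation_oracle(self):
        """Under Poisson placement the slice-MND mean equals
        v * E[1/n | n >= 1], not v / E[n] (Jensen bias of the estimator)."""
        spec = SyntheticFiberSpec(min_spacing=0.0, sub_sarcolemmal_depth=2.0)
        lam = spec.nuclei_per_100um * 20.0 / 100.0
        ns = np.arange(1, 60)
        e_inv = float(np.sum(poisson.pmf(ns, lam) / ns) / (1 - poisson.pmf(0, lam)))
        v = spec.geometry().csa * 20.0
        expected = v * e_inv
        vals = []
        for seed in range(150):
            nuclei, geom = generate_fiber(spec, rng=np.random.default_rng(seed))
            x = np.array([n.centroid[0] for n in nuclei])
            res = myonuclear_domain(x, geom.csa, segment_length=360.0,
                                    fiber_length=spec.fiber_length)
            vals.append(res.mnd_mean)
        sem = np.std(vals, ddof=1) / math.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 3 * sem


class TestSinusDistribution:
    def test_all_zero_in_first_bin(self):
        df = sinus_distribution(np.zeros(50))
        assert df.percentage.iloc[0] == 100.0
        assert df.percentage.sum() == pytest.approx(100.0)

    def test_value_one_lands_in_last_closed_bin(self):
        df = sinus_distribution([1.0, 0.95])
        assert df.percentage.iloc[-1] == 100.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sinus_distribution([0.5, 1.2])

    def test_uniform_angles_match_arcsine_oracle(self, rng):
        """sin of a uniform angle follows the arcsine-type law; bin masses
        from numerical integration."""
        angles = rng.uniform(0, math.pi, 200000)
        s = np.sin(angles)
        df = sinus_distribution(s)

        def bin_mass(a, b):
            # sin of U[0, pi) has density 2 / (pi sqrt(1 - s^2)) on [0, 1)
            mass, _ = quad(lambda s: 2.0 / (math.pi * math.sqrt(1.0 - s**2)),
                           a, min(b, 1.0), limit=200)
            return mass * 100

        for k in range(10):
            a, b = k / 10, (k + 1) / 10 if k < 9 else 1.0 + 1e-12
            expect = bin_mass(a, b)
            se = math.sqrt(expect / 100 * (1 - expect / 100) / len(s)) * 100
            assert abs(df.percentage.iloc[k] - expect) < max(4 * se, 0.25)

    def test_main_ranges_aggregate(self):
        vals = [0.05, 0.25, 0.45, 0.55, 0.7, 0.99, 1.0, 0.1]
        df = sinus_distribution(vals)
        main = df.attrs["main_ranges"]
        assert main[(0.0, 0.3)] == pytest.approx(100 * 3 / 8)
        assert main[(0.3, 0.6)] == pytest.approx(100 * 2 / 8)
        assert main[(0.6, 1.0)] == pytest.approx(100 * 3 / 8)
        assert sum(main.values()) == pytest.approx(100.0)
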