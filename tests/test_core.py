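"""Alignment transforms, channel normalization, and the GI/LI decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from debias.core import (
    PairedSample,
    alignment_angle,
    alignment_values,
    compute_debias,
    intensity_difference,
    normalize_channel,
    resampled_alignment,
    wrap_orientation,
)
from debias.distributions import emd, quantize, uniform_reference
from debias.simulate import OrientationSimConfig, simulate_coorientation


class TestAlignmentAngle:
    @pytest.mark.parametrize(
        "x, y, expected",
        [(30, 50, 20), (0, 0, 0), (-45, -45, 0), (-80, 80, 20), (90, -90, 0), (45, -45, 90)],
    )
    def test_piecewise_formula(self, x, y, expected):
        assert alignment_angle(x, y) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            alignment_angle(120.0, 0.0)

    @given(st.floats(min_value=-90, max_value=90), st.floats(min_value=-90, max_value=90))
    def test_symmetric_and_bounded(self, x, y):
        t = alignment_angle(x, y)
        assert 0 <= t <= 90
        assert t == pytest.approx(alignment_angle(y, x))


class TestWrapOrientation:
    def test_mod_180_fold(self):
        assert wrap_orientation(135.0) == pytest.approx(-45.0)
        assert wrap_orientation(-135.0) == pytest.approx(45.0)
        assert wrap_orientation(90.0) == 90.0
        assert wrap_orientation(180.0) == pytest.approx(0.0)

    @given(st.floats(min_value=-720, max_value=720, allow_nan=False))
    def test_axis_preserved(self, v):
        w = float(wrap_orientation(v))
        assert -90 <= w <= 90
        assert (v - w) % 180 == pytest.approx(0, abs=1e-9) or (v - w) % 180 == pytest.approx(180, abs=1e-9)


class TestNormalizeChannel:
    def test_linspace_midpoint(self):
        v = np.linspace(0, 100, 101)
        out = normalize_channel(v)
        assert out[50] == pytest.approx(0.5)  # (50 - 5) / (95 - 5)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_clipping_beyond_anchors(self):
        v = np.concatenate([np.linspace(0, 100, 100), [1e6]])
        assert normalize_channel(v)[-1] == 1.0

    def test_constant_channel_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_channel(np.full(50, 7.0))


class TestIntensityDifference:
    def test_identical_channels_are_zero(self):
        x = np.linspace(1, 100, 200)
        s = PairedSample("colocalization", x, x.copy())
        np.testing.assert_allclose(intensity_difference(s), 0.0)

    def test_requires_colocalization_mode(self):
        s = PairedSample("orientation", [0.0, 10.0], [5.0, 15.0])
        with pytest.raises(ValueError):
            intensity_difference(s)

    def test_reduced_differences_increase_li(self):
        """Shrinking the per-pair intensity gap raises the local index."""
        rng = np.random.default_rng(4)
        x = rng.uniform(0.05, 0.95, 4000)
        y_far = np.clip(x + rng.normal(0, 0.3, x.size), 0, 1)
        y_near = np.clip(x + rng.normal(0, 0.05, x.size), 0, 1)
        li = {}
        for name, y in (("far", y_far), ("near", y_near)):
            s = PairedSample("colocalization", x, y)
            li[name] = compute_debias(s, k=19, seed=11, normalize=False).li
        assert li["near"] > li["far"]


class TestResampledAlignment:
    def test_constant_inputs_give_zero(self):
        s = PairedSample("orientation", np.full(100, 30.0), np.full(100, 30.0))
        np.testing.assert_array_equal(resampled_alignment(s, seed=1), 0.0)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(9)
        s = PairedSample("orientation", rng.uniform(-90, 90, 500), rng.uniform(-90, 90, 500))
        a = resampled_alignment(s, seed=42)
        b = resampled_alignment(s, seed=42)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, resampled_alignment(s, seed=43))


class TestComputeDebias:
    def test_result_identity_and_metadata(self):
        rng = np.random.default_rng(2)
        s = PairedSample("orientation", rng.uniform(-90, 90, 1000), rng.uniform(-90, 90, 1000))
        r = compute_debias(s, k=15, seed=5, resample_reps=3)
        assert r.gi == r.emd_resampled
        assert r.gi + r.li == pytest.approx(r.emd_observed, abs=1e-12)
        assert (r.k, r.n, r.mode, r.seed, r.resample_reps) == (15, 1000, "orientation", 5, 3)

    def test_bitwise_deterministic(self):
        rng = np.random.default_rng(3)
        s = PairedSample("orientation", rng.uniform(-90, 90, 800), rng.uniform(-90, 90, 800))
        assert compute_debias(s, k=15, seed=7) == compute_debias(s, k=15, seed=7)

    @pytest.mark.parametrize("k", [2, 3, 15, 33, 50])
    def test_constant_identical_inputs_maximal_gi(self, k):
        """All pairs identical and equal: GI = (K-1)/2 exactly, LI = 0."""
        s = PairedSample("orientation", np.full(200, 12.0), np.full(200, 12.0))
        r = compute_debias(s, k=k, seed=1)
        assert r.gi == pytest.approx((k - 1) / 2, abs=1e-12)
        assert r.li == pytest.approx(0.0, abs=1e-12)

    def test_perfect_alignment_uniform_marginals(self):
        """x uniform and y = x: LI tends to (K-1)/2 and GI to 0."""
        x = np.random.default_rng(3).uniform(-90, 90, 100_000)
        r = compute_debias(PairedSample("orientation", x, x.copy()), k=15, seed=5)
        assert r.li == pytest.approx(7.0, abs=0.2)
        assert r.gi == pytest.approx(0.0, abs=0.2)

    def test_independent_marginals_li_near_zero(self):
        """Destroying nothing: for independent x, y the median LI vanishes."""
        lis = []
        for s in range(50):
            samp = simulate_coorientation(
                OrientationSimConfig(sigma_x=30, sigma_y=30, n=10_000, seed=s)
            )
            lis.append(compute_debias(samp, k=15, seed=7000 + s).li)
        assert abs(np.median(lis)) < 0.15

    def test_uniform_marginals_gi_near_zero(self):
        gis = []
        for s in range(50):
            g = np.random.default_rng(s)
            samp = PairedSample(
                "orientation", g.uniform(-90, 90, 10_000), g.uniform(-90, 90, 10_000)
            )
            gis.append(compute_debias(samp, k=15, seed=8000 + s).gi)
        assert abs(np.median(gis)) < 0.15

    def test_gi_decreases_with_marginal_spread(self):
        """Wider truncated-normal marginals mean less global bias."""
        means = []
        for sigma in (5, 10, 20, 40, 80):
            gis = [
                compute_debias(
                    simulate_coorientation(
                        OrientationSimConfig(sigma_x=sigma, sigma_y=sigma, n=3000, seed=s)
                    ),
                    k=15,
                    seed=300 + s,
                ).gi
                for s in range(20)
            ]
            means.append(np.mean(gis))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_li_lower_bounds_true_interaction_contribution(self):
        """LI never exceeds the observed-alignment shift the interaction caused."""
        excess = []
        u = uniform_reference(15, 0, 90)
        for s in range(20):
            base = dict(sigma_x=25, sigma_y=25, n=5000, seed=s)
            pre = simulate_coorientation(
                OrientationSimConfig(interaction=("constant", 0.0), **base)
            )
            post = simulate_coorientation(
                OrientationSimConfig(interaction=("constant", 5.0), **base)
            )
            e_pre = emd(u, quantize(alignment_values(pre), 0, 90, 15))
            e_post = emd(u, quantize(alignment_values(post), 0, 90, 15))
            li = compute_debias(post, k=15, seed=900 + s).li
            excess.append(li - (e_post - e_pre))
        assert np.mean(excess) <= 0.2

    def test_anti_alignment_gives_negative_li(self):
        lis = [
            compute_debias(
                simulate_coorientation(
                    OrientationSimConfig(
                        sigma_x=25, sigma_y=25, interaction=("proportional", -0.5),
                        n=5000, seed=s,
                    )
                ),
                k=15,
                seed=500 + s,
            ).li
            for s in range(10)
        ]
        assert np.mean(lis) < 0

    def test_li_never_clipped(self):
        """A strongly anti-aligned sample must report li < 0, not 0."""
        samp = simulate_coorientation(
            OrientationSimConfig(
                sigma_x=25, sigma_y=25, interaction=("proportional", -1.0), n=5000, seed=3
            )
        )
        assert compute_debias(samp, k=15, seed=4).li < -0.5

    def test_subsample_robustness_and_k_ordering(self):
        """Indices are stable in N and condition ordering is stable in K."""
        full = simulate_coorientation(
            OrientationSimConfig(
                sigma_x=25, sigma_y=25, interaction=("proportional", 0.5), n=10_000, seed=11
            )
        )
        rf = compute_debias(full, k=15, seed=77)
        g = np.random.default_rng(123)
        for n in (500, 1000, 3000):
            gis, lis = [], []
            for _ in range(11):
                r = compute_debias(full.subsample(n, g), k=15, seed=int(g.integers(2**31)))
                gis.append(r.gi)
                lis.append(r.li)
            assert abs(np.median(gis) - rf.gi) / rf.gi < 0.10
            assert abs(np.median(lis) - rf.li) / rf.li < 0.10

        a = simulate_coorientation(
            OrientationSimConfig(sigma_x=25, sigma_y=25, interaction=("proportional", 0.2), n=10_000, seed=21)
        )
        b = simulate_coorientation(
            OrientationSimConfig(sigma_x=25, sigma_y=25, interaction=("proportional", 0.5), n=10_000, seed=22)
        )
        li_sign = gi_sign = None
        for k in (5, 10, 15, 20, 25):
            ra, rb = compute_debias(a, k=k, seed=31), compute_debias(b, k=k, seed=32)
            ls, gs = np.sign(rb.li - ra.li), np.sign(rb.gi - ra.gi)
            li_sign = ls if li_sign is None else li_sign
            gi_sign = gs if gi_sign is None else gi_sign
            assert ls == li_sign and gs == gi_sign

    def test_resample_reps_reduce_gi_spread(self):
        """Averaging several resampled histograms shrinks GI's seed variance."""
        rng = np.random.default_rng(8)
        s = PairedSample("orientation", rng.uniform(-90, 90, 400), rng.uniform(-90, 90, 400))
        gi1 = [compute_debias(s, k=15, seed=i).gi for i in range(30)]
        gi20 = [compute_debias(s, k=15, seed=i, resample_reps=20).gi for i in range(30)]
        assert np.std(gi20) < np.std(gi1)
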