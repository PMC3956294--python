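import numpy as np
import pytest

from nodescale.profiles import (
    IntensityProfile,
    ProfileError,
    _midplane_outline,
    cortical_profile_by_angle,
    count_molecules,
    find_nodes,
    fit_decay_length,
    fit_frap,
    fit_node_band,
    medial_band_intensity,
    read_profile_csv,
    write_profile_csv,
)
from nodescale.synthetic import (
    SyntheticCell,
    gen_frap,
    gen_node_dot_profile,
    gen_pom1_profiles,
)


def gaussian_profile(a=10.0, x0=0.0, sigma=1.2, b=1.0, span=10.0, n=101,
                     background=0.0):
    x = np.linspace(-span / 2, span / 2, n)
    I = a * np.exp(-((x - x0) ** 2) / (2 * sigma**2)) + b
    return IntensityProfile(x=x, I=I, background=background, L=span)


class TestDecayLength:
    def test_noiseless_recovery(self):
        p = gen_pom1_profiles(lam=1.5, fluctuation_cv=0.0, n=1, seed=0)[0]
        fit = fit_decay_length(p)
        assert fit.ok
        assert fit.lam == pytest.approx(1.5, abs=1e-3)

    def test_flat_profile_flagged(self):
        x = np.arange(0.0, 6.0, 0.05)
        p = IntensityProfile(x=x, I=np.ones_like(x), kind="tip-gradient")
        fit = fit_decay_length(p)
        assert not fit.ok and np.isnan(fit.lam)

    def test_rising_profile_flagged(self):
        x = np.arange(0.0, 6.0, 0.05)
        p = IntensityProfile(x=x, I=1 + x, kind="tip-gradient")
        assert not fit_decay_length(p).ok

    def test_monte_carlo_recovery(self):
        """100 noisy replicates at lambda = 1.0 recover the mean within 3%."""
        lams = [fit_decay_length(p).lam
                for p in gen_pom1_profiles(lam=1.0, fluctuation_cv=0.05,
                                           n=100, seed=42)]
        assert np.mean(lams) == pytest.approx(1.0, rel=0.03)

    def test_scale_invariance(self):
        p = gen_pom1_profiles(lam=1.2, fluctuation_cv=0.03, n=1, seed=7)[0]
        lam0 = fit_decay_length(p).lam
        for c in (0.1, 17.0):
            scaled = IntensityProfile(x=p.x, I=c * p.I,
                                      background=c * p.background,
                                      kind="tip-gradient")
            assert fit_decay_length(scaled).lam == pytest.approx(lam0, rel=1e-6)

    def test_short_profile_rejected(self):
        x = np.arange(0.0, 3.0, 0.05)
        p = IntensityProfile(x=x, I=np.exp(-x), kind="tip-gradient")
        with pytest.raises(ProfileError):
            fit_decay_length(p)


class TestNodeBand:
    def test_noiseless_exact_recovery(self):
        fit = fit_node_band(gaussian_profile(a=10, x0=0, sigma=1.2, b=1))
        assert fit.accepted
        assert fit.amp == pytest.approx(10.0, rel=1e-6)
        assert fit.center == pytest.approx(0.0, abs=1e-8)
        assert fit.sigma == pytest.approx(1.2, rel=1e-6)
        assert fit.offset == pytest.approx(1.0, rel=1e-6)

    def test_narrow_band_rejected_by_sigma_filter(self):
        """A very narrow apparent band (one bright node) fails the filter."""
        fit = fit_node_band(gaussian_profile(sigma=0.3))
        assert fit.sigma < 0.5
        assert not fit.accepted
        assert "sigma" in fit.reason

    def test_poor_fit_rejected(self, rng):
        x = np.linspace(-5, 5, 101)
        p = IntensityProfile(x=x, I=rng.uniform(0, 10, x.size), L=10.0)
        fit = fit_node_band(p)
        assert not fit.accepted

    def test_batch_yield_matches_filter_fraction(self, rng):
        """Of 385 profiles generated so that 237/385 carry a wide clean band
        and the rest a narrow one, about 237 pass the sigma/quality filter."""
        n, n_good = 385, 237
        accepted = 0
        for i in range(n):
            sigma = 1.2 if i < n_good else 0.3
            x = np.linspace(-5, 5, 101)
            I = (8.0 * np.exp(-x**2 / (2 * sigma**2)) + 1.0)
            I = I * (1 + 0.03 * rng.standard_normal(x.size))
            if fit_node_band(IntensityProfile(x=x, I=I, L=10.0)).accepted:
                accepted += 1
        sd = np.sqrt(n * (n_good / n) * (1 - n_good / n))
        assert abs(accepted - n_good) <= 3 * sd + 1

    def test_scale_invariance(self, rng):
        x = np.linspace(-5, 5, 101)
        I = 8 * np.exp(-x**2 / (2 * 1.1**2)) + 1 + 0.05 * rng.standard_normal(x.size)
        f0 = fit_node_band(IntensityProfile(x=x, I=I, L=10.0))
        f1 = fit_node_band(IntensityProfile(x=x, I=5.5 * I, L=10.0))
        assert f1.sigma == pytest.approx(f0.sigma, rel=1e-6)
        assert f1.center == pytest.approx(f0.center, abs=1e-6)

    def test_too_few_points_rejected(self):
        p = IntensityProfile(x=[0, 1, 2, 3], I=[1, 2, 1, 0.5])
        with pytest.raises(ProfileError):
            fit_node_band(p)


class TestMedialBand:
    def test_pure_background_sums_to_zero(self):
        x = np.linspace(-5, 5, 101)
        p = IntensityProfile(x=x, I=np.full(x.size, 2.5), background=2.5)
        total, mean = medial_band_intensity(p, width=3.0)
        assert total == pytest.approx(0.0, abs=1e-12)
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_known_band_signal_recovered(self):
        cell = SyntheticCell(id="c", L=12.0, R=1.5)
        from nodescale.synthetic import gen_cdr2_profiles

        profs = gen_cdr2_profiles(cell, rho_cor=0.5, rho_nod=40.0,
                                  noise=0.0, seed=0)
        total, _ = medial_band_intensity(profs["axial"], width=3.0)
        assert total == pytest.approx(cell.truth["band_signal_sum"], rel=1e-9)

    def test_full_width_equals_whole_profile_sum(self):
        x = np.linspace(-6, 6, 121)
        I = 3 + np.exp(-x**2)
        p = IntensityProfile(x=x, I=I, background=3.0)
        total, _ = medial_band_intensity(p, width=12.0)
        assert total == pytest.approx(np.sum(I - 3.0), rel=1e-12)

    def test_additive_over_disjoint_subbands(self):
        x = np.linspace(-6, 6, 241)
        p = IntensityProfile(x=x, I=np.exp(-x**2 / 2) + 1, background=1.0)
        whole, _ = medial_band_intensity(p, width=4.0, center=0.0)
        left, _ = medial_band_intensity(p, width=2.0, center=-1.0)
        # right half-band: points with 0 < x <= 2 (avoid double-counting x=0)
        sel = (x > 0) & (x <= 2)
        right = np.sum(p.I[sel] - 1.0)
        assert whole == pytest.approx(left + right, rel=1e-9)

    def test_band_beyond_extent_rejected(self):
        p = gaussian_profile(span=4.0)
        with pytest.raises(ProfileError):
            medial_band_intensity(p, width=6.0)


class TestFindNodes:
    def _peaks_profile(self, centers, background=1.0, height=10.0):
        x = np.arange(0.0, 12.0, 0.02)
        I = np.full(x.size, background)
        for c in centers:
            I = I + height * np.exp(-((x - c) ** 2) / (2 * 0.1**2))
        return IntensityProfile(x=x, I=I, background=background)

    def test_counts_well_separated_peaks(self):
        centers = [1.5, 3.0, 4.5, 6.0, 7.5, 9.0, 10.5]
        count, intensities = find_nodes(self._peaks_profile(centers))
        assert count == 7
        assert np.allclose(intensities, 10.0, rtol=1e-3)

    def test_background_only_finds_nothing(self):
        x = np.arange(0.0, 12.0, 0.02)
        p = IntensityProfile(x=x, I=np.full(x.size, 1.0), background=1.0)
        assert find_nodes(p)[0] == 0

    def test_merged_peaks_undercount(self):
        """Two nodes within one resolution element register once."""
        count, _ = find_nodes(self._peaks_profile([5.0, 5.08]))
        assert count == 1

    def test_count_monotone_in_threshold(self):
        p = self._peaks_profile([2, 4, 6, 8], height=3.0)
        counts = [find_nodes(p, threshold_factor=tf)[0]
                  for tf in (3.5, 2.0, 1.2)]
        assert counts == sorted(counts)

    def test_dot_profile_counts_rise_with_length(self):
        means = []
        for L in (8.0, 14.0):
            vals = []
            for seed in range(8):
                cell = SyntheticCell(id="c", L=L, R=1.5)
                prof = gen_node_dot_profile(cell, rho_nod=2.5 * L / 10,
                                            seed=seed)
                vals.append(find_nodes(prof)[0])
            means.append(np.mean(vals))
        assert means[1] > means[0]


class TestFrap:
    def test_noiseless_inversion(self):
        t, I = gen_frap(noise=0.0, n=1, seed=0)[0]
        fit = fit_frap(t, I)
        assert fit.ok
        assert fit.t_half == pytest.approx(180.0, rel=1e-9)

    def test_monte_carlo_half_time(self):
        """14 noisy traces at t1/2 = 3 min recover the mean within 10%."""
        fits = [fit_frap(t, I) for t, I in gen_frap(noise=0.05, n=14, seed=11)]
        assert all(f.ok for f in fits)
        assert np.mean([f.t_half for f in fits]) == pytest.approx(180.0, rel=0.10)

    def test_flat_trace_flagged(self):
        t = np.linspace(0, 600, 30)
        fit = fit_frap(t, np.ones_like(t))
        assert not fit.ok

    def test_decreasing_trace_flagged(self):
        t = np.linspace(0, 600, 30)
        fit = fit_frap(t, np.exp(-t / 100.0))
        assert not fit.ok

    def test_too_few_points_rejected(self):
        with pytest.raises(ProfileError):
            fit_frap([0, 1, 2], [0, 0.5, 0.7])


class TestMoleculeCounting:
    @pytest.mark.parametrize(
        "sample, standard, count, expect",
        [(5.0, 5.0, 22, 22.0), (4.09 * 22, 22, 22, 90.0), (0.0, 7.0, 22, 0.0)],
    )
    def test_ratio(self, sample, standard, count, expect):
        assert count_molecules(sample, standard, count) == pytest.approx(
            expect, abs=0.05)

    def test_bad_standard_rejected(self):
        with pytest.raises(ValueError):
            count_molecules(1.0, 0.0)


class TestCorticalLoop:
    def _painted_loop(self, L=12.0, R=1.5, fn=None, n=600):
        """Loop whose intensity is a known function of tip distance."""
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        th_ref, d_ref = _midplane_outline(L, R)
        order = np.argsort(th_ref)
        folded = np.where(theta <= np.pi, theta, 2 * np.pi - theta)
        d = np.interp(folded, th_ref[order], d_ref[order])
        I = fn(d) if fn else np.full(n, 1.0)
        return IntensityProfile(x=theta, I=I, kind="cortical-loop", L=L)

    def test_uniform_loop(self):
        loop = self._painted_loop()
        out = cortical_profile_by_angle(loop, sectors=100, R=1.5)
        assert not out["missing"].any()
        assert np.allclose(out["intensity"], 1.0)

    def test_painted_gradient_round_trip(self):
        lam = 1.5
        loop = self._painted_loop(fn=lambda d: np.exp(-d / lam))
        out = cortical_profile_by_angle(loop, sectors=100, R=1.5)
        expect = np.exp(-out["tip_distance_um"] / lam)
        assert np.nanmax(np.abs(out["intensity"] - expect)) < 0.05

    def test_opposite_tip_distance(self):
        """The sector at angle pi sits half a perimeter from the near tip."""
        L, R = 12.0, 1.5
        loop = self._painted_loop(L=L, R=R)
        out = cortical_profile_by_angle(loop, sectors=100, R=R)
        i = np.argmin(np.abs(out["angle_rad"] - np.pi))
        half_perimeter = np.pi * R + (L - 2 * R)
        assert out["tip_distance_um"].iloc[i] == pytest.approx(
            half_perimeter, rel=0.02)

    def test_empty_sectors_flagged_not_interpolated(self):
        theta = np.linspace(0, np.pi, 100)  # only half the loop sampled
        loop = IntensityProfile(x=theta, I=np.ones(100),
                                kind="cortical-loop", L=12.0)
        out = cortical_profile_by_angle(loop, sectors=100, R=1.5)
        assert out["missing"].any()
        assert np.isnan(out.loc[out["missing"], "intensity"]).all()


def test_profile_csv_round_trip(tmp_path):
    p = gen_pom1_profiles(lam=1.1, fluctuation_cv=0.05, n=1, seed=5)[0]
    path = tmp_path / "profile.csv"
    write_profile_csv(p, path)
    q = read_profile_csv(path)
    assert np.allclose(p.x, q.x) and np.allclose(p.I, q.I)
    assert q.kind == p.kind and q.background == p.background
    assert q.cell_id == p.cell_id
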