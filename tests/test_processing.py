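import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmropls.processing import (
    BinnedMatrix,
    ExclusionPolicy,
    ReferencingError,
    Spectrum,
    apply_exclusions,
    bin_cohort,
    bin_spectrum,
    default_exclusion_policy,
    detect_noise_bins,
    normalize,
    reference_spectrum,
)
from nmropls.simulate import CohortDesign, simulate_cohort, simulate_spectrum
from nmropls.templates import MetaboliteTemplate, Peak


def make_spectrum(ppm, intensity, matrix="plasma", sample_id="s1"):
    return Spectrum(ppm=np.asarray(ppm, float), intensity=np.asarray(intensity, float),
                    sample_id=sample_id, matrix=matrix)


def lorentzian(ppm, center, hw=0.0035, height=1.0):
    return height * hw**2 / ((ppm - center) ** 2 + hw**2)


class TestSpectrumInvariants:
    def test_non_monotonic_rejected(self):
        with pytest.raises(ValueError, match="monotonic"):
            make_spectrum([0.0, 1.0, 0.5], [1, 1, 1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            make_spectrum([0.0, 1.0], [1, 1, 1])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            make_spectrum([0.0, 1.0, 2.0], [1, np.nan, 1])


class TestReferencing:
    def test_apex_shift(self):
        ppm = np.linspace(-0.2, 0.2, 2001)
        s = make_spectrum(ppm, lorentzian(ppm, 0.013, height=50.0), matrix="brain")
        out = reference_spectrum(s, 0.0, (-0.1, 0.1))
        assert out.meta["reference_shift"] == pytest.approx(-0.013, abs=1e-9)
        apex = out.ppm[np.argmax(out.intensity)]
        assert apex == pytest.approx(0.0, abs=1e-9)
        assert np.array_equal(out.intensity, s.intensity)

    def test_idempotent(self):
        ppm = np.linspace(-0.2, 0.2, 2001)
        s = make_spectrum(ppm, lorentzian(ppm, 0.0, height=50.0), matrix="brain")
        out = reference_spectrum(s, 0.0, (-0.1, 0.1))
        assert out.meta["reference_shift"] == pytest.approx(0.0, abs=1e-12)
        assert np.array_equal(out.ppm, s.ppm)

    def test_plasma_lactate_lands_on_target(self):
        # simulate with known jitter: apex must land at 1.33 +/- a grid step
        design = CohortDesign(
            n_group_a=2, n_group_b=2, matrix="plasma",
            effects={}, noise_sd=0.01, shift_jitter_sd=0.004,
            baseline_amplitude=0.0, ppm_grid=(0.5, 2.0, 3001), seed=21,
        )
        grid_step = 1.5 / 3000
        for i in range(2):
            s = simulate_spectrum(design, "A", i)
            out = reference_spectrum(s, 1.33, (1.2, 1.45))
            apex = out.ppm[np.argmax(np.where((out.ppm > 1.2) & (out.ppm < 1.45),
                                              out.intensity, -np.inf))]
            assert abs(apex - 1.33) <= grid_step + 1e-12

    def test_no_peak_rejected(self):
        ppm = np.linspace(0.0, 1.0, 1001)
        rng = np.random.default_rng(0)
        s = make_spectrum(ppm, rng.normal(0, 1e-3, ppm.size))
        with pytest.raises(ReferencingError, match="noise floor"):
            reference_spectrum(s, 0.5, (0.4, 0.6))

    def test_window_off_axis_rejected(self):
        ppm = np.linspace(0.0, 1.0, 1001)
        s = make_spectrum(ppm, lorentzian(ppm, 0.5))
        with pytest.raises(ReferencingError, match="overlap"):
            reference_spectrum(s, 5.0, (4.0, 6.0))


class TestBinning:
    def test_constant_intensity_two_bins(self):
        # 40 evenly spaced points spanning [0.00, 0.04)
        ppm = np.arange(40) * 0.001
        values, edges = bin_spectrum(make_spectrum(ppm, np.ones(40)), width=0.02)
        assert len(values) == 2
        assert values[0] == pytest.approx(20.0)
        assert values[1] == pytest.approx(20.0)
        assert edges == [(0.0, 0.02), (0.02, 0.04)]

    def test_conservation(self):
        design = CohortDesign(
            n_group_a=2, n_group_b=2, matrix="plasma", effects={},
            ppm_grid=(0.0, 5.0, 5001), seed=3,
        )
        s = simulate_spectrum(design, "A", 0)
        values, _ = bin_spectrum(s)
        assert values.sum() == pytest.approx(s.intensity.sum(), rel=1e-10)

    def test_straddled_bins_conserve_singlet(self):
        # narrow gaussian, center shifted by an integer number of grid steps:
        # brute-force per-point assignment is the oracle
        step = 0.0005
        ppm = np.arange(0.0, 1.0, step)
        sigma = 0.001

        def binned_by_bruteforce(center):
            y = np.exp(-((ppm - center) ** 2) / (2 * sigma**2))
            sums = {}
            for x, v in zip(ppm, y):
                k = int(np.floor(x / 0.02))
                sums[k] = sums.get(k, 0.0) + v
            return y, sums

        y_mid, oracle_mid = binned_by_bruteforce(0.51)  # mid-bin of [0.50, 0.52)
        y_edge, oracle_edge = binned_by_bruteforce(0.50)  # straddles the edge

        values_mid, edges = bin_spectrum(make_spectrum(ppm, y_mid), width=0.02)
        values_edge, _ = bin_spectrum(make_spectrum(ppm, y_edge), width=0.02)
        k_lo = int(round(edges[0][0] / 0.02))
        for k, expected in oracle_mid.items():
            assert values_mid[k - k_lo] == pytest.approx(expected, rel=1e-12)
        centered = values_mid[25 - k_lo]
        straddled = values_edge[24 - k_lo] + values_edge[25 - k_lo]
        assert straddled == pytest.approx(centered, rel=1e-9)

    def test_bad_width_rejected(self):
        ppm = np.linspace(0, 1, 100)
        with pytest.raises(ValueError, match="width"):
            bin_spectrum(make_spectrum(ppm, np.ones(100)), width=0.0)

    @given(scale=st.floats(0.1, 10.0), offset=st.floats(-0.009, 0.009))
    @settings(max_examples=20, deadline=None)
    def test_conservation_property(self, scale, offset):
        ppm = np.linspace(0.7 + offset, 2.0 + offset, 500)
        rng = np.random.default_rng(8)
        intensity = scale * rng.random(500)
        values, _ = bin_spectrum(make_spectrum(ppm, intensity))
        assert values.sum() == pytest.approx(intensity.sum(), rel=1e-10)


def toy_matrix(values, lo_ppm=0.7, matrix="plasma", groups=None):
    values = np.asarray(values, float)
    n, p = values.shape
    edges = [(round(lo_ppm + 0.02 * i, 10), round(lo_ppm + 0.02 * (i + 1), 10)) for i in range(p)]
    return BinnedMatrix(
        values=values,
        bin_edges=edges,
        sample_ids=[f"s{i}" for i in range(n)],
        groups=groups or ["A"] * n,
        matrix=matrix,
        stages=["bin"],
    )


def grid_matrix(lo=0.7, hi=9.38, n_samples=3, matrix="plasma"):
    n_bins = int(round((hi - lo) / 0.02))
    return toy_matrix(np.ones((n_samples, n_bins)), lo_ppm=lo, matrix=matrix)


class TestExclusions:
    def test_retained_count_384(self):
        # (9.38-0.7)/0.02 - (6.0-5.0)/0.02 = 434 - 50
        m = grid_matrix()
        policy = ExclusionPolicy(regions=[
            (-np.inf, 0.7, "below-0.7"),
            (9.38, np.inf, "above-9.38"),
            (5.0, 6.0, "water/noise-region"),
        ])
        out = apply_exclusions(m, policy)
        assert int(out.retained.sum()) == 384

    def test_zero_regions_identity(self):
        m = grid_matrix()
        out = apply_exclusions(m, ExclusionPolicy(regions=[]))
        assert not out.excluded.any()

    def test_edta_plasma_only(self):
        plasma = apply_exclusions(grid_matrix(matrix="plasma"),
                                  default_exclusion_policy("plasma"))
        brain = apply_exclusions(grid_matrix(matrix="brain"),
                                 default_exclusion_policy("brain"))
        assert "EDTA" in set(plasma.excluded_reason)
        assert "EDTA" not in set(brain.excluded_reason)

    def test_values_untouched(self):
        m = grid_matrix()
        out = apply_exclusions(m, default_exclusion_policy("plasma"))
        assert np.array_equal(out.values, m.values)

    def test_one_reason_per_bin(self):
        m = grid_matrix(lo=0.0, hi=9.5)
        out = apply_exclusions(m, default_exclusion_policy("plasma"))
        for reason in out.excluded_reason:
            assert reason is None or isinstance(reason, str)

    def test_bad_label_rejected(self):
        with pytest.raises(ValueError, match="label"):
            ExclusionPolicy(regions=[(1.0, 2.0, "mystery")])


class TestNoiseBins:
    @staticmethod
    def tiled_gaussian_design(noise_sd):
        # gaussian peaks tile [0.1, 0.8]; [0.8, 1.0] is true empty noise
        peaks = tuple(Peak(c, 1.0, 0.02, "gaussian") for c in np.arange(0.1, 0.8, 0.04))
        lib = [MetaboliteTemplate("blanket", "plasma", peaks)]
        return CohortDesign(
            n_group_a=5, n_group_b=5, matrix="plasma", effects={},
            noise_sd=noise_sd, shift_jitter_sd=0.0, baseline_amplitude=0.0,
            biological_sd=0.15, ppm_grid=(0.0, 1.0, 2000), seed=17, library=lib,
        )

    def run(self, noise_sd):
        spectra, meta, _ = simulate_cohort(self.tiled_gaussian_design(noise_sd))
        m = bin_cohort(spectra, list(meta.group))
        policy = ExclusionPolicy(regions=[(-np.inf, 0.05, "below-0.7")])
        m = apply_exclusions(m, policy)
        return detect_noise_bins(m, policy)

    def test_pure_noise_bins_flagged(self):
        out = self.run(noise_sd=0.05)
        flagged = np.array([r == "RSD-noise" for r in out.excluded_reason])
        is_noise = np.array([lo >= 0.84 for lo, _ in out.bin_edges])
        assert flagged[is_noise].mean() >= 0.9

    def test_no_peak_bins_flagged_in_noiseless_cohort(self):
        out = self.run(noise_sd=0.0)
        flagged = np.array([r == "RSD-noise" for r in out.excluded_reason])
        is_peak = np.array([hi <= 0.8 and lo >= 0.08 for lo, hi in out.bin_edges])
        assert not flagged[is_peak].any()

    def test_identical_values_never_flagged(self):
        m = toy_matrix(np.ones((4, 10)))
        policy = ExclusionPolicy(regions=[])
        m = apply_exclusions(m, policy)
        out = detect_noise_bins(m, policy)
        assert "RSD-noise" not in set(out.excluded_reason)

    def test_zero_mean_bin_infinite_rsd(self):
        values = np.ones((4, 10))
        values[:, 3] = [1.0, -1.0, 1.0, -1.0]  # mean 0
        m = toy_matrix(values)
        policy = ExclusionPolicy(regions=[])
        m = apply_exclusions(m, policy)
        out = detect_noise_bins(m, policy)
        log = out.meta["noise_log"]
        assert np.isinf(log.rsd.iloc[3])
        assert out.excluded_reason[3] == "RSD-noise"

    def test_two_samples_rejected(self):
        m = toy_matrix(np.ones((2, 10)))
        policy = ExclusionPolicy(regions=[])
        m = apply_exclusions(m, policy)
        with pytest.raises(ValueError, match=">=3 samples"):
            detect_noise_bins(m, policy)

    def test_requires_exclusions_first(self):
        m = toy_matrix(np.ones((4, 10)))
        with pytest.raises(ValueError, match="apply_exclusions"):
            detect_noise_bins(m, ExclusionPolicy(regions=[]))


class TestNormalize:
    def test_total_area_rows_sum_100(self, plasma_matrix):
        sums = plasma_matrix.retained_values().sum(axis=1)
        assert np.allclose(sums, 100.0, rtol=1e-8)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        values = rng.random((4, 20)) + 0.1
        m1 = apply_exclusions(toy_matrix(values), ExclusionPolicy(regions=[]))
        scaled = values.copy()
        scaled[2] *= 7.0
        m2 = apply_exclusions(toy_matrix(scaled), ExclusionPolicy(regions=[]))
        n1 = normalize(m1, "total_area")
        n2 = normalize(m2, "total_area")
        assert np.allclose(n1.values, n2.values, rtol=1e-12)

    def test_total_area_idempotent(self):
        rng = np.random.default_rng(6)
        m = apply_exclusions(toy_matrix(rng.random((3, 15)) + 0.1),
                             ExclusionPolicy(regions=[]))
        once = normalize(m, "total_area")
        twice = normalize(once, "total_area")
        assert np.allclose(once.values, twice.values, rtol=1e-12)

    def test_tsp_column_constant_one(self):
        # brain cohort with TSP abundance varied +/-20% across samples
        rng = np.random.default_rng(9)
        values = rng.random((5, 50)) + 0.5
        tsp_col = 0  # bin [0.0, 0.02)
        values[:, tsp_col] = 1.0 + rng.uniform(-0.2, 0.2, 5)
        m = toy_matrix(values, lo_ppm=0.0, matrix="brain")
        m = apply_exclusions(m, ExclusionPolicy(regions=[(-np.inf, 0.7, "below-0.7")]))
        out = normalize(normalize(m, "total_area"), "tsp")
        assert np.allclose(out.values[:, tsp_col], 1.0, rtol=1e-12)
        assert out.normalization == "total_area+tsp"

    def test_tsp_for_plasma_rejected(self):
        m = toy_matrix(np.ones((3, 10)), lo_ppm=0.0, matrix="plasma")
        with pytest.raises(ValueError, match="brain"):
            normalize(m, "tsp")

    def test_nonpositive_tsp_bin_rejected(self):
        values = np.ones((3, 10))
        values[1, 0] = 0.0
        m = toy_matrix(values, lo_ppm=0.0, matrix="brain")
        with pytest.raises(ValueError, match="TSP"):
            normalize(m, "tsp")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            normalize(toy_matrix(np.ones((3, 5))), "pqn")

    def test_pipeline_order_recorded(self, plasma_matrix):
        assert plasma_matrix.stages == [
            "bin", "exclude", "noise-detect", "normalize:total_area",
        ]
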