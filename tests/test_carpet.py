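"""Carpet extraction, pCF/pCCF correlations, alignment, distances."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nanolayers import synthgen
from nanolayers.carpet import (
    IntensityCarpet,
    align_carpet,
    apply_shifts,
    average_aligned_profile,
    column_distances,
    distance_distribution,
    extract_carpet,
    pccf,
    pcf,
    refined_argmax,
)
from nanolayers.containers import (
    GeometryError,
    InvalidParameterError,
    SuperResImage,
)

QUIET = synthgen.NoiseSpec(poisson=False, read_sigma=0.0, background=0.0)


def _gauss_profile(n, center, sigma=3.0, amp=100.0, baseline=5.0):
    y = np.arange(n)
    return baseline + amp * np.exp(-((y - center) ** 2) / (2 * sigma ** 2))


def _carpet_from_centers(centers, n=80, replicate="cell0", **kw):
    cols = np.column_stack([_gauss_profile(n, c, **kw) for c in centers])
    return IntensityCarpet(columns=cols, row_spacing_nm=25.0,
                           replicate_id=replicate)


class TestExtraction:
    def test_identity_rotation_matches_subimage(self):
        rng = np.random.default_rng(0)
        img = SuperResImage(rng.random((40, 60)), 25.0)
        c = extract_carpet(img, (250.0, 250.0, 750.0, 500.0), 0.0)
        np.testing.assert_allclose(c.columns, img.values[10:30, 10:40],
                                   atol=1e-9)

    def test_quarter_turn_maps_vertical_stripe_to_constant_peak_row(self):
        img_v = np.zeros((60, 60))
        img_v[:, 30] = 100.0  # vertical stripe: membrane along y
        img = SuperResImage(img_v, 25.0)
        c = extract_carpet(img, (250.0, 250.0, 1000.0, 1000.0), 90.0)
        peaks = c.columns.argmax(axis=0)
        assert np.all(peaks == peaks[0])
        assert c.columns.max() > 10.0

    def test_column_binning_averages_pixel_columns(self):
        rng = np.random.default_rng(1)
        img = SuperResImage(rng.random((20, 40)), 25.0)
        c = extract_carpet(img, (0.0, 0.0, 1000.0, 500.0), 0.0,
                           column_width_nm=50.0)
        expect = img.values.reshape(20, 20, 2).mean(axis=2)
        np.testing.assert_allclose(c.columns, expect, atol=1e-9)

    def test_rotated_roi_outside_image_rejected(self):
        img = SuperResImage(np.ones((20, 20)), 25.0)
        with pytest.raises(GeometryError):
            extract_carpet(img, (0.0, 0.0, 500.0, 500.0), 45.0)

    def test_column_peaks_track_the_membrane_apex(self, deformed_membrane_pair):
        ref, _ = deformed_membrane_pair
        c = extract_carpet(ref, (0.0, 0.0, 10_000.0, 5_000.0), 0.0)
        y_true = np.array(ref.provenance["ground_truth"]["centerline_y_nm"])
        peaks_nm = c.y_nm[c.columns.argmax(axis=0)]
        # smoothed per-column apex positions follow the ground truth
        err = peaks_nm - y_true
        assert np.median(np.abs(err)) <= 25.0  # within one pixel


class TestPairedCorrelation:
    def test_autocorrelation_peaks_at_zero_lag(self):
        p = _gauss_profile(60, 30.0)
        lags, vals = pcf(p, p, 20)
        assert lags[np.nanargmax(vals)] == 0

    def test_integer_translation_recovered_exactly(self):
        p = _gauss_profile(80, 35.0)
        for k in (-5, -1, 2, 7):
            shifted = np.roll(p, k)
            lags, vals = pcf(p, shifted, 15)
            assert lags[np.nanargmax(vals)] == k

    def test_constant_profile_gives_zero_everywhere(self):
        lags, vals = pcf(np.full(50, 3.0), _gauss_profile(50, 25.0), 10)
        np.testing.assert_allclose(vals, 0.0, atol=1e-12)

    def test_zero_mean_profile_rejected(self):
        with pytest.raises(InvalidParameterError):
            pcf(np.zeros(30), np.ones(30), 5)

    def test_subbin_shift_recovered_noiseless(self):
        y = np.arange(120)
        for true in (0.3, -0.45, 1.35):
            a = 100.0 * np.exp(-((y - 60.0) ** 2) / (2 * 4.0 ** 2)) + 10.0
            b = 100.0 * np.exp(-((y - 60.0 - true) ** 2) / (2 * 4.0 ** 2)) + 10.0
            lags, vals = pcf(a, b, 20)
            lag, _ = refined_argmax(lags, vals)
            assert abs(lag - true) <= 0.05

    def test_subbin_shift_estimator_unbiased_at_snr_ten(self):
        # single-column estimates jitter with the correlation noise; the
        # estimator is accurate to < 0.2 bin once ~30 columns average out
        rng = np.random.default_rng(2)
        y = np.arange(200)
        true = 0.35
        lags_hat = []
        for _ in range(30):
            a = (100.0 * np.exp(-((y - 100.0) ** 2) / (2 * 2.0 ** 2)) + 10.0
                 + rng.normal(0, 10.0, y.size))
            b = (100.0 * np.exp(-((y - 100.0 - true) ** 2) / (2 * 2.0 ** 2))
                 + 10.0 + rng.normal(0, 10.0, y.size))
            lag, _ = refined_argmax(*pcf(a, b, 20))
            lags_hat.append(lag)
        assert abs(np.mean(lags_hat) - true) <= 0.2

    def test_pccf_sign_convention_negative_toward_cytoplasm(self):
        # test-channel peak at smaller y (cytoplasm side) -> negative lag
        p1 = _gauss_profile(80, 40.0)
        p2 = _gauss_profile(80, 36.0)
        lags, vals = pccf(p1, p2, 15)
        lag, _ = refined_argmax(lags, vals)
        assert lag == pytest.approx(-4.0, abs=0.1)

    def test_pccf_antisymmetry_under_channel_swap(self):
        p1 = _gauss_profile(90, 45.0)
        p2 = _gauss_profile(90, 41.7)
        l12, _ = refined_argmax(*pccf(p1, p2, 15))
        l21, _ = refined_argmax(*pccf(p2, p1, 15))
        assert l12 == pytest.approx(-l21, abs=0.2)


class TestAlignment:
    def test_undeformed_carpet_needs_no_shifts(self):
        carpet = _carpet_from_centers([40.0] * 12)
        shifts, aligned = align_carpet(carpet)
        np.testing.assert_allclose(shifts.shifts_nm, 0.0, atol=1e-9)
        np.testing.assert_allclose(aligned.columns, carpet.columns)

    def test_known_apex_displacements_recovered(self):
        d = np.array([0.0, 2.0, -3.0, 5.0, 1.0, -2.0, 4.0, 0.0])
        carpet = _carpet_from_centers(40.0 + d)
        shifts, aligned = align_carpet(carpet)
        np.testing.assert_allclose(shifts.shifts_nm / 25.0, d, atol=1.0)
        # after alignment the residual pCF argmax of every column is ~0
        ref = aligned.columns[:, 0]
        for c in range(1, aligned.n_columns):
            lag, _ = refined_argmax(*pcf(ref, aligned.columns[:, c], 10))
            assert abs(lag) <= 0.5

    def test_alignment_shrinks_peak_position_spread(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.0, 6.0, 40)
        carpet = _carpet_from_centers(40.0 + d)
        _, aligned = align_carpet(carpet)
        sd_before = np.std(carpet.columns.argmax(axis=0))
        sd_after = np.std(aligned.columns.argmax(axis=0))
        assert sd_after <= sd_before / 5.0

    def test_featureless_column_flagged_unalignable(self):
        carpet = _carpet_from_centers([40.0, 40.0, 40.0])
        carpet.columns[:, 2] = 5.0  # flat column: no correlation peak
        shifts, aligned = align_carpet(carpet)
        assert not shifts.valid[2] and shifts.valid[:2].all()
        np.testing.assert_array_equal(aligned.columns[:, 2],
                                      carpet.columns[:, 2])

    def test_reference_column_shift_is_zero(self):
        carpet = _carpet_from_centers([40.0, 44.0, 37.0])
        shifts, _ = align_carpet(carpet)
        assert shifts.shifts_nm[carpet.reference_index] == 0.0


class TestAverageProfile:
    def test_identical_replicates_have_zero_sem(self):
        c1 = _carpet_from_centers([40.0] * 5, replicate="a")
        c2 = _carpet_from_centers([40.0] * 5, replicate="b")
        avg = average_aligned_profile([c1, c2])
        np.testing.assert_allclose(avg.sem, 0.0, atol=1e-12)

    def test_two_replicate_closed_form(self):
        c1 = _carpet_from_centers([40.0] * 3, replicate="a", amp=100.0)
        c2 = _carpet_from_centers([40.0] * 3, replicate="b", amp=140.0)
        avg = average_aligned_profile([c1, c2])
        a = c1.columns[:, 0]
        b = c2.columns[:, 0]
        np.testing.assert_allclose(avg.mean, (a + b) / 2.0, atol=1e-9)
        np.testing.assert_allclose(avg.sem, np.abs(a - b) / 2.0, atol=1e-9)

    def test_single_replicate_flagged(self):
        avg = average_aligned_profile([_carpet_from_centers([40.0] * 4)])
        assert avg.sem is None and avg.n_replicates == 1

    def test_sem_scales_with_replicate_noise(self):
        rng = np.random.default_rng(4)
        sigma_rep = 8.0
        carpets = []
        for r in range(10):
            base = _carpet_from_centers([40.0] * 6, replicate=f"r{r}")
            base.columns += rng.normal(0.0, sigma_rep)  # per-replicate offset
            carpets.append(base)
        avg = average_aligned_profile(carpets)
        expect = sigma_rep / np.sqrt(10)
        assert np.mean(avg.sem) == pytest.approx(expect, rel=0.3)


class TestDistanceDistribution:
    def _pair(self, offset_bins, n_cols=20, replicate="cell0"):
        ref = _carpet_from_centers([40.0] * n_cols, replicate=replicate)
        test = _carpet_from_centers([40.0 + offset_bins] * n_cols,
                                    replicate=replicate)
        return ref, test

    def test_uniform_offset_recovered_with_zero_sem_and_one_mode(self):
        pairs = [self._pair(-26.0 / 25.0, replicate="a"),
                 self._pair(-26.0 / 25.0, replicate="b")]
        dist = distance_distribution(pairs)
        # the overlap-mean normalization of the pCCF skews the refined
        # argmax by up to ~0.1 bin for narrow peaks on a baseline
        assert dist.mean_nm == pytest.approx(-26.0, abs=3.0)
        assert dist.sem_nm == pytest.approx(0.0, abs=0.5)
        assert len(dist.modes) == 1
        assert dist.reliable

    def test_bimodal_mixture_yields_two_opposite_sign_modes(self):
        rng = np.random.default_rng(5)
        pairs = []
        for r in range(4):
            n = 16
            jitter = rng.normal(0.0, 0.1, n)
            sign = -1.0 if r % 2 == 0 else 1.0
            centers_test = 40.0 + sign * 26.0 / 25.0 + jitter
            ref = _carpet_from_centers([40.0] * n, replicate=f"c{r}")
            test = _carpet_from_centers(centers_test, replicate=f"c{r}")
            pairs.append((ref, test))
        dist = distance_distribution(pairs)
        locs = sorted(m[0] for m in dist.modes)
        assert len(locs) == 2
        assert locs[0] < 0 < locs[1]
        assert abs(dist.mean_nm) < 10.0

    def test_opposite_condition_distributions_differ(self):
        rng = np.random.default_rng(6)

        def condition(sign, tag):
            pairs = []
            for r in range(3):
                n = 14
                centers = 40.0 + sign * 26.0 / 25.0 + rng.normal(0, 0.15, n)
                ref = _carpet_from_centers([40.0] * n, replicate=f"{tag}{r}")
                test = _carpet_from_centers(centers, replicate=f"{tag}{r}")
                pairs.append((ref, test))
            return distance_distribution(pairs)

        wt = condition(-1.0, "wt")
        mut = condition(+1.0, "mut")
        _, p = stats.kruskal(wt.distances["distance_nm"],
                             mut.distances["distance_nm"])
        assert p < 1e-4

    def test_too_few_columns_rejected(self):
        with pytest.raises(InvalidParameterError):
            distance_distribution([self._pair(0.5, n_cols=5)])

    def test_single_replicate_flagged_unreliable(self):
        dist = distance_distribution([self._pair(1.0, n_cols=30)])
        assert not dist.reliable and dist.sem_nm is None


class TestPipelineRecovery:
    def test_membrane_pair_offset_recovered_end_to_end(self,
                                                       deformed_membrane_pair):
        ref, test = deformed_membrane_pair
        rect = (0.0, 0.0, 10_000.0, 5_000.0)
        rc = extract_carpet(ref, rect, 0.0, replicate_id="cell0")
        tc = extract_carpet(test, rect, 0.0, replicate_id="cell0")
        shifts, rc_a = align_carpet(rc)
        tc_a = apply_shifts(tc, shifts)
        d = column_distances(rc_a, tc_a)
        assert np.isfinite(d).sum() > 300
        assert np.nanmean(d) == pytest.approx(-26.0, abs=5.0)
        assert np.nanstd(d) <= 10.0

    def test_sparse_labeling_broadens_distances_across_both_signs(self):
        # at low labeling density and photon budget the per-column
        # distance distribution is broad and covers both signs even
        # though its mean stays negative
        model = synthgen.MembraneModel(
            window_nm=(10_000.0, 5_000.0), layer_offsets_nm=(0.0, -26.0),
            deformation_amplitude_nm=200.0,
            deformation_correlation_length_nm=1000.0,
            emitter_density_per_um=30.0, brightness=40.0)
        noise = synthgen.NoiseSpec(poisson=True, read_sigma=1.0,
                                   background=5.0)
        rect = (0.0, 0.0, 10_000.0, 5_000.0)
        pooled = []
        for seed in (21, 22):
            ref, test = synthgen.simulate_membrane_pair(
                model, psf_sigma_nm=40.0, pixel_size_nm=25.0, seed=seed,
                noise=noise)
            rc = extract_carpet(ref, rect, 0.0, replicate_id=f"c{seed}")
            tc = extract_carpet(test, rect, 0.0, replicate_id=f"c{seed}")
            shifts, rc_a = align_carpet(rc, max_lag_nm=500.0)
            tc_a = apply_shifts(tc, shifts)
            d = column_distances(rc_a, tc_a, max_lag_nm=500.0)
            pooled.append(d[np.isfinite(d)])
        d = np.concatenate(pooled)
        assert len(d) > 40  # low-confidence columns are rejected
        assert np.mean(d) < 0
        assert np.std(d) > 50.0  # broad
        assert (d > 0).sum() >= 5 and (d < 0).sum() >= 5
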