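"""Pharmacokinetic estimation: plasma vertex, Toeplitz deconvolution, maps."""
import numpy as np
import pytest
from scipy.optimize import nnls

import camdce
from camdce import (
    AIFParams,
    CompartmentBasis,
    PlasmaInput,
    StudyFit,
    SyntheticConfig,
    TransferMaps,
    fit_flux_rate,
    fit_local_transfer_maps,
    generate_synthetic_study,
    identify_plasma_vertex,
    longitudinal_compare,
    partial_volume_fraction,
    population_aif,
    preprocess,
    solve_compartment,
    toeplitz_input_matrix,
)

from conftest import pure_pixel_curves, truth_basis_processed


def _normalized(curve):
    curve = np.asarray(curve, float)
    return curve / curve.sum()


@pytest.fixture(scope="module")
def aif():
    times = np.arange(19) * 0.5
    return population_aif(times, AIFParams(onset=0.25, tau=0.1))


class TestIdentifyPlasmaVertex:
    def test_finds_aif_among_tissue_curves(self, aif):
        curves = np.column_stack(
            [
                _normalized(solve_compartment(aif, 0.25, 1.5)),
                _normalized(aif.concentration),
                _normalized(solve_compartment(aif, 0.12, 0.15)),
            ]
        )
        assert identify_plasma_vertex(curves) == 1

    def test_earlier_peak_wins(self):
        a = np.zeros(10)
        a[2] = 1.0
        b = np.zeros(10)
        b[7] = 1.0
        assert identify_plasma_vertex(np.column_stack([b, a])) == 1

    def test_tie_broken_by_steeper_upslope(self):
        shallow = np.array([0.2, 0.3, 0.4, 0.5, 0.6, 0.55, 0.5, 0.45])
        steep = np.array([0.0, 0.17, 0.34, 0.51, 0.68, 0.6, 0.5, 0.4])
        curves = np.column_stack([shallow, steep])
        assert np.argmax(shallow) == np.argmax(steep)
        assert identify_plasma_vertex(curves) == 1

    def test_flat_curves_are_ambiguous(self):
        with pytest.raises(ValueError, match="ambiguous"):
            identify_plasma_vertex(np.ones((6, 3)))


class TestToeplitzInputMatrix:
    def test_unit_impulse_gives_identity_action(self):
        conc = np.zeros(8)
        conc[0] = 1.0
        cp = PlasmaInput(times=np.arange(8, dtype=float), concentration=conc)
        mat = toeplitz_input_matrix(cp)
        h = np.exp(-0.3 * np.arange(8))
        np.testing.assert_allclose(mat @ h, h, atol=1e-15)

    def test_exactly_lower_triangular(self, aif):
        mat = toeplitz_input_matrix(aif)
        assert np.all(mat[np.triu_indices_from(mat, k=1)] == 0)

    def test_consistent_with_forward_convolution(self, aif):
        mat = toeplitz_input_matrix(aif)
        t_rel = aif.times - aif.times[0]
        for kep in (0.1, 0.6, 2.0):
            np.testing.assert_allclose(
                mat @ np.exp(-kep * t_rel),
                solve_compartment(aif, 1.0, kep),
                atol=1e-12,
            )

    def test_nonuniform_spacing_rejected(self):
        cp = PlasmaInput(times=[0.0, 0.5, 1.5], concentration=[1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="uniform"):
            toeplitz_input_matrix(cp)


class TestFitFluxRate:
    def test_noise_free_recovery(self, aif):
        curve = _normalized(solve_compartment(aif, 0.2, 0.6))
        cp = PlasmaInput(times=aif.times, concentration=_normalized(aif.concentration))
        fit = fit_flux_rate(curve, cp)
        assert fit.kep == pytest.approx(0.6, rel=1e-4)
        assert fit.reliable

    def test_zero_washout_limit_fits_running_integral(self, aif):
        cp = PlasmaInput(times=aif.times, concentration=_normalized(aif.concentration))
        data = _normalized(np.cumsum(cp.concentration))
        fit = fit_flux_rate(data, cp)
        assert fit.kep <= 0.02  # pinned near the lower search bound
        mat = toeplitz_input_matrix(cp)
        t_rel = cp.times - cp.times[0]
        fitted = fit.ktrans * (mat @ np.exp(-fit.kep * t_rel))
        scale = data.max()
        np.testing.assert_allclose(fitted / scale, data / scale, atol=0.02)

    def test_matches_two_stage_deconvolution_oracle(self):
        """Grid search equals NNLS deconvolution + log-linear decay fit."""
        times = np.arange(25) * 0.4
        cp = population_aif(times, AIFParams())  # cp(0) > 0: invertible system
        for ktrans, kep in [(0.3, 0.4), (0.15, 1.2), (0.5, 0.08)]:
            curve = solve_compartment(cp, ktrans, kep)
            fit = fit_flux_rate(curve, cp)
            mat = toeplitz_input_matrix(cp)
            h, _ = nnls(mat, curve)
            usable = h > 1e-8 * h.max()
            slope, intercept = np.polyfit(
                times[usable] - times[0], np.log(h[usable]), 1
            )
            assert fit.kep == pytest.approx(-slope, rel=0.02)
            assert fit.ktrans == pytest.approx(np.exp(intercept), rel=0.02)

    def test_vertex_proportional_to_input_flagged_unreliable(self, aif):
        cp = PlasmaInput(times=aif.times, concentration=_normalized(aif.concentration))
        with pytest.warns(RuntimeWarning, match="unreliable"):
            fit = fit_flux_rate(cp.concentration, cp)
        assert not fit.reliable

    def test_length_mismatch_rejected(self, aif):
        with pytest.raises(ValueError, match="length"):
            fit_flux_rate(np.ones(5), aif)


class TestFitLocalTransferMaps:
    def _toy_basis(self):
        t = np.arange(10) * 0.5
        cp = population_aif(t, AIFParams(onset=0.25, tau=0.1))
        curves = np.column_stack(
            [
                _normalized(solve_compartment(cp, 1.0, 1.2)),
                _normalized(solve_compartment(cp, 1.0, 0.2)),
                _normalized(cp.concentration),
            ]
        )
        return CompartmentBasis(curves=curves, plasma_index=2)

    def test_pure_pixel_gets_one_hot_weights(self):
        basis = self._toy_basis()
        series = camdce.DynamicSeries(
            times=np.arange(10) * 0.5,
            values=basis.curves[:, [1]],
            normalized=True,
        )
        maps = fit_local_transfer_maps(series, basis)
        np.testing.assert_allclose(maps.mixing[0], [0, 1, 0], atol=1e-9)
        assert maps.residual[0] <= 1e-12
        assert not maps.partial_volume_flag[0]

    def test_two_compartment_weights_match_grid_oracle(self):
        t = np.arange(8) * 0.5
        cp = population_aif(t, AIFParams(onset=0.25, tau=0.1))
        a = np.column_stack(
            [_normalized(solve_compartment(cp, 1.0, 0.8)), _normalized(cp.concentration)]
        )
        x = _normalized(a @ np.array([0.65, 0.35]) + 0.002 * np.arange(8))
        w, _ = nnls(a, x)
        # exhaustive grid over the weight plane at 1e-4 resolution
        scale = np.linspace(0, 2, 20001)
        best = min(
            (
                (np.linalg.norm(x - a @ np.array([w1, w2])), (w1, w2))
                for w1 in scale[::100]
                for w2 in scale[::100]
            ),
        )[1]
        fine1 = np.arange(max(best[0] - 0.01, 0), best[0] + 0.01, 1e-4)
        fine2 = np.arange(max(best[1] - 0.01, 0), best[1] + 0.01, 1e-4)
        resid = np.linalg.norm(
            x[:, None, None] - np.einsum("tj,j...->t...", a, np.stack(
                np.meshgrid(fine1, fine2, indexing="ij"))),
            axis=0,
        )
        i, j = np.unravel_index(np.argmin(resid), resid.shape)
        np.testing.assert_allclose(w, [fine1[i], fine2[j]], atol=2e-4)

    def test_noise_free_maps_match_truth_up_to_column_scale(
        self, processed_noisefree
    ):
        processed, report, truth = processed_noisefree
        basis = CompartmentBasis(
            curves=truth_basis_processed(truth), plasma_index=2
        )
        maps = fit_local_transfer_maps(processed, basis)
        for fitted, true_col in [
            (maps.ktrans_local[:, 0], truth.ktrans_local[report.retained_index, 0]),
            (maps.ktrans_local[:, 1], truth.ktrans_local[report.retained_index, 1]),
            (maps.vp_local, truth.vp_local[report.retained_index]),
        ]:
            r = np.corrcoef(fitted, true_col)[0, 1]
            assert r >= 1 - 1e-9

    def test_ill_conditioned_basis_rejected(self):
        t = np.arange(10) * 0.5
        cp = population_aif(t, AIFParams(onset=0.25, tau=0.1))
        c1 = _normalized(solve_compartment(cp, 1.0, 0.50))
        c2 = _normalized(solve_compartment(cp, 1.0, 0.50 + 1e-8))
        basis = CompartmentBasis(curves=np.column_stack([c1, c2]), plasma_index=0)
        series = camdce.DynamicSeries(
            times=t, values=np.column_stack([c1]), normalized=True
        )
        with pytest.raises(ValueError, match="ill-conditioned"):
            fit_local_transfer_maps(series, basis)

    def test_requires_normalized_series(self):
        basis = self._toy_basis()
        raw = camdce.DynamicSeries(
            times=np.arange(10) * 0.5, values=np.ones((10, 2))
        )
        with pytest.raises(ValueError, match="normalized"):
            fit_local_transfer_maps(raw, basis)


class TestPartialVolumeFraction:
    def _maps(self, mixing):
        mixing = np.asarray(mixing, float)
        return TransferMaps(
            ktrans_local=mixing[:, :-1],
            vp_local=mixing[:, -1],
            residual=np.zeros(len(mixing)),
            partial_volume_flag=np.zeros(len(mixing), bool),
            mixing=mixing,
        )

    def test_all_pure_gives_zero(self):
        maps = self._maps([[1.0, 0, 0], [0, 0, 1.0], [0, 1.0, 0]])
        assert partial_volume_fraction(maps) == 0.0

    def test_equal_mixtures_give_one(self):
        maps = self._maps([[0.5, 0.5, 0.0]] * 4)
        assert partial_volume_fraction(maps, 0.8) == 1.0

    def test_zero_weight_pixels_excluded_with_warning(self):
        maps = self._maps([[1.0, 0, 0], [0, 0, 0]])
        with pytest.warns(RuntimeWarning, match="zero-weight"):
            assert partial_volume_fraction(maps) == 0.0

    def test_noise_free_study_matches_designed_fraction(self, processed_noisefree):
        processed, report, truth = processed_noisefree
        basis = CompartmentBasis(
            curves=truth_basis_processed(truth), plasma_index=2
        )
        maps = fit_local_transfer_maps(processed, basis)
        measured = partial_volume_fraction(maps, truth.purity_threshold)
        assert measured == pytest.approx(truth.mixed_fraction, abs=0.05)


class TestLongitudinalCompare:
    def test_identical_studies_have_zero_deltas(self):
        fit = StudyFit(label="t0", ktrans=[0.3, 0.1], kep=[1.2, 0.2])
        out = longitudinal_compare([fit, StudyFit("t1", [0.3, 0.1], [1.2, 0.2])])
        np.testing.assert_allclose(out.kep_delta, 0.0)
        np.testing.assert_allclose(out.ktrans_delta, 0.0)

    def test_matching_is_invariant_to_compartment_order(self):
        a = StudyFit("t0", ktrans=[0.3, 0.1], kep=[1.2, 0.2])
        b = StudyFit("t1", ktrans=[0.12, 0.28], kep=[0.25, 1.0])  # permuted
        out = longitudinal_compare([a, b])
        np.testing.assert_allclose(out.kep[1], [1.0, 0.25])
        np.testing.assert_allclose(out.ktrans[1], [0.28, 0.12])

    def test_mismatched_j_pads_with_nan(self):
        a = StudyFit("t0", ktrans=[0.3, 0.1], kep=[1.2, 0.2])
        b = StudyFit("t1", ktrans=[0.25], kep=[1.0])
        out = longitudinal_compare([a, b])
        assert np.isnan(out.kep[1, 1])
        assert np.isfinite(out.kep_delta[0, 0])

    def test_single_study_rejected(self):
        with pytest.raises(ValueError):
            longitudinal_compare([StudyFit("t0", [0.3], [1.2])])

    def test_simulated_therapy_halves_fast_pool_kep(self):
        """Fast-pool kep drop of 50% is recovered within +-5 points at 40 dB."""
        from camdce import PKParameters

        fits = []
        for label, kep_fast in (("baseline", 1.5), ("interim", 0.75)):
            cfg = SyntheticConfig(
                pk=PKParameters(ktrans=(0.25, 0.12), kep=(kep_fast, 0.15), vp=0.05),
                snr_db=40.0,
                seed=17,
            )
            series, truth = generate_synthetic_study(cfg)
            processed, report = preprocess(series, mask=truth.mask)
            curves = pure_pixel_curves(processed, report, truth)
            cp = PlasmaInput(times=processed.times, concentration=curves[-1])
            pool_fits = [fit_flux_rate(curves[j], cp) for j in range(2)]
            fits.append(
                StudyFit(
                    label,
                    ktrans=[f.ktrans for f in pool_fits],
                    kep=[f.kep for f in pool_fits],
                )
            )
        out = longitudinal_compare(fits)
        assert out.kep_delta_pct[0, 0] == pytest.approx(-50.0, abs=5.0)

    def test_frame_conversion(self):
        a = StudyFit("t0", ktrans=[0.3, 0.1], kep=[1.2, 0.2], partial_volume=0.4)
        b = StudyFit("t1", ktrans=[0.2, 0.1], kep=[0.8, 0.2], partial_volume=0.5)
        frame = longitudinal_compare([a, b]).to_frame()
        assert len(frame) == 4
        assert {"timepoint", "pool", "kep_per_min"} <= set(frame.columns)
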