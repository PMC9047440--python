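import numpy as np
import pytest

from mrmprep.alignment import (
    RTShiftModel,
    build_prototype,
    estimate_shift_model,
    fit_quadratic_shift,
    propagate_borders,
    refine_shifts,
    select_reference,
    xcorr_shift,
)
from mrmprep.io import ProcessingParams
from mrmprep.models import fallback_score
from mrmprep.simulate import SimConfig, generate_batch

from conftest import gaussian_chrom

GRID_STEP = 0.005


def drifted_batch(drift_a=0.005, jitter=0.0, noise=0.0, n_samples=5,
                  n_metabolites=8, seed=11, **kw):
    cfg = SimConfig(
        n_samples=n_samples, n_metabolites=n_metabolites, drift_a=drift_a,
        jitter_sd=jitter, noise_sd=noise, p_missing=0.0, p_decoy=0.0,
        seed=seed, **kw,
    )
    return generate_batch(cfg)


class TestSelectReference:
    def test_highest_mean_wins(self):
        scores = {"s1": {"m": 0.5}, "s2": {"m": 0.9}, "s3": {"m": 0.7}}
        assert select_reference(scores) == "s2"

    def test_single_sample(self):
        assert select_reference({"only": {"m": 0.1}}) == "only"

    def test_tie_goes_to_first_in_batch_order(self):
        assert select_reference({"s1": {"m": 0.8}, "s2": {"m": 0.8}}) == "s1"

    def test_missing_metabolites_count_as_zero(self):
        scores = {"s1": {"a": 0.6, "b": 0.6}, "s2": {"a": 0.9}}
        assert select_reference(scores) == "s1"  # 0.6 vs (0.9+0)/2

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            select_reference({})


class TestXcorrShift:
    def test_identical_traces_have_zero_shift(self):
        c = gaussian_chrom(mu=5.0)
        assert xcorr_shift({"quantifier": c}, {"quantifier": c}, 5.0, 0.5) == 0.0

    def test_translated_gaussian_recovered_within_grid_step(self):
        ref = gaussian_chrom(mu=5.0)
        sample = gaussian_chrom(mu=5.10)
        shift = xcorr_shift({"quantifier": sample}, {"quantifier": ref}, 5.0, 0.5)
        assert shift == pytest.approx(0.10, abs=GRID_STEP + 1e-12)

    def test_shift_beyond_window_clamps_to_edge(self):
        ref = gaussian_chrom(mu=5.0, t0=3.5, t1=6.5)
        sample = gaussian_chrom(mu=5.8, t0=3.5, t1=6.5)
        shift = xcorr_shift({"quantifier": sample}, {"quantifier": ref}, 5.0, 0.5)
        assert shift == pytest.approx(0.5, abs=GRID_STEP + 1e-12)

    def test_flat_traces_default_to_zero(self):
        flat = gaussian_chrom(amplitude=0.0)
        shift = xcorr_shift({"quantifier": flat}, {"quantifier": flat}, 5.0, 0.5)
        assert shift == 0.0


class TestQuadraticFit:
    def test_three_point_fit_is_exact(self):
        rts = [1.0, 2.0, 3.0]
        shifts = [0.01 * rt**2 for rt in rts]
        a, b, c = fit_quadratic_shift(rts, shifts)
        assert a == pytest.approx(0.01, abs=1e-9)
        assert b == pytest.approx(0.0, abs=1e-9)
        assert c == pytest.approx(0.0, abs=1e-9)

    def test_zero_shifts_give_zero_model(self):
        a, b, c = fit_quadratic_shift([1, 2, 3, 4], [0, 0, 0, 0])
        assert (a, b, c) == (0.0, 0.0, 0.0)

    def test_noisy_quadratic_recovered_within_three_se(self):
        rng = np.random.default_rng(42)
        rts = np.linspace(1, 8, 20)
        shifts = 0.01 * rts**2 + rng.normal(0, 0.01, rts.size)
        a, _, _ = fit_quadratic_shift(rts, shifts)
        X = np.column_stack([rts**2, rts, np.ones_like(rts)])
        resid = shifts - X @ np.linalg.lstsq(X, shifts, rcond=None)[0]
        cov = np.linalg.inv(X.T @ X) * resid.var(ddof=3)
        se_a = np.sqrt(cov[0, 0])
        assert abs(a - 0.01) < 3 * se_a

    def test_fewer_than_three_points_degrade_to_median(self):
        assert fit_quadratic_shift([2.0], [0.3]) == (0.0, 0.0, 0.3)
        assert fit_quadratic_shift([2.0, 4.0], [0.1, 0.3]) == (0.0, 0.0, 0.2)

    def test_no_points_give_zero_model(self):
        assert fit_quadratic_shift([], []) == (0.0, 0.0, 0.0)
        assert fit_quadratic_shift([1.0], [np.nan]) == (0.0, 0.0, 0.0)


class TestTwoPassAlignment:
    def test_noise_free_drift_recovered_within_grid_step(self, params):
        samples, metabolites, truth = drifted_batch()
        reference = samples[0]  # drift-free by construction
        t = truth.set_index(["metabolite", "sample"])
        for sample in samples[1:]:
            first = estimate_shift_model(sample, reference, metabolites, params)
            refined = refine_shifts(sample, reference, metabolites, first, params)
            for m in metabolites:
                true_shift = t.at[(m.name, sample.sample_id), "true_shift"]
                assert refined.fitted_shifts[m.name] == pytest.approx(
                    true_shift, abs=GRID_STEP + 1e-9
                )

    def test_zero_drift_batch_gives_null_model(self, params):
        samples, metabolites, _ = drifted_batch(drift_a=1e-12)
        reference = samples[0]
        first = estimate_shift_model(samples[2], reference, metabolites, params)
        refined = refine_shifts(samples[2], reference, metabolites, first, params)
        for value in refined.fitted_shifts.values():
            assert abs(value) <= GRID_STEP

    def test_translation_moves_only_the_constant_term(self, params):
        # translating one sample's time axis by delta shifts c by delta
        samples, metabolites, _ = drifted_batch(n_samples=3)
        reference = samples[0]
        delta = 0.06
        sample = samples[1]
        base = refine_shifts(
            sample, reference, metabolites,
            estimate_shift_model(sample, reference, metabolites, params), params,
        )
        for per_met in sample.chromatograms.values():
            for chrom in per_met.values():
                chrom.times = chrom.times + delta
        moved = refine_shifts(
            sample, reference, metabolites,
            estimate_shift_model(sample, reference, metabolites, params), params,
        )
        assert moved.coeffs[2] - base.coeffs[2] == pytest.approx(delta, abs=0.01)
        assert moved.coeffs[0] == pytest.approx(base.coeffs[0], abs=1e-3)
        assert moved.coeffs[1] == pytest.approx(base.coeffs[1], abs=1e-2)


class TestPrototype:
    @staticmethod
    def _samples(mus, sigma=0.05):
        from mrmprep.io import SampleRecord
        from conftest import textbook_metabolite

        metab = textbook_metabolite(expected_rt=5.0)
        samples = []
        for i, mu in enumerate(mus):
            rec = SampleRecord(sample_id=f"s{i}")
            rec.chromatograms["Met"] = {
                "quantifier": gaussian_chrom(1.0, mu, sigma),
                "qualifier1": gaussian_chrom(0.5, mu, sigma, prod=40.0),
            }
            samples.append(rec)
        return samples, metab

    def test_identical_samples_sum_linearly(self, params):
        samples, metab = self._samples([5.0] * 4)
        models = {s.sample_id: RTShiftModel(s.sample_id) for s in samples}
        proto = build_prototype(samples, metab, models, params, fallback_score)
        assert proto.n_samples == 4
        assert proto.summed["quantifier"].intensities.max() == pytest.approx(
            4.0, rel=0.01
        )

    def test_alignment_restores_single_sample_width(self, params):
        # two samples shifted +-0.04 min; with correct shift models the
        # prototype peak is as narrow as one sample's, the unaligned sum wider
        from mrmprep.chromatogram import detect_borders

        samples, metab = self._samples([5.04, 4.96])
        good = {
            "s0": RTShiftModel("s0", raw_shifts={"Met": 0.04}),
            "s1": RTShiftModel("s1", raw_shifts={"Met": -0.04}),
        }
        null = {sid: RTShiftModel(sid) for sid in ("s0", "s1")}
        aligned = build_prototype(samples, metab, good, params, fallback_score)
        unaligned = build_prototype(samples, metab, null, params, fallback_score)
        single = samples[0].chromatograms["Met"]["quantifier"]
        s0, e0 = detect_borders(
            single, int(np.argmax(single.intensities)), params.border_frac,
            params.smoothing_width,
        )
        w_single = e0 - s0
        w_aligned = aligned.best_peak.end_time - aligned.best_peak.start_time
        w_unaligned = unaligned.best_peak.end_time - unaligned.best_peak.start_time
        assert w_aligned == pytest.approx(w_single, abs=2 * GRID_STEP)
        assert w_unaligned > w_aligned + 2 * GRID_STEP
        assert aligned.best_peak.height > unaligned.best_peak.height

    def test_all_zero_traces_have_no_best_peak(self, params):
        samples, metabolites, _ = drifted_batch(n_samples=3)
        metab = metabolites[0]
        for s in samples:
            chrom = s.chromatograms[metab.name]["quantifier"]
            chrom.intensities = np.zeros_like(chrom.intensities)
        models = {s.sample_id: RTShiftModel(s.sample_id) for s in samples}
        proto = build_prototype(samples, metab, models, params, fallback_score)
        assert proto.best_peak is None


class TestPropagateBorders:
    def _proto(self):
        from mrmprep.chromatogram import PeakCandidate
        from mrmprep.alignment import PrototypeChromatogram

        peak = PeakCandidate("m", "<prototype>", 0, 5.15, 5.0, 5.3, 10, 1)
        return PrototypeChromatogram("m", 5.15, np.array([5.0, 5.3]), {}, peak)

    def test_positive_shift_moves_borders_later(self):
        model = RTShiftModel("s", coeffs=(0.0, 0.0, 0.1))
        assert propagate_borders(self._proto(), model) == (
            pytest.approx(5.1), pytest.approx(5.4)
        )

    def test_zero_shift_keeps_borders(self):
        model = RTShiftModel("s")
        assert propagate_borders(self._proto(), model) == (5.0, 5.3)

    def test_borders_clipped_to_trace_extent(self):
        model = RTShiftModel("s", coeffs=(0.0, 0.0, 0.5))
        trace = gaussian_chrom(t0=4.0, t1=5.5)
        start, end = propagate_borders(self._proto(), model, trace)
        assert end == pytest.approx(5.5, abs=1e-9)
        assert start == pytest.approx(5.5, abs=0.11)

    def test_refined_per_metabolite_shift_takes_precedence(self):
        model = RTShiftModel("s", coeffs=(0.0, 0.0, 0.1),
                             raw_shifts={"m": 0.25})
        start, end = propagate_borders(self._proto(), model)
        assert start == pytest.approx(5.25)
        assert end == pytest.approx(5.55)

    def test_missing_prototype_peak_rejected(self):
        proto = self._proto()
        proto.best_peak = None
        with pytest.raises(ValueError):
            propagate_borders(proto, RTShiftModel("s"))
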