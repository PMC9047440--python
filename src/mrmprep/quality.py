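"""Chromatographic quality scores.

Every peak candidate is described by a 20-element quality-score (QS)
vector; each score lies in [0, 1] with 1 ideal.  The scores fall into three
families:

* **relative height** — how much the peak stands out over its surroundings
  (apex vs. highest point outside the peak, apex vs. borders, apex vs.
  noise floor),
* **quantifier/qualifier agreement** — trace correlation, observed vs.
  expected intensity ratio, qualifier presence,
* **shape and retention time** — Gaussian resemblance, symmetry, width
  plausibility, fraction of non-zero points, deviation from the expected RT
  with and without the predicted per-sample shift.

Raw ratios ``r >= 0`` are squashed onto [0, 1] with ``s = max(0, 1 - 1/r)``
so that all scores are commensurable (required because the no-model
fallback classifier simply averages them).  Correlation-type scores are
``max(0, Pearson r)``.  Scores that need a qualifier trace are 0 when no
qualifier exists.

For the peak-reporting stage the 20 QS are extended with the peak-picking
classifier score of the sample (``output_H``) and the 0/25/50/75/100th
percentiles of that score across all samples of the batch (``RF0`` ...
``RF100``), 26 features in total.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .chromatogram import PeakCandidate, gaussian
from .io import Chromatogram, MetaboliteDef, ProcessingParams

__all__ = [
    "QS_NAMES",
    "REPORTING_FEATURE_NAMES",
    "squash",
    "compute_qs",
    "assemble_reporting_features",
]

#: Fixed order of the 20 quality scores.
QS_NAMES = (
    "QS_T.o",      # quantifier apex / highest point outside the peak
    "QS_To2",      # same as QS_T.o for the qualifier trace(s)
    "QS_T.h",      # qualifier apex / higher peak border
    "QS_T.l",      # qualifier apex / lower peak border
    "QS_dRT",      # deviation from expected RT
    "QS_dRTs",     # deviation from expected RT incl. predicted shift
    "QS_cor123",   # mean pairwise correlation among quant + qualifier traces
    "QS_gauss",    # correlation of the quantifier peak with a Gaussian
    "QS_ratio",    # observed vs expected quantifier/qualifier ratio
    "QS_width",    # peak width plausibility
    "QS_noise",    # quantifier apex vs noise floor outside the peak
    "QS_sym",      # quantifier peak symmetry (left/right area balance)
    "QS_zero",     # fraction of non-zero points inside the quantifier peak
    "QS_qual",     # qualifier presence flag
    "QS_T.hQ",     # quantifier apex / higher peak border
    "QS_T.lQ",     # quantifier apex / lower peak border
    "QS_gauss2",   # Gaussian correlation of the qualifier peak
    "QS_sym2",     # qualifier peak symmetry
    "QS_zero2",    # fraction of non-zero points inside the qualifier peak
    "QS_noise2",   # qualifier apex vs noise floor outside the peak
)

#: Feature order for the peak-reporting classifier.
REPORTING_FEATURE_NAMES = QS_NAMES + ("output_H", "RF0", "RF25", "RF50", "RF75", "RF100")

# Plausible chromatographic peak width range (minutes) for QS_width.
WIDTH_RANGE = (0.02, 0.6)

# Noise scores reach 1 only for apex >> noise; r = height / (NOISE_K * floor).
NOISE_K = 3.0


def squash(ratio: float) -> float:
    """Map a raw ratio r >= 0 onto [0, 1): 1 - 1/r, clipped below at 0."""
    if not np.isfinite(ratio):
        return 1.0 if ratio > 0 else 0.0
    if ratio <= 0:
        return 0.0
    return max(0.0, 1.0 - 1.0 / ratio)


def _sym_ratio(a: float, b: float) -> float:
    """min/max ratio of two non-negative magnitudes, in [0, 1]."""
    if a <= 0 or b <= 0:
        return 0.0
    return min(a, b) / max(a, b)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """max(0, Pearson r); 0 for degenerate (short or zero-variance) input."""
    if len(x) < 3 or len(y) != len(x):
        return 0.0
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(max(0.0, r)) if np.isfinite(r) else 0.0


def _window_mask(times: np.ndarray, start: float, end: float) -> np.ndarray:
    return (times >= start) & (times <= end)


def _gauss_corr(times: np.ndarray, values: np.ndarray) -> float:
    """Correlation of a peak window with its least-squares Gaussian fit."""
    if len(times) < 4 or np.ptp(values) == 0:
        return 0.0
    baseline = float(values.min())
    y = values - baseline
    total = y.sum()
    if total <= 0:
        return 0.0
    scale = float(y.max())
    yn = y / scale  # normalized so the fit path is intensity-scale invariant
    mu0 = float((times * yn).sum() / (total / scale))
    var0 = float((yn * (times - mu0) ** 2).sum() / (total / scale))
    sigma0 = max(np.sqrt(max(var0, 0.0)), (times[1] - times[0]) / 2)
    p0 = (1.0, mu0, sigma0)

    def jac(t, amp, mu, sigma):
        z = (t - mu) / sigma
        e = np.exp(-0.5 * z * z)
        return np.column_stack((e, amp * e * z / sigma, amp * e * z * z / sigma))

    try:
        popt, _ = curve_fit(
            gaussian, times, yn, p0=p0, jac=jac, method="lm", maxfev=100
        )
        fit = gaussian(times, *popt)
    except Exception:
        fit = gaussian(times, *p0)
    return _pearson(yn, fit)


def _snr_score(height: float, outside: np.ndarray) -> float:
    """Squashed apex-height vs noise-floor ratio.

    The noise floor is the robust SD of successive differences of the
    trace outside the peak (insensitive to slow baseline trends); a zero
    floor with positive height scores 1.
    """
    if height <= 0:
        return 0.0
    if outside.size < 4:
        return 1.0
    diffs = np.diff(outside)
    mad = np.median(np.abs(diffs - np.median(diffs)))
    floor = 1.4826 * mad / np.sqrt(2.0)
    if floor <= 0:
        return 1.0
    return squash(height / (NOISE_K * floor))


def _shape_scores(
    times: np.ndarray, values: np.ndarray, start: float, end: float, apex_time: float
) -> tuple[float, float, float, float, float, float, float]:
    """Per-trace scores: T.o, T.h, T.l, gauss, sym, zero, noise."""
    mask = _window_mask(times, start, end)
    tw, yw = times[mask], values[mask]
    if tw.size == 0:
        return (0.0,) * 7
    apex_int = float(yw.max())
    outside = values[~mask]
    highest_out = float(outside.max()) if outside.size else 0.0
    t_o = squash(apex_int / highest_out) if highest_out > 0 else (
        1.0 if apex_int > 0 else 0.0
    )
    b_lo = float(np.interp(start, times, values))
    b_hi = float(np.interp(end, times, values))
    hi_border, lo_border = max(b_lo, b_hi), min(b_lo, b_hi)
    t_h = squash(apex_int / hi_border) if hi_border > 0 else (
        1.0 if apex_int > 0 else 0.0
    )
    t_l = squash(apex_int / lo_border) if lo_border > 0 else (
        1.0 if apex_int > 0 else 0.0
    )
    g = _gauss_corr(tw, yw)
    baseline = np.interp(tw, [start, end], [b_lo, b_hi])
    excess = np.clip(yw - baseline, 0.0, None)
    left = float(np.trapezoid(excess[tw <= apex_time], tw[tw <= apex_time])) if (
        (tw <= apex_time).sum() >= 2
    ) else 0.0
    right = float(np.trapezoid(excess[tw >= apex_time], tw[tw >= apex_time])) if (
        (tw >= apex_time).sum() >= 2
    ) else 0.0
    sym = _sym_ratio(left, right)
    zero = float((yw > 0).mean())
    noise = _snr_score(apex_int - float(np.interp(apex_time, [start, end], [b_lo, b_hi])), outside)
    return t_o, t_h, t_l, g, sym, zero, noise


def compute_qs(
    candidate: PeakCandidate,
    traces: Mapping[str, Chromatogram],
    metab: MetaboliteDef,
    predicted_shift: float,
    params: ProcessingParams,
) -> np.ndarray:
    """Compute the 20-element quality-score vector for one candidate.

    ``traces`` maps roles (``quantifier``, ``qualifier1``, ``qualifier2``)
    to chromatograms; qualifier-dependent scores are 0 when no qualifier
    trace is available.  ``predicted_shift`` is the fitted per-sample RT
    shift at this metabolite (0 during the initial pass).
    """
    quant = traces["quantifier"]
    quals = [traces[r] for r in ("qualifier1", "qualifier2") if r in traces]
    start, end, apex_t = candidate.start_time, candidate.end_time, candidate.apex_time

    qt_o, qt_h, qt_l, qgauss, qsym, qzero, qnoise = _shape_scores(
        quant.times, quant.intensities, start, end, apex_t
    )

    qual_shape = [
        _shape_scores(q.times, q.intensities, start, end, apex_t) for q in quals
    ]
    if qual_shape:
        to2 = float(np.mean([s[0] for s in qual_shape]))
        t_h = float(np.mean([s[1] for s in qual_shape]))
        t_l = float(np.mean([s[2] for s in qual_shape]))
        gauss2 = float(np.mean([s[3] for s in qual_shape]))
        sym2 = float(np.mean([s[4] for s in qual_shape]))
        zero2 = float(np.mean([s[5] for s in qual_shape]))
        noise2 = float(np.mean([s[6] for s in qual_shape]))
        qual_flag = 1.0
    else:
        to2 = t_h = t_l = gauss2 = sym2 = zero2 = noise2 = qual_flag = 0.0

    drt = max(0.0, 1.0 - abs(apex_t - metab.expected_rt) / params.drt_window)
    drts = max(
        0.0,
        1.0 - abs(apex_t - (metab.expected_rt + predicted_shift)) / params.drt_window,
    )

    # mean pairwise correlation among quantifier and qualifier traces,
    # all evaluated on the quantifier's in-window time points
    mask = _window_mask(quant.times, start, end)
    tw = quant.times[mask]
    series = [quant.intensities[mask]]
    for q in quals:
        series.append(np.interp(tw, q.times, q.intensities, left=0.0, right=0.0))
    if len(series) > 1 and tw.size >= 3:
        pairs = [
            _pearson(series[i], series[j])
            for i in range(len(series))
            for j in range(i + 1, len(series))
        ]
        cor123 = float(np.mean(pairs))
    else:
        cor123 = 0.0

    # observed vs expected quantifier/qualifier apex ratio; the unlabeled
    # qualifier is the reference for the expected ratio when one exists
    if quals:
        roles = [r for r in ("qualifier1", "qualifier2") if r in traces]
        unlabeled = [
            r for r in roles
            if metab.istd_role is None or r != metab.istd_role
        ]
        ref_role = unlabeled[0] if unlabeled else roles[0]
        q = traces[ref_role]
        qmask = _window_mask(q.times, start, end)
        qual_apex = float(q.intensities[qmask].max()) if qmask.any() else 0.0
        quant_apex = float(quant.intensities[mask].max()) if mask.any() else 0.0
        if metab.expected_ratio is None:
            ratio_score = 0.5  # qualifier present but no expectation: neutral
        elif qual_apex > 0 and quant_apex > 0:
            r_obs = quant_apex / qual_apex
            ratio_score = _sym_ratio(r_obs, metab.expected_ratio)
        else:
            ratio_score = 0.0
    else:
        ratio_score = 0.0

    width = end - start
    lo, hi = WIDTH_RANGE
    if width < lo:
        width_score = max(0.0, width / lo)
    elif width > hi:
        width_score = hi / width
    else:
        width_score = 1.0

    values = {
        "QS_T.o": qt_o,
        "QS_To2": to2,
        "QS_T.h": t_h,
        "QS_T.l": t_l,
        "QS_dRT": drt,
        "QS_dRTs": drts,
        "QS_cor123": cor123,
        "QS_gauss": qgauss,
        "QS_ratio": ratio_score,
        "QS_width": width_score,
        "QS_noise": qnoise,
        "QS_sym": qsym,
        "QS_zero": qzero,
        "QS_qual": qual_flag,
        "QS_T.hQ": qt_h,
        "QS_T.lQ": qt_l,
        "QS_gauss2": gauss2,
        "QS_sym2": sym2,
        "QS_zero2": zero2,
        "QS_noise2": noise2,
    }
    out = np.array([values[name] for name in QS_NAMES], dtype=float)
    assert out.shape == (20,)
    if not np.all(np.isfinite(out)):
        out = np.nan_to_num(out, nan=0.0, posinf=1.0, neginf=0.0)
    return np.clip(out, 0.0, 1.0)


def assemble_reporting_features(
    qs: np.ndarray, output_h: float, all_scores: Sequence[float]
) -> np.ndarray:
    """Concatenate QS(20), output_H and batch percentiles RF0..RF100.

    ``all_scores`` holds the picking-classifier scores of this metabolite
    across all samples in the batch (including this sample); percentiles
    use linear interpolation between order statistics.
    """
    qs = np.asarray(qs, dtype=float)
    if qs.shape != (len(QS_NAMES),):
        raise ValueError(f"expected {len(QS_NAMES)} quality scores")
    scores = np.asarray(list(all_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("all_scores must be non-empty")
    rf = np.percentile(scores, [0, 25, 50, 75, 100])
    return np.concatenate([qs, [float(output_h)], rf])
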