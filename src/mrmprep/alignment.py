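"""Retention-time alignment and prototype (consensus) chromatograms.

HILIC retention times drift between runs, typically as a function of the
squared RT, while individual metabolites can deviate from that trend by up
to half a minute.  Alignment therefore proceeds in two passes: per-metabolite
shifts against a reference sample are measured by simultaneous normalized
cross-correlation of quantifier and qualifier traces, regularized by an
ordinary-least-squares quadratic fit of shift vs. RT, then re-measured in a
narrow window around the fitted value and refit.

Sign convention: ``shift = sample RT - reference RT`` (positive when the
sample elutes later); aligning a sample means subtracting its shift.

The aligned chromatograms of one metabolite are summed across samples into
a prototype chromatogram on which peak picking is most robust; the borders
of the best prototype peak are propagated back into each sample's own time
coordinates for integration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .chromatogram import PeakCandidate, find_candidates, resample
from .io import Chromatogram, MetaboliteDef, ProcessingParams, SampleRecord
from .quality import compute_qs

logger = logging.getLogger("mrmprep")

__all__ = [
    "RTShiftModel",
    "PrototypeChromatogram",
    "select_reference",
    "xcorr_shift",
    "fit_quadratic_shift",
    "estimate_shift_model",
    "refine_shifts",
    "build_prototype",
    "propagate_borders",
]


@dataclass
class RTShiftModel:
    """Per-sample quadratic drift model ``shift(rt) = a rt^2 + b rt + c``."""

    sample_id: str
    coeffs: tuple[float, float, float] = (0.0, 0.0, 0.0)
    raw_shifts: dict[str, float] = field(default_factory=dict)
    fitted_shifts: dict[str, float] = field(default_factory=dict)

    def shift_at(self, rt: float) -> float:
        a, b, c = self.coeffs
        return a * rt * rt + b * rt + c

    def shift_for(self, metabolite: str, rt: float) -> float:
        """Refined per-metabolite shift; quadratic prediction as fallback.

        The narrow second measurement pass recovers the individual
        deviation of a metabolite from the batch drift trend; when it is
        unavailable (flat trace) the fitted curve stands in.
        """
        raw = self.raw_shifts.get(metabolite, np.nan)
        return float(raw) if np.isfinite(raw) else self.shift_at(rt)


@dataclass
class PrototypeChromatogram:
    """Summed, RT-aligned chromatograms of one metabolite across samples."""

    metabolite: str
    expected_rt: float
    grid: np.ndarray
    summed: dict[str, Chromatogram]
    best_peak: PeakCandidate | None = None
    n_samples: int = 0


def select_reference(
    initial_scores: Mapping[str, Mapping[str, float]],
) -> str:
    """Sample with the highest mean peak-classification score over metabolites.

    Missing metabolites count as 0; the metabolite universe is the union
    over all samples.  Ties resolve to the first sample in batch order.
    """
    if not initial_scores:
        raise ValueError("empty batch: no samples to select a reference from")
    universe: set[str] = set()
    for per_met in initial_scores.values():
        universe.update(per_met)
    n = max(len(universe), 1)
    best_id, best_mean = None, -np.inf
    for sample_id, per_met in initial_scores.items():
        mean = sum(per_met.get(m, 0.0) or 0.0 for m in universe) / n
        if mean > best_mean:
            best_id, best_mean = sample_id, mean
    return best_id


def xcorr_shift(
    traces: Mapping[str, Chromatogram],
    ref_traces: Mapping[str, Chromatogram],
    center: float,
    halfwidth: float,
    pad: float = 0.25,
    lag_center: float = 0.0,
) -> float:
    """RT shift of a sample vs. the reference around ``center`` (minutes).

    Maximizes, over lags in ``lag_center +- halfwidth``, the sum over
    available roles of the Pearson correlation between the sample trace and
    the lag-shifted reference trace, both resampled to a uniform grid of
    the reference quantifier's median sampling interval over
    ``center +- (halfwidth + pad)``.  Ties prefer the lag closest to
    ``lag_center``.  A positive result means the sample elutes later than
    the reference.  The refined alignment pass passes the fitted drift as
    ``lag_center`` to restrict the search to its neighbourhood.
    """
    roles = [r for r in traces if r in ref_traces]
    if "quantifier" not in roles:
        raise ValueError("both samples must provide the quantifier trace")
    ref_q = ref_traces["quantifier"]
    step = float(np.median(np.diff(ref_q.times)))
    grid = np.arange(center - halfwidth - pad, center + halfwidth + pad + step, step)
    nlags = int(round(halfwidth / step))
    lags = lag_center + np.arange(-nlags, nlags + 1) * step

    sample_vals = {r: resample(traces[r], grid) for r in roles}
    best_lag, best_score = lag_center, -np.inf
    any_signal = False
    for lag in lags[np.argsort(np.abs(lags - lag_center), kind="stable")]:
        total = 0.0
        for r in roles:
            ref_vals = resample(ref_traces[r], grid - lag)
            s, v = sample_vals[r], ref_vals
            if np.ptp(s) == 0 or np.ptp(v) == 0:
                continue
            any_signal = True
            c = np.corrcoef(s, v)[0, 1]
            if np.isfinite(c):
                total += c
        if total > best_score:
            best_score, best_lag = total, float(lag)
    if not any_signal:
        logger.warning("flat traces around %.2f min: shift set to 0", center)
        return lag_center
    return float(best_lag)


def fit_quadratic_shift(
    expected_rts: Sequence[float],
    shifts: Sequence[float],
    robust: bool = False,
) -> tuple[float, float, float]:
    """Ordinary least squares of shift on (rt^2, rt, 1).

    Non-finite pairs are dropped.  With exactly 3 points the fit is exact;
    with 1-2 points the model degrades to a constant (median shift); with
    none it is the zero model.  ``robust=True`` adds one reweighting pass
    that drops residuals beyond 3x the MAD.
    """
    rts = np.asarray(expected_rts, dtype=float)
    sh = np.asarray(shifts, dtype=float)
    ok = np.isfinite(rts) & np.isfinite(sh)
    rts, sh = rts[ok], sh[ok]
    if rts.size == 0:
        logger.warning("no usable shifts: using zero drift model")
        return (0.0, 0.0, 0.0)
    if rts.size < 3:
        return (0.0, 0.0, float(np.median(sh)))
    coeffs = np.polyfit(rts, sh, 2)
    if robust:
        resid = sh - np.polyval(coeffs, rts)
        mad = np.median(np.abs(resid - np.median(resid)))
        if mad > 0:
            keep = np.abs(resid - np.median(resid)) <= 3 * 1.4826 * mad
            if keep.sum() >= 3:
                coeffs = np.polyfit(rts[keep], sh[keep], 2)
    a, b, c = (float(v) for v in coeffs)
    return (a, b, c)


def estimate_shift_model(
    sample: SampleRecord,
    reference: SampleRecord,
    metabolites: Sequence[MetaboliteDef],
    params: ProcessingParams,
) -> RTShiftModel:
    """First-pass shift model: wide-window cross-correlation + quadratic fit."""
    return _shift_pass(
        sample, reference, metabolites, params,
        centers={m.name: m.expected_rt for m in metabolites},
        halfwidth=params.initial_shift_window,
    )


def refine_shifts(
    sample: SampleRecord,
    reference: SampleRecord,
    metabolites: Sequence[MetaboliteDef],
    model: RTShiftModel,
    params: ProcessingParams,
) -> RTShiftModel:
    """Second pass: re-measure in a narrow window around the fitted shift."""
    centers = {
        m.name: m.expected_rt + model.shift_at(m.expected_rt) for m in metabolites
    }
    return _shift_pass(
        sample, reference, metabolites, params,
        centers=centers, halfwidth=params.refined_shift_window,
    )


def _shift_pass(
    sample: SampleRecord,
    reference: SampleRecord,
    metabolites: Sequence[MetaboliteDef],
    params: ProcessingParams,
    centers: Mapping[str, float],
    halfwidth: float,
) -> RTShiftModel:
    raw: dict[str, float] = {}
    for metab in metabolites:
        traces = sample.chromatograms.get(metab.name, {})
        ref_traces = reference.chromatograms.get(metab.name, {})
        if "quantifier" not in traces or "quantifier" not in ref_traces:
            raw[metab.name] = np.nan
            continue
        # the lag search is centred on the current shift estimate; the
        # returned lag is always the absolute sample-minus-reference shift
        lag_center = centers[metab.name] - metab.expected_rt
        raw[metab.name] = xcorr_shift(
            traces, ref_traces, centers[metab.name], halfwidth,
            lag_center=lag_center,
        )
    coeffs = fit_quadratic_shift(
        [m.expected_rt for m in metabolites],
        [raw[m.name] for m in metabolites],
        robust=params.robust_fit,
    )
    model = RTShiftModel(sample_id=sample.sample_id, coeffs=coeffs, raw_shifts=raw)
    model.fitted_shifts = {
        m.name: model.shift_at(m.expected_rt) for m in metabolites
    }
    return model


def build_prototype(
    samples: Sequence[SampleRecord],
    metab: MetaboliteDef,
    models: Mapping[str, RTShiftModel],
    params: ProcessingParams,
    scorer: Callable[[np.ndarray], float],
    pad: float = 0.3,
) -> PrototypeChromatogram:
    """Sum the RT-aligned chromatograms of one metabolite across samples.

    Each sample's traces are shifted by -fitted_shift (evaluated at the
    metabolite's expected RT), resampled to a uniform grid derived from the
    first contributing sample, and summed per role.  Peak picking plus
    quality scoring (via ``scorer``) then selects the best prototype peak;
    ``best_peak`` is None when the summed trace is flat (metabolite absent
    batch-wide).
    """
    contributing = [
        s for s in samples if "quantifier" in s.chromatograms.get(metab.name, {})
    ]
    if not contributing:
        raise ValueError(f"{metab.name}: no sample has the quantifier trace")
    base = contributing[0].chromatograms[metab.name]["quantifier"]
    step = float(np.median(np.diff(base.times)))
    halfspan = params.initial_shift_window + pad
    grid = np.arange(
        metab.expected_rt - halfspan, metab.expected_rt + halfspan + step, step
    )

    summed: dict[str, np.ndarray] = {}
    for sample in contributing:
        shift = models[sample.sample_id].shift_for(metab.name, metab.expected_rt)
        for role, trace in sample.chromatograms[metab.name].items():
            vals = resample(trace, grid + shift)  # undo the sample's shift
            summed[role] = summed.get(role, 0.0) + vals

    chroms = {
        role: Chromatogram(
            contributing[0].chromatograms[metab.name].get(
                role, base
            ).transition,
            grid,
            np.clip(vals, 0.0, None),
        )
        for role, vals in summed.items()
    }
    proto = PrototypeChromatogram(
        metabolite=metab.name,
        expected_rt=metab.expected_rt,
        grid=grid,
        summed=chroms,
        n_samples=len(contributing),
    )
    candidates = find_candidates(
        chroms["quantifier"], params,
        window_center=metab.expected_rt,
        window_halfwidth=params.initial_shift_window,
        metabolite=metab.name, sample_id="<prototype>",
    )
    for cand in candidates:
        cand.qs = compute_qs(cand, chroms, metab, 0.0, params)
        cand.score = float(scorer(cand.qs))
    if candidates:
        proto.best_peak = max(candidates, key=lambda c: c.score)
    return proto


def plot_shifts(
    models: Mapping[str, RTShiftModel],
    metabolites: Sequence[MetaboliteDef],
    path,
) -> None:
    """Diagnostic plot: per-metabolite raw shifts and fitted drift curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    rts = np.array([m.expected_rt for m in metabolites])
    order = np.argsort(rts)
    grid = np.linspace(rts.min(), rts.max(), 100)
    for model in models.values():
        raw = np.array([model.raw_shifts.get(m.name, np.nan) for m in metabolites])
        (line,) = ax.plot(
            grid, [model.shift_at(rt) for rt in grid], lw=1, alpha=0.8,
            label=model.sample_id,
        )
        ax.plot(rts[order], raw[order], "o", ms=3, color=line.get_color())
    ax.set_xlabel("expected RT (min)")
    ax.set_ylabel("shift vs reference (min)")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def propagate_borders(
    prototype: PrototypeChromatogram,
    model: RTShiftModel,
    trace: Chromatogram | None = None,
) -> tuple[float, float]:
    """Map prototype peak borders into one sample's own time coordinates.

    The sample's refined shift for this metabolite (quadratic prediction
    when unavailable) is added to the prototype borders; when ``trace`` is
    given the borders are clipped to its extent.
    """
    if prototype.best_peak is None:
        raise ValueError(f"{prototype.metabolite}: prototype has no best peak")
    shift = model.shift_for(prototype.metabolite, prototype.expected_rt)
    start = prototype.best_peak.start_time + shift
    end = prototype.best_peak.end_time + shift
    if trace is not None:
        t0, t1 = float(trace.times[0]), float(trace.times[-1])
        if start < t0 or end > t1:
            logger.warning(
                "%s/%s: propagated borders clipped to trace extent",
                prototype.metabolite, model.sample_id,
            )
        start, end = max(start, t0), min(end, t1)
    return float(start), float(end)
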