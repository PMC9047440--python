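"""End-to-end batch preprocessing and model training.

``process_batch`` runs the full chain on one batch: initial candidate
picking and scoring per metabolite per sample, reference-sample selection,
two-pass retention-time alignment with a quadratic drift model, prototype
summation and best-peak selection, border propagation and per-sample
integration, reporting-feature assembly, the quality gate, and table
output.  Per-metabolite failures are quarantined (logged, cells left
empty) so that one bad trace cannot abort an unattended batch.

``train_models`` runs the two-stage training workflow: a no-model pass
produces candidate quality scores for the peak-picking model, then a second
pass with the fresh picking model produces the reporting features for the
peak-reporting model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import io as mio
from .alignment import (
    PrototypeChromatogram,
    RTShiftModel,
    build_prototype,
    estimate_shift_model,
    propagate_borders,
    refine_shifts,
    select_reference,
)
from .chromatogram import PeakCandidate, find_candidates, integrate, smooth
from .io import MetaboliteDef, ProcessingParams, SampleRecord
from .models import (
    TrainedClassifier,
    derive_picking_labels,
    derive_reporting_labels,
    fallback_score,
    predict_score,
    save_model,
    train_classifier,
)
from .quality import QS_NAMES, assemble_reporting_features, compute_qs

logger = logging.getLogger("mrmprep")

__all__ = [
    "BatchResult",
    "process_batch",
    "train_models",
    "normalize_to_istd",
    "peakcheck_template",
]


@dataclass
class BatchResult:
    """All per-(metabolite, sample) outputs of one batch run.

    The matrices are DataFrames indexed by metabolite (DB order) with one
    column per sample (file order).
    """

    metabolites: list[str]
    sample_ids: list[str]
    area: pd.DataFrame
    height: pd.DataFrame
    normalized_area: pd.DataFrame
    normalized_height: pd.DataFrame
    apex_time: pd.DataFrame
    start_time: pd.DataFrame
    end_time: pd.DataFrame
    output_h: pd.DataFrame
    report_score: pd.DataFrame
    reported: pd.DataFrame
    reference_sample: str = ""
    shift_models: dict[str, RTShiftModel] = field(default_factory=dict)
    prototypes: dict[str, PrototypeChromatogram] = field(default_factory=dict)
    reporting_features: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    candidates: list[PeakCandidate] = field(default_factory=list)
    log: list[str] = field(default_factory=list)


def normalize_to_istd(area: float, istd_area: float | None) -> float | None:
    """Analyte area divided by the 13C internal-standard area (or None)."""
    if istd_area is None or not np.isfinite(istd_area) or istd_area <= 0:
        logger.warning("non-positive ISTD area: normalized value left empty")
        return None
    return area / istd_area


def _empty_frame(metabolites: list[str], sample_ids: list[str], fill=np.nan):
    return pd.DataFrame(fill, index=metabolites, columns=sample_ids)


def process_batch(
    samples: Sequence[SampleRecord],
    metabolites: Sequence[MetaboliteDef],
    params: ProcessingParams,
    picking_model: TrainedClassifier | None = None,
    reporting_model: TrainedClassifier | None = None,
    collect_candidates: bool = False,
) -> BatchResult:
    """Run the full preprocessing chain on one batch (see module docstring)."""
    if not samples:
        raise ValueError("no samples in batch")
    if not metabolites:
        raise ValueError("no metabolites defined")

    met_names = [m.name for m in metabolites]
    sample_ids = [s.sample_id for s in samples]
    by_id = {s.sample_id: s for s in samples}

    result = BatchResult(
        metabolites=met_names,
        sample_ids=sample_ids,
        area=_empty_frame(met_names, sample_ids),
        height=_empty_frame(met_names, sample_ids),
        normalized_area=_empty_frame(met_names, sample_ids),
        normalized_height=_empty_frame(met_names, sample_ids),
        apex_time=_empty_frame(met_names, sample_ids),
        start_time=_empty_frame(met_names, sample_ids),
        end_time=_empty_frame(met_names, sample_ids),
        output_h=_empty_frame(met_names, sample_ids),
        report_score=_empty_frame(met_names, sample_ids),
        reported=_empty_frame(met_names, sample_ids, fill=False).astype(bool),
    )

    def pick_score(qs: np.ndarray) -> float:
        if picking_model is not None:
            return float(predict_score(picking_model, qs))
        return fallback_score(qs)

    def pick_score_many(qs_matrix: np.ndarray) -> np.ndarray:
        if picking_model is not None:
            return np.asarray(predict_score(picking_model, qs_matrix))
        return qs_matrix.mean(axis=1)

    # ---- stage 1: initial peak picking + quality scores + scoring -------
    initial_scores: dict[str, dict[str, float]] = {sid: {} for sid in sample_ids}
    for sample in samples:
        for metab in metabolites:
            traces = sample.chromatograms.get(metab.name, {})
            if "quantifier" not in traces:
                continue
            try:
                cands = find_candidates(
                    traces["quantifier"], params,
                    window_center=metab.expected_rt,
                    window_halfwidth=params.initial_shift_window,
                    metabolite=metab.name, sample_id=sample.sample_id,
                )
                for cand in cands:
                    cand.qs = compute_qs(cand, traces, metab, 0.0, params)
                if cands:
                    scores = pick_score_many(np.vstack([c.qs for c in cands]))
                    for cand, score in zip(cands, scores):
                        cand.score = float(score)
                    initial_scores[sample.sample_id][metab.name] = float(
                        scores.max()
                    )
                if collect_candidates:
                    result.candidates.extend(cands)
            except Exception:
                logger.exception(
                    "initial picking failed for %s/%s",
                    metab.name, sample.sample_id,
                )
    n_cands = sum(len(v) for v in initial_scores.values())
    result.log.append(f"stage=initial_picking scored_cells={n_cands}")

    # ---- stage 2: reference selection -----------------------------------
    reference_id = select_reference(initial_scores)
    result.reference_sample = reference_id
    reference = by_id[reference_id]
    result.log.append(f"stage=reference_selection reference={reference_id}")

    # ---- stage 3 + 4: two-pass RT shift estimation ----------------------
    for sample in samples:
        first = estimate_shift_model(sample, reference, metabolites, params)
        refined = refine_shifts(sample, reference, metabolites, first, params)
        result.shift_models[sample.sample_id] = refined
    result.log.append(f"stage=rt_alignment samples={len(samples)}")
    if params.write_plots and params.output_dir:
        from .alignment import plot_shifts

        out = Path(params.output_dir)
        out = out if out.suffix == "" else out.parent
        out.mkdir(parents=True, exist_ok=True)
        plot_shifts(result.shift_models, metabolites, out / "shiftplots.png")

    # ---- stage 5: prototype build + border propagation + integration ----
    for metab in metabolites:
        try:
            proto = build_prototype(
                samples, metab, result.shift_models, params, pick_score
            )
        except ValueError:
            logger.warning("%s: no quantifier trace in any sample", metab.name)
            continue
        result.prototypes[metab.name] = proto
        if proto.best_peak is None:
            logger.info("%s: no peak on prototype, absent batch-wide", metab.name)
            continue
        for sample in samples:
            traces = sample.chromatograms.get(metab.name, {})
            if "quantifier" not in traces:
                continue
            model = result.shift_models[sample.sample_id]
            quant = traces["quantifier"]
            start, end = propagate_borders(proto, model, quant)
            if not start < end:
                continue
            area, height = integrate(quant, start, end)
            result.area.at[metab.name, sample.sample_id] = area
            result.height.at[metab.name, sample.sample_id] = height
            result.start_time.at[metab.name, sample.sample_id] = start
            result.end_time.at[metab.name, sample.sample_id] = end
            mask = (quant.times >= start) & (quant.times <= end)
            if mask.any():
                w = smooth(quant.intensities, params.smoothing_width)[mask]
                apex_t = float(quant.times[mask][np.argmax(w)])
            else:
                apex_t = (start + end) / 2
            result.apex_time.at[metab.name, sample.sample_id] = apex_t
            istd_role = metab.istd_role
            if istd_role and istd_role in traces:
                istd = traces[istd_role]
                s0 = max(start, float(istd.times[0]))
                s1 = min(end, float(istd.times[-1]))
                if s0 < s1:
                    istd_area, istd_height = integrate(istd, s0, s1)
                    na = normalize_to_istd(area, istd_area)
                    nh = normalize_to_istd(height, istd_height)
                    if na is not None:
                        result.normalized_area.at[metab.name, sample.sample_id] = na
                    if nh is not None:
                        result.normalized_height.at[metab.name, sample.sample_id] = nh
    result.log.append(
        f"stage=prototype_integration metabolites={len(result.prototypes)}"
    )

    # ---- stage 6: reporting features + gate -----------------------------
    for metab in metabolites:
        proto = result.prototypes.get(metab.name)
        if proto is None or proto.best_peak is None:
            continue
        per_sample_qs: dict[str, np.ndarray] = {}
        for sample in samples:
            traces = sample.chromatograms.get(metab.name, {})
            start = result.start_time.at[metab.name, sample.sample_id]
            end = result.end_time.at[metab.name, sample.sample_id]
            if "quantifier" not in traces or not np.isfinite(start):
                continue
            quant = traces["quantifier"]
            apex_t = result.apex_time.at[metab.name, sample.sample_id]
            apex_idx = int(np.argmin(np.abs(quant.times - apex_t)))
            cand = PeakCandidate(
                metabolite=metab.name,
                sample_id=sample.sample_id,
                apex_idx=apex_idx,
                apex_time=float(apex_t),
                start_time=float(start),
                end_time=float(end),
                height=float(result.height.at[metab.name, sample.sample_id]),
                area=float(result.area.at[metab.name, sample.sample_id]),
            )
            shift = result.shift_models[sample.sample_id].shift_for(
                metab.name, metab.expected_rt
            )
            qs = compute_qs(cand, traces, metab, shift, params)
            per_sample_qs[sample.sample_id] = qs
        if not per_sample_qs:
            continue
        sids = list(per_sample_qs)
        batch_scores = pick_score_many(np.vstack([per_sample_qs[s] for s in sids]))
        scores = {s: float(v) for s, v in zip(sids, batch_scores)}
        all_scores = list(scores.values())
        feats_by_sid = {
            sid: assemble_reporting_features(qs, scores[sid], all_scores)
            for sid, qs in per_sample_qs.items()
        }
        if reporting_model is not None:
            rscores = np.asarray(
                predict_score(
                    reporting_model, np.vstack([feats_by_sid[s] for s in sids])
                )
            )
            report_scores = dict(zip(sids, rscores))
        else:
            report_scores = {
                sid: fallback_score(qs) for sid, qs in per_sample_qs.items()
            }
        for sid, feats in feats_by_sid.items():
            result.reporting_features[(metab.name, sid)] = feats
            result.output_h.at[metab.name, sid] = scores[sid]
            rscore = float(report_scores[sid])
            result.report_score.at[metab.name, sid] = rscore
            result.reported.at[metab.name, sid] = bool(
                rscore >= params.report_threshold
                and np.isfinite(result.area.at[metab.name, sid])
            )
    result.log.append(
        f"stage=reporting_gate reported={int(result.reported.to_numpy().sum())}"
    )

    # ---- stage 7: outputs ------------------------------------------------
    if params.output_dir is not None:
        paths = mio.write_peak_tables(result, params)
        result.log.append(f"stage=output tables={len(paths)}")
        if params.write_qslog:
            rows = [
                {
                    "metabolite": c.metabolite,
                    "sample": c.sample_id,
                    "candidate": i,
                    "apex_time": c.apex_time,
                    "start_time": c.start_time,
                    "end_time": c.end_time,
                    "height": c.height,
                    "area": c.area,
                    **dict(zip(QS_NAMES, c.qs if c.qs is not None else [])),
                    "score": c.score,
                }
                for i, c in enumerate(result.candidates)
            ]
            out = Path(params.output_dir)
            out = out if out.suffix == "" else out.parent
            mio.write_qslog(rows, out / "qslog_initial.tsv")
    for line in result.log:
        logger.info(line)
    return result


def peakcheck_template(result: BatchResult) -> pd.DataFrame:
    """Template for the manual reporting review: one row per cell, blank value."""
    rows = [
        {"metabolite": m, "sample": s, "value": ""}
        for m in result.metabolites
        for s in result.sample_ids
    ]
    return pd.DataFrame(rows)


def train_models(
    samples: Sequence[SampleRecord],
    metabolites: Sequence[MetaboliteDef],
    params: ProcessingParams,
    picking_solution: pd.DataFrame | str | Path,
    reporting_solution: pd.DataFrame | str | Path,
    algorithm: str = "random_forest",
    seed: int | None = None,
) -> tuple[TrainedClassifier, TrainedClassifier]:
    """Two-stage training of the picking and reporting classifiers.

    Stage 1 processes the batch without any model, collects all candidate
    quality scores, labels them against the picking solution (correct iff
    the solution area is positive and the candidate apex falls between the
    solution borders) and trains the picking model.  Stage 2 reprocesses
    the batch with that model, assembles the reporting features, labels
    them against the 0/1/2 review table and trains the reporting model.
    Both models are persisted when ``params`` carries model paths.
    """
    if seed is None:
        seed = params.random_seed
    if isinstance(picking_solution, (str, Path)):
        picking_solution = pd.read_csv(picking_solution)
    if isinstance(reporting_solution, (str, Path)):
        reporting_solution = pd.read_csv(reporting_solution)

    stage1 = process_batch(
        samples, metabolites, params, collect_candidates=True
    )
    picking_examples = derive_picking_labels(stage1.candidates, picking_solution)
    picking = train_classifier(
        picking_examples, algorithm=algorithm, seed=seed, task="picking"
    )

    stage2 = process_batch(
        samples, metabolites, params, picking_model=picking
    )
    reporting_examples = derive_reporting_labels(
        stage2.reporting_features, reporting_solution
    )
    if not reporting_examples:
        raise ValueError(
            "no usable training examples for the reporting model "
            "(all review values are 1 = excluded)"
        )
    reporting = train_classifier(
        reporting_examples, algorithm=algorithm, seed=seed, task="reporting"
    )
    if params.picking_model_path:
        save_model(picking, params.picking_model_path)
    if params.reporting_model_path:
        save_model(reporting, params.reporting_model_path)
    return picking, reporting
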