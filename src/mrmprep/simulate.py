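"""Synthetic MRM batch generator with known ground truth.

Emulates the statistical structure of a HILIC LC-QQQ-MS batch so that every
pipeline stage is testable without instrument data:

* per-metabolite expected RTs drawn uniformly over the gradient,
* per-sample RT drift quadratic in RT (``a_s * rt^2``) whose coefficient
  ramps linearly over the injection sequence up to ``drift_a`` — mimicking
  a column that drifts as the batch progresses — plus a per-metabolite
  normal jitter truncated at +-0.5 min,
* Gaussian analyte peaks (optionally with an exponentially-modified-
  Gaussian tail) on a constant baseline with additive Gaussian noise
  clipped at zero,
* one unlabeled qualifier at a fixed fraction of the quantifier and one
  13C-labeled internal-standard qualifier of constant amplitude that is
  present in every sample (it is spiked in, so it persists even when the
  analyte peak is missing),
* missing peaks with probability ``p_missing`` (truth area 0) and, with
  probability ``p_decoy``, an interfering decoy peak 0.3-0.8 min away on
  the quantifier trace only.

Each transition is recorded as a dynamic-MRM style time segment centred on
the metabolite's expected RT.  The truth table stores apex, borders
(apex +- 4 sigma), the closed-form area ``A * sigma * sqrt(2*pi)`` and the
applied shift per (metabolite, sample).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chromatogram import gaussian
from .io import Chromatogram, MetaboliteDef, SampleRecord, TransitionKey

__all__ = ["SimConfig", "generate_batch", "emit_training_solutions", "write_mzml"]


@dataclass(frozen=True)
class SimConfig:
    """Batch-simulation parameters (times in minutes, signals in counts)."""

    n_samples: int = 12
    n_metabolites: int = 10
    rt_range: tuple[float, float] = (1.0, 8.0)
    drift_a: float = 0.005          # max quadratic drift coefficient, 1/min
    jitter_sd: float = 0.05         # per-metabolite RT jitter, min
    peak_sd_range: tuple[float, float] = (0.03, 0.06)
    amplitude_range: tuple[float, float] = (2e3, 1e5)
    noise_sd: float = 20.0
    baseline: float = 50.0
    qualifier_ratio: float = 0.5    # qualifier/quantifier amplitude
    p_missing: float = 0.1
    p_decoy: float = 0.2
    sampling_interval: float = 0.005
    segment_halfwidth: float = 1.0  # DMRM-style acquisition window, min
    emg_tau: float = 0.0            # exponential tail constant; 0 = Gaussian
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_missing, self.p_decoy):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        for name in ("peak_sd_range", "amplitude_range", "rt_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive, ordered range")
        if self.segment_halfwidth <= 4 * self.peak_sd_range[1]:
            raise ValueError("segment_halfwidth too small for the peak widths")
        if self.rt_range[1] - self.rt_range[0] <= 8 * self.peak_sd_range[1]:
            raise ValueError("rt_range shorter than the peaks it must hold")


#: truncation bound for per-metabolite RT jitter (minutes)
JITTER_BOUND = 0.5


def _peak_shape(t: np.ndarray, amp: float, mu: float, sigma: float, tau: float):
    if tau <= 0:
        return gaussian(t, amp, mu, sigma)
    from scipy.stats import exponnorm

    k = tau / sigma
    shape = exponnorm.pdf(t, K=k, loc=mu, scale=sigma)
    peak = shape / shape.max() * amp if shape.max() > 0 else shape
    return peak


def _truncated_normal(rng: np.random.Generator, sd: float, bound: float) -> float:
    if sd <= 0:
        return 0.0
    for _ in range(100):
        v = rng.normal(0.0, sd)
        if abs(v) <= bound:
            return float(v)
    return float(np.clip(v, -bound, bound))


def generate_batch(
    cfg: SimConfig,
) -> tuple[list[SampleRecord], list[MetaboliteDef], pd.DataFrame]:
    """Generate one batch: samples, metabolite definitions and truth table.

    All randomness flows from ``cfg.seed`` through spawned child generators
    (one for the metabolite panel, one per sample), so regenerating with the
    same config is bit-identical.
    """
    root = np.random.default_rng(cfg.seed)
    met_rng, *sample_rngs = root.spawn(1 + cfg.n_samples)

    lo_rt, hi_rt = cfg.rt_range
    margin = 4 * cfg.peak_sd_range[1]
    metabolites: list[MetaboliteDef] = []
    met_sigma: dict[str, float] = {}
    met_amp: dict[str, float] = {}
    met_istd_amp: dict[str, float] = {}
    for i in range(cfg.n_metabolites):
        name = f"M{i + 1:03d}"
        rt = float(met_rng.uniform(lo_rt + margin, hi_rt - margin))
        prec = 100.0 + 13.7 * i
        prod = prec - 42.0 - 3.1 * (i % 5)
        quant = TransitionKey(prec, prod, "positive")
        qual1 = TransitionKey(prec, prod - 18.0, "positive")
        qual2 = TransitionKey(prec + 3.0, prod - 15.0, "positive")  # 13C ISTD
        lo_a, hi_a = cfg.amplitude_range
        amp = float(np.exp(met_rng.uniform(np.log(lo_a), np.log(hi_a))))
        met_sigma[name] = float(met_rng.uniform(*cfg.peak_sd_range))
        met_amp[name] = amp
        met_istd_amp[name] = float(np.sqrt(lo_a * hi_a))
        metabolites.append(
            MetaboliteDef(
                name=name,
                quantifier=quant,
                qualifiers=[qual1, qual2],
                c13_qualifier_index=1,
                expected_rt=rt,
                expected_ratio=1.0 / cfg.qualifier_ratio,
                db_ids={"sim": f"SIM:{i + 1:04d}"},
            )
        )

    # per-sample drift coefficient ramps over the injection sequence;
    # the first sample is drift-free
    denom = max(cfg.n_samples - 1, 1)
    drift_coeffs = [cfg.drift_a * s / denom for s in range(cfg.n_samples)]

    samples: list[SampleRecord] = []
    truth_rows: list[dict] = []
    for s, rng in enumerate(sample_rngs):
        sample_id = f"S{s + 1:02d}"
        record = SampleRecord(
            sample_id=sample_id,
            metadata={"injection_order": str(s + 1), "group": f"G{s // 4 + 1}"},
        )
        a_s = drift_coeffs[s]
        for metab in metabolites:
            name = metab.name
            sigma = met_sigma[name]
            rt = metab.expected_rt
            jitter = _truncated_normal(rng, cfg.jitter_sd, JITTER_BOUND)
            shift = a_s * rt * rt + jitter
            apex = rt + shift
            amp = met_amp[name] * float(np.exp(rng.normal(0.0, 0.3)))
            present = rng.uniform() >= cfg.p_missing
            has_decoy = rng.uniform() < cfg.p_decoy
            decoy_offset = float(rng.uniform(0.3, 0.8)) * (
                1 if rng.uniform() < 0.5 else -1
            )
            decoy_amp = amp * float(rng.uniform(0.5, 2.0))

            t0 = max(0.0, rt - cfg.segment_halfwidth)
            grid = np.arange(
                t0, rt + cfg.segment_halfwidth + cfg.sampling_interval / 2,
                cfg.sampling_interval,
            )
            quant_y = np.full_like(grid, cfg.baseline)
            qual1_y = np.full_like(grid, cfg.baseline)
            qual2_y = np.full_like(grid, cfg.baseline)
            if present:
                peak = _peak_shape(grid, amp, apex, sigma, cfg.emg_tau)
                quant_y = quant_y + peak
                qual1_y = qual1_y + cfg.qualifier_ratio * peak
            if has_decoy:
                decoy_mu = float(np.clip(apex + decoy_offset, grid[0], grid[-1]))
                quant_y = quant_y + gaussian(grid, decoy_amp, decoy_mu, sigma)
            # 13C internal standard: spiked into every sample
            qual2_y = qual2_y + _peak_shape(
                grid, met_istd_amp[name], apex, sigma, cfg.emg_tau
            )
            if cfg.noise_sd > 0:
                quant_y = quant_y + rng.normal(0.0, cfg.noise_sd, grid.size)
                qual1_y = qual1_y + rng.normal(0.0, cfg.noise_sd, grid.size)
                qual2_y = qual2_y + rng.normal(0.0, cfg.noise_sd, grid.size)
            roles = metab.roles()
            record.chromatograms[name] = {
                "quantifier": Chromatogram(
                    roles["quantifier"], grid, np.clip(quant_y, 0.0, None)
                ),
                "qualifier1": Chromatogram(
                    roles["qualifier1"], grid, np.clip(qual1_y, 0.0, None)
                ),
                "qualifier2": Chromatogram(
                    roles["qualifier2"], grid, np.clip(qual2_y, 0.0, None)
                ),
            }
            truth_rows.append(
                {
                    "metabolite": name,
                    "sample": sample_id,
                    "present": bool(present),
                    "true_apex": apex if present else np.nan,
                    "true_start": apex - 4 * sigma if present else np.nan,
                    "true_end": apex + 4 * sigma if present else np.nan,
                    "true_area": amp * sigma * np.sqrt(2 * np.pi) if present else 0.0,
                    "true_height": amp if present else 0.0,
                    "true_sigma": sigma,
                    "true_shift": shift,
                    "drift_coeff": a_s,
                    "has_decoy": bool(has_decoy),
                    "istd_area": met_istd_amp[name] * sigma * np.sqrt(2 * np.pi),
                }
            )
        samples.append(record)

    truth = pd.DataFrame(truth_rows)
    return samples, metabolites, truth


#: half-width of expert-marked peak borders in the picking solution, in
#: units of the true peak sigma.  An operator marks the visible extent of a
#: peak, which is tighter than the analytic integration borders; candidates
#: on the near-baseline tails are not "the peak" to a reviewer.
EXPERT_BORDER_SIGMAS = 2.5


def emit_training_solutions(
    truth: pd.DataFrame,
    picking_path: str | Path | None = None,
    reporting_path: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive the two expert-solution tables from the generator truth.

    The picking solution carries area/start/end per (metabolite, sample)
    with area 0 for absent peaks and borders at the expert-visible peak
    extent (apex +- 2.5 sigma); the reporting solution carries 2 where a
    peak is present and 0 where it is absent.  Optionally written as CSV.
    """
    picking = truth[["metabolite", "sample", "true_area"]].rename(
        columns={"true_area": "area"}
    )
    picking = picking.copy()
    hw = EXPERT_BORDER_SIGMAS * truth["true_sigma"]
    picking["start"] = truth["true_apex"] - hw
    picking["end"] = truth["true_apex"] + hw
    picking.loc[~truth["present"].to_numpy(), ["start", "end"]] = np.nan
    reporting = truth[["metabolite", "sample"]].copy()
    reporting["value"] = np.where(truth["present"], 2, 0)
    if picking_path is not None:
        picking.to_csv(picking_path, index=False)
    if reporting_path is not None:
        reporting.to_csv(reporting_path, index=False)
    return picking, reporting


# --------------------------------------------------------------------------
# Fixture mzML serializer
# --------------------------------------------------------------------------

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="UNIT-ONTOLOGY" URI="http://ontologies.berkeleybop.org/uo.obo"/>
  </cvList>
  <run id="{run_id}">
    <chromatogramList count="{count}" defaultDataProcessingRef="dp">
"""

_MZML_FOOTER = """    </chromatogramList>
  </run>
</mzML>
"""


def _b64(values: np.ndarray) -> str:
    import base64

    return base64.b64encode(
        np.asarray(values, dtype="<f8").tobytes()
    ).decode("ascii")


def _chromatogram_xml(
    index: int, chrom: Chromatogram, time_unit: str = "minute"
) -> str:
    t = chrom.times if time_unit == "minute" else chrom.times * 60.0
    unit_acc = "UO:0000031" if time_unit == "minute" else "UO:0000010"
    tb64, ib64 = _b64(t), _b64(chrom.intensities)
    key = chrom.transition
    pol = ""
    if key.polarity == "positive":
        pol = '<cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>'
    elif key.polarity == "negative":
        pol = '<cvParam cvRef="MS" accession="MS:1000129" name="negative scan" value=""/>'
    return f"""      <chromatogram index="{index}" id="SRM SIC Q1={key.precursor_mz} Q3={key.product_mz}" defaultArrayLength="{len(chrom)}">
        <cvParam cvRef="MS" accession="MS:1001473" name="selected reaction monitoring chromatogram" value=""/>
        {pol}
        <precursor>
          <isolationWindow>
            <cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{key.precursor_mz}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
          </isolationWindow>
        </precursor>
        <product>
          <isolationWindow>
            <cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{key.product_mz}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
          </isolationWindow>
        </product>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(tb64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000595" name="time array" value="" unitCvRef="UO" unitAccession="{unit_acc}" unitName="{time_unit}"/>
            <binary>{tb64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(ib64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{ib64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </chromatogram>
"""


def write_mzml(
    sample: SampleRecord, path: str | Path, time_unit: str = "minute"
) -> Path:
    """Serialize one sample's chromatograms as a minimal valid mzML file.

    A fixture serializer for round-trip testing of the mzML reader; it
    writes only what an SRM chromatogram list needs (base64 64-bit float
    arrays, no compression).  ``time_unit`` may be "second" to exercise
    unit conversion on read.
    """
    path = Path(path)
    chroms = [
        chrom
        for per_met in sample.chromatograms.values()
        for chrom in per_met.values()
    ]
    parts = [_MZML_HEADER.format(run_id=sample.sample_id, count=len(chroms))]
    for i, chrom in enumerate(chroms):
        parts.append(_chromatogram_xml(i, chrom, time_unit))
    parts.append(_MZML_FOOTER)
    path.write_text("".join(parts))
    return path
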