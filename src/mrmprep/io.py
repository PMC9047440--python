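"""Input/output for MRM batches.

Reads SRM/MRM chromatograms from mzML, metabolite definitions and sample
metadata from tabular files, and writes the result matrices.

The mzML reader is deliberately narrow: it only consumes the
``chromatogramList`` section (one intensity-vs-time trace per transition),
decoding cvParam-annotated binary arrays (64/32-bit float, zlib or no
compression) and normalising retention times to minutes.  Spectrum data is
ignored entirely.
"""

from __future__ import annotations

import base64
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from lxml import etree

logger = logging.getLogger("mrmprep")

__all__ = [
    "TransitionKey",
    "Chromatogram",
    "MetaboliteDef",
    "SampleRecord",
    "ProcessingParams",
    "MzmlParseError",
    "SchemaError",
    "read_mrm_mzml",
    "read_metabolite_db",
    "read_sample_info",
    "write_peak_tables",
    "read_peak_table",
    "write_qslog",
]


class MzmlParseError(ValueError):
    """Raised for unreadable mzML or ambiguous transition matches."""


class SchemaError(ValueError):
    """Raised when a tabular input is missing mandatory columns or values."""


@dataclass(frozen=True)
class TransitionKey:
    """A monitored precursor -> product ion pair."""

    precursor_mz: float
    product_mz: float
    polarity: str | None = None  # "positive" | "negative" | None (unknown)

    def __post_init__(self) -> None:
        if not (self.precursor_mz > 0 and self.product_mz > 0):
            raise ValueError("transition m/z values must be positive")

    def matches(self, other: "TransitionKey", tol: float) -> bool:
        if (
            self.polarity is not None
            and other.polarity is not None
            and self.polarity != other.polarity
        ):
            return False
        return (
            abs(self.precursor_mz - other.precursor_mz) <= tol
            and abs(self.product_mz - other.product_mz) <= tol
        )


@dataclass
class Chromatogram:
    """One transition's intensity-vs-time trace for one sample (minutes)."""

    transition: TransitionKey
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must be 1-D and equal length")
        if len(self.times) < 2:
            raise ValueError("chromatogram needs at least 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.times)


# Transition roles used throughout the pipeline. "qualifier2" conventionally
# holds the 13C-labeled internal-standard transition when one exists.
ROLES = ("quantifier", "qualifier1", "qualifier2")


@dataclass
class MetaboliteDef:
    """Target definition: transitions, expected RT and intensity ratio."""

    name: str
    quantifier: TransitionKey
    qualifiers: list[TransitionKey] = field(default_factory=list)
    c13_qualifier_index: int | None = None  # index into qualifiers, or None
    expected_rt: float = 0.0  # minutes
    expected_ratio: float | None = None  # quantifier/qualifier intensity ratio
    db_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.expected_rt > 0:
            raise ValueError(f"{self.name}: expected_rt must be > 0")
        if self.expected_ratio is not None and not self.expected_ratio > 0:
            raise ValueError(f"{self.name}: expected_ratio must be > 0")

    def roles(self) -> dict[str, TransitionKey]:
        out = {"quantifier": self.quantifier}
        for i, q in enumerate(self.qualifiers[:2]):
            out[f"qualifier{i + 1}"] = q
        return out

    @property
    def istd_role(self) -> str | None:
        """Role name of the 13C internal-standard qualifier, if any."""
        if self.c13_qualifier_index is None:
            return None
        return f"qualifier{self.c13_qualifier_index + 1}"


@dataclass
class SampleRecord:
    """One sample: metadata plus its per-metabolite chromatograms."""

    sample_id: str
    mzml_path: str | None = None
    metadata: dict[str, str] = field(default_factory=dict)
    # metabolite name -> role -> Chromatogram
    chromatograms: dict[str, dict[str, Chromatogram]] = field(default_factory=dict)
    missing: list[tuple[str, str]] = field(default_factory=list)  # (metabolite, role)


@dataclass
class ProcessingParams:
    """Tunable processing parameters (times in minutes)."""

    smoothing_width: int = 5          # points, odd
    n_candidates: int = 5
    initial_shift_window: float = 0.5
    refined_shift_window: float = 0.17
    drt_window: float = 0.5
    border_frac: float = 0.01         # border threshold as fraction of apex
    mz_tolerance: float = 0.05        # Th, transition matching
    report_threshold: float = 0.5
    random_seed: int = 0
    picking_model_path: str | None = None
    reporting_model_path: str | None = None
    output_dir: str | None = None
    write_qslog: bool = False
    write_plots: bool = False
    robust_fit: bool = False

    def __post_init__(self) -> None:
        if self.n_candidates < 1:
            raise ValueError("n_candidates must be >= 1")
        if self.smoothing_width < 1 or self.smoothing_width % 2 == 0:
            raise ValueError("smoothing_width must be odd and >= 1")
        for name in ("initial_shift_window", "refined_shift_window", "drt_window"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.report_threshold <= 1.0:
            raise ValueError("report_threshold must be in [0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "ProcessingParams":
        """Load parameters from YAML or TSV ``key<TAB>value`` config."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yml", ".yaml"):
            raw = yaml.safe_load(text) or {}
        else:
            raw = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("\t")
                raw[key.strip()] = value.strip()
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {}
        for key, value in raw.items():
            if key not in known:
                logger.warning("unknown parameter %r ignored", key)
                continue
            target = cls.__dataclass_fields__[key].type
            if value is None or value == "":
                kwargs[key] = None
            elif "bool" in str(target):
                kwargs[key] = str(value).lower() in ("1", "true", "yes")
            elif "int" in str(target):
                kwargs[key] = int(value)
            elif "float" in str(target):
                kwargs[key] = float(value)
            else:
                kwargs[key] = str(value)
        return cls(**kwargs)


# --------------------------------------------------------------------------
# mzML chromatogram parsing
# --------------------------------------------------------------------------

_ACC_TIME_ARRAY = "MS:1000595"
_ACC_INTENSITY_ARRAY = "MS:1000515"
_ACC_64BIT = "MS:1000523"
_ACC_32BIT = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_TARGET_MZ = "MS:1000827"
_ACC_NEG_SCAN = "MS:1000129"
_ACC_POS_SCAN = "MS:1000130"
_ACC_UNIT_MINUTE = "UO:0000031"
_ACC_UNIT_SECOND = "UO:0000010"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(elem) -> list[dict]:
    return [
        dict(child.attrib)
        for child in elem.iter()
        if _local(child.tag) == "cvParam"
    ]


def _decode_binary_array(bda) -> tuple[np.ndarray, dict]:
    params = {p.get("accession"): p for p in _cv_params(bda)}
    binary = None
    for child in bda:
        if _local(child.tag) == "binary":
            binary = child.text or ""
    raw = base64.b64decode(binary.encode()) if binary else b""
    if _ACC_ZLIB in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_32BIT in params else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float), params


def _isolation_target(elem, tag: str) -> float | None:
    for child in elem.iter():
        if _local(child.tag) == tag:
            for p in _cv_params(child):
                if p.get("accession") == _ACC_TARGET_MZ:
                    return float(p["value"])
    return None


def parse_chromatograms(path: str | Path) -> list[Chromatogram]:
    """Parse every SRM chromatogram (with precursor/product m/z) in an mzML file.

    Times are converted to minutes regardless of the unit recorded in the
    file (second-unit arrays are divided by 60).  Chromatograms without both
    a precursor and a product isolation target (e.g. TIC) are skipped.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise MzmlParseError(f"cannot parse mzML file {path}: {exc}") from exc

    out: list[Chromatogram] = []
    for elem in tree.iter():
        if _local(elem.tag) != "chromatogram":
            continue
        precursor = product = None
        polarity = None
        times = intensities = None
        for p in _cv_params(elem):
            acc = p.get("accession")
            if acc == _ACC_NEG_SCAN:
                polarity = "negative"
            elif acc == _ACC_POS_SCAN:
                polarity = "positive"
        for child in elem:
            name = _local(child.tag)
            if name == "precursor":
                precursor = _isolation_target(child, "isolationWindow")
            elif name == "product":
                product = _isolation_target(child, "isolationWindow")
            elif name == "binaryDataArrayList":
                for bda in child:
                    if _local(bda.tag) != "binaryDataArray":
                        continue
                    values, params = _decode_binary_array(bda)
                    if _ACC_TIME_ARRAY in params:
                        unit = params[_ACC_TIME_ARRAY].get("unitAccession")
                        unit_name = params[_ACC_TIME_ARRAY].get("unitName", "")
                        if unit == _ACC_UNIT_SECOND or "second" in unit_name:
                            values = values / 60.0
                        times = values
                    elif _ACC_INTENSITY_ARRAY in params:
                        intensities = values
        if precursor is None or product is None:
            continue
        if times is None or intensities is None or len(times) < 2:
            raise MzmlParseError(
                f"{path}: chromatogram {elem.get('id')!r} lacks usable "
                "time/intensity arrays"
            )
        out.append(
            Chromatogram(
                TransitionKey(precursor, product, polarity),
                times,
                np.clip(intensities, 0.0, None),
            )
        )
    if not out:
        raise MzmlParseError(f"{path}: no SRM chromatograms found")
    return out


def read_mrm_mzml(
    path: str | Path,
    metabolites: Sequence[MetaboliteDef],
    mz_tolerance: float = 0.05,
    sample_id: str | None = None,
) -> SampleRecord:
    """Read one sample's mzML file and match traces to metabolite transitions.

    Every metabolite transition is matched to at most one chromatogram by
    (precursor, product) m/z within ``mz_tolerance``; unmatched transitions
    are recorded in ``SampleRecord.missing`` with a logged warning rather
    than raising, so one bad trace cannot abort a batch.
    """
    path = Path(path)
    chroms = parse_chromatograms(path)
    record = SampleRecord(
        sample_id=sample_id or path.stem, mzml_path=str(path)
    )
    for metab in metabolites:
        record.chromatograms[metab.name] = {}
        for role, key in metab.roles().items():
            hits = [c for c in chroms if key.matches(c.transition, mz_tolerance)]
            if len(hits) > 1:
                pairs = [
                    (c.transition.precursor_mz, c.transition.product_mz)
                    for c in hits
                ]
                raise MzmlParseError(
                    f"{path}: transition ({key.precursor_mz}, {key.product_mz}) "
                    f"of {metab.name}/{role} matches {len(hits)} chromatograms "
                    f"within {mz_tolerance} Th: {pairs}"
                )
            if not hits:
                record.missing.append((metab.name, role))
                logger.warning(
                    "%s: no chromatogram for %s/%s (%.4g -> %.4g)",
                    path.name, metab.name, role,
                    key.precursor_mz, key.product_mz,
                )
                continue
            record.chromatograms[metab.name][role] = hits[0]
    return record


# --------------------------------------------------------------------------
# Tabular inputs
# --------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".xlsx", ".xls"):
        return pd.read_excel(path)
    sep = "\t" if suffix in (".tsv", ".txt", ".info") else ","
    return pd.read_csv(path, sep=sep)


_MANDATORY_DB_COLS = ("name", "quant_prec_mz", "quant_prod_mz", "expected_rt")


def read_metabolite_db(path: str | Path) -> list[MetaboliteDef]:
    """Read the metabolite definition table (CSV/TSV or xlsx).

    Mandatory columns: ``name``, ``quant_prec_mz``, ``quant_prod_mz``,
    ``expected_rt``.  Optional: ``qual1_prec_mz``/``qual1_prod_mz``,
    ``qual2_prec_mz``/``qual2_prod_mz``, ``c13_qualifier`` (1-based index of
    the labeled qualifier), ``expected_ratio``, ``polarity`` and any number
    of ``id_<database>`` columns collected into ``db_ids``.
    """
    df = _read_table(path)
    for col in _MANDATORY_DB_COLS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    out: list[MetaboliteDef] = []
    for idx, row in df.iterrows():
        rt = float(row["expected_rt"])
        if not rt > 0:
            raise SchemaError(
                f"{path}: row {idx} ({row['name']}): expected_rt must be > 0, "
                f"got {rt}"
            )
        polarity = None
        if "polarity" in df.columns and pd.notna(row.get("polarity")):
            polarity = str(row["polarity"]).strip().lower() or None
        qualifiers = []
        for i in (1, 2):
            pc, pr = row.get(f"qual{i}_prec_mz"), row.get(f"qual{i}_prod_mz")
            if pd.notna(pc) and pd.notna(pr) and str(pc) != "" and str(pr) != "":
                qualifiers.append(TransitionKey(float(pc), float(pr), polarity))
        c13 = None
        if "c13_qualifier" in df.columns and pd.notna(row.get("c13_qualifier")):
            c13 = int(row["c13_qualifier"]) - 1
            if not 0 <= c13 < len(qualifiers):
                raise SchemaError(
                    f"{path}: row {idx}: c13_qualifier={c13 + 1} has no "
                    "matching qualifier columns"
                )
        ratio = None
        if "expected_ratio" in df.columns and pd.notna(row.get("expected_ratio")):
            ratio = float(row["expected_ratio"])
        db_ids = {
            col[3:]: str(row[col])
            for col in df.columns
            if col.startswith("id_") and pd.notna(row[col])
        }
        out.append(
            MetaboliteDef(
                name=str(row["name"]),
                quantifier=TransitionKey(
                    float(row["quant_prec_mz"]),
                    float(row["quant_prod_mz"]),
                    polarity,
                ),
                qualifiers=qualifiers,
                c13_qualifier_index=c13,
                expected_rt=rt,
                expected_ratio=ratio,
                db_ids=db_ids,
            )
        )
    return out


def write_metabolite_db(
    metabolites: Sequence[MetaboliteDef], path: str | Path
) -> Path:
    """Write a metabolite definition table readable by read_metabolite_db."""
    path = Path(path)
    rows = []
    for m in metabolites:
        row: dict = {
            "name": m.name,
            "quant_prec_mz": m.quantifier.precursor_mz,
            "quant_prod_mz": m.quantifier.product_mz,
            "expected_rt": m.expected_rt,
            "expected_ratio": m.expected_ratio,
            "polarity": m.quantifier.polarity,
            "c13_qualifier": (
                m.c13_qualifier_index + 1
                if m.c13_qualifier_index is not None
                else None
            ),
        }
        for i, q in enumerate(m.qualifiers[:2]):
            row[f"qual{i + 1}_prec_mz"] = q.precursor_mz
            row[f"qual{i + 1}_prod_mz"] = q.product_mz
        for db, ident in m.db_ids.items():
            row[f"id_{db}"] = ident
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_sample_info(path: str | Path) -> pd.DataFrame:
    """Read the flat sample metadata file (TSV with at least ``sample_id``)."""
    df = _read_table(path)
    if "sample_id" not in df.columns:
        raise SchemaError(f"{path}: missing mandatory column 'sample_id'")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise SchemaError(f"{path}: duplicate sample_id values {dupes}")
    return df


# --------------------------------------------------------------------------
# Result tables
# --------------------------------------------------------------------------

TABLE_NAMES = (
    "reported_area",      # primary: quantifier area, empty where not reported
    "raw_area",
    "raw_height",
    "normalized_area",    # area / 13C-ISTD area
    "normalized_height",
)


def write_peak_tables(results, params: ProcessingParams) -> dict[str, Path]:
    """Write the five result matrices (metabolites x samples).

    ``results`` is a :class:`mrmprep.pipeline.BatchResult`.  If
    ``params.output_dir`` ends in ``.xlsx`` a single workbook with five
    sheets is written; otherwise one CSV per table is written into the
    directory.  CSV is the canonical, bit-exact dialect.
    """
    out = Path(params.output_dir or ".")
    tables = {
        "reported_area": results.area.where(results.reported),
        "raw_area": results.area,
        "raw_height": results.height,
        "normalized_area": results.normalized_area,
        "normalized_height": results.normalized_height,
    }
    paths: dict[str, Path] = {}
    if out.suffix.lower() == ".xlsx":
        out.parent.mkdir(parents=True, exist_ok=True)
        with pd.ExcelWriter(out) as writer:
            for name in TABLE_NAMES:
                tables[name].to_excel(writer, sheet_name=name)
        return {name: out for name in TABLE_NAMES}
    out.mkdir(parents=True, exist_ok=True)
    for name in TABLE_NAMES:
        p = out / f"{name}.csv"
        tables[name].to_csv(p, index_label="metabolite")
        paths[name] = p
    return paths


def read_peak_table(path: str | Path) -> pd.DataFrame:
    """Re-read a CSV written by :func:`write_peak_tables` (round-trip exact)."""
    return pd.read_csv(path, index_col="metabolite")


def write_qslog(rows: Sequence[Mapping], path: str | Path) -> Path:
    """Write the per-candidate quality-score log (TSV, fixed column order)."""
    from .quality import QS_NAMES  # late import avoids a cycle

    path = Path(path)
    cols = [
        "metabolite", "sample", "candidate", "apex_time", "start_time",
        "end_time", "height", "area", *QS_NAMES, "score", "label",
    ]
    df = pd.DataFrame(list(rows))
    for col in cols:
        if col not in df.columns:
            df[col] = np.nan
    df[cols].to_csv(path, sep="\t", index=False)
    return path
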