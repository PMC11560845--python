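"""Table and configuration I/O.

Conventions enforced here, once:

* fractions internally, percent only at the file boundary — any CSV column
  suffixed ``_pct`` is divided by 100 and the suffix dropped on read;
* CSV files may carry ``#``-prefixed provenance comment lines (config hash,
  seed), which readers skip;
* the measurement-table schema uses exactly the field names of
  :class:`symbiopop.inference.RoundMeasurement`.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional

import pandas as pd

from .inference import ALLELE_TABLE_COLUMNS, RoundMeasurement, validate_allele_table

__all__ = [
    "MEASUREMENT_COLUMNS",
    "read_table",
    "write_table",
    "parse_measurement_table",
    "measurements_to_frame",
    "write_measurement_table",
    "read_allele_table",
    "write_allele_table",
    "config_hash",
    "write_manifest",
    "read_manifest",
]

MEASUREMENT_COLUMNS = (
    "line_id",
    "round",
    "facs_analyzed",
    "facs_positive",
    "wells_sorted_pos",
    "germinated_day1_pos",
    "germinated_day2_pos",
    "wells_sorted_neg",
    "germinated_day1_neg",
    "germinated_day2_neg",
)

_REQUIRED_MEASUREMENT_COLUMNS = MEASUREMENT_COLUMNS[:7]


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV, skipping ``#`` comments and converting ``_pct`` columns.

    Percent-valued columns must be suffixed ``_pct``; they are converted to
    fractions exactly once, on read, and renamed without the suffix.
    """
    frame = pd.read_csv(path, comment="#")
    pct_cols = [c for c in frame.columns if c.endswith("_pct")]
    for col in pct_cols:
        bare = col[: -len("_pct")]
        if bare in frame.columns:
            raise ValueError(
                f"{path}: both {col!r} and {bare!r} present; units ambiguous"
            )
        frame[bare] = frame[col].astype(float) / 100.0
        frame = frame.drop(columns=[col])
    return frame


def write_table(
    frame: pd.DataFrame,
    path: str | Path,
    provenance: Optional[Mapping[str, Any]] = None,
) -> None:
    """Write a CSV with an optional provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if provenance:
            for key, value in provenance.items():
                fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, index=False)


def _opt_int(value: Any) -> Optional[int]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return int(value)


def parse_measurement_table(path: str | Path) -> list[RoundMeasurement]:
    """Parse and validate a round-measurement CSV.

    Row-level validation errors are reported with their (1-based, header
    excluded) row numbers.
    """
    frame = read_table(path)
    missing = [c for c in _REQUIRED_MEASUREMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    records: list[RoundMeasurement] = []
    errors: list[str] = []
    for i, row in enumerate(frame.to_dict("records"), start=1):
        try:
            records.append(
                RoundMeasurement(
                    line_id=str(row["line_id"]),
                    round=int(row["round"]),
                    facs_analyzed=int(row["facs_analyzed"]),
                    facs_positive=int(row["facs_positive"]),
                    wells_sorted_pos=int(row["wells_sorted_pos"]),
                    germinated_day1_pos=int(row["germinated_day1_pos"]),
                    germinated_day2_pos=int(row["germinated_day2_pos"]),
                    wells_sorted_neg=_opt_int(row.get("wells_sorted_neg")),
                    germinated_day1_neg=_opt_int(row.get("germinated_day1_neg")),
                    germinated_day2_neg=_opt_int(row.get("germinated_day2_neg")),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValueError(f"{path}: invalid rows:\n" + "\n".join(errors))
    return records


def measurements_to_frame(measurements: Iterable[RoundMeasurement]) -> pd.DataFrame:
    frame = pd.DataFrame([m.__dict__ for m in measurements])
    if not len(frame):
        return pd.DataFrame(columns=MEASUREMENT_COLUMNS)
    return frame[list(MEASUREMENT_COLUMNS)]


def write_measurement_table(
    measurements: Iterable[RoundMeasurement],
    path: str | Path,
    provenance: Optional[Mapping[str, Any]] = None,
) -> None:
    write_table(measurements_to_frame(measurements), path, provenance)


def read_allele_table(path: str | Path) -> pd.DataFrame:
    return validate_allele_table(read_table(path))


def write_allele_table(
    table: pd.DataFrame,
    path: str | Path,
    provenance: Optional[Mapping[str, Any]] = None,
) -> None:
    validate_allele_table(table)
    write_table(table[list(ALLELE_TABLE_COLUMNS)], path, provenance)


def config_hash(config: Mapping[str, Any]) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_manifest(manifest: Mapping[str, Any], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
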