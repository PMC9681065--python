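"""Study-record data model and table I/O.

A *corpus* is a flat table of control-vs-treatment contrasts from ocean
acidification (OA) fish-behaviour experiments: one row per effect-size
contrast, carrying arm means/SDs/sample sizes, the measurement scale
(percentage, proportion or continuous), publication years, the CO2
treatment level and the screening flags used downstream.

The canonical in-memory container is a :class:`pandas.DataFrame` with the
columns in :data:`CORPUS_COLUMNS`.  :func:`read_corpus` validates rows
against the record invariants and rejects offending rows with row-level
diagnostics instead of failing wholesale; :func:`write_table` emits
deterministic CSV so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

SCALE_TYPES = ("percentage", "proportion", "continuous")

#: Upper bound of each bounded measurement scale (continuous is unbounded).
SCALE_BOUNDS = {"percentage": 100.0, "proportion": 1.0}

FLAG_COLUMNS = (
    "is_sham",
    "is_fluctuating_co2",
    "is_procedural_control",
    "direction_opposite",
)

#: Columns that must be present (possibly via the schema column map).
REQUIRED_COLUMNS = (
    "record_id",
    "scale_type",
    "control_mean",
    "treatment_mean",
    "control_sd",
    "treatment_sd",
    "control_n",
    "treatment_n",
    "co2_uatm",
)

#: Full canonical column order of a corpus table.
CORPUS_COLUMNS = (
    "record_id",
    "study_id",
    "year_online",
    "year_print",
    "species",
    "life_stage",
    "cue_type",
    "behaviour_metric",
    "scale_type",
    "control_mean",
    "treatment_mean",
    "control_sd",
    "treatment_sd",
    "control_n",
    "treatment_n",
    "co2_uatm",
) + FLAG_COLUMNS

_NUMERIC_COLUMNS = (
    "control_mean",
    "treatment_mean",
    "control_sd",
    "treatment_sd",
    "co2_uatm",
)
_INT_COLUMNS = ("control_n", "treatment_n")

_TRUE_STRINGS = {"true", "1", "yes", "t", "y"}
_FALSE_STRINGS = {"false", "0", "no", "f", "n", ""}


@dataclasses.dataclass(frozen=True)
class SchemaConfig:
    """How a source table maps onto the canonical corpus schema.

    Parameters
    ----------
    column_map : mapping canonical name -> source column name; canonical
        names not listed are taken verbatim from the source header.
    variability : ``"sd"`` if the variability columns hold standard
        deviations, ``"se"`` if they hold standard errors.  SEs are
        converted at load time via ``SD = SE * sqrt(n)``.
    year_source : which year column drives year binning downstream
        (``"online"`` or ``"print"``).
    year_range : inclusive (min, max) publication-year window; rows with a
        year outside it are rejected.
    """

    column_map: Mapping[str, str] = dataclasses.field(default_factory=dict)
    variability: str = "sd"
    year_source: str = "online"
    year_range: tuple[int, int] = (2009, 2019)

    def __post_init__(self) -> None:
        if self.variability not in ("sd", "se"):
            raise ValueError(f"variability must be 'sd' or 'se', got {self.variability!r}")
        if self.year_source not in ("online", "print"):
            raise ValueError(f"year_source must be 'online' or 'print', got {self.year_source!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SchemaConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "column_map" in raw:
            kwargs["column_map"] = dict(raw["column_map"])
        for key in ("variability", "year_source"):
            if key in raw:
                kwargs[key] = raw[key]
        if "year_range" in raw:
            kwargs["year_range"] = tuple(raw["year_range"])
        return cls(**kwargs)

    @property
    def year_column(self) -> str:
        return "year_online" if self.year_source == "online" else "year_print"


@dataclasses.dataclass
class LoadReport:
    """Row-level accounting of a corpus load."""

    n_read: int = 0
    n_accepted: int = 0
    rejects: list[tuple[int, str, str]] = dataclasses.field(default_factory=list)
    #: (0-based data-row index, record_id if parseable, reason)

    @property
    def n_rejected(self) -> int:
        return len(self.rejects)


def _parse_flag(value) -> bool | None:
    """Parse a boolean flag cell; None signals an unparseable value."""
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return False
    if isinstance(value, (int, np.integer)):
        return bool(value)
    text = str(value).strip().lower()
    if text in _TRUE_STRINGS:
        return True
    if text in _FALSE_STRINGS:
        return False
    return None


def read_corpus(
    path: str | Path,
    schema: SchemaConfig | None = None,
) -> tuple[pd.DataFrame, LoadReport]:
    """Read and validate a corpus CSV.

    Returns the accepted records (canonical columns, canonical dtypes) and a
    :class:`LoadReport`.  Rows that violate record invariants are rejected
    individually with a diagnostic naming the row; a missing required column
    is a hard error naming the column.
    """
    schema = schema or SchemaConfig()
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw = raw.rename(columns={src: canon for canon, src in schema.column_map.items()})

    for col in REQUIRED_COLUMNS:
        if col not in raw.columns:
            raise ValueError(f"required column {col!r} missing from {path}")
    if "year_online" not in raw.columns and "year_print" not in raw.columns:
        raise ValueError(f"required column 'year_online' or 'year_print' missing from {path}")

    report = LoadReport(n_read=len(raw))
    rows: list[dict] = []
    seen_ids: set[str] = set()
    ymin, ymax = schema.year_range

    for idx, row in raw.iterrows():
        rid = str(row.get("record_id", "")).strip()

        def reject(reason: str) -> None:
            report.rejects.append((int(idx), rid, reason))

        if not rid:
            reject("empty record_id")
            continue
        if rid in seen_ids:
            reject(f"duplicate record_id {rid!r}")
            continue

        scale = str(row["scale_type"]).strip().lower()
        if scale not in SCALE_TYPES:
            reject(f"unknown scale_type {row['scale_type']!r}")
            continue

        rec: dict = {"record_id": rid, "scale_type": scale}

        ok = True
        for col in _NUMERIC_COLUMNS:
            val = pd.to_numeric(pd.Series([row[col]]), errors="coerce").iloc[0]
            if pd.isna(val):
                reject(f"non-numeric {col} {row[col]!r}")
                ok = False
                break
            rec[col] = float(val)
        if not ok:
            continue
        for col in _INT_COLUMNS:
            val = pd.to_numeric(pd.Series([row[col]]), errors="coerce").iloc[0]
            if pd.isna(val) or float(val) != int(float(val)):
                reject(f"non-integer {col} {row[col]!r}")
                ok = False
                break
            rec[col] = int(val)
        if not ok:
            continue

        year_vals: dict[str, int] = {}
        for col in ("year_online", "year_print"):
            if col in raw.columns and str(row[col]).strip() != "":
                val = pd.to_numeric(pd.Series([row[col]]), errors="coerce").iloc[0]
                if pd.isna(val) or float(val) != int(float(val)):
                    reject(f"non-integer {col} {row[col]!r}")
                    ok = False
                    break
                year_vals[col] = int(val)
        if not ok:
            continue
        if not year_vals:
            reject("no publication year given")
            continue
        rec["year_online"] = year_vals.get("year_online", year_vals.get("year_print"))
        rec["year_print"] = year_vals.get("year_print", year_vals.get("year_online"))
        year = rec[schema.year_column]
        if not (ymin <= year <= ymax):
            reject(f"{schema.year_column}={year} outside [{ymin}, {ymax}]")
            continue

        if schema.variability == "se":
            rec["control_sd"] = rec["control_sd"] * np.sqrt(rec["control_n"])
            rec["treatment_sd"] = rec["treatment_sd"] * np.sqrt(rec["treatment_n"])

        bound = SCALE_BOUNDS.get(scale)
        if bound is not None:
            bad = next(
                (
                    c
                    for c in ("control_mean", "treatment_mean")
                    if not (0.0 <= rec[c] <= bound)
                ),
                None,
            )
            if bad is not None:
                reject(f"{bad}={rec[bad]} outside [0, {bound}] for scale {scale}")
                continue
        if rec["control_sd"] < 0 or rec["treatment_sd"] < 0:
            reject("negative SD")
            continue
        if rec["control_n"] < 2 or rec["treatment_n"] < 2:
            reject("sample size below 2")
            continue
        if rec["co2_uatm"] <= 0:
            reject(f"co2_uatm={rec['co2_uatm']} must be positive")
            continue

        flag_ok = True
        for col in FLAG_COLUMNS:
            parsed = _parse_flag(row[col]) if col in raw.columns else False
            if parsed is None:
                reject(f"unparseable boolean {col} {row[col]!r}")
                flag_ok = False
                break
            rec[col] = parsed
        if not flag_ok:
            continue

        for col in ("study_id", "species", "life_stage", "cue_type", "behaviour_metric"):
            rec[col] = str(row[col]).strip() if col in raw.columns else ""
        if not rec["study_id"]:
            rec["study_id"] = rid

        seen_ids.add(rid)
        rows.append(rec)

    corpus = pd.DataFrame(rows, columns=list(CORPUS_COLUMNS))
    corpus = corpus.astype(
        {
            "year_online": int,
            "year_print": int,
            "control_n": int,
            "treatment_n": int,
            **{c: bool for c in FLAG_COLUMNS},
        }
    ) if len(corpus) else corpus
    report.n_accepted = len(corpus)
    logger.info(
        "read_corpus(%s): %d rows read, %d accepted, %d rejected",
        path, report.n_read, report.n_accepted, report.n_rejected,
    )
    for idx, rid, reason in report.rejects:
        logger.warning("rejected row %d (record_id=%r): %s", idx, rid, reason)
    return corpus, report


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as deterministic CSV.

    Column order is the frame's own; floats use Python's shortest
    round-trip representation so ``read -> write -> read`` is lossless and
    identical inputs yield byte-identical files.
    """
    rows.to_csv(path, index=False, lineterminator="\n")


def validate_corpus(corpus: pd.DataFrame) -> None:
    """Assert corpus invariants on an in-memory frame (raises ValueError)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in corpus.columns]
    if missing:
        raise ValueError(f"corpus missing required columns: {missing}")
    if corpus["record_id"].duplicated().any():
        dupes = corpus.loc[corpus["record_id"].duplicated(), "record_id"].tolist()
        raise ValueError(f"duplicate record_ids: {dupes[:5]}")
    for scale, bound in SCALE_BOUNDS.items():
        sub = corpus[corpus["scale_type"] == scale]
        for col in ("control_mean", "treatment_mean"):
            bad = sub[(sub[col] < 0) | (sub[col] > bound)]
            if len(bad):
                raise ValueError(
                    f"{scale} {col} outside [0, {bound}] for records "
                    f"{bad['record_id'].tolist()[:5]}"
                )
    if (corpus[["control_sd", "treatment_sd"]] < 0).any().any():
        raise ValueError("negative SDs present")
    if (corpus[["control_n", "treatment_n"]] < 2).any().any():
        raise ValueError("sample sizes below 2 present")
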