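"""Peak-table and pair-database readers/writers, plus the inclusion filter.

On-disk contracts
-----------------
*Peak table* (one spectrum): CSV with mandatory ``frequency,intensity``
columns and optional ``fwhm,snr,channel`` plus record-level columns
``species,conformer,source,functional,basis`` (constant within a file);
or a JSON object mirroring the field names 1:1.  Frequencies are
written at 0.1 cm-1 precision — below experimental resolution — so
round-trips are exact.

*Pair database*: one row per experimental fundamental with columns
``species,conformer,mode_class,nu_exp,intensity_exp`` and one harmonic
column ``omega__<functional>__<basis>`` per theory level.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .errors import FormatError, ValidationError
from .records import (
    Channel,
    FrequencyPair,
    ModeClass,
    Peak,
    SpectrumRecord,
    TheoryLevel,
)

__all__ = [
    "read_peak_table",
    "write_peak_table",
    "read_pair_database",
    "write_pair_database",
    "filter_fundamentals",
]

logger = logging.getLogger(__name__)

_PEAK_COLUMNS = ("frequency", "intensity", "fwhm", "snr", "channel")
_RECORD_COLUMNS = ("species", "conformer", "source", "functional", "basis")

PathLike = Union[str, Path]


def _infer_dialect(path: Path, dialect: Optional[str]) -> str:
    if dialect is not None:
        if dialect not in ("csv", "json"):
            raise ValueError(f"dialect must be 'csv' or 'json', got {dialect!r}")
        return dialect
    return "json" if path.suffix.lower() == ".json" else "csv"


def _peak_from_row(row: dict, index: int) -> Peak:
    freq = row.get("frequency")
    inten = row.get("intensity")
    try:
        freq = float(freq)
        inten = float(inten)
    except (TypeError, ValueError) as exc:
        raise ValidationError(
            f"row {index}: non-numeric frequency/intensity ({freq!r}, {inten!r})"
        ) from exc
    if not math.isfinite(freq) or freq <= 0:
        raise ValidationError(f"row {index}: frequency must be > 0, got {freq}")
    fwhm = row.get("fwhm")
    snr = row.get("snr")
    fwhm = None if fwhm is None or (isinstance(fwhm, float) and math.isnan(fwhm)) else float(fwhm)
    snr = None if snr is None or (isinstance(snr, float) and math.isnan(snr)) else float(snr)
    channel = row.get("channel") or "loss"
    try:
        channel = Channel(channel)
    except ValueError as exc:
        raise ValidationError(f"row {index}: unknown channel {channel!r}") from exc
    try:
        return Peak(freq, inten, fwhm=fwhm, snr=snr, channel=channel)
    except ValidationError as exc:
        raise ValidationError(f"row {index}: {exc}") from exc


def read_peak_table(path: PathLike, dialect: Optional[str] = None) -> SpectrumRecord:
    """Read one spectrum from a CSV or JSON peak table.

    The dialect is inferred from the file suffix unless given.  Unknown
    columns are preserved in ``record.metadata``; peaks come back sorted
    by ascending frequency regardless of file order.
    """
    path = Path(path)
    dialect = _infer_dialect(path, dialect)

    if dialect == "json":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        rows = doc.get("peaks")
        if rows is None:
            raise FormatError(f"{path}: JSON peak table lacks a 'peaks' array")
        for key in ("frequency", "intensity"):
            for i, row in enumerate(rows):
                if key not in row:
                    raise FormatError(f"{path}: peak {i} lacks mandatory key {key!r}")
        header = {k: doc.get(k) for k in _RECORD_COLUMNS if doc.get(k) is not None}
        extra = {
            k: v
            for k, v in doc.items()
            if k not in _RECORD_COLUMNS and k != "peaks"
        }
    else:
        frame = pd.read_csv(path)
        for col in ("frequency", "intensity"):
            if col not in frame.columns:
                raise FormatError(f"{path}: missing mandatory column {col!r}")
        rows = frame.to_dict("records")
        header = {}
        for k in _RECORD_COLUMNS:
            if k in frame.columns and len(frame) and not frame[k].isna().all():
                header[k] = str(frame[k].iloc[0])
        extra = {
            k: frame[k].tolist()
            for k in frame.columns
            if k not in _PEAK_COLUMNS and k not in _RECORD_COLUMNS
        }

    peaks = [_peak_from_row(dict(row), i) for i, row in enumerate(rows)]

    theory = None
    functional, basis = header.get("functional"), header.get("basis")
    if functional and basis:
        theory = TheoryLevel(functional, basis)
    return SpectrumRecord(
        species=str(header.get("species", path.stem)),
        conformer=str(header.get("conformer", "")),
        source=str(header.get("source", "experimental")),
        theory=theory,
        peaks=tuple(peaks),
        metadata=extra,
    )


def _peak_row(peak: Peak) -> dict:
    row = {
        "frequency": round(peak.frequency, 1),
        "intensity": peak.intensity,
    }
    if peak.fwhm is not None:
        row["fwhm"] = peak.fwhm
    if peak.snr is not None:
        row["snr"] = peak.snr
    row["channel"] = peak.channel.value
    return row


def write_peak_table(
    record: SpectrumRecord, path: PathLike, dialect: Optional[str] = None
) -> None:
    """Write a spectrum so that :func:`read_peak_table` reproduces it."""
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    header: dict = {"species": record.species}
    if record.conformer:
        header["conformer"] = record.conformer
    header["source"] = record.source
    if record.theory is not None:
        header["functional"] = record.theory.functional
        header["basis"] = record.theory.basis

    # per-peak metadata (e.g. mode-class labels) rides along as extra
    # columns; anything whose length matches the peak count qualifies
    per_peak_meta = {
        key: list(val)
        for key, val in record.metadata.items()
        if isinstance(val, (list, tuple)) and len(val) == len(record.peaks)
    }

    if dialect == "json":
        doc = dict(header)
        doc.update(per_peak_meta)
        doc["peaks"] = [_peak_row(p) for p in record.peaks]
        path.write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")
        return

    rows = []
    for i, p in enumerate(record.peaks):
        row = dict(header)
        row.update(_peak_row(p))
        for key, val in per_peak_meta.items():
            row[key] = val[i]
        rows.append(row)
    columns = list(header) + [
        c for c in _PEAK_COLUMNS if any(c in r for r in rows) or not rows
    ] + list(per_peak_meta)
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, index=False)


def write_pair_database(
    pairs: Sequence[FrequencyPair],
    levels: Sequence[TheoryLevel],
    path: PathLike,
) -> None:
    """Write pairs grouped by fundamental to the database CSV dialect.

    Pairs sharing (record_key, nu_exp) are one row; each pair's theory
    level comes from ``record_key[-1]`` and fills that level's omega
    column.
    """
    rows: dict[tuple, dict] = {}
    for pair in pairs:
        species, conformer, level = _split_key(pair.record_key)
        key = (species, conformer, round(pair.nu_exp, 1))
        row = rows.setdefault(
            key,
            {
                "species": species,
                "conformer": conformer,
                "mode_class": pair.mode_class.value if pair.mode_class else "",
                "nu_exp": round(pair.nu_exp, 1),
                "intensity_exp": pair.intensity_exp,
            },
        )
        if level is None:
            raise ValidationError(
                f"pair at {pair.nu_exp} cm-1 lacks a theory level in its record_key"
            )
        row[level.column] = round(pair.omega_calc, 1)
    columns = ["species", "conformer", "mode_class", "nu_exp", "intensity_exp"]
    columns += [lvl.column for lvl in levels]
    frame = pd.DataFrame(list(rows.values()), columns=columns)
    frame.to_csv(path, index=False)


def _split_key(record_key: tuple):
    species = record_key[0] if len(record_key) > 0 else ""
    conformer = record_key[1] if len(record_key) > 1 else ""
    level = record_key[2] if len(record_key) > 2 else None
    return species, conformer, level


def read_pair_database(
    path: PathLike, levels: Optional[Sequence[TheoryLevel]] = None
) -> list[FrequencyPair]:
    """Read a fundamentals/harmonics database into frequency pairs.

    One :class:`FrequencyPair` is produced per (row, theory level).
    ``levels`` restricts which omega columns are read; by default every
    ``omega__*`` column found in the file is used.  Rows lacking a
    harmonic value for a level are excluded from that level with a
    warning, as are pairs whose nu/omega ratio falls outside the sanity
    window.
    """
    frame = pd.read_csv(path)
    for col in ("nu_exp", "intensity_exp", "mode_class"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")

    if levels is None:
        levels = [
            TheoryLevel.from_column(col)
            for col in frame.columns
            if col.startswith("omega__")
        ]
    if not levels:
        raise FormatError(f"{path}: no omega__<functional>__<basis> columns found")

    pairs: list[FrequencyPair] = []
    for level in levels:
        col = level.column
        if col not in frame.columns:
            raise FormatError(f"{path}: missing column {col!r}")
        n_missing = 0
        for idx, row in frame.iterrows():
            omega = row[col]
            if pd.isna(omega):
                n_missing += 1
                continue
            mode = row["mode_class"]
            mode_class = ModeClass(mode) if isinstance(mode, str) and mode else None
            pair = FrequencyPair(
                nu_exp=float(row["nu_exp"]),
                omega_calc=float(omega),
                intensity_exp=float(row["intensity_exp"]),
                mode_class=mode_class,
                record_key=(
                    str(row.get("species", "")),
                    str(row.get("conformer", "")),
                    level,
                ),
            )
            if not pair.ratio_in_window():
                logger.warning(
                    "row %d: nu/omega = %.3f outside sanity window at %s",
                    idx,
                    pair.ratio,
                    level,
                )
            pairs.append(pair)
        if n_missing:
            logger.warning(
                "%s: %d rows lack a harmonic frequency at %s and were excluded",
                path,
                n_missing,
                level,
            )
    return pairs


def filter_fundamentals(
    record: SpectrumRecord, snr_min: float = 2.5, fwhm_min: float = 4.0
) -> SpectrumRecord:
    """Keep only distinct fundamental bands.

    A peak survives when ``snr > snr_min`` *and* ``fwhm > fwhm_min``
    (strict inequalities), which excludes noise spikes and spurious
    narrow features.  Peaks lacking either metadata field pass
    unchanged but are tallied in the log, since curated peak lists may
    omit the quality columns.
    """
    kept, removed, unjudged = [], 0, 0
    for peak in record.peaks:
        if peak.snr is None or peak.fwhm is None:
            unjudged += 1
            kept.append(peak)
        elif peak.snr > snr_min and peak.fwhm > fwhm_min:
            kept.append(peak)
        else:
            removed += 1
    if removed or unjudged:
        logger.info(
            "filter_fundamentals(%s/%s): removed %d peaks, passed %d without "
            "snr/fwhm metadata",
            record.species,
            record.conformer,
            removed,
            unjudged,
        )
    return record.with_peaks(kept)
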