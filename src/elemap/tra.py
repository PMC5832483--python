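"""Reading, writing and stitching of time-resolved-analysis (TRA) tables.

ICPMS instruments export raster runs as delimited text: one elapsed-time
column plus one column per monitored isotope (intensities in counts per
second).  The column layout differs per vendor, so parsing is driven by an
explicit :class:`TRADialect`.  Long acquisitions are often split across
several files; :func:`stitch` recombines them into one continuous series.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, MonotonicityError, SchemaError, StitchingError

_TIME_FACTORS = {"s": 1.0, "ms": 1e-3, "min": 60.0}


@dataclass(frozen=True)
class TRADialect:
    """Description of a delimited TRA file layout.

    Parameters
    ----------
    delimiter : single character separating fields.
    n_header_rows : rows before the first data row.  When ≥ 1 the first row
        carries column names (extra header rows, e.g. a units line, are
        skipped); when 0, columns are addressed by integer position.
    time_column : name or 0-based position of the elapsed-time column.
    time_unit : unit of the time column, one of ``s``, ``ms``, ``min``.
    isotope_columns : ordered ``(column, isotope_label)`` pairs.  ``None``
        means "every column except the time column", labelled by its header
        name (requires ``n_header_rows ≥ 1``).
    decimal_mark : decimal separator used in numbers.
    """

    delimiter: str = ","
    n_header_rows: int = 1
    time_column: int | str = 0
    time_unit: str = "s"
    isotope_columns: tuple[tuple[int | str, str], ...] | None = None
    decimal_mark: str = "."

    def __post_init__(self) -> None:
        if len(self.delimiter) != 1:
            raise SchemaError("delimiter must be a single character")
        if self.n_header_rows < 0:
            raise SchemaError("n_header_rows must be >= 0")
        if self.time_unit not in _TIME_FACTORS:
            raise SchemaError(f"time_unit must be one of {sorted(_TIME_FACTORS)}")
        if self.isotope_columns is not None:
            cols = [c for c, _ in self.isotope_columns]
            labels = [lab for _, lab in self.isotope_columns]
            if self.time_column in cols:
                raise SchemaError("time_column must not appear in isotope_columns")
            if len(set(labels)) != len(labels):
                raise SchemaError("isotope labels must be unique")
        if isinstance(self.time_column, int) and self.n_header_rows == 0:
            pass  # positional addressing is the only option without headers
        if self.isotope_columns is None and self.n_header_rows == 0:
            raise SchemaError(
                "isotope_columns must be given explicitly when the file has no header row"
            )


DEFAULT_DIALECT = TRADialect()


@dataclass
class TRASeries:
    """A time-ordered multi-isotope signal record.

    ``times`` are seconds (strictly increasing), ``intensities`` is an
    ``[n_readings, n_isotopes]`` array in CPS, and ``source_files`` holds a
    per-reading integer file id so multi-file provenance survives stitching.
    """

    times: np.ndarray
    intensities: np.ndarray
    isotope_labels: list[str]
    source_files: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise SchemaError("intensities must be a 2-D array [n_readings, n_isotopes]")
        n, k = self.intensities.shape
        if k != len(self.isotope_labels):
            raise SchemaError("isotope_labels length must match intensity columns")
        if k < 1:
            raise SchemaError("a TRA series needs at least one isotope (n_isotopes >= 1)")
        if n < 2:
            raise SchemaError("a TRA series needs at least two readings")
        if self.times.shape != (n,):
            raise SchemaError("times length must match number of readings")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.intensities)):
            raise SchemaError("times and intensities must be finite")
        diffs = np.diff(self.times)
        bad = np.nonzero(diffs <= 0)[0]
        if bad.size:
            raise MonotonicityError(
                f"times must be strictly increasing; first violation at reading {bad[0] + 1}"
            )
        if self.source_files is None:
            self.source_files = np.zeros(n, dtype=int)
        else:
            self.source_files = np.asarray(self.source_files, dtype=int)
            if self.source_files.shape != (n,):
                raise SchemaError("source_files length must match number of readings")

    @property
    def n_readings(self) -> int:
        return self.times.size

    @property
    def n_isotopes(self) -> int:
        return len(self.isotope_labels)

    @property
    def reading_interval(self) -> float:
        """Median of successive time differences, in seconds — robust to the
        occasional dropped reading."""
        return float(np.median(np.diff(self.times)))

    def column(self, label: str) -> np.ndarray:
        try:
            j = self.isotope_labels.index(label)
        except ValueError:
            raise SchemaError(f"isotope {label!r} not in series") from None
        return self.intensities[:, j]


def _resolve_column(df: pd.DataFrame, col: int | str, *, what: str) -> pd.Series:
    if isinstance(col, int):
        if col >= df.shape[1]:
            raise FormatError(f"{what} column index {col} out of range (file has {df.shape[1]} columns)")
        return df.iloc[:, col]
    if col not in df.columns:
        raise FormatError(f"{what} column {col!r} not found; file columns: {list(df.columns)}")
    return df[col]


def read_tra(path: str | Path, dialect: TRADialect = DEFAULT_DIALECT) -> TRASeries:
    """Parse one delimited TRA file into a :class:`TRASeries`.

    Times are converted to seconds.  Rows with non-numeric intensity cells
    are rejected with a row-indexed :class:`FormatError`; non-monotone time
    raises :class:`MonotonicityError` naming the first offending reading.
    """
    path = Path(path)
    read_kwargs: dict = dict(
        sep=dialect.delimiter,
        decimal=dialect.decimal_mark,
        dtype=str,
        skipinitialspace=True,
        skip_blank_lines=False,
    )
    if dialect.n_header_rows == 0:
        df = pd.read_csv(path, header=None, **read_kwargs)
    else:
        # First row carries names; any additional header rows (units etc.)
        # are skipped.
        df = pd.read_csv(
            path,
            header=0,
            skiprows=range(1, dialect.n_header_rows),
            **read_kwargs,
        )
        df.columns = [str(c).strip() for c in df.columns]
    df = df.dropna(how="all")

    time_raw = _resolve_column(df, dialect.time_column, what="time")
    if dialect.isotope_columns is not None:
        pairs = list(dialect.isotope_columns)
        iso_raw = [_resolve_column(df, c, what=f"isotope {lab!r}") for c, lab in pairs]
        labels = [lab for _, lab in pairs]
    else:
        labels, iso_raw = [], []
        for c in df.columns:
            if c == dialect.time_column:
                continue
            labels.append(str(c))
            iso_raw.append(df[c])
    if not labels:
        raise FormatError(f"{path}: no isotope columns found")

    def _numeric(s: pd.Series, what: str) -> np.ndarray:
        if dialect.decimal_mark != ".":
            s = s.str.replace(dialect.decimal_mark, ".", regex=False)
        try:
            # exact strtod conversion (pd.to_numeric's fast path is lossy)
            arr = s.to_numpy(dtype=float)
            nan_rows = np.nonzero(np.isnan(arr))[0]
            if nan_rows.size:
                rows = ", ".join(str(i) for i in nan_rows[:5])
                raise FormatError(
                    f"{path}: missing {what} value at data row(s) {rows}"
                    + ("..." if nan_rows.size > 5 else "")
                )
            return arr
        except (ValueError, TypeError):
            coerced = pd.to_numeric(s, errors="coerce")
            bad = np.nonzero(coerced.isna().to_numpy())[0]
            rows = ", ".join(str(i) for i in bad[:5])
            raise FormatError(
                f"{path}: non-numeric {what} value at data row(s) {rows}"
                + ("..." if bad.size > 5 else "")
            ) from None

    times = _numeric(time_raw.astype(str), "time") * _TIME_FACTORS[dialect.time_unit]
    intensities = np.column_stack(
        [_numeric(col.astype(str), f"intensity ({lab})") for col, lab in zip(iso_raw, labels)]
    )
    return TRASeries(times=times, intensities=intensities, isotope_labels=labels)


def stitch(
    series_list: Sequence[TRASeries],
    offsets: Sequence[float] | None = None,
) -> TRASeries:
    """Concatenate per-file series into one continuous record.

    All series must share identical isotope labels in identical order.  With
    ``offsets`` omitted: if the concatenated time axis is already globally
    monotone the files are joined as-is; otherwise each file is shifted so it
    starts one reading interval after the previous file's last time.  Explicit
    per-file ``offsets`` (seconds, added to each file's times) override this;
    if they yield a non-monotone axis a :class:`StitchingError` is raised.
    """
    if not series_list:
        raise SchemaError("stitch needs at least one series")
    first = series_list[0]
    for s in series_list[1:]:
        if s.isotope_labels != first.isotope_labels:
            raise SchemaError(
                "cannot stitch: isotope labels differ "
                f"({s.isotope_labels} vs {first.isotope_labels})"
            )
    if len(series_list) == 1 and offsets is None:
        return replace(first)

    if offsets is not None:
        if len(offsets) != len(series_list):
            raise SchemaError("offsets must have one entry per series")
        times = np.concatenate([s.times + off for s, off in zip(series_list, offsets)])
        if np.any(np.diff(times) <= 0):
            raise StitchingError("supplied offsets produce a non-monotone time axis")
    else:
        raw = np.concatenate([s.times for s in series_list])
        if np.all(np.diff(raw) > 0):
            times = raw
        else:
            shifted = [series_list[0].times]
            for s in series_list[1:]:
                start = shifted[-1][-1] + series_list[0].reading_interval
                shifted.append(s.times - s.times[0] + start)
            times = np.concatenate(shifted)
            if np.any(np.diff(times) <= 0):
                raise StitchingError("cumulative offsets produce a non-monotone time axis")

    intensities = np.vstack([s.intensities for s in series_list])
    source = np.concatenate(
        [np.full(s.n_readings, i, dtype=int) for i, s in enumerate(series_list)]
    )
    return TRASeries(
        times=times,
        intensities=intensities,
        isotope_labels=list(first.isotope_labels),
        source_files=source,
    )


def write_tra(series: TRASeries, path: str | Path, dialect: TRADialect = DEFAULT_DIALECT) -> None:
    """Write a series as a delimited TRA file readable with the same dialect.

    The round trip ``read_tra(write_tra(s))`` reproduces times and
    intensities to better than 6 significant digits.
    """
    path = Path(path)
    n_iso = series.n_isotopes
    if n_iso < 1:
        raise SchemaError("cannot write a series with no isotopes")

    # Resolve positional layout: time + isotope columns must tile 0..n.
    if isinstance(dialect.time_column, int):
        iso_cols = (
            [c for c, _ in dialect.isotope_columns]
            if dialect.isotope_columns is not None
            else list(range(1, n_iso + 1)) if dialect.time_column == 0 else None
        )
        if iso_cols is None or any(not isinstance(c, int) for c in iso_cols):
            raise SchemaError("mixed name/position columns are not supported for writing")
        positions = [dialect.time_column] + list(iso_cols)
        if sorted(positions) != list(range(len(positions))):
            raise SchemaError("time/isotope column indices must tile 0..n for writing")
        order = np.argsort(positions)
        names = ["Time [" + dialect.time_unit + "]"] + list(series.isotope_labels)
    else:
        order = np.arange(n_iso + 1)
        names = [str(dialect.time_column)] + [
            str(c) for c, _ in dialect.isotope_columns
        ] if dialect.isotope_columns is not None else [str(dialect.time_column)] + list(
            series.isotope_labels
        )

    times_out = series.times / _TIME_FACTORS[dialect.time_unit]
    cols = [times_out] + [series.intensities[:, j] for j in range(n_iso)]
    cols = [cols[i] for i in order]
    names = [names[i] for i in order]

    def _fmt(x: float) -> str:
        s = format(x, ".17g")
        if dialect.decimal_mark != ".":
            s = s.replace(".", dialect.decimal_mark)
        return s

    lines: list[str] = []
    if dialect.n_header_rows >= 1:
        lines.append(dialect.delimiter.join(names))
        for _ in range(dialect.n_header_rows - 1):
            lines.append(dialect.delimiter.join([""] * len(names)))
    for i in range(series.n_readings):
        lines.append(dialect.delimiter.join(_fmt(c[i]) for c in cols))
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"failed to write TRA file {path}: {exc}") from exc
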