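"""Readers, writers and core containers for spectra and cohort tables.

Spectra travel either as a wide CSV matrix (header row of wavenumbers, first
column of sample ids) or as single-spectrum JCAMP-DX 4.24 files, the usual
exchange format for dispersive/FT-IR instruments.  Cohort tables are plain
delimited files whose columns are the clinical covariates recorded for each
patient plus the 6-month outcome.

Wavenumber grids are stored ascending internally regardless of the order on
disk; spectroscopists plot descending, but a single indexing convention keeps
every downstream slice unambiguous.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Stage",
    "Spectrum",
    "SpectraSet",
    "CohortTable",
    "FormatError",
    "ParseError",
    "ValidationError",
    "UnsupportedUnitError",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_jcampdx",
    "read_cohort_table",
    "write_cohort_table",
    "COHORT_COLUMNS",
]


class FormatError(ValueError):
    """The file is structurally not what the reader expects."""


class ParseError(ValueError):
    """A cell/record could not be converted to its declared type."""


class ValidationError(ValueError):
    """Values parsed fine but violate a domain contract."""


class UnsupportedUnitError(FormatError):
    """JCAMP-DX x-axis units other than wavenumbers (1/CM)."""


class Stage(str, Enum):
    """Position of a spectrum in the preprocessing chain."""

    RAW = "raw"
    GAP_REPLACED = "gap_replaced"
    DERIVATIVE = "derivative"
    NORMALIZED = "normalized"


def _as_float_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be 1-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass
class Spectrum:
    """A single sample's absorbance trace on a wavenumber grid (cm^-1).

    The grid must be strictly monotonic; descending input is flipped so the
    stored order is always ascending.
    """

    sample_id: str
    wavenumbers: np.ndarray
    absorbance: np.ndarray
    stage: Stage = Stage.RAW

    def __post_init__(self) -> None:
        wn = _as_float_vector(self.wavenumbers, "wavenumbers")
        ab = _as_float_vector(self.absorbance, "absorbance")
        if wn.size != ab.size:
            raise ValidationError(
                f"wavenumbers ({wn.size}) and absorbance ({ab.size}) lengths differ"
            )
        if wn.size >= 2:
            d = np.diff(wn)
            if np.all(d < 0):
                wn, ab = wn[::-1], ab[::-1]
            elif not np.all(d > 0):
                raise ValidationError("wavenumbers must be strictly monotonic")
        self.wavenumbers = wn
        self.absorbance = ab
        self.stage = Stage(self.stage)

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_values(
        self,
        wavenumbers: np.ndarray,
        absorbance: np.ndarray,
        stage: Optional[Stage] = None,
    ) -> "Spectrum":
        return Spectrum(
            sample_id=self.sample_id,
            wavenumbers=wavenumbers,
            absorbance=absorbance,
            stage=self.stage if stage is None else stage,
        )


@dataclass
class SpectraSet:
    """Aligned spectral matrix: rows are samples, columns are wavenumbers."""

    sample_ids: list
    grid: np.ndarray
    matrix: np.ndarray
    labels: Optional[np.ndarray] = None
    stage: Stage = Stage.RAW

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        grid = _as_float_vector(self.grid, "grid")
        M = np.asarray(self.matrix, dtype=float)
        if M.ndim != 2:
            raise ValidationError("matrix must be 2-dimensional")
        if not np.all(np.isfinite(M)):
            raise ValidationError("matrix contains non-finite values")
        if M.shape != (len(self.sample_ids), grid.size):
            raise ValidationError(
                f"matrix shape {M.shape} does not match "
                f"{len(self.sample_ids)} samples x {grid.size} wavenumbers"
            )
        if grid.size >= 2:
            d = np.diff(grid)
            if np.all(d < 0):
                grid, M = grid[::-1], M[:, ::-1]
            elif not np.all(d > 0):
                raise ValidationError("grid must be strictly monotonic")
        self.grid = grid
        self.matrix = np.ascontiguousarray(M)
        if self.labels is not None:
            lab = np.asarray(self.labels)
            if lab.shape != (len(self.sample_ids),):
                raise ValidationError("labels length does not match samples")
            if not np.isin(lab, [0, 1]).all():
                raise ValidationError("labels must be 0 (alive) or 1 (deceased)")
            self.labels = lab.astype(int)
        self.stage = Stage(self.stage)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_wavenumbers(self) -> int:
        return self.grid.size

    def spectra(self) -> Iterator[Spectrum]:
        for i, sid in enumerate(self.sample_ids):
            yield Spectrum(sid, self.grid, self.matrix[i], stage=self.stage)

    def column_indices(self, wavenumbers: Sequence[float], tol: float = 1e-6) -> np.ndarray:
        """Indices of the columns closest to *wavenumbers* (must match within tol)."""
        idx = np.searchsorted(self.grid, wavenumbers)
        idx = np.clip(idx, 0, self.grid.size - 1)
        # the insertion point may sit one to the right of the nearest grid value
        left = np.clip(idx - 1, 0, self.grid.size - 1)
        idx = np.where(
            np.abs(self.grid[left] - wavenumbers) < np.abs(self.grid[idx] - wavenumbers),
            left,
            idx,
        )
        off = np.abs(self.grid[idx] - np.asarray(wavenumbers, dtype=float))
        if np.any(off > tol):
            bad = np.asarray(wavenumbers)[off > tol]
            raise ValidationError(f"wavenumbers not on grid: {bad.tolist()}")
        return idx

    def select_wavenumbers(self, wavenumbers: Sequence[float]) -> np.ndarray:
        """Sub-matrix of the columns at the given wavenumbers."""
        return self.matrix[:, self.column_indices(wavenumbers)]


# ---------------------------------------------------------------------------
# spectra CSV

def _detect_delimiter(first_line: str) -> str:
    return ";" if first_line.count(";") > first_line.count(",") else ","


def read_spectra_csv(path) -> SpectraSet:
    """Read a wide spectra matrix: header row of wavenumbers, first column ids.

    Comma or semicolon delimited (auto-detected); descending wavenumber headers
    are reordered to the internal ascending convention.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if len(lines) < 2:
        raise FormatError(f"{path}: need a header row and at least one sample row")
    delim = _detect_delimiter(lines[0])
    rows = list(csv.reader(lines, delimiter=delim))
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise FormatError(
                f"{path}: ragged rows (row {i + 1} has {len(row)} fields, expected {width})"
            )
    header = rows[0]
    try:
        grid = np.array([float(v) for v in header[1:]], dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric wavenumber in header: {exc}") from exc
    ids, values = [], []
    for i, row in enumerate(rows[1:], start=2):
        ids.append(row[0])
        try:
            values.append([float(v) for v in row[1:]])
        except ValueError:
            bad = next(j for j, v in enumerate(row[1:], start=2) if not _is_float(v))
            raise ParseError(f"{path}: non-numeric cell at row {i}, column {bad}")
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise FormatError(f"{path}: duplicate sample ids: {dupes}")
    return SpectraSet(sample_ids=ids, grid=grid, matrix=np.array(values, dtype=float))


def _is_float(v: str) -> bool:
    try:
        float(v)
        return True
    except ValueError:
        return False


def write_spectra_csv(path, spectra: SpectraSet, delimiter: str = ",") -> None:
    """Write the matrix with full round-trip precision (17 significant digits)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["sample_id"] + [_fmt(v) for v in spectra.grid])
        for sid, row in zip(spectra.sample_ids, spectra.matrix):
            w.writerow([sid] + [_fmt(v) for v in row])


def _fmt(v: float) -> str:
    return format(float(v), ".17g")


# ---------------------------------------------------------------------------
# JCAMP-DX

def read_jcampdx(path) -> Spectrum:
    """Read a single-spectrum JCAMP-DX 4.24 file (AFFN tables only).

    Supports ``##XYDATA=(X++(Y..Y))`` with x reconstructed from FIRSTX/DELTAX
    and y scaled by YFACTOR, and ``##XYPOINTS=(XY..XY)`` pair tables.
    Compressed (SQZ/DIF) ordinates are not supported.  X units must be 1/CM.
    """
    path = Path(path)
    records: dict = {}
    data_label = None
    data_lines: list = []
    for raw in path.read_text().splitlines():
        line = raw.split("$$")[0].rstrip()
        if not line.strip():
            continue
        if line.startswith("##"):
            label, _, value = line[2:].partition("=")
            label = label.strip().upper().replace(" ", "")
            value = value.strip()
            if label in ("XYDATA", "XYPOINTS"):
                data_label = label
                records[label] = value
                data_lines = []
                records["_data"] = data_lines
            elif label == "END":
                data_label = None
            else:
                records[label] = value
                data_label = None
        elif data_label is not None:
            data_lines.append(line)

    if "XUNITS" not in records:
        raise FormatError(f"{path}: missing required ##XUNITS record")
    xunits = records["XUNITS"].upper().replace(" ", "")
    if xunits not in ("1/CM", "1/CM."):
        raise UnsupportedUnitError(f"{path}: unsupported XUNITS {records['XUNITS']!r}")
    title = records.get("TITLE", path.stem) or path.stem

    if "XYDATA" in records:
        for key in ("FIRSTX", "DELTAX", "NPOINTS"):
            if key not in records:
                raise FormatError(f"{path}: ##XYDATA requires ##{key}")
        firstx = float(records["FIRSTX"])
        deltax = float(records["DELTAX"])
        npoints = int(float(records["NPOINTS"]))
        yfactor = float(records.get("YFACTOR", 1.0))
        ys: list = []
        for line in records["_data"]:
            parts = line.replace(",", " ").split()
            if not parts:
                continue
            try:
                nums = [float(p) for p in parts]
            except ValueError as exc:
                raise ParseError(f"{path}: non-numeric ordinate: {exc}") from exc
            ys.extend(nums[1:])  # first number on each line is the abscissa check value
        if len(ys) != npoints:
            raise FormatError(f"{path}: expected {npoints} ordinates, found {len(ys)}")
        x = firstx + deltax * np.arange(npoints)
        y = np.asarray(ys, dtype=float) * yfactor
    elif "XYPOINTS" in records:
        pairs: list = []
        for line in records["_data"]:
            parts = line.replace(";", " ").replace(",", " ").split()
            try:
                pairs.extend(float(p) for p in parts)
            except ValueError as exc:
                raise ParseError(f"{path}: non-numeric value: {exc}") from exc
        if len(pairs) % 2:
            raise FormatError(f"{path}: odd number of values in ##XYPOINTS")
        arr = np.asarray(pairs, dtype=float).reshape(-1, 2)
        x, y = arr[:, 0], arr[:, 1] * float(records.get("YFACTOR", 1.0))
    else:
        raise FormatError(f"{path}: no ##XYDATA or ##XYPOINTS table found")

    return Spectrum(sample_id=title, wavenumbers=x, absorbance=y, stage=Stage.RAW)


# ---------------------------------------------------------------------------
# cohort table

#: canonical clinical columns (Table-style cohort description, units fixed)
COHORT_COLUMNS = [
    "age",                # years
    "sex",                # "M"/"F"
    "creatinine",         # µmol/L
    "albumin",            # g/L
    "bilirubin",          # µmol/L
    "prothrombin_ratio",  # %
    "inr",
    "sodium",             # mmol/L
    "ast",                # IU/L
    "alt",                # IU/L
    "ggt",                # IU/L
    "alp",                # IU/L
    "crp",                # mg/L
    "beta_blockers",      # bool
    "meld",               # [6, 40]
    "child_pugh",         # [5, 15]
]

_ALIASES = {
    "child-pugh": "child_pugh",
    "childpugh": "child_pugh",
    "prothrombin": "prothrombin_ratio",
    "na": "sodium",
}


@dataclass
class CohortTable:
    """Clinical covariates per sample, plus the 6-month outcome when known.

    ``frame`` holds one row per sample; unknown columns are carried through
    untouched and listed by :attr:`extras`.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        df.columns = [
            _ALIASES.get(str(c).strip().lower(), str(c).strip().lower()) for c in df.columns
        ]
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"cohort table missing columns: {missing}")
        numeric = [c for c in COHORT_COLUMNS if c not in ("sex", "beta_blockers")]
        for col in numeric + (["outcome"] if "outcome" in df.columns else []):
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise ParseError(f"column {col!r} is not numeric: {exc}") from exc
        if (df["meld"].lt(6) | df["meld"].gt(40)).any():
            raise ValidationError("MELD values outside [6, 40]")
        if (df["child_pugh"].lt(5) | df["child_pugh"].gt(15)).any():
            raise ValidationError("Child-Pugh values outside [5, 15]")
        if "outcome" in df.columns and not df["outcome"].isin([0, 1]).all():
            raise ValidationError("outcome must be 0 (alive) or 1 (deceased)")
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def extras(self) -> list:
        known = set(COHORT_COLUMNS) | {"sample_id", "outcome"}
        return [c for c in self.frame.columns if c not in known]

    @property
    def outcome(self) -> Optional[np.ndarray]:
        if "outcome" not in self.frame.columns:
            return None
        return self.frame["outcome"].to_numpy(dtype=int)


def read_cohort_table(path, require_outcome: bool = True) -> CohortTable:
    """Read a delimited cohort table (comma or semicolon, auto-detected)."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    table = CohortTable(pd.read_csv(path, sep=_detect_delimiter(first)))
    if require_outcome and "outcome" not in table.frame.columns:
        raise ValidationError(f"{path}: outcome column required but absent")
    return table


def write_cohort_table(path, table: CohortTable, delimiter: str = ",") -> None:
    table.frame.to_csv(Path(path), sep=delimiter, index=False)
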