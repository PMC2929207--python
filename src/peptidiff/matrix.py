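"""Peak lists, reference-peak recalibration, and the analysis matrix.

The analysis matrix is the central container of the pipeline: a peaks x
samples table of peak intensities at aligned consensus m/z positions, with
one group label per sample column.  Cells are ``NaN`` where a sample did
not detect the peak ("absent", deliberately distinct from zero intensity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, ConfigurationError, MatrixParseError

MZ_DUPLICATE_TOL = 1e-6  # u; peaks closer than this are considered duplicates


@dataclass(frozen=True)
class PeakList:
    """One sample's centroided peak list (m/z, intensity, optional S/N).

    Peaks are sorted ascending by m/z on construction; duplicate m/z values
    (within 1e-6 u) are rejected.
    """

    sample_id: str
    mz: np.ndarray
    intensity: np.ndarray
    sn: np.ndarray | None = None

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if mz.shape != intensity.shape or mz.ndim != 1:
            raise ConfigurationError("peaks: mz and intensity must be equal-length 1-D")
        if np.any(mz <= 0):
            raise ConfigurationError("mz: all values must be positive")
        if np.any(intensity < 0):
            raise ConfigurationError("intensity: all values must be non-negative")
        order = np.argsort(mz, kind="stable")
        mz = mz[order]
        intensity = intensity[order]
        sn = self.sn
        if sn is not None:
            sn = np.asarray(sn, dtype=float)[order]
            if np.any(sn[np.isfinite(sn)] < 0):
                raise ConfigurationError("sn: values must be non-negative")
        if mz.size > 1 and np.any(np.diff(mz) < MZ_DUPLICATE_TOL):
            raise ConfigurationError("mz: duplicate peaks within 1e-6 u")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)
        object.__setattr__(self, "sn", sn)

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


def read_peaklist(path, sample_id: str | None = None) -> PeakList:
    """Read a delimited peak list (columns mz, intensity[, sn]; header optional)."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    # Drop a header row if the first cell is not numeric.
    try:
        float(df.iloc[0, 0])
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    df = df.apply(pd.to_numeric)
    sn = df.iloc[:, 2].to_numpy() if df.shape[1] >= 3 else None
    return PeakList(
        sample_id=sample_id or path.stem,
        mz=df.iloc[:, 0].to_numpy(),
        intensity=df.iloc[:, 1].to_numpy(),
        sn=sn,
    )


def write_peaklist(pl: PeakList, path) -> None:
    """Write a peak list as tab-separated mz, intensity[, sn] with header."""
    cols = {"mz": pl.mz, "intensity": pl.intensity}
    if pl.sn is not None:
        cols["sn"] = pl.sn
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class CalibrationModel:
    """Linear m/z recalibration fitted to reference (calibrant) peaks.

    ``corrected = slope * observed + intercept``.  ``residuals_ppm`` are the
    post-calibration errors at the matched references.
    """

    slope: float
    intercept: float
    n_refs_matched: int
    residuals_ppm: tuple[float, ...]

    def apply(self, mz: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(mz, dtype=float) + self.intercept


def calibrate_peaklist(
    pl: PeakList,
    reference_mzs: Sequence[float],
    match_tol_ppm: float = 20.0,
) -> tuple[PeakList, CalibrationModel]:
    """Recalibrate a peak list against known reference peptide masses.

    For each reference mass the nearest observed peak is taken; pairs within
    ``match_tol_ppm`` enter an ordinary least-squares fit of reference on
    observed m/z (slope + intercept).  All peak m/z values are transformed
    by the fitted model.

    Raises
    ------
    CalibrationError
        If fewer than two references match; carries the match count.
    """
    if match_tol_ppm <= 0:
        raise ConfigurationError("match_tol_ppm: must be positive")
    refs = np.sort(np.asarray(reference_mzs, dtype=float))
    observed = []
    target = []
    for ref in refs:
        if pl.n_peaks == 0:
            break
        idx = int(np.argmin(np.abs(pl.mz - ref)))
        err_ppm = 1e6 * (pl.mz[idx] - ref) / ref
        if abs(err_ppm) <= match_tol_ppm:
            observed.append(pl.mz[idx])
            target.append(ref)
    n = len(observed)
    if n < 2:
        raise CalibrationError(
            f"only {n} of {len(refs)} reference peaks matched within "
            f"{match_tol_ppm} ppm for sample {pl.sample_id!r}",
            n_matched=n,
        )
    obs = np.asarray(observed)
    tgt = np.asarray(target)
    slope, intercept = np.polyfit(obs, tgt, 1)
    corrected_refs = slope * obs + intercept
    residuals = tuple(1e6 * (corrected_refs - tgt) / tgt)
    model = CalibrationModel(
        slope=float(slope),
        intercept=float(intercept),
        n_refs_matched=n,
        residuals_ppm=residuals,
    )
    calibrated = PeakList(
        sample_id=pl.sample_id,
        mz=model.apply(pl.mz),
        intensity=pl.intensity.copy(),
        sn=None if pl.sn is None else pl.sn.copy(),
    )
    return calibrated, model


@dataclass
class AnalysisMatrix:
    """Peaks x samples intensity matrix with group labels.

    ``intensities`` is indexed by consensus m/z (strictly ascending floats)
    with one column per sample; absent cells are ``NaN``.  ``groups`` maps
    every sample id to exactly one group label.
    """

    intensities: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        mzs = self.intensities.index.to_numpy(dtype=float)
        if mzs.size > 1 and np.any(np.diff(mzs) <= 0):
            raise ConfigurationError("peak_mzs: must be strictly ascending")
        missing = [s for s in self.intensities.columns if s not in self.groups]
        if missing:
            raise ConfigurationError(f"groups: no label for sample(s) {missing}")

    @property
    def peak_mzs(self) -> np.ndarray:
        return self.intensities.index.to_numpy(dtype=float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_peaks(self) -> int:
        return int(self.intensities.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.intensities.shape[1])

    def group_samples(self, label: str) -> list[str]:
        return [s for s in self.intensities.columns if self.groups[s] == label]

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for s in self.intensities.columns:
            sizes[self.groups[s]] = sizes.get(self.groups[s], 0) + 1
        return sizes

    def subset_samples(self, sample_ids: Iterable[str]) -> "AnalysisMatrix":
        ids = [s for s in self.intensities.columns if s in set(sample_ids)]
        return AnalysisMatrix(
            intensities=self.intensities[ids].copy(),
            groups={s: self.groups[s] for s in ids},
        )


def build_matrix(
    peaklists: Sequence[PeakList],
    cluster_tol_ppm: float = 5.0,
    groups: Mapping[str, str] | None = None,
) -> AnalysisMatrix:
    """Align peaks across samples into an analysis matrix.

    All peaks are pooled, sorted by m/z, and clustered by single linkage
    with a relative gap threshold: a new cluster starts wherever the gap to
    the previous peak exceeds ``cluster_tol_ppm``.  Each cluster becomes a
    matrix row with consensus m/z equal to the intensity-weighted mean of
    its member peaks.  A sample contributes at most one peak per cluster
    (the most intense wins, with a warning); samples contributing no peak
    get an absent (NaN) cell.
    """
    if groups is None:
        raise ConfigurationError("groups: a sample -> group mapping is required")
    if len(peaklists) < 2:
        raise ConfigurationError("peaklists: need at least two samples")
    if cluster_tol_ppm <= 0:
        raise ConfigurationError("cluster_tol_ppm: must be positive")
    sample_ids = [pl.sample_id for pl in peaklists]
    if len(set(sample_ids)) != len(sample_ids):
        raise ConfigurationError("peaklists: duplicate sample ids")
    for sid in sample_ids:
        if sid not in groups:
            raise ConfigurationError(f"groups: sample {sid!r} has no group label")

    mz = np.concatenate([pl.mz for pl in peaklists])
    intensity = np.concatenate([pl.intensity for pl in peaklists])
    sample_idx = np.concatenate(
        [np.full(pl.n_peaks, i) for i, pl in enumerate(peaklists)]
    ).astype(int)
    order = np.argsort(mz, kind="stable")
    mz, intensity, sample_idx = mz[order], intensity[order], sample_idx[order]

    # Single-linkage clustering on the sorted axis: split at large gaps.
    if mz.size == 0:
        table = pd.DataFrame(np.empty((0, len(sample_ids))), columns=sample_ids)
        return AnalysisMatrix(table, dict(groups))
    gaps_ppm = 1e6 * np.diff(mz) / mz[:-1]
    breaks = np.flatnonzero(gaps_ppm > cluster_tol_ppm) + 1
    cluster_bounds = np.concatenate([[0], breaks, [mz.size]])

    consensus: list[float] = []
    rows: list[np.ndarray] = []
    for lo, hi in zip(cluster_bounds[:-1], cluster_bounds[1:]):
        c_mz, c_int, c_smp = mz[lo:hi], intensity[lo:hi], sample_idx[lo:hi]
        weights = np.where(c_int > 0, c_int, 1.0)  # all-zero cluster: plain mean
        consensus.append(float(np.average(c_mz, weights=weights)))
        row = np.full(len(sample_ids), np.nan)
        for m, it, s in zip(c_mz, c_int, c_smp):
            if not np.isnan(row[s]):
                warnings.warn(
                    f"sample {sample_ids[s]!r}: two peaks in one cluster near "
                    f"{m:.4f} u; keeping the more intense",
                    stacklevel=2,
                )
                row[s] = max(row[s], it)
            else:
                row[s] = it
        rows.append(row)

    table = pd.DataFrame(rows, index=pd.Index(consensus, name="m/z"), columns=sample_ids)
    return AnalysisMatrix(table, {s: groups[s] for s in sample_ids})


def read_groups(path) -> dict[str, str]:
    """Read a two-column sample sheet (sample_id, group); header optional."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    first = str(df.iloc[0, 0]).strip().lower()
    if first in {"sample", "sample_id", "id"}:
        df = df.iloc[1:]
    out: dict[str, str] = {}
    for _, row in df.iterrows():
        sid, grp = str(row.iloc[0]).strip(), str(row.iloc[1]).strip()
        if sid in out:
            raise MatrixParseError(f"duplicate sample id {sid!r} in sample sheet", row=sid)
        out[sid] = grp
    return out


def write_groups(groups: Mapping[str, str], path) -> None:
    pd.DataFrame(
        {"sample_id": list(groups), "group": [groups[s] for s in groups]}
    ).to_csv(path, sep="\t", index=False)


def write_matrix(matrix: AnalysisMatrix, path, dialect: str | None = None) -> None:
    """Write the matrix (first column "m/z", one column per sample, blanks absent).

    ``dialect`` is "delimited" (tab-separated) or "xlsx"; inferred from the
    file suffix when omitted.
    """
    path = Path(path)
    dialect = dialect or ("xlsx" if path.suffix.lower() == ".xlsx" else "delimited")
    df = matrix.intensities.copy()
    df.index.name = "m/z"
    if dialect == "xlsx":
        df.to_excel(path, engine="openpyxl")
    elif dialect == "delimited":
        df.to_csv(path, sep="\t", float_format=None)
    else:
        raise ConfigurationError(f"dialect: unknown dialect {dialect!r}")


def read_matrix(
    path,
    groups: Mapping[str, str] | None = None,
    dialect: str | None = None,
) -> AnalysisMatrix:
    """Read an analysis matrix from delimited text or XLSX.

    The first column must be the consensus m/z; remaining columns are one
    per sample with empty cells meaning absent.  ``groups`` maps sample id
    to group label; samples not covered raise a configuration error.
    """
    path = Path(path)
    dialect = dialect or ("xlsx" if path.suffix.lower() == ".xlsx" else "delimited")
    if dialect == "xlsx":
        raw = pd.read_excel(path, header=0, dtype=object, engine="openpyxl")
    elif dialect == "delimited":
        raw = pd.read_csv(path, sep=None, engine="python", header=0, dtype=object)
    else:
        raise ConfigurationError(f"dialect: unknown dialect {dialect!r}")
    if raw.shape[1] < 2:
        raise MatrixParseError("matrix needs an m/z column plus >=1 sample column")
    columns = [str(c) for c in raw.columns]
    sample_cols = columns[1:]
    seen: set[str] = set()
    for c in sample_cols:
        base = c.split(".")[0] if c.split(".")[-1].isdigit() else c
        if base in seen:
            raise MatrixParseError(f"duplicate sample column {base!r}", column=base)
        seen.add(base)
    def exact_floats(series, col_name):
        # float() is correctly rounded; pd.to_numeric's fast parser is not,
        # and the matrix contract requires full-precision round trips
        out = np.full(len(series), np.nan)
        for k, cell in enumerate(series.to_numpy()):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                continue
            try:
                out[k] = float(cell)
            except (TypeError, ValueError):
                raise MatrixParseError(
                    f"non-numeric cell {cell!r} in column {col_name!r}",
                    row=k + 2,  # 1-based, counting the header line
                    column=col_name,
                ) from None
        return out

    values = pd.DataFrame(
        {col: exact_floats(raw[col], col) for col in sample_cols},
        columns=sample_cols,
    )
    mzs = exact_floats(raw.iloc[:, 0], columns[0])
    if np.isnan(mzs).any():
        raise MatrixParseError("missing m/z value", column=columns[0])
    values.index = pd.Index(mzs, name="m/z")
    if groups is None:
        groups = {s: "unknown" for s in sample_cols}
    return AnalysisMatrix(values, {s: groups[s] for s in sample_cols})


def matrices_equal(a: AnalysisMatrix, b: AnalysisMatrix, rtol: float = 0.0) -> bool:
    """Exact (or rtol-relative) equality of two matrices, absences included."""
    if a.sample_ids != b.sample_ids or a.groups != b.groups:
        return False
    if a.intensities.shape != b.intensities.shape:
        return False
    if not np.allclose(a.peak_mzs, b.peak_mzs, rtol=rtol, atol=0.0):
        return False
    av, bv = a.intensities.to_numpy(), b.intensities.to_numpy()
    if not np.array_equal(np.isnan(av), np.isnan(bv)):
        return False
    mask = ~np.isnan(av)
    return bool(np.allclose(av[mask], bv[mask], rtol=rtol, atol=0.0))
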