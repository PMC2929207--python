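"""Blood-contamination QC for CSF samples.

Serum/plasma carries far higher protein concentrations than CSF, so even
slight blood contamination skews a CSF peptide profile.  Two independent
rules flag contaminated samples; a sample is excluded if either fires:

1. *Marker S/N rule* — the hemoglobin-gamma peptide peak at m/z 1274.7255
   with signal-to-noise >= 4 in the MALDI peak list.
2. *Identification rule* — any confidently identified peptide (XC above
   the charge-dependent SEQUEST thresholds 1.8 / 2.2 / 3.75 for 1+/2+/3+)
   mapping to a blood-specific protein (hemoglobin subunits or
   apolipoprotein B-100).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .matrix import PeakList

HEMOGLOBIN_GAMMA_MARKER_MZ = 1274.7255
DEFAULT_SN_THRESHOLD = 4.0
DEFAULT_XC_THRESHOLDS = {1: 1.8, 2: 2.2, 3: 3.75}
DEFAULT_BLOOD_PROTEINS = (
    # hemoglobin alpha, beta, delta, gamma-1, gamma-2; apolipoprotein B-100
    "P69905", "HBA_HUMAN",
    "P68871", "HBB_HUMAN",
    "P02042", "HBD_HUMAN",
    "P69891", "HBG1_HUMAN",
    "P69892", "HBG2_HUMAN",
    "P04114", "APOB_HUMAN",
)

PSM_COLUMNS = ["sample_id", "peptide", "accession", "charge", "xc"]


@dataclass
class QCReport:
    """Outcome of the contamination rules for one sample.

    ``flags`` holds (rule name, evidence) pairs; the sample passes iff no
    rule flagged it.  A rule that could not be evaluated (e.g. missing S/N
    values) contributes a ``not-evaluable`` flag rather than silently
    passing.
    """

    sample_id: str
    flags: list[tuple[str, str]] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.flags


def marker_sn_check(
    pl: PeakList,
    marker_mz: float = HEMOGLOBIN_GAMMA_MARKER_MZ,
    tol_ppm: float = 10.0,
    sn_threshold: float = DEFAULT_SN_THRESHOLD,
) -> QCReport:
    """Flag a sample whose marker peak reaches the S/N threshold.

    The sample is flagged iff any peak within ``tol_ppm`` of ``marker_mz``
    has S/N >= ``sn_threshold``.  At most one flag is emitted regardless of
    how many peaks qualify.  If peaks fall in the window but carry no S/N
    value, the rule reports ``not-evaluable`` instead of passing.
    """
    report = QCReport(sample_id=pl.sample_id)
    if pl.n_peaks == 0:
        return report
    window = np.abs(1e6 * (pl.mz - marker_mz) / marker_mz) <= tol_ppm
    if not window.any():
        return report
    if pl.sn is None:
        report.flags.append(
            ("marker-sn", f"peak(s) near {marker_mz} u but no S/N values: not evaluable")
        )
        return report
    sn = pl.sn[window]
    if np.isnan(sn).any():
        report.flags.append(
            ("marker-sn", f"peak(s) near {marker_mz} u with missing S/N: not evaluable")
        )
        return report
    hits = sn >= sn_threshold
    if hits.any():
        mzs = pl.mz[window][hits]
        report.flags.append(
            (
                "marker-sn",
                f"marker {marker_mz} u detected at S/N "
                f"{', '.join(f'{v:.2f}' for v in sn[hits])} "
                f"(m/z {', '.join(f'{v:.4f}' for v in mzs)}) >= {sn_threshold}",
            )
        )
    return report


def read_psm_table(path) -> pd.DataFrame:
    """Read a PSM table (sample_id, peptide, accession, charge, xc)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"psm table: missing column(s) {missing}")
    df["charge"] = df["charge"].astype(int)
    df["xc"] = df["xc"].astype(float)
    if (df["xc"] < 0).any():
        raise ConfigurationError("psm table: xc must be non-negative")
    return df[PSM_COLUMNS]


def psm_filter(
    t: pd.DataFrame, thresholds: Mapping[int, float] | None = None
) -> pd.DataFrame:
    """Keep PSMs at or above the charge-dependent minimum XC; order preserved.

    Raises a configuration error naming the offending rows if a charge
    state has no threshold.
    """
    thresholds = dict(DEFAULT_XC_THRESHOLDS if thresholds is None else thresholds)
    unknown = t.loc[~t["charge"].isin(thresholds)]
    if len(unknown):
        raise ConfigurationError(
            f"psm table: no XC threshold for charge(s) "
            f"{sorted(unknown['charge'].unique().tolist())} "
            f"(rows {unknown.index.tolist()})"
        )
    if t.empty:
        return t.copy()
    mins = t["charge"].map(thresholds)
    return t.loc[t["xc"] >= mins].copy()


def identification_check(
    t: pd.DataFrame,
    blood_proteins: Sequence[str] = DEFAULT_BLOOD_PROTEINS,
    thresholds: Mapping[int, float] | None = None,
) -> dict[str, QCReport]:
    """Flag samples with a confidently identified blood-protein peptide.

    XC filtering is applied internally; a sample is flagged iff at least
    one surviving PSM's accession is in ``blood_proteins`` (case
    insensitive).  Every sample in the table gets a report.
    """
    blood = {a.upper() for a in blood_proteins}
    surviving = psm_filter(t, thresholds)
    reports = {str(s): QCReport(sample_id=str(s)) for s in t["sample_id"].unique()}
    for sid, grp in surviving.groupby("sample_id", sort=False):
        hits = grp.loc[grp["accession"].str.upper().isin(blood)]
        if len(hits):
            peptides = ", ".join(
                f"{r.peptide} ({r.accession}, z={r.charge}, XC={r.xc})"
                for r in hits.itertuples()
            )
            reports[str(sid)].flags.append(
                ("blood-identification", f"blood-protein PSM(s): {peptides}")
            )
    return reports


def combine_reports(*report_sets: Mapping[str, QCReport] | QCReport) -> dict[str, QCReport]:
    """Merge per-rule reports; a sample is excluded iff any rule flagged it."""
    merged: dict[str, QCReport] = {}
    flat: list[QCReport] = []
    for rs in report_sets:
        if isinstance(rs, QCReport):
            flat.append(rs)
        else:
            flat.extend(rs.values())
    for rep in flat:
        target = merged.setdefault(rep.sample_id, QCReport(sample_id=rep.sample_id))
        target.flags.extend(rep.flags)
    return merged


def passing_samples(reports: Mapping[str, QCReport]) -> list[str]:
    return [s for s, rep in reports.items() if rep.passed]


def write_qc_reports(reports: Mapping[str, QCReport], path) -> None:
    rows = []
    for sid, rep in reports.items():
        if rep.flags:
            for rule, evidence in rep.flags:
                rows.append({"sample_id": sid, "passed": False, "rule": rule, "evidence": evidence})
        else:
            rows.append({"sample_id": sid, "passed": True, "rule": "", "evidence": ""})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
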