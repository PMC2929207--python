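"""Synthetic peptide-profiling data with the structure the analysis assumes.

The generator emulates a label-free MALDI peak-profiling experiment on
three sample groups (disease subtypes PP and RR plus controls, default
sizes 10/11/10): per-peak log-normal intensities with a per-peak location
spread, per-peak/per-group detection probabilities, planted differential
peaks (fold changes on the log-mean, or detection-probability shifts for
incidence contrasts), a uniform m/z calibration drift, omnipresent albumin
calibrant peaks, and hemoglobin-marker contamination spikes.

Randomness is organised so that equal (config, seed) gives byte-identical
output, and every sample draws from its own stream keyed by (seed, group,
within-group index) — adding samples or groups never perturbs the data of
existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .matrix import AnalysisMatrix, PeakList
from .peptides import hsa_reference_mzs
from .qc import HEMOGLOBIN_GAMMA_MARKER_MZ

DEFAULT_GROUP_SIZES = {"PP": 10, "RR": 11, "control": 10}


@dataclass(frozen=True)
class PlantedEffect:
    """A differential effect planted on one peak in one group.

    ``fold`` multiplies the group's (geometric) mean intensity;
    ``incidence_delta`` shifts the group's detection probability (clipped
    to [0, 1]).
    """

    peak_index: int
    group: str
    fold: float = 1.0
    incidence_delta: float = 0.0

    def __post_init__(self):
        if self.fold < 1.0:
            raise ConfigurationError("planted_effects: fold multiplier must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic experiment; defaults mirror the study design."""

    n_samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    n_peaks: int = 1000
    base_intensity_log_mean: float = 9.0
    base_intensity_log_sd: float = 0.6
    peak_log_mean_spread: float = 1.0
    detection_prob: float = 1.0
    planted_effects: tuple[PlantedEffect, ...] = ()
    mz_range: tuple[float, float] = (700.0, 3500.0)
    calibration_drift_ppm: float = 0.0
    contamination: tuple[tuple[str, float], ...] = ()
    seed: int = 0

    def __post_init__(self):
        if not self.n_samples_per_group:
            raise ConfigurationError("n_samples_per_group: at least one group required")
        for g, n in self.n_samples_per_group.items():
            if int(n) < 1:
                raise ConfigurationError(f"n_samples_per_group: group {g!r} must be >= 1")
        if self.n_peaks < 1:
            raise ConfigurationError("n_peaks: must be positive")
        if self.base_intensity_log_sd <= 0:
            raise ConfigurationError("base_intensity_log_sd: must be positive")
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ConfigurationError("detection_prob: must be in [0, 1]")
        lo, hi = self.mz_range
        if not 0 < lo < hi:
            raise ConfigurationError("mz_range: require 0 < low < high")
        for eff in self.planted_effects:
            if not 0 <= eff.peak_index < self.n_peaks:
                raise ConfigurationError(
                    f"planted_effects: peak index {eff.peak_index} out of range"
                )
            if eff.group not in self.n_samples_per_group:
                raise ConfigurationError(
                    f"planted_effects: unknown group {eff.group!r}"
                )
        for sid, sn in self.contamination:
            if sn <= 0:
                raise ConfigurationError(f"contamination: S/N for {sid!r} must be positive")


def _peak_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng([config.seed, 0])


def _sample_rng(config: SimulationConfig, group: str, index: int) -> np.random.Generator:
    key = zlib.crc32(group.encode("utf-8"))
    return np.random.default_rng([config.seed, 2, key, index])


def _peak_params(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Consensus m/z positions (sorted) and per-peak log-mean offsets."""
    rng = _peak_rng(config)
    lo, hi = config.mz_range
    mzs = np.sort(rng.uniform(lo, hi, config.n_peaks))
    # enforce strictly ascending (duplicates have measure zero, but be safe)
    mzs += np.arange(config.n_peaks) * 1e-9
    offsets = rng.normal(0.0, config.peak_log_mean_spread, config.n_peaks)
    return mzs, offsets


def sample_ids_for(config: SimulationConfig) -> dict[str, str]:
    """Deterministic sample id -> group mapping implied by the config."""
    out: dict[str, str] = {}
    for group, n in config.n_samples_per_group.items():
        for i in range(int(n)):
            out[f"{group}_{i + 1:02d}"] = group
    return out


def _generate_matrix(config: SimulationConfig) -> AnalysisMatrix:
    mzs, offsets = _peak_params(config)
    n_peaks = config.n_peaks

    log_shift = {g: np.zeros(n_peaks) for g in config.n_samples_per_group}
    det_prob = {
        g: np.full(n_peaks, config.detection_prob) for g in config.n_samples_per_group
    }
    for eff in config.planted_effects:
        log_shift[eff.group][eff.peak_index] += np.log(eff.fold)
        det_prob[eff.group][eff.peak_index] = np.clip(
            det_prob[eff.group][eff.peak_index] + eff.incidence_delta, 0.0, 1.0
        )

    columns: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    for group, n in config.n_samples_per_group.items():
        mu = config.base_intensity_log_mean + offsets + log_shift[group]
        for i in range(int(n)):
            rng = _sample_rng(config, group, i)
            z = rng.standard_normal(n_peaks)
            u = rng.uniform(size=n_peaks)
            values = np.exp(mu + config.base_intensity_log_sd * z)
            values[u >= det_prob[group]] = np.nan
            sid = f"{group}_{i + 1:02d}"
            columns[sid] = values
            groups[sid] = group
    table = pd.DataFrame(columns, index=pd.Index(mzs, name="m/z"))
    return AnalysisMatrix(table, groups)


def gen_null_matrix(config: SimulationConfig) -> AnalysisMatrix:
    """Matrix with no group structure: every peak i.i.d. across all samples.

    Requires a config without planted effects and with at least two groups.
    Undetected entries are absent (NaN), not zero.
    """
    if config.planted_effects:
        raise ConfigurationError("planted_effects: must be empty for a null matrix")
    if len(config.n_samples_per_group) < 2:
        raise ConfigurationError("n_samples_per_group: need >= 2 groups")
    return _generate_matrix(config)


def gen_differential_matrix(
    config: SimulationConfig,
) -> tuple[AnalysisMatrix, pd.DataFrame]:
    """Matrix with planted effects plus the ground-truth table.

    The truth table lists exactly the planted peaks: columns
    ``peak_index``, ``mz``, ``group``, ``fold``, ``incidence_delta``.
    With only no-op effects (fold 1, delta 0) the matrix is identical to
    the null generator's output for the same config and seed.
    """
    if not config.planted_effects:
        raise ConfigurationError("planted_effects: need >= 1 planted effect")
    matrix = _generate_matrix(config)
    mzs = matrix.peak_mzs
    truth = pd.DataFrame(
        [
            {
                "peak_index": eff.peak_index,
                "mz": mzs[eff.peak_index],
                "group": eff.group,
                "fold": eff.fold,
                "incidence_delta": eff.incidence_delta,
            }
            for eff in config.planted_effects
        ]
    )
    return matrix, truth


def gen_contaminated_peaklist(
    base: PeakList, marker_mz: float = HEMOGLOBIN_GAMMA_MARKER_MZ, sn: float = 5.0
) -> PeakList:
    """Spike a blood-marker peak with the requested S/N into a peak list.

    All other peaks are unchanged.  The spike's intensity is scaled from
    the base list's intensity/S-N ratio so the stated S/N is physically
    consistent.
    """
    if sn <= 0:
        raise ConfigurationError("sn: must be positive")
    if not 300.0 <= marker_mz <= 6000.0:
        raise ConfigurationError("marker_mz: outside plausible peptide range (300-6000 u)")
    if base.sn is not None and base.n_peaks:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = base.intensity / base.sn
        ratio = ratio[np.isfinite(ratio) & (ratio > 0)]
        scale = float(np.median(ratio)) if ratio.size else 1.0
    else:
        scale = 1.0
    mz = np.append(base.mz, marker_mz)
    intensity = np.append(base.intensity, sn * scale)
    sn_col = np.append(
        base.sn if base.sn is not None else np.full(base.n_peaks, np.nan), sn
    )
    return PeakList(sample_id=base.sample_id, mz=mz, intensity=intensity, sn=sn_col)


def gen_peaklists(
    config: SimulationConfig, include_reference_peaks: bool = True
) -> list[PeakList]:
    """Per-sample peak lists consistent with the generated matrix.

    Each sample's detected peaks become (m/z, intensity, S/N) rows; the
    m/z axis is shifted by ``calibration_drift_ppm`` (emulating instrument
    drift), albumin calibrant peaks are added to every sample when
    ``include_reference_peaks`` (so downstream recalibration can undo the
    drift), and contamination spikes from the config are applied.
    """
    matrix = _generate_matrix(config)
    drift = 1.0 + config.calibration_drift_ppm * 1e-6
    refs = np.asarray(hsa_reference_mzs()) if include_reference_peaks else np.empty(0)
    noise_floor = np.exp(
        config.base_intensity_log_mean - 2.0 * config.base_intensity_log_sd
    )
    contamination = dict(config.contamination)
    out: list[PeakList] = []
    for sid in matrix.sample_ids:
        col = matrix.intensities[sid].to_numpy()
        detected = ~np.isnan(col)
        mz = matrix.peak_mzs[detected]
        intensity = col[detected]
        if refs.size:
            ref_intensity = np.full(refs.size, 10.0 * np.exp(config.base_intensity_log_mean))
            mz = np.concatenate([mz, refs])
            intensity = np.concatenate([intensity, ref_intensity])
        order = np.argsort(mz)
        pl = PeakList(
            sample_id=sid,
            mz=mz[order] * drift,
            intensity=intensity[order],
            sn=intensity[order] / noise_floor,
        )
        if sid in contamination:
            pl = gen_contaminated_peaklist(pl, sn=contamination[sid])
        out.append(pl)
    return out


def gen_psm_table(
    sample_ids: Sequence[str],
    contaminated: Sequence[str] = (),
    n_psms_per_sample: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic PSM table: ordinary CSF identifications everywhere, plus a
    confident hemoglobin-beta PSM for each sample listed in ``contaminated``."""
    rng = np.random.default_rng([seed, 7])
    csf_peptides = [
        ("VEHSDLSFSK", "B2MG_HUMAN"),
        ("LVNEVTEFAK", "ALBU_HUMAN"),
        ("YLYEIAR", "ALBU_HUMAN"),
        ("TCMEGWMGPECNRAICR", "JAG1_HUMAN"),
        ("ELPEHTVKLCDNLSTKNSK", "VTDB_HUMAN"),
    ]
    rows = []
    for sid in sample_ids:
        for _ in range(n_psms_per_sample):
            pep, acc = csf_peptides[rng.integers(len(csf_peptides))]
            charge = int(rng.integers(1, 4))
            xc = float(rng.uniform(0.5, 5.0))
            rows.append(
                {"sample_id": sid, "peptide": pep, "accession": acc, "charge": charge, "xc": xc}
            )
        if sid in set(contaminated):
            rows.append(
                {
                    "sample_id": sid,
                    "peptide": "VNVDEVGGEALGR",
                    "accession": "HBB_HUMAN",
                    "charge": 2,
                    "xc": 3.5,
                }
            )
    return pd.DataFrame(rows)


def gen_immunoassay_table(
    group_stats: Mapping[str, tuple[float, float, int]],
    analyte: str,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic immunoassay measurements from per-group (mean, sd, n).

    Values are drawn normal and reflected to stay positive (concentrations
    and photoluminescence readouts cannot be negative).
    """
    rng = np.random.default_rng([seed, 11])
    rows = []
    for group, (mean, sd, n) in group_stats.items():
        values = np.abs(rng.normal(mean, sd, int(n)))
        for i, v in enumerate(values):
            rows.append(
                {
                    "sample_id": f"{group}_{i + 1:02d}",
                    "group": group,
                    "analyte": analyte,
                    "value": float(v),
                }
            )
    return pd.DataFrame(rows)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different master seed."""
    return replace(config, seed=seed)
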