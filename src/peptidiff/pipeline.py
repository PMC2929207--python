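"""End-to-end orchestration of the profiling analysis.

Stage order follows the experimental workflow: contamination QC, m/z
recalibration, matrix construction, the three pairwise group comparisons,
a permutation background per comparison, theoretical-mass annotation, and
immunoassay validation.  QC-excluded samples never enter the matrix.
Re-running with identical config and seed reproduces every output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import matrix as mx
from . import peptides as pep
from . import qc as qcmod
from . import stats as st
from . import validation as val
from .errors import PeptidiffError, PipelineError
from .permutation import background_count

log = logging.getLogger("peptidiff")


@dataclass
class PipelineConfig:
    """Inputs and parameters of a full run; defaults are the study constants."""

    groups_path: str | Path | None = None
    peaklist_paths: Sequence[str | Path] = ()
    matrix_path: str | Path | None = None
    psm_path: str | Path | None = None
    fasta_path: str | Path | None = None
    immunoassay_path: str | Path | None = None
    out_dir: str | Path = "peptidiff_out"
    reference_mzs: Sequence[float] | None = None  # default: albumin calibrants
    alpha: float = 0.01
    n_iter: int = 50
    cluster_tol_ppm: float = 5.0
    calibration_tol_ppm: float = 20.0
    marker_tol_ppm: float = 10.0
    sn_threshold: float = 4.0
    annotation_cutoff_ppm: float = 2.0
    missing_policy: str = "zero"
    incidence_rounding: str = "round"
    seed: int = 0
    extra: dict = field(default_factory=dict)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except PeptidiffError as exc:
                raise PipelineError(name, str(exc)) from exc

        return inner

    return wrap


@_stage("qc")
def _run_qc(config: PipelineConfig, peaklists, out_dir: Path):
    reports = {}
    for pl in peaklists:
        reports[pl.sample_id] = qcmod.marker_sn_check(
            pl, tol_ppm=config.marker_tol_ppm, sn_threshold=config.sn_threshold
        )
    if config.psm_path:
        psm = qcmod.read_psm_table(config.psm_path)
        reports = qcmod.combine_reports(reports, qcmod.identification_check(psm))
    merged = qcmod.combine_reports(reports) if reports else {}
    if merged:
        qcmod.write_qc_reports(merged, out_dir / "qc_report.tsv")
    for sid, rep in merged.items():
        if not rep.passed:
            log.info("QC excluded sample %s: %s", sid, rep.flags)
    return merged


@_stage("calibrate")
def _run_calibration(config: PipelineConfig, peaklists):
    refs = (
        list(config.reference_mzs)
        if config.reference_mzs
        else pep.hsa_reference_mzs()
    )
    calibrated = []
    for pl in peaklists:
        cal, model = mx.calibrate_peaklist(pl, refs, config.calibration_tol_ppm)
        log.info(
            "calibrated %s: slope=%.8f intercept=%.6f (%d refs)",
            pl.sample_id, model.slope, model.intercept, model.n_refs_matched,
        )
        calibrated.append(cal)
    return calibrated


@_stage("annotate")
def _run_annotation(config: PipelineConfig, matrix: mx.AnalysisMatrix):
    candidates = pep.digest_fasta(config.fasta_path, max_missed=2)
    return pep.match_masses(
        matrix.peak_mzs, candidates, cutoff_ppm=config.annotation_cutoff_ppm
    )


def _annotation_columns(matches, mzs):
    by_mz: dict[float, list] = {}
    for m in matches:
        by_mz.setdefault(m.observed_mz, []).append(m)
    acc, seq = [], []
    for mz in mzs:
        hits = by_mz.get(mz, [])
        acc.append(";".join(h.peptide.source_protein for h in hits))
        seq.append(";".join(h.peptide.sequence for h in hits))
    return acc, seq


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the machine-readable summary.

    Outputs written under ``config.out_dir``: the QC report, the analysis
    matrix, one Table-style comparison file and one background file per
    pairwise comparison, an annotated comparison table when a FASTA is
    given, validation tables when measurements are given, and
    ``summary.json`` / ``summary.txt``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.groups_path is None:
        raise PipelineError("config", "groups_path is required")
    groups = mx.read_groups(config.groups_path)

    excluded: dict[str, list] = {}
    if config.matrix_path:
        matrix = mx.read_matrix(config.matrix_path, groups)
        if config.psm_path:
            psm = qcmod.read_psm_table(config.psm_path)
            reports = qcmod.identification_check(psm)
            qcmod.write_qc_reports(reports, out_dir / "qc_report.tsv")
            excluded = {s: r.flags for s, r in reports.items() if not r.passed}
            keep = [s for s in matrix.sample_ids if s not in excluded]
            matrix = matrix.subset_samples(keep)
    else:
        if not config.peaklist_paths:
            raise PipelineError("config", "need peaklist_paths or matrix_path")
        peaklists = [mx.read_peaklist(p) for p in config.peaklist_paths]
        reports = _run_qc(config, peaklists, out_dir)
        excluded = {s: r.flags for s, r in reports.items() if not r.passed}
        peaklists = [pl for pl in peaklists if pl.sample_id not in excluded]
        if len(peaklists) < 2:
            raise PipelineError("qc", "fewer than two samples survive QC")
        peaklists = _run_calibration(config, peaklists)
        matrix = mx.build_matrix(peaklists, config.cluster_tol_ppm, groups)
    mx.write_matrix(matrix, out_dir / "analysis_matrix.tsv")

    labels = sorted(set(matrix.groups.values()))
    if len(labels) < 2:
        raise PipelineError("compare", "need at least two groups after QC")

    annotation = None
    results: dict[str, st.ComparisonResult] = {}
    backgrounds = {}
    for ga, gb in combinations(labels, 2):
        name = f"{ga}_vs_{gb}"
        res = st.peak_statistics(
            matrix, ga, gb,
            missing_policy=config.missing_policy,
            alpha=config.alpha,
            incidence_rounding=config.incidence_rounding,
            name=name,
        )
        results[name] = res
        bg = background_count(
            matrix, ga, gb,
            alpha=config.alpha,
            n_iter=config.n_iter,
            seed=config.seed,
            missing_policy=config.missing_policy,
        )
        backgrounds[name] = bg
        table = res.table.copy()
        if config.fasta_path:
            if annotation is None:
                annotation = _run_annotation(config, matrix)
            acc, seq = _annotation_columns(annotation, matrix.peak_mzs)
            table.insert(1, "accession", acc)
            table.insert(2, "peptide", seq)
        table.to_csv(out_dir / f"comparison_{name}.tsv", sep="\t", index=False)
        pd.DataFrame({"iteration": range(1, bg.n_iter + 1), "count": bg.counts}).to_csv(
            out_dir / f"background_{name}.tsv", sep="\t", index=False
        )

    validation = []
    if config.immunoassay_path:
        table = val.read_immunoassay(config.immunoassay_path)
        va, vb = config.extra.get("validation_groups", (labels[0], labels[1]))
        for analyte in sorted(table["analyte"].unique()):
            rep = val.validation_report(table, analyte, va, vb)
            rep.to_csv(out_dir / f"validation_{analyte}.tsv", sep="\t", index=False)
            validation.append(rep.iloc[0].to_dict())

    summary = {
        "seed": config.seed,
        "alpha": config.alpha,
        "n_iter": config.n_iter,
        "missing_policy": config.missing_policy,
        "n_peaks": matrix.n_peaks,
        "group_sizes": matrix.group_sizes(),
        "excluded_samples": {s: [f"{r}: {e}" for r, e in fl] for s, fl in excluded.items()},
        "comparisons": {
            name: {
                "n_significant": st.count_significant(res),
                "background_mean": backgrounds[name].mean,
                "background_sd": backgrounds[name].sd,
            }
            for name, res in results.items()
        },
        "overlaps": {
            f"{n1} & {n2}": st.overlap_significant(results[n1], results[n2])
            for n1, n2 in combinations(sorted(results), 2)
        },
        "validation": validation,
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    with open(out_dir / "summary.txt", "w") as fh:
        for name, c in summary["comparisons"].items():
            fh.write(
                f"{name}: significant={c['n_significant']} "
                f"background={c['background_mean']:.2f}+/-{c['background_sd']:.2f}\n"
            )
        for pair, n in summary["overlaps"].items():
            fh.write(f"overlap {pair}: {n}\n")
    return summary


def load_config(path) -> PipelineConfig:
    """Load a flat key:value (YAML) config document into a PipelineConfig."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    kwargs = {k: v for k, v in raw.items() if k in known}
    extra = {k: v for k, v in raw.items() if k not in known}
    cfg = PipelineConfig(**kwargs)
    cfg.extra.update(extra)
    return cfg
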