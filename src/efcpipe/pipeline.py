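"""End-to-end pipeline: preprocessing, GLM, PPI-based connectivity,
subnetwork clustering and network comparison, from one or more runs.

The pipeline operates on ROI-level time series.  Signals may be in raw scanner
units (converted to percent signal change against the rest baseline) or
already in PSC-like additive units (the synthetic generator's default), in
which case the baseline division is skipped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._validation import ValidationError, require
from .clustering import (
    Partition,
    build_features,
    cophenetic,
    correlation_distance_matrix,
    cut,
    inter_roi_corr,
    to_newick,
    wpgma,
)
from .config import PipelineConfig
from .design import StimulusDesign
from .hrf_glm import (
    CycleAverage,
    build_design,
    canonical_hrf,
    compute_psc,
    cycle_average,
    fit_glm,
    fit_two_gamma,
    rest_baseline_mask,
)
from .netcompare import compare_networks, export_edges, subnetwork_stats
from .ppi import EFCResult, build_ppi, compare_mww, extract_seed, fit_efc, group_level
from .preprocess import ROITimeSeries, detrend_demean, discard_initial, lowpass_filter, regress_out, select_nuisance_components
from .synth import SyntheticDataset

log = logging.getLogger(__name__)

PPI_CONDITIONS = ("heat", "heat_fus")


@dataclass
class RunInput:
    """One run: ROI series, its stimulus design and optional nuisance matrix."""

    ts: ROITimeSeries
    design: StimulusDesign
    nuisance: np.ndarray | None = None
    run_id: str = "run-1"
    subject_id: str = "sub-1"
    signals_are_psc: bool = True

    @classmethod
    def from_dataset(cls, ds: SyntheticDataset, run_id: str = "run-1", subject_id: str = "sub-1") -> "RunInput":
        ts = ROITimeSeries(
            times=ds.times, values=ds.signals, roi_names=tuple(ds.roi_names), tr=ds.design.tr
        )
        return cls(ts=ts, design=ds.design, nuisance=ds.nuisance, run_id=run_id, subject_id=subject_id)


@dataclass
class RunResult:
    """Per-run intermediate products consumed by the group stage."""

    run_id: str
    subject_id: str
    roi_names: list[str]
    efc: EFCResult
    cycles: dict  # condition -> roi -> CycleAverage
    corr: dict  # condition -> InterROICorr
    glm_t: dict  # condition -> per-ROI t
    glm_beta: dict


def preprocess_run(run: RunInput, config: PipelineConfig) -> tuple[ROITimeSeries, StimulusDesign, np.ndarray]:
    """Discard, nuisance-regress (PCA-reduced), low-pass filter; returns the
    conditioned series, the shifted design and the PSC matrix."""
    ts = discard_initial(run.ts, config.n_discard)
    shift = config.n_discard * run.ts.tr
    design = run.design.shifted(shift) if config.n_discard else run.design
    if run.nuisance is not None and run.nuisance.shape[1] > 0:
        nuis = run.nuisance[config.n_discard:]
        if nuis.shape[1] > 1:
            nuis = select_nuisance_components(nuis, config.cum_var)
        means = ts.values.mean(axis=0)
        ts = regress_out(ts, nuis)
        # restore the baseline level removed with the intercept
        ts = ts.with_values(ts.values + means, "restore_mean")
    ts = lowpass_filter(ts, config.lowpass_cutoff, config.filter_order, config.stop_atten)
    if run.signals_are_psc:
        psc = ts.values
    else:
        base = rest_baseline_mask(design, ts.times, mode=config.psc_baseline)
        psc = compute_psc(ts.values, base)
    return ts, design, psc


def analyze_run(run: RunInput, config: PipelineConfig) -> RunResult:
    """Single-run analysis: GLM, cycle averages, PPI-EFC, correlation matrices."""
    ts, design, psc = preprocess_run(run, config)
    roi_names = list(ts.roi_names)
    hrf = config.hrf_spec()
    X = build_design(design, hrf, conditions=[c for c in design.conditions() if c in PPI_CONDITIONS],
                     times=ts.times)
    glm = fit_glm(psc, X)

    cycles: dict[str, dict] = {}
    for cond in PPI_CONDITIONS:
        cycles[cond] = {
            roi: cycle_average(psc[:, i], ts.times, design, cond, config.cycle_window_s)
            for i, roi in enumerate(roi_names)
        }

    seed_roi = config.seed_roi or roi_names[0]
    require(seed_roi in roi_names, f"seed ROI {seed_roi!r} not in the series")
    seed = extract_seed(psc[:, roi_names.index(seed_roi)], seed_roi)
    if config.ppi_hrf == "fitted":
        fit = fit_two_gamma(cycles["heat"][seed_roi], seed=config.seed)
        kernel = fit.kernel(dt=design.tr)
    else:
        kernel = canonical_hrf(hrf)
    ppi = build_ppi(seed, design, kernel, conditions=PPI_CONDITIONS)
    efc = fit_efc(psc, ppi, X, roi_names=roi_names, run_id=run.run_id, subject_id=run.subject_id)

    corr = {
        cond: inter_roi_corr(
            psc, roi_names, threshold=config.corr_threshold, condition=cond,
            condition_mask=design.cycle_mask(cond, ts.times),
        )
        for cond in PPI_CONDITIONS
    }
    return RunResult(
        run_id=run.run_id,
        subject_id=run.subject_id,
        roi_names=roi_names,
        efc=efc,
        cycles=cycles,
        corr=corr,
        glm_t={c: glm.t_for(c) for c in PPI_CONDITIONS if c in glm.condition_map},
        glm_beta={c: glm.beta_for(c) for c in PPI_CONDITIONS if c in glm.condition_map},
    )


def _mean_cycles(results: list[RunResult], cond: str, roi: str) -> CycleAverage:
    cycles = [r.cycles[cond][roi] for r in results]
    mean = np.mean([c.mean_psc for c in cycles], axis=0)
    return CycleAverage(
        window_times=cycles[0].window_times,
        mean_psc=mean,
        se_psc=np.std([c.mean_psc for c in cycles], axis=0, ddof=1) / np.sqrt(len(cycles)) if len(cycles) > 1 else cycles[0].se_psc,
        n_cycles=sum(c.n_cycles for c in cycles),
        condition=cond,
    )


def _mean_corr(results: list[RunResult], cond: str, config: PipelineConfig):
    from .clustering import InterROICorr

    r = np.mean([res.corr[cond].r for res in results], axis=0)
    np.fill_diagonal(r, 1.0)
    return InterROICorr(
        roi_names=results[0].roi_names, r=r, threshold=config.corr_threshold, condition=cond
    )


def run_pipeline(runs: list[RunInput], config: PipelineConfig | None = None, outdir: str | Path | None = None) -> dict:
    """Execute the full analysis over one or more runs.

    Returns a JSON-serializable report; when ``outdir`` is given also writes
    the stage artifacts (TSV tables, Newick trees, report.json).
    """
    config = config or PipelineConfig()
    require(len(runs) >= 1, "need at least one run")
    results = []
    for run in runs:
        try:
            results.append(analyze_run(run, config))
        except ValidationError as exc:
            raise ValidationError(f"run {run.run_id}: {exc}") from exc
    roi_names = results[0].roi_names
    for r in results[1:]:
        require(r.roi_names == roi_names, "ROI sets differ across runs")

    group = group_level([r.efc for r in results])

    # per-ROI MWW between conditions across runs
    mww_rows = []
    if len(results) >= 2:
        for i, roi in enumerate(roi_names):
            a = [r.efc.beta_for("heat")[i] for r in results]
            b = [r.efc.beta_for("heat_fus")[i] for r in results]
            m = compare_mww(a, b)
            stars = "**" if m.p < 0.005 else ("*" if m.p < 0.05 else "")
            mww_rows.append({"roi": roi, "U": m.U, "p": m.p, "direction": m.effect_direction, "stars": stars})

    corr = {cond: _mean_corr(results, cond, config) for cond in PPI_CONDITIONS}

    cluster_report = {}
    partitions = {}
    for cond in PPI_CONDITIONS:
        fits = {roi: fit_two_gamma(_mean_cycles(results, cond, roi), seed=config.seed) for roi in roi_names}
        betas = {roi: float(np.mean([r.efc.beta_for(cond)[i] for r in results])) for i, roi in enumerate(roi_names)}
        cycles = {roi: _mean_cycles(results, cond, roi) for roi in roi_names}
        feats = build_features(fits, betas, cycles, condition=cond)
        names, D = correlation_distance_matrix(feats)
        dendro = wpgma(D, leaf_names=names)
        coph = cophenetic(dendro, D)
        part = cut(dendro, config.cut_height)
        partitions[cond] = part
        cluster_report[cond] = {
            "leaves": dendro.leaves,
            "merges": [[int(a), int(b), float(h)] for a, b, h in dendro.merges],
            "newick": to_newick(dendro),
            "cophenetic_correlation": coph.correlation,
            "cut_height": config.cut_height,
            "labels": part.labels,
            "n_subnetworks": part.n_subnetworks,
        }

    comparison = compare_networks(
        corr["heat"], corr["heat_fus"],
        delta_r=config.dice_delta_r,
        edge_threshold=config.corr_threshold,
        edge_set_rule=config.power_edge_set,
    )
    sub_stats = subnetwork_stats(partitions["heat"], corr["heat"], corr["heat_fus"])
    edges = {cond: export_edges(corr[cond], partitions[cond], config.edge_r_min) for cond in PPI_CONDITIONS}

    report = {
        "config": config.to_dict(),
        "n_runs": len(results),
        "roi_names": roi_names,
        "seed_roi": config.seed_roi or roi_names[0],
        "efc_runs": [
            {
                "run_id": r.run_id,
                "subject_id": r.subject_id,
                "beta": {c: [float(x) for x in r.efc.beta_for(c)] for c in PPI_CONDITIONS},
                "p": {c: [float(x) for x in r.efc.p[:, r.efc.conditions.index(c)]] for c in PPI_CONDITIONS},
            }
            for r in results
        ],
        "group": {
            "mean_beta": {c: [float(x) for x in group["mean_beta"][:, group["conditions"].index(c)]] for c in PPI_CONDITIONS},
            "p": {c: [float(x) for x in group["p"][:, group["conditions"].index(c)]] for c in PPI_CONDITIONS},
            "n_units": group["n_units"],
            "runs_per_subject": group["runs_per_subject"],
        },
        "mww": mww_rows,
        "correlation": {c: [[float(x) for x in row] for row in corr[c].r] for c in PPI_CONDITIONS},
        "clustering": cluster_report,
        "comparison": {
            "dice": None if not comparison.dice.defined else float(comparison.dice.value),
            "dice_defined": comparison.dice.defined,
            "delta_r_criterion": comparison.delta_r_criterion,
            "power_change_pct": comparison.power_change_pct,
            "edge_threshold": comparison.edge_threshold,
        },
        "subnetwork_stats": sub_stats,
        "edges": edges,
    }

    if outdir is not None:
        _write_artifacts(report, results, corr, partitions, outdir)
    return report


def _write_artifacts(report: dict, results: list[RunResult], corr, partitions, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in results:
        for c in PPI_CONDITIONS:
            j = r.efc.conditions.index(c)
            for i, roi in enumerate(r.roi_names):
                rows.append((r.run_id, r.subject_id, roi, c, r.efc.beta[i, j], r.efc.t[i, j], r.efc.p[i, j]))
    pd.DataFrame(rows, columns=["run_id", "subject_id", "roi", "condition", "beta", "t", "p"]).to_csv(
        outdir / "efc_runs.tsv", sep="\t", index=False, float_format="%.10g"
    )
    for c in PPI_CONDITIONS:
        pd.DataFrame(corr[c].r, index=corr[c].roi_names, columns=corr[c].roi_names).to_csv(
            outdir / f"corr_{c}.tsv", sep="\t", float_format="%.10g"
        )
        (outdir / f"dendrogram_{c}.nwk").write_text(report["clustering"][c]["newick"] + "\n")
        pd.DataFrame(
            sorted(partitions[c].labels.items()), columns=["roi", "subnetwork"]
        ).to_csv(outdir / f"partition_{c}.tsv", sep="\t", index=False)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
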