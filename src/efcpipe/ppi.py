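"""Condition-specific effective functional connectivity via
psychophysiological-interaction (PPI) regression.

The seed's percent-signal-change series (detrended, demeaned) is multiplied
element-wise with the HRF-convolved, demeaned task time course; the product is
split by condition cycle (block + following rest) into one regressor per
condition, and each ROI is regressed on both alongside the task main effects
and confounds.  Group inference is two-stage summary statistics; condition
contrasts use the Mann-Whitney-Wilcoxon rank-sum test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from ._validation import ValidationError, require
from .design import StimulusDesign
from .hrf_glm import ActivationMap, DesignMatrix, GLMResult, fit_glm

log = logging.getLogger(__name__)

__all__ = [
    "SeedSignal",
    "PPIRegressorSet",
    "EFCResult",
    "extract_seed",
    "build_ppi",
    "fit_efc",
    "group_level",
    "compare_mww",
    "MWWResult",
]

PPI_CONDITIONS = ("heat", "heat_fus")


def _detrend_demean_1d(y: np.ndarray) -> np.ndarray:
    t = np.arange(len(y), dtype=float)
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


@dataclass(frozen=True)
class SeedSignal:
    """Mean suprathreshold seed PSC, detrended and demeaned."""

    values: np.ndarray
    source_voxel_count: int
    seed_roi: str
    preprocessing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        object.__setattr__(self, "values", v)
        t = np.arange(len(v), dtype=float)
        slope = np.polyfit(t, v, 1)[0] if len(v) > 1 else 0.0
        require(abs(v.mean()) < 1e-6 * (1 + np.abs(v).max()), "seed signal must be demeaned")
        require(abs(slope) < 1e-6 * (1 + np.abs(v).max()), "seed signal must be detrended")


def extract_seed(
    psc: np.ndarray,
    seed_roi: str,
    activation: ActivationMap | None = None,
    seed_mask: np.ndarray | None = None,
) -> SeedSignal:
    """Mean PSC over qualifying seed voxels, then detrended and demeaned.

    ROI mode: ``psc`` is a 1-D series for the seed ROI (``activation`` and
    ``seed_mask`` omitted).  Voxel mode: ``psc`` has shape
    ``grid + (time,)``; qualifying voxels are ``seed_mask & activation.mask``.
    """
    psc = np.asarray(psc, float)
    if seed_mask is None:
        require(psc.ndim == 1, "ROI mode expects a 1-D PSC series")
        series = psc
        count = 1
    else:
        require(activation is not None, "voxel mode requires an activation map")
        qualify = np.asarray(seed_mask, bool) & activation.mask
        count = int(qualify.sum())
        if count == 0:
            raise ValidationError(
                f"empty seed: no suprathreshold voxels inside {seed_roi!r} mask"
            )
        series = psc[qualify].mean(axis=0)
    return SeedSignal(
        values=_detrend_demean_1d(series),
        source_voxel_count=count,
        seed_roi=seed_roi,
        preprocessing=("detrend", "demean"),
    )


@dataclass
class PPIRegressorSet:
    """Full-run PPI product and its condition-masked splits."""

    ppi_full: np.ndarray
    ppi_by_condition: dict  # condition -> per-volume vector (zero off-support)
    task_convolved: dict  # condition -> HRF-convolved demeaned boxcar
    condition_masks: dict  # condition -> boolean support
    hrf_kernel: np.ndarray

    def conditions(self) -> list[str]:
        return list(self.ppi_by_condition)


def build_ppi(
    seed: SeedSignal,
    design: StimulusDesign,
    hrf_kernel: tuple[np.ndarray, np.ndarray],
    conditions: tuple[str, ...] = PPI_CONDITIONS,
) -> PPIRegressorSet:
    """Construct the PPI regressors.

    Per condition: the 0/1 block boxcar is demeaned over the full run,
    convolved with ``hrf_kernel`` (given as ``(t, h)`` sampled at any step;
    resampled to the TR grid), and multiplied element-wise with the seed
    series.  The product is then masked to the condition's cycles
    (block + following rest); trailing partial cycles are dropped.
    """
    times = design.frame_times()
    require(len(seed.values) == design.n_volumes, "seed length must equal design volumes")
    kt, kh = hrf_kernel
    # resample kernel onto the TR grid for discrete convolution
    tr_grid = np.arange(0.0, float(kt[-1]) + design.tr / 2, design.tr)
    kernel_tr = np.interp(tr_grid, kt, kh)
    by_cond: dict[str, np.ndarray] = {}
    task: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    for cond in conditions:
        box = design.boxcar(cond, times)
        box_dm = box - box.mean()
        conv = np.convolve(box_dm, kernel_tr)[: len(times)]
        product = conv * seed.values
        mask = design.cycle_mask(cond, times)
        vec = np.where(mask, product, 0.0)
        by_cond[cond] = vec
        task[cond] = conv
        masks[cond] = mask
    full = np.sum(list(by_cond.values()), axis=0)
    return PPIRegressorSet(
        ppi_full=full, ppi_by_condition=by_cond, task_convolved=task,
        condition_masks=masks, hrf_kernel=kernel_tr,
    )


@dataclass
class EFCResult:
    """Per-ROI, per-condition PPI regression coefficients with inference."""

    roi_names: list[str]
    conditions: list[str]
    beta: np.ndarray  # ROI x condition
    t: np.ndarray
    p: np.ndarray
    run_id: str = "run-1"
    subject_id: str = "sub-1"
    mean_p_suprathreshold: np.ndarray | None = None
    contrast_t: np.ndarray | None = None  # per-ROI t of beta[cond0] - beta[cond1]
    contrast_p: np.ndarray | None = None

    def beta_for(self, condition: str) -> np.ndarray:
        return self.beta[:, self.conditions.index(condition)]


def fit_efc(
    Y: np.ndarray,
    ppi: PPIRegressorSet,
    X_base: DesignMatrix,
    roi_names: list[str] | None = None,
    run_id: str = "run-1",
    subject_id: str = "sub-1",
    collinearity_max_r: float = 0.99,
) -> EFCResult:
    """Fit the EFC GLM: ``Y ~ [X_base | ppi_heat | ppi_heat_fus]``.

    The EFC beta per ROI and condition is the coefficient on that condition's
    PPI column; task and confound columns of ``X_base`` are retained as
    covariates.  Near-collinearity between a PPI column and any base column
    raises with the offending correlation.
    """
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    conds = ppi.conditions()
    cols = [ppi.ppi_by_condition[c] for c in conds]
    for c, col in zip(conds, cols):
        for j, name in enumerate(X_base.names):
            base = X_base.matrix[:, j]
            if np.std(base) == 0 or np.std(col) == 0:
                continue
            r = float(np.corrcoef(col, base)[0, 1])
            if abs(r) > collinearity_max_r:
                raise ValidationError(
                    f"PPI column {c!r} nearly collinear with {name!r} (r = {r:.4f})"
                )
    M = np.column_stack([X_base.matrix] + cols)
    names = list(X_base.names) + [f"ppi_{c}" for c in conds]
    cond_map = {c: len(X_base.names) + i for i, c in enumerate(conds)}
    X = DesignMatrix(times=X_base.times, matrix=M, names=names, condition_map=cond_map)
    res = fit_glm(Y, X)
    idx = [cond_map[c] for c in conds]
    if roi_names is None:
        roi_names = [f"roi{i:02d}" for i in range(Y.shape[1])]
    contrast_t = contrast_p = None
    if len(conds) == 2:
        # t-test of beta[cond0] - beta[cond1] using the coefficient covariance
        xtx_inv = np.linalg.pinv(M.T @ M)
        c = np.zeros(M.shape[1])
        c[idx[0]], c[idx[1]] = 1.0, -1.0
        var_c = float(c @ xtx_inv @ c)
        diff = res.beta[:, idx[0]] - res.beta[:, idx[1]]
        se = np.sqrt(res.residual_variance * var_c)
        with np.errstate(divide="ignore", invalid="ignore"):
            contrast_t = np.where(se > 0, diff / se, 0.0)
        contrast_p = 2.0 * sps.t.sf(np.abs(contrast_t), res.dof)
    return EFCResult(
        roi_names=list(roi_names),
        conditions=list(conds),
        beta=res.beta[:, idx],
        t=res.t[:, idx],
        p=res.p[:, idx],
        run_id=run_id,
        subject_id=subject_id,
        contrast_t=contrast_t,
        contrast_p=contrast_p,
    )


def group_level(results: list[EFCResult]) -> dict:
    """Two-stage group inference.

    Run-level betas are averaged within subject (unweighted by run count),
    then a one-sample t-test across subject means gives the group t and p per
    ROI and condition.  With a single subject the test falls back to
    run-level inference and a warning is logged.
    """
    require(len(results) >= 1, "need at least one run result")
    first = results[0]
    for r in results:
        require(r.roi_names == first.roi_names, "ROI sets differ across runs")
        require(r.conditions == first.conditions, "condition sets differ across runs")
    subjects = sorted({r.subject_id for r in results})
    if len(subjects) < 2:
        log.warning("single subject: group inference falls back to run-level one-sample test")
        units = np.stack([r.beta for r in results])  # run x ROI x cond
    else:
        units = np.stack([
            np.mean([r.beta for r in results if r.subject_id == s], axis=0) for s in subjects
        ])  # subject x ROI x cond
    mean = units.mean(axis=0)
    n_units = units.shape[0]
    if n_units > 1:
        sd = units.std(axis=0, ddof=1)
        se = sd / np.sqrt(n_units)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, mean / se, np.where(mean == 0, 0.0, np.inf))
        p = 2.0 * sps.t.sf(np.abs(t), n_units - 1)
    else:
        t = np.full_like(mean, np.nan)
        p = np.full_like(mean, np.nan)
    return {
        "roi_names": list(first.roi_names),
        "conditions": list(first.conditions),
        "mean_beta": mean,
        "t": t,
        "p": p,
        "n_units": n_units,
        "runs_per_subject": {s: sum(r.subject_id == s for r in results) for s in subjects},
        "within_subject_variance": float(np.mean([np.var([r.beta for r in results if r.subject_id == s], axis=0).mean() for s in subjects])) if len(results) > len(subjects) else 0.0,
    }


@dataclass(frozen=True)
class MWWResult:
    U: float
    p: float
    effect_direction: int  # +1 if a tends larger, -1 if b, 0 if tied
    method: str


def compare_mww(a, b, sides: str = "two-sided") -> MWWResult:
    """Mann-Whitney-Wilcoxon rank-sum test.

    Exact p-value when the combined sample size is at most 20 and no ties are
    present; tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    require(a.size >= 1 and b.size >= 1, "both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    n = a.size + b.size
    if np.ptp(pooled) == 0:
        # all values identical: no evidence either way
        return MWWResult(U=a.size * b.size / 2.0, p=1.0, effect_direction=0, method="degenerate")
    if not has_ties and n <= 20:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=sides, method=method)
    u_a = float(res.statistic)  # number of (a > b) pairs
    expected = a.size * b.size / 2.0
    direction = 0 if u_a == expected else (1 if u_a > expected else -1)
    return MWWResult(U=u_a, p=float(min(res.pvalue, 1.0)), effect_direction=direction, method=method)
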