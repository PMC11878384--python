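"""Readers and writers for the pipeline's plain-text formats.

Events TSV (BIDS dialect: onset, duration, trial_type), ROI time-series TSV
(first column ``time`` in seconds, one column per ROI), nuisance TSV, ground
truth JSON and 4-D NIfTI volumes with integer ROI label masks.  Every reader
validates its schema and reports the offending file, row and column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._validation import ValidationError
from .design import StimulusDesign, StimulusEvent
from .preprocess import ROITimeSeries
from .synth import GroundTruth, SyntheticDataset


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file not found")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    return df


def _numeric(df: pd.DataFrame, cols: list[str], path: Path) -> pd.DataFrame:
    for col in cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, counting the header line
            raise ValidationError(f"{path}: non-numeric value in column {col!r} at line {row}")
        df[col] = converted
    return df


# --- events -----------------------------------------------------------------


def read_events(path: str | Path, tr: float, n_volumes: int) -> StimulusDesign:
    """Read a BIDS-style events table into a validated StimulusDesign."""
    path = Path(path)
    df = _read_tsv(path, ["onset", "duration", "trial_type"])
    df = _numeric(df, ["onset", "duration"], path)
    events = tuple(
        StimulusEvent(onset=float(r.onset), duration=float(r.duration), condition=str(r.trial_type))
        for r in df.itertuples()
    )
    try:
        return StimulusDesign(tr=tr, n_volumes=n_volumes, events=events)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_events(design: StimulusDesign, path: str | Path) -> None:
    df = pd.DataFrame(
        [(ev.onset, ev.duration, ev.condition) for ev in design.events],
        columns=["onset", "duration", "trial_type"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# --- ROI time series --------------------------------------------------------


def read_roits(path: str | Path) -> ROITimeSeries:
    """Read a ROI time-series TSV (column ``time`` plus one column per ROI)."""
    path = Path(path)
    df = _read_tsv(path, ["time"])
    roi_names = [c for c in df.columns if c != "time"]
    if not roi_names:
        raise ValidationError(f"{path}: no ROI columns beside 'time'")
    df = _numeric(df, list(df.columns), path)
    times = df["time"].to_numpy(float)
    if len(times) < 2:
        raise ValidationError(f"{path}: need at least 2 rows")
    steps = np.diff(times)
    if not (np.all(steps > 0) and np.allclose(steps, steps[0], atol=1e-6)):
        raise ValidationError(f"{path}: column 'time' must increase with a constant step")
    return ROITimeSeries(
        times=times,
        values=df[roi_names].to_numpy(float),
        roi_names=tuple(roi_names),
        tr=float(steps[0]),
        provenance=(f"read_roits({path.name})",),
    )


def write_roits(ts: ROITimeSeries, path: str | Path) -> None:
    df = pd.DataFrame(ts.values, columns=list(ts.roi_names))
    df.insert(0, "time", ts.times)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# --- nuisance ---------------------------------------------------------------


def read_nuisance(path: str | Path) -> np.ndarray:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    df = _numeric(df, list(df.columns), path)
    return df.to_numpy(float)


def write_nuisance(nuisance: np.ndarray, path: str | Path) -> None:
    cols = [f"nuisance_{i}" for i in range(nuisance.shape[1])]
    pd.DataFrame(nuisance, columns=cols).to_csv(path, sep="\t", index=False, float_format="%.10g")


# --- ground truth -----------------------------------------------------------


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "roi_names": list(truth.roi_names),
        "subnetwork_label": list(truth.subnetwork_label),
        "response_amplitude": {k: list(map(float, v)) for k, v in truth.response_amplitude.items()},
        "seed_name": truth.seed_name,
        "suppression_factor": truth.suppression_factor,
        "latent_coupling": truth.latent_coupling,
        "task_coupling": truth.task_coupling,
        "ar_coefficient": truth.ar_coefficient,
        "noise_sd": truth.noise_sd,
        "drift_slope": truth.drift_slope,
        "n_motion_regressors": truth.n_motion_regressors,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_truth(path: str | Path) -> GroundTruth:
    data = json.loads(Path(path).read_text())
    return GroundTruth(
        roi_names=tuple(data["roi_names"]),
        subnetwork_label=tuple(data["subnetwork_label"]),
        response_amplitude={k: np.asarray(v, float) for k, v in data["response_amplitude"].items()},
        seed_name=data["seed_name"],
        suppression_factor=data["suppression_factor"],
        latent_coupling=data["latent_coupling"],
        task_coupling=data.get("task_coupling", 0.0),
        ar_coefficient=data["ar_coefficient"],
        noise_sd=data["noise_sd"],
        drift_slope=data["drift_slope"],
        n_motion_regressors=data["n_motion_regressors"],
    )


# --- dataset bundle ---------------------------------------------------------


def write_dataset(ds: SyntheticDataset, outdir: str | Path, prefix: str = "run-1") -> dict:
    """Write the four text artifacts of one synthetic run; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ts = ROITimeSeries(
        times=ds.times, values=ds.signals, roi_names=tuple(ds.roi_names), tr=ds.design.tr
    )
    paths = {
        "signals": outdir / f"{prefix}_bold.tsv",
        "events": outdir / f"{prefix}_events.tsv",
        "nuisance": outdir / f"{prefix}_nuisance.tsv",
        "truth": outdir / f"{prefix}_truth.json",
    }
    write_roits(ts, paths["signals"])
    write_events(ds.design, paths["events"])
    write_nuisance(ds.nuisance, paths["nuisance"])
    write_truth(ds.truth, paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def read_dataset(outdir: str | Path, prefix: str = "run-1", rng_seed: int = 0) -> SyntheticDataset:
    outdir = Path(outdir)
    ts = read_roits(outdir / f"{prefix}_bold.tsv")
    truth = read_truth(outdir / f"{prefix}_truth.json")
    design = read_events(outdir / f"{prefix}_events.tsv", tr=ts.tr, n_volumes=ts.n_volumes)
    nuisance = read_nuisance(outdir / f"{prefix}_nuisance.tsv")
    return SyntheticDataset(design=design, signals=ts.values, nuisance=nuisance, truth=truth, rng_seed=rng_seed)


# --- volumes ----------------------------------------------------------------


def write_volume(volume: np.ndarray, labels: np.ndarray, bold_path: str | Path, mask_path: str | Path) -> None:
    """Write a 4-D float32 BOLD NIfTI and an integer ROI label mask NIfTI."""
    import nibabel as nib

    affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(volume, np.float32), affine), str(bold_path))
    nib.save(nib.Nifti1Image(np.asarray(labels, np.int16), affine), str(mask_path))


def read_volume(bold_path: str | Path, mask_path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a 4-D volume and label mask; returns (volume, labels, affine)."""
    import nibabel as nib

    img = nib.load(str(bold_path))
    mask = nib.load(str(mask_path))
    return np.asarray(img.dataobj, float), np.asarray(mask.dataobj).astype(int), img.affine
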