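"""Synthetic block-design BOLD generator.

Produces runs with the statistical structure the downstream analysis assumes:
HRF-convolved block responses per ROI, two (or more) planted subnetworks
sharing latent signals, a seed region whose evoked response and outgoing
coupling are suppressed during the heat+FUS condition, AR(1) noise, linear
drift and smooth motion-like nuisance regressors.  Everything is
bit-reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from ._validation import ValidationError, require
from .design import CONDITIONS, StimulusDesign, StimulusEvent

__all__ = [
    "StimulusDesign",
    "StimulusEvent",
    "GroundTruth",
    "SyntheticDataset",
    "default_design",
    "two_subnetwork_truth",
    "simulate_dataset",
    "simulate_volume",
    "evoked_signal",
]


def default_design(
    rng_seed: int,
    tr: float = 2.0,
    block_s: float = 16.0,
    rest_s: float = 30.0,
    repetitions: int = 7,
    conditions: tuple[str, ...] = CONDITIONS,
    lead_in_s: float = 30.0,
    n_volumes: int | None = None,
) -> StimulusDesign:
    """Interleaved block design: each condition repeated ``repetitions`` times
    in a seeded random order, 16-s blocks separated by 30-s rests.

    ``n_volumes`` defaults to the smallest count covering the full schedule
    including the final rest.  (With the default three conditions and seven
    repetitions the schedule spans 996 s, i.e. 498 volumes at TR 2 s.)
    """
    rng = np.random.default_rng(rng_seed)
    order = np.repeat(np.arange(len(conditions)), repetitions)
    rng.shuffle(order)
    events = []
    onset = lead_in_s
    for idx in order:
        events.append(StimulusEvent(onset=onset, duration=block_s, condition=conditions[idx]))
        onset += block_s + rest_s
    if n_volumes is None:
        n_volumes = int(np.ceil(onset / tr))
    return StimulusDesign(tr=tr, n_volumes=n_volumes, events=tuple(events))


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a synthetic run.

    ``response_amplitude`` maps condition -> per-ROI evoked amplitude (PSC
    units).  ROIs sharing the seed's ``subnetwork_label`` are "seed-coupled":
    under heat+FUS their evoked amplitude, their share of the subnetwork
    latent signal and their task-modulated drive from the seed are multiplied
    by ``1 - suppression_factor``.  ``task_coupling`` sets the strength of
    that drive (stimulus-gated transmission of the seed subnetwork's latent
    signal to the other members), the condition-dependent coupling the PPI
    regression estimates; it is scaled by ``latent_coupling`` so that
    ``latent_coupling = 0`` removes all shared structure.
    """

    roi_names: tuple[str, ...]
    subnetwork_label: tuple[int, ...]
    response_amplitude: dict  # condition -> array of len(roi_names)
    seed_name: str
    suppression_factor: float = 0.0
    latent_coupling: float = 1.0
    task_coupling: float = 0.8
    ar_coefficient: float = 0.3
    noise_sd: float = 0.5
    drift_slope: float = 0.0
    n_motion_regressors: int = 3

    def __post_init__(self) -> None:
        require(len(self.roi_names) > 0, "GroundTruth.roi_names must be non-empty")
        require(len(self.subnetwork_label) == len(self.roi_names), "subnetwork_label length mismatch")
        require(0 <= self.suppression_factor <= 1, "suppression_factor must be in [0, 1]")
        require(0 <= self.ar_coefficient < 1, "ar_coefficient must be in [0, 1)")
        require(self.noise_sd >= 0, "noise_sd must be >= 0")
        require(self.seed_name in self.roi_names, f"seed {self.seed_name!r} not among roi_names")
        for cond, amps in self.response_amplitude.items():
            require(cond in CONDITIONS, f"unknown condition {cond!r} in response_amplitude")
            require(len(amps) == len(self.roi_names), f"amplitude length mismatch for {cond!r}")

    @property
    def seed_index(self) -> int:
        return self.roi_names.index(self.seed_name)

    @property
    def seed_coupled(self) -> np.ndarray:
        """Boolean per-ROI: member of the seed's subnetwork."""
        labels = np.asarray(self.subnetwork_label)
        return labels == labels[self.seed_index]


def two_subnetwork_truth(
    n_rois: int = 10,
    suppression_factor: float = 0.6,
    latent_coupling: float = 1.0,
    task_coupling: float = 0.8,
    noise_sd: float = 0.5,
    heat_amplitude: tuple[float, float] = (1.0, 0.55),
    ar_coefficient: float = 0.3,
    drift_slope: float = 0.0,
    n_motion_regressors: int = 3,
) -> GroundTruth:
    """Convenience factory: two equal subnetworks, seed = first ROI.

    The two subnetworks differ in evoked amplitude (``heat_amplitude`` per
    subnetwork) so that response-shape features separate them.
    """
    require(n_rois >= 4, "need at least 4 ROIs for two subnetworks")
    names = tuple(f"roi{i:02d}" for i in range(n_rois))
    half = n_rois // 2
    labels = tuple([1] * half + [2] * (n_rois - half))
    amp = np.where(np.asarray(labels) == 1, heat_amplitude[0], heat_amplitude[1]).astype(float)
    return GroundTruth(
        roi_names=names,
        subnetwork_label=labels,
        response_amplitude={
            "heat": amp,
            "heat_fus": amp.copy(),
            "fus": np.zeros(n_rois),
        },
        seed_name=names[0],
        suppression_factor=suppression_factor,
        latent_coupling=latent_coupling,
        task_coupling=task_coupling,
        ar_coefficient=ar_coefficient,
        noise_sd=noise_sd,
        drift_slope=drift_slope,
        n_motion_regressors=n_motion_regressors,
    )


@dataclass
class SyntheticDataset:
    design: StimulusDesign
    signals: np.ndarray  # time x ROI
    nuisance: np.ndarray  # time x regressor
    truth: GroundTruth
    rng_seed: int

    def __post_init__(self) -> None:
        require(self.signals.shape[0] == self.design.n_volumes, "signal rows must equal n_volumes")

    @property
    def times(self) -> np.ndarray:
        return self.design.frame_times()

    @property
    def roi_names(self) -> list[str]:
        return list(self.truth.roi_names)


def evoked_signal(
    design: StimulusDesign, truth: GroundTruth, hrf_spec=None
) -> np.ndarray:
    """Noise-free evoked component per ROI (time x ROI).

    Seed-coupled ROIs have their heat+FUS amplitude multiplied by
    ``1 - suppression_factor``.
    """
    from .hrf_glm import HRFSpec, convolved_regressor  # deferred to avoid cycle

    if hrf_spec is None:
        hrf_spec = HRFSpec()
    times = design.frame_times()
    n, p = design.n_volumes, len(truth.roi_names)
    coupled = truth.seed_coupled
    out = np.zeros((n, p))
    for cond in design.conditions():
        amps = np.asarray(truth.response_amplitude.get(cond, np.zeros(p)), float).copy()
        if cond == "heat_fus":
            amps[coupled] *= 1.0 - truth.suppression_factor
        if not np.any(amps):
            continue
        reg = convolved_regressor(design, cond, hrf_spec, times)
        out += np.outer(reg, amps)
    return out


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float, size: int) -> np.ndarray:
    """Stationary AR(1) columns with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros((n, size))
    innov_sd = sd * np.sqrt(1.0 - phi**2) if phi > 0 else sd
    e = rng.normal(0.0, innov_sd, size=(n, size))
    x = np.empty((n, size))
    x[0] = rng.normal(0.0, sd, size=size)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + e[t]
    return x


def _smooth_series(rng: np.random.Generator, n: int, k: int, smooth_sigma: float = 5.0) -> np.ndarray:
    """Motion-like nuisance: gaussian-smoothed random walks, unit-scaled."""
    w = rng.normal(size=(n, k)).cumsum(axis=0)
    w = ndimage.gaussian_filter1d(w, smooth_sigma, axis=0, mode="nearest")
    w -= w.mean(axis=0)
    sd = w.std(axis=0)
    sd[sd == 0] = 1.0
    return w / sd


def simulate_dataset(
    design: StimulusDesign,
    truth: GroundTruth,
    rng_seed: int,
    nuisance_amplitude: float = 0.0,
    hrf_spec=None,
) -> SyntheticDataset:
    """Simulate one run.

    Per ROI the signal is the sum of
    (i) the evoked HRF response (seed-coupled amplitudes suppressed under
    heat+FUS),
    (ii) the subnetwork-shared latent Gaussian signal scaled by
    ``latent_coupling`` — non-seed members of the seed's subnetwork receive it
    scaled by ``1 - suppression_factor`` during heat+FUS cycles (the
    transmission, not the seed itself, is suppressed),
    (iii) for non-seed members of the seed's subnetwork, the stimulus-gated
    drive ``task_coupling * latent_coupling * conv(boxcar) * latent``, with
    the heat+FUS gate scaled by ``1 - suppression_factor`` (the
    condition-dependent coupling the PPI regression estimates),
    (iv) independent AR(1) noise, linear drift and optional leakage of the
    motion-like nuisance series.
    """
    from .hrf_glm import HRFSpec, convolved_regressor  # deferred to avoid cycle

    if hrf_spec is None:
        hrf_spec = HRFSpec()
    n, p = design.n_volumes, len(truth.roi_names)
    ss = np.random.SeedSequence(rng_seed)
    rng_latent, rng_noise, rng_motion = (np.random.default_rng(s) for s in ss.spawn(3))

    signals = evoked_signal(design, truth, hrf_spec)
    times = design.frame_times()

    # subnetwork-shared latent signals with suppressed transmission
    labels = np.asarray(truth.subnetwork_label)
    hf_mask = design.cycle_mask("heat_fus")
    seed_label = labels[truth.seed_index]
    keep = 1.0 - truth.suppression_factor
    for lab in np.unique(labels):
        latent = rng_latent.normal(size=n)
        members = labels == lab
        gain = np.full(n, truth.latent_coupling)
        if lab != seed_label:
            signals[:, members] += (gain * latent)[:, None]
            continue
        # the seed keeps its full latent signal; its targets receive it
        # attenuated during heat+FUS cycles
        target_gain = gain.copy()
        target_gain[hf_mask] *= keep
        for i in np.flatnonzero(members):
            g = gain if i == truth.seed_index else target_gain
            signals[:, i] += g * latent
        # stimulus-gated co-activation: active during blocks, suppressed for
        # the heat+FUS condition.  The seed carries its own gated modulation
        # (its response is what gets suppressed); the other members receive
        # the transmitted copy.
        if truth.task_coupling and truth.latent_coupling:
            gate = np.zeros(n)
            for cond, cond_keep in (("heat", 1.0), ("heat_fus", keep)):
                if design.events_of(cond):
                    gate += cond_keep * convolved_regressor(design, cond, hrf_spec, times)
            drive = truth.task_coupling * truth.latent_coupling * gate * latent
            signals[:, members] += drive[:, None]

    signals += _ar1(rng_noise, n, truth.ar_coefficient, truth.noise_sd, p)
    signals += (truth.drift_slope * np.arange(n))[:, None]

    nuisance = _smooth_series(rng_motion, n, truth.n_motion_regressors) if truth.n_motion_regressors else np.zeros((n, 0))
    if nuisance_amplitude and nuisance.shape[1]:
        weights = rng_motion.normal(scale=nuisance_amplitude, size=(nuisance.shape[1], p))
        signals += nuisance @ weights

    return SyntheticDataset(design=design, signals=signals, nuisance=nuisance, truth=truth, rng_seed=rng_seed)


def simulate_volume(
    dataset: SyntheticDataset,
    voxels_per_roi: int,
    grid_shape: tuple[int, int, int],
    voxel_noise_sd: float = 0.0,
    rng_seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Embed ROI time series into a 4-D grid as contiguous voxel patches.

    Each ROI occupies ``voxels_per_roi`` consecutive voxels along the first
    axis of its own row (rows are spaced by one to keep patches of different
    ROIs non-adjacent).  Every in-ROI voxel carries the ROI series plus
    independent Gaussian noise; background voxels carry noise only.

    Returns ``(volume, labels)`` where ``volume`` has shape
    ``grid_shape + (n_volumes,)`` and ``labels`` is an integer mask
    (0 = background, i+1 = ROI i).
    """
    nx, ny, nz = grid_shape
    p = len(dataset.roi_names)
    rows_available = ((ny + 1) // 2) * nz
    if voxels_per_roi > nx or p > rows_available:
        raise ValidationError(
            f"grid {grid_shape} too small for {p} ROIs of {voxels_per_roi} voxels"
        )
    rng = np.random.default_rng(dataset.rng_seed + 104729 if rng_seed is None else rng_seed)
    n = dataset.signals.shape[0]
    vol = rng.normal(0.0, voxel_noise_sd, size=(nx, ny, nz, n)) if voxel_noise_sd > 0 else np.zeros((nx, ny, nz, n))
    labels = np.zeros((nx, ny, nz), dtype=int)
    for i in range(p):
        row = i % ((ny + 1) // 2)
        slab = i // ((ny + 1) // 2)
        y, z = 2 * row, slab
        labels[:voxels_per_roi, y, z] = i + 1
        vol[:voxels_per_roi, y, z, :] += dataset.signals[:, i]
    return vol, labels
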