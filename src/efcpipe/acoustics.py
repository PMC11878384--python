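"""Pulsed focused-ultrasound dose arithmetic.

Duty cycle of a nested pulse scheme (fast pulses within slowly repeated
trains), time-averaged acoustic power, the cranial thermal index (TIC) and an
advisory lookup against configurable TIC/sonication-duration bands.

All functions return full-precision values; rounding for display is left to
callers and reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._validation import ValidationError, require

__all__ = [
    "PulseScheme",
    "TransducerSpec",
    "AdvisoryBand",
    "Advisory",
    "DEFAULT_ADVISORY_BANDS",
    "duty_cycle",
    "time_averaged_power",
    "thermal_index_cranial",
    "itrusst_advisory",
]


@dataclass(frozen=True)
class PulseScheme:
    """Nested pulse timing: fast pulses inside trains repeated at a slow rate.

    Parameters
    ----------
    pulse_duration : float
        Single pulse on-time in seconds.
    fast_prf : float
        Pulse repetition frequency within a train, Hz.
    train_duration : float
        Duration of one pulse train, seconds.
    slow_rate : float
        Train repetition rate, Hz.
    block_duration : float
        Duration of the whole stimulation block, seconds.
    ramp_duration : float
        Per-pulse cosine ramp duration, seconds. Recorded as metadata only;
        it does not enter the duty-cycle arithmetic.
    """

    pulse_duration: float
    fast_prf: float
    train_duration: float
    slow_rate: float
    block_duration: float = 16.0
    ramp_duration: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pulse_duration", "fast_prf", "train_duration", "slow_rate", "block_duration"):
            require(getattr(self, name) > 0, f"PulseScheme.{name} must be > 0")
        require(self.ramp_duration >= 0, "PulseScheme.ramp_duration must be >= 0")
        require(
            self.pulse_duration <= 1.0 / self.fast_prf + 1e-12,
            "PulseScheme.pulse_duration must not exceed 1/fast_prf",
        )
        require(
            self.train_duration <= 1.0 / self.slow_rate + 1e-12,
            "PulseScheme.train_duration must not exceed 1/slow_rate",
        )
        require(
            self.block_duration >= self.train_duration,
            "PulseScheme.block_duration must be >= train_duration",
        )


@dataclass(frozen=True)
class TransducerSpec:
    """Electrical and geometric description of the transducer.

    ``tic_coefficient`` is the standard 40 mW/cm denominator constant of the
    cranial thermal index.  ``transmission`` and ``target_pressure`` are
    metadata and do not enter any computation here.
    """

    electrical_power: float
    efficiency: float
    equivalent_aperture: float
    tic_coefficient: float = 40.0
    transmission: float = 0.39
    target_pressure: float | None = None

    def __post_init__(self) -> None:
        require(self.electrical_power >= 0, "TransducerSpec.electrical_power must be >= 0")
        require(0 < self.efficiency <= 1, "TransducerSpec.efficiency must be in (0, 1]")
        require(self.equivalent_aperture > 0, "TransducerSpec.equivalent_aperture must be > 0")
        require(self.tic_coefficient > 0, "TransducerSpec.tic_coefficient must be > 0")


def duty_cycle(scheme: PulseScheme) -> float:
    """Effective duty cycle of the block: fast duty times slow (train) duty.

    Returns ``(pulse_duration * fast_prf) * (train_duration * slow_rate)``,
    a dimensionless fraction in [0, 1].  Ramps are ignored.
    """
    fast = scheme.pulse_duration * scheme.fast_prf
    slow = scheme.train_duration * scheme.slow_rate
    return fast * slow


def time_averaged_power(spec: TransducerSpec, duty: float) -> float:
    """Time-averaged acoustic power in watts: electrical power x efficiency x duty."""
    require(0 <= duty <= 1, "duty must be in [0, 1]")
    return spec.electrical_power * spec.efficiency * duty


def thermal_index_cranial(acoustic_power: float, aperture: float, coefficient: float = 40.0) -> float:
    """Cranial thermal index: time-averaged power in mW over (coefficient x aperture).

    Parameters
    ----------
    acoustic_power : float
        Time-averaged acoustic power, watts (converted to mW internally).
    aperture : float
        Equivalent active aperture, cm.
    coefficient : float
        Denominator constant, mW/cm (default 40).
    """
    require(aperture > 0, "aperture must be > 0")
    require(coefficient > 0, "coefficient must be > 0")
    require(acoustic_power >= 0, "acoustic_power must be >= 0")
    return (acoustic_power * 1000.0) / (coefficient * aperture)


@dataclass(frozen=True)
class AdvisoryBand:
    """One row of the TIC advisory table: a closed TIC interval and its limit."""

    tic_low: float
    tic_high: float
    duration_limit: float  # seconds

    def contains(self, tic: float) -> bool:
        return self.tic_low <= tic <= self.tic_high


# Only the band actually quoted by the guidance we implement; other bands are
# user configuration, never invented here.
DEFAULT_ADVISORY_BANDS: tuple[AdvisoryBand, ...] = (AdvisoryBand(5.0, 6.0, 10.0),)


@dataclass(frozen=True)
class Advisory:
    """Result of the advisory lookup.

    ``band`` / ``duration_limit`` are ``None`` when the TIC falls outside every
    configured band, in which case ``compliant`` is also ``None`` (unknown).
    """

    tic: float
    sonication_duration: float
    band: AdvisoryBand | None
    duration_limit: float | None
    compliant: bool | None


def itrusst_advisory(
    tic: float,
    sonication_duration: float,
    bands: tuple[AdvisoryBand, ...] = DEFAULT_ADVISORY_BANDS,
) -> Advisory:
    """Map a TIC value to its configured duration-limit band and compliance flag."""
    require(tic >= 0, "tic must be >= 0")
    require(sonication_duration > 0, "sonication_duration must be > 0")
    for band in bands:
        if band.contains(tic):
            return Advisory(
                tic=tic,
                sonication_duration=sonication_duration,
                band=band,
                duration_limit=band.duration_limit,
                compliant=sonication_duration <= band.duration_limit,
            )
    return Advisory(tic, sonication_duration, band=None, duration_limit=None, compliant=None)


def dose_report(scheme: PulseScheme, spec: TransducerSpec, sonication_duration: float | None = None) -> dict:
    """Full dose arithmetic as a JSON-serializable dict (used by the CLI)."""
    duty = duty_cycle(scheme)
    tap = time_averaged_power(spec, duty)
    tic = thermal_index_cranial(tap, spec.equivalent_aperture, spec.tic_coefficient)
    duration = scheme.block_duration if sonication_duration is None else sonication_duration
    adv = itrusst_advisory(tic, duration)
    return {
        "duty": duty,
        "duty_pct": duty * 100.0,
        "tap_w": tap,
        "tic": tic,
        "advisory": {
            "sonication_duration_s": duration,
            "band": None if adv.band is None else [adv.band.tic_low, adv.band.tic_high],
            "duration_limit_s": adv.duration_limit,
            "compliant": adv.compliant,
        },
    }
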