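"""Synthetic calibration datasets and absorbance traces with known truth.

No public dataset exists for spectroelectrochemical gas-exposure traces
or thiolate calibration series, so fitting and trace analysis are
validated against simulated data whose ground truth is known exactly.

Two generators:

* :func:`simulate_trace` — an exposure-protocol absorbance trace: the
  mean is piecewise linear (absorbance rises at the programmed signal
  during gas-ON, holds during OFF, and ramps sharply back to baseline
  during an electrochemical RESET), with i.i.d. Gaussian photometric
  noise on top.  This emulates the three-exposure measurement protocol
  of the reference sensor; it does not emulate instrument drift,
  baseline wander or autocorrelated noise.
* :func:`simulate_rate_dataset` — initial rates on the second-order
  rate-law line ``v = k·[anion]·[receptor]`` plus Gaussian noise scaled
  to the largest rate, emulating a rate-vs-concentration calibration
  experiment.

Both are deterministic for a fixed seed (numpy ``default_rng``), and
both can write the CSV dialects consumed by :mod:`gasbiosense.kinetics`
with a JSON ground-truth sidecar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import AbsorbanceTrace, RateDataset, TraceEvent, reaction_rate
from .quantities import DomainError, Quantity, magnitude

__all__ = [
    "ExposureProtocol",
    "AbsorbanceTrace",
    "simulate_trace",
    "simulate_rate_dataset",
]


@dataclass(frozen=True)
class ExposureProtocol:
    """Timing of a repeated gas-exposure measurement.

    Defaults mirror a three-exposure protocol with a 60 s
    electrochemical reset between exposures; the ON/OFF durations
    (10 min / 2 min) are fixture choices at the scale typical of slow
    optical gas measurements.
    """

    n_exposures: int = 3
    on_duration_s: float = 600.0
    off_duration_s: float = 120.0
    reset_duration_s: float = 60.0
    baseline_au: float = 0.0

    def __post_init__(self) -> None:
        if self.n_exposures < 1:
            raise DomainError(f"n_exposures must be >= 1, got {self.n_exposures}")
        if min(self.on_duration_s, self.off_duration_s, self.reset_duration_s) <= 0:
            raise DomainError("all protocol durations must be > 0")


def simulate_trace(
    protocol: ExposureProtocol,
    true_signal: Quantity,
    noise_sd_au: float = 0.0,
    sampling_rate_hz: float = 1.0,
    seed: int = 0,
    max_absorbance_au: float | None = None,
) -> AbsorbanceTrace:
    """Simulate an annotated absorbance trace with programmed slope.

    ``true_signal`` is the ON-segment slope in AU/min (zeroth-order
    appearance of the reduced receptor — valid in the initial-rate
    regime).  ``max_absorbance_au`` optionally clips the mean at the
    full-reduction amplitude.  Gaussian noise of standard deviation
    ``noise_sd_au`` is added i.i.d. to every sample.
    """
    slope_au_s = magnitude(true_signal, "AU/min", "true_signal") / 60.0
    if slope_au_s < 0:
        raise DomainError(f"true_signal must be >= 0, got {true_signal}")
    if noise_sd_au < 0:
        raise DomainError(f"noise_sd_au must be >= 0, got {noise_sd_au}")
    if sampling_rate_hz <= 0:
        raise DomainError(f"sampling_rate_hz must be > 0, got {sampling_rate_hz}")

    dt = 1.0 / sampling_rate_hz
    cycle = protocol.on_duration_s + protocol.off_duration_s + protocol.reset_duration_s
    total = protocol.n_exposures * cycle
    times = np.arange(0.0, total + dt / 2, dt)
    mean = np.full_like(times, protocol.baseline_au)
    events = []
    for i in range(protocol.n_exposures):
        t_on = i * cycle
        t_off = t_on + protocol.on_duration_s
        t_reset = t_off + protocol.off_duration_s
        t_end = t_reset + protocol.reset_duration_s
        events += [
            TraceEvent(t_on, "ON"),
            TraceEvent(t_off, "OFF"),
            TraceEvent(t_reset, "RESET"),
        ]
        on = (times >= t_on) & (times < t_off)
        mean[on] = protocol.baseline_au + slope_au_s * (times[on] - t_on)
        plateau = protocol.baseline_au + slope_au_s * protocol.on_duration_s
        off = (times >= t_off) & (times < t_reset)
        mean[off] = plateau
        resetting = (times >= t_reset) & (times < t_end)
        # sharp linear decay back to baseline over the reset period
        mean[resetting] = plateau + (protocol.baseline_au - plateau) * (
            times[resetting] - t_reset
        ) / protocol.reset_duration_s
    mean[times >= protocol.n_exposures * cycle - dt / 2] = protocol.baseline_au
    if max_absorbance_au is not None:
        mean = np.minimum(mean, max_absorbance_au)
    rng = np.random.default_rng(seed)
    absorbance = mean + rng.normal(0.0, noise_sd_au, size=times.shape) if noise_sd_au else mean
    return AbsorbanceTrace(
        times_s=times,
        absorbances_au=absorbance,
        events=tuple(events),
        metadata={
            "generator": "gasbiosense.synthetic_data.simulate_trace",
            "true_signal_AU_per_min": slope_au_s * 60.0,
            "noise_sd_AU": noise_sd_au,
            "sampling_rate_Hz": sampling_rate_hz,
            "seed": seed,
            "noise_model": "iid Gaussian on absorbance",
            "protocol": {
                "n_exposures": protocol.n_exposures,
                "on_duration_s": protocol.on_duration_s,
                "off_duration_s": protocol.off_duration_s,
                "reset_duration_s": protocol.reset_duration_s,
                "baseline_AU": protocol.baseline_au,
            },
        },
    )


def simulate_rate_dataset(
    k_true: Quantity,
    receptor: Quantity,
    anion_concentrations: list,
    noise_fraction: float = 0.0,
    seed: int = 0,
) -> RateDataset:
    """Simulate an initial-rate calibration series on the rate-law line.

    Rates are ``v = k_true·[anion]·[receptor]`` plus Gaussian noise with
    standard deviation ``noise_fraction × max(v)``.  Concentrations may
    be plain molar floats or concentration quantities.
    """
    if magnitude(k_true, "uM^-1 s^-1", "k_true") <= 0:
        raise DomainError(f"k_true must be > 0, got {k_true}")
    if noise_fraction < 0:
        raise DomainError(f"noise_fraction must be >= 0, got {noise_fraction}")
    concs = [
        c.to("M") if isinstance(c, Quantity) else Quantity(float(c), "M")
        for c in anion_concentrations
    ]
    rates = np.array([reaction_rate(k_true, c, receptor).m_as("uM/s") for c in concs])
    if noise_fraction and rates.size:
        rng = np.random.default_rng(seed)
        rates = rates + rng.normal(0.0, noise_fraction * rates.max(), size=rates.shape)
    return RateDataset(
        anion_concentrations=tuple(concs),
        rates=tuple(float(r) for r in rates),
        receptor_concentration=receptor,
    )
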