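"""Step D — the signal-generating redox reaction and its rate analysis.

The optical signal originates from a bimolecular electron transfer
between the active anion and the oxidized receptor protein (thiolate →
cytochrome c in the reference scenario), with second-order rate law

    v = k · [anion] · [receptor_ox]        (v in μM/s, k in μM⁻¹ s⁻¹)

Three analyses live here:

* :func:`reaction_rate` — evaluate the rate law;
* :func:`fit_rate_constant` — recover k from initial-rate calibration
  data (rate vs anion concentration at fixed, excess receptor, i.e.
  pseudo-first-order in the anion);
* :func:`rate_from_trace` — extract per-exposure absorbance slopes from
  an annotated 550 nm time trace and convert them to concentration
  rates via the Beer–Lambert relation (slope / (Δε·d)).

Receptor consumption is assumed negligible over the analysis window
(initial-rate regime); a warning is emitted when the implied consumption
exceeds a configurable threshold.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantities import DomainError, Quantity, magnitude

__all__ = [
    "SensorSpec",
    "RateConstantFit",
    "RateDataset",
    "AbsorbanceTrace",
    "TraceEvent",
    "WindowPolicy",
    "TraceRateResult",
    "DegenerateDesignError",
    "AnalysisError",
    "reaction_rate",
    "fit_rate_constant",
    "rate_from_trace",
]

logger = logging.getLogger(__name__)

FIT_MODES = ("free_intercept", "through_origin")
EVENT_KINDS = ("ON", "OFF", "RESET")


class DegenerateDesignError(ValueError):
    """Calibration design cannot identify a slope (no concentration spread)."""


class AnalysisError(ValueError):
    """A trace contains no usable exposure segment."""


@dataclass(frozen=True)
class SensorSpec:
    """Geometry and optics of the layered optical biosensor.

    ``receptor_concentration`` is the *effective bulk* concentration of
    the immobilized receptor: total immobilized amount divided by the
    geometric volume of the porous sensing layer, treated as homogeneous
    for kinetics.  ``sensing_layer_thickness`` doubles as the optical
    path through the receptor layer.  ``effective_delta_epsilon`` is the
    reduced-minus-oxidized difference absorption coefficient at the
    readout wavelength.
    """

    receptor_concentration: Quantity
    sensing_layer_thickness: Quantity
    cover_layer_thickness: Quantity
    effective_delta_epsilon: Quantity

    def __post_init__(self) -> None:
        for name, unit in (
            ("receptor_concentration", "M"),
            ("sensing_layer_thickness", "m"),
            ("cover_layer_thickness", "m"),
            ("effective_delta_epsilon", "mM^-1 cm^-1"),
        ):
            if magnitude(getattr(self, name), unit, name) <= 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def total_liquid_depth(self) -> Quantity:
        """Cover plus sensing layer — the diffusion depth x_max."""
        return Quantity(
            self.cover_layer_thickness.m_as("m")
            + self.sensing_layer_thickness.m_as("m"),
            "m",
        )


@dataclass(frozen=True)
class RateConstantFit:
    """Result of a linear rate-vs-concentration fit.

    ``k`` = slope / receptor concentration, in μM⁻¹ s⁻¹.
    ``r_squared`` is the ordinary coefficient of determination
    (uncentred for through-origin fits, so it stays in [0, 1]).
    """

    k: Quantity
    intercept: Quantity
    r_squared: float
    n_points: int
    mode: str


@dataclass(frozen=True)
class RateDataset:
    """Initial-rate calibration data: rate vs active anion concentration.

    CSV dialect: columns ``anion_concentration_M``, ``rate_uM_per_s``.
    """

    anion_concentrations: tuple
    rates: tuple
    receptor_concentration: Quantity

    def __post_init__(self) -> None:
        concs = tuple(Quantity(c, "M") if not isinstance(c, Quantity) else c.to("M")
                      for c in self.anion_concentrations)
        rates = tuple(Quantity(r, "uM/s") if not isinstance(r, Quantity) else r.to("uM/s")
                      for r in self.rates)
        object.__setattr__(self, "anion_concentrations", concs)
        object.__setattr__(self, "rates", rates)
        if len(concs) != len(rates):
            raise DomainError("concentration and rate columns differ in length")
        if any(c.value < 0 for c in concs):
            raise DomainError("anion concentrations must be >= 0")
        if magnitude(self.receptor_concentration, "M", "receptor_concentration") <= 0:
            raise DomainError("receptor_concentration must be > 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "anion_concentration_M": [c.m_as("M") for c in self.anion_concentrations],
                "rate_uM_per_s": [r.m_as("uM/s") for r in self.rates],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, receptor_concentration: Quantity) -> "RateDataset":
        df = pd.read_csv(path)
        missing = {"anion_concentration_M", "rate_uM_per_s"} - set(df.columns)
        if missing:
            raise DomainError(f"rate dataset CSV missing columns {sorted(missing)}")
        return cls(
            anion_concentrations=tuple(df["anion_concentration_M"].astype(float)),
            rates=tuple(df["rate_uM_per_s"].astype(float)),
            receptor_concentration=receptor_concentration,
        )


@dataclass(frozen=True)
class TraceEvent:
    """An annotated instant on a trace: gas switched ON/OFF or a RESET
    (electrochemical re-oxidation of the receptor to restore baseline)."""

    time_s: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise DomainError(f"event kind must be one of {EVENT_KINDS}, got {self.kind!r}")


@dataclass(frozen=True)
class AbsorbanceTrace:
    """A sampled absorbance-vs-time record with exposure annotations.

    CSV dialect: columns ``time_s``, ``absorbance_AU`` and an ``event``
    column that is empty except at event rows (values ON/OFF/RESET).
    ``metadata`` carries generator provenance (sampling rate, noise sd,
    programmed ground-truth slope) when the trace is synthetic.
    """

    times_s: np.ndarray
    absorbances_au: np.ndarray
    events: tuple = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        a = np.asarray(self.absorbances_au, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "absorbances_au", a)
        if t.shape != a.shape or t.ndim != 1:
            raise DomainError("times and absorbances must be 1-D and equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise DomainError("trace times must be strictly increasing")
        if t.size:
            for ev in self.events:
                if not (t[0] <= ev.time_s <= t[-1]):
                    raise DomainError(
                        f"event {ev.kind} at {ev.time_s} s outside trace range"
                    )

    def to_frame(self) -> pd.DataFrame:
        event_col = [""] * len(self.times_s)
        for ev in self.events:
            idx = int(np.argmin(np.abs(self.times_s - ev.time_s)))
            event_col[idx] = ev.kind
        return pd.DataFrame(
            {
                "time_s": self.times_s,
                "absorbance_AU": self.absorbances_au,
                "event": event_col,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
        meta_path = str(path) + ".meta.json"
        with open(meta_path, "w") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True)

    @classmethod
    def from_csv(cls, path) -> "AbsorbanceTrace":
        df = pd.read_csv(path, keep_default_na=False)
        missing = {"time_s", "absorbance_AU"} - set(df.columns)
        if missing:
            raise DomainError(f"trace CSV missing columns {sorted(missing)}")
        events = []
        if "event" in df.columns:
            for _, row in df[df["event"].astype(str).str.len() > 0].iterrows():
                events.append(TraceEvent(float(row["time_s"]), str(row["event"])))
        metadata = {}
        try:
            with open(str(path) + ".meta.json") as fh:
                metadata = json.load(fh)
        except OSError:
            pass
        return cls(
            times_s=df["time_s"].to_numpy(float),
            absorbances_au=df["absorbance_AU"].to_numpy(float),
            events=tuple(events),
            metadata=metadata,
        )

    def exposure_segments(self) -> list[tuple[float, float]]:
        """(t_on, t_off) pairs from the event annotations, in order."""
        segments = []
        t_on = None
        for ev in sorted(self.events, key=lambda e: e.time_s):
            if ev.kind == "ON":
                t_on = ev.time_s
            elif ev.kind == "OFF" and t_on is not None:
                segments.append((t_on, ev.time_s))
                t_on = None
        return segments


@dataclass(frozen=True)
class WindowPolicy:
    """Which part of each ON→OFF segment enters the slope fit.

    ``settle_s`` drops the initial transient after gas-ON while the
    analyte front diffuses through the layer (the reference sensor
    equilibrates to >90 % in ~0.5 s, so 1 s is conservative);
    ``min_fit_duration_s`` skips segments whose remaining window is too
    short to support a slope estimate.
    """

    settle_s: float = 1.0
    min_fit_duration_s: float = 5.0


@dataclass(frozen=True)
class TraceRateResult:
    """Per-exposure absorbance slopes and the derived concentration rates."""

    signals_au_per_min: tuple
    rates_um_per_s: tuple
    mean_signal: Quantity
    sd_signal: Quantity | None  # None when only one exposure (sd undefined)
    mean_rate: Quantity
    sd_rate: Quantity | None


def reaction_rate(k: Quantity, anion: Quantity, receptor: Quantity) -> Quantity:
    """Second-order rate ``v = k·[anion]·[receptor]`` in μM/s.

    With k = 2.8 × 10⁻³ μM⁻¹s⁻¹, 0.02 μM anion and 10 mM receptor this
    evaluates to 0.56 μM/s (the reference prediction's ≈0.6 μM/s).
    """
    k_v = magnitude(k, "uM^-1 s^-1", "k")
    a = magnitude(anion, "M", "anion") * 1e6  # -> uM
    r = magnitude(receptor, "M", "receptor") * 1e6  # -> uM
    if k_v < 0 or a < 0 or r < 0:
        raise DomainError("k, anion and receptor concentrations must be >= 0")
    return Quantity(k_v * a * r, "uM/s")


def fit_rate_constant(data: RateDataset, mode: str = "free_intercept") -> RateConstantFit:
    """Least-squares estimate of the second-order rate constant k.

    Fits rate (μM/s) against anion concentration (μM); the slope has
    units s⁻¹ (a pseudo-first-order constant at fixed receptor) and is
    divided by the receptor concentration to give k in μM⁻¹ s⁻¹.
    ``through_origin`` constrains the intercept to zero as the rate law
    demands; ``free_intercept`` (default) leaves it free and reports it.
    """
    if mode not in FIT_MODES:
        raise ValueError(f"mode must be one of {FIT_MODES}, got {mode!r}")
    x = np.array([c.m_as("M") * 1e6 for c in data.anion_concentrations])  # uM
    y = np.array([r.m_as("uM/s") for r in data.rates])
    if x.size < 2:
        raise DegenerateDesignError("need at least 2 calibration points")
    if np.ptp(x) == 0:
        raise DegenerateDesignError(
            "all anion concentrations identical; slope unidentifiable"
        )
    if mode == "free_intercept":
        design = np.column_stack([x, np.ones_like(x)])
        (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - (slope * x + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
    else:
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
        resid = y - slope * x
        ss_tot = float(np.sum(y**2))  # uncentred
    ss_res = float(np.sum(resid**2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    receptor_um = data.receptor_concentration.m_as("M") * 1e6
    fit = RateConstantFit(
        k=Quantity(float(slope) / receptor_um, "uM^-1 s^-1"),
        intercept=Quantity(float(intercept), "uM/s"),
        r_squared=r2,
        n_points=int(x.size),
        mode=mode,
    )
    logger.info(
        "Step D (fit, %s): slope %.4g 1/s over %d points -> k = %s (R^2 = %.4f)",
        mode, slope, fit.n_points, fit.k, r2,
    )
    return fit


def rate_from_trace(
    trace: AbsorbanceTrace,
    sensor: SensorSpec,
    window_policy: WindowPolicy = WindowPolicy(),
    consumption_warn_fraction: float = 0.05,
) -> TraceRateResult:
    """Extract reduction rates from an annotated absorbance trace.

    For each annotated ON→OFF exposure, the ordinary least-squares slope
    of absorbance vs time is taken over ``[t_on + settle, t_off]`` and
    converted to a concentration rate via ``v = slope / (Δε·d)`` with
    ``d`` the sensing-layer optical path.  Returns per-exposure values
    plus mean ± sample standard deviation (sd is None for one exposure).

    Segments with too short a window or fewer than two samples are
    skipped with a warning; a trace with no usable segment raises
    :class:`AnalysisError`.
    """
    segments = trace.exposure_segments()
    if not segments:
        raise AnalysisError("trace has no annotated ON->OFF exposure segment")
    eps = sensor.effective_delta_epsilon.m_as("mM^-1 cm^-1") * 1e-3  # uM^-1 cm^-1
    d_cm = sensor.sensing_layer_thickness.m_as("cm")
    receptor_um = sensor.receptor_concentration.m_as("M") * 1e6
    signals = []
    rates = []
    for i, (t_on, t_off) in enumerate(segments):
        t0 = t_on + window_policy.settle_s
        if t_off - t0 < window_policy.min_fit_duration_s:
            warnings.warn(
                f"exposure {i}: window [{t0:g}, {t_off:g}] s shorter than "
                f"{window_policy.min_fit_duration_s:g} s; segment skipped",
                UserWarning,
                stacklevel=2,
            )
            continue
        mask = (trace.times_s >= t0) & (trace.times_s <= t_off)
        if int(mask.sum()) < 2:
            warnings.warn(
                f"exposure {i}: fewer than 2 samples in window; segment skipped",
                UserWarning,
                stacklevel=2,
            )
            continue
        t = trace.times_s[mask]
        a = trace.absorbances_au[mask]
        slope_au_s = float(np.polyfit(t, a, 1)[0])
        rate_um_s = slope_au_s / (eps * d_cm)
        consumed_um = abs(rate_um_s) * (t[-1] - t[0])
        if consumed_um > consumption_warn_fraction * receptor_um:
            warnings.warn(
                f"exposure {i}: implied receptor consumption {consumed_um:.3g} uM "
                f"exceeds {consumption_warn_fraction:.0%} of the receptor pool; "
                "initial-rate assumption questionable",
                UserWarning,
                stacklevel=2,
            )
        signals.append(slope_au_s * 60.0)
        rates.append(rate_um_s)
    if not signals:
        raise AnalysisError("no exposure segment satisfied the window policy")
    sig = np.array(signals)
    rat = np.array(rates)
    sd = Quantity(float(np.std(sig, ddof=1)), "AU/min") if sig.size > 1 else None
    sd_r = Quantity(float(np.std(rat, ddof=1)), "uM/s") if rat.size > 1 else None
    result = TraceRateResult(
        signals_au_per_min=tuple(Quantity(s, "AU/min") for s in signals),
        rates_um_per_s=tuple(Quantity(r, "uM/s") for r in rates),
        mean_signal=Quantity(float(sig.mean()), "AU/min"),
        sd_signal=sd,
        mean_rate=Quantity(float(rat.mean()), "uM/s"),
        sd_rate=sd_r,
    )
    logger.info(
        "Trace analysis: %d usable exposures, mean signal %s (sd %s)",
        sig.size, result.mean_signal, result.sd_signal,
    )
    return result
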