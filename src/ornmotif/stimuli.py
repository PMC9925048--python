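"""Odor stimulus generation: pulses, pulse trains, and gamma-statistics plumes.

All stimuli are dimensionless valve traces (baseline 0, open valve 1) sampled
on the map-model time grid of h = 0.5 ms.  Naturalistic plumes alternate
odorized bursts and clean-air gaps whose durations follow gamma distributions
whose parameters depend on the distance between sensor and odor source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.signal import lfilter
from scipy.special import digamma

#: Map-model iteration step, seconds (0.5 ms).
H_STEP = 5e-4


@dataclass
class StimulusTrace:
    """Odor concentration trace on the map time grid.

    Parameters
    ----------
    samples : ndarray
        Concentration values, dimensionless, >= 0.
    dt : float
        Sample step in seconds; the map model requires ``H_STEP``.
    """

    samples: np.ndarray
    dt: float = H_STEP

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("stimulus samples must be a 1-D array")
        if np.any(self.samples < 0):
            raise ValueError("stimulus samples must be non-negative")

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return len(self.samples) * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt

    def lowpassed(self, tau: float) -> "StimulusTrace":
        """First-order low-pass of the valve trace (odor-delivery dynamics).

        ``tau`` is the relaxation time constant in seconds.
        """
        if tau <= 0:
            raise ValueError("tau must be positive")
        g = np.exp(-self.dt / tau)
        out = lfilter([1.0 - g], [1.0, -g], self.samples)
        return StimulusTrace(out, dt=self.dt)

    def to_text(self, path) -> None:
        np.savetxt(path, np.column_stack([self.times, self.samples]),
                   fmt="%.6f %.8g", header="time_s value")

    @classmethod
    def from_text(cls, path) -> "StimulusTrace":
        arr = np.loadtxt(path)
        t, v = arr[:, 0], arr[:, 1]
        dt = float(np.median(np.diff(t))) if len(t) > 1 else H_STEP
        return cls(v, dt=dt)


def _n_samples(duration: float, dt: float) -> int:
    n = int(round(duration / dt))
    if abs(n * dt - duration) > 1e-9:
        raise ValueError(f"duration {duration} s is not a multiple of the step {dt} s")
    return n


def square_pulse(onset: float, width: float, total: float, dt: float = H_STEP) -> StimulusTrace:
    """Single square odor pulse of unit concentration.

    Pulse is 1 on [onset, onset + width), 0 elsewhere.
    """
    if width < 0:
        raise ValueError("pulse width must be non-negative")
    if onset < 0 or onset + width > total + 1e-12:
        raise ValueError("pulse does not fit within the trace")
    s = np.zeros(_n_samples(total, dt))
    i0 = int(round(onset / dt))
    i1 = int(round((onset + width) / dt))
    s[i0:i1] = 1.0
    return StimulusTrace(s, dt=dt)


def pulse_train(n_pulses: int, width: float, ipi: float, total: float,
                onset: float = 0.0, dt: float = H_STEP) -> StimulusTrace:
    """Train of identical square pulses.

    ``ipi`` is the inter-pulse interval measured offset-to-onset, so pulse
    onsets are spaced ``width + ipi`` apart.
    """
    if n_pulses < 1:
        raise ValueError("need at least one pulse")
    span = onset + n_pulses * width + (n_pulses - 1) * ipi
    if span > total + 1e-12:
        raise ValueError(f"train of length {span} s exceeds total {total} s")
    s = np.zeros(_n_samples(total, dt))
    for k in range(n_pulses):
        t0 = onset + k * (width + ipi)
        i0 = int(round(t0 / dt))
        i1 = int(round((t0 + width) / dt))
        s[i0:i1] = 1.0
    return StimulusTrace(s, dt=dt)


def solve_gamma_shape(mu: float, geo: float, tol: float = 1e-12) -> float:
    """Solve for the gamma shape parameter from arithmetic and geometric means.

    For a gamma(k, theta) distribution the arithmetic mean is mu = k*theta and
    the geometric mean satisfies log(geo) = psi(k) + log(theta), so the shape k
    solves::

        log(k) - psi(k) = log(mu) - log(geo)

    with psi the digamma function.  The scale follows as theta = mu / k.
    """
    if not (mu > geo > 0):
        raise ValueError("need arithmetic mean > geometric mean > 0")
    rhs = np.log(mu) - np.log(geo)

    def f(log_k: float) -> float:
        k = np.exp(log_k)
        return np.log(k) - digamma(k) - rhs

    # log k - psi(k) decreases monotonically from +inf (k->0) to 0 (k->inf).
    return float(np.exp(brentq(f, -40.0, 40.0, xtol=tol, rtol=8.9e-16)))


def gamma_log_geo_mean(k: float, theta: float) -> float:
    """log of the geometric mean of gamma(k, theta): psi(k) + log(theta)."""
    return float(digamma(k) + np.log(theta))


@dataclass
class GammaDurations:
    """Gamma-distributed segment durations (seconds)."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be positive")

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def geometric_mean(self) -> float:
        return float(np.exp(gamma_log_geo_mean(self.shape, self.scale)))


@dataclass
class PlumeSpec:
    """Plume statistics for a given sensor-to-source distance."""

    distance_m: str
    burst_len: GammaDurations
    inter_burst: GammaDurations

    @property
    def burst_frequency(self) -> float:
        """Mean number of odor bursts per second."""
        return 1.0 / (self.burst_len.mean + self.inter_burst.mean)


# Burst-length / inter-burst gamma parameters per distance to source.  The
# numeric values follow open-field tracer-plume phenomenology: close to the
# source the plume flickers rapidly (short bursts, short gaps); with
# distance both burst durations and return times lengthen as the fine
# structure mixes out and large-scale meander dominates, so burst frequency
# falls monotonically.  Editable; see docs/methods.md for provenance.
_PRESET_TABLE: dict[str, dict[str, tuple[float, float]]] = {
    # label: {"burst": (shape, mean_s), "inter": (shape, mean_s)}
    "2.5": {"burst": (0.9, 0.25), "inter": (0.80, 0.50)},
    "5": {"burst": (0.85, 0.40), "inter": (0.75, 1.20)},
    "10": {"burst": (0.8, 0.70), "inter": (0.70, 2.80)},
    "20": {"burst": (0.75, 1.20), "inter": (0.65, 6.00)},
}

DISTANCES_M = tuple(_PRESET_TABLE)


def distance_preset(distance_m) -> PlumeSpec:
    """Return the plume spec for one of the measured distances (2.5/5/10/20 m)."""
    label = f"{float(distance_m):g}"
    if label not in _PRESET_TABLE:
        raise KeyError(
            f"unknown distance {distance_m!r}; available presets: {', '.join(_PRESET_TABLE)} (m)"
        )
    row = _PRESET_TABLE[label]
    kb, mb = row["burst"]
    ki, mi = row["inter"]
    return PlumeSpec(
        distance_m=label,
        burst_len=GammaDurations(kb, mb / kb),
        inter_burst=GammaDurations(ki, mi / ki),
    )


def load_preset_table(path) -> dict[str, PlumeSpec]:
    """Load a YAML preset table mapping distance label -> gamma parameters."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for label, row in raw.items():
        out[str(label)] = PlumeSpec(
            distance_m=str(label),
            burst_len=GammaDurations(row["burst_shape"], row["burst_scale"]),
            inter_burst=GammaDurations(row["inter_shape"], row["inter_scale"]),
        )
    return out


def generate_plume(spec: PlumeSpec, duration: float, seed: int,
                   dt: float = H_STEP) -> StimulusTrace:
    """Generate a binary plume trace of alternating gaps and bursts.

    Gap and burst durations are drawn iid from the spec's gamma distributions;
    the trace starts with a gap, is truncated at ``duration`` and is fully
    reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = _n_samples(duration, dt)
    s = np.zeros(n)
    pos = 0
    burst = False
    while pos < n:
        g = spec.burst_len if burst else spec.inter_burst
        length = max(1, int(round(rng.gamma(g.shape, g.scale) / dt)))
        if burst:
            s[pos:pos + length] = 1.0
        pos += length
        burst = not burst
    return StimulusTrace(s, dt=dt)


def segment_lengths(trace: StimulusTrace) -> tuple[np.ndarray, np.ndarray]:
    """Extract burst and gap durations (s) from a binary plume trace.

    Returns ``(burst_lengths, gap_lengths)``; the leading and trailing
    (truncated) segments are dropped.
    """
    s = (trace.samples > 0.5).astype(int)
    edges = np.flatnonzero(np.diff(s))
    if len(edges) < 2:
        return np.array([]), np.array([])
    runs = np.diff(edges) * trace.dt
    vals = s[edges[:-1] + 1]  # value of each interior run
    return runs[vals == 1], runs[vals == 0]
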