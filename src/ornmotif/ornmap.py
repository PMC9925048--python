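"""Map-based (difference-equation) ORN spiking model.

Each neuron is a two-variable discrete-time map iterated at h = 0.5 ms: a
fast variable ``x`` whose single-iteration excursion to x = 1 is a spike, and
a slow variable ``y`` controlling excitability and adaptation.  Odor input is
shaped into an input current ``I`` by motif-specific discrete-time filters and
coupled into the map through a fast path (beta, into the fast variable) and a
slow path (sigma_n, into the slow variable).  Channel noise is a discrete
Ornstein-Uhlenbeck (AR(1)) process.

Fast map::

    x_{n+1} = f_alpha(x_n, y_n + beta_n)

    f_alpha(x, u) = alpha*(1 - x) + u   if x <  -0.5
                    1                   if -0.5 <= x < 1     (spike)
                    -1                  if x >= 1            (reset)

Slow map::

    y_{n+1} = y_n - mu * (1 + x_n - sigma - sigma_n)

Input coupling::

    beta_n  = beta_xi  * xi_n + beta_r  * I_n    (fast path)
    sigma_n = sigma_xi * xi_n + sigma_r * I_n    (slow path)

Noise::

    xi_{n+1} = q * xi_n - p * w_n,   q = exp(-h/tau_c),  p = d*sqrt(1 - q^2)

so the stationary standard deviation of xi equals d and its correlation time
equals tau_c.

Gain placement.  The fast path carries the input current at unit gain
(beta_r = 1) and the small per-motif coefficient sets the slow-path
(adaptation) gain.  Fixed-point analysis of the two-variable map shows this
is the only placement under which the four motifs behave as documented: the
slow variable drains during fast-driven excitatory firing (the onset peak
decelerates back toward baseline and decrements over pulse trains) and
charges toward a bounded level while the fast path holds an offset/inhibited
cell below threshold (a post-stimulus rebound whose size grows with the
slow-path gain: 0.2 for offset > 0.1 for inhibited).  See docs/methods.md
for the full argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.signal import lfilter

from ornmotif.stimuli import H_STEP, StimulusTrace

MOTIFS = ("excitatory", "delayed", "offset", "inhibitory")

#: Map iteration step in milliseconds.
H_MS = H_STEP * 1e3


def heaviside(x):
    """Heaviside step with the package convention H(0) = 0."""
    return np.where(np.asarray(x) > 0, 1.0, 0.0)


@dataclass(frozen=True)
class NoiseParams:
    """Discrete Ornstein-Uhlenbeck channel-noise parameters.

    tau_c : correlation time, ms.  d : stationary standard deviation of xi.
    beta_xi, sigma_xi : coupling gains of xi into the fast and slow paths.
    """

    tau_c: float = 3.0
    d: float = 0.01
    beta_xi: float = 1.0
    sigma_xi: float = 0.1

    @property
    def q(self) -> float:
        """AR(1) retention factor giving correlation time tau_c."""
        return float(np.exp(-H_MS / self.tau_c))

    @property
    def p(self) -> float:
        """Innovation gain; stationary std of xi equals d for unit-variance w."""
        q = self.q
        return float(self.d * np.sqrt(1.0 - q * q))

    def __post_init__(self):
        if self.tau_c <= 0 or self.d < 0:
            raise ValueError("tau_c must be positive and d non-negative")


@dataclass
class DelayedAux:
    """Auxiliary input currents of the delayed motif (I_d, h_p, I_p)."""

    I_d: float = 0.0
    h_p: float = 0.0
    I_p: float = 0.0


@dataclass
class MapNeuronState:
    """Full state of one map neuron between iterations."""

    x: float
    y: float
    I: float = 0.0
    xi: float = 0.0
    aux: Optional[DelayedAux] = None


# Intrinsic parameters alpha, sigma, mu are calibrated (scripts/calibrate_map.py)
# so that with the stated noise the baseline is low tonic firing (~2-5 spikes/s)
# and gain-1 pulse responses show the four motif shapes and their adaptation
# directions; see docs/methods.md.  The input-shaping gain pairs are the
# published per-motif values with the unit gain on the fast path and the
# small gain on the slow (adaptation) path -- the only placement that
# reproduces the documented motif phenomenology (see module docstring).
_MOTIF_TABLE: dict[str, dict[str, float]] = {
    "excitatory": dict(a_s=0.039, gamma_s=0.995, beta_r=1.0, sigma_r=0.1),
    "inhibitory": dict(a_s=-0.02, gamma_s=0.998, beta_r=1.0, sigma_r=0.1),
    "offset": dict(a_s=-0.04, gamma_s=0.998, beta_r=1.0, sigma_r=0.2),
    "delayed": dict(
        a_s=0.0, gamma_s=0.999, beta_r=1.0, sigma_r=0.01,
        a_p=0.08, gamma_p=0.999, a_d=0.8, gamma_d=0.99, gamma_h=0.99985, L=-0.04,
    ),
}

_INTRINSIC_DEFAULTS: dict[str, dict[str, float]] = {
    # frozen output of scripts/calibrate_map.py
    "excitatory": dict(alpha=0.01, sigma=0.473, mu=2.0e-3),
    "delayed": dict(alpha=0.01, sigma=0.473, mu=5.0e-3),
    "offset": dict(alpha=0.01, sigma=0.473, mu=3.0e-4),
    "inhibitory": dict(alpha=0.01, sigma=0.472, mu=1.0e-5),
}


@dataclass
class MotifParams:
    """Per-motif map and input-shaping parameters.

    ``alpha``, ``sigma``, ``mu`` are the intrinsic map parameters (baseline
    state, spiking regime and slow timescale); ``a_s``/``gamma_s`` the
    low-pass input gain and relaxation; ``beta_r``/``sigma_r`` the fast/slow
    input coupling gains.  The delayed motif replaces the simple low-pass with
    a high-pass/low-pass cascade parameterized by ``a_p, gamma_p, a_d,
    gamma_d, gamma_h, L``.
    """

    motif: str
    alpha: float
    sigma: float
    mu: float
    a_s: float
    gamma_s: float
    beta_r: float
    sigma_r: float
    a_p: Optional[float] = None
    gamma_p: Optional[float] = None
    a_d: Optional[float] = None
    gamma_d: Optional[float] = None
    gamma_h: Optional[float] = None
    L: Optional[float] = None

    def __post_init__(self):
        if self.motif not in MOTIFS:
            raise ValueError(f"unknown motif {self.motif!r}; expected one of {MOTIFS}")
        if not (0.0 < self.mu < 1.0):
            raise ValueError("mu must lie in (0, 1)")
        if not (0.0 < self.gamma_s < 1.0):
            raise ValueError("gamma_s must lie in (0, 1)")
        if self.motif == "delayed":
            for name in ("a_p", "gamma_p", "a_d", "gamma_d", "gamma_h", "L"):
                if getattr(self, name) is None:
                    raise ValueError(f"delayed motif requires {name}")
            for name in ("gamma_p", "gamma_d", "gamma_h"):
                if not (0.0 < getattr(self, name) < 1.0):
                    raise ValueError(f"{name} must lie in (0, 1)")
        else:
            if any(getattr(self, n) is not None
                   for n in ("a_p", "gamma_p", "a_d", "gamma_d", "gamma_h", "L")):
                raise ValueError("delayed-only parameters set on a non-delayed motif")

    @classmethod
    def for_motif(cls, motif: str, **overrides) -> "MotifParams":
        """Default parameters for a motif (published table + calibrated intrinsics)."""
        if motif not in MOTIFS:
            raise ValueError(f"unknown motif {motif!r}; expected one of {MOTIFS}")
        kwargs = dict(_MOTIF_TABLE[motif])
        kwargs.update(_INTRINSIC_DEFAULTS[motif])
        kwargs.update(overrides)
        return cls(motif=motif, **kwargs)

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}

    @classmethod
    def from_dict(cls, d: dict) -> "MotifParams":
        return cls(**d)


def default_params() -> dict[str, MotifParams]:
    """Default parameter set for all four motifs."""
    return {m: MotifParams.for_motif(m) for m in MOTIFS}


def params_to_yaml(path, params: Optional[dict[str, MotifParams]] = None,
                   noise: Optional[NoiseParams] = None) -> None:
    """Serialize motif and noise parameters to a YAML config."""
    params = params or default_params()
    noise = noise or NoiseParams()
    payload = {
        "noise": {k: getattr(noise, k) for k in ("tau_c", "d", "beta_xi", "sigma_xi")},
        "motifs": {m: p.to_dict() for m, p in params.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def params_from_yaml(path) -> tuple[dict[str, MotifParams], NoiseParams]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    noise = NoiseParams(**payload.get("noise", {}))
    motifs = {m: MotifParams.from_dict(d) for m, d in payload["motifs"].items()}
    return motifs, noise


# ---------------------------------------------------------------------------
# Elementary map operations
# ---------------------------------------------------------------------------

def map_f(x, u, alpha):
    """Discontinuous fast map f_alpha(x, u).

    alpha*(1-x)+u below -0.5; the spike value 1 on [-0.5, 1); reset -1 above.
    """
    x = np.asarray(x, dtype=float)
    return np.where(x >= 1.0, -1.0,
                    np.where(x >= -0.5, 1.0, alpha * (1.0 - x) + u))


def slow_update(y, x, sigma, sigma_n, mu):
    """One step of the slow variable: y' = y - mu*(1 + x - sigma - sigma_n).

    The drift vanishes when the running mean of x equals sigma - 1 + sigma_n,
    so the slow variable steers the time-averaged fast activity toward an
    input-shifted set point.  Because the fast path drives x directly and
    more strongly (unit gain), y acts as an adaptation variable: it drains
    while fast input holds firing above the set point (excitatory onset peaks
    decelerate and decrement over pulse trains) and charges while fast input
    pins the cell below it (offset/inhibited cells rebound after stimulus
    release).  See docs/methods.md for the sign/grouping rationale.
    """
    return y - mu * (1.0 + x - sigma - sigma_n)


def step_noise(xi, params: NoiseParams, w):
    """One AR(1) step of the OU noise state: xi' = q*xi - p*w."""
    return params.q * xi - params.p * w


def couple_inputs(xi, I, params: MotifParams, noise: NoiseParams):
    """Fast and slow input variables (beta_n, sigma_n) from noise and current."""
    beta_n = noise.beta_xi * xi + params.beta_r * I
    sigma_n = noise.sigma_xi * xi + params.sigma_r * I
    return beta_n, sigma_n


def shape_input_simple(I, s, params: MotifParams):
    """First-order low-pass input current update for the three simple motifs."""
    if params.motif == "delayed":
        raise ValueError("shape_input_simple is undefined for the delayed motif; "
                         "use shape_input_delayed")
    return params.gamma_s * I + (1.0 - params.gamma_s) * params.a_s * s


def shape_input_delayed(aux: DelayedAux, s_now, s_prev, params: MotifParams):
    """One step of the delayed-motif input cascade; returns (aux', I).

    A fast high-pass (I_d) of the stimulus increment forms a short negative
    pulse at response onset; a slow high-pass envelope (h_p) gated by the
    stimulus feeds a slow low-pass (I_p) that carries the delayed excitation.
    The mixed current I_M = I_p - H(I_d)*I_d is passed when above the depth
    limit L and zeroed otherwise (H(0) = 0 convention).
    """
    if params.motif != "delayed":
        raise ValueError("shape_input_delayed requires the delayed motif")
    ds = s_now - s_prev
    I_d = params.gamma_d * aux.I_d + params.a_d * ds
    h_p = params.gamma_h * aux.h_p + ds
    I_p = params.gamma_p * aux.I_p + (1.0 - params.gamma_p) * params.a_p * s_now * h_p
    I_M = I_p - (I_d if I_d > 0 else 0.0)
    I = I_M if I_M > params.L else 0.0
    return DelayedAux(I_d=I_d, h_p=h_p, I_p=I_p), I


# ---------------------------------------------------------------------------
# Trace-level input currents (vectorized over time and neurons)
# ---------------------------------------------------------------------------

def input_current_trace(params: MotifParams, samples: np.ndarray,
                        gains: Optional[np.ndarray] = None) -> np.ndarray:
    """Input current I_n for a full stimulus trace.

    ``gains`` scales the effective stimulus per neuron (odor-response
    efficacy); returns shape (T,) without gains or (T, N) with gains.
    """
    samples = np.asarray(samples, dtype=float)
    if gains is None:
        s_eff = samples
    else:
        s_eff = samples[:, None] * np.asarray(gains, dtype=float)[None, :]
    if params.motif != "delayed":
        b = [0.0, (1.0 - params.gamma_s) * params.a_s]
        return lfilter(b, [1.0, -params.gamma_s], s_eff, axis=0)
    ds = np.diff(s_eff, axis=0, prepend=np.zeros((1,) + s_eff.shape[1:]))
    I_d = lfilter([0.0, params.a_d], [1.0, -params.gamma_d], ds, axis=0)
    h_p_next = lfilter([1.0], [1.0, -params.gamma_h], ds, axis=0)
    drive = s_eff * h_p_next
    I_p = lfilter([0.0, (1.0 - params.gamma_p) * params.a_p],
                  [1.0, -params.gamma_p], drive, axis=0)
    I_M = I_p - np.where(I_d > 0.0, I_d, 0.0)
    return np.where(I_M > params.L, I_M, 0.0)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _check_stimulus(stimulus: StimulusTrace) -> None:
    if abs(stimulus.dt - H_STEP) > 1e-12:
        raise ValueError(
            f"stimulus sampled at {stimulus.dt} s; the map model requires h = {H_STEP} s"
        )


def _rest_state(alpha: float, sigma) -> tuple[np.ndarray, np.ndarray]:
    """Quiescent fixed point: x* = sigma - 1 with y at the matching value."""
    x0 = np.asarray(sigma) - 1.0
    y0 = x0 * (1.0 + alpha) - alpha
    return x0, y0


def simulate_batch(
    params: MotifParams,
    stimulus: StimulusTrace,
    gains: np.ndarray,
    n_trials: int = 1,
    seed: int = 0,
    noise: Optional[NoiseParams] = None,
    sigma_jitter: float = 0.0,
    sigma_offsets: Optional[np.ndarray] = None,
    neuron_ids: Optional[np.ndarray] = None,
    chunk: int = 1024,
) -> np.ndarray:
    """Simulate a batch of same-motif neurons over a shared stimulus.

    Each (neuron, trial) gets an independent noise stream derived from
    ``seed`` and its global neuron id, so results do not depend on how a
    population is split into batches.  Baseline heterogeneity comes either
    from explicit per-neuron ``sigma_offsets`` (a fixed property of the
    population, stable across stimuli and seeds) or from a ``sigma_jitter``
    width drawn per neuron id.  Returns an event array of shape
    (n_events, 3) with columns (neuron_index, trial, spike_time_s), where
    neuron_index refers to the position within ``gains``.
    """
    _check_stimulus(stimulus)
    noise = noise or NoiseParams()
    gains = np.atleast_1d(np.asarray(gains, dtype=float))
    if np.any((gains < 0) | (gains > 1)):
        raise ValueError("gains must lie in [0, 1]")
    n_neurons = len(gains)
    if n_neurons == 0:
        raise ValueError("empty batch")
    if neuron_ids is None:
        neuron_ids = np.arange(n_neurons)
    neuron_ids = np.asarray(neuron_ids, dtype=np.int64)

    T = len(stimulus.samples)
    I_all = input_current_trace(params, stimulus.samples, gains)  # (T, N)

    # per-neuron baseline heterogeneity
    if sigma_offsets is not None:
        sigma_i = params.sigma + np.asarray(sigma_offsets, dtype=float)
        if len(sigma_i) != n_neurons:
            raise ValueError("sigma_offsets must match the number of neurons")
    else:
        sigma_i = np.empty(n_neurons)
        for j, nid in enumerate(neuron_ids):
            r = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(int(nid), 2**20)))
            sigma_i[j] = params.sigma + sigma_jitter * r.standard_normal()

    q, p = noise.q, noise.p
    alpha, mu = params.alpha, params.mu
    bxi, sxi = noise.beta_xi, noise.sigma_xi
    br, sr = params.beta_r, params.sigma_r

    ev_neuron: list[np.ndarray] = []
    ev_trial: list[np.ndarray] = []
    ev_step: list[np.ndarray] = []

    cols = [(j, t) for t in range(n_trials) for j in range(n_neurons)]
    for lo in range(0, len(cols), chunk):
        sub = cols[lo:lo + chunk]
        B = len(sub)
        jj = np.array([c[0] for c in sub])
        tt = np.array([c[1] for c in sub])
        # independent OU noise per (neuron, trial), precomputed as an AR(1) filter
        W = np.empty((T, B))
        for b, (j, t) in enumerate(sub):
            r = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(int(neuron_ids[j]), int(t))))
            W[:, b] = r.standard_normal(T)
        xi = lfilter([0.0, -p], [1.0, -q], W, axis=0)  # xi[n] uses w up to n-1
        I = I_all[:, jj]
        sig_b = sigma_i[jj]
        x, y = _rest_state(alpha, sig_b)
        x = x.copy()
        y = y.copy()
        spike_steps: list[np.ndarray] = []
        spike_cols: list[np.ndarray] = []
        for n in range(T):
            beta_n = bxi * xi[n] + br * I[n]
            sigma_n = sxi * xi[n] + sr * I[n]
            x_new = np.where(x >= 1.0, -1.0,
                             np.where(x >= -0.5, 1.0, alpha * (1.0 - x) + y + beta_n))
            y -= mu * (1.0 + x - sig_b - sigma_n)
            x = x_new
            sp = np.flatnonzero(x == 1.0)
            if sp.size:
                spike_cols.append(sp)
                spike_steps.append(np.full(sp.size, n + 1))
        if spike_steps:
            cols_cat = np.concatenate(spike_cols)
            steps_cat = np.concatenate(spike_steps)
            ev_neuron.append(jj[cols_cat])
            ev_trial.append(tt[cols_cat])
            ev_step.append(steps_cat)

    if not ev_neuron:
        return np.empty((0, 3))
    out = np.column_stack([
        np.concatenate(ev_neuron).astype(float),
        np.concatenate(ev_trial).astype(float),
        np.concatenate(ev_step) * H_STEP,
    ])
    order = np.lexsort((out[:, 2], out[:, 1], out[:, 0]))
    return out[order]


def simulate_neuron(
    params: MotifParams,
    stimulus: StimulusTrace,
    gain: float = 1.0,
    seed: int = 0,
    noise: Optional[NoiseParams] = None,
) -> np.ndarray:
    """Simulate one neuron; returns spike times in seconds."""
    events = simulate_batch(params, stimulus, np.array([gain]), n_trials=1,
                            seed=seed, noise=noise)
    return events[:, 2]
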