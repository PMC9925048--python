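"""Whole-population ORN simulation and spike-train containers.

The population simulator is the study's synthetic-data generator: given a
set of ORN selectivity profiles with motif labels, an odor vector and a
stimulus trace, it produces one spike train per (neuron, trial), with trial
variability arising only from independent noise instantiations.  Spike
tables can be binned (50 ms default), smoothed into rates (Gaussian,
sigma = 50 ms), or generated directly from rate templates as surrogate
recordings for testing the analysis pipeline independently of the map model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from ornmotif import odorspace, ornmap
from ornmotif.odorspace import OdorVector, SelectivityProfile
from ornmotif.ornmap import MOTIFS, MotifParams, NoiseParams
from ornmotif.stimuli import StimulusTrace

DEFAULT_BIN_S = 0.05
DEFAULT_SMOOTH_SIGMA_S = 0.05
#: Baseline epoch used by the adaptation analysis: 2 s before first onset.
DEFAULT_BASELINE_S = 2.0


@dataclass
class PopulationSpec:
    """Selectivity profiles plus per-neuron motif labels (one odor condition)."""

    profiles: list[SelectivityProfile]
    motif_labels: np.ndarray
    params: Optional[dict[str, MotifParams]] = None
    sigma_offsets: Optional[np.ndarray] = None

    def __post_init__(self):
        self.motif_labels = np.asarray(self.motif_labels, dtype=object)
        if len(self.profiles) != len(self.motif_labels):
            raise ValueError("profiles and motif_labels must have equal length")
        if len(self.profiles) == 0:
            raise ValueError("empty population")
        if self.params is None:
            self.params = ornmap.default_params()
        if self.sigma_offsets is None:
            self.sigma_offsets = np.zeros(len(self.profiles))
        else:
            self.sigma_offsets = np.asarray(self.sigma_offsets, dtype=float)
            if len(self.sigma_offsets) != len(self.profiles):
                raise ValueError("sigma_offsets must match the population size")

    def __len__(self) -> int:
        return len(self.profiles)

    @classmethod
    def random(cls, n: int, seed: int = 0, proportions=None, p: float = 1.0,
               sigma_jitter: float = 0.002) -> "PopulationSpec":
        """Random population: uniform-octant selectivities, multinomial motifs,
        and fixed per-neuron baseline-excitability offsets of width
        ``sigma_jitter`` (drawn once; stable across stimuli and trials)."""
        rng = np.random.default_rng(seed + 2)
        return cls(
            profiles=odorspace.sample_selectivity(n, seed=seed, p=p),
            motif_labels=odorspace.assign_motifs(n, proportions, seed=seed + 1),
            sigma_offsets=sigma_jitter * rng.standard_normal(n),
        )


@dataclass
class SpikeTable:
    """Spike events as (neuron_id, trial, time_s) with experiment metadata."""

    events: pd.DataFrame
    n_neurons: int
    n_trials: int
    duration: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        req = ["neuron_id", "trial", "time_s"]
        if list(self.events.columns) != req:
            self.events = self.events[req]
        self.events = self.events.sort_values(req).reset_index(drop=True)
        if len(self.events) and (
                self.events.time_s.min() < 0 or self.events.time_s.max() > self.duration):
            raise ValueError("spike times outside [0, duration]")

    def spike_times(self, neuron_id: int, trial: int) -> np.ndarray:
        m = (self.events.neuron_id == neuron_id) & (self.events.trial == trial)
        return self.events.time_s[m].to_numpy()

    def to_text(self, path, meta_path=None) -> None:
        self.events.to_csv(path, sep="\t", index=False, float_format="%.6f")
        if meta_path is not None:
            payload = dict(self.meta, n_neurons=self.n_neurons,
                           n_trials=self.n_trials, duration=self.duration)
            with open(meta_path, "w") as fh:
                json.dump(payload, fh, indent=1, default=str)

    @classmethod
    def from_text(cls, path, n_neurons: int, n_trials: int, duration: float) -> "SpikeTable":
        df = pd.read_csv(path, sep="\t")
        return cls(df, n_neurons=n_neurons, n_trials=n_trials, duration=duration)


@dataclass
class BinnedResponse:
    """Spike counts per (neuron, trial, bin); bins are half-open [t, t+dt)."""

    counts: np.ndarray  # (n_neurons, n_trials, n_bins) int
    bin_width: float
    t0: float = 0.0

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def bin_centers(self) -> np.ndarray:
        return self.t0 + (np.arange(self.n_bins) + 0.5) * self.bin_width

    def trial_averaged(self) -> np.ndarray:
        """(n_neurons, n_bins) mean counts across trials."""
        return self.counts.mean(axis=1)

    def rates(self) -> np.ndarray:
        """(n_neurons, n_trials, n_bins) firing rates in spikes/s."""
        return self.counts / self.bin_width


@dataclass
class RateTrace:
    """Smoothed firing rates (spikes/s) on a regular grid.

    ``rate`` has shape (n_neurons, n_samples) for trial-averaged traces or
    (n_neurons, n_trials, n_samples) when per-trial traces are kept.
    """

    rate: np.ndarray
    dt: float
    smoothing_sigma: float = DEFAULT_SMOOTH_SIGMA_S

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.rate.shape[-1]) * self.dt


def simulate_population(
    orns: PopulationSpec,
    odor: OdorVector,
    stimulus: StimulusTrace,
    n_trials: int = 1,
    seed: int = 0,
    noise: Optional[NoiseParams] = None,
) -> SpikeTable:
    """Simulate every ORN of a population responding to one odor.

    Response magnitude per neuron is the angle-based efficacy of (profile,
    odor); temporal shape is set by the neuron's motif label.  Trials differ
    only in their noise instantiations and the whole table is a deterministic
    function of ``seed``.
    """
    n = len(orns)
    gains = odorspace.efficacies(orns.profiles, odor)
    frames = []
    for motif in MOTIFS:
        idx = np.flatnonzero(orns.motif_labels == motif)
        if idx.size == 0:
            continue
        events = ornmap.simulate_batch(
            orns.params[motif], stimulus, gains[idx], n_trials=n_trials,
            seed=seed, noise=noise, sigma_offsets=orns.sigma_offsets[idx],
            neuron_ids=idx,
        )
        if len(events) == 0:
            continue
        frames.append(pd.DataFrame({
            "neuron_id": idx[events[:, 0].astype(int)],
            "trial": events[:, 1].astype(int),
            "time_s": events[:, 2],
        }))
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=["neuron_id", "trial", "time_s"])
    meta = {
        "seed": seed,
        "odor": odor.v.tolist(),
        "motif_labels": orns.motif_labels.tolist(),
        "efficacies": gains.tolist(),
        "stimulus_duration": stimulus.duration,
    }
    return SpikeTable(df, n_neurons=n, n_trials=n_trials,
                      duration=stimulus.duration, meta=meta)


def bin_spikes(spikes: SpikeTable, bin_width: float = DEFAULT_BIN_S) -> BinnedResponse:
    """Bin spikes into half-open [t, t+dt) windows; trailing partial bin dropped."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.floor(spikes.duration / bin_width + 1e-9))
    counts = np.zeros((spikes.n_neurons, spikes.n_trials, n_bins), dtype=int)
    if len(spikes.events):
        b = np.floor(spikes.events.time_s.to_numpy() / bin_width).astype(int)
        keep = b < n_bins
        np.add.at(counts, (spikes.events.neuron_id.to_numpy()[keep],
                           spikes.events.trial.to_numpy()[keep], b[keep]), 1)
    return BinnedResponse(counts=counts, bin_width=bin_width)


def smooth_rate(
    spikes: SpikeTable,
    sigma: float = DEFAULT_SMOOTH_SIGMA_S,
    dt: float = 0.01,
    per_trial: bool = False,
) -> RateTrace:
    """Gaussian-smoothed firing rates (spikes/s), trial-averaged by default.

    The Gaussian kernel has unit area on the grid, so the integral of the
    rate approximates the mean spike count per trial.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    n_samples = int(round(spikes.duration / dt))
    shape = (spikes.n_neurons, spikes.n_trials, n_samples)
    counts = np.zeros(shape)
    if len(spikes.events):
        b = np.minimum((spikes.events.time_s.to_numpy() / dt).astype(int), n_samples - 1)
        np.add.at(counts, (spikes.events.neuron_id.to_numpy(),
                           spikes.events.trial.to_numpy(), b), 1.0)
    smoothed = gaussian_filter1d(counts / dt, sigma / dt, axis=-1, mode="constant")
    if not per_trial:
        smoothed = smoothed.mean(axis=1)
    return RateTrace(rate=smoothed, dt=dt, smoothing_sigma=sigma)


def motif_rate_templates(
    duration: float = 6.0,
    onset: float = 2.0,
    width: float = 1.0,
    dt: float = 0.01,
    baseline: float = 4.0,
    peak: float = 25.0,
) -> dict[str, np.ndarray]:
    """Canonical rate templates (spikes/s) of the four motifs for a square pulse.

    Used by the surrogate-recording generator: excitatory = sharp onset with
    fast decay; delayed = slow rise and fall; offset = suppression then
    post-offset rebound; inhibitory = suppression returning to baseline.
    """
    t = np.arange(int(round(duration / dt))) * dt
    rel = t - onset
    off = t - (onset + width)
    exc = baseline + peak * (rel >= 0) * np.exp(-np.maximum(rel, 0) / 0.25)
    delayed = baseline + 0.7 * peak * (rel >= 0.2) * (
        (1 - np.exp(-np.maximum(rel - 0.2, 0) / 0.4)) * np.exp(-np.maximum(rel - 0.2, 0) / 1.5))
    inhib = baseline - baseline * 0.9 * (
        ((rel >= 0) & (off < 0)) * 1.0 + (off >= 0) * np.exp(-np.maximum(off, 0) / 0.3))
    offset = baseline - baseline * 0.9 * ((rel >= 0) & (off < 0)) \
        + 0.8 * peak * (off >= 0) * np.exp(-np.maximum(off, 0) / 0.3)
    return {
        "excitatory": exc,
        "delayed": delayed,
        "offset": np.maximum(offset, 0.0),
        "inhibitory": np.maximum(inhib, 0.0),
    }


def surrogate_recordings(
    templates: dict[str, np.ndarray],
    n_pairs: int = 198,
    trials: int = 5,
    rate_jitter: float = 0.15,
    seed: int = 0,
    dt: float = 0.01,
    proportions=None,
) -> SpikeTable:
    """Template-plus-noise surrogate of an in vivo ORN-odor pair dataset.

    Each pair is assigned one of the motif rate templates (multinomial,
    equal by default), its template is scaled by a per-pair lognormal jitter
    of width ``rate_jitter``, and ``trials`` inhomogeneous-Poisson spike
    trains are drawn.  Ground-truth motif labels are stored in ``meta``.
    """
    names = list(templates)
    for name, tpl in templates.items():
        if np.any(np.asarray(tpl) < 0):
            raise ValueError(f"template {name!r} has negative rates")
    rng = np.random.default_rng(seed)
    if proportions is None:
        proportions = np.full(len(names), 1.0 / len(names))
    labels = rng.choice(len(names), size=n_pairs, p=np.asarray(proportions))
    T = len(next(iter(templates.values())))
    duration = T * dt
    rows_n, rows_t, rows_s = [], [], []
    for i in range(n_pairs):
        tpl = np.asarray(templates[names[labels[i]]], dtype=float)
        gain = np.exp(rate_jitter * rng.standard_normal() - 0.5 * rate_jitter ** 2)
        lam = tpl * gain * dt
        for tr in range(trials):
            counts = rng.poisson(lam)
            idx = np.repeat(np.arange(T), counts)
            if idx.size:
                times = (idx + rng.random(idx.size)) * dt
                rows_n.append(np.full(times.size, i))
                rows_t.append(np.full(times.size, tr))
                rows_s.append(np.sort(times))
    if rows_n:
        df = pd.DataFrame({
            "neuron_id": np.concatenate(rows_n),
            "trial": np.concatenate(rows_t),
            "time_s": np.concatenate(rows_s),
        })
    else:
        df = pd.DataFrame(columns=["neuron_id", "trial", "time_s"])
    meta = {"true_motif": [names[k] for k in labels], "seed": seed,
            "rate_jitter": rate_jitter}
    return SpikeTable(df, n_neurons=n_pairs, n_trials=trials,
                      duration=duration, meta=meta)
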