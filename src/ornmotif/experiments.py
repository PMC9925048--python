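"""Composed in-silico experiments of the study.

Each function wires together the stimulus generators, the population
simulator and one analysis pipeline, exposing the handful of parameters a
user would scan.  These are the entry points used by the acceptance script
and the heavier tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ornmotif import decoding, lnmodel, odorspace, population, stimuli
from ornmotif.odorspace import OdorVector
from ornmotif.ornmap import MOTIFS
from ornmotif.population import BinnedResponse, PopulationSpec

#: Pulse protocol of the single-odor experiments: 2 s baseline, 4 s odor,
#: 2 s recovery.
PULSE_ONSET_S = 2.0
PULSE_WIDTH_S = 4.0
PULSE_TOTAL_S = 8.0


def seeded_odor(seed: int) -> OdorVector:
    """A seeded random unit odor vector in the positive octant."""
    rng = np.random.default_rng(seed)
    return OdorVector(np.abs(rng.standard_normal(3)))


def _pulse_window_bins(binned: BinnedResponse) -> BinnedResponse:
    b0 = int(round(PULSE_ONSET_S / binned.bin_width))
    b1 = int(round((PULSE_ONSET_S + PULSE_WIDTH_S) / binned.bin_width))
    return BinnedResponse(binned.counts[:, :, b0:b1], binned.bin_width,
                          t0=PULSE_ONSET_S)


def simulate_pulse_response(
    n: int,
    proportions,
    seed: int,
    n_trials: int = 10,
    odor: Optional[OdorVector] = None,
    pulse_width: float = PULSE_WIDTH_S,
    motif_labels: Optional[np.ndarray] = None,
) -> tuple[PopulationSpec, BinnedResponse]:
    """Simulate a population's 50 ms-binned response to a single odor pulse."""
    pop = PopulationSpec.random(n, seed=seed,
                                proportions=np.asarray(proportions, dtype=float))
    if motif_labels is not None:
        pop.motif_labels = np.asarray(motif_labels, dtype=object)
    odor = odor or seeded_odor(seed + 1)
    total = PULSE_ONSET_S + pulse_width + 2.0
    stim = stimuli.square_pulse(PULSE_ONSET_S, pulse_width, total)
    table = population.simulate_population(pop, odor, stim, n_trials=n_trials,
                                           seed=seed + 2)
    return pop, population.bin_spikes(table)


def dimensionality_experiment(
    n: int = 1374,
    n_trials: int = 10,
    seed: int = 0,
    proportions_all=(0.25, 0.25, 0.25, 0.25),
) -> dict:
    """Population-PCA dimensionality of excitatory-only vs all-motif codes.

    PCA observations are per-trial 50 ms bins of the 4 s stimulus epoch;
    variables are neurons.  Returns first-component shares (percent) of both
    compositions and the number of components needed for 30% cumulative
    variance in the all-motif case.
    """
    out = {}
    for key, props in [("excitatory_only", (1.0, 0.0, 0.0, 0.0)),
                       ("all_motifs", tuple(proportions_all))]:
        _, binned = simulate_pulse_response(n, props, seed=seed, n_trials=n_trials)
        spec, _ = decoding.response_pca(_pulse_window_bins(binned))
        out[key] = {
            "pc1_percent": float(spec.fractions[0] * 100.0),
            "n_components_30": int(spec.n_components_for(0.30)),
            "spectrum_top10": (spec.fractions[:10] * 100.0).tolist(),
        }
    return out


def ln_filter_experiment(
    n: int = 50,
    n_trials: int = 5,
    seed: int = 0,
    motif: str = "excitatory",
    duration: float = 40.0,
    distance_m: float = 2.5,
    train_span: tuple[float, float] = (0.0, 16.0),
) -> dict:
    """Mean LN filter of one motif's ORNs driven by a 40 s plume.

    Returns the motif-averaged filter, its peak delay (s), and the per-ORN
    filters.  Rates are trial-averaged and smoothed (sigma = 50 ms) before
    deconvolution.
    """
    import pandas as pd

    from ornmotif import ornmap

    plume = stimuli.generate_plume(stimuli.distance_preset(distance_m), duration,
                                   seed=seed + 10)
    params = ornmap.MotifParams.for_motif(motif)
    rng = np.random.default_rng(seed)
    gains = rng.uniform(0.7, 1.0, n)
    ev = ornmap.simulate_batch(params, plume, gains, n_trials=n_trials,
                               seed=seed + 1, sigma_jitter=0.002,
                               neuron_ids=np.arange(n))
    df = pd.DataFrame({"neuron_id": ev[:, 0].astype(int),
                       "trial": ev[:, 1].astype(int), "time_s": ev[:, 2]})
    table = population.SpikeTable(df, n_neurons=n, n_trials=n_trials,
                                  duration=duration)
    rates = population.smooth_rate(table, dt=lnmodel.LN_DT)
    filters = []
    for i in range(n):
        if rates.rate[i].std() == 0:
            continue
        model = lnmodel.fit_ln_model(plume, rates.rate[i], train_span=train_span)
        filters.append(model.filter)
    filters = np.asarray(filters)
    mean_f = filters.mean(axis=0)
    return {
        "mean_filter": mean_f,
        "peak_delay_s": float(np.argmax(mean_f) * lnmodel.LN_DT),
        "filters": filters,
        "stimulus": plume,
    }


def switching_experiment(
    n: int = 500,
    n_trials: int = 10,
    seed: int = 0,
    angle: float = 20.0,
    p_switches: Sequence[float] = (0.0, 0.1, 0.5),
    pulse_width: float = PULSE_WIDTH_S,
) -> dict:
    """Odor-pair classification vs motif-switching probability.

    Odor 2 sits at ``angle`` degrees from odor 1; for each switching
    probability the odor-2 motif labels are re-drawn and a per-bin SVM with
    rotating held-out trial classifies the two odors.  Also reports the
    PCA-plane trajectory separation per switching probability.

    Odor 1 sits near the first axis of odor space so that companion odors
    exist inside the positive octant for the whole 0-80 degree sweep (from
    the octant center nothing farther than ~55 degrees is reachable).
    """
    odor1 = OdorVector(np.array([1.0, 0.25, 0.2]))
    odor2 = odorspace.make_odor_at_angle(odor1, angle, seed=seed + 3)
    pop = PopulationSpec.random(n, seed=seed)
    total = PULSE_ONSET_S + pulse_width + 2.0
    stim = stimuli.square_pulse(PULSE_ONSET_S, pulse_width, total)
    table1 = population.simulate_population(pop, odor1, stim, n_trials=n_trials,
                                            seed=seed + 2)
    binned1 = population.bin_spikes(table1)
    accuracy = {}
    separation = {}
    for p_sw in p_switches:
        labels2 = odorspace.apply_switching(pop.motif_labels, p_sw,
                                            seed=seed + 7)
        pop2 = PopulationSpec(profiles=pop.profiles, motif_labels=labels2,
                              params=pop.params, sigma_offsets=pop.sigma_offsets)
        table2 = population.simulate_population(pop2, odor2, stim,
                                                n_trials=n_trials, seed=seed + 4)
        binned2 = population.bin_spikes(table2)
        report = decoding.odor_classification(
            [_pulse_window_bins(binned1), _pulse_window_bins(binned2)])
        accuracy[p_sw] = report.accuracy
        separation[p_sw] = decoding.trajectory_separation(
            _pulse_window_bins(binned1), _pulse_window_bins(binned2))
    return {"accuracy": accuracy, "separation": separation, "angle": angle}


def distance_experiment(
    n: int = 800,
    n_trials: int = 10,
    seed: int = 0,
    duration: float = 15.0,
    n_cells: int = 192,
    n_ensembles: int = 25,
    subsets: Optional[Sequence[tuple[str, ...]]] = None,
    window_bins: Optional[int] = None,
) -> dict:
    """Distance-to-source decoding from motif subsets.

    Each distance is represented by one seeded, repeatable plume delivered
    for ``n_trials`` trials (trials differ only in the neurons' noise
    instantiations, as with the pulse protocols); SVM ensembles are trained
    on concatenated NCells x NBins features for each motif subset.  Also
    returns binned responses and motif-averaged rates for correlation and
    duration analyses.
    """
    pop = PopulationSpec.random(n, seed=seed)
    odor = seeded_odor(seed + 1)
    binned_by_distance = []
    rates_by_distance = []
    for di, dist in enumerate(stimuli.DISTANCES_M):
        plume = stimuli.generate_plume(stimuli.distance_preset(dist), duration,
                                       seed=seed + 100 + 17 * di)
        table = population.simulate_population(pop, odor, plume,
                                               n_trials=n_trials,
                                               seed=seed + 500 + 31 * di)
        arr = population.bin_spikes(table).counts  # (n, trials, bins)
        binned_by_distance.append(BinnedResponse(arr, 0.05))
        rates_by_distance.append(arr.mean(axis=1) / 0.05)
    subsets = list(subsets) if subsets is not None else decoding.all_motif_subsets()
    ensembles = {}
    for sub in subsets:
        rep = decoding.distance_classification(
            binned_by_distance, pop.motif_labels, sub, n_cells=n_cells,
            n_ensembles=n_ensembles, seed=seed + 9, window_bins=window_bins)
        ensembles[sub] = rep.ensemble
    motif_mean_rates = {
        m: np.stack([r[pop.motif_labels == m].mean(axis=0)
                     for r in rates_by_distance]).mean(axis=0)
        for m in MOTIFS
    }
    return {
        "ensembles": ensembles,
        "binned_by_distance": binned_by_distance,
        "motif_labels": pop.motif_labels,
        "motif_mean_rates": motif_mean_rates,
    }
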