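"""Calibration report for the intrinsic map parameters (alpha, sigma, mu).

The intrinsic parameters of the map neuron are not derivable from the
input-shaping tables; they were chosen per motif so that, with the stated
noise (tau_c = 3 ms, d = 0.01):

  * baseline firing is low tonic, ~2-5 spikes/s, for every motif;
  * a gain-1 4 s pulse elicits the four motif shapes with realistic peak
    rates (tens of spikes/s): excitatory = sharp onset peak decaying toward
    baseline, delayed = slower rise with gradual decay, inhibitory =
    suppression returning to baseline, offset = suppression followed by a
    rebound exceeding baseline;
  * a train of ten 200 ms pulses at 0.5 s IPI adapts in motif-specific
    directions (excitatory peaks decrease, offset rebounds increase,
    inhibitory changes least).

Running this script re-measures all three properties for the frozen
defaults and prints a report.  Usage::

    python scripts/calibrate_map.py [--seed 0]
"""

import argparse

import numpy as np

from ornmotif import ornmap
from ornmotif.ornmap import MOTIFS, MotifParams
from ornmotif.stimuli import pulse_train, square_pulse


def psth(params, stim, n_rep, seed, bin_s=0.05):
    ev = ornmap.simulate_batch(params, stim, np.ones(n_rep), n_trials=1,
                               seed=seed, neuron_ids=np.arange(n_rep))
    nb = int(stim.duration / bin_s)
    counts = np.zeros(nb)
    if len(ev):
        b = np.minimum((ev[:, 2] / bin_s).astype(int), nb - 1)
        np.add.at(counts, b, 1)
    return counts / (n_rep * bin_s)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n", type=int, default=40, help="repeats per measurement")
    args = ap.parse_args()

    print("motif        alpha  sigma   mu       baseline  peak   late   post-peak")
    pulse = square_pulse(2.0, 4.0, 8.0)
    for motif in MOTIFS:
        p = MotifParams.for_motif(motif)
        r_base = psth(p, square_pulse(0, 0, 20.0), args.n // 2, args.seed)
        r = psth(p, pulse, args.n, args.seed + 1)
        t = np.arange(len(r)) * 0.05
        during = r[(t >= 2) & (t < 6)]
        post = r[t >= 6]
        print(f"{motif:<12} {p.alpha:<6g} {p.sigma:<7g} {p.mu:<8g} "
              f"{r_base.mean():8.2f} {during.max():6.1f} {during[-10:].mean():6.1f} "
              f"{post.max():9.1f}")

    print("\nadaptation (10 x 200 ms pulses, 0.5 s IPI): per-pulse |peak - baseline|")
    total = 2 + 10 * 0.2 + 9 * 0.5 + 2.5
    stim = pulse_train(10, 0.2, 0.5, total, onset=2.0)
    for motif in MOTIFS:
        p = MotifParams.for_motif(motif)
        r = psth(p, stim, args.n, args.seed + 2)
        t = np.arange(len(r)) * 0.05
        base = r[t < 2].mean()
        peaks = []
        for k in range(10):
            on = 2.0 + k * 0.7
            if motif == "offset":
                w = (t >= on + 0.2) & (t < on + 0.7)
            else:
                w = (t >= on) & (t < on + 0.4)
            peaks.append(np.abs(r[w] - base).max())
        print(f"{motif:<12} first={peaks[0]:6.1f} last={peaks[-1]:6.1f} "
              f"all={np.round(peaks, 1)}")


if __name__ == "__main__":
    main()
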