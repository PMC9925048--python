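"""Population-level analyses: PCA dimensionality/trajectories, SVM decoding
of odor identity and source distance, and motif correlation analysis.

PCA treats neurons as variables and 50 ms time bins (concatenated across
trials) as observations, quantifying how many components are needed to
capture the population response variance.  Odor classification trains a
linear SVM per time bin with a rotating held-out trial; distance
classification concatenates binned responses across cells into
NCells x NBins feature vectors and trains ensembles of SVMs on random cell
and trial subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import f_oneway, pearsonr
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from ornmotif.population import BinnedResponse


@dataclass
class VarianceSpectrum:
    """Explained-variance fractions of a population PCA."""

    fractions: np.ndarray

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.fractions)

    def n_components_for(self, target: float) -> int:
        """Smallest number of components whose cumulative share >= target."""
        return int(np.searchsorted(self.cumulative, target) + 1)


@dataclass
class ClassificationReport:
    """Decoding accuracy with per-bin / per-repeat detail."""

    accuracy: float
    per_bin: Optional[np.ndarray] = None
    confusion: Optional[np.ndarray] = None
    ensemble: Optional[np.ndarray] = None
    config: dict = field(default_factory=dict)


def _observation_matrix(binned: BinnedResponse, trial_average: bool) -> np.ndarray:
    """(observations x neurons) matrix: time bins, concatenated across trials."""
    counts = binned.counts  # (N, T, B)
    if trial_average:
        return counts.mean(axis=1).T  # (B, N)
    n, t, b = counts.shape
    return counts.transpose(1, 2, 0).reshape(t * b, n)


def response_pca(binned: BinnedResponse, n_components: Optional[int] = None,
                 trial_average: bool = False):
    """PCA over binned population responses.

    Observations are 50 ms time bins (per trial by default), variables are
    neurons.  Returns (VarianceSpectrum, trajectories) where trajectories
    are the observations projected on the first two components, averaged
    across trials.
    """
    X = _observation_matrix(binned, trial_average)
    if X.shape[0] < 2:
        raise ValueError("need at least two time bins")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("degenerate (constant) population response")
    pca = PCA(n_components=n_components)
    proj = pca.fit_transform(X)
    fractions = pca.explained_variance_ratio_
    if trial_average:
        traj = proj[:, :2]
    else:
        n, t, b = binned.counts.shape
        traj = proj[:, :2].reshape(t, b, 2).mean(axis=0)
    return VarianceSpectrum(fractions=fractions), traj


def trajectory_separation(binned_a: BinnedResponse, binned_b: BinnedResponse) -> float:
    """Mean distance between two conditions' trajectories in a joint 2-D PCA.

    Both conditions are projected into the PCA plane fitted on their pooled
    observations; returns the time-bin-averaged Euclidean distance between
    the two trial-averaged trajectories.
    """
    Xa = _observation_matrix(binned_a, trial_average=False)
    Xb = _observation_matrix(binned_b, trial_average=False)
    pca = PCA(n_components=2)
    pca.fit(np.vstack([Xa, Xb]))

    def avg_traj(binned):
        X = _observation_matrix(binned, trial_average=False)
        proj = pca.transform(X)
        n, t, b = binned.counts.shape
        return proj.reshape(t, b, 2).mean(axis=0)

    ta, tb = avg_traj(binned_a), avg_traj(binned_b)
    m = min(len(ta), len(tb))
    return float(np.linalg.norm(ta[:m] - tb[:m], axis=1).mean())


def odor_classification(binned_by_odor: Sequence[BinnedResponse],
                        C: float = 1.0) -> ClassificationReport:
    """Per-bin SVM odor classification with a rotating held-out trial.

    Each odor contributes n_trials population vectors per 50 ms bin; for
    every rotation one trial per odor is held out and a linear SVM
    (one-vs-one for >2 odors) is trained on the rest.  Accuracy is averaged
    over bins and rotations.
    """
    if len(binned_by_odor) < 2:
        raise ValueError("need at least two odors")
    shapes = {b.counts.shape for b in binned_by_odor}
    if len(shapes) != 1:
        raise ValueError("all odors need identical (neurons, trials, bins) shapes")
    n_neurons, n_trials, n_bins = shapes.pop()
    if n_trials < 2:
        raise ValueError("need at least two trials for held-out evaluation")
    n_odors = len(binned_by_odor)
    per_bin = np.zeros(n_bins)
    confusion = np.zeros((n_odors, n_odors), dtype=int)
    for b in range(n_bins):
        # (odor, trial) -> population vector at this bin
        vecs = np.stack([bd.counts[:, :, b].T for bd in binned_by_odor])  # (O, T, N)
        correct = 0
        total = 0
        for held in range(n_trials):
            train_idx = [t for t in range(n_trials) if t != held]
            Xtr = vecs[:, train_idx, :].reshape(-1, n_neurons)
            ytr = np.repeat(np.arange(n_odors), len(train_idx))
            Xte = vecs[:, held, :]
            yte = np.arange(n_odors)
            if len(np.unique(Xtr, axis=0)) == 1:
                # degenerate bin (e.g. all-zero counts): chance performance
                pred = np.zeros(n_odors, dtype=int)
            else:
                clf = SVC(kernel="linear", C=C, decision_function_shape="ovo")
                clf.fit(Xtr, ytr)
                pred = clf.predict(Xte)
            correct += int(np.sum(pred == yte))
            total += n_odors
            for yt, yp in zip(yte, pred):
                confusion[yt, yp] += 1
        per_bin[b] = correct / total
    return ClassificationReport(accuracy=float(per_bin.mean()), per_bin=per_bin,
                                confusion=confusion,
                                config={"n_odors": n_odors, "n_trials": n_trials})


def distance_classification(
    binned_by_distance: Sequence[BinnedResponse],
    motif_labels: np.ndarray,
    motif_subset: Sequence[str],
    n_cells: int = 192,
    n_ensembles: int = 25,
    seed: int = 0,
    C: float = 1.0,
    window_bins: Optional[int] = None,
) -> ClassificationReport:
    """Ensemble SVM classification of plume distance from motif subsets.

    For each of ``n_ensembles`` repeats, sample ``n_cells`` cells whose motif
    label is in ``motif_subset``, split trials into equal train/test halves,
    build NCells x NBins concatenated feature vectors and record the test
    accuracy of a linear SVM.  ``window_bins`` truncates the response window
    used for the features.
    """
    if not motif_subset:
        raise ValueError("motif_subset must be nonempty")
    motif_labels = np.asarray(motif_labels, dtype=object)
    pool = np.flatnonzero(np.isin(motif_labels, list(motif_subset)))
    if len(pool) < n_cells:
        raise ValueError(
            f"motif subset {tuple(motif_subset)} has only {len(pool)} cells; "
            f"{n_cells} required")
    shapes = {b.counts.shape for b in binned_by_distance}
    if len(shapes) != 1:
        raise ValueError("conditions need identical shapes")
    _, n_trials, n_bins = shapes.pop()
    if window_bins is not None:
        n_bins = min(n_bins, window_bins)
    n_classes = len(binned_by_distance)
    rng = np.random.default_rng(seed)
    accs = np.empty(n_ensembles)
    for rep in range(n_ensembles):
        cells = rng.choice(pool, size=n_cells, replace=False)
        perm = rng.permutation(n_trials)
        half = n_trials // 2
        tr, te = perm[:half], perm[half:2 * half]
        Xtr, ytr, Xte, yte = [], [], [], []
        for ci, bd in enumerate(binned_by_distance):
            feats = bd.counts[cells][:, :, :n_bins]  # (cells, trials, bins)
            for t in tr:
                Xtr.append(feats[:, t, :].ravel())
                ytr.append(ci)
            for t in te:
                Xte.append(feats[:, t, :].ravel())
                yte.append(ci)
        clf = SVC(kernel="linear", C=C, decision_function_shape="ovo")
        clf.fit(np.asarray(Xtr), np.asarray(ytr))
        accs[rep] = clf.score(np.asarray(Xte), np.asarray(yte))
    return ClassificationReport(
        accuracy=float(accs.mean()), ensemble=accs,
        config={"motif_subset": tuple(motif_subset), "n_cells": n_cells,
                "n_ensembles": n_ensembles, "n_classes": n_classes,
                "window_bins": n_bins})


def all_motif_subsets() -> list[tuple[str, ...]]:
    """All 15 nonempty subsets of the four motifs, by size then order."""
    from itertools import combinations

    from ornmotif.ornmap import MOTIFS
    out = []
    for r in range(1, 5):
        out.extend(combinations(MOTIFS, r))
    return out


def motif_subset_anova(ensembles_by_subset: dict) -> tuple[float, tuple[int, int], float, list]:
    """One-way ANOVA across motif-subset ensembles plus post-hoc grouping.

    Returns (F, (df_between, df_within), p, groups) where ``groups`` is a
    list of lists of subset keys whose ensemble means are not statistically
    separable from their neighbors (simple gap-based grouping on sorted
    means using Tukey-style pooled SE).
    """
    keys = list(ensembles_by_subset)
    if len(keys) < 2:
        raise ValueError("need at least two subsets")
    samples = [np.asarray(ensembles_by_subset[k], dtype=float) for k in keys]
    F, p = f_oneway(*samples)
    k = len(samples)
    n_total = sum(len(s) for s in samples)
    df = (k - 1, n_total - k)
    # post-hoc: sort by mean, split where adjacent gap exceeds 2 pooled SEMs
    means = np.array([s.mean() for s in samples])
    sems = np.array([s.std(ddof=1) / np.sqrt(len(s)) for s in samples])
    order = np.argsort(means)
    groups: list[list] = [[keys[order[0]]]]
    for prev, cur in zip(order[:-1], order[1:]):
        gap = means[cur] - means[prev]
        if gap > 2.0 * np.hypot(sems[cur], sems[prev]):
            groups.append([])
        groups[-1].append(keys[cur])
    return float(F), df, float(p), groups


def motif_correlation(rates_by_motif: dict, window: float, dt: float,
                      reference: str = "excitatory") -> dict:
    """Pearson correlation of each motif's mean rate with the excitatory one.

    ``rates_by_motif`` maps motif -> motif-averaged rate trace on grid
    ``dt``; traces are truncated to ``window`` seconds before correlating.
    """
    if reference not in rates_by_motif:
        raise ValueError(f"reference motif {reference!r} missing")
    n = int(round(window / dt))
    ref = np.asarray(rates_by_motif[reference], dtype=float)[:n]
    out = {}
    for motif, trace in rates_by_motif.items():
        tr = np.asarray(trace, dtype=float)[:n]
        if np.std(tr) == 0 or np.std(ref) == 0:
            raise ValueError(f"zero-variance trace for {motif!r}")
        out[motif] = float(pearsonr(ref, tr[:len(ref)])[0])
    return out
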