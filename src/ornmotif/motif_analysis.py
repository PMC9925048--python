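"""Response-motif clustering with bootstrap validation, motif-switching
quantification, and adaptation analysis.

Responses (50 ms-binned PSTHs of responsive ORN-odor pairs) are z-normalized
and grouped by Ward/Euclidean agglomerative clustering.  Two statistical
tests decide whether a clustering is meaningful: Test 1 compares each
cluster's mean intra-cluster pairwise distance against a bootstrap null of
random same-size subsets; Test 2 compares intra- vs inter-cluster distances
with Bonferroni-corrected two-sample t-tests (a non-symmetric comparison).
The number of motifs is the largest cluster count for which every cluster
passes Test 1 and every ordered pair passes Test 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import ttest_ind

from ornmotif.population import BinnedResponse, RateTrace

TEST1_PERCENTILE = 5.0
ALPHA = 0.05


@dataclass
class ClusterResult:
    """Clustering plus both validity tests at one cluster count."""

    labels: np.ndarray  # 1..k per response
    k: int
    test1_pass: dict[int, bool]
    test1_overlap: dict[int, float]
    test2_p: np.ndarray  # (k, k) Bonferroni-adjusted, NaN on diagonal

    @property
    def all_pass(self) -> bool:
        off = ~np.eye(self.k, dtype=bool)
        return all(self.test1_pass.values()) and bool(
            np.all(self.test2_p[off] < ALPHA))


@dataclass
class AdaptationProfile:
    """Normalized per-pulse response-change indices for one condition."""

    values: np.ndarray  # (n_trials_or_units, n_pulses) normalized, in [-1, 1]
    ipi: float
    motif: Optional[str] = None
    windows: Optional[list[tuple[float, float]]] = None

    @property
    def mean(self) -> np.ndarray:
        return self.values.mean(axis=0)


def response_matrix(binned: BinnedResponse, stim_start_bin: int = 0) -> np.ndarray:
    """Trial-averaged response vectors (n_responses x n_bins)."""
    return binned.trial_averaged()[:, stim_start_bin:]


def responsive_mask(binned: BinnedResponse, pre_window: float,
                    threshold_sd: float = 2.0) -> np.ndarray:
    """Mark responsive units: any stimulus-epoch bin beyond 2 pre-stimulus SDs.

    The deviation is two-sided so suppressed (inhibitory/offset) responses
    count as responses.  Pre-stimulus mean and SD are taken across the
    trial-averaged bins before ``pre_window`` seconds.
    """
    n_pre = int(round(pre_window / binned.bin_width))
    if n_pre < 1:
        raise ValueError("pre-stimulus window contains no bins")
    avg = binned.trial_averaged()
    pre = avg[:, :n_pre]
    mu = pre.mean(axis=1)
    sd = pre.std(axis=1)
    zero = sd == 0
    if np.any(zero):
        import warnings
        warnings.warn("zero pre-stimulus variance for some units; using SD = eps")
        sd = np.where(zero, np.finfo(float).eps, sd)
    dev = np.abs(avg[:, n_pre:] - mu[:, None])
    return (dev > threshold_sd * sd[:, None]).any(axis=1)


def znormalize(responses: np.ndarray) -> np.ndarray:
    """Center each response vector and scale to unit standard deviation."""
    mu = responses.mean(axis=1, keepdims=True)
    sd = responses.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (responses - mu) / sd


def cluster_motifs(responses: np.ndarray, k: int, normalize: bool = True) -> np.ndarray:
    """Ward/Euclidean agglomerative clustering cut at k clusters.

    ``responses`` is (n_responses, n_bins); returns labels in 1..k.
    """
    n = len(responses)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"cannot form {k} clusters from {n} responses")
    X = znormalize(responses) if normalize else np.asarray(responses, dtype=float)
    Z = linkage(X, method="ward", metric="euclidean")
    return fcluster(Z, t=k, criterion="maxclust")


def _mean_pairwise(D: np.ndarray, idx: np.ndarray) -> float:
    sub = D[np.ix_(idx, idx)]
    m = len(idx)
    if m < 2:
        return np.nan
    return sub[np.triu_indices(m, k=1)].mean()


def cluster_test1(responses: np.ndarray, labels: np.ndarray, n_boot: int = 10000,
                  seed: int = 0, normalize: bool = True,
                  replace: bool = False) -> tuple[dict[int, bool], dict[int, float]]:
    """Bootstrap compactness test (Test 1).

    For each cluster of size m, draw ``n_boot`` random size-m subsets of all
    responses and compute each subset's mean pairwise Euclidean distance.
    The cluster passes if its own mean intra-cluster distance falls below the
    5th percentile of that null distribution (i.e. overlaps with less than 5%
    of the random distance distribution).  Returns (pass, overlap-fraction)
    per cluster label.  Subsets are drawn without replacement by default.
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000 for a stable 5th percentile")
    X = znormalize(responses) if normalize else np.asarray(responses, dtype=float)
    D = squareform(pdist(X, metric="euclidean"))
    rng = np.random.default_rng(seed)
    n = len(X)
    passed: dict[int, bool] = {}
    overlap: dict[int, float] = {}
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        m = len(idx)
        if m < 2:
            import warnings
            warnings.warn(f"cluster {lab} has a single member; Test 1 fails")
            passed[int(lab)] = False
            overlap[int(lab)] = 1.0
            continue
        own = _mean_pairwise(D, idx)
        if own == 0.0:
            # identical responses: maximally compact, zero overlap by definition
            passed[int(lab)] = True
            overlap[int(lab)] = 0.0
            continue
        null = np.empty(n_boot)
        for b in range(n_boot):
            sub = rng.choice(n, size=m, replace=replace)
            null[b] = _mean_pairwise(D, sub)
        frac = float(np.mean(null <= own))
        overlap[int(lab)] = frac
        passed[int(lab)] = frac < TEST1_PERCENTILE / 100.0
    return passed, overlap


def cluster_test2(responses: np.ndarray, labels: np.ndarray,
                  normalize: bool = True) -> np.ndarray:
    """Intra- vs inter-cluster distance t-tests (Test 2).

    Entry (A, B) holds the Bonferroni-adjusted p of a two-sample t-test
    comparing A's intra-cluster pairwise distances with the A-to-B
    inter-cluster distances.  The matrix is not symmetric: the intra-cluster
    reference changes with the row.  Diagonal entries are NaN.
    """
    X = znormalize(responses) if normalize else np.asarray(responses, dtype=float)
    D = squareform(pdist(X, metric="euclidean"))
    labs = np.unique(labels)
    k = len(labs)
    if k < 2:
        raise ValueError("Test 2 requires at least two clusters")
    n_comp = k * (k - 1)
    P = np.full((k, k), np.nan)
    for i, a in enumerate(labs):
        ia = np.flatnonzero(labels == a)
        intra = D[np.ix_(ia, ia)][np.triu_indices(len(ia), k=1)]
        for j, b in enumerate(labs):
            if a == b:
                continue
            ib = np.flatnonzero(labels == b)
            inter = D[np.ix_(ia, ib)].ravel()
            if len(intra) < 2 or len(inter) < 2:
                raise ValueError("not enough distances for a t-test")
            p = ttest_ind(intra, inter, equal_var=False).pvalue
            P[i, j] = min(1.0, p * n_comp)
    return P


def select_cluster_count(responses: np.ndarray, k_max: int = 6,
                         n_boot: int = 10000, seed: int = 0) -> int:
    """Largest k in [2, k_max] passing both validity tests; 1 if none do."""
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    best = 1
    for k in range(2, min(k_max, len(responses)) + 1):
        labels = cluster_motifs(responses, k)
        t1_pass, _ = cluster_test1(responses, labels, n_boot=n_boot, seed=seed + k)
        if not all(t1_pass.values()):
            continue
        P = cluster_test2(responses, labels)
        off = ~np.eye(len(np.unique(labels)), dtype=bool)
        if np.all(P[off] < ALPHA):
            best = k
    return best


def validate_clustering(responses: np.ndarray, k: int, n_boot: int = 10000,
                        seed: int = 0) -> ClusterResult:
    """Cluster at k and run both validity tests."""
    labels = cluster_motifs(responses, k)
    t1_pass, t1_overlap = cluster_test1(responses, labels, n_boot=n_boot, seed=seed)
    P = cluster_test2(responses, labels)
    return ClusterResult(labels=labels, k=k, test1_pass=t1_pass,
                         test1_overlap=t1_overlap, test2_p=P)


# ---------------------------------------------------------------------------
# Motif switching
# ---------------------------------------------------------------------------

def switching_rate(labels_odor1, labels_odor2) -> float:
    """Observed motif switches divided by switching opportunities.

    Entries that are None/NaN (no detectable response to that odor) are
    excluded from the opportunity count.
    """
    a = np.asarray(labels_odor1, dtype=object)
    b = np.asarray(labels_odor2, dtype=object)
    if a.shape != b.shape:
        raise ValueError("label arrays must align")
    valid = np.array([x is not None and y is not None and x == x and y == y
                      for x, y in zip(a, b)])
    n_opp = int(valid.sum())
    if n_opp == 0:
        raise ValueError("no switching opportunities (no unit responded to both odors)")
    switches = int(np.sum(a[valid] != b[valid]))
    return switches / n_opp


def conditional_motif_matrix(labels_odor1, labels_odor2,
                             motifs: Optional[tuple] = None) -> pd.DataFrame:
    """Row-stochastic P(motif to odor 2 | motif to odor 1).

    Rows with no observations are left as NaN.
    """
    from ornmotif.ornmap import MOTIFS
    motifs = motifs or MOTIFS
    a = np.asarray(labels_odor1, dtype=object)
    b = np.asarray(labels_odor2, dtype=object)
    M = np.zeros((len(motifs), len(motifs)))
    for x, y in zip(a, b):
        if x in motifs and y in motifs:
            M[motifs.index(x), motifs.index(y)] += 1
    sums = M.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(sums > 0, M / sums, np.nan)
    return pd.DataFrame(P, index=list(motifs), columns=list(motifs))


# ---------------------------------------------------------------------------
# Adaptation
# ---------------------------------------------------------------------------

def default_windows(motif: str, onsets: np.ndarray, offsets: np.ndarray,
                    ipi: float) -> list[tuple[float, float]]:
    """Per-pulse detection windows.

    Excitatory/delayed/inhibitory: [onset, offset + 0.2 s].  Offset motif:
    [offset, offset + min(ipi, 0.5 s)] (its response follows pulse offset).
    """
    wins = []
    for on, off in zip(onsets, offsets):
        if motif == "offset":
            wins.append((off, off + min(ipi, 0.5)))
        else:
            wins.append((on, off + 0.2))
    return wins


def adaptation_profile(rates: RateTrace, windows: list[tuple[float, float]],
                       baseline_window: float, ipi: float,
                       motif: Optional[str] = None) -> AdaptationProfile:
    """Per-pulse normalized maximum absolute rate change from baseline.

    ``rates.rate`` must be per-trial, shape (n_units, n_trials, n_samples)
    or (n_trials, n_samples).  For each trial: baseline = mean rate over the
    ``baseline_window`` seconds before the first window; per pulse, the
    maximum |rate - baseline| inside the pulse's detection window, normalized
    by the trial's maximum rate; the sign of the extreme deviation is
    restored for direction reporting.
    """
    r = rates.rate
    if r.ndim == 2:
        r = r[None]
    n_units, n_trials, n_samples = r.shape
    dt = rates.dt
    t0 = windows[0][0]
    b0 = int(max(0, round((t0 - baseline_window) / dt)))
    b1 = int(round(t0 / dt))
    if b1 <= b0:
        raise ValueError("baseline window is empty")
    vals = np.zeros((n_units * n_trials, len(windows)))
    row = 0
    for u in range(n_units):
        for tr in range(n_trials):
            trace = r[u, tr]
            base = trace[b0:b1].mean()
            peak = trace.max()
            norm = peak if peak > 0 else 1.0
            for k, (lo, hi) in enumerate(windows):
                i0, i1 = int(round(lo / dt)), int(round(hi / dt))
                if i1 <= i0 or i1 > n_samples:
                    raise ValueError(f"window {k} is empty or outside the trace")
                seg = trace[i0:i1] - base
                ext = seg[np.argmax(np.abs(seg))]
                vals[row, k] = ext / norm
            row += 1
    return AdaptationProfile(values=vals, ipi=ipi, motif=motif, windows=windows)


def adaptation_anova(profile: AdaptationProfile) -> tuple[float, float]:
    """One-way repeated-measures ANOVA across pulse index.

    Subjects are rows of ``profile.values`` (trials or recordings); the
    within-subject factor is pulse number.  Returns (F, p); no sphericity
    correction is applied.
    """
    from statsmodels.stats.anova import AnovaRM

    vals = profile.values
    n_sub, n_pulse = vals.shape
    if n_pulse < 2:
        raise ValueError("need at least two pulses")
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(n_sub), n_pulse),
        "pulse": np.tile(np.arange(n_pulse), n_sub),
        "value": vals.ravel(),
    })
    if np.allclose(vals.var(axis=0), 0):
        return 0.0, 1.0
    res = AnovaRM(df, depvar="value", subject="subject", within=["pulse"]).fit()
    row = res.anova_table.iloc[0]
    return float(row["F Value"]), float(row["Pr > F"])
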