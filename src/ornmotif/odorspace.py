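"""Odor/receptor vector geometry, response efficacy, and motif switching.

Odors and ORN selectivities are unit vectors in the positive octant of a
3-D chemical space.  The response efficacy of an odor-receptor pair is a
sigmoid of the cosine of the angle between the two vectors, so nearby odors
drive overlapping ORN ensembles.  Motif identity per (neuron, odor) is
assigned independently of efficacy, and switching between odors is modeled
as a seeded Markov draw over motif labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ornmotif.ornmap import MOTIFS

#: Sigmoid steepness and midpoint of the efficacy response function.
A1_DEFAULT = 15.0
A2_DEFAULT = 0.3


def _unit_positive(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("zero-length vector has no direction")
    if np.any(v < 0):
        raise ValueError("vector components must be non-negative (positive octant)")
    return v / norm


@dataclass
class OdorVector:
    """Unit-length characteristic vector of an odor (positive octant)."""

    v: np.ndarray

    def __post_init__(self):
        self.v = _unit_positive(self.v)


@dataclass
class SelectivityProfile:
    """Chemical selectivity of one ORN.

    ``p`` sets the receptive-field width (larger p = narrower tuning);
    ``a1``/``a2`` are the sigmoid steepness and midpoint.
    """

    v: np.ndarray
    p: float = 1.0
    a1: float = A1_DEFAULT
    a2: float = A2_DEFAULT

    def __post_init__(self):
        self.v = _unit_positive(self.v)
        if self.p <= 0:
            raise ValueError("receptive-field exponent p must be positive")


def angle_between(a, b) -> float:
    """Angle between two vectors in degrees."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def response_efficacy(orn: SelectivityProfile, odor: OdorVector) -> float:
    """Odor-receptor response efficacy R in [0, 1].

    R = sigmoid(|V_odor| * cos^p(theta)) with sigmoid(x) =
    1 / (1 + exp(-a1 (x - a2))).  For theta > 90 deg the cos^p argument is
    clamped to 0 (fractional p would otherwise be complex-valued).
    """
    cos_t = float(np.dot(orn.v, odor.v))
    cos_t = max(cos_t, 0.0)
    drive = np.linalg.norm(odor.v) * cos_t ** orn.p
    return float(1.0 / (1.0 + np.exp(-orn.a1 * (drive - orn.a2))))


def efficacies(profiles: list[SelectivityProfile], odor: OdorVector) -> np.ndarray:
    """Vector of efficacies of one odor across a list of ORN profiles."""
    return np.array([response_efficacy(p, odor) for p in profiles])


def make_odor_at_angle(reference: OdorVector, angle: float, seed: int = 0,
                       max_tries: int = 200) -> OdorVector:
    """Unit odor vector at a given angular separation from a reference.

    The rotation direction within the positive octant is seeded; raises if
    no positive-octant vector exists at the requested angle after
    ``max_tries`` seeded attempts.
    """
    if not (0.0 <= angle <= 90.0):
        raise ValueError("angle must lie in [0, 90] degrees")
    if angle == 0.0:
        return OdorVector(reference.v.copy())
    rng = np.random.default_rng(seed)
    theta = np.radians(angle)
    ref = reference.v
    for _ in range(max_tries):
        r = rng.standard_normal(ref.shape)
        orth = r - np.dot(r, ref) * ref
        norm = np.linalg.norm(orth)
        if norm < 1e-12:
            continue
        cand = np.cos(theta) * ref + np.sin(theta) * orth / norm
        if np.all(cand >= 0):
            return OdorVector(cand)
    raise ValueError(
        f"no positive-octant vector found at {angle} deg from {ref} "
        f"after {max_tries} seeded attempts")


def make_odor_series(reference: OdorVector, angles, seed: int = 0) -> list[OdorVector]:
    """Odor vectors at increasing angles from a reference (odor 2, 3, ...)."""
    return [make_odor_at_angle(reference, a, seed=seed + i)
            for i, a in enumerate(angles)]


def sample_selectivity(n: int, seed: int = 0, p: float = 1.0) -> list[SelectivityProfile]:
    """n ORN selectivity profiles uniform over positive-octant directions.

    Folding a standard normal into the positive octant gives directions
    uniform on the spherical triangle.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    vs = np.abs(rng.standard_normal((n, 3)))
    return [SelectivityProfile(v, p=p) for v in vs]


def assign_motifs(n: int, proportions=None, seed: int = 0) -> np.ndarray:
    """Seeded multinomial assignment of the four motifs to n neurons."""
    if proportions is None:
        proportions = np.full(4, 0.25)
    proportions = np.asarray(proportions, dtype=float)
    if np.any(proportions < 0):
        raise ValueError("motif proportions must be non-negative")
    if abs(proportions.sum() - 1.0) > 1e-9:
        raise ValueError("motif proportions must sum to 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(4, size=n, p=proportions)
    return np.array(MOTIFS, dtype=object)[idx]


def uniform_switch_matrix(p_switch: float) -> np.ndarray:
    """4x4 motif transition matrix: keep with 1-p, else uniform over the rest."""
    if not (0.0 <= p_switch <= 1.0):
        raise ValueError("p_switch must lie in [0, 1]")
    m = np.full((4, 4), p_switch / 3.0)
    np.fill_diagonal(m, 1.0 - p_switch)
    return m


def apply_switching(labels: np.ndarray, p_switch: float, seed: int = 0,
                    transition: np.ndarray | None = None) -> np.ndarray:
    """Motif labels for a second odor given labels for the first.

    Each neuron independently keeps its motif with probability 1 - p_switch,
    otherwise takes one of the other three uniformly; an explicit 4x4
    row-stochastic ``transition`` matrix overrides this default.
    """
    if transition is None:
        transition = uniform_switch_matrix(p_switch)
    transition = np.asarray(transition, dtype=float)
    if transition.shape != (4, 4) or np.any(transition < 0) \
            or not np.allclose(transition.sum(axis=1), 1.0):
        raise ValueError("transition must be a 4x4 row-stochastic matrix")
    rng = np.random.default_rng(seed)
    motif_index = {m: i for i, m in enumerate(MOTIFS)}
    out = np.empty(len(labels), dtype=object)
    for i, lab in enumerate(labels):
        row = transition[motif_index[lab]]
        out[i] = MOTIFS[rng.choice(4, p=row)]
    return out
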