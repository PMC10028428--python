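"""Distribution comparison and sampling-error statistics.

Measured and analytic state distributions are compared with the (squared)
Hellinger fidelity ``F_s(I, O) = (sum_s sqrt(p_I(s) p_O(s)))²`` and its
normalized form ``F_normed = (F_s(I,O) - F_s(I,U)) / (1 - F_s(I,U))``, which
maps agreement with the uniform distribution U to 0 and perfect agreement
with I to 1 (and can go negative for outputs worse than uniform).  Empirical
distributions use raw maximum-likelihood frequencies, no smoothing, over the
full 2**n state universe.  The binomial sampling error of a frequency ``p``
over ``m`` shots is ``sqrt(p (1-p) / m)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .circuits import MeasurementDistribution
from .classical import WeightVector

__all__ = [
    "DiscreteDistribution",
    "hellinger_fidelity",
    "normalized_fidelity",
    "sampling_error",
]


@dataclass(frozen=True)
class DiscreteDistribution:
    """Probability vector over the full state set S = {0, ..., 2**n - 1}."""

    p: np.ndarray

    def __post_init__(self):
        if np.any(self.p < -1e-12):
            raise ValueError("probabilities must be non-negative")
        if abs(float(self.p.sum()) - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    @property
    def size(self) -> int:
        return len(self.p)

    @classmethod
    def uniform(cls, n_states: int) -> "DiscreteDistribution":
        return cls(np.full(n_states, 1.0 / n_states))

    @classmethod
    def from_counts(
        cls, dist: MeasurementDistribution, n_states: int | None = None
    ) -> "DiscreteDistribution":
        if n_states is None:
            n_states = 1 << dist.width
        p = np.zeros(n_states, dtype=np.float64)
        for state, count in dist.counts_by_int().items():
            if state >= n_states:
                raise ValueError("outcome outside declared state universe")
            p[state] = count / dist.shots
        return cls(p)

    @classmethod
    def from_weights(cls, w: WeightVector) -> "DiscreteDistribution":
        return cls(np.asarray(w.w, dtype=np.float64))

    @classmethod
    def from_law(cls, law: dict[int, float], n_states: int) -> "DiscreteDistribution":
        p = np.zeros(n_states, dtype=np.float64)
        for state, prob in law.items():
            p[state] = prob
        return cls(p)


def _as_dist(d) -> DiscreteDistribution:
    return d if isinstance(d, DiscreteDistribution) else DiscreteDistribution(np.asarray(d, float))


def hellinger_fidelity(I, O) -> float:
    """Squared Bhattacharyya overlap (sum_s sqrt(p_I p_O))², in [0, 1]."""
    I, O = _as_dist(I), _as_dist(O)
    if I.size != O.size:
        raise ValueError("distributions must share the same state universe")
    return float(np.sum(np.sqrt(I.p * O.p)) ** 2)


def normalized_fidelity(I, O) -> float:
    """Fidelity rescaled against I's overlap with the uniform baseline.

    Undefined (raises) when I itself is uniform, since the baseline overlap
    is then 1 and the rescaling degenerates.
    """
    I, O = _as_dist(I), _as_dist(O)
    base = hellinger_fidelity(I, DiscreteDistribution.uniform(I.size))
    if 1.0 - base < 1e-12:
        raise ValueError(
            "normalized fidelity is undefined for a uniform ideal distribution"
        )
    return (hellinger_fidelity(I, O) - base) / (1.0 - base)


def sampling_error(p: float, m: int) -> float:
    """Binomial standard error sqrt(p (1 - p) / m) of a measured frequency."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return math.sqrt(p * (1.0 - p) / m)
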