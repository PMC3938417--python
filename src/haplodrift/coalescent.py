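"""Neutral coalescent simulation.

Genealogies follow the Kingman n-coalescent.  Time is measured in units
of N generations for a haploid (mtDNA-transmitting) population of size N,
so the coalescence rate for k open lineages is k(k-1)/2, and a pair has
expected TMRCA 1.  Two mutation schemes are provided:

* fixed-S conditioning — exactly S mutations placed uniformly on the
  total branch length (the convention DnaSP uses for neutrality-test
  null distributions);
* Poisson mutations at rate theta/2 per unit branch length, optionally
  on a genealogy drawn under a sudden-expansion population history
  (theta0 -> theta1 at mutational time tau before present), which is the
  parametric bootstrap engine for mismatch goodness-of-fit tests.

All mutations hit distinct sites (infinite-sites), so a sample is
represented as a binary (n, S) matrix of derived-state indicators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Genealogy",
    "sample_genealogy",
    "place_mutations_fixed_s",
    "place_mutations_poisson",
    "simulate_fixed_s",
    "simulate_expansion_sample",
]


@dataclass
class Genealogy:
    """A coalescent tree over n tips.

    Nodes 0..n-1 are tips (time 0); nodes n..2n-2 are coalescence events
    in time order; node 2n-2 is the root.  ``parent[i]`` is -1 for the
    root.
    """

    n: int
    parent: np.ndarray
    time: np.ndarray

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for the root)."""
        lengths = np.zeros(2 * self.n - 1)
        has_parent = self.parent >= 0
        lengths[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return lengths

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def tmrca(self) -> float:
        return float(self.time[-1])

    def tip_sets(self) -> np.ndarray:
        """Boolean (2n-1, n) matrix: tips descending from each node."""
        n = self.n
        sets = np.zeros((2 * n - 1, n), dtype=bool)
        sets[np.arange(n), np.arange(n)] = True
        # children appear before parents, so one forward pass suffices
        for node in range(2 * n - 2):
            p = self.parent[node]
            if p >= 0:
                sets[p] |= sets[node]
        return sets


def _coalescence_times(n: int, rng: np.random.Generator) -> np.ndarray:
    """Event times under a constant-size history (rate k(k-1)/2)."""
    k = np.arange(n, 1, -1)
    waits = rng.exponential(1.0) / (k * (k - 1) / 2.0)
    return np.cumsum(waits)


def _coalescence_times_expansion(
    n: int, t_exp: float, size_ratio: float, rng: np.random.Generator
) -> np.ndarray:
    """Event times under a sudden size change at ``t_exp`` before present.

    The present relative size is 1; older than ``t_exp`` it is
    ``size_ratio`` (theta0/theta1 < 1 for an expansion).  A zero ratio
    collapses all remaining lineages instantly at the change point.
    """
    times = np.empty(n - 1)
    t = 0.0
    for i, k in enumerate(range(n, 1, -1)):
        rate = k * (k - 1) / 2.0
        w = rng.exponential(1.0 / rate)
        if t < t_exp and t + w > t_exp:
            # re-draw the residual wait in the older, rescaled epoch
            if size_ratio == 0.0:
                t = t_exp
            else:
                t = t_exp + rng.exponential(size_ratio / rate)
        else:
            if t >= t_exp and size_ratio == 0.0:
                pass  # already in the instant-coalescence epoch
            elif t >= t_exp:
                w = rng.exponential(size_ratio / rate)
                t = t + w
            else:
                t = t + w
        times[i] = t
    return times


def sample_genealogy(
    n: int,
    rng: np.random.Generator,
    *,
    expansion: tuple[float, float] | None = None,
) -> Genealogy:
    """Draw one Kingman genealogy over ``n`` tips.

    ``expansion=(t_exp, size_ratio)`` switches the population to relative
    size ``size_ratio`` older than ``t_exp`` (sudden-expansion history).
    """
    if n < 2:
        raise ValueError("need at least 2 lineages")
    if expansion is None:
        times = _coalescence_times(n, rng)
    else:
        times = _coalescence_times_expansion(n, expansion[0], expansion[1], rng)

    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    open_lineages = list(range(n))
    for event in range(n - 1):
        node = n + event
        i = rng.integers(len(open_lineages))
        a = open_lineages.pop(i)
        j = rng.integers(len(open_lineages))
        b = open_lineages.pop(j)
        parent[a] = node
        parent[b] = node
        time[node] = times[event]
        open_lineages.append(node)
    return Genealogy(n, parent, time)


def place_mutations_fixed_s(
    gen: Genealogy, s: int, rng: np.random.Generator
) -> np.ndarray:
    """Place exactly ``s`` mutations uniformly on the total branch length.

    Returns the (n, s) binary derived-state matrix; every column is
    segregating by construction.
    """
    if s < 0:
        raise ValueError("s must be non-negative")
    lengths = gen.branch_lengths()
    if s == 0:
        return np.zeros((gen.n, 0), dtype=bool)
    branches = rng.choice(len(lengths), size=s, p=lengths / lengths.sum())
    return gen.tip_sets()[branches].T.copy()


def place_mutations_poisson(
    gen: Genealogy, theta: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson mutations at rate ``theta / 2`` per unit branch length."""
    if theta < 0:
        raise ValueError("theta must be non-negative")
    s = rng.poisson(theta / 2.0 * gen.total_branch_length())
    return place_mutations_fixed_s(gen, int(s), rng)


def simulate_fixed_s(
    n: int, s: int, rng: np.random.Generator
) -> np.ndarray:
    """One standard-neutral sample conditioned on ``s`` segregating sites."""
    gen = sample_genealogy(n, rng)
    return place_mutations_fixed_s(gen, s, rng)


def simulate_expansion_sample(
    n: int,
    tau: float,
    theta0: float,
    theta1: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One sample under the sudden-expansion model.

    The population changed from scaled mutation rate ``theta0`` to
    ``theta1`` at mutational time ``tau`` before present; in coalescent
    units of N1 generations the change point is ``tau / theta1`` and the
    older relative size is ``theta0 / theta1``.  Mutations are Poisson at
    rate ``theta1 / 2`` per unit branch length.
    """
    if min(tau, theta0) < 0 or theta1 <= 0:
        raise ValueError("invalid expansion parameters")
    gen = sample_genealogy(n, rng, expansion=(tau / theta1, theta0 / theta1))
    return place_mutations_poisson(gen, theta1, rng)
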