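"""Forward-time simulation of mtDNA haplotype drift under rodent control.

Three demographic scenarios for a European Norway-rat population founded
around 1750 A.D. (2 generations per year, 500 generations simulated):

* ``L`` — constant effective size Ne0 (default 10,000): pure drift.
* ``M`` — rodenticide introduction at generation t1 (default 400, i.e.
  ~1950) crashes the population to Nei (default 100, "99% mortality"),
  which is then held: control stays effective.
* ``R`` — the crash at t1 is followed by the evolution of anticoagulant
  resistance within 10 years (t1 to t2, default generation 420): an
  autosomal resistance locus (representing Vkorc1 Y139C) under balancing
  selection (heterozygote advantage, coefficient s = 0.3) enters at
  frequency p_R0 in association with the focal haplotype.  Rodent control
  keeps the census at Nei while resistance evolves (t1 to t2); once
  resistance is established the census recovers to Ne0 by constant growth
  over the following ``recovery_gens`` generations (default 20).

The population starts with ``n_haplotypes`` (default 25) mtDNA
haplotypes: one focal haplotype at initial frequency i0 and the rest
sharing 1 - i0 equally.  No mutation occurs during the simulated 500
generations.  Since mtDNA is transmitted maternally, the drifting pool
holds Ne/2 copies per generation under the default ``mt_copy_rule``
("half": the female half of a two-sex census of Ne diploids); "full" uses
Ne copies as a sensitivity switch.

State is a per-replicate count vector over haplotype classes (scenarios
L/M) or joint haplotype x resistance-genotype classes (scenario R),
resampled multinomially each generation — the exact Wright-Fisher law at
this resolution, vectorised across replicates.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

__all__ = [
    "DemographicModel",
    "SimulationResult",
    "ThresholdResult",
    "initial_haplotype_counts",
    "simulate_model",
    "prob_exceed",
    "threshold_initial_frequency",
]

_GENOTYPES = ("SS", "RS", "RR")
_MATERNAL_R = np.array([0.0, 0.5, 1.0])  # P(transmit R | genotype)
_DOSE = np.array([0.0, 1.0, 2.0])


@dataclass
class DemographicModel:
    """Full parameterisation of one simulation scenario."""

    scenario: str = "L"
    Ne0: int = 10_000
    Nei: int = 100
    generations_total: int = 500
    t1_gen: int = 400
    t2_gen: int = 420
    n_haplotypes: int = 25
    i0: float = 0.04
    w_SS: float = 0.7
    w_RS: float = 1.0
    w_RR: float = 0.7
    p_R0: float = 0.05
    assoc0: float = 1.0
    growth: str = "linear"
    recovery_gens: int = 20
    mt_copy_rule: str = "half"

    def __post_init__(self) -> None:
        if self.scenario not in ("L", "M", "R"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not (0.0 < self.i0 <= 1.0):
            raise ValueError("i0 must be in (0, 1]")
        if not (self.t1_gen < self.t2_gen <= self.generations_total):
            raise ValueError("need t1 < t2 <= generations_total")
        if self.Nei > self.Ne0:
            raise ValueError("Nei cannot exceed Ne0")
        if self.n_haplotypes < 1:
            raise ValueError("need at least one haplotype")
        if self.mt_copy_rule not in ("half", "full"):
            raise ValueError("mt_copy_rule must be 'half' or 'full'")
        if self.growth not in ("linear", "exponential"):
            raise ValueError("growth must be 'linear' or 'exponential'")
        if not (0.0 <= self.p_R0 <= 1.0 and 0.0 <= self.assoc0 <= 1.0):
            raise ValueError("p_R0 and assoc0 must be in [0, 1]")

    @property
    def fitness(self) -> np.ndarray:
        return np.array([self.w_SS, self.w_RS, self.w_RR])

    def census(self, t: int) -> int:
        """Census effective size at generation t (0..generations_total)."""
        if self.scenario == "L" or t <= self.t1_gen:
            return self.Ne0
        if self.scenario == "M":
            return self.Nei
        # scenario R: control holds the census at Nei while resistance
        # evolves (t1 -> t2); afterwards it recovers to Ne0 over
        # recovery_gens generations of constant growth
        if t <= self.t2_gen:
            return self.Nei
        end = self.t2_gen + self.recovery_gens
        if t >= end or self.recovery_gens <= 0:
            return self.Ne0
        frac = (t - self.t2_gen) / self.recovery_gens
        if self.growth == "linear":
            return round(self.Nei + (self.Ne0 - self.Nei) * frac)
        return round(self.Nei * (self.Ne0 / self.Nei) ** frac)

    def transmitters(self, t: int) -> int:
        n = self.census(t)
        return max(2, n // 2) if self.mt_copy_rule == "half" else n

    def replace(self, **kwargs) -> "DemographicModel":
        d = asdict(self)
        d.update(kwargs)
        return DemographicModel(**d)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DemographicModel":
        return cls(**json.loads(text))


@dataclass
class SimulationResult:
    """Final focal-haplotype frequencies over replicates."""

    model: DemographicModel
    replicates: int
    final_focal_freqs: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.final_focal_freqs = np.asarray(self.final_focal_freqs, dtype=float)
        if self.final_focal_freqs.size != self.replicates:
            raise ValueError("one final frequency per replicate required")
        if ((self.final_focal_freqs < 0) | (self.final_focal_freqs > 1)).any():
            raise ValueError("frequencies must lie in [0, 1]")


def initial_haplotype_counts(n_haplotypes: int, n_copies: int, i0: float) -> np.ndarray:
    """Largest-remainder rounding of the founding haplotype spectrum.

    One focal haplotype (index 0) at frequency ~i0, the remaining
    ``1 - i0`` shared equally by the other haplotypes.
    """
    if not (0.0 < i0 <= 1.0):
        raise ValueError("i0 must be in (0, 1]")
    if n_haplotypes == 1:
        return np.array([n_copies])
    targets = np.full(n_haplotypes, (1.0 - i0) / (n_haplotypes - 1)) * n_copies
    targets[0] = i0 * n_copies
    counts = np.floor(targets).astype(int)
    remainder = targets - counts
    short = n_copies - counts.sum()
    # ties broken by index order (focal first): deterministic
    order = np.argsort(-remainder, kind="stable")
    counts[order[:short]] += 1
    if counts[0] == 0:
        raise ValueError(
            f"i0={i0} rounds the focal haplotype to zero copies at n={n_copies}"
        )
    return counts


def _resample(rng: np.random.Generator, m_next: int, freqs: np.ndarray) -> np.ndarray:
    """Multinomial resampling of every replicate row to size ``m_next``."""
    # guard against tiny negative/over-1 float error
    freqs = np.clip(freqs, 0.0, None)
    freqs = freqs / freqs.sum(axis=-1, keepdims=True)
    return rng.multinomial(m_next, freqs)


def _introduce_resistance(
    counts: np.ndarray, model: DemographicModel
) -> np.ndarray:
    """Expand haplotype counts (reps, K) to joint (reps, K, 3) classes at t1.

    R allele copies (2 * M * p_R0 in total) enter as heterozygotes,
    ``assoc0`` of them in focal-haplotype individuals, the rest spread
    over all individuals proportionally.  Deterministic rounding; any
    focal shortfall falls back to non-focal carriers.
    """
    reps, k = counts.shape
    joint = np.zeros((reps, k, 3), dtype=np.int64)
    joint[:, :, 0] = counts
    m = counts.sum(axis=1)  # transmitters per replicate (constant)
    r_copies = np.round(2 * m * model.p_R0).astype(int)
    for rep in range(reps):
        r = r_copies[rep]
        focal_r = min(int(round(model.assoc0 * r)), int(counts[rep, 0]))
        joint[rep, 0, 0] -= focal_r
        joint[rep, 0, 1] += focal_r
        rest = r - focal_r
        if rest > 0:
            # distribute the remaining copies over SS individuals by share
            pool = joint[rep, :, 0].astype(float)
            if pool.sum() > 0:
                alloc = np.floor(pool / pool.sum() * rest).astype(int)
                alloc = np.minimum(alloc, joint[rep, :, 0])
                deficit = rest - alloc.sum()
                order = np.argsort(-(joint[rep, :, 0] - alloc))
                for h in order:
                    if deficit <= 0:
                        break
                    room = joint[rep, h, 0] - alloc[h]
                    take = min(room, deficit)
                    alloc[h] += take
                    deficit -= take
                joint[rep, :, 0] -= alloc
                joint[rep, :, 1] += alloc
    return joint


def _selection_generation(
    rng: np.random.Generator,
    joint: np.ndarray,
    m_next: int,
    fitness: np.ndarray,
) -> np.ndarray:
    """One generation with viability selection and random mating.

    Mothers are drawn from the post-selection joint (haplotype, genotype)
    pool; the offspring haplotype is maternal, the maternal allele follows
    Mendelian transmission and the paternal allele is an independent draw
    from the post-selection allele pool.
    """
    reps, k, _ = joint.shape
    f = joint.astype(float)
    f = f * fitness[None, None, :]
    tot = f.sum(axis=(1, 2), keepdims=True)
    f = f / tot
    # paternal R-allele frequency per replicate
    p = (f * (_DOSE / 2.0)[None, None, :]).sum(axis=(1, 2))[:, None]
    # maternal transmitted-allele masses per haplotype
    mat_r = (f * _MATERNAL_R[None, None, :]).sum(axis=2)  # (reps, k)
    mat_s = (f * (1.0 - _MATERNAL_R)[None, None, :]).sum(axis=2)
    q = np.empty_like(f)
    q[:, :, 0] = mat_s * (1.0 - p)
    q[:, :, 1] = mat_s * p + mat_r * (1.0 - p)
    q[:, :, 2] = mat_r * p
    flat = _resample(rng, m_next, q.reshape(reps, k * 3))
    return flat.reshape(reps, k, 3)


def simulate_model(
    model: DemographicModel,
    replicates: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SimulationResult:
    """Simulate final focal-haplotype frequencies under one scenario.

    All replicates advance in lock-step through vectorised multinomial
    resampling; ``seed`` makes the run reproducible.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    k = model.n_haplotypes
    m_now = model.transmitters(0)
    counts = np.tile(initial_haplotype_counts(k, m_now, model.i0), (replicates, 1))

    neutral_until = (
        model.generations_total if model.scenario != "R" else model.t1_gen
    )

    for t in range(1, model.generations_total + 1):
        m_next = model.transmitters(t)
        if model.scenario == "R" and t == model.t1_gen + 1 and counts.ndim == 2:
            # the crash happens together with the introduction of resistance
            counts = _introduce_resistance(counts, model)
        if counts.ndim == 2:
            counts = _resample(rng, m_next, counts / m_now)
        else:
            counts = _selection_generation(rng, counts, m_next, model.fitness)
        m_now = m_next
        if t <= neutral_until and counts.ndim == 3:  # pragma: no cover
            raise AssertionError("joint state before t1")

    if counts.ndim == 3:
        focal = counts[:, 0, :].sum(axis=1)
    else:
        focal = counts[:, 0]
    return SimulationResult(model, replicates, focal / m_now, seed)


def prob_exceed(result: SimulationResult, threshold: float = 0.72) -> float:
    """Fraction of replicates whose final focal frequency is >= threshold."""
    if result.final_focal_freqs.size == 0:
        raise ValueError("empty simulation result")
    return float(np.mean(result.final_focal_freqs >= threshold - 1e-12))


def _pava_increasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: least-squares isotonic (increasing) fit."""
    y = np.asarray(y, dtype=float)
    vals: list[float] = []
    wts: list[float] = []
    starts: list[int] = []
    for i, v in enumerate(y):
        vals.append(float(v))
        wts.append(1.0)
        starts.append(i)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v2, w2 = vals.pop(), wts.pop()
            starts.pop()
            vals[-1] = (vals[-1] * wts[-1] + v2 * w2) / (wts[-1] + w2)
            wts[-1] += w2
    fitted = np.empty_like(y)
    bounds = starts + [len(y)]
    for v, lo, hi in zip(vals, bounds[:-1], bounds[1:]):
        fitted[lo:hi] = v
    return fitted


@dataclass
class ThresholdResult:
    """Outcome of an initial-frequency sweep."""

    threshold: float  # interpolated minimal i0 (NaN when not attained)
    attained: bool
    grid: np.ndarray
    probs: np.ndarray  # raw exceedance probabilities per grid point
    probs_isotonic: np.ndarray
    max_prob: float
    target: float
    alpha: float


def threshold_initial_frequency(
    model_base: DemographicModel,
    target: float = 0.72,
    alpha: float = 0.05,
    grid_step: float = 0.01,
    replicates: int = 1000,
    seed: int | None = None,
    i0_grid: np.ndarray | None = None,
    bracket: bool = True,
) -> ThresholdResult:
    """Smallest initial focal frequency whose exceedance probability at
    ``target`` reaches ``alpha``.

    Sweeps i0 over a grid (default step 0.01 over (0, 1)), estimates
    P(final >= target) with ``replicates`` runs per point, enforces
    monotonicity in i0 by isotonic (PAVA) smoothing, then reports the
    crossing with linear interpolation between the bracketing grid
    points.  ``bracket=True`` first locates the crossing with a coarse,
    cheap sweep and only evaluates the fine grid around it, extending the
    window whenever the crossing falls on its edge.
    """
    full = np.round(np.arange(grid_step, 1.0, grid_step), 10)

    def point_rng(i0: float, phase: int) -> np.random.Generator:
        idx = int(round(i0 / grid_step))
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(phase, idx))
        return np.random.default_rng(ss)

    cache: dict[float, float] = {}

    def evaluate(i0: float, reps: int, phase: int) -> float:
        model = model_base.replace(i0=float(i0))
        res = simulate_model(model, reps, rng=point_rng(i0, phase))
        return prob_exceed(res, target)

    def eval_grid(points: np.ndarray, reps: int, phase: int) -> np.ndarray:
        out = np.empty(len(points))
        for idx, i0 in enumerate(points):
            key = round(float(i0), 10)
            if key not in cache:
                cache[key] = evaluate(i0, reps, phase)
            out[idx] = cache[key]
        return out

    if i0_grid is not None:
        grid = np.round(np.asarray(i0_grid, dtype=float), 10)
    elif bracket:
        coarse_step = max(grid_step, 0.05)
        coarse = np.round(np.arange(grid_step, 1.0, coarse_step), 10)
        coarse_probs = np.empty(len(coarse))
        for idx, i0 in enumerate(coarse):
            coarse_probs[idx] = evaluate(i0, max(100, replicates // 4), phase=0)
        coarse_iso = _pava_increasing(coarse_probs)
        above = np.where(coarse_iso >= alpha)[0]
        if above.size == 0:
            lo, hi = float(coarse[-1]), float(full[-1])
        else:
            first = int(above[0])
            lo = float(coarse[max(0, first - 2)]) - coarse_step
            hi = float(coarse[first]) + 2 * coarse_step
        grid = full[(full >= lo - 1e-9) & (full <= hi + 1e-9)]
    else:
        grid = full

    while True:
        probs = eval_grid(grid, replicates, phase=1)
        iso = _pava_increasing(probs)
        above = np.where(iso >= alpha)[0]
        grid_exhausted = grid[-1] >= full[-1] - 1e-9
        if above.size == 0:
            if grid_exhausted or i0_grid is not None:
                return ThresholdResult(
                    math.nan, False, grid, probs, iso, float(iso.max()), target, alpha
                )
            # crossing lies above the window: extend upward
            hi = min(full[-1], grid[-1] + 0.1)
            grid = full[(full >= grid[0] - 1e-9) & (full <= hi + 1e-9)]
            continue
        j = int(above[0])
        if j == 0 and grid[0] > full[0] + 1e-9 and i0_grid is None:
            # crossing may lie below the window: extend downward
            lo = max(full[0], grid[0] - 0.1)
            grid = full[(full >= lo - 1e-9) & (full <= grid[-1] + 1e-9)]
            continue
        break

    if j == 0 or iso[j] <= iso[j - 1]:
        crossing = float(grid[j])
    else:
        x0, x1 = grid[j - 1], grid[j]
        y0, y1 = iso[j - 1], iso[j]
        crossing = float(x0 + (alpha - y0) * (x1 - x0) / (y1 - y0))
    return ThresholdResult(
        crossing, True, grid, probs, iso, float(iso.max()), target, alpha
    )
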