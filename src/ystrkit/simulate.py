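"""Synthetic Y-STR cohorts under a stepwise mutation model.

The generator emulates the structure of a multi-population forensic
Y-STR study: a handful of founder patrilineages per population, each
sampled male descending from a founder through an independent line of
``g`` generations (a star-genealogy approximation), every locus
mutating per generation with probability mu and stepping +-1 repeat
(symmetric single-step SMM).  Under this model the repeat-count offset
of one line after g generations has mean 0 and variance mu * g, which
is the calibration oracle for the whole engine.

Per-locus default rates sit inside the range observed for Y-STR loci
(roughly 4e-4 to 7e-2 per generation), faster for the rapidly mutating
loci (DYS458, DYS439, DYS456).  DYS389II is represented internally as
DYS389I plus an independently mutating second repeat stretch, so the
DYS389II >= DYS389I constraint holds by construction.  Repeat counts
reflect at the validity bounds [5, 60].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .markers import Haplotype, PopulationSample, YFILER17
from . import stats as _stats

__all__ = [
    "SIM_SLOTS",
    "BASE_ALLELES",
    "DEFAULT_MUT_RATES",
    "MUT_RATE_RANGE",
    "SimulationConfig",
    "smm_offsets",
    "make_founders",
    "simulate_population",
    "simulate_divergent_pair",
    "make_study_like_dataset",
]

# 17 independently simulated allele slots (DYS385 as two slots; DYS389II
# as DYS389I + the second stretch "DYS389B").
SIM_SLOTS: tuple[str, ...] = (
    "DYS19", "DYS385a", "DYS385b", "DYS389I", "DYS389B", "DYS390",
    "DYS391", "DYS392", "DYS393", "DYS437", "DYS438", "DYS439",
    "DYS448", "DYS456", "DYS458", "DYS635", "Y_GATA_H4",
)

# modal alleles of common reference haplotypes, used as the ancestral state
BASE_ALLELES: dict[str, int] = {
    "DYS19": 14, "DYS385a": 11, "DYS385b": 14, "DYS389I": 13, "DYS389B": 16,
    "DYS390": 24, "DYS391": 10, "DYS392": 11, "DYS393": 12, "DYS437": 15,
    "DYS438": 10, "DYS439": 12, "DYS448": 19, "DYS456": 15, "DYS458": 16,
    "DYS635": 23, "Y_GATA_H4": 12,
}

MUT_RATE_RANGE = (1e-5, 1e-1)

# per-generation, per-locus single-step rates (slow loci ~5e-4, fast ~8e-3)
DEFAULT_MUT_RATES: dict[str, float] = {
    "DYS19": 2.2e-3, "DYS385a": 2.1e-3, "DYS385b": 2.1e-3,
    "DYS389I": 2.5e-3, "DYS389B": 2.7e-3, "DYS390": 2.1e-3,
    "DYS391": 2.6e-3, "DYS392": 5.0e-4, "DYS393": 1.1e-3,
    "DYS437": 1.2e-3, "DYS438": 5.0e-4, "DYS439": 5.1e-3,
    "DYS448": 1.8e-3, "DYS456": 4.2e-3, "DYS458": 8.2e-3,
    "DYS635": 3.8e-3, "Y_GATA_H4": 2.8e-3,
}

_REFLECT_LO, _REFLECT_HI = 5, 60


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters.

    populations: (label, n) pairs; n_founders founder lineages are shared
    across populations, mixed with population-specific Dirichlet weights.
    genealogy_depth: generations from founder to each sampled male.
    divergence_generations: population-private drift of the founder
    haplotypes before within-population sampling.
    """

    populations: tuple[tuple[str, int], ...]
    n_founders: int = 6
    genealogy_depth: int = 60
    divergence_generations: int = 0
    mutation_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MUT_RATES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for label, n in self.populations:
            if n < 2:
                raise ValueError(f"population {label} needs n >= 2")
        for slot, mu in self.mutation_rates.items():
            if not (MUT_RATE_RANGE[0] <= mu <= MUT_RATE_RANGE[1]):
                raise ValueError(
                    f"mutation rate {mu} at {slot} outside {MUT_RATE_RANGE}"
                )


def smm_offsets(rng: np.random.Generator, n: int, g: int, mu: float) -> np.ndarray:
    """Net repeat offsets of n independent lines after g generations.

    Each generation mutates with probability mu, stepping +1 or -1 with
    equal probability, so Var(offset) = mu * g exactly.
    """
    k = rng.binomial(g, mu, size=n)
    up = rng.binomial(k, 0.5)
    return (2 * up - k).astype(np.int64)


def _reflect(values: np.ndarray, lo: int = _REFLECT_LO, hi: int = _REFLECT_HI) -> np.ndarray:
    v = values.astype(np.int64)
    for _ in range(8):  # converges immediately at realistic drift scales
        over, under = v > hi, v < lo
        if not (over.any() or under.any()):
            break
        v[over] = 2 * hi - v[over]
        v[under] = 2 * lo - v[under]
    return np.clip(v, lo, hi)


def make_founders(
    rng: np.random.Generator, k: int, spread: float = 0.9
) -> list[dict[str, int]]:
    """Draw k distinct founder haplotypes around the modal ancestral state.

    Each slot of each founder is shifted by a signed Poisson(spread)
    number of repeat steps, producing inter-lineage distances of a few
    mutational steps — the backbone structure of a real cohort's
    haplogroups.
    """
    founders: list[dict[str, int]] = []
    seen = set()
    while len(founders) < k:
        f = {}
        for slot in SIM_SLOTS:
            steps = int(rng.poisson(spread))
            sign = 1 if rng.random() < 0.5 else -1
            f[slot] = int(
                _reflect(np.array([BASE_ALLELES[slot] + sign * steps]))[0]
            )
        key = tuple(f[s] for s in SIM_SLOTS)
        if key not in seen:
            seen.add(key)
            founders.append(f)
    return founders


def _evolve(
    founder: Mapping[str, int],
    g: int,
    rates: Mapping[str, float],
    rng: np.random.Generator,
    n: int = 1,
) -> np.ndarray:
    """(n, slots) matrix of alleles after n independent g-generation lines."""
    out = np.empty((n, len(SIM_SLOTS)), dtype=np.int64)
    for j, slot in enumerate(SIM_SLOTS):
        base = founder[slot]
        out[:, j] = _reflect(base + smm_offsets(rng, n, g, rates[slot]))
    return out


def _row_to_haplotype(row: np.ndarray, sample_id: str, population: str) -> Haplotype:
    slots = dict(zip(SIM_SLOTS, (int(x) for x in row)))
    alleles: dict[str, object] = {
        "DYS385": (float(slots["DYS385a"]), float(slots["DYS385b"])),
        "DYS389I": float(slots["DYS389I"]),
        "DYS389II": float(slots["DYS389I"] + slots["DYS389B"]),
    }
    for slot in SIM_SLOTS:
        if slot in ("DYS385a", "DYS385b", "DYS389I", "DYS389B"):
            continue
        alleles[slot] = float(slots[slot])
    return Haplotype(sample_id=sample_id, population=population, alleles=alleles)


def simulate_population(
    label: str,
    n: int,
    founders: Sequence[Mapping[str, int]],
    weights: Sequence[float],
    genealogy_depth: int,
    rates: Mapping[str, float],
    rng: np.random.Generator,
) -> PopulationSample:
    """Sample n males, each an independent line from a weighted founder."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    choices = rng.choice(len(founders), size=n, p=w)
    haps = []
    for i, fi in enumerate(choices):
        row = _evolve(founders[fi], genealogy_depth, rates, rng, n=1)[0]
        haps.append(_row_to_haplotype(row, f"{label}-{i + 1:04d}", label))
    return PopulationSample(label=label, haplotypes=tuple(haps), panel=YFILER17)


def simulate_divergent_pair(
    cfg: SimulationConfig, t_split: int
) -> tuple[PopulationSample, PopulationSample]:
    """Two populations drifting apart for t_split generations.

    Shared founders evolve independently in each daughter population for
    t_split generations before within-population sampling; larger
    t_split stochastically increases the between-population Rst.
    """
    if len(cfg.populations) != 2:
        raise ValueError("simulate_divergent_pair needs exactly 2 populations")
    rng = np.random.default_rng(cfg.seed)
    founders = make_founders(rng, cfg.n_founders)
    weights = np.ones(cfg.n_founders)
    out = []
    for label, n in cfg.populations:
        local = [
            dict(zip(SIM_SLOTS, _evolve(f, t_split, cfg.mutation_rates, rng)[0]))
            for f in founders
        ]
        out.append(
            simulate_population(
                label, n, local, weights, cfg.genealogy_depth,
                cfg.mutation_rates, rng,
            )
        )
    return out[0], out[1]


STUDY_SIZES: tuple[tuple[str, int], ...] = (
    ("PopA", 128), ("PopB", 122), ("PopC", 108), ("PopD", 135),
)


def make_study_like_dataset(
    seed: int,
    sizes: tuple[tuple[str, int], ...] = STUDY_SIZES,
    n_founders: int = 6,
    genealogy_depth: int = 60,
    divergence_generations: int = 40,
    max_retries: int = 5,
) -> list[PopulationSample]:
    """A four-population cohort shaped like a real Yfiler study.

    Sample sizes 128/122/108/135, six founder lineages with Dirichlet
    mixing proportions per population, population-private founder drift,
    and per-individual genealogy depth chosen so every population's
    17-locus haplotype diversity lands in [0.98, 1.0] (checked at
    generation time; the depth is increased and the cohort redrawn on
    the rare miss).
    """
    rates = dict(DEFAULT_MUT_RATES)
    g = genealogy_depth
    for attempt in range(max_retries):
        rng = np.random.default_rng((seed + 7919 * attempt) % (2**31))
        founders = make_founders(rng, n_founders)
        samples = []
        for label, n in sizes:
            weights = rng.dirichlet(np.ones(n_founders))
            local = [
                dict(zip(SIM_SLOTS, _evolve(f, divergence_generations, rates, rng)[0]))
                for f in founders
            ]
            samples.append(
                simulate_population(label, n, local, weights, g, rates, rng)
            )
        hds = [_stats.haplotype_summary(s, per_locus=False).hd for s in samples]
        if all(0.98 <= hd <= 1.0 for hd in hds):
            return samples
        g = int(g * 1.5) + 1
    raise RuntimeError(
        f"could not reach haplotype diversity >= 0.98 within {max_retries} retries"
    )
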