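"""Two-level AMOVA and pairwise population distances (Rst / Fst).

Analysis of molecular variance partitions distance-based variation
within versus among populations.  For two populations with sample sizes
n_a, n_b (N = n_a + n_b) and a squared inter-individual distance d_ij:

    SSD_total  = (1/N) * sum_{i<j over all} d_ij
    SSD_within = sum_g (1/n_g) * sum_{i<j in g} d_ij
    SSD_among  = SSD_total - SSD_within
    sigma2_w   = SSD_within / (N - 2)
    n0         = N - (n_a^2 + n_b^2)/N          (df_among = 1)
    sigma2_a   = (SSD_among - sigma2_w) / n0
    Phi_st     = sigma2_a / (sigma2_a + sigma2_w)

Two haplotype metrics give the two familiar Y-STR statistics:

* ``identity`` (Fst): d = 0 if the haplotypes are equal on the active
  loci, else 1.
* ``repeat_ssd`` (Rst): d = sum over single-copy loci of the squared
  repeat-count difference — the stepwise-mutation-aware distance.

Significance comes from permuting individuals across the two samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .markers import (
    DYS389_DELTA,
    Haplotype,
    Panel,
    PopulationSample,
    to_repeat_vector,
)

__all__ = [
    "HaplotypeMetric",
    "AmovaResult",
    "DistanceMatrix",
    "IDENTITY",
    "REPEAT_SSD",
    "metric_by_name",
    "haplotype_distance",
    "squared_distance_matrix",
    "amova_two_pop",
    "pairwise_matrix",
    "permutation_pvalue",
]


@dataclass(frozen=True)
class HaplotypeMetric:
    """Inter-haplotype distance definition used by AMOVA.

    ``repeat_ssd`` uses squared repeat differences over single-copy
    loci.  By default DYS389II enters as the difference DYS389II -
    DYS389I (two independent repeat stretches, no double counting) and
    DYS385 is excluded (no canonical pairing of the duplicated alleles);
    when included, DYS385 contributes the minimum squared-difference sum
    over the two pairings of the sorted pairs.  ``identity`` compares
    whole haplotypes on the active loci (DYS385 included by default).
    """

    name: str = "repeat_ssd"
    loci: tuple[str, ...] | None = None
    include_dys385: bool | None = None
    split_dys389: bool = True

    def __post_init__(self) -> None:
        if self.name not in ("identity", "repeat_ssd"):
            raise ValueError(f"unknown metric {self.name!r}")

    @property
    def dys385_included(self) -> bool:
        if self.include_dys385 is not None:
            return self.include_dys385
        return self.name == "identity"

    def active_loci(self, panel: Panel) -> tuple[str, ...]:
        """Locus tokens this metric evaluates on a given panel."""
        if self.loci is not None:
            return self.loci
        out: list[str] = []
        for locus in panel.loci:
            if locus.name == "DYS385":
                if self.dys385_included:
                    out.append("DYS385")
                continue
            if (
                locus.name == "DYS389II"
                and self.split_dys389
                and "DYS389I" in panel
                and self.name == "repeat_ssd"
            ):
                out.append(DYS389_DELTA)
                continue
            out.append(locus.name)
        return tuple(out)


IDENTITY = HaplotypeMetric(name="identity")
REPEAT_SSD = HaplotypeMetric(name="repeat_ssd")


def metric_by_name(name: str) -> HaplotypeMetric:
    aliases = {"fst": IDENTITY, "identity": IDENTITY,
               "rst": REPEAT_SSD, "repeat_ssd": REPEAT_SSD}
    try:
        return aliases[name.lower()]
    except KeyError:
        raise ValueError(f"unknown metric {name!r}") from None


def _dys385_sq(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    a = (p1[0] - p2[0]) ** 2 + (p1[1] - p2[1]) ** 2
    b = (p1[0] - p2[1]) ** 2 + (p1[1] - p2[0]) ** 2
    return min(a, b)


def _locus_value(h: Haplotype, token: str) -> float:
    if token == DYS389_DELTA:
        return float(h.alleles["DYS389II"]) - float(h.alleles["DYS389I"])
    return float(h.alleles[token])


def haplotype_distance(
    h1: Haplotype, h2: Haplotype, metric: HaplotypeMetric, panel: Panel
) -> float:
    """Metric distance between two complete haplotypes on a panel."""
    loci = metric.active_loci(panel)
    for h in (h1, h2):
        nulls = [l for l in loci if not h.is_complete([l])]
        if nulls:
            raise ValueError(
                f"sample {h.sample_id} has null alleles at: " + ", ".join(nulls)
            )
    if metric.name == "identity":
        same = all(
            (h1.alleles["DYS385"] == h2.alleles["DYS385"])
            if l == "DYS385"
            else (_locus_value(h1, l) == _locus_value(h2, l))
            for l in loci
        )
        return 0.0 if same else 1.0
    total = 0.0
    for l in loci:
        if l == "DYS385":
            total += _dys385_sq(h1.alleles["DYS385"], h2.alleles["DYS385"])
        else:
            d = _locus_value(h1, l) - _locus_value(h2, l)
            total += d * d
    return total


def _complete_on_metric(
    sample: PopulationSample, metric: HaplotypeMetric
) -> list[Haplotype]:
    loci = metric.active_loci(sample.panel)
    return [h for h in sample.haplotypes if h.is_complete(loci)]


def squared_distance_matrix(
    haplotypes: Sequence[Haplotype], metric: HaplotypeMetric, panel: Panel
) -> np.ndarray:
    """Pairwise squared-metric matrix over individuals (dense, symmetric)."""
    loci = metric.active_loci(panel)
    n = len(haplotypes)
    if metric.name == "repeat_ssd":
        vec_loci = tuple(l for l in loci if l != "DYS385")
        X = np.array([[_locus_value(h, l) for l in vec_loci] for h in haplotypes])
        D = cdist(X, X, metric="sqeuclidean") if n else np.zeros((0, 0))
        if "DYS385" in loci:
            pairs = [h.alleles["DYS385"] for h in haplotypes]
            extra = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    extra[i, j] = extra[j, i] = _dys385_sq(pairs[i], pairs[j])
            D = D + extra
        return D
    keys = []
    for h in haplotypes:
        keys.append(tuple(
            h.alleles["DYS385"] if l == "DYS385" else _locus_value(h, l)
            for l in loci
        ))
    codes = {k: i for i, k in enumerate(dict.fromkeys(keys))}
    c = np.array([codes[k] for k in keys])
    return (c[:, None] != c[None, :]).astype(float)


@dataclass(frozen=True)
class AmovaResult:
    """Variance decomposition from a two-population AMOVA."""

    ssd_total: float
    ssd_within: float
    ssd_among: float
    df_among: int
    df_within: int
    sigma2_within: float
    sigma2_among: float
    n0: float
    phi: float


def _phi_from_matrix(D: np.ndarray, n_a: int, n_b: int) -> AmovaResult:
    N = n_a + n_b
    idx_a = np.arange(n_a)
    idx_b = np.arange(n_a, N)
    total = D.sum() / 2.0 / N
    within_a = D[np.ix_(idx_a, idx_a)].sum() / 2.0 / n_a
    within_b = D[np.ix_(idx_b, idx_b)].sum() / 2.0 / n_b
    within = within_a + within_b
    among = total - within
    df_within = N - 2
    sigma2_w = within / df_within
    n0 = N - (n_a * n_a + n_b * n_b) / N
    sigma2_a = (among / 1.0 - sigma2_w) / n0
    denom = sigma2_a + sigma2_w
    phi = sigma2_a / denom if denom != 0 else 0.0
    return AmovaResult(
        ssd_total=total,
        ssd_within=within,
        ssd_among=among,
        df_among=1,
        df_within=df_within,
        sigma2_within=sigma2_w,
        sigma2_among=sigma2_a,
        n0=n0,
        phi=phi,
    )


def amova_two_pop(
    a: PopulationSample,
    b: PopulationSample,
    metric: HaplotypeMetric = REPEAT_SSD,
) -> AmovaResult:
    """Two-level AMOVA between two population samples."""
    ha, hb = _complete_on_metric(a, metric), _complete_on_metric(b, metric)
    if len(ha) < 2 or len(hb) < 2:
        raise ValueError("AMOVA requires n >= 2 complete haplotypes per sample")
    D = squared_distance_matrix(list(ha) + list(hb), metric, a.panel)
    return _phi_from_matrix(D, len(ha), len(hb))


@dataclass(frozen=True)
class DistanceMatrix:
    """Labeled symmetric matrix of pairwise Phi-st with optional p-values."""

    labels: tuple[str, ...]
    values: np.ndarray
    pvalues: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        assert v.shape == (len(self.labels), len(self.labels))
        assert np.allclose(v, v.T) and np.allclose(np.diag(v), 0)

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def permutation_pvalue(
    a: PopulationSample,
    b: PopulationSample,
    metric: HaplotypeMetric = REPEAT_SSD,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value for Phi > 0.

    Individuals are permuted across the two samples keeping sizes fixed;
    p = (#{Phi_perm >= Phi_obs} + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ha, hb = _complete_on_metric(a, metric), _complete_on_metric(b, metric)
    n_a, n_b = len(ha), len(hb)
    if n_a < 2 or n_b < 2:
        raise ValueError("AMOVA requires n >= 2 complete haplotypes per sample")
    D = squared_distance_matrix(list(ha) + list(hb), metric, a.panel)
    observed = _phi_from_matrix(D, n_a, n_b).phi
    rng = np.random.default_rng(seed)
    hits = 0
    N = n_a + n_b
    for _ in range(n_perm):
        perm = rng.permutation(N)
        Dp = D[np.ix_(perm, perm)]
        if _phi_from_matrix(Dp, n_a, n_b).phi >= observed:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def pairwise_matrix(
    samples: Sequence[PopulationSample],
    metric: HaplotypeMetric = REPEAT_SSD,
    n_perm: int = 0,
    seed: int = 0,
) -> DistanceMatrix:
    """All-pairs Phi-st matrix (and p-values when ``n_perm`` > 0)."""
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    m = len(samples)
    values = np.zeros((m, m))
    pvals = np.ones((m, m)) if n_perm else None
    for i in range(m):
        for j in range(i + 1, m):
            values[i, j] = values[j, i] = amova_two_pop(
                samples[i], samples[j], metric
            ).phi
            if n_perm:
                p = permutation_pvalue(
                    samples[i], samples[j], metric, n_perm=n_perm,
                    seed=seed + 1000 * i + j,
                )
                pvals[i, j] = pvals[j, i] = p
    if pvals is not None:
        np.fill_diagonal(pvals, 1.0)
    return DistanceMatrix(
        labels=tuple(s.label for s in samples), values=values, pvalues=pvals
    )
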