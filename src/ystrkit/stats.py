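"""Direct-count frequencies and forensic diversity statistics.

All frequencies come from direct counting: the frequency of an allele
(or whole haplotype) is its count divided by the number of called
individuals.  From haplotype frequencies p_h and sample size n:

    RMP (random match probability)  = sum_h p_h^2
    HD  (haplotype diversity)       = n/(n-1) * (1 - RMP)        (Nei)
    TH  = number of distinct haplotypes
    UH  = number of singleton haplotypes
    DC  (discrimination capacity)   = TH / n
    %UH                             = UH / n

Gene diversity (GD) is the locus-level analog of HD computed from allele
frequencies; DYS385 is treated as one key holding the unordered allele
pair ("combination").  Polymorphic information content uses the Botstein
form and discrimination power the haploid 1 - sum p^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Hashable, Iterable, Mapping, Sequence

import pandas as pd

from .markers import Panel, PopulationSample, restrict_to_panel

__all__ = [
    "FrequencyTable",
    "DiversitySummary",
    "allele_frequencies",
    "haplotype_frequencies",
    "nei_diversity",
    "gene_diversity",
    "pic",
    "power_of_discrimination",
    "haplotype_summary",
    "resolution_table",
    "overall_gene_diversity",
]


@dataclass(frozen=True)
class FrequencyTable:
    """Counts and relative frequencies for alleles, pairs, or haplotypes."""

    counts: Mapping[Hashable, int]
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("frequency table needs n >= 1")
        total = sum(self.counts.values())
        if total != self.n:
            raise ValueError(f"counts sum to {total}, expected n={self.n}")
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("zero or negative count in frequency table")

    def frequency(self, key: Hashable) -> float:
        return self.counts[key] / self.n

    @property
    def frequencies(self) -> dict[Hashable, float]:
        return {k: c / self.n for k, c in self.counts.items()}

    @property
    def sum_p_squared(self) -> float:
        return sum((c / self.n) ** 2 for c in self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)


def _called_values(sample: PopulationSample, locus: str) -> list:
    out = []
    for h in sample.haplotypes:
        v = h.alleles.get(locus)
        if v is not None:
            out.append(v)
    return out


def allele_frequencies(sample: PopulationSample, locus) -> FrequencyTable:
    """Direct-count allele frequencies at one locus.

    For DYS385 the keys are the unordered (sorted) allele pairs — the
    forensic "combinations" — so each male contributes one observation.
    Individuals with a null call at the locus are excluded; n is the
    number of called individuals.
    """
    name = getattr(locus, "name", locus)
    values = _called_values(sample, name)
    if not values:
        raise ValueError(f"no called individuals at {name} in {sample.label}")
    counts: dict[Hashable, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    return FrequencyTable(counts=counts, n=len(values))


def haplotype_frequencies(
    sample: PopulationSample, panel: Panel | None = None
) -> FrequencyTable:
    """Direct-count whole-haplotype frequencies on a panel.

    Individuals with any null call on the panel are excluded (direct
    counting is only defined over complete profiles).
    """
    panel = panel or sample.panel
    work = restrict_to_panel(sample, panel) if panel is not sample.panel else sample
    complete = work.complete_haplotypes()
    if not complete:
        raise ValueError(f"no complete haplotypes at {panel.name} in {sample.label}")
    counts: dict[Hashable, int] = {}
    for h in complete:
        k = h.key(panel)
        counts[k] = counts.get(k, 0) + 1
    return FrequencyTable(counts=counts, n=len(complete))


def nei_diversity(n: int, sum_p_squared: float) -> float:
    """The unbiased diversity n/(n-1) * (1 - sum p^2).

    Shared by gene diversity (allele frequencies) and haplotype
    diversity (haplotype frequencies, where sum p^2 is the random match
    probability).
    """
    if n < 2:
        raise ValueError("diversity requires n >= 2")
    return n / (n - 1) * (1.0 - sum_p_squared)


def gene_diversity(freqs: FrequencyTable) -> float:
    """Nei's unbiased gene diversity n/(n-1) * (1 - sum p^2)."""
    return nei_diversity(freqs.n, freqs.sum_p_squared)


def power_of_discrimination(freqs: FrequencyTable) -> float:
    """Haploid discrimination power 1 - sum p^2."""
    if freqs.n < 2:
        raise ValueError("discrimination power requires n >= 2")
    return 1.0 - freqs.sum_p_squared


def pic(freqs: FrequencyTable) -> float:
    """Botstein polymorphic information content.

    PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2; always <= the
    discrimination power on the same table.
    """
    if freqs.n < 2:
        raise ValueError("PIC requires n >= 2")
    p = list(freqs.frequencies.values())
    return (
        1.0
        - sum(x * x for x in p)
        - sum(2.0 * a * a * b * b for a, b in combinations(p, 2))
    )


@dataclass(frozen=True)
class DiversitySummary:
    """Haplotype-level forensic parameters plus per-locus diversity maps."""

    population: str
    panel: str
    n: int
    th: int
    uh: int
    rmp: float
    hd: float
    dc: float
    pct_uh: float
    locus_gd: Mapping[str, float] = field(default_factory=dict)
    locus_pic: Mapping[str, float] = field(default_factory=dict)
    locus_dp: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert 0 <= self.uh <= self.th <= self.n


def haplotype_summary(
    sample: PopulationSample, panel: Panel | None = None, per_locus: bool = True
) -> DiversitySummary:
    """Compute the full set of haplotype-level forensic parameters."""
    panel = panel or sample.panel
    hf = haplotype_frequencies(sample, panel)
    n = hf.n
    if n < 2:
        raise ValueError("haplotype summary requires n >= 2 complete haplotypes")
    th = len(hf)
    uh = sum(1 for c in hf.counts.values() if c == 1)
    rmp = hf.sum_p_squared
    hd = nei_diversity(n, rmp)
    locus_gd: dict[str, float] = {}
    locus_pic: dict[str, float] = {}
    locus_dp: dict[str, float] = {}
    if per_locus:
        for locus in panel.locus_names:
            try:
                ft = allele_frequencies(sample, locus)
            except ValueError:
                continue
            if ft.n >= 2:
                locus_gd[locus] = gene_diversity(ft)
                locus_pic[locus] = pic(ft)
                locus_dp[locus] = power_of_discrimination(ft)
    return DiversitySummary(
        population=sample.label,
        panel=panel.name,
        n=n,
        th=th,
        uh=uh,
        rmp=rmp,
        hd=hd,
        dc=th / n,
        pct_uh=uh / n,
        locus_gd=locus_gd,
        locus_pic=locus_pic,
        locus_dp=locus_dp,
    )


def resolution_table(
    sample: PopulationSample, panels: Sequence[Panel]
) -> pd.DataFrame:
    """One row of forensic parameters per panel (haplotype resolution levels)."""
    rows = []
    for panel in panels:
        s = haplotype_summary(sample, panel, per_locus=False)
        rows.append(
            {
                "population": s.population,
                "panel": s.panel,
                "n": s.n,
                "RMP": s.rmp,
                "HD": s.hd,
                "TH": s.th,
                "UH": s.uh,
                "DC": s.dc,
                "pct_UH": s.pct_uh,
            }
        )
    return pd.DataFrame(rows)


def overall_gene_diversity(
    sample: PopulationSample,
    panel: Panel | None = None,
    include_dys385: bool = True,
) -> float:
    """Unweighted mean of per-locus gene diversities over the panel.

    The averaging scheme (with or without the DYS385 combination key) is
    a convention; both are exposed.
    """
    panel = panel or sample.panel
    gds = []
    for locus in panel.locus_names:
        if locus == "DYS385" and not include_dys385:
            continue
        ft = allele_frequencies(sample, locus)
        if ft.n >= 2:
            gds.append(gene_diversity(ft))
    if not gds:
        raise ValueError("no loci with n >= 2 called individuals")
    return sum(gds) / len(gds)
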