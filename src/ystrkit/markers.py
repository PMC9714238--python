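"""Data model for Y-STR haplotypes and forensic marker panels.

Y chromosome short tandem repeats (Y-STRs) are typed as repeat counts
("alleles") at named loci.  A male's calls across a panel of loci form a
haplotype, inherited patrilineally without recombination.  Forensic
practice uses a small family of nested panels: the minimal haplotype
(MH-9), the SWGDAM extension (SWGDAM-11), PowerPlex Y (PPY-12) and the
Yfiler kit (Yfiler-17).  DYS385 is a duplicated locus amplified as an
unordered pair of alleles; DYS389II physically contains the DYS389I
repeat stretch, so DYS389II >= DYS389I whenever both are called.

Microvariant alleles (e.g. 17.2, a partial repeat) are legal and kept as
exact decimal values; they are never rounded to integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "LocusDef",
    "Panel",
    "Haplotype",
    "PopulationSample",
    "MH9",
    "SWGDAM11",
    "PPY12",
    "YFILER17",
    "BUILTIN_PANELS",
    "NETWORK_LOCI_14",
    "DYS389_DELTA",
    "AlleleValidationError",
    "PanelError",
    "validate_allele",
    "restrict_to_panel",
    "to_repeat_vector",
]

# Allowed fractional parts for microvariant alleles (x.0, x.1, x.2, x.3).
_MICROVARIANT_FRACTIONS = (0.0, 0.1, 0.2, 0.3)
ALLELE_MIN = 5.0
ALLELE_MAX = 60.0

# Virtual locus name for the DYS389II - DYS389I difference used in
# repeat-vector space (network construction, optionally Rst).
DYS389_DELTA = "DYS389II-I"


class AlleleValidationError(ValueError):
    """An allele value outside forensic plausibility or a malformed call."""


class PanelError(ValueError):
    """Panel composition or projection error."""


def validate_allele(value: float, locus: str = "?", context: str = "") -> float:
    """Validate a single repeat count; returns the value unchanged.

    Raises :class:`AlleleValidationError` for values outside [5, 60] or
    with a fractional part not in {.0, .1, .2, .3}.
    """
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise AlleleValidationError(
            f"unparseable allele {value!r} at {locus}{' ' + context if context else ''}"
        ) from None
    if not (ALLELE_MIN <= v <= ALLELE_MAX):
        raise AlleleValidationError(
            f"allele {v} at {locus} outside [{ALLELE_MIN:g}, {ALLELE_MAX:g}]"
            f"{' ' + context if context else ''}"
        )
    frac = round(v - int(v), 6)
    if not any(abs(frac - f) < 1e-6 for f in _MICROVARIANT_FRACTIONS):
        raise AlleleValidationError(
            f"allele {v} at {locus} has non-microvariant fractional part"
            f"{' ' + context if context else ''}"
        )
    return v


@dataclass(frozen=True)
class LocusDef:
    """A Y-STR locus: its name and copy number (2 for duplicated DYS385)."""

    name: str
    copy_number: int = 1
    notes: str = ""

    def __post_init__(self) -> None:
        if self.copy_number not in (1, 2):
            raise PanelError(f"copy_number must be 1 or 2, got {self.copy_number}")


@dataclass(frozen=True)
class Panel:
    """An ordered collection of loci defining a haplotype resolution level."""

    name: str
    loci: tuple[LocusDef, ...]

    def __post_init__(self) -> None:
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise PanelError(f"duplicate locus names in panel {self.name}")

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.loci)

    @property
    def n_slots(self) -> int:
        """Number of allele slots (DYS385 contributes two)."""
        return sum(l.copy_number for l in self.loci)

    def locus(self, name: str) -> LocusDef:
        for l in self.loci:
            if l.name == name:
                return l
        raise PanelError(f"locus {name} not in panel {self.name}")

    def __contains__(self, name: object) -> bool:
        return any(l.name == name for l in self.loci)

    def issubset(self, other: "Panel") -> bool:
        return set(self.locus_names) <= set(other.locus_names)


def _panel(name: str, names: Sequence[str]) -> Panel:
    return Panel(
        name,
        tuple(
            LocusDef(n, copy_number=2 if n == "DYS385" else 1) for n in names
        ),
    )


_MH9_LOCI = (
    "DYS19",
    "DYS385",
    "DYS389I",
    "DYS389II",
    "DYS390",
    "DYS391",
    "DYS392",
    "DYS393",
)
MH9 = _panel("MH-9", _MH9_LOCI)
SWGDAM11 = _panel("SWGDAM-11", _MH9_LOCI + ("DYS438", "DYS439"))
PPY12 = _panel("PPY-12", SWGDAM11.locus_names + ("DYS437",))
YFILER17 = _panel(
    "Yfiler-17",
    PPY12.locus_names + ("DYS448", "DYS456", "DYS458", "DYS635", "Y_GATA_H4"),
)

BUILTIN_PANELS: dict[str, Panel] = {
    "mh9": MH9,
    "swgdam11": SWGDAM11,
    "ppy12": PPY12,
    "yfiler17": YFILER17,
}

# The 14 single-copy loci used for repeat-vector space: DYS385 excluded
# (ambiguous pairing), DYS389II replaced by the DYS389II-I difference so
# the two DYS389 slots are independent repeat stretches.
NETWORK_LOCI_14: tuple[str, ...] = (
    "DYS19",
    DYS389_DELTA,
    "DYS390",
    "DYS391",
    "DYS392",
    "DYS393",
    "DYS437",
    "DYS438",
    "DYS439",
    "DYS448",
    "DYS456",
    "DYS458",
    "DYS635",
    "Y_GATA_H4",
)


def _canonical_dys385(value) -> tuple[float, float]:
    """Sort a DYS385 pair ascending; a single peak becomes a duplicated pair."""
    if isinstance(value, (tuple, list)):
        if len(value) == 1:
            a = b = float(value[0])
        elif len(value) == 2:
            a, b = float(value[0]), float(value[1])
        else:
            raise AlleleValidationError(f"DYS385 takes 1 or 2 values, got {value!r}")
    else:
        a = b = float(value)
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class Haplotype:
    """One male's allele calls keyed by locus name.

    ``alleles`` maps locus name to a float (single-copy loci) or an
    ascending pair of floats (DYS385).  Missing calls are ``None``,
    never 0.  Construction canonicalizes DYS385 and validates values.
    """

    sample_id: str
    population: str
    alleles: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, object] = {}
        for locus, value in self.alleles.items():
            if value is None:
                clean[locus] = None
                continue
            if locus == "DYS385":
                pair = _canonical_dys385(value)
                validate_allele(pair[0], locus, f"(sample {self.sample_id})")
                validate_allele(pair[1], locus, f"(sample {self.sample_id})")
                clean[locus] = pair
            else:
                clean[locus] = validate_allele(
                    value, locus, f"(sample {self.sample_id})"
                )
        i, ii = clean.get("DYS389I"), clean.get("DYS389II")
        if i is not None and ii is not None and ii < i:
            raise AlleleValidationError(
                f"DYS389II ({ii}) < DYS389I ({i}) for sample {self.sample_id}"
            )
        object.__setattr__(self, "alleles", clean)

    def get(self, locus: str):
        return self.alleles.get(locus)

    def is_complete(self, loci: Iterable[str]) -> bool:
        return all(self.alleles.get(l) is not None for l in self._expand(loci))

    @staticmethod
    def _expand(loci: Iterable[str]) -> list[str]:
        out = []
        for l in loci:
            if l == DYS389_DELTA:
                out.extend(["DYS389I", "DYS389II"])
            else:
                out.append(l)
        return out

    def key(self, panel: Panel) -> tuple:
        """Hashable identity of this haplotype on a panel's loci."""
        return tuple(self.alleles.get(l) for l in panel.locus_names)

    def restricted(self, panel: Panel) -> "Haplotype":
        return replace(
            self, alleles={l: self.alleles.get(l) for l in panel.locus_names}
        )


@dataclass(frozen=True)
class PopulationSample:
    """A labeled collection of haplotypes typed on a shared panel."""

    label: str
    haplotypes: tuple[Haplotype, ...]
    panel: Panel

    def __post_init__(self) -> None:
        object.__setattr__(self, "haplotypes", tuple(self.haplotypes))

    @property
    def n(self) -> int:
        return len(self.haplotypes)

    def complete_haplotypes(self, loci: Iterable[str] | None = None) -> tuple[Haplotype, ...]:
        """Haplotypes with no missing call at the given loci (default: panel)."""
        loci = tuple(loci) if loci is not None else self.panel.locus_names
        return tuple(h for h in self.haplotypes if h.is_complete(loci))


def restrict_to_panel(sample: PopulationSample, target: Panel) -> PopulationSample:
    """Project a sample onto a smaller panel; sample size is unchanged."""
    missing = set(target.locus_names) - set(sample.panel.locus_names)
    if missing:
        raise PanelError(
            f"target panel {target.name} has loci absent from {sample.panel.name}: "
            + ", ".join(sorted(missing))
        )
    return PopulationSample(
        label=sample.label,
        haplotypes=tuple(h.restricted(target) for h in sample.haplotypes),
        panel=target,
    )


def to_repeat_vector(
    h: Haplotype, loci: Sequence[str] = NETWORK_LOCI_14
) -> tuple[float, ...]:
    """Repeat-count vector over single-copy loci, in the given fixed order.

    The virtual locus ``DYS389II-I`` yields DYS389II - DYS389I, making the
    two DYS389 slots independent repeat stretches.  DYS385 is not a legal
    entry (unordered pair has no single coordinate).
    """
    nulls = [l for l in loci if not h.is_complete([l])]
    if nulls:
        raise AlleleValidationError(
            f"sample {h.sample_id} has null alleles at: " + ", ".join(nulls)
        )
    vec = []
    for l in loci:
        if l == "DYS385":
            raise PanelError("DYS385 cannot appear in a repeat vector")
        if l == DYS389_DELTA:
            vec.append(float(h.alleles["DYS389II"]) - float(h.alleles["DYS389I"]))
        else:
            vec.append(float(h.alleles[l]))
    return tuple(vec)
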