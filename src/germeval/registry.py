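"""The fixed 34-trait panel measured on every cotton accession.

The panel comprises 26 cottonseed nutritional traits — protein, oil
(both % of kernel dry weight), 16 amino acids (% of kernel dry weight)
and 8 fatty acids (% of total fatty acids) — plus 8 fiber traits:
3 yield components (boll weight BW, lint percentage LP, seed index SI)
and 5 quality components (fiber length FL, uniformity FU, strength FS,
micronaire FM, elongation FE).

Each trait carries a *desirability* flag used only to orient principal
components deterministically during composite scoring: ``higher_better``
traits are the breeding targets (protein, amino acids, unsaturated fatty
acids, fiber yield and quality), ``lower_better`` marks saturated fatty
acids, and micronaire is ``neutral`` (mid-range optimum).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .errors import ValidationError

FAMILIES = (
    "protein",
    "oil",
    "amino_acid",
    "fatty_acid",
    "fiber_yield",
    "fiber_quality",
)

#: Families that make up the 26 cottonseed nutritional traits.
NUTRITIONAL_FAMILIES = ("protein", "oil", "amino_acid", "fatty_acid")

DESIRABILITIES = ("higher_better", "lower_better", "neutral")

#: Saturated / unsaturated fatty acid trait codes.
SFA_CODES = ("C14:0", "C16:0", "C18:0", "C20:0")
UFA_CODES = ("C16:1", "C18:1", "C18:2", "C18:3")

#: Essential amino acids of the 16 measured.
EAA_CODES = ("Thr", "Val", "Met", "Ile", "Leu", "Phe", "Lys", "His")


@dataclass(frozen=True)
class TraitEntry:
    """One trait of the panel."""

    code: str
    long_name: str
    family: str
    units: str
    desirability: str

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown trait family {self.family!r}")
        if self.desirability not in DESIRABILITIES:
            raise ValidationError(f"unknown desirability {self.desirability!r}")


@dataclass(frozen=True)
class TraitRegistry:
    """Ordered registry of the 34 panel traits.

    The registry order is the canonical column order for every matrix
    and file the pipeline produces.
    """

    entries: tuple[TraitEntry, ...]

    def __post_init__(self) -> None:
        codes = [e.code for e in self.entries]
        if len(self.entries) != 34:
            raise ValidationError(
                f"registry must hold exactly 34 traits, got {len(self.entries)}"
            )
        if len(set(codes)) != len(codes):
            raise ValidationError("duplicate trait codes in registry")
        counts = {f: sum(e.family == f for e in self.entries) for f in FAMILIES}
        expected = {
            "protein": 1,
            "oil": 1,
            "amino_acid": 16,
            "fatty_acid": 8,
            "fiber_yield": 3,
            "fiber_quality": 5,
        }
        if counts != expected:
            raise ValidationError(f"bad family composition: {counts}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[TraitEntry]:
        return iter(self.entries)

    @property
    def codes(self) -> list[str]:
        return [e.code for e in self.entries]

    def index(self, code: str) -> int:
        """Column index of a trait code in registry order."""
        for i, e in enumerate(self.entries):
            if e.code == code:
                return i
        raise KeyError(f"unknown trait code {code!r}")

    def entry(self, code: str) -> TraitEntry:
        return self.entries[self.index(code)]

    def family_codes(self, family: str) -> list[str]:
        if family not in FAMILIES:
            raise ValidationError(f"unknown trait family {family!r}")
        return [e.code for e in self.entries if e.family == family]

    def family_indices(self, family: str) -> list[int]:
        return [i for i, e in enumerate(self.entries) if e.family == family]

    @property
    def nutritional_codes(self) -> list[str]:
        """The 26 nutritional trait codes (protein, oil, amino acids, fatty acids)."""
        return [e.code for e in self.entries if e.family in NUTRITIONAL_FAMILIES]

    def desirability_signs(self) -> list[int]:
        """+1 for higher_better, -1 for lower_better, 0 for neutral."""
        m = {"higher_better": 1, "lower_better": -1, "neutral": 0}
        return [m[e.desirability] for e in self.entries]


_AMINO_ACIDS = [
    ("Asp", "aspartic acid"),
    ("Thr", "threonine"),
    ("Ser", "serine"),
    ("Glu", "glutamic acid"),
    ("Gly", "glycine"),
    ("Ala", "alanine"),
    ("Val", "valine"),
    ("Met", "methionine"),
    ("Ile", "isoleucine"),
    ("Leu", "leucine"),
    ("Tyr", "tyrosine"),
    ("Phe", "phenylalanine"),
    ("Lys", "lysine"),
    ("His", "histidine"),
    ("Arg", "arginine"),
    ("Pro", "proline"),
]

_FATTY_ACIDS = [
    ("C14:0", "myristic acid", "lower_better"),
    ("C16:0", "palmitic acid", "lower_better"),
    ("C16:1", "palmitoleic acid", "higher_better"),
    ("C18:0", "stearic acid", "lower_better"),
    ("C18:1", "oleic acid", "higher_better"),
    ("C18:2", "linoleic acid", "higher_better"),
    ("C18:3", "alpha-linolenic acid", "higher_better"),
    ("C20:0", "arachidic acid", "lower_better"),
]

_FIBER = [
    ("BW", "boll weight (20 bolls)", "fiber_yield", "g", "higher_better"),
    ("LP", "lint percentage", "fiber_yield", "%", "higher_better"),
    ("SI", "seed index (100-seed weight)", "fiber_yield", "g", "higher_better"),
    ("FL", "fiber length", "fiber_quality", "mm", "higher_better"),
    ("FU", "fiber uniformity", "fiber_quality", "%", "higher_better"),
    ("FS", "fiber strength", "fiber_quality", "cN/tex", "higher_better"),
    ("FM", "fiber micronaire", "fiber_quality", "", "neutral"),
    ("FE", "fiber elongation", "fiber_quality", "%", "higher_better"),
]


def default_registry() -> TraitRegistry:
    """The canonical 34-trait cotton panel in its canonical order."""
    entries: list[TraitEntry] = [
        TraitEntry("protein", "crude protein", "protein", "%", "higher_better"),
        TraitEntry("oil", "crude oil", "oil", "%", "higher_better"),
    ]
    for code, name in _AMINO_ACIDS:
        entries.append(TraitEntry(code, name, "amino_acid", "%", "higher_better"))
    for code, name, desir in _FATTY_ACIDS:
        entries.append(TraitEntry(code, name, "fatty_acid", "%", desir))
    for code, name, family, units, desir in _FIBER:
        entries.append(TraitEntry(code, name, family, units, desir))
    return TraitRegistry(tuple(entries))
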