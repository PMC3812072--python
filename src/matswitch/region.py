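"""Mating-type region architectures of *Schizosaccharomyces pombe*.

The fission-yeast mating-type region carries an expressed locus, *mat1*,
and two silent donor cassettes, *mat2* and *mat3*.  Each cassette slot
holds mating-type content (P or M) and may carry a cis-acting
recombination enhancer (SRE2 or SRE3) next to it.  A strain architecture
is fully described by the two slots plus two trans-acting genotype flags:
whether the heterochromatin protein Swi6 is present, and whether the
Swi2/Swi5 recombination-promoting complex (RPC) is functional.

This module answers purely structural questions: which named laboratory
architectures exist, and whether converting *mat1* from a given donor
slot would change the cell's mating type (a *heterologous*, productive
conversion) or leave it unchanged (a *homologous*, futile one).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, replace
from typing import Union

__all__ = [
    "Allele",
    "Enhancer",
    "CassetteSlot",
    "RegionConfig",
    "ConfigurationError",
    "NAMED_ARCHITECTURES",
    "GENOTYPE_MODIFIERS",
    "make_named_config",
    "is_heterologous",
    "swap_labels",
]


class Allele(str, enum.Enum):
    """Mating-type content: Plus or Minus."""

    P = "P"
    M = "M"

    def other(self) -> "Allele":
        return Allele.M if self is Allele.P else Allele.P


class Enhancer(str, enum.Enum):
    """Recombination enhancer occupying a cassette-adjacent slot.

    ``NONE`` models a deletion of the enhancer next to that cassette.
    """

    SRE2 = "SRE2"
    SRE3 = "SRE3"
    NONE = "NONE"


class ConfigurationError(ValueError):
    """Raised for unknown strain names or malformed region configurations."""


def _as_allele(value: Union[str, Allele]) -> Allele:
    if isinstance(value, Allele):
        return value
    try:
        return Allele(str(value).upper())
    except ValueError:
        raise ConfigurationError(
            f"unknown allele {value!r}; expected one of {[a.value for a in Allele]}"
        ) from None


def _as_enhancer(value: Union[str, Enhancer]) -> Enhancer:
    if isinstance(value, Enhancer):
        return value
    try:
        return Enhancer(str(value).upper())
    except ValueError:
        raise ConfigurationError(
            f"unknown enhancer {value!r}; expected one of {[e.value for e in Enhancer]}"
        ) from None


@dataclass(frozen=True)
class CassetteSlot:
    """One silent cassette: its mating-type content and adjacent enhancer."""

    content: Allele
    enhancer: Enhancer

    def __post_init__(self) -> None:
        object.__setattr__(self, "content", _as_allele(self.content))
        object.__setattr__(self, "enhancer", _as_enhancer(self.enhancer))

    def to_dict(self) -> dict:
        return {"content": self.content.value, "enhancer": self.enhancer.value}

    @classmethod
    def from_dict(cls, d: dict) -> "CassetteSlot":
        return cls(content=d["content"], enhancer=d["enhancer"])


@dataclass(frozen=True)
class RegionConfig:
    """A complete strain description: both donor slots plus trans genotype.

    ``swi6_present=False`` models *swi6Δ* (loss of heterochromatin bias);
    ``rpc_present=False`` models *swi2Δ* or *swi5Δ* (loss of the
    recombination-promoting complex, crippling conversion attempts).
    """

    mat2: CassetteSlot
    mat3: CassetteSlot
    swi6_present: bool = True
    rpc_present: bool = True

    @property
    def slots(self) -> tuple:
        return (self.mat2, self.mat3)

    def to_json(self) -> str:
        return json.dumps(
            {
                "mat2": self.mat2.to_dict(),
                "mat3": self.mat3.to_dict(),
                "swi6_present": self.swi6_present,
                "rpc_present": self.rpc_present,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, s: str) -> "RegionConfig":
        d = json.loads(s)
        unknown = set(d) - {"mat2", "mat3", "swi6_present", "rpc_present"}
        if unknown:
            raise ConfigurationError(f"unknown RegionConfig keys: {sorted(unknown)}")
        return cls(
            mat2=CassetteSlot.from_dict(d["mat2"]),
            mat3=CassetteSlot.from_dict(d["mat3"]),
            swi6_present=bool(d.get("swi6_present", True)),
            rpc_present=bool(d.get("rpc_present", True)),
        )


def _slot(content: str, enhancer: str) -> CassetteSlot:
    return CassetteSlot(Allele(content), Enhancer(enhancer))


#: The named laboratory architectures, exactly as drawn in strain diagrams.
#: h90 is wild type (mat2-P SRE2 / mat3-M SRE3); h09 swaps the cassette
#: contents; the *_swapped variants transpose the SRE elements instead of
#: (h09_swapped) or in addition to (h90_swapped) the native layout; the 2x
#: strains duplicate one enhancer; the *del strains delete enhancers.
NAMED_ARCHITECTURES: dict = {
    "h90": (_slot("P", "SRE2"), _slot("M", "SRE3")),
    "h09": (_slot("M", "SRE2"), _slot("P", "SRE3")),
    "h09_swapped": (_slot("M", "SRE3"), _slot("P", "SRE2")),
    "h90_swapped": (_slot("P", "SRE3"), _slot("M", "SRE2")),
    "2xSRE2": (_slot("P", "SRE2"), _slot("M", "SRE2")),
    "2xSRE3": (_slot("P", "SRE3"), _slot("M", "SRE3")),
    "SRE2del": (_slot("P", "NONE"), _slot("M", "SRE3")),
    "SRE3del": (_slot("P", "SRE2"), _slot("M", "NONE")),
    "SRE2del_SRE3del": (_slot("P", "NONE"), _slot("M", "NONE")),
}

#: Genotype-modifier suffixes accepted after an architecture name.
GENOTYPE_MODIFIERS: dict = {
    "swi6del": {"swi6_present": False},
    "swi2del": {"rpc_present": False},
    "swi5del": {"rpc_present": False},
}


def make_named_config(name: str) -> RegionConfig:
    """Build a :class:`RegionConfig` from a strain name.

    Accepts an architecture name (e.g. ``"h90"``, ``"2xSRE2"``,
    ``"SRE3del"``) optionally followed by genotype modifiers
    (``swi6del``, ``swi2del``, ``swi5del``) separated by spaces or
    underscores, e.g. ``"h90 swi2del"`` or ``"SRE3del_swi6del"``.
    """
    tokens = str(name).strip().replace(" ", "_").split("_")
    flags: dict = {}
    while tokens and tokens[-1].lower() in GENOTYPE_MODIFIERS:
        flags.update(GENOTYPE_MODIFIERS[tokens.pop().lower()])
    base = "_".join(tokens)
    # tolerate case variation in the architecture name
    lookup = {k.lower(): k for k in NAMED_ARCHITECTURES}
    if base.lower() not in lookup:
        raise ConfigurationError(
            f"unknown strain architecture {base!r} (from {name!r}); "
            f"valid names: {sorted(NAMED_ARCHITECTURES)}, optionally "
            f"suffixed with {sorted(GENOTYPE_MODIFIERS)}"
        )
    mat2, mat3 = NAMED_ARCHITECTURES[lookup[base.lower()]]
    return RegionConfig(mat2=mat2, mat3=mat3, **flags)


def is_heterologous(cell: Union[str, Allele], slot: CassetteSlot) -> bool:
    """True iff conversion of *mat1* by ``slot`` changes the mating type.

    A donor whose content equals the cell's allele supports only futile,
    homologous conversion.
    """
    return slot.content is not _as_allele(cell)


def swap_labels(config: RegionConfig) -> RegionConfig:
    """Exchange P and M contents in both slots; enhancers untouched.

    An involution used for symmetry checks: swapping labels of h90 yields
    h09 and vice versa.
    """
    return replace(
        config,
        mat2=replace(config.mat2, content=config.mat2.content.other()),
        mat3=replace(config.mat3, content=config.mat3.content.other()),
    )
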