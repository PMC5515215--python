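"""N-acyl homoserine lactone (AHL) naming.

AHLs are named by acyl chain length and the substitution at the C3
position of the acyl chain: ``C6-HSL`` (unsubstituted hexanoyl),
``3OC8-HSL`` (3-oxo-octanoyl), ``3OHC10-HSL`` (3-hydroxy-decanoyl).
"""
from __future__ import annotations

import re
from dataclasses import dataclass

VALID_CHAIN_LENGTHS = (4, 6, 7, 8, 10, 12, 14)
SUBSTITUTIONS = ("unsubstituted", "3-oxo", "3-hydroxy")

_PREFIX = {"unsubstituted": "", "3-oxo": "3O", "3-hydroxy": "3OHC"}
_ACRONYM_RE = re.compile(r"^(3OHC|3OC|C)(\d+)-HSL$")


@dataclass(frozen=True)
class AHL:
    """An AHL signal species identified by acronym, chain length and C3 substitution."""

    acronym: str
    chain_length: int
    substitution: str

    def __post_init__(self) -> None:
        if self.chain_length not in VALID_CHAIN_LENGTHS:
            raise ValueError(f"unsupported acyl chain length {self.chain_length}")
        if self.substitution not in SUBSTITUTIONS:
            raise ValueError(f"unknown substitution {self.substitution!r}")
        if self.acronym != make_acronym(self.chain_length, self.substitution):
            raise ValueError(
                f"acronym {self.acronym!r} inconsistent with "
                f"(C{self.chain_length}, {self.substitution})"
            )

    @property
    def is_long_chain(self) -> bool:
        """Long-chain AHLs carry acyl chains of >= 10 carbons."""
        return self.chain_length >= 10


def make_acronym(chain_length: int, substitution: str = "unsubstituted") -> str:
    if substitution == "unsubstituted":
        return f"C{chain_length}-HSL"
    if substitution == "3-oxo":
        return f"3OC{chain_length}-HSL"
    if substitution == "3-hydroxy":
        return f"3OHC{chain_length}-HSL"
    raise ValueError(f"unknown substitution {substitution!r}")


def parse_acronym(acronym: str) -> AHL:
    """Parse an acronym like ``3OC8-HSL`` into an :class:`AHL`."""
    m = _ACRONYM_RE.match(acronym)
    if m is None:
        raise ValueError(f"cannot parse AHL acronym {acronym!r}")
    prefix, n = m.group(1), int(m.group(2))
    substitution = {"C": "unsubstituted", "3OC": "3-oxo", "3OHC": "3-hydroxy"}[prefix]
    return AHL(acronym=acronym, chain_length=n, substitution=substitution)
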