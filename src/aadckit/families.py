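"""The nine amino-acid-decarboxylase (AADC) families tracked by this package.

Each family is identified by its EC number and carries a cofactor class:
most bacterial AADCs bind pyridoxal 5'-phosphate (PLP) through a Schiff
base to a conserved active-site lysine, while histidine and aspartate-1
decarboxylases use a self-derived pyruvoyl group instead.  Arginine
decarboxylases are a mixed bag: several evolutionary classes exist, some
PLP-dependent and some pyruvoyl-dependent (the latter typically under
200 residues long).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class CofactorClass(enum.Enum):
    PLP = "PLP"
    PYRUVOYL = "PYRUVOYL"
    MIXED = "MIXED"


@dataclass(frozen=True)
class AADCFamily:
    """One decarboxylase family: short name, EC number, cofactor class."""

    name: str
    ec: str
    cofactor_class: CofactorClass

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def _f(name: str, ec: str, cof: CofactorClass) -> AADCFamily:
    return AADCFamily(name, ec, cof)


ARG_DC = _f("ArgDC", "4.1.1.19", CofactorClass.MIXED)
LYS_DC = _f("LysDC", "4.1.1.18", CofactorClass.PLP)
TRP_DC = _f("TrpDC", "4.1.1.105", CofactorClass.PLP)
AAA_DC = _f("AAADC", "4.1.1.28", CofactorClass.PLP)
A4_DC = _f("A4DC", "4.1.1.12", CofactorClass.PLP)
GLU_DC = _f("GluDC", "4.1.1.15", CofactorClass.PLP)
HIS_DC = _f("HisDC", "4.1.1.22", CofactorClass.PYRUVOYL)
A1_DC = _f("A1DC", "4.1.1.11", CofactorClass.PYRUVOYL)
TYR_DC = _f("TyrDC", "4.1.1.25", CofactorClass.PLP)

#: All nine families, in the order they are conventionally tabulated.
FAMILIES: tuple[AADCFamily, ...] = (
    ARG_DC,
    LYS_DC,
    TRP_DC,
    AAA_DC,
    A4_DC,
    GLU_DC,
    HIS_DC,
    A1_DC,
    TYR_DC,
)

FAMILY_BY_NAME: dict[str, AADCFamily] = {f.name: f for f in FAMILIES}
_EC_TO_FAMILY: dict[str, AADCFamily] = {f.ec: f for f in FAMILIES}

#: TrpDC and AAADC annotations resolve to the same enzymes in practice;
#: for motif work the two are treated as one group.
MOTIF_GROUP_NAME: dict[str, str] = {
    **{f.name: f.name for f in FAMILIES},
    "TrpDC": "AAADC/TrpDC",
    "AAADC": "AAADC/TrpDC",
}


def map_ec_to_family(ec: str) -> AADCFamily | None:
    """Return the AADC family with EC number ``ec``, or None if unmapped.

    >>> map_ec_to_family("4.1.1.19").name
    'ArgDC'
    """
    parts = ec.split(".")
    if len(parts) != 4 or not all(p.isdigit() for p in parts):
        raise ValueError(f"not a valid EC number: {ec!r}")
    return _EC_TO_FAMILY.get(ec)
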