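"""The five embryo phenotype decision classes.

Zebrafish (*Danio rerio*) embryos exposed to a toxicant are scored into one
of five morphological states at the end of the assay window: coagulated/dead,
pericardial edema, blood stasis (localized blood pooling with preserved
cardiac activity), necrosed yolk sac, or normal development.  Every image
carries exactly one decision class.
"""

from __future__ import annotations

import enum


class PhenotypeClass(enum.IntEnum):
    """Embryo phenotype classes with a stable 0-4 integer encoding."""

    DEAD = 0
    EDEMA = 1
    BLOOD_STASIS = 2
    NECROSED_YOLK_SAC = 3
    NORMAL = 4

    @property
    def display_name(self) -> str:
        return _DISPLAY_NAMES[self]

    @classmethod
    def from_name(cls, name: str) -> "PhenotypeClass":
        """Resolve a class from an enum name, display name, or directory name."""
        key = name.strip().lower().replace(" ", "_").replace("-", "_")
        for member in cls:
            if key in (member.name.lower(), member.display_name.lower().replace(" ", "_")):
                return member
        raise ValueError(f"unknown phenotype class: {name!r}")


_DISPLAY_NAMES = {
    PhenotypeClass.DEAD: "Dead",
    PhenotypeClass.EDEMA: "Edema",
    PhenotypeClass.BLOOD_STASIS: "Blood stasis",
    PhenotypeClass.NECROSED_YOLK_SAC: "Necrosed yolk sac",
    PhenotypeClass.NORMAL: "Normal",
}

#: Class names in index order, as used for directory layouts and reports.
CLASS_NAMES = tuple(c.name.lower() for c in PhenotypeClass)

N_CLASSES = len(PhenotypeClass)
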