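"""Cancer-site registry.

Fifteen sites are tracked: fourteen with individually quantifiable radiogenic
risk plus an aggregate ``residual`` category for sites where epidemiological
data are too sparse to support a site-specific model. Each site maps to the
dosimetry organ whose absorbed dose drives its excess rate, and declares which
sexes it applies to (breast, uterus and ovary are female-only; prostate is
male-only).
"""
from __future__ import annotations

from dataclasses import dataclass

SEXES = ("male", "female")


@dataclass(frozen=True)
class Site:
    name: str
    target_organ: str
    sexes: tuple[str, ...] = SEXES
    leukaemia: bool = False


SITE_REGISTRY: tuple[Site, ...] = (
    Site("stomach", "stomach"),
    Site("colon", "colon"),
    Site("liver", "liver"),
    Site("lung", "lung"),
    Site("breast", "breast", sexes=("female",)),
    Site("prostate", "prostate", sexes=("male",)),
    Site("uterus", "uterus", sexes=("female",)),
    Site("ovary", "ovary", sexes=("female",)),
    Site("bladder", "urinary_bladder"),
    Site("kidney", "kidneys"),
    Site("thyroid", "thyroid"),
    Site("brain_cns", "brain"),
    Site("skin", "skin"),
    Site("leukaemia", "red_marrow", leukaemia=True),
    Site("residual", "other_tissues"),
)

SITE_NAMES: tuple[str, ...] = tuple(s.name for s in SITE_REGISTRY)
_BY_NAME = {s.name: s for s in SITE_REGISTRY}


def get_site(name: str) -> Site:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown cancer site {name!r}; known sites: {', '.join(SITE_NAMES)}"
        ) from None


def sites_for_sex(sex: str) -> tuple[Site, ...]:
    """Sites applicable to one sex (12 for males, 14 for females)."""
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
    return tuple(s for s in SITE_REGISTRY if sex in s.sexes)
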