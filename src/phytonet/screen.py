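"""Admissibility screening of candidate ingredients.

Compounds from herbal-ingredient databases are screened on two ADME
attributes: oral bioavailability (OB, percent) and drug-likeness (DL,
unitless).  The conventional cutoffs OB >= 30% and DL >= 0.18 are the
defaults; both comparisons are inclusive and configurable.  A second,
literature-derived compound list can be merged in afterwards, keyed on
molecule id, so the stage generalizes beyond any particular herb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .datatypes import Ingredient

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds for the OB/DL admissibility screen.

    ob_min : minimum oral bioavailability in percent (default 30.0).
    dl_min : minimum drug-likeness score (default 0.18).
    inclusive : whether the comparisons are >= (default) or strict >.
    """

    ob_min: float = 30.0
    dl_min: float = 0.18
    inclusive: bool = True

    def __post_init__(self) -> None:
        if self.ob_min < 0:
            raise ValueError(f"ob_min must be >= 0, got {self.ob_min}")
        if self.dl_min < 0:
            raise ValueError(f"dl_min must be >= 0, got {self.dl_min}")

    def admits(self, ingredient: Ingredient) -> bool:
        if self.inclusive:
            return ingredient.ob >= self.ob_min and ingredient.dl >= self.dl_min
        return ingredient.ob > self.ob_min and ingredient.dl > self.dl_min


def screen_ingredients(
    lib: Iterable[Ingredient], cfg: ScreenConfig | None = None
) -> list[Ingredient]:
    """Return the ingredients passing the OB/DL screen, in input order."""
    cfg = cfg or ScreenConfig()
    return [ing for ing in lib if cfg.admits(ing)]


def merge_with_literature(
    screened: Sequence[Ingredient], literature: Sequence[Ingredient]
) -> list[Ingredient]:
    """Union screened and literature-reported ingredients, keyed on mol_id.

    The screened entry wins on conflict (its name is kept; a differing
    literature name is logged).  Literature-only entries are flagged
    ``source="literature"``.  Order: screened entries first, then the
    literature additions, each in input order.
    """
    out: list[Ingredient] = []
    by_id: dict[str, Ingredient] = {}
    for ing in screened:
        if ing.mol_id not in by_id:
            by_id[ing.mol_id] = ing
            out.append(ing)
    for ing in literature:
        prev = by_id.get(ing.mol_id)
        if prev is not None:
            if prev.name != ing.name:
                logger.warning(
                    "merge_with_literature: %s named %r in screen, %r in literature; "
                    "keeping %r",
                    ing.mol_id, prev.name, ing.name, prev.name,
                )
            continue
        flagged = ing if ing.source == "literature" else replace(ing, source="literature")
        by_id[ing.mol_id] = flagged
        out.append(flagged)
    return out
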