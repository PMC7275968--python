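"""Greenness assessment: NEMI four-quadrant profile and Analytical Eco-Scale.

The Eco-Scale starts from 100 points and deducts penalty points (PPs) for
reagent amounts and hazards, instrument energy, occupational exposure, and
waste.  Reagent PPs are amount points multiplied by hazard points (number of
GHS pictograms x signal-word score); instrument-side PPs are additive.  A
score above 75 is conventionally read as a green method.  The penalty rule
tables ship as an editable YAML data file.

Under the literal multiplication rule a non-hazardous reagent (hazard 0)
contributes zero penalty even when its amount bracket carries points; the
worked-example sheet for the spectrophotometric method (water + ethanol,
total PPs 5, score 95) follows exactly that arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

__all__ = [
    "NemiProfile",
    "EcoScaleItem",
    "EcoScaleSheet",
    "eco_scale",
    "nemi",
    "load_rules",
    "method_sheet_items",
]

_REAGENT = "reagent"
_CATEGORIES = (_REAGENT, "instrument-energy", "occupational-hazard", "waste")


def load_rules() -> dict:
    """Load the Eco-Scale penalty rule tables shipped with the package."""
    text = resources.files("quadspec.data").joinpath("eco_scale_rules.yaml").read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class EcoScaleItem:
    """One penalty line: reagent items multiply amount x hazard points."""

    name: str
    category: str
    amount_penalty: float = 0.0
    hazard_penalty: float = 0.0

    def __post_init__(self) -> None:
        if self.category not in _CATEGORIES:
            raise ValueError(f"category must be one of {_CATEGORIES}")
        if self.amount_penalty < 0 or self.hazard_penalty < 0:
            raise ValueError("penalty points must be non-negative")

    @property
    def total_penalty(self) -> float:
        if self.category == _REAGENT:
            return self.amount_penalty * self.hazard_penalty
        return self.amount_penalty + self.hazard_penalty


@dataclass(frozen=True)
class EcoScaleSheet:
    items: tuple[EcoScaleItem, ...]
    total_penalty: float
    score: float


def eco_scale(items) -> EcoScaleSheet:
    """Sum penalty points and subtract from 100."""
    items = tuple(items)
    total = sum(it.total_penalty for it in items)
    return EcoScaleSheet(items=items, total_penalty=total, score=100.0 - total)


def method_sheet_items() -> list[EcoScaleItem]:
    """Penalty items of the developed spectrophotometric methods.

    Water <10 mL (amount 1, non-hazardous), ethanol <10 mL (amount 1,
    hazard 2 = one pictogram x danger), energy <0.1 kWh per sample (0),
    vapor emission treated as negligible for a closed cuvette (0), and
    1-10 mL waste (3).
    """
    rules = load_rules()
    amt = rules["reagent_amount_points"]["<10 mL (<10 g)"]
    eth = rules["common_reagent_hazards"]["ethanol"]
    eth_hazard = eth["pictograms"] * rules["signal_word_score"][eth["signal_word"]]
    return [
        EcoScaleItem("water", _REAGENT, amount_penalty=amt, hazard_penalty=0),
        EcoScaleItem("ethanol", _REAGENT, amount_penalty=amt, hazard_penalty=eth_hazard),
        EcoScaleItem("energy", "instrument-energy",
                     amount_penalty=rules["instrument_energy_points"]["<=0.1 kWh per sample"]),
        EcoScaleItem("vapour emission", "occupational-hazard", amount_penalty=0),
        EcoScaleItem("waste", "waste", amount_penalty=rules["waste_points"]["1-10 mL (1-10 g)"]),
    ]


@dataclass(frozen=True)
class NemiProfile:
    """Four NEMI quadrants: each is colored iff its criterion is met."""

    pbt_free: bool
    non_hazardous: bool
    non_corrosive: bool  # 2 <= pH <= 12 throughout the procedure
    low_waste: bool  # <= 50 g waste per sample


def nemi(profile: NemiProfile) -> dict:
    """Render the NEMI profile as flags plus a small text pictogram.

    Pure function of the flags: the same profile always yields the same
    rendering.
    """
    q = {
        "PBT": profile.pbt_free,
        "Hazardous": profile.non_hazardous,
        "Corrosive": profile.non_corrosive,
        "Waste": profile.low_waste,
    }
    mark = {True: "##", False: ".."}
    text = (
        f"+----+----+\n"
        f"|{mark[q['PBT']]}  |  {mark[q['Hazardous']]}|\n"
        f"+----+----+\n"
        f"|{mark[q['Corrosive']]}  |  {mark[q['Waste']]}|\n"
        f"+----+----+"
    )
    return {"quadrants": q, "all_green": all(q.values()), "text": text}
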