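"""Neuropathology scorecards, total/sub-scores, and mild/severe calls.

Each animal's brain is scored per region (eight territories from cortex to
thalamus) and per coronal section (720 at the lateral ventricle, 1080 at
the thalamus/hippocampus) on four components: tissue damage on
acid-fuchsin/thionine staining, microglial activation (Iba1),
galectin-3-positive ameboid microglia, and GFAP astrogliosis.  The summed
total classifies the animal: below 10 is mild, above 10 severe.  A total
of exactly 10 — unobserved in practice, and not covered by the <10 / >10
rule — is called severe with a boundary flag so callers can override.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger("ucoseq")

REGIONS = (
    "cortex",
    "subcortical WM",
    "periventricular WM",
    "corpus callosum",
    "external capsule",
    "striatum/basal ganglia",
    "hippocampus",
    "thalamus",
)
SECTIONS = (720, 1080)

#: legal score values per component (half-points mark mild/small findings)
LEGAL_SCORES: dict[str, tuple[float, ...]] = {
    "acid_fuchsin": (0, 0.5, 1, 2),
    "microglial_activation": (0, 0.5, 1, 2, 3),
    "galectin3": (0, 0.5, 1, 2),
    "gfap": (0, 0.5, 1, 2),
}
COMPONENTS = tuple(LEGAL_SCORES)
NEUROINFLAMMATION_COMPONENTS = ("microglial_activation", "galectin3")

#: maximum attainable per (region, section) cell block: 2 + 3 + 2 + 2
MAX_BLOCK_SCORE = sum(max(v) for v in LEGAL_SCORES.values())

MILD_SEVERE_CUTOFF = 10.0


class ScoreError(ValueError):
    """A scorecard entry is outside its legal value set."""


@dataclass
class Scorecard:
    """Per-animal scores keyed by (region, section, component).

    Cards need not be rectangular: regions assessed but unremarkable may
    simply be absent and contribute nothing to the total.
    """

    animal_id: str
    entries: dict[tuple[str, int, str], float] = field(default_factory=dict)

    def set(self, region: str, section: int, component: str, score: float) -> None:
        self.entries[(region, int(section), component)] = float(score)


def validate(card: Scorecard) -> Scorecard:
    """Check every entry against its component's legal value set."""
    for (region, section, component), score in card.entries.items():
        if component not in LEGAL_SCORES:
            raise ScoreError(
                f"{card.animal_id}: unknown component {component!r} "
                f"at ({region}, {section}); legal: {COMPONENTS}"
            )
        if score not in LEGAL_SCORES[component]:
            raise ScoreError(
                f"{card.animal_id}: illegal {component} score {score} at "
                f"({region}, {section}); legal set {LEGAL_SCORES[component]}"
            )
    missing = [
        (r, s, c)
        for r in REGIONS
        for s in SECTIONS
        for c in COMPONENTS
        if (r, s, c) not in card.entries
    ]
    if missing:
        logger.debug(
            "scorecard %s: %d of %d cells absent (contribute 0)",
            card.animal_id, len(missing), len(REGIONS) * len(SECTIONS) * len(COMPONENTS),
        )
    return card


def total_score(card: Scorecard) -> float:
    """Sum over all scored (region, section, component) cells."""
    validate(card)
    return float(sum(card.entries.values()))


def neuroinflammation_score(card: Scorecard) -> float:
    """Sum restricted to the inflammatory components (Iba1 + galectin-3)."""
    validate(card)
    return float(
        sum(v for (r, s, c), v in card.entries.items() if c in NEUROINFLAMMATION_COMPONENTS)
    )


@dataclass
class InjuryCall:
    animal_id: str
    total_score: float
    neuroinflammation_score: float
    injury_class: str  # mild | severe
    boundary_flag: bool = False


def classify(total: float) -> tuple[str, bool]:
    """Mild/severe call from a total score; returns (class, boundary_flag)."""
    if total < 0:
        raise ValueError(f"negative total score {total}")
    if total < MILD_SEVERE_CUTOFF:
        return "mild", False
    if total > MILD_SEVERE_CUTOFF:
        return "severe", False
    return "severe", True


def call_injury(card: Scorecard) -> InjuryCall:
    total = total_score(card)
    cls, flag = classify(total)
    return InjuryCall(
        animal_id=card.animal_id,
        total_score=total,
        neuroinflammation_score=neuroinflammation_score(card),
        injury_class=cls,
        boundary_flag=flag,
    )


def cohort_region_medians(cards: list[Scorecard]) -> pd.DataFrame:
    """Median per-region score (summed over sections/components) across animals."""
    rows = []
    for card in cards:
        for region in REGIONS:
            s = sum(v for (r, _, _), v in card.entries.items() if r == region)
            rows.append({"animal_id": card.animal_id, "region": region, "score": s})
    df = pd.DataFrame(rows)
    return df.groupby("region", sort=False)["score"].median().reset_index()


# ---------------------------------------------------------------------------
# on-disk format: long TSV, one row per scored cell


def write_scorecards(cards: list[Scorecard], path: str | Path) -> None:
    rows = []
    for card in cards:
        for (region, section, component), score in sorted(card.entries.items()):
            rows.append(
                {
                    "animal_id": card.animal_id,
                    "region": region,
                    "section": section,
                    "component": component,
                    "score": score,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_scorecards(path: str | Path) -> list[Scorecard]:
    df = pd.read_csv(path, sep="\t", comment="#")
    cards = []
    for animal, grp in df.groupby("animal_id", sort=False):
        card = Scorecard(animal_id=str(animal))
        for _, row in grp.iterrows():
            card.set(row["region"], int(row["section"]), row["component"], float(row["score"]))
        cards.append(validate(card))
    return cards


def score_cohort(cards: list[Scorecard]) -> pd.DataFrame:
    """Injury calls for a cohort of validated scorecards."""
    calls = [call_injury(c) for c in cards]
    return pd.DataFrame(
        {
            "animal_id": [c.animal_id for c in calls],
            "total_score": [c.total_score for c in calls],
            "neuroinflammation_score": [c.neuroinflammation_score for c in calls],
            "injury_class": [c.injury_class for c in calls],
            "boundary_flag": [c.boundary_flag for c in calls],
        }
    )
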