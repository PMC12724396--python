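"""Heat prevention plan (HPP) catalogue: scores, classes, subperiod indicator.

An HPP is summarised by its implementation year and a total score: the sum
of expert-weighted actions (each worth 0 to 2 points) across 8 core
elements of heat-health action plans.  Countries are stratified into three
HPP classes by terciles of the scheme's maximum score.  The subperiod-level
HPP indicator marks subperiods in which a plan was in place.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

N_CORE_ELEMENTS = 8

#: readings of the subperiod HPP indicator (the catalogue sentence defining
#: it is ambiguous as printed; "start_year" is the default: the plan counts
#: as present from the first subperiod whose whole span is post-implementation)
INDICATOR_RULES = ("start_year", "strictly_after", "any_overlap")


@dataclass
class HPPRecord:
    country: str
    implementation_year: int | None
    #: core element (1..8) -> list of action weights, each in [0, 2]
    actions: dict[int, list[float]] = field(default_factory=dict)
    hpp_class: int | None = None

    def __post_init__(self) -> None:
        for element, weights in self.actions.items():
            if not 1 <= int(element) <= N_CORE_ELEMENTS:
                raise ValueError(f"HPPRecord: core element {element} outside 1..{N_CORE_ELEMENTS}")
            for w in weights:
                if not 0.0 <= w <= 2.0:
                    raise ValueError(f"HPPRecord: action weight {w} outside [0, 2]")

    @property
    def total_score(self) -> float:
        return score_hpp(self.actions)


def score_hpp(actions: dict[int, list[float]]) -> float:
    """Total HPP score: the plain sum of action weights across elements."""
    total = 0.0
    for element, weights in actions.items():
        if not 1 <= int(element) <= N_CORE_ELEMENTS:
            raise ValueError(f"score_hpp: core element {element} outside 1..{N_CORE_ELEMENTS}")
        for w in weights:
            if not 0.0 <= float(w) <= 2.0:
                raise ValueError(f"score_hpp: action weight {w} outside [0, 2]")
            total += float(w)
    return total


def classify_hpp(scores: dict[str, float], max_score: float) -> dict[str, int]:
    """Tercile classification of country scores against the scheme maximum.

    Cut points at max/3 and 2*max/3; a score exactly on a boundary is
    assigned upward (score == max/3 is class 2).
    """
    if max_score <= 0:
        raise ValueError("classify_hpp: max_score must be > 0")
    cuts = (max_score / 3.0, 2.0 * max_score / 3.0)
    out: dict[str, int] = {}
    for country, s in scores.items():
        if s > max_score:
            raise ValueError(f"classify_hpp: score {s} for {country} exceeds max_score {max_score}")
        if s < cuts[0]:
            out[country] = 1
        elif s < cuts[1]:
            out[country] = 2
        else:
            out[country] = 3
    return out


def hpp_indicator(
    implementation_year: int | None,
    subperiod_start_year: int,
    subperiod_end_year: int,
    rule: str = "start_year",
) -> int:
    """Subperiod-level HPP presence indicator (0/1).

    start_year (default): 1 when the plan was implemented no later than the
    subperiod's first year.  strictly_after: 1 only from the subperiod after
    the one containing the implementation year.  any_overlap: 1 when the
    plan existed during any year of the subperiod.
    """
    if rule not in INDICATOR_RULES:
        raise ValueError(f"hpp_indicator: unknown rule {rule!r}; choose from {INDICATOR_RULES}")
    if implementation_year is None:
        return 0
    if rule == "start_year":
        return int(implementation_year <= subperiod_start_year)
    if rule == "strictly_after":
        return int(implementation_year < subperiod_start_year)
    return int(implementation_year <= subperiod_end_year)  # any_overlap


# ---------------------------------------------------------------------------
# catalogue table I/O
# ---------------------------------------------------------------------------

def catalogue_to_frame(records: list[HPPRecord], max_score: float) -> pd.DataFrame:
    """Tidy catalogue table: per-element scores, total and tercile class."""
    rows = []
    classes = classify_hpp({r.country: r.total_score for r in records}, max_score)
    for r in sorted(records, key=lambda r: r.country):
        row: dict = {"country": r.country, "hpp_year": r.implementation_year}
        for e in range(1, N_CORE_ELEMENTS + 1):
            row[f"element_{e}"] = float(sum(r.actions.get(e, [])))
        row["total_score"] = r.total_score
        row["hpp_class"] = classes[r.country]
        rows.append(row)
    return pd.DataFrame(rows)


def load_catalogue(path) -> pd.DataFrame:
    """Read and validate a catalogue CSV (country, hpp_year, element_1..8,
    total_score, hpp_class)."""
    df = pd.read_csv(path)
    required = {"country", "hpp_year", "total_score", "hpp_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"catalogue missing columns: {sorted(missing)}")
    if df["country"].duplicated().any():
        raise ValueError("catalogue has duplicated countries")
    element_cols = [c for c in df.columns if c.startswith("element_")]
    if element_cols:
        elems = df[element_cols].to_numpy(float)
        if (elems < 0).any():
            raise ValueError("catalogue element scores must be nonnegative")
        if not np.allclose(elems.sum(axis=1), df["total_score"].to_numpy(float), atol=1e-9):
            raise ValueError("catalogue total_score does not equal the sum of element scores")
    if not df["hpp_class"].isin([1, 2, 3]).all():
        raise ValueError("catalogue hpp_class must be 1, 2 or 3")
    return df


def country_indicator_table(
    catalogue: pd.DataFrame,
    subperiods: list,
    rule: str = "start_year",
) -> pd.DataFrame:
    """HPP indicator for every country x subperiod in long form."""
    rows = []
    for _, rec in catalogue.iterrows():
        year = rec["hpp_year"]
        year = None if pd.isna(year) else int(year)
        if year is None:
            log.warning("country %s has no implementation year; indicator fixed at 0", rec["country"])
        for sp in subperiods:
            rows.append(
                {
                    "country": rec["country"],
                    "subperiod": sp.index,
                    "hpp": hpp_indicator(year, sp.start_year, sp.end_year, rule=rule),
                }
            )
    return pd.DataFrame(rows)
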