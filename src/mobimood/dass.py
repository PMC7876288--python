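"""DASS-21 scoring and severity categorization.

The Depression Anxiety Stress Scales short form has 21 items rated 0-3
("did not apply to me at all" .. "applied to me very much"). Each of the
three subscales (depression, anxiety, stress) sums its 7 items, giving
subscores on 0-21; severity categories follow the standard short-form
cut-offs. Subscores are raw sums -- no doubling to the 42-item scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

SCALES = ("depression", "anxiety", "stress")

#: Standard DASS-21 item -> subscale assignment (item numbers 1..21).
SUBSCALE_ITEMS: dict[str, tuple[int, ...]] = {
    "depression": (3, 5, 10, 13, 16, 17, 21),
    "anxiety": (2, 4, 7, 9, 15, 19, 20),
    "stress": (1, 6, 8, 11, 12, 14, 18),
}

#: Severity cut-offs as closed integer ranges (lo, hi, label) per subscale.
SEVERITY_CUTOFFS: dict[str, tuple[tuple[int, int, str], ...]] = {
    "depression": (
        (0, 4, "normal"),
        (5, 6, "mild"),
        (7, 10, "moderate"),
        (11, 13, "severe"),
        (14, 21, "extremely severe"),
    ),
    "anxiety": (
        (0, 3, "normal"),
        (4, 5, "mild"),
        (6, 7, "moderate"),
        (8, 9, "severe"),
        (10, 21, "extremely severe"),
    ),
    "stress": (
        (0, 7, "normal"),
        (8, 9, "mild"),
        (10, 12, "moderate"),
        (13, 16, "severe"),
        (17, 21, "extremely severe"),
    ),
}

SEVERITY_ORDER = ("normal", "mild", "moderate", "severe", "extremely severe")


@dataclass(frozen=True)
class DassResponse:
    """One questionnaire administration: 21 item ratings keyed 1..21."""

    assessment_point: str  # "T0", "T1" or "T2"
    items: Mapping[int, int]

    def __post_init__(self) -> None:
        if set(self.items) != set(range(1, 22)):
            missing = set(range(1, 22)) - set(self.items)
            extra = set(self.items) - set(range(1, 22))
            raise ValueError(
                f"expected items 1..21; missing {sorted(missing)}, extra {sorted(extra)}"
            )
        bad = {k: v for k, v in self.items.items() if v not in (0, 1, 2, 3)}
        if bad:
            raise ValueError(f"item ratings must be in 0..3, got {bad}")


@dataclass(frozen=True)
class DassSubscores:
    depression: int | None
    anxiety: int | None
    stress: int | None
    categories: dict[str, str | None] = field(default_factory=dict)

    def as_dict(self) -> dict[str, int | None]:
        return {s: getattr(self, s) for s in SCALES}


def score_dass(response: DassResponse | Mapping[int, int]) -> DassSubscores:
    """Sum each subscale's 7 items into 0-21 subscores and categorize.

    A plain mapping of item ratings (possibly incomplete) is accepted; a
    subscale with any missing item gets an undefined (None) subscore.
    """
    items = response.items if isinstance(response, DassResponse) else dict(response)
    scores: dict[str, int | None] = {}
    for scale, members in SUBSCALE_ITEMS.items():
        if all(i in items and items[i] is not None for i in members):
            scores[scale] = int(sum(items[i] for i in members))
        else:
            scores[scale] = None
    categories = {
        scale: (categorize(scores[scale], scale) if scores[scale] is not None else None)
        for scale in SCALES
    }
    return DassSubscores(
        depression=scores["depression"],
        anxiety=scores["anxiety"],
        stress=scores["stress"],
        categories=categories,
    )


def categorize(subscore: int, scale: str) -> str:
    """Map an integer subscore in [0, 21] to its severity category."""
    if scale not in SEVERITY_CUTOFFS:
        raise ValueError(f"unknown scale {scale!r}; expected one of {SCALES}")
    if not isinstance(subscore, (int,)) or isinstance(subscore, bool):
        if not float(subscore).is_integer():
            raise ValueError(f"subscore must be an integer, got {subscore!r}")
        subscore = int(subscore)
    if not 0 <= subscore <= 21:
        raise ValueError(f"subscore {subscore} outside [0, 21]")
    for lo, hi, label in SEVERITY_CUTOFFS[scale]:
        if lo <= subscore <= hi:
            return label
    raise AssertionError("cut-off table does not cover 0..21")  # pragma: no cover
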