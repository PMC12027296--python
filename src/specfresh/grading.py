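"""Threshold-based cross-classification of (TVB-N, TAC, MPN) triples into
four freshness grades, plus the coarse/fine hierarchy used by the
hierarchical classifier.

Grade thresholds: TVB-N 15 and 25 mg/100 g (left-open/right-closed
intervals), TAC 6.0 log CFU/g, MPN 5.0 log MPN/100 g.  The four explicit
rules do not partition indicator space; triples matching no rule are
resolved by the ``severity`` policy (most severe grade implied by any
exceeded threshold) or rejected under ``strict``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra_io import GRADE_VOCABULARY

__all__ = [
    "GradeRule",
    "HierarchyMap",
    "GRADE_RULES",
    "assign_grade",
    "to_coarse",
    "severity_rank",
    "UncoveredCombinationError",
]

TVBN_LOW, TVBN_HIGH = 15.0, 25.0
TAC_BOUND = 6.0
MPN_BOUND = 5.0


class UncoveredCombinationError(ValueError):
    """Raised under the strict policy for triples matched by no rule."""


@dataclass(frozen=True)
class GradeRule:
    """One row of the grade table: interval on TVB-N plus TAC/MPN bounds."""

    tvbn_low: float  # exclusive
    tvbn_high: float  # inclusive; inf = unbounded
    tac_above: bool  # False: TAC <= bound, True: TAC > bound
    mpn_above: bool
    label: str

    def matches(self, tvbn: float, tac: float, mpn: float) -> bool:
        if not (self.tvbn_low < tvbn <= self.tvbn_high):
            return False
        if (tac > TAC_BOUND) != self.tac_above:
            return False
        if (mpn > MPN_BOUND) != self.mpn_above:
            return False
        return True


GRADE_RULES: tuple[GradeRule, ...] = (
    GradeRule(0.0, TVBN_LOW, False, False, "Fresh"),
    GradeRule(TVBN_LOW, TVBN_HIGH, False, False, "SubFresh"),
    GradeRule(TVBN_LOW, TVBN_HIGH, False, True, "PreSpoiled"),
    GradeRule(TVBN_HIGH, float("inf"), True, True, "Spoiled"),
)

_SEVERITY = {g: i for i, g in enumerate(GRADE_VOCABULARY)}


def severity_rank(label: str) -> int:
    """Fresh=0 < SubFresh=1 < PreSpoiled=2 < Spoiled=3."""
    return _SEVERITY[label]


def _severity_levels(tvbn: float, tac: float, mpn: float) -> tuple[int, int, int]:
    # per-indicator severity implied by the exceeded thresholds
    if tvbn > TVBN_HIGH:
        lv_tvbn = 3
    elif tvbn > TVBN_LOW:
        lv_tvbn = 1
    else:
        lv_tvbn = 0
    lv_tac = 3 if tac > TAC_BOUND else 0
    lv_mpn = 2 if mpn > MPN_BOUND else 0
    return lv_tvbn, lv_tac, lv_mpn


def assign_grade(tvbn: float, tac: float, mpn: float, policy: str = "severity") -> str:
    """Map an indicator triple to a grade label.

    The four explicit rules are checked first; uncovered triples are
    resolved per ``policy`` — ``severity`` takes the most severe grade
    among thresholds the triple violates, ``strict`` raises.
    """
    if policy not in ("severity", "strict"):
        raise ValueError(f"unknown policy {policy!r}")
    if not (np.isfinite(tvbn) and np.isfinite(tac) and np.isfinite(mpn)):
        raise ValueError("indicators must be finite")
    if tvbn <= 0:
        raise ValueError("TVB-N must be positive")
    matched = [r.label for r in GRADE_RULES if r.matches(tvbn, tac, mpn)]
    if len(matched) > 1:  # pragma: no cover - rules are disjoint by construction
        raise AssertionError(f"rules not disjoint at ({tvbn}, {tac}, {mpn})")
    if matched:
        return matched[0]
    if policy == "strict":
        raise UncoveredCombinationError(
            f"no grade rule covers (TVB-N={tvbn}, TAC={tac}, MPN={mpn})"
        )
    level = max(_severity_levels(tvbn, tac, mpn))
    return GRADE_VOCABULARY[level]


@dataclass
class HierarchyMap:
    """Fine-label -> coarse-label mapping consumed by the hierarchical heads."""

    coarse_of: dict = field(
        default_factory=lambda: {
            "Fresh": "Acceptable",
            "SubFresh": "Acceptable",
            "PreSpoiled": "Unacceptable",
            "Spoiled": "Unacceptable",
        }
    )

    def __post_init__(self) -> None:
        missing = set(GRADE_VOCABULARY) - set(self.coarse_of)
        if missing:
            raise ValueError(f"hierarchy map missing fine label(s): {sorted(missing)}")

    @property
    def coarse_labels(self) -> list[str]:
        seen: list[str] = []
        for fine in GRADE_VOCABULARY:
            c = self.coarse_of[fine]
            if c not in seen:
                seen.append(c)
        return seen

    def to_dict(self) -> dict:
        return dict(self.coarse_of)

    @classmethod
    def from_dict(cls, d: dict) -> "HierarchyMap":
        return cls(coarse_of=dict(d))


def to_coarse(label: str, hierarchy: HierarchyMap | None = None) -> str:
    """Deterministic parent lookup in the hierarchy map."""
    hierarchy = hierarchy or HierarchyMap()
    if label not in hierarchy.coarse_of:
        raise KeyError(f"unknown fine label {label!r}")
    return hierarchy.coarse_of[label]
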