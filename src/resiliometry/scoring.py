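"""Item-level scoring for the study instruments.

Covers the Strengths and Difficulties Questionnaire (SDQ, total difficulties
0-40 with informant-specific clinical cut-offs), the GHQ-12 under binary
0-0-1-1 scoring, the LTE-Q life-event tally, the summed rating scales
(behavioural self-esteem, self-efficacy, emotional self-control, child-parent
and child-teacher relationship quality), the z-average self-concept
composite, and Cronbach's alpha.

No missing-item proration is performed anywhere: the analyses are
complete-case, so a missing or out-of-range response is an error, never an
imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "ScaleDefinition",
    "SdqScore",
    "SDQ_SUBSCALES",
    "SDQ_CUTOFFS",
    "DEFAULT_SCALES",
    "score_sdq",
    "score_ghq12",
    "score_lteq",
    "score_sum_scale",
    "composite_self_concept",
    "cronbach_alpha",
    "load_scale_config",
]


@dataclass(frozen=True)
class ScaleDefinition:
    """A summed rating scale: k items on a common response range.

    ``reverse_items`` are 0-based indices flipped within the item range before
    summation (used for the conflict block of the relationship scales, so that
    higher totals always mean better-quality relationships).
    """

    name: str
    item_count: int
    item_min: int
    item_max: int
    reverse_items: tuple[int, ...] = ()
    higher_is_better: bool = True

    def __post_init__(self):
        if self.item_count < 1 or self.item_max <= self.item_min:
            raise ValueError(f"invalid scale definition {self.name!r}")
        if any(not 0 <= i < self.item_count for i in self.reverse_items):
            raise ValueError(f"{self.name}: reverse item index out of range")

    @property
    def total_range(self) -> tuple[int, int]:
        return self.item_count * self.item_min, self.item_count * self.item_max


# Default definitions.  The relationship short forms have 15 items; the
# conflict block (items 8-15, 0-based 7..14) is reverse-coded by default --
# the exact published reversal set is configuration, not an assertion.
DEFAULT_SCALES: dict[str, ScaleDefinition] = {
    "self_esteem": ScaleDefinition("self_esteem", 14, 1, 5),
    "self_efficacy": ScaleDefinition("self_efficacy", 9, 1, 4),
    "self_control": ScaleDefinition("self_control", 8, 1, 5),
    "child_parent_rel": ScaleDefinition("child_parent_rel", 15, 1, 5, tuple(range(7, 15))),
    "child_teacher_rel": ScaleDefinition("child_teacher_rel", 15, 1, 5, tuple(range(7, 15))),
}

# Standard 25-item SDQ subscale partition (0-based item indices).  Responses
# are assumed already difficulty-coded 0-2.  Total difficulties excludes the
# prosocial subscale.
SDQ_SUBSCALES: dict[str, tuple[int, ...]] = {
    "emotional": (2, 7, 12, 15, 23),
    "conduct": (4, 6, 11, 17, 21),
    "hyperactivity": (1, 9, 14, 20, 24),
    "peer": (5, 10, 13, 18, 22),
    "prosocial": (0, 3, 8, 16, 19),
}

# Clinical cut-offs are strict: totals *above* the threshold are flagged.
SDQ_CUTOFFS: dict[str, int] = {"parent": 14, "teacher": 12}


@dataclass
class SdqScore:
    total: int
    subscales: dict[str, int] = field(default_factory=dict)
    clinical_flag: bool = False


def _validate_items(items, n: int, lo: int, hi: int, what: str) -> np.ndarray:
    arr = np.asarray(items)
    if arr.ndim != 1 or len(arr) != n:
        raise ValueError(f"{what}: expected exactly {n} item responses, got {arr.shape}")
    if np.any(pd_isna(arr)):
        raise ValueError(f"{what}: missing item responses (no imputation performed)")
    arr = arr.astype(float)
    if not np.all(arr == np.round(arr)):
        raise ValueError(f"{what}: non-integer response codes")
    bad = np.where((arr < lo) | (arr > hi))[0]
    if len(bad):
        raise ValueError(f"{what}: out-of-range response at item index {bad[0]} (value {arr[bad[0]]:g})")
    return arr.astype(int)


def pd_isna(arr) -> np.ndarray:
    a = np.asarray(arr, dtype=object)
    return np.array([x is None or (isinstance(x, float) and np.isnan(x)) for x in a.ravel()]).reshape(a.shape)


def score_sdq(
    items,
    informant: str,
    subscales: dict[str, tuple[int, ...]] | None = None,
    cutoffs: dict[str, int] | None = None,
) -> SdqScore:
    """Score the 25-item SDQ for one child.

    Total difficulties is the sum of the emotional, conduct, hyperactivity
    and peer subscales (prosocial excluded); the clinical flag is true iff
    the total is strictly above the informant's cut-off (14 parent,
    12 teacher).
    """
    if informant not in ("parent", "teacher"):
        raise ValueError(f"informant must be 'parent' or 'teacher', got {informant!r}")
    subscales = subscales or SDQ_SUBSCALES
    cutoffs = cutoffs or SDQ_CUTOFFS
    arr = _validate_items(items, 25, 0, 2, "SDQ")
    sub = {name: int(arr[list(idx)].sum()) for name, idx in subscales.items()}
    total = sum(v for k, v in sub.items() if k != "prosocial")
    return SdqScore(total=total, subscales=sub, clinical_flag=total > cutoffs[informant])


def score_ghq12(items) -> tuple[int, bool]:
    """GHQ-12 under binary 0-0-1-1 scoring.

    Each of the 12 items (coded 0-3) contributes 1 iff the response is 2 or 3;
    a total of 1 or more flags clinical-level psychological distress.
    """
    arr = _validate_items(items, 12, 0, 3, "GHQ-12")
    total = int((arr >= 2).sum())
    return total, total >= 1


def score_lteq(events) -> int:
    """Tally of the 12 LTE-Q family stressful life-event categories (0/1 each)."""
    arr = _validate_items(events, 12, 0, 1, "LTE-Q")
    return int(arr.sum())


def score_sum_scale(items, definition: ScaleDefinition) -> int:
    """Sum a rating scale after flipping its reverse-coded items."""
    arr = _validate_items(items, definition.item_count, definition.item_min,
                          definition.item_max, definition.name)
    arr = arr.copy()
    rev = list(definition.reverse_items)
    if rev:
        arr[rev] = definition.item_min + definition.item_max - arr[rev]
    return int(arr.sum())


def composite_self_concept(self_esteem, self_efficacy) -> np.ndarray:
    """Average of the within-sample z-scores of self-esteem and self-efficacy.

    The composite has sample mean 0 and SD sqrt((1+r)/2) where r is the
    correlation between the two components (so SD = 1 only when they are
    perfectly correlated).
    """
    a = np.asarray(self_esteem, dtype=float)
    b = np.asarray(self_efficacy, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("components must be equal-length vectors of length >= 3")
    for name, v in (("self_esteem", a), ("self_efficacy", b)):
        if v.std(ddof=1) == 0:
            raise ValueError(f"{name} has zero variance")
    za = (a - a.mean()) / a.std(ddof=1)
    zb = (b - b.mean()) / b.std(ddof=1)
    return (za + zb) / 2.0


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum of item variances / total variance)."""
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("need >= 3 respondents and >= 2 items")
    if np.isnan(X).any():
        raise ValueError("complete rows required")
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    item_var = X.var(axis=0, ddof=1).sum()
    return k / (k - 1) * (1 - item_var / total_var)


def load_scale_config(path) -> dict[str, ScaleDefinition]:
    """Read scale definitions from a YAML file.

    Expected layout per scale name: ``items``, ``item_min``, ``item_max``,
    optional ``reverse_items`` (0-based list) and ``higher_is_better``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for name, spec in raw.items():
        out[name] = ScaleDefinition(
            name=name,
            item_count=int(spec["items"]),
            item_min=int(spec["item_min"]),
            item_max=int(spec["item_max"]),
            reverse_items=tuple(spec.get("reverse_items", ())),
            higher_is_better=bool(spec.get("higher_is_better", True)),
        )
    return out
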