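"""Exclusive cross-classification of rule-engine and token-engine outcomes.

Every cohort patient lands in exactly one of 8 categories defined by
(rule-engine matched yes/no) x (token-engine level: none, permissive-only,
permissive+balanced, or all three thresholds).  Category ids follow the
row numbering used throughout the reporting:

    rule no-match:  1 none, 2 permissive-only, 3 permissive+balanced, 4 all
    rule match:     5 none, 6 permissive-only, 7 permissive+balanced, 8 all
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._util import ConfigError, InvariantError

PPRL_LEVELS = ("none", "permissive_only", "permissive_balanced", "all_three")

_LEVEL_OFFSET = {lvl: i + 1 for i, lvl in enumerate(PPRL_LEVELS)}

CATEGORY_IDS = tuple(range(1, 9))

# Category ids contributing to each algorithm's match total.
ALGORITHM_ROWS: dict[str, tuple[int, ...]] = {
    "rule": (5, 6, 7, 8),
    "strict": (4, 8),
    "balanced": (3, 4, 7, 8),
    "permissive": (2, 3, 4, 6, 7, 8),
}

FULL_AGREEMENT_CATEGORIES = (1, 8)


def classify_patient(ce_matched: bool, pprl_level: str) -> int:
    """Map one patient's engine outcomes to its exclusive category id."""
    if pprl_level not in _LEVEL_OFFSET:
        raise ConfigError(f"invalid pprl_level {pprl_level!r}; expected one of {PPRL_LEVELS}")
    return (4 if ce_matched else 0) + _LEVEL_OFFSET[pprl_level]


def pprl_level_of(record_id: str, strict_ids: set, balanced_ids: set, permissive_ids: set) -> str:
    """Containment-consistent threshold level of one cohort record."""
    if not (strict_ids <= balanced_ids <= permissive_ids):
        raise InvariantError("match sets violate threshold containment")
    if record_id in strict_ids:
        return "all_three"
    if record_id in balanced_ids:
        return "permissive_balanced"
    if record_id in permissive_ids:
        return "permissive_only"
    return "none"


@dataclass(frozen=True)
class CategoryTable:
    """Counts of the 8 exclusive categories over a cohort."""

    counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.counts) - set(CATEGORY_IDS)
        if bad:
            raise ConfigError(f"invalid category ids: {sorted(bad)}")
        if any(v < 0 for v in self.counts.values()):
            raise ConfigError("category counts must be non-negative")

    def count(self, category_id: int) -> int:
        return int(self.counts.get(category_id, 0))

    @property
    def cohort_size(self) -> int:
        return sum(self.count(c) for c in CATEGORY_IDS)

    @property
    def matches_any(self) -> int:
        """Union proxy gold standard size: everyone matched by either engine."""
        return self.cohort_size - self.count(1)

    def algorithm_total(self, algorithm: str) -> int:
        return sum(self.count(c) for c in ALGORITHM_ROWS[algorithm])

    def totals(self) -> dict[str, int]:
        return {a: self.algorithm_total(a) for a in ALGORITHM_ROWS}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"category_id": CATEGORY_IDS,
             "count": [self.count(c) for c in CATEGORY_IDS]}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CategoryTable":
        df = pd.read_csv(path)
        if not {"category_id", "count"} <= set(df.columns):
            raise ConfigError(f"{path} must have category_id,count columns")
        return cls(dict(zip(df["category_id"].astype(int), df["count"].astype(int))))


@dataclass
class CategoryAssignment:
    """Per-patient categories plus the aggregate table."""

    table: CategoryTable
    membership: dict  # category_id -> sorted list of cohort record ids


def build_category_table(
    cohort_ids,
    rule_matched_ids: set,
    strict_ids: set,
    balanced_ids: set,
    permissive_ids: set,
) -> CategoryAssignment:
    """Partition the cohort and count each exclusive category.

    Match-set arguments hold cohort-side record ids.  Raises on containment
    violations (a record strict-matched but not balanced-matched) rather than
    silently misclassifying.
    """
    if not (strict_ids <= balanced_ids <= permissive_ids):
        raise InvariantError("match sets violate threshold containment")
    membership: dict[int, list] = {c: [] for c in CATEGORY_IDS}
    for rid in cohort_ids:
        level = pprl_level_of(rid, strict_ids, balanced_ids, permissive_ids)
        cat = classify_patient(rid in rule_matched_ids, level)
        membership[cat].append(rid)
    for ids in membership.values():
        ids.sort()
    table = CategoryTable({c: len(ids) for c, ids in membership.items()})
    if table.cohort_size != len(list(cohort_ids)):
        raise InvariantError("category counts do not sum to cohort size")  # pragma: no cover
    return CategoryAssignment(table=table, membership=membership)


def plot_categories(table: CategoryTable, path: str | Path) -> None:
    """Render exclusive category counts as a simple UpSet-style figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ids = list(CATEGORY_IDS)
    counts = [table.count(c) for c in ids]
    fig, (ax_bar, ax_dot) = plt.subplots(
        2, 1, figsize=(8, 5), sharex=True,
        gridspec_kw={"height_ratios": [3, 1.4]},
    )
    ax_bar.bar(ids, counts, color="#4477aa")
    ax_bar.set_ylabel("patients")
    ax_bar.set_yscale("symlog")
    algos = list(ALGORITHM_ROWS)
    for y, algo in enumerate(reversed(algos)):
        member = [c in ALGORITHM_ROWS[algo] for c in ids]
        ax_dot.scatter(ids, [y] * len(ids),
                       s=[60 if m else 12 for m in member],
                       c=["#222222" if m else "#cccccc" for m in member])
    ax_dot.set_yticks(range(len(algos)))
    ax_dot.set_yticklabels(list(reversed(algos)))
    ax_dot.set_xticks(ids)
    ax_dot.set_xlabel("exclusive category")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
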