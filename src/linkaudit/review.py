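"""Stratified audit sampling and adjudication of proposed matches.

Synthetic mode samples patients from the disagreement categories, looks up
whether each sampled patient's proposed cross-site pair is genuine in the
truth ledger, and perturbs the verdicts with configurable uncertainty and
restricted-record exclusion noise.  Replication mode instead ingests a
completed review table (category_id, sample_reviewed, fm_count, um_count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import ConfigError

logger = logging.getLogger(__name__)

VERDICTS = ("true_match", "false_match", "uncertain", "excluded_restricted")

# Default: audit every category except the two full-agreement ones (1 and 8).
DEFAULT_REVIEW_CATEGORIES = (2, 3, 4, 5, 6, 7)


@dataclass(frozen=True)
class ReviewPlan:
    categories: tuple[int, ...] = DEFAULT_REVIEW_CATEGORIES
    n_per_category: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_category <= 0:
            raise ConfigError("n_per_category must be positive")
        if any(c not in range(1, 9) for c in self.categories):
            raise ConfigError("review categories must be category ids 1-8")


@dataclass(frozen=True)
class Adjudication:
    record_id: str
    category_id: int
    verdict: str

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ConfigError(f"invalid verdict {self.verdict!r}")


def draw_samples(membership: dict, plan: ReviewPlan) -> dict[int, list[str]]:
    """Simple random sample without replacement per planned category.

    A category smaller than ``n_per_category`` is taken whole (with a warning);
    identical plans (including seed) yield identical samples.
    """
    rng = np.random.default_rng(np.random.SeedSequence([plan.seed, 2]))
    samples: dict[int, list[str]] = {}
    for cat in plan.categories:
        members = sorted(membership.get(cat, []))
        if len(members) < plan.n_per_category:
            logger.warning(
                "category %d has only %d members (< %d); sampling all",
                cat, len(members), plan.n_per_category,
            )
            samples[cat] = members
            continue
        idx = rng.choice(len(members), size=plan.n_per_category, replace=False)
        samples[cat] = [members[i] for i in sorted(idx)]
    return samples


def simulate_adjudication(
    samples: dict[int, list[str]],
    truth_labels: dict[str, bool],
    uncertainty_rate: float = 0.0,
    restricted_rate: float = 0.0,
    seed: int = 0,
) -> list[Adjudication]:
    """Adjudicate sampled patients against ground truth with reviewer noise.

    ``truth_labels`` maps record id to whether its proposed pair is genuine.
    Each verdict starts from truth, is flipped to restricted-exclusion with
    ``restricted_rate``, otherwise to uncertain with ``uncertainty_rate``.
    """
    for rate, name in ((uncertainty_rate, "uncertainty_rate"),
                       (restricted_rate, "restricted_rate")):
        if not (0.0 <= rate <= 1.0):
            raise ConfigError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    out: list[Adjudication] = []
    for cat in sorted(samples):
        for rid in samples[cat]:
            if rid not in truth_labels:
                raise ConfigError(f"sampled record {rid} missing from truth labels")
            if rng.random() < restricted_rate:
                verdict = "excluded_restricted"
            elif rng.random() < uncertainty_rate:
                verdict = "uncertain"
            else:
                verdict = "true_match" if truth_labels[rid] else "false_match"
            out.append(Adjudication(rid, cat, verdict))
    return out


@dataclass(frozen=True)
class ReviewTable:
    """Per-category audit outcome counts (restricted exclusions already removed)."""

    rows: dict = field(default_factory=dict)  # category_id -> (sample_reviewed, fm, um)

    def __post_init__(self) -> None:
        for cat, (n, fm, um) in self.rows.items():
            if cat not in range(1, 9):
                raise ConfigError(f"invalid category id {cat}")
            if min(n, fm, um) < 0 or fm + um > n:
                raise ConfigError(f"inconsistent review counts for category {cat}")

    @property
    def categories(self) -> list[int]:
        return sorted(self.rows)

    def sample_reviewed(self, cat: int) -> int:
        return self.rows[cat][0]

    def fm_count(self, cat: int) -> int:
        return self.rows[cat][1]

    def um_count(self, cat: int) -> int:
        return self.rows[cat][2]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"category_id": c, "sample_reviewed": n, "fm_count": fm, "um_count": um}
             for c, (n, fm, um) in sorted(self.rows.items())]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReviewTable":
        df = pd.read_csv(path)
        required = {"category_id", "sample_reviewed", "fm_count", "um_count"}
        if not required <= set(df.columns):
            raise ConfigError(f"{path} must have columns {sorted(required)}")
        rows = {
            int(r.category_id): (int(r.sample_reviewed), int(r.fm_count), int(r.um_count))
            for r in df.itertuples(index=False)
        }
        return cls(rows)


def summarize_reviews(adjudications: list[Adjudication]) -> ReviewTable:
    """Tally adjudications into a review table.

    Restricted exclusions shrink the reviewed sample (they are not resampled),
    mirroring how privacy-flagged charts reduce an audit's denominator.
    """
    rows: dict[int, list[int]] = {}
    for adj in adjudications:
        n, fm, um = rows.setdefault(adj.category_id, [0, 0, 0])
        if adj.verdict == "excluded_restricted":
            continue
        rows[adj.category_id][0] += 1
        if adj.verdict == "false_match":
            rows[adj.category_id][1] += 1
        elif adj.verdict == "uncertain":
            rows[adj.category_id][2] += 1
    return ReviewTable({c: tuple(v) for c, v in rows.items()})


def write_adjudications(adjudications: list[Adjudication], path: str | Path) -> None:
    pd.DataFrame(
        [{"record_id": a.record_id, "category_id": a.category_id, "verdict": a.verdict}
         for a in adjudications]
    ).to_csv(path, index=False, lineterminator="\n")
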