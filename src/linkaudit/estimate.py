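"""False-match-rate estimation, population projection, precision and recall.

The statistical core of the evaluation.  For each audited category the
false-match (FM) rate is fm_count / (sample_reviewed - um_count) — uncertain
verdicts leave the denominator — with an exact (Clopper-Pearson) binomial 95%
CI.  Rates and CI bounds are projected onto the category's population count,
summed (unrounded) over each algorithm's constituent categories, and converted
to precision and recall against the union proxy gold standard:

    precision_a = (M_a - FM_a) / M_a
    recall_a    = (M_a - FM_a) / matches_any

Unaudited full-agreement categories contribute zero projected errors.  All
intermediate arithmetic keeps full float precision; rounding (half-up) happens
only at display.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import beta, norm

from ._util import ConfigError, InestimableError, format_rate_percent, round_half_up
from .categories import ALGORITHM_ROWS, CATEGORY_IDS, CategoryTable
from .review import ReviewTable

Z_DEFAULT_CONFIDENCE = 0.95


def exact_binomial_ci(successes: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact CI for a binomial proportion via beta quantiles.

    Lower bound is 0 when successes == 0 and upper bound is 1 when
    successes == n.  ``n == 0`` is inestimable.
    """
    if n <= 0:
        raise InestimableError("exact CI undefined for n = 0")
    if not 0 <= successes <= n:
        raise ConfigError(f"successes {successes} outside [0, {n}]")
    alpha = 1.0 - confidence
    lo = 0.0 if successes == 0 else float(beta.ppf(alpha / 2, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lo, hi


@dataclass(frozen=True)
class FMRateEstimate:
    """Audited false-match rate for one category, or an explicit undefined state."""

    category_id: int
    fm_count: int
    um_count: int
    sample_reviewed: int
    denominator: int
    rate: float | None
    ci_lo: float | None
    ci_hi: float | None

    @property
    def estimable(self) -> bool:
        return self.rate is not None


def fm_rate(fm_count: int, um_count: int, sample_reviewed: int,
            category_id: int = 0, confidence: float = 0.95) -> FMRateEstimate:
    """Point FM rate with exact CI; a zero denominator propagates as undefined."""
    if min(fm_count, um_count, sample_reviewed) < 0:
        raise ConfigError("counts must be non-negative")
    if fm_count + um_count > sample_reviewed:
        raise ConfigError("fm_count + um_count exceeds sample_reviewed")
    denom = sample_reviewed - um_count
    if denom == 0:
        return FMRateEstimate(category_id, fm_count, um_count, sample_reviewed,
                              0, None, None, None)
    lo, hi = exact_binomial_ci(fm_count, denom, confidence)
    return FMRateEstimate(category_id, fm_count, um_count, sample_reviewed,
                          denom, fm_count / denom, lo, hi)


@dataclass(frozen=True)
class ProjectedErrors:
    """One category's FM rate projected onto its population count (unrounded)."""

    category_id: int
    category_count: int
    fm: float | None
    lo: float | None
    hi: float | None

    @property
    def estimable(self) -> bool:
        return self.fm is not None


def project_to_population(estimate: FMRateEstimate, category_count: int) -> ProjectedErrors:
    """category_count x (rate, ci_lo, ci_hi).  A zero-count category projects 0
    even when its rate is undefined; a populated category with an undefined
    rate stays undefined."""
    if category_count < 0:
        raise ConfigError("category_count must be non-negative")
    if category_count == 0:
        return ProjectedErrors(estimate.category_id, 0, 0.0, 0.0, 0.0)
    if not estimate.estimable:
        return ProjectedErrors(estimate.category_id, category_count, None, None, None)
    return ProjectedErrors(
        estimate.category_id, category_count,
        category_count * estimate.rate,
        category_count * estimate.ci_lo,
        category_count * estimate.ci_hi,
    )


def algorithm_errors(projections: dict[int, ProjectedErrors],
                     rows: tuple[int, ...]) -> tuple[float, float, float] | None:
    """Sum unrounded projected errors over an algorithm's categories.

    Categories absent from ``projections`` (the unaudited full-agreement ones)
    contribute zero.  Any constituent inestimable projection makes the whole
    algorithm inestimable (None).
    """
    fm = lo = hi = 0.0
    for cat in rows:
        proj = projections.get(cat)
        if proj is None:
            continue
        if not proj.estimable:
            return None
        fm += proj.fm
        lo += proj.lo
        hi += proj.hi
    return fm, lo, hi


def precision(total_matches: int, fm: float, fm_lo: float, fm_hi: float) -> tuple[float, float, float]:
    """(point, ci_lo, ci_hi): CI endpoints come from the projected-error bounds."""
    if total_matches <= 0:
        raise InestimableError("precision undefined for zero matches")
    return (
        (total_matches - fm) / total_matches,
        (total_matches - fm_hi) / total_matches,
        (total_matches - fm_lo) / total_matches,
    )


def recall(total_matches: int, fm: float, fm_lo: float, fm_hi: float,
           matches_any: int, confidence: float = 0.95) -> tuple[float, float, float]:
    """(point, ci_lo, ci_hi) against the union proxy gold standard.

    CI construction (documented formula): normal-approximation binomial bounds
    on the recall proportion, additionally widened by the projected-FM-count
    bounds —

        lo = (M - FM_hi)/N - z * se,   hi = (M - FM_lo)/N + z * se,

    where se = sqrt(p(1-p)/N) at the point recall p.  Endpoints are clipped to
    [0, 1].
    """
    if matches_any <= 0:
        raise InestimableError("recall undefined for an empty union gold standard")
    p = (total_matches - fm) / matches_any
    z = float(norm.ppf(1 - (1 - confidence) / 2))
    se = (max(p * (1 - p), 0.0) / matches_any) ** 0.5
    lo = (total_matches - fm_hi) / matches_any - z * se
    hi = (total_matches - fm_lo) / matches_any + z * se
    return p, max(lo, 0.0), min(hi, 1.0)


@dataclass(frozen=True)
class AlgorithmAccuracy:
    algorithm: str
    rows: tuple[int, ...]
    total_matches: int
    status: str  # "ok" | "inestimable"
    fm: float | None = None
    fm_lo: float | None = None
    fm_hi: float | None = None
    precision: float | None = None
    precision_lo: float | None = None
    precision_hi: float | None = None
    net_true: float | None = None
    net_true_lo: float | None = None
    net_true_hi: float | None = None
    recall: float | None = None
    recall_lo: float | None = None
    recall_hi: float | None = None


@dataclass
class AccuracyReport:
    """Full evaluation output: audited rates, projections, per-algorithm accuracy."""

    cohort_size: int
    matches_any: int
    estimates: dict = field(default_factory=dict)     # category_id -> FMRateEstimate
    projections: dict = field(default_factory=dict)   # category_id -> ProjectedErrors
    algorithms: dict = field(default_factory=dict)    # name -> AlgorithmAccuracy

    @property
    def inestimable(self) -> bool:
        return any(a.status != "ok" for a in self.algorithms.values())

    def review_frame(self) -> pd.DataFrame:
        """Category-level audit results and projections (review-table analog)."""
        rows = []
        for cat in sorted(self.estimates):
            e: FMRateEstimate = self.estimates[cat]
            p: ProjectedErrors = self.projections[cat]
            rows.append({
                "category_id": cat,
                "sample_reviewed": e.sample_reviewed,
                "fm_count": e.fm_count,
                "um_count": e.um_count,
                "fm_denominator": e.denominator,
                "fm_rate_pct": format_rate_percent(e.rate) if e.estimable else "inestimable",
                "fm_rate_ci": (f"{format_rate_percent(e.ci_lo)}%-{format_rate_percent(e.ci_hi)}%"
                               if e.estimable else ""),
                "projected_fm": round_half_up(p.fm) if p.estimable else None,
                "projected_fm_lo": round_half_up(p.lo) if p.estimable else None,
                "projected_fm_hi": round_half_up(p.hi) if p.estimable else None,
            })
        return pd.DataFrame(rows)

    def accuracy_frame(self) -> pd.DataFrame:
        """Per-algorithm totals, projected errors, precision and recall."""
        rows = []
        for name, a in self.algorithms.items():
            row = {"algorithm": name,
                   "rows_summed": ",".join(map(str, a.rows)),
                   "total_matches": a.total_matches,
                   "status": a.status}
            if a.status == "ok":
                row.update({
                    "projected_errors": round_half_up(a.fm),
                    "projected_errors_lo": round_half_up(a.fm_lo),
                    "projected_errors_hi": round_half_up(a.fm_hi),
                    "precision_pct": round_half_up(100 * a.precision, 1),
                    "precision_lo_pct": round_half_up(100 * a.precision_lo, 1),
                    "precision_hi_pct": round_half_up(100 * a.precision_hi, 1),
                    "net_true_matches": round_half_up(a.net_true),
                    "recall_pct": round_half_up(100 * a.recall, 1),
                    "recall_lo_pct": round_half_up(100 * a.recall_lo, 1),
                    "recall_hi_pct": round_half_up(100 * a.recall_hi, 1),
                })
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "cohort_size": self.cohort_size,
            "matches_any": self.matches_any,
            "categories": self.review_frame().to_dict("records"),
            "algorithms": self.accuracy_frame().to_dict("records"),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=float) + "\n")


def full_report(
    category_table: CategoryTable,
    review_table: ReviewTable,
    row_map: dict[str, tuple[int, ...]] | None = None,
    confidence: float = 0.95,
) -> AccuracyReport:
    """Run the whole estimation chain from category counts and review counts."""
    row_map = dict(row_map) if row_map is not None else dict(ALGORITHM_ROWS)
    for name, rows in row_map.items():
        if any(c not in CATEGORY_IDS for c in rows):
            raise ConfigError(f"row map for {name!r} references invalid categories")

    estimates: dict[int, FMRateEstimate] = {}
    projections: dict[int, ProjectedErrors] = {}
    for cat in review_table.categories:
        est = fm_rate(review_table.fm_count(cat), review_table.um_count(cat),
                      review_table.sample_reviewed(cat), category_id=cat,
                      confidence=confidence)
        estimates[cat] = est
        projections[cat] = project_to_population(est, category_table.count(cat))

    report = AccuracyReport(
        cohort_size=category_table.cohort_size,
        matches_any=category_table.matches_any,
        estimates=estimates,
        projections=projections,
    )

    for name, rows in row_map.items():
        total = sum(category_table.count(c) for c in rows)
        errors = algorithm_errors(projections, tuple(rows))
        if errors is None or total == 0:
            report.algorithms[name] = AlgorithmAccuracy(
                algorithm=name, rows=tuple(rows), total_matches=total,
                status="inestimable",
            )
            continue
        fm, fm_lo, fm_hi = errors
        prec, prec_lo, prec_hi = precision(total, fm, fm_lo, fm_hi)
        rec, rec_lo, rec_hi = recall(total, fm, fm_lo, fm_hi,
                                     category_table.matches_any, confidence)
        report.algorithms[name] = AlgorithmAccuracy(
            algorithm=name, rows=tuple(rows), total_matches=total, status="ok",
            fm=fm, fm_lo=fm_lo, fm_hi=fm_hi,
            precision=prec, precision_lo=prec_lo, precision_hi=prec_hi,
            net_true=total - fm, net_true_lo=total - fm_hi, net_true_hi=total - fm_lo,
            recall=rec, recall_lo=rec_lo, recall_hi=rec_hi,
        )
    return report
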