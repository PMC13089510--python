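"""End-to-end orchestration.

``run_synthetic`` chains simulate -> tokenize -> match (both engines) ->
partition -> sample -> adjudicate -> estimate on generated registries.
``run_replication`` runs only the estimation chain on previously published
category-count and review-count tables (packaged fixtures by default).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from . import __version__
from ._util import ConfigError, sha256_file, sha256_text
from .categories import ALGORITHM_ROWS, CategoryAssignment, CategoryTable, build_category_table
from .engines import (
    IDENTITY_CALIBRATION,
    MonotoneCalibration,
    PPRLMatchResult,
    ThresholdSet,
    WeightTable,
    calibrate_scores,
    candidate_pairs,
    pprl_match,
    rule_match_registry,
    token_similarity,
)
from .estimate import AccuracyReport, full_report
from .review import (
    DEFAULT_REVIEW_CATEGORIES,
    ReviewPlan,
    ReviewTable,
    draw_samples,
    simulate_adjudication,
    summarize_reviews,
    write_adjudications,
)
from .synth import (
    SimulationConfig,
    generate_population,
    render_registries,
    write_registry,
    write_truth,
)
from .tokens import DEFAULT_SCHEMA, TokenizeStats, normalize_pii, tokenize_registry, write_tokens

_FIXTURE_CATEGORIES = "replication_categories.csv"
_FIXTURE_REVIEWS = "replication_reviews.csv"


@dataclass
class PipelineConfig:
    """Everything a synthetic end-to-end run needs, fully seed-determined."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    salt: str = "linkaudit-shared-salt"
    thresholds: ThresholdSet = field(default_factory=ThresholdSet)
    rule_weights: WeightTable = field(default_factory=WeightTable)
    review_categories: tuple[int, ...] = DEFAULT_REVIEW_CATEGORIES
    n_per_category: int = 200
    uncertainty_rate: float = 0.02
    restricted_rate: float = 0.0225  # ~27 exclusions per 1200 sampled
    calibration_site_size: int = 3000
    calibration_overlap: float = 0.5

    def __post_init__(self) -> None:
        if not self.salt:
            raise ConfigError("salt must be non-empty")
        if self.calibration_site_size < 100:
            raise ConfigError("calibration_site_size must be at least 100")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = SimulationConfig.from_dict(d.pop("simulation", {}))
        thresholds = ThresholdSet(**d.pop("thresholds", {}))
        wt = d.pop("rule_weights", None)
        weights = WeightTable(**wt) if wt else WeightTable()
        if "review_categories" in d:
            d["review_categories"] = tuple(d["review_categories"])
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown pipeline config keys: {sorted(extra)}")
        return cls(simulation=sim, thresholds=thresholds, rule_weights=weights, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path} must contain a YAML mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "simulation": self.simulation.to_dict(),
            "salt": self.salt,
            "thresholds": self.thresholds.as_dict(),
            "rule_weights": {"weights": dict(self.rule_weights.weights),
                             "match_threshold": self.rule_weights.match_threshold},
            "review_categories": list(self.review_categories),
            "n_per_category": self.n_per_category,
            "uncertainty_rate": self.uncertainty_rate,
            "restricted_rate": self.restricted_rate,
            "calibration_site_size": self.calibration_site_size,
            "calibration_overlap": self.calibration_overlap,
        }


def build_benchmark_calibration(config: PipelineConfig) -> MonotoneCalibration:
    """Fit the score calibration on a held-out labeled benchmark.

    A separate registry pair is simulated from the same corruption settings
    under a derived seed (standing in for external benchmarking datasets),
    candidate pairs are scored raw, labeled from that benchmark's own truth
    ledger, and a monotone calibration is fit.  Falls back to the identity map
    when the benchmark yields only one class.
    """
    sim = config.simulation
    n = min(config.calibration_site_size, max(sim.n_site_a, sim.n_site_b))
    bench_sim = dataclasses.replace(
        sim, n_site_a=n, n_site_b=n,
        overlap_fraction=config.calibration_overlap,
        seed=sim.seed + 1_000_003,
    )
    population = generate_population(bench_sim)
    reg_a, reg_b, truth, _ = render_registries(population, bench_sim)
    tok_a, _ = tokenize_registry(reg_a, DEFAULT_SCHEMA, config.salt)
    tok_b, _ = tokenize_registry(reg_b, DEFAULT_SCHEMA, config.salt)

    truth_pairs = set(zip(truth["record_id_site_a"], truth["record_id_site_b"]))
    ids_a = tok_a["record_id"].tolist()
    ids_b = tok_b["record_id"].tolist()
    cols = [c for c in tok_a.columns if c != "record_id"]
    arrs_a = tok_a[cols].values.tolist()
    arrs_b = tok_b[cols].values.tolist()

    raws, labels = [], []
    for i, j in candidate_pairs(tok_a, tok_b):
        raw = token_similarity(arrs_a[i], arrs_b[j])
        if raw <= 0.0:
            continue
        raws.append(raw)
        labels.append((ids_a[i], ids_b[j]) in truth_pairs)
    if len(set(labels)) < 2:
        return IDENTITY_CALIBRATION
    return calibrate_scores(raws, labels)


@dataclass
class SyntheticRunResult:
    config: PipelineConfig
    calibration: MonotoneCalibration
    registries: tuple
    truth: object
    tokenize_stats: dict[str, TokenizeStats]
    pprl: PPRLMatchResult
    rule_outcomes: list
    assignment: CategoryAssignment
    review_table: ReviewTable
    report: AccuracyReport
    adjudications: list


def run_synthetic(config: PipelineConfig, outdir: str | Path | None = None) -> SyntheticRunResult:
    """Full synthetic evaluation; identical configs yield identical results."""
    sim = config.simulation
    population = generate_population(sim)
    reg_a, reg_b, truth, _corr_stats = render_registries(population, sim)
    truth_pairs = set(zip(truth["record_id_site_a"], truth["record_id_site_b"]))

    tok_a, stats_a = tokenize_registry(reg_a, DEFAULT_SCHEMA, config.salt)
    tok_b, stats_b = tokenize_registry(reg_b, DEFAULT_SCHEMA, config.salt)

    calibration = build_benchmark_calibration(config)
    pprl = pprl_match(tok_a, tok_b, calibration, config.thresholds)

    queries = [normalize_pii(r) for r in reg_a.to_dict("records")]
    cands = [normalize_pii(r) for r in reg_b.to_dict("records")]
    rule_outcomes = rule_match_registry(queries, cands, config.rule_weights)
    rule_matched = {o.record_id: o.matched_record_id for o in rule_outcomes if o.matched}

    cohort_ids = reg_a["record_id"].tolist()
    assignment = build_category_table(
        cohort_ids,
        set(rule_matched),
        pprl.matched_ids_a("strict"),
        pprl.matched_ids_a("balanced"),
        pprl.matched_ids_a("permissive"),
    )

    plan = ReviewPlan(categories=tuple(config.review_categories),
                      n_per_category=config.n_per_category, seed=sim.seed)
    samples = draw_samples(assignment.membership, plan)

    # The reviewed pair for each sampled patient: the token-engine counterpart
    # when one exists, otherwise the rule-engine counterpart (rule-only category).
    pprl_partner = {a: b for a, b in pprl.match_sets["permissive"]}
    truth_labels: dict[str, bool] = {}
    for cat, ids in samples.items():
        for rid in ids:
            partner = pprl_partner.get(rid) or rule_matched.get(rid)
            truth_labels[rid] = partner is not None and (rid, partner) in truth_pairs

    adjudications = simulate_adjudication(
        samples, truth_labels,
        uncertainty_rate=config.uncertainty_rate,
        restricted_rate=config.restricted_rate,
        seed=sim.seed,
    )
    review_table = summarize_reviews(adjudications)
    report = full_report(assignment.table, review_table)

    result = SyntheticRunResult(
        config=config, calibration=calibration, registries=(reg_a, reg_b),
        truth=truth, tokenize_stats={"A": stats_a, "B": stats_b}, pprl=pprl,
        rule_outcomes=rule_outcomes, assignment=assignment,
        review_table=review_table, report=report, adjudications=adjudications,
    )
    if outdir is not None:
        _write_artifacts(result, Path(outdir))
    return result


def _write_artifacts(result: SyntheticRunResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_registry(result.registries[0], outdir / "registry_site_a.csv")
    write_registry(result.registries[1], outdir / "registry_site_b.csv")
    write_truth(result.truth, outdir / "truth_ledger.csv")
    tok_cols = ["record_id", *[t.template_id for t in DEFAULT_SCHEMA.templates]]
    del tok_cols  # token files are reproducible; keep assignment + tables only
    result.pprl.assignment.to_csv(outdir / "pprl_assignment.csv", index=False,
                                  lineterminator="\n")
    result.assignment.table.to_csv(outdir / "category_table.csv")
    result.review_table.to_csv(outdir / "review_table.csv")
    write_adjudications(result.adjudications, outdir / "adjudications.csv")
    result.report.to_json(outdir / "accuracy_report.json")
    (outdir / "calibration.json").write_text(
        json.dumps(result.calibration.to_dict(), indent=2) + "\n")
    write_manifest(result.config, outdir)


def write_manifest(config: PipelineConfig, outdir: Path) -> None:
    config_text = json.dumps(config.to_dict(), sort_keys=True)
    files = sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json")
    manifest = {
        "linkaudit_version": __version__,
        "config": config.to_dict(),
        "config_digest": sha256_text(config_text),
        "seed": config.simulation.seed,
        "file_digests": {name: sha256_file(outdir / name) for name in files},
        "created_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _fixture_path(name: str):
    return resources.files("linkaudit.data").joinpath(name)


def load_replication_fixtures() -> tuple[CategoryTable, ReviewTable]:
    """The packaged published count tables used by replication mode."""
    with resources.as_file(_fixture_path(_FIXTURE_CATEGORIES)) as p:
        cats = CategoryTable.from_csv(p)
    with resources.as_file(_fixture_path(_FIXTURE_REVIEWS)) as p:
        reviews = ReviewTable.from_csv(p)
    return cats, reviews


def run_replication(
    categories_csv: str | Path | None = None,
    reviews_csv: str | Path | None = None,
    row_map: dict[str, tuple[int, ...]] | None = None,
) -> AccuracyReport:
    """Estimation chain over printed count tables (packaged fixtures by default)."""
    if categories_csv is None or reviews_csv is None:
        fix_cats, fix_reviews = load_replication_fixtures()
    cats = CategoryTable.from_csv(categories_csv) if categories_csv else fix_cats
    reviews = ReviewTable.from_csv(reviews_csv) if reviews_csv else fix_reviews
    return full_report(cats, reviews, row_map=row_map or ALGORITHM_ROWS)
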