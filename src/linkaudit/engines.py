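"""Two linkage engines.

``rule_match`` is a deterministic matcher in the style of EHR patient-lookup
modules: it sums per-identifier agreement weights over 12 comparisons and
declares a match only when exactly one candidate clears the point threshold
(two candidates above threshold is an ambiguity and the query fails).  SSN is
deliberately absent from the default weight table.

``pprl_match`` scores hashed token arrays with a weighted Jaccard agreement,
maps the raw similarity to a 0-100 calibrated match-probability score via a
monotone (isotonic) calibration fit on labeled pairs, applies candidate
blocking on shared token values, and produces one greedy one-to-one assignment
from which the strict/balanced/permissive (98/95/90) match sets are read off —
so threshold containment holds structurally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import ConfigError, InvariantError

logger = logging.getLogger(__name__)

SOUNDEX_SENTINEL = "0000"

_SOUNDEX_CODES = {}
for _letters, _digit in (("BFPV", "1"), ("CGJKQSXZ", "2"), ("DT", "3"),
                         ("L", "4"), ("MN", "5"), ("R", "6")):
    for _c in _letters:
        _SOUNDEX_CODES[_c] = _digit


def soundex(name: str) -> str:
    """American Soundex: initial letter + 3 digits, zero-padded.

    Letters coded in six groups; vowels (and Y) separate equal codes, H and W
    do not.  Non-alphabetic characters are ignored; fully non-alphabetic or
    empty input yields the sentinel "0000".
    """
    letters = [c for c in name.upper() if "A" <= c <= "Z"]
    if not letters:
        logger.warning("soundex: no alphabetic content in %r", name)
        return SOUNDEX_SENTINEL
    first = letters[0]
    prev = _SOUNDEX_CODES.get(first, "")
    digits = []
    for c in letters[1:]:
        if c in "HW":
            continue  # transparent: previous code survives across H/W
        code = _SOUNDEX_CODES.get(c, "")
        if code and code != prev:
            digits.append(code)
        prev = code
    return (first + "".join(digits) + "000")[:4]


# ---------------------------------------------------------------------------
# Rule-based engine
# ---------------------------------------------------------------------------

RULE_COMPARISONS = (
    "exact_full_name", "soundex_first", "soundex_last", "exact_dob",
    "year_of_birth", "exact_email", "exact_phone", "exact_address",
    "exact_zip", "exact_gender", "exact_middle_initial", "exact_first_name",
)

DEFAULT_WEIGHTS = {
    "exact_full_name": 25.0,
    "soundex_first": 8.0,
    "soundex_last": 8.0,
    "exact_dob": 30.0,
    "year_of_birth": 10.0,
    "exact_email": 15.0,
    "exact_phone": 15.0,
    "exact_address": 10.0,
    "exact_zip": 5.0,
    "exact_gender": 5.0,
    "exact_middle_initial": 5.0,
    "exact_first_name": 10.0,
}


@dataclass(frozen=True)
class WeightTable:
    """Identifier-agreement weights and the uniqueness-qualified match threshold.

    Defaults are a documented stand-in, not any vendor's production settings;
    date-of-birth and exact-name agreement carry the largest weights.
    """

    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    match_threshold: float = 60.0

    def __post_init__(self) -> None:
        unknown = set(self.weights) - set(RULE_COMPARISONS)
        if unknown:
            raise ConfigError(f"unknown rule comparisons: {sorted(unknown)}")
        if any(w < 0 for w in self.weights.values()):
            raise ConfigError("weights must be non-negative")
        if self.match_threshold <= 0:
            raise ConfigError("match_threshold must be positive")


@dataclass(frozen=True)
class RuleMatchOutcome:
    record_id: str
    status: str  # "matched" | "unsuccessful"
    matched_record_id: str | None
    points: float

    @property
    def matched(self) -> bool:
        return self.status == "matched"


def _rule_features(rec: dict) -> dict:
    """Precompute derived comparison fields from a normalized record."""
    return {
        "record_id": rec["record_id"],
        "first": rec.get("first_name", ""),
        "last": rec.get("last_name", ""),
        "sdx_first": soundex(rec["first_name"]) if rec.get("first_name") else "",
        "sdx_last": soundex(rec["last_name"]) if rec.get("last_name") else "",
        "dob": rec.get("dob", ""),
        "yob": rec.get("dob", "")[-4:],
        "email": rec.get("email", ""),
        "phone": rec.get("phone", ""),
        "address": rec.get("street_address", ""),
        "zip": rec.get("zip", ""),
        "gender": rec.get("gender", ""),
        "mi": (rec.get("middle_name") or "")[:1],
    }


def _agree(a: str, b: str) -> bool:
    return bool(a) and a == b


def _pair_points(q: dict, c: dict, weights: dict) -> float:
    pts = 0.0
    full_name = _agree(q["first"], c["first"]) and _agree(q["last"], c["last"])
    checks = {
        "exact_full_name": full_name,
        "soundex_first": _agree(q["sdx_first"], c["sdx_first"]),
        "soundex_last": _agree(q["sdx_last"], c["sdx_last"]),
        "exact_dob": _agree(q["dob"], c["dob"]),
        "year_of_birth": _agree(q["yob"], c["yob"]),
        "exact_email": _agree(q["email"], c["email"]),
        "exact_phone": _agree(q["phone"], c["phone"]),
        "exact_address": _agree(q["address"], c["address"]),
        "exact_zip": _agree(q["zip"], c["zip"]),
        "exact_gender": _agree(q["gender"], c["gender"]),
        "exact_middle_initial": _agree(q["mi"], c["mi"]),
        "exact_first_name": _agree(q["first"], c["first"]),
    }
    for name, hit in checks.items():
        if hit:
            pts += weights.get(name, 0.0)
    return pts


def rule_match(query: dict, candidates: list[dict], weights: WeightTable) -> RuleMatchOutcome:
    """Match one normalized query record against normalized candidate records.

    Matched iff exactly one candidate's weight sum strictly exceeds the
    threshold; zero or multiple qualifying candidates are unsuccessful.
    """
    q = _rule_features(query)
    best_pts, best_id = 0.0, None
    above = 0
    for cand in candidates:
        c = _rule_features(cand)
        pts = _pair_points(q, c, weights.weights)
        if pts > weights.match_threshold:
            above += 1
            if pts > best_pts or (pts == best_pts and (best_id is None or c["record_id"] < best_id)):
                best_pts, best_id = pts, c["record_id"]
        elif pts > best_pts and above == 0:
            best_pts, best_id = pts, c["record_id"]
    if above == 1:
        return RuleMatchOutcome(q["record_id"], "matched", best_id, best_pts)
    return RuleMatchOutcome(q["record_id"], "unsuccessful", None, best_pts)


# Blocking keys for registry-scale rule matching.  With the default weights a
# pair sharing neither dob, phone, email, nor both name soundexes can collect
# at most 53 points (exact first name 10 + its soundex 8 + year of birth 10 +
# address 10 + zip 5 + gender 5 + middle initial 5), so these blocks lose no
# qualifying candidate for any threshold above 53 (default 60).
def _rule_block_keys(f: dict) -> list[tuple]:
    keys = []
    if f["dob"]:
        keys.append(("dob", f["dob"]))
    if f["phone"]:
        keys.append(("phone", f["phone"]))
    if f["email"]:
        keys.append(("email", f["email"]))
    if f["sdx_last"] and f["sdx_first"]:
        keys.append(("name", f["sdx_last"], f["sdx_first"]))
    return keys


def rule_match_registry(
    queries: list[dict], candidates: list[dict], weights: WeightTable
) -> list[RuleMatchOutcome]:
    """Blocked rule matching of every query against a candidate registry."""
    cand_feats = [_rule_features(c) for c in candidates]
    index: dict[tuple, list[int]] = {}
    for i, f in enumerate(cand_feats):
        for key in _rule_block_keys(f):
            index.setdefault(key, []).append(i)

    out = []
    for query in queries:
        q = _rule_features(query)
        seen: set[int] = set()
        for key in _rule_block_keys(q):
            seen.update(index.get(key, ()))
        best_pts, best_id = 0.0, None
        above = 0
        for i in sorted(seen):
            c = cand_feats[i]
            pts = _pair_points(q, c, weights.weights)
            if pts > weights.match_threshold:
                above += 1
                if pts > best_pts or (pts == best_pts and (best_id is None or c["record_id"] < best_id)):
                    best_pts, best_id = pts, c["record_id"]
            elif pts > best_pts and above == 0:
                best_pts, best_id = pts, c["record_id"]
        if above == 1:
            out.append(RuleMatchOutcome(q["record_id"], "matched", best_id, best_pts))
        else:
            out.append(RuleMatchOutcome(q["record_id"], "unsuccessful", None, best_pts))
    return out


# ---------------------------------------------------------------------------
# Token-overlap engine
# ---------------------------------------------------------------------------


def token_similarity(a: list, b: list, token_weights: list[float] | None = None) -> float:
    """Weighted Jaccard agreement over two equal-length token arrays.

    Numerator: weight of templates where both tokens are non-null and equal.
    Denominator: weight of templates where at least one token is non-null.
    Templates null on both sides are ignored; an all-null union scores 0.
    """
    if len(a) != len(b):
        raise ConfigError("token arrays come from different schemas")
    w = token_weights if token_weights is not None else [1.0] * len(a)
    if len(w) != len(a):
        raise ConfigError("token_weights length does not match schema")
    inter = union = 0.0
    for ta, tb, wt in zip(a, b, w):
        if ta is None and tb is None:
            continue
        union += wt
        if ta is not None and tb is not None and ta == tb:
            inter += wt
    return inter / union if union > 0 else 0.0


@dataclass(frozen=True)
class MonotoneCalibration:
    """Piecewise-linear monotone map from raw similarity to a 0-100 score."""

    xs: tuple[float, ...]
    ys: tuple[float, ...]  # calibrated probabilities in [0, 1], non-decreasing

    def __post_init__(self) -> None:
        if len(self.xs) != len(self.ys) or not self.xs:
            raise ConfigError("calibration breakpoints malformed")
        if any(b < a for a, b in zip(self.ys, self.ys[1:])):
            raise ConfigError("calibration must be non-decreasing")

    def score(self, raw) -> np.ndarray:
        return 100.0 * np.interp(np.asarray(raw, dtype=float), self.xs, self.ys)

    def to_dict(self) -> dict:
        return {"xs": list(self.xs), "ys": list(self.ys)}

    @classmethod
    def from_dict(cls, d: dict) -> "MonotoneCalibration":
        return cls(tuple(d["xs"]), tuple(d["ys"]))


IDENTITY_CALIBRATION = MonotoneCalibration((0.0, 1.0), (0.0, 1.0))


def calibrate_scores(raw_similarities, labels) -> MonotoneCalibration:
    """Fit an isotonic (pool-adjacent-violators) map raw similarity -> P(true).

    Requires both classes among the labels.  The fitted step means at the
    unique raw values become piecewise-linear breakpoints, so the returned map
    is monotone non-decreasing with range within [0, 1].
    """
    x = np.asarray(raw_similarities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise ConfigError("raw similarities and labels must align and be non-empty")
    if len(np.unique(y)) < 2:
        raise ConfigError("calibration needs both true and false pairs")

    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    ux, start = np.unique(x, return_index=True)
    counts = np.diff(np.append(start, x.size)).astype(float)
    means = np.add.reduceat(y, start) / counts

    # pool adjacent violators
    vals = list(means)
    wts = list(counts)
    xs = list(ux)
    i = 0
    while i < len(vals) - 1:
        if vals[i] > vals[i + 1] + 1e-15:
            w = wts[i] + wts[i + 1]
            v = (vals[i] * wts[i] + vals[i + 1] * wts[i + 1]) / w
            vals[i:i + 2] = [v]
            wts[i:i + 2] = [w]
            xs[i:i + 2] = [xs[i + 1]]  # block keyed by its right edge
            i = max(i - 1, 0)
        else:
            i += 1
    return MonotoneCalibration(tuple(float(v) for v in xs), tuple(float(v) for v in vals))


@dataclass(frozen=True)
class ThresholdSet:
    strict: float = 98.0
    balanced: float = 95.0
    permissive: float = 90.0

    def __post_init__(self) -> None:
        if not (self.strict >= self.balanced >= self.permissive):
            raise ConfigError("thresholds must satisfy strict >= balanced >= permissive")

    def as_dict(self) -> dict[str, float]:
        return {"strict": self.strict, "balanced": self.balanced,
                "permissive": self.permissive}


@dataclass
class PPRLMatchResult:
    scored_pairs: pd.DataFrame  # all candidate pairs: record_id_a, record_id_b, raw, score
    assignment: pd.DataFrame    # greedy one-to-one subset of scored_pairs
    match_sets: dict            # threshold name -> set of (record_id_a, record_id_b)

    def matched_ids_a(self, level: str) -> set[str]:
        return {a for a, _ in self.match_sets[level]}


def _token_lists(tokens: pd.DataFrame) -> tuple[list[str], list[list]]:
    ids = tokens["record_id"].tolist()
    cols = [c for c in tokens.columns if c != "record_id"]
    arrs = tokens[cols].where(pd.notna(tokens[cols]), None).values.tolist()
    return ids, arrs


def candidate_pairs(tokens_a: pd.DataFrame, tokens_b: pd.DataFrame) -> list[tuple[int, int]]:
    """Blocking: all (i, j) index pairs sharing at least one non-null token value.

    Complete for the weighted-Jaccard scorer: raw_similarity > 0 requires a
    shared token, hence a shared block.
    """
    cols = [c for c in tokens_a.columns if c != "record_id"]
    if cols != [c for c in tokens_b.columns if c != "record_id"]:
        raise ConfigError("token files come from different schemas")
    pairs: set[tuple[int, int]] = set()
    for col in cols:
        index: dict[str, list[int]] = {}
        for j, v in enumerate(tokens_b[col].tolist()):
            if v is not None and not pd.isna(v):
                index.setdefault(v, []).append(j)
        for i, v in enumerate(tokens_a[col].tolist()):
            if v is None or pd.isna(v):
                continue
            for j in index.get(v, ()):
                pairs.add((i, j))
    return sorted(pairs)


def pprl_match(
    tokens_a: pd.DataFrame,
    tokens_b: pd.DataFrame,
    calibration: MonotoneCalibration = IDENTITY_CALIBRATION,
    thresholds: ThresholdSet = ThresholdSet(),
    blocking: bool = True,
    token_weights: list[float] | None = None,
) -> PPRLMatchResult:
    """Score candidate pairs, assign one-to-one, and cut the threshold family.

    The greedy assignment walks pairs by descending score with lexicographic
    (record_id_a, record_id_b) tie-breaking; each record participates in at
    most one assigned pair.  All three match sets are cut from that single
    assignment, so strict ⊆ balanced ⊆ permissive holds by construction.
    """
    ids_a, arrs_a = _token_lists(tokens_a)
    ids_b, arrs_b = _token_lists(tokens_b)

    if blocking:
        idx_pairs = candidate_pairs(tokens_a, tokens_b)
    else:
        idx_pairs = [(i, j) for i in range(len(ids_a)) for j in range(len(ids_b))]

    rows = []
    for i, j in idx_pairs:
        raw = token_similarity(arrs_a[i], arrs_b[j], token_weights)
        if raw <= 0.0:
            continue
        rows.append((ids_a[i], ids_b[j], raw))
    scored = pd.DataFrame(rows, columns=["record_id_a", "record_id_b", "raw"])
    scored["score"] = calibration.score(scored["raw"]) if len(scored) else []

    scored = scored.sort_values(
        ["score", "record_id_a", "record_id_b"], ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)

    used_a: set[str] = set()
    used_b: set[str] = set()
    keep = []
    for row in scored.itertuples(index=False):
        if row.record_id_a in used_a or row.record_id_b in used_b:
            continue
        used_a.add(row.record_id_a)
        used_b.add(row.record_id_b)
        keep.append(row)
    assignment = pd.DataFrame(keep, columns=scored.columns)

    match_sets = {}
    for name, cutoff in thresholds.as_dict().items():
        sel = assignment[assignment["score"] >= cutoff]
        match_sets[name] = set(zip(sel["record_id_a"], sel["record_id_b"]))
    if not (match_sets["strict"] <= match_sets["balanced"] <= match_sets["permissive"]):
        raise InvariantError("threshold containment violated")  # pragma: no cover
    return PPRLMatchResult(scored_pairs=scored, assignment=assignment, match_sets=match_sets)
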