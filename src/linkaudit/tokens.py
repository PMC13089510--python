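"""PII normalization and hashed feature-combination tokens.

Each record is reduced to an ordered array of one-way keyed hashes, one per
template in a :class:`TokenSchema`.  A template names an ordered list of
feature extractors (full surname, first initial, soundex of surname, gender,
date of birth, SSN, ...); the token is the HMAC-SHA256 of the canonical
pre-hash string under a run-level shared salt, or null whenever any constituent
feature is missing.  Records from two sites that agree on a feature combination
therefore produce identical tokens without exchanging the underlying values.

Canonical pre-hash string (byte-exact contract, needed for cross-implementation
token equality):  ``template_id + US + feature_1 + US + ... + feature_k`` where
US is the unit separator ``\\x1f``, features are the normalized field values,
and the HMAC key is the UTF-8 salt.
"""

from __future__ import annotations

import datetime
import hashlib
import hmac
import logging
from dataclasses import dataclass, field

import pandas as pd

from ._util import ConfigError
from .engines import soundex

logger = logging.getLogger(__name__)

_US = "\x1f"


class InvalidRecordError(ValueError):
    """Record cannot be normalized (e.g. unparseable date of birth)."""


@dataclass(frozen=True)
class TokenTemplate:
    template_id: str
    features: tuple[str, ...]


@dataclass(frozen=True)
class TokenSchema:
    templates: tuple[TokenTemplate, ...]

    def __post_init__(self) -> None:
        ids = [t.template_id for t in self.templates]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate template_id in schema")
        unknown = {f for t in self.templates for f in t.features} - set(_EXTRACTORS)
        if unknown:
            raise ConfigError(f"unknown feature extractors: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.templates)

    @property
    def template_ids(self) -> list[str]:
        return [t.template_id for t in self.templates]


def _extract_yob(rec: dict) -> str:
    return rec["dob"][-4:] if rec.get("dob") else ""


def _initial(value: str) -> str:
    return value[:1]


_EXTRACTORS = {
    "first_name": lambda r: r.get("first_name", ""),
    "last_name": lambda r: r.get("last_name", ""),
    "first_initial": lambda r: _initial(r.get("first_name", "")),
    "last_initial": lambda r: _initial(r.get("last_name", "")),
    "soundex_first": lambda r: soundex(r["first_name"]) if r.get("first_name") else "",
    "soundex_last": lambda r: soundex(r["last_name"]) if r.get("last_name") else "",
    "gender": lambda r: r.get("gender", ""),
    "dob": lambda r: r.get("dob", ""),
    "yob": _extract_yob,
    "ssn": lambda r: r.get("ssn", ""),
    "phone": lambda r: r.get("phone", ""),
    "email": lambda r: r.get("email", ""),
    "zip": lambda r: r.get("zip", ""),
}

# Default 18-combination schema.  T01 is the canonical surname + first initial
# + gender + DOB combination; the rest mix name, phonetic-name, SSN, contact
# and geographic features following common deterministic-PPRL practice.
DEFAULT_SCHEMA = TokenSchema(tuple(
    TokenTemplate(tid, tuple(feats.split("+")))
    for tid, feats in [
        ("T01", "last_name+first_initial+gender+dob"),
        ("T02", "last_name+first_name+gender+dob"),
        ("T03", "soundex_last+soundex_first+gender+dob"),
        ("T04", "last_name+first_name+dob"),
        ("T05", "last_name+first_name+gender+yob"),
        ("T06", "soundex_last+first_initial+gender+dob"),
        ("T07", "ssn"),
        ("T08", "ssn+dob"),
        ("T09", "ssn+first_initial+last_initial"),
        ("T10", "email"),
        ("T11", "email+dob"),
        ("T12", "phone+dob"),
        ("T13", "phone+last_name"),
        ("T14", "last_name+first_name+zip"),
        ("T15", "last_name+first_name+phone"),
        ("T16", "first_name+gender+dob+zip"),
        ("T17", "last_name+gender+dob+zip"),
        ("T18", "soundex_last+soundex_first+gender+yob+zip"),
    ]
))

_DATE_FORMATS = ("%m/%d/%Y", "%Y-%m-%d", "%m-%d-%Y", "%Y/%m/%d")


def _normalize_dob(raw: str) -> str:
    for fmt in _DATE_FORMATS:
        try:
            return datetime.datetime.strptime(raw, fmt).strftime("%m/%d/%Y")
        except ValueError:
            continue
    raise InvalidRecordError(f"unparseable date of birth: {raw!r}")


def normalize_pii(record: dict) -> dict:
    """Normalize one record's PII fields; idempotent; missing fields stay missing.

    SSN and phone lose hyphens; DOB is rendered mm/dd/yyyy; names and email are
    case-folded and whitespace-trimmed (an extension beyond minimal hyphen/date
    handling, without which exact-hash tokens are needlessly brittle).
    """
    out = dict(record)
    for f in ("first_name", "middle_name", "last_name", "email"):
        if out.get(f):
            out[f] = " ".join(out[f].split()).lower()
    for f in ("ssn", "phone"):
        if out.get(f):
            out[f] = out[f].replace("-", "").strip()
    if out.get("gender"):
        out["gender"] = out["gender"].strip().lower()
    if out.get("zip"):
        out["zip"] = out["zip"].strip()
    if out.get("dob"):
        out["dob"] = _normalize_dob(out["dob"].strip())
    return out


def build_token(record: dict, template: TokenTemplate, salt: str) -> str | None:
    """HMAC-SHA256 token for one normalized record under one template.

    Returns None when any constituent feature is missing.
    """
    if not salt:
        raise ConfigError("salt must be non-empty")
    feats = [_EXTRACTORS[f](record) for f in template.features]
    if any(not f for f in feats):
        return None
    msg = _US.join([template.template_id, *feats])
    return hmac.new(salt.encode("utf-8"), msg.encode("utf-8"), hashlib.sha256).hexdigest()


@dataclass
class TokenizeStats:
    n_records: int = 0
    n_invalid: int = 0
    null_counts: dict = field(default_factory=dict)


def tokenize_registry(
    records: pd.DataFrame, schema: TokenSchema = DEFAULT_SCHEMA, salt: str = ""
) -> tuple[pd.DataFrame, TokenizeStats]:
    """Tokenize every valid record; invalid records are dropped and counted.

    Returns a DataFrame with record_id plus one column per template_id (None
    for null tokens), row order following the input, and summary stats.
    """
    stats = TokenizeStats(null_counts={tid: 0 for tid in schema.template_ids})
    rows = []
    for rec in records.to_dict("records"):
        try:
            norm = normalize_pii(rec)
        except InvalidRecordError:
            stats.n_invalid += 1
            continue
        row: dict = {"record_id": rec["record_id"]}
        for t in schema.templates:
            tok = build_token(norm, t, salt)
            if tok is None:
                stats.null_counts[t.template_id] += 1
            row[t.template_id] = tok
        rows.append(row)
    stats.n_records = len(rows)
    if stats.n_invalid:
        logger.warning("excluded %d records with unparseable fields", stats.n_invalid)
    out = pd.DataFrame(rows, columns=["record_id", *schema.template_ids])
    return out, stats


def write_tokens(tokens: pd.DataFrame, path) -> None:
    tokens.fillna("").to_csv(path, index=False, lineterminator="\n")


def read_tokens(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return df.replace({"": None})
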