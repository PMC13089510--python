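"""Synthetic two-site patient registry generator with ground-truth linkage labels.

Generates an underlying person population shared between two sites, then renders
each site's registry as an independently corrupted view of that population
(typos, nickname substitution, compound-surname variants, stale contact data,
per-field missingness).  The identity confounders that make real-world matching
hard — twins sharing a surname and date of birth, and very common names — are
injected at configurable rates.  A truth ledger of cross-site record-id pairs is
emitted separately from the registry files so downstream matching code never
sees it.
"""

from __future__ import annotations

import dataclasses
import datetime
import string
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import ConfigError, InvariantError

REFERENCE_DATE = datetime.date(2023, 6, 30)
TOP_COMMON_RANK = 100

REGISTRY_COLUMNS = [
    "record_id",
    "first_name",
    "middle_name",
    "last_name",
    "gender",
    "dob",
    "ssn",
    "phone",
    "email",
    "street_address",
    "zip",
]

# Decade age bins (lo, hi, weight); weights follow a plausible adult-skewed
# health-system age mix and are renormalized at sampling time.
DEFAULT_AGE_BINS: tuple[tuple[int, int, float], ...] = (
    (0, 10, 7.1),
    (11, 20, 9.4),
    (21, 30, 12.3),
    (31, 40, 16.4),
    (41, 50, 13.8),
    (51, 60, 12.9),
    (61, 70, 12.8),
    (71, 80, 9.2),
    (81, 90, 4.4),
    (91, 100, 1.3),
    (101, 110, 0.1),
)

NICKNAMES = {
    "robert": "bob",
    "william": "bill",
    "richard": "rick",
    "james": "jim",
    "john": "jack",
    "michael": "mike",
    "christopher": "chris",
    "joseph": "joe",
    "thomas": "tom",
    "charles": "chuck",
    "daniel": "dan",
    "matthew": "matt",
    "anthony": "tony",
    "steven": "steve",
    "andrew": "drew",
    "joshua": "josh",
    "kenneth": "ken",
    "timothy": "tim",
    "edward": "ed",
    "jeffrey": "jeff",
    "elizabeth": "liz",
    "jennifer": "jen",
    "jessica": "jess",
    "margaret": "peggy",
    "katherine": "kate",
    "kimberly": "kim",
    "deborah": "debbie",
    "stephanie": "steph",
    "rebecca": "becky",
    "patricia": "pat",
    "barbara": "barb",
    "susan": "sue",
    "sandra": "sandy",
    "pamela": "pam",
    "christine": "chris",
    "victoria": "vicky",
    "alexander": "alex",
    "benjamin": "ben",
    "nicholas": "nick",
    "samantha": "sam",
}

_STREETS = [
    "Oak St", "Maple Ave", "Cedar Ln", "Elm St", "Pine Rd", "Washington Blvd",
    "Sunset Blvd", "Wilshire Blvd", "Main St", "2nd St", "Highland Ave",
    "Park Ave", "Lake Dr", "Hillcrest Rd", "Valley View Dr", "Canyon Rd",
]
_EMAIL_DOMAINS = ["example.com", "example.org", "mail.example.net", "inbox.example.com"]


def _load_name_list(filename: str) -> list[str]:
    text = resources.files("linkaudit.data").joinpath(filename).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


@dataclass(frozen=True)
class PersonProfile:
    """Ground-truth identity; registry records are corrupted renderings of this."""

    person_id: str
    first_name: str
    middle_name: str
    last_name: str
    gender: str  # "F", "M" or "" (unknown)
    dob: datetime.date
    ssn: str
    phone: str
    email: str
    street_address: str
    zip: str
    is_twin_of: str | None = None
    name_commonness_rank: int | None = None


@dataclass
class SimulationConfig:
    """Parameters of the two-site population and its corruption processes."""

    n_site_a: int = 50_000
    n_site_b: int = 50_000
    overlap_fraction: float = 0.30
    twin_rate: float = 0.004
    common_name_fraction: float = 0.35
    hyphenated_name_fraction: float = 0.06
    # per-site, per-record field missingness
    ssn_missing_rate: float = 0.35
    email_missing_rate: float = 0.25
    phone_missing_rate: float = 0.10
    # per-site, per-record corruption operators
    typo_rate: float = 0.02
    compound_name_variant_rate: float = 0.30  # applies to hyphenated surnames
    nickname_rate: float = 0.03
    middle_name_inclusion_rate: float = 0.70
    stale_contact_rate: float = 0.10
    # marginals
    female_fraction: float = 0.536
    gender_missing_rate: float = 0.005
    age_bins: tuple[tuple[int, int, float], ...] = DEFAULT_AGE_BINS
    seed: int = 0

    _RATE_FIELDS = (
        "overlap_fraction", "twin_rate", "common_name_fraction",
        "hyphenated_name_fraction", "ssn_missing_rate", "email_missing_rate",
        "phone_missing_rate", "typo_rate", "compound_name_variant_rate",
        "nickname_rate", "middle_name_inclusion_rate", "stale_contact_rate",
        "female_fraction", "gender_missing_rate",
    )

    def __post_init__(self) -> None:
        for name in self._RATE_FIELDS:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v!r}")
        if self.n_site_a <= 0 or self.n_site_b <= 0:
            raise ConfigError("site sizes must be positive")
        if self.female_fraction + self.gender_missing_rate > 1.0:
            raise ConfigError("female_fraction + gender_missing_rate exceeds 1")
        if not self.age_bins or any(w < 0 for _, _, w in self.age_bins):
            raise ConfigError("age_bins must be non-empty with non-negative weights")
        if self.n_overlap > min(self.n_site_a, self.n_site_b):
            raise ConfigError("overlap exceeds the smaller site size")

    @property
    def n_overlap(self) -> int:
        return int(round(self.overlap_fraction * self.n_site_b))

    @property
    def n_persons(self) -> int:
        return self.n_site_a + self.n_site_b - self.n_overlap

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_bins"] = [list(b) for b in self.age_bins]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "age_bins" in d:
            d["age_bins"] = tuple(tuple(b) for b in d["age_bins"])
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown simulation config keys: {sorted(extra)}")
        return cls(**d)


def _random_dob(rng: np.random.Generator, bins) -> datetime.date:
    weights = np.array([w for _, _, w in bins], dtype=float)
    weights /= weights.sum()
    lo, hi, _ = bins[rng.choice(len(bins), p=weights)]
    age_days = rng.integers(lo * 365, (hi + 1) * 365)
    return REFERENCE_DATE - datetime.timedelta(days=int(age_days))


def _fresh_contact(rng: np.random.Generator, first: str, last: str):
    phone = "".join(str(d) for d in rng.integers(0, 10, size=10))
    domain = _EMAIL_DOMAINS[rng.integers(0, len(_EMAIL_DOMAINS))]
    email = f"{first.lower()}.{last.lower().replace('-', '')}{rng.integers(1, 1000)}@{domain}"
    street = f"{rng.integers(1, 10000)} {_STREETS[rng.integers(0, len(_STREETS))]}"
    zipcode = f"9{rng.integers(0, 10000):04d}"
    return phone, email, street, zipcode


def generate_population(config: SimulationConfig) -> list[PersonProfile]:
    """Create the shared underlying population (site views come later).

    Persons drawn with probability ``common_name_fraction`` carry both a
    top-100-ranked first name and a top-100-ranked surname; everyone else draws
    from below rank 100, so the realized common-name share is directly testable.
    Twin pairs share surname and date of birth and point at each other through
    ``is_twin_of``.
    """
    first_names = _load_name_list("first_names.txt")
    last_names = _load_name_list("last_names.txt")
    if len(first_names) <= TOP_COMMON_RANK or len(last_names) <= TOP_COMMON_RANK:
        raise ConfigError("packaged name lists must extend beyond rank 100")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n = config.n_persons

    # Zipf-ish weights inside the top-100 block so rank-1 names really are common.
    top_w = 1.0 / np.arange(1, TOP_COMMON_RANK + 1)
    top_w /= top_w.sum()

    used_ssn: set[str] = set()
    persons: list[PersonProfile] = []
    for i in range(n):
        common = rng.random() < config.common_name_fraction
        if common:
            fr = int(rng.choice(TOP_COMMON_RANK, p=top_w)) + 1
            lr = int(rng.choice(TOP_COMMON_RANK, p=top_w)) + 1
        else:
            fr = int(rng.integers(TOP_COMMON_RANK, len(first_names))) + 1
            lr = int(rng.integers(TOP_COMMON_RANK, len(last_names))) + 1
        first = first_names[fr - 1]
        last = last_names[lr - 1]
        if rng.random() < config.hyphenated_name_fraction:
            other = last_names[int(rng.integers(0, len(last_names)))]
            if other != last:
                last = f"{last}-{other}"
        middle = first_names[int(rng.integers(0, len(first_names)))]

        u = rng.random()
        if u < config.gender_missing_rate:
            gender = ""
        elif u < config.gender_missing_rate + config.female_fraction:
            gender = "F"
        else:
            gender = "M"

        dob = _random_dob(rng, config.age_bins)

        while True:
            ssn = f"{rng.integers(100_000_000, 1_000_000_000)}"
            if ssn not in used_ssn:
                used_ssn.add(ssn)
                break
        phone, email, street, zipcode = _fresh_contact(rng, first, last)

        persons.append(PersonProfile(
            person_id=f"P{i:07d}",
            first_name=first,
            middle_name=middle,
            last_name=last,
            gender=gender,
            dob=dob,
            ssn=ssn,
            phone=phone,
            email=email,
            street_address=street,
            zip=zipcode,
            name_commonness_rank=min(fr, lr) if min(fr, lr) <= TOP_COMMON_RANK else None,
        ))

    # Twin pairing: the second member of each pair adopts the first's surname
    # and date of birth.
    n_pairs = int(round(config.twin_rate * n / 2.0))
    if n_pairs > 0:
        idx = rng.choice(n, size=2 * n_pairs, replace=False)
        for a, b in zip(idx[0::2], idx[1::2]):
            pa, pb = persons[a], persons[b]
            persons[b] = dataclasses.replace(
                pb, last_name=pa.last_name, dob=pa.dob, is_twin_of=pa.person_id
            )
            persons[a] = dataclasses.replace(pa, is_twin_of=pb.person_id)
    return persons


def _apply_typo(rng: np.random.Generator, text: str) -> str:
    """One uniformly positioned edit: substitution, transposition or deletion."""
    if not text:
        return text
    op = rng.integers(0, 3)
    pos = int(rng.integers(0, len(text)))
    if op == 0:  # substitution
        repl = string.ascii_lowercase[rng.integers(0, 26)]
        if text[pos].isupper():
            repl = repl.upper()
        return text[:pos] + repl + text[pos + 1:]
    if op == 1 and len(text) >= 2:  # transposition
        pos = min(pos, len(text) - 2)
        return text[:pos] + text[pos + 1] + text[pos] + text[pos + 2:]
    return text[:pos] + text[pos + 1:]  # deletion


@dataclass
class CorruptionStats:
    """Realized per-operator application counts for one rendered site."""

    n_records: int = 0
    typo: int = 0
    nickname: int = 0
    compound_variant: int = 0
    compound_eligible: int = 0
    middle_included: int = 0
    stale_contact: int = 0
    ssn_missing: int = 0
    email_missing: int = 0
    phone_missing: int = 0


def _render_site(persons, site: str, config: SimulationConfig,
                 rng: np.random.Generator) -> tuple[pd.DataFrame, CorruptionStats]:
    rows = []
    stats = CorruptionStats(n_records=len(persons))
    for i, p in enumerate(persons):
        first, last = p.first_name, p.last_name

        if rng.random() < config.nickname_rate:
            stats.nickname += 1
            first = NICKNAMES.get(first.lower(), first[:3].lower()).capitalize()
        if "-" in last:
            stats.compound_eligible += 1
            if rng.random() < config.compound_name_variant_rate:
                stats.compound_variant += 1
                parts = last.split("-")
                last = parts[int(rng.integers(0, len(parts)))]
        if rng.random() < config.typo_rate:
            stats.typo += 1
            if rng.random() < 0.5:
                first = _apply_typo(rng, first)
            else:
                last = _apply_typo(rng, last)

        middle = ""
        if rng.random() < config.middle_name_inclusion_rate:
            stats.middle_included += 1
            middle = p.middle_name

        phone, email, street, zipcode = p.phone, p.email, p.street_address, p.zip
        if rng.random() < config.stale_contact_rate:
            stats.stale_contact += 1
            phone, email, street, zipcode = _fresh_contact(rng, p.first_name, p.last_name)

        ssn = p.ssn
        if rng.random() < config.ssn_missing_rate:
            stats.ssn_missing += 1
            ssn = ""
        if rng.random() < config.email_missing_rate:
            stats.email_missing += 1
            email = ""
        if rng.random() < config.phone_missing_rate:
            stats.phone_missing += 1
            phone = ""

        rows.append({
            "record_id": f"{site}{i:07d}",
            "first_name": first,
            "middle_name": middle,
            "last_name": last,
            "gender": p.gender,
            "dob": p.dob.strftime("%m/%d/%Y"),
            "ssn": ssn,
            "phone": phone,
            "email": email,
            "street_address": street,
            "zip": zipcode,
        })
    return pd.DataFrame(rows, columns=REGISTRY_COLUMNS), stats


def render_registries(
    population: list[PersonProfile], config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, CorruptionStats]]:
    """Render both site registries plus the truth ledger.

    Returns (records_a, records_b, truth, stats) where truth has columns
    record_id_site_a / record_id_site_b and stats maps site label to realized
    corruption counts.  Site A takes the first ``n_site_a`` persons, site B the
    last ``n_site_b``; the overlap is the middle slice, giving exactly
    ``n_overlap`` truth pairs.
    """
    if len(population) != config.n_persons:
        raise ConfigError("population size does not match config")
    n_a, n_b, k = config.n_site_a, config.n_site_b, config.n_overlap
    site_a_persons = population[:n_a]
    site_b_persons = population[n_a - k:]
    if len(site_b_persons) != n_b:
        raise InvariantError("site-B slice has wrong size")

    ss = np.random.SeedSequence([config.seed, 1])
    rng_a, rng_b = (np.random.default_rng(s) for s in ss.spawn(2))
    df_a, stats_a = _render_site(site_a_persons, "A", config, rng_a)
    df_b, stats_b = _render_site(site_b_persons, "B", config, rng_b)

    pairs = [
        {"record_id_site_a": f"A{n_a - k + j:07d}", "record_id_site_b": f"B{j:07d}"}
        for j in range(k)
    ]
    truth = pd.DataFrame(pairs, columns=["record_id_site_a", "record_id_site_b"])
    return df_a, df_b, truth, {"A": stats_a, "B": stats_b}


def person_index(population: list[PersonProfile], config: SimulationConfig) -> dict[str, str]:
    """Map record_id -> person_id for both sites (the non-public identity ledger)."""
    n_a, k = config.n_site_a, config.n_overlap
    out: dict[str, str] = {}
    for i, p in enumerate(population[:n_a]):
        out[f"A{i:07d}"] = p.person_id
    for j, p in enumerate(population[n_a - k:]):
        out[f"B{j:07d}"] = p.person_id
    return out


def write_registry(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def read_registry(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"registry file {path} lacks columns {missing}")
    return df[REGISTRY_COLUMNS]


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, index=False, lineterminator="\n")


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def check_truth_consistency(truth: pd.DataFrame, record_to_person: dict[str, str]) -> None:
    """Every truth pair links one A record and one B record of the same person."""
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    for a, b in truth.itertuples(index=False):
        if not a.startswith("A") or not b.startswith("B"):
            raise InvariantError(f"truth pair ({a}, {b}) does not cross sites")
        if record_to_person[a] != record_to_person[b]:
            raise InvariantError(f"truth pair ({a}, {b}) links different persons")
        if a in seen_a or b in seen_b:
            raise InvariantError(f"record appears in more than one truth pair: ({a}, {b})")
        seen_a.add(a)
        seen_b.add(b)
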