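"""Registry-based temporal phenotyping of gestational diabetes.

Each delivery anchors a *pregnancy window* from 280 days (40 weeks) before
delivery to 35 days (5 weeks) after, both ends inclusive. A pregnancy
meets inclusion criteria when (I1) a gestational-diabetes code, or (I2)
any diabetes code, occurs inside the window, or (I3) an abnormal
blood-glucose marker from the birth registry is attached to the pregnancy.
A pregnancy is excluded when, strictly before its window starts, the
person has (E1) any diabetes code occurring outside every one of her
pregnancy windows, (E2) significant pancreatic disease (chronic
pancreatitis, pancreatic necrosis, pancreatic cancer, cystic fibrosis) or
(E3) any type 1 or type 2 diabetes code. Pregnancies passing exclusion
without inclusion are 'unaffected'.

At the person level, a case has at least one GDM pregnancy; a control has
only unaffected pregnancies; anyone else with a delivery is excluded.
Nulliparous individuals are outside the cohort.

Diagnosis-code lists are configuration, not algorithm: the shipped
defaults are ICD-10/9/8-style prefix patterns and can be replaced from
YAML to match any registry's exact endpoint definitions.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "CodeSetConfig",
    "EventRecord",
    "PregnancyRecord",
    "PersonStatus",
    "build_windows",
    "classify_pregnancy",
    "classify_person",
    "classify_cohort",
    "cohort_summary",
]

#: gestation (40 weeks) before delivery and 5 weeks after, in days
DAYS_BEFORE_DELIVERY = 280
DAYS_AFTER_DELIVERY = 35

#: vocabularies whose codes are matched against ICD-style prefix patterns
ICD_VOCABULARIES = {"ICD-10", "ICD-9", "ICD-8"}
REGISTRY_VOCABULARY = "REGISTRY"


def _norm(code: str) -> str:
    return str(code).replace(".", "").upper()


@dataclass(frozen=True)
class CodeSetConfig:
    """Named diagnosis-code prefix lists driving the phenotyping rules.

    Patterns are matched as prefixes of dot-stripped, upper-cased codes
    (so ``O24.4`` matches pattern ``O244``). The defaults are documented
    placeholders covering common ICD-10/9/8 conventions; registry-exact
    lists should be supplied via :meth:`from_yaml`.
    """

    gdm_codes: tuple = ("O244", "6488")
    t1d_t2d_codes: tuple = ("E10", "E11", "2500", "2501", "2502")
    any_diabetes_codes: tuple = ("O24", "E10", "E11", "E12", "E13", "E14",
                                 "250", "6488")
    pancreatic_codes: tuple = ("K860", "K861", "K868", "C25", "E84", "5771",
                               "5772", "2770")
    abnormal_glucose_codes: tuple = ("ABN_GLUC",)

    def __post_init__(self):
        for attr in ("gdm_codes", "t1d_t2d_codes", "any_diabetes_codes",
                     "pancreatic_codes", "abnormal_glucose_codes"):
            object.__setattr__(self, attr,
                               tuple(_norm(c) for c in getattr(self, attr)))
        # a GDM code must always count as a diabetes code
        for g in self.gdm_codes:
            if not any(g.startswith(d) for d in self.any_diabetes_codes):
                raise ValueError(
                    f"gdm code pattern {g!r} is not covered by "
                    "any_diabetes_codes")

    @classmethod
    def from_yaml(cls, path) -> "CodeSetConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**{k: tuple(v) for k, v in raw.items()})

    def matches(self, code: str, patterns: tuple) -> bool:
        c = _norm(code)
        return any(c.startswith(p) for p in patterns)


@dataclass(frozen=True)
class EventRecord:
    """One dated diagnosis or registry event for a person."""

    person_id: str
    date: dt.date
    vocabulary: str
    code: str


@dataclass
class PregnancyRecord:
    """A delivery-anchored window with its rule-derived status."""

    person_id: str
    delivery_date: dt.date
    window_start: dt.date = field(init=False)
    window_end: dt.date = field(init=False)
    status: str = "PENDING"
    reasons: frozenset = frozenset()

    def __post_init__(self):
        self.window_start = self.delivery_date - dt.timedelta(
            days=DAYS_BEFORE_DELIVERY)
        self.window_end = self.delivery_date + dt.timedelta(
            days=DAYS_AFTER_DELIVERY)


@dataclass(frozen=True)
class PersonStatus:
    """Person-level case/control assignment."""

    person_id: str
    status: str
    n_pregnancies: int
    n_gdm_pregnancies: int


def _as_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return pd.Timestamp(value).date()


def build_windows(deliveries) -> list[PregnancyRecord]:
    """Turn (person_id, delivery_date) records into pending pregnancy windows.

    Accepts an iterable of tuples or a DataFrame with columns
    ``person_id, delivery_date``. Duplicate (person, date) deliveries are
    dropped with a warning; windows are sorted by delivery date within
    each person.
    """
    if isinstance(deliveries, pd.DataFrame):
        rows = [(str(r.person_id), _as_date(r.delivery_date))
                for r in deliveries.itertuples(index=False)]
    else:
        rows = [(str(p), _as_date(d)) for p, d in deliveries]
    seen, unique = set(), []
    for row in rows:
        if row in seen:
            logger.warning("build_windows: duplicate delivery %s dropped",
                           row)
            continue
        seen.add(row)
        unique.append(row)
    unique.sort(key=lambda r: (r[0], r[1]))
    return [PregnancyRecord(person_id=p, delivery_date=d) for p, d in unique]


def _in_window(date, rec: PregnancyRecord) -> bool:
    return rec.window_start <= date <= rec.window_end


def classify_pregnancy(record: PregnancyRecord, events: list[EventRecord],
                       codes: CodeSetConfig,
                       all_windows: "list[PregnancyRecord] | None" = None,
                       ) -> PregnancyRecord:
    """Apply inclusion rules I1-I3 and exclusion rules E1-E3 to one pregnancy.

    Parameters
    ----------
    record : PregnancyRecord
        The index pregnancy (status pending).
    events : list of EventRecord
        All events for the same person, any order.
    codes : CodeSetConfig
    all_windows : list of PregnancyRecord, optional
        Every pregnancy window of the person, needed for E1's
        "outside a pregnancy window" clause; defaults to the index
        pregnancy only.

    Returns
    -------
    PregnancyRecord
        With ``status`` set to GDM / UNAFFECTED / EXCLUDED and
        ``reasons`` holding the triggered rule identifiers.
    """
    if any(e.person_id != record.person_id for e in events):
        raise ValueError("events must belong to the pregnancy's person")
    windows = all_windows if all_windows else [record]
    reasons = set()
    n_unknown_vocab = 0
    for ev in events:
        date = _as_date(ev.date)
        if ev.vocabulary in ICD_VOCABULARIES:
            is_diabetes = codes.matches(ev.code, codes.any_diabetes_codes)
            if _in_window(date, record):
                if codes.matches(ev.code, codes.gdm_codes):
                    reasons.add("I1")
                if is_diabetes:
                    reasons.add("I2")
            if date < record.window_start:
                if is_diabetes and not any(_in_window(date, w)
                                           for w in windows):
                    reasons.add("E1")
                if codes.matches(ev.code, codes.pancreatic_codes):
                    reasons.add("E2")
                if codes.matches(ev.code, codes.t1d_t2d_codes):
                    reasons.add("E3")
        elif ev.vocabulary == REGISTRY_VOCABULARY:
            if (codes.matches(ev.code, codes.abnormal_glucose_codes)
                    and date == record.delivery_date):
                reasons.add("I3")
        else:
            n_unknown_vocab += 1
    if n_unknown_vocab:
        logger.info("classify_pregnancy: ignored %d event(s) with unknown "
                    "vocabulary", n_unknown_vocab)

    if reasons & {"E1", "E2", "E3"}:
        status = "EXCLUDED"
    elif reasons & {"I1", "I2", "I3"}:
        status = "GDM"
    else:
        status = "UNAFFECTED"
    record.status = status
    record.reasons = frozenset(reasons)
    return record


def classify_person(pregnancies: list[PregnancyRecord]) -> PersonStatus:
    """Assign CASE / CONTROL / EXCLUDED from classified pregnancies.

    A case has >= 1 GDM pregnancy; a control only unaffected ones;
    otherwise the person is excluded. An empty list raises (nulliparous
    individuals are out of cohort).
    """
    if not pregnancies:
        raise ValueError("person has no pregnancies (out of cohort)")
    person_id = pregnancies[0].person_id
    statuses = [p.status for p in pregnancies]
    if "PENDING" in statuses:
        raise ValueError("all pregnancies must be classified first")
    n_gdm = statuses.count("GDM")
    if n_gdm:
        status = "CASE"
    elif all(s == "UNAFFECTED" for s in statuses):
        status = "CONTROL"
    else:
        status = "EXCLUDED"
    return PersonStatus(person_id=person_id, status=status,
                        n_pregnancies=len(pregnancies),
                        n_gdm_pregnancies=n_gdm)


def classify_cohort(deliveries, events, codes: CodeSetConfig | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full pipeline: windows, pregnancy rules, person status.

    Parameters
    ----------
    deliveries : DataFrame or iterable of (person_id, delivery_date)
    events : DataFrame with columns person_id, date, vocabulary, code,
        or iterable of EventRecord.
    codes : CodeSetConfig, optional

    Returns
    -------
    (pregnancies, persons) : tuple of DataFrame
        Per-pregnancy statuses with reason codes, and per-person statuses.
    """
    codes = codes or CodeSetConfig()
    windows = build_windows(deliveries)
    if isinstance(events, pd.DataFrame):
        events = [EventRecord(str(r.person_id), _as_date(r.date),
                              str(r.vocabulary), str(r.code))
                  for r in events.itertuples(index=False)]
    by_person_events: dict[str, list] = {}
    for ev in events:
        by_person_events.setdefault(ev.person_id, []).append(ev)
    by_person_windows: dict[str, list] = {}
    for w in windows:
        by_person_windows.setdefault(w.person_id, []).append(w)

    preg_rows, person_rows = [], []
    for pid, pw in by_person_windows.items():
        pev = by_person_events.get(pid, [])
        for rec in pw:
            classify_pregnancy(rec, pev, codes, all_windows=pw)
            preg_rows.append((pid, rec.delivery_date.isoformat(),
                              rec.window_start.isoformat(),
                              rec.window_end.isoformat(), rec.status,
                              ",".join(sorted(rec.reasons))))
        ps = classify_person(pw)
        person_rows.append((pid, ps.status, ps.n_pregnancies,
                            ps.n_gdm_pregnancies))
    pregnancies = pd.DataFrame(
        preg_rows, columns=["person_id", "delivery_date", "window_start",
                            "window_end", "status", "reasons"])
    persons = pd.DataFrame(
        person_rows, columns=["person_id", "status", "n_pregnancies",
                              "n_gdm_pregnancies"])
    return pregnancies, persons


def cohort_summary(persons) -> dict:
    """Tabulate person-level statuses into {status: count} (zeros included)."""
    counts = {"CASE": 0, "CONTROL": 0, "EXCLUDED": 0}
    if isinstance(persons, pd.DataFrame):
        statuses = persons["status"].tolist()
    else:
        statuses = [p.status for p in persons]
    for s in statuses:
        if s not in counts:
            raise ValueError(f"unknown person status {s!r}")
        counts[s] += 1
    return counts
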