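"""Reading, filtering and time-slicing of coded encounter records.

Raw input is event-level: one row per (patient, date, ICD-10 code).  The
progression model consumes *time slices*: all of a patient's codes within a
fixed window (default one year) collapsed to a binary set, with slice index
measured in whole windows from the patient's first retained event.  Codes
are opaque strings; no ontology rollup is performed.

Two preprocessing rules shape the model-ready data:

* codes with fewer than ``min_count`` total occurrences across the whole
  event stream are dropped before anything else;
* patients contributing fewer than two non-empty slices are excluded,
  because the temporal layers of the model need at least one interval.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

#: Length of the unit slicing window in days (one Julian year).
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class RawEvent:
    """One coded event: a patient received one ICD-10 code on one date."""

    patient_id: str
    event_date: _dt.date
    code: str

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("RawEvent.code must be non-empty")


class FindingVocabulary:
    """Ordered set of retained ICD-10 codes; position is the model index."""

    def __init__(self, codes) -> None:
        codes = tuple(str(c) for c in codes)
        if len(set(codes)) != len(codes):
            dupes = [c for c, k in Counter(codes).items() if k > 1]
            raise ValueError(f"duplicate codes in vocabulary: {dupes}")
        self.codes = codes
        self.index = {c: i for i, c in enumerate(codes)}

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, code: str) -> bool:
        return code in self.index

    def __getitem__(self, i: int) -> str:
        return self.codes[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, FindingVocabulary) and self.codes == other.codes

    def encode(self, code: str) -> int:
        return self.index[code]

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for code in self.codes:
                fh.write(code + "\n")

    @classmethod
    def from_file(cls, path) -> "FindingVocabulary":
        with open(path, encoding="utf-8") as fh:
            return cls([line.strip() for line in fh if line.strip()])

    def __repr__(self) -> str:
        return f"FindingVocabulary(n={len(self)})"


@dataclass(frozen=True)
class PatientHistory:
    """Time-sliced observations for one patient.

    ``slices`` is an ordered tuple of ``(year_index, findings)`` pairs where
    ``year_index`` counts whole windows since the patient's first retained
    event (so the first slice of ingested data is always index 0) and
    ``findings`` is a frozenset of vocabulary indices.  Slices built from raw
    events are non-empty by construction, but an empty findings set is a
    legal, informative observation (an encounter at which nothing was coded
    positive) and is produced by the simulator.
    """

    patient_id: str
    slices: tuple

    def __post_init__(self) -> None:
        years = [y for y, _ in self.slices]
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError(f"{self.patient_id}: year_index must be strictly increasing")
        if years and years[0] < 0:
            raise ValueError(f"{self.patient_id}: negative year_index")

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def years(self):
        return tuple(y for y, _ in self.slices)

    @property
    def finding_sets(self):
        return tuple(f for _, f in self.slices)


def filter_codes(events, min_count: int):
    """Drop codes occurring fewer than ``min_count`` times overall.

    Occurrences are counted per event row across all patients, before any
    patient-level exclusion.  Returns the lexicographically ordered
    vocabulary of retained codes and the retained events.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts = Counter(e.code for e in events)
    kept_codes = sorted(c for c, k in counts.items() if k >= min_count)
    vocabulary = FindingVocabulary(kept_codes)
    kept = [e for e in events if e.code in vocabulary]
    logger.info(
        "filter_codes: %d/%d codes retained (min_count=%d), %d/%d events kept",
        len(kept_codes), len(counts), min_count, len(kept), len(events),
    )
    return vocabulary, kept


def build_time_slices(events, vocabulary: FindingVocabulary, granularity_years: float = 1.0):
    """Aggregate code-filtered events into per-patient yearly slices.

    Events are binned by ``floor(days_since_first_event / window)`` with the
    window anchored at each patient's first retained event, so slicing is
    invariant to shifting a patient's dates by a constant.  Patients with
    fewer than two slices are excluded.
    """
    if granularity_years <= 0:
        raise ValueError("granularity_years must be > 0")
    window_days = granularity_years * DAYS_PER_YEAR
    by_patient = defaultdict(list)
    for e in events:
        if e.code not in vocabulary:
            raise ValueError(f"event code {e.code!r} not in vocabulary; filter first")
        by_patient[e.patient_id].append(e)

    histories = []
    for pid in sorted(by_patient):
        pevents = by_patient[pid]
        first = min(e.event_date for e in pevents)
        bins = defaultdict(set)
        for e in pevents:
            b = math.floor((e.event_date - first).days / window_days)
            bins[b].add(vocabulary.encode(e.code))
        if len(bins) < 2:
            continue
        slices = tuple((b, frozenset(bins[b])) for b in sorted(bins))
        histories.append(PatientHistory(pid, slices))
    return histories


def encounter_stats(histories):
    """Total encounter (slice) count and total positive observations."""
    n_encounters = sum(h.n_slices for h in histories)
    n_positive = sum(len(f) for h in histories for f in h.finding_sets)
    return n_encounters, n_positive


# ---------------------------------------------------------------------------
# I/O

def read_events(path) -> list:
    """Read events from a CSV with columns patient_id,event_date,icd10.

    Dates must be ISO-8601; rows with unparseable dates or empty codes are
    dropped with a logged warning rather than aborting the ingest.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "icd10": str})
    missing = {"patient_id", "event_date", "icd10"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return _events_from_frame(df, str(path))


def read_events_jsonl(path) -> list:
    """Read events from line-delimited JSON records with the same fields."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                rows.append(json.loads(line))
    df = pd.DataFrame(rows, columns=["patient_id", "event_date", "icd10"])
    return _events_from_frame(df, str(path))


def _events_from_frame(df: pd.DataFrame, source: str) -> list:
    dates = pd.to_datetime(df["event_date"], format="ISO8601", errors="coerce")
    bad_date = dates.isna()
    bad_code = df["icd10"].isna() | (df["icd10"].astype(str).str.len() == 0)
    n_bad = int((bad_date | bad_code).sum())
    if n_bad:
        logger.warning("%s: dropped %d rows with unparseable dates or empty codes",
                       source, n_bad)
    keep = ~(bad_date | bad_code)
    return [
        RawEvent(str(p), d.date(), str(c))
        for p, d, c in zip(df.loc[keep, "patient_id"], dates[keep], df.loc[keep, "icd10"])
    ]


def write_histories_jsonl(histories, vocabulary: FindingVocabulary, path) -> None:
    """Write histories as line-delimited JSON, with codes spelled out."""
    with open(path, "w", encoding="utf-8") as fh:
        for h in histories:
            rec = {
                "patient_id": h.patient_id,
                "slices": [[y, sorted(vocabulary[i] for i in f)] for y, f in h.slices],
            }
            fh.write(json.dumps(rec) + "\n")


def read_histories_jsonl(path, vocabulary: FindingVocabulary):
    histories = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            slices = tuple(
                (int(y), frozenset(vocabulary.encode(c) for c in codes))
                for y, codes in rec["slices"]
            )
            histories.append(PatientHistory(str(rec["patient_id"]), slices))
    return histories
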