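"""Synthetic-patient generation and ground-truth fixture models.

A synthetic patient starts at time 0 in stage I.  The continuous-time stage
process is sampled exactly: exponential holding times with rate ``|Q_kk|``
and next stage proportional to ``Q_kj``.  Observation happens at yearly
encounters (matching the one-year slice granularity of ingested data): at
year 0 complications are present with the stage-I initial-onset
probabilities, at each later year an inactive complication activates with
the per-year hazard of the stage occupied at that encounter, and the
finding set is drawn from the noisy-or given the active complications.
Encounters with no positive finding are emitted (they are informative
observations), and conversion helpers drop them when exporting to the raw
event format, which only carries positive codes.

Generation stops one residence year after entering the last stage, or at
the horizon for patients truncated earlier.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import FindingVocabulary, PatientHistory
from .model import AnchorSet, ProgressionModel, make_connectivity_mask, noisy_or_probs


@dataclass(frozen=True)
class SyntheticPatient:
    """One generated trajectory with its latent ground truth.

    ``stage_entry_years`` holds the continuous entry time of each visited
    stage (starting at 0.0 for stage I); ``onset_years`` maps an activated
    complication to the integer encounter year at which it first appears;
    ``encounters`` are yearly ``(year, findings)`` slices.
    """

    patient_id: str
    stage_entry_years: tuple
    onset_years: dict
    encounters: tuple
    reached_last_stage: bool
    n_stages: int
    n_complications: int

    def stage_at(self, year: float) -> int:
        """Stage occupied at a (continuous) time."""
        s = 0
        for i, e in enumerate(self.stage_entry_years):
            if year >= e:
                s = i
        return s

    def stage_exit(self, s: int) -> float:
        """Exit time of stage s, +inf if never left within observation."""
        if s + 1 < len(self.stage_entry_years):
            return self.stage_entry_years[s + 1]
        return float("inf")

    def occupies(self, s: int) -> bool:
        return s < len(self.stage_entry_years)

    def active_during(self, w: int, s: int) -> bool:
        """Was complication w active at any time while the patient was in stage s?"""
        if not self.occupies(s):
            return False
        y = self.onset_years.get(w)
        return y is not None and y < self.stage_exit(s)


def generate_patient(model: ProgressionModel, rng, horizon_years: float = 60.0,
                     residence_years: float = 1.0, observation_years: float | None = None,
                     entry_delay_years: float = 0.0,
                     patient_id: str = "p0") -> SyntheticPatient:
    """Sample one full trajectory; see the module docstring for the scheme.

    By default observation ends one residence year after entry to the last
    stage (the stopping time depends on the latent path).  Passing
    ``observation_years`` instead emits encounters over a fixed follow-up
    window regardless of progression, the way a registry with a fixed study
    window does; this keeps the censoring exogenous, which matters when the
    cohort is used for likelihood-based parameter recovery.

    ``entry_delay_years`` left-censors the record: the latent trajectory
    still starts at year 0 in stage I, but encounters before the delay are
    not emitted, mimicking patients who enter a registry mid-course.
    """
    if horizon_years <= 0:
        raise ValueError("horizon_years must be > 0")
    if entry_delay_years < 0:
        raise ValueError("entry_delay_years must be >= 0")
    K, W = model.K, model.W
    entries = [0.0]
    t, k = 0.0, 0
    while k < K - 1:
        rate = -model.Q[k, k]
        if rate <= 0:  # dead-end stage before the last: truncate at horizon
            break
        t = t + rng.exponential(1.0 / rate)
        if t >= horizon_years:
            break
        probs = model.Q[k, k + 1:] / rate
        k = k + 1 + int(rng.choice(K - 1 - k, p=probs))
        entries.append(t)
    reached = k == K - 1
    if observation_years is not None:
        end_time = min(observation_years, horizon_years)
    elif reached:
        end_time = min(entries[-1] + residence_years, horizon_years)
    else:
        end_time = horizon_years

    active = np.zeros(W, dtype=bool)
    onset_years = {}
    encounters = []
    first_observed = int(np.ceil(entry_delay_years))
    for year in range(int(np.floor(end_time)) + 1):
        s = 0
        for i, e in enumerate(entries):
            if year >= e:
                s = i
        if year == 0:
            newly = rng.random(W) < model.pi_onset[s]
        else:
            newly = (~active) & (rng.random(W) < model.h_onset[s])
        for w in np.flatnonzero(newly & ~active):
            onset_years[int(w)] = year
        active |= newly
        p = noisy_or_probs(active, model)
        findings = frozenset(int(n) for n in np.flatnonzero(rng.random(model.N) < p))
        if year >= first_observed:  # latent process runs from year 0 regardless
            encounters.append((year, findings))
    return SyntheticPatient(
        patient_id=patient_id,
        stage_entry_years=tuple(entries),
        onset_years=onset_years,
        encounters=tuple(encounters),
        reached_last_stage=reached,
        n_stages=K,
        n_complications=W,
    )


def generate_cohort(model: ProgressionModel, n_patients: int, seed: int,
                    horizon_years: float = 60.0, residence_years: float = 1.0,
                    observation_years: float | None = None,
                    max_entry_delay_years: float = 0.0):
    """n independent patients from one seeded stream; fully reproducible.

    ``max_entry_delay_years > 0`` draws a uniform per-patient entry delay,
    left-censoring the records the way a fixed-window registry truncates
    long disease courses.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    width = len(str(n_patients - 1))
    out = []
    for i in range(n_patients):
        delay = rng.uniform(0.0, max_entry_delay_years) if max_entry_delay_years > 0 else 0.0
        out.append(generate_patient(model, rng, horizon_years, residence_years,
                                    observation_years, entry_delay_years=delay,
                                    patient_id=f"s{i:0{width}d}"))
    return out


# ---------------------------------------------------------------------------
# Fixture models

_FIXTURE_CODES = ("C00", "C01", "C02", "C03", "C04", "C05")


def make_fixture_model(K: int = 3, W: int = 2, N: int = 6,
                       seed: int | None = None) -> ProgressionModel:
    """A small ground-truth model for recovery and oracle tests.

    With the default dimensions and ``seed=None`` the parameters are fixed,
    chosen to emulate the shape of sparse coded encounter data: roughly two
    positive codes per encounter once complications are active, yearly
    slices, forward-only stages with multi-year holding times, and one
    anchored code per complication.  With a seed, parameters are drawn from
    wide but valid ranges (used to randomize oracle comparisons).
    """
    codes = tuple(f"C{n:02d}" for n in range(N))
    vocabulary = FindingVocabulary(codes)
    n_anchored = min(W, N // 2)
    anchors = AnchorSet({w: (codes[w],) for w in range(n_anchored)})
    mask = make_connectivity_mask(anchors, vocabulary, W)

    if seed is None:
        if (K, W, N) != (3, 2, 6):
            raise ValueError("the canonical fixture is defined for K=3, W=2, N=6; "
                             "pass a seed for other dimensions")
        Q = np.array([[-0.35, 0.35, 0.0],
                      [0.0, -0.30, 0.30],
                      [0.0, 0.0, 0.0]])
        pi = np.array([[0.15, 0.10],
                       [0.40, 0.30],
                       [0.60, 0.50]])
        h = np.array([[0.12, 0.08],
                      [0.30, 0.22],
                      [0.45, 0.35]])
        A = np.array([[0.85, 0.00, 0.45, 0.35, 0.25, 0.15],
                      [0.00, 0.75, 0.30, 0.20, 0.35, 0.25]])
        leak = np.full(N, 0.04)
    else:
        rng = np.random.default_rng(seed)
        Q = np.zeros((K, K))
        for i in range(K - 1):
            Q[i, i + 1] = rng.uniform(0.2, 0.7)
            Q[i, i + 2:] = rng.uniform(0.0, 0.08, size=max(K - 2 - i, 0))
            Q[i, i] = -Q[i].sum()
        pi = rng.uniform(0.05, 0.4, size=(K, W))
        h = rng.uniform(0.05, 0.5, size=(K, W))
        A = rng.uniform(0.1, 0.6, size=(W, N))
        for w in range(n_anchored):
            A[w, w] = rng.uniform(0.6, 0.9)
        leak = rng.uniform(0.02, 0.2, size=N)
    A = np.where(mask.allowed, A, 0.0)
    model = ProgressionModel(K=K, W=W, N=N, Q=Q, pi_onset=pi, h_onset=h, A=A,
                             leak=leak, mask=mask, codes=codes, anchor_set=anchors)
    violations = model.validate()
    if violations:
        raise RuntimeError(f"fixture model invalid: {violations}")
    return model


# ---------------------------------------------------------------------------
# Conversions and I/O

def cohort_to_histories(cohort, drop_empty: bool = False, min_slices: int = 0):
    """Turn generated encounters into PatientHistory objects for fitting.

    By default empty encounters are kept (an all-negative observation is
    informative).  ``drop_empty=True`` mimics real ingested data, where a
    year with no coded event leaves no slice.
    """
    out = []
    for p in cohort:
        slices = tuple((y, f) for y, f in p.encounters if f or not drop_empty)
        if len(slices) < max(min_slices, 2):
            continue
        first = slices[0][0]
        slices = tuple((y - first, f) for y, f in slices)
        out.append(PatientHistory(p.patient_id, slices))
    return out


def cohort_to_events(cohort, vocabulary: FindingVocabulary,
                     start_date: _dt.date = _dt.date(2000, 1, 1)) -> pd.DataFrame:
    """Export encounters as raw event rows (positive codes only).

    Encounter years are spaced 366 days apart so that whole-year offsets
    stay in distinct floor-binned slices when re-ingested (valid for
    trajectories up to ~487 years).
    """
    rows = []
    for p in cohort:
        for year, findings in p.encounters:
            d = start_date + _dt.timedelta(days=366 * year)
            for n in sorted(findings):
                rows.append((p.patient_id, d.isoformat(), vocabulary[n]))
    return pd.DataFrame(rows, columns=["patient_id", "event_date", "icd10"])


def write_cohort_jsonl(cohort, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in cohort:
            rec = {
                "patient_id": p.patient_id,
                "stage_entry_years": list(p.stage_entry_years),
                "onset_years": {str(w): y for w, y in p.onset_years.items()},
                "encounters": [[y, sorted(f)] for y, f in p.encounters],
                "reached_last_stage": p.reached_last_stage,
                "n_stages": p.n_stages,
                "n_complications": p.n_complications,
            }
            fh.write(json.dumps(rec) + "\n")


def read_cohort_jsonl(path):
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            r = json.loads(line)
            out.append(SyntheticPatient(
                patient_id=str(r["patient_id"]),
                stage_entry_years=tuple(r["stage_entry_years"]),
                onset_years={int(w): y for w, y in r["onset_years"].items()},
                encounters=tuple((int(y), frozenset(f)) for y, f in r["encounters"]),
                reached_last_stage=bool(r["reached_last_stage"]),
                n_stages=int(r["n_stages"]),
                n_complications=int(r["n_complications"]),
            ))
    return out
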