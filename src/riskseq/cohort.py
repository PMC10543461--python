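"""Case/control cohort construction with encounter-level augmentation.

A *case* sample is (patient, index date) such that the patient's first
new-onset adverse event falls inside the prediction window
``(index, index + window]``; a *control* sample is an encounter after the
first qualifying diagnosis with no adverse-event record in that window.
Case patients contribute one sample per eligible encounter between the
first qualifying diagnosis and the onset (data augmentation); control
samples are drawn uniformly without replacement to match
``round(control_sampling_ratio * n_case_samples)``.

A patient who already had an adverse-event type before (or at) the first
qualifying diagnosis remains eligible for *new other types*; the
pre-existing type's records stay in the history as ordinary features.

Splitting into train/validation/test is by patient (all samples of one
patient land in one fold) so that augmented near-duplicate sequences never
leak across folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import EventRecord

__all__ = [
    "CohortConfig",
    "CohortSample",
    "OnsetMap",
    "EmptyCohortError",
    "find_onsets",
    "build_samples",
    "split",
    "write_manifest",
]

logger = logging.getLogger(__name__)


class EmptyCohortError(ValueError):
    """No eligible case sample could be constructed."""


@dataclass
class CohortConfig:
    qualifying_codes: frozenset[str] = frozenset({"DX_QUALIFYING"})
    adverse_event_codes: frozenset[str] = frozenset({"AE_PRIMARY", "AE_SECONDARY"})
    prediction_window_days: int = 90
    control_sampling_ratio: float = 1.0
    split_ratios: tuple[float, float, float] = (8.0, 1.0, 1.0)
    allow_case_patients_as_controls: bool = False
    seed: int = 0

    def __post_init__(self):
        self.qualifying_codes = frozenset(self.qualifying_codes)
        self.adverse_event_codes = frozenset(self.adverse_event_codes)
        if self.prediction_window_days <= 0:
            raise ValueError("prediction_window_days must be > 0")
        if self.control_sampling_ratio <= 0:
            raise ValueError("control_sampling_ratio must be > 0")
        if any(r <= 0 for r in self.split_ratios):
            raise ValueError("split_ratios must be positive")
        total = sum(self.split_ratios)
        self.split_ratios = tuple(r / total for r in self.split_ratios)


@dataclass
class OnsetMap:
    """Per-patient qualification and first new-onset adverse events."""

    qualifying_date: dict[str, int]
    # patient -> [(event code, first-occurrence day)] for NEW onsets only,
    # in date order
    onsets: dict[str, list[tuple[str, int]]]
    excluded_patients: list[str] = field(default_factory=list)


@dataclass
class CohortSample:
    patient_id: str
    index_date: int
    label: int  # 1 = case, 0 = control
    history: list[EventRecord]
    target_event_code: str | None = None


def find_onsets(events: list[EventRecord], config: CohortConfig) -> OnsetMap:
    """Locate each patient's first qualifying date and new-onset events.

    An adverse-event type is a *new onset* when its first record postdates
    the patient's first qualifying diagnosis; types first recorded before
    or on that date are pre-existing and produce no onset. Patients with
    adverse-event records but no qualifying code are excluded (logged).
    """
    by_patient: dict[str, list[EventRecord]] = {}
    for e in events:
        by_patient.setdefault(e.patient_id, []).append(e)

    qual: dict[str, int] = {}
    onsets: dict[str, list[tuple[str, int]]] = {}
    excluded: list[str] = []
    for pid, pevs in by_patient.items():
        qdays = [e.date for e in pevs if e.code in config.qualifying_codes]
        first_ae: dict[str, int] = {}
        for e in pevs:
            if e.code in config.adverse_event_codes:
                if e.code not in first_ae or e.date < first_ae[e.code]:
                    first_ae[e.code] = e.date
        if not qdays:
            if first_ae:
                excluded.append(pid)
                logger.info("patient %s has adverse events but no qualifying code; excluded", pid)
            continue
        q = min(qdays)
        qual[pid] = q
        new = sorted(
            ((code, day) for code, day in first_ae.items() if day > q),
            key=lambda cd: (cd[1], cd[0]),
        )
        onsets[pid] = new
    return OnsetMap(qualifying_date=qual, onsets=onsets, excluded_patients=excluded)


def _encounter_days(pevs: list[EventRecord]) -> list[int]:
    return sorted({e.date for e in pevs})


def build_samples(events: list[EventRecord], onset_map: OnsetMap,
                  config: CohortConfig) -> list[CohortSample]:
    """Emit augmented case samples and ratio-matched control samples.

    Case: for each encounter day ``e`` in ``[qualifying, first_onset)``
    with ``first_onset <= e + window``, one sample (history truncated at
    ``e``; the onset record itself is excluded from the history by the
    truncation since onset > e). Control eligibility requires no
    adverse-event record in ``(e, e + window]``; by default encounters of
    case patients are not control-eligible.
    """
    w = config.prediction_window_days
    by_patient: dict[str, list[EventRecord]] = {}
    for e in events:
        by_patient.setdefault(e.patient_id, []).append(e)

    cases: list[CohortSample] = []
    control_pool: list[tuple[str, int]] = []
    for pid, q in sorted(onset_map.qualifying_date.items()):
        pevs = sorted(by_patient.get(pid, []), key=lambda e: e.date)
        ae_days = sorted(e.date for e in pevs if e.code in config.adverse_event_codes)
        new_onsets = onset_map.onsets.get(pid, [])
        enc = _encounter_days(pevs)
        if new_onsets:
            code0, day0 = new_onsets[0]
            for e_day in enc:
                if q <= e_day < day0 and day0 <= e_day + w:
                    hist = [ev for ev in pevs if ev.date <= e_day]
                    cases.append(CohortSample(pid, e_day, 1, hist, code0))
            if not config.allow_case_patients_as_controls:
                continue
        for e_day in enc:
            if e_day < q:
                continue
            if new_onsets and q <= e_day < new_onsets[0][1] and new_onsets[0][1] <= e_day + w:
                continue  # already a case sample
            in_window = any(e_day < d <= e_day + w for d in ae_days)
            if not in_window:
                control_pool.append((pid, e_day))

    if not cases:
        raise EmptyCohortError("no eligible case sample could be constructed")

    n_controls = round(config.control_sampling_ratio * len(cases))
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0xC0,)))
    if n_controls < len(control_pool):
        pick = rng.choice(len(control_pool), size=n_controls, replace=False)
        chosen = [control_pool[i] for i in sorted(pick)]
    else:
        chosen = control_pool
    controls = []
    for pid, e_day in chosen:
        pevs = sorted(by_patient[pid], key=lambda e: e.date)
        hist = [ev for ev in pevs if ev.date <= e_day]
        controls.append(CohortSample(pid, e_day, 0, hist, None))
    return cases + controls


def split(samples: list[CohortSample], config: CohortConfig
          ) -> tuple[list[CohortSample], list[CohortSample], list[CohortSample]]:
    """Partition samples by patient, approximating the split ratios.

    Patients are shuffled under the config seed and assigned greedily to
    the fold with the largest remaining deficit relative to its target
    share of samples, so realized proportions track the ratios as closely
    as patient granularity allows. Deterministic under seed.
    """
    by_patient: dict[str, list[CohortSample]] = {}
    for s in samples:
        by_patient.setdefault(s.patient_id, []).append(s)
    pids = sorted(by_patient)
    if len(pids) < 3:
        raise ValueError(f"need >= 3 patients to split, got {len(pids)}")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0x5B,)))
    order = rng.permutation(len(pids))
    ratios = config.split_ratios
    counts = [0, 0, 0]
    folds: tuple[list[CohortSample], ...] = ([], [], [])
    total = len(samples)
    for idx in order:
        pid = pids[idx]
        k = len(by_patient[pid])
        # deficit = target share minus realized share if assigned here
        deficits = [ratios[f] - (counts[f]) / total for f in range(3)]
        f = int(np.argmax(deficits))
        folds[f].extend(by_patient[pid])
        counts[f] += k
    # guarantee non-empty folds (tiny cohorts): move one patient if needed
    for f in range(3):
        if not folds[f]:
            donor = max(range(3), key=lambda g: counts[g])
            move_pid = folds[donor][0].patient_id
            moved = [s for s in folds[donor] if s.patient_id == move_pid]
            folds[donor][:] = [s for s in folds[donor] if s.patient_id != move_pid]
            folds[f].extend(moved)
            counts[donor] -= len(moved)
            counts[f] += len(moved)
    return folds


def write_manifest(folds: tuple[list[CohortSample], ...], path) -> None:
    rows = []
    for name, fold in zip(("train", "validation", "test"), folds):
        for s in fold:
            rows.append((s.patient_id, s.index_date, s.label, name, s.target_event_code or ""))
    pd.DataFrame(
        rows, columns=["patient_id", "index_date", "label", "fold", "target_event_code"],
    ).to_csv(path, index=False)
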