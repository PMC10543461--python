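"""Synthetic longitudinal EMR generator with planted risk/protective effects.

Real EMR extracts of the kind this pipeline targets (dated diagnosis,
medication and lab events per patient, plus individual and zip-code-linked
neighborhood social determinants of health) are private, so every
downstream stage is exercised against simulated data in which the ground
truth is known by construction.

The outcome model is discrete time: after a patient's first qualifying
diagnosis, adverse-event onset is drawn per 90-day window as a Bernoulli
trial whose probability is ``baseline_hazard`` multiplied by the odds
factors of planted-effect codes present in the patient's recent history
(365-day lookback by default), clamped to [0, 1]. An odds factor > 1 is a
risk effect, < 1 protective. This makes planted-effect recovery
analytically checkable: among carriers of a single planted code with
factor f, the per-window onset rate is ``clamp(baseline_hazard * f)``.

Dates are integer day offsets from an arbitrary epoch; ISO-8601 dates are
accepted on input and converted. Randomness uses one master seed with
per-patient substreams (``SeedSequence(seed, spawn_key=(patient,))``), so
growing ``n_patients`` never reshuffles earlier patients, and raising an
odds factor never decreases any carrier's simulated onset rate because
window uniforms are drawn from a stream independent of the factor values.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CodeType",
    "LabFlag",
    "SimConfig",
    "EventRecord",
    "GroundTruth",
    "ConfigError",
    "EventParseError",
    "generate_dataset",
    "write_events",
    "read_events",
    "write_sdoh_table",
    "read_sdoh_table",
]

_EPOCH = _dt.date(2004, 1, 1)

EVENT_COLUMNS = ["patient_id", "date", "code_type", "code", "lab_flag", "zip5"]


class CodeType(str, Enum):
    DIAGNOSIS = "DIAGNOSIS"
    MEDICATION = "MEDICATION"
    LAB = "LAB"
    SDOH_IND = "SDOH_IND"


class LabFlag(str, Enum):
    ABNORMAL = "ABNORMAL"
    HIGH = "HIGH"
    LOW = "LOW"


class ConfigError(ValueError):
    """Invalid simulation configuration; names the offending field."""


class EventParseError(ValueError):
    """Malformed event row; carries the 1-based data line number."""


@dataclass(frozen=True)
class EventRecord:
    """One dated clinical event for one patient (the atomic input row)."""

    patient_id: str
    date: int
    code_type: CodeType
    code: str
    lab_flag: LabFlag | None = None
    zip5: str | None = None

    def __post_init__(self):
        if (self.code_type == CodeType.LAB) != (self.lab_flag is not None):
            raise ValueError(
                "lab_flag must be present iff code_type is LAB "
                f"(got {self.code_type.value} with flag {self.lab_flag})"
            )


@dataclass
class GroundTruth:
    """Planted truth for a simulated dataset."""

    qualifying_date: dict[str, int]
    onset_dates: dict[str, list[tuple[str, int]]]  # patient -> [(event code, day)]
    planted_effects: dict[str, float]
    carriers: dict[str, set[str]]  # planted code -> patient ids


@dataclass
class SimConfig:
    """Study-design knobs for one simulated dataset.

    ``planted_effects`` maps a code (e.g. ``"RX_RISK"``) to a multiplicative
    odds factor on the per-window adverse-event probability; ``carrier_probs``
    gives the fraction of patients carrying each planted code (default 0.5).
    ``carrier_mode`` draws carrier status independently per code
    (``"independent"``) or assigns each patient at most one planted code by
    a single categorical draw (``"exclusive"``, carrier probabilities then
    summing to at most 1) — the exclusive mode emulates mutually exclusive
    exposure arms such as alternative first-line prescriptions. Planted
    codes live in the medication stream unless the code starts with ``DX_``
    (diagnosis stream) or ``SD_`` (individual SDoH stream).
    """

    n_patients: int = 1000
    vocab_sizes: dict[str, int] = field(default_factory=lambda: {
        "diagnosis": 40, "medication": 40, "lab": 20,
        "sdoh_individual": 6, "sdoh_neighborhood": 5,
    })
    baseline_hazard: float = 0.1
    planted_effects: dict[str, float] = field(default_factory=dict)
    carrier_probs: dict[str, float] = field(default_factory=dict)
    encounters_per_patient: tuple[float, float] = (10.0, 1.0)  # mean, dispersion
    followup_days: int = 1080
    lab_flag_probs: dict[str, float] = field(default_factory=lambda: {
        "ABNORMAL": 0.10, "HIGH": 0.10, "LOW": 0.10,
    })
    window_days: int = 90
    lookback_days: int = 365
    qualifying_code: str = "DX_QUALIFYING"
    adverse_event_codes: tuple[str, ...] = ("AE_PRIMARY", "AE_SECONDARY")
    preexisting_event_prob: float = 0.0
    n_zip_codes: int = 40
    events_per_encounter: float = 3.0
    planted_emission_prob: float = 0.35  # episode start probability per block
    planted_persistence: float | None = None  # P(stay on) next block; None = iid blocks
    planted_encounter_prob: float = 1.0  # P(record at an encounter while on)
    planted_initial_emission: bool = True  # first prescription at cohort entry
    carrier_mode: str = "independent"  # "independent" | "exclusive"
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        for k, v in self.vocab_sizes.items():
            if v < 1:
                raise ConfigError(f"vocab_sizes[{k!r}] must be >= 1")
        for name in ("baseline_hazard", "preexisting_event_prob", "planted_emission_prob",
                     "planted_encounter_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        for code, f in self.planted_effects.items():
            if not f > 0:
                raise ConfigError(f"planted_effects[{code!r}] must be > 0")
        for code, p in self.carrier_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"carrier_probs[{code!r}] must be in [0, 1]")
        for k, p in self.lab_flag_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"lab_flag_probs[{k!r}] must be in [0, 1]")
        if sum(self.lab_flag_probs.values()) > 1.0 + 1e-12:
            raise ConfigError("lab_flag_probs must sum to <= 1")
        if self.window_days < 1:
            raise ConfigError("window_days must be >= 1")
        if self.followup_days < 1:
            raise ConfigError("followup_days must be >= 1")
        if self.encounters_per_patient[0] <= 0:
            raise ConfigError("encounters_per_patient mean must be > 0")
        if self.carrier_mode not in ("independent", "exclusive"):
            raise ConfigError("carrier_mode must be 'independent' or 'exclusive'")
        if self.carrier_mode == "exclusive":
            total = sum(self.carrier_probs.get(c, 0.5) for c in self.planted_effects)
            if total > 1.0 + 1e-12:
                raise ConfigError("carrier_probs must sum to <= 1 in exclusive carrier_mode")


_RACES = ["RACE:WHITE", "RACE:BLACK", "RACE:ASIAN", "RACE:OTHER"]
_GENDERS = ["GENDER:F", "GENDER:M"]

SDOH_FEATURE_NAMES = [
    "nses_index", "gini_index", "park_proximity", "pct_no_vehicle", "health_literacy",
]


def _planted_code_type(code: str) -> CodeType:
    if code.startswith("DX_"):
        return CodeType.DIAGNOSIS
    if code.startswith("SD_"):
        return CodeType.SDOH_IND
    return CodeType.MEDICATION


def generate_dataset(config: SimConfig) -> tuple[list[EventRecord], GroundTruth, pd.DataFrame]:
    """Simulate a dataset; deterministic for a fixed config (incl. seed).

    Returns the flat event list (sorted by patient then date), the ground
    truth, and the zip5 -> neighborhood-SDoH feature table.
    """
    config.validate()
    master = np.random.SeedSequence(config.seed)

    # Neighborhood table from its own substream (independent of n_patients).
    rng_nb = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0xFACE,)))
    nb_names = SDOH_FEATURE_NAMES[: config.vocab_sizes.get("sdoh_neighborhood", 5)]
    zips = [f"{15000 + i:05d}" for i in range(config.n_zip_codes)]
    sdoh_table = pd.DataFrame(
        rng_nb.normal(0.0, 1.0, size=(config.n_zip_codes, len(nb_names))),
        columns=nb_names,
    )
    sdoh_table.insert(0, "zip5", zips)

    planted = sorted(config.planted_effects)
    events: list[EventRecord] = []
    truth = GroundTruth(
        qualifying_date={}, onset_dates={},
        planted_effects=dict(config.planted_effects),
        carriers={c: set() for c in planted},
    )

    n_dx = config.vocab_sizes.get("diagnosis", 1)
    n_rx = config.vocab_sizes.get("medication", 1)
    n_lab = config.vocab_sizes.get("lab", 1)
    flag_names = list(config.lab_flag_probs)
    flag_p = np.array([config.lab_flag_probs[f] for f in flag_names])
    p_none = max(0.0, 1.0 - flag_p.sum())
    flag_choices = flag_names + [None]
    flag_probs = np.append(flag_p, p_none)
    flag_probs = flag_probs / flag_probs.sum()

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(i,)))
        zip5 = zips[int(rng.integers(config.n_zip_codes))]

        # carrier status per planted code, in sorted-code order so that the
        # draw stream is stable when only factor values change
        carrier = {code: False for code in planted}
        if config.carrier_mode == "exclusive" and planted:
            u = rng.random()
            acc = 0.0
            for code in planted:
                acc += config.carrier_probs.get(code, 0.5)
                if u < acc:
                    carrier[code] = True
                    break
        else:
            for code in planted:
                carrier[code] = rng.random() < config.carrier_probs.get(code, 0.5)
        for code in planted:
            if carrier[code]:
                truth.carriers[code].add(pid)

        # encounter timeline: first encounter at day 0 carries the
        # qualifying diagnosis; later encounters negative-binomial count
        mean, disp = config.encounters_per_patient
        n_extra = int(rng.negative_binomial(disp, disp / (disp + mean))) if disp > 0 else int(rng.poisson(mean))
        extra_days = np.sort(rng.integers(1, config.followup_days, size=n_extra))
        enc_days = np.unique(np.concatenate([[0], extra_days])).astype(int)

        pevents: list[EventRecord] = [
            EventRecord(pid, 0, CodeType.SDOH_IND, _RACES[int(rng.integers(len(_RACES)))], None, zip5),
            EventRecord(pid, 0, CodeType.SDOH_IND, _GENDERS[int(rng.integers(2))], None, zip5),
            EventRecord(pid, 0, CodeType.SDOH_IND, f"AGE:{int(rng.integers(18, 90))}", None, zip5),
            EventRecord(pid, 0, CodeType.DIAGNOSIS, config.qualifying_code, None, zip5),
        ]
        truth.qualifying_date[pid] = 0

        for day in enc_days:
            k = 1 + int(rng.poisson(max(config.events_per_encounter - 1, 0)))
            for _ in range(k):
                r = rng.random()
                if r < 0.4:
                    pevents.append(EventRecord(
                        pid, int(day), CodeType.DIAGNOSIS, f"DX{int(rng.integers(n_dx)):03d}", None, zip5))
                elif r < 0.75:
                    pevents.append(EventRecord(
                        pid, int(day), CodeType.MEDICATION, f"RX{int(rng.integers(n_rx)):03d}", None, zip5))
                else:
                    flag = flag_choices[int(rng.choice(len(flag_choices), p=flag_probs))]
                    if flag is not None:
                        pevents.append(EventRecord(
                            pid, int(day), CodeType.LAB, f"LAB{int(rng.integers(n_lab)):03d}",
                            LabFlag(flag), zip5))
            # planted codes are emitted in therapy-like episodes (below),
            # not per encounter
            pass

        # planted codes follow an episodic exposure pattern, like courses of
        # a repeat prescription: in each 90-day block the carrier is either
        # on or off (on with planted_emission_prob, independently per block;
        # the first block is always on when planted_initial_emission is
        # set), and while on, the code is recorded at every encounter in
        # the block. Exposure therefore waxes and wanes, so the hazard
        # lookback sees the code only in and just after active blocks.
        n_blocks = int(np.ceil(config.followup_days / config.window_days)) or 1
        active: dict[str, np.ndarray] = {}
        for code in planted:
            u = rng.random(n_blocks)
            on = np.zeros(n_blocks, dtype=bool)
            for k in range(n_blocks):
                thr = config.planted_emission_prob
                if k and on[k - 1] and config.planted_persistence is not None:
                    thr = config.planted_persistence
                on[k] = u[k] < thr
            if config.planted_initial_emission:
                on[0] = True
            active[code] = on
            if carrier[code]:
                for day in enc_days:
                    if on[min(int(day) // config.window_days, n_blocks - 1)] and (
                            day == 0 or config.planted_encounter_prob >= 1.0
                            or rng.random() < config.planted_encounter_prob):
                        pevents.append(EventRecord(
                            pid, int(day), _planted_code_type(code), code, None, zip5))

        # optional pre-existing adverse event (before/at qualification)
        onsets: list[tuple[str, int]] = []
        if config.preexisting_event_prob > 0 and rng.random() < config.preexisting_event_prob:
            code = config.adverse_event_codes[int(rng.integers(len(config.adverse_event_codes)))]
            pevents.append(EventRecord(pid, 0, CodeType.DIAGNOSIS, code, None, zip5))

        # discrete-time outcome: one Bernoulli per 90-day window; window
        # uniforms come from a dedicated substream so they are invariant to
        # the effect-factor values (monotonicity under common random numbers)
        rng_outcome = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(i, 0xBEEF)))
        starts = np.arange(0, config.followup_days, config.window_days)
        u = rng_outcome.random(len(starts))
        day_arr = np.array([e.date for e in pevents])
        code_arr = np.array([e.code for e in pevents])
        for w, t in enumerate(starts):
            h = config.baseline_hazard
            for code in planted:
                if carrier[code]:
                    lo = t - config.lookback_days
                    present = np.any((code_arr == code) & (day_arr >= lo) & (day_arr <= t))
                    if present:
                        h *= config.planted_effects[code]
            h = min(max(h, 0.0), 1.0)
            if u[w] < h:
                onset_day = int(t + 1 + rng_outcome.integers(config.window_days))
                code = config.adverse_event_codes[
                    int(rng_outcome.integers(len(config.adverse_event_codes)))]
                pevents.append(EventRecord(pid, onset_day, CodeType.DIAGNOSIS, code, None, zip5))
                onsets.append((code, onset_day))
                break  # follow-up ends at first onset

        truth.onset_dates[pid] = onsets
        pevents.sort(key=lambda e: (e.date, e.code_type.value, e.code))
        events.extend(pevents)

    return events, truth, sdoh_table


# ---------------------------------------------------------------------------
# I/O: long-format CSV with header, ISO-8601 or integer day offsets
# ---------------------------------------------------------------------------

def _date_to_int(value: str, lineno: int) -> int:
    s = str(value).strip()
    try:
        return int(s)
    except ValueError:
        pass
    try:
        return (_dt.date.fromisoformat(s) - _EPOCH).days
    except ValueError as exc:
        raise EventParseError(f"line {lineno}: unparseable date {value!r}") from exc


def write_events(events: Iterable[EventRecord], path) -> None:
    rows = [
        (e.patient_id, e.date, e.code_type.value, e.code,
         e.lab_flag.value if e.lab_flag else "", e.zip5 or "")
        for e in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events(path) -> list[EventRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise EventParseError(f"missing columns: {missing}")
    out: list[EventRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        try:
            ctype = CodeType(row.code_type)
        except ValueError as exc:
            raise EventParseError(f"line {idx}: unknown code_type {row.code_type!r}") from exc
        flag_s = row.lab_flag.strip()
        try:
            flag = LabFlag(flag_s) if flag_s else None
        except ValueError as exc:
            raise EventParseError(f"line {idx}: unknown lab_flag {flag_s!r}") from exc
        try:
            rec = EventRecord(
                patient_id=row.patient_id,
                date=_date_to_int(row.date, idx),
                code_type=ctype,
                code=row.code,
                lab_flag=flag,
                zip5=row.zip5 or None,
            )
        except ValueError as exc:
            raise EventParseError(f"line {idx}: {exc}") from exc
        out.append(rec)
    return out


def write_sdoh_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_sdoh_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"zip5": str})
    if "zip5" not in df.columns:
        raise EventParseError("sdoh table must have a zip5 column")
    return df
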