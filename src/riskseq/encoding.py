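"""Tokenization of multimodal events and assembly of visit sequences.

Events map to a discrete token vocabulary by modality:

* diagnoses -> ``DX:<cluster>`` through an optional user-supplied cluster
  map (identity when absent), standing in for an ICD-to-category ontology;
* medications -> ``RX:<mapped>`` through an optional drug-id map (e.g.
  name -> DrugBank id), identity when absent;
* lab results -> ``LAB:<code>:<flag>`` and only when flagged ABNORMAL,
  HIGH or LOW — normal results are dropped;
* individual SDoH -> ``SD:<code>``, with continuous age binned to decades
  (``SD:AGE:40``);
* neighborhood SDoH -> per-feature quantile-bin tokens ``NB:<feature>:Q<k>``
  joined through the patient's zip5 (``NB:MISSING`` when the zip is absent
  from the table).

A *visit* is the set of tokens sharing one calendar date. The vocabulary
is built on the training fold only; tokens carried by fewer than
``min_patient_count`` distinct training patients collapse to UNK, and
encoding of validation/test never adds tokens.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortSample
from .synthetic import CodeType, EventRecord

__all__ = [
    "PAD", "UNK",
    "Vocabulary",
    "EncodedSequence",
    "NeighborhoodBinner",
    "tokenize",
    "attach_neighborhood_sdoh",
    "build_vocabulary",
    "encode_sample",
    "encode_fold",
    "load_maps",
]

PAD = 0
UNK = 1
_SPECIALS = ["<PAD>", "<UNK>"]


@dataclass
class Vocabulary:
    token_to_id: dict[str, int]
    id_to_token: list[str]
    patient_counts: dict[str, int]

    @property
    def size(self) -> int:
        return len(self.id_to_token)

    def lookup(self, token: str) -> int:
        return self.token_to_id.get(token, UNK)

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for tok in self.id_to_token:
            h.update(tok.encode())
            h.update(b"\x00")
        return h.hexdigest()[:16]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("token\tid\tpatient_count\n")
            for i, tok in enumerate(self.id_to_token):
                fh.write(f"{tok}\t{i}\t{self.patient_counts.get(tok, 0)}\n")

    @classmethod
    def from_tsv(cls, path) -> "Vocabulary":
        df = pd.read_csv(path, sep="\t", dtype={"token": str})
        df = df.sort_values("id")
        toks = df["token"].tolist()
        return cls(
            token_to_id={t: i for i, t in enumerate(toks)},
            id_to_token=toks,
            patient_counts=dict(zip(df["token"], df["patient_count"])),
        )


@dataclass
class EncodedSequence:
    """Model input: ordered visits of token-id sets plus static tokens."""

    visits: list[tuple[int, list[int]]]  # (day offset from first visit, ids)
    static_tokens: list[int]
    label: int
    patient_id: str = ""
    index_date: int = 0


def tokenize(record: EventRecord, cluster_map: dict[str, str] | None = None,
             drug_map: dict[str, str] | None = None) -> list[str]:
    """Map one event to zero or more tokens (normal labs map to none)."""
    if record.code_type == CodeType.DIAGNOSIS:
        code = (cluster_map or {}).get(record.code, record.code)
        return [f"DX:{code}"]
    if record.code_type == CodeType.MEDICATION:
        code = (drug_map or {}).get(record.code, record.code)
        return [f"RX:{code}"]
    if record.code_type == CodeType.LAB:
        if record.lab_flag is None:
            return []
        return [f"LAB:{record.code}:{record.lab_flag.value}"]
    # individual SDoH; age collapses to decades
    code = record.code
    if code.upper().startswith("AGE:"):
        try:
            decade = (int(float(code.split(":", 1)[1])) // 10) * 10
            return [f"SD:AGE:{decade}"]
        except ValueError:
            pass
    return [f"SD:{code}"]


class NeighborhoodBinner:
    """Rank-based quantile binning of neighborhood SDoH features.

    Bins are computed over the feature's values across the zip table, so
    two patients with the same zip always receive identical tokens and
    bin populations differ by at most one zip when values are distinct.
    The middle bin of an odd number of bins contains the median.
    """

    def __init__(self, sdoh_table: pd.DataFrame, n_bins: int = 5):
        if n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        self.n_bins = n_bins
        self.features = [c for c in sdoh_table.columns if c != "zip5"]
        self._sorted = {f: np.sort(sdoh_table[f].to_numpy(dtype=float)) for f in self.features}
        self._by_zip = sdoh_table.set_index("zip5")

    def bin_of(self, feature: str, value: float) -> int:
        vals = self._sorted[feature]
        rank = int(np.searchsorted(vals, value, side="left"))
        return 1 + (rank * self.n_bins) // len(vals)

    def tokens_for_zip(self, zip5: str | None) -> list[str]:
        if zip5 is None or zip5 not in self._by_zip.index:
            return ["NB:MISSING"]
        row = self._by_zip.loc[zip5]
        return [f"NB:{f}:Q{self.bin_of(f, float(row[f]))}" for f in self.features]


def attach_neighborhood_sdoh(sample: CohortSample, binner: NeighborhoodBinner) -> list[str]:
    """Neighborhood tokens for a sample via the patient's zip5."""
    zip5 = None
    for e in sample.history:
        if e.zip5:
            zip5 = e.zip5
            break
    return binner.tokens_for_zip(zip5)


def _sample_tokens(sample: CohortSample, cluster_map, drug_map,
                   binner: NeighborhoodBinner | None,
                   include_sdoh: bool) -> tuple[dict[int, list[str]], list[str]]:
    """(per-date dynamic tokens, static tokens) for one sample."""
    by_date: dict[int, list[str]] = {}
    static: list[str] = []
    for e in sorted(sample.history, key=lambda e: e.date):
        toks = tokenize(e, cluster_map, drug_map)
        if e.code_type == CodeType.SDOH_IND:
            if include_sdoh:
                static.extend(t for t in toks if t not in static)
        else:
            by_date.setdefault(e.date, []).extend(toks)
    if include_sdoh and binner is not None:
        static.extend(attach_neighborhood_sdoh(sample, binner))
    return by_date, static


def build_vocabulary(train_samples: list[CohortSample], min_patient_count: int = 10,
                     cluster_map: dict[str, str] | None = None,
                     drug_map: dict[str, str] | None = None,
                     binner: NeighborhoodBinner | None = None,
                     include_sdoh: bool = True) -> Vocabulary:
    """Count distinct training patients per token; retain frequent ones."""
    if not train_samples:
        raise ValueError("vocabulary requires a nonempty training fold")
    patients_per_token: dict[str, set[str]] = {}
    for s in train_samples:
        by_date, static = _sample_tokens(s, cluster_map, drug_map, binner, include_sdoh)
        for toks in list(by_date.values()) + [static]:
            for t in toks:
                patients_per_token.setdefault(t, set()).add(s.patient_id)
    kept = sorted(t for t, ps in patients_per_token.items() if len(ps) >= min_patient_count)
    id_to_token = _SPECIALS + kept
    return Vocabulary(
        token_to_id={t: i for i, t in enumerate(id_to_token)},
        id_to_token=id_to_token,
        patient_counts={t: len(ps) for t, ps in patients_per_token.items() if t in set(kept)},
    )


def encode_sample(sample: CohortSample, vocab: Vocabulary,
                  cluster_map: dict[str, str] | None = None,
                  drug_map: dict[str, str] | None = None,
                  binner: NeighborhoodBinner | None = None,
                  include_sdoh: bool = True,
                  max_visits: int = 200) -> EncodedSequence:
    """Group events into date visits, map to ids, keep most recent visits.

    Tokens within a visit are deduplicated; empty visits (e.g. only normal
    lab results) are dropped. An empty history yields a sequence with
    static tokens only, which is valid model input.
    """
    by_date, static = _sample_tokens(sample, cluster_map, drug_map, binner, include_sdoh)
    days = sorted(by_date)
    visits: list[tuple[int, list[int]]] = []
    first_day = days[0] if days else 0
    for d in days:
        ids = sorted({vocab.lookup(t) for t in by_date[d]})
        if ids:
            visits.append((d - first_day, ids))
    if max_visits and len(visits) > max_visits:
        visits = visits[-max_visits:]
    static_ids = sorted({vocab.lookup(t) for t in static})
    return EncodedSequence(
        visits=visits, static_tokens=static_ids, label=sample.label,
        patient_id=sample.patient_id, index_date=sample.index_date,
    )


def encode_fold(samples: list[CohortSample], vocab: Vocabulary, **kw) -> list[EncodedSequence]:
    return [encode_sample(s, vocab, **kw) for s in samples]


def load_maps(path) -> dict[str, str]:
    """Two-column CSV (raw,mapped) -> dict."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw_col, mapped_col = df.columns[:2]
    return dict(zip(df[raw_col], df[mapped_col]))
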