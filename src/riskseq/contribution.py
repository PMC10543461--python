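"""Perturbation-based feature attribution and the relative-contribution test.

For every token occurring in a scored sequence, its per-occurrence
contribution is the drop in predicted risk when that single occurrence is
removed (*occlusion*; the default, deterministic) or the mean drop over K
seeded random perturbations of the token's embedding (*noise* mode). The
per-patient feature contribution FC is the sum of per-occurrence drops
over all of the patient's samples — a feature appearing several times in
one patient contributes its total value.

The relative contribution of a feature is

    RC = mean(FC | event patients) / mean(FC | no-event patients),

with a delta-method variance on the log scale,

    Var(ln RC) = (sd_e / mean_e)^2 / m + (sd_c / mean_c)^2 / n,

where m, n are the numbers of event / no-event patients carrying the
feature and the sd's are sample standard deviations. The 95% CI is
``exp(ln RC +/- 1.96 sqrt(Var))`` and the two-sided p-value comes from
``z = ln RC / sqrt(Var)`` under a normal reference. RC > 1 classifies the
feature as a risk factor, RC < 1 as protective. If either group mean is
not positive the log transform is undefined: the ratio is still reported
when computable, but CI/p are suppressed and the classification is
UNDEFINED (no silent rescaling is applied).

A patient contributing samples under both labels appears in both groups
(FC is aggregated per patient-and-label), matching the m/n patient
counting above. Bonferroni uses M = number of features tested; FDR is
Benjamini-Hochberg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .encoding import EncodedSequence, Vocabulary
from .models import TrainedModel, _forward, _visit_lists

__all__ = [
    "FeatureContribution",
    "RCResult",
    "feature_contributions",
    "relative_contribution",
    "adjust_pvalues",
    "rank_features",
    "rc_table",
    "write_fc_table",
    "write_rc_table",
    "read_rc_table",
]

RC_COLUMNS = ["Feature Name", "RC", "95%CIup", "95%CIdown", "FDR_Q",
              "Bonferroni corrected p-value"]


@dataclass
class FeatureContribution:
    feature: str
    patient_id: str
    label: int
    fc_value: float


@dataclass
class RCResult:
    feature: str
    rc: float
    ci_low: float
    ci_high: float
    var_ln_rc: float
    p_raw: float
    n_event: int
    n_noevent: int
    classification: str  # RISK | PROTECTIVE | UNDEFINED | INSUFFICIENT
    p_bonferroni: float = math.nan
    q_fdr: float = math.nan


# ---------------------------------------------------------------------------
# feature contributions
# ---------------------------------------------------------------------------

def _occluded_variants(visits: list[list[int]]) -> list[tuple[int, int, list[list[int]]]]:
    """All (token id, visit index, visit list with that occurrence removed)."""
    out = []
    for vi, visit in enumerate(visits):
        for tok in visit:
            new = [list(v) for v in visits]
            # the visit stays (possibly empty) so the only change is the
            # occluded occurrence itself
            new[vi] = [t for t in new[vi] if t != tok]
            out.append((tok, vi, new))
    return out


def feature_contributions(model: TrainedModel, seqs: list[EncodedSequence],
                          vocab: Vocabulary, mode: str = "occlusion",
                          n_perturbations: int = 10, noise_scale: float = 1.0,
                          seed: int = 0, batch_size: int = 256
                          ) -> list[FeatureContribution]:
    """Per-patient, per-feature contribution records.

    Occlusion mode is deterministic: each occurrence's contribution is
    ``score(original) - score(without that occurrence)``. Noise mode
    replaces occlusion by the mean drop under ``n_perturbations`` seeded
    Gaussian perturbations of the occluded token's embedding row. Tokens
    absent from a patient's samples yield no record.
    """
    if mode not in ("occlusion", "noise"):
        raise ValueError(f"unknown perturbation mode {mode!r}")
    acc: dict[tuple[str, int, str], float] = {}
    vlists = _visit_lists(seqs, model.config)
    base_scores = np.empty(len(seqs))
    for lo in range(0, len(seqs), batch_size):
        base_scores[lo:lo + batch_size] = _forward(
            model.params, model.config, vlists[lo:lo + batch_size]).data

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0xFC,)))
    for si, (seq, visits) in enumerate(zip(seqs, vlists)):
        variants = _occluded_variants(visits)
        if not variants:
            continue
        if mode == "occlusion":
            drops = np.empty(len(variants))
            for lo in range(0, len(variants), batch_size):
                chunk = [v for _, _, v in variants[lo:lo + batch_size]]
                drops[lo:lo + batch_size] = base_scores[si] - _forward(
                    model.params, model.config, chunk).data
        else:
            emb = model.params["emb"]
            drops = np.zeros(len(variants))
            for k, (tok, vi, _) in enumerate(variants):
                orig_row = emb.data[tok].copy()
                vals = np.empty(n_perturbations)
                for j in range(n_perturbations):
                    emb.data[tok] = orig_row + rng.normal(0.0, noise_scale, size=orig_row.shape)
                    vals[j] = _forward(model.params, model.config, [visits]).data[0]
                emb.data[tok] = orig_row
                drops[k] = base_scores[si] - vals.mean()
        for (tok, _, _), d in zip(variants, drops):
            key = (seq.patient_id, seq.label, vocab.id_to_token[tok])
            acc[key] = acc.get(key, 0.0) + float(d)
    return [FeatureContribution(feature=f, patient_id=pid, label=lab, fc_value=v)
            for (pid, lab, f), v in sorted(acc.items())]


# ---------------------------------------------------------------------------
# RC statistic
# ---------------------------------------------------------------------------

def relative_contribution(feature: str, fc_event: np.ndarray,
                          fc_noevent: np.ndarray) -> RCResult:
    """Delta-method RC inference for one feature.

    Requires at least two patients in each group for the sample SDs;
    otherwise the result is flagged INSUFFICIENT with no inference.
    """
    fc_event = np.asarray(fc_event, dtype=float)
    fc_noevent = np.asarray(fc_noevent, dtype=float)
    m, n = len(fc_event), len(fc_noevent)
    nan = math.nan
    if m < 2 or n < 2:
        return RCResult(feature, nan, nan, nan, nan, nan, m, n, "INSUFFICIENT")
    mean_e, mean_c = fc_event.mean(), fc_noevent.mean()
    rc = mean_e / mean_c if mean_c != 0 else nan
    if not rc > 0 or rc == 1.0:
        # the log-ratio needs rc > 0: means of opposite sign (or a zero
        # denominator) leave it undefined, as does the exact boundary rc=1;
        # report the ratio when computable, suppress inference. Two negative
        # means still give a positive ratio (protective features under
        # occlusion have negative contributions in both groups) and keep
        # full inference since the delta-method variance uses squared
        # coefficients of variation.
        return RCResult(feature, rc, nan, nan, nan, nan, m, n, "UNDEFINED")
    sd_e = fc_event.std(ddof=1)
    sd_c = fc_noevent.std(ddof=1)
    var_ln = (sd_e / mean_e) ** 2 / m + (sd_c / mean_c) ** 2 / n
    ln_rc = math.log(rc)
    half = 1.96 * math.sqrt(var_ln)
    # np.exp saturates to inf/0 instead of raising on extreme half-widths
    ci_low = float(np.exp(ln_rc - half))
    ci_high = float(np.exp(ln_rc + half))
    if var_ln > 0:
        z = ln_rc / math.sqrt(var_ln)
        p = 2.0 * float(norm.sf(abs(z)))
    else:
        p = 0.0 if ln_rc != 0 else 1.0
    cls = "RISK" if rc > 1 else "PROTECTIVE"
    return RCResult(feature, rc, ci_low, ci_high, var_ln, p, m, n, cls)


def adjust_pvalues(p_raw: list[float]) -> tuple[list[float], list[float]]:
    """Order-preserving Bonferroni (min(1, M p)) and Benjamini-Hochberg q."""
    if len(p_raw) == 0:
        return [], []
    p = np.asarray(p_raw, dtype=float)
    _, p_bonf, _, _ = multipletests(p, method="bonferroni")
    _, q_fdr, _, _ = multipletests(p, method="fdr_bh")
    return p_bonf.tolist(), q_fdr.tolist()


def rc_table(fcs: list[FeatureContribution], min_group: int = 2) -> list[RCResult]:
    """RC inference for every feature with multiple-testing adjustment.

    Features with a defined p-value form the testing family for the
    Bonferroni multiplier and the BH adjustment.
    """
    by_feature: dict[str, tuple[list[float], list[float]]] = {}
    for fc in fcs:
        e, c = by_feature.setdefault(fc.feature, ([], []))
        (e if fc.label == 1 else c).append(fc.fc_value)
    results = [relative_contribution(f, np.array(e), np.array(c))
               for f, (e, c) in sorted(by_feature.items())]
    tested = [r for r in results if not math.isnan(r.p_raw)]
    if tested:
        bonf, q = adjust_pvalues([r.p_raw for r in tested])
        for r, pb, qf in zip(tested, bonf, q):
            r.p_bonferroni, r.q_fdr = pb, qf
    return results


def rank_features(results: list[RCResult], by: str = "q_fdr") -> pd.DataFrame:
    """Report rows ordered by FDR q (default); undefined rows sink last.

    Column order matches the reporting layout: Feature Name, RC, 95%CIup,
    95%CIdown, FDR_Q, Bonferroni corrected p-value.
    """
    rows = []
    for r in results:
        rows.append({
            "Feature Name": r.feature, "RC": r.rc,
            "95%CIup": r.ci_high, "95%CIdown": r.ci_low,
            "FDR_Q": r.q_fdr, "Bonferroni corrected p-value": r.p_bonferroni,
            "classification": r.classification,
            "n_event": r.n_event, "n_noevent": r.n_noevent, "p_raw": r.p_raw,
        })
    df = pd.DataFrame(rows, columns=RC_COLUMNS + ["classification", "n_event",
                                                  "n_noevent", "p_raw"])
    if len(df):
        key = {"q_fdr": "FDR_Q", "rc": "RC", "p_raw": "p_raw"}[by]
        df = df.sort_values(key, na_position="last", kind="mergesort").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_fc_table(fcs: list[FeatureContribution], path) -> None:
    pd.DataFrame(
        [(f.feature, f.patient_id, f.label, f.fc_value) for f in fcs],
        columns=["feature", "patient_id", "label", "fc"],
    ).to_csv(path, index=False)


def write_rc_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def read_rc_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
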