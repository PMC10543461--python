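"""RC statistic, delta-method CI, multiple testing, ranking, attribution."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import riskseq as rs
from riskseq.contribution import rc_table, RC_COLUMNS
from riskseq.models import ModelConfig, _init_params
from tests.conftest import make_separable_sequences


def oracle_rc(fc_e, fc_c):
    """Straight-line reimplementation of the RC inference chain."""
    m, n = len(fc_e), len(fc_c)
    mean_e = sum(fc_e) / m
    mean_c = sum(fc_c) / n
    rc = mean_e / mean_c
    sd_e = math.sqrt(sum((x - mean_e) ** 2 for x in fc_e) / (m - 1))
    sd_c = math.sqrt(sum((x - mean_c) ** 2 for x in fc_c) / (n - 1))
    var = (sd_e / mean_e) ** 2 / m + (sd_c / mean_c) ** 2 / n
    ln_rc = math.log(rc)
    lo = math.exp(ln_rc - 1.96 * math.sqrt(var))
    hi = math.exp(ln_rc + 1.96 * math.sqrt(var))
    if var > 0:
        z = ln_rc / math.sqrt(var)
        p = math.erfc(abs(z) / math.sqrt(2))
    else:
        p = 0.0 if ln_rc != 0 else 1.0
    return rc, var, lo, hi, p


class TestRelativeContribution:
    def test_hand_example_means_three_and_one(self):
        r = rs.relative_contribution("f", np.array([2.0, 4.0]), np.array([1.0, 1.0, 1.0]))
        assert r.rc == pytest.approx(3.0)
        assert r.classification == "RISK"

    def test_hand_example_rc_one_with_variance(self):
        r = rs.relative_contribution("f", np.array([1.0, 3.0]), np.array([2.0, 2.0]))
        assert r.rc == pytest.approx(1.0)
        # rc exactly 1 sits on the risk/protective boundary
        assert r.classification == "UNDEFINED"

    def test_closed_form_variance_and_ci(self):
        # shift the event group so rc != 1: events {2,4}, controls {2,2}
        r = rs.relative_contribution("f", np.array([2.0, 4.0]), np.array([2.0, 2.0]))
        # var = ((sd_e/mean_e)^2)/2 + 0 = ((sqrt(2)/3)^2)/2 = 1/9
        assert r.var_ln_rc == pytest.approx(1 / 9)
        assert r.ci_low == pytest.approx(1.5 * math.exp(-1.96 / 3))
        assert r.ci_high == pytest.approx(1.5 * math.exp(1.96 / 3))

    def test_identical_groups_rc_one_undefined(self):
        x = np.array([1.0, 2.0, 3.0])
        r = rs.relative_contribution("f", x, x.copy())
        assert r.rc == pytest.approx(1.0)
        assert r.classification == "UNDEFINED"

    def test_small_groups_flagged_insufficient(self):
        r = rs.relative_contribution("f", np.array([1.0]), np.array([1.0, 2.0]))
        assert r.classification == "INSUFFICIENT"
        assert math.isnan(r.rc)

    def test_opposite_sign_means_suppress_inference(self):
        r = rs.relative_contribution("f", np.array([1.0, 2.0]), np.array([-1.0, -2.0]))
        assert r.classification == "UNDEFINED"
        assert math.isnan(r.ci_low) and math.isnan(r.p_raw)

    def test_both_negative_means_keep_inference(self):
        """Protective features under occlusion have negative contributions
        in both groups; the ratio of means is positive and inference holds."""
        r = rs.relative_contribution("f", np.array([-1.0, -2.0, -1.5]),
                                     np.array([-4.0, -5.0, -4.5]))
        assert 0 < r.rc < 1
        assert r.classification == "PROTECTIVE"
        assert not math.isnan(r.p_raw)

    def test_oracle_equivalence_on_random_tables(self):
        """rc/var/CI/p agree with the straight-line oracle to 1e-12."""
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(1000):
            m = int(rng.integers(2, 40))
            n = int(rng.integers(2, 40))
            fc_e = rng.lognormal(0.0, 1.0, m)
            fc_c = rng.lognormal(0.0, 1.0, n)
            r = rs.relative_contribution("f", fc_e, fc_c)
            rc, var, lo, hi, p = oracle_rc(list(fc_e), list(fc_c))
            assert r.rc == pytest.approx(rc, abs=1e-12)
            assert r.var_ln_rc == pytest.approx(var, abs=1e-12)
            assert r.ci_low == pytest.approx(lo, abs=1e-12)
            assert r.ci_high == pytest.approx(hi, abs=1e-12)
            assert r.p_raw == pytest.approx(p, abs=1e-12)
            checked += 1
        assert checked == 1000

    def test_ci_calibration_under_null(self):
        """Equal-median lognormal FC, m=n=200: the 95% CI covers 1 in
        95% +/- 1.5% of 2000 replicates."""
        rng = np.random.default_rng(2024)
        cover = 0
        for _ in range(2000):
            fc_e = rng.lognormal(0.0, 0.5, 200)
            fc_c = rng.lognormal(0.0, 0.5, 200)
            r = rs.relative_contribution("f", fc_e, fc_c)
            if r.ci_low <= 1.0 <= r.ci_high:
                cover += 1
        assert abs(cover / 2000 - 0.95) <= 0.015


def brute_force_bonferroni(ps):
    return [min(1.0, len(ps) * p) for p in ps]


def brute_force_bh(ps):
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running_min = min(running_min, m * ps[i] / (rank_idx + 1))
        q[i] = running_min
    return q


class TestAdjustPvalues:
    def test_worked_examples(self):
        bonf, _ = rs.adjust_pvalues([0.001] + [0.5] * 49)
        assert bonf[0] == pytest.approx(0.05)
        _, q = rs.adjust_pvalues([0.01, 0.02, 0.04])
        assert q == pytest.approx([0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        bonf, q = rs.adjust_pvalues([0.2])
        assert bonf == [0.2] and q == [0.2]

    def test_empty_lists(self):
        assert rs.adjust_pvalues([]) == ([], [])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(500):
            m = int(rng.integers(1, 30))
            ps = list(np.round(rng.random(m), 3))
            bonf, q = rs.adjust_pvalues(ps)
            assert bonf == pytest.approx(brute_force_bonferroni(ps), abs=1e-12)
            assert q == pytest.approx(brute_force_bh(ps), abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=20),
           st.randoms(use_true_random=False))
    def test_bh_monotone_and_permutation_invariant(self, ps, rnd):
        _, q = rs.adjust_pvalues(ps)
        order = np.argsort(ps, kind="mergesort")
        sorted_q = np.array(q)[order]
        assert np.all(np.diff(sorted_q) >= -1e-12)
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        _, q_perm = rs.adjust_pvalues([ps[i] for i in perm])
        assert [q_perm[perm.index(i)] for i in range(len(ps))] == pytest.approx(q, abs=1e-12)


class TestRankFeatures:
    def _results(self):
        out = []
        for name, e, c in [("low_q", [5.0, 6.0, 7.0], [1.0, 1.1, 0.9]),
                           ("high_q", [1.0, 1.2, 1.1], [1.0, 1.05, 0.95]),
                           ("undef", [1.0, -2.0], [1.0, 1.0, 1.0])]:
            out.append(rs.relative_contribution(name, np.array(e), np.array(c)))
        bonf, q = rs.adjust_pvalues([r.p_raw for r in out if not math.isnan(r.p_raw)])
        k = 0
        for r in out:
            if not math.isnan(r.p_raw):
                r.p_bonferroni, r.q_fdr = bonf[k], q[k]
                k += 1
        return out

    def test_sorted_by_q_with_undefined_last(self):
        df = rs.rank_features(self._results())
        assert df["Feature Name"].tolist() == ["low_q", "high_q", "undef"]
        assert list(df.columns[:6]) == RC_COLUMNS

    def test_csv_round_trip_preserves_order_and_precision(self, tmp_path):
        df = rs.rank_features(self._results())
        path = tmp_path / "rc.csv"
        rs.write_rc_table(df, path)
        back = pd.read_csv(path)
        assert back["Feature Name"].tolist() == df["Feature Name"].tolist()
        for col in ("RC", "95%CIup", "95%CIdown"):
            a, b = back[col].to_numpy(), df[col].to_numpy()
            mask = ~np.isnan(b)
            assert np.allclose(a[mask], b[mask], rtol=1e-5)


@pytest.fixture(scope="module")
def model_and_seqs(toy_vocab):
    rng = np.random.default_rng(12)
    seqs = make_separable_sequences(16, rng)
    cfg = ModelConfig(architecture="tlstm", embedding_dim=8, hidden_size=8,
                      num_layers=1, dropout=0.0, seed=3)
    model = rs.TrainedModel(config=cfg, params=_init_params(cfg, toy_vocab.size),
                            vocab_fingerprint=toy_vocab.fingerprint(),
                            vocab_size=toy_vocab.size)
    return model, seqs


class TestFeatureContributions:
    def test_ignored_token_has_zero_fc(self, toy_vocab, model_and_seqs):
        model, seqs = model_and_seqs
        tok = 4
        model.params["emb"].data[tok] = 0.0  # model cannot see token 4
        fcs = rs.feature_contributions(model, seqs, toy_vocab)
        for fc in fcs:
            if fc.feature == toy_vocab.id_to_token[tok]:
                assert fc.fc_value == pytest.approx(0.0, abs=1e-12)

    def test_occurrence_drops_sum_per_patient(self, toy_vocab, model_and_seqs):
        model, _ = model_and_seqs
        # token 5 occurs in two visits of the same patient's single sample
        seq = rs.EncodedSequence(visits=[(0, [5, 6]), (3, [5, 7])],
                                 static_tokens=[], label=1, patient_id="pp")
        fcs = rs.feature_contributions(model, [seq], toy_vocab)
        fc5 = [f for f in fcs if f.feature == toy_vocab.id_to_token[5]]
        assert len(fc5) == 1
        base = rs.score_batch(model, [seq])[0]
        drop_a = base - rs.score_batch(model, [rs.EncodedSequence(
            visits=[(0, [6]), (3, [5, 7])], static_tokens=[], label=1, patient_id="pp")])[0]
        drop_b = base - rs.score_batch(model, [rs.EncodedSequence(
            visits=[(0, [5, 6]), (3, [7])], static_tokens=[], label=1, patient_id="pp")])[0]
        assert fc5[0].fc_value == pytest.approx(drop_a + drop_b, abs=1e-12)

    def test_occlusion_deterministic(self, toy_vocab, model_and_seqs):
        model, seqs = model_and_seqs
        a = rs.feature_contributions(model, seqs, toy_vocab)
        b = rs.feature_contributions(model, seqs, toy_vocab)
        assert [(f.feature, f.patient_id, f.fc_value) for f in a] == \
            [(f.feature, f.patient_id, f.fc_value) for f in b]

    def test_absent_token_yields_no_record(self, toy_vocab, model_and_seqs):
        model, _ = model_and_seqs
        seq = rs.EncodedSequence(visits=[(0, [2])], static_tokens=[], label=0,
                                 patient_id="solo")
        fcs = rs.feature_contributions(model, [seq], toy_vocab)
        assert {f.feature for f in fcs} == {toy_vocab.id_to_token[2]}

    def test_noise_mode_seeded_reproducible(self, toy_vocab, model_and_seqs):
        model, seqs = model_and_seqs
        a = rs.feature_contributions(model, seqs[:4], toy_vocab, mode="noise",
                                     n_perturbations=3, seed=5)
        b = rs.feature_contributions(model, seqs[:4], toy_vocab, mode="noise",
                                     n_perturbations=3, seed=5)
        assert [(f.feature, f.fc_value) for f in a] == [(f.feature, f.fc_value) for f in b]

    def test_patient_in_both_groups_gets_two_records(self, toy_vocab, model_and_seqs):
        model, _ = model_and_seqs
        seqs = [rs.EncodedSequence(visits=[(0, [3])], static_tokens=[], label=1,
                                   patient_id="dual"),
                rs.EncodedSequence(visits=[(0, [3])], static_tokens=[], label=0,
                                   patient_id="dual")]
        fcs = rs.feature_contributions(model, seqs, toy_vocab)
        recs = [f for f in fcs if f.feature == toy_vocab.id_to_token[3]]
        assert sorted(f.label for f in recs) == [0, 1]
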