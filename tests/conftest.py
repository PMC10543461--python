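import numpy as np
import pytest

import riskseq as rs


@pytest.fixture(scope="session")
def small_sim_config():
    return rs.SimConfig(
        n_patients=60,
        seed=7,
        planted_effects={"RX_RISK": 4.0},
        baseline_hazard=0.1,
        vocab_sizes={"diagnosis": 10, "medication": 10, "lab": 5,
                     "sdoh_individual": 6, "sdoh_neighborhood": 3},
        encounters_per_patient=(6.0, 1.0),
        followup_days=360,
        n_zip_codes=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_sim_config):
    return rs.generate_dataset(small_sim_config)


@pytest.fixture(scope="session")
def toy_vocab():
    toks = ["<PAD>", "<UNK>"] + [f"t{i}" for i in range(8)]
    return rs.Vocabulary(
        token_to_id={t: i for i, t in enumerate(toks)},
        id_to_token=toks,
        patient_counts={},
    )


def make_separable_sequences(n, rng, signal_token=2, vocab_size=10):
    """Label-1 sequences always contain signal_token; others never do."""
    seqs = []
    for i in range(n):
        y = int(rng.random() < 0.5)
        toks = list(rng.choice(np.arange(3, vocab_size), size=4))
        if y:
            toks.append(signal_token)
        half = len(toks) // 2
        visits = [(0, sorted(set(int(t) for t in toks[:half]))),
                  (7, sorted(set(int(t) for t in toks[half:])))]
        visits = [(d, v) for d, v in visits if v]
        seqs.append(rs.EncodedSequence(visits=visits, static_tokens=[], label=y,
                                       patient_id=f"p{i}"))
    return seqs
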