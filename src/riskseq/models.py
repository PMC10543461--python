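"""Sequence classifiers over coded visit histories: tanh-LSTM and RETAIN.

Two architectures score the probability of an adverse event in the
prediction window from a patient's visit sequence:

* **TLSTM** — stacked LSTM layers whose input/forget/output gates use a
  tanh activation in place of the conventional sigmoid (bounding gate
  outputs in (-1, 1) for stronger gradient signal); visit embeddings are
  the sum of the visit's token embeddings; the final hidden state feeds an
  affine + sigmoid head.
* **RETAIN** — two recurrent nets run over the visit sequence in reverse
  time order produce visit-level attention scalars (softmax alpha) and
  token-level gates (tanh-bounded beta vectors); the context vector
  ``sum_t alpha_t * (beta_t * v_t)`` feeds an affine + sigmoid head, so
  recent influential visits can be read off the attention weights.

Both are trained by minibatch Adam on binary cross-entropy with early
stopping on validation AUROC (strict improvement, configurable patience).
Everything is NumPy on top of :mod:`riskseq.autograd`; inference is
deterministic (dropout only during training).

Static SDoH tokens are injected as a pseudo-visit at the start of the
sequence (configurable to the end), so both architectures consume
identical encoded inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import precision_recall_fscore_support

from .autograd import Adam, Tensor, concat, embedding_bag, softmax_last
from .cohort import CohortConfig, build_samples, find_onsets, split
from .encoding import (
    EncodedSequence, NeighborhoodBinner, Vocabulary, build_vocabulary, encode_fold,
)

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "EvalReport",
    "VocabularyMismatchError",
    "auroc",
    "score",
    "score_batch",
    "train",
    "evaluate",
    "repeat_experiment",
    "save_model",
    "load_model",
]

METRIC_ROWS = ["Validation AUC", "Test AUC", "Test Precision", "Test Recall", "Test F1"]


class VocabularyMismatchError(ValueError):
    """Sequence was encoded under a different vocabulary than the model's."""


@dataclass
class ModelConfig:
    architecture: str = "tlstm"  # "tlstm" | "retain"
    embedding_dim: int = 128
    hidden_size: int = 128
    dropout: float = 0.2
    num_layers: int = 8
    patience: int = 3
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    batch_size: int = 64
    max_epochs: int = 50
    seed: int = 0
    gate_activation: str = "tanh"  # "tanh" | "sigmoid"
    aggregation: str = "sum"  # visit embedding: "sum" | "mean"
    threshold: float = 0.5
    sdoh_position: str = "start"  # pseudo-visit placement: "start" | "end"

    def __post_init__(self):
        if self.architecture not in ("tlstm", "retain"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.gate_activation not in ("tanh", "sigmoid"):
            raise ValueError(f"unknown gate_activation {self.gate_activation!r}")
        if min(self.embedding_dim, self.hidden_size, self.num_layers) <= 0:
            raise ValueError("dims and num_layers must be > 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainedModel:
    config: ModelConfig
    params: dict[str, Tensor]
    vocab_fingerprint: str
    vocab_size: int
    training_log: list[tuple[int, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------

def _visit_lists(seqs: list[EncodedSequence], config: ModelConfig) -> list[list[list[int]]]:
    """Per sample: ordered visits as token-id lists, static pseudo-visit added."""
    out = []
    for s in seqs:
        visits = [ids for _, ids in s.visits]
        if s.static_tokens:
            if config.sdoh_position == "start":
                visits = [list(s.static_tokens)] + visits
            else:
                visits = visits + [list(s.static_tokens)]
        if not visits:
            visits = [[]]  # empty history: single empty visit (zero embedding)
        out.append(visits)
    return out


def _batch_arrays(visit_lists: list[list[list[int]]]):
    """Flatten a batch into embedding-bag form.

    Returns (token_ids, offsets, mask) where bags are laid out time-major
    as ``t * B + b`` and mask is (B, T) with 1 on real visits.
    """
    B = len(visit_lists)
    T = max(len(v) for v in visit_lists)
    ids: list[int] = []
    offsets = [0]
    mask = np.zeros((B, T))
    for t in range(T):
        for b, visits in enumerate(visit_lists):
            if t < len(visits):
                ids.extend(visits[t])
                mask[b, t] = 1.0
            offsets.append(len(ids))
    return np.asarray(ids, dtype=np.intp), np.asarray(offsets, dtype=np.intp), mask


# ---------------------------------------------------------------------------
# parameter init and forward passes
# ---------------------------------------------------------------------------

def _glorot(rng, fan_in, fan_out):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


def _init_params(config: ModelConfig, vocab_size: int) -> dict[str, Tensor]:
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0x1417,)))
    E, H, L = config.embedding_dim, config.hidden_size, config.num_layers
    p: dict[str, np.ndarray] = {"emb": rng.normal(0.0, 0.1, size=(vocab_size, E))}
    p["emb"][0] = 0.0  # PAD row
    if config.architecture == "tlstm":
        for l in range(L):
            din = E if l == 0 else H
            p[f"Wx{l}"] = _glorot(rng, din, 4 * H)
            p[f"Wh{l}"] = _glorot(rng, H, 4 * H)
            p[f"b{l}"] = np.zeros(4 * H)
        p["w_out"] = _glorot(rng, H, 1)
        p["b_out"] = np.zeros(1)
    else:  # retain: two reverse-order recurrent streams (alpha and beta)
        for stream in ("a", "b"):
            for l in range(L):
                din = E if l == 0 else H
                p[f"{stream}Wx{l}"] = _glorot(rng, din, 4 * H)
                p[f"{stream}Wh{l}"] = _glorot(rng, H, 4 * H)
                p[f"{stream}b{l}"] = np.zeros(4 * H)
        p["w_alpha"] = _glorot(rng, H, 1)
        p["b_alpha"] = np.zeros(1)
        p["W_beta"] = _glorot(rng, H, E)
        p["b_beta"] = np.zeros(E)
        p["w_out"] = _glorot(rng, E, 1)
        p["b_out"] = np.zeros(1)
    return {k: Tensor(v, requires_grad=True) for k, v in p.items()}


def _lstm_stack(xs: list[Tensor], mask: np.ndarray, params, prefix: str,
                config: ModelConfig, drop_rng=None) -> list[Tensor]:
    """Run stacked (tanh-gated) LSTM layers over a list of (B, din) steps.

    Masked steps carry the previous state through unchanged. Returns the
    top layer's hidden state at every step. ``drop_rng`` enables inverted
    dropout between layers (training mode).
    """
    H = config.hidden_size
    gate = (lambda t: t.tanh()) if config.gate_activation == "tanh" else (lambda t: t.sigmoid())
    B, T = mask.shape
    seq = xs
    for l in range(config.num_layers):
        Wx, Wh, b = params[f"{prefix}Wx{l}"], params[f"{prefix}Wh{l}"], params[f"{prefix}b{l}"]
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outs: list[Tensor] = []
        for t in range(T):
            z = seq[t].matmul(Wx) + h.matmul(Wh) + b
            i = gate(z.slice_last(0, H))
            f = gate(z.slice_last(H, 2 * H))
            g = z.slice_last(2 * H, 3 * H).tanh()
            o = gate(z.slice_last(3 * H, 4 * H))
            c_new = f * c + i * g
            h_new = o * c_new.tanh()
            m = Tensor(mask[:, t:t + 1])
            c = m * c_new + (1.0 - m) * c
            h = m * h_new + (1.0 - m) * h
            outs.append(h)
        if drop_rng is not None and config.dropout > 0 and l < config.num_layers - 1:
            keep = 1.0 - config.dropout
            outs = [out * Tensor(drop_rng.random((B, H)) < keep) * (1.0 / keep) for out in outs]
        seq = outs
    return seq


def _forward(params: dict[str, Tensor], config: ModelConfig,
             visit_lists: list[list[list[int]]], training: bool = False,
             drop_rng=None, return_attention: bool = False):
    """Batch forward pass; returns probability Tensor of shape (B,)."""
    token_ids, offsets, mask = _batch_arrays(visit_lists)
    B, T = mask.shape
    emb = params["emb"]
    bags = embedding_bag(emb, token_ids, offsets, (T, B))  # (T, B, E)
    if config.aggregation == "mean":
        counts = np.maximum(np.diff(offsets).reshape(T, B), 1)
        bags = bags * Tensor(1.0 / counts[..., None])
    steps = _split_time(bags, T)

    if config.architecture == "tlstm":
        hs = _lstm_stack(steps, mask, params, "", config,
                         drop_rng if training else None)
        logit = hs[-1].matmul(params["w_out"]) + params["b_out"]
        prob = logit.sigmoid().reshape(B)
        return (prob, None) if return_attention else prob

    # RETAIN: reverse-time recurrence for both streams
    rsteps = steps[::-1]
    rmask = mask[:, ::-1]
    ga = _lstm_stack(rsteps, rmask, params, "a", config, drop_rng if training else None)
    gb = _lstm_stack(rsteps, rmask, params, "b", config, drop_rng if training else None)
    ga = ga[::-1]  # back to forward time order
    gb = gb[::-1]
    e_scores = concat([g.matmul(params["w_alpha"]) + params["b_alpha"] for g in ga], axis=1)  # (B, T)
    alpha = softmax_last(e_scores, mask=mask)  # (B, T); pads get exactly 0
    ctx_terms = []
    for t in range(T):
        beta_t = (gb[t].matmul(params["W_beta"]) + params["b_beta"]).tanh()  # (B, E)
        a_t = alpha.slice_last(t, t + 1)  # (B, 1)
        ctx_terms.append(a_t * (beta_t * steps[t]))
    ctx = ctx_terms[0]
    for term in ctx_terms[1:]:
        ctx = ctx + term
    logit = ctx.matmul(params["w_out"]) + params["b_out"]
    prob = logit.sigmoid().reshape(B)
    if return_attention:
        return prob, alpha.data
    return prob


def _split_time(bags: Tensor, T: int) -> list[Tensor]:
    """(T, B, E) Tensor -> list of T (B, E) Tensors (differentiable)."""
    B, E = bags.shape[1], bags.shape[2]
    flat = bags.reshape(T * B, E)
    return [_rows(flat, t * B, (t + 1) * B) for t in range(T)]


def _rows(x: Tensor, start: int, stop: int) -> Tensor:
    """Differentiable row slice of a 2-D Tensor."""
    out = Tensor(x.data[start:stop])
    out.requires_grad = x.requires_grad
    if out.requires_grad:
        out._parents = (x,)

        def _bw(g, start=start, stop=stop):
            full = np.zeros_like(x.data)
            full[start:stop] = g
            return ((x, full),)

        out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# scoring and metrics
# ---------------------------------------------------------------------------

def _check_vocab(model: TrainedModel, seqs: list[EncodedSequence], fingerprint: str | None):
    if fingerprint is not None and fingerprint != model.vocab_fingerprint:
        raise VocabularyMismatchError(
            f"model was trained under vocabulary {model.vocab_fingerprint}, got {fingerprint}")
    for s in seqs:
        ids = [i for _, v in s.visits for i in v] + list(s.static_tokens)
        if ids and max(ids) >= model.vocab_size:
            raise VocabularyMismatchError(
                f"token id {max(ids)} out of range for vocab size {model.vocab_size}")


def score_batch(model: TrainedModel, seqs: list[EncodedSequence],
                vocab_fingerprint: str | None = None) -> np.ndarray:
    """Deterministic inference-mode risk scores in (0, 1)."""
    _check_vocab(model, seqs, vocab_fingerprint)
    out = np.empty(len(seqs))
    bs = max(model.config.batch_size, 1)
    vlists = _visit_lists(seqs, model.config)
    for lo in range(0, len(seqs), bs):
        prob = _forward(model.params, model.config, vlists[lo:lo + bs], training=False)
        out[lo:lo + bs] = prob.data
    return out


def score(model: TrainedModel, seq: EncodedSequence,
          vocab_fingerprint: str | None = None) -> float:
    return float(score_batch(model, [seq], vocab_fingerprint)[0])


def attention_weights(model: TrainedModel, seq: EncodedSequence) -> np.ndarray:
    """RETAIN visit-attention weights (sum to 1 over real visits)."""
    if model.config.architecture != "retain":
        raise ValueError("attention weights are defined for the retain architecture")
    _, alpha = _forward(model.params, model.config,
                        _visit_lists([seq], model.config), return_attention=True)
    return alpha[0]


def auroc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-statistic AUROC with midrank tie handling.

    Equals the probability that a random positive outscores a random
    negative, ties counted half.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC undefined: test set contains a single class")
    r = rankdata(scores)  # average (mid) ranks
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def evaluate(model: TrainedModel, seqs: list[EncodedSequence],
             threshold: float | None = None) -> dict[str, float]:
    """AUROC plus thresholded precision/recall/F1 on a held-out fold."""
    import warnings

    if not seqs:
        raise ValueError("empty evaluation fold")
    thr = model.config.threshold if threshold is None else threshold
    y = np.array([s.label for s in seqs])
    p = score_batch(model, seqs)
    au = auroc(y, p)
    yhat = (p >= thr).astype(int)
    if yhat.sum() == 0:
        warnings.warn("no predicted positives at threshold; precision reported as 0")
    prec, rec, f1, _ = precision_recall_fscore_support(
        y, yhat, average="binary", zero_division=0)
    return {"auroc": au, "precision": float(prec), "recall": float(rec), "f1": float(f1)}


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train(train_seqs: list[EncodedSequence], val_seqs: list[EncodedSequence],
          config: ModelConfig, vocab: Vocabulary) -> TrainedModel:
    """Minibatch Adam on binary cross-entropy; early stop on val AUROC.

    Stops when validation AUROC has not strictly improved for ``patience``
    consecutive epochs; the best-validation parameters are returned.
    Fully deterministic under ``config.seed``.
    """
    if not train_seqs or not val_seqs:
        raise ValueError("training and validation folds must be nonempty")
    y_train = np.array([s.label for s in train_seqs])
    if len(np.unique(y_train)) < 2:
        raise ValueError("training fold contains a single class")

    params = _init_params(config, vocab.size)
    opt = Adam(params, lr=config.learning_rate, weight_decay=config.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0x7A,)))
    drop_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0xD0,)))
    vlists = _visit_lists(train_seqs, config)

    model = TrainedModel(config=config, params=params,
                         vocab_fingerprint=vocab.fingerprint(), vocab_size=vocab.size)
    best_val = -np.inf
    best_params = None
    stale = 0
    eps = 1e-12
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_seqs))
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo:lo + config.batch_size]
            batch = [vlists[i] for i in idx]
            y = Tensor(y_train[idx].astype(float))
            opt.zero_grad()
            p = _forward(params, config, batch, training=True, drop_rng=drop_rng)
            loss = -((y * (p + eps).log() + (1.0 - y) * (1.0 - p + eps).log()).mean())
            loss.backward()
            opt.step()
        val_auroc = auroc(np.array([s.label for s in val_seqs]),
                          score_batch(model, val_seqs))
        model.training_log.append((epoch, float(val_auroc)))
        if val_auroc > best_val:
            best_val = val_auroc
            best_params = {k: p.data.copy() for k, p in params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if best_params is not None:
        for k, p in params.items():
            p.data = best_params[k]
    return model


# ---------------------------------------------------------------------------
# repeated evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-repeat metrics plus mean and sample SD, mirroring the standard
    repeated-evaluation table layout (Validation AUC, Test AUC, Test
    Precision, Test Recall, Test F1)."""

    per_repeat: list[dict[str, float]]

    @property
    def table(self) -> pd.DataFrame:
        n = len(self.per_repeat)
        cols = {str(i + 1): [] for i in range(n)}
        keys = ["val_auc", "test_auc", "test_precision", "test_recall", "test_f1"]
        data = np.array([[rep[k] for rep in self.per_repeat] for k in keys])
        df = pd.DataFrame(data, index=METRIC_ROWS,
                          columns=[str(i + 1) for i in range(n)])
        df["average"] = data.mean(axis=1)
        df["std.s"] = data.std(axis=1, ddof=1) if n > 1 else 0.0
        return df


def repeat_experiment(events, sdoh_table, cohort_config: CohortConfig,
                      model_config: ModelConfig, n_repeats: int = 10,
                      include_sdoh: bool = True, min_patient_count: int = 10,
                      max_visits: int = 200) -> EvalReport:
    """Re-split, retrain and evaluate ``n_repeats`` times with derived seeds."""
    import dataclasses as _dc

    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    binner = NeighborhoodBinner(sdoh_table) if include_sdoh else None
    reps = []
    for r in range(n_repeats):
        sub = int(np.random.SeedSequence(cohort_config.seed, spawn_key=(r,))
                  .generate_state(1)[0] % (2**31))
        cc = _dc.replace(cohort_config, seed=sub)
        mc = _dc.replace(model_config, seed=sub)
        onsets = find_onsets(events, cc)
        samples = build_samples(events, onsets, cc)
        tr, va, te = split(samples, cc)
        vocab = build_vocabulary(tr, min_patient_count, binner=binner,
                                 include_sdoh=include_sdoh)
        kw = dict(binner=binner, include_sdoh=include_sdoh, max_visits=max_visits)
        enc_tr = encode_fold(tr, vocab, **kw)
        enc_va = encode_fold(va, vocab, **kw)
        enc_te = encode_fold(te, vocab, **kw)
        model = train(enc_tr, enc_va, mc, vocab)
        val_m = evaluate(model, enc_va)
        test_m = evaluate(model, enc_te)
        reps.append({
            "val_auc": val_m["auroc"], "test_auc": test_m["auroc"],
            "test_precision": test_m["precision"], "test_recall": test_m["recall"],
            "test_f1": test_m["f1"],
        })
    return EvalReport(per_repeat=reps)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path_npz, path_json) -> None:
    np.savez(path_npz, **{k: p.data for k, p in model.params.items()})
    with open(path_json, "w") as fh:
        json.dump({
            "config": asdict(model.config),
            "vocab_fingerprint": model.vocab_fingerprint,
            "vocab_size": model.vocab_size,
            "training_log": model.training_log,
        }, fh, indent=2)


def load_model(path_npz, path_json) -> TrainedModel:
    with open(path_json) as fh:
        meta = json.load(fh)
    arrs = np.load(path_npz)
    params = {k: Tensor(arrs[k], requires_grad=True) for k in arrs.files}
    return TrainedModel(
        config=ModelConfig(**meta["config"]), params=params,
        vocab_fingerprint=meta["vocab_fingerprint"], vocab_size=meta["vocab_size"],
        training_log=[tuple(x) for x in meta["training_log"]],
    )
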