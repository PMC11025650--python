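"""The Sentence Gestalt network and its Semantic Update measure.

The model has two components.  The *update network* (encoder) maps a word
sequence to a sequence of latent gestalt states: a learned input embedding
feeds a one-layer LSTM whose hidden state after word t is the gestalt
sg_t, a distributed representation of the sentence meaning given words
1..t.  The *query network* (decoder) combines a gestalt state with a probe
vector through a tanh hidden layer and produces, through per-unit logistic
outputs, the completed role-filler vector.  Training interrogates the model
with every sentence probe after every word, so the gestalt must anticipate
all arguments of the event before their words arrive; the error signal is
Bernoulli cross-entropy between completion and target.

Semantic Update (SU) is the mean absolute difference between consecutive
gestalt states — the amount by which a word changes the implicit predictive
representation of sentence meaning — and is the model's correlate of
single-trial N400 amplitude.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from ._nn import LSTM, Adamax, glorot, sigmoid, accumulate_embedding_grad
from .corpus_io import (
    EncodingConfig,
    FillerFeatureTable,
    FrameAnnotatedSentence,
    Lexicon,
    build_lexicon,
    binarize_embeddings,
    encode_probes,
    synthetic_embeddings,
)

logger = logging.getLogger("sgn400")

_EPS = 1e-12


@dataclass
class SGConfig:
    """Sizes and training hyperparameters.

    Defaults are desk scale (small sizes for laptop-speed experiments);
    ``SGConfig.paper_scale()`` restores the full-scale sizes (600-unit
    embeddings, 1,200-unit gestalt, 150-epoch cap).  The learning-rate and
    batch settings are the same at both scales.
    """

    embedding_size: int = 32
    gestalt_size: int = 64
    query_hidden: int = 64
    learning_rate: float = 0.01     # Adamax
    batch_size: int = 32            # sentences per mini-batch
    max_epochs: int = 40
    validation_fraction: float = 0.10
    patience: int = 10              # early-stopping patience (epochs)
    seed: int = 0
    filler_mode: str = "semantic-features"   # or "lexical-one-hot"
    max_lexicon: int = 6000
    su_state: str = "hidden"        # gestalt read-out: "hidden" or "hidden+cell"

    def __post_init__(self):
        if min(self.embedding_size, self.gestalt_size, self.query_hidden) < 1:
            raise ValueError("layer sizes must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation fraction must be in (0, 1)")
        if self.filler_mode not in ("semantic-features", "lexical-one-hot"):
            raise ValueError(f"unknown filler_mode {self.filler_mode!r}")

    @classmethod
    def paper_scale(cls, **kw) -> "SGConfig":
        return cls(embedding_size=600, gestalt_size=1200, query_hidden=1200,
                   max_epochs=150, **kw)


@dataclass
class SGModel:
    params: dict[str, np.ndarray]
    lexicon: Lexicon
    encoding: EncodingConfig
    config: SGConfig

    @property
    def lstm(self) -> LSTM:
        return LSTM(self.params, "u_", self.config.gestalt_size)

    def save(self, path: str | Path) -> None:
        meta = {
            "config": asdict(self.config),
            "lexicon": dict(self.lexicon.index),
            "encoding": {
                "role_inventory": list(self.encoding.role_inventory),
                "n_features": self.encoding.n_features,
                "n_frames": self.encoding.n_frames,
            },
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "SGModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            params = {k: data[k] for k in data.files if k != "__meta__"}
        enc = meta["encoding"]
        return cls(
            params=params,
            lexicon=Lexicon(meta["lexicon"]),
            encoding=EncodingConfig(tuple(enc["role_inventory"]),
                                    enc["n_features"], enc["n_frames"]),
            config=SGConfig(**meta["config"]),
        )


# ---------------------------------------------------------------------------
# Forward passes
# ---------------------------------------------------------------------------

def sg_forward(model: SGModel, tokens: Sequence[str], state: str | None = None) -> np.ndarray:
    """Gestalt trajectory (T x H) for a token sequence.

    Only the word sequence drives the encoder; probes play no role here.
    ``state`` selects the gestalt read-out used downstream: the LSTM hidden
    vector (default) or the hidden and cell vectors concatenated.
    """
    if len(tokens) == 0:
        raise ValueError("empty sentence")
    state = state or model.config.su_state
    ids = model.lexicon.encode(tokens)
    xs = model.params["E"][ids]
    hs, cache = model.lstm.forward(xs)
    if state == "hidden":
        return hs
    if state == "hidden+cell":
        return np.concatenate([hs, cache[2]], axis=1)
    raise ValueError(f"unknown gestalt state read-out {state!r}")


def query(model: SGModel, sg_state: np.ndarray, probe_vector: np.ndarray) -> np.ndarray:
    """Query-network completion of a probe given one gestalt state; per-unit
    logistic activations in (0, 1) over the full role-filler layout."""
    if probe_vector.shape[-1] != model.encoding.output_width:
        raise ValueError(
            f"probe width {probe_vector.shape[-1]} != output width "
            f"{model.encoding.output_width}"
        )
    h = np.tanh(sg_state @ model.params["q_Ws"] + probe_vector @ model.params["q_Wp"]
                + model.params["q_bh"])
    return sigmoid(h @ model.params["q_Wo"] + model.params["q_bo"])


def decode_filler(model: SGModel, sg_state: np.ndarray, role: str, frame_index: int,
                  candidates: Sequence[str], features: FillerFeatureTable) -> str:
    """Nearest-target decoding: present the filler-probe for (role, frame)
    and return the candidate word whose feature vector best matches the
    completed filler part (lowest cross-entropy)."""
    enc = model.encoding
    probe = np.concatenate([np.zeros(enc.n_features), enc.role_onehot(role),
                            enc.frame_onehot(frame_index)])
    out = query(model, sg_state, probe)[: enc.n_features]
    best, best_ce = None, np.inf
    for w in candidates:
        t = features.get(w)
        ce = -np.sum(t * np.log(out + _EPS) + (1 - t) * np.log(1 - out + _EPS))
        if ce < best_ce:
            best, best_ce = w, ce
    return best


# ---------------------------------------------------------------------------
# Semantic Update
# ---------------------------------------------------------------------------

def mean_abs_update(trajectory: np.ndarray) -> np.ndarray:
    """Per-word mean absolute change of a latent trajectory.

    ``update_t = (1/H) * sum_j |x_t[j] - x_{t-1}[j]|`` with the state before
    the first word taken to be the zero vector, so the first entry is the
    mean absolute activation after word one.
    """
    traj = np.asarray(trajectory, dtype=np.float64)
    if traj.ndim != 2 or traj.shape[0] < 1:
        raise ValueError("trajectory must be a non-empty (T, H) matrix")
    prev = np.vstack([np.zeros((1, traj.shape[1])), traj[:-1]])
    return np.abs(traj - prev).mean(axis=1)


def semantic_update(trajectory: np.ndarray) -> np.ndarray:
    """Semantic Update series of a gestalt trajectory (alias of the shared
    mean-absolute-update formula; nonnegative, one value per word)."""
    return mean_abs_update(trajectory)


def score_su(model: SGModel, sentences: Sequence[Sequence[str]],
             drop_initial: bool = False) -> list[np.ndarray]:
    """SU series for each token sequence; optionally drop the
    sentence-initial value (which reflects the zero initial state)."""
    out = []
    for toks in sentences:
        su = semantic_update(sg_forward(model, toks))
        out.append(su[1:] if drop_initial else su)
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _init_params(cfg: SGConfig, vocab: int, out_width: int,
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    params: dict[str, np.ndarray] = {}
    params["E"] = 0.1 * rng.standard_normal((vocab, cfg.embedding_size))
    LSTM.init(params, "u_", cfg.embedding_size, cfg.gestalt_size, rng)
    params["q_Ws"] = glorot(rng, cfg.gestalt_size, cfg.query_hidden)
    params["q_Wp"] = glorot(rng, out_width, cfg.query_hidden)
    params["q_bh"] = np.zeros(cfg.query_hidden)
    params["q_Wo"] = glorot(rng, cfg.query_hidden, out_width)
    params["q_bo"] = np.zeros(out_width)
    return params


def _sentence_loss_and_grads(model: SGModel, ids: np.ndarray, probes: np.ndarray,
                             targets: np.ndarray, grads: dict | None):
    """Loss (and gradients if ``grads`` is given) for one sentence.

    After every word, every sentence probe is presented; the loss is the
    Bernoulli cross-entropy summed over output units, averaged over the
    probes of a word, summed over words.
    """
    p = model.params
    xs = p["E"][ids]
    lstm = model.lstm
    hs, cache = lstm.forward(xs)              # (T, H)
    A = hs @ p["q_Ws"]                        # (T, Q)
    B = probes @ p["q_Wp"]                    # (P, Q)
    Hq = np.tanh(A[:, None, :] + B[None, :, :] + p["q_bh"])   # (T, P, Q)
    out = sigmoid(Hq @ p["q_Wo"] + p["q_bo"])                 # (T, P, O)
    n_probes = probes.shape[0]
    tgt = targets[None, :, :]
    ce = -(tgt * np.log(out + _EPS) + (1 - tgt) * np.log(1 - out + _EPS))
    loss = ce.sum() / n_probes
    if grads is None:
        return loss
    d_pre = (out - tgt) / n_probes            # (T, P, O)
    T, P, Q = Hq.shape
    O = out.shape[-1]
    grads["q_Wo"] = grads.get("q_Wo", 0) + Hq.reshape(-1, Q).T @ d_pre.reshape(-1, O)
    grads["q_bo"] = grads.get("q_bo", 0) + d_pre.sum(axis=(0, 1))
    dHq = (d_pre @ p["q_Wo"].T) * (1.0 - Hq ** 2)
    grads["q_bh"] = grads.get("q_bh", 0) + dHq.sum(axis=(0, 1))
    dA = dHq.sum(axis=1)                      # (T, Q)
    dB = dHq.sum(axis=0)                      # (P, Q)
    grads["q_Ws"] = grads.get("q_Ws", 0) + hs.T @ dA
    grads["q_Wp"] = grads.get("q_Wp", 0) + probes.T @ dB
    dhs = dA @ p["q_Ws"].T
    dxs = lstm.backward(dhs, cache, grads)
    accumulate_embedding_grad(grads, "E", p["E"].shape, ids, dxs)
    return loss


def train_sg(
    corpus: Sequence[FrameAnnotatedSentence],
    config: SGConfig | None = None,
    features: FillerFeatureTable | None = None,
    encoding: EncodingConfig | None = None,
    lexicon: Lexicon | None = None,
) -> tuple[SGModel, dict]:
    """Train the Sentence Gestalt network on a frame-annotated corpus.

    The corpus should already satisfy the training filters (6-15 words,
    <= 8 frames).  Sentences are shuffled once, cut into mini-batches of
    ``batch_size``, and split 90/10 into training and validation batches;
    optimization uses Adamax with early stopping on validation loss, and the
    best-validation weights are returned.

    When ``features`` is omitted, semantic-feature mode binarizes seeded
    synthetic embeddings over the corpus vocabulary; lexical-one-hot mode
    uses word-identity features (output width = lexicon size + R + K).
    """
    config = config or SGConfig()
    if not corpus:
        raise ValueError("empty training corpus")
    rng = np.random.default_rng(config.seed)
    lexicon = lexicon or build_lexicon(corpus, config.max_lexicon)

    encoding = encoding or EncodingConfig()
    if config.filler_mode == "lexical-one-hot":
        features = FillerFeatureTable.identity(lexicon)
        encoding = EncodingConfig(encoding.role_inventory, len(lexicon),
                                  encoding.n_frames)
    elif features is None:
        vocab_words = sorted({t.lower() for s in corpus for t in s.tokens})
        emb = synthetic_embeddings(vocab_words, encoding.n_features,
                                   seed=config.seed + 1)
        features = binarize_embeddings(emb)
    if features.n_features != encoding.n_features:
        raise ValueError("feature table width does not match encoding n_features")

    model = SGModel(_init_params(config, len(lexicon), encoding.output_width, rng),
                    lexicon, encoding, config)

    # Pre-encode every sentence once: token ids, probe matrix, target matrix.
    encoded = []
    for s in corpus:
        pairs = encode_probes(s, features, encoding)
        if not pairs:
            continue
        probes = np.stack([pr.vector for pr, _ in pairs])
        targets = np.stack([t for _, t in pairs])
        encoded.append((lexicon.encode(s.tokens), probes, targets))
    if not encoded:
        raise ValueError("no probe-bearing sentences in corpus")

    order = rng.permutation(len(encoded))
    bs = config.batch_size
    batches = [order[i:i + bs] for i in range(0, len(order), bs)]
    n_val = max(1, int(round(config.validation_fraction * len(batches)))) \
        if len(batches) > 1 else 0
    val_batches, train_batches = batches[:n_val], batches[n_val:]
    if not train_batches:
        train_batches, val_batches = batches, []

    opt = Adamax(model.params, lr=config.learning_rate)
    log = {"train": [], "val": [], "n_train_batches": len(train_batches),
           "n_val_batches": len(val_batches)}
    best_val = np.inf
    best_params = None
    stale = 0
    for epoch in range(config.max_epochs):
        ep_loss = 0.0
        for batch in train_batches:
            grads: dict[str, np.ndarray] = {}
            bloss = 0.0
            for j in batch:
                bloss += _sentence_loss_and_grads(model, *encoded[j], grads)
            for k in grads:
                grads[k] = grads[k] / len(batch)
            opt.step(grads)
            ep_loss += bloss / len(batch)
        log["train"].append(ep_loss / len(train_batches))
        if val_batches:
            vloss = np.mean([
                _sentence_loss_and_grads(model, *encoded[j], None)
                for b in val_batches for j in b
            ])
        else:
            vloss = log["train"][-1]
        log["val"].append(float(vloss))
        if vloss < best_val - 1e-9:
            best_val = vloss
            best_params = {k: v.copy() for k, v in model.params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                logger.info("SG early stop at epoch %d (best val %.4f)", epoch, best_val)
                break
    if best_params is not None:
        model.params = best_params
    return model, log


def validation_loss(model: SGModel, corpus: Sequence[FrameAnnotatedSentence],
                    features: FillerFeatureTable) -> float:
    """Mean per-sentence probe loss of a model on a corpus."""
    losses = []
    for s in corpus:
        pairs = encode_probes(s, features, model.encoding)
        if not pairs:
            continue
        probes = np.stack([pr.vector for pr, _ in pairs])
        targets = np.stack([t for _, t in pairs])
        losses.append(_sentence_loss_and_grads(
            model, model.lexicon.encode(s.tokens), probes, targets, None))
    return float(np.mean(losses))
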