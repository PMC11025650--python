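"""The matched next-word-prediction language model.

Architecturally the twin of the Sentence Gestalt encoder — learned input
embeddings feeding a one-layer LSTM, then a tanh hidden layer — but with a
softmax output over the lexicon, trained on the raw word sequences with the
semantic annotation discarded.  From a trained model we extract two
per-word series:

* **surprisal**: ``surp(w_t) = -ln P(w_t | <s>, w_1..w_{t-1})`` in nats.
  A sentence-start symbol conditions the first word, so first-word
  surprisal is defined; conditioning is per sentence, matching word-by-word
  sentence presentation.  Summed over a sentence, surprisal equals the
  negative log-probability of the sentence under the model (chain rule).
* **internal update**: the same mean-absolute-change formula as Semantic
  Update, applied to the LSTM recurrent trajectory — the LM's analogue of
  the gestalt update.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from ._nn import LSTM, Adamax, glorot, softmax, accumulate_embedding_grad
from .corpus_io import FrameAnnotatedSentence, Lexicon, build_lexicon
from .sg_model import mean_abs_update

logger = logging.getLogger("sgn400")

#: Probability floor when scoring: a zero-probability word is capped at
#: surprisal -ln(PROB_FLOOR) with a warning.
PROB_FLOOR = 1e-12


@dataclass
class LMConfig:
    """Desk-scale defaults; ``LMConfig.paper_scale()`` restores the
    600/1,200 layer sizes and the 150-epoch cap (lexicon capped at the
    full-scale 300,000 there, 6,000 here)."""

    embedding_size: int = 32
    hidden_size: int = 64           # LSTM recurrent layer
    post_hidden: int = 64           # tanh layer between LSTM and softmax
    max_lexicon: int = 6000
    learning_rate: float = 0.002    # Adamax
    batch_size: int = 32
    max_epochs: int = 30
    validation_fraction: float = 0.10
    patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if min(self.embedding_size, self.hidden_size, self.post_hidden) < 1:
            raise ValueError("layer sizes must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation fraction must be in (0, 1)")

    @classmethod
    def paper_scale(cls, **kw) -> "LMConfig":
        return cls(embedding_size=600, hidden_size=1200, post_hidden=1200,
                   max_lexicon=300_000, max_epochs=150, **kw)


@dataclass
class LMModel:
    params: dict[str, np.ndarray]
    lexicon: Lexicon
    config: LMConfig

    @property
    def lstm(self) -> LSTM:
        return LSTM(self.params, "r_", self.config.hidden_size)

    def save(self, path: str | Path) -> None:
        meta = {"config": asdict(self.config), "lexicon": dict(self.lexicon.index)}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "LMModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            params = {k: data[k] for k in data.files if k != "__meta__"}
        return cls(params, Lexicon(meta["lexicon"]), LMConfig(**meta["config"]))


# ---------------------------------------------------------------------------
# Forward pass and scoring
# ---------------------------------------------------------------------------

def lm_forward(model: LMModel, tokens: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Next-word distributions and recurrent trajectory for one sentence.

    The start symbol is prepended internally: distribution t predicts token
    t of the input, and the trajectory row t is the recurrent state after
    reading token t (T rows for T tokens, start-symbol state excluded).
    """
    if len(tokens) == 0:
        raise ValueError("empty sentence")
    p = model.params
    ids = model.lexicon.encode(tokens)
    inp = np.concatenate([[model.lexicon.start_index], ids])
    xs = p["E"][inp]
    hs, _ = model.lstm.forward(xs)                 # (T+1, H)
    h2 = np.tanh(hs @ p["h_W"] + p["h_b"])
    dists = softmax(h2 @ p["o_W"] + p["o_b"], axis=1)   # (T+1, V)
    return dists[:-1], hs[1:]


def surprisal(model: LMModel, tokens: Sequence[str]) -> np.ndarray:
    """Per-word surprisal in nats; zero-probability words are capped at
    -ln(PROB_FLOOR) with a warning."""
    dists, _ = lm_forward(model, tokens)
    ids = model.lexicon.encode(tokens)
    probs = dists[np.arange(len(ids)), ids]
    if (probs < PROB_FLOOR).any():
        logger.warning("capping %d near-zero word probabilities at %.0e",
                       int((probs < PROB_FLOOR).sum()), PROB_FLOOR)
        probs = np.maximum(probs, PROB_FLOOR)
    return -np.log(probs)


def internal_update(recurrent_trajectory: np.ndarray) -> np.ndarray:
    """Mean absolute change of the LM recurrent state per word (identical
    formula and implementation as the gestalt Semantic Update)."""
    return mean_abs_update(recurrent_trajectory)


def perplexity(model: LMModel, sentences: Sequence[Sequence[str]]) -> float:
    """exp(mean per-token surprisal) over a set of sentences."""
    total, n = 0.0, 0
    for toks in sentences:
        s = surprisal(model, toks)
        total += s.sum()
        n += len(s)
    return float(np.exp(total / n))


def unigram_perplexity(train: Sequence[Sequence[str]],
                       test: Sequence[Sequence[str]]) -> float:
    """Held-out perplexity of an add-one-smoothed unigram count model over
    the training vocabulary; the baseline a trained LM must beat."""
    from collections import Counter
    counts = Counter(t.lower() for s in train for t in s)
    vocab = set(counts) | {t.lower() for s in test for t in s}
    total = sum(counts.values())
    denom = total + len(vocab)
    ll, n = 0.0, 0
    for s in test:
        for t in s:
            ll += np.log((counts.get(t.lower(), 0) + 1) / denom)
            n += 1
    return float(np.exp(-ll / n))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _lm_loss_and_grads(model: LMModel, ids: np.ndarray, grads: dict | None):
    """Summed next-word cross-entropy for one sentence (start symbol
    prepended); accumulates gradients when ``grads`` is given."""
    p = model.params
    inp = np.concatenate([[model.lexicon.start_index], ids[:-1]])
    xs = p["E"][inp]
    lstm = model.lstm
    hs, cache = lstm.forward(xs)                  # (T, H)
    h2 = np.tanh(hs @ p["h_W"] + p["h_b"])
    logits = h2 @ p["o_W"] + p["o_b"]
    dists = softmax(logits, axis=1)
    T = len(ids)
    loss = -np.log(dists[np.arange(T), ids] + PROB_FLOOR).sum()
    if grads is None:
        return loss
    d_logits = dists.copy()
    d_logits[np.arange(T), ids] -= 1.0
    grads["o_W"] = grads.get("o_W", 0) + h2.T @ d_logits
    grads["o_b"] = grads.get("o_b", 0) + d_logits.sum(axis=0)
    dh2 = (d_logits @ p["o_W"].T) * (1.0 - h2 ** 2)
    grads["h_W"] = grads.get("h_W", 0) + hs.T @ dh2
    grads["h_b"] = grads.get("h_b", 0) + dh2.sum(axis=0)
    dhs = dh2 @ p["h_W"].T
    dxs = lstm.backward(dhs, cache, grads)
    accumulate_embedding_grad(grads, "E", p["E"].shape, inp, dxs)
    return loss


def train_lm(
    corpus: Sequence[Sequence[str]] | Sequence[FrameAnnotatedSentence],
    config: LMConfig | None = None,
    lexicon: Lexicon | None = None,
) -> tuple[LMModel, dict]:
    """Train the LM on raw token sequences (frame annotation, if present,
    is ignored).  Same regime as the SG model: Adamax, mini-batches of 32
    sentences, 90/10 train/validation batch split, early stopping, and the
    best-validation weights returned."""
    config = config or LMConfig()
    if not corpus:
        raise ValueError("empty training corpus")
    token_seqs = [s.tokens if isinstance(s, FrameAnnotatedSentence) else tuple(s)
                  for s in corpus]
    if lexicon is None:
        frames_free = [FrameAnnotatedSentence(t, ()) for t in token_seqs]
        lexicon = build_lexicon(frames_free, config.max_lexicon)
    rng = np.random.default_rng(config.seed)

    params: dict[str, np.ndarray] = {}
    params["E"] = 0.1 * rng.standard_normal((len(lexicon), config.embedding_size))
    LSTM.init(params, "r_", config.embedding_size, config.hidden_size, rng)
    params["h_W"] = glorot(rng, config.hidden_size, config.post_hidden)
    params["h_b"] = np.zeros(config.post_hidden)
    params["o_W"] = glorot(rng, config.post_hidden, len(lexicon))
    params["o_b"] = np.zeros(len(lexicon))
    model = LMModel(params, lexicon, config)

    encoded = [lexicon.encode(t) for t in token_seqs]
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
    best_val, best_params, stale = np.inf, None, 0
    for epoch in range(config.max_epochs):
        ep_loss = 0.0
        for batch in train_batches:
            grads: dict[str, np.ndarray] = {}
            bloss = 0.0
            ntok = 0
            for j in batch:
                bloss += _lm_loss_and_grads(model, encoded[j], grads)
                ntok += len(encoded[j])
            for k in grads:
                grads[k] = grads[k] / ntok
            opt.step(grads)
            ep_loss += bloss / ntok
        log["train"].append(ep_loss / len(train_batches))
        if val_batches:
            vtot, vn = 0.0, 0
            for b in val_batches:
                for j in b:
                    vtot += _lm_loss_and_grads(model, encoded[j], None)
                    vn += len(encoded[j])
            vloss = vtot / vn
        else:
            vloss = log["train"][-1]
        log["val"].append(float(vloss))
        if vloss < best_val - 1e-9:
            best_val, stale = vloss, 0
            best_params = {k: v.copy() for k, v in model.params.items()}
        else:
            stale += 1
            if stale >= config.patience:
                logger.info("LM early stop at epoch %d (best val %.4f)", epoch, best_val)
                break
    if best_params is not None:
        model.params = best_params
    return model, log
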