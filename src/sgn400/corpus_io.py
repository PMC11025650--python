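"""Frame-annotated corpora, lexica, and role-filler/probe encodings.

A corpus is a sequence of sentences, each carrying the PropBank-style event
frames it describes: every frame has a predicate and a list of
(role, filler) arguments.  Sentences are serialized as JSON Lines, one
sentence per line::

    {"tokens": ["the", "boy", "opened", "the", "door", "."],
     "frames": [{"index": 1, "predicate": "opened",
                 "args": [{"role": "A0", "filler": "boy"},
                          {"role": "V",  "filler": "opened"},
                          {"role": "A1", "filler": "door"}]}]}

The event representation used for training the Sentence Gestalt network is a
set of role-filler vectors: the concatenation of a binary semantic feature
vector for the filler word, a one-hot thematic-role identifier, and a
one-hot frame index.  A probe is the same vector with either the role part
(role-probe) or the filler part (filler-probe) zeroed; the network must
complete the full vector.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("sgn400")

#: Default PropBank-style role inventory (26 labels: numbered arguments plus
#: the common modifier roles).
DEFAULT_ROLE_INVENTORY: tuple[str, ...] = (
    "A0", "A1", "A2", "A3", "A4", "A5", "V",
    "AM-ADV", "AM-CAU", "AM-DIR", "AM-DIS", "AM-EXT", "AM-LOC",
    "AM-MNR", "AM-MOD", "AM-NEG", "AM-PNC", "AM-PRD", "AM-REC",
    "AM-TMP", "C-A1", "C-V", "R-A0", "R-A1", "R-AM-LOC", "R-AM-TMP",
)

#: Compact inventory used by the synthetic micro-language.
MICRO_ROLE_INVENTORY: tuple[str, ...] = ("A0", "V", "A1", "AM-LOC", "AM-MNR", "AM-TMP")

OOV_TOKEN = "<oov>"
START_TOKEN = "<s>"


class CorpusParseError(ValueError):
    """Malformed corpus record; message carries the 1-based line number."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Frame:
    index: int
    predicate: str
    args: tuple[tuple[str, str], ...]  # (role label, filler word)


@dataclass(frozen=True)
class FrameAnnotatedSentence:
    """Token sequence plus the nested event frames it describes."""

    tokens: tuple[str, ...]
    frames: tuple[Frame, ...]

    def validate(self, role_inventory: Sequence[str]) -> None:
        if len(self.tokens) < 1:
            raise ValueError("sentence must contain at least one token")
        indices = [f.index for f in self.frames]
        if indices != list(range(1, len(indices) + 1)):
            raise ValueError(f"frame indices must be contiguous from 1, got {indices}")
        roles = set(role_inventory)
        for f in self.frames:
            for role, filler in f.args:
                if role not in roles:
                    raise ValueError(f"unknown role label {role!r}")
                if not isinstance(filler, str) or not filler or " " in filler:
                    raise ValueError(f"filler must be a single word, got {filler!r}")

    @property
    def n_words(self) -> int:
        return len(self.tokens)

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class Lexicon:
    """Contiguous word -> index mapping with OOV and sentence-start symbols."""

    index: Mapping[str, int]

    def __post_init__(self):
        vals = sorted(self.index.values())
        if vals != list(range(len(vals))):
            raise ValueError("lexicon indices must be contiguous from 0")
        for special in (OOV_TOKEN, START_TOKEN):
            if special not in self.index:
                raise ValueError(f"lexicon must contain {special!r}")

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, word: str) -> bool:
        return word in self.index

    def get(self, word: str) -> int:
        """Index of ``word`` (lower-cased), or the OOV index."""
        return self.index.get(word.lower(), self.index[OOV_TOKEN])

    def encode(self, tokens: Iterable[str]) -> np.ndarray:
        return np.array([self.get(t) for t in tokens], dtype=np.int64)

    @property
    def oov_index(self) -> int:
        return self.index[OOV_TOKEN]

    @property
    def start_index(self) -> int:
        return self.index[START_TOKEN]

    @property
    def words(self) -> list[str]:
        inv = {i: w for w, i in self.index.items()}
        return [inv[i] for i in range(len(inv))]


@dataclass
class FillerFeatureTable:
    """word -> fixed-length binary semantic feature vector (values in {0,1})."""

    features: dict[str, np.ndarray]
    n_features: int

    def __post_init__(self):
        for w, v in self.features.items():
            v = np.asarray(v)
            if v.shape != (self.n_features,):
                raise ValueError(f"feature vector for {w!r} has wrong length")
            if not np.isin(v, (0, 1)).all():
                raise ValueError(f"feature vector for {w!r} is not binary")
            self.features[w] = v.astype(np.float64)

    def get(self, word: str) -> np.ndarray:
        """Features of ``word``; unknown fillers map to all-zeros with a warning."""
        w = word.lower()
        if w not in self.features:
            logger.warning("OOV filler %r mapped to zero feature vector", word)
            return np.zeros(self.n_features)
        return self.features[w]

    @classmethod
    def identity(cls, lexicon: Lexicon) -> "FillerFeatureTable":
        """Lexical one-hot features: each word is its own single feature.

        Used by the lexical-filler Sentence Gestalt variant, in which the
        network predicts the lexical form of fillers rather than semantic
        features.
        """
        n = len(lexicon)
        feats = {}
        for w, i in lexicon.index.items():
            v = np.zeros(n)
            v[i] = 1.0
            feats[w] = v
        return cls(feats, n)


@dataclass(frozen=True)
class EncodingConfig:
    """Width bookkeeping for role-filler vectors: F + R + K total units."""

    role_inventory: tuple[str, ...] = MICRO_ROLE_INVENTORY
    n_features: int = 16        # F: filler feature units
    n_frames: int = 2           # K: one-hot frame-index units

    @property
    def n_roles(self) -> int:
        return len(self.role_inventory)

    @property
    def output_width(self) -> int:
        return self.n_features + self.n_roles + self.n_frames

    def role_onehot(self, role: str) -> np.ndarray:
        v = np.zeros(self.n_roles)
        v[self.role_inventory.index(role)] = 1.0
        return v

    def frame_onehot(self, index: int) -> np.ndarray:
        if not 1 <= index <= self.n_frames:
            raise ValueError(
                f"frame index {index} exceeds configured maximum {self.n_frames}"
            )
        v = np.zeros(self.n_frames)
        v[index - 1] = 1.0
        return v


@dataclass(frozen=True)
class Probe:
    """A role-filler vector with one part zeroed; the query-network input."""

    vector: np.ndarray
    probe_kind: str  # "role" (role part zeroed) or "filler" (filler part zeroed)


# ---------------------------------------------------------------------------
# Corpus serialization
# ---------------------------------------------------------------------------

def read_frame_corpus(
    path: str | Path,
    role_inventory: Sequence[str] = DEFAULT_ROLE_INVENTORY,
) -> list[FrameAnnotatedSentence]:
    """Read a JSONL frame-annotated corpus; raises CorpusParseError with the
    offending 1-based line number on any malformed record."""
    sentences = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                frames = tuple(
                    Frame(
                        index=int(fr["index"]),
                        predicate=str(fr["predicate"]),
                        args=tuple((a["role"], a["filler"]) for a in fr["args"]),
                    )
                    for fr in rec["frames"]
                )
                sent = FrameAnnotatedSentence(tuple(rec["tokens"]), frames)
                sent.validate(role_inventory)
            except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
                raise CorpusParseError(f"line {lineno}: {exc}") from exc
            sentences.append(sent)
    return sentences


def write_frame_corpus(path: str | Path, corpus: Iterable[FrameAnnotatedSentence]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sent in corpus:
            rec = {
                "tokens": list(sent.tokens),
                "frames": [
                    {
                        "index": f.index,
                        "predicate": f.predicate,
                        "args": [{"role": r, "filler": w} for r, w in f.args],
                    }
                    for f in sent.frames
                ],
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# Lexicon and embeddings
# ---------------------------------------------------------------------------

def build_lexicon(corpus: Sequence[FrameAnnotatedSentence], max_size: int) -> Lexicon:
    """Lexicon of the ``max_size`` most frequent (lower-cased) word forms,
    plus the OOV and sentence-start specials.  Ties break lexicographically."""
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    if not corpus:
        raise ValueError("corpus is empty")
    counts = Counter(t.lower() for s in corpus for t in s.tokens)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    kept = [w for w, _ in ranked[:max_size]]
    index = {OOV_TOKEN: 0, START_TOKEN: 1}
    for w in kept:
        index[w] = len(index)
    return Lexicon(index)


def read_word2vec_text(path: str | Path) -> dict[str, np.ndarray]:
    """Read a word2vec-style text embedding file ("V F" header, then one
    word and F floats per line)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        n_words, dim = int(header[0]), int(header[1])
        table = {}
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(f"embedding row for {parts[0]!r} has wrong length")
            table[parts[0]] = np.array(parts[1:], dtype=np.float64)
    if len(table) != n_words:
        raise ValueError(f"header declares {n_words} words, file has {len(table)}")
    return table


def write_word2vec_text(path: str | Path, table: Mapping[str, np.ndarray]) -> None:
    dims = {len(v) for v in table.values()}
    if len(dims) != 1:
        raise ValueError("ragged embedding table")
    (dim,) = dims
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(table)} {dim}\n")
        for w, v in table.items():
            fh.write(w + " " + " ".join(f"{x:.6g}" for x in v) + "\n")


def binarize_embeddings(
    real_embeddings: Mapping[str, np.ndarray], threshold: float = 0.0
) -> FillerFeatureTable:
    """Threshold real-valued embeddings into binary presence/absence features:
    a unit is 1 iff its raw value is strictly greater than ``threshold``."""
    dims = {len(v) for v in real_embeddings.values()}
    if len(dims) != 1:
        raise ValueError("ragged embedding table")
    (dim,) = dims
    feats = {
        w.lower(): (np.asarray(v, dtype=np.float64) > threshold).astype(np.float64)
        for w, v in real_embeddings.items()
    }
    return FillerFeatureTable(feats, dim)


def synthetic_embeddings(
    words: Sequence[str], dim: int = 16, seed: int = 0
) -> dict[str, np.ndarray]:
    """Seeded Gaussian stand-in embeddings for micro-language fillers."""
    rng = np.random.default_rng(seed)
    return {w: rng.standard_normal(dim) for w in words}


# ---------------------------------------------------------------------------
# Probe construction and training filters
# ---------------------------------------------------------------------------

def _role_filler_vector(
    cfg: EncodingConfig, features: FillerFeatureTable, frame_index: int,
    role: str, filler: str,
) -> np.ndarray:
    return np.concatenate(
        [features.get(filler), cfg.role_onehot(role), cfg.frame_onehot(frame_index)]
    )


def encode_probes(
    sentence: FrameAnnotatedSentence,
    features: FillerFeatureTable,
    cfg: EncodingConfig,
) -> list[tuple[Probe, np.ndarray]]:
    """All (probe, target) pairs for one sentence.

    For every argument actually present in the sentence's frames, two probes
    are emitted — one role-probe (role part zeroed) and one filler-probe
    (filler part zeroed) — both targeting the complete role-filler vector.
    Probes appear frame-major, role-probe before filler-probe.
    """
    F, R = cfg.n_features, cfg.n_roles
    out = []
    for frame in sentence.frames:
        for role, filler in frame.args:
            target = _role_filler_vector(cfg, features, frame.index, role, filler)
            role_probe = target.copy()
            role_probe[F:F + R] = 0.0
            filler_probe = target.copy()
            filler_probe[:F] = 0.0
            out.append((Probe(role_probe, "role"), target))
            out.append((Probe(filler_probe, "filler"), target))
    return out


def filter_training_sentences(
    corpus: Iterable[FrameAnnotatedSentence],
    min_words: int = 6,
    max_words: int = 15,
    max_frames: int = 8,
) -> list[FrameAnnotatedSentence]:
    """Keep sentences of 6-15 words with at most 8 frames (order preserved);
    the constraint limits deeply nested subordinate events and keeps
    mini-batches homogeneous."""
    return [
        s for s in corpus
        if min_words <= s.n_words <= max_words and s.n_frames <= max_frames
    ]
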