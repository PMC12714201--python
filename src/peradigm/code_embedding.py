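"""ICD-10 code embeddings from description text.

Pipeline: tokenize each code's textual description (lowercase, punctuation
and English stopwords removed); treat each patient's chronological record
of description tokens as one sentence; train a CBOW word2vec model on the
sentence corpus; average a code's in-vocabulary token vectors into the
code embedding e_k.

The CBOW trainer is implemented in-package (numba-jitted negative-sampling
word2vec); training is single-threaded and bitwise-reproducible given the
seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .ehr_io import PatientHistory

logger = logging.getLogger(__name__)

__all__ = [
    "CbowParams",
    "WordVectorTable",
    "CodeEmbeddingMatrix",
    "default_stopwords",
    "tokenize_description",
    "tokenize_dictionary",
    "build_sentences",
    "train_cbow",
    "embed_codes",
    "save_word2vec",
    "load_word2vec",
]


def default_stopwords() -> frozenset[str]:
    """The fixed English stopword list shipped with the package."""
    text = (
        resources.files("peradigm").joinpath("data/stopwords_en.txt").read_text()
    )
    return frozenset(
        w.strip() for w in text.splitlines() if w.strip() and not w.startswith("#")
    )


def tokenize_description(
    description: str, stopwords: Iterable[str] | None = None
) -> list[str]:
    """Lowercase alphabetic tokens of a description, order preserved.

    Punctuation and digits are stripped; stopwords removed. May return an
    empty list (punctuation-only descriptions), handled downstream.
    """
    stop = frozenset(stopwords) if stopwords is not None else default_stopwords()
    tokens: list[str] = []
    word: list[str] = []
    for ch in description.lower():
        if ch.isalpha():
            word.append(ch)
        elif word:
            tokens.append("".join(word))
            word = []
    if word:
        tokens.append("".join(word))
    return [t for t in tokens if t not in stop]


def tokenize_dictionary(
    dictionary: Mapping[str, str], stopwords: Iterable[str] | None = None
) -> dict[str, list[str]]:
    """Tokenize every description in a code dictionary."""
    stop = frozenset(stopwords) if stopwords is not None else default_stopwords()
    return {c: tokenize_description(d, stop) for c, d in dictionary.items()}


def build_sentences(
    histories: Mapping[str, PatientHistory],
    dictionary: Mapping[str, str],
    stopwords: Iterable[str] | None = None,
    *,
    dedup_codes: bool = False,
    code_tokens: bool = False,
) -> list[list[str]]:
    """One sentence per patient: tokenized descriptions in event order.

    Codes missing from the dictionary are skipped with a warning. Repeated
    codes within a patient are kept by default (they carry longitudinal
    weight); ``dedup_codes=True`` keeps the first occurrence only.
    ``code_tokens=True`` trains directly on code symbols instead of
    description words (ablation mode).
    """
    tokenized = (
        None if code_tokens else tokenize_dictionary(dictionary, stopwords)
    )
    unresolved: set[str] = set()
    sentences: list[list[str]] = []
    for eid in sorted(histories):
        h = histories[eid]
        sent: list[str] = []
        seen: set[str] = set()
        for _, code in sorted(h.events, key=lambda e: (e[0], e[1])):
            if dedup_codes and code in seen:
                continue
            seen.add(code)
            if code not in dictionary:
                unresolved.add(code)
                continue
            if code_tokens:
                sent.append(code)
            else:
                sent.extend(tokenized[code])
        if sent:
            sentences.append(sent)
    if unresolved:
        logger.warning(
            "%d codes had no dictionary entry and were skipped (e.g. %s)",
            len(unresolved),
            sorted(unresolved)[:3],
        )
    if not sentences:
        raise ValueError("empty training corpus: no patient produced a sentence")
    return sentences


@dataclass
class CbowParams:
    """CBOW hyperparameters.

    ``window=None`` means "span the longest sentence", so every code in a
    patient record shares context with every other; at scale a finite
    window is the practical choice and is exposed here.
    """

    d: int = 100
    window: int | None = None
    min_count: int = 1
    epochs: int = 10
    negative: int = 5
    alpha: float = 0.025
    seed: int = 0


@dataclass
class WordVectorTable:
    """token -> d-dimensional vector, stored as a matrix plus vocab index."""

    vocab: list[str]
    vectors: np.ndarray  # (V, d) float32
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors[self._index[token]]

    def __post_init__(self) -> None:
        self._index = {w: i for i, w in enumerate(self.vocab)}


def train_cbow(
    corpus: Sequence[Sequence[str]], params: CbowParams | None = None
) -> WordVectorTable:
    """Train CBOW word2vec with negative sampling on a sentence corpus.

    Deterministic given ``params.seed`` (single-worker training). Raises if
    no token reaches ``min_count``.
    """
    from ._kernels import _train_epochs

    params = params or CbowParams()
    if not corpus:
        raise ValueError("corpus is empty")
    counts: dict[str, int] = {}
    for sent in corpus:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = sorted(w for w, c in counts.items() if c >= params.min_count)
    if not vocab:
        raise ValueError(
            f"no token reaches min_count={params.min_count}; corpus too small"
        )
    index = {w: i for i, w in enumerate(vocab)}
    kept = [[index[t] for t in sent if t in index] for sent in corpus]
    kept = [s for s in kept if len(s) >= 1]
    tokens = np.fromiter(
        (t for s in kept for t in s), dtype=np.int32, count=sum(len(s) for s in kept)
    )
    offsets = np.zeros(len(kept) + 1, dtype=np.int64)
    np.cumsum([len(s) for s in kept], out=offsets[1:])
    window = params.window
    if window is None:
        window = max(len(s) for s in kept)

    # unigram^0.75 negative-sampling table
    freq = np.array([counts[w] for w in vocab], dtype=np.float64) ** 0.75
    cum = np.cumsum(freq / freq.sum())
    table_size = max(1 << 16, 8 * len(vocab))
    neg_table = np.searchsorted(
        cum, (np.arange(table_size) + 0.5) / table_size
    ).astype(np.int32)

    rng = np.random.default_rng(params.seed)
    syn0 = (
        (rng.random((len(vocab), params.d), dtype=np.float32) - 0.5) / params.d
    )
    syn1 = np.zeros((len(vocab), params.d), dtype=np.float32)
    _train_epochs(
        tokens,
        offsets,
        syn0,
        syn1,
        neg_table,
        int(window),
        int(params.negative),
        int(params.epochs),
        float(params.alpha),
        float(params.alpha) * 1e-4,
        int(params.seed) % (2**31 - 1),
    )
    return WordVectorTable(vocab, syn0, {w: counts[w] for w in vocab})


@dataclass
class CodeEmbeddingMatrix:
    """code -> d-dimensional embedding e_k (mean of token vectors)."""

    vectors: dict[str, np.ndarray]
    dim: int

    def __contains__(self, code: str) -> bool:
        return code in self.vectors

    def __getitem__(self, code: str) -> np.ndarray:
        return self.vectors[code]

    def codes(self) -> list[str]:
        return list(self.vectors)


def embed_codes(
    word_vectors: WordVectorTable, tokenized_codes: Mapping[str, Sequence[str]]
) -> CodeEmbeddingMatrix:
    """e_k = unweighted mean of a code's in-vocabulary token vectors.

    Codes with zero in-vocabulary tokens are omitted and logged.
    """
    out: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for code, toks in tokenized_codes.items():
        vecs = [word_vectors[t] for t in toks if t in word_vectors]
        if not vecs:
            dropped.append(code)
            continue
        out[code] = np.mean(np.asarray(vecs, dtype=np.float64), axis=0)
    if dropped:
        logger.warning(
            "%d codes had no in-vocabulary token and were dropped (e.g. %s)",
            len(dropped),
            sorted(dropped)[:3],
        )
    return CodeEmbeddingMatrix(out, word_vectors.dim)


def save_word2vec(path: str | Path, keys: Sequence[str], matrix: np.ndarray) -> None:
    """Write vectors in word2vec text format (``count dim`` header)."""
    matrix = np.asarray(matrix)
    with open(path, "w") as fh:
        fh.write(f"{len(keys)} {matrix.shape[1]}\n")
        for key, row in zip(keys, matrix):
            fh.write(key + " " + " ".join(repr(float(x)) for x in row) + "\n")


def load_word2vec(path: str | Path) -> tuple[list[str], np.ndarray]:
    with open(path) as fh:
        n, d = map(int, fh.readline().split())
        keys: list[str] = []
        mat = np.empty((n, d), dtype=np.float64)
        for i in range(n):
            parts = fh.readline().rstrip("\n").split(" ")
            keys.append(parts[0])
            mat[i] = [float(x) for x in parts[1:]]
    return keys, mat
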