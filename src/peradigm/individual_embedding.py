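"""Individual phenotype embeddings.

An individual's embedding is the weight-normalized average of the
embeddings of their *rare* ICD-10 codes (cohort frequency <= 0.01):

    D_i = sum_k w_k e_k / sum_k w_k

over the individual's distinct qualifying codes. The normalization makes
D_i invariant to rescaling all weights, and the distinct-code semantics
make it invariant to repeated records and event order. Individuals with no
qualifying code get status "empty" and are excluded from all similarity
computations (cosine is undefined on the zero vector).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .code_embedding import CodeEmbeddingMatrix
from .ehr_io import CodeFrequencyTable, PatientHistory

logger = logging.getLogger(__name__)

__all__ = [
    "IndividualEmbedding",
    "EmbeddingSet",
    "embed_individual",
    "embed_cohort",
    "embed_group_selected",
]


@dataclass
class IndividualEmbedding:
    individual_id: str
    vector: np.ndarray | None
    n_codes_used: int
    status: str  # "ok" | "empty"


class EmbeddingSet:
    """Usable (status=ok) individual embeddings as an id-indexed matrix."""

    def __init__(self, ids: Sequence[str], matrix: np.ndarray):
        self.ids = list(ids)
        self.matrix = np.asarray(matrix, dtype=np.float64)
        norms = np.linalg.norm(self.matrix, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("zero vector in embedding set")
        self.unit = self.matrix / norms
        self.index = {eid: i for i, eid in enumerate(self.ids)}

    @classmethod
    def from_embeddings(
        cls, embeddings: Mapping[str, IndividualEmbedding]
    ) -> "EmbeddingSet":
        ok = [e for e in embeddings.values() if e.status == "ok"]
        n_empty = len(embeddings) - len(ok)
        if n_empty:
            logger.info("%d individuals have empty embeddings (excluded)", n_empty)
        if not ok:
            raise ValueError("no usable embeddings")
        ok.sort(key=lambda e: e.individual_id)
        return cls([e.individual_id for e in ok], np.vstack([e.vector for e in ok]))

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, eid: str) -> bool:
        return eid in self.index

    def subset_indices(self, ids: Iterable[str]) -> np.ndarray:
        return np.array(
            sorted(self.index[i] for i in ids if i in self.index), dtype=np.int64
        )


def _qualifying(
    codes: Iterable[str],
    code_embeddings: CodeEmbeddingMatrix,
    weights: Mapping[str, float],
    frequencies: CodeFrequencyTable | None,
    freq_threshold: float,
) -> list[str]:
    out = []
    for c in set(codes):
        if c not in code_embeddings or c not in weights:
            continue
        if frequencies is not None:
            r = frequencies.get(c)
            if r is None or r > freq_threshold:
                continue
        out.append(c)
    return sorted(out)


def embed_individual(
    history: PatientHistory,
    code_embeddings: CodeEmbeddingMatrix,
    weights: Mapping[str, float],
    frequencies: CodeFrequencyTable,
    freq_threshold: float = 0.01,
) -> IndividualEmbedding:
    """Weighted average embedding over the individual's rare distinct codes."""
    quals = _qualifying(
        history.distinct_codes(), code_embeddings, weights, frequencies, freq_threshold
    )
    if not quals:
        return IndividualEmbedding(history.individual_id, None, 0, "empty")
    w = np.array([weights[c] for c in quals], dtype=np.float64)
    total = w.sum()
    if total <= 0:
        raise ValueError(
            f"total weight is {total} for {history.individual_id}; cannot normalize"
        )
    E = np.vstack([code_embeddings[c] for c in quals])
    vec = (w @ E) / total
    return IndividualEmbedding(history.individual_id, vec, len(quals), "ok")


def embed_cohort(
    histories: Mapping[str, PatientHistory],
    code_embeddings: CodeEmbeddingMatrix,
    weights: Mapping[str, float],
    frequencies: CodeFrequencyTable,
    freq_threshold: float = 0.01,
) -> dict[str, IndividualEmbedding]:
    """Embed every individual; vectorized sparse implementation.

    Equivalent to calling :func:`embed_individual` per individual (checked
    by tests) but builds one sparse indicator matrix over the rare-code
    universe, so cohort-scale embedding is a single matrix product.
    """
    from scipy import sparse

    rare = sorted(
        c
        for c in code_embeddings.codes()
        if c in weights
        and frequencies.get(c) is not None
        and frequencies.get(c) <= freq_threshold
    )
    cidx = {c: j for j, c in enumerate(rare)}
    ids = sorted(histories)
    rows, cols = [], []
    for i, eid in enumerate(ids):
        for c in histories[eid].distinct_codes():
            j = cidx.get(c)
            if j is not None:
                rows.append(i)
                cols.append(j)
    out: dict[str, IndividualEmbedding] = {}
    if rare:
        A = sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(len(ids), len(rare))
        )
        w = np.array([weights[c] for c in rare], dtype=np.float64)
        if np.any(w < 0):
            raise ValueError("negative code weight")
        E = np.vstack([code_embeddings[c] for c in rare])
        totals = A @ w
        numer = A.multiply(w) @ E
        ncodes = np.asarray(A.sum(axis=1)).ravel().astype(int)
    else:
        totals = np.zeros(len(ids))
        ncodes = np.zeros(len(ids), dtype=int)
        numer = np.zeros((len(ids), code_embeddings.dim))
    for i, eid in enumerate(ids):
        if ncodes[i] == 0:
            out[eid] = IndividualEmbedding(eid, None, 0, "empty")
        elif totals[i] <= 0:
            raise ValueError(f"total weight is 0 for {eid}; cannot normalize")
        else:
            out[eid] = IndividualEmbedding(
                eid, numer[i] / totals[i], int(ncodes[i]), "ok"
            )
    return out


def embed_group_selected(
    histories: Mapping[str, PatientHistory],
    member_ids: Iterable[str],
    selected_codes: Iterable[str],
    code_embeddings: CodeEmbeddingMatrix,
    weights: Mapping[str, float],
    frequencies: CodeFrequencyTable | None = None,
    freq_threshold: float = 0.01,
    repeat_weighted: bool = False,
) -> dict[str, IndividualEmbedding]:
    """Embed group members using only a preselected phenotype code set.

    Supports the expert-knowledge variants: e.g. embedding diagnosed
    patients with only disease-related codes. By default a repeated
    selected code contributes once; ``repeat_weighted=True`` multiplies
    each code's weight by its longitudinal record count (the
    "longitudinal codes only" variant). Members with no selected code get
    status "empty".
    """
    selected = set(selected_codes)
    if not selected:
        raise ValueError("selected_codes must be non-empty")
    out: dict[str, IndividualEmbedding] = {}
    for eid in sorted(member_ids):
        h = histories[eid]
        quals = _qualifying(
            (c for c in h.distinct_codes() if c in selected),
            code_embeddings,
            weights,
            frequencies,
            freq_threshold,
        )
        if not quals:
            out[eid] = IndividualEmbedding(eid, None, 0, "empty")
            continue
        counts = {c: h.codes().count(c) for c in quals} if repeat_weighted else {}
        w = np.array(
            [weights[c] * (counts.get(c, 1)) for c in quals], dtype=np.float64
        )
        total = w.sum()
        if total <= 0:
            raise ValueError(f"total weight is 0 for {eid}; cannot normalize")
        E = np.vstack([code_embeddings[c] for c in quals])
        out[eid] = IndividualEmbedding(eid, (w @ E) / total, len(quals), "ok")
    return out
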