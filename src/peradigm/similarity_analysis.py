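"""Intra-group pairwise similarity versus size-matched random controls.

Quantifies whether a patient or carrier group shares a distinctive
phenotype profile: all C(n,2) pairwise cosine similarities within the
group are compared with those of an equal-sized random draw from the rest
of the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .individual_embedding import EmbeddingSet

__all__ = [
    "IntraGroupReport",
    "intra_group_similarity",
    "control_similarity",
    "summarize_intra",
    "intra_group_report",
]


@dataclass
class IntraGroupReport:
    label: str
    group_values: np.ndarray
    control_values: np.ndarray
    control_seed: int

    @property
    def group_mean(self) -> float:
        return float(self.group_values.mean())

    @property
    def control_mean(self) -> float:
        return float(self.control_values.mean())

    @property
    def mean_difference(self) -> float:
        return self.group_mean - self.control_mean

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format pair values for boxplot export."""
        rows = [
            {"group": self.label, "pair_id": i, "similarity": v}
            for i, v in enumerate(self.group_values)
        ] + [
            {"group": f"{self.label}_control", "pair_id": i, "similarity": v}
            for i, v in enumerate(self.control_values)
        ]
        return pd.DataFrame(rows)


def _pairwise_cosines(unit_rows: np.ndarray) -> np.ndarray:
    g = unit_rows @ unit_rows.T
    iu = np.triu_indices(len(unit_rows), k=1)
    return np.clip(g[iu], -1.0, 1.0)


def intra_group_similarity(
    member_ids: Iterable[str], embeddings: EmbeddingSet
) -> np.ndarray:
    """Cosine similarity of every unordered pair within the group."""
    idx = embeddings.subset_indices(member_ids)
    if len(idx) < 2:
        raise ValueError("need at least 2 members with usable embeddings")
    return _pairwise_cosines(embeddings.unit[idx])


def control_similarity(
    group_size: int,
    pool_ids: Iterable[str],
    exclude_ids: Iterable[str],
    embeddings: EmbeddingSet,
    seed: int = 0,
) -> np.ndarray:
    """Pairwise cosines of a random size-matched control group.

    Controls are drawn without replacement from ``pool_ids`` minus
    ``exclude_ids`` (e.g. the cohort minus the target group, or minus all
    carriers of the target gene); reproducible given the seed.
    """
    pool = sorted(set(pool_ids) - set(exclude_ids))
    pool = [i for i in pool if i in embeddings]
    if len(pool) < group_size:
        raise ValueError(
            f"control pool ({len(pool)}) smaller than group size {group_size}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=group_size, replace=False)
    idx = embeddings.subset_indices([pool[i] for i in chosen])
    return _pairwise_cosines(embeddings.unit[idx])


def summarize_intra(report: IntraGroupReport) -> dict[str, float]:
    return {
        "group_mean": report.group_mean,
        "control_mean": report.control_mean,
        "mean_difference": report.mean_difference,
    }


def intra_group_report(
    label: str,
    member_ids: Iterable[str],
    pool_ids: Iterable[str],
    embeddings: EmbeddingSet,
    exclude_ids: Iterable[str] | None = None,
    seed: int = 0,
    n_control_draws: int = 1,
) -> IntraGroupReport:
    """Group vs. control similarity report.

    One control draw by default; ``n_control_draws > 1`` pools several
    draws (stability mode for small groups).
    """
    member_ids = set(member_ids)
    group = intra_group_similarity(member_ids, embeddings)
    n = len(embeddings.subset_indices(member_ids))
    excl = member_ids if exclude_ids is None else set(exclude_ids)
    controls = [
        control_similarity(n, pool_ids, excl, embeddings, seed + k)
        for k in range(n_control_draws)
    ]
    return IntraGroupReport(label, group, np.concatenate(controls), seed)
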