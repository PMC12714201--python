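"""End-to-end two-stage driver tying the modules together.

Stage 1 builds the phenotype representation: cohort definition, code
frequencies, phenome scan, per-code weights, CBOW code embeddings and
individual embeddings. Stage 2 runs the gene scan against the empirical
sampling null. The driver is the shared engine behind the CLI, the
calibration re-runs and the power simulations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

from . import association_weights as aw
from . import code_embedding as ce
from . import ehr_io
from . import individual_embedding as ie
from . import risk_mapping as rm
from .genotype_carriers import CarrierTable
from .synthetic_data import GeneratedCohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "Stage1", "PipelineResult", "run_stage1", "run_end_to_end"]


@dataclass(frozen=True)
class PipelineConfig:
    freq_threshold: float = 0.01
    scheme: str = "pvalue_ic"
    n_reps: int = 10_000
    adjustment: str = "bonferroni"
    exclude_self: bool = False
    min_carriers: int = 5
    keep_null_scores: bool = False
    cbow: ce.CbowParams = field(default_factory=ce.CbowParams)
    seed: int = 0

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed, cbow=replace(self.cbow, seed=seed))


@dataclass
class Stage1:
    cohort: ehr_io.Cohort
    frequencies: ehr_io.CodeFrequencyTable
    scan: pd.DataFrame
    weight_table: pd.DataFrame
    weights: dict[str, float]
    code_embeddings: ce.CodeEmbeddingMatrix
    embedding_map: dict[str, ie.IndividualEmbedding]
    embeddings: ie.EmbeddingSet


@dataclass
class PipelineResult:
    stage1: Stage1
    scan: pd.DataFrame
    config: PipelineConfig


def run_stage1(
    histories: Mapping[str, ehr_io.PatientHistory],
    dictionary: Mapping[str, str],
    covariates: pd.DataFrame,
    case_codes: Iterable[str],
    config: PipelineConfig | None = None,
    code_embeddings: ce.CodeEmbeddingMatrix | None = None,
    scan: pd.DataFrame | None = None,
) -> Stage1:
    """Stage 1; precomputed ``code_embeddings``/``scan`` can be supplied to
    avoid retraining when only the weighting scheme changes."""
    config = config or PipelineConfig()
    cohort = ehr_io.define_cohort(histories, case_codes)
    frequencies = ehr_io.code_frequency(histories)
    if scan is None:
        scan = aw.scan_phenotypes(histories, cohort.case_ids, covariates)
    weight_table = aw.build_weight_table(scan, frequencies, scheme=config.scheme)
    weights = dict(zip(weight_table["code"], weight_table["weight"]))
    if code_embeddings is None:
        corpus = ce.build_sentences(histories, dictionary)
        cbow = replace(config.cbow, seed=config.cbow.seed or config.seed)
        word_vectors = ce.train_cbow(corpus, cbow)
        tokenized = ce.tokenize_dictionary(dictionary)
        code_embeddings = ce.embed_codes(word_vectors, tokenized)
    embedding_map = ie.embed_cohort(
        histories, code_embeddings, weights, frequencies, config.freq_threshold
    )
    embeddings = ie.EmbeddingSet.from_embeddings(embedding_map)
    logger.info(
        "stage 1: %d cases, %d usable embeddings of %d individuals",
        cohort.n_cases,
        len(embeddings),
        len(histories),
    )
    return Stage1(
        cohort,
        frequencies,
        scan,
        weight_table,
        weights,
        code_embeddings,
        embedding_map,
        embeddings,
    )


def run_end_to_end(
    cohort_data: GeneratedCohort,
    config: PipelineConfig | None = None,
    carrier_table: CarrierTable | None = None,
    case_codes: Iterable[str] | None = None,
    code_embeddings: ce.CodeEmbeddingMatrix | None = None,
    scan: pd.DataFrame | None = None,
) -> PipelineResult:
    """Full scan on a generated (or equivalently structured) cohort."""
    config = config or PipelineConfig()
    case_codes = (
        list(case_codes)
        if case_codes is not None
        else [cohort_data.ground_truth.case_code]
    )
    stage1 = run_stage1(
        cohort_data.histories,
        cohort_data.dictionary,
        cohort_data.covariates,
        case_codes,
        config,
        code_embeddings=code_embeddings,
        scan=scan,
    )
    table = carrier_table or cohort_data.carrier_table
    table = CarrierTable(
        {
            g: s
            for g, s in table.carriers.items()
            if len({i for i in s if i in stage1.embeddings}) >= config.min_carriers
        }
    )
    scan = rm.scan_genes(
        table,
        stage1.embeddings,
        stage1.cohort,
        n_reps=config.n_reps,
        seed=config.seed,
        exclude_self=config.exclude_self,
        adjustment=config.adjustment,
        keep_null_scores=config.keep_null_scores,
    )
    return PipelineResult(stage1, scan, config)
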