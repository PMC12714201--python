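"""Variant QC, LoF selection, carrier sets, kinship pruning, CHIP filter.

Quality control mirrors standard biobank rare-variant practice: drop
variants with MAF > 0.01 or Hardy-Weinberg exact-test p < 1e-6, keep only
the five predicted loss-of-function consequence classes (stop-gain,
stop-loss, frameshift insertion/deletion, essential splice), build
per-gene carrier sets (an individual with >=1 alternate allele at >=1
retained LoF variant of the gene), require at least five carriers per
gene, prune first/second-degree relatives to one random member per family,
and flag genes whose carriers are significantly older than non-carriers
(a clonal-hematopoiesis signature) with a one-sided Wilcoxon rank-sum test
under Bonferroni correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "CarrierTable",
    "LOF_CONSEQUENCES",
    "hwe_exact_test",
    "qc_variants",
    "select_lof",
    "carrier_sets",
    "read_carrier_tsv",
    "write_carrier_tsv",
    "read_vcf_carriers",
    "prune_related",
    "chip_filter",
]


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    maf: float
    hwe_p: float = 1.0

    def __post_init__(self):
        if not 0 <= self.maf <= 0.5:
            raise ValueError(f"MAF {self.maf} out of [0, 0.5]")
        if not 0 <= self.hwe_p <= 1:
            raise ValueError(f"HWE p {self.hwe_p} out of [0, 1]")


@dataclass
class CarrierTable:
    """gene -> set of carrier individual ids (n_Gi = set size)."""

    carriers: dict[str, set[str]]

    def __getitem__(self, gene: str) -> set[str]:
        return self.carriers[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.carriers

    def genes(self) -> list[str]:
        return sorted(self.carriers)

    def counts(self) -> dict[str, int]:
        return {g: len(s) for g, s in self.carriers.items()}

    def restrict_individuals(self, keep: Iterable[str]) -> "CarrierTable":
        keep = set(keep)
        return CarrierTable({g: s & keep for g, s in self.carriers.items()})

    def drop_genes(self, genes: Iterable[str]) -> "CarrierTable":
        drop = set(genes)
        return CarrierTable(
            {g: set(s) for g, s in self.carriers.items() if g not in drop}
        )


# Consequence synonym map covering VEP- and ANNOVAR-style vocabularies for
# the five LoF classes.
LOF_CONSEQUENCES: dict[str, str] = {
    # stop-gain
    "stop_gained": "stop_gain",
    "stopgain": "stop_gain",
    "stop-gain": "stop_gain",
    "stop_gain": "stop_gain",
    "nonsense": "stop_gain",
    # stop-loss
    "stop_lost": "stop_loss",
    "stoploss": "stop_loss",
    "stop-loss": "stop_loss",
    "stop_loss": "stop_loss",
    # frameshift
    "frameshift_insertion": "frameshift_insertion",
    "frameshift_deletion": "frameshift_deletion",
    "frameshift_variant": "frameshift",
    "frameshift": "frameshift",
    # essential splice (donor/acceptor +-2bp)
    "splice_acceptor_variant": "essential_splice",
    "splice_donor_variant": "essential_splice",
    "essential_splice": "essential_splice",
    "splicing": "essential_splice",
}


def hwe_exact_test(n_het: int, n_hom_alt: int, n_hom_ref: int) -> float:
    """Exact Hardy-Weinberg test p-value from genotype counts.

    Sums the probabilities of all heterozygote counts (conditional on
    allele counts) no more likely than the observed one — the standard
    exact HWE formulation. Mid-p correction is not applied.
    """
    n = n_het + n_hom_alt + n_hom_ref
    n_alt = n_het + 2 * n_hom_alt
    if min(n_het, n_hom_alt, n_hom_ref) < 0:
        raise ValueError("negative genotype count")
    rare = min(n_alt, 2 * n - n_alt)
    if rare == 0 or n == 0:
        return 1.0
    # log-probabilities over all het counts with the observed parity
    hets = np.arange(rare % 2, rare + 1, 2)
    from scipy.special import gammaln

    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(hom_r + 1)
        - gammaln(hom_c + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[np.searchsorted(hets, n_het)]
    return float(min(1.0, prob[prob <= obs * (1 + 1e-12)].sum()))


def qc_variants(
    variants: Sequence[VariantRecord],
    maf_max: float = 0.01,
    hwe_min_p: float = 1e-6,
) -> list[VariantRecord]:
    """Keep variants with MAF <= maf_max and HWE p >= hwe_min_p."""
    kept, n_maf, n_hwe = [], 0, 0
    for v in variants:
        if v.maf > maf_max:
            n_maf += 1
        elif v.hwe_p < hwe_min_p:
            n_hwe += 1
        else:
            kept.append(v)
    logger.info(
        "qc_variants: kept %d / %d (removed %d by MAF, %d by HWE)",
        len(kept),
        len(variants),
        n_maf,
        n_hwe,
    )
    return kept


def select_lof(variants: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Keep the five LoF consequence classes, applying the synonym map.

    Unknown consequence strings are warned about and treated as non-LoF.
    """
    kept = []
    unknown: set[str] = set()
    known_non_lof = {
        "missense_variant",
        "missense",
        "nonsynonymous_snv",
        "synonymous_variant",
        "synonymous",
        "intron_variant",
        "intergenic_variant",
        "utr_variant",
        "splice_region_variant",
        "inframe_insertion",
        "inframe_deletion",
        "start_lost",
    }
    for v in variants:
        key = v.consequence.strip().lower()
        if key in LOF_CONSEQUENCES:
            kept.append(replace(v, consequence=LOF_CONSEQUENCES[key]))
        elif key not in known_non_lof:
            unknown.add(v.consequence)
    if unknown:
        logger.warning(
            "unknown consequence strings treated as non-LoF: %s", sorted(unknown)[:5]
        )
    return kept


def carrier_sets(
    genotypes: Mapping[tuple[str, int, str, str], Iterable[str]],
    lof_variants: Sequence[VariantRecord],
    min_carriers: int = 5,
) -> CarrierTable:
    """Per-gene carrier sets from (variant -> carrier ids) genotypes.

    A carrier holds >=1 alternate allele at >=1 retained LoF variant of
    the gene (set semantics: multiple qualifying variants count once).
    Genes with fewer than ``min_carriers`` carriers are excluded.
    """
    by_gene: dict[str, set[str]] = {}
    for v in lof_variants:
        key = (v.chrom, v.pos, v.ref, v.alt)
        ids = genotypes.get(key, ())
        by_gene.setdefault(v.gene, set()).update(str(i) for i in ids)
    dropped = [g for g, s in by_gene.items() if len(s) < min_carriers]
    if dropped:
        logger.info("%d genes below min_carriers=%d excluded", len(dropped), min_carriers)
    return CarrierTable(
        {g: s for g, s in by_gene.items() if len(s) >= min_carriers}
    )


def read_carrier_tsv(path: str | Path, min_carriers: int = 0) -> CarrierTable:
    """Read a plain ``gene, eid`` carrier table (the desk-scale surface)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    df.columns = [c.lower() for c in df.columns]
    if not {"gene", "eid"} <= set(df.columns):
        raise ValueError("carrier table needs columns gene, eid")
    carriers: dict[str, set[str]] = {}
    for g, e in zip(df["gene"], df["eid"]):
        carriers.setdefault(str(g), set()).add(str(e))
    if min_carriers:
        carriers = {g: s for g, s in carriers.items() if len(s) >= min_carriers}
    return CarrierTable(carriers)


def write_carrier_tsv(table: CarrierTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\teid\n")
        for g in table.genes():
            for e in sorted(table[g]):
                fh.write(f"{g}\t{e}\n")


def read_vcf_carriers(
    path: str | Path,
    gene_field: str = "GENE",
    consequence_field: str = "CSQ",
    maf_max: float = 0.01,
    hwe_min_p: float = 1e-6,
    min_carriers: int = 5,
) -> CarrierTable:
    """Carrier sets straight from an annotated VCF (needs cyvcf2).

    Per-variant gene and consequence are read from INFO fields; MAF and
    HWE are computed from the genotypes when absent. Applies
    :func:`qc_variants` and :func:`select_lof` before set construction.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = [str(s) for s in vcf.samples]
    variants: list[VariantRecord] = []
    genos: dict[tuple[str, int, str, str], set[str]] = {}
    for rec in vcf:
        gene = rec.INFO.get(gene_field)
        csq = rec.INFO.get(consequence_field)
        if gene is None or csq is None:
            continue
        gts = rec.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        n_het = int((gts == 1).sum())
        n_hom_alt = int((gts == 3).sum())
        n_hom_ref = int((gts == 0).sum())
        n_called = n_het + n_hom_alt + n_hom_ref
        if n_called == 0:
            continue
        af = (n_het + 2 * n_hom_alt) / (2 * n_called)
        maf = min(af, 1 - af)
        info_maf = rec.INFO.get("MAF")
        info_hwe = rec.INFO.get("HWE_P")
        v = VariantRecord(
            chrom=str(rec.CHROM),
            pos=int(rec.POS),
            ref=str(rec.REF),
            alt=str(rec.ALT[0]) if rec.ALT else ".",
            gene=str(gene),
            consequence=str(csq).split("|")[0],
            maf=float(info_maf) if info_maf is not None else maf,
            hwe_p=float(info_hwe)
            if info_hwe is not None
            else hwe_exact_test(n_het, n_hom_alt, n_hom_ref),
        )
        variants.append(v)
        key = (v.chrom, v.pos, v.ref, v.alt)
        genos[key] = {
            samples[i] for i in np.flatnonzero((gts == 1) | (gts == 3))
        }
    lof = select_lof(qc_variants(variants, maf_max, hwe_min_p))
    return carrier_sets(genos, lof, min_carriers)


def prune_related(
    individual_ids: Iterable[str],
    kinship_pairs: Iterable[tuple[str, str]],
    seed: int = 0,
) -> set[str]:
    """Reduce each related family to one randomly retained member.

    Families are connected components of the relatedness graph over the
    supplied pairs; reproducible given the seed, and the retained set
    contains no related pair.
    """
    ids = set(individual_ids)
    g = nx.Graph()
    g.add_edges_from(
        (a, b) for a, b in kinship_pairs if a in ids and b in ids and a != b
    )
    rng = np.random.default_rng(seed)
    keep = set(ids)
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        retained = comp[rng.integers(len(comp))]
        keep -= set(comp) - {retained}
    return keep


def chip_filter(
    carrier_table: CarrierTable,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    explicit_remove: Iterable[str] | None = None,
) -> list[str]:
    """Flag genes whose LoF carriers are significantly *older* than
    non-carriers (clonal-hematopoiesis signal).

    One-sided Wilcoxon rank-sum test per gene, Bonferroni-corrected over
    the tested genes. ``explicit_remove`` appends a curated removal list
    (e.g. the classic CHIP genes ASXL1, TET2, DNMT3A) regardless of the
    test. Returns the sorted flagged gene list; callers drop those genes.
    """
    ages = covariates["age"]
    all_ids = set(ages.index)
    flagged: dict[str, float] = {}
    tested: list[tuple[str, float]] = []
    for gene in carrier_table.genes():
        carr = sorted(carrier_table[gene] & all_ids)
        non = sorted(all_ids - set(carr))
        if len(carr) < 2 or len(non) < 2:
            logger.info("chip_filter: gene %s skipped (<2 carriers with age)", gene)
            continue
        stat = mannwhitneyu(
            ages.loc[carr], ages.loc[non], alternative="greater"
        )
        tested.append((gene, stat.pvalue))
    m = len(tested)
    for gene, p in tested:
        if p * m < alpha:
            flagged[gene] = p * m
    out = set(flagged)
    if explicit_remove:
        out |= set(explicit_remove)
    if out:
        logger.info("chip_filter flagged %d genes: %s", len(out), sorted(out))
    return sorted(out)
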