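"""Ultra-rare variant filtering, annotation-tier weighting, and gene burdens.

Qualifying variants are *ultra-rare*: gnomAD population-max allele frequency
<= 0.01% and cohort allele count <= 3. Each qualifying variant receives a
weight on the six-value ladder {0, 0.2, 0.4, 0.6, 0.8, 1.0} from its
consequence class and in-silico scores:

====  =========================================================================
1.0   canonical LoF (canonical splice / nonsense / frameshift / stop-gain /
      start-loss) flagged high-confidence (HC) by LOFTEE
0.8   canonical LoF flagged low-confidence or unlabeled by LOFTEE;
      noncanonical splice with SpliceAI > 0.5; missense with REVEL > 0.8
0.6   in-frame indel with CADD > 20; missense with 0.6 < REVEL <= 0.8
0.4   in-frame indel with 10 < CADD <= 20; missense with 0.4 < REVEL <= 0.6
0.2   remaining in-frame indels; missense with 0.2 < REVEL <= 0.4
0     everything else (missense with REVEL <= 0.2 or no score, noncanonical
      splice with SpliceAI <= 0.5, other consequence classes)
====  =========================================================================

The per-individual, per-gene *mutational burden* is the maximum weight over
the qualifying variants that individual carries in the gene (carrier =
allele count >= 1, a dominant-model reading); non-carriers score 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CSQ_CLASSES = ("lof_canonical", "noncanonical_splice", "missense", "inframe_indel", "other")
WEIGHT_LADDER = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)

#: default ultra-rare gates
AF_MAX = 1e-4
AC_MAX = 3


@dataclass(frozen=True)
class VariantAnnotation:
    """One annotated single-alt variant (multi-allelic sites must be pre-split)."""

    variant_id: str
    gene_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    csq_class: str
    loftee: Optional[str] = None  # "HC", "LC", or None (unlabeled)
    spliceai: Optional[float] = None
    revel: Optional[float] = None
    cadd: Optional[float] = None
    popmax_af: float = 0.0
    cohort_ac: int = 0

    def __post_init__(self) -> None:
        if self.csq_class not in CSQ_CLASSES:
            raise ValueError(
                f"{self.variant_id}: unknown consequence class {self.csq_class!r}"
            )
        if self.loftee not in (None, "HC", "LC"):
            raise ValueError(f"{self.variant_id}: LOFTEE flag must be HC/LC/None")
        for name, score, hi in (("spliceai", self.spliceai, 1.0), ("revel", self.revel, 1.0)):
            if score is not None and not (0.0 <= score <= hi):
                raise ValueError(f"{self.variant_id}: {name}={score} out of [0, {hi}]")
        if self.cadd is not None and self.cadd < 0:
            raise ValueError(f"{self.variant_id}: cadd must be >= 0")
        if not (0.0 <= self.popmax_af <= 1.0):
            raise ValueError(f"{self.variant_id}: popmax_af out of [0, 1]")
        if self.cohort_ac < 0:
            raise ValueError(f"{self.variant_id}: cohort_ac must be >= 0")


@dataclass(frozen=True)
class WeightedVariant:
    variant_id: str
    gene_id: str
    weight: float
    tier_reason: str

    def __post_init__(self) -> None:
        if self.weight not in WEIGHT_LADDER:
            raise ValueError(f"{self.variant_id}: weight {self.weight} off the ladder")


@dataclass
class GenotypeMatrix:
    """Allele counts (0/1/2) per sample x variant."""

    samples: list[str]
    variant_ids: list[str]
    counts: np.ndarray  # shape (n_samples, n_variants), small ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.samples), len(self.variant_ids)):
            raise ValueError("genotype matrix shape does not match labels")
        if self.counts.min(initial=0) < 0 or self.counts.max(initial=0) > 2:
            raise ValueError("allele counts must be 0, 1 or 2")
        self._col = {v: j for j, v in enumerate(self.variant_ids)}

    def column(self, variant_id: str) -> np.ndarray:
        return self.counts[:, self._col[variant_id]]

    def allele_counts(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=0), index=self.variant_ids)


@dataclass
class BurdenMatrix:
    """Per-sample, per-gene max-weight burden."""

    samples: list[str]
    genes: list[str]
    values: np.ndarray  # shape (n_samples, n_genes), floats on the ladder

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.genes)):
            raise ValueError("burden matrix shape does not match labels")
        self._col = {g: j for j, g in enumerate(self.genes)}

    def __contains__(self, gene: str) -> bool:
        return gene in self._col

    def gene_burdens(self, gene: str) -> np.ndarray:
        if gene not in self._col:
            raise KeyError(f"gene {gene!r} not in burden matrix")
        return self.values[:, self._col[gene]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.samples, name="sample"),
                            columns=self.genes)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BurdenMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


def filter_ultra_rare(
    variants: Iterable[VariantAnnotation],
    af_max: float = AF_MAX,
    ac_max: int = AC_MAX,
    genotypes: GenotypeMatrix | None = None,
) -> list[VariantAnnotation]:
    """Keep variants with popmax AF <= ``af_max`` and cohort AC <= ``ac_max``.

    A missing (zero) popmax AF means the variant is absent from gnomAD and
    passes the frequency gate. If ``genotypes`` is given, cohort allele
    counts are recomputed from it and override the annotated value.
    """
    kept = []
    ac_from_geno = None
    if genotypes is not None:
        totals = genotypes.counts.sum(axis=0)
        ac_from_geno = {vid: int(totals[j]) for j, vid in enumerate(genotypes.variant_ids)}
    for v in variants:
        ac = v.cohort_ac if ac_from_geno is None else ac_from_geno[v.variant_id]
        if v.popmax_af == 0.0:
            logger.debug("%s: popmax_af absent/0, treated as not in gnomAD", v.variant_id)
        if v.popmax_af <= af_max and ac <= ac_max:
            kept.append(v)
    return kept


def assign_weight(v: VariantAnnotation) -> WeightedVariant:
    """Place one qualifying variant on the weight ladder (see module docstring)."""
    w, reason = _weight_and_reason(
        v.csq_class, v.loftee, v.spliceai, v.revel, v.cadd
    )
    return WeightedVariant(v.variant_id, v.gene_id, w, reason)


def _weight_and_reason(
    csq: str,
    loftee: Optional[str],
    spliceai: Optional[float],
    revel: Optional[float],
    cadd: Optional[float],
) -> tuple[float, str]:
    if csq not in CSQ_CLASSES:
        raise ValueError(f"unknown consequence class {csq!r}")
    if csq == "lof_canonical":
        if loftee == "HC":
            return 1.0, "lof_loftee_hc"
        return 0.8, "lof_loftee_lc_or_unlabeled"
    if csq == "noncanonical_splice":
        if spliceai is not None and spliceai > 0.5:
            return 0.8, "noncanonical_splice_spliceai_gt_0.5"
        return 0.0, "noncanonical_splice_low_spliceai"
    if csq == "missense":
        if revel is None:
            return 0.0, "missense_no_revel"
        if revel > 0.8:
            return 0.8, "missense_revel_gt_0.8"
        if revel > 0.6:
            return 0.6, "missense_revel_0.6_0.8"
        if revel > 0.4:
            return 0.4, "missense_revel_0.4_0.6"
        if revel > 0.2:
            return 0.2, "missense_revel_0.2_0.4"
        return 0.0, "missense_revel_le_0.2"
    if csq == "inframe_indel":
        if cadd is not None and cadd > 20:
            return 0.6, "inframe_cadd_gt_20"
        if cadd is not None and cadd > 10:
            return 0.4, "inframe_cadd_10_20"
        return 0.2, "inframe_remaining"
    return 0.0, "other_class"


def assign_weights(variants: Sequence[VariantAnnotation]) -> list[WeightedVariant]:
    """Vectorized convenience over :func:`assign_weight`."""
    return [assign_weight(v) for v in variants]


def compute_gene_burden(
    genotypes: GenotypeMatrix,
    weights: Sequence[WeightedVariant],
    genes: Sequence[str] | None = None,
) -> BurdenMatrix:
    """Max carried weight per sample per gene; 0 for non-carriers.

    Carrier status is dominant: allele count >= 1. ``genes`` fixes the
    column set (genes without qualifying variants get all-zero columns);
    by default the columns are the genes present among ``weights``.
    """
    missing = [w.variant_id for w in weights if w.variant_id not in genotypes._col]
    if missing:
        raise ValueError(f"weighted variants absent from genotypes: {missing[:5]}")
    if genes is None:
        genes = sorted({w.gene_id for w in weights})
    genes = list(genes)
    gene_ix = {g: j for j, g in enumerate(genes)}
    n = len(genotypes.samples)
    burden = np.zeros((n, len(genes)))
    by_gene: dict[str, list[WeightedVariant]] = {}
    for w in weights:
        if w.gene_id in gene_ix:
            by_gene.setdefault(w.gene_id, []).append(w)
    for gene, ws in by_gene.items():
        cols = np.array([genotypes._col[w.variant_id] for w in ws])
        wvec = np.array([w.weight for w in ws])
        carried = genotypes.counts[:, cols] >= 1
        burden[:, gene_ix[gene]] = np.where(carried, wvec, 0.0).max(axis=1)
    return BurdenMatrix(list(genotypes.samples), genes, burden)
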