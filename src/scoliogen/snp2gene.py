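"""SNP-to-gene mapping for GWAS loci.

Genome-wide-significant SNPs are reduced to an independent set by greedy
LD clumping (independence means pairwise r^2 < 0.6), re-expanded to their
LD blocks (r^2 >= 0.6 with an independent SNP, one hop, no transitive
closure), and then mapped to candidate genes by three strategies:

* positional -- the SNP falls inside a gene span or within 10 kb of it;
* eQTL -- a SNP-gene expression association with FDR <= 0.05 in any tissue;
* chromatin -- a significant Hi-C style interaction (FDR <= 1e-6) whose one
  end overlaps the SNP and whose other end overlaps the gene promoter,
  defined as -250 bp to +500 bp around the TSS (mirrored on the - strand).

The union of the three maps is the candidate-gene panel passed downstream
to the rare-variant burden analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

GENOME_WIDE_SIGNIFICANCE = 5e-8


@dataclass(frozen=True)
class GwasSnp:
    """A genome-wide-significant SNP from an association study.

    ``pos`` is 1-based, as in VCF and GWAS summary statistics.
    """

    rsid: str
    chrom: str
    pos: int
    pvalue: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: pos must be >= 1, got {self.pos}")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.rsid}: pvalue must be in (0, 1], got {self.pvalue}")


@dataclass(frozen=True)
class GeneModel:
    """A gene span with its transcription start site.

    ``start``/``end`` are 0-based half-open (BED convention); ``tss`` is
    1-based. On the + strand the TSS sits at the left edge of the span, on
    the - strand at the right edge.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not (self.start + 1 <= self.tss <= self.end):
            raise ValueError(f"{self.gene_id}: tss {self.tss} outside span")

    def promoter(
        self,
        upstream_bp: int = 250,
        downstream_bp: int = 500,
        strand_aware: bool = True,
    ) -> tuple[int, int]:
        """Promoter window as a 1-based closed interval around the TSS.

        On the + strand (or with ``strand_aware=False``) the window is
        [tss - upstream, tss + downstream]; on the - strand it is mirrored
        to [tss - downstream, tss + upstream] so that "upstream" follows
        the direction of transcription.
        """
        if self.strand == "-" and strand_aware:
            lo, hi = self.tss - downstream_bp, self.tss + upstream_bp
        else:
            lo, hi = self.tss - upstream_bp, self.tss + downstream_bp
        return max(lo, 1), hi


@dataclass(frozen=True)
class EqtlRecord:
    """A SNP-gene expression association in one tissue."""

    rsid: str
    gene_id: str
    tissue: str
    fdr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"eQTL {self.rsid}-{self.gene_id}: fdr out of [0, 1]")


Region = tuple[str, int, int]  # chrom, 0-based half-open start/end


@dataclass(frozen=True)
class ChromatinInteraction:
    """A pairwise chromatin contact between two genomic regions."""

    region_a: Region
    region_b: Region
    fdr: float

    def __post_init__(self) -> None:
        for name, (chrom, start, end) in (("region_a", self.region_a), ("region_b", self.region_b)):
            if start < 0 or start >= end:
                raise ValueError(f"{name} malformed: {chrom}:{start}-{end}")
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError("interaction fdr out of [0, 1]")


class LdMatrix:
    """Sparse symmetric pairwise r^2 lookup.

    Unstored pairs are taken to be in linkage equilibrium (r^2 = 0); the
    diagonal is identically 1.
    """

    def __init__(self, pairs: dict[tuple[str, str], float] | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.set_r2(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set_r2(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2({a},{b})={r2} out of [0, 1]")
        if a == b:
            if r2 != 1.0:
                raise ValueError("diagonal r2 must be 1")
            return
        self._r2[self._key(a, b)] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def pairs(self) -> dict[tuple[str, str], float]:
        return dict(self._r2)


@dataclass
class GeneEvidence:
    """Evidence accumulated for one candidate gene."""

    gene_id: str
    positional_snps: set[str] = field(default_factory=set)
    eqtl_snps: set[str] = field(default_factory=set)
    chromatin_snps: set[str] = field(default_factory=set)

    @property
    def positional(self) -> bool:
        return bool(self.positional_snps)

    @property
    def eqtl(self) -> bool:
        return bool(self.eqtl_snps)

    @property
    def chromatin(self) -> bool:
        return bool(self.chromatin_snps)

    def merge(self, other: "GeneEvidence") -> None:
        self.positional_snps |= other.positional_snps
        self.eqtl_snps |= other.eqtl_snps
        self.chromatin_snps |= other.chromatin_snps


class CandidateGeneSet:
    """Mapping gene_id -> GeneEvidence; every member has >= 1 evidence flag."""

    def __init__(self) -> None:
        self._genes: dict[str, GeneEvidence] = {}

    def add(self, evidence: GeneEvidence) -> None:
        if not (evidence.positional or evidence.eqtl or evidence.chromatin):
            raise ValueError(f"{evidence.gene_id}: candidate gene without evidence")
        if evidence.gene_id in self._genes:
            self._genes[evidence.gene_id].merge(evidence)
        else:
            self._genes[evidence.gene_id] = evidence

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self):
        return iter(sorted(self._genes))

    def __getitem__(self, gene_id: str) -> GeneEvidence:
        return self._genes[gene_id]

    def genes(self) -> list[str]:
        return sorted(self._genes)


def prune_independent(
    snps: list[GwasSnp], ld: LdMatrix, r2_thresh: float = 0.6
) -> list[GwasSnp]:
    """Greedy LD clumping: keep the most significant SNP, drop its LD partners.

    SNPs are visited in ascending p (ties broken by rsid for determinism);
    a SNP is retained iff its r^2 with every already-retained SNP is below
    ``r2_thresh``. The returned set is pairwise independent and every
    dropped SNP is tagged (r^2 >= threshold) by a retained SNP of smaller
    or equal p.
    """
    rsids = [s.rsid for s in snps]
    if len(set(rsids)) != len(rsids):
        raise ValueError("duplicate rsids in SNP list")
    kept: list[GwasSnp] = []
    for snp in sorted(snps, key=lambda s: (s.pvalue, s.rsid)):
        if all(ld.r2(snp.rsid, k.rsid) < r2_thresh for k in kept):
            kept.append(snp)
    return kept


def expand_to_blocks(
    independent: list[GwasSnp],
    all_known: list[GwasSnp],
    ld: LdMatrix,
    r2_thresh: float = 0.6,
) -> list[GwasSnp]:
    """Add every known SNP in an LD block (r^2 >= thresh) with an independent SNP.

    A single hop only: partners of partners are not pulled in.
    """
    ind_ids = {s.rsid for s in independent}
    if not ind_ids <= {s.rsid for s in all_known}:
        raise ValueError("independent SNPs must be a subset of all_known")
    out = list(independent)
    for snp in all_known:
        if snp.rsid in ind_ids:
            continue
        if any(ld.r2(snp.rsid, i) >= r2_thresh for i in ind_ids):
            out.append(snp)
    return out


def map_positional(
    snps: list[GwasSnp],
    genes: list[GeneModel],
    max_dist_bp: int = 10_000,
) -> CandidateGeneSet:
    """Flag genes containing a SNP or within ``max_dist_bp`` of one.

    Distance is measured from the SNP to the nearer span edge; the 10 kb
    window applies symmetrically up- and downstream. SNPs on chromosomes
    absent from the gene set contribute nothing (a warning is emitted).
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.start - max_dist_bp, g.end + max_dist_bp, g
        )
    result = CandidateGeneSet()
    for snp in snps:
        tree = trees.get(snp.chrom)
        if tree is None:
            warnings.warn(
                f"SNP {snp.rsid}: chromosome {snp.chrom!r} not present in gene models",
                stacklevel=2,
            )
            continue
        pos0 = snp.pos - 1  # 0-based coordinate of the SNP base
        for iv in tree.at(pos0):
            gene: GeneModel = iv.data
            result.add(GeneEvidence(gene.gene_id, positional_snps={snp.rsid}))
    return result


def map_eqtl(
    snps: list[GwasSnp],
    eqtls: list[EqtlRecord],
    fdr_thresh: float = 0.05,
) -> CandidateGeneSet:
    """Flag genes with a significant eQTL (FDR <= thresh) for an input SNP.

    Any tissue qualifies; tissue identity is kept only as provenance on
    the eQTL records themselves.
    """
    snp_ids = {s.rsid for s in snps}
    result = CandidateGeneSet()
    for rec in eqtls:
        if rec.rsid in snp_ids and rec.fdr <= fdr_thresh:
            result.add(GeneEvidence(rec.gene_id, eqtl_snps={rec.rsid}))
    return result


def _overlaps(region: Region, chrom: str, lo: int, hi: int) -> bool:
    """Half-open interval overlap on the same chromosome."""
    rchrom, rstart, rend = region
    return rchrom == chrom and rstart < hi and lo < rend


def map_chromatin(
    snps: list[GwasSnp],
    interactions: list[ChromatinInteraction],
    genes: list[GeneModel],
    fdr_thresh: float = 1e-6,
    promoter_up_bp: int = 250,
    promoter_down_bp: int = 500,
    strand_aware_promoter: bool = True,
) -> CandidateGeneSet:
    """Flag genes whose promoter contacts a SNP-bearing region.

    An interaction counts only if it is significant (FDR <= thresh) and the
    SNP and the promoter overlap *opposite* ends of the contact. The
    promoter is the -250/+500 bp window around the TSS, mirrored on the
    minus strand unless ``strand_aware_promoter`` is False.
    """
    result = CandidateGeneSet()
    sig = [ia for ia in interactions if ia.fdr <= fdr_thresh]
    if not sig:
        return result
    promoters = []
    for g in genes:
        lo1, hi1 = g.promoter(promoter_up_bp, promoter_down_bp, strand_aware_promoter)
        promoters.append((g, lo1 - 1, hi1))  # to 0-based half-open
    for ia in sig:
        for ends in ((ia.region_a, ia.region_b), (ia.region_b, ia.region_a)):
            snp_end, gene_end = ends
            hit_snps = {
                s.rsid for s in snps if _overlaps(snp_end, s.chrom, s.pos - 1, s.pos)
            }
            if not hit_snps:
                continue
            for gene, plo, phi in promoters:
                if _overlaps(gene_end, gene.chrom, plo, phi):
                    result.add(GeneEvidence(gene.gene_id, chromatin_snps=set(hit_snps)))
    return result


def combine_candidates(*maps: CandidateGeneSet) -> CandidateGeneSet:
    """Union of candidate sets, merging evidence flags per gene."""
    combined = CandidateGeneSet()
    for m in maps:
        for gene_id in m:
            ev = m[gene_id]
            combined.add(
                GeneEvidence(
                    gene_id,
                    positional_snps=set(ev.positional_snps),
                    eqtl_snps=set(ev.eqtl_snps),
                    chromatin_snps=set(ev.chromatin_snps),
                )
            )
    return combined
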