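"""Tabular input/output for every pipeline stage.

Conventions: SNPs, LD, eQTL, phenotypes, burden matrices and results are
tab-separated with headers; gene models are BED6 plus a TSS side table
(BED is 0-based half-open, the TSS column is 1-based); chromatin
interactions are BEDPE with the interaction FDR in column 8; variants and
genotypes are a minimal VCF 4.2 with annotation INFO keys (GENE,
CSQ_CLASS, LOFTEE, SPLICEAI, REVEL, CADD, GNOMAD_POPMAX_AF) and GT
genotypes; traces and trajectories are headed CSV.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .burden import PhenotypeVector
from .coordination import BilateralTrace
from .snp2gene import (
    CandidateGeneSet,
    ChromatinInteraction,
    EqtlRecord,
    GeneModel,
    GwasSnp,
    LdMatrix,
)
from .weighting import BurdenMatrix, GenotypeMatrix, VariantAnnotation, WeightedVariant

# --- GWAS SNPs -------------------------------------------------------------


def write_snps_tsv(snps: Sequence[GwasSnp], path: str | Path) -> None:
    pd.DataFrame(
        [{"rsid": s.rsid, "chrom": s.chrom, "pos": s.pos, "p": s.pvalue} for s in snps]
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_snps_tsv(path: str | Path) -> list[GwasSnp]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        GwasSnp(str(r.rsid), str(r.chrom), int(r.pos), float(r.p))
        for r in df.itertuples()
    ]


# --- LD --------------------------------------------------------------------


def write_ld_tsv(ld: LdMatrix, path: str | Path) -> None:
    rows = [
        {"rsid1": a, "rsid2": b, "r2": r2}
        for (a, b), r2 in sorted(ld.pairs().items())
    ]
    pd.DataFrame(rows, columns=["rsid1", "rsid2", "r2"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_ld_tsv(path: str | Path) -> LdMatrix:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    ld = LdMatrix()
    for r in df.itertuples():
        ld.set_r2(str(r.rsid1), str(r.rsid2), float(r.r2))
    return ld


# --- gene models -----------------------------------------------------------


def write_genes_bed(genes: Sequence[GeneModel], bed_path: str | Path,
                    tss_path: str | Path) -> None:
    with open(bed_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for g in genes:
            w.writerow([g.chrom, g.start, g.end, g.gene_id, 0, g.strand])
    pd.DataFrame(
        [{"gene_id": g.gene_id, "tss": g.tss} for g in genes]
    ).to_csv(tss_path, sep="\t", index=False)


def read_genes_bed(bed_path: str | Path, tss_path: str | Path) -> list[GeneModel]:
    bed = pd.read_csv(
        bed_path, sep="\t", header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
    )
    tss = pd.read_csv(tss_path, sep="\t").set_index("gene_id")["tss"]
    return [
        GeneModel(str(r.gene_id), str(r.chrom), int(r.start), int(r.end),
                  str(r.strand), int(tss[r.gene_id]))
        for r in bed.itertuples()
    ]


# --- eQTL ------------------------------------------------------------------


def write_eqtl_tsv(eqtls: Sequence[EqtlRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{"rsid": e.rsid, "gene_id": e.gene_id, "tissue": e.tissue, "fdr": e.fdr}
         for e in eqtls]
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_eqtl_tsv(path: str | Path) -> list[EqtlRecord]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        EqtlRecord(str(r.rsid), str(r.gene_id), str(r.tissue), float(r.fdr))
        for r in df.itertuples()
    ]


# --- chromatin interactions (BEDPE) ---------------------------------------


def write_interactions_bedpe(
    interactions: Sequence[ChromatinInteraction], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for i, ia in enumerate(interactions):
            (c1, s1, e1), (c2, s2, e2) = ia.region_a, ia.region_b
            w.writerow([c1, s1, e1, c2, s2, e2, f"hic{i + 1}", ia.fdr])


def read_interactions_bedpe(path: str | Path) -> list[ChromatinInteraction]:
    df = pd.read_csv(
        path, sep="\t", header=None, float_precision="round_trip",
        names=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "fdr"],
    )
    return [
        ChromatinInteraction(
            (str(r.chrom1), int(r.start1), int(r.end1)),
            (str(r.chrom2), int(r.start2), int(r.end2)),
            float(r.fdr),
        )
        for r in df.itertuples()
    ]


# --- VCF -------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID={contigs}>
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene identifier">
##INFO=<ID=CSQ_CLASS,Number=1,Type=String,Description="Consequence class">
##INFO=<ID=LOFTEE,Number=1,Type=String,Description="LOFTEE confidence (HC/LC)">
##INFO=<ID=SPLICEAI,Number=1,Type=Float,Description="SpliceAI delta score">
##INFO=<ID=REVEL,Number=1,Type=Float,Description="REVEL score">
##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD phred score">
##INFO=<ID=GNOMAD_POPMAX_AF,Number=1,Type=Float,Description="gnomAD popmax AF">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(
    variants: Sequence[VariantAnnotation],
    genotypes: GenotypeMatrix,
    path: str | Path,
) -> None:
    """Minimal VCF 4.2 with annotation INFO keys and GT genotypes."""
    idx = sorted(range(len(variants)), key=lambda i: (variants[i].chrom,
                                                      variants[i].pos,
                                                      variants[i].variant_id))
    contigs = sorted({v.chrom for v in variants}) or ["chr1"]
    with open(path, "w", newline="") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        for line in _VCF_HEADER.splitlines()[2:]:
            fh.write(line + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.samples) + "\n")
        for i in idx:
            v = variants[i]
            info = [f"GENE={v.gene_id}", f"CSQ_CLASS={v.csq_class}"]
            if v.loftee is not None:
                info.append(f"LOFTEE={v.loftee}")
            if v.spliceai is not None:
                info.append(f"SPLICEAI={v.spliceai:.4g}")
            if v.revel is not None:
                info.append(f"REVEL={v.revel:.4g}")
            if v.cadd is not None:
                info.append(f"CADD={v.cadd:.4g}")
            info.append(f"GNOMAD_POPMAX_AF={v.popmax_af:.6g}")
            gts = "\t".join(_GT_STRINGS[int(g)] for g in genotypes.column(v.variant_id))
            fh.write(f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}\t.\t.\t"
                     + ";".join(info) + f"\tGT\t{gts}\n")


def read_vcf(path: str | Path) -> tuple[list[VariantAnnotation], GenotypeMatrix]:
    """Read an annotated VCF back into variants + genotype matrix."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[VariantAnnotation] = []
    cols: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"{rec.ID}: multi-allelic records must be pre-split")
        # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.asarray(rec.gt_types)
        counts = np.select([gt == 1, gt == 3], [1, 2], default=0).astype(np.int8)
        cols.append(counts)
        info = rec.INFO

        def fget(key):
            val = info.get(key)
            return None if val is None else float(val)

        variants.append(VariantAnnotation(
            variant_id=str(rec.ID),
            gene_id=str(info.get("GENE")),
            chrom=str(rec.CHROM), pos=int(rec.POS),
            ref=str(rec.REF), alt=str(rec.ALT[0]),
            csq_class=str(info.get("CSQ_CLASS")),
            loftee=None if info.get("LOFTEE") is None else str(info.get("LOFTEE")),
            spliceai=fget("SPLICEAI"), revel=fget("REVEL"), cadd=fget("CADD"),
            popmax_af=float(info.get("GNOMAD_POPMAX_AF") or 0.0),
            cohort_ac=int(counts.sum()),
        ))
    counts_mat = (np.column_stack(cols) if cols
                  else np.zeros((len(samples), 0), dtype=np.int8))
    geno = GenotypeMatrix(samples, [v.variant_id for v in variants], counts_mat)
    return variants, geno


# --- phenotypes ------------------------------------------------------------


def write_phenotypes_tsv(phenotype: PhenotypeVector, path: str | Path) -> None:
    phenotype.to_frame().to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path: str | Path) -> PhenotypeVector:
    df = pd.read_csv(path, sep="\t")
    status = df["status"].astype(str).str.lower().eq("case").to_numpy()
    cov_cols = [c for c in df.columns if c not in ("sample", "status")]
    cov = df[cov_cols] if cov_cols else None
    return PhenotypeVector([str(s) for s in df["sample"]], status, cov)


# --- weighted variants / burden matrix / results ---------------------------


def write_weighted_tsv(weights: Sequence[WeightedVariant], path: str | Path) -> None:
    pd.DataFrame(
        [{"variant_id": w.variant_id, "gene_id": w.gene_id, "weight": w.weight,
          "tier_reason": w.tier_reason} for w in weights]
    ).to_csv(path, sep="\t", index=False)


def write_burden_tsv(burden: BurdenMatrix, path: str | Path) -> None:
    burden.to_frame().to_csv(path, sep="\t")


def read_burden_tsv(path: str | Path) -> BurdenMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return BurdenMatrix.from_frame(df)


def write_candidates_tsv(candidates: CandidateGeneSet, path: str | Path) -> None:
    rows = []
    for gene_id in candidates:
        ev = candidates[gene_id]
        snps = sorted(ev.positional_snps | ev.eqtl_snps | ev.chromatin_snps)
        rows.append({
            "gene_id": gene_id,
            "positional": int(ev.positional),
            "eqtl": int(ev.eqtl),
            "chromatin": int(ev.chromatin),
            "supporting_snps": ",".join(snps),
        })
    pd.DataFrame(
        rows, columns=["gene_id", "positional", "eqtl", "chromatin", "supporting_snps"]
    ).to_csv(path, sep="\t", index=False)


def write_results_tsv(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False)


# --- traces and trajectories ----------------------------------------------


def write_trace_csv(trace: BilateralTrace, path: str | Path) -> None:
    trace.to_frame().to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> BilateralTrace:
    df = pd.read_csv(path)
    return BilateralTrace(df["time"].to_numpy(), df["left"].to_numpy(),
                          df["right"].to_numpy())


def write_trajectory_csv(traj: pd.DataFrame, path: str | Path) -> None:
    traj.to_csv(path, index=False)


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
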