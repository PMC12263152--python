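"""Synthetic inputs for every pipeline stage.

Real cohorts for this analysis sit under restricted accessions, so the
package ships a generator that emulates their statistical structure: a toy
chromosome of non-overlapping genes, GWAS SNPs arranged in LD blocks with
planted eQTL and chromatin links to a causal gene, an annotated
case-control cohort with ultra-rare qualifying variants and a carrier
enrichment planted at a target odds ratio, and bilateral calcium traces /
swim trajectories with known ground truth.

Defaults mirror the published study design: 41 genome-wide-significant
SNPs, a 156-gene candidate panel, 411 cases vs 3800 controls, and a causal
gene planted at OR ~ 4. Everything is deterministic per seed: one root
seed spawns an independent child stream per generator component.

The carrier model is a per-gene Bernoulli collapse: an individual either
carries >= 1 qualifying variant in a gene or not, with control carrier
probability p0 and case probability p1 chosen so that
odds(p1)/odds(p0) = target_or exactly. Each carrier receives a private
qualifying variant with positive weight; decoy variants that violate the
allele-frequency or allele-count gates (and weight-zero variants) are
added on top to exercise the downstream filters without perturbing the
planted effect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .snp2gene import ChromatinInteraction, EqtlRecord, GeneModel, GwasSnp, LdMatrix
from .weighting import AF_MAX, GenotypeMatrix, VariantAnnotation
from .burden import PhenotypeVector
from .coordination import BilateralTrace, EventSeries

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

# fixed child-stream ids so components stay independent of each other
_STREAMS = {
    "genes": 11,
    "gwas": 23,
    "cohort": 37,
    "traces": 53,
    "trajectory": 71,
}


@dataclass(frozen=True)
class ScoreParams:
    """Per-class in-silico score distributions for simulated variants.

    REVEL ~ Beta(a, b), CADD ~ Gamma(shape, scale), SpliceAI ~ Uniform.
    Carrier variants draw from these truncated to the qualifying side of
    the lowest positive weight tier; decoys draw the complementary side.
    Only threshold crossings matter downstream, so the shapes are free
    parameters of the simulation.
    """

    revel_a: float = 2.0
    revel_b: float = 2.0
    cadd_shape: float = 3.0
    cadd_scale: float = 5.0


@dataclass(frozen=True)
class TraceParams:
    """Bilateral calcium-trace generator settings.

    Recordings emulate 1-minute spinning-disk GCaMP movies at 10 fps:
    baseline fluorescence plus half-sine event bursts with Gaussian noise.
    Event rates are per channel in events/s.
    """

    fps: float = 10.0
    duration_s: float = 60.0
    f_left: float = 0.5
    f_right: float = 0.5
    noise_sd: float = 2.0  # raw intensity units
    pulse_width_s: float = 0.5
    baseline: float = 100.0
    amplitude: float = 150.0
    min_gap_s: float = 1.2  # enforced event separation (> pulse width + refractory)


@dataclass(frozen=True)
class TrajectoryParams:
    """Swim-track generator settings (centroid positions, mm)."""

    n_steps: int = 1200
    dt_s: float = 0.2
    step_len_mm: float = 1.0
    noise_sd_deg: float = 30.0


@dataclass(frozen=True)
class SimConfig:
    """Root configuration; identical config + seed gives identical outputs."""

    seed: int = 0
    n_genes: int = 156
    n_snps: int = 41
    ld_block_size: int = 4
    n_cases: int = 411
    n_controls: int = 3800
    causal_gene: str = "G0001"
    target_or: float = 4.0
    baseline_carrier_rate: float = 0.002
    variant_class_mix: dict[str, float] = field(
        default_factory=lambda: {
            "lof_canonical": 0.10,
            "noncanonical_splice": 0.10,
            "missense": 0.55,
            "inframe_indel": 0.15,
            "other": 0.10,
        }
    )
    score_params: ScoreParams = field(default_factory=ScoreParams)
    trace_params: TraceParams = field(default_factory=TraceParams)
    trajectory_params: TrajectoryParams = field(default_factory=TrajectoryParams)

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_snps", "ld_block_size", "n_cases", "n_controls"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.target_or <= 0:
            raise ValueError("target_or must be > 0")
        if not (0.0 <= self.baseline_carrier_rate <= 1.0):
            raise ValueError("baseline_carrier_rate must be in [0, 1]")
        mix = self.variant_class_mix
        if any(p < 0 for p in mix.values()) or not math.isclose(sum(mix.values()), 1.0,
                                                                abs_tol=1e-9):
            raise ValueError("variant_class_mix must be non-negative and sum to 1")

    def rng(self, component: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[component]])


def case_carrier_rate(p0: float, target_or: float) -> float:
    """Invert the odds ratio: p1 such that odds(p1) = target_or * odds(p0)."""
    if not (0.0 < p0 < 1.0):
        raise ValueError("baseline carrier rate must be in (0, 1) to plant an OR")
    odds1 = target_or * p0 / (1.0 - p0)
    p1 = odds1 / (1.0 + odds1)
    if p1 >= 1.0:  # unreachable for finite odds; guards degenerate float overflow
        raise ValueError("implied case carrier rate >= 1")
    return p1


def gen_gene_models(cfg: SimConfig) -> list[GeneModel]:
    """Non-overlapping gene spans on a toy chromosome.

    Genes are laid left to right with inter-gene gaps wide enough (>= 25 kb)
    that the 10 kb positional window around one gene can never reach its
    neighbour, keeping planted positional evidence unambiguous.
    """
    rng = cfg.rng("genes")
    genes: list[GeneModel] = []
    pos = 10_000
    for i in range(cfg.n_genes):
        length = int(rng.integers(2_000, 20_000))
        gap = int(rng.integers(25_000, 60_000))
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = pos, pos + length
        tss = start + 1 if strand == "+" else end
        genes.append(GeneModel(f"G{i + 1:04d}", "chr1", start, end, strand, tss))
        pos = end + gap
    return genes


def _causal_index(cfg: SimConfig, genes: list[GeneModel]) -> int:
    ids = [g.gene_id for g in genes]
    if cfg.causal_gene not in ids:
        raise ValueError(f"causal gene {cfg.causal_gene!r} not among generated genes")
    return ids.index(cfg.causal_gene)


def gen_gwas_inputs(
    cfg: SimConfig, genes: list[GeneModel]
) -> tuple[list[GwasSnp], LdMatrix, list[EqtlRecord], list[ChromatinInteraction]]:
    """SNPs in LD blocks plus planted and decoy mapping records.

    Each LD block sits near one gene (cycling through the gene list); the
    block lead SNP is genome-wide significant (p < 5e-8) and the rest are
    sub-threshold known SNPs. Within-block r^2 ~ Uniform(0.5, 0.95) so both
    prune-away (r^2 >= 0.6) and retain (r^2 < 0.6) pairs occur; across
    blocks r^2 = 0. eQTL and chromatin records link the causal gene's block
    to the causal gene below the significance thresholds, with decoy
    records above the thresholds that must never contribute a gene.
    """
    if not genes:
        raise ValueError("genes must be nonempty")
    rng = cfg.rng("gwas")
    causal_ix = _causal_index(cfg, genes)

    snps: list[GwasSnp] = []
    ld = LdMatrix()
    n_blocks = math.ceil(cfg.n_snps / cfg.ld_block_size)
    block_members: list[list[str]] = []
    for b in range(n_blocks):
        gene = genes[b % len(genes)]
        members: list[str] = []
        size = min(cfg.ld_block_size, cfg.n_snps - b * cfg.ld_block_size)
        for j in range(size):
            rsid = f"rs{b + 1:03d}{j:02d}"
            pos = int(gene.tss + rng.integers(-5_000, 5_000))
            pval = float(10 ** rng.uniform(-12, -9)) if j == 0 else float(
                10 ** rng.uniform(-6, -2)
            )
            snps.append(GwasSnp(rsid, gene.chrom, max(pos, 1), pval))
            members.append(rsid)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                ld.set_r2(members[i], members[j], float(rng.uniform(0.5, 0.95)))
        block_members.append(members)

    causal_block = block_members[causal_ix % n_blocks]
    causal_gene = genes[causal_ix]

    eqtls: list[EqtlRecord] = [
        EqtlRecord(causal_block[0], causal_gene.gene_id, "Muscle_Skeletal", 0.01)
    ]
    if len(causal_block) > 1:  # LD partner also carries the planted signal
        eqtls.append(
            EqtlRecord(causal_block[-1], causal_gene.gene_id, "Nerve_Tibial", 0.04)
        )
    for members in block_members:  # decoys above the 0.05 FDR threshold
        gene = genes[int(rng.integers(0, len(genes)))]
        eqtls.append(
            EqtlRecord(members[0], gene.gene_id, "Whole_Blood",
                       float(rng.uniform(0.06, 0.5)))
        )

    lead_snp = next(s for s in snps if s.rsid == causal_block[0])
    promoter_lo, promoter_hi = causal_gene.promoter()
    planted = ChromatinInteraction(
        (lead_snp.chrom, lead_snp.pos - 1_000, lead_snp.pos + 1_000),
        (causal_gene.chrom, promoter_lo - 1, promoter_hi),
        1e-8,
    )
    interactions = [planted]
    for members in block_members:  # significant but promoter-free decoy ends
        s = next(x for x in snps if x.rsid == members[0])
        far = int(rng.integers(5_000_000, 9_000_000))
        interactions.append(
            ChromatinInteraction(
                (s.chrom, s.pos - 1_000, s.pos + 1_000),
                (s.chrom, far, far + 2_000),
                1e-7,
            )
        )
        # sub-threshold decoy with perfect promoter geometry
        interactions.append(
            ChromatinInteraction(
                (s.chrom, s.pos - 1_000, s.pos + 1_000),
                (causal_gene.chrom, promoter_lo - 1, promoter_hi),
                1e-3,
            )
        )
    return snps, ld, eqtls, interactions


def _truncated_beta(rng: np.random.Generator, n: int, a: float, b: float,
                    lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    """Beta(a, b) draws conditioned on (lo, hi], by inverse-CDF sampling."""
    from scipy.stats import beta as beta_dist

    f_lo, f_hi = beta_dist.cdf([lo, hi], a, b)
    u = f_hi - rng.uniform(0.0, f_hi - f_lo, size=n)  # open at lo, closed at hi
    return beta_dist.ppf(u, a, b)


def _draw_carrier_variant_annotations(
    rng: np.random.Generator, n: int, cfg: SimConfig
) -> pd.DataFrame:
    """Classes and scores for carrier variants, constrained to weight > 0.

    Classes follow ``variant_class_mix`` renormalized over the four
    weight-bearing classes. Scores follow the configured distributions
    (REVEL ~ Beta, CADD ~ Gamma, SpliceAI ~ Uniform), with REVEL and
    SpliceAI truncated to the qualifying side of the lowest positive tier
    so every carrier's private variant has positive weight and the planted
    carrier odds ratio survives weighting intact (in-frame indels qualify
    at any CADD, so the Gamma is untruncated).
    """
    sp = cfg.score_params
    classes = ["lof_canonical", "noncanonical_splice", "missense", "inframe_indel"]
    probs = np.array([cfg.variant_class_mix.get(c, 0.0) for c in classes])
    if probs.sum() == 0:
        probs = np.ones(4)
    probs = probs / probs.sum()
    csq = rng.choice(classes, size=n, p=probs)
    loftee = np.where(rng.random(n) < 0.7, "HC", "LC")
    out = pd.DataFrame({
        "csq_class": csq,
        "loftee": np.where(csq == "lof_canonical", loftee, None),
        "spliceai": np.where(csq == "noncanonical_splice",
                             rng.uniform(np.nextafter(0.5, 1.0), 1.0, n),
                             np.nan),
        "revel": np.where(csq == "missense",
                          _truncated_beta(rng, n, sp.revel_a, sp.revel_b, lo=0.2),
                          np.nan),
        "cadd": np.where(csq == "inframe_indel",
                         rng.gamma(sp.cadd_shape, sp.cadd_scale, n), np.nan),
    })
    return out


def gen_cohort(
    cfg: SimConfig, genes: list[GeneModel]
) -> tuple[list[VariantAnnotation], GenotypeMatrix, PhenotypeVector]:
    """Annotated ultra-rare variants, genotypes and phenotypes with a planted OR.

    Carrier status per sample per gene is Bernoulli: control rate p0 =
    ``baseline_carrier_rate`` everywhere; case rate at the causal gene is
    p1 with odds(p1)/odds(p0) = ``target_or`` (equal rates when
    target_or = 1). Each carrier gets one private heterozygous qualifying
    variant. Per gene, three kinds of decoy variants exercise the filters:
    one with popmax AF above the 0.01% gate, one with cohort allele count
    above 3, and one qualifying but weight-zero variant.
    """
    if not genes:
        raise ValueError("genes must be nonempty")
    rng = cfg.rng("cohort")
    causal_ix = _causal_index(cfg, genes)
    n = cfg.n_cases + cfg.n_controls
    samples = [f"case{i + 1:05d}" for i in range(cfg.n_cases)] + [
        f"ctrl{i + 1:05d}" for i in range(cfg.n_controls)
    ]
    status = np.zeros(n, dtype=bool)
    status[: cfg.n_cases] = True

    p0 = cfg.baseline_carrier_rate
    p1 = case_carrier_rate(p0, cfg.target_or) if cfg.target_or != 1.0 else p0
    rates = np.full((n, len(genes)), p0)
    rates[status, causal_ix] = p1
    carrier = rng.random((n, len(genes))) < rates

    variant_rows: list[dict] = []
    geno_cols: list[np.ndarray] = []
    vid = 0
    for gix, gene in enumerate(genes):
        carriers = np.flatnonzero(carrier[:, gix])
        ann = _draw_carrier_variant_annotations(rng, carriers.size, cfg)
        a_csq = ann["csq_class"].to_numpy()
        a_loftee = ann["loftee"].to_numpy(dtype=object)
        a_spliceai = ann["spliceai"].to_numpy()
        a_revel = ann["revel"].to_numpy()
        a_cadd = ann["cadd"].to_numpy()
        a_pos = rng.integers(gene.start + 1, gene.end + 1, size=carriers.size)
        a_in_gnomad = rng.random(carriers.size) >= 0.6
        a_af = np.where(a_in_gnomad, rng.uniform(0, AF_MAX, carriers.size), 0.0)
        for row_ix, sample_ix in enumerate(carriers):
            vid += 1
            col = np.zeros(n, dtype=np.int8)
            col[sample_ix] = 1
            geno_cols.append(col)
            variant_rows.append({
                "variant_id": f"v{vid:06d}", "gene_id": gene.gene_id,
                "chrom": gene.chrom, "pos": int(a_pos[row_ix]),
                "csq_class": a_csq[row_ix], "loftee": a_loftee[row_ix],
                "spliceai": a_spliceai[row_ix], "revel": a_revel[row_ix],
                "cadd": a_cadd[row_ix], "popmax_af": float(a_af[row_ix]),
            })
        # decoy 1: too common in gnomAD (caught by the AF gate)
        vid += 1
        col = np.zeros(n, dtype=np.int8)
        col[rng.choice(n, size=2, replace=False)] = 1
        geno_cols.append(col)
        variant_rows.append({
            "variant_id": f"v{vid:06d}", "gene_id": gene.gene_id,
            "chrom": gene.chrom,
            "pos": int(rng.integers(gene.start + 1, gene.end + 1)),
            "csq_class": "missense", "loftee": None, "spliceai": np.nan,
            "revel": float(_truncated_beta(rng, 1, cfg.score_params.revel_a,
                                           cfg.score_params.revel_b, lo=0.2)[0]),
            "cadd": np.nan,
            "popmax_af": float(rng.uniform(1.5 * AF_MAX, 5e-3)),
        })
        # decoy 2: cohort allele count above the AC gate
        vid += 1
        col = np.zeros(n, dtype=np.int8)
        col[rng.choice(n, size=5, replace=False)] = 1
        geno_cols.append(col)
        variant_rows.append({
            "variant_id": f"v{vid:06d}", "gene_id": gene.gene_id,
            "chrom": gene.chrom,
            "pos": int(rng.integers(gene.start + 1, gene.end + 1)),
            "csq_class": "missense", "loftee": None, "spliceai": np.nan,
            "revel": float(_truncated_beta(rng, 1, cfg.score_params.revel_a,
                                           cfg.score_params.revel_b, lo=0.2)[0]),
            "cadd": np.nan,
            "popmax_af": 0.0,
        })
        # decoy 3: qualifying but weight-zero (benign missense)
        vid += 1
        col = np.zeros(n, dtype=np.int8)
        col[int(rng.integers(0, n))] = 1
        geno_cols.append(col)
        variant_rows.append({
            "variant_id": f"v{vid:06d}", "gene_id": gene.gene_id,
            "chrom": gene.chrom,
            "pos": int(rng.integers(gene.start + 1, gene.end + 1)),
            "csq_class": "missense", "loftee": None, "spliceai": np.nan,
            "revel": float(_truncated_beta(rng, 1, cfg.score_params.revel_a,
                                           cfg.score_params.revel_b, hi=0.2)[0]),
            "cadd": np.nan,
            "popmax_af": 0.0,
        })

    counts = np.column_stack(geno_cols) if geno_cols else np.zeros((n, 0), dtype=np.int8)
    ac_all = counts.sum(axis=0)
    ref = rng.choice(_BASES, size=len(variant_rows))
    variants = []
    for j, row in enumerate(variant_rows):
        alt_choices = [b for b in "ACGT" if b != ref[j]]
        variants.append(VariantAnnotation(
            variant_id=row["variant_id"], gene_id=row["gene_id"],
            chrom=row["chrom"], pos=row["pos"], ref=str(ref[j]),
            alt=alt_choices[j % 3],
            csq_class=row["csq_class"],
            loftee=None if row["loftee"] is None else str(row["loftee"]),
            spliceai=None if pd.isna(row["spliceai"]) else float(row["spliceai"]),
            revel=None if pd.isna(row["revel"]) else float(row["revel"]),
            cadd=None if pd.isna(row["cadd"]) else float(row["cadd"]),
            popmax_af=row["popmax_af"],
            cohort_ac=int(ac_all[j]),
        ))
    genotypes = GenotypeMatrix(samples, [v.variant_id for v in variants], counts)
    phenotype = PhenotypeVector(samples, status)
    return variants, genotypes, phenotype


def _event_times(rng: np.random.Generator, rate: float, duration: float,
                 min_gap: float, offset: float = 0.0) -> np.ndarray:
    """Poisson event count, times uniform subject to a minimum gap."""
    if rate <= 0:
        return np.array([])
    start = 1.0 + offset  # keep pulses clear of the trace edges
    avail = duration - start - 1.0
    k_max = max(int(avail // min_gap), 0)
    k = min(int(rng.poisson(rate * duration)), k_max)
    if k == 0:
        return np.array([])
    slack = avail - (k - 1) * min_gap
    u = np.sort(rng.uniform(0, slack, size=k))
    return start + u + min_gap * np.arange(k)


def gen_bilateral_traces(cfg: SimConfig) -> tuple[BilateralTrace, EventSeries]:
    """Baseline + half-sine burst traces with ground-truth event times.

    Event counts per channel are Poisson at the configured rates (capped so
    the minimum gap is feasible); the right channel is phase-offset by half
    the left inter-event interval so the two sides alternate, as in an
    intact left-right central pattern generator. Returns the raw trace and
    the ground-truth event series.
    """
    tp = cfg.trace_params
    if tp.fps <= 0 or tp.duration_s <= 0:
        raise ValueError("fps and duration must be positive")
    rng = cfg.rng("traces")
    n_frames = int(round(tp.fps * tp.duration_s))
    time = np.arange(n_frames) / tp.fps
    left_t = _event_times(rng, tp.f_left, tp.duration_s, tp.min_gap_s)
    offset = 0.5 / tp.f_left if tp.f_left > 0 else 0.0
    right_t = _event_times(rng, tp.f_right, tp.duration_s, tp.min_gap_s,
                           offset=min(offset, tp.min_gap_s))

    def synth(events: np.ndarray) -> np.ndarray:
        sig = np.full(n_frames, tp.baseline)
        for t0 in events:
            mask = (time >= t0) & (time < t0 + tp.pulse_width_s)
            sig[mask] += tp.amplitude * np.sin(
                np.pi * (time[mask] - t0) / tp.pulse_width_s
            )
        if tp.noise_sd > 0:
            sig = sig + rng.normal(0, tp.noise_sd, n_frames)
        return np.maximum(sig, 0.01 * tp.baseline)  # fluorescence stays positive

    trace = BilateralTrace(time, synth(left_t), synth(right_t))
    truth = EventSeries(left_t, right_t, tp.duration_s)
    return trace, truth


def gen_trajectory(
    cfg: SimConfig, turn_bias_deg_per_step: float = 0.0
) -> pd.DataFrame:
    """Correlated random-walk swim track (columns time, x, y).

    Heading changes per step are ``turn_bias_deg_per_step`` plus Gaussian
    noise; a non-zero bias emulates the one-sided turning preference of
    left-right-uncoordinated larvae. The first step heads along +x, so a
    track of n steps exposes n - 1 turning angles.
    """
    tj = cfg.trajectory_params
    if tj.n_steps < 2:
        raise ValueError("need at least 2 steps")
    rng = cfg.rng("trajectory")
    turns = np.radians(
        turn_bias_deg_per_step + rng.normal(0, tj.noise_sd_deg, tj.n_steps - 1)
    )
    headings = np.concatenate([[0.0], np.cumsum(turns)])
    dx = tj.step_len_mm * np.cos(headings)
    dy = tj.step_len_mm * np.sin(headings)
    x = np.concatenate([[0.0], np.cumsum(dx)])
    y = np.concatenate([[0.0], np.cumsum(dy)])
    time = np.arange(tj.n_steps + 1) * tj.dt_s
    return pd.DataFrame({"time": time, "x": x, "y": y})
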