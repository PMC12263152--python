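"""LD pruning, block expansion and the three gene-mapping strategies."""

import itertools

import numpy as np
import pytest

from scoliogen.snp2gene import (
    CandidateGeneSet,
    ChromatinInteraction,
    EqtlRecord,
    GeneEvidence,
    GeneModel,
    GwasSnp,
    LdMatrix,
    combine_candidates,
    expand_to_blocks,
    map_chromatin,
    map_eqtl,
    map_positional,
    prune_independent,
)


def snp(rsid, pos=100, p=1e-9, chrom="chr1"):
    return GwasSnp(rsid, chrom, pos, p)


def pruning_oracle(snps, ld, r2_thresh):
    """All subsets satisfying the clumping post-condition, by enumeration.

    A subset qualifies if it is pairwise independent (all r^2 < thresh) and
    every excluded SNP is tagged by a retained SNP of smaller-or-equal p.
    """
    valid = []
    for r in range(len(snps) + 1):
        for subset in itertools.combinations(snps, r):
            ids = {s.rsid for s in subset}
            if any(ld.r2(a.rsid, b.rsid) >= r2_thresh
                   for a, b in itertools.combinations(subset, 2)):
                continue
            ok = all(
                any(k.pvalue <= s.pvalue and ld.r2(s.rsid, k.rsid) >= r2_thresh
                    for k in subset)
                for s in snps if s.rsid not in ids
            )
            if ok:
                valid.append(ids)
    return valid


class TestPruneIndependent:
    def test_three_snp_example(self):
        a, b, c = snp("A", p=1e-10), snp("B", p=1e-9), snp("C", p=1e-8)
        ld = LdMatrix({("A", "B"): 0.7, ("A", "C"): 0.1, ("B", "C"): 0.1})
        kept = prune_independent([a, b, c], ld)
        assert {s.rsid for s in kept} == {"A", "C"}
        assert {s.rsid for s in kept} in pruning_oracle([a, b, c], ld, 0.6)

    def test_single_snp(self):
        assert prune_independent([snp("A")], LdMatrix()) == [snp("A")]

    def test_no_ld_keeps_all(self):
        snps = [snp(f"S{i}", p=10 ** -(9 + i)) for i in range(5)]
        assert prune_independent(snps, LdMatrix()) == sorted(
            snps, key=lambda s: s.pvalue
        )

    def test_duplicate_rsids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            prune_independent([snp("A"), snp("A")], LdMatrix())

    def test_idempotent(self, rng):
        snps = [snp(f"S{i}", p=float(p)) for i, p in
                enumerate(rng.uniform(1e-12, 1e-8, 8))]
        ld = LdMatrix()
        for i in range(8):
            for j in range(i + 1, 8):
                if rng.random() < 0.4:
                    ld.set_r2(f"S{i}", f"S{j}", float(rng.uniform(0.3, 1.0)))
        once = prune_independent(snps, ld)
        assert prune_independent(once, ld) == once

    def test_matches_oracle_on_random_instances(self, rng):
        """Greedy clumping satisfies the enumerated post-condition, n <= 12."""
        for _ in range(60):
            n = int(rng.integers(2, 9))
            snps = [snp(f"S{i}", p=float(p)) for i, p in
                    enumerate(rng.uniform(1e-12, 1e-8, n))]
            ld = LdMatrix()
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.5:
                        ld.set_r2(f"S{i}", f"S{j}", float(rng.uniform(0.0, 1.0)))
            kept = {s.rsid for s in prune_independent(snps, ld)}
            assert kept in pruning_oracle(snps, ld, 0.6)


class TestExpandToBlocks:
    def test_partner_above_threshold_included(self):
        a, d = snp("A", p=1e-10), snp("D", p=1e-3)
        ld = LdMatrix({("A", "D"): 0.65})
        assert {s.rsid for s in expand_to_blocks([a], [a, d], ld)} == {"A", "D"}

    def test_boundary_inclusive_at_0_6(self):
        a, d, e = snp("A", p=1e-10), snp("D", p=1e-3), snp("E", p=1e-3)
        ld = LdMatrix({("A", "D"): 0.6, ("A", "E"): 0.59})
        assert {s.rsid for s in expand_to_blocks([a], [a, d, e], ld)} == {"A", "D"}

    def test_no_transitive_closure(self):
        a, d, f = snp("A", p=1e-10), snp("D", p=1e-3), snp("F", p=1e-3)
        ld = LdMatrix({("A", "D"): 0.7, ("D", "F"): 0.7, ("A", "F"): 0.1})
        expanded = {s.rsid for s in expand_to_blocks([a], [a, d, f], ld)}
        # transitive closure oracle would pull in F through D
        closure = {"A", "D", "F"}
        assert expanded == {"A", "D"} and expanded != closure

    def test_independent_must_be_subset(self):
        with pytest.raises(ValueError):
            expand_to_blocks([snp("A")], [snp("B")], LdMatrix())


GENE = GeneModel("G1", "chr1", 50_000, 60_000, "+", 50_001)


class TestMapPositional:
    @pytest.mark.parametrize(
        "pos, included",
        [
            (50_001 - 9_999, True),   # 9,999 bp upstream
            (50_001 - 10_000, True),  # exactly 10 kb
            (50_001 - 10_001, False),  # 10,001 bp upstream
            (55_000, True),            # inside the span
            (60_000 + 10_000, True),   # 10 kb downstream
            (60_000 + 10_001, False),
        ],
    )
    def test_10kb_window(self, pos, included):
        result = map_positional([snp("S", pos=pos)], [GENE])
        assert ("G1" in result) is included

    def test_chromosome_mismatch_warns(self):
        with pytest.warns(UserWarning, match="chromosome"):
            result = map_positional([snp("S", chrom="chr9")], [GENE])
        assert len(result) == 0

    def test_monotone_in_max_dist(self, rng):
        snps = [snp(f"S{i}", pos=int(p)) for i, p in
                enumerate(rng.integers(1, 200_000, 30))]
        small = map_positional(snps, [GENE], max_dist_bp=5_000)
        large = map_positional(snps, [GENE], max_dist_bp=50_000)
        assert set(small.genes()) <= set(large.genes())


class TestMapEqtl:
    def test_fdr_boundary_inclusive(self):
        rec_in = EqtlRecord("S", "G1", "muscle", 0.05)
        rec_out = EqtlRecord("S", "G1", "muscle", 0.051)
        assert "G1" in map_eqtl([snp("S")], [rec_in])
        assert "G1" not in map_eqtl([snp("S")], [rec_out])

    def test_snp_not_in_input(self):
        rec = EqtlRecord("OTHER", "G1", "muscle", 0.01)
        assert len(map_eqtl([snp("S")], [rec])) == 0

    def test_monotone_in_fdr_thresh(self, rng):
        recs = [EqtlRecord("S", f"G{i}", "t", float(f))
                for i, f in enumerate(rng.uniform(0, 0.2, 20))]
        lo = map_eqtl([snp("S")], recs, fdr_thresh=0.01)
        hi = map_eqtl([snp("S")], recs, fdr_thresh=0.1)
        assert set(lo.genes()) <= set(hi.genes())


class TestMapChromatin:
    # promoter of GENE (+ strand, tss 50,001): 1-based [49,751, 50,501]
    SNP = snp("S", pos=10_000)
    REGION_SNP = ("chr1", 9_000, 11_000)
    REGION_PROM = ("chr1", 49_900, 50_100)

    def test_significant_interaction_maps_gene(self):
        ia = ChromatinInteraction(self.REGION_SNP, self.REGION_PROM, 1e-7)
        assert "G1" in map_chromatin([self.SNP], [ia], [GENE])

    def test_subthreshold_fdr_excluded(self):
        ia = ChromatinInteraction(self.REGION_SNP, self.REGION_PROM, 1e-5)
        assert "G1" not in map_chromatin([self.SNP], [ia], [GENE])

    def test_same_end_only_excluded(self):
        """SNP and promoter on the same end must not pair (oracle check)."""
        both = ("chr1", 9_000, 60_000)  # covers SNP and promoter together
        far = ("chr2", 1, 1_000)
        ia = ChromatinInteraction(both, far, 1e-8)
        result = map_chromatin([self.SNP], [ia], [GENE])
        # brute-force end pairing: only (A->B) and (B->A) are legal pairings
        legal = any(
            s and g
            for s, g in [
                (True, False),  # snp in A, promoter must be in B: it is not
                (False, True),  # snp in B: it is not
            ]
        )
        assert not legal and "G1" not in result

    def test_minus_strand_promoter_mirrored(self):
        gene_minus = GeneModel("Gm", "chr1", 50_000, 60_000, "-", 60_000)
        # mirrored promoter: [tss-500, tss+250] = [59,500, 60,250]
        prom_hit = ("chr1", 59_400, 59_550)
        ia = ChromatinInteraction(self.REGION_SNP, prom_hit, 1e-8)
        assert "Gm" in map_chromatin([self.SNP], [ia], [gene_minus])
        assert "Gm" not in map_chromatin(
            [self.SNP], [ia], [gene_minus], strand_aware_promoter=False
        )


class TestCombineAndInvariance:
    def _set(self, genes, flag):
        cs = CandidateGeneSet()
        for g in genes:
            cs.add(GeneEvidence(g, **{flag: {"S"}}))
        return cs

    def test_union_arithmetic(self):
        combined = combine_candidates(
            self._set(["A", "B"], "positional_snps"),
            self._set(["C", "D", "E"], "eqtl_snps"),
            self._set(["F", "G", "H", "I"], "chromatin_snps"),
        )
        assert len(combined) == 9

    def test_same_gene_three_flags(self):
        combined = combine_candidates(
            self._set(["A"], "positional_snps"),
            self._set(["A"], "eqtl_snps"),
            self._set(["A"], "chromatin_snps"),
        )
        assert len(combined) == 1
        ev = combined["A"]
        assert ev.positional and ev.eqtl and ev.chromatin

    def test_empty_inputs(self):
        assert len(combine_candidates(CandidateGeneSet(), CandidateGeneSet())) == 0

    def test_strand_reflection_symmetry(self, rng):
        """Mirroring all coordinates and strands leaves the candidate set fixed."""
        L = 1_000_000
        genes, snps = [], []
        for i in range(5):
            start = int(rng.integers(10_000, L - 50_000))
            end = start + int(rng.integers(2_000, 10_000))
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start + 1 if strand == "+" else end
            genes.append(GeneModel(f"G{i}", "chr1", start, end, strand, tss))
        for i in range(10):
            snps.append(snp(f"S{i}", pos=int(rng.integers(1, L))))

        def reflect_gene(g):
            start, end = L - g.end, L - g.start
            strand = "-" if g.strand == "+" else "+"
            tss = start + 1 if strand == "+" else end
            return GeneModel(g.gene_id, g.chrom, start, end, strand, tss)

        def reflect_snp(s):
            return GwasSnp(s.rsid, s.chrom, L - s.pos + 1, s.pvalue)

        fwd = map_positional(snps, genes)
        rev = map_positional([reflect_snp(s) for s in snps],
                             [reflect_gene(g) for g in genes])
        assert set(fwd.genes()) == set(rev.genes())
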