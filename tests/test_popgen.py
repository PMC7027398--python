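"""F_ST, diversity and dN/dS estimators against hand values and oracles."""

import itertools

import numpy as np
import pytest

from gardenscan.containers import Gene
from gardenscan.popgen import (
    codon_path_differences,
    codon_site_counts,
    gene_pi,
    jukes_cantor,
    ld_thin,
    pairwise_dnds,
    pca,
    site_pi,
    weir_cockerham_fst,
)
from oracles import (
    make_dataset,
    ng_differences_oracle,
    ng_dnds_oracle,
    ng_sites_oracle,
    site_pi_oracle,
    wc_theta_oracle,
)


def two_group_fst(dosage, n_a, n_b):
    d = np.asarray(dosage, np.int8)
    return weir_cockerham_fst(d, np.arange(n_a), np.arange(n_a, n_a + n_b))


class TestWeirCockerham:
    def test_fixed_difference_components_exact(self):
        """5 hom-REF vs 5 hom-ALT: a = 0.5, b = c = 0, theta = 1."""
        dosage = [[0] * 5 + [2] * 5]
        res = two_group_fst(dosage, 5, 5)
        assert res["a"].item() == pytest.approx(0.5, abs=1e-12)
        assert res["b"].item() == pytest.approx(0.0, abs=1e-12)
        assert res["c"].item() == pytest.approx(0.0, abs=1e-12)
        assert res["theta"].item() == pytest.approx(1.0, abs=1e-12)

    def test_identical_groups_nonpositive(self):
        dosage = [[0, 1, 2, 1, 0] * 2]
        res = two_group_fst(dosage, 5, 5)
        assert res["defined"].item()
        assert res["theta"].item() <= 0

    def test_monomorphic_undefined(self):
        res = two_group_fst([[0] * 10], 5, 5)
        assert not res["defined"].item()
        assert np.isnan(res["theta"].item())

    def test_small_group_undefined(self):
        dosage = np.array([[2, -1, -1, 0, 0, 1, 1, 0]], np.int8)
        res = weir_cockerham_fst(dosage, np.arange(3), np.arange(3, 8))
        assert not res["defined"].item()  # only 1 called in group a

    def test_label_swap_and_within_group_permutation_invariance(self):
        rng = np.random.default_rng(7)
        dosage = rng.integers(0, 3, (50, 25)).astype(np.int8)
        dosage[rng.random((50, 25)) < 0.1] = -1
        a, b = np.arange(5), np.arange(5, 25)
        t1 = weir_cockerham_fst(dosage, a, b)["theta"]
        t2 = weir_cockerham_fst(dosage, b, a)["theta"]
        t3 = weir_cockerham_fst(dosage, rng.permutation(a), rng.permutation(b))["theta"]
        np.testing.assert_allclose(t1, t2, atol=1e-12)
        np.testing.assert_allclose(t1, t3, atol=1e-12)

    def test_matches_scalar_per_allele_oracle(self):
        """200 random SNPs, groups of 5 and 20 with missingness: theta agrees
        with the independent per-allele-sum formulation to 1e-10."""
        rng = np.random.default_rng(12)
        dosage = rng.integers(0, 3, (200, 25)).astype(np.int8)
        dosage[rng.random((200, 25)) < 0.15] = -1
        res = weir_cockerham_fst(dosage, np.arange(5), np.arange(5, 25))
        for i in range(200):
            want = wc_theta_oracle(dosage[i, :5].tolist(), dosage[i, 5:].tolist())
            if want is None:
                assert not res["defined"][i]
            else:
                assert res["defined"][i]
                assert res["theta"][i] == pytest.approx(want, abs=1e-10)


class TestPi:
    def test_site_pi_hand_value(self):
        """2 diploids with 2 ref and 2 alt alleles: 6 allele pairs, 4 differ
        -> 2/3; over a 100 bp CDS the gene pi is 0.006667."""
        assert site_pi(np.array([1, 1], np.int8), np.arange(2)) == pytest.approx(2 / 3)
        gene = Gene("g", "chr1", "+", 0, 102, cds=[(0, 102)])
        ds = make_dataset(np.array([[1, 1]], np.int8), positions=[10])
        assert gene_pi(ds, gene, np.arange(2)) == pytest.approx((2 / 3) / 102)

    def test_monomorphic_gene_zero(self):
        gene = Gene("g", "chr1", "+", 0, 60, cds=[(0, 60)])
        ds = make_dataset(np.zeros((3, 4), np.int8), positions=[5, 10, 15])
        assert gene_pi(ds, gene, np.arange(4)) == 0.0

    def test_no_cds_undefined(self):
        gene = Gene("g", "chr1", "+", 0, 60, cds=[])
        ds = make_dataset(np.zeros((1, 4), np.int8))
        assert np.isnan(gene_pi(ds, gene, np.arange(4)))

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(19)
        gene = Gene("g", "chr1", "+", 0, 300, cds=[(0, 300)])
        for trial in range(10):
            dosage = rng.integers(0, 3, (8, 10)).astype(np.int8)
            dosage[rng.random((8, 10)) < 0.2] = -1
            pos = sorted(rng.choice(np.arange(1, 301), size=8, replace=False))
            ds = make_dataset(dosage, positions=pos)
            want = sum(site_pi_oracle(dosage[i]) for i in range(8)) / 300
            assert gene_pi(ds, gene, np.arange(10)) == pytest.approx(want, abs=1e-12)

    def test_invariant_to_order_and_monomorphic_records(self):
        rng = np.random.default_rng(20)
        gene = Gene("g", "chr1", "+", 0, 120, cds=[(0, 120)])
        dosage = rng.integers(0, 3, (5, 8)).astype(np.int8)
        pos = [11, 25, 40, 77, 102]
        base = gene_pi(make_dataset(dosage, positions=pos), gene, np.arange(8))
        perm = [3, 1, 4, 0, 2]
        shuffled = gene_pi(make_dataset(dosage[perm], positions=[pos[i] for i in perm]),
                           gene, np.arange(8))
        padded = gene_pi(make_dataset(
            np.vstack([dosage, np.zeros((2, 8), np.int8)]), positions=pos + [55, 90]),
            gene, np.arange(8))
        assert shuffled == pytest.approx(base, abs=1e-15)
        assert padded == pytest.approx(base, abs=1e-15)


def _coding_gene_with_snps(cds_seq, snp_cds_idx, dosage, strand="+"):
    """Build a single-exon gene + dataset with SNPs at given CDS indices."""
    L = len(cds_seq)
    genomic = cds_seq if strand == "+" else "".join(
        {"A": "T", "C": "G", "G": "C", "T": "A"}[b] for b in reversed(cds_seq))
    genome = {"chr1": genomic}
    gene = Gene("g", "chr1", strand, 0, L, exons=[(0, L)], cds=[(0, L)])
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    positions, refs, alts = [], [], []
    for i, alt_mrna in snp_cds_idx:
        pos0 = i if strand == "+" else L - 1 - i
        ref = genome["chr1"][pos0]
        alt = alt_mrna if strand == "+" else comp[alt_mrna]
        positions.append(pos0 + 1)
        refs.append(ref)
        alts.append(alt)
    order = np.argsort(positions)
    ds = make_dataset(np.asarray(dosage, np.int8)[order],
                      positions=[positions[i] for i in order],
                      ref=[refs[i] for i in order], alt=[alts[i] for i in order])
    return gene, genome, ds


class TestDnDs:
    def test_identical_sequences_zero(self):
        cds = "ATGAAACCCGGGTTTTGA"
        gene, genome, ds = _coding_gene_with_snps(cds, [], np.empty((0, 4)))
        res = pairwise_dnds(ds, gene, genome, np.arange(4))
        assert res.dn == 0 and res.ds == 0 and np.isnan(res.ratio)

    def test_fourfold_degenerate_third_position(self):
        """GGT <-> GGC (both Gly): one synonymous difference, dN = 0."""
        cds = "ATGGGTAAACCCTGA"
        # SNP at CDS index 5 (third base of GGT), ALT C on mRNA
        dosage = [[0, 0, 2, 2]]  # two hom-ref, two hom-alt diploids
        gene, genome, ds = _coding_gene_with_snps(cds, [(5, "C")], dosage)
        res = pairwise_dnds(ds, gene, genome, np.arange(4))
        assert res.dn == 0.0
        assert res.ds > 0
        n_codon = codon_site_counts("GGT")
        assert n_codon[1] == pytest.approx(1.0)  # GGT has exactly 1 syn site

    def test_codon_pathway_function_matches_enumeration(self):
        rng = np.random.default_rng(27)
        bases = "ACGT"
        for _ in range(300):
            c1 = "".join(rng.choice(list(bases), 3))
            c2 = "".join(rng.choice(list(bases), 3))
            if c1 in ("TAA", "TAG", "TGA") or c2 in ("TAA", "TAG", "TGA"):
                continue
            got = codon_path_differences(c1, c2)
            want = ng_differences_oracle(c1, c2)
            assert got[0] == pytest.approx(want[0], abs=1e-12)
            assert got[1] == pytest.approx(want[1], abs=1e-12)

    def test_site_counts_match_enumeration(self):
        rng = np.random.default_rng(28)
        codons = [c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
                  if c not in ("TAA", "TAG", "TGA")]
        for c in rng.choice(codons, 30, replace=False):
            n, s = codon_site_counts(str(c))
            wn, ws = ng_sites_oracle(str(c))
            assert n == pytest.approx(wn, abs=1e-12)
            assert s == pytest.approx(ws, abs=1e-12)

    def test_random_gene_matches_sequence_oracle(self):
        """dN/dS over random diploid genotypes equals explicit enumeration
        over every haplotype pair of full sequences."""
        rng = np.random.default_rng(29)
        nonstop = [c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
                   if c not in ("TAA", "TAG", "TGA")]
        cds = "ATG" + "".join(rng.choice(nonstop, 28)) + "TGA"
        snps = []
        for i in sorted(rng.choice(np.arange(3, len(cds) - 3), 6, replace=False)):
            ref = cds[i]
            alt = [b for b in "ACGT" if b != ref][rng.integers(0, 3)]
            snps.append((int(i), alt))
        dosage = rng.integers(0, 3, (6, 5))
        gene, genome, ds = _coding_gene_with_snps(cds, snps, dosage)
        res = pairwise_dnds(ds, gene, genome, np.arange(5))

        # oracle: build all 10 haplotype sequences explicitly
        order = np.argsort([i for i, _ in snps])
        sorted_snps = [snps[k] for k in order]
        sorted_dosage = np.asarray(dosage)[order]
        haps = []
        for j in range(5):
            for hap in range(2):
                seq = list(cds)
                for (i, alt), d in zip(sorted_snps, sorted_dosage[:, j]):
                    carries = d == 2 or (d == 1 and hap == 0)  # ALT on hap 1
                    if carries:
                        seq[i] = alt
                haps.append("".join(seq[:-3]))  # drop terminal stop codon
        dns, dss = [], []
        for s1, s2 in itertools.combinations(haps, 2):
            dn, dsyn = ng_dnds_oracle(s1, s2)
            dns.append(dn)
            dss.append(dsyn)
        assert res.dn == pytest.approx(np.mean(dns), abs=1e-10)
        assert res.ds == pytest.approx(np.mean(dss), abs=1e-10)

    def test_minus_strand_consistent(self):
        cds = "ATGGGTAAACCCTGA"
        dosage = [[0, 2, 1]]
        gp, genp, dsp = _coding_gene_with_snps(cds, [(5, "C")], dosage, strand="+")
        gm, genm, dsm = _coding_gene_with_snps(cds, [(5, "C")], dosage, strand="-")
        rp = pairwise_dnds(dsp, gp, genp, np.arange(3))
        rm = pairwise_dnds(dsm, gm, genm, np.arange(3))
        assert rp.dn == pytest.approx(rm.dn, abs=1e-12)
        assert rp.ds == pytest.approx(rm.ds, abs=1e-12)

    def test_neutral_variation_ratio_near_one(self):
        """Random substitutions sprinkled uniformly over codon positions give
        dN/dS ~ 1 within Monte-Carlo error."""
        rng = np.random.default_rng(30)
        nonstop = [c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
                   if c not in ("TAA", "TAG", "TGA")]
        ratios = []
        for trial in range(15):
            cds = "ATG" + "".join(rng.choice(nonstop, 200)) + "TGA"
            snps = []
            for i in sorted(rng.choice(np.arange(3, len(cds) - 3), 12, replace=False)):
                ref = cds[i]
                alt = [b for b in "ACGT" if b != ref][rng.integers(0, 3)]
                snps.append((int(i), alt))
            dosage = rng.integers(0, 3, (12, 6))
            gene, genome, ds = _coding_gene_with_snps(cds, snps, dosage)
            res = pairwise_dnds(ds, gene, genome, np.arange(6))
            if np.isfinite(res.ratio):
                ratios.append(res.ratio)
        assert 0.75 < np.mean(ratios) < 1.3

    def test_jukes_cantor_saturation_flagged(self):
        d, ok = jukes_cantor(0.8)
        assert d == 0.8 and not ok


class TestLdThin:
    def test_window_arithmetic(self):
        ds_sites = make_dataset(np.ones((3, 2)), positions=[100, 4900, 5100]).sites
        keep = ld_thin(ds_sites, 5000)
        assert ds_sites.loc[keep, "pos"].tolist() == [100, 5100]

    def test_single_window_keeps_one(self):
        sites = make_dataset(np.ones((10, 2)), positions=list(range(200, 1200, 100))).sites
        assert ld_thin(sites, 5000).sum() == 1

    def test_matches_floor_grouping_oracle(self):
        rng = np.random.default_rng(33)
        pos = np.sort(rng.choice(np.arange(1, 50_000), 400, replace=False))
        scaff = rng.choice(["s1", "s2"], 400)
        sites = make_dataset(np.ones((400, 2)), positions=pos, scaffold=scaff).sites
        keep = ld_thin(sites, 5000)
        expect = set()
        best = {}
        for i in range(400):
            key = (scaff[i], (pos[i] - 1) // 5000)
            if key not in best or pos[i] < best[key][1]:
                best[key] = (i, pos[i])
        expect = {i for i, _ in best.values()}
        assert set(np.flatnonzero(keep)) == expect


class TestPca:
    def test_two_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(37)
        p1 = rng.uniform(0.05, 0.3, 150)
        p2 = np.clip(p1 + 0.5, 0, 0.95)
        g1 = rng.binomial(2, p1[:, None], (150, 12))
        g2 = rng.binomial(2, p2[:, None], (150, 12))
        dosage = np.hstack([g1, g2]).astype(np.int8)
        scores, varfrac = pca(dosage)
        pc1 = scores[:, 0]
        side1, side2 = pc1[:12], pc1[12:]
        assert (side1.mean() < side2.min()) or (side1.mean() > side2.max())
        assert varfrac.sum() == pytest.approx(1.0, abs=1e-9)

    def test_scores_match_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(38)
        dosage = rng.integers(0, 3, (200, 20)).astype(np.int8)
        scores, _ = pca(dosage)
        X = dosage.T.astype(float)
        p = X.mean(0) / 2
        ok = (p > 0) & (p < 1)
        Xc = (X[:, ok] - 2 * p[ok]) / np.sqrt(2 * p[ok] * (1 - p[ok]))
        evals, evecs = np.linalg.eigh(Xc @ Xc.T)
        order = np.argsort(evals)[::-1]
        for k in range(3):
            want = evecs[:, order[k]] * np.sqrt(evals[order[k]])
            got = scores[:, k]
            assert (np.allclose(got, want, atol=1e-8)
                    or np.allclose(got, -want, atol=1e-8))

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError):
            pca(np.zeros((5, 1), np.int8))
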