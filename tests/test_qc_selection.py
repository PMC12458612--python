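"""Selection pipeline kernels against independent oracles: beta values, the
Hardy-Weinberg exact test, the per-SNP regression scan, window/promoter
linking, hypergeometric enrichment, and fixed-point pruning."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

import hinnlab as hl
from hinnlab.qc_selection import prune_unconnected


def _fm(values, modality="genotype", prefix="f"):
    values = np.asarray(values, float)
    return hl.FeatureMatrix(values,
                            [f"S{i}" for i in range(values.shape[0])],
                            [f"{prefix}{j}" for j in range(values.shape[1])],
                            modality)


# ---------------------------------------------------------------------------
# Beta values
# ---------------------------------------------------------------------------

class TestComputeBeta:
    def test_forced_values(self):
        M = _fm([[30.0]], "expression")
        U = _fm([[70.0]], "expression")
        beta, _ = hl.compute_beta(M, U)
        assert beta.values[0, 0] == pytest.approx(0.30, abs=1e-15)

    def test_equal_intensities_give_half(self):
        rng = np.random.default_rng(0)
        M = _fm(rng.uniform(1, 100, (4, 5)), "expression")
        beta, _ = hl.compute_beta(M, M)
        np.testing.assert_allclose(beta.values, 0.5, atol=1e-15)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(1)
        m = rng.uniform(0.1, 500, (20, 10))
        u = rng.uniform(0.1, 500, (20, 10))
        beta, _ = hl.compute_beta(_fm(m, "expression"), _fm(u, "expression"))
        np.testing.assert_allclose(beta.values, m / (m + u), atol=1e-12, rtol=0)

    def test_zero_total_counts_as_missing(self):
        m = np.array([[0.0, 5.0]])
        u = np.array([[0.0, 5.0]])
        beta, report = hl.compute_beta(_fm(m, "expression"), _fm(u, "expression"))
        assert report["n_zero_intensity_cells"] == 1
        assert np.isnan(beta.values[0, 0]) and beta.values[0, 1] == 0.5


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n_hom1, n_het, n_hom2):
    """Independent full enumeration: log-probability of every genotype table
    with the same allele counts, conditional two-sided tail."""
    n = n_hom1 + n_het + n_hom2
    n_a = 2 * n_hom1 + n_het          # allele A count
    hets, logps = [], []
    for het in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
        hom1 = (n_a - het) // 2
        hom2 = n - hom1 - het
        if hom1 < 0 or hom2 < 0:
            continue
        hets.append(het)
        logps.append(gammaln(n + 1) - gammaln(hom1 + 1) - gammaln(het + 1)
                     - gammaln(hom2 + 1) + het * np.log(2))
    logps = np.array(logps) - max(logps)
    probs = np.exp(logps)
    probs /= probs.sum()
    obs = probs[hets.index(n_het)]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


class TestHweExactTest:
    def test_monomorphic_is_one(self):
        assert hl.hwe_exact_test(0, 0, 50) == pytest.approx(1.0)
        assert hl.hwe_exact_test(50, 0, 0) == pytest.approx(1.0)

    def test_balanced_table_matches_enumeration(self):
        assert hl.hwe_exact_test(25, 50, 25) == pytest.approx(
            hwe_enumeration_oracle(25, 50, 25), rel=1e-10)

    @pytest.mark.parametrize("table", [(5, 20, 30), (1, 1, 1), (0, 7, 3),
                                       (40, 4, 40), (12, 0, 8)])
    def test_allele_relabeling_symmetry(self, table):
        a, b, c = table
        assert hl.hwe_exact_test(a, b, c) == pytest.approx(hl.hwe_exact_test(c, b, a))

    def test_agrees_with_enumeration_for_small_totals(self):
        for n in range(1, 26):
            for hom1 in range(n + 1):
                for het in range(n - hom1 + 1):
                    hom2 = n - hom1 - het
                    got = hl.hwe_exact_test(hom1, het, hom2)
                    want = hwe_enumeration_oracle(hom1, het, hom2)
                    assert got == pytest.approx(want, rel=1e-9), (hom1, het, hom2)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            hl.hwe_exact_test(0, 0, 0)
        with pytest.raises(ValueError):
            hl.hwe_exact_test(-1, 2, 3)


# ---------------------------------------------------------------------------
# Genotype QC
# ---------------------------------------------------------------------------

class TestGenotypeQC:
    def test_monomorphic_snp_removed_by_maf(self):
        geno = _fm(np.zeros((40, 1)), "genotype", "rs")
        geno.values[:, 0] = 0.0
        full = _fm(np.column_stack([np.zeros(40), np.tile([0, 1, 1, 2], 10)]),
                   "genotype", "rs")
        out, rep = hl.qc_filter_genotypes(full, hl.QCThresholds())
        assert rep.snps_removed_maf == 1
        assert out.feature_ids == ["rs1"]

    def test_clean_balanced_snp_retained(self):
        col = np.repeat([0.0, 1.0, 2.0], [25, 50, 25])
        out, rep = hl.qc_filter_genotypes(_fm(col[:, None], "genotype", "rs"),
                                          hl.QCThresholds())
        assert out.feature_ids == ["rs0"]
        assert rep.n_snps_out == 1

    def test_engineered_fixture_counts(self):
        """10 SNPs built so exactly 4 survive: 2 fail missingness, 2 fail MAF,
        2 fail HWE, 4 clean."""
        rng = np.random.default_rng(0)
        n = 200
        cols, = [],
        # 4 clean SNPs in good HWE with MAF 0.5
        for _ in range(4):
            cols.append(rng.permutation(np.repeat([0.0, 1.0, 2.0], [50, 100, 50])))
        # 2 with 20% missing calls (> 5% cutoff)
        for _ in range(2):
            c = rng.permutation(np.repeat([0.0, 1.0, 2.0], [50, 100, 50]))
            c[:40] = hl.MISSING_GENOTYPE
            cols.append(rng.permutation(c))
        # 2 rare (MAF 2%)
        for _ in range(2):
            cols.append(rng.permutation(np.repeat([0.0, 1.0], [192, 8])))
        # 2 with extreme heterozygote deficit (HWE p ~ 0)
        for _ in range(2):
            cols.append(rng.permutation(np.repeat([0.0, 2.0], [100, 100])))
        geno = _fm(np.column_stack(cols), "genotype", "rs")
        # with only 10 SNPs per sample the per-sample cutoff must exceed 2/10
        thr = hl.QCThresholds(max_missing_rate_sample=0.25,
                              max_missing_rate_snp=0.10)
        out, rep = hl.qc_filter_genotypes(geno, thr)
        assert rep.samples_removed_missingness == 0
        assert rep.snps_removed_missingness == 2
        assert rep.snps_removed_maf == 2
        assert rep.snps_removed_hwe == 2
        assert out.shape[1] == 4

    def test_empty_result_is_an_error(self):
        geno = _fm(np.zeros((20, 2)), "genotype", "rs")
        with pytest.raises(ValueError, match="QC removed everything"):
            hl.qc_filter_genotypes(geno, hl.QCThresholds())


# ---------------------------------------------------------------------------
# GWAS scan
# ---------------------------------------------------------------------------

class TestGwasScan:
    def test_constant_phenotype_gives_zero_slopes(self):
        rng = np.random.default_rng(2)
        geno = _fm(rng.integers(0, 3, (30, 5)), "genotype", "rs")
        res = hl.gwas_linear_scan(geno, np.full(30, 7.0))
        assert all(r.slope == pytest.approx(0.0, abs=1e-12) for r in res)

    def test_single_snp_matches_closed_form_ols(self):
        x = np.array([0, 1, 2, 0, 1, 2, 1, 0], float)
        y = np.array([1.0, 2.1, 2.9, 1.2, 2.2, 3.3, 1.8, 0.9])
        (res,) = hl.gwas_linear_scan(_fm(x[:, None], "genotype", "rs"), y)
        # normal-equations oracle
        n = len(x)
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        resid = y - (y.mean() + slope * (x - x.mean()))
        se = np.sqrt(resid @ resid / (n - 2) / sxx)
        t = slope / se
        p = 2 * stats.t.sf(abs(t), n - 2)
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.stderr == pytest.approx(se, abs=1e-10)
        assert res.t_stat == pytest.approx(t, abs=1e-10)
        assert res.p_raw == pytest.approx(p, abs=1e-10)

    def test_bonferroni_is_min_one_m_times_p(self):
        rng = np.random.default_rng(3)
        geno = _fm(rng.integers(0, 3, (50, 7)), "genotype", "rs")
        y = rng.normal(size=50)
        res = hl.gwas_linear_scan(geno, y, adjustment="bonferroni")
        for r in res:
            assert r.p_adjusted == pytest.approx(min(1.0, 7 * r.p_raw))
            assert r.p_adjusted >= r.p_raw

    def test_zero_variance_snp_flagged_untestable(self):
        geno = _fm(np.column_stack([np.ones(20), np.tile([0, 2], 10)]),
                   "genotype", "rs")
        res = hl.gwas_linear_scan(geno, np.random.default_rng(0).normal(size=20))
        assert not res[0].testable and res[0].p_raw == 1.0
        assert res[1].testable

    def test_missing_dosages_excluded_per_snp(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 3, 40).astype(float)
        y = x + rng.normal(0, 0.1, 40)
        x_miss = x.copy()
        x_miss[:10] = hl.MISSING_GENOTYPE
        (res,) = hl.gwas_linear_scan(_fm(x_miss[:, None], "genotype", "rs"), y)
        (oracle,) = hl.gwas_linear_scan(_fm(x[10:, None], "genotype", "rs"), y[10:])
        assert res.n_used == 30
        assert res.slope == pytest.approx(oracle.slope, abs=1e-12)


class TestIntersectSignificant:
    def _mk(self, pairs, pheno):
        return [hl.AssociationResult(s, pheno, 0, 0, 0, p, p, 10) for s, p in pairs]

    def test_single_phenotype_returns_its_own_set(self):
        res = self._mk([("a", 0.001), ("b", 0.5)], "x")
        assert hl.intersect_significant([res], 0.01) == {"a"}

    def test_disjoint_sets_intersect_empty(self):
        r1 = self._mk([("a", 0.001), ("b", 0.9)], "x")
        r2 = self._mk([("a", 0.9), ("b", 0.001)], "y")
        assert hl.intersect_significant([r1, r2], 0.01) == set()

    def test_constructed_three_way_overlap(self):
        sig = {"s1", "s2", "s3"}
        lists = []
        for pheno, extra in (("x", "e1"), ("y", "e2"), ("z", "e3")):
            pairs = [(s, 0.005) for s in sig | {extra}] + [("null", 0.9)]
            lists.append(self._mk(pairs, pheno))
        assert hl.intersect_significant(lists, 0.01) == sig


# ---------------------------------------------------------------------------
# Window and promoter linking
# ---------------------------------------------------------------------------

def _snp(i, chrom, pos):
    return hl.GenomicAnnotation(f"rs{i}", chrom, position=pos)


def _cpg(i, chrom, pos):
    return hl.GenomicAnnotation(f"cg{i}", chrom, position=pos)


def _gene(i, chrom, tss, strand):
    return hl.GenomicAnnotation(f"G{i}", chrom, tss=tss, strand=strand,
                                gene_symbol=f"G{i}")


class TestWindowLinking:
    def test_boundary_is_inclusive(self):
        snps = [_snp(0, "chr1", 1_000_000)]
        cpgs = [_cpg(0, "chr1", 1_000_000),       # distance 0
                _cpg(1, "chr1", 2_000_000),       # exactly window
                _cpg(2, "chr1", 2_000_001)]       # window + 1
        edges = hl.link_snp_cpg_window(snps, cpgs, 1_000_000)
        linked = {c for _, c, _ in edges}
        assert linked == {"cg0", "cg1"}

    def test_cross_chromosome_pairs_never_link(self):
        edges = hl.link_snp_cpg_window([_snp(0, "chr1", 100)],
                                       [_cpg(0, "chr2", 100)], 10**9)
        assert edges == []

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(5)
        snps = [_snp(i, f"chr{rng.integers(1, 3)}", int(p))
                for i, p in enumerate(rng.integers(0, 10**7, 60))]
        cpgs = [_cpg(i, f"chr{rng.integers(1, 3)}", int(p))
                for i, p in enumerate(rng.integers(0, 10**7, 80))]
        w = 500_000
        got = {(s, c) for s, c, _ in hl.link_snp_cpg_window(snps, cpgs, w)}
        want = {(s.feature_id, c.feature_id)
                for s in snps for c in cpgs
                if s.chromosome == c.chromosome and abs(s.position - c.position) <= w}
        assert got == want

    def test_window_monotonicity(self):
        rng = np.random.default_rng(6)
        snps = [_snp(i, "chr1", int(p)) for i, p in enumerate(rng.integers(0, 10**7, 40))]
        cpgs = [_cpg(i, "chr1", int(p)) for i, p in enumerate(rng.integers(0, 10**7, 40))]
        prev = set()
        for w in (10_000, 100_000, 1_000_000, 5_000_000):
            cur = {(s, c) for s, c, _ in hl.link_snp_cpg_window(snps, cpgs, w)}
            assert prev <= cur
            prev = cur


class TestPromoterMapping:
    def test_cpg_just_upstream_is_tss200(self):
        edges = hl.map_cpg_promoter([_cpg(0, "chr1", 9_999)],
                                    [_gene(0, "chr1", 10_000, "+")])
        assert edges == [("cg0", "G0", "TSS200")]

    def test_minus_strand_flips_the_window(self):
        edges = hl.map_cpg_promoter([_cpg(0, "chr1", 9_999)],
                                    [_gene(0, "chr1", 10_000, "-")])
        assert edges == []
        edges = hl.map_cpg_promoter([_cpg(0, "chr1", 10_001)],
                                    [_gene(0, "chr1", 10_000, "-")])
        assert edges == [("cg0", "G0", "TSS200")]

    def test_tss1500_band(self):
        cpgs = [_cpg(0, "chr1", 10_000 - 201), _cpg(1, "chr1", 10_000 - 1500),
                _cpg(2, "chr1", 10_000 - 1501), _cpg(3, "chr1", 10_000)]
        edges = hl.map_cpg_promoter(cpgs, [_gene(0, "chr1", 10_000, "+")])
        assert {(c, t) for c, _, t in edges} == {("cg0", "TSS1500"), ("cg1", "TSS1500")}

    def test_matches_brute_force_interval_check(self):
        rng = np.random.default_rng(7)
        cpgs = [_cpg(i, "chr1", int(p)) for i, p in enumerate(rng.integers(0, 10**6, 150))]
        genes = [_gene(i, "chr1", int(t), "+" if rng.random() < 0.5 else "-")
                 for i, t in enumerate(rng.integers(2000, 10**6, 30))]
        got = {(c, g, t) for c, g, t in hl.map_cpg_promoter(cpgs, genes)}
        want = set()
        for g in genes:
            for c in cpgs:
                d = (g.tss - c.position) if g.strand == "+" else (c.position - g.tss)
                if 1 <= d <= 200:
                    want.add((c.feature_id, g.feature_id, "TSS200"))
                elif 200 < d <= 1500:
                    want.add((c.feature_id, g.feature_id, "TSS1500"))
        assert got == want


# ---------------------------------------------------------------------------
# Min-max normalization and enrichment
# ---------------------------------------------------------------------------

class TestMinMaxNormalize:
    def test_example_feature(self):
        out = hl.min_max_normalize(_fm(np.array([[2.0], [4.0], [6.0]]), "expression"))
        np.testing.assert_allclose(out.values[:, 0], [0, 0.5, 1])

    def test_idempotent_on_full_range(self):
        v = np.array([[0.0, 0.2], [0.4, 1.0], [1.0, 0.0]])
        out = hl.min_max_normalize(_fm(v, "expression"))
        np.testing.assert_allclose(out.values, v)

    def test_columns_span_unit_interval(self):
        rng = np.random.default_rng(8)
        out = hl.min_max_normalize(_fm(rng.normal(3, 10, (40, 12)), "expression"))
        np.testing.assert_allclose(out.values.min(axis=0), 0, atol=1e-15)
        np.testing.assert_allclose(out.values.max(axis=0), 1, atol=1e-15)

    def test_constant_feature_maps_to_half(self):
        out = hl.min_max_normalize(_fm(np.full((5, 1), 3.3), "expression"))
        np.testing.assert_allclose(out.values, 0.5)


class TestGoEnrichment:
    def _thr(self, adj="none"):
        return hl.QCThresholds(enrichment_adjustment=adj)

    def test_full_overlap_closed_form(self):
        """Universe 10, term = selected (5 genes), overlap 5: p = 1/C(10,5)."""
        universe = {f"g{i}" for i in range(10)}
        sel = {f"g{i}" for i in range(5)}
        sets = hl.GeneSetCollection()
        sets.add("T", "t", sel)
        (res,) = hl.enrich_go_terms(sel, universe, sets, self._thr())
        from math import comb
        assert res.p_raw == pytest.approx(1 / comb(10, 5), rel=1e-10)

    def test_zero_overlap_never_enriched(self):
        universe = {f"g{i}" for i in range(20)}
        sets = hl.GeneSetCollection()
        sets.add("T", "t", {"g10", "g11", "g12"})
        (res,) = hl.enrich_go_terms({"g0", "g1"}, universe, sets, self._thr())
        assert res.p_raw >= 0.5 and res.n_overlap == 0

    def test_selected_equals_universe_gives_p_one(self):
        universe = {f"g{i}" for i in range(12)}
        sets = hl.GeneSetCollection()
        sets.add("A", "a", {"g0", "g1"})
        sets.add("B", "b", {"g5", "g6", "g7"})
        for res in hl.enrich_go_terms(universe, universe, sets, self._thr()):
            assert res.p_raw == pytest.approx(1.0)

    def test_matches_hypergeometric_sum_oracle(self):
        rng = np.random.default_rng(9)
        universe = {f"g{i}" for i in range(60)}
        sel = set(rng.choice(sorted(universe), 18, replace=False))
        sets = hl.GeneSetCollection()
        for t in range(8):
            sets.add(f"T{t}", "t", rng.choice(sorted(universe),
                                              int(rng.integers(4, 20)), replace=False))
        for res in hl.enrich_go_terms(sel, universe, sets, self._thr()):
            members = sets[res.term_id].members
            k = len(members & sel)
            from math import comb
            N, K, n = 60, len(members), 18
            want = sum(comb(K, i) * comb(N - K, n - i) for i in
                       range(k, min(K, n) + 1)) / comb(N, n)
            assert res.p_raw == pytest.approx(want, abs=1e-10)

    def test_empty_selection_is_an_error(self):
        with pytest.raises(ValueError):
            hl.enrich_go_terms(set(), {"a"}, hl.GeneSetCollection(), self._thr())


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

class TestPruneUnconnected:
    def test_isolated_snp_dropped_chain_kept(self):
        rel = prune_unconnected([("s1", "c1", 5), ("s2", "c9", 5)],
                                [("c1", "p1", "TSS200")], [("p1", "t1")])
        assert rel.snps == ["s1"] and rel.cpgs == ["c1"]
        assert rel.probes == ["p1"] and rel.terms == ["t1"]

    def test_cascade_removal_propagates(self):
        # removing c1's probe edge orphans s1 and p1
        with pytest.raises(ValueError, match="empty"):
            prune_unconnected([("s1", "c1", 5)], [("c2", "p1", "TSS200")],
                              [("p1", "t1")])

    def test_matches_repeated_sweep_oracle(self):
        rng = np.random.default_rng(10)
        for trial in range(20):
            sc = [(f"s{rng.integers(8)}", f"c{rng.integers(8)}", 1) for _ in range(12)]
            cp = [(f"c{rng.integers(8)}", f"p{rng.integers(6)}", "TSS200")
                  for _ in range(10)]
            pt = [(f"p{rng.integers(6)}", f"t{rng.integers(4)}") for _ in range(6)]
            # naive oracle: sweep until no change
            snps = {e[0] for e in sc}; cpgs = {e[1] for e in sc} | {e[0] for e in cp}
            probes = {e[1] for e in cp} | {e[0] for e in pt}; terms = {e[1] for e in pt}
            changed = True
            while changed:
                changed = False
                for s in list(snps):
                    if not any(a == s and b in cpgs for a, b, _ in sc):
                        snps.discard(s); changed = True
                for c in list(cpgs):
                    has_in = any(b == c and a in snps for a, b, _ in sc)
                    has_out = any(a == c and b in probes for a, b, _ in cp)
                    if not (has_in and has_out):
                        cpgs.discard(c); changed = True
                for p in list(probes):
                    if not any(b == p and a in cpgs for a, b, _ in cp):
                        probes.discard(p); changed = True
                for t in list(terms):
                    if not any(b == t and a in probes for a, b in pt):
                        terms.discard(t); changed = True
            try:
                rel = prune_unconnected(sc, cp, pt)
            except ValueError:
                assert not (snps and cpgs and probes)
                continue
            assert set(rel.snps) == snps and set(rel.cpgs) == cpgs
            assert set(rel.probes) == probes and set(rel.terms) == terms

    def test_pruned_fixed_point_invariants(self):
        rng = np.random.default_rng(11)
        sc = [(f"s{rng.integers(10)}", f"c{rng.integers(10)}", 1) for _ in range(25)]
        cp = [(f"c{rng.integers(10)}", f"p{rng.integers(8)}", "TSS1500")
              for _ in range(20)]
        pt = [(f"p{rng.integers(8)}", f"t{rng.integers(5)}") for _ in range(10)]
        rel = prune_unconnected(sc, cp, pt)
        out_of = lambda edges, i: {e[i] for e in edges}
        assert set(rel.snps) <= out_of(rel.snp_cpg, 0)
        for c in rel.cpgs:
            assert c in out_of(rel.snp_cpg, 1) and c in out_of(rel.cpg_probe, 0)
        assert set(rel.probes) <= out_of(rel.cpg_probe, 1)


def test_pipeline_is_deterministic(default_cohort):
    cohort, _ = default_cohort
    thr = hl.QCThresholds()
    a = hl.select_features(cohort, thr).relation_map
    b = hl.select_features(cohort, thr).relation_map
    assert (a.snps, a.cpgs, a.probes, a.terms) == (b.snps, b.cpgs, b.probes, b.terms)
    assert a.snp_cpg == b.snp_cpg and a.cpg_probe == b.cpg_probe


def test_most_causal_snps_survive_selection(default_cohort, selection):
    _, truth = default_cohort
    causal = truth.causal_ids("snp")
    kept = causal & set(selection.relation_map.snps)
    assert len(kept) / len(causal) >= 0.8
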