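"""Biologically-related feature selection: beta computation, genotype QC,
per-SNP linear-regression scans, multi-phenotype intersection, meQTL-style
window linking, promoter mapping, GO enrichment, and cross-layer pruning.

The end product is a :class:`RelationMap` — the directed SNP->CpG->probe->GO
edge sets, pruned to a fixed point so that every retained feature carries at
least one cross-layer relationship.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .io_formats import (FeatureMatrix, GeneSetCollection, GenomicAnnotation,
                         QCThresholdsConfig)

logger = logging.getLogger("hinnlab")

QCThresholds = QCThresholdsConfig


# ---------------------------------------------------------------------------
# Beta values
# ---------------------------------------------------------------------------

def compute_beta(methylated: FeatureMatrix,
                 unmethylated: FeatureMatrix) -> tuple[FeatureMatrix, dict]:
    """Beta = M / (M + U), elementwise. Cells with M + U = 0 are set missing
    (NaN) and counted in the returned QC report."""
    M, U = methylated.values, unmethylated.values
    if M.shape != U.shape:
        raise ValueError("intensity matrices differ in shape")
    if (M < 0).any() or (U < 0).any():
        raise ValueError("intensities must be nonnegative")
    total = M + U
    zero = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(zero, np.nan, M / np.where(zero, 1.0, total))
    report = {"n_zero_intensity_cells": int(zero.sum())}
    if report["n_zero_intensity_cells"]:
        logger.warning("compute_beta: %d cells with zero total intensity set missing",
                       report["n_zero_intensity_cells"])
    fm = FeatureMatrix(beta, methylated.sample_ids, methylated.feature_ids, "methylation")
    return fm, report


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Wigginton et al. style two-sided exact p)
# ---------------------------------------------------------------------------

def hwe_exact_test(n_aa_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact two-sided HWE p: sum the conditional probabilities (given allele
    counts) of all heterozygote counts whose probability does not exceed the
    observed one."""
    n_hom1, n_het, n_hom2 = int(n_aa_hom1), int(n_het), int(n_hom2)
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("no genotype observations")
    # rare allele count
    rare = 2 * min(n_hom1, n_hom2) + n_het
    # feasible heterozygote counts share the parity of `rare`
    hets = np.arange(rare % 2, rare + 1, 2)
    # unnormalized log-probabilities of each het count given allele counts
    logp = (-gammaln(hets + 1.0)
            - gammaln((rare - hets) // 2 + 1.0)
            - gammaln(n - (rare + hets) // 2 + 1.0)
            + hets * math.log(2.0))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[hets == n_het]
    if obs.size == 0:  # unreachable given consistent counts
        raise ValueError("observed heterozygote count infeasible")
    p = probs[probs <= obs[0] * (1 + 1e-12)].sum()
    return float(min(1.0, p))


# ---------------------------------------------------------------------------
# Genotype QC
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    n_samples_in: int = 0
    n_snps_in: int = 0
    samples_removed_missingness: int = 0
    snps_removed_missingness: int = 0
    snps_removed_maf: int = 0
    snps_removed_hwe: int = 0
    n_samples_out: int = 0
    n_snps_out: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def qc_filter_genotypes(geno: FeatureMatrix,
                        thr: QCThresholds) -> tuple[FeatureMatrix, QCReport]:
    """Apply, in order: sample missingness, SNP missingness, MAF (on
    non-missing calls), and HWE exact-test filters.

    With ``thr.literal_directions`` False (default, conventional semantics)
    a sample/SNP is removed when its missing rate exceeds the threshold and a
    SNP is removed when its HWE p-value falls below ``hwe_alpha``.  The
    literal switch inverts both directions to match the printed protocol.
    """
    if geno.modality != "genotype":
        raise ValueError("qc_filter_genotypes expects a genotype matrix")
    rep = QCReport(n_samples_in=geno.shape[0], n_snps_in=geno.shape[1])
    values = geno.values
    obs = geno.observed_mask()

    def fails_missing(rate: np.ndarray, cutoff: float) -> np.ndarray:
        if thr.literal_directions:
            # printed form: exclude call rate > 95%  <=>  missing rate < 5%
            return (1.0 - rate) > (1.0 - cutoff)
        return rate > cutoff

    sample_miss = 1.0 - obs.mean(axis=1)
    keep_samples = ~fails_missing(sample_miss, thr.max_missing_rate_sample)
    rep.samples_removed_missingness = int((~keep_samples).sum())
    values, obs = values[keep_samples], obs[keep_samples]
    sample_ids = [s for s, k in zip(geno.sample_ids, keep_samples) if k]

    snp_miss = 1.0 - obs.mean(axis=0)
    keep = ~fails_missing(snp_miss, thr.max_missing_rate_snp)
    rep.snps_removed_missingness = int((~keep).sum())

    # MAF on non-missing calls
    with np.errstate(invalid="ignore"):
        called = np.where(obs, values, np.nan)
        freq = np.nanmean(called, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    maf_fail = keep & ((maf < thr.min_maf) | ~np.isfinite(maf))
    rep.snps_removed_maf = int(maf_fail.sum())
    keep &= ~maf_fail

    # HWE exact test on surviving SNPs
    hwe_fail = np.zeros_like(keep)
    for j in np.nonzero(keep)[0]:
        col = called[:, j]
        col = col[np.isfinite(col)]
        n0 = int((col == 0).sum()); n1 = int((col == 1).sum()); n2 = int((col == 2).sum())
        if n0 + n1 + n2 == 0:
            hwe_fail[j] = True
            continue
        p = hwe_exact_test(n0, n1, n2)
        hwe_fail[j] = (p > thr.hwe_alpha) if thr.literal_directions else (p < thr.hwe_alpha)
    rep.snps_removed_hwe = int(hwe_fail.sum())
    keep &= ~hwe_fail

    snp_ids = [s for s, k in zip(geno.feature_ids, keep) if k]
    rep.n_samples_out, rep.n_snps_out = len(sample_ids), len(snp_ids)
    if rep.n_samples_out == 0 or rep.n_snps_out == 0:
        raise ValueError(f"QC removed everything: {rep.to_dict()}")
    out = FeatureMatrix(values[:, keep], sample_ids, snp_ids, "genotype",
                        geno.missing_code)
    logger.info("genotype QC: %s", rep.to_dict())
    return out, rep


# ---------------------------------------------------------------------------
# GWAS linear scan
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    snp_id: str
    phenotype: str
    slope: float
    stderr: float
    t_stat: float
    p_raw: float
    p_adjusted: float
    n_used: int
    testable: bool = True


def gwas_linear_scan(geno: FeatureMatrix, phenotype: pd.Series | np.ndarray,
                     phenotype_name: str = "phenotype",
                     adjustment: str = "bonferroni") -> list[AssociationResult]:
    """Simple per-SNP linear regression of phenotype on additive dosage over
    non-missing samples; two-sided t-test p-values; family-wise adjustment
    over all tested SNPs (default Bonferroni). Zero-variance dosages are
    flagged untestable with p = 1 by convention."""
    y_all = np.asarray(phenotype, dtype=float)
    if y_all.shape[0] != geno.shape[0]:
        raise ValueError("phenotype length does not match sample count")
    obs = geno.observed_mask() & np.isfinite(y_all)[:, None]
    G = np.where(obs, geno.values, 0.0)
    Y = np.where(obs, y_all[:, None], 0.0)

    n = obs.sum(axis=0).astype(float)
    if (n < 3).any():
        raise ValueError("every SNP needs >= 3 non-missing observations")
    sx, sy = G.sum(axis=0), Y.sum(axis=0)
    sxx, syy = (G * G).sum(axis=0), (Y * Y).sum(axis=0)
    sxy = (G * Y).sum(axis=0)
    ssx = sxx - sx * sx / n
    ssy = syy - sy * sy / n
    spxy = sxy - sx * sy / n

    testable = ssx > 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(testable, spxy / ssx, 0.0)
        rss = np.maximum(ssy - slope * spxy, 0.0)
        df = n - 2
        sigma2 = np.where(df > 0, rss / np.maximum(df, 1), np.nan)
        se = np.sqrt(np.where(testable, sigma2 / np.maximum(ssx, 1e-300), np.nan))
        t = np.where(testable & (se > 0), slope / np.where(se > 0, se, 1.0), 0.0)
        p = np.where(testable, 2.0 * stats.t.sf(np.abs(t), df), 1.0)
    p = np.clip(p, 0.0, 1.0)

    m = len(geno.feature_ids)
    if adjustment == "bonferroni":
        p_adj = np.minimum(1.0, p * m)
    elif adjustment == "BH":
        p_adj = multipletests(p, method="fdr_bh")[1]
    elif adjustment == "none":
        p_adj = p.copy()
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")

    return [AssociationResult(sid, phenotype_name, float(slope[j]), float(se[j])
                              if np.isfinite(se[j]) else float("nan"),
                              float(t[j]), float(p[j]), float(p_adj[j]),
                              int(n[j]), bool(testable[j]))
            for j, sid in enumerate(geno.feature_ids)]


def intersect_significant(results_per_phenotype: list[list[AssociationResult]],
                          alpha: float) -> set[str]:
    """SNPs with adjusted p <= alpha in EVERY phenotype scan."""
    if not results_per_phenotype:
        raise ValueError("need at least one phenotype scan")
    sets = [{r.snp_id for r in res if r.testable and r.p_adjusted <= alpha}
            for res in results_per_phenotype]
    out = set.intersection(*sets)
    logger.info("GWAS intersection: %s -> %d SNPs",
                [len(s) for s in sets], len(out))
    return out


# ---------------------------------------------------------------------------
# Window and promoter linking
# ---------------------------------------------------------------------------

def link_snp_cpg_window(snps: list[GenomicAnnotation], cpgs: list[GenomicAnnotation],
                        window_bp: int) -> list[tuple[str, str, int]]:
    """Edges (snp_id, cpg_id, distance_bp) for same-chromosome pairs with
    |pos_snp - pos_cpg| <= window_bp (inclusive boundary)."""
    edges: list[tuple[str, str, int]] = []
    by_chrom: dict[str, list[GenomicAnnotation]] = {}
    for c in cpgs:
        by_chrom.setdefault(c.chromosome, []).append(c)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda a: a.position)
    for s in snps:
        group = by_chrom.get(s.chromosome, ())
        if not group:
            continue
        pos = np.array([c.position for c in group])
        lo = np.searchsorted(pos, s.position - window_bp, side="left")
        hi = np.searchsorted(pos, s.position + window_bp, side="right")
        for c in group[lo:hi]:
            edges.append((s.feature_id, c.feature_id, abs(s.position - c.position)))
    return edges


def map_cpg_promoter(cpgs: list[GenomicAnnotation], genes: list[GenomicAnnotation],
                     offsets: tuple[int, int] = (200, 1500)
                     ) -> list[tuple[str, str, str]]:
    """Edges (cpg_id, gene_symbol, tag) for CpGs in a promoter window.

    Strand-aware upstream distance d = tss - pos on '+' (pos - tss on '-');
    d in [1, near] => TSS<near> tag; d in (near, far] => TSS<far> tag.
    """
    near, far = offsets
    edges: list[tuple[str, str, str]] = []
    for g in genes:
        if g.strand not in ("+", "-"):
            raise ValueError(f"gene {g.feature_id} lacks strand")
        for c in cpgs:
            if c.chromosome != g.chromosome:
                continue
            d = (g.tss - c.position) if g.strand == "+" else (c.position - g.tss)
            if 1 <= d <= near:
                edges.append((c.feature_id, g.feature_id, f"TSS{near}"))
            elif near < d <= far:
                edges.append((c.feature_id, g.feature_id, f"TSS{far}"))
    return edges


# ---------------------------------------------------------------------------
# Expression normalization and GO enrichment
# ---------------------------------------------------------------------------

def min_max_normalize(expr: FeatureMatrix) -> FeatureMatrix:
    """Per-feature (x - min)/(max - min) into [0,1]; constant features map to
    0.5 with a logged warning."""
    v = expr.values.astype(float).copy()
    mn, mx = np.nanmin(v, axis=0), np.nanmax(v, axis=0)
    span = mx - mn
    constant = span <= 0
    if constant.any():
        logger.warning("min_max_normalize: %d constant features mapped to 0.5",
                       int(constant.sum()))
    span_safe = np.where(constant, 1.0, span)
    out = (v - mn) / span_safe
    out[:, constant] = 0.5
    return FeatureMatrix(out, expr.sample_ids, expr.feature_ids, expr.modality)


@dataclass
class EnrichmentResult:
    term_id: str
    name: str
    n_members: int
    n_overlap: int
    p_raw: float
    p_adjusted: float
    overlap_genes: list[str] = field(default_factory=list)
    significant: bool = False


def enrich_go_terms(selected_genes: set[str], universe: set[str],
                    sets: GeneSetCollection,
                    thr: QCThresholds) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation test per term (P[overlap
    >= observed] given universe size, term size, selection size), adjusted per
    ``thr.enrichment_adjustment``; results sorted by raw p."""
    if not selected_genes:
        raise ValueError("empty selected gene set")
    if not selected_genes <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    N, n_sel = len(universe), len(selected_genes)
    rows = []
    for term_id, gs in sets.items():
        members = gs.members & universe
        if not members:
            continue
        k = len(members & selected_genes)
        # P[X >= k], X ~ Hypergeom(N, |members|, n_sel)
        p = float(stats.hypergeom.sf(k - 1, N, len(members), n_sel))
        rows.append((term_id, gs.name, len(members), k, min(1.0, p),
                     sorted(members & selected_genes)))
    if not rows:
        return []
    p_raw = np.array([r[4] for r in rows])
    if thr.enrichment_adjustment == "BH":
        p_adj = multipletests(p_raw, method="fdr_bh")[1]
    elif thr.enrichment_adjustment == "bonferroni":
        p_adj = np.minimum(1.0, p_raw * len(p_raw))
    else:
        p_adj = p_raw.copy()
    results = [EnrichmentResult(tid, name, nm, k, pr, float(pa), genes,
                                significant=float(pa) <= thr.enrichment_alpha)
               for (tid, name, nm, k, pr, genes), pa in zip(rows, p_adj)]
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    return results


# ---------------------------------------------------------------------------
# RelationMap and pruning
# ---------------------------------------------------------------------------

@dataclass
class RelationMap:
    """Directed cross-layer edges with provenance, at the pruned fixed point."""

    snp_cpg: list[tuple[str, str, int]]          # (snp, cpg, distance bp)
    cpg_probe: list[tuple[str, str, str]]        # (cpg, probe, TSS tag)
    probe_term: list[tuple[str, str]]            # (probe, term)
    snps: list[str]
    cpgs: list[str]
    probes: list[str]
    terms: list[str]

    def validate(self) -> None:
        s, c, p, t = map(set, (self.snps, self.cpgs, self.probes, self.terms))
        for a, b, *_ in self.snp_cpg:
            if a not in s or b not in c:
                raise ValueError(f"snp_cpg edge endpoint missing: {(a, b)}")
        for a, b, *_ in self.cpg_probe:
            if a not in c or b not in p:
                raise ValueError(f"cpg_probe edge endpoint missing: {(a, b)}")
        for a, b in self.probe_term:
            if a not in p or b not in t:
                raise ValueError(f"probe_term edge endpoint missing: {(a, b)}")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "snp_cpg": [list(e) for e in self.snp_cpg],
            "cpg_probe": [list(e) for e in self.cpg_probe],
            "probe_term": [list(e) for e in self.probe_term],
            "retained": {"snps": self.snps, "cpgs": self.cpgs,
                         "probes": self.probes, "terms": self.terms},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "RelationMap":
        with open(path) as fh:
            doc = json.load(fh)
        r = doc["retained"]
        return cls(
            snp_cpg=[(a, b, int(d)) for a, b, d in doc["snp_cpg"]],
            cpg_probe=[tuple(e) for e in doc["cpg_probe"]],
            probe_term=[tuple(e) for e in doc["probe_term"]],
            snps=r["snps"], cpgs=r["cpgs"], probes=r["probes"], terms=r["terms"],
        )


def prune_unconnected(snp_cpg: list[tuple[str, str, int]],
                      cpg_probe: list[tuple[str, str, str]],
                      probe_term: list[tuple[str, str]],
                      require_go_connected_probes: bool = False) -> RelationMap:
    """Iterate to a fixed point: SNPs need an outgoing CpG edge, CpGs need
    both an incoming SNP edge and an outgoing probe edge, probes need an
    incoming CpG edge (and a GO edge only if configured); cascaded orphans
    are re-dropped until stable."""
    snps = {e[0] for e in snp_cpg}
    cpgs = {e[1] for e in snp_cpg} | {e[0] for e in cpg_probe}
    probes = {e[1] for e in cpg_probe} | {e[0] for e in probe_term}
    terms = {e[1] for e in probe_term}
    while True:
        sc = [e for e in snp_cpg if e[0] in snps and e[1] in cpgs]
        cp = [e for e in cpg_probe if e[0] in cpgs and e[1] in probes]
        pt = [e for e in probe_term if e[0] in probes and e[1] in terms]
        new_snps = {e[0] for e in sc}
        new_cpgs = {e[1] for e in sc} & {e[0] for e in cp}
        new_probes = {e[1] for e in cp}
        if require_go_connected_probes:
            new_probes &= {e[0] for e in pt}
        new_terms = {e[1] for e in pt if e[0] in new_probes}
        if (new_snps, new_cpgs, new_probes, new_terms) == (snps, cpgs, probes, terms):
            break
        snps, cpgs, probes, terms = new_snps, new_cpgs, new_probes, new_terms
    if not (snps and cpgs and probes):
        raise ValueError("a feature layer is empty after pruning")
    rel = RelationMap(
        snp_cpg=sorted(e for e in snp_cpg if e[0] in snps and e[1] in cpgs),
        cpg_probe=sorted(e for e in cpg_probe if e[0] in cpgs and e[1] in probes),
        probe_term=sorted(e for e in probe_term if e[0] in probes and e[1] in terms),
        snps=sorted(snps), cpgs=sorted(cpgs), probes=sorted(probes),
        terms=sorted(terms),
    )
    rel.validate()
    return rel


# ---------------------------------------------------------------------------
# Pipeline orchestrator
# ---------------------------------------------------------------------------

@dataclass
class SelectionOutput:
    relation_map: RelationMap
    qc_report: QCReport
    associations: dict[str, list[AssociationResult]]
    significant_snps: set[str]
    enrichment: list[EnrichmentResult]
    genotype_qc: FeatureMatrix


def select_features(cohort, thr: QCThresholds,
                    phenotypes: list[str] | None = None) -> SelectionOutput:
    """Run the full pipeline on a cohort (synthetic or loaded bundle):
    QC -> per-phenotype GWAS -> intersection -> window linking -> promoter
    mapping -> GO enrichment -> cross-layer pruning."""
    geno_qc, qc_report = qc_filter_genotypes(cohort.genotype, thr)
    phenos = phenotypes or list(cohort.scores.columns)
    scans = {}
    for name in phenos:
        y = cohort.scores.loc[geno_qc.sample_ids, name]
        scans[name] = gwas_linear_scan(geno_qc, y, name, thr.gwas_adjustment)
    sig = intersect_significant(list(scans.values()), thr.gwas_adjusted_alpha)
    if not sig:
        raise ValueError("no SNP significant in all phenotypes")

    snp_ann = [a for a in cohort.snp_annotations if a.feature_id in sig]
    snp_cpg = link_snp_cpg_window(snp_ann, cohort.cpg_annotations, thr.window_bp)
    cpg_gene = map_cpg_promoter(cohort.cpg_annotations, cohort.gene_annotations,
                                thr.promoter_offsets_bp)
    if thr.require_promoter_for_cpg:
        promoter_cpgs = {e[0] for e in cpg_gene}
        snp_cpg = [e for e in snp_cpg if e[1] in promoter_cpgs]

    # probes whose gene has a promoter CpG among the window-linked CpGs
    window_cpgs = {e[1] for e in snp_cpg}
    gene_probes: dict[str, list[str]] = {}
    for probe, gene in cohort.probe_gene_map.items():
        gene_probes.setdefault(gene, []).append(probe)
    cpg_probe = [(cpg, probe, tag)
                 for cpg, gene, tag in cpg_gene if cpg in window_cpgs
                 for probe in gene_probes.get(gene, ())]

    selected_genes = {cohort.probe_gene_map[p] for _, p, _ in cpg_probe}
    universe = set(cohort.probe_gene_map.values())
    enrichment = enrich_go_terms(selected_genes, universe, cohort.gene_sets, thr)
    probe_term = [(probe, r.term_id)
                  for r in enrichment if r.significant
                  for g in r.overlap_genes
                  for probe in gene_probes.get(g, ())]

    rel = prune_unconnected(snp_cpg, cpg_probe, probe_term,
                            thr.require_go_connected_probes)
    logger.info("selection retained %d SNPs, %d CpGs, %d probes, %d GO terms",
                len(rel.snps), len(rel.cpgs), len(rel.probes), len(rel.terms))
    return SelectionOutput(rel, qc_report, scans, sig, enrichment, geno_qc)
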