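"""Synthetic multi-omics cohorts with planted SNP -> CpG -> expression -> score
cascades.

The generator emulates the statistical structure the selection pipeline and
the hierarchical network assume: common variants acting as cis-meQTLs on
promoter CpGs (logit-scale additive allele effect), methylation suppressing
expression of the promoter's gene (negative linear coupling of beta with
expression), and a latent cognitive trait driven by the causal genes'
expression plus demographic covariates.  Observed cognitive tests are noisy
bounded monotone transforms of the latent trait (MMSE/MoCA-like increasing,
ADAS11-like decreasing), a plasma p-Tau proxy is a noisy decreasing
log-scale transform of the same latent, and CN/CI diagnosis is the latent
tertile (top third CN).  One linear chromosome by default.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (FeatureMatrix, GeneSet, GeneSetCollection,
                         GenomicAnnotation, MISSING_GENOTYPE,
                         SimulationConfigModel, write_bed_annotations,
                         write_gmt, write_matrix, read_matrix,
                         read_bed_annotations, read_gmt)

logger = logging.getLogger("hinnlab")

# SimulationParams is the validated pydantic model shared with RunConfig.
SimulationParams = SimulationConfigModel


@dataclass
class Cascade:
    snp_id: str
    cpg_id: str
    probe_id: str
    gene_symbol: str
    term_id: str
    meqtl_effect: float
    meth_expr_effect: float


@dataclass
class GroundTruth:
    cascades: list[Cascade]
    enriched_terms: list[str]
    latent_score: np.ndarray  # standardized per-sample latent trait

    def causal_ids(self, layer: str) -> set[str]:
        key = {"snp": "snp_id", "cpg": "cpg_id", "probe": "probe_id",
               "gene": "gene_symbol", "term": "term_id"}[layer]
        return {getattr(c, key) for c in self.cascades}

    def to_json(self, path: str | Path) -> None:
        doc = {
            "cascades": [asdict(c) for c in self.cascades],
            "enriched_terms": list(self.enriched_terms),
            "latent_score": [float(x) for x in self.latent_score],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            cascades=[Cascade(**c) for c in doc["cascades"]],
            enriched_terms=list(doc["enriched_terms"]),
            latent_score=np.asarray(doc["latent_score"], dtype=float),
        )


@dataclass
class SyntheticCohort:
    genotype: FeatureMatrix
    methylation: FeatureMatrix
    expression: FeatureMatrix
    covariates: pd.DataFrame          # age, sex, education, apoe4, ptau181, diagnosis
    scores: pd.DataFrame              # one column per cognitive test
    snp_annotations: list[GenomicAnnotation]
    cpg_annotations: list[GenomicAnnotation]
    gene_annotations: list[GenomicAnnotation]
    gene_sets: GeneSetCollection
    probe_gene_map: dict[str, str] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return self.genotype.sample_ids

    def validate(self) -> None:
        sids = self.genotype.sample_ids
        for fm in (self.methylation, self.expression):
            if fm.sample_ids != sids:
                raise ValueError("matrices do not share sample ordering")
        if list(self.covariates.index) != sids or list(self.scores.index) != sids:
            raise ValueError("covariates/scores do not share sample ordering")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def simulate_cohort(params: SimulationParams) -> tuple[SyntheticCohort, GroundTruth]:
    """Draw one cohort plus the planted ground truth. Fixed seed => identical
    output, bit for bit."""
    p = params
    rng = np.random.default_rng(p.seed)
    near, far = p.promoter_offsets_bp
    if p.chromosome_length < 2 * p.window_bp + far + 10_000:
        raise ValueError("chromosome too short for the requested window placement")

    chroms = [f"chr{i+1}" for i in range(p.n_chromosomes)]
    sample_ids = [f"S{i:04d}" for i in range(p.n_samples)]
    snp_ids = [f"rs{i:05d}" for i in range(p.n_snps)]
    cpg_ids = [f"cg{i:06d}" for i in range(p.n_cpgs)]
    gene_symbols = [f"GENE{i:03d}" for i in range(p.n_genes)]
    probe_ids = [f"{11700000 + i}_at" for i in range(p.n_genes)]
    term_ids = [f"GO:{7000000 + i}" for i in range(p.n_go_terms)]

    # --- placement -------------------------------------------------------
    lo = p.window_bp + far + 1000
    hi = p.chromosome_length - p.window_bp - 1000
    gene_chrom = rng.integers(0, p.n_chromosomes, p.n_genes)
    gene_tss = rng.integers(lo, hi, p.n_genes)
    gene_strand = np.where(rng.random(p.n_genes) < 0.5, "+", "-")

    k = p.n_causal_cascades
    causal_genes = rng.choice(p.n_genes, size=k, replace=False)
    causal_cpgs = np.arange(k)
    causal_snps = np.arange(k)

    cpg_chrom = rng.integers(0, p.n_chromosomes, p.n_cpgs)
    cpg_pos = rng.integers(0, p.chromosome_length, p.n_cpgs)
    # ~40% of non-causal CpGs sit in a random gene's promoter window
    promoter_cpgs = np.nonzero(rng.random(p.n_cpgs) < 0.4)[0]
    promoter_cpgs = promoter_cpgs[promoter_cpgs >= k]
    for j in promoter_cpgs:
        g = rng.integers(0, p.n_genes)
        d = int(rng.integers(1, far + 1))
        cpg_chrom[j] = gene_chrom[g]
        cpg_pos[j] = gene_tss[g] - d if gene_strand[g] == "+" else gene_tss[g] + d
    # causal CpGs sit in their causal gene's promoter
    for j, g in zip(causal_cpgs, causal_genes):
        d = int(rng.integers(1, far + 1))
        cpg_chrom[j] = gene_chrom[g]
        cpg_pos[j] = gene_tss[g] - d if gene_strand[g] == "+" else gene_tss[g] + d

    snp_chrom = rng.integers(0, p.n_chromosomes, p.n_snps)
    snp_pos = rng.integers(0, p.chromosome_length, p.n_snps)
    for j, c in zip(causal_snps, causal_cpgs):
        snp_chrom[j] = cpg_chrom[c]
        offset = int(rng.integers(-p.window_bp, p.window_bp + 1))
        snp_pos[j] = int(np.clip(cpg_pos[c] + offset, 0, p.chromosome_length - 1))

    # --- genotypes -------------------------------------------------------
    maf = rng.uniform(*p.maf_range, p.n_snps)
    clo, chi = p.causal_maf_range
    maf[causal_snps] = rng.uniform(clo, chi, k)
    geno_true = rng.binomial(2, maf, size=(p.n_samples, p.n_snps)).astype(float)
    geno = geno_true.copy()
    if p.missing_rate > 0:
        miss = rng.random(geno.shape) < p.missing_rate
        geno[miss] = MISSING_GENOTYPE

    # --- methylation (logit scale, then squashed to (0,1)) ---------------
    base_logit = rng.uniform(-2.0, 2.0, p.n_cpgs)
    base_logit[causal_cpgs] = rng.uniform(-1.0, 1.0, k)  # keep causal CpGs variable
    logit = np.tile(base_logit, (p.n_samples, 1))
    logit += rng.normal(0.0, p.cpg_logit_noise_sd, size=logit.shape)
    for j, s in zip(causal_cpgs, causal_snps):
        dosage = geno_true[:, s]
        logit[:, j] += p.meqtl_effect * (dosage - dosage.mean())
    beta = _sigmoid(logit)

    # --- expression -------------------------------------------------------
    expr_base = rng.normal(5.0, 1.0, p.n_genes)   # constant per gene
    expr = expr_base + rng.normal(0.0, p.expr_noise_sd,
                                  size=(p.n_samples, p.n_genes))
    for g, c in zip(causal_genes, causal_cpgs):
        expr[:, g] -= p.meth_expr_effect * (beta[:, c] - beta[:, c].mean())

    # --- covariates -------------------------------------------------------
    age = np.clip(rng.normal(75, 7, p.n_samples), 55, 93).round(1)
    sex = rng.integers(0, 2, p.n_samples).astype(float)
    education = rng.integers(12, 21, p.n_samples).astype(float)
    apoe4 = rng.choice([0.0, 1.0, 2.0], p.n_samples, p=[0.57, 0.35, 0.08])
    cov_combo = (-0.5 * _standardize(age) + 0.25 * _standardize(education)
                 - 0.8 * _standardize(apoe4))
    cov_combo = _standardize(cov_combo)

    # --- latent trait and scores -----------------------------------------
    h2, cshare = p.score_heritability, p.covariate_variance_share
    if causal_genes.size:
        signal = _standardize(
            np.sum([_standardize(expr[:, g]) for g in causal_genes], axis=0))
    else:
        signal = np.zeros(p.n_samples)
    latent = (np.sqrt(h2) * signal + np.sqrt(cshare) * cov_combo
              + np.sqrt(max(1.0 - h2 - cshare, 0.0)) * rng.normal(size=p.n_samples))
    latent = _standardize(latent)

    def test_score(scale, slope, sign):
        noisy = sign * (latent + rng.normal(0.0, p.test_noise_sd, p.n_samples))
        return scale * _sigmoid(slope * noisy)

    scores = pd.DataFrame({
        "mmse": test_score(30.0, 1.2, +1),
        "moca": test_score(30.0, 1.0, +1),
        "adas11": test_score(70.0, 1.0, -1),   # higher = worse
        "ravlt_immediate": test_score(75.0, 0.9, +1),
    }, index=sample_ids)

    c = p.ptau_coupling
    ptau_z = -c * latent + np.sqrt(max(1 - c * c, 0.0)) * rng.normal(size=p.n_samples)
    ptau = np.exp(3.0 + 0.8 * ptau_z)   # lognormal, median ~20 pg/mL

    cn_threshold = np.quantile(latent, 2.0 / 3.0)
    diagnosis = np.where(latent >= cn_threshold, "CN", "CI")

    covariates = pd.DataFrame({
        "age": age, "sex": sex, "education": education, "apoe4": apoe4,
        "ptau181": ptau, "diagnosis": diagnosis,
    }, index=sample_ids)

    # --- gene sets --------------------------------------------------------
    gene_sets = GeneSetCollection()
    enriched_terms = [term_ids[i] for i in range(k)]
    causal_set = [gene_symbols[g] for g in causal_genes]
    for i, tid in enumerate(term_ids):
        if i < k:
            # planted enrichment: the full causal gene set plus one bystander
            members = set(causal_set)
            members.add(str(rng.choice(gene_symbols)))
        else:
            size = int(rng.integers(8, 16))
            members = set(rng.choice(gene_symbols, size, replace=False))
        gene_sets[tid] = GeneSet(name=f"synthetic process {i}", members=members)

    # --- assemble ---------------------------------------------------------
    snp_ann = [GenomicAnnotation(snp_ids[j], chroms[snp_chrom[j]], position=int(snp_pos[j]))
               for j in range(p.n_snps)]
    cpg_ann = [GenomicAnnotation(cpg_ids[j], chroms[cpg_chrom[j]], position=int(cpg_pos[j]))
               for j in range(p.n_cpgs)]
    gene_ann = [GenomicAnnotation(gene_symbols[g], chroms[gene_chrom[g]],
                                  tss=int(gene_tss[g]), strand=str(gene_strand[g]),
                                  gene_symbol=gene_symbols[g])
                for g in range(p.n_genes)]

    cohort = SyntheticCohort(
        genotype=FeatureMatrix(geno, sample_ids, snp_ids, "genotype"),
        methylation=FeatureMatrix(beta, sample_ids, cpg_ids, "methylation"),
        expression=FeatureMatrix(expr, sample_ids, probe_ids, "expression"),
        covariates=covariates,
        scores=scores,
        snp_annotations=snp_ann,
        cpg_annotations=cpg_ann,
        gene_annotations=gene_ann,
        gene_sets=gene_sets,
        probe_gene_map=dict(zip(probe_ids, gene_symbols)),
    )
    cohort.validate()

    truth = GroundTruth(
        cascades=[Cascade(snp_ids[s], cpg_ids[c_], probe_ids[g], gene_symbols[g],
                          term_ids[i], p.meqtl_effect, p.meth_expr_effect)
                  for i, (s, c_, g) in enumerate(zip(causal_snps, causal_cpgs, causal_genes))],
        enriched_terms=enriched_terms,
        latent_score=latent,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# Disk bundle
# ---------------------------------------------------------------------------

_FILES = {
    "genotype": "genotype.tsv", "methylation": "methylation.tsv",
    "expression": "expression.tsv", "covariates": "covariates.tsv",
    "scores": "scores.tsv", "snps": "snps.bed", "cpgs": "cpgs.bed",
    "genes": "genes.bed", "gene_sets": "go_terms.gmt",
    "probe_gene_map": "probe_gene_map.tsv", "ground_truth": "ground_truth.json",
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_cohort(cohort: SyntheticCohort, truth: GroundTruth,
                 out_dir: str | Path) -> dict[str, str]:
    """Write the full TSV/BED/GMT/JSON bundle; returns {filename: sha256}.
    On failure the partially written directory is removed."""
    out_dir = Path(out_dir)
    created = not out_dir.exists()
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        write_matrix(cohort.genotype, out_dir / _FILES["genotype"])
        write_matrix(cohort.methylation, out_dir / _FILES["methylation"])
        write_matrix(cohort.expression, out_dir / _FILES["expression"])
        cov = cohort.covariates.copy()
        cov.index.name = "sample_id"
        cov.to_csv(out_dir / _FILES["covariates"], sep="\t")
        sc = cohort.scores.copy()
        sc.index.name = "sample_id"
        sc.to_csv(out_dir / _FILES["scores"], sep="\t", float_format="%.17g")
        write_bed_annotations(cohort.snp_annotations, out_dir / _FILES["snps"], "snp")
        write_bed_annotations(cohort.cpg_annotations, out_dir / _FILES["cpgs"], "cpg")
        write_bed_annotations(cohort.gene_annotations, out_dir / _FILES["genes"], "gene")
        write_gmt(cohort.gene_sets, out_dir / _FILES["gene_sets"])
        pd.Series(cohort.probe_gene_map, name="gene_symbol").rename_axis("probe_id") \
            .to_csv(out_dir / _FILES["probe_gene_map"], sep="\t")
        truth.to_json(out_dir / _FILES["ground_truth"])
    except Exception:
        if created:
            shutil.rmtree(out_dir, ignore_errors=True)
        raise
    manifest = {name: _sha256(out_dir / name) for name in _FILES.values()}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_cohort(in_dir: str | Path) -> tuple[SyntheticCohort, GroundTruth]:
    """Read a bundle written by :func:`write_cohort`."""
    d = Path(in_dir)
    covariates = pd.read_csv(d / _FILES["covariates"], sep="\t", index_col=0)
    covariates.index = covariates.index.map(str)
    scores = pd.read_csv(d / _FILES["scores"], sep="\t", index_col=0)
    scores.index = scores.index.map(str)
    probe_map = pd.read_csv(d / _FILES["probe_gene_map"], sep="\t", index_col=0,
                            dtype=str)["gene_symbol"].to_dict()
    cohort = SyntheticCohort(
        genotype=read_matrix(d / _FILES["genotype"], "genotype"),
        methylation=read_matrix(d / _FILES["methylation"], "methylation"),
        expression=read_matrix(d / _FILES["expression"], "expression"),
        covariates=covariates,
        scores=scores,
        snp_annotations=read_bed_annotations(d / _FILES["snps"], "snp"),
        cpg_annotations=read_bed_annotations(d / _FILES["cpgs"], "cpg"),
        gene_annotations=read_bed_annotations(d / _FILES["genes"], "gene"),
        gene_sets=read_gmt(d / _FILES["gene_sets"]),
        probe_gene_map=probe_map,
    )
    cohort.validate()
    truth = GroundTruth.from_json(d / _FILES["ground_truth"])
    return cohort, truth
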