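"""Readers and writers for every external representation the pipeline touches.

All genomic coordinates are 0-based, half-open (BED convention); point
features (SNPs, CpGs) are stored as single integer positions and encoded on
disk as ``[p, p+1)`` intervals.  Matrices are exchanged as tab-separated
text with feature ids in the header row and sample ids in the first column.
Genotype dosages use a dedicated missing sentinel (default ``-1``) rather
than NaN so that QC missingness counts are exact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

logger = logging.getLogger("hinnlab")

MISSING_GENOTYPE = -1.0

MODALITIES = ("genotype", "methylation", "expression", "covariate")


class FormatError(ValueError):
    """A file violated the dialect this package expects."""


# ---------------------------------------------------------------------------
# FeatureMatrix
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Dense samples x features matrix for one omics modality.

    Invariants: unique, ordered sample and feature ids whose counts match the
    value shape; methylation values (when present) lie in [0, 1]; genotype
    values are in {0, 1, 2} or equal to ``missing_code``.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    modality: str
    missing_code: float = MISSING_GENOTYPE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = list(map(str, self.sample_ids))
        self.feature_ids = list(map(str, self.feature_ids))
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.feature_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample_ids")
        if len(set(self.feature_ids)) != p:
            raise ValueError("duplicate feature_ids")
        if self.modality == "methylation" and self.values.size:
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
                raise ValueError(
                    "methylation beta values must lie in [0, 1]; "
                    f"observed range [{finite.min():g}, {finite.max():g}]"
                )
        if self.modality == "genotype" and self.values.size:
            obs = self.observed_mask()
            called = self.values[obs]
            bad = called[~np.isin(called, (0.0, 1.0, 2.0))]
            if bad.size:
                raise ValueError(
                    f"genotype calls must be in {{0,1,2}} or missing; found {bad[:5]}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def observed_mask(self) -> np.ndarray:
        """Boolean mask of non-missing cells (genotype sentinel aware)."""
        if self.modality == "genotype":
            return self.values != self.missing_code
        return np.isfinite(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def subset(self, sample_ids=None, feature_ids=None) -> "FeatureMatrix":
        df = self.to_frame()
        if sample_ids is not None:
            df = df.loc[list(sample_ids)]
        if feature_ids is not None:
            df = df[list(feature_ids)]
        return FeatureMatrix(df.to_numpy(), list(df.index), list(df.columns),
                             self.modality, self.missing_code)


def read_matrix(path: str | Path, modality: str,
                missing_code: float = MISSING_GENOTYPE) -> FeatureMatrix:
    """Read a TSV matrix (header = feature ids, first column = sample ids)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise FormatError(f"{path}: duplicate feature ids {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate sample ids {dups}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce")
            mask = bad.isna() & df[col].notna()
            if mask.any():
                row = df.index[mask.to_numpy().argmax()]
                raise FormatError(
                    f"{path}: non-numeric value {df.loc[row, col]!r} "
                    f"at row {row!r}, column {col!r}"
                ) from None
        raise
    return FeatureMatrix(values, list(df.index), list(df.columns), modality, missing_code)


def write_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# Genomic annotations (BED dialect)
# ---------------------------------------------------------------------------

@dataclass
class GenomicAnnotation:
    """Location of one feature. Point features carry ``position``; genes carry
    ``tss`` + ``strand`` (TSS = interval start on '+', end-1 on '-')."""

    feature_id: str
    chromosome: str
    position: Optional[int] = None
    tss: Optional[int] = None
    strand: Optional[str] = None
    gene_symbol: Optional[str] = None


def read_bed_annotations(path: str | Path, modality: str) -> list[GenomicAnnotation]:
    """Parse a BED file. ``modality`` is 'snp' or 'cpg' (point features) or
    'gene' (strand in column 6, gene symbol in column 4)."""
    if modality not in ("snp", "cpg", "gene"):
        raise ValueError(f"unknown annotation modality {modality!r}")
    path = Path(path)
    out: list[GenomicAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected >= 4 BED columns, got {len(fields)}")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer interval bounds") from None
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start {start}")
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end {end} <= start {start}")
            if modality == "gene":
                if len(fields) < 6 or fields[5] not in ("+", "-"):
                    raise FormatError(f"{path}:{lineno}: gene row missing strand in column 6")
                strand = fields[5]
                tss = start if strand == "+" else end - 1
                ann = GenomicAnnotation(name, chrom, tss=tss, strand=strand, gene_symbol=name)
            else:
                gene = fields[6] if len(fields) > 6 and fields[6] != "." else None
                ann = GenomicAnnotation(name, chrom, position=start, gene_symbol=gene)
            if ann.feature_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate feature id {ann.feature_id!r}")
            seen.add(ann.feature_id)
            out.append(ann)
    return out


def write_bed_annotations(annotations: Iterable[GenomicAnnotation],
                          path: str | Path, modality: str) -> None:
    with open(path, "w") as fh:
        for ann in annotations:
            if modality == "gene":
                # interval chosen so the strand rule recovers the tss exactly
                if ann.strand == "+":
                    start, end = ann.tss, ann.tss + 1000
                else:
                    start, end = max(0, ann.tss - 999), ann.tss + 1
                fh.write(f"{ann.chromosome}\t{start}\t{end}\t{ann.feature_id}\t.\t{ann.strand}\n")
            else:
                gene = ann.gene_symbol or "."
                fh.write(f"{ann.chromosome}\t{ann.position}\t{ann.position + 1}"
                         f"\t{ann.feature_id}\t.\t.\t{gene}\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    name: str
    members: set[str]


class GeneSetCollection(dict):
    """Mapping term_id -> GeneSet; no empty member sets, unique term ids."""

    def add(self, term_id: str, name: str, members: Iterable[str]) -> None:
        members = set(members)
        if not members:
            raise ValueError(f"term {term_id!r} has no members")
        if term_id in self:
            raise ValueError(f"duplicate term id {term_id!r}")
        self[term_id] = GeneSet(name, members)


def read_gmt(path: str | Path) -> GeneSetCollection:
    path = Path(path)
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 2 fields")
            term_id, name = fields[0], fields[1]
            members = {m for m in fields[2:] if m}
            if not members:
                logger.warning("%s:%d: term %s is empty, dropped", path, lineno, term_id)
                continue
            if term_id in coll:
                raise FormatError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            coll[term_id] = GeneSet(name, members)
    return coll


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term_id, gs in collection.items():
            fh.write("\t".join([term_id, gs.name, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

class QCThresholdsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    max_missing_rate_snp: float = Field(0.05, gt=0, lt=1)
    max_missing_rate_sample: float = Field(0.05, gt=0, lt=1)
    min_maf: float = Field(0.05, ge=0, lt=0.5)
    hwe_alpha: float = Field(1e-6, gt=0, lt=1)
    # literal_directions reproduces the printed (inverted) QC reading:
    # exclude call rate > 95% and HWE p > alpha.
    literal_directions: bool = False
    gwas_adjusted_alpha: float = Field(0.01, gt=0, le=1)
    gwas_adjustment: str = Field("bonferroni", pattern="^(bonferroni|BH|none)$")
    window_bp: int = Field(1_000_000, gt=0)
    promoter_offsets_bp: tuple[int, int] = (200, 1500)
    require_promoter_for_cpg: bool = False
    enrichment_alpha: float = Field(0.05, gt=0, le=1)
    enrichment_adjustment: str = Field("BH", pattern="^(none|BH|bonferroni)$")
    require_go_connected_probes: bool = False

    @model_validator(mode="after")
    def _check_offsets(self):
        near, far = self.promoter_offsets_bp
        if not (0 < near < far):
            raise ValueError("promoter offsets must satisfy 0 < near < far")
        return self


class ArchitectureConfigModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    variant: str = Field("hinn", pattern="^(hinn|fully_connected|hierarchy_only|"
                                         "randomized|drop_snp|drop_cpg|drop_expr|no_go|pgnn)$")
    bypass_width: int = Field(20, gt=0)
    dense_head_blocks: int = Field(4, gt=0)
    dense_head_width: int = Field(128, gt=0)
    bottleneck_width: int = Field(20, gt=0)
    bn_momentum: float = Field(0.9, ge=0, lt=1)
    bn_epsilon: float = Field(0.005, gt=0)
    dropout: float = Field(0.7, ge=0, lt=1)
    l2_strength: float = Field(1e-4, ge=0)
    omics_activation: str = Field("relu", pattern="^(relu|tanh|sigmoid)$")
    denominator_epsilon: float = Field(1e-6, gt=0)
    demographic_features: list[str] = ["age", "sex", "education", "apoe4", "ptau181", "race"]


class TrainConfigModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    test_fraction: float = Field(0.30, gt=0, lt=1)
    validation_fraction: float = Field(0.20, gt=0, lt=1)
    n_repeats: int = Field(3, ge=1)
    patience: int = Field(50, ge=1)
    max_epochs: int = Field(500, ge=1)
    learning_rate: float = Field(3e-3, gt=0)
    batch_size: int = Field(64, ge=1)
    grad_clip: float = Field(5.0, gt=0)
    seed: int = 0


class SimulationConfigModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_samples: int = Field(500, gt=0)
    n_snps: int = Field(200, gt=0)
    n_cpgs: int = Field(300, gt=0)
    n_genes: int = Field(100, gt=0)
    n_go_terms: int = Field(30, gt=0)
    n_causal_cascades: int = Field(5, gt=0)
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_maf_range: tuple[float, float] = (0.15, 0.5)
    meqtl_effect: float = 1.5
    meth_expr_effect: float = 2.0
    score_heritability: float = Field(0.6, ge=0, le=1)
    covariate_variance_share: float = Field(0.1, ge=0, lt=1)
    cpg_logit_noise_sd: float = Field(0.5, ge=0)
    expr_noise_sd: float = Field(0.3, ge=0)
    test_noise_sd: float = Field(0.3, ge=0)
    missing_rate: float = Field(0.02, ge=0, lt=1)
    chromosome_length: int = Field(50_000_000, gt=0)
    n_chromosomes: int = Field(1, ge=1)
    window_bp: int = Field(1_000_000, gt=0)
    promoter_offsets_bp: tuple[int, int] = (200, 1500)
    ptau_coupling: float = Field(0.35, ge=-1, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_causal_cascades > min(self.n_snps, self.n_cpgs, self.n_genes):
            raise ValueError("n_causal_cascades exceeds a layer size")
        return self


class RunConfig(BaseModel):
    """Validated hierarchical run configuration. Unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = 1
    seed: int = 0
    simulation: SimulationConfigModel = SimulationConfigModel()
    qc: QCThresholdsConfig = QCThresholdsConfig()
    architecture: ArchitectureConfigModel = ArchitectureConfigModel()
    training: TrainConfigModel = TrainConfigModel()
    phenotypes: list[str] = ["mmse", "moca", "adas11", "ravlt_immediate"]
    top_k: int = Field(10, ge=1)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run config; echo the resolved document."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    cfg = RunConfig.model_validate(raw or {})
    logger.info("resolved config from %s:\n%s",
                path, yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=False))
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    doc = cfg.model_dump(mode="json")
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(doc, fh, indent=2)
        else:
            yaml.safe_dump(doc, fh, sort_keys=False)
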