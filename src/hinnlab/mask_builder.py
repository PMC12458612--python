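"""Binary connectivity masks derived from a RelationMap, plus the ablation
variants (fully connected, edge-count-preserving randomization, and a
row-degree-preserving shuffle)."""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .qc_selection import RelationMap


@dataclass
class MaskSet:
    """Ordered layer ids and the three binary masks
    M1 (snp x cpg), M2 (cpg x probe), M3 (probe x term)."""

    snp_ids: list[str]
    cpg_ids: list[str]
    probe_ids: list[str]
    term_ids: list[str]
    m1: np.ndarray
    m2: np.ndarray
    m3: np.ndarray
    variant: str = "biological"

    def __post_init__(self) -> None:
        for name, m, rows, cols in (("M1", self.m1, self.snp_ids, self.cpg_ids),
                                    ("M2", self.m2, self.cpg_ids, self.probe_ids),
                                    ("M3", self.m3, self.probe_ids, self.term_ids)):
            m = np.asarray(m, dtype=float)
            if m.shape != (len(rows), len(cols)):
                raise ValueError(f"{name} shape {m.shape} != ({len(rows)}, {len(cols)})")
            if not np.isin(m, (0.0, 1.0)).all():
                raise ValueError(f"{name} entries must be binary")
        self.m1 = np.asarray(self.m1, float)
        self.m2 = np.asarray(self.m2, float)
        self.m3 = np.asarray(self.m3, float)

    @property
    def masks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.m1, self.m2, self.m3

    def edge_counts(self) -> tuple[int, int, int]:
        return int(self.m1.sum()), int(self.m2.sum()), int(self.m3.sum())

    def save(self, prefix: str | Path) -> None:
        """Write <prefix>.npz (masks) + <prefix>.json sidecar (orderings, tag)."""
        prefix = Path(prefix)
        np.savez(prefix.with_suffix(".npz"), m1=self.m1, m2=self.m2, m3=self.m3)
        with open(prefix.with_suffix(".json"), "w") as fh:
            json.dump({"snp_ids": self.snp_ids, "cpg_ids": self.cpg_ids,
                       "probe_ids": self.probe_ids, "term_ids": self.term_ids,
                       "variant": self.variant}, fh, indent=2)

    @classmethod
    def load(cls, prefix: str | Path) -> "MaskSet":
        prefix = Path(prefix)
        arrays = np.load(prefix.with_suffix(".npz"))
        with open(prefix.with_suffix(".json")) as fh:
            meta = json.load(fh)
        return cls(meta["snp_ids"], meta["cpg_ids"], meta["probe_ids"],
                   meta["term_ids"], arrays["m1"], arrays["m2"], arrays["m3"],
                   meta["variant"])


def _ordering(ids: list[str], annotations=None) -> list[str]:
    if annotations:
        pos = {a.feature_id: (a.chromosome, a.position if a.position is not None
                              else a.tss, a.feature_id) for a in annotations}
        return sorted(ids, key=lambda i: pos.get(i, ("~", 0, i)))
    return sorted(ids)


def build_masks(rel: RelationMap, snp_annotations=None, cpg_annotations=None,
                gene_annotations=None) -> MaskSet:
    """Populate M1/M2/M3 from RelationMap edges with deterministic layer
    orderings (lexicographic by chromosome, position, id when annotations are
    given; plain lexicographic otherwise)."""
    if not (rel.snps and rel.cpgs and rel.probes and rel.terms):
        raise ValueError("RelationMap has an empty layer")
    snp_ids = _ordering(rel.snps, snp_annotations)
    cpg_ids = _ordering(rel.cpgs, cpg_annotations)
    probe_ids = sorted(rel.probes)
    term_ids = sorted(rel.terms)
    si = {s: i for i, s in enumerate(snp_ids)}
    ci = {c: i for i, c in enumerate(cpg_ids)}
    pi = {p: i for i, p in enumerate(probe_ids)}
    ti = {t: i for i, t in enumerate(term_ids)}
    m1 = np.zeros((len(snp_ids), len(cpg_ids)))
    m2 = np.zeros((len(cpg_ids), len(probe_ids)))
    m3 = np.zeros((len(probe_ids), len(term_ids)))
    for s, c, _ in rel.snp_cpg:
        m1[si[s], ci[c]] = 1.0
    for c, p, _ in rel.cpg_probe:
        m2[ci[c], pi[p]] = 1.0
    for p, t in rel.probe_term:
        m3[pi[p], ti[t]] = 1.0
    return MaskSet(snp_ids, cpg_ids, probe_ids, term_ids, m1, m2, m3, "biological")


def edges_from_masks(masks: MaskSet) -> tuple[set, set, set]:
    """Inverse map: recover (snp,cpg), (cpg,probe), (probe,term) edge sets."""
    e1 = {(masks.snp_ids[i], masks.cpg_ids[j]) for i, j in zip(*np.nonzero(masks.m1))}
    e2 = {(masks.cpg_ids[i], masks.probe_ids[j]) for i, j in zip(*np.nonzero(masks.m2))}
    e3 = {(masks.probe_ids[i], masks.term_ids[j]) for i, j in zip(*np.nonzero(masks.m3))}
    return e1, e2, e3


def ablate_full(masks: MaskSet) -> MaskSet:
    """All-ones masks of identical shapes; orderings unchanged."""
    return replace(masks, m1=np.ones_like(masks.m1), m2=np.ones_like(masks.m2),
                   m3=np.ones_like(masks.m3), variant="full")


def _randomize(m: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    k = int(m.sum())
    flat = np.zeros(m.size)
    flat[rng.choice(m.size, size=k, replace=False)] = 1.0
    return flat.reshape(m.shape)


def ablate_randomized(masks: MaskSet, seed: int) -> MaskSet:
    """Preserve each mask's 1-entry count but place the entries uniformly at
    random over all positions (seeded, reproducible)."""
    rng = np.random.default_rng(seed)
    return replace(masks, m1=_randomize(masks.m1, rng),
                   m2=_randomize(masks.m2, rng),
                   m3=_randomize(masks.m3, rng), variant="randomized")


def ablate_shuffled_rows(masks: MaskSet, seed: int) -> MaskSet:
    """Row-degree-preserving alternative: shuffle each row's 1-entries among
    its columns (keeps every source node's out-degree)."""
    rng = np.random.default_rng(seed)

    def shuffle(m: np.ndarray) -> np.ndarray:
        out = np.zeros_like(m)
        for i in range(m.shape[0]):
            k = int(m[i].sum())
            out[i, rng.choice(m.shape[1], size=k, replace=False)] = 1.0
        return out

    return replace(masks, m1=shuffle(masks.m1), m2=shuffle(masks.m2),
                   m3=shuffle(masks.m3), variant="randomized")
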