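"""Stratified Spearman correlation analyses: CpG <-> expression by cognitive
group (CN vs CI), and SNP/CpG/probe/cognition <-> plasma p-Tau181.

Rho uses average (mid) ranks.  P-values come from the two-sided t
approximation, except for very small samples (n <= 9) where the exact
permutation distribution is enumerated in full.  Significance is flagged on
the raw p-value by default — mirroring the reporting convention of the
stratified tables this module reproduces — with BH-adjusted p-values always
reported alongside.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("hinnlab")

EXACT_N_MAX = 9


@dataclass
class CohortGroups:
    """sample_id -> group in {CN, CI}; CI comprises MCI and AD diagnoses."""

    assignment: dict[str, str]

    @classmethod
    def from_diagnosis(cls, diagnosis: pd.Series) -> "CohortGroups":
        mapping = {"CN": "CN", "CI": "CI", "MCI": "CI", "AD": "CI"}
        out = {}
        for sid, dx in diagnosis.items():
            if dx not in mapping:
                raise ValueError(f"unknown diagnosis {dx!r} for sample {sid}")
            out[str(sid)] = mapping[dx]
        return cls(out)

    def members(self, group: str) -> list[str]:
        return [s for s, g in self.assignment.items() if g == group]


def spearman_correlation(x, y) -> tuple[float, float]:
    """Midrank Spearman rho with a two-sided p-value (exact permutation
    enumeration for n <= 9, t approximation otherwise) over pairwise-complete
    observations.  Zero variance in either vector yields (nan, nan)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("vectors differ in length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 pairwise-complete observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_N_MAX:
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum())
        perms = np.array(list(itertools.permutations(ryc)))
        rhos = (perms @ rxc) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, p


def _correlate_pairs(frame_a: pd.DataFrame, frame_b: pd.DataFrame,
                     pairs: list[tuple[str, str]], layer_a: str, layer_b: str,
                     groups: "CohortGroups | None", alpha: float,
                     flag_on: str = "raw") -> pd.DataFrame:
    """Shared worker: per pair x group rho/p with BH adjustment per group."""
    group_ids: dict[str, list[str]]
    if groups is None:
        group_ids = {"all": list(frame_a.index)}
    else:
        group_ids = {g: [s for s in groups.members(g) if s in frame_a.index]
                     for g in ("CN", "CI")}
    rows = []
    for group, sids in group_ids.items():
        if len(sids) < 3:
            logger.warning("group %s has %d samples (< 3); skipped", group, len(sids))
            continue
        for a, b in pairs:
            x = frame_a.loc[sids, a].to_numpy(float)
            y = frame_b.loc[sids, b].to_numpy(float)
            rho, p = spearman_correlation(x, y)
            if not np.isfinite(rho):
                logger.warning("pair (%s, %s) in %s has zero variance; excluded",
                               a, b, group)
                continue
            rows.append({"feature_a": a, "layer_a": layer_a, "feature_b": b,
                         "layer_b": layer_b, "group": group, "n": len(sids),
                         "rho": rho, "p_raw": p})
    if not rows:
        return pd.DataFrame(columns=["feature_a", "layer_a", "feature_b",
                                     "layer_b", "group", "n", "rho", "p_raw",
                                     "p_adjusted", "significant"])
    table = pd.DataFrame(rows)
    table["p_adjusted"] = np.nan
    for group in table["group"].unique():
        mask = table["group"] == group
        table.loc[mask, "p_adjusted"] = multipletests(
            table.loc[mask, "p_raw"], method="fdr_bh")[1]
    pcol = "p_raw" if flag_on == "raw" else "p_adjusted"
    table["significant"] = table[pcol] <= alpha
    return table


def methylation_expression_correlation(betas: pd.DataFrame, expr: pd.DataFrame,
                                       pairs: list[tuple[str, str]],
                                       groups: CohortGroups | None,
                                       alpha: float = 0.05,
                                       flag_on: str = "raw") -> pd.DataFrame:
    """Per (CpG, probe) pair and cognitive group: midrank Spearman rho, raw
    and BH-adjusted p. Pairs normally come from the RelationMap's promoter
    edges. The table is sorted by probe then CpG, one block per group."""
    table = _correlate_pairs(betas, expr, pairs, "cpg", "probe", groups,
                             alpha, flag_on)
    if len(table):
        table = table.sort_values(["feature_b", "feature_a", "group"]).reset_index(drop=True)
    return table


def ptau_feature_correlation(features: pd.DataFrame, ptau: pd.Series,
                             groups: CohortGroups | None, layer: str = "feature",
                             alpha: float = 0.05,
                             flag_on: str = "raw") -> pd.DataFrame:
    """Per feature x group correlation with the plasma p-Tau181 proxy."""
    ptau_frame = ptau.to_frame("ptau181").astype(float)
    pairs = [(f, "ptau181") for f in features.columns]
    table = _correlate_pairs(features, ptau_frame, pairs, layer, "biomarker",
                             groups, alpha, flag_on)
    if len(table):
        table = table.sort_values(["feature_a", "group"]).reset_index(drop=True)
    return table


def ptau_cognition_correlation(scores: pd.DataFrame, ptau: pd.Series,
                               alpha: float = 0.05,
                               flag_on: str = "raw") -> pd.DataFrame:
    """One whole-cohort rho/p per cognitive test against p-Tau181."""
    ptau_frame = ptau.to_frame("ptau181").astype(float)
    pairs = [(c, "ptau181") for c in scores.columns]
    return _correlate_pairs(scores, ptau_frame, pairs, "cognition", "biomarker",
                            None, alpha, flag_on)
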