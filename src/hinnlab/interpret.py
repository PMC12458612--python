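"""DeepLIFT-style attribution over trained models, cross-test aggregation of
feature importance, and Sankey export of prioritized multi-layer cascades.

The attribution walks the recorded forward graph backwards propagating
DeepLIFT multipliers: linear operations pass multipliers through the linear
map itself, elementwise nonlinearities use the Rescale rule
(multiplier = delta-output / delta-input, falling back to the local gradient
for vanishing input deltas), and two-input products use the symmetric
half-split product rule, so sum-to-delta holds exactly up to float error:

    sum_i contribution_i = f(x) - f(reference)       (per sample)

The epsilon-clamped reciprocal of the division stage is treated as one
elementwise unit.  Models are evaluated with frozen normalization statistics
and no dropout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .hinn_core import Graph, HinnModel, Node, _activate
from .qc_selection import RelationMap

logger = logging.getLogger("hinnlab")

_DELTA_TOL = 1e-7


def _rescale_mult(x_val, r_val, out_x, out_r, grad_at_x):
    delta_in = x_val - r_val
    delta_out = out_x - out_r
    small = np.abs(delta_in) < _DELTA_TOL
    safe = np.where(small, 1.0, delta_in)
    return np.where(small, grad_at_x, delta_out / safe)


def deeplift_contributions(model: HinnModel, X: dict[str, np.ndarray],
                           reference: dict[str, np.ndarray]
                           ) -> tuple[dict[str, np.ndarray], np.ndarray, float]:
    """Per-sample, per-feature contributions of the raw-scale prediction
    relative to ``reference`` (a single row per input).

    Returns ``(contribs, f_x, f_ref)``: contributions keyed like the model's
    graph inputs, the per-sample predictions, and the scalar reference
    prediction.
    """
    n = next(v.shape[0] for k, v in X.items() if k != "demo_names")
    ref_tiled = {}
    for key, val in X.items():
        if key == "demo_names":
            continue
        r = np.asarray(reference[key], float).reshape(1, -1)
        if r.shape[1] != val.shape[1]:
            raise ValueError(f"reference width mismatch for {key!r}: "
                             f"{r.shape[1]} != {val.shape[1]}")
        ref_tiled[key] = np.tile(r, (n, 1))

    gx, out_x = model.forward(X, mode="eval")
    gr, out_r = model.forward(ref_tiled, mode="eval")
    mults = rescale_multipliers(gx, gr, out_x, np.full((n, 1), model.y_std))
    contribs = {}
    for name, node in gx.inputs.items():
        m = mults.get(node.idx, np.zeros_like(node.value))
        contribs[name] = m * (node.value - ref_tiled[name])
    f_x = out_x.value[:, 0] * model.y_std + model.y_mean
    f_ref = float(out_r.value[0, 0] * model.y_std + model.y_mean)
    return contribs, f_x, f_ref


def rescale_multipliers(gx: Graph, gr: Graph, out: Node,
                        seed_mult: np.ndarray) -> dict[int, np.ndarray]:
    """Propagate DeepLIFT multipliers backwards through a pair of recorded
    graphs (actual input vs reference).  Returns node index -> multiplier."""
    if len(gx.nodes) != len(gr.nodes):
        raise RuntimeError("forward graphs differ between input and reference")

    mults: dict[int, np.ndarray] = {}

    def send(node: Node, m: np.ndarray) -> None:
        if node.idx in mults:
            mults[node.idx] = mults[node.idx] + m
        else:
            mults[node.idx] = m

    send(out, np.asarray(seed_mult, float))
    for nx, nr in zip(reversed(gx.nodes), reversed(gr.nodes)):
        m = mults.get(nx.idx)
        if m is None or nx.op == "input":
            continue
        op = nx.op
        if op == "matmul":
            send(nx.parents[0], m @ nx.cache["weff"].T)
        elif op == "diag":
            send(nx.parents[0], m * nx.params[0].value)
        elif op == "bias":
            send(nx.parents[0], m)
        elif op == "add":
            send(nx.parents[0], m)
            send(nx.parents[1], m)
        elif op == "mul":
            ax, bx = nx.parents
            ar, br = nr.parents
            da, db = ax.value - ar.value, bx.value - br.value
            send(ax, m * (br.value + 0.5 * db))
            send(bx, m * (ar.value + 0.5 * da))
        elif op == "recip":
            x, xr = nx.parents[0], nr.parents[0]
            eps = nx.cache["eps"]
            grad = np.where(x.value >= eps, -nx.value ** 2, 0.0)
            send(x, m * _rescale_mult(x.value, xr.value, nx.value, nr.value, grad))
        elif op == "act":
            x, xr = nx.parents[0], nr.parents[0]
            kind = nx.cache["kind"]
            if kind == "relu":
                grad = (x.value > 0).astype(float)
            elif kind == "tanh":
                grad = 1.0 - nx.value ** 2
            else:
                grad = nx.value * (1.0 - nx.value)
            send(x, m * _rescale_mult(x.value, xr.value, nx.value, nr.value, grad))
        elif op == "concat":
            start = 0
            for parent, w in zip(nx.parents, nx.cache["widths"]):
                send(parent, m[:, start:start + w])
                start += w
        elif op == "bn":
            if nx.cache["mode"] != "eval":
                raise RuntimeError("attribution requires eval-mode batch norm")
            send(nx.parents[0], m * nx.params[0].value * nx.cache["invstd"])
        elif op == "dropout":
            raise RuntimeError("attribution requires eval mode (no dropout)")
        else:  # pragma: no cover
            raise RuntimeError(f"unknown op {op}")
    return mults


# ---------------------------------------------------------------------------
# Attribution tables
# ---------------------------------------------------------------------------

_LAYER_OF_INPUT = {"snp": "snp", "cpg": "cpg", "expr": "probe",
                   "demo": "demographic"}


def reference_inputs(X: dict[str, np.ndarray], policy: str = "mean"
                     ) -> dict[str, np.ndarray]:
    """Reference row per input: feature-wise mean ('mean') or zeros."""
    if policy not in ("mean", "zeros"):
        raise ValueError(f"unknown reference policy {policy!r}")
    out = {}
    for key, val in X.items():
        if key == "demo_names":
            continue
        out[key] = val.mean(axis=0) if policy == "mean" else np.zeros(val.shape[1])
    return out


def deeplift_attributions(model: HinnModel, X: dict[str, np.ndarray],
                          reference: str = "mean",
                          phenotype: str = "score") -> pd.DataFrame:
    """AttributionTable for one trained model: one row per (feature, layer)
    with the mean absolute and mean signed per-sample contribution.  Layers
    absent from a variant (e.g. SNPs under drop_snp) get exactly zero."""
    ref = reference_inputs(X, reference)
    contribs, f_x, f_ref = deeplift_contributions(model, X, ref)

    feature_ids = {"snp": model.masks.snp_ids, "cpg": model.masks.cpg_ids,
                   "expr": model.masks.probe_ids,
                   "demo": X.get("demo_names",
                                 [f"demo{i}" for i in range(X["demo"].shape[1])])}
    rows = []
    for key, layer in _LAYER_OF_INPUT.items():
        ids = feature_ids[key]
        c = contribs.get(key)
        if c is None:
            score = signed = np.zeros(len(ids))
        else:
            score = np.abs(c).mean(axis=0)
            signed = c.mean(axis=0)
        for fid, s, sg in zip(ids, score, signed):
            rows.append((fid, layer, phenotype, float(s), float(sg)))
    return pd.DataFrame(rows, columns=["feature_id", "layer", "phenotype",
                                       "score", "score_signed"])


def aggregate_importance(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean |score| across phenotype tables, with percentile ranks computed
    within each layer separately."""
    if not tables:
        raise ValueError("no attribution tables")
    keys = [set(zip(t["feature_id"], t["layer"])) for t in tables]
    for i, k in enumerate(keys[1:], 1):
        if k != keys[0]:
            diff = sorted(k ^ keys[0])
            raise ValueError(f"feature sets differ between tables: {diff[:10]}")
    stacked = pd.concat(tables, ignore_index=True)
    agg = (stacked.groupby(["feature_id", "layer"], as_index=False)
           .agg(score=("score", lambda s: np.mean(np.abs(s))),
                score_signed=("score_signed", "mean")))
    agg["percentile"] = 0.0
    for layer, idx in agg.groupby("layer").groups.items():
        scores = agg.loc[idx, "score"].to_numpy()
        agg.loc[idx, "percentile"] = rankdata(scores, method="average") / len(scores) * 100.0
    return agg.sort_values(["layer", "percentile"],
                           ascending=[True, False]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Sankey export
# ---------------------------------------------------------------------------

@dataclass
class SankeyGraph:
    nodes: list[dict] = field(default_factory=list)
    links: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"nodes": self.nodes, "links": self.links}, fh, indent=2)

    def complete_chains(self) -> set[tuple[str, str, str, str]]:
        """All SNP -> CpG -> probe -> term paths present in the graph."""
        by_src: dict[str, list[str]] = {}
        for link in self.links:
            by_src.setdefault(link["source"], []).append(link["target"])
        layer = {nd["id"]: nd["layer"] for nd in self.nodes}
        chains = set()
        for s in [nd["id"] for nd in self.nodes if nd["layer"] == "snp"]:
            for c in by_src.get(s, ()):
                if layer.get(c) != "cpg":
                    continue
                for p in by_src.get(c, ()):
                    if layer.get(p) != "probe":
                        continue
                    for t in by_src.get(p, ()):
                        if layer.get(t) == "term":
                            chains.add((s, c, p, t))
        return chains


def export_sankey(agg: pd.DataFrame, rel: RelationMap,
                  top_k: int = 10) -> SankeyGraph:
    """Keep the top_k features per molecular layer by attribution percentile;
    a link appears only when both endpoints are selected and the edge exists
    in the RelationMap.  GO terms are ranked by the mean attribution of their
    selected upstream probes."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    selected: dict[str, list[str]] = {}
    score_of: dict[tuple[str, str], float] = {}
    for layer in ("snp", "cpg", "probe"):
        sub = agg[agg["layer"] == layer].sort_values(
            ["score", "feature_id"], ascending=[False, True])
        selected[layer] = sub["feature_id"].head(top_k).tolist()
        for _, row in sub.iterrows():
            score_of[(layer, row["feature_id"])] = float(row["score"])

    s_set, c_set, p_set = (set(selected[l]) for l in ("snp", "cpg", "probe"))
    links = []
    for s, c, _dist in rel.snp_cpg:
        if s in s_set and c in c_set:
            links.append({"source": s, "target": c, "provenance": "window",
                          "weight": score_of[("snp", s)]})
    for c, p, tag in rel.cpg_probe:
        if c in c_set and p in p_set:
            links.append({"source": c, "target": p, "provenance": tag,
                          "weight": score_of[("cpg", c)]})
    term_score: dict[str, list[float]] = {}
    for p, t in rel.probe_term:
        if p in p_set:
            term_score.setdefault(t, []).append(score_of[("probe", p)])
    top_terms = sorted(term_score,
                       key=lambda t: (-float(np.mean(term_score[t])), t))[:top_k]
    t_set = set(top_terms)
    for p, t in rel.probe_term:
        if p in p_set and t in t_set:
            links.append({"source": p, "target": t, "provenance": "annotation",
                          "weight": score_of[("probe", p)]})

    graph = SankeyGraph()
    for layer in ("snp", "cpg", "probe"):
        for rank, fid in enumerate(selected[layer], 1):
            graph.nodes.append({"id": fid, "layer": layer, "rank": rank})
    for rank, t in enumerate(top_terms, 1):
        graph.nodes.append({"id": t, "layer": "term", "rank": rank})
    graph.links = links
    if not links:
        logger.warning("export_sankey: no links survive joint prioritization")
    return graph
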