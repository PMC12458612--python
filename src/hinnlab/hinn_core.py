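"""The hierarchical input network: mask-constrained forward model, ablation
variants, PGNN, training protocol and classical baselines.

The model is built on a small reverse-mode layer graph over numpy arrays.
Each forward pass records a DAG of primitive operations; the same DAG drives
exact gradient backpropagation during training and (in ``interpret``) the
DeepLIFT Rescale rule during attribution.  Masked affine layers apply the
Hadamard product ``M (*) W`` before the matrix product, so weights at
masked-out positions have provably zero influence on outputs and gradients.

Signal flow of the full hierarchical variant (n samples):

    Y1 = act(X_snp @ (M1 (*) W1) + b1)                      # SNP -> CpG-space
    Y2 = act(featurewise_scale(X_cpg) (*) Y1 + b2)          # multiplicative
    Y3 = act(featurewise_scale(X_expr) / f(Y2, M2) + b3)    # division-based
    Y4 = act(Y3 @ (M3 (*) W3) + b4)                         # probe -> GO term

with a 20-node fully-connected bypass chained alongside (SNP stage ->
methylation stage -> expression stage -> GO stage), then a dense head of
four (batch-norm, 128-unit ReLU dense, dropout) blocks, a 20-node
bottleneck, concatenation of demographic covariates, one more
(batch-norm, dense, dropout) block and a single linear output.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .io_formats import ArchitectureConfigModel, FeatureMatrix, TrainConfigModel
from .mask_builder import MaskSet, ablate_full, ablate_randomized
from .qc_selection import min_max_normalize

logger = logging.getLogger("hinnlab")

ArchitectureConfig = ArchitectureConfigModel
TrainConfig = TrainConfigModel

VARIANTS = ("hinn", "fully_connected", "hierarchy_only", "randomized",
            "drop_snp", "drop_cpg", "drop_expr", "no_go", "pgnn")


# ---------------------------------------------------------------------------
# Standalone kernels of the masked-connection framework
# ---------------------------------------------------------------------------

def _activate(x: np.ndarray, act: str) -> np.ndarray:
    if act == "identity":
        return x
    if act == "relu":
        return np.maximum(x, 0.0)
    if act == "tanh":
        return np.tanh(x)
    if act == "sigmoid":
        return 1.0 / (1.0 + np.exp(-x))
    raise ValueError(f"unknown activation {act!r}")


def masked_affine(X: np.ndarray, M: np.ndarray, W: np.ndarray, B: np.ndarray,
                  act: str = "identity") -> np.ndarray:
    """act(X @ (M (*) W) + B). The mask gates which weights carry signal."""
    X, M, W, B = (np.asarray(a, float) for a in (X, M, W, B))
    if M.shape != W.shape:
        raise ValueError(f"mask shape {M.shape} != weight shape {W.shape}")
    if X.shape[1] != M.shape[0]:
        raise ValueError(f"input width {X.shape[1]} != mask rows {M.shape[0]}")
    if not np.isin(M, (0.0, 1.0)).all():
        raise ValueError("mask entries must be binary")
    return _activate(X @ (M * W) + B, act)


def featurewise_scale(X: np.ndarray, diag: np.ndarray) -> np.ndarray:
    """Column j of X scaled by diag_j (the identity-masked one-to-one layer)."""
    X, diag = np.asarray(X, float), np.asarray(diag, float)
    if diag.ndim != 1 or X.shape[1] != diag.shape[0]:
        raise ValueError(f"diagonal length {diag.shape} != input width {X.shape[1]}")
    return X * diag


# ---------------------------------------------------------------------------
# Reverse-mode graph
# ---------------------------------------------------------------------------

class Param:
    __slots__ = ("value", "grad", "name", "decay", "mask")

    def __init__(self, value: np.ndarray, name: str, decay: bool = False,
                 mask: Optional[np.ndarray] = None):
        self.value = np.asarray(value, float)
        self.grad = np.zeros_like(self.value)
        self.name = name
        self.decay = decay
        self.mask = mask


class Node:
    __slots__ = ("value", "op", "parents", "params", "cache", "grad", "idx")

    def __init__(self, value, op, parents=(), params=(), cache=None, idx=0):
        self.value = value
        self.op = op
        self.parents = list(parents)
        self.params = list(params)
        self.cache = cache or {}
        self.grad = None
        self.idx = idx

    @property
    def shape(self):
        return self.value.shape


class Graph:
    """One recorded forward pass. Node creation order is topological."""

    def __init__(self):
        self.nodes: list[Node] = []
        self.inputs: dict[str, Node] = {}

    def _add(self, value, op, parents=(), params=(), cache=None) -> Node:
        node = Node(value, op, parents, params, cache, idx=len(self.nodes))
        self.nodes.append(node)
        return node

    def input(self, name: str, value: np.ndarray) -> Node:
        node = self._add(np.asarray(value, float), "input")
        self.inputs[name] = node
        return node

    def matmul(self, x: Node, w: Param) -> Node:
        weff = w.value if w.mask is None else w.mask * w.value
        return self._add(x.value @ weff, "matmul", [x], [w], {"weff": weff})

    def diag(self, x: Node, w: Param) -> Node:
        return self._add(x.value * w.value, "diag", [x], [w])

    def bias(self, x: Node, b: Param) -> Node:
        return self._add(x.value + b.value, "bias", [x], [b])

    def add(self, a: Node, b: Node) -> Node:
        return self._add(a.value + b.value, "add", [a, b])

    def mul(self, a: Node, b: Node) -> Node:
        return self._add(a.value * b.value, "mul", [a, b])

    def recip_clamped(self, x: Node, eps: float) -> Node:
        clamped = np.maximum(x.value, eps)
        node = self._add(1.0 / clamped, "recip", [x], cache={"eps": eps})
        node.cache["n_clamped"] = int((x.value < eps).sum())
        return node

    def act(self, x: Node, kind: str) -> Node:
        if kind == "identity":
            return x
        return self._add(_activate(x.value, kind), "act", [x], cache={"kind": kind})

    def concat(self, parts: list[Node]) -> Node:
        widths = [p.value.shape[1] for p in parts]
        return self._add(np.concatenate([p.value for p in parts], axis=1),
                         "concat", parts, cache={"widths": widths})

    def batchnorm(self, x: Node, gamma: Param, beta: Param, state: "BNState",
                  mode: str, momentum: float, eps: float) -> Node:
        if mode == "train":
            mu = x.value.mean(axis=0)
            var = x.value.var(axis=0)
            state.mean = momentum * state.mean + (1 - momentum) * mu
            state.var = momentum * state.var + (1 - momentum) * var
        elif mode == "calibrate":
            # refresh inference statistics on dropout-free activations to
            # avoid the dropout-induced variance shift at eval time
            mu = state.mean = x.value.mean(axis=0)
            var = state.var = x.value.var(axis=0)
        else:
            mu, var = state.mean, state.var
        invstd = 1.0 / np.sqrt(var + eps)
        xhat = (x.value - mu) * invstd
        return self._add(gamma.value * xhat + beta.value, "bn", [x],
                         [gamma, beta],
                         {"xhat": xhat, "invstd": invstd, "mode": mode})

    def dropout(self, x: Node, rate: float, rng: np.random.Generator) -> Node:
        keep = 1.0 - rate
        mask = (rng.random(x.value.shape) < keep).astype(float) / keep
        return self._add(x.value * mask, "dropout", [x], cache={"mask": mask})


def backward(graph: Graph, out: Node, seed_grad: np.ndarray) -> None:
    """Accumulate dL/dparam into ``Param.grad`` and dL/dinput into node
    ``.grad`` for the whole recorded graph."""
    for node in graph.nodes:
        node.grad = None
    out.grad = np.asarray(seed_grad, float)
    for node in reversed(graph.nodes):
        g = node.grad
        if g is None:
            continue

        def send(parent: Node, grad: np.ndarray) -> None:
            parent.grad = grad if parent.grad is None else parent.grad + grad

        op = node.op
        if op == "input":
            continue
        elif op == "matmul":
            (x,), (w,) = node.parents, node.params
            send(x, g @ node.cache["weff"].T)
            gw = x.value.T @ g
            w.grad += gw if w.mask is None else w.mask * gw
        elif op == "diag":
            (x,), (w,) = node.parents, node.params
            send(x, g * w.value)
            w.grad += (g * x.value).sum(axis=0)
        elif op == "bias":
            (x,), (b,) = node.parents, node.params
            send(x, g)
            b.grad += g.sum(axis=0)
        elif op == "add":
            send(node.parents[0], g)
            send(node.parents[1], g)
        elif op == "mul":
            a, b = node.parents
            send(a, g * b.value)
            send(b, g * a.value)
        elif op == "recip":
            (x,) = node.parents
            active = x.value >= node.cache["eps"]
            send(x, np.where(active, -g * node.value * node.value, 0.0))
        elif op == "act":
            (x,) = node.parents
            kind = node.cache["kind"]
            if kind == "relu":
                d = (x.value > 0).astype(float)
            elif kind == "tanh":
                d = 1.0 - node.value ** 2
            else:  # sigmoid
                d = node.value * (1.0 - node.value)
            send(x, g * d)
        elif op == "concat":
            start = 0
            for parent, w in zip(node.parents, node.cache["widths"]):
                send(parent, g[:, start:start + w])
                start += w
        elif op == "bn":
            (x,), (gamma, beta) = node.parents, node.params
            xhat, invstd = node.cache["xhat"], node.cache["invstd"]
            gamma.grad += (g * xhat).sum(axis=0)
            beta.grad += g.sum(axis=0)
            dxhat = g * gamma.value
            if node.cache["mode"] == "train":
                n = x.value.shape[0]
                send(x, invstd / n * (n * dxhat - dxhat.sum(axis=0)
                                      - xhat * (dxhat * xhat).sum(axis=0)))
            else:
                send(x, dxhat * invstd)
        elif op == "dropout":
            send(node.parents[0], g * node.cache["mask"])
        else:  # pragma: no cover
            raise RuntimeError(f"unknown op {op}")


class BNState:
    __slots__ = ("mean", "var")

    def __init__(self, width: int):
        self.mean = np.zeros(width)
        self.var = np.ones(width)


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

class HinnModel:
    """Parameters and wiring for one architecture variant.

    Parameters are created lazily, in a fixed order, on the first forward
    pass; the construction seed therefore fully determines initialization.
    """

    def __init__(self, masks: MaskSet, arch: ArchitectureConfig, n_demo: int,
                 seed: int = 0):
        if arch.variant not in VARIANTS:
            raise ValueError(f"unknown variant {arch.variant!r}")
        self.arch = arch
        self.n_demo = n_demo
        self.variant = arch.variant
        if arch.variant == "fully_connected":
            masks = ablate_full(masks)
        elif arch.variant == "randomized":
            masks = ablate_randomized(masks, seed + 777)
        self.masks = masks
        self.params: dict[str, Param] = {}
        self.bn_states: dict[str, BNState] = {}
        self._init_rng = np.random.default_rng(seed)
        self.y_mean, self.y_std = 0.0, 1.0
        self.y_range: Optional[tuple[float, float]] = None
        self.clamp_events = 0
        # mask for the single sparse PGNN layer, built on demand
        if arch.variant == "pgnn":
            m1, m2, m3 = masks.masks
            snp_term = ((m1 @ m2 @ m3) > 0).astype(float)
            cpg_term = ((m2 @ m3) > 0).astype(float)
            self.pgnn_mask = np.vstack([snp_term, cpg_term, m3])
        else:
            self.pgnn_mask = None

    # -- parameter helpers ------------------------------------------------

    def _param(self, name: str, shape: tuple, init: str = "he",
               decay: bool = False, mask: Optional[np.ndarray] = None) -> Param:
        if name not in self.params:
            if init == "he":
                if mask is not None:
                    # masked layers start as a nonnegative pass-through so the
                    # structured path carries signal from the first epoch;
                    # variance scaling uses per-unit fan-in under the mask
                    fan_in = np.maximum(mask.sum(axis=0), 1.0)
                    value = np.abs(self._init_rng.normal(size=shape)) * np.sqrt(2.0 / fan_in)
                else:
                    value = self._init_rng.normal(size=shape) * np.sqrt(2.0 / shape[0])
            elif init == "ones":
                value = np.ones(shape)
            elif init == "zeros":
                value = np.zeros(shape)
            else:  # pragma: no cover
                raise ValueError(init)
            self.params[name] = Param(value, name, decay=decay, mask=mask)
        return self.params[name]

    def _bn_state(self, name: str, width: int) -> BNState:
        if name not in self.bn_states:
            self.bn_states[name] = BNState(width)
        return self.bn_states[name]

    def parameters(self) -> list[Param]:
        return list(self.params.values())

    def count_effective_params(self) -> int:
        total = 0
        for p in self.params.values():
            total += int(p.mask.sum()) if p.mask is not None else p.value.size
        return total

    # -- layer builders ---------------------------------------------------

    def _dense(self, g: Graph, x: Node, width: int, name: str,
               act: str = "relu") -> Node:
        w = self._param(f"{name}.W", (x.shape[1], width), decay=True)
        b = self._param(f"{name}.b", (width,), init="zeros")
        return g.act(g.bias(g.matmul(x, w), b), act)

    def _masked(self, g: Graph, x: Node, mask: np.ndarray, name: str,
                act: str) -> Node:
        w = self._param(f"{name}.W", mask.shape, mask=mask)
        # the division-stage denominator starts at 1 (neutral attenuation)
        b = self._param(f"{name}.b", (mask.shape[1],),
                        init="ones" if name == "m2" else "zeros")
        return g.act(g.bias(g.matmul(x, w), b), act)

    def _diag(self, g: Graph, x: Node, name: str) -> Node:
        w = self._param(f"{name}.w", (x.shape[1],), init="ones")
        return g.diag(x, w)

    def _bn(self, g: Graph, x: Node, name: str, mode: str) -> Node:
        gamma = self._param(f"{name}.gamma", (x.shape[1],), init="ones")
        beta = self._param(f"{name}.beta", (x.shape[1],), init="zeros")
        state = self._bn_state(name, x.shape[1])
        return g.batchnorm(x, gamma, beta, state, mode,
                           self.arch.bn_momentum, self.arch.bn_epsilon)

    def _drop(self, g: Graph, x: Node, mode: str, rng) -> Node:
        if mode == "train" and self.arch.dropout > 0:
            return g.dropout(x, self.arch.dropout, rng)
        return x

    def _head(self, g: Graph, h: Node, demo: Node, mode: str, rng) -> Node:
        a = self.arch
        for i in range(a.dense_head_blocks):
            h = self._bn(g, h, f"head{i}.bn", mode)
            h = self._dense(g, h, a.dense_head_width, f"head{i}.dense")
            h = self._drop(g, h, mode, rng)
        h = self._dense(g, h, a.bottleneck_width, "bottleneck")
        h = g.concat([h, demo])
        h = self._bn(g, h, "merge.bn", mode)
        h = self._dense(g, h, a.dense_head_width, "merge.dense")
        h = self._drop(g, h, mode, rng)
        return self._dense(g, h, 1, "out", act="identity")

    # -- forward ----------------------------------------------------------

    def forward(self, X: dict[str, np.ndarray], mode: str = "eval",
                rng: Optional[np.random.Generator] = None) -> tuple[Graph, Node]:
        """Record one forward pass. ``X`` holds 'snp', 'cpg', 'expr', 'demo'
        matrices over the mask orderings; variants ignore dropped inputs."""
        if mode not in ("train", "eval", "calibrate"):
            raise ValueError(mode)
        if mode == "train" and rng is None:
            raise ValueError("train mode needs an rng for dropout")
        a, (m1, m2, m3) = self.arch, self.masks.masks
        act = a.omics_activation
        bw = a.bypass_width
        g = Graph()
        demo = g.input("demo", X["demo"])
        v = self.variant

        if v == "pgnn":
            xs = [g.input(k, X[k]) for k in ("snp", "cpg", "expr")]
            h = self._masked(g, g.concat(xs), self.pgnn_mask, "pgnn", act)
            return g, self._head(g, h, demo, mode, rng)

        if v == "hierarchy_only":
            x_snp = g.input("snp", X["snp"])
            x_cpg = g.input("cpg", X["cpg"])
            x_expr = g.input("expr", X["expr"])
            z1 = self._dense(g, x_snp, m1.shape[1], "h1", act)
            z2 = self._dense(g, g.concat([x_cpg, z1]), m2.shape[1], "h2", act)
            z3 = self._dense(g, g.concat([x_expr, z2]), m3.shape[1], "h3", act)
            b1 = self._dense(g, x_snp, bw, "bypass1", act)
            b2 = self._dense(g, g.concat([b1, z2]), bw, "bypass2", act)
            b3 = self._dense(g, g.concat([b2, z3]), bw, "bypass3", act)
            return g, self._head(g, g.concat([z3, b3]), demo, mode, rng)

        # hierarchical family (hinn / fully_connected / randomized / drop_* / no_go)
        y2 = None
        if v == "drop_snp":
            x_cpg = g.input("cpg", X["cpg"])
            y2 = g.act(g.bias(self._diag(g, x_cpg, "s2"), self._param(
                "y2.b", (m2.shape[0],), init="zeros")), act)
            bypass = self._dense(g, x_cpg, bw, "bypass1", act)
        elif v == "drop_cpg":
            x_snp = g.input("snp", X["snp"])
            y2 = self._masked(g, x_snp, m1, "m1", act)   # Y1 stands in for Y2
            bypass = self._dense(g, x_snp, bw, "bypass1", act)
        else:
            x_snp = g.input("snp", X["snp"])
            x_cpg = g.input("cpg", X["cpg"])
            y1 = self._masked(g, x_snp, m1, "m1", act)
            y2 = g.act(g.bias(g.mul(self._diag(g, x_cpg, "s2"), y1),
                              self._param("y2.b", (m1.shape[1],), init="zeros")), act)
            b1 = self._dense(g, x_snp, bw, "bypass1", act)
            bypass = self._dense(g, g.concat([b1, y2]), bw, "bypass2", act)

        if v == "drop_expr":
            m23 = ((m2 @ m3) > 0).astype(float)
            y4 = self._masked(g, y2, m23, "m23", act)
            return g, self._head(g, g.concat([y4, bypass]), demo, mode, rng)

        x_expr = g.input("expr", X["expr"])
        denom = self._masked(g, y2, m2, "m2", act)
        inv = g.recip_clamped(denom, a.denominator_epsilon)
        self.clamp_events += inv.cache["n_clamped"]
        y3 = g.act(g.bias(g.mul(self._diag(g, x_expr, "s3"), inv),
                          self._param("y3.b", (m2.shape[1],), init="zeros")), act)
        bypass = self._dense(g, g.concat([bypass, y3]), bw, "bypass3", act)

        if v == "no_go":
            return g, self._head(g, g.concat([y3, bypass]), demo, mode, rng)
        y4 = self._masked(g, y3, m3, "m3", act)
        return g, self._head(g, g.concat([y4, bypass]), demo, mode, rng)

    def predict(self, X: dict[str, np.ndarray]) -> np.ndarray:
        """Raw-scale predictions, clipped to the training target range when
        one was recorded (cognitive scores are bounded by definition; the
        clip also bounds the influence of rare division-stage outliers)."""
        _, out = self.forward(X, mode="eval")
        pred = out.value[:, 0] * self.y_std + self.y_mean
        if self.y_range is not None:
            pred = np.clip(pred, *self.y_range)
        return pred

    # -- (de)serialization -------------------------------------------------

    def state_dict(self) -> dict:
        return {
            "params": {k: p.value.copy() for k, p in self.params.items()},
            "bn": {k: (s.mean.copy(), s.var.copy()) for k, s in self.bn_states.items()},
            "y_scale": (self.y_mean, self.y_std),
            "y_range": self.y_range,
        }

    def load_state_dict(self, state: dict) -> None:
        for k, v in state["params"].items():
            self.params[k].value = v.copy()
        for k, (m, s) in state["bn"].items():
            self.bn_states[k].mean, self.bn_states[k].var = m.copy(), s.copy()
        self.y_mean, self.y_std = state["y_scale"]
        self.y_range = state.get("y_range")

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        arrays = {f"param::{k}": p.value for k, p in self.params.items()}
        for k, s in self.bn_states.items():
            arrays[f"bnmean::{k}"] = s.mean
            arrays[f"bnvar::{k}"] = s.var
        np.savez(prefix.with_suffix(".npz"), **arrays)
        meta = {"arch": self.arch.model_dump(mode="json"), "n_demo": self.n_demo,
                "y_mean": self.y_mean, "y_std": self.y_std,
                "y_range": self.y_range,
                "mask_orderings": {"snp_ids": self.masks.snp_ids,
                                   "cpg_ids": self.masks.cpg_ids,
                                   "probe_ids": self.masks.probe_ids,
                                   "term_ids": self.masks.term_ids}}
        with open(prefix.with_suffix(".json"), "w") as fh:
            json.dump(meta, fh, indent=2)
        self.masks.save(prefix.parent / (prefix.name + "_masks"))

    @classmethod
    def load(cls, prefix: str | Path) -> "HinnModel":
        prefix = Path(prefix)
        with open(prefix.with_suffix(".json")) as fh:
            meta = json.load(fh)
        masks = MaskSet.load(prefix.parent / (prefix.name + "_masks"))
        arch = ArchitectureConfig.model_validate(meta["arch"])
        # reconstruct with the raw (biological) masks disabled transforms:
        model = cls.__new__(cls)
        model.arch = arch
        model.n_demo = meta["n_demo"]
        model.variant = arch.variant
        model.masks = masks
        model.params = {}
        model.bn_states = {}
        model._init_rng = np.random.default_rng(0)
        model.y_mean, model.y_std = meta["y_mean"], meta["y_std"]
        model.y_range = tuple(meta["y_range"]) if meta.get("y_range") else None
        model.clamp_events = 0
        if arch.variant == "pgnn":
            m1, m2, m3 = masks.masks
            model.pgnn_mask = np.vstack([((m1 @ m2 @ m3) > 0).astype(float),
                                         ((m2 @ m3) > 0).astype(float), m3])
        else:
            model.pgnn_mask = None
        arrays = np.load(prefix.with_suffix(".npz"))
        # build params by a dry forward on zeros, then overwrite values
        widths = {"snp": len(masks.snp_ids), "cpg": len(masks.cpg_ids),
                  "expr": len(masks.probe_ids), "demo": meta["n_demo"]}
        X0 = {k: np.zeros((2, w)) for k, w in widths.items()}
        model.forward(X0, mode="eval")
        for key in arrays.files:
            kind, name = key.split("::", 1)
            if kind == "param":
                model.params[name].value = arrays[key]
            elif kind == "bnmean":
                model.bn_states[name].mean = arrays[key]
            else:
                model.bn_states[name].var = arrays[key]
        return model


def build_variant(arch: ArchitectureConfig, masks: MaskSet, n_demo: int,
                  seed: int = 0) -> HinnModel:
    """Instantiate a model under the variant semantics named in ``arch``."""
    if masks.variant != "biological" and arch.variant in ("fully_connected",
                                                          "randomized"):
        raise ValueError("variant transforms expect biological masks")
    return HinnModel(masks, arch, n_demo, seed=seed)


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------

def prepare_model_inputs(cohort, masks: MaskSet,
                         arch: ArchitectureConfig) -> dict[str, np.ndarray]:
    """Assemble the network's input matrices over the mask orderings:
    mean-imputed genotype dosages, beta values, min-max-normalized
    expression, and standardized demographic covariates (categorical ones
    left as small integer codes)."""
    geno = cohort.genotype.subset(feature_ids=masks.snp_ids)
    G = geno.values.copy()
    obs = geno.observed_mask()
    with np.errstate(invalid="ignore"):
        col_mean = np.where(obs, G, np.nan)
        col_mean = np.nanmean(col_mean, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    G = np.where(obs, G, col_mean)

    meth = cohort.methylation.subset(feature_ids=masks.cpg_ids).values
    expr = min_max_normalize(cohort.expression.subset(feature_ids=masks.probe_ids)).values

    cols, names = [], []
    for feat in arch.demographic_features:
        if feat not in cohort.covariates.columns:
            logger.info("demographic feature %r absent from cohort; skipped", feat)
            continue
        x = cohort.covariates[feat].to_numpy(dtype=float)
        if feat in ("age", "education"):
            x = (x - x.mean()) / (x.std() or 1.0)
        elif feat == "ptau181":
            x = np.log1p(x)
            x = (x - x.mean()) / (x.std() or 1.0)
        cols.append(x)
        names.append(feat)
    demo = np.column_stack(cols) if cols else np.zeros((G.shape[0], 0))
    return {"snp": G, "cpg": meth, "expr": expr, "demo": demo,
            "demo_names": names}


# ---------------------------------------------------------------------------
# Training protocol
# ---------------------------------------------------------------------------

@dataclass
class EvalMetrics:
    variant: str
    phenotype: str
    mae_per_repeat: list[float] = field(default_factory=list)
    mse_per_repeat: list[float] = field(default_factory=list)

    @property
    def mae_mean(self) -> float:
        return float(np.mean(self.mae_per_repeat))

    @property
    def mae_sd(self) -> float:
        return float(np.std(self.mae_per_repeat, ddof=0))

    @property
    def mse_mean(self) -> float:
        return float(np.mean(self.mse_per_repeat))

    @property
    def mse_sd(self) -> float:
        return float(np.std(self.mse_per_repeat, ddof=0))

    def to_dict(self) -> dict:
        return {"variant": self.variant, "phenotype": self.phenotype,
                "mae_per_repeat": self.mae_per_repeat,
                "mse_per_repeat": self.mse_per_repeat,
                "mae": {"mean": self.mae_mean, "sd": self.mae_sd},
                "mse": {"mean": self.mse_mean, "sd": self.mse_sd}}


def split_indices(n: int, tc: TrainConfig, repeat: int
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded 70/30 train/test split, then 20% of training as validation.
    Each repeat re-randomizes both the split and the initialization."""
    rng = np.random.default_rng((tc.seed * 100003 + repeat) % (2 ** 31))
    perm = rng.permutation(n)
    n_test = int(round(tc.test_fraction * n))
    test = perm[:n_test]
    rest = perm[n_test:]
    n_val = int(round(tc.validation_fraction * rest.size))
    return rest[n_val:], rest[:n_val], test


class Adam:
    def __init__(self, params: list[Param], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1; m += (1 - b1) * p.grad
            v *= b2; v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _subset(X: dict, idx: np.ndarray) -> dict:
    return {k: (v[idx] if isinstance(v, np.ndarray) else v) for k, v in X.items()}


def _train_one(model: HinnModel, X: dict, y: np.ndarray, tc: TrainConfig,
               idx_train: np.ndarray, idx_val: np.ndarray,
               rng: np.random.Generator) -> None:
    y_train = y[idx_train]
    model.y_mean = float(y_train.mean())
    model.y_std = float(y_train.std() or 1.0)
    model.y_range = (float(y_train.min()), float(y_train.max()))
    yz = (y - model.y_mean) / model.y_std

    Xtr, Xval = _subset(X, idx_train), _subset(X, idx_val)
    model.forward(_subset(Xtr, np.arange(min(2, idx_train.size))), mode="eval")
    opt = Adam(model.parameters(), tc.learning_rate)
    best_val, best_state, patience = np.inf, None, 0
    n = idx_train.size
    for epoch in range(tc.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, tc.batch_size):
            batch = order[start:start + tc.batch_size]
            if batch.size < 2:
                continue  # batch-norm needs >= 2 samples
            Xb = _subset(Xtr, batch)
            g, out = model.forward(Xb, mode="train", rng=rng)
            resid = out.value[:, 0] - yz[idx_train][batch]
            loss = float(np.mean(resid ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(variant {model.variant})")
            for p in model.parameters():
                p.grad[...] = 0.0
            backward(g, out, (2.0 * resid / resid.size)[:, None])
            for p in model.parameters():
                if p.decay and model.arch.l2_strength > 0:
                    p.grad += 2.0 * model.arch.l2_strength * p.value
            total = np.sqrt(sum(float((p.grad ** 2).sum())
                                for p in model.parameters()))
            if total > tc.grad_clip:
                scale = tc.grad_clip / total
                for p in model.parameters():
                    p.grad *= scale
            opt.step()
        model.forward(Xtr, mode="calibrate")
        val_pred = model.predict(Xval)
        val_mse = float(np.mean((val_pred - y[idx_val]) ** 2))
        if val_mse < best_val - 1e-9:
            best_val, best_state, patience = val_mse, model.state_dict(), 0
        else:
            patience += 1
            if patience >= tc.patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)


def train_model(model_factory: Callable[[int], HinnModel], X: dict,
                y: np.ndarray, tc: TrainConfig, variant: str = "hinn",
                phenotype: str = "score"
                ) -> tuple[list[HinnModel], EvalMetrics]:
    """Repeat-seeded training: per repeat, split, fit with early stopping on
    validation MSE, restore best parameters, report test MAE/MSE; aggregate
    mean +- sd over repeats."""
    y = np.asarray(y, float)
    metrics = EvalMetrics(variant, phenotype)
    models: list[HinnModel] = []
    failures: list[str] = []
    for r in range(tc.n_repeats):
        idx_train, idx_val, idx_test = split_indices(y.size, tc, r)
        rng = np.random.default_rng((tc.seed * 7919 + r + 1) % (2 ** 31))
        model = model_factory((tc.seed * 104729 + r) % (2 ** 31))
        try:
            _train_one(model, X, y, tc, idx_train, idx_val, rng)
        except FloatingPointError as exc:
            logger.warning("repeat %d aborted: %s", r, exc)
            failures.append(str(exc))
            continue
        pred = model.predict(_subset(X, idx_test))
        metrics.mae_per_repeat.append(float(np.mean(np.abs(pred - y[idx_test]))))
        metrics.mse_per_repeat.append(float(np.mean((pred - y[idx_test]) ** 2)))
        models.append(model)
    if not models:
        raise RuntimeError(f"all repeats failed: {failures}")
    logger.info("%s/%s: MAE %.3f +- %.3f, MSE %.3f +- %.3f", variant, phenotype,
                metrics.mae_mean, metrics.mae_sd, metrics.mse_mean, metrics.mse_sd)
    return models, metrics


# ---------------------------------------------------------------------------
# Classical baselines
# ---------------------------------------------------------------------------

BASELINE_GRIDS = {
    "L1": {"alpha": [0.001, 0.01, 0.1, 1.0]},
    "SVM": {"C": [0.1, 1.0, 10.0]},
    "RF": {"max_depth": [None, 10]},
    "NN": {"hidden_layer_sizes": [(64,), (128, 64)]},
}


def run_baselines(X: dict, y: np.ndarray, tc: TrainConfig,
                  methods: tuple[str, ...] = ("L1", "SVM", "RF", "NN"),
                  phenotype: str = "score") -> dict[str, EvalMetrics]:
    """Flat-feature baselines on the identical splits, each tuned by 10-fold
    CV over a small grid on the training data, evaluated on the test split,
    repeated ``tc.n_repeats`` times."""
    from sklearn.linear_model import Lasso
    from sklearn.svm import SVR
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.neural_network import MLPRegressor
    from sklearn.model_selection import GridSearchCV

    flat = np.hstack([X["snp"], X["cpg"], X["expr"], X["demo"]])
    y = np.asarray(y, float)
    out: dict[str, EvalMetrics] = {}
    for method in methods:
        grid = BASELINE_GRIDS[method]
        if not grid or not all(len(v) for v in grid.values()):
            raise ValueError(f"degenerate grid for {method}")
        metrics = EvalMetrics(method, phenotype)
        for r in range(tc.n_repeats):
            idx_train, idx_val, idx_test = split_indices(y.size, tc, r)
            train = np.concatenate([idx_train, idx_val])
            seed = (tc.seed * 31 + r) % (2 ** 31)
            if method == "L1":
                est = Lasso(max_iter=50_000, random_state=seed)
            elif method == "SVM":
                est = SVR()
            elif method == "RF":
                est = RandomForestRegressor(n_estimators=200, random_state=seed)
            else:
                est = MLPRegressor(max_iter=800, random_state=seed)
            search = GridSearchCV(est, grid, cv=10,
                                  scoring="neg_mean_squared_error", n_jobs=1)
            search.fit(flat[train], y[train])
            pred = search.predict(flat[idx_test])
            metrics.mae_per_repeat.append(float(np.mean(np.abs(pred - y[idx_test]))))
            metrics.mse_per_repeat.append(float(np.mean((pred - y[idx_test]) ** 2)))
        out[method] = metrics
    return out
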