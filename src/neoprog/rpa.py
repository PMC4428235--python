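"""Recursive-partitioning survival tree with log-rank splitting.

At each node every dichotomic candidate predictor is evaluated by the
two-sample log-rank test between the patients with and without the factor.
Among candidates significant at the node-level alpha (raw p by default; an
optional Bonferroni correction over the candidates is provided) whose two
children both meet the minimum child size, the split maximising the absolute
separation of 5-year survival between the children is chosen; ties go to the
larger log-rank statistic, then to the earlier declared candidate. Growth
stops at the node-size floor, the depth cap, or when no admissible split
remains. Each node records its Kaplan-Meier survival at 3 and 5 years with
Greenwood standard errors; where no follow-up reaches 60 months the last
available KM value is carried forward (flagged as extrapolated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import km_estimate, logrank_test

__all__ = ["RPANode", "grow_tree", "node_summaries"]


@dataclass
class RPANode:
    """One node of the survival tree (leaf iff ``split_variable`` is None)."""

    patient_index: np.ndarray          # row positions of the cohort at this node
    depth: int
    n: int
    s3y: float
    s3y_se: float
    s5y: float
    s5y_se: float
    s5y_extrapolated: bool
    split_variable: str | None = None
    logrank_chi: float | None = None
    p_value: float | None = None
    children: list = field(default_factory=list)  # [factor-absent, factor-present]

    @property
    def is_leaf(self) -> bool:
        return self.split_variable is None


def _km_at(times, events, horizon):
    km = km_estimate(times, events)
    s = float(km.at(horizon))
    se = float(km.se_at(horizon))
    max_obs = float(np.max(times)) if len(times) else 0.0
    return s, se, max_obs < horizon


def _make_node(idx, t, e, depth) -> RPANode:
    s3, se3, _ = _km_at(t[idx], e[idx], 36.0)
    s5, se5, extrap = _km_at(t[idx], e[idx], 60.0)
    return RPANode(idx, depth, len(idx), s3, se3, s5, se5, extrap)


def grow_tree(cohort, candidate_predictors=None, alpha: float = 0.05,
              min_node: int = 20, min_child: int = 7, max_depth: int = 4,
              bonferroni: bool = False) -> RPANode:
    """Grow the survival tree; returns the root :class:`RPANode`.

    ``candidate_predictors`` are names of binary design covariates (default:
    every binary covariate of the full design; continuous variables are not
    candidates). ``min_node`` is the smallest node still considered for
    splitting, ``min_child`` the smallest admissible child.
    """
    if len(cohort) == 0:
        raise ValueError("cannot grow a tree on an empty cohort")
    if min_node < 2 * min_child:
        raise ValueError("min_node must be at least twice the minimum child size")
    if candidate_predictors is None:
        candidate_predictors = _default_candidates(cohort)
    candidates = list(candidate_predictors)
    Xdf = cohort.design_matrix(candidates)
    X = Xdf.to_numpy(float)
    for j, name in enumerate(candidates):
        vals = np.unique(X[:, j])
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError(f"candidate '{name}' is not binary (0/1)")
    t, e = cohort.outcome("os")

    def split_node(node: RPANode) -> None:
        if node.n < min_node or node.depth >= max_depth:
            return
        idx = node.patient_index
        best = None  # (gap, chi, -order, name, mask1)
        for j, name in enumerate(candidates):
            mask1 = X[idx, j] == 1.0
            n1 = int(mask1.sum())
            n0 = len(idx) - n1
            if n1 < min_child or n0 < min_child:
                continue
            lr = logrank_test(t[idx], e[idx], mask1.astype(int))
            p = lr.p_value * len(candidates) if bonferroni else lr.p_value
            if p >= alpha:
                continue
            s5_1 = _km_at(t[idx[mask1]], e[idx[mask1]], 60.0)[0]
            s5_0 = _km_at(t[idx[~mask1]], e[idx[~mask1]], 60.0)[0]
            key = (abs(s5_1 - s5_0), lr.chi_square, -j)
            if best is None or key > best[0]:
                best = (key, name, mask1, lr, min(p, 1.0))
        if best is None:
            return
        _key, name, mask1, lr, p = best
        node.split_variable = name
        node.logrank_chi = lr.chi_square
        node.p_value = p
        child0 = _make_node(idx[~mask1], t, e, node.depth + 1)
        child1 = _make_node(idx[mask1], t, e, node.depth + 1)
        node.children = [child0, child1]
        split_node(child0)
        split_node(child1)

    root = _make_node(np.arange(len(cohort)), t, e, 0)
    split_node(root)
    return root


def _default_candidates(cohort) -> list:
    """All binary covariates of the full design (continuous ones excluded)."""
    Xdf = cohort.design_matrix("clinical_plus_path")
    out = []
    for name in Xdf.columns:
        col = Xdf[name].to_numpy(float)
        if np.all(np.isin(np.unique(col), (0.0, 1.0))):
            out.append(name)
    return out


def node_summaries(tree: RPANode) -> pd.DataFrame:
    """One row per node, pre-order: size, split, log-rank, S3y/S5y with SEs."""
    rows = []

    def walk(node: RPANode, label: str):
        rows.append({
            "node": label,
            "depth": node.depth,
            "n": node.n,
            "split_variable": node.split_variable,
            "logrank_chi": node.logrank_chi,
            "p_value": node.p_value,
            "s3y": node.s3y, "s3y_se": node.s3y_se,
            "s5y": node.s5y, "s5y_se": node.s5y_se,
            "s5y_extrapolated": node.s5y_extrapolated,
        })
        if not node.is_leaf:
            walk(node.children[0], f"{label}/{node.split_variable}=0")
            walk(node.children[1], f"{label}/{node.split_variable}=1")

    walk(tree, "root")
    return pd.DataFrame(rows)


def tree_to_dict(tree: RPANode) -> dict:
    """Nested plain-dict form of the tree (JSON-serialisable)."""
    d = {
        "n": tree.n, "depth": tree.depth,
        "s3y": tree.s3y, "s3y_se": tree.s3y_se,
        "s5y": tree.s5y, "s5y_se": tree.s5y_se,
        "s5y_extrapolated": tree.s5y_extrapolated,
        "split_variable": tree.split_variable,
        "logrank_chi": tree.logrank_chi,
        "p_value": tree.p_value,
    }
    if not tree.is_leaf:
        d["children"] = [tree_to_dict(c) for c in tree.children]
    return d
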