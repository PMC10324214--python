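"""Phylogenetic comparative statistics for continuous traits.

Ancestral states of a continuous trait (for example genome size in Gb, or
TE content as percent of the genome) are reconstructed under Brownian
motion by maximum likelihood.  Under BM the joint distribution of tip and
node states is multivariate normal with covariances given by shared
root-to-node path lengths; the ML estimate at an internal node is the
conditional expectation of that node's state given the tip values.  It is
computed here by re-rooting the tree at the node and taking the recursive
inverse-branch-length-weighted mean of the subtrees (two-pass pruning),
which is algebraically identical to the brute-force conditional mean but
linear-time per node.  The estimate at the root is the generalized
(GLS) mean of the tips.

The module also provides the ordinary-least-squares battery used to relate
genome size to its candidate correlates (plain OLS, not phylogenetically
corrected regression, is deliberate: the correlate tables these fits target
were produced by simple linear regression), and habitat niche-width
profiles (niche width = number of distinct habitat types recorded for a
species).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AncestralStates",
    "RegressionResult",
    "HabitatProfile",
    "anc_states_ml",
    "ols_fit",
    "niche_width",
    "correlate_panel",
]


@dataclass(frozen=True)
class AncestralStates:
    """Per-internal-node ML estimates and variances under Brownian motion."""

    estimates: dict[str, float]
    variances: dict[str, float]
    sigma2_hat: float
    root_label: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": list(self.estimates),
                "estimate": list(self.estimates.values()),
                "variance": [self.variances[k] for k in self.estimates],
            }
        )


def _label_internal_nodes(tree: dendropy.Tree) -> None:
    """Assign labels node1, node2, ... to unlabeled internal nodes
    (preorder, root first)."""
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        i += 1
        if not node.label:
            node.label = f"node{i}"


def _adjacency(
    tree: dendropy.Tree,
) -> tuple[dict[int, list[tuple[int, float]]], dict[int, str], list[int], list[int]]:
    """Undirected weighted adjacency over dendropy nodes (ids)."""
    adj: dict[int, list[tuple[int, float]]] = {}
    names: dict[int, str] = {}
    tips: list[int] = []
    internals: list[int] = []
    for node in tree.preorder_node_iter():
        nid = id(node)
        adj.setdefault(nid, [])
        if node.is_leaf():
            names[nid] = node.taxon.label if node.taxon else (node.label or "")
            tips.append(nid)
        else:
            names[nid] = node.label or ""
            internals.append(nid)
        for child in node.child_nodes():
            bl = child.edge.length
            if bl is None:
                raise ValueError(f"missing branch length above {names.get(id(child), 'a node')}")
            if bl <= 0:
                raise ValueError(
                    "zero-length branch encountered; collapse it into a "
                    "polytomy before reconstruction"
                )
            adj[nid].append((id(child), float(bl)))
            adj.setdefault(id(child), []).append((nid, float(bl)))
    return adj, names, tips, internals


def anc_states_ml(
    tree: dendropy.Tree,
    traits: Mapping[str, float],
) -> AncestralStates:
    """ML ancestral states of a continuous trait under Brownian motion.

    Every tip must have a trait value; polytomies are handled natively by
    the pruning recursion.  For each internal node the estimate is the
    re-rooted weighted mean of the tips, and the variance is
    ``sigma2_hat`` times the conditional-variance branch-length factor at
    the re-rooted node, with ``sigma2_hat`` the ML Brownian rate.
    """
    tree = tree.clone(depth=1)
    _label_internal_nodes(tree)
    adj, names, tips, internals = _adjacency(tree)
    tip_values: dict[int, float] = {}
    for nid in tips:
        label = names[nid]
        if label not in traits:
            raise ValueError(f"tip {label!r} has no trait value")
        tip_values[nid] = float(traits[label])

    def message(src: int, dst: int, edge_len: float) -> tuple[float, float]:
        """(mean, variance-length) of the subtree behind src, seen from dst."""
        if src in tip_values:
            return tip_values[src], edge_len
        num = den = 0.0
        for nbr, bl in adj[src]:
            if nbr == dst:
                continue
            m, v = message(nbr, src, bl)
            num += m / v
            den += 1.0 / v
        return num / den, 1.0 / den + edge_len

    estimates: dict[str, float] = {}
    cond_factors: dict[str, float] = {}
    for nid in internals:
        num = den = 0.0
        for nbr, bl in adj[nid]:
            m, v = message(nbr, nid, bl)
            num += m / v
            den += 1.0 / v
        estimates[names[nid]] = num / den
        cond_factors[names[nid]] = 1.0 / den

    sigma2 = _ml_rate(tree, tip_values)
    variances = {k: sigma2 * f for k, f in cond_factors.items()}
    root_label = names[id(tree.seed_node)]
    return AncestralStates(
        estimates=estimates,
        variances=variances,
        sigma2_hat=sigma2,
        root_label=root_label,
    )


def _ml_rate(tree: dendropy.Tree, tip_values: dict[int, float]) -> float:
    """ML Brownian rate via Felsenstein pruning.

    Accumulates the quadratic form (x - a_hat)' C^{-1} (x - a_hat) while
    pruning tips toward the root; sigma2_hat = Q / n.
    """
    n = len(tip_values)
    quad = 0.0

    def prune(node: dendropy.Node, stem: float) -> tuple[float, float]:
        nonlocal quad
        if node.is_leaf():
            return tip_values[id(node)], stem
        msgs = [
            prune(child, float(child.edge.length))
            for child in node.child_nodes()
        ]
        den = sum(1.0 / v for _, v in msgs)
        xhat = sum(m / v for m, v in msgs) / den
        quad += sum((m - xhat) ** 2 / v for m, v in msgs)
        return xhat, 1.0 / den + stem

    prune(tree.seed_node, 0.0)
    return quad / n


@dataclass(frozen=True)
class RegressionResult:
    n: int
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    residual_se: float


def ols_fit(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Simple least-squares fit of y on x with R^2 and the slope test.

    The two-sided p-value for slope = 0 from the t statistic coincides
    with the F-test p-value in simple regression.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y differ in length")
    n = len(x)
    if n < 3:
        raise ValueError("regression requires n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    p = float(res.pvalue) if ss_tot > 0 else 1.0
    return RegressionResult(
        n=n,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        p_value=p,
        residual_se=float(np.sqrt(ss_res / (n - 2))),
    )


@dataclass(frozen=True)
class HabitatProfile:
    species: str
    habitat_types: frozenset[str]

    @property
    def niche_width(self) -> int:
        return len(self.habitat_types)


def niche_width(
    habitat_table: pd.DataFrame,
    expected_species: Sequence[str] | None = None,
) -> tuple[list[HabitatProfile], list[str]]:
    """Niche width (count of distinct habitat types) per species.

    Duplicate (species, habitat) rows are deduplicated.  Species listed in
    ``expected_species`` but absent from the table carry no habitat
    information; they are excluded and returned in the second element.
    """
    grouped = habitat_table.groupby("species")["habitat_type"].agg(set)
    profiles = [
        HabitatProfile(species=sp, habitat_types=frozenset(habs))
        for sp, habs in grouped.items()
    ]
    excluded: list[str] = []
    if expected_species is not None:
        present = set(grouped.index)
        excluded = sorted(set(expected_species) - present)
    return profiles, excluded


def correlate_panel(
    trait_table: pd.DataFrame,
    size_column: str = "genome_size",
) -> pd.DataFrame:
    """OLS of every metric column against genome size.

    ``trait_table`` is keyed by species and must contain ``size_column``;
    every other numeric column is regressed on it.  Metrics with fewer
    than 3 non-missing species are skipped with a warning.
    """
    if size_column not in trait_table.columns:
        raise ValueError(f"missing {size_column!r} column")
    rows = []
    for col in trait_table.columns:
        if col == size_column or not pd.api.types.is_numeric_dtype(trait_table[col]):
            continue
        sub = trait_table[[size_column, col]].dropna()
        if len(sub) < 3:
            warnings.warn(f"metric {col!r}: fewer than 3 species, skipped")
            continue
        fit = ols_fit(sub[size_column].to_numpy(), sub[col].to_numpy())
        rows.append(
            {
                "metric": col,
                "n": fit.n,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "p_value": fit.p_value,
            }
        )
    return pd.DataFrame(
        rows, columns=["metric", "n", "slope", "intercept", "r_squared", "p_value"]
    )
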