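"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a different mechanism than the
implementation under test: exhaustive recursion for alignment scores,
regex enumeration over all primitive motifs for tandem runs, and explicit
multivariate-normal conditioning from path-length covariance matrices for
Brownian-motion ancestral states.
"""

from __future__ import annotations

import itertools
import re
from functools import lru_cache

import numpy as np


# ---------------------------------------------------------------------------
# Global alignment score by exhaustive recursion


def brute_alignment_score(a: str, b: str, match=1, mismatch=-1, gap=-2) -> int:
    @lru_cache(maxsize=None)
    def f(i: int, j: int) -> int:
        if i == 0:
            return gap * j
        if j == 0:
            return gap * i
        s = match if a[i - 1] == b[j - 1] else mismatch
        return max(f(i - 1, j - 1) + s, f(i - 1, j) + gap, f(i, j - 1) + gap)

    return f(len(a), len(b))


def score_alignment(aln_a: str, aln_b: str, match=1, mismatch=-1, gap=-2) -> int:
    total = 0
    for x, y in zip(aln_a, aln_b):
        if x == "-" or y == "-":
            total += gap
        elif x == y:
            total += match
        else:
            total += mismatch
    return total


# ---------------------------------------------------------------------------
# Perfect-SSR enumeration over all primitive motifs, via regex


def _is_primitive(motif: str) -> bool:
    return motif not in (motif + motif)[1:-1]


_PRIMITIVE_MOTIFS: list[str] = [
    "".join(m)
    for size in range(1, 7)
    for m in itertools.product("ACGT", repeat=size)
    if _is_primitive("".join(m))
]


def regex_ssr_oracle(seq: str, min_repeats: dict[int, int]) -> list[tuple[int, int, str]]:
    """All maximal tandem runs passing the thresholds, as the scanner
    reports them: primitive motif, N-free, non-overlapping leftmost-first.

    Runs are located by regex over every primitive motif of length 1-6,
    then extended by single-base comparison to maximal (including a
    trailing partial unit).  Returns (start, end, motif) 1-based tuples.
    """
    n = len(seq)
    raw: set[tuple[int, int]] = set()
    for motif in _PRIMITIVE_MOTIFS:
        if motif + motif not in seq:
            continue
        m = len(motif)
        for match in re.finditer(f"(?:{motif}){{2,}}", seq):
            start, end = match.start(), match.end()  # 0-based half-open
            while start > 0 and seq[start - 1] == seq[start - 1 + m] and seq[start - 1] != "N":
                start -= 1
            while end < n and seq[end] == seq[end - m] and seq[end] != "N":
                end += 1
            raw.add((start, end))
    candidates = []
    for start, end in raw:
        # determine the period: smallest m such that the run is period-m
        span = end - start
        for m in range(1, 7):
            if span >= 2 * m and all(
                seq[i] == seq[i + m] for i in range(start, end - m)
            ):
                break
        else:
            continue
        motif = seq[start : start + m]
        if "N" in seq[start:end] or not _is_primitive(motif):
            continue
        repeats = span / m
        if repeats < min_repeats.get(m, 10**9):
            continue
        candidates.append((start + 1, start + span, motif))
    candidates.sort(key=lambda c: (c[0], len(c[2])))
    selected: list[tuple[int, int, str]] = []
    last_end = 0
    for start, end, motif in candidates:
        if start > last_end:
            selected.append((start, end, motif))
            last_end = end
    return selected


# ---------------------------------------------------------------------------
# Brownian-motion conditional means from explicit covariance matrices


def mvn_ancestral_oracle(tree, traits: dict[str, float]):
    """Conditional mean and variance of each internal node given the tips.

    Builds the full tip covariance matrix from shared root-to-node path
    lengths, takes the GLS root estimate, and applies the multivariate
    normal conditional mean/variance.  Returns (estimates, variance
    factors, sigma2_hat) keyed by internal node label.
    """
    depth: dict[int, float] = {}
    nodes = list(tree.preorder_node_iter())
    for nd in nodes:
        if nd.parent_node is None:
            depth[id(nd)] = 0.0
        else:
            depth[id(nd)] = depth[id(nd.parent_node)] + float(nd.edge.length)

    def mrca_depth(a, b) -> float:
        ancestors = set()
        x = a
        while x is not None:
            ancestors.add(id(x))
            x = x.parent_node
        x = b
        while id(x) not in ancestors:
            x = x.parent_node
        return depth[id(x)]

    tips = [leaf for leaf in tree.leaf_node_iter()]
    internals = [nd for nd in nodes if not nd.is_leaf()]
    n = len(tips)
    C = np.array([[mrca_depth(a, b) for b in tips] for a in tips])
    x = np.array([traits[t.taxon.label] for t in tips])
    Ci = np.linalg.inv(C)
    one = np.ones(n)
    ahat = float(one @ Ci @ x) / float(one @ Ci @ one)
    sigma2 = float((x - ahat) @ Ci @ (x - ahat)) / n
    estimates: dict[str, float] = {}
    var_factors: dict[str, float] = {}
    for nd in internals:
        c = np.array([mrca_depth(nd, t) for t in tips])
        estimates[nd.label] = ahat + float(c @ Ci @ (x - ahat))
        var_factors[nd.label] = (
            depth[id(nd)]
            - float(c @ Ci @ c)
            + (1.0 - float(one @ Ci @ c)) ** 2 / float(one @ Ci @ one)
        )
    return estimates, var_factors, sigma2
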