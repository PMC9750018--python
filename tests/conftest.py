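"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's prior/posterior code paths:
clade membership is recomputed by walking the tree structure, transition
matrices come from scipy's matrix exponential, and numerators are direct
floating-point products over enumerated placements.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.linalg import expm

from mutorder.error_model import AMBIGUOUS, MISSING
from mutorder.phylogeny import Phylogeny, read_newick


# ---------------------------------------------------------------------------
# trees


@pytest.fixture
def cherry():
    return read_newick("(A:1.0,B:1.0);")


@pytest.fixture
def three_tip():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def four_tip():
    return read_newick("((A:0.1,B:0.2):0.3,(C:0.4,D:0.5):0.6);")


@pytest.fixture
def five_tip():
    # mirrors the worked 5-cell example: a cherry-of-cherries plus an
    # outgroup cell; 8 branches
    return read_newick("((((C1:0.3,C2:0.4):0.2,C3:0.5):0.3,C4:0.6):0.7,C5:0.9);")


def random_bifurcating_newick(n_tips: int, rng: np.random.Generator,
                              mean: float = 0.5) -> str:
    """Random topology by sequential pair joining; exponential lengths."""
    nodes = [f"T{i}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        la, lb = rng.exponential(mean, 2)
        nodes.append(f"({a}:{la:.10g},{b}:{lb:.10g})")
    return nodes[0] + ";"


# ---------------------------------------------------------------------------
# structural helpers (independent of CladeIndex)


def bf_clade_tips(tree: Phylogeny, branch: int) -> set[int]:
    """Tip column indices below a branch, by direct traversal."""
    order = {tree.tip_node[lab]: k for k, lab in enumerate(tree.tip_labels)}
    out: set[int] = set()
    stack = [int(tree.branch_child[branch])]
    while stack:
        node = stack.pop()
        if tree.is_tip(node):
            out.add(order[node])
        stack.extend(tree.children[node])
    return out


def bf_clade_edges(tree: Phylogeny, branch: int) -> set[int]:
    out: set[int] = set()
    stack = list(tree.children[int(tree.branch_child[branch])])
    while stack:
        node = stack.pop()
        out.add(int(tree.branch_of_node[node]))
        stack.extend(tree.children[node])
    return out


def bf_binary_p(lam: float, t: float) -> np.ndarray:
    q = np.array([[-lam, lam], [0.0, 0.0]])
    return expm(q * t)


def bf_ternary_p(lam1: float, lam2: float, t: float) -> np.ndarray:
    q = np.array([
        [-(lam1 + lam1 * lam2), lam1, lam1 * lam2],
        [0.0, -lam2, lam2],
        [0.0, 0.0, 0.0],
    ])
    return expm(q * t)


# ---------------------------------------------------------------------------
# brute-force placement priors


def bf_prior_binary(tree: Phylogeny, lam: float) -> np.ndarray:
    nb = tree.n_branches
    num = np.zeros(nb)
    for x in range(nb):
        clade = bf_clade_edges(tree, x)
        prod = 1.0
        for b in range(nb):
            p = bf_binary_p(lam, float(tree.lengths[b]))
            if b == x:
                prod *= p[0, 1]
            elif b in clade:
                prod *= p[1, 1]
            else:
                prod *= p[0, 0]
        num[x] = prod
    return num / num.sum()


def bf_ternary_numerators(tree: Phylogeny, lam1: float, lam2: float):
    """Numerators for every mechanism placement: (het, hom, {(x, y): q})."""
    nb = tree.n_branches
    mats = [bf_ternary_p(lam1, lam2, float(t)) for t in tree.lengths]
    het = np.zeros(nb)
    hom = np.zeros(nb)
    pair: dict[tuple[int, int], float] = {}
    for x in range(nb):
        clade_x = bf_clade_edges(tree, x)
        p_het = p_hom = 1.0
        for b in range(nb):
            p = mats[b]
            if b == x:
                p_het *= p[0, 1]
                p_hom *= p[0, 2]
            elif b in clade_x:
                p_het *= p[1, 1]
                p_hom *= p[2, 2]
            else:
                p_het *= p[0, 0]
                p_hom *= p[0, 0]
        het[x] = p_het
        hom[x] = p_hom
        for y in clade_x:
            clade_y = bf_clade_edges(tree, y)
            prod = 1.0
            for b in range(nb):
                p = mats[b]
                if b == x:
                    prod *= p[0, 1]
                elif b == y:
                    prod *= p[1, 2]
                elif b in clade_y:
                    prod *= p[2, 2]
                elif b in clade_x:
                    prod *= p[1, 1]
                else:
                    prod *= p[0, 0]
            pair[(x, y)] = prod
    return het, hom, pair


def bf_prior_ternary(tree: Phylogeny, lam1: float, lam2: float) -> np.ndarray:
    het, hom, pair = bf_ternary_numerators(tree, lam1, lam2)
    total = het.sum() + hom.sum() + sum(pair.values())
    marg = het + hom
    for (x, _), q in pair.items():
        marg[x] += q
    return marg / total


# ---------------------------------------------------------------------------
# brute-force posteriors


def _bf_cell_lik(obs: int, g: int, n: np.ndarray, n_states: int) -> float:
    if obs == AMBIGUOUS:
        return float(n[g, :n_states].mean())
    return float(n[g, obs])


def bf_posterior_binary(tree: Phylogeny, obs_row: np.ndarray, lam: float,
                        alpha: float, beta: float) -> np.ndarray:
    """Direct enumeration of P(S, B = x); complete data (no missing)."""
    assert not np.any(obs_row == MISSING)
    nb = tree.n_branches
    n = np.array([[1 - alpha, alpha], [beta, 1 - beta]])
    prior = bf_prior_binary(tree, lam)
    num = np.zeros(nb)
    for x in range(nb):
        carriers = bf_clade_tips(tree, x)
        lik = 1.0
        for j, s in enumerate(obs_row):
            g = 1 if j in carriers else 0
            lik *= _bf_cell_lik(int(s), g, n, 2)
        num[x] = prior[x] * lik
    return num / num.sum()


def bf_posterior_ternary(tree: Phylogeny, obs_row: np.ndarray, lam1: float,
                         lam2: float, alpha: float, beta: float) -> np.ndarray:
    assert not np.any(obs_row == MISSING)
    nb = tree.n_branches
    n = np.array([
        [1 - alpha - alpha * beta / 2, alpha, alpha * beta / 2],
        [beta / 2, 1 - beta, beta / 2],
        [0.0, 0.0, 1.0],
    ])
    het, hom, pair = bf_ternary_numerators(tree, lam1, lam2)
    z = het.sum() + hom.sum() + sum(pair.values())

    def lik(genotypes: np.ndarray) -> float:
        out = 1.0
        for j, s in enumerate(obs_row):
            out *= _bf_cell_lik(int(s), int(genotypes[j]), n, 3)
        return out

    num = np.zeros(nb)
    for x in range(nb):
        carriers = bf_clade_tips(tree, x)
        g1 = np.zeros(len(obs_row), dtype=int)
        g2 = np.zeros(len(obs_row), dtype=int)
        for j in carriers:
            g1[j] = 1
            g2[j] = 2
        num[x] += (het[x] / z) * lik(g1)
        num[x] += (hom[x] / z) * lik(g2)
        for y in bf_clade_edges(tree, x):
            gp = g1.copy()
            for j in bf_clade_tips(tree, y):
                gp[j] = 2
            num[x] += (pair[(x, y)] / z) * lik(gp)
    return num / num.sum()
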