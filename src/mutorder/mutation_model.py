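"""Continuous-time Markov models of somatic genotype change and the prior
probability that a mutation is first acquired on each branch of a fixed tree.

Binary genotypes evolve 0 -> 1 at rate ``lam``; ternary genotypes evolve
0 -> 1 at ``lam1``, 1 -> 2 at ``lam2``, and 0 -> 2 directly at ``lam1*lam2``.
A mutation arises exactly once on the tree (one-origin constraint), so the
per-branch acquisition probabilities are renormalized over all branches and,
for ternary data, over the three generating mechanisms.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.special import logsumexp

from .phylogeny import CladeIndex, Phylogeny

__all__ = [
    "BinaryRates",
    "TernaryRates",
    "Mechanism",
    "PlacementPrior",
    "transition_matrix_binary",
    "transition_matrix_ternary",
    "placement_prior_binary",
    "placement_prior_ternary",
    "true_genotypes_for_placement",
]

_SINGULAR_TOL = 1e-12


@dataclass(frozen=True)
class BinaryRates:
    """Instantaneous 0->1 transition rate per site (per unit branch length)."""

    lam: float

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")


@dataclass(frozen=True)
class TernaryRates:
    """0->1 rate ``lam1`` and 1->2 rate ``lam2``; direct 0->2 rate is lam1*lam2.

    ``lam2 = 0`` reduces the model to the binary (infinite-sites diploid)
    model with rate ``lam1``.
    """

    lam1: float
    lam2: float

    def __post_init__(self) -> None:
        if self.lam1 < 0 or self.lam2 < 0:
            raise ValueError("rates must be >= 0")

    @property
    def exit_rate(self) -> float:
        """Total rate of leaving state 0: lam1 + lam1*lam2."""
        return self.lam1 + self.lam1 * self.lam2


class Mechanism(str, Enum):
    """Generating mechanism of a ternary mutation."""

    HET = "0->1"          # 0 -> 1, no further change
    HOM_DIRECT = "0->2"   # direct 0 -> 2
    HET_THEN_HOM = "0->1,1->2"  # 0 -> 1 on x, then 1 -> 2 on y below x


def transition_matrix_binary(rates: BinaryRates, t: float) -> np.ndarray:
    """2x2 transition probability matrix exp(Q t) for the binary model."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    p01 = -np.expm1(-rates.lam * t)
    return np.array([[1.0 - p01, p01], [0.0, 1.0]])


def transition_matrix_ternary(rates: TernaryRates, t: float) -> np.ndarray:
    """3x3 transition probability matrix exp(Q t) for the ternary model.

    The closed form has a removable singularity when the exit rate from
    state 0 equals ``lam2``; that case is evaluated by its limit.
    """
    if t < 0:
        raise ValueError("branch length must be >= 0")
    a = rates.exit_rate
    l2 = rates.lam2
    p00 = np.exp(-a * t)
    p11 = np.exp(-l2 * t)
    denom = l2 - a
    if abs(denom) < _SINGULAR_TOL * max(1.0, a, l2):
        # lim_{l2->a} lam1 (e^{-at} - e^{-l2 t}) / (l2 - a) = lam1 t e^{-at}
        p01 = rates.lam1 * t * p00
    else:
        p01 = rates.lam1 * (p00 - p11) / denom
    p02 = 1.0 - p00 - p01
    p12 = 1.0 - p11
    # clip tiny negatives from cancellation
    mat = np.array([[p00, p01, p02], [0.0, p11, p12], [0.0, 0.0, 1.0]])
    return np.clip(mat, 0.0, 1.0)


@dataclass(frozen=True)
class PlacementPrior:
    """Prior over the branch on which a mutation is first acquired.

    ``probs[x]`` is P(B = x) over the tree's branches.  For ternary data the
    mechanism decomposition is retained: ``p_het``/``p_hom_direct`` per
    branch and ``p_het_then_hom[x, y]`` for a 0->1 on x followed by 1->2 on
    y in E^x(w); all of these sum to 1 jointly and marginalize to ``probs``.
    """

    probs: np.ndarray
    log_probs: np.ndarray
    mode: str  # "binary" | "ternary"
    p_het: np.ndarray | None = None
    p_hom_direct: np.ndarray | None = None
    p_het_then_hom: np.ndarray | None = None


def _binary_log_numerators(tree: Phylogeny, index: CladeIndex,
                           rates: BinaryRates) -> np.ndarray:
    t = tree.lengths
    with np.errstate(divide="ignore"):
        log_p00 = -rates.lam * t
        log_p01 = np.log(-np.expm1(-rates.lam * t))
    total_p00 = log_p00.sum()
    desc = index.earlier_matrix
    # general form: outside product of P00, P01 on x, clade product of P11;
    # log P11 = 0 in the binary model so the clade term vanishes
    return (total_p00 - log_p00 - desc @ log_p00) + log_p01


def placement_prior_binary(tree: Phylogeny, index: CladeIndex,
                           rates: BinaryRates) -> PlacementPrior:
    """One-origin placement prior P(B = x) for the binary model."""
    log_num = _binary_log_numerators(tree, index, rates)
    if np.all(np.isneginf(log_num)):
        raise ValueError("all placement numerators are zero; prior undefined")
    log_z = logsumexp(log_num)
    logp = log_num - log_z
    return PlacementPrior(probs=np.exp(logp), log_probs=logp, mode="binary")


def _ternary_log_terms(tree: Phylogeny, index: CladeIndex, rates: TernaryRates):
    """Per-branch log transition factors for the ternary model."""
    t = tree.lengths
    mats = np.array([transition_matrix_ternary(rates, ti) for ti in t])
    with np.errstate(divide="ignore"):
        logs = np.log(mats)
    return logs  # (nb, 3, 3)


def ternary_log_numerators(tree: Phylogeny, index: CladeIndex,
                           rates: TernaryRates):
    """Unnormalized log prior mass for every mechanism placement.

    Returns ``(q_het, q_hom, q_pair)`` where ``q_het[x]`` and ``q_hom[x]``
    are the single-branch mechanisms and ``q_pair[x, y]`` is 0->1 on x with
    1->2 on y (``-inf`` for y outside E^x(w)).
    """
    logs = _ternary_log_terms(tree, index, rates)
    l00, l01, l02 = logs[:, 0, 0], logs[:, 0, 1], logs[:, 0, 2]
    l11, l12, l22 = logs[:, 1, 1], logs[:, 1, 2], logs[:, 2, 2]
    total_p00 = l00.sum()
    desc = index.earlier_matrix

    outside = total_p00 - l00 - desc @ l00
    q_het = outside + l01 + desc @ l11
    q_hom = outside + l02 + desc @ l22
    # pair (x, y): start from q_het[x], swap the clade of y from P11 to P22
    # and y itself from P11 to P12
    swap = -l11 + l12 + desc @ (l22 - l11)
    with np.errstate(invalid="ignore"):
        q_pair = np.where(desc, q_het[:, None] + swap[None, :], -np.inf)
    return q_het, q_hom, q_pair


def placement_prior_ternary(tree: Phylogeny, index: CladeIndex,
                            rates: TernaryRates) -> PlacementPrior:
    """One-origin placement prior with mechanism decomposition (ternary)."""
    q_het, q_hom, q_pair = ternary_log_numerators(tree, index, rates)
    all_terms = np.concatenate([q_het, q_hom, q_pair.ravel()])
    if np.all(np.isneginf(all_terms)):
        raise ValueError("all placement numerators are zero; prior undefined")
    log_z = logsumexp(all_terms)
    p_het = np.exp(q_het - log_z)
    p_hom = np.exp(q_hom - log_z)
    p_pair = np.exp(q_pair - log_z)
    probs = p_het + p_hom + p_pair.sum(axis=1)
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    return PlacementPrior(
        probs=probs, log_probs=logp, mode="ternary",
        p_het=p_het, p_hom_direct=p_hom, p_het_then_hom=p_pair,
    )


def true_genotypes_for_placement(tree: Phylogeny, index: CladeIndex,
                                 branch: int,
                                 mechanism: Mechanism = Mechanism.HET,
                                 second_branch: int | None = None) -> np.ndarray:
    """True genotype vector over tips (tree tip order) for a placement.

    Binary usage passes ``Mechanism.HET`` (carriers get state 1).  For the
    two-step mechanism the 1->2 branch must lie inside the clade of the
    first branch.
    """
    g = np.zeros(tree.n_tips, dtype=np.int8)
    carriers = index.tip_mask[branch]
    if mechanism is Mechanism.HET:
        g[carriers] = 1
    elif mechanism is Mechanism.HOM_DIRECT:
        g[carriers] = 2
    elif mechanism is Mechanism.HET_THEN_HOM:
        if second_branch is None:
            raise ValueError("two-step mechanism needs second_branch")
        if not index.is_earlier(branch, second_branch):
            raise ValueError("second_branch must be a descendant of branch")
        g[carriers] = 1
        g[index.tip_mask[second_branch]] = 2
    else:  # pragma: no cover
        raise ValueError(mechanism)
    return g
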