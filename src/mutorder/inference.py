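"""Posterior inference of mutation locations and temporal order.

For each site the cells with missing observations are pruned (subtree
projection), a one-origin placement prior is combined with the error-model
likelihood in log space, and the normalized posterior over subtree branches
is mapped back to the original branches.  Posterior mass on a merged branch
path is allocated proportionally to the original branch lengths (uniform
when the whole path has zero length) — the small-rate-consistent choice.

Parameter uncertainty is handled by Monte Carlo integration: the
unnormalized per-branch numerators are averaged across prior draws and
normalized once (Rao-Blackwellized over branches).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .error_model import MISSING, ErrorRates, ObservedMatrix, per_cell_state_loglik
from .mutation_model import (
    BinaryRates,
    TernaryRates,
    placement_prior_binary,
    placement_prior_ternary,
    ternary_log_numerators,
)
from .phylogeny import CladeIndex, Phylogeny, clade_index, project_subtree

__all__ = [
    "PlacementPosterior",
    "CredibleSet",
    "PairwiseOrder",
    "ParamPrior",
    "PriorSpec",
    "SiteInferenceError",
    "placement_posterior",
    "integrate_posterior",
    "infer_matrix",
    "map_location",
    "credible_set",
    "pairwise_order",
    "joint_map_order",
    "joint_credible_set",
]


class SiteInferenceError(RuntimeError):
    """Posterior undefined for a site (all numerators zero, or < 2 cells)."""




@dataclass(frozen=True)
class PlacementPosterior:
    """Posterior distribution of one mutation's branch placement.

    ``probs`` is indexed by the *original* tree's branch ids; entries are
    zero for branches outside the site's observed subtree.  For ternary
    data the per-mechanism marginals are retained on the same indexing.
    """

    site: int
    probs: np.ndarray
    log_evidence: float
    mode: str
    mech_het: np.ndarray | None = None
    mech_hom_direct: np.ndarray | None = None
    mech_het_then_hom: np.ndarray | None = None


@dataclass(frozen=True)
class CredibleSet:
    level: float
    branches: tuple[int, ...]
    cumulative: float


@dataclass(frozen=True)
class PairwiseOrder:
    p_before: float
    p_after: float
    p_same: float
    p_incomparable: float


# ---------------------------------------------------------------------------
# priors over model parameters


@dataclass(frozen=True)
class ParamPrior:
    """A fixed value, Beta(a, b) or Gamma(shape, scale) prior for a parameter."""

    dist: str
    params: tuple[float, ...]

    @classmethod
    def fixed(cls, value: float) -> "ParamPrior":
        return cls("fixed", (float(value),))

    @classmethod
    def beta(cls, a: float, b: float) -> "ParamPrior":
        if a <= 0 or b <= 0:
            raise ValueError("beta hyperparameters must be > 0")
        return cls("beta", (a, b))

    @classmethod
    def gamma(cls, shape: float, scale: float) -> "ParamPrior":
        if shape <= 0 or scale <= 0:
            raise ValueError("gamma hyperparameters must be > 0")
        return cls("gamma", (shape, scale))

    def sample(self, rng: np.random.Generator) -> float:
        if self.dist == "fixed":
            return self.params[0]
        if self.dist == "beta":
            return float(rng.beta(*self.params))
        if self.dist == "gamma":
            return float(rng.gamma(self.params[0], self.params[1]))
        raise ValueError(self.dist)

    @property
    def mean(self) -> float:
        if self.dist == "fixed":
            return self.params[0]
        if self.dist == "beta":
            a, b = self.params
            return a / (a + b)
        return self.params[0] * self.params[1]


@dataclass(frozen=True)
class PriorSpec:
    """Priors for the transition rates and error probabilities.

    Degenerate (``fixed``) entries reproduce fixed-parameter inference.
    """

    lam1: ParamPrior
    alpha: ParamPrior
    beta: ParamPrior
    lam2: ParamPrior | None = None  # required for ternary mode
    mc_samples: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mc_samples < 1:
            raise ValueError("mc_samples must be >= 1")


# ---------------------------------------------------------------------------
# single-site machinery


def _site_context(tree: Phylogeny, obs: ObservedMatrix, site: int):
    """Project away missing cells; return (projection, subtree index, cells).

    ``cells`` are the observed-matrix column indices ordered like the
    subtree's tip labels, so clade tip masks align with likelihood tables.
    """
    col = {lab: j for j, lab in enumerate(obs.cell_labels)}
    missing = set(obs.missing_cells(site))
    try:
        proj = project_subtree(tree, missing)
    except Exception as exc:
        raise SiteInferenceError(f"site {site}: {exc}") from exc
    sub = proj.subtree
    cells = np.array([col[lab] for lab in sub.tip_labels], dtype=np.int64)
    return proj, clade_index(sub), cells


def _backmap(proj, sub_probs: np.ndarray, n_branches: int) -> np.ndarray:
    """Distribute subtree-branch mass over merged original-branch paths."""
    out = np.zeros(n_branches)
    for k, path in enumerate(proj.branch_paths):
        mass = sub_probs[k]
        if mass == 0.0:
            continue
        if len(path) == 1:
            out[path[0]] += mass
            continue
        lens = np.array([proj._orig_lengths[b] for b in path])
        total = lens.sum()
        weights = lens / total if total > 0 else np.full(len(path), 1.0 / len(path))
        for b, w in zip(path, weights):
            out[b] += mass * w
    return out


def _site_log_numerators(sindex: CladeIndex, obs_row: np.ndarray, site: int,
                         cells: np.ndarray, mut_rates, err_rates: ErrorRates,
                         mode: str, ambiguity=None):
    """Marginal log numerator per subtree branch: log prior + log likelihood.

    Impossible observations (likelihood exactly 0, e.g. a mismatch at
    alpha = beta = 0) are handled by counting them per candidate placement:
    the finite log terms are summed separately and any placement with a
    positive impossible-count gets ``-inf``, avoiding inf arithmetic in the
    vectorized clade sums.
    """
    sub = sindex.tree
    table = per_cell_state_loglik(obs_row, err_rates, site, mode, ambiguity, cells)
    bad = np.isneginf(table)            # (cells, states)
    finite = np.where(bad, 0.0, table)
    badc = bad.astype(np.float64)
    mask = sindex.tip_mask              # (nb, n_tips) bool
    base = finite[:, 0].sum()
    base_bad = badc[:, 0].sum()
    if mode == "binary":
        prior = placement_prior_binary(sub, sindex, mut_rates)
        lik = base + mask @ (finite[:, 1] - finite[:, 0])
        nbad = base_bad + mask @ (badc[:, 1] - badc[:, 0])
        lik = np.where(nbad > 0.5, -np.inf, lik)
        return prior.log_probs + lik, None
    # ternary: three mechanisms
    q_het, q_hom, q_pair = ternary_log_numerators(sub, sindex, mut_rates)
    log_z = logsumexp(np.concatenate([q_het, q_hom, q_pair.ravel()]))
    if np.isneginf(log_z):
        raise ValueError("all placement numerators are zero; prior undefined")
    d10 = mask @ (finite[:, 1] - finite[:, 0])
    d21 = mask @ (finite[:, 2] - finite[:, 1])
    b10 = mask @ (badc[:, 1] - badc[:, 0])
    b21 = mask @ (badc[:, 2] - badc[:, 1])
    lik_het = np.where(base_bad + b10 > 0.5, -np.inf, base + d10)
    lik_hom = np.where(base_bad + b10 + b21 > 0.5, -np.inf, base + d10 + d21)
    num_het = (q_het - log_z) + lik_het
    num_hom = (q_hom - log_z) + lik_hom
    # pair numerator: prior(x, y) + base + d10[x] + d21[y]
    lik_pair = base + d10[:, None] + d21[None, :]
    nbad_pair = base_bad + b10[:, None] + b21[None, :]
    lik_pair = np.where(nbad_pair > 0.5, -np.inf, lik_pair)
    with np.errstate(invalid="ignore"):
        num_pair = np.where(np.isneginf(q_pair), -np.inf,
                            (q_pair - log_z) + lik_pair)
    return (num_het, num_hom, num_pair), None


def _ternary_marginal(num_tuple):
    num_het, num_hom, num_pair = num_tuple
    with np.errstate(invalid="ignore"):
        pair_row = logsumexp(num_pair, axis=1)
    stacked = np.stack([num_het, num_hom, pair_row])
    return logsumexp(stacked, axis=0)


def _finalize(site: int, proj, sindex, num, mode: str,
              n_branches: int) -> PlacementPosterior:
    if mode == "binary":
        log_num = num
    else:
        num_het, num_hom, num_pair = num
        log_num = _ternary_marginal(num)
    if np.all(np.isneginf(log_num)):
        raise SiteInferenceError(
            f"site {site}: zero posterior everywhere (impossible data under rates)"
        )
    log_ev = logsumexp(log_num)
    sub_probs = np.exp(log_num - log_ev)
    probs = _backmap(proj, sub_probs, n_branches)
    if mode == "binary":
        return PlacementPosterior(site=site, probs=probs, log_evidence=float(log_ev),
                                  mode=mode)
    p_het = _backmap(proj, np.exp(num_het - log_ev), n_branches)
    p_hom = _backmap(proj, np.exp(num_hom - log_ev), n_branches)
    with np.errstate(invalid="ignore"):
        pair_row = np.exp(logsumexp(num_pair, axis=1) - log_ev)
    p_pair = _backmap(proj, pair_row, n_branches)
    return PlacementPosterior(
        site=site, probs=probs, log_evidence=float(log_ev), mode=mode,
        mech_het=p_het, mech_hom_direct=p_hom, mech_het_then_hom=p_pair,
    )


def _attach_orig_lengths(tree: Phylogeny, proj) -> None:
    object.__setattr__(proj, "_orig_lengths", np.asarray(tree.lengths))


def placement_posterior(tree: Phylogeny, obs: ObservedMatrix, site: int,
                        mut_rates: BinaryRates | TernaryRates,
                        err_rates: ErrorRates,
                        mode: str | None = None) -> PlacementPosterior:
    """Posterior over branch placements for one site at fixed parameters."""
    mode = mode or obs.mode
    _check_rates(mut_rates, mode)
    proj, sindex, cells = _site_context(tree, obs, site)
    _attach_orig_lengths(tree, proj)
    num, _ = _site_log_numerators(sindex, obs.data[site], site, cells,
                                  mut_rates, err_rates, mode, obs.ambiguity)
    return _finalize(site, proj, sindex, num, mode, tree.n_branches)


def _check_rates(mut_rates, mode: str) -> None:
    if mode == "binary" and not isinstance(mut_rates, BinaryRates):
        raise TypeError("binary mode requires BinaryRates")
    if mode == "ternary" and not isinstance(mut_rates, TernaryRates):
        raise TypeError("ternary mode requires TernaryRates")


def integrate_posterior(tree: Phylogeny, obs: ObservedMatrix, site: int,
                        priors: PriorSpec, mode: str | None = None,
                        rng: np.random.Generator | None = None) -> PlacementPosterior:
    """Monte Carlo integration of the posterior over parameter priors.

    Draws (lambda, alpha, beta) ``mc_samples`` times, averages the
    unnormalized per-branch numerators across draws, then normalizes.
    Deterministic for a given seed / generator.
    """
    mode = mode or obs.mode
    if mode == "ternary" and priors.lam2 is None:
        raise ValueError("ternary mode requires a lam2 prior")
    if rng is None:
        rng = np.random.default_rng(priors.seed)
    proj, sindex, cells = _site_context(tree, obs, site)
    _attach_orig_lengths(tree, proj)
    m = priors.mc_samples
    draws = []
    for _ in range(m):
        lam1 = priors.lam1.sample(rng)
        a = priors.alpha.sample(rng)
        b = priors.beta.sample(rng)
        err = ErrorRates(alpha=a, beta=b)
        if mode == "binary":
            mut = BinaryRates(lam=lam1)
        else:
            mut = TernaryRates(lam1=lam1, lam2=priors.lam2.sample(rng))
        try:
            num, _ = _site_log_numerators(sindex, obs.data[site], site, cells,
                                          mut, err, mode, obs.ambiguity)
        except ValueError:
            # degenerate draw (e.g. all-zero prior numerators): contributes 0
            nb = sindex.tree.n_branches
            num = (np.full(nb, -np.inf) if mode == "binary" else
                   (np.full(nb, -np.inf), np.full(nb, -np.inf),
                    np.full((nb, nb), -np.inf)))
        draws.append(num)
    log_m = np.log(m)
    if mode == "binary":
        avg = logsumexp(np.stack(draws), axis=0) - log_m
        return _finalize(site, proj, sindex, avg, mode, tree.n_branches)
    het = logsumexp(np.stack([d[0] for d in draws]), axis=0) - log_m
    hom = logsumexp(np.stack([d[1] for d in draws]), axis=0) - log_m
    with np.errstate(invalid="ignore"):
        pair = logsumexp(np.stack([d[2] for d in draws]), axis=0) - log_m
    return _finalize(site, proj, sindex, (het, hom, pair), mode, tree.n_branches)


def infer_matrix(tree: Phylogeny, obs: ObservedMatrix,
                 mut_rates=None, err_rates: ErrorRates | None = None,
                 priors: PriorSpec | None = None,
                 mode: str | None = None):
    """Run per-site inference over a whole matrix.

    Returns ``(posteriors, failures)`` where ``posteriors[i]`` is ``None``
    for failed sites and ``failures`` maps site index to the error message.
    """
    mode = mode or obs.mode
    posteriors: list[PlacementPosterior | None] = []
    failures: dict[int, str] = {}
    rng = np.random.default_rng(priors.seed) if priors is not None else None
    for i in range(obs.n_sites):
        try:
            if priors is not None:
                post = integrate_posterior(tree, obs, i, priors, mode, rng=rng)
            else:
                post = placement_posterior(tree, obs, i, mut_rates, err_rates, mode)
            posteriors.append(post)
        except SiteInferenceError as exc:
            posteriors.append(None)
            failures[i] = str(exc)
    return posteriors, failures


# ---------------------------------------------------------------------------
# summaries


def map_location(post: PlacementPosterior, tol: float = 1e-12) -> tuple[int, bool]:
    """MAP branch id and a tie flag; ties resolved to the smallest id."""
    p = post.probs
    top = p.max()
    tied = np.flatnonzero(p >= top - tol)
    return int(tied[0]), len(tied) > 1


def credible_set(post: PlacementPosterior, theta: float = 0.05) -> CredibleSet:
    """Greedy (1 - theta) credible set: branches in decreasing posterior order."""
    if not (0 < 1 - theta <= 1):
        raise ValueError("theta must lie in [0, 1)")
    order = np.lexsort((np.arange(len(post.probs)), -post.probs))
    cum = 0.0
    chosen: list[int] = []
    target = 1.0 - theta
    for b in order:
        chosen.append(int(b))
        cum += float(post.probs[b])
        if cum >= target - 1e-12:
            break
    return CredibleSet(level=1.0 - theta, branches=tuple(chosen), cumulative=cum)


def pairwise_order(post_i: PlacementPosterior, post_j: PlacementPosterior,
                   index: CladeIndex) -> PairwiseOrder:
    """Probabilities that mutation i precedes / follows / shares / is
    incomparable with mutation j, under posterior independence."""
    e = index.earlier_matrix
    pi, pj = post_i.probs, post_j.probs
    before = float(pi @ e @ pj)
    after = float(pj @ e @ pi)
    same = float(pi @ pj)
    inc = max(0.0, 1.0 - before - after - same)
    return PairwiseOrder(p_before=before, p_after=after, p_same=same,
                         p_incomparable=inc)


def joint_map_order(posts: list[PlacementPosterior]) -> tuple[np.ndarray, float]:
    """Joint MAP branch assignment over all sites and its probability.

    Site independence makes the joint posterior a product of marginals, so
    the joint MAP is the vector of per-site MAP branches.
    """
    branches = np.empty(len(posts), dtype=np.int64)
    log_p = 0.0
    for k, post in enumerate(posts):
        b, _ = map_location(post)
        branches[k] = b
        log_p += float(np.log(post.probs[b]))
    return branches, float(np.exp(log_p))


def joint_credible_set(posts: list[PlacementPosterior], theta: float = 0.05,
                       cap: int = 10 ** 6):
    """(1 - theta) credible set of joint assignments, best-first.

    Lazily enumerates joint assignments in decreasing product probability
    using a heap over per-site rank vectors.  Returns
    ``(assignments, probabilities, truncated)``; ``truncated`` is True when
    the enumeration cap was hit before reaching the target mass.
    """
    orders = []
    logs = []
    for post in posts:
        o = np.lexsort((np.arange(len(post.probs)), -post.probs))
        orders.append(o)
        with np.errstate(divide="ignore"):
            logs.append(np.log(post.probs[o]))
    n = len(posts)
    start = (0,) * n
    start_lp = float(sum(l[0] for l in logs))
    heap = [(-start_lp, start)]
    seen = {start}
    out_assign: list[tuple[int, ...]] = []
    out_probs: list[float] = []
    cum = 0.0
    target = 1.0 - theta
    truncated = False
    count = 0
    while heap:
        neg_lp, ranks = heapq.heappop(heap)
        prob = float(np.exp(-neg_lp))
        out_assign.append(tuple(int(orders[k][r]) for k, r in enumerate(ranks)))
        out_probs.append(prob)
        cum += prob
        count += 1
        if cum >= target - 1e-12:
            break
        if count >= cap:
            truncated = True
            break
        for k in range(n):
            if ranks[k] + 1 >= len(orders[k]):
                continue
            nxt = ranks[:k] + (ranks[k] + 1,) + ranks[k + 1:]
            if nxt in seen:
                continue
            seen.add(nxt)
            lp = -neg_lp - logs[k][ranks[k]] + logs[k][ranks[k] + 1]
            if np.isneginf(lp):
                continue
            heapq.heappush(heap, (-lp, nxt))
    return out_assign, out_probs, truncated
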