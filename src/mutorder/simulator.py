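"""Synthetic data generation: random trees, model-based mutation placement,
error injection, missing-data masking, mutation loss, and finite-sites
histories.

Three simulation styles are supported:

1. infinite-sites placement proportional to branch length on neutral
   coalescent trees (optionally followed by mutation loss),
2. model-based placement sampled from the one-origin placement prior on
   random-split trees with exponential branch lengths,
3. finite-sites two-state histories simulated edge-by-edge (Gillespie),
   where sites may mutate repeatedly and back-mutate.

All randomness flows through a single :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .error_model import MISSING, ErrorRates, ObservedMatrix, error_matrix
from .mutation_model import (
    BinaryRates,
    Mechanism,
    TernaryRates,
    placement_prior_binary,
    placement_prior_ternary,
    true_genotypes_for_placement,
)
from .phylogeny import CladeIndex, Phylogeny, clade_index, read_newick

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "Placement",
    "LossEvent",
    "MutationEvent",
    "simulate_tree",
    "simulate_placements",
    "inject_errors",
    "mask_missing",
    "introduce_losses",
    "simulate_finite_sites",
    "simulate_dataset",
    "scenario_config",
    "SCENARIOS",
]


@dataclass(frozen=True)
class Placement:
    """True origin of one mutation: branch, mechanism, optional 1->2 branch."""

    branch: int
    mechanism: Mechanism = Mechanism.HET
    second_branch: int | None = None


@dataclass(frozen=True)
class LossEvent:
    site: int
    branch: int


@dataclass(frozen=True)
class MutationEvent:
    """One state flip in a finite-sites history."""

    site: int
    branch: int
    time: float  # offset from the branch's parent end
    from_state: int
    to_state: int


@dataclass
class SimulationConfig:
    """Knobs for one simulated replicate."""

    tips: int = 10
    sites: int = 20
    tree_generator: Literal["coalescent", "random-split"] = "random-split"
    branch_length_mean: float = 0.2
    coalescent_scale: float = 0.2
    mode: Literal["binary", "ternary"] = "binary"
    lam: float = 1.0
    lam1: float = 1e-7
    lam2: float = 1e-2
    alpha: float = 0.0
    beta: float = 0.0
    missing_fraction: float = 0.0
    loss_rate: float = 0.0
    loss_cap: int = 1
    finite_sites: bool = False
    rate01: float = 100.0
    rate10: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tips < 2:
            raise ValueError("need at least 2 tips")
        if self.sites < 1:
            raise ValueError("need at least 1 site")
        for p in (self.alpha, self.beta, self.missing_fraction, self.loss_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SimulatedDataset:
    """Everything generated for one replicate, truth included."""

    config: SimulationConfig
    tree: Phylogeny
    index: CladeIndex
    placements: list[Placement]
    genotypes_true: np.ndarray      # before loss, in the simulated mode
    genotypes: np.ndarray           # after loss / ternary->binary conversion
    observed: ObservedMatrix
    masked_tips: list[list[str]]    # per site
    loss_events: list[LossEvent] = field(default_factory=list)
    mutation_events: list[MutationEvent] = field(default_factory=list)


# ---------------------------------------------------------------------------
# trees


def _newick_from_merges(labels: list[str], rng: np.random.Generator,
                        scale: float) -> str:
    """Neutral coalescent: exponential waiting times, uniform pair merges."""
    n = len(labels)
    nodes = [(lab, 0.0) for lab in labels]  # (newick, node time)
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        rate = k * (k - 1) / 2.0
        t += rng.exponential(scale / rate)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (nw_j, t_j) = nodes.pop(j)
        (nw_i, t_i) = nodes.pop(i)
        merged = f"({nw_i}:{t - t_i:.12g},{nw_j}:{t - t_j:.12g})"
        nodes.append((merged, t))
    return nodes[0][0] + ";"


def _newick_random_split(labels: list[str], rng: np.random.Generator,
                         mean: float) -> str:
    if len(labels) == 1:
        return labels[0]
    k = int(rng.integers(1, len(labels)))
    perm = rng.permutation(len(labels))
    left = [labels[i] for i in sorted(perm[:k])]
    right = [labels[i] for i in sorted(perm[k:])]
    lnw = _newick_random_split(left, rng, mean)
    rnw = _newick_random_split(right, rng, mean)
    lt = rng.exponential(mean)
    rt = rng.exponential(mean)
    return f"({lnw}:{lt:.12g},{rnw}:{rt:.12g})"


def simulate_tree(tips: int, generator: str = "random-split",
                  rng: np.random.Generator | None = None,
                  branch_length_mean: float = 0.2,
                  coalescent_scale: float = 0.2) -> Phylogeny:
    """Random rooted bifurcating tree with ``tips`` leaves labeled C1..CJ."""
    rng = rng if rng is not None else np.random.default_rng(0)
    labels = [f"C{i + 1}" for i in range(tips)]
    if generator == "coalescent":
        nwk = _newick_from_merges(labels, rng, coalescent_scale)
    elif generator == "random-split":
        nwk = _newick_random_split(labels, rng, branch_length_mean) + ";"
    else:
        raise ValueError(f"unknown tree generator {generator!r}")
    return read_newick(nwk)


# ---------------------------------------------------------------------------
# placements and genotypes


def simulate_placements(tree: Phylogeny, index: CladeIndex, rates,
                        mode: str, n_sites: int,
                        rng: np.random.Generator,
                        by_length: bool = False):
    """Sample true placements (and genotypes) from the placement prior.

    With ``by_length`` the branch is instead drawn proportionally to branch
    length (the classic infinite-sites placement used for coalescent-style
    simulations); the mechanism is then a plain 0->1.
    """
    nb = tree.n_branches
    placements: list[Placement] = []
    if by_length:
        w = np.asarray(tree.lengths, dtype=float)
        if w.sum() <= 0:
            raise ValueError("cannot place by length on a zero-length tree")
        p = w / w.sum()
        branches = rng.choice(nb, size=n_sites, p=p)
        placements = [Placement(int(b)) for b in branches]
    elif mode == "binary":
        prior = placement_prior_binary(tree, index, rates)
        branches = rng.choice(nb, size=n_sites, p=prior.probs)
        placements = [Placement(int(b)) for b in branches]
    else:
        prior = placement_prior_ternary(tree, index, rates)
        flat = np.concatenate([
            prior.p_het, prior.p_hom_direct, prior.p_het_then_hom.ravel(),
        ])
        flat = flat / flat.sum()
        idx = rng.choice(len(flat), size=n_sites, p=flat)
        for code in idx:
            if code < nb:
                placements.append(Placement(int(code), Mechanism.HET))
            elif code < 2 * nb:
                placements.append(Placement(int(code - nb), Mechanism.HOM_DIRECT))
            else:
                x, y = divmod(int(code - 2 * nb), nb)
                placements.append(Placement(x, Mechanism.HET_THEN_HOM, y))
    g = np.stack([
        true_genotypes_for_placement(tree, index, p.branch, p.mechanism,
                                     p.second_branch)
        for p in placements
    ])
    return placements, g


def ternary_to_binary(g: np.ndarray) -> np.ndarray:
    """Collapse states {1, 2} to 1."""
    return (np.asarray(g) > 0).astype(np.int8)


def inject_errors(g: np.ndarray, rates: ErrorRates, mode: str,
                  rng: np.random.Generator) -> np.ndarray:
    """Resample every entry from its error-matrix row, independently."""
    g = np.asarray(g)
    out = np.empty_like(g, dtype=np.int8)
    n_states = 2 if mode == "binary" else 3
    scalar = np.asarray(rates.alpha).ndim == 0 and np.asarray(rates.beta).ndim == 0
    if scalar:
        n = error_matrix(rates, 0, 0, mode)
        for s in range(n_states):
            sel = g == s
            k = int(sel.sum())
            if k:
                out[sel] = rng.choice(n_states, size=k, p=n[s])
    else:
        for i in range(g.shape[0]):
            for j in range(g.shape[1]):
                n = error_matrix(rates, i, j, mode)
                out[i, j] = rng.choice(n_states, p=n[g[i, j]])
    return out


def mask_missing(s: np.ndarray, fraction: float, rng: np.random.Generator,
                 per_site: bool = False):
    """Set a fraction of tips to MISSING; returns (masked copy, tips per site).

    Default policy masks the same tips for every site (whole cells dropped);
    ``per_site`` redraws the masked tips independently per site.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    s = np.asarray(s)
    n_sites, n_cells = s.shape
    n_mask = int(round(fraction * n_cells))
    if n_cells - n_mask < 2:
        raise ValueError("masking would leave fewer than 2 observed cells")
    out = s.copy().astype(np.int8)
    masked: list[list[int]] = []
    if n_mask == 0:
        return out, [[] for _ in range(n_sites)]
    if per_site:
        for i in range(n_sites):
            tips = sorted(int(t) for t in rng.choice(n_cells, n_mask, replace=False))
            out[i, tips] = MISSING
            masked.append(tips)
    else:
        tips = sorted(int(t) for t in rng.choice(n_cells, n_mask, replace=False))
        out[:, tips] = MISSING
        masked = [list(tips) for _ in range(n_sites)]
    return out, masked


def introduce_losses(tree: Phylogeny, index: CladeIndex,
                     placements: list[Placement], g: np.ndarray,
                     rate: float, cap: int, rng: np.random.Generator):
    """Mutation loss: per site, up to ``cap`` accepted losses.

    Each round proposes a uniformly drawn branch and accepts it with
    probability ``rate``; on acceptance the cells below that branch revert
    to state 0 for the site.  Returns (modified genotypes, events, proposal
    count, acceptance count).
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    g = np.asarray(g).copy()
    nb = tree.n_branches
    events: list[LossEvent] = []
    proposals = 0
    accepted = 0
    for i in range(g.shape[0]):
        losses = 0
        for _ in range(cap):
            if losses >= cap:
                break
            branch = int(rng.integers(nb))
            proposals += 1
            if rng.random() < rate:
                g[i, index.tip_mask[branch]] = 0
                events.append(LossEvent(site=i, branch=branch))
                losses += 1
                accepted += 1
    return g, events, proposals, accepted


def simulate_finite_sites(tree: Phylogeny, rate01: float, rate10: float,
                          n_sites: int, rng: np.random.Generator):
    """Two-state finite-sites histories simulated branch-by-branch.

    Returns (tip genotypes, events, first_origin) where ``first_origin[i]``
    is the branch of the first 0->1 flip for site i (-1 if the site never
    mutates).
    """
    if rate01 < 0 or rate10 < 0:
        raise ValueError("rates must be >= 0")
    tip_order = {tree.tip_node[lab]: k for k, lab in enumerate(tree.tip_labels)}
    g = np.zeros((n_sites, tree.n_tips), dtype=np.int8)
    events: list[MutationEvent] = []
    first_origin = np.full(n_sites, -1, dtype=np.int64)

    for i in range(n_sites):
        # preorder walk carrying the state at the top of each branch
        stack = [(tree.root, 0)]
        while stack:
            node, state = stack.pop()
            bid = int(tree.branch_of_node[node])
            if bid >= 0:
                t_total = float(tree.lengths[bid])
                t = 0.0
                while True:
                    rate = rate01 if state == 0 else rate10
                    if rate == 0:
                        break
                    t += rng.exponential(1.0 / rate)
                    if t >= t_total:
                        break
                    new_state = 1 - state
                    events.append(MutationEvent(site=i, branch=bid, time=t,
                                                from_state=state,
                                                to_state=new_state))
                    if state == 0 and first_origin[i] < 0:
                        first_origin[i] = bid
                    state = new_state
            if tree.is_tip(node):
                g[i, tip_order[node]] = state
            else:
                for kid in tree.children[node]:
                    stack.append((kid, state))
    return g, events, first_origin


# ---------------------------------------------------------------------------
# end-to-end replicate


def simulate_dataset(config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> SimulatedDataset:
    """Generate one replicate: tree, true placements, losses, errors, masks."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    tree = simulate_tree(config.tips, config.tree_generator, rng,
                         config.branch_length_mean, config.coalescent_scale)
    index = clade_index(tree)
    mutation_events: list[MutationEvent] = []

    if config.finite_sites:
        g_true, mutation_events, first_origin = simulate_finite_sites(
            tree, config.rate01, config.rate10, config.sites, rng)
        placements = [Placement(int(b)) if b >= 0 else Placement(-1)
                      for b in first_origin]
        mode = "binary"
    else:
        mode = config.mode
        by_length = config.tree_generator == "coalescent"
        rates = (BinaryRates(config.lam) if mode == "binary"
                 else TernaryRates(config.lam1, config.lam2))
        placements, g_true = simulate_placements(
            tree, index, rates, mode, config.sites, rng, by_length=by_length)

    g = g_true.copy()
    loss_events: list[LossEvent] = []
    if config.loss_rate > 0:
        g, loss_events, _, _ = introduce_losses(
            tree, index, placements, g, config.loss_rate, config.loss_cap, rng)

    err = ErrorRates(alpha=config.alpha, beta=config.beta)
    s = inject_errors(g, err, mode, rng)
    s, masked_idx = mask_missing(s, config.missing_fraction, rng)
    masked_tips = [[tree.tip_labels[t] for t in tips] for tips in masked_idx]

    obs = ObservedMatrix(
        data=s,
        site_labels=tuple(f"m{i + 1}" for i in range(config.sites)),
        cell_labels=tuple(tree.tip_labels),
        mode=mode,
    )
    return SimulatedDataset(
        config=config, tree=tree, index=index, placements=placements,
        genotypes_true=g_true, genotypes=g, observed=obs,
        masked_tips=masked_tips, loss_events=loss_events,
        mutation_events=mutation_events,
    )


SCENARIOS: dict[str, dict] = {
    # coalescent trees, infinite-sites placement by branch length
    "scenario1": dict(tips=10, tree_generator="coalescent"),
    "scenario2": dict(tips=50, tree_generator="coalescent"),
    # as above with mutation loss
    "scenario3": dict(tips=10, tree_generator="coalescent", loss_rate=0.1,
                      loss_cap=1),
    "scenario4": dict(tips=50, tree_generator="coalescent", loss_rate=0.1,
                      loss_cap=1),
    # model-based placement on random-split trees
    "scenario5": dict(tips=10, tree_generator="random-split", mode="ternary"),
    "scenario6": dict(tips=50, tree_generator="random-split", mode="ternary"),
    # finite-sites histories
    "scenario7": dict(tips=10, tree_generator="coalescent", finite_sites=True,
                      rate01=100.0, rate10=1.0),
    "scenario8": dict(tips=50, tree_generator="coalescent", finite_sites=True,
                      rate01=100.0, rate10=1.0),
    # scalability-style setting (scaled down by default; override sites/tips)
    "scenario9": dict(tips=500, sites=1000, tree_generator="coalescent",
                      alpha=0.1, beta=0.1),
}

# parameter grids explored in the scenario sweeps
GRID_ALPHA = (0.0, 0.05, 0.1)
GRID_BETA = (0.0, 0.1, 0.25, 0.5)
GRID_MISSING = (0.0, 0.1, 0.2)
GRID_SITES = (20, 40, 80)
GRID_LOSS_RATE = (0.1, 0.2)
GRID_LOSS_CAP = (1, 2)
GRID_RATE10 = (1.0, 10.0, 100.0)


def scenario_config(name: str, **overrides) -> SimulationConfig:
    """Named scenario defaults, optionally overridden (alpha, beta, sites...)."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    kwargs = dict(SCENARIOS[name])
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)
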