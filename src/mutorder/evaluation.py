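"""Accuracy metrics comparing inferred placements and orders to truth.

All metrics are ratios with their numerator/denominator counts retained so
replicates can be pooled by summing counts rather than averaging ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .inference import CredibleSet
from .phylogeny import CladeIndex

__all__ = [
    "Ratio",
    "EvaluationResult",
    "location_accuracy",
    "order_accuracy",
    "adjacent_order_accuracy",
    "credible_set_accuracy",
    "pool",
]


@dataclass(frozen=True)
class Ratio:
    numerator: int
    denominator: int

    @property
    def value(self) -> float:
        if self.denominator == 0:
            return math.nan
        return self.numerator / self.denominator

    def __add__(self, other: "Ratio") -> "Ratio":
        return Ratio(self.numerator + other.numerator,
                     self.denominator + other.denominator)


def pool(ratios: list[Ratio]) -> Ratio:
    """Pool replicates by summing counts (not averaging per-replicate ratios)."""
    total = Ratio(0, 0)
    for r in ratios:
        total = total + r
    return total


@dataclass(frozen=True)
class EvaluationResult:
    location: Ratio
    order: Ratio
    adjacent_order: Ratio
    credible_set: Ratio | None = None


def _as_branches(placements) -> list[int]:
    out = []
    for p in placements:
        out.append(int(p if isinstance(p, (int, np.integer)) else p.branch))
    return out


def location_accuracy(truth, inferred) -> Ratio:
    """Fraction of sites whose inferred branch equals the true branch.

    Sites whose true branch is undefined (< 0, e.g. a finite-sites history
    with no mutation) are excluded from the denominator.
    """
    t = _as_branches(truth)
    f = _as_branches(inferred)
    if len(t) != len(f):
        raise ValueError("truth and inferred cover different site sets")
    pairs = [(a, b) for a, b in zip(t, f) if a >= 0]
    num = sum(1 for a, b in pairs if a == b)
    return Ratio(num, len(pairs))


def _relation(a: int, b: int, index: CladeIndex) -> str:
    if a == b:
        return "same"
    if index.is_earlier(a, b):
        return "before"
    if index.is_earlier(b, a):
        return "after"
    return "incomparable"


def order_accuracy(truth, inferred, index: CladeIndex,
                   include_same_branch: bool = True) -> Ratio:
    """Pairwise order accuracy over all ancestor-descendant true pairs.

    A truly ordered pair is counted correct only when inferred with the same
    strict direction (both mutations inferred on one branch is incorrect);
    a truly same-branch pair is correct iff inferred on one common branch.
    """
    t = _as_branches(truth)
    f = _as_branches(inferred)
    if len(t) != len(f):
        raise ValueError("truth and inferred cover different site sets")
    num = den = 0
    for i in range(len(t)):
        for j in range(i + 1, len(t)):
            if t[i] < 0 or t[j] < 0:
                continue
            rel = _relation(t[i], t[j], index)
            if rel == "incomparable":
                continue
            if rel == "same" and not include_same_branch:
                continue
            den += 1
            if rel == "same":
                num += f[i] == f[j]
            else:
                num += _relation(f[i], f[j], index) == rel
    return Ratio(num, den)


def adjacent_order_accuracy(truth, inferred, index: CladeIndex,
                            include_same_branch: bool = True) -> Ratio:
    """Order accuracy restricted to true pairs on adjacent branches.

    Correct when the inferred pair also sits on adjacent branches with the
    same direction; true same-branch pairs (included by default) are correct
    iff inferred on one common branch.
    """
    t = _as_branches(truth)
    f = _as_branches(inferred)
    if len(t) != len(f):
        raise ValueError("truth and inferred cover different site sets")
    num = den = 0
    for i in range(len(t)):
        for j in range(i + 1, len(t)):
            if t[i] < 0 or t[j] < 0:
                continue
            rel = _relation(t[i], t[j], index)
            if rel == "same":
                if not include_same_branch:
                    continue
                den += 1
                num += f[i] == f[j]
                continue
            if rel == "incomparable" or not index.are_adjacent(t[i], t[j]):
                continue
            den += 1
            if (index.are_adjacent(f[i], f[j])
                    and _relation(f[i], f[j], index) == rel):
                num += 1
    return Ratio(num, den)


def credible_set_accuracy(truth, credible_sets: list[CredibleSet]) -> Ratio:
    """Fraction of sites whose true branch lies in the site's credible set."""
    t = _as_branches(truth)
    if len(t) != len(credible_sets):
        raise ValueError("truth and credible sets cover different site sets")
    pairs = [(a, cs) for a, cs in zip(t, credible_sets) if a >= 0]
    num = sum(1 for a, cs in pairs if a in cs.branches)
    return Ratio(num, len(pairs))
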