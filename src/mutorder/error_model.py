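"""Single-cell sequencing error model: conditional probabilities of observed
states given true genotypes, ambiguity weighting, and mutation-matrix I/O.

Observed matrices use integer codes internally: 0/1/2 are genotype states,
``MISSING`` (-1) drops the cell for that site, ``AMBIGUOUS`` (-2) keeps it
with a weight vector over possible states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "AMBIGUOUS",
    "ErrorRates",
    "ObservedMatrix",
    "error_matrix",
    "ambiguity_weights",
    "site_log_likelihood",
    "per_cell_state_loglik",
    "read_matrix",
    "write_matrix",
]

MISSING = -1
AMBIGUOUS = -2

_TOKEN_TO_CODE = {"0": 0, "1": 1, "2": 2, "-": MISSING, "?": AMBIGUOUS}
_CODE_TO_TOKEN = {v: k for k, v in _TOKEN_TO_CODE.items()}

LOG_ZERO = -np.inf


@dataclass(frozen=True)
class ErrorRates:
    """False positive probability ``alpha`` and false negative ``beta``.

    Scalars are broadcast over all sites and cells; arrays must be I x J.
    The ternary model additionally requires alpha + alpha*beta/2 <= 1.
    """

    alpha: float | np.ndarray
    beta: float | np.ndarray

    def __post_init__(self) -> None:
        a, b = np.asarray(self.alpha), np.asarray(self.beta)
        if np.any(a < 0) or np.any(a > 1) or np.any(b < 0) or np.any(b > 1):
            raise ValueError("alpha and beta must lie in [0, 1]")

    def at(self, site: int, cell: int) -> tuple[float, float]:
        a, b = np.asarray(self.alpha), np.asarray(self.beta)
        av = float(a[site, cell]) if a.ndim == 2 else float(a)
        bv = float(b[site, cell]) if b.ndim == 2 else float(b)
        return av, bv


def error_matrix(rates: ErrorRates, site: int = 0, cell: int = 0,
                 mode: str = "binary") -> np.ndarray:
    """Conditional probability matrix N[true, observed] for one site/cell."""
    a, b = rates.at(site, cell)
    if mode == "binary":
        return np.array([[1.0 - a, a], [b, 1.0 - b]])
    if mode == "ternary":
        r0 = 1.0 - a - a * b / 2.0
        if r0 < -1e-12:
            raise ValueError(
                f"invalid ternary rates: alpha + alpha*beta/2 > 1 (alpha={a}, beta={b})"
            )
        return np.array([
            [max(r0, 0.0), a, a * b / 2.0],
            [b / 2.0, 1.0 - b, b / 2.0],
            [0.0, 0.0, 1.0],
        ])
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class ObservedMatrix:
    """An I x J observed mutation matrix with site and cell labels."""

    data: np.ndarray  # int8 codes
    site_labels: tuple[str, ...]
    cell_labels: tuple[str, ...]
    mode: str = "binary"
    ambiguity: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.shape != (len(self.site_labels), len(self.cell_labels)):
            raise ValueError("data shape does not match labels")
        if self.mode == "binary" and np.any(self.data == 2):
            raise ValueError("binary matrix contains state 2")
        valid = {0, 1, 2, MISSING, AMBIGUOUS}
        if not set(np.unique(self.data)) <= valid:
            raise ValueError("invalid state codes in matrix")

    @property
    def n_sites(self) -> int:
        return self.data.shape[0]

    @property
    def n_cells(self) -> int:
        return self.data.shape[1]

    def missing_cells(self, site: int) -> list[str]:
        row = self.data[site]
        return [self.cell_labels[j] for j in np.flatnonzero(row == MISSING)]


def ambiguity_weights(mode: str, override: np.ndarray | None = None) -> np.ndarray:
    """Default (uniform) weight vector over the mode's states for '?' entries."""
    k = 2 if mode == "binary" else 3
    if override is not None:
        w = np.asarray(override, dtype=float)
        if w.shape != (k,) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("ambiguity weights must be a length-k simplex vector")
        return w
    return np.full(k, 1.0 / k)


def per_cell_state_loglik(obs_row: np.ndarray, rates: ErrorRates, site: int,
                          mode: str,
                          ambiguity: dict[tuple[int, int], np.ndarray] | None = None,
                          cells: np.ndarray | None = None) -> np.ndarray:
    """log P(observation_j | true state g) for each kept cell and each g.

    Returns an array of shape (n_kept_cells, n_states); callers sum rows
    according to a candidate genotype vector.  ``cells`` selects column
    indices (defaults to all non-missing entries of ``obs_row``).
    """
    n_states = 2 if mode == "binary" else 3
    if cells is None:
        cells = np.flatnonzero(obs_row != MISSING)
    out = np.empty((len(cells), n_states))
    default_w = ambiguity_weights(mode)
    with np.errstate(divide="ignore"):
        for k, j in enumerate(cells):
            n = error_matrix(rates, site, int(j), mode)
            s = int(obs_row[j])
            if s == AMBIGUOUS:
                w = default_w
                if ambiguity and (site, int(j)) in ambiguity:
                    w = ambiguity_weights(mode, ambiguity[(site, int(j))])
                out[k] = np.log(n @ w)
            else:
                out[k] = np.log(n[:, s])
    return out


def site_log_likelihood(obs_row: np.ndarray, genotypes: np.ndarray,
                        rates: ErrorRates, site: int, mode: str,
                        ambiguity: dict[tuple[int, int], np.ndarray] | None = None,
                        cells: np.ndarray | None = None) -> float:
    """log P(observed row | true genotypes) over the kept cells.

    Missing cells are excluded; ambiguous cells contribute a weighted sum
    over their possible observed states.  Returns ``-inf`` when the data are
    impossible under the rates (e.g. a mismatch at alpha = beta = 0).
    """
    if cells is None:
        cells = np.flatnonzero(obs_row != MISSING)
    table = per_cell_state_loglik(obs_row, rates, site, mode, ambiguity, cells)
    g = np.asarray(genotypes)
    if len(g) != len(cells):
        raise ValueError("genotypes must cover exactly the kept cells")
    return float(table[np.arange(len(cells)), g].sum())


def read_matrix(path_or_buffer, mode: str = "binary") -> ObservedMatrix:
    """Read a mutation matrix: header row of cell labels, first column sites.

    Tab-separated by default; commas are autodetected.  Entries must be one
    of ``0 1 2 - ?``; anything else raises with line/column diagnostics.
    """
    df = pd.read_csv(path_or_buffer, sep=None, engine="python", dtype=str,
                     index_col=0, comment="#")
    if df.empty:
        raise ValueError("empty mutation matrix")
    data = np.empty(df.shape, dtype=np.int8)
    for i, (_, row) in enumerate(df.iterrows()):
        for j, val in enumerate(row):
            tok = str(val).strip()
            if tok not in _TOKEN_TO_CODE:
                raise ValueError(
                    f"invalid entry {val!r} at row {df.index[i]!r}, "
                    f"column {df.columns[j]!r}"
                )
            data[i, j] = _TOKEN_TO_CODE[tok]
    return ObservedMatrix(
        data=data,
        site_labels=tuple(str(s) for s in df.index),
        cell_labels=tuple(str(c) for c in df.columns),
        mode=mode,
    )


def write_matrix(matrix: ObservedMatrix, path, header_comment: str | None = None) -> None:
    """Write the matrix in the TSV dialect accepted by :func:`read_matrix`."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("site\t" + "\t".join(matrix.cell_labels) + "\n")
        for i, lab in enumerate(matrix.site_labels):
            toks = [_CODE_TO_TOKEN[int(v)] for v in matrix.data[i]]
            fh.write(lab + "\t" + "\t".join(toks) + "\n")
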