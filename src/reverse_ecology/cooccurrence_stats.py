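"""Species co-occurrence and its association with interaction matrices.

Co-occurrence across samples is summarised by the Jaccard similarity of
presence/absence profiles; the association between a co-occurrence matrix
and an interaction matrix is tested with the Mantel permutation test.

The Mantel statistic used here is the Pearson correlation over *all*
``n(n-1)`` off-diagonal cells, so it applies to the asymmetric interaction
matrices as well as to symmetric similarity matrices; the null distribution
permutes rows and columns of the second matrix jointly, preserving its
internal structure.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass
from typing import Literal, TextIO

import numpy as np
import pandas as pd

from .errors import FormatError, ReverseEcologyError


@dataclass
class AbundanceTable:
    """Species×sample non-negative abundances (rows species, columns samples)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise FormatError("species and sample ids must be unique")
        if (self.data.to_numpy() < 0).any():
            raise FormatError("abundances must be non-negative")

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @classmethod
    def from_tsv(cls, stream: TextIO) -> "AbundanceTable":
        df = pd.read_csv(stream, sep="\t", index_col=0)
        return cls(df.astype(float))

    def write_tsv(self, stream: TextIO) -> None:
        self.data.to_csv(stream, sep="\t")


def jaccard_cooccurrence(
    table: AbundanceTable, presence_threshold: float = 0.0
) -> pd.DataFrame:
    """Jaccard similarity of species presence profiles across samples.

    A species is present in a sample when its abundance strictly exceeds
    ``presence_threshold`` (default 0: any positive abundance counts).
    ``similarity[i, j]`` = |samples with both| / |samples with either|;
    pairs present nowhere score 0 by convention.  Species absent from every
    sample trigger a warning but are kept with zeros off-diagonal.
    """
    if len(table.species_ids) < 2:
        raise ReverseEcologyError("need at least two species")
    if len(table.sample_ids) < 1:
        raise ReverseEcologyError("need at least one sample")
    if presence_threshold < 0:
        raise ReverseEcologyError("presence_threshold must be non-negative")
    present = (table.data.to_numpy() > presence_threshold).astype(np.int64)
    counts = present.sum(axis=1)
    absent = [s for s, c in zip(table.species_ids, counts) if c == 0]
    if absent:
        warnings.warn(
            f"species present in no sample: {', '.join(absent)}", stacklevel=2
        )
    inter = present @ present.T
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(sim, (counts > 0).astype(float))
    return pd.DataFrame(sim, index=table.species_ids, columns=table.species_ids)


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    rng_seed: int
    alternative: str = "two-sided"

    def to_json(self) -> str:
        return json.dumps(
            {
                "r": self.r,
                "p": self.p,
                "n_perm": self.n_perm,
                "rng_seed": self.rng_seed,
                "alternative": self.alternative,
            },
            indent=1,
        )


def _offdiag(m: np.ndarray) -> np.ndarray:
    mask = ~np.eye(m.shape[0], dtype=bool)
    return m[mask]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ReverseEcologyError(
            "constant off-diagonal entries: Mantel correlation undefined"
        )
    return float((xc @ yc) / denom)


def _permuted_correlations(
    x: np.ndarray, m2: np.ndarray, perms: np.ndarray
) -> np.ndarray:
    """Pearson r of x against each jointly row/column-permuted copy of m2."""
    n = m2.shape[0]
    mask = ~np.eye(n, dtype=bool)
    permuted = m2[perms[:, :, None], perms[:, None, :]]  # (k, n, n)
    y = permuted[:, mask]  # (k, n(n-1))
    xc = x - x.mean()
    yc = y - y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc @ xc) * (yc * yc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (yc @ xc) / np.maximum(denom, 1e-300), 0.0)


def mantel_test(
    m1: np.ndarray,
    m2: np.ndarray,
    n_perm: int = 999,
    rng_seed: int = 0,
    alternative: Literal["two-sided", "greater", "less"] = "two-sided",
    exact: bool = False,
) -> MantelResult:
    """Mantel permutation test between two square matrices.

    ``r`` is the Pearson correlation over all off-diagonal entries.  The
    null permutes the rows and columns of ``m2`` jointly.  With
    ``exact=True`` all ``n!`` permutations are enumerated (n ≤ 8) and ``p``
    is the exact fraction (the identity permutation included); otherwise
    ``n_perm`` random permutations are drawn and the add-one estimator
    ``p = (1 + exceedances) / (1 + n_perm)`` is used.
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.ndim != 2 or m1.shape[0] != m1.shape[1] or m1.shape != m2.shape:
        raise ReverseEcologyError("m1 and m2 must be square matrices of equal shape")
    n = m1.shape[0]
    if n < 4:
        raise ReverseEcologyError("need at least a 4x4 matrix")
    if not exact and n_perm < 99:
        raise ReverseEcologyError("n_perm must be at least 99")

    x = _offdiag(m1)
    r_obs = _pearson(x, _offdiag(m2))  # raises if either side is constant

    tol = 1e-12
    if exact:
        if n > 8:
            raise ReverseEcologyError("exact enumeration limited to n <= 8")
        perms = np.array(list(itertools.permutations(range(n))))
        null_r = _permuted_correlations(x, m2, perms)
        exceed = _count_exceed(null_r, r_obs, alternative, tol)
        return MantelResult(r_obs, exceed / len(perms), len(perms), rng_seed, alternative)

    rng = np.random.default_rng(rng_seed)
    perms = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    null_r = _permuted_correlations(x, m2, perms)
    exceed = _count_exceed(null_r, r_obs, alternative, tol)
    return MantelResult(
        r_obs, (1 + exceed) / (1 + n_perm), n_perm, rng_seed, alternative
    )


def _count_exceed(
    null_r: np.ndarray, r_obs: float, alternative: str, tol: float
) -> int:
    if alternative == "two-sided":
        return int((np.abs(null_r) >= abs(r_obs) - tol).sum())
    if alternative == "greater":
        return int((null_r >= r_obs - tol).sum())
    if alternative == "less":
        return int((null_r <= r_obs + tol).sum())
    raise ReverseEcologyError(f"unknown alternative {alternative!r}")


def read_square_tsv(stream: TextIO) -> tuple[list[str], np.ndarray]:
    """Read a labelled square matrix TSV (first column = row ids)."""
    df = pd.read_csv(stream, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise FormatError("matrix TSV is not square")
    return list(df.index), df.to_numpy(dtype=float)
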