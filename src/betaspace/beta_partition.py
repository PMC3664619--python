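"""Pairwise partition of incidence-based beta diversity.

For two sites sharing ``a`` species, with ``b`` and ``c`` species unique to
each, total dissimilarity (the Jaccard complement) splits additively into a
species-replacement part and a richness-difference part::

    beta_total = (b + c) / (a + b + c)
    beta_repl  = 2 * min(b, c) / (a + b + c)
    beta_rich  = |b - c| / (a + b + c)

The identity ``beta_total = beta_repl + beta_rich`` holds exactly: replacement
counts balanced substitutions (each substitution swaps one species for
another, hence the factor 2), and the remainder of ``b + c`` is the surplus of
the richer site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import DistMatrix, IncidenceMatrix

__all__ = ["AbcCounts", "BetaTriple", "pairwise_abc", "beta_components",
           "beta_matrices", "summarize_beta"]


@dataclass(frozen=True)
class AbcCounts:
    a: int  # shared species
    b: int  # unique to first site
    c: int  # unique to second site

    def __post_init__(self):
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("a, b, c must be non-negative")


@dataclass
class BetaTriple:
    """The three pairwise dissimilarity matrices from one incidence matrix."""

    beta_total: DistMatrix
    beta_repl: DistMatrix
    beta_rich: DistMatrix

    def __post_init__(self):
        t, r, q = self.beta_total.values, self.beta_repl.values, self.beta_rich.values
        ok = np.isfinite(t)
        if not np.allclose(t[ok], (r + q)[ok], atol=1e-12, rtol=0):
            raise ValueError("additivity violated: beta_total != beta_repl + beta_rich")


def pairwise_abc(row_j, row_k) -> AbcCounts:
    """Count shared (a) and site-unique (b, c) species for two binary vectors."""
    row_j = np.asarray(row_j)
    row_k = np.asarray(row_k)
    if row_j.shape != row_k.shape:
        raise ValueError("incidence vectors differ in length")
    a = int(np.sum((row_j == 1) & (row_k == 1)))
    b = int(np.sum((row_j == 1) & (row_k == 0)))
    c = int(np.sum((row_j == 0) & (row_k == 1)))
    return AbcCounts(a, b, c)


def beta_components(abc: AbcCounts) -> tuple[float, float, float]:
    """(beta_total, beta_repl, beta_rich) for one pair of sites.

    Raises on ``a + b + c = 0`` (two empty sites): the partition is undefined
    there and silently returning 0 would corrupt downstream matrix tests.
    """
    a, b, c = abc.a, abc.b, abc.c
    s = a + b + c
    if s == 0:
        raise ValueError("beta components undefined for a pair of empty sites (a+b+c=0)")
    return (b + c) / s, 2 * min(b, c) / s, abs(b - c) / s


def beta_matrices(inc: IncidenceMatrix, *, tolerant: bool = False) -> BetaTriple:
    """All-pairs beta partition of an incidence matrix.

    Parameters
    ----------
    inc
        Binary site x species matrix; abundances must be binarised upstream.
    tolerant
        If True, pairs of empty sites yield NaN instead of raising; summaries
        then skip those pairs.
    """
    if inc.n_sites < 2:
        raise ValueError("need at least 2 sites for pairwise dissimilarity")
    X = inc.values.astype(float)
    shared = X @ X.T                       # a
    rich = X.sum(axis=1)                   # per-site richness
    b = rich[:, None] - shared             # unique to row site
    c = rich[None, :] - shared             # unique to column site
    s = shared + b + c
    empty_pair = s == 0
    if empty_pair.any() and not tolerant:
        i, j = np.argwhere(np.triu(empty_pair, k=1))[0]
        raise ValueError(
            f"pair of empty sites ({inc.site_ids[i]!r}, {inc.site_ids[j]!r}): "
            "beta components undefined (pass tolerant=True to emit NaN)"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        total = (b + c) / s
        repl = 2 * np.minimum(b, c) / s
        richd = np.abs(b - c) / s
    for m in (total, repl, richd):
        m[empty_pair] = np.nan
        np.fill_diagonal(m, 0.0)
    labels = list(inc.site_ids)
    return BetaTriple(DistMatrix(labels, total), DistMatrix(labels, repl),
                      DistMatrix(labels, richd))


def summarize_beta(bt: BetaTriple) -> dict[str, dict[str, float]]:
    """Mean and sample SD over the n(n-1)/2 unordered pairs of each component."""
    out = {}
    for name, dm in (("beta_total", bt.beta_total), ("beta_repl", bt.beta_repl),
                     ("beta_rich", bt.beta_rich)):
        v = dm.condensed()
        v = v[np.isfinite(v)]
        out[name] = {
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
            "n_pairs": int(v.size),
        }
    return out
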