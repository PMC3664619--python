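"""Distance decay of community similarity: matrix regression and Mantel test.

Dissimilarity is regressed on geographic distance over the n(n-1)/2
unordered site pairs (descriptive OLS — the pairs are not independent, so no
standard errors are reported), and the association between the two matrices
is tested by Mantel permutation: rows and columns of one matrix are permuted
simultaneously and the Pearson correlation of the off-diagonal entries is
recomputed.  For n <= 7 an exhaustive mode enumerates all n! relabellings.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core_data import DistMatrix, SiteTable

__all__ = ["DecayResult", "geo_distance", "mantel"]


@dataclass
class DecayResult:
    intercept: float
    slope: float          # per km when D2 is a km distance matrix
    mantel_r: float
    perm_p: float
    n_perm: int
    tail: str             # "directional" | "two-sided"


def geo_distance(sites: SiteTable) -> DistMatrix:
    """Pairwise Euclidean distances (km) between projected site coordinates."""
    return DistMatrix(list(sites.site_ids), squareform(pdist(sites.coords())))


def mantel(D1: DistMatrix, D2: DistMatrix, n_perm: int = 1000,
           seed: int | None = None, tail: str = "directional",
           exhaustive: bool = False) -> DecayResult:
    """Mantel association between two distance matrices, with decay regression.

    ``mantel_r`` is the Pearson correlation over unordered pairs and the
    intercept/slope come from the OLS regression of D1 entries on D2 entries
    (so pass the dissimilarity as ``D1`` and geographic distance as ``D2``
    for a distance-decay fit).  The default test is directional: one-tailed
    in the sign of the observed r; ``tail="two-sided"`` compares |r|.
    ``exhaustive=True`` (n <= 7) replaces Monte-Carlo sampling with full
    enumeration of the n! relabellings of ``D1``.
    """
    if D1.labels != D2.labels:
        raise ValueError("mantel requires identically ordered site labels")
    n = D1.n
    if n < 4:
        raise ValueError("mantel needs at least 4 sites")
    if tail not in ("directional", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")
    v1, v2 = D1.condensed(), D2.condensed()
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("zero variance in off-diagonal entries")
    r_obs = float(np.corrcoef(v1, v2)[0, 1])
    slope, intercept = np.polyfit(v2, v1, 1)

    def perm_r(order: np.ndarray) -> float:
        vp = D1.values[np.ix_(order, order)][np.triu_indices(n, k=1)]
        return float(np.corrcoef(vp, v2)[0, 1])

    def exceeds(rp: float) -> bool:
        if tail == "two-sided":
            return abs(rp) >= abs(r_obs) - 1e-12
        return rp >= r_obs - 1e-12 if r_obs >= 0 else rp <= r_obs + 1e-12

    if exhaustive:
        if n > 7:
            raise ValueError("exhaustive enumeration limited to n <= 7")
        hits = sum(exceeds(perm_r(np.array(p)))
                   for p in itertools.permutations(range(n)))
        p_val = hits / math.factorial(n)
        n_used = math.factorial(n)
    else:
        rng = np.random.default_rng(seed)
        hits = sum(exceeds(perm_r(rng.permutation(n))) for _ in range(n_perm))
        p_val = (hits + 1) / (n_perm + 1)
        n_used = n_perm
    return DecayResult(float(intercept), float(slope), r_obs, p_val, n_used, tail)
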