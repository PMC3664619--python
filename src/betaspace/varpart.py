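"""Two-set variation partitioning of a dissimilarity matrix.

Three constrained ordinations — environment alone, space alone, both — give
three adjusted R^2 values; their differences split total variation into pure
environmental [a], spatially structured environmental [b], pure spatial [c]
and unexplained [d] fractions::

    [a] = adjR2(env+spa) - adjR2(spa)
    [c] = adjR2(env+spa) - adjR2(env)
    [b] = adjR2(env) + adjR2(spa) - adjR2(env+spa)
    [d] = 1 - adjR2(env+spa)

Small negative fractions are legitimate sampling artefacts of the adjustment
and are reported as-is (with a warning), never clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cap_ordination import CapFit, cap_fit
from .core_data import DistMatrix

__all__ = ["VarPartResult", "varpart2", "fractions_from_adj_r2"]


@dataclass
class VarPartResult:
    adj_r2_env: float
    adj_r2_spatial: float
    adj_r2_both: float
    pure_env: float        # [a]
    shared: float          # [b]
    pure_spatial: float    # [c]
    unexplained: float     # [d]
    fit_env: CapFit | None = None
    fit_spatial: CapFit | None = None
    fit_both: CapFit | None = None

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("adj_r2_env", "adj_r2_spatial", "adj_r2_both",
                 "pure_env", "shared", "pure_spatial", "unexplained")}


def fractions_from_adj_r2(adj_env: float, adj_spatial: float,
                          adj_both: float) -> VarPartResult:
    """Pure/shared/unexplained fractions from the three model adjusted R^2."""
    a = adj_both - adj_spatial
    c = adj_both - adj_env
    b = adj_env + adj_spatial - adj_both
    d = 1 - adj_both
    if min(a, b, c) < 0:
        warnings.warn("negative variation-partitioning fraction (sampling artefact "
                      "of adjusted R^2); reported unclipped", stacklevel=3)
    return VarPartResult(adj_env, adj_spatial, adj_both, a, b, c, d)


def varpart2(beta: DistMatrix, X_env, X_spatial, n_perm: int = 0,
             seed: int | None = None) -> VarPartResult:
    """Partition variation in ``beta`` between two predictor sets.

    Each adjusted R^2 comes from a constrained ordination of the respective
    predictor set; permutation tests (if ``n_perm > 0``) are run for the
    three full models only, not for individual fractions.
    """
    env_empty = X_env is None or np.size(X_env) == 0
    spa_empty = X_spatial is None or np.size(X_spatial) == 0
    if env_empty and spa_empty:
        raise ValueError("both predictor sets are empty")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**31, size=3)

    def fit(X, s):
        return cap_fit(beta, X, n_perm=n_perm, seed=int(s))

    if env_empty:
        fs = fit(X_spatial, seeds[1])
        res = fractions_from_adj_r2(0.0, fs.adj_r2, fs.adj_r2)
        res.fit_spatial = res.fit_both = fs
        return res
    if spa_empty:
        fe = fit(X_env, seeds[0])
        res = fractions_from_adj_r2(fe.adj_r2, 0.0, fe.adj_r2)
        res.fit_env = res.fit_both = fe
        return res
    Xe = X_env if isinstance(X_env, pd.DataFrame) else pd.DataFrame(np.asarray(X_env))
    Xs = (X_spatial if isinstance(X_spatial, pd.DataFrame)
          else pd.DataFrame(np.asarray(X_spatial)))
    Xs = Xs.copy()
    Xs.columns = [f"spa_{c}" for c in Xs.columns]
    Xe = Xe.copy()
    Xe.index = Xs.index
    both = pd.concat([Xe, Xs], axis=1)
    fe, fs, fb = fit(Xe, seeds[0]), fit(Xs, seeds[1]), fit(both, seeds[2])
    res = fractions_from_adj_r2(fe.adj_r2, fs.adj_r2, fb.adj_r2)
    res.fit_env, res.fit_spatial, res.fit_both = fe, fs, fb
    return res
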