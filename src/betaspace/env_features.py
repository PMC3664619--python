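"""Environmental predictor matrix: transforms, standardisation, climate PCA.

Pipeline order is fixed: log-transform the disturbance index, standardise
every variable to zero mean and unit SD, collapse the five collinear climate
variables (annual precipitation, min/max relative humidity, min/max annual
temperature) to their first two principal components, and assemble the final
predictor table (Litter, NumSpp, Soil_pH, OrgMat, DUrb, Altitude, Slope,
Climate_PC1, Climate_PC2, Disturb).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ClimatePca", "climate_pca", "standardize", "log_disturb",
           "build_env_matrix", "CLIMATE_COLUMNS", "FINAL_COLUMNS"]

CLIMATE_COLUMNS = ["Precipitation", "RH_max", "RH_min", "T_max", "T_min"]
FINAL_COLUMNS = ["Litter", "NumSpp", "Soil_pH", "OrgMat", "DUrb", "Altitude",
                 "Slope", "Climate_PC1", "Climate_PC2", "Disturb"]


@dataclass
class ClimatePca:
    """Correlation-matrix PCA of the climate variables."""

    loadings: pd.DataFrame        # variables x components
    eigenvalues: np.ndarray       # non-increasing
    scores: pd.DataFrame          # sites x components
    variance_fractions: np.ndarray


def standardize(df: pd.DataFrame) -> pd.DataFrame:
    """Column-wise (x - mean) / sd with sample SD (ddof=1)."""
    out = {}
    for col in df.columns:
        v = df[col].to_numpy(dtype=float)
        sd = np.std(v, ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"cannot standardise constant column {col!r}")
        out[col] = (v - v.mean()) / sd
    return pd.DataFrame(out, index=df.index)


def log_disturb(d) -> np.ndarray:
    """ln(d + 1); the +1 offset keeps zero-disturbance cells legal."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("disturbance values must be non-negative")
    return np.log1p(d)


def climate_pca(climate: pd.DataFrame) -> ClimatePca:
    """PCA of the climate table on its correlation matrix.

    Variables are standardised first, so component eigenvalues sum to the
    number of variables.  Sign convention: each component is flipped so that
    its largest-magnitude loading is positive (component signs are otherwise
    arbitrary and would depend on the eigensolver).
    """
    if len(climate) < 3:
        raise ValueError("climate PCA needs at least 3 sites")
    Z = standardize(climate).to_numpy()
    n, p = Z.shape
    # SVD of the standardised data; eigenvalues of the correlation matrix
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eigvals = s**2 / (n - 1)
    loadings = Vt.T
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            U[:, k] *= -1
    scores = U * s
    comp_names = [f"PC{i + 1}" for i in range(p)]
    return ClimatePca(
        loadings=pd.DataFrame(loadings, index=climate.columns, columns=comp_names),
        eigenvalues=eigvals,
        scores=pd.DataFrame(scores, index=climate.index, columns=comp_names),
        variance_fractions=eigvals / eigvals.sum(),
    )


def build_env_matrix(env_raw: pd.DataFrame,
                     climate_columns: list[str] | None = None) -> pd.DataFrame:
    """Assemble the standardised environmental predictor matrix.

    ``env_raw`` must hold the raw field/GIS variables including the five
    climate columns and ``Disturb`` (percent scale).  Returns the final
    ten-column matrix, every column standardised to mean 0 / SD 1.
    """
    climate_columns = climate_columns or CLIMATE_COLUMNS
    missing = [c for c in climate_columns + ["Disturb"] if c not in env_raw.columns]
    if missing:
        raise ValueError(f"environment table lacks required columns: {missing}")
    if env_raw.isna().any().any():
        bad = env_raw.columns[env_raw.isna().any()].tolist()
        raise ValueError(f"missing environmental values in columns {bad}; not imputed")
    work = env_raw.copy()
    work["Disturb"] = log_disturb(work["Disturb"])
    pca = climate_pca(work[climate_columns])
    plain = [c for c in work.columns if c not in climate_columns]
    parts = work[plain].copy()
    parts["Climate_PC1"] = pca.scores["PC1"].to_numpy()
    parts["Climate_PC2"] = pca.scores["PC2"].to_numpy()
    std = standardize(parts)
    order = [c for c in FINAL_COLUMNS if c in std.columns]
    order += [c for c in std.columns if c not in order]
    return std[order]
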