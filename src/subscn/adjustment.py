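"""Covariate adjustment: regress age and intracranial volume out of ROI volumes.

All covariance networks are built on the residuals of an ordinary
least-squares fit of each ROI's volume on [1, age, ICV].  The fit can be
pooled over the two groups entering a comparison (the default — correction
is done once, before permutation, and pooled fitting preserves
exchangeability under the null), pooled over everyone, or per group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .io import ROIVolumeTable

__all__ = ["ResidualTable", "FitError", "residualize"]

FitScope = Literal["per_group", "pooled_pair", "pooled_all"]


class FitError(ValueError):
    """Raised for rank-deficient or under-determined covariate designs."""


@dataclass
class ResidualTable:
    """Covariate-adjusted volumes.

    ``residuals`` shares the index/columns of the source volume table
    (mm^3, mean ~ 0 per ROI within each fitting sample); ``coefficients``
    records the per-ROI (intercept, slope_age, slope_icv) for audit — the
    intercept refers to mean-centered covariates.
    """

    participants: pd.DataFrame
    residuals: pd.DataFrame
    fit_scope: str
    coefficients: pd.DataFrame

    @property
    def roi_names(self) -> list[str]:
        return list(self.residuals.columns)

    def groups(self) -> pd.Series:
        return self.participants["group"]

    def group_matrix(self, group: str) -> np.ndarray:
        """Residual matrix (participants x ROIs) for one group."""
        mask = (self.participants["group"] == group).to_numpy()
        return self.residuals.to_numpy()[mask]


def _ols_residuals(
    y: np.ndarray, age: np.ndarray, icv: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Residuals and coefficients of per-column OLS on [1, age, icv].

    Covariates are mean-centered before fitting; residuals are unaffected
    but the normal equations stay well conditioned with ICV ~ 1e6 mm^3.
    """
    n = y.shape[0]
    if n < 4:
        raise FitError("need at least 4 participants per fitting sample")
    x = np.column_stack([np.ones(n), age - age.mean(), icv - icv.mean()])
    for j, name in ((1, "age"), (2, "icv")):
        if np.ptp(x[:, j]) == 0:
            raise FitError(f"covariate {name!r} is constant in the fitting sample")
    if np.linalg.matrix_rank(x) < 3:
        raise FitError("rank-deficient covariate design (age and icv collinear)")
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ coef, coef


def residualize(table: ROIVolumeTable, fit_scope: FitScope = "pooled_pair") -> ResidualTable:
    """Regress age and ICV out of every ROI volume.

    ``pooled_pair`` and ``pooled_all`` both fit one regression over every
    participant in ``table`` (pass a two-group subset for pooled_pair);
    ``per_group`` fits separately within each group.
    """
    part = table.participants
    if not {"age", "icv"} <= set(part.columns):
        raise FitError("participants lack age/icv covariates")
    y = table.volumes.to_numpy(float)
    age = part["age"].to_numpy(float)
    icv = part["icv"].to_numpy(float)
    rois = table.roi_names

    if fit_scope in ("pooled_pair", "pooled_all"):
        resid, coef = _ols_residuals(y, age, icv)
        coef_df = pd.DataFrame(
            coef.T, index=rois, columns=["intercept", "slope_age", "slope_icv"]
        )
    elif fit_scope == "per_group":
        resid = np.empty_like(y)
        frames = {}
        for g in part["group"].unique():
            mask = (part["group"] == g).to_numpy()
            resid[mask], coef = _ols_residuals(y[mask], age[mask], icv[mask])
            frames[g] = pd.DataFrame(
                coef.T, index=rois, columns=["intercept", "slope_age", "slope_icv"]
            )
        coef_df = pd.concat(frames, names=["group", "roi"])
    else:
        raise ValueError(f"unknown fit_scope {fit_scope!r}")

    residuals = pd.DataFrame(resid, index=table.volumes.index, columns=rois)
    return ResidualTable(part, residuals, fit_scope, coef_df)
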