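"""Fixed-effect design matrices for the phenotype models.

Factors (gender, farm, breed, birth year) are one-hot coded against a
first-level reference; slaughter age (or any numeric column) enters as a
linear covariate.  The design is *fitted* on training rows only, so
validation rows carrying a factor level unseen in training are flagged
(their effect is inestimable) rather than silently extrapolated.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.linalg import qr

__all__ = ["FixedEffectDesign", "AliasedDesignError"]

logger = logging.getLogger(__name__)


class AliasedDesignError(ValueError):
    """Raised when fixed-effect columns are linearly confounded."""


class FixedEffectDesign:
    """Build (and re-apply) a fixed-effect design matrix.

    Parameters
    ----------
    effects:
        Phenotype-table column names to include.  Numeric columns become
        covariates, all others factors.
    """

    def __init__(self, effects: list[str]):
        self.effects = list(effects)
        self.levels_: dict[str, list] = {}
        self.covariates_: list[str] = []
        self.columns_: list[str] = []

    def fit(self, df: pd.DataFrame) -> "FixedEffectDesign":
        self.levels_ = {}
        self.covariates_ = []
        for name in self.effects:
            if name not in df.columns:
                raise KeyError(f"fixed effect column {name!r} not in phenotype table")
            if pd.api.types.is_numeric_dtype(df[name]) and df[name].nunique() > 12:
                self.covariates_.append(name)
            else:
                self.levels_[name] = sorted(df[name].unique().tolist())
        self.columns_ = ["intercept"]
        for name, levels in self.levels_.items():
            self.columns_.extend(f"{name}[{lv}]" for lv in levels[1:])
        self.columns_.extend(self.covariates_)
        X, _ = self.transform(df)
        self._check_rank(X)
        return self

    def _check_rank(self, X: np.ndarray) -> None:
        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
        rank = int((diag > tol).sum())
        if rank < X.shape[1]:
            aliased = [self.columns_[j] for j in piv[rank:]]
            raise AliasedDesignError(
                f"fixed-effect design is rank deficient; aliased columns: {aliased}"
            )

    def transform(self, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Design matrix and a boolean mask of usable rows.

        Rows with factor levels unseen at fit time are masked out with a
        warning; their design rows are zero-filled placeholders.
        """
        n = len(df)
        usable = np.ones(n, dtype=bool)
        cols = [np.ones(n)]
        for name, levels in self.levels_.items():
            vals = df[name].to_numpy()
            known = np.isin(vals, np.asarray(levels, dtype=vals.dtype))
            if not known.all():
                unseen = sorted(set(vals[~known]))
                warnings.warn(
                    f"{(~known).sum()} rows dropped: unseen {name} levels {unseen}",
                    stacklevel=2,
                )
                usable &= known
            for lv in levels[1:]:
                cols.append((vals == lv).astype(float))
        for name in self.covariates_:
            cols.append(df[name].to_numpy(dtype=float))
        X = np.column_stack(cols)
        X[~usable] = 0.0
        return X, usable

    @property
    def n_columns(self) -> int:
        return len(self.columns_)
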