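"""Anterior-posterior corneal radius ratio and the C-factor correction.

Myopic excimer ablation flattens only the anterior corneal surface, so the
ratio of the anterior to the posterior radius of curvature (the A-P ratio,
about 7.5/6.3 ~ 1.19 in unoperated eyes) rises with the amount of
correction.  Because standard keratometry infers total corneal power from
the anterior surface alone through the keratometric index, the double-K
prediction error grows with the A-P ratio.  The C-factor is the linear
calibration of that error:

    C = slope * (A-P ratio) + intercept        [diopters]

with the published calibration slope 3.28 D per unit ratio and intercept
-4.00 D.  Adding C to the double-K predicted refraction (or subtracting it
from the target when solving for power) yields the ISS prediction.

Calibration follows the statsmodels idiom: :class:`CFactorRegression` is a
model built from per-eye (ratio, double-K prediction error) data; its
:meth:`~CFactorRegression.fit` returns a :class:`CFactorRegressionResults`
carrying coefficient estimates, standard errors, the Pearson correlation
and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "ap_ratio",
    "CFactorModel",
    "DEFAULT_C_FACTOR",
    "CFactorRegression",
    "CFactorRegressionResults",
    "fit_c_factor",
]


def ap_ratio(r_anterior_mm: float, r_posterior_mm: float) -> float:
    """Anterior/posterior corneal radius ratio (dimensionless), from the
    3.0 mm-zone mean radii."""
    if r_anterior_mm <= 0 or r_posterior_mm <= 0:
        raise ValueError(
            f"radii must be positive, got anterior={r_anterior_mm}, "
            f"posterior={r_posterior_mm}"
        )
    return r_anterior_mm / r_posterior_mm


@dataclass(frozen=True)
class CFactorModel:
    """Coefficients of the C-factor law C = slope*ratio + intercept (D)."""

    slope: float
    intercept: float
    n: int | None = None
    pearson_r: float | None = None
    p_value: float | None = None
    provenance: str = "unspecified"

    def apply(self, ratio: float | np.ndarray) -> float | np.ndarray:
        """C-factor (D) at a given A-P ratio."""
        arr = np.asarray(ratio, dtype=float)
        if np.any(arr <= 0):
            raise ValueError("A-P ratio must be positive")
        out = self.slope * arr + self.intercept
        return out if isinstance(ratio, np.ndarray) else float(out)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(doc + "\n")
        return doc

    @classmethod
    def from_json(cls, source: str | Path) -> "CFactorModel":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))


#: The published calibration (30 post-LASIK eyes, one IOL model).
DEFAULT_C_FACTOR = CFactorModel(
    slope=3.28,
    intercept=-4.00,
    n=30,
    pearson_r=0.678,
    provenance="published 30-eye calibration",
)


def c_factor_apply(model: CFactorModel, ratio: float) -> float:
    """Functional alias for :meth:`CFactorModel.apply`."""
    return float(model.apply(ratio))


class CFactorRegression:
    """Ordinary-least-squares calibration of the C-factor law.

    Parameters
    ----------
    ratio : array-like
        Per-eye A-P ratios (dimensionless).
    error_d : array-like
        Per-eye double-K prediction errors, actual minus predicted (D).
    """

    def __init__(self, ratio: Sequence[float], error_d: Sequence[float]):
        ratio = np.asarray(ratio, dtype=float)
        error_d = np.asarray(error_d, dtype=float)
        if ratio.shape != error_d.shape or ratio.ndim != 1:
            raise ValueError("ratio and error_d must be equal-length 1-d arrays")
        if ratio.size < 3:
            raise ValueError(f"need at least 3 calibration eyes, got {ratio.size}")
        if np.ptp(ratio) == 0:
            raise ValueError("zero variance in A-P ratio: regression is degenerate")
        self.ratio = ratio
        self.error_d = error_d

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        ratio_col: str = "ap_ratio",
        error_col: str = "double_k_error_d",
    ) -> "CFactorRegression":
        return cls(data[ratio_col].to_numpy(), data[error_col].to_numpy())

    def fit(self) -> "CFactorRegressionResults":
        X = sm.add_constant(self.ratio)
        ols = sm.OLS(self.error_d, X).fit()
        r, p = scipy.stats.pearsonr(self.ratio, self.error_d)
        return CFactorRegressionResults(self, ols, float(r), float(p))


class CFactorRegressionResults:
    """Fitted C-factor calibration: coefficient estimates, uncertainties and
    correlation diagnostics."""

    def __init__(self, model: CFactorRegression, ols_results, pearson_r, p_value):
        self.model = model
        self._ols = ols_results
        self.pearson_r = pearson_r
        self.p_value = p_value

    @property
    def slope(self) -> float:
        return float(self._ols.params[1])

    @property
    def intercept(self) -> float:
        return float(self._ols.params[0])

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            {"intercept": self.intercept, "slope": self.slope}, name="coef"
        )

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            {"intercept": float(self._ols.bse[0]), "slope": float(self._ols.bse[1])},
            name="std err",
        )

    @property
    def nobs(self) -> int:
        return int(self._ols.nobs)

    @property
    def rsquared(self) -> float:
        return float(self._ols.rsquared)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = np.asarray(self._ols.conf_int(alpha))
        return pd.DataFrame(
            ci, index=["intercept", "slope"], columns=["lower", "upper"]
        )

    def as_model(self, provenance: str = "fitted") -> CFactorModel:
        """Freeze the fit into the coefficient container used downstream."""
        return CFactorModel(
            slope=self.slope,
            intercept=self.intercept,
            n=self.nobs,
            pearson_r=self.pearson_r,
            p_value=self.p_value,
            provenance=provenance,
        )

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "C-factor calibration (OLS)",
            "=" * 54,
            f"n eyes                 {self.nobs:d}",
            f"slope     (D/ratio)    {self.slope: .4f}  SE {self.bse['slope']:.4f}  "
            f"95% CI [{ci.loc['slope', 'lower']: .4f}, {ci.loc['slope', 'upper']: .4f}]",
            f"intercept (D)          {self.intercept: .4f}  SE {self.bse['intercept']:.4f}  "
            f"95% CI [{ci.loc['intercept', 'lower']: .4f}, {ci.loc['intercept', 'upper']: .4f}]",
            f"Pearson r              {self.pearson_r: .4f}  (p = {self.p_value:.3g})",
            f"R-squared              {self.rsquared: .4f}",
            "=" * 54,
            f"C = {self.slope:.2f} x A-P ratio + ({self.intercept:.2f})",
        ]
        return "\n".join(lines)


def fit_c_factor(
    ratio: Sequence[float], error_d: Sequence[float], provenance: str = "fitted"
) -> CFactorModel:
    """One-shot calibration: OLS fit of error against A-P ratio, returned as
    a :class:`CFactorModel` with Pearson r and its two-sided p attached."""
    return CFactorRegression(ratio, error_d).fit().as_model(provenance)
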