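"""Expected-intake model and residual feed intake.

Within each period, expected intake is a single multiple regression with
intercept,

    DMI_i = b0 + B1 * MBW_i + B2 * ADG_i + e_i,

fitted across the cohort by ordinary least squares (Koch-style residual feed
intake).  An animal's RFI is the residual: observed DMI minus expected.  By
the OLS identities the cohort mean RFI is zero and RFI is uncorrelated with
both regressors; lower RFI means the animal eats less than its body size and
growth predict, i.e. it is more feed-efficient.

The size regressor defaults to metabolic body weight (MBW = MTBW^0.75);
``size_regressor="mtbw"`` switches to raw mid-test weight for sensitivity
analysis.  Periods are always fitted separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InsufficientDataError, SingularFitError

#: condition number above which the design is treated as collinear
CONDITION_LIMIT = 1e10


@dataclass
class IntakeModel:
    """Fitted expected-intake regression for one period."""

    period: str
    intercept: float      # b0, kg DM/day
    b1: float             # kg DM/day per kg^0.75 (or per kg if size regressor is mtbw)
    b2: float             # kg DM/day per kg/day of gain
    resid_sd: float       # kg DM/day
    r_squared: float
    n: int
    size_regressor: str = "mbw"

    def predict(self, pheno: pd.DataFrame) -> np.ndarray:
        """Expected DMI for each animal in `pheno`."""
        return (
            self.intercept
            + self.b1 * pheno[self.size_regressor].to_numpy()
            + self.b2 * pheno["adg"].to_numpy()
        )


def fit_intake_model(
    pheno: pd.DataFrame, period: str = "", size_regressor: str = "mbw"
) -> IntakeModel:
    """Fit DMI ~ 1 + size + ADG across the cohort of one period."""
    cols = [size_regressor, "adg", "dmi"]
    data = pheno[cols].to_numpy(dtype=float)
    ok = np.all(np.isfinite(data), axis=1)
    data = data[ok]
    n = data.shape[0]
    if n < 4:
        raise InsufficientDataError(
            f"intake model needs >= 4 animals with finite DMI/{size_regressor}/ADG, have {n}"
        )
    X = sm.add_constant(data[:, :2], has_constant="add")
    if np.linalg.cond(X) > CONDITION_LIMIT:
        raise SingularFitError(f"collinear {size_regressor}/ADG design (condition number too large)")
    res = sm.OLS(data[:, 2], X).fit()
    return IntakeModel(
        period=period,
        intercept=float(res.params[0]),
        b1=float(res.params[1]),
        b2=float(res.params[2]),
        resid_sd=float(np.sqrt(res.mse_resid)),
        r_squared=float(res.rsquared),
        n=n,
        size_regressor=size_regressor,
    )


def compute_rfi(pheno: pd.DataFrame, model: IntakeModel) -> pd.DataFrame:
    """Fill the ``rfi`` column: observed DMI minus model-expected DMI."""
    out = pheno.copy()
    out["rfi"] = out["dmi"].to_numpy(dtype=float) - model.predict(out)
    return out


def model_summary(models: list[IntakeModel]) -> pd.DataFrame:
    """Tidy one-row-per-period summary of fitted intake models."""
    return pd.DataFrame(
        [
            {
                "period": m.period,
                "intercept": m.intercept,
                "b1": m.b1,
                "b2": m.b2,
                "resid_sd": m.resid_sd,
                "r_squared": m.r_squared,
                "n": m.n,
                "size_regressor": m.size_regressor,
            }
            for m in models
        ]
    )
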