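"""Temperature adjustment of maximum growth rates.

Maximum growth rates are measured at whatever culture temperature suits each
species, and rates run faster at higher temperatures. To compare growth
capacity across species the analysis uses temperature-adjusted maximum
growth rates: residuals, in log10 units, from an ordinary least-squares
regression of log10(mu_max) on growth temperature. A residual of +1 means a
species grows tenfold faster than expected at its growth temperature.

The regression can be refit on the data at hand (default) or fixed to the
reference coefficients slope 0.0105 log10(h^-1)/degC, intercept -1.2003,
for applying the published convention to new data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: reference coefficients of the published growth-rate vs temperature fit
REFERENCE_SLOPE = 0.0105
REFERENCE_INTERCEPT = -1.2003


@dataclass(frozen=True)
class TempAdjustModel:
    """OLS fit of log10(mu_max) on growth temperature (degC)."""

    slope: float  # log10(h^-1) per degC
    intercept: float  # log10(h^-1)
    r2: float
    n: int

    def predict(self, T):
        return self.slope * np.asarray(T, dtype=float) + self.intercept


#: the published convention, usable without refitting
REFERENCE_MODEL = TempAdjustModel(REFERENCE_SLOPE, REFERENCE_INTERCEPT, 0.11, 618)


def fit_temp_model(mu_max, T) -> TempAdjustModel:
    """Fit log10(mu_max) = slope*T + intercept by OLS over paired values."""
    mu = np.asarray(mu_max, dtype=float)
    t = np.asarray(T, dtype=float)
    if mu.shape != t.shape:
        raise ValueError("mu_max and T must be paired vectors of equal length")
    ok = np.isfinite(mu) & np.isfinite(t)
    mu, t = mu[ok], t[ok]
    if mu.size < 3:
        raise ValueError(f"need at least 3 paired (mu_max, T) values, got {mu.size}")
    if np.any(mu <= 0):
        raise ValueError("mu_max values must be strictly positive")
    if np.ptp(t) == 0:
        raise ValueError("growth temperature has zero variance; slope is unidentifiable")
    y = np.log10(mu)
    if np.ptp(y) == 0:
        # flat response: slope 0, no variance explained
        return TempAdjustModel(0.0, float(y[0]), 0.0, int(y.size))
    res = stats.linregress(t, y)
    return TempAdjustModel(
        float(res.slope), float(res.intercept), float(res.rvalue**2), int(y.size)
    )


def adjust(mu_max, T, model: TempAdjustModel):
    """Temperature-adjusted max growth rate: log10(mu_max) - (slope*T + intercept).

    Missing temperature (or missing mu_max) yields a missing adjusted value;
    such species drop out of growth-rate analyses rather than being imputed.
    """
    mu = np.asarray(mu_max, dtype=float)
    t = np.asarray(T, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(
            np.isfinite(mu) & (mu > 0) & np.isfinite(t),
            np.log10(np.where(mu > 0, mu, np.nan)) - model.predict(t),
            np.nan,
        )
    if g.ndim == 0:
        return float(g)
    return g


def adjust_table(
    species: pd.DataFrame, mode: str = "refit", model: TempAdjustModel | None = None
) -> tuple[pd.DataFrame, TempAdjustModel]:
    """Add a ``g_adj`` column to a species table.

    mode="refit" fits the regression on the table's own paired
    (mu_max, T) values; mode="fixed" applies ``model`` (defaulting to the
    reference coefficients) without refitting.
    """
    if mode not in {"refit", "fixed"}:
        raise ValueError(f"temp_adjust mode must be 'refit' or 'fixed', got {mode!r}")
    if mode == "refit":
        model = fit_temp_model(
            species["mu_max_per_h"].to_numpy(), species["growth_temp_C"].to_numpy()
        )
    elif model is None:
        model = REFERENCE_MODEL
    out = species.copy()
    out["g_adj"] = adjust(
        species["mu_max_per_h"].to_numpy(), species["growth_temp_C"].to_numpy(), model
    )
    return out, model
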