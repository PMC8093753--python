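"""Correlation matrix, AIC model-selection suite, variance partition,
trophic-group separation, and density contours on species-level traits.

All quantitative traits enter the statistics log10-scaled; the
temperature-adjusted maximum growth rate ``g_adj`` is already a log10-scale
residual and enters as-is. Polynomial diameter terms are centered on the
mean of log10 diameter before squaring to reduce collinearity (R-squared,
AIC and df are unaffected by centering).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .taxo_phylo import RegressionModel, ols_fit

#: trait -> transform onto the analysis (log) scale
LOG_TRAITS = ("cell_diameter_um", "genome_size_bp", "rrn_copies", "mu_max_per_h")
DEFAULT_TRAITS = ("g_adj", "cell_diameter_um", "genome_size_bp", "rrn_copies")

TRAIT_LABELS = {
    "g_adj": "Temperature-adjusted max growth rate",
    "cell_diameter_um": "Cell radial diameter",
    "genome_size_bp": "Genome size",
    "rrn_copies": "rRNA operon copy number",
    "mu_max_per_h": "Max growth rate",
}

MODEL_LABELS = (
    "1. growth ~ cell_diam",
    "2. growth ~ genome_size",
    "3. growth ~ cell_diam * genome_size",
    "4. growth ~ cell_diam + cell_diam^2",
    "5. growth ~ genome_size + genome_size^2",
    "6. growth ~ habitat",
    "7. growth ~ (cell_diam + cell_diam^2) + habitat",
    "8. growth ~ (cell_diam + cell_diam^2) * habitat",
    "9. growth ~ (cell_diam + cell_diam^2) * genome_size * habitat",
)


def analysis_scale(table: pd.DataFrame, traits=DEFAULT_TRAITS) -> pd.DataFrame:
    """Return the requested traits on the analysis scale (log10 where needed)."""
    out = {}
    for t in traits:
        if t not in table.columns:
            raise KeyError(f"trait column {t!r} not in table")
        col = pd.to_numeric(table[t], errors="coerce")
        if t in LOG_TRAITS:
            with np.errstate(invalid="ignore", divide="ignore"):
                col = np.log10(col.where(col > 0))
        out[t] = col
    return pd.DataFrame(out, index=table.index)


@dataclass
class CorrelationMatrix:
    """Squared Pearson correlations of log-scaled traits, pairwise-complete."""

    traits: tuple
    r2: pd.DataFrame  # symmetric, NaN diagonal cells where undefined
    n: pd.DataFrame  # species count per pair

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.traits):
            for b in self.traits[i + 1 :]:
                rows.append(
                    {"trait_a": a, "trait_b": b, "r2": self.r2.loc[a, b], "n": self.n.loc[a, b]}
                )
        return pd.DataFrame(rows)


def pairwise_r2(table: pd.DataFrame, traits=DEFAULT_TRAITS) -> CorrelationMatrix:
    """Squared Pearson correlation for each unordered trait pair.

    Each cell uses the rows where both traits are present; cells with fewer
    than 3 complete pairs are reported missing. ``n`` carries the pairwise
    species counts.
    """
    X = analysis_scale(table, traits)
    k = len(traits)
    r2 = pd.DataFrame(np.full((k, k), np.nan), index=traits, columns=traits)
    nmat = pd.DataFrame(np.zeros((k, k), dtype=int), index=traits, columns=traits)
    for i, a in enumerate(traits):
        for j in range(i, k):
            b = traits[j]
            ok = X[a].notna() & X[b].notna()
            n = int(ok.sum())
            nmat.loc[a, b] = nmat.loc[b, a] = n
            if i == j:
                r2.loc[a, b] = 1.0 if n >= 3 else np.nan
                continue
            if n < 3:
                continue
            xa = X.loc[ok, a].to_numpy()
            xb = X.loc[ok, b].to_numpy()
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                continue
            r = np.corrcoef(xa, xb)[0, 1]
            r2.loc[a, b] = r2.loc[b, a] = float(r**2)
    return CorrelationMatrix(tuple(traits), r2, nmat)


def aic(model: RegressionModel) -> float:
    """Gaussian AIC: -2*loglik + 2*(p + 1); the +1 counts the residual variance."""
    if model.rss <= 0:
        raise ValueError("AIC undefined for a degenerate perfect fit (RSS = 0)")
    ll = -0.5 * model.n * (math.log(2.0 * math.pi * model.rss / model.n) + 1.0)
    return -2.0 * ll + 2.0 * (model.p + 1)


@dataclass
class ModelSuiteResult:
    """Nine nested-and-crossed OLS models on a common complete-case row set."""

    models: list = field(default_factory=list)
    labels: tuple = ()
    n: int = 0
    habitat_levels: tuple = ()

    @property
    def best_index(self) -> int:
        """0-based index of the minimum-AIC model."""
        aics = [m.aic for m in self.models]
        return int(np.argmin(aics))

    @property
    def best_label(self) -> str:
        return self.labels[self.best_index]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": list(self.labels),
                "AIC": [m.aic for m in self.models],
                "R2": [m.r2 for m in self.models],
                "df": [m.df_resid for m in self.models],
            }
        )


def _suite_designs(ld, lg, dummies, dummy_names):
    """Design matrices for the nine models; quantitative terms pre-centered."""
    one = np.ones_like(ld)
    ld2 = ld**2
    lg2 = lg**2
    H = dummies  # (n, L-1)

    def hab_cols(prefix=""):
        return [f"{prefix}habitat[{nm}]" for nm in dummy_names]

    designs = {
        0: ([one, ld], ["const", "ld"]),
        1: ([one, lg], ["const", "lg"]),
        2: ([one, ld, lg, ld * lg], ["const", "ld", "lg", "ld:lg"]),
        3: ([one, ld, ld2], ["const", "ld", "ld^2"]),
        4: ([one, lg, lg2], ["const", "lg", "lg^2"]),
    }
    if H is not None:
        designs[5] = ([one] + list(H.T), ["const"] + hab_cols())
        designs[6] = ([one, ld, ld2] + list(H.T), ["const", "ld", "ld^2"] + hab_cols())
        cols8, names8 = [one, ld, ld2], ["const", "ld", "ld^2"]
        for j, nm in enumerate(dummy_names):
            cols8 += [H[:, j], ld * H[:, j], ld2 * H[:, j]]
            names8 += [f"habitat[{nm}]", f"ld:habitat[{nm}]", f"ld^2:habitat[{nm}]"]
        designs[7] = (cols8, names8)
        cols9, names9 = [], []
        for a_col, a_nm in ((one, ""), (ld, "ld:"), (ld2, "ld^2:")):
            for b_col, b_nm in ((one, ""), (lg, "lg:")):
                base = a_col * b_col
                nm_base = (a_nm + b_nm).rstrip(":") or "const"
                cols9.append(base)
                names9.append(nm_base)
                for j, nm in enumerate(dummy_names):
                    cols9.append(base * H[:, j])
                    names9.append(f"{a_nm}{b_nm}habitat[{nm}]")
        designs[8] = (cols9, names9)
    return {k: (np.column_stack(cols), names) for k, (cols, names) in designs.items()}


def fit_model_suite(table: pd.DataFrame, min_n: int = 30) -> ModelSuiteResult:
    """Fit the nine-model suite for g_adj on one complete-case row set.

    Models with successively more terms predict the temperature-adjusted
    maximum growth rate from log10 cell diameter (linear, quadratic), log10
    genome size, and a dummy-coded habitat factor (reference level =
    alphabetically first). All nine models use only the rows where every
    variable is present, so AIC values are commensurate. If habitat has a
    single level the habitat models are skipped with a warning.
    """
    needed = ["g_adj", "cell_diameter_um", "genome_size_bp", "habitat"]
    for c in needed:
        if c not in table.columns:
            raise KeyError(f"model suite requires column {c!r}")
    X = analysis_scale(table, ("g_adj", "cell_diameter_um", "genome_size_bp"))
    df = pd.DataFrame(
        {
            "y": X["g_adj"],
            "ld": X["cell_diameter_um"],
            "lg": X["genome_size_bp"],
            "habitat": table["habitat"],
        }
    ).dropna()
    n = len(df)
    if n < min_n:
        raise ValueError(f"need >= {min_n} complete cases for the model suite, got {n}")
    y = df["y"].to_numpy()
    ld = df["ld"].to_numpy()
    lg = df["lg"].to_numpy()
    ld = ld - ld.mean()
    lg = lg - lg.mean()
    levels = tuple(sorted(df["habitat"].astype(str).unique()))
    if len(levels) < 2:
        warnings.warn("habitat has a single level; habitat models (6-9) skipped")
        dummies, dummy_names = None, []
    else:
        dummy_names = list(levels[1:])  # reference level = alphabetically first
        dummies = np.column_stack(
            [(df["habitat"].astype(str) == lvl).to_numpy(float) for lvl in dummy_names]
        )
    designs = _suite_designs(ld, lg, dummies, dummy_names)
    models, labels = [], []
    for k in sorted(designs):
        Xk, names = designs[k]
        models.append(ols_fit(y, Xk, terms=names))
        labels.append(MODEL_LABELS[k])
    return ModelSuiteResult(models=models, labels=tuple(labels), n=n, habitat_levels=levels)


def variance_partition(suite: ModelSuiteResult) -> dict:
    """Partition model 7's R2 into habitat and quadratic-diameter shares.

    habitat_share = R2(7) - R2(4); diameter_quadratic_share = R2(7) - R2(6);
    total = R2(7). Shares are of total variance in g_adj.
    """
    if len(suite.models) < 7:
        raise ValueError("variance partition requires models 4, 6 and 7")
    r2_4 = suite.models[3].r2
    r2_6 = suite.models[5].r2
    r2_7 = suite.models[6].r2
    return {
        "habitat_share": r2_7 - r2_4,
        "diameter_quadratic_share": r2_7 - r2_6,
        "total": r2_7,
    }


def group_separation(
    table: pd.DataFrame, trait: str = "g_adj", label_col: str = "trophic"
) -> dict:
    """Separation of labelled oligotrophs vs copiotrophs along one trait.

    Positive standardized difference means copiotrophs higher. The overlap
    fraction is the mean, over the two groups, of the fraction of one group
    lying inside the other's central 90% interval.
    """
    if label_col not in table.columns:
        raise ValueError(f"missing label column {label_col!r}")
    vals = analysis_scale(table, (trait,))[trait]
    lab = table[label_col].astype(str)
    olig = vals[(lab == "oligotroph") & vals.notna()].to_numpy()
    copi = vals[(lab == "copiotroph") & vals.notna()].to_numpy()
    if olig.size < 2 or copi.size < 2:
        raise ValueError("need at least 2 labelled species per trophic group")
    mo, mc = float(olig.mean()), float(copi.mean())
    pooled = math.sqrt(
        ((olig.size - 1) * olig.var(ddof=1) + (copi.size - 1) * copi.var(ddof=1))
        / (olig.size + copi.size - 2)
    )
    smd = 0.0 if pooled == 0 else (mc - mo) / pooled

    def frac_inside(x, other):
        lo, hi = np.quantile(other, [0.05, 0.95])
        return float(np.mean((x >= lo) & (x <= hi)))

    overlap = 0.5 * (frac_inside(olig, copi) + frac_inside(copi, olig))
    return {
        "mean_oligotroph": mo,
        "mean_copiotroph": mc,
        "standardized_mean_difference": float(smd),
        "overlap_fraction": overlap,
        "n_oligotroph": int(olig.size),
        "n_copiotroph": int(copi.size),
    }


def density_contours(x, y, levels=(0.25, 0.5, 0.75), gridsize: int = 128) -> dict:
    """Contours of a 2-D Gaussian kernel density at fractions of its maximum.

    Bandwidth per axis follows the bivariate normal-reference rule
    h_j = sigma_j * n^(-1/6). Returns {level: [polyline arrays (m, 2)]} in
    data coordinates; a level of 1.0 degenerates to the mode point.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 20:
        raise ValueError(f"need at least 20 points for density contours, got {n}")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("degenerate (zero-variance) axis")
    hx = sx * n ** (-1.0 / 6.0)
    hy = sy * n ** (-1.0 / 6.0)
    gx = np.linspace(x.min() - 3 * hx, x.max() + 3 * hx, gridsize)
    gy = np.linspace(y.min() - 3 * hy, y.max() + 3 * hy, gridsize)
    wx = np.exp(-0.5 * ((gx[:, None] - x[None, :]) / hx) ** 2)
    wy = np.exp(-0.5 * ((gy[:, None] - y[None, :]) / hy) ** 2)
    dens = (wx @ wy.T) / (n * 2.0 * math.pi * hx * hy)
    dmax = dens.max()
    from skimage import measure

    out = {}
    dx = gx[1] - gx[0]
    dy = gy[1] - gy[0]
    for lv in levels:
        if not 0 < lv <= 1:
            raise ValueError(f"contour level must be in (0, 1], got {lv}")
        if lv == 1.0:
            i, j = np.unravel_index(np.argmax(dens), dens.shape)
            out[lv] = [np.array([[gx[i], gy[j]]])]
            continue
        pieces = []
        for contour in measure.find_contours(dens, lv * dmax):
            pieces.append(
                np.column_stack([gx[0] + contour[:, 0] * dx, gy[0] + contour[:, 1] * dy])
            )
        out[lv] = pieces
    return out


def contours_to_frame(contours: dict) -> pd.DataFrame:
    """Flatten contour polylines to a long table (level, piece, x, y)."""
    rows = []
    for lv, pieces in contours.items():
        for k, arr in enumerate(pieces):
            for px, py in arr:
                rows.append({"level": lv, "piece": k, "x": px, "y": py})
    return pd.DataFrame(rows)
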