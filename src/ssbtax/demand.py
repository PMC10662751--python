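"""Beverage demand: Almost Ideal Demand System estimation and tax pass-through.

The demand side of the tax simulation rests on uncompensated price
elasticities for a three-good beverage partition {SSB, fruit juice, other
beverages}.  Elasticities are either estimated from a household budget-share
panel with a linear-approximate Almost Ideal Demand System (LA-AIDS, Stone
price index) or taken from the package's German defaults:

* own-price SSB        −0.956  (95%-CI [−1.174, −0.738])
* own-price juice      −1.106  (95%-CI [−1.397, −0.814])
* cross SSB↔juice       0.052  (95%-CI [−0.138,  0.242])
* tax pass-through      0.82   (95%-CI [ 0.66,   0.98])

The LA-AIDS share equation is

    w_i = alpha_i + sum_j gamma_ij ln p_j + beta_i ln(x / P*)

with Stone index ln P* = sum_j wbar_j ln p_j, and uncompensated elasticities

    e_ij = -delta_ij + gamma_ij / wbar_i - beta_i wbar_j / wbar_i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

GOODS = ("ssb", "juice", "other")
N_GOODS = len(GOODS)

# Printed German defaults (point estimate, 95% CI).
DEFAULT_ELASTICITIES = {
    ("ssb", "ssb"): (-0.956, (-1.174, -0.738)),
    ("juice", "juice"): (-1.106, (-1.397, -0.814)),
    ("juice", "ssb"): (0.052, (-0.138, 0.242)),
    ("ssb", "juice"): (0.052, (-0.138, 0.242)),
}
DEFAULT_PASS_THROUGH = 0.82
DEFAULT_PASS_THROUGH_CI = (0.66, 0.98)


def ci_to_se(lower: float, upper: float) -> float:
    """Standard error from a normal-approximation 95% confidence interval."""
    return (upper - lower) / (2.0 * 1.959963984540054)


@dataclass
class DemandParameters:
    """LA-AIDS coefficients for the goods in :data:`GOODS`.

    alpha : (G,) intercepts, summing to 1 (adding-up)
    beta  : (G,) expenditure coefficients, summing to 0
    gamma : (G, G) price coefficients; rows sum to 0 (homogeneity), columns
            sum to 0 (adding-up); symmetric when the restriction is imposed.
    cov   : optional covariance of the stacked (alpha, beta, vec(gamma))
            parameter vector, used for delta-method elasticity SEs.
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    cov: np.ndarray | None = None
    goods: tuple[str, ...] = GOODS

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)

    def validate(self, tol: float = 1e-8, symmetry: bool = True) -> None:
        if abs(self.alpha.sum() - 1.0) > tol:
            raise ValueError("adding-up violated: sum(alpha) != 1")
        if abs(self.beta.sum()) > tol:
            raise ValueError("adding-up violated: sum(beta) != 0")
        if np.abs(self.gamma.sum(axis=0)).max() > tol:
            raise ValueError("adding-up violated: column sums of gamma != 0")
        if np.abs(self.gamma.sum(axis=1)).max() > tol:
            raise ValueError("homogeneity violated: row sums of gamma != 0")
        if symmetry and np.abs(self.gamma - self.gamma.T).max() > tol:
            raise ValueError("symmetry violated: gamma != gamma.T")


@dataclass
class ElasticityMatrix:
    """Uncompensated own-/cross-price elasticities with standard errors.

    ``values[i, j]`` is the % change in consumption of good i per 1% change
    in the price of good j.
    """

    values: np.ndarray
    se: np.ndarray | None = None
    goods: tuple[str, ...] = GOODS

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("elasticities must be finite")
        if self.se is None:
            self.se = np.zeros_like(self.values)
        self.se = np.asarray(self.se, dtype=float)
        if np.any(self.se < 0):
            raise ValueError("standard errors must be >= 0")

    def __getitem__(self, pair):
        i, j = pair
        return self.values[self.goods.index(i), self.goods.index(j)]

    def to_dict(self) -> dict:
        out = {}
        for i, gi in enumerate(self.goods):
            for j, gj in enumerate(self.goods):
                out[f"e_{gi}_{gj}"] = {
                    "estimate": float(self.values[i, j]),
                    "se": float(self.se[i, j]),
                }
        return out

    def without_substitution(self) -> "ElasticityMatrix":
        """Copy with all cross-price terms zeroed (own-price responses only)."""
        return ElasticityMatrix(np.diag(np.diag(self.values)), np.diag(np.diag(self.se)), self.goods)


def default_elasticity_matrix() -> ElasticityMatrix:
    """The package's German default elasticity matrix.

    Entries not estimated in the source analysis (those involving the
    residual 'other beverages' good) are set to unit own-price elasticity and
    zero cross-price response.
    """
    values = -np.eye(N_GOODS)
    se = np.zeros((N_GOODS, N_GOODS))
    for (gi, gj), (point, ci) in DEFAULT_ELASTICITIES.items():
        i, j = GOODS.index(gi), GOODS.index(gj)
        values[i, j] = point
        se[i, j] = ci_to_se(*ci)
    return ElasticityMatrix(values, se)


# ---------------------------------------------------------------------------
# LA-AIDS estimation
# ---------------------------------------------------------------------------

RESTRICTIONS = ("none", "homogeneity", "homogeneity+symmetry")


class LAAIDS:
    """Linear-approximate Almost Ideal Demand System.

    Parameters
    ----------
    shares : (n, G) array of budget shares, rows summing to 1.
    prices : (n, G) array of positive prices.
    expenditure : (n,) total (beverage) expenditure.
    goods : names of the goods, defaults to ("ssb", "juice", "other").

    The model drops the last good's share equation and recovers its
    coefficients by adding-up.  ``fit`` imposes homogeneity and symmetry as
    linear reparameterisations and solves the stacked system by OLS (with
    identical regressors across equations OLS coincides with SUR).
    """

    def __init__(self, shares, prices, expenditure, goods: tuple[str, ...] = GOODS):
        self.shares = np.asarray(shares, dtype=float)
        self.prices = np.asarray(prices, dtype=float)
        self.expenditure = np.asarray(expenditure, dtype=float)
        self.goods = tuple(goods)
        g = len(self.goods)
        if g < 3:
            raise ValueError("LA-AIDS needs at least 3 goods")
        if self.shares.shape != self.prices.shape or self.shares.shape[1] != g:
            raise ValueError("shares and prices must be (n, n_goods)")
        if np.any(self.prices <= 0):
            raise ValueError("prices must be strictly positive")
        if np.abs(self.shares.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValueError("budget shares must sum to 1 per household")
        self.nobs = self.shares.shape[0]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, goods: tuple[str, ...] = GOODS) -> "LAAIDS":
        shares = df[[f"w_{g}" for g in goods]].to_numpy()
        prices = df[[f"p_{g}" for g in goods]].to_numpy()
        return cls(shares, prices, df["expenditure"].to_numpy(), goods)

    # -- internals ---------------------------------------------------------

    def _design(self):
        lnp = np.log(self.prices)
        wbar = self.shares.mean(axis=0)
        stone = lnp @ wbar
        z = np.log(self.expenditure) - stone
        self._check_collinearity(lnp, z)
        return lnp, z, wbar

    def _check_collinearity(self, lnp, z):
        cols = [lnp[:, j] for j in range(lnp.shape[1])] + [z]
        names = [f"ln p_{g}" for g in self.goods] + ["ln(x/P*)"]
        X = np.column_stack([np.ones(self.nobs)] + cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            # name the offending columns via pairwise correlation
            bad = []
            for a in range(len(cols)):
                if np.std(cols[a]) < 1e-12:
                    bad.append(names[a])
                for b in range(a + 1, len(cols)):
                    if np.std(cols[a]) > 0 and np.std(cols[b]) > 0:
                        r = np.corrcoef(cols[a], cols[b])[0, 1]
                        if abs(r) > 1 - 1e-10:
                            bad.extend([names[a], names[b]])
            raise np.linalg.LinAlgError(
                "collinear price/expenditure columns: " + ", ".join(sorted(set(bad)) or names)
            )

    def fit(self, restrictions: str = "homogeneity+symmetry") -> "LAAIDSResults":
        if restrictions not in RESTRICTIONS:
            raise ValueError(f"restrictions must be one of {RESTRICTIONS}")
        g = len(self.goods)
        k_eq = g - 1  # estimated equations
        lnp, z, wbar = self._design()
        n = self.nobs

        # free parameter layout, per restriction level
        if restrictions == "none":
            # theta = [alpha_i, gamma_i1..gamma_iG, beta_i] per equation
            names = []
            for i in range(k_eq):
                names += [f"alpha_{i}"] + [f"gamma_{i}{j}" for j in range(g)] + [f"beta_{i}"]
        elif restrictions == "homogeneity":
            names = []
            for i in range(k_eq):
                names += [f"alpha_{i}"] + [f"gamma_{i}{j}" for j in range(g - 1)] + [f"beta_{i}"]
        else:  # homogeneity + symmetry: keep gamma_ij for j >= i only
            names = []
            for i in range(k_eq):
                names += [f"alpha_{i}"] + [f"gamma_{i}{j}" for j in range(i, g - 1)] + [f"beta_{i}"]
        k = len(names)
        idx = {nm: c for c, nm in enumerate(names)}

        # log price regressors: levels for 'none', differences vs last good
        # for homogeneity-restricted fits (gamma_iG = -sum_{j<G} gamma_ij)
        L = lnp if restrictions == "none" else lnp[:, : g - 1] - lnp[:, [g - 1]]

        X = np.zeros((n * k_eq, k))
        y = np.empty(n * k_eq)
        for i in range(k_eq):
            rows = slice(i * n, (i + 1) * n)
            y[rows] = self.shares[:, i]
            X[rows, idx[f"alpha_{i}"]] = 1.0
            X[rows, idx[f"beta_{i}"]] = z
            ncols = g if restrictions == "none" else g - 1
            for j in range(ncols):
                nm = f"gamma_{i}{j}"
                if nm not in idx:  # symmetry: gamma_ij with j < i maps to gamma_ji
                    nm = f"gamma_{j}{i}"
                X[rows, idx[nm]] += L[:, j]

        ols = sm.OLS(y, X).fit()
        theta = ols.params
        cov_theta = ols.cov_params()

        # expand theta into the full (alpha, beta, gamma) arrays via a linear
        # map T so that the full covariance is T cov_theta T'.
        T = np.zeros((2 * g + g * g, k))  # order: alpha(g), beta(g), vec(gamma)(g*g)

        def put(row, nm, w=1.0):
            T[row, idx[nm]] += w

        for i in range(k_eq):
            put(i, f"alpha_{i}")
            put(g + i, f"beta_{i}")
        for i in range(k_eq):  # adding-up for the dropped good
            put(k_eq, f"alpha_{i}", -1.0)
            put(g + k_eq, f"beta_{i}", -1.0)
        # gamma rows for the estimated equations
        for i in range(k_eq):
            if restrictions == "none":
                for j in range(g):
                    put(2 * g + i * g + j, f"gamma_{i}{j}")
            else:
                for j in range(g - 1):
                    nm = f"gamma_{i}{j}"
                    if nm not in idx:
                        nm = f"gamma_{j}{i}"
                    put(2 * g + i * g + j, nm)
                    put(2 * g + i * g + (g - 1), nm, -1.0)  # homogeneity
        # gamma row for the dropped good: column adding-up
        for j in range(g):
            for i in range(k_eq):
                T[2 * g + k_eq * g + j] -= T[2 * g + i * g + j]

        full = T @ theta
        cov_full = T @ cov_theta @ T.T
        params = DemandParameters(
            alpha=np.r_[full[:g]], beta=np.r_[full[g : 2 * g]],
            gamma=full[2 * g :].reshape(g, g), cov=cov_full, goods=self.goods,
        )
        # intercept of dropped alpha: adding-up to 1, not 0
        params.alpha[k_eq] += 1.0
        return LAAIDSResults(self, params, ols, wbar, restrictions)


class LAAIDSResults:
    """Fit results for :class:`LAAIDS`: parameters, covariance, elasticities."""

    def __init__(self, model, params, ols_results, mean_shares, restrictions):
        self.model = model
        self.params = params
        self._ols = ols_results
        self.mean_shares = mean_shares
        self.restrictions = restrictions
        self.nobs = model.nobs

    @property
    def bse(self) -> np.ndarray:
        return self._ols.bse

    @property
    def rsquared(self) -> float:
        return self._ols.rsquared

    def elasticities(self, mean_shares: np.ndarray | None = None) -> ElasticityMatrix:
        wbar = self.mean_shares if mean_shares is None else np.asarray(mean_shares, float)
        return elasticities_from_params(self.params, wbar)

    def summary(self) -> str:
        g = len(self.model.goods)
        lines = [
            "LA-AIDS estimation results",
            "=" * 60,
            f"goods: {', '.join(self.model.goods)}   n = {self.nobs}",
            f"restrictions: {self.restrictions}   R2 (stacked): {self.rsquared:.4f}",
            "-" * 60,
            f"{'':8s}" + "".join(f"{gd:>12s}" for gd in self.model.goods),
            f"{'alpha':8s}" + "".join(f"{a:12.4f}" for a in self.params.alpha),
            f"{'beta':8s}" + "".join(f"{b:12.4f}" for b in self.params.beta),
        ]
        for i in range(g):
            lines.append(
                f"gamma_{self.model.goods[i][:2]:2s}" + "".join(f"{v:12.4f}" for v in self.params.gamma[i])
            )
        E = self.elasticities()
        lines.append("-" * 60)
        lines.append("uncompensated elasticities (rows: quantity, cols: price)")
        for i in range(g):
            lines.append(
                f"{self.model.goods[i]:8s}"
                + "".join(f"{E.values[i, j]:8.3f} ({E.se[i, j]:.3f})" for j in range(g))
            )
        return "\n".join(lines)


def estimate_laaids(panel: pd.DataFrame, restrictions: str = "homogeneity+symmetry",
                    goods: tuple[str, ...] = GOODS) -> DemandParameters:
    """Fit LA-AIDS to a household panel and return the coefficient set.

    ``panel`` must carry columns ``w_<good>``, ``p_<good>`` and
    ``expenditure``.  A minimum of 10 households per free parameter is
    required.
    """
    model = LAAIDS.from_dataframe(panel, goods)
    n_free = {"none": 10, "homogeneity": 8, "homogeneity+symmetry": 7}[restrictions]
    if model.nobs < 10 * n_free:
        raise ValueError(f"need at least {10 * n_free} households for {n_free} free parameters")
    return model.fit(restrictions).params


def elasticities_from_params(params: DemandParameters, mean_shares: np.ndarray) -> ElasticityMatrix:
    """Uncompensated elasticities e_ij = −δ_ij + γ_ij/w̄_i − β_i·w̄_j/w̄_i."""
    wbar = np.asarray(mean_shares, dtype=float)
    if np.any(wbar <= 0):
        raise ValueError("mean shares must be strictly positive")
    g = len(wbar)
    delta = np.eye(g)
    values = -delta + params.gamma / wbar[:, None] - np.outer(params.beta, wbar) / wbar[:, None]

    se = np.zeros((g, g))
    if params.cov is not None:
        # delta method treating wbar as fixed; parameter order alpha,beta,vec(gamma)
        for i in range(g):
            for j in range(g):
                grad = np.zeros(2 * g + g * g)
                grad[g + i] = -wbar[j] / wbar[i]          # d/d beta_i
                grad[2 * g + i * g + j] = 1.0 / wbar[i]   # d/d gamma_ij
                var = grad @ params.cov @ grad
                se[i, j] = np.sqrt(max(var, 0.0))
    return ElasticityMatrix(values, se, params.goods)


# ---------------------------------------------------------------------------
# tax mechanics
# ---------------------------------------------------------------------------

def consumer_price_change(statutory_rate: float, pass_through: float) -> float:
    """Relative consumer price change Δp/p = statutory rate × pass-through."""
    if statutory_rate < 0 or pass_through < 0:
        raise ValueError("statutory rate and pass-through must be non-negative")
    if statutory_rate > 1.5 or pass_through > 1.5:
        raise ValueError("statutory rate and pass-through must be <= 1.5")
    return statutory_rate * pass_through


def apply_demand_response(quantities, price_changes, elasticities: ElasticityMatrix):
    """Shift consumption in response to relative price changes.

    Q'_i = Q_i × (1 + Σ_j e_ij × Δp_j/p_j), floored at zero.  ``quantities``
    is an array whose last axis runs over the goods (individuals may occupy
    leading axes); ``price_changes`` is a (G,) vector of Δp/p.
    """
    q = np.asarray(quantities, dtype=float)
    dp = np.asarray(price_changes, dtype=float)
    if np.any(q < 0):
        raise ValueError("quantities must be non-negative")
    shifted = q * (1.0 + elasticities.values @ dp)
    return np.maximum(shifted, 0.0)
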