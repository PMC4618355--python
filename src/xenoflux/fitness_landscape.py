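"""Dosage-dependent flux-fitness model and cross-property statistics.

The core model maps the functional dosage of an essential enzyme — the
product of its relative intracellular abundance A and catalytic efficiency
kcat/Km — onto growth rate through a saturating Michaelis-Menten-form
landscape

    fitness(d) = a * d / (b + d),        d = A * (kcat/Km)

where the plateau ``a`` (growth-rate units) and half-saturation ``b``
(dosage units) absorb the topology of the surrounding metabolic network.
The module also provides the Spearman cross-correlation matrix over strain
properties with pairwise deletion of missing values, the quadratic net-charge
regression, two-sample Kolmogorov-Smirnov distribution shifts, and a
per-strain landscape report flagging strains that fall below the fitted
curve (the abundance-barrier outliers).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "StrainRecord",
    "FluxFitnessFit",
    "ChargeFit",
    "CorrelationMatrix",
    "SEVERE_FITNESS_OUTLIERS",
    "FIT_EXCLUSION_PRESET",
    "dosage",
    "flux_fitness",
    "fit_flux_model",
    "spearman_matrix",
    "spearman_with_p",
    "quadratic_charge_fit",
    "distribution_shift",
    "landscape_report",
]

# Named exclusion presets: the severe-fitness-drop set includes one strain
# whose enzyme could not be purified (no kcat/Km), hence the smaller set used
# when fitting the landscape.
SEVERE_FITNESS_OUTLIERS = ("DHFR-23", "DHFR-35", "DHFR-36", "DHFR-37", "DHFR-38", "DHFR-43")
FIT_EXCLUSION_PRESET = ("DHFR-23", "DHFR-35", "DHFR-36", "DHFR-38", "DHFR-43")

#: canonical strain-table columns (the on-disk TSV uses these names verbatim)
STRAIN_COLUMNS = [
    "strain_id",
    "species",
    "growth_rate_naive",
    "growth_rate_evolved",
    "tm_c",
    "kcat_over_km",
    "abundance_total_naive",
    "abundance_total_evolved",
    "abundance_soluble_naive",
    "abundance_soluble_evolved",
    "promoter_activity_naive",
    "promoter_activity_evolved",
    "net_charge",
    "gc_percent",
    "identity_percent",
    "cai",
    "mrna_dg",
]


@dataclass(frozen=True)
class StrainRecord:
    """One ortholog-replacement strain with its molecular and growth phenotypes."""

    strain_id: str
    species: str = ""
    growth_rate_naive: float = math.nan
    growth_rate_evolved: float = math.nan
    tm_c: float = math.nan
    kcat_over_km: float = math.nan
    abundance_total_naive: float = math.nan
    abundance_total_evolved: float = math.nan
    abundance_soluble_naive: float = math.nan
    abundance_soluble_evolved: float = math.nan
    promoter_activity_naive: float = math.nan
    promoter_activity_evolved: float = math.nan
    net_charge: float = math.nan
    gc_percent: float = math.nan
    identity_percent: float = math.nan
    cai: float = math.nan
    mrna_dg: float = math.nan


def records_to_frame(records: list[StrainRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=STRAIN_COLUMNS)


@dataclass(frozen=True)
class FluxFitnessFit:
    a: float
    b: float
    excluded_ids: tuple[str, ...]
    dropped_missing: tuple[str, ...]
    r_squared: float
    p_value: float
    n_used: int
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))

    def predict(self, d: np.ndarray) -> np.ndarray:
        return flux_fitness(np.asarray(d, dtype=float), self.a, self.b)


@dataclass(frozen=True)
class ChargeFit:
    beta0: float
    beta1: float
    c: float
    p_value: float
    c_estimated: bool


@dataclass(frozen=True)
class CorrelationMatrix:
    properties: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    neg_log10_p: pd.DataFrame
    n_pairs: pd.DataFrame


def dosage(abundance_rel, kcat_over_km):
    """Functional dosage: abundance (WT-relative) times kcat/Km; NaN propagates."""
    a = np.asarray(abundance_rel, dtype=float)
    k = np.asarray(kcat_over_km, dtype=float)
    if np.any(a[~np.isnan(a)] < 0) or np.any(k[~np.isnan(k)] < 0):
        raise ValueError("abundance and kcat/Km must be non-negative")
    out = a * k
    if out.ndim == 0:
        return float(out)
    return out


def flux_fitness(d, a: float, b: float):
    """Saturating flux-fitness landscape a*d/(b+d)."""
    if a <= 0 or b <= 0:
        raise ValueError("a and b must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d[~np.isnan(d)] < 0):
        raise ValueError("dosage must be non-negative")
    out = a * d / (b + d)
    if out.ndim == 0:
        return float(out)
    return out


def fit_flux_model(
    table: pd.DataFrame,
    phase: str = "naive",
    abundance_field: str = "total",
    exclude: tuple[str, ...] = (),
) -> FluxFitnessFit:
    """Nonlinear least-squares fit of the flux-fitness landscape to a strain table.

    ``phase`` selects naive or evolved growth/abundance columns;
    ``abundance_field`` selects total-lysate (default) or soluble abundance.
    Strains in ``exclude`` or with missing dosage/growth are dropped (the
    latter reported in ``dropped_missing``).  Significance is an F-test of
    the two-parameter fit against the constant-mean model.
    """
    if phase not in ("naive", "evolved"):
        raise ValueError("phase must be 'naive' or 'evolved'")
    if abundance_field not in ("total", "soluble"):
        raise ValueError("abundance_field must be 'total' or 'soluble'")
    growth_col = f"growth_rate_{phase}"
    abund_col = f"abundance_{abundance_field}_{phase}"
    df = table.copy()
    df["_dosage"] = dosage(df[abund_col].to_numpy(), df["kcat_over_km"].to_numpy())
    excluded = df["strain_id"].isin(exclude)
    missing = df["_dosage"].isna() | df[growth_col].isna()
    dropped = tuple(df.loc[~excluded & missing, "strain_id"])
    use = df.loc[~excluded & ~missing]
    d = use["_dosage"].to_numpy(dtype=float)
    g = use[growth_col].to_numpy(dtype=float)
    if d.size < 3:
        raise ValueError(f"insufficient data: {d.size} usable strains (< 3)")
    if np.allclose(d, d[0]):
        raise ValueError("all dosages equal; a and b are not identifiable")

    a0 = max(g.max(), 1e-6)
    b0 = max(float(np.median(d[d > 0])) if np.any(d > 0) else 1.0, 1e-9)

    def resid(logp: np.ndarray) -> np.ndarray:
        a, b = np.exp(logp)
        return a * d / (b + d) - g

    sol = optimize.least_squares(
        resid, x0=np.log([a0, b0]), xtol=1e-15, ftol=1e-15, gtol=1e-15
    )
    if not sol.success:
        raise RuntimeError(f"flux-fitness fit did not converge: {sol.message}")
    a, b = np.exp(sol.x)
    res = sol.fun
    ss_res = float(res @ res)
    ss_tot = float(np.sum((g - g.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    # F-test vs the constant-mean model (1 parameter) — 1 extra df
    n = d.size
    if ss_res <= 0:
        p_value = 0.0
    else:
        f_stat = (ss_tot - ss_res) / 1.0 / (ss_res / (n - 2))
        p_value = float(stats.f.sf(f_stat, 1, n - 2)) if f_stat > 0 else 1.0
    return FluxFitnessFit(
        a=float(a),
        b=float(b),
        excluded_ids=tuple(exclude),
        dropped_missing=dropped,
        r_squared=r2,
        p_value=p_value,
        n_used=n,
        residuals=res,
    )


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact Spearman p by full enumeration of rank permutations."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    count = 0
    total = 0
    denom_x = np.sum((rx - rx.mean()) ** 2)
    for perm in itertools.permutations(range(n)):
        ryp = ry[list(perm)]
        denom_y = np.sum((ryp - ryp.mean()) ** 2)
        if denom_x == 0 or denom_y == 0:
            rho = 0.0
        else:
            rho = float(np.sum((rx - rx.mean()) * (ryp - ryp.mean())) / np.sqrt(denom_x * denom_y))
        total += 1
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def spearman_with_p(x: np.ndarray, y: np.ndarray, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rho with average ranks for ties; exact permutation p for small n."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan, math.nan
    rho, p_t = stats.spearmanr(x, y)
    if len(x) <= exact_max_n:
        return float(rho), _exact_spearman_p(x, y, float(rho))
    return float(rho), float(p_t)


def spearman_matrix(
    table: pd.DataFrame,
    properties: list[str],
    min_pairs: int = 5,
) -> CorrelationMatrix:
    """Spearman correlation matrix over strain properties with pairwise deletion.

    Cells with fewer than ``min_pairs`` complete pairs, or with a constant
    property, are marked unavailable (NaN).
    """
    k = len(properties)
    r = pd.DataFrame(np.full((k, k), np.nan), index=properties, columns=properties)
    p = r.copy()
    npairs = pd.DataFrame(np.zeros((k, k), dtype=int), index=properties, columns=properties)
    for i, pi in enumerate(properties):
        for j, pj in enumerate(properties):
            if j < i:
                continue
            sub = table[[pi, pj]].dropna()
            npairs.loc[pi, pj] = npairs.loc[pj, pi] = len(sub)
            if i == j:
                if len(sub) >= min_pairs:
                    r.loc[pi, pj] = 1.0
                    p.loc[pi, pj] = 0.0
                continue
            if len(sub) < min_pairs:
                continue
            rho, pv = spearman_with_p(sub[pi].to_numpy(), sub[pj].to_numpy())
            r.loc[pi, pj] = r.loc[pj, pi] = rho
            p.loc[pi, pj] = p.loc[pj, pi] = pv
    with np.errstate(divide="ignore"):
        neg_log10 = -np.log10(p.where(p > 0, other=np.nan))
    return CorrelationMatrix(
        properties=tuple(properties), r=r, p=p, neg_log10_p=neg_log10, n_pairs=npairs
    )


def quadratic_charge_fit(
    q: np.ndarray,
    growth: np.ndarray,
    c: float | None = 3.5,
) -> ChargeFit:
    """Regression of growth on the shifted squared net charge (q + c)^2.

    With ``c`` fixed this is ordinary least squares on the transformed
    predictor; with ``c=None`` the offset is estimated by a nested 1-D search
    minimizing the residual sum of squares.  ``beta1`` is the curvature — it
    is negative when fitness falls away from q = -c.
    """
    q = np.asarray(q, dtype=float)
    g = np.asarray(growth, dtype=float)
    mask = ~(np.isnan(q) | np.isnan(g))
    q, g = q[mask], g[mask]
    estimate_c = c is None
    min_n = 4 if estimate_c else 3
    if q.size < min_n:
        raise ValueError(f"need at least {min_n} points")
    if np.allclose(q, q[0]):
        raise ValueError("all charges equal; curvature not identifiable")

    def ols(c_val: float) -> tuple[float, float, float, float]:
        x = (q + c_val) ** 2
        if np.allclose(x, x[0]):
            b0 = float(g.mean())
            return b0, 0.0, 1.0, float(np.sum((g - b0) ** 2))
        res = stats.linregress(x, g)
        rss = float(np.sum((res.intercept + res.slope * x - g) ** 2))
        return float(res.intercept), float(res.slope), float(res.pvalue), rss

    if estimate_c:
        span = float(q.max() - q.min())
        sol = optimize.minimize_scalar(
            lambda cc: ols(cc)[3],
            bounds=(-q.max() - 2 * span, -q.min() + 2 * span),
            method="bounded",
            options={"xatol": 1e-10},
        )
        c_val = float(sol.x)
    else:
        c_val = float(c)
    beta0, beta1, pv, _ = ols(c_val)
    return ChargeFit(beta0=beta0, beta1=beta1, c=c_val, p_value=pv, c_estimated=estimate_c)


def distribution_shift(values_pre, values_post) -> dict:
    """Two-sample Kolmogorov-Smirnov shift between paired conditions.

    Returns D, the p-value (exact for small samples, asymptotic otherwise,
    via scipy's auto policy) and the direction of the shift: the sign of
    mean(post) - mean(pre) (0 for no shift).
    """
    pre = np.asarray(values_pre, dtype=float)
    post = np.asarray(values_post, dtype=float)
    pre = pre[~np.isnan(pre)]
    post = post[~np.isnan(post)]
    if pre.size < 2 or post.size < 2:
        raise ValueError("both samples need at least 2 values")
    res = stats.ks_2samp(pre, post, method="auto")
    delta = float(post.mean() - pre.mean())
    direction = 0 if np.isclose(delta, 0.0) else int(np.sign(delta))
    return {"D": float(res.statistic), "p": float(res.pvalue), "direction": direction}


def landscape_report(
    table: pd.DataFrame,
    fit: FluxFitnessFit,
    phase: str = "naive",
    abundance_field: str = "total",
    residual_threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-strain dosage, observed vs predicted growth, residual, barrier flag.

    ``barrier_flag`` marks strains whose observed growth falls below the
    model prediction by more than ``residual_threshold`` (growth-rate units)
    — the abundance-barrier outliers of the landscape.  Strains with missing
    dosage get a missing prediction and flag.
    """
    growth_col = f"growth_rate_{phase}"
    abund_col = f"abundance_{abundance_field}_{phase}"
    if table.empty:
        return pd.DataFrame(
            columns=["strain_id", "dosage", "observed", "predicted", "residual", "barrier_flag"]
        )
    d = dosage(table[abund_col].to_numpy(), table["kcat_over_km"].to_numpy())
    observed = table[growth_col].to_numpy(dtype=float)
    predicted = np.where(np.isnan(d), np.nan, fit.predict(np.nan_to_num(d)))
    residual = observed - predicted
    flag = pd.array(residual < -residual_threshold, dtype="boolean")
    flag[np.isnan(residual)] = pd.NA
    out = pd.DataFrame(
        {
            "strain_id": table["strain_id"].to_numpy(),
            "dosage": d,
            "observed": observed,
            "predicted": predicted,
            "residual": residual,
            "barrier_flag": flag,
        }
    )
    return out
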