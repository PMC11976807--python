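"""Between-tissue ratios and duplicate-catheter limits of agreement.

Both analyses operate on per-catheter derived PK parameters (AUC_0–last,
Cmax, T1/2, Tmax) on the log scale, with a random animal intercept:

* :func:`compare_tissues` fits ``log(param) ~ tissue + (1 | animal)`` and
  reports the back-transformed tissue contrast — a ratio of estimated
  medians — with a Wald 95% CI and two-sided p-value, unadjusted for
  multiplicity (a Bonferroni option is exposed for users who want it).
* :func:`limits_of_agreement` quantifies reproducibility of duplicate
  catheters in the same tissue: with residual log-scale SD σ from
  ``log(param) ~ 1 + (1 | animal)``, 95% of same-animal catheter ratios fall
  within a factor ``LOA = exp(1.96 · √2 · σ)`` of each other.  The √2 arises
  because a ratio of two catheters compounds two independent residuals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RatioResult", "LOAResult", "compare_tissues", "limits_of_agreement", "oneway_reml"]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class RatioResult:
    """Back-transformed tissue contrast on one PK parameter."""

    tissue_num: str
    tissue_den: str
    parameter: str
    ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_num: int
    n_den: int

    def summary(self) -> str:
        return (
            f"{self.parameter}: {self.tissue_num}/{self.tissue_den} = "
            f"{self.ratio:.2f} (95% CI {self.ci_low:.2f}; {self.ci_high:.2f}, "
            f"P = {self.p_value:.3f})"
        )


@dataclass(frozen=True)
class LOAResult:
    """Limits-of-agreement factor for duplicate catheters in one tissue."""

    tissue: str
    parameter: str
    loa_factor: float
    ci_low: float
    ci_high: float
    sigma_within: float
    sigma_animal: float
    n: int

    def summary(self) -> str:
        ci = ""
        if np.isfinite(self.ci_low):
            ci = f" (95% CI {self.ci_low:.2f}; {self.ci_high:.2f})"
        return f"{self.parameter}: {self.tissue} LOA factor = {self.loa_factor:.2f}{ci}"


def _log_values(table: pd.DataFrame, parameter: str) -> np.ndarray:
    if parameter not in table.columns:
        raise ValueError(f"parameter {parameter!r} not in table")
    v = table[parameter].to_numpy(float)
    if np.any(v <= 0):
        raise ValueError(f"{parameter} must be positive for log-scale analysis")
    return np.log(v)


def compare_tissues(
    per_catheter: pd.DataFrame,
    parameter: str,
    tissue_a: str,
    tissue_b: str,
    *,
    tissue_col: str = "tissue",
) -> RatioResult:
    """Ratio of estimated medians, tissue_b over tissue_a.

    Fits a linear mixed model on log(parameter) with a tissue fixed effect
    and random animal intercept (statsmodels MixedLM, REML); the ratio is
    the exponentiated contrast, the CI exponentiated Wald bounds, the p a
    two-sided Wald test.  With a degenerate design (all values identical)
    the null result is returned directly.
    """
    sub = per_catheter[per_catheter[tissue_col].isin([tissue_a, tissue_b])]
    n_a = int((sub[tissue_col] == tissue_a).sum())
    n_b = int((sub[tissue_col] == tissue_b).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError(f"both tissues must be present ({tissue_a}: {n_a}, {tissue_b}: {n_b})")
    for t in (tissue_a, tissue_b):
        if sub.loc[sub[tissue_col] == t, "animal_id"].nunique() < 2:
            raise ValueError(f"tissue {t!r} needs >= 2 animals for a mixed comparison")

    y = _log_values(sub, parameter)
    if np.ptp(y) == 0:  # identical values everywhere: exact null
        return RatioResult(tissue_b, tissue_a, parameter, 1.0, 1.0, 1.0, 1.0, n_b, n_a)

    import statsmodels.api as sm

    x = np.column_stack([np.ones(len(sub)), (sub[tissue_col] == tissue_b).to_numpy(float)])
    groups = sub["animal_id"].to_numpy()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM(y, x, groups=groups).fit(reml=True)
        beta = float(fit.params[1])
        se = float(fit.bse[1])
    except (np.linalg.LinAlgError, ValueError):
        # degenerate residual structure (e.g. noise-free data): drop the
        # random intercept and report the plain contrast
        warnings.warn("mixed model singular; falling back to OLS contrast")
        fit = sm.OLS(y, x).fit()
        beta = float(fit.params[1])
        se = float(fit.bse[1])
    from scipy import stats as sps

    if not np.isfinite(se) or se == 0:
        p = 1.0 if beta == 0 else 0.0
        lo = hi = math.exp(beta)
    else:
        z = beta / se
        p = float(2 * sps.norm.sf(abs(z)))
        lo, hi = math.exp(beta - _Z95 * se), math.exp(beta + _Z95 * se)
    return RatioResult(tissue_b, tissue_a, parameter, math.exp(beta), lo, hi, p, n_b, n_a)


# ---------------------------------------------------------------------------
# one-way random-intercept REML (used by limits_of_agreement and its
# parametric bootstrap; cross-checked against statsmodels MixedLM in tests)
# ---------------------------------------------------------------------------
def _reml_neg2(log_lam: float, y: np.ndarray, idx: list[np.ndarray]) -> tuple[float, float, float]:
    """Profiled −2·REML log-likelihood at variance ratio λ = σ_a²/σ_e².

    For the balanced-or-not one-way model V_i = σ_e²(I + λJ); using
    Sherman–Morrison, everything reduces to per-group sums.  Returns
    (criterion, GLS mean, profiled σ_e²).
    """
    lam = math.exp(log_lam)
    sw = 0.0  # Σ 1'V⁻¹1 (in σe²=1 units)
    swy = 0.0
    logdet = 0.0
    for ii in idx:
        n_i = ii.size
        c = lam / (1.0 + n_i * lam)
        s_y = float(y[ii].sum())
        sw += n_i - c * n_i * n_i
        swy += s_y - c * n_i * s_y
        logdet += math.log1p(n_i * lam)
    mu = swy / sw
    q = 0.0
    for ii in idx:
        n_i = ii.size
        c = lam / (1.0 + n_i * lam)
        r = y[ii] - mu
        s_r = float(r.sum())
        q += float(r @ r) - c * s_r * s_r
    dof = y.size - 1  # one fixed effect
    s2e = q / dof
    crit = dof * math.log(max(s2e, 1e-300)) + logdet + math.log(sw) + dof
    return crit, mu, s2e


def oneway_reml(y: np.ndarray, groups: np.ndarray) -> tuple[float, float, float]:
    """REML fit of ``y = mu + a_group + e``; returns (mu, sigma_a, sigma_e)."""
    y = np.asarray(y, float)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    idx = [np.flatnonzero(groups == g) for g in uniq]
    if np.ptp(y) == 0:
        return float(y[0]), 0.0, 0.0
    means = np.array([y[ii].mean() for ii in idx])
    ss_within = sum(float(((y[ii] - m) ** 2).sum()) for ii, m in zip(idx, means))
    if ss_within <= 1e-14 * float(np.var(y)) * y.size:
        # duplicates agree exactly: all variability is between animals
        sa = float(np.std(means, ddof=1)) if len(means) > 1 else 0.0
        return float(means.mean()), sa, 0.0
    # scalar search over log variance ratio
    from scipy import optimize

    grid = np.linspace(-12, 8, 41)
    vals = [_reml_neg2(g, y, idx)[0] for g in grid]
    g0 = grid[int(np.argmin(vals))]
    res = optimize.minimize_scalar(
        lambda g: _reml_neg2(g, y, idx)[0],
        bounds=(max(g0 - 4.0, -14.0), min(g0 + 4.0, 10.0)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    crit, mu, s2e = _reml_neg2(res.x, y, idx)
    lam = math.exp(res.x)
    # ratio at the lower search bound means "no animal component"
    sigma_a = math.sqrt(lam * s2e) if res.x > -13.5 else 0.0
    return float(mu), float(sigma_a), float(math.sqrt(max(s2e, 0.0)))


def limits_of_agreement(
    per_catheter: pd.DataFrame,
    tissue: str,
    parameter: str,
    *,
    tissue_col: str = "organ",
    n_boot: int = 1000,
    seed: int = 0,
    ci: bool = True,
) -> LOAResult:
    """LOA factor for duplicate catheters within ``tissue``.

    Requires at least two animals carrying two or more catheters in the
    tissue.  The factor is exp(1.96·√2·σ̂) with σ̂ the residual SD of the
    random-animal-intercept model; its CI comes from a seeded parametric
    bootstrap (``n_boot`` refits of data simulated from the fitted model).
    """
    sub = per_catheter[per_catheter[tissue_col] == tissue]
    if sub.empty:
        raise ValueError(f"no rows for tissue {tissue!r} in column {tissue_col!r}")
    caths_per_animal = sub.groupby("animal_id")["catheter_id"].nunique()
    if (caths_per_animal >= 2).sum() < 2:
        raise ValueError(
            f"tissue {tissue!r} needs >= 2 catheters in >= 2 animals for limits of agreement"
        )
    y = _log_values(sub, parameter)
    groups = sub["animal_id"].to_numpy()
    mu, sig_a, sig_e = oneway_reml(y, groups)
    factor = math.exp(_Z95 * math.sqrt(2.0) * sig_e)

    lo = hi = float("nan")
    if ci and n_boot > 0:
        rng = np.random.default_rng(seed)
        uniq = pd.unique(groups)
        idx = [np.flatnonzero(groups == g) for g in uniq]
        sizes = [ii.size for ii in idx]
        boots = np.empty(n_boot)
        for b in range(n_boot):
            yb = np.empty_like(y)
            a = rng.normal(0.0, sig_a, size=len(idx))
            for k, ii in enumerate(idx):
                yb[ii] = mu + a[k] + rng.normal(0.0, sig_e, size=sizes[k])
            _, _, se_b = oneway_reml(yb, groups)
            boots[b] = math.exp(_Z95 * math.sqrt(2.0) * se_b)
        lo, hi = np.percentile(boots, [2.5, 97.5])
    return LOAResult(tissue, parameter, factor, float(lo), float(hi), sig_e, sig_a, len(sub))
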