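"""Nonlinear mixed-effects estimation of tissue pharmacokinetics.

One :class:`TissuePKModel` is fitted per tissue compartment.  The structural
model is the zero-order-input / first-order-elimination curve of
:mod:`hipecpk.kinetics`; observations are interval-averaged tissue
concentrations and are modelled with log-normal (additive on the log scale)
residual error.  Animals contribute random effects on log k_in and log k_e;
the input duration t_in is a tissue-level constant — a handful of animals
cannot support a third variance component and peak times vary little.

Writing y_ij for the j-th observation of animal i over interval (s, e):

    log y_ij = log Cbar(s_ij, e_ij; k_in,i, t_in, k_e,i) + eps_ij
    log k_in,i = log k_in + b_i1,   log k_e,i = log k_e + b_i2
    b_i ~ N(0, diag(omega_kin^2, omega_ke^2)),   eps_ij ~ N(0, sigma^2)

Estimation maximizes the Laplace-approximate marginal likelihood over the
animal random effects; exponentiated fixed effects are population *medians*.
Per-animal parameters are empirical-Bayes modes.  The fit is deterministic
given data, options and starting values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .kinetics import PKParams, _cumint, concentration_at, derived_parameters

__all__ = ["TissuePKModel", "TissuePKResults", "starting_values", "fit_all_tissues"]

_LOG2 = math.log(2.0)
# variance components are bounded away from 0 on the log-SD scale so the
# zero-noise limit stays finite; estimates at the lower bound mean "no
# detectable variability at this level"
_LOG_SD_MIN = math.log(1e-6)
_LOG_SD_MAX = math.log(10.0)

OBS_COLUMNS = ("animal_id", "catheter_id", "t_start_min", "t_end_min", "c_tissue_ug_ml")


def starting_values(obs: pd.DataFrame) -> PKParams:
    """Heuristic initial structural parameters from raw observations.

    t_in starts at the interval-midpoint time of the largest observation;
    k_e from the log-linear slope of the post-peak observations (falling back
    to ln2/30, the middle of plausible tissue half-lives, when fewer than two
    post-peak points exist); k_in from inverting the peak formula
    ``Cmax = k_in (1 − e^{−k_e t_in}) / k_e``.
    """
    if len(obs) < 4:
        raise ValueError(f"need >= 4 observations for starting values, got {len(obs)}")
    c = obs["c_tissue_ug_ml"].to_numpy(float)
    if not np.any(c > 0):
        raise ValueError("all observations are zero; cannot initialize")
    t_mid = 0.5 * (obs["t_start_min"].to_numpy(float) + obs["t_end_min"].to_numpy(float))
    i_max = int(np.argmax(c))
    t_in = max(float(t_mid[i_max]), 1.0)
    c_max = float(c[i_max])

    post = (t_mid > t_in) & (c > 0)
    if post.sum() >= 2:
        slope = np.polyfit(t_mid[post], np.log(c[post]), 1)[0]
        k_e = max(-float(slope), 1e-4)
    else:
        k_e = _LOG2 / 30.0
    k_in = c_max * k_e / -np.expm1(-k_e * t_in)
    return PKParams(k_in=max(k_in, 1e-8), t_in=t_in, k_e=k_e)


def _log_interval_avg(lkin: float, ltin: float, lke: float, s: np.ndarray, e: np.ndarray) -> np.ndarray:
    """log of the interval-average prediction, vectorized over intervals."""
    k_in, t_in, k_e = math.exp(lkin), math.exp(ltin), math.exp(lke)
    avg = (_cumint(k_in, t_in, k_e, e) - _cumint(k_in, t_in, k_e, s)) / (e - s)
    return np.log(np.maximum(avg, 1e-300))


def _log_point(lkin: float, ltin: float, lke: float, s: np.ndarray, e: np.ndarray) -> np.ndarray:
    """log of the interval-midpoint point prediction (optional error model)."""
    k_in, t_in, k_e = math.exp(lkin), math.exp(ltin), math.exp(lke)
    t = 0.5 * (s + e)
    c_peak = (k_in / k_e) * -np.expm1(-k_e * t_in)
    c = np.where(t <= t_in, (k_in / k_e) * -np.expm1(-k_e * t), c_peak * np.exp(-k_e * np.maximum(t - t_in, 0)))
    return np.log(np.maximum(c, 1e-300))


@dataclass
class _AnimalData:
    animal_id: object
    s: np.ndarray
    e: np.ndarray
    logy: np.ndarray
    catheters: tuple


class TissuePKModel:
    """Population PK model for one tissue compartment.

    Parameters
    ----------
    data : DataFrame
        Observation table with columns ``animal_id, catheter_id, t_start_min,
        t_end_min, c_tissue_ug_ml`` and optionally ``censored`` (bool).
    tissue : str, optional
        Label carried through to results.
    censored_handling : {"drop", "lloq_half"}
        Censored rows are excluded by default; ``lloq_half`` replaces them by
        LLOQ/2 (requires ``lloq``).
    lloq : float, optional
        Quantification limit used by ``lloq_half``.
    prediction : {"interval_average", "midpoint"}
        Whether a sample is predicted by the analytic mean concentration over
        its collection window (physically faithful default) or by the point
        concentration at the window midpoint.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        tissue: str | None = None,
        *,
        censored_handling: str = "drop",
        lloq: float | None = None,
        prediction: str = "interval_average",
    ):
        missing = set(OBS_COLUMNS) - set(data.columns)
        if missing:
            raise ValueError(f"observation table missing columns: {sorted(missing)}")
        if prediction not in {"interval_average", "midpoint"}:
            raise ValueError(f"unknown prediction mode {prediction!r}")
        df = data.copy()
        if "censored" in df.columns:
            cens = df["censored"].astype(bool)
            if censored_handling == "drop":
                df = df[~cens]
            elif censored_handling == "lloq_half":
                if lloq is None:
                    raise ValueError("lloq required for lloq_half")
                df.loc[cens, "c_tissue_ug_ml"] = lloq / 2.0
            else:
                raise ValueError(f"unknown censored_handling {censored_handling!r}")
        df = df[df["c_tissue_ug_ml"] > 0]
        if len(df) < 4:
            raise ValueError(f"insufficient data: {len(df)} usable observations (< 4)")
        self.tissue = tissue
        self.prediction = prediction
        self.data = df.sort_values(["animal_id", "catheter_id", "t_start_min"]).reset_index(drop=True)
        self._pred = _log_interval_avg if prediction == "interval_average" else _log_point
        self._animals = [
            _AnimalData(
                a,
                g["t_start_min"].to_numpy(float),
                g["t_end_min"].to_numpy(float),
                np.log(g["c_tissue_ug_ml"].to_numpy(float)),
                tuple(sorted(g["catheter_id"].unique())),
            )
            for a, g in self.data.groupby("animal_id", sort=True)
        ]
        self.n_animals = len(self._animals)
        self.nobs = len(self.data)

    @classmethod
    def from_observations(cls, obs: pd.DataFrame, tissue: str, tissue_col: str = "tissue", **kwargs):
        """Build the model for one tissue out of a multi-tissue table."""
        sub = obs[obs[tissue_col] == tissue]
        if sub.empty:
            raise ValueError(f"no observations for tissue {tissue!r}")
        return cls(sub, tissue=tissue, **kwargs)

    # ---- likelihood ----------------------------------------------------
    # The animal random effects are b = (b_kin, b_ke) added to the log fixed
    # effects.  b_kin shifts the log-prediction additively (the prediction is
    # proportional to k_in), so for fixed b_ke its conditional mode is the
    # ridge-regression closed form; the joint mode therefore reduces to a 1-D
    # scalar search over b_ke.
    def _neg_joint_profiled(self, b_ke: float, theta: np.ndarray, ani: _AnimalData) -> tuple[float, float, np.ndarray]:
        lkin, ltin, lke, lw1, lw2, lsig = theta
        p0 = self._pred(lkin, ltin, lke + b_ke, ani.s, ani.e)
        r = ani.logy - p0
        n = r.size
        s2 = math.exp(2.0 * lsig)
        w1sq = math.exp(2.0 * lw1)
        b_kin = (float(r.sum()) / s2) / (n / s2 + 1.0 / w1sq)
        rr = r - b_kin
        val = (
            0.5 * float(rr @ rr) / s2
            + n * lsig
            + 0.5 * b_kin**2 / w1sq
            + lw1
            + 0.5 * b_ke**2 / math.exp(2.0 * lw2)
            + lw2
        )
        return val, b_kin, p0

    def _mode_b_ke(self, theta: np.ndarray, ani: _AnimalData, b_start: float) -> float:
        """1-D mode search for the k_e random effect (b_kin profiled out).

        Newton with central-difference curvature from the warm start; falls
        back to bounded Brent when Newton strays or curvature is not positive.
        """
        lkin, ltin, lke, lw1, lw2, lsig = theta
        w2 = math.exp(lw2)
        if w2 < 1e-5:
            return 0.0
        lim = min(8.0 * w2, 4.0)
        s2 = math.exp(2.0 * lsig)
        w2sq = w2 * w2
        b = float(np.clip(b_start, -lim, lim))
        h = 1e-5
        ok = False
        for _ in range(30):
            f0, b_kin, p0 = self._neg_joint_profiled(b, theta, ani)
            p_plus = self._pred(lkin, ltin, lke + b + h, ani.s, ani.e)
            p_minus = self._pred(lkin, ltin, lke + b - h, ani.s, ani.e)
            dg = (p_plus - p_minus) / (2.0 * h)
            d2g = (p_plus - 2.0 * p0 + p_minus) / h**2
            r = ani.logy - p0 - b_kin
            grad = -float(r @ dg) / s2 + b / w2sq
            curv = (float(dg @ dg) - float(r @ d2g)) / s2 + 1.0 / w2sq
            if curv <= 0:
                break
            step = grad / curv
            b_new = float(np.clip(b - step, -lim, lim))
            if abs(b_new - b) < 1e-10:
                b = b_new
                ok = True
                break
            f_new, _, _ = self._neg_joint_profiled(b_new, theta, ani)
            if f_new > f0 + 1e-12:
                # halve until improving, else bail to Brent
                shrink = 0.5
                while shrink > 1e-3 and f_new > f0:
                    b_try = float(np.clip(b - shrink * step, -lim, lim))
                    f_new, _, _ = self._neg_joint_profiled(b_try, theta, ani)
                    if f_new <= f0:
                        b_new = b_try
                        break
                    shrink *= 0.5
                if f_new > f0:
                    break
            b = b_new
        if not ok:
            res = optimize.minimize_scalar(
                lambda x: self._neg_joint_profiled(x, theta, ani)[0],
                bounds=(-lim, lim),
                method="bounded",
                options={"xatol": 1e-9},
            )
            if self._neg_joint_profiled(float(res.x), theta, ani)[0] < self._neg_joint_profiled(b, theta, ani)[0]:
                b = float(res.x)
        return b

    def _laplace_animal(self, theta: np.ndarray, ani: _AnimalData, b0: np.ndarray) -> tuple[float, np.ndarray]:
        lkin, ltin, lke, lw1, lw2, lsig = theta
        b_ke = self._mode_b_ke(theta, ani, float(b0[1]))
        f0, b_kin, p0 = self._neg_joint_profiled(b_ke, theta, ani)

        # 2x2 Hessian of the joint at the mode: the b_kin block is analytic,
        # the b_ke derivatives of the prediction come from central differences
        n = ani.logy.size
        s2 = math.exp(2.0 * lsig)
        w1sq = math.exp(2.0 * lw1)
        w2sq = math.exp(2.0 * lw2)
        h = 1e-5
        p_plus = self._pred(lkin, ltin, lke + b_ke + h, ani.s, ani.e)
        p_minus = self._pred(lkin, ltin, lke + b_ke - h, ani.s, ani.e)
        dg = (p_plus - p_minus) / (2.0 * h)
        d2g = (p_plus - 2.0 * p0 + p_minus) / h**2
        r = ani.logy - p0 - b_kin
        H00 = n / s2 + 1.0 / w1sq
        H01 = float(dg.sum()) / s2
        H11 = (float(dg @ dg) - float(r @ d2g)) / s2 + 1.0 / w2sq
        det = max(H00 * H11 - H01 * H01, 1e-300)
        # -log integral ≈ g(b̂) − log 2π + ½ log det H
        return f0 - math.log(2.0 * math.pi) + 0.5 * math.log(det), np.array([b_kin, b_ke])

    def _neg_marginal(self, theta: np.ndarray, warm: dict) -> float:
        total = 0.0
        for ani in self._animals:
            nll, b_hat = self._laplace_animal(theta, ani, warm.get(ani.animal_id, np.zeros(2)))
            warm[ani.animal_id] = b_hat
            if not np.isfinite(nll):
                return 1e12
            total += nll
        return total

    # ---- fixed-effects-only fallback ----------------------------------
    def _fit_fixed_only(self, start: PKParams) -> "TissuePKResults":
        s = self.data["t_start_min"].to_numpy(float)
        e = self.data["t_end_min"].to_numpy(float)
        logy = np.log(self.data["c_tissue_ug_ml"].to_numpy(float))

        def resid(x):
            return logy - self._pred(x[0], x[1], x[2], s, e)

        x0 = np.log([start.k_in, start.t_in, start.k_e])
        sol = optimize.least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        r = resid(sol.x)
        dof = max(len(r) - 3, 1)
        sigma = float(np.sqrt(r @ r / dof))
        # Gauss-Newton covariance of the log-parameters
        J = sol.jac
        try:
            cov = np.linalg.inv(J.T @ J) * sigma**2
        except np.linalg.LinAlgError:
            cov = np.full((3, 3), np.nan)
        theta = np.concatenate([sol.x, [_LOG_SD_MIN, _LOG_SD_MIN, math.log(max(sigma, 1e-12))]])
        eb = {ani.animal_id: np.zeros(2) for ani in self._animals}
        return TissuePKResults(
            model=self,
            params=theta,
            cov_fixed=cov,
            random_effects={k: (0.0, 0.0) for k in eb},
            converged=bool(sol.success),
            loglik=float(-0.5 * (r @ r) / sigma**2 - len(r) * math.log(sigma)) if sigma > 0 else np.inf,
            mixed=False,
            message=str(sol.status),
        )

    # ---- public fit -----------------------------------------------------
    def fit(
        self,
        start: PKParams | None = None,
        *,
        random_effects: bool | None = None,
        start_variances: tuple[float, float, float] = (0.3, 0.15, 0.3),
        maxiter: int = 200,
    ) -> "TissuePKResults":
        """Maximize the (Laplace) marginal likelihood.

        ``random_effects=None`` enables animal random effects whenever at
        least two animals are present.  Optimization is Nelder–Mead on
        (log k_in, log t_in, log k_e, log ω_kin, log ω_ke, log σ), which is
        robust to the small numerical roughness the inner per-animal
        optimizations introduce, followed by a covariance evaluation from the
        numeric Hessian at the optimum.
        """
        if start is None:
            start = starting_values(self.data)
        if random_effects is None:
            random_effects = self.n_animals >= 2
        if not random_effects:
            return self._fit_fixed_only(start)
        if self.n_animals < 2:
            raise ValueError("mixed fit requires >= 2 animals")
        for ani in self._animals:
            if ani.logy.size < 4:
                raise ValueError(f"animal {ani.animal_id!r} has < 4 usable observations")

        # stage 1: pooled fixed-effects least squares pins the structural
        # parameters (cheap and well identified), so the mixed optimization
        # starts in the right basin instead of a fixed-effect/variance ridge
        pooled = self._fit_fixed_only(start)
        lkin0, ltin0, lke0 = pooled.params[:3]
        sg0 = min(max(pooled.sigma, 1e-4), 1.0)
        w1, w2, _ = start_variances
        theta0 = np.array([lkin0, ltin0, lke0, math.log(w1), math.log(w2), math.log(sg0)])
        warm: dict = {}
        lo = np.array([-20.0, math.log(5.0), -10.0, _LOG_SD_MIN, _LOG_SD_MIN, _LOG_SD_MIN])
        hi = np.array([10.0, math.log(480.0), 2.0, _LOG_SD_MAX, _LOG_SD_MAX, _LOG_SD_MAX])

        def obj(theta):
            th = np.clip(theta, lo, hi)
            penalty = 1e4 * float(np.sum((theta - th) ** 2))
            return self._neg_marginal(th, warm) + penalty

        # stage 2: variance components only, fixed effects pinned — avoids
        # the ridge where a wrong fixed effect hides inside a huge omega
        def obj_var(v):
            return obj(np.concatenate([theta0[:3], v]))

        res_v = optimize.minimize(
            obj_var,
            theta0[3:],
            method="Nelder-Mead",
            options={"maxiter": 300, "xatol": 1e-4, "fatol": 1e-6, "adaptive": True},
        )
        theta1 = np.concatenate([theta0[:3], np.clip(res_v.x, lo[3:], hi[3:])])

        # stage 3: full joint polish with native bounds
        f0 = obj(theta1)
        res = optimize.minimize(
            obj,
            theta1,
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-6, "eps": 1e-5},
        )
        theta = np.clip(res.x, lo, hi)
        # a line-search failure at a variance bound still counts as converged
        # when the polish no longer moves the objective
        converged = np.isfinite(res.fun) and (bool(res.success) or res.fun >= f0 - 1e-6 * max(abs(f0), 1.0))
        if res.fun > f0 + 1e-9:  # never accept a point worse than the stage-2 result
            theta = np.clip(theta1, lo, hi)
            converged = np.isfinite(f0)

        # empirical-Bayes modes at the optimum
        eb: dict = {}
        nll = 0.0
        for ani in self._animals:
            l, b_hat = self._laplace_animal(theta, ani, warm.get(ani.animal_id, np.zeros(2)))
            eb[ani.animal_id] = b_hat
            nll += l

        cov = self._cov_fixed(theta, dict(warm))
        return TissuePKResults(
            model=self,
            params=theta,
            cov_fixed=cov,
            random_effects={k: (float(v[0]), float(v[1])) for k, v in eb.items()},
            converged=converged,
            loglik=-nll,
            mixed=True,
            message=res.message,
        )

    def _cov_fixed(self, theta: np.ndarray, warm: dict) -> np.ndarray:
        """Asymptotic covariance of the fixed effects from the numeric Hessian
        of the negative marginal log-likelihood (variance components fixed at
        their estimates)."""
        idx = [0, 1, 2]
        h = 1e-3
        H = np.empty((3, 3))

        def f(x):
            th = theta.copy()
            th[idx] = x
            return self._neg_marginal(th, warm)

        x0 = theta[idx].copy()
        f0 = f(x0)
        for i in range(3):
            ei = np.zeros(3)
            ei[i] = h
            H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h**2
            for j in range(i + 1, 3):
                ej = np.zeros(3)
                ej[j] = h
                H[i, j] = H[j, i] = (
                    f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
                ) / (4 * h**2)
        # enforce positive definiteness: clip eigenvalues so near-flat or
        # noise-corrupted directions yield wide (not zero) uncertainties
        w, V = np.linalg.eigh(0.5 * (H + H.T))
        w = np.clip(w, 1e-6 * max(float(w.max()), 1.0), None)
        return V @ np.diag(1.0 / w) @ V.T


_FIXED_NAMES = ("log_k_in", "log_t_in", "log_k_e")
_DERIVED_NAMES = ("auc_0_last", "t_half", "c_max", "t_max")


@dataclass
class TissuePKResults:
    """Fitted population PK for one tissue.

    ``params`` is the internal parameter vector (log k_in, log t_in, log k_e,
    log ω_kin, log ω_ke, log σ); use the named accessors.  Exponentiated
    fixed effects are population medians.
    """

    model: TissuePKModel
    params: np.ndarray
    cov_fixed: np.ndarray
    random_effects: dict
    converged: bool
    loglik: float
    mixed: bool
    message: str = ""

    # -- accessors -------------------------------------------------------
    @property
    def fixed_effects(self) -> pd.Series:
        return pd.Series(self.params[:3], index=list(_FIXED_NAMES))

    @property
    def population_params(self) -> PKParams:
        """Population-median structural parameters."""
        return PKParams(*np.exp(self.params[:3]))

    @property
    def bse(self) -> pd.Series:
        se = np.sqrt(np.clip(np.diag(self.cov_fixed), 0, None))
        return pd.Series(se, index=list(_FIXED_NAMES))

    @property
    def omega(self) -> tuple[float, float]:
        """Between-animal SDs of (log k_in, log k_e)."""
        return (math.exp(self.params[3]), math.exp(self.params[4]))

    @property
    def sigma(self) -> float:
        """Residual SD on the log-concentration scale."""
        return math.exp(self.params[5])

    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(self.cov_fixed, index=list(_FIXED_NAMES), columns=list(_FIXED_NAMES))

    def animal_params(self, animal_id) -> PKParams:
        """Empirical-Bayes structural parameters for one animal."""
        b1, b2 = self.random_effects[animal_id]
        lkin, ltin, lke = self.params[:3]
        return PKParams(math.exp(lkin + b1), math.exp(ltin), math.exp(lke + b2))

    def predict(self, t, animal_id=None) -> np.ndarray:
        """Fitted concentration curve at times ``t`` (population median by
        default, or one animal's empirical-Bayes curve)."""
        p = self.population_params if animal_id is None else self.animal_params(animal_id)
        return concentration_at(p, np.asarray(t, float))

    # -- derived quantities ----------------------------------------------
    def per_catheter_parameters(self, t_last: float = 480.0) -> pd.DataFrame:
        """Derived PK per catheter from the empirical-Bayes animal curves.

        Catheters of the same animal share that animal's parameters (no
        catheter-level refinement); columns mirror the usual PK report:
        one row per catheter with k_in, t_in, k_e, AUC_0–last, Cmax, Tmax,
        T1/2.
        """
        rows = []
        for ani in self.model._animals:
            if ani.animal_id not in self.random_effects:
                warnings.warn(f"animal {ani.animal_id!r} missing from fit; skipped")
                continue
            p = self.animal_params(ani.animal_id)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d = derived_parameters(p, t_last)
            for cath in ani.catheters:
                rows.append(
                    {
                        "tissue": self.model.tissue,
                        "animal_id": ani.animal_id,
                        "catheter_id": cath,
                        "k_in": p.k_in,
                        "t_in": p.t_in,
                        "k_e": p.k_e,
                        "auc_0_last": d.auc_0_last,
                        "c_max": d.c_max,
                        "t_max": d.t_max,
                        "t_half": d.t_half,
                    }
                )
        return pd.DataFrame(rows)

    def population_derived(self, t_last: float = 480.0, alpha: float = 0.05) -> pd.DataFrame:
        """Population-median derived PK with Wald CIs.

        Standard errors come from the delta method on the log scale using the
        fixed-effect covariance; intervals are back-transformed, so they are
        always positive.
        """
        from scipy import stats as sps

        lkin, ltin, lke = self.params[:3]

        def logderived(x):
            p = PKParams(*np.exp(x))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d = derived_parameters(p, t_last)
            return np.log([d.auc_0_last, d.t_half, d.c_max, d.t_max])

        x0 = np.array([lkin, ltin, lke])
        g0 = logderived(x0)
        h = 1e-6
        J = np.empty((4, 3))
        for j in range(3):
            ej = np.zeros(3)
            ej[j] = h
            J[:, j] = (logderived(x0 + ej) - logderived(x0 - ej)) / (2 * h)
        var = np.einsum("ij,jk,ik->i", J, self.cov_fixed, J)
        se = np.sqrt(np.clip(var, 0, None))
        z = sps.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "parameter": list(_DERIVED_NAMES),
                "median": np.exp(g0),
                "ci_low": np.exp(g0 - z * se),
                "ci_high": np.exp(g0 + z * se),
            }
        )

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        p = self.population_params
        w1, w2 = self.omega
        lines = [
            f"Tissue PK mixed-effects fit: {self.model.tissue or '<unnamed>'}",
            f"  observations: {self.model.nobs}   animals: {self.model.n_animals}   "
            f"converged: {self.converged}   logLik: {self.loglik:.3f}",
            f"  error model: log-normal, prediction = {self.model.prediction}",
            "",
            "  population medians (back-transformed fixed effects)",
            f"    k_in  = {p.k_in:.5g} ug/mL/min   (se log: {self.bse['log_k_in']:.3g})",
            f"    t_in  = {p.t_in:.5g} min          (se log: {self.bse['log_t_in']:.3g})",
            f"    k_e   = {p.k_e:.5g} 1/min        (se log: {self.bse['log_k_e']:.3g})",
            f"    t_half = {_LOG2 / p.k_e:.4g} min",
            "",
            f"  between-animal SD (log scale): k_in {w1:.3g}, k_e {w2:.3g}",
            f"  residual SD (log scale): {self.sigma:.3g}",
        ]
        if not self.mixed:
            lines.append("  note: fixed-effects-only fit (single animal or random effects disabled)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "tissue": self.model.tissue,
            "fixed_effects": {k: float(v) for k, v in self.fixed_effects.items()},
            "population": {
                "k_in": self.population_params.k_in,
                "t_in": self.population_params.t_in,
                "k_e": self.population_params.k_e,
            },
            "omega": {"log_k_in": self.omega[0], "log_k_e": self.omega[1]},
            "sigma": self.sigma,
            "cov_fixed": self.cov_fixed.tolist(),
            "random_effects": {str(k): list(v) for k, v in self.random_effects.items()},
            "converged": self.converged,
            "loglik": self.loglik,
            "mixed": self.mixed,
        }


def fit_all_tissues(
    obs: pd.DataFrame,
    tissue_col: str = "tissue",
    min_animals: int = 2,
    min_obs_per_animal: int = 4,
    **model_kwargs,
) -> dict:
    """Fit every tissue in a corrected observation table.

    Tissues with too little usable data are skipped with a warning; returns
    a dict tissue -> TissuePKResults.
    """
    out = {}
    for tissue in sorted(obs[tissue_col].unique()):
        sub = obs[obs[tissue_col] == tissue]
        cens = sub["censored"].astype(bool) if "censored" in sub.columns else pd.Series(False, index=sub.index)
        usable = sub[~cens & (sub["c_tissue_ug_ml"] > 0)]
        counts = usable.groupby("animal_id").size()
        if (counts >= min_obs_per_animal).sum() < min_animals:
            warnings.warn(f"tissue {tissue!r}: insufficient data for a mixed fit; skipped")
            continue
        ok_animals = counts[counts >= min_obs_per_animal].index
        sub = sub[sub["animal_id"].isin(ok_animals)]
        model = TissuePKModel(sub, tissue=tissue, **model_kwargs)
        out[tissue] = model.fit()
    return out
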