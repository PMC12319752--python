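"""Distributional normative regression (GAMLSS-style) for one brain measure.

Fits, per region × hemisphere × metric, a four-parameter distributional
model in which location (mu), scale (sigma), skew (nu) and kurtosis
(tau) each get their own additive predictor:

* mu:    intercept + smooth(age) + sex + site (random intercept)
* sigma: intercept + smooth(age) + sex + site (random intercept), log link
* nu:    intercept + smooth(age) + sex
* tau:   intercept + smooth(age), log link

The age smooth is a cubic B-spline with interior knots at age quantiles
and a second-order difference penalty; the smoothing parameter per
submodel is selected by generalised AIC on a log grid at the submodel's
first update and then frozen.  Site enters as a normal random intercept
realised as ridge-penalised site dummies whose shrinkage variance is
profiled in the first outer iterations.  Estimation is penalised maximum
likelihood by cyclic (Rigby–Stasinopoulos-style) updating of the four
submodels with numerically differentiated score/curvature and
step-halving, so the penalised log-likelihood is non-decreasing once the
penalties are frozen.

Usage follows the statsmodels pattern::

    model = NormativeGAMLSS.from_cohort(cohort, ("precentral", "left", "log10_thickness_mm"))
    res = model.fit()
    res.summary()
    res.predict_params(age=40.0, sex="female", site_mode="reference")
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .families import Family, get_family
from .io_tables import Cohort

logger = logging.getLogger(__name__)

__all__ = ["FitConfig", "DistParams", "NormativeGAMLSS", "NormativeResults",
           "ModelSet", "fit_normative"]

DEFAULT_TERMS = {
    "mu": ("intercept", "spline", "sex", "site"),
    "sigma": ("intercept", "spline", "sex", "site"),
    "nu": ("intercept", "spline", "sex"),
    "tau": ("intercept", "spline"),
}

SERIAL_VERSION = 1


@dataclass
class FitConfig:
    """Tunable fitting choices.

    Attributes
    ----------
    family : str
        "shash" (default), "gaussian" (nu/tau frozen) or "bcpe".
    n_knots : int
        Interior knots of the age B-spline, placed at age quantiles.
    max_iter, tol : int, float
        Outer-cycle budget and relative penalised-deviance tolerance.
    min_n : int
        Minimum subjects per model.
    terms : dict
        Per-parameter term tuples overriding the default covariate
        structure (used e.g. to force an intercept-only sigma).
    site_random : bool
        Random (shrunken) site intercepts; if False, unshrunken fixed
        site effects.
    reference_site : str or None
        Default None = training site with the most subjects.
    """

    family: str = "shash"
    n_knots: int = 10
    spline_degree: int = 3
    penalty_order: int = 2
    lambda_grid: tuple = tuple(float(v) for v in np.logspace(-2.0, 8.0, 11))
    max_iter: int = 200
    tol: float = 1e-6
    min_n: int = 200
    terms: dict = field(default_factory=dict)
    site_random: bool = True
    reference_site: str | None = None
    freeze_penalties_at: int = 3
    base_ridge: float = 1e-7

    def terms_for(self, param: str) -> tuple:
        return tuple(self.terms.get(param, DEFAULT_TERMS[param]))


@dataclass
class DistParams:
    """Predicted distribution parameters at given covariates."""

    mu: np.ndarray | float
    sigma: np.ndarray | float
    nu: np.ndarray | float
    tau: np.ndarray | float

    def as_tuple(self):
        return self.mu, self.sigma, self.nu, self.tau


@dataclass
class SplineSpec:
    """Cubic B-spline basis with frozen knots and column centring."""

    knots: np.ndarray
    degree: int
    centers: np.ndarray | None = None

    @classmethod
    def from_ages(cls, age: np.ndarray, n_knots: int, degree: int) -> "SplineSpec":
        lo, hi = float(np.min(age)), float(np.max(age))
        if hi - lo < 1e-9:
            hi = lo + 1.0
        qs = np.linspace(0, 1, n_knots + 2)[1:-1]
        interior = np.unique(np.quantile(age, qs))
        interior = interior[(interior > lo + 1e-9) & (interior < hi - 1e-9)]
        knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
        spec = cls(knots=knots, degree=degree)
        spec.centers = spec._raw(age).mean(axis=0)
        return spec

    @property
    def n_cols(self) -> int:
        return len(self.knots) - self.degree - 1

    def _raw(self, age: np.ndarray) -> np.ndarray:
        lo, hi = self.knots[self.degree], self.knots[-self.degree - 1]
        x = np.clip(np.asarray(age, dtype=float), lo, hi)
        return BSpline.design_matrix(x, self.knots, self.degree).toarray()

    def basis(self, age: np.ndarray) -> np.ndarray:
        return self._raw(age) - self.centers

    def support(self) -> tuple[float, float]:
        return float(self.knots[self.degree]), float(self.knots[-self.degree - 1])


def _diff_penalty(m: int, order: int) -> np.ndarray:
    D = np.diff(np.eye(m), n=order, axis=0)
    return D.T @ D


@dataclass
class Submodel:
    """One distribution parameter's additive predictor."""

    name: str
    link_name: str
    terms: tuple
    spline: SplineSpec | None
    site_levels: tuple = ()
    lambda_smooth: float | None = None
    lambda_site: float = 0.0
    coef: np.ndarray | None = None
    colnames: list = field(default_factory=list)
    cov: np.ndarray | None = None

    def slices(self) -> dict:
        out, pos = {}, 0
        for term in self.terms:
            width = {"intercept": 1, "sex": 1,
                     "spline": self.spline.n_cols if self.spline else 0,
                     "site": len(self.site_levels)}[term]
            out[term] = slice(pos, pos + width)
            pos += width
        out["__total__"] = pos
        return out

    def design(self, age, sex_male, site, site_mode=None) -> np.ndarray:
        """Assemble the design matrix.

        ``site`` is an array of site labels for training rows; for
        prediction pass ``site=None`` and a ``site_mode`` of
        "population" (site effect zero), a site name, or an indicator
        array is built per-row from ``site``.
        """
        age = np.atleast_1d(np.asarray(age, dtype=float))
        n = len(age)
        blocks = []
        for term in self.terms:
            if term == "intercept":
                blocks.append(np.ones((n, 1)))
            elif term == "spline":
                blocks.append(self.spline.basis(age))
            elif term == "sex":
                blocks.append(np.asarray(sex_male, dtype=float).reshape(n, 1))
            elif term == "site":
                Z = np.zeros((n, len(self.site_levels)))
                if site is not None:
                    idx = {s: j for j, s in enumerate(self.site_levels)}
                    for i, s in enumerate(np.asarray(site)):
                        Z[i, idx[s]] = 1.0
                elif site_mode not in (None, "population"):
                    if site_mode not in self.site_levels:
                        raise KeyError(f"unknown site {site_mode!r}; trained sites: {list(self.site_levels)}")
                    Z[:, self.site_levels.index(site_mode)] = 1.0
                blocks.append(Z)
        return np.hstack(blocks) if blocks else np.zeros((n, 0))

    def penalty(self, base_ridge: float) -> np.ndarray:
        sl = self.slices()
        p = sl["__total__"]
        P = np.eye(p) * base_ridge
        if "spline" in sl and self.spline is not None and self.lambda_smooth:
            s = sl["spline"]
            P[s, s] += self.lambda_smooth * _diff_penalty(self.spline.n_cols, 2)
        if "site" in sl and self.lambda_site:
            s = sl["site"]
            P[s, s] += self.lambda_site * np.eye(len(self.site_levels))
        return P

    def site_effects(self) -> dict:
        if "site" not in self.terms or self.coef is None:
            return {}
        s = self.slices()["site"]
        return dict(zip(self.site_levels, self.coef[s]))


def _sex_male(sex) -> np.ndarray:
    arr = np.asarray(sex)
    if arr.dtype.kind in "fiub":
        return arr.astype(float)
    return (pd.Series(arr).astype(str).str.lower().isin(["male", "m", "1"])).to_numpy(dtype=float)


class NormativeGAMLSS:
    """Model object: data + configuration; ``fit()`` returns results."""

    def __init__(self, y, age, sex, site, config: FitConfig | None = None,
                 target: tuple | None = None):
        self.config = config or FitConfig()
        self.y = np.asarray(y, dtype=float)
        self.age = np.asarray(age, dtype=float)
        self.sex_male = _sex_male(sex)
        self.site = np.asarray(site).astype(str)
        self.target = target
        n = len(self.y)
        if not (len(self.age) == len(self.sex_male) == len(self.site) == n):
            raise ValueError("y, age, sex, site must be aligned")
        if n < self.config.min_n:
            raise ValueError(f"n = {n} below min_n = {self.config.min_n}")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite response values")
        self.family: Family = get_family(self.config.family)
        self.site_levels = tuple(sorted(pd.unique(self.site)))

    @classmethod
    def from_cohort(cls, cohort: Cohort, target: tuple, config: FitConfig | None = None,
                    controls_only: bool = True) -> "NormativeGAMLSS":
        """Build from a joined cohort for one (region, hemisphere, metric)."""
        data = (cohort.controls() if controls_only else cohort).aligned(*target)
        if data.empty:
            raise ValueError(f"no data for target {target}")
        return cls(data["value"], data["age"], data["sex"], data["site"],
                   config=config, target=tuple(target))

    # ---- fitting -----------------------------------------------------

    def _build_submodels(self) -> dict:
        cfg = self.config
        spline = SplineSpec.from_ages(self.age, cfg.n_knots, cfg.spline_degree)
        one_sex = len(np.unique(self.sex_male)) < 2
        few_sites = len(self.site_levels) < 2
        subs = {}
        for name in self.family.free_params:
            terms = list(cfg.terms_for(name))
            if "sex" in terms and one_sex:
                warnings.warn(f"only one sex present; dropping sex term from {name}", stacklevel=3)
                terms.remove("sex")
            if "site" in terms and few_sites:
                warnings.warn("fewer than 2 sites; dropping site effect (intercept absorbs it)",
                              stacklevel=3)
                terms.remove("site")
            link = self.family.links[name].name
            subs[name] = Submodel(name=name, link_name=link, terms=tuple(terms),
                                  spline=spline if "spline" in terms else None,
                                  site_levels=self.site_levels if "site" in terms else ())
        if 2 <= len(self.site_levels) < 10 and any("site" in s.terms for s in subs.values()):
            logger.warning("only %d sites: random site effects are poorly identified below "
                           "~10 levels; consider site_random=False", len(self.site_levels))
        return subs

    def _params_from(self, subs: dict, etas: dict) -> tuple:
        out = []
        for name in ("mu", "sigma", "nu", "tau"):
            if name in subs:
                out.append(self.family.links[name].inverse(etas[name]))
            else:
                out.append(np.full_like(self.y, self.family.neutral.get(name, 0.0))
                           if name in ("nu", "tau") else None)
        return tuple(out)

    def _loglik(self, params) -> float:
        with np.errstate(all="ignore"):
            ll = self.family.logpdf(self.y, *params)
        return float(np.sum(ll)) if np.all(np.isfinite(ll)) else -np.inf

    def _penalty_value(self, subs: dict) -> float:
        tot = 0.0
        for s in subs.values():
            P = s.penalty(self.config.base_ridge)
            tot += float(s.coef @ P @ s.coef)
        return 0.5 * tot

    def _objective(self, subs, designs) -> float:
        etas = {k: designs[k] @ subs[k].coef for k in subs}
        return self._loglik(self._params_from(subs, etas)) - self._penalty_value(subs)

    def _eta_loglik(self, subs, etas, name, eta_try) -> np.ndarray:
        trial = dict(etas)
        trial[name] = eta_try
        params = self._params_from(subs, trial)
        with np.errstate(all="ignore"):
            return self.family.logpdf(self.y, *params)

    def _score_curvature(self, subs, etas, name):
        eta = etas[name]
        h = 1e-4 * (1.0 + np.abs(eta))
        lp = self._eta_loglik(subs, etas, name, eta + h)
        lm = self._eta_loglik(subs, etas, name, eta - h)
        l0 = self._eta_loglik(subs, etas, name, eta)
        g = (lp - lm) / (2 * h)
        H = (lp - 2 * l0 + lm) / (h * h)
        bad = ~(np.isfinite(g) & np.isfinite(H))
        g[bad] = 0.0
        w = -H
        pos = w[np.isfinite(w) & (w > 0)]
        floor = max(1e-10, 1e-4 * float(np.median(pos))) if pos.size else 1e-10
        # floor relative to the typical curvature: a hard tiny floor would let
        # the working response wreck the score of low-curvature observations
        w = np.clip(w, floor, 1e12)
        w[bad] = floor
        return g, w

    def _cross_curvature(self, subs, etas, name_a, name_b):
        """Mixed second derivative d²l / (deta_a deta_b), per observation."""
        ea, eb = etas[name_a], etas[name_b]
        ha = 1e-4 * (1.0 + np.abs(ea))
        hb = 1e-4 * (1.0 + np.abs(eb))

        def ll(da, db):
            trial = dict(etas)
            trial[name_a] = ea + da
            trial[name_b] = eb + db
            params = self._params_from(subs, trial)
            with np.errstate(all="ignore"):
                return self.family.logpdf(self.y, *params)

        d = (ll(ha, hb) - ll(ha, -hb) - ll(-ha, hb) + ll(-ha, -hb)) / (4 * ha * hb)
        d[~np.isfinite(d)] = 0.0
        return d

    def _select_lambda(self, sub: Submodel, X, w, u, n):
        """Generalised AIC (k = 2) over the lambda grid for the age smooth."""
        if sub.spline is None or "spline" not in sub.terms:
            sub.lambda_smooth = 0.0
            return
        best = (np.inf, self.config.lambda_grid[0])
        XtW = X.T * w
        XtWX = XtW @ X
        XtWu = XtW @ u
        for lam in self.config.lambda_grid:
            sub.lambda_smooth = lam
            P = sub.penalty(self.config.base_ridge)
            try:
                A = XtWX + P
                beta = np.linalg.solve(A, XtWu)
                edf = float(np.trace(np.linalg.solve(A, XtWX)))
            except np.linalg.LinAlgError:
                continue
            rss = float(w @ (u - X @ beta) ** 2)
            gaic = n * np.log(max(rss / n, 1e-300)) + 2.0 * edf
            if gaic < best[0]:
                best = (gaic, lam)
        sub.lambda_smooth = best[1]

    def _init_site_variance(self, sub: Submodel, resid: np.ndarray, scale_guess: float):
        """Method-of-moments between-site variance -> ridge penalty."""
        if "site" not in sub.terms:
            return
        if not self.config.site_random:
            sub.lambda_site = self.config.base_ridge
            return
        s = pd.Series(resid).groupby(pd.Series(self.site)).agg(["mean", "count"])
        between = float(np.var(s["mean"].to_numpy(), ddof=1)) if len(s) > 1 else 0.0
        sampling = float(np.mean(scale_guess ** 2 / s["count"].to_numpy()))
        var_site = max(between - sampling, 1e-4 * scale_guess ** 2, 1e-10)
        sub.lambda_site = 1.0 / var_site

    def fit(self) -> "NormativeResults":
        """Penalised ML via cyclic submodel updating with step-halving."""
        cfg = self.config
        subs = self._build_submodels()
        designs = {k: s.design(self.age, self.sex_male, self.site) for k, s in subs.items()}
        n = len(self.y)

        # --- initial values: Gaussian-flavoured warm start
        mu_sub = subs["mu"]
        X = designs["mu"]
        w0 = np.ones(n)
        self._select_lambda(mu_sub, X, w0, self.y, n)
        # site variance from residuals of a no-site pre-fit
        sl = mu_sub.slices()
        nosite = np.ones(X.shape[1], dtype=bool)
        if "site" in sl:
            nosite[sl["site"]] = False
        Xi = X[:, nosite]
        Pi = mu_sub.penalty(cfg.base_ridge)[np.ix_(nosite, nosite)]
        beta_i = np.linalg.solve(Xi.T @ Xi + Pi, Xi.T @ self.y)
        resid0 = self.y - Xi @ beta_i
        scale0 = float(np.std(resid0)) or 1e-6
        self._init_site_variance(mu_sub, resid0, scale0)
        beta0 = np.zeros(X.shape[1])
        beta0[nosite] = beta_i
        mu_sub.coef = np.linalg.solve(X.T @ X + mu_sub.penalty(cfg.base_ridge), X.T @ self.y)

        for name in ("sigma", "nu", "tau"):
            if name not in subs:
                continue
            s = subs[name]
            p = s.slices()["__total__"]
            s.coef = np.zeros(p)
            neutral_eta = {"sigma": np.log(scale0),
                           "nu": self.family.neutral.get("nu", 0.0),
                           "tau": np.log(self.family.neutral.get("tau", 1.0))
                           if s.link_name == "log" else self.family.neutral.get("tau", 1.0)}[name]
            if "intercept" in s.terms:
                s.coef[s.slices()["intercept"]] = neutral_eta
            if name == "sigma" and "site" in s.terms:
                # between-site spread of log residual SD
                grp = pd.Series(resid0).groupby(pd.Series(self.site))
                log_sds = np.log(grp.std().to_numpy() + 1e-12)
                var_site = max(float(np.var(log_sds, ddof=1)) if len(log_sds) > 1 else 0.0, 1e-4)
                s.lambda_site = (1.0 / var_site) if cfg.site_random else cfg.base_ridge
            s.lambda_smooth = None  # selected at first update

        # --- outer cycle
        objective = self._objective(subs, designs)
        history = []
        converged = False
        it = 0
        for it in range(1, cfg.max_iter + 1):
            for name, sub in subs.items():
                X = designs[name]
                etas = {k: designs[k] @ subs[k].coef for k in subs}
                g, w = self._score_curvature(subs, etas, name)
                u = etas[name] + g / w
                if sub.lambda_smooth is None:
                    self._select_lambda(sub, X, w, u, n)
                    objective = self._objective(subs, designs)
                P = sub.penalty(cfg.base_ridge)
                XtW = X.T * w
                try:
                    beta_prop = np.linalg.solve(XtW @ X + P, XtW @ u)
                except np.linalg.LinAlgError:
                    continue
                old = sub.coef.copy()
                step = 1.0
                for _ in range(30):
                    sub.coef = old + step * (beta_prop - old)
                    trial = self._objective(subs, designs)
                    if np.isfinite(trial) and trial >= objective - 1e-10:
                        objective = max(objective, trial)
                        break
                    step *= 0.5
                else:
                    sub.coef = old
            if it == cfg.freeze_penalties_at:
                # one EM refinement of the site shrinkage variances, then freeze
                for sub in subs.values():
                    if "site" in sub.terms and cfg.site_random:
                        b = np.array(list(sub.site_effects().values()))
                        var_site = max(float(np.mean(b * b)), 1e-10)
                        sub.lambda_site = 1.0 / var_site
                objective = self._objective(subs, designs)
                history = [objective]
                continue
            prev = history[-1] if history else None
            history.append(objective)
            if prev is not None and abs(objective - prev) / (abs(prev) + 0.1) < cfg.tol:
                converged = True
                break
        if not converged:
            warnings.warn(f"normative fit did not converge in {cfg.max_iter} outer iterations "
                          f"(target {self.target})", stacklevel=2)

        # --- covariances at convergence: joint observed information across
        # all submodels (cross-parameter curvature matters: e.g. mu and nu
        # jointly shift the location, so block-diagonal SEs would be too small)
        etas = {k: designs[k] @ subs[k].coef for k in subs}
        names = list(subs)
        sizes = [len(subs[k].coef) for k in names]
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        A = np.zeros((offsets[-1], offsets[-1]))
        for a, na in enumerate(names):
            Xa = designs[na]
            _, w = self._score_curvature(subs, etas, na)
            blk = (Xa.T * w) @ Xa + subs[na].penalty(cfg.base_ridge)
            A[offsets[a]:offsets[a + 1], offsets[a]:offsets[a + 1]] = blk
            for b in range(a + 1, len(names)):
                nb = names[b]
                d = self._cross_curvature(subs, etas, na, nb)
                Xb = designs[nb]
                cross = (Xa.T * np.clip(-d, -1e10, 1e10)) @ Xb
                A[offsets[a]:offsets[a + 1], offsets[b]:offsets[b + 1]] = cross
                A[offsets[b]:offsets[b + 1], offsets[a]:offsets[a + 1]] = cross.T
        try:
            cov_full = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            cov_full = np.full_like(A, np.nan)
        for a, na in enumerate(names):
            sub = subs[na]
            sub.cov = cov_full[offsets[a]:offsets[a + 1], offsets[a]:offsets[a + 1]]
            sub.colnames = self._colnames(sub)

        mu_hat = etas["mu"]
        resid = self.y - mu_hat
        per_site_sd = {s: float(np.std(resid[self.site == s], ddof=1))
                       for s in self.site_levels}
        counts = pd.Series(self.site).value_counts()
        reference_site = cfg.reference_site or str(counts.idxmax())
        if reference_site not in self.site_levels:
            raise ValueError(f"reference site {reference_site!r} not among training sites")
        ss_tot = float(np.sum((self.y - self.y.mean()) ** 2))
        if ss_tot <= 0:
            raise ValueError("zero variance in response")
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot

        return NormativeResults(
            model=self, submodels=subs, converged=converged, iterations=it,
            penalized_loglik=objective, loglik_history=list(history),
            reference_site=reference_site, per_site_residual_sd=per_site_sd,
            r2_train=r2,
            training_summary={
                "n": n, "n_sites": len(self.site_levels),
                "sites": list(self.site_levels),
                "age_range": [float(self.age.min()), float(self.age.max())],
                "target": list(self.target) if self.target else None,
            },
        )

    def _colnames(self, sub: Submodel) -> list:
        names = []
        for term in sub.terms:
            if term == "intercept":
                names.append("intercept")
            elif term == "sex":
                names.append("sex[male]")
            elif term == "spline":
                names += [f"spline_{j}" for j in range(sub.spline.n_cols)]
            elif term == "site":
                names += [f"site[{s}]" for s in sub.site_levels]
        return names


@dataclass
class NormativeResults:
    """Fitted normative model: estimates, uncertainties, diagnostics.

    Carries everything needed to predict distribution parameters for new
    covariates, draw centile curves, compute quantile residuals and R²,
    and serialise to versioned JSON.
    """

    model: NormativeGAMLSS | None
    submodels: dict
    converged: bool
    iterations: int
    penalized_loglik: float
    loglik_history: list
    reference_site: str
    per_site_residual_sd: dict
    r2_train: float
    training_summary: dict
    family_name: str = ""

    def __post_init__(self):
        if not self.family_name:
            self.family_name = self.model.family.name

    @property
    def family(self) -> Family:
        return get_family(self.family_name)

    @property
    def params(self) -> dict:
        return {name: pd.Series(s.coef, index=s.colnames or None)
                for name, s in self.submodels.items()}

    @property
    def bse(self) -> dict:
        out = {}
        for name, s in self.submodels.items():
            se = np.sqrt(np.diag(s.cov)) if s.cov is not None else np.full(len(s.coef), np.nan)
            out[name] = pd.Series(se, index=s.colnames or None)
        return out

    # ---- prediction --------------------------------------------------

    def predict_params(self, age, sex, site_mode: str = "reference",
                       allow_unconverged: bool = False) -> DistParams:
        """Evaluate the four submodels at the given covariates.

        ``site_mode``: "reference" (the designated reference site's
        effect), "population" (site effect 0) or a named training site.
        Ages outside the training range are clamped to the boundary of
        the age smooth with an extrapolation warning.
        """
        if not self.converged and not allow_unconverged:
            raise RuntimeError("model did not converge; pass allow_unconverged=True to predict anyway")
        age_arr = np.atleast_1d(np.asarray(age, dtype=float))
        lo, hi = self.training_summary["age_range"]
        if np.any(age_arr < lo - 1e-9) or np.any(age_arr > hi + 1e-9):
            warnings.warn(f"age outside training range [{lo:.1f}, {hi:.1f}]; "
                          "extrapolating with boundary values", stacklevel=2)
        sex_male = _sex_male(np.broadcast_to(np.asarray(sex), age_arr.shape).copy()
                             if np.ndim(sex) == 0 else sex)
        mode = self.reference_site if site_mode == "reference" else site_mode
        values = {}
        for name in ("mu", "sigma", "nu", "tau"):
            if name in self.submodels:
                s = self.submodels[name]
                X = s.design(age_arr, sex_male, site=None, site_mode=mode)
                values[name] = self.family.links[name].inverse(X @ s.coef)
            else:
                values[name] = np.full(age_arr.shape, self.family.neutral[name])
        scalar = np.ndim(age) == 0
        if scalar:
            values = {k: float(v[0]) for k, v in values.items()}
        return DistParams(**values)

    def centile_curves(self, ages, sex, centiles=(0.05, 0.25, 0.5, 0.75, 0.95),
                       site_mode: str = "population") -> pd.DataFrame:
        """Inverse-CDF curves over an age grid; one column per probability."""
        centiles = np.asarray(centiles, dtype=float)
        if np.any(centiles <= 0) or np.any(centiles >= 1):
            raise ValueError("centile probabilities must lie in (0, 1)")
        p = self.predict_params(ages, sex, site_mode=site_mode)
        cols = {}
        for c in centiles:
            cols[c] = self.family.ppf(c, *p.as_tuple())
        return pd.DataFrame(cols, index=pd.Index(np.atleast_1d(ages), name="age"))

    def residuals(self, y=None, age=None, sex=None, site=None) -> np.ndarray:
        """Raw residuals about fitted mu (training data by default)."""
        if y is None:
            m = self.model
            if m is None:
                raise ValueError("deserialised results hold no training data; pass y/age/sex/site")
            y, age, sex, site = m.y, m.age, m.sex_male, m.site
        mus = np.empty(len(np.atleast_1d(y)), dtype=float)
        site = np.asarray(site).astype(str)
        for s in np.unique(site):
            mask = site == s
            mode = s if s in self.submodels["mu"].site_levels else "population"
            p = self.predict_params(np.asarray(age)[mask], np.asarray(sex)[mask], site_mode=mode)
            mus[mask] = p.mu
        return np.asarray(y, dtype=float) - mus

    def r2(self, y=None, age=None, sex=None, site=None) -> float:
        """R² = 1 - SS_resid/SS_total about fitted mu (covariates + site)."""
        if y is None:
            return self.r2_train
        y = np.asarray(y, dtype=float)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot <= 0:
            raise ValueError("zero variance in response")
        resid = self.residuals(y, age, sex, site)
        return 1.0 - float(np.sum(resid ** 2)) / ss_tot

    def quantile_residuals(self, y=None, age=None, sex=None, site=None) -> np.ndarray:
        """Normalised quantile residuals Phi^-1(F(y)) given full params."""
        if y is None:
            m = self.model
            y, age, sex, site = m.y, m.age, m.sex_male, m.site
        y = np.asarray(y, dtype=float)
        out = np.empty(len(y))
        site = np.asarray(site).astype(str)
        for s in np.unique(site):
            mask = site == s
            mode = s if s in self.submodels["mu"].site_levels else "population"
            p = self.predict_params(np.asarray(age)[mask], np.asarray(sex)[mask], site_mode=mode)
            out[mask] = self.family.quantile_residuals(y[mask], *p.as_tuple())
        return out

    def summary(self) -> str:
        ts = self.training_summary
        lines = [
            "Normative distributional regression results",
            "=" * 46,
            f"target:          {ts.get('target')}",
            f"family:          {self.family_name}",
            f"n subjects:      {ts['n']}   sites: {ts['n_sites']}   "
            f"age range: {ts['age_range'][0]:.1f}-{ts['age_range'][1]:.1f}",
            f"converged:       {self.converged} ({self.iterations} outer iterations)",
            f"penalised loglik: {self.penalized_loglik:.3f}",
            f"R² (training):   {self.r2_train:.4f}",
            f"reference site:  {self.reference_site}",
            "",
        ]
        bse = self.bse
        for name, coefs in self.params.items():
            lines.append(f"[{name}]  link={self.submodels[name].link_name}  "
                         f"lambda_smooth={self.submodels[name].lambda_smooth}")
            for label, val in coefs.items():
                if isinstance(label, str) and label.startswith("spline_"):
                    continue
                se = bse[name].get(label, np.nan)
                lines.append(f"    {label:<20s} {val:+.5f}  (se {se:.5f})")
            lines.append("")
        return "\n".join(lines)

    # ---- serialisation ------------------------------------------------

    def to_dict(self) -> dict:
        subs = {}
        for name, s in self.submodels.items():
            subs[name] = {
                "link": s.link_name,
                "terms": list(s.terms),
                "site_levels": list(s.site_levels),
                "lambda_smooth": s.lambda_smooth,
                "lambda_site": s.lambda_site,
                "coef": np.asarray(s.coef).tolist(),
                "colnames": list(s.colnames),
                "cov": np.asarray(s.cov).tolist() if s.cov is not None else None,
                "spline": None if s.spline is None else {
                    "knots": s.spline.knots.tolist(),
                    "degree": s.spline.degree,
                    "centers": s.spline.centers.tolist(),
                },
            }
        return {
            "serial_version": SERIAL_VERSION,
            "family": self.family_name,
            "submodels": subs,
            "converged": self.converged,
            "iterations": self.iterations,
            "penalized_loglik": self.penalized_loglik,
            "reference_site": self.reference_site,
            "per_site_residual_sd": self.per_site_residual_sd,
            "r2_train": self.r2_train,
            "training_summary": self.training_summary,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormativeResults":
        if d.get("serial_version") != SERIAL_VERSION:
            raise ValueError(f"unsupported model serialisation version: {d.get('serial_version')}")
        subs = {}
        for name, sd in d["submodels"].items():
            spline = None
            if sd["spline"] is not None:
                spline = SplineSpec(knots=np.asarray(sd["spline"]["knots"]),
                                    degree=int(sd["spline"]["degree"]),
                                    centers=np.asarray(sd["spline"]["centers"]))
            subs[name] = Submodel(
                name=name, link_name=sd["link"], terms=tuple(sd["terms"]),
                spline=spline, site_levels=tuple(sd["site_levels"]),
                lambda_smooth=sd["lambda_smooth"], lambda_site=sd["lambda_site"],
                coef=np.asarray(sd["coef"], dtype=float), colnames=list(sd["colnames"]),
                cov=None if sd["cov"] is None else np.asarray(sd["cov"], dtype=float),
            )
        return cls(model=None, submodels=subs, converged=d["converged"],
                   iterations=d["iterations"], penalized_loglik=d["penalized_loglik"],
                   loglik_history=[], reference_site=d["reference_site"],
                   per_site_residual_sd=dict(d["per_site_residual_sd"]),
                   r2_train=d["r2_train"], training_summary=d["training_summary"],
                   family_name=d["family"])


def fit_normative(cohort: Cohort, target: tuple, config: FitConfig | None = None,
                  controls_only: bool = True) -> NormativeResults:
    """Convenience wrapper: build the model from a cohort and fit it."""
    return NormativeGAMLSS.from_cohort(cohort, target, config, controls_only).fit()


@dataclass
class ModelSet:
    """Fitted models keyed by (region, hemisphere, metric) + training summary."""

    models: dict
    training_summary: dict = field(default_factory=dict)

    @staticmethod
    def key(target) -> str:
        return "|".join(target)

    def get(self, region: str, hemisphere: str, metric: str) -> NormativeResults:
        return self.models[self.key((region, hemisphere, metric))]

    @classmethod
    def fit(cls, cohort: Cohort, targets=None, config: FitConfig | None = None) -> "ModelSet":
        """Fit all targets on one identical (post-QC) subject list."""
        targets = targets if targets is not None else cohort.morphometry.targets()
        ctrl = cohort.controls()
        subject_list = sorted(ctrl.meta["subject_id"])
        models = {}
        for target in targets:
            models[cls.key(target)] = fit_normative(cohort, target, config)
        meta = ctrl.meta
        summary = {
            "n_subjects": len(subject_list),
            "n_sites": int(meta["site"].nunique()),
            "age_range": [float(meta["age"].min()), float(meta["age"].max())],
            "targets": [list(t) for t in targets],
        }
        return cls(models=models, training_summary=summary)

    def to_json(self, path) -> None:
        payload = {
            "serial_version": SERIAL_VERSION,
            "training_summary": self.training_summary,
            "models": {k: m.to_dict() for k, m in self.models.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ModelSet":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("serial_version") != SERIAL_VERSION:
            raise ValueError("unsupported ModelSet serialisation version")
        models = {k: NormativeResults.from_dict(d) for k, d in payload["models"].items()}
        return cls(models=models, training_summary=payload["training_summary"])
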