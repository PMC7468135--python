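"""Stage-2 Bayesian Gaussian mixed models of per-series trend and
fluctuation estimates.

The workhorse is a blocked Gibbs sampler for

    y_i = x_i' beta + b_{s(i)} + e_i,
    b_s ~ N(0, var_species),      e_i ~ N(0, var_residual [+ mev_i]),

with conjugate normal updates for the coefficients and random intercepts and
inverse-gamma updates for the variances.  Categorical predictors are fitted
with a zero intercept (one coefficient per level, no reference category) so
each level's net trend is tested directly against zero; continuous
predictors get an ordinary intercept.

Known per-observation measurement-error variances (mev) are handled by
latent-truth augmentation: y_i ~ N(theta_i, mev_i) with theta_i following
the mixed model, which keeps every update conjugate.  An alternative
relative-precision weighting is available behind ``weighting='precision'``.

Coefficient priors are N(0, 1e8); variance priors are inverse-gamma(0.001,
0.001) by default (a proper, weakly informative stand-in for the improper
limiting prior sometimes quoted for such models); both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MCMCSettings",
    "ModelSpec",
    "HierarchicalResults",
    "HierarchicalFit",
    "HierarchicalGaussianModel",
    "gibbs_mixed_fit",
    "posterior_summary",
    "standardize_effect",
]


@dataclass
class MCMCSettings:
    """Sampler run length.  ``iterations`` counts total Gibbs sweeps; draws
    after ``burnin`` are retained every ``thin`` sweeps."""

    iterations: int = 120_000
    burnin: int = 20_000
    thin: int = 10
    chains: int = 1
    seed: int | None = None

    def __post_init__(self):
        if self.iterations <= self.burnin:
            raise ValueError("iterations must exceed burnin")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burnin) // self.thin


@dataclass
class ModelSpec:
    """Declarative description of one stage-2 model."""

    response: str
    fixed: str | None = None
    fixed_type: str = "categorical"  # or "continuous"
    intercept: bool | None = None  # default: zero for categorical, on otherwise
    random_species: bool = True
    mev: np.ndarray | None = None
    weighting: str = "mev"  # or "precision"
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)


@dataclass
class HierarchicalResults:
    """Posterior draws and summaries from the Gibbs sampler.

    ``draws`` maps parameter names (coefficients, 'var_species',
    'var_residual') to arrays of retained samples with shape
    (chains, n_retained) flattened to 1-D for single-chain runs.
    """

    param_names: list[str]
    draws: dict[str, np.ndarray]
    spec: ModelSpec
    input_sds: dict[str, float] = field(default_factory=dict)

    def _flat(self, name) -> np.ndarray:
        return np.ravel(self.draws[name])

    def summary_frame(self, level: float = 0.95) -> pd.DataFrame:
        return posterior_summary(self, level=level)

    def summary(self, level: float = 0.95) -> str:
        df = self.summary_frame(level)
        head = (f"Hierarchical Gaussian model: response={self.spec.response}, "
                f"fixed={self.spec.fixed or '(intercept only)'}, "
                f"species random intercept={'on' if self.spec.random_species else 'off'}")
        return head + "\n" + df.to_string(float_format=lambda v: f"{v: .5f}")

    def standardized_effects(self) -> dict[str, float]:
        """Posterior-mean effects divided by the sd of their input variable
        (comparable across predictors)."""
        out = {}
        for name in self.param_names:
            sd = self.input_sds.get(name)
            if sd:
                out[name] = standardize_effect(float(np.mean(self._flat(name))), sd)
        return out

    def rhat(self) -> dict[str, float]:
        """Split-R-hat per parameter (needs >= 2 chains)."""
        out = {}
        for name, arr in self.draws.items():
            a = np.atleast_2d(arr)
            if a.shape[0] < 2:
                # split a single chain in halves
                half = a.shape[1] // 2
                a = np.vstack([a[0, :half], a[0, half:2 * half]])
            m, n = a.shape
            half = n // 2
            a = a[:, : 2 * half].reshape(2 * m, half)
            chain_means = a.mean(axis=1)
            b = half * np.var(chain_means, ddof=1)
            w = np.mean(np.var(a, axis=1, ddof=1))
            var_plus = (half - 1) / half * w + b / half
            out[name] = float(np.sqrt(var_plus / w)) if w > 0 else np.nan
        return out


#: legacy alias matching the pipeline vocabulary
HierarchicalFit = HierarchicalResults


def standardize_effect(effect: float, input_sd: float) -> float:
    """Effect size divided by the standard deviation of its input data."""
    if input_sd <= 0:
        raise ValueError("input_sd must be positive")
    return effect / input_sd


def posterior_summary(fit: HierarchicalResults, level: float = 0.95) -> pd.DataFrame:
    """Posterior mean and central credible interval per parameter, with a
    'differs from zero' flag (interval excludes zero) for the effects."""
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    rows = []
    names = fit.param_names + [n for n in ("var_species", "var_residual")
                               if n in fit.draws]
    for name in names:
        d = fit._flat(name)
        if d.size < 100:
            raise ValueError("need at least 100 retained draws to summarise")
        lo, hi = np.quantile(d, [lo_q, hi_q])
        rows.append(dict(
            parameter=name, mean=float(np.mean(d)), ci_lo=float(lo),
            ci_hi=float(hi),
            differs_from_zero=bool(hi < 0 or lo > 0) if not name.startswith("var_")
            else False,
        ))
    return pd.DataFrame(rows).set_index("parameter")


class HierarchicalGaussianModel:
    """Gaussian mixed model fitted by blocked Gibbs sampling.

    Build with :meth:`from_dataframe`, then call :meth:`fit`.
    """

    def __init__(self, y, X, param_names, species=None, mev=None,
                 weighting="mev", spec: ModelSpec | None = None,
                 input_sds=None, beta_prior_var: float = 1e8,
                 ig_shape: float = 0.001, ig_scale: float = 0.001):
        self.y = np.asarray(y, dtype=float)
        if not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite response values")
        self.X = np.asarray(X, dtype=float)
        self.param_names = list(param_names)
        if self.X.shape != (self.y.size, len(self.param_names)):
            raise ValueError("design matrix shape mismatch")
        self.species = None
        if species is not None:
            labels, idx = np.unique(np.asarray(species), return_inverse=True)
            self.species_labels, self.species_idx = labels, idx
            self.n_species = labels.size
            self.species = idx
        self.mev = None if mev is None else np.asarray(mev, dtype=float)
        if self.mev is not None and np.any(self.mev < 0):
            raise ValueError("mev variances must be >= 0")
        self.weighting = weighting
        self.spec = spec
        self.input_sds = dict(input_sds or {})
        self.beta_prior_var = beta_prior_var
        self.ig_shape = ig_shape
        self.ig_scale = ig_scale

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str,
                       fixed: str | None = None, fixed_type: str = "categorical",
                       intercept: bool | None = None, species: str | None = "species",
                       mev: str | np.ndarray | None = None,
                       weighting: str = "mev", mcmc: MCMCSettings | None = None,
                       **prior_kw) -> "HierarchicalGaussianModel":
        """Build the design from a stage-2 table.

        Categorical predictors use the zero-intercept parameterisation (one
        column per sorted level).  Continuous predictors get an intercept
        unless ``intercept=False`` (e.g., the duration sensitivity model,
        where zero duration must imply zero change).
        """
        y = df[response].to_numpy(dtype=float)
        input_sds = {}
        if fixed is None:
            X = np.ones((y.size, 1))
            names = ["intercept"]
        elif fixed_type == "categorical":
            levels = np.unique(df[fixed].astype(str))
            codes = pd.Categorical(df[fixed].astype(str), categories=levels).codes
            X = np.eye(levels.size)[codes]
            names = [f"{fixed}[{lev}]" for lev in levels]
            sd_y = float(np.std(y, ddof=1)) if y.size > 1 else 0.0
            for n in names:
                input_sds[n] = sd_y
        elif fixed_type == "continuous":
            x = df[fixed].to_numpy(dtype=float)
            use_icpt = True if intercept is None else bool(intercept)
            if use_icpt:
                X = np.column_stack([np.ones_like(x), x])
                names = ["intercept", fixed]
            else:
                X = x[:, None]
                names = [fixed]
            input_sds[fixed] = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        else:
            raise ValueError("fixed_type must be 'categorical' or 'continuous'")
        sp = df[species].to_numpy() if (species and species in df.columns) else None
        mev_arr = None
        if isinstance(mev, str):
            mev_arr = df[mev].to_numpy(dtype=float)
        elif mev is not None:
            mev_arr = np.asarray(mev, dtype=float)
        spec = ModelSpec(response=response, fixed=fixed, fixed_type=fixed_type,
                         intercept=intercept, random_species=sp is not None,
                         mev=mev_arr, weighting=weighting,
                         mcmc=mcmc or MCMCSettings())
        return cls(y, X, names, species=sp, mev=mev_arr, weighting=weighting,
                   spec=spec, input_sds=input_sds, **prior_kw)

    # ------------------------------------------------------------------
    def _run_chain(self, settings: MCMCSettings, rng,
                   residual_var: float | None = None) -> dict[str, np.ndarray]:
        y, X = self.y, self.X
        n, p = X.shape
        use_re = self.species is not None
        idx = self.species if use_re else None
        q = self.n_species if use_re else 0
        a0, b0 = self.ig_shape, self.ig_scale
        prior_prec = 1.0 / self.beta_prior_var

        precision_mode = self.mev is not None and self.weighting == "precision"
        mev_mode = self.mev is not None and self.weighting == "mev"
        if precision_mode:
            # relative residual variances c_i (geometric mean 1): e_i ~ N(0, var_e*c_i)
            c_rel = np.maximum(self.mev, 1e-300)
            c_rel = c_rel / np.exp(np.mean(np.log(c_rel)))
            w_rel = 1.0 / c_rel
        else:
            w_rel = np.ones(n)
        XtX = (X * w_rel[:, None]).T @ X  # reused whenever weights are iteration-fixed

        mev_pos = mev_mode and bool(np.any(self.mev > 0))
        if mev_pos:
            pos = self.mev > 0
            mev_p = self.mev[pos]

        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        b = np.zeros(q) if use_re else None
        resid0 = y - X @ beta
        var_e = residual_var if residual_var is not None \
            else max(float(np.var(resid0)), 1e-6)
        var_b = max(var_e, 1e-6)

        keep = (settings.iterations - settings.burnin) // settings.thin
        out_beta = np.empty((keep, p))
        out_var_e = np.empty(keep)
        out_var_b = np.empty(keep) if use_re else None
        k = 0
        eye_p = np.eye(p)
        for it in range(settings.iterations):
            zb = b[idx] if use_re else 0.0
            # per-observation precisions; under mev the latent truths are
            # marginalised out of the beta/b updates so the chain mixes even
            # when var_e << mev
            if mev_mode:
                wi = 1.0 / (var_e + self.mev)
                XtWX = (X * wi[:, None]).T @ X
            else:
                wi = w_rel / var_e
                XtWX = XtX / var_e
            # --- coefficients
            prec = XtWX + prior_prec * eye_p
            rhs = X.T @ (wi * (y - zb))
            L = np.linalg.cholesky(prec)
            m = np.linalg.solve(L.T, np.linalg.solve(L, rhs))
            beta = m + np.linalg.solve(L.T, rng.standard_normal(p))
            fit = X @ beta
            # --- species intercepts
            if use_re:
                r = y - fit
                sums = np.bincount(idx, weights=r * wi, minlength=q)
                counts = np.bincount(idx, weights=wi, minlength=q)
                prec_b = counts + 1.0 / var_b
                mean_b = sums / prec_b
                b = mean_b + rng.standard_normal(q) / np.sqrt(prec_b)
                zb = b[idx]
                var_b = 1.0 / rng.gamma(a0 + q / 2.0, 1.0 / (b0 + 0.5 * b @ b))
            # --- residual variance (skipped when known/fixed)
            if residual_var is None:
                mu_i = fit + zb
                if mev_pos:
                    # impute latent truths where mev > 0, then conjugate update
                    theta = y.copy()
                    prec_t = 1.0 / mev_p + 1.0 / var_e
                    mean_t = (y[pos] / mev_p + mu_i[pos] / var_e) / prec_t
                    theta[pos] = mean_t + rng.standard_normal(mev_p.size) / np.sqrt(prec_t)
                    r = theta - mu_i
                    ssr = float(r @ r)
                else:
                    r = y - mu_i
                    ssr = float(r * w_rel @ r)
                var_e = 1.0 / rng.gamma(a0 + n / 2.0, 1.0 / (b0 + 0.5 * ssr))
            if it >= settings.burnin and (it - settings.burnin) % settings.thin == 0:
                out_beta[k] = beta
                out_var_e[k] = var_e
                if use_re:
                    out_var_b[k] = var_b
                k += 1
        draws = {nm: out_beta[:, j] for j, nm in enumerate(self.param_names)}
        draws["var_residual"] = out_var_e
        if use_re:
            draws["var_species"] = out_var_b
        return draws

    def fit(self, iterations: int | None = None, burnin: int | None = None,
            thin: int | None = None, chains: int | None = None,
            seed: int | None = None,
            residual_var: float | None = None) -> HierarchicalResults:
        """Run the Gibbs sampler; reproducible given ``seed``.

        ``residual_var`` fixes the residual variance at a known value
        (useful for conjugate closed-form checks and error-calibration
        studies); by default it is sampled.
        """
        base = self.spec.mcmc if self.spec else MCMCSettings()
        settings = MCMCSettings(
            iterations=iterations or base.iterations,
            burnin=base.burnin if burnin is None else burnin,
            thin=thin or base.thin,
            chains=chains or base.chains,
            seed=base.seed if seed is None else seed,
        )
        ss = np.random.SeedSequence(settings.seed)
        chains_out = [self._run_chain(settings, np.random.default_rng(s),
                                      residual_var=residual_var)
                      for s in ss.spawn(settings.chains)]
        draws = {}
        for name in chains_out[0]:
            stacked = np.stack([c[name] for c in chains_out])
            draws[name] = stacked[0] if settings.chains == 1 else stacked
        spec = self.spec or ModelSpec(response="y")
        spec.mcmc = settings
        return HierarchicalResults(self.param_names, draws, spec,
                                   input_sds=self.input_sds)


def gibbs_mixed_fit(df: pd.DataFrame, spec: ModelSpec, **kw) -> HierarchicalResults:
    """Fit a stage-2 model described by ``spec`` on a (response, predictor,
    species) table; returns posterior draws and summaries."""
    model = HierarchicalGaussianModel.from_dataframe(
        df, response=spec.response, fixed=spec.fixed, fixed_type=spec.fixed_type,
        intercept=spec.intercept,
        species="species" if spec.random_species else None,
        mev=spec.mev, weighting=spec.weighting, mcmc=spec.mcmc, **kw,
    )
    return model.fit()
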