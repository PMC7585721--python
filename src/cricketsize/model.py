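"""Bayesian hierarchical trait-size model.

Per morphological trait, the latent true size of individual *i* at site
*j(i)* follows a linear model in the design factors

    z_i = x_i' beta + u_{j(i)},      u_j ~ Normal(0, sigma_site^2)

with fixed effects for isolation (continuous vs isolated), rearing origin
(field vs laboratory), sex, year, and the isolation x sex,
isolation x origin, origin x sex and isolation x origin x sex interactions
(reference levels continuous / field / male / 2008). Digitally measured
rows observe z_i with residual noise sigma^2; calliper-measured rows
observe z_i shifted by the instrument conversion offset, whose posterior
uncertainty enters as extra observation-level variance. Marginalising the
latent size, the observation model is

    y_i - offset_i ~ Normal(x_i' beta + u_{j(i)},  sigma^2 + tau_i^2)

where (offset_i, tau_i) are the calibration posterior mean and sd for
calliper rows and (0, 0) for digital rows.

Priors are minimally informative: the intercept is centred on 5 mm with a
wide sd (all traits are positive lengths of a few mm), the beta
coefficients on 0; the site and residual sds get half-normal priors.
Sampling is Gibbs for the conditionally conjugate blocks (beta, site
effects) with adaptive random-walk Metropolis on the log of each sd.

The user-facing surface follows the Model/Results convention: build a
:class:`TraitModel` from a records frame, call :meth:`TraitModel.fit`, and
work with the returned :class:`~cricketsize.results.TraitModelResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import ConversionEstimate
from .design import POOLED_TERMS, SEX_SPECIFIC_TERMS, SHARED_TRAITS, trait_sex

SEX_MODES = ("pooled", "male_only", "female_only")


@dataclass(frozen=True)
class Priors:
    """Prior hyperparameters (mm scale)."""

    intercept_mean: float = 5.0
    intercept_sd: float = 100.0
    beta_sd: float = 100.0
    site_sd_scale: float = 10.0      # half-normal scale
    residual_sd_scale: float = 10.0  # half-normal scale

    def __post_init__(self):
        for name in ("intercept_sd", "beta_sd", "site_sd_scale",
                     "residual_sd_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler protocol. Defaults follow the two-chain, 10k burn-in,
    10k retained-draw protocol of the original analysis."""

    chains: int = 2
    burn_in: int = 10_000
    samples: int = 10_000
    thin: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if self.burn_in <= 0 or self.samples <= 0 or self.thin < 1:
            raise ValueError("burn_in and samples must be positive, thin >= 1")


@dataclass
class DesignMatrix:
    """Fixed-effect design plus site grouping for one trait model."""

    X: np.ndarray               # (n, p) including the intercept column
    names: list[str]            # column names, names[0] == "intercept"
    y: np.ndarray               # observed lengths, mm (unshifted)
    site_index: np.ndarray      # (n,) integer site codes into site_codes
    site_codes: list[str]
    site_isolation: dict[str, str]
    rows: pd.DataFrame          # the retained records (for PPC / prediction)
    n_dropped: int              # rows excluded for a missing trait value

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]


def _trait_column(trait: str) -> str:
    return trait if trait in SHARED_TRAITS else "genital"


def _indicators(df: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        "isolation": (df["isolation"].to_numpy() == "isolated").astype(float),
        "origin": (df["origin"].to_numpy() == "laboratory").astype(float),
        "sex": (df["sex"].to_numpy() == "female").astype(float),
        "year": (df["year"].to_numpy(int) != 2008).astype(float),
    }


def build_design(records: pd.DataFrame, trait: str,
                 sex_mode: str = "pooled") -> DesignMatrix:
    """Indicator-coded design for one trait.

    Reference levels are continuous / field / male / 2008; interaction
    columns are element-wise products of their parent columns. Sex-limited
    traits require the matching single-sex mode, which drops the sex term
    and every sex interaction. Rows with a missing value for the modelled
    trait are excluded (per trait, not per individual) and counted in
    ``n_dropped``.
    """
    if sex_mode not in SEX_MODES:
        raise ValueError(f"sex_mode must be one of {SEX_MODES}")
    restricted = trait_sex(trait)
    if restricted == "male" and sex_mode != "male_only":
        raise ValueError(f"{trait!r} is male-limited; use sex_mode='male_only'")
    if restricted == "female" and sex_mode != "female_only":
        raise ValueError(f"{trait!r} is female-limited; use sex_mode='female_only'")

    df = records
    if sex_mode == "male_only":
        df = df[df["sex"] == "male"]
    elif sex_mode == "female_only":
        df = df[df["sex"] == "female"]

    col = _trait_column(trait)
    if col not in df.columns:
        raise ValueError(f"records lack a {col!r} column")
    present = df[col].notna()
    n_dropped = int((~present).sum())
    df = df[present].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no rows with a {trait} measurement")

    for fac, known in (("isolation", {"continuous", "isolated"}),
                       ("origin", {"field", "laboratory"}),
                       ("sex", {"male", "female"})):
        bad = set(df[fac].unique()) - known
        if bad:
            raise ValueError(f"unknown {fac} level(s): {sorted(bad)}")

    ind = _indicators(df)
    terms = POOLED_TERMS if sex_mode == "pooled" else SEX_SPECIFIC_TERMS
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for term in terms:
        parts = term.split(":")
        x = np.ones(len(df))
        for part in parts:
            x = x * ind[part]
        cols.append(x)
        names.append(term)
    X = np.column_stack(cols)

    site_codes = sorted(df["site"].unique())
    code_to_idx = {c: k for k, c in enumerate(site_codes)}
    site_index = df["site"].map(code_to_idx).to_numpy(int)
    site_isolation = (df.drop_duplicates("site").set_index("site")["isolation"]
                      .to_dict())
    return DesignMatrix(X=X, names=names, y=df[col].to_numpy(float),
                        site_index=site_index, site_codes=site_codes,
                        site_isolation=site_isolation, rows=df,
                        n_dropped=n_dropped)


def _observation_layer(design: DesignMatrix,
                       conversion: ConversionEstimate | None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Shifted observations and per-row extra variance from the calibration."""
    y = design.y.copy()
    extra_var = np.zeros_like(y)
    instr = design.rows["instrument"].to_numpy()
    calliper = instr == "calliper"
    if calliper.any():
        if conversion is None:
            raise ValueError(
                "records contain calliper measurements but no conversion "
                "estimate was provided")
        y[calliper] -= conversion.offset_mean
        extra_var[calliper] = conversion.offset_sd**2
    return y, extra_var


def _half_normal_logpdf(s: float, scale: float) -> float:
    return -0.5 * (s / scale) ** 2


def _slice_sample(logf, x0: float, rng: np.random.Generator,
                  width: float = 1.0, max_steps: int = 50) -> float:
    """Univariate slice sampler (stepping out + shrinkage)."""
    y = logf(x0) + np.log(rng.uniform())
    lo = x0 - width * rng.uniform()
    hi = lo + width
    for _ in range(max_steps):
        if logf(lo) <= y:
            break
        lo -= width
    for _ in range(max_steps):
        if logf(hi) <= y:
            break
        hi += width
    while True:
        x1 = rng.uniform(lo, hi)
        if logf(x1) > y:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1


def _run_chain(y: np.ndarray, X: np.ndarray, site_index: np.ndarray,
               n_sites: int, extra_var: np.ndarray, priors: Priors,
               burn_in: int, samples: int, thin: int,
               rng: np.random.Generator,
               sweep_groups: list[tuple[np.ndarray, list[tuple[int, float]]]]
               | None = None) -> dict[str, np.ndarray]:
    """One MCMC chain; returns retained draws.

    ``sweep_groups`` configures exact Gibbs sweeps along the likelihood-flat
    directions that trade site effects off against location coefficients
    (intercept / isolation): each entry is ``(site_js, [(beta_k, sign), ...])``
    meaning the transformation ``u[site_js] -= delta, beta[k] += sign*delta``
    leaves every fitted mean unchanged. Sampling delta from its exact
    Gaussian conditional removes the slow random-walk mixing these soft
    non-identifiabilities otherwise cause with few sites.
    """
    n, p = X.shape
    prior_mean = np.zeros(p)
    prior_mean[0] = priors.intercept_mean
    prior_prec = np.full(p, 1.0 / priors.beta_sd**2)
    prior_prec[0] = 1.0 / priors.intercept_sd**2

    # initial state: least squares for beta, residual scale from its fit
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid0 = y - X @ beta
    sig_res = max(float(resid0.std()), 1e-3)
    u = np.zeros(n_sites)

    total = burn_in + samples * thin
    out_beta = np.empty((samples, p))
    out_u = np.empty((samples, n_sites))
    out_sig_site = np.empty(samples)
    out_sig_res = np.empty(samples)
    kept = 0

    log_sig_site = np.log(0.1)
    log_sig_res = np.log(sig_res)

    for it in range(total):
        v = np.exp(2 * log_sig_res) + extra_var
        w = 1.0 / v

        # beta | rest  (weighted least squares conjugate update)
        r_beta = y - u[site_index]
        Xw = X * w[:, None]
        A = X.T @ Xw + np.diag(prior_prec)
        b = Xw.T @ r_beta + prior_prec * prior_mean
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, b)
        z = rng.standard_normal(p)
        beta = mean + np.linalg.solve(L.T, z)

        r_site = y - X @ beta
        sw = np.bincount(site_index, weights=w, minlength=n_sites)
        swr = np.bincount(site_index, weights=w * r_site, minlength=n_sites)
        occupied = sw > 0
        m_site = np.where(occupied, swr / np.where(occupied, sw, 1.0), 0.0)

        # sigma_site with the site effects integrated out ("collapsed"):
        # the weighted site mean m_j ~ Normal(0, sigma_site^2 + 1/sw_j)
        # marginally, which avoids the funnel between u and sigma_site
        def site_logpost(theta: float) -> float:
            s2 = np.exp(2 * theta)
            var_m = s2 + 1.0 / sw[occupied]
            return (-0.5 * np.sum(np.log(var_m))
                    - 0.5 * np.sum(m_site[occupied] ** 2 / var_m)
                    + _half_normal_logpdf(np.exp(theta), priors.site_sd_scale)
                    + theta)
        log_sig_site = _slice_sample(site_logpost, log_sig_site, rng)

        # site effects | rest
        prec_u = sw + np.exp(-2 * log_sig_site)
        mean_u = swr / prec_u
        u = mean_u + rng.standard_normal(n_sites) / np.sqrt(prec_u)
        # residuals are invariant under the sweeps below (fitted means are
        # unchanged), so compute them from the pre-sweep state
        resid = r_site - u[site_index]

        # exact sweeps along likelihood-flat directions (see docstring)
        if sweep_groups:
            su2 = np.exp(-2 * log_sig_site)
            for site_js, beta_terms in sweep_groups:
                prec_d = len(site_js) * su2
                lin = u[site_js].sum() * su2
                for k, sign in beta_terms:
                    prec_d += sign**2 * prior_prec[k]
                    lin -= sign * (beta[k] - prior_mean[k]) * prior_prec[k]
                delta = lin / prec_d + rng.standard_normal() / np.sqrt(prec_d)
                u[site_js] -= delta
                for k, sign in beta_terms:
                    beta[k] += sign * delta

        # sigma_res | rest
        def res_logpost(theta: float) -> float:
            vv = np.exp(2 * theta) + extra_var
            return (-0.5 * np.sum(np.log(vv)) - 0.5 * np.sum(resid**2 / vv)
                    + _half_normal_logpdf(np.exp(theta), priors.residual_sd_scale)
                    + theta)
        log_sig_res = _slice_sample(res_logpost, log_sig_res, rng, width=0.3)

        if it >= burn_in and (it - burn_in) % thin == 0:
            out_beta[kept] = beta
            out_u[kept] = u
            out_sig_site[kept] = np.exp(log_sig_site)
            out_sig_res[kept] = np.exp(log_sig_res)
            kept += 1

    assert kept == samples
    return {"beta": out_beta, "site_effect": out_u,
            "site_sd": out_sig_site, "residual_sd": out_sig_res}


class TraitModel:
    """Hierarchical linear model for one morphological trait.

    Parameters
    ----------
    records
        Validated individual-level records (see :mod:`cricketsize.io`).
    trait
        ``femur``, ``wing`` or ``pronotum`` (pooled-sex), or the
        sex-limited ``cerci`` / ``ovipositor``.
    sex_mode
        ``pooled`` fits both sexes with a sex term and its interactions;
        ``male_only`` / ``female_only`` fit one sex without them (required
        for the genital traits).
    conversion
        Calibration estimate propagated to calliper-measured rows;
        mandatory if any row was measured with callipers.
    priors
        Prior hyperparameters; defaults are minimally informative.

    Examples
    --------
    >>> model = TraitModel(records, "femur", conversion=conv["femur"])
    >>> res = model.fit(seed=1)
    >>> res.summary()              # doctest: +SKIP
    """

    def __init__(self, records: pd.DataFrame, trait: str,
                 sex_mode: str = "pooled",
                 conversion: ConversionEstimate | None = None,
                 priors: Priors | None = None):
        self.trait = trait
        self.sex_mode = sex_mode
        self.priors = priors or Priors()
        self.conversion = conversion
        self.design = build_design(records, trait, sex_mode)
        self._y_obs, self._extra_var = _observation_layer(self.design, conversion)
        # a singular design cannot identify the betas
        rank = np.linalg.matrix_rank(self.design.X)
        if rank < self.design.p:
            raise ValueError(
                f"singular design for {trait}: rank {rank} < {self.design.p} "
                "columns (a factor level is missing or confounded)")

    @classmethod
    def from_dataframe(cls, records: pd.DataFrame, trait: str, **kwargs
                       ) -> "TraitModel":
        return cls(records, trait, **kwargs)

    def fit(self, chains: int | None = None, burn_in: int | None = None,
            samples: int | None = None, thin: int | None = None,
            seed: int | None = None,
            settings: MCMCSettings | None = None):
        """Run the sampler and return a :class:`TraitModelResults`.

        Individual keyword arguments override fields of ``settings``.
        The fit is reproducible: identical settings (including the seed)
        give identical draws. A warning is emitted if any split-R-hat
        exceeds 1.05.
        """
        from .results import TraitModelResults  # deferred: results imports us

        base = settings or MCMCSettings()
        cfg = MCMCSettings(
            chains=chains if chains is not None else base.chains,
            burn_in=burn_in if burn_in is not None else base.burn_in,
            samples=samples if samples is not None else base.samples,
            thin=thin if thin is not None else base.thin,
            seed=seed if seed is not None else base.seed,
        )
        d = self.design
        sweep_groups = []
        if "isolation" in d.names:
            iso_k = d.names.index("isolation")
            cont_js = np.array([j for j, c in enumerate(d.site_codes)
                                if d.site_isolation.get(c) == "continuous"])
            isol_js = np.array([j for j, c in enumerate(d.site_codes)
                                if d.site_isolation.get(c) == "isolated"])
            if len(cont_js):
                sweep_groups.append((cont_js, [(0, 1.0), (iso_k, -1.0)]))
            if len(isol_js):
                sweep_groups.append((isol_js, [(iso_k, 1.0)]))
        else:
            sweep_groups.append((np.arange(len(d.site_codes)), [(0, 1.0)]))

        seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.chains)
        chains_out = [
            _run_chain(self._y_obs, self.design.X, self.design.site_index,
                       len(self.design.site_codes), self._extra_var,
                       self.priors, cfg.burn_in, cfg.samples, cfg.thin,
                       np.random.default_rng(s), sweep_groups=sweep_groups)
            for s in seeds
        ]
        posterior = {
            key: np.stack([c[key] for c in chains_out])
            for key in chains_out[0]
        }
        results = TraitModelResults(self, posterior, cfg)
        if cfg.chains >= 2:
            bad = results.check_convergence().flagged
            if bad:
                warnings.warn(
                    f"{self.trait}: split-R-hat > 1.05 for {sorted(bad)}; "
                    "inspect traces / increase burn-in", RuntimeWarning)
        return results


def check_convergence(results, threshold: float = 1.05):
    """Split-R-hat / ESS diagnostics for a fitted model (functional form of
    :meth:`~cricketsize.results.TraitModelResults.check_convergence`)."""
    return results.check_convergence(threshold=threshold)


def posterior_predictive_check(results, statistic: str = "mean",
                               n_replicates: int = 1000, seed: int = 0):
    """Bayes-P posterior-predictive check (functional form of
    :meth:`~cricketsize.results.TraitModelResults.posterior_predictive_check`)."""
    return results.posterior_predictive_check(
        statistic, n_replicates=n_replicates, seed=seed)


def fit_trait_model(records: pd.DataFrame, trait: str,
                    sex_mode: str = "pooled",
                    conversion: ConversionEstimate | None = None,
                    priors: Priors | None = None,
                    mcmc: MCMCSettings | None = None):
    """Functional wrapper: construct a :class:`TraitModel` and fit it."""
    model = TraitModel(records, trait, sex_mode=sex_mode,
                       conversion=conversion, priors=priors)
    return model.fit(settings=mcmc)
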