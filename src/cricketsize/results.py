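"""Posterior results: summaries, diagnostics, checks and group predictions."""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

RHAT_THRESHOLD = 1.05
BAYES_P_BAND = (0.1, 0.9)


@dataclass(frozen=True)
class ConvergenceReport:
    """Split-R-hat / effective-sample-size diagnostics for one fit."""

    rhat: pd.Series
    ess_bulk: pd.Series
    flagged: list[str]
    threshold: float = RHAT_THRESHOLD

    @property
    def passed(self) -> bool:
        return not self.flagged


@dataclass(frozen=True)
class PPCResult:
    """Posterior-predictive check for one test statistic.

    ``bayes_p`` is the fraction of model-replicated datasets whose
    statistic exceeds the observed one; values near 0 or 1 indicate
    misfit. The pass band follows the 0.1-0.9 convention.
    """

    statistic: str
    bayes_p: float
    observed: float
    n_replicates: int

    @property
    def passed(self) -> bool:
        lo, hi = BAYES_P_BAND
        return lo < self.bayes_p < hi


@dataclass
class GroupPrediction:
    """Posterior draws of the expected trait length for one factor group."""

    label: dict
    draws: np.ndarray  # flattened over chains

    @property
    def mean(self) -> float:
        return float(self.draws.mean())

    @property
    def sd(self) -> float:
        return float(self.draws.std(ddof=1))

    def __repr__(self) -> str:
        parts = ", ".join(f"{k}={v}" for k, v in self.label.items())
        return f"GroupPrediction({parts}: {self.mean:.2f} +/- {self.sd:.2f} mm)"


class TraitModelResults:
    """Posterior draws and derived quantities for one fitted trait model.

    Attributes
    ----------
    posterior
        ``{"beta": (chains, draws, p), "site_effect": (chains, draws, J),
        "site_sd": (chains, draws), "residual_sd": (chains, draws)}``.
    """

    def __init__(self, model, posterior: dict[str, np.ndarray], settings):
        self.model = model
        self.posterior = posterior
        self.settings = settings
        self.trait = model.trait
        d = model.design
        self._names = d.names
        self._site_codes = d.site_codes
        self._idata: az.InferenceData | None = None

    # -- basic accessors ---------------------------------------------------

    @property
    def n_chains(self) -> int:
        return self.posterior["beta"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.posterior["beta"].shape[1]

    def beta_draws(self, term: str) -> np.ndarray:
        """Flattened draws of one fixed-effect coefficient."""
        k = self._names.index(term)
        return self.posterior["beta"][:, :, k].reshape(-1)

    def site_effect_draws(self, site: str) -> np.ndarray:
        j = self._site_codes.index(site)
        return self.posterior["site_effect"][:, :, j].reshape(-1)

    def scalar_draws(self, name: str) -> np.ndarray:
        return self.posterior[name].reshape(-1)

    # -- arviz bridge ------------------------------------------------------

    def to_inference_data(self) -> az.InferenceData:
        if self._idata is None:
            self._idata = az.from_dict(
                posterior={
                    "beta": self.posterior["beta"],
                    "site_effect": self.posterior["site_effect"],
                    "site_sd": self.posterior["site_sd"],
                    "residual_sd": self.posterior["residual_sd"],
                },
                coords={"term": list(self._names),
                        "site": list(self._site_codes)},
                dims={"beta": ["term"], "site_effect": ["site"]},
            )
        return self._idata

    # -- diagnostics -------------------------------------------------------

    def _flat_param_series(self, dataset) -> pd.Series:
        vals = {}
        for term, v in zip(self._names, np.atleast_1d(
                dataset["beta"].values)):
            vals[term] = float(v)
        for site, v in zip(self._site_codes, np.atleast_1d(
                dataset["site_effect"].values)):
            vals[f"site_effect[{site}]"] = float(v)
        vals["site_sd"] = float(dataset["site_sd"].values)
        vals["residual_sd"] = float(dataset["residual_sd"].values)
        return pd.Series(vals)

    def rhat(self) -> pd.Series:
        """Per-parameter split-R-hat (rank-normalised)."""
        if self.n_chains < 2:
            raise ValueError("R-hat needs at least two chains")
        return self._flat_param_series(az.rhat(self.to_inference_data()))

    def ess(self) -> pd.Series:
        """Per-parameter bulk effective sample size."""
        return self._flat_param_series(az.ess(self.to_inference_data()))

    def check_convergence(self, threshold: float = RHAT_THRESHOLD
                          ) -> ConvergenceReport:
        """Flag parameters whose split-R-hat exceeds ``threshold``."""
        r = self.rhat()
        ess = self.ess()
        flagged = list(r.index[r > threshold])
        return ConvergenceReport(rhat=r, ess_bulk=ess, flagged=flagged,
                                 threshold=threshold)

    def summary(self) -> pd.DataFrame:
        """Posterior summary table (mean, sd, 95% credible interval,
        split-R-hat and bulk ESS per parameter)."""
        rows = {}
        def add(name, draws2d):
            flat = draws2d.reshape(-1)
            lo, hi = np.percentile(flat, [2.5, 97.5])
            rows[name] = {"mean": flat.mean(), "sd": flat.std(ddof=1),
                          "ci_2.5%": lo, "ci_97.5%": hi}
        for k, term in enumerate(self._names):
            add(term, self.posterior["beta"][:, :, k])
        for j, site in enumerate(self._site_codes):
            add(f"site_effect[{site}]", self.posterior["site_effect"][:, :, j])
        add("site_sd", self.posterior["site_sd"])
        add("residual_sd", self.posterior["residual_sd"])
        out = pd.DataFrame(rows).T
        if self.n_chains >= 2:
            out["rhat"] = self.rhat()
            out["ess_bulk"] = self.ess()
        return out

    def prior_flatness(self) -> pd.Series:
        """Ratio of prior density at the posterior 2.5% vs 97.5% quantiles
        for each location parameter; values near 1 mean the prior is flat
        over the range the posterior occupies (minimally informative)."""
        pr = self.model.priors
        out = {}
        for k, term in enumerate(self._names):
            flat = self.posterior["beta"][:, :, k].reshape(-1)
            lo, hi = np.percentile(flat, [2.5, 97.5])
            mu = pr.intercept_mean if term == "intercept" else 0.0
            sd = pr.intercept_sd if term == "intercept" else pr.beta_sd
            dens = lambda x: np.exp(-0.5 * ((x - mu) / sd) ** 2)
            a, b = dens(lo), dens(hi)
            out[term] = float(min(a, b) / max(a, b))
        return pd.Series(out)

    # -- posterior predictive ----------------------------------------------

    def posterior_predictive_check(self, statistic: str = "mean",
                                   n_replicates: int = 1000,
                                   seed: int = 0) -> PPCResult:
        """Bayes-P posterior-predictive check.

        For ``n_replicates`` posterior draws a replicate dataset is
        simulated from the fitted observation model and the test statistic
        (``"mean"`` or ``"cv"``, the coefficient of variation) compared to
        the observed data (on the conversion-adjusted scale). ``bayes_p``
        is the fraction of replicates whose statistic exceeds the observed
        one.
        """
        if statistic not in ("mean", "cv"):
            raise ValueError("statistic must be 'mean' or 'cv'")
        y_obs = self.model._y_obs
        extra = self.model._extra_var
        X = self.model.design.X
        site_idx = self.model.design.site_index

        def stat(y: np.ndarray) -> float:
            if statistic == "mean":
                return float(y.mean())
            m = y.mean()
            if m == 0:
                raise ZeroDivisionError("CV undefined: zero mean")
            return float(y.std(ddof=1) / m)

        obs = stat(y_obs)
        total = self.n_chains * self.n_draws
        take = min(n_replicates, total)
        pick = np.linspace(0, total - 1, take).astype(int)
        beta = self.posterior["beta"].reshape(total, -1)[pick]
        u = self.posterior["site_effect"].reshape(total, -1)[pick]
        sig = self.posterior["residual_sd"].reshape(total)[pick]

        rng = np.random.default_rng(seed)
        mu = beta @ X.T + u[:, site_idx]                    # (take, n)
        sd = np.sqrt(sig[:, None] ** 2 + extra[None, :])
        y_rep = rng.normal(mu, sd)
        stats_rep = np.array([stat(row) for row in y_rep])
        bayes_p = float(np.mean(stats_rep > obs))
        return PPCResult(statistic=statistic, bayes_p=bayes_p, observed=obs,
                         n_replicates=take)

    # -- predictions -------------------------------------------------------

    def _year_fraction(self, isolation: str, origin: str,
                       sex: str | None) -> float:
        """Empirical share of post-2008 rows among records of the group."""
        rows = self.model.design.rows
        m = (rows["isolation"] == isolation) & (rows["origin"] == origin)
        if sex is not None and self.model.sex_mode == "pooled":
            m &= rows["sex"] == sex
        sub = rows[m] if m.any() else rows[rows["origin"] == origin]
        if sub.empty:
            sub = rows
        return float((sub["year"].to_numpy(int) != 2008).mean())

    def predict_group(self, isolation: str, origin: str,
                      sex: str | None = None, site: str | None = None,
                      year: int | str = "mix") -> GroupPrediction:
        """Posterior draws of the expected trait length for a factor group.

        Parameters
        ----------
        isolation, origin, sex
            Factor levels of the group; ``sex`` is required for pooled-sex
            models and ignored for single-sex models.
        site
            ``None`` (default) averages the site-effect draws over the
            sites of the requested isolation class (a population-level
            prediction); a site code uses that site's own effect.
        year
            ``"mix"`` (default) averages the prediction over the group's
            empirical 2008/2010 composition; an integer year predicts at
            that year. Laboratory groups are entirely post-2008 cohorts
            either way.
        """
        d = self.model.design
        if isolation not in ("continuous", "isolated"):
            raise ValueError(f"unknown isolation level {isolation!r}")
        if origin not in ("field", "laboratory"):
            raise ValueError(f"unknown origin {origin!r}")
        if self.model.sex_mode == "pooled" and sex not in ("male", "female"):
            raise ValueError("pooled-sex model: specify sex='male'/'female'")
        if site is not None and site not in d.site_codes:
            raise ValueError(f"unknown site {site!r}")

        iso = 1.0 if isolation == "isolated" else 0.0
        lab = 1.0 if origin == "laboratory" else 0.0
        fem = 1.0 if sex == "female" else 0.0
        if year == "mix":
            yr = (self._year_fraction(isolation, origin, sex)
                  if origin == "field" else 1.0)
        else:
            yr = 1.0 if int(year) != 2008 else 0.0

        ind = {"isolation": iso, "origin": lab, "sex": fem, "year": yr}
        x = np.array([1.0 if n == "intercept"
                      else np.prod([ind[p] for p in n.split(":")])
                      for n in self._names])

        total = self.n_chains * self.n_draws
        beta = self.posterior["beta"].reshape(total, -1)
        u = self.posterior["site_effect"].reshape(total, -1)
        if site is not None:
            site_term = u[:, d.site_codes.index(site)]
        else:
            cls = [j for j, c in enumerate(d.site_codes)
                   if d.site_isolation.get(c) == isolation]
            if not cls:
                raise ValueError(f"no sites with isolation {isolation!r}")
            site_term = u[:, cls].mean(axis=1)
        draws = beta @ x + site_term
        label = {"trait": self.trait, "isolation": isolation, "origin": origin}
        if self.model.sex_mode == "pooled":
            label["sex"] = sex
        else:
            label["sex"] = self.model.sex_mode.removesuffix("_only")
        if site is not None:
            label["site"] = site
        return GroupPrediction(label=label, draws=draws)
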