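"""Group contrasts: posterior differences and directional probabilities.

The headline quantity of the analysis is the posterior distribution of a
group difference (isolated minus continuous), obtained by draw-wise
subtraction of two group predictions from the same posterior. The
proportion of difference draws above zero is the probability that the
isolated group is larger, written P_iso>con.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .results import GroupPrediction, TraitModelResults


@dataclass
class ContrastResult:
    """Posterior summary of a paired group difference (mm)."""

    trait: str
    label_a: dict
    label_b: dict
    draws: np.ndarray   # paired difference draws a - b

    @property
    def diff_mean(self) -> float:
        return float(self.draws.mean())

    @property
    def diff_sd(self) -> float:
        return float(self.draws.std(ddof=1))

    @property
    def p_greater(self) -> float:
        return prob_greater(self.draws)

    def __repr__(self) -> str:
        return (f"ContrastResult({self.trait}: {self.diff_mean:.2f} "
                f"+/- {self.diff_sd:.2f} mm, P(>0)={self.p_greater:.3f})")


def prob_greater(draws) -> float:
    """Exact proportion of draws strictly greater than zero."""
    if isinstance(draws, ContrastResult):
        draws = draws.draws
    draws = np.asarray(draws, float)
    if draws.size == 0:
        raise ValueError("no draws")
    return float(np.mean(draws > 0))


def difference(a: GroupPrediction, b: GroupPrediction) -> ContrastResult:
    """Draw-wise difference a - b of two paired group predictions."""
    if len(a.draws) != len(b.draws):
        raise ValueError(
            f"unpaired draws: {len(a.draws)} vs {len(b.draws)}; both "
            "predictions must come from the same posterior")
    return ContrastResult(trait=a.label.get("trait", "?"), label_a=a.label,
                          label_b=b.label, draws=a.draws - b.draws)


def predict_group(res: TraitModelResults, isolation: str, origin: str,
                  sex: str | None = None, site: str | None = None,
                  year: int | str = "mix") -> GroupPrediction:
    """Functional form of :meth:`TraitModelResults.predict_group`."""
    return res.predict_group(isolation, origin, sex=sex, site=site, year=year)


def isolation_contrast(res: TraitModelResults, origin: str,
                       sex: str | None = None,
                       year: int | str = "mix") -> ContrastResult:
    """Isolated-minus-continuous contrast for one rearing condition."""
    iso = res.predict_group("isolated", origin, sex=sex, year=year)
    con = res.predict_group("continuous", origin, sex=sex, year=year)
    return difference(iso, con)


def general_contrast(res: TraitModelResults, sex: str | None = None,
                     year: int | str = "mix") -> ContrastResult:
    """Isolation contrast pooled over rearing condition.

    Field-only and laboratory-only contrast draws are combined draw-wise
    with equal weight, giving the posterior of the average of the two
    condition-specific differences; its mean always lies between the
    field-only and laboratory-only means.
    """
    fld = isolation_contrast(res, "field", sex=sex, year=year)
    lab = isolation_contrast(res, "laboratory", sex=sex, year=year)
    out = ContrastResult(trait=fld.trait, label_a={**fld.label_a, "origin": "general"},
                         label_b={**fld.label_b, "origin": "general"},
                         draws=0.5 * (fld.draws + lab.draws))
    return out


def _sexes_for(res: TraitModelResults) -> list[str | None]:
    if res.model.sex_mode == "pooled":
        return ["male", "female"]
    return [None]


def group_estimates_table(results: dict[str, TraitModelResults],
                          year: int | str = "mix") -> pd.DataFrame:
    """Group-prediction table: per trait and sex, the posterior mean +/- sd
    of the continuous and isolated groups under each rearing condition and
    the probability the isolated group is larger."""
    rows = []
    for trait, res in results.items():
        for sex in _sexes_for(res):
            sex_label = sex or res.model.sex_mode.removesuffix("_only")
            for origin in ("field", "laboratory"):
                con = res.predict_group("continuous", origin, sex=sex, year=year)
                iso = res.predict_group("isolated", origin, sex=sex, year=year)
                diff = difference(iso, con)
                rows.append({
                    "trait": trait, "sex": sex_label, "origin": origin,
                    "continuous_mean": con.mean, "continuous_sd": con.sd,
                    "isolated_mean": iso.mean, "isolated_sd": iso.sd,
                    "p_iso_gt_con": diff.p_greater,
                })
    return pd.DataFrame(rows)


def isolation_differences_table(results: dict[str, TraitModelResults],
                                year: int | str = "mix") -> pd.DataFrame:
    """Difference table: isolated-minus-continuous per trait and sex for
    field, laboratory and the pooled 'general' rearing condition."""
    rows = []
    for trait, res in results.items():
        for sex in _sexes_for(res):
            sex_label = sex or res.model.sex_mode.removesuffix("_only")
            contrasts = {
                "field": isolation_contrast(res, "field", sex=sex, year=year),
                "laboratory": isolation_contrast(res, "laboratory", sex=sex,
                                                 year=year),
                "general": general_contrast(res, sex=sex, year=year),
            }
            row: dict = {"trait": trait, "sex": sex_label}
            for cond, c in contrasts.items():
                row[f"{cond}_diff_mean"] = c.diff_mean
                row[f"{cond}_diff_sd"] = c.diff_sd
                row[f"{cond}_p_iso_gt_con"] = c.p_greater
            rows.append(row)
    return pd.DataFrame(rows)


def site_estimates_table(results: dict[str, TraitModelResults],
                         year: int | str = "mix") -> pd.DataFrame:
    """Site-specific estimate table: per site, rearing condition, trait and
    sex, the posterior mean +/- sd using that site's own intercept shift."""
    rows = []
    for trait, res in results.items():
        d = res.model.design
        for sex in _sexes_for(res):
            sex_label = sex or res.model.sex_mode.removesuffix("_only")
            for site in d.site_codes:
                isolation = d.site_isolation[site]
                for origin in ("field", "laboratory"):
                    g = res.predict_group(isolation, origin, sex=sex,
                                          site=site, year=year)
                    rows.append({
                        "site": site, "isolation": isolation,
                        "origin": origin, "trait": trait, "sex": sex_label,
                        "mean": g.mean, "sd": g.sd,
                    })
    return pd.DataFrame(rows)


def make_results_tables(results: dict[str, TraitModelResults],
                        year: int | str = "mix") -> dict[str, pd.DataFrame]:
    """All three result tables (group estimates, isolation differences,
    site-specific estimates) from a set of fitted trait models."""
    return {
        "group_estimates": group_estimates_table(results, year=year),
        "isolation_differences": isolation_differences_table(results, year=year),
        "site_estimates": site_estimates_table(results, year=year),
    }


def plot_forest(results: dict[str, TraitModelResults], ax=None,
                year: int | str = "mix"):
    """Forest plot of trait lengths standardised to the continuous group.

    For every trait, sex and rearing condition, the median and 95%
    credible interval of the isolated-minus-continuous difference is drawn
    relative to the continuous group's zero line.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.45 * 2 * len(results) + 2))
    ticks, labels = [], []
    pos = 0
    for trait, res in results.items():
        for sex in _sexes_for(res):
            sex_label = sex or res.model.sex_mode.removesuffix("_only")
            for origin, marker in (("field", "o"), ("laboratory", "s")):
                c = isolation_contrast(res, origin, sex=sex, year=year)
                med = float(np.median(c.draws))
                lo, hi = np.percentile(c.draws, [2.5, 97.5])
                ax.errorbar(med, pos, xerr=[[med - lo], [hi - med]],
                            fmt=marker, color="k", capsize=2)
                ticks.append(pos)
                labels.append(f"{trait} {sex_label} {origin}")
                pos += 1
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(ticks, labels)
    ax.set_xlabel("isolated - continuous (mm)")
    ax.invert_yaxis()
    return ax
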