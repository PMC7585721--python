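"""Seeded synthetic-data generator.

Draws individual-level morphometric records under the random-intercept
linear model the analysis assumes: one site effect per (site, trait),
shared by every individual of that site, plus independent residual noise.
Dual-instrument calibration pairs are generated on top of simulated
individuals by adding an additive calliper offset with noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import (
    EffectConfig,
    StudyDesign,
    genital_trait_for,
    trait_sex,
    SHARED_TRAITS,
)

MORPH_COLUMNS = [
    "individual_id", "site", "isolation", "origin", "sex", "year",
    "instrument", "femur", "wing", "pronotum", "genital",
]


def _column_for(trait: str) -> str:
    return trait if trait in SHARED_TRAITS else "genital"


def simulate_individuals(design: StudyDesign, effects: EffectConfig,
                         seed: int, return_site_effects: bool = False):
    """Simulate one morphometric dataset under ``design`` and ``effects``.

    For each trait, a site intercept is drawn once per site from
    Normal(0, site_sd) and added to the cell mean of every individual of
    that site; residuals are independent Normal(0, residual_sd). Sex-limited
    traits (cerci, ovipositor) are generated only for the matching sex and
    stored in the shared ``genital`` column.

    Recorded values are *measurements*: rows whose cohort the design
    assigns to the calliper instrument additionally carry the calliper
    offset plus its noise, so that converting them back through a fitted
    calibration recovers the digital scale.

    Identical ``(design, effects, seed)`` yields an identical table.
    With ``return_site_effects`` the realised ``(trait, site) -> shift``
    draws are returned alongside the table (useful for recovery studies).
    """
    missing = [t for t in design.traits if t not in effects]
    if missing:
        raise ValueError(f"effects config lacks traits: {missing}")
    rng = np.random.default_rng(seed)

    # one site intercept per (trait, site), drawn up-front in fixed order
    site_eff = {
        (trait, site.code): rng.normal(0.0, effects[trait].site_sd)
        for trait in design.traits for site in design.sites
    }

    rows = []
    counter = 0
    for site in design.sites:
        for (code, origin, sex, year), n in sorted(design.counts.items()):
            if code != site.code or n <= 0:
                continue
            instrument = design.instrument_for(origin, year)
            for _ in range(n):
                counter += 1
                row = {
                    "individual_id": f"ind{counter:04d}",
                    "site": code,
                    "isolation": site.isolation,
                    "origin": origin,
                    "sex": sex,
                    "year": year,
                    "instrument": instrument,
                    "femur": np.nan, "wing": np.nan,
                    "pronotum": np.nan, "genital": np.nan,
                }
                for trait in design.traits:
                    restricted = trait_sex(trait)
                    if restricted is not None and restricted != sex:
                        continue
                    eff = effects[trait]
                    mu = (eff.linear_predictor(isolation=site.isolation,
                                               origin=origin, sex=sex,
                                               year=year)
                          + site_eff[(trait, code)])
                    value = mu + rng.normal(0.0, eff.residual_sd)
                    if instrument == "calliper":
                        value += (eff.conversion_offset
                                  + rng.normal(0.0, eff.conversion_noise_sd))
                    row[_column_for(trait)] = value
                rows.append(row)
    table = pd.DataFrame(rows, columns=MORPH_COLUMNS)
    if return_site_effects:
        return table, site_eff
    return table


def simulate_dual_measurements(records: pd.DataFrame, effects: EffectConfig,
                               n_pairs: int, seed: int) -> pd.DataFrame:
    """Simulate paired calliper/digital measurements for calibration.

    ``n_pairs`` individuals are taken from ``records`` (2010 individuals
    preferred, balancing sexes as far as the data allow, mirroring the
    24 + 24 re-measured individuals of the original study). For every trait
    an individual carries, the digital value is the recorded trait value
    plus small digitisation noise, and the calliper value adds the additive
    instrument offset plus its noise.

    Returns one row per (individual, trait) with columns
    ``individual_id, trait, calliper_mm, digital_mm``.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    if n_pairs > len(records):
        raise ValueError(f"n_pairs={n_pairs} exceeds {len(records)} records")
    rng = np.random.default_rng(seed)

    pool = records[records["year"] == 2010] if (records["year"] == 2010).sum() >= n_pairs else records
    chosen_idx: list = []
    per_sex = n_pairs // 2
    for sex, quota in (("male", per_sex), ("female", n_pairs - per_sex)):
        grp = pool[pool["sex"] == sex]
        take = min(quota, len(grp))
        if take > 0:
            chosen_idx.extend(rng.choice(grp.index.to_numpy(), size=take,
                                         replace=False))
    # top up from the remaining pool if one sex was short
    if len(chosen_idx) < n_pairs:
        rest = pool.index.difference(chosen_idx).to_numpy()
        extra = rng.choice(rest, size=n_pairs - len(chosen_idx), replace=False)
        chosen_idx.extend(extra)
    chosen = records.loc[sorted(chosen_idx)]

    rows = []
    for _, rec in chosen.iterrows():
        for col in ("femur", "wing", "pronotum", "genital"):
            value = rec[col]
            if pd.isna(value):
                continue
            trait = genital_trait_for(rec["sex"]) if col == "genital" else col
            if trait not in effects:
                continue
            eff = effects[trait]
            digital = value + rng.normal(0.0, eff.digital_noise_sd)
            calliper = (digital + eff.conversion_offset
                        + rng.normal(0.0, eff.conversion_noise_sd))
            rows.append({"individual_id": rec["individual_id"], "trait": trait,
                         "calliper_mm": calliper, "digital_mm": digital})
    return pd.DataFrame(rows, columns=["individual_id", "trait",
                                       "calliper_mm", "digital_mm"])
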