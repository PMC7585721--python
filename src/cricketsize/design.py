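"""Study designs and effect configurations for the synthetic-data generator.

A :class:`StudyDesign` describes the sampling layout of a two-origin
(field-caught vs laboratory-reared), two-year common-garden morphometric
study of Roesel's bush-cricket *Metrioptera roeselii*: which sites were
sampled, whether each site belongs to the genetically isolated or the
continuous part of the species' range, and how many adults of each sex
were obtained per (site, origin, year) cell.

An :class:`EffectConfig` holds, per morphological trait, the linear-model
truth used to simulate individuals: the reference-group intercept, the
fixed-effect coefficients on 0/1 indicators (reference levels
continuous / field / male / 2008), the between-site and residual standard
deviations, and the additive calliper-instrument offset used when paired
dual-instrument measurements are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

ISOLATION_LEVELS = ("continuous", "isolated")
ORIGINS = ("field", "laboratory")
SEXES = ("male", "female")
YEARS = (2008, 2010)
INSTRUMENTS = ("calliper", "digital")

#: traits measured on every adult, in mm
SHARED_TRAITS = ("femur", "wing", "pronotum")
#: sex-limited genital appendage traits (stored in the ``genital`` column)
MALE_GENITAL = "cerci"
FEMALE_GENITAL = "ovipositor"
ALL_TRAITS = SHARED_TRAITS + (MALE_GENITAL, FEMALE_GENITAL)

#: names of the fixed-effect terms of the pooled-sex model, in design order
POOLED_TERMS = (
    "isolation",
    "origin",
    "sex",
    "year",
    "isolation:sex",
    "isolation:origin",
    "origin:sex",
    "isolation:origin:sex",
)
#: fixed-effect terms once the sex term (and every sex interaction) is dropped
SEX_SPECIFIC_TERMS = ("isolation", "origin", "year", "isolation:origin")


def genital_trait_for(sex: str) -> str:
    """Name of the genital-appendage trait measured on ``sex``."""
    return MALE_GENITAL if sex == "male" else FEMALE_GENITAL


def trait_sex(trait: str) -> str | None:
    """The sex a trait is restricted to, or ``None`` for shared traits."""
    if trait == MALE_GENITAL:
        return "male"
    if trait == FEMALE_GENITAL:
        return "female"
    return None


@dataclass(frozen=True)
class Site:
    code: str
    isolation: str

    def __post_init__(self):
        if self.isolation not in ISOLATION_LEVELS:
            raise ValueError(f"unknown isolation level {self.isolation!r}")


@dataclass
class StudyDesign:
    """Sampling layout: sites, per-cell counts and the instrument rule.

    Parameters
    ----------
    sites
        Sites with their isolation label; each site code appears once.
    counts
        ``(site_code, origin, sex, year) -> n`` sampled adults. Cells not
        listed are empty.
    traits
        Trait names generated for this design (sex-limited traits are only
        produced for the matching sex).
    calliper_cells
        ``(origin, year)`` cells measured with hand-held callipers; all
        other cells are measured digitally. The field-2008 cohort is the
        only calliper cohort when emulating the original study.
    """

    sites: list[Site]
    counts: dict[tuple[str, str, str, int], int]
    traits: tuple[str, ...] = ALL_TRAITS
    calliper_cells: frozenset[tuple[str, int]] = frozenset({("field", 2008)})

    def __post_init__(self):
        codes = [s.code for s in self.sites]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate site codes in design")
        for key, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for cell {key}")
            site, origin, sex, year = key
            if site not in codes:
                raise ValueError(f"count refers to unknown site {site!r}")
            if origin not in ORIGINS or sex not in SEXES:
                raise ValueError(f"bad factor level in cell {key}")

    def instrument_for(self, origin: str, year: int) -> str:
        return "calliper" if (origin, year) in self.calliper_cells else "digital"

    def isolation_of(self, site_code: str) -> str:
        for s in self.sites:
            if s.code == site_code:
                return s.isolation
        raise KeyError(site_code)

    @property
    def site_codes(self) -> list[str]:
        return [s.code for s in self.sites]

    def total_n(self) -> int:
        return sum(self.counts.values())


# Per-cell sample sizes of the original four-site study (males, females).
_STUDY_COUNTS = {
    # site: (field-2008 m/f, field-2010 m/f, laboratory-2010 m/f)
    "KAA": ((13, 11), (10, 2), (19, 14)),
    "TAL": ((23, 1), (12, 2), (26, 21)),
    "ALA": ((12, 12), (10, 14), (18, 24)),
    "VAS": ((12, 12), (6, 8), (28, 23)),
}
_STUDY_ISOLATION = {"KAA": "continuous", "TAL": "continuous",
                    "ALA": "isolated", "VAS": "isolated"}


def default_study_design() -> StudyDesign:
    """The four-site design of the original study.

    Two continuous-range sites (KAA Kaarina, TAL Talin) and two genetically
    isolated sites (ALA Aland, VAS Vasteras) at ~60 N, with wild-caught
    adults in 2008 and 2010 and laboratory-reared adults from the 2010
    nymph cohort; the field-2008 cohort was measured with callipers, all
    2010 individuals digitally.
    """
    sites = [Site(code, _STUDY_ISOLATION[code]) for code in _STUDY_COUNTS]
    counts: dict[tuple[str, str, str, int], int] = {}
    for code, ((m08, f08), (m10, f10), (ml, fl)) in _STUDY_COUNTS.items():
        counts[(code, "field", "male", 2008)] = m08
        counts[(code, "field", "female", 2008)] = f08
        counts[(code, "field", "male", 2010)] = m10
        counts[(code, "field", "female", 2010)] = f10
        counts[(code, "laboratory", "male", 2010)] = ml
        counts[(code, "laboratory", "female", 2010)] = fl
    return StudyDesign(sites=sites, counts=counts)


@dataclass
class TraitEffects:
    """Generating truth for one trait (all lengths in mm)."""

    intercept: float
    betas: dict[str, float] = field(default_factory=dict)
    site_sd: float = 0.1
    residual_sd: float = 0.5
    conversion_offset: float = 0.30
    conversion_noise_sd: float = 0.05
    digital_noise_sd: float = 0.02

    def __post_init__(self):
        if self.site_sd < 0:
            raise ValueError("site_sd must be >= 0")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if self.conversion_noise_sd < 0:
            raise ValueError("conversion_noise_sd must be >= 0")
        valid = set(POOLED_TERMS)
        unknown = set(self.betas) - valid
        if unknown:
            raise ValueError(f"unknown beta terms: {sorted(unknown)}")

    def linear_predictor(self, *, isolation: str, origin: str, sex: str,
                         year: int) -> float:
        """Cell mean (excluding site effect and residual) for one factor cell."""
        iso = 1.0 if isolation == "isolated" else 0.0
        lab = 1.0 if origin == "laboratory" else 0.0
        fem = 1.0 if sex == "female" else 0.0
        yr = 1.0 if year != YEARS[0] else 0.0
        b = self.betas
        return (self.intercept
                + b.get("isolation", 0.0) * iso
                + b.get("origin", 0.0) * lab
                + b.get("sex", 0.0) * fem
                + b.get("year", 0.0) * yr
                + b.get("isolation:sex", 0.0) * iso * fem
                + b.get("isolation:origin", 0.0) * iso * lab
                + b.get("origin:sex", 0.0) * lab * fem
                + b.get("isolation:origin:sex", 0.0) * iso * lab * fem)


EffectConfig = dict[str, TraitEffects]


def _solve_pooled_betas(cells: Mapping[tuple[str, str], float]) -> tuple[float, dict]:
    """Solve intercept + 8 betas from the 8 (isolation, origin) x sex cell means.

    ``cells`` maps (sex, "CF"/"IF"/"CL"/"IL") -> mean, where C/I is
    continuous/isolated and F/L is field/laboratory.
    """
    cf_m, if_m = cells[("male", "CF")], cells[("male", "IF")]
    cl_m, il_m = cells[("male", "CL")], cells[("male", "IL")]
    cf_f, if_f = cells[("female", "CF")], cells[("female", "IF")]
    cl_f, il_f = cells[("female", "CL")], cells[("female", "IL")]
    b = {}
    intercept = cf_m
    b["isolation"] = if_m - cf_m
    b["origin"] = cl_m - cf_m
    b["sex"] = cf_f - cf_m
    b["isolation:origin"] = (il_m - cl_m) - b["isolation"]
    b["isolation:sex"] = (if_f - cf_f) - b["isolation"]
    b["origin:sex"] = (cl_f - cf_f) - b["origin"]
    b["isolation:origin:sex"] = (
        il_f - intercept - b["isolation"] - b["origin"] - b["sex"]
        - b["isolation:origin"] - b["isolation:sex"] - b["origin:sex"])
    return intercept, b


# Posterior group means (mm) of the original analysis, used as generating
# cell means for the synthetic defaults: (sex, cell) -> mean where cell is
# continuous/isolated x field/laboratory.
_GROUP_MEANS = {
    "femur": {("male", "CF"): 13.02, ("male", "IF"): 13.52,
              ("male", "CL"): 12.51, ("male", "IL"): 13.02,
              ("female", "CF"): 13.97, ("female", "IF"): 15.04,
              ("female", "CL"): 13.56, ("female", "IL"): 14.25},
    "wing": {("male", "CF"): 8.86, ("male", "IF"): 8.76,
             ("male", "CL"): 9.01, ("male", "IL"): 8.97,
             ("female", "CF"): 6.20, ("female", "IF"): 6.41,
             ("female", "CL"): 6.20, ("female", "IL"): 6.37},
    "pronotum": {("male", "CF"): 4.06, ("male", "IF"): 4.38,
                 ("male", "CL"): 3.88, ("male", "IL"): 4.16,
                 ("female", "CF"): 4.40, ("female", "IF"): 4.80,
                 ("female", "CL"): 3.98, ("female", "IL"): 4.44},
}
# sex-limited traits: continuous-field intercept and the three remaining terms
_GENITAL_MEANS = {
    MALE_GENITAL: {"CF": 2.71, "IF": 2.97, "CL": 2.69, "IL": 2.96},
    FEMALE_GENITAL: {"CF": 5.95, "IF": 6.40, "CL": 5.42, "IL": 6.09},
}

# residual / between-site sds (mm) are not observable from the published
# summaries alone; defaults back-calculated from posterior sds of group
# means at the published per-group sample sizes, and from the spread of
# site-specific estimates within an isolation class.
_NOISE = {  # trait: (residual_sd, site_sd)
    "femur": (0.70, 0.12),
    "wing": (0.90, 0.15),
    "pronotum": (0.30, 0.08),
    MALE_GENITAL: (0.20, 0.04),
    FEMALE_GENITAL: (0.35, 0.08),
}
_YEAR_EFFECT = {"femur": 0.10, "wing": 0.10, "pronotum": 0.04,
                MALE_GENITAL: 0.02, FEMALE_GENITAL: 0.05}


def default_study_effects() -> EffectConfig:
    """Effect configuration whose cell means reproduce the published group
    estimates, with noise scales matched to the published posterior sds."""
    cfg: EffectConfig = {}
    for trait, cells in _GROUP_MEANS.items():
        intercept, betas = _solve_pooled_betas(cells)
        betas["year"] = _YEAR_EFFECT[trait]
        res_sd, site_sd = _NOISE[trait]
        cfg[trait] = TraitEffects(intercept=intercept, betas=betas,
                                  site_sd=site_sd, residual_sd=res_sd)
    for trait, cells in _GENITAL_MEANS.items():
        betas = {
            "isolation": cells["IF"] - cells["CF"],
            "origin": cells["CL"] - cells["CF"],
            "year": _YEAR_EFFECT[trait],
        }
        betas["isolation:origin"] = (cells["IL"] - cells["CL"]) - betas["isolation"]
        res_sd, site_sd = _NOISE[trait]
        cfg[trait] = TraitEffects(intercept=cells["CF"], betas=betas,
                                  site_sd=site_sd, residual_sd=res_sd)
    return cfg


def null_effects(template: EffectConfig | None = None) -> EffectConfig:
    """Copy of an effect configuration with every beta set to zero
    (group structure removed; intercept and noise scales kept)."""
    template = template or default_study_effects()
    return {
        trait: TraitEffects(
            intercept=eff.intercept, betas={},
            site_sd=eff.site_sd, residual_sd=eff.residual_sd,
            conversion_offset=eff.conversion_offset,
            conversion_noise_sd=eff.conversion_noise_sd,
            digital_noise_sd=eff.digital_noise_sd)
        for trait, eff in template.items()
    }


def effects_to_yaml(cfg: EffectConfig, path) -> None:
    """Write an effect configuration as a YAML file, one block per trait."""
    payload = {trait: asdict(eff) for trait, eff in cfg.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def effects_from_yaml(path) -> EffectConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return {trait: TraitEffects(**block) for trait, block in payload.items()}
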