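"""Instrument calibration: the additive calliper-to-digital conversion.

A subset of individuals is measured with both hand-held callipers and the
digital landmark technique. Per trait, the conversion is the mean of the
per-pair differences (calliper minus digital) under a normal model with a
minimally informative Normal(0, prior_sd^2) prior on the offset; the noise
scale is taken as the sample sd of the differences, giving the conjugate
normal-normal posterior for the offset. The posterior sd of the offset is
what the trait models propagate as observation-level error on every
calliper-measured row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

DEFAULT_PRIOR_SD = 10.0  # mm; flat at trait scale


@dataclass(frozen=True)
class ConversionEstimate:
    """Posterior summary of the additive calliper - digital offset for one trait."""

    trait: str
    offset_mean: float      # mm
    offset_sd: float        # mm
    n_pairs: int
    pearson_r: float

    def __post_init__(self):
        if self.offset_sd < 0:
            raise ValueError("offset_sd must be >= 0")
        if self.n_pairs < 2:
            raise ValueError("need at least 2 pairs")


def identity_conversion(trait: str) -> ConversionEstimate:
    """A zero-offset, zero-uncertainty conversion (digital == calliper)."""
    return ConversionEstimate(trait=trait, offset_mean=0.0, offset_sd=0.0,
                              n_pairs=2, pearson_r=1.0)


def fit_conversion(pairs: pd.DataFrame, trait: str,
                   prior_sd: float = DEFAULT_PRIOR_SD,
                   seed: int | None = None) -> ConversionEstimate:
    """Posterior for the additive offset of one trait.

    With differences d_i = calliper_i - digital_i, sample mean dbar and
    sample sd s, the posterior under the Normal(0, prior_sd^2) prior is

        offset | d ~ Normal(m, v),
        1/v = 1/prior_sd^2 + n/s^2,   m = v * (n/s^2) * dbar.

    If the differences have zero variance the offset is the common
    difference with zero posterior sd. ``seed`` is accepted for interface
    symmetry with the samplers; the posterior here is closed-form.
    """
    sub = pairs[pairs["trait"] == trait]
    n = len(sub)
    if n < 2:
        raise ValueError(f"need >= 2 calibration pairs for {trait!r}, got {n}")
    call = sub["calliper_mm"].to_numpy(float)
    digi = sub["digital_mm"].to_numpy(float)
    d = call - digi
    dbar = float(d.mean())
    s = float(d.std(ddof=1))
    if np.std(call) == 0.0 or np.std(digi) == 0.0:
        r = 1.0 if s == 0.0 else 0.0
    else:
        r = float(np.corrcoef(call, digi)[0, 1])
    if s == 0.0:
        return ConversionEstimate(trait=trait, offset_mean=dbar, offset_sd=0.0,
                                  n_pairs=n, pearson_r=r)
    prec = 1.0 / prior_sd**2 + n / s**2
    v = 1.0 / prec
    m = v * (n / s**2) * dbar
    return ConversionEstimate(trait=trait, offset_mean=m,
                              offset_sd=float(np.sqrt(v)), n_pairs=n,
                              pearson_r=r)


def fit_all_conversions(pairs: pd.DataFrame,
                        prior_sd: float = DEFAULT_PRIOR_SD) -> dict[str, ConversionEstimate]:
    """Fit the conversion for every trait present in the paired table."""
    return {trait: fit_conversion(pairs, trait, prior_sd=prior_sd)
            for trait in sorted(pairs["trait"].unique())}


def convert_calliper(value: float, est: ConversionEstimate,
                     trait: str | None = None) -> tuple[float, float]:
    """Observation-layer parameters for one calliper measurement.

    Returns ``(value - offset_mean, offset_sd)``: the calliper reading
    shifted onto the digital scale, with the conversion uncertainty as
    extra observation error. With a (0, 0) conversion the raw value passes
    through with no extra error.
    """
    if trait is not None and trait != est.trait:
        raise ValueError(f"conversion is for {est.trait!r}, not {trait!r}")
    return value - est.offset_mean, est.offset_sd


def conversions_to_json(ests: dict[str, ConversionEstimate], path) -> None:
    with open(path, "w") as fh:
        json.dump({t: asdict(e) for t, e in ests.items()}, fh, indent=2,
                  sort_keys=True)


def conversions_from_json(path) -> dict[str, ConversionEstimate]:
    with open(path) as fh:
        payload = json.load(fh)
    return {t: ConversionEstimate(**block) for t, block in payload.items()}
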