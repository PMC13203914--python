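"""Synthetic cohort generator with the study's hierarchical variance structure.

The real experiment collects one ejaculate per donor per week, splits it
into seven aliquots (one fresh, six frozen under different extender /
antioxidant conditions) and measures the same 14 features on each. Three
facts dominate that design and must be reproduced for the downstream
analyses to be testable:

* **donor effects dominate** — each donor carries a persistent random
  offset on every feature, larger than the residual noise;
* **freezing shifts most features strongly** — motility, velocities, MMP
  and the whole-cell/midpiece volumes drop, the stress and DNA-damage
  markers rise, while the *nuclear* volume is untouched;
* **antioxidant-specific effects are small and inconsistent** — at most a
  fifth of the residual noise, concentrated on the midpiece volume, with
  matcha/horseradish losing about twice as much midpiece volume as
  spirulina/quercetin.

Each feature value is generated additively on the measurement scale:

    value = baseline + donor_offset(d) + 1[frozen] * freeze_shift
            + antiox_shift(treatment) + noise

with percentages clipped to [0, 100] and volumes floored at a small
positive bound. The single RNG stream is consumed in a fixed order (donor
offsets, then ages, then per-row noise) so that changing the replicate
count never changes the donor offsets.

Baseline magnitudes are plausible literature-scale values for equine
semen; no fidelity to the study's (unpublished) group means is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .feature_table import (
    FEATURES,
    FROZEN_TREATMENTS,
    PERCENT_FEATURES,
    TREATMENTS,
    VOLUME_FEATURES,
    FeatureTable,
)

_VOLUME_FLOOR = 1e-3  # µm³; volumes are clipped up to stay strictly positive


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration."""


def _as_feature_vector(d: Mapping[str, float], what: str) -> np.ndarray:
    missing = [f for f in FEATURES if f not in d]
    if missing:
        raise ConfigError(f"{what} missing features {missing}")
    return np.array([float(d[f]) for f in FEATURES])


@dataclass(frozen=True)
class EffectProfile:
    """Hierarchical effect sizes, all keyed by feature name.

    ``antiox_shift`` maps each frozen treatment to a (possibly partial)
    feature→shift mapping; unlisted features shift by 0.
    """

    baseline_means: Mapping[str, float]
    donor_sd: Mapping[str, float]
    freeze_shift: Mapping[str, float]
    antiox_shift: Mapping[str, Mapping[str, float]]
    noise_sd: Mapping[str, float]

    def validate(self) -> None:
        base = _as_feature_vector(self.baseline_means, "baseline_means")
        dsd = _as_feature_vector(self.donor_sd, "donor_sd")
        nsd = _as_feature_vector(self.noise_sd, "noise_sd")
        _as_feature_vector(self.freeze_shift, "freeze_shift")
        if np.any(dsd < 0) or np.any(nsd < 0):
            raise ConfigError("effect SDs must be non-negative")
        for f in PERCENT_FEATURES:
            b = float(self.baseline_means[f])
            if not 0.0 < b < 100.0:
                raise ConfigError(f"percentage baseline {f}={b} must lie inside (0, 100)")
        for t in self.antiox_shift:
            if t not in FROZEN_TREATMENTS:
                raise ConfigError(f"antiox_shift for non-frozen treatment {t!r}")

    def zeroed(self) -> "EffectProfile":
        """Copy with donor, freeze and antioxidant effects removed (noise kept)."""
        zero = {f: 0.0 for f in FEATURES}
        return replace(self, donor_sd=zero, freeze_shift=dict(zero), antiox_shift={})

    # -- vector views used by the generator ---------------------------------
    def _vectors(self):
        return (
            _as_feature_vector(self.baseline_means, "baseline_means"),
            _as_feature_vector(self.donor_sd, "donor_sd"),
            _as_feature_vector(self.freeze_shift, "freeze_shift"),
            _as_feature_vector(self.noise_sd, "noise_sd"),
        )

    def _antiox_vector(self, treatment: str) -> np.ndarray:
        shifts = self.antiox_shift.get(treatment, {})
        return np.array([float(shifts.get(f, 0.0)) for f in FEATURES])


# Residual (within donor × treatment) noise SDs, in feature units.
_NOISE_SD = {
    "tm": 5.0, "pm": 5.0, "vcl": 10.0, "vsl": 8.0, "vap": 8.0,
    "mmp": 0.2,
    "lpo": 10.0, "ros": 12.0, "no": 8.0,
    "tunel_dfi": 2.0, "scsa_dfi": 2.5,
    "vol_whole": 1.5, "vol_mid": 0.5, "vol_nuc": 0.35,
}

# Grand means at the fresh condition, in feature units (%, µm/s, a.u., µm³).
_BASELINE = {
    "tm": 80.0, "pm": 55.0, "vcl": 150.0, "vsl": 90.0, "vap": 110.0,
    "mmp": 2.0,
    "lpo": 100.0, "ros": 120.0, "no": 80.0,
    "tunel_dfi": 8.0, "scsa_dfi": 12.0,
    "vol_whole": 28.0, "vol_mid": 6.5, "vol_nuc": 4.5,
}


def default_effect_profile() -> EffectProfile:
    """Default profile mirroring the study's qualitative contrasts.

    Donor offsets have SD 1.5× the residual noise on every feature (donor
    identity dominates); freezing shifts motility/velocity/MMP and the
    whole-cell and midpiece volumes down, and the stress/DNA markers up,
    by 1.5× noise SD; the nuclear volume freeze shift is exactly 0;
    antioxidant-specific shifts are ≤ 0.2× noise SD and target the
    midpiece volume, matcha/horseradish twice as strongly as
    spirulina/quercetin.
    """
    noise = dict(_NOISE_SD)
    donor = {f: 1.5 * s for f, s in noise.items()}
    sign = {f: -1.0 for f in ("tm", "pm", "vcl", "vsl", "vap", "mmp", "vol_whole", "vol_mid")}
    sign.update({f: 1.0 for f in ("lpo", "ros", "no", "tunel_dfi", "scsa_dfi")})
    sign["vol_nuc"] = 0.0
    freeze = {f: sign[f] * 1.5 * noise[f] for f in FEATURES}
    mid = noise["vol_mid"]
    antiox = {
        "CTRL-": {},
        "CTRL+": {"vol_mid": -0.16 * mid, "vol_whole": -0.16 * noise["vol_whole"]},
        "Matcha": {"vol_mid": -0.20 * mid},
        "Horseradish": {"vol_mid": -0.20 * mid},
        "Spirulina": {"vol_mid": -0.10 * mid},
        "Quercetin": {"vol_mid": -0.10 * mid},
    }
    profile = EffectProfile(
        baseline_means=dict(_BASELINE),
        donor_sd=donor,
        freeze_shift=freeze,
        antiox_shift=antiox,
        noise_sd=noise,
    )
    profile.validate()
    return profile


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort design: 10 donors × 7 treatments × replicates rows."""

    n_donors: int = 10
    treatments: Sequence[str] = TREATMENTS
    replicates: int = 3
    age_range: tuple[int, int] = (4, 17)
    profile: EffectProfile = field(default_factory=default_effect_profile)
    seed: int = 0
    #: ages constant per donor (as in reality, so age may partially identify
    #: donors); False draws an independent age per row, which is what makes a
    #: null cohort's donor labels truly uninformative
    ages_per_donor: bool = True

    def validate(self) -> None:
        if self.n_donors < 2:
            raise ConfigError("need at least 2 donors")
        if self.replicates < 1:
            raise ConfigError("need at least 1 replicate")
        if not self.treatments:
            raise ConfigError("treatment list is empty")
        for t in self.treatments:
            if t not in TREATMENTS:
                raise ConfigError(f"unknown treatment {t!r}")
        freeze = _as_feature_vector(self.profile.freeze_shift, "freeze_shift")
        if np.any(freeze != 0) and "Fresh" not in self.treatments:
            raise ConfigError("nonzero freeze effects require the Fresh condition")
        if self.age_range[0] > self.age_range[1] or self.age_range[0] < 0:
            raise ConfigError(f"invalid age range {self.age_range}")
        self.profile.validate()

    def donor_ids(self) -> list[str]:
        # the study's donors are numbered #3 .. #12
        return [f"#{i + 3}" for i in range(self.n_donors)]


def generate_cohort(config: SyntheticConfig) -> FeatureTable:
    """Draw one cohort; byte-identical output for identical config + seed."""
    config.validate()
    prof = config.profile
    base, donor_sd, freeze, noise_sd = prof._vectors()
    rng = np.random.default_rng(config.seed)

    # fixed consumption order: donor offsets -> ages -> residual noise
    donor_offsets = rng.standard_normal((config.n_donors, len(FEATURES))) * donor_sd
    lo, hi = config.age_range
    ages_pool = np.arange(lo, hi + 1)
    n_rows = config.n_donors * len(config.treatments) * config.replicates
    if config.ages_per_donor:
        # without replacement where possible, so ages mostly distinguish donors
        replace_draw = len(ages_pool) < config.n_donors
        donor_ages = rng.choice(ages_pool, size=config.n_donors, replace=replace_draw)
        row_ages = None
    else:
        donor_ages = None
        row_ages = rng.choice(ages_pool, size=n_rows, replace=True)

    noise = rng.standard_normal((n_rows, len(FEATURES))) * noise_sd

    rows = []
    r = 0
    donors = config.donor_ids()
    for d in range(config.n_donors):
        for t in config.treatments:
            shift = np.zeros(len(FEATURES))
            if t != "Fresh":
                shift = freeze + prof._antiox_vector(t)
            for _ in range(config.replicates):
                x = base + donor_offsets[d] + shift + noise[r]
                age = donor_ages[d] if row_ages is None else row_ages[r]
                rows.append((donors[d], t, int(age), x))
                r += 1

    df = pd.DataFrame(
        [(d, t, a, *x) for d, t, a, x in rows],
        columns=["donor_id", "treatment", "age", *FEATURES],
    )
    for f in PERCENT_FEATURES:
        df[f] = df[f].clip(0.0, 100.0)
    for f in VOLUME_FEATURES:
        df[f] = df[f].clip(lower=_VOLUME_FLOOR)
    # enforce subcellular <= whole-cell (essentially never binds at defaults)
    df["vol_mid"] = np.minimum(df["vol_mid"], df["vol_whole"])
    df["vol_nuc"] = np.minimum(df["vol_nuc"], df["vol_whole"])
    return FeatureTable(df)


def null_cohort(config: SyntheticConfig) -> FeatureTable:
    """Cohort in which labels carry no information (pure residual noise).

    Equivalent to :func:`generate_cohort` with a zeroed effect profile and
    ages drawn independently per row — a per-donor constant age would by
    itself identify donors, so it too must be severed from the labels.
    """
    return generate_cohort(
        replace(config, profile=config.profile.zeroed(), ages_per_donor=False)
    )
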