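"""Synthetic replicate-level data with the 13-pair study's structure.

The generator emulates the replication design of the living-shoreline /
natural-marsh comparison — 13 pairs, 18 metrics plus the auxiliary
low-marsh-only mussel variant, with 3 soil cores, 12 low-marsh (+6 sill
at LS) quadrats, 2 fyke nets + 10 minnow traps over 2 years, and 3-6
camera/visual surveys per site — so that every downstream stage can be
exercised and calibrated without the field data.

The model behind a metric's replicate values is hierarchical:

    site mean  theta[p, t] = B + tau*u[p] + s_site*e[p, t] + shift[p, t]
    replicate  value ~ family(mean=theta, sd=s_within)

where ``B`` is the metric's baseline, ``u`` a shared pair effect,
``e`` independent site noise, and ``shift`` applies the metric's true
standardized offset delta (LS only), expressed in units of the SD that
its Z-score will be standardized by (the within-site replicate SD for
local-SD metrics, the among-pair spread for regional-SD metrics).
Under delta = 0 the two site types are exchangeable, so every
pair-level Z-score is symmetric about zero by construction.

Noise families respect each metric's support: truncated normal for soil
weight percentages, lognormal for densities/abundances/biomasses, gamma
for the heron use ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .metrics import METRICS, METRICS_BY_ID
from .study import N_PAIRS, SITE_AGES_YEARS


@dataclass(frozen=True)
class StudyDesign:
    """Replication plan of one simulated study."""

    n_pairs: int = N_PAIRS
    ages: tuple[int, ...] = SITE_AGES_YEARS
    seed: int = 0
    # per-metric (LS, NM) replicate count overrides
    replicate_plan: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_pairs < 2:
            raise ConfigurationError("need at least two pairs")
        if len(self.ages) != self.n_pairs:
            raise ConfigurationError(
                f"{self.n_pairs} pairs but {len(self.ages)} ages supplied"
            )
        if any(a <= 0 for a in self.ages):
            raise ConfigurationError("all ages must be positive (log is taken)")
        for m, (nls, nnm) in self.replicate_plan.items():
            if m not in METRICS_BY_ID:
                raise ConfigurationError(f"replicate plan names unknown metric {m!r}")
            if nls < 1 or nnm < 1:
                raise ConfigurationError(f"replicate counts for {m!r} must be >= 1")

    def replicates(self, metric_id: str) -> tuple[int, int]:
        if metric_id in self.replicate_plan:
            return self.replicate_plan[metric_id]
        mdef = METRICS_BY_ID[metric_id]
        return mdef.n_rep_ls, mdef.n_rep_nm


@dataclass(frozen=True)
class EffectSpec:
    """True effect and noise structure of a simulated study.

    ``delta`` holds the true standardized LS - NM offset per metric (SD
    units; metrics absent default to 0).  The coefficients of variation
    set, relative to each metric's baseline, the within-site replicate
    SD (``within_cv``), the independent site-level noise (``site_cv``)
    and the among-pair spread (``among_cv``).  ``age_slope`` optionally
    makes the offset grow with ln(age).
    """

    delta: Mapping[str, float] = field(default_factory=dict)
    within_cv: float = 0.40
    site_cv: float = 0.15
    among_cv: float = 0.30
    age_slope: Mapping[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("within_cv", "site_cv", "among_cv"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for m in list(self.delta) + list(self.age_slope):
            if m not in METRICS_BY_ID:
                raise ConfigurationError(f"effect spec names unknown metric {m!r}")


def _family_draw(rng, family: str, mean: np.ndarray, sd: float) -> np.ndarray:
    """Draw with the requested support, matching the first two moments."""
    mean = np.asarray(mean, dtype=float)
    if family == "normal":
        return rng.normal(mean, sd)
    floor = 1e-9
    m = np.clip(mean, floor, None)
    if family == "lognormal":
        s2 = np.log1p((sd / m) ** 2)
        return rng.lognormal(np.log(m) - s2 / 2.0, np.sqrt(s2))
    if family == "gamma":
        shape = (m / sd) ** 2
        return rng.gamma(shape, (sd**2) / m)
    raise ConfigurationError(f"unknown noise family {family!r}")


def _metric_frame(design: StudyDesign, effects: EffectSpec,
                  mdef, stream_index: int) -> pd.DataFrame:
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=design.seed, spawn_key=(stream_index,))
    )
    n = design.n_pairs
    B = mdef.baseline
    s_within = effects.within_cv * B
    s_site = effects.site_cv * B
    tau = effects.among_cv * B

    u = rng.normal(0.0, 1.0, size=n)  # shared pair effect
    e = rng.normal(0.0, 1.0, size=(n, 2))  # site noise, col 0 = LS
    delta = float(effects.delta.get(mdef.metric_id, 0.0))
    slope = float(effects.age_slope.get(mdef.metric_id, 0.0))
    ages = np.asarray(design.ages, dtype=float)
    delta_p = delta + slope * np.log(ages)
    # SD unit the metric's Z-score divides by
    if mdef.sd_mode == "local":
        unit = s_within
    else:
        unit = np.sqrt(tau**2 + s_site**2)

    n_ls, n_nm = design.replicates(mdef.metric_id)
    rows = []
    for p in range(n):
        for t, (site, n_rep) in enumerate((("LS", n_ls), ("NM", n_nm))):
            theta = B + tau * u[p] + s_site * e[p, t]
            if site == "LS":
                theta = theta + delta_p[p] * unit
            vals = _family_draw(rng, mdef.noise_family, np.full(n_rep, theta),
                                s_within)
            if mdef.units in ("%", "0-100"):
                vals = np.clip(vals, 0.0, 100.0)
            elif mdef.noise_family != "normal":
                vals = np.clip(vals, 0.0, None)
            for r, v in enumerate(vals, start=1):
                rows.append((p + 1, site, mdef.metric_id, r, float(v)))
    frame = pd.DataFrame(
        rows, columns=["pair", "site_type", "metric", "replicate", "value"]
    )
    # zone labels: quadrat metrics at LS carry 12 low-marsh + 6 sill
    if mdef.group in ("invertebrates", "plants"):
        frame["zone"] = "low_marsh"
        sill = (frame["site_type"] == "LS") & (frame["replicate"] > 12)
        frame.loc[sill, "zone"] = "sill"
    else:
        frame["zone"] = pd.NA
    # nekton replicates span two survey years
    if mdef.group == "nekton":
        half_ls = max(1, n_ls // 2)
        half_nm = max(1, n_nm // 2)
        frame["year"] = 2018
        for site, half in (("LS", half_ls), ("NM", half_nm)):
            late = (frame["site_type"] == site) & (frame["replicate"] > half)
            frame.loc[late, "year"] = 2019
    else:
        frame["year"] = pd.NA
    # effort context: survey hours for terrapin, recording time for herons
    if mdef.group == "terrapin":
        frame["effort"] = 0.5  # hours per visual survey
    elif mdef.group == "herons":
        frame["effort"] = 4 * 1800.0  # seconds recorded per camera survey
    else:
        frame["effort"] = 1.0
    return frame


def simulate_study(design: StudyDesign, effects: EffectSpec | None = None) -> pd.DataFrame:
    """Draw one full replicate-level study as a tidy table.

    Returns columns (pair, site_type, metric, replicate, value, zone,
    year, effort) covering all 19 metric columns (18 net-score metrics
    plus the auxiliary low-marsh-only mussel variant, which is derived
    from the same simulated mussel quadrats rather than redrawn).
    Deterministic given ``design.seed``; each metric consumes its own
    RNG substream keyed by registry position, so adding a metric never
    perturbs the others.
    """
    effects = effects or EffectSpec()
    design.validate()
    effects.validate()
    frames = []
    mussel_frame = None
    for idx, mdef in enumerate(METRICS):
        if mdef.metric_id == "mussels_lm_only":
            continue  # derived below from the mussel quadrats
        frame = _metric_frame(design, effects, mdef, stream_index=idx)
        if mdef.metric_id == "mussels":
            mussel_frame = frame
        frames.append(frame)
    lm = mussel_frame[mussel_frame["zone"] == "low_marsh"].copy()
    lm["metric"] = "mussels_lm_only"
    frames.append(lm)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["metric", "pair", "site_type", "replicate"],
                           kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# terrapin sighting simulator


@dataclass(frozen=True)
class TerrapinSimSpec:
    """True detection process for simulated point-transect surveys.

    ``key`` in {half-normal, hazard-rate, uniform}; ``sigma`` the scale
    (m); ``shape`` the hazard-rate shape b > 1; ``density`` expected
    animals per survey within the truncation circle; ``w`` truncation
    distance (m); ``wind_coef`` log-scale effect of standardized wind
    speed on sigma.
    """

    key: str = "hazard-rate"
    sigma: float = 25.0
    shape: float = 2.5
    density: float = 8.0
    w: float = 100.0
    wind_coef: float = 0.0

    def validate(self) -> None:
        if self.key not in ("half-normal", "hazard-rate", "uniform"):
            raise ConfigurationError(f"unknown key function {self.key!r}")
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be positive")
        if self.key == "hazard-rate" and self.shape <= 1:
            raise ConfigurationError("hazard-rate shape must exceed 1")
        if self.w <= 0:
            raise ConfigurationError("truncation distance must be positive")
        if self.density <= 0:
            raise ConfigurationError("density must be positive")

    def g(self, r: np.ndarray, sigma: float | np.ndarray | None = None) -> np.ndarray:
        sigma = self.sigma if sigma is None else sigma
        r = np.asarray(r, dtype=float)
        if self.key == "uniform":
            return np.ones_like(r)
        if self.key == "half-normal":
            return np.exp(-(r**2) / (2.0 * sigma**2))
        with np.errstate(divide="ignore"):
            return 1.0 - np.exp(-((r / sigma) ** (-self.shape)))


def simulate_terrapin_distances(
    spec: TerrapinSimSpec, n_surveys: int, seed: int
) -> pd.DataFrame:
    """Simulate radial sighting distances from point-transect surveys.

    Candidate animals are uniform over the disc of radius ``w`` (radial
    density proportional to r) and detected with probability
    g(r; sigma_i), where ln sigma_i shifts by ``wind_coef`` times the
    survey's standardized wind speed.  Returns a tidy sighting table
    (distance_m, wind_mps, site, survey); reproducible given ``seed``.
    """
    spec.validate()
    if n_surveys < 1:
        raise ConfigurationError("need at least one survey")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_surveys):
        site = "LS" if s % 2 == 0 else "NM"
        wind = rng.uniform(0.0, 8.0)
        sigma = spec.sigma * np.exp(spec.wind_coef * (wind - 4.0) / 2.0)
        n_cand = rng.poisson(spec.density)
        if n_cand == 0:
            continue
        r = spec.w * np.sqrt(rng.uniform(size=n_cand))
        keep = rng.uniform(size=n_cand) < spec.g(r, sigma)
        for d in r[keep]:
            rows.append((float(d), float(wind), site, s + 1))
    return pd.DataFrame(rows, columns=["distance_m", "wind_mps", "site", "survey"])
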