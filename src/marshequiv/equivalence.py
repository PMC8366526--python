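"""Paired Z-scores and the net functional-equivalence score.

For each metric of each living-shoreline/natural-marsh pair the
standardized difference is

    Z = (LS - NM) / sigma_pooled

with the natural-marsh value subtracted from the living-shoreline
value, so positive Z means the living shoreline shows the higher level
of function.  The pooled SD is either

* local (within-pair):   sigma_L = sqrt((sd_LS^2 + sd_NM^2) / 2)
  from the two within-site replicate SDs — available only to metrics
  sampled with identical effort and replication at both sites; or
* regional (among-pair): sigma_R = sqrt((SD_LS^2 + SD_NM^2) / 2)
  where SD_LS / SD_NM are the sample SDs of the site-level values
  across all pairs — one shared value per metric.

A metric is called functionally equivalent when |mean Z| < 1.  The mean
of a pair's metric Z-scores (the auxiliary low-marsh-only mussel column
excluded) is its net functional-equivalence score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateSDError, MarshEquivError
from .metrics import METRICS_BY_ID, MetricDefinition

EQUIVALENCE_THRESHOLD = 1.0


def pooled_sd_local(sd_ls: float, sd_nm: float) -> float:
    """Within-pair pooled SD: sqrt((sd_LS^2 + sd_NM^2)/2)."""
    if sd_ls < 0 or sd_nm < 0:
        raise MarshEquivError("standard deviations must be non-negative")
    if sd_ls == 0 and sd_nm == 0:
        raise DegenerateSDError("both within-site SDs are zero; Z undefined")
    return math.sqrt((sd_ls**2 + sd_nm**2) / 2.0)


def pooled_sd_regional(ls_site_means, nm_site_means) -> float:
    """Among-pair pooled SD from site-level values, one per site.

    Sample SDs (n-1) of the living-shoreline values across pairs and of
    the natural-marsh values across pairs, pooled as
    sqrt((SD_LS^2 + SD_NM^2)/2).
    """
    ls = np.asarray(ls_site_means, dtype=float)
    nm = np.asarray(nm_site_means, dtype=float)
    if ls.size < 2 or nm.size < 2:
        raise MarshEquivError("regional SD requires at least two pairs")
    sd = math.sqrt((ls.std(ddof=1) ** 2 + nm.std(ddof=1) ** 2) / 2.0)
    if sd == 0:
        raise DegenerateSDError("zero among-pair spread; Z undefined")
    return sd


def z_score(ls_mean: float, nm_mean: float, pooled_sd: float) -> float:
    """Standardized LS - NM difference; positive favors the living shoreline."""
    if pooled_sd <= 0:
        raise DegenerateSDError("pooled SD must be positive")
    return (ls_mean - nm_mean) / pooled_sd


@dataclass
class EquivalenceTable:
    """Z-score matrix plus the derived per-pair and per-metric summaries.

    ``z``                pairs x metrics DataFrame (NaN where a pooled SD
                         was degenerate and the score was excluded);
    ``net_scores``       per-pair mean Z over the included (net-score)
                         metrics;
    ``metric_means``     per-metric mean Z over pairs;
    ``grand_mean``/``grand_sd``       over all included pair x metric scores;
    ``metric_mean_sd``   SD of the 18 metric-level means (the printed
                         grand mean is ambiguous between the two
                         spreads, so both are exposed);
    ``equivalent``       per-metric flag |mean Z| < 1.
    """

    z: pd.DataFrame
    net_scores: pd.Series
    metric_means: pd.Series
    grand_mean: float
    grand_sd: float
    metric_mean_sd: float
    equivalent: pd.Series
    sd_mode: dict[str, str] = field(default_factory=dict)
    pooled_sds: pd.DataFrame | None = None

    @property
    def included_metrics(self) -> list[str]:
        return [m for m in self.z.columns
                if METRICS_BY_ID.get(m) is None or METRICS_BY_ID[m].include_in_net]


def build_equivalence_table(
    summaries: pd.DataFrame,
    metric_defs: dict[str, MetricDefinition] | None = None,
) -> EquivalenceTable:
    """Score every pair x metric and assemble the equivalence table.

    ``summaries`` has one row per (pair, site_type, metric) with columns
    ``mean``, ``sd``, ``n`` (sd may be NaN for regional-SD metrics).
    Both site types must be present for every (pair, metric); gaps are
    reported together in one error.  A degenerate pooled SD excludes
    that metric (locally, for the affected pair; regionally, for the
    whole metric) with a warning instead of emitting infinities.
    """
    metric_defs = metric_defs or METRICS_BY_ID
    piv = summaries.pivot_table(
        index="pair", columns=["metric", "site_type"], values="mean", aggfunc="first"
    )
    sd_piv = summaries.pivot_table(
        index="pair", columns=["metric", "site_type"], values="sd", aggfunc="first"
    )
    metrics = sorted({m for m, _ in piv.columns}, key=list(metric_defs).index)
    pairs = list(piv.index)

    gaps = []
    for m in metrics:
        for st in ("LS", "NM"):
            if (m, st) not in piv.columns:
                gaps.append(f"metric {m!r}: no {st} sites at all")
                continue
            for p in pairs:
                if pd.isna(piv.loc[p, (m, st)]):
                    gaps.append(f"pair {p}, metric {m!r}: missing {st} value")
    if gaps:
        raise MarshEquivError(
            "incomplete pairs in summaries: " + "; ".join(gaps)
        )

    z = pd.DataFrame(index=pairs, columns=metrics, dtype=float)
    pooled = pd.DataFrame(index=pairs, columns=metrics, dtype=float)
    sd_mode_used: dict[str, str] = {}
    for m in metrics:
        mdef = metric_defs.get(m)
        if mdef is None:
            raise MarshEquivError(f"no metric definition for {m!r}")
        sd_mode_used[m] = mdef.sd_mode
        ls_means = piv[(m, "LS")].astype(float)
        nm_means = piv[(m, "NM")].astype(float)
        if mdef.sd_mode == "regional":
            try:
                sd = pooled_sd_regional(ls_means.values, nm_means.values)
            except DegenerateSDError:
                warnings.warn(f"metric {m!r}: degenerate regional SD; excluded")
                continue
            z[m] = (ls_means - nm_means) / sd
            pooled[m] = sd
        else:
            for p in pairs:
                sls = sd_piv.loc[p, (m, "LS")]
                snm = sd_piv.loc[p, (m, "NM")]
                if pd.isna(sls) or pd.isna(snm):
                    warnings.warn(
                        f"pair {p}, metric {m!r}: missing within-site SD; excluded"
                    )
                    continue
                try:
                    sd = pooled_sd_local(float(sls), float(snm))
                except DegenerateSDError:
                    warnings.warn(
                        f"pair {p}, metric {m!r}: both SDs zero; excluded"
                    )
                    continue
                z.loc[p, m] = z_score(ls_means[p], nm_means[p], sd)
                pooled.loc[p, m] = sd

    included = [m for m in metrics if metric_defs[m].include_in_net]
    net = z[included].mean(axis=1, skipna=True)
    metric_means = z.mean(axis=0, skipna=True)
    all_scores = z[included].values.ravel()
    all_scores = all_scores[~np.isnan(all_scores)]
    inc_means = metric_means[included]
    return EquivalenceTable(
        z=z,
        net_scores=net,
        metric_means=metric_means,
        grand_mean=float(all_scores.mean()) if all_scores.size else math.nan,
        grand_sd=float(all_scores.std(ddof=1)) if all_scores.size > 1 else math.nan,
        metric_mean_sd=float(inc_means.std(ddof=1)) if len(inc_means) > 1 else math.nan,
        equivalent=metric_means.abs() < EQUIVALENCE_THRESHOLD,
        sd_mode=sd_mode_used,
        pooled_sds=pooled,
    )
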