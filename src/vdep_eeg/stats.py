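"""Nonparametric comparison of band power between VDEP classes.

Normality is screened with the Kolmogorov-Smirnov test using the
Lilliefors correction (parameters estimated from the sample); class
differences are assessed with the two-sided Mann-Whitney U test, per
band and per design principle.  The report mirrors the usual rank-table
layout: sample sizes, mean ranks, U, p, effect direction and a
significance flag, with Holm-adjusted p-values available as an option.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as _sm_lilliefors

from .config import BAND_NAMES

__all__ = ["lilliefors", "mann_whitney", "compare_vdep_bands", "violin_data", "StatsReport"]


class StatsError(ValueError):
    """Raised on statistics-contract violations."""


def lilliefors(values: np.ndarray) -> tuple[float, float]:
    """Kolmogorov-Smirnov normality test with Lilliefors correction.

    Returns (D, p) where D is the sup-distance between the empirical
    CDF and a normal CDF with sample-estimated mean and SD.  Requires
    n >= 5 and a non-constant sample.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 5:
        raise StatsError("lilliefors requires a 1-D sample with n >= 5")
    if np.ptp(x) == 0:
        raise StatsError("lilliefors is undefined for a constant sample")
    d, p = _sm_lilliefors(x, dist="norm", pvalmethod="table")
    return float(d), float(p)


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with midrank ties.

    U is the rank-sum statistic for ``x``.  The p-value is exact (full
    enumeration) for small untied samples (n1 + n2 <= 12), otherwise
    the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise StatsError("mann_whitney requires two non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class StatsReport:
    """Per-(vdep, band) rank-sum comparison results."""

    vdep: str
    alpha: float
    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=2)


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj


def compare_vdep_bands(table: pd.DataFrame, vdep: str, alpha: float = 0.05,
                       holm: bool = False,
                       bands: list[str] | None = None) -> StatsReport:
    """Mann-Whitney comparison of every band's power between classes.

    ``table`` is a band-power table (one row per epoch) for a single
    design principle with a ``cls`` column in {1, 2}.  ``holm=True``
    bases the significance flag on Holm-adjusted p-values; the adjusted
    column is reported either way.
    """
    bands = list(bands) if bands is not None else list(BAND_NAMES)
    sub = table[table["vdep"] == vdep] if "vdep" in table.columns else table
    g1 = sub[sub["cls"] == 1]
    g2 = sub[sub["cls"] == 2]
    if len(g1) == 0 or len(g2) == 0:
        raise StatsError(f"{vdep!r}: both classes must be present to compare")
    rows = []
    for band in bands:
        x, y = g1[band].to_numpy(), g2[band].to_numpy()
        u, p = mann_whitney(x, y)
        ranks = sps.rankdata(np.concatenate([x, y]))
        mr1 = float(ranks[: len(x)].mean())
        mr2 = float(ranks[len(x) :].mean())
        direction = 1 if mr1 > mr2 else (2 if mr2 > mr1 else 0)
        rows.append((vdep, band, len(x), len(y), mr1, mr2, u, p, direction))
    rep = pd.DataFrame(rows, columns=["vdep", "band", "n1", "n2", "mean_rank_1",
                                      "mean_rank_2", "U", "p", "direction"])
    rep["p_holm"] = _holm(rep["p"].to_numpy())
    rep["significant"] = (rep["p_holm"] if holm else rep["p"]) < alpha
    return StatsReport(vdep=vdep, alpha=alpha, table=rep)


def violin_data(table: pd.DataFrame, bands: list[str] | None = None) -> pd.DataFrame:
    """Long-format (band, cls, power) export for violin plots."""
    bands = list(bands) if bands is not None else list(BAND_NAMES)
    long = table.melt(id_vars=["cls"], value_vars=bands,
                      var_name="band", value_name="power")
    return long[["band", "cls", "power"]]
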