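"""Practical identifiability diagnostics on the calibration archive.

Two complementary views of estimation uncertainty:

* Pearson correlations over the top-100 estimates — a strong pairwise
  correlation means the data constrain only a combination of the two
  parameters, not each individually.  Pairs where either parameter's
  estimates are (numerically) unique are reported as r = 0.
* Bootstrap confidence intervals from the best-15 estimates — for each
  parameter, 1000 resampled means; the 95% CI is mean +/- 1.96 sd of the
  bootstrap distribution (a percentile CI is available behind a flag).

A parameter is flagged practically non-identifiable when its top-100
relative spread exceeds a threshold while it is strongly correlated
(|r| > 0.8) with another parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

__all__ = ["correlation_matrix", "bootstrap_ci", "IdentifiabilityReport",
           "build_report"]

_UNIQUE_TOL = 1e-12


def correlation_matrix(estimates: np.ndarray) -> np.ndarray:
    """Pearson correlations between parameter columns of the top estimates.

    ``estimates`` is (m, d) with m >= 3.  Columns with zero variance get
    r = 0 against everything (their estimated value is unique, so no
    linear dependence is expressed).  The diagonal is 1.
    """
    estimates = np.asarray(estimates, float)
    if estimates.ndim != 2 or estimates.shape[0] < 3:
        raise ValueError("need at least 3 estimate vectors")
    m, d = estimates.shape
    sd = estimates.std(axis=0, ddof=1)
    centered = estimates - estimates.mean(axis=0)
    corr = np.zeros((d, d))
    nz = sd > _UNIQUE_TOL * np.maximum(np.abs(estimates).max(axis=0), 1.0)
    idx = np.where(nz)[0]
    if idx.size:
        sub = centered[:, idx] / sd[idx]
        corr[np.ix_(idx, idx)] = np.clip(sub.T @ sub / (m - 1), -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def bootstrap_ci(values: Sequence[float], n_boot: int = 1000,
                 level: float = 0.95, seed: int = 0,
                 percentile: bool = False) -> tuple[float, float]:
    """Confidence interval of the mean by bootstrap resampling.

    Default is the normal-approximation interval mean_boot +/- z * sd_boot
    from ``n_boot`` resampled means; ``percentile=True`` returns the
    empirical quantiles instead.
    """
    values = np.asarray(values, float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    samples = rng.choice(values, size=(n_boot, values.size), replace=True)
    means = samples.mean(axis=1)
    if percentile:
        alpha = (1.0 - level) / 2.0
        return (float(np.quantile(means, alpha)),
                float(np.quantile(means, 1.0 - alpha)))
    z = norm.ppf(0.5 + level / 2.0)
    mu, sd = float(means.mean()), float(means.std(ddof=1))
    return (mu - z * sd, mu + z * sd)


@dataclass
class IdentifiabilityReport:
    names: list[str]
    correlations: np.ndarray          # (d, d)
    ci_low: np.ndarray                # (d,)
    ci_high: np.ndarray
    non_identifiable: list[str]

    def __post_init__(self) -> None:
        c = self.correlations
        if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise ValueError("correlation matrix must be symmetric with "
                             "unit diagonal")
        if np.any(self.ci_low > self.ci_high):
            raise ValueError("CI low must not exceed CI high")

    def to_dict(self) -> dict:
        return {
            "parameters": self.names,
            "correlations": self.correlations.tolist(),
            "ci": {n: [float(lo), float(hi)] for n, lo, hi in
                   zip(self.names, self.ci_low, self.ci_high)},
            "non_identifiable": self.non_identifiable,
        }


def build_report(names: Sequence[str], top_estimates: np.ndarray,
                 best_estimates: np.ndarray, n_boot: int = 1000,
                 level: float = 0.95, seed: int = 0,
                 corr_threshold: float = 0.8,
                 spread_threshold: float = 0.10) -> IdentifiabilityReport:
    """Assemble the identifiability report for one calibration stage.

    ``top_estimates`` (m, d) feeds the correlation matrix; each column of
    ``best_estimates`` (k, d) feeds a bootstrap CI.  Flags are invariant
    to parameter ordering.
    """
    names = list(names)
    corr = correlation_matrix(top_estimates)
    lows, highs = [], []
    for j in range(len(names)):
        lo, hi = bootstrap_ci(best_estimates[:, j], n_boot=n_boot,
                              level=level, seed=seed + j)
        lows.append(lo)
        highs.append(hi)
    top = np.asarray(top_estimates, float)
    mean = np.abs(top.mean(axis=0))
    spread = np.where(mean > 0, top.std(axis=0, ddof=1) / np.maximum(mean, 1e-300),
                      0.0)
    flagged = []
    for j, name in enumerate(names):
        r_others = np.abs(np.delete(corr[j], j)) if len(names) > 1 else np.array([0.0])
        if spread[j] > spread_threshold and r_others.max() > corr_threshold:
            flagged.append(name)
    return IdentifiabilityReport(names=names, correlations=corr,
                                 ci_low=np.array(lows), ci_high=np.array(highs),
                                 non_identifiable=sorted(flagged))
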