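"""Size-distribution fitting and the group statistics used on droplet data.

Diameter distributions are fitted on histogram counts by unweighted least
squares with Gaussian and log-normal count models; Akaike's Information
Criterion (computed from the residual sum of squares) selects the model most
likely to have generated the data, with the Akaike weight reported as the
selection certainty.  Group comparisons use the extra sum-of-squares F-test
on nested Gaussian fits, and non-parametric Kruskal-Wallis + Dunn tests on
raw diameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .config import AnalysisConfig
from .errors import FitError


# ---------------------------------------------------------------------------
# histograms

@dataclass
class Histogram:
    centers: np.ndarray
    counts: np.ndarray
    bin_width: float

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def diameter_histogram(diameters: Sequence[float],
                       cfg: Optional[AnalysisConfig] = None,
                       bin_width: Optional[float] = None) -> Histogram:
    """Histogram droplet diameters at the configured bin width (µm).

    Bin edges are aligned to multiples of the bin width, so e.g. 0.52 and
    0.53 µm share the 0.50-0.55 bin at the default width.
    """
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise ValueError("no diameters to histogram")
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    w = bin_width if bin_width is not None else \
        (cfg or AnalysisConfig()).diameter_bin
    lo = np.floor(d.min() / w) * w
    hi = np.ceil(d.max() / w) * w
    if hi <= lo:
        hi = lo + w
    edges = np.arange(lo, hi + w / 2, w)
    counts, _ = np.histogram(d, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Histogram(centers, counts.astype(float), w)


# ---------------------------------------------------------------------------
# count models

def gaussian_counts(x, amplitude, mean, sd):
    x = np.asarray(x, dtype=float)
    return amplitude * np.exp(-((x - mean) ** 2) / (2.0 * sd ** 2))


def lognormal_counts(x, amplitude, geo_mean, log_sd):
    x = np.asarray(x, dtype=float)
    return amplitude * np.exp(-((np.log(x) - np.log(geo_mean)) ** 2)
                              / (2.0 * log_sd ** 2))


_MODELS = {"gaussian": gaussian_counts, "lognormal": lognormal_counts}


@dataclass
class DistributionFit:
    model: str
    params: Dict[str, float]
    rss: float
    aic: float
    akaike_weight: float
    converged: bool
    n_bins: int

    @property
    def location(self) -> float:
        """The fitted mean (gaussian) or geometric mean (lognormal), µm."""
        return self.params["location"]


@dataclass
class DistributionFitPair:
    gaussian: DistributionFit
    lognormal: DistributionFit
    chosen: str

    @property
    def certainty(self) -> float:
        """Akaike weight of the preferred model."""
        return getattr(self, self.chosen).akaike_weight

    def summary(self) -> str:
        lines = [
            f"{'model':<10}{'RSS':>14}{'AIC':>12}{'weight':>10}"
            f"{'location':>12}{'scale':>10}",
        ]
        for fit in (self.gaussian, self.lognormal):
            mark = " *" if fit.model == self.chosen else "  "
            lines.append(
                f"{fit.model:<10}{fit.rss:>14.4g}{fit.aic:>12.3f}"
                f"{fit.akaike_weight:>10.4f}{fit.params['location']:>12.4f}"
                f"{fit.params['scale']:>10.4f}{mark}")
        lines.append(f"chosen: {self.chosen} "
                     f"(certainty {self.certainty:.4%})")
        return "\n".join(lines)


def _fit_one(model: str, hist: Histogram) -> DistributionFit:
    x, y = hist.centers, hist.counts
    mass = y.sum()
    mean = float((x * y).sum() / mass)
    sd = float(np.sqrt(((x - mean) ** 2 * y).sum() / mass)) or hist.bin_width
    if model == "gaussian":
        p0 = [y.max(), mean, sd]
        bounds = ([0, 0, 1e-6], [np.inf, np.inf, np.inf])
    else:
        log_x = np.log(x)
        lmean = float((log_x * y).sum() / mass)
        lsd = float(np.sqrt(((log_x - lmean) ** 2 * y).sum() / mass)) or 0.1
        p0 = [y.max(), np.exp(lmean), lsd]
        bounds = ([0, 1e-9, 1e-6], [np.inf, np.inf, np.inf])
    try:
        popt, _ = optimize.curve_fit(_MODELS[model], x, y, p0=p0,
                                     bounds=bounds, maxfev=20000)
        converged = True
    except (RuntimeError, ValueError):
        popt, converged = p0, False
    resid = y - _MODELS[model](x, *popt)
    rss = float((resid ** 2).sum())
    n = len(x)
    k = 3
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
    return DistributionFit(model,
                           {"amplitude": float(popt[0]),
                            "location": float(popt[1]),
                            "scale": float(popt[2])},
                           rss, float(aic), np.nan, converged, n)


def akaike_weights(aics: Sequence[float]) -> np.ndarray:
    """Akaike weights exp(-dAIC/2), normalised; equal AICs share weight."""
    aics = np.asarray(aics, dtype=float)
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def fit_distributions(hist: Histogram) -> DistributionFitPair:
    """Fit Gaussian and log-normal count models; choose by Akaike weight.

    Requires at least 5 nonzero bins.  AIC = n ln(RSS/n) + 2k with k the
    parameter count; weights are exp(-dAIC/2) normalised over the two
    models; the chosen model is the one with the larger weight.
    """
    if int((hist.counts > 0).sum()) < 5:
        raise ValueError("need at least 5 nonzero histogram bins")
    fits = {m: _fit_one(m, hist) for m in ("gaussian", "lognormal")}
    ok = {m: f for m, f in fits.items() if f.converged}
    if not ok:
        raise FitError("neither the Gaussian nor the log-normal model "
                       "converged")
    aics = [fits[m].aic if fits[m].converged else np.inf
            for m in ("gaussian", "lognormal")]
    w = akaike_weights(aics)
    fits["gaussian"].akaike_weight = float(w[0])
    fits["lognormal"].akaike_weight = float(w[1])
    chosen = "gaussian" if w[0] >= w[1] else "lognormal"
    return DistributionFitPair(fits["gaussian"], fits["lognormal"], chosen)


# ---------------------------------------------------------------------------
# extra sum-of-squares F-test on Gaussian means

def compare_gaussian_means(hist_a: Histogram, hist_b: Histogram
                           ) -> Tuple[float, float]:
    """Extra sum-of-squares F-test: shared vs separate Gaussian means.

    Both histograms are fitted with Gaussian count models sharing amplitude
    and SD freely per group; the null model constrains the two means to be
    equal.  Returns (F, p)."""
    for h in (hist_a, hist_b):
        if h.counts.sum() <= 0:
            raise ValueError("empty histogram")
    xa, ya = hist_a.centers, hist_a.counts
    xb, yb = hist_b.centers, hist_b.counts
    n = len(xa) + len(xb)

    def resid_sep(p):
        a1, s1, m1, a2, s2, m2 = p
        return np.concatenate([ya - gaussian_counts(xa, a1, m1, abs(s1)),
                               yb - gaussian_counts(xb, a2, m2, abs(s2))])

    def resid_shared(p):
        a1, s1, a2, s2, m = p
        return np.concatenate([ya - gaussian_counts(xa, a1, m, abs(s1)),
                               yb - gaussian_counts(xb, a2, m, abs(s2))])

    def moments(x, y):
        mass = max(y.sum(), 1e-12)
        m = (x * y).sum() / mass
        s = np.sqrt(max(((x - m) ** 2 * y).sum() / mass, 1e-6))
        return m, s

    ma, sa = moments(xa, ya)
    mb, sb = moments(xb, yb)
    sol1 = optimize.least_squares(
        resid_sep, [ya.max(), sa, ma, yb.max(), sb, mb], method="lm",
        max_nfev=20000)
    sol0 = optimize.least_squares(
        resid_shared, [ya.max(), sa, yb.max(), sb, (ma + mb) / 2],
        method="lm", max_nfev=20000)
    rss1 = float((sol1.fun ** 2).sum())
    rss0 = float((sol0.fun ** 2).sum())
    df1 = n - 6
    df0 = n - 5
    if df1 <= 0:
        raise ValueError("not enough histogram bins for the F-test")
    F = max((rss0 - rss1) / (df0 - df1), 0.0) / (rss1 / df1)
    p = float(sps.f.sf(F, df0 - df1, df1))
    return float(F), p


# ---------------------------------------------------------------------------
# non-parametric group tests

def kruskal_wallis(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Kruskal-Wallis H with mid-rank tie correction; p from chi-squared.

    Degenerate all-tied data return H = 0, p = 1 (the 0/0 tie correction is
    guarded)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    if sum(g.size for g in groups) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    H, p = sps.kruskal(*groups)
    return float(H), float(p)


def dunn_posthoc(groups: Sequence[Sequence[float]],
                 labels: Optional[Sequence[str]] = None,
                 adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's multiple-comparison z tests on pooled mid-ranks.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with the
    tie correction T = sum(t^3 - t) / (12 (N - 1)); two-sided p values are
    family-wise adjusted (Bonferroni by default, Sidak optionally).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    if adjust not in ("bonferroni", "sidak", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    labels = list(labels) if labels is not None else \
        [f"group{k}" for k in range(len(groups))]
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    pos = 0
    for g in groups:
        mean_ranks.append(ranks[pos:pos + g.size].mean())
        pos += g.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    T = float(((tie_counts ** 3 - tie_counts).sum())
              / (12.0 * (N - 1))) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - T

    m = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            var = var_base * (1.0 / groups[i].size + 1.0 / groups[j].size)
            if var <= 0:
                z, p = 0.0, 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
                p = 2.0 * sps.norm.sf(abs(z))
            if adjust == "bonferroni":
                p_adj = min(1.0, p * m)
            elif adjust == "sidak":
                p_adj = 1.0 - (1.0 - p) ** m
            else:
                p_adj = p
            rows.append({"group_i": labels[i], "group_j": labels[j],
                         "z": float(z), "p": float(p),
                         "p_adj": float(p_adj)})
    return pd.DataFrame(rows)
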