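"""Statistical layer over tidy per-cell tables.

Covers the analyses used to relate morphometry to differentiation readouts:
ALP-positive fractions with exact binomial confidence intervals, Spearman
rank correlation (exact permutation p for small n), volume–response trend
fits (linear and saturating), and basic group comparisons (t / one-way ANOVA
with Bonferroni-adjusted pairwise follow-up).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "TrendFit",
    "alp_positive_fraction",
    "spearman",
    "fit_volume_response",
    "binned_positive_fraction",
    "group_compare",
]


@dataclass
class TrendFit:
    """A fitted volume→response trend.

    ``params``/``stderr`` are keyed ``slope``/``intercept`` for the linear
    model and ``a``/``k`` for the saturating model r(V) = a·V/(k+V).
    ``predict`` evaluates the fitted curve.
    """

    model: str
    params: dict
    stderr: dict
    n: int
    r_squared: float
    predict: Callable = field(repr=False, default=None)


def alp_positive_fraction(data, cutoff: float | None = None,
                          alpha: float = 0.05) -> dict:
    """Percentage of ALP-positive cells with an exact binomial CI.

    ``data`` is either a table with a binary ``alp_positive`` column, or an
    iterable of per-cell mean stain intensities, scored positive when the
    intensity exceeds ``cutoff``.
    """
    if isinstance(data, pd.DataFrame):
        if "alp_positive" not in data.columns:
            raise ValueError("table lacks an 'alp_positive' column")
        pos = np.asarray(data["alp_positive"], dtype=bool)
    else:
        vals = np.asarray(list(data), dtype=float)
        if cutoff is None:
            raise ValueError("intensity input requires a cutoff")
        pos = vals > cutoff
    n = pos.size
    if n == 0:
        raise ValueError("no cells to score")
    k = int(pos.sum())
    lo, hi = proportion_confint(k, n, alpha=alpha, method="beta")  # Clopper-Pearson
    return {
        "percent": 100.0 * k / n,
        "ci_low_percent": 100.0 * float(lo),
        "ci_high_percent": 100.0 * float(hi),
        "n_positive": k,
        "n": n,
    }


# ---------------------------------------------------------------------------
# Spearman

def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx**2).sum() * (ry**2).sum()))
    if denom == 0:
        return float("nan")
    return float((rx * ry).sum() / denom)


def spearman(x, y, exact_max_n: int = 10) -> dict:
    """Spearman rank correlation with mid-ranks for ties.

    p-value: exact full-permutation enumeration for n ≤ ``exact_max_n``
    (two-sided, fraction of permutations with |ρ| ≥ |ρ_obs|), otherwise the
    usual t approximation with n−2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx = sps.rankdata(x)  # mid-ranks
    ry = sps.rankdata(y)
    rho = _rank_rho(rx, ry)
    if math.isnan(rho):
        return {"rho": float("nan"), "p": float("nan"), "n": n, "method": "degenerate"}

    if n <= exact_max_n:
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = math.sqrt(float((rx_c**2).sum() * (ry_c**2).sum()))
        target = abs(rho) - 1e-12
        count = 0
        total = 0
        chunk = 40320
        it = itertools.permutations(range(n))
        while True:
            block = list(itertools.islice(it, chunk))
            if not block:
                break
            perm = np.asarray(block, dtype=np.intp)
            rhos = (ry_c[perm] @ rx_c) / denom
            count += int(np.count_nonzero(np.abs(rhos) >= target))
            total += perm.shape[0]
        return {"rho": rho, "p": count / total, "n": n, "method": "exact-permutation"}

    if abs(rho) >= 1.0:
        return {"rho": rho, "p": 0.0, "n": n, "method": "t-approximation"}
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
    return {"rho": rho, "p": min(p, 1.0), "n": n, "method": "t-approximation"}


# ---------------------------------------------------------------------------
# trend fits

def fit_volume_response(volumes, responses, model: str = "linear",
                        max_iter: int = 10000) -> TrendFit:
    """Fit the volume→response trend.

    ``linear``: ordinary least squares.  ``saturating``: r(V) = a·V/(k+V)
    by nonlinear least squares, initialized at a = max(r), k = median(V).
    """
    v = np.asarray(volumes, dtype=float)
    r = np.asarray(responses, dtype=float)
    if v.size != r.size:
        raise ValueError("volumes and responses must have equal length")
    if model == "linear":
        if v.size < 3:
            raise ValueError("need n >= 3 for a linear fit")
        fit = sps.linregress(v, r)
        params = {"slope": float(fit.slope), "intercept": float(fit.intercept)}
        stderr = {"slope": float(fit.stderr), "intercept": float(fit.intercept_stderr)}
        pred = lambda x, p=params: p["intercept"] + p["slope"] * np.asarray(x, float)
        ss_res = float(((r - pred(v)) ** 2).sum())
        ss_tot = float(((r - r.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return TrendFit("linear", params, stderr, int(v.size), r2, pred)

    if model == "saturating":
        if v.size < 3:
            raise ValueError("need n >= 3 for a saturating fit")

        def f(x, a, k):
            return a * x / (k + x)

        p0 = (float(r.max()), float(np.median(v)))
        try:
            popt, pcov = optimize.curve_fit(f, v, r, p0=p0, maxfev=max_iter)
        except RuntimeError as err:
            raise RuntimeError(
                f"saturating fit did not converge from p0={p0}: {err}"
            ) from err
        perr = np.sqrt(np.diag(pcov))
        params = {"a": float(popt[0]), "k": float(popt[1])}
        stderr = {"a": float(perr[0]), "k": float(perr[1])}
        pred = lambda x, p=params: f(np.asarray(x, float), p["a"], p["k"])
        ss_res = float(((r - pred(v)) ** 2).sum())
        ss_tot = float(((r - r.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return TrendFit("saturating", params, stderr, int(v.size), r2, pred)

    raise ValueError(f"unknown model {model!r}")


def binned_positive_fraction(volumes, positives, n_bins: int = 8) -> pd.DataFrame:
    """Percent-positive per volume bin (equal-count bins).

    The per-bin summary is how image-level positive fractions arise in
    practice (many cells per field), and is the natural input for the
    saturating trend fit against volume.
    """
    v = np.asarray(volumes, dtype=float)
    pos = np.asarray(positives, dtype=bool)
    if v.size != pos.size or v.size == 0:
        raise ValueError("volumes/positives must be equal-length and non-empty")
    q = np.quantile(v, np.linspace(0, 1, n_bins + 1))
    q[-1] = np.nextafter(q[-1], np.inf)
    idx = np.clip(np.digitize(v, q) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        rows.append({
            "volume_um3": float(v[sel].mean()),
            "percent_positive": 100.0 * float(pos[sel].mean()),
            "n": int(sel.sum()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group comparisons

def group_compare(table: pd.DataFrame, value: str, group: str,
                  test: str = "anova") -> pd.DataFrame:
    """Two-sample t test or one-way ANOVA across groups of a tidy table.

    ANOVA output includes Bonferroni-adjusted pairwise t-test p-values as
    follow-up rows.
    """
    groups = {g: np.asarray(sub[value], dtype=float)
              for g, sub in table.groupby(group)}
    names = list(groups)
    if test == "t":
        if len(names) != 2:
            raise ValueError(f"t test needs exactly 2 groups, got {len(names)}")
        a, b = groups[names[0]], groups[names[1]]
        res = sps.ttest_ind(a, b)
        return pd.DataFrame([{
            "test": "t", "comparison": f"{names[0]} vs {names[1]}",
            "statistic": float(res.statistic), "p": float(res.pvalue),
            "p_adjusted": float(res.pvalue),
        }])
    if test == "anova":
        if len(names) < 2:
            raise ValueError("ANOVA needs at least 2 groups")
        f, p = sps.f_oneway(*groups.values())
        rows = [{"test": "anova", "comparison": "overall",
                 "statistic": float(f), "p": float(p), "p_adjusted": float(p)}]
        pairs = list(itertools.combinations(names, 2))
        for g1, g2 in pairs:
            res = sps.ttest_ind(groups[g1], groups[g2])
            rows.append({
                "test": "pairwise-t", "comparison": f"{g1} vs {g2}",
                "statistic": float(res.statistic), "p": float(res.pvalue),
                "p_adjusted": min(1.0, float(res.pvalue) * len(pairs)),  # Bonferroni
            })
        return pd.DataFrame(rows)
    raise ValueError(f"unknown test {test!r}")
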