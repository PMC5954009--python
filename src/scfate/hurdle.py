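"""Two-part (hurdle) differential-expression test for semi-continuous
single-cell expression data.

A gene's expression across cells is bimodal: a point mass at 0 ("not
detected") and a continuous positive component.  The hurdle model treats
these separately —

* **discrete part**: detection is Bernoulli with per-group probability; the
  likelihood-ratio statistic contrasts per-group detection frequencies
  against the pooled frequency,
* **continuous part**: detected values are normal with per-group means and
  (by default) a shared variance; with the variance profiled out the
  likelihood-ratio statistic is ``n_det * ln(RSS_null / RSS_alt)``.

The parts are orthogonal, so the total statistic is their sum and is
referred to a chi-square with 2 degrees of freedom (1 when the continuous
part is undefined, e.g. one group entirely undetected).  Groups are thus
compared jointly on *frequency of expression* and *mean positive
expression*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix

_EPS = 1e-300


@dataclass
class HurdleTestResult:
    """Per-gene two-group hurdle test outcome."""

    gene: str
    groups: tuple[str, str]
    freq: tuple[float, float]          # detection frequency per group
    pos_mean: tuple[float, float]      # mean of detected values per group
    pos_sd: float                      # pooled sd of detected values
    lrt_discrete: float
    lrt_continuous: float
    lrt_total: float
    df: int
    p_value: float
    status: str                        # ok | discrete_only | undefined
    p_adjusted: float | None = None


def _bernoulli_ll(k: int, n: int) -> float:
    """Maximized Bernoulli log-likelihood for k successes of n."""
    if n == 0:
        return 0.0
    p = k / n
    ll = 0.0
    if k > 0:
        ll += k * np.log(p)
    if n - k > 0:
        ll += (n - k) * np.log(1.0 - p)
    return ll


def fit_hurdle_two_group(
    values_a, values_b, gene: str = "", groups: tuple[str, str] = ("A", "B"),
    equal_var: bool = True,
) -> HurdleTestResult:
    """Two-group hurdle likelihood-ratio test on raw expression vectors.

    Zeros are nondetects.  ``equal_var=False`` switches the continuous part
    to per-group variances (each group then needs >= 2 detected values for
    that part to be defined).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite expression values")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("expression values must be nonnegative")

    det_a, det_b = a[a > 0], b[b > 0]
    ka, na = det_a.size, a.size
    kb, nb = det_b.size, b.size
    freq = (ka / na, kb / nb)

    if ka == 0 and kb == 0:
        return HurdleTestResult(
            gene, groups, freq, (np.nan, np.nan), np.nan,
            0.0, 0.0, 0.0, 0, np.nan, "undefined",
        )

    # discrete part
    lrt_disc = 2.0 * (
        _bernoulli_ll(ka, na) + _bernoulli_ll(kb, nb)
        - _bernoulli_ll(ka + kb, na + nb)
    )
    lrt_disc = max(lrt_disc, 0.0)

    pos_mean = (
        det_a.mean() if ka else np.nan,
        det_b.mean() if kb else np.nan,
    )
    pooled = np.concatenate([det_a, det_b])
    n_det = pooled.size
    pos_sd = float(pooled.std(ddof=1)) if n_det > 1 else np.nan

    min_per_group = 1 if equal_var else 2
    continuous_ok = ka >= min_per_group and kb >= min_per_group and n_det >= 3
    if continuous_ok:
        rss_alt_a = float(((det_a - det_a.mean()) ** 2).sum())
        rss_alt_b = float(((det_b - det_b.mean()) ** 2).sum())
        rss_null = float(((pooled - pooled.mean()) ** 2).sum())
        if equal_var:
            rss_alt = rss_alt_a + rss_alt_b
            if rss_alt <= 0.0:
                lrt_cont = 0.0 if rss_null <= 0.0 else np.inf
            else:
                lrt_cont = n_det * np.log(rss_null / rss_alt)
        else:
            if rss_alt_a <= 0.0 or rss_alt_b <= 0.0 or rss_null <= 0.0:
                lrt_cont = 0.0 if rss_null <= max(rss_alt_a + rss_alt_b, 0.0) \
                    else np.inf
            else:
                lrt_cont = (
                    n_det * np.log(rss_null / n_det)
                    - ka * np.log(rss_alt_a / ka)
                    - kb * np.log(rss_alt_b / kb)
                )
        lrt_cont = max(float(lrt_cont), 0.0)
        df, status = 2, "ok"
    else:
        lrt_cont = 0.0
        df, status = 1, "discrete_only"

    lrt_total = lrt_disc + lrt_cont
    p = float(stats.chi2.sf(lrt_total, df)) if np.isfinite(lrt_total) else 0.0
    return HurdleTestResult(
        gene, groups, freq, pos_mean, pos_sd,
        float(lrt_disc), float(lrt_cont), float(lrt_total), df, p, status,
    )


def test_all_genes(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    group_field: str,
    group_a: str,
    group_b: str,
    adjust: str = "none",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Run the hurdle test for every gene; returns a tidy results table.

    ``adjust`` is ``"none"`` or ``"benjamini_hochberg"``; adjustment is
    applied across genes with a defined p-value only.
    """
    if adjust not in ("none", "benjamini_hochberg"):
        raise ValueError(f"unknown adjustment: {adjust!r}")
    if group_field not in annotation.columns:
        raise KeyError(f"group field {group_field!r} missing from annotation")
    labels = annotation[group_field]
    for g in (group_a, group_b):
        if g not in set(labels):
            raise ValueError(f"unknown group label: {g!r}")
    cells_a = annotation.index[labels == group_a]
    cells_b = annotation.index[labels == group_b]

    rows = []
    for gene in matrix.gene_ids:
        res = fit_hurdle_two_group(
            matrix.values.loc[cells_a, gene],
            matrix.values.loc[cells_b, gene],
            gene=gene, groups=(group_a, group_b), equal_var=equal_var,
        )
        rows.append(res)

    table = pd.DataFrame(
        {
            "gene": [r.gene for r in rows],
            "freq_a": [r.freq[0] for r in rows],
            "freq_b": [r.freq[1] for r in rows],
            "pos_mean_a": [r.pos_mean[0] for r in rows],
            "pos_mean_b": [r.pos_mean[1] for r in rows],
            "pos_sd": [r.pos_sd for r in rows],
            "lrt_discrete": [r.lrt_discrete for r in rows],
            "lrt_continuous": [r.lrt_continuous for r in rows],
            "lrt_total": [r.lrt_total for r in rows],
            "df": [r.df for r in rows],
            "p_value": [r.p_value for r in rows],
            "status": [r.status for r in rows],
        }
    ).set_index("gene")

    table["p_adjusted"] = np.nan
    if adjust == "benjamini_hochberg":
        ok = table["status"] != "undefined"
        if ok.any():
            table.loc[ok, "p_adjusted"] = multipletests(
                table.loc[ok, "p_value"], method="fdr_bh"
            )[1]
    return table


def summarize_violin(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    genes: list[str],
    group_field: str,
    grid_points: int = 128,
) -> list[dict]:
    """Per-gene, per-group raw values plus a kernel-density summary.

    Returns one record per (gene, group) with the raw values, a fixed
    evaluation grid and the Gaussian-KDE density (which integrates to ~1
    over the grid).  Degenerate groups (n == 1 or constant values) carry a
    flag and no density.
    """
    missing = [g for g in genes if g not in matrix.values.columns]
    if missing:
        raise KeyError(f"genes not in matrix: {missing}")
    records: list[dict] = []
    for gene in genes:
        for group, sub in annotation.groupby(group_field, sort=False):
            vals = matrix.values.loc[sub.index, gene].to_numpy()
            rec: dict = {"gene": gene, "group": group, "values": vals,
                         "flag": "ok", "grid": None, "density": None}
            if vals.size == 1:
                rec["flag"] = "single_point"
            elif np.ptp(vals) == 0:
                rec["flag"] = "degenerate_constant"
            else:
                kde = stats.gaussian_kde(vals)
                span = np.ptp(vals)
                lo, hi = vals.min() - 0.5 * span, vals.max() + 0.5 * span
                grid = np.linspace(lo, hi, grid_points)
                rec["grid"] = grid
                rec["density"] = kde(grid)
            records.append(rec)
    return records
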