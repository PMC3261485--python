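"""Regional summaries, Welch comparisons and the FA-vs-GM-fraction regression.

The unit of analysis is the subject-level tissue centroid: one (MD, FA)
pair per tissue per subject per region, the mean over that subject's
retained voxels.  Voxels within a subject are not independent, so pooling
them across subjects would overstate the effective sample size; averaging
to one value per subject first keeps the between-region t-tests honest and
naturally produces unequal sample sizes when a tissue cluster is missing
in some subjects.

Between-region comparisons use Welch's two-sample t-test (unequal
variances, Welch-Satterthwaite degrees of freedom) with an optional
Bonferroni correction over the full family of comparisons (by default
m = 18: 3 region pairs x 3 tissues x 2 metrics).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reference import REGIONS, TISSUES

#: Subject-level tissue centroids: tissue -> (md, fa, n_voxels).
SubjectCentroids = dict[str, tuple[float, float, int]]


@dataclass
class WelchResult:
    """Welch two-sample t-test: statistic, fractional df, two-sided p."""

    t: float
    df: float
    p: float


@dataclass
class RegressionResult:
    """Ordinary least-squares line fit with coefficient of determination."""

    slope: float
    intercept: float
    r_squared: float
    n: int


def welch_t_test(a, b) -> WelchResult:
    """Welch's two-sample t-test for unequal sample sizes and variances.

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b), with
    Welch-Satterthwaite degrees of freedom and a two-sided p-value from the
    t distribution.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs at least 2 observations")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va + vb == 0:
        raise ValueError("zero variance in both samples")
    sa, sb = va / na, vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(p))


def bonferroni(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni correction: corrected p = min(1, m * p)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, m * p)


def regress_fa_on_gm(fa, gm_percent) -> RegressionResult:
    """OLS regression of regional WM FA on grey-matter area percentage."""
    fa = np.asarray(fa, dtype=float)
    gm = np.asarray(gm_percent, dtype=float)
    if len(fa) != len(gm):
        raise ValueError("fa and gm_percent must have equal length")
    if len(fa) < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(gm) == 0:
        raise ValueError("constant predictor")
    fit = stats.linregress(gm, fa)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=len(fa),
    )


def summarize(subjects: list[SubjectCentroids], region: str) -> pd.DataFrame:
    """Per-tissue mean and SD of subject-level centroids for one region.

    Returns rows (region, tissue, md_mean, md_sd, fa_mean, fa_sd,
    n_subjects, n_voxels).  A tissue with no subject contributing any
    retained voxel is omitted.  SDs use ddof = 1 and are reported as 0 for a
    single subject.
    """
    if not subjects:
        raise ValueError("no subjects for region")
    rows = []
    for tissue in TISSUES:
        vals = [s[tissue] for s in subjects if tissue in s]
        if not vals:
            continue
        md = np.array([v[0] for v in vals])
        fa = np.array([v[1] for v in vals])
        nvox = int(sum(v[2] for v in vals))
        rows.append(
            {
                "region": region,
                "tissue": tissue,
                "md_mean": md.mean(),
                "md_sd": md.std(ddof=1) if len(md) > 1 else 0.0,
                "fa_mean": fa.mean(),
                "fa_sd": fa.std(ddof=1) if len(fa) > 1 else 0.0,
                "n_subjects": len(vals),
                "n_voxels": nvox,
            }
        )
    return pd.DataFrame(rows)


def compare_regions(
    centroids_by_region: dict[str, list[SubjectCentroids]],
    m_tests: int = 18,
    alpha: float = 0.05,
    raw_alpha: float = 0.001,
) -> pd.DataFrame:
    """All pairwise between-region Welch comparisons, per tissue and metric.

    Subjects missing a tissue (collapsed cluster) are dropped from that
    comparison.  Returns one row per (tissue, metric, region pair) with the
    t statistic, Welch df, raw and Bonferroni-corrected p, and significance
    flags at the uncorrected strict threshold (default 0.001) and at the
    corrected ``alpha``.
    """
    regions = [r for r in REGIONS if r in centroids_by_region]
    if len(regions) < 2:
        raise ValueError("need at least two regions to compare")
    rows = []
    for tissue in TISSUES:
        for metric_idx, metric in enumerate(("MD", "FA")):
            for ra, rb in itertools.combinations(regions, 2):
                a = [s[tissue][metric_idx] for s in centroids_by_region[ra] if tissue in s]
                b = [s[tissue][metric_idx] for s in centroids_by_region[rb] if tissue in s]
                if len(a) < 2 or len(b) < 2:
                    continue
                res = welch_t_test(a, b)
                rows.append(
                    {
                        "tissue": tissue,
                        "metric": metric,
                        "region_a": ra,
                        "region_b": rb,
                        "n_a": len(a),
                        "n_b": len(b),
                        "t": res.t,
                        "df": res.df,
                        "p": res.p,
                    }
                )
    df = pd.DataFrame(rows)
    if len(df):
        m = max(m_tests, len(df))
        df["p_bonferroni"] = bonferroni(df["p"].to_numpy(), m=m)
        df["sig_raw"] = df["p"] < raw_alpha
        df["sig_raw_05"] = df["p"] < alpha
        df["sig_corrected"] = df["p_bonferroni"] < alpha
    return df
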