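"""Per-CpG differential methylation testing with overdispersion correction.

The model at each CpG is a binomial logistic regression of the methylated
proportion on a two-level group indicator, with the sample's coverage as
the number of trials. With a single binary covariate the maximum
likelihood fit is closed-form — the coverage-weighted pooled proportion
within each group — so the likelihood-ratio (deviance) statistic can be
evaluated vectorized across all sites.

Overdispersion (extra-binomial scatter between replicate animals) is
absorbed by scaling the deviance statistic with the Pearson dispersion
of the full model,

    phi = max(1, sum(r_i^2) / (n_samples - 2)),

and referring (D_null - D_full) / phi to a chi-square with 1 degree of
freedom. The clamp at 1 means the correction is never applied in the
anti-conservative direction. Significance calling uses Benjamini-
Hochberg q-values with a strict q < threshold rule and no minimum-
difference filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from rrbsdiff.io import MethylationMatrix

logger = logging.getLogger(__name__)

_EPS = 1e-8  # fitted-proportion clip inside deviance evaluation


@dataclass
class ComparisonSpec:
    """A two-group comparison: which samples, and the filtering thresholds.

    ``min_samples_per_group`` of None requires every listed sample to be
    covered (the strict rule); the relaxed inclusion rule of the pooled
    analysis corresponds to 4 with six samples per group.
    """

    name: str
    group_a: list[str]  # reference (e.g. UNT)
    group_b: list[str]  # treated
    min_coverage: int = 10
    min_samples_per_group: int | None = None
    q_threshold: float = 0.01

    def __post_init__(self) -> None:
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError("each group needs at least 2 samples")
        if not 0.0 < self.q_threshold < 1.0:
            raise ValueError("q_threshold must be in (0, 1)")
        if set(self.group_a) & set(self.group_b):
            raise ValueError("groups share samples")

    def required_per_group(self) -> tuple[int, int]:
        if self.min_samples_per_group is None:
            return len(self.group_a), len(self.group_b)
        return (
            min(self.min_samples_per_group, len(self.group_a)),
            min(self.min_samples_per_group, len(self.group_b)),
        )


@dataclass
class DispersionEstimate:
    raw_phi: float
    df: int

    @property
    def phi(self) -> float:
        """Dispersion as applied: clamped below at 1."""
        return max(1.0, self.raw_phi)


def filter_by_coverage(
    matrix: MethylationMatrix, spec: ComparisonSpec
) -> MethylationMatrix:
    """Apply the per-cell coverage floor and the per-group presence rule.

    A cell survives iff coverage >= min_coverage (a read depth of 9 is
    dropped, 10 kept); a site survives iff each group keeps at least the
    required number of cells.
    """
    sub = matrix.select_samples(list(spec.group_a) + list(spec.group_b))
    with np.errstate(invalid="ignore"):
        low = sub.cov < spec.min_coverage
    sub.meth[low] = np.nan
    sub.cov[low] = np.nan

    na = len(spec.group_a)
    need_a, need_b = spec.required_per_group()
    kept_a = (~np.isnan(sub.cov[:, :na])).sum(axis=1)
    kept_b = (~np.isnan(sub.cov[:, na:])).sum(axis=1)
    keep = (kept_a >= need_a) & (kept_b >= need_b)
    logger.info(
        "%s: coverage filter retained %d / %d sites",
        spec.name, int(keep.sum()), matrix.n_sites,
    )
    return sub.select_sites(keep)


def _binom_loglik(m: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Sum over samples of the binomial kernel m*log p + (n-m)*log(1-p).

    NaN cells (missing samples) contribute 0. Constant binomial
    coefficients cancel in every deviance difference and are omitted.
    """
    p = np.clip(p, _EPS, 1.0 - _EPS)
    with np.errstate(invalid="ignore"):
        terms = m * np.log(p) + (n - m) * np.log1p(-p)
    return np.nansum(terms, axis=-1)


def _comparison_arrays(matrix: MethylationMatrix, spec: ComparisonSpec):
    na = len(spec.group_a)
    ma, ca = matrix.meth[:, :na], matrix.cov[:, :na]
    mb, cb = matrix.meth[:, na:], matrix.cov[:, na:]
    return ma, ca, mb, cb


def test_comparison(matrix: MethylationMatrix, spec: ComparisonSpec) -> pd.DataFrame:
    """Vectorized per-site deviance test over a coverage-filtered matrix.

    Returns one row per tested site with meth_diff (percentage points,
    group_b - group_a, coverage-weighted pooled), the scaled deviance
    statistic, p, and the dispersion columns raw_phi / phi. Sites where a
    group has zero total coverage are excluded (logged).
    """
    ma, ca, mb, cb = _comparison_arrays(matrix, spec)

    Ma, Ca = np.nansum(ma, axis=1), np.nansum(ca, axis=1)
    Mb, Cb = np.nansum(mb, axis=1), np.nansum(cb, axis=1)
    ok = (Ca > 0) & (Cb > 0)
    if not ok.all():
        logger.info(
            "%s: excluded %d sites with zero group coverage",
            spec.name, int((~ok).sum()),
        )

    pa = np.where(Ca > 0, Ma / np.maximum(Ca, 1), np.nan)
    pb = np.where(Cb > 0, Mb / np.maximum(Cb, 1), np.nan)
    p0 = (Ma + Mb) / np.maximum(Ca + Cb, 1)

    # log-likelihoods under the saturated, full (per-group) and null fits
    with np.errstate(invalid="ignore", divide="ignore"):
        phat_a, phat_b = ma / ca, mb / cb
    ll_sat = _binom_loglik(ma, ca, phat_a) + _binom_loglik(mb, cb, phat_b)
    ll_full = _binom_loglik(ma, ca, pa[:, None]) + _binom_loglik(mb, cb, pb[:, None])
    ll_null = _binom_loglik(ma, ca, p0[:, None]) + _binom_loglik(mb, cb, p0[:, None])

    d_full = np.maximum(2.0 * (ll_sat - ll_full), 0.0)
    d_null = np.maximum(2.0 * (ll_sat - ll_null), 0.0)
    lr = np.maximum(d_null - d_full, 0.0)

    # Pearson dispersion of the full model
    pac = np.clip(pa, _EPS, 1 - _EPS)[:, None]
    pbc = np.clip(pb, _EPS, 1 - _EPS)[:, None]
    with np.errstate(invalid="ignore"):
        r2 = np.nansum((ma - ca * pac) ** 2 / (ca * pac * (1 - pac)), axis=1)
        r2 += np.nansum((mb - cb * pbc) ** 2 / (cb * pbc * (1 - pbc)), axis=1)
    k = (~np.isnan(ca)).sum(axis=1) + (~np.isnan(cb)).sum(axis=1)
    df = k - 2
    raw_phi = np.where(df > 0, r2 / np.maximum(df, 1), 1.0)
    phi = np.maximum(raw_phi, 1.0)

    statistic = lr / phi
    p = stats.chi2.sf(statistic, df=1)

    out = pd.DataFrame(
        {
            "chrom": matrix.sites["chrom"],
            "pos": matrix.sites["pos"],
            "strand": matrix.sites["strand"],
            "meth_diff": 100.0 * (pb - pa),
            "statistic": statistic,
            "p": p,
            "raw_phi": raw_phi,
            "phi": phi,
            "df": df,
        }
    )
    return out.loc[ok].reset_index(drop=True)


def pooled_difference(
    counts_a: list[tuple[int, int]], counts_b: list[tuple[int, int]]
) -> float:
    """Coverage-weighted pooled methylation difference in percentage points.

    Counts are (methylated, coverage) pairs; the result is
    100 * (sum M_b / sum C_b - sum M_a / sum C_a).
    """
    ma, ca = (sum(x) for x in zip(*counts_a))
    mb, cb = (sum(x) for x in zip(*counts_b))
    if ca == 0 or cb == 0:
        raise ValueError("zero total coverage in a group; difference undefined")
    return 100.0 * (mb / cb - ma / ca)


def test_site(
    counts_a: list[tuple[int, int]], counts_b: list[tuple[int, int]]
) -> tuple[float, float, DispersionEstimate]:
    """Single-site convenience wrapper around :func:`test_comparison`.

    Returns (statistic, p, DispersionEstimate) for one CpG with counts
    given as (methylated, coverage) pairs per sample.
    """
    samples_a = [f"a{i}" for i in range(len(counts_a))]
    samples_b = [f"b{i}" for i in range(len(counts_b))]
    meth = np.array([[m for m, _ in counts_a] + [m for m, _ in counts_b]], float)
    cov = np.array([[c for _, c in counts_a] + [c for _, c in counts_b]], float)
    matrix = MethylationMatrix(
        sites=pd.DataFrame({"chrom": ["chr1"], "pos": [0], "strand": ["+"]}),
        samples=samples_a + samples_b,
        meth=meth,
        cov=cov,
    )
    spec = ComparisonSpec(
        name="site", group_a=samples_a, group_b=samples_b,
        min_coverage=0, min_samples_per_group=0,
    )
    row = test_comparison(matrix, spec).iloc[0]
    est = DispersionEstimate(raw_phi=float(row["raw_phi"]), df=int(row["df"]))
    return float(row["statistic"]), float(row["p"]), est


def adjust_and_call(records: pd.DataFrame, spec: ComparisonSpec) -> pd.DataFrame:
    """Benjamini-Hochberg adjustment and DMS calling over all tested sites.

    Adds q, direction (hyper when meth_diff > 0, hypo otherwise) and the
    boolean is_dms: q strictly below the threshold, excluding zero-
    difference sites. Output sorted by (chrom, pos).
    """
    records = records.copy()
    if len(records) == 0:
        records["q"] = pd.Series(dtype=float)
        records["direction"] = pd.Series(dtype=object)
        records["is_dms"] = pd.Series(dtype=bool)
        return records
    records["q"] = multipletests(records["p"].to_numpy(), method="fdr_bh")[1]
    records["direction"] = np.where(records["meth_diff"] > 0, "hyper", "hypo")
    records["is_dms"] = (records["q"] < spec.q_threshold) & (records["meth_diff"] != 0)
    return (
        records.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    )


def call_dms(matrix: MethylationMatrix, spec: ComparisonSpec) -> pd.DataFrame:
    """Full per-comparison chain: filter -> test -> adjust/call."""
    filtered = filter_by_coverage(matrix, spec)
    tested = test_comparison(filtered, spec)
    return adjust_and_call(tested, spec)
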