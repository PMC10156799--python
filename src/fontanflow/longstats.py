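"""Longitudinal nonparametric statistics for regional hemodynamic metrics.

The study design: each subject has a baseline and a follow-up scan; every
regional metric change is annualized (divided by the follow-up interval in
years).  Groups with unequal vs equal baseline IVC flow distribution are
compared by Wilcoxon rank-sum; within-subject changes are tested by
Wilcoxon signed-rank; associations by Spearman rank correlation (with a
permutation p-value) followed by ordinary least-squares regression; and a
Monte-Carlo post-hoc power is attached to each test.

Small samples (the cohort is ~10 subjects) make asymptotic null
distributions dubious, so the rank tests use exact enumeration whenever
scipy can (no ties, n small) and fall back to the tie-corrected normal
approximation otherwise.  No multiple-testing correction is applied; the
number of tests performed is reported alongside the results.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05
EXACT_RANKSUM_MAX_N = 10     # per group
EXACT_SIGNRANK_MAX_N = 15
EXACT_PERMUTATION_MAX_N = 8  # exact Spearman permutation p
N_PERMUTATIONS = 100_000


@dataclass
class StatResult:
    """One test: statistic, two-sided p, effect descriptor, and power."""

    statistic: float
    p_value: float
    effect: float | None = None
    effect_name: str = ""
    n: int | tuple = 0
    method: str = ""
    achieved_power: float | None = None
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class LongitudinalRecord:
    """Per-subject regional metrics at both timepoints.

    ``baseline`` / ``followup`` map (region, metric) -> value;
    ``followup_years`` must exceed 0.5 (the study requires more than six
    months between valid scans).
    """

    subject_id: str
    followup_years: float
    baseline: dict
    followup: dict
    fd_ivc_baseline: float | None = None
    fd_svc_baseline: float | None = None

    def __post_init__(self) -> None:
        if self.followup_years <= 0.5:
            raise ValueError("follow-up interval must exceed 0.5 years")
        if set(self.baseline) != set(self.followup):
            raise ValueError("baseline and follow-up must cover the same regions/metrics")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def annualized_delta(record: LongitudinalRecord, metric: str, region: str) -> float:
    """(follow-up - baseline) / follow-up years for one regional metric."""
    key = (region, metric)
    if key not in record.baseline:
        raise KeyError(f"{key} missing from record {record.subject_id}")
    return (record.followup[key] - record.baseline[key]) / record.followup_years


def group_compare(values_a, values_b) -> StatResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test between two groups.

    Exact enumeration null when both groups have <= 10 observations and the
    pooled data has no ties; tie-corrected normal approximation otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    flags = []
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        flags.append("degenerate: all observations tied")
        return StatResult(statistic=np.nan, p_value=1.0, effect=0.0,
                          effect_name="median_diff", n=(len(a), len(b)),
                          method="ranksum", flags=flags)
    ties = len(np.unique(pooled)) < len(pooled)
    exact = (not ties and len(a) <= EXACT_RANKSUM_MAX_N and len(b) <= EXACT_RANKSUM_MAX_N)
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return StatResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      effect=float(np.median(a) - np.median(b)),
                      effect_name="median_diff", n=(len(a), len(b)),
                      method="ranksum_exact" if exact else "ranksum_normal",
                      flags=flags)


def paired_change_test(deltas) -> StatResult:
    """Two-sided Wilcoxon signed-rank test of median change = 0.

    Zero deltas are dropped (Wilcoxon's original treatment); the exact null
    is used for up to 15 nonzero deltas without tied magnitudes.
    """
    d = np.asarray(deltas, dtype=float)
    nz = d[d != 0]
    if len(nz) == 0:
        raise ValueError("all deltas are zero; signed-rank test undefined")
    flags = []
    if len(nz) < len(d):
        flags.append(f"{len(d) - len(nz)} zero deltas dropped")
    ties = len(np.unique(np.abs(nz))) < len(nz)
    exact = not ties and len(nz) <= EXACT_SIGNRANK_MAX_N
    res = stats.wilcoxon(nz, zero_method="wilcox", alternative="two-sided",
                         method="exact" if exact else "approx")
    return StatResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      effect=float(np.median(nz)), effect_name="median_delta",
                      n=len(nz), method="signrank_exact" if exact else "signrank_normal",
                      flags=flags)


def _spearman_rho(rx, ry):
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum())
    return float((rxc * ryc).sum() / denom)


@functools.lru_cache(maxsize=4)
def _all_permutations(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))))


def _perm_rhos(rx, ry, perms):
    """Spearman rho for many permutations of rx at once (rows of perms)."""
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum())
    return (rxc[perms] @ ryc) / denom


def rank_correlation(x, y, seed: int = 0,
                     n_permutations: int = N_PERMUTATIONS) -> StatResult:
    """Spearman rank correlation with a permutation p-value.

    rho uses average ranks on ties.  The p-value is the two-sided
    permutation probability of |rho| at least as large as observed: exact
    over all n! pairings for n <= 8, otherwise ``n_permutations`` seeded
    random permutations (with the observed pairing counted, the standard
    add-one estimator).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rank correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _spearman_rho(rx, ry)

    n = len(x)
    if n <= EXACT_PERMUTATION_MAX_N:
        perms = _all_permutations(n)
        rhos = _perm_rhos(rx, ry, perms)
        p = float((np.abs(rhos) >= abs(rho) - 1e-12).mean())
        method = "spearman_exact_perm"
    else:
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.tile(np.arange(n), (n_permutations, 1)), axis=1)
        rhos = _perm_rhos(rx, ry, perms)
        hits = 1 + int((np.abs(rhos) >= abs(rho) - 1e-12).sum())
        p = hits / (n_permutations + 1)
        method = "spearman_mc_perm"
    return StatResult(statistic=rho, p_value=p, effect=rho, effect_name="rho",
                      n=n, method=method)


def linear_fit(x, y) -> StatResult:
    """Ordinary least squares y = a + b*x with R^2 and two-sided slope p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    out = StatResult(statistic=float(res.slope), p_value=float(res.pvalue),
                     effect=float(res.rvalue ** 2), effect_name="r_squared",
                     n=len(x), method="ols")
    out.flags.append(f"intercept={res.intercept:.6g}")
    return out


def posthoc_power(test: str, n_a: int, n_b: int | None = None,
                  mean_a: float = 0.0, sd_a: float = 1.0,
                  mean_b: float = 0.0, sd_b: float = 1.0,
                  rho: float = 0.0, alpha: float = ALPHA,
                  n_sims: int = 2000, seed: int = 0) -> float:
    """Monte-Carlo post-hoc power with plug-in normal effect models.

    test: ``"ranksum"`` (two independent normals with the observed moments),
    ``"signrank"`` (one normal sample of deltas tested against zero), or
    ``"spearman"`` (bivariate normal with the observed rho).  Returns the
    fraction of ``n_sims`` simulated datasets rejected at ``alpha``.
    """
    if n_sims < 1000:
        raise ValueError("n_sims must be >= 1000 for a stable power estimate")
    rng = np.random.default_rng(seed)
    if test == "ranksum":
        # continuous draws are tie-free a.s., so the method choice below
        # matches group_compare on every simulated dataset
        a = rng.normal(mean_a, sd_a, (n_sims, n_a))
        b = rng.normal(mean_b, sd_b, (n_sims, n_b))
        exact = n_a <= EXACT_RANKSUM_MAX_N and n_b <= EXACT_RANKSUM_MAX_N
        ps = stats.mannwhitneyu(a, b, alternative="two-sided",
                                method="exact" if exact else "asymptotic",
                                axis=1).pvalue
    elif test == "signrank":
        d = rng.normal(mean_a, sd_a, (n_sims, n_a))
        exact = n_a <= EXACT_SIGNRANK_MAX_N
        ps = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                            method="exact" if exact else "approx", axis=1).pvalue
    elif test == "spearman":
        cov = [[1.0, rho], [rho, 1.0]]
        ps = np.empty(n_sims)
        for i in range(n_sims):
            xy = rng.multivariate_normal([0, 0], cov, size=n_a)
            # fewer permutations per simulated dataset keep the power
            # simulation tractable; the p granularity (1/2000) is far below
            # the Monte-Carlo error of the power estimate itself
            ps[i] = rank_correlation(xy[:, 0], xy[:, 1],
                                     seed=int(rng.integers(2 ** 31 - 1)),
                                     n_permutations=2000).p_value
    else:
        raise ValueError(f"unknown test {test!r}")
    return float((ps <= alpha).mean())


# ---------------------------------------------------------------------------
# cohort-level pipeline
# ---------------------------------------------------------------------------

def records_from_table(df: pd.DataFrame):
    """Long-format table -> LongitudinalRecord list.

    Expects columns: subject, region, metric, timepoint (baseline/followup),
    value, followup_years, and optionally fd_ivc_baseline.
    """
    records = []
    for subject, g in df.groupby("subject"):
        years = float(g["followup_years"].iloc[0])
        fd = float(g["fd_ivc_baseline"].iloc[0]) if "fd_ivc_baseline" in g else None
        base, follow = {}, {}
        for _, row in g.iterrows():
            key = (row["region"], row["metric"])
            (base if row["timepoint"] == "baseline" else follow)[key] = float(row["value"])
        records.append(LongitudinalRecord(subject_id=str(subject), followup_years=years,
                                          baseline=base, followup=follow,
                                          fd_ivc_baseline=fd))
    return records


def is_unequal_fd(fraction_lpa: float) -> bool:
    """Unequal flow distribution: < 30% or > 70% to the LPA (strict)."""
    return fraction_lpa < 0.30 or fraction_lpa > 0.70


def run_longitudinal_analysis(df: pd.DataFrame, seed: int = 0,
                              power_sims: int = 2000) -> pd.DataFrame:
    """The full statistics stage on a long-format metrics table.

    For every (region, metric): the signed-rank test of the annualized
    deltas; the rank-sum comparison of deltas between unequal- and
    equal-flow-distribution groups (IVC baseline); and, per caval vein, the
    Spearman correlation and OLS fit of annualized EL changes against
    annualized peak-velocity changes.  Each test row carries a Monte-Carlo
    post-hoc power at the observed effect size.
    """
    rng = np.random.default_rng(seed)
    records = records_from_table(df)
    regions = sorted({r for rec in records for (r, _) in rec.baseline})
    metrics = sorted({m for rec in records for (_, m) in rec.baseline})
    rows = []

    def _power_seed():
        return int(rng.integers(2 ** 31 - 1))

    for region in regions:
        for metric in metrics:
            deltas = np.array([annualized_delta(rec, metric, region) for rec in records])
            if np.all(deltas == 0):
                continue
            sr = paired_change_test(deltas)
            sr.achieved_power = posthoc_power(
                "signrank", n_a=len(deltas), mean_a=float(np.mean(deltas)),
                sd_a=float(np.std(deltas, ddof=1)), n_sims=power_sims, seed=_power_seed())
            rows.append({"analysis": "change_from_baseline", "region": region,
                         "metric": metric, **_result_row(sr)})

            if any(rec.fd_ivc_baseline is not None for rec in records):
                unequal = [d for d, rec in zip(deltas, records)
                           if is_unequal_fd(rec.fd_ivc_baseline)]
                equal = [d for d, rec in zip(deltas, records)
                         if not is_unequal_fd(rec.fd_ivc_baseline)]
                if len(unequal) >= 2 and len(equal) >= 2:
                    gc = group_compare(unequal, equal)
                    gc.achieved_power = posthoc_power(
                        "ranksum", n_a=len(unequal), n_b=len(equal),
                        mean_a=float(np.mean(unequal)), sd_a=float(np.std(unequal, ddof=1)),
                        mean_b=float(np.mean(equal)), sd_b=float(np.std(equal, ddof=1)),
                        n_sims=power_sims, seed=_power_seed())
                    rows.append({"analysis": "unequal_vs_equal_fd", "region": region,
                                 "metric": metric, **_result_row(gc)})

    # EL changes vs peak-velocity changes in the caval veins
    for el_metric in ("el_tot", "el_mean"):
        if el_metric not in metrics or "peak_velocity" not in metrics:
            continue
        combined_x, combined_y = [], []
        for region in ("IVC", "SVC"):
            if region not in regions:
                continue
            dv = np.array([annualized_delta(r, "peak_velocity", region) for r in records])
            de = np.array([annualized_delta(r, el_metric, region) for r in records])
            combined_x.append(dv)
            combined_y.append(de)
            rc = rank_correlation(dv, de, seed=_power_seed())
            rc.achieved_power = posthoc_power(
                "spearman", n_a=len(dv), rho=rc.statistic,
                n_sims=max(1000, power_sims // 2), seed=_power_seed())
            rows.append({"analysis": f"corr_d{el_metric}_vs_dpeak", "region": region,
                         "metric": el_metric, **_result_row(rc)})
        if combined_x:
            xx = np.concatenate(combined_x)
            yy = np.concatenate(combined_y)
            lf = linear_fit(xx, yy)
            rows.append({"analysis": f"ols_d{el_metric}_vs_dpeak", "region": "IVC+SVC",
                         "metric": el_metric, **_result_row(lf)})

    out = pd.DataFrame(rows)
    out.attrs["n_tests"] = len(out)           # no multiple-testing correction
    out.attrs["n_subjects"] = len(records)
    return out


def _result_row(r: StatResult) -> dict:
    return {"statistic": r.statistic, "p_value": r.p_value, "effect": r.effect,
            "effect_name": r.effect_name, "n": str(r.n), "method": r.method,
            "achieved_power": r.achieved_power,
            "flags": ";".join(r.flags)}
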