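"""Case/control allelic association scan with permutation correction.

The test is the 1-df Pearson chi-square on the 2x2 allele-count table
(alt/ref x case/control), no continuity correction — the convention of
the standard array-GWAS allelic test. Genome-wide significance comes from
Bonferroni on the post-QC SNP count and from the Max(T) permutation
procedure: case/control labels are permuted preserving group sizes, the
genome-wide maximum statistic is recorded per permutation, and the
empirical p of a SNP is the fraction of permutations whose maximum
reaches its observed statistic, with the (r+1)/(N+1) estimator so no p is
ever exactly zero.

Confounding by stratification/relatedness is diagnosed with the genomic
inflation factor (lambda) and optionally corrected with a simplified
one-variance-ratio mixed-model score test on a genomic relationship
matrix; the lambda-reduction behaviour, not numerical identity with any
specific mixed-model program, is the design goal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import CASE, CONTROL, MISSING, GenotypeDataset

#: Median of the chi-square distribution with 1 df.
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, df=1))


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion thresholds; all filters use strict 'less than'."""

    min_snp_call_rate: float = 0.97
    min_maf: float = 0.05
    min_sample_call_rate: float = 0.90

    def __post_init__(self) -> None:
        for f in (self.min_snp_call_rate, self.min_maf, self.min_sample_call_rate):
            if not 0.0 <= f <= 1.0:
                raise ValueError("thresholds must be in [0, 1]")


@dataclass
class QCReport:
    excluded_samples: pd.DataFrame  # sample_id, reason, value
    excluded_snps: pd.DataFrame  # snp_id, reason, value


@dataclass
class InflationReport:
    lambda_raw: float
    qq: pd.DataFrame  # expected/observed -log10 p quantile pairs
    lambda_corrected: float | None = None


def apply_qc(
    dataset: GenotypeDataset, thresholds: QCThresholds = QCThresholds()
) -> tuple[GenotypeDataset, QCReport]:
    """Filter samples by call rate, then SNPs by call rate, then SNPs by
    MAF computed on the retained samples — in that fixed order."""
    nonmissing = dataset.calls != MISSING

    sample_cr = nonmissing.mean(axis=1)
    keep_samples = sample_cr >= thresholds.min_sample_call_rate
    excl_samples = pd.DataFrame(
        {
            "sample_id": [s for s, k in zip(dataset.sample_ids, keep_samples) if not k],
            "reason": "call_rate",
            "value": sample_cr[~keep_samples],
        }
    )
    ds = dataset.select_samples(keep_samples)

    nonmissing = ds.calls != MISSING
    snp_cr = nonmissing.mean(axis=0) if ds.n_samples else np.zeros(ds.n_snps)
    keep_cr = snp_cr >= thresholds.min_snp_call_rate

    with np.errstate(invalid="ignore"):
        alt_freq = np.where(
            nonmissing.sum(axis=0) > 0,
            np.where(ds.calls == MISSING, 0, ds.calls).sum(axis=0)
            / (2 * np.maximum(nonmissing.sum(axis=0), 1)),
            0.0,
        )
    maf = np.minimum(alt_freq, 1 - alt_freq)
    keep_maf = maf >= thresholds.min_maf

    excl_rows = []
    for j in np.flatnonzero(~keep_cr):
        excl_rows.append((ds.snps.at[j, "snp_id"], "call_rate", snp_cr[j]))
    for j in np.flatnonzero(keep_cr & ~keep_maf):
        excl_rows.append((ds.snps.at[j, "snp_id"], "maf", maf[j]))
    excl_snps = pd.DataFrame(excl_rows, columns=["snp_id", "reason", "value"])

    ds = ds.select_snps(keep_cr & keep_maf)
    if ds.n_samples == 0 or ds.n_snps == 0:
        raise ValueError("dataset empty after QC filtering")
    return ds, QCReport(excl_samples, excl_snps)


def allelic_test(
    case_alt: float, case_ref: float, ctrl_alt: float, ctrl_ref: float
) -> tuple[float, float, bool]:
    """Pearson 1-df chi-square on a 2x2 allele-count table.

    Returns (statistic, p, monomorphic). A zero margin (monomorphic SNP or
    an empty group) yields statistic 0 and p 1 with the monomorphic flag.
    """
    if min(case_alt, case_ref, ctrl_alt, ctrl_ref) < 0:
        raise ValueError("counts must be non-negative")
    a, b, c, d = case_alt, case_ref, ctrl_alt, ctrl_ref
    n = a + b + c + d
    if n <= 0:
        raise ValueError("total count must be positive")
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if min(margins) == 0:
        return 0.0, 1.0, True
    stat = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return float(stat), float(stats.chi2.sf(stat, df=1)), False


def _allele_counts(
    calls: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-SNP allele counts for a binary label vector.

    ``labels`` is 1 for cases. Missing calls are excluded per SNP.
    """
    nonmiss = (calls != MISSING).astype(np.float64)
    alt = np.where(calls == MISSING, 0, calls).astype(np.float64)
    case_alt = labels @ alt
    case_n = labels @ nonmiss
    ctrl_alt = alt.sum(axis=0) - case_alt
    ctrl_n = nonmiss.sum(axis=0) - case_n
    return case_alt, 2 * case_n - case_alt, ctrl_alt, 2 * ctrl_n - ctrl_alt


def _chi2_vector(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> np.ndarray:
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, n * (a * d - b * c) ** 2 / np.where(denom > 0, denom, 1), 0.0)
    return stat


def association_scan(dataset: GenotypeDataset) -> pd.DataFrame:
    """Per-SNP allelic test over a QC-filtered dataset.

    Returns a DataFrame (snp_id, chrom, pos, the four allele counts,
    chi2, p_raw, monomorphic) with attrs ``bonferroni`` (0.05 / n SNPs)
    and ``top_snp`` (smallest p, ties broken by smallest chromosome then
    position). Scan order and statistics are invariant to sample order.
    """
    cases = dataset.case_mask()
    controls = dataset.control_mask()
    if cases.sum() == 0 or controls.sum() == 0:
        raise ValueError("association scan needs both cases and controls")
    used = dataset.select_samples(cases | controls)
    labels = used.case_mask().astype(np.float64)
    a, b, c, d = _allele_counts(used.calls, labels)
    chi2 = _chi2_vector(a, b, c, d)
    mono = np.minimum.reduce([a + b, c + d, a + c, b + d]) == 0
    p = np.where(mono, 1.0, stats.chi2.sf(chi2, df=1))

    out = used.snps[["snp_id", "chrom", "pos"]].copy()
    out["case_alt"] = a
    out["case_ref"] = b
    out["ctrl_alt"] = c
    out["ctrl_ref"] = d
    out["chi2"] = chi2
    out["p_raw"] = p
    out["monomorphic"] = mono
    out.attrs["bonferroni"] = 0.05 / len(out)

    # numeric chromosome sort where possible for tie-breaking
    chrom_key = pd.to_numeric(out["chrom"], errors="coerce").fillna(np.inf)
    order = np.lexsort((out["pos"], chrom_key, out["p_raw"]))
    out.attrs["top_snp"] = out.iloc[order[0]]["snp_id"]
    return out


def maxt_permutation(
    dataset: GenotypeDataset, n_perm: int = 100_000, seed: int = 0
) -> pd.DataFrame:
    """Max(T) permutation p-values.

    Permutes phenotype labels preserving case/control counts; per
    permutation records the genome-wide maximum chi-square;
    ``p_genome(SNP) = (1 + #{perm max >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cases = dataset.case_mask()
    controls = dataset.control_mask()
    used = dataset.select_samples(cases | controls)
    labels = used.case_mask().astype(np.float64)
    n_case = int(labels.sum())
    if n_case == 0 or n_case == len(labels):
        raise ValueError("need both cases and controls")

    obs_chi2 = _chi2_vector(*_allele_counts(used.calls, labels))

    rng = np.random.default_rng(seed)
    n = len(labels)
    perm_labels = np.zeros((n_perm, n))
    for r in range(n_perm):
        perm_labels[r, rng.choice(n, size=n_case, replace=False)] = 1.0

    nonmiss = (used.calls != MISSING).astype(np.float64)
    alt = np.where(used.calls == MISSING, 0, used.calls).astype(np.float64)
    case_alt = perm_labels @ alt
    case_n = perm_labels @ nonmiss
    tot_alt = alt.sum(axis=0)
    tot_n = nonmiss.sum(axis=0)
    a = case_alt
    b = 2 * case_n - case_alt
    c = tot_alt - case_alt
    d = 2 * (tot_n - case_n) - c
    perm_chi2 = _chi2_vector(a, b, c, d)
    perm_max = perm_chi2.max(axis=1)

    p_genome = (1 + (perm_max[:, None] >= obs_chi2[None, :]).sum(axis=0)) / (n_perm + 1)
    out = used.snps[["snp_id", "chrom", "pos"]].copy()
    out["chi2"] = obs_chi2
    out["p_genome"] = p_genome
    return out


def genomic_inflation(chi_squares: np.ndarray) -> InflationReport:
    """lambda = median(chi2) / median of the 1-df chi-square reference,
    with expected/observed -log10 p quantile pairs for a Q-Q plot."""
    chi = np.asarray(chi_squares, dtype=float)
    chi = chi[np.isfinite(chi)]
    if chi.size == 0:
        raise ValueError("no finite statistics")
    lam = float(np.median(chi) / CHI2_MEDIAN_1DF)
    p_obs = np.sort(stats.chi2.sf(chi, df=1))
    m = len(p_obs)
    p_exp = (np.arange(1, m + 1) - 0.5) / m
    qq = pd.DataFrame(
        {"expected": -np.log10(p_exp), "observed": -np.log10(np.maximum(p_obs, 1e-300))}
    )
    return InflationReport(lambda_raw=lam, qq=qq)


# ---------------------------------------------------------------------------
# Simplified mixed-model association


def genomic_relationship_matrix(dataset: GenotypeDataset) -> np.ndarray:
    """GRM from standardized genotypes; missing calls mean-imputed per SNP,
    monomorphic SNPs dropped."""
    calls = dataset.calls.astype(np.float64)
    calls[dataset.calls == MISSING] = np.nan
    mean = np.nanmean(calls, axis=0)
    freq = mean / 2
    poly = (freq > 0) & (freq < 1)
    calls = np.where(np.isnan(calls), mean, calls)[:, poly]
    z = (calls - mean[poly]) / np.sqrt(2 * freq[poly] * (1 - freq[poly]))
    return z @ z.T / z.shape[1]


def mixed_model_scan(dataset: GenotypeDataset) -> tuple[pd.DataFrame, InflationReport]:
    """Score test under a one-variance-ratio mixed model.

    The phenotype (0/1) is modeled as ``y = mu + g + e`` with
    ``cov(g) = sg^2 K`` for the genomic relationship matrix K. A single
    variance ratio ``delta = se^2/sg^2`` is fitted once on the null model
    by 1-D maximum likelihood over the eigenbasis of K; each SNP is then
    tested with a generalized-least-squares score test using the null
    covariance. Returns the per-SNP table and an inflation report with
    both the raw and corrected lambda.
    """
    cases = dataset.case_mask()
    controls = dataset.control_mask()
    used = dataset.select_samples(cases | controls)
    y = used.case_mask().astype(np.float64)
    n = len(y)

    k = genomic_relationship_matrix(used)
    evals, u = np.linalg.eigh(k)
    n_null = int((evals < 1e-8).sum())
    if n_null:
        evals = evals + 1e-6  # ridge; one null direction is expected (centering)
        if n_null > 1:
            import warnings

            warnings.warn(
                f"relationship matrix singular ({n_null} null directions); ridge added"
            )

    yt = u.T @ y
    xt = u.T @ np.ones(n)

    def neg_loglik(log_delta: float) -> float:
        delta = 10.0 ** log_delta
        w = 1.0 / (evals + delta)
        xtwx = np.sum(w * xt * xt)
        beta = np.sum(w * xt * yt) / xtwx
        resid = yt - xt * beta
        rss = np.sum(w * resid * resid)
        sg2 = rss / n
        return 0.5 * (n * np.log(2 * np.pi * sg2) + np.sum(np.log(evals + delta)) + n)

    res = optimize.minimize_scalar(neg_loglik, bounds=(-5.0, 5.0), method="bounded")
    delta = 10.0 ** res.x
    w = 1.0 / (evals + delta)

    # project out the intercept under the null covariance
    xtwx = np.sum(w * xt * xt)
    beta0 = np.sum(w * xt * yt) / xtwx
    resid = yt - xt * beta0
    sigma2 = np.sum(w * resid * resid) / (n - 1)

    calls = used.calls.astype(np.float64)
    calls[used.calls == MISSING] = np.nan
    mean = np.nanmean(calls, axis=0)
    calls = np.where(np.isnan(calls), mean, calls)
    gt = u.T @ calls  # rotated genotypes, n x m

    gw_x = (w[:, None] * gt).T @ xt / xtwx  # per-SNP projection on intercept
    g_adj = gt - np.outer(gw_x, xt).T
    num = (w[:, None] * g_adj).T @ resid
    den = np.einsum("ij,ij->j", w[:, None] * g_adj, g_adj)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(den > 1e-12, num**2 / (den * sigma2), 0.0)
    p = stats.chi2.sf(chi2, df=1)

    out = used.snps[["snp_id", "chrom", "pos"]].copy()
    out["chi2_mm"] = chi2
    out["p_mm"] = p

    raw = _chi2_vector(*_allele_counts(used.calls, y))
    report = genomic_inflation(raw)
    report.lambda_corrected = float(np.median(chi2) / CHI2_MEDIAN_1DF)
    return out, report
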