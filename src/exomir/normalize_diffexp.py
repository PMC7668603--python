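"""Normalization and negative-binomial differential expression.

Normalization follows a fixed composition: counts are first corrected with
the spike-in controls together with each library's total mapped reads
(per-million scaling times the relative spike-in recovery rate), then with
median-of-ratios size factors.  piRNAs get a class-specific treatment: their
size factors are computed from the miRNA submatrix, and miRNAs are removed
before piRNA testing.

Differential expression is a per-species negative-binomial log-link GLM with
size-factor offsets, fitted by Fisher-scoring IRLS with a fixed (moderated)
dispersion; the group coefficient is reported as log2 fold change with a
Wald z test.  Dispersions are method-of-moments estimates shrunk in log
space toward a parametric a0 + a1/mean trend — a simplified empirical-Bayes
scheme, not a re-derivation of any particular package's Cox-Reid machinery.
Candidates are flagged on raw p < 0.05 (the selection rule used for
downstream experimental validation); BH-adjusted q-values are reported
alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .annotate_quantify import CountMatrix

_LN2 = np.log(2.0)
_DISP_FLOOR = 1e-8


@dataclass
class SizeFactors:
    values: pd.Series
    provenance: str  # spikein | median_of_ratios | mirna_derived

    def __post_init__(self) -> None:
        if (self.values <= 0).any():
            raise ValueError("size factors must be positive")


# ---------------------------------------------------------------------------
# normalization

def spikein_size_factors(m: CountMatrix) -> SizeFactors:
    """Per-sample divisors combining spike-in recovery and library depth.

    Dividing by these factors equals scaling each library to reads-per-
    million mapped and then correcting by its spike-in rate relative to the
    cross-sample mean rate, so duplicating a library at twice the depth
    (spike-ins included) leaves normalized columns unchanged.
    """
    zero = m.spikein_counts[m.spikein_counts <= 0]
    if len(zero):
        raise ValueError("zero spike-in count in sample(s): "
                         f"{sorted(zero.index)}")
    rate = m.spikein_counts / m.total_mapped
    f = m.spikein_counts / (1e6 * rate.mean())
    return SizeFactors(f, "spikein")


def spikein_normalize(m: CountMatrix) -> CountMatrix:
    """Spike-in + total-mapped normalized copy of the matrix."""
    f = spikein_size_factors(m).values
    return CountMatrix(m.counts / f, m.classes,
                       m.total_mapped / f, m.spikein_counts / f)


def size_factors_median_of_ratios(counts: pd.DataFrame) -> SizeFactors:
    """Median-of-ratios size factors over species with all-positive counts."""
    pos = counts[(counts > 0).all(axis=1)]
    if pos.empty:
        raise ValueError("no species with all-positive counts for "
                         "median-of-ratios size factors")
    log_geo = np.log(pos).mean(axis=1)
    ratios = np.log(pos).sub(log_geo, axis=0)
    return SizeFactors(np.exp(ratios.median(axis=0)), "median_of_ratios")


# ---------------------------------------------------------------------------
# dispersion estimation

def estimate_dispersions(counts: pd.DataFrame, sf: SizeFactors | pd.Series,
                         condition: pd.Series) -> pd.DataFrame:
    """Per-species NB dispersion: raw method-of-moments within groups,
    a robust a0 + a1/mean trend, and a log-space shrink toward the trend.

    Returns a frame (raw_dispersion, trended_dispersion, final_dispersion,
    base_mean, tested); all-zero species are marked untested.
    """
    sfv = sf.values if isinstance(sf, SizeFactors) else sf
    norm = counts / pd.Series(sfv).reindex(counts.columns)
    base_mean = norm.mean(axis=1)
    groups = condition.reindex(counts.columns)

    num = pd.Series(0.0, index=counts.index)
    den = pd.Series(0.0, index=counts.index)
    for _, samples in groups.groupby(groups):
        cols = list(samples.index)
        if len(cols) < 2:
            continue
        sub = norm[cols]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (var - mu) / mu ** 2
        a = a.where(mu > 0, np.nan)
        w = float(len(cols) - 1)
        num += w * a.fillna(0.0)
        den += w * a.notna()
    # pooled moment estimate: kept signed for the trend fit (its mean is
    # unbiased for the true dispersion), clipped at 0 for reporting
    raw_signed = num / den.replace(0.0, np.nan)
    raw = raw_signed.clip(lower=0.0)

    tested = base_mean > 0
    trend = _fit_dispersion_trend(base_mean[tested], raw_signed[tested])
    trended = pd.Series(np.nan, index=counts.index)
    trended[tested] = trend

    n = counts.shape[1]
    p = groups.nunique()
    # approximate sampling variance of a log dispersion estimate
    s2_samp = float(special.polygamma(1, max(n - p, 1) / 2.0))
    log_trend = np.log(trended.clip(lower=_DISP_FLOOR))
    # a zero/negative moment estimate carries no dispersion information:
    # those species take the trend value rather than a log of the floor
    log_raw = np.log(raw.where(raw > 0))
    resid = (log_raw - log_trend)[tested & log_raw.notna()]
    mad = float((resid - resid.median()).abs().median()) * 1.4826 if len(resid) else 0.5
    s2_prior = max(mad ** 2 - s2_samp, 0.25)
    w_raw = s2_prior / (s2_prior + s2_samp)
    log_final = w_raw * log_raw.fillna(log_trend) + (1 - w_raw) * log_trend
    final = np.exp(log_final).clip(lower=_DISP_FLOOR)
    return pd.DataFrame({"raw_dispersion": raw,
                         "trended_dispersion": trended,
                         "final_dispersion": final.where(tested),
                         "base_mean": base_mean,
                         "tested": tested})


def _fit_dispersion_trend(mean: pd.Series, raw: pd.Series) -> pd.Series:
    """Fit alpha = a0 + a1/mean to the signed moment estimates.

    Plain least squares targets the mean of the (noisy but unbiased) signed
    estimates; gross outliers are trimmed over a few reweighting rounds.
    Coefficients are clipped at 0.
    """
    ok = raw.notna() & (mean > 0)
    if ok.sum() >= 10:
        y = raw[ok].values
        X = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok].values])
        keep = np.ones(len(y), dtype=bool)
        a0 = a1 = 0.0
        for _ in range(3):
            coef, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
            pred = X @ coef
            resid = y - pred
            scale = np.median(np.abs(resid - np.median(resid))) * 1.4826
            if scale <= 0:
                break
            keep = np.abs(resid - np.median(resid)) <= 5 * scale
            a0, a1 = coef
        a0, a1 = max(a0, 0.0), max(a1, 0.0)
        if a0 + a1 <= 0:
            a0 = max(float(np.mean(np.clip(y, 0, None))), _DISP_FLOOR)
    else:
        med = float(raw.dropna().mean()) if raw.notna().any() else 0.01
        if not np.isfinite(med) or med <= 0:
            med = 0.01
        a0, a1 = med, 0.0
    return pd.Series(a0 + a1 / mean.clip(lower=1e-12),
                     index=mean.index).clip(lower=_DISP_FLOOR)


# ---------------------------------------------------------------------------
# NB Wald test

def _nb_irls(y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float,
             max_iter: int = 100, tol: float = 1e-8):
    """Fisher-scoring fit of an NB log-link GLM with fixed dispersion."""
    beta = np.linalg.lstsq(X, np.log(y + 0.5) - offset, rcond=None)[0]
    info = None
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -30.0, 30.0)
        mu = np.exp(eta)
        denom = 1.0 + alpha * mu
        W = mu / denom
        info = X.T @ (X * W[:, None])
        score = X.T @ ((y - mu) / denom)
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            return beta, None, False
        beta = beta + np.clip(delta, -10.0, 10.0)
        if np.max(np.abs(delta)) < tol:
            break
    else:
        return beta, info, False
    return beta, info, True


def nb_wald_test(counts: pd.DataFrame, condition: pd.Series,
                 sf: SizeFactors | pd.Series,
                 dispersions: pd.Series | pd.DataFrame | None = None,
                 *, batch: pd.Series | None = None,
                 baseline: str | None = None,
                 candidate_threshold: float = 0.05,
                 candidate_on_adjusted: bool = False) -> pd.DataFrame:
    """Per-species NB Wald test of the two-level ``condition`` factor.

    ``counts`` are raw (fractional) counts; normalization enters through the
    size-factor offsets.  Returns one row per species with base_mean,
    log2fc (non-baseline vs baseline), se, wald_stat, p_value, BH q_value
    and the candidate flag.  Non-converged fits keep a missing p-value;
    all-zero species are marked untested.
    """
    samples = list(counts.columns)
    cond = condition.reindex(samples)
    levels = sorted(cond.unique())
    if len(levels) != 2:
        raise ValueError(f"condition must have 2 levels, got {levels}")
    if baseline is None:
        baseline = "control" if "control" in levels else levels[0]
    other = [l for l in levels if l != baseline][0]
    if (cond == baseline).sum() < 2 or (cond == other).sum() < 2:
        raise ValueError("need >= 2 samples per group")

    sfv = (sf.values if isinstance(sf, SizeFactors) else sf).reindex(samples)
    offset = np.log(sfv.values.astype(float))
    cols = [np.ones(len(samples)), (cond == other).astype(float).values]
    if batch is not None:
        b = batch.reindex(samples)
        for lev in sorted(b.unique())[1:]:
            cols.append((b == lev).astype(float).values)
    X = np.column_stack(cols)

    if dispersions is None:
        dispersions = estimate_dispersions(counts, sfv, cond)
    if isinstance(dispersions, pd.DataFrame):
        disp = dispersions["final_dispersion"]
    else:
        disp = dispersions
    disp = disp.reindex(counts.index)

    norm = counts / sfv
    out = []
    for sid, row in counts.iterrows():
        y = row.values.astype(float)
        rec = {"species_id": sid, "base_mean": float(norm.loc[sid].mean()),
               "log2fc": np.nan, "se": np.nan, "wald_stat": np.nan,
               "p_value": np.nan, "tested": False, "converged": False}
        alpha = disp.get(sid, np.nan)
        if y.sum() > 0 and np.isfinite(alpha):
            beta, info, conv = _nb_irls(y, X, offset, max(alpha, _DISP_FLOOR))
            rec["converged"] = conv
            if info is not None and conv:
                try:
                    cov = np.linalg.inv(info)
                    se = float(np.sqrt(max(cov[1, 1], 0.0)))
                except np.linalg.LinAlgError:
                    se = np.nan
                if np.isfinite(se) and se > 0:
                    rec["tested"] = True
                    rec["log2fc"] = float(beta[1] / _LN2)
                    rec["se"] = se / _LN2
                    z = float(beta[1] / se)
                    rec["wald_stat"] = z
                    rec["p_value"] = float(2.0 * stats.norm.sf(abs(z)))
        out.append(rec)
    res = pd.DataFrame(out).set_index("species_id")
    res["q_value"] = bh_adjust(res["p_value"])
    flag_on = res["q_value"] if candidate_on_adjusted else res["p_value"]
    res["candidate"] = flag_on < candidate_threshold
    return res


def bh_adjust(p: pd.Series) -> pd.Series:
    """Benjamini-Hochberg adjustment, missing p-values left missing."""
    from statsmodels.stats.multitest import multipletests

    q = pd.Series(np.nan, index=p.index)
    ok = p.notna()
    if ok.any():
        q[ok] = multipletests(p[ok].values, method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# class-specific pipelines

def mirna_derived_size_factors(m: CountMatrix) -> SizeFactors:
    """Median-of-ratios factors computed on the miRNA submatrix only."""
    mir = m.subset_class("miRNA")
    if mir.counts.empty:
        raise ValueError("count matrix contains no miRNA rows")
    sf = size_factors_median_of_ratios(mir.counts)
    return SizeFactors(sf.values, "mirna_derived")


def differential_expression(m: CountMatrix, sheet: pd.DataFrame,
                            timepoint: str | None = None,
                            rna_class: str = "miRNA",
                            *, use_spikein: bool = True,
                            batch_covariate: bool = False,
                            candidate_threshold: float = 0.05,
                            ) -> pd.DataFrame:
    """Full normalization + NB Wald contrast for one class and timepoint.

    Composition order is fixed: spike-in/total-mapped correction first, then
    median-of-ratios size factors (computed on the miRNA submatrix for both
    classes: miRNAs normalize themselves and serve as the reference set for
    piRNAs, which are then tested with miRNA rows removed).
    """
    sub_sheet = sheet if timepoint is None else sheet[
        sheet["timepoint"] == timepoint]
    sub = m.subset_samples(list(sub_sheet["sample"]))
    sf1 = (spikein_size_factors(sub).values if use_spikein
           else pd.Series(1.0, index=sub.samples))
    m1 = CountMatrix(sub.counts / sf1, sub.classes,
                     sub.total_mapped / sf1, sub.spikein_counts)
    sf2 = mirna_derived_size_factors(m1).values
    total_sf = sf1 * sf2
    total_sf = total_sf / np.exp(np.log(total_sf).mean())
    cls = sub.subset_class(rna_class)
    if cls.counts.empty:
        warnings.warn(f"no {rna_class} rows to test")
        return pd.DataFrame()
    cond = sub_sheet.set_index("sample")["condition"]
    batch = (sub_sheet.set_index("sample")["batch"] if batch_covariate
             else None)
    disp = estimate_dispersions(cls.counts, total_sf, cond)
    res = nb_wald_test(cls.counts, cond, total_sf, disp, batch=batch,
                       candidate_threshold=candidate_threshold)
    res.insert(0, "rna_class", rna_class)
    return res


def pirna_specific_pipeline(m: CountMatrix, sheet: pd.DataFrame,
                            timepoint: str | None = None,
                            **kwargs) -> pd.DataFrame:
    """piRNA differential expression with miRNA-derived size factors
    (miRNA rows are removed before testing)."""
    if m.subset_class("piRNA").counts.empty:
        warnings.warn("no piRNA rows present; empty result")
        return pd.DataFrame()
    return differential_expression(m, sheet, timepoint, "piRNA", **kwargs)


# ---------------------------------------------------------------------------
# class enrichment

@dataclass
class ClassEnrichmentResult:
    t_stat: float
    p_value: float
    df: int
    mean_difference: float     # piRNA minus miRNA
    ci_low: float
    ci_high: float
    per_sample: pd.DataFrame   # miRNA/piRNA summary per sample


def class_enrichment_test(m: CountMatrix,
                          statistic: str = "abundance",
                          ) -> ClassEnrichmentResult:
    """Paired comparison of piRNA vs miRNA per sample.

    ``statistic`` is either summed normalized counts per class
    ("abundance") or the number of detected species per class
    ("richness"); pairing is by sample.  Reports the two-sided paired t
    test and the 95% confidence interval of the mean paired difference.
    """
    if m.counts.shape[1] < 2:
        raise ValueError("need >= 2 samples for the paired test")
    per = {}
    for cls in ("miRNA", "piRNA"):
        sub = m.subset_class(cls).counts
        if statistic == "abundance":
            per[cls] = sub.sum(axis=0)
        elif statistic == "richness":
            per[cls] = (sub > 0).sum(axis=0).astype(float)
        else:
            raise ValueError("statistic must be 'abundance' or 'richness'")
    tab = pd.DataFrame(per)
    d = tab["piRNA"] - tab["miRNA"]
    n = len(d)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            t_stat, p = 0.0, 1.0
        else:
            warnings.warn("degenerate paired differences (zero variance); "
                          "p reported below machine precision")
            t_stat = np.inf if mean > 0 else -np.inf
            p = float(np.finfo(float).tiny)
        return ClassEnrichmentResult(t_stat, p, n - 1, mean, mean, mean, tab)
    se = sd / np.sqrt(n)
    t_stat = mean / se
    p = float(2.0 * stats.t.sf(abs(t_stat), n - 1))
    half = float(stats.t.ppf(0.975, n - 1)) * se
    return ClassEnrichmentResult(float(t_stat), p, n - 1, mean,
                                 mean - half, mean + half, tab)
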