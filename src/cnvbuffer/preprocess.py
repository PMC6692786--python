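"""Normalization and filtering chain from raw-style matrices to analysis-ready ones.

All functions operate on feature-by-sample DataFrames (rows = proteins /
phosphosites / genes, columns = samples), the orientation used by the TSV
interchange format.  The default cancer-cohort order is: replicate merging
-> isoform selection -> quantile normalization -> coverage filter ->
z-scoring -> confounder regression; tissue panels use z-score before
quantile normalization instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CoverageFilterSpec:
    """Keep features observed in at least ``min_fraction_observed`` of
    ``reference_sample_count`` samples (inclusive threshold)."""

    min_fraction_observed: float
    reference_sample_count: int

    def __post_init__(self) -> None:
        if not 0.0 < self.min_fraction_observed <= 1.0:
            raise ValueError("min_fraction_observed must be in (0, 1]")
        if self.reference_sample_count < 1:
            raise ValueError("reference_sample_count must be positive")


def merge_replicates(
    matrix: pd.DataFrame, replicate_map: dict[str, str], method: str = "mean"
) -> pd.DataFrame:
    """Collapse replicate columns to one column per sample.

    ``replicate_map`` maps each column of ``matrix`` to its sample id.
    ``method='mean'`` averages protein replicates; ``method='median'`` is
    used when collapsing phosphopeptides to one site intensity.  Missing
    values are ignored unless a whole group is missing.
    """
    if method not in ("mean", "median"):
        raise ValueError(f"unknown method {method!r}")
    missing = [c for c in matrix.columns if c not in replicate_map]
    if missing:
        raise ValueError(f"columns not covered by replicate_map: {missing[:5]}")
    groups = matrix.T.groupby([replicate_map[c] for c in matrix.columns])
    if any(len(g) == 0 for _, g in groups):
        raise ValueError("empty replicate group")
    merged = groups.mean() if method == "mean" else groups.median()
    return merged.T


def select_isoform(matrix: pd.DataFrame, isoform_to_gene: dict[str, str]) -> pd.DataFrame:
    """Keep, per gene, the isoform row with the highest median across samples.

    Ties are broken by the lexicographically smallest isoform id.  The
    output is indexed by gene.
    """
    unmapped = [i for i in matrix.index if i not in isoform_to_gene]
    if unmapped:
        raise ValueError(f"isoforms without gene mapping: {unmapped[:5]}")
    medians = matrix.median(axis=1, skipna=True)
    table = pd.DataFrame(
        {
            "gene": [isoform_to_gene[i] for i in matrix.index],
            "median": medians.to_numpy(),
            "isoform": matrix.index,
        }
    )
    # highest median wins; ties -> smallest isoform id
    table = table.sort_values(
        ["gene", "median", "isoform"], ascending=[True, False, True], kind="mergesort"
    )
    winners = table.drop_duplicates("gene")
    out = matrix.loc[winners["isoform"]]
    out.index = pd.Index(winners["gene"].to_numpy(), name="gene")
    return out


def filter_by_coverage(matrix: pd.DataFrame, spec: CoverageFilterSpec) -> pd.DataFrame:
    """Drop rows observed in fewer than the required fraction of samples."""
    observed = matrix.notna().sum(axis=1)
    frac = observed / spec.reference_sample_count
    return matrix.loc[frac >= spec.min_fraction_observed]


def _tmm_factor(
    obs: np.ndarray, ref: np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05
) -> float:
    """Trimmed-mean-of-M-values scaling factor of one sample against a reference."""
    lib_obs, lib_ref = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep] / lib_obs, ref[keep] / lib_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # asymptotic (delta-method) weights, as in the published method
    w = (lib_obs - obs[keep]) / (lib_obs * obs[keep]) + (lib_ref - ref[keep]) / (
        lib_ref * ref[keep]
    )
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[finite], a[finite], w[finite]
    if m.size == 0:
        return 1.0
    m_lo, m_hi = np.quantile(m, [trim_m, 1 - trim_m])
    a_lo, a_hi = np.quantile(a, [trim_a, 1 - trim_a])
    sel = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
    if not sel.any():
        return 1.0
    f = np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])
    return float(2.0**f)


def normalize_counts(
    counts: pd.DataFrame,
    min_mean_cpm: float = 1.0,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Raw counts -> log2-CPM with TMM between-sample normalization.

    Genes with mean counts-per-million below ``min_mean_cpm`` are removed
    first.  The TMM reference is the sample whose upper quartile is closest
    to the mean upper quartile; scaling factors are normalized to have
    geometric mean 1 and fold into effective library sizes.
    """
    x = counts.to_numpy(dtype=float)
    if (x < 0).any() or np.isnan(x).any():
        raise ValueError("counts must be nonnegative and complete")
    lib = x.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("all-zero sample in counts matrix")
    cpm = x / lib * 1e6
    keep = cpm.mean(axis=1) >= min_mean_cpm
    x = x[keep]
    lib = x.sum(axis=0)
    uq = np.quantile(x / lib, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array(
        [_tmm_factor(x[:, j], x[:, ref_idx], trim_m, trim_a) for j in range(x.shape[1])]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    eff_lib = lib * factors
    logcpm = np.log2((x + prior_count) / (eff_lib + 1.0) * 1e6)
    return pd.DataFrame(logcpm, index=counts.index[keep], columns=counts.columns)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force all columns to share the mean empirical distribution.

    Each column's sorted values are replaced by the across-column mean of
    sorted values; ties get the mean of their quantile values.  Missing
    entries stay missing and are excluded from the quantile computation,
    with observed values mapped by rank fraction onto the mean
    distribution.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 columns")
    x = matrix.to_numpy(dtype=float)
    n_rows = x.shape[0]
    if not np.isnan(x).any():
        order = np.argsort(x, axis=0, kind="mergesort")
        sorted_vals = np.take_along_axis(x, order, axis=0)
        mean_dist = sorted_vals.mean(axis=1)
        out = np.empty_like(x)
        for j in range(x.shape[1]):
            idx = order[:, j]
            vals = x[idx, j]
            res = mean_dist.copy()
            bounds = np.flatnonzero(np.diff(vals) != 0)
            starts = np.concatenate(([0], bounds + 1))
            ends = np.concatenate((bounds + 1, [n_rows]))
            for s, e in zip(starts, ends):
                if e - s > 1:
                    res[s:e] = res[s:e].mean()
            out[idx, j] = res
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    # missing-aware: per-column quantile grid over observed values
    grid = np.linspace(0.0, 1.0, n_rows)
    quantiles = np.empty((n_rows, x.shape[1]))
    for j in range(x.shape[1]):
        obs = x[~np.isnan(x[:, j]), j]
        if obs.size == 0:
            quantiles[:, j] = np.nan
            continue
        quantiles[:, j] = np.quantile(obs, grid)
    mean_dist = np.nanmean(quantiles, axis=1)
    out = np.full_like(x, np.nan)
    for j in range(x.shape[1]):
        mask = ~np.isnan(x[:, j])
        obs = x[mask, j]
        if obs.size == 0:
            continue
        if obs.size == 1:
            out[mask, j] = np.interp(0.5, grid, mean_dist)
            continue
        ranks = pd.Series(obs).rank(method="average").to_numpy()
        frac = (ranks - 1.0) / (obs.size - 1.0)
        out[mask, j] = np.interp(frac, grid, mean_dist)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def zscore_rows(matrix: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Standardize each row to mean 0, sd 1 over its observed entries.

    Constant rows cannot be standardized and are dropped with a warning.
    """
    mean = matrix.mean(axis=1, skipna=True)
    sd = matrix.std(axis=1, skipna=True, ddof=ddof)
    constant = sd.fillna(0.0) == 0.0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant row(s) in z-scoring",
            stacklevel=2,
        )
    out = matrix.loc[~constant]
    return out.sub(mean[~constant], axis=0).div(sd[~constant], axis=0)


def design_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """Intercept + dummy-coded categoricals + numeric columns, aliased columns dropped."""
    parts = [pd.Series(1.0, index=covariates.index, name="intercept")]
    for col in covariates.columns:
        series = covariates[col]
        if pd.api.types.is_numeric_dtype(series):
            parts.append(series.astype(float))
        else:
            dummies = pd.get_dummies(series.astype(str), prefix=col, drop_first=True)
            parts.append(dummies.astype(float))
    design = pd.concat(parts, axis=1)
    x = design.to_numpy()
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # greedily drop columns that do not increase rank
        keep: list[int] = []
        for j in range(x.shape[1]):
            cand = keep + [j]
            if np.linalg.matrix_rank(x[:, cand]) == len(cand):
                keep.append(j)
        dropped = [design.columns[j] for j in range(x.shape[1]) if j not in keep]
        warnings.warn(f"dropping aliased design columns: {dropped}", stacklevel=2)
        design = design.iloc[:, keep]
    return design


def regress_confounders(
    matrix: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Residualize each feature row on the sample covariates by OLS.

    Covariates (cancer type, batch, technology, age, gender, ...) are
    dummy-coded; each row is fitted on its observed entries only and
    replaced by the fit residuals.
    """
    if not covariates.index.equals(pd.Index(matrix.columns)):
        covariates = covariates.loc[matrix.columns]
    if covariates.isna().any().any():
        raise ValueError("covariates must be complete for all samples")
    design = design_matrix(covariates).to_numpy()
    x = matrix.to_numpy(dtype=float)
    out = np.full_like(x, np.nan)
    full_mask = ~np.isnan(x)
    complete = full_mask.all(axis=1)
    if complete.any():
        y = x[complete].T
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        out[complete] = (y - design @ beta).T
    for i in np.flatnonzero(~complete):
        mask = full_mask[i]
        if mask.sum() <= design.shape[1]:
            continue  # underdetermined row left missing
        d = design[mask]
        y = x[i, mask]
        beta, *_ = np.linalg.lstsq(d, y, rcond=None)
        out[i, mask] = y - d @ beta
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
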