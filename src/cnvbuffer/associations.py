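"""Nested-model likelihood-ratio screens for interaction-mediated control.

For a physical interaction pair (X, Y) the null model predicts the protein
level of Y from Y's own mRNA plus sample covariates; the alternative adds
the copy number of X (CNV variant), X's mRNA (mRNA variant), or a
phosphosite of X (phospho variant, on top of X's CNV and protein).  Both
models are ordinary least squares on the identical complete-case sample
set; the likelihood ratio statistic uses the Gaussian likelihood with the
maximum-likelihood variance RSS/n, hence LRT = n * ln(RSS_null/RSS_alt),
referred to a chi-squared distribution with one degree of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import OmicsCohort, site_to_gene
from .preprocess import design_matrix

PROTEIN_SCREEN_COVARIATES = ("cancer_type", "batch", "technology", "age", "gender")
PHOSPHO_SCREEN_COVARIATES = ("batch", "age", "gender")


@dataclass(frozen=True)
class AssociationResult:
    """One controller->controlled test."""

    controller: str
    controlled: str
    model_variant: str
    beta7: float
    lrt_stat: float
    p: float
    fdr: float
    n_samples_used: int
    phosphosite: str | None = None


def benjamini_hochberg(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fit_nested_lrt(
    y: np.ndarray, base: np.ndarray, added: np.ndarray
) -> tuple[float, float, float]:
    """LRT of adding one predictor to an OLS base model.

    ``y`` (n,), ``base`` (n, k) including the intercept column, and
    ``added`` (n,) must already be complete cases.  Returns
    (beta7, lrt_stat, p).  Raises ValueError if the added predictor is
    constant or collinear with the base design, or if n is too small.
    """
    y = np.asarray(y, dtype=float)
    base = np.asarray(base, dtype=float)
    added = np.asarray(added, dtype=float)
    n, k = base.shape
    if n <= k + 3:
        raise ValueError(f"too few complete cases (n={n}) for {k + 1} parameters")
    var_added = added.var()
    if var_added == 0:
        raise ValueError("added predictor is constant")
    coef_a, *_ = np.linalg.lstsq(base, added, rcond=None)
    resid_added = added - base @ coef_a
    if resid_added.var() <= 1e-10 * var_added:
        raise ValueError("added predictor is collinear with the base design")
    beta0, *_ = np.linalg.lstsq(base, y, rcond=None)
    rss0 = float(np.sum((y - base @ beta0) ** 2))
    full = np.column_stack([base, added])
    beta1, *_ = np.linalg.lstsq(full, y, rcond=None)
    rss1 = float(np.sum((y - full @ beta1) ** 2))
    if rss1 <= 0:
        raise ValueError("perfect fit in the alternative model")
    lrt = max(0.0, n * np.log(rss0 / rss1))
    p = float(stats.chi2.sf(lrt, df=1))
    return float(beta1[-1]), float(lrt), max(p, np.finfo(float).tiny)


def _covariate_design(cohort: OmicsCohort, columns: tuple[str, ...]) -> np.ndarray:
    cov = cohort.covariates[[c for c in columns if c in cohort.covariates.columns]]
    return design_matrix(cov).to_numpy()


def screen_pairs(
    cohort: OmicsCohort,
    pairs: list[tuple[str, str]],
    variant: str = "cnv",
    covariates: tuple[str, ...] = PROTEIN_SCREEN_COVARIATES,
    min_samples: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Directed controller->controlled screen over interaction pairs.

    Each ordered pair (X, Y) with X in the added-predictor assay and Y in
    both protein and mRNA is tested with :func:`fit_nested_lrt` using base
    predictors {intercept, T_y, covariates} and added predictor G_x
    (``variant='cnv'``) or T_x (``variant='mrna'``).  FDR is
    Benjamini-Hochberg over all tested pairs in the screen.

    Returns ``(results, skipped)``; results are sorted by p.
    """
    if variant not in ("cnv", "mrna"):
        raise ValueError(f"unknown screen variant {variant!r}")
    added_matrix = cohort.cnv if variant == "cnv" else cohort.mrna
    design = _covariate_design(cohort, covariates)
    prot = cohort.protein
    mrna = cohort.mrna
    rows, skipped = [], []
    for x, y in pairs:
        if x == y:
            skipped.append((x, y, "homodimer"))
            continue
        if x not in added_matrix.columns:
            skipped.append((x, y, f"controller_missing_from_{variant}"))
            continue
        if y not in prot.columns or y not in mrna.columns:
            skipped.append((x, y, "controlled_missing"))
            continue
        py = prot[y].to_numpy(dtype=float)
        ty = mrna[y].to_numpy(dtype=float)
        gx = added_matrix[x].to_numpy(dtype=float)
        mask = ~np.isnan(py) & ~np.isnan(ty) & ~np.isnan(gx)
        n = int(mask.sum())
        base = np.column_stack([design[mask], ty[mask]])
        if min_samples is not None and n < min_samples:
            skipped.append((x, y, "insufficient_samples"))
            continue
        try:
            beta7, lrt, p = fit_nested_lrt(py[mask], base, gx[mask])
        except ValueError as err:
            skipped.append((x, y, str(err)))
            continue
        rows.append((x, y, variant, beta7, lrt, p, n))
    results = pd.DataFrame(
        rows,
        columns=[
            "controller",
            "controlled",
            "model_variant",
            "beta7",
            "lrt_stat",
            "p",
            "n_samples_used",
        ],
    )
    if len(results):
        results["fdr"] = benjamini_hochberg(results["p"].to_numpy())
        results = results.sort_values(
            ["p", "controller", "controlled"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        results["fdr"] = pd.Series(dtype=float)
    skipped_df = pd.DataFrame(skipped, columns=["controller", "controlled", "reason"])
    return results, skipped_df


def intersect_variants(
    cnv_results: pd.DataFrame, mrna_results: pd.DataFrame, threshold: float = 0.05
) -> set[tuple[str, str]]:
    """Pairs significant (FDR strictly below threshold) in both screens."""

    def sig(res: pd.DataFrame) -> set[tuple[str, str]]:
        hit = res[res["fdr"] < threshold]
        return set(zip(hit["controller"], hit["controlled"]))

    return sig(cnv_results) & sig(mrna_results)


def _pairwise_corr(a: np.ndarray, b: np.ndarray) -> float:
    mask = ~np.isnan(a) & ~np.isnan(b)
    if mask.sum() < 3:
        return np.nan
    x, y = a[mask], b[mask]
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def deduplicate_colocalized(
    pairs: set[tuple[str, str]] | list[tuple[str, str]],
    cnv_results: pd.DataFrame,
    mrna_results: pd.DataFrame,
    gene_chromosome: dict[str, str],
    cnv: pd.DataFrame,
    max_cnv_corr: float = 0.5,
) -> set[tuple[str, str]]:
    """Resolve genomically co-localized controllers of the same gene.

    For each controlled gene, same-chromosome controllers are ranked by
    Borda aggregation of the CNV-screen and mRNA-screen p-value orderings
    (rank sum; ties broken by smaller CNV p, then gene id).  The top
    controller is kept; a further same-chromosome controller survives only
    if its CNV profile correlates below ``max_cnv_corr`` (Pearson) with
    every controller already retained on that chromosome.  Controllers on
    distinct chromosomes are unaffected.
    """
    pairs = sorted(set(pairs))
    p_cnv = {
        (x, y): p
        for x, y, p in zip(
            cnv_results["controller"], cnv_results["controlled"], cnv_results["p"]
        )
    }
    p_mrna = {
        (x, y): p
        for x, y, p in zip(
            mrna_results["controller"], mrna_results["controlled"], mrna_results["p"]
        )
    }
    kept: set[tuple[str, str]] = set()
    by_controlled: dict[str, list[str]] = {}
    for x, y in pairs:
        by_controlled.setdefault(y, []).append(x)
    for y, controllers in by_controlled.items():
        unknown = [x for x in controllers if x not in gene_chromosome]
        if unknown:
            warnings.warn(
                f"no chromosome for controller(s) {unknown} of {y}; passed through",
                stacklevel=2,
            )
            kept.update((x, y) for x in unknown)
        known = [x for x in controllers if x in gene_chromosome]
        by_chrom: dict[str, list[str]] = {}
        for x in known:
            by_chrom.setdefault(gene_chromosome[x], []).append(x)
        for _chrom, group in by_chrom.items():
            if len(group) == 1:
                kept.add((group[0], y))
                continue
            worst = len(group) + 1

            def rank_in(plist: dict, xs: list[str]) -> dict[str, float]:
                vals = {x: plist.get((x, y), np.inf) for x in xs}
                series = pd.Series(vals).rank(method="average")
                return {x: (worst if np.isinf(vals[x]) else series[x]) for x in xs}

            r1 = rank_in(p_cnv, group)
            r2 = rank_in(p_mrna, group)
            ordered = sorted(
                group,
                key=lambda x: (r1[x] + r2[x], p_cnv.get((x, y), np.inf), x),
            )
            retained = [ordered[0]]
            for cand in ordered[1:]:
                corrs = [
                    _pairwise_corr(
                        cnv[cand].to_numpy(dtype=float), cnv[k].to_numpy(dtype=float)
                    )
                    for k in retained
                    if cand in cnv.columns and k in cnv.columns
                ]
                if all(np.isnan(c) or c < max_cnv_corr for c in corrs):
                    retained.append(cand)
            kept.update((x, y) for x in retained)
    return kept


def classify_control_status(pairs: set[tuple[str, str]]) -> pd.DataFrame:
    """Label each gene controlling / controlled / both from the final pair set."""
    if not pairs:
        raise ValueError("empty pair set")
    controlling = {x for x, _ in pairs}
    controlled = {y for _, y in pairs}
    rows = []
    for g in sorted(controlling | controlled):
        if g in controlling and g in controlled:
            status = "both"
        elif g in controlling:
            status = "controlling"
        else:
            status = "controlled"
        rows.append((g, status))
    return pd.DataFrame(rows, columns=["gene", "status"])


def screen_phospho(
    cohort: OmicsCohort,
    pairs: list[tuple[str, str]],
    protein_significant: set[tuple[str, str]] | None = None,
    covariates: tuple[str, ...] = PHOSPHO_SCREEN_COVARIATES,
    fdr_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phosphosite->protein control screen.

    For each interaction pair (X, Y) and each measured phosphosite Xp of
    X, the base model {intercept, T_y, G_x, P_x, covariates} is compared
    with the model adding Pho_x.  FDR is Benjamini-Hochberg across all
    tested site-protein pairs.  When ``protein_significant`` is given, the
    returned results carry ``in_final_set`` marking significant phospho
    associations whose (X, Y) is also in the protein-level significant
    set.
    """
    design = _covariate_design(cohort, covariates)
    sites_by_gene: dict[str, list[str]] = {}
    for site in cohort.phospho.columns:
        sites_by_gene.setdefault(site_to_gene(site), []).append(site)
    rows, skipped = [], []
    for x, y in pairs:
        if x == y:
            skipped.append((None, x, y, "homodimer"))
            continue
        eligible = (
            x in cohort.protein.columns
            and x in cohort.cnv.columns
            and y in cohort.protein.columns
            and y in cohort.mrna.columns
        )
        if not eligible:
            skipped.append((None, x, y, "pair_not_eligible"))
            continue
        for site in sites_by_gene.get(x, []):
            py = cohort.protein[y].to_numpy(dtype=float)
            ty = cohort.mrna[y].to_numpy(dtype=float)
            gx = cohort.cnv[x].to_numpy(dtype=float)
            px = cohort.protein[x].to_numpy(dtype=float)
            pho = cohort.phospho[site].to_numpy(dtype=float)
            mask = (
                ~np.isnan(py)
                & ~np.isnan(ty)
                & ~np.isnan(gx)
                & ~np.isnan(px)
                & ~np.isnan(pho)
            )
            base = np.column_stack(
                [design[mask], ty[mask], gx[mask], px[mask]]
            )
            try:
                beta7, lrt, p = fit_nested_lrt(py[mask], base, pho[mask])
            except ValueError as err:
                skipped.append((site, x, y, str(err)))
                continue
            rows.append((site, x, y, "phospho", beta7, lrt, p, int(mask.sum())))
    results = pd.DataFrame(
        rows,
        columns=[
            "phosphosite",
            "controller",
            "controlled",
            "model_variant",
            "beta7",
            "lrt_stat",
            "p",
            "n_samples_used",
        ],
    )
    if len(results):
        results["fdr"] = benjamini_hochberg(results["p"].to_numpy())
        results = results.sort_values(
            ["p", "phosphosite", "controlled"], kind="mergesort"
        ).reset_index(drop=True)
        if protein_significant is not None:
            results["in_final_set"] = [
                fdr < fdr_threshold and (x, y) in protein_significant
                for x, y, fdr in zip(
                    results["controller"], results["controlled"], results["fdr"]
                )
            ]
    else:
        results["fdr"] = pd.Series(dtype=float)
        if protein_significant is not None:
            results["in_final_set"] = pd.Series(dtype=bool)
    skipped_df = pd.DataFrame(
        skipped, columns=["phosphosite", "controller", "controlled", "reason"]
    )
    return results, skipped_df
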