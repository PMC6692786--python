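"""Validation of controlling->controlled pairs on normal-tissue panels.

If interaction-mediated control operates outside the discovery cohort,
controlled proteins should track their controller's protein profile across
tissues more strongly than random interaction pairs do, while their own
mRNA-to-protein correlation should weaken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attenuation import compare_groups
from .preprocess import quantile_normalize, zscore_rows


@dataclass
class TissuePanel:
    """Harmonized gene x tissue matrices with shared axes."""

    mrna: pd.DataFrame
    protein: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.mrna.index.equals(self.protein.index):
            raise ValueError("gene axes differ between mRNA and protein panels")
        if list(self.mrna.columns) != list(self.protein.columns):
            raise ValueError("tissue axes differ between mRNA and protein panels")

    @property
    def tissues(self) -> list[str]:
        return list(self.mrna.columns)


def harmonize_panel(
    raw_mrna: pd.DataFrame,
    raw_protein: pd.DataFrame,
    subtissue_map: dict[str, str] | None = None,
    min_tissues: int = 10,
) -> TissuePanel:
    """Merge sub-tissues, filter on joint expression coverage, normalize.

    ``subtissue_map`` maps raw mRNA columns to merged tissue names (e.g.
    the heart, esophagus and colon sub-tissues); mapped columns are
    averaged.  Genes are retained when expressed (nonmissing and nonzero)
    in at least ``min_tissues`` tissues in BOTH matrices (inclusive).
    Rows are then z-scored and quantile normalized, in that order.
    """
    mrna = raw_mrna.copy()
    if subtissue_map:
        merged = {}
        for col in mrna.columns:
            merged.setdefault(subtissue_map.get(col, col), []).append(col)
        mrna = pd.DataFrame(
            {name: mrna[cols].mean(axis=1) for name, cols in merged.items()}
        )
    common_tissues = [t for t in mrna.columns if t in raw_protein.columns]
    if len(common_tissues) < 2:
        raise ValueError("fewer than 2 tissues shared between the panels")
    mrna = mrna[common_tissues]
    protein = raw_protein[common_tissues]
    common_genes = mrna.index.intersection(protein.index)
    mrna, protein = mrna.loc[common_genes], protein.loc[common_genes]

    def expressed(df: pd.DataFrame) -> pd.Series:
        return (df.notna() & (df != 0)).sum(axis=1)

    keep = (expressed(mrna) >= min_tissues) & (expressed(protein) >= min_tissues)
    mrna, protein = mrna.loc[keep], protein.loc[keep]
    mrna = quantile_normalize(zscore_rows(mrna))
    protein = quantile_normalize(zscore_rows(protein))
    shared = mrna.index.intersection(protein.index)  # z-scoring can drop rows
    return TissuePanel(mrna=mrna.loc[shared], protein=protein.loc[shared])


def _pair_corr(a: np.ndarray, b: np.ndarray, min_obs: int = 3) -> float:
    mask = ~np.isnan(a) & ~np.isnan(b)
    if mask.sum() < min_obs:
        return np.nan
    x, y = a[mask], b[mask]
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def stratified_pair_correlations(
    panel: TissuePanel,
    pairs: pd.DataFrame,
    mrna_band: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Across-tissue correlations per (controller, controlled) pair.

    ``pairs`` needs columns controller / controlled / fdr_class, where
    fdr_class stratifies by association strength (e.g. nonsig / sig /
    highsig).  For each pair measured in the panel, three Pearson
    correlations are computed over complete tissue pairs:
    protein-protein, mRNA-mRNA, and mRNA-protein of the controlled gene.
    Pairs with fewer than 3 complete observations are skipped; with
    ``mrna_band`` set, only pairs whose mRNA-mRNA correlation falls inside
    the (inclusive) band are retained.
    """
    rows = []
    prot = panel.protein
    mrna = panel.mrna
    for x, y, klass in zip(pairs["controller"], pairs["controlled"], pairs["fdr_class"]):
        if x not in prot.index or y not in prot.index:
            continue
        r_pp = _pair_corr(prot.loc[x].to_numpy(float), prot.loc[y].to_numpy(float))
        r_mm = _pair_corr(mrna.loc[x].to_numpy(float), mrna.loc[y].to_numpy(float))
        r_mp = _pair_corr(mrna.loc[y].to_numpy(float), prot.loc[y].to_numpy(float))
        if np.isnan(r_pp) or np.isnan(r_mm) or np.isnan(r_mp):
            continue
        rows.append((x, y, klass, r_pp, r_mm, r_mp))
    out = pd.DataFrame(
        rows,
        columns=[
            "controller",
            "controlled",
            "fdr_class",
            "r_protein_protein",
            "r_mrna_mrna",
            "r_mrna_protein_controlled",
        ],
    )
    if mrna_band is not None and len(out):
        lo, hi = mrna_band
        out = out[(out["r_mrna_mrna"] >= lo) & (out["r_mrna_mrna"] <= hi)]
        out = out.reset_index(drop=True)
    return out


def compare_correlation_strata(
    correlations: pd.DataFrame, value_column: str = "r_protein_protein"
) -> pd.DataFrame:
    """Wilcoxon rank-sum comparison of a correlation measure across strata."""
    return compare_groups(
        correlations[value_column], correlations["fdr_class"].astype(str)
    )
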