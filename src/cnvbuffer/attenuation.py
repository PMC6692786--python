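"""Per-gene dosage-attenuation potentials, mixture-model classification,
complex enrichment, and the group-comparison utilities built on them.

The attenuation potential of a gene is the difference between the Pearson
correlation of its copy number with its mRNA and with its protein:
large positive values flag genes whose dosage changes reach the
transcriptome but are buffered at the protein level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve
from sklearn.mixture import GaussianMixture

from .cohort import OmicsCohort

NON = "non_attenuated"
LOW = "low_attenuated"
HIGH = "high_attenuated"
CLASS_ORDER = (NON, LOW, HIGH)


@dataclass(frozen=True)
class AttenuationRecord:
    gene: str
    r_cnv_mrna: float
    r_cnv_protein: float
    n_used: int
    potential: float
    attenuation_class: str | None = None


def _pairwise_pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Pearson r over pairwise-complete entries; (nan, n) if degenerate."""
    mask = ~np.isnan(a) & ~np.isnan(b)
    n = int(mask.sum())
    if n < 2:
        return np.nan, n
    x, y = a[mask], b[mask]
    if x.std() == 0 or y.std() == 0:
        return np.nan, n
    return float(np.corrcoef(x, y)[0, 1]), n


def compute_attenuation(
    cohort: OmicsCohort, min_pairs: int = 20
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attenuation potential per gene present in CNV, mRNA and protein.

    Correlations use pairwise-complete samples.  Genes with fewer than
    ``min_pairs`` complete pairs (in either correlation) or with constant
    CNV are excluded; exclusions are returned, not raised.

    Returns ``(records, excluded)`` where ``records`` has columns
    gene / r_cnv_mrna / r_cnv_protein / n_used / potential and
    ``excluded`` has columns gene / reason.
    """
    genes = [
        g
        for g in cohort.cnv.columns
        if g in cohort.mrna.columns and g in cohort.protein.columns
    ]
    rows, excluded = [], []
    cnv = cohort.cnv[genes].to_numpy(dtype=float)
    mrna = cohort.mrna[genes].to_numpy(dtype=float)
    prot = cohort.protein[genes].to_numpy(dtype=float)
    for j, g in enumerate(genes):
        r_cm, n_cm = _pairwise_pearson(cnv[:, j], mrna[:, j])
        r_cp, n_cp = _pairwise_pearson(cnv[:, j], prot[:, j])
        n_used = min(n_cm, n_cp)
        if np.isnan(r_cm) or np.isnan(r_cp):
            excluded.append((g, "constant_predictor"))
            continue
        if n_used < min_pairs:
            excluded.append((g, "insufficient_pairs"))
            continue
        rows.append((g, r_cm, r_cp, n_used, r_cm - r_cp))
    records = pd.DataFrame(
        rows, columns=["gene", "r_cnv_mrna", "r_cnv_protein", "n_used", "potential"]
    )
    excl = pd.DataFrame(excluded, columns=["gene", "reason"])
    return records, excl


def classify_attenuation(
    potentials: pd.Series,
    n_components: int = 4,
    seed: int = 0,
    n_init: int = 50,
    tol: float = 1e-8,
) -> tuple[pd.Series, GaussianMixture]:
    """Cluster attenuation potentials with a 1-D Gaussian mixture.

    A mixture with ``n_components`` components (distinct means and
    variances) is fitted by EM with k-means++ initialization and
    ``n_init`` restarts.  Components are ordered by mean and reduced to
    the three attenuation classes in two steps: every negative-mean
    component is first merged into the lowest nonnegative-mean component
    (a gene whose protein tracks copy number better than its mRNA is not
    attenuated); while more than three groups remain, the adjacent pair
    with the smallest mean separation relative to the pooled component
    spread is merged, so the surplus component is absorbed by whichever
    cluster it subdivides.  Groups are labelled non / low / high
    attenuated by ascending mean; assignment is by maximum posterior
    responsibility.
    """
    x = potentials.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("potentials must be complete")
    if len(x) < n_components * 10:
        raise ValueError(
            f"need at least {n_components * 10} genes to fit {n_components} components"
        )
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: all potentials equal")
    gmm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        tol=tol,
        n_init=n_init,
        init_params="k-means++",
        max_iter=500,
        random_state=seed,
    )
    gmm.fit(x[:, None])
    if not gmm.converged_:
        raise RuntimeError("Gaussian mixture EM did not converge")
    means = gmm.means_.ravel()
    variances = gmm.covariances_.reshape(-1)
    weights = gmm.weights_.ravel()
    order = np.argsort(means)
    # groups of component indices, ordered by mean
    groups: list[list[int]] = [[int(k)] for k in order]
    negative = [g for g in groups if means[g[0]] < 0]
    nonneg = [g for g in groups if means[g[0]] >= 0]
    if negative and nonneg:
        merged = [k for g in negative for k in g] + nonneg[0]
        groups = [merged] + nonneg[1:]
    elif negative:
        groups = [[k for g in negative for k in g]]

    def moments(g: list[int]) -> tuple[float, float]:
        w = weights[g]
        m = float(np.average(means[g], weights=w))
        v = float(np.average(variances[g] + (means[g] - m) ** 2, weights=w))
        return m, v

    while len(groups) > 3:
        stats_ = [moments(g) for g in groups]
        gaps = [
            abs(stats_[i + 1][0] - stats_[i][0])
            / np.sqrt(stats_[i][1] + stats_[i + 1][1])
            for i in range(len(groups) - 1)
        ]
        j = int(np.argmin(gaps))
        groups = groups[:j] + [groups[j] + groups[j + 1]] + groups[j + 2 :]
    labels_by_group = {
        1: (NON,),
        2: (NON, HIGH),
        3: (NON, LOW, HIGH),
    }[len(groups)]
    label_of = {
        k: lab for g, lab in zip(groups, labels_by_group) for k in g
    }
    comp = gmm.predict(x[:, None])
    labels = pd.Series(
        [label_of[k] for k in comp], index=potentials.index, name="attenuation_class"
    )
    return labels, gmm


def jaccard_deduplicate(
    complexes: dict[str, frozenset[str]] | dict[str, set[str]],
    max_jaccard: float = 0.9,
) -> dict[str, frozenset[str]]:
    """Greedy near-duplicate removal: complexes are processed in descending
    size (ties by name) and a complex is dropped if its Jaccard index with
    any already-kept complex is >= ``max_jaccard``."""
    ordered = sorted(complexes.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    kept: dict[str, frozenset[str]] = {}
    for name, members in ordered:
        members = frozenset(members)
        dup = any(
            len(members & other) / len(members | other) >= max_jaccard
            for other in kept.values()
        )
        if not dup:
            kept[name] = members
    return kept


def enrich_complexes(
    attenuated: set[str],
    complexes: dict[str, frozenset[str]] | dict[str, set[str]],
    universe: set[str],
    min_size: int = 6,
    max_jaccard: float = 0.9,
) -> pd.DataFrame:
    """Hypergeometric enrichment of each complex in the attenuated gene set.

    Complexes are first deduplicated by the greedy Jaccard filter and
    restricted to more than five members (``min_size=6``) within the
    universe.  The p-value is the one-sided upper tail of the
    hypergeometric distribution; FDR is Benjamini-Hochberg.
    """
    if not universe:
        raise ValueError("empty universe")
    att = attenuated & universe
    kept = jaccard_deduplicate(complexes, max_jaccard)
    rows = []
    for name, members in kept.items():
        members_u = frozenset(members) & universe
        if len(members_u) < min_size:
            continue
        overlap = len(members_u & att)
        p = float(
            stats.hypergeom.sf(overlap - 1, len(universe), len(att), len(members_u))
        )
        rows.append((name, len(members_u), overlap, p))
    table = pd.DataFrame(rows, columns=["complex", "size", "overlap", "p"])
    if len(table):
        from .associations import benjamini_hochberg

        table["fdr"] = benjamini_hochberg(table["p"].to_numpy())
        table = table.sort_values("p", kind="mergesort").reset_index(drop=True)
    else:
        table["fdr"] = pd.Series(dtype=float)
    return table


def roc_pair_prediction(
    labels: np.ndarray | pd.Series, scores: np.ndarray | pd.Series
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC for predicting complex co-membership of a pair from an
    abundance-profile correlation score; returns (fpr, tpr, auc)."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(y, s)
    return fpr, tpr, float(_auc(fpr, tpr))


def compare_groups(
    values: pd.Series, labels: pd.Series, exact_max_n: int = 25
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests between label groups.

    Exact enumeration is used when both groups have at most
    ``exact_max_n`` observations and no ties straddle the groups;
    otherwise the normal approximation with tie correction applies.
    """
    values, labels = values.align(labels, join="inner")
    groups = {k: values[labels == k].dropna().to_numpy() for k in labels.unique()}
    for k, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            va, vb = groups[a], groups[b]
            small = len(va) <= exact_max_n and len(vb) <= exact_max_n
            has_ties = len(np.unique(np.concatenate([va, vb]))) < len(va) + len(vb)
            method = "exact" if small and not has_ties else "asymptotic"
            res = stats.mannwhitneyu(va, vb, alternative="two-sided", method=method)
            rows.append((a, b, len(va), len(vb), float(res.statistic), float(res.pvalue)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b", "u", "p"])
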