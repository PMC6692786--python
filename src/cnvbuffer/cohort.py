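"""The multi-omics cohort container shared by all analysis stages."""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GISTIC_LEVELS = (-2, -1, 0, 1, 2)

_SITE_RE = re.compile(r"^(?P<gene>.+)_(?P<residue>[STY]\d+)$")


def site_to_gene(site_id: str) -> str:
    """Map a phosphosite id like ``GENE12_S492`` to its parent gene."""
    m = _SITE_RE.match(site_id)
    if m is None:
        raise ValueError(f"malformed phosphosite id: {site_id!r}")
    return m.group("gene")


@dataclass
class OmicsCohort:
    """Aligned sample x feature matrices plus per-sample covariates.

    All omics matrices are oriented samples x features (rows = samples).
    ``cnv`` holds discretized GISTIC scores in {-2,-1,0,1,2}; ``mrna`` and
    ``protein`` are log-scale abundances (may contain NaN); ``phospho`` is
    indexed by site ids of the form ``<gene>_<residue><position>``.
    ``covariates`` carries cancer_type, batch, technology (categorical),
    age (numeric) and gender (categorical).
    """

    cnv: pd.DataFrame
    mrna: pd.DataFrame
    protein: pd.DataFrame
    phospho: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        samples = self.cnv.index
        for name in ("mrna", "protein", "phospho", "covariates"):
            other = getattr(self, name)
            if not other.index.equals(samples):
                raise ValueError(f"sample axis of {name!r} does not match cnv")
        observed = self.cnv.to_numpy()
        ok = np.isin(observed[~np.isnan(observed)], GISTIC_LEVELS)
        if not ok.all():
            raise ValueError("cnv matrix contains values outside GISTIC levels")
        for site in self.phospho.columns:
            gene = site_to_gene(site)
            if gene not in self.protein.columns:
                raise ValueError(f"phosphosite {site!r} has no parent protein column")

    @property
    def samples(self) -> pd.Index:
        return self.cnv.index

    @property
    def genes(self) -> pd.Index:
        return self.cnv.columns

    # --- persistence ------------------------------------------------------
    def to_dir(self, path: str | Path) -> None:
        """Write the cohort as TSVs (features as rows, samples as columns)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name in ("cnv", "mrna", "protein", "phospho"):
            getattr(self, name).T.to_csv(path / f"{name}.tsv", sep="\t", na_rep="NA")
        self.covariates.to_csv(path / "covariates.tsv", sep="\t", na_rep="NA")

    @classmethod
    def from_dir(cls, path: str | Path) -> "OmicsCohort":
        path = Path(path)
        mats = {
            name: pd.read_csv(path / f"{name}.tsv", sep="\t", index_col=0).T
            for name in ("cnv", "mrna", "protein", "phospho")
        }
        cov = pd.read_csv(path / "covariates.tsv", sep="\t", index_col=0)
        for c in ("cancer_type", "batch", "technology", "gender"):
            if c in cov:
                cov[c] = cov[c].astype(str)
        return cls(covariates=cov, **mats)
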