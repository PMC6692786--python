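"""Solvent accessibility, interface extraction and interface-size metrics.

SASA is computed with the Shrake-Rupley method: a fixed quasi-uniform
point sphere is placed on every atom at radius (r_vdw + probe) and a point
counts as accessible when it lies outside every other inflated atom
sphere.  A residue belongs to an interface when its relative SASA changes
between the bound complex and the isolated chain.  Because the sphere
points are fixed, per-residue SASA in the complex is exactly bounded above
by the isolated-chain SASA (adding atoms can only occlude points).

Hydrogens and hetero atoms (waters, ligands) are stripped before any
computation, following the convention of standard accessibility tools.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

# single-sphere van der Waals radii by element (Angstrom)
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "H": 1.20,
}
DEFAULT_RADIUS = 1.70

# theoretical maximum accessible surface areas per residue type (A^2),
# used to convert absolute to relative SASA
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLU": 223.0, "GLN": 225.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


@dataclass
class StructureModel:
    """Atoms of one (possibly multi-chain) structure.

    ``chain_proteins`` maps chain id to the protein identity of that
    chain; when absent, the chain id doubles as the protein id.
    """

    structure_id: str
    chain_ids: np.ndarray  # (n,) str
    res_ids: np.ndarray  # (n,) int
    res_names: np.ndarray  # (n,) str
    elements: np.ndarray  # (n,) str
    coords: np.ndarray  # (n, 3) float, Angstrom
    radii: np.ndarray  # (n,) float, Angstrom
    chain_proteins: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.coords) == 0:
            raise ValueError("structure has no atoms")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        if (self.radii <= 0).any():
            raise ValueError("radii must be positive")

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for c in self.chain_ids:
            if c not in seen:
                seen.append(c)
        return seen

    def protein_of(self, chain: str) -> str:
        return self.chain_proteins.get(chain, chain)

    def subset(self, chain: str) -> "StructureModel":
        mask = self.chain_ids == chain
        if not mask.any():
            raise KeyError(f"no chain {chain!r} in {self.structure_id}")
        return StructureModel(
            structure_id=f"{self.structure_id}:{chain}",
            chain_ids=self.chain_ids[mask],
            res_ids=self.res_ids[mask],
            res_names=self.res_names[mask],
            elements=self.elements[mask],
            coords=self.coords[mask],
            radii=self.radii[mask],
            chain_proteins=dict(self.chain_proteins),
        )

    def chain_lengths(self) -> dict[str, int]:
        return {
            c: len(set(self.res_ids[self.chain_ids == c].tolist()))
            for c in self.chains
        }


def read_pdb(
    source: str | Path,
    structure_id: str | None = None,
    chain_proteins: dict[str, str] | None = None,
) -> StructureModel:
    """Parse ATOM records of a PDB file (path or literal text) into a model.

    Hydrogens, hetero atoms and alternate locations other than ''/'A' are
    discarded; insertion codes are folded into the residue numbering order.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    text: str
    path = Path(str(source))
    if "\n" in str(source) or not path.exists():
        if "\n" not in str(source):
            raise FileNotFoundError(source)
        text = str(source)
        sid = structure_id or "structure"
    else:
        text = path.read_text()
        sid = structure_id or path.stem
    pdb = PDBFile.read(io.StringIO(text))
    atoms = pdb.get_structure(model=1, altloc="first")
    keep = ~atoms.hetero & (atoms.element != "H")
    atoms = atoms[keep]
    if atoms.array_length() == 0:
        raise ValueError(f"{sid}: no protein atoms")
    # renumber through insertion codes so residue keys stay ordered
    res_starts = struc.get_residue_starts(atoms)
    res_index = np.zeros(atoms.array_length(), dtype=int)
    res_index[res_starts] = 1
    res_index = np.cumsum(res_index) - 1
    res_ids = atoms.res_id[res_starts][
        res_index
    ]  # original numbering, per renumbered residue
    radii = np.array([VDW_RADII.get(e.upper(), DEFAULT_RADIUS) for e in atoms.element])
    return StructureModel(
        structure_id=sid,
        chain_ids=atoms.chain_id.astype(str),
        res_ids=res_ids.astype(int),
        res_names=atoms.res_name.astype(str),
        elements=atoms.element.astype(str),
        coords=atoms.coord.astype(float),
        radii=radii,
        chain_proteins=dict(chain_proteins or {}),
    )


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA
# ---------------------------------------------------------------------------


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def atom_sasa(
    model: StructureModel, probe_radius: float = 1.4, n_sphere_points: int = 960
) -> np.ndarray:
    """Per-atom solvent accessible surface area (A^2)."""
    pts = _sphere_points(n_sphere_points)
    coords = model.coords
    r_ext = model.radii + probe_radius
    tree = cKDTree(coords)
    max_ext = r_ext.max()
    out = np.empty(len(coords))
    for i in range(len(coords)):
        sphere = coords[i] + r_ext[i] * pts
        neigh = tree.query_ball_point(coords[i], r_ext[i] + max_ext)
        neigh = [
            j
            for j in neigh
            if j != i
            and np.dot(coords[j] - coords[i], coords[j] - coords[i])
            < (r_ext[i] + r_ext[j]) ** 2
        ]
        if neigh:
            d2 = ((sphere[:, None, :] - coords[neigh][None, :, :]) ** 2).sum(axis=2)
            accessible = (d2 >= (r_ext[neigh] ** 2)[None, :]).all(axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        out[i] = frac * 4.0 * np.pi * r_ext[i] ** 2
    return out


def compute_sasa(
    model: StructureModel, probe_radius: float = 1.4, n_sphere_points: int = 960
) -> pd.DataFrame:
    """Per-residue SASA and relative SASA.

    Returns a DataFrame with columns chain / res_id / res_name / sasa /
    rel_sasa.  Residue types absent from the reference maximum-ASA table
    get NaN relative SASA (with a warning) and must be judged on absolute
    areas.
    """
    per_atom = atom_sasa(model, probe_radius, n_sphere_points)
    df = pd.DataFrame(
        {
            "chain": model.chain_ids,
            "res_id": model.res_ids,
            "res_name": model.res_names,
            "sasa": per_atom,
        }
    )
    res = (
        df.groupby(["chain", "res_id", "res_name"], sort=True)["sasa"]
        .sum()
        .reset_index()
    )
    unknown = sorted(set(res["res_name"]) - set(MAX_ASA))
    if unknown:
        warnings.warn(
            f"no maximum-ASA reference for residue type(s) {unknown}; "
            "relative SASA left undefined",
            stacklevel=2,
        )
    res["rel_sasa"] = [
        s / MAX_ASA[rn] if rn in MAX_ASA else np.nan
        for s, rn in zip(res["sasa"], res["res_name"])
    ]
    return res


@dataclass
class InterfaceSummary:
    """Interface residues and burial per chain of one complex structure."""

    structure_id: str
    interface_residues: dict[str, set[int]]
    buried_fraction: dict[str, float]

    @property
    def interface_size_per_chain(self) -> dict[str, int]:
        return {c: len(r) for c, r in self.interface_residues.items()}

    @property
    def interface_size_total(self) -> int:
        return sum(len(r) for r in self.interface_residues.values())


def extract_interface(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    tolerance: float = 1e-4,
    abs_tolerance: float = 0.01,
) -> InterfaceSummary:
    """Interface residues from the bound-vs-unbound accessibility change.

    Relative SASA is computed for every residue in the full complex and in
    each chain isolated (all other chains deleted); a residue joins the
    interface when the relative SASA changes by more than ``tolerance``
    (``abs_tolerance``, in A^2, for residue types without a reference
    maximum area).  Buried fraction per chain is
    (SASA_unbound - SASA_bound) / SASA_unbound over whole-chain totals.
    """
    chains = model.chains
    if len(chains) < 2:
        raise ValueError("interface extraction needs at least 2 chains")
    bound = compute_sasa(model, probe_radius, n_sphere_points)
    interface: dict[str, set[int]] = {}
    buried: dict[str, float] = {}
    for chain in chains:
        unbound = compute_sasa(model.subset(chain), probe_radius, n_sphere_points)
        unbound["chain"] = chain
        b = bound[bound["chain"] == chain].set_index("res_id")
        u = unbound.set_index("res_id")
        resids = u.index
        rel_change = (u["rel_sasa"] - b.loc[resids, "rel_sasa"]).abs()
        abs_change = (u["sasa"] - b.loc[resids, "sasa"]).abs()
        changed = np.where(
            rel_change.notna(), rel_change > tolerance, abs_change > abs_tolerance
        )
        interface[chain] = set(resids[changed].tolist())
        total_unbound = float(u["sasa"].sum())
        total_bound = float(b["sasa"].sum())
        if total_unbound <= 0:
            raise ValueError(f"zero unbound SASA for chain {chain}")
        buried[chain] = (total_unbound - total_bound) / total_unbound
    return InterfaceSummary(
        structure_id=model.structure_id,
        interface_residues=interface,
        buried_fraction=buried,
    )


def buried_fraction(summary: InterfaceSummary, chain: str) -> float:
    """(SASA outside complex - SASA inside complex) / SASA outside complex."""
    return summary.buried_fraction[chain]


# ---------------------------------------------------------------------------
# structure-level QC and metrics
# ---------------------------------------------------------------------------


def filter_structures(
    structures: list[StructureModel],
    uniprot_lengths: dict[str, int],
    min_total_residues: int = 100,
) -> tuple[list[StructureModel], pd.DataFrame]:
    """QC filter for binary-complex models.

    Drops homodimers, structures with fewer than ``min_total_residues``
    residues in total, structures with any chain longer than its UniProt
    protein length, two-chain structures whose chains have equal length,
    and structures whose protein ids have no known length.
    Returns (kept, dropped) where dropped lists structure_id / reason.
    """
    kept, dropped = [], []
    for model in structures:
        lengths = model.chain_lengths()
        proteins = [model.protein_of(c) for c in model.chains]
        if len(proteins) >= 2 and len(set(proteins)) == 1:
            dropped.append((model.structure_id, "homodimer"))
            continue
        if sum(lengths.values()) < min_total_residues:
            dropped.append((model.structure_id, "too_few_residues"))
            continue
        unknown = [p for p in proteins if p not in uniprot_lengths]
        if unknown:
            dropped.append((model.structure_id, f"unknown_protein:{unknown[0]}"))
            continue
        too_long = [
            c
            for c in model.chains
            if lengths[c] > uniprot_lengths[model.protein_of(c)]
        ]
        if too_long:
            dropped.append((model.structure_id, "chain_exceeds_uniprot_length"))
            continue
        if len(model.chains) == 2 and len(set(lengths.values())) == 1:
            dropped.append((model.structure_id, "equal_chain_lengths"))
            continue
        kept.append(model)
    return kept, pd.DataFrame(dropped, columns=["structure_id", "reason"])


def interface_fraction(
    protein: str,
    summaries: list[tuple[StructureModel, InterfaceSummary]],
    protein_length: int,
) -> float:
    """Unique interface residues of a protein across structures / protein length."""
    if protein_length <= 0:
        raise ValueError("protein length must be positive")
    residues: set[tuple[str, int]] = set()
    for model, summary in summaries:
        for chain, resids in summary.interface_residues.items():
            if model.protein_of(chain) == protein:
                residues.update((protein, r) for r in resids)
    frac = len(residues) / protein_length
    if frac > 1.0:
        warnings.warn(
            f"interface residue union exceeds length for {protein}; capped at 1",
            stacklevel=2,
        )
        frac = 1.0
    return frac


def correlate_interface_with_stats(
    table: pd.DataFrame,
    size_column: str = "interface_size",
    beta_column: str = "beta7",
    fdr_column: str = "fdr",
) -> dict[str, tuple[float, float]]:
    """Pearson correlation of interface size with the association statistics.

    Returns {'beta': (r, p), 'neg_log10_fdr': (r, p)} over rows with
    complete values; the FDR enters as -log10(FDR).
    """
    sub = table[[size_column, beta_column, fdr_column]].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 paired observations")
    size = sub[size_column].to_numpy(dtype=float)
    out = {}
    for key, vec in (
        ("beta", sub[beta_column].to_numpy(dtype=float)),
        ("neg_log10_fdr", -np.log10(sub[fdr_column].to_numpy(dtype=float))),
    ):
        if np.std(size) == 0 or np.std(vec) == 0:
            raise ValueError("constant vector in correlation")
        r, p = stats.pearsonr(size, vec)
        out[key] = (float(r), float(p))
    return out
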