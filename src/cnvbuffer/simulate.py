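"""Synthetic multi-omics cohorts with known dosage-buffering ground truth.

The generative model encodes the assumptions the downstream analyses test:
gene dosage (discretized copy number) propagates linearly to mRNA; for most
genes protein tracks its own mRNA, while for *attenuated* genes the protein
level is partially set by the realized protein abundance of a controlling
complex partner (buffering).  Confounders (cancer type, batch, technology,
age, gender) act additively on the log scale; controller pairs can be
placed in genomic co-localization blocks with correlated copy number; a
fraction of controlling proteins carry a regulatory phosphosite whose
abundance feeds into the controlled partner's protein level.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import GISTIC_LEVELS, OmicsCohort

CANCER_TYPES = ("BRCA", "COREAD", "OV")
BATCHES = ("B1", "B2", "B3", "B4")
TECHNOLOGIES = ("TMT", "LabelFree")
GENDERS = ("F", "M")

DEFAULT_COVARIATE_EFFECT_SDS = {
    "cancer_type": 0.3,
    "batch": 0.2,
    "technology": 0.2,
    "age": 0.1,
    "gender": 0.1,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    ``buffering_strength_high``/``_low`` give the mixing weight b of the
    controller's protein in a controlled gene's protein level (1 = protein
    fully tracks the controller, 0 = tracks its own mRNA).
    ``frac_high_within_attenuated`` splits the attenuated set into the
    high- and low-buffering classes.
    """

    n_samples: int = 368
    n_genes: int = 2000
    n_complexes: int = 140
    complex_size_range: tuple[int, int] = (4, 12)
    frac_attenuated: float = 0.42
    frac_high_within_attenuated: float = 0.25
    buffering_strength_high: float = 0.8
    buffering_strength_low: float = 0.4
    cnv_level_probs: tuple[float, ...] = (0.05, 0.20, 0.50, 0.20, 0.05)
    mrna_dosage_slope: float = 1.0
    noise_sd_mrna: float = 0.5
    noise_sd_protein: float = 0.5
    noise_sd_phospho: float = 0.5
    covariate_effect_sds: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECT_SDS)
    )
    n_chromosomes: int = 22
    colocalization_block_size: int = 5
    cnv_block_coupling: float = 0.9
    frac_colocalized_controllers: float = 0.05
    frac_phospho_regulatory: float = 0.2
    frac_genes_with_phospho: float = 0.3
    phospho_effect: float = 0.4
    missing_rate_protein: float = 0.10
    missing_rate_phospho: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.cnv_level_probs, dtype=float)
        if probs.shape != (5,) or (probs < 0).any() or abs(probs.sum() - 1) > 1e-9:
            raise ValueError("cnv_level_probs must be 5 nonnegative values summing to 1")
        for name in (
            "frac_attenuated",
            "frac_high_within_attenuated",
            "buffering_strength_high",
            "buffering_strength_low",
            "cnv_block_coupling",
            "frac_colocalized_controllers",
            "frac_phospho_regulatory",
            "frac_genes_with_phospho",
            "missing_rate_protein",
            "missing_rate_phospho",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.complex_size_range
        if lo < 2 or hi < lo:
            raise ValueError("complex_size_range must be (min, max) with 2 <= min <= max")
        for name in ("noise_sd_mrna", "noise_sd_protein", "noise_sd_phospho"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_samples < 2 or self.n_genes < 2:
            raise ValueError("need at least 2 samples and 2 genes")


class SizingError(ValueError):
    """Raised when n_genes cannot accommodate the requested complex demand."""


@dataclass
class GroundTruth:
    """Hidden parameters of a simulated cohort, the recovery target.

    ``classes`` maps every gene to non/low/high attenuation; ``edges`` are
    (controller, controlled, true beta) triples; ``phospho_regulators`` are
    (site id, controlled gene, true beta) triples.
    """

    classes: dict[str, str]
    edges: list[tuple[str, str, float]]
    phospho_regulators: list[tuple[str, str, float]]
    gene_chromosome: dict[str, str]
    gene_position: dict[str, int]
    complexes: list[frozenset[str]]

    def __post_init__(self) -> None:
        controlled = {y for _, y, _ in self.edges}
        attenuated = {g for g, c in self.classes.items() if c != "non"}
        if attenuated - controlled:
            raise ValueError("every attenuated gene must have a controlling edge")

    @property
    def attenuated_fraction(self) -> float:
        n = len(self.classes)
        return sum(c != "non" for c in self.classes.values()) / n

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classes": self.classes,
            "edges": [[x, y, b] for x, y, b in self.edges],
            "phospho_regulators": [[s, y, b] for s, y, b in self.phospho_regulators],
            "gene_chromosome": self.gene_chromosome,
            "gene_position": self.gene_position,
            "complexes": [sorted(c) for c in self.complexes],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            classes=d["classes"],
            edges=[(x, y, float(b)) for x, y, b in d["edges"]],
            phospho_regulators=[(s, y, float(b)) for s, y, b in d["phospho_regulators"]],
            gene_chromosome=d["gene_chromosome"],
            gene_position={g: int(p) for g, p in d["gene_position"].items()},
            complexes=[frozenset(c) for c in d["complexes"]],
        )


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------


def _draw_covariates(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_samples
    samples = [f"S{i:04d}" for i in range(n)]
    return pd.DataFrame(
        {
            "cancer_type": rng.choice(CANCER_TYPES, n),
            "batch": rng.choice(BATCHES, n),
            "technology": rng.choice(TECHNOLOGIES, n),
            "age": np.round(rng.normal(60.0, 10.0, n), 1),
            "gender": rng.choice(GENDERS, n),
        },
        index=pd.Index(samples, name="sample"),
    )


def _covariate_effects(
    cfg: SimulationConfig,
    covariates: pd.DataFrame,
    n_genes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Additive per-sample, per-gene covariate contribution (samples x genes)."""
    n = len(covariates)
    total = np.zeros((n, n_genes))
    sds = cfg.covariate_effect_sds
    for col, levels in (
        ("cancer_type", CANCER_TYPES),
        ("batch", BATCHES),
        ("technology", TECHNOLOGIES),
        ("gender", GENDERS),
    ):
        sd = sds.get(col, 0.0)
        level_eff = rng.normal(0.0, sd, (len(levels), n_genes)) if sd > 0 else np.zeros(
            (len(levels), n_genes)
        )
        lookup = {lev: i for i, lev in enumerate(levels)}
        idx = np.array([lookup[v] for v in covariates[col]])
        total += level_eff[idx]
    sd_age = sds.get("age", 0.0)
    if sd_age > 0:
        age_z = (covariates["age"].to_numpy() - 60.0) / 10.0
        coef = rng.normal(0.0, sd_age, n_genes)
        total += np.outer(age_z, coef)
    return total


def _layout_genome(
    cfg: SimulationConfig,
    genes: list[str],
    coloc_pairs: list[tuple[str, str]],
    rng: np.random.Generator,
) -> tuple[dict[str, str], dict[str, int], np.ndarray]:
    """Assign genes to chromosome positions; co-localized pairs get adjacent slots.

    Returns (gene->chromosome, gene->position, block id per gene index).
    """
    n = len(genes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    slots = np.full(n, -1, dtype=int)  # gene index occupying each genomic slot
    block_size = max(cfg.colocalization_block_size, 2)
    n_blocks = int(np.ceil(n / block_size))
    # place each co-localized pair at the start of its own block
    free_blocks = list(rng.permutation(n_blocks))
    placed: set[int] = set()
    for x, y in coloc_pairs:
        ix, iy = gene_idx[x], gene_idx[y]
        if ix in placed or iy in placed or not free_blocks:
            continue
        b = free_blocks.pop()
        start = b * block_size
        if start + 1 >= n or slots[start] != -1 or slots[start + 1] != -1:
            continue
        slots[start], slots[start + 1] = ix, iy
        placed.update((ix, iy))
    remaining = [i for i in range(n) if i not in placed]
    rng.shuffle(remaining)
    empty = np.flatnonzero(slots == -1)
    slots[empty] = remaining
    # invert: gene index -> slot
    position_of = np.empty(n, dtype=int)
    position_of[slots] = np.arange(n)
    per_chrom = int(np.ceil(n / cfg.n_chromosomes))
    chrom = {g: f"chr{position_of[i] // per_chrom + 1}" for g, i in gene_idx.items()}
    pos = {g: int(position_of[i]) for g, i in gene_idx.items()}
    block_of_gene = position_of // block_size
    return chrom, pos, block_of_gene


def simulate_cohort(config: SimulationConfig) -> tuple[OmicsCohort, GroundTruth]:
    """Generate one cohort and its ground truth, reproducibly from the seed.

    Raises :class:`SizingError` when the complex membership demand exceeds
    ``n_genes``, or when too few complex-member genes are available to host
    the requested attenuated fraction.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]

    # --- complexes and attenuation classes --------------------------------
    lo, hi = cfg.complex_size_range
    sizes = rng.integers(lo, hi + 1, cfg.n_complexes)
    if sizes.sum() > cfg.n_genes:
        raise SizingError(
            f"complex demand {int(sizes.sum())} exceeds n_genes={cfg.n_genes}"
        )
    shuffled = list(rng.permutation(genes))
    complexes: list[frozenset[str]] = []
    cursor = 0
    for s in sizes:
        complexes.append(frozenset(shuffled[cursor : cursor + int(s)]))
        cursor += int(s)

    # one designated controller per complex; other members may be attenuated
    controllers = {}
    candidates: list[str] = []
    for cx in complexes:
        members = sorted(cx)
        ctrl = members[int(rng.integers(len(members)))]
        controllers[cx] = ctrl
        candidates.extend(m for m in members if m != ctrl)
    n_att = int(round(cfg.frac_attenuated * cfg.n_genes))
    if n_att > len(candidates):
        raise SizingError(
            f"{n_att} attenuated genes requested but only {len(candidates)} "
            "complex members are available as candidates"
        )
    attenuated = list(rng.choice(candidates, n_att, replace=False))
    n_high = int(round(cfg.frac_high_within_attenuated * n_att))
    high = set(rng.choice(attenuated, n_high, replace=False)) if n_high else set()
    low = set(attenuated) - high
    classes = {g: "high" if g in high else "low" if g in low else "non" for g in genes}

    controller_of: dict[str, str] = {}
    for cx in complexes:
        for m in cx:
            if classes[m] != "non":
                controller_of[m] = controllers[cx]
    edges = [
        (
            controller_of[y],
            y,
            (cfg.buffering_strength_high if classes[y] == "high" else cfg.buffering_strength_low)
            * cfg.mrna_dosage_slope,
        )
        for y in attenuated
    ]

    # --- genome layout with co-localized controller pairs -----------------
    n_coloc = int(round(cfg.frac_colocalized_controllers * len(edges)))
    coloc_idx = rng.choice(len(edges), n_coloc, replace=False) if n_coloc else []
    coloc_edges = [(edges[i][0], edges[i][1]) for i in coloc_idx]
    chrom, pos, block_of_gene = _layout_genome(cfg, genes, coloc_edges, rng)

    # --- copy number -------------------------------------------------------
    levels = np.array(GISTIC_LEVELS)
    n_blocks = int(block_of_gene.max()) + 1
    block_cnv = rng.choice(levels, size=(cfg.n_samples, n_blocks), p=cfg.cnv_level_probs)
    own_cnv = rng.choice(levels, size=(cfg.n_samples, cfg.n_genes), p=cfg.cnv_level_probs)
    use_block = rng.random((cfg.n_samples, cfg.n_genes)) < cfg.cnv_block_coupling
    cnv = np.where(use_block, block_cnv[:, block_of_gene], own_cnv)

    # --- covariates and expression -----------------------------------------
    covariates = _draw_covariates(cfg, rng)
    eff_mrna = _covariate_effects(cfg, covariates, cfg.n_genes, rng)
    eff_prot = _covariate_effects(cfg, covariates, cfg.n_genes, rng)

    mrna = (
        cfg.mrna_dosage_slope * cnv
        + eff_mrna
        + rng.normal(0.0, cfg.noise_sd_mrna, cnv.shape)
    )
    prot_noise = rng.normal(0.0, cfg.noise_sd_protein, cnv.shape)
    protein = mrna + eff_prot + prot_noise
    gi = {g: i for i, g in enumerate(genes)}
    for x, y, _b in edges:
        b = (
            cfg.buffering_strength_high
            if classes[y] == "high"
            else cfg.buffering_strength_low
        )
        protein[:, gi[y]] = (
            (1.0 - b) * mrna[:, gi[y]]
            + b * protein[:, gi[x]]
            + eff_prot[:, gi[y]]
            + prot_noise[:, gi[y]]
        )

    # --- phosphosites -------------------------------------------------------
    n_pho_genes = int(round(cfg.frac_genes_with_phospho * cfg.n_genes))
    pho_genes = set(rng.choice(genes, n_pho_genes, replace=False))
    n_reg = int(round(cfg.frac_phospho_regulatory * len(edges)))
    reg_idx = rng.choice(len(edges), n_reg, replace=False) if n_reg else []
    reg_edges = [edges[i] for i in reg_idx]
    pho_genes.update(x for x, _y, _b in reg_edges)
    pho_genes_sorted = sorted(pho_genes)
    residues = rng.choice(["S", "T", "Y"], len(pho_genes_sorted))
    positions = rng.integers(1, 999, len(pho_genes_sorted))
    site_of_gene = {
        g: f"{g}_{r}{p}" for g, r, p in zip(pho_genes_sorted, residues, positions)
    }
    site_ids = [site_of_gene[g] for g in pho_genes_sorted]
    site_noise = rng.normal(0.0, cfg.noise_sd_phospho, (cfg.n_samples, len(site_ids)))
    phospho = protein[:, [gi[g] for g in pho_genes_sorted]] + site_noise

    phospho_regulators: list[tuple[str, str, float]] = []
    si = {s: i for i, s in enumerate(site_ids)}
    for x, y, _b in reg_edges:
        site = site_of_gene[x]
        protein[:, gi[y]] = protein[:, gi[y]] + cfg.phospho_effect * phospho[:, si[site]]
        phospho_regulators.append((site, y, cfg.phospho_effect))

    # --- missingness (completely at random) ---------------------------------
    protein = np.where(
        rng.random(protein.shape) < cfg.missing_rate_protein, np.nan, protein
    )
    phospho = np.where(
        rng.random(phospho.shape) < cfg.missing_rate_phospho, np.nan, phospho
    )

    samples = covariates.index
    cohort = OmicsCohort(
        cnv=pd.DataFrame(cnv, index=samples, columns=genes),
        mrna=pd.DataFrame(mrna, index=samples, columns=genes),
        protein=pd.DataFrame(protein, index=samples, columns=genes),
        phospho=pd.DataFrame(phospho, index=samples, columns=site_ids),
        covariates=covariates,
    )
    truth = GroundTruth(
        classes=classes,
        edges=edges,
        phospho_regulators=phospho_regulators,
        gene_chromosome=chrom,
        gene_position=pos,
        complexes=complexes,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# tissue panel generator
# ---------------------------------------------------------------------------

TISSUES_14 = (
    "frontal_cortex",
    "spinal_cord",
    "liver",
    "ovary",
    "testis",
    "lung",
    "adrenal_gland",
    "pancreas",
    "kidney",
    "urinary_bladder",
    "prostate_gland",
    "heart",
    "esophagus",
    "colon",
)


def simulate_tissue_panel(
    config: SimulationConfig,
    ground_truth: GroundTruth,
    n_tissues: int = 14,
    noise_sd: float | None = None,
    missing_rate: float = 0.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x tissue mRNA and protein panels mirroring the cohort's buffering.

    Controlled genes' protein profiles follow the controller's mRNA profile
    with weight b (the gene's class buffering strength); all other proteins
    track their own mRNA.  Returns (mrna, protein) DataFrames.
    """
    rng = np.random.default_rng(config.seed + 104729 if seed is None else seed)
    sd = config.noise_sd_protein if noise_sd is None else noise_sd
    genes = sorted(ground_truth.classes)
    tissues = list(TISSUES_14[:n_tissues]) + [
        f"tissue_{i}" for i in range(len(TISSUES_14), n_tissues)
    ]
    gi = {g: i for i, g in enumerate(genes)}
    mrna = rng.standard_normal((len(genes), n_tissues))
    protein = mrna + rng.normal(0.0, sd, mrna.shape)
    for x, y, _beta in ground_truth.edges:
        b = (
            config.buffering_strength_high
            if ground_truth.classes[y] == "high"
            else config.buffering_strength_low
        )
        protein[gi[y]] = (
            (1.0 - b) * mrna[gi[y]]
            + b * mrna[gi[x]]
            + rng.normal(0.0, sd, n_tissues)
        )
    if missing_rate > 0:
        protein = np.where(rng.random(protein.shape) < missing_rate, np.nan, protein)
    idx = pd.Index(genes, name="gene")
    return (
        pd.DataFrame(mrna, index=idx, columns=tissues),
        pd.DataFrame(protein, index=idx, columns=tissues),
    )


# ---------------------------------------------------------------------------
# eQTL / LD / GWAS table generator
# ---------------------------------------------------------------------------


def simulate_eqtl_tables(
    config: SimulationConfig,
    ground_truth: GroundTruth,
    n_tissues: int = 10,
    mean_blocks_per_gene: float = 4.0,
    block_size_range: tuple[int, int] = (1, 4),
    base_tagging_prob: float = 0.4,
    tagging_factor_low: float = 1.0,
    tagging_factor_high: float = 0.5,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str], dict]:
    """Synthetic eQTL, LD and GWAS-catalogue tables with latent LD blocks.

    Variants of one gene are grouped into latent blocks; within-block LD
    r^2 > 0.8, across blocks r^2 <= 0.5.  Slope signs are consistent per
    block across a variable number of tissues.  A block's probability of
    being GWAS-tagged is ``base_tagging_prob`` multiplied by the class
    factor of its gene.  Returns (eqtl, ld, gwas, truth) where truth maps
    'blocks' -> {block id: [variants]} and 'tagged' -> set of block ids.
    """
    rng = np.random.default_rng(config.seed + 224737 if seed is None else seed)
    factors = {"non": 1.0, "low": tagging_factor_low, "high": tagging_factor_high}
    eqtl_rows, ld_rows, gwas, truth_blocks, truth_tagged = [], [], [], {}, set()
    counter = 0
    for gene in sorted(ground_truth.classes):
        n_blocks = max(1, int(rng.poisson(mean_blocks_per_gene)))
        gene_variants: list[tuple[str, int]] = []  # (variant, block index)
        for b in range(n_blocks):
            size = int(rng.integers(block_size_range[0], block_size_range[1] + 1))
            members = [f"rs{counter + k}" for k in range(size)]
            counter += size
            block_id = f"{gene}_b{b}"
            truth_blocks[block_id] = members
            n_consistent = int(rng.integers(1, n_tissues + 1))
            sign = rng.choice([-1.0, 1.0])
            for v in members:
                gene_variants.append((v, b))
                for t in range(n_consistent):
                    eqtl_rows.append(
                        (v, gene, f"tissue_{t}", sign * abs(rng.normal(0.3, 0.1)))
                    )
                # one discordant tissue, if room
                if n_consistent < n_tissues:
                    eqtl_rows.append(
                        (
                            v,
                            gene,
                            f"tissue_{n_consistent}",
                            -sign * abs(rng.normal(0.3, 0.1)),
                        )
                    )
            # within-block LD
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    ld_rows.append(
                        (members[i], members[j], rng.uniform(0.81, 1.0))
                    )
            # GWAS tagging via a proxy variant in high LD with one member
            p_tag = base_tagging_prob * factors[ground_truth.classes[gene]]
            if rng.random() < p_tag:
                proxy = f"rs{counter}"
                counter += 1
                ld_rows.append((members[0], proxy, rng.uniform(0.81, 1.0)))
                gwas.append(proxy)
                truth_tagged.add(block_id)
        # sparse cross-block LD, below threshold
        blocks_seen = sorted({b for _, b in gene_variants})
        for i in range(len(blocks_seen) - 1):
            va = truth_blocks[f"{gene}_b{blocks_seen[i]}"][0]
            vb = truth_blocks[f"{gene}_b{blocks_seen[i + 1]}"][0]
            ld_rows.append((va, vb, rng.uniform(0.0, 0.5)))
    eqtl = pd.DataFrame(eqtl_rows, columns=["variant", "gene", "tissue", "slope"])
    ld = pd.DataFrame(ld_rows, columns=["variant_a", "variant_b", "r2"])
    return eqtl, ld, gwas, {"blocks": truth_blocks, "tagged": truth_tagged}


# ---------------------------------------------------------------------------
# toy PDB structures
# ---------------------------------------------------------------------------


@dataclass
class ChainSpec:
    """One chain of a toy structure: a straight run of CA pseudo-atoms."""

    chain_id: str
    protein: str
    n_residues: int
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    spacing: float = 3.8
    residue_name: str = "ALA"

    def coordinates(self) -> np.ndarray:
        axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("chain axis must be nonzero")
        axis = axis / norm
        t = np.arange(self.n_residues)[:, None] * self.spacing
        return np.asarray(self.origin, dtype=float) + t * axis


def make_toy_complex(chains: list[ChainSpec]) -> str:
    """Render a toy multi-chain structure as PDB text (one CA atom/residue).

    Contact residues are known by construction from the chain geometry, so
    the result serves as a fixture with an exact distance-based oracle for
    interface extraction.
    """
    if not chains:
        raise ValueError("at least one chain required")
    ids = [c.chain_id for c in chains]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate chain ids")
    lines = []
    serial = 1
    for spec in chains:
        if spec.n_residues < 1:
            raise ValueError("chain must have at least one residue")
        if len(spec.chain_id) != 1:
            raise ValueError("PDB chain id must be a single character")
        for res_i, (x, y, z) in enumerate(spec.coordinates(), start=1):
            lines.append(
                f"ATOM  {serial:5d}  CA  {spec.residue_name:<3s} "
                f"{spec.chain_id}{res_i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {'C':>2s}"
            )
            serial += 1
        lines.append(f"TER   {serial:5d}      {spec.residue_name:<3s} {spec.chain_id}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# persistence of generator outputs
# ---------------------------------------------------------------------------


def write_simulation(
    out_dir: str | Path, cohort: OmicsCohort, truth: GroundTruth
) -> None:
    """Write cohort TSVs, the interaction pair list, and ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.to_dir(out)
    pairs = pd.DataFrame(
        [(x, y) for cx in truth.complexes for x in cx for y in cx if x < y],
        columns=["gene_a", "gene_b"],
    )
    pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)
    truth.to_json(out / "ground_truth.json")


def config_from_dict(d: dict) -> SimulationConfig:
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    if "complex_size_range" in d:
        d = {**d, "complex_size_range": tuple(d["complex_size_range"])}
    if "cnv_level_probs" in d:
        d = {**d, "cnv_level_probs": tuple(d["cnv_level_probs"])}
    return SimulationConfig(**d)
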