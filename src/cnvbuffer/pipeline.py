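"""End-to-end orchestration: simulate -> preprocess -> attenuation ->
association screens -> phospho screen -> interfaces -> tissue validation ->
eQTL stratification -> report, with a checksummed manifest for provenance.

Stages communicate through TSV/JSON files in a run directory, so each
stage can also be invoked on its own (and from the command line).  The
attenuation analysis runs on confounder-regressed residuals; the
association screens run on standardized matrices with the covariates as
model terms, mirroring the nested-model formulation.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import associations as assoc
from . import attenuation as att
from . import eqtl as eqtl_mod
from . import structure as struc
from . import tissue as tissue_mod
from .cohort import OmicsCohort
from .preprocess import regress_confounders, zscore_rows
from .simulate import (
    ChainSpec,
    GroundTruth,
    SimulationConfig,
    config_from_dict,
    make_toy_complex,
    simulate_cohort,
    simulate_eqtl_tables,
    simulate_tissue_panel,
    write_simulation,
)

DEFAULT_CONFIG: dict = {
    "out_dir": "run",
    "seed": 0,
    "stages": {
        "simulate": True,
        "preprocess": True,
        "attenuation": True,
        "associations": True,
        "phospho": True,
        "interfaces": True,
        "tissues": True,
        "eqtl": True,
    },
    "simulation": {},
    "attenuation": {"min_pairs": 20, "n_components": 4},
    "associations": {"fdr": 0.05},
    "interfaces": {"contact_counts": [0, 5, 10, 20], "chain_length": 40},
    "tissues": {"mrna_band": [0.0, 0.4], "min_tissues": 10},
    "eqtl": {"r2": 0.8, "min_tissues": 3, "max_blocks": 100},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(config: dict | None) -> dict:
    return _merge(DEFAULT_CONFIG, config or {})


def _read_matrix(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def _write_matrix(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA")


class PipelineError(RuntimeError):
    pass


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"stage {stage!r} needs missing input {path.name}; run the upstream stage"
        )
    return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(out: Path, cfg: dict) -> None:
    sim_cfg = config_from_dict({"seed": cfg["seed"], **cfg["simulation"]})
    cohort, truth = simulate_cohort(sim_cfg)
    write_simulation(out, cohort, truth)
    (out / "simulation_config.json").write_text(
        json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(sim_cfg).items()},
            indent=1,
        )
    )


def _load_cohort(out: Path, stage: str) -> OmicsCohort:
    _require(out / "cnv.tsv", stage)
    return OmicsCohort.from_dir(out)


def stage_preprocess(out: Path, cfg: dict) -> None:
    cohort = _load_cohort(out, "preprocess")
    proc = out / "processed"
    proc.mkdir(exist_ok=True)
    for name in ("mrna", "protein", "phospho"):
        mat = getattr(cohort, name).T  # features x samples
        z = zscore_rows(mat)
        _write_matrix(z, proc / f"{name}_z.tsv")
        resid = regress_confounders(z, cohort.covariates)
        _write_matrix(resid, proc / f"{name}_resid.tsv")


def _processed_cohort(out: Path, stage: str, residual: bool) -> OmicsCohort:
    cohort = _load_cohort(out, stage)
    proc = out / "processed"
    suffix = "resid" if residual else "z"
    mats = {}
    for name in ("mrna", "protein", "phospho"):
        path = _require(proc / f"{name}_{suffix}.tsv", stage)
        mats[name] = _read_matrix(path).T.reindex(cohort.samples)
    return OmicsCohort(
        cnv=cohort.cnv, covariates=cohort.covariates, **mats
    )


def stage_attenuation(out: Path, cfg: dict) -> None:
    cohort = _processed_cohort(out, "attenuation", residual=True)
    records, excluded = att.compute_attenuation(
        cohort, min_pairs=cfg["attenuation"]["min_pairs"]
    )
    labels, _ = att.classify_attenuation(
        records.set_index("gene")["potential"],
        n_components=cfg["attenuation"]["n_components"],
        seed=cfg["seed"],
    )
    records["attenuation_class"] = labels.reindex(records["gene"]).to_numpy()
    records.to_csv(out / "attenuation.tsv", sep="\t", index=False)
    excluded.to_csv(out / "attenuation_excluded.tsv", sep="\t", index=False)
    truth = GroundTruth.from_json(_require(out / "ground_truth.json", "attenuation"))
    complexes = {f"complex_{i}": cx for i, cx in enumerate(truth.complexes)}
    attenuated = set(records.loc[records["attenuation_class"] != att.NON, "gene"])
    enrichment = att.enrich_complexes(
        attenuated, complexes, universe=set(records["gene"])
    )
    enrichment.to_csv(out / "attenuation_enrichment.tsv", sep="\t", index=False)


def _directed_pairs(out: Path, stage: str) -> list[tuple[str, str]]:
    pairs = pd.read_csv(_require(out / "pairs.tsv", stage), sep="\t")
    directed = []
    for a, b in zip(pairs["gene_a"], pairs["gene_b"]):
        directed.append((a, b))
        directed.append((b, a))
    return directed


def stage_associations(out: Path, cfg: dict) -> None:
    cohort = _processed_cohort(out, "associations", residual=False)
    pairs = _directed_pairs(out, "associations")
    threshold = cfg["associations"]["fdr"]
    cnv_res, cnv_skip = assoc.screen_pairs(cohort, pairs, variant="cnv")
    mrna_res, _ = assoc.screen_pairs(cohort, pairs, variant="mrna")
    cnv_res.to_csv(out / "associations_cnv.tsv", sep="\t", index=False)
    mrna_res.to_csv(out / "associations_mrna.tsv", sep="\t", index=False)
    cnv_skip.to_csv(out / "associations_skipped.tsv", sep="\t", index=False)
    significant = assoc.intersect_variants(cnv_res, mrna_res, threshold)
    truth = GroundTruth.from_json(_require(out / "ground_truth.json", "associations"))
    final = assoc.deduplicate_colocalized(
        significant, cnv_res, mrna_res, truth.gene_chromosome, cohort.cnv
    )
    final_df = cnv_res[
        [
            (x, y) in final
            for x, y in zip(cnv_res["controller"], cnv_res["controlled"])
        ]
    ]
    final_df.to_csv(out / "associations_final.tsv", sep="\t", index=False)
    if final:
        status = assoc.classify_control_status(final)
    else:
        status = pd.DataFrame(columns=["gene", "status"])
    status.to_csv(out / "control_status.tsv", sep="\t", index=False)


def stage_phospho(out: Path, cfg: dict) -> None:
    cohort = _processed_cohort(out, "phospho", residual=False)
    pairs = _directed_pairs(out, "phospho")
    final = pd.read_csv(_require(out / "associations_final.tsv", "phospho"), sep="\t")
    protein_sig = set(zip(final["controller"], final["controlled"]))
    results, skipped = assoc.screen_phospho(
        cohort, pairs, protein_significant=protein_sig,
        fdr_threshold=cfg["associations"]["fdr"],
    )
    results.to_csv(out / "phospho_associations.tsv", sep="\t", index=False)
    skipped.to_csv(out / "phospho_skipped.tsv", sep="\t", index=False)


def stage_interfaces(out: Path, cfg: dict) -> None:
    """Build toy dimers with controlled contact counts and extract interfaces."""
    rows = []
    pdb_dir = out / "structures"
    pdb_dir.mkdir(exist_ok=True)
    length = cfg["interfaces"]["chain_length"]
    for k in cfg["interfaces"]["contact_counts"]:
        offset = 4.0 if k > 0 else 100.0
        chains = [
            ChainSpec("A", "PA", length),
            ChainSpec(
                "B",
                "PB",
                max(k, 1) if k > 0 else length,
                origin=(0.0, offset, 0.0),
            ),
        ]
        text = make_toy_complex(chains)
        pdb_path = pdb_dir / f"toy_contacts_{k}.pdb"
        pdb_path.write_text(text)
        model = struc.read_pdb(pdb_path, chain_proteins={"A": "PA", "B": "PB"})
        summary = struc.extract_interface(model)
        for chain in model.chains:
            rows.append(
                (
                    model.structure_id,
                    chain,
                    model.protein_of(chain),
                    summary.interface_size_per_chain[chain],
                    summary.interface_size_total,
                    summary.buried_fraction[chain],
                )
            )
    pd.DataFrame(
        rows,
        columns=[
            "structure_id",
            "chain",
            "protein",
            "interface_size_chain",
            "interface_size_total",
            "buried_fraction",
        ],
    ).to_csv(out / "interfaces.tsv", sep="\t", index=False)


def stage_tissues(out: Path, cfg: dict) -> None:
    sim_cfg = config_from_dict(
        {"seed": cfg["seed"], **cfg["simulation"]}
    )
    truth = GroundTruth.from_json(_require(out / "ground_truth.json", "tissues"))
    mrna, protein = simulate_tissue_panel(sim_cfg, truth)
    panel = tissue_mod.TissuePanel(mrna=mrna, protein=protein)
    cnv_res = pd.read_csv(
        _require(out / "associations_cnv.tsv", "tissues"), sep="\t"
    )
    fdr = cnv_res["fdr"].to_numpy()
    klass = np.where(fdr < 0.01, "highsig", np.where(fdr < 0.05, "sig", "nonsig"))
    pairs = pd.DataFrame(
        {
            "controller": cnv_res["controller"],
            "controlled": cnv_res["controlled"],
            "fdr_class": klass,
        }
    )
    cors = tissue_mod.stratified_pair_correlations(
        panel, pairs, mrna_band=tuple(cfg["tissues"]["mrna_band"])
    )
    cors.to_csv(out / "tissue_correlations.tsv", sep="\t", index=False)
    if cors["fdr_class"].nunique() >= 2 and (cors.groupby("fdr_class").size() >= 2).all():
        tests = tissue_mod.compare_correlation_strata(cors)
        tests.to_csv(out / "tissue_strata_tests.tsv", sep="\t", index=False)


def stage_eqtl(out: Path, cfg: dict) -> None:
    sim_cfg = config_from_dict({"seed": cfg["seed"], **cfg["simulation"]})
    truth = GroundTruth.from_json(_require(out / "ground_truth.json", "eqtl"))
    eqtl, ld, gwas, _ = simulate_eqtl_tables(sim_cfg, truth)
    eqtl.to_csv(out / "eqtl.tsv", sep="\t", index=False)
    ld.to_csv(out / "ld.tsv", sep="\t", index=False)
    pd.DataFrame({"variant": gwas}).to_csv(out / "gwas.tsv", sep="\t", index=False)
    surviving = eqtl_mod.filter_tissue_consistency(
        eqtl, min_tissues=cfg["eqtl"]["min_tissues"]
    )
    blocks, excluded = eqtl_mod.build_blocks(
        surviving, ld, r2_threshold=cfg["eqtl"]["r2"],
        max_blocks_per_gene=cfg["eqtl"]["max_blocks"],
    )
    blocks = eqtl_mod.tag_blocks(blocks, ld, set(gwas), r2_threshold=cfg["eqtl"]["r2"])
    attn = pd.read_csv(_require(out / "attenuation.tsv", "eqtl"), sep="\t")
    classes = dict(zip(attn["gene"], attn["attenuation_class"]))
    fractions = eqtl_mod.tagging_fraction_by_class(blocks, classes)
    fractions.to_csv(out / "eqtl_fractions.tsv", sep="\t", index=False)
    pd.DataFrame({"gene": excluded}).to_csv(
        out / "eqtl_excluded_genes.tsv", sep="\t", index=False
    )


STAGES = (
    ("simulate", stage_simulate),
    ("preprocess", stage_preprocess),
    ("attenuation", stage_attenuation),
    ("associations", stage_associations),
    ("phospho", stage_phospho),
    ("interfaces", stage_interfaces),
    ("tissues", stage_tissues),
    ("eqtl", stage_eqtl),
)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | None = None) -> dict:
    """Run the toggled stages in dependency order; returns the manifest."""
    cfg = load_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg["seed"], "config": cfg, "stages": {}}
    for name, fn in STAGES:
        if not cfg["stages"].get(name, False):
            continue
        t0 = time.time()
        fn(out, cfg)
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 2)}
    manifest["files"] = {
        str(p.relative_to(out)): _checksum(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def report(run_dir: str | Path) -> dict:
    """Summarize a completed run as one machine-readable dictionary."""
    out = Path(run_dir)
    summary: dict = {}

    def table(name: str) -> pd.DataFrame | None:
        path = out / name
        return pd.read_csv(path, sep="\t") if path.exists() else None

    attn = table("attenuation.tsv")
    if attn is not None:
        summary["attenuation_class_counts"] = (
            attn["attenuation_class"].value_counts().to_dict()
        )
        summary["n_genes_scored"] = int(len(attn))
    for key, name in (
        ("n_associations_cnv_tested", "associations_cnv.tsv"),
        ("n_associations_final", "associations_final.tsv"),
        ("n_phospho_tested", "phospho_associations.tsv"),
    ):
        t = table(name)
        if t is not None:
            summary[key] = int(len(t))
    status = table("control_status.tsv")
    if status is not None and len(status):
        summary["control_status_counts"] = status["status"].value_counts().to_dict()
    pho = table("phospho_associations.tsv")
    if pho is not None and "in_final_set" in pho:
        summary["n_phospho_final"] = int(pho["in_final_set"].sum())
    truth_path = out / "ground_truth.json"
    final = table("associations_final.tsv")
    if truth_path.exists() and final is not None:
        truth = GroundTruth.from_json(truth_path)
        true_edges = {(x, y) for x, y, _ in truth.edges}
        found = set(zip(final["controller"], final["controlled"]))
        summary["association_true_positives"] = len(found & true_edges)
        summary["association_false_positives"] = len(found - true_edges)
        summary["n_true_edges"] = len(true_edges)
    frac = table("eqtl_fractions.tsv")
    if frac is not None:
        summary["eqtl_fraction_rows"] = int(len(frac))
    (out / "report.json").write_text(json.dumps(summary, indent=1))
    return summary
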