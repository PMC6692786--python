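"""SASA numerics, interface extraction, QC filters and interface metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnvbuffer.simulate import ChainSpec, make_toy_complex
from cnvbuffer.structure import (
    InterfaceSummary,
    StructureModel,
    atom_sasa,
    compute_sasa,
    correlate_interface_with_stats,
    extract_interface,
    filter_structures,
    interface_fraction,
    read_pdb,
)

PROBE = 1.4
R_C = 1.7


def _model(coords, radii=None, chains=None, res_ids=None, res_names=None):
    n = len(coords)
    return StructureModel(
        structure_id="toy",
        chain_ids=np.array(chains or ["A"] * n),
        res_ids=np.array(res_ids or list(range(1, n + 1))),
        res_names=np.array(res_names or ["ALA"] * n),
        elements=np.array(["C"] * n),
        coords=np.asarray(coords, dtype=float),
        radii=np.asarray(radii if radii is not None else [R_C] * n),
    )


def _dimer(gap=4.5, n_a=20, n_b=20, offset_x=0.0):
    return [
        ChainSpec("A", "PA", n_a),
        ChainSpec("B", "PB", n_b, origin=(offset_x, gap, 0.0)),
    ]


def _read(chains):
    return read_pdb(make_toy_complex(chains), "toy", {"A": "PA", "B": "PB"})


# --- SASA ------------------------------------------------------------------


def test_isolated_atom_matches_analytic_sphere():
    sasa = atom_sasa(_model([[0, 0, 0]]))[0]
    exact = 4 * np.pi * (R_C + PROBE) ** 2
    assert abs(sasa - exact) / exact < 0.005


def test_two_sphere_burial_matches_cap_formula():
    d = 3.0
    sasa = atom_sasa(_model([[0, 0, 0], [d, 0, 0]]))
    R = R_C + PROBE
    cap = 2 * np.pi * R * (R - d / 2)  # buried cap on each equal sphere
    expected = 4 * np.pi * R**2 - cap
    for s in sasa:
        assert abs(s - expected) / expected < 0.01


def test_sasa_converges_when_doubling_sphere_points():
    # single-atom residues with half-buried spheres are the worst case for
    # the point quadrature; doubling the lattice moves no residue by >1%
    model = _read(_dimer())
    a = compute_sasa(model, n_sphere_points=960)["sasa"].to_numpy()
    b = compute_sasa(model, n_sphere_points=1920)["sasa"].to_numpy()
    assert np.max(np.abs(a - b) / np.maximum(b, 1e-9)) < 0.01
    c = compute_sasa(model, n_sphere_points=3840)["sasa"].to_numpy()
    assert np.max(np.abs(b - c) / np.maximum(c, 1e-9)) < np.max(
        np.abs(a - b) / np.maximum(b, 1e-9)
    )


def test_sasa_monotone_occlusion_exact():
    """Bound per-residue SASA never exceeds unbound SASA, exactly at the
    fixed sphere points."""
    model = _read(_dimer())
    bound = compute_sasa(model)
    for chain in model.chains:
        unbound = compute_sasa(model.subset(chain))
        b = bound[bound["chain"] == chain].set_index("res_id")["sasa"]
        u = unbound.set_index("res_id")["sasa"]
        assert (b.loc[u.index].to_numpy() <= u.to_numpy() + 1e-12).all()


def test_sasa_cross_check_against_biotite():
    """Independent Shrake-Rupley implementation agrees within a few percent."""
    import io

    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    text = make_toy_complex(_dimer())
    atoms = PDBFile.read(io.StringIO(text)).get_structure(model=1)
    atoms = atoms[~atoms.hetero]
    ref = struc.sasa(
        atoms, probe_radius=PROBE, point_number=960,
        vdw_radii=np.full(atoms.array_length(), R_C),
    )
    ours = atom_sasa(read_pdb(text, "toy"))
    assert ours.shape == ref.shape
    np.testing.assert_allclose(ours, ref, rtol=0.05, atol=0.5)


def test_unknown_residue_type_warns_and_gets_nan_relative():
    model = _model([[0, 0, 0]], res_names=["XYZ"])
    with pytest.warns(UserWarning):
        res = compute_sasa(model)
    assert np.isnan(res["rel_sasa"].iloc[0])
    assert res["sasa"].iloc[0] > 0


# --- interface extraction --------------------------------------------------


def test_far_chains_have_no_interface():
    summary = extract_interface(_read(_dimer(gap=100.0)))
    assert summary.interface_size_total == 0
    for chain in ("A", "B"):
        assert summary.buried_fraction[chain] == pytest.approx(0.0, abs=1e-12)


def test_interface_matches_distance_threshold_oracle():
    """On convex toy geometry the interface equals the set of residues with
    any atom within r_i + r_j + 2*probe of the partner chain."""
    chains = _dimer(gap=4.5, n_a=25, n_b=12, offset_x=30.0)
    summary = extract_interface(_read(chains))
    ca, cb = chains[0].coordinates(), chains[1].coordinates()
    thr = 2 * R_C + 2 * PROBE
    d2 = ((ca[:, None, :] - cb[None, :, :]) ** 2).sum(-1)
    oracle_a = set((np.flatnonzero((d2 < thr**2).any(axis=1)) + 1).tolist())
    oracle_b = set((np.flatnonzero((d2 < thr**2).any(axis=0)) + 1).tolist())
    assert summary.interface_residues["A"] == oracle_a
    assert summary.interface_residues["B"] == oracle_b


def test_interface_symmetry():
    summary = extract_interface(_read(_dimer()))
    a, b = summary.interface_size_per_chain.values()
    assert (a > 0) == (b > 0)


def test_interface_invariant_under_rigid_transform():
    model = _read(_dimer())
    base = extract_interface(model)
    theta = 0.7
    rot = np.array(
        [
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ]
    )
    moved = StructureModel(
        structure_id="moved",
        chain_ids=model.chain_ids,
        res_ids=model.res_ids,
        res_names=model.res_names,
        elements=model.elements,
        coords=model.coords @ rot.T + np.array([5.0, -3.0, 11.0]),
        radii=model.radii,
        chain_proteins=model.chain_proteins,
    )
    rotated = extract_interface(moved)
    # the interface residue sets are exactly invariant; the areas move only
    # by point-quadrature error (the sphere lattice has a fixed orientation)
    assert rotated.interface_residues == base.interface_residues
    for chain in ("A", "B"):
        assert rotated.buried_fraction[chain] == pytest.approx(
            base.buried_fraction[chain], rel=0.05
        )


def test_single_chain_interface_raises():
    with pytest.raises(ValueError):
        extract_interface(read_pdb(make_toy_complex([ChainSpec("A", "P", 5)])))


def test_buried_fraction_matches_definition():
    model = _read(_dimer())
    summary = extract_interface(model)
    bound = compute_sasa(model)
    for chain in ("A", "B"):
        unbound = compute_sasa(model.subset(chain))
        total_u = unbound["sasa"].sum()
        total_b = bound[bound["chain"] == chain]["sasa"].sum()
        assert summary.buried_fraction[chain] == pytest.approx(
            (total_u - total_b) / total_u, abs=1e-10
        )


# --- QC filters ------------------------------------------------------------


def _qc_model(sid, lens, proteins):
    chains, res_ids = [], []
    for cid, n in zip("ABCD", lens):
        chains += [cid] * n
        res_ids += list(range(1, n + 1))
    n_atoms = len(chains)
    return StructureModel(
        structure_id=sid,
        chain_ids=np.array(chains),
        res_ids=np.array(res_ids),
        res_names=np.array(["ALA"] * n_atoms),
        elements=np.array(["C"] * n_atoms),
        coords=np.arange(3 * n_atoms, dtype=float).reshape(n_atoms, 3),
        radii=np.full(n_atoms, R_C),
        chain_proteins=dict(zip("ABCD", proteins)),
    )


def test_filter_structures_rules():
    lengths = {"P1": 500, "P2": 500, "P3": 40}
    models = [
        _qc_model("homodimer", [60, 60], ["P1", "P1"]),
        _qc_model("small99", [50, 49], ["P1", "P2"]),
        _qc_model("ok100", [60, 40], ["P1", "P2"]),
        _qc_model("equal", [75, 75], ["P1", "P2"]),
        _qc_model("too_long", [60, 41], ["P1", "P3"]),
        _qc_model("unknown", [60, 41], ["P1", "P9"]),
    ]
    kept, dropped = filter_structures(models, lengths)
    assert [m.structure_id for m in kept] == ["ok100"]
    reasons = dict(zip(dropped["structure_id"], dropped["reason"]))
    assert reasons["homodimer"] == "homodimer"
    assert reasons["small99"] == "too_few_residues"
    assert reasons["equal"] == "equal_chain_lengths"
    assert reasons["too_long"] == "chain_exceeds_uniprot_length"
    assert reasons["unknown"].startswith("unknown_protein")


# --- interface metrics -----------------------------------------------------


def test_interface_fraction_union():
    m1 = _qc_model("s1", [10, 10], ["P", "Q"])
    m2 = _qc_model("s2", [10, 10], ["P", "Q"])
    s1 = InterfaceSummary("s1", {"A": set(range(1, 11)), "B": set()}, {"A": 0.1, "B": 0.1})
    s2 = InterfaceSummary("s2", {"A": set(range(6, 16)), "B": set()}, {"A": 0.1, "B": 0.1})
    assert interface_fraction("P", [(m1, s1), (m2, s2)], 100) == pytest.approx(0.15)
    assert interface_fraction("P", [], 100) == 0.0
    with pytest.warns(UserWarning):
        assert interface_fraction("P", [(m1, s1)], 5) == 1.0


def test_correlation_with_association_stats(rng):
    beta = rng.normal(1, 0.2, 10)
    table = pd.DataFrame(
        {"interface_size": 10 * beta, "beta7": beta, "fdr": rng.uniform(0.001, 0.9, 10)}
    )
    out = correlate_interface_with_stats(table)
    assert out["beta"][0] == pytest.approx(1.0, abs=1e-12)
    # formula oracle for the fdr correlation
    x = table["interface_size"].to_numpy()
    y = -np.log10(table["fdr"].to_numpy())
    r_manual = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
    )
    assert out["neg_log10_fdr"][0] == pytest.approx(r_manual, abs=1e-12)
    r, p = stats.pearsonr(x, y)
    assert out["neg_log10_fdr"] == pytest.approx((r, p), abs=1e-12)


def test_correlation_needs_three_points():
    table = pd.DataFrame({"interface_size": [1, 2], "beta7": [1, 2], "fdr": [0.1, 0.2]})
    with pytest.raises(ValueError):
        correlate_interface_with_stats(table)
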