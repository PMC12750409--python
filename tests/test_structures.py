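import numpy as np
import pytest

from voasim import (
    CANONICAL_CONFORMERS,
    ConformerSpec,
    GeometryError,
    build_fibril,
    build_polypeptide,
    deuterate,
    from_pdb,
    from_xyz,
    guess_bonds,
    measure_torsions,
    mirror,
    to_pdb,
    to_xyz,
    write_torsion_restraints,
)
from voasim.structures import dihedral_angle, expected_atom_count, EXCHANGEABLE_NAMES

from conftest import rotation_matrix


# ---------------------------------------------------------------------------
# builder / torsion round trip
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("name,phi,psi", [
    ("PPII", -75.0, 150.0),
    ("alpha", -60.0, -45.0),
    ("three10", -49.0, -26.0),
    ("beta_parallel", -140.0, 130.0),
    ("beta_antiparallel", -120.0, 115.0),
])
def test_conformer_round_trip(name, phi, psi):
    """Building a canonical conformer and re-measuring its backbone torsions
    recovers the requested (phi, psi) within 1 degree on interior residues."""
    spec = CANONICAL_CONFORMERS[name]
    assert (spec.phi, spec.psi) == (phi, psi)
    g = build_polypeptide(8, name)
    tors = measure_torsions(g)
    interior = tors[1:-1]
    assert np.abs(interior[:, 0] - phi).max() < 1.0
    assert np.abs(interior[:, 1] - psi).max() < 1.0


def test_torsions_match_independent_dihedral_oracle():
    """Re-measured torsions agree with a four-point dihedral computed by an
    independent routine (MDAnalysis) on the same coordinates."""
    mda = pytest.importorskip("MDAnalysis")
    from MDAnalysis.lib.distances import calc_dihedrals

    g = build_polypeptide(5, "alpha", protonation="protonated")
    tors = measure_torsions(g)
    for r in range(1, 4):
        quad = [g.find_atom(0, r - 1, "C"), g.find_atom(0, r, "N"),
                g.find_atom(0, r, "CA"), g.find_atom(0, r, "C")]
        ref = np.degrees(calc_dihedrals(*[g.coords[i][None, :] for i in quad]))[0]
        assert abs(tors[r, 0] - ref) < 1e-3  # oracle computes in float32
        assert abs(tors[r, 0] - (-60.0)) < 1.0


def test_two_residue_boundary():
    g = build_polypeptide(2, "PPII")
    tors = measure_torsions(g)
    # no residue has both phi and psi defined
    assert np.isnan(tors[0, 0]) and np.isnan(tors[1, 1])
    assert np.isfinite(tors[0, 1]) and np.isfinite(tors[1, 0])


@pytest.mark.parametrize("protonation,per_res", [("deprotonated", 15), ("protonated", 16)])
def test_atom_count_closed_form(protonation, per_res):
    for n in (2, 5, 9):
        g = build_polypeptide(n, "PPII", protonation=protonation)
        assert g.n_atoms == per_res * n + 3 == expected_atom_count(n, protonation)


def test_backbone_bond_lengths_in_range():
    g = build_polypeptide(6, "beta_antiparallel", protonation="protonated")
    for i, j in guess_bonds(g):
        d = np.linalg.norm(g.coords[i] - g.coords[j])
        assert 0.7 <= d <= 1.9


def test_invalid_requests_rejected():
    with pytest.raises(GeometryError):
        build_polypeptide(1, "PPII")
    with pytest.raises(GeometryError):
        build_polypeptide(5, ConformerSpec("bad", -200.0, 10.0))
    with pytest.raises(GeometryError):
        build_polypeptide(5, "no_such_conformer")
    with pytest.raises(GeometryError):
        build_polypeptide(5, "PPII", protonation="half")


def test_torsions_rotation_translation_invariant():
    g = build_polypeptide(5, "three10")
    ref = measure_torsions(g)
    g2 = g.copy()
    g2.coords = g.coords @ rotation_matrix(11).T + np.array([3.0, -7.0, 1.5])
    assert np.nanmax(np.abs(measure_torsions(g2) - ref)) < 1e-8


def test_collinear_backbone_flagged_undefined():
    assert np.isnan(dihedral_angle(np.zeros(3), np.array([1.0, 0, 0]),
                                   np.array([2.0, 0, 0]), np.array([3.0, 0, 0])))


def test_missing_backbone_atom_rejected(strand6):
    g = strand6.copy()
    keep = [i for i in range(g.n_atoms)
            if not (g.residue_index[i] == 2 and g.atom_names[i] == "CA")]
    broken = g.subset(keep)
    with pytest.raises(GeometryError, match="residue 2"):
        measure_torsions(broken)


# ---------------------------------------------------------------------------
# mirror
# ---------------------------------------------------------------------------

def test_mirror_is_involution_and_negates_torsions(strand6):
    tors = measure_torsions(strand6)
    gm = mirror(strand6)
    tm = measure_torsions(gm)
    assert np.nanmax(np.abs(tors + tm)) < 1e-8
    back = mirror(gm)
    assert np.abs(back.coords - strand6.coords).max() < 1e-10
    assert back.elements == strand6.elements
    assert np.array_equal(back.masses, strand6.masses)


def test_mirror_of_planar_molecule_is_identity(water_toy):
    # the toy lies in the z = 0 plane; reflecting through it changes nothing
    g = water_toy.copy()
    g.coords = g.coords[:, [2, 1, 0]]  # move the flat axis onto x
    gm = mirror(g)
    assert np.abs(gm.coords - g.coords).max() == 0.0


# ---------------------------------------------------------------------------
# deuteration
# ---------------------------------------------------------------------------

def test_deuterate_exchangeable_swaps_nh_oh_only():
    g = build_polypeptide(4, "alpha", protonation="protonated")
    gd = deuterate(g, "exchangeable")
    assert np.abs(gd.coords - g.coords).max() == 0.0
    swapped = [n for n, l in zip(gd.atom_names, gd.isotope_labels) if l == "D"]
    assert set(swapped) <= EXCHANGEABLE_NAMES
    # every amide H and carboxyl HE2 swapped, no C-H touched
    assert swapped.count("HE2") == 4
    assert swapped.count("H") == 3  # residues 1..3; terminal NH2 has H1/H2
    for nm in ("HA", "HB2", "HG3"):
        idx = [i for i, n in enumerate(gd.atom_names) if n == nm]
        assert all(gd.isotope_labels[i] == "H" for i in idx)
    n_sw = len(swapped)
    assert np.isclose(gd.masses.sum() - g.masses.sum(), n_sw * (2.014 - 1.008))


def test_deuterate_deprotonated_has_no_sidechain_exchange():
    g = build_polypeptide(4, "PPII", protonation="deprotonated")
    gd = deuterate(g, "exchangeable")
    swapped = {n for n, l in zip(gd.atom_names, gd.isotope_labels) if l == "D"}
    assert "HE2" not in swapped


def test_deuterate_all_h(alpha4):
    gd = deuterate(alpha4, "all_H")
    h = [i for i, e in enumerate(gd.elements) if e == "H"]
    assert all(np.isclose(gd.masses[i], 2.014) for i in h)
    assert gd.n_atoms == alpha4.n_atoms


# ---------------------------------------------------------------------------
# fibril assembly
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("sheets,strands", [(1, 1), (1, 2), (2, 2), (3, 4)])
def test_fibril_chain_count(sheets, strands):
    f = build_fibril(sheets, strands, residues_per_strand=6)
    assert f.n_chains == sheets * strands


def test_fibril_single_strand_degenerate_case():
    f = build_fibril(1, 1, residues_per_strand=5)
    g = build_polypeptide(5, "beta_antiparallel", protonation="protonated")
    assert np.abs(f.coords - g.coords).max() == 0.0


def test_fibril_antiparallel_neighbors_and_spacing():
    from scipy.spatial import cKDTree

    f = build_fibril(1, 2, residues_per_strand=8)
    ca = []
    for ch in (0, 1):
        ca.append(np.array([f.coords[f.find_atom(ch, r, "CA")]
                            for r in f.chain_residues(ch)]))
    assert np.dot(ca[0][-1] - ca[0][0], ca[1][-1] - ca[1][0]) < 0
    # brute-force nearest CA-CA distances around the 4.8 A strand spacing
    near = cKDTree(ca[0]).query(ca[1])[0]
    assert near.min() >= 4.8 - 1.0 and near.min() <= 4.8 + 1.0


def test_fibril_no_interchain_clash():
    from scipy.spatial import cKDTree

    f = build_fibril(2, 2, residues_per_strand=8)
    for a in range(4):
        ta = cKDTree(f.coords[f.chain_index == a])
        for b in range(a + 1, 4):
            assert ta.query(f.coords[f.chain_index == b])[0].min() > 1.5


def test_fibril_clash_rejected():
    with pytest.raises(GeometryError, match="clash"):
        build_fibril(1, 2, residues_per_strand=6, strand_spacing=1.0)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def test_pdb_round_trip(tmp_path, alpha4):
    path = str(tmp_path / "g.pdb")
    to_pdb(alpha4, path)
    back = from_pdb(path, protonation="protonated")
    assert back.elements == alpha4.elements
    assert back.atom_names == alpha4.atom_names
    assert np.array_equal(back.residue_index, alpha4.residue_index)
    assert np.abs(back.coords - alpha4.coords).max() < 1e-3  # PDB precision


def test_xyz_round_trip(tmp_path, water_toy):
    path = str(tmp_path / "g.xyz")
    to_xyz(water_toy, path)
    back = from_xyz(path)
    assert back.elements == water_toy.elements
    assert np.abs(back.coords - water_toy.coords).max() < 1e-12


def test_restraint_listing(tmp_path, strand6):
    path = str(tmp_path / "restraints.txt")
    write_torsion_restraints(strand6, path)
    lines = [l for l in open(path) if not l.startswith("#")]
    # phi for residues 1..5 plus psi for residues 0..4
    assert len(lines) == 10
    for line in lines:
        parts = line.split()
        assert parts[8] == "5.0" and parts[9] == "128.0"
        assert all(int(p) >= 1 for p in parts[3:7])
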