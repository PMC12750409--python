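import numpy as np
import pytest

from voasim import (
    PropertySet,
    TransferError,
    best_fit_rotation,
    build_assignment,
    build_polypeptide,
    make_fragments,
    normal_mode_analysis,
    read_property_set,
    shift_origin,
    surrogate_engine,
    transfer_properties,
    write_property_set,
)

from conftest import rotation_matrix


# ---------------------------------------------------------------------------
# best-fit rotation
# ---------------------------------------------------------------------------

def _centered_cloud(seed=0, n=6):
    pts = np.random.default_rng(seed).normal(size=(n, 3))
    return pts - pts.mean(axis=0)


def test_best_fit_rotation_identity():
    pts = _centered_cloud(1)
    assert np.abs(best_fit_rotation(pts, pts) - np.eye(3)).max() < 1e-12


def test_best_fit_rotation_recovers_known_rotation():
    pts = _centered_cloud(2)
    for seed in (3, 4, 5):
        rot = rotation_matrix(seed)
        rec = best_fit_rotation(pts, pts @ rot.T)
        assert np.abs(rec - rot).max() < 1e-10
        assert np.abs(rec @ pts.T - (pts @ rot.T).T).max() < 1e-10


def test_best_fit_rotation_never_reflects():
    pts = _centered_cloud(6)
    mirrored = pts * np.array([-1.0, 1.0, 1.0])
    rec = best_fit_rotation(pts, mirrored)
    assert np.linalg.det(rec) > 0.999
    # a proper rotation cannot superpose a chiral cloud on its mirror image
    assert np.linalg.norm(rec @ pts.T - mirrored.T) > 0.1


def test_best_fit_rotation_degenerate_rejected():
    line = np.outer(np.linspace(-1, 1, 5), np.array([1.0, 2.0, 3.0]))
    with pytest.raises(TransferError, match="collinear|degenerate"):
        best_fit_rotation(line, line)
    with pytest.raises(TransferError):
        best_fit_rotation(np.zeros((2, 3)), np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def test_assignment_verbatim_fragments_identity_rotations(strand6, strand6_bonds):
    frags = make_fragments(strand6, 3, 1, parent_bonds=strand6_bonds)
    asn = build_assignment(strand6, frags, parent_bonds=strand6_bonds)
    asn.validate()
    for lst in asn.entries:
        total = 0.0
        for _, _, rot, w in lst:
            assert np.abs(rot - np.eye(3)).max() < 1e-10
            total += w
        assert abs(total - 1.0) < 1e-12


def test_assignment_detects_rigidly_rotated_fragment(strand6, strand6_bonds):
    frags = make_fragments(strand6, 6, 1, parent_bonds=strand6_bonds)
    rot = rotation_matrix(7)
    fg = frags[0].fragment_geometry
    fg.coords = fg.coords @ rot.T + np.array([2.0, 0.0, -1.0])
    asn = build_assignment(strand6, frags, parent_bonds=strand6_bonds)
    for lst in asn.entries:
        for _, _, r, _ in lst:
            # fitted rotation maps fragment frame back onto the parent frame
            assert np.abs(r - rot.T).max() < 1e-8


def test_assignment_uncovered_atom_rejected(strand6, strand6_bonds):
    frags = make_fragments(strand6, 3, 1, parent_bonds=strand6_bonds)[:-1]
    missing_ok = all((strand6.residue_index != 5).all() for _ in [0])
    with pytest.raises(TransferError, match="no covering fragment"):
        build_assignment(strand6, frags[:2], parent_bonds=strand6_bonds)


# ---------------------------------------------------------------------------
# transfer
# ---------------------------------------------------------------------------

def test_transfer_identity_exact(strand6, strand6_bonds):
    """A single whole-molecule fragment with identity assignment reproduces
    every input tensor."""
    direct = surrogate_engine(strand6)
    frags = make_fragments(strand6, 6, 1, parent_bonds=strand6_bonds)
    fprops = [surrogate_engine(f.fragment_geometry, origin=direct.origin)
              for f in frags]
    asn = build_assignment(strand6, frags, parent_bonds=strand6_bonds)
    out = transfer_properties(fprops, asn, strand6, origin=direct.origin)
    for name in ("hessian", "apt", "aat", "dalpha", "dgprime", "da"):
        a, b = getattr(direct, name), getattr(out, name)
        scale = max(1.0, np.abs(a).max())
        assert np.abs(a - b).max() < 1e-9 * scale, name
    assert out.meta["zeroed_cross_blocks"] == 0


def test_transfer_equivariance_under_rigid_motion(strand6, strand6_bonds):
    """Transferring the unrotated fragment set onto a rigidly moved parent
    reproduces the direct vibrational frequencies."""
    direct = surrogate_engine(strand6)
    ref = normal_mode_analysis(direct).wavenumbers
    rot = rotation_matrix(13)
    moved = strand6.copy()
    moved.coords = strand6.coords @ rot.T + np.array([1.0, -2.0, 3.0])
    frags = make_fragments(strand6, 6, 1, parent_bonds=strand6_bonds)
    fprops = [surrogate_engine(f.fragment_geometry) for f in frags]
    asn = build_assignment(moved, frags, parent_bonds=strand6_bonds)
    out = transfer_properties(fprops, asn, moved)
    nu = normal_mode_analysis(out).wavenumbers
    sel = ref > 20.0  # sqrt sensitivity makes zero modes meaningless
    assert np.abs(nu[sel] - ref[sel]).max() < 1e-6
    assert np.abs(nu[~sel] - ref[~sel]).max() < 0.05


def test_transfer_overlap_weighted_mean_of_equal_values(strand6, strand6_bonds):
    """Two identical whole-molecule fragments: the overlap combination of
    equal contributions returns that common value."""
    direct = surrogate_engine(strand6)
    frags = make_fragments(strand6, 6, 1, parent_bonds=strand6_bonds) * 2
    fprops = [surrogate_engine(f.fragment_geometry, origin=direct.origin)
              for f in frags]
    asn = build_assignment(strand6, frags, parent_bonds=strand6_bonds)
    out = transfer_properties(fprops, asn, strand6, origin=direct.origin)
    assert np.abs(out.hessian - direct.hessian).max() < 1e-9
    assert np.abs(out.apt - direct.apt).max() < 1e-12


def test_transfer_output_symmetries(strand6, strand6_bonds):
    frags = make_fragments(strand6, 3, 1, parent_bonds=strand6_bonds)
    fprops = [surrogate_engine(f.fragment_geometry) for f in frags]
    asn = build_assignment(strand6, frags, parent_bonds=strand6_bonds)
    out = transfer_properties(fprops, asn, strand6)
    assert np.abs(out.hessian - out.hessian.T).max() == 0.0
    assert np.abs(out.da - out.da.transpose(0, 1, 2, 4, 3)).max() < 1e-12
    out.validate()


def test_zeroed_block_count_decreases_with_span(strand6, strand6_bonds):
    counts = []
    for span in (2, 3, 4, 5):
        frags = make_fragments(strand6, span, 1, parent_bonds=strand6_bonds)
        fprops = [surrogate_engine(f.fragment_geometry) for f in frags]
        asn = build_assignment(strand6, frags, parent_bonds=strand6_bonds)
        out = transfer_properties(fprops, asn, strand6)
        counts.append(out.meta["zeroed_cross_blocks"])
    assert counts == sorted(counts, reverse=True)
    assert counts[0] > counts[-1]


# ---------------------------------------------------------------------------
# origin handling and serialization
# ---------------------------------------------------------------------------

def test_shift_origin_matches_distributed_construction(chiral_toy):
    """Shifting the origin of the surrogate tensors reproduces a fresh
    engine run referenced to the shifted origin."""
    new_origin = np.array([2.0, -1.0, 0.5])
    p0 = surrogate_engine(chiral_toy)
    p1 = shift_origin(p0, new_origin)
    p2 = surrogate_engine(chiral_toy, origin=new_origin)
    for name in ("aat", "dgprime", "da"):
        a, b = getattr(p1, name), getattr(p2, name)
        assert np.abs(a - b).max() < 1e-8 * max(1.0, np.abs(b).max()), name
    # round trip back
    p3 = shift_origin(p1, p0.origin)
    assert np.abs(p3.aat - p0.aat).max() < 1e-12


def test_property_exchange_round_trip(tmp_path, chiral_toy):
    props = surrogate_engine(chiral_toy)
    f1 = tmp_path / "p1.txt"
    f2 = tmp_path / "p2.txt"
    write_property_set(props, str(f1))
    back = read_property_set(str(f1), chiral_toy)
    write_property_set(back, str(f2))
    assert f1.read_text() == f2.read_text()  # bit-identical on ASCII level
    for name in ("hessian", "apt", "aat", "dalpha", "dgprime", "da"):
        a, b = getattr(props, name), getattr(back, name)
        assert np.abs(a - b).max() <= 1e-11 * max(1.0, np.abs(a).max())
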