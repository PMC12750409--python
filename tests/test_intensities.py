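import numpy as np
import pytest

from voasim import (
    BandSet,
    Geometry,
    PropertySet,
    SurrogateEngine,
    boltzmann_factor,
    broaden,
    default_grid,
    ir_vcd_intensities,
    mirror,
    mode_derivatives,
    normal_mode_analysis,
    raman_roa_intensities,
    read_bands,
    scattering_prefactor,
    shift_origin,
    surrogate_engine,
    write_bands,
)
from voasim.constants import HC_OVER_KB
from voasim.intensities import IntensityError, raman_invariants, roa_invariants

from conftest import rotation_matrix


@pytest.fixture(scope="module")
def chiral_setup(chiral_toy):
    props = surrogate_engine(chiral_toy)
    modes = normal_mode_analysis(props)
    return chiral_toy, props, modes


# ---------------------------------------------------------------------------
# mode contraction
# ---------------------------------------------------------------------------

def test_mode_derivatives_matches_explicit_loop(chiral_setup):
    _, props, modes = chiral_setup
    arr = np.random.default_rng(0).normal(size=(props.n_atoms, 3, 3, 3))
    fast = mode_derivatives(modes, arr)
    slow = np.zeros_like(fast)
    for i in range(modes.n_modes):
        for a in range(props.n_atoms):
            for k in range(3):
                slow[i] += arr[a, k] * modes.displacements[i, a, k]
    assert np.abs(fast - slow).max() < 1e-12 * max(1.0, np.abs(slow).max())


def test_mode_derivatives_zero_and_delta(chiral_setup):
    _, props, modes = chiral_setup
    assert np.abs(mode_derivatives(modes, np.zeros((props.n_atoms, 3, 5)))).max() == 0.0
    # a single-atom unit displacement mode returns that atom's raw slice
    n = props.n_atoms
    disp = np.zeros((1, n, 3))
    disp[0, 2, 1] = 1.0
    unit_modes = type(modes)(wavenumbers=np.array([1000.0]), displacements=disp,
                             geometry_ref=modes.geometry_ref)
    arr = np.random.default_rng(1).normal(size=(n, 3, 4))
    assert np.abs(mode_derivatives(unit_modes, arr)[0] - arr[2, 1]).max() == 0.0


def test_mode_derivatives_dimension_mismatch(chiral_setup):
    _, _, modes = chiral_setup
    with pytest.raises(IntensityError):
        mode_derivatives(modes, np.zeros((2, 3, 3)))


# ---------------------------------------------------------------------------
# IR / VCD
# ---------------------------------------------------------------------------

def test_ir_nonnegative_and_vcd_available(chiral_setup):
    _, props, modes = chiral_setup
    ir, vcd = ir_vcd_intensities(modes, props)
    assert (ir.intensities >= 0).all()
    assert vcd is not None and np.abs(vcd.intensities).max() > 0


def test_vcd_unavailable_without_aat(chiral_setup):
    _, props, modes = chiral_setup
    p = props.copy()
    p.aat = None
    ir, vcd = ir_vcd_intensities(modes, p)
    assert vcd is None and ir.intensities.size > 0


def test_rotational_strength_sum_rule(chiral_setup):
    """Summed over the complete (unprojected) mode set the rotational
    strengths cancel exactly."""
    _, props, _ = chiral_setup
    modes_all = normal_mode_analysis(props, project_rigid=False)
    _, vcd = ir_vcd_intensities(modes_all, props, min_wavenumber=None)
    assert abs(vcd.intensities.sum()) < 1e-8 * np.abs(vcd.intensities).max()


def test_planar_molecule_has_zero_vcd_and_roa(water_toy):
    g = water_toy.copy()
    g.coords = g.coords + 0.0
    props = surrogate_engine(g)
    modes = normal_mode_analysis(props)
    _, vcd = ir_vcd_intensities(modes, props)
    scale_r = max(np.abs(mode_derivatives(modes, np.swapaxes(props.apt, 1, 2))).max(), 1.0)
    assert np.abs(vcd.intensities).max() < 1e-10 * scale_r
    raman, roa = raman_roa_intensities(modes, props)
    assert np.abs(roa.intensities).max() < 1e-10 * np.abs(raman.intensities).max()


def test_mirror_flips_vcd_and_roa_per_mode(chiral_setup):
    """The L and D forms of a molecule with non-degenerate modes give
    identical wavenumbers and IR/Raman but sign-flipped VCD/ROA, mode by
    mode: the computational twin of an enantiomer measurement."""
    g, props, modes = chiral_setup
    gm = mirror(g)
    pm = surrogate_engine(gm)
    mm = normal_mode_analysis(pm)
    assert np.abs(modes.wavenumbers - mm.wavenumbers).max() < 1e-6
    ir_l, vcd_l = ir_vcd_intensities(modes, props)
    ir_d, vcd_d = ir_vcd_intensities(mm, pm)
    scale = np.abs(ir_l.intensities).max()
    assert np.abs(ir_l.intensities - ir_d.intensities).max() < 1e-8 * scale
    assert np.abs(vcd_l.intensities + vcd_d.intensities).max() < 1e-8 * np.abs(vcd_l.intensities).max()
    ram_l, roa_l = raman_roa_intensities(modes, props)
    ram_d, roa_d = raman_roa_intensities(mm, pm)
    assert np.abs(ram_l.intensities - ram_d.intensities).max() < 1e-8 * np.abs(ram_l.intensities).max()
    assert np.abs(roa_l.intensities + roa_d.intensities).max() < 1e-8 * np.abs(roa_l.intensities).max()


# ---------------------------------------------------------------------------
# Raman / ROA invariants
# ---------------------------------------------------------------------------

def test_isotropic_tensor_toy_closed_form():
    """alpha' proportional to the identity gives beta invariants of zero,
    zero ROA and Raman proportional to 45 a^2."""
    alpha_p = np.stack([2.5 * np.eye(3)])
    a, beta2 = raman_invariants(alpha_p)
    assert abs(a[0] - 2.5) < 1e-12
    assert abs(beta2[0]) < 1e-10
    beta_g, beta_a = roa_invariants(alpha_p, np.zeros((1, 3, 3)),
                                    np.zeros((1, 3, 3, 3)), 18797.0)
    assert abs(beta_g[0]) == 0.0 and abs(beta_a[0]) == 0.0


def test_roa_unavailable_without_chiral_tensors(chiral_setup):
    _, props, modes = chiral_setup
    p = props.copy()
    p.dgprime = None
    raman, roa = raman_roa_intensities(modes, p)
    assert roa is None and raman.intensities.size > 0


def test_roa_origin_independence(chiral_setup):
    """A 5 A origin shift with consistently re-referenced G'/A leaves every
    backscattering ROA band unchanged."""
    _, props, modes = chiral_setup
    _, roa0 = raman_roa_intensities(modes, props)
    shifted = shift_origin(props, props.origin + np.array([5.0, 0.0, 0.0]))
    ram1, roa1 = raman_roa_intensities(modes, shifted)
    assert np.abs(roa1.intensities - roa0.intensities).max() \
        < 1e-8 * np.abs(roa0.intensities).max()


def test_vcd_origin_independence(chiral_setup):
    _, props, modes = chiral_setup
    _, vcd0 = ir_vcd_intensities(modes, props)
    shifted = shift_origin(props, props.origin + np.array([-3.0, 4.0, 1.0]))
    _, vcd1 = ir_vcd_intensities(modes, shifted)
    assert np.abs(vcd1.intensities - vcd0.intensities).max() \
        < 1e-8 * np.abs(vcd0.intensities).max()


def test_rotational_invariance_of_all_bands(chiral_toy):
    """Rigidly rotating geometry and tensors leaves every band intensity
    unchanged to 1e-8 relative (compared via broadened spectra to absorb
    the arbitrary mode ordering)."""
    props = surrogate_engine(chiral_toy)
    modes = normal_mode_analysis(props)
    rot = rotation_matrix(33)
    g2 = chiral_toy.copy()
    g2.coords = chiral_toy.coords @ rot.T
    props2 = surrogate_engine(g2)
    modes2 = normal_mode_analysis(props2)
    grid = default_grid(50, 4000, 2.0)
    for maker in (lambda m, p: ir_vcd_intensities(m, p),
                  lambda m, p: raman_roa_intensities(m, p)):
        for b1, b2 in zip(maker(modes, props), maker(modes2, props2)):
            s1 = broaden(b1, grid)
            s2 = broaden(b2, grid)
            assert np.abs(s1.values - s2.values).max() \
                < 1e-8 * np.abs(s1.values).max(), b1.spectroscopy


# ---------------------------------------------------------------------------
# prefactors and serialization
# ---------------------------------------------------------------------------

def test_boltzmann_prefactor_closed_form():
    t = 300.0
    for nu in (100.0, 1600.0):
        expected = 1.0 / (1.0 - np.exp(-HC_OVER_KB * nu / t))
        assert np.isclose(boltzmann_factor(nu, t), expected, rtol=1e-12)
    # low-wavenumber bands are strictly amplified
    assert boltzmann_factor(100.0, t) > boltzmann_factor(1600.0, t) > 1.0
    ratio = scattering_prefactor(np.array([100.0]), 18797.0, t)[0] \
        / scattering_prefactor(np.array([1600.0]), 18797.0, t)[0]
    expected = ((18797.0 - 100.0) ** 4 / 100.0 * boltzmann_factor(100.0, t)) \
        / ((18797.0 - 1600.0) ** 4 / 1600.0 * boltzmann_factor(1600.0, t))
    assert np.isclose(ratio, expected, rtol=1e-12)


def test_band_table_round_trip(tmp_path, chiral_setup):
    _, props, modes = chiral_setup
    _, roa = raman_roa_intensities(modes, props)
    path = str(tmp_path / "roa.txt")
    write_bands(roa, path)
    back = read_bands(path)
    assert back.spectroscopy == "ROA"
    assert np.abs(back.wavenumbers - roa.wavenumbers).max() < 1e-6
    assert np.allclose(back.intensities, roa.intensities, rtol=1e-10)
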