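"""Surrogate physics engine and fixture generators.

The engine stands in for the quantum-chemical stage of the pipeline: from a
geometry it derives a harmonic force field (pairwise distance harmonics over
bonded 1-2, 1-3 and 1-4 atom pairs, with analytic gradients and Hessians)
and physically shaped intensity tensors:

* APT from per-element charges plus a bond charge-flux term;
* alpha derivatives from a bond-polarizability model (isotropic plus
  anisotropic contribution along each bond, both growing linearly with the
  bond length, so the Cartesian derivatives are analytic);
* AAT, G' and A derivatives from the distributed-origin construction over
  per-atom alpha/APT contributions, which makes every parity property
  (mirror geometries give sign-flipped chiral tensors) and every
  origin-shift relation hold exactly by construction.

The surrogate is physically shaped but deliberately not DFT-accurate:
default force constants put amide-like C=O stretches in 1600-1800 cm^-1 and
X-H stretches in 2800-3600 cm^-1, so spectral regions carry their usual
qualitative meaning, while every quantitative check built on the engine is
structural (parity, invariance, convergence), never band-position agreement
with electronic-structure results.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .constants import ATOMIC_MASSES, DEFAULT_EXCITATION_WAVENUMBER
from .structures import Geometry, GeometryError, guess_bonds, build_polypeptide, \
    measure_torsions, ConformerSpec
from .cct import PropertySet, EPS, AAT_GAUGE
from .intensities import BandSet
from .spectra import Spectrum, broaden


class SurrogateError(ValueError):
    pass


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def _default_bond_k() -> dict:
    # (sorted element pair) -> [(max_length, k in mdyn/A), ...]; shorter bonds
    # (higher bond order) are stiffer
    return {
        ("C", "C"): [(1.42, 8.5), (99.0, 4.5)],
        ("C", "N"): [(1.40, 6.6), (99.0, 5.3)],
        ("C", "O"): [(1.30, 10.2), (99.0, 5.1)],
        ("C", "H"): [(99.0, 4.8)],
        ("H", "N"): [(99.0, 6.2)],
        ("H", "O"): [(99.0, 7.2)],
        ("N", "N"): [(99.0, 5.0)],
        ("O", "O"): [(99.0, 4.5)],
        ("Na", "O"): [(99.0, 0.8)],
        ("H", "Na"): [(99.0, 0.5)],
        ("C", "Na"): [(99.0, 0.5)],
        ("N", "Na"): [(99.0, 0.6)],
        ("Na", "Na"): [(99.0, 0.3)],
    }


@dataclasses.dataclass
class SurrogateParams:
    """Force-field and intensity-model parameters of the surrogate engine.

    bond_k maps a sorted element pair to (length cutoff, force constant)
    tiers; angle_k / torsion_k are effective distance-space constants for
    1-3 and 1-4 pairs (mdyn/A); charges (e) and the charge-flux weight feed
    the APT model; pol_iso / pol_aniso are bond-polarizability slopes per
    unit bond length.  noise > 0 applies seeded multiplicative jitter to the
    per-pair force constants (emulating snapshot-to-snapshot heterogeneity).
    """

    bond_k: dict = dataclasses.field(default_factory=_default_bond_k)
    angle_k: float = 0.55
    angle_k_h: float = 0.38
    torsion_k: float = 0.07
    charges: dict = dataclasses.field(default_factory=lambda: {
        "H": 0.18, "C": 0.12, "N": -0.40, "O": -0.42, "Na": 1.0, "S": -0.2,
    })
    charge_flux: float = 0.25
    pol_iso: float = 1.10   # per Angstrom of bond length
    pol_aniso: float = 0.85
    excitation_wavenumber: float = DEFAULT_EXCITATION_WAVENUMBER
    noise: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for pair, tiers in self.bond_k.items():
            for _, k in tiers:
                if k <= 0:
                    raise SurrogateError(f"non-positive force constant for {pair}")
        for el in ("H", "C", "N", "O", "Na"):
            if el not in self.charges:
                raise SurrogateError(f"charge table incomplete: missing {el}")

    def bond_constant(self, el_a: str, el_b: str, length: float) -> float:
        pair = tuple(sorted((el_a, el_b)))
        tiers = self.bond_k.get(pair)
        if tiers is None:
            raise SurrogateError(f"no bond force constant for pair {pair}")
        for cutoff, k in tiers:
            if length <= cutoff:
                return k
        return tiers[-1][1]


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------

class SurrogateEngine:
    """Deterministic harmonic engine anchored at a reference geometry.

    The reference geometry defines the pair list (1-2 bonds from covalent
    radii, 1-3 and 1-4 pairs from the bond graph) and the equilibrium pair
    distances, making the reference the exact minimum of the energy surface.
    `evaluate` implements the EnergyEngine contract at arbitrary
    displacements of the same atom set; `properties` returns the PropertySet
    (force field + intensity tensors) at the reference point.
    """

    def __init__(self, geometry: Geometry, params: SurrogateParams | None = None):
        self.reference = geometry.copy()
        self.params = params or SurrogateParams()
        self.params.validate()
        bonds = guess_bonds(geometry)
        n = geometry.n_atoms
        adj: list[set[int]] = [set() for _ in range(n)]
        for i, j in bonds:
            adj[i].add(j)
            adj[j].add(i)
        orphans = [i for i in range(n) if not adj[i]] if n > 1 else []
        if orphans:
            raise SurrogateError(f"disconnected atoms: {orphans[:10]}")
        self.bonds = bonds
        self.adjacency = adj

        b12 = set(bonds)
        b13, b14 = set(), set()
        for j in range(n):
            nb = sorted(adj[j])
            for x in range(len(nb)):
                for y in range(x + 1, len(nb)):
                    p = (nb[x], nb[y])
                    if p not in b12:
                        b13.add(p)
        for i, j in bonds:
            for k in adj[j] - {i}:
                for l in adj[k] - {j, i}:
                    p = (min(i, l), max(i, l))
                    if i != l and p not in b12 and p not in b13:
                        b14.add(p)
            for k in adj[i] - {j}:
                for l in adj[k] - {i, j}:
                    p = (min(j, l), max(j, l))
                    if j != l and p not in b12 and p not in b13:
                        b14.add(p)

        coords = geometry.coords
        els = geometry.elements
        rng = np.random.default_rng(self.params.seed)

        def jitter() -> float:
            if self.params.noise <= 0:
                return 1.0
            return float(max(0.1, rng.normal(1.0, self.params.noise)))

        pairs: list[tuple[int, int, float, float, str]] = []
        for i, j in sorted(b12):
            r0 = float(np.linalg.norm(coords[i] - coords[j]))
            k = self.params.bond_constant(els[i], els[j], r0) * jitter()
            pairs.append((i, j, k, r0, "bond"))
        for i, j in sorted(b13):
            r0 = float(np.linalg.norm(coords[i] - coords[j]))
            k = (self.params.angle_k_h if "H" in (els[i], els[j])
                 else self.params.angle_k) * jitter()
            pairs.append((i, j, k, r0, "angle"))
        for i, j in sorted(b14):
            r0 = float(np.linalg.norm(coords[i] - coords[j]))
            pairs.append((i, j, self.params.torsion_k * jitter(), r0, "torsion"))
        self.pairs = pairs

    # -- EnergyEngine contract ---------------------------------------------

    def evaluate(self, geometry: Geometry, need_hessian: bool = False
                 ) -> tuple[float, np.ndarray, np.ndarray | None]:
        x = geometry.coords
        n = x.shape[0]
        energy = 0.0
        grad = np.zeros((n, 3))
        hess = np.zeros((3 * n, 3 * n)) if need_hessian else None
        for i, j, k, r0, _ in self.pairs:
            d = x[i] - x[j]
            r = float(np.linalg.norm(d))
            u = d / r
            dr = r - r0
            energy += 0.5 * k * dr * dr
            g = k * dr * u
            grad[i] += g
            grad[j] -= g
            if need_hessian:
                blk = k * (np.outer(u, u) + (dr / r) * (np.eye(3) - np.outer(u, u)))
                ii, jj = 3 * i, 3 * j
                hess[ii:ii + 3, ii:ii + 3] += blk
                hess[jj:jj + 3, jj:jj + 3] += blk
                hess[ii:ii + 3, jj:jj + 3] -= blk
                hess[jj:jj + 3, ii:ii + 3] -= blk
        return energy, grad, hess

    # -- intensity tensors at the reference geometry ------------------------

    def properties(self, origin: np.ndarray | None = None) -> PropertySet:
        g = self.reference
        n = g.n_atoms
        x = g.coords
        p = self.params
        if origin is None:
            origin = x.mean(axis=0)
        origin = np.asarray(origin, float)

        # Hessian at the minimum: sum of k u u^T pair blocks
        hess = np.zeros((3 * n, 3 * n))
        for i, j, k, r0, _ in self.pairs:
            d = x[i] - x[j]
            u = d / np.linalg.norm(d)
            blk = k * np.outer(u, u)
            ii, jj = 3 * i, 3 * j
            hess[ii:ii + 3, ii:ii + 3] += blk
            hess[jj:jj + 3, jj:jj + 3] += blk
            hess[ii:ii + 3, jj:jj + 3] -= blk
            hess[jj:jj + 3, ii:ii + 3] -= blk

        # APT: atomic charge plus bond charge flux
        apt = np.zeros((n, 3, 3))
        for a in range(n):
            apt[a] = p.charges[g.elements[a]] * np.eye(3)
        for i, j in self.bonds:
            d = x[i] - x[j]
            u = d / np.linalg.norm(d)
            flux = p.charge_flux * np.outer(u, u)
            apt[i] += flux
            apt[j] -= flux

        # bond polarizability: per-atom alpha contributions and derivatives
        # alpha_atom[a] = 1/2 sum_{bonds at a} alpha_bond
        # dalpha_atom[c, kappa, a] = d alpha_atom[a] / dx_{c,kappa}
        alpha_atom = np.zeros((n, 3, 3))
        dalpha_atom = np.zeros((n, 3, n, 3, 3))  # (c, kappa, a, alpha, beta)
        for i, j in self.bonds:
            d = x[i] - x[j]
            r = float(np.linalg.norm(d))
            u = d / r
            uu = np.outer(u, u)
            iso, aniso = p.pol_iso, p.pol_aniso
            alpha_bond = iso * r * np.eye(3) + aniso * r * (uu - np.eye(3) / 3.0)
            du = (np.eye(3) - uu) / r  # du_alpha/dx_{i,kappa} = du[kappa, alpha]
            # derivative of alpha_bond wrt x_i (x_j is the negative)
            dab = np.zeros((3, 3, 3))  # (kappa, alpha, beta)
            for kap in range(3):
                term = iso * u[kap] * np.eye(3) \
                    + aniso * u[kap] * (uu - np.eye(3) / 3.0) \
                    + aniso * r * (np.outer(du[kap], u) + np.outer(u, du[kap]))
                dab[kap] = term
            for a in (i, j):
                alpha_atom[a] += 0.5 * alpha_bond
                dalpha_atom[i, :, a] += 0.5 * dab
                dalpha_atom[j, :, a] -= 0.5 * dab

        dalpha = dalpha_atom.sum(axis=2)  # total d alpha / dx_{c,kappa}

        # AAT: distributed-origin construction from atomic APT contributions
        rel = x - origin
        aat = AAT_GAUGE * np.einsum("xgd,ag,adb->axb", EPS, rel, apt)

        # G' derivative: (w/2) eps_{beta g d} [delta_{ac} delta_{g kappa}
        #   alpha^a_{alpha d} + rel_{a g} dalpha^a_{alpha d}/dx_{c kappa}]
        w = p.excitation_wavenumber
        dgprime = 0.5 * w * (
            np.einsum("bkd,cxd->ckxb", EPS, alpha_atom)
            + np.einsum("bgd,ag,ckaxd->ckxb", EPS, rel, dalpha_atom)
        )

        # A derivative: position-symmetrized atomic alpha contributions
        eye = np.eye(3)
        da = 1.5 * (
            np.einsum("bk,cxg->ckxbg", eye, alpha_atom)
            + np.einsum("ab,ckaxg->ckxbg", rel, dalpha_atom)
            + np.einsum("gk,cxb->ckxbg", eye, alpha_atom)
            + np.einsum("ag,ckaxb->ckxbg", rel, dalpha_atom)
        ) - (
            np.einsum("bg,dk,cxd->ckxbg", eye, eye, alpha_atom)
            + np.einsum("bg,ad,ckaxd->ckxbg", eye, rel, dalpha_atom)
        )

        props = PropertySet(
            geometry_ref=g,
            hessian=hess,
            apt=apt,
            aat=aat,
            dalpha=dalpha,
            dgprime=dgprime,
            da=da,
            origin=origin,
            excitation_wavenumber=w,
        )
        props.validate()
        return props


def surrogate_engine(geometry: Geometry, params: SurrogateParams | None = None,
                     origin: np.ndarray | None = None) -> PropertySet:
    """Convenience wrapper: PropertySet of the surrogate engine at the given
    geometry.  The engine itself is available in meta["engine"] as the
    EnergyEngine view."""
    eng = SurrogateEngine(geometry, params)
    props = eng.properties(origin=origin)
    props.meta["engine"] = eng
    return props


class QuadraticEngine:
    """Exact quadratic surface E = 1/2 (x-x*)^T H (x-x*): the closed-form
    test bed for constrained optimization."""

    def __init__(self, hessian: np.ndarray, minimum_coords: np.ndarray):
        self.hessian = np.asarray(hessian, float)
        self.minimum = np.asarray(minimum_coords, float).ravel()

    def evaluate(self, geometry: Geometry, need_hessian: bool = False):
        dx = geometry.coords.ravel() - self.minimum
        energy = 0.5 * float(dx @ self.hessian @ dx)
        grad = (self.hessian @ dx).reshape(-1, 3)
        return energy, grad, (self.hessian if need_hessian else None)


# ---------------------------------------------------------------------------
# snapshot and reference-spectrum generators
# ---------------------------------------------------------------------------

def jitter_snapshots(geometry: Geometry, torsion_sigma: float, n: int,
                     seed: int = 0) -> list[Geometry]:
    """Rebuild a single-chain peptide n times with backbone torsions
    perturbed by zero-mean Gaussian noise of the given spread (degrees).

    Emulates the torsion diversity of restrained-dynamics snapshots.
    Deterministic for a fixed seed; sigma = 0 returns n identical copies.
    """
    if torsion_sigma < 0:
        raise SurrogateError("torsion_sigma must be >= 0")
    if geometry.n_chains != 1:
        raise SurrogateError("snapshot jitter supports single-chain geometries")
    if torsion_sigma == 0:
        return [geometry.copy() for _ in range(n)]
    tors = measure_torsions(geometry)
    nres = tors.shape[0]
    phi = tors[:, 0].copy()
    psi = tors[:, 1].copy()
    phi[np.isnan(phi)] = np.nanmean(phi)
    psi[np.isnan(psi)] = np.nanmean(psi)
    spec = ConformerSpec("custom", float(np.mean(phi)), float(np.mean(psi)))
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        dphi = np.clip(phi + rng.normal(0.0, torsion_sigma, nres), -179.9, 180.0)
        dpsi = np.clip(psi + rng.normal(0.0, torsion_sigma, nres), -179.9, 180.0)
        out.append(build_polypeptide(
            nres, spec, protonation=geometry.protonation_state,
            phi_list=dphi, psi_list=dpsi,
        ))
    return out


def make_reference_spectrum(
    bands: BandSet,
    grid: np.ndarray,
    fwhm: float = 10.0,
    noise_sigma: float = 0.0,
    baseline_poly: np.ndarray | list | None = None,
    seed: int = 0,
) -> Spectrum:
    """Synthetic stand-in for an experimental spectrum: broadened bands plus
    Gaussian noise and a polynomial baseline (coefficients over the grid
    normalized to [0, 1]).  Generation parameters are recorded in meta."""
    spec = broaden(bands, grid, fwhm, provenance="synthetic")
    rng = np.random.default_rng(seed)
    values = spec.values.copy()
    if baseline_poly is not None and len(baseline_poly):
        t = (spec.grid - spec.grid[0]) / (spec.grid[-1] - spec.grid[0])
        values = values + np.polyval(np.asarray(baseline_poly, float), t)
    if noise_sigma > 0:
        values = values + rng.normal(0.0, noise_sigma, values.shape)
    spec.values = values
    spec.meta.update({
        "fwhm": fwhm, "noise_sigma": noise_sigma,
        "baseline_poly": list(baseline_poly or []), "seed": seed,
    })
    return spec
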