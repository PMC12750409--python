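"""Mass-weighted harmonic analysis and normal-mode-constrained optimization.

Wavenumbers come from eigenvalues of the mass-weighted Hessian (mdyn/A, amu)
via nu~ = 1302.79 * sqrt(lambda).  Rigid-body translations and infinitesimal
rotations are removed with an Eckart projector.  Partial optimization
minimizes a pluggable energy engine in normal-mode coordinates while
freezing all modes below a wavenumber threshold, the standard trick for
relaxing high-frequency internal strain without disturbing the backbone
conformation.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Protocol

import numpy as np

from .constants import WAVENUMBER_CONVERSION
from .structures import Geometry, GeometryError
from .cct import PropertySet


class HarmonicError(ValueError):
    pass


class EnergyEngine(Protocol):
    """Deterministic energy/gradient (and optionally Hessian) provider."""

    def evaluate(self, geometry: Geometry, need_hessian: bool = False
                 ) -> tuple[float, np.ndarray, np.ndarray | None]:
        ...


@dataclasses.dataclass
class NormalModes:
    """Harmonic wavenumbers and mode vectors.

    displacements[i, a, :] is the Cartesian displacement of atom a in mode i;
    the stored convention is mass-weighted orthonormality,
    sum_a m_a S_i^a . S_j^a = delta_ij.  Imaginary modes (negative
    eigenvalues beyond tolerance) are reported with negative wavenumbers and
    listed in imaginary_modes.
    """

    wavenumbers: np.ndarray
    displacements: np.ndarray
    geometry_ref: Geometry
    imaginary_modes: list[int] = dataclasses.field(default_factory=list)

    @property
    def n_modes(self) -> int:
        return self.wavenumbers.size


def is_linear(geometry: Geometry, rel_tol: float = 1e-8) -> bool:
    """Linearity via degeneracy of the smallest principal moment of inertia."""
    m = geometry.masses
    x = geometry.coords - np.average(geometry.coords, axis=0, weights=m)
    inertia = np.einsum("a,ij->ij", m * (x ** 2).sum(axis=1), np.eye(3)) \
        - np.einsum("a,ai,aj->ij", m, x, x)
    ev = np.linalg.eigvalsh(inertia)
    return ev[0] < rel_tol * max(ev[-1], 1e-300)


def rigid_body_vectors(geometry: Geometry) -> np.ndarray:
    """Mass-weighted orthonormal translation/rotation vectors (3N, 6 or 5)."""
    n = geometry.n_atoms
    m = np.sqrt(geometry.masses)
    x = geometry.coords - np.average(geometry.coords, axis=0, weights=geometry.masses)
    vecs = []
    for k in range(3):
        v = np.zeros((n, 3))
        v[:, k] = m
        vecs.append(v.ravel())
    for k in range(3):
        axis = np.zeros(3)
        axis[k] = 1.0
        v = (m[:, None] * np.cross(np.broadcast_to(axis, (n, 3)), x)).ravel()
        vecs.append(v)
    q, r = np.linalg.qr(np.stack(vecs, axis=1))
    keep = np.abs(np.diag(r)) > 1e-8 * np.abs(r).max()
    return q[:, keep]


def project_rigid_body(hessian: np.ndarray, geometry: Geometry) -> np.ndarray:
    """Project translations and infinitesimal rotations out of the
    mass-weighted Hessian.  Idempotent: projecting twice equals once."""
    b = rigid_body_vectors(geometry)
    p = np.eye(hessian.shape[0]) - b @ b.T
    return p @ hessian @ p


def mass_weighted_hessian(props: PropertySet) -> np.ndarray:
    g = props.geometry_ref
    inv = 1.0 / np.sqrt(np.repeat(g.masses, 3))
    return props.hessian * np.outer(inv, inv)


def normal_mode_analysis(
    props: PropertySet,
    project_rigid: bool = True,
    sym_tol: float = 1e-8,
) -> NormalModes:
    """Diagonalize the (projected) mass-weighted Hessian.

    With projection on, the 6 rigid-body directions (5 for linear systems)
    are removed and exactly 3N-6 (3N-5) vibrational modes are returned.
    Negative projected eigenvalues beyond numerical zero are flagged as
    imaginary modes and reported with negative wavenumbers.
    """
    g = props.geometry_ref
    n = g.n_atoms
    scale = max(1.0, np.abs(props.hessian).max())
    if np.abs(props.hessian - props.hessian.T).max() > sym_tol * scale:
        raise HarmonicError("Hessian asymmetric beyond tolerance")
    mwh = mass_weighted_hessian(props)
    mwh = 0.5 * (mwh + mwh.T)
    if project_rigid:
        mwh = project_rigid_body(mwh, g)
    evals, evecs = np.linalg.eigh(mwh)
    if project_rigid:
        n_rigid = 5 if is_linear(g) else 6
        order = np.argsort(np.abs(evals))
        keep = np.sort(order[n_rigid:])
        evals, evecs = evals[keep], evecs[:, keep]
    nu = WAVENUMBER_CONVERSION * np.sign(evals) * np.sqrt(np.abs(evals))
    imag = [int(i) for i in np.flatnonzero(evals < -1e-10 * max(scale, 1.0))]
    inv_sqrt_m = 1.0 / np.sqrt(np.repeat(g.masses, 3))
    disp = (evecs * inv_sqrt_m[:, None]).T.reshape(-1, n, 3)
    order = np.argsort(nu)
    return NormalModes(
        wavenumbers=nu[order],
        displacements=disp[order],
        geometry_ref=g,
        imaginary_modes=[int(np.flatnonzero(order == i)[0]) for i in imag],
    )


# ---------------------------------------------------------------------------
# partial optimization in normal-mode coordinates
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class OptimizationResult:
    geometry: Geometry
    converged: bool
    n_steps: int
    final_gradient_norm: float
    energies: list[float]


def partial_optimize(
    geometry: Geometry,
    engine: EnergyEngine,
    freeze_below: float = 100.0,
    max_steps: int = 200,
    grad_tol: float = 1e-6,
    trust_radius: float = 0.3,
    fixed_basis: bool = False,
) -> OptimizationResult:
    """Minimize the engine energy along modes with wavenumber >= freeze_below.

    The mode basis is recomputed from the engine Hessian at every step by
    default; with fixed_basis=True the initial basis is kept, in which case
    the displacement along frozen modes is exactly zero throughout.  Newton
    steps (trust-radius limited) are taken when the engine provides a
    Hessian, projected gradient descent otherwise.  Steps that would raise
    the energy are rejected with a halved trust radius.
    """
    if freeze_below < 0:
        raise HarmonicError("freeze_below must be >= 0")
    g = geometry.copy()
    n = g.n_atoms
    sqrt_m = np.sqrt(np.repeat(g.masses, 3))
    energies: list[float] = []
    basis = None
    omega = None
    tr = trust_radius

    def mode_basis(hess: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        props = PropertySet(geometry_ref=g, hessian=0.5 * (hess + hess.T))
        mwh = mass_weighted_hessian(props)
        mwh = project_rigid_body(0.5 * (mwh + mwh.T), g)
        evals, evecs = np.linalg.eigh(mwh)
        nu = WAVENUMBER_CONVERSION * np.sign(evals) * np.sqrt(np.abs(evals))
        return nu, evecs

    energy, grad, hess = engine.evaluate(g, need_hessian=True)
    energies.append(energy)
    grad_norm = np.inf
    step_count = 0
    for step_count in range(1, max_steps + 1):
        if basis is None or not fixed_basis:
            if hess is None:
                _, _, hess = engine.evaluate(g, need_hessian=True)
            omega, basis = mode_basis(hess)
        active = omega >= freeze_below
        # remove near-rigid directions from the active set
        active &= np.abs(omega) > 1e-6
        v = basis[:, active]
        gq = v.T @ (grad.ravel() / sqrt_m)
        grad_norm = float(np.linalg.norm(gq))
        if grad_norm < grad_tol:
            return OptimizationResult(g, True, step_count - 1, grad_norm, energies)
        if hess is not None:
            hq = v.T @ ((hess / np.outer(sqrt_m, sqrt_m)) @ v)
            ev, evec = np.linalg.eigh(hq)
            ev = np.where(np.abs(ev) < 1e-12, 1e-12, np.abs(ev))
            dq = -evec @ ((evec.T @ gq) / ev)
        else:
            dq = -gq
        norm = np.linalg.norm(dq)
        if norm > tr:
            dq *= tr / norm
        dx = (v @ dq) / sqrt_m
        trial = g.copy()
        trial.coords = g.coords + dx.reshape(n, 3)
        e_new, grad_new, hess_new = engine.evaluate(trial, need_hessian=True)
        if e_new <= energies[-1] + 1e-15:
            g = trial
            energies.append(e_new)
            grad, hess = grad_new, hess_new
            tr = min(trust_radius, tr * 1.5)
        else:
            tr *= 0.5
            if tr < 1e-8:
                break
    return OptimizationResult(g, grad_norm < grad_tol, step_count, grad_norm, energies)


# ---------------------------------------------------------------------------
# mode report
# ---------------------------------------------------------------------------

def write_mode_report(modes: NormalModes, path: str, top: int = 3) -> None:
    """Plain-text mode table: index, wavenumber, largest-amplitude atoms."""
    g = modes.geometry_ref
    with open(path, "w") as fh:
        fh.write("# mode wavenumber_cm-1 largest_amplitude_atoms\n")
        for i, (nu, disp) in enumerate(zip(modes.wavenumbers, modes.displacements)):
            amp = np.linalg.norm(disp, axis=1) * np.sqrt(g.masses)
            lead = np.argsort(amp)[::-1][:top]
            tags = ",".join(f"{g.atom_names[a]}:{a + 1}" for a in lead)
            fh.write(f"{i + 1} {nu:12.4f} {tags}\n")


def write_mode_file(modes: NormalModes, path: str) -> None:
    """Machine-readable mode file (wavenumbers + displacement matrix)."""
    n = modes.geometry_ref.n_atoms
    with open(path, "w") as fh:
        fh.write(f"VOASIM MODES {modes.n_modes} {n}\n")
        fh.write(" ".join("%.12e" % v for v in modes.wavenumbers) + "\n")
        for i in range(modes.n_modes):
            fh.write(" ".join("%.12e" % v for v in modes.displacements[i].ravel()) + "\n")


def read_mode_file(path: str, geometry: Geometry) -> NormalModes:
    with open(path) as fh:
        header = fh.readline().split()
        n_modes, n = int(header[2]), int(header[3])
        nu = np.array([float(v) for v in fh.readline().split()])
        disp = np.array([
            [float(v) for v in fh.readline().split()] for _ in range(n_modes)
        ]).reshape(n_modes, n, 3)
    if geometry.n_atoms != n:
        raise HarmonicError("geometry does not match mode file")
    return NormalModes(wavenumbers=nu, displacements=disp, geometry_ref=geometry)
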