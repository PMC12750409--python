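"""Cartesian-coordinate transfer (CCT) of vibrational property tensors.

Per-fragment harmonic force fields and intensity tensors (APT, AAT and the
Raman/ROA polarizability derivatives) are mapped onto a parent structure
using best-fit proper rotations of local atomic neighbourhoods.  Where
fragments overlap, contributions are combined with normalized weights;
Hessian blocks between atoms that never co-reside in a fragment are zeroed
and counted.  Origin-dependent tensors (AAT, G' and A derivatives) are
re-referenced to the parent origin before mixing.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

from .structures import Geometry, GeometryError, guess_bonds
from .fragmentation import FragmentMap
from .constants import DEFAULT_EXCITATION_WAVENUMBER

logger = logging.getLogger(__name__)

# Levi-Civita symbol
EPS = np.zeros((3, 3, 3))
EPS[0, 1, 2] = EPS[1, 2, 0] = EPS[2, 0, 1] = 1.0
EPS[0, 2, 1] = EPS[2, 1, 0] = EPS[1, 0, 2] = -1.0

#: gauge factor of the distributed-origin atomic axial tensors
AAT_GAUGE = 0.25


class TransferError(ValueError):
    pass


# ---------------------------------------------------------------------------
# property container
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PropertySet:
    """Harmonic force field plus intensity tensors for one Geometry.

    Index conventions (a = atom, Greek = Cartesian):
      hessian[3a+alpha, 3b+beta]      d2E / dx_{a,alpha} dx_{b,beta}   (mdyn/A)
      apt[a, alpha, beta]             d mu_alpha / dx_{a,beta}
      aat[a, alpha, beta]             d m_alpha  / dx_{a,beta}
      dalpha[a, kappa, alpha, beta]   d alpha_{alpha,beta} / dx_{a,kappa}
      dgprime[a, kappa, alpha, beta]  d G'_{alpha,beta}    / dx_{a,kappa}
      da[a, kappa, alpha, beta, gamma] d A_{alpha,beta gamma} / dx_{a,kappa}
    Origin-dependent tensors (aat, dgprime, da) refer to `origin` (Angstrom).
    """

    geometry_ref: Geometry
    hessian: np.ndarray
    apt: np.ndarray | None = None
    aat: np.ndarray | None = None
    dalpha: np.ndarray | None = None
    dgprime: np.ndarray | None = None
    da: np.ndarray | None = None
    origin: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(3))
    excitation_wavenumber: float = DEFAULT_EXCITATION_WAVENUMBER
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hessian = np.asarray(self.hessian, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def n_atoms(self) -> int:
        return self.geometry_ref.n_atoms

    def validate(self, rtol: float = 1e-10) -> None:
        n = self.n_atoms
        if self.hessian.shape != (3 * n, 3 * n):
            raise TransferError("hessian dimension does not match geometry")
        scale = max(1.0, np.abs(self.hessian).max())
        if np.abs(self.hessian - self.hessian.T).max() > rtol * scale:
            raise TransferError("hessian not symmetric within tolerance")
        if self.da is not None:
            if np.abs(self.da - self.da.transpose(0, 1, 2, 4, 3)).max() > 1e-8 * max(
                1.0, np.abs(self.da).max()
            ):
                raise TransferError("A-tensor derivative not symmetric in its last two indices")

    def translational_sum_rule_residual(self) -> float:
        """Largest net force response under rigid translation (should vanish)."""
        n = self.n_atoms
        h = self.hessian.reshape(n, 3, n, 3)
        return float(np.abs(h.sum(axis=2)).max())

    def copy(self) -> "PropertySet":
        return PropertySet(
            geometry_ref=self.geometry_ref,
            hessian=self.hessian.copy(),
            apt=None if self.apt is None else self.apt.copy(),
            aat=None if self.aat is None else self.aat.copy(),
            dalpha=None if self.dalpha is None else self.dalpha.copy(),
            dgprime=None if self.dgprime is None else self.dgprime.copy(),
            da=None if self.da is None else self.da.copy(),
            origin=self.origin.copy(),
            excitation_wavenumber=self.excitation_wavenumber,
            meta=dict(self.meta),
        )


def shift_origin(props: PropertySet, new_origin: np.ndarray) -> PropertySet:
    """Re-reference the origin-dependent tensors to a new Cartesian origin.

    Uses the standard shift relations: for a shift d = new - old,
      AAT   gains  -AAT_GAUGE * eps_{alpha gamma delta} d_gamma APT_{delta beta}
      dG'   gains  -(nu_exc/2) * eps_{beta gamma delta} d_gamma dalpha_{alpha delta}
      dA    gains  -(3/2)(d_beta dalpha_{alpha gamma} + d_gamma dalpha_{alpha beta})
                   + delta_{beta gamma} d_delta dalpha_{alpha delta}
    """
    d = np.asarray(new_origin, float) - props.origin
    out = props.copy()
    out.origin = np.asarray(new_origin, float)
    if not np.any(d):
        return out
    _shift_tensors_inplace(out, d)
    return out


def _shift_tensors_inplace(props: PropertySet, d: np.ndarray) -> None:
    if props.aat is not None and props.apt is not None:
        # aat[a, alpha, beta] -= AAT_GAUGE * eps[alpha,g,dl] d[g] apt[a,dl,beta]
        props.aat -= AAT_GAUGE * np.einsum("xgd,g,ndb->nxb", EPS, d, props.apt)
    if props.dgprime is not None and props.dalpha is not None:
        w = 0.5 * props.excitation_wavenumber
        props.dgprime -= w * np.einsum("bgd,g,nkxd->nkxb", EPS, d, props.dalpha)
    if props.da is not None and props.dalpha is not None:
        da = props.dalpha
        props.da -= 1.5 * (np.einsum("b,nkxg->nkxbg", d, da)
                           + np.einsum("g,nkxb->nkxbg", d, da))
        props.da += np.einsum("bg,d,nkxd->nkxbg", np.eye(3), d, da)


# ---------------------------------------------------------------------------
# best-fit rotations and assignments
# ---------------------------------------------------------------------------

def best_fit_rotation(source_points: np.ndarray, target_points: np.ndarray) -> np.ndarray:
    """Kabsch superposition: proper rotation R minimizing sum |R s_i - t_i|^2.

    Both point sets must be centred (centroids removed) and contain at least
    three non-collinear points; det(R) = +1 is enforced, so a reflected
    target is never matched exactly.
    """
    s = np.asarray(source_points, float)
    t = np.asarray(target_points, float)
    if s.shape != t.shape or s.shape[0] < 3:
        raise TransferError("need >= 3 matched points")
    if np.linalg.matrix_rank(s, tol=1e-8) < 2 or np.linalg.matrix_rank(t, tol=1e-8) < 2:
        raise TransferError("degenerate (collinear) point set")
    u, _, vt = np.linalg.svd(t.T @ s)
    det = np.linalg.det(u @ vt)
    u[:, -1] *= np.sign(det)
    return u @ vt


@dataclasses.dataclass
class TransferAssignment:
    """Per parent atom: covering (fragment id, fragment atom, rotation, weight).

    Weights over all covering fragments of an atom sum to 1; every rotation
    is proper orthogonal.
    """

    entries: list[list[tuple[int, int, np.ndarray, float]]]

    def validate(self) -> None:
        for a, lst in enumerate(self.entries):
            if not lst:
                raise TransferError(f"parent atom {a} has no covering fragment")
            total = sum(w for _, _, _, w in lst)
            if abs(total - 1.0) > 1e-8:
                raise TransferError(f"weights of atom {a} sum to {total}")
            for _, _, rot, _ in lst:
                if np.abs(rot @ rot.T - np.eye(3)).max() > 1e-8 or np.linalg.det(rot) < 0:
                    raise TransferError(f"invalid rotation for atom {a}")


def _fragment_weight(frag: FragmentMap, chain: int, res: int, span_half: float) -> float:
    """Triangular weight: linear decay with residue distance from the centre
    of the fragment segment on the atom's chain."""
    seg = [r for c, r in frag.anchor_residues if c == chain]
    if not seg:
        return 0.0
    center = (min(seg) + max(seg)) / 2.0
    return max(0.05, 1.0 - abs(res - center) / (span_half + 1.0))


def build_assignment(
    parent: Geometry,
    fragments: Sequence[FragmentMap],
    neighborhood_radius: float = 2.5,
    weight_rule: str = "triangular",
    parent_bonds: Sequence[tuple[int, int]] | None = None,
) -> TransferAssignment:
    """Compute per-atom local rotations and normalized overlap weights.

    The rotation for a parent atom within a fragment is fitted on the matched
    neighbourhood: covalently bonded atoms plus atoms within
    neighborhood_radius, at least 4 points (falling back to the residue
    backbone if degenerate).
    """
    if weight_rule not in ("triangular", "uniform"):
        raise TransferError(f"unknown weight rule {weight_rule!r}")
    if parent_bonds is None:
        parent_bonds = guess_bonds(parent)
    from scipy.spatial import cKDTree

    neighbors: list[set[int]] = [set() for _ in range(parent.n_atoms)]
    for i, j in parent_bonds:
        neighbors[i].add(j)
        neighbors[j].add(i)
    tree = cKDTree(parent.coords)
    close = tree.query_ball_point(parent.coords, neighborhood_radius)
    entries: list[list[tuple[int, int, np.ndarray, float]]] = [
        [] for _ in range(parent.n_atoms)
    ]
    for fid, frag in enumerate(fragments):
        fg = frag.fragment_geometry
        p2f = {int(p): i for i, p in enumerate(frag.parent_atoms) if p >= 0}
        span = len({r for _, r in frag.anchor_residues})
        for p, fa in p2f.items():
            nbh = (neighbors[p] | set(close[p]) | {p}) & p2f.keys()
            if len(nbh) < 4:
                res, ch = parent.residue_index[p], parent.chain_index[p]
                bb = [parent.find_atom(ch, res, nm) for nm in ("N", "CA", "C", "O")]
                nbh |= {b for b in bb if b >= 0 and b in p2f}
                nbh.add(p)
            nb = sorted(nbh)
            target = parent.coords[nb]
            source = fg.coords[[p2f[q] for q in nb]]
            try:
                rot = best_fit_rotation(source - source.mean(axis=0),
                                        target - target.mean(axis=0))
            except TransferError:
                rot = np.eye(3)
            if weight_rule == "uniform":
                w = 1.0
            else:
                w = _fragment_weight(frag, int(parent.chain_index[p]),
                                     int(parent.residue_index[p]), span / 2.0)
            entries[p].append((fid, fa, rot, w))

    uncovered = [a for a, lst in enumerate(entries) if not lst]
    if uncovered:
        raise TransferError(f"atoms with no covering fragment: {uncovered[:10]}")
    for lst in entries:
        total = sum(w for *_, w in lst)
        for i, (fid, fa, rot, w) in enumerate(lst):
            lst[i] = (fid, fa, rot, w / total)
    return TransferAssignment(entries=entries)


# ---------------------------------------------------------------------------
# the transfer itself
# ---------------------------------------------------------------------------

def _rot2(R: np.ndarray, T: np.ndarray) -> np.ndarray:
    return R @ T @ R.T


def transfer_properties(
    fragment_properties: Sequence[PropertySet],
    assignment: TransferAssignment,
    parent: Geometry,
    fragments: Sequence[FragmentMap] | None = None,
    origin: np.ndarray | None = None,
) -> PropertySet:
    """Assemble a parent PropertySet from per-fragment properties.

    Rank-2 atom blocks transform as R T R^T, Hessian cross blocks as
    R_a F_ab R_b^T, and every index of the rank-3/4 derivative tensors
    rotates with the owning atom's rotation.  Origin-dependent tensors are
    re-referenced to the parent origin before weighted combination.  Hessian
    blocks between atoms never co-resident in a fragment are zeroed; their
    count is stored in meta["zeroed_cross_blocks"].
    """
    n = parent.n_atoms
    if origin is None:
        origin = parent.coords.mean(axis=0)
    origin = np.asarray(origin, float)
    exc = fragment_properties[0].excitation_wavenumber

    have = {
        name: all(getattr(fp, name) is not None for fp in fragment_properties)
        for name in ("apt", "aat", "dalpha", "dgprime", "da")
    }
    out = PropertySet(
        geometry_ref=parent,
        hessian=np.zeros((3 * n, 3 * n)),
        apt=np.zeros((n, 3, 3)) if have["apt"] else None,
        aat=np.zeros((n, 3, 3)) if have["aat"] else None,
        dalpha=np.zeros((n, 3, 3, 3)) if have["dalpha"] else None,
        dgprime=np.zeros((n, 3, 3, 3)) if have["dgprime"] else None,
        da=np.zeros((n, 3, 3, 3, 3)) if have["da"] else None,
        origin=origin,
        excitation_wavenumber=exc,
    )

    # map (fid -> {parent atom -> (frag atom, R, w)})
    byfrag: dict[int, dict[int, tuple[int, np.ndarray, float]]] = {}
    for p, lst in enumerate(assignment.entries):
        for fid, fa, rot, w in lst:
            byfrag.setdefault(fid, {})[p] = (fa, rot, w)

    # per-atom tensors
    for p, lst in enumerate(assignment.entries):
        for fid, fa, rot, w in lst:
            fp = fragment_properties[fid]
            fg = fp.geometry_ref
            # effective origin shift for this atom's contribution, in the
            # parent frame: fragment origin mapped through the local motion
            d = origin - (rot @ (fp.origin - fg.coords[fa]) + parent.coords[p])
            if have["apt"]:
                out.apt[p] += w * _rot2(rot, fp.apt[fa])
            if have["aat"]:
                blk = _rot2(rot, fp.aat[fa])
                if have["apt"]:
                    blk = blk - AAT_GAUGE * np.einsum(
                        "xgd,g,db->xb", EPS, d, _rot2(rot, fp.apt[fa])
                    )
                out.aat[p] += w * blk
            if have["dalpha"]:
                dal = np.einsum("ip,jq,kr,pqr->ijk", rot, rot, rot, fp.dalpha[fa])
                out.dalpha[p] += w * dal
                if have["dgprime"]:
                    dg = np.einsum("ip,jq,kr,pqr->ijk", rot, rot, rot, fp.dgprime[fa])
                    dg = dg - 0.5 * exc * np.einsum("bgd,g,kxd->kxb", EPS, d, dal)
                    out.dgprime[p] += w * dg
                if have["da"]:
                    dA = np.einsum("ip,jq,kr,ls,pqrs->ijkl", rot, rot, rot, rot, fp.da[fa])
                    dA = dA - 1.5 * (np.einsum("b,kxg->kxbg", d, dal)
                                     + np.einsum("g,kxb->kxbg", d, dal))
                    dA = dA + np.einsum("bg,d,kxd->kxbg", np.eye(3), d, dal)
                    out.da[p] += w * dA

    # Hessian blocks
    num = np.zeros((n, n, 3, 3))
    den = np.zeros((n, n))
    for fid, amap in byfrag.items():
        fp = fragment_properties[fid]
        nf = fp.n_atoms
        hf = fp.hessian.reshape(nf, 3, nf, 3)
        atoms = sorted(amap)
        for i, p in enumerate(atoms):
            fa, ra, wa = amap[p]
            for q in atoms[i:]:
                fb, rb, wb = amap[q]
                w = wa if p == q else float(np.sqrt(wa * wb))
                num[p, q] += w * (ra @ hf[fa, :, fb, :] @ rb.T)
                den[p, q] += w

    covered = den > 0
    num[covered] /= den[covered][:, None, None]
    h = out.hessian.reshape(n, 3, n, 3)
    iu = np.triu_indices(n)
    for p, q in zip(*iu):
        if covered[p, q]:
            h[p, :, q, :] = num[p, q]
            if p != q:
                h[q, :, p, :] = num[p, q].T
    out.hessian = 0.5 * (out.hessian + out.hessian.T)
    zeroed = int(np.sum(~covered[np.triu_indices(n, k=1)]))
    out.meta["zeroed_cross_blocks"] = zeroed
    logger.info("transfer: %d Hessian cross blocks zeroed (no co-resident fragment)", zeroed)
    return out


# ---------------------------------------------------------------------------
# property-exchange text format
# ---------------------------------------------------------------------------

_FMT = "%.12e"


def write_property_set(props: PropertySet, path: str) -> None:
    """Plain-text property-exchange file (documented fixed layout)."""
    n = props.n_atoms
    with open(path, "w") as fh:
        fh.write("VOASIM PROPERTY EXCHANGE 1\n")
        fh.write(f"NATOMS {n}\n")
        fh.write("ORIGIN " + " ".join(_FMT % v for v in props.origin) + "\n")
        fh.write(f"EXCITATION {_FMT % props.excitation_wavenumber}\n")
        fh.write("UNITS angstrom amu mdyn_per_angstrom\n")
        _write_block(fh, "HESSIAN", props.hessian)
        for name, arr in (("APT", props.apt), ("AAT", props.aat),
                          ("DALPHA", props.dalpha), ("DGPRIME", props.dgprime),
                          ("DA", props.da)):
            if arr is not None:
                _write_block(fh, name, arr.reshape(arr.shape[0], -1))


def _write_block(fh, name: str, mat: np.ndarray) -> None:
    fh.write(f"{name} {mat.shape[0]} {mat.shape[1]}\n")
    for row in mat:
        fh.write(" ".join(_FMT % v for v in row) + "\n")


def read_property_set(path: str, geometry: Geometry) -> PropertySet:
    with open(path) as fh:
        if fh.readline().strip() != "VOASIM PROPERTY EXCHANGE 1":
            raise TransferError(f"{path}: not a property-exchange file")
        n = int(fh.readline().split()[1])
        origin = np.array([float(v) for v in fh.readline().split()[1:]])
        exc = float(fh.readline().split()[1])
        fh.readline()  # units
        blocks: dict[str, np.ndarray] = {}
        line = fh.readline()
        while line:
            name, rows, cols = line.split()
            mat = np.array([
                [float(v) for v in fh.readline().split()] for _ in range(int(rows))
            ])
            blocks[name] = mat.reshape(int(rows), int(cols))
            line = fh.readline()
    if geometry.n_atoms != n:
        raise TransferError("geometry does not match property file")

    def shaped(name: str, shape: tuple[int, ...]) -> np.ndarray | None:
        if name not in blocks:
            return None
        return blocks[name].reshape(shape)

    return PropertySet(
        geometry_ref=geometry,
        hessian=blocks["HESSIAN"],
        apt=shaped("APT", (n, 3, 3)),
        aat=shaped("AAT", (n, 3, 3)),
        dalpha=shaped("DALPHA", (n, 3, 3, 3)),
        dgprime=shaped("DGPRIME", (n, 3, 3, 3)),
        da=shaped("DA", (n, 3, 3, 3, 3)),
        origin=origin,
        excitation_wavenumber=exc,
    )
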