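"""Polyglutamate model building: strands, helices and multistrand fibrils.

Geometries are constructed residue by residue from standard internal
coordinates (bond lengths, valence angles) with user-controlled backbone
torsions, using the natural-extension-reference-frame (NeRF) placement rule.
The module also provides torsion measurement, mirror and deuteration
operations, connectivity perception and PDB/XYZ serialization.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Sequence

import numpy as np

from .constants import ATOMIC_MASSES, COVALENT_RADII, RESTRAINT_FLAT_WIDTH, RESTRAINT_FORCE_CONSTANT


class GeometryError(ValueError):
    """Raised for chemically or numerically invalid geometry requests."""


# ---------------------------------------------------------------------------
# core container
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Geometry:
    """A molecular structure with residue/chain bookkeeping.

    Attributes
    ----------
    elements : list of element symbols (isotope-independent, "H" for D).
    masses : per-atom masses in amu (deuteration changes the mass).
    coords : (N, 3) Cartesian positions in Angstrom.
    residue_index, chain_index : per-atom integer labels (0-based internally).
    atom_names : PDB-style role labels (N, CA, C, O, H, CB, ... OE2, HE2).
    protonation_state : "protonated" or "deprotonated" side-chain carboxyls.
    isotope_labels : per-atom "H"/"D" for hydrogens, "" otherwise.
    """

    elements: list[str]
    masses: np.ndarray
    coords: np.ndarray
    residue_index: np.ndarray
    chain_index: np.ndarray
    atom_names: list[str]
    protonation_state: str = "deprotonated"
    isotope_labels: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.chain_index = np.asarray(self.chain_index, dtype=int)
        if not self.isotope_labels:
            self.isotope_labels = ["H" if e == "H" else "" for e in self.elements]
        if np.any(self.masses <= 0):
            raise GeometryError("atomic masses must be strictly positive")
        if not np.all(np.isfinite(self.coords)):
            raise GeometryError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_residues(self) -> int:
        return len(np.unique(np.stack([self.chain_index, self.residue_index]), axis=1).T)

    @property
    def n_chains(self) -> int:
        return len(np.unique(self.chain_index))

    def copy(self) -> "Geometry":
        return Geometry(
            elements=list(self.elements),
            masses=self.masses.copy(),
            coords=self.coords.copy(),
            residue_index=self.residue_index.copy(),
            chain_index=self.chain_index.copy(),
            atom_names=list(self.atom_names),
            protonation_state=self.protonation_state,
            isotope_labels=list(self.isotope_labels),
        )

    def find_atom(self, chain: int, residue: int, name: str) -> int:
        """Index of a uniquely named atom, or -1 if absent."""
        hits = np.flatnonzero(
            (self.chain_index == chain)
            & (self.residue_index == residue)
            & np.array([n == name for n in self.atom_names])
        )
        return int(hits[0]) if hits.size else -1

    def chain_residues(self, chain: int) -> np.ndarray:
        return np.unique(self.residue_index[self.chain_index == chain])

    def subset(self, indices: Sequence[int]) -> "Geometry":
        idx = np.asarray(indices, dtype=int)
        return Geometry(
            elements=[self.elements[i] for i in idx],
            masses=self.masses[idx],
            coords=self.coords[idx],
            residue_index=self.residue_index[idx],
            chain_index=self.chain_index[idx],
            atom_names=[self.atom_names[i] for i in idx],
            protonation_state=self.protonation_state,
            isotope_labels=[self.isotope_labels[i] for i in idx],
        )


# ---------------------------------------------------------------------------
# conformer table
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ConformerSpec:
    """Named backbone conformation given by (phi, psi) and the peptide torsion omega."""

    name: str
    phi: float
    psi: float
    omega: float = 180.0

    def __post_init__(self) -> None:
        for label, value in (("phi", self.phi), ("psi", self.psi), ("omega", self.omega)):
            if not (-180.0 < value <= 180.0):
                raise GeometryError(f"{label} = {value} outside (-180, 180]")


#: canonical backbone torsions for polyglutamate secondary structures (degrees)
CANONICAL_CONFORMERS: dict[str, ConformerSpec] = {
    "PPII": ConformerSpec("PPII", -75.0, 150.0),
    "alpha": ConformerSpec("alpha", -60.0, -45.0),
    "three10": ConformerSpec("three10", -49.0, -26.0),
    "beta_parallel": ConformerSpec("beta_parallel", -140.0, 130.0),
    "beta_antiparallel": ConformerSpec("beta_antiparallel", -120.0, 115.0),
}


def get_conformer(spec: "ConformerSpec | str") -> ConformerSpec:
    if isinstance(spec, ConformerSpec):
        return spec
    try:
        return CANONICAL_CONFORMERS[spec]
    except KeyError:
        raise GeometryError(
            f"unknown conformer {spec!r}; known: {sorted(CANONICAL_CONFORMERS)}"
        ) from None


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------

def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion p0-p1-p2-p3 in degrees, in (-180, 180].

    Returns NaN for degenerate (collinear) configurations.
    """
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    nb1 = np.linalg.norm(b1)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10 or nb1 < 1e-10:
        return float("nan")
    angle = math.degrees(math.atan2(np.dot(np.cross(n1, n2), b1) / nb1, np.dot(n1, n2)))
    if angle <= -180.0:
        angle += 360.0
    return angle


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position d bonded to c with |dc| = bond,
    angle(b,c,d) = angle_deg and dihedral(a,b,c,d) = torsion_deg."""
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise GeometryError("collinear reference atoms in NeRF placement")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(chi),
        bond * math.sin(theta) * math.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------------------------------
# internal-coordinate template (glutamic acid)
# ---------------------------------------------------------------------------

# backbone geometry (Angstrom / degrees), standard peptide values
BB = {
    "N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231,
    "N-H": 1.010, "CA-HA": 1.090, "C-OXT": 1.330, "O-H": 0.980,
    "N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7,
    "CA-C-O": 120.5, "C-N-H": 119.0,
}

# Glu side chain
SC = {
    "CA-CB": 1.530, "CB-CG": 1.520, "CG-CD": 1.516,
    "CD-OE1": 1.214, "CD-OE2p": 1.318, "CD-OEd": 1.250,
    "C-H": 1.090, "OE2-HE2": 0.974,
    "N-CA-CB": 110.5, "CA-CB-CG": 114.1, "CB-CG-CD": 113.0,
    "CG-CD-OE1": 123.0, "CG-CD-OE2": 115.0, "CD-OE2-HE2": 110.0,
}

# improper torsions about the N-CA axis fixing the L configuration
# (dihedral(C, N, CA, X) for substituent X on CA)
IMPROPER_CB = 122.5
IMPROPER_HA = -119.5

CHI1_DEFAULT = 180.0
CHI2_DEFAULT = 180.0
CHI3_DEFAULT = 0.0


def _glu_atom_count(protonated: bool) -> int:
    return 16 if protonated else 15


def expected_atom_count(n_residues: int, protonation: str, termini: str = "neutral") -> int:
    """Closed-form atom count for a built polyglutamate chain."""
    per = _glu_atom_count(protonation == "protonated")
    # neutral termini: extra N-terminal H, plus OXT + HXT at the C terminus
    return per * n_residues + 3


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_polypeptide(
    n_residues: int,
    spec: "ConformerSpec | str",
    protonation: str = "deprotonated",
    termini: str = "neutral",
    phi_list: Sequence[float] | None = None,
    psi_list: Sequence[float] | None = None,
    chi1: float = CHI1_DEFAULT,
    chi2: float = CHI2_DEFAULT,
    chain_index: int = 0,
) -> Geometry:
    """Build an L-polyglutamate chain with the requested backbone torsions.

    Parameters
    ----------
    n_residues : number of glutamate residues (>= 2).
    spec : a ConformerSpec or the name of a canonical conformer.
    protonation : "protonated" (Glu side-chain COOH) or "deprotonated" (COO-).
    termini : only "neutral" (NH2 / COOH caps) is currently built.
    phi_list, psi_list : optional per-residue torsion overrides (degrees).

    The first residue has no phi and the last no psi; requested values for
    interior residues are reproduced within 1 degree on re-measurement.
    """
    if n_residues < 2:
        raise GeometryError("a peptide needs at least 2 residues")
    if protonation not in ("protonated", "deprotonated"):
        raise GeometryError(f"unknown protonation state {protonation!r}")
    if termini != "neutral":
        raise GeometryError(f"unsupported termini chemistry {termini!r}")
    cs = get_conformer(spec)
    phis = np.full(n_residues, cs.phi) if phi_list is None else np.asarray(phi_list, float)
    psis = np.full(n_residues, cs.psi) if psi_list is None else np.asarray(psi_list, float)
    if phis.size != n_residues or psis.size != n_residues:
        raise GeometryError("phi/psi override lists must have one entry per residue")
    for v in np.concatenate([phis, psis]):
        if not (-180.0 < v <= 180.0):
            raise GeometryError(f"torsion {v} outside (-180, 180]")

    protonated = protonation == "protonated"
    elements: list[str] = []
    names: list[str] = []
    res_idx: list[int] = []
    coords: list[np.ndarray] = []

    def add(name: str, element: str, xyz: np.ndarray, res: int) -> int:
        elements.append(element)
        names.append(name)
        res_idx.append(res)
        coords.append(np.asarray(xyz, float))
        return len(coords) - 1

    # backbone heavy atoms, chained through NeRF
    bb: list[dict[str, int]] = []
    for i in range(n_residues):
        if i == 0:
            n_pos = np.zeros(3)
            ca_pos = np.array([BB["N-CA"], 0.0, 0.0])
            th = math.radians(BB["N-CA-C"])
            c_pos = ca_pos + BB["CA-C"] * np.array([-math.cos(th), math.sin(th), 0.0])
        else:
            p = bb[i - 1]
            n_pos = place_atom(coords[p["N"]], coords[p["CA"]], coords[p["C"]],
                               BB["C-N"], BB["CA-C-N"], psis[i - 1])
            ca_pos = place_atom(coords[p["CA"]], coords[p["C"]], n_pos,
                                BB["N-CA"], BB["C-N-CA"], cs.omega)
            c_pos = place_atom(coords[p["C"]], n_pos, ca_pos,
                               BB["CA-C"], BB["N-CA-C"], phis[i])
        bb.append({
            "N": add("N", "N", n_pos, i),
            "CA": add("CA", "C", ca_pos, i),
            "C": add("C", "C", c_pos, i),
        })

    # decoration: O, H, HA, side chain, termini
    for i in range(n_residues):
        N, CA, C = (coords[bb[i][k]] for k in ("N", "CA", "C"))
        last = i == n_residues - 1
        # carbonyl O anti to the next N (dihedral N-CA-C-O = psi + 180)
        o_t = psis[i] + 180.0
        o_pos = place_atom(N, CA, C, BB["C-O"], BB["CA-C-O"], o_t)
        o_idx = add("O", "O", o_pos, i)
        if last:
            oxt = place_atom(N, CA, C, BB["C-OXT"], BB["CA-C-O"], psis[i])
            oxt_idx = add("OXT", "O", oxt, i)
            hxt = place_atom(CA, C, coords[oxt_idx], BB["O-H"], 108.0, 180.0)
            add("HXT", "H", hxt, i)
        if i == 0:
            # neutral NH2 terminus: two hydrogens on N
            for name, t in (("H1", 60.0), ("H2", -60.0)):
                h = place_atom(C, CA, N, BB["N-H"], 109.5, t)
                add(name, "H", h, 0)
        else:
            # amide H trans to the carbonyl O across the peptide bond
            po = coords[_find(names, res_idx, i - 1, "O")]
            pc = coords[bb[i - 1]["C"]]
            h = place_atom(po, pc, N, BB["N-H"], BB["C-N-H"], 180.0)
            add("H", "H", h, i)
        ha = place_atom(C, N, CA, BB["CA-HA"], 109.0, IMPROPER_HA)
        add("HA", "H", ha, i)
        cb = place_atom(C, N, CA, SC["CA-CB"], SC["N-CA-CB"], IMPROPER_CB)
        cb_idx = add("CB", "C", cb, i)
        cg = place_atom(N, CA, cb, SC["CB-CG"], SC["CA-CB-CG"], chi1)
        cg_idx = add("CG", "C", cg, i)
        for name, t in (("HB2", chi1 + 120.0), ("HB3", chi1 - 120.0)):
            add(name, "H", place_atom(N, CA, cb, SC["C-H"], 109.0, _wrap(t)), i)
        cd = place_atom(CA, cb, cg, SC["CG-CD"], SC["CB-CG-CD"], chi2)
        cd_idx = add("CD", "C", cd, i)
        for name, t in (("HG2", chi2 + 120.0), ("HG3", chi2 - 120.0)):
            add(name, "H", place_atom(CA, cb, cg, SC["C-H"], 109.0, _wrap(t)), i)
        r_oe1 = SC["CD-OE1"] if protonated else SC["CD-OEd"]
        r_oe2 = SC["CD-OE2p"] if protonated else SC["CD-OEd"]
        oe1 = place_atom(cb, cg, cd, r_oe1, SC["CG-CD-OE1"], CHI3_DEFAULT)
        add("OE1", "O", oe1, i)
        oe2 = place_atom(cb, cg, cd, r_oe2, SC["CG-CD-OE2"], _wrap(CHI3_DEFAULT + 180.0))
        oe2_idx = add("OE2", "O", oe2, i)
        if protonated:
            he2 = place_atom(cg, cd, coords[oe2_idx], SC["OE2-HE2"], SC["CD-OE2-HE2"], 180.0)
            add("HE2", "H", he2, i)

    n_atoms = len(coords)
    geom = Geometry(
        elements=elements,
        masses=np.array([ATOMIC_MASSES[e] for e in elements]),
        coords=np.array(coords),
        residue_index=np.array(res_idx),
        chain_index=np.full(n_atoms, chain_index),
        atom_names=names,
        protonation_state=protonation,
    )
    assert geom.n_atoms == expected_atom_count(n_residues, protonation, termini)
    return geom


def _wrap(angle: float) -> float:
    a = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def _find(names: list[str], res_idx: list[int], res: int, name: str) -> int:
    for j in range(len(names) - 1, -1, -1):
        if res_idx[j] == res and names[j] == name:
            return j
    raise GeometryError(f"atom {name} of residue {res} not found")


# ---------------------------------------------------------------------------
# torsion measurement
# ---------------------------------------------------------------------------

def measure_torsions(geometry: Geometry, chain: int | None = None) -> np.ndarray:
    """Per-residue backbone (phi, psi) in degrees for one chain.

    Returns an (n_residues, 2) array; phi of the first and psi of the last
    residue are NaN, as is any torsion with collinear defining atoms.
    """
    if chain is None:
        chains = np.unique(geometry.chain_index)
        if chains.size != 1:
            raise GeometryError("multi-chain geometry: pass an explicit chain index")
        chain = int(chains[0])
    residues = geometry.chain_residues(chain)
    if residues.size < 2:
        raise GeometryError("torsion measurement needs at least 2 residues")

    def atom(res: int, name: str) -> np.ndarray:
        k = geometry.find_atom(chain, res, name)
        if k < 0:
            raise GeometryError(f"residue {res} is missing backbone atom {name}")
        return geometry.coords[k]

    out = np.full((residues.size, 2), np.nan)
    for j, r in enumerate(residues):
        n, ca, c = atom(r, "N"), atom(r, "CA"), atom(r, "C")
        if j > 0:
            out[j, 0] = dihedral_angle(atom(residues[j - 1], "C"), n, ca, c)
        if j < residues.size - 1:
            out[j, 1] = dihedral_angle(n, ca, c, atom(residues[j + 1], "N"))
    return out


# ---------------------------------------------------------------------------
# fibril assembly
# ---------------------------------------------------------------------------

def _aligned_flattened_strand(strand: Geometry) -> np.ndarray:
    """Strand coordinates with the CA trace along +x and the natural strand
    twist removed (per-residue counter-rotation about the strand axis), so
    side chains point consistently along +-z.  A standard idealization for
    cross-beta starting models."""
    residues = strand.chain_residues(0)
    n = residues.size
    ca = np.array([strand.coords[strand.find_atom(0, r, "CA")] for r in residues])
    center = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - center)
    axis = vt[0]
    if axis @ (ca[-1] - ca[0]) < 0:
        axis = -axis
    rot = _rotation_onto(axis, np.array([1.0, 0.0, 0.0]))
    base = (strand.coords - center) @ rot.T
    if n < 4:
        return base
    cb = np.array([strand.coords[strand.find_atom(0, r, "CB")] for r in residues])
    v = (cb - center) @ rot.T - (ca - center) @ rot.T
    # twist rate from the even-residue CB azimuth drift
    az_even = np.degrees(np.arctan2(v[::2, 2], v[::2, 1]))
    slope = np.polyfit(np.arange(0, n, 2), np.unwrap(az_even, period=360.0), 1)[0]
    out = base.copy()
    mid = (n - 1) / 2.0
    for j, r in enumerate(residues):
        ang = math.radians(-slope * (j - mid))
        c, s = math.cos(ang), math.sin(ang)
        R = np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])
        sel = strand.residue_index == r
        out[sel] = base[sel] @ R.T
    # roll so even-residue side chains point along +z
    idx_ca = [strand.find_atom(0, r, "CA") for r in residues]
    idx_cb = [strand.find_atom(0, r, "CB") for r in residues]
    v2 = out[idx_cb] - out[idx_ca]
    az = np.degrees(np.arctan2(v2[::2, 2], v2[::2, 1])).mean()
    ang = math.radians(90.0 - az)
    c, s = math.cos(ang), math.sin(ang)
    return out @ np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]]).T


def build_fibril(
    n_sheets: int = 3,
    strands_per_sheet: int = 4,
    residues_per_strand: int = 30,
    sheet_spec: "ConformerSpec | str" = "beta_antiparallel",
    strand_spacing: float = 4.8,
    sheet_spacing: float = 10.0,
    protonation: str = "protonated",
    clash_cutoff: float = 1.5,
    roll_deg: float = -30.0,
    antiparallel_offset: tuple[float, float] | None = None,
) -> Geometry:
    """Stack beta strands into an n_sheets x strands_per_sheet cross-beta model.

    Strands run along x, repeat along y within a sheet (antiparallel sheets
    alternate strand direction via a 180 degree rotation about z plus a small
    registry offset along x/z) and sheets stack along z.  The packing
    parameters are starting-geometry conventions chosen to give clash-free
    assemblies; no claim is made about the true side-chain registry.
    """
    if n_sheets < 1 or strands_per_sheet < 1:
        raise GeometryError("n_sheets and strands_per_sheet must be >= 1")
    if antiparallel_offset is None:
        # registry shift of roughly a quarter repeat; the pleat pattern of a
        # flipped strand lines up differently for even and odd lengths
        x_reg = 0.9 if residues_per_strand % 2 == 0 else 0.9 - 3.3
        antiparallel_offset = (x_reg, -0.6)
    cs = get_conformer(sheet_spec)
    strand = build_polypeptide(residues_per_strand, cs, protonation=protonation)
    if n_sheets * strands_per_sheet == 1:
        return strand

    base = _aligned_flattened_strand(strand)
    rr = math.radians(roll_deg)
    c, s = math.cos(rr), math.sin(rr)
    base = base @ np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]]).T

    antiparallel = cs.name == "beta_antiparallel"
    flip = np.diag([-1.0, -1.0, 1.0])  # 180 degrees about z

    pieces: list[Geometry] = []
    chain = 0
    for sh in range(n_sheets):
        for k in range(strands_per_sheet):
            g = strand.copy()
            xyz = base.copy()
            shift = np.array([0.0, k * strand_spacing, sh * sheet_spacing])
            if antiparallel and k % 2 == 1:
                xyz = xyz @ flip.T
                shift += np.array([antiparallel_offset[0], 0.0, antiparallel_offset[1]])
            g.coords = xyz + shift
            g.chain_index = np.full(g.n_atoms, chain)
            pieces.append(g)
            chain += 1

    fibril = concatenate(pieces)
    _check_clashes(fibril, clash_cutoff)
    return fibril


def _rotation_onto(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # pick any axis perpendicular to a
        p = np.array([1.0, 0.0, 0.0])
        if abs(a @ p) > 0.9:
            p = np.array([0.0, 1.0, 0.0])
        v = np.cross(a, p)
        v /= np.linalg.norm(v)
        return 2.0 * np.outer(v, v) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def concatenate(geometries: Sequence[Geometry]) -> Geometry:
    """Join geometries; chain indices are kept as provided."""
    return Geometry(
        elements=[e for g in geometries for e in g.elements],
        masses=np.concatenate([g.masses for g in geometries]),
        coords=np.concatenate([g.coords for g in geometries]),
        residue_index=np.concatenate([g.residue_index for g in geometries]),
        chain_index=np.concatenate([g.chain_index for g in geometries]),
        atom_names=[n for g in geometries for n in g.atom_names],
        protonation_state=geometries[0].protonation_state,
        isotope_labels=[l for g in geometries for l in g.isotope_labels],
    )


def _check_clashes(geometry: Geometry, cutoff: float) -> None:
    from scipy.spatial import cKDTree

    chains = np.unique(geometry.chain_index)
    trees = {c: cKDTree(geometry.coords[geometry.chain_index == c]) for c in chains}
    for i, a in enumerate(chains):
        for b in chains[i + 1:]:
            d = trees[a].query_ball_tree(trees[b], cutoff)
            hit = next((j for j, lst in enumerate(d) if lst), None)
            if hit is not None:
                raise GeometryError(
                    f"steric clash (< {cutoff} A) between chains {a} and {b}"
                )


# ---------------------------------------------------------------------------
# mirror and isotope operations
# ---------------------------------------------------------------------------

def mirror(geometry: Geometry) -> Geometry:
    """Reflect through the x = 0 plane, turning L into D structures."""
    g = geometry.copy()
    g.coords[:, 0] *= -1.0
    return g


EXCHANGEABLE_NAMES = {"H", "H1", "H2", "H3", "HE2", "HXT"}


def deuterate(geometry: Geometry, mode: str = "exchangeable") -> Geometry:
    """Relabel hydrogens as deuterium (mass 2.014), coordinates unchanged.

    mode="exchangeable" swaps only N-H and O-H hydrogens (amide H, terminal
    NH2, carboxyl HE2/HXT), emulating dissolution in D2O; mode="all_H" swaps
    every hydrogen.
    """
    if mode not in ("exchangeable", "all_H"):
        raise GeometryError(f"unknown deuteration mode {mode!r}")
    g = geometry.copy()
    swapped = 0
    for i, el in enumerate(g.elements):
        if el != "H":
            continue
        if mode == "all_H" or g.atom_names[i] in EXCHANGEABLE_NAMES:
            g.masses[i] = ATOMIC_MASSES["D"]
            g.isotope_labels[i] = "D"
            swapped += 1
    if swapped == 0:
        warnings.warn("deuterate: no hydrogens exchanged")
    return g


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------

def guess_bonds(geometry: Geometry, scale: float = 1.25) -> list[tuple[int, int]]:
    """Covalent bonds from interatomic distances vs scaled covalent radii."""
    from scipy.spatial import cKDTree

    radii = np.array([COVALENT_RADII[e] for e in geometry.elements])
    tree = cKDTree(geometry.coords)
    pairs = tree.query_pairs(scale * 2.0 * radii.max(), output_type="ndarray")
    bonds = []
    for i, j in pairs:
        cut = scale * (radii[i] + radii[j])
        if np.linalg.norm(geometry.coords[i] - geometry.coords[j]) <= cut:
            if geometry.elements[i] == "H" and geometry.elements[j] == "H":
                continue
            bonds.append((int(i), int(j)))
    return sorted(bonds)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def to_pdb(geometry: Geometry, path: str) -> None:
    """Write a PDB file; chain IDs encode chain_index (A, B, ...)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = geometry.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = geometry.coords.astype(np.float32)
    arr.chain_id = np.array([chr(ord("A") + int(c) % 26) for c in geometry.chain_index])
    arr.res_id = geometry.residue_index + 1
    arr.res_name = np.full(n, "GLU")
    arr.atom_name = np.array(geometry.atom_names)
    arr.element = np.array(geometry.elements)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(path)


def from_pdb(path: str, protonation: str = "deprotonated") -> Geometry:
    """Read a PDB file back into a Geometry (element column sets the masses)."""
    from biotite.structure.io.pdb import PDBFile

    arr = PDBFile.read(path).get_structure(model=1)
    chain_map = {c: i for i, c in enumerate(dict.fromkeys(arr.chain_id))}
    elements = [e.capitalize() for e in arr.element]
    return Geometry(
        elements=elements,
        masses=np.array([ATOMIC_MASSES[e] for e in elements]),
        coords=np.asarray(arr.coord, dtype=float),
        residue_index=np.asarray(arr.res_id, dtype=int) - 1,
        chain_index=np.array([chain_map[c] for c in arr.chain_id]),
        atom_names=list(arr.atom_name),
        protonation_state=protonation,
    )


def to_xyz(geometry: Geometry, path: str, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{geometry.n_atoms}\n{comment}\n")
        for el, xyz in zip(geometry.elements, geometry.coords):
            fh.write(f"{el:<2s} {xyz[0]:18.12f} {xyz[1]:18.12f} {xyz[2]:18.12f}\n")


def from_xyz(path: str) -> Geometry:
    """Read a bare XYZ file; residue/chain bookkeeping defaults to a single unit."""
    with open(path) as fh:
        n = int(fh.readline())
        fh.readline()
        elements, coords = [], []
        for _ in range(n):
            parts = fh.readline().split()
            elements.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
    return Geometry(
        elements=elements,
        masses=np.array([ATOMIC_MASSES[e] for e in elements]),
        coords=np.array(coords),
        residue_index=np.zeros(n, dtype=int),
        chain_index=np.zeros(n, dtype=int),
        atom_names=list(elements),
    )


def write_torsion_restraints(geometry: Geometry, path: str) -> None:
    """Emit flat-bottom backbone torsion restraints (plain text) for external MD.

    One line per defined phi/psi: chain, residue, torsion name, the four atom
    indices (1-based), target angle, flat width (+-5 deg) and force constant
    (128 kcal/mol on both walls).
    """
    lines = ["# chain residue torsion a1 a2 a3 a4 target_deg r1_r4_halfwidth_deg rk2_rk3_kcal_mol"]
    for c in np.unique(geometry.chain_index):
        residues = geometry.chain_residues(int(c))
        tors = measure_torsions(geometry, chain=int(c))
        for j, r in enumerate(residues):
            quads = {}
            if j > 0:
                quads["phi"] = (
                    geometry.find_atom(c, residues[j - 1], "C"),
                    geometry.find_atom(c, r, "N"),
                    geometry.find_atom(c, r, "CA"),
                    geometry.find_atom(c, r, "C"),
                    tors[j, 0],
                )
            if j < residues.size - 1:
                quads["psi"] = (
                    geometry.find_atom(c, r, "N"),
                    geometry.find_atom(c, r, "CA"),
                    geometry.find_atom(c, r, "C"),
                    geometry.find_atom(c, residues[j + 1], "N"),
                    tors[j, 1],
                )
            for name, (a1, a2, a3, a4, target) in quads.items():
                lines.append(
                    f"{c} {r} {name} {a1 + 1} {a2 + 1} {a3 + 1} {a4 + 1} "
                    f"{target:.2f} {RESTRAINT_FLAT_WIDTH:.1f} {RESTRAINT_FORCE_CONSTANT:.1f}"
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
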