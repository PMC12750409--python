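"""Cutting a parent structure into overlapping capped fragments.

Fragments are verbatim sub-geometries (mapped atoms keep their parent
coordinates exactly) covering whole residues, so side chains are never
severed.  Backbone cuts (N-CA side of a window start, C-N side of a window
end) are completed either with hydrogen caps placed along the severed bond
direction or with chemically realistic acetyl / N-methylamide caps.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from .structures import Geometry, GeometryError, guess_bonds, place_atom, concatenate
from .constants import ATOMIC_MASSES

# cap X-H bond lengths by the element keeping the hydrogen
_CAP_XH = {"C": 1.09, "N": 1.01, "O": 0.97}


@dataclasses.dataclass
class FragmentMap:
    """A capped fragment and its correspondence to the parent.

    parent_atoms[i] is the parent index of fragment atom i, or -1 for cap
    atoms; cap_atoms lists the fragment-local cap indices.  anchor_residues
    holds the covered (chain, residue) pairs.
    """

    parent_atoms: np.ndarray
    cap_atoms: np.ndarray
    fragment_geometry: Geometry
    anchor_residues: list[tuple[int, int]]

    @property
    def mapped(self) -> np.ndarray:
        """Fragment-local indices of atoms with a parent counterpart."""
        return np.flatnonzero(self.parent_atoms >= 0)

    def validate(self, parent: Geometry) -> None:
        for i in self.mapped:
            p = self.parent_atoms[i]
            if self.fragment_geometry.elements[i] != parent.elements[p]:
                raise GeometryError(f"element mismatch at fragment atom {i}")
            if not np.allclose(self.fragment_geometry.coords[i], parent.coords[p]):
                raise GeometryError(f"coordinate mismatch at fragment atom {i}")


def fragment_count(n_residues: int, span: int, stride: int) -> int:
    """Closed-form number of overlapping windows per chain."""
    if span >= n_residues:
        return 1
    return int(np.ceil((n_residues - span) / stride)) + 1


def _window_starts(n_residues: int, span: int, stride: int) -> list[int]:
    starts = list(range(0, n_residues - span + 1, stride))
    if starts[-1] != n_residues - span:
        starts.append(n_residues - span)
    return starts


def make_fragments(
    parent: Geometry,
    span: int,
    stride: int = 1,
    cap_chemistry: str = "hydrogen",
    parent_bonds: Sequence[tuple[int, int]] | None = None,
) -> list[FragmentMap]:
    """Overlapping residue windows of the given span along every chain.

    Consecutive windows overlap by span - stride residues; the window count
    per chain is ceil((n_residues - span)/stride) + 1.  A span exceeding the
    chain length yields one whole-chain fragment (with a warning).
    """
    if stride < 1:
        raise GeometryError("stride must be >= 1")
    if stride > span:
        raise GeometryError("stride must not exceed span (windows would leave gaps)")
    if parent_bonds is None:
        parent_bonds = guess_bonds(parent)
    fragments: list[FragmentMap] = []
    for chain in np.unique(parent.chain_index):
        residues = parent.chain_residues(int(chain))
        n = residues.size
        eff_span = span
        if span > n:
            warnings.warn(f"span {span} exceeds chain length {n}; using the whole chain")
            eff_span = n
        for start in _window_starts(n, eff_span, stride):
            segs = [(int(chain), [int(r) for r in residues[start:start + eff_span]])]
            fragments.append(
                _extract(parent, segs, cap_chemistry, parent_bonds)
            )
    _check_coverage(parent, fragments)
    return fragments


def make_cross_fragments(
    parent: Geometry,
    amide_span: int = 4,
    pair_rule: float = 5.0,
    window: int = 2,
    cap_chemistry: str = "hydrogen",
    parent_bonds: Sequence[tuple[int, int]] | None = None,
) -> list[FragmentMap]:
    """Fibril fragmentation: intra-strand windows plus cross-strand pairs.

    Single-chain fragments cover amide_span + 1 consecutive residues (i.e.
    amide_span internal amide bonds).  Cross fragments combine a
    `window`-residue segment from each of two chains whose minimum
    heavy-atom distance is <= pair_rule (Angstrom).
    """
    from scipy.spatial import cKDTree

    chains = np.unique(parent.chain_index)
    if chains.size < 2:
        raise GeometryError("cross-fragment request requires at least 2 chains")
    if parent_bonds is None:
        parent_bonds = guess_bonds(parent)

    fragments = make_fragments(parent, amide_span + 1, 1, cap_chemistry, parent_bonds)

    heavy = np.array([e != "H" for e in parent.elements])
    n_cross = 0
    for ia, a in enumerate(chains):
        sel_a = (parent.chain_index == a) & heavy
        tree_a = cKDTree(parent.coords[sel_a])
        res_a = parent.residue_index[sel_a]
        for b in chains[ia + 1:]:
            sel_b = (parent.chain_index == b) & heavy
            res_b = parent.residue_index[sel_b]
            pairs = tree_a.query_ball_tree(cKDTree(parent.coords[sel_b]), pair_rule)
            seen: set[tuple[int, int]] = set()
            for i, lst in enumerate(pairs):
                for j in lst:
                    wa = int(res_a[i]) // window * window
                    wb = int(res_b[j]) // window * window
                    if (wa, wb) in seen:
                        continue
                    seen.add((wa, wb))
                    ra = parent.chain_residues(int(a))
                    rb = parent.chain_residues(int(b))
                    seg_a = [int(r) for r in ra[(ra >= wa) & (ra < wa + window)]]
                    seg_b = [int(r) for r in rb[(rb >= wb) & (rb < wb + window)]]
                    if not seg_a or not seg_b:
                        continue
                    fragments.append(
                        _extract(parent, [(int(a), seg_a), (int(b), seg_b)],
                                 cap_chemistry, parent_bonds)
                    )
                    n_cross += 1
    if n_cross == 0:
        warnings.warn(f"no inter-chain contacts within {pair_rule} A; "
                      "cross-fragment list is empty")
    return fragments


# ---------------------------------------------------------------------------
# extraction and capping
# ---------------------------------------------------------------------------

def _extract(parent: Geometry, segments: list[tuple[int, list[int]]],
             cap_chemistry: str, parent_bonds: Sequence[tuple[int, int]]) -> FragmentMap:
    keep = np.zeros(parent.n_atoms, dtype=bool)
    anchors: list[tuple[int, int]] = []
    for chain, residues in segments:
        anchors.extend((chain, r) for r in residues)
        for r in residues:
            keep |= (parent.chain_index == chain) & (parent.residue_index == r)
    idx = np.flatnonzero(keep)
    frag_geom = parent.subset(idx)
    fm = FragmentMap(
        parent_atoms=idx.copy(),
        cap_atoms=np.array([], dtype=int),
        fragment_geometry=frag_geom,
        anchor_residues=anchors,
    )
    return cap_fragment(fm, parent, cap_chemistry, parent_bonds)


def cap_fragment(
    fragment: FragmentMap,
    parent: Geometry,
    chemistry: str = "hydrogen",
    parent_bonds: Sequence[tuple[int, int]] | None = None,
) -> FragmentMap:
    """Complete dangling valences created by severed parent bonds.

    chemistry="hydrogen" places one H per severed bond along the bond
    direction; chemistry="methyl_amide" builds an acetyl group on a severed
    N-side (3 heavy atoms) and an N-methylamide on a severed C-side (2 heavy
    atoms), reusing the parent neighbour positions.
    """
    if chemistry not in ("hydrogen", "methyl_amide"):
        raise GeometryError(f"unknown cap chemistry {chemistry!r}")
    if parent_bonds is None:
        parent_bonds = guess_bonds(parent)
    in_frag = {int(p): i for i, p in enumerate(fragment.parent_atoms) if p >= 0}
    severed: list[tuple[int, int]] = []  # (kept parent atom, lost parent atom)
    for i, j in parent_bonds:
        if i in in_frag and j not in in_frag:
            severed.append((i, j))
        elif j in in_frag and i not in in_frag:
            severed.append((j, i))

    g = fragment.fragment_geometry
    elements = list(g.elements)
    names = list(g.atom_names)
    coords = list(g.coords)
    res_idx = list(g.residue_index)
    ch_idx = list(g.chain_index)
    iso = list(g.isotope_labels)
    pmap = list(fragment.parent_atoms)
    caps: list[int] = []

    def add_cap(name: str, element: str, xyz: np.ndarray, like: int) -> int:
        elements.append(element)
        names.append(name)
        coords.append(np.asarray(xyz, float))
        res_idx.append(res_idx[like])
        ch_idx.append(ch_idx[like])
        iso.append("H" if element == "H" else "")
        pmap.append(-1)
        caps.append(len(elements) - 1)
        return len(elements) - 1

    for kept, lost in severed:
        k = in_frag[kept]
        el = parent.elements[kept]
        if el not in _CAP_XH:
            raise GeometryError(
                f"cannot cap severed bond at parent atom {kept} (element {el})"
            )
        direction = parent.coords[lost] - parent.coords[kept]
        direction /= np.linalg.norm(direction)
        if chemistry == "hydrogen":
            add_cap("HCP", "H", parent.coords[kept] + _CAP_XH[el] * direction, k)
            continue
        # methyl_amide: rebuild the lost backbone neighbour as a cap group
        lc, lr = parent.chain_index[lost], parent.residue_index[lost]
        lost_name = parent.atom_names[lost]
        if lost_name == "C":  # severed N-CA(prev C) bond -> acetyl
            c_pos = parent.coords[lost]
            o = parent.find_atom(lc, lr, "O")
            ca = parent.find_atom(lc, lr, "CA")
            ci = add_cap("CCP", "C", c_pos, k)
            oi = add_cap("OCP", "O", parent.coords[o] if o >= 0 else
                         place_atom(coords[k], c_pos, c_pos + direction, 1.23, 120.0, 0.0), k)
            cm = add_cap("CMC", "C", parent.coords[ca] if ca >= 0 else
                         c_pos + 1.51 * direction, k)
            _add_methyl_h(add_cap, coords, oi, ci, cm)
        elif lost_name == "N":  # severed C-N(next) bond -> N-methylamide
            n_pos = parent.coords[lost]
            h = parent.find_atom(lc, lr, "H")
            ca = parent.find_atom(lc, lr, "CA")
            ni = add_cap("NCP", "N", n_pos, k)
            if h >= 0:
                add_cap("HNC", "H", parent.coords[h], k)
            cm = add_cap("CMN", "C", parent.coords[ca] if ca >= 0 else
                         n_pos + 1.46 * direction, k)
            _add_methyl_h(add_cap, coords, k, ni, cm)
        else:
            add_cap("HCP", "H", parent.coords[kept] + _CAP_XH[el] * direction, k)

    new_geom = Geometry(
        elements=elements,
        masses=np.array([g.masses[i] if i < g.n_atoms else ATOMIC_MASSES[elements[i]]
                         for i in range(len(elements))]),
        coords=np.array(coords),
        residue_index=np.array(res_idx),
        chain_index=np.array(ch_idx),
        atom_names=names,
        protonation_state=g.protonation_state,
        isotope_labels=iso,
    )
    return FragmentMap(
        parent_atoms=np.array(pmap),
        cap_atoms=np.array(caps, dtype=int),
        fragment_geometry=new_geom,
        anchor_residues=fragment.anchor_residues,
    )


def _add_methyl_h(add_cap, coords, a: int, b: int, c: int) -> None:
    for t in (60.0, 180.0, -60.0):
        h = place_atom(coords[a], coords[b], coords[c], 1.09, 109.5, t)
        add_cap("HMC", "H", h, c)


def _check_coverage(parent: Geometry, fragments: list[FragmentMap]) -> None:
    covered = np.zeros(parent.n_atoms, dtype=bool)
    for f in fragments:
        covered[f.parent_atoms[f.parent_atoms >= 0]] = True
    if not covered.all():
        missing = np.flatnonzero(~covered)
        raise GeometryError(f"{missing.size} parent atoms uncovered, e.g. {missing[:5]}")


# ---------------------------------------------------------------------------
# serialization: multi-record XYZ plus a sidecar mapping table
# ---------------------------------------------------------------------------

def write_fragments(fragments: list[FragmentMap], xyz_path: str, map_path: str) -> None:
    with open(xyz_path, "w") as fh:
        for fid, f in enumerate(fragments):
            g = f.fragment_geometry
            fh.write(f"{g.n_atoms}\nfragment {fid}\n")
            for el, xyz in zip(g.elements, g.coords):
                fh.write(f"{el:<2s} {xyz[0]:18.12f} {xyz[1]:18.12f} {xyz[2]:18.12f}\n")
    with open(map_path, "w") as fh:
        fh.write("# fragment_id fragment_atom parent_atom_or_CAP\n")
        for fid, f in enumerate(fragments):
            for i, p in enumerate(f.parent_atoms):
                tag = "CAP" if p < 0 else str(int(p) + 1)
                fh.write(f"{fid} {i + 1} {tag}\n")
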