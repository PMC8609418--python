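"""Three-criterion structural impact score for missense substitutions.

* Criterion A — change in occupied side-chain volume: 0 (|ΔV| ≤ 30 Å³),
  1 (30 < |ΔV| ≤ 120 Å³) or 2 (|ΔV| > 120 Å³).
* Criterion B — change of charge / polarity / water affinity: 0 identical,
  1 appearance or disappearance of charge or polarity, 2 opposite charge or
  an opposed polar/hydrophobic flip.
* Criterion C — steric compatibility with the surrounding structure: the
  target side chain is placed on the fixed backbone in every rotamer of a
  coarse backbone-independent library and heavy-atom van der Waals clashes
  (overlap ≥ 0.6 Å, Chimera-style, against non-adjacent residues) are
  counted; the minimum count m over rotamers maps to 0 (m = 0),
  1 (minimisable, m ≤ 3) or 2 (non-minimisable, m > 3).

The total A+B+C classifies the variant: red (≥ 4), yellow (2–3),
green (< 2).  Positions not resolved in the structure score ``not_visible``
(criteria A and B are still reported).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.info as struc_info
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "SubstitutionTables",
    "StructureModel",
    "ClashParams",
    "CriterionScores",
    "load_structure",
    "score_criterion_A",
    "score_criterion_B",
    "score_criterion_C",
    "score_variant_structure",
    "colour_for_total",
    "make_toy_structure",
    "HERG_UNRESOLVED_SPANS",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

#: hERG spans unresolved in the cryo-EM structure (protein numbering).
HERG_UNRESOLVED_SPANS = ((140, 341), (870, 1006))


@dataclass(frozen=True)
class SubstitutionTables:
    """Per-residue side-chain volume and physico-chemical classes."""

    volume_A3: dict[str, float]
    charge: dict[str, str]  # "+", "-", "0"
    polarity: dict[str, str]  # "polar" | "nonpolar"
    hydropathy: dict[str, str]  # "hydrophobic" | "neutral" | "hydrophilic"

    def __post_init__(self) -> None:
        for name in ("volume_A3", "charge", "polarity", "hydropathy"):
            missing = set(STANDARD_AA) - set(getattr(self, name))
            if missing:
                raise ValueError(f"{name}: missing residues {sorted(missing)}")

    @classmethod
    def packaged(cls) -> "SubstitutionTables":
        path = resources.files("hergkit") / "data" / "substitution_tables.csv"
        return cls.from_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SubstitutionTables":
        vol, chg, pol, hyd = {}, {}, {}, {}
        with open(str(path), newline="") as fh:
            rows = [r for r in csv.DictReader(
                (line for line in fh if not line.startswith("#"))
            )]
        for r in rows:
            aa = r["residue"].strip()
            vol[aa] = float(r["volume_A3"])
            chg[aa] = r["charge"].strip()
            pol[aa] = r["polarity"].strip()
            hyd[aa] = r["hydropathy"].strip()
        return cls(vol, chg, pol, hyd)


def _check_aa(aa: str) -> str:
    aa = aa.upper()
    if aa not in STANDARD_AA:
        raise ValueError(f"non-standard residue {aa!r}")
    return aa


def score_criterion_A(wild_aa: str, target_aa: str, tables: SubstitutionTables) -> int:
    """Occupied-space change, binned at 30 and 120 Å³."""
    w, t = _check_aa(wild_aa), _check_aa(target_aa)
    dv = abs(tables.volume_A3[t] - tables.volume_A3[w])
    if dv <= 30.0:
        return 0
    if dv <= 120.0:
        return 1
    return 2


def score_criterion_B(wild_aa: str, target_aa: str, tables: SubstitutionTables) -> int:
    """Charge / polarity / hydrophilicity change."""
    w, t = _check_aa(wild_aa), _check_aa(target_aa)
    cw, ct = tables.charge[w], tables.charge[t]
    pw, pt = tables.polarity[w], tables.polarity[t]
    hw, ht = tables.hydropathy[w], tables.hydropathy[t]
    if {cw, ct} == {"+", "-"}:
        return 2
    if pw != pt and {hw, ht} == {"hydrophilic", "hydrophobic"}:
        return 2
    if cw != ct or pw != pt:
        return 1
    return 0


def colour_for_total(total: int) -> str:
    """Colour classification of the summed score."""
    if not 0 <= total <= 6:
        raise ValueError("total must lie in [0, 6]")
    if total >= 4:
        return "red"
    if total >= 2:
        return "yellow"
    return "green"


@dataclass(frozen=True)
class CriterionScores:
    A: int
    B: int
    C: int | None  # None when the position is not resolved
    colour: str

    @property
    def total(self) -> int | None:
        return None if self.C is None else self.A + self.B + self.C


# --------------------------------------------------------------------------
# structure handling
# --------------------------------------------------------------------------


@dataclass
class StructureModel:
    """Heavy-atom protein structure with per-chain resolved-residue sets."""

    atoms: struc.AtomArray
    resolved: dict[str, set[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.atoms.coord)):
            raise ValueError("structure contains non-finite coordinates")
        if not self.resolved:
            self.resolved = {
                str(ch): set(
                    int(r) for r in np.unique(self.atoms.res_id[self.atoms.chain_id == ch])
                )
                for ch in np.unique(self.atoms.chain_id)
            }

    def is_resolved(self, chain: str, position: int) -> bool:
        return position in self.resolved.get(chain, set())

    def residue_mask(self, chain: str, position: int) -> np.ndarray:
        return (self.atoms.chain_id == chain) & (self.atoms.res_id == position)


def load_structure(path) -> StructureModel:
    """Read a PDB file (first model, amino-acid heavy atoms only)."""
    arr = PDBFile.read(str(path)).get_structure(model=1)
    arr = arr[struc.filter_amino_acids(arr) & (arr.element != "H")]
    if arr.array_length() == 0:
        raise ValueError(f"no amino-acid atoms in {path}")
    return StructureModel(atoms=arr)


@dataclass(frozen=True)
class ClashParams:
    """Chimera-style clash definition: overlap = r_i + r_j − d ≥ cutoff."""

    overlap_cutoff_A: float = 0.6
    exclude_adjacent: int = 1  # residues within +/- this of the target are ignored


# chi dihedral definitions (atom-name quadruples) per residue
_CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

_BACKBONE = {"N", "CA", "C", "O", "OXT"}
_CHI_SAMPLES = (-60.0, 60.0, 180.0)


def _template(res3: str) -> struc.AtomArray:
    tpl = struc_info.residue(res3)
    return tpl[(tpl.element != "H") & ~np.isin(tpl.atom_name, ["OXT"])]


def _distal_atoms(tpl: struc.AtomArray, a2: str, a3: str) -> np.ndarray:
    """Atoms on the a3 side of the a2–a3 bond (the set a chi rotation moves)."""
    bonds = tpl.bonds.as_array()[:, :2]
    names = list(tpl.atom_name)
    i2, i3 = names.index(a2), names.index(a3)
    adj: dict[int, set[int]] = {}
    for i, j in bonds:
        adj.setdefault(int(i), set()).add(int(j))
        adj.setdefault(int(j), set()).add(int(i))
    adj[i2].discard(i3)
    adj[i3].discard(i2)
    seen, stack = {i3}, [i3]
    while stack:
        k = stack.pop()
        for nb in adj.get(k, ()):
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    seen.discard(i3)
    return np.array(sorted(seen), dtype=int)


def _set_chi(coord: np.ndarray, tpl: struc.AtomArray, quad, target_deg: float) -> None:
    names = list(tpl.atom_name)
    idx = [names.index(a) for a in quad]
    p = coord[idx]
    current = math.degrees(struc.dihedral(*(p[k] for k in range(4))))
    axis = p[2] - p[1]
    axis = axis / np.linalg.norm(axis)
    angle = math.radians(target_deg - current)
    moving = _distal_atoms(tpl, quad[1], quad[2])
    rel = coord[moving] - p[2]
    c, s = math.cos(angle), math.sin(angle)
    # Rodrigues rotation about the chi bond axis
    coord[moving] = (
        p[2]
        + rel * c
        + np.cross(axis, rel) * s
        + np.outer(rel @ axis, axis) * (1 - c)
    )


def _place_rotamers(
    res3: str, backbone_coord: dict[str, np.ndarray]
) -> list[struc.AtomArray]:
    """All coarse-library rotamers of ``res3`` grafted onto a backbone.

    The CCD ideal-geometry residue is superimposed on the target N/CA/C
    backbone; each chi angle is then set to every combination of −60/60/180°.
    Residues without chi angles (Ala, Gly) and Pro (ring) return the single
    grafted conformation.
    """
    tpl = _template(res3)
    names = list(tpl.atom_name)
    fixed = struc.AtomArray(3)
    fixed.coord = np.stack([backbone_coord[a] for a in ("N", "CA", "C")])
    mobile = tpl[np.isin(tpl.atom_name, ["N", "CA", "C"])]
    order = [list(mobile.atom_name).index(a) for a in ("N", "CA", "C")]
    mobile = mobile[order]
    _, transform = struc.superimpose(fixed, mobile)
    base = transform.apply(tpl)

    chis = _CHI_ATOMS.get(res3, [])
    if not chis:
        return [base]
    rotamers = []
    combos = [[]]
    for _ in chis:
        combos = [c + [v] for c in combos for v in _CHI_SAMPLES]
    for combo in combos:
        conf = base.copy()
        coord = conf.coord
        for quad, ang in zip(chis, combo):
            _set_chi(coord, tpl, quad, ang)
        rotamers.append(conf)
    return rotamers


def _vdw(element: str) -> float:
    r = struc_info.vdw_radius_single(element)
    return r if r is not None else 1.7


def _count_clashes(
    side_chain: struc.AtomArray, env: struc.AtomArray, cutoff: float
) -> int:
    if env.array_length() == 0 or side_chain.array_length() == 0:
        return 0
    r_sc = np.array([_vdw(e) for e in side_chain.element])
    r_env = np.array([_vdw(e) for e in env.element])
    d = np.linalg.norm(
        side_chain.coord[:, None, :] - env.coord[None, :, :], axis=-1
    )
    overlap = r_sc[:, None] + r_env[None, :] - d
    return int(np.count_nonzero(overlap >= cutoff))


def score_criterion_C(
    structure: StructureModel,
    chain: str,
    position: int,
    target_aa: str,
    clash_params: ClashParams = ClashParams(),
) -> int | None:
    """Minimum rotamer clash count, binned; ``None`` if position unresolved."""
    t = _check_aa(target_aa)
    if not structure.is_resolved(chain, position):
        return None
    res_mask = structure.residue_mask(chain, position)
    res = structure.atoms[res_mask]
    backbone = {}
    for a in ("N", "CA", "C"):
        sel = res.atom_name == a
        if not np.any(sel):
            raise ValueError(f"{chain}/{position}: backbone atom {a} missing")
        backbone[a] = res.coord[sel][0]

    atoms = structure.atoms
    env_mask = ~(
        (atoms.chain_id == chain)
        & (np.abs(atoms.res_id - position) <= clash_params.exclude_adjacent)
    )
    env = atoms[env_mask]
    m_best = None
    for rot in _place_rotamers(_1TO3[t], backbone):
        sc = rot[~np.isin(rot.atom_name, list(_BACKBONE))]
        m = _count_clashes(sc, env, clash_params.overlap_cutoff_A)
        if m_best is None or m < m_best:
            m_best = m
        if m_best == 0:
            break
    return _bin_clashes(m_best)


def _bin_clashes(m: int) -> int:
    if m == 0:
        return 0
    if m <= 3:
        return 1
    return 2


def score_variant_structure(
    wild_aa: str,
    position: int,
    target_aa: str,
    structure: StructureModel,
    tables: SubstitutionTables | None = None,
    chain: str = "A",
    clash_params: ClashParams = ClashParams(),
) -> CriterionScores:
    """Full A/B/C score of one substitution on a structure.

    When the position lies in an unresolved region the result carries
    ``C = None`` and colour ``not_visible`` while A and B are still reported.
    """
    tables = tables or SubstitutionTables.packaged()
    a = score_criterion_A(wild_aa, target_aa, tables)
    b = score_criterion_B(wild_aa, target_aa, tables)
    c = score_criterion_C(structure, chain, position, target_aa, clash_params)
    if c is None:
        return CriterionScores(A=a, B=b, C=None, colour="not_visible")
    return CriterionScores(A=a, B=b, C=c, colour=colour_for_total(a + b + c))


# --------------------------------------------------------------------------
# synthetic toy structure
# --------------------------------------------------------------------------


def make_toy_structure() -> StructureModel:
    """Synthetic dozen-residue toy structure for exercising criterion C.

    This is *not* a real protein: residues sit on a line 6 Å apart (so
    non-adjacent residues do not touch), with engineered steric environments:

    * residue 3 (Thr) has six blocking atoms caged 2.6 Å around its CB —
      every rotamer of any grafted side chain clashes heavily (criterion 2);
    * residue 6 (Thr) has exactly one blocking atom 2.6 Å from its CB — every
      rotamer counts that single clash but nothing else (criterion 1);
    * residue 1 (Gly) and residue 8 (Ala) have empty surroundings
      (criterion 0).
    """
    chains = []
    seq = ["GLY", "ALA", "THR", "ALA", "GLY", "THR", "ALA", "ALA"]
    arrays = []
    cb_pos = {}
    for i, res3 in enumerate(seq, start=1):
        tpl = _template(res3)
        shift = np.array([6.0 * (i - 1), 0.0, 0.0]) - tpl.coord[
            list(tpl.atom_name).index("CA")
        ]
        tpl = tpl.copy()
        tpl.coord = tpl.coord + shift
        tpl.res_id[:] = i
        tpl.chain_id[:] = "A"
        names = list(tpl.atom_name)
        if "CB" in names:
            cb_pos[i] = tpl.coord[names.index("CB")].copy()
        else:  # glycine: pseudo-CB direction off CA
            cb_pos[i] = tpl.coord[names.index("CA")] + np.array([0.0, 1.5, 0.0])
        arrays.append(tpl)

    def blocker(res_id: int, point: np.ndarray, direction: np.ndarray):
        """Pseudo-alanine whose CB sits at ``point`` with the rest of the
        residue retreating along ``direction`` (away from the target)."""
        u = direction / np.linalg.norm(direction)
        arr = struc.AtomArray(5)
        arr.coord = np.stack(
            [
                point + 2.99 * u,  # N
                point + 1.54 * u,  # CA
                point + 4.21 * u,  # C
                point + 5.44 * u,  # O
                point,             # CB
            ]
        )
        arr.atom_name = np.array(["N", "CA", "C", "O", "CB"])
        arr.element = np.array(["N", "C", "C", "O", "C"])
        arr.res_name = np.array(["ALA"] * 5)
        arr.res_id = np.array([res_id] * 5)
        arr.chain_id = np.array(["B"] * 5)
        arr.hetero = np.array([False] * 5)
        return arr

    # cage around residue 3's CB: six octahedral blockers at 2.6 A
    cage_dirs = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )
    rid = 101
    for d in cage_dirs:
        arrays.append(blocker(rid, cb_pos[3] + 2.6 * d, d))
        rid += 1
    # single blocker near residue 6's CB
    arrays.append(blocker(rid, cb_pos[6] + np.array([0.0, 2.6, 0.0]), np.array([0.0, 1.0, 0.0])))

    atoms = arrays[0]
    for arr in arrays[1:]:
        # align annotation categories before concatenation
        atoms = atoms + arr
    return StructureModel(atoms=atoms)


def write_structure_pdb(model: StructureModel, path) -> None:
    pdb = PDBFile()
    pdb.set_structure(model.atoms)
    pdb.write(str(path))
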