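"""Residue contact-environment analysis on PDB coordinates.

Neighborhood detection is side-chain-centric: a residue is a neighbor of
the center iff any of its side-chain heavy atoms lies within the cutoff
(default 5.5 A) of any side-chain heavy atom of the center.  Detected
pairs are then classified geometrically: hydrogen bond when an N/O donor
of one residue is within 3.5 A of an N/O acceptor of the other (backbone
included, no angle term), hydrophobic when two apolar carbons are within
4.5 A; a pair may carry both labels, otherwise it is proximal_only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import PDBParseError, ResidueLookupError, StructureError

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

HBOND_CUTOFF = 3.5
HYDROPHOBIC_CUTOFF = 4.5
NEIGHBOR_CUTOFF = 5.5

#: Side-chain apolar carbons per residue (carbons not bonded to N or O).
APOLAR_CARBONS = {
    "ALA": {"CB"},
    "ARG": {"CB", "CG"},
    "ASN": {"CB"},
    "ASP": {"CB"},
    "CYS": {"CB"},
    "GLN": {"CB", "CG"},
    "GLU": {"CB", "CG"},
    "GLY": set(),
    "HIS": {"CB"},
    "ILE": {"CB", "CG1", "CG2", "CD1"},
    "LEU": {"CB", "CG", "CD1", "CD2"},
    "LYS": {"CB", "CG", "CD"},
    "MET": {"CB", "CG", "CE"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "PRO": {"CB", "CG"},
    "SER": set(),
    "THR": {"CG2"},
    "TRP": {"CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2"},
    "VAL": {"CB", "CG1", "CG2"},
}

#: N/O hydrogen-bond donors (heavy atoms with implicit H) per residue,
#: beyond the backbone amide N.
SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
}

#: N/O hydrogen-bond acceptors per residue, beyond the backbone carbonyl.
SIDECHAIN_ACCEPTORS = {
    "ASN": {"OD1"},
    "ASP": {"OD1", "OD2"},
    "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
}


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    atom_name: str
    alt_loc: str
    residue_name: str
    chain_id: str
    residue_number: int
    xyz: tuple[float, float, float]
    occupancy: float = 1.0
    element: str = ""
    het: bool = False

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass(frozen=True)
class Partner:
    chain_id: str
    residue_number: int
    residue_name: str
    min_distance: float
    classes: tuple[str, ...] = ("proximal_only",)
    scope: str = "intra_chain"  # or "inter_chain"


@dataclass(frozen=True)
class ContactReport:
    center: tuple[str, int, str]  # (chain, residue_number, residue_name)
    cutoff: float
    partners: tuple[Partner, ...]

    def partner(self, chain_id: str, residue_number: int) -> Partner | None:
        for p in self.partners:
            if p.chain_id == chain_id and p.residue_number == residue_number:
                return p
        return None

    def to_dict(self) -> dict:
        return {
            "center": {"chain": self.center[0], "residue_number": self.center[1],
                       "residue_name": self.center[2]},
            "cutoff": self.cutoff,
            "partners": [
                {"chain": p.chain_id, "residue_number": p.residue_number,
                 "residue_name": p.residue_name,
                 "min_distance": round(p.min_distance, 3),
                 "classes": list(p.classes), "scope": p.scope}
                for p in self.partners
            ],
        }


def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    for ch in stripped:
        if ch.isalpha():
            # digits prefix hydrogens like 1HB2; first letter is the element
            return "H" if ch.upper() == "H" else ch.upper()
    return ""


def parse_coordinates(pdb_text: str) -> list[AtomRecord]:
    """Parse ATOM/HETATM records from fixed-column PDB text.

    Alternate locations are collapsed to the highest-occupancy copy (ties
    prefer alt_loc 'A').  Hydrogens are kept; distance rules skip them.
    """
    if not pdb_text or not pdb_text.strip():
        raise ValueError("empty PDB input")
    atoms: list[AtomRecord] = []
    for lineno, raw in enumerate(pdb_text.splitlines(), start=1):
        rec = raw[:6]
        if rec not in ("ATOM  ", "HETATM"):
            continue
        try:
            serial = int(raw[6:11])
            atom_name = raw[12:16].strip()
            alt_loc = raw[16].strip()
            residue_name = raw[17:20].strip()
            chain_id = raw[21].strip()
            residue_number = int(raw[22:26])
            x = float(raw[30:38])
            y = float(raw[38:46])
            z = float(raw[46:54])
            occ_field = raw[54:60].strip()
            occupancy = float(occ_field) if occ_field else 1.0
            element = raw[76:78].strip().upper() if len(raw) >= 77 else ""
        except (ValueError, IndexError) as exc:
            raise PDBParseError(
                f"malformed coordinate line {lineno}: {raw!r}", line_number=lineno
            ) from exc
        if not all(map(math.isfinite, (x, y, z))):
            raise PDBParseError(
                f"non-finite coordinates on line {lineno}", line_number=lineno
            )
        if not element:
            element = _infer_element(atom_name)
        atoms.append(AtomRecord(
            serial=serial, atom_name=atom_name, alt_loc=alt_loc,
            residue_name=residue_name, chain_id=chain_id,
            residue_number=residue_number, xyz=(x, y, z),
            occupancy=occupancy, element=element, het=(rec == "HETATM"),
        ))
    if not any(not a.het for a in atoms):
        raise ValueError("input contains no ATOM records")

    # collapse alternate locations
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for a in atoms:
        key = (a.chain_id, a.residue_number, a.residue_name, a.atom_name)
        if key not in best:
            best[key] = a
            order.append(key)
            continue
        cur = best[key]
        if a.occupancy > cur.occupancy or (
            a.occupancy == cur.occupancy and a.alt_loc == "A" != cur.alt_loc
        ):
            best[key] = a
    return [best[k] for k in order]


def write_pdb(atoms: list[AtomRecord]) -> str:
    """Serialize records as fixed-column PDB text (serials renumbered)."""
    lines = []
    for i, a in enumerate(atoms, start=1):
        name = a.atom_name
        # standard PDB alignment: element starts in column 14 for 1-2 char
        # organic atom names
        name_field = f" {name:<3s}" if len(name) < 4 else name
        x, y, z = a.xyz
        lines.append(
            f"{'HETATM' if a.het else 'ATOM':<6s}{i:>5d} {name_field}"
            f"{a.alt_loc or ' '}{a.residue_name:>3s} {a.chain_id or 'A'}"
            f"{a.residue_number:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Residue utilities
# ---------------------------------------------------------------------------


def residues(atoms: list[AtomRecord]) -> dict[tuple[str, int], list[AtomRecord]]:
    """Group atoms by (chain_id, residue_number), preserving input order."""
    out: dict[tuple[str, int], list[AtomRecord]] = {}
    for a in atoms:
        out.setdefault((a.chain_id, a.residue_number), []).append(a)
    return out


def side_chain_heavy(res_atoms: list[AtomRecord]) -> list[AtomRecord]:
    return [
        a for a in res_atoms
        if a.atom_name not in BACKBONE_ATOMS and not a.is_hydrogen
    ]


def _min_distance(group_a: list[AtomRecord], group_b: list[AtomRecord]) -> float:
    if not group_a or not group_b:
        return math.inf
    pa = np.array([a.xyz for a in group_a])
    pb = np.array([b.xyz for b in group_b])
    d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))


def neighbor_residues(
    atoms: list[AtomRecord],
    chain: str,
    residue_number: int,
    cutoff: float = NEIGHBOR_CUTOFF,
) -> ContactReport:
    """Residues whose side-chain heavy atoms come within cutoff of the
    center residue's side-chain heavy atoms (classes left proximal_only)."""
    by_res = residues(atoms)
    key = (chain, residue_number)
    if key not in by_res:
        raise ResidueLookupError(
            f"residue {residue_number} in chain {chain!r} not found"
        )
    center_atoms = side_chain_heavy(by_res[key])
    center_name = by_res[key][0].residue_name
    partners = []
    for other_key, other_atoms in by_res.items():
        if other_key == key:
            continue
        d = _min_distance(center_atoms, side_chain_heavy(other_atoms))
        if d <= cutoff:
            partners.append(Partner(
                chain_id=other_key[0],
                residue_number=other_key[1],
                residue_name=other_atoms[0].residue_name,
                min_distance=d,
                classes=("proximal_only",),
                scope="intra_chain" if other_key[0] == chain else "inter_chain",
            ))
    partners.sort(key=lambda p: (p.chain_id, p.residue_number))
    return ContactReport(
        center=(chain, residue_number, center_name),
        cutoff=cutoff,
        partners=tuple(partners),
    )


def _donors(res_atoms: list[AtomRecord]) -> list[AtomRecord]:
    out = []
    for a in res_atoms:
        if a.is_hydrogen:
            continue
        if a.atom_name == "N" and a.residue_name != "PRO":
            out.append(a)
        elif a.atom_name in SIDECHAIN_DONORS.get(a.residue_name, ()):
            out.append(a)
    return out


def _acceptors(res_atoms: list[AtomRecord]) -> list[AtomRecord]:
    out = []
    for a in res_atoms:
        if a.is_hydrogen:
            continue
        if a.atom_name in ("O", "OXT"):
            out.append(a)
        elif a.atom_name in SIDECHAIN_ACCEPTORS.get(a.residue_name, ()):
            out.append(a)
    return out


def _apolar_carbons(res_atoms: list[AtomRecord]) -> list[AtomRecord]:
    return [
        a for a in res_atoms
        if a.atom_name in APOLAR_CARBONS.get(a.residue_name, ())
    ]


def classify_contacts(report: ContactReport, atoms: list[AtomRecord]) -> ContactReport:
    """Fill hbond/hydrophobic labels on a proximity report.

    Hydrogen bonds and hydrophobic contacts may use backbone donors and
    acceptors; apolar carbons are side-chain by construction.
    """
    by_res = residues(atoms)
    center_atoms = by_res[(report.center[0], report.center[1])]
    c_don, c_acc = _donors(center_atoms), _acceptors(center_atoms)
    c_apo = _apolar_carbons(center_atoms)
    new_partners = []
    for p in report.partners:
        other = by_res[(p.chain_id, p.residue_number)]
        labels = []
        hb = min(
            _min_distance(c_don, _acceptors(other)),
            _min_distance(_donors(other), c_acc),
        )
        if hb <= HBOND_CUTOFF:
            labels.append("hbond")
        if _min_distance(c_apo, _apolar_carbons(other)) <= HYDROPHOBIC_CUTOFF:
            labels.append("hydrophobic")
        if not labels:
            labels = ["proximal_only"]
        new_partners.append(replace(p, classes=tuple(labels)))
    return replace(report, partners=tuple(new_partners))


def contact_environment(
    atoms: list[AtomRecord],
    chain: str,
    residue_number: int,
    cutoff: float = NEIGHBOR_CUTOFF,
) -> ContactReport:
    """neighbor_residues followed by classify_contacts."""
    return classify_contacts(
        neighbor_residues(atoms, chain, residue_number, cutoff), atoms
    )


def interface_contacts(
    atoms: list[AtomRecord],
    residue_number: int,
    cutoff: float = NEIGHBOR_CUTOFF,
) -> dict[str, ContactReport]:
    """Classified contacts of the given residue restricted to partners in
    other chains, reported once per chain copy of the residue."""
    chains = sorted({a.chain_id for a in atoms})
    if len(chains) < 2:
        raise ValueError(
            "interface analysis needs >= 2 chains; "
            "use neighbor_residues for a monomer"
        )
    out = {}
    for ch in chains:
        if (ch, residue_number) not in residues(atoms):
            continue
        rep = contact_environment(atoms, ch, residue_number, cutoff)
        inter = tuple(p for p in rep.partners if p.scope == "inter_chain")
        out[ch] = replace(rep, partners=inter)
    if not out:
        raise ResidueLookupError(
            f"residue {residue_number} not present in any chain"
        )
    return out


# ---------------------------------------------------------------------------
# Ala <-> Thr substitution by ideal internal coordinates
# ---------------------------------------------------------------------------

CB_OG1_BOND = 1.43
CB_CG2_BOND = 1.52
TETRAHEDRAL_ANGLE = 109.47
THR_CHI1 = -60.0  # gauche- rotamer for the built OG1


def _place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float):
    """NeRF placement of atom D given positions A-B-C, the C-D bond length,
    the B-C-D angle and the A-B-C-D dihedral."""
    a, b, c = (np.asarray(v, dtype=float) for v in (a, b, c))
    theta = math.radians(angle_deg)
    chi = math.radians(dihedral_deg)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(chi),
        bond * math.sin(theta) * math.sin(chi),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return tuple(np.round(c + frame @ d_local, 6))


def mutate_ala_thr(
    atoms: list[AtomRecord], chain: str, residue_number: int
) -> list[AtomRecord]:
    """Swap ALA -> THR (build OG1/CG2 at ideal geometry, chi1 = -60) or
    THR -> ALA (drop side-chain atoms beyond CB) at the given residue."""
    by_res = residues(atoms)
    key = (chain, residue_number)
    if key not in by_res:
        raise ResidueLookupError(
            f"residue {residue_number} in chain {chain!r} not found"
        )
    res_atoms = by_res[key]
    resname = res_atoms[0].residue_name
    if resname not in ("ALA", "THR"):
        raise ValueError(
            f"mutate_ala_thr requires ALA or THR at the center, got {resname}"
        )
    coords = {a.atom_name: a.xyz for a in res_atoms}
    missing = {"N", "CA", "C", "CB"} - set(coords)
    if missing:
        raise StructureError(
            f"residue {chain}/{residue_number} missing atoms {sorted(missing)}"
        )

    out: list[AtomRecord] = []
    if resname == "ALA":
        og1 = _place_atom(coords["N"], coords["CA"], coords["CB"],
                          CB_OG1_BOND, TETRAHEDRAL_ANGLE, THR_CHI1)
        cg2 = _place_atom(coords["N"], coords["CA"], coords["CB"],
                          CB_CG2_BOND, TETRAHEDRAL_ANGLE, THR_CHI1 + 120.0)
        max_serial = max(a.serial for a in atoms)
        for a in atoms:
            if (a.chain_id, a.residue_number) == key:
                a = replace(a, residue_name="THR")
            out.append(a)
            if (a.chain_id, a.residue_number) == key and a.atom_name == "CB":
                out.append(AtomRecord(max_serial + 1, "OG1", "", "THR", chain,
                                      residue_number, og1, 1.0, "O"))
                out.append(AtomRecord(max_serial + 2, "CG2", "", "THR", chain,
                                      residue_number, cg2, 1.0, "C"))
    else:  # THR -> ALA
        keep_names = BACKBONE_ATOMS | {"CB"}
        for a in atoms:
            if (a.chain_id, a.residue_number) == key:
                if a.atom_name not in keep_names:
                    continue
                a = replace(a, residue_name="ALA")
            out.append(a)
    return out
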