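"""Protein structure handling: PDB I/O, chain selection, ligand-binding-site
extraction by distance cutoff, Kabsch superposition, and joining trace
statuses onto structure residues.

Parsing and fixed-column PDB writing are delegated to ``gemmi``; this module
exposes light containers (chains -> residues -> atoms in Angstroms) so that
the geometric operations are independent of the parser.  Altlocs resolve to
the first conformer; only the first MODEL is used; waters never count as
protein.  The distance condition for a binding site is inclusive: a residue
belongs to the site iff the minimum atom-to-ligand-atom distance is <= the
cutoff (5 Angstroms by default, the classical contact definition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .alignio import needleman_wunsch, GAP
from .trace import ResidueStatusMap, Status

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
WATER_NAMES = {"HOH", "WAT", "DOD"}

#: B-factor codes used by :func:`write_annotated_pdb`
STATUS_BFACTOR = {
    Status.NEUTRAL: 0.0,
    Status.GROUP_SPECIFIC: 50.0,
    Status.CONSERVED: 99.99,
    None: 25.0,  # unmapped
}


class StructureError(ValueError):
    pass


@dataclass
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    bfactor: float = 0.0

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Residue:
    name: str
    seqnum: int
    icode: str = ""
    het: bool = False
    atoms: list[Atom] = field(default_factory=list)

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms])


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if not r.is_water and not r.het]

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.protein_residues)


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise StructureError(
            f"no chain {chain_id!r}; available: {[c.id for c in self.chains]}"
        )

    @property
    def chain_ids(self) -> list[str]:
        return [c.id for c in self.chains]

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)


# ---------------------------------------------------------------------------
# PDB I/O

def _prescan_coordinates(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(("ATOM  ", "HETATM")):
                for lo, hi, label in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                    fragment = line[lo:hi].strip()
                    try:
                        value = float(fragment)
                    except ValueError:
                        raise StructureError(
                            f"malformed {label}-coordinate {fragment!r} on line {lineno}"
                        ) from None
                    if not np.isfinite(value):
                        raise StructureError(
                            f"non-finite {label}-coordinate on line {lineno}"
                        )


def read_pdb(path) -> Structure:
    """Read a fixed-column PDB file into a :class:`Structure`.

    Keeps the first altloc conformer, warns on and ignores MODELs beyond
    the first, and raises :class:`StructureError` with a line number for a
    malformed coordinate field.
    """
    _prescan_coordinates(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.remove_alternative_conformations()
    if len(st) > 1:
        warnings.warn(
            f"{path}: {len(st)} models present, using the first", stacklevel=2
        )
    if len(st) == 0:
        raise StructureError(f"{path}: no coordinate model found")
    model = st[0]
    chains = []
    for ch in model:
        residues = []
        for res in ch:
            atoms = []
            seen = set()
            for atom in res:
                if atom.name in seen:  # first altloc only
                    continue
                seen.add(atom.name)
                atoms.append(
                    Atom(
                        name=atom.name,
                        element=atom.element.name,
                        x=atom.pos.x,
                        y=atom.pos.y,
                        z=atom.pos.z,
                        occupancy=atom.occ,
                        bfactor=atom.b_iso,
                    )
                )
            residues.append(
                Residue(
                    name=res.name,
                    seqnum=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    het=(res.het_flag == "H"),
                    atoms=atoms,
                )
            )
        chains.append(Chain(id=ch.name, residues=residues))
    structure = Structure(id=st.name or str(path), chains=chains)
    if all(r.is_water or r.het for c in structure.chains for r in c.residues):
        warnings.warn(f"{path}: no protein (ATOM) residues found", stacklevel=2)
    return structure


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model(1)
    for chain in structure.chains:
        gch = gemmi.Chain(chain.id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seqnum, res.icode or " ")
            gres.het_flag = "H" if (res.het or res.is_water) else "A"
            for atom in res.atoms:
                gat = gemmi.Atom()
                gat.name = atom.name
                gat.element = gemmi.Element(atom.element)
                gat.pos = gemmi.Position(atom.x, atom.y, atom.z)
                gat.occ = atom.occupancy
                gat.b_iso = atom.bfactor
                gres.add_atom(gat)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(structure: Structure, path) -> None:
    _to_gemmi(structure).write_pdb(str(path))


def select_chain(structure: Structure, chain_id: str) -> Structure:
    """Sub-structure containing exactly one chain."""
    chain = structure.chain(chain_id)
    return Structure(id=f"{structure.id}:{chain_id}", chains=[chain])


# ---------------------------------------------------------------------------
# Ligand selection and binding site

@dataclass
class LigandSelection:
    """The atoms treated as "the ligand", with their parent residues."""

    atoms: list[tuple[Residue, Atom]]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(f"empty ligand selection ({self.description})")

    @property
    def residue_keys(self) -> set[tuple[int, str, str]]:
        return {(r.seqnum, r.icode, r.name) for r, _ in self.atoms}

    @property
    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for _, a in self.atoms])


def ligand_selection(
    structure: Structure,
    chain: str | None = None,
    resnames: list[str] | None = None,
) -> LigandSelection:
    """Select ligand atoms.

    Default rule: every HETATM residue that is not water.  Overrides: a
    whole chain (peptidomimetic inhibitors are often deposited as their own
    polymer chain) or a set of residue names.
    """
    atoms: list[tuple[Residue, Atom]] = []
    if chain is not None:
        for res in structure.chain(chain).residues:
            if not res.is_water:
                atoms.extend((res, a) for a in res.atoms)
        desc = f"chain {chain}"
    elif resnames is not None:
        wanted = {n.upper() for n in resnames}
        for ch in structure.chains:
            for res in ch.residues:
                if res.name in wanted:
                    atoms.extend((res, a) for a in res.atoms)
        desc = f"resnames {sorted(wanted)}"
    else:
        for ch in structure.chains:
            for res in ch.residues:
                if res.het and not res.is_water:
                    atoms.extend((res, a) for a in res.atoms)
        desc = "all non-water HETATM"
    return LigandSelection(atoms=atoms, description=desc)


@dataclass
class BindingSite:
    """Residues within the cutoff of the ligand, with their closest-approach
    distances."""

    entries: list[tuple[int, str, float]]  # (resnum, 3-letter name, min dist)
    cutoff: float = 5.0

    def __post_init__(self) -> None:
        nums = [n for n, _, _ in self.entries]
        if len(nums) != len(set(nums)):
            raise StructureError("duplicate residue numbers in binding site")
        if any(d > self.cutoff + 1e-9 for _, _, d in self.entries):
            raise StructureError("binding-site entry beyond the cutoff")
        self.entries = sorted(self.entries)

    @property
    def resnums(self) -> list[int]:
        return [n for n, _, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["resnum", "resname", "min_distance"])

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df["min_distance"] = df["min_distance"].round(3)
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def binding_site(
    protein: Structure,
    ligand: LigandSelection,
    cutoff: float = 5.0,
    heavy_only: bool = False,
) -> BindingSite:
    """Protein residues with any atom within ``cutoff`` of any ligand atom.

    The condition is inclusive (<= cutoff).  Waters and the ligand's own
    residues are excluded from the protein side; hydrogens participate if
    present unless ``heavy_only`` is set.
    """
    if cutoff <= 0:
        raise StructureError("cutoff must be positive")
    lig_coords = ligand.coords
    lig_keys = ligand.residue_keys
    entries = []
    for chain in protein.chains:
        for res in chain.residues:
            if res.is_water or (res.seqnum, res.icode, res.name) in lig_keys:
                continue
            atoms = res.atoms
            if heavy_only:
                atoms = [a for a in atoms if a.element.upper() != "H"]
            if not atoms:
                continue
            coords = np.array([[a.x, a.y, a.z] for a in atoms])
            dmin = float(cdist(coords, lig_coords).min())
            if dmin <= cutoff:
                entries.append((res.seqnum, res.name, dmin))
    return BindingSite(entries=entries, cutoff=cutoff)


# ---------------------------------------------------------------------------
# Superposition

def match_calphas(a: Structure | Chain, b: Structure | Chain):
    """Pair C-alpha atoms of two chains by global sequence alignment.

    One-letter sequences are derived from the protein residues
    (non-standard residues map to ``X``), aligned with Needleman-Wunsch,
    and residues aligned to each other are paired where both carry a CA
    atom.  Returns ``(coords_a, coords_b, pairs)`` with equal-length
    coordinate arrays.
    """

    def residues_of(obj):
        chain = obj.chains[0] if isinstance(obj, Structure) else obj
        return chain.protein_residues

    res_a, res_b = residues_of(a), residues_of(b)
    if len(res_a) < 3 or len(res_b) < 3:
        raise StructureError("need at least 3 protein residues per chain")
    aln = needleman_wunsch(
        "".join(r.one_letter for r in res_a), "".join(r.one_letter for r in res_b)
    )
    ia = ib = 0
    pairs = []
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != GAP and y != GAP:
            ca_a, ca_b = res_a[ia].atom("CA"), res_b[ib].atom("CA")
            if ca_a is not None and ca_b is not None:
                pairs.append((res_a[ia], res_b[ib]))
        ia += x != GAP
        ib += y != GAP
    if len(pairs) < 3:
        raise StructureError("insufficient pairs: fewer than 3 matched C-alphas")
    coords_a = np.array([ra.atom("CA").coords for ra, _ in pairs])
    coords_b = np.array([rb.atom("CA").coords for _, rb in pairs])
    return coords_a, coords_b, pairs


@dataclass
class SuperpositionResult:
    """Optimal rigid-body fit of the second point set onto the first."""

    rotation: np.ndarray  # 3x3 proper rotation
    translation: np.ndarray  # 3-vector, Angstroms
    rmsd: float
    n_pairs: int
    pairs: list | None = None

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(p: np.ndarray, q: np.ndarray, pairs=None) -> SuperpositionResult:
    """Least-squares rigid superposition of ``q`` onto ``p`` (Kabsch, via
    SVD with reflection correction).  Inputs are not modified."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise StructureError("point sets must be matching (n, 3) arrays")
    if len(p) == 0:
        raise StructureError("empty point sets")
    if not (np.isfinite(p).all() and np.isfinite(q).all()):
        raise StructureError("non-finite coordinates")
    cp, cq = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - cp, q - cq
    cov = q0.T @ p0
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = cp - rotation @ cq
    moved = q0 @ rotation.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - p0) ** 2, axis=1))))
    return SuperpositionResult(
        rotation=rotation,
        translation=translation,
        rmsd=rmsd,
        n_pairs=len(p),
        pairs=pairs,
    )


def superpose_chains(a: Structure | Chain, b: Structure | Chain) -> SuperpositionResult:
    """Convenience: match C-alphas by sequence, then Kabsch-fit them."""
    ca, cb, pairs = match_calphas(a, b)
    return kabsch_superpose(ca, cb, pairs=pairs)


# ---------------------------------------------------------------------------
# Joining trace statuses onto structure

def annotate_binding_site(
    site: BindingSite, statuses: ResidueStatusMap
) -> pd.DataFrame:
    """Per binding-site residue: number, name, trace status, closest
    distance.  Residues absent from the status map are reported UNMAPPED."""
    rows = []
    for resnum, name, dist in site.entries:
        status = statuses.status_of(resnum)
        rows.append(
            (resnum, name, status.value if status else "UNMAPPED", round(dist, 3))
        )
    return pd.DataFrame(rows, columns=["resnum", "resname", "status", "min_distance"])


def flap_intersection(site: BindingSite, flap_start: int, flap_end: int) -> list[int]:
    """Binding-site residues inside an inclusive residue-number range (the
    flexible flap that covers an aspartyl protease's active site)."""
    if flap_start > flap_end:
        raise StructureError("flap_start must be <= flap_end")
    return [n for n in site.resnums if flap_start <= n <= flap_end]


def write_annotated_pdb(
    structure: Structure, statuses: ResidueStatusMap, path
) -> None:
    """Write a PDB copy whose B-factor column encodes the trace status:
    0.00 neutral, 50.00 group-specific, 99.99 conserved, 25.00 unmapped."""
    annotated = Structure(id=structure.id, chains=[])
    for chain in structure.chains:
        new_res = []
        for res in chain.residues:
            if res.het or res.is_water:
                b = STATUS_BFACTOR[None]
            else:
                b = STATUS_BFACTOR[statuses.status_of(res.seqnum)]
            atoms = [
                Atom(a.name, a.element, a.x, a.y, a.z, a.occupancy, b)
                for a in res.atoms
            ]
            new_res.append(
                Residue(res.name, res.seqnum, res.icode, res.het, atoms)
            )
        annotated.chains.append(Chain(id=chain.id, residues=new_res))
    write_pdb(annotated, path)
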