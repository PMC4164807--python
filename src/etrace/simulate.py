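"""Synthetic data with planted ground truth.

Two generators make every pipeline stage testable without downloads:

* :func:`simulate_family` emits a two-group ortholog family whose columns
  have known conserved / group-specific / neutral statuses, emulating the
  structure of a paralog dataset of >80%-identical orthologs;
* :func:`simulate_complex` emits a toy protein-ligand PDB complex whose
  true 5-Angstrom binding site is known by construction.

:func:`table1_fixture` ships the BACE1/BACE2 ligand-binding-site reference
table (residue numbers, names, and trace statuses, with the BACE1<->BACE2
correspondence) in machine-readable form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .alignio import MultipleAlignment, SequenceRecord, percent_identity
from .phylogeny import GroupPartition
from .structure import Atom, BindingSite, Chain, Residue, Structure, write_pdb
from .trace import Status

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Sequence families

@dataclass(frozen=True)
class FamilySpec:
    """Parameters of a planted two-group ortholog family.

    Defaults mirror the worked example's regime: two paralog groups of
    seven mammalian orthologs each, ~40% conserved and ~25% group-specific
    columns, mild within-group variability at neutral columns.
    """

    n_groups: int = 2
    seqs_per_group: int = 7
    length: int = 200
    fraction_conserved: float = 0.4
    fraction_group_specific: float = 0.25
    fraction_neutral: float = 0.35
    neutral_alphabet_size: int = 4
    within_group_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups != 2:
            raise SimulationError("only two-group families are supported")
        total = (
            self.fraction_conserved
            + self.fraction_group_specific
            + self.fraction_neutral
        )
        if abs(total - 1.0) > 1e-9:
            raise SimulationError("status fractions must sum to 1")
        if min(
            self.fraction_conserved,
            self.fraction_group_specific,
            self.fraction_neutral,
        ) < 0:
            raise SimulationError("fractions must be non-negative")
        if self.neutral_alphabet_size < 2:
            raise SimulationError("neutral_alphabet_size must be >= 2")
        if not 0 <= self.within_group_noise <= 1:
            raise SimulationError("within_group_noise must be in [0, 1]")
        if self.seqs_per_group < 2 or self.length < 1:
            raise SimulationError("need >= 2 sequences per group and length >= 1")


@dataclass
class PlantedTruth:
    """Ground truth for a simulated family."""

    statuses: list[Status]
    group_letters: dict[int, list[str | None]]  # planted consensus, None = neutral
    identities: dict[str, float] = field(default_factory=dict)


def simulate_family(
    spec: FamilySpec,
) -> tuple[MultipleAlignment, GroupPartition, PlantedTruth]:
    """Generate an alignment with planted column statuses.

    Conserved columns carry one letter everywhere; group-specific columns
    one letter per group, differing between groups.  Neutral columns carry
    a small per-column alphabet: sequences mutate away from the column's
    base letter at the ``within_group_noise`` rate, and two randomly chosen
    members of one group are forced to disagree so the column is genuinely
    variable even at zero noise.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    n_c = int(round(spec.fraction_conserved * L))
    n_g = int(round(spec.fraction_group_specific * L))
    n_n = L - n_c - n_g
    if n_n < 0:
        raise SimulationError("infeasible fractions for this length")
    status_order = (
        [Status.CONSERVED] * n_c + [Status.GROUP_SPECIFIC] * n_g + [Status.NEUTRAL] * n_n
    )
    perm = rng.permutation(L)
    statuses: list[Status] = [None] * L  # type: ignore[list-item]
    for pos, status in zip(perm, status_order):
        statuses[pos] = status

    ids = {
        g: [f"G{g}_s{i}" for i in range(spec.seqs_per_group)]
        for g in (1, 2)
    }
    seqs = {g: [[""] * L for _ in range(spec.seqs_per_group)] for g in (1, 2)}
    group_letters: dict[int, list[str | None]] = {1: [None] * L, 2: [None] * L}

    for col in range(L):
        status = statuses[col]
        if status is Status.CONSERVED:
            letter = AMINO_ACIDS[rng.integers(20)]
            for g in (1, 2):
                group_letters[g][col] = letter
                for row in seqs[g]:
                    row[col] = letter
        elif status is Status.GROUP_SPECIFIC:
            i1, i2 = rng.choice(20, size=2, replace=False)
            for g, idx in ((1, i1), (2, i2)):
                letter = AMINO_ACIDS[idx]
                group_letters[g][col] = letter
                for row in seqs[g]:
                    row[col] = letter
        else:
            alphabet = [
                AMINO_ACIDS[i]
                for i in rng.choice(20, size=spec.neutral_alphabet_size, replace=False)
            ]
            base = alphabet[0]
            for g in (1, 2):
                for row in seqs[g]:
                    if rng.random() < spec.within_group_noise:
                        row[col] = alphabet[rng.integers(len(alphabet))]
                    else:
                        row[col] = base
            # force genuine variability regardless of the noise draw; the
            # disagreeing pair is drawn per column so no single sequence
            # accumulates an outlier branch
            g_force = int(rng.integers(1, 3))
            m1, m2 = (int(i) for i in rng.choice(spec.seqs_per_group, size=2, replace=False))
            seqs[g_force][m1][col] = alphabet[0]
            seqs[g_force][m2][col] = alphabet[1]

    records = []
    assignment = {}
    for g in (1, 2):
        for sid, row in zip(ids[g], seqs[g]):
            records.append(SequenceRecord(sid, "".join(row)))
            assignment[sid] = g
    msa = MultipleAlignment(records, group_labels={i: f"group{g}" for i, g in assignment.items()})
    partition = GroupPartition(assignment)

    truth = PlantedTruth(statuses=statuses, group_letters=group_letters)
    for g in (1, 2):
        query = msa.record(ids[g][0])
        for sid in ids[g]:
            truth.identities[sid] = percent_identity(msa.record(sid), query)
    return msa, partition, truth


# ---------------------------------------------------------------------------
# Toy complexes

@dataclass(frozen=True)
class ToyComplexSpec:
    """A toy protein-ligand complex with planted contact distances.

    The protein is a single chain of backbone atoms (N, CA, C, O) on an
    idealised helix (1.5 A rise, 100 deg twist, 2.3 A radius) or a straight
    chain at 3.8 A CA spacing.  Each ligand atom is placed at an exact
    distance from a target residue's CA along a given direction.
    """

    n_residues: int = 30
    geometry: str = "helix"  # or "straight"
    ligand_placements: tuple[tuple[int, float, tuple[float, float, float]], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in ("helix", "straight"):
            raise SimulationError("geometry must be 'helix' or 'straight'")
        if self.n_residues < 3:
            raise SimulationError("need at least 3 residues")
        for target, dist, direction in self.ligand_placements:
            if not 1 <= target <= self.n_residues:
                raise SimulationError(f"target residue {target} out of range")
            if dist < 1.0:
                raise SimulationError("requested ligand distances must be >= 1 A")
            if float(np.linalg.norm(direction)) < 1e-9:
                raise SimulationError("direction vector must be non-zero")


def _backbone_coords(spec: ToyComplexSpec) -> np.ndarray:
    i = np.arange(spec.n_residues)
    if spec.geometry == "helix":
        theta = np.deg2rad(100.0) * i
        ca = np.column_stack(
            [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i]
        )
    else:
        ca = np.column_stack([3.8 * i, np.zeros_like(i, float), np.zeros_like(i, float)])
    return ca


def simulate_complex(
    spec: ToyComplexSpec, path=None
) -> tuple[Structure, BindingSite]:
    """Emit the toy complex and its true binding site at the 5 A cutoff.

    The truth is measured from the emitted coordinates by an exhaustive
    atom-pair scan, so it is correct by construction whatever the backbone
    does around the planted contacts.
    """
    rng = np.random.default_rng(spec.seed)
    ca = _backbone_coords(spec)
    letters = [AMINO_ACIDS[i] for i in rng.integers(0, 20, size=spec.n_residues)]
    residues = []
    for idx in range(spec.n_residues):
        c = ca[idx]
        atoms = [
            Atom("N", "N", *(c + np.array([-0.8, -0.9, 0.0]))),
            Atom("CA", "C", *c),
            Atom("C", "C", *(c + np.array([0.9, 0.8, 0.0]))),
            Atom("O", "O", *(c + np.array([0.9, 0.8, 1.2]))),
        ]
        residues.append(
            Residue(THREE_LETTER[letters[idx]], idx + 1, atoms=atoms)
        )
    chain = Chain(id="A", residues=residues)

    lig_atoms = []
    for k, (target, dist, direction) in enumerate(spec.ligand_placements):
        unit = np.asarray(direction, float)
        unit = unit / np.linalg.norm(unit)
        pos = ca[target - 1] + dist * unit
        lig_atoms.append(Atom(f"C{k + 1}", "C", *pos))
    chains = [chain]
    if lig_atoms:
        chains.append(
            Chain(id="L", residues=[Residue("LIG", 900, het=True, atoms=lig_atoms)])
        )
    structure = Structure(id="toy_complex", chains=chains)

    entries = []
    if lig_atoms:
        lig = np.array([[a.x, a.y, a.z] for a in lig_atoms])
        for res in residues:
            dmin = min(
                float(np.linalg.norm(np.array([a.x, a.y, a.z]) - l))
                for a in res.atoms
                for l in lig
            )
            if dmin <= 5.0:
                entries.append((res.seqnum, res.name, dmin))
    truth = BindingSite(entries=entries, cutoff=5.0)

    if path is not None:
        write_pdb(structure, path)
    return structure, truth


# ---------------------------------------------------------------------------
# Reference table

def table1_fixture() -> pd.DataFrame:
    """The packaged BACE1/BACE2 binding-site reference table.

    28 BACE1 rows and 24 BACE2 rows (residue name, structure residue
    number, trace status); rows with both sides present give the
    BACE1<->BACE2 correspondence.
    """
    with resources.files("etrace.data").joinpath("table1.tsv").open() as fh:
        df = pd.read_csv(
            fh,
            sep="\t",
            dtype={"bace1_resnum": "Int64", "bace2_resnum": "Int64"},
        )
    return df
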