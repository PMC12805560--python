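"""SMILES input handling, molecular graphs, and 3D conformer embedding.

The pipeline front end: trivial names or SMILES strings (single,
comma-separated, or from a CSV file) are turned into hydrogen-explicit
molecular graphs, which are then embedded in 3D by distance geometry.

SMILES carries connectivity only — atoms, bonds, rings, branches — and no
geometry, so 3D coordinates are generated by a stochastic embedding.  A
fixed seed makes a run reproducible; different seeds produce different
conformations, which is deliberate: seeing a fresh conformer on each
generation is part of the teaching value of the original tools.

RDKit does the parsing, hydrogenation and distance-geometry embedding;
this module wraps it behind plain dataclasses so the mesh and export
layers never touch RDKit objects.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

from . import names
from .errors import (
    EmbeddingFailure,
    EmptyFile,
    EmptyInput,
    EmptyToken,
    InvalidSmiles,
    ValenceError,
)

# RDKit logs parse failures to stderr on its own; we raise instead.
RDLogger.DisableLog("rdApp.error")

_BOND_ORDER = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}
_ORDER_BOND = {v: k for k, v in _BOND_ORDER.items()}

#: maximum seed accepted by the embedder (RDKit takes a signed 32-bit int)
MAX_SEED = 2**31 - 1


class Atom(NamedTuple):
    index: int
    element: str
    formal_charge: int


class Bond(NamedTuple):
    atom_a: int
    atom_b: int
    order: str  # one of single / double / triple / aromatic


@dataclass
class MoleculeGraph:
    """Chemical graph parsed from SMILES.

    Heavy atoms only until :func:`add_hydrogens` is applied; afterwards
    hydrogens are appended after the original heavy atoms so indices of
    heavy atoms are stable.  ``_rdmol`` keeps the RDKit molecule (with any
    stereo descriptors from the input) for the embedder; it is rebuilt
    from the graph if absent.
    """

    atoms: list[Atom]
    bonds: list[Bond]
    source_smiles: str
    _rdmol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]


@dataclass(frozen=True)
class Conformer:
    """One 3D embedding of a molecule, coordinates in Ångström.

    ``coordinates`` is an (n_atoms, 3) float array index-aligned with
    ``MoleculeGraph.atoms``; the centroid is at the origin.
    """

    coordinates: np.ndarray
    seed: int

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coordinates must be an (n, 3) array")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coordinates", coords)


@dataclass(frozen=True)
class BatchInput:
    """An ordered batch of input strings (trivial names or SMILES)."""

    entries: tuple[str, ...]
    source: str  # "inline" or "csv"

    def __post_init__(self):
        if not self.entries:
            raise EmptyInput("batch contains no entries")
        if any(not e.strip() for e in self.entries):
            raise EmptyToken("batch contains a blank entry")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def resolve_input(text: str) -> str:
    """Resolve a trivial name to SMILES, or pass SMILES through unchanged.

    Lookup is against the bundled offline dictionary
    (:data:`molforge.names.TRIVIAL_NAMES`); unknown strings are returned
    as-is for :func:`parse_smiles` to validate.
    """
    if not text or not text.strip():
        raise EmptyInput("input is empty")
    hit = names.lookup(text)
    return hit if hit is not None else text.strip()


def parse_smiles(smiles: str) -> MoleculeGraph:
    """Parse a SMILES string into a heavy-atom molecular graph.

    Aromatic rings are kekulized to alternating single/double bonds so the
    representation builders only ever see discrete bond orders.  Implicit
    hydrogens are *not* added here; see :func:`add_hydrogens`.

    Raises :class:`InvalidSmiles` with the offending input echoed for
    syntax errors, unclosed rings, unknown elements, or valence violations.
    """
    if not smiles or not smiles.strip():
        raise EmptyInput("SMILES string is empty")
    smiles = smiles.strip()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmiles(smiles)
    try:
        Chem.Kekulize(mol, clearAromaticFlags=True)
    except Chem.KekulizeException:
        raise InvalidSmiles(smiles, "cannot kekulize aromatic system") from None
    return _graph_from_rdmol(mol, smiles)


def add_hydrogens(graph: MoleculeGraph) -> MoleculeGraph:
    """Append explicit hydrogens so every atom reaches standard valence.

    Atom order in the result: the original heavy atoms first (indices
    unchanged), then the hydrogens.  Idempotent on already-saturated
    graphs.  Raises :class:`ValenceError` if an atom already exceeds its
    standard valence.
    """
    mol = _rdmol_for(graph)
    molh = Chem.AddHs(mol)
    return _graph_from_rdmol(molh, graph.source_smiles)


def embed_conformer(
    graph: MoleculeGraph, seed: int, max_retries: int = 10
) -> Conformer:
    """Generate one random 3D embedding of a hydrogen-explicit graph.

    Uses ETKDG distance geometry.  Identical (graph, seed) pairs yield
    bit-identical coordinates across runs; different seeds generally give
    different conformations.  The centroid is translated to the origin.

    If the primary attempt fails (rare, pathological topologies), up to
    ``max_retries`` deterministic fallback seeds derived from ``seed`` are
    tried before :class:`EmbeddingFailure` is raised.
    """
    if not (0 <= seed <= MAX_SEED):
        raise ValueError(f"seed must be in [0, {MAX_SEED}]")
    mol = Chem.Mol(_rdmol_for(graph))  # work on a copy
    for attempt in range(max_retries + 1):
        params = AllChem.ETKDGv3()
        params.randomSeed = int((seed + attempt * 7919) % (MAX_SEED + 1))
        # ETKDG seeds its own RNG from randomSeed, so this is reproducible
        if AllChem.EmbedMolecule(mol, params) == 0:
            coords = np.array(mol.GetConformer().GetPositions(), dtype=float)
            coords -= coords.mean(axis=0)
            conf = Conformer(coordinates=coords, seed=seed)
            if _distances_sane(graph, conf):
                return conf
    raise EmbeddingFailure(
        f"could not embed {graph.source_smiles!r} after {max_retries + 1} attempts"
    )


def split_batch_text(text: str) -> BatchInput:
    """Split a comma-separated list of inputs (e.g. ``"CCO, CO"``).

    Tokens are trimmed and order is preserved; a blank token between
    commas raises :class:`EmptyToken`.
    """
    if not text or not text.strip():
        raise EmptyInput("batch text is empty")
    tokens = [t.strip() for t in text.split(",")]
    if any(not t for t in tokens):
        raise EmptyToken(f"blank entry in batch: {text!r}")
    return BatchInput(entries=tuple(tokens), source="inline")


def read_batch_csv(path: str | Path, header: bool = False) -> BatchInput:
    """Read a batch from a CSV file: first column of each non-empty row.

    The dialect is plain comma-separated UTF-8.  ``header=True`` skips the
    first row.  Raises ``FileNotFoundError``, :class:`EmptyFile` for a
    file with no usable rows, or :class:`EmptyToken` for a row whose first
    column is blank.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"batch file not found: {path}")
    entries: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        for i, row in enumerate(reader):
            if header and i == 0:
                continue
            if not row or all(not cell.strip() for cell in row):
                continue  # ignore fully blank lines
            first = row[0].strip()
            if not first:
                raise EmptyToken(f"blank first column in row {i + 1} of {path}")
            entries.append(first)
    if not entries:
        raise EmptyFile(f"no entries in batch file: {path}")
    return BatchInput(entries=tuple(entries), source="csv")


def prepare_molecule(
    text: str, seed: int = 0, hydrogens: bool = True, max_retries: int = 10
) -> tuple[MoleculeGraph, Conformer]:
    """Convenience: resolve → parse → (hydrogenate) → embed one input."""
    graph = parse_smiles(resolve_input(text))
    # embedding always uses the hydrogen-explicit molecule for realistic
    # geometry; `hydrogens=False` only trims the graph/coordinates after
    full = add_hydrogens(graph)
    conf = embed_conformer(full, seed, max_retries=max_retries)
    if hydrogens:
        return full, conf
    n = graph.n_atoms
    heavy_coords = conf.coordinates[:n] - conf.coordinates[:n].mean(axis=0)
    return graph, Conformer(coordinates=heavy_coords, seed=seed)


# ---------------------------------------------------------------------------
# internals


def _graph_from_rdmol(mol: Chem.Mol, source_smiles: str) -> MoleculeGraph:
    atoms = [
        Atom(a.GetIdx(), a.GetSymbol(), a.GetFormalCharge()) for a in mol.GetAtoms()
    ]
    bonds = [
        Bond(
            b.GetBeginAtomIdx(),
            b.GetEndAtomIdx(),
            _BOND_ORDER.get(b.GetBondType(), "single"),
        )
        for b in mol.GetBonds()
    ]
    return MoleculeGraph(atoms=atoms, bonds=bonds, source_smiles=source_smiles, _rdmol=mol)


def _rdmol_for(graph: MoleculeGraph) -> Chem.Mol:
    """The RDKit molecule behind a graph, rebuilt from the fields if needed."""
    if graph._rdmol is not None:
        return graph._rdmol
    rw = Chem.RWMol()
    for atom in graph.atoms:
        a = Chem.Atom(atom.element)
        a.SetFormalCharge(atom.formal_charge)
        rw.AddAtom(a)
    for bond in graph.bonds:
        rw.AddBond(bond.atom_a, bond.atom_b, _ORDER_BOND[bond.order])
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Chem.AtomValenceException as exc:
        raise ValenceError(f"atom exceeds standard valence in {graph.source_smiles!r}") from exc
    except Chem.MolSanitizeException as exc:
        raise InvalidSmiles(graph.source_smiles, str(exc)) from exc
    return mol


def _distances_sane(graph: MoleculeGraph, conf: Conformer) -> bool:
    """Check the geometric sanity invariants of an embedding.

    Bonded atoms must be 0.7–2.2 Å apart; non-bonded pairs must not
    overlap (> 0.5 Å).
    """
    coords = conf.coordinates
    n = len(coords)
    if n == 1:
        return True
    bonded = {(min(b.atom_a, b.atom_b), max(b.atom_a, b.atom_b)) for b in graph.bonds}
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    iu, ju = np.triu_indices(n, k=1)
    for i, j, d in zip(iu, ju, dist[iu, ju]):
        if (int(i), int(j)) in bonded:
            if not (0.7 <= d <= 2.2):
                return False
        elif d <= 0.5:
            return False
    return True


def iter_resolved(batch: BatchInput) -> Iterable[tuple[str, str]]:
    """Yield (original entry, resolved SMILES) pairs for a batch."""
    for entry in batch:
        yield entry, resolve_input(entry)
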