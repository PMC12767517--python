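"""Two-chain complex structures and residue contact graphs.

A protein complex is reduced to a residue-level undirected graph: one node per
residue of either chain, one edge per residue pair whose minimal heavy-atom
distance does not exceed a threshold (4.5 Å by default, boundary inclusive).
Edges are recorded for both intra- and inter-chain contacts; nodes incident to
at least one inter-chain edge form the binding interface.

Structures are read with :mod:`gemmi` (mmCIF or PDB). Hydrogens and deuteriums
are stripped, alternate locations are resolved to the highest-occupancy
conformer, waters and non-polymer ligands are dropped, and residues are
renumbered sequentially within each chain so that variant positions index the
FASTA sequence rather than author numbering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    ChainNotFoundError,
    DegenerateInputError,
    StructureFormatError,
)

INTERACTOR = "interactor"
PARTNER = "partner"

DEFAULT_CONTACT_THRESHOLD = 4.5  # Å, minimal heavy-atom distance

_THREE_TO_ONE_FALLBACK = "X"


@dataclass
class Residue:
    """A residue reduced to its heavy atoms.

    ``position`` is 1-based and sequential within the chain; author numbering
    gaps are ignored so positions line up with the sequence.
    """

    position: int
    amino_acid: str
    elements: list[str]
    coords: np.ndarray  # (n_heavy_atoms, 3) in Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.coords) == 0:
            raise DegenerateInputError(
                f"residue at position {self.position} has no heavy atoms"
            )


@dataclass
class ChainStructure:
    chain_id: str
    residues: list[Residue]

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)


@dataclass
class ComplexStructure:
    """A two-chain complex with explicit interactor/partner roles."""

    interactor: ChainStructure
    partner: ChainStructure
    source_tag: str = ""

    def flipped(self) -> "ComplexStructure":
        """Swap interactor and partner roles (for partner-chain variants)."""
        return ComplexStructure(
            interactor=self.partner,
            partner=self.interactor,
            source_tag=self.source_tag,
        )


@dataclass
class ContactGraph:
    """Residue contact graph of a complex (or a monomer).

    Nodes are indexed 0-based, interactor chain first. ``edges`` holds
    unordered index pairs as sorted tuples; there are no self-edges.
    """

    chain_role: list[str]
    position: np.ndarray  # 1-based within chain
    amino_acid: list[str]
    edges: set[tuple[int, int]]
    contact_threshold: float
    n_interactor: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=int)

    @property
    def n_nodes(self) -> int:
        return len(self.chain_role)

    def adjacency(self) -> np.ndarray:
        """Dense boolean adjacency without self-loops."""
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for i, j in self.edges:
            a[i, j] = a[j, i] = True
        return a

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def inter_chain_edges(self) -> set[tuple[int, int]]:
        return {
            (i, j)
            for i, j in self.edges
            if self.chain_role[i] != self.chain_role[j]
        }


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is None or not info.found():
        return _THREE_TO_ONE_FALLBACK
    code = info.one_letter_code.upper()
    return code if code.isalpha() else _THREE_TO_ONE_FALLBACK


def _extract_chain(model: gemmi.Model, chain_id: str) -> ChainStructure:
    chain = model.find_chain(chain_id)
    if chain is None:
        available = ", ".join(c.name for c in model) or "none"
        raise ChainNotFoundError(
            f"chain {chain_id!r} not found (available: {available})"
        )
    residues: list[Residue] = []
    pos = 0
    for res in chain:
        info = gemmi.find_tabulated_residue(res.name)
        if info is not None and info.found():
            if info.is_water():
                continue
            if not info.is_amino_acid():
                continue  # hetero ligand: outside the residue-graph model
        # pick highest-occupancy conformer per atom name; ties by altloc order
        best: dict[str, gemmi.Atom] = {}
        for atom in res:
            if atom.element.is_hydrogen:
                continue
            prev = best.get(atom.name)
            if prev is None or atom.occ > prev.occ or (
                atom.occ == prev.occ and atom.altloc < prev.altloc
            ):
                best[atom.name] = atom
        if not best:
            warnings.warn(
                f"residue {res.name} {res.seqid} in chain {chain_id} has no "
                "heavy-atom coordinates; omitted",
                stacklevel=3,
            )
            continue
        pos += 1
        names = sorted(best)
        residues.append(
            Residue(
                position=pos,
                amino_acid=_one_letter(res.name),
                elements=[best[n].element.name for n in names],
                coords=np.array(
                    [[best[n].pos.x, best[n].pos.y, best[n].pos.z] for n in names]
                ),
            )
        )
    return ChainStructure(chain_id=chain_id, residues=residues)


def parse_complex(
    path: str | Path, interactor_chain: str, partner_chain: str
) -> ComplexStructure:
    """Read a two-chain complex from an mmCIF or PDB file.

    Hydrogens are stripped, altlocs resolved to the highest-occupancy
    conformer, and residues renumbered 1..n within each chain.
    """
    path = Path(path)
    if not path.exists():
        raise StructureFormatError(f"no such structure file: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path} contains no models")
    model = st[0]
    return ComplexStructure(
        interactor=_extract_chain(model, interactor_chain),
        partner=_extract_chain(model, partner_chain),
        source_tag=str(path),
    )


def _chain_atoms(chain: ChainStructure) -> tuple[np.ndarray, np.ndarray]:
    """Stack heavy-atom coordinates with their residue index (0-based)."""
    coords = []
    owner = []
    for idx, res in enumerate(chain.residues):
        coords.append(res.coords)
        owner.append(np.full(len(res.coords), idx))
    return np.concatenate(coords), np.concatenate(owner)


def _contact_edges(
    coords: np.ndarray, owner: np.ndarray, threshold: float
) -> set[tuple[int, int]]:
    """Residue pairs with any atom pair within ``threshold`` (inclusive)."""
    tree = cKDTree(coords)
    # inflate the query radius slightly, then apply the exact <= test so the
    # boundary case (distance exactly equal to threshold) is always an edge
    pairs = tree.query_pairs(r=threshold * (1 + 1e-9), output_type="ndarray")
    edges: set[tuple[int, int]] = set()
    if len(pairs) == 0:
        return edges
    d2 = np.sum((coords[pairs[:, 0]] - coords[pairs[:, 1]]) ** 2, axis=1)
    keep = d2 <= threshold * threshold
    for a, b in pairs[keep]:
        ra, rb = owner[a], owner[b]
        if ra != rb:
            edges.add((min(ra, rb), max(ra, rb)))
    return edges


def build_contact_graph(
    complex_: ComplexStructure,
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
) -> ContactGraph:
    """Build the residue contact graph of a two-chain complex.

    Residues are in contact when any heavy-atom pair is within ``threshold``
    Å (boundary inclusive). Intra- and inter-chain contacts are both edges.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    for role, chain in ((INTERACTOR, complex_.interactor), (PARTNER, complex_.partner)):
        if len(chain) == 0:
            raise DegenerateInputError(f"{role} chain {chain.chain_id!r} is empty")
    ci, cp = complex_.interactor, complex_.partner
    coords_i, owner_i = _chain_atoms(ci)
    coords_p, owner_p = _chain_atoms(cp)
    coords = np.concatenate([coords_i, coords_p])
    owner = np.concatenate([owner_i, owner_p + len(ci)])
    edges = _contact_edges(coords, owner, threshold)
    return ContactGraph(
        chain_role=[INTERACTOR] * len(ci) + [PARTNER] * len(cp),
        position=np.concatenate(
            [np.arange(1, len(ci) + 1), np.arange(1, len(cp) + 1)]
        ),
        amino_acid=[r.amino_acid for r in ci.residues]
        + [r.amino_acid for r in cp.residues],
        edges=edges,
        contact_threshold=threshold,
        n_interactor=len(ci),
    )


def build_monomer_graph(
    chain: ChainStructure, threshold: float = DEFAULT_CONTACT_THRESHOLD
) -> ContactGraph:
    """Contact graph of a single chain (stability pretraining substrate)."""
    if len(chain) == 0:
        raise DegenerateInputError(f"chain {chain.chain_id!r} is empty")
    coords, owner = _chain_atoms(chain)
    edges = _contact_edges(coords, owner, threshold)
    return ContactGraph(
        chain_role=[INTERACTOR] * len(chain),
        position=np.arange(1, len(chain) + 1),
        amino_acid=[r.amino_acid for r in chain.residues],
        edges=edges,
        contact_threshold=threshold,
        n_interactor=len(chain),
    )


def interface_nodes(graph: ContactGraph) -> set[int]:
    """Nodes incident to at least one inter-chain edge."""
    nodes: set[int] = set()
    for i, j in graph.edges:
        if graph.chain_role[i] != graph.chain_role[j]:
            nodes.add(i)
            nodes.add(j)
    return nodes


# ---------------------------------------------------------------------------
# plain-text serialization (edge-list with a node table header)

def graph_to_text(graph: ContactGraph) -> str:
    lines = [f"# contact_graph v1\tthreshold={graph.contact_threshold!r}"]
    lines.append("# node\tindex\tchain_role\tposition\taa")
    for idx in range(graph.n_nodes):
        lines.append(
            "node\t{}\t{}\t{}\t{}".format(
                idx, graph.chain_role[idx], graph.position[idx], graph.amino_acid[idx]
            )
        )
    for i, j in sorted(graph.edges):
        lines.append(f"edge\t{i}\t{j}")
    return "\n".join(lines) + "\n"


def graph_from_text(text: str) -> ContactGraph:
    threshold = DEFAULT_CONTACT_THRESHOLD
    roles: list[str] = []
    positions: list[int] = []
    aas: list[str] = []
    edges: set[tuple[int, int]] = set()
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "threshold=" in line:
                threshold = float(line.split("threshold=")[1])
            continue
        parts = line.split("\t")
        if parts[0] == "node":
            roles.append(parts[2])
            positions.append(int(parts[3]))
            aas.append(parts[4])
        elif parts[0] == "edge":
            i, j = int(parts[1]), int(parts[2])
            edges.add((min(i, j), max(i, j)))
    return ContactGraph(
        chain_role=roles,
        position=np.array(positions),
        amino_acid=aas,
        edges=edges,
        contact_threshold=threshold,
        n_interactor=sum(1 for r in roles if r == INTERACTOR),
    )


def graph_to_npz(graph: ContactGraph, path: str | Path) -> None:
    """Compressed binary serialization for pipeline caching."""
    edges = np.array(sorted(graph.edges), dtype=np.int32).reshape(-1, 2)
    np.savez_compressed(
        path,
        chain_role=np.array([r == INTERACTOR for r in graph.chain_role]),
        position=graph.position.astype(np.int32),
        amino_acid=np.array(graph.amino_acid),
        edges=edges,
        threshold=np.array([graph.contact_threshold]),
    )


def graph_from_npz(path: str | Path) -> ContactGraph:
    with np.load(path, allow_pickle=False) as data:
        roles = [INTERACTOR if r else PARTNER for r in data["chain_role"]]
        return ContactGraph(
            chain_role=roles,
            position=data["position"].astype(int),
            amino_acid=[str(a) for a in data["amino_acid"]],
            edges={(int(i), int(j)) for i, j in data["edges"]},
            contact_threshold=float(data["threshold"][0]),
            n_interactor=sum(1 for r in roles if r == INTERACTOR),
        )


# ---------------------------------------------------------------------------
# PDB writing (used by the synthetic generators and fixtures)

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}


def write_pdb(chains: list[ChainStructure], path: str | Path) -> None:
    """Write chains to a minimal PDB file via gemmi."""
    st = gemmi.Structure()
    st.name = "edgetic"
    model = gemmi.Model(1)
    for chain in chains:
        ch = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            r = gemmi.Residue()
            r.name = _ONE_TO_THREE.get(res.amino_acid, "UNK")
            r.seqid = gemmi.SeqId(res.position, " ")
            for k, (el, xyz) in enumerate(zip(res.elements, res.coords)):
                atom = gemmi.Atom()
                atom.name = "CA" if k == 0 else f"CB"
                atom.element = gemmi.Element(el)
                atom.pos = gemmi.Position(*map(float, xyz))
                atom.occ = 1.0
                r.add_atom(atom)
            ch.add_residue(r)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
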