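"""Per-residue embeddings, node features and the mutation encoding.

Node features of a complex graph are the per-residue language-model embedding
rows of the *mutant* interactor sequence and the *wild-type* partner sequence,
mapped onto the graph by within-chain position. The mutation itself is encoded
as the difference between the mutant and wild-type residue embeddings at the
variant site, z-score normalized across the training variants.

Embedders are pluggable: production uses a protein language model (1024-dim
per-residue vectors) consumed from a file cache; tests and examples use the
deterministic :class:`SyntheticEmbedder`, whose output depends only on the
local k-mer context so that a point substitution perturbs a small window of
rows around the site.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from Bio import SeqIO

from .errors import (
    AlignmentError,
    DimensionError,
    InsufficientDataError,
    ReferenceMismatchError,
)
from .structure import INTERACTOR, ContactGraph

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_VARIANT_RE = re.compile(r"^(?:p\.)?([A-Za-z])(\d+)([A-Za-z])$")


@dataclass(frozen=True)
class MutationSpec:
    """A missense variant: wild-type residue, 1-based position, mutant residue."""

    position: int
    wt_aa: str
    mut_aa: str
    protein_id: str | None = None

    def __post_init__(self) -> None:
        if self.wt_aa == self.mut_aa:
            raise ValueError("wild-type and mutant residue must differ")
        if self.position < 1:
            raise ValueError("positions are 1-based")

    @classmethod
    def parse(cls, text: str, protein_id: str | None = None) -> "MutationSpec":
        """Parse ``C61G`` / ``p.C61G`` notation."""
        m = _VARIANT_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse variant {text!r}")
        return cls(
            position=int(m.group(2)),
            wt_aa=m.group(1).upper(),
            mut_aa=m.group(3).upper(),
            protein_id=protein_id,
        )

    def short(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"

    def reversed(self) -> "MutationSpec":
        return MutationSpec(self.position, self.mut_aa, self.wt_aa, self.protein_id)


def apply_mutation(sequence: str, spec: MutationSpec) -> str:
    """Apply a missense variant to a sequence, validating the reference."""
    if not 1 <= spec.position <= len(sequence):
        raise IndexError(
            f"position {spec.position} outside sequence of length {len(sequence)}"
        )
    idx = spec.position - 1
    if sequence[idx] != spec.wt_aa:
        raise ReferenceMismatchError(
            f"sequence has {sequence[idx]} at position {spec.position}, "
            f"variant states {spec.wt_aa}"
        )
    return sequence[:idx] + spec.mut_aa + sequence[idx + 1 :]


def encode_mutation_raw(
    wt_emb: np.ndarray, mut_emb: np.ndarray, position: int
) -> np.ndarray:
    """Difference of mutant and wild-type residue embeddings at the site."""
    wt_emb = np.asarray(wt_emb, dtype=float)
    mut_emb = np.asarray(mut_emb, dtype=float)
    if wt_emb.shape != mut_emb.shape or wt_emb.ndim != 2:
        raise DimensionError(
            f"embedding shapes differ: {wt_emb.shape} vs {mut_emb.shape}"
        )
    if not 1 <= position <= wt_emb.shape[0]:
        raise IndexError(f"position {position} outside embedding of length {wt_emb.shape[0]}")
    return mut_emb[position - 1] - wt_emb[position - 1]


@dataclass
class MutationEncoding:
    vector: np.ndarray
    normalized: bool = False


@dataclass
class Normalizer:
    """Per-dimension z-score statistics fitted on training-set raw encodings.

    Uses the population standard deviation (divide by n). Dimensions with zero
    variance are flagged and map to 0 after transformation.
    """

    mean_: np.ndarray | None = None
    std_: np.ndarray | None = None
    zero_variance_: np.ndarray | None = None

    def fit(self, raw_encodings) -> "Normalizer":
        mat = np.asarray(list(raw_encodings), dtype=float)
        if mat.ndim != 2 or mat.shape[0] < 2:
            raise InsufficientDataError(
                "need at least 2 raw encodings to fit a normalizer"
            )
        self.mean_ = mat.mean(axis=0)
        self.std_ = mat.std(axis=0)  # population sd
        self.zero_variance_ = self.std_ == 0.0
        return self

    @property
    def fitted(self) -> bool:
        return self.mean_ is not None

    def transform(self, raw: np.ndarray) -> MutationEncoding:
        if not self.fitted:
            raise InsufficientDataError("normalizer not fitted")
        raw = np.asarray(raw, dtype=float)
        safe_std = np.where(self.zero_variance_, 1.0, self.std_)
        z = (raw - self.mean_) / safe_std
        z = np.where(self.zero_variance_, 0.0, z)
        return MutationEncoding(vector=z, normalized=True)

    def to_dict(self) -> dict:
        return {
            "mean": self.mean_.tolist(),
            "std": self.std_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Normalizer":
        n = cls()
        n.mean_ = np.asarray(d["mean"], dtype=float)
        n.std_ = np.asarray(d["std"], dtype=float)
        n.zero_variance_ = n.std_ == 0.0
        return n


def fit_normalizer(raw_encodings) -> Normalizer:
    return Normalizer().fit(raw_encodings)


def normalize(raw: np.ndarray, normalizer: Normalizer) -> MutationEncoding:
    return normalizer.transform(raw)


def build_node_features(
    graph: ContactGraph,
    interactor_emb: np.ndarray,
    partner_emb: np.ndarray | None = None,
) -> np.ndarray:
    """Map embedding rows onto graph nodes by chain role and position.

    Interactor-role nodes receive rows of ``interactor_emb`` (the *mutant*
    interactor embedding in the prediction pipeline); partner-role nodes
    receive rows of the wild-type ``partner_emb``.
    """
    interactor_emb = np.asarray(interactor_emb, dtype=float)
    n_i = sum(1 for r in graph.chain_role if r == INTERACTOR)
    n_p = graph.n_nodes - n_i
    if interactor_emb.shape[0] != n_i:
        raise AlignmentError(
            f"interactor embedding has {interactor_emb.shape[0]} rows, "
            f"graph has {n_i} interactor residues"
        )
    if n_p > 0:
        if partner_emb is None:
            raise AlignmentError("graph has partner residues but no partner embedding")
        partner_emb = np.asarray(partner_emb, dtype=float)
        if partner_emb.shape[0] != n_p:
            raise AlignmentError(
                f"partner embedding has {partner_emb.shape[0]} rows, "
                f"graph has {n_p} partner residues"
            )
        if partner_emb.shape[1] != interactor_emb.shape[1]:
            raise DimensionError("interactor and partner embedding dimensions differ")
    x = np.empty((graph.n_nodes, interactor_emb.shape[1]), dtype=float)
    for idx in range(graph.n_nodes):
        row = graph.position[idx] - 1
        if graph.chain_role[idx] == INTERACTOR:
            x[idx] = interactor_emb[row]
        else:
            x[idx] = partner_emb[row]
    return x


# ---------------------------------------------------------------------------
# embedders

class SyntheticEmbedder:
    """Deterministic stand-in for a protein language model.

    The embedding row at position k is a pseudo-random unit-scale vector
    seeded by (seed, local k-mer context), where the context is the window
    ``seq[k-w : k+w+1]``. A point substitution therefore perturbs only rows
    within ``window`` of the site, and repeated calls are bit-identical.
    """

    def __init__(self, dimension: int = 32, seed: int = 0, window: int = 1):
        if dimension < 2:
            raise ValueError("dimension must be >= 2")
        self.name = "synthetic"
        self.dimension = dimension
        self.seed = seed
        self.window = window
        self._cache: dict[str, np.ndarray] = {}

    def _row(self, context: str) -> np.ndarray:
        digest = hashlib.sha256(
            f"{self.seed}|{self.window}|{context}".encode()
        ).digest()
        rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
        return rng.standard_normal(self.dimension)

    def embed(self, sequence: str) -> np.ndarray:
        cached = self._cache.get(sequence)
        if cached is not None:
            return cached
        w = self.window
        rows = []
        for k in range(len(sequence)):
            lo, hi = max(0, k - w), min(len(sequence), k + w + 1)
            context = f"{k - lo}:{sequence[lo:hi]}"
            rows.append(self._row(context))
        mat = np.asarray(rows)
        mat.setflags(write=False)
        self._cache[sequence] = mat
        return mat


class PrecomputedEmbedder:
    """Embedder backed by an HDF5 cache of per-residue embedding matrices.

    This is how production language-model embeddings (e.g. 1024-dim ProtT5
    rows computed offline) enter the pipeline; the cache is keyed by the
    SHA-256 of the sequence.
    """

    def __init__(self, cache_path: str | Path, name: str = "precomputed"):
        self.name = name
        self.cache_path = Path(cache_path)
        with h5py.File(self.cache_path, "r") as fh:
            self.dimension = int(fh.attrs["dimension"])

    @staticmethod
    def key(sequence: str) -> str:
        return hashlib.sha256(sequence.encode()).hexdigest()

    def embed(self, sequence: str) -> np.ndarray:
        with h5py.File(self.cache_path, "r") as fh:
            key = self.key(sequence)
            if key not in fh:
                raise KeyError(f"no cached embedding for sequence hash {key[:12]}…")
            return fh[key][()]


def write_embedding_cache(
    path: str | Path, sequences: dict[str, str], embedder
) -> None:
    """Embed every sequence and store the matrices keyed by sequence hash."""
    with h5py.File(path, "w") as fh:
        fh.attrs["dimension"] = embedder.dimension
        fh.attrs["embedder"] = embedder.name
        for seq in sequences.values():
            key = PrecomputedEmbedder.key(seq)
            if key not in fh:
                fh.create_dataset(key, data=embedder.embed(seq), track_times=False)


def get_embedder(kind: str, dimension: int = 32, seed: int = 0, cache: str | None = None):
    """Select an embedder by config key.

    ``synthetic`` builds the deterministic test embedder; ``prott5`` (or the
    generic ``precomputed``) reads per-residue matrices computed offline by
    the language model from an HDF5 cache.
    """
    if kind == "synthetic":
        return SyntheticEmbedder(dimension=dimension, seed=seed)
    if kind in ("prott5", "precomputed"):
        if cache is None:
            raise ValueError(f"{kind} embedder needs a cache path")
        return PrecomputedEmbedder(cache, name=kind)
    raise ValueError(f"unknown embedder kind {kind!r}")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
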