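"""Featurization: from records + structures + an embedder to model inputs.

The conventions enforced here mirror the prediction contract: the interactor
chain carries the *mutant* sequence embedding, the partner chain the
wild-type embedding, and the mutation encoding is the raw (un-normalized)
difference vector — normalization statistics are fitted downstream on
training data only. Variants on the partner chain must be handled by
flipping roles *before* featurization (:func:`flip_pair`).
"""

from __future__ import annotations

from .corpus import VariantPartnerPair
from .errors import DataError
from .features import apply_mutation, build_node_features, encode_mutation_raw
from .gat import TrainingExample
from .structure import (
    DEFAULT_CONTACT_THRESHOLD,
    ComplexStructure,
    build_contact_graph,
    build_monomer_graph,
)


def featurize_pair(
    pair: VariantPartnerPair,
    complex_: ComplexStructure,
    embedder,
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
    graph=None,
) -> TrainingExample:
    """Build a model input for one variant-partner triplet.

    ``graph`` may be supplied to reuse a cached contact graph (structures
    and graphs are per protein pair; embeddings and encodings per variant).
    """
    if pair.interactor_seq is None or pair.partner_seq is None:
        raise DataError(f"pair {pair.key} lacks sequences")
    if graph is None:
        graph = build_contact_graph(complex_, threshold)
    wt_emb = embedder.embed(pair.interactor_seq)
    mut_seq = apply_mutation(pair.interactor_seq, pair.mutation)
    mut_emb = embedder.embed(mut_seq)
    partner_emb = embedder.embed(pair.partner_seq)
    x = build_node_features(graph, mut_emb, partner_emb)
    raw = encode_mutation_raw(wt_emb, mut_emb, pair.mutation.position)
    return TrainingExample(
        graph=graph,
        node_features=x,
        raw_encoding=raw,
        mutation_node=pair.mutation.position - 1,
        label=pair.label,
        record=pair,
    )


def featurize_pairs(
    pairs,
    structures: dict[tuple[str, str], ComplexStructure],
    embedder,
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
) -> list[TrainingExample]:
    """Featurize triplets, reusing one contact graph per protein pair."""
    graph_cache: dict[tuple[str, str], object] = {}
    examples = []
    for pair in pairs:
        key = (pair.interactor_id, pair.partner_id)
        if key not in structures:
            raise DataError(f"no structure for pair {key}")
        if key not in graph_cache:
            graph_cache[key] = build_contact_graph(structures[key], threshold)
        examples.append(
            featurize_pair(pair, structures[key], embedder, threshold,
                           graph=graph_cache[key])
        )
    return examples


def featurize_stability(
    records,
    chains: dict[str, object],
    embedder,
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
) -> list[TrainingExample]:
    """Monomer examples for stability pretraining.

    Records whose |ΔΔG| falls between the class thresholds carry no label
    and are dropped here (they are excluded from pretraining).
    """
    graph_cache: dict[str, object] = {}
    examples = []
    for rec in records:
        if rec.label is None:
            continue
        if rec.sequence is None:
            raise DataError(f"record {rec.key} lacks a sequence")
        if rec.protein_id not in chains:
            raise DataError(f"no structure for protein {rec.protein_id}")
        if rec.protein_id not in graph_cache:
            graph_cache[rec.protein_id] = build_monomer_graph(
                chains[rec.protein_id], threshold
            )
        graph = graph_cache[rec.protein_id]
        wt_emb = embedder.embed(rec.sequence)
        mut_seq = apply_mutation(rec.sequence, rec.mutation)
        mut_emb = embedder.embed(mut_seq)
        x = build_node_features(graph, mut_emb)
        raw = encode_mutation_raw(wt_emb, mut_emb, rec.mutation.position)
        examples.append(
            TrainingExample(
                graph=graph,
                node_features=x,
                raw_encoding=raw,
                mutation_node=rec.mutation.position - 1,
                label=rec.label,
                record=rec,
            )
        )
    if not examples:
        raise DataError("no labeled stability examples after exclusion")
    return examples


def flip_pair(pair: VariantPartnerPair) -> VariantPartnerPair:
    """Swap interactor and partner (for variants on the partner protein)."""
    return VariantPartnerPair(
        interactor_id=pair.partner_id,
        mutation=pair.mutation,
        partner_id=pair.interactor_id,
        label=pair.label,
        source=pair.source,
        interactor_seq=pair.partner_seq,
        partner_seq=pair.interactor_seq,
        structure_failed=pair.structure_failed,
    )
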