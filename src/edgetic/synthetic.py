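"""Deterministic synthetic data with planted signal for every pipeline input.

The generators produce toy two-chain complexes with a designed interface,
monomeric lattice proteins with a buried core, labeled variant-partner
triplets (interface variants disrupt), stability records (buried variants
destabilize) and simulated edgotype scenarios with planted quasi-null and
edgetic rates. Everything is bit-reproducible under a fixed seed, so model
training, leakage-aware evaluation and enrichment statistics can be tested
end to end without any external data.

Geometry: chains are jittered straight-chain lattices (Cα every 3.8 Å plus
one pseudo side-chain atom per residue). Interface patch residues occupy
every other position around the chain midpoint and their side-chain atoms
reach across the chain gap to 4.0 Å — inside the 4.5 Å contact rule — while
every non-designed inter-chain atom pair stays beyond 6 Å, so the planted
interface is unambiguous.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import (
    StabilityRecord,
    VariantPartnerPair,
    write_stability,
    write_triplets,
)
from .edgotype import EDGETIC, QUASI_NULL, QUASI_WILD_TYPE, VariantProfile
from .errors import SpecError
from .features import AMINO_ACIDS, MutationSpec, write_fasta
from .structure import ChainStructure, ComplexStructure, Residue, write_pdb

_CA_SPACING = 3.8
_CHAIN_GAP = 10.0       # Cα-to-Cα separation of the two chains
_PATCH_REACH = 3.0      # patch side-chain y offset toward the other chain
_AWAY_OFFSET = -1.0     # non-patch side chains point away
_JITTER = 0.05


@dataclass
class SynthComplexSpec:
    n_interactor: int
    n_partner: int
    patch_size: int
    seed: int = 0

    def patch_indices(self) -> list[int]:
        """0-based residue indices (same on both chains) forming the interface."""
        if self.patch_size == 0:
            return []
        span = 2 * self.patch_size - 1
        shorter = min(self.n_interactor, self.n_partner)
        if span > shorter:
            raise SpecError(
                f"patch of {self.patch_size} needs {span} positions, "
                f"chain has {shorter}"
            )
        start = (shorter - span) // 2
        return [start + 2 * i for i in range(self.patch_size)]


@dataclass
class PlantedRule:
    kind: str = "interface-disrupts"   # or "buried-disrupts"
    noise: float = 0.0                 # label-noise rate ε
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.noise < 0.5:
            raise SpecError("label noise must be in [0, 0.5)")


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _build_chain(chain_id: str, sequence: str, patch: set[int],
                 y_ca: float, toward: float, rng: np.random.Generator) -> ChainStructure:
    residues = []
    for j, aa in enumerate(sequence):
        if j in patch:
            y_cb = y_ca + toward * _PATCH_REACH
        else:
            y_cb = y_ca + toward * _AWAY_OFFSET
        coords = np.array(
            [
                [_CA_SPACING * j, y_ca, 0.0],
                [_CA_SPACING * j, y_cb, 0.0],
            ]
        )
        coords = coords + rng.uniform(-_JITTER, _JITTER, size=coords.shape)
        residues.append(
            Residue(position=j + 1, amino_acid=aa, elements=["C", "C"],
                    coords=coords)
        )
    return ChainStructure(chain_id=chain_id, residues=residues)


def generate_complex(
    spec: SynthComplexSpec,
    interactor_seq: str | None = None,
    partner_seq: str | None = None,
) -> ComplexStructure:
    """Two-chain toy complex whose interface is exactly the designed patch."""
    rng = np.random.default_rng(spec.seed)
    if interactor_seq is None:
        interactor_seq = _random_sequence(spec.n_interactor, rng)
    if partner_seq is None:
        partner_seq = _random_sequence(spec.n_partner, rng)
    if len(interactor_seq) != spec.n_interactor or len(partner_seq) != spec.n_partner:
        raise SpecError("sequence lengths disagree with the spec")
    patch = set(spec.patch_indices())
    interactor = _build_chain("A", interactor_seq, patch, 0.0, +1.0, rng)
    partner = _build_chain("B", partner_seq, patch, _CHAIN_GAP, -1.0, rng)
    return ComplexStructure(interactor=interactor, partner=partner,
                            source_tag=f"synthetic:seed={spec.seed}")


# ---------------------------------------------------------------------------
# PPI perturbation dataset with a planted interface-disrupts rule

def _mutate_sequence(seq: str, fraction: float, rng: np.random.Generator) -> str:
    n = max(1, int(fraction * len(seq)))
    positions = rng.choice(len(seq), size=n, replace=False)
    chars = list(seq)
    for pos in positions:
        choices = [a for a in AMINO_ACIDS if a != chars[pos]]
        chars[pos] = choices[rng.integers(len(choices))]
    return "".join(chars)


def generate_ppi_dataset(
    n_pairs: int = 40,
    variants_per_pair: int = 10,
    rule: PlantedRule | None = None,
    chain_length: int = 20,
    patch_size: int = 4,
    clones_per_family: int = 2,
    far_margin: int = 3,
):
    """Labeled triplets over synthetic complexes, with family structure.

    Half of each pair's variants sit on interface-patch positions of the
    interactor, half at least ``far_margin`` positions away from any patch
    residue. Under the interface-disrupts rule the label is disruptive iff
    the variant is at the interface, XOR a noise flip with probability ε.
    Protein pairs come in families of near-identical clones (≤10% sequence
    divergence) so that sequence clustering and group CV are exercised.

    Returns (pairs, structures, sequences) where structures maps
    (interactor_id, partner_id) to a :class:`ComplexStructure`.
    """
    rule = rule or PlantedRule()
    if rule.kind != "interface-disrupts":
        raise SpecError("PPI generator implements the interface-disrupts rule")
    rng = np.random.default_rng(rule.seed)
    n_families = math.ceil(n_pairs / clones_per_family)
    spec_proto = SynthComplexSpec(chain_length, chain_length, patch_size)
    patch = spec_proto.patch_indices()
    patch_set = set(patch)
    far_positions = [
        j for j in range(chain_length)
        if all(abs(j - p) >= far_margin for p in patch_set)
    ]
    if not far_positions:
        raise SpecError("chain too short to place non-interface variants")

    pairs: list[VariantPartnerPair] = []
    structures: dict[tuple[str, str], ComplexStructure] = {}
    sequences: dict[str, str] = {}
    made = 0
    for fam in range(n_families):
        base_i = _random_sequence(chain_length, rng)
        base_p = _random_sequence(chain_length, rng)
        for clone in range(clones_per_family):
            if made >= n_pairs:
                break
            made += 1
            seq_i = base_i if clone == 0 else _mutate_sequence(base_i, 0.08, rng)
            seq_p = base_p if clone == 0 else _mutate_sequence(base_p, 0.08, rng)
            iid, pid = f"I{fam:03d}c{clone}", f"P{fam:03d}c{clone}"
            sequences[iid], sequences[pid] = seq_i, seq_p
            spec = SynthComplexSpec(
                chain_length, chain_length, patch_size,
                seed=int(rng.integers(2**31)),
            )
            structures[(iid, pid)] = generate_complex(spec, seq_i, seq_p)
            n_iface = variants_per_pair // 2
            sites = [
                (int(patch[rng.integers(len(patch))]), True)
                for _ in range(n_iface)
            ] + [
                (int(far_positions[rng.integers(len(far_positions))]), False)
                for _ in range(variants_per_pair - n_iface)
            ]
            for site, at_interface in sites:
                wt = seq_i[site]
                mut = [a for a in AMINO_ACIDS if a != wt][rng.integers(19)]
                disruptive = at_interface
                if rng.random() < rule.noise:
                    disruptive = not disruptive
                pairs.append(
                    VariantPartnerPair(
                        interactor_id=iid,
                        mutation=MutationSpec(site + 1, wt, mut, protein_id=iid),
                        partner_id=pid,
                        label=int(disruptive),
                        source=f"synthetic:{'interface' if at_interface else 'far'}",
                        interactor_seq=seq_i,
                        partner_seq=seq_p,
                    )
                )
    return pairs, structures, sequences


# ---------------------------------------------------------------------------
# stability dataset with a planted buried-disrupts rule

def _lattice_chain(protein_id: str, sequence: str, box: tuple[int, int, int],
                   rng: np.random.Generator) -> tuple[ChainStructure, list[bool]]:
    nx, ny, nz = box
    sites = [(x, y, z) for z in range(nz) for y in range(ny) for x in range(nx)]
    sites = sites[: len(sequence)]
    occupied = set(sites)
    buried = []
    residues = []
    for j, ((x, y, z), aa) in enumerate(zip(sites, sequence)):
        neighbors = [
            (x + dx, y + dy, z + dz)
            for dx, dy, dz in
            [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
        ]
        buried.append(all(nb in occupied for nb in neighbors))
        coords = 4.0 * np.array([[x, y, z]], dtype=float)
        coords = coords + rng.uniform(-_JITTER, _JITTER, size=coords.shape)
        residues.append(
            Residue(position=j + 1, amino_acid=aa, elements=["C"], coords=coords)
        )
    return ChainStructure(chain_id="A", residues=residues), buried


def generate_stability_dataset(
    n_proteins: int = 20,
    variants_per_protein: int = 16,
    rule: PlantedRule | None = None,
    box: tuple[int, int, int] = (4, 4, 4),
):
    """Monomer lattice proteins with ΔΔG planted on burial.

    Buried-core variants receive |ΔΔG| drawn in [1.5, 4.0] kcal/mol and
    surface variants in [0, 0.5); with probability ε the ranges are swapped
    (label noise). Returns (records, chains, sequences).
    """
    rule = rule or PlantedRule(kind="buried-disrupts")
    if rule.kind != "buried-disrupts":
        raise SpecError("stability generator implements the buried-disrupts rule")
    rng = np.random.default_rng(rule.seed)
    length = box[0] * box[1] * box[2]
    records: list[StabilityRecord] = []
    chains: dict[str, ChainStructure] = {}
    sequences: dict[str, str] = {}
    for n in range(n_proteins):
        pid = f"M{n:03d}"
        seq = _random_sequence(length, rng)
        chain, buried = _lattice_chain(pid, seq, box, rng)
        chains[pid], sequences[pid] = chain, seq
        buried_sites = [j for j, b in enumerate(buried) if b]
        surface_sites = [j for j, b in enumerate(buried) if not b]
        half = variants_per_protein // 2
        picks = [
            (int(buried_sites[rng.integers(len(buried_sites))]), True)
            for _ in range(half)
        ] + [
            (int(surface_sites[rng.integers(len(surface_sites))]), False)
            for _ in range(variants_per_protein - half)
        ]
        for site, is_buried in picks:
            wt = seq[site]
            mut = [a for a in AMINO_ACIDS if a != wt][rng.integers(19)]
            destabilizing = is_buried
            if rng.random() < rule.noise:
                destabilizing = not destabilizing
            mag = (
                rng.uniform(1.5, 4.0) if destabilizing else rng.uniform(0.0, 0.4999)
            )
            sign = 1.0 if rng.random() < 0.8 else -1.0
            records.append(
                StabilityRecord(
                    protein_id=pid,
                    mutation=MutationSpec(site + 1, wt, mut, protein_id=pid),
                    ddg=float(sign * mag),
                    sequence=seq,
                )
            )
    return records, chains, sequences


# ---------------------------------------------------------------------------
# edgotype scenarios

@dataclass
class EdgotypeScenario:
    """Planted per-stratum edgotype rates (quasi-null, edgetic)."""

    strata: dict[str, tuple[float, float]]   # name -> (quasi-null, edgetic)
    n_variants: int = 200
    partner_range: tuple[int, int] = (3, 8)  # inclusive bounds
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (qn, ed) in self.strata.items():
            if qn < 0 or ed < 0 or qn + ed > 1:
                raise SpecError(f"stratum {name}: rates must be in [0,1] and sum <= 1")


def generate_edgotype_scenario(
    scenario: EdgotypeScenario,
) -> dict[str, list[VariantProfile]]:
    """Draw variant profiles whose edgotype follows the planted rates.

    Per variant an edgotype is drawn from the stratum's categorical rates,
    then partner probabilities consistent with it: all < 0.5 for
    quasi-wild-type, all ≥ 0.5 for quasi-null, at least one of each for
    edgetic (which forces ≥2 partners).
    """
    rng = np.random.default_rng(scenario.seed)
    lo, hi = scenario.partner_range
    out: dict[str, list[VariantProfile]] = {}
    for name in sorted(scenario.strata):
        qn, ed = scenario.strata[name]
        profiles = []
        for v in range(scenario.n_variants):
            u = rng.random()
            if u < qn:
                edgotype = QUASI_NULL
            elif u < qn + ed:
                edgotype = EDGETIC
            else:
                edgotype = QUASI_WILD_TYPE
            m = int(rng.integers(lo, hi + 1))
            if edgotype == EDGETIC and m < 2:
                m = 2
            if edgotype == QUASI_NULL:
                probs = rng.uniform(0.55, 0.95, size=m)
            elif edgotype == QUASI_WILD_TYPE:
                probs = rng.uniform(0.05, 0.45, size=m)
            else:
                n_pert = int(rng.integers(1, m))
                probs = np.concatenate(
                    [rng.uniform(0.55, 0.95, size=n_pert),
                     rng.uniform(0.05, 0.45, size=m - n_pert)]
                )
                rng.shuffle(probs)
            profiles.append(
                VariantProfile(
                    variant_key=(name, f"v{v:05d}"),
                    partner_probs=[(f"p{j}", float(p)) for j, p in enumerate(probs)],
                    available_partner_count=m,
                )
            )
        out[name] = profiles
    return out


# ---------------------------------------------------------------------------
# fixture workspace

def write_fixture_workspace(
    outdir: str | Path,
    seed: int = 0,
    n_pairs: int = 12,
    variants_per_pair: int = 6,
    n_proteins: int = 6,
    variants_per_protein: int = 10,
    noise: float = 0.05,
) -> dict:
    """Emit a complete small workspace: structures, FASTA, TSVs, scenario.

    Layout: ``complexes/<iid>__<pid>.pdb`` (chains A/B), ``monomers/<pid>.pdb``,
    ``sequences.fasta``, ``triplets.tsv``, ``stability.tsv``, and the three
    edgotype-scenario tables. Returns the manifest that is also written to
    ``manifest.json``.
    """
    outdir = Path(outdir)
    (outdir / "complexes").mkdir(parents=True, exist_ok=True)
    (outdir / "monomers").mkdir(parents=True, exist_ok=True)

    pairs, structures, sequences = generate_ppi_dataset(
        n_pairs=n_pairs, variants_per_pair=variants_per_pair,
        rule=PlantedRule("interface-disrupts", noise=noise, seed=seed),
    )
    for (iid, pid), cplx in structures.items():
        write_pdb([cplx.interactor, cplx.partner],
                  outdir / "complexes" / f"{iid}__{pid}.pdb")
    write_triplets(outdir / "triplets.tsv", pairs)

    records, chains, mono_seqs = generate_stability_dataset(
        n_proteins=n_proteins, variants_per_protein=variants_per_protein,
        rule=PlantedRule("buried-disrupts", noise=noise, seed=seed + 1),
    )
    for pid, chain in chains.items():
        write_pdb([chain], outdir / "monomers" / f"{pid}.pdb")
    write_stability(outdir / "stability.tsv", records)

    sequences.update(mono_seqs)
    write_fasta(outdir / "sequences.fasta", sequences)

    scenario = EdgotypeScenario(
        strata={"baseline": (0.1, 0.2), "disease": (0.45, 0.3)},
        n_variants=150, seed=seed + 2,
    )
    strata = generate_edgotype_scenario(scenario)
    pred_rows, strata_rows, count_rows = [], [], []
    for name, profiles in strata.items():
        for profile in profiles:
            interactor, variant = profile.variant_key
            strata_rows.append(
                {"interactor_id": interactor, "variant": variant, "stratum": name}
            )
            count_rows.append(
                {"interactor_id": interactor, "variant": variant,
                 "available_partners": profile.available_partner_count}
            )
            for partner, prob in profile.partner_probs:
                pred_rows.append(
                    {"interactor_id": interactor, "variant": variant,
                     "partner_id": partner, "probability": f"{prob:.6f}"}
                )
    pd.DataFrame(pred_rows).to_csv(outdir / "scenario_predictions.tsv",
                                   sep="\t", index=False)
    pd.DataFrame(strata_rows).to_csv(outdir / "scenario_strata.tsv",
                                     sep="\t", index=False)
    pd.DataFrame(count_rows).to_csv(outdir / "scenario_partner_counts.tsv",
                                    sep="\t", index=False)

    manifest = {
        "seed": seed,
        "n_triplets": len(pairs),
        "n_complexes": len(structures),
        "n_stability_records": len(records),
        "n_monomers": len(chains),
        "scenario_strata": {k: len(v) for k, v in strata.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
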