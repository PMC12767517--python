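"""Variant–partner triplets, stability records, labeling and cleaning.

Two record kinds feed the two training stages:

* :class:`StabilityRecord` — a missense variant in a monomeric protein with a
  measured folding free-energy change ΔΔG (kcal/mol). Variants are labeled
  stability-preserving when |ΔΔG| < 0.5 and stability-disrupting when
  |ΔΔG| ≥ 1.5; intermediate variants are excluded from pretraining.
* :class:`VariantPartnerPair` — the triplet (interactor, variant, partner)
  with an optional binary disruption label; the unit of fine-tuning and
  evaluation.

Cleaning removes exact duplicates, identity keys with conflicting labels
(removed entirely, regardless of source), and records flagged as having
failed structure generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import DataError, SchemaError
from .features import MutationSpec, apply_mutation

PRESERVING = "preserving"
DISRUPTING = "disrupting"
EXCLUDED = "excluded"

DISRUPTIVE = "disruptive"
NON_DISRUPTIVE = "non-disruptive"

# |ΔΔG| thresholds (kcal/mol) bounding the stability classes
STABILITY_PRESERVING_MAX = 0.5
STABILITY_DISRUPTING_MIN = 1.5


@dataclass
class VariantPartnerPair:
    interactor_id: str
    mutation: MutationSpec
    partner_id: str
    label: int | None = None  # 1 = disruptive, 0 = non-disruptive
    source: str = ""
    interactor_seq: str | None = None
    partner_seq: str | None = None
    structure_failed: bool = False

    @property
    def key(self) -> tuple:
        """Identity key used for duplicate/conflict detection."""
        m = self.mutation
        return (self.interactor_id, m.wt_aa, m.position, m.mut_aa, self.partner_id)

    @property
    def variant_key(self) -> tuple:
        """Variant identity irrespective of partner (blind-test exclusion)."""
        m = self.mutation
        return (self.interactor_id, m.wt_aa, m.position, m.mut_aa)

    def validate_sequences(self) -> None:
        if self.interactor_seq is not None:
            apply_mutation(self.interactor_seq, self.mutation)


@dataclass
class StabilityRecord:
    protein_id: str
    mutation: MutationSpec
    ddg: float  # kcal/mol, signed
    sequence: str | None = None
    structure_failed: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.ddg):
            raise ValueError("ddG must be finite")

    @property
    def key(self) -> tuple:
        m = self.mutation
        return (self.protein_id, m.wt_aa, m.position, m.mut_aa)

    @property
    def label(self) -> int | None:
        cls = label_stability(self.ddg)
        if cls == EXCLUDED:
            return None
        return 1 if cls == DISRUPTING else 0


def label_stability(ddg: float) -> str:
    """Discretize ΔΔG into stability classes by its absolute value.

    |ΔΔG| < 0.5 → preserving; |ΔΔG| ≥ 1.5 → disrupting (boundary inclusive);
    anything between is excluded from pretraining.
    """
    if not math.isfinite(ddg):
        raise ValueError("ddG must be finite")
    mag = abs(ddg)
    if mag < STABILITY_PRESERVING_MAX:
        return PRESERVING
    if mag >= STABILITY_DISRUPTING_MIN:
        return DISRUPTING
    return EXCLUDED


@dataclass
class Dataset:
    records: list
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def label_counts(self) -> dict:
        counts: dict = {}
        for rec in self.records:
            counts[rec.label] = counts.get(rec.label, 0) + 1
        return counts


def clean_dataset(records, provenance: str = "") -> tuple[Dataset, dict]:
    """Deduplicate, drop conflicting identity keys and failed structures.

    Returns the cleaned dataset and a removal report with counts for every
    category. ``conflicts`` counts identity keys, ``conflict_records`` the
    records they covered; the conservation law is
    ``input = kept + duplicates + conflict_records + structure_failed``.
    """
    import warnings

    report = {
        "input": len(records),
        "kept": 0,
        "duplicates": 0,
        "conflicts": 0,
        "conflict_records": 0,
        "structure_failed": 0,
    }
    survivors = []
    for rec in records:
        if rec.structure_failed:
            report["structure_failed"] += 1
        else:
            survivors.append(rec)

    by_key: dict[tuple, list] = {}
    for rec in survivors:
        by_key.setdefault(rec.key, []).append(rec)

    kept = []
    for key, group in by_key.items():
        labels = {rec.label for rec in group}
        if len(labels) > 1:
            report["conflicts"] += 1
            report["conflict_records"] += len(group)
            continue
        kept.append(group[0])
        report["duplicates"] += len(group) - 1
    report["kept"] = len(kept)
    if not kept:
        warnings.warn("cleaning removed every record", stacklevel=2)
    return Dataset(records=kept, provenance=provenance), report


# ---------------------------------------------------------------------------
# TSV I/O

TRIPLET_COLUMNS = ["interactor_id", "variant", "partner_id", "label", "source"]
STABILITY_COLUMNS = ["protein_id", "variant", "ddg"]

_LABEL_MAP = {
    DISRUPTIVE: 1,
    NON_DISRUPTIVE: 0,
    "1": 1,
    "0": 0,
    "": None,
}


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error variety
        raise SchemaError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df

def read_triplets(path: str | Path) -> list[VariantPartnerPair]:
    """Read variant-partner triplets from TSV.

    Columns: interactor_id, variant (e.g. ``p.C61G`` or ``C61G``),
    partner_id, label (``disruptive``/``non-disruptive``/1/0/empty), source.
    Optional column ``structure_failed`` (0/1).
    """
    df = _read_tsv(path, ["interactor_id", "variant", "partner_id"])
    records = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            mutation = MutationSpec.parse(d["variant"], protein_id=d["interactor_id"])
        except ValueError as exc:
            raise SchemaError(f"{path}, line {line_no}: {exc}") from exc
        raw_label = d.get("label", "").strip().lower()
        if raw_label not in _LABEL_MAP:
            raise SchemaError(
                f"{path}, line {line_no}: unknown label {raw_label!r}"
            )
        records.append(
            VariantPartnerPair(
                interactor_id=d["interactor_id"],
                mutation=mutation,
                partner_id=d["partner_id"],
                label=_LABEL_MAP[raw_label],
                source=d.get("source", ""),
                structure_failed=d.get("structure_failed", "0") in ("1", "true"),
            )
        )
    return records


def read_stability(path: str | Path) -> list[StabilityRecord]:
    """Read stability records (protein_id, variant, ddg in kcal/mol)."""
    df = _read_tsv(path, STABILITY_COLUMNS)
    records = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            mutation = MutationSpec.parse(d["variant"], protein_id=d["protein_id"])
            ddg = float(d["ddg"])
        except ValueError as exc:
            raise SchemaError(f"{path}, line {line_no}: {exc}") from exc
        records.append(
            StabilityRecord(
                protein_id=d["protein_id"],
                mutation=mutation,
                ddg=ddg,
                structure_failed=d.get("structure_failed", "0") in ("1", "true"),
            )
        )
    return records


def write_triplets(path: str | Path, records: list[VariantPartnerPair]) -> None:
    rows = []
    for rec in records:
        label = "" if rec.label is None else (DISRUPTIVE if rec.label else NON_DISRUPTIVE)
        rows.append(
            {
                "interactor_id": rec.interactor_id,
                "variant": rec.mutation.short(),
                "partner_id": rec.partner_id,
                "label": label,
                "source": rec.source,
            }
        )
    pd.DataFrame(rows, columns=TRIPLET_COLUMNS).to_csv(path, sep="\t", index=False)


def write_stability(path: str | Path, records: list[StabilityRecord]) -> None:
    rows = [
        {
            "protein_id": rec.protein_id,
            "variant": rec.mutation.short(),
            "ddg": f"{rec.ddg:.4f}",
        }
        for rec in records
    ]
    pd.DataFrame(rows, columns=STABILITY_COLUMNS).to_csv(path, sep="\t", index=False)


def attach_sequences(records, sequences: dict[str, str]) -> None:
    """Attach wild-type sequences by protein id and validate variants."""
    for rec in records:
        if isinstance(rec, VariantPartnerPair):
            if rec.interactor_id not in sequences:
                raise DataError(f"no sequence for interactor {rec.interactor_id}")
            if rec.partner_id not in sequences:
                raise DataError(f"no sequence for partner {rec.partner_id}")
            rec.interactor_seq = sequences[rec.interactor_id]
            rec.partner_seq = sequences[rec.partner_id]
            rec.validate_sequences()
        else:
            if rec.protein_id not in sequences:
                raise DataError(f"no sequence for protein {rec.protein_id}")
            rec.sequence = sequences[rec.protein_id]
            apply_mutation(rec.sequence, rec.mutation)
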