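"""Subfamily assignment and per-organism repertoires.

A query protein is assigned to one of the eleven CPF subfamilies by the
subfamily of its nearest reference (Jukes-Cantor distance after global
alignment), cross-checked against its motif profile: a candidate whose own
diagnostic motifs are entirely absent while another subfamily's motifs are
well supported is demoted to "unassigned" (the analogue of tree branches
that cannot be assigned cleanly).  Assignments aggregate into a binary
organism x subfamily repertoire matrix.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import motifkit, phylokit
from .motifkit import MotifPattern
from .seqio import ProteinRecord

logger = logging.getLogger(__name__)

#: The eleven CPF subfamily labels.
SUBFAMILIES = (
    "6-4 PL",
    "CPDI",
    "CPDII",
    "CPDIII",
    "PPL",
    "DASH",
    "MCRY",
    "DCRY",
    "ACRY",
    "PCRY",
    "PCRY-like",
)

UNASSIGNED = "unassigned"


@dataclass
class ReferencePanel:
    """One curated reference protein per CPF subfamily."""

    members: list[tuple[str, ProteinRecord]]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("reference panel is empty")
        labels = [label for label, _ in self.members]
        if len(set(labels)) != len(labels):
            raise ValueError("a subfamily appears more than once in the panel")
        unknown = set(labels) - set(SUBFAMILIES)
        if unknown:
            raise ValueError(f"unknown subfamily labels in panel: {sorted(unknown)}")

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.members]

    def label_of(self, reference_id: str) -> str:
        for label, rec in self.members:
            if rec.id == reference_id:
                return label
        raise KeyError(reference_id)

    def records(self) -> list[ProteinRecord]:
        return [rec for _, rec in self.members]

    @classmethod
    def from_files(cls, table_path: str | Path, fasta_path: str | Path) -> "ReferencePanel":
        """Load a panel from a TSV (columns: type, species, name, accession)
        plus a FASTA keyed by accession."""
        from .seqio import read_fasta

        by_id = {r.id: r for r in read_fasta(fasta_path)}
        members = []
        with open(table_path) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                acc = row["accession"]
                if acc not in by_id:
                    raise ValueError(f"panel accession {acc!r} missing from FASTA")
                rec = by_id[acc]
                rec.organism = rec.organism or row.get("species", "")
                members.append((row["type"], rec))
        return cls(members)


@dataclass
class SubfamilyAssignment:
    """Per-sequence subfamily call with its supporting evidence."""

    sequence_id: str
    label: str
    organism: str = ""
    mcry_subtype: str | None = None
    nearest_ref: str = ""
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mcry_subtype is not None and self.label != "MCRY":
            raise ValueError("mcry_subtype only applies to MCRY assignments")


def _motif_support(
    query: ProteinRecord, library: Sequence[MotifPattern]
) -> dict[str, float]:
    """Per-subfamily fraction of that subfamily's motifs hitting the query."""
    by_subfamily: dict[str, list[MotifPattern]] = {}
    for m in library:
        by_subfamily.setdefault(m.subfamily, []).append(m)
    support = {}
    for subfamily, motifs in by_subfamily.items():
        n_hit = sum(1 for m in motifs if motifkit.scan_sequence(query, m))
        support[subfamily] = n_hit / len(motifs)
    return support


def assign_subfamily(
    query: ProteinRecord,
    panel: ReferencePanel,
    library: Sequence[MotifPattern],
    margin: float = 0.05,
    tree_check: bool = False,
    **align_kw,
) -> SubfamilyAssignment:
    """Assign a query to a CPF subfamily.

    The candidate label is the subfamily of the nearest reference.  If the
    candidate's own motifs are entirely absent while some other subfamily
    reaches motif support >= 0.5, the call is demoted to "unassigned" with
    the conflict flag set.  If the second-nearest reference disagrees and
    lies within the relative *margin* of the nearest distance, the candidate
    is kept but flagged.  With *tree_check*, an NJ tree of panel plus query
    is built and a disagreeing nearest tree neighbor also sets the flag.
    """
    if not library:
        raise ValueError("motif library is empty")
    ranked = phylokit.nearest_reference(query, panel.records(), **align_kw)
    nearest_id, nearest_d = ranked[0]
    candidate = panel.label_of(nearest_id)
    second_d = ranked[1][1] if len(ranked) > 1 else float("inf")
    second_label = panel.label_of(ranked[1][0]) if len(ranked) > 1 else None

    support = _motif_support(query, library)
    candidate_support = support.get(candidate, 0.0)
    best_other = max(
        (v for k, v in support.items() if k != candidate), default=0.0
    )

    conflict = False
    label = candidate
    if candidate_support == 0.0 and best_other >= 0.5:
        label = UNASSIGNED
        conflict = True
    elif (
        second_label is not None
        and second_label != candidate
        and (second_d - nearest_d) / max(nearest_d, 1e-12) < margin
    ):
        conflict = True

    if tree_check and label != UNASSIGNED:
        agreement = _tree_check(query, panel, **align_kw)
        if agreement is not None and agreement != candidate:
            conflict = True

    return SubfamilyAssignment(
        sequence_id=query.id,
        label=label,
        organism=query.organism,
        nearest_ref=nearest_id,
        evidence={
            "nearest_distance": nearest_d,
            "second_distance": second_d,
            "motif_support": candidate_support,
            "conflict_flag": conflict,
        },
    )


def _tree_check(query: ProteinRecord, panel: ReferencePanel, **align_kw) -> str | None:
    """Subfamily of the query's nearest leaf in an NJ tree of panel+query."""
    records = panel.records() + [query]
    dm = phylokit.distance_matrix(records, **align_kw)
    tree = phylokit.nj_tree(dm)
    paths = phylokit.tree_distance_matrix(tree)
    others = [(paths[query.id, rec.id], rec.id) for rec in panel.records()]
    others.sort()
    return panel.label_of(others[0][1])


def assign_all(
    records: Iterable[ProteinRecord],
    panel: ReferencePanel,
    library: Sequence[MotifPattern],
    margin: float = 0.05,
    tree_check: bool = False,
    **align_kw,
) -> list[SubfamilyAssignment]:
    return [
        assign_subfamily(r, panel, library, margin, tree_check, **align_kw)
        for r in records
    ]


def assign_mcry_subtype(
    query: ProteinRecord,
    subtype_motifs: Mapping[str, Sequence[MotifPattern]],
) -> str:
    """Subtype an MCRY query as "st", "MCRY1" or "MCRY2".

    The subtype with the highest motif support wins; ties or no support at
    all fall back to the standard type "st".  Subtype patterns are
    data-driven (supplied by the user or a fixture).
    """
    if not subtype_motifs:
        logger.warning("no MCRY subtype motifs supplied; defaulting to 'st'")
        return "st"
    support = {}
    for subtype, motifs in subtype_motifs.items():
        if not motifs:
            support[subtype] = 0.0
            continue
        n_hit = sum(1 for m in motifs if motifkit.scan_sequence(query, m))
        support[subtype] = n_hit / len(motifs)
    best = max(support.values())
    if best == 0.0:
        return "st"
    winners = [s for s, v in support.items() if v == best]
    return winners[0] if len(winners) == 1 else "st"


@dataclass
class RepertoireMatrix:
    """Binary organism x (subfamily + "other") presence matrix with lineages."""

    presence: pd.DataFrame  # index: organism; columns: SUBFAMILIES + ("other",)
    taxonomy: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        expected = list(SUBFAMILIES) + ["other"]
        if list(self.presence.columns) != expected:
            raise ValueError("repertoire columns must be the 11 subfamilies + 'other'")
        if not self.presence.isin([0, 1]).all().all():
            raise ValueError("repertoire cells must be binary")


def build_repertoire(
    assignments: Iterable[SubfamilyAssignment],
    taxonomy: Mapping[str, Mapping[str, str]],
) -> RepertoireMatrix:
    """Aggregate assignments into a binary organism x subfamily matrix.

    An organism possesses a subfamily iff at least one of its sequences
    carries that label; unassigned sequences are tracked in an "other"
    column.
    """
    columns = list(SUBFAMILIES) + ["other"]
    rows: dict[str, dict[str, int]] = {}
    for a in assignments:
        org = a.organism
        if org not in taxonomy:
            raise ValueError(f"organism {org!r} missing from taxonomy")
        row = rows.setdefault(org, {c: 0 for c in columns})
        col = a.label if a.label in SUBFAMILIES else "other"
        row[col] = 1
    presence = pd.DataFrame.from_dict(rows, orient="index", columns=columns).astype(int)
    tax = {org: dict(taxonomy[org]) for org in presence.index}
    return RepertoireMatrix(presence=presence, taxonomy=tax)


def write_assignments(assignments: Iterable[SubfamilyAssignment], path: str | Path) -> None:
    rows = []
    for a in assignments:
        rows.append(
            {
                "sequence_id": a.sequence_id,
                "label": a.label,
                "mcry_subtype": a.mcry_subtype or "",
                "nearest_ref": a.nearest_ref,
                "nearest_dist": a.evidence.get("nearest_distance", ""),
                "motif_support": a.evidence.get("motif_support", ""),
                "conflict": int(bool(a.evidence.get("conflict_flag", False))),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
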