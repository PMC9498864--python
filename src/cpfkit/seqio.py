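"""Sequence and table I/O plus homology-hit curation rules.

Reads protein FASTA, 12-column tabular homology-search hit tables and
ranked-lineage taxonomy tables, and implements the three curation steps
applied to raw homology hits before tree building: an e-value cutoff,
removal of duplicate sequences within an organism, and per-order /
per-family subsampling of organisms so that heavily sequenced taxa do not
dominate the tree.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .util import RANKS, SEQUENCE_ALPHABET

#: Columns of the standard 12-column tabular homology-search output.
HIT_TABLE_COLUMNS = (
    "query_id",
    "subject_id",
    "pident",
    "length",
    "mismatches",
    "gapopens",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)

#: Ambiguity letters reserved for motif patterns; rejected in sequences.
_RESERVED = frozenset("BJZ")

_HEADER_RE = re.compile(r"^(?P<id>\S+)(?:\s+\[(?P<organism>[^\]]+)\])?\s*$")


@dataclass
class ProteinRecord:
    """One amino-acid sequence with organism and lineage metadata.

    ``residues`` is an uppercase string over the 20 standard letters plus X
    (unknown residue).  The ambiguity codes B/J/Z are reserved for motif
    patterns and are rejected here so that pattern semantics stay
    unambiguous.
    """

    id: str
    residues: str
    organism: str = ""
    lineage: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.residues):
            if ch not in SEQUENCE_ALPHABET:
                raise ValueError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(
    path: str | Path,
    taxonomy: Mapping[str, Mapping[str, str]] | None = None,
) -> list[ProteinRecord]:
    """Read protein records from FASTA, preserving file order.

    Headers follow the ``>id [organism]`` convention; a bare ``>id`` is
    allowed, with the organism (and lineage) resolved from *taxonomy* when
    provided.  Residues are uppercased and ``*`` stop symbols stripped.
    Raises ``ValueError`` for malformed headers or illegal residue letters,
    naming the offending record and position.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        m = _HEADER_RE.match(rec.description)
        if not rec.id or m is None:
            raise ValueError(f"malformed FASTA header for entry {i + 1}: {rec.description!r}")
        organism = m.group("organism") or ""
        residues = str(rec.seq).upper().replace("*", "")
        lineage: dict[str, str] = {}
        if taxonomy is not None and organism in taxonomy:
            lineage = dict(taxonomy[organism])
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            ProteinRecord(id=rec.id, residues=residues, organism=organism, lineage=lineage)
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA with ``>id [organism]`` headers."""
    out = []
    for r in records:
        description = f"[{r.organism}]" if r.organism else ""
        out.append(SeqRecord(Seq(r.residues), id=r.id, description=description))
    SeqIO.write(out, str(path), "fasta-2line")


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read a 12-column tab-separated homology hit table.

    Columns are named per :data:`HIT_TABLE_COLUMNS`; e-values are validated
    to be non-negative.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=HIT_TABLE_COLUMNS, comment="#")
    if (df["evalue"] < 0).any():
        bad = df.index[df["evalue"] < 0][0]
        raise ValueError(f"negative e-value in hit table at row {bad}")
    return df


def filter_by_evalue(rows: pd.DataFrame, threshold: float = 1e-15) -> pd.DataFrame:
    """Keep only hits with e-value strictly below *threshold*.

    The comparison is strict (``evalue < threshold``): a hit at exactly the
    threshold is removed.  Row order is preserved and the input is not
    modified.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return rows[rows["evalue"] < threshold].copy()


def read_taxonomy(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a taxonomy TSV (``organism`` column plus one column per rank).

    Empty cells are recorded as *absent* ranks, not empty strings.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "organism" not in df.columns:
        raise ValueError("taxonomy table must have an 'organism' column")
    taxonomy: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        lineage = {
            rank: row[rank]
            for rank in RANKS
            if rank in df.columns and isinstance(row[rank], str) and row[rank] != ""
        }
        taxonomy[row["organism"]] = lineage
    return taxonomy


def write_taxonomy(taxonomy: Mapping[str, Mapping[str, str]], path: str | Path) -> None:
    rows = [
        {"organism": org, **{r: lin.get(r, "") for r in RANKS}}
        for org, lin in taxonomy.items()
    ]
    pd.DataFrame(rows, columns=("organism",) + RANKS).to_csv(path, sep="\t", index=False)


def subsample_by_taxon(
    records: Sequence[ProteinRecord],
    max_per_order: int = 5,
    max_per_family: int = 2,
    keep_list: Iterable[str] = (),
    seed: int | None = None,
    random_mode: bool = False,
) -> list[ProteinRecord]:
    """Cap the number of organisms retained per order and per family.

    At most *max_per_order* distinct organisms are kept from any one order
    and at most *max_per_family* from any one family.  Organisms on
    *keep_list* are retained preferentially (an error is raised if the keep
    list alone violates a cap); remaining slots are filled in input order,
    or in seeded random order when *random_mode* is set.  All sequences of a
    retained organism are kept.  Organisms lacking a rank value are not
    constrained at that rank.
    """
    keep = set(keep_list)
    order_of_first: list[str] = []
    by_org: dict[str, list[ProteinRecord]] = {}
    for r in records:
        if r.organism not in by_org:
            by_org[r.organism] = []
            order_of_first.append(r.organism)
        by_org[r.organism].append(r)

    missing = keep - set(order_of_first)
    if missing:
        raise ValueError(f"keep_list organisms not present in records: {sorted(missing)}")

    candidates = [o for o in order_of_first if o not in keep]
    if random_mode:
        from .util import stream_rng

        rng = stream_rng(0 if seed is None else seed, "subsample")
        candidates = [candidates[i] for i in rng.permutation(len(candidates))]

    order_counts: dict[str, int] = {}
    family_counts: dict[str, int] = {}
    retained: set[str] = set()

    def _taxa(org: str) -> tuple[str | None, str | None]:
        lin = by_org[org][0].lineage
        return lin.get("order"), lin.get("family")

    for org in order_of_first:
        if org not in keep:
            continue
        o, f = _taxa(org)
        if o is not None:
            order_counts[o] = order_counts.get(o, 0) + 1
            if order_counts[o] > max_per_order:
                raise ValueError(
                    f"keep_list exceeds per-order cap {max_per_order} for order {o!r}"
                )
        if f is not None:
            family_counts[f] = family_counts.get(f, 0) + 1
            if family_counts[f] > max_per_family:
                raise ValueError(
                    f"keep_list exceeds per-family cap {max_per_family} for family {f!r}"
                )
        retained.add(org)

    for org in candidates:
        o, f = _taxa(org)
        if o is not None and order_counts.get(o, 0) >= max_per_order:
            continue
        if f is not None and family_counts.get(f, 0) >= max_per_family:
            continue
        if o is not None:
            order_counts[o] = order_counts.get(o, 0) + 1
        if f is not None:
            family_counts[f] = family_counts.get(f, 0) + 1
        retained.add(org)

    return [r for r in records if r.organism in retained]


def _pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical columns in a global alignment of *a* and *b*.

    Uses a match/mismatch scoring with mild gap costs; identity is counted
    over all alignment columns, so a strict prefix of length m of an n-mer
    has identity m/n.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    aln = aligner.align(a, b)[0]
    r0, r1 = aln[0], aln[1]
    matches = sum(1 for x, y in zip(r0, r1) if x == y and x != "-")
    return matches / len(r0)


def deduplicate(
    records: Sequence[ProteinRecord],
    identity_threshold: float = 1.0,
) -> tuple[list[ProteinRecord], list[tuple[str, str]]]:
    """Remove duplicate sequences within each organism.

    With the default threshold of 1.0 only exact-sequence duplicates are
    collapsed; a threshold below 1.0 additionally collapses near-duplicates
    (alignment identity >= threshold), still only within one organism.  Of
    any duplicate group the longest sequence is kept (ties: lexicographically
    smallest id).  Returns the surviving records (input order) and a report
    of ``(removed_id, kept_id)`` pairs.  The operation is idempotent.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")

    removed_to_kept: dict[str, str] = {}
    by_org: dict[str, list[ProteinRecord]] = {}
    for r in records:
        by_org.setdefault(r.organism, []).append(r)

    drop: set[str] = set()
    for org_records in by_org.values():
        # longest first so the keeper of each group is seen before its dups
        ranked = sorted(org_records, key=lambda r: (-len(r.residues), r.id))
        kept: list[ProteinRecord] = []
        for r in ranked:
            keeper = None
            for k in kept:
                if r.residues == k.residues:
                    keeper = k
                elif (
                    identity_threshold < 1.0
                    and _pairwise_identity(r.residues, k.residues) >= identity_threshold
                ):
                    keeper = k
                if keeper is not None:
                    break
            if keeper is None:
                kept.append(r)
            else:
                drop.add(r.id)
                removed_to_kept[r.id] = keeper.id

    survivors = [r for r in records if r.id not in drop]
    report = [(rid, kid) for rid, kid in sorted(removed_to_kept.items())]
    return survivors, report
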