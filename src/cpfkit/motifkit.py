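"""Subfamily-diagnostic amino-acid motifs: patterns, scanning, discovery.

CPF subfamilies (cryptochromes and photolyases) are distinguished by short
conserved amino-acid motifs.  Patterns are written over the 20 standard
letters plus three wildcards: lowercase ``x`` matches any residue, ``B``
matches D or N, ``J`` matches I or L and ``Z`` matches E or Q.  The unknown
residue ``X`` in a sequence matches nothing except pattern ``x``.  A
per-pattern mismatch budget allows substitutions at the concrete
(non-wildcard) positions only; wildcard-class positions must always match
their class.

The module scans sequences for motif hits, tabulates per-subfamily motif
frequencies, derives consensus strings from stacked subfamily alignments and
discovers novel subfamily-specific motifs from those consensi by prevalence
screening against all other subfamilies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seqio import ProteinRecord
from .util import AA20, percent

#: Wildcard classes of the pattern alphabet.  ``x`` matches any residue
#: (including the unknown residue X); B/J/Z follow the extended one-letter
#: ambiguity codes.
WILDCARDS: dict[str, frozenset[str]] = {
    "x": frozenset(AA20) | {"X"},
    "B": frozenset("DN"),
    "J": frozenset("IL"),
    "Z": frozenset("EQ"),
}

PATTERN_ALPHABET = frozenset(AA20) | frozenset(WILDCARDS)


@dataclass(frozen=True)
class MotifPattern:
    """A named wildcard motif pattern diagnostic for one CPF subfamily."""

    name: str
    pattern: str
    subfamily: str
    max_mismatches: int = 0
    source: str = "user"

    def __post_init__(self) -> None:
        if len(self.pattern) < 3:
            raise ValueError(f"motif {self.name!r}: pattern shorter than 3")
        if self.pattern[0] == "x":
            raise ValueError(f"motif {self.name!r}: pattern must not start with x")
        bad = set(self.pattern) - PATTERN_ALPHABET
        if bad:
            raise ValueError(f"motif {self.name!r}: illegal pattern letters {sorted(bad)}")
        concrete = sum(1 for c in self.pattern if c not in WILDCARDS)
        if concrete < math.ceil(len(self.pattern) / 2):
            raise ValueError(
                f"motif {self.name!r}: fewer than half of the positions are concrete"
            )
        if self.max_mismatches < 0:
            raise ValueError(f"motif {self.name!r}: negative mismatch budget")

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class MotifHit:
    """A located motif match; coordinates are 0-based, half-open."""

    sequence_id: str
    motif_name: str
    start: int
    end: int
    matched: str
    mismatches: int


def _window_mismatches(window: str, pattern: str, budget: int) -> int | None:
    """Mismatch count of *window* against *pattern*, or None if no match.

    Wildcard positions must match their class exactly; substitutions are
    only tolerated (and counted) at concrete positions, up to *budget*.
    """
    mismatches = 0
    for w, p in zip(window, pattern):
        allowed = WILDCARDS.get(p)
        if allowed is not None:
            if w not in allowed:
                return None
        elif w != p:
            mismatches += 1
            if mismatches > budget:
                return None
    return mismatches


def scan_sequence(
    record: ProteinRecord,
    motif: MotifPattern,
    max_mismatches: int | None = None,
) -> list[MotifHit]:
    """All (possibly overlapping) matches of *motif* in *record*.

    Hits are reported sorted by start position.  *max_mismatches* overrides
    the pattern's own budget when given.
    """
    budget = motif.max_mismatches if max_mismatches is None else max_mismatches
    seq = record.residues
    pattern = motif.pattern
    w = len(pattern)
    hits: list[MotifHit] = []
    for start in range(len(seq) - w + 1):
        window = seq[start : start + w]
        mm = _window_mismatches(window, pattern, budget)
        if mm is not None:
            hits.append(
                MotifHit(
                    sequence_id=record.id,
                    motif_name=motif.name,
                    start=start,
                    end=start + w,
                    matched=window,
                    mismatches=mm,
                )
            )
    return hits


def scan_collection(
    records: Iterable[ProteinRecord],
    library: Iterable[MotifPattern],
) -> list[MotifHit]:
    """Scan every record against every pattern in the library."""
    library = list(library)
    hits: list[MotifHit] = []
    for rec in records:
        for motif in library:
            hits.extend(scan_sequence(rec, motif))
    return hits


@dataclass
class MotifFrequencyTable:
    """Per-(subfamily, motif) presence counts and integer percentages.

    A sequence counts once per motif regardless of how many hits it has.
    ``display()`` reproduces the reporting convention of showing only cells
    with at least 50% frequency.
    """

    table: pd.DataFrame  # columns: subfamily, motif, n_present, n_total, percent

    def percent_of(self, subfamily: str, motif: str) -> int:
        sel = self.table[
            (self.table["subfamily"] == subfamily) & (self.table["motif"] == motif)
        ]
        if sel.empty:
            raise KeyError((subfamily, motif))
        return int(sel["percent"].iloc[0])

    def display(self, min_percent: int = 50) -> pd.DataFrame:
        """Wide subfamily x motif view suppressing cells below *min_percent*."""
        wide = self.table.pivot(index="subfamily", columns="motif", values="percent")
        return wide.where(wide >= min_percent)


def tabulate_frequencies(
    hits: Iterable[MotifHit],
    assignments: Mapping[str, str],
    library: Iterable[MotifPattern],
) -> MotifFrequencyTable:
    """Tabulate motif presence per subfamily.

    *assignments* maps sequence id to subfamily label; every scanned
    sequence must appear in it.  For each (subfamily, motif) pair,
    ``n_total`` is the number of sequences assigned to the subfamily and
    ``n_present`` the number of those with at least one hit of the motif.
    """
    library = list(library)
    if not library:
        raise ValueError("motif library is empty")
    present: dict[tuple[str, str], set[str]] = {}
    for h in hits:
        if h.sequence_id not in assignments:
            raise ValueError(f"no subfamily assignment for sequence {h.sequence_id!r}")
        key = (assignments[h.sequence_id], h.motif_name)
        present.setdefault(key, set()).add(h.sequence_id)

    totals: dict[str, int] = {}
    for label in assignments.values():
        totals[label] = totals.get(label, 0) + 1

    rows = []
    for subfamily in sorted(totals):
        n_total = totals[subfamily]
        for motif in library:
            n_present = len(present.get((subfamily, motif.name), ()))
            rows.append(
                {
                    "subfamily": subfamily,
                    "motif": motif.name,
                    "n_present": n_present,
                    "n_total": n_total,
                    "percent": percent(n_present, n_total),
                }
            )
    return MotifFrequencyTable(pd.DataFrame(rows))


def build_consensus(aligned_rows: Sequence[str], column_threshold: float = 0.6) -> str:
    """Consensus string of equal-length gapped rows.

    Majority-gap columns (more gaps than residues) are dropped.  A column
    contributes its most frequent residue when that residue reaches
    *column_threshold* among the non-gap rows and at least half of all rows
    are non-gap; otherwise it contributes the wildcard ``x``.
    """
    if not aligned_rows:
        raise ValueError("empty alignment")
    if not 0.5 < column_threshold <= 1:
        raise ValueError("column_threshold must be in (0.5, 1]")
    n = len(aligned_rows)
    width = len(aligned_rows[0])
    if any(len(r) != width for r in aligned_rows):
        raise ValueError("alignment rows differ in length")

    out: list[str] = []
    for col in range(width):
        residues = [r[col] for r in aligned_rows if r[col] != "-"]
        n_nongap = len(residues)
        if n - n_nongap > n_nongap:  # majority gap
            continue
        counts: dict[str, int] = {}
        for ch in residues:
            counts[ch] = counts.get(ch, 0) + 1
        best = min(counts, key=lambda c: (-counts[c], c))
        if counts[best] / n_nongap >= column_threshold and 2 * n_nongap >= n:
            out.append(best)
        else:
            out.append("x")
    return "".join(out)


def _prevalence(records: Sequence[ProteinRecord], motif: MotifPattern) -> float:
    hit = sum(1 for r in records if scan_sequence(r, motif))
    return hit / len(records)


def discover_motifs(
    consensus: str,
    own_set: Sequence[ProteinRecord],
    other_sets: Mapping[str, Sequence[ProteinRecord]],
    w_min: int = 4,
    max_x_fraction: float = 1 / 3,
    p_in: float = 0.7,
    p_out: float = 0.05,
    subfamily: str = "",
    name_prefix: str = "novel",
) -> list[MotifPattern]:
    """Subfamily-specific motif candidates from a consensus string.

    Every window of *consensus* with length >= *w_min*, concrete first and
    last characters, wildcard fraction <= *max_x_fraction* and at least half
    concrete positions is a syntactic candidate.  A candidate is emitted
    when its scan prevalence is >= *p_in* in *own_set* and <= *p_out* in
    every other set; windows contained in a longer emitted window at the
    same specificity are dropped (only maximal windows are reported).
    Results are sorted by own-set prevalence (descending), then length
    (descending), then start position.
    """
    if not own_set:
        raise ValueError("own_set is empty")
    candidates: list[tuple[float, int, int, str]] = []
    n = len(consensus)
    for start in range(n):
        if consensus[start] in WILDCARDS:
            continue
        for end in range(start + w_min, n + 1):
            window = consensus[start:end]
            if window[-1] in WILDCARDS:
                continue
            n_wild = sum(1 for c in window if c in WILDCARDS)
            if n_wild / len(window) > max_x_fraction:
                continue
            if len(window) - n_wild < math.ceil(len(window) / 2):
                continue
            probe = MotifPattern(name="probe", pattern=window, subfamily=subfamily)
            own_prev = _prevalence(own_set, probe)
            if own_prev < p_in:
                continue
            if any(
                _prevalence(recs, probe) > p_out
                for recs in other_sets.values()
                if len(recs) > 0
            ):
                continue
            candidates.append((own_prev, len(window), start, window))

    # keep only maximal windows: drop candidates nested inside another
    maximal = []
    for prev, length, start, window in candidates:
        nested = any(
            (s2 <= start and start + length <= s2 + l2) and (l2 > length)
            for _, l2, s2, _ in candidates
        )
        if not nested:
            maximal.append((prev, length, start, window))

    maximal.sort(key=lambda t: (-t[0], -t[1], t[2]))
    return [
        MotifPattern(
            name=f"{name_prefix}{i + 1}",
            pattern=window,
            subfamily=subfamily,
            source="user",
        )
        for i, (_, _, _, window) in enumerate(maximal)
    ]


# ---------------------------------------------------------------------------
# Motif library: shipped patterns, placeholders and TSV round-trip
# ---------------------------------------------------------------------------

#: Patterns printed in the main text of the source study.  The remaining
#: subfamily motifs are catalogued only in supplementary material and ship
#: here as named placeholders (see :data:`APPENDIX_PLACEHOLDERS`).
MAIN_TEXT_MOTIFS: tuple[MotifPattern, ...] = (
    MotifPattern("pl1", "VGLR", "PCRY-like", 0, "paper-main"),
    MotifPattern("pl2", "WRDLAY", "PCRY-like", 0, "paper-main"),
    MotifPattern("pl3", "MWQNxG", "PCRY-like", 0, "paper-main"),
    MotifPattern("dm1", "HTLWxP", "DCRY", 0, "paper-main"),
    MotifPattern("ppl1", "ESxSxxPVYCFDPR", "PPL", 0, "paper-main"),
    MotifPattern("ppl2", "BSJYGANFSCKI", "PPL", 0, "paper-main"),
    MotifPattern("ppl3", "FFRFxTxK", "PPL", 0, "paper-main"),
    MotifPattern("cterm64", "YIYEPWKAP", "6-4 PL", 0, "paper-main"),
)

#: Subfamily motifs known by name only; their patterns must be supplied by
#: the user (motif-library TSV rows with a pattern) before they can be
#: scanned.
APPENDIX_PLACEHOLDERS: dict[str, str] = {
    **{f"a{i}": "6-4 PL" for i in (8, 10, 12, 14, 15, 16, 17, 18)},
    "sl": "6-4 PL",
    "pn": "6-4 PL",
    "4a": "CRY4",
    "4b": "CRY4",
    "4c": "CRY4",
    "4Y": "CRY4",
    "m2pu": "MCRY",
    "m2pl": "MCRY",
    "mpm": "MCRY",
    "ml": "MCRY",
    "mcl": "MCRY",
    "mct": "MCRY",
    "mnc": "MCRY",
    "I": "MCRY",
    "II": "MCRY",
    "d2pu": "DCRY",
    "d2pl": "DCRY",
    "dcl": "DCRY",
    "cc1": "CPDII",
    "cc2": "CPDII",
    "cc3": "CPDII",
    "mts": "CPDII",
    "c3": "CPDIII",
    "c1/3-1": "CPDI",
    "c3-2": "CPDI",
    "db1": "DASH",
    "db2": "DASH",
    "dlr": "DASH",
    "pd1": "PCRY",
    "pd2": "PCRY",
    "pc": "PCRY",
    "pc1": "PCRY",
}

_LIBRARY_HEADER = "name\tpattern\tsubfamily\tmax_mismatches\tsource"


def default_library() -> list[MotifPattern]:
    """The shipped scannable motif library (main-text patterns only)."""
    return list(MAIN_TEXT_MOTIFS)


def read_motif_library(path: str | Path) -> list[MotifPattern]:
    """Read a motif library TSV; rows with an empty pattern (placeholders
    awaiting user-supplied sequences) are skipped."""
    motifs: list[MotifPattern] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _LIBRARY_HEADER:
            raise ValueError(f"unexpected motif library header: {header!r}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            name, pattern, subfamily, max_mm, source = line.split("\t")
            if pattern == "":
                continue
            motifs.append(MotifPattern(name, pattern, subfamily, int(max_mm), source))
    return motifs


def write_motif_library(motifs: Iterable[MotifPattern], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_LIBRARY_HEADER + "\n")
        for m in motifs:
            fh.write(f"{m.name}\t{m.pattern}\t{m.subfamily}\t{m.max_mismatches}\t{m.source}\n")


def hits_to_tsv(hits: Iterable[MotifHit], path: str | Path) -> None:
    pd.DataFrame([h.__dict__ for h in hits]).to_csv(path, sep="\t", index=False)


def hits_to_gff3(hits: Iterable[MotifHit], path: str | Path) -> None:
    """Write hits as GFF3 protein features (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for h in hits:
            attrs = f"Name={h.motif_name};mismatches={h.mismatches};matched={h.matched}"
            fh.write(
                f"{h.sequence_id}\tcpfkit\tprotein_motif\t{h.start + 1}\t{h.end}\t"
                f".\t.\t.\t{attrs}\n"
            )
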