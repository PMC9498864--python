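"""Taxon-level subfamily prevalence tables.

Aggregates a binary organism x subfamily repertoire matrix to a chosen
taxonomic rank and reports, per taxon, the integer percentage of organisms
possessing each subfamily.  Zero counts render as "-", and a display cutoff
can mask low-prevalence cells (strictly-greater-than semantics) without
altering the stored numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .classify import RepertoireMatrix
from .util import percent

UNRANKED = "unranked"


@dataclass
class PrevalenceTable:
    """Per-taxon organism counts and integer-percent prevalence cells."""

    counts: pd.DataFrame  # taxon x column: organisms with presence
    n: pd.Series  # taxon -> organisms aggregated
    percents: pd.DataFrame  # taxon x column: integer percent

    def render(self, cutoff: float | None = None) -> pd.DataFrame:
        """Human-readable view: "-" for zero counts; with *cutoff*, cells at
        or below it are masked (only strictly greater cells are shown)."""
        out = pd.DataFrame(index=self.percents.index, columns=self.percents.columns, dtype=object)
        for taxon in self.percents.index:
            for col in self.percents.columns:
                count = int(self.counts.loc[taxon, col])
                pct = int(self.percents.loc[taxon, col])
                if count == 0:
                    out.loc[taxon, col] = "-"
                elif cutoff is not None and pct <= cutoff:
                    out.loc[taxon, col] = ""
                else:
                    out.loc[taxon, col] = f"{pct}%"
        out.index = [f"{taxon} ({int(self.n[taxon])})" for taxon in self.percents.index]
        return out

    def to_tsv(self, path: str | Path, cutoff: float | None = None) -> None:
        self.render(cutoff).to_csv(path, sep="\t")

    def to_markdown(self, cutoff: float | None = None) -> str:
        return self.render(cutoff).to_markdown()


def prevalence_by_taxon(matrix: RepertoireMatrix, rank: str) -> PrevalenceTable:
    """Prevalence of each subfamily per taxon at the given rank.

    Organisms lacking a value at *rank* are grouped under an explicit
    "unranked" row so that counts are conserved.  Percentages are rounded
    half away from zero to whole percent.
    """
    if matrix.presence.empty:
        raise ValueError("empty repertoire matrix")
    groups: dict[str, list[str]] = {}
    for org in matrix.presence.index:
        taxon = matrix.taxonomy.get(org, {}).get(rank, UNRANKED)
        groups.setdefault(taxon, []).append(org)

    taxa = sorted(groups)
    counts = pd.DataFrame(0, index=taxa, columns=matrix.presence.columns, dtype=int)
    n = pd.Series(0, index=taxa, dtype=int)
    for taxon, orgs in groups.items():
        sub = matrix.presence.loc[orgs]
        counts.loc[taxon] = sub.sum(axis=0)
        n[taxon] = len(orgs)
    percents = counts.copy()
    for taxon in taxa:
        percents.loc[taxon] = [percent(int(c), int(n[taxon])) for c in counts.loc[taxon]]
    return PrevalenceTable(counts=counts, n=n, percents=percents)


def render_clade_summary(table: PrevalenceTable, cutoff_percent: float = 10.0) -> pd.DataFrame:
    """Display view masking cells at or below *cutoff_percent*.

    The mask applies to the rendered view only; the table's stored counts
    and percentages are untouched (rendering is pure).
    """
    return table.render(cutoff=cutoff_percent)
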