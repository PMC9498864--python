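"""Deterministic synthetic CPF fixture generator.

Real CPF surveys start from thousands of downloaded accessions; this module
replaces them with fully offline, seed-deterministic stand-ins so that every
other module is testable at desk scale:

* per-subfamily protein sets of realistic length (500 aa by default,
  1000 aa for the internally duplicated ACRY proteins) whose sequences are
  point-mutated copies of a screened random scaffold with diagnostic motifs
  planted at configured prevalences, and
* mock taxonomies with per-taxon subfamily presence planted at configured
  rates, mirroring the published kingdom-level prevalence rows.

Planting uses exact counts (``round(rate * n)`` sequences or organisms,
chosen by seeded shuffle) rather than Bernoulli draws, so configured rates
round-trip exactly through the scanner and the prevalence tabulator.
Scaffolds are rejected until they contain no accidental match to any
library motif, and mutated copies are redrawn on the rare accidental match,
so a sequence has a motif hit if and only if the motif was planted in it.

All randomness flows through named PCG64 substreams of one master seed
(see :func:`cpfkit.util.stream_rng`); a fixed seed yields byte-identical
output on every platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import motifkit
from .classify import SUBFAMILIES, ReferencePanel, RepertoireMatrix
from .motifkit import MotifPattern, WILDCARDS
from .seqio import ProteinRecord
from .util import AA20, round_half_away, stream_rng

#: Subfamilies whose proteins are roughly twice the family-typical length.
LONG_SUBFAMILIES = frozenset({"ACRY"})

DEFAULT_SCAFFOLD_LENGTH = 500
ACRY_SCAFFOLD_LENGTH = 1000

#: Printed per-subfamily frequencies of the main-text motifs; these are the
#: default planting rates of the frequency fixture.
MAIN_TEXT_MOTIF_RATES: dict[str, dict[str, float]] = {
    "PCRY-like": {"pl1": 0.74, "pl2": 0.83, "pl3": 0.97},
    "DCRY": {"dm1": 0.70},
    "PPL": {"ppl1": 0.85, "ppl2": 0.75, "ppl3": 0.85},
    "6-4 PL": {"cterm64": 0.81},
}

#: Default set sizes for the frequency fixture.  The PCRY-like set size is
#: the one reported for that subfamily (103 sequences); the DCRY, PPL and
#: 6-4 PL sizes are stand-ins chosen so that whole-percent planting rates
#: survive the plant-count/percentage round trip exactly.
DEFAULT_SET_SIZES: dict[str, int] = {"PCRY-like": 103, "DCRY": 100, "PPL": 20, "6-4 PL": 100}

#: Published kingdom-level subfamily presence rates (fraction of organisms
#: in the taxon possessing the subfamily).  Zero-rate subfamilies are
#: simply omitted.
KINGDOM_PRESENCE: tuple[tuple[str, str, int, dict[str, float]], ...] = (
    # (domain, taxon, n_organisms, subfamily -> presence fraction)
    ("Eukaryota", "Metazoa", 497, {
        "MCRY": 0.86, "6-4 PL": 0.47, "DCRY": 0.18, "ACRY": 0.02,
        "PCRY-like": 0.18, "CPDI": 0.02, "CPDII": 0.76, "CPDIII": 0.01,
        "DASH": 0.50, "other": 0.02,
    }),
    ("Eukaryota", "Fungi", 34, {
        "6-4 PL": 0.65, "CPDI": 0.85, "CPDII": 0.12, "DASH": 0.53,
    }),
    ("Eukaryota", "Viridiplantae", 28, {
        "6-4 PL": 0.86, "PCRY-like": 0.11, "CPDI": 0.04, "CPDII": 0.86,
        "CPDIII": 0.04, "PCRY": 0.75, "DASH": 0.82, "PPL": 0.61,
    }),
    ("Eukaryota", "unicellular Eukaryota", 51, {
        "6-4 PL": 0.63, "PCRY-like": 0.25, "CPDI": 0.14, "CPDII": 0.73,
        "CPDIII": 0.02, "DASH": 0.65, "PPL": 0.06, "other": 0.22,
    }),
    ("Bacteria", "Bacteria", 20, {
        "6-4 PL": 0.15, "CPDI": 0.65, "CPDII": 0.25, "CPDIII": 0.15, "DASH": 0.30,
    }),
    ("Archaea", "Archaea", 9, {
        "6-4 PL": 0.33, "CPDI": 0.22, "CPDII": 0.44, "CPDIII": 0.11,
    }),
)


def _slug(name: str) -> str:
    return name.replace(" ", "_").replace("/", "_")


@dataclass
class SubfamilyProfile:
    """Generation recipe for one subfamily's synthetic sequence set."""

    subfamily: str
    n_sequences: int
    motif_plant_rates: dict[str, float] = field(default_factory=dict)
    scaffold_length: int = DEFAULT_SCAFFOLD_LENGTH
    mutation_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.n_sequences <= 0:
            raise ValueError("n_sequences must be positive")
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in [0, 1)")
        for name, rate in self.motif_plant_rates.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"plant rate for {name!r} outside [0, 1]")


@dataclass
class TaxonRow:
    """One mock taxon: its size and per-subfamily presence fractions."""

    taxon: str
    n_organisms: int
    presence: dict[str, float]
    domain: str = "Eukaryota"


@dataclass
class SimulationConfig:
    seed: int
    profiles: list[SubfamilyProfile]
    taxon_rows: list[TaxonRow]
    library: list[MotifPattern] = field(default_factory=motifkit.default_library)


def _instantiate(pattern: str, rng: np.random.Generator) -> str:
    """A concrete residue string matching *pattern* (wildcards resolved)."""
    out = []
    for ch in pattern:
        allowed = WILDCARDS.get(ch)
        if allowed is None:
            out.append(ch)
        else:
            choices = sorted(allowed - {"X"})
            out.append(choices[int(rng.integers(len(choices)))])
    return "".join(out)


def _has_any_hit(residues: str, library: list[MotifPattern]) -> bool:
    probe = ProteinRecord(id="probe", residues=residues)
    return any(motifkit.scan_sequence(probe, m) for m in library)


def make_scaffold(
    length: int,
    library: list[MotifPattern],
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> str:
    """Random scaffold over the 20 standard residues with no motif match.

    Regenerated until no library motif matches anywhere; raises after
    *max_attempts* failures (pathologically permissive motif library).
    """
    letters = np.array(list(AA20))
    for _ in range(max_attempts):
        scaffold = "".join(letters[rng.integers(0, 20, size=length)])
        if not _has_any_hit(scaffold, library):
            return scaffold
    raise RuntimeError(f"could not screen a motif-free scaffold in {max_attempts} attempts")


def _mutate(
    residues: str,
    rate: float,
    protected: set[int],
    rng: np.random.Generator,
) -> str:
    seq = list(residues)
    draws = rng.random(len(seq))
    for pos, u in enumerate(draws):
        if pos in protected or u >= rate:
            continue
        alternatives = [c for c in AA20 if c != seq[pos]]
        seq[pos] = alternatives[int(rng.integers(19))]
    return "".join(seq)


def simulate_subfamily_set(
    profile: SubfamilyProfile,
    seed: int,
    library: list[MotifPattern] | None = None,
    scaffold: str | None = None,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Generate one subfamily's synthetic sequence set plus its truth table.

    Returns the records (ids ``<subfamily>_0000`` ...) and a boolean
    sequence x motif truth table recording which motifs were planted where.
    Each motif occupies a fixed site on the scaffold and is planted in
    exactly ``round(rate * n_sequences)`` sequences chosen by seeded
    shuffle; mutations never touch planted windows, and any mutated copy
    that accidentally gains or loses a motif match is redrawn, so scanner
    output reproduces the truth table exactly.  If *scaffold* is given
    (classification mode: a reference-anchored scaffold) it is used as-is
    and must itself be motif-free.
    """
    if library is None:
        library = motifkit.default_library()
    by_name = {m.name: m for m in library}
    missing = set(profile.motif_plant_rates) - set(by_name)
    if missing:
        raise ValueError(f"plant rates refer to motifs not in library: {sorted(missing)}")
    planted_motifs = [by_name[name] for name in profile.motif_plant_rates]

    sub = profile.subfamily
    if scaffold is None:
        scaffold = make_scaffold(
            profile.scaffold_length, library, stream_rng(seed, "scaffold", sub)
        )
    elif _has_any_hit(scaffold, library):
        raise ValueError("supplied scaffold already matches a library motif")

    # fixed, non-overlapping site per motif
    sites: dict[str, tuple[int, int]] = {}
    cursor = 10
    for m in planted_motifs:
        end = cursor + len(m.pattern)
        if end + 10 > len(scaffold):
            raise ValueError(
                f"scaffold of length {len(scaffold)} too short for planted motifs"
            )
        sites[m.name] = (cursor, end)
        cursor = end + 7

    instances = {
        m.name: _instantiate(m.pattern, stream_rng(seed, "instance", sub, m.name))
        for m in planted_motifs
    }

    n = profile.n_sequences
    carriers: dict[str, set[int]] = {}
    for m in planted_motifs:
        count = round_half_away(profile.motif_plant_rates[m.name] * n)
        order = stream_rng(seed, "carriers", sub, m.name).permutation(n)
        carriers[m.name] = set(int(i) for i in order[:count])

    records: list[ProteinRecord] = []
    truth_rows = []
    for i in range(n):
        mine = [m for m in planted_motifs if i in carriers[m.name]]
        protected: set[int] = set()
        base = list(scaffold)
        for m in mine:
            start, end = sites[m.name]
            base[start:end] = instances[m.name]
            protected.update(range(start, end))
        base = "".join(base)

        rng = stream_rng(seed, "mutate", sub, i)
        planted_names = {m.name for m in mine}
        for _ in range(200):
            candidate = _mutate(base, profile.mutation_rate, protected, rng)
            rec = ProteinRecord(id=f"{_slug(sub)}_{i:04d}", residues=candidate,
                                organism=f"{_slug(sub)}_org_{i:04d}")
            hits_ok = True
            for m in library:
                has_hit = bool(motifkit.scan_sequence(rec, m))
                if has_hit != (m.name in planted_names):
                    hits_ok = False
                    break
            if hits_ok:
                break
        else:
            raise RuntimeError(
                f"could not draw an accident-free mutant for {sub} sequence {i}"
            )
        records.append(rec)
        truth_rows.append(
            {"sequence_id": rec.id, **{m.name: (i in carriers[m.name]) for m in planted_motifs}}
        )

    truth = pd.DataFrame(truth_rows).set_index("sequence_id")
    return records, truth


def default_simulation_config(seed: int = 42) -> SimulationConfig:
    """The default frequency fixture: main-text motifs planted at their
    printed per-subfamily frequencies, and mock taxa with the published
    kingdom-level presence rates."""
    profiles = [
        SubfamilyProfile(
            subfamily=sub,
            n_sequences=DEFAULT_SET_SIZES[sub],
            motif_plant_rates=dict(rates),
            scaffold_length=(
                ACRY_SCAFFOLD_LENGTH if sub in LONG_SUBFAMILIES else DEFAULT_SCAFFOLD_LENGTH
            ),
        )
        for sub, rates in MAIN_TEXT_MOTIF_RATES.items()
    ]
    taxon_rows = [
        TaxonRow(taxon=taxon, n_organisms=n, presence=dict(presence), domain=domain)
        for domain, taxon, n, presence in KINGDOM_PRESENCE
    ]
    return SimulationConfig(seed=seed, profiles=profiles, taxon_rows=taxon_rows)


def simulate_repertoires(
    config: SimulationConfig,
) -> tuple[RepertoireMatrix, dict[str, dict[str, str]]]:
    """Mock organisms with planted subfamily presence flags.

    Per taxon row, each subfamily is marked present in exactly
    ``round(fraction * n_organisms)`` organisms (seeded choice); organism
    names are deterministic.  Returns the repertoire matrix and a taxonomy
    suitable for :func:`cpfkit.prevalence.prevalence_by_taxon`.
    """
    columns = list(SUBFAMILIES) + ["other"]
    rows: dict[str, dict[str, int]] = {}
    taxonomy: dict[str, dict[str, str]] = {}
    for row in config.taxon_rows:
        unknown = set(row.presence) - set(columns)
        if unknown:
            raise ValueError(f"unknown subfamily in taxon row {row.taxon!r}: {sorted(unknown)}")
        orgs = [f"{_slug(row.taxon)}_{i:04d}" for i in range(row.n_organisms)]
        for org in orgs:
            rows[org] = {c: 0 for c in columns}
            taxonomy[org] = {"domain": row.domain, "kingdom": row.taxon}
        for sub, frac in row.presence.items():
            count = round_half_away(frac * row.n_organisms)
            order = stream_rng(config.seed, "repertoire", row.taxon, sub).permutation(
                row.n_organisms
            )
            for i in order[:count]:
                rows[orgs[int(i)]][sub] = 1
    presence = pd.DataFrame.from_dict(rows, orient="index", columns=columns).astype(int)
    return RepertoireMatrix(presence=presence, taxonomy=taxonomy), taxonomy


# ---------------------------------------------------------------------------
# Classification-mode fixture
# ---------------------------------------------------------------------------


def synthetic_diagnostic_motifs(seed: int, min_per_subfamily: int = 2) -> list[MotifPattern]:
    """Synthetic stand-in diagnostic motifs for subfamilies whose published
    patterns live only in supplementary material.

    Random concrete 8-mers (no wildcards), generated on named substreams so
    they are seed-deterministic; enough are added that every subfamily has
    at least *min_per_subfamily* scannable motifs.
    """
    motifs: list[MotifPattern] = []
    counts = {sub: 0 for sub in SUBFAMILIES}
    for m in motifkit.default_library():
        counts[m.subfamily] += 1
    for sub in SUBFAMILIES:
        k = 0
        while counts[sub] + k < min_per_subfamily:
            k += 1
            rng = stream_rng(seed, "synmotif", sub, k)
            letters = np.array(list(AA20))
            pattern = "".join(letters[rng.integers(0, 20, size=8)])
            motifs.append(
                MotifPattern(
                    name=f"syn_{_slug(sub)}_{k}", pattern=pattern, subfamily=sub,
                    source="user",
                )
            )
    return motifs


def simulate_classification_fixture(
    seed: int = 42,
    n_per_subfamily: int = 50,
    mutation_rate: float = 0.05,
    diagnostic_rate: float = 1.0,
) -> dict:
    """Reference-anchored fixture for classifier recovery.

    For each of the eleven subfamilies a screened random scaffold serves as
    the synthetic reference; queries are copies mutated at *mutation_rate*
    with at least two subfamily-diagnostic motifs planted (main-text
    patterns where available, synthetic stand-ins elsewhere).  Returns a
    dict with the ``panel`` (:class:`~cpfkit.classify.ReferencePanel` of the
    synthetic references), ``records``, ``truth`` (sequence id -> generating
    subfamily) and the scanning ``library``.
    """
    library = motifkit.default_library() + synthetic_diagnostic_motifs(seed)
    by_subfamily: dict[str, list[MotifPattern]] = {}
    for m in library:
        by_subfamily.setdefault(m.subfamily, []).append(m)

    members = []
    records: list[ProteinRecord] = []
    truth: dict[str, str] = {}
    for sub in SUBFAMILIES:
        length = ACRY_SCAFFOLD_LENGTH if sub in LONG_SUBFAMILIES else DEFAULT_SCAFFOLD_LENGTH
        scaffold = make_scaffold(length, library, stream_rng(seed, "refscaffold", sub))
        ref = ProteinRecord(
            id=f"REF_{_slug(sub)}", residues=scaffold, organism=f"ref_{_slug(sub)}"
        )
        members.append((sub, ref))

        rates = {m.name: diagnostic_rate for m in by_subfamily[sub][:2]}
        profile = SubfamilyProfile(
            subfamily=sub,
            n_sequences=n_per_subfamily,
            motif_plant_rates=rates,
            scaffold_length=length,
            mutation_rate=mutation_rate,
        )
        recs, _ = simulate_subfamily_set(profile, seed, library=library, scaffold=scaffold)
        records.extend(recs)
        truth.update({r.id: sub for r in recs})

    return {
        "panel": ReferencePanel(members),
        "records": records,
        "truth": truth,
        "library": library,
    }


def write_fixture(outdir: str | Path, config: SimulationConfig) -> None:
    """Emit the frequency fixture as plain-text files (FASTA, taxonomy TSV,
    truth TSV, repertoire TSV)."""
    from .seqio import write_fasta, write_taxonomy

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_records: list[ProteinRecord] = []
    truths = []
    for profile in config.profiles:
        recs, truth = simulate_subfamily_set(profile, config.seed, library=config.library)
        all_records.extend(recs)
        truth.insert(0, "subfamily", profile.subfamily)
        truths.append(truth)
    write_fasta(all_records, outdir / "sequences.fasta")
    combined = pd.concat(truths)
    motif_cols = [c for c in combined.columns if c != "subfamily"]
    combined[motif_cols] = combined[motif_cols].where(
        combined[motif_cols].notna(), False
    ).astype(bool)
    combined.to_csv(outdir / "truth.tsv", sep="\t")
    rep, taxonomy = simulate_repertoires(config)
    rep.presence.to_csv(outdir / "repertoire.tsv", sep="\t")
    write_taxonomy(taxonomy, outdir / "taxonomy.tsv")
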