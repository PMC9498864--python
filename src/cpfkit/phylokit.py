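"""Pairwise alignment, corrected protein distances and Neighbor-Joining.

Distances follow the classic distance-matrix recipe for protein trees:
true global alignment (end gaps penalized) under the Dayhoff-derived PAM100
matrix with affine gap costs 10/1, an observed mismatch fraction p over
columns where both rows carry a residue, a 20-state Jukes-Cantor correction
d = -(19/20) ln(1 - (20/19) p), and Saitou-Nei Neighbor-Joining on the
resulting matrix.  Trees are unrooted with non-negative branch lengths and
serialize to Newick via scikit-bio.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix, TreeNode

from .seqio import ProteinRecord

#: Number of amino-acid states in the Jukes-Cantor generalization.
JC_STATES = 20
#: Mismatch fractions at or above this are treated as saturated.
P_MAX = 0.95 - 1e-9
#: Distance assigned to saturated pairs.
D_CAP = 10.0

_BUNDLED_MATRICES = {"PAM100"}


def load_matrix(name: str = "PAM100"):
    """Load a substitution matrix: bundled PAM100, else the Biopython set."""
    if name in _BUNDLED_MATRICES:
        ref = importlib.resources.files("cpfkit.data") / f"{name}.txt"
        with importlib.resources.as_file(ref) as path:
            return substitution_matrices.read(str(path))
    try:
        return substitution_matrices.load(name)
    except FileNotFoundError as e:
        raise ValueError(f"unknown substitution matrix {name!r}") from e


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global pairwise alignment: two equal-length gapped rows."""

    ids: tuple[str, str]
    rows: tuple[str, str]
    score: float

    def __post_init__(self) -> None:
        r0, r1 = self.rows
        if len(r0) != len(r1):
            raise ValueError("alignment rows differ in length")
        if any(a == "-" and b == "-" for a, b in zip(r0, r1)):
            raise ValueError("alignment contains a gap/gap column")


def _make_aligner(matrix_name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = load_matrix(matrix_name)
    # first residue of a gap costs gap_open, each further residue gap_extend
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(
    a: ProteinRecord,
    b: ProteinRecord,
    matrix_name: str = "PAM100",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> PairwiseAlignment:
    """Optimal global alignment of two protein records.

    Affine penalty: a gap of length L costs ``gap_open + (L-1)*gap_extend``;
    end gaps are penalized (true global alignment).  Among co-optimal
    alignments the first alignment of Biopython's deterministic traceback
    order is returned.
    """
    if not a.residues or not b.residues:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(matrix_name, gap_open, gap_extend)
    try:
        best = aligner.align(a.residues, b.residues)[0]
    except ValueError as e:
        raise ValueError(
            f"alignment of {a.id!r} vs {b.id!r} failed (residue missing from "
            f"{matrix_name}?): {e}"
        ) from e
    return PairwiseAlignment(ids=(a.id, b.id), rows=(best[0], best[1]), score=best.score)


def p_distance(alignment: PairwiseAlignment) -> float:
    """Observed mismatch fraction over columns where both rows are residues."""
    r0, r1 = alignment.rows
    comparable = mismatches = 0
    for x, y in zip(r0, r1):
        if x == "-" or y == "-":
            continue
        comparable += 1
        if x != y:
            mismatches += 1
    if comparable == 0:
        raise ValueError(f"no comparable columns in alignment {alignment.ids}")
    return mismatches / comparable


def jc_correct(p: float, n_states: int = JC_STATES, p_max: float = P_MAX, d_cap: float = D_CAP) -> float:
    """Jukes-Cantor correction generalized to *n_states* states.

    d = -((n-1)/n) ln(1 - (n/(n-1)) p), capped at *d_cap* for p >= *p_max*
    (the correction diverges as p approaches (n-1)/n).
    """
    if p < 0:
        raise ValueError("p must be non-negative")
    if p >= p_max:
        return d_cap
    frac = (n_states - 1) / n_states
    return min(-frac * math.log(1.0 - p / frac), d_cap)


def jc_distance(alignment: PairwiseAlignment) -> float:
    """Jukes-Cantor corrected distance of a pairwise alignment."""
    return jc_correct(p_distance(alignment))


def distance_matrix(
    records: Sequence[ProteinRecord],
    matrix_name: str = "PAM100",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> DistanceMatrix:
    """All-pairs Jukes-Cantor distance matrix from pairwise alignments."""
    ids = [r.id for r in records]
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(records[i], records[j], matrix_name, gap_open, gap_extend)
            d[i, j] = d[j, i] = jc_distance(aln)
    return DistanceMatrix(d, ids)


# ---------------------------------------------------------------------------
# Neighbor-Joining
# ---------------------------------------------------------------------------


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei Neighbor-Joining tree of a distance matrix.

    Each round joins the pair minimizing
    Q(i,j) = (r-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k); exact ties are
    broken by the lexicographically smallest pair of cluster keys (a
    cluster's key is the smallest leaf label it contains).  Negative branch
    lengths are clamped to zero.  The returned tree is unrooted, represented
    with a trifurcating root; on an additive matrix it is the unique
    generating tree with exact branch lengths.
    """
    labels = list(dm.ids)
    if len(labels) < 3:
        raise ValueError("neighbor-joining needs at least 3 labels")

    # active clusters: key -> (min leaf label, TreeNode)
    nodes: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in labels}
    keys = sorted(labels)
    d: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            d[_pairkey(a, b)] = float(dm[a, b])

    while len(keys) > 3:
        r = len(keys)
        sums = {k: sum(d[_pairkey(k, m)] for m in keys if m != k) for k in keys}
        best_q = None
        best_pair: tuple[str, str] | None = None
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                q = (r - 2) * d[_pairkey(a, b)] - sums[a] - sums[b]
                pair = (a, b) if a < b else (b, a)
                if best_q is None or q < best_q or (q == best_q and pair < best_pair):
                    best_q, best_pair = q, pair
        a, b = best_pair
        dab = d[_pairkey(a, b)]
        va = 0.5 * dab + (sums[a] - sums[b]) / (2 * (r - 2))
        vb = dab - va
        va, vb = max(va, 0.0), max(vb, 0.0)

        parent = TreeNode()
        child_a, child_b = nodes.pop(a), nodes.pop(b)
        child_a.length, child_b.length = va, vb
        parent.extend([child_a, child_b])

        new_key = min(a, b)
        rest = [k for k in keys if k not in (a, b)]
        for k in rest:
            duk = 0.5 * (d[_pairkey(a, k)] + d[_pairkey(b, k)] - dab)
            d[_pairkey(new_key, k)] = duk
        keys = sorted(rest + [new_key])
        nodes[new_key] = parent

    # final three-point join
    a, b, c = keys
    dab, dac, dbc = d[_pairkey(a, b)], d[_pairkey(a, c)], d[_pairkey(b, c)]
    va = 0.5 * (dab + dac - dbc)
    vb = 0.5 * (dab + dbc - dac)
    vc = 0.5 * (dac + dbc - dab)
    root = TreeNode()
    for key, v in ((a, va), (b, vb), (c, vc)):
        child = nodes.pop(key)
        child.length = max(v, 0.0)
        root.append(child)
    return root


def _pairkey(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def tree_distance_matrix(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree."""
    return tree.tip_tip_distances()


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_phylip_dm(dm: DistanceMatrix, path: str | Path) -> None:
    """Write a distance matrix in PHYLIP square format."""
    with open(path, "w") as fh:
        fh.write(f"{dm.shape[0]}\n")
        for label in dm.ids:
            row = " ".join(f"{dm[label, other]:.9f}" for other in dm.ids)
            fh.write(f"{label} {row}\n")


def read_phylip_dm(path: str | Path) -> DistanceMatrix:
    with open(path) as fh:
        n = int(fh.readline())
        labels, rows = [], []
        for _ in range(n):
            parts = fh.readline().split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1 : n + 1]])
    return DistanceMatrix(np.array(rows), labels)


# ---------------------------------------------------------------------------
# Nearest reference and center-star stacking
# ---------------------------------------------------------------------------


def nearest_reference(
    query: ProteinRecord,
    references: Iterable[ProteinRecord],
    matrix_name: str = "PAM100",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> list[tuple[str, float]]:
    """References ranked by Jukes-Cantor distance to the query (ties by id)."""
    references = list(references)
    if not references:
        raise ValueError("reference set is empty")
    ranked = [
        (ref.id, jc_distance(global_align(query, ref, matrix_name, gap_open, gap_extend)))
        for ref in references
    ]
    ranked.sort(key=lambda t: (t[1], t[0]))
    return ranked


def center_star_rows(
    records: Sequence[ProteinRecord],
    matrix_name: str = "PAM100",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> list[str]:
    """Stack sequences into equal-length rows by center-star alignment.

    The medoid (minimum summed distance to the others) is the center; every
    other sequence is pairwise-aligned to it and the pairwise alignments are
    merged on the center's coordinates ("once a gap, always a gap").  The
    stack is a lightweight stand-in for a full progressive MSA, sufficient
    to feed consensus derivation.  Rows are returned in input order.
    """
    if not records:
        raise ValueError("no records")
    if len(records) == 1:
        return [records[0].residues]

    dm = distance_matrix(records, matrix_name, gap_open, gap_extend)
    sums = dm.data.sum(axis=1)
    center_idx = int(np.argmin(sums))
    center = records[center_idx]

    alignments = {}
    for i, rec in enumerate(records):
        if i == center_idx:
            continue
        alignments[i] = global_align(center, rec, matrix_name, gap_open, gap_extend)

    # insertion length needed before each center position (and at the end)
    n_center = len(center.residues)
    ins = [0] * (n_center + 1)
    parsed: dict[int, list[tuple[int, str]]] = {}
    for i, aln in alignments.items():
        rc, rs = aln.rows
        events: list[tuple[int, str]] = []  # (center_pos, other chunk) per slot
        cpos = 0
        chunk = ""
        for x, y in zip(rc, rs):
            if x == "-":
                chunk += y
            else:
                events.append((cpos, chunk))
                chunk = ""
                cpos += 1
        events.append((cpos, chunk))  # trailing insertion
        parsed[i] = events
        for cpos, chunk in events:
            ins[cpos] = max(ins[cpos], len(chunk))

    def project(events: list[tuple[int, str]], rc: str, rs: str) -> str:
        # rebuild the row on the merged coordinate system
        out = []
        residue_cols = [(x, y) for x, y in zip(rc, rs) if x != "-"]
        chunks = {cpos: chunk for cpos, chunk in events}
        for cpos in range(n_center + 1):
            chunk = chunks.get(cpos, "")
            out.append(chunk.ljust(ins[cpos], "-"))
            if cpos < n_center:
                out.append(residue_cols[cpos][1])
        return "".join(out)

    rows: list[str] = []
    for i, rec in enumerate(records):
        if i == center_idx:
            out = []
            for cpos in range(n_center + 1):
                out.append("-" * ins[cpos])
                if cpos < n_center:
                    out.append(center.residues[cpos])
            rows.append("".join(out))
        else:
            aln = alignments[i]
            rows.append(project(parsed[i], aln.rows[0], aln.rows[1]))
    return rows
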