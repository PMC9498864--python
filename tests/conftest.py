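"""Shared fixtures and independent oracles.

The oracles here are deliberately written as naive, direct computations
(sliding-window comparison, full enumeration of alignment paths, random
tree construction) so they stay independent of the library code paths they
check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from skbio import TreeNode

from cpfkit.motifkit import WILDCARDS
from cpfkit.util import AA20

# ---------------------------------------------------------------------------
# Motif-scanner oracle: naive sliding window, shared wildcard semantics
# ---------------------------------------------------------------------------


def naive_scan(sequence: str, pattern: str, max_mismatches: int = 0) -> list[tuple[int, int]]:
    """All (start, mismatches) matches by direct position-wise comparison."""
    out = []
    w = len(pattern)
    for start in range(len(sequence) - w + 1):
        mm = 0
        ok = True
        for offset in range(w):
            p = pattern[offset]
            s = sequence[start + offset]
            if p in WILDCARDS:
                if s not in WILDCARDS[p]:
                    ok = False
                    break
            elif s != p:
                mm += 1
        if ok and mm <= max_mismatches:
            out.append((start, mm))
    return out


def pattern_to_regex(pattern: str) -> str:
    """Expand a wildcard pattern to a plain regular expression (0-mismatch)."""
    parts = []
    for ch in pattern:
        if ch == "x":
            parts.append("[A-Z]")
        elif ch in WILDCARDS:
            parts.append("[" + "".join(sorted(WILDCARDS[ch])) + "]")
        else:
            parts.append(ch)
    return "".join(parts)


# ---------------------------------------------------------------------------
# Alignment oracle: full enumeration of global alignment paths
# ---------------------------------------------------------------------------


def enumerate_best_score(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Optimal global score by enumerating every alignment path.

    Affine costs: a gap of length L costs gap_open + (L-1)*gap_extend; end
    gaps are penalized.  Exponential: only usable for short sequences.
    """
    best = [-np.inf]

    def rec(i: int, j: int, last: str | None, score: float) -> None:
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "m", score + matrix[a[i], b[j]])
        if i < len(a):
            cost = gap_extend if last == "a" else gap_open
            rec(i + 1, j, "a", score - cost)
        if j < len(b):
            cost = gap_extend if last == "b" else gap_open
            rec(i, j + 1, "b", score - cost)

    rec(0, 0, None, 0.0)
    return best[0]


def all_sequences(alphabet: str, max_len: int):
    for n in range(1, max_len + 1):
        for tup in itertools.product(alphabet, repeat=n):
            yield "".join(tup)


# ---------------------------------------------------------------------------
# Random additive trees
# ---------------------------------------------------------------------------


def random_unrooted_tree(rng: np.random.Generator, n_leaves: int) -> TreeNode:
    """Random unrooted binary tree with branch lengths U(0.1, 2)."""
    nodes = [TreeNode(name=f"L{i}") for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(int(j))
        left = nodes.pop(int(i))
        left.length = float(rng.uniform(0.1, 2.0))
        right.length = float(rng.uniform(0.1, 2.0))
        parent = TreeNode()
        parent.extend([left, right])
        nodes.append(parent)
    root = TreeNode()
    for child in nodes:
        child.length = float(rng.uniform(0.1, 2.0))
        root.append(child)
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[frozenset[str]]]:
    """Non-trivial bipartitions of the leaf set induced by internal edges."""
    tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(tips) - 1:
            out.add(frozenset([side, tips - side]))
    return out


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def pam100():
    from cpfkit.phylokit import load_matrix

    return load_matrix("PAM100")


@pytest.fixture(scope="session")
def freq_fixture():
    """The default frequency fixture (seed 42): PCRY-like/DCRY/PPL/6-4 PL
    sets with main-text motifs planted at printed rates."""
    from cpfkit import synthetic_data as sd

    config = sd.default_simulation_config(42)
    sets = {}
    for profile in config.profiles:
        records, truth = sd.simulate_subfamily_set(profile, config.seed, library=config.library)
        sets[profile.subfamily] = (records, truth)
    return config, sets


def random_protein(rng: np.random.Generator, length: int, x_rate: float = 0.0) -> str:
    letters = list(AA20)
    seq = [letters[int(i)] for i in rng.integers(0, 20, size=length)]
    if x_rate > 0:
        for pos in range(length):
            if rng.random() < x_rate:
                seq[pos] = "X"
    return "".join(seq)


def random_pattern(rng: np.random.Generator, length: int) -> str:
    """Random valid motif pattern: first char concrete, >= half concrete."""
    letters = list(AA20)
    wild = ["x", "B", "J", "Z"]
    while True:
        chars = []
        for pos in range(length):
            if pos > 0 and rng.random() < 0.3:
                chars.append(wild[int(rng.integers(4))])
            else:
                chars.append(letters[int(rng.integers(20))])
        n_wild = sum(1 for c in chars if c in wild)
        if length - n_wild >= (length + 1) // 2:
            return "".join(chars)
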