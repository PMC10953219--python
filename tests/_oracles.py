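"""Independent oracles used by the tests.

Everything here is deliberately naive (enumeration, brute force, closed
form) and shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

_BASES = "ACGT"

# Standard genetic code, written out independently of the package.
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

SENSE = sorted(c for c, a in GENETIC_CODE.items() if a != "*")


def brute_sites(codon: str) -> tuple[float, float]:
    """Enumerate the nine single-nucleotide neighbours directly."""
    s = n = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            neighbour = codon[:pos] + base + codon[pos + 1:]
            if GENETIC_CODE[neighbour] == GENETIC_CODE[codon]:
                s += 1 / 3
            else:
                n += 1 / 3
    return s, n


def brute_pathways(a: str, b: str):
    """All-permutation pathway averaging, skipping stop intermediates."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    tallies = []
    for order in itertools.permutations(diff):
        cur, syn, non = a, 0, 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if GENETIC_CODE[nxt] == "*":
                ok = False
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            tallies.append((syn, non))
    if not tallies:
        return None
    return (sum(t[0] for t in tallies) / len(tallies),
            sum(t[1] for t in tallies) / len(tallies))


# ------------------------------------------------------- additive trees

class _Node:
    def __init__(self, name=None):
        self.name = name
        self.children = []   # (child, edge length)


def random_additive_tree(n_leaves: int, rng: np.random.Generator) -> _Node:
    nodes = [_Node(f"L{i:02d}") for i in range(n_leaves)]
    while len(nodes) > 1:
        idx = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = _Node()
        parent.children = [(nodes[idx[0]], rng.uniform(0.05, 1.0)),
                           (nodes[idx[1]], rng.uniform(0.05, 1.0))]
        nodes = [x for k, x in enumerate(nodes) if k not in idx] + [parent]
    return nodes[0]


def tree_path_distances(root: _Node) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}

    def walk(node) -> dict[str, float]:
        if not node.children:
            return {node.name: 0.0}
        maps = [{k: v + length for k, v in walk(child).items()}
                for child, length in node.children]
        for i in range(len(maps)):
            for j in range(i + 1, len(maps)):
                for x, dx in maps[i].items():
                    for y, dy in maps[j].items():
                        out[tuple(sorted((x, y)))] = dx + dy
        merged = {}
        for m in maps:
            merged.update(m)
        return merged

    walk(root)
    return out


def tree_bipartitions(root: _Node) -> set[frozenset[str]]:
    leaves = set()

    def collect(node):
        if not node.children:
            leaves.add(node.name)
        for child, _ in node.children:
            collect(child)

    collect(root)
    all_leaves = frozenset(leaves)
    anchor = min(all_leaves)
    splits = set()

    def below(node) -> frozenset:
        if not node.children:
            return frozenset([node.name])
        acc = frozenset()
        for child, _ in node.children:
            acc |= below(child)
        return acc

    def walk(node):
        for child, _ in node.children:
            side = below(child)
            if 2 <= len(side) <= len(all_leaves) - 2:
                splits.add(all_leaves - side if anchor in side else side)
            walk(child)

    walk(root)
    return splits


def nj_tree_path_distances(tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths of a package Tree object."""
    out: dict[tuple[str, str], float] = {}

    def walk(node) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: node.branch_length}
        maps = []
        for child in node.children:
            m = walk(child)
            if not child.is_leaf:
                m = {k: v + child.branch_length for k, v in m.items()}
            maps.append(m)
        for i in range(len(maps)):
            for j in range(i + 1, len(maps)):
                for x, dx in maps[i].items():
                    for y, dy in maps[j].items():
                        out[tuple(sorted((x, y)))] = dx + dy
        merged = {}
        for m in maps:
            merged.update(m)
        return merged

    walk(tree.root)
    return out


# ------------------------------------------------- brute-force alignment

def brute_global_score(a: str, b: str, matrix, gap_open: float,
                       gap_extend: float) -> float:
    """Exhaustive best global alignment score with affine gaps, by
    recursion over all alignments of two tiny sequences."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(matrix[a[i]][b[j]] + best(i + 1, j + 1, "m"))
        if i < len(a):
            cost = gap_extend if state == "a" else gap_open
            options.append(-cost + best(i + 1, j, "a"))
        if j < len(b):
            cost = gap_extend if state == "b" else gap_open
            options.append(-cost + best(i, j + 1, "b"))
        return max(options)

    return best(0, 0, "m")
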