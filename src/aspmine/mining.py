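"""Exhaustive enumeration of contiguous amino-acid patterns.

A *pattern* is a nonempty contiguous subsequence of a protein sequence.
Patterns are organized in a prefix tree: the children of pattern ``q`` are
the patterns ``q + c`` for each residue ``c``, and a child's support
(number of proteins containing it) never exceeds its parent's
(anti-monotonicity).  The tree is traversed depth-first with projected
occurrence lists: a node stores the end positions of all matches of its
pattern, and a child's occurrences are obtained by extending the parent's
by one residue.  Subtrees can be cut by a support threshold or by a
caller-supplied pruning predicate; anti-monotone predicates keep the
traversal exhaustive over the surviving patterns.

Support is document frequency: each protein counts at most once no matter
how many times the pattern occurs in it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .dataset import ProteinDataset

__all__ = [
    "SupportTriple",
    "TraversalStats",
    "Corpus",
    "count_support",
    "enumerate_patterns",
    "count_distinct_patterns",
    "count_distinct_patterns_naive",
    "possible_pattern_count",
]


@dataclass(frozen=True)
class SupportTriple:
    """Per-pattern protein counts: overall, among allergens, among nonallergens."""

    d_all: int
    d_pos: int
    d_neg: int

    def __post_init__(self):
        assert self.d_all == self.d_pos + self.d_neg


@dataclass
class TraversalStats:
    nodes_visited: int = 0
    subtrees_pruned: int = 0
    support_pruned: int = 0

    @property
    def pruning_rate(self) -> float:
        total = self.nodes_visited + self.subtrees_pruned
        return self.subtrees_pruned / total if total else 0.0


class Corpus:
    """Flattened numpy view of a dataset for fast projected-database mining.

    All sequences are concatenated into one uint8 array with a 0 sentinel
    after each protein (so rightward extension never crosses protein
    boundaries); parallel arrays map every position to its protein index.
    """

    def __init__(self, dataset: ProteinDataset):
        self.dataset = dataset
        seqs = dataset.sequences
        n_total = sum(len(s) for s in seqs) + len(seqs)
        text = np.zeros(n_total, dtype=np.uint8)
        prot = np.full(n_total, -1, dtype=np.int64)
        pos = 0
        starts = []
        for i, s in enumerate(seqs):
            starts.append(pos)
            b = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
            text[pos : pos + len(b)] = b
            prot[pos : pos + len(b)] = i
            pos += len(b) + 1  # sentinel 0
        self.text = text
        self.prot = prot
        self.starts = starts
        self.labels = dataset.labels
        self.pos_mask = self.labels == 1
        self.n_pos = int(self.pos_mask.sum())
        self.n_neg = len(dataset) - self.n_pos

    def pattern_at(self, end_pos: int, length: int) -> str:
        return self.text[end_pos - length : end_pos].tobytes().decode("ascii")


def count_support(dataset: ProteinDataset, pattern: str) -> SupportTriple:
    """Count proteins containing ``pattern`` as a contiguous substring, by class."""
    if not pattern:
        raise ValueError("pattern must be nonempty")
    d_pos = d_neg = 0
    for r in dataset:
        if pattern in r.sequence:
            if r.label == 1:
                d_pos += 1
            else:
                d_neg += 1
    return SupportTriple(d_pos + d_neg, d_pos, d_neg)


def _dfs(
    corpus: Corpus,
    min_support: int,
    max_length: Optional[int],
    handle: Callable[[int, np.ndarray, np.ndarray], bool],
    stats: TraversalStats,
) -> None:
    """Depth-first traversal core.

    ``handle(depth, end_positions, unique_protein_indices)`` is called once
    per pattern with ``d_all >= min_support``; a True return cuts the
    subtree.  Children are expanded in residue order (alphabetical), so the
    visit sequence is deterministic.
    """
    text = corpus.text
    prot = corpus.prot

    # stack of (depth, end_positions) pending expansion; children pushed in
    # reverse alphabetical order so they pop alphabetically
    root_pos = np.flatnonzero(text != 0)
    stack: list[tuple[int, np.ndarray]] = []

    def expand(depth: int, occ_next: np.ndarray) -> None:
        """Group candidate match-end positions by their residue; push children."""
        chars = text[occ_next]
        live = chars != 0
        occ_next = occ_next[live]
        chars = chars[live]
        if occ_next.size == 0:
            return
        order = np.argsort(chars, kind="stable")
        occ_sorted = occ_next[order]
        chars_sorted = chars[order]
        bounds = np.flatnonzero(np.diff(chars_sorted)) + 1
        groups = np.split(occ_sorted, bounds)
        for g in reversed(groups):
            stack.append((depth, g + 1))

    expand(1, root_pos)
    while stack:
        depth, occ = stack.pop()
        prots = np.unique(prot[occ - 1])
        if len(prots) < min_support:
            stats.support_pruned += 1
            continue
        stats.nodes_visited += 1
        if handle(depth, occ, prots):
            stats.subtrees_pruned += 1
            continue
        if max_length is None or depth < max_length:
            expand(depth + 1, occ)


def enumerate_patterns(
    dataset: ProteinDataset | Corpus,
    min_support: int = 1,
    max_length: Optional[int] = None,
    visit: Optional[Callable[[str, SupportTriple], None]] = None,
    prune: Optional[Callable[[str, SupportTriple], bool]] = None,
) -> TraversalStats:
    """Visit every pattern with support >= ``min_support`` exactly once.

    ``visit(pattern, support)`` is called for each surviving pattern in
    depth-first order; ``prune(pattern, support)`` returning True cuts the
    pattern's subtree (the pattern itself has already been visited).
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    corpus = dataset if isinstance(dataset, Corpus) else Corpus(dataset)
    pos_mask = corpus.pos_mask
    stats = TraversalStats()

    def handle(depth: int, occ: np.ndarray, prots: np.ndarray) -> bool:
        d_all = len(prots)
        d_pos = int(pos_mask[prots].sum())
        triple = SupportTriple(d_all, d_pos, d_all - d_pos)
        pattern = corpus.pattern_at(int(occ[0]), depth)
        if visit is not None:
            visit(pattern, triple)
        return bool(prune(pattern, triple)) if prune is not None else False

    _dfs(corpus, min_support, max_length, handle, stats)
    return stats


# ---------------------------------------------------------------------------
# Distinct-substring counting (generalized suffix automaton)
# ---------------------------------------------------------------------------


class _SuffixAutomaton:
    """Generalized suffix automaton over multiple strings.

    Each state represents an equivalence class of substrings; the number of
    distinct substrings of the whole collection is
    sum(len(v) - len(link(v))) over non-root states.
    """

    def __init__(self):
        self.link = [-1]
        self.length = [0]
        self.next: list[dict[str, int]] = [{}]

    def _clone(self, q: int, new_len: int) -> int:
        self.link.append(self.link[q])
        self.length.append(new_len)
        self.next.append(dict(self.next[q]))
        return len(self.link) - 1

    def _new_state(self, link: int, length: int) -> int:
        self.link.append(link)
        self.length.append(length)
        self.next.append({})
        return len(self.link) - 1

    def extend(self, last: int, c: str) -> int:
        # generalized construction: reuse existing transitions where possible
        if c in self.next[last]:
            q = self.next[last][c]
            if self.length[q] == self.length[last] + 1:
                return q
            clone = self._clone(q, self.length[last] + 1)
            self.link[q] = clone
            p = last
            while p != -1 and self.next[p].get(c) == q:
                self.next[p][c] = clone
                p = self.link[p]
            return clone
        cur = self._new_state(-1, self.length[last] + 1)
        p = last
        while p != -1 and c not in self.next[p]:
            self.next[p][c] = cur
            p = self.link[p]
        if p == -1:
            self.link[cur] = 0
            return cur
        q = self.next[p][c]
        if self.length[q] == self.length[p] + 1:
            self.link[cur] = q
            return cur
        clone = self._clone(q, self.length[p] + 1)
        self.link[q] = clone
        self.link[cur] = clone
        while p != -1 and self.next[p].get(c) == q:
            self.next[p][c] = clone
            p = self.link[p]
        return cur

    def add_string(self, s: str) -> None:
        last = 0
        for c in s:
            last = self.extend(last, c)

    def distinct_substrings(self) -> int:
        return sum(
            self.length[v] - self.length[self.link[v]] for v in range(1, len(self.link))
        )


def count_distinct_patterns(dataset: ProteinDataset | list[str]) -> int:
    """Number of distinct contiguous substrings across all sequences.

    Runs in time linear in total sequence length via a generalized suffix
    automaton, so it scales to datasets where the naive hash-set count
    (quadratic per sequence) is infeasible.
    """
    seqs = dataset if isinstance(dataset, list) else dataset.sequences
    sam = _SuffixAutomaton()
    for s in seqs:
        sam.add_string(s)
    return sam.distinct_substrings()


def count_distinct_patterns_naive(dataset: ProteinDataset | list[str]) -> int:
    """Hash-set oracle for :func:`count_distinct_patterns` (quadratic)."""
    seqs = dataset if isinstance(dataset, list) else dataset.sequences
    seen: set[str] = set()
    for s in seqs:
        for i in range(len(s)):
            for j in range(i + 1, len(s) + 1):
                seen.add(s[i:j])
    return len(seen)


def possible_pattern_count(alphabet_size: int, max_len: int) -> int:
    """Exact count of all strings of length 1..max_len over the alphabet."""
    if alphabet_size < 1 or max_len < 1:
        raise ValueError("alphabet_size and max_len must be >= 1")
    return sum(alphabet_size**k for k in range(1, max_len + 1))
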