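"""Concatenation of ASPs into maximal ConcASPs.

Two strings x and y admit an *overlapped concatenation* x' . w . y' when
x = x' . w and y = w . y' for some (possibly empty) overlap w.  A ConcASP
is a string that (i) occurs in at least one allergenic protein and (ii) is
an overlapped concatenation of any number of ASPs.  Within a witness
protein, every such chain corresponds to a run of ASP occurrence intervals
that pairwise overlap or abut, so the ConcASPs witnessed by a protein are
exactly the maximal unions of overlapping-or-adjacent ASP intervals.
After collecting candidates from all allergenic proteins, only maximal
strings are kept (candidates contained in another candidate are dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dataset import ProteinDataset

__all__ = [
    "ConcASPRecord",
    "MatchTable",
    "find_concasps",
    "maximal_filter",
    "exact_inclusion_match",
    "write_concasp_fasta",
    "write_concasp_table",
]


@dataclass
class ConcASPRecord:
    seq: str
    constituents: list[str] = field(default_factory=list)
    witnesses: list[tuple[str, int, int]] = field(default_factory=list)  # (protein_id, start, end)

    @property
    def length(self) -> int:
        return len(self.seq)


def _all_occurrences(pattern: str, text: str) -> list[tuple[int, int]]:
    """All (start, end) occurrences of pattern in text, overlaps included."""
    out = []
    i = text.find(pattern)
    while i != -1:
        out.append((i, i + len(pattern)))
        i = text.find(pattern, i + 1)
    return out


def find_concasps(asps: list[str], dataset: ProteinDataset) -> list[ConcASPRecord]:
    """Merge ASP occurrences within allergenic proteins into maximal ConcASPs."""
    if not asps:
        return []
    patterns = sorted(set(asps))
    by_seq: dict[str, ConcASPRecord] = {}
    for rec in dataset:
        if rec.label != 1:
            continue
        intervals: list[tuple[int, int, str]] = []
        for p in patterns:
            for s, e in _all_occurrences(p, rec.sequence):
                intervals.append((s, e, p))
        if not intervals:
            continue
        intervals.sort(key=lambda t: (t[0], t[1]))
        cur_s, cur_e = intervals[0][0], intervals[0][1]
        members = [intervals[0][2]]
        merged: list[tuple[int, int, list[str]]] = []
        for s, e, p in intervals[1:]:
            if s <= cur_e:  # overlap or abut
                cur_e = max(cur_e, e)
                members.append(p)
            else:
                merged.append((cur_s, cur_e, members))
                cur_s, cur_e, members = s, e, [p]
        merged.append((cur_s, cur_e, members))
        for s, e, members in merged:
            seq = rec.sequence[s:e]
            entry = by_seq.setdefault(seq, ConcASPRecord(seq))
            for m in members:
                if m not in entry.constituents:
                    entry.constituents.append(m)
            entry.witnesses.append((rec.id, s, e))

    keep = set(maximal_filter(list(by_seq)))
    records = [r for seq, r in by_seq.items() if seq in keep]
    records.sort(key=lambda r: (-r.length, r.seq))
    for r in records:
        r.constituents.sort()
    return records


def maximal_filter(candidates: list[str]) -> list[str]:
    """Drop every string that is a substring of another candidate.

    The output is pairwise substring-free and every input is contained in
    some output.  Sorted by decreasing length, then lexicographically.
    """
    unique = sorted(set(candidates), key=lambda s: (-len(s), s))
    accepted: list[str] = []
    for x in unique:
        if not any(x in y for y in accepted):
            accepted.append(x)
    return accepted


@dataclass
class MatchTable:
    matches: dict[str, list[str]]
    n_matched_queries: int
    n_matched_targets: int


def exact_inclusion_match(queries: list[str], targets: list[ConcASPRecord | str]) -> MatchTable:
    """For each query peptide, the ConcASPs containing it as a substring."""
    target_seqs = [t.seq if isinstance(t, ConcASPRecord) else t for t in targets]
    matches: dict[str, list[str]] = {}
    hit_targets: set[str] = set()
    for q in queries:
        hits = [t for t in target_seqs if q in t]
        matches[q] = hits
        hit_targets.update(hits)
    n_q = sum(1 for hits in matches.values() if hits)
    return MatchTable(matches, n_q, len(hit_targets))


def write_concasp_fasta(records: list[ConcASPRecord], path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(records, start=1):
            fh.write(
                f">concasp_{i} constituents={len(r.constituents)} witnesses={len(r.witnesses)}\n"
            )
            for j in range(0, len(r.seq), 60):
                fh.write(r.seq[j : j + 60] + "\n")


def write_concasp_table(records: list[ConcASPRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("seq\tlength\tn_constituents\tn_witnesses\n")
        for r in records:
            fh.write(f"{r.seq}\t{r.length}\t{len(r.constituents)}\t{len(r.witnesses)}\n")
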