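"""Selection of allergen-specific patterns (ASPs) among significant patterns.

A pattern is an ASP when

1. it occurs statistically significantly more often in allergenic than in
   nonallergenic proteins (two-tailed FET p-value below the WY-calibrated
   level delta, with higher empirical frequency on the allergen side),
2. it occurs in **no** nonallergenic protein, and
3. it is not attributable to a single biological category, i.e. it occurs
   (3a) in at least one paired category, or (3b) in at least two distinct
   positive-only categories.

Non-ASPs mirror the construction on the nonallergen side: significantly
more frequent in nonallergens (they may still occur in a few allergens),
and not category-specific — here taken as occurring in a paired category
or in at least two distinct categories overall.  Non-ASPs are used only as
predictive features, never reported as allergen motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dataset import CategoryProfile, ProteinDataset, classify_categories
from .mining import Corpus, SupportTriple, TraversalStats, _dfs
from .significance import FETCalculator, WYCalibration, adjusted_pvalue

__all__ = [
    "Candidate",
    "ASPRecord",
    "find_significant_patterns",
    "select_asps",
    "select_non_asps",
    "asp_report",
    "write_asp_table",
]


@dataclass
class Candidate:
    """A significant pattern before the ASP screen."""

    pattern: str
    support: SupportTriple
    p_raw: float
    protein_indices: np.ndarray


@dataclass
class ASPRecord:
    pattern: str
    support: SupportTriple
    p_raw: float
    p_adj: Optional[float]
    cond2: bool
    cond3a: bool
    cond3b: bool
    categories: list[str] = field(default_factory=list)
    direction: str = "allergen_enriched"
    protein_ids: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.pattern)


def find_significant_patterns(
    dataset: ProteinDataset | Corpus,
    delta: float,
    direction: str = "allergen",
    min_support: int = 1,
    max_length: Optional[int] = None,
) -> tuple[list[Candidate], TraversalStats]:
    """Mine all patterns with raw FET p-value < delta, enriched on one side.

    Subtrees are pruned when the label-free lower bound on descendant
    p-values already exceeds delta, so the search touches only a small
    corner of the pattern tree when delta is stringent.
    """
    if not 0 < delta <= 1:
        raise ValueError("delta must be in (0, 1]")
    if direction not in ("allergen", "nonallergen"):
        raise ValueError("direction must be 'allergen' or 'nonallergen'")
    corpus = dataset if isinstance(dataset, Corpus) else Corpus(dataset)
    fet = FETCalculator(corpus.n_pos, corpus.n_neg)
    pos_mask = corpus.pos_mask
    n_pos, n_neg = corpus.n_pos, corpus.n_neg
    out: list[Candidate] = []
    stats = TraversalStats()

    def handle(depth: int, occ: np.ndarray, prots: np.ndarray) -> bool:
        d_all = len(prots)
        if fet.lower_bound(d_all) > delta:
            return True
        d_pos = int(pos_mask[prots].sum())
        d_neg = d_all - d_pos
        p = fet.pvalue(d_all, d_pos)
        if p < delta:
            if direction == "allergen":
                enriched = d_pos * n_neg > d_neg * n_pos
            else:
                enriched = d_neg * n_pos > d_pos * n_neg
            if enriched:
                out.append(
                    Candidate(
                        corpus.pattern_at(int(occ[0]), depth),
                        SupportTriple(d_all, d_pos, d_neg),
                        p,
                        prots.copy(),
                    )
                )
        return False

    _dfs(corpus, min_support, max_length, handle, stats)
    return out, stats


def _annotate(
    cand: Candidate,
    dataset: ProteinDataset,
    profile: CategoryProfile,
    calibration: Optional[WYCalibration],
    direction: str,
) -> ASPRecord:
    cats = sorted({dataset[i].category for i in cand.protein_indices})
    cond3a = any(profile.type_of(c) == "paired" for c in cats)
    cond3b = sum(1 for c in cats if profile.type_of(c) == "positive_only") >= 2
    return ASPRecord(
        pattern=cand.pattern,
        support=cand.support,
        p_raw=cand.p_raw,
        p_adj=adjusted_pvalue(cand.p_raw, calibration) if calibration else None,
        cond2=cand.support.d_neg == 0,
        cond3a=cond3a,
        cond3b=cond3b,
        categories=cats,
        direction=direction,
        protein_ids=[dataset[i].id for i in cand.protein_indices],
    )


def select_asps(
    candidates: list[Candidate],
    dataset: ProteinDataset,
    profile: Optional[CategoryProfile] = None,
    calibration: Optional[WYCalibration] = None,
) -> list[ASPRecord]:
    """Apply the ASP screen (conditions 2 and 3a/3b) to allergen-enriched
    significant patterns."""
    profile = profile or classify_categories(dataset)
    records = []
    for cand in candidates:
        rec = _annotate(cand, dataset, profile, calibration, "allergen_enriched")
        if rec.cond2 and (rec.cond3a or rec.cond3b):
            records.append(rec)
    return records


def select_non_asps(
    candidates: list[Candidate],
    dataset: ProteinDataset,
    profile: Optional[CategoryProfile] = None,
    calibration: Optional[WYCalibration] = None,
) -> list[ASPRecord]:
    """Apply the category-specificity screen to nonallergen-enriched
    patterns: keep those seen in a paired category or in >= 2 distinct
    categories overall."""
    profile = profile or classify_categories(dataset)
    records = []
    for cand in candidates:
        rec = _annotate(cand, dataset, profile, calibration, "nonallergen_enriched")
        if rec.cond3a or len(rec.categories) >= 2:
            records.append(rec)
    return records


def asp_report(records: list[ASPRecord]) -> dict:
    """Summary distributions of a mined ASP set.

    Returns histogram tables for pattern length, adjusted p-value, support,
    ASPs-per-protein (over proteins containing at least one ASP), and
    categories-per-ASP.
    """
    length_hist: dict[int, int] = {}
    support_hist: dict[int, int] = {}
    ncat_hist: dict[int, int] = {}
    per_protein: dict[str, int] = {}
    p_adj_values = []
    for r in records:
        length_hist[r.length] = length_hist.get(r.length, 0) + 1
        support_hist[r.support.d_all] = support_hist.get(r.support.d_all, 0) + 1
        ncat_hist[len(r.categories)] = ncat_hist.get(len(r.categories), 0) + 1
        for pid in r.protein_ids:
            per_protein[pid] = per_protein.get(pid, 0) + 1
        if r.p_adj is not None:
            p_adj_values.append(r.p_adj)
    asps_per_protein: dict[int, int] = {}
    for cnt in per_protein.values():
        asps_per_protein[cnt] = asps_per_protein.get(cnt, 0) + 1
    if p_adj_values:
        counts, edges = np.histogram(p_adj_values, bins=10, range=(0.0, 1.0))
        p_adj_hist = {"counts": counts.tolist(), "edges": edges.tolist()}
    else:
        p_adj_hist = {"counts": [], "edges": []}
    return {
        "n_records": len(records),
        "length": dict(sorted(length_hist.items())),
        "support": dict(sorted(support_hist.items())),
        "categories_per_pattern": dict(sorted(ncat_hist.items())),
        "patterns_per_protein": dict(sorted(asps_per_protein.items())),
        "p_adj_histogram": p_adj_hist,
    }


def write_asp_table(records: list[ASPRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "pattern\tlength\td_all\td_pos\td_neg\tp_raw\tp_adj\t"
            "cond2\tcond3a\tcond3b\tn_categories\tcategories\n"
        )
        for r in records:
            p_adj = "" if r.p_adj is None else f"{r.p_adj:.6g}"
            fh.write(
                f"{r.pattern}\t{r.length}\t{r.support.d_all}\t{r.support.d_pos}\t"
                f"{r.support.d_neg}\t{r.p_raw:.6g}\t{p_adj}\t"
                f"{int(r.cond2)}\t{int(r.cond3a)}\t{int(r.cond3b)}\t"
                f"{len(r.categories)}\t{';'.join(r.categories)}\n"
            )
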