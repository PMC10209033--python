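"""Model/Results facade over the mining + calibration + selection pipeline.

``PatternSignificanceModel`` is constructed from a labeled, categorized
protein dataset and holds the study design (FWER level alpha, number of
label permutations M, support threshold, random seed).  ``fit()`` runs the
Westfall-Young calibration, mines the significant patterns on both sides,
applies the ASP / non-ASP screens, concatenates ASPs into maximal
ConcASPs, and returns a ``PatternSignificanceResults`` carrying the
adjusted significance level delta, the selected pattern records with
adjusted p-values, and a printable summary table.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .dataset import ProteinDataset, ProteinRecord, classify_categories, dataset_summary
from .mining import Corpus
from .significance import WYCalibration, generate_permutations, wy_calibrate
from .asp import ASPRecord, asp_report, find_significant_patterns, select_asps, select_non_asps
from .concasp import ConcASPRecord, find_concasps

__all__ = ["PatternSignificanceModel", "PatternSignificanceResults"]


class PatternSignificanceModel:
    """Significant-pattern mining model for a labeled protein dataset.

    Parameters
    ----------
    dataset
        The labeled, categorized protein collection.
    alpha
        Target family-wise error rate (default 0.05).
    m_perms
        Number of label permutations M for the Westfall-Young calibration
        (default 1000; 10,000 is typical at full scale).
    min_support
        Minimum number of proteins a pattern must occur in to be tested.
    seed
        Seed for the permutation plan (required for a reproducible fit).
    """

    def __init__(
        self,
        dataset: ProteinDataset,
        alpha: float = 0.05,
        m_perms: int = 1000,
        min_support: int = 1,
        max_length: Optional[int] = None,
        seed: int = 0,
    ):
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.dataset = dataset
        self.alpha = alpha
        self.m_perms = m_perms
        self.min_support = min_support
        self.max_length = max_length
        self.seed = seed
        self.profile = classify_categories(dataset)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "PatternSignificanceModel":
        """Build from a DataFrame with columns id, sequence, category, label."""
        records = [
            ProteinRecord(str(r.id), str(r.sequence).upper(), str(r.category), int(r.label))
            for r in df.itertuples(index=False)
        ]
        return cls(ProteinDataset(records), **kwargs)

    def fit(self, prune_level: str = "distribution") -> "PatternSignificanceResults":
        corpus = Corpus(self.dataset)
        plan = generate_permutations(self.dataset, self.m_perms, self.seed)
        calibration = wy_calibrate(
            corpus, plan, alpha=self.alpha, min_support=self.min_support,
            prune_level=prune_level,
        )
        delta = calibration.delta
        pos_cands, pos_stats = find_significant_patterns(
            corpus, delta, "allergen", self.min_support, self.max_length
        )
        neg_cands, _ = find_significant_patterns(
            corpus, delta, "nonallergen", self.min_support, self.max_length
        )
        asps = select_asps(pos_cands, self.dataset, self.profile, calibration)
        non_asps = select_non_asps(neg_cands, self.dataset, self.profile, calibration)
        concasps = find_concasps([r.pattern for r in asps], self.dataset)
        return PatternSignificanceResults(
            self, calibration, asps, non_asps, concasps,
            n_significant_allergen=len(pos_cands),
            n_significant_nonallergen=len(neg_cands),
        )


class PatternSignificanceResults:
    """Fit results: calibration, selected patterns, and summaries."""

    def __init__(
        self,
        model: PatternSignificanceModel,
        calibration: WYCalibration,
        asps: list[ASPRecord],
        non_asps: list[ASPRecord],
        concasps: list[ConcASPRecord],
        n_significant_allergen: int,
        n_significant_nonallergen: int,
    ):
        self.model = model
        self.calibration = calibration
        self.asps = asps
        self.non_asps = non_asps
        self.concasps = concasps
        self.n_significant_allergen = n_significant_allergen
        self.n_significant_nonallergen = n_significant_nonallergen

    @property
    def delta(self) -> float:
        return self.calibration.delta

    def asp_table(self) -> pd.DataFrame:
        rows = [
            {
                "pattern": r.pattern,
                "length": r.length,
                "d_all": r.support.d_all,
                "d_pos": r.support.d_pos,
                "d_neg": r.support.d_neg,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "cond2": r.cond2,
                "cond3a": r.cond3a,
                "cond3b": r.cond3b,
                "categories": ";".join(r.categories),
            }
            for r in self.asps
        ]
        return pd.DataFrame(rows)

    def report(self) -> dict:
        return asp_report(self.asps)

    def summary(self) -> str:
        ds = dataset_summary(self.model.dataset)
        cal = self.calibration
        lines = [
            "Allergen-specific pattern mining results",
            "=" * 56,
            f"proteins                 {ds['n']} ({ds['n_pos']} allergen / {ds['n_neg']} nonallergen)",
            f"categories               {ds['n_categories']} "
            f"(paired {ds['category_types']['paired']}, "
            f"positive-only {ds['category_types']['positive_only']}, "
            f"negative-only {ds['category_types']['negative_only']})",
            f"sequence length          mean {ds['mean_length']:.1f}, "
            f"min {ds['min_length']}, max {ds['max_length']}",
            "-" * 56,
            f"FWER level alpha         {cal.alpha}",
            f"permutations M           {cal.m_perms} (seed {self.model.seed})",
            f"adjusted level delta     {cal.delta:.4g}",
            f"estimated FWER           {cal.fwer_estimate:.4g}",
            f"tree nodes visited       {cal.stats.nodes_visited}",
            f"subtrees pruned          {cal.stats.subtrees_pruned}",
            "-" * 56,
            f"significant (allergen)   {self.n_significant_allergen}",
            f"significant (nonallerg.) {self.n_significant_nonallergen}",
            f"ASPs                     {len(self.asps)}",
            f"non-ASPs                 {len(self.non_asps)}",
            f"ConcASPs                 {len(self.concasps)}",
        ]
        if self.concasps:
            n15 = sum(1 for c in self.concasps if c.length >= 15)
            lines.append(f"ConcASPs length >= 15    {n15}")
        if self.asps:
            lens = [r.length for r in self.asps]
            lines.append(
                f"ASP length               median {int(np.median(lens))}, "
                f"range {min(lens)}-{max(lens)}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<PatternSignificanceResults: {len(self.asps)} ASPs, "
            f"{len(self.non_asps)} non-ASPs, delta={self.delta:.3g}>"
        )
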