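"""Synthetic labeled protein datasets with known ground truth.

The generator emulates the category taxonomy of real allergen databases —
paired categories holding both classes, positive-only categories holding
only allergens, a negative-only category — with i.i.d. background residues
and optional planted motifs.  A planted motif overwrites a uniformly
chosen window (length-preserving, so motif planting cannot leak into the
sequence-length distribution), independently per protein, with a
class-specific insertion probability in its eligible categories.  The
ground truth records every realized insertion so tests can verify recovery
and count calibration exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np

from .dataset import ProteinDataset, ProteinRecord

__all__ = [
    "AMINO_ACIDS",
    "CategorySpec",
    "PlantedMotif",
    "GeneratorConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_null_replicates",
    "small_profile",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class CategorySpec:
    name: str
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class PlantedMotif:
    seq: str
    p_pos: float  # insertion probability per allergenic protein
    p_neg: float = 0.0  # insertion probability per nonallergenic protein
    categories: Optional[tuple[str, ...]] = None  # None = all categories eligible

    def eligible(self, category: str) -> bool:
        return self.categories is None or category in self.categories


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int
    categories: tuple[CategorySpec, ...]
    length_min: int = 50
    length_max: int = 150
    background: Optional[tuple[float, ...]] = None  # default uniform over 20 residues
    motifs: tuple[PlantedMotif, ...] = ()

    def validate(self) -> None:
        if self.length_min < 1 or self.length_max < self.length_min:
            raise ValueError("invalid length range")
        if self.background is not None:
            bg = np.asarray(self.background)
            if len(bg) != len(AMINO_ACIDS) or not np.isclose(bg.sum(), 1.0):
                raise ValueError("background must be a 20-vector summing to 1")
        for m in self.motifs:
            if not 0 <= m.p_pos <= 1 or not 0 <= m.p_neg <= 1:
                raise ValueError(f"motif {m.seq}: probabilities must be in [0, 1]")
            if not set(m.seq) <= set(AMINO_ACIDS):
                raise ValueError(f"motif {m.seq}: letters outside the amino-acid alphabet")
            if len(m.seq) > self.length_min:
                raise ValueError(f"motif {m.seq} longer than minimum sequence length")


@dataclass
class GroundTruth:
    #: motif seq -> {"pos": int, "neg": int, "by_category": {name: count}}
    motif_counts: dict[str, dict] = field(default_factory=dict)
    #: protein id -> list of (motif seq, start position)
    insertions: dict[str, list[tuple[str, int]]] = field(default_factory=dict)


def generate_dataset(config: GeneratorConfig) -> tuple[ProteinDataset, GroundTruth]:
    """Draw one dataset; fully reproducible from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    bg = (
        np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
        if config.background is None
        else np.asarray(config.background, dtype=float)
    )
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    truth = GroundTruth(
        motif_counts={
            m.seq: {"pos": 0, "neg": 0, "by_category": {}} for m in config.motifs
        }
    )
    records = []
    idx = 0
    for cat in config.categories:
        for label, count in ((1, cat.n_pos), (-1, cat.n_neg)):
            for _ in range(count):
                rid = f"p{idx:05d}"
                idx += 1
                length = int(rng.integers(config.length_min, config.length_max + 1))
                seq_arr = rng.choice(alphabet, size=length, p=bg)
                occupied: list[tuple[int, int]] = []
                for m in config.motifs:
                    if not m.eligible(cat.name):
                        continue
                    p = m.p_pos if label == 1 else m.p_neg
                    if p <= 0 or rng.random() >= p:
                        continue
                    mlen = len(m.seq)
                    start = _place_window(rng, length, mlen, occupied)
                    if start is None:
                        continue  # no non-overlapping slot left
                    occupied.append((start, start + mlen))
                    seq_arr[start : start + mlen] = np.frombuffer(
                        m.seq.encode(), dtype=np.uint8
                    )
                    mc = truth.motif_counts[m.seq]
                    mc["pos" if label == 1 else "neg"] += 1
                    mc["by_category"][cat.name] = mc["by_category"].get(cat.name, 0) + 1
                    truth.insertions.setdefault(rid, []).append((m.seq, start))
                records.append(
                    ProteinRecord(rid, seq_arr.tobytes().decode("ascii"), cat.name, label)
                )
    return ProteinDataset(records), truth


def _place_window(rng, length: int, mlen: int, occupied: list[tuple[int, int]]) -> Optional[int]:
    """Uniform start for a window of mlen avoiding already-planted windows."""
    free = [
        s
        for s in range(length - mlen + 1)
        if all(s + mlen <= a or s >= b for a, b in occupied)
    ]
    if not free:
        return None
    return int(free[rng.integers(len(free))])


def generate_null_replicates(
    config: GeneratorConfig, n_replicates: int
) -> Iterator[tuple[ProteinDataset, GroundTruth]]:
    """Independent label-sequence-independent datasets, deterministic from
    the master seed (one derived seed per replicate)."""
    if config.motifs:
        raise ValueError("null replicates require a config without planted motifs")
    rng = np.random.default_rng(config.seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    for s in child_seeds:
        yield generate_dataset(replace(config, seed=int(s)))


def small_profile(
    seed: int = 0,
    motifs: Sequence[PlantedMotif] = (),
    n_paired: int = 5,
    n_positive_only: int = 4,
    paired_size: tuple[int, int] = (10, 10),
    positive_only_size: int = 10,
    negative_only_size: int = 20,
    length_range: tuple[int, int] = (50, 150),
) -> GeneratorConfig:
    """Desk-scale profile mirroring the paired / positive-only /
    negative-only category taxonomy of real allergen datasets."""
    cats = [CategorySpec(f"paired_{i}", *paired_size) for i in range(n_paired)]
    cats += [CategorySpec(f"posonly_{i}", positive_only_size, 0) for i in range(n_positive_only)]
    cats += [CategorySpec("negonly_0", 0, negative_only_size)]
    return GeneratorConfig(
        seed=seed,
        categories=tuple(cats),
        length_min=length_range[0],
        length_max=length_range[1],
        motifs=tuple(motifs),
    )
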