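"""Strain-level phenotypes: spore viability, MI nondisjunction, conversions.

Meiosis I nondisjunction sends both homologs to one pole; after the second
division this yields two disomic spores (carrying both parental centromere
alleles — a BOTH call at centromere-linked markers) and two nullisomic, dead
spores, so an elevated nondisjunction rate shows up both as a preponderance
of two- and zero-viable-spore tetrads and as spores calling BOTH at the
centromere-linked marker(s).

Gene conversion is scored as non-reciprocal 3:1 or 1:3 segregation of a
single marker; 4:0/0:4 patterns are tallied separately as irregular rather
than counted as conversions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .model import (
    BOTH,
    MarkerMap,
    Tetrad,
    TetradError,
    calls_matrix,
    segregation_pattern_table,
)
from .mapping import tetrad_crossover_counts

__all__ = [
    "ViabilityDistribution", "DisomeRecord", "DisomeScore", "ConversionCrossTab",
    "viability_distribution", "score_disomes", "conversion_crosstab",
]


@dataclass
class ViabilityDistribution:
    """Tetrad counts by number of viable spores, plus spore-level viability."""

    counts: dict[int, int]  # {4: n4, 3: n3, 2: n2, 1: n1, 0: n0}
    total_tetrads: int
    total_spores: int
    viable_spores: int

    @property
    def viability_pct(self) -> float:
        return 100.0 * self.viable_spores / self.total_spores if self.total_spores else float("nan")


@dataclass(frozen=True)
class DisomeRecord:
    tetrad_id: str
    disomic_spores: tuple[str, ...]


@dataclass
class DisomeScore:
    records: list[DisomeRecord]
    n_tetrads: int

    @property
    def n_flagged(self) -> int:
        return len(self.records)

    @property
    def fraction(self) -> float:
        return self.n_flagged / self.n_tetrads if self.n_tetrads else float("nan")


@dataclass
class ConversionCrossTab:
    """2×2 cross-tabulation of E0 membership × detectable gene conversion."""

    table: np.ndarray  # rows: (E0, exchange); cols: (conversion, none)
    p_value: float     # Fisher's exact (two-sided)
    n_irregular: int   # tetrads with a 4:0/0:4 marker, reported separately
    n_unclassified: int

    @property
    def n(self) -> int:
        return int(self.table.sum())

    @property
    def conversion_fraction(self) -> float:
        return float(self.table[:, 0].sum()) / self.n if self.n else float("nan")

    @property
    def e0_conversion_fraction(self) -> float:
        row = self.table[0]
        return float(row[0]) / row.sum() if row.sum() else float("nan")

    @property
    def exchange_conversion_fraction(self) -> float:
        row = self.table[1]
        return float(row[0]) / row.sum() if row.sum() else float("nan")


def viability_distribution(tetrads: Sequence[Tetrad]) -> ViabilityDistribution:
    """Exact integer viability tallies (round only at presentation)."""
    counts = {k: 0 for k in (4, 3, 2, 1, 0)}
    for t in tetrads:
        counts[t.n_viable] += 1
    total = len(tetrads)
    viable = sum(k * v for k, v in counts.items())
    return ViabilityDistribution(
        counts=counts,
        total_tetrads=total,
        total_spores=4 * total,
        viable_spores=viable,
    )


def score_disomes(
    tetrads: Sequence[Tetrad],
    mmap: MarkerMap,
    cen_markers: Sequence[str] | str | None = None,
    max_cen_distance_cM: float = 10.0,
) -> DisomeScore:
    """Flag spores disomic for the chromosome via centromere-linked markers.

    A spore is disomic iff it is viable and calls BOTH at every designated
    centromere-linked marker. In origin coding a heteroallelic marker pair
    inserted at the same centromeric locus collapses to a single marker, so
    one or more marker names are accepted; the default is the marker at the
    map's centromere index. Markers far from the centromere would confound
    nondisjunction with crossing-over, hence the distance warning.
    """
    if cen_markers is None:
        cen_markers = [mmap.names[mmap.centromere_index]]
    elif isinstance(cen_markers, str):
        cen_markers = [cen_markers]
    idx = [mmap.index(m) for m in cen_markers]
    cen_pos = mmap.positions[mmap.centromere_index]
    far = [m for m, i in zip(cen_markers, idx) if abs(mmap.positions[i] - cen_pos) > max_cen_distance_cM]
    if far:
        warnings.warn(
            f"markers {far} are >{max_cen_distance_cM:g} cM from the centromere; "
            "disome scoring assumes tight centromere linkage",
            stacklevel=2,
        )
    records = []
    for t in tetrads:
        disomic = tuple(
            s.spore_id
            for s in t.spores
            if s.viable and all(s.calls[i] == BOTH for i in idx)
        )
        if disomic:
            records.append(DisomeRecord(t.tetrad_id, disomic))
    return DisomeScore(records=records, n_tetrads=len(tetrads))


def conversion_crosstab(tetrads: Sequence[Tetrad], mmap: MarkerMap) -> ConversionCrossTab:
    """Cross-tabulate non-exchange (E0) status against gene conversion.

    Conversion = any marker segregating 3:1 or 1:3 among the four viable
    spores. E0 status uses minimal crossover counts summed over the
    intervals that remain scorable (a converted marker only blinds its two
    flanking intervals, it does not discard the tetrad). Tetrads that are
    dead, disomic or otherwise yield no scorable interval are excluded from
    the table and counted in ``n_unclassified``. Association is tested with
    Fisher's exact test.
    """
    if len(tetrads) == 0:
        raise TetradError("empty tetrad collection")
    C, V = calls_matrix(tetrads)
    pat = segregation_pattern_table(C, V)
    conv = ((pat == 1) | (pat == 2)).any(axis=1)  # 3:1 or 1:3 anywhere
    irregular = ((pat == 3) | (pat == 4)).any(axis=1)  # 4:0 or 0:4
    counts, valid = tetrad_crossover_counts(
        tetrads, mmap, filter_policy="none", drop="interval"
    )
    e0 = valid & (counts == 0)
    ex = valid & (counts > 0)
    table = np.array(
        [
            [int((e0 & conv).sum()), int((e0 & ~conv).sum())],
            [int((ex & conv).sum()), int((ex & ~conv).sum())],
        ]
    )
    p = float(stats.fisher_exact(table)[1]) if table.sum() else float("nan")
    return ConversionCrossTab(
        table=table,
        p_value=p,
        n_irregular=int(irregular[valid].sum()),
        n_unclassified=int((~valid).sum()),
    )
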