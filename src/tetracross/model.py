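"""Domain types and classification for four-spore tetrads.

A tetrad is the set of four haploid spores from one yeast meiosis, each
genotyped at an ordered set of markers along a chromosome. Marker calls are
parental-origin coded: ``P1``/``P2`` name the two parental haplotypes, ``BOTH``
encodes a disomic spore carrying both parental alleles (the signature of
meiosis I nondisjunction), and ``MISSING`` marks dead or unscorable spores.
Keeping the statistics origin-coded leaves allele-name bookkeeping (URA3 vs
ura3 and so on) to the I/O layer.

Two classifications drive everything downstream:

* per-marker segregation (2:2 is Mendelian; 3:1/1:3 flag gene conversion);
* per-interval ditype class — parental ditype (PD), tetratype (TT) and
  non-parental ditype (NPD), the inputs to the Perkins map-distance and
  Papazian interference estimators.

The ditype class codes are chosen so that the code *is* the minimal number of
crossovers implied by the class (PD=0, TT=1, NPD=2), which makes crossover-
class (E0, E1, ...) reconstruction a row sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "P1", "P2", "BOTH", "MISSING",
    "CALL_CHARS", "CHAR_TO_CALL",
    "PD", "TT", "NPD", "UNSCORABLE", "CLASS_NAMES",
    "MarkerMap", "SporeGenotype", "Tetrad",
    "SegregationClass", "DitypeClass", "IntervalTally",
    "calls_matrix", "segregation_pattern_table", "mendelian_matrix",
    "score_segregation", "classify_interval", "interval_class_matrix",
    "tally_intervals",
]

# Allele-call codes (int8 throughout).
P1: int = 0
P2: int = 1
BOTH: int = 2
MISSING: int = 3

#: single-character codes used in the tetrad-table TSV format
CALL_CHARS = "PMB-"
CHAR_TO_CALL = {c: i for i, c in enumerate(CALL_CHARS)}

# Ditype class codes. PD/TT/NPD double as minimal crossover counts.
PD: int = 0
TT: int = 1
NPD: int = 2
UNSCORABLE: int = 3
CLASS_NAMES = ("PD", "TT", "NPD", "UNSCORABLE")

_SEG_PATTERNS = ("2:2", "3:1", "1:3", "4:0", "0:4", "aberrant")
_SEG_CODE = {(2, 2): 0, (3, 1): 1, (1, 3): 2, (4, 0): 3, (0, 4): 4}


class TetradError(ValueError):
    """Invalid tetrad data or marker lookup."""


@dataclass(frozen=True)
class MarkerMap:
    """Ordered markers with genetic positions along one chromosome.

    Positions are cM from the left-most marker and must be strictly
    increasing. ``centromere_index`` locates the centromere within the marker
    order; it may coincide with a centromere-linked marker.
    """

    chromosome_id: str
    names: tuple[str, ...]
    positions_cM: tuple[float, ...]
    centromere_index: int = 0

    def __post_init__(self) -> None:
        if len(self.names) < 2:
            raise TetradError("a marker map needs at least two markers")
        if len(self.names) != len(self.positions_cM):
            raise TetradError("names and positions differ in length")
        if len(set(self.names)) != len(self.names):
            raise TetradError("duplicate marker names")
        pos = np.asarray(self.positions_cM, dtype=float)
        if (pos < 0).any() or not (np.diff(pos) > 0).all():
            raise TetradError("positions must be non-negative and strictly increasing")
        if not 0 <= self.centromere_index < len(self.names):
            raise TetradError("centromere_index out of range")

    @classmethod
    def from_markers(
        cls,
        chromosome_id: str,
        markers: Iterable[tuple[str, float]],
        centromere_index: int = 0,
    ) -> "MarkerMap":
        names, pos = zip(*markers)
        return cls(chromosome_id, tuple(names), tuple(float(p) for p in pos), centromere_index)

    @property
    def n_markers(self) -> int:
        return len(self.names)

    @property
    def positions(self) -> np.ndarray:
        return np.asarray(self.positions_cM, dtype=float)

    @property
    def intervals(self) -> tuple[tuple[str, str], ...]:
        """Adjacent marker pairs, left to right."""
        return tuple(zip(self.names[:-1], self.names[1:]))

    @property
    def interval_lengths_cM(self) -> np.ndarray:
        return np.diff(self.positions)

    @property
    def total_cM(self) -> float:
        return float(self.positions_cM[-1] - self.positions_cM[0])

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise TetradError(f"unknown marker {name!r} on {self.chromosome_id}") from None

    def interval_index(self, interval: tuple[str, str]) -> int:
        a, b = sorted((self.index(interval[0]), self.index(interval[1])))
        if b - a != 1:
            raise TetradError(f"{interval} is not an adjacent-marker interval")
        return a


@dataclass
class SporeGenotype:
    """One spore: identity, viability and per-marker origin calls."""

    spore_id: str
    viable: bool
    calls: np.ndarray  # int8, one call per marker

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 1:
            raise TetradError("calls must be a 1-D vector")
        if ((self.calls < 0) | (self.calls > 3)).any():
            raise TetradError("calls must be in {P1, P2, BOTH, MISSING}")

    @classmethod
    def from_codes(cls, spore_id: str, viable: bool, codes: str) -> "SporeGenotype":
        try:
            calls = np.fromiter((CHAR_TO_CALL[c] for c in codes), dtype=np.int8, count=len(codes))
        except KeyError as exc:
            raise TetradError(f"unknown allele code {exc.args[0]!r}") from None
        return cls(spore_id, viable, calls)

    def to_codes(self) -> str:
        return "".join(CALL_CHARS[c] for c in self.calls)

    def effective_calls(self, override_dead: bool = False) -> np.ndarray:
        """Calls as seen by classification: dead spores read as MISSING."""
        if self.viable or override_dead:
            return self.calls
        return np.full_like(self.calls, MISSING)


@dataclass
class Tetrad:
    """Exactly four spores from a single meiosis."""

    tetrad_id: str
    spores: tuple[SporeGenotype, SporeGenotype, SporeGenotype, SporeGenotype]

    def __post_init__(self) -> None:
        self.spores = tuple(self.spores)  # type: ignore[assignment]
        if len(self.spores) != 4:
            raise TetradError(f"tetrad {self.tetrad_id!r} must have exactly four spores")
        ids = [s.spore_id for s in self.spores]
        if len(set(ids)) != 4:
            raise TetradError(f"tetrad {self.tetrad_id!r} has duplicate spore ids")
        n_markers = {s.calls.size for s in self.spores}
        if len(n_markers) != 1:
            raise TetradError(f"tetrad {self.tetrad_id!r} has inconsistent marker counts")

    @property
    def n_viable(self) -> int:
        return sum(s.viable for s in self.spores)

    @property
    def n_markers(self) -> int:
        return self.spores[0].calls.size


@dataclass(frozen=True)
class SegregationClass:
    marker: str
    pattern: str  # one of _SEG_PATTERNS


@dataclass(frozen=True)
class DitypeClass:
    interval: tuple[str, str]
    klass: str  # PD / TT / NPD / UNSCORABLE


@dataclass
class IntervalTally:
    """PD/NPD/TT counts for one marker interval (Perkins/Papazian input)."""

    interval: tuple[str, str]
    PD: int
    NPD: int
    TT: int
    unscorable: int = 0

    def __post_init__(self) -> None:
        if min(self.PD, self.NPD, self.TT, self.unscorable) < 0:
            raise TetradError("tally counts must be non-negative")

    @property
    def n(self) -> int:
        """Scorable tetrads: PD + NPD + TT."""
        return self.PD + self.NPD + self.TT


# ---------------------------------------------------------------------------
# vectorized core


def calls_matrix(
    tetrads: Sequence[Tetrad], override_dead: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Stack tetrads into a ``(n, 4, M)`` call array and ``(n, 4)`` viability mask."""
    if len(tetrads) == 0:
        raise TetradError("empty tetrad collection")
    C = np.stack(
        [[s.effective_calls(override_dead) for s in t.spores] for t in tetrads]
    ).astype(np.int8)
    V = np.array([[s.viable for s in t.spores] for t in tetrads], dtype=bool)
    return C, V


def segregation_pattern_table(C: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Per-marker segregation pattern codes, shape ``(n, M)``.

    Codes index into ``("2:2","3:1","1:3","4:0","0:4","aberrant")``. Counting
    is P1:P2 among viable spores; a BOTH or MISSING call in a viable spore, or
    a count pair outside the recognised set, is aberrant.
    """
    v = V[:, :, None]
    bad = ((C >= BOTH) & v).any(axis=1)  # (n, M)
    p1 = ((C == P1) & v).sum(axis=1)
    p2 = ((C == P2) & v).sum(axis=1)
    out = np.full(p1.shape, 5, dtype=np.int8)  # aberrant by default
    for (a, b), code in _SEG_CODE.items():
        out[(p1 == a) & (p2 == b)] = code
    out[bad] = 5
    return out


def mendelian_matrix(C: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Boolean ``(n, M)``: marker segregates 2:2 in the tetrad."""
    return segregation_pattern_table(C, V) == 0


def score_segregation(tetrad: Tetrad, marker: str, mmap: MarkerMap) -> SegregationClass:
    """Classify a marker's segregation pattern (non-2:2 flags gene conversion)."""
    mi = mmap.index(marker)
    C, V = calls_matrix([tetrad])
    code = segregation_pattern_table(C, V)[0, mi]
    return SegregationClass(marker, _SEG_PATTERNS[code])


def _pair_classes(
    C: np.ndarray, V: np.ndarray, ai: int, bi: int, both_anywhere: np.ndarray
) -> np.ndarray:
    """Base PD/TT/NPD/UNSCORABLE codes for a marker pair, shape ``(n,)``.

    A tetrad is scorable for the pair only if all four spores are viable with
    plain P1/P2 calls at both markers and no spore carries BOTH anywhere on
    the chromosome (disomy breaks the euploid assumptions of tetrad mapping).
    """
    a = C[:, :, ai]
    b = C[:, :, bi]
    scorable = V & (a <= P2) & (b <= P2)
    all4 = scorable.all(axis=1)
    parental = (a == b) & scorable
    npar = parental.sum(axis=1)
    out = np.full(C.shape[0], UNSCORABLE, dtype=np.int8)
    ok = all4 & ~both_anywhere
    out[ok & (npar == 4)] = PD
    out[ok & (npar == 2)] = TT
    out[ok & (npar == 0)] = NPD
    # odd parental counts (possible only with non-2:2 markers) stay UNSCORABLE
    return out


def interval_class_matrix(
    tetrads: Sequence[Tetrad],
    mmap: MarkerMap,
    filter_policy: str = "paper",
    pairs: Sequence[tuple[str, str]] | None = None,
) -> np.ndarray:
    """Ditype class codes for each tetrad × interval, shape ``(n, K)``.

    filter_policy:
      ``"paper"``   — only 4-viable-spore tetrads segregating 2:2 at *every*
                      map marker are scorable (chromosome-wide Mendelian
                      filter, the convention used for map distances);
      ``"lenient"`` — each interval requires 2:2 only at its two flanking
                      markers;
      ``"none"``    — no Mendelian requirement beyond pair scorability.
    """
    if filter_policy not in ("paper", "lenient", "none"):
        raise TetradError(f"unknown filter_policy {filter_policy!r}")
    C, V = calls_matrix(tetrads)
    if C.shape[2] != mmap.n_markers:
        raise TetradError("tetrad marker count does not match the map")
    if pairs is None:
        idx_pairs = [(i, i + 1) for i in range(mmap.n_markers - 1)]
    else:
        idx_pairs = []
        for a, b in pairs:
            ia, ib = mmap.index(a), mmap.index(b)
            if ia == ib:
                raise TetradError(f"interval markers must differ (got {a!r} twice)")
            idx_pairs.append((min(ia, ib), max(ia, ib)))
    both_anywhere = ((C == BOTH) & V[:, :, None]).any(axis=(1, 2))
    out = np.stack(
        [_pair_classes(C, V, ai, bi, both_anywhere) for ai, bi in idx_pairs], axis=1
    )
    if filter_policy == "none":
        return out
    mend = mendelian_matrix(C, V)
    if filter_policy == "paper":
        keep = mend.all(axis=1) & (V.sum(axis=1) == 4)
        out[~keep, :] = UNSCORABLE
    else:  # lenient
        for k, (ai, bi) in enumerate(idx_pairs):
            out[~(mend[:, ai] & mend[:, bi]), k] = UNSCORABLE
    return out


def classify_interval(
    tetrad: Tetrad,
    interval: tuple[str, str],
    mmap: MarkerMap,
    filter_policy: str = "lenient",
) -> DitypeClass:
    """PD/NPD/TT/UNSCORABLE for one tetrad and one marker pair.

    Symmetric in marker order. The pair need not be map-adjacent.
    """
    code = interval_class_matrix([tetrad], mmap, filter_policy, pairs=[interval])[0, 0]
    return DitypeClass(tuple(interval), CLASS_NAMES[code])


def tally_intervals(
    tetrads: Sequence[Tetrad],
    mmap: MarkerMap,
    filter_policy: str = "paper",
) -> dict[tuple[str, str], IntervalTally]:
    """PD/NPD/TT tallies for every adjacent interval of the map.

    Under ``filter_policy="paper"`` a tetrad contributes either to every
    interval or to none, so PD+NPD+TT is the same for all intervals and equals
    the number of fully Mendelian four-viable-spore tetrads.
    """
    cls = interval_class_matrix(tetrads, mmap, filter_policy)
    out: dict[tuple[str, str], IntervalTally] = {}
    for k, iv in enumerate(mmap.intervals):
        col = cls[:, k]
        out[iv] = IntervalTally(
            interval=iv,
            PD=int((col == PD).sum()),
            NPD=int((col == NPD).sum()),
            TT=int((col == TT).sum()),
            unscorable=int((col == UNSCORABLE).sum()),
        )
    return out
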