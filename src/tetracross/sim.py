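"""Forward simulation of yeast tetrads on a marker map.

One simulated meiosis proceeds through the stages the tetrad estimators
assume:

1. a crossover number N for the bivalent — Poisson(λ), or a stationary
   counting-model (chi-square renewal) process in which crossovers are every
   (m+1)-th event of an underlying Poisson process, the standard generative
   model for crossover interference (m = 0 reduces to Poisson);
2. optional crossover assurance failure: with probability q the meiosis is
   forced to zero crossovers (modelling stochastic pairing failure), and
   optionally an obligate crossover (zero-truncation by rejection) for the
   remaining meioses;
3. crossover placement on the genetic map (uniform per cM under the Poisson
   model; at the renewal points under the counting model) and, for each
   crossover, a uniform independent choice of one chromatid per homolog (no
   chromatid interference — the assumption baked into the Perkins and
   Papazian formulas), exchanging all markers distal to the crossover;
4. per-marker gene conversion with probability c (one random chromatid's
   allele is flipped; single-marker events, no co-conversion tracts);
5. segregation: an achiasmate bivalent nondisjoins at meiosis I with
   probability 1−b (b = efficiency of the backup segregation system), giving
   two disomic spores (BOTH at every marker) and two dead nullisomic spores;
   exchange bivalents always disjoin;
6. spore death, independent per spore.

Every stochastic choice is recorded per tetrad in a truth record, and
:func:`replay_genotypes` re-derives the emitted genotypes from the truth
alone — the two must agree bit-exactly, which the test suite checks against
the vectorized forward pass.

Defaults emulate the wild-type chromosome III study design: eight intervals
spanning 131.6 cM, strong interference (m = 4), an obligate crossover,
per-marker conversion at 1%, and 4% spore death. The ``dmc1_hed1_like``
preset adds the assurance-failure mixture (q = 0.15, backup efficiency 0.9)
on a 116.8 cM map with weakened interference and 29.5% spore death.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import (
    BOTH,
    MISSING,
    P1,
    P2,
    MarkerMap,
    SporeGenotype,
    Tetrad,
    TetradError,
)

__all__ = [
    "SimConfig", "TetradTruth", "SimResult",
    "chr3_map", "wild_type_like", "dmc1_hed1_like",
    "simulate_tetrads", "replay_genotypes",
    "interval_recombinant_fraction", "interval_true_cM",
]

_SPORE_IDS = ("a", "b", "c", "d")


def chr3_map(total_cM: float = 131.6) -> MarkerMap:
    """Chromosome-III-like map: nine ordered markers, eight intervals.

    Marker names follow the loci used for chromosome III tetrad mapping
    (CEN3 stands for the heteroallelic centromere-linked insert, scored as a
    single origin-coded locus). Interval lengths are scaled so the map totals
    ``total_cM`` (131.6 cM wild-type-like; 116.8 cM for the mutant preset).
    """
    base = [
        ("CHA1", 0.0),
        ("TRP1", 12.0),
        ("HIS4", 25.0),
        ("LEU2", 42.0),
        ("CEN3", 50.0),
        ("MAT", 75.0),
        ("THR4", 95.0),
        ("ABP1", 113.0),
        ("GIT1", 131.6),
    ]
    scale = total_cM / 131.6
    return MarkerMap.from_markers(
        "III", [(name, pos * scale) for name, pos in base], centromere_index=4
    )


@dataclass(frozen=True)
class SimConfig:
    """Full generative specification for a simulated tetrad dataset.

    mean_CO is λ, the mean crossover number per bivalent per meiosis, before
    assurance-failure forcing and obligate-crossover truncation; None means
    total map length / 50. ``interference_m`` is the counting-model
    parameter (crossovers are every (m+1)-th underlying event; larger m =
    stronger interference).
    """

    map: MarkerMap = field(default_factory=chr3_map)
    n_tetrads: int = 1000
    co_model: str = "counting"            # "poisson" | "counting"
    interference_m: int = 4
    mean_CO: float | None = None
    obligate_CO: bool = True
    assurance_fail_q: float = 0.0
    conversion_prob: float = 0.01
    backup_efficiency: float = 0.9
    spore_death_rate: float = 0.04
    disome_viable: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.co_model not in ("poisson", "counting"):
            raise TetradError(f"unknown crossover model {self.co_model!r}")
        if self.n_tetrads < 1:
            raise TetradError("n_tetrads must be positive")
        if self.interference_m < 0:
            raise TetradError("interference_m must be non-negative")
        for name in ("assurance_fail_q", "conversion_prob", "backup_efficiency", "spore_death_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise TetradError(f"{name} must lie in [0, 1]")
        if self.mean_CO is not None and self.mean_CO < 0:
            raise TetradError("mean_CO must be non-negative")
        if self.obligate_CO and self.lam == 0.0:
            raise TetradError("obligate_CO with zero mean crossover number is contradictory")

    @property
    def lam(self) -> float:
        return self.map.total_cM / 50.0 if self.mean_CO is None else float(self.mean_CO)


def wild_type_like(n_tetrads: int = 1000, seed: int = 0) -> SimConfig:
    """Wild-type-like conditions: 131.6 cM, strong interference, obligate CO."""
    return SimConfig(n_tetrads=n_tetrads, seed=seed)


def dmc1_hed1_like(n_tetrads: int = 1500, seed: int = 0) -> SimConfig:
    """Assurance-failure mixture emulating the crossover-control-defective
    regime: 15% of meioses forced achiasmate, backup segregation rescuing 90%
    of them, weakened interference, 116.8 cM realized-scale map, ~30% spore
    death on top."""
    return SimConfig(
        map=chr3_map(116.8),
        n_tetrads=n_tetrads,
        interference_m=1,
        mean_CO=2.6,
        obligate_CO=True,
        assurance_fail_q=0.15,
        conversion_prob=0.009,
        backup_efficiency=0.9,
        spore_death_rate=0.295,
        seed=seed,
    )


@dataclass(frozen=True)
class TetradTruth:
    """Everything the simulator decided for one meiosis."""

    tetrad_id: str
    n_crossovers: int
    positions: tuple[float, ...]            # sorted, cM from the left marker
    chromatids: tuple[tuple[int, int], ...]  # (homolog-1 chromatid, homolog-2 chromatid)
    conversions: tuple[tuple[int, int], ...]  # (marker index, chromatid)
    forced_e0: bool
    nondisjoined: bool
    spore_chromatids: tuple[int, int, int, int]  # chromatid delivered to each spore slot
    disomic_slots: tuple[int, ...]
    dead_slots: tuple[bool, bool, bool, bool]


@dataclass
class SimResult:
    config: SimConfig
    tetrads: list[Tetrad]
    truth: list[TetradTruth]

    def crossover_counts(self) -> np.ndarray:
        return np.array([t.n_crossovers for t in self.truth], dtype=int)

    @property
    def realized_e0_fraction(self) -> float:
        counts = self.crossover_counts()
        return float((counts == 0).mean())


# ---------------------------------------------------------------------------
# crossover-count / position draws


def _draw_poisson(rng: np.random.Generator, n: int, lam: float, L: float,
                  obligate: bool, forced: np.ndarray) -> np.ndarray:
    """Sorted crossover positions, inf-padded, shape (n, maxN)."""
    N = rng.poisson(lam, size=n) if lam > 0 else np.zeros(n, dtype=int)
    if obligate:
        redo = ~forced & (N == 0)
        while redo.any():
            N[redo] = rng.poisson(lam, size=int(redo.sum()))
            redo = ~forced & (N == 0)
    N[forced] = 0
    max_n = int(N.max()) if n else 0
    if max_n == 0:
        return np.full((n, 0), np.inf)
    pos = rng.uniform(0.0, L, size=(n, max_n))
    pos[np.arange(max_n)[None, :] >= N[:, None]] = np.inf
    pos.sort(axis=1)
    return pos


def _draw_counting_block(rng: np.random.Generator, n: int, lam: float, m: int,
                         L: float) -> np.ndarray:
    """Stationary counting-model crossover positions (inf-padded, sorted).

    Crossovers are every (m+1)-th event of a rate-(m+1)·λ/L Poisson process;
    stationarity comes from a uniform random phase, so the expected crossover
    count in any sub-interval of length d is λ·d/L.
    """
    mp1 = m + 1
    rho = mp1 * lam / L
    max_x = int(np.ceil(lam + 8.0 * np.sqrt(max(lam, 1.0)) + 12.0))
    K = mp1 * (max_x + 1)
    gaps = rng.exponential(1.0 / rho, size=(n, K))
    times = np.cumsum(gaps, axis=1)
    phase = rng.integers(0, mp1, size=n)
    cols = phase[:, None] + mp1 * np.arange(max_x + 1)[None, :]
    xo = np.take_along_axis(times, cols, axis=1)
    if (xo[:, -1] <= L).any():  # cap exceeded; astronomically unlikely
        raise RuntimeError("counting-model crossover cap exceeded; increase the cap")
    xo[xo > L] = np.inf
    return xo


def _draw_counting(rng: np.random.Generator, n: int, lam: float, m: int, L: float,
                   obligate: bool, forced: np.ndarray) -> np.ndarray:
    if lam == 0:
        return np.full((n, 0), np.inf)
    pos = _draw_counting_block(rng, n, lam, m, L)
    if obligate:
        redo = ~forced & np.isinf(pos).all(axis=1)
        while redo.any():
            pos[redo] = _draw_counting_block(rng, int(redo.sum()), lam, m, L)
            redo = ~forced & np.isinf(pos).all(axis=1)
    pos[forced, :] = np.inf
    finite = np.isfinite(pos).sum(axis=1)
    max_n = int(finite.max()) if n else 0
    return pos[:, :max_n]


# ---------------------------------------------------------------------------
# forward pass


def simulate_tetrads(config: SimConfig) -> SimResult:
    """Run the generative model; identical config (incl. seed) gives
    bit-identical output."""
    rng = np.random.default_rng(config.seed)
    mmap = config.map
    n, M, L = config.n_tetrads, mmap.n_markers, mmap.total_cM
    marker_pos = mmap.positions - mmap.positions[0]

    forced = rng.random(n) < config.assurance_fail_q
    if config.co_model == "poisson":
        pos = _draw_poisson(rng, n, config.lam, L, config.obligate_CO, forced)
    else:
        pos = _draw_counting(rng, n, config.lam, config.interference_m, L,
                             config.obligate_CO, forced)
    N = np.isfinite(pos).sum(axis=1).astype(int)
    max_n = pos.shape[1]

    ci = rng.integers(0, 2, size=(n, max_n))
    cj = rng.integers(2, 4, size=(n, max_n))

    # chromatids 0,1 carry P1; 2,3 carry P2. Crossovers pair one *original*
    # chromatid of each homolog; `follow` tracks which output row currently
    # carries each original strand's distal content, so that successive
    # exchanges compose correctly (strand-following construction).
    A = np.zeros((n, 4, M), dtype=np.int8)
    A[:, 2:, :] = P2
    follow = np.tile(np.arange(4), (n, 1))
    for k in range(max_n):
        active = N > k
        if not active.any():
            break
        rows = np.flatnonzero(active)
        x = pos[rows, k]
        ri = follow[rows, ci[rows, k]]
        rj = follow[rows, cj[rows, k]]
        distal = marker_pos[None, :] > x[:, None]
        ai = A[rows, ri, :]
        aj = A[rows, rj, :]
        tmp = ai[distal].copy()
        ai[distal] = aj[distal]
        aj[distal] = tmp
        A[rows, ri, :] = ai
        A[rows, rj, :] = aj
        follow[rows, ci[rows, k]] = rj
        follow[rows, cj[rows, k]] = ri

    conv_mask = rng.random((n, M)) < config.conversion_prob
    conv_chromatid = rng.integers(0, 4, size=(n, M))
    r_idx, m_idx = np.nonzero(conv_mask)
    A[r_idx, conv_chromatid[r_idx, m_idx], m_idx] ^= 1

    perm = rng.permuted(np.tile(np.arange(4), (n, 1)), axis=1)
    G = np.take_along_axis(A, perm[:, :, None], axis=1)

    achiasmate = N == 0
    nd = achiasmate & (rng.random(n) < (1.0 - config.backup_efficiency))
    disomic_slot = perm < 2  # slots receiving a homolog-1 chromatid become disomic
    viable = np.ones((n, 4), dtype=bool)
    G[nd] = np.where(disomic_slot[nd, :, None], BOTH, G[nd])
    viable[nd] = disomic_slot[nd]
    if not config.disome_viable:
        viable[nd] = False

    death = rng.random((n, 4)) < config.spore_death_rate
    viable &= ~death
    G[~viable] = MISSING

    width = max(6, len(str(n)))
    tetrads: list[Tetrad] = []
    truth: list[TetradTruth] = []
    for i in range(n):
        tid = f"T{i:0{width}d}"
        spores = tuple(
            SporeGenotype(_SPORE_IDS[s], bool(viable[i, s]), G[i, s].copy())
            for s in range(4)
        )
        tetrads.append(Tetrad(tid, spores))
        k = int(N[i])
        conv_markers = np.flatnonzero(conv_mask[i])
        truth.append(
            TetradTruth(
                tetrad_id=tid,
                n_crossovers=k,
                positions=tuple(float(p) for p in pos[i, :k]),
                chromatids=tuple((int(ci[i, j]), int(cj[i, j])) for j in range(k)),
                conversions=tuple(
                    (int(mk), int(conv_chromatid[i, mk])) for mk in conv_markers
                ),
                forced_e0=bool(forced[i]),
                nondisjoined=bool(nd[i]),
                spore_chromatids=tuple(int(c) for c in perm[i]),
                disomic_slots=tuple(int(s) for s in np.flatnonzero(disomic_slot[i]))
                if nd[i]
                else (),
                dead_slots=tuple(bool(v) for v in ~viable[i]),
            )
        )
    return SimResult(config=config, tetrads=tetrads, truth=truth)


# ---------------------------------------------------------------------------
# truth replay and truth-based oracles


def _chromatids_from_crossovers(rec: TetradTruth, marker_pos: np.ndarray) -> np.ndarray:
    """Scalar re-derivation of the four chromatid allele vectors."""
    M = marker_pos.size
    A = np.zeros((4, M), dtype=np.int8)
    A[2:, :] = P2
    follow = [0, 1, 2, 3]
    for x, (a, b) in zip(rec.positions, rec.chromatids):
        i, j = follow[a], follow[b]
        distal = marker_pos > x
        tmp = A[i, distal].copy()
        A[i, distal] = A[j, distal]
        A[j, distal] = tmp
        follow[a], follow[b] = j, i
    return A


def replay_genotypes(rec: TetradTruth, mmap: MarkerMap) -> tuple[np.ndarray, np.ndarray]:
    """Re-derive one tetrad's (4, M) calls and viability from its truth record.

    Independent scalar reference for the vectorized forward pass; the test
    suite asserts bit-exact agreement with the emitted tetrad table.
    """
    marker_pos = mmap.positions - mmap.positions[0]
    A = _chromatids_from_crossovers(rec, marker_pos)
    for mk, chromatid in rec.conversions:
        A[chromatid, mk] ^= 1
    G = A[list(rec.spore_chromatids), :]
    for s in rec.disomic_slots:
        G[s, :] = BOTH
    viable = ~np.array(rec.dead_slots, dtype=bool)
    G[~viable] = MISSING
    return G, viable


def interval_recombinant_fraction(
    result: SimResult, interval: tuple[str, str]
) -> dict[str, float]:
    """Exact PD/TT/NPD frequencies for an interval, straight from the truth.

    Bypasses genotype scoring entirely (conversions, deaths and
    nondisjunction do not enter): the class is determined by the crossovers
    falling in [left marker, right marker) and their chromatid choices.
    """
    mmap = result.config.map
    ia, ib = sorted((mmap.index(interval[0]), mmap.index(interval[1])))
    marker_pos = mmap.positions - mmap.positions[0]
    pa, pb = marker_pos[ia], marker_pos[ib]
    counts = {"PD": 0, "TT": 0, "NPD": 0}
    origin = np.array([P1, P1, P2, P2], dtype=np.int8)
    for rec in result.truth:
        alleles = np.stack([origin, origin], axis=1)  # (chromatid, marker a/b)
        follow = [0, 1, 2, 3]
        for x, (a, b) in zip(rec.positions, rec.chromatids):
            if x >= pb:
                break  # positions are sorted; later crossovers touch neither marker
            i, j = follow[a], follow[b]
            cols = np.array([pa > x, pb > x])
            tmp = alleles[i, cols].copy()
            alleles[i, cols] = alleles[j, cols]
            alleles[j, cols] = tmp
            follow[a], follow[b] = j, i
        npar = int((alleles[:, 0] == alleles[:, 1]).sum())
        counts["PD" if npar == 4 else "NPD" if npar == 0 else "TT"] += 1
    n = len(result.truth)
    return {k: v / n for k, v in counts.items()}


def interval_true_cM(result: SimResult, interval: tuple[str, str]) -> float:
    """Realized genetic length of an interval: 50 × mean crossovers in it."""
    mmap = result.config.map
    ia, ib = sorted((mmap.index(interval[0]), mmap.index(interval[1])))
    marker_pos = mmap.positions - mmap.positions[0]
    pa, pb = marker_pos[ia], marker_pos[ib]
    total = sum(
        sum(1 for x in rec.positions if pa <= x < pb) for rec in result.truth
    )
    return 50.0 * total / len(result.truth)
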