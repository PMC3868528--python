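"""End-to-end analysis: tetrads in, report tables out.

:func:`run_pipeline` takes either an observed tetrad table + marker map or a
simulation config, and produces an :class:`AnalysisReport` holding the
standard result tables: per-interval Perkins map distances, NPD-ratio and
adjacent-interval interference tables (on the full data and, optionally, on
the E0-purged exchange subset), the crossover-class distribution with the
Poisson assurance test, and the phenotype summary (viability, disomes,
conversions). A provenance block (input hashes or the full simulation
config, seed, package version) makes every number in the report
recomputable; regenerated reports are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .model import TetradError, tally_intervals
from .mapping import (
    adjacent_interference,
    assurance_test,
    crossover_classes,
    npd_ratio,
    perkins_cM,
    purge_nonexchange,
)
from .phenotypes import conversion_crosstab, score_disomes, viability_distribution
from .io import read_marker_map, read_tetrad_table
from .sim import SimConfig, simulate_tetrads

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline"]

logger = logging.getLogger("tetracross")


@dataclass
class PipelineConfig:
    """Inputs and switches for one analysis run.

    Exactly one of (``tetrad_table`` + ``marker_map``) or ``sim`` must be
    set. ``purge_e0`` additionally reports interference on the exchange
    (non-E0) subset. ``n_permutations`` controls the adjacent-interval
    permutation test (0 skips p-values).
    """

    tetrad_table: str | Path | None = None
    marker_map: str | Path | None = None
    sim: SimConfig | None = None
    filter_policy: str = "paper"
    purge_e0: bool = False
    cen_markers: Sequence[str] | None = None
    n_permutations: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.tetrad_table is not None and self.marker_map is not None
        if has_files == (self.sim is not None):
            raise TetradError(
                "provide either tetrad_table+marker_map or a simulation config, not both"
            )


@dataclass
class AnalysisReport:
    map_table: pd.DataFrame
    npd_table: pd.DataFrame
    adj_table: pd.DataFrame
    eclass_table: pd.DataFrame
    assurance: dict
    phenotype_table: pd.DataFrame
    provenance: dict
    npd_table_purged: pd.DataFrame | None = None
    adj_table_purged: pd.DataFrame | None = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "map_distances.tsv": self.map_table,
            "npd_ratios.tsv": self.npd_table,
            "adjacent_interference.tsv": self.adj_table,
            "crossover_classes.tsv": self.eclass_table,
            "phenotypes.tsv": self.phenotype_table,
        }
        if self.npd_table_purged is not None:
            tables["npd_ratios_purged.tsv"] = self.npd_table_purged
        if self.adj_table_purged is not None:
            tables["adjacent_interference_purged.tsv"] = self.adj_table_purged
        for name, df in tables.items():
            df.to_csv(out / name, sep="\t", index=False)
        (out / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True) + "\n"
        )
        (out / "summary.txt").write_text(self.summary())

    def summary(self) -> str:
        a = self.assurance
        lines = [
            "tetracross analysis summary",
            f"total map length: {self.map_table['cM'].sum():.1f} cM "
            f"(n = {int(self.map_table['n'].iloc[0])} scorable tetrads)",
            f"E0 (non-exchange) tetrads: {a['observed_e0']}/{a['n']} "
            f"({100 * a['observed_fraction']:.1f}%); Poisson expectation "
            f"{100 * a['expected_fraction']:.1f}% (mean {a['mean_CO']:.2f} CO); "
            f"P(excess) = {a['p_excess']:.2g}, P(deficit) = {a['p_deficit']:.2g}",
        ]
        ph = self.phenotype_table.set_index("quantity")["value"]
        lines.append(
            f"spore viability: {ph['viability_pct']:.1f}%  "
            f"disome tetrads: {100 * ph['disome_fraction']:.2f}%  "
            f"conversion tetrads: {100 * ph['conversion_fraction']:.2f}%"
        )
        return "\n".join(lines) + "\n"


def _map_table(tallies) -> pd.DataFrame:
    rows = []
    for iv, tal in tallies.items():
        est = perkins_cM(tal)
        rows.append(
            {
                "interval": f"{iv[0]}-{iv[1]}",
                "cM": est.cM,
                "se_cM": est.se_cM,
                "n": est.n,
                "PD": tal.PD,
                "TT": tal.TT,
                "NPD": tal.NPD,
            }
        )
    return pd.DataFrame(rows)


def _npd_table(tallies) -> pd.DataFrame:
    rows = []
    for iv, tal in tallies.items():
        r = npd_ratio(tal)
        rows.append(
            {
                "interval": f"{iv[0]}-{iv[1]}",
                "NPD_observed": tal.NPD,
                "NPD_expected": r.expected_npd_freq * tal.n,
                "ratio": r.npd_ratio,
                "p_value": r.p_value,
                "n": tal.n,
            }
        )
    return pd.DataFrame(rows)


def _adj_table(tetrads, mmap, policy, n_permutations, seed) -> pd.DataFrame:
    rows = []
    ivs = mmap.intervals
    for k in range(len(ivs) - 1):
        res = adjacent_interference(
            tetrads, mmap, ivs[k], ivs[k + 1],
            filter_policy=policy, n_permutations=n_permutations, seed=seed,
        )
        rows.append(
            {
                "interval_pair": f"{ivs[k][0]}-{ivs[k][1]} / {ivs[k+1][0]}-{ivs[k+1][1]}",
                "adj_ratio": res.adj_ratio,
                "ratio_forward": res.adj_ratio_forward,
                "ratio_reverse": res.adj_ratio_reverse,
                "p_value": res.p_value,
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute the full analysis; deterministic given inputs and seed."""
    stage = "load inputs"
    logger.info("pipeline start: seed=%d filter_policy=%s purge_e0=%s",
                config.seed, config.filter_policy, config.purge_e0)
    try:
        if config.sim is not None:
            result = simulate_tetrads(config.sim)
            tetrads, mmap = result.tetrads, config.sim.map
            provenance_inputs = {"sim_config": repr(config.sim)}
        else:
            mmap = read_marker_map(config.marker_map)
            tetrads = read_tetrad_table(config.tetrad_table, mmap)
            provenance_inputs = {
                "tetrad_table_sha256": _sha256(config.tetrad_table),
                "marker_map_sha256": _sha256(config.marker_map),
            }

        stage = "map distances"
        logger.info("stage: %s", stage)
        tallies = tally_intervals(tetrads, mmap, config.filter_policy)
        map_table = _map_table(tallies)

        stage = "NPD ratios"
        logger.info("stage: %s", stage)
        npd_table = _npd_table(tallies)

        stage = "adjacent-interval interference"
        logger.info("stage: %s (seed=%d, %d permutations)", stage, config.seed,
                    config.n_permutations)
        adj_table = _adj_table(
            tetrads, mmap, config.filter_policy, config.n_permutations, config.seed
        )

        stage = "crossover classes"
        logger.info("stage: %s", stage)
        dist = crossover_classes(tetrads, mmap, config.filter_policy)
        eclass_table = pd.DataFrame(
            {"E_class": [f"E{k}" for k in range(dist.counts.size)], "count": dist.counts}
        )
        assur = assurance_test(dist)
        assurance = {
            "n": assur.n,
            "observed_e0": assur.observed_e0,
            "observed_fraction": assur.observed_fraction,
            "expected_fraction": assur.expected_fraction,
            "mean_CO": assur.mean_CO,
            "p_excess": assur.p_excess,
            "p_deficit": assur.p_deficit,
        }

        npd_purged = adj_purged = None
        if config.purge_e0:
            stage = "E0 purging"
            logger.info("stage: %s", stage)
            purged = purge_nonexchange(tetrads, mmap, config.filter_policy)
            if purged.exchange:
                tall_p = tally_intervals(purged.exchange, mmap, config.filter_policy)
                npd_purged = _npd_table(tall_p)
                adj_purged = _adj_table(
                    purged.exchange, mmap, config.filter_policy,
                    config.n_permutations, config.seed,
                )

        stage = "phenotypes"
        logger.info("stage: %s", stage)
        viab = viability_distribution(tetrads)
        disomes = score_disomes(tetrads, mmap, config.cen_markers)
        crosstab = conversion_crosstab(tetrads, mmap)
        phen_rows = [
            ("tetrads_4_viable", viab.counts[4]),
            ("tetrads_3_viable", viab.counts[3]),
            ("tetrads_2_viable", viab.counts[2]),
            ("tetrads_1_viable", viab.counts[1]),
            ("tetrads_0_viable", viab.counts[0]),
            ("viability_pct", viab.viability_pct),
            ("disome_fraction", disomes.fraction),
            ("conversion_fraction", crosstab.conversion_fraction),
            ("e0_conversion_fraction", crosstab.e0_conversion_fraction),
            ("conversion_assoc_p", crosstab.p_value),
        ]
        phenotype_table = pd.DataFrame(phen_rows, columns=["quantity", "value"])

        provenance = {
            "package": "tetracross",
            "version": __version__,
            "seed": config.seed,
            "filter_policy": config.filter_policy,
            "purge_e0": config.purge_e0,
            "n_permutations": config.n_permutations,
            "inputs": provenance_inputs,
        }
        return AnalysisReport(
            map_table=map_table,
            npd_table=npd_table,
            adj_table=adj_table,
            eclass_table=eclass_table,
            assurance=assurance,
            phenotype_table=phenotype_table,
            provenance=provenance,
            npd_table_purged=npd_purged,
            adj_table_purged=adj_purged,
        )
    except Exception as exc:
        raise TetradError(f"pipeline stage {stage!r} failed: {exc}") from exc
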