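"""Readers and writers for the tetrad-table, marker-map, quant-table and
simulation-config formats.

All tabular formats are plain TSV. Grammars (EBNF-ish):

Tetrad table::

    table    := header row+
    header   := "tetrad_id" TAB "spore_id" TAB "viable" (TAB marker_name)+
    row      := tetrad_id TAB spore_id TAB viable (TAB call)+
    spore_id := "a" | "b" | "c" | "d"
    viable   := "0" | "1"
    call     := "P" | "M" | "B" | "-"     # P1, P2, BOTH, MISSING

Each tetrad_id must appear on exactly four consecutive rows with distinct
spore ids. Reading is lossless: read → write → read is the identity.

Marker map::

    map      := "#chromosome" TAB label NL "#centromere_index" TAB int NL
                "name" TAB "position_cM" NL (marker_row)+
    marker_row := name TAB float

Quant table (percent of total lane signal per molecular species)::

    quant    := "species" TAB "percent_signal" NL (label TAB float)+

Simulation configs are YAML mappings of :class:`~tetracross.sim.SimConfig`
fields, with the map either inline (``map: {chromosome, centromere_index,
markers: [[name, pos], ...]}``) or referenced (``map_file: path.tsv``).
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Sequence

import yaml

from .model import (
    CALL_CHARS,
    CHAR_TO_CALL,
    MarkerMap,
    SporeGenotype,
    Tetrad,
)
from .sim import SimConfig, SimResult

__all__ = [
    "TetradTableError",
    "read_tetrad_table", "write_tetrad_table",
    "read_marker_map", "write_marker_map",
    "read_quant_table", "write_quant_table",
    "read_sim_config", "write_sim_config",
    "write_truth_table", "tetrad_table_string",
]

_SPORE_IDS = ("a", "b", "c", "d")


class TetradTableError(ValueError):
    """Malformed input file; the message names the offending line(s)."""


def _open(path_or_buf, mode: str):
    if hasattr(path_or_buf, "read") or hasattr(path_or_buf, "write"):
        return path_or_buf, False
    return open(path_or_buf, mode, encoding="utf-8", newline=""), True


# -- tetrad table ------------------------------------------------------------


def read_tetrad_table(path_or_buf, mmap: MarkerMap | None = None) -> list[Tetrad]:
    """Parse a tetrad-table TSV; validate against ``mmap`` if given."""
    fh, close = _open(path_or_buf, "r")
    try:
        lines = fh.read().splitlines()
    finally:
        if close:
            fh.close()
    if not lines:
        raise TetradTableError("empty tetrad table")
    header = lines[0].split("\t")
    if header[:3] != ["tetrad_id", "spore_id", "viable"]:
        raise TetradTableError(
            "line 1: header must start with tetrad_id, spore_id, viable"
        )
    markers = header[3:]
    if not markers:
        raise TetradTableError("line 1: no marker columns")
    if mmap is not None and tuple(markers) != mmap.names:
        raise TetradTableError(
            f"marker columns {markers} do not match the map {list(mmap.names)}"
        )
    errors: list[str] = []
    groups: dict[str, list[tuple[int, str, bool, str]]] = {}
    order: list[str] = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3 + len(markers):
            errors.append(f"line {ln}: expected {3 + len(markers)} fields, got {len(fields)}")
            continue
        tid, sid, viab = fields[0], fields[1], fields[2]
        if sid not in _SPORE_IDS:
            errors.append(f"line {ln}: spore_id must be one of a–d, got {sid!r}")
            continue
        if viab not in ("0", "1"):
            errors.append(f"line {ln}: viable must be 0 or 1, got {viab!r}")
            continue
        bad = [c for c in fields[3:] if c not in CHAR_TO_CALL]
        if bad:
            errors.append(f"line {ln}: unknown allele code {bad[0]!r}")
            continue
        if tid not in groups:
            groups[tid] = []
            order.append(tid)
        groups[tid].append((ln, sid, viab == "1", "".join(fields[3:])))
    for tid in order:
        rows = groups[tid]
        sids = [r[1] for r in rows]
        if len(rows) != 4:
            errors.append(
                f"tetrad {tid!r} has {len(rows)} spores (lines "
                f"{', '.join(str(r[0]) for r in rows)}); exactly four required"
            )
        elif len(set(sids)) != 4:
            errors.append(f"tetrad {tid!r} has duplicate spore ids {sids}")
    if errors:
        raise TetradTableError("; ".join(errors))
    return [
        Tetrad(
            tid,
            tuple(
                SporeGenotype.from_codes(sid, viab, codes)
                for _, sid, viab, codes in sorted(groups[tid], key=lambda r: r[1])
            ),
        )
        for tid in order
    ]


def write_tetrad_table(tetrads: Sequence[Tetrad], mmap: MarkerMap, path_or_buf) -> None:
    fh, close = _open(path_or_buf, "w")
    try:
        fh.write("tetrad_id\tspore_id\tviable\t" + "\t".join(mmap.names) + "\n")
        for t in tetrads:
            for s in t.spores:
                fh.write(
                    f"{t.tetrad_id}\t{s.spore_id}\t{int(s.viable)}\t"
                    + "\t".join(CALL_CHARS[c] for c in s.calls)
                    + "\n"
                )
    finally:
        if close:
            fh.close()


def tetrad_table_string(tetrads: Sequence[Tetrad], mmap: MarkerMap) -> str:
    buf = _io.StringIO()
    write_tetrad_table(tetrads, mmap, buf)
    return buf.getvalue()


# -- marker map --------------------------------------------------------------


def read_marker_map(path_or_buf) -> MarkerMap:
    fh, close = _open(path_or_buf, "r")
    try:
        lines = [l for l in fh.read().splitlines() if l.strip()]
    finally:
        if close:
            fh.close()
    meta: dict[str, str] = {}
    body: list[str] = []
    for line in lines:
        if line.startswith("#"):
            key, _, val = line[1:].partition("\t")
            meta[key.strip()] = val.strip()
        else:
            body.append(line)
    if "chromosome" not in meta or "centromere_index" not in meta:
        raise TetradTableError(
            "marker map must declare #chromosome and #centromere_index header lines"
        )
    if not body or body[0].split("\t")[:2] != ["name", "position_cM"]:
        raise TetradTableError("marker map needs a 'name\\tposition_cM' column header")
    markers = []
    for ln, line in enumerate(body[1:], start=1):
        fields = line.split("\t")
        if len(fields) < 2:
            raise TetradTableError(f"marker row {ln}: expected name\\tposition_cM")
        try:
            markers.append((fields[0], float(fields[1])))
        except ValueError:
            raise TetradTableError(
                f"marker row {ln}: position {fields[1]!r} is not a number"
            ) from None
    return MarkerMap.from_markers(
        meta["chromosome"], markers, centromere_index=int(meta["centromere_index"])
    )


def write_marker_map(mmap: MarkerMap, path_or_buf) -> None:
    fh, close = _open(path_or_buf, "w")
    try:
        fh.write(f"#chromosome\t{mmap.chromosome_id}\n")
        fh.write(f"#centromere_index\t{mmap.centromere_index}\n")
        fh.write("name\tposition_cM\n")
        for name, pos in zip(mmap.names, mmap.positions_cM):
            fh.write(f"{name}\t{pos:g}\n")
    finally:
        if close:
            fh.close()


# -- quant table -------------------------------------------------------------


def read_quant_table(path_or_buf) -> dict[str, float]:
    """Species → percent-of-total-signal mapping (validated non-negative, ≤100)."""
    fh, close = _open(path_or_buf, "r")
    try:
        lines = [l for l in fh.read().splitlines() if l.strip()]
    finally:
        if close:
            fh.close()
    if not lines or lines[0].split("\t")[:2] != ["species", "percent_signal"]:
        raise TetradTableError("quant table needs a 'species\\tpercent_signal' header")
    out: dict[str, float] = {}
    for ln, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) < 2:
            raise TetradTableError(f"line {ln}: expected species\\tpercent_signal")
        try:
            val = float(fields[1])
        except ValueError:
            raise TetradTableError(f"line {ln}: {fields[1]!r} is not a number") from None
        if not 0.0 <= val <= 100.0:
            raise TetradTableError(f"line {ln}: percent signal {val} outside [0, 100]")
        if fields[0] in out:
            raise TetradTableError(f"line {ln}: duplicate species {fields[0]!r}")
        out[fields[0]] = val
    return out


def write_quant_table(quant: dict[str, float], path_or_buf) -> None:
    fh, close = _open(path_or_buf, "w")
    try:
        fh.write("species\tpercent_signal\n")
        for k, v in quant.items():
            fh.write(f"{k}\t{v:g}\n")
    finally:
        if close:
            fh.close()


# -- simulation config -------------------------------------------------------

_SIM_KEYS = (
    "n_tetrads", "co_model", "interference_m", "mean_CO", "obligate_CO",
    "assurance_fail_q", "conversion_prob", "backup_efficiency",
    "spore_death_rate", "disome_viable", "seed",
)


def read_sim_config(path_or_buf, base_dir: Path | None = None) -> SimConfig:
    fh, close = _open(path_or_buf, "r")
    try:
        data = yaml.safe_load(fh.read())
    finally:
        if close:
            fh.close()
    if not isinstance(data, dict):
        raise TetradTableError("simulation config must be a YAML mapping")
    kwargs = {k: data[k] for k in _SIM_KEYS if k in data}
    if "map" in data:
        m = data["map"]
        kwargs["map"] = MarkerMap.from_markers(
            m["chromosome"],
            [(str(n), float(p)) for n, p in m["markers"]],
            centromere_index=int(m.get("centromere_index", 0)),
        )
    elif "map_file" in data:
        p = Path(data["map_file"])
        if base_dir is not None and not p.is_absolute():
            p = base_dir / p
        kwargs["map"] = read_marker_map(p)
    unknown = set(data) - set(_SIM_KEYS) - {"map", "map_file"}
    if unknown:
        raise TetradTableError(f"unknown simulation config keys: {sorted(unknown)}")
    return SimConfig(**kwargs)


def write_sim_config(config: SimConfig, path_or_buf) -> None:
    data: dict = {k: getattr(config, k) for k in _SIM_KEYS}
    data["map"] = {
        "chromosome": config.map.chromosome_id,
        "centromere_index": config.map.centromere_index,
        "markers": [[n, float(p)] for n, p in zip(config.map.names, config.map.positions_cM)],
    }
    fh, close = _open(path_or_buf, "w")
    try:
        yaml.safe_dump(data, fh, sort_keys=False)
    finally:
        if close:
            fh.close()


# -- truth table -------------------------------------------------------------


def write_truth_table(result: SimResult, path_or_buf) -> None:
    """Per-tetrad ground-truth TSV (crossovers, conversions, segregation)."""
    fh, close = _open(path_or_buf, "w")
    try:
        fh.write(
            "tetrad_id\tn_crossovers\tpositions_cM\tchromatids\tconversions\t"
            "forced_e0\tnondisjoined\tspore_chromatids\tdead_slots\n"
        )
        for rec in result.truth:
            fh.write(
                "\t".join(
                    [
                        rec.tetrad_id,
                        str(rec.n_crossovers),
                        ",".join(f"{p:.6f}" for p in rec.positions),
                        ",".join(f"{i}|{j}" for i, j in rec.chromatids),
                        ",".join(f"{m}|{c}" for m, c in rec.conversions),
                        str(int(rec.forced_e0)),
                        str(int(rec.nondisjoined)),
                        ",".join(str(c) for c in rec.spore_chromatids),
                        ",".join(str(int(d)) for d in rec.dead_slots),
                    ]
                )
                + "\n"
            )
    finally:
        if close:
            fh.close()
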