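"""Plain-text round-tripping of simulation and inference artifacts.

Everything is TSV/CSV/JSON with '#'-prefixed ``key=value`` header lines, so
any run can be regenerated bit-identically from the metadata it records.
Methylation patterns are abstract lattice states (no genomic coordinates),
hence no BED-like formats.
"""

from __future__ import annotations

import json
from typing import Optional

import numpy as np
import pandas as pd

from .reaction_model import Params, STATE_CHARS
from .simulator import ReadDataset, SampleMatrix, SimConfig
from .sumstats import STAT_NAMES, ReplicateSummary, SummaryStats

__all__ = [
    "write_sample_matrix",
    "read_sample_matrix",
    "write_reads",
    "read_reads",
    "write_summary_tsv",
    "read_summary_tsv",
    "write_posterior_csv",
    "read_posterior_csv",
]

_CODE = {c: i for i, c in enumerate(STATE_CHARS)}


def _header_lines(meta: dict) -> list[str]:
    return [f"# {k}={v}" for k, v in meta.items()]


def _parse_headers(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
    return meta


def write_sample_matrix(sm: SampleMatrix, path) -> None:
    """One row per snapshot, one u/h/m letter column per CpG."""
    p, cfg = sm.params, sm.config
    meta = {
        "a": repr(p.a), "x": repr(p.x), "y": repr(p.y),
        "N": cfg.N, "T": cfg.T, "seed": cfg.seed,
        "initial_state": cfg.initial_state,
        "burn_in_time": repr(sm.burn_in_time),
        "burn_in_events": sm.burn_in_events,
        "dt": repr(sm.dt),
    }
    chars = np.array(list(STATE_CHARS))
    with open(path, "w") as fh:
        fh.write("\n".join(_header_lines(meta)) + "\n")
        for row in sm.data:
            fh.write("\t".join(chars[row]) + "\n")


def read_sample_matrix(path) -> SampleMatrix:
    meta = _parse_headers(path)
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            rows.append([_CODE[c] for c in line.split()])
    data = np.asarray(rows, dtype=np.int8)
    params = Params(a=float(meta["a"]), x=float(meta["x"]), y=float(meta["y"]))
    cfg = SimConfig(
        N=int(meta["N"]), T=int(meta["T"]), seed=int(meta["seed"]),
        initial_state=meta.get("initial_state", "uniform"),
    )
    return SampleMatrix(
        data=data, params=params, config=cfg,
        burn_in_time=float(meta["burn_in_time"]),
        burn_in_events=int(meta["burn_in_events"]),
        dt=float(meta["dt"]),
    )


def write_reads(reads: ReadDataset, path) -> None:
    """Two-column TSV: 0-based cpg_index, u/h/m state letter."""
    meta = {"N": reads.N, "coverage": reads.coverage}
    if reads.params is not None:
        meta.update(a=repr(reads.params.a), x=repr(reads.params.x), y=repr(reads.params.y))
    if reads.seed is not None:
        meta["seed"] = reads.seed
    with open(path, "w") as fh:
        fh.write("\n".join(_header_lines(meta)) + "\n")
        fh.write("cpg_index\tstate\n")
        for i, s in zip(reads.cpg_index, reads.states):
            fh.write(f"{i}\t{STATE_CHARS[s]}\n")


def read_reads(path) -> ReadDataset:
    meta = _parse_headers(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    params = None
    if "x" in meta:
        params = Params(a=float(meta["a"]), x=float(meta["x"]), y=float(meta["y"]))
    return ReadDataset(
        cpg_index=df["cpg_index"].to_numpy(np.int64),
        states=df["state"].map(_CODE).to_numpy(np.int8),
        N=int(meta["N"]),
        coverage=int(meta["coverage"]),
        params=params,
        seed=int(meta["seed"]) if "seed" in meta else None,
    )


def _stats_row(stats) -> dict:
    d = stats.as_dict() if isinstance(stats, SummaryStats) else dict(stats)
    return {k: ("" if d[k] is None else repr(float(d[k]))) for k in STAT_NAMES}


def write_summary_tsv(stats, path, meta: Optional[dict] = None) -> None:
    """One-row TSV in fixed column order; undefined statistics are blank."""
    row = _stats_row(stats)
    with open(path, "w") as fh:
        if meta:
            fh.write("\n".join(_header_lines(meta)) + "\n")
        fh.write("\t".join(STAT_NAMES) + "\n")
        fh.write("\t".join(row[k] for k in STAT_NAMES) + "\n")


def read_summary_tsv(path) -> SummaryStats:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    row = df.iloc[0]
    vals = {k: (None if pd.isna(row[k]) else float(row[k])) for k in STAT_NAMES}
    return SummaryStats(**vals)


def write_posterior_csv(posterior, path, meta: Optional[dict] = None) -> None:
    """Weighted posterior samples as CSV columns x, y, weight."""
    with open(path, "w") as fh:
        if meta:
            fh.write("\n".join(_header_lines(meta)) + "\n")
        fh.write("x,y,weight\n")
        for (x, y), w in zip(posterior.samples, posterior.weights):
            fh.write(f"{float(x)!r},{float(y)!r},{float(w)!r}\n")


def read_posterior_csv(path):
    from .inference import Posterior

    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return Posterior(
        samples=df[["x", "y"]].to_numpy(float),
        weights=df["weight"].to_numpy(float),
    )
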