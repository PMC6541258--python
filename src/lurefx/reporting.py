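"""Assemble result tables and a reproducible run directory.

Outputs mirror the standard reporting surfaces of a baited camera-trap
study: a per-species descriptive summary (independent captures, capture
rate per 100 trap-days, naive detection, naive occupancy), per-species
model-selection tables, per-species permutation tables with null draws for
violin plots, detection-probability curves, and a JSON manifest with input
digests so reruns can be verified bit-for-bit.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .data_io import CaptureRecord, Deployment, total_trap_days
from .event_processing import (
    build_detection_matrix,
    capture_rate,
    filter_independent,
    naive_summaries,
)

__all__ = ["RunManifest", "table1_summary", "assemble_run"]


def table1_summary(
    captures: Sequence[CaptureRecord],
    deployments: Sequence[Deployment],
    species_list: Sequence[str],
    window_hours: float = 1.0,
) -> pd.DataFrame:
    """Per-species descriptive summary over one survey effort pool.

    One row per species: independent captures (>= ``window_hours`` apart at
    a station), capture rate per 100 trap-days, naive detection, and naive
    occupancy.
    """
    effort = total_trap_days(deployments)
    independent = filter_independent(captures, window_hours)
    rows = []
    for sp in species_list:
        sp_caps = [c for c in independent if c.species == sp]
        dm = build_detection_matrix(sp_caps, deployments, sp)
        naive_occ, naive_det = naive_summaries(dm)
        rows.append(
            {
                "species": sp,
                "independent_captures": len(sp_caps),
                "trap_days": effort,
                "capture_rate": capture_rate(len(sp_caps), effort),
                "naive_detection": naive_det,
                "naive_occupancy": naive_occ,
            }
        )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """What a run consumed and produced, with content digests."""

    seed: int
    config: dict
    inputs: dict[str, str] = field(default_factory=dict)     # name -> digest
    outputs: dict[str, str] = field(default_factory=dict)
    record_counts: dict[str, int] = field(default_factory=dict)
    created: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "config": self.config,
                "inputs": self.inputs,
                "outputs": self.outputs,
                "record_counts": self.record_counts,
                "created": self.created,
            },
            indent=2,
            sort_keys=True,
            default=str,
        )


def assemble_run(
    out_dir: str | Path,
    tables: dict[str, pd.DataFrame],
    seed: int,
    config: dict,
    input_paths: dict[str, str | Path] | None = None,
    record_counts: dict[str, int] | None = None,
    timestamp: str = "",
) -> RunManifest:
    """Write every result table as CSV and a manifest listing all of them.

    ``tables`` maps output file stems to frames; a missing (None) table is a
    hard error — partial runs must fail loudly rather than emit an
    incomplete directory.  Leave ``timestamp`` empty for bit-identical
    reruns.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=seed, config=config, created=timestamp)
    for name, path in (input_paths or {}).items():
        manifest.inputs[name] = _sha256(Path(path))
    for stem, frame in tables.items():
        if frame is None:
            raise ValueError(f"stage output {stem!r} is missing")
        path = out / f"{stem}.csv"
        frame.to_csv(path, index=False)
        manifest.outputs[f"{stem}.csv"] = _sha256(path)
    manifest.record_counts = dict(record_counts or {})
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
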