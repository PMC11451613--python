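"""File formats and run configuration.

Desk-scale, inspectable text formats throughout: traces as long CSV
(trace_id, time_s, channel, intensity[, true_state]), dwell tables as CSV
(condition, duration_s, censored), binding sites as BED6 plus affinity
columns, read pools as FASTA, energy models and fit reports as JSON.
Times are seconds in trace/dwell files; correlation reports use minutes,
matching the conventions of the assays they summarise.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .binding import BindingSiteRecord
from .simulate import AcquisitionSettings, DwellDataset, IntensityTrace

__all__ = [
    "read_traces",
    "write_traces",
    "read_sites",
    "write_sites",
    "read_dwells",
    "write_dwells",
    "read_fasta",
    "write_fasta",
    "RunConfig",
]


def write_traces(traces: Sequence[IntensityTrace], path) -> None:
    rows = []
    for tr in traces:
        for ch, values in (("ch1", tr.intensity), ("ch2", tr.intensity2)):
            if values is None:
                continue
            for i, (t, v) in enumerate(zip(tr.time, values)):
                row = {"trace_id": tr.trace_id, "time_s": t, "channel": ch, "intensity": v}
                if tr.true_state is not None:
                    row["true_state"] = int(tr.true_state[i])
                rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_traces(path) -> List[IntensityTrace]:
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{path}: empty trace file")
        return []
    out = []
    for tid, grp in df.groupby("trace_id", sort=False):
        channels = {}
        state = None
        for ch, sub in grp.groupby("channel"):
            if not sub["time_s"].is_monotonic_increasing:
                warnings.warn(f"trace {tid}: out-of-order rows sorted by time")
                sub = sub.sort_values("time_s")
            channels[ch] = sub
        lengths = {ch: len(sub) for ch, sub in channels.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"trace {tid}: ragged channels {lengths}")
        first = channels.get("ch1")
        if first is None:
            raise ValueError(f"trace {tid}: missing channel ch1")
        if "true_state" in first.columns and first["true_state"].notna().all():
            state = first["true_state"].to_numpy(dtype=int)
        out.append(
            IntensityTrace(
                trace_id=str(tid),
                time=first["time_s"].to_numpy(dtype=float),
                intensity=first["intensity"].to_numpy(dtype=float),
                intensity2=(
                    channels["ch2"]["intensity"].to_numpy(dtype=float)
                    if "ch2" in channels
                    else None
                ),
                true_state=state,
            )
        )
    return out


_SITE_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "relative_affinity", "best_kmer"]


def write_sites(sites: Sequence[BindingSiteRecord], path) -> None:
    rows = [
        {
            "chrom": s.chrom,
            "start": s.start,
            "end": s.end,
            "name": s.name,
            "score": 0,
            "strand": s.strand,
            "relative_affinity": s.relative_affinity,
            "best_kmer": s.best_kmer,
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=_SITE_COLUMNS).to_csv(path, sep="\t", index=False, header=False)


def read_sites(path) -> List[BindingSiteRecord]:
    df = pd.read_csv(path, sep="\t", header=None, names=_SITE_COLUMNS, dtype={"best_kmer": str})
    out = []
    for _, row in df.iterrows():
        if row["strand"] not in {"+", "-"}:
            raise ValueError(f"malformed strand field: {row['strand']!r}")
        if int(row["end"]) <= int(row["start"]):
            raise ValueError(f"site {row['name']}: end <= start")
        out.append(
            BindingSiteRecord(
                chrom=str(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                strand=str(row["strand"]),
                relative_affinity=float(row["relative_affinity"]),
                best_kmer="" if pd.isna(row["best_kmer"]) else str(row["best_kmer"]),
                name=str(row["name"]),
            )
        )
    return out


def write_dwells(datasets: Sequence[DwellDataset], path) -> None:
    pd.concat([ds.to_frame() for ds in datasets], ignore_index=True).to_csv(path, index=False)
    meta = {
        ds.condition: {
            "acquisition": ds.acquisition.to_dict(),
            "truth": ds.truth.to_dict() if ds.truth is not None else None,
        }
        for ds in datasets
    }
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def read_dwells(path, acquisition: Optional[AcquisitionSettings] = None) -> List[DwellDataset]:
    df = pd.read_csv(path)
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    out = []
    for cond, grp in df.groupby("condition", sort=False):
        if str(cond) in meta:
            acq = AcquisitionSettings(**meta[str(cond)]["acquisition"])
        elif acquisition is not None:
            acq = acquisition
        else:
            raise ValueError("no acquisition metadata found; pass acquisition explicitly")
        out.append(
            DwellDataset(
                condition=str(cond),
                durations=grp["duration_s"].to_numpy(dtype=float),
                censored=grp["censored"].to_numpy(dtype=bool),
                acquisition=acq,
            )
        )
    return out


def write_fasta(reads: Sequence[str], path, prefix: str = "read") -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(s), id=f"{prefix}_{i:07d}", description="") for i, s in enumerate(reads)
    ]
    seqio_write(records, str(path), "fasta")


def read_fasta(path) -> List[str]:
    from Bio import SeqIO

    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]


_CONFIG_KEYS = {"seed", "inputs", "outputs", "stages", "ddg_units"}


@dataclass
class RunConfig:
    """Seed, paths and stage parameters for a reproducible pipeline run."""

    seed: int = 0
    inputs: Dict[str, str] = field(default_factory=dict)
    outputs: Dict[str, str] = field(default_factory=dict)
    stages: Dict[str, dict] = field(default_factory=dict)
    ddg_units: str = "RT"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        unknown = set(data) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "stages": self.stages,
            "ddg_units": self.ddg_units,
        }

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance(self) -> dict:
        return {"seed": self.seed, "config_hash": self.hash}
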