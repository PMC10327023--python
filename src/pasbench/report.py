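"""Benchmark result records and consolidation.

Each metric computation is packaged as one self-describing JSON record
(event, dataset, method, window, parameters, metrics, input digests).
Consolidation groups records by event and dataset into one summary document
per group with per-method metric arrays; it is idempotent, so feeding a
consolidated document back in reproduces it unchanged.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Iterable

import pasbench

RECORD_SCHEMA = "pasbench-record/1"
CONSOLIDATED_SCHEMA = "pasbench-consolidated/1"


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class BenchmarkRecord:
    event: str  # identification | abs_quant | rel_quant
    dataset_id: str
    method_id: str
    window_n: int
    params: dict[str, Any] = field(default_factory=dict)
    metrics: dict[str, Any] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)
    schema: str = RECORD_SCHEMA

    def key(self) -> tuple:
        return (
            self.event,
            self.dataset_id,
            self.method_id,
            self.window_n,
            self.params.get("mode"),
            self.params.get("subset"),
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkRecord":
        if d.get("schema") != RECORD_SCHEMA:
            raise ValueError(f"not a benchmark record (schema={d.get('schema')!r})")
        return cls(**{k: d[k] for k in ("event", "dataset_id", "method_id", "window_n", "params", "metrics", "provenance")})


def make_record(
    event: str,
    dataset_id: str,
    method_id: str,
    window_n: int,
    metrics: dict[str, Any],
    params: dict[str, Any] | None = None,
    input_paths: Iterable[str | Path] = (),
) -> BenchmarkRecord:
    provenance = {
        "tool_version": pasbench.__version__,
        "inputs": {str(p): file_digest(p) for p in input_paths},
    }
    return BenchmarkRecord(
        event=event,
        dataset_id=dataset_id,
        method_id=method_id,
        window_n=window_n,
        params=params or {},
        metrics=metrics,
        provenance=provenance,
    )


def consolidate(documents: Iterable[dict]) -> dict:
    """Group benchmark records by (event, dataset) into one summary document.

    Accepts raw records and/or previously consolidated documents (their
    records are re-used), errors on records sharing a key but disagreeing
    in content, and produces deterministic output.
    """
    records: dict[tuple, BenchmarkRecord] = {}
    for doc in documents:
        if doc.get("schema") == CONSOLIDATED_SCHEMA:
            inner = [BenchmarkRecord.from_dict(r) for r in doc["records"]]
        else:
            inner = [BenchmarkRecord.from_dict(doc)]
        for rec in inner:
            key = rec.key()
            if key in records:
                if asdict(records[key]) != asdict(rec):
                    raise ValueError(f"conflicting duplicate record for key {key}")
                continue
            records[key] = rec

    groups: dict[tuple[str, str], list[BenchmarkRecord]] = {}
    for rec in records.values():
        groups.setdefault((rec.event, rec.dataset_id), []).append(rec)

    out_groups = []
    for (event, dataset_id), recs in sorted(groups.items()):
        methods: dict[str, list[dict]] = {}
        for rec in sorted(recs, key=lambda r: (r.method_id, r.window_n, str(r.key()))):
            methods.setdefault(rec.method_id, []).append(
                {
                    "window_n": rec.window_n,
                    "params": rec.params,
                    "metrics": rec.metrics,
                }
            )
        out_groups.append({"event": event, "dataset_id": dataset_id, "methods": methods})

    return {
        "schema": CONSOLIDATED_SCHEMA,
        "groups": out_groups,
        "records": [asdict(records[k]) for k in sorted(records, key=str)],
    }


def metrics_long_tsv(records: Iterable[BenchmarkRecord]) -> str:
    """Long-format TSV (one metric per row) for external plotting."""
    lines = ["event\tdataset_id\tmethod_id\twindow_n\tmode\tsubset\tmetric\tvalue"]
    for rec in records:
        mode = rec.params.get("mode", "")
        subset = rec.params.get("subset", "")
        for name, value in sorted(rec.metrics.items()):
            if isinstance(value, (list, dict)):
                continue
            lines.append(
                f"{rec.event}\t{rec.dataset_id}\t{rec.method_id}\t{rec.window_n}"
                f"\t{mode}\t{subset}\t{name}\t{value}"
            )
    return "\n".join(lines) + "\n"
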