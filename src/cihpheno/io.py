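"""Plain-text readers/writers for traces, tables, events and module definitions.

Traces are 2-column tab-delimited files (time_s, value) with a
``# sample_rate_hz:`` header line; breath/beat/count tables are TSV;
module definitions use a compact text format::

    MGB001<TAB>GABA synthesis
    K01580
    K07250,K00823

    MGB002<TAB>...

i.e. a header line ``module_id<TAB>name`` followed by one line per step
listing comma-separated alternative KO IDs, modules separated by blank
lines.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .breath import FlowTrace
from .challenges import EpochDefinition
from .events import RespEvent
from .hrv import PressureTrace
from .microbiome import CountTable, ModuleDefinition

__all__ = [
    "write_trace",
    "read_flow_trace",
    "read_pressure_trace",
    "write_table",
    "read_table",
    "write_count_table",
    "read_count_table",
    "write_events",
    "read_events",
    "read_epochs",
    "write_epochs",
    "read_module_definitions",
    "write_module_definitions",
]


def write_trace(path: str | Path, samples: np.ndarray, sample_rate_hz: float, **meta) -> None:
    path = Path(path)
    t = np.arange(len(samples)) / sample_rate_hz
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz: {sample_rate_hz:g}\n")
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        for ti, vi in zip(t, samples):
            fh.write(f"{ti:.6f}\t{vi:.8g}\n")


def _read_trace(path: str | Path) -> tuple[np.ndarray, float, dict]:
    meta: dict[str, str] = {}
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
                continue
            values.append(float(line.split("\t")[1]))
    if "sample_rate_hz" not in meta:
        raise ValueError(f"{path}: missing '# sample_rate_hz:' header")
    return np.asarray(values), float(meta["sample_rate_hz"]), meta


def read_flow_trace(path: str | Path) -> FlowTrace:
    samples, fs, meta = _read_trace(path)
    mass = meta.get("body_mass_g")
    return FlowTrace(
        samples=samples,
        sample_rate_hz=fs,
        subject_id=meta.get("subject_id", ""),
        body_mass_g=float(mass) if mass else None,
    )


def read_pressure_trace(path: str | Path) -> PressureTrace:
    samples, fs, meta = _read_trace(path)
    return PressureTrace(samples=samples, sample_rate_hz=fs, subject_id=meta.get("subject_id", ""))


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_count_table(path: str | Path, table: CountTable) -> None:
    out = table.counts.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_count_table(path: str | Path, groups: pd.Series | None = None) -> CountTable:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index.name = None
    return CountTable(counts, groups)


def write_events(path: str | Path, events: list[RespEvent]) -> None:
    rows = [
        {
            "kind": e.kind,
            "onset_s": e.onset_s,
            "duration_s": e.duration_s,
            "amplitude_ml": e.amplitude_ml,
            "amplitude_ml_100g": e.amplitude_ml_100g,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=["kind", "onset_s", "duration_s", "amplitude_ml", "amplitude_ml_100g"]).to_csv(
        path, sep="\t", index=False
    )


def read_events(path: str | Path) -> list[RespEvent]:
    df = pd.read_csv(path, sep="\t")
    return [
        RespEvent(
            kind=r.kind,
            onset_s=r.onset_s,
            duration_s=r.duration_s,
            amplitude_ml=r.amplitude_ml,
            amplitude_ml_100g=r.amplitude_ml_100g,
        )
        for r in df.itertuples()
    ]


def write_epochs(path: str | Path, epochs: list[EpochDefinition]) -> None:
    pd.DataFrame(
        [{"label": e.label, "start_s": e.start_s, "end_s": e.end_s} for e in epochs]
    ).to_csv(path, sep="\t", index=False)


def read_epochs(path: str | Path) -> list[EpochDefinition]:
    df = pd.read_csv(path, sep="\t")
    return [EpochDefinition(r.label, float(r.start_s), float(r.end_s)) for r in df.itertuples()]


def write_module_definitions(path: str | Path, definitions: list[ModuleDefinition]) -> None:
    with open(path, "w") as fh:
        for d in definitions:
            fh.write(f"{d.module_id}\t{d.name}\n")
            for step in d.steps:
                fh.write(",".join(sorted(step)) + "\n")
            fh.write("\n")


def read_module_definitions(path: str | Path) -> list[ModuleDefinition]:
    defs: list[ModuleDefinition] = []
    header: tuple[str, str] | None = None
    steps: list[frozenset[str]] = []

    def flush() -> None:
        nonlocal header, steps
        if header is not None:
            defs.append(ModuleDefinition(header[0], header[1], tuple(steps)))
        header, steps = None, []

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            if "\t" in line:
                flush()
                mid, _, name = line.partition("\t")
                header = (mid.strip(), name.strip())
            else:
                steps.append(frozenset(k.strip() for k in line.split(",") if k.strip()))
    flush()
    return defs
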