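"""Table writers shared by the CLI subcommands.

Data files are deterministic for a given configuration and seed: fixed
column order, full numeric precision, no timestamps.  Each output gets a
sidecar ``<name>.meta.json`` recording the resolved run configuration and
the package version, so any file can be regenerated exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig

__all__ = ["write_table", "write_meta", "FORMATS"]

FORMATS = ("csv", "tsv", "json", "markdown")


def _to_markdown(df: pd.DataFrame) -> str:
    cols = [str(c) for c in df.columns]
    cells = [[_cell(v) for v in row] for row in df.itertuples(index=False)]
    widths = [max(len(c), *(len(r[k]) for r in cells)) if cells else len(c)
              for k, c in enumerate(cols)]
    def line(items: list[str]) -> str:
        return "| " + " | ".join(s.ljust(w) for s, w in zip(items, widths)) + " |"
    out = [line(cols), "| " + " | ".join("-" * w for w in widths) + " |"]
    out.extend(line(r) for r in cells)
    return "\n".join(out) + "\n"


def _cell(value) -> str:
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return str(value)


def write_table(df: pd.DataFrame, path: str | Path, fmt: str = "csv") -> Path:
    """Write ``df`` to ``path`` as csv, tsv, json (records) or markdown."""
    path = Path(path)
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; choose from {FORMATS}")
    if fmt == "csv":
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)  # csv.writer emits CRLF per RFC 4180
            writer.writerow(df.columns)
            for row in df.itertuples(index=False):
                writer.writerow(row)
    elif fmt == "tsv":
        df.to_csv(path, index=False, sep="\t")
    elif fmt == "json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=2) + "\n")
    else:
        path.write_text(_to_markdown(df))
    return path


def write_meta(path: str | Path, run_config: RunConfig) -> Path:
    """Write the sidecar metadata JSON next to an output file."""
    path = Path(path)
    meta_path = path.with_name(path.name + ".meta.json")
    meta = {"package": "porestates", "version": __version__,
            "run_config": run_config.to_dict()}
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return meta_path
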