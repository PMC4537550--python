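"""Reading and writing expression tables and result files.

The input format is a delimited text matrix (TSV or CSV): one header row of
strictly increasing numeric times, then one row per probe/gene with its id
in the first column.  Empty cells are allowed and masked; time units are
never rescaled on input (only the embedding's internal map onto [0, 2*pi]
touches them).  Every writer can attach a JSON sidecar carrying the full
run configuration and master seed, from which any output can be
regenerated bit-identically.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import BenchmarkDataset, TimeSeries

__all__ = [
    "ExpressionTable",
    "read_table",
    "write_table",
    "drop_leading_samples",
    "write_scores_tsv",
    "write_dataset_tsv",
    "write_sidecar",
]


@dataclass(frozen=True)
class ExpressionTable:
    """Row ids, numeric time header, value matrix with missing-value mask."""

    ids: tuple
    times: np.ndarray
    values: np.ndarray  # NaN where missing
    source: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("need at least 2 time columns")
        if not np.all(np.diff(t) > 0):
            raise ValueError("header times must be strictly increasing")
        if v.shape != (len(self.ids), t.size):
            raise ValueError("value matrix shape must be (n_rows, n_times)")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if list(self.ids).count(i) > 1})
            raise ValueError(f"duplicate row ids: {dupes[:5]}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def mask(self) -> np.ndarray:
        """True where a value is missing."""
        return np.isnan(self.values)

    def row(self, i: int) -> TimeSeries:
        """Row i as a TimeSeries over its observed samples only."""
        obs = ~self.mask[i]
        return TimeSeries(
            id=self.ids[i], times=self.times[obs], values=self.values[i, obs]
        )

    def __len__(self) -> int:
        return len(self.ids)


def _sniff_delimiter(path: Path) -> str:
    if path.suffix.lower() == ".csv":
        return ","
    if path.suffix.lower() in (".tsv", ".tab", ".txt"):
        return "\t"
    head = path.read_text().splitlines()[0]
    return "," if head.count(",") > head.count("\t") else "\t"


def read_table(path, delimiter: str | None = None) -> ExpressionTable:
    """Read a delimited expression matrix.

    Errors name the offending line/column: a non-numeric header entry, a
    non-increasing time pair, or a duplicated row id all reject the file.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delimiter))
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = rows[0]
    # the header may or may not carry a leading id-column label
    has_id_label = not _is_number(header[0])
    raw_times = header[1:] if has_id_label else header
    times = []
    for col, tok in enumerate(raw_times, start=2 if has_id_label else 1):
        try:
            times.append(float(tok))
        except ValueError:
            raise ValueError(
                f"{path}: line 1, column {col}: non-numeric time {tok!r}"
            ) from None
    for a in range(1, len(times)):
        if times[a] <= times[a - 1]:
            raise ValueError(
                f"{path}: line 1: times must be strictly increasing "
                f"(columns {a} and {a + 1}: {times[a - 1]} >= {times[a]})"
            )
    ids = []
    values = []
    for ln, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(times) + 1:
            raise ValueError(
                f"{path}: line {ln}: expected {len(times) + 1} fields, got {len(row)}"
            )
        ids.append(row[0])
        vals = []
        for col, tok in enumerate(row[1:], start=2):
            tok = tok.strip()
            if tok == "" or tok.upper() in ("NA", "NAN"):
                vals.append(np.nan)
            else:
                try:
                    vals.append(float(tok))
                except ValueError:
                    raise ValueError(
                        f"{path}: line {ln}, column {col}: non-numeric value {tok!r}"
                    ) from None
        values.append(vals)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate row ids: {dupes[:5]}")
    return ExpressionTable(
        ids=tuple(ids),
        times=np.asarray(times),
        values=np.asarray(values, dtype=float),
        source=str(path),
    )


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_table(table: ExpressionTable, path, delimiter: str = "\t") -> None:
    """Write an expression table back to delimited text (round-trip safe)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh, delimiter=delimiter)
        wr.writerow(["id"] + [repr(float(t)) for t in table.times])
        for i, rid in enumerate(table.ids):
            row = [rid] + [
                "" if np.isnan(v) else repr(float(v)) for v in table.values[i]
            ]
            wr.writerow(row)


def drop_leading_samples(table: ExpressionTable, k: int) -> ExpressionTable:
    """Remove the first k time columns (e.g. to skip a stress response)."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    if k >= table.times.size - 1:
        raise ValueError(
            f"cannot drop {k} of {table.times.size} time columns; "
            "at least 2 must remain"
        )
    if k == 0:
        return table
    return ExpressionTable(
        ids=table.ids,
        times=table.times[k:],
        values=table.values[:, k:],
        source=table.source,
    )


def write_scores_tsv(results, path) -> None:
    """Serialize scorer results: id, score, b, d, M, w, L, flags.

    Scores are reported to 6 decimals; a rank column (1 = most periodic,
    ties averaged) is appended.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "id": r.id,
                "score": round(r.score, 6),
                "b": round(r.b, 6) if not np.isnan(r.b) else "",
                "d": round(r.d, 6) if not np.isnan(r.d) else "",
                "M": r.params.M if r.params else "",
                "w": round(r.params.w, 6) if r.params else "",
                "L": r.params.L if r.params else "",
                "flags": ";".join(r.flags),
            }
        )
    df = pd.DataFrame(rows)
    df["rank"] = df["score"].rank(method="average")
    df.to_csv(path, sep="\t", index=False)


def write_dataset_tsv(dataset: BenchmarkDataset, path, sidecar: bool = True) -> None:
    """Write a synthetic dataset: one block per sampling density.

    Columns: id, shape, label, noise_model, noise_level, then one column per
    time point with a numeric-time header.  Cells with different sampling
    grids go to separate files suffixed with the sample count; a JSON
    sidecar records the generation config and seed.
    """
    path = Path(path)
    by_sampling: dict = {}
    for rec in dataset.records:
        by_sampling.setdefault(rec.n_samples, []).append(rec)
    many = len(by_sampling) > 1
    for n_samples, recs in by_sampling.items():
        out = (
            path.with_name(f"{path.stem}_n{n_samples}{path.suffix or '.tsv'}")
            if many
            else path
        )
        times = recs[0].series.times
        with open(out, "w", newline="") as fh:
            wr = csv.writer(fh, delimiter="\t")
            wr.writerow(
                ["id", "shape", "label", "noise_model", "noise_level"]
                + [repr(float(t)) for t in times]
            )
            for rec in recs:
                wr.writerow(
                    [
                        rec.series.id,
                        rec.shape,
                        "periodic" if rec.periodic else "non-periodic",
                        rec.noise_model,
                        repr(float(rec.noise_level)),
                    ]
                    + [repr(float(v)) for v in rec.series.values]
                )
    if sidecar:
        write_sidecar(
            path.with_suffix(".json"), {"config": dataset.config, "seed": dataset.seed}
        )


def write_sidecar(path, payload: dict) -> None:
    """JSON sidecar with configuration, seed and package version."""
    from . import __version__

    body = dict(payload)
    body.setdefault("version", __version__)
    Path(path).write_text(json.dumps(body, indent=2, sort_keys=True) + "\n")
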