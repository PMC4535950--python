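"""Ratings CSV dialect, JSON output, run manifests and the fixture registry.

The ratings CSV has one row per expert and one column per question, integer
cells, comma-delimited, with an optional header row (detected as any first
row that does not parse entirely as integers).
"""

from __future__ import annotations

import csv
import datetime
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from . import __version__
from .indices import IndexReport, RatingMatrix


class RatingsParseError(ValueError):
    """A ratings CSV cell that is not an integer on the scale, located by
    row and column (1-based, counting data rows only)."""


def read_ratings_csv(path: str | Path, scale_max: int = 10) -> RatingMatrix:
    """Read a ratings matrix (rows = experts, columns = questions).

    A first row with any non-integer cell is treated as a header and
    skipped.  Any later malformed or out-of-scale cell raises
    `RatingsParseError` naming the offending row and column.
    """
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh) if any(cell.strip() for cell in row)]
    if not rows:
        raise RatingsParseError(f"{path}: no data rows")

    def parse_row(cells: list[str]) -> list[int] | None:
        try:
            return [int(c.strip()) for c in cells]
        except ValueError:
            return None

    if parse_row(rows[0]) is None:
        rows = rows[1:]
        if not rows:
            raise RatingsParseError(f"{path}: header but no data rows")
    data = []
    for rnum, row in enumerate(rows, start=1):
        parsed = []
        for cnum, cell in enumerate(row, start=1):
            try:
                value = int(cell.strip())
            except ValueError:
                raise RatingsParseError(
                    f"{path}: row {rnum}, column {cnum}: not an integer: {cell!r}")
            if not 1 <= value <= scale_max:
                raise RatingsParseError(
                    f"{path}: row {rnum}, column {cnum}: rating {value} outside "
                    f"[1, {scale_max}]")
            parsed.append(value)
        if data and len(parsed) != len(data[0]):
            raise RatingsParseError(
                f"{path}: row {rnum} has {len(parsed)} cells, expected {len(data[0])}")
        data.append(parsed)
    return RatingMatrix(np.array(data, dtype=np.int64), scale_max)


def write_ratings_csv(matrix: RatingMatrix, path: str | Path,
                      header: bool = False) -> None:
    """Write a ratings matrix in the same dialect `read_ratings_csv` accepts."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if header:
            writer.writerow([f"Q{i + 1}" for i in range(matrix.n_items)])
        writer.writerows(matrix.scores.tolist())


def reports_to_json(reports: dict[str, IndexReport]) -> str:
    return json.dumps({k: v.to_dict() for k, v in reports.items()}, indent=2)


@dataclass(frozen=True)
class RunManifest:
    """Provenance record written alongside every output directory.

    Echoes the full configuration and master seed so any table or matrix in
    the directory can be regenerated bit-for-bit.
    """

    command: str
    config: dict
    master_seed: int | None
    outputs: tuple[str, ...]
    version: str = __version__
    timestamp: str = ""

    def write(self, directory: str | Path) -> Path:
        payload = {
            "command": self.command,
            "config": self.config,
            "master_seed": self.master_seed,
            "outputs": list(self.outputs),
            "version": self.version,
            "timestamp": self.timestamp
            or datetime.datetime.now(datetime.timezone.utc).isoformat(),
        }
        path = Path(directory) / "manifest.json"
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path


# ---------------------------------------------------------------------------
# Fixture registry: small deterministic matrices used in examples and tests
# ---------------------------------------------------------------------------

def _column(*scores: int) -> RatingMatrix:
    return RatingMatrix(np.array(scores, dtype=np.int64)[:, None])

_FIXTURES: dict[str, Callable[[], RatingMatrix]] = {
    # 9 experts split 3-vs-5 across the scale extremes, one straggler at 5:
    # the canonical clustered-dissensus worked example.
    "bimodal-9v3": lambda: _column(1, 1, 2, 9, 9, 10, 10, 10, 5),
    # Full unanimity at mid-scale.
    "unanimous-4": lambda: RatingMatrix(np.full((6, 2), 4, dtype=np.int64)),
    # One expert per scale point: maximal spread, no modal score.
    "uniform-spread": lambda: _column(*range(1, 11)),
    # Two tied modal scores two points apart: a single window covers both.
    "tied-modes": lambda: _column(5, 5, 7, 7),
    # Minimal disagreement: two experts agree, one dissents.
    "split-2v1": lambda: _column(5, 5, 7),
}


def fixture_names() -> tuple[str, ...]:
    return tuple(sorted(_FIXTURES))


def make_fixture(name: str) -> RatingMatrix:
    """Return a registered deterministic example matrix by name."""
    try:
        return _FIXTURES[name]()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; known: {', '.join(fixture_names())}")
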