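"""Contour readers/writers, mask tracing, run configuration, batch tables."""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .contours import DEFAULT_CURV_TOL, DEFAULT_STEP, DEFAULT_TOL, Contour
from .fuzzy import CLASS_IDS, round_half_up
from .pipeline import Diagnosis

logger = logging.getLogger("sinquad")


@dataclass(frozen=True)
class RunConfig:
    """Run-wide settings; the defaults reproduce the reference setup."""

    step: float = DEFAULT_STEP
    tol: float = DEFAULT_TOL
    curv_tol: float = DEFAULT_CURV_TOL
    class_config_path: str | None = None
    seed: int = 0
    log_level: str = "WARNING"


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("csv", "json"):
            raise ValueError("dialect must be 'csv' or 'json'")
        return dialect
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    return "csv"


def read_contour(path, dialect: str | None = None) -> Contour:
    """Read a contour from CSV (``x,y`` per row, optional header) or JSON
    (array of ``[x, y]`` pairs).  Points are taken in mathematical
    convention (y up); malformed rows are reported with their line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    kind = _infer_dialect(path, dialect)
    if kind == "json":
        with open(path) as fh:
            doc = json.load(fh)
        if not isinstance(doc, list):
            raise ValueError(f"{path}: JSON contour must be an array of [x, y] pairs")
        pts = []
        for k, row in enumerate(doc):
            if not isinstance(row, (list, tuple)) or len(row) != 2:
                raise ValueError(f"{path}: entry {k} is not an [x, y] pair")
            try:
                pts.append((float(row[0]), float(row[1])))
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}: entry {k} is not numeric") from exc
    else:
        pts = []
        with open(path, newline="") as fh:
            for lineno, row in enumerate(csv.reader(fh), start=1):
                if not row or all(not cell.strip() for cell in row):
                    continue
                cells = [cell.strip() for cell in row[:2]]
                if len(row) < 2:
                    raise ValueError(f"{path}:{lineno}: expected two columns x,y")
                try:
                    pts.append((float(cells[0]), float(cells[1])))
                except ValueError:
                    if lineno == 1:
                        continue  # optional header row
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric row {row!r}"
                    ) from None
    if len(pts) < 3:
        raise ValueError(f"{path}: contour needs at least 3 points, got {len(pts)}")
    return Contour(pts)


def write_contour(contour: Contour, path, dialect: str | None = None) -> None:
    """Write a contour at full precision in the CSV or JSON dialect."""
    path = Path(path)
    kind = _infer_dialect(path, dialect)
    pts = contour.points
    if kind == "json":
        with open(path, "w") as fh:
            json.dump([[float(x), float(y)] for x, y in pts], fh)
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["x", "y"])
            for x, y in pts:
                writer.writerow([repr(float(x)), repr(float(y))])


def contour_from_mask(mask) -> Contour:
    """Trace the outer boundary of a binary mask as a Contour.

    Marching squares at level 0.5 on the zero-padded mask; the longest
    boundary is kept.  Image row coordinates (y down) are flipped to the
    mathematical convention (y up) on ingest.
    """
    from skimage import measure

    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError("mask must be a 2-D array")
    arr = (arr > 0).astype(float)
    if arr.sum() == 0:
        raise ValueError("mask is empty")
    padded = np.pad(arr, 1)
    rings = measure.find_contours(padded, 0.5)
    if not rings:
        raise ValueError("no boundary found in mask")
    ring = max(rings, key=len)
    rows = ring[:, 0] - 1.0
    cols = ring[:, 1] - 1.0
    height = arr.shape[0]
    pts = np.column_stack([cols, (height - 1.0) - rows])
    return Contour(pts)


def diagnosis_table(entries: list[tuple[str, Diagnosis]]) -> pd.DataFrame:
    """Batch results as a table with per-class membership columns.

    One row per contour; for each anatomical class there are two columns
    (``mu_s_<K>``, ``mu_ns_<K>``) holding the 2-decimal memberships for the
    row's own class and the placeholder ``"x"`` for all absent classes —
    atypical contours carry ``"x"`` everywhere.
    """
    rows = []
    for name, diag in entries:
        row: dict[str, object] = {
            "contour": name,
            "key": diag.clinical_key,
            "coarse": diag.coarse,
            "alpha": "" if diag.alpha is None else f"{diag.alpha:.1f}",
            "final": diag.final,
        }
        for cid in CLASS_IDS:
            if diag.fuzzy is not None and cid == diag.class_id:
                row[f"mu_s_{cid}"] = f"{round_half_up(diag.fuzzy.mu_syn):.2f}"
                row[f"mu_ns_{cid}"] = f"{round_half_up(diag.fuzzy.mu_non_syn):.2f}"
            else:
                row[f"mu_s_{cid}"] = "x"
                row[f"mu_ns_{cid}"] = "x"
        rows.append(row)
    columns = ["contour", "key", "coarse", "alpha", "final"]
    for cid in CLASS_IDS:
        columns += [f"mu_s_{cid}", f"mu_ns_{cid}"]
    return pd.DataFrame(rows, columns=columns)
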