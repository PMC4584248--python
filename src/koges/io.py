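"""Plain-text file formats for direction sets and tensor coefficients.

Native direction files hold one direction per line as three whitespace
separated floats; ``#`` starts a comment.  The FSL bvec dialect (three
rows of N values) is auto-detected on read: a 3-row table whose column
count differs from 3 is transposed, and an ambiguous 3x3 table is read as
native with a warning.  Writers emit 16 significant digits plus a ``#``
provenance header.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np

from .tensor_model import DirectionSet, TensorCoeffs

__all__ = [
    "read_directions",
    "write_directions",
    "read_tensor",
    "write_tensor",
]

logger = logging.getLogger(__name__)


def _read_table(path) -> list[list[float]]:
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        try:
            rows.append([float(tok) for tok in body.split()])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: not a number row: {body!r}") from exc
    return rows


def read_directions(path, unit_tol: float = 1e-3) -> DirectionSet:
    """Read a direction file, auto-detecting native vs bvec layout."""
    rows = _read_table(path)
    if not rows:
        raise ValueError(f"{path}: no directions found")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged rows (widths {sorted(widths)})")
    arr = np.array(rows, dtype=float)
    if arr.shape[1] == 3:
        if arr.shape[0] == 3:
            logger.warning(
                "%s: 3x3 direction table is ambiguous; reading as native "
                "(one direction per line)", path,
            )
        return DirectionSet(arr, unit_tol=unit_tol)
    if arr.shape[0] == 3:
        return DirectionSet(arr.T, unit_tol=unit_tol)
    raise ValueError(f"{path}: expected an Nx3 or 3xN table, got {arr.shape}")


def write_directions(path, dirs: DirectionSet,
                     header: Iterable[str] = ()) -> None:
    """Write a native direction file (17 significant digits, enough
    to reconstruct the doubles exactly)."""
    lines = [f"# {h}" for h in header]
    lines += [" ".join(f"{v:.17g}" for v in p) for p in dirs.points]
    Path(path).write_text("\n".join(lines) + "\n")


def read_tensor(path, order: int = 4) -> TensorCoeffs:
    """Read a tensor coefficient file: one float per line (or one row)."""
    rows = _read_table(path)
    vals = np.array([v for r in rows for v in r], dtype=float)
    return TensorCoeffs(order, vals)


def write_tensor(path, t: TensorCoeffs, header: Iterable[str] = ()) -> None:
    lines = [f"# {h}" for h in header]
    lines += [f"{v:.17g}" for v in t.coeffs]
    Path(path).write_text("\n".join(lines) + "\n")
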