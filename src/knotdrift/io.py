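"""Readers/writers and seed management binding the modules together.

One tabular dialect everywhere: tab-separated values with ``#``-prefixed
metadata/header lines, written deterministically (fixed float format) so
that write -> read -> write is byte-stable.  3D frames use plain XYZ.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "write_tsv",
    "read_tsv",
    "write_xyz",
    "read_xyz",
    "load_config",
    "spawn_seeds",
    "compare_curves",
]

_FLOAT_FMT = "%.10g"


def write_tsv(path, columns: dict[str, np.ndarray],
              meta: Optional[dict] = None) -> None:
    """Write named columns as TSV with ``#`` metadata and header lines."""
    path = Path(path)
    names = list(columns)
    arrs = [np.asarray(columns[n]) for n in names]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("all columns must have equal length")
    with path.open("w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k} = {v}\n")
        fh.write("# " + "\t".join(names) + "\n")
        for i in range(n):
            fh.write("\t".join(
                _FLOAT_FMT % a[i] if np.issubdtype(a.dtype, np.floating)
                else str(a[i]) for a in arrs) + "\n")


def read_tsv(path) -> tuple[dict[str, np.ndarray], dict[str, str]]:
    """Read a TSV written by :func:`write_tsv`; returns (columns, meta)."""
    meta: dict[str, str] = {}
    header: Optional[list[str]] = None
    rows: list[list[str]] = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                else:
                    header = body.split("\t")
            else:
                rows.append(line.split("\t"))
    if header is None:
        raise ValueError(f"{path}: missing '# name\\tname...' header line")
    cols: dict[str, np.ndarray] = {}
    for j, name in enumerate(header):
        vals = [r[j] for r in rows]
        try:
            cols[name] = np.array([float(v) for v in vals])
        except ValueError:
            cols[name] = np.array(vals)
    return cols, meta


def write_xyz(path, frames: np.ndarray, element: str = "C",
              comment: str = "") -> None:
    """Write (n_frames, N, 3) positions as a multi-frame XYZ file."""
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    with Path(path).open("w") as fh:
        for f, frame in enumerate(frames):
            fh.write(f"{len(frame)}\n{comment} frame {f}\n")
            for x, y, z in frame:
                fh.write(f"{element} {_FLOAT_FMT % x} {_FLOAT_FMT % y} {_FLOAT_FMT % z}\n")


def read_xyz(path) -> np.ndarray:
    """Read a multi-frame XYZ file into (n_frames, N, 3)."""
    frames = []
    with Path(path).open() as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        block = lines[i + 2: i + 2 + n]
        frames.append([[float(v) for v in ln.split()[1:4]] for ln in block])
        i += 2 + n
    return np.array(frames)


def load_config(path) -> dict:
    """Flat JSON key-value experiment configuration."""
    with Path(path).open() as fh:
        return json.load(fh)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Fan one global seed out to n reproducible child seeds (< 2^31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n, dtype=np.uint64)]


def compare_curves(
    t_a: np.ndarray, y_a: np.ndarray,
    t_b: np.ndarray, y_b: np.ndarray,
    n_runs: Optional[int] = None,
) -> dict:
    """Max deviation (and Monte-Carlo z-scores) between two curves.

    Curve B is linearly resampled onto A's grid.  When ``n_runs`` is
    given, y_a is treated as an empirical probability from n_runs
    Bernoulli trials and per-point z-scores use the binomial error
    ``sqrt(p (1-p) / n)`` (floored at 1/n to avoid zero division).
    """
    t_a = np.asarray(t_a, float)
    y_a = np.asarray(y_a, float)
    yb = np.interp(t_a, np.asarray(t_b, float), np.asarray(y_b, float))
    dev = y_a - yb
    out = {"max_abs_dev": float(np.max(np.abs(dev)))}
    if n_runs:
        p = np.clip(yb, 0.0, 1.0)
        sigma = np.sqrt(np.maximum(p * (1 - p), 1.0 / n_runs) / n_runs)
        out["z"] = dev / sigma
        out["max_abs_z"] = float(np.max(np.abs(dev / sigma)))
    return out
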