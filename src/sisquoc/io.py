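"""Structured-text file formats for margins, joints, pattern frequencies
and study configuration.

All formats are plain text.  Floating-point values are written with
Python's shortest round-trip ``repr``, so writer -> reader round trips
are bit-exact.  Readers validate the same invariants as the in-memory
constructors and report parse failures with line numbers.

Margins file layout (``# sisquoc-margins v1``)::

    # sisquoc-margins v1
    items 3
    categories 2 3 2
    kind probability        # or: kind count, followed by "N <int>"
    seed <free-form provenance, optional>
    item 0
    0.25 0.75
    ...
    pair 0 1
    0.1 0.05 0.1
    0.15 0.3 0.3

Joint file: ``# sisquoc-joint v1``, a ``shape`` line, then the pattern
probabilities one per line in C (lexicographic) order.  Pattern
frequencies are CSV with one column per item plus ``freq``.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import FileFormatError, SisquocError
from .core import BivariateTable, MarginVector
from .fit_propensity import FPStudyConfig
from .ipfp import JointTable
from .sampler import DatasetMargins

__all__ = [
    "write_margins",
    "read_margins",
    "write_joint",
    "read_joint",
    "write_pattern_freqs",
    "read_pattern_freqs",
    "write_fp_config",
    "read_fp_config",
]

_MARGINS_MAGIC = "# sisquoc-margins v1"
_JOINT_MAGIC = "# sisquoc-joint v1"


def _fmt(values: np.ndarray) -> str:
    return " ".join(repr(float(v)) for v in np.asarray(values).reshape(-1))


def write_margins(d: DatasetMargins, path: str | Path, seed_note: str | None = None) -> None:
    """Write a margins dataset; lossless to full double precision."""
    lines = [_MARGINS_MAGIC]
    spec = d.item_spec
    lines.append(f"items {spec.n_items}")
    lines.append("categories " + " ".join(str(k) for k in spec.categories))
    if d.sample_size is None:
        lines.append("kind probability")
    else:
        lines.append("kind count")
        lines.append(f"N {d.sample_size}")
    if seed_note is not None:
        lines.append(f"seed {seed_note}")
    for j, m in enumerate(d.univariate):
        lines.append(f"item {j}")
        lines.append(_fmt(m.probs))
    for (i, j), t in sorted(d.bivariate.items()):
        lines.append(f"pair {i} {j}")
        for row in t.cells:
            lines.append(_fmt(row))
    Path(path).write_text("\n".join(lines) + "\n")


class _Cursor:
    def __init__(self, path: Path):
        self.lines = path.read_text().splitlines()
        self.i = 0

    def next(self) -> str:
        while self.i < len(self.lines) and not self.lines[self.i].strip():
            self.i += 1
        if self.i >= len(self.lines):
            raise FileFormatError(f"unexpected end of file at line {self.i + 1}")
        self.i += 1
        return self.lines[self.i - 1].strip()

    def err(self, msg: str) -> FileFormatError:
        return FileFormatError(f"line {self.i}: {msg}")


def _floats(line: str, cur: _Cursor, n: int) -> np.ndarray:
    try:
        vals = np.array([float(x) for x in line.split()])
    except ValueError as e:
        raise cur.err(f"expected numbers, got {line!r}") from e
    if vals.size != n:
        raise cur.err(f"expected {n} values, got {vals.size}")
    return vals


def read_margins(path: str | Path) -> DatasetMargins:
    """Parse a margins file, validating all dataset invariants."""
    cur = _Cursor(Path(path))
    if cur.next() != _MARGINS_MAGIC:
        raise cur.err(f"not a margins file (missing {_MARGINS_MAGIC!r})")
    n_items = int(cur.next().split()[1])
    cats = [int(x) for x in cur.next().split()[1:]]
    if len(cats) != n_items:
        raise cur.err("categories line disagrees with item count")
    kind = cur.next().split()[1]
    sample_size = None
    if kind == "count":
        sample_size = int(cur.next().split()[1])
    elif kind != "probability":
        raise cur.err(f"unknown kind {kind!r}")
    # optional provenance line
    line = cur.next()
    if line.startswith("seed"):
        line = cur.next()

    uni: list[MarginVector] = []
    for j in range(n_items):
        if j > 0:
            line = cur.next()
        if line != f"item {j}":
            raise cur.err(f"expected 'item {j}', got {line!r}")
        try:
            uni.append(MarginVector(_floats(cur.next(), cur, cats[j])))
        except SisquocError as e:
            raise cur.err(f"item {j} margin invalid: {e}") from e
    biv: dict[tuple[int, int], BivariateTable] = {}
    for i in range(n_items):
        for j in range(i + 1, n_items):
            line = cur.next()
            if line != f"pair {i} {j}":
                raise cur.err(f"expected 'pair {i} {j}', got {line!r}")
            rows = [_floats(cur.next(), cur, cats[j]) for _ in range(cats[i])]
            try:
                biv[(i, j)] = BivariateTable(np.array(rows), row_item=i, col_item=j)
            except SisquocError as e:
                raise cur.err(f"pair ({i}, {j}) table invalid: {e}") from e
    try:
        return DatasetMargins(uni, biv, sample_size=sample_size)
    except SisquocError as e:
        raise FileFormatError(f"{path}: {e}") from e


def write_joint(joint: JointTable, path: str | Path) -> None:
    lines = [_JOINT_MAGIC, "shape " + " ".join(str(k) for k in joint.probs.shape)]
    lines.append(
        f"meta iterations={joint.iterations} converged={joint.converged} "
        f"max_change={joint.max_change!r} max_margin_residual={joint.max_margin_residual!r}"
    )
    lines.extend(repr(float(p)) for p in joint.probs.reshape(-1))
    Path(path).write_text("\n".join(lines) + "\n")


def read_joint(path: str | Path) -> JointTable:
    cur = _Cursor(Path(path))
    if cur.next() != _JOINT_MAGIC:
        raise cur.err(f"not a joint file (missing {_JOINT_MAGIC!r})")
    shape = tuple(int(x) for x in cur.next().split()[1:])
    meta = dict(kv.split("=") for kv in cur.next().split()[1:])
    total = int(np.prod(shape))
    vals = np.array([float(cur.next()) for _ in range(total)]).reshape(shape)
    if np.any(vals < 0):
        raise FileFormatError(f"{path}: negative pattern probability")
    if abs(vals.sum() - 1.0) > 1e-8:
        raise FileFormatError(f"{path}: pattern probabilities sum to {vals.sum()}")
    return JointTable(
        vals,
        iterations=int(meta.get("iterations", 0)),
        max_change=float(meta.get("max_change", "nan")),
        converged=meta.get("converged", "True") == "True",
        max_margin_residual=float(meta.get("max_margin_residual", "nan")),
    )


def write_pattern_freqs(freqs: pd.DataFrame, path: str | Path) -> None:
    freqs.to_csv(path, index=False)


def read_pattern_freqs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "freq" not in df.columns:
        raise FileFormatError(f"{path}: missing 'freq' column")
    item_cols = [c for c in df.columns if c != "freq"]
    if df[item_cols].duplicated().any():
        dup = df[item_cols][df[item_cols].duplicated()].iloc[0].tolist()
        raise FileFormatError(f"{path}: duplicate pattern row {dup}")
    if (df["freq"] < 0).any():
        raise FileFormatError(f"{path}: negative frequency")
    return df


def write_fp_config(cfg: FPStudyConfig, path: str | Path) -> None:
    d = asdict(cfg)
    d["models"] = list(d["models"])
    if d["cutoffs"] is not None:
        d["cutoffs"] = list(d["cutoffs"])
    Path(path).write_text(json.dumps(d, indent=2) + "\n")


def read_fp_config(path: str | Path) -> FPStudyConfig:
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise FileFormatError(f"{path}: {e}") from e
    d["models"] = tuple(d.get("models", ("grm", "gpcm")))
    if d.get("cutoffs") is not None:
        d["cutoffs"] = tuple(d["cutoffs"])
    try:
        return FPStudyConfig(**d)
    except TypeError as e:
        raise FileFormatError(f"{path}: {e}") from e
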