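"""Genotype-table and model-file I/O.

Genotype-table format: tab-separated with a header row; column
``genotype`` holds the L-character 0/1 string (site 0 first, i.e. in
``site_labels`` order) and either a single ``fitness`` column or replicate
columns ``rep1``, ``rep2``, ...  An optional leading comment line
``# site_labels: 26,27,...`` carries site identifiers.  Rows are written
in ascending integer-encoding order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .landscape import EpistasisCoefficients, FitnessLandscape, bits_to_index

__all__ = [
    "read_genotype_table",
    "write_genotype_table",
    "read_coefficients",
    "write_coefficients",
    "read_global_model",
    "write_global_model",
    "GenotypeTableError",
]


class GenotypeTableError(ValueError):
    """Malformed genotype table (message includes the offending line)."""


def write_genotype_table(
    path: str | Path,
    ls: FitnessLandscape | None = None,
    replicates: np.ndarray | None = None,
    site_labels: list[str] | None = None,
) -> None:
    """Write a landscape or a replicate set in the genotype-table format."""
    if ls is not None:
        L = ls.L
        labels = site_labels or ls.site_labels
        columns = {"fitness": ls.fitness}
    elif replicates is not None:
        replicates = np.atleast_2d(np.asarray(replicates, dtype=float))
        L = int(np.log2(replicates.shape[1]))
        if replicates.shape[1] != 2**L:
            raise ValueError("replicate tables must have 2**L rows")
        labels = site_labels
        columns = {f"rep{i + 1}": replicates[i] for i in range(replicates.shape[0])}
    else:
        raise ValueError("provide a landscape or replicates")
    with open(path, "w") as fh:
        if labels is not None:
            fh.write("# site_labels: " + ",".join(labels) + "\n")
        fh.write("genotype\t" + "\t".join(columns) + "\n")
        for idx in range(2**L):
            bits = "".join(str((idx >> i) & 1) for i in range(L))
            vals = "\t".join(f"{columns[c][idx]:.10g}" for c in columns)
            fh.write(f"{bits}\t{vals}\n")


def read_genotype_table(
    path: str | Path,
) -> tuple[FitnessLandscape | None, np.ndarray | None, list[str] | None]:
    """Read and validate a genotype table.

    Returns ``(landscape, replicates, site_labels)``: ``landscape`` is set
    when the file has a single ``fitness`` column, ``replicates`` (shape
    ``(n_rep, 2**L)``) when it has ``rep*`` columns.  Completeness (every
    genotype exactly once) is enforced.
    """
    labels: list[str] | None = None
    header: list[str] | None = None
    L = None
    values: dict[int, list[float]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if "site_labels:" in line:
                    labels = [
                        s.strip()
                        for s in line.split("site_labels:", 1)[1].split(",")
                    ]
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header[0] != "genotype":
                    raise GenotypeTableError(
                        f"line {lineno}: first column must be 'genotype'"
                    )
                data_cols = header[1:]
                if data_cols != ["fitness"] and not all(
                    c.startswith("rep") for c in data_cols
                ):
                    raise GenotypeTableError(
                        f"line {lineno}: data columns must be 'fitness' or 'rep*'"
                    )
                continue
            if len(fields) != len(header):
                raise GenotypeTableError(
                    f"line {lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            bits_str = fields[0]
            if L is None:
                L = len(bits_str)
            if len(bits_str) != L or any(ch not in "01" for ch in bits_str):
                raise GenotypeTableError(
                    f"line {lineno}: malformed genotype {bits_str!r}"
                )
            idx = bits_to_index([int(ch) for ch in bits_str])
            if idx in values:
                raise GenotypeTableError(
                    f"line {lineno}: duplicate genotype {bits_str}"
                )
            try:
                values[idx] = [float(v) for v in fields[1:]]
            except ValueError as e:
                raise GenotypeTableError(f"line {lineno}: non-numeric fitness") from e
    if header is None or L is None:
        raise GenotypeTableError("empty genotype table")
    n = 2**L
    if len(values) != n:
        missing = next(i for i in range(n) if i not in values)
        bits = "".join(str((missing >> i) & 1) for i in range(L))
        raise GenotypeTableError(
            f"incomplete table: genotype {bits} absent ({len(values)}/{n} present)"
        )
    mat = np.array([values[i] for i in range(n)], dtype=float).T
    if labels is not None and len(labels) != L:
        raise GenotypeTableError("site_labels length does not match genotype length")
    if header[1:] == ["fitness"]:
        return FitnessLandscape(L, mat[0], labels), None, labels
    return None, mat, labels


def write_global_model(path: str | Path, model) -> None:
    """Serialize a fitted global-epistasis model as JSON text."""
    obj = {
        "L": model.L,
        "h": [float(v) for v in model.h],
        "g_knots": [[float(k), float(v)] for k, v in zip(model.g_knots, model.g_values)],
    }
    Path(path).write_text(json.dumps(obj, indent=1))


def read_global_model(path: str | Path):
    from .inference import GlobalEpistasisModel

    obj = json.loads(Path(path).read_text())
    knots = np.array([k for k, _ in obj["g_knots"]])
    values = np.array([v for _, v in obj["g_knots"]])
    return GlobalEpistasisModel(int(obj["L"]), np.array(obj["h"]), knots, values)


def write_coefficients(path: str | Path, c: EpistasisCoefficients) -> None:
    """Serialize (h, J, K) coefficients as structured JSON text."""
    from .synthetic import _coefficients_to_json

    Path(path).write_text(json.dumps(_coefficients_to_json(c), indent=1))


def read_coefficients(path: str | Path) -> EpistasisCoefficients:
    from .synthetic import _coefficients_from_json

    return _coefficients_from_json(json.loads(Path(path).read_text()))
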