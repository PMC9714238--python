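"""Readers and writers: genotype tables, distance matrices, JSON samples.

The genotype table contract: a delimited text file with a header row
naming a sample-ID column, a population column, and one column per locus.
DYS385 may appear either as a single column holding both alleles
("11,14") or as two columns DYS385a/DYS385b.  Microvariants are decimal
("17.2").  Missing calls are empty cells or one of ``-``, ``NA``,
``null``.
"""

from __future__ import annotations

import io as _io
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd

from .markers import (
    AlleleValidationError,
    Haplotype,
    Panel,
    PopulationSample,
    YFILER17,
)

__all__ = [
    "GenotypeFormatError",
    "TableDialect",
    "load_genotype_table",
    "write_genotype_table",
    "read_distance_matrix",
    "write_distance_matrix",
    "samples_to_json",
    "samples_from_json",
]

_MISSING_TOKENS = {"", "-", ".", "na", "n/a", "null", "none", "nan"}

_ID_COLUMNS = {"sampleid", "sample", "id", "sample_id", "sampleno"}
_POP_COLUMNS = {"population", "pop", "group", "ethnicgroup", "ethnicity"}


class GenotypeFormatError(ValueError):
    """Structural problem with a genotype table (missing/ambiguous columns)."""


@dataclass(frozen=True)
class TableDialect:
    """Parsing options for genotype tables.

    delimiter: column separator; ``None`` sniffs between tab and comma.
    dys385_sep: separator inside a single DYS385 cell ("11,14", "11-14").
    """

    delimiter: str | None = None
    dys385_sep: str = ","


def _norm(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", name.lower())


def _match_locus_columns(columns: Sequence[str], panel: Panel) -> dict[str, object]:
    """Map panel locus name -> source column name (or (a, b) for split DYS385)."""
    by_norm = {_norm(c): c for c in columns}
    mapping: dict[str, object] = {}
    for locus in panel.locus_names:
        key = _norm(locus)
        if locus == "DYS385":
            if key in by_norm:
                mapping[locus] = by_norm[key]
            elif key + "a" in by_norm and key + "b" in by_norm:
                mapping[locus] = (by_norm[key + "a"], by_norm[key + "b"])
            else:
                raise GenotypeFormatError(
                    "missing required column DYS385 (or DYS385a/DYS385b)"
                )
        else:
            if key not in by_norm:
                raise GenotypeFormatError(f"missing required column {locus}")
            mapping[locus] = by_norm[key]
    return mapping


def _parse_cell(raw: object) -> float | None:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    s = str(raw).strip()
    if s.lower() in _MISSING_TOKENS:
        return None
    return float(s)  # ValueError propagates to caller for row reporting


def load_genotype_table(
    source: str | Path | TextIO,
    panel: Panel = YFILER17,
    dialect: TableDialect = TableDialect(),
    errors: str = "strict",
) -> list[PopulationSample]:
    """Parse a delimited genotype table into one sample per population label.

    ``errors='strict'`` raises on the first bad row; ``errors='report'``
    returns good samples and attaches the list of (sample_id, message)
    problems as the ``.problems`` attribute of the returned list.
    """
    if errors not in ("strict", "report"):
        raise ValueError("errors must be 'strict' or 'report'")
    sep = dialect.delimiter
    if sep is None:
        if hasattr(source, "read"):
            text = source.read()
        else:
            text = Path(source).read_text()
        data_lines = [l for l in text.splitlines() if l and not l.startswith("#")]
        first = data_lines[0] if data_lines else ""
        sep = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
        source = _io.StringIO(text)
    df = pd.read_csv(source, sep=sep, dtype=str, comment="#", skipinitialspace=True)
    df.columns = [str(c).strip() for c in df.columns]

    id_col = next((c for c in df.columns if _norm(c) in _ID_COLUMNS), None)
    pop_col = next((c for c in df.columns if _norm(c) in _POP_COLUMNS), None)
    if id_col is None:
        raise GenotypeFormatError("missing required sample-ID column (e.g. 'SampleID')")
    if pop_col is None:
        raise GenotypeFormatError("missing required population column (e.g. 'Population')")
    locus_cols = _match_locus_columns(df.columns, panel)

    by_pop: dict[str, list[Haplotype]] = {}
    problems: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        sid = str(row[id_col]).strip()
        pop = str(row[pop_col]).strip()
        try:
            alleles: dict[str, object] = {}
            for locus, col in locus_cols.items():
                if locus == "DYS385":
                    if isinstance(col, tuple):
                        a, b = _parse_cell(row[col[0]]), _parse_cell(row[col[1]])
                        vals = [v for v in (a, b) if v is not None]
                        alleles[locus] = tuple(vals) if vals else None
                    else:
                        cell = row[col]
                        if (
                            cell is None
                            or (isinstance(cell, float) and np.isnan(cell))
                            or str(cell).strip().lower() in _MISSING_TOKENS
                        ):
                            alleles[locus] = None
                        else:
                            parts = str(cell).strip().split(dialect.dys385_sep)
                            alleles[locus] = tuple(float(p.strip()) for p in parts)
                else:
                    alleles[locus] = _parse_cell(row[col])
            hap = Haplotype(sample_id=sid, population=pop, alleles=alleles)
        except (ValueError, AlleleValidationError) as exc:
            msg = f"row {sid}: {exc}"
            if errors == "strict":
                raise AlleleValidationError(msg) from exc
            problems.append((sid, str(exc)))
            continue
        by_pop.setdefault(pop, []).append(hap)

    samples = [
        PopulationSample(label=pop, haplotypes=tuple(haps), panel=panel)
        for pop, haps in by_pop.items()
    ]
    if errors == "report":
        class _ReportList(list):
            pass

        out = _ReportList(samples)
        out.problems = problems
        return out
    return samples


def _fmt_allele(v: float | None) -> str:
    if v is None:
        return ""
    return f"{v:g}"


def write_genotype_table(
    samples: Iterable[PopulationSample],
    path: str | Path | TextIO,
    dialect: TableDialect = TableDialect(delimiter="\t"),
    header_comment: str | None = None,
) -> None:
    """Write samples back to a delimited table (inverse of the loader)."""
    samples = list(samples)
    if not samples:
        raise ValueError("no samples to write")
    panel = samples[0].panel
    sep = dialect.delimiter or "\t"
    rows = []
    for s in samples:
        for h in s.haplotypes:
            row = {"SampleID": h.sample_id, "Population": s.label}
            for locus in panel.locus_names:
                v = h.alleles.get(locus)
                if locus == "DYS385":
                    row[locus] = (
                        "" if v is None
                        else dialect.dys385_sep.join(_fmt_allele(x) for x in v)
                    )
                else:
                    row[locus] = _fmt_allele(v)
            rows.append(row)
    df = pd.DataFrame(rows)
    if hasattr(path, "write"):
        if header_comment:
            path.write(f"# {header_comment}\n")
        df.to_csv(path, sep=sep, index=False)
    else:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, sep=sep, index=False)


def write_distance_matrix(
    labels: Sequence[str],
    values: np.ndarray,
    path: str | Path | TextIO,
    pvalues: np.ndarray | None = None,
    header_comment: str | None = None,
) -> None:
    """Write a labeled square matrix as TSV.

    If ``pvalues`` is given, the upper triangle holds p-values and the
    lower triangle the distances (the conventional compact layout).
    """
    values = np.asarray(values, dtype=float)
    m = values.copy()
    if pvalues is not None:
        pv = np.asarray(pvalues, dtype=float)
        iu = np.triu_indices(len(labels), k=1)
        m[iu] = pv[iu]
    df = pd.DataFrame(m, index=list(labels), columns=list(labels))
    if hasattr(path, "write"):
        if header_comment:
            path.write(f"# {header_comment}\n")
        df.to_csv(path, sep="\t", index_label="")
    else:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, sep="\t", index_label="")


def read_distance_matrix(path: str | Path | TextIO) -> tuple[list[str], np.ndarray]:
    """Read a labeled square matrix written by :func:`write_distance_matrix`.

    Returns (labels, full matrix as stored); callers wanting a symmetric
    matrix from the compact layout should mirror the lower triangle.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    labels = [str(x) for x in df.index]
    if list(map(str, df.columns)) != labels:
        raise ValueError("distance matrix rows and columns disagree")
    return labels, df.to_numpy(dtype=float)


def samples_to_json(samples: Iterable[PopulationSample]) -> str:
    """JSON serialization of samples (panel by name, alleles by locus)."""
    payload = []
    for s in samples:
        payload.append(
            {
                "label": s.label,
                "panel": s.panel.name,
                "panel_loci": list(s.panel.locus_names),
                "haplotypes": [
                    {
                        "sample_id": h.sample_id,
                        "alleles": {
                            k: (
                                list(h.alleles[k])
                                if isinstance(h.alleles[k], tuple)
                                else h.alleles[k]
                            )
                            for k in s.panel.locus_names  # canonical order
                            if k in h.alleles
                        },
                    }
                    for h in s.haplotypes
                ],
            }
        )
    return json.dumps(payload, indent=1)


def samples_from_json(text: str) -> list[PopulationSample]:
    from .markers import LocusDef

    payload = json.loads(text)
    out = []
    for entry in payload:
        panel = Panel(
            entry["panel"],
            tuple(
                LocusDef(n, copy_number=2 if n == "DYS385" else 1)
                for n in entry["panel_loci"]
            ),
        )
        haps = tuple(
            Haplotype(
                sample_id=h["sample_id"],
                population=entry["label"],
                alleles={
                    k: (tuple(v) if isinstance(v, list) else v)
                    for k, v in h["alleles"].items()
                },
            )
            for h in entry["haplotypes"]
        )
        out.append(PopulationSample(label=entry["label"], haplotypes=haps, panel=panel))
    return out
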