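"""Readers and writers for the external file formats.

Conventions: genomic coordinates are 0-based half-open everywhere; TSV is
the canonical tabular dialect (CSV only for dose matrices); parsers
reject malformed input with the offending line or cell rather than
silently coercing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .drug import DoseMatrix
from .peaks import PeakSet, RegionSet
from .stratify import ExpressionMatrix
from .motifs import read_pfm  # noqa: F401  (re-exported format reader)
from .signatures import read_signature, write_signature  # noqa: F401

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_clinical_tsv",
    "write_clinical_tsv",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_bed_regions",
    "read_bed6_hits",
    "read_dose_matrix_csv",
    "write_dose_matrix_csv",
    "read_pfm",
    "read_signature",
    "write_signature",
    "write_manifest",
]


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Expression TSV: first column gene symbols, remaining columns samples."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    dup = {s for s in samples if samples.count(s) > 1}
    if dup:
        raise ValueError(f"duplicate sample column(s) in {path.name}: {sorted(dup)}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.columns = samples
    try:
        values = df.astype(float)
    except ValueError:
        for gene, row in df.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at gene {gene!r}, sample {sample!r}: {cell!r}"
                    ) from None
        raise
    return ExpressionMatrix(values)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene", float_format="%.9g")


def read_clinical_tsv(path: str | Path) -> pd.DataFrame:
    """Clinical TSV with columns sample, time, event and optional extras."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"clinical table requires a '{col}' column")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"duplicate sample in clinical table: {dup!r}")
    return df


def write_clinical_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.9g")


def _parse_peak_line(fields: list[str], lineno: int, path: Path):
    try:
        chrom = fields[0]
        start, end = int(fields[1]), int(fields[2])
        score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
        if len(fields) >= 10:
            off = int(fields[9])
            summit = start + off if off >= 0 else (start + end) // 2
        else:
            summit = (start + end) // 2
        if not (start <= summit < end) or end <= start:
            raise ValueError
        return chrom, start, end, summit, score
    except (ValueError, IndexError):
        raise ValueError(f"malformed peak line {lineno} in {path.name}") from None


def read_narrowpeak(path: str | Path) -> PeakSet:
    """ENCODE narrowPeak (10 columns) or BED6 fallback.

    The summit is start + column-10 offset; an offset of -1 (or a BED6
    file) falls back to the interval midpoint.
    """
    path = Path(path)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            records.append(_parse_peak_line(line.split("\t"), lineno, path))
    if not records:
        raise ValueError(f"no peaks in {path.name}")
    return PeakSet(
        pd.DataFrame(records, columns=["chrom", "start", "end", "summit", "score"])
    )


def write_narrowpeak(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, row in peaks.frame.iterrows():
            off = int(row["summit"]) - int(row["start"])
            fh.write(
                f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t"
                f"peak_{i}\t{row['score']:.6g}\t.\t0\t-1\t-1\t{off}\n"
            )


def read_bed_regions(path: str | Path) -> RegionSet:
    """BED3+ region file -> RegionSet (extra columns ignored)."""
    path = Path(path)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                records.append((fields[0], int(fields[1]), int(fields[2])))
            except (ValueError, IndexError):
                raise ValueError(
                    f"malformed BED line {lineno} in {path.name}"
                ) from None
    if not records:
        raise ValueError(f"no regions in {path.name}")
    return RegionSet(pd.DataFrame(records, columns=["chrom", "start", "end"]))


def read_bed6_hits(path: str | Path) -> pd.DataFrame:
    """Motif hits as BED6 (chrom, start, end, name, score, strand)."""
    path = Path(path)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                records.append(
                    (f[0], int(f[1]), int(f[2]), f[5], float(f[4]))
                )
            except (ValueError, IndexError):
                raise ValueError(
                    f"malformed BED6 line {lineno} in {path.name}"
                ) from None
    return pd.DataFrame(
        records, columns=["chrom", "start", "end", "strand", "score"]
    )


def read_dose_matrix_csv(path: str | Path) -> DoseMatrix:
    """Dose matrix CSV: first row / first column hold the doses (0 included)."""
    df = pd.read_csv(path, index_col=0)
    try:
        doses_a = df.index.astype(float).to_numpy()
        doses_b = df.columns.astype(float).to_numpy()
    except (TypeError, ValueError):
        raise ValueError("dose labels must be numeric") from None
    return DoseMatrix(
        doses_a=doses_a, doses_b=doses_b, inhibition=df.to_numpy(dtype=float)
    )


def write_dose_matrix_csv(matrix: DoseMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, index_label="dose_a", float_format="%.9g")


def write_manifest(path: str | Path, **entries) -> None:
    """Write a JSON run manifest (inputs, parameters, seed, version)."""
    from . import __version__

    payload = {"package_version": __version__, **entries}

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        return str(o)

    Path(path).write_text(json.dumps(payload, indent=2, default=default) + "\n")
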