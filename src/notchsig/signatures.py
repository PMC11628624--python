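"""Gene-signature curation from differential-expression tables.

Signatures are built in three steps: thresholded selection of regulated
genes per experiment, union across cell lines, intersection with a
gain-of-function experiment, and merge with a canonical target list.
The curated 77-gene TNBC NOTCH activity signature ships as packaged data.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import pandas as pd

__all__ = [
    "DETable",
    "GeneSignature",
    "select_regulated_genes",
    "curate_signature",
    "load_packaged_signature",
    "PACKAGED_SIGNATURES",
]


def _clean_symbol(sym: str) -> str:
    return str(sym).strip().upper()


@dataclass(frozen=True)
class DETable:
    """Differential-expression table: one record per gene.

    Parameters
    ----------
    frame : DataFrame with columns ``gene``, ``log2fc`` and optionally
        ``padj``. Gene symbols must be unique after upper-casing.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("gene", "log2fc"):
            if col not in df.columns:
                raise ValueError(f"DETable requires a '{col}' column")
        genes = df["gene"].map(_clean_symbol)
        if (genes == "").any():
            raise ValueError("DETable contains an empty gene symbol")
        dup = genes[genes.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate gene in DETable: {dup.iloc[0]!r}")
        if "padj" in df.columns:
            p = df["padj"].dropna()
            if ((p < 0) | (p > 1)).any():
                raise ValueError("padj values must lie in [0, 1]")
        clean = df.copy()
        clean["gene"] = genes.values
        object.__setattr__(self, "frame", clean.reset_index(drop=True))

    @classmethod
    def from_records(
        cls, records: Mapping[str, tuple[float, float | None]] | Iterable
    ) -> "DETable":
        """Build from {gene: (log2fc, padj)} or iterable of such tuples."""
        if not records:
            return cls(pd.DataFrame(columns=["gene", "log2fc", "padj"]))
        if isinstance(records, Mapping):
            rows = [
                {"gene": g, "log2fc": v[0], "padj": v[1] if len(v) > 1 else None}
                for g, v in records.items()
            ]
        else:
            rows = [dict(zip(("gene", "log2fc", "padj"), r)) for r in records]
        return cls(pd.DataFrame(rows))

    @property
    def has_padj(self) -> bool:
        return "padj" in self.frame.columns and self.frame["padj"].notna().all()


@dataclass(frozen=True)
class GeneSignature:
    """Named, ordered set of unique uppercase gene symbols."""

    name: str
    genes: tuple[str, ...]
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = tuple(_clean_symbol(g) for g in self.genes)
        if any(g == "" for g in cleaned):
            raise ValueError("empty gene symbol in signature")
        if len(set(cleaned)) != len(cleaned):
            seen: set[str] = set()
            for g in cleaned:
                if g in seen:
                    raise ValueError(f"duplicate symbol in signature: {g!r}")
                seen.add(g)
        object.__setattr__(self, "genes", cleaned)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, sym: str) -> bool:
        return _clean_symbol(sym) in self.genes

    def __iter__(self):
        return iter(self.genes)


def select_regulated_genes(
    table: DETable,
    lfc_min: float,
    padj_max: float | None = None,
    direction: Literal["up", "down", "both"] = "up",
) -> set[str]:
    """Select genes passing a |log2FC| threshold and optional adjusted-p cut.

    ``direction`` restricts the sign of log2fc before the magnitude
    threshold is applied; ``padj_max=None`` disables the p-value filter
    (fold-change-only selection).
    """
    if lfc_min < 0:
        raise ValueError("lfc_min must be >= 0")
    if direction not in ("up", "down", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    df = table.frame
    if padj_max is not None:
        if "padj" not in df.columns or df["padj"].isna().any():
            raise ValueError("padj filter requested but padj absent for some records")
    lfc = df["log2fc"]
    if direction == "up":
        mask = lfc >= lfc_min
    elif direction == "down":
        mask = lfc <= -lfc_min
    else:
        mask = lfc.abs() >= lfc_min
    if padj_max is not None:
        mask &= df["padj"] <= padj_max
    return set(df.loc[mask, "gene"])


def curate_signature(
    washout_sets: list[set[str]],
    gof_set: set[str],
    canonical: set[str],
    name: str = "signature",
) -> GeneSignature:
    """Combine gene sets into a curated signature.

    result = ((union of washout sets) ∩ gof_set) ∪ canonical, with symbols
    uppercased, deduplicated and sorted lexicographically. Provenance
    records which rule admitted each gene.
    """
    if not washout_sets:
        raise ValueError("at least one washout set is required")
    washout_union = {_clean_symbol(g) for s in washout_sets for g in s}
    gof = {_clean_symbol(g) for g in gof_set}
    canon = {_clean_symbol(g) for g in canonical}
    core = washout_union & gof
    genes = sorted(core | canon)
    provenance = {}
    for g in genes:
        rules = []
        if g in core:
            rules.append("washout-union ∩ gain-of-function")
        if g in canon:
            rules.append("canonical target list")
        provenance[g] = "; ".join(rules)
    return GeneSignature(name=name, genes=tuple(genes), provenance=provenance)


def _read_signature_text(text: str, name: str | None = None) -> GeneSignature:
    notes: list[str] = []
    genes: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            notes.append(line.lstrip("# "))
            continue
        genes.append(line)
    if name is None:
        name = notes[0] if notes else "signature"
    prov = {g: "; ".join(notes[1:]) for g in genes} if len(notes) > 1 else {}
    return GeneSignature(name=name, genes=tuple(genes), provenance=prov)


def read_signature(path: str | Path, name: str | None = None) -> GeneSignature:
    """Read a signature file: one symbol per line, '#' provenance headers.

    The first '#' header line is taken as the signature name unless one is
    given explicitly; later header lines are provenance notes.
    """
    path = Path(path)
    return _read_signature_text(path.read_text(), name)


def write_signature(sig: GeneSignature, path: str | Path) -> None:
    lines = [f"# {sig.name}"]
    lines += [g for g in sig.genes]
    Path(path).write_text("\n".join(lines) + "\n")


PACKAGED_SIGNATURES = {"TNBC_NOTCH_77": "tnbc_notch_77.txt"}


def load_packaged_signature(name: str) -> GeneSignature:
    """Load a signature shipped with the package by registered name."""
    if name not in PACKAGED_SIGNATURES:
        raise KeyError(
            f"unknown packaged signature {name!r}; "
            f"available: {sorted(PACKAGED_SIGNATURES)}"
        )
    ref = importlib.resources.files("notchsig.data") / PACKAGED_SIGNATURES[name]
    return _read_signature_text(ref.read_text(), name)
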