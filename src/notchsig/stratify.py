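"""Cohort scoring and stratification against a gene signature.

Per-gene median dichotomization within the scored cohort, HIGH-call
tallying per patient, equal-sized tertile stratification, single-gene
33%-quantile dichotomization, four-way cross-stratification, and
classification of NOTCH genetic alterations from mutation/copy-number
call tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ScoreVector",
    "GroupLabels",
    "median_dichotomize",
    "signature_score",
    "stratify_equal_groups",
    "quantile_dichotomize",
    "cross_stratify",
    "classify_notch_alteration",
    "NOTCH_RECEPTORS",
]

NOTCH_RECEPTORS = ("NOTCH1", "NOTCH2", "NOTCH3", "NOTCH4")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes × samples matrix of log2-scale expression values.

    Wraps a DataFrame (index = gene symbols, columns = sample IDs).
    Duplicate genes or samples are rejected; genes containing missing
    values are tracked so scoring can drop them and report coverage.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate gene in expression matrix: {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise ValueError(f"duplicate sample in expression matrix: {dup!r}")
        idx = df.index.astype(str).str.strip().str.upper()
        clean = df.copy()
        clean.index = idx
        object.__setattr__(self, "values", clean)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def genes_with_missing(self) -> list[str]:
        mask = self.values.isna().any(axis=1)
        return list(self.values.index[mask])


@dataclass(frozen=True)
class ScoreVector:
    """Per-sample integer signature score with gene coverage."""

    scores: pd.Series  # sample -> int
    coverage: float  # fraction of signature genes found and scored
    genes_used: tuple[str, ...] = ()
    genes_missing: tuple[str, ...] = ()


@dataclass(frozen=True)
class GroupLabels:
    """Per-sample labels drawn from a declared label set."""

    labels: pd.Series  # sample -> label
    label_set: tuple[str, ...]
    dropped: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - set(self.label_set)
        if bad:
            raise ValueError(f"labels outside declared set: {sorted(bad)}")

    def counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(self.label_set, fill_value=0)


def median_dichotomize(
    matrix: ExpressionMatrix, genes: Sequence[str] | set[str]
) -> pd.DataFrame:
    """Call each requested gene HIGH/LOW per sample against its cohort median.

    HIGH means strictly greater than the per-gene median over all samples
    (even n: midpoint of the two central order statistics). Ties at the
    median are LOW, guaranteeing at most 50% HIGH calls per gene. Genes
    absent from the matrix, or with any missing value, are dropped.

    Returns a boolean DataFrame (True = HIGH), attrs carrying the dropped
    gene lists.
    """
    wanted = [str(g).strip().upper() for g in genes]
    if matrix.values.shape[1] < 2:
        raise ValueError("need at least 2 samples to dichotomize")
    present = [g for g in dict.fromkeys(wanted) if g in matrix.genes]
    absent = [g for g in dict.fromkeys(wanted) if g not in matrix.genes]
    if not present:
        raise ValueError("none of the requested genes are present in the matrix")
    sub = matrix.values.loc[present]
    with_missing = list(sub.index[sub.isna().any(axis=1)])
    sub = sub.drop(index=with_missing)
    if sub.empty:
        raise ValueError("all requested genes have missing values")
    medians = sub.median(axis=1)
    calls = sub.gt(medians, axis=0)
    calls.attrs["absent_genes"] = absent
    calls.attrs["missing_value_genes"] = with_missing
    return calls


def signature_score(matrix: ExpressionMatrix, sig) -> ScoreVector:
    """Tally per-sample HIGH calls over the signature genes present.

    The score of a sample is the number of scored signature genes whose
    expression exceeds the cohort median for that gene; coverage is the
    fraction of signature genes that could be scored.
    """
    genes = list(sig)
    calls = median_dichotomize(matrix, genes)
    scores = calls.sum(axis=0).astype(int)
    used = tuple(calls.index)
    missing = tuple(
        calls.attrs.get("absent_genes", []) + calls.attrs.get("missing_value_genes", [])
    )
    coverage = len(used) / len(genes) if genes else 0.0
    return ScoreVector(
        scores=scores, coverage=coverage, genes_used=used, genes_missing=missing
    )


def _ordered_samples(values: pd.Series) -> list:
    # ascending by (value, sample ID) — ID tie-break makes labels permutation-invariant
    return sorted(values.index, key=lambda s: (values[s], str(s)))


def stratify_equal_groups(
    scores: ScoreVector | pd.Series,
    k: int = 3,
    labels: Sequence[str] = ("LOW", "INT", "HIGH"),
) -> GroupLabels:
    """Cut a cohort into k contiguous, equal-sized groups by ascending score.

    Group sizes differ by at most one; when n mod k != 0 the larger groups
    sit at the low end. Ties are broken deterministically by sample ID.
    """
    values = scores.scores if isinstance(scores, ScoreVector) else scores
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(labels) != k:
        raise ValueError("need exactly k labels")
    n = len(values)
    if n < k:
        raise ValueError(f"cannot cut {n} samples into {k} groups")
    order = _ordered_samples(values)
    base, rem = divmod(n, k)
    sizes = [base + 1 if i < rem else base for i in range(k)]
    out = {}
    pos = 0
    for lab, size in zip(labels, sizes):
        for s in order[pos : pos + size]:
            out[s] = lab
        pos += size
    series = pd.Series(out).reindex(values.index)
    return GroupLabels(labels=series, label_set=tuple(labels))


def quantile_dichotomize(
    values: Mapping | pd.Series,
    q: float = 1 / 3,
    labels: Sequence[str] = ("LOW", "EXCLUDED", "HIGH"),
) -> GroupLabels:
    """Label the bottom floor(q*n) samples LOW and the top floor(q*n) HIGH.

    The remainder is EXCLUDED (dropped from downstream survival contrasts).
    Ties are broken by sample ID for determinism.
    """
    values = pd.Series(values)
    if not 0 < q <= 0.5:
        raise ValueError("q must lie in (0, 0.5]")
    n = len(values)
    if n < 3:
        raise ValueError("need at least 3 samples")
    low_lab, mid_lab, high_lab = labels
    m = int(np.floor(q * n))
    order = _ordered_samples(values)
    out = {s: mid_lab for s in order}
    for s in order[:m]:
        out[s] = low_lab
    if m:
        for s in order[-m:]:
            out[s] = high_lab
    series = pd.Series(out).reindex(values.index)
    return GroupLabels(labels=series, label_set=tuple(labels))


def cross_stratify(
    a: GroupLabels,
    b: GroupLabels,
    a_name: str = "A",
    b_name: str = "B",
    a_keep: Sequence[str] = ("LOW", "HIGH"),
    b_keep: Sequence[str] = ("LOW", "HIGH"),
) -> GroupLabels:
    """Combine two stratifications into four joint groups.

    Samples with an intermediate/excluded label in either input are
    dropped and reported via ``dropped``.
    """
    if set(a.labels.index) != set(b.labels.index):
        raise ValueError("sample sets of the two stratifications differ")
    combined = {}
    dropped = []
    for s in a.labels.index:
        la, lb = a.labels[s], b.labels[s]
        if la in a_keep and lb in b_keep:
            combined[s] = f"{a_name}_{la}/{b_name}_{lb}"
        else:
            dropped.append(s)
    label_set = tuple(
        f"{a_name}_{la}/{b_name}_{lb}" for la in a_keep for lb in b_keep
    )
    series = pd.Series(combined, dtype=object)
    return GroupLabels(labels=series, label_set=label_set, dropped=tuple(dropped))


def classify_notch_alteration(
    table: pd.DataFrame, genes: Sequence[str] = NOTCH_RECEPTORS
) -> pd.Series:
    """Classify samples as mutated / amplified / mutated+amplified / none.

    ``table`` has columns sample, gene, missense (bool-like) and cna
    (integer codes in {-2,-1,0,1,2}). A sample is *mutated* if any listed
    receptor carries a missense mutation and *amplified* if any carries a
    high-level amplification (cna == 2); the flags are independent.
    """
    for col in ("sample", "gene"):
        if col not in table.columns:
            raise ValueError(f"alteration table requires a '{col}' column")
    cna = table["cna"] if "cna" in table.columns else pd.Series(0, index=table.index)
    bad = set(cna.dropna().unique()) - {-2, -1, 0, 1, 2}
    if bad:
        raise ValueError(f"unknown cna codes: {sorted(bad)}")
    genes = {str(g).upper() for g in genes}
    sub = table[table["gene"].astype(str).str.upper().isin(genes)]
    missense = (
        sub.get("missense", pd.Series(False, index=sub.index))
        .fillna(False)
        .astype(bool)
    )
    out = {}
    for s in table["sample"].unique():
        rows = sub["sample"] == s
        mut = bool(missense[rows].any())
        amp = bool((sub.loc[rows, "cna"] == 2).any()) if "cna" in sub.columns else False
        if mut and amp:
            out[s] = "mutated+amplified"
        elif mut:
            out[s] = "mutated"
        elif amp:
            out[s] = "amplified"
        else:
            out[s] = "none"
    return pd.Series(out, dtype=object)
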