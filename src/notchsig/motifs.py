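"""Minimal position-weight-matrix scanning and motif co-occurrence.

A deliberately small replacement for a full motif-scanning suite: PWMs are
built from JASPAR-style count matrices with a background-distributed
pseudocount, and sequences are scored window by window on both strands
against a score threshold expressed as a fraction of the maximum
attainable log-odds score. No p-value calibration is attempted.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

__all__ = [
    "PWM",
    "MotifHitSet",
    "read_pfm",
    "pwm_scan",
    "pair_motif_cooccurrence",
    "CooccurrenceResult",
]

_ALPHABET = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class PWM:
    """Per-position log-odds (bits) over A, C, G, T."""

    motif_id: str
    log_odds: np.ndarray  # shape (4, k), rows in A,C,G,T order
    background: np.ndarray  # length 4, sums to 1

    def __post_init__(self) -> None:
        lo = np.asarray(self.log_odds, dtype=float)
        if lo.shape[0] != 4 or lo.shape[1] < 4:
            raise ValueError("PWM must be 4 x k with k >= 4")
        if not np.all(np.isfinite(lo)):
            raise ValueError("log-odds must be finite (apply a pseudocount)")
        object.__setattr__(self, "log_odds", lo)

    @property
    def length(self) -> int:
        return self.log_odds.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        pseudocount: float = 0.8,
        background: np.ndarray | None = None,
    ) -> "PWM":
        """Build log-odds from a 4 x k count matrix.

        The pseudocount is distributed over the four bases according to
        the background (uniform by default), the FIMO convention.
        """
        counts = np.asarray(counts, dtype=float)
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=float)
        background = background / background.sum()
        col_tot = counts.sum(axis=0)
        probs = (counts + pseudocount * background[:, None]) / (
            col_tot + pseudocount
        )
        log_odds = np.log2(probs / background[:, None])
        return cls(motif_id=motif_id, log_odds=log_odds, background=background)


# Motif hits are plain DataFrames with columns
# chrom, start, end, strand, score (bits); end - start == motif length.
MotifHitSet = pd.DataFrame


def read_pfm(
    path: str | Path, pseudocount: float = 0.8, background=None
) -> PWM:
    """Read a JASPAR-style PFM/count matrix file into a PWM."""
    text = Path(path).read_text()
    fmt = "jaspar" if text.lstrip().startswith(">") else "pfm-four-columns"
    try:
        motif = bio_motifs.read(_io.StringIO(text), fmt)
    except Exception:
        motif = bio_motifs.read(_io.StringIO(text), "pfm")
    counts = np.array([motif.counts[b] for b in _ALPHABET], dtype=float)
    name = getattr(motif, "matrix_id", None) or motif.name or Path(path).stem
    return PWM.from_counts(name, counts, pseudocount=pseudocount, background=background)


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_ALPHABET):
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def _scan_one_strand(codes: np.ndarray, pwm: PWM, min_score: float) -> list[tuple[int, float]]:
    k = pwm.length
    n = len(codes)
    if n < k:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    cols = np.arange(k)
    scores = np.where(
        valid,
        pwm.log_odds[np.where(windows >= 0, windows, 0), cols].sum(axis=1),
        -np.inf,
    )
    hits = np.where(scores >= min_score)[0]
    return [(int(i), float(scores[i])) for i in hits]


def pwm_scan(
    sequence: str,
    pwm: PWM,
    threshold_frac: float = 0.8,
    strands: str = "both",
    chrom: str = "seq",
    offset: int = 0,
) -> pd.DataFrame:
    """Report every window scoring at least threshold_frac * max score.

    Windows containing N are skipped. The reverse strand is scanned
    against the reverse complement with hit coordinates mapped back to
    the forward strand. ``offset`` shifts reported coordinates (e.g. the
    genomic start of the scanned sequence).
    """
    if not 0 < threshold_frac <= 1:
        raise ValueError("threshold_frac must lie in (0, 1]")
    if strands not in ("both", "+", "-"):
        raise ValueError("strands must be 'both', '+' or '-'")
    min_score = threshold_frac * pwm.max_score
    k = pwm.length
    n = len(sequence)
    records = []
    if strands in ("both", "+"):
        for start, score in _scan_one_strand(_encode(sequence), pwm, min_score):
            records.append((chrom, offset + start, offset + start + k, "+", score))
    if strands in ("both", "-"):
        rc = reverse_complement(sequence)
        for start, score in _scan_one_strand(_encode(rc), pwm, min_score):
            fwd_start = n - start - k
            records.append((chrom, offset + fwd_start, offset + fwd_start + k, "-", score))
    return pd.DataFrame(
        records, columns=["chrom", "start", "end", "strand", "score"]
    ).sort_values(["start", "strand"], ignore_index=True)


@dataclass(frozen=True)
class CooccurrenceResult:
    n_both: int
    n_pairs: int

    @property
    def fraction(self) -> float:
        return self.n_both / self.n_pairs if self.n_pairs else 0.0


def _merge_pair_intervals(a_row, b_row) -> list[tuple[str, int, int]]:
    if a_row["chrom"] != b_row["chrom"]:
        return [
            (a_row["chrom"], int(a_row["start"]), int(a_row["end"])),
            (b_row["chrom"], int(b_row["start"]), int(b_row["end"])),
        ]
    s1, e1 = int(a_row["start"]), int(a_row["end"])
    s2, e2 = int(b_row["start"]), int(b_row["end"])
    if s1 > s2:
        (s1, e1), (s2, e2) = (s2, e2), (s1, e1)
    if s2 <= e1:  # overlapping or touching -> union footprint
        return [(a_row["chrom"], s1, max(e1, e2))]
    return [(a_row["chrom"], s1, e1), (a_row["chrom"], s2, e2)]


def _any_hit_within(hits: pd.DataFrame, intervals) -> bool:
    for chrom, s, e in intervals:
        sub = hits[hits["chrom"] == chrom]
        if ((sub["start"] >= s) & (sub["end"] <= e)).any():
            return True
    return False


def pair_motif_cooccurrence(
    coloc, a, b, hits_a: pd.DataFrame, hits_b: pd.DataFrame
) -> CooccurrenceResult:
    """Fraction of co-localized peak pairs containing both motifs.

    A pair "contains both" when at least one hit of each motif falls
    entirely within the union footprint (merged intervals) of the pair's
    two partner peaks.
    """
    n_both = 0
    for _, pair in coloc.pairs.iterrows():
        a_row = a.frame.iloc[int(pair["index_a"])]
        b_row = b.frame.iloc[int(pair["index_b"])]
        intervals = _merge_pair_intervals(a_row, b_row)
        if _any_hit_within(hits_a, intervals) and _any_hit_within(hits_b, intervals):
            n_both += 1
    return CooccurrenceResult(n_both=n_both, n_pairs=len(coloc.pairs))
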