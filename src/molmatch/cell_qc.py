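"""Cell calling regimes and per-cell quality metrics.

Two calling regimes are contrasted: a knee-point rule on the barcode-rank
curve (long-read pipeline behaviour: high-RNA-content cells only) and a
knee-plus-rescue rule that additionally retains sub-knee barcodes above a
count floor (short-read pipeline behaviour: low-RNA-content cells are kept).
Empty-droplet detection follows the quantile-threshold-plus-edit-distance
rule: barcodes above (95th percentile of the top expected-cell counts)/20
are cell-associated; of the rest, barcodes at edit distance >= 5 from every
cell-associated barcode are called empty, capped in number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from molmatch.config import DEFAULT_TSO


@dataclass
class BarcodeRank:
    barcode: str
    umi_count: int
    rank: int
    called_class: str = "uncalled"


def _ranked(counts: dict[str, int]) -> list[tuple[str, int]]:
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def knee_call(counts: dict[str, int]) -> set[str]:
    """Barcodes at or above the knee of the log-log barcode-rank curve.

    The knee is the point of maximal perpendicular distance to the chord
    from the first to the last point of the log10(rank)-log10(count) curve.
    """
    ranked = [(b, c) for b, c in _ranked(counts) if c > 0]
    if len(ranked) < 10:
        raise ValueError("need at least 10 barcodes with positive counts")
    x = np.log10(np.arange(1, len(ranked) + 1))
    y = np.log10(np.array([c for _, c in ranked], dtype=float))
    if np.allclose(y, y[0]):
        warnings.warn("flat barcode-rank curve: no knee found")
        return set()
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / norm
    knee = int(np.argmax(dist))
    return {b for b, _ in ranked[: knee + 1]}


def call_cells_short(counts: dict[str, int], rescue_min_count: int = 10) -> set[str]:
    """Knee cells plus rescued sub-knee barcodes above a count floor."""
    knee = knee_call(counts)
    rescued = {b for b, c in counts.items() if c >= rescue_min_count}
    return knee | rescued


def empty_droplet_call(counts: dict[str, int], expected_cells: int,
                       cap: int = 2000, quantile: float = 95.0,
                       divisor: float = 20.0, min_dist: int = 5
                       ) -> dict[str, str]:
    """Partition barcodes into cell_associated / empty / other."""
    if expected_cells < 1:
        raise ValueError("expected_cells must be >= 1")
    ranked = _ranked(counts)
    if expected_cells > len(ranked):
        warnings.warn("expected_cells exceeds number of barcodes; using all")
        expected_cells = len(ranked)
    top = np.array([c for _, c in ranked[:expected_cells]], dtype=float)
    threshold = np.percentile(top, quantile) / divisor
    out = {}
    cell_assoc = []
    rest = []
    for b, c in ranked:
        if c > threshold:
            out[b] = "cell_associated"
            cell_assoc.append(b)
        else:
            rest.append((b, c))
    n_empty = 0
    for b, c in rest:  # descending count order
        label = "other"
        if n_empty < cap and cell_assoc:
            # bounded search reports -1 when the distance is >= min_dist
            far = all(
                edlib.align(b, cb, task="distance",
                            k=min_dist - 1)["editDistance"] == -1
                for cb in cell_assoc)
            if far:
                label = "empty"
                n_empty += 1
        out[b] = label
    return out


def barcode_rank_table(counts: dict[str, int],
                       called: dict[str, str] | None = None) -> pd.DataFrame:
    rows = []
    for rank, (b, c) in enumerate(_ranked(counts), start=1):
        rows.append({"barcode": b, "umi_count": c, "rank": rank,
                     "called_class": (called or {}).get(b, "uncalled")})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# contamination metrics

def _is_tso(seq: str, tso: str, max_mismatch: int) -> bool:
    if len(seq) < len(tso):
        return False
    head = seq[: len(tso)]
    return sum(a != b for a, b in zip(head, tso)) <= max_mismatch


def _has_polya(seq: str, run: int, max_interrupt: int) -> bool:
    """Any window of ``run`` nt with at most ``max_interrupt`` non-A bases."""
    n = len(seq)
    if n < run:
        return False
    is_a = [c == "A" for c in seq]
    cnt = sum(is_a[:run])
    if run - cnt <= max_interrupt:
        return True
    for i in range(run, n):
        cnt += is_a[i] - is_a[i - run]
        if run - cnt <= max_interrupt:
            return True
    return False


def tso_polya_contamination(records, tso: str = DEFAULT_TSO,
                            max_mismatch: int = 3, polya_run: int = 15,
                            polya_max_interrupt: int = 1,
                            cell_of: dict[str, str] | None = None):
    """Per-record TSO / polyA contamination flags, aggregated per cell.

    A read is TSO-contaminated if its first 30 nt (or leading soft-clip)
    match the TSO within the mismatch allowance; polyA-contaminated if it
    contains an adenine run of the configured length with at most one
    interruption.  Records without sequence are excluded from denominators.
    """
    rows = []
    n_no_seq = 0
    for r in records:
        seq = r.sequence or r.leading_softclip_seq
        if not seq:
            n_no_seq += 1
            continue
        probe = r.leading_softclip_seq if r.leading_softclip_seq else seq
        is_tso = _is_tso(probe, tso, max_mismatch)
        is_polya = _has_polya(seq, polya_run, polya_max_interrupt)
        bc = (r.tag_key or "")[:16]
        rows.append({"query_name": r.query_name, "barcode": bc,
                     "cell_class": (cell_of or {}).get(bc, "unknown"),
                     "tso": is_tso, "polya": is_polya})
    df = pd.DataFrame(rows, columns=["query_name", "barcode", "cell_class",
                                     "tso", "polya"])
    overall = {
        "frac_tso": float(df["tso"].mean()) if len(df) else float("nan"),
        "frac_polya": float(df["polya"].mean()) if len(df) else float("nan"),
        "n_records": int(len(df)),
        "n_without_sequence": n_no_seq,
    }
    per_class = (df.groupby("cell_class")[["tso", "polya"]].mean()
                 if len(df) else pd.DataFrame(columns=["tso", "polya"]))
    per_cell = (df.groupby("barcode")[["tso", "polya"]].mean()
                if len(df) else pd.DataFrame(columns=["tso", "polya"]))
    return df, per_cell, per_class, overall


def content_fraction(matrix: pd.DataFrame, gene_flags: dict[str, bool]) -> pd.Series:
    """Per-cell fraction of counts in flagged (e.g. mitochondrial) genes."""
    flagged = [g for g in matrix.index if gene_flags.get(g, False)]
    totals = matrix.sum(axis=0)
    part = matrix.loc[flagged].sum(axis=0) if flagged else pd.Series(0.0, index=matrix.columns)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = part / totals
    return frac.fillna(0.0)
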