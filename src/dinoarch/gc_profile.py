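"""Sliding-window GC content and GC-dip detection.

A GC dip is a maximal run of consecutive sliding windows whose GC falls
below the scaffold-wide background, kept when (1) every window sits below
background, (2) the largest deviation exceeds a depth threshold
(percentage points of GC, default 0.05) and (3) the spanned region is
longer than a minimum (default 5000 bp). Dips are detected genome-wide and
then associated with converging inter-block regions (putative TAD
boundaries).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from dinoarch.model import GCDipRegion, GCWindow, InterBlockRegion

logger = logging.getLogger("dinoarch")

DEFAULT_WIDTH = 4000
DEFAULT_STEP = 100
DEFAULT_DIP_PP = 0.05
DEFAULT_MIN_LENGTH = 5000

_GC_BYTES = frozenset(b"GC")
_UNAMBIG = frozenset(b"GCAT")


def _indicator_arrays(sequence: str) -> tuple[np.ndarray, np.ndarray]:
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_valid = is_gc | (arr == ord("A")) | (arr == ord("T"))
    return is_gc, is_valid


def scaffold_background_gc(sequence: str) -> float:
    """GC / (GC + AT) over the whole scaffold; ambiguous bases excluded.

    Raises on an empty or all-ambiguous scaffold (callers skip such
    scaffolds with a warning).
    """
    if not sequence:
        raise ValueError("empty sequence")
    is_gc, is_valid = _indicator_arrays(sequence)
    n_valid = int(is_valid.sum())
    if n_valid == 0:
        raise ValueError("scaffold contains only ambiguous bases; background GC undefined")
    return float(is_gc.sum()) / n_valid


def sliding_gc(
    sequence: str,
    scaffold: str = "",
    width: int = DEFAULT_WIDTH,
    step: int = DEFAULT_STEP,
) -> list[GCWindow]:
    """GC fraction in fully contained windows at offsets 0, step, 2*step, ...

    Windows overlapping ambiguous runs use only their unambiguous bases;
    a window with no unambiguous base is dropped. Scaffolds shorter than
    ``width`` yield no windows.
    """
    n = len(sequence)
    if n < width:
        logger.warning("scaffold %s shorter than window width (%d < %d)", scaffold, n, width)
        return []
    is_gc, is_valid = _indicator_arrays(sequence)
    cum_gc = np.concatenate(([0], np.cumsum(is_gc)))
    cum_valid = np.concatenate(([0], np.cumsum(is_valid)))
    starts = np.arange(0, n - width + 1, step)
    gc_counts = cum_gc[starts + width] - cum_gc[starts]
    valid_counts = cum_valid[starts + width] - cum_valid[starts]
    windows: list[GCWindow] = []
    for start, g, v in zip(starts, gc_counts, valid_counts):
        if v == 0:
            continue
        windows.append(GCWindow(scaffold=scaffold, start=int(start), width=width, gc=float(g) / float(v)))
    return windows


def detect_dips(
    windows: Sequence[GCWindow],
    background: float,
    dip_threshold_pp: float = DEFAULT_DIP_PP,
    min_length_bp: int = DEFAULT_MIN_LENGTH,
) -> list[GCDipRegion]:
    """Merge maximal runs of below-background windows; apply the criteria.

    ``windows`` must come from one scaffold in position order. A maximal
    run of consecutive below-background windows yields the candidate
    region of positions covered *only* by below-background windows: the
    run's span eroded by one window width at each side (first window's
    end to last window's start). The sliding average smears any deep dip
    outward by up to a window width on each flank; the erosion undoes
    that, so the length criterion tests the dip itself rather than its
    smeared image — a sub-threshold dip segment is rejected regardless
    of how the windows align with it. The region is kept iff the run's
    maximum deviation (background - window GC, x100) exceeds
    ``dip_threshold_pp`` and the eroded span exceeds ``min_length_bp``.
    """
    dips: list[GCDipRegion] = []
    run: list[GCWindow] = []

    def flush() -> None:
        if not run:
            return
        start = run[0].end
        end = run[-1].start
        if end <= start:
            run.clear()
            return
        max_dev = max((background - w.gc) * 100.0 for w in run)
        if max_dev > dip_threshold_pp and (end - start) > min_length_bp:
            dips.append(
                GCDipRegion(
                    scaffold=run[0].scaffold,
                    start=start,
                    end=end,
                    max_deviation=max_dev,
                    background_gc=background,
                )
            )
        run.clear()

    for w in windows:
        if w.gc < background:
            run.append(w)
        else:
            flush()
    flush()
    return dips


def associate_dips(
    regions: Sequence[InterBlockRegion],
    dips: Sequence[GCDipRegion],
    mode: str = "overlap",
) -> list[dict]:
    """Flag each inter-block region that coincides with a GC dip.

    ``overlap`` flags a region when any dip overlaps its interval by at
    least 1 bp; ``midpoint`` when a dip contains the interval midpoint.
    Zero-length intervals (abutting or overlapping flanking genes) have
    no sequence to test and are reported unflagged with a reason.
    """
    if mode not in ("overlap", "midpoint"):
        raise ValueError(f"unknown association mode {mode!r}")
    by_scaffold: dict[str, list[GCDipRegion]] = {}
    for d in dips:
        by_scaffold.setdefault(d.scaffold, []).append(d)
    out: list[dict] = []
    for r in regions:
        row = {"region": r, "flagged": False, "reason": ""}
        if r.length == 0:
            row["reason"] = "no sequence"
            out.append(row)
            continue
        for d in by_scaffold.get(r.scaffold, []):
            if mode == "overlap":
                hit = d.start < r.end and r.start < d.end
            else:
                mid = (r.start + r.end) // 2
                hit = d.start <= mid < d.end
            if hit:
                row["flagged"] = True
                break
        out.append(row)
    return out


def boundary_dip_summary(
    flags: Sequence[dict], n_values: Sequence[int] = (4, 6, 8, 10)
) -> dict[int, tuple[int, int]]:
    """(flagged, total) over converging regions qualifying at each N."""
    summary: dict[int, tuple[int, int]] = {}
    for n in n_values:
        rows = [
            f
            for f in flags
            if f["region"].orientation_class == "converging" and f["region"].qualifies(n)
        ]
        summary[n] = (sum(1 for f in rows if f["flagged"]), len(rows))
    return summary
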