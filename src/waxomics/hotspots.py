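"""Sliding-window detection of multi-trait GWAS hotspots.

Windows of 200 kb tile each chromosome at a step of one-fifth of the window
size; each window counts the GWAS locus peaks it contains.  The count
threshold is the ceiling of the 95% quantile of the genome-wide per-window
count distribution (floored at 2), qualifying windows that partially overlap
are merged, and a hotspot's boundaries are the union of its qualifying
windows.  Intraclass scans use the loci of one wax class; interclass scans
use all traits except the grand total and additionally require traits from
at least two classes.  Output intervals are 0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .integrate import Locus


@dataclass
class Hotspot:
    chrom: str
    start: int  # 0-based half-open
    end: int
    label: str  # "intraclass:<CLASS>" or "interclass"
    loci: list[Locus] = field(default_factory=list)

    @property
    def traits(self) -> set[str]:
        return {l.trait_id for l in self.loci}

    @property
    def classes(self) -> set[str]:
        return {l.wax_class for l in self.loci if l.wax_class}

    @property
    def n_loci(self) -> int:
        return len(self.loci)


def window_counts(
    loci: Sequence[Locus],
    chrom_lengths: Sequence[tuple[str, int]],
    window_bp: int = 200_000,
    step_frac: float = 0.2,
) -> pd.DataFrame:
    """Per-window locus counts for windows tiling each chromosome.

    Windows are [start, start + window_bp) at step = step_frac * window_bp,
    starting at 0; a locus is counted in every window containing its peak
    position.  Returns a DataFrame (chrom, start, end, count).
    """
    step = int(round(step_frac * window_bp))
    if step <= 0 or window_bp <= 0:
        raise ValueError("window_bp and step must be positive")
    pos_by_chrom: dict[str, np.ndarray] = {}
    for chrom, _ in chrom_lengths:
        pos_by_chrom[chrom] = np.sort(
            np.array([l.pos for l in loci if l.chrom == chrom], dtype=np.int64)
        )
    rows = []
    for chrom, L in chrom_lengths:
        pos = pos_by_chrom[chrom]
        for start in range(0, int(L), step):
            end = start + window_bp
            c = int(np.searchsorted(pos, end, side="left") - np.searchsorted(pos, start, side="left"))
            rows.append((chrom, start, end, c))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])


def empirical_threshold(counts: np.ndarray, q: float = 0.95) -> int:
    """Integer hotspot threshold: ceil of the q-quantile of window counts.

    A floor of 2 applies — a "hotspot" of a single locus is meaningless.
    """
    counts = np.asarray(counts, float)
    if counts.size == 0:
        raise ValueError("empty count vector")
    return max(2, int(math.ceil(np.quantile(counts, q))))


def call_hotspots(
    loci: Sequence[Locus],
    chrom_lengths: Sequence[tuple[str, int]],
    mode: str = "interclass",
    window_bp: int = 200_000,
    step_frac: float = 0.2,
    q: float = 0.95,
    threshold: int | None = None,
) -> list[Hotspot]:
    """Call hotspots of the given mode from a set of GWAS loci.

    ``mode`` is "interclass" or "intraclass:<CLASS>"; in intraclass mode the
    loci are filtered to the named class first.  The caller is expected to
    have already excluded the grand-total trait for interclass scans.  The
    threshold defaults to :func:`empirical_threshold` of this scan's own
    window counts, pooled genome-wide.
    """
    if mode.startswith("intraclass"):
        cls = mode.split(":", 1)[1] if ":" in mode else None
        if cls is None:
            raise ValueError("intraclass mode requires a class, e.g. 'intraclass:WE'")
        loci = [l for l in loci if l.wax_class == cls]
        label = f"intraclass:{cls}"
        min_classes = 1
    elif mode == "interclass":
        label = "interclass"
        min_classes = 2
    else:
        raise ValueError(f"unknown mode {mode!r}")

    wc = window_counts(loci, chrom_lengths, window_bp, step_frac)
    thr = empirical_threshold(wc["count"].to_numpy(), q) if threshold is None else threshold
    qual = wc[wc["count"] >= thr]
    hotspots: list[Hotspot] = []
    for chrom, sub in qual.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur_s, cur_e = None, None
        merged: list[tuple[int, int]] = []
        for r in sub.itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e = r.start, r.end
            elif r.start < cur_e:  # partially overlapping windows chain together
                cur_e = max(cur_e, r.end)
            else:
                merged.append((cur_s, cur_e))
                cur_s, cur_e = r.start, r.end
        if cur_s is not None:
            merged.append((cur_s, cur_e))
        for s, e in merged:
            members = [l for l in loci if l.chrom == chrom and s <= l.pos < e]
            hs = Hotspot(chrom=str(chrom), start=int(s), end=int(e), label=label, loci=members)
            if len(hs.classes) >= min_classes:
                hotspots.append(hs)
    return hotspots


def hotspot_coincidence(
    set_a: Sequence[Hotspot], set_b: Sequence[Hotspot], min_overlap: float = 0.5
) -> list[tuple[Hotspot, Hotspot, float]]:
    """Pairs of hotspots whose overlap covers >= min_overlap of the shorter one."""
    pairs = []
    for a in set_a:
        for b in set_b:
            if a.chrom != b.chrom:
                continue
            ov = min(a.end, b.end) - max(a.start, b.start)
            if ov <= 0:
                continue
            frac = ov / min(a.end - a.start, b.end - b.start)
            if frac >= min_overlap:
                pairs.append((a, b, float(frac)))
    return pairs


def hotspots_to_bed(hotspots: Sequence[Hotspot]) -> pd.DataFrame:
    """BED-style frame (0-based half-open) with member summaries."""
    rows = [
        (
            h.chrom,
            h.start,
            h.end,
            h.label,
            h.n_loci,
            ",".join(sorted(h.traits)),
            ",".join(sorted(h.classes)),
        )
        for h in hotspots
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "label", "n_loci", "traits", "classes"]
    )
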