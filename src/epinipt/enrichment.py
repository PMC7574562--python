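"""Annotation enrichment of high-signal windows and DMR sets.

Top-signal selection tiles the genome into 1-kb non-overlapping windows,
averages per-window total coverage within a sample group and keeps the top
10% (boundary ties all included, which keeps the selection deterministic).
Enrichment is then tested at CG-site resolution: each catalog CG is
cross-classified by membership in a top window and overlap with the
annotation, and Fisher's exact test gives the odds ratio. mQTL-probe
enrichment works the same way with array probes as the unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import CoverageMatrix, window_stats
from .synthetic_data import _in_intervals


@dataclass
class EnrichmentResult:
    name: str
    table: tuple[int, int, int, int]   # (top&annot, top only, annot only, neither)
    odds_ratio: float
    p: float
    overlap_fraction: float
    haldane_corrected: bool = False
    degenerate: bool = False


def _fisher_or(table: tuple[int, int, int, int]) -> tuple[float, float, bool]:
    n11, n10, n01, n00 = table
    _, p = stats.fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
    if 0 in table:
        oh = ((n11 + 0.5) * (n00 + 0.5)) / ((n10 + 0.5) * (n01 + 0.5))
        return float(oh), float(p), True
    return n11 * n00 / (n10 * n01), float(p), False


def top_signal_windows(
    matrix: CoverageMatrix,
    groups: list[str] | np.ndarray,
    width: int = 1000,
    quantile: float = 0.10,
) -> dict[str, pd.DataFrame]:
    """Top-``quantile`` most covered windows per sample group.

    Per group the window totals are averaged over member samples and every
    window at or above the (1 - quantile) coverage quantile is returned;
    ties at the boundary are all included (flagged ``degenerate`` when the
    tie rule selects everything, e.g. perfectly uniform coverage).
    """
    if not 0.0 <= quantile <= 1.0:
        raise ValueError("quantile must lie in [0, 1]")
    groups = np.asarray(groups)
    if groups.size != matrix.n_samples:
        raise ValueError("groups length must match samples")
    ws = window_stats(matrix, width=width)
    frame = ws.window_frame()
    out: dict[str, pd.DataFrame] = {}
    for g in np.unique(groups):
        mask = groups == g
        if not mask.any():
            raise ValueError(f"empty group {g!r}")
        mean_cov = ws.coverage[mask].mean(axis=0)
        if quantile == 0.0:               # degenerate: select nothing
            sel = np.zeros(mean_cov.size, dtype=bool)
        elif quantile == 1.0:             # degenerate: select everything
            sel = np.ones(mean_cov.size, dtype=bool)
        else:
            cutoff = np.quantile(mean_cov, 1.0 - quantile)
            sel = mean_cov >= cutoff
        tbl = frame.copy()
        tbl["mean_coverage"] = mean_cov
        tbl["top"] = sel
        tbl.attrs["degenerate"] = bool(sel.all())
        if sel.all():
            warnings.warn(
                f"group {g!r}: boundary ties select every window (uniform signal)"
            )
        out[str(g)] = tbl
    return out


def site_enrichment(
    top_windows: pd.DataFrame,
    annotation: dict[str, np.ndarray],
    catalog,
    name: str = "annotation",
) -> EnrichmentResult:
    """CG-site level enrichment of an annotation among top-signal windows.

    ``top_windows`` is one group's table from :func:`top_signal_windows`;
    ``annotation`` maps chromosome -> (k, 2) half-open intervals. A CG
    overlaps the annotation when its C position lies inside an interval.
    The universe is every CG in the catalog.
    """
    sl = catalog.slices()
    known = [c for c in annotation if c in sl]
    if not known:
        warnings.warn(f"annotation {name!r} has no chromosomes in the catalog")
        return EnrichmentResult(name, (0, 0, 0, catalog.n_sites), 1.0, 1.0, 0.0,
                                degenerate=True)
    width = int(top_windows["end"].iloc[0] - top_windows["start"].iloc[0])
    top = top_windows[top_windows["top"]]
    top_by_chrom = {
        c: set(grp["start"] // width) for c, grp in top.groupby("chrom")
    }
    in_top = np.zeros(catalog.n_sites, dtype=bool)
    in_annot = np.zeros(catalog.n_sites, dtype=bool)
    for chrom, s in sl.items():
        pos = catalog.pos[s]
        wids = pos // width
        tset = top_by_chrom.get(chrom)
        if tset:
            in_top[s] = np.isin(wids, np.fromiter(tset, dtype=np.int64))
        if chrom in annotation:
            in_annot[s] = _in_intervals(pos, annotation[chrom])
    n11 = int((in_top & in_annot).sum())
    n10 = int((in_top & ~in_annot).sum())
    n01 = int((~in_top & in_annot).sum())
    n00 = int((~in_top & ~in_annot).sum())
    odds, p, haldane = _fisher_or((n11, n10, n01, n00))
    denom = n11 + n10
    return EnrichmentResult(
        name, (n11, n10, n01, n00), odds, p,
        overlap_fraction=n11 / denom if denom else 0.0,
        haldane_corrected=haldane,
    )


def probe_dmr_enrichment(
    probes: pd.DataFrame,
    dmr_set: dict[str, np.ndarray],
    name: str = "mQTL",
) -> EnrichmentResult:
    """Enrichment of mQTL-flagged array probes inside DMR intervals.

    ``probes`` holds columns ``chrom``, ``pos``, ``is_mqtl``; ``dmr_set``
    maps chromosome -> (k, 2) DMR intervals. The unit is the probe; the
    result additionally reports the fraction of DMRs that contain at least
    one mQTL probe.
    """
    dmr_chroms = {c for c, iv in dmr_set.items() if len(iv)}
    sub = probes[probes["chrom"].isin(dmr_chroms)]
    if sub.empty:
        raise ValueError("no probes on the DMR chromosomes")
    in_dmr = np.zeros(len(probes), dtype=bool)
    for chrom, grp in probes.groupby("chrom"):
        iv = np.asarray(dmr_set.get(chrom, np.empty((0, 2), dtype=np.int64)))
        if iv.size:
            order = np.argsort(iv[:, 0])
            in_dmr[grp.index] = _in_intervals(grp["pos"].to_numpy(), iv[order])
    is_mqtl = probes["is_mqtl"].to_numpy(bool)
    n11 = int((is_mqtl & in_dmr).sum())
    n10 = int((is_mqtl & ~in_dmr).sum())
    n01 = int((~is_mqtl & in_dmr).sum())
    n00 = int((~is_mqtl & ~in_dmr).sum())
    odds, p, haldane = _fisher_or((n11, n10, n01, n00))

    n_dmrs = sum(len(iv) for iv in dmr_set.values())
    hit = 0
    mq = probes[probes["is_mqtl"]]
    for chrom, iv in dmr_set.items():
        ppos = np.sort(mq.loc[mq["chrom"] == chrom, "pos"].to_numpy())
        for s, e in np.asarray(iv).reshape(-1, 2):
            lo = np.searchsorted(ppos, s, side="left")
            hi = np.searchsorted(ppos, e, side="left")
            hit += int(hi > lo)
    return EnrichmentResult(
        name, (n11, n10, n01, n00), odds, p,
        overlap_fraction=hit / n_dmrs if n_dmrs else 0.0,
        haldane_corrected=haldane,
    )
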