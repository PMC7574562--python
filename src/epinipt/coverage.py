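"""Per-CG read counting and coverage summaries.

Turns mapped read starts into per-CG-site counts (a read is credited to the
nearest CG whose C is within 3 bp of the read's 5' start, on either strand)
and computes the two chromosome-level signals used throughout the pipeline:

* CG-coverage  — total read count over the CG sites of a chromosome/window;
* CG-fraction  — fraction of CG sites covered by at least one read.

Also provides fixed-width window summaries, without-replacement read
subsampling (multivariate hypergeometric) and the Hellinger transformation
used upstream of ordination QC.

All coordinates are 0-based half-open (BED convention); a CG site is indexed
by the position of its forward-strand C.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: maximum distance (bp, inclusive) between a read 5' start and the C of a CG
#: for the read to be assigned to that site
MAX_ASSIGN_DIST = 3


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SiteIndex:
    """Sorted catalog of CG sites across chromosomes.

    Sites are stored as parallel arrays sorted by (chromosome, position);
    ``chrom_id`` indexes into ``chrom_names``.
    """

    chrom_names: list[str]
    chrom_lengths: np.ndarray          # (n_chroms,) int
    chrom_id: np.ndarray               # (n_sites,) int32, non-decreasing
    pos: np.ndarray                    # (n_sites,) int64, increasing per chrom

    def __post_init__(self) -> None:
        self.chrom_id = np.asarray(self.chrom_id, dtype=np.int32)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom_lengths = np.asarray(self.chrom_lengths, dtype=np.int64)
        if np.any(np.diff(self.chrom_id) < 0):
            raise ValueError("sites must be sorted by chromosome")
        for cid in range(len(self.chrom_names)):
            p = self.pos[self.chrom_id == cid]
            if p.size and (np.any(np.diff(p) <= 0) or p[-1] >= self.chrom_lengths[cid]):
                raise ValueError(
                    f"positions must be strictly increasing and < length on "
                    f"{self.chrom_names[cid]}"
                )

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    def slices(self) -> dict[str, slice]:
        """Contiguous site slice per chromosome name."""
        bounds = np.searchsorted(self.chrom_id, np.arange(len(self.chrom_names) + 1))
        return {
            name: slice(int(bounds[i]), int(bounds[i + 1]))
            for i, name in enumerate(self.chrom_names)
        }

    def length_of(self, chrom: str) -> int:
        return int(self.chrom_lengths[self.chrom_names.index(chrom)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": np.asarray(self.chrom_names)[self.chrom_id], "pos": self.pos}
        )


@dataclass
class CoverageMatrix:
    """samples x CG-sites non-negative integer read counts."""

    counts: np.ndarray                 # (n_samples, n_sites) int
    sample_ids: list[str]
    sites: SiteIndex

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (samples x sites)")
        if self.counts.shape != (len(self.sample_ids), self.sites.n_sites):
            raise ValueError("counts shape does not match sample_ids / sites")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    def totals(self) -> np.ndarray:
        """Total assigned reads per sample."""
        return self.counts.sum(axis=1)

    def subset_samples(self, ids: list[str]) -> "CoverageMatrix":
        idx = [self.sample_ids.index(s) for s in ids]
        return CoverageMatrix(self.counts[idx].copy(), list(ids), self.sites)

    @classmethod
    def concat_samples(cls, a: "CoverageMatrix", b: "CoverageMatrix") -> "CoverageMatrix":
        if a.sites is not b.sites and (
            not np.array_equal(a.sites.pos, b.sites.pos)
            or not np.array_equal(a.sites.chrom_id, b.sites.chrom_id)
        ):
            raise ValueError("site catalogs differ; cannot concatenate samples")
        return cls(
            np.vstack([a.counts, b.counts]),
            list(a.sample_ids) + list(b.sample_ids),
            a.sites,
        )


@dataclass
class WindowStats:
    """Per-sample summaries over fixed-width non-overlapping windows.

    Only windows containing at least one CG site are materialised; empty
    windows are excluded from testing by construction and their count is
    reported in ``n_empty_windows``.
    """

    width: int
    chrom_id: np.ndarray               # (n_windows,) int32
    start: np.ndarray                  # (n_windows,) int64 (window start, bp)
    n_cg: np.ndarray                   # (n_windows,) int64 CG sites per window
    coverage: np.ndarray               # (n_samples, n_windows) int
    covered: np.ndarray                # (n_samples, n_windows) int sites w/ >=1 read
    sample_ids: list[str]
    chrom_names: list[str]
    n_empty_windows: int = 0

    @property
    def cg_fraction(self) -> np.ndarray:
        return self.covered / self.n_cg

    @property
    def end(self) -> np.ndarray:
        return self.start + self.width

    def window_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": np.asarray(self.chrom_names)[self.chrom_id],
                "start": self.start,
                "end": self.end,
                "n_cg": self.n_cg,
            }
        )


# ---------------------------------------------------------------------------
# read -> CG assignment
# ---------------------------------------------------------------------------

def assign_reads_to_sites(
    starts: np.ndarray, site_pos: np.ndarray, max_dist: int = MAX_ASSIGN_DIST
) -> np.ndarray:
    """Index of the CG site each read start is assigned to, or -1 if none.

    A read is assigned to the nearest site with ``|start - pos| <= max_dist``;
    exact distance ties are broken to the lower-coordinate site. Strand is
    ignored for the distance (both strands are counted together).
    """
    starts = np.asarray(starts, dtype=np.int64)
    if site_pos.size == 0:
        return np.full(starts.size, -1, dtype=np.int64)
    right = np.searchsorted(site_pos, starts, side="left")
    left = right - 1
    big = np.int64(2**62)
    d_left = np.where(left >= 0, starts - site_pos[np.clip(left, 0, None)], big)
    d_right = np.where(
        right < site_pos.size, site_pos[np.clip(right, None, site_pos.size - 1)] - starts, big
    )
    take_left = d_left <= d_right            # tie -> lower coordinate
    chosen = np.where(take_left, left, right)
    dist = np.where(take_left, d_left, d_right)
    return np.where(dist <= max_dist, chosen, -1)


def count_cg_coverage(
    read_starts: pd.DataFrame,
    catalog: SiteIndex,
    max_dist: int = MAX_ASSIGN_DIST,
) -> tuple[CoverageMatrix, pd.DataFrame]:
    """Count reads per CG site for every sample.

    Parameters
    ----------
    read_starts
        DataFrame with columns ``chrom``, ``start`` and ``sample_id``
        (a ``strand`` column is accepted and ignored for assignment).
    catalog
        CG-site catalog the reads are assigned against.

    Returns
    -------
    (matrix, qc)
        The per-site count matrix and a per-sample QC table with the number
        of assigned reads, reads with no CG within ``max_dist`` bp, and reads
        on chromosomes absent from the catalog (both dropped).
    """
    required = {"chrom", "start", "sample_id"}
    if not required.issubset(read_starts.columns):
        raise ValueError(f"read_starts needs columns {sorted(required)}")
    sample_ids = sorted(read_starts["sample_id"].unique())
    s_index = {s: i for i, s in enumerate(sample_ids)}
    sl = catalog.slices()
    counts = np.zeros((len(sample_ids), catalog.n_sites), dtype=np.int64)
    qc = {s: {"assigned": 0, "unassigned": 0, "unknown_chrom": 0} for s in sample_ids}

    for (sample, chrom), grp in read_starts.groupby(["sample_id", "chrom"], sort=False):
        row = s_index[sample]
        if chrom not in sl:
            qc[sample]["unknown_chrom"] += len(grp)
            continue
        sub = sl[chrom]
        idx = assign_reads_to_sites(
            grp["start"].to_numpy(), catalog.pos[sub], max_dist=max_dist
        )
        hit = idx >= 0
        np.add.at(counts[row], idx[hit] + sub.start, 1)
        qc[sample]["assigned"] += int(hit.sum())
        qc[sample]["unassigned"] += int((~hit).sum())

    qc_df = pd.DataFrame.from_dict(qc, orient="index").rename_axis("sample_id").reset_index()
    return CoverageMatrix(counts, sample_ids, catalog), qc_df


# ---------------------------------------------------------------------------
# chromosome / window summaries
# ---------------------------------------------------------------------------

def chrom_stats(matrix: CoverageMatrix) -> pd.DataFrame:
    """Per (sample, chromosome) CG-coverage and CG-fraction.

    Returns a long DataFrame with columns ``sample_id``, ``chrom``,
    ``total_coverage``, ``n_covered``, ``n_sites`` and ``cg_fraction``.
    """
    if matrix.n_samples == 0 or matrix.sites.n_sites == 0:
        raise ValueError("empty coverage matrix")
    sl = matrix.sites.slices()
    rows = []
    for chrom, s in sl.items():
        block = matrix.counts[:, s]
        total = block.sum(axis=1)
        covered = (block > 0).sum(axis=1)
        n = s.stop - s.start
        for i, sid in enumerate(matrix.sample_ids):
            rows.append(
                (sid, chrom, int(total[i]), int(covered[i]), n,
                 covered[i] / n if n else 0.0)
            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "total_coverage", "n_covered", "n_sites",
                 "cg_fraction"],
    )


def window_stats(matrix: CoverageMatrix, width: int = 100) -> WindowStats:
    """Summarise counts over non-overlapping ``width``-bp windows.

    Raw (un-logged) coverage and covered-site counts are stored; any log
    transform is applied downstream. Windows holding no CG are excluded and
    counted in ``n_empty_windows``.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    sites = matrix.sites
    # global window key: chrom_id * max_windows + pos // width
    per_chrom_w = np.ceil(sites.chrom_lengths / width).astype(np.int64)
    offset = np.concatenate([[0], np.cumsum(per_chrom_w)[:-1]])
    key = offset[sites.chrom_id] + sites.pos // width
    uniq, inverse, n_cg = np.unique(key, return_inverse=True, return_counts=True)
    n_w = uniq.size
    n_samples = matrix.n_samples
    coverage = np.zeros((n_samples, n_w), dtype=np.int64)
    covered = np.zeros((n_samples, n_w), dtype=np.int64)
    for i in range(n_samples):
        coverage[i] = np.bincount(inverse, weights=matrix.counts[i], minlength=n_w)
        covered[i] = np.bincount(inverse, weights=(matrix.counts[i] > 0), minlength=n_w)
    w_chrom = np.searchsorted(np.cumsum(per_chrom_w), uniq, side="right").astype(np.int32)
    w_start = (uniq - offset[w_chrom]) * width
    n_empty = int(per_chrom_w.sum() - n_w)
    return WindowStats(
        width=width,
        chrom_id=w_chrom,
        start=w_start.astype(np.int64),
        n_cg=n_cg.astype(np.int64),
        coverage=coverage,
        covered=covered,
        sample_ids=list(matrix.sample_ids),
        chrom_names=list(sites.chrom_names),
        n_empty_windows=n_empty,
    )


# ---------------------------------------------------------------------------
# subsampling & Hellinger
# ---------------------------------------------------------------------------

def subsample_counts(
    matrix: CoverageMatrix,
    n_reads: int | np.ndarray,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> CoverageMatrix:
    """Draw ``n_reads`` reads per sample without replacement.

    Each sample's site counts are subsampled by a multivariate hypergeometric
    draw, emulating random selection of already-assigned reads.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    totals = matrix.totals()
    n = np.broadcast_to(np.asarray(n_reads, dtype=np.int64), (matrix.n_samples,))
    for i, sid in enumerate(matrix.sample_ids):
        if n[i] > totals[i]:
            raise ValueError(
                f"cannot subsample {n[i]} reads from sample {sid!r} "
                f"({totals[i]} available)"
            )
        if n[i] < 0:
            raise ValueError("subsample size must be non-negative")
    out = np.zeros_like(matrix.counts, dtype=np.int64)
    for i in range(matrix.n_samples):
        if n[i] == totals[i]:
            out[i] = matrix.counts[i]
        elif n[i] > 0:
            out[i] = rng.multivariate_hypergeometric(
                matrix.counts[i].astype(np.int64), int(n[i]), method="marginals"
            )
    return CoverageMatrix(out, list(matrix.sample_ids), matrix.sites)


def hellinger(counts: np.ndarray, sample_ids: list[str] | None = None) -> np.ndarray:
    """Hellinger transform: sqrt of row-relative abundances.

    Each row (sample) is divided by its total and square-rooted, so every
    transformed row has unit sum of squares.
    """
    counts = np.asarray(counts, dtype=float)
    row_sums = counts.sum(axis=1)
    bad = np.where(row_sums <= 0)[0]
    if bad.size:
        name = sample_ids[bad[0]] if sample_ids else f"row {bad[0]}"
        raise ValueError(f"zero-sum row for sample {name!r}; Hellinger undefined")
    return np.sqrt(counts / row_sums[:, None])
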