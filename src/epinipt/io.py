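"""File formats: BED readers/writers, counts TSV, metadata, truth JSON.

All tables are tab-separated with a header row; floats are serialised at 6
significant digits; coordinates are 0-based half-open with no track lines.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import CoverageMatrix, SiteIndex
from .synthetic_data import CohortTruth, GenomeModel, SampleMeta

FLOAT_FMT = "%.6g"


class BedParseError(ValueError):
    pass


def read_bed(path: str | Path, expected_columns: int = 3) -> pd.DataFrame:
    """Read a BED-like tab-separated file (0-based half-open), validated.

    Supports 3 columns (intervals), 4 (named intervals / flagged points) and
    6 (read starts: chrom, start, end, name, score, strand). Records are
    returned sorted by (chrom, start); malformed lines raise
    :class:`BedParseError` naming the line number.
    """
    names = {
        3: ["chrom", "start", "end"],
        4: ["chrom", "start", "end", "name"],
        6: ["chrom", "start", "end", "name", "score", "strand"],
    }
    if expected_columns not in names:
        raise ValueError("expected_columns must be 3, 4 or 6")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != expected_columns:
                raise BedParseError(
                    f"{path}:{lineno}: expected {expected_columns} columns, "
                    f"got {len(parts)}"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0:
                raise BedParseError(f"{path}:{lineno}: negative coordinate")
            if start >= end:
                raise BedParseError(f"{path}:{lineno}: start >= end")
            rows.append([parts[0], start, end] + parts[3:])
    df = pd.DataFrame(rows, columns=names[expected_columns])
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def write_cg_catalog(sites: SiteIndex, path: str | Path) -> None:
    """CG catalog as BED3 (one-bp intervals at each C position)."""
    frame = sites.to_frame()
    frame["end"] = frame["pos"] + 1
    frame[["chrom", "pos", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_cg_catalog(path: str | Path, chrom_lengths: dict[str, int]) -> SiteIndex:
    bed = read_bed(path, expected_columns=3)
    chrom_names = list(chrom_lengths)
    cid = bed["chrom"].map({c: i for i, c in enumerate(chrom_names)})
    if cid.isna().any():
        missing = bed.loc[cid.isna(), "chrom"].unique().tolist()
        raise BedParseError(f"catalog chromosomes missing lengths: {missing}")
    order = np.lexsort((bed["start"].to_numpy(), cid.to_numpy()))
    return SiteIndex(
        chrom_names,
        np.array([chrom_lengths[c] for c in chrom_names], dtype=np.int64),
        cid.to_numpy()[order].astype(np.int32),
        bed["start"].to_numpy()[order],
    )


def write_read_starts(reads: pd.DataFrame, path: str | Path) -> None:
    """Read starts as BED6 (score = 0, name = sample id)."""
    out = pd.DataFrame(
        {
            "chrom": reads["chrom"],
            "start": reads["start"],
            "end": reads["start"] + 1,
            "name": reads["sample_id"],
            "score": 0,
            "strand": reads["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_read_starts(path: str | Path) -> pd.DataFrame:
    bed = read_bed(path, expected_columns=6)
    return pd.DataFrame(
        {"chrom": bed["chrom"], "start": bed["start"], "strand": bed["strand"],
         "sample_id": bed["name"]}
    )


def write_counts(matrix: CoverageMatrix, path: str | Path) -> None:
    """Counts TSV: site_id (chrom:pos) rows x sample columns."""
    frame = matrix.sites.to_frame()
    site_id = frame["chrom"].astype(str) + ":" + frame["pos"].astype(str)
    df = pd.DataFrame(matrix.counts.T, columns=matrix.sample_ids)
    df.insert(0, "site_id", site_id)
    df.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path, chrom_lengths: dict[str, int]) -> CoverageMatrix:
    df = pd.read_csv(path, sep="\t")
    chrom = df["site_id"].str.rsplit(":", n=1).str[0]
    pos = df["site_id"].str.rsplit(":", n=1).str[1].astype(np.int64)
    chrom_names = list(chrom_lengths)
    cid = chrom.map({c: i for i, c in enumerate(chrom_names)}).to_numpy()
    order = np.lexsort((pos.to_numpy(), cid))
    sites = SiteIndex(
        chrom_names,
        np.array([chrom_lengths[c] for c in chrom_names], dtype=np.int64),
        cid[order].astype(np.int32),
        pos.to_numpy()[order],
    )
    sample_ids = [c for c in df.columns if c != "site_id"]
    counts = df[sample_ids].to_numpy().T[:, order]
    return CoverageMatrix(counts, sample_ids, sites)


def write_metadata(meta: list[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"sample_id": m.sample_id, "group": m.group, "assay": m.assay,
             "fetal_sex": m.fetal_sex, "ff": m.ff, "depth": m.depth}
            for m in meta
        ]
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_metadata(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    return [
        SampleMeta(r.sample_id, r.group, r.assay, str(r.fetal_sex),
                   float(r.ff), int(r.depth))
        for r in df.itertuples()
    ]


def write_truth(truth: CohortTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "ff": truth.ff,
                "karyotype": truth.karyotype,
                "planted_dmr_windows": {
                    k: [[c, int(s), d] for c, s, d in v]
                    for k, v in truth.planted_dmr_windows.items()
                },
            },
            fh,
            indent=1,
        )


def read_truth(path: str | Path) -> CohortTruth:
    with open(path) as fh:
        d = json.load(fh)
    return CohortTruth(
        ff=d["ff"],
        karyotype=d["karyotype"],
        planted_dmr_windows={
            k: [(c, int(s), dd) for c, s, dd in v]
            for k, v in d["planted_dmr_windows"].items()
        },
    )


def write_annotations(genome: GenomeModel, path: str | Path) -> None:
    """All annotations as BED4 (interval + element name)."""
    rows = []
    for name, by_chrom in genome.annotations.items():
        for chrom, iv in by_chrom.items():
            for s, e in np.asarray(iv).reshape(-1, 2):
                rows.append((chrom, int(s), int(e), name))
    pd.DataFrame(rows).sort_values([0, 1]).to_csv(
        path, sep="\t", header=False, index=False
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Generic results TSV with the package-wide float format."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
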