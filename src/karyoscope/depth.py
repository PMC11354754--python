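"""Binned sequencing depth: computation from alignments, table I/O, robust summaries.

Coverage is evaluated in fixed-width windows (default 10 kb) tiling each
sequence; whole-chromosome depth is then summarised robustly (outlier masking
by median absolute deviation, then a two-sided trimmed mean) so that sporadic
repeat-driven depth spikes do not bias per-chromosome copy-number estimates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy.stats import trim_mean

DEFAULT_BIN_SIZE = 10_000

BIN_COLUMNS = ["sequence", "start", "end", "depth"]


@dataclass
class DepthBins:
    """Per-bin mean coverage tiling a genome.

    ``table`` holds one row per bin with columns sequence/start/end/depth
    (0-based half-open coordinates, depth = mean per-base coverage in the
    bin). Bins tile each sequence without overlap; the last bin of a
    sequence may be shorter than ``bin_size``.
    """

    table: pd.DataFrame
    bin_size: int
    source: str = "table"

    def __post_init__(self) -> None:
        missing = [c for c in BIN_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"depth table missing columns: {missing}")
        t = self.table
        if (t["end"] <= t["start"]).any():
            raise ValueError("bins must satisfy end > start")
        if (t["depth"] < 0).any():
            bad = int(t.index[t["depth"] < 0][0])
            raise ValueError(f"negative depth at row {bad}")
        for seq, grp in t.groupby("sequence", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            order = np.argsort(starts)
            if (ends[order][:-1] > starts[order][1:]).any():
                raise ValueError(f"overlapping bins on sequence {seq!r}")

    @property
    def sequences(self) -> list[str]:
        return list(dict.fromkeys(self.table["sequence"]))

    def full_bins(self) -> pd.DataFrame:
        """Bins of exactly ``bin_size`` width (terminal short bins dropped)."""
        widths = self.table["end"] - self.table["start"]
        return self.table[widths == self.bin_size]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def scaled(self, factor: float) -> "DepthBins":
        t = self.table.copy()
        t["depth"] = t["depth"] * factor
        return DepthBins(t, self.bin_size, self.source)


@dataclass
class ChromosomeDepth:
    """Robust whole-chromosome depth summary."""

    sequence: str
    n_bins: int
    robust_depth: float
    mad: float
    masked_fraction: float

    def to_dict(self) -> dict:
        return {
            "sequence": self.sequence,
            "n_bins": self.n_bins,
            "robust_depth": self.robust_depth,
            "mad": self.mad,
            "masked_fraction": self.masked_fraction,
        }


def make_bins(lengths: dict[str, int], bin_size: int = DEFAULT_BIN_SIZE) -> pd.DataFrame:
    """Tile each sequence with half-open windows of ``bin_size``."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    for seq, length in lengths.items():
        if length <= 0:
            raise ValueError(f"sequence {seq!r} has non-positive length")
        starts = np.arange(0, length, bin_size)
        ends = np.minimum(starts + bin_size, length)
        rows.append(pd.DataFrame({"sequence": seq, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def compute_bins(
    alignments: str | Path,
    bin_size: int = DEFAULT_BIN_SIZE,
    mapq_min: int = 0,
    exclude_flags: int = 0x900 | 0x400 | 0x4,
) -> DepthBins:
    """Per-bin mean coverage from a coordinate-sorted BAM/SAM file.

    Depth of a bin is the total number of aligned bases overlapping the bin
    divided by the bin width. Secondary, supplementary, duplicate and
    unmapped records are excluded, as are records below ``mapq_min``.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    path = str(alignments)
    with pysam.AlignmentFile(path) as af:
        hd = af.header.to_dict().get("HD", {})
        if hd.get("SO") != "coordinate":
            raise ValueError(
                f"{path}: alignments must be coordinate-sorted (HD SO={hd.get('SO')!r})"
            )
        lengths = {name: af.get_reference_length(name) for name in af.references}
        bins = make_bins(lengths, bin_size)
        cov: dict[str, np.ndarray] = {
            name: np.zeros(int(np.ceil(length / bin_size))) for name, length in lengths.items()
        }
        n_used = 0
        for rec in af.fetch(until_eof=True):
            if rec.flag & exclude_flags or rec.mapping_quality < mapq_min:
                continue
            n_used += 1
            for blk_start, blk_end in rec.get_blocks():
                first = blk_start // bin_size
                last = (blk_end - 1) // bin_size
                arr = cov[rec.reference_name]
                for b in range(first, last + 1):
                    lo = max(blk_start, b * bin_size)
                    hi = min(blk_end, (b + 1) * bin_size)
                    arr[b] += hi - lo
    if n_used == 0:
        warnings.warn("no usable alignments; all bins are zero", stacklevel=2)
    widths = (bins["end"] - bins["start"]).to_numpy()
    depth = np.empty(len(bins))
    for seq, grp in bins.groupby("sequence", sort=False):
        idx = grp.index.to_numpy()
        depth[idx] = cov[seq][grp["start"].to_numpy() // bin_size]
    bins["depth"] = depth / widths
    return DepthBins(bins, bin_size, source="alignments")


def read_depth_table(
    path: str | Path,
    dialect: str = "karyoscope",
    bin_size: int | None = None,
    allow_ragged: bool = False,
) -> DepthBins:
    """Load a per-bin depth table.

    Dialects:
      * ``karyoscope`` — headered TSV with columns sequence/start/end/depth.
      * ``sambamba`` — headered TSV whose first columns are
        ``# chrom  chromStart  chromEnd  readCount  meanCoverage ...``;
        meanCoverage is taken as depth.
    """
    if dialect == "karyoscope":
        t = pd.read_csv(path, sep="\t")
        missing = [c for c in BIN_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        t = t[BIN_COLUMNS]
    elif dialect == "sambamba":
        t = pd.read_csv(path, sep="\t")
        t.columns = [c.lstrip("# ") for c in t.columns]
        rename = {"chrom": "sequence", "chromStart": "start", "chromEnd": "end",
                  "meanCoverage": "depth"}
        missing = [c for c in rename if c not in t.columns]
        if missing:
            raise ValueError(f"{path}: sambamba dialect missing columns {missing}")
        t = t.rename(columns=rename)[BIN_COLUMNS]
    else:
        raise ValueError(f"unknown depth-table dialect {dialect!r}")
    for col in ("start", "end"):
        bad = t.index[~t[col].astype(str).str.match(r"^\d+$")]
        if len(bad):
            raise ValueError(f"{path}: malformed {col} at line {int(bad[0]) + 2}")
    neg = t.index[t["depth"] < 0]
    if len(neg):
        raise ValueError(f"{path}: negative depth at line {int(neg[0]) + 2}")
    widths = (t["end"] - t["start"]).to_numpy()
    inferred = int(np.max(widths)) if bin_size is None else bin_size
    # Non-terminal bins must all share the bin size unless explicitly ragged.
    if not allow_ragged:
        for seq, grp in t.groupby("sequence", sort=False):
            w = (grp["end"] - grp["start"]).to_numpy()
            if (w[:-1] != inferred).any():
                raise ValueError(
                    f"{path}: inconsistent bin sizes on {seq!r}; pass allow_ragged=True"
                )
    return DepthBins(t, inferred, source="table")


def summarize_chromosome_depth(
    bins: DepthBins,
    trim_fraction: float = 0.1,
    mad_cutoff: float = 5.0,
) -> list[ChromosomeDepth]:
    """Robust per-chromosome depth.

    For each sequence, terminal short bins are excluded, bins further than
    ``mad_cutoff`` scaled MADs from the chromosome median are masked, and
    the robust depth is the two-sided trimmed mean (``trim_fraction`` per
    tail) of the remaining bins.
    """
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    full = bins.full_bins()
    out: list[ChromosomeDepth] = []
    for seq in bins.sequences:
        d = full.loc[full["sequence"] == seq, "depth"].to_numpy(dtype=float)
        if d.size == 0:
            raise ValueError(f"sequence {seq!r} has no full-width bins")
        med = float(np.median(d))
        mad = float(np.median(np.abs(d - med)))
        scale = 1.4826 * mad
        if scale > 0:
            keep = np.abs(d - med) <= mad_cutoff * scale
        else:
            keep = d == med
        if not keep.any():
            raise ValueError(f"sequence {seq!r}: all bins masked as outliers")
        robust = float(trim_mean(d[keep], trim_fraction))
        out.append(
            ChromosomeDepth(
                sequence=seq,
                n_bins=int(d.size),
                robust_depth=robust,
                mad=mad,
                masked_fraction=float(1 - keep.mean()),
            )
        )
    return out


def write_summary_json(summaries: list[ChromosomeDepth], path: str | Path) -> None:
    Path(path).write_text(json.dumps([s.to_dict() for s in summaries], indent=2) + "\n")
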