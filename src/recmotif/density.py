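"""q-discounted motif density tracks.

Each motif occurrence contributes (1 - q) to the genomic bin holding its
start coordinate, so per-window densities are discounted by match quality:
confident matches (q near 0) count fully, marginal ones fade out.  The sum
over all bins equals the genome-wide discounted total, and rebinning to
coarser windows conserves it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DensityTrack", "density_track", "sliding_density", "total_count", "rebin"]


@dataclass
class DensityTrack:
    """Per-bin sum of (1 - q) over motif occurrences."""

    motif: str
    bin_size: int
    values: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for chrom, vals in self.values.items():
            starts = np.arange(len(vals), dtype=np.int64) * self.bin_size
            ends = np.minimum(starts + self.bin_size, self.chrom_lengths[chrom])
            parts.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": ends, "density": vals}
                )
            )
        return pd.concat(parts, ignore_index=True)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    def write_bedgraph(self, path) -> None:
        df = self.to_frame()
        df.to_csv(path, sep="\t", index=False, header=False, float_format="%.10g")


def density_track(
    occ: pd.DataFrame,
    chrom_lengths: dict[str, int],
    bin_size: int = 1000,
    motif: str | None = None,
) -> DensityTrack:
    """Tile the genome into ``bin_size`` windows and sum (1 - q) per bin.

    Each occurrence is assigned to exactly one bin by its start coordinate
    (single assignment keeps totals conserved for boundary-spanning matches).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if "q" not in occ.columns:
        raise ValueError("occurrences lack q-scores; run compute_qvalues first")
    values: dict[str, np.ndarray] = {}
    grouped = dict(iter(occ.groupby("chrom"))) if len(occ) else {}
    for chrom, length in chrom_lengths.items():
        n = -(-length // bin_size)
        sub = grouped.get(chrom)
        if sub is None or len(sub) == 0:
            values[chrom] = np.zeros(n)
            continue
        starts = sub["start"].to_numpy(np.int64)
        if (starts < 0).any() or (sub["end"].to_numpy(np.int64) > length).any():
            raise ValueError(f"occurrence outside {chrom} bounds")
        w = 1.0 - sub["q"].to_numpy(float)
        values[chrom] = np.bincount(starts // bin_size, weights=w, minlength=n)
    extra = set(occ["chrom"].unique()) - set(chrom_lengths) if len(occ) else set()
    if extra:
        raise ValueError(f"occurrences on unknown chromosomes: {sorted(extra)}")
    return DensityTrack(
        motif=motif or occ.attrs.get("motif", "motif"),
        bin_size=bin_size,
        values=values,
        chrom_lengths=dict(chrom_lengths),
    )


def sliding_density(
    occ: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window: int = 1000,
    stride: int = 500,
    motif: str | None = None,
) -> pd.DataFrame:
    """Overlapping-window variant: sum of (1 - q) in windows of ``window`` bp
    every ``stride`` bp.  Returned as a tidy frame (windows overlap, so this
    does not conserve totals and is not a :class:`DensityTrack`)."""
    if window <= 0 or stride <= 0:
        raise ValueError("window and stride must be positive")
    parts = []
    grouped = dict(iter(occ.groupby("chrom"))) if len(occ) else {}
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, max(length - window, 0) + 1, stride, dtype=np.int64)
        vals = np.zeros(len(starts))
        sub = grouped.get(chrom)
        if sub is not None and len(sub):
            pos = np.sort(sub["start"].to_numpy(np.int64))
            w = (1.0 - sub["q"].to_numpy(float))[np.argsort(sub["start"].to_numpy())]
            cum = np.concatenate([[0.0], np.cumsum(w)])
            lo = np.searchsorted(pos, starts, side="left")
            hi = np.searchsorted(pos, starts + window, side="left")
            vals = cum[hi] - cum[lo]
        parts.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + window,
                    "density": vals,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def total_count(occ: pd.DataFrame) -> float:
    """Genome-wide discounted motif count: sum of (1 - q) over occurrences."""
    if len(occ) == 0:
        return 0.0
    if "q" not in occ.columns:
        raise ValueError("occurrences lack q-scores; run compute_qvalues first")
    return float((1.0 - occ["q"].to_numpy(float)).sum())


def rebin(track: DensityTrack, factor: int) -> DensityTrack:
    """Sum consecutive groups of ``factor`` bins into coarser bins.

    A trailing partial group is kept as its own (shorter) bin, so totals are
    conserved exactly.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return DensityTrack(
            motif=track.motif,
            bin_size=track.bin_size,
            values={c: v.copy() for c, v in track.values.items()},
            chrom_lengths=dict(track.chrom_lengths),
        )
    values = {}
    for chrom, vals in track.values.items():
        edges = np.arange(0, len(vals), factor)
        values[chrom] = np.add.reduceat(vals, edges)
    return DensityTrack(
        motif=track.motif,
        bin_size=track.bin_size * factor,
        values=values,
        chrom_lengths=dict(track.chrom_lengths),
    )
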