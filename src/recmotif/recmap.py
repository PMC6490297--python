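"""Recombination maps: reading, unit normalization, smoothing and segmentation.

A recombination map is a per-chromosome track of rates over fixed-width
genomic bins.  Rates are either population-scaled (rho, from LD-based
estimators) or genetic-map units (cM/Mb); the map carries an explicit unit
flag and rho maps can be rescaled to cM/Mb by anchoring the total genetic
length of marker intervals to known centimorgan values.

Smoothing uses a moving median (order-statistic smoother): with odd windows,
every interior smoothed value is a member of the raw window's multiset, so
the smoothed map contains only values present in the raw data.  LOESS local
linear regression is provided as an alternative smoother.

Segmentation splits each chromosome at its median rate into high- and
low-recombining bins, the classes used for differential motif discovery.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RecombinationMap",
    "AnchorSet",
    "RegionLabels",
    "read_map",
    "write_map",
    "normalize_to_cM",
    "moving_median",
    "loess_smooth",
    "split_high_low",
    "LOW",
    "HIGH",
    "EXCLUDED",
]

UNIT_RHO = "rho"
UNIT_CM = "cM_per_Mb"

LOW, HIGH, EXCLUDED = 0, 1, 2
_LABEL_NAMES = {LOW: "low", HIGH: "high", EXCLUDED: "excluded"}


@dataclass
class RecombinationMap:
    """Fixed-bin recombination-rate track over one or more chromosomes.

    Parameters
    ----------
    bin_size : int
        Bin width in bp; uniform across chromosomes.
    unit : str
        ``"rho"`` or ``"cM_per_Mb"``.
    rates : dict
        Chromosome name -> float array of per-bin rates; missing bins are NaN.
    lengths : dict
        Chromosome name -> chromosome length in bp.
    """

    bin_size: int
    unit: str
    rates: dict[str, np.ndarray]
    lengths: dict[str, int]

    def __post_init__(self) -> None:
        if self.unit not in (UNIT_RHO, UNIT_CM):
            raise ValueError(f"unknown rate unit {self.unit!r}")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, vals in self.rates.items():
            vals = np.asarray(vals, dtype=float)
            self.rates[chrom] = vals
            expected = math.ceil(self.lengths[chrom] / self.bin_size)
            if len(vals) != expected:
                raise ValueError(
                    f"{chrom}: {len(vals)} bins but length {self.lengths[chrom]} "
                    f"at bin size {self.bin_size} implies {expected}"
                )
            finite = vals[~np.isnan(vals)]
            if (finite < 0).any():
                raise ValueError(f"{chrom}: negative rates")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.rates)

    def n_bins(self, chrom: str) -> int:
        return len(self.rates[chrom])

    def copy(self, **updates) -> "RecombinationMap":
        kw = dict(
            bin_size=self.bin_size,
            unit=self.unit,
            rates={c: v.copy() for c, v in self.rates.items()},
            lengths=dict(self.lengths),
        )
        kw.update(updates)
        return RecombinationMap(**kw)

    def bin_starts(self, chrom: str) -> np.ndarray:
        return np.arange(self.n_bins(chrom), dtype=np.int64) * self.bin_size

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-bin table with columns chrom, start, end, rate."""
        parts = []
        for chrom, vals in self.rates.items():
            starts = self.bin_starts(chrom)
            ends = np.minimum(starts + self.bin_size, self.lengths[chrom])
            parts.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": ends, "rate": vals}
                )
            )
        return pd.concat(parts, ignore_index=True)


@dataclass
class AnchorSet:
    """Marker intervals with known genetic lengths, used to rescale rho maps.

    Each anchor is ``(chrom, start, end, cM)`` with 0-based half-open
    coordinates and a non-negative genetic length in centimorgans.
    """

    anchors: list[tuple[str, int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, cm in self.anchors:
            if end <= start:
                raise ValueError(f"anchor {chrom}:{start}-{end} is empty")
            if cm < 0:
                raise ValueError("anchor genetic length must be >= 0")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping anchors on {chrom}")

    @property
    def total_cM(self) -> float:
        return float(sum(a[3] for a in self.anchors))


@dataclass
class RegionLabels:
    """Per-bin high/low/excluded labels from the median-rate split."""

    bin_size: int
    labels: dict[str, np.ndarray]

    def to_bed(self) -> pd.DataFrame:
        rows = []
        for chrom, lab in self.labels.items():
            starts = np.arange(len(lab), dtype=np.int64) * self.bin_size
            for s, code in zip(starts, lab):
                rows.append(
                    (chrom, int(s), int(s + self.bin_size), _LABEL_NAMES[int(code)], 0, ".")
                )
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name", "score", "strand"]
        )


def read_map(path, unit: str = UNIT_CM) -> RecombinationMap:
    """Read a per-window rate table (CSV, header ``chrom,start,end,rate``).

    Rows may be unordered; gaps become missing (NaN) bins.  Bin width must be
    uniform per chromosome (the final bin of a chromosome may be shorter).
    """
    df = pd.read_csv(path, comment="#")
    required = {"chrom", "start", "end", "rate"}
    if not required.issubset(df.columns):
        raise ValueError(f"map file must have columns {sorted(required)}")
    rates: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    bin_size = None
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        vals = sub["rate"].to_numpy(float)
        if (ends <= starts).any():
            raise ValueError(f"{chrom}: empty or inverted bins")
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"{chrom}: overlapping bins")
        if (vals[~np.isnan(vals)] < 0).any():
            raise ValueError(f"{chrom}: negative rates")
        widths = ends - starts
        bs = int(widths[0]) if len(widths) == 1 else int(np.max(widths))
        if bin_size is None:
            bin_size = bs
        elif bs != bin_size:
            raise ValueError(f"{chrom}: bin size {bs} != {bin_size} elsewhere")
        # all rows except a trailing partial bin must have the uniform width
        bad = widths != bin_size
        if bad[:-1].any() or (bad[-1] and ends[-1] - starts[-1] > bin_size):
            raise ValueError(f"{chrom}: non-uniform bin widths")
        if (starts % bin_size != 0).any():
            raise ValueError(f"{chrom}: bins not aligned to bin size")
        length = int(ends[-1])
        n = math.ceil(length / bin_size)
        track = np.full(n, np.nan)
        track[starts // bin_size] = vals
        rates[str(chrom)] = track
        lengths[str(chrom)] = length
    if bin_size is None:
        raise ValueError("empty map file")
    return RecombinationMap(bin_size=bin_size, unit=unit, rates=rates, lengths=lengths)


def write_map(m: RecombinationMap, path) -> None:
    m.to_frame().to_csv(path, index=False, float_format="%.10g")


def normalize_to_cM(m: RecombinationMap, anchors: AnchorSet) -> RecombinationMap:
    """Rescale a rho map to cM/Mb by anchoring total genetic length.

    A single constant ``c = (sum of anchor cM) / (map genetic length summed
    over the anchor intervals)`` multiplies every bin, so bin-to-bin ratios
    are preserved and the anchor intervals jointly re-sum to the anchor total.
    """
    if m.unit != UNIT_RHO:
        raise ValueError("map is not in rho units")
    if not anchors.anchors:
        raise ValueError("no anchors supplied")
    mass = 0.0  # genetic length before scaling, in rate * Mb
    for chrom, a_start, a_end, _cm in anchors.anchors:
        if chrom not in m.rates:
            raise ValueError(f"anchor chromosome {chrom!r} absent from map")
        vals = m.rates[chrom]
        starts = m.bin_starts(chrom)
        ends = np.minimum(starts + m.bin_size, m.lengths[chrom])
        overlap = np.clip(
            np.minimum(ends, a_end) - np.maximum(starts, a_start), 0, None
        )
        with np.errstate(invalid="ignore"):
            contrib = np.where(np.isnan(vals), 0.0, vals) * overlap
        mass += float(contrib.sum()) / 1e6
    if mass <= 0:
        raise ValueError("zero rho mass within anchor intervals")
    c = anchors.total_cM / mass
    out = m.copy(unit=UNIT_CM)
    for chrom in out.rates:
        out.rates[chrom] = out.rates[chrom] * c
    return out


def _moving_median_1d(vals: np.ndarray, w: int) -> np.ndarray:
    """Moving median with truncated edge windows and NaN exclusion.

    For windows whose non-missing multiset has even size (edges, or interior
    windows with missing bins) the lower of the two central order statistics
    is taken, so every output value is a member of its window's multiset.
    """
    n = len(vals)
    half = w // 2
    padded = np.concatenate(
        [np.full(half, np.nan), vals.astype(float), np.full(half, np.nan)]
    )
    out = np.empty(n)
    chunk = max(1, int(4_000_000 // w))
    for lo in range(0, n, chunk):
        hi = min(n, lo + chunk)
        win = np.lib.stride_tricks.sliding_window_view(padded[lo : hi + 2 * half], w)
        sw = np.sort(win, axis=1)  # NaNs sort to the end
        k = w - np.isnan(sw).sum(axis=1)
        idx = (np.maximum(k, 1) - 1) // 2
        vals_out = sw[np.arange(hi - lo), idx]
        vals_out[k == 0] = np.nan
        out[lo:hi] = vals_out
    return out


def moving_median(m: RecombinationMap, window_kb: float) -> RecombinationMap:
    """Moving-median smoothing at a window of ``window_kb`` kilobases.

    The window must correspond to an odd number of bins (so interior smoothed
    values are members of the raw window multiset) and must not exceed any
    chromosome's bin count.  Edge bins use the truncated window; missing bins
    are excluded from each window's multiset.  ``w = 1`` is the identity.
    """
    w_f = window_kb * 1000 / m.bin_size
    w = int(round(w_f))
    if abs(w_f - w) > 1e-9:
        raise ValueError(
            f"window of {window_kb} kb is not a whole number of {m.bin_size}-bp bins"
        )
    if w < 1 or w % 2 == 0:
        raise ValueError(f"window must be an odd number of bins, got {w}")
    for chrom in m.rates:
        if w > m.n_bins(chrom):
            raise ValueError(
                f"window of {w} bins exceeds {chrom} ({m.n_bins(chrom)} bins)"
            )
    if w == 1:
        return m.copy()
    out = m.copy()
    for chrom, vals in m.rates.items():
        out.rates[chrom] = _moving_median_1d(vals, w)
    return out


def _loess_1d(x: np.ndarray, y: np.ndarray, span: float) -> np.ndarray:
    """Tricube-weighted local linear regression evaluated at every x."""
    n = len(x)
    k = min(n, max(2, math.ceil(span * n)))
    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        dmax = np.partition(d, k - 1)[k - 1]
        if dmax == 0:
            raise ValueError("degenerate design: all x identical in window")
        u = np.clip(d / dmax, 0, 1)
        w = (1 - u**3) ** 3
        sw = w.sum()
        xm = (w * x).sum() / sw
        ym = (w * y).sum() / sw
        sxx = (w * (x - xm) ** 2).sum()
        if sxx <= 0:
            fitted[i] = ym
            continue
        beta = (w * (x - xm) * (y - ym)).sum() / sxx
        fitted[i] = ym + beta * (x[i] - xm)
    return fitted


def loess_smooth(m: RecombinationMap, span: float) -> RecombinationMap:
    """LOESS (local linear, tricube weights) alternative smoother.

    ``span`` is the fraction of a chromosome's bins in each local fit.
    Negative fitted rates are clipped to zero; missing bins stay missing.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    out = m.copy()
    for chrom, vals in m.rates.items():
        good = ~np.isnan(vals)
        if good.sum() < 10:
            raise ValueError(f"{chrom}: need >= 10 non-missing bins for LOESS")
        x = np.flatnonzero(good).astype(float)
        fitted = _loess_1d(x, vals[good], span)
        track = np.full_like(vals, np.nan)
        track[good] = np.clip(fitted, 0, None)
        out.rates[chrom] = track
    return out


def split_high_low(m: RecombinationMap) -> RegionLabels:
    """Label bins high/low relative to each chromosome's median rate.

    Bins with rate strictly greater than the per-chromosome median of
    non-missing rates are labelled high, the rest low; missing bins are
    excluded.  On a chromosome whose rates are all equal the high class is
    empty (the degenerate case downstream discovery must refuse).
    """
    labels: dict[str, np.ndarray] = {}
    for chrom, vals in m.rates.items():
        good = ~np.isnan(vals)
        if good.sum() < 2:
            raise ValueError(f"{chrom}: need >= 2 non-missing bins to split")
        med = float(np.median(vals[good]))
        lab = np.full(len(vals), EXCLUDED, dtype=np.int8)
        lab[good & (vals > med)] = HIGH
        lab[good & (vals <= med)] = LOW
        if len(np.unique(vals[good])) >= 2 and not (lab == HIGH).any():
            warnings.warn(f"{chrom}: empty high class despite distinct rates")
        labels[chrom] = lab
    return RegionLabels(bin_size=m.bin_size, labels=labels)
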