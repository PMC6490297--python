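"""Motif-density / recombination-rate association statistics.

For every motif x chromosome x smoothing scale (and pooled over all
chromosomes) two statistics quantify the association between the
q-discounted motif density track and the recombination map: Spearman's rank
correlation (a nonparametric estimate robust to the heavy-tailed density
distribution) and an ordinary least-squares fit of rate on density (an
explicit directional effect with a slope test).
"""

from __future__ import annotations

import math
import warnings
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .density import DensityTrack, rebin
from .recmap import RecombinationMap

__all__ = ["spearman", "ols_fit", "association_grid", "plot_grid"]

P_FLOOR = 1e-300  # reported instead of an exact zero p-value

EXACT_PERMUTATION_MAX_N = 10  # below this, the Spearman p is exact


def _rankdata(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman(density: np.ndarray, rate: np.ndarray) -> tuple[float, float]:
    """Spearman's rho with average ranks for ties.

    Pairs with a missing rate or density are dropped.  The p-value uses the
    t-approximation with n-2 degrees of freedom for n >= 10 and an exact
    permutation distribution over all n! orderings for smaller n.  Constant
    input on either side leaves the correlation undefined: (nan, nan) is
    returned with a warning.
    """
    x = np.asarray(density, dtype=float)
    y = np.asarray(rate, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    good = ~(np.isnan(x) | np.isnan(y))
    x, y = x[good], y[good]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input: Spearman correlation undefined")
        return (math.nan, math.nan)
    rx, ry = _rankdata(x), _rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if n < EXACT_PERMUTATION_MAX_N:
        perms = np.array(list(permutations(range(n))))
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt((rxc**2).sum() * (ryc**2).sum())
        rhos = (ryc[perms] @ rxc) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            return rho, P_FLOOR
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, max(p, P_FLOOR)


def ols_fit(
    density: np.ndarray, rate: np.ndarray
) -> tuple[float, float, float, float]:
    """OLS of rate on density: (slope, intercept, slope p, r squared).

    The slope p-value is the two-sided t-test; an exact zero-residual fit is
    reported at the floor constant rather than p = 0.  Constant density
    leaves the slope undefined: NaNs are returned with a warning.
    """
    x = np.asarray(density, dtype=float)
    y = np.asarray(rate, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    good = ~(np.isnan(x) | np.isnan(y))
    x, y = x[good], y[good]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]):
        warnings.warn("constant density: OLS slope undefined")
        return (math.nan, math.nan, math.nan, math.nan)
    res = stats.linregress(x, y)
    p = res.pvalue if np.isfinite(res.pvalue) and res.pvalue > 0 else P_FLOOR
    return (
        float(res.slope),
        float(res.intercept),
        float(max(p, P_FLOOR)),
        float(res.rvalue**2),
    )


GRID_COLUMNS = [
    "motif",
    "stratum",
    "scale_kb",
    "n",
    "rho",
    "rho_p",
    "slope",
    "intercept",
    "slope_p",
    "r2",
]


def _one_cell(motif, stratum, scale_kb, x, y):
    good = ~(np.isnan(x) | np.isnan(y))
    n = int(good.sum())
    row = dict(motif=motif, stratum=stratum, scale_kb=scale_kb, n=n)
    if n < 3:
        row.update(
            rho=math.nan, rho_p=math.nan, slope=math.nan, intercept=math.nan,
            slope_p=math.nan, r2=math.nan,
        )
        return row
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, rho_p = spearman(x, y)
        slope, intercept, slope_p, r2 = ols_fit(x, y)
    row.update(rho=rho, rho_p=rho_p, slope=slope, intercept=intercept,
               slope_p=slope_p, r2=r2)
    return row


def association_grid(
    maps_by_scale: dict[float, RecombinationMap],
    densities: dict[str, DensityTrack],
    chromosomes: list[str] | None = None,
    add_bh: bool = False,
) -> pd.DataFrame:
    """Association statistics for every motif x stratum x smoothing scale.

    ``maps_by_scale`` maps a smoothing scale (kb) to the smoothed map at
    that scale; all maps must share bin size and chromosomes.  Each motif's
    density track must match the map bin size (rebin first — a mismatch is a
    contract error, never silently resampled).  Per-chromosome strata are
    emitted plus a pooled ``"genome"`` stratum (concatenated bin vectors)
    whenever at least two chromosomes are present.  ``add_bh`` appends a
    Benjamini-Hochberg column over the grid's Spearman p-values.
    """
    rows = []
    for scale_kb, m in sorted(maps_by_scale.items()):
        chroms = chromosomes if chromosomes is not None else m.chromosomes
        for motif, track in densities.items():
            if track.bin_size != m.bin_size:
                raise ValueError(
                    f"density bin size {track.bin_size} != map bin size "
                    f"{m.bin_size} at scale {scale_kb} kb; rebin first"
                )
            xs, ys = [], []
            for chrom in chroms:
                if chrom not in track.values or chrom not in m.rates:
                    raise ValueError(f"chromosome {chrom!r} missing from inputs")
                x = track.values[chrom]
                y = m.rates[chrom]
                if len(x) != len(y):
                    raise ValueError(
                        f"{chrom}: {len(x)} density bins vs {len(y)} map bins"
                    )
                rows.append(_one_cell(motif, chrom, scale_kb, x, y))
                xs.append(x)
                ys.append(y)
            if len(chroms) >= 2:
                rows.append(
                    _one_cell(
                        motif, "genome", scale_kb, np.concatenate(xs), np.concatenate(ys)
                    )
                )
    grid = pd.DataFrame(rows, columns=GRID_COLUMNS)
    if add_bh:
        p = grid["rho_p"].to_numpy(float)
        ok = ~np.isnan(p)
        bh = np.full(len(p), math.nan)
        if ok.any():
            pv = p[ok]
            order = np.argsort(pv, kind="mergesort")
            ranked = pv[order] * len(pv) / np.arange(1, len(pv) + 1)
            qv = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
            out = np.empty_like(qv)
            out[order] = qv
            bh[ok] = out
        grid["rho_p_bh"] = bh
    return grid


def rebin_density_to_map(track: DensityTrack, m: RecombinationMap) -> DensityTrack:
    """Rebin a fine density track to a coarser map's bin size (exact factor)."""
    if m.bin_size % track.bin_size != 0:
        raise ValueError("map bin size is not a multiple of the density bin size")
    return rebin(track, m.bin_size // track.bin_size)


def plot_grid(grid: pd.DataFrame, path, motifs=None) -> None:
    """Bar panel of Spearman's rho per stratum and scale (p as transparency)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    motifs = motifs or sorted(grid["motif"].unique())
    strata = list(dict.fromkeys(grid["stratum"]))
    scales = sorted(grid["scale_kb"].unique())
    fig, axes = plt.subplots(
        len(scales), len(strata), figsize=(2.2 * len(strata), 1.6 * len(scales)),
        squeeze=False, sharey=True,
    )
    for i, scale in enumerate(scales):
        for j, stratum in enumerate(strata):
            ax = axes[i][j]
            sub = grid[(grid["scale_kb"] == scale) & (grid["stratum"] == stratum)]
            sub = sub.set_index("motif").reindex(motifs)
            alphas = 1.0 - np.clip(sub["rho_p"].fillna(1.0), 0, 1) * 0.8
            ax.bar(range(len(motifs)), sub["rho"].fillna(0), alpha=None,
                   color=[(0.2, 0.3, 0.7, a) for a in alphas])
            ax.axhline(0, lw=0.5, color="k")
            if i == 0:
                ax.set_title(str(stratum), fontsize=8)
            if j == 0:
                ax.set_ylabel(f"{scale:g} kb", fontsize=8)
            ax.set_xticks(range(len(motifs)))
            ax.set_xticklabels(motifs, fontsize=6, rotation=90)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
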