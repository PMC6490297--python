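"""PWM construction and genome scanning with exact p-values and q-scores.

Consensus motifs become letter-probability matrices in a *hard* dialect
(expected base probability 1, others 0) or a *soft* dialect (0.97 vs 0.01).
Matches are scored by log-odds against an order-0 background; per-match
p-values come from the exact null score distribution, obtained by dynamic
programming over discretized per-column scores (position-wise convolution of
the column score distributions under the background).  Reported matches are
those with p at or below a threshold (default 1e-4); Benjamini-Hochberg
q-scores over the total number of scanned positions are then attached, and
downstream densities discount each match by (1 - q).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import BASES, N_CODE, encode

__all__ = [
    "Background",
    "MotifMatrix",
    "ScoreMatrix",
    "PValueTable",
    "consensus_to_matrix",
    "estimate_background",
    "log_odds",
    "score_pvalue_table",
    "scan",
    "compute_qvalues",
    "scan_with_qvalues",
]

OCCURRENCE_COLUMNS = ["chrom", "start", "end", "strand", "score", "p"]


@dataclass(frozen=True)
class Background:
    """Order-0 base frequencies over A, C, G, T (strictly positive, sum 1)."""

    freqs: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", f)
        if f.shape != (4,):
            raise ValueError("background must have 4 frequencies (A,C,G,T)")
        if not np.all(f > 0):
            raise ValueError("background frequencies must be strictly positive")
        if abs(f.sum() - 1.0) > 1e-12:
            raise ValueError("background frequencies must sum to 1")

    @classmethod
    def uniform(cls) -> "Background":
        return cls(np.full(4, 0.25))

    def as_dict(self) -> dict[str, float]:
        return dict(zip(BASES, map(float, self.freqs)))


@dataclass
class MotifMatrix:
    """Letter-probability matrix: one column of base probabilities per position."""

    name: str
    probs: np.ndarray  # (L, 4)
    dialect: str = "hard"

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        self.probs = p
        if p.ndim != 2 or p.shape[1] != 4 or p.shape[0] == 0:
            raise ValueError("probability matrix must be (L, 4) with L >= 1")
        if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("each column must sum to 1")
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")

    def __len__(self) -> int:
        return self.probs.shape[0]

    def reverse_complement(self) -> "MotifMatrix":
        return MotifMatrix(
            name=self.name, probs=self.probs[::-1, ::-1].copy(), dialect=self.dialect
        )


@dataclass
class ScoreMatrix:
    """Per-position log-odds scores in bits, with the pseudocount used."""

    name: str
    scores: np.ndarray  # (L, 4), bits
    pseudocount: float

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        self.scores = s
        if not np.all(np.isfinite(s)):
            raise ValueError("log-odds scores must be finite")

    def __len__(self) -> int:
        return self.scores.shape[0]


DIALECT_PROBS = {"hard": (1.0, 0.0), "soft": (0.97, 0.01)}


def consensus_to_matrix(
    consensus: str, dialect: str = "hard", name: str | None = None
) -> MotifMatrix:
    """Letter-probability matrix for an unambiguous consensus string.

    ``hard`` gives the expected base probability 1 and others 0; ``soft``
    gives 0.97 vs 0.01.  Ambiguity codes are not supported.
    """
    if dialect not in DIALECT_PROBS:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not consensus:
        raise ValueError("empty consensus string")
    consensus = consensus.upper()
    if any(b not in BASES for b in consensus):
        raise ValueError(f"unsupported characters in consensus {consensus!r}")
    hit, miss = DIALECT_PROBS[dialect]
    probs = np.full((len(consensus), 4), miss)
    for i, b in enumerate(consensus):
        probs[i, BASES.index(b)] = hit
    return MotifMatrix(name=name or consensus, probs=probs, dialect=dialect)


def estimate_background(genome: dict[str, str], floor: float = 1e-6) -> Background:
    """Strand-symmetrized order-0 base frequencies of a genome.

    Counts each sequence and its reverse complement (so A/T and C/G are
    balanced), skips N bases, replaces zero frequencies with ``floor`` and
    renormalizes.
    """
    counts = np.zeros(4, dtype=np.int64)
    for seq in genome.values():
        codes = encode(seq)
        counts += np.bincount(codes, minlength=5)[:4]
    total = counts.sum()
    if total == 0:
        raise ValueError("genome contains no unambiguous A/C/G/T bases")
    sym = (counts + counts[::-1]) / (2.0 * total)  # revcomp pairs A<->T, C<->G
    sym = np.where(sym == 0, floor, sym)
    return Background(sym / sym.sum())


def log_odds(
    matrix: MotifMatrix, bg: Background, pseudocount: float = 0.1
) -> ScoreMatrix:
    """Background-proportional pseudocount regularization, then log2 odds.

    ``p' = (p + eps * bg) / (1 + eps)``; ``score = log2(p' / bg)``.  A
    positive pseudocount keeps hard-matrix mismatch scores finite.
    """
    if pseudocount <= 0 and np.any(matrix.probs == 0):
        raise ValueError("pseudocount must be > 0 for matrices with zero entries")
    p = (matrix.probs + pseudocount * bg.freqs) / (1.0 + pseudocount)
    return ScoreMatrix(
        name=matrix.name,
        scores=np.log2(p / bg.freqs),
        pseudocount=pseudocount,
    )


class PValueTable:
    """Exact null distribution of the discretized match score.

    Scores are rounded to integer multiples of ``granularity`` bits.  The
    null PMF of the total score of a random word drawn from the background is
    the convolution of the per-column score distributions; ``p(s)`` is the
    upper tail P(S >= s).  Every score a genomic window can achieve is a sum
    of one discretized entry per column and therefore lies in the table's
    support.
    """

    def __init__(self, sm: ScoreMatrix, bg: Background, granularity: float = 1e-3):
        if granularity <= 0:
            raise ValueError("granularity must be positive")
        int_scores = np.round(sm.scores / granularity).astype(np.int64)
        span = int(int_scores.max(axis=1).sum() - int_scores.min(axis=1).sum())
        if span > 50_000_000:
            raise ValueError("score range too wide for chosen granularity")
        self.granularity = float(granularity)
        self.int_scores = int_scores
        lo = int(int_scores.min(axis=1).sum())
        hi = int(int_scores.max(axis=1).sum())
        # running support [cur_lo, cur_lo + len(cur) - 1]
        cur_lo = 0
        cur = np.array([1.0])
        for col in range(int_scores.shape[0]):
            cmin = int(int_scores[col].min())
            cmax = int(int_scores[col].max())
            new = np.zeros(len(cur) + (cmax - cmin))
            for b in range(4):
                off = int(int_scores[col, b]) - cmin
                new[off : off + len(cur)] += cur * bg.freqs[b]
            cur = new
            cur_lo += cmin
        assert cur_lo == lo and len(cur) == hi - lo + 1
        pmf = cur
        self.min_score = lo
        self.max_score = hi
        self.pmf = pmf
        # upper tail, clipped into (0, 1]
        tail = np.cumsum(pmf[::-1])[::-1]
        self.pvals = np.clip(tail, np.finfo(float).tiny, 1.0)

    def p_of_int_score(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=np.int64)
        idx = np.clip(s - self.min_score, 0, len(self.pvals) - 1)
        out = self.pvals[idx]
        return np.where(s > self.max_score, np.finfo(float).tiny, out)

    def threshold_int_score(self, p_threshold: float) -> int | None:
        """Smallest achievable integer score with p <= threshold, or None."""
        ok = np.flatnonzero(self.pvals <= p_threshold)
        if len(ok) == 0:
            return None
        return int(ok[0] + self.min_score)


def score_pvalue_table(
    sm: ScoreMatrix, bg: Background, granularity: float = 1e-3
) -> PValueTable:
    """Exact p-value lookup for a score matrix under a background (see
    :class:`PValueTable`)."""
    return PValueTable(sm, bg, granularity)


def _int_score_lut(int_scores: np.ndarray) -> np.ndarray:
    """(L, 5) lookup with an extra zero column for N codes (N windows are
    excluded separately, the zero keeps the accumulation well-defined)."""
    L = int_scores.shape[0]
    lut = np.zeros((L, 5), dtype=np.int64)
    lut[:, :4] = int_scores
    return lut


def scan(
    genome: dict[str, str],
    matrix: MotifMatrix,
    bg: Background,
    p_threshold: float = 1e-4,
    pseudocount: float = 0.1,
    granularity: float = 1e-3,
    max_stored_scores: int = 50_000_000,
) -> pd.DataFrame:
    """Report motif occurrences with p <= threshold on both strands.

    Every window position on both strands is scored (the reverse strand by
    scoring the reverse-complement matrix on the forward sequence); windows
    containing N are skipped.  Overlapping matches are all reported, sorted
    by (chrom, start, strand).  The result carries ``attrs['n_tests']``, the
    total number of scanned (N-free) positions over both strands, used for
    q-score correction.

    ``max_stored_scores`` caps the number of reported occurrences (a
    streaming memory guard mirroring scanner conventions); exceeding it
    raises rather than silently truncating.
    """
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0, 1)")
    L = len(matrix)
    sm_fwd = log_odds(matrix, bg, pseudocount)
    sm_rev = log_odds(matrix.reverse_complement(), bg, pseudocount)
    table = PValueTable(sm_fwd, bg, granularity)
    s_thr = table.threshold_int_score(p_threshold)
    luts = {
        "+": _int_score_lut(np.round(sm_fwd.scores / granularity).astype(np.int64)),
        "-": _int_score_lut(np.round(sm_rev.scores / granularity).astype(np.int64)),
    }
    rows = []
    n_tests = 0
    for chrom in genome:
        seq = genome[chrom]
        if len(seq) < L:
            raise ValueError(f"{chrom} is shorter than the motif ({L} bp)")
        codes = encode(seq)
        npos = len(codes) - L + 1
        is_n = np.concatenate([[0], np.cumsum(codes == N_CODE)])
        valid = (is_n[L:] - is_n[:-L]) == 0
        n_tests += 2 * int(valid.sum())
        for strand, lut in luts.items():
            total = np.zeros(npos, dtype=np.int64)
            for i in range(L):
                total += lut[i][codes[i : i + npos]]
            if s_thr is None:
                continue
            hit = valid & (total >= s_thr)
            starts = np.flatnonzero(hit)
            if len(starts) == 0:
                continue
            scores = total[starts]
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts.astype(np.int64),
                        "end": (starts + L).astype(np.int64),
                        "strand": strand,
                        "score": scores * granularity,
                        "p": table.p_of_int_score(scores),
                    }
                )
            )
    if rows:
        occ = pd.concat(rows, ignore_index=True)
        occ = occ.sort_values(["chrom", "start", "strand"], kind="mergesort")
        occ = occ.reset_index(drop=True)
    else:
        occ = pd.DataFrame(
            {
                "chrom": pd.Series(dtype=str),
                "start": pd.Series(dtype=np.int64),
                "end": pd.Series(dtype=np.int64),
                "strand": pd.Series(dtype=str),
                "score": pd.Series(dtype=float),
                "p": pd.Series(dtype=float),
            }
        )
    if len(occ) > max_stored_scores:
        raise ValueError(
            f"{len(occ)} occurrences exceed max_stored_scores={max_stored_scores}"
        )
    occ.attrs["n_tests"] = n_tests
    occ.attrs["motif"] = matrix.name
    return occ


def compute_qvalues(occ: pd.DataFrame, n_tests: int | None = None) -> pd.DataFrame:
    """Attach Benjamini-Hochberg q-scores with denominator ``n_tests``.

    ``q_(i) = min_{j >= i}( p_(j) * n_tests / j )`` over the p-sorted
    occurrences, capped at 1.  ``n_tests`` defaults to the scan's recorded
    total of scanned positions.
    """
    if n_tests is None:
        n_tests = occ.attrs.get("n_tests")
    if n_tests is None:
        raise ValueError("n_tests not given and not recorded on the occurrence set")
    if n_tests < len(occ):
        raise ValueError("n_tests smaller than the number of occurrences")
    out = occ.copy()
    out.attrs.update(occ.attrs)
    if len(occ) == 0:
        out["q"] = pd.Series(dtype=float)
        return out
    p = occ["p"].to_numpy(float)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n_tests / np.arange(1, len(p) + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    out["q"] = q
    return out


def scan_with_qvalues(genome, matrix, bg, **kwargs) -> pd.DataFrame:
    """Convenience: :func:`scan` followed by :func:`compute_qvalues`."""
    occ = scan(genome, matrix, bg, **kwargs)
    return compute_qvalues(occ)


def write_occurrences_tsv(occ: pd.DataFrame, path, source: str = "recmotif") -> None:
    """GFF3-like TSV: chrom, source, motif, 1-based inclusive start/end,
    score, strand, p, q."""
    motif = occ.attrs.get("motif", ".")
    df = pd.DataFrame(
        {
            "chrom": occ["chrom"],
            "source": source,
            "motif": motif,
            "start": occ["start"] + 1,
            "end": occ["end"],
            "score": occ["score"],
            "strand": occ["strand"],
            "p": occ["p"],
            "q": occ.get("q", np.nan),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
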