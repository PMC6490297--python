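"""Enumerative discovery of repeat motifs enriched in high-recombining regions.

Every recombination-associated motif this analysis targets is a short tandem
repeat (poly-A/G tracts, CA/TA dinucleotide and GCA trinucleotide repeats),
so discovery enumerates all tandem-repeat candidates over 1-3 bp units,
counts their exact occurrences (both strands, overlaps allowed) in high- vs
low-recombining bins, and tests for excess in the high class with a
one-sided hypergeometric test on match vs non-match start positions.  The
reported E-value is the Bonferroni-style p times the number of candidates
examined.  This is an exact-count stand-in with the same contract as a
differential-enrichment motif search; it is not an EM-based PWM optimizer.

Discovered motifs from several species and smoothing scales are collapsed
into a consensus set: keep motifs significant (E <= 0.01) somewhere, reduce
matrices to their most likely base per position, group by canonical minimal
repeat unit up to rotation and reverse complement, and fix each group's
length to the longest representable in every contributing species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ._util import (
    BASES,
    canonical_unit_key,
    encode,
    minimal_repeat_unit,
    minimal_rotation,
    revcomp,
)
from .recmap import HIGH, LOW, RegionLabels

__all__ = [
    "MotifRecord",
    "EnrichmentResult",
    "ConsensusMotif",
    "enumerate_candidates",
    "differential_enrichment",
    "simplify_motif",
    "build_consensus_set",
]


@dataclass
class MotifRecord:
    """A discovered motif: species, smoothing scale, motif, significance."""

    species: str
    scale_kb: float
    motif: object  # consensus string or (L, 4) probability matrix
    E_value: float

    def consensus(self) -> str:
        if isinstance(self.motif, str):
            return self.motif.upper()
        return simplify_motif(np.asarray(self.motif))


@dataclass
class EnrichmentResult:
    """2x2 enrichment of one candidate in high- vs low-recombining bins."""

    candidate: str
    count_high: int
    count_low: int
    positions_high: int
    positions_low: int
    p_value: float
    E_value: float


@dataclass
class ConsensusMotif:
    """A collapsed cross-species repeat consensus, e.g. unit AC x 6."""

    id: str
    unit: str
    count: int
    string: str
    species: frozenset
    single_species: bool
    records: list = field(default_factory=list)

    @property
    def label(self) -> str:
        return f"[{self.unit}]{self.count}"


def enumerate_candidates(
    unit_lengths=(1, 2, 3), length_range=(8, 12)
) -> list[str]:
    """All tandem repeats ``unit^k`` with primitive units of the given sizes
    and total length inside ``length_range``, deduplicated by rotation and
    reverse complement of the unit.

    Candidates are emitted with the canonical (smallest-rotation, strand-
    canonical) unit, sorted by (unit length, unit, total length).
    """
    lo, hi = length_range
    out: list[str] = []
    seen: set[tuple[str, int]] = set()
    for ul in sorted(unit_lengths):
        for letters in product(BASES, repeat=ul):
            unit = "".join(letters)
            if len(minimal_repeat_unit(unit)) != ul:
                continue  # non-primitive unit, covered at a shorter unit length
            key = min(minimal_rotation(unit), minimal_rotation(revcomp(unit)))
            for k in range(max(1, -(-lo // ul)), hi // ul + 1):
                total = ul * k
                if not lo <= total <= hi:
                    continue
                if (key, total) in seen:
                    continue
                seen.add((key, total))
                out.append(key * k)
    return out


def _match_starts(codes: np.ndarray, cand: np.ndarray) -> np.ndarray:
    L = len(cand)
    npos = len(codes) - L + 1
    if npos <= 0:
        return np.empty(0, dtype=np.int64)
    hit = codes[:npos] == cand[0]
    for i in range(1, L):
        hit &= codes[i : i + npos] == cand[i]
    return np.flatnonzero(hit).astype(np.int64)


def differential_enrichment(
    genome: dict[str, str],
    labels: RegionLabels,
    candidates: list[str],
    n_candidates: int | None = None,
) -> list[EnrichmentResult]:
    """Exact-count differential enrichment of candidates in high vs low bins.

    Occurrence start positions on both strands (plus-strand matches of the
    candidate and of its reverse complement) are assigned to the bin holding
    them; the one-sided hypergeometric tail P(X >= count_high) on the 2x2
    table of (match, non-match) x (high, low) positions tests for excess in
    the high class.  ``E = p * n_candidates`` (default: the number of
    candidates supplied).  Results are sorted by E then candidate.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    n_cand = n_candidates if n_candidates is not None else len(candidates)
    bin_size = labels.bin_size
    encoded = {c: encode(s) for c, s in genome.items()}
    chrom_labels = {}
    for chrom in genome:
        if chrom not in labels.labels:
            raise ValueError(f"labels missing chromosome {chrom!r}")
        chrom_labels[chrom] = labels.labels[chrom]

    # per candidate length: scanned start positions per class (identical for
    # all candidates of that length)
    pos_per_class: dict[int, tuple[int, int]] = {}

    def class_positions(L: int) -> tuple[int, int]:
        if L not in pos_per_class:
            nh = nl = 0
            for chrom, codes in encoded.items():
                npos = len(codes) - L + 1
                if npos <= 0:
                    continue
                lab = chrom_labels[chrom][np.arange(npos) // bin_size]
                nh += int((lab == HIGH).sum())
                nl += int((lab == LOW).sum())
            pos_per_class[L] = (2 * nh, 2 * nl)  # both strands
        return pos_per_class[L]

    any_high = any((lab == HIGH).any() for lab in chrom_labels.values())
    any_low = any((lab == LOW).any() for lab in chrom_labels.values())
    if not any_high or not any_low:
        raise ValueError("degenerate split: empty high or low class")

    results = []
    for cand in candidates:
        cand = cand.upper()
        L = len(cand)
        kh = kl = 0
        for strand_seq in (cand, revcomp(cand)):
            cc = encode(strand_seq)
            for chrom, codes in encoded.items():
                starts = _match_starts(codes, cc)
                if len(starts) == 0:
                    continue
                lab = chrom_labels[chrom][starts // bin_size]
                kh += int((lab == HIGH).sum())
                kl += int((lab == LOW).sum())
        nh, nl = class_positions(L)
        M = nh + nl
        K = kh + kl
        p = float(hypergeom.sf(kh - 1, M, K, nh)) if M > 0 else 1.0
        p = min(max(p, np.finfo(float).tiny), 1.0)
        results.append(
            EnrichmentResult(
                candidate=cand,
                count_high=kh,
                count_low=kl,
                positions_high=nh,
                positions_low=nl,
                p_value=p,
                E_value=min(p * n_cand, float(n_cand)),
            )
        )
    results.sort(key=lambda r: (r.E_value, r.candidate))
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "candidate": r.candidate,
                "count_high": r.count_high,
                "count_low": r.count_low,
                "positions_high": r.positions_high,
                "positions_low": r.positions_low,
                "p": r.p_value,
                "E": r.E_value,
            }
            for r in results
        ]
    )


def simplify_motif(probs: np.ndarray) -> str:
    """Most likely base per column; ties broken alphabetically (A<C<G<T)."""
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] == 0:
        raise ValueError("expected an (L, 4) probability matrix")
    return "".join(BASES[i] for i in probs.argmax(axis=1))


def build_consensus_set(
    records: list[MotifRecord],
    species_list: list[str] | None = None,
    e_threshold: float = 0.01,
) -> list[ConsensusMotif]:
    """Collapse discovered motifs into a cross-species repeat consensus set.

    1. Keep motif strings reaching ``E <= e_threshold`` in at least one
       record (any scale, any species).
    2. Simplify matrices to their most-likely-base consensus.
    3. Group by canonical minimal repeat unit, up to rotation and reverse
       complement.
    4. Per group the consensus length is the minimum over contributing
       species of that species' maximum record length (the longest length
       representable in every species); single-species groups keep their
       species' maximum length and are flagged.
    5. Emit unit-repeat strings (length truncated to whole units).
    """
    if not records:
        raise ValueError("no motif records supplied")
    # E <= threshold anywhere for this exact consensus string
    best_e: dict[str, float] = {}
    for rec in records:
        s = rec.consensus()
        best_e[s] = min(best_e.get(s, np.inf), rec.E_value)
    kept = [rec for rec in records if best_e[rec.consensus()] <= e_threshold]
    groups: dict[str, list[MotifRecord]] = {}
    for rec in kept:
        groups.setdefault(canonical_unit_key(rec.consensus()), []).append(rec)
    out = []
    for idx, unit in enumerate(sorted(groups), start=1):
        recs = groups[unit]
        by_species: dict[str, int] = {}
        for rec in recs:
            s = rec.consensus()
            by_species[rec.species] = max(by_species.get(rec.species, 0), len(s))
        length = min(by_species.values())
        count = max(1, length // len(unit))
        species = frozenset(by_species)
        out.append(
            ConsensusMotif(
                id=f"C{idx}",
                unit=unit,
                count=count,
                string=unit * count,
                species=species,
                single_species=len(species) == 1,
                records=recs,
            )
        )
    return out
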