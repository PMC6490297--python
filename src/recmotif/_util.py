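"""Sequence codecs and repeat-motif notation helpers shared across modules."""

from __future__ import annotations

import re

import numpy as np

BASES = "ACGT"
N_CODE = 4  # anything that is not an unambiguous base

_ENCODE_LUT = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i

_DECODE_LUT = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


def decode(codes: np.ndarray) -> str:
    """uint8 codes -> uppercase DNA string."""
    return _DECODE_LUT[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


_BRACKET_RE = re.compile(r"^\[([ACGTacgt]+)\](\d+)$")


def parse_motif(text: str) -> str:
    """Expand bracketed repeat shorthand, e.g. ``[CA]6`` -> ``CACACACACACA``.

    Plain unambiguous DNA strings pass through unchanged (uppercased).
    """
    text = text.strip()
    m = _BRACKET_RE.match(text)
    if m:
        unit, count = m.group(1).upper(), int(m.group(2))
        if count < 1:
            raise ValueError(f"repeat count must be >= 1 in {text!r}")
        return unit * count
    seq = text.upper()
    if not seq or any(b not in BASES for b in seq):
        raise ValueError(f"not a valid motif string: {text!r}")
    return seq


def minimal_rotation(s: str) -> str:
    """Lexicographically smallest rotation of ``s`` (Booth by brute force: s is short)."""
    return min(s[i:] + s[:i] for i in range(len(s)))


def minimal_repeat_unit(s: str) -> str:
    """Canonical minimal repeat unit of ``s``.

    The shortest ``u`` such that ``s`` is a prefix of ``u`` repeated, returned as
    the lexicographically smallest rotation of ``u``; e.g. ``CACACA`` -> ``AC``.
    """
    if not s:
        raise ValueError("empty string has no repeat unit")
    n = len(s)
    for p in range(1, n + 1):
        unit = s[:p]
        reps = -(-n // p)  # ceil
        if (unit * reps)[:n] == s:
            return minimal_rotation(unit)
    raise AssertionError("unreachable")  # p == n always matches


def canonical_unit_key(s: str) -> str:
    """Grouping key for a repeat motif: minimal unit, canonical up to rotation
    and reverse complement (``CACA...`` and ``GTGT...`` share the key ``AC``)."""
    unit = minimal_repeat_unit(s)
    rc = minimal_rotation(revcomp(unit))
    return min(unit, rc)


def format_motif(s: str) -> str:
    """Bracketed repeat notation for a string, e.g. ``CACACACACACA`` -> ``[AC]6``.

    The unit shown is the canonical minimal rotation; strings that are not a
    whole number of unit repeats fall back to the plain sequence.
    """
    unit = minimal_repeat_unit(s)
    if len(s) % len(unit) == 0:
        return f"[{unit}]{len(s) // len(unit)}"
    return s
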