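"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's normalization/classification code
paths: equivalence is decided by editing the reference sequence and
comparing the resulting haplotype strings.
"""

from __future__ import annotations

import math

from itckit.variant_model import Variant


def edit(seq: str, pos: int, ref: str, alt: str) -> str:
    """Apply a 1-based substitution to a sequence, asserting REF consistency."""
    assert seq[pos - 1 : pos - 1 + len(ref)] == ref, "oracle: REF mismatch"
    return seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]


def same_haplotype(seq: str, a: Variant, b: Variant) -> bool:
    return edit(seq, a.pos, a.ref, a.alt) == edit(seq, b.pos, b.ref, b.alt)


def enumerate_equivalents(seq: str, v: Variant, window: int = 50) -> list[Variant]:
    """All minimal anchored representations of ``v`` within +/- ``window`` bp.

    For each candidate position the REF/ALT pair is reconstructed directly
    from the edited haplotype, then validated by re-editing; nothing is
    shared with the left-alignment loop under test.
    """
    target = edit(seq, v.pos, v.ref, v.alt)
    delta = len(v.alt) - len(v.ref)
    out = []
    lo = max(1, v.pos - window)
    hi = min(len(seq), v.pos + window)
    for p in range(lo, hi + 1):
        if delta > 0:  # insertion of delta bases after the anchor at p
            ref = seq[p - 1]
            alt = target[p - 1 : p + delta]
            if len(alt) != delta + 1 or alt[0] != ref:
                continue
        elif delta < 0:  # deletion of -delta bases after the anchor at p
            ref = seq[p - 1 : p - delta]
            alt = seq[p - 1]
            if len(ref) != 1 - delta:
                continue
        else:
            continue
        if ref == alt:
            continue
        try:
            cand = Variant(v.chrom, p, ref, alt)
        except ValueError:
            continue
        try:
            if edit(seq, cand.pos, cand.ref, cand.alt) == target:
                out.append(cand)
        except AssertionError:
            continue
    return out


def leftmost_equivalent(seq: str, v: Variant, window: int = 50) -> Variant:
    """The canonical (leftmost minimal) representation by exhaustive search."""
    equivalents = enumerate_equivalents(seq, v, window)
    assert equivalents, f"oracle found no representation for {v}"
    return min(equivalents, key=lambda x: x.pos)


def per_base_set(intervals: list[tuple[str, int, int]]) -> set[tuple[str, int]]:
    """Brute-force expansion of BED intervals into (chrom, base) points."""
    return {(c, i) for c, s, e in intervals for i in range(s, e)}


def binom_tail(n: int, p: float, k: int) -> float:
    """P(X >= k) for X ~ Binomial(n, p), by direct summation."""
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))
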