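"""Set algebra over call sets: per-caller intersection across aligners,
union across callers, and overlap/partition statistics."""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .caller_io import CallRecord, CallSet


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (``round()`` is banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class OverlapStats:
    """Two-set overlap with pairwise-unique percentages.

    Percentages are unique/(unique + shared) * 100, i.e. each side's unique
    calls as a share of that side's intersection-inclusive total, reported to
    one decimal (half-up); 0.0 when the denominator is 0.
    """

    a_only: int
    shared: int
    b_only: int

    @property
    def pct_a_only(self) -> float:
        return _unique_pct(self.a_only, self.shared)

    @property
    def pct_b_only(self) -> float:
        return _unique_pct(self.b_only, self.shared)


def _unique_pct(unique: int, shared: int) -> float:
    denom = unique + shared
    if denom == 0:
        return 0.0
    return round_half_up(100.0 * unique / denom, 1)


def unique_fraction_pct(unique: int, shared: int) -> float:
    """Unrounded unique/(unique+shared) percentage (0 when denominator is 0)."""
    denom = unique + shared
    return 100.0 * unique / denom if denom else 0.0


@dataclass(frozen=True)
class ThreeWayPartition:
    """Partition of a union into first-only / both / second-only counts."""

    first_only: int
    shared: int
    second_only: int

    @property
    def total(self) -> int:
        return self.first_only + self.shared + self.second_only


def _check_vclass(a: CallSet, b: CallSet) -> None:
    if a.vclass != b.vclass and "MIXED" not in (a.vclass, b.vclass):
        raise ValueError(f"variant-class mismatch: {a.vclass} vs {b.vclass}")


def _merge_provenance(first: CallRecord, second: CallRecord) -> CallRecord:
    return replace(first, provenance=first.provenance | second.provenance)


def intersect_callsets(a: CallSet, b: CallSet) -> CallSet:
    """Records keyed in both sets; body from ``a``, provenance merged.

    Commutative in key set; the first operand determines the surviving
    representation and depths, so pass operands in a deterministic order.
    """
    _check_vclass(a, b)
    records = {
        k: _merge_provenance(a.records[k], b.records[k])
        for k in a.records.keys() & b.records.keys()
    }
    return CallSet(
        records=records,
        caller=a.caller if a.caller == b.caller else "merged",
        aligner=f"{a.aligner}&{b.aligner}" if a.aligner != b.aligner else a.aligner,
        sample=a.sample,
        vclass=a.vclass,
    )


def union_callsets(sets: Sequence[CallSet], allow_mixed: bool = False) -> CallSet:
    """Union keyed by variant; first occurrence wins the body, provenance merged.

    Inputs must share a variant class unless ``allow_mixed`` is set (used when
    merging a caller's separate SNV and indel files into one product).
    """
    if not sets:
        raise ValueError("union of zero call sets")
    vclasses = {s.vclass for s in sets}
    if len(vclasses) > 1 and "MIXED" not in vclasses and not allow_mixed:
        raise ValueError(f"variant-class mismatch in union: {sorted(vclasses)}")
    records: dict[tuple, CallRecord] = {}
    for s in sets:
        for k, rec in s.records.items():
            records[k] = _merge_provenance(records[k], rec) if k in records else rec
    callers = {s.caller for s in sets}
    aligners = {s.aligner for s in sets}
    return CallSet(
        records=records,
        caller=callers.pop() if len(callers) == 1 else "merged",
        aligner=aligners.pop() if len(aligners) == 1 else "merged",
        sample=sets[0].sample,
        vclass=next(iter(vclasses)) if len(vclasses) == 1 else "MIXED",
    )


def itc(calls: Mapping[str, Mapping[str, CallSet]]) -> CallSet:
    """Intersect-then-combine: per caller, intersect across its two aligners;
    then union the per-caller intersections.

    ``calls`` maps caller -> aligner -> CallSet; every caller must carry the
    same two aligner labels. Aligners are intersected in lexicographic order
    so output bodies are deterministic.
    """
    if not calls:
        raise ValueError("no callers supplied")
    aligner_sets = {frozenset(m) for m in calls.values()}
    if len(aligner_sets) != 1:
        raise ValueError(
            f"aligner labels differ across callers: {[sorted(s) for s in aligner_sets]}"
        )
    aligners = sorted(aligner_sets.pop())
    if len(aligners) != 2:
        raise ValueError(f"exactly two aligners required, got {aligners}")
    per_caller = [
        intersect_callsets(calls[caller][aligners[0]], calls[caller][aligners[1]])
        for caller in sorted(calls)
    ]
    return union_callsets(per_caller)


def overlap_stats(a: CallSet, b: CallSet) -> OverlapStats:
    _check_vclass(a, b)
    ka, kb = a.keys(), b.keys()
    shared = len(ka & kb)
    return OverlapStats(a_only=len(ka) - shared, shared=shared, b_only=len(kb) - shared)


def three_way(first: CallSet, second: CallSet) -> ThreeWayPartition:
    _check_vclass(first, second)
    ka, kb = first.keys(), second.keys()
    shared = len(ka & kb)
    return ThreeWayPartition(
        first_only=len(ka) - shared, shared=shared, second_only=len(kb) - shared
    )
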