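"""Caller-specific admission rules: default and optimized filtering policies.

The optimized policy relaxes Mutect2's internal alt-allele-in-normal
criterion, replacing it with a normal-VAF bound (<= 7%) combined with a
tumour/normal VAF-ratio requirement (> 5), and moves the Strelka score
thresholds up (QSS_NT > 25, QSI_NT > 35) while admitting tier-2-supported
calls.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace

from .caller_io import MUTECT2, STRELKA, CallRecord, CallSet, vaf

logger = logging.getLogger(__name__)

#: Mutect2 (GATK 3.5) internal filter vocabulary, used to sanity-check
#: rescue_filters configuration.
KNOWN_MUTECT2_FILTERS = frozenset(
    {
        "alt_allele_in_normal",
        "clustered_events",
        "germline_risk",
        "homologous_mapping_event",
        "multi_event_alt_allele_in_normal",
        "panel_of_normals",
        "str_contraction",
        "t_lod_fstar",
        "triallelic_site",
    }
)

ALT_IN_NORMAL = "alt_allele_in_normal"


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds for one admission pass.

    ``mode='default'`` reproduces the callers' recommended criteria (plus the
    clustered-events/homologous-mapping rescue for Mutect2);
    ``mode='optimized'`` applies the relaxed normal-allele bound with the T/N
    ratio for Mutect2 and the raised, tier-2-inclusive Strelka thresholds.
    """

    mode: str = "default"  # 'default' | 'optimized'
    max_normal_af: float = 0.07
    min_tn_ratio: float = 5.0
    qss_nt_min: float = 15.0
    qsi_nt_min: float = 30.0
    tlod_min: float = 6.3
    rescue_filters: frozenset[str] = frozenset(
        {"clustered_events", "homologous_mapping_event"}
    )
    include_tier2: bool = False
    tn_ratio_on_pass: bool = True  # apply the T/N rule to PASS records too
    proximity_window: int | None = None
    proximity_min_neighbours: int = 2

    def __post_init__(self) -> None:
        if self.mode not in ("default", "optimized"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in ("max_normal_af", "min_tn_ratio", "qss_nt_min", "qsi_nt_min", "tlod_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        unknown = self.rescue_filters - KNOWN_MUTECT2_FILTERS
        if unknown:
            logger.warning("rescue filters not in the known Mutect2 vocabulary: %s", sorted(unknown))

    @classmethod
    def default(cls) -> "FilterPolicy":
        return cls(mode="default")

    @classmethod
    def optimized(cls) -> "FilterPolicy":
        return cls(mode="optimized", qss_nt_min=25.0, qsi_nt_min=35.0, include_tier2=True)

    @classmethod
    def named(cls, name: str, **overrides) -> "FilterPolicy":
        base = cls.optimized() if name == "optimized" else cls.default()
        return replace(base, **overrides) if overrides else base


def tn_ratio(t_vaf: float, n_vaf: float) -> float:
    """Tumour VAF over normal VAF; +inf when only the tumour has signal, 0 when neither."""
    if t_vaf == 0:
        return 0.0
    if n_vaf == 0:
        return math.inf
    return t_vaf / n_vaf


def _require_caller(rec: CallRecord, caller: str) -> None:
    if rec.caller != caller:
        raise ValueError(f"expected a {caller} record, got {rec.caller} at {rec.variant}")


def mutect2_admit_default(rec: CallRecord, policy: FilterPolicy) -> bool:
    """PASS records, plus records failing only rescued filters."""
    _require_caller(rec, MUTECT2)
    return not (rec.filters - policy.rescue_filters)


def mutect2_admit_optimized(rec: CallRecord, policy: FilterPolicy) -> bool:
    """Relaxed normal-allele rule: admit iff non-rescued filters other than
    ``alt_allele_in_normal`` are absent, normal VAF <= ``max_normal_af``,
    T/N ratio > ``min_tn_ratio``, and TLOD (when present) >= ``tlod_min``."""
    _require_caller(rec, MUTECT2)
    blocking = rec.filters - policy.rescue_filters - {ALT_IN_NORMAL}
    if blocking:
        return False
    n_vaf = vaf(rec, "normal")
    if n_vaf > policy.max_normal_af:
        return False
    if policy.tn_ratio_on_pass or ALT_IN_NORMAL in rec.filters:
        if tn_ratio(vaf(rec, "tumour"), n_vaf) <= policy.min_tn_ratio:
            return False
    if rec.qual_score is not None and rec.qual_score < policy.tlod_min:
        return False
    return True


def _strelka_threshold(rec: CallRecord, policy: FilterPolicy) -> float:
    return policy.qss_nt_min if rec.variant.vtype == "SNV" else policy.qsi_nt_min


def strelka_admit(rec: CallRecord, policy: FilterPolicy) -> bool:
    """Default mode: PASS + tier-1 alt support + score above threshold.
    Optimized mode: score above the raised threshold with tier-1 support, or
    tier-2 support when ``include_tier2`` is set (internal filters waived, as
    tier-2 calls are by definition those failing tier-1 filtration)."""
    _require_caller(rec, STRELKA)
    if rec.tier_counts is None:
        raise ValueError(f"strelka record without tier counts at {rec.variant}")
    threshold = _strelka_threshold(rec, policy)
    tier1_alt = rec.tier_counts["tumour"][1][0]
    if rec.qual_score is None or rec.qual_score <= threshold:
        return False
    if policy.mode == "default":
        return rec.is_pass and tier1_alt > 0
    tier2_alt = rec.tier_counts["tumour"][2][0]
    return tier1_alt > 0 or (policy.include_tier2 and tier2_alt > 0)


def admit(rec: CallRecord, policy: FilterPolicy) -> bool:
    if rec.caller == MUTECT2:
        if policy.mode == "optimized":
            return mutect2_admit_optimized(rec, policy)
        return mutect2_admit_default(rec, policy)
    if rec.caller == STRELKA:
        return strelka_admit(rec, policy)
    raise ValueError(f"unknown caller {rec.caller!r}")


def apply_policy(cs: CallSet, policy: FilterPolicy) -> CallSet:
    """Admit a subset of ``cs`` under ``policy``; the input is never mutated."""
    callers = {r.caller for r in cs}
    if len(callers) > 1:
        raise ValueError(f"apply_policy requires a single-caller CallSet, got {sorted(callers)}")
    admitted = {}
    for key, rec in cs.records.items():
        ok = admit(rec, policy)
        logger.debug("%s %s under %s policy", "admit" if ok else "reject", rec.variant, policy.mode)
        if ok:
            admitted[key] = rec
    out = CallSet(
        records=admitted,
        caller=cs.caller,
        aligner=cs.aligner,
        sample=cs.sample,
        vclass=cs.vclass,
    )
    logger.info(
        "policy %s: admitted %d/%d records (%s/%s)",
        policy.mode, len(out), len(cs), cs.caller, cs.aligner,
    )
    if policy.proximity_window:
        out = proximity_filter(out, policy.proximity_window, policy.proximity_min_neighbours)
    return out


def proximity_filter(cs: CallSet, window: int, min_neighbours: int = 2) -> CallSet:
    """Drop records with >= ``min_neighbours`` other calls within +/- ``window`` bp."""
    if window <= 0:
        raise ValueError("window must be positive")
    by_chrom: dict[str, list[int]] = {}
    for rec in cs:
        by_chrom.setdefault(rec.variant.chrom, []).append(rec.variant.pos)
    for positions in by_chrom.values():
        positions.sort()
    kept = {}
    for key, rec in cs.records.items():
        positions = by_chrom[rec.variant.chrom]
        lo = bisect_left(positions, rec.variant.pos - window)
        hi = bisect_right(positions, rec.variant.pos + window)
        neighbours = (hi - lo) - 1  # exclude the record itself
        if neighbours < min_neighbours:
            kept[key] = rec
    return CallSet(records=kept, caller=cs.caller, aligner=cs.aligner, sample=cs.sample, vclass=cs.vclass)
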