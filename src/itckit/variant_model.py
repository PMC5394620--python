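"""Core variant and interval types, representation normalization, region algebra.

Coordinate conventions: variants are 1-based (VCF), intervals are 0-based
half-open (BED). Conversions happen only at I/O boundaries.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")

#: ``ref_lookup(chrom, start0, end0) -> str`` over 0-based half-open coordinates.
RefLookup = Callable[[str, int, int], str]


class ReferenceMismatchError(ValueError):
    """The variant's REF allele disagrees with the reference sequence."""


class UnknownChromosomeError(KeyError):
    """Chromosome not present in the supplied reference."""


@dataclass(frozen=True, order=True)
class Variant:
    """A biallelic genomic change; the unit of matching across call sets.

    ``pos`` is the 1-based position of the first REF base. ``vtype`` is
    derived: SNV for 1->1 substitutions, INS/DEL for pure length changes,
    MNV otherwise.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError(f"empty allele in {self.chrom}:{self.pos} {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos} ({self.ref})")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _VALID_BASES:
                raise ValueError(f"non-ACGTN allele {allele!r} at {self.chrom}:{self.pos}")

    @property
    def vtype(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        if len(self.ref) < len(self.alt) and self.alt.startswith(self.ref):
            return "INS"
        if len(self.ref) > len(self.alt) and self.ref.startswith(self.alt):
            return "DEL"
        return "MNV"

    @property
    def is_indel(self) -> bool:
        return self.vtype in ("INS", "DEL", "MNV") and len(self.ref) != len(self.alt)

    @property
    def end(self) -> int:
        """1-based inclusive end of the REF footprint."""
        return self.pos + len(self.ref) - 1

    def __str__(self) -> str:  # pragma: no cover - repr aid
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def variant_key(v: Variant) -> tuple[str, int, str, str]:
    """Hashable identity for matching: equal iff (chrom, pos, ref, alt) equal."""
    return (v.chrom, v.pos, v.ref, v.alt)


def make_ref_lookup(reference: Mapping[str, str] | object) -> RefLookup:
    """Adapt a chrom->sequence mapping or a pyfaidx.Fasta to the lookup signature."""
    if isinstance(reference, Mapping):
        seqs = reference

        def lookup(chrom: str, start0: int, end0: int) -> str:
            if chrom not in seqs:
                raise UnknownChromosomeError(chrom)
            return str(seqs[chrom][start0:end0]).upper()

        return lookup

    def lookup(chrom: str, start0: int, end0: int) -> str:
        try:
            rec = reference[chrom]  # type: ignore[index]
        except KeyError as exc:
            raise UnknownChromosomeError(chrom) from exc
        return str(rec[start0:end0]).upper()

    return lookup


def apply_variant(seq: str, v: Variant) -> str:
    """Apply ``v`` to a chromosome sequence, checking REF consistency.

    The independent haplotype-equality oracle for normalization is built on
    this: two representations are equivalent iff the edited sequences match.
    """
    i = v.pos - 1
    observed = seq[i : i + len(v.ref)].upper()
    if observed != v.ref:
        raise ReferenceMismatchError(
            f"{v}: reference has {observed!r}, variant claims {v.ref!r}"
        )
    return seq[:i] + v.alt + seq[i + len(v.ref) :]


def trim_variant(v: Variant) -> Variant:
    """Remove shared suffix, then shared prefix bases (keeping >=1 base per allele)."""
    pos, ref, alt = v.pos, v.ref, v.alt
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:
        raise ValueError(f"{v} trims to a non-variant")
    return Variant(v.chrom, pos, ref, alt)


def normalize_variant(v: Variant, ref_lookup: RefLookup | None) -> Variant:
    """Left-align and trim to the canonical minimal representation.

    The classic left-alignment loop: while REF and ALT end in the same base,
    either trim that base (both alleles longer than 1 bp) or extend both
    alleles one reference base to the left; finally trim the shared prefix
    beyond the anchor. Editing the reference with the input and with the
    output yields the same haplotype, and the operation is idempotent.

    With ``ref_lookup=None`` only trimming is performed (exact-match
    semantics); a warning is logged once per process.
    """
    if ref_lookup is None:
        _warn_no_reference()
        return trim_variant(v)

    pos, ref, alt = v.pos, v.ref.upper(), v.alt.upper()
    observed = ref_lookup(v.chrom, pos - 1, pos - 1 + len(ref))
    if observed != ref:
        raise ReferenceMismatchError(
            f"{v}: reference has {observed!r}, variant claims {ref!r}"
        )

    changed = True
    while changed:
        changed = False
        if ref[-1] == alt[-1]:
            if len(ref) > 1 and len(alt) > 1:
                ref, alt = ref[:-1], alt[:-1]
                changed = True
            elif pos > 1:
                prev = ref_lookup(v.chrom, pos - 2, pos - 1)
                ref, alt = prev + ref[:-1], prev + alt[:-1]
                pos -= 1
                changed = True
        if len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
            changed = True

    return Variant(v.chrom, pos, ref, alt)


_no_ref_warned = False


def _warn_no_reference() -> None:
    global _no_ref_warned
    if not _no_ref_warned:
        logger.warning(
            "no reference FASTA supplied: variant matching degrades to "
            "exact (chrom, pos, ref, alt) equality after trimming"
        )
        _no_ref_warned = True


def shift_right_once(v: Variant, ref_lookup: RefLookup) -> Variant | None:
    """One right-shift of a minimal anchored insertion or deletion.

    Returns the equivalent representation one base to the right, or None when
    the flanking reference base does not permit a shift. Inverse of one step
    of the left-alignment loop; haplotype-preserving by construction.
    """
    if v.vtype == "INS":
        seq = v.alt[1:]
        nxt = ref_lookup(v.chrom, v.pos, v.pos + 1)
        if not nxt or nxt != seq[0]:
            return None
        rotated = seq[1:] + seq[0]
        return Variant(v.chrom, v.pos + 1, nxt, nxt + rotated)
    if v.vtype == "DEL":
        seq = v.ref[1:]
        nxt = ref_lookup(v.chrom, v.pos + len(seq), v.pos + len(seq) + 1)
        if not nxt or nxt != seq[0]:
            return None
        new_tail = ref_lookup(v.chrom, v.pos + 1, v.pos + 1 + len(seq))
        return Variant(v.chrom, v.pos + 1, seq[0] + new_tail, seq[0])
    return None


def decompose_multiallelic(
    chrom: str, pos: int, ref: str, alts: Sequence[str]
) -> list[Variant]:
    """Split a multiallelic VCF record into biallelic ``Variant`` objects.

    Each alt becomes one trimmed biallelic variant; callers may instead
    elect to drop multiallelic records entirely (the benchmark truth loader
    does).
    """
    if not alts:
        raise ValueError(f"no alternate alleles at {chrom}:{pos}")
    return [trim_variant(Variant(chrom, pos, ref, alt)) for alt in alts]


# ---------------------------------------------------------------------------
# Region algebra (BED convention: 0-based half-open)
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} (start >= end)"
            )
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class RegionSet:
    """Merged, sorted intervals per chromosome plus the total footprint."""

    _by_chrom: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def total_bp(self) -> int:
        return sum(e - s for ivs in self._by_chrom.values() for s, e in ivs)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(c, s, e)
            for c in sorted(self._by_chrom)
            for s, e in self._by_chrom[c]
        ]

    def __contains__(self, item: tuple[str, int]) -> bool:
        chrom, pos = item
        return point_in_regions(self, chrom, pos)

    def __bool__(self) -> bool:
        return any(self._by_chrom.values())


def build_region_set(intervals: Iterable[GenomicInterval | tuple]) -> RegionSet:
    """Merge raw intervals into a canonical ``RegionSet`` (abutting runs join)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        if not isinstance(iv, GenomicInterval):
            iv = GenomicInterval(*iv)
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out: list[tuple[int, int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[chrom] = out
    return RegionSet(merged)


def intersect_regions(a: RegionSet, b: RegionSet) -> RegionSet:
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom in set(a._by_chrom) & set(b._by_chrom):
        xs, ys = a._by_chrom[chrom], b._by_chrom[chrom]
        i = j = 0
        ivs: list[tuple[int, int]] = []
        while i < len(xs) and j < len(ys):
            s = max(xs[i][0], ys[j][0])
            e = min(xs[i][1], ys[j][1])
            if s < e:
                ivs.append((s, e))
            if xs[i][1] < ys[j][1]:
                i += 1
            else:
                j += 1
        if ivs:
            out[chrom] = ivs
    return RegionSet(out)


def subtract_regions(a: RegionSet, b: RegionSet) -> RegionSet:
    """a minus b, interval arithmetic per chromosome."""
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, xs in a._by_chrom.items():
        ys = b._by_chrom.get(chrom, [])
        ivs: list[tuple[int, int]] = []
        j = 0
        for s, e in xs:
            cur = s
            while j < len(ys) and ys[j][1] <= cur:
                j += 1
            k = j
            while k < len(ys) and ys[k][0] < e:
                bs, be = ys[k]
                if bs > cur:
                    ivs.append((cur, bs))
                cur = max(cur, be)
                if be >= e:
                    break
                k += 1
            if cur < e:
                ivs.append((cur, e))
        if ivs:
            out[chrom] = ivs
    return RegionSet(out)


def subtract_loci(a: RegionSet, loci: Iterable[Variant]) -> RegionSet:
    """Remove the reference-spanning footprint of each variant from ``a``."""
    spans = [
        GenomicInterval(v.chrom, v.pos - 1, v.pos - 1 + len(v.ref)) for v in loci
    ]
    if not spans:
        return build_region_set(a.intervals())
    return subtract_regions(a, build_region_set(spans))


def point_in_regions(r: RegionSet, chrom: str, pos: int) -> bool:
    """Membership of a 1-based position in the region set."""
    ivs = r._by_chrom.get(chrom)
    if not ivs:
        return False
    p0 = pos - 1
    i = bisect_right(ivs, (p0, float("inf"))) - 1
    return i >= 0 and ivs[i][0] <= p0 < ivs[i][1]


def read_bed(path: str) -> RegionSet:
    """Load a 3+ column BED file into a merged RegionSet."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            intervals.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return build_region_set(intervals)


def write_bed(r: RegionSet, path: str) -> None:
    with open(path, "w") as fh:
        for iv in r.intervals():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
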