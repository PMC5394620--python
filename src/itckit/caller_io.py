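"""Read/write the two supported somatic-caller VCF dialects and compute VAFs.

Supported dialects: Mutect2 as bundled with GATK 3.5 (tumour-normal mode,
per-sample AD counts, TLOD in INFO) and Strelka v1 somatic output (separate
SNV and indel files with tiered counts: AU/CU/GU/TU for SNVs, TAR/TIR for
indels, QSS_NT / QSI_NT scores in INFO).

Parsing is backed by :mod:`pysam`; writing is plain deterministic VCF 4.2
text so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional

import pysam

from .variant_model import Variant, trim_variant, variant_key

logger = logging.getLogger(__name__)

MUTECT2 = "mutect2"
STRELKA = "strelka"

Sample = Literal["tumour", "normal"]

#: tier -> (alt_count, depth) per sample
TierCounts = dict[str, dict[int, tuple[int, int]]]


class DialectError(ValueError):
    """Input VCF does not match the expected caller dialect."""


@dataclass(frozen=True)
class CallRecord:
    """One biallelic call with caller/aligner provenance and read support."""

    variant: Variant
    caller: str
    aligner: str
    filters: frozenset[str] = frozenset()
    tumour_depth: int = 0
    tumour_alt: int = 0
    normal_depth: int = 0
    normal_alt: int = 0
    qual_score: Optional[float] = None
    tier_counts: Optional[TierCounts] = None
    provenance: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        if not (0 <= self.tumour_alt <= self.tumour_depth):
            raise ValueError(
                f"tumour alt {self.tumour_alt} outside depth {self.tumour_depth} at {self.variant}"
            )
        if not (0 <= self.normal_alt <= self.normal_depth):
            raise ValueError(
                f"normal alt {self.normal_alt} outside depth {self.normal_depth} at {self.variant}"
            )
        if not self.provenance:
            object.__setattr__(
                self, "provenance", frozenset({(self.caller, self.aligner)})
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return variant_key(self.variant)

    @property
    def is_pass(self) -> bool:
        return not self.filters


@dataclass
class CallSet:
    """Keyed collection of records from one (caller, aligner) or a merged product."""

    records: dict[tuple, CallRecord] = field(default_factory=dict)
    caller: str = ""
    aligner: str = ""
    sample: str = ""
    vclass: str = "MIXED"  # SNV | INDEL | MIXED

    def add(self, rec: CallRecord) -> None:
        if rec.key in self.records:
            raise ValueError(f"duplicate record key {rec.key}")
        self.records[rec.key] = rec

    def keys(self) -> set[tuple]:
        return set(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def __contains__(self, key: tuple) -> bool:
        return key in self.records

    def sorted_records(self) -> list[CallRecord]:
        return [self.records[k] for k in sorted(self.records)]

    def subset(self, keys: Iterable[tuple]) -> "CallSet":
        keep = set(keys)
        return CallSet(
            records={k: r for k, r in self.records.items() if k in keep},
            caller=self.caller,
            aligner=self.aligner,
            sample=self.sample,
            vclass=self.vclass,
        )


def _vclass_of(variants: Iterable[Variant]) -> str:
    kinds = {"SNV" if v.vtype == "SNV" else "INDEL" for v in variants}
    if len(kinds) == 1:
        return kinds.pop()
    return "MIXED"


def _info_get(rec: "pysam.VariantRecord", key: str):
    # pysam raises ValueError for keys absent from the header
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def _format_get(fmt, key: str):
    try:
        return fmt.get(key)
    except (KeyError, ValueError):
        return None


def _filters_of(rec: "pysam.VariantRecord") -> frozenset[str]:
    names = set(rec.filter.keys())
    if not names:
        logger.warning("record %s:%s has '.' FILTER; treating as unfiltered", rec.chrom, rec.pos)
        return frozenset()
    names.discard("PASS")
    return frozenset(names)


def read_mutect2(path: str, tumour_label: str, normal_label: str, aligner: str = "") -> CallSet:
    """Load a Mutect2 (GATK 3.5 dialect) tumour-normal VCF.

    Samples are located by header name; multiallelic records are decomposed
    into one :class:`CallRecord` per alt allele with that allele's AD count.
    """
    cs = CallSet(caller=MUTECT2, aligner=aligner, sample=tumour_label)
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        for label in (tumour_label, normal_label):
            if label not in samples:
                raise DialectError(
                    f"sample {label!r} not in VCF header (has {samples}); "
                    "mutect2 samples are matched by name, not position"
                )
        for rec in vcf:
            filters = _filters_of(rec)
            tlod = _info_get(rec, "TLOD")
            if isinstance(tlod, tuple):
                tlod = tlod[0]
            t_ad = _format_get(rec.samples[tumour_label], "AD")
            n_ad = _format_get(rec.samples[normal_label], "AD")
            if t_ad is None or n_ad is None:
                raise DialectError(f"missing AD at {rec.chrom}:{rec.pos}")
            for ai, alt in enumerate(rec.alts or (), start=1):
                v = trim_variant(Variant(rec.chrom, rec.pos, rec.ref, alt))
                cs.add(
                    CallRecord(
                        variant=v,
                        caller=MUTECT2,
                        aligner=aligner,
                        filters=filters,
                        tumour_depth=int(sum(x for x in t_ad if x is not None)),
                        tumour_alt=int(t_ad[ai] or 0),
                        normal_depth=int(sum(x for x in n_ad if x is not None)),
                        normal_alt=int(n_ad[ai] or 0),
                        qual_score=float(tlod) if tlod is not None else None,
                    )
                )
    cs.vclass = _vclass_of(r.variant for r in cs)
    return cs


_SNV_TIER_FIELDS = {"A": "AU", "C": "CU", "G": "GU", "T": "TU"}


def read_strelka_snv(path: str, aligner: str = "") -> CallSet:
    """Load a Strelka v1 somatic SNV VCF with tiered per-base counts."""
    cs = CallSet(caller=STRELKA, aligner=aligner, vclass="SNV")
    with pysam.VariantFile(path) as vcf:
        _require_samples(vcf, path)
        for rec in vcf:
            qss_nt = _info_get(rec, "QSS_NT")
            if qss_nt is None:
                raise DialectError(f"missing QSS_NT at {rec.chrom}:{rec.pos}; not a Strelka v1 SNV file")
            filters = _filters_of(rec)
            for alt in rec.alts or ():
                if alt not in _SNV_TIER_FIELDS:
                    raise DialectError(f"non-SNV alt {alt!r} in Strelka SNV file at {rec.chrom}:{rec.pos}")
                tiers: TierCounts = {}
                for role, sm in (("tumour", "TUMOR"), ("normal", "NORMAL")):
                    fmt = rec.samples[sm]
                    per_base = {}
                    for base, tag in _SNV_TIER_FIELDS.items():
                        counts = _format_get(fmt, tag)
                        if counts is None:
                            raise DialectError(f"missing {tag} at {rec.chrom}:{rec.pos}")
                        per_base[base] = counts
                    tiers[role] = {
                        t: (
                            int(per_base[alt][t - 1]),
                            int(sum(per_base[b][t - 1] for b in "ACGT")),
                        )
                        for t in (1, 2)
                    }
                t1_t, t1_n = tiers["tumour"][1], tiers["normal"][1]
                cs.add(
                    CallRecord(
                        variant=trim_variant(Variant(rec.chrom, rec.pos, rec.ref, alt)),
                        caller=STRELKA,
                        aligner=aligner,
                        filters=filters,
                        tumour_alt=t1_t[0],
                        tumour_depth=t1_t[1],
                        normal_alt=t1_n[0],
                        normal_depth=t1_n[1],
                        qual_score=float(qss_nt),
                        tier_counts=tiers,
                    )
                )
    return cs


def read_strelka_indel(path: str, aligner: str = "") -> CallSet:
    """Load a Strelka v1 somatic indel VCF (TAR/TIR tiered counts, QSI_NT)."""
    cs = CallSet(caller=STRELKA, aligner=aligner, vclass="INDEL")
    with pysam.VariantFile(path) as vcf:
        _require_samples(vcf, path)
        for rec in vcf:
            qsi_nt = _info_get(rec, "QSI_NT")
            if qsi_nt is None:
                raise DialectError(f"missing QSI_NT at {rec.chrom}:{rec.pos}; not a Strelka v1 indel file")
            filters = _filters_of(rec)
            for alt in rec.alts or ():
                tiers = {}
                for role, sm in (("tumour", "TUMOR"), ("normal", "NORMAL")):
                    fmt = rec.samples[sm]
                    tar, tir = _format_get(fmt, "TAR"), _format_get(fmt, "TIR")
                    if tar is None or tir is None:
                        raise DialectError(f"missing TAR/TIR at {rec.chrom}:{rec.pos}")
                    tiers[role] = {
                        t: (int(tir[t - 1]), int(tar[t - 1]) + int(tir[t - 1]))
                        for t in (1, 2)
                    }
                t1_t, t1_n = tiers["tumour"][1], tiers["normal"][1]
                cs.add(
                    CallRecord(
                        variant=trim_variant(Variant(rec.chrom, rec.pos, rec.ref, alt)),
                        caller=STRELKA,
                        aligner=aligner,
                        filters=filters,
                        tumour_alt=t1_t[0],
                        tumour_depth=t1_t[1],
                        normal_alt=t1_n[0],
                        normal_depth=t1_n[1],
                        qual_score=float(qsi_nt),
                        tier_counts=tiers,
                    )
                )
    return cs


def _require_samples(vcf: "pysam.VariantFile", path: str) -> None:
    samples = set(vcf.header.samples)
    if not {"TUMOR", "NORMAL"} <= samples:
        raise DialectError(f"{path}: Strelka files must carry TUMOR and NORMAL samples, found {sorted(samples)}")


def vaf(rec: CallRecord, sample: Sample = "tumour", tier: Optional[int] = None) -> float:
    """Variant allele fraction ``alt / depth``; 0.0 (with a warning) at depth 0."""
    if tier is not None:
        if rec.tier_counts is None:
            raise ValueError(f"tier counts requested but absent (caller={rec.caller})")
        alt, depth = rec.tier_counts[sample][tier]
    elif sample == "tumour":
        alt, depth = rec.tumour_alt, rec.tumour_depth
    else:
        alt, depth = rec.normal_alt, rec.normal_depth
    if depth == 0:
        logger.warning("zero %s depth at %s; VAF reported as 0.0", sample, rec.variant)
        return 0.0
    return alt / depth


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

_GENERIC_HEADER_INFO = [
    '##INFO=<ID=ITC_CALLERS,Number=.,Type=String,Description="Callers supporting this record">',
    '##INFO=<ID=ITC_ALIGNERS,Number=.,Type=String,Description="Aligners supporting this record">',
    '##INFO=<ID=ITC_PROV,Number=.,Type=String,Description="Supporting caller:aligner pairs">',
    '##INFO=<ID=ITC_SCORE,Number=1,Type=Float,Description="Original caller quality score">',
]


def _fileformat_lines(contigs: Optional[dict[str, int]]) -> list[str]:
    lines = ["##fileformat=VCFv4.2"]
    for name, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={name},length={length}>")
    return lines


def write_callset(cs: CallSet, path: str, contigs: Optional[dict[str, int]] = None) -> None:
    """Serialize a (possibly merged) CallSet as VCF 4.2 with provenance INFO tags.

    Round-tripping through :func:`read_callset` recovers keys, filter sets,
    depths, quality scores and provenance exactly.
    """
    recs = cs.sorted_records()
    filter_names = sorted({f for r in recs for f in r.filters})
    lines = _fileformat_lines(contigs)
    lines += [f'##FILTER=<ID={name},Description="Caller-reported filter">' for name in filter_names]
    lines += _GENERIC_HEADER_INFO
    lines += [
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Ref and alt read counts">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOUR\tNORMAL",
    ]
    for r in recs:
        callers = ",".join(sorted({c for c, _ in r.provenance}))
        aligners = ",".join(sorted({a for _, a in r.provenance}))
        prov = ",".join(f"{c}:{a}" for c, a in sorted(r.provenance))
        info = f"ITC_CALLERS={callers};ITC_ALIGNERS={aligners};ITC_PROV={prov}"
        if r.qual_score is not None:
            info += f";ITC_SCORE={r.qual_score:g}"
        filt = ";".join(sorted(r.filters)) if r.filters else "PASS"
        v = r.variant
        t_ad = f"{r.tumour_depth - r.tumour_alt},{r.tumour_alt}"
        n_ad = f"{r.normal_depth - r.normal_alt},{r.normal_alt}"
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t{filt}\t{info}\t"
            f"AD:DP\t{t_ad}:{r.tumour_depth}\t{n_ad}:{r.normal_depth}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_callset(path: str) -> CallSet:
    """Read a VCF produced by :func:`write_callset`."""
    cs = CallSet()
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            filters = _filters_of(rec)
            prov = _info_get(rec, "ITC_PROV") or ()
            if isinstance(prov, str):
                prov = (prov,)
            provenance = frozenset(tuple(p.split(":", 1)) for p in prov)
            score = _info_get(rec, "ITC_SCORE")
            t = rec.samples["TUMOUR"]
            n = rec.samples["NORMAL"]
            callers = sorted({c for c, _ in provenance})
            for alt in rec.alts or ():
                cs.add(
                    CallRecord(
                        variant=Variant(rec.chrom, rec.pos, rec.ref, alt),
                        caller=callers[0] if len(callers) == 1 else "merged",
                        aligner="",
                        filters=filters,
                        tumour_depth=int(t["DP"]),
                        tumour_alt=int(t["AD"][1]),
                        normal_depth=int(n["DP"]),
                        normal_alt=int(n["AD"][1]),
                        qual_score=float(score) if score is not None else None,
                        provenance=provenance,
                    )
                )
    cs.vclass = _vclass_of(r.variant for r in cs)
    return cs


def write_mutect2_vcf(
    records: Iterable[CallRecord],
    path: str,
    tumour_label: str = "TUMOR",
    normal_label: str = "NORMAL",
    contigs: Optional[dict[str, int]] = None,
) -> None:
    """Emit records in the Mutect2 (GATK 3.5) dialect: AD per sample, TLOD in INFO."""
    recs = sorted(records, key=lambda r: r.key)
    filter_names = sorted({f for r in recs for f in r.filters})
    lines = _fileformat_lines(contigs)
    lines += [f'##FILTER=<ID={name},Description="Mutect2 internal filter">' for name in filter_names]
    lines += [
        '##INFO=<ID=TLOD,Number=1,Type=Float,Description="Tumor LOD score">',
        '##INFO=<ID=SOMATIC,Number=0,Type=Flag,Description="Somatic event">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{tumour_label}\t{normal_label}",
    ]
    for r in recs:
        v = r.variant
        filt = ";".join(sorted(r.filters)) if r.filters else "PASS"
        info = "SOMATIC"
        if r.qual_score is not None:
            info += f";TLOD={r.qual_score:.2f}"
        t_ad = f"{r.tumour_depth - r.tumour_alt},{r.tumour_alt}"
        n_ad = f"{r.normal_depth - r.normal_alt},{r.normal_alt}"
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t{filt}\t{info}\t"
            f"GT:AD\t0/1:{t_ad}\t0/0:{n_ad}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_strelka_snv_vcf(
    records: Iterable[CallRecord], path: str, contigs: Optional[dict[str, int]] = None
) -> None:
    """Emit records in the Strelka v1 somatic SNV dialect (AU/CU/GU/TU, QSS_NT)."""
    recs = sorted(records, key=lambda r: r.key)
    filter_names = sorted({f for r in recs for f in r.filters})
    lines = _fileformat_lines(contigs)
    lines += [f'##FILTER=<ID={name},Description="Strelka internal filter">' for name in filter_names]
    lines += [
        '##INFO=<ID=SOMATIC,Number=0,Type=Flag,Description="Somatic event">',
        '##INFO=<ID=QSS,Number=1,Type=Integer,Description="Quality score for all somatic SNVs">',
        '##INFO=<ID=QSS_NT,Number=1,Type=Integer,Description="Quality score reflecting joint probability of somatic variant and normal genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AU,Number=2,Type=Integer,Description="A counts, tiers 1 and 2">',
        '##FORMAT=<ID=CU,Number=2,Type=Integer,Description="C counts, tiers 1 and 2">',
        '##FORMAT=<ID=GU,Number=2,Type=Integer,Description="G counts, tiers 1 and 2">',
        '##FORMAT=<ID=TU,Number=2,Type=Integer,Description="T counts, tiers 1 and 2">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNORMAL\tTUMOR",
    ]
    for r in recs:
        v = r.variant
        if v.vtype != "SNV":
            raise ValueError(f"non-SNV record {v} in Strelka SNV writer")
        tiers = r.tier_counts or _tiers_from_flat(r)
        filt = ";".join(sorted(r.filters)) if r.filters else "PASS"
        q = int(round(r.qual_score or 0))
        info = f"SOMATIC;QSS={q};QSS_NT={q}"
        fmt_vals = []
        for role in ("normal", "tumour"):
            base_counts = {b: [0, 0] for b in "ACGT"}
            for t in (1, 2):
                alt, depth = tiers[role][t]
                base_counts[v.alt][t - 1] = alt
                base_counts[v.ref][t - 1] += depth - alt
            dp = sum(base_counts[b][0] for b in "ACGT")
            au = ":".join(",".join(map(str, base_counts[b])) for b in "ACGT")
            fmt_vals.append(f"{dp}:{au}")
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t{filt}\t{info}\t"
            f"DP:AU:CU:GU:TU\t{fmt_vals[0]}\t{fmt_vals[1]}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_strelka_indel_vcf(
    records: Iterable[CallRecord], path: str, contigs: Optional[dict[str, int]] = None
) -> None:
    """Emit records in the Strelka v1 somatic indel dialect (TAR/TIR, QSI_NT)."""
    recs = sorted(records, key=lambda r: r.key)
    filter_names = sorted({f for r in recs for f in r.filters})
    lines = _fileformat_lines(contigs)
    lines += [f'##FILTER=<ID={name},Description="Strelka internal filter">' for name in filter_names]
    lines += [
        '##INFO=<ID=SOMATIC,Number=0,Type=Flag,Description="Somatic event">',
        '##INFO=<ID=QSI,Number=1,Type=Integer,Description="Quality score for all somatic indels">',
        '##INFO=<ID=QSI_NT,Number=1,Type=Integer,Description="Quality score reflecting joint probability of somatic indel and normal genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=TAR,Number=2,Type=Integer,Description="Reads strongly supporting alternate allele, tiers 1 and 2">',
        '##FORMAT=<ID=TIR,Number=2,Type=Integer,Description="Reads strongly supporting indel allele, tiers 1 and 2">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNORMAL\tTUMOR",
    ]
    for r in recs:
        v = r.variant
        tiers = r.tier_counts or _tiers_from_flat(r)
        filt = ";".join(sorted(r.filters)) if r.filters else "PASS"
        q = int(round(r.qual_score or 0))
        info = f"SOMATIC;QSI={q};QSI_NT={q}"
        fmt_vals = []
        for role in ("normal", "tumour"):
            tar = ",".join(str(tiers[role][t][1] - tiers[role][t][0]) for t in (1, 2))
            tir = ",".join(str(tiers[role][t][0]) for t in (1, 2))
            dp = tiers[role][1][1]
            fmt_vals.append(f"{dp}:{tar}:{tir}")
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t{filt}\t{info}\t"
            f"DP:TAR:TIR\t{fmt_vals[0]}\t{fmt_vals[1]}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _tiers_from_flat(r: CallRecord) -> TierCounts:
    """Duplicate the flat counts into both tiers when tiered counts are absent."""
    return {
        "tumour": {1: (r.tumour_alt, r.tumour_depth), 2: (r.tumour_alt, r.tumour_depth)},
        "normal": {1: (r.normal_alt, r.normal_depth), 2: (r.normal_alt, r.normal_depth)},
    }


def with_normalized(rec: CallRecord, norm: Variant) -> CallRecord:
    return replace(rec, variant=norm) if norm != rec.variant else rec
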