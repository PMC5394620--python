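"""Truth-set evaluation: TP/FP/FN classification, sensitivity, FPR/Mb,
dilution-series reporting, FN breakdown, and replicate-concordance metrics.

False-positive accounting is restricted to the confident reference regions
(confident intervals intersected with the capture target, minus truth
footprints); calls outside them are reported as unclassified.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pysam

from .caller_io import CallSet
from .variant_model import (
    RegionSet,
    Variant,
    decompose_multiallelic,
    normalize_variant,
    point_in_regions,
    variant_key,
)

logger = logging.getLogger(__name__)


@dataclass
class TruthSet:
    """Truth variants plus confident non-variant reference regions (n_ref)."""

    variants: dict[tuple, Variant]
    regions: RegionSet

    @property
    def n_ref_bp(self) -> int:
        return self.regions.total_bp

    def of_vclass(self, vclass: str) -> "TruthSet":
        if vclass == "MIXED":
            return self
        want_snv = vclass == "SNV"
        subset = {
            k: v
            for k, v in self.variants.items()
            if (v.vtype == "SNV") == want_snv
        }
        return TruthSet(variants=subset, regions=self.regions)

    def __len__(self) -> int:
        return len(self.variants)


def make_truth_set(variants: Iterable[Variant], regions: RegionSet) -> TruthSet:
    out: dict[tuple, Variant] = {}
    for v in variants:
        k = variant_key(v)
        if k in out:
            raise ValueError(f"duplicate truth variant {v}")
        out[k] = v
    return TruthSet(variants=out, regions=regions)


def load_truth(path: str, ref_lookup=None) -> list[Variant]:
    """Load truth variants from a VCF or a 4-column TSV (chrom, pos, ref, alt).

    Multiallelic rows are rejected; variants are normalized when a reference
    lookup is supplied, trimmed otherwise.
    """
    variants: list[Variant] = []
    if path.endswith((".vcf", ".vcf.gz")):
        with pysam.VariantFile(path) as vcf:
            for rec in vcf:
                alts = rec.alts or ()
                if len(alts) != 1:
                    raise ValueError(
                        f"multiallelic truth record at {rec.chrom}:{rec.pos}; "
                        "truth sets must be biallelic"
                    )
                variants.extend(decompose_multiallelic(rec.chrom, rec.pos, rec.ref, alts))
    else:
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                chrom, pos, ref, alt = line.split("\t")[:4]
                if "," in alt:
                    raise ValueError(f"multiallelic truth row at {chrom}:{pos}")
                variants.append(Variant(chrom, int(pos), ref, alt))
    return [normalize_variant(v, ref_lookup) for v in variants]


@dataclass(frozen=True)
class BenchmarkResult:
    tp: int
    fp: int
    fn: int
    unclassified: int
    n_ref_bp: int
    fn_keys: frozenset = frozenset()

    @property
    def sensitivity(self) -> Optional[float]:
        return sensitivity(self.tp, self.fn)

    @property
    def fpr_per_mb(self) -> float:
        return fpr_per_mb(self.fp, self.n_ref_bp)

    @property
    def precision(self) -> Optional[float]:
        # secondary metric only; headline reporting is sensitivity + FPR/Mb
        denom = self.tp + self.fp
        return self.tp / denom if denom else None


def sensitivity(tp: int, fn: int) -> Optional[float]:
    """TP / (TP + FN); None when there is nothing to detect."""
    denom = tp + fn
    if denom == 0:
        logger.warning("sensitivity undefined: tp + fn = 0")
        return None
    return tp / denom


def fpr_per_mb(fp: int, n_ref_bp: int) -> float:
    """False positives per megabase of reference regions: fp / n_ref * 1e6."""
    if n_ref_bp <= 0:
        raise ValueError("n_ref_bp must be positive")
    return fp / n_ref_bp * 1e6


def classify(cs: CallSet, truth: TruthSet) -> BenchmarkResult:
    """Match calls against truth keys; count FPs only inside truth.regions.

    A call matching a truth key is TP regardless of region membership (truth
    footprints were subtracted from the regions at construction). Non-truth
    calls are FP when their 1-based start position falls in the reference
    regions, unclassified otherwise.
    """
    if cs.vclass != "MIXED":
        truth = truth.of_vclass(cs.vclass)
    truth_keys = set(truth.variants)
    tp = fp = unclassified = 0
    matched: set[tuple] = set()
    for rec in cs:
        k = rec.key
        if k in truth_keys:
            tp += 1
            matched.add(k)
        elif point_in_regions(truth.regions, rec.variant.chrom, rec.variant.pos):
            fp += 1
        else:
            unclassified += 1
    fn_keys = truth_keys - matched
    return BenchmarkResult(
        tp=tp,
        fp=fp,
        fn=len(fn_keys),
        unclassified=unclassified,
        n_ref_bp=truth.n_ref_bp,
        fn_keys=frozenset(fn_keys),
    )


@dataclass(frozen=True)
class DilutionPoint:
    purity: float
    label: str

    def __post_init__(self) -> None:
        if not (0 < self.purity <= 1):
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")


def expected_vaf(purity: float, zygosity: str) -> float:
    """Expected allele fraction in a dilution mixture: purity/2 (het) or purity (hom)."""
    if not (0 <= purity <= 1):
        raise ValueError(f"purity must be in [0, 1], got {purity}")
    if zygosity == "het":
        return purity / 2
    if zygosity == "hom":
        return purity
    raise ValueError(f"unknown zygosity {zygosity!r}")


def evaluate_dilution_series(
    series: Mapping[DilutionPoint, CallSet], truth: TruthSet
) -> list[dict]:
    """One row per dilution point with sensitivity; FPR/Mb is reported only at
    the minimum-purity point (new variants in low-dilution samples would be
    wrongly counted as false positives, so the rate is withheld there)."""
    if not series:
        raise ValueError("empty dilution series")
    labels = [p.label for p in series]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate dilution-point labels")
    min_purity = min(p.purity for p in series)
    rows = []
    for point in sorted(series, key=lambda p: -p.purity):
        result = classify(series[point], truth)
        rows.append(
            {
                "label": point.label,
                "purity": point.purity,
                "tp": result.tp,
                "fn": result.fn,
                "fp": result.fp,
                "sensitivity": result.sensitivity,
                "fpr_per_mb": result.fpr_per_mb if point.purity == min_purity else None,
            }
        )
    return rows


def fn_breakdown(
    result: BenchmarkResult,
    pileup: Mapping[tuple[str, int], tuple[int, int]],
    min_depth: int = 10,
) -> dict:
    """Partition false negatives by locus coverage: low_coverage (depth <
    ``min_depth``), allele_dropout (covered but zero alt reads), other.

    ``pileup`` maps (chrom, pos) to (depth, alt_count); loci absent from it
    count as depth 0.
    """
    counts = {"low_coverage": 0, "allele_dropout": 0, "other": 0}
    for chrom, pos, _ref, _alt in sorted(result.fn_keys):
        depth, alt = pileup.get((chrom, pos), (0, 0))
        if depth < min_depth:
            counts["low_coverage"] += 1
        elif alt == 0:
            counts["allele_dropout"] += 1
        else:
            counts["other"] += 1
    total = sum(counts.values())
    pct = {
        k: (100.0 * n / total if total else 0.0) for k, n in counts.items()
    }
    return {"counts": counts, "percentages": pct, "total_fn": total}


def load_pileup(path: str) -> dict[tuple[str, int], tuple[int, int]]:
    """Read a per-locus TSV (chrom, pos, depth, alt_count)."""
    out: dict[tuple[str, int], tuple[int, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos, depth, alt = line.split("\t")[:4]
            out[(chrom, int(pos))] = (int(depth), int(alt))
    return out


def replicate_fpr(comparisons: Sequence[CallSet], region_bp: int) -> dict:
    """Treat every call in each replicate-vs-replicate comparison as a false
    positive and summarise the per-comparison FPR/Mb distribution."""
    if not comparisons:
        raise ValueError("no comparisons supplied")
    if region_bp <= 0:
        raise ValueError("region_bp must be positive")
    values = [fpr_per_mb(len(cs), region_bp) for cs in comparisons]
    arr = np.asarray(values, dtype=float)
    return {
        "per_comparison": values,
        "n": len(values),
        "min": float(arr.min()),
        "q1": float(np.percentile(arr, 25)),
        "median": float(np.percentile(arr, 50)),
        "q3": float(np.percentile(arr, 75)),
        "max": float(arr.max()),
    }


def replicate_overlap(r1: CallSet, r2: CallSet) -> tuple[int, float, float]:
    """(shared count, share as % of r1, share as % of r2); 0 for empty sets."""
    if r1.vclass != r2.vclass and "MIXED" not in (r1.vclass, r2.vclass):
        raise ValueError(f"variant-class mismatch: {r1.vclass} vs {r2.vclass}")
    n = len(r1.keys() & r2.keys())
    pct1 = 100.0 * n / len(r1) if len(r1) else 0.0
    pct2 = 100.0 * n / len(r2) if len(r2) else 0.0
    return n, pct1, pct2


def binomial_tail_ge(n: int, p: float, k: int) -> float:
    """P(Binomial(n, p) >= k) by direct summation; closed-form detection oracle."""
    if k <= 0:
        return 1.0
    prob = 0.0
    for i in range(k, n + 1):
        prob += math.comb(n, i) * p**i * (1 - p) ** (n - i)
    return min(prob, 1.0)
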