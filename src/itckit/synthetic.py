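"""Call-level simulator: mini reference, truth sets, and caller-dialect VCF
quartets across a purity dilution series.

The simulator emits what the pipeline consumes downstream of the callers —
no reads, no BAMs. Per truth variant it draws a shared locus depth
(Poisson) and alt support (binomial at the purity-scaled expected VAF);
each of the four (caller, aligner) pipelines then applies an independent
detection coin. False positives come from a per-caller shared pool (placed
identically in both aligners' sets) plus aligner-specific draws. Strelka
indel representations can be right-shifted ("representation jitter") to
exercise normalization.

Random streams are split per purpose from the master seed, so changing one
parameter perturbs only its stream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .benchmark import TruthSet, expected_vaf, make_truth_set
from .caller_io import (
    MUTECT2,
    STRELKA,
    CallRecord,
    CallSet,
    write_mutect2_vcf,
    write_strelka_indel_vcf,
    write_strelka_snv_vcf,
)
from .variant_model import (
    GenomicInterval,
    RegionSet,
    Variant,
    apply_variant,
    build_region_set,
    intersect_regions,
    make_ref_lookup,
    normalize_variant,
    shift_right_once,
    subtract_loci,
    variant_key,
    write_bed,
)

logger = logging.getLogger(__name__)

ALIGNERS = ("bwa", "novoalign")

#: default purity series emulating a 100% -> 0.2% dilution ladder
DEFAULT_PURITIES = (1.0, 0.8, 0.6, 0.4, 0.2, 0.1, 0.05, 0.02, 0.01, 0.005, 0.002)

# stream ids for seed splitting
_S_REFERENCE, _S_TRUTH, _S_DEPTH, _S_DETECT, _S_FP, _S_JITTER, _S_SCORE, _S_NORMAL = range(8)


@dataclass(frozen=True)
class SimulationConfig:
    genome_length: int = 100_000
    repeat_density: float = 0.15
    n_snv: int = 500
    n_indel: int = 30
    het_fraction: float = 0.67
    purities: tuple[float, ...] = DEFAULT_PURITIES
    depth_mean: float = 100.0
    fp_rate_per_mb: float = 400.0
    shared_fp_fraction: float = 0.3
    representation_jitter_prob: float = 0.0
    detection_alt_threshold: int = 3
    detection_rate: float = 0.97
    aain_fraction: float = 0.2
    fp_indel_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "repeat_density",
            "het_fraction",
            "shared_fp_fraction",
            "representation_jitter_prob",
            "detection_rate",
            "aain_fraction",
            "fp_indel_fraction",
        ):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_snv <= 0 or self.n_indel < 0 or self.genome_length <= 0:
            raise ValueError("counts and genome length must be positive")
        if any(p <= 0 or p > 1 for p in self.purities):
            raise ValueError("purities must lie in (0, 1]")
        if list(self.purities) != sorted(self.purities, reverse=True) or len(
            set(self.purities)
        ) != len(self.purities):
            raise ValueError("purities must be strictly decreasing")


def _rng(cfg: SimulationConfig, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream, *extra])


@dataclass
class Reference:
    seqs: dict[str, str]
    runs: RegionSet  # annotated low-complexity runs

    def lookup(self):
        return make_ref_lookup(self.seqs)

    def contigs(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}

    def write_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.seqs):
                fh.write(f">{chrom}\n")
                seq = self.seqs[chrom]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def make_reference(cfg: SimulationConfig) -> Reference:
    """Deterministic random genome with planted homopolymer/dinucleotide runs.

    Runs are overwritten onto iid background sequence until the annotated
    run footprint reaches ``repeat_density`` of the genome.
    """
    if cfg.genome_length < 10_000:
        raise ValueError("genome_length must be >= 10 kb")
    rng = _rng(cfg, _S_REFERENCE)
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=cfg.genome_length)
    target_bp = int(cfg.repeat_density * cfg.genome_length)
    runs: list[GenomicInterval] = []
    covered = 0
    while covered < target_bp:
        length = int(rng.integers(8, 31))
        start = int(rng.integers(0, cfg.genome_length - length))
        if rng.random() < 0.5:
            unit = rng.choice(bases, size=1)
        else:
            unit = rng.choice(bases, size=2, replace=False)
        motif = np.resize(unit, length)
        seq[start : start + length] = motif
        runs.append(GenomicInterval("chr1", start, start + length))
        covered += length
    run_set = build_region_set(runs) if runs else RegionSet({})
    return Reference(seqs={"chr1": "".join(seq)}, runs=run_set)


@dataclass
class TruthFixture:
    """Truth variants with zygosity plus the region files of a study."""

    truth: TruthSet
    zygosity: dict[tuple, str]  # key -> 'het' | 'hom'
    confident: RegionSet
    target: RegionSet


def make_truth(reference: Reference, cfg: SimulationConfig) -> TruthFixture:
    """Plant non-overlapping SNVs and indels, build target/confident regions,
    and subtract truth footprints to obtain the reference regions."""
    rng = _rng(cfg, _S_TRUTH)
    chrom = "chr1"
    seq = reference.seqs[chrom]
    L = len(seq)
    margin = 200
    spacing = 20
    n_total = cfg.n_snv + cfg.n_indel
    usable = (L - 2 * margin) // spacing
    if n_total > usable:
        raise ValueError(
            f"genome too small: {n_total} variants requested, {usable} slots available"
        )
    slot_order = rng.permutation(usable)
    lookup = reference.lookup()

    variants: list[Variant] = []
    zygosity: dict[tuple, str] = {}
    seen: set[tuple] = set()
    alt_choices = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}
    placed_snv = placed_indel = 0
    for slot in slot_order:
        if placed_snv == cfg.n_snv and placed_indel == cfg.n_indel:
            break
        pos = int(margin + slot * spacing + 1)  # 1-based
        ref_base = seq[pos - 1]
        if placed_snv < cfg.n_snv:
            alt = alt_choices[ref_base][int(rng.integers(0, 3))]
            v = Variant(chrom, pos, ref_base, alt)
        else:
            k = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                # tandem duplication of the next k bases: always right-shiftable
                dup = seq[pos : pos + k]
                v = Variant(chrom, pos, ref_base, ref_base + dup)
            else:
                v = Variant(chrom, pos, ref_base + seq[pos : pos + k], ref_base)
        v = normalize_variant(v, lookup)
        key = variant_key(v)
        if key in seen:
            continue  # normalization collision inside a repeat; try another slot
        seen.add(key)
        variants.append(v)
        if v.vtype == "SNV":
            placed_snv += 1
        else:
            placed_indel += 1
        zygosity[key] = "het" if rng.random() < cfg.het_fraction else "hom"
    if placed_snv < cfg.n_snv or placed_indel < cfg.n_indel:
        raise ValueError("genome too small to place the requested truth variants")

    target = build_region_set([GenomicInterval(chrom, margin // 2, L - margin // 2)])
    # confident regions: target minus a few random low-confidence gaps (<10%)
    gap_bp = 0
    gaps: list[GenomicInterval] = []
    max_gap_bp = int(0.05 * target.total_bp)
    while gap_bp < max_gap_bp:
        glen = int(rng.integers(50, 400))
        gstart = int(rng.integers(margin // 2, L - margin // 2 - glen))
        gaps.append(GenomicInterval(chrom, gstart, gstart + glen))
        gap_bp += glen
    confident = (
        subtract_loci_regions(target, gaps) if gaps else target
    )
    regions = intersect_regions(confident, target)
    regions = subtract_loci(regions, variants)
    truth = make_truth_set(
        (v for v in variants if variant_key(v) in zygosity), regions
    )
    return TruthFixture(truth=truth, zygosity=zygosity, confident=confident, target=target)


def subtract_loci_regions(a: RegionSet, gaps: Sequence[GenomicInterval]) -> RegionSet:
    from .variant_model import subtract_regions

    return subtract_regions(a, build_region_set(gaps))


@dataclass
class SimulatedCalls:
    """Four caller x aligner call sets for one purity point, with oracles."""

    purity: float
    callsets: dict[str, dict[str, CallSet]]  # caller -> aligner -> CallSet
    #: mutect2 records planted with alt_allele_in_normal and whether the
    #: relaxed normal-VAF + T/N rule should re-admit them
    mutect2_expected_admit: dict[tuple, bool]
    #: truth keys whose emitted Strelka representation was jittered
    jittered_keys: set[tuple]
    #: per-variant pileup (depth, alt) for FN breakdowns
    pileup: dict[tuple[str, int], tuple[int, int]]


def _sample_positions_in_regions(
    regions: RegionSet, n: int, rng: np.random.Generator
) -> list[tuple[str, int]]:
    ivs = regions.intervals()
    lengths = np.array([len(iv) for iv in ivs], dtype=float)
    if not ivs or n == 0:
        return []
    picks = rng.choice(len(ivs), size=n, p=lengths / lengths.sum())
    out = []
    for i in picks:
        iv = ivs[int(i)]
        out.append((iv.chrom, int(rng.integers(iv.start, iv.end)) + 1))
    return out


def simulate_callsets(
    reference: Reference,
    fixture: TruthFixture,
    purity: float,
    cfg: SimulationConfig,
    purity_index: int = 0,
) -> SimulatedCalls:
    """Generate the Mutect2/Strelka x bwa/novoalign call quartet at one purity."""
    if not (0 < purity <= 1):
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    lookup = reference.lookup()
    truth = fixture.truth
    depth_rng = _rng(cfg, _S_DEPTH, purity_index)
    detect_rng = _rng(cfg, _S_DETECT, purity_index)
    fp_rng = _rng(cfg, _S_FP, purity_index)
    jitter_rng = _rng(cfg, _S_JITTER, purity_index)
    score_rng = _rng(cfg, _S_SCORE, purity_index)
    normal_rng = _rng(cfg, _S_NORMAL, purity_index)

    pipelines = [(c, a) for c in (MUTECT2, STRELKA) for a in ALIGNERS]
    sets: dict[str, dict[str, list[CallRecord]]] = {
        MUTECT2: {a: [] for a in ALIGNERS},
        STRELKA: {a: [] for a in ALIGNERS},
    }
    expected_admit: dict[tuple, bool] = {}
    jittered: set[tuple] = set()
    pileup: dict[tuple[str, int], tuple[int, int]] = {}

    for key in sorted(truth.variants):
        v = truth.variants[key]
        zyg = fixture.zygosity[key]
        p_alt = expected_vaf(purity, zyg)
        depth = int(depth_rng.poisson(cfg.depth_mean))
        alt = int(depth_rng.binomial(depth, p_alt)) if depth else 0
        pileup[(v.chrom, v.pos)] = (depth, alt)
        n_depth = max(int(depth_rng.poisson(cfg.depth_mean)), 1)

        # mutect2: occasionally planted alt_allele_in_normal with a normal VAF
        # drawn around the 7% bound, so the relaxed rule re-admits a known subset
        flag_aain = normal_rng.random() < cfg.aain_fraction
        if flag_aain:
            n_vaf_drawn = float(normal_rng.uniform(0.005, 0.14))
            n_alt = min(max(int(round(n_vaf_drawn * n_depth)), 1), n_depth)
        else:
            n_alt = 0
        # quantized to what the dialects serialize, so round-trips are exact
        tlod = round(float(score_rng.uniform(15.0, 60.0)), 2)
        m2_filters = frozenset({"alt_allele_in_normal"}) if flag_aain else frozenset()

        # strelka representation jitter: consistent across this caller's aligners
        sv = v
        if v.is_indel and jitter_rng.random() < cfg.representation_jitter_prob:
            shifted = shift_right_once(v, lookup)
            steps = 0
            while shifted is not None and (steps == 0 or jitter_rng.random() < 0.5):
                sv, steps = shifted, steps + 1
                nxt = shift_right_once(sv, lookup)
                if nxt is None:
                    break
                shifted = nxt
            if sv != v:
                jittered.add(key)
        strelka_q = float(
            score_rng.integers(30, 71) if v.vtype == "SNV" else score_rng.integers(40, 81)
        )
        # a small extra pool of tier-2-only evidence
        t2_extra = int(score_rng.integers(0, 3))

        detected = {
            (c, a): alt >= cfg.detection_alt_threshold
            and detect_rng.random() < cfg.detection_rate
            for (c, a) in pipelines
        }

        if alt > 0 and flag_aain:
            t_vaf = alt / depth if depth else 0.0
            n_vaf = n_alt / n_depth
            expected_admit[key] = (
                n_vaf <= 0.07 and (n_vaf > 0 and t_vaf / n_vaf > 5.0 or (n_vaf == 0 and t_vaf > 0))
            )

        for aligner in ALIGNERS:
            if detected[(MUTECT2, aligner)]:
                sets[MUTECT2][aligner].append(
                    CallRecord(
                        variant=v,
                        caller=MUTECT2,
                        aligner=aligner,
                        filters=m2_filters,
                        tumour_depth=depth,
                        tumour_alt=alt,
                        normal_depth=n_depth,
                        normal_alt=n_alt,
                        qual_score=tlod,
                    )
                )
            if detected[(STRELKA, aligner)]:
                tiers = {
                    "tumour": {1: (alt, depth), 2: (alt + t2_extra, depth + t2_extra)},
                    "normal": {1: (n_alt, n_depth), 2: (n_alt, n_depth)},
                }
                sets[STRELKA][aligner].append(
                    CallRecord(
                        variant=sv,
                        caller=STRELKA,
                        aligner=aligner,
                        filters=frozenset(),
                        tumour_depth=depth,
                        tumour_alt=alt,
                        normal_depth=n_depth,
                        normal_alt=n_alt,
                        qual_score=strelka_q,
                        tier_counts=tiers,
                    )
                )

    _add_false_positives(sets, fixture, cfg, fp_rng, reference)

    callsets: dict[str, dict[str, CallSet]] = {}
    for caller, by_aligner in sets.items():
        callsets[caller] = {}
        for aligner, records in by_aligner.items():
            cs = CallSet(caller=caller, aligner=aligner, vclass="MIXED")
            for rec in records:
                if rec.key not in cs.records:
                    cs.add(rec)
            callsets[caller][aligner] = cs
    return SimulatedCalls(
        purity=purity,
        callsets=callsets,
        mutect2_expected_admit=expected_admit,
        jittered_keys=jittered,
        pileup=pileup,
    )


def _add_false_positives(
    sets: dict[str, dict[str, list[CallRecord]]],
    fixture: TruthFixture,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    reference: Reference,
) -> None:
    """Per caller: one shared FP pool placed in both aligners, plus
    independent aligner-specific pools, inside the reference regions."""
    regions = fixture.truth.regions
    mean_total = cfg.fp_rate_per_mb * regions.total_bp / 1e6
    truth_keys = set(fixture.truth.variants)
    seq = reference.seqs
    for caller in (MUTECT2, STRELKA):
        n_shared = int(rng.poisson(cfg.shared_fp_fraction * mean_total))
        shared = [
            _random_fp_record(caller, chrom, pos, cfg, rng, seq)
            for chrom, pos in _sample_positions_in_regions(regions, n_shared, rng)
        ]
        shared = [r for r in shared if r is not None and r.key not in truth_keys]
        for aligner in ALIGNERS:
            n_specific = int(rng.poisson((1 - cfg.shared_fp_fraction) * mean_total))
            specific = [
                _random_fp_record(caller, chrom, pos, cfg, rng, seq)
                for chrom, pos in _sample_positions_in_regions(regions, n_specific, rng)
            ]
            specific = [r for r in specific if r is not None and r.key not in truth_keys]
            sets[caller][aligner].extend(
                rec if rec.aligner == aligner else _with_aligner(rec, aligner)
                for rec in shared + specific
            )


def _with_aligner(rec: CallRecord, aligner: str) -> CallRecord:
    from dataclasses import replace

    return replace(rec, aligner=aligner, provenance=frozenset({(rec.caller, aligner)}))


def _random_fp_record(
    caller: str,
    chrom: str,
    pos: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    seqs: dict[str, str],
) -> Optional[CallRecord]:
    seq = seqs[chrom]
    ref_base = seq[pos - 1]
    if ref_base not in "ACGT":
        return None
    depth = max(int(rng.poisson(cfg.depth_mean)), 10)
    alt_reads = int(rng.integers(cfg.detection_alt_threshold, max(6, depth // 10)))
    alt_reads = min(alt_reads, depth)
    if rng.random() < cfg.fp_indel_fraction:
        k = int(rng.integers(1, 3))
        if rng.random() < 0.5 and pos + k <= len(seq):
            variant = Variant(chrom, pos, ref_base, ref_base + seq[pos : pos + k])
        elif pos + k <= len(seq):
            variant = Variant(chrom, pos, ref_base + seq[pos : pos + k], ref_base)
        else:
            return None
        if variant.ref == variant.alt:
            return None
    else:
        alts = [b for b in "ACGT" if b != ref_base]
        variant = Variant(chrom, pos, ref_base, alts[int(rng.integers(0, 3))])
    variant = normalize_variant(variant, make_ref_lookup(seqs))
    if caller == MUTECT2:
        # FP scores straddle the TLOD default so filters see both sides
        return CallRecord(
            variant=variant,
            caller=MUTECT2,
            aligner=ALIGNERS[0],
            filters=frozenset(),
            tumour_depth=depth,
            tumour_alt=alt_reads,
            normal_depth=depth,
            normal_alt=0,
            qual_score=round(float(rng.uniform(6.3 - 3, 6.3 + 10)), 2),
        )
    base = 25.0 if variant.vtype == "SNV" else 35.0
    return CallRecord(
        variant=variant,
        caller=STRELKA,
        aligner=ALIGNERS[0],
        filters=frozenset(),
        tumour_depth=depth,
        tumour_alt=alt_reads,
        normal_depth=depth,
        normal_alt=0,
        qual_score=float(rng.integers(int(base) - 10, int(base) + 11)),
        tier_counts={
            "tumour": {1: (alt_reads, depth), 2: (alt_reads, depth)},
            "normal": {1: (0, depth), 2: (0, depth)},
        },
    )


def _purity_label(purity: float) -> str:
    return f"purity_{purity:g}".replace(".", "_")


def simulate_study(cfg: SimulationConfig, out_dir: str, force: bool = False) -> dict:
    """Write the full study tree: reference, truth, regions, and one VCF
    quartet per purity point, with a checksum manifest. Returns the manifest."""
    if os.path.isdir(out_dir) and os.listdir(out_dir) and not force:
        raise FileExistsError(f"{out_dir} exists and is not empty (use force)")
    os.makedirs(out_dir, exist_ok=True)
    reference = make_reference(cfg)
    fixture = make_truth(reference, cfg)
    contigs = reference.contigs()

    paths: list[str] = []

    def emit(rel: str, writer) -> None:
        path = os.path.join(out_dir, rel)
        os.makedirs(os.path.dirname(path), exist_ok=True)
        writer(path)
        paths.append(rel)

    emit("reference.fasta", reference.write_fasta)
    emit("runs.bed", lambda p: write_bed(reference.runs, p))
    emit("target.bed", lambda p: write_bed(fixture.target, p))
    emit("confident.bed", lambda p: write_bed(fixture.confident, p))
    emit("regions.bed", lambda p: write_bed(fixture.truth.regions, p))

    def write_truth(path: str) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tpos\tref\talt\tzygosity\n")
            for key in sorted(fixture.truth.variants):
                v = fixture.truth.variants[key]
                fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{fixture.zygosity[key]}\n")

    emit("truth.tsv", write_truth)

    for idx, purity in enumerate(cfg.purities):
        sim = simulate_callsets(reference, fixture, purity, cfg, purity_index=idx)
        label = _purity_label(purity)
        for aligner in ALIGNERS:
            emit(
                f"{label}/mutect2_{aligner}.vcf",
                lambda p, a=aligner: write_mutect2_vcf(
                    sim.callsets[MUTECT2][a], p, contigs=contigs
                ),
            )
            strelka = sim.callsets[STRELKA][aligner]
            snvs = [r for r in strelka if r.variant.vtype == "SNV"]
            indels = [r for r in strelka if r.variant.vtype != "SNV"]
            emit(
                f"{label}/strelka_{aligner}_snv.vcf",
                lambda p, rs=snvs: write_strelka_snv_vcf(rs, p, contigs=contigs),
            )
            emit(
                f"{label}/strelka_{aligner}_indel.vcf",
                lambda p, rs=indels: write_strelka_indel_vcf(rs, p, contigs=contigs),
            )

        def write_pileup(path: str, data=sim.pileup) -> None:
            with open(path, "w") as fh:
                fh.write("#chrom\tpos\tdepth\talt_count\n")
                for (chrom, pos), (depth, alt) in sorted(data.items()):
                    fh.write(f"{chrom}\t{pos}\t{depth}\t{alt}\n")

        emit(f"{label}/pileup.tsv", write_pileup)

        def write_admit(path: str, data=sim.mutect2_expected_admit) -> None:
            with open(path, "w") as fh:
                fh.write("#chrom\tpos\tref\talt\texpected_admit\n")
                for key in sorted(data):
                    chrom, pos, ref, alt = key
                    fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{int(data[key])}\n")

        emit(f"{label}/mutect2_expected_admit.tsv", write_admit)

    manifest = {
        "config": asdict(cfg),
        "files": {
            rel: hashlib.sha256(
                open(os.path.join(out_dir, rel), "rb").read()
            ).hexdigest()
            for rel in sorted(paths)
        },
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("wrote study with %d files to %s", len(paths), out_dir)
    return manifest
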