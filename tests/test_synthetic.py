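import json

import numpy as np
import pytest

from itckit.benchmark import classify
from itckit.caller_io import read_mutect2, read_strelka_snv
from itckit.combine import intersect_callsets, itc, overlap_stats
from itckit.synthetic import (
    ALIGNERS,
    SimulationConfig,
    make_reference,
    make_truth,
    simulate_callsets,
    simulate_study,
)
from itckit.variant_model import make_ref_lookup, normalize_variant, variant_key

from .oracles import binom_tail, edit


def tiny_cfg(**kw):
    base = dict(genome_length=30_000, n_snv=80, n_indel=12, purities=(1.0, 0.1), seed=5)
    base.update(kw)
    return SimulationConfig(**base)


class TestMakeReference:
    def test_deterministic(self):
        cfg = tiny_cfg()
        assert make_reference(cfg).seqs == make_reference(cfg).seqs

    def test_seed_changes_sequence(self):
        assert make_reference(tiny_cfg()).seqs != make_reference(tiny_cfg(seed=6)).seqs

    def test_repeat_density_within_tolerance(self):
        cfg = tiny_cfg(genome_length=100_000, repeat_density=0.2)
        ref = make_reference(cfg)
        target = 0.2 * cfg.genome_length
        assert 0.8 * target <= ref.runs.total_bp <= 1.25 * target

    def test_zero_density_no_runs(self):
        ref = make_reference(tiny_cfg(repeat_density=0.0))
        assert ref.runs.total_bp == 0

    def test_fasta_write_deterministic(self, tmp_path):
        cfg = tiny_cfg()
        a, b = tmp_path / "a.fa", tmp_path / "b.fa"
        make_reference(cfg).write_fasta(str(a))
        make_reference(cfg).write_fasta(str(b))
        assert a.read_bytes() == b.read_bytes()

    def test_minimum_length_enforced(self):
        with pytest.raises(ValueError, match="10 kb"):
            make_reference(tiny_cfg(genome_length=5000))


class TestMakeTruth:
    def test_exact_counts(self):
        cfg = tiny_cfg(n_snv=100, n_indel=15)
        fx = make_truth(make_reference(cfg), cfg)
        vtypes = [v.vtype for v in fx.truth.variants.values()]
        assert sum(t == "SNV" for t in vtypes) == 100
        assert sum(t != "SNV" for t in vtypes) == 15

    def test_truth_variants_are_normalized(self):
        cfg = tiny_cfg()
        ref = make_reference(cfg)
        fx = make_truth(ref, cfg)
        lookup = ref.lookup()
        for v in fx.truth.variants.values():
            assert normalize_variant(v, lookup) == v

    def test_regions_exclude_truth_loci(self):
        cfg = tiny_cfg()
        fx = make_truth(make_reference(cfg), cfg)
        from itckit.variant_model import point_in_regions

        for v in fx.truth.variants.values():
            assert not point_in_regions(fx.truth.regions, v.chrom, v.pos)

    def test_confident_covers_most_of_target(self):
        cfg = tiny_cfg()
        fx = make_truth(make_reference(cfg), cfg)
        assert fx.confident.total_bp >= 0.9 * fx.target.total_bp

    def test_region_totals_brute_force(self):
        # per-base oracle on a small genome: regions == (confident & target)
        # minus truth footprints
        cfg = tiny_cfg(genome_length=12_000, n_snv=30, n_indel=5)
        fx = make_truth(make_reference(cfg), cfg)
        conf = {(iv.chrom, i) for iv in fx.confident.intervals() for i in range(iv.start, iv.end)}
        targ = {(iv.chrom, i) for iv in fx.target.intervals() for i in range(iv.start, iv.end)}
        footprint = {
            (v.chrom, p)
            for v in fx.truth.variants.values()
            for p in range(v.pos - 1, v.pos - 1 + len(v.ref))
        }
        assert fx.truth.regions.total_bp == len((conf & targ) - footprint)

    def test_het_fraction_extremes(self):
        cfg = tiny_cfg(het_fraction=1.0)
        fx = make_truth(make_reference(cfg), cfg)
        assert set(fx.zygosity.values()) == {"het"}


class TestSimulateCallsets:
    def test_determinism(self, small_cfg, reference, truth_fixture):
        a = simulate_callsets(reference, truth_fixture, 1.0, small_cfg, purity_index=0)
        b = simulate_callsets(reference, truth_fixture, 1.0, small_cfg, purity_index=0)
        for caller in a.callsets:
            for aligner in ALIGNERS:
                assert a.callsets[caller][aligner].keys() == b.callsets[caller][aligner].keys()

    def test_purity_bounds(self, small_cfg, reference, truth_fixture):
        with pytest.raises(ValueError, match="purity"):
            simulate_callsets(reference, truth_fixture, 0.0, small_cfg)

    def test_detection_probability_closed_form(self):
        # at purity 1.0 and depth 100, P(Binomial(100, 0.5) >= 3) ~ 1, so
        # per-pipeline sensitivity before FP filtering ~ detection_rate
        cfg = tiny_cfg(
            genome_length=120_000,
            n_snv=600,
            n_indel=0,
            het_fraction=1.0,
            fp_rate_per_mb=0.0,
            detection_rate=0.9,
            seed=21,
        )
        ref = make_reference(cfg)
        fx = make_truth(ref, cfg)
        sim = simulate_callsets(ref, fx, 1.0, cfg)
        p_detect = binom_tail(100, 0.5, 3) * 0.9
        assert p_detect == pytest.approx(0.9, abs=1e-6)
        n = len(fx.truth)
        se = np.sqrt(n * p_detect * (1 - p_detect))
        for caller in sim.callsets:
            for aligner in ALIGNERS:
                hits = len(sim.callsets[caller][aligner])
                assert abs(hits - n * p_detect) <= 4 * se

    def test_planted_admission_oracle_members_exist(self, sim_pure):
        m2 = sim_pure.callsets["mutect2"]["bwa"]
        planted = {k for k in sim_pure.mutect2_expected_admit if k in m2.records}
        assert planted, "expected some planted alt_allele_in_normal records"
        for k in planted:
            assert m2.records[k].filters == {"alt_allele_in_normal"}

    def test_shared_fp_fraction_zero_gives_near_empty_fp_intersection(self):
        # over 20 seeds: with no shared pool, cross-aligner FP overlap is
        # collisions only
        total_shared_fp = 0
        total_fp = 0
        for seed in range(20):
            cfg = tiny_cfg(
                n_snv=10, n_indel=0, fp_rate_per_mb=700.0, shared_fp_fraction=0.0, seed=100 + seed
            )
            ref = make_reference(cfg)
            fx = make_truth(ref, cfg)
            sim = simulate_callsets(ref, fx, 1.0, cfg)
            truth_keys = set(fx.truth.variants)
            m2 = sim.callsets["mutect2"]
            fp_bwa = m2["bwa"].keys() - truth_keys
            fp_novo = m2["novoalign"].keys() - truth_keys
            total_shared_fp += len(fp_bwa & fp_novo)
            total_fp += len(fp_bwa)
        assert total_fp > 100
        # analytic collision bound: two ~N-site draws over >= 25 kb of regions
        assert total_shared_fp <= 0.02 * total_fp

    def test_jitter_emits_equivalent_representations(self, small_cfg, reference, truth_fixture):
        import dataclasses

        cfg = dataclasses.replace(small_cfg, representation_jitter_prob=1.0)
        sim = simulate_callsets(reference, truth_fixture, 1.0, cfg, purity_index=0)
        assert sim.jittered_keys, "jitter=1 should shift at least one indel"
        seq = reference.seqs["chr1"]
        strelka = sim.callsets["strelka"]["bwa"]
        truth = truth_fixture.truth
        shifted = [r for r in strelka if r.key not in truth.variants and r.variant.is_indel]
        lookup = reference.lookup()
        for key in sim.jittered_keys:
            v_truth = truth.variants[key]
            emitted = [
                r.variant
                for r in strelka
                if variant_key(normalize_variant(r.variant, lookup)) == key
            ]
            for ev in emitted:
                assert edit(seq, ev.pos, ev.ref, ev.alt) == edit(
                    seq, v_truth.pos, v_truth.ref, v_truth.alt
                )
                assert ev != v_truth


class TestJitterNormalizationProperty:
    def _cross_caller_shared(self, sim, lookup, truth_keys):
        """Shared keys between per-caller intersections, optionally normalized."""
        def norm_keys(cs):
            if lookup is None:
                return cs.keys()
            return {variant_key(normalize_variant(r.variant, lookup)) for r in cs}

        per_caller = []
        for caller in ("mutect2", "strelka"):
            ka = norm_keys(sim.callsets[caller]["bwa"])
            kb = norm_keys(sim.callsets[caller]["novoalign"])
            per_caller.append(ka & kb)
        return per_caller[0] & per_caller[1] & truth_keys

    def test_with_reference_jitter_is_invisible(self, small_cfg, reference, truth_fixture):
        import dataclasses

        lookup = reference.lookup()
        truth_keys = set(truth_fixture.truth.variants)
        cfg0 = dataclasses.replace(small_cfg, representation_jitter_prob=0.0)
        cfg1 = dataclasses.replace(small_cfg, representation_jitter_prob=1.0)
        sim0 = simulate_callsets(reference, truth_fixture, 1.0, cfg0, purity_index=0)
        sim1 = simulate_callsets(reference, truth_fixture, 1.0, cfg1, purity_index=0)
        shared0 = self._cross_caller_shared(sim0, lookup, truth_keys)
        shared1 = self._cross_caller_shared(sim1, lookup, truth_keys)
        assert shared1 == shared0
        # without a reference, matching collapses for every jittered indel
        raw1 = self._cross_caller_shared(sim1, None, truth_keys)
        assert raw1 == shared1 - sim1.jittered_keys
        assert sim1.jittered_keys & shared1, "jitter must affect some shared indel"


class TestSimulateStudy:
    def test_tree_layout_and_determinism(self, tmp_path):
        cfg = tiny_cfg()
        m1 = simulate_study(cfg, str(tmp_path / "a"))
        m2 = simulate_study(cfg, str(tmp_path / "b"))
        assert m1["files"] == m2["files"]  # identical checksums
        # 2 purities x (2 mutect2 + 4 strelka + pileup + admission) + 6 top-level
        assert len(m1["files"]) == 2 * 8 + 6

    def test_existing_nonempty_dir_requires_force(self, tmp_path):
        cfg = tiny_cfg()
        out = tmp_path / "study"
        simulate_study(cfg, str(out))
        with pytest.raises(FileExistsError):
            simulate_study(cfg, str(out))
        simulate_study(cfg, str(out), force=True)

    def test_manifest_matches_files(self, tmp_path):
        import hashlib

        cfg = tiny_cfg()
        out = tmp_path / "study"
        manifest = simulate_study(cfg, str(out))
        on_disk = json.loads((out / "manifest.json").read_text())
        assert on_disk["files"] == manifest["files"]
        for rel, digest in manifest["files"].items():
            assert hashlib.sha256((out / rel).read_bytes()).hexdigest() == digest

    def test_end_to_end_consumable(self, tmp_path):
        cfg = tiny_cfg()
        out = tmp_path / "study"
        simulate_study(cfg, str(out))
        import pyfaidx

        from itckit.benchmark import load_truth, make_truth_set
        from itckit.variant_model import read_bed, subtract_loci

        lookup = make_ref_lookup(pyfaidx.Fasta(str(out / "reference.fasta")))
        truth_vars = load_truth(str(out / "truth.tsv"), lookup)
        regions = read_bed(str(out / "regions.bed"))
        truth = make_truth_set(truth_vars, regions)
        assert len(truth) == cfg.n_snv + cfg.n_indel

        label = "purity_1"
        calls = {
            "mutect2": {
                a: read_mutect2(str(out / label / f"mutect2_{a}.vcf"), "TUMOR", "NORMAL", aligner=a)
                for a in ALIGNERS
            },
            "strelka": {},
        }
        from itckit.caller_io import read_strelka_indel
        from itckit.combine import union_callsets

        for a in ALIGNERS:
            snv = read_strelka_snv(str(out / label / f"strelka_{a}_snv.vcf"), aligner=a)
            ind = read_strelka_indel(str(out / label / f"strelka_{a}_indel.vcf"), aligner=a)
            merged = union_callsets([snv, ind], allow_mixed=True)
            merged.vclass = "MIXED"
            calls["strelka"][a] = merged
        for c in calls:
            for a in ALIGNERS:
                calls[c][a].vclass = "MIXED"
        final = itc(calls)
        res = classify(final, truth)
        assert res.tp + res.fn == len(truth)
        assert res.tp > 0

    def test_expected_vcf_count_for_default_series(self, tmp_path):
        cfg = tiny_cfg(purities=(1.0, 0.8, 0.6, 0.4, 0.2, 0.1, 0.05, 0.02, 0.01, 0.005, 0.002))
        manifest = simulate_study(cfg, str(tmp_path / "full"))
        vcfs = [f for f in manifest["files"] if f.endswith(".vcf")]
        assert len(vcfs) == 11 * 6  # 2 mutect2 + 4 strelka files per purity


class TestParameterRecovery:
    def test_shared_fp_fraction_recovered(self):
        # overlap_stats on FP-only call sets converges to the configured
        # shared fraction (small-sample version; the full 50-seed check runs
        # in the acceptance suite)
        s = 0.4
        shared_counts = total_counts = 0
        for seed in range(12):
            cfg = tiny_cfg(
                n_snv=10,
                n_indel=0,
                fp_rate_per_mb=800.0,
                shared_fp_fraction=s,
                seed=300 + seed,
            )
            ref = make_reference(cfg)
            fx = make_truth(ref, cfg)
            sim = simulate_callsets(ref, fx, 1.0, cfg)
            truth_keys = set(fx.truth.variants)
            m2 = sim.callsets["mutect2"]
            fp_a = m2["bwa"].subset(m2["bwa"].keys() - truth_keys)
            fp_b = m2["novoalign"].subset(m2["novoalign"].keys() - truth_keys)
            st_ = overlap_stats(fp_a, fp_b)
            shared_counts += st_.shared
            total_counts += st_.shared + st_.a_only
        measured = shared_counts / total_counts
        se = np.sqrt(s * (1 - s) / total_counts)
        assert abs(measured - s) <= 4 * se + 0.02
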