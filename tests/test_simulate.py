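import math

import numpy as np
import pytest
from Bio.Seq import Seq

from conftest import variant_key
from orgpopgen.io import AnnotatedGenome, Feature
from orgpopgen.simulate import (
    SimulationConfig,
    build_reference,
    concat_alignments,
    expected_mutation_counts,
    simulate_population,
    simulate_regions,
)
from orgpopgen.variants import call_variants


class TestBuildReference:
    def test_ir_copies_are_mutual_reverse_complements(self, plastome):
        ira, irb = sorted(plastome.features_of_type("IR"), key=lambda f: f.start)
        a = plastome.sequence[ira.start - 1 : ira.end]
        b = plastome.sequence[irb.start - 1 : irb.end]
        assert a == str(Seq(b).reverse_complement())
        assert len(a) == len(b) > 1000

    def test_plastome_has_hotspot_spacers_and_introns(self, plastome):
        from orgpopgen.annotate import build_region_inventory

        inv = build_region_inventory(
            [f for f in plastome.features if f.ftype != "IR"],
            len(plastome),
            circular=True,
        )
        names = {r.name for r in inv}
        assert {"ndhD—ccsA", "rps4—rps16", "trnL(UAG)—ndhF"} <= names
        assert any(r.rclass == "intron" for r in inv)

    def test_mitogenome_chromosome_assignment(self, mito_regions):
        assert len(mito_regions) == 14
        chroms = [g.name.split("_")[0] for g in mito_regions]
        assert chroms.count("chMt1") == 8
        assert chroms.count("chMt2") == 4
        assert chroms.count("chMt3") == 2

    def test_same_seed_identical_output(self):
        a = build_reference("plastome", seed=42)
        b = build_reference("plastome", seed=42)
        assert a.sequence == b.sequence and a.features == b.features

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="unknown reference kind"):
            build_reference("nuclear")


class TestSimulatePopulation:
    def test_zero_rates_yield_identical_samples(self, plastome):
        cfg = SimulationConfig(
            seed=1,
            snp_rate={"exon": 0, "intron": 0, "spacer": 0},
            indel_rate={"exon": 0, "intron": 0, "spacer": 0},
        )
        truth = simulate_population(plastome, cfg)
        assert truth.variants == []
        rows = {truth.alignment[s] for s in truth.alignment.ids}
        assert rows == {plastome.sequence}

    def test_determinism(self, plastome):
        cfg = SimulationConfig.calibrated(plastome, seed=5)
        t1 = simulate_population(plastome, cfg)
        t2 = simulate_population(plastome, cfg)
        assert list(map(variant_key, t1.variants)) == list(map(variant_key, t2.variants))
        assert all(t1.alignment[s] == t2.alignment[s] for s in t1.alignment.ids)

    def test_infinite_kappa_gives_only_transitions(self, plastome):
        cfg = SimulationConfig.calibrated(plastome, seed=2, kappa=math.inf)
        truth = simulate_population(plastome, cfg)
        transitions = {frozenset(p) for p in (("A", "G"), ("C", "T"))}
        snps = [v for v in truth.variants if v.vtype == "SNP"]
        assert snps
        assert all(
            frozenset((v.ref_allele, v.alt_alleles[0])) in transitions for v in snps
        )

    def test_reference_individual_never_carries(self, plastome_truth):
        _, truth = plastome_truth
        for v in truth.variants:
            assert truth.reference_id not in v.carriers

    def test_saturation_refused(self, plastome):
        cfg = SimulationConfig(
            seed=1, snp_rate={"exon": 0.9, "intron": 0.9, "spacer": 0.9}
        )
        with pytest.raises(ValueError, match="saturation refused"):
            simulate_population(plastome, cfg)

    def test_snp_count_matches_binomial_expectation(self, plastome):
        """Planted SNP totals across seeds behave like the configured binomial."""
        cfg = SimulationConfig.calibrated(plastome, total_snps=64.0)
        expected, _ = expected_mutation_counts(plastome, cfg)
        assert abs(expected - 64.0) < 1e-6
        counts = []
        for seed in range(20):
            cfg.seed = seed
            counts.append(simulate_population(plastome, cfg).count("SNP"))
        mean = np.mean(counts)
        # 3 sigma band for the mean of 20 binomial draws
        sd = math.sqrt(expected) / math.sqrt(20)
        assert abs(mean - expected) < 3 * sd

    def test_carriers_confined_to_one_population(self, plastome_truth):
        cfg, truth = plastome_truth
        popmap = cfg.population_map
        for v in truth.variants:
            assert len({popmap[s] for s in v.carriers}) == 1


def _two_spacer_genome():
    """g1 --- hot spacer --- g2 --- cold spacer --- g3, spacers equal length."""
    seq_len = 1000 + 2000 + 1000 + 2000 + 1000 + 2000
    rng = np.random.default_rng(99)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, seq_len)])
    feats = [
        Feature("g1", "gene", 1, 1000),
        Feature("g2", "gene", 3001, 4000),
        Feature("g3", "gene", 6001, 7000),
    ]
    return AnnotatedGenome("toy", seq, feats)


class TestHotspots:
    def test_multiplier_scales_planted_counts(self):
        genome = _two_spacer_genome()
        m = 4.0
        hot = cold = 0
        for seed in range(50):
            cfg = SimulationConfig(
                seed=seed,
                snp_rate={"exon": 0, "intron": 0, "spacer": 2e-3},
                indel_rate={"exon": 0, "intron": 0, "spacer": 0},
                hotspot_regions={"g1—g2": m},
            )
            truth = simulate_population(genome, cfg)
            hot += truth.per_region_counts.get(("g1—g2", "SNP"), 0)
            cold += truth.per_region_counts.get(("g2—g3", "SNP"), 0)
        ratio = hot / cold
        # Poisson sampling error on the ratio of pooled counts
        se = ratio * math.sqrt(1 / hot + 1 / cold)
        assert abs(ratio - m) < 3 * se


class TestRegions:
    def test_region_simulation_and_concat(self, mito_regions):
        cfg = SimulationConfig.calibrated(
            mito_regions, total_snps=8, total_indels=16, seed=3
        )
        truths = simulate_regions(mito_regions, cfg)
        assert set(truths) == {g.name for g in mito_regions}
        for g in mito_regions:
            t = truths[g.name]
            called = call_variants(t.alignment, t.reference_id)
            assert sorted(map(variant_key, called)) == sorted(
                map(variant_key, t.variants)
            )
        combined = concat_alignments([truths[g.name].alignment for g in mito_regions])
        assert combined.length == sum(
            truths[g.name].alignment.length for g in mito_regions
        )

    def test_indels_confined_to_noncoding_by_default(self, plastome, plastome_truth):
        _, truth = plastome_truth
        exon_indels = [
            (name, vt)
            for (name, vt), n in truth.per_region_counts.items()
            if vt == "InDel"
        ]
        from orgpopgen.annotate import build_region_inventory

        inv = build_region_inventory(
            [f for f in plastome.features if f.ftype != "IR"],
            len(plastome),
            circular=True,
        )
        classes = {r.name: r.rclass for r in inv}
        assert all(classes[name] != "exon" for name, _ in exon_indels)
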