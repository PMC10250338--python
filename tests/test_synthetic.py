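import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from minicirc.seq import gc_fraction, revcomp
from minicirc.synthetic import (
    SimulationParams,
    _random_cds,
    build_species_model,
    default_config,
    generate_minicircles,
    mutate_sequence,
    simulate_reads,
)
from oracles import levenshtein


def _small_config(**overrides):
    cfg = {
        "species_id": "mini",
        "seed": 3,
        "gc_constant": 0.6,
        "constant_templates": [
            {
                "id": "CRX",
                "length": 400,
                "repeat_regions": [
                    {"id": "A", "unit_length": 30, "min_units": 1, "max_units": 4},
                ],
            }
        ],
        "genes": [
            {"name": "g1", "cds_length": 300, "ncr_length": 100, "gc": 0.6},
            {"name": "g2", "cds_length": 450, "ncr_length": 100, "gc": 0.6},
        ],
        "circle_plan": [
            {"gene": "g1", "template": "CRX", "units": {"A": 3}},
            {"gene": "g2", "template": "CRX", "units": {"A": 1}},
        ],
    }
    cfg.update(overrides)
    return cfg


class TestBuildSpeciesModel:
    def test_default_config_shape(self, model):
        assert len(model.circle_plan) == 13
        assert len(model.constant_templates) == 3
        groups = set(model.gene_to_group().values())
        assert len(groups) == 3

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            build_species_model(_small_config(genes=[], circle_plan=[]))

    def test_duplicate_gene_names_rejected(self):
        cfg = _small_config()
        cfg["genes"].append(dict(cfg["genes"][0]))
        with pytest.raises(ValueError):
            build_species_model(cfg)

    def test_unknown_template_rejected(self):
        cfg = _small_config()
        cfg["circle_plan"][0]["template"] = "nope"
        with pytest.raises(ValueError):
            build_species_model(cfg)

    def test_cds_length_must_be_codon_multiple(self):
        cfg = _small_config()
        cfg["genes"][0]["cds_length"] = 301
        with pytest.raises(ValueError):
            build_species_model(cfg)

    def test_shared_template_gives_identical_backbone(self):
        model = build_species_model(_small_config())
        a, b = generate_minicircles(model, 7)
        # same unit counts for the single repeat region -> identical constants
        cfg = _small_config()
        cfg["circle_plan"][1]["units"] = {"A": 3}
        model2 = build_species_model(cfg)
        a2, b2 = generate_minicircles(model2, 7)
        assert a2.constant_seq == b2.constant_seq


class TestGenerateMinicircles:
    def test_deterministic(self, model):
        first = generate_minicircles(model, 42)
        second = generate_minicircles(model, 42)
        assert [c.sequence for c in first] == [c.sequence for c in second]

    def test_seed_changes_output(self, model):
        assert [c.sequence for c in generate_minicircles(model, 1)] != [
            c.sequence for c in generate_minicircles(model, 2)
        ]

    def test_unit_count_difference_changes_length_by_two_units(self):
        model = build_species_model(_small_config())
        c3, c1 = generate_minicircles(model, 7)
        unit_len = 30
        cassette_diff = len(c3.cassette_seq) - len(c1.cassette_seq)
        assert (len(c3) - cassette_diff) - len(c1) == 2 * unit_len

    def test_cassette_gc_concentrates_on_target(self):
        # long CDS at GC 0.55: binomial concentration within +/- 0.02
        rng = np.random.default_rng(0)
        cds = _random_cds(rng, 9000, 0.55)
        assert abs(gc_fraction(cds) - 0.55) < 0.02

    def test_constant_gc_converges_within_3_sigma(self, model, circles):
        target = model.gc_constant
        for c in circles:
            seq = c.constant_seq
            sigma = (target * (1 - target) / len(seq)) ** 0.5
            assert abs(gc_fraction(seq) - target) < 3.5 * sigma

    def test_intervals_partition_circle(self, circles):
        for c in circles:
            ca, cb = c.cassette_interval
            ka, kb = c.constant_interval
            assert (cb - ca) + (kb - ka) == len(c)
            assert c.cassette_seq + c.constant_seq == c.sequence


class TestMutateSequence:
    def test_zero_rates_identity(self):
        seq = "ACGT" * 50
        assert mutate_sequence(seq, 0.0, 0.0, 1) == seq

    def test_deterministic(self):
        seq = "ACGTTGCA" * 100
        assert mutate_sequence(seq, 0.1, 0.05, 9) == mutate_sequence(seq, 0.1, 0.05, 9)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            mutate_sequence("ACGT", -0.1, 0.0, 1)
        with pytest.raises(ValueError):
            mutate_sequence("ACGT", 0.0, 0.5, 1)

    def test_substitution_count_matches_binomial_oracle(self):
        # sub-only mutation preserves positions: edit distance = Hamming
        rng = np.random.default_rng(123)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        n, p, n_seeds = 10_000, 0.05, 100
        total = 0
        for seed in range(n_seeds):
            mut = mutate_sequence(seq, p, 0.0, seed)
            total += sum(x != y for x, y in zip(seq, mut))
        mean = total / n_seeds
        sigma_mean = (n * p * (1 - p) / n_seeds) ** 0.5
        assert abs(mean - n * p) < 3 * sigma_mean

    def test_hamming_equals_edit_distance_for_substitutions(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        mut = mutate_sequence(seq, 0.05, 0.0, 2)
        hamming = sum(x != y for x, y in zip(seq, mut))
        assert levenshtein(seq, mut) == hamming


class TestSimulateReads:
    def test_all_single_when_fractions_zero(self, circles):
        reads, truth = simulate_reads(circles, SimulationParams(n_reads=30, seed=1))
        assert set(truth["category"]) == {"single"}

    def test_truth_conservation(self, noisy_sim):
        reads, truth = noisy_sim
        assert len(truth) == len(reads)
        assert truth["category"].value_counts().sum() == len(reads)

    def test_fractions_over_one_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(n_reads=10, fraction_homo=0.6, fraction_hetero=0.6)

    def test_determinism_bytewise(self, circles):
        params = SimulationParams(
            n_reads=40, sub_rate=0.02, indel_rate=0.01, fraction_homo=0.1, seed=3
        )
        r1, t1 = simulate_reads(circles, params)
        r2, t2 = simulate_reads(circles, params)
        assert [r.sequence for r in r1] == [r.sequence for r in r2]
        assert [r.quality for r in r1] == [r.quality for r in r2]
        assert t1.equals(t2)

    def test_hetero_reads_contain_two_cassettes_around_full_constant(self, circles):
        params = SimulationParams(n_reads=20, fraction_hetero=1.0, seed=13)
        reads, truth = simulate_reads(circles, params)
        by_id = {c.circle_id: c for c in circles}
        for read, row in zip(reads, truth.itertuples()):
            seq = read.sequence if row.strand == "+" else revcomp(read.sequence)
            a, b = (by_id[cid] for cid in row.circle_ids.split("+"))
            block = a.cassette_seq + a.constant_seq + b.cassette_seq
            assert block in seq

    def test_hetero_respects_constant_groups(self, circles, model):
        params = SimulationParams(n_reads=60, fraction_hetero=1.0, seed=17)
        _, truth = simulate_reads(circles, params)
        groups = model.gene_to_group()
        for genes in truth["genes"]:
            g1, g2 = genes.split("+")
            assert groups[g1] == groups[g2]
            assert g1 != g2

    def test_homo_reads_are_tandem_copies(self, circles):
        params = SimulationParams(n_reads=10, fraction_homo=1.0, seed=19)
        reads, truth = simulate_reads(circles, params)
        by_id = {c.circle_id: c for c in circles}
        for read, row in zip(reads, truth.itertuples()):
            circle = by_id[row.circle_ids]
            assert len(read.sequence) == row.unit_count * len(circle)
            assert row.unit_count >= 2

    def test_read_length_mode_near_circle_length(self, circles):
        params = SimulationParams(n_reads=3000, length_sigma_rel=0.05, seed=23)
        reads, truth = simulate_reads(circles, params)
        by_gene = {}
        lengths = {c.gene: len(c) for c in circles}
        for read, row in zip(reads, truth.itertuples()):
            by_gene.setdefault(row.genes, []).append(len(read.sequence))
        for gene, ls in by_gene.items():
            if len(ls) < 50:
                continue
            counts, edges = np.histogram(ls, bins=30)
            mode = (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1]) / 2
            assert abs(mode - lengths[gene]) / lengths[gene] < 0.05

    def test_hetero_without_shared_group_rejected(self):
        cfg = _small_config()
        cfg["constant_templates"].append(
            {"id": "CRY", "length": 400, "repeat_regions": []}
        )
        cfg["circle_plan"][1]["template"] = "CRY"
        model = build_species_model(cfg)
        circles = generate_minicircles(model, 1)
        with pytest.raises(ValueError):
            simulate_reads(
                circles, SimulationParams(n_reads=10, fraction_hetero=0.5, seed=1)
            )


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_mutation_determinism_property(seed):
    seq = "ACGTGGCTA" * 30
    assert mutate_sequence(seq, 0.08, 0.03, seed) == mutate_sequence(seq, 0.08, 0.03, seed)
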