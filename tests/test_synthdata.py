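"""Fixture invariants, sequence mutation, and the founder-chain simulator."""

import numpy as np
import pytest
from scipy import stats

from mitopop.haplotyper import assign_haplogroup
from mitopop.refvar import Variant
from mitopop.synthdata import (
    BRS_LENGTH,
    FounderChainParams,
    draw_mutated_base,
    fixture_population_set,
    generate_nguni_fixture,
    mutate,
    scale_position,
    scaled_haplogroup_tree,
    simulate_serial_founders,
    synthetic_reference,
)


# --- synthetic reference ---------------------------------------------------

class TestSyntheticReference:
    def test_deterministic_and_full_length(self):
        a, b = synthetic_reference(), synthetic_reference()
        assert a.sequence == b.sequence
        assert len(a) == BRS_LENGTH
        assert a.circular

    def test_transversion_anchor_base(self):
        assert synthetic_reference().base(14523) == "A"
        short = synthetic_reference(2000)
        assert short.base(scale_position(14523, 2000)) == "A"

    def test_scaled_tree_keeps_positions_distinct(self):
        tree = scaled_haplogroup_tree(1000)
        positions = [m.position for n in tree.nodes.values() for m in n.motif]
        assert len(positions) == len(set(positions))


# --- mutate ----------------------------------------------------------------

class TestMutate:
    def test_empty_set_is_identity(self, reference_small):
        assert mutate(reference_small, []) == reference_small.sequence

    def test_single_substitution_hamming_one(self, reference_small):
        base = reference_small.base(700)
        alt = next(b for b in "ACGT" if b != base)
        seq = mutate(reference_small, [Variant.substitution(700, base, alt)])
        diffs = sum(x != y for x, y in zip(seq, reference_small.sequence))
        assert diffs == 1

    def test_insertion_lengthens_by_one(self, reference_small):
        seq = mutate(reference_small, [Variant.insertion(900, "A")])
        assert len(seq) == len(reference_small) + 1
        assert seq[:900] == reference_small.sequence[:900]
        assert seq[900] == "A"

    def test_wrong_ref_allele_rejected(self, reference_small):
        base = reference_small.base(50)
        wrong = next(b for b in "ACGT" if b != base)
        alt = next(b for b in "ACGT" if b not in (base, wrong))
        with pytest.raises(ValueError, match="reference base"):
            mutate(reference_small, [Variant.substitution(50, wrong, alt)])

    def test_overlapping_variants_rejected(self, reference_small):
        ref2 = reference_small.sequence[99:101]
        with pytest.raises(ValueError, match="overlap"):
            mutate(
                reference_small,
                [
                    Variant.deletion(100, ref2),
                    Variant.substitution(
                        101, reference_small.base(101),
                        next(b for b in "ACGT" if b != reference_small.base(101)),
                    ),
                ],
            )


# --- fixture ---------------------------------------------------------------

class TestFixture:
    def test_thirty_five_deterministic_profiles(self, reference_full, tree):
        first = generate_nguni_fixture(reference_full, tree)
        second = generate_nguni_fixture(reference_full, tree)
        assert len(first) == 35
        assert [p.sample_id for p in first] == [p.sample_id for p in second]
        assert all(set(a) == set(b) for a, b in zip(first, second))

    def test_universal_markers(self, fixture_profiles):
        for p in fixture_profiles:
            assert p.substitution_at(16050) is not None
            assert p.substitution_at(16113) is not None
            assert p.insertion_at(16201) is not None

    def test_insertion_alleles(self, fixture_profiles):
        for p in fixture_profiles:
            expected = "G" if p.sample_id in {"6", "10", "15"} else "A"
            assert p.insertion_at(16201).alt_allele == expected

    def test_reversion_trio(self, fixture_profiles):
        for p in fixture_profiles:
            has_16255 = p.substitution_at(16255) is not None
            has_7542 = p.substitution_at(7542) is not None
            if p.sample_id in {"6", "7", "8"}:
                assert not has_16255 and has_7542
            elif p.sample_id in {"16", "27", "40"}:
                assert has_16255 and not has_7542
            else:
                assert has_16255 and has_7542

    def test_conflict_quartet_markers(self, fixture_profiles):
        for p in fixture_profiles:
            if p.sample_id in {"4", "24", "26", "32"}:
                assert p.substitution_at(16122) is not None
                v = p.substitution_at(14523)
                assert v is not None and (v.ref_allele, v.alt_allele) == ("A", "T")

    def test_sample_28_lacks_16022(self, fixture_profiles):
        p28 = next(p for p in fixture_profiles if p.sample_id == "28")
        assert p28.substitution_at(7542) is not None
        assert p28.substitution_at(16022) is None

    def test_classifier_recovers_published_assignments(self, fixture_profiles, tree):
        assigned = {
            p.sample_id: assign_haplogroup(p, tree).haplogroup
            for p in fixture_profiles
        }
        assert assigned["40"] == "T1"
        assert assigned["16"] == "T1c"
        assigned_27 = assigned["27"]
        assert assigned_27 == "T1d"
        lineage = [
            s for s, h in assigned.items() if "T1b" in tree.path(h)
        ]
        assert len(lineage) == 32

    def test_population_set_rendering(self, reference_full, tree):
        ps = fixture_population_set(reference_full, tree)
        assert ps.labels == ["Nguni"]
        seqs = ps.populations["Nguni"]
        assert len(seqs) == 35
        # the shared single-base insertion lengthens every genome by one
        assert all(len(s) == len(reference_full) + 1 for s in seqs)


# --- simulator -------------------------------------------------------------

def small_params(seed, **kw):
    defaults = dict(
        genome_length=2000,
        effective_sizes=(80, 80, 80),
        final_sample_sizes=(12, 12, 12),
        generations_between_steps=20,
        founder_private_mutations=5.0,
    )
    defaults.update(kw)
    return FounderChainParams(seed=seed, **defaults)


class TestSimulator:
    def test_same_seed_bitwise_reproducible(self):
        a = simulate_serial_founders(small_params(7))
        b = simulate_serial_founders(small_params(7))
        assert a.population_set.populations == b.population_set.populations
        assert a.haplogroup_truth == b.haplogroup_truth

    def test_different_seeds_differ(self):
        a = simulate_serial_founders(small_params(7))
        b = simulate_serial_founders(small_params(8))
        assert a.population_set.populations != b.population_set.populations

    def test_chain_order_and_sample_sizes(self):
        sim = simulate_serial_founders(small_params(3))
        ps = sim.population_set
        assert ps.labels == ["Egypt", "Ethiopia", "Nguni"]
        assert [len(ps.populations[l]) for l in ps.labels] == [12, 12, 12]

    def test_single_population_chain(self):
        sim = simulate_serial_founders(
            FounderChainParams(
                seed=1, n_populations=1, population_names=("Pool",),
                chain_sizes=(), final_sample_sizes=(10,), effective_sizes=(50,),
                genome_length=1000, generations_between_steps=10,
            )
        )
        assert sim.population_set.labels == ["Pool"]

    def test_founders_exceeding_source_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            simulate_serial_founders(
                small_params(1, chain_sizes=(120, 10))
            )

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FounderChainParams(seed=1, ts_tv_ratio=0.0)
        with pytest.raises(ValueError):
            FounderChainParams(seed=1, final_sample_sizes=(26, 170, 2000))
        with pytest.raises(ValueError):
            FounderChainParams(
                seed=1, haplogroup_seed_frequencies={"T1b": 0.5}
            )

    def test_ts_tv_ratio_realized(self):
        rng = np.random.default_rng(99)
        kappa = 20.0
        ts = tv = 0
        for _ in range(20_000):
            base = "ACGT"[rng.integers(4)]
            new = draw_mutated_base(base, rng, kappa)
            if new == {"A": "G", "G": "A", "C": "T", "T": "C"}[base]:
                ts += 1
            else:
                tv += 1
        assert abs(ts / tv - kappa) / kappa < 0.10

    def test_head_haplogroup_frequencies_multinomial(self):
        # pooled over replicates, seed-lineage haplogroup counts at the
        # chain head should match the configured frequencies
        freqs = {"T1a": 0.269, "T1b": 0.269, "T1c": 0.385, "T1d": 0.038,
                 "T1f": 0.039}
        counts = {k: 0 for k in freqs}
        total = 0
        for seed in range(8):
            sim = simulate_serial_founders(
                FounderChainParams(
                    seed=seed, n_populations=1, population_names=("Head",),
                    chain_sizes=(), final_sample_sizes=(60,), effective_sizes=(60,),
                    genome_length=1000, generations_between_steps=0,
                    founder_private_mutations=0.0,
                )
            )
            for hg in sim.haplogroup_truth["Head"]:
                counts[hg] += 1
                total += 1
        observed = [counts[k] for k in sorted(freqs)]
        expected = [freqs[k] * total for k in sorted(freqs)]
        assert stats.chisquare(observed, expected).pvalue > 0.001

    def test_no_bottleneck_no_mutation_preserves_composition(self):
        # with mutation off and founder count equal to the population
        # size, the chain is pure resampling: every downstream haplotype
        # already exists at the head
        sim = simulate_serial_founders(
            small_params(
                5, mutation_rate=0.0, chain_sizes=(80, 80),
                final_sample_sizes=(80, 80, 80),
            )
        )
        pops = sim.population_set.populations
        head = set(pops["Egypt"])
        assert set(pops["Ethiopia"]) <= head
        assert set(pops["Nguni"]) <= head

    def test_profiles_match_sequences(self):
        from mitopop.synthdata import mutate as apply

        sim = simulate_serial_founders(small_params(2))
        by_id = {p.sample_id: p for p in sim.profiles}
        for sid, label, seq in sim.population_set.samples():
            rebuilt = apply(sim.reference, list(by_id[sid]))
            assert rebuilt == seq
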