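"""The synthetic virome generator: determinism, planted structure, truth."""

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_force_orfs
from virosift.homology import best_hits_by_contig, classify_viral
from virosift.quantify import normalize
from virosift.strand import logit_ci
from virosift.synthetic import (
    SampleModel,
    Scenario,
    VirusModel,
    default_scenario,
    generate_dataset,
    generate_genomes,
    simulate_counts,
    simulate_hits,
)


def virus(name="v", cls="plus_ss_rna", segments=(2000,), polarity=0.95,
          abundance=None, identity=75.0):
    return VirusModel(name, cls, tuple(segments), polarity, abundance or {}, identity)


def sample(sid="s1", total=1_000_000, rrna=0.2, sources=()):
    return SampleModel(sid, total, rrna, tuple(sources))


class TestModels:
    def test_segment_length_floor_enforced(self):
        with pytest.raises(ValueError, match="500"):
            virus(segments=(499,))

    def test_polarity_range_enforced(self):
        with pytest.raises(ValueError):
            virus(polarity=0.0)
        with pytest.raises(ValueError):
            virus(polarity=1.2)

    def test_switch_rate_capped(self):
        with pytest.raises(ValueError):
            sample(sources=(("s2", 0.06),))

    def test_non_rrna_total_derived(self):
        assert sample(total=1_000_000, rrna=0.25).non_rrna_total == 750_000


class TestGenomes:
    def test_empty_model_list_gives_empty_records(self):
        assert generate_genomes([], seed=1) == []

    def test_every_segment_carries_a_long_planted_orf(self):
        model = virus(segments=(2000, 1500))
        records = generate_genomes([model], seed=7)
        assert [r.id for r in records] == ["v|seg1", "v|seg2"]
        assert [len(r.seq) for r in records] == [2000, 1500]
        for rec in records:
            orfs = brute_force_orfs(str(rec.seq), 150)
            assert any(frame == 1 for frame, _, _ in orfs)

    def test_same_seed_is_byte_identical(self):
        models = [virus(segments=(900, 600))]
        a = generate_genomes(models, seed=3)
        b = generate_genomes(models, seed=3)
        assert [str(r.seq) for r in a] == [str(r.seq) for r in b]
        c = generate_genomes(models, seed=4)
        assert [str(r.seq) for r in a] != [str(r.seq) for r in c]


class TestCounts:
    def test_zero_abundance_everywhere_gives_empty_table(self):
        models = [virus(abundance={"s1": 0.0})]
        counts = simulate_counts(models, [sample()], seed=1, host_coi_depth=0)
        assert counts.empty

    def test_positive_fraction_within_binomial_envelope(self):
        # ~10,000 reads at planted polarity 0.30
        lib = sample(total=12_500_000, rrna=0.2)  # 10 M non-rRNA
        model = virus(cls="minus_ss_rna", segments=(1000,), polarity=0.30,
                      abundance={"s1": 1000.0})
        counts = simulate_counts([model], [lib], seed=21, host_coi_depth=0)
        pos = int(counts.loc[counts["strand"] == "+", "count"].sum())
        total = int(counts["count"].sum())
        assert total > 5000
        lo, hi = logit_ci(pos, total, level=0.99)
        assert lo <= 0.30 <= hi

    def test_planted_abundance_round_trips_through_normalization(self):
        planted = 5.0
        lib = sample(total=12_500_000, rrna=0.2)
        model = virus(segments=(3000,), abundance={"s1": planted})
        counts = simulate_counts([model], [lib], seed=9, host_coi_depth=0)
        raw = int(counts["count"].sum())
        recovered = normalize(raw, 3000, lib.non_rrna_total)
        # Poisson error on the summed count, 4 sigma
        se = planted / np.sqrt(raw)
        assert recovered == pytest.approx(planted, abs=4 * se)

    def test_contamination_copies_reads_between_libraries(self):
        src = sample("src", total=2_000_000, rrna=0.0)
        recv = sample("recv", total=2_000_000, rrna=0.0, sources=(("src", 0.05),))
        model = virus(segments=(2000,), abundance={"src": 500.0})
        counts = simulate_counts([model], [src, recv], seed=2, host_coi_depth=0)
        leaked = counts.loc[counts["sample"] == "recv", "count"].sum()
        src_total = counts.loc[counts["sample"] == "src", "count"].sum()
        assert leaked > 0
        assert leaked == pytest.approx(0.05 * src_total, rel=0.25)


class TestHits:
    def test_no_viruses_and_no_decoys_classifies_nothing(self):
        from virosift.synthetic import generate_host_contigs

        contigs = generate_host_contigs(5, seed=1)
        hits = simulate_hits(contigs, [], decoy_fraction=0.0, seed=1)
        assert classify_viral(best_hits_by_contig(hits)) == set()

    def test_three_planted_viruses_recovered_as_three_groups(self):
        models = [
            virus("a", segments=(600,)),
            virus("b", segments=(700, 800)),
            virus("c", segments=(900,)),
        ]
        contigs = generate_genomes(models, seed=5)
        hits = simulate_hits(contigs, models, decoy_fraction=0.0, seed=5)
        viral = classify_viral(best_hits_by_contig(hits))
        groups = {cid.split("|")[0] for cid in viral}
        assert groups == {"a", "b", "c"}

    def test_equal_evalue_tie_fixture_emitted(self):
        models = [virus("a", segments=(600,))]
        contigs = generate_genomes(models, seed=5)
        hits = simulate_hits(contigs, models, decoy_fraction=0.0, seed=5)
        tied = [h for h in hits if h.qseqid == "a|seg1"]
        assert len(tied) == 2
        assert tied[0].evalue == tied[1].evalue
        assert tied[0].bitscore != tied[1].bitscore


class TestDataset:
    def test_identical_seeds_give_identical_datasets(self):
        a = generate_dataset(default_scenario(), seed=101)
        b = generate_dataset(default_scenario(), seed=101)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.coi, b.coi)
        assert [str(r.seq) for r in a.contigs] == [str(r.seq) for r in b.contigs]
        assert a.truth == b.truth

    def test_different_seeds_differ(self):
        a = generate_dataset(default_scenario(), seed=101)
        b = generate_dataset(default_scenario(), seed=102)
        assert not a.counts.equals(b.counts)

    def test_truth_lists_every_virus_planted_above_threshold(self, default_dataset):
        truth = default_dataset.truth
        threshold = truth["detection_threshold"]
        for v in truth["viruses"]:
            for sid, abundance in v["per_sample_abundance"].items():
                expected = v["name"] in truth["expected_detections"][sid]
                assert expected == (abundance >= threshold)

    def test_counts_are_nonnegative_integers(self, default_dataset):
        counts = default_dataset.counts
        assert (counts["count"] >= 0).all()
        assert counts["count"].dtype.kind == "i"

    def test_written_files_round_trip(self, dataset_paths):
        counts = pd.read_csv(dataset_paths["counts"], sep="\t")
        assert set(counts.columns) == {"sample", "reference", "strand", "count"}
        samples = pd.read_csv(dataset_paths["samples"], sep="\t")
        assert len(samples) == 5
        import json

        truth = json.loads(dataset_paths["truth"].read_text())
        assert len(truth["viruses"]) == 9
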