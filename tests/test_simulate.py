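from __future__ import annotations

import numpy as np
import pytest

from clonoscope.composition import middle_aa_frequencies
from clonoscope.diversity import expanded_read_fraction, normalized_shannon
from clonoscope.io import aggregate_clonotypes, read_airr, read_immunoseq, write_immunoseq
from clonoscope.simulate import (
    DirichletModel,
    SimParams,
    SpikeModel,
    derive_sample_seed,
    simulate_cohort,
    simulate_repertoire,
)
from clonoscope.vusage import usage_matrix


class TestModels:
    def test_invalid_params_rejected_before_sampling(self):
        with pytest.raises(ValueError):
            SpikeModel(m=3, f_e=0.4)  # m * f_e >= 1
        with pytest.raises(ValueError):
            DirichletModel(alpha=0.0)
        with pytest.raises(ValueError):
            SimParams(n_clonotypes=0).validate()
        with pytest.raises(ValueError):
            SimParams(length_dist={10: 0.5, 11: 0.4}).validate()  # does not sum to 1
        with pytest.raises(ValueError):
            SimParams(usage_shift={"NOT_A_GENE": 0.1}).validate()

    def test_spike_truth_mass(self):
        _, truth = simulate_repertoire(
            SimParams(n_clonotypes=100, depth=10_000, clone_model=SpikeModel(m=4, f_e=0.1), seed=0))
        assert truth.expanded_mass == pytest.approx(0.4)
        assert truth.clone_frequencies.sum() == pytest.approx(1.0)


class TestSimulateRepertoire:
    def test_depth_exactly_conserved(self):
        rep, _ = simulate_repertoire(SimParams(n_clonotypes=500, depth=12_345, seed=2))
        assert rep.total_count == 12_345

    def test_deterministic_and_byte_identical_output(self, tmp_path):
        params = SimParams(n_clonotypes=300, depth=5_000, seed=11)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_immunoseq(simulate_repertoire(params)[0], p1)
        write_immunoseq(simulate_repertoire(params)[0], p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_spike_expansion_recovered(self):
        params = SimParams(n_clonotypes=3000, depth=10**6,
                           clone_model=SpikeModel(m=3, f_e=0.05), seed=7)
        rep, truth = simulate_repertoire(params)
        assert truth.expanded_mass == pytest.approx(0.15)
        # the 2997 background clones sit at ~2.8e-4, well below 0.1%
        assert expanded_read_fraction(aggregate_clonotypes(rep, "nt"), 0.001) == pytest.approx(0.15, abs=0.01)

    def test_high_concentration_gives_high_evenness(self):
        rep, _ = simulate_repertoire(
            SimParams(n_clonotypes=1000, depth=100_000, clone_model=DirichletModel(alpha=50), seed=8))
        assert normalized_shannon(aggregate_clonotypes(rep, "nt")) > 0.95

    def test_generated_tables_pass_reader_validation(self, tmp_path):
        rep, _ = simulate_repertoire(SimParams(n_clonotypes=400, depth=8_000, seed=9))
        write_immunoseq(rep, tmp_path / "sim.tsv")
        back = read_immunoseq(tmp_path / "sim.tsv")
        agg = aggregate_clonotypes(back, "nt")
        assert agg.total_count == rep.total_count
        assert all(r.productive for r in back.records)

    def test_cdr3_anchors_and_length_support(self):
        rep, _ = simulate_repertoire(SimParams(n_clonotypes=200, depth=2_000, seed=10))
        for r in rep.records:
            assert r.cdr3_aa.startswith("C") and r.cdr3_aa.endswith("F")
            assert 9 <= len(r.cdr3_aa) <= 20
            assert len(r.cdr3_nt) == 3 * len(r.cdr3_aa)

    def test_middle_enrichment_truth_is_exact_delta(self):
        params = SimParams(middle_enrichment={"Y": 0.08})
        truth_probs = simulate_repertoire(
            SimParams(n_clonotypes=50, depth=500, middle_enrichment={"Y": 0.08}, seed=1))[1].middle_residue_probs
        assert truth_probs["Y"] == pytest.approx(0.05 + 0.08)
        assert sum(truth_probs.values()) == pytest.approx(1.0)

    def test_usage_shift_truth_is_exact_delta(self):
        _, truth = simulate_repertoire(
            SimParams(n_clonotypes=50, depth=500, usage_shift={"TCRBV05-01": 0.10}, seed=1))
        base = SimParams().v_gene_probs["TCRBV05-01"]
        assert truth.v_gene_probs["TCRBV05-01"] == pytest.approx(base + 0.10)
        assert sum(truth.v_gene_probs.values()) == pytest.approx(1.0)


class TestCohort:
    def test_two_groups_three_samples(self, tmp_path):
        groups = {
            "gA": SimParams(n_clonotypes=100, depth=1_000, seed=0),
            "gB": SimParams(n_clonotypes=100, depth=1_000, seed=0),
        }
        manifest, truths = simulate_cohort(groups, 3, tmp_path, master_seed=5)
        assert len(manifest) == 6
        assert sorted(truths) == sorted(manifest["sample_id"])
        assert (tmp_path / "manifest.tsv").exists()
        for path in manifest["path"]:
            assert read_immunoseq(path).total_count == 1_000

    def test_airr_output_format(self, tmp_path):
        manifest, _ = simulate_cohort({"g": SimParams(n_clonotypes=50, depth=500, seed=0)},
                                      1, tmp_path, master_seed=1, fmt="airr")
        rep = read_airr(manifest["path"][0])
        assert len(rep) > 0

    def test_per_sample_seeds_distinct_and_stable(self):
        seeds = [derive_sample_seed(42, i) for i in range(6)]
        assert len(set(seeds)) == 6
        assert seeds == [derive_sample_seed(42, i) for i in range(6)]
        assert all(0 <= s < 2**31 for s in seeds)

    def test_usage_shift_recovered_across_groups(self, tmp_path):
        delta = 0.10
        gene = "TCRBV05-01"
        k = 5000
        groups = {
            "ctrl": SimParams(n_clonotypes=k, depth=20_000, seed=0),
            "shift": SimParams(n_clonotypes=k, depth=20_000, usage_shift={gene: delta}, seed=0),
        }
        manifest, _ = simulate_cohort(groups, 3, tmp_path, master_seed=21)
        reps = [read_immunoseq(p, sample_id=s, group=g)
                for p, s, g in zip(manifest["path"], manifest["sample_id"], manifest["group"])]
        um = usage_matrix(reps, "nt").to_frame()
        ctrl = um.loc[[s for s in um.index if s.startswith("ctrl")], gene]
        shift = um.loc[[s for s in um.index if s.startswith("shift")], gene]
        diff = shift.mean() - ctrl.mean()
        p = SimParams().v_gene_probs[gene]
        se = np.sqrt((p * (1 - p) + (p + delta) * (1 - p - delta)) / k / 3)
        assert abs(diff - delta) < 3 * se

    def test_middle_enrichment_recovered(self, tmp_path):
        delta, background = 0.08, 0.05
        rep, truth = simulate_repertoire(
            SimParams(n_clonotypes=20_000, depth=200_000, middle_enrichment={"Y": delta}, seed=33))
        comp = middle_aa_frequencies(aggregate_clonotypes(rep, "nt"))
        p = background + delta
        se = np.sqrt(p * (1 - p) / comp.n_observations)
        assert abs(comp.freq["Y"] - p) < 3 * se
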