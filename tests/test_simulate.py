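"""Properties of the synthetic-data generator and its truth table."""

import numpy as np
import pytest

from cerna_forge.errors import SpecError
from cerna_forge.model import ExpressionMatrix
from cerna_forge.simulate import (
    SimulationSpec,
    simulate_annotations,
    simulate_expression,
    simulate_qpcr,
    simulate_sequences,
    simulate_term_map,
)
from cerna_forge.targets import seed_sequence


class TestSpecValidation:
    def test_triplets_cannot_exceed_pools(self):
        with pytest.raises(SpecError):
            SimulationSpec(n_lnc=5, n_mrna=50, n_mirna=50, n_triplets=6)

    def test_implied_r_bounds(self):
        with pytest.raises(SpecError):
            SimulationSpec(implied_r=1.0)

    def test_latent_loading_matches_implied_r(self):
        spec = SimulationSpec(implied_r=0.95, noise_sd=0.3)
        lam = spec.latent_loading
        assert lam**2 / (lam**2 + 0.3**2) == pytest.approx(0.95)


class TestSimulateExpression:
    def test_pure_noise_when_nothing_planted(self):
        spec = SimulationSpec(n_lnc=20, n_mrna=20, n_mirna=20, n_triplets=0,
                              n_de_lnc=0, n_de_mrna=0, n_de_mirna=0, seed=0)
        matrices, truth = simulate_expression(spec)
        assert truth.de_genes == {} and truth.planted_triplets == []
        # no structure: paired differences should be mean ~0
        m = matrices["mRNA"]
        case, control = m.paired_columns()
        diffs = m.values[case].to_numpy() - m.values[control].to_numpy()
        assert abs(diffs.mean()) < 0.05

    def test_same_seed_bitwise_identical(self, small_spec):
        a, _ = simulate_expression(small_spec)
        b, _ = simulate_expression(small_spec)
        for biotype in a:
            assert a[biotype].values.equals(b[biotype].values)

    def test_different_seed_differs(self, small_spec):
        import dataclasses
        a, _ = simulate_expression(small_spec)
        b, _ = simulate_expression(dataclasses.replace(small_spec, seed=small_spec.seed + 1))
        assert not a["mRNA"].values.equals(b["mRNA"].values)

    def test_planted_pairs_reach_target_correlation(self):
        # 50 pairs -> n=100 samples; Fisher-z sampling error at r=0.95 is
        # ~0.03 on the z scale, so every planted |r| should exceed 0.85
        rs = []
        for seed in range(20):
            spec = SimulationSpec(n_lnc=30, n_mrna=30, n_mirna=30, n_pairs=50,
                                  n_triplets=10, n_de_lnc=10, n_de_mrna=10,
                                  n_de_mirna=10, seed=seed)
            matrices, truth = simulate_expression(spec)
            values = {}
            for m in matrices.values():
                for g in m.gene_ids:
                    values[g] = m.values.loc[g].to_numpy()
            for lnc, mir, mrna in truth.planted_triplets:
                rs.append(np.corrcoef(values[lnc], values[mrna])[0, 1])
                rs.append(-np.corrcoef(values[lnc], values[mir])[0, 1])
                rs.append(-np.corrcoef(values[mir], values[mrna])[0, 1])
        assert min(rs) >= 0.85

    def test_truth_table_consistency(self, small_dataset):
        _, truth = small_dataset
        truth.validate()  # raises on violation
        for lnc, mir, mrna in truth.planted_triplets:
            assert truth.biotype_of[lnc] == "lncRNA"
            assert truth.biotype_of[mir] == "miRNA"
            assert truth.biotype_of[mrna] == "mRNA"
            # forced-DE default: opposite shifts for the miRNA vs its partners
            assert truth.de_genes[mir] == -truth.de_genes[lnc]
            assert truth.de_genes[lnc] == truth.de_genes[mrna]

    def test_truth_json_round_trip(self, tmp_path, small_dataset):
        _, truth = small_dataset
        truth.to_json(tmp_path / "truth.json")
        from cerna_forge.simulate import TruthTable
        back = TruthTable.from_json(tmp_path / "truth.json")
        assert back.de_genes == truth.de_genes
        assert back.planted_triplets == truth.planted_triplets
        assert back.planted_seed_sites == truth.planted_seed_sites
        assert back.planted_motif_sites == truth.planted_motif_sites


class TestSimulateSequences:
    def test_same_seed_identical(self, small_spec, small_dataset):
        _, truth = small_dataset
        a = simulate_sequences(truth, small_spec)
        b = simulate_sequences(truth, small_spec)
        assert a.sequences == b.sequences

    def test_planted_seed_written_as_reverse_complement(self, small_spec, small_dataset):
        _, truth = small_dataset
        seqs = simulate_sequences(truth, small_spec)
        for (mir, target), offset in truth.planted_seed_sites.items():
            site = seed_sequence(seqs[mir])
            assert seqs[target][offset:offset + 7] == site

    def test_background_7mer_frequency_near_uniform(self):
        # with no planted sites a fixed 7-mer appears ~ L * 4^-7 per sequence
        spec = SimulationSpec(n_lnc=50, n_mrna=50, n_mirna=5, n_triplets=0,
                              n_de_lnc=0, n_de_mrna=0, n_de_mirna=0,
                              lnc_length=1000, seed=3)
        counts, positions = 0, 0
        for seed in range(20):
            matrices, truth = simulate_expression(
                __import__("dataclasses").replace(spec, seed=seed))
            seqs = simulate_sequences(truth, spec, seed=seed + 1000)
            for lnc in (g for g, b in truth.biotype_of.items() if b == "lncRNA"):
                s = seqs[lnc]
                counts += sum(1 for i in range(len(s) - 6) if s[i:i + 7] == "GTGCCTT")
                positions += len(s) - 6
        expected = positions * 0.25**7
        sd = np.sqrt(expected)
        assert abs(counts - expected) < 6 * sd + 3

    def test_offset_beyond_length_rejected(self, small_spec, small_dataset):
        _, truth = small_dataset
        import copy
        bad = copy.deepcopy(truth)
        (mir, target), _ = next(iter(bad.planted_seed_sites.items()))
        bad.planted_seed_sites[(mir, target)] = 10_000
        with pytest.raises(SpecError):
            simulate_sequences(bad, small_spec)


class TestSimulateQpcr:
    def test_null_gene_fold_near_one_and_effect_gene_near_double(self):
        from cerna_forge.validation import ddct_fold_change
        folds_null, fold_ratios = [], []
        for seed in range(20):
            spec = SimulationSpec(n_lnc=10, n_mrna=10, n_mirna=10, n_triplets=2,
                                  n_de_lnc=4, n_de_mrna=4, n_de_mirna=4,
                                  de_log2fc=1.0, seed=seed)
            _, truth = simulate_expression(spec)
            de_gene = next(g for g, b in truth.biotype_of.items()
                           if b == "mRNA" and g in truth.de_genes)
            null_gene = next(g for g, b in truth.biotype_of.items()
                             if b == "mRNA" and g not in truth.de_genes)
            table = simulate_qpcr(truth, [de_gene, null_gene], n_pairs=12,
                                  seed=seed + 50)
            expected = 2.0 ** truth.de_genes[de_gene]
            fold_ratios.append(
                ddct_fold_change(table, de_gene, ["Actb"]).mean_fc / expected)
            folds_null.append(ddct_fold_change(table, null_gene, ["Actb"]).mean_fc)
        # a planted log2 effect e yields mean fold ~ 2^e; e=0 yields ~1
        assert np.mean(folds_null) == pytest.approx(1.0, abs=0.1)
        assert np.mean(fold_ratios) == pytest.approx(1.0, rel=0.12)

    def test_reference_gene_delta_ct_variance_bounded(self):
        spec = SimulationSpec(seed=5)
        _, truth = simulate_expression(
            SimulationSpec(n_lnc=10, n_mrna=10, n_mirna=10, n_triplets=2,
                           n_de_lnc=2, n_de_mrna=2, n_de_mirna=2, seed=5))
        noise_sd = 0.25
        table = simulate_qpcr(truth, [], n_pairs=50, seed=6, noise_sd=noise_sd)
        refs = table[table["is_reference"]]
        u6 = refs[refs["gene_id"] == "U6"].set_index("sample_id")["ct"]
        actb = refs[refs["gene_id"] == "Actb"].set_index("sample_id")["ct"]
        delta = (u6 - actb).to_numpy()
        # Var(Ct_u6 - Ct_actb) = 2 * noise_sd^2 (sample shift cancels)
        assert np.var(delta, ddof=1) < 2 * 2 * noise_sd**2

    def test_unknown_gene_rejected(self, small_dataset):
        _, truth = small_dataset
        with pytest.raises(SpecError):
            simulate_qpcr(truth, ["not_a_gene"], n_pairs=4, seed=0)


class TestAnnotationsAndTerms:
    def test_cis_pairs_planted_within_window(self, small_spec, small_dataset):
        from cerna_forge.targets import cis_targets
        _, truth = small_dataset
        anns = simulate_annotations(truth, small_spec, n_cis_pairs=3)
        by_id = {a.gene_id: a for a in anns}
        lnc = [by_id[t[0]] for t in truth.planted_triplets[:3]]
        mrna = [by_id[t[2]] for t in truth.planted_triplets[:3]]
        pairs = {(l, m) for l, m, _ in cis_targets(lnc, mrna, 10_000)}
        for (l, _, m) in truth.planted_triplets[:3]:
            assert (l, m) in pairs

    def test_enriched_term_contains_de_genes(self, small_spec, small_dataset):
        _, truth = small_dataset
        tm = simulate_term_map(truth, small_spec)
        de_mrnas = {g for g in truth.de_genes if truth.biotype_of[g] == "mRNA"}
        enriched = tm["path_enriched_00"]
        assert len(enriched & de_mrnas) >= len(enriched) * 0.4
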