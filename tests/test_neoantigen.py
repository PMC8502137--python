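"""Neoantigen layer: peptide windows, predictors, calling, burdens."""

import numpy as np
import pandas as pd
import pytest

from gcsubtype.neoantigen import (
    LookupPredictor,
    MissingAffinityError,
    ToyPredictor,
    call_neoantigens,
    compute_tmb,
    enumerate_mutant_peptides,
    nea_cluster,
    neoantigen_gene_matrix,
    toy_proteome,
    validate_calls,
)

from test_io import make_mutation


def brute_force_windows(protein, position, residue, lengths):
    """Independent oracle: enumerate every substring and keep those that
    contain the mutant site."""
    mutated = protein[: position - 1] + residue + protein[position:]
    out = []
    for length in lengths:
        for start in range(1, len(protein) - length + 2):
            if start <= position <= start + length - 1:
                out.append(mutated[start - 1: start - 1 + length])
    seen = set()
    return [p for p in out if not (p in seen or seen.add(p))]


class TestPeptideWindows:
    @pytest.mark.parametrize("position,lengths,expected_n", [
        (10, (9,), 9),   # interior: all 9 windows fit
        (3, (9,), 3),    # near N-terminus: windows starting 1..3
        (30, (9,), 9),   # near C-terminus of a 30-mer: starts 22..30 clipped
    ])
    def test_window_counts(self, position, lengths, expected_n):
        protein = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL"  # 30 aa, all distinct windows
        peptides = enumerate_mutant_peptides(protein, position, "W", lengths)
        if position == 30:
            expected_n = len(brute_force_windows(protein, position, "W", lengths))
        assert len(peptides) == expected_n

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=40))
        for position in (1, 7, 25, 40):
            ours = enumerate_mutant_peptides(protein, position, "M", (8, 9, 10, 11))
            oracle = brute_force_windows(protein, position, "M", (8, 9, 10, 11))
            assert ours == oracle

    def test_out_of_range_position_rejected(self):
        with pytest.raises(ValueError):
            enumerate_mutant_peptides("ACDEF" * 10, 51, "M")


class TestToyPredictor:
    def test_deterministic_and_consistent_with_batch(self):
        pred = ToyPredictor(seed=3)
        a = pred.predict("SIINFEKL", "HLA-A*02:01")
        b = pred.predict("SIINFEKL", "HLA-A*02:01")
        assert a == b
        batch = pred.predict_many(["SIINFEKL"], ["HLA-A*02:01"])
        assert batch[0] == a

    def test_binder_fraction_calibrated(self):
        """Fraction of random 9-mers under 500 nM sits within 0.1 +/- 0.01."""
        rng = np.random.default_rng(1)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        peptides = ["".join(rng.choice(aa, 9)) for _ in range(10_000)]
        pred = ToyPredictor(seed=0, binder_fraction=0.1)
        ic50 = pred.predict_many(peptides, ["HLA-A*02:01"] * len(peptides))
        assert abs((ic50 < 500).mean() - 0.1) < 0.01
        assert ic50.min() >= 1.0 and ic50.max() <= 50_000.0

    def test_lookup_miss_is_explicit_error(self):
        pred = LookupPredictor({("PEP", "HLA-A*02:01"): 100.0})
        assert pred.predict("PEP", "HLA-A*02:01") == 100.0
        with pytest.raises(MissingAffinityError):
            pred.predict("PEP", "HLA-B*58:01")


class FixedPredictor:
    """Scores every pair with one constant; batch-capable."""

    def __init__(self, ic50):
        self.ic50 = ic50

    def predict(self, peptide, allele):
        return self.ic50

    def predict_many(self, peptides, alleles):
        return np.full(len(peptides), self.ic50)


class TestCalling:
    def setup_method(self):
        self.proteome = toy_proteome(["TP53"])
        self.hla = {"S1": ["HLA-A*02:01", "HLA-B*58:01"]}
        self.mutation = make_mutation()

    def test_single_binding_peptide_gives_tnb_one(self):
        calls, burden = call_neoantigens([self.mutation], self.hla,
                                         FixedPredictor(400.0), self.proteome,
                                         lengths=(9,))
        assert burden.loc["S1", "tnb"] == 1
        assert burden.loc["S1", "tnb_peptides"] == len(calls)
        assert (calls["ic50_nM"] == 400.0).all()
        validate_calls(calls)

    def test_no_binders_gives_tnb_zero(self):
        calls, burden = call_neoantigens([self.mutation], self.hla,
                                         FixedPredictor(600.0), self.proteome)
        assert calls.empty
        assert burden.loc["S1", "tnb"] == 0

    def test_mutation_level_vs_peptide_level_counts(self):
        calls, burden = call_neoantigens([self.mutation], self.hla,
                                         FixedPredictor(10.0), self.proteome,
                                         lengths=(9,))
        assert burden.loc["S1", "tnb"] == 1           # one source mutation
        assert burden.loc["S1", "tnb_peptides"] > 1   # many windows bind

    def test_sample_without_hla_skipped(self):
        other = make_mutation(sample_id="S2")
        _, burden = call_neoantigens([self.mutation, other], self.hla,
                                     FixedPredictor(400.0), self.proteome)
        assert list(burden.index) == ["S1"]

    def test_row_order_invariance(self, small_cohort):
        missense = [m for m in small_cohort.mutations
                    if m.variant_class == "missense"][:60]
        proteome = toy_proteome(sorted({m.gene for m in missense}))
        pred = ToyPredictor(seed=0)
        calls_a, burden_a = call_neoantigens(missense, small_cohort.hla, pred, proteome)
        reversed_in = list(reversed(missense))
        calls_b, burden_b = call_neoantigens(reversed_in, small_cohort.hla, pred, proteome)
        pd.testing.assert_frame_equal(calls_a, calls_b)
        pd.testing.assert_frame_equal(burden_a, burden_b)

    def test_stored_calls_always_below_threshold(self):
        bad = pd.DataFrame({"ic50_nM": [400.0, 600.0]})
        with pytest.raises(ValueError):
            validate_calls(bad)


class TestBurdens:
    def test_tmb_counts_nonsynonymous_only(self):
        records = ([make_mutation(pos=i) for i in range(1, 11)]
                   + [make_mutation(pos=100 + i, variant_class="silent")
                      for i in range(5)])
        tmb = compute_tmb(records)
        assert tmb["S1"] == 10

    def test_empty_sample_zero(self):
        tmb = compute_tmb([make_mutation(variant_class="silent")])
        assert tmb["S1"] == 0

    def test_tnb_never_exceeds_tmb(self, small_cohort):
        from gcsubtype.pipeline import run_pipeline

        # mutation-level TNB counts a subset of non-synonymous mutations
        missense = [m for m in small_cohort.mutations if m.variant_class == "missense"]
        proteome = toy_proteome(sorted({m.gene for m in missense}))
        _, burden = call_neoantigens(missense, small_cohort.hla,
                                     ToyPredictor(seed=1), proteome)
        tmb = compute_tmb(small_cohort.mutations)
        assert (burden["tnb"] <= tmb.reindex(burden.index)).all()


class TestNeaCluster:
    def test_high_vs_zero_burden_split(self):
        matrix = pd.DataFrame(0, index=[f"S{i}" for i in range(10)],
                              columns=[f"G{i}" for i in range(20)])
        matrix.iloc[:5] = 1
        tnb = pd.Series([20] * 5 + [0] * 5, index=matrix.index, dtype=float)
        labels, report = nea_cluster(matrix, k=2, tnb=tnb)
        assert set(labels[:5]) == {1} and set(labels[5:]) == {2}
        assert report["tnb_medians_differ"]

    def test_degenerate_constant_matrix(self):
        matrix = pd.DataFrame(0, index=["A", "B", "C"], columns=["G1"])
        labels, report = nea_cluster(matrix, k=2)
        assert report["degenerate"]
        assert set(labels) == {1}

    def test_gene_matrix_from_calls(self):
        calls = pd.DataFrame({
            "sample_id": ["S1", "S1", "S2"], "gene": ["TP53", "TP53", "LRP1B"],
            "peptide": ["A", "B", "C"], "allele": ["x", "x", "y"],
            "ic50_nM": [10, 20, 30], "chrom": ["1"] * 3, "pos": [1, 1, 2],
        })
        matrix = neoantigen_gene_matrix(calls, ["S1", "S2", "S3"])
        assert matrix.loc["S1", "TP53"] == 1
        assert matrix.loc["S2", "LRP1B"] == 1
        assert matrix.loc["S3"].sum() == 0
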