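"""Synthetic data: trypsin digestion, digestion kinetics, LC-MS simulation."""

import numpy as np
import pytest

from specprofiler import (
    CleavageModel,
    classify_record,
    gillespie_digestion,
    parse_peptide,
    random_protein,
    simulate_digestion,
    simulate_lcms,
    trypsin_digest,
)
from specprofiler.peakgroups import RatioRecord

TIMES = [0.0, 30.0, 60.0, 120.0, 300.0]


class TestTrypsinDigest:
    def test_basic_rule(self):
        assert [p.sequence for p in trypsin_digest("AKCPR", 0)] == ["AK", "CPR"]

    def test_proline_suppression(self):
        assert [p.sequence for p in trypsin_digest("AKPGR", 0)] == ["AKPGR"]

    def test_missed_cleavage_products(self):
        seqs = {p.sequence for p in trypsin_digest("GQEFTITGQKRALEQATR", 1)}
        assert {"GQEFTITGQKR", "ALEQATR"} <= seqs
        assert "GQEFTITGQK" in seqs  # zero-missed product also present

    def test_min_len_filter(self):
        seqs = {p.sequence for p in trypsin_digest("AKCPR", 0, min_len=3)}
        assert seqs == {"CPR"}

    def test_reconstruction_on_random_proteins(self):
        """Zero-missed-cleavage products concatenate back to the protein."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            prot = random_protein(rng, int(rng.integers(10, 300)))
            parts = [p.sequence for p in trypsin_digest(prot, 0)]
            assert "".join(parts) == prot

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            trypsin_digest("")
        with pytest.raises(ValueError):
            trypsin_digest("AKX")


class TestDigestionKinetics:
    def test_inert_model_is_identity(self):
        p = parse_peptide("YGGFMKR")
        states = simulate_digestion(p, CleavageModel(rate={}), 100.0, TIMES)
        for st in states:
            assert st.fraction(p) == pytest.approx(1.0)

    def test_acidic_cterm_is_not_processed(self):
        p = parse_peptide("ARLSQKFPKAE")
        state = simulate_digestion(p, CleavageModel(), 100.0, [0.0, 300.0])[-1]
        assert state.fraction(p) == pytest.approx(1.0)

    def test_arg_removed_completely_within_300_min(self):
        """100 nM enzyme leaves <1% of a C-terminal-Arg peptide after 300
        min; the des-Arg product accumulates to >=99% when its own Lys
        terminus is blocked by the P1 context."""
        p = parse_peptide("YGGFMKR")
        model = CleavageModel(p1_modifier={"K": 1.0, "M": 0.0})
        state = simulate_digestion(p, model, 100.0, [0.0, 300.0])[-1]
        assert state.fraction(p) < 0.01
        assert state.fraction(parse_peptide("YGGFMK")) >= 0.99

    def test_default_model_arg_vs_lys_contrast(self):
        """Under the default model the Arg peptide is consumed while the
        Lys peptide is only partially processed at 300 min."""
        r_state = simulate_digestion(parse_peptide("YGGFMKR"), CleavageModel(),
                                     100.0, [0.0, 300.0])[-1]
        k_state = simulate_digestion(parse_peptide("YGGFMKK"), CleavageModel(),
                                     100.0, [0.0, 300.0])[-1]
        assert r_state.fraction(parse_peptide("YGGFMKR")) < 0.01
        k_remaining = k_state.fraction(parse_peptide("YGGFMKK"))
        assert 0.5 < k_remaining < 0.95  # cleaved, but only a small proportion

    def test_conservation(self):
        p = parse_peptide("ARLSQKFPKARR")
        for conc in (0.0, 1.0, 100.0):
            for st in simulate_digestion(p, CleavageModel(), conc, TIMES):
                assert sum(st.species.values()) == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_time_and_concentration(self):
        p = parse_peptide("YGGFMKR")
        fracs_t = [st.fraction(p) for st in
                   simulate_digestion(p, CleavageModel(), 10.0, TIMES)]
        assert all(b <= a + 1e-12 for a, b in zip(fracs_t, fracs_t[1:]))
        fracs_c = [simulate_digestion(p, CleavageModel(), c, [0.0, 60.0])[-1]
                   .fraction(p) for c in (0.1, 1.0, 10.0, 100.0)]
        assert all(b <= a + 1e-12 for a, b in zip(fracs_c, fracs_c[1:]))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            simulate_digestion(parse_peptide("AAR"), CleavageModel(), 1.0, [-1.0])

    def test_gillespie_matches_deterministic(self):
        p = parse_peptide("YGGFMKR")
        det = simulate_digestion(p, CleavageModel(), 100.0, TIMES)
        sto = gillespie_digestion(p, CleavageModel(), 100.0, TIMES,
                                  n_molecules=20000, seed=4)
        for d, s in zip(det, sto):
            for species, frac in d.species.items():
                assert s.fraction(species) == pytest.approx(frac, abs=0.02)


class TestSimulateLCMS:
    def test_same_seed_is_bitwise_identical(self, e2e_library):
        a = simulate_lcms(e2e_library, noise_cv=0.05, seed=9)
        b = simulate_lcms(e2e_library, noise_cv=0.05, seed=9)
        assert [(f.mz, f.intensity, f.retention_time, f.charge)
                for f in a.features] == \
               [(f.mz, f.intensity, f.retention_time, f.charge)
                for f in b.features]

    def test_uncleavable_peptide_has_unit_ratios_and_is_non_substrate(self):
        p = parse_peptide("IIEPSLL")
        exp = simulate_lcms([p], noise_cv=0.0, seed=0)
        assert all(v == pytest.approx(1.0)
                   for v in exp.noiseless_ratios[p].values())
        assert exp.truth[p] == "non_substrate"

    def test_strongly_cleavable_peptide_classified_good(self):
        """A peptide depleted below 40% at the top dose classifies good
        downstream of the noiseless ratios."""
        p = parse_peptide("GQEFTITGQKR")
        exp = simulate_lcms([p], noise_cv=0.0, seed=0)
        assert exp.noiseless_ratios[p][100.0] < 0.4
        rec = RatioRecord(p, dict(exp.noiseless_ratios[p]))
        assert classify_record(rec) == "good_substrate"
        assert exp.truth[p] == "good_substrate"

    def test_every_feature_traces_to_ground_truth(self, e2e_experiment):
        assert len(e2e_experiment.features) == len(e2e_experiment.feature_sources)
        labels = set(e2e_experiment.design.labels)
        for f, (pep, label, z) in zip(e2e_experiment.features,
                                      e2e_experiment.feature_sources):
            assert label in labels and f.charge == z

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            simulate_lcms([])
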