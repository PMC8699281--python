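"""Round-trip ranking, TYPICAL similarity, top-k protocol, CASMI scoring."""

import numpy as np
import pytest
from rdkit import Chem, DataStructs
from rdkit.Chem import AllChem, MACCSkeys

import ms2mol as m
from ms2mol.rank import FINGERPRINTS, tanimoto

FREE = m.FragmentationConfig(min_fragment_mass=0.0)


class TestTypicalSimilarity:
    def test_identical_molecules_score_one_under_every_encoding(self):
        for name in FINGERPRINTS:
            assert tanimoto("CCO", "OCC", name) == pytest.approx(1.0)
        score, _ = m.typical_similarity("CCO", "OCC")
        assert score == pytest.approx(1.0)

    def test_symmetry(self):
        ab, _ = m.typical_similarity("c1ccccc1O", "c1ccncc1")
        ba, _ = m.typical_similarity("c1ccncc1", "c1ccccc1O")
        assert ab == pytest.approx(ba)

    def test_max_aggregation_against_per_encoding_oracle(self):
        a = Chem.MolFromSmiles("c1ccccc1")
        b = Chem.MolFromSmiles("c1ccncc1")
        per_encoding = {
            "rdkit": DataStructs.TanimotoSimilarity(Chem.RDKFingerprint(a), Chem.RDKFingerprint(b)),
            "atom_pair": DataStructs.TanimotoSimilarity(
                AllChem.GetHashedAtomPairFingerprintAsBitVect(a, nBits=2048),
                AllChem.GetHashedAtomPairFingerprintAsBitVect(b, nBits=2048)),
            "torsion": DataStructs.TanimotoSimilarity(
                AllChem.GetHashedTopologicalTorsionFingerprintAsBitVect(a, nBits=2048),
                AllChem.GetHashedTopologicalTorsionFingerprintAsBitVect(b, nBits=2048)),
            "maccs": DataStructs.TanimotoSimilarity(MACCSkeys.GenMACCSKeys(a), MACCSkeys.GenMACCSKeys(b)),
            "morgan": DataStructs.TanimotoSimilarity(
                AllChem.GetMorganFingerprintAsBitVect(a, 2, nBits=2048),
                AllChem.GetMorganFingerprintAsBitVect(b, 2, nBits=2048)),
            "pattern": DataStructs.TanimotoSimilarity(
                Chem.PatternFingerprint(a), Chem.PatternFingerprint(b)),
        }
        score, which = m.typical_similarity("c1ccccc1", "c1ccncc1")
        assert score == pytest.approx(max(per_encoding.values()))
        assert per_encoding[which] == pytest.approx(score)

    def test_dominates_each_individual_encoding(self, fixture_molecules):
        a = fixture_molecules[0].smiles_canonical
        b = fixture_molecules[1].smiles_canonical
        score, _ = m.typical_similarity(a, b)
        for name in FINGERPRINTS:
            assert score >= tanimoto(a, b, name) - 1e-12


class TestRoundtripRank:
    def test_self_query_ranks_first_with_unit_score(self, fixture_molecules):
        candidates = [r.smiles_canonical for r in fixture_molecules[:5]]
        spec = m.fragment(candidates[2], FREE)
        ranked = m.roundtrip_rank(candidates, list(spec.peaks), FREE)
        assert ranked.top().smiles_canonical == candidates[2]
        assert ranked.entries[0][1] == pytest.approx(1.0)

    def test_scores_match_dense_cosine_oracle(self, fixture_molecules):
        candidates = [r.smiles_canonical for r in fixture_molecules[:5]]
        query_spec = m.fragment(candidates[0], FREE)
        query_bins = m.encode_spectrum([mz for mz in query_spec.peaks if mz < 500])
        ranked = m.roundtrip_rank(candidates, list(query_spec.peaks), FREE)
        qv = np.zeros(50_000)
        qv[list(query_bins.bins)] = 1
        for record, score, _ in ranked.entries:
            spec = m.fragment(record.smiles_canonical, FREE)
            cv = np.zeros(50_000)
            cv[[m.bin_index(mz) for mz in spec.peaks if mz < 500]] = 1
            expected = float(qv @ cv / (np.linalg.norm(qv) * np.linalg.norm(cv)))
            assert score == pytest.approx(expected, abs=1e-12)

    def test_duplicates_score_identically_with_stable_order(self):
        spec = m.fragment("CCO", FREE)
        ranked = m.roundtrip_rank(["CCO", "OCC", "CCN"], list(spec.peaks), FREE)
        assert ranked.entries[0][1] == ranked.entries[1][1] == pytest.approx(1.0)
        assert [e[0].smiles_canonical for e in ranked.entries[:2]] == ["CCO", "CCO"]

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            m.roundtrip_rank([], [100.0])

    def test_unfragmentable_candidate_scores_zero_with_warning(self):
        spec = m.fragment("CCO", FREE)
        with pytest.warns(UserWarning, match="round-trip"):
            ranked = m.roundtrip_rank(
                ["CCO", "[He]"], list(spec.peaks), FREE
            )
        scores = {e[0].smiles_canonical: e[1] for e in ranked.entries}
        assert scores["[He]"] == 0.0


class TestTopkProcedure:
    def test_single_peak_base_case(self, trained_toy_model, fixture_molecules):
        model, _ = trained_toy_model
        record = fixture_molecules[0]
        spectrum = m.ExperimentalSpectrum(
            peaks=((record.protonated_mz, 100.0),), precursor_mz=record.protonated_mz
        )
        config = m.EvalConfig(n_runs_per_k=10)
        merged, final = m.topk_procedure(
            spectrum, model, target_formula=record.formula, config=config, seed=0
        )
        assert merged.n_runs == 10  # exactly one iteration of 10 runs

    def test_missing_intensities_rejected(self, trained_toy_model):
        model, _ = trained_toy_model
        spectrum = m.ExperimentalSpectrum(peaks=((100.0, None), (120.0, None)))
        with pytest.raises(ValueError, match="intensities"):
            m.topk_procedure(spectrum, model, precursor_mz=120.0)

    def test_las_vegas_property_on_overfit_fixtures(
        self, trained_toy_model, fixture_molecules, fixture_dataset
    ):
        """The pipeline answers correctly or not at all, never confidently
        wrong: the most frequent formula-matching prediction for a training
        spectrum is the true molecule or absent."""
        model, _ = trained_toy_model
        by_mol = {s.molecule.smiles_canonical: s for s in fixture_dataset if s.depth == 3}
        for seed in (0, 1):
            for record in fixture_molecules[:8]:
                sample = by_mol[record.smiles_canonical]
                preds = m.sample_predictions(model, sample.input, n_runs=30, seed=seed)
                preds = m.formula_filter(preds, target_formula=record.formula)
                assert preds.most_frequent() in (record.smiles_canonical, None)


def _challenge(peaks=((100.0, 1.0), (150.0, 2.0)), mode="positive", smiles="CCO"):
    return (peaks, mode, smiles)


class TestCasmiFilter:
    def test_rule_composition(self):
        challenges = [
            _challenge(),
            _challenge(mode="NEGATIVE"),
            _challenge(peaks=((512.3, 1.0),)),
            _challenge(peaks=tuple((1.0 + 0.1 * k, 1.0) for k in range(100))),
            _challenge(smiles="C" * 100),
            _challenge(),
        ]
        kept, counts = m.casmi_filter(challenges)
        assert kept == [0, 5]
        assert counts == {
            "malformed": 0, "ion_mode": 1, "mz_range": 1,
            "peak_count": 1, "smiles_length": 1, "retained": 2,
        }

    def test_boundaries_are_strict(self):
        # a single peak at exactly 500 and a 99-peak spectrum
        at_limit = [
            _challenge(peaks=((500.0, 1.0),)),
            _challenge(peaks=tuple((1.0 + 0.5 * k, 1.0) for k in range(99))),
        ]
        kept, counts = m.casmi_filter(at_limit)
        assert kept == [1]
        assert counts["mz_range"] == 1

    def test_pure_function(self):
        challenges = [_challenge(), _challenge(mode="negative")]
        assert m.casmi_filter(challenges) == m.casmi_filter(challenges)


class TestCasmiScore:
    def _preds(self, smiles_list):
        tally = {m.canonicalize(s): 1 for s in smiles_list}
        return m.PredictionSet(
            raw_outputs=tuple(smiles_list),
            unique_canonical=tally,
            n_invalid=0,
            formula_filtered=tally,
        )

    def test_truth_in_set_is_correct(self):
        outcome = m.casmi_score(self._preds(["OCC", "CCN"]), "CCO")
        assert outcome.category == "correct"
        assert outcome.best_ts == 1.0

    def test_formula_isomers_without_truth_are_unknown(self):
        # C3H8O isomers of propanol, truth not among them
        outcome = m.casmi_score(self._preds(["COC", "CC(C)O"]), "CCCO")
        assert outcome.category == "unknown"
        assert 0 <= outcome.best_ts < 1.0

    def test_empty_filtered_set_is_no_prediction(self):
        outcome = m.casmi_score(self._preds([]), "CCO")
        assert outcome.category == "no_prediction"

    def test_typical_flag_reports_at_least_single_fingerprint_ts(self):
        preds = self._preds(["COC"])
        single = m.casmi_score(preds, "CCO", use_typical=False)
        typical = m.casmi_score(preds, "CCO", use_typical=True)
        assert typical.best_ts >= single.best_ts


class TestExpandCandidatesHook:
    def test_default_returns_input(self):
        out = m.expand_candidates("CCO")
        assert [r.smiles_canonical for r in out] == ["CCO"]
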