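import numpy as np
import pytest

from pipesim.abundance_model import GroundTruthSamples
from pipesim.detection import ObservedPeptideTable
from pipesim.rollup import (
    STAGE_CORRELATION,
    STAGE_MISSING_RATE,
    STAGE_NON_UNIQUE,
    STAGE_PASSED,
    RollupConfig,
    estimate_protein,
    filter_peptides,
    missing_value_rates,
    quantification_error,
)


def _table(catalog, abundance, observed=None):
    n_pep, n_s = abundance.shape
    observed = np.ones_like(abundance, bool) if observed is None else observed
    return ObservedPeptideTable(
        detected=observed.copy(),
        identified=observed.copy(),
        observed=observed,
        abundance=np.where(observed, abundance, np.nan),
        identifiability=np.full(n_pep, 0.5),
        overlap_count=np.ones(n_pep, int),
    )


@pytest.fixture
def toy_table(toy_catalog):
    """Fully observed table where each peptide's abundance equals the sum of
    its parents' (index+1)*10 signature, constant across 10 samples."""
    base = {p.id: (i + 1) * 10.0 for i, p in enumerate(toy_catalog.proteins)}
    rng = np.random.default_rng(0)
    profile = rng.uniform(0.8, 1.2, 10)  # shared sample profile => corr 1
    ab = np.array(
        [sum(base[pid] for pid in pep.parents) * profile
         for pep in toy_catalog.peptides]
    )
    return _table(toy_catalog, ab)


class TestFilters:
    def test_shared_peptide_removed_first(self, toy_catalog, toy_table):
        survivors, audit = filter_peptides(toy_table, toy_catalog)
        shared = toy_catalog.peptide_by_sequence()["SSSEEEGGGK"]
        assert audit[shared.id] == STAGE_NON_UNIQUE
        assert all(shared.id not in v for v in survivors.values())

    def test_high_missing_rate_removed_second(self, toy_catalog, toy_table):
        obs = np.ones_like(toy_table.observed)
        target = 0  # first peptide observed in only 1 of 10 samples (rate 0.9)
        obs[target, 1:] = False
        table = _table(toy_catalog, np.nan_to_num(toy_table.abundance, nan=1.0), obs)
        _, audit = filter_peptides(table, toy_catalog)
        assert audit[toy_catalog.peptides[target].id] == STAGE_MISSING_RATE

    def test_correlated_siblings_retained(self, toy_catalog, toy_table):
        survivors, audit = filter_peptides(toy_table, toy_catalog)
        # T3's three unique peptides share a perfectly correlated profile
        t3 = survivors["T3"]
        assert len(t3) == 3
        for i in t3:
            assert audit[toy_catalog.peptides[i].id] == STAGE_PASSED

    def test_lone_peptide_fails_correlation_stage(self, toy_catalog, toy_table):
        survivors, audit = filter_peptides(toy_table, toy_catalog)
        # T5 has a single unique peptide: no sibling, no qualifying correlation
        assert "T5" not in survivors
        lone = toy_catalog.peptide_by_sequence()["ACDEFGHIK"]
        assert audit[lone.id] == STAGE_CORRELATION

    def test_uncorrelated_sibling_dropped(self, toy_catalog, toy_table):
        ab = np.nan_to_num(toy_table.abundance, nan=0.0).copy()
        seqs = [p.sequence for p in toy_catalog.peptides]
        bad = seqs.index("AAAGGGK")  # T1 peptide with an anti-correlated profile
        ab[bad] = ab[bad][::-1] * np.array([1, -1] * 5) + 100
        table = _table(toy_catalog, ab)
        survivors, audit = filter_peptides(table, toy_catalog)
        assert bad not in survivors.get("T1", [])
        assert audit[toy_catalog.peptides[bad].id] == STAGE_CORRELATION

    def test_too_few_common_samples_give_no_correlation(self, toy_catalog, toy_table):
        # T4's peptides observed in disjoint sample sets: no pair shares >= 3
        obs = np.ones_like(toy_table.observed)
        seqs = [p.sequence for p in toy_catalog.peptides]
        t4 = [seqs.index(s) for s in ("NNNQQQR", "TTTWWWR", "VVVYYYR")]
        obs[t4[0], 5:] = False
        obs[t4[1], :5] = False
        obs[t4[2], :5] = False
        obs[t4[2], 7:] = False  # only samples 5,6 shared with t4[1]
        table = _table(toy_catalog, np.nan_to_num(toy_table.abundance, nan=1.0), obs)
        survivors, _ = filter_peptides(table, toy_catalog)
        assert "T4" not in survivors

    def test_relaxing_thresholds_never_shrinks_survivors(self, toy_catalog):
        rng = np.random.default_rng(3)
        ab = rng.uniform(10, 100, (toy_catalog.n_pep, 20))
        obs = rng.random(ab.shape) < 0.6
        table = _table(toy_catalog, ab, obs)
        strict, _ = filter_peptides(
            table, toy_catalog, RollupConfig(max_missing_rate=0.3, min_corr=0.6)
        )
        loose, _ = filter_peptides(
            table, toy_catalog, RollupConfig(max_missing_rate=0.8, min_corr=-1.0)
        )
        for pid, idxs in strict.items():
            assert set(idxs) <= set(loose.get(pid, []))


class TestEstimate:
    def test_mean_then_divide_by_kappa(self, toy_catalog):
        ab = np.zeros((toy_catalog.n_pep, 2))
        seqs = [p.sequence for p in toy_catalog.peptides]
        i, j = seqs.index("DDDEEEK"), seqs.index("GGGHHHK")
        ab[i] = [10.0, 10.0]
        ab[j] = [20.0, 20.0]
        table = _table(toy_catalog, ab)
        est = estimate_protein(table, {"T3": [i, j]}, toy_catalog, kappa=5.0)
        t3 = est.protein_ids.index("T3")
        assert est.abundance_hat[t3, 0] == 15.0
        assert est.conc_hat[t3, 0] == 3.0

    def test_single_survivor_protein_not_quantified(self, toy_catalog):
        ab = np.full((toy_catalog.n_pep, 2), 10.0)
        table = _table(toy_catalog, ab)
        est = estimate_protein(table, {"T3": [0]}, toy_catalog, kappa=5.0)
        t3 = est.protein_ids.index("T3")
        assert np.all(est.abundance_hat[t3] == 0)
        assert not est.quantified[t3]

    def test_sample_with_no_observed_survivor_gets_zero(self, toy_catalog):
        ab = np.full((toy_catalog.n_pep, 3), 10.0)
        obs = np.ones_like(ab, bool)
        seqs = [p.sequence for p in toy_catalog.peptides]
        i, j = seqs.index("DDDEEEK"), seqs.index("GGGHHHK")
        obs[i, 2] = obs[j, 2] = False
        table = _table(toy_catalog, ab, obs)
        est = estimate_protein(table, {"T3": [i, j]}, toy_catalog, kappa=1.0)
        t3 = est.protein_ids.index("T3")
        assert est.abundance_hat[t3, 0] == 10.0
        assert est.abundance_hat[t3, 2] == 0.0
        assert est.quantified[t3]


def _truth_like(est, conc):
    n_pro, n_s = conc.shape
    return GroundTruthSamples(
        concentrations=conc,
        class_labels=np.array([0] * (n_s // 2) + [1] * (n_s - n_s // 2)),
        eta=conc[:, 0].copy(),
        fold=np.ones(n_pro),
        marker_ids=[],
        protein_ids=list(est.protein_ids),
    )


class TestQuantificationError:
    def _estimate(self, conc_hat, kappa=1.0):
        from pipesim.rollup import ProteinEstimate

        return ProteinEstimate(
            abundance_hat=conc_hat * kappa,
            conc_hat=conc_hat,
            quantified=conc_hat.any(axis=1),
            filter_audit={},
            protein_ids=[f"P{i}" for i in range(conc_hat.shape[0])],
        )

    def test_perfect_estimate_is_zero(self):
        conc = np.random.default_rng(1).uniform(10, 100, (4, 6))
        est = self._estimate(conc.copy())
        assert quantification_error(_truth_like(est, conc), est) == 0.0

    def test_all_zero_estimate_is_one(self):
        conc = np.random.default_rng(2).uniform(10, 100, (4, 6))
        est = self._estimate(np.zeros_like(conc))
        assert quantification_error(_truth_like(est, conc), est) == 1.0

    def test_half_perfect_half_zero(self):
        conc = np.random.default_rng(3).uniform(10, 100, (4, 6))
        chat = conc.copy()
        chat[2:] = 0.0
        est = self._estimate(chat)
        assert quantification_error(_truth_like(est, conc), est) == pytest.approx(0.5)

    def test_zero_true_concentration_excluded_with_warning(self, caplog):
        conc = np.ones((2, 2))
        conc[0, 0] = 0.0
        est = self._estimate(conc.copy())
        with caplog.at_level("WARNING"):
            qerr = quantification_error(_truth_like(est, conc), est)
        assert qerr == 0.0
        assert "zero true concentration" in caplog.text


class TestMissingRates:
    def test_everything_observed_and_quantified(self, toy_catalog):
        ab = np.full((toy_catalog.n_pep, 4), 5.0)
        table = _table(toy_catalog, ab)
        seqs = [p.sequence for p in toy_catalog.peptides]
        survivors = {"T3": [seqs.index("DDDEEEK"), seqs.index("GGGHHHK")]}
        est = estimate_protein(table, survivors, toy_catalog, kappa=1.0)
        pep_rate, pro_rate = missing_value_rates(table, est)
        assert pep_rate == 0.0
        assert pro_rate == pytest.approx(4 / 5)  # only T3 quantified

    def test_nothing_observed(self, toy_catalog):
        ab = np.zeros((toy_catalog.n_pep, 4))
        table = _table(toy_catalog, ab, np.zeros_like(ab, bool))
        est = estimate_protein(table, {}, toy_catalog, kappa=1.0)
        assert missing_value_rates(table, est) == (1.0, 1.0)
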