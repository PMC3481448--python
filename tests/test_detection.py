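import numpy as np
import pytest

from pipesim.detection import (
    DetectionConfig,
    assign_identifiability,
    detect_ms1,
    identify_ms2,
    link,
    overlap_counts,
    snr,
    tpr,
)
from pipesim.proteome import Peptide, Protein, ProteomeCatalog


def _fake_catalog(masses, rts):
    """Catalog with hand-set peptide masses and RTs (sequence irrelevant)."""
    prot = Protein(id="P0", sequence="AAAK")
    peps = [
        Peptide(id=f"p{i}", sequence=f"A{i}", mono_mass=m, rt=r,
                parents=frozenset({"P0"}))
        for i, (m, r) in enumerate(zip(masses, rts))
    ]
    return ProteomeCatalog(proteins=[prot], peptides=peps)


class TestSnr:
    def test_zero_signal_has_zero_snr(self):
        assert snr(np.array([0.0]), 0.03, 3.6)[0] == 0.0

    def test_direct_evaluation(self):
        # mu/(alpha*mu + beta) at mu = 120: 120 / (3.6 + 3.6)
        assert snr(np.array([120.0]), 0.03, 3.6)[0] == pytest.approx(50.0 / 3.0)

    def test_saturates_at_inverse_alpha(self):
        assert snr(np.array([1e12]), 0.03, 3.6)[0] == pytest.approx(1 / 0.03, rel=1e-4)

    def test_monotone_in_mu(self):
        mu = np.linspace(0, 1e5, 1000)
        s = snr(mu, 0.03, 3.6)
        assert np.all(np.diff(s) >= 0)

    def test_noiseless_signal_is_infinite(self):
        s = snr(np.array([0.0, 5.0]), 0.0, 0.0)
        assert s[0] == 0.0 and np.isinf(s[1])


class TestOverlap:
    def test_close_mass_and_rt_overlap(self):
        # relative mass gap 5e-6 < 1e-5 at resolution 1e5, same RT
        oc = overlap_counts(
            _fake_catalog([1000.0, 1000.005], [500.0, 500.0]), 1e5, 1000
        )
        assert list(oc) == [2, 2]

    def test_isolated_peptide_counts_itself(self):
        oc = overlap_counts(_fake_catalog([1000.0], [500.0]), 1e5, 1000)
        assert list(oc) == [1]

    def test_distant_masses_never_overlap(self):
        oc = overlap_counts(
            _fake_catalog([1000.0, 1100.0], [500.0, 500.0]), 1e9, 1000
        )
        assert list(oc) == [1, 1]

    def test_close_mass_distant_rt_do_not_overlap(self):
        oc = overlap_counts(
            _fake_catalog([1000.0, 1000.005], [100.0, 900.0]), 1e5, 1000
        )
        assert list(oc) == [1, 1]

    def test_three_way_clash(self):
        oc = overlap_counts(
            _fake_catalog([1000.0, 1000.002, 1000.004], [500.0] * 3), 1e5, 1000
        )
        assert list(oc) == [3, 3, 3]


class TestTpr:
    def test_polynomial_curve_clamped_at_one(self):
        cfg = DetectionConfig(k=0.0016, p=2, b=0)
        out = tpr(np.array([[25.0]]), np.array([1]), cfg)
        assert out[0, 0] == 1.0  # 0.0016 * 625 = 1.0 exactly

    def test_floor_at_zero_snr(self):
        cfg = DetectionConfig(b=0.0)
        assert tpr(np.array([[0.0]]), np.array([1]), cfg)[0, 0] == 0.0
        cfg_b = DetectionConfig(b=0.1)
        assert tpr(np.array([[0.0]]), np.array([1]), cfg_b)[0, 0] == 0.1

    def test_overlap_sensitive_attenuation(self):
        cfg = DetectionConfig(k=0.0016, p=2, b=0, overlap_aware=False)
        out = tpr(np.array([[25.0]]), np.array([4]), cfg)
        assert out[0, 0] == pytest.approx(0.25)

    def test_perfect_detection_flag(self):
        cfg = DetectionConfig(perfect_detection=True)
        out = tpr(np.array([[0.0, 1e-9, 50.0]]), np.array([1]), cfg)
        assert list(out[0]) == [0.0, 1.0, 1.0]

    def test_infinite_snr_handled(self):
        cfg = DetectionConfig()
        assert tpr(np.array([[np.inf]]), np.array([1]), cfg)[0, 0] == 1.0


class TestDetectMs1:
    def test_degenerate_rates(self):
        assert np.all(detect_ms1(np.ones((5, 5)), seed=1))
        assert not np.any(detect_ms1(np.zeros((5, 5)), seed=1))

    def test_binomial_concentration(self):
        det = detect_ms1(np.full((1000, 100), 0.3), seed=2)
        assert det.mean() == pytest.approx(0.3, abs=0.01)

    def test_dominance_under_shared_seed(self):
        """With identical seeds, an overlap-aware algorithm detects a superset
        of what an overlap-sensitive one detects."""
        rng = np.random.default_rng(0)
        s = rng.uniform(0, 30, (200, 20))
        overlap = rng.integers(1, 5, 200)
        aware = tpr(s, overlap, DetectionConfig(overlap_aware=True))
        sens = tpr(s, overlap, DetectionConfig(overlap_aware=False))
        d_aware = detect_ms1(aware, seed=7)
        d_sens = detect_ms1(sens, seed=7)
        assert np.all(d_aware | ~d_sens)  # sens => aware, cellwise

    def test_out_of_range_tpr_rejected(self):
        with pytest.raises(ValueError):
            detect_ms1(np.array([[1.5]]), seed=0)


class TestIdentifiability:
    def test_beta_model_mean(self):
        cat = _fake_catalog(
            np.linspace(500, 4000, 100_000), np.full(100_000, 500.0)
        )
        p = assign_identifiability(cat, DetectionConfig(), seed=3)
        assert p.mean() == pytest.approx(0.2, abs=0.005)
        assert np.all((p >= 0) & (p <= 1))

    def test_deterministic_given_seed(self, toy_catalog):
        a = assign_identifiability(toy_catalog, DetectionConfig(), seed=4)
        b = assign_identifiability(toy_catalog, DetectionConfig(), seed=4)
        assert np.array_equal(a, b)

    def test_logistic_model_is_sequence_determined(self, toy_catalog):
        cfg = DetectionConfig(identifiability_model="logistic")
        a = assign_identifiability(toy_catalog, cfg, seed=1)
        b = assign_identifiability(toy_catalog, cfg, seed=999)
        assert np.array_equal(a, b)
        assert np.all((a > 0) & (a < 1))

    def test_perfect_model(self, toy_catalog):
        cfg = DetectionConfig(identifiability_model="perfect")
        assert np.all(assign_identifiability(toy_catalog, cfg, seed=0) == 1.0)

    def test_unknown_model_rejected(self, toy_catalog):
        with pytest.raises(ValueError):
            assign_identifiability(
                toy_catalog, DetectionConfig(identifiability_model="magic"), seed=0
            )


class TestIdentifyMs2:
    def test_replicates_boost_per_cell_rate(self):
        p = np.full(1000, 0.5)
        ident = identify_ms2(p, n_samples=100, n_replicates=2, seed=5)
        assert ident.mean() == pytest.approx(0.75, abs=0.01)

    def test_degenerate_probabilities(self):
        assert not np.any(identify_ms2(np.zeros(10), 50, 3, seed=6))
        assert np.all(identify_ms2(np.ones(10), 50, 1, seed=6))

    def test_monotone_in_replicates(self):
        p = np.full(2000, 0.2)
        rates = [
            identify_ms2(p, 100, r, seed=8).mean() for r in (1, 2, 4)
        ]
        assert rates[0] < rates[1] < rates[2]


class TestLink:
    def test_and_rule(self):
        detected = np.array([[True, True, False, False]])
        identified = np.array([[True, False, True, False]])
        v = np.array([[10.0, 20.0, 30.0, 40.0]])
        table = link(detected, identified, v, np.array([0.5]), np.array([1]))
        assert list(table.observed[0]) == [True, False, False, False]
        assert table.abundance[0, 0] == 10.0
        assert np.all(np.isnan(table.abundance[0, 1:]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            link(np.ones((1, 2), bool), np.ones((1, 3), bool),
                 np.ones((1, 2)), np.array([0.5]), np.array([1]))


def test_tpr_curve_recovery_by_regression():
    """Empirical detection rates regressed on SNR^p recover the gain k."""
    rng = np.random.default_rng(42)
    s = rng.uniform(0, 20, (1000, 100))  # TPR = 0.0016 s^2 <= 0.64, unclamped
    cfg = DetectionConfig(k=0.0016, p=2, b=0)
    rates = tpr(s, np.ones(1000, dtype=int), cfg)
    det = detect_ms1(rates, seed=11)
    x = (s**2).ravel()
    k_hat = (det.ravel() @ x) / (x @ x)
    assert k_hat == pytest.approx(0.0016, rel=0.1)
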