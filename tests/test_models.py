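"""Model-contract tests: HLR closed forms and recovery, GBT and FFNN
capacity checks, deep-set permutation invariance, prediction modes."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse
from scipy.special import expit, logit

from readmit.embedding import EmbeddingTable
from readmit.models import (HospitalAssignment, encode_cohort,
                            fit_deepset, fit_ffnn, fit_gbt, fit_hlr)
from readmit.models.hlr import HLRModel


def _sim_glmm(rng, n_hosp, per_hosp, sigma, beta):
    """Simulate a logistic random-intercept dataset with known truth."""
    H = n_hosp
    u = rng.normal(0, sigma, H)
    n = n_hosp * per_hosp
    hosp = np.repeat(np.arange(H), per_hosp)
    X = rng.normal(size=(n, len(beta) - 1))
    eta = beta[0] + X @ beta[1:] + u[hosp]
    y = (rng.random(n) < expit(eta)).astype(int)
    return X, hosp, y, u


class TestHLR:
    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(0)
        y = (rng.random(5000) < 0.2).astype(int)
        hosp = np.zeros(5000, dtype=int)
        m = fit_hlr(np.empty((5000, 0)), hosp, y, fixed_sigma=0.0)
        assert m.beta[0] == pytest.approx(logit(y.mean()), abs=1e-3)

    def test_recovery_sigma_zero(self):
        # data generated without hospital effects: fitted sigma collapses
        rng = np.random.default_rng(1)
        beta = np.array([-1.5, 0.8, -0.5])
        X, hosp, y, _ = _sim_glmm(rng, 100, 500, 0.0, beta)
        m = fit_hlr(X, hosp, y)
        assert m.sigma_u < 0.05
        se = 3.0 / np.sqrt(len(y))  # generous CI at n=50,000
        for b_hat, b_true in zip(m.beta, beta):
            assert b_hat == pytest.approx(b_true, abs=5 * se + 0.05)

    def test_recovery_sigma_04(self):
        # 200 hospitals x 250 admissions, sigma_u = 0.4
        rng = np.random.default_rng(2)
        beta = np.array([-2.0, 0.5])
        X, hosp, y, _ = _sim_glmm(rng, 200, 250, 0.4, beta)
        m = fit_hlr(X, hosp, y)
        assert 0.3 <= m.sigma_u <= 0.5

    def test_matches_lme4_glmer_laplace(self, tmp_path):
        """Cross-check the Laplace fit against R lme4's glmer (nAGQ=1),
        which maximizes the same approximate marginal likelihood."""
        import shutil
        import subprocess
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(3)
        beta = np.array([-1.0, 0.7])
        X, hosp, y, _ = _sim_glmm(rng, 30, 100, 0.5, beta)
        df = pd.DataFrame({"y": y, "x": X[:, 0], "h": hosp})
        csv = tmp_path / "glmm.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            'd <- read.csv("%s")\n'
            "suppressMessages(library(lme4))\n"
            "m <- glmer(y ~ x + (1|h), data=d, family=binomial, nAGQ=1)\n"
            "cat(fixef(m), sqrt(unlist(VarCorr(m))))\n" % csv)
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        r_b0, r_b1, r_sigma = map(float, out.stdout.split())
        m = fit_hlr(X, hosp, y)
        assert m.beta[0] == pytest.approx(r_b0, abs=0.02)
        assert m.beta[1] == pytest.approx(r_b1, abs=0.02)
        assert m.sigma_u == pytest.approx(r_sigma, abs=0.03)

    def test_degenerate_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_hlr(np.zeros((10, 1)), np.zeros(10, dtype=int),
                    np.zeros(10))


class TestPredictionModes:
    @pytest.fixture()
    def hand_model(self):
        # beta = (-2, 1), u known for two hospitals
        return HLRModel(beta=np.array([-2.0, 1.0]), sigma_u=0.5,
                        u=np.array([0.5, -0.25]),
                        hospital_index={"A": 0, "B": 1})

    def test_closed_form_probabilities(self, hand_model):
        X = np.array([[0.0], [1.0], [0.0]])
        hosp = np.array(["A", "A", "B"])
        p = hand_model.predict((X, hosp))
        expected = expit(np.array([-2 + 0.5, -1 + 0.5, -2 - 0.25]))
        np.testing.assert_allclose(p, expected, atol=1e-12)

    def test_forced_minus_population_is_u_on_logit_scale(self, hand_model):
        X = np.array([[0.3], [1.2], [-0.7]])
        hosp = np.array(["A", "B", "A"])
        p_forced = hand_model.predict((X, hosp), HospitalAssignment.forced("A"))
        p_pop = hand_model.predict((X, hosp), HospitalAssignment.POPULATION)
        np.testing.assert_allclose(logit(p_forced) - logit(p_pop), 0.5,
                                   atol=1e-12)

    def test_forced_zero_u_equals_population(self, hand_model):
        hand_model.u = np.array([0.0, -0.25])
        X = np.array([[0.3], [1.2]])
        hosp = np.array(["A", "B"])
        np.testing.assert_allclose(
            hand_model.predict((X, hosp), HospitalAssignment.forced("A")),
            hand_model.predict((X, hosp), HospitalAssignment.POPULATION),
            atol=1e-15)

    def test_unknown_forced_hospital_rejected(self, hand_model):
        with pytest.raises(ValueError):
            hand_model.predict((np.zeros((1, 1)), np.array(["A"])),
                               HospitalAssignment.forced("Z"))


def _toy_classification(rng, n=600, d=12):
    X = rng.normal(size=(n, d))
    w = rng.normal(size=d)
    y = (X @ w > 0).astype(int)  # linearly separable
    return sparse.csr_matrix(X), y


class TestGBT:
    def test_zero_rounds_constant_base_rate(self):
        rng = np.random.default_rng(0)
        X, y = _toy_classification(rng)
        m = fit_gbt(X, y, X, y, n_rounds=0)
        p = m.predict(X)
        assert np.allclose(p, p[0])
        assert p[0] == pytest.approx(y.mean(), abs=0.02)

    def test_separable_data_auc_approaches_one(self):
        rng = np.random.default_rng(1)
        X, y = _toy_classification(rng)
        m = fit_gbt(X, y, X, y, learning_rate=0.3, n_rounds=200,
                    early_stopping_rounds=50)
        from readmit.evaluation import compute_auc
        assert compute_auc(y, m.predict(X)) > 0.98

    def test_empty_features_rejected(self):
        with pytest.raises(ValueError):
            fit_gbt(sparse.csr_matrix((5, 0)), np.zeros(5),
                    sparse.csr_matrix((5, 0)), np.zeros(5))


class TestFFNN:
    def test_softmax_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        X, y = _toy_classification(rng, n=300)
        m = fit_ffnn(X, y, X, y, hidden=(16, 8), max_epochs=3, seed=0)
        P = m.predict_classes_proba(X)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_inference_deterministic(self):
        rng = np.random.default_rng(3)
        X, y = _toy_classification(rng, n=300)
        m = fit_ffnn(X, y, X, y, hidden=(16, 8), max_epochs=3, seed=0)
        np.testing.assert_array_equal(m.predict(X), m.predict(X))

    def test_learns_separable_data(self):
        rng = np.random.default_rng(4)
        X, y = _toy_classification(rng, n=800)
        m = fit_ffnn(X, y, X, y, hidden=(32, 16), learning_rate=0.01,
                     max_epochs=60, patience=60, seed=1)
        from readmit.evaluation import compute_auc
        assert compute_auc(y, m.predict(X)) > 0.95

    def test_seeded_fit_reproducible(self):
        rng = np.random.default_rng(5)
        X, y = _toy_classification(rng, n=200)
        a = fit_ffnn(X, y, X, y, hidden=(8, 4), max_epochs=3, seed=7)
        b = fit_ffnn(X, y, X, y, hidden=(8, 4), max_epochs=3, seed=7)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))


def _toy_set_data(rng, n=400, vocab=30, dim=8):
    dx_table = EmbeddingTable([f"D{i}" for i in range(vocab)],
                              rng.normal(size=(vocab, dim)))
    proc_table = EmbeddingTable([f"P{i}" for i in range(10)],
                                rng.normal(size=(10, 4)))
    rows = []
    for i in range(n):
        sec = list(rng.choice(dx_table.codes, size=rng.integers(0, 8),
                              replace=False))
        procs = list(rng.choice(proc_table.codes, size=rng.integers(0, 4),
                                replace=False))
        rows.append({"principal_dx": str(rng.choice(dx_table.codes)),
                     "secondary_dx": sec, "procedures": procs,
                     "age": float(rng.normal(65, 10)),
                     "female": int(rng.integers(0, 2)),
                     "hospital_id": int(rng.integers(0, 6))})
    records = pd.DataFrame(rows)
    enc = encode_cohort(records, dx_table, proc_table, 65.0, 10.0)
    y = rng.integers(0, 2, n)
    return records, enc, y, dx_table, proc_table


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(10)
    records, enc, y, dx_table, proc_table = _toy_set_data(rng)
    m = fit_deepset(enc, y, enc, y, dx_table, proc_table,
                    phi_width=8, rho_width=8, head_width=8,
                    max_epochs=3, seed=0)
    return records, enc, y, dx_table, proc_table, m


class TestDeepSet:

    def test_permutation_invariance_100_shuffles(self, fitted):
        records, enc, y, dx_table, proc_table, m = fitted
        base = m.predict(enc)
        rng = np.random.default_rng(99)
        for _ in range(100):
            shuffled = records.copy()
            shuffled["secondary_dx"] = [
                list(rng.permutation(s)) for s in records["secondary_dx"]]
            shuffled["procedures"] = [
                list(rng.permutation(s)) for s in records["procedures"]]
            enc2 = encode_cohort(shuffled, dx_table, proc_table, 65.0, 10.0)
            np.testing.assert_allclose(m.predict(enc2), base, atol=1e-6)

    def test_empty_sets_give_finite_probability(self, fitted):
        _, _, _, dx_table, proc_table, m = fitted
        df = pd.DataFrame([{"principal_dx": "D0", "secondary_dx": [],
                            "procedures": [], "age": 70.0, "female": 1,
                            "hospital_id": 0}])
        enc = encode_cohort(df, dx_table, proc_table, 65.0, 10.0)
        p = m.predict(enc)
        assert np.isfinite(p).all()
        assert 0 < p[0] < 1

    def test_forced_vs_population_assignment(self, fitted):
        _, enc, _, _, _, m = fitted
        h0 = m.hospital_ids()[0]
        p_forced = m.predict(enc, HospitalAssignment.forced(h0))
        p_pop = m.predict(enc, HospitalAssignment.POPULATION)
        assert p_forced.shape == p_pop.shape
        with pytest.raises(ValueError):
            m.predict(enc, HospitalAssignment.forced("nope"))

    def test_margin_fast_path_equals_bruteforce(self, fitted):
        _, enc, _, _, _, m = fitted
        sub = enc.take(np.arange(60))
        ids, means = m.predictive_margins(sub)
        for h, mean in zip(ids, means):
            brute = m.predict(sub, HospitalAssignment.forced(h)).mean()
            assert mean == pytest.approx(brute, abs=1e-12)

    def test_dimension_mismatch_rejected(self, fitted):
        _, enc, y, dx_table, proc_table, _ = fitted
        bad = EmbeddingTable(dx_table.codes[:5], dx_table.vectors[:5])
        with pytest.raises(ValueError):
            fit_deepset(enc, y, enc, y, bad, proc_table, max_epochs=1)
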