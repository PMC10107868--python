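"""Trait-evolution machinery: likelihoods against a path-enumeration MVN
oracle, Mk marginals against brute-force enumeration, nested-model
limits, AICc bookkeeping and parameter recovery."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from cicadasong import (aicc, akaike_weights, ancestral_discrete_marginal,
                        evo_loglik, fit_multi_regime, fit_single_regime,
                        model_comparison, paint_regimes, parse_newick,
                        simulate_continuous, threshold_binary)
from cicadasong.evomodels import EvoModelFit, RegimePainting, _mk_transition

from conftest import make_random_tree


# ---------------------------------------------------------------------------
# Independent covariance oracle: explicit per-pair ancestor walks


def _root_path(tree, i):
    """Nodes on the root->i path (excluding root), rootward first."""
    path = []
    v = i
    while tree.parent[v] >= 0:
        path.append(v)
        v = tree.parent[v]
    return path[::-1]


def oracle_cov_and_mean(tree, model, params, regimes=None):
    depth = tree.node_depths()
    T = tree.height()
    n = tree.n_tips
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            shared = [v for v in _root_path(tree, i)
                      if v in set(_root_path(tree, j))]
            if model == "BM":
                V[i, j] = params["sigma2"] * sum(tree.length[v] for v in shared)
            elif model == "EB":
                r = params["r"]
                acc = 0.0
                for v in shared:
                    t1, t2 = depth[tree.parent[v]], depth[v]
                    acc += ((np.exp(r * t2) - np.exp(r * t1)) / r if r != 0
                            else t2 - t1)
                V[i, j] = params["sigma2"] * acc
            elif model == "OU":
                a, s2 = params["alpha"], params["sigma2"]
                t_ij = sum(tree.length[v] for v in shared)
                V[i, j] = (s2 / (2 * a)) * np.exp(-2 * a * (T - t_ij)) \
                    * (1 - np.exp(-2 * a * t_ij))
            elif model == "BMS":
                s2 = np.asarray(params["sigma2"])
                V[i, j] = sum(s2[regimes[v]] * tree.length[v] for v in shared)
            elif model == "OUMV":
                a = params["alpha"]
                s2 = np.asarray(params["sigma2"])
                acc = 0.0
                for v in shared:
                    t1, t2 = depth[tree.parent[v]], depth[v]
                    acc += s2[regimes[v]] * (np.exp(2 * a * t2)
                                             - np.exp(2 * a * t1)) / (2 * a)
                V[i, j] = acc * np.exp(-2 * a * T)
    if model in ("BM", "EB"):
        mean = np.full(n, params["z0"])
    elif model in ("OU", "BMS"):
        mean = np.full(n, params["theta"])
    else:
        a = params["alpha"]
        th = np.asarray(params["theta"])
        mean = np.zeros(n)
        for i in range(n):
            m = th[regimes[_root_path(tree, i)[0]] if False else regimes[
                tree.root]] * np.exp(-a * T)
            for v in _root_path(tree, i):
                t1, t2 = depth[tree.parent[v]], depth[v]
                m += th[regimes[v]] * (np.exp(-a * (T - t2))
                                       - np.exp(-a * (T - t1)))
            mean[i] = m
    return V, mean


def _random_painting(tree, seed):
    """Deterministic two-regime painting: one root-child clade = regime 1."""
    reg = np.zeros(tree.n_nodes, dtype=int)
    clade = tree.children[tree.root][0]
    stack = [clade]
    while stack:
        v = stack.pop()
        reg[v] = 1
        stack.extend(tree.children[v])
    probs = np.zeros((tree.n_nodes, 2))
    probs[np.arange(tree.n_nodes), reg] = 1.0
    return RegimePainting(branch_regime=reg, node_probs=probs)


class TestLikelihoodOracle:
    @pytest.mark.parametrize("model,params", [
        ("BM", {"sigma2": 0.7, "z0": 1.2}),
        ("OU", {"sigma2": 0.9, "alpha": 1.7, "theta": 0.4}),
        ("EB", {"sigma2": 0.8, "r": -1.3, "z0": -0.5}),
        ("BMS", {"sigma2": [0.3, 2.1], "theta": 0.9}),
        ("OUMV", {"alpha": 1.1, "sigma2": [0.4, 1.6], "theta": [0.2, 1.4]}),
    ])
    def test_loglik_matches_direct_mvn(self, model, params):
        """Each model's lnL equals a direct MVN density with an
        independently path-enumerated covariance on 5-tip trees."""
        rng = np.random.default_rng(1)
        for seed in range(20):
            t = make_random_tree(5, seed)
            paint = _random_painting(t, seed)
            se = rng.uniform(0.01, 0.2, 5)
            x = rng.normal(size=5)
            V, mean = oracle_cov_and_mean(t, model, params,
                                          regimes=paint.branch_regime)
            expect = multivariate_normal.logpdf(x, mean=mean,
                                                cov=V + np.diag(se**2))
            got = evo_loglik(t, x, se, model, params, painting=paint)
            assert got == pytest.approx(expect, abs=1e-6)


class TestNestedLimits:
    def test_ladder(self):
        """EB(r=0)=BM; OU(alpha~0)~BM; BMS(equal rates)=BM;
        OUMV(one regime)=OU — the models nest numerically."""
        t = make_random_tree(10, 3)
        x = simulate_continuous(t, "BM", {"sigma2": 0.5, "z0": 1.0}, seed=4)
        se = np.full(10, 0.05)
        one = RegimePainting(branch_regime=np.zeros(t.n_nodes, dtype=int),
                             node_probs=np.tile([1.0, 0.0], (t.n_nodes, 1)))
        bm = evo_loglik(t, x, se, "BM", {"sigma2": 0.5, "z0": 1.0})
        assert evo_loglik(t, x, se, "EB", {"sigma2": 0.5, "r": 0.0, "z0": 1.0}) \
            == pytest.approx(bm, abs=1e-12)
        assert evo_loglik(t, x, se, "OU",
                          {"sigma2": 0.5, "alpha": 1e-8, "theta": 1.0}) \
            == pytest.approx(evo_loglik(t, x, se, "BM",
                                        {"sigma2": 0.5, "z0": 1.0}), abs=1e-4)
        assert evo_loglik(t, x, se, "BMS",
                          {"sigma2": [0.5, 0.5], "theta": 1.0}, one) \
            == pytest.approx(bm, abs=1e-12)
        ou = evo_loglik(t, x, se, "OU",
                        {"sigma2": 0.5, "alpha": 1.3, "theta": 1.0})
        assert evo_loglik(t, x, se, "OUMV",
                          {"alpha": 1.3, "sigma2": [0.5, 0.5],
                           "theta": [1.0, 1.0]}, one) \
            == pytest.approx(ou, abs=1e-10)

    def test_fitted_degenerate_painting(self):
        """Fitting BMS/OUMV on a single-regime painting reproduces the
        single-regime fits within optimizer tolerance."""
        t = make_random_tree(8, 6)
        x = simulate_continuous(t, "BM", {"sigma2": 0.5, "z0": 2.0}, seed=7)
        se = np.full(8, 0.1)
        one = RegimePainting(branch_regime=np.zeros(t.n_nodes, dtype=int),
                             node_probs=np.tile([1.0, 0.0], (t.n_nodes, 1)))
        bm = fit_single_regime(t, x, se, model="BM", seed=0)
        bms = fit_multi_regime(t, x, se, painting=one, model="BMS", seed=0)
        assert bms.loglik == pytest.approx(bm.loglik, abs=1e-6)
        ou = fit_single_regime(t, x, se, model="OU", seed=0)
        oumv = fit_multi_regime(t, x, se, painting=one, model="OUMV", seed=0)
        assert oumv.loglik == pytest.approx(ou.loglik, abs=1e-4)


class TestSingleRegimeFits:
    def test_cherry_closed_form(self):
        """2-tip cherry, branches 1, tips (0, 2): BM MLEs are z0=1 and
        sigma2 = d^2/(4t) = 1."""
        t = parse_newick("(A:1,B:1);")
        fit = fit_single_regime(t, {"A": 0.0, "B": 2.0}, None, model="BM",
                                seed=0)
        assert fit.params["z0"] == pytest.approx(1.0, abs=1e-6)
        assert fit.params["sigma2"] == pytest.approx(1.0, rel=1e-4)

    def test_sigma2_recovery_and_se_direction(self):
        """BM rate recovered with small bias at 200 tips; ignoring real
        within-species error inflates the rate estimate."""
        est, est_ignoring = [], []
        for seed in range(30):
            t = make_random_tree(200, seed + 10)
            x = simulate_continuous(t, "BM", {"sigma2": 1.0, "z0": 0.0},
                                    seed=seed + 110)
            noisy = x + np.random.default_rng(seed).normal(0, 0.5, 200)
            se = np.full(200, 0.5)
            est.append(fit_single_regime(t, noisy, se, model="BM",
                                         n_starts=1, seed=0).params["sigma2"])
            est_ignoring.append(
                fit_single_regime(t, noisy, None, model="BM",
                                  n_starts=1, seed=0).params["sigma2"])
        assert abs(np.mean(est) - 1.0) < 0.1
        assert np.mean(est_ignoring) > np.mean(est)

    def test_non_ultrametric_rejected_for_ou_eb(self):
        t = parse_newick("((A:1,B:2):1,C:2);")
        for model in ("OU", "EB"):
            with pytest.raises(ValueError):
                fit_single_regime(t, {"A": 0, "B": 1, "C": 2}, model=model)


class TestMultiRegimeFits:
    def test_bms_rate_ordering_recovery(self):
        """sigma2 ratio 10 between regimes: the fitted ordering is correct
        in >= 90% of replicates."""
        ok = 0
        n_rep = 30
        for seed in range(n_rep):
            t = make_random_tree(100, seed + 200)
            paint = _random_painting(t, seed)
            x = simulate_continuous(
                t, "BMS", {"sigma2": [0.2, 2.0], "theta": 0.0},
                seed=seed + 300, regimes=paint.branch_regime)
            fit = fit_multi_regime(t, x, None, painting=paint, model="BMS",
                                   n_starts=2, seed=0)
            s = fit.params["sigma2"]
            ok += int(s[1] > s[0])
        assert ok >= 0.9 * n_rep

    def test_oumv_simulation_matches_analytic_covariance(self):
        """Empirical covariance of 20000 OUMV replicates on a painted
        6-tip tree matches the analytic V within 3 MC SEs entrywise."""
        t = make_random_tree(6, 17)
        paint = _random_painting(t, 17)
        params = {"alpha": 1.5, "sigma2": [0.5, 2.0], "theta": [0.0, 2.0]}
        n_rep = 20000
        X = simulate_continuous(t, "OUMV", params, seed=99, n_rep=n_rep,
                                regimes=paint.branch_regime)
        emp = np.cov(X.T)
        from cicadasong.evomodels import evo_covariance
        V = evo_covariance(t, "OUMV", params, paint)
        mc_se = np.sqrt((np.outer(np.diag(V), np.diag(V)) + V**2) / n_rep)
        assert np.all(np.abs(emp - V) <= 3 * mc_se + 1e-12)


class TestMkMarginals:
    def test_two_tip_symmetry(self):
        t = parse_newick("(A:1,B:1);")
        probs, q = ancestral_discrete_marginal(t, {"A": 0, "B": 1})
        assert probs[t.root] == pytest.approx([0.5, 0.5], abs=1e-8)

    def test_matches_enumeration_oracle(self):
        """Marginals equal exhaustive summation over all internal-state
        assignments on 4-tip trees."""
        for seed in range(10):
            t = make_random_tree(4, seed + 30)
            rng = np.random.default_rng(seed)
            states = np.array([0, 1, rng.integers(2), rng.integers(2)])
            probs, q = ancestral_discrete_marginal(t, states)
            internals = [v for v in range(t.n_nodes) if t.children[v]]
            # enumerate assignments
            marg = {v: np.zeros(2) for v in internals}
            total = 0.0
            for code in range(2 ** len(internals)):
                assign = {v: (code >> k) & 1 for k, v in enumerate(internals)}
                full = dict(assign)
                for i in range(t.n_tips):
                    full[i] = states[i]
                pr = 0.5  # stationary root prior
                for v in range(t.n_nodes):
                    p = t.parent[v]
                    if p >= 0:
                        P = _mk_transition(q, t.length[v])
                        pr *= P[full[p], full[v]]
                total += pr
                for v in internals:
                    marg[v][assign[v]] += pr
            for v in internals:
                assert probs[v] == pytest.approx(marg[v] / total, abs=1e-8)

    def test_monomorphic_limit(self):
        t = make_random_tree(6, 41)
        probs, q = ancestral_discrete_marginal(t, np.ones(6, dtype=int))
        assert np.all(probs[:, 1] > 0.999)


class TestPainting:
    def test_two_clade_split_hand_painted(self):
        t = parse_newick("(((A:1,B:1):1,C:2):1,((D:1,E:1):1,F:2):1);")
        b = {"A": 0, "B": 0, "C": 0, "D": 1, "E": 1, "F": 1}
        probs, _ = ancestral_discrete_marginal(t, b)
        paint = paint_regimes(t, probs)
        M = t.branch_tip_incidence()
        for v in range(t.n_nodes):
            tips_under = {t.tip_labels[i] for i in np.flatnonzero(M[v])}
            if tips_under <= {"A", "B", "C"}:
                assert paint.branch_regime[v] == 0
            elif tips_under <= {"D", "E", "F"}:
                assert paint.branch_regime[v] == 1

    def test_tie_requires_flag(self):
        t = parse_newick("(A:1,B:1);")
        probs, _ = ancestral_discrete_marginal(t, {"A": 0, "B": 1})
        with pytest.raises(ValueError):
            paint_regimes(t, probs)
        paint = paint_regimes(t, probs, tie_state=0)
        assert paint.branch_regime[t.root] == 0


class TestAICc:
    def test_formula_worked_example(self):
        """k=2, n=14, lnL=-17.10 -> AICc = 34.20 + 4 + 12/11 = 39.29."""
        assert aicc(-17.10, 2, 14) == pytest.approx(39.2909, abs=1e-3)

    def test_equal_scores_give_equal_weights(self):
        delta, w = akaike_weights([10.0] * 7)
        assert np.allclose(w, 1 / 7)

    def test_weights_sum_and_shift_invariance(self):
        rng = np.random.default_rng(5)
        s = rng.uniform(10, 60, 7)
        d1, w1 = akaike_weights(s)
        d2, w2 = akaike_weights(s + 123.4)
        assert np.allclose(d1, d2)
        assert np.allclose(w1, w2)
        assert abs(w1.sum() - 1.0) < 1e-12

    def test_printed_call_duration_row(self):
        """Recomputing weights from the printed call-duration AIC scores
        gives the Brownian model 0.68 of the weight."""
        scores = [42.24, 38.20, 42.24, 49.59, 48.86, 42.71, 42.89]
        _, w = akaike_weights(scores)
        assert round(float(w[1]), 2) == 0.68

    def test_comparison_refuses_missing_fit(self):
        f = EvoModelFit(model="BM", params={}, loglik=-10, k=2,
                        aicc=25.0, n=14, se_included=False)
        with pytest.raises(ValueError):
            model_comparison({"BM": f, "OU": None})

    def test_comparison_table(self):
        fits = {}
        for name, lnl, k in (("BM", -10.0, 2), ("OU", -9.9, 3), ("EB", -14.0, 3)):
            fits[name] = EvoModelFit(model=name, params={}, loglik=lnl, k=k,
                                     aicc=aicc(lnl, k, 14), n=14,
                                     se_included=False)
        comp = model_comparison(fits)
        assert comp.best_model == "BM"
        tab = comp.table.set_index("model")
        assert tab.loc["BM", "delta_aicc"] == 0.0
        assert abs(tab["aic_weight"].sum() - 1.0) < 1e-12
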