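"""Likelihood engine, distances/NJ, bootstrap, topology tests, ML adapter."""

import math
import os
import stat

import numpy as np
import pytest

from conftest import random_tree

from ribophy.alignment import PartitionedAlignment
from ribophy.likelihood import (
    ExternalMLConfig,
    GTRParams,
    SiteLikelihoodMatrix,
    bootstrap_columns,
    discrete_gamma_rates,
    external_ml_adapter,
    nj_tree,
    pairwise_distance,
    site_log_likelihoods,
    topology_tests,
)
from ribophy.recoding import recode_mk, recode_ry, recode_rymk
from ribophy.simulate import SimProfile, simulate_alignment
from ribophy.trees import bipartitions, leaf_labels, parse_newick, reroot


class TestModel:
    def test_rate_matrix_rows_sum_to_zero_and_mean_rate_one(self, rng):
        freqs = rng.dirichlet(np.ones(4))
        exch = np.abs(rng.normal(1, 0.3, size=(4, 4)))
        exch = (exch + exch.T) / 2
        params = GTRParams(exch, freqs, gamma_alpha=0.7)
        q = params.rate_matrix()
        assert np.allclose(q.sum(axis=1), 0.0)
        assert np.isclose(-(freqs * np.diag(q)).sum(), 1.0)

    def test_transition_matrix_is_stochastic_and_stationary(self, rng):
        params = GTRParams.jc(4)
        p = params.transition_matrix(0.7)
        assert np.allclose(p.sum(axis=1), 1.0)
        assert np.allclose(params.freqs @ p, params.freqs)

    def test_gamma_rates_have_mean_one(self):
        for alpha in (0.2, 0.5, 1.0, 5.0):
            rates = discrete_gamma_rates(alpha, 4)
            assert np.isclose(rates.mean(), 1.0)
            assert np.all(np.diff(rates) > 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="simplex"):
            GTRParams(np.ones((4, 4)) - np.eye(4), np.array([0.5, 0.5, 0.5, 0.5]))
        with pytest.raises(ValueError, match="positive"):
            GTRParams(np.zeros((4, 4)), np.full(4, 0.25))


class TestSiteLogLikelihoods:
    def test_two_leaf_jc_matches_closed_form(self):
        """JC match-site likelihood = (1/16)(1 + 3 e^{-4d/3}) to 1e-10."""
        params = GTRParams.jc(4)
        for d in (0.01, 0.1, 0.5, 1.5):
            tree = parse_newick(f"(a:{d / 2},b:{d / 2});")
            aln = PartitionedAlignment({"a": "A", "b": "A"})
            ll = site_log_likelihoods(tree, aln, params)[0]
            assert ll == pytest.approx(
                math.log((1 + 3 * math.exp(-4 * d / 3)) / 16), abs=1e-10
            )
            mism = PartitionedAlignment({"a": "A", "b": "C"})
            llm = site_log_likelihoods(tree, mism, params)[0]
            assert llm == pytest.approx(
                math.log((1 - math.exp(-4 * d / 3)) / 16), abs=1e-10
            )

    def test_zero_distance_limit_is_quarter(self):
        tree = parse_newick("(a:0,b:0);")
        aln = PartitionedAlignment({"a": "A", "b": "A"})
        ll = site_log_likelihoods(tree, aln, GTRParams.jc(4))[0]
        assert ll == pytest.approx(math.log(0.25), abs=1e-12)

    def test_two_state_cavender_farris_closed_form(self):
        """Two-state symmetric model: P(same) = (1 + e^{-2d})/2."""
        params = GTRParams.jc(2)
        for d in (0.05, 0.3, 1.0):
            tree = parse_newick(f"(a:{d / 2},b:{d / 2});")
            aln = PartitionedAlignment({"a": "R", "b": "R"}, alphabet="ry2")
            ll = site_log_likelihoods(tree, aln, params)[0]
            assert ll == pytest.approx(
                math.log(0.5 * 0.5 * (1 + math.exp(-2 * d))), abs=1e-10
            )

    def test_all_missing_column_contributes_zero(self):
        tree = parse_newick("(a:0.1,b:0.1);")
        aln = PartitionedAlignment({"a": "?A", "b": "-A"})
        ll = site_log_likelihoods(tree, aln, GTRParams.jc(4))
        assert ll[0] == pytest.approx(0.0, abs=1e-12)

    def test_pulley_principle_reroot_invariance(self, rng):
        """Total lnL of a reversible model is invariant under rerooting."""
        for _ in range(3):
            tree = random_tree(8, rng)
            freqs = rng.dirichlet(np.ones(4) * 10)
            exch = np.abs(rng.normal(1, 0.2, (4, 4)))
            exch = (exch + exch.T) / 2
            params = GTRParams(exch, freqs, gamma_alpha=0.8)
            prof = SimProfile(
                tree=tree.as_string(schema="newick").strip(),
                root_freqs=freqs,
                gamma_alpha=None,
                partition_lengths={"all": 60},
                seed=int(rng.integers(2**31)),
            )
            aln = simulate_alignment(prof)
            base = site_log_likelihoods(tree, aln, params).sum()
            for leaf in sorted(leaf_labels(tree))[:3]:
                rerooted = reroot(tree, {leaf})
                alt = site_log_likelihoods(rerooted, aln, params).sum()
                assert alt == pytest.approx(base, abs=1e-8)

    def test_rymk_likelihood_is_ry_plus_mk(self, rng):
        tree = random_tree(6, rng)
        prof = SimProfile(
            tree=tree.as_string(schema="newick").strip(),
            gamma_alpha=None,
            partition_lengths={"all": 80},
            seed=11,
        )
        aln = simulate_alignment(prof)
        params = GTRParams.jc(2, gamma_alpha=0.6)
        total_rymk = site_log_likelihoods(tree, recode_rymk(aln), params).sum()
        total_ry = site_log_likelihoods(tree, recode_ry(aln), params).sum()
        total_mk = site_log_likelihoods(tree, recode_mk(aln), params).sum()
        assert total_rymk == pytest.approx(total_ry + total_mk, abs=1e-8)

    def test_negative_branch_length_rejected(self):
        tree = parse_newick("(a:-0.1,b:0.1);")
        aln = PartitionedAlignment({"a": "A", "b": "A"})
        with pytest.raises(ValueError, match="negative"):
            site_log_likelihoods(tree, aln, GTRParams.jc(4))

    def test_zero_frequency_of_observed_state_rejected(self):
        tree = parse_newick("(a:0.1,b:0.1);")
        aln = PartitionedAlignment({"a": "T", "b": "T"})
        exch = np.ones((4, 4)) - np.eye(4)
        params = GTRParams(exch, np.array([0.5, 0.25, 0.25, 0.0]))
        with pytest.raises(ValueError, match="zero"):
            site_log_likelihoods(tree, aln, params)


class TestDistancesAndNJ:
    def test_identical_sequences_give_zero(self):
        aln = PartitionedAlignment({"a": "ACGTACGT", "b": "ACGTACGT"})
        _, d = pairwise_distance(aln, "jc4")
        assert d[0, 1] == 0.0

    def test_gapped_columns_ignored_per_pair(self):
        aln = PartitionedAlignment({"a": "ACGT", "b": "A-GA"})
        _, d = pairwise_distance(aln, "p")
        assert d[0, 1] == pytest.approx(1 / 3)

    def test_saturation_capped_with_warning(self):
        aln = PartitionedAlignment({"a": "AAAA", "b": "CCCC"})
        with pytest.warns(UserWarning, match="capped"):
            _, d = pairwise_distance(aln, "jc4", cap=5.0)
        assert d[0, 1] == 5.0

    def test_cfn2_requires_binary_alphabet(self):
        aln = PartitionedAlignment({"a": "ACGT", "b": "ACGT"})
        with pytest.raises(ValueError, match="two-state"):
            pairwise_distance(aln, "cfn2")

    def test_nj_recovers_additive_topology(self):
        # additive matrix on ((a,b),(c,d),e) with internal edges 3 and 4
        labels = ["a", "b", "c", "d", "e"]
        #        a   b   c   d   e
        d = np.array(
            [
                [0, 2, 9, 10, 8],
                [2, 0, 9, 10, 8],
                [9, 9, 0, 3, 7],
                [10, 10, 3, 0, 8],
                [8, 8, 7, 8, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(d, labels)
        assert frozenset({"c", "d"}) in bipartitions(tree)
        assert frozenset({"c", "d", "e"}) in bipartitions(tree)

    def test_nj_input_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(np.array([[0.0, 1.0], [2.0, 0.0]]), ["a", "b"])
        with pytest.raises(ValueError, match="match"):
            nj_tree(np.zeros((2, 2)), ["a"])


class TestBootstrap:
    def test_reproducible_and_shape_preserving(self):
        aln = PartitionedAlignment({"a": "ACGTACGTAC", "b": "ACGTTCGTAC"})
        r1 = bootstrap_columns(aln, 3, seed=9)
        r2 = bootstrap_columns(aln, 3, seed=9)
        assert [x.rows for x in r1] == [x.rows for x in r2]
        assert all(rep.n_cols == aln.n_cols for rep in r1)

    def test_expected_missing_fraction_near_exp_minus_one(self):
        # alignment whose 256 columns are pairwise distinct (all 4-mers), so
        # the absent-original-column fraction is observable from the strings
        import itertools

        cols = ["".join(m) for m in itertools.product("ACGT", repeat=4)]
        rows = {f"t{i}": "".join(c[i] for c in cols) for i in range(4)}
        aln = PartitionedAlignment(rows)
        reps = bootstrap_columns(aln, 40, seed=3)
        missing = []
        for rep in reps:
            seen = {
                "".join(rep.rows[f"t{i}"][j] for i in range(4))
                for j in range(rep.n_cols)
            }
            missing.append(1.0 - len(seen) / len(cols))
        assert np.mean(missing) == pytest.approx(math.exp(-1), abs=0.02)


def _matrix_for_two_trees(n_sites=400, seed=0, separation=0.02):
    rng = np.random.default_rng(seed)
    base = rng.normal(-1.3, 0.2, size=n_sites)
    a = base + rng.normal(separation, 0.05, size=n_sites)
    b = base
    return SiteLikelihoodMatrix(["A", "B"], np.vstack([a, b]))


class TestTopologyTests:
    def test_identical_rows_are_indistinguishable(self):
        vals = np.tile(np.linspace(-2, -1, 50), (2, 1))
        m = SiteLikelihoodMatrix(["A", "B"], vals)
        res = topology_tests(m, n_rell=300, seed=1)
        assert res.p_sh["A"] == pytest.approx(1.0)
        assert res.p_sh["B"] == pytest.approx(1.0)
        assert res.p_au["A"] in (1.0, pytest.approx(1.0, abs=0.2))

    def test_best_tree_never_rejected_by_sh(self, rng):
        for seed in range(5):
            m = _matrix_for_two_trees(seed=seed)
            res = topology_tests(m, n_rell=300, seed=seed)
            best = m.tree_ids[int(np.argmax(m.totals()))]
            assert res.p_sh[best] >= 0.5

    def test_pvalues_invariant_to_per_site_constant_shift(self):
        m1 = _matrix_for_two_trees(seed=4)
        shifted = SiteLikelihoodMatrix(m1.tree_ids, m1.values + 7.5)
        r1 = topology_tests(m1, n_rell=400, seed=10)
        r2 = topology_tests(shifted, n_rell=400, seed=10)
        for tid in m1.tree_ids:
            assert r1.p_kh[tid] == pytest.approx(r2.p_kh[tid], abs=1e-12)
            assert r1.p_au[tid] == pytest.approx(r2.p_au[tid], abs=1e-12)

    def test_single_tree_rejected_and_rell_warning(self):
        m = SiteLikelihoodMatrix(["A"], np.zeros((1, 50)))
        with pytest.raises(ValueError, match="two trees"):
            topology_tests(m)
        with pytest.warns(UserWarning, match="n_rell"):
            topology_tests(_matrix_for_two_trees(), n_rell=50, seed=0)


class TestExternalAdapter:
    def _mock_executable(self, tmp_path, body):
        exe = tmp_path / "mock_ml"
        exe.write_text("#!/bin/sh\n" + body)
        exe.chmod(exe.stat().st_mode | stat.S_IEXEC)
        return exe

    def test_mock_executable_round_trip(self, tmp_path):
        work = tmp_path / "work"
        body = (
            f'mkdir -p "{work}"\n'
            f'echo "((a:1,b:1):1,c:1);" > "{work}/best.nwk"\n'
            f'printf "((a,b),c);\\n((a,c),b);\\n" > "{work}/boots.nwk"\n'
        )
        exe = self._mock_executable(tmp_path, body)
        aln = PartitionedAlignment({"a": "ACGT", "b": "ACGT", "c": "ACGA"})
        cfg = ExternalMLConfig(
            command=f"{exe} {{phylip}}",
            best_tree="best.nwk",
            bootstrap_trees="boots.nwk",
            bootstraps=1000,
        )
        best, boots = external_ml_adapter(aln, cfg, work)
        assert leaf_labels(best) == {"a", "b", "c"}
        assert len(boots) == 2

    def test_missing_binary_gives_actionable_error(self, tmp_path):
        aln = PartitionedAlignment({"a": "ACGT", "b": "ACGT"})
        cfg = ExternalMLConfig(
            command="/nonexistent/raxml {phylip}",
            best_tree="best.nwk",
            bootstrap_trees="boots.nwk",
        )
        with pytest.raises(RuntimeError, match="not found"):
            external_ml_adapter(aln, cfg, tmp_path / "w")

    def test_nonzero_exit_surfaces_stderr(self, tmp_path):
        exe = self._mock_executable(tmp_path, 'echo "boom" >&2\nexit 3\n')
        aln = PartitionedAlignment({"a": "ACGT", "b": "ACGT"})
        cfg = ExternalMLConfig(
            command=f"{exe}", best_tree="b.nwk", bootstrap_trees="t.nwk"
        )
        with pytest.raises(RuntimeError, match="boom"):
            external_ml_adapter(aln, cfg, tmp_path / "w")
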