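import numpy as np
import pytest

from panelex import (SyntheticSpec, WrapperConfig, WrapperError, generate,
                     rank_molecules, rank_panels, run_wrapper,
                     selected_molecules)
from panelex.dlda import CVConfig
from panelex.wrapper_stage import WrapperResult, forward_select

from conftest import make_two_group_table


def _small_config(**kwargs):
    defaults = dict(n_repeats=10, subsample_fraction=0.8,
                    inner_cv=CVConfig(n_folds=5), max_panel_size=9, seed=0)
    defaults.update(kwargs)
    return WrapperConfig(**defaults)


class TestForwardSelect:
    def test_single_perfect_molecule_wins_alone(self):
        t = make_two_group_table(20, 20, seed=0, shifts={4: 50.0}, sd=1.0)
        X = t.samples_by_molecules().to_numpy()
        y = (t.condition_vector() == "b").astype(int)
        panel = forward_select(X, y, _small_config(),
                               np.random.default_rng(0),
                               candidate_ids=t.molecule_ids)
        assert panel == ["m004"]

    def test_jointly_informative_pair_both_selected(self):
        """Two individually weak molecules with additive signal are both
        picked because the second one still improves inner-CV accuracy."""
        rng = np.random.default_rng(1)
        n = 60
        z = np.repeat([0, 1], n)
        weak1 = 1.1 * z + rng.normal(0, 1, 2 * n)
        weak2 = 1.1 * z + rng.normal(0, 1, 2 * n)
        noise = rng.normal(0, 1, (2 * n, 18))
        X = np.column_stack([weak1, weak2, noise]) + 10
        panel = forward_select(X, z, _small_config(max_panel_size=4),
                               np.random.default_rng(2),
                               candidate_ids=[f"c{j}" for j in range(20)])
        assert {"c0", "c1"} <= set(panel)

    def test_negative_gain_forces_growth_to_max_size(self):
        t = make_two_group_table(12, 15, seed=2)
        X = t.samples_by_molecules().to_numpy()
        y = (t.condition_vector() == "b").astype(int)
        cfg = _small_config(max_panel_size=5, min_accuracy_gain=-1.0)
        panel = forward_select(X, y, cfg, np.random.default_rng(3),
                               candidate_ids=t.molecule_ids)
        assert len(panel) == 5

    def test_single_class_errors(self):
        with pytest.raises(WrapperError):
            forward_select(np.zeros((4, 2)), np.zeros(4, dtype=int),
                           _small_config(), np.random.default_rng(0))


class TestRunWrapper:
    def test_planted_signal_dominates_counts(self):
        t = make_two_group_table(20, 20, seed=3, shifts={9: 50.0}, sd=1.0)
        res = run_wrapper(t, t.molecule_ids, _small_config())
        assert res.panel_counts.get(("m009",), 0) == 10

    def test_panel_count_conservation(self, planted_dataset):
        res = run_wrapper(planted_dataset.table,
                          sorted(planted_dataset.table.molecule_ids),
                          _small_config(n_repeats=25))
        assert sum(res.panel_counts.values()) == 25
        assert all(c <= 25 for c in res.molecule_counts.values())
        members = {m for p in res.panel_counts for m in p}
        assert members == set(res.molecule_counts)

    def test_same_seed_bit_identical_and_parallel_safe(self, planted_dataset):
        t = planted_dataset.table
        cands = sorted(t.molecule_ids)
        r1 = run_wrapper(t, cands, _small_config(n_repeats=20, seed=5))
        r2 = run_wrapper(t, cands, _small_config(n_repeats=20, seed=5))
        r3 = run_wrapper(t, cands, _small_config(n_repeats=20, seed=5),
                         n_jobs=2)
        assert r1.panel_counts == r2.panel_counts == r3.panel_counts
        assert r1.molecule_counts == r3.molecule_counts
        r4 = run_wrapper(t, cands, _small_config(n_repeats=20, seed=6))
        assert r4.panel_counts != r1.panel_counts

    def test_row_permutation_invariance(self, planted_dataset):
        t = planted_dataset.table
        cands = sorted(t.molecule_ids)
        rng = np.random.default_rng(0)
        perm = rng.permutation(t.n_molecules)
        shuffled = t.subset_molecules([t.molecule_ids[i] for i in perm])
        r1 = run_wrapper(t, cands, _small_config(n_repeats=15, seed=1))
        r2 = run_wrapper(shuffled, cands, _small_config(n_repeats=15, seed=1))
        assert r1.panel_counts == r2.panel_counts

    def test_empty_candidates_error(self, planted_dataset):
        with pytest.raises(WrapperError):
            run_wrapper(planted_dataset.table, [], _small_config())


class TestRanking:
    def _result(self, counts, candidates=None):
        mol = {}
        for p, c in counts.items():
            for m in p:
                mol[m] = mol.get(m, 0) + c
        return WrapperResult(panel_counts=counts, molecule_counts=mol,
                             n_repeats=sum(counts.values()),
                             candidates=candidates or sorted(mol),
                             config=_small_config(
                                 n_repeats=sum(counts.values())))

    def test_smaller_panel_wins_count_tie(self):
        res = self._result({("a", "b"): 5, ("c",): 5, ("d",): 3})
        ranked = rank_panels(res)
        assert ranked[0][0] == ("c",)
        assert ranked[1][0] == ("a", "b")
        assert ranked[2][0] == ("d",)

    def test_top_n_truncation_and_brute_force_order(self):
        rng = np.random.default_rng(4)
        counts = {tuple(sorted({f"m{i}", f"m{(i*3) % 7}"})): int(c)
                  for i, c in enumerate(rng.integers(1, 6, size=7))}
        res = self._result(counts)
        ranked = rank_panels(res, top_n=100)
        expected = sorted(counts.items(),
                          key=lambda kv: (-kv[1], len(kv[0]), kv[0]))
        assert ranked == expected

    def test_molecule_tie_broken_by_candidate_rank(self):
        res = self._result({("a",): 3, ("b",): 3}, candidates=["b", "a"])
        assert rank_molecules(res) == [("b", 3), ("a", 3)]

    def test_selected_molecules_threshold(self):
        res = self._result({("a",): 8, ("b",): 2})
        assert selected_molecules(res, min_fraction=0.5) == ["a"]
        assert selected_molecules(res, min_fraction=0.1) == ["a", "b"]


def test_relevant_molecules_selected_more_often_than_nulls():
    """Stochastic dominance of planted relevant molecules in selection
    frequency, averaged over many independent datasets."""
    spec = SyntheticSpec()
    rel_freq, null_freq = [], []
    for seed in range(50):
        ds = generate(spec, seed=1000 + seed)
        res = run_wrapper(ds.table, sorted(ds.table.molecule_ids),
                          _small_config(n_repeats=40, seed=seed))
        for m in ds.table.molecule_ids:
            (rel_freq if m in ds.relevant else null_freq).append(
                res.molecule_counts.get(m, 0))
    assert np.mean(rel_freq) > np.mean(null_freq)
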