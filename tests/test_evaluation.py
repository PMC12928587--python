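"""Stratified perplexity, per-layer pruning profiles and Δmetric statistics.

The Δmetric tests compare the implementation against brute-force oracles:
a closed-form paired t statistic and an exact two-sample KS computed by a
full ECDF sweep plus lattice-path enumeration of all interleavings.
"""

from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plmsubnet import (
    AnnotationError,
    ConfigError,
    DomainRecord,
    Partition,
    SplitAssignment,
    delta_metric_stats,
    per_layer_pruning,
    stratified_perplexity,
)
from plmsubnet.evaluation import evaluation_nlls
from plmsubnet.objectives import perplexity


# ---------------------------------------------------------------- oracles
def paired_t_oracle(a, b):
    d = np.asarray(a, float) - np.asarray(b, float)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return t, p


def ks_oracle(x, y):
    """Two-sample KS: statistic by ECDF sweep, exact p by path enumeration."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n, m = x.size, y.size
    d_obs = 0.0
    for v in np.concatenate([x, y]):
        d_obs = max(d_obs, abs(np.mean(x <= v) - np.mean(y <= v)))
    tol = 1e-12

    @lru_cache(maxsize=None)
    def paths_below(i, j):
        # interleavings from (i, j) to (n, m) whose ECDF gap stays < d_obs
        if abs(i / n - j / m) >= d_obs - tol:
            return 0
        if i == n and j == m:
            return 1
        total = 0
        if i < n:
            total += paths_below(i + 1, j)
        if j < m:
            total += paths_below(i, j + 1)
        return total

    p = 1.0 - paths_below(0, 0) / comb(n + m, n)
    paths_below.cache_clear()
    return d_obs, p


def metric_table(supp_sub, supp_base, maint_sub, maint_base, metric="RMSD"):
    rows = []
    for i, (a, b) in enumerate(zip(supp_sub, supp_base)):
        rows.append(dict(id=f"s{i}", set_label="suppression", metric_name=metric,
                         value_subnet=a, value_baseline=b))
    for i, (a, b) in enumerate(zip(maint_sub, maint_base)):
        rows.append(dict(id=f"m{i}", set_label="maintenance", metric_name=metric,
                         value_subnet=a, value_baseline=b))
    return pd.DataFrame(rows)


# ------------------------------------------------------- stratified report
class TestStratifiedPerplexity:
    def _setup(self, corpus):
        split = SplitAssignment(
            {r.id: ("test" if i % 5 == 4 else "validation" if i % 5 == 3 else "train")
             for i, r in enumerate(corpus)},
            seed=0,
        )
        supp = frozenset(r.id for r in corpus if r.cath_label.startswith("1"))
        maint = frozenset(r.id for r in corpus) - supp
        part = Partition(level="sequence", suppressed_ids=supp, maintained_ids=maint)
        return split, part

    def test_all_ones_mask_equals_baseline_everywhere(self, tiny_model, tiny_corpus):
        split, part = self._setup(tiny_corpus)
        rep = stratified_perplexity(
            tiny_model, np.ones(tiny_model.num_maskable), tiny_corpus, split, part,
            seed=4,
        )
        for side in ("suppression", "maintenance"):
            for p in ("train", "validation", "test"):
                assert rep.cell("subnetwork", side, p) == rep.cell("baseline", side, p)
        assert rep.sparsity == 0.0

    def test_cells_match_hand_computed_nll_pool(self, tiny_model, tiny_corpus):
        split, part = self._setup(tiny_corpus)
        m = np.ones(tiny_model.num_maskable)
        rep = stratified_perplexity(tiny_model, m, tiny_corpus, split, part, seed=4)
        test_records = [r for r in tiny_corpus if split.assignment[r.id] == "test"]
        nlls = evaluation_nlls(tiny_model, test_records, mask=m, rate=0.15, seed=4)
        pooled = np.concatenate(
            [nlls[r.id][1] for r in test_records if r.id in part.suppressed_ids]
        )
        assert rep.cell("subnetwork", "suppression", "test") == pytest.approx(
            perplexity(pooled), rel=1e-12
        )

    def test_residue_level_cell_uses_only_target_positions(self, tiny_model, tiny_corpus):
        recs = tiny_corpus[:6]
        split = SplitAssignment({r.id: "test" for r in recs}, seed=0)
        positions = {
            r.id: np.array([i for i, s in enumerate(r.ss3) if s == "H"], dtype=np.intp)
            for r in recs
        }
        part = Partition(
            level="residue",
            suppressed_ids=frozenset(r.id for r in recs),
            maintained_ids=frozenset(r.id for r in recs),
            residue_positions=positions,
            record_lengths={r.id: len(r) for r in recs},
        )
        m = np.ones(tiny_model.num_maskable)
        rep = stratified_perplexity(tiny_model, m, recs, split, part, seed=8)
        nlls = evaluation_nlls(tiny_model, recs, mask=m, rate=0.15, seed=8)
        pool = []
        for r in recs:
            pos, vals = nlls[r.id]
            pool.append(vals[np.isin(pos, positions[r.id])])
        expected = perplexity(np.concatenate(pool))
        assert rep.cell("subnetwork", "suppression", "test") == pytest.approx(expected, rel=1e-12)
        assert rep.cell("subnetwork", "suppression", "train") is None  # empty stratum


# ------------------------------------------------------ per-layer pruning
class TestPerLayerPruning:
    def test_all_ones_gives_zero_everywhere(self, tiny_model):
        table = per_layer_pruning(np.ones(tiny_model.num_maskable), tiny_model)
        assert np.all(table["pruned_percent"] == 0.0)

    def test_half_of_one_layer(self, tiny_model):
        layers = tiny_model.slot_layers()
        m = np.ones(tiny_model.num_maskable)
        idx = np.nonzero(layers == 1)[0]
        m[idx[: idx.size // 2]] = 0.0
        table = per_layer_pruning(m, tiny_model).set_index("layer")
        assert table.loc[1, "pruned_percent"] == pytest.approx(50.0)
        assert table.loc[0, "pruned_percent"] == 0.0

    def test_weighted_mean_equals_overall_sparsity(self, tiny_model, rng):
        from plmsubnet import sparsity

        m = (rng.random(tiny_model.num_maskable) > 0.3).astype(float)
        table = per_layer_pruning(m, tiny_model)
        weighted = np.average(table["pruned_percent"], weights=table["n_slots"])
        assert weighted == pytest.approx(sparsity(m), abs=1e-9)

    def test_length_mismatch(self, tiny_model):
        with pytest.raises(ConfigError):
            per_layer_pruning(np.ones(3), tiny_model)


# --------------------------------------------------------- delta metrics
class TestDeltaMetricStats:
    def test_identical_values_give_zero_t(self):
        base = [1.0, 2.0, 3.0, 4.0]
        table = metric_table(base, base, base, base)
        rep = delta_metric_stats(table)
        entry = rep.metrics["RMSD"]
        assert entry["suppression"]["t_statistic"] == 0.0
        assert entry["suppression"]["p_value"] == 1.0
        assert entry["mean_abs_delta_gap"] == 0.0

    def test_five_row_fixture_matches_oracles(self):
        rng = np.random.default_rng(5)
        ss, sb = rng.normal(2, 1, 5), rng.normal(0, 1, 5)
        ms, mb = rng.normal(0.2, 1, 5), rng.normal(0, 1, 5)
        rep = delta_metric_stats(metric_table(ss, sb, ms, mb)).metrics["RMSD"]
        t_ref, p_ref = paired_t_oracle(ss, sb)
        assert rep["suppression"]["t_statistic"] == pytest.approx(t_ref, abs=1e-10)
        assert rep["suppression"]["p_value"] == pytest.approx(p_ref, abs=1e-10)
        d_ref, ksp_ref = ks_oracle(np.abs(ss - sb), np.abs(ms - mb))
        assert rep["ks_statistic"] == pytest.approx(d_ref, abs=1e-12)
        assert rep["ks_p_value"] == pytest.approx(ksp_ref, abs=1e-8)

    def test_hundred_random_fixtures_match_oracles(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(3, 11))
            m = int(rng.integers(3, 11))
            ss, sb = rng.normal(1, 1, n), rng.normal(0, 1, n)
            ms, mb = rng.normal(0, 1, m), rng.normal(0, 1, m)
            rep = delta_metric_stats(metric_table(ss, sb, ms, mb)).metrics["RMSD"]
            t_ref, p_ref = paired_t_oracle(ss, sb)
            d_ref, ksp_ref = ks_oracle(np.abs(ss - sb), np.abs(ms - mb))
            assert abs(rep["suppression"]["t_statistic"] - t_ref) < 1e-8
            assert abs(rep["suppression"]["p_value"] - p_ref) < 1e-8
            assert abs(rep["ks_statistic"] - d_ref) < 1e-12
            assert abs(rep["ks_p_value"] - ksp_ref) < 1e-8

    def test_ks_statistic_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        ss, sb = rng.normal(1, 1, 8), rng.normal(0, 1, 8)
        ms, mb = rng.normal(0, 1, 8), rng.normal(0, 1, 8)
        plain = delta_metric_stats(metric_table(ss, sb, ms, mb)).metrics["RMSD"]
        # exp() applied to |delta| via transformed values with baseline 0
        f = lambda v: np.exp(np.abs(v))
        transformed = delta_metric_stats(
            metric_table(f(ss - sb), np.zeros(8), f(ms - mb), np.zeros(8))
        ).metrics["RMSD"]
        assert plain["ks_statistic"] == pytest.approx(transformed["ks_statistic"])

    def test_single_row_set_is_error(self):
        table = metric_table([1.0], [0.5], [1.0, 2.0], [0.5, 1.5])
        with pytest.raises(ConfigError, match=">= 2"):
            delta_metric_stats(table)

    def test_unpaired_rows_error_lists_ids(self):
        table = metric_table([1.0, 2.0], [0.5, 1.0], [1.0, 2.0], [0.5, 1.5])
        table.loc[0, "value_baseline"] = np.nan
        with pytest.raises(AnnotationError, match="s0"):
            delta_metric_stats(table)

    def test_large_samples_use_asymptotic_path(self):
        rng = np.random.default_rng(8)
        n = 60
        ss, sb = rng.normal(1, 1, n), rng.normal(0, 1, n)
        ms, mb = rng.normal(0, 1, n), rng.normal(0, 1, n)
        rep = delta_metric_stats(metric_table(ss, sb, ms, mb)).metrics["RMSD"]
        ref = stats.ks_2samp(np.abs(ss - sb), np.abs(ms - mb), method="asymp")
        assert rep["ks_p_value"] == pytest.approx(ref.pvalue, abs=1e-12)
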