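"""Bioset filtering, vote-based metasignature, and cross-species overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from colitis_metasig.metasig import (
    Bioset,
    MetasigConfig,
    OrthologMap,
    derive_metasignature,
    filter_bioset,
    overlap,
)


def _bioset(study, rows):
    return Bioset(study, pd.DataFrame(rows, columns=["gene", "fc", "p"]))


def brute_force_metasignature(biosets, cfg):
    """Independent enumerator of the three admission criteria."""
    filtered = []
    for b in biosets:
        recs = {}
        for _, row in b.records.iterrows():
            if abs(row["fc"]) >= cfg.list_fc_min and row["p"] <= cfg.list_p_max:
                recs[row["gene"]] = row["fc"]
        filtered.append(recs)
    genes = set().union(*[set(f) for f in filtered]) if filtered else set()
    members = {}
    for g in genes:
        occ = [f[g] for f in filtered if g in f]
        if len(occ) < cfg.min_votes:
            continue
        if np.mean([abs(v) for v in occ]) < cfg.mean_fc_min:
            continue
        ups = sum(1 for v in occ if v > 0)
        if cfg.direction_rule == "strict_all":
            if 0 < ups < len(occ):
                continue
            d = "up" if ups else "down"
        else:
            if ups * 2 == len(occ):
                continue
            d = "up" if ups * 2 > len(occ) else "down"
        members[g] = d
    return members


def _random_biosets(rng, n_genes=200, n_lists=18):
    genes = [f"g{i:03d}" for i in range(n_genes)]
    biosets = []
    for j in range(n_lists):
        chosen = rng.choice(genes, size=rng.integers(20, 80), replace=False)
        fc = rng.choice([-1, 1], len(chosen)) * rng.uniform(1.0, 6.0, len(chosen))
        p = rng.uniform(0, 0.2, len(chosen))
        biosets.append(
            Bioset(f"s{j}", pd.DataFrame({"gene": chosen, "fc": fc, "p": p}))
        )
    return biosets


class TestFilter:
    def test_bounds_inclusive(self):
        b = _bioset("x", [("g1", 1.5, 0.05), ("g2", -1.5, 0.05), ("g3", 1.4, 0.001)])
        kept = filter_bioset(b)
        assert set(kept.records["gene"]) == {"g1", "g2"}

    def test_matches_comprehension_oracle(self):
        rng = np.random.default_rng(1)
        for b in _random_biosets(rng, n_lists=5):
            kept = set(filter_bioset(b).records["gene"])
            oracle = {
                r["gene"]
                for _, r in b.records.iterrows()
                if abs(r["fc"]) >= 1.5 and r["p"] <= 0.05
            }
            assert kept == oracle


class TestDeriveMetasignature:
    def test_threshold_membership(self):
        # 9/18 lists, all up, mean |fc| exactly 2.0 -> member
        biosets = [
            _bioset(f"s{j}", [("hit", 2.0, 0.01)] if j < 9 else [(f"other{j}", 3.0, 0.01)])
            for j in range(18)
        ]
        sig = derive_metasignature(biosets)
        assert sig["gene"].tolist() == ["hit"]
        assert sig.iloc[0]["votes"] == 9 and sig.iloc[0]["direction"] == "up"

    def test_vote_shortfall_excluded(self):
        biosets = [
            _bioset(f"s{j}", [("hit", 5.0, 0.001)] if j < 8 else [(f"other{j}", 3.0, 0.01)])
            for j in range(18)
        ]
        assert "hit" not in set(derive_metasignature(biosets)["gene"])

    def test_direction_inconsistency_excluded_strict(self):
        rows = [[("g", 3.0 if j else -3.0, 0.01)] for j in range(10)]
        biosets = [_bioset(f"s{j}", r) for j, r in enumerate(rows)]
        cfg = MetasigConfig(min_votes=9, n_lists=10)
        assert len(derive_metasignature(biosets, cfg)) == 0
        cfg_maj = MetasigConfig(min_votes=9, n_lists=10, direction_rule="majority")
        out = derive_metasignature(biosets, cfg_maj)
        assert out["gene"].tolist() == ["g"] and out.iloc[0]["direction"] == "up"

    @pytest.mark.parametrize("seed", [2, 3, 4])
    def test_matches_bruteforce_enumerator(self, seed):
        rng = np.random.default_rng(seed)
        biosets = _random_biosets(rng)
        cfg = MetasigConfig()
        sig = derive_metasignature(biosets, cfg)
        oracle = brute_force_metasignature(biosets, cfg)
        assert dict(zip(sig["gene"], sig["direction"])) == oracle

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(5)
        biosets = _random_biosets(rng)
        base = set(derive_metasignature(biosets, MetasigConfig())["gene"])
        for cfg in [MetasigConfig(min_votes=11), MetasigConfig(mean_fc_min=3.0)]:
            assert set(derive_metasignature(biosets, cfg)["gene"]) <= base

    def test_votes_equal_recount(self):
        rng = np.random.default_rng(6)
        biosets = _random_biosets(rng)
        cfg = MetasigConfig()
        sig = derive_metasignature(biosets, cfg)
        filtered = [filter_bioset(b, cfg) for b in biosets]
        for _, row in sig.iterrows():
            recount = sum(row["gene"] in set(f.records["gene"]) for f in filtered)
            assert recount == row["votes"]

    def test_too_few_biosets_error(self):
        with pytest.raises(ValueError, match="min_votes"):
            derive_metasignature([_bioset("a", [("g", 2.0, 0.01)])], MetasigConfig())


class TestOverlap:
    def test_disjoint_sets(self):
        res = overlap({"a"}, {"b"}, None, {"a", "b", "c"})
        assert res.n_overlap == 0 and res.p_value == 1.0

    def test_degenerate_full_overlap(self):
        u = {f"g{i}" for i in range(10)}
        res = overlap(u, u, None, u)
        assert res.n_overlap == 10 and res.p_value == pytest.approx(1.0)

    def test_symmetric_under_bijection(self):
        rng = np.random.default_rng(7)
        universe = [f"g{i}" for i in range(100)]
        a = set(rng.choice(universe, 20, replace=False))
        b = set(rng.choice(universe, 30, replace=False))
        identity = OrthologMap(pd.DataFrame({"source": universe, "target": universe}))
        r1 = overlap(a, b, identity, universe)
        r2 = overlap(b, a, identity, universe)
        assert r1.n_overlap == r2.n_overlap and r1.p_value == pytest.approx(r2.p_value)

    def test_hypergeometric_against_permutation(self):
        rng = np.random.default_rng(8)
        universe = [f"g{i}" for i in range(300)]
        a = set(rng.choice(universe, 40, replace=False))
        b = set(rng.choice(universe, 40, replace=False))
        res = overlap(a, b, None, universe)
        draws = rng.hypergeometric(len(b), 300 - len(b), len(a), size=20000)
        emp = (draws >= res.n_overlap).mean()
        se = np.sqrt(max(emp * (1 - emp), 1e-6) / 20000)
        assert abs(emp - res.p_value) < 4 * se + 1e-3

    def test_direction_concordance_counted(self):
        res = overlap(
            {"a", "b"},
            {"a", "b"},
            None,
            {"a", "b", "c"},
            directions_a={"a": "up", "b": "down"},
            directions_b={"a": "up", "b": "up"},
        )
        assert res.n_overlap == 2 and res.n_concordant == 1

    def test_empty_universe_error(self):
        with pytest.raises(ValueError, match="universe"):
            overlap({"a"}, {"a"}, None, set())
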