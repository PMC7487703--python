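"""Pedigree kinship recursion against a path-counting oracle, resampling
null calibration, MDS embedding and outlier/family grouping."""

import itertools

import numpy as np
import pandas as pd
import pytest

from recmap.io_formats import PedigreeTable
from recmap.kinship import (
    GroupKinshipSummary,
    OutlierRule,
    ResamplingConfig,
    detect_outliers,
    family_groups,
    group_summary,
    kinship_matrix,
    kinship_pair,
    mds_components,
    mean_pairwise_kinship,
    resample_null,
)


def ped(rows):
    return PedigreeTable(
        pd.DataFrame(rows, columns=["dog_id", "sire_id", "dam_id", "sex", "birth_year"])
    )


FULL_SIBS = ped(
    [
        ("S", "", "", "M", 2009),
        ("D", "", "", "F", 2009),
        ("A", "S", "D", "M", 2011),
        ("B", "S", "D", "F", 2011),
    ]
)

HALF_SIBS = ped(
    [
        ("S", "", "", "M", 2009),
        ("D1", "", "", "F", 2009),
        ("D2", "", "", "F", 2009),
        ("A", "S", "D1", "M", 2011),
        ("B", "S", "D2", "F", 2011),
    ]
)


# ---------------------------------------------------------------------------
# Path-counting oracle: phi(i,j) = sum over common ancestors A and over
# non-overlapping ancestor-path pairs of (1/2)^(n1+n2+1) * (1 + F_A).


def _ancestor_paths(pedigree, dog):
    """All paths (as node tuples, dog first) from dog to each ancestor."""
    paths = [(dog,)]
    out = [(dog,)]
    frontier = [(dog,)]
    while frontier:
        nxt = []
        for path in frontier:
            for p in pedigree.parents(path[-1]):
                if p is not None and p in pedigree._parents:
                    new = path + (p,)
                    out.append(new)
                    nxt.append(new)
        frontier = nxt
    return out


def oracle_inbreeding(pedigree, dog):
    s, d = pedigree.parents(dog)
    if s is None or d is None:
        return 0.0
    return oracle_phi(pedigree, s, d)


def oracle_phi(pedigree, i, j):
    if i == j:
        return 0.5 * (1 + oracle_inbreeding(pedigree, i))
    total = 0.0
    for pi in _ancestor_paths(pedigree, i):
        for pj in _ancestor_paths(pedigree, j):
            if pi[-1] != pj[-1]:
                continue
            # paths must share only the common ancestor
            if set(pi[:-1]) & set(pj):
                continue
            if set(pj[:-1]) & set(pi):
                continue
            n1, n2 = len(pi) - 1, len(pj) - 1
            total += 0.5 ** (n1 + n2 + 1) * (1 + oracle_inbreeding(pedigree, pi[-1]))
    return total


def random_pedigree(rng, n_dogs):
    rows = []
    for k in range(n_dogs):
        dog = f"d{k}"
        if k < 2 or rng.random() < 0.3:
            rows.append((dog, "", "", "M" if k % 2 else "F", 2009))
        else:
            sire, dam = rng.choice(k, size=2, replace=False)
            rows.append((dog, f"d{sire}", f"d{dam}", "M" if k % 2 else "F", 2010))
    return ped(rows)


class TestKinshipPair:
    def test_full_siblings(self):
        assert kinship_pair(FULL_SIBS, "A", "B") == pytest.approx(0.25)

    def test_half_siblings(self):
        assert kinship_pair(HALF_SIBS, "A", "B") == pytest.approx(0.125)

    def test_self_kinship_non_inbred(self):
        assert kinship_pair(FULL_SIBS, "A", "A") == pytest.approx(0.5)

    def test_self_kinship_full_sib_mating_offspring(self):
        inbred = ped(
            FULL_SIBS.records.values.tolist()
            + [("X", "A", "B", "M", 2013)]
        )
        assert kinship_pair(inbred, "X", "X") == pytest.approx(0.625)  # (1+0.25)/2

    def test_parent_offspring(self):
        assert kinship_pair(FULL_SIBS, "S", "A") == pytest.approx(0.25)

    def test_unrelated_founders(self):
        assert kinship_pair(FULL_SIBS, "S", "D") == 0.0

    def test_absent_id_error(self):
        with pytest.raises(KeyError):
            kinship_pair(FULL_SIBS, "A", "NOPE")

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_path_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pedigree = random_pedigree(rng, int(rng.integers(5, 13)))
        ids = pedigree.ids
        for i, j in itertools.combinations_with_replacement(ids, 2):
            assert kinship_pair(pedigree, i, j) == pytest.approx(
                oracle_phi(pedigree, i, j), abs=1e-12
            )


class TestKinshipMatrix:
    def test_trio_values(self):
        trio = ped(
            [("S", "", "", "M", 2009), ("D", "", "", "F", 2009),
             ("P", "S", "D", "M", 2011)]
        )
        m = kinship_matrix(trio)
        assert m.loc("P", "S") == pytest.approx(0.25)
        assert m.loc("P", "D") == pytest.approx(0.25)
        assert m.loc("S", "D") == 0.0

    def test_equals_pairwise_calls(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            pedigree = random_pedigree(rng, 10)
            m = kinship_matrix(pedigree)
            for a, b in itertools.combinations(range(len(m.ids)), 2):
                assert m.values[a, b] == pytest.approx(
                    kinship_pair(pedigree, m.ids[a], m.ids[b])
                )

    def test_order_equivariance(self):
        m1 = kinship_matrix(FULL_SIBS, ["A", "B", "S"])
        m2 = kinship_matrix(FULL_SIBS, ["S", "A", "B"])
        assert m1.loc("A", "S") == m2.loc("A", "S")

    def test_positive_semidefinite(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            pedigree = random_pedigree(rng, 12)
            m = kinship_matrix(pedigree)
            assert np.linalg.eigvalsh(m.values).min() >= -1e-8


class TestMeanPairwise:
    def test_all_founders_zero(self):
        founders = ped([(f"f{i}", "", "", "M", 2009) for i in range(4)])
        mean, sd = mean_pairwise_kinship(kinship_matrix(founders))
        assert (mean, sd) == (0.0, 0.0)

    def test_single_full_sib_pair(self):
        m = kinship_matrix(FULL_SIBS, ["A", "B"])
        mean, sd = mean_pairwise_kinship(m)
        assert mean == pytest.approx(0.25)
        assert sd == 0.0

    def test_agrees_with_direct_enumeration(self):
        rng = np.random.default_rng(5)
        pedigree = random_pedigree(rng, 10)
        m = kinship_matrix(pedigree)
        vals = [
            kinship_pair(pedigree, a, b)
            for a, b in itertools.combinations(m.ids, 2)
        ]
        mean, sd = mean_pairwise_kinship(m)
        assert mean == pytest.approx(np.mean(vals))
        assert sd == pytest.approx(np.std(vals, ddof=1))

    def test_fewer_than_two_error(self):
        with pytest.raises(ValueError):
            mean_pairwise_kinship(kinship_matrix(FULL_SIBS), ["A"])


class TestResampleNull:
    def _pool_pedigree(self, n=30):
        rows = [(f"f{i}", "", "", "M" if i % 2 else "F", 2010) for i in range(n)]
        return ped(rows)

    def test_observed_below_all_replicates_gives_p_one(self):
        pedigree = self._pool_pedigree()
        cfg = ResamplingConfig(sample_size=5, replicates=50, seed=0,
                               birth_year_range=None)
        res = resample_null(pedigree, pedigree.ids, cfg, observed_mean=-1.0)
        assert res.p_value == 1.0

    def test_observed_above_all_replicates_gives_lower_bound(self):
        pedigree = self._pool_pedigree()
        cfg = ResamplingConfig(sample_size=5, replicates=1500, seed=0,
                               birth_year_range=None)
        res = resample_null(pedigree, pedigree.ids, cfg, observed_mean=0.9)
        assert res.p_value == pytest.approx(1 / 1501)
        assert res.p_value < 0.001
        assert res.exceeds_replicate_max

    def test_birth_year_filter_applied(self):
        rows = [(f"a{i}", "", "", "M", 2000) for i in range(10)]
        rows += [(f"b{i}", "", "", "F", 2012) for i in range(10)]
        pedigree = ped(rows)
        cfg = ResamplingConfig(sample_size=15, replicates=5, seed=0,
                               birth_year_range=(2009, 2017))
        with pytest.raises(ValueError, match="pool"):
            resample_null(pedigree, pedigree.ids, cfg, 0.1)

    def test_null_calibration_uniform_p(self):
        """Sampling the cohort itself from the pool yields roughly uniform
        empirical p-values across seeds."""
        rng = np.random.default_rng(3)
        pedigree = random_pedigree(rng, 40)
        m = kinship_matrix(pedigree)
        ids = pedigree.ids
        ps = []
        for seed in range(60):
            srng = np.random.default_rng(1000 + seed)
            cohort = list(srng.choice(ids, size=8, replace=False))
            obs, _ = mean_pairwise_kinship(m, cohort)
            cfg = ResamplingConfig(sample_size=8, replicates=99, seed=seed,
                                   birth_year_range=None)
            ps.append(resample_null(pedigree, ids, cfg, obs).p_value)
        ps = np.asarray(ps)
        # crude uniformity checks: mean near 0.5, mass in both halves
        assert 0.3 < ps.mean() < 0.7
        assert (ps < 0.5).mean() > 0.2 and (ps > 0.5).mean() > 0.2


class TestMds:
    def _two_families(self):
        rows = []
        for fam, tag in enumerate(["X", "Y"]):
            rows.append((f"{tag}S", "", "", "M", 2009))
            rows.append((f"{tag}D", "", "", "F", 2009))
            for k in range(4):
                rows.append((f"{tag}{k}", f"{tag}S", f"{tag}D", "M", 2011))
        return ped(rows)

    def test_component_one_separates_families(self):
        pedigree = self._two_families()
        m = kinship_matrix(pedigree)
        coords, _ = mds_components(m, 2)
        x_ids = [d for d in m.ids if d.startswith("X")]
        y_ids = [d for d in m.ids if d.startswith("Y")]
        cx = coords.loc[x_ids, "C1"]
        cy = coords.loc[y_ids, "C1"]
        gap = abs(cx.mean() - cy.mean())
        spread = max(cx.max() - cx.min(), cy.max() - cy.min())
        assert gap > spread

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(11)
        pedigree = random_pedigree(rng, 10)
        m = kinship_matrix(pedigree)
        n = len(m.ids)
        coords, evals = mds_components(m, n - 1)
        diag = np.diag(m.values)
        d2 = diag[:, None] + diag[None, :] - 2 * m.values
        x = coords.to_numpy()
        recon = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
        # distances are preserved up to the dropped non-positive eigenvalues
        assert np.abs(recon - d2).max() < 1e-8

    def test_all_founder_matrix_degenerate_simplex(self):
        founders = ped([(f"f{i}", "", "", "M", 2009) for i in range(5)])
        m = kinship_matrix(founders)
        coords, evals = mds_components(m, 4)
        x = coords.to_numpy()
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
        off = d[np.triu_indices(5, k=1)]
        assert np.allclose(off, off[0])
        assert np.allclose(evals, evals[0])


class TestOutliers:
    def test_planted_outlier_flagged(self):
        rng = np.random.default_rng(0)
        coords = pd.DataFrame(
            rng.normal(size=(200, 3)), columns=["C1", "C2", "C3"],
            index=[f"d{i}" for i in range(200)],
        )
        coords.loc["d7", "C2"] = 10 * coords["C2"].std()
        flagged = detect_outliers(coords, OutlierRule(3, 0.5, 99.5))
        assert "d7" in flagged

    def test_vacuous_rule_flags_nobody(self):
        rng = np.random.default_rng(1)
        coords = pd.DataFrame(rng.normal(size=(50, 3)), columns=["C1", "C2", "C3"])
        assert detect_outliers(coords, OutlierRule(3, 0.0, 100.0)) == []
        with pytest.raises(ValueError):
            OutlierRule(3, 99.5, 0.5)

    def test_uniform_flag_rate_near_union_bound(self):
        rng = np.random.default_rng(2)
        n = 1000
        coords = pd.DataFrame(
            rng.uniform(size=(n, 3)), columns=["C1", "C2", "C3"],
            index=[f"d{i}" for i in range(n)],
        )
        flagged = detect_outliers(coords, OutlierRule(3, 0.5, 99.5))
        # 1% per component, union over 3 components, minus overlaps
        assert 0.01 * n <= len(flagged) <= 0.05 * n


class TestFamilyGroups:
    def test_two_planted_sibships(self):
        pedigree = ped(
            [
                ("S1", "", "", "M", 2009), ("D1", "", "", "F", 2009),
                ("S2", "", "", "M", 2009), ("D2", "", "", "F", 2009),
                ("a", "S1", "D1", "M", 2011), ("b", "S1", "D1", "F", 2011),
                ("c", "S2", "D2", "M", 2011), ("d", "S2", "D2", "F", 2011),
            ]
        )
        groups = family_groups(pedigree, ["a", "b", "c", "d"])
        assert sorted(map(sorted, groups)) == [["a", "b"], ["c", "d"]]

    def test_unrelated_founders_singletons(self):
        founders = ped([(f"f{i}", "", "", "M", 2009) for i in range(3)])
        groups = family_groups(founders, founders.ids)
        assert sorted(map(tuple, groups)) == [("f0",), ("f1",), ("f2",)]

    def test_depth_zero_groups_by_shared_parents_only(self):
        # cousins: common grandparents, different parents
        pedigree = ped(
            [
                ("GS", "", "", "M", 2005), ("GD", "", "", "F", 2005),
                ("P1", "GS", "GD", "M", 2008), ("P2", "GS", "GD", "F", 2008),
                ("M1", "", "", "F", 2008), ("M2", "", "", "M", 2008),
                ("c1", "P1", "M1", "M", 2011), ("c2", "M2", "P2", "F", 2011),
            ]
        )
        assert len(family_groups(pedigree, ["c1", "c2"], max_depth=0)) == 2
        assert len(family_groups(pedigree, ["c1", "c2"], max_depth=1)) == 1


class TestGroupSummary:
    def test_full_sib_group_mean(self):
        m = kinship_matrix(FULL_SIBS)
        summary = group_summary(m, {"sibs": ["A", "B"], "parents": ["S", "D"]})
        assert summary.means.at["sibs", "sibs"] == pytest.approx(0.25)
        assert summary.means.at["parents", "parents"] == 0.0

    def test_unrelated_groups_between_mean_zero(self):
        rows = [(f"x{i}", "", "", "M", 2009) for i in range(3)]
        rows += [(f"y{i}", "", "", "F", 2009) for i in range(3)]
        pedigree = ped(rows)
        m = kinship_matrix(pedigree)
        summary = group_summary(m, {"X": [f"x{i}" for i in range(3)],
                                    "Y": [f"y{i}" for i in range(3)]})
        assert summary.means.at["X", "Y"] == 0.0

    def test_singleton_group_within_mean_missing(self):
        m = kinship_matrix(FULL_SIBS)
        summary = group_summary(m, {"solo": ["A"], "pair": ["S", "D"]})
        assert np.isnan(summary.means.at["solo", "solo"])

    def test_agrees_with_brute_force_on_random_partitions(self):
        rng = np.random.default_rng(9)
        pedigree = random_pedigree(rng, 15)
        m = kinship_matrix(pedigree)
        ids = list(m.ids)
        rng.shuffle(ids)
        groups = {"A": ids[:5], "B": ids[5:9], "C": ids[9:]}
        summary = group_summary(m, groups)
        for la, lb in itertools.combinations_with_replacement("ABC", 2):
            if la == lb:
                vals = [
                    kinship_pair(pedigree, a, b)
                    for a, b in itertools.combinations(groups[la], 2)
                ]
            else:
                vals = [
                    kinship_pair(pedigree, a, b)
                    for a in groups[la]
                    for b in groups[lb]
                ]
            assert summary.means.at[la, lb] == pytest.approx(np.mean(vals))
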