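"""Tracing-topography statistics on constructed and planted cohorts."""

import numpy as np
import pandas as pd
import pytest

import ceatopo as ct
from ceatopo import InsufficientDataError


def _counts(rows):
    return pd.DataFrame(rows, columns=["subject_id", "region", "hemisphere", "count"])


def _cohort_from_fractions(frac_by_region, total=1000):
    """Region count tables whose per-subject fractions are as given."""
    n_subj = len(next(iter(frac_by_region.values())))
    rows = []
    for j in range(n_subj):
        named = sum(f[j] for f in frac_by_region.values())
        rows.append((f"S{j}", "REST", "ipsi", int(round(total * (1 - named)))))
        for region, fracs in frac_by_region.items():
            rows.append((f"S{j}", region, "ipsi", int(round(total * fracs[j]))))
    return _counts(rows)


class TestFilterRegions:
    def test_one_percent_region_retained(self):
        tables = _cohort_from_fractions({"A": [0.01, 0.01, 0.01]})
        assert "A" in ct.filter_regions(tables)

    def test_exact_boundary_excluded(self):
        tables = _cohort_from_fractions({"A": [0.005, 0.005, 0.005]})
        assert "A" not in ct.filter_regions(tables)

    def test_empty_table_empty_set(self):
        assert ct.filter_regions(_counts([])) == []

    def test_idempotent_and_subject_order_invariant(self):
        tables = _cohort_from_fractions({"A": [0.02, 0.001, 0.02], "B": [0.004, 0.006, 0.004]})
        kept = ct.filter_regions(tables)
        shuffled = tables.iloc[::-1].reset_index(drop=True)
        assert ct.filter_regions(shuffled) == kept
        sub = tables[tables["region"].isin(kept + ["REST"])]
        assert set(ct.filter_regions(sub)) >= set(kept) - {"REST"}

    def test_zero_total_subject_excluded_with_warning(self):
        tables = _counts([("S0", "A", "ipsi", 10), ("S1", "A", "ipsi", 0)])
        with pytest.warns(UserWarning, match="S1"):
            kept = ct.filter_regions(tables)
        assert kept == ["A"]


class TestConnectivityCorrelation:
    def test_perfectly_covarying_and_anticovarying_regions(self):
        tables = _cohort_from_fractions(
            {"A": [0.1, 0.2, 0.3, 0.4], "B": [0.1, 0.2, 0.3, 0.4], "C": [0.4, 0.3, 0.2, 0.1]}
        )
        corr = ct.connectivity_correlation_matrix(tables, ["A", "B", "C"])
        assert corr.loc["A", "B"] == pytest.approx(1.0, abs=1e-12)
        assert corr.loc["A", "C"] == pytest.approx(-1.0, abs=1e-12)
        assert np.allclose(np.diag(corr), 1.0)

    def test_invariant_to_subject_total_rescaling(self):
        tables = _cohort_from_fractions({"A": [0.1, 0.2, 0.3], "B": [0.3, 0.1, 0.2]})
        scaled = tables.copy()
        scaled.loc[scaled["subject_id"] == "S0", "count"] *= 7
        a = ct.connectivity_correlation_matrix(tables, ["A", "B"])
        b = ct.connectivity_correlation_matrix(scaled, ["A", "B"])
        assert np.allclose(a.values, b.values, atol=1e-12)

    def test_zero_variance_region_excluded(self):
        tables = _cohort_from_fractions({"A": [0.1, 0.1, 0.1], "B": [0.1, 0.2, 0.3]})
        with pytest.warns(UserWarning, match="A"):
            corr = ct.connectivity_correlation_matrix(tables, ["A", "B"])
        assert "A" not in corr.columns

    def test_needs_three_subjects(self):
        tables = _cohort_from_fractions({"A": [0.1, 0.2]})
        with pytest.raises(InsufficientDataError):
            ct.connectivity_correlation_matrix(tables, ["A"])


class TestHierarchicalCluster:
    def test_planted_two_block_matrix_recovered(self):
        regions = ["A1", "A2", "A3", "B1", "B2"]
        corr = pd.DataFrame(-0.2, index=regions, columns=regions)
        for grp in (["A1", "A2", "A3"], ["B1", "B2"]):
            corr.loc[grp, grp] = 0.9
        np.fill_diagonal(corr.values, 1.0)
        out = ct.hierarchical_cluster(corr, n_clusters=2)
        assert set(out.as_sets()) == {frozenset({"A1", "A2", "A3"}), frozenset({"B1", "B2"})}

    def test_identity_matrix_gives_singletons(self):
        regions = list("ABCD")
        corr = pd.DataFrame(np.eye(4), index=regions, columns=regions)
        out = ct.hierarchical_cluster(corr, n_clusters=4)
        assert out.n_clusters == 4

    def test_single_region(self):
        corr = pd.DataFrame([[1.0]], index=["A"], columns=["A"])
        out = ct.hierarchical_cluster(corr, n_clusters=1)
        assert out.labels["A"] == 1

    def test_asymmetric_matrix_rejected(self):
        corr = pd.DataFrame([[1.0, 0.5], [0.2, 1.0]], index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ValueError):
            ct.hierarchical_cluster(corr, n_clusters=2)


class TestClusterStarterRelationship:
    def _starters(self, centroids):
        rows = [(f"S{j}", ap, "CeL", 10) for j, ap in enumerate(centroids)]
        return pd.DataFrame(rows, columns=["subject_id", "ap_level", "subnucleus", "count"])

    def test_fractions_proportional_to_centroid_give_unit_r(self):
        centroids = [-1.8, -1.5, -1.2, -0.9]
        fracs = [0.1, 0.2, 0.3, 0.4]  # rises toward less-negative AP
        tables = _cohort_from_fractions({"A": fracs})
        clusters = ct.ClusterAssignment.from_labels({"A": 1})
        out = ct.cluster_starter_relationship(clusters, tables, self._starters(centroids))
        assert out.loc[0, "r"] == pytest.approx(1.0, abs=1e-9)
        assert out.loc[0, "direction"] == "rostral"

    def test_two_subjects_rejected(self):
        tables = _cohort_from_fractions({"A": [0.1, 0.2]})
        clusters = ct.ClusterAssignment.from_labels({"A": 1})
        with pytest.raises(InsufficientDataError):
            ct.cluster_starter_relationship(clusters, tables, self._starters([-1.5, -1.0]))

    def test_null_coupling_rejection_near_alpha(self):
        rejections = 0
        n_cohorts = 60
        rng = np.random.default_rng(0)
        for i in range(n_cohorts):
            fracs = rng.uniform(0.1, 0.3, size=8)
            tables = _cohort_from_fractions({"A": list(fracs)})
            centroids = rng.uniform(-2.0, -0.8, size=8)
            clusters = ct.ClusterAssignment.from_labels({"A": 1})
            out = ct.cluster_starter_relationship(clusters, tables, self._starters(centroids))
            rejections += out.loc[0, "p"] < 0.05
        assert rejections / n_cohorts < 0.2


class TestInplaneCorrelation:
    def _sections(self, n_subjects=8, coupled=True, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for j in range(n_subjects):
            ap = np.linspace(-2.0, -1.0, 10)
            starter = rng.poisson(30, size=10) + 1
            inp = starter * 2 if coupled else rng.poisson(30, size=10)
            rows += [(f"S{j}", a, int(i), int(s)) for a, i, s in zip(ap, inp, starter)]
        return pd.DataFrame(rows, columns=["subject_id", "section_ap", "input_count", "starter_count"])

    def test_perfect_coupling_detected(self):
        table, p = ct.inplane_correlation_test(self._sections(coupled=True), n_shuffle=200, seed=0)
        assert np.allclose(table["r_real"], 1.0)
        assert p < 0.05

    def test_constant_counts_excluded_with_warning(self):
        df = self._sections(n_subjects=7)
        df.loc[df["subject_id"] == "S0", "starter_count"] = 5
        with pytest.warns(UserWarning, match="S0"):
            table, _ = ct.inplane_correlation_test(df, n_shuffle=50, seed=0)
        assert not table.loc[table["subject_id"] == "S0", "included"].iloc[0]

    def test_too_few_subjects_rejected(self):
        with pytest.raises(InsufficientDataError):
            ct.inplane_correlation_test(self._sections(n_subjects=4), n_shuffle=50, seed=0)


class TestLocalConnectivityRegression:
    def test_exact_doubling_recovered(self):
        starters = pd.DataFrame(
            {"CeC": [1.0, 2.0, 3.0, 4.0, 5.0], "CeL": [2.0, 1.0, 4.0, 3.0, 5.0]},
            index=[f"S{j}" for j in range(5)],
        )
        neighbors = pd.DataFrame({"BLA": 2.0 * starters["CeC"]}, index=starters.index)
        out = ct.local_connectivity_regression(neighbors, starters)
        row = out[(out["source"] == "BLA") & (out["target"] == "CeC")].iloc[0]
        assert row["slope"] == pytest.approx(2.0, abs=1e-10)
        assert row["p"] < 1e-6
        assert row["ci_low"] <= 2.0 <= row["ci_high"]

    def test_three_subjects_rejected(self):
        starters = pd.DataFrame({"CeC": [1.0, 2.0, 3.0]}, index=["S0", "S1", "S2"])
        neighbors = pd.DataFrame({"BLA": [1.0, 2.0, 3.0]}, index=starters.index)
        with pytest.raises(InsufficientDataError):
            ct.local_connectivity_regression(neighbors, starters)

    def test_zero_variance_predictor_flagged(self):
        starters = pd.DataFrame({"CeC": [2.0] * 5}, index=[f"S{j}" for j in range(5)])
        neighbors = pd.DataFrame({"BLA": np.arange(5.0)}, index=starters.index)
        out = ct.local_connectivity_regression(neighbors, starters)
        assert not out.iloc[0]["defined"]


class TestProjectionBias:
    def test_hand_three_point_oracle(self):
        proj = pd.DataFrame(
            {
                "subject_id": ["S0"] * 3,
                "region": ["injection_site"] * 3,
                "ap_level": [-2.0, -1.0, 0.0],
                "normalized_fluorescence": [1.0, 2.0, 4.0],
                "group": ["rostral"] * 3,
            }
        )
        assert ct.projection_bias(proj)["S0"] == pytest.approx(1.5, abs=1e-12)

    def test_single_level_rejected(self):
        proj = pd.DataFrame(
            {
                "subject_id": ["S0"],
                "region": ["injection_site"],
                "ap_level": [-1.0],
                "normalized_fluorescence": [1.0],
                "group": ["rostral"],
            }
        )
        with pytest.raises(InsufficientDataError):
            ct.projection_bias(proj)


class TestCompareProjectionTargets:
    def test_sidak_closed_form(self):
        assert ct.sidak_adjust(0.01, 5) == pytest.approx(1 - 0.99**5, abs=1e-12)

    def test_identical_groups_not_significant(self):
        proj = ct.generate_projection_dataset(
            4, [-2.0, -1.5, -1.0], 0.0, seed=0, noise_sd=0.05, regions=("SI", "BSTal")
        )
        anova, per_target = ct.compare_projection_targets(proj, proj)
        assert (per_target["p_adjusted"] > 0.9).all()

    def test_shifted_target_detected(self):
        rostral = ct.generate_projection_dataset(
            5, [-2.0, -1.5, -1.0], 0.0, seed=1, noise_sd=0.05, regions=("SI", "BSTal", "LH")
        )
        caudal = ct.generate_projection_dataset(
            5, [-2.0, -1.5, -1.0], 0.0, seed=2, noise_sd=0.05, regions=("SI", "BSTal", "LH")
        )
        caudal.loc[caudal["region"] == "BSTal", "normalized_fluorescence"] += 2.0
        _, per_target = ct.compare_projection_targets(rostral, caudal)
        hit = per_target.set_index("target")["p_adjusted"]
        assert hit["BSTal"] < 0.01
        assert (hit.drop("BSTal") > 0.05).all()

    def test_single_subject_group_rejected(self):
        proj = ct.generate_projection_dataset(1, [-2.0, -1.0], 0.0, seed=0)
        with pytest.raises(InsufficientDataError):
            ct.compare_projection_targets(proj, proj)


class TestIncidenceComparison:
    def test_identical_incidence_trivial(self):
        out = ct.incidence_comparison((5, 10), (5, 10))
        assert out["p_mannwhitney"] == 1.0
        assert out["p_fisher"] == 1.0

    def test_printed_counts_strongly_significant(self):
        out = ct.incidence_comparison((13, 20), (1, 21))
        assert out["p_mannwhitney"] < 0.001
        assert out["p_fisher"] < 0.001

    def test_total_separation_hypergeometric_tail(self):
        out = ct.incidence_comparison((20, 20), (0, 20))
        # Fisher exact two-sided p = 2 / C(40, 20)
        from math import comb

        assert out["p_fisher"] == pytest.approx(2.0 / comb(40, 20), rel=1e-6)
        assert out["p_fisher"] < 1e-9

    def test_zero_n_rejected(self):
        with pytest.raises(InsufficientDataError):
            ct.incidence_comparison((0, 0), (1, 2))
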