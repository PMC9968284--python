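import numpy as np
import pandas as pd
import pytest
from scipy import stats

from viromeflow.communal import (
    assign_strata,
    bootstrap_sharing,
    communal_set,
    strata_abundance,
    subject_presence,
)
from viromeflow.io_formats import (
    CohortDesign,
    SampleRecord,
    ValidationError,
    VirusRecord,
)
from conftest import toy_design


def _presence(design, data):
    """data: virus -> set of sample ids where present."""
    samples = design.sample_ids
    viruses = sorted(data)
    return pd.DataFrame(
        [[s in data[v] for s in samples] for v in viruses],
        index=viruses,
        columns=samples,
    )


class TestSubjectPresence:
    def test_union_vs_single_timepoint(self):
        design = toy_design(2, 3)
        pres = _presence(design, {"v1": {"S0_T1"}, "v2": {"S1_T2", "S1_T3"}})
        union = subject_presence(pres, design, mode="union")
        assert bool(union.loc["v1", "S0"]) and not bool(union.loc["v1", "S1"])
        t2 = subject_presence(pres, design, mode="single_timepoint", timepoint=2)
        assert not bool(t2.loc["v1", "S0"])
        assert bool(t2.loc["v2", "S1"])

    def test_absent_everywhere_absent_in_both_modes(self):
        design = toy_design(2, 2)
        pres = _presence(design, {"v1": set()})
        for mode, kw in (("union", {}), ("single_timepoint", {"timepoint": 1})):
            sp = subject_presence(pres, design, mode=mode, **kw)
            assert not sp.to_numpy().any()

    def test_union_equals_rowwise_or_oracle(self, rng):
        design = toy_design(5, 3)
        viruses = [f"v{i}" for i in range(40)]
        pres = pd.DataFrame(
            rng.random((40, len(design))) < 0.3,
            index=viruses,
            columns=design.sample_ids,
        )
        union = subject_presence(pres, design, mode="union")
        for subj in design.subject_ids:
            cols = [r.sample_id for r in design.by_subject[subj]]
            assert (union[subj] == pres[cols].any(axis=1)).all()

    def test_missing_fixed_timepoint_excludes_subject(self, caplog):
        samples = [
            SampleRecord("A_T1", "A", "Control", 1, 0),
            SampleRecord("A_T2", "A", "Control", 2, 90),
            SampleRecord("B_T1", "B", "Control", 1, 0),
        ]
        design = CohortDesign(samples)
        pres = _presence(design, {"v1": {"A_T2"}})
        sp = subject_presence(pres, design, mode="single_timepoint", timepoint=2)
        assert list(sp.columns) == ["A"]


class TestCommunalSet:
    def test_universal_and_private_extremes(self):
        design = toy_design(3, 1)
        all_shared = _presence(
            design, {"v1": set(design.sample_ids), "v2": set(design.sample_ids)}
        )
        prof = communal_set(subject_presence(all_shared, design))
        assert prof["is_communal"].all()
        assert (prof["sharing_fraction"] == 1.0).all()

        private = _presence(design, {"v1": {"S0_T1"}, "v2": {"S1_T1"}})
        prof = communal_set(subject_presence(private, design))
        assert not prof["is_communal"].any()

    def test_three_subject_overlap_enumeration(self):
        design = toy_design(3, 1)
        pres = _presence(
            design,
            {
                "v1": {"S0_T1", "S1_T1"},
                "v2": {"S2_T1"},
                "v3": {"S0_T1", "S1_T1", "S2_T1"},
            },
        )
        prof = communal_set(subject_presence(pres, design))
        assert prof.loc["v1", "subjects_detected"] == 2
        assert prof.loc["v2", "subjects_detected"] == 1
        assert prof.loc["v3", "subjects_detected"] == 3
        assert prof["is_communal"].tolist() == [True, False, True]
        assert prof.loc["v3", "sharing_fraction"] == pytest.approx(1.0)


class TestBootstrapSharing:
    def _cohort(self, rng, n_subjects=15, n_virus=30, p=0.5):
        design = toy_design(n_subjects, 3)
        carriage = rng.random((n_virus, n_subjects)) < p
        data = {}
        for v in range(n_virus):
            cells = set()
            for s in range(n_subjects):
                if carriage[v, s]:
                    cells |= {f"S{s}_T{t}" for t in (1, 2, 3)}
            data[f"v{v:03d}"] = cells
        return design, _presence(design, data), carriage

    def test_fixed_seed_bit_identical(self, rng):
        design, pres, _ = self._cohort(rng)
        communal = list(pres.index)
        a = bootstrap_sharing(pres, design, communal, 10, 5, seed=7)
        b = bootstrap_sharing(pres, design, communal, 10, 5, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_spectrum_non_increasing_in_k(self, rng):
        design, pres, _ = self._cohort(rng)
        spec = bootstrap_sharing(pres, design, list(pres.index), 10, 10, seed=3)
        for (_, _), grp in spec.groupby(["condition", "replicate"]):
            counts = grp.sort_values("k")["count"].tolist()
            assert counts == sorted(counts, reverse=True)

    def test_universally_shared_spectrum_flat(self):
        design = toy_design(12, 2)
        pres = _presence(
            design, {f"v{i}": set(design.sample_ids) for i in range(5)}
        )
        spec = bootstrap_sharing(pres, design, [f"v{i}" for i in range(5)], 10, 4, 1)
        assert (spec["count"] == 5).all()

    def test_extending_reps_preserves_earlier_replicates(self, rng):
        design, pres, _ = self._cohort(rng)
        communal = list(pres.index)
        short = bootstrap_sharing(pres, design, communal, 10, 4, seed=11)
        long = bootstrap_sharing(pres, design, communal, 10, 8, seed=11)
        pd.testing.assert_frame_equal(short, long[long["replicate"] < 4].reset_index(drop=True))

    def test_small_condition_rejected_with_suggestion(self):
        design = toy_design(4, 2)
        pres = _presence(design, {"v1": set(design.sample_ids)})
        with pytest.raises(ValidationError, match="n_subjects"):
            bootstrap_sharing(pres, design, ["v1"], n_subjects=10, reps=2, seed=0)

    def test_converges_to_hypergeometric_expectation(self, rng):
        """With carriage fixed, the bootstrap mean at each k converges to the
        closed-form hypergeometric tail expectation over the realised cohort."""
        n_subj, n_draw = 20, 10
        design, pres, carriage = self._cohort(rng, n_subjects=n_subj, p=0.5)
        reps = 2000
        spec = bootstrap_sharing(pres, design, list(pres.index), n_draw, reps, seed=5)
        m = carriage.sum(axis=1)  # realised carriers per virus
        for k in range(1, n_draw + 1):
            expect = sum(
                stats.hypergeom.sf(k - 1, n_subj, mv, n_draw) for mv in m
            )
            per_virus_var = [
                stats.hypergeom.sf(k - 1, n_subj, mv, n_draw)
                * (1 - stats.hypergeom.sf(k - 1, n_subj, mv, n_draw))
                for mv in m
            ]
            se = np.sqrt(sum(per_virus_var) / reps)
            got = spec.loc[spec["k"] == k, "count"].mean()
            assert abs(got - expect) <= 3 * max(se, 0.02)


class TestStrata:
    def test_single_virus_lands_in_30_40_stratum(self):
        labels = assign_strata(pd.Series({"v1": 0.35}))
        assert labels["v1"] == "30-40%"

    def test_bin_edges_left_open_right_closed(self):
        s = pd.Series({"a": 0.1, "b": 0.1000001, "c": 0.4, "d": 0.41, "e": 1.0})
        labels = assign_strata(s)
        assert labels["a"] == "0-10%"
        assert labels["b"] == "10-20%"
        assert labels["c"] == "30-40%"
        assert labels["d"] == "40-100%"
        assert labels["e"] == "40-100%"

    def _toy(self):
        design = CohortDesign(
            [
                SampleRecord("c1", "A", "Control", 1, 0),
                SampleRecord("c2", "B", "Control", 1, 0),
                SampleRecord("d1", "C", "CD", 1, 0),
                SampleRecord("d2", "D", "CD", 1, 0),
            ]
        )
        rel = pd.DataFrame(
            {
                "c1": [0.5, 0.3, 0.2, 0.0],
                "c2": [0.4, 0.4, 0.0, 0.2],
                "d1": [0.1, 0.6, 0.3, 0.0],
                "d2": [0.2, 0.5, 0.0, 0.3],
            },
            index=["v1", "v2", "v3", "v4"],
        )
        profile = pd.DataFrame(
            {
                "subjects_detected": [4, 4, 2, 2],
                "sharing_fraction": [1.0, 0.35, 0.15, 0.05],
                "is_communal": [True, True, True, True],
            },
            index=["v1", "v2", "v3", "v4"],
        )
        return design, rel, profile

    def test_stratum_means_match_hand_enumeration(self):
        design, rel, profile = self._toy()
        out = strata_abundance(rel, profile, design)
        row = out[(out.stratum == "40-100%") & (out.condition == "Control")].iloc[0]
        assert row["mean_ra"] == pytest.approx((0.5 + 0.4) / 2)  # v1 across c1,c2
        assert row["n_viruses"] == 1
        row = out[(out.stratum == "30-40%") & (out.condition == "CD")].iloc[0]
        assert row["mean_ra"] == pytest.approx((0.6 + 0.5) / 2)  # v2 across d1,d2

    def test_cumulative_conserves_total_communal_abundance(self):
        design, rel, profile = self._toy()
        out = strata_abundance(rel, profile, design)
        for cond, samples in (("Control", ["c1", "c2"]), ("CD", ["d1", "d2"])):
            total = rel.loc[profile.index[profile.is_communal], samples].mean(axis=1).sum()
            got = out.loc[out.condition == cond, "cum_ra"].sum()
            assert got == pytest.approx(total, abs=1e-9)

    def test_subset_commutes_with_stratification(self):
        design, rel, profile = self._toy()
        catalog = [
            VirusRecord("v1", 5000, lysogenic=True),
            VirusRecord("v2", 5000, lysogenic=False),
            VirusRecord("v3", 5000, lysogenic=True),
            VirusRecord("v4", 5000, lysogenic=None),
        ]
        # filter-then-stratify
        lys = [r.virus_id for r in catalog if r.lysogenic is True]
        pre = strata_abundance(
            rel.loc[lys], profile.loc[lys], design, subset="all"
        )
        # stratify-then-filter
        post = strata_abundance(
            rel, profile, design, subset="lysogenic", catalog=catalog
        )
        pd.testing.assert_frame_equal(
            pre[["stratum", "condition", "mean_ra", "cum_ra", "n_viruses"]],
            post[["stratum", "condition", "mean_ra", "cum_ra", "n_viruses"]],
        )

    def test_empty_stratum_reported_without_test(self):
        design, rel, profile = self._toy()
        out = strata_abundance(rel, profile, design)
        empty = out[(out.stratum == "20-30%")]
        assert (empty["n_viruses"] == 0).all()
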