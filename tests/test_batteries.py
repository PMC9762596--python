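"""Per-clade regression batteries and significance filtering."""

import numpy as np
import pandas as pd
import pytest

from cladal.batteries import (filter_significant, run_age_battery,
                              run_diet_battery, run_il6_battery,
                              combined_significant)
from cladal.clades import build_clade_matrix, enumerate_clades
from cladal.simulate import (PlantedEffect, SimulationDesign,
                             simulate_dataset, simulate_metadata,
                             simulate_counts, simulate_tree)
from cladal.tables import AsvTable, prevalence_filter, rarefy
from cladal.tree import ValidationError

from conftest import make_metadata


def planted_dataset(covariate, n_tips=24, seed=5, log_fc=1.5, **scope):
    """Simulated dataset with a single planted effect on one small clade."""
    tree = simulate_tree(n_tips, seed=seed)
    clades = enumerate_clades(tree)
    small = [(cid, mem) for cid, mem in clades if len(mem) == 2]
    cid, mem = small[0]
    eff = PlantedEffect(cid, mem, covariate, log_fc, **scope)
    design = SimulationDesign(n_tips=n_tips, hosts_per_cell=10,
                              effects=(eff,), seed=seed)
    meta = simulate_metadata(design)
    table, truth = simulate_counts(design, tree, meta)
    ctu = build_clade_matrix(tree, rarefy(table, int(table.sample_totals().min()),
                                          seed=seed))
    return ctu, meta, cid


class TestFilterSignificant:
    @pytest.fixture
    def frame(self):
        return pd.DataFrame({
            "clade_id": ["c1", "c2", "c3", "c4"],
            "battery": "age", "family": "all",
            "slope": [1.0, 1.0, 1.0, 1.0], "se": 0.1,
            "p": [0.001, 0.001, 0.15, 0.001],
            "q": [0.01, 0.01, 0.20, 0.01],
            "intercept": [-0.3, 1.2, 1.2, 0.5],
            "theta": 2.0, "sigma_b": np.nan,
            "converged": [True, True, True, False],
            "n_obs": 100, "excluded_reason": "", "significant": False,
        })

    def test_negative_intercept_excluded_with_reason(self, frame):
        out = filter_significant(frame)
        row = out[out["clade_id"] == "c1"].iloc[0]
        assert not row["significant"]
        assert row["excluded_reason"] == "negative_intercept"

    def test_positive_intercept_retained(self, frame):
        out = filter_significant(frame)
        assert out[out["clade_id"] == "c2"].iloc[0]["significant"]

    def test_non_significant_q_not_marked(self, frame):
        out = filter_significant(frame)
        row = out[out["clade_id"] == "c3"].iloc[0]
        assert not row["significant"]
        assert row["excluded_reason"] == ""

    def test_nonconverged_excluded(self, frame):
        out = filter_significant(frame)
        row = out[out["clade_id"] == "c4"].iloc[0]
        assert not row["significant"]
        assert row["excluded_reason"] == "nonconverged"

    def test_invalid_alpha_rejected(self, frame):
        with pytest.raises(ValidationError, match="alpha"):
            filter_significant(frame, alpha=1.5)


class TestAgeBattery:
    def test_planted_age_effect_recovered(self):
        """A log-FC 1.5 age effect on one clade is detected in nearly
        every replicate at these sample sizes."""
        hits = 0
        n_rep = 10
        for i in range(n_rep):
            ctu, meta, cid = planted_dataset("age", seed=100 + i)
            res = run_age_battery(ctu, meta)
            hits += int(cid in set(res.significant["clade_id"]))
        assert hits >= 9

    def test_identical_age_groups_nothing_significant(self):
        """Counts copied between age groups: exchangeability gives no
        discoveries."""
        tree = simulate_tree(12, seed=3)
        rng = np.random.default_rng(0)
        block = rng.integers(0, 40, size=(20, 12))
        counts = pd.DataFrame(np.vstack([block, block]),
                              columns=tree.tip_names)
        meta = make_metadata(hosts_per_cell=5)
        counts.index = [s for s in meta.sample_ids][:80][:40]
        # first 40 sample ids: assign 20 young and 20 old with equal counts
        md = meta.data
        young = md[md["age"] == "young"].index[:20]
        old = md[md["age"] == "old"].index[:20]
        counts.index = list(young) + list(old)
        ctu = build_clade_matrix(tree, AsvTable(counts))
        res = run_age_battery(ctu, meta.subset(counts.index))
        assert int(res.table["significant"].sum()) == 0

    def test_all_zero_clade_marked_degenerate(self, quartet_tree):
        counts = pd.DataFrame(
            np.column_stack([np.zeros(16, dtype=int),
                             np.zeros(16, dtype=int),
                             np.ones(16, dtype=int) * 5,
                             np.arange(16) + 1]),
            columns=list("abcd"))
        meta = make_metadata(hosts_per_cell=2)
        counts.index = meta.sample_ids[:16]
        ctu = build_clade_matrix(quartet_tree, AsvTable(counts))
        res = run_age_battery(ctu, meta.subset(counts.index))
        ab = [cid for cid, mem in ctu.members.items() if mem == frozenset("ab")]
        row = res.table[res.table["clade_id"] == ab[0]].iloc[0]
        assert row["excluded_reason"] == "degenerate"
        assert not row["significant"]

    def test_deterministic_rerun(self):
        ctu, meta, _ = planted_dataset("age", seed=7)
        r1 = run_age_battery(ctu, meta).table
        r2 = run_age_battery(ctu, meta).table
        pd.testing.assert_frame_equal(r1, r2)


class TestDietBattery:
    def test_planted_effect_found_only_in_its_family(self):
        """Effect planted in the old ZAM2 family: detected there and in
        no other age x study family."""
        in_fam = 0
        other_fam = 0
        n_rep = 8
        for i in range(n_rep):
            ctu, meta, cid = planted_dataset("diet", n_tips=16,
                                             seed=200 + i,
                                             age="old", study="ZAM2")
            res = run_diet_battery(ctu, meta)
            sig = res.significant
            hit = sig[(sig["clade_id"] == cid)]
            in_fam += int("old_ZAM2" in set(hit["family"]))
            other_fam += int(len(set(hit["family"]) - {"old_ZAM2"}) > 0)
        assert in_fam >= 7
        assert other_fam <= 1

    def test_host_baseline_offsets_absorbed_by_random_intercept(self):
        """Abundance differing between arms only through per-host offsets
        constant across timepoints: the random intercept moves inference
        to the host level, so the slope SE grows to cover the host
        variance and discoveries are rare.  (All clades share the same
        host offsets, so the rare false-positive dataset flags a whole
        family at once; the typical dataset flags nothing.)"""
        from cladal.nb import NBGLM, NBGLMM
        tree = simulate_tree(8, seed=1)
        zero_sig_runs = 0
        n_seeds = 4
        for seed in range(n_seeds):
            meta = make_metadata(hosts_per_cell=10, seed=2)
            md = meta.data
            rng = np.random.default_rng(seed)
            off = {h: rng.normal(0, 0.5) for h in md["host_id"].unique()}
            mu = np.exp(3.0 + np.array([off[h] for h in md["host_id"]]))
            counts = pd.DataFrame(
                rng.poisson(mu[:, None], size=(len(md), 8)),
                index=md.index, columns=tree.tip_names)
            ctu = build_clade_matrix(tree, AsvTable(counts))
            res = run_diet_battery(ctu, meta)
            zero_sig_runs += int(res.table["significant"].sum() == 0)
            # GLMM slope SE exceeds the independence-assuming GLM SE
            fam = md[(md["age"] == "young") & (md["study"] == "ZAM1")]
            y = ctu.abundances.loc[fam.index, ctu.root_clade_id].to_numpy()
            x = (fam["diet"] == "ZS").to_numpy(dtype=float)
            X = np.column_stack([np.ones(len(x)), x])
            glm_se = NBGLM(y, X).fit().bse[1]
            glmm_se = NBGLMM(y, X, fam["host_id"].to_numpy()).fit().bse[1]
            # the GLM partially absorbs host variance into theta, so the
            # gap is moderate but systematic
            assert glmm_se > 1.25 * glm_se
        assert zero_sig_runs >= n_seeds - 1

    def test_family_with_too_few_hosts_skipped(self):
        ctu, meta, _ = planted_dataset("age", n_tips=8, seed=11)
        # drop all but one ZS host in the young ZAM1 family
        md = meta.data
        zs_young = md[(md["age"] == "young") & (md["diet"] == "ZS")]
        keep_host = zs_young["host_id"].unique()[0]
        drop = zs_young[zs_young["host_id"] != keep_host].index
        kept = md.index.difference(drop)
        from cladal.clades import CladeMatrix
        sub = CladeMatrix(ctu.abundances.loc[kept], ctu.members,
                          ctu.taxonomy_labels)
        res = run_diet_battery(sub, meta.subset(kept))
        assert "young_ZAM1" in res.skipped
        assert "fewer than 2 hosts" in res.skipped["young_ZAM1"]


class TestIl6Battery:
    def test_planted_il6_slope_detected_with_positive_sign(self):
        hits = 0
        n_rep = 10
        for i in range(n_rep):
            ctu, meta, cid = planted_dataset("il6", seed=400 + i,
                                             log_fc=0.02, age="old")
            res = run_il6_battery(ctu, meta)
            sig = res.significant
            hit = sig[(sig["clade_id"] == cid) & (sig["family"] == "old")]
            hits += int(len(hit) > 0 and (hit["slope"] > 0).all())
        assert hits >= 9

    def test_wk0_samples_ignored(self):
        ctu, meta, _ = planted_dataset("age", n_tips=8, seed=21)
        res = run_il6_battery(ctu, meta)
        n_wk6_young = ((meta.data["timepoint"] == "wk6")
                       & (meta.data["age"] == "young")
                       & meta.data["il6"].notna()).sum()
        young = res.table[res.table["family"] == "young"]
        assert (young["n_obs"] == n_wk6_young).all()

    def test_constant_il6_group_skipped(self):
        ctu, meta, _ = planted_dataset("age", n_tips=8, seed=22)
        md = meta.data.copy()
        md.loc[md["age"] == "young", "il6"] = \
            md.loc[md["age"] == "young", "il6"].notna() * 77.0
        md.loc[(md["age"] == "young") & (md["timepoint"] == "wk0"), "il6"] = np.nan
        from cladal.tables import SampleMetadata
        res = run_il6_battery(ctu, SampleMetadata(md))
        assert res.skipped.get("young") == "IL-6 constant within the group"

    def test_shuffled_il6_rarely_discovers(self):
        """Permuting IL-6 across samples breaks every association."""
        any_sig = 0
        n_rep = 12
        for i in range(n_rep):
            ctu, meta, cid = planted_dataset("age", n_tips=16, seed=500 + i)
            rng = np.random.default_rng(600 + i)
            md = meta.data.copy()
            wk6 = md["timepoint"] == "wk6"
            md.loc[wk6, "il6"] = rng.permutation(md.loc[wk6, "il6"].values)
            from cladal.tables import SampleMetadata
            res = run_il6_battery(ctu, SampleMetadata(md))
            any_sig += int(res.table["significant"].sum() > 0)
        assert any_sig <= 2


class TestCombined:
    def test_union_table_covers_all_batteries(self):
        ctu, meta, cid = planted_dataset("age", seed=33)
        age = run_age_battery(ctu, meta)
        il6 = run_il6_battery(ctu, meta)
        combined = combined_significant([age, il6])
        assert set(combined["battery"]) <= {"age", "il6"}
        assert len(combined) == len(age.significant) + len(il6.significant)
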