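"""Mixed-ANOVA SnPM: closed-form oracles, exhaustive enumeration,
calibration and power properties.

The primary oracle is an independently written, loop-based split-plot
sum-of-squares calculation; pingouin's mixed_anova provides a second,
external cross-check.
"""

import itertools

import numpy as np
import pytest

from gaitwave.signal_io import DEFAULT_MONTAGE
from gaitwave.snpm_stats import (DesignMatrix, anova_curves, build_designs,
                                 cluster_inference, normality_check,
                                 n_distinct_permutations, omnibus_p,
                                 permutation_distribution,
                                 permutation_threshold, posthoc, run_snpm,
                                 run_snpm_all_electrodes,
                                 threshold_from_distribution)
from gaitwave.synthetic_data import (DEFAULT_CYCLE_NOISE_SD, EffectSpec,
                                     generate_cohort_matrices)


def oracle_mixed_anova(y, groups):
    """Textbook split-plot ANOVA by explicit cell-mean arithmetic.

    ``y``: subjects x 2 array (one timepoint); ``groups``: per-subject
    labels.  Returns (F_group, F_condition, F_interaction).
    """
    y = np.asarray(y, dtype=float)
    labels = sorted(set(groups))
    n = y.shape[0]
    c = 2
    grand = y.mean()
    subj_means = y.mean(axis=1)
    ss_between_subj = c * sum((m - grand) ** 2 for m in subj_means)
    ss_group = 0.0
    for g in labels:
        sel = [i for i in range(n) if groups[i] == g]
        ss_group += c * len(sel) * (subj_means[sel].mean() - grand) ** 2
    ss_subj_within = ss_between_subj - ss_group

    cond_means = y.mean(axis=0)
    ss_cond = sum(n * (cm - grand) ** 2 for cm in cond_means)
    ss_int = 0.0
    for g in labels:
        sel = [i for i in range(n) if groups[i] == g]
        gm = subj_means[sel].mean()
        for j in range(c):
            cell = y[sel, j].mean()
            ss_int += len(sel) * (cell - gm - cond_means[j] + grand) ** 2
    ss_within_subj = float(((y - subj_means[:, None]) ** 2).sum())
    ss_err = ss_within_subj - ss_cond - ss_int

    ms_subj = ss_subj_within / (n - 2)
    ms_err = ss_err / (n - 2)
    return ss_group / ms_subj, ss_cond / ms_err, ss_int / ms_err


def random_design(rng, n1=4, n2=5, t=3, scale=1.0):
    data = rng.normal(scale=scale, size=(n1 + n2, 2, t)) \
        + rng.normal(size=(n1 + n2, 1, 1))  # subject random effects
    groups = np.array(["O"] * n1 + ["T"] * n2, dtype=object)
    return DesignMatrix(data=data, group=groups)


class TestAnovaCurves:
    def test_matches_loop_oracle_on_many_random_designs(self, rng):
        for _ in range(100):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 6))
            dm = random_design(rng, n1, n2, t=2)
            curves = anova_curves(dm)
            for t in range(2):
                fg, fc, fi = oracle_mixed_anova(dm.data[:, :, t], dm.group)
                assert curves.F_group[t] == pytest.approx(fg, rel=1e-8)
                assert curves.F_condition[t] == pytest.approx(fc, rel=1e-8)
                assert curves.F_interaction[t] == pytest.approx(fi, rel=1e-8)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        dm = random_design(rng, 5, 7, t=1)
        curves = anova_curves(dm)
        rows = []
        for i in range(dm.n_subjects):
            for ci, cond in enumerate(("sSC", "SC")):
                rows.append({"subj": i, "grp": dm.group[i], "cond": cond,
                             "y": dm.data[i, ci, 0]})
        aov = pg.mixed_anova(pd.DataFrame(rows), dv="y", within="cond",
                             subject="subj", between="grp")
        by_src = {r.Source: r.F for r in aov.itertuples()}
        assert curves.F_group[0] == pytest.approx(by_src["grp"], rel=1e-9)
        assert curves.F_condition[0] == pytest.approx(by_src["cond"], rel=1e-9)
        assert curves.F_interaction[0] == pytest.approx(
            by_src["Interaction"], rel=1e-9)

    def test_identical_observations_flagged_degenerate(self):
        dm = DesignMatrix(data=np.ones((6, 2, 4)),
                          group=np.array(["O"] * 3 + ["T"] * 3, dtype=object))
        curves = anova_curves(dm)
        assert curves.degenerate["interaction"].all()
        assert np.all(np.isnan(curves.F_interaction))

    def test_pure_condition_shift_gives_infinite_condition_f(self, rng):
        base = rng.normal(size=(8, 1, 5))
        data = np.concatenate([base + 1.0, base], axis=1)  # same shift, all
        dm = DesignMatrix(data=data,
                          group=np.array(["O"] * 4 + ["T"] * 4, dtype=object))
        curves = anova_curves(dm)
        # with an exactly-zero error mean square the F ratio is +inf;
        # floating-point cancellation can leave a finite but
        # astronomically large ratio at some timepoints
        assert np.all(np.isinf(curves.F_condition)
                      | (curves.F_condition > 1e12))
        assert np.all(curves.degenerate["condition"]
                      == np.isinf(curves.F_condition))
        finite_int = curves.F_interaction[np.isfinite(curves.F_interaction)]
        assert np.allclose(finite_int, 0.0, atol=1e-6)

    def test_single_subject_group_rejected(self, rng):
        dm = DesignMatrix(data=rng.normal(size=(3, 2, 4)),
                          group=np.array(["O", "T", "T"], dtype=object))
        with pytest.raises(ValueError, match="2 subjects per group"):
            anova_curves(dm)


class TestPermutationMachinery:
    def test_distinct_permutation_counts(self, rng):
        dm = random_design(rng, 2, 2, t=2)
        assert n_distinct_permutations(dm, "group") == 6
        assert n_distinct_permutations(dm, "condition") == 16
        assert n_distinct_permutations(dm, "interaction") == 96

    def test_exhaustive_enumeration_matches_brute_force(self, rng):
        """For 2 subjects per group, the condition-effect permutation
        distribution equals a brute-force enumeration of all 16
        within-subject label swaps."""
        dm = random_design(rng, 2, 2, t=3)
        dist = permutation_distribution(dm, "condition", n_perm=100, seed=0)
        assert dist.exhaustive and dist.n_perm == 16

        maxima = []
        for flips in itertools.product([False, True], repeat=4):
            flipped = dm.data.copy()
            for i, f in enumerate(flips):
                if f:
                    flipped[i] = flipped[i, ::-1, :]
            brute = anova_curves(DesignMatrix(
                data=flipped, group=dm.group.copy()))
            maxima.append(np.nan_to_num(brute.F_condition).max())
        assert np.allclose(np.sort(dist.maxima), np.sort(maxima), atol=1e-10)

    def test_alpha_one_returns_distribution_minimum(self, rng):
        dm = random_design(rng, 5, 5, t=4)
        f_star, dist = permutation_threshold(dm, "interaction", n_perm=200,
                                             alpha=1.0, seed=1,
                                             return_distribution=True)
        assert f_star == pytest.approx(dist.maxima.min())

    def test_unattainable_alpha_rejected(self, rng):
        dm = random_design(rng, 2, 2, t=3)
        with pytest.raises(ValueError, match="alpha unattainable"):
            permutation_threshold(dm, "group", n_perm=1000, alpha=0.05,
                                  seed=0)

    def test_threshold_stable_when_doubling_permutations(self, rng):
        """Monte-Carlo F* moves by less than the binomial quantile error
        when n_perm doubles."""
        dm = random_design(rng, 8, 8, t=50)
        f1, d1 = permutation_threshold(dm, "interaction", n_perm=2000,
                                       alpha=0.05, seed=3,
                                       return_distribution=True)
        f2, d2 = permutation_threshold(dm, "interaction", n_perm=4000,
                                       alpha=0.05, seed=4,
                                       return_distribution=True)
        # binomial CI on the 95th percentile of the 2000-draw stream
        order = np.sort(d1.maxima)[::-1]
        lo, hi = order[140], order[64]  # ranks 100 +/- ~2.5 sd(=22)
        assert lo <= f2 <= hi

    def test_exhaustive_and_monte_carlo_agree(self, rng):
        """On a design with 2^8 condition relabelings, the exhaustive
        threshold sits inside the Monte-Carlo binomial error band."""
        dm = random_design(rng, 4, 4, t=20)
        f_ex, d_ex = permutation_threshold(dm, "condition", n_perm=256,
                                           alpha=0.05, seed=0,
                                           return_distribution=True)
        assert d_ex.exhaustive
        f_mc, d_mc = permutation_threshold(dm, "condition", n_perm=200,
                                           alpha=0.05, seed=5,
                                           return_distribution=True)
        assert not d_mc.exhaustive
        order = np.sort(d_mc.maxima)[::-1]
        # ranks 10 +/- 2.5 * sqrt(200 * .05 * .95) ~ 10 +/- 8
        assert order[17] <= f_ex <= order[1]

    def test_relabeled_data_is_distribution_member(self, rng):
        """Applying one scheme permutation to the data and re-running
        yields a max-F that the permutation distribution contains."""
        dm = random_design(rng, 3, 3, t=5)
        dist = permutation_distribution(dm, "condition", n_perm=100, seed=0)
        flipped = dm.data.copy()
        flipped[0] = flipped[0, ::-1, :]
        f_re = np.nan_to_num(anova_curves(DesignMatrix(
            data=flipped, group=dm.group.copy())).F_condition).max()
        assert np.any(np.isclose(dist.maxima, f_re, atol=1e-10))


class TestClusterInference:
    def _dist_for(self, rng, t=100):
        dm = random_design(rng, 6, 6, t=t)
        return dm, permutation_distribution(dm, "interaction", n_perm=300,
                                            seed=2)

    def test_curve_below_threshold_yields_no_clusters(self, rng):
        dm, dist = self._dist_for(rng)
        clusters = cluster_inference(np.zeros(100), 5.0, dist)
        assert clusters == []

    def test_single_run_yields_single_cluster(self, rng):
        dm, dist = self._dist_for(rng)
        curve = np.zeros(100)
        curve[40:45] = 10.0
        clusters = cluster_inference(curve, 5.0, dist)
        assert len(clusters) == 1
        c = clusters[0]
        assert 39.0 <= c.start_pct <= 40.0
        assert 44.0 <= c.end_pct <= 45.0
        assert c.f_max == 10.0
        assert 0 < c.p_cluster <= 1

    def test_cluster_edges_interpolate_at_threshold(self, rng):
        dm, dist = self._dist_for(rng)
        curve = np.zeros(100)
        curve[49:52] = [4.0, 8.0, 4.0]  # crossings between points
        clusters = cluster_inference(curve, 6.0, dist)
        assert len(clusters) == 1
        assert clusters[0].start_pct == pytest.approx(49.5)
        assert clusters[0].end_pct == pytest.approx(50.5)

    def test_interaction_recovery_power(self):
        """An interaction bump at Fz over [3, 8]% of the cycle at 1.5x
        the per-cycle noise SD is recovered (overlapping cluster) in at
        least 90% of replicate cohorts of 12 subjects per group."""
        effect = EffectSpec(
            electrodes=("Fz",), phase_window=(3.0, 8.0),
            amplitude_delta=1.5 * DEFAULT_CYCLE_NOISE_SD,
            factor="interaction", affected_cells=frozenset({"TsSC"}))
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            mats = generate_cohort_matrices(12, effect, seed=40_000 + rep)
            dm = build_designs(mats, DEFAULT_MONTAGE.active_labels)["Fz"]
            dist = permutation_distribution(dm, "interaction", n_perm=1000,
                                            seed=rep)
            f_star = threshold_from_distribution(dist, 0.05)
            obs = np.nan_to_num(anova_curves(dm).F_interaction)
            clusters = cluster_inference(obs, f_star, dist)
            if any(c.overlaps(3.0, 8.0) and c.p_cluster <= 0.05
                   for c in clusters):
                hits += 1
        assert hits / n_rep >= 0.90

    def test_power_monotone_in_effect_size(self):
        """Detection power never decreases over an increasing
        amplitude grid."""
        rates = []
        for delta in (0.0, 0.5 * DEFAULT_CYCLE_NOISE_SD,
                      1.5 * DEFAULT_CYCLE_NOISE_SD):
            effect = EffectSpec(electrodes=("Fz",), phase_window=(3.0, 8.0),
                                amplitude_delta=delta,
                                affected_cells=frozenset({"TsSC"}))
            hits = 0
            for rep in range(20):
                mats = generate_cohort_matrices(12, effect, seed=60_000 + rep)
                dm = build_designs(mats, DEFAULT_MONTAGE.active_labels)["Fz"]
                dist = permutation_distribution(dm, "interaction",
                                                n_perm=500, seed=rep)
                obs = np.nan_to_num(anova_curves(dm).F_interaction)
                hits += omnibus_p(dist, float(obs.max())) <= 0.05
            rates.append(hits / 20)
        assert rates[0] <= rates[1] + 0.1  # MC slack on the null step
        assert rates[1] <= rates[2]
        assert rates[2] >= 0.9


class TestPosthoc:
    def test_identical_cells_give_unit_adjusted_p(self):
        data = np.tile(np.linspace(-1, 1, 10)[None, None, :], (8, 2, 1))
        data += np.arange(8)[:, None, None] * 0.0
        dm = DesignMatrix(data=data,
                          group=np.array(["O"] * 4 + ["T"] * 4, dtype=object))
        results = posthoc(dm, n_perm=200, seed=0)
        assert all(r.p_adjusted == 1.0 for r in results)

    def test_bonferroni_multiplies_by_comparison_count(self, rng):
        dm = random_design(rng, 6, 6, t=10)
        results = posthoc(dm, n_perm=500, seed=1)
        assert len(results) == 4
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, 4 * r.p_raw))

    def test_elevated_cell_drives_its_contrast(self):
        """A TsSC-only elevation puts TsSC vs OsSC at the smallest
        adjusted p (ties allowed: the elevation also separates TsSC
        from its own cued condition) in at least 90% of replicates,
        while the unaffected OSC vs TSC contrast stays clearly above."""
        effect = EffectSpec(electrodes=("Fz",), phase_window=(3.0, 8.0),
                            amplitude_delta=1.5 * DEFAULT_CYCLE_NOISE_SD,
                            affected_cells=frozenset({"TsSC"}))
        wins = 0
        n_rep = 50
        for rep in range(n_rep):
            mats = generate_cohort_matrices(12, effect, seed=70_000 + rep)
            dm = build_designs(mats, DEFAULT_MONTAGE.active_labels)["Fz"]
            results = posthoc(dm, n_perm=300, seed=rep)
            by_pair = {frozenset(r.pair): r.p_adjusted for r in results}
            smallest = min(by_pair.values())
            ok = (by_pair[frozenset({"TsSC", "OsSC"})] == smallest
                  and by_pair[frozenset({"OSC", "TSC"})] > smallest)
            wins += ok
        assert wins / n_rep >= 0.90

    def test_unknown_cell_rejected(self, rng):
        dm = random_design(rng, 3, 3, t=5)
        with pytest.raises(ValueError, match="cell"):
            posthoc(dm, comparisons=(("OSC", "XsSC"),), n_perm=200, seed=0)


class TestNormality:
    def test_p_uniform_under_normal_residuals(self):
        """Shapiro-Wilk p-values are uniform when residuals really are
        normal (KS test over 200 replicate designs)."""
        from scipy import stats as ss

        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(200):
            dm = random_design(rng, 12, 12, t=1)
            pvals.append(normality_check(dm).pvalue[0])
        assert ss.kstest(pvals, "uniform").pvalue > 0.01

    def test_detects_skewed_residuals(self):
        rng = np.random.default_rng(1)
        rejections = 0
        for _ in range(100):
            data = rng.exponential(size=(24, 2, 1))
            dm = DesignMatrix(data=data, group=np.array(
                ["O"] * 12 + ["T"] * 12, dtype=object))
            rejections += normality_check(dm).pvalue[0] < 0.05
        assert rejections > 90

    def test_too_small_design_rejected(self, rng):
        dm = DesignMatrix(data=rng.normal(size=(2, 2, 3)),
                          group=np.array(["O", "T"], dtype=object))
        with pytest.raises(ValueError, match="few"):
            normality_check(dm)


class TestOmnibusDriver:
    def test_same_seed_identical_reports(self, rng):
        mats = generate_cohort_matrices(4, EffectSpec.null(), seed=3)
        r1 = run_snpm_all_electrodes(mats, DEFAULT_MONTAGE.active_labels[:2],
                                     n_perm=200, seed=5)
        r2 = run_snpm_all_electrodes(mats, DEFAULT_MONTAGE.active_labels[:2],
                                     n_perm=200, seed=5)
        for label in r1:
            assert r1[label].to_dict() == r2[label].to_dict()

    def test_effect_localized_to_injected_electrode(self):
        """A strong Fz-only interaction lights up Fz and no more than a
        false-positive share of the other electrodes."""
        effect = EffectSpec(electrodes=("Fz",), phase_window=(3.0, 8.0),
                            amplitude_delta=2 * DEFAULT_CYCLE_NOISE_SD,
                            affected_cells=frozenset({"TsSC"}))
        mats = generate_cohort_matrices(12, effect, seed=123)
        results = run_snpm_all_electrodes(
            mats, DEFAULT_MONTAGE.active_labels, n_perm=500, seed=9,
            run_posthoc=False)
        assert results["Fz"].significant("interaction")
        others = [lab for lab, r in results.items()
                  if lab != "Fz" and r.significant("interaction")]
        assert len(others) <= 4  # ~29 null electrodes at alpha 0.05

    def test_posthoc_runs_only_after_significant_interaction(self):
        effect = EffectSpec(electrodes=("Fz",), phase_window=(3.0, 8.0),
                            amplitude_delta=2 * DEFAULT_CYCLE_NOISE_SD,
                            affected_cells=frozenset({"TsSC"}))
        mats = generate_cohort_matrices(12, effect, seed=321)
        designs = build_designs(mats, DEFAULT_MONTAGE.active_labels)
        hit = run_snpm(designs["Fz"], n_perm=500, seed=2)
        assert hit.significant("interaction")
        assert len(hit.posthoc) == 4
        null_mats = generate_cohort_matrices(12, EffectSpec.null(), seed=322)
        null_designs = build_designs(null_mats,
                                     DEFAULT_MONTAGE.active_labels)
        miss = run_snpm(null_designs["Cz"], n_perm=500, seed=2)
        if not miss.significant("interaction"):
            assert miss.posthoc == []

    def test_subject_missing_condition_rejected(self, rng):
        mats = generate_cohort_matrices(2, EffectSpec.null(), seed=0)
        with pytest.raises(ValueError, match="missing condition"):
            build_designs(mats[:-1], DEFAULT_MONTAGE.active_labels)
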