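"""Median-split labeling, t test and mixed ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from corticolfp.phenotype import (
    PhenotypeLabels,
    average_last_sessions,
    median_split,
    mixed_anova_2x2,
    two_sample_t,
)
from corticolfp.synthetic import CohortSpec, generate_drinking_table


def drinking_frame(sessions_by_subject, session_type="training"):
    rows = [
        (s, i + 1, session_type, v)
        for s, vals in sessions_by_subject.items()
        for i, v in enumerate(vals)
    ]
    return pd.DataFrame(
        rows, columns=["subject_id", "session_index", "session_type", "g_per_kg"]
    )


class TestAverageLastSessions:
    def test_mean_of_last_k(self):
        table = drinking_frame({"a": [1.0, 2.0, 3.0]})
        assert average_last_sessions(table, k=3) == {"a": 2.0}

    def test_k_one_takes_final_session(self):
        table = drinking_frame({"a": [1.0, 2.0, 5.0]})
        assert average_last_sessions(table, k=1) == {"a": 5.0}

    def test_twelve_sessions_k3_uses_sessions_10_to_12(self):
        vals = list(np.arange(1.0, 13.0))  # session i has value i
        table = drinking_frame({"a": vals})
        # brute-force slice oracle
        expected = np.mean(sorted(vals)[-3:])
        assert average_last_sessions(table, k=3)["a"] == pytest.approx(expected)
        # order independence: shuffle row order
        shuffled = table.sample(frac=1, random_state=0)
        assert average_last_sessions(shuffled, k=3)["a"] == pytest.approx(expected)

    def test_too_few_sessions_names_subject(self):
        table = drinking_frame({"a": [1.0, 2.0], "b": [1, 2, 3]})
        with pytest.raises(ValueError, match="'a'"):
            average_last_sessions(table, k=3)

    def test_only_requested_session_type_counted(self):
        training = drinking_frame({"a": [1.0, 1.0, 1.0]})
        stim = drinking_frame({"a": [9.0, 9.0, 9.0]}, session_type="stimulation")
        stim["session_index"] += 3
        table = pd.concat([training, stim], ignore_index=True)
        assert average_last_sessions(table, k=3) == {"a": 1.0}


class TestMedianSplit:
    def test_thirteen_distinct_values_split_7_6(self):
        values = {f"r{i}": float(i) for i in range(13)}
        labels = median_split(values)
        assert len(labels.subjects("HD")) == 7
        assert len(labels.subjects("LD")) == 6
        assert labels.group("r6") == "HD"  # the median subject

    def test_two_subjects(self):
        labels = median_split({"lo": 1.0, "hi": 2.0})
        assert labels.labels == {"lo": "LD", "hi": "HD"}

    def test_all_equal_degenerate_all_hd(self):
        labels = median_split({"a": 1.0, "b": 1.0, "c": 1.0})
        assert set(labels.labels.values()) == {"HD"}

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.integers(min_value=-1000, max_value=1000),
            min_size=3, max_size=15, unique=True,
        )
    )
    def test_invariant_under_monotone_transform(self, values):
        subjects = {f"s{i}": float(v) for i, v in enumerate(values)}
        base = median_split(subjects)
        # strictly monotone map preserving distinctness on this grid
        warped = median_split(
            {k: float(np.expm1(v / 500.0)) for k, v in subjects.items()}
        )
        assert base.labels == warped.labels


class TestTwoSampleT:
    def test_identical_groups(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == 1.0
        assert res.df == 4

    def test_df_is_n_minus_2(self):
        res = two_sample_t(np.arange(7.0), np.arange(6.0))
        assert res.df == 11

    def test_matches_brute_force_formula(self):
        """Agrees with the from-sums pooled-t computation to 1e-10."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.normal(0, 1, 7), rng.normal(0.5, 2, 6)
            res = two_sample_t(a, b)
            na, nb = 7, 6
            sa = ((a - a.mean()) ** 2).sum()
            sb = ((b - b.mean()) ** 2).sum()
            sp = np.sqrt((sa + sb) / (na + nb - 2) * (1 / na + 1 / nb))
            t_bf = (a.mean() - b.mean()) / sp
            assert res.t == pytest.approx(t_bf, abs=1e-10)
            assert res.p == pytest.approx(2 * stats.t.sf(abs(t_bf), 11), abs=1e-10)
            # and with the reference implementation
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert res.t == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_contracts(self):
        res = two_sample_t([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(res.t) and res.p == 0.0
        res = two_sample_t([1.0, 1.0], [1.0, 1.0])
        assert res.t == 0.0 and res.p == 1.0


def random_anova_inputs(seed, n_hd=7, n_ld=6, hd_drop=0.0):
    rng = np.random.default_rng(seed)
    subs = [f"r{i}" for i in range(n_hd + n_ld)]
    labels = PhenotypeLabels(
        {s: ("HD" if i < n_hd else "LD") for i, s in enumerate(subs)}, 0.0
    )
    pre = {s: float(rng.normal(1.0, 0.3)) for s in subs}
    stim = {
        s: pre[s] + float(rng.normal(-hd_drop if labels.group(s) == "HD" else 0.0, 0.2))
        for s in subs
    }
    return pre, stim, labels


class TestMixedAnova:
    def test_no_change_gives_zero_time_effects(self):
        pre, _, labels = random_anova_inputs(1)
        res = mixed_anova_2x2(pre, dict(pre), labels)
        assert res["time"]["F"] == 0.0
        assert res["time*group"]["F"] == 0.0

    def test_denominator_df_is_11_for_13_subjects(self):
        pre, stim, labels = random_anova_inputs(2)
        res = mixed_anova_2x2(pre, stim, labels)
        for effect in ("group", "time", "time*group"):
            assert res[effect]["df1"] == 1
            assert res[effect]["df2"] == 11

    def test_interaction_equals_squared_difference_score_t(self):
        """Classical 2-level equivalence, asserted to 1e-8."""
        for seed in range(10):
            pre, stim, labels = random_anova_inputs(seed, hd_drop=0.3)
            res = mixed_anova_2x2(pre, stim, labels)
            d_hd = [stim[s] - pre[s] for s in labels.subjects("HD")]
            d_ld = [stim[s] - pre[s] for s in labels.subjects("LD")]
            t = two_sample_t(d_hd, d_ld).t
            assert res["time*group"]["F"] == pytest.approx(t**2, abs=1e-8)

    def test_matches_pingouin_reference(self):
        """F, p and partial eta squared agree with pingouin.mixed_anova."""
        pg = pytest.importorskip("pingouin")
        pre, stim, labels = random_anova_inputs(7, hd_drop=0.3)
        res = mixed_anova_2x2(pre, stim, labels)
        long = pd.DataFrame(
            [
                {"subject": s, "time": ph, "group": labels.group(s),
                 "y": (pre if ph == "pre" else stim)[s]}
                for s in pre for ph in ("pre", "stim")
            ]
        )
        ref = pg.mixed_anova(
            long, dv="y", within="time", subject="subject", between="group"
        ).set_index("Source")
        for ours, theirs in [("group", "group"), ("time", "time"),
                             ("time*group", "Interaction")]:
            assert res[ours]["F"] == pytest.approx(ref.loc[theirs, "F"], rel=1e-9)
            assert res[ours]["p"] == pytest.approx(ref.loc[theirs, "p_unc"], rel=1e-9)
            assert res[ours]["partial_eta_sq"] == pytest.approx(
                ref.loc[theirs, "np2"], rel=1e-9
            )

    def test_partial_eta_sq_consistent_with_f(self):
        """np2 = F / (F + df2) algebra for single-df effects."""
        pre, stim, labels = random_anova_inputs(3, hd_drop=0.4)
        res = mixed_anova_2x2(pre, stim, labels)
        for effect in ("group", "time", "time*group"):
            F, df2 = res[effect]["F"], res[effect]["df2"]
            assert res[effect]["partial_eta_sq"] == pytest.approx(
                F / (F + df2), abs=1e-10
            )

    def test_group_smaller_than_two_rejected(self):
        pre, stim, labels = random_anova_inputs(4, n_hd=1, n_ld=5)
        with pytest.raises(ValueError, match="fewer than 2"):
            mixed_anova_2x2(pre, stim, labels)

    def test_detects_injected_stimulation_response(self):
        """Cohort generator's HD stimulation drop yields a large interaction F."""
        spec = CohortSpec(
            n_subjects=13,
            group_effect={"stim_drop_g_per_kg": 0.5},
            drinking_sd=0.15,
        )
        table = generate_drinking_table(spec, seed=3)
        pre = average_last_sessions(table, k=3)
        stim = {
            s: float(v)
            for s, v in table[table["session_type"] == "stimulation"]
            .groupby("subject_id")["g_per_kg"].mean().items()
        }
        labels = PhenotypeLabels(
            {s: ("HD" if int(s[3:]) <= 7 else "LD") for s in pre}, 0.0
        )
        res = mixed_anova_2x2(pre, stim, labels)
        assert res["time*group"]["p"] < 0.05
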