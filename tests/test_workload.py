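import numpy as np
import pandas as pd
import pytest

from starlimit.workload import (
    TLXRecord,
    likert_summary,
    rm_anova,
    rm_anova_all,
    tlx_total,
)


class TestTLXScoring:
    def test_all_tens_sum_to_sixty(self):
        rec = TLXRecord("N01", "exoscope", 10, 10, 10, 10, 10, 10)
        assert tlx_total(rec) == 60

    def test_scale_maximum(self):
        rec = TLXRecord("N01", "exoscope", 20, 20, 20, 20, 20, 20)
        assert tlx_total(rec) == 120

    def test_hand_sum(self):
        rec = TLXRecord("N01", "microscope", 12, 8, 15, 9, 11, 6)
        assert tlx_total(rec) == 61

    def test_out_of_scale_rejected(self):
        with pytest.raises(ValueError, match="20-point scale"):
            TLXRecord("N01", "exoscope", 25, 10, 10, 10, 10, 10)

    def test_zero_rating_accepted_but_flagged(self):
        rec = TLXRecord("N01", "exoscope", 0, 10, 10, 10, 10, 10)
        assert any("rated 0" in n for n in rec.notes)


def _tlx_table(values):
    """values: {(subject, device): response}; alternate group assignment."""
    rows = []
    subjects = sorted({s for s, _ in values})
    for i, s in enumerate(subjects):
        for dev in ("exoscope", "microscope"):
            rows.append(
                {
                    "subject_id": s,
                    "device": dev,
                    "group": "exo_first" if i % 2 == 0 else "micro_first",
                    "total": values[(s, dev)],
                }
            )
    return pd.DataFrame(rows)


def _cell_means_decomposition(tbl, response="total"):
    """Independent oracle: classical mixed-design sums of squares."""
    grand = tbl[response].mean()
    D = tbl["device"].nunique()
    subj_means = tbl.groupby("subject_id")[response].mean()
    grp_of = tbl.groupby("subject_id")["group"].first()
    grp_means = tbl.groupby("group")[response].mean()
    dev_means = tbl.groupby("device")[response].mean()
    cell_means = tbl.groupby(["group", "device"])[response].mean()
    n_per_group = grp_of.value_counts()

    ss_between_subj = D * ((subj_means - grand) ** 2).sum()
    ss_group = D * sum(
        n_per_group[g] * (grp_means[g] - grand) ** 2 for g in grp_means.index
    )
    ss_subj_within = ss_between_subj - ss_group
    N = len(subj_means)
    ss_device = N * ((dev_means - grand) ** 2).sum()
    ss_inter = sum(
        n_per_group[g] * (cell_means[(g, d)] - grp_means[g] - dev_means[d] + grand) ** 2
        for g, d in cell_means.index
    )
    ss_total = ((tbl[response] - grand) ** 2).sum()
    ss_error = ss_total - ss_group - ss_subj_within - ss_device - ss_inter
    return {
        "group": ss_group,
        "device": ss_device,
        "interaction": ss_inter,
        "subj_within": ss_subj_within,
        "error": ss_error,
        "total": ss_total,
    }


class TestRMAnova:
    def test_constant_response_gives_zero_f(self):
        tbl = _tlx_table({(f"S{i}", d): 50.0 for i in range(8) for d in ("exoscope", "microscope")})
        out = rm_anova(tbl, "total")
        assert np.allclose(out["F"], 0.0)

    def test_pure_device_offset_without_noise(self):
        vals = {}
        for i in range(8):
            vals[(f"S{i}", "exoscope")] = 70.0
            vals[(f"S{i}", "microscope")] = 60.0
        out = rm_anova(_tlx_table(vals), "total")
        dev = out[out["effect"] == "device"].iloc[0]
        grp = out[out["effect"] == "group"].iloc[0]
        assert np.isinf(dev["F"]) and dev["p"] == pytest.approx(0.0)
        assert grp["F"] == pytest.approx(0.0)

    def test_sums_of_squares_match_cell_means_oracle(self):
        rng = np.random.default_rng(17)
        vals = {
            (f"S{i}", d): float(rng.normal(60, 8))
            for i in range(8)
            for d in ("exoscope", "microscope")
        }
        tbl = _tlx_table(vals)
        out = rm_anova(tbl, "total").set_index("effect")
        oracle = _cell_means_decomposition(tbl)
        for effect in ("group", "device", "interaction"):
            assert out.loc[effect, "SS"] == pytest.approx(oracle[effect], abs=1e-8)

    def test_partition_of_total_sum_of_squares(self):
        rng = np.random.default_rng(23)
        vals = {
            (f"S{i}", d): float(rng.normal(55, 10))
            for i in range(10)
            for d in ("exoscope", "microscope")
        }
        oracle = _cell_means_decomposition(_tlx_table(vals))
        parts = (
            oracle["group"]
            + oracle["subj_within"]
            + oracle["device"]
            + oracle["interaction"]
            + oracle["error"]
        )
        assert parts == pytest.approx(oracle["total"], abs=1e-8)

    def test_incomplete_subject_excluded_with_warning(self):
        vals = {
            (f"S{i}", d): 50.0 + i
            for i in range(6)
            for d in ("exoscope", "microscope")
        }
        tbl = _tlx_table(vals)
        tbl = tbl[~((tbl["subject_id"] == "S0") & (tbl["device"] == "microscope"))]
        with pytest.warns(UserWarning, match="S0"):
            out = rm_anova(tbl, "total")
        assert not out.empty

    def test_bh_adjustment_across_responses(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(8):
            for dev in ("exoscope", "microscope"):
                row = {
                    "subject_id": f"S{i}",
                    "device": dev,
                    "group": "exo_first" if i % 2 == 0 else "micro_first",
                }
                row.update({d: float(rng.normal(10, 3)) for d in
                            ("mental", "physical", "temporal", "performance", "effort", "frustration")})
                row["total"] = sum(row[d] for d in
                                   ("mental", "physical", "temporal", "performance", "effort", "frustration"))
                rows.append(row)
        out = rm_anova_all(pd.DataFrame(rows))
        assert np.all(out["p_adj"] >= out["p"] - 1e-12)


class TestLikert:
    def test_three_quarters_prefer(self):
        # 12 of 16 rate 1-2 (prefer the microscope side)
        ratings = pd.DataFrame({"visualization": [1] * 6 + [2] * 6 + [3] * 2 + [4] * 2})
        out = likert_summary(ratings)
        row = out.iloc[0]
        assert row["prefer_microscope"] == 12 and row["n"] == 16
        assert row["pct_microscope"] == pytest.approx(75.0)

    def test_all_neutral(self):
        out = likert_summary(pd.DataFrame({"q": [3] * 10}))
        row = out.iloc[0]
        assert row["pct_microscope"] == 0.0 and row["pct_exoscope"] == 0.0

    def test_exact_percentage_reported_with_fraction(self):
        ratings = pd.DataFrame({"q": [1] * 9 + [4] * 7})
        row = likert_summary(ratings).iloc[0]
        # 9/16 is 56.25% exactly; the fraction is reported to expose rounding
        assert row["pct_microscope"] == pytest.approx(56.25)
        assert row["frac_microscope"] == "9/16"

    def test_off_scale_rating_rejected(self):
        with pytest.raises(ValueError, match="5-level"):
            likert_summary(pd.DataFrame({"q": [0, 3, 6]}))
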