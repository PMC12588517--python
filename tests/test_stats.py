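"""Block organization and the mixed-design inferential battery."""

import numpy as np
import pandas as pd
import pytest

from interceptsim.errors import DataError, InvalidParameterError
from interceptsim.protocol import generate_exposure_schedule
from interceptsim.stats import (eta_band, mixed_anova, ncor_t_test,
                                normality_gate, organize_blocks,
                                partial_eta_sq, tukey_posthoc)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def trials_from_schedule(participant, group, values=None, seed=0):
    """Per-trial measures table following a real 129-trial schedule."""
    sched = generate_exposure_schedule(seed)
    rows = []
    for e in sched.entries:
        val = values(e) if values else 1.0
        rows.append({
            "participant": participant, "group": group,
            "trial_index": e.index, "kind": e.kind,
            "perturbation_ordinal": e.perturbation_ordinal,
            "ce": val, "tpv": val, "ncor": 0.0 if e.kind == "control" else val,
        })
    return pd.DataFrame(rows)


def balanced_cells(n_per_group, effects, rng):
    """Long table: one value per subject x block with additive effects."""
    rows = []
    for gi, group in enumerate(("SG", "SSG")):
        for i in range(n_per_group):
            pid = f"{group}{i:02d}"
            subj = rng.normal(0, 1)
            for bi, block in enumerate(("Pre", "P", "Post")):
                y = (subj + effects.get("group", 0.0) * gi
                     + effects.get("block", 0.0) * bi + rng.normal(0, 1))
                rows.append({"participant": pid, "group": group,
                             "block": block, "y": y})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# organize_blocks
# ---------------------------------------------------------------------------

class TestOrganizeBlocks:
    def test_shape_three_moments_three_blocks(self):
        measures = trials_from_schedule("P01", "SG")
        summary = organize_blocks(measures)
        assert len(summary) == 2 * 3 * 3     # kinds x moments x blocks
        fast = summary[summary["kind"] == "fast"]
        assert set(fast["moment"]) == {"Early", "Intermediate", "Later"}
        assert set(fast["block"]) == {"Pre", "P", "Post"}

    def test_constant_values_give_constant_cells(self):
        summary = organize_blocks(trials_from_schedule("P01", "SG"))
        assert np.allclose(summary["ce"], 1.0)

    def test_hand_computed_cell_means(self):
        # value = trial index; each cell mean is the mean of its 3 indices
        measures = trials_from_schedule("P01", "SG",
                                        values=lambda e: float(e.index))
        sched = generate_exposure_schedule(0)
        fast_idx = [e.index for e in sched.entries if e.kind == "fast"]
        summary = organize_blocks(measures)
        early = summary[(summary["kind"] == "fast")
                        & (summary["moment"] == "Early")]
        expect_p = np.mean(fast_idx[:3])
        assert early.loc[early["block"] == "P", "ce"].iloc[0] == \
            pytest.approx(expect_p)
        assert early.loc[early["block"] == "Pre", "ce"].iloc[0] == \
            pytest.approx(expect_p - 1)
        assert early.loc[early["block"] == "Post", "ce"].iloc[0] == \
            pytest.approx(expect_p + 1)

    def test_ncor_only_in_perturbation_blocks(self):
        summary = organize_blocks(trials_from_schedule("P01", "SG"))
        assert summary.loc[summary["block"] == "P", "ncor"].notna().all()
        assert summary.loc[summary["block"] != "P", "ncor"].isna().all()

    def test_missing_flanking_control_flagged(self):
        measures = trials_from_schedule("P01", "SG")
        sched = generate_exposure_schedule(0)
        first_fast = next(e.index for e in sched.entries if e.kind == "fast")
        measures = measures[measures["trial_index"] != first_fast - 1]
        summary = organize_blocks(measures)
        early = summary[(summary["kind"] == "fast")
                        & (summary["moment"] == "Early")]
        assert early["incomplete"].all()

    def test_missing_column_rejected(self):
        with pytest.raises(DataError):
            organize_blocks(pd.DataFrame({"participant": []}))


# ---------------------------------------------------------------------------
# mixed ANOVA
# ---------------------------------------------------------------------------

class TestMixedAnova:
    def test_hand_toy_table(self):
        # 2 groups x 3 blocks, n=2: SG (1,2,2),(2,4,3); SSG (3,6,5),(5,7,9).
        # Oracle table computed independently with pingouin 0.6.1:
        # group  SS 36.75,  F 6.784615, p 0.121177, eta_p^2 0.772329
        # block  SS 10.6667, F 8.0,     p 0.04,     eta_p^2 0.8
        # inter  SS 2.0,     F 1.5,     p 0.326531, eta_p^2 0.428571
        rows = []
        data = {"SG": [(1, 2, 2), (2, 4, 3)], "SSG": [(3, 6, 5), (5, 7, 9)]}
        for g, subs in data.items():
            for i, vals in enumerate(subs):
                for b, y in zip(("Pre", "P", "Post"), vals):
                    rows.append({"participant": f"{g}{i}", "group": g,
                                 "block": b, "y": float(y)})
        res = mixed_anova(pd.DataFrame(rows), "y")
        g, b, i = (res.effects[k] for k in ("group", "block", "interaction"))
        assert g.ss == pytest.approx(36.75, rel=1e-9)
        assert g.f == pytest.approx(6.784615384615, rel=1e-9)
        assert g.p == pytest.approx(0.1211773518, rel=1e-8)
        assert g.eta_p_sq == pytest.approx(0.7723292469, rel=1e-9)
        assert b.ss == pytest.approx(10.666666666667, rel=1e-9)
        assert b.f == pytest.approx(8.0, rel=1e-9)
        assert b.p == pytest.approx(0.04, rel=1e-8)
        assert i.ss == pytest.approx(2.0, rel=1e-9)
        assert i.f == pytest.approx(1.5, rel=1e-9)
        assert (g.df_num, g.df_den) == (1, 2)
        assert (b.df_num, b.df_den) == (2, 4)

    def test_matches_pingouin_on_random_data(self, rng):
        pg = pytest.importorskip("pingouin")
        df = balanced_cells(12, {"group": 0.4, "block": 0.2}, rng)
        res = mixed_anova(df, "y")
        ref = pg.mixed_anova(data=df, dv="y", within="block",
                             subject="participant", between="group")
        ref = ref.set_index("Source")
        assert res.effects["group"].f == pytest.approx(
            ref.loc["group", "F"], rel=1e-9)
        assert res.effects["block"].f == pytest.approx(
            ref.loc["block", "F"], rel=1e-9)
        assert res.effects["interaction"].f == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9)
        assert res.effects["block"].eta_p_sq == pytest.approx(
            ref.loc["block", "np2"], rel=1e-9)

    def test_df_fingerprint_n40(self, rng):
        df = balanced_cells(20, {}, rng)
        res = mixed_anova(df, "y")
        assert (res.effects["group"].df_num, res.effects["group"].df_den) == (1, 38)
        assert (res.effects["block"].df_num, res.effects["block"].df_den) == (2, 76)
        assert (res.effects["interaction"].df_num,
                res.effects["interaction"].df_den) == (2, 76)

    def test_constant_dv_handled_without_crash(self, rng):
        df = balanced_cells(5, {}, rng)
        df["y"] = 3.0
        res = mixed_anova(df, "y")
        assert res.effects["group"].f == 0.0
        assert res.effects["group"].p == 1.0
        assert res.effects["group"].degenerate

    def test_block_effect_power_and_group_null(self):
        # additive block effect, no group effect: block detected, group not
        hits_block = hits_group = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            df = balanced_cells(20, {"block": 0.8}, rng)
            res = mixed_anova(df, "y")
            hits_block += res.effects["block"].p < 0.01
            hits_group += res.effects["group"].p < 0.05
        assert hits_block / n_rep >= 0.95
        assert hits_group / n_rep <= 0.15

    def test_unbalanced_and_missing_rejected(self, rng):
        df = balanced_cells(4, {}, rng)
        with pytest.raises(DataError):
            mixed_anova(df.iloc[:-1], "y")          # missing cell
        df2 = df[df["participant"] != "SG00"]
        with pytest.raises(DataError):
            mixed_anova(df2, "y")                   # unbalanced groups


class TestPartialEtaSq:
    def test_bands_and_values(self):
        assert partial_eta_sq(0.0, 1.0) == (0.0, "trivial")
        assert partial_eta_sq(1.0, 1.0) == (0.5, "large")
        # SS ratio 18:7 -> 0.72, the large-effect regime
        eta, band = partial_eta_sq(18.0, 7.0)
        assert eta == pytest.approx(0.72)
        assert band == "large"

    def test_band_edges(self):
        assert eta_band(0.005) == "trivial"
        assert eta_band(0.03) == "small"
        assert eta_band(0.14) == "medium"
        assert eta_band(0.141) == "large"

    def test_degenerate(self):
        eta, band = partial_eta_sq(0.0, 0.0)
        assert np.isnan(eta) and band == "undefined"

    def test_negative_rejected(self):
        with pytest.raises(InvalidParameterError):
            partial_eta_sq(-1.0, 1.0)


class TestNcorTTest:
    @staticmethod
    def _summary(sg_vals, ssg_vals):
        rows = []
        for g, vals in (("SG", sg_vals), ("SSG", ssg_vals)):
            for i, v in enumerate(vals):
                rows.append({"participant": f"{g}{i}", "group": g,
                             "kind": "fast", "moment": "Early", "block": "P",
                             "ncor": float(v), "incomplete": False})
        return pd.DataFrame(rows)

    def test_textbook_values(self):
        res = ncor_t_test(self._summary([1, 2, 3], [4, 5, 6]), "fast")
        assert res["t"] == pytest.approx(-3.6742346, rel=1e-6)
        assert res["df"] == 4
        assert res["p"] == pytest.approx(0.0213116, rel=1e-5)

    def test_identical_groups(self):
        res = ncor_t_test(self._summary([2, 2], [2, 2]), "fast")
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_too_few_participants(self):
        with pytest.raises(DataError):
            ncor_t_test(self._summary([1], [2, 3]), "fast")


class TestTukey:
    @staticmethod
    def _anova(values_by_group, rng, noise=1.0):
        rows = []
        for g, shifts in values_by_group.items():
            for i in range(10):
                subj = rng.normal(0, 0.5)
                for b, shift in zip(("Pre", "P", "Post"), shifts):
                    rows.append({"participant": f"{g}{i}", "group": g,
                                 "block": b,
                                 "y": subj + shift + rng.normal(0, noise)})
        return mixed_anova(pd.DataFrame(rows), "y")

    def test_all_equal_no_pair_significant(self, rng):
        res = self._anova({"SG": (0, 0, 0), "SSG": (0, 0, 0)}, rng)
        ph = tukey_posthoc(res, effect="block", n_per_group=10)
        assert not ph["significant"].any()

    def test_single_shifted_level_detected(self, rng):
        res = self._anova({"SG": (0, 3, 0), "SSG": (0, 3, 0)}, rng, noise=0.5)
        ph = tukey_posthoc(res, effect="block", n_per_group=10)
        involving_p = ph[(ph["a"] == "P") | (ph["b"] == "P")]
        others = ph[(ph["a"] != "P") & (ph["b"] != "P")]
        assert involving_p["significant"].all()
        assert not others["significant"].any()

    def test_interaction_yields_fifteen_pairs(self, rng):
        res = self._anova({"SG": (0, 1, 0), "SSG": (0, 2, 0)}, rng)
        ph = tukey_posthoc(res, effect="interaction", n_per_group=10)
        assert len(ph) == 15      # C(6,2) over group x block cell means


class TestNormalityGate:
    @staticmethod
    def _cells(draws, n=20):
        rows = []
        for g in ("SG", "SSG"):
            for b in ("Pre", "P", "Post"):
                for i, v in enumerate(draws(n)):
                    rows.append({"participant": f"{g}{i}", "group": g,
                                 "block": b, "y": float(v)})
        return pd.DataFrame(rows)

    def test_gaussian_cells_proceed(self):
        passed = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            gate = normality_gate(self._cells(lambda n: rng.normal(size=n)),
                                  "y")
            passed += gate["proceed"]
        assert passed >= 16      # ~ (1 - alpha)^cells of seeds survive

    def test_skewed_cells_fail(self):
        failed = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            gate = normality_gate(
                self._cells(lambda n: rng.exponential(size=n), ), "y")
            failed += not gate["proceed"]
        assert failed >= 16

    def test_degenerate_cells_skipped_with_warning(self):
        df = self._cells(lambda n: np.ones(n))
        gate = normality_gate(df, "y")
        assert gate["per_cell_p"] == {}
        assert len(gate["warnings"]) == 6
        assert not gate["proceed"]
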