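"""Region quantification and transcription-replication statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from oriterm.genomic_io import GenomeLayout, StrandedTrack
from oriterm.replication_corr import (
    FLANK,
    TranscriptionQuant,
    conditional_firing,
    partition_classes,
    quantify,
    rank_and_compare,
    regress,
    select_high_incoming,
)

from conftest import make_origin


def _setup(strand="+", anchor=2000, distance=130, n=2000 * 3):
    layout = GenomeLayout.from_dict({"chrT": n})
    sec = anchor + distance if strand == "+" else anchor - distance
    rec = make_origin(anchor, strand, secondary_anchor=sec)
    return layout, rec


def brute_force_quant(track, rec, b_len):
    """Slice-sum oracle working directly in genomic coordinates."""
    plus = track.values(rec.chrom, "+")
    minus = track.values(rec.chrom, "-")
    a = rec.anchor

    def gsum(vals, rel_lo, rel_hi):  # inclusive rel range
        if rec.strand == "+":
            return vals[a + rel_lo : a + rel_hi + 1].sum()
        return vals[a - rel_hi : a - rel_lo + 1].sum()

    sense, anti = (plus, minus) if rec.strand == "+" else (minus, plus)
    return {
        "A": gsum(sense, -FLANK, -1),
        "Ba": gsum(sense, 0, b_len - 1),
        "Bas": gsum(anti, 0, b_len - 1),
        "C": gsum(anti, b_len, b_len + FLANK - 1),
        "acs_window": gsum(sense, 0, 99) + gsum(anti, 0, 99),
    }


class TestQuantify:
    def test_zero_track_gives_zero_sums(self):
        layout, rec = _setup()
        q = quantify(StrandedTrack.zeros(layout), [rec])[0]
        assert (q.region_A, q.region_B, q.region_C, q.acs_window) == (0, 0, 0, 0)

    def test_uniform_track_fixed_area(self):
        layout, rec = _setup()
        track = StrandedTrack.zeros(layout)
        track.data["chrT"]["+"] += 1.0
        track.data["chrT"]["-"] += 1.0
        q = quantify(track, [rec], activity_area=150)[0]
        assert q.region_B == 300  # 150 per strand
        assert q.region_A == FLANK and q.region_C == FLANK
        assert q.acs_window == 200

    def test_protected_mode_uses_anchor_to_anchor_span(self):
        layout, rec = _setup(distance=130)
        track = StrandedTrack.zeros(layout)
        track.data["chrT"]["+"] += 1.0
        track.data["chrT"]["-"] += 1.0
        q = quantify(track, [rec], "protected")[0]
        assert q.b_length == 131  # both anchors inclusive
        assert q.region_B == 262

    def test_missing_secondary_skipped_with_warning(self, caplog):
        layout, _ = _setup()
        rec = make_origin(2000, "+")  # no secondary
        with caplog.at_level("WARNING"):
            quants = quantify(StrandedTrack.zeros(layout), [rec], "protected")
        assert quants == []
        assert "no secondary ACS" in caplog.text

    @pytest.mark.parametrize("seed", range(12))
    def test_slice_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        strand = "+" if seed % 2 else "-"
        distance = int(rng.integers(70, 200))
        layout, rec = _setup(strand=strand, distance=distance)
        track = StrandedTrack.zeros(layout)
        track.data["chrT"]["+"] = rng.poisson(0.7, 6000).astype(float)
        track.data["chrT"]["-"] = rng.poisson(0.7, 6000).astype(float)
        q = quantify(track, [rec], "protected")[0]
        expect = brute_force_quant(track, rec, distance + 1)
        assert q.region_A == pytest.approx(expect["A"], rel=1e-12)
        assert q.region_Ba == pytest.approx(expect["Ba"], rel=1e-12)
        assert q.region_Bas == pytest.approx(expect["Bas"], rel=1e-12)
        assert q.region_C == pytest.approx(expect["C"], rel=1e-12)
        assert q.acs_window == pytest.approx(expect["acs_window"], rel=1e-12)
        assert q.region_B == q.region_Ba + q.region_Bas


def _quants_from_values(values, key="acs_window"):
    return [
        TranscriptionQuant(
            origin_id=f"o{i}", region_A=0, region_C=0,
            region_Ba=v if key != "acs_window" else 0, region_Bas=0,
            acs_window=v if key == "acs_window" else 0, b_length=100,
        )
        for i, v in enumerate(values)
    ]


def _metrics_frame(values, metric="P_L"):
    df = pd.DataFrame({
        "origin_id": [f"o{i}" for i in range(len(values))],
        "P_L": 0.5, "P_F": 0.25, "T_half": 20.0,
    })
    df[metric] = values
    return df


def pooled_t(a, b):
    """Textbook pooled-variance two-sample t statistic."""
    na, nb = len(a), len(b)
    va = sum((x - sum(a) / na) ** 2 for x in a) / (na - 1)
    vb = sum((x - sum(b) / nb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    return (sum(a) / na - sum(b) / nb) / math.sqrt(sp2 * (1 / na + 1 / nb))


class TestRankAndCompare:
    def test_identical_groups_give_t_zero_p_one(self):
        values = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        quants = _quants_from_values([6, 5, 4, 3, 2, 1])
        metrics = _metrics_frame(values)
        cmp = rank_and_compare(quants, metrics, top_n=3)
        assert cmp.t_statistic == 0.0 and cmp.p_value == 1.0

    def test_matches_closed_form_pooled_t(self):
        quants = _quants_from_values([60, 50, 40, 3, 2, 1])
        metrics = _metrics_frame([5.0, 6.0, 7.0, 1.0, 2.0, 3.0])
        cmp = rank_and_compare(quants, metrics, top_n=3)
        expect = pooled_t([5.0, 6.0, 7.0], [1.0, 2.0, 3.0])
        assert cmp.t_statistic == pytest.approx(expect, rel=1e-12)
        assert cmp.n_top == 3 and cmp.n_rest == 3

    def test_top_n_must_leave_a_remainder(self):
        quants = _quants_from_values(range(10))
        metrics = _metrics_frame(np.linspace(0, 1, 10))
        with pytest.raises(ValueError, match="top_n"):
            rank_and_compare(quants, metrics, top_n=10)

    def test_unmatched_origins_are_dropped(self):
        quants = _quants_from_values(range(12))
        metrics = _metrics_frame(np.linspace(0, 1, 12)).iloc[:8]
        cmp = rank_and_compare(quants, metrics, top_n=3)
        assert cmp.n_top + cmp.n_rest == 8

    def test_power_with_planted_shift(self):
        # top group shifted by 2 pooled SDs: p < 0.05 nearly always
        rng = np.random.default_rng(31)
        hits = 0
        for _ in range(200):
            rest = rng.normal(0.5, 0.1, 160)
            top = rng.normal(0.7, 0.1, 30)
            values = np.concatenate([top, rest])
            quants = _quants_from_values(np.arange(190)[::-1])
            metrics = _metrics_frame(values)
            cmp = rank_and_compare(quants, metrics, top_n=30)
            hits += cmp.p_value < 0.05
        assert hits >= 0.95 * 200


class TestConditionalFiring:
    def test_simple_ratio(self):
        df = _metrics_frame([0.8])
        df["P_F"] = 0.4
        out = conditional_firing(df)
        assert out["P_F_L"].iloc[0] == pytest.approx(0.5)

    def test_equal_probabilities_give_one(self):
        df = _metrics_frame([0.6])
        df["P_F"] = 0.6
        assert conditional_firing(df)["P_F_L"].iloc[0] == pytest.approx(1.0)

    def test_construction_oracle_recovers_ratio(self):
        rng = np.random.default_rng(2)
        p_l = rng.uniform(0.1, 1.0, 50)
        p_fl = rng.uniform(0.0, 1.0, 50)
        df = _metrics_frame(p_l)
        df["P_F"] = p_l * p_fl
        out = conditional_firing(df)
        np.testing.assert_allclose(out["P_F_L"].to_numpy(), p_fl, rtol=1e-12)

    def test_zero_licensing_excluded_and_excess_flagged(self, caplog):
        df = _metrics_frame([0.0, 0.5, 0.4])
        df["P_F"] = [0.0, 0.6, 0.2]
        with caplog.at_level("WARNING"):
            out = conditional_firing(df)
        assert len(out) == 2
        assert "P_L = 0" in caplog.text
        assert out["pfl_inconsistent"].tolist() == [True, False]


class TestPartitionClasses:
    def test_threshold_partition(self):
        df = _metrics_frame([1.0, 1.0, 1.0])
        df["P_F"] = [1.0, 0.95, 0.5]
        high, low = partition_classes(df, threshold=0.9)
        assert sorted(high["P_F_L"]) == [0.95, 1.0]
        assert low["P_F_L"].tolist() == [0.5]

    def test_zero_threshold_puts_all_high(self):
        df = _metrics_frame([0.5] * 4)
        df["P_F"] = [0.1, 0.2, 0.3, 0.4]
        high, low = partition_classes(df, threshold=0.0)
        assert len(high) == 4 and len(low) == 0


class TestRegress:
    def test_exact_linear_fit(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        res = regress(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_orthogonal_data_gives_zero_slope(self):
        x = np.array([-1.0, 0.0, 1.0, -1.0, 0.0, 1.0])
        y = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 1.0])  # cov(x, y) = 0
        res = regress(x, y)
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        x = rng.normal(size=n)
        y = 0.7 * x + rng.normal(size=n)
        res = regress(x, y)
        # independent normal-equations evaluation
        X = np.column_stack([np.ones(n), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        ss_res = resid @ resid
        ss_tot = ((y - y.mean()) ** 2).sum()
        se = math.sqrt(ss_res / (n - 2) / ((x - x.mean()) ** 2).sum())
        from scipy import stats as sps

        t = beta[1] / se
        p = 2 * sps.t.sf(abs(t), n - 2)
        assert res.slope == pytest.approx(beta[1], rel=1e-10)
        assert res.intercept == pytest.approx(beta[0], rel=1e-10)
        assert res.r_squared == pytest.approx(1 - ss_res / ss_tot, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-8)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            regress(np.ones(5), np.arange(5.0))
        with pytest.raises(ValueError, match="3 points"):
            regress(np.arange(2.0), np.arange(2.0))


class TestSelectHighIncoming:
    def _quant(self, a, c):
        return TranscriptionQuant("o", a, c, 0, 0, 0, 100)

    def test_strictly_above_threshold_kept(self):
        assert select_high_incoming([self._quant(11, 11)]) != []

    def test_boundary_is_strict(self):
        assert select_high_incoming([self._quant(10, 50)]) == []
        assert select_high_incoming([self._quant(50, 10)]) == []

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(8)
        quants = [
            self._quant(float(a), float(c))
            for a, c in rng.integers(0, 30, size=(100, 2))
        ]
        kept = select_high_incoming(quants, min_reads=10)
        expect = [q for q in quants if q.region_A > 10 and q.region_C > 10]
        assert kept == expect
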