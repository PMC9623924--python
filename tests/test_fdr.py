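"""TDS and cTDS estimators, q-values, thresholding, FMR and P(t) summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ctds.fdr import (
    accept_at,
    accepted_psms,
    correction_factor,
    ctds_fdr,
    fdr_curve,
    fmr,
    p_distribution_summary,
    read_psms_tsv,
    tds_fdr,
    tds_fdr_corrected,
    write_psms_tsv,
)
from tests.conftest import make_psms


class TestPointEstimators:
    @pytest.mark.parametrize("T, D, expected", [(100, 0, 0.01), (200, 1, 0.01), (10, 9, 1.0)])
    def test_tds(self, T, D, expected):
        assert tds_fdr(T, D) == pytest.approx(expected)

    def test_tds_no_targets(self):
        with pytest.raises(ValueError):
            tds_fdr(0, 5)

    @pytest.mark.parametrize(
        "T, D, f, expected", [(100, 0, 1.0, 0.01), (100, 1, 0.5, 0.01), (100, 9, 2.0, 0.2)]
    )
    def test_tds_corrected(self, T, D, f, expected):
        assert tds_fdr_corrected(T, D, f) == pytest.approx(expected)

    def test_correction_factor(self):
        rows = []
        for i in range(500):
            rows.append(dict(spectrum_id=f"S{i}", rank=5, peptide="P", score=0.0, label="target"))
        for i in range(400):
            rows.append(dict(spectrum_id=f"S{i}", rank=5, peptide="P", score=0.0, label="decoy"))
        # rows at other ranks must be ignored
        rows.append(dict(spectrum_id="X", rank=1, peptide="P", score=9.0, label="decoy"))
        assert correction_factor(pd.DataFrame(rows), rank=5) == pytest.approx(1.25)

    def test_correction_factor_no_decoys(self):
        df = pd.DataFrame([dict(spectrum_id="S", rank=5, peptide="P", score=0.0, label="target")])
        with pytest.raises(ValueError, match="rank"):
            correction_factor(df, rank=5)


class TestCtdsFdr:
    def test_all_half_reduces_to_d_over_t(self, psm_builder):
        psms = psm_builder(100, 1)
        assert ctds_fdr(psms) == pytest.approx((1 * 2) / (100 * 2))

    def test_mixed_weights(self, psm_builder):
        psms = psm_builder(2, 1, target_counts=(1, 1), decoy_counts=(3, 1))
        # targets contribute 2 each; the decoy has P(d) = 1/4, weight 4
        assert ctds_fdr(psms) == pytest.approx(4 / 4)

    def test_matches_two_pass_summation_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 200))
            t = rng.integers(1, 30, size=n)
            d = rng.integers(1, 30, size=n)
            labels = np.where(rng.random(n) < 0.8, "target", "decoy")
            psms = pd.DataFrame(
                dict(
                    spectrum_id=[f"S{i}" for i in range(n)],
                    rank=1,
                    peptide="P",
                    score=rng.normal(size=n),
                    label=labels,
                    target_count=t,
                    decoy_count=d,
                )
            )
            if not (labels == "target").any():
                continue
            num = sum(
                (ti + di) / di for ti, di, l in zip(t, d, labels) if l == "decoy"
            )
            den = sum(
                (ti + di) / ti for ti, di, l in zip(t, d, labels) if l == "target"
            )
            assert ctds_fdr(psms) == pytest.approx(num / den, rel=1e-12)

    def test_no_targets_raises(self, psm_builder):
        with pytest.raises(ValueError):
            ctds_fdr(psm_builder(0, 3))

    def test_scale_invariance(self, psm_builder):
        psms = psm_builder(50, 5, target_counts=(2, 3), decoy_counts=(1, 4))
        scaled = psms.assign(
            target_count=psms["target_count"] * 7, decoy_count=psms["decoy_count"] * 7
        )
        assert ctds_fdr(scaled) == pytest.approx(ctds_fdr(psms))


class TestFdrCurve:
    def test_single_target(self, psm_builder):
        curve = fdr_curve(psm_builder(1, 0))
        assert len(curve) == 1
        assert curve.table["fdr_tds"].iloc[0] == 1.0

    def test_equal_counts_identity(self, psm_builder):
        """With all candidate counts equal, cTDS is D/T at every cutoff while
        TDS keeps its +1 pseudocount."""
        psms = psm_builder(200, 20, target_scores=np.linspace(10, 5, 200),
                           decoy_scores=np.linspace(9.9, 4.9, 20))
        curve = fdr_curve(psms).table
        T = curve["cum_targets"].to_numpy()
        D = curve["cum_decoys"].to_numpy()
        ok = T > 0
        np.testing.assert_allclose(curve["fdr_ctds"].to_numpy()[ok], (D / T)[ok])
        np.testing.assert_allclose(curve["fdr_tds"].to_numpy()[ok], ((D + 1) / T)[ok])

    def test_plus_one_conventions(self, psm_builder):
        psms = psm_builder(10, 2)
        none = fdr_curve(psms, plus_one="none").table
        both = fdr_curve(psms, plus_one="both").table
        T = none["cum_targets"].to_numpy()
        D = none["cum_decoys"].to_numpy()
        ok = T > 0
        np.testing.assert_allclose(none["fdr_tds"].to_numpy()[ok], (D / T)[ok])
        assert (both["fdr_ctds"].to_numpy()[ok] > none["fdr_ctds"].to_numpy()[ok]).all()

    def test_qvalues_monotone_random(self, rng):
        n = 500
        psms = pd.DataFrame(
            dict(
                spectrum_id=[f"S{i}" for i in range(n)],
                rank=1,
                peptide="P",
                score=rng.normal(size=n),
                label=np.where(rng.random(n) < 0.7, "target", "decoy"),
                target_count=rng.integers(1, 20, n),
                decoy_count=rng.integers(1, 20, n),
            )
        )
        curve = fdr_curve(psms).table
        for col in ("q_tds", "q_ctds"):
            q = curve[col].to_numpy()
            assert (np.diff(q) >= -1e-12).all()
            assert (q <= 1.0).all()

    def test_factor_scales_tds_not_ctds(self, psm_builder):
        psms = psm_builder(50, 5, target_counts=(2, 1), decoy_counts=(1, 3))
        a = fdr_curve(psms, factor=1.0).table
        b = fdr_curve(psms, factor=2.0).table
        ok = a["cum_targets"] > 0
        np.testing.assert_allclose(b["fdr_tds"][ok], 2.0 * a["fdr_tds"][ok])
        np.testing.assert_allclose(b["fdr_ctds"][ok], a["fdr_ctds"][ok])

    def test_conservative_tie_break(self):
        """Permuting equal-score PSMs never increases the accepted count:
        the decoy is placed above the targets it ties with."""
        rows = [dict(spectrum_id=f"T{i}", rank=1, peptide="P", score=10.0, label="target",
                     target_count=1, decoy_count=1) for i in range(20)]
        rows.append(dict(spectrum_id="D0", rank=1, peptide="P", score=10.0, label="decoy",
                         target_count=1, decoy_count=1))
        results = set()
        for perm in (rows, rows[::-1], rows[10:] + rows[:10]):
            curve = fdr_curve(pd.DataFrame(perm))
            assert curve.table["label"].iloc[0] == "decoy"  # decoy sorted above tied targets
            # with the decoy counted first, the whole tied block has q = 2/20
            results.add(accept_at(curve, 0.05, method="tds"))
        assert all(n == 0 for _, n in results)
        counts = {
            accept_at(fdr_curve(pd.DataFrame(p)), 0.2, method="tds")[1]
            for p in (rows, rows[::-1], rows[5:] + rows[:5])
        }
        assert counts == {20}

    def test_duplicate_rank1_rejected(self):
        rows = [
            dict(spectrum_id="S", rank=1, peptide="P", score=1.0, label="target"),
            dict(spectrum_id="S", rank=1, peptide="Q", score=0.5, label="target"),
        ]
        with pytest.raises(ValueError, match="rank-1"):
            fdr_curve(pd.DataFrame(rows))

    def test_no_rank1_rejected(self):
        df = pd.DataFrame([dict(spectrum_id="S", rank=2, peptide="P", score=1.0, label="target")])
        with pytest.raises(ValueError):
            fdr_curve(df)


class TestAcceptAt:
    def fixture_curve(self):
        """99 high-scoring targets, then one decoy, then one more target."""
        rows = [dict(spectrum_id=f"T{i:03d}", rank=1, peptide="P", score=100.0 - i,
                     label="target", target_count=1, decoy_count=1) for i in range(99)]
        rows.append(dict(spectrum_id="D000", rank=1, peptide="P", score=0.5, label="decoy",
                         target_count=1, decoy_count=1))
        rows.append(dict(spectrum_id="T099", rank=1, peptide="P", score=0.4, label="target",
                         target_count=1, decoy_count=1))
        return fdr_curve(pd.DataFrame(rows))

    def test_hand_evaluated_sweep(self):
        curve = self.fixture_curve()
        cutoff, n = accept_at(curve, 0.02, method="ctds")
        # accepting through the decoy and final target gives cTDS 1/100 <= 0.02
        assert n == 100
        assert cutoff == pytest.approx(0.4)

    def test_alpha_below_min_q(self):
        curve = self.fixture_curve()
        cutoff, n = accept_at(curve, 0.005, method="tds")
        assert n == 0 and np.isnan(cutoff)

    def test_alpha_near_one_accepts_all(self, psm_builder):
        curve = fdr_curve(psm_builder(30, 3))
        _, n = accept_at(curve, 0.999, method="tds")
        assert n == 30

    def test_invalid_arguments(self):
        curve = self.fixture_curve()
        with pytest.raises(ValueError):
            accept_at(curve, 0.0)
        with pytest.raises(ValueError):
            accept_at(curve, 0.01, method="percolator")


class TestFmr:
    def accepted(self, n_entrap, n_ref, n_decoy=0):
        rows = [dict(label="target", ref_class="entrapment") for _ in range(n_entrap)]
        rows += [dict(label="target", ref_class="reference") for _ in range(n_ref)]
        rows += [dict(label="decoy", ref_class="") for _ in range(n_decoy)]
        return pd.DataFrame(rows)

    def test_arithmetic(self):
        assert fmr(self.accepted(5, 500)) == pytest.approx(0.01)

    def test_zero_entrapment(self):
        assert fmr(self.accepted(0, 100)) == 0.0

    def test_decoys_ignored(self):
        assert fmr(self.accepted(5, 500, n_decoy=50)) == pytest.approx(0.01)

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError):
            fmr(self.accepted(5, 0))


class TestPDistributionSummary:
    def test_all_half(self, psm_builder):
        summary = p_distribution_summary(psm_builder(10, 5))
        target = summary[summary["label"] == "target"].iloc[0]
        assert (target["frac_below"], target["frac_exact"], target["frac_above"]) == (0, 1, 0)

    def test_split_counts(self):
        rows = [
            dict(spectrum_id="A", rank=1, peptide="P", score=1.0, label="target",
                 target_count=3, decoy_count=1),
            dict(spectrum_id="B", rank=1, peptide="P", score=1.0, label="target",
                 target_count=1, decoy_count=3),
        ]
        s = p_distribution_summary(pd.DataFrame(rows))
        t = s[s["label"] == "target"].iloc[0]
        assert (t["frac_below"], t["frac_exact"], t["frac_above"]) == (0.5, 0, 0.5)

    def test_fractions_partition(self, rng):
        n = 200
        psms = pd.DataFrame(
            dict(
                spectrum_id=[f"S{i}" for i in range(n)],
                rank=1, peptide="P", score=1.0,
                label=np.where(rng.random(n) < 0.5, "target", "decoy"),
                target_count=rng.integers(1, 10, n),
                decoy_count=rng.integers(1, 10, n),
            )
        )
        for _, row in p_distribution_summary(psms).iterrows():
            assert row["frac_below"] + row["frac_exact"] + row["frac_above"] == pytest.approx(1.0)

    def test_correction_factor_restores_half(self):
        rows = [dict(spectrum_id="A", rank=1, peptide="P", score=1.0, label="target",
                     target_count=2, decoy_count=4)]
        s = p_distribution_summary(pd.DataFrame(rows), factor=0.5)
        assert s[s["label"] == "target"].iloc[0]["frac_exact"] == 1.0


class TestIO:
    def test_roundtrip_and_label_derivation(self, tmp_path):
        psms = make_psms(3, 2)
        path = tmp_path / "psms.tsv"
        write_psms_tsv(psms, path, comments=["params here"])
        back = read_psms_tsv(path)
        assert len(back) == 5 and set(back["label"]) == {"target", "decoy"}

        derived = tmp_path / "derived.tsv"
        pd.DataFrame(
            dict(spectrum_id=["S1", "S2"], rank=[1, 1], peptide=["P", "Q"],
                 score=[2.0, 1.0], protein=["sp|P1", "DECOY_sp|P2"])
        ).to_csv(derived, sep="\t", index=False)
        out = read_psms_tsv(derived, decoy_prefix="DECOY_")
        assert list(out["label"]) == ["target", "decoy"]

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame(dict(spectrum_id=["S"], score=[1.0])).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError):
            read_psms_tsv(path)
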