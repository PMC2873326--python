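"""Differential expression: baseline filter, moderated t, BH, gene aggregation."""

import itertools
import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domsil import de
from domsil.models import ProbeMatrix
from tests.conftest import make_gene


def make_matrix(control, treated):
    """Build a ProbeMatrix from per-group value arrays (probes x samples)."""
    control = np.atleast_2d(np.asarray(control, dtype=float))
    treated = np.atleast_2d(np.asarray(treated, dtype=float))
    n_c, n_t = control.shape[1], treated.shape[1]
    cols = [f"c{i}" for i in range(n_c)] + [f"t{i}" for i in range(n_t)]
    values = pd.DataFrame(
        np.hstack([control, treated]), columns=cols,
        index=[f"p{i}" for i in range(control.shape[0])],
    )
    design = pd.Series(["control"] * n_c + ["treated"] * n_t, index=cols)
    return ProbeMatrix(values, design)


# ---------------------------------------------------------------------------
# baseline
# ---------------------------------------------------------------------------

class TestSilentBaseline:
    def test_median_of_silent_values(self, toy_matrix):
        sub = toy_matrix.values.loc[["pA"]].to_numpy()
        assert de.estimate_silent_baseline(toy_matrix, ["pA"]) == np.median(sub)

    def test_empty_silent_set_raises_with_skip_advice(self, toy_matrix):
        with pytest.raises(ValueError, match="skip filtering"):
            de.estimate_silent_baseline(toy_matrix, [])

    def test_baseline_near_truth_for_simulated_silent_probes(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(4.0, 0.5, size=(100, 6))
        m = make_matrix(vals[:, :3], vals[:, 3:])
        baseline = de.estimate_silent_baseline(m, m.probe_ids)
        assert baseline == np.median(vals)
        assert 3.8 <= baseline <= 4.2

    def test_filter_drops_probe_below_baseline_everywhere(self):
        m = make_matrix([[4.1, 4.9, 4.5], [4.1, 5.2, 4.5]], [[4.8, 4.2, 4.0], [4.8, 4.2, 4.0]])
        out = de.filter_unexpressed(m, 5.0)
        assert out.probe_ids == ["p1"]  # one sample at 5.2 >= baseline
        assert out.sample_ids == m.sample_ids

    def test_filter_disabled_with_minus_inf(self, toy_matrix):
        out = de.filter_unexpressed(toy_matrix, -math.inf)
        pd.testing.assert_frame_equal(out.values, toy_matrix.values)


# ---------------------------------------------------------------------------
# fold change and moderated t
# ---------------------------------------------------------------------------

class TestModeratedT:
    def test_fold_change_treated_minus_control(self):
        m = make_matrix([[8, 8, 8]], [[7, 7, 7]])
        assert de.probe_fold_change(m).iloc[0] == pytest.approx(-1.0)
        m2 = make_matrix([[8.0, 8.2]], [[7.4, 7.0]])
        assert de.probe_fold_change(m2).iloc[0] == pytest.approx(-0.9)

    def test_posterior_variance_formula_forced_params(self):
        """d0=4, s0^2=1, n=3v3, s_g^2=1, lfc=-1 -> t = -1/sqrt(2/3), df=8."""
        rng = np.random.default_rng(0)
        # craft one probe with pooled variance exactly 1 and lfc exactly -1
        control = np.array([[8.0, 9.0, 10.0]])  # var 1
        treated = control - 1.0
        m = make_matrix(control, treated)
        params = de.ModeratedTParams(d0=4.0, s0_sq=1.0)
        _, frame = de.fit_moderated_t(m, params)
        assert frame["s_sq"].iloc[0] == pytest.approx(1.0)
        expected_t = -1.0 / math.sqrt((4 * 1 + 4 * 1) / 8 * (2 / 3))
        assert frame["t_mod"].iloc[0] == pytest.approx(expected_t)
        assert expected_t == pytest.approx(-1.2247, abs=1e-4)

    def test_equal_variance_limit_matches_ordinary_t(self):
        """When every probe has the same s_g^2 the moderated t is the pooled t."""
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, size=3)
        base = (base - base.mean()) / base.std(ddof=1)  # variance exactly 1
        control = 8.0 + np.tile(base, (1000, 1))
        treated = control + rng.uniform(-2, 2, size=1000)[:, None]
        m = make_matrix(control, treated)
        params, frame = de.fit_moderated_t(m)
        lfc = frame["log_fc"].to_numpy()
        pooled = lfc / np.sqrt(frame["s_sq"].to_numpy() * (2 / 3))
        assert np.max(np.abs(frame["t_mod"].to_numpy() - pooled)) < 1e-10

    def test_hyperparameter_recovery_from_scaled_f_model(self):
        """Moment matching recovers planted (d0, s0^2) from simulated variances."""
        rng = np.random.default_rng(42)
        d0, s0_sq, d_g, n = 4.0, 0.05, 4, 2000
        sigma_sq = d0 * s0_sq / rng.chisquare(d0, n)
        s_sq = sigma_sq * rng.chisquare(d_g, n) / d_g
        params = de._fit_variance_prior(s_sq, d_g)
        assert abs(params.d0 - d0) / d0 <= 0.25
        assert abs(params.s0_sq - s0_sq) / s0_sq <= 0.10

    def test_all_zero_variances_rejected(self):
        m = make_matrix([[5, 5, 5], [6, 6, 6]], [[5, 5, 5], [7, 7, 7]])
        with pytest.raises(ValueError, match="degenerate"):
            de.fit_moderated_t(m)

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma
        for x in (0.05, 0.5, 2.0, 30.0, 1e4):
            y = float(polygamma(1, x))
            assert de.trigamma_inverse(y) == pytest.approx(x, rel=1e-6)

    def test_matches_limma_reference(self, tmp_path):
        """Cross-check t_mod and p against the limma implementation in R."""
        rng = np.random.default_rng(5)
        # heteroscedastic probes so the prior df is finite
        sd = np.sqrt(0.25 * 4 / rng.chisquare(4, size=40))
        control = 8.0 + rng.normal(0, 1, size=(40, 3)) * sd[:, None]
        treated = 8.0 + rng.normal(0, 1, size=(40, 3)) * sd[:, None]
        treated[:10] -= 1.0
        m = make_matrix(control, treated)
        mpath = tmp_path / "m.tsv"
        m.values.to_csv(mpath, sep="\t")
        rscript = textwrap.dedent("""
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("%s", row.names = 1))
            design <- cbind(Intercept = 1, Treated = c(0, 0, 0, 1, 1, 1))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t = fit$t[, "Treated"], p = fit$p.value[, "Treated"],
                              d0 = fit$df.prior, s0sq = fit$s2.prior)
            write.table(out, "%s", sep = "\t", quote = FALSE)
        """ % (mpath, tmp_path / "limma.tsv"))
        try:
            subprocess.run(["Rscript", "-e", rscript], check=True, capture_output=True,
                           timeout=120)
        except (FileNotFoundError, subprocess.CalledProcessError) as exc:
            pytest.skip(f"Rscript/limma unavailable: {exc}")
        ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
        params, frame = de.fit_moderated_t(m)
        assert math.isfinite(params.d0)
        np.testing.assert_allclose(frame["t_mod"], ref["t"], rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(frame["p"], ref["p"], rtol=1e-6, atol=1e-10)
        assert params.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert params.s0_sq == pytest.approx(ref["s0sq"].iloc[0], rel=1e-4)


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def bh_brute_force(p):
    """Direct step-up: adj_i = min_{j >= i} p_(j) * m / j (in sorted order)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank, m + 1)
        ]
        adj_sorted[rank - 1] = min(1.0, min(candidates))
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(
            de.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_value_identity(self):
        np.testing.assert_allclose(de.bh_adjust([1.0]), [1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.5, 1.5])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_matches_brute_force_step_up(self, p):
        np.testing.assert_allclose(de.bh_adjust(p), bh_brute_force(p), atol=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_in_p_ordering(self, p):
        adj = de.bh_adjust(p)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# status calls, gene aggregation, severity, deciles
# ---------------------------------------------------------------------------

class TestStatusAndAggregation:
    @pytest.mark.parametrize(
        "log_fc,fdr,expected",
        [(-0.8, 0.01, "down"), (-0.8, 0.06, "none"), (0.3, 0.04, "up"), (0.0, 0.01, "none")],
    )
    def test_probe_status_rule(self, log_fc, fdr, expected):
        assert de.call_probe_status([log_fc], [fdr]).iloc[0] == expected

    @staticmethod
    def _probe_de(statuses, lfcs):
        return pd.DataFrame(
            {
                "probe_set_id": [f"p{i}" for i in range(len(statuses))],
                "log_fc": lfcs,
                "status": statuses,
            }
        )

    def test_down_gene_mean_of_down_probes_only(self):
        gene = make_gene("g1", 0, 1000, probes=["p0", "p1"])
        pdx = self._probe_de(["down", "none"], [-1.2, -0.1])
        out = de.aggregate_gene_status([gene], pdx)
        row = out.iloc[0]
        assert row.status == "down"
        assert row.expr_value == pytest.approx(-1.2)
        assert row.pct_reduction == pytest.approx(100 * (1 - 2 ** -1.2), abs=0.05)
        assert row.severity == "strong"

    def test_down_probe_average_forced(self):
        gene = make_gene("g1", 0, 1000, probes=["p0", "p1"])
        pdx = self._probe_de(["down", "down"], [-0.5, -1.5])
        row = de.aggregate_gene_status([gene], pdx).iloc[0]
        assert row.expr_value == pytest.approx(-1.0)
        assert row.pct_reduction == pytest.approx(50.0)

    def test_discordant_gene_is_no_change(self):
        gene = make_gene("g1", 0, 1000, probes=["p0", "p1"])
        pdx = self._probe_de(["down", "up"], [-1.0, 0.5])
        row = de.aggregate_gene_status([gene], pdx).iloc[0]
        assert row.status == "no_change" and row.discordant

    def test_probeless_gene_flagged_unscored(self):
        row = de.aggregate_gene_status([make_gene("g1", 0, 1000)], self._probe_de([], [])).iloc[0]
        assert row.status == "no_change" and row.unscored

    def test_never_down_with_any_up_probe_exhaustive(self):
        """Check every status multiset of size <= 4."""
        for size in range(1, 5):
            for combo in itertools.product(["down", "up", "none"], repeat=size):
                gene = make_gene("g1", 0, 1000, probes=[f"p{i}" for i in range(size)])
                pdx = self._probe_de(list(combo), [-0.5 if s == "down" else 0.5 for s in combo])
                row = de.aggregate_gene_status([gene], pdx).iloc[0]
                if "up" in combo:
                    assert row.status != "down"
                if "up" in combo and "down" in combo:
                    assert row.status == "no_change"

    @pytest.mark.parametrize("pct,expected", [(55, "strong"), (50.0, "moderate"),
                                              (30.0, "moderate"), (20, "weak")])
    def test_severity_bands(self, pct, expected):
        assert de.severity_class(pct) == expected

    def test_severity_out_of_range(self):
        with pytest.raises(ValueError):
            de.severity_class(0.0)
        with pytest.raises(ValueError):
            de.severity_class(100.0)

    def test_pct_reduction_strictly_decreasing_in_expr_value(self):
        gene = make_gene("g1", 0, 1000, probes=["p0"])
        values = np.linspace(-3, -0.01, 50)
        pcts = []
        for v in values:
            pdx = self._probe_de(["down"], [v])
            pcts.append(de.aggregate_gene_status([gene], pdx).iloc[0].pct_reduction)
        assert np.all(np.diff(pcts) < 0)


class TestDecileLabels:
    @staticmethod
    def _gene_de(expr_values):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i:02d}" for i in range(len(expr_values))],
                "status": ["down" if v < 0 else "no_change" for v in expr_values],
                "expr_value": [v if v < 0 else np.nan for v in expr_values],
            }
        )

    def test_exact_count(self):
        labels = de.decile_labels(self._gene_de([-1] * 5 + [0] * 15), 10)
        assert labels.sum() == 2

    def test_most_negative_first(self):
        gd = self._gene_de([-2, -1, -0.5] + [0] * 7)
        labels = de.decile_labels(gd, 20)
        assert list(labels[:3]) == [1, 1, 0]

    def test_degenerate_all_no_change_tie_broken_lexicographically(self):
        gd = self._gene_de([0] * 10)
        labels = de.decile_labels(gd, 20)
        assert labels.sum() == 2
        assert list(gd.loc[labels == 1, "gene_id"]) == ["g00", "g01"]


def test_global_null_fdr_control():
    """Without any effect, probe-level discoveries at FDR 5% stay near zero."""
    fracs = []
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        vals = 8.0 + rng.normal(0, 0.3, size=(5000, 6))
        m = make_matrix(vals[:, :3], vals[:, 3:])
        _, frame = de.run_probe_de(m)
        fracs.append((frame["fdr"] <= 0.05).mean())
    se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
    assert np.mean(fracs) <= 0.05 + 3 * se
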