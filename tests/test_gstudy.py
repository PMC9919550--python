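import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import burstrel as br
from burstrel.exceptions import DesignError
from burstrel.gstudy import CellArray, _mean_squares

from oracle_anova import brute_force_components


def _cells(values: np.ndarray) -> CellArray:
    if values.ndim == 3:
        values = values[..., None]
    a, b, c, r = values.shape
    return CellArray(values.astype(float), list(range(a)), list(range(b)),
                     list(range(c)), "session", "task")


class TestEmsOracle:
    @pytest.mark.parametrize("shape", [(2, 2, 2), (3, 3, 3), (4, 3, 2), (3, 4, 2, 2)])
    def test_matches_brute_force(self, shape, rng):
        """Vectorized EMS equals loop-based mean squares solved from first principles."""
        y = rng.normal(5, 2, size=shape)
        est = br.estimate_components_ems(_cells(y))
        oracle = brute_force_components(y)
        for k, v in oracle.items():
            assert est.raw[k] == pytest.approx(v, abs=1e-10)
            assert est.to_dict()[k] == pytest.approx(max(0.0, v), abs=1e-10)

    def test_constant_data_all_zero(self):
        est = br.estimate_components_ems(_cells(np.full((3, 3, 3), 7.0)))
        assert est.total() == 0.0

    def test_unbalanced_input_rejected(self):
        y = np.full((3, 3, 3), 1.0)
        y[0, 0, 0] = np.nan
        with pytest.raises(DesignError, match="iterative"):
            br.estimate_components_ems(_cells(y))

    def test_residual_df_includes_replicates(self, rng):
        y = rng.normal(size=(3, 3, 3, 2))
        _, ms = _mean_squares(y)
        # pooled residual df = (a-1)(b-1)(c-1) + abc(r-1) = 8 + 27 = 35
        ss_res = ms["e"] * 35
        assert ss_res > 0


class TestParameterRecovery:
    def test_study2_truth_recovered_at_scale(self):
        """EMS recovers the generating components on a large balanced burst."""
        from burstrel.synthetic_data import study2_config

        cfg = study2_config(n_persons=1000, n_days=5, sessions_per_day=3,
                            compliance=1.0, seed=42, exact_marginals=True)
        res = br.simulate(cfg)
        vc = br.estimate_components_ems(br.build_cells(res.data, "session", "task"))
        truth = {"p": 0.871, "o": 0.008, "i": 4.639, "po": 0.094,
                 "pi": 0.381, "oi": 0.0, "e": 1.409}
        est = vc.to_dict()
        for k in ("p", "i", "e"):
            assert est[k] == pytest.approx(truth[k], rel=0.05)
        for k in ("po", "pi"):
            assert est[k] == pytest.approx(truth[k], rel=0.15)

    def test_equivariance_shift_and_scale(self, interior_result):
        """Adding a constant changes nothing; scaling by c scales by c^2."""
        cells = br.build_cells(interior_result.data, "session", "task")
        base = br.estimate_components_ems(cells)

        shifted = _cells(cells.values + 100.0)
        scaled = _cells(cells.values * 3.0)
        vs = br.estimate_components_ems(shifted)
        vc = br.estimate_components_ems(scaled)
        for k, v in base.to_dict().items():
            assert vs.to_dict()[k] == pytest.approx(v, abs=1e-8)
            assert vc.to_dict()[k] == pytest.approx(9.0 * v, rel=1e-9, abs=1e-8)


class TestIterative:
    def test_matches_ems_on_balanced_data(self, interior_result):
        cells = br.build_cells(interior_result.data, "session", "task")
        ems = br.estimate_components_ems(cells)
        reml = br.estimate_components_iterative(cells)
        for k, v in ems.to_dict().items():
            assert reml.to_dict()[k] == pytest.approx(v, abs=1e-4)

    def test_daily_replicates_balanced_agreement(self):
        """EMS equals REML on a balanced replicated design with interior solutions.

        The classical equivalence requires every unconstrained ANOVA solution
        to be nonnegative (otherwise constrained REML redistributes the
        boundary component), so this uses enough days and moment-matched
        draws to keep all raw estimates interior.
        """
        from conftest import interior_config

        cfg = interior_config(n_days=4, sessions_per_day=3, seed=14,
                              exact_marginals=True)
        data = br.simulate(cfg).data
        cells = br.build_cells(data, "day", "task")
        assert cells.n_rep == 3
        ems = br.estimate_components_ems(cells)
        assert all(v > 0 for v in ems.raw.values())
        reml = br.estimate_components_iterative(cells)
        for k, v in ems.to_dict().items():
            assert reml.to_dict()[k] == pytest.approx(v, abs=1e-4)

    def test_missing_data_recovery(self):
        """REML recovers generating components from 10% MCAR-deleted cells.

        At 80 persons the sampling SD of the person component is ~20% of its
        value (2 (s2_p + s2_po/b + s2_pi/c + s2_e/(bc))^2 / (a-1), square
        root), so a 2-SD band is ~40%; the residual is estimated from ~1700
        df and is held to 10%.
        """
        from burstrel.synthetic_data import study2_config

        cfg = study2_config(n_persons=80, n_days=2, sessions_per_day=4,
                            compliance=1.0, seed=11)
        res = br.simulate(cfg)
        cells = br.build_cells(res.data, "session", "task")
        rng = np.random.default_rng(5)
        cells.values[rng.random(cells.values.shape) < 0.10] = np.nan
        vc = br.estimate_components_iterative(cells)
        assert vc.sigma2_p == pytest.approx(0.871, rel=0.40)
        assert vc.sigma2_e == pytest.approx(1.409, rel=0.10)

    def test_person_with_no_cells_dropped(self, interior_result, caplog):
        import logging

        cells = br.build_cells(interior_result.data, "session", "task")
        cells.values[0] = np.nan
        with caplog.at_level(logging.INFO, logger="burstrel.gstudy"):
            vc = br.estimate_components_iterative(cells)
        assert vc.n_p == cells.values.shape[0] - 1
        assert any("no observed cells" in r.message for r in caplog.records)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_agrees_with_lme4_reml(self, tmp_path, interior_result):
        """Cross-check against an independent REML fit (lme4) on unbalanced data."""
        cells = br.build_cells(br.first_k_sessions(interior_result.data, 5),
                               "session", "task")
        rng = np.random.default_rng(2)
        cells.values[rng.random(cells.values.shape) < 0.08] = np.nan
        ours = br.estimate_components_iterative(cells)

        obs = ~np.isnan(cells.values[..., 0])
        p, o, i = np.nonzero(obs)
        df = pd.DataFrame({
            "y": cells.values[..., 0][obs], "p": p, "o": o, "i": i,
            "po": p * 100 + o, "pi": p * 100 + i, "oi": o * 100 + i,
        })
        csv = tmp_path / "cells.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(f"""
suppressMessages(library(lme4))
d <- read.csv("{csv}")
for (col in c("p","o","i","po","pi","oi")) d[[col]] <- factor(d[[col]])
fit <- lmer(y ~ 1 + (1|p) + (1|o) + (1|i) + (1|po) + (1|pi) + (1|oi), data=d,
            control=lmerControl(check.nobs.vs.nlev="ignore",
                                check.nobs.vs.nRE="ignore"))
vc <- as.data.frame(VarCorr(fit))
write.csv(vc[, c("grp","vcov")], "{tmp_path / 'vc.csv'}", row.names=FALSE)
""")
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "vc.csv").set_index("grp")["vcov"]
        mapping = {"p": "p", "o": "o", "i": "i", "po": "po", "pi": "pi",
                   "oi": "oi", "Residual": "e"}
        for grp, key in mapping.items():
            assert ours.to_dict()[key] == pytest.approx(ref[grp], abs=5e-3), key


class TestBuildCells:
    def test_momentary_task_geometry(self, interior_result):
        cells = br.build_cells(interior_result.data, "session", "task")
        assert (cells.n_p, cells.n_o, cells.n_i, cells.n_rep) == (25, 6, 3, 1)

    def test_daily_sessions_become_replicates(self, interior_result):
        cells = br.build_cells(interior_result.data, "day", "task")
        assert (cells.n_o, cells.n_rep) == (2, 3)

    def test_trial_items_single_task(self, study3_balanced):
        cells = br.build_cells(study3_balanced.data, "session", "trial")
        assert cells.n_i == 3 and cells.item_meaning == "trial"

    def test_trial_items_require_task_selector(self, interior_result):
        with pytest.raises(DesignError, match="task"):
            br.build_cells(interior_result.data, "session", "trial")

    def test_too_few_levels_rejected(self, study3_balanced):
        one_day = study3_balanced.data.subset(
            study3_balanced.data.frame["day_index"] == 1
        )
        with pytest.raises(DesignError):
            br.build_cells(one_day, "day", "trial")


class TestIcc:
    def test_zero_within_variance_gives_one(self):
        df = pd.DataFrame({"person_id": ["a"] * 3 + ["b"] * 3,
                           "value": [1.0] * 3 + [4.0] * 3})
        assert br.icc_oneway(df).icc == pytest.approx(1.0)

    def test_zero_between_variance_gives_zero(self):
        # every person has the same mean; all variance is within persons
        df = pd.DataFrame({"person_id": ["a", "a", "b", "b", "c", "c"],
                           "value": [1.0, -1.0, 2.0, -2.0, 0.5, -0.5]})
        assert br.icc_oneway(df).icc == 0.0

    def test_matches_generating_components(self, study3_balanced):
        """ICC of session scores approximates the component-implied ratio.

        For 3-trial session sums y = 3 mu + 3(a_p + b_o + ...), the stable
        between-person part is 9 s2_p + 9 s2_pi/3 + ... ; rather than expand
        every term, check against the empirical decomposition implied by the
        generating draw at 500 persons.
        """
        from burstrel.synthetic_data import study3_config

        cfg = study3_config(n_persons=500, compliance=1.0, seed=23)
        res = br.simulate(cfg)
        scores = br.score_sessions(res.data).rename(columns={"span_score": "value"})
        icc = br.icc_oneway(scores, "value")
        comp = cfg.components
        # session sum of 3 trials: between = 9 s2_p + 3 s2_pi (pi averages over
        # trials: var of sum of 3 correlated-by-person terms), within = rest
        between = 9 * comp.p + 3 * comp.pi
        within = 9 * (comp.o + comp.po) + 3 * (comp.oi + comp.e)
        expected = between / (between + within)
        assert icc.icc == pytest.approx(expected, abs=0.05)
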