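import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import burstrel as br
from burstrel.dstudy import DStudyDesign
from burstrel.exceptions import UndefinedReliabilityError
from burstrel.gstudy import VarianceComponents


def _vc(p=0.0, o=0.0, i=0.0, po=0.0, pi=0.0, oi=0.0, e=0.0, **kw):
    return VarianceComponents(sigma2_p=p, sigma2_o=o, sigma2_i=i, sigma2_po=po,
                              sigma2_pi=pi, sigma2_oi=oi, sigma2_e=e, **kw)


class TestPublishedValues:
    """The reference component tables reproduce every published coefficient."""

    @pytest.mark.parametrize(
        "study, timescale, expected",
        [
            ("study2_composite", "momentary", 0.17),
            ("study2_composite", "daily", 0.32),
            ("study3_rspan", "momentary", 0.37),
            ("study3_rspan", "daily", 0.48),
        ],
    )
    def test_within_person_reliability(self, study, timescale, expected):
        vc, m = br.load_reference_components(study, timescale)
        assert br.round_half_up(br.r_within(vc, m), 2) == expected

    @pytest.mark.parametrize(
        "study, k, expected",
        [("study2_composite", 15, 0.96), ("study3_rspan", 29, 0.97)],
    )
    def test_between_person_burst_reliability(self, study, k, expected):
        vc, m = br.load_reference_components(study, "momentary")
        assert br.round_half_up(br.r_between(vc, m=m, k=k), 2) == expected

    def test_doubling_daily_items_projection(self):
        """m 12 -> 24 lifts daily within-person reliability to ~0.5."""
        vc, _ = br.load_reference_components("study2_composite", "daily")
        surf = br.projection(vc, m_grid=[12, 24], k_grid=[1])
        r24 = float(surf.loc[surf["m"] == 24, "r_wp"].iloc[0])
        assert 0.48 <= r24 <= 0.50
        assert br.round_half_up(r24, 1) == 0.5


class TestLimits:
    def test_r_within_limits(self):
        assert br.r_within(_vc(po=0.0, e=1.0), 3) == 0.0
        assert br.r_within(_vc(po=0.5, e=0.0), 3) == 1.0
        with pytest.raises(UndefinedReliabilityError):
            br.r_within(_vc(), 3)

    def test_r_between_limits(self):
        assert br.r_between(_vc(p=1.0), m=3, k=5) == 1.0
        assert br.r_between(_vc(po=0.3, e=1.0), m=3, k=5) == 0.0
        with pytest.raises(UndefinedReliabilityError):
            br.r_between(_vc(), m=3, k=5)

    def test_r_within_large_m_limit(self):
        vc = _vc(po=0.2, e=5.0)
        assert br.r_within(vc, 10**9) == pytest.approx(1.0, abs=1e-6)

    def test_design_validation(self):
        with pytest.raises(ValueError):
            DStudyDesign(m=0, k=5)


@given(
    comps=st.tuples(*[st.floats(0.001, 10.0) for _ in range(4)]),
    c=st.floats(0.01, 100.0),
    m=st.integers(1, 50),
    k=st.integers(1, 50),
)
def test_scale_invariance(comps, c, m, k):
    """Multiplying all components by c > 0 leaves both coefficients unchanged."""
    p, po, pi, e = comps
    vc = _vc(p=p, po=po, pi=pi, e=e)
    scaled = vc.scaled(np.sqrt(c))
    assert br.r_within(scaled, m) == pytest.approx(br.r_within(vc, m), rel=1e-9)
    assert br.r_between(scaled, m=m, k=k) == pytest.approx(
        br.r_between(vc, m=m, k=k), rel=1e-9)


@given(
    comps=st.tuples(*[st.floats(0.001, 10.0) for _ in range(4)]),
    m=st.integers(1, 40),
    k=st.integers(1, 40),
)
def test_monotonicity_in_m_and_k(comps, m, k):
    """R_BP rises with k always, and with m when the person x item signal
    does not dominate: d R_BP/dm >= 0 iff s2_po s2_pi <= s2_e s2_p (more items
    dilute the pi/m signal term, so the direction can flip otherwise).
    R_WP always rises with m."""
    p, po, pi, e = comps
    vc = _vc(p=p, po=po, pi=pi, e=e)
    assert br.r_between(vc, m=m, k=k + 1) >= br.r_between(vc, m=m, k=k)
    if po * pi <= e * p:
        assert br.r_between(vc, m=m + 1, k=k) >= br.r_between(vc, m=m, k=k) - 1e-12
    else:
        assert br.r_between(vc, m=m + 1, k=k) <= br.r_between(vc, m=m, k=k) + 1e-12
    assert br.r_within(vc, m + 1) >= br.r_within(vc, m)


def test_projection_surface_monotone():
    vc, _ = br.load_reference_components("study3_rspan", "momentary")
    surf = br.projection(vc, m_grid=[1, 3, 6, 12], k_grid=[1, 5, 15, 29])
    wide = surf.pivot(index="m", columns="k", values="r_bp")
    assert (wide.diff().dropna() >= 0).all().all()          # in m
    assert (wide.diff(axis=1).dropna(axis=1) >= 0).all().all()  # in k


class TestIncrementalRbp:
    def test_truth_curve_value_at_k2(self):
        """Closed-form curve from the generating components: k=2 gives 0.670."""
        vc, m = br.load_reference_components("study3_rspan", "momentary")
        assert br.round_half_up(br.r_between(vc, m=m, k=2), 3) == 0.670

    def test_estimated_curve_tracks_truth(self):
        """Re-estimated curve at 500 persons stays within 0.05 of the
        component-implied curve at every k."""
        from burstrel.synthetic_data import study3_config

        cfg = study3_config(n_persons=500, compliance=1.0, seed=31,
                            exact_marginals=True)
        res = br.simulate(cfg)
        ks = range(2, 30)
        curve = br.incremental_r_bp(res.data, ks, item_meaning="trial",
                                    estimator="ems")
        vc_truth = cfg.components.to_variance_components()
        for _, row in curve.iterrows():
            truth = br.r_between(vc_truth, m=3, k=int(row["k"]))
            assert abs(row["r_bp"] - truth) <= 0.05

    def test_full_burst_consistency(self, study3_balanced):
        """k = full burst reproduces r_between on the full dataset."""
        data = study3_balanced.data
        k_full = int(data.frame["session_index"].max())
        curve = br.incremental_r_bp(data, [k_full], item_meaning="trial",
                                    estimator="ems")
        cells = br.build_cells(data, "session", "trial")
        vc = br.estimate_components_ems(cells)
        direct = br.r_between(vc, m=3, k=k_full)
        assert curve["r_bp"].iloc[0] == pytest.approx(direct, abs=1e-12)

    def test_fixed_components_mode_matches_projection(self):
        vc, m = br.load_reference_components("study3_rspan", "momentary")
        curve = br.incremental_r_bp(None, range(2, 6), fixed_components=vc)
        for _, row in curve.iterrows():
            assert row["r_bp"] == pytest.approx(
                br.r_between(vc, m=m, k=int(row["k"])))


class TestIncrementalCriterion:
    def test_criterion_equal_to_burst_mean_gives_r_of_one(self, study3_balanced):
        data = study3_balanced.data
        k_full = int(data.frame["session_index"].max())
        scores = br.score_sessions(data)
        comp = br.composite_wmc(scores)
        crit = comp.groupby("person_id")["composite"].mean()
        curve = br.incremental_criterion_correlation(data, crit, [k_full])
        assert curve["r"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_independent_criterion_uncorrelated(self, study3_balanced):
        rng = np.random.default_rng(11)
        data = study3_balanced.data
        crit = pd.Series(rng.normal(size=len(data.persons)), index=data.persons)
        curve = br.incremental_criterion_correlation(data, crit, [2, 10, 29])
        assert (curve["r"].abs() < 0.3).all()

    def test_attenuation_law(self):
        """Observed r(k) tracks rho * sqrt(R_BP(k)) (Spearman attenuation)."""
        from burstrel.synthetic_data import study3_config

        cfg = study3_config(n_persons=500, compliance=1.0, seed=37,
                            criteria=dict(r_lab=0.8))
        res = br.simulate(cfg)
        crit = res.criteria.set_index("person_id")["lab_wmc"]
        ks = [2, 5, 10, 20, 29]
        curve = br.incremental_criterion_correlation(res.data, crit, ks)
        vc = cfg.components.to_variance_components()
        for _, row in curve.iterrows():
            expected = 0.8 * np.sqrt(br.r_between(vc, m=3, k=int(row["k"])))
            assert row["r"] == pytest.approx(expected, abs=0.05)
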