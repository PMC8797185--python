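import itertools

import numpy as np
import pandas as pd
import pytest

from spliceprog import classify
from spliceprog.classify import (
    LABEL_DEPENDENT,
    LABEL_INDEPENDENT,
    LABEL_NO_COVERAGE,
    LABEL_SENSITIVE,
    call_regulated_events,
    call_sex_differential,
    classify_emic,
    define_control_sets,
    delta_psi,
    group_shift_test,
)

from conftest import fly_design, make_psi_matrix


class TestDeltaPsi:
    def test_arithmetic_and_range_gap(self):
        m = make_psi_matrix(
            {"r1": {"e": 80.0}, "r2": {"e": 90.0}, "t1": {"e": 10.0}, "t2": {"e": 20.0}},
            {s: {} for s in ("r1", "r2", "t1", "t2")},
        )
        dp = delta_psi(m, ["t1", "t2"], ["r1", "r2"])
        assert dp.at["e", "dpsi"] == -70
        assert dp.at["e", "range_gap_down"] == 80 - 20

    def test_identical_groups_give_zero(self):
        m = make_psi_matrix({"a": {"e": 42.0}, "b": {"e": 42.0}}, {"a": {}, "b": {}})
        assert delta_psi(m, ["a"], ["b"]).at["e", "dpsi"] == 0

    def test_fully_masked_group_is_no_coverage(self):
        m = make_psi_matrix({"a": {"e": np.nan}, "b": {"e": 50.0}}, {"a": {}, "b": {}})
        dp = delta_psi(m, ["a"], ["b"])
        assert np.isnan(dp.at["e", "dpsi"]) and dp.at["e", "n_test"] == 0


class TestCallRegulated:
    def _dp(self, dpsi, sex_f, sex_m):
        return pd.DataFrame({"dpsi": [dpsi], "dpsi_f": [sex_f], "dpsi_m": [sex_m]},
                            index=["e"])

    @pytest.mark.parametrize(
        "dpsi,f,m,expect",
        [
            (-25, -22, -28, "down"),
            (-25, -22, -12, "none"),  # one stratum misses the 15 cut
            (30, 20, 40, "up"),
        ],
    )
    def test_stratum_confirmation(self, dpsi, f, m, expect):
        res = call_regulated_events(self._dp(dpsi, f, m))
        assert res.at["e", "direction"] == expect

    def test_tightening_threshold_never_adds_events(self):
        rng = np.random.default_rng(0)
        dp = pd.DataFrame(
            {
                "dpsi": rng.uniform(-60, 60, 200),
                "dpsi_f": rng.uniform(-60, 60, 200),
                "dpsi_m": rng.uniform(-60, 60, 200),
            },
            index=[f"e{i}" for i in range(200)],
        )
        prev = None
        for thr in (10, 20, 30, 40):
            cur = set(call_regulated_events(dp, dpsi_thresh=thr).query("regulated").index)
            if prev is not None:
                assert cur <= prev
            prev = cur


def _fly_matrix(event_values: dict) -> "classify.PsiMatrix":
    """event_values: {event: fn(stage, sex, genotype) -> psi}."""
    meta = fly_design()
    values = {
        s: {e: fn(*s.split("_")[:3]) for e, fn in event_values.items()}
        for s in meta
    }
    return make_psi_matrix(values, meta)


class TestClassifyEmicFly:
    def test_decision_branches(self):
        mat = _fly_matrix(
            {
                # main branch: dPSI -30, both sexes -30
                "dep_main": lambda st, sx, g: 90.0 if g == "control" else 60.0,
                # low-inclusion branch: dPSI -11.5 but knockout PSI <= 1
                "dep_low": lambda st, sx, g: 12.0 if g == "control" else 0.5,
                # both sexes <= -10 without reaching -20: sensitive
                "sens": lambda st, sx, g: 50.0 if g == "control" else 38.0,
                # dPSI -21 but one sex at -12: fails main, passes sensitive
                "sens_sexfail": lambda st, sx, g: 90.0 if g == "control"
                else (60.0 if sx == "f" else 78.0),
                # one sex below -10 only: independent
                "indep_onesex": lambda st, sx, g: 50.0 if g == "control"
                else (38.0 if sx == "f" else 45.0),
                "indep_flat": lambda st, sx, g: 55.0,
                "no_cov": lambda st, sx, g: np.nan,
            }
        )
        calls = classify_emic(mat, preset="fly")
        assert calls.at["dep_main", "label"] == LABEL_DEPENDENT
        assert calls.at["dep_main", "branch"] == "dpsi20-sex15"
        assert calls.at["dep_low", "label"] == LABEL_DEPENDENT
        assert calls.at["dep_low", "branch"] == "low-inclusion"
        assert calls.at["sens", "label"] == LABEL_SENSITIVE
        assert calls.at["sens_sexfail", "label"] == LABEL_SENSITIVE
        assert calls.at["indep_onesex", "label"] == LABEL_INDEPENDENT
        assert calls.at["indep_flat", "label"] == LABEL_INDEPENDENT
        assert calls.at["no_cov", "label"] == LABEL_NO_COVERAGE

    def test_either_stage_suffices(self):
        # knockout effect in larval samples only
        mat = _fly_matrix(
            {"e": lambda st, sx, g: 80.0 if (g == "control" or st == "adult") else 20.0}
        )
        assert classify_emic(mat, preset="fly").at["e", "label"] == LABEL_DEPENDENT

    def test_oe_rescued_events_are_sensitive(self):
        mat = _fly_matrix({"e": lambda st, sx, g: 50.0})
        oe = pd.Series({"e": 30.0})
        calls = classify_emic(mat, preset="fly", oe_dpsi=oe)
        assert calls.at["e", "label"] == LABEL_SENSITIVE
        assert calls.at["e", "branch"] == "srrm4-oe"

    def test_partition_covers_every_event_once(self):
        rng = np.random.default_rng(3)
        events = {
            f"e{i}": (lambda base, eff: (lambda st, sx, g:
                      base if g == "control" else float(np.clip(base + eff, 0, 100))))(
                rng.uniform(5, 95), rng.uniform(-40, 10))
            for i in range(50)
        }
        calls = classify_emic(_fly_matrix(events), preset="fly")
        assert set(calls["label"]) <= {
            LABEL_DEPENDENT, LABEL_SENSITIVE, LABEL_INDEPENDENT, LABEL_NO_COVERAGE
        }
        assert calls["label"].notna().all() and len(calls) == 50


def _mouse_matrix(event_values):
    meta = {}
    for ds in ("n2a", "hippocampus", "cortex"):
        for geno in ("control", "mutant"):
            for r in range(2):
                meta[f"{ds}_{geno}_{r}"] = dict(dataset=ds, genotype=geno)
    values = {
        s: {e: fn(s.split("_")[0], s.split("_")[1], int(s.split("_")[2]))
            for e, fn in event_values.items()}
        for s in meta
    }
    return make_psi_matrix(values, meta)


class TestClassifyEmicMouse:
    def test_decision_branches(self):
        mat = _mouse_matrix(
            {
                # n2a dPSI -38 with clean range separation
                "dep": lambda ds, g, r: (80.0 - r * 2 if g == "control" else 42.0 - r * 2)
                if ds == "n2a" else 50.0,
                # dPSI <= -10 with mutant PSI <= 1
                "dep_low": lambda ds, g, r: 12.0 if g == "control" else 0.4,
                # n2a dPSI -16, range gap >= 5, never reaching -20
                "sens_n2a": lambda ds, g, r: (59.0 + r if g == "control" else 43.0)
                if ds == "n2a" else 50.0,
                # -12 in both brain knockouts, nothing in n2a
                "sens_brain": lambda ds, g, r: 50.0
                if ds == "n2a" or g == "control" else 38.0,
                "indep": lambda ds, g, r: 60.0,
            }
        )
        calls = classify_emic(mat, preset="mouse")
        assert calls.at["dep", "label"] == LABEL_DEPENDENT
        assert calls.at["dep_low", "label"] == LABEL_DEPENDENT
        assert calls.at["dep_low", "branch"] == "low-inclusion"
        assert calls.at["sens_n2a", "label"] == LABEL_SENSITIVE
        assert calls.at["sens_brain", "label"] == LABEL_SENSITIVE
        assert calls.at["indep", "label"] == LABEL_INDEPENDENT


class TestClassifyEmicHuman:
    def test_overexpression_enhancement(self):
        meta = {}
        for geno in ("control", "mutant"):
            for rep in (1, 2):
                meta[f"{geno}_{rep}"] = dict(genotype=geno, replicate=rep)
        values = {
            s: {
                "enh": 10.0 if s.startswith("control") else 60.0,
                "rep_discordant": 10.0 if s.startswith("control")
                else (80.0 if s.endswith("1") else 55.0),
                "weak": 10.0 if s.startswith("control") else 40.0,
            }
            for s in meta
        }
        calls = classify_emic(make_psi_matrix(values, meta), preset="human_oe")
        assert calls.at["enh", "label"] == LABEL_DEPENDENT
        assert calls.at["rep_discordant", "label"] == LABEL_INDEPENDENT
        assert calls.at["weak", "label"] == LABEL_INDEPENDENT


class TestSexDifferential:
    def _mat(self, fn):
        meta = fly_design()
        values = {s: {"e": fn(*s.split("_")[:3])} for s in meta}
        return make_psi_matrix(values, meta)

    def test_called_when_both_conditions_hold(self):
        # KO effect -40 in males; M-F difference 25 in controls
        mat = self._mat(lambda st, sx, g:
                        (75.0 if sx == "m" else 50.0) if g == "control"
                        else (35.0 if sx == "m" else 50.0))
        res = call_sex_differential(mat)
        assert bool(res.at["e", "sex_differential"])
        assert "control" in res.at["e", "sexdiff_genotype"]

    def test_no_sex_difference_not_called(self):
        mat = self._mat(lambda st, sx, g: 90.0 if g == "control" else 50.0)
        assert not bool(call_sex_differential(mat).at["e", "sex_differential"])

    def test_weak_ko_effect_not_called(self):
        mat = self._mat(lambda st, sx, g:
                        (75.0 if sx == "m" else 50.0) if g == "control"
                        else (60.0 if sx == "m" else 35.0))
        assert not bool(call_sex_differential(mat).at["e", "sex_differential"])


class TestControlSets:
    def _tissue_matrix(self, event_values, n_tissues=4):
        meta = {}
        for t in range(n_tissues):
            meta[f"t{t}"] = dict(tissue_group=f"g{t}")
        values = {s: dict(event_values[int(s[1:])]) for s in meta}
        # reorganize: event_values: {tissue_index: {event: psi}}
        return make_psi_matrix(values, meta)

    def test_membership_rules(self):
        ev = {
            t: {"hi": 95 + t, "lo": 2 + t, "alt": 50.0, "mid": 30.0 + 20 * t}
            for t in range(4)
        }
        m = self._tissue_matrix(ev)
        cs = define_control_sets(m, seed=1)
        assert "hi" in cs.high_psi and "lo" in cs.low_psi and "alt" in cs.ase
        assert "hi" not in cs.ase and "lo" not in cs.ase

    def test_cap_is_reproducible_and_exact(self):
        ev = {t: {f"h{i}": 95.0 for i in range(1500)} for t in range(4)}
        m = self._tissue_matrix(ev)
        a = define_control_sets(m, highpsi_cap=1000, seed=7)
        b = define_control_sets(m, highpsi_cap=1000, seed=7)
        assert len(a.high_psi) == 1000 and a.high_psi == b.high_psi
        c = define_control_sets(m, highpsi_cap=1000, seed=8)
        assert c.high_psi != a.high_psi

    def test_sets_are_disjoint_and_exclude_regulated(self):
        ev = {t: {"hi": 95.0, "alt": 50.0, "reg": 95.0} for t in range(4)}
        m = self._tissue_matrix(ev)
        cs = define_control_sets(m, exclude=["reg"], neural_events=["alt"], seed=0)
        sets = list(cs.as_dict().values())
        for a, b in itertools.combinations(sets, 2):
            assert not (set(a) & set(b))
        assert "reg" not in set().union(*map(set, sets))
        assert cs.neural == ["alt"] and cs.ase == []

    def test_too_few_tissues_is_error(self):
        ev = {t: {"e": 50.0} for t in range(2)}
        m = self._tissue_matrix(ev, n_tissues=2)
        with pytest.raises(ValueError, match="3"):
            define_control_sets(m)


class TestGroupShift:
    def test_identical_distributions_near_one(self):
        x = [1, 2, 3, 4, 5]
        res = group_shift_test({"kd": x}, {"kd": x})
        assert res["p"].iloc[0] > 0.9

    def test_complete_separation_minimal_exact_p(self):
        res = group_shift_test({"kd": [-50, -51, -52, -53, -54]},
                               {"kd": [0, 1, 2, 3, 4]})
        # two-sided exact minimum for n=m=5: 2 / C(10,5)
        assert res["p"].iloc[0] == pytest.approx(2 / 252)

    def test_single_perturbation_bh_equals_raw(self):
        res = group_shift_test({"kd": [-30, -31, -29, -32]}, {"kd": [0, 1, -1, 2]})
        assert res["q"].iloc[0] == pytest.approx(res["p"].iloc[0])

    def test_small_groups_skipped(self):
        res = group_shift_test({"kd": [1, 2]}, {"kd": [1, 2, 3]})
        assert len(res) == 0
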