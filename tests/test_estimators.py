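import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wmltm.estimators import (
    RecognitionCounts,
    adjust_estimate,
    bias_rates,
    binding_cells,
    binding_score_from_counts,
    capacity_k,
    estimate_p,
    object_id_rates,
    score_cohort,
    table2_summary,
    tally_recognition,
    transfer_ratio,
)
from wmltm.response_model import (
    AgeGroupProfile,
    ParticipantParams,
    response_probabilities,
    simulate_cohort,
    simulate_participant,
)
from wmltm.task_design import Condition, relabel_colors, COLORS
from wmltm._util import substream


def _records(rows):
    df = pd.DataFrame(rows)
    df["set_size"] = df["set_size"].astype("Int64")
    return df


def row(phase="WM", cond="SAME_SAME", s=2, resp="SS", wasp=False, pid="p1"):
    return dict(participant_id=pid, age_group="g", phase=phase, probe_index=1,
                set_size=s, condition=cond, was_wm_probe=wasp, response=resp,
                object_correct=True, fully_correct=True)


# ---------------------------------------------------------------------------
# recognition tallies and the corrected proportion

def test_all_ss_gives_unit_hit_rate():
    rows = [row(resp="SS") for _ in range(18)] + [
        row(cond="DIFF_OBJ_ARRAYCOLOR", resp="DO") for _ in range(9)
    ]
    counts = tally_recognition(_records(rows), "WM", 2)
    assert counts.h == 1.0 and counts.f == 0.0


def test_do_on_old_probe_is_a_miss():
    rows = [row(resp=r) for r in ("SS", "SD", "DO")] + [
        row(cond="DIFF_OBJ_NOVELCOLOR", resp="DO")
    ]
    counts = tally_recognition(_records(rows), "WM", 2)
    assert counts.n_old_called_old == 2  # either same-object option counts


def test_tally_raises_on_empty_scope():
    with pytest.raises(ValueError):
        tally_recognition(_records([row()]), "WM", 4)


def test_estimate_p_worked_example():
    counts = RecognitionCounts("WM", 2, n_old=10, n_old_called_old=9,
                               n_new=10, n_new_called_old=2)
    # algebraic inversion: h = p + (1-p) g with g = f = .2 and h = .9
    assert estimate_p(counts) == pytest.approx(0.875)


def test_estimate_p_edges():
    eq = RecognitionCounts("WM", 2, 10, 3, 10, 3)
    assert estimate_p(eq) == pytest.approx(0.0)
    top = RecognitionCounts("WM", 2, 10, 10, 10, 7)
    assert estimate_p(top) == pytest.approx(1.0)
    degenerate = RecognitionCounts("WM", 2, 10, 10, 10, 10)
    with pytest.raises(ValueError):
        estimate_p(degenerate)


def test_adjustment_rules():
    p, adj = adjust_estimate(0.1, "WM", 4)
    assert (p, adj) == (0.25, True)  # k floored at 1 item
    p, adj = adjust_estimate(-0.07, "LTM")
    assert (p, adj) == (0.0, True)
    p, adj = adjust_estimate(0.79, "WM", 2)
    assert (p, adj) == (0.79, False)


def test_adjustment_alternative_reading():
    p, adj = adjust_estimate(0.79, "WM", 2, mode="p_floor")
    assert (p, adj) == (1.0, True)


@given(st.floats(-1, 1), st.sampled_from([2, 3, 4]))
@settings(max_examples=200, deadline=None)
def test_adjustment_idempotent_and_never_lowers(raw, s):
    p1, _ = adjust_estimate(raw, "WM", s)
    p2, flag2 = adjust_estimate(p1, "WM", s)
    assert p2 == p1 and not flag2
    assert p1 >= raw
    q1, _ = adjust_estimate(raw, "LTM")
    q2, flag = adjust_estimate(q1, "LTM")
    assert q2 == q1 and not flag
    assert q1 >= raw


def test_capacity_k_identities():
    assert capacity_k(0.90, 4) == pytest.approx(3.6)
    assert capacity_k(0.79, 2) == pytest.approx(1.58)
    assert capacity_k(0.0, 3) == 0.0


def test_transfer_ratio():
    assert transfer_ratio(0.52, 0.95) == pytest.approx(0.547, abs=5e-4)
    assert transfer_ratio(0.0, 0.5) == 0.0
    with pytest.raises(ZeroDivisionError):
        transfer_ratio(0.2, 0.0)


# ---------------------------------------------------------------------------
# binding and bias

def test_aggregate_binding_scores_from_mean_frequencies():
    # re-paired trials: correct = "different color"; intact: correct = "old"
    assert round(binding_score_from_counts(13.07, 5.62), 2) == 0.70
    assert round(binding_score_from_counts(22.19, 9.91), 2) == 0.69


def test_binding_no_errors_when_all_intact_answered_ss():
    rows = [row(resp="SS") for _ in range(12)]
    cells = binding_cells(_records(rows), "WM")
    cell = next(c for c in cells if c.set_size == 2)
    assert cell.n_eligible == 12 and cell.n_errors == 0 and cell.error_rate == 0.0


def test_binding_eligibility_filters():
    rows = [
        row(cond="SAME_SAME", resp="SD"),              # eligible, error
        row(cond="SAME_DIFF_SWAP", resp="SS"),         # eligible, error
        row(cond="SAME_DIFF_SWAP", resp="SD"),         # eligible, correct
        row(cond="SAME_SAME", resp="DO"),              # object missed: dropped
        row(cond="SAME_DIFF_NOVEL", resp="SS"),        # novel color: never eligible
        row(phase="LTM", cond="SAME_SAME", resp="SS", wasp=True),  # WM-probed: dropped
        row(phase="LTM", cond="SAME_SAME", resp="SD"),
    ]
    wm_cell = next(c for c in binding_cells(_records(rows), "WM") if c.set_size == 2)
    assert (wm_cell.n_eligible, wm_cell.n_errors) == (3, 2)
    ltm_cell = next(c for c in binding_cells(_records(rows), "LTM") if c.set_size == 2)
    assert (ltm_cell.n_eligible, ltm_cell.n_errors) == (1, 1)
    assert ltm_cell.excluded  # fewer than 5 eligible trials
    ltm_all = next(
        c for c in binding_cells(_records(rows), "LTM", include_all=True)
        if c.set_size == 2
    )
    assert not ltm_all.excluded


def test_bias_rate_simple():
    rows = [row(cond="DIFF_OBJ_ARRAYCOLOR", resp="SS") for _ in range(7)]
    rows += [row(cond="DIFF_OBJ_NOVELCOLOR", resp="SD") for _ in range(3)]
    rows += [row(cond="DIFF_OBJ_ARRAYCOLOR", resp="DO") for _ in range(5)]
    be = bias_rates(_records(rows), "WM")
    assert (be.n_false_old, be.n_same_color) == (10, 7)
    assert be.rate == pytest.approx(0.7)


def test_bias_rate_undefined_without_false_olds():
    rows = [row(cond="DIFF_OBJ_ARRAYCOLOR", resp="DO")]
    assert np.isnan(bias_rates(_records(rows), "WM").rate)


def test_object_id_rates_ceiling():
    rows = [row(resp="SS"), row(cond="SAME_DIFF_NOVEL", resp="SD")]
    assert object_id_rates(_records(rows), "WM")[2] == 1.0


def test_equal_bias_cancellation():
    """With no binding memory the expected error rate on a balanced
    intact/re-paired eligible set is exactly 1/2, for any guess bias."""
    for beta in (0.1, 0.5, 0.9):
        p = ParticipantParams(k_true=2.0, g_old=0.3, beta_same=beta, b_wm=0.0,
                              d_novel=0.0, tau_ltm=0.5, b_ltm=0.0, g_old_ltm=0.3)
        t_ss = response_probabilities(Condition.SAME_SAME, "WM", 2, p)
        t_sw = response_probabilities(Condition.SAME_DIFF_SWAP, "WM", 2, p)
        # per-trial-type error probabilities conditional on "called old"
        err_ss = t_ss[1] / (t_ss[0] + t_ss[1])
        err_sw = t_sw[0] / (t_sw[0] + t_sw[1])
        assert err_ss + err_sw == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# oracle recounts on simulated data

def _brute_force_recount(records):
    """Plain-python pass over the rows, independent of the estimators."""
    out = {}
    rows = records.to_dict(orient="records")
    old = {"SAME_SAME", "SAME_DIFF_SWAP", "SAME_DIFF_NOVEL"}
    for phase in ("WM", "LTM"):
        for s in (2, 3, 4):
            n_old = n_hit = 0
            n_new = n_fa = 0
            n_elig = n_err = 0
            for r in rows:
                if r["phase"] != phase:
                    continue
                if r["condition"] in old and r["set_size"] == s:
                    n_old += 1
                    if r["response"] != "DO":
                        n_hit += 1
                is_wm_lure = phase == "WM" and r["condition"].startswith("DIFF_OBJ") \
                    and r["set_size"] == s
                is_ltm_lure = phase == "LTM" and r["condition"] == "NEW"
                if is_wm_lure or is_ltm_lure:
                    n_new += 1
                    if r["response"] != "DO":
                        n_fa += 1
                if (
                    r["condition"] in ("SAME_SAME", "SAME_DIFF_SWAP")
                    and r["set_size"] == s
                    and r["response"] != "DO"
                    and not (phase == "LTM" and r["was_wm_probe"])
                ):
                    n_elig += 1
                    wrong = (r["condition"] == "SAME_SAME" and r["response"] == "SD") or (
                        r["condition"] == "SAME_DIFF_SWAP" and r["response"] == "SS"
                    )
                    n_err += int(wrong)
            out[(phase, s)] = (n_old, n_hit, n_new, n_fa, n_elig, n_err)
    return out


def test_tallies_and_binding_match_brute_force(wm_design, ltm_design, params, rng):
    rec = simulate_participant(params, wm_design, ltm_design, rng)
    rec.insert(0, "age_group", "g")
    rec.insert(0, "participant_id", "p1")
    oracle = _brute_force_recount(rec)
    for phase in ("WM", "LTM"):
        cells = {c.set_size: c for c in binding_cells(rec, phase)}
        for s in (2, 3, 4):
            n_old, n_hit, n_new, n_fa, n_elig, n_err = oracle[(phase, s)]
            counts = tally_recognition(rec, phase, s)
            assert (counts.n_old, counts.n_old_called_old) == (n_old, n_hit)
            assert (counts.n_new, counts.n_new_called_old) == (n_new, n_fa)
            assert (cells[s].n_eligible, cells[s].n_errors) == (n_elig, n_err)


def test_mean_ratio_matches_per_participant_recount(wm_design, ltm_design):
    profile = AgeGroupProfile(
        name="g", n=8,
        means=dict(k_true=2.5, g_old=0.3, beta_same=0.7, b_wm=0.6, d_novel=0.85,
                   tau_ltm=0.5, b_ltm=0.5, g_old_ltm=0.25),
    )
    _, rec = simulate_cohort(wm_design, ltm_design, profile, 5)
    scored = score_cohort(rec)
    ratios = scored["ratios"]
    for s in (2, 3, 4):
        per_participant = []
        for pid, df in rec.groupby("participant_id"):
            wm_c = tally_recognition(df, "WM", s)
            lt_c = tally_recognition(df, "LTM", s)
            p_wm, _ = adjust_estimate(estimate_p(wm_c), "WM", s)
            p_lt, _ = adjust_estimate(estimate_p(lt_c), "LTM")
            per_participant.append(transfer_ratio(p_lt, p_wm))
        got = ratios[ratios["set_size"] == s].sort_values("participant_id")["ratio"]
        assert np.mean(per_participant) == pytest.approx(got.mean(), abs=1e-12)


def test_estimator_consistency_oversampled():
    """At ~10k probes per cell the corrected estimates recover the generating
    availability and the bias rate recovers the guess bias."""
    p = ParticipantParams(k_true=1.6, g_old=0.4, beta_same=0.72, b_wm=0.6,
                          d_novel=0.8, tau_ltm=0.5, b_ltm=0.5, g_old_ltm=0.3)
    rng = np.random.default_rng(2024)
    T = 10_000
    rows = []
    specs = [("WM", "SAME_SAME", 2), ("WM", "DIFF_OBJ_ARRAYCOLOR", 2),
             ("LTM", "SAME_SAME", 2), ("LTM", "NEW", None)]
    for phase, cond, s in specs:
        triple = response_probabilities(Condition(cond), phase, s, p)
        draws = rng.choice(["SS", "SD", "DO"], size=T, p=triple)
        rows += [row(phase=phase, cond=cond, s=s, resp=r) for r in draws]
    rec = _records(rows)
    wm_c = tally_recognition(rec, "WM", 2)
    assert estimate_p(wm_c) == pytest.approx(min(1.6 / 2, 1), abs=0.01)
    lt_c = tally_recognition(rec, "LTM", 2)
    assert estimate_p(lt_c) == pytest.approx(min(1.6 / 2, 1) * 0.5, abs=0.02)
    assert bias_rates(rec, "WM").rate == pytest.approx(0.72, abs=0.01)


def test_cohort_bias_recovery(wm_design, ltm_design):
    profile = AgeGroupProfile(
        name="g", n=200,
        means=dict(k_true=2.5, g_old=0.35, beta_same=0.72, b_wm=0.6, d_novel=0.85,
                   tau_ltm=0.5, b_ltm=0.5, g_old_ltm=0.3),
    )
    _, rec = simulate_cohort(wm_design, ltm_design, profile, 77)
    scored = score_cohort(rec)
    bias = scored["bias"]
    wm_rate = bias[(bias["phase"] == "WM") & (bias["n_false_old"] > 0)]["rate"].mean()
    assert wm_rate == pytest.approx(0.72, abs=0.02)


def test_binding_invariant_to_color_relabeling(wm_design, params):
    from wmltm.task_design import _generate_ltm

    mapping = dict(zip(COLORS, COLORS[::-1]))
    wm2 = relabel_colors(wm_design, mapping)
    rng_a = substream(55, 9)
    rng_b = substream(55, 9)
    ltm_a = _generate_ltm(wm_design, substream(3, 1))
    ltm_b = _generate_ltm(wm2, substream(3, 1))
    rec_a = simulate_participant(params, wm_design, ltm_a, rng_a)
    rec_b = simulate_participant(params, wm2, ltm_b, rng_b)
    for phase in ("WM", "LTM"):
        cells_a = binding_cells(rec_a, phase, participant_id="x")
        cells_b = binding_cells(rec_b, phase, participant_id="x")
        assert cells_a == cells_b


def test_score_cohort_bookkeeping_conserves(wm_design, ltm_design):
    profile = AgeGroupProfile(name="g", n=4, means=dict(
        k_true=2.5, g_old=0.3, beta_same=0.7, b_wm=0.6, d_novel=0.85,
        tau_ltm=0.5, b_ltm=0.5, g_old_ltm=0.25))
    _, rec = simulate_cohort(wm_design, ltm_design, profile, 13)
    book = score_cohort(rec)["bookkeeping"].set_index("stage")["count"]
    assert book["records_total"] == len(rec)
    assert (
        book["binding_eligible_trials"] + book["binding_filtered_trials"]
        == book["binding_condition_probes"]
    )


def test_table2_shape(wm_design, ltm_design):
    profile = AgeGroupProfile(name="g", n=4, means=dict(
        k_true=2.5, g_old=0.3, beta_same=0.7, b_wm=0.6, d_novel=0.85,
        tau_ltm=0.5, b_ltm=0.5, g_old_ltm=0.25))
    _, rec = simulate_cohort(wm_design, ltm_design, profile, 17)
    t2 = table2_summary(rec)
    assert len(t2) == 4  # one group x {WM, LTM} x {repaired, intact}
    repaired_wm = t2[(t2.phase == "WM") & (t2.trial_type == "repaired")].iloc[0]
    total = (repaired_wm.freq_old_intact + repaired_wm.freq_diffcol
             + repaired_wm.freq_diffobj)
    assert total == pytest.approx(20, abs=0.1)  # 20 re-paired WM trials
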