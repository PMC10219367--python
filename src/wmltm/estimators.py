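"""Guessing-corrected recognition estimators, capacity, transfer ratio,
contingent binding scoring with eligibility filters, and guess-bias rates.

All operations consume long-format response records (one row per probe
response) with the columns written by :mod:`wmltm.response_model`:
``participant_id, age_group, phase, probe_index, set_size, condition,
was_wm_probe, response, object_correct, fully_correct``.

Scoring logic:

* item memory — a probe of a studied object is a *hit* when the response is
  either "same object" option; a lure called old is a *false alarm*.  The
  remembered proportion is ``p = (h - f) / (1 - f)``, capacity ``k = p * S``.
* implausible values — estimates implying a capacity below one item are
  floored at ``k = 1``; negative delayed-test proportions are floored at 0.
* binding — among intact and re-paired probes on which the object was called
  old, an error is claiming a color change on an intact probe or no change on
  a re-paired probe.  Novel-color probes are excluded (color novelty alone
  solves them), as are delayed-test probes of objects already used as WM
  probes; delayed-test cells resting on fewer than 5 eligible trials are
  flagged for exclusion.
* bias — among lures incorrectly called old, the rate of "same color" picks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import round_half_up
from .task_design import Condition, Response

OLD_CONDS = [c.value for c in (Condition.SAME_SAME, Condition.SAME_DIFF_SWAP,
                               Condition.SAME_DIFF_NOVEL)]
WM_LURE_CONDS = [Condition.DIFF_OBJ_ARRAYCOLOR.value, Condition.DIFF_OBJ_NOVELCOLOR.value]
BINDING_CONDS = [Condition.SAME_SAME.value, Condition.SAME_DIFF_SWAP.value]

MIN_LTM_BINDING_TRIALS = 5


@dataclass(frozen=True)
class RecognitionCounts:
    phase: str
    set_size: int | None
    n_old: int
    n_old_called_old: int
    n_new: int
    n_new_called_old: int

    @property
    def h(self) -> float:
        return self.n_old_called_old / self.n_old

    @property
    def f(self) -> float:
        return self.n_new_called_old / self.n_new


@dataclass(frozen=True)
class CapacityEstimate:
    p_wm: float
    k: float
    set_size: int
    adjusted: bool


@dataclass(frozen=True)
class LtmEstimate:
    p_ltm: float
    set_size: int
    adjusted: bool


@dataclass(frozen=True)
class BindingCell:
    participant_id: str
    phase: str
    set_size: int
    n_eligible: int
    n_errors: int
    excluded: bool

    @property
    def error_rate(self) -> float:
        if self.n_eligible == 0:
            return float("nan")
        return self.n_errors / self.n_eligible


@dataclass(frozen=True)
class BiasEstimate:
    participant_id: str
    phase: str
    n_false_old: int
    n_same_color: int

    @property
    def rate(self) -> float:
        if self.n_false_old == 0:
            return float("nan")
        return self.n_same_color / self.n_false_old


def _called_old(records: pd.DataFrame) -> pd.Series:
    return records["response"] != Response.DO.value


def tally_recognition(
    records: pd.DataFrame,
    phase: str,
    set_size: int | None = None,
    pool_wm_lures: bool = False,
) -> RecognitionCounts:
    """Hit/false-alarm tallies for one participant.

    WM lures are tallied within the given set size unless ``pool_wm_lures``;
    delayed-test lures carry no set size and are always pooled.
    """
    recs = records[records["phase"] == phase]
    if phase == "WM":
        if set_size is None:
            raise ValueError("WM tallies require a set size")
        old = recs[recs["condition"].isin(OLD_CONDS) & (recs["set_size"] == set_size)]
        new = recs[recs["condition"].isin(WM_LURE_CONDS)]
        if not pool_wm_lures:
            new = new[new["set_size"] == set_size]
    elif phase == "LTM":
        old = recs[recs["condition"].isin(OLD_CONDS)]
        if set_size is not None:
            old = old[old["set_size"] == set_size]
        new = recs[recs["condition"] == Condition.NEW.value]
    else:
        raise ValueError(f"unknown phase {phase!r}")
    if len(old) == 0 or len(new) == 0:
        raise ValueError(f"empty tally scope: phase={phase}, set_size={set_size}")
    return RecognitionCounts(
        phase=phase,
        set_size=set_size,
        n_old=len(old),
        n_old_called_old=int(_called_old(old).sum()),
        n_new=len(new),
        n_new_called_old=int(_called_old(new).sum()),
    )


def estimate_p(counts: RecognitionCounts) -> float:
    """Raw remembered proportion ``(h - f) / (1 - f)``; may be negative."""
    h, f = counts.h, counts.f
    if f >= 1.0:
        raise ValueError("false alarm rate of 1: degenerate respondent, exclude")
    return (h - f) / (1.0 - f)


def adjust_estimate(
    raw_p: float, phase: str, set_size: int | None = None, mode: str = "k_floor"
) -> tuple[float, bool]:
    """Floor implausible estimates.

    WM: estimates implying a capacity below 1 item are raised to k = 1
    (``mode="k_floor"``, the default reading) or, under the alternative
    reading ``mode="p_floor"``, proportions below 1 are raised to 1.
    LTM: negative proportions are raised to 0.
    """
    if phase == "WM":
        if set_size not in (2, 3, 4):
            raise ValueError("WM adjustment requires set size in {2, 3, 4}")
        if mode == "k_floor":
            if raw_p * set_size < 1.0:
                return 1.0 / set_size, True
        elif mode == "p_floor":
            if raw_p < 1.0:
                return 1.0, True
        else:
            raise ValueError(f"unknown adjustment mode {mode!r}")
        return raw_p, False
    if phase == "LTM":
        if raw_p < 0.0:
            return 0.0, True
        return raw_p, False
    raise ValueError(f"unknown phase {phase!r}")


def capacity_k(p_wm: float, set_size: int) -> float:
    """Items in memory: ``k = p * S``."""
    return p_wm * set_size


def transfer_ratio(p_ltm: float, p_wm: float) -> float:
    """Per-participant, per-set-size retention into the delayed test."""
    if p_wm == 0:
        raise ZeroDivisionError("p_wm = 0: transfer ratio undefined")
    return p_ltm / p_wm


def binding_score_from_counts(n_correct_color: float, n_wrong_color: float) -> float:
    """Aggregate binding score: correct-color responses over old-classified
    responses (works on mean frequencies as well as raw counts)."""
    return n_correct_color / (n_correct_color + n_wrong_color)


def binding_cells(
    records: pd.DataFrame,
    phase: str,
    include_all: bool = False,
    participant_id: str | None = None,
) -> list[BindingCell]:
    """Contingent binding scoring for one participant, per set size.

    Eligible probes: intact or re-paired, object called old; delayed-test
    probes of objects re-used from WM probing are dropped.  ``include_all``
    disables the <5-trial exclusion flag (robustness-check mode).
    """
    recs = records[records["phase"] == phase]
    if participant_id is None:
        ids = recs["participant_id"].unique() if "participant_id" in recs else [""]
        if len(ids) > 1:
            raise ValueError("records span multiple participants")
        participant_id = str(ids[0]) if len(ids) else ""
    elig = recs[recs["condition"].isin(BINDING_CONDS) & _called_old(recs)]
    if phase == "LTM":
        elig = elig[~elig["was_wm_probe"].astype(bool)]
    err = (
        ((elig["condition"] == Condition.SAME_SAME.value)
         & (elig["response"] == Response.SD.value))
        | ((elig["condition"] == Condition.SAME_DIFF_SWAP.value)
           & (elig["response"] == Response.SS.value))
    )
    cells = []
    for s in (2, 3, 4):
        mask = elig["set_size"] == s
        n_elig = int(mask.sum())
        n_err = int(err[mask].sum())
        excluded = (
            phase == "LTM" and not include_all and n_elig < MIN_LTM_BINDING_TRIALS
        )
        cells.append(
            BindingCell(
                participant_id=participant_id, phase=phase, set_size=s,
                n_eligible=n_elig, n_errors=n_err, excluded=excluded,
            )
        )
    return cells


def bias_rates(
    records: pd.DataFrame, phase: str, participant_id: str | None = None
) -> BiasEstimate:
    """Same-color guess rate among lures incorrectly called old."""
    recs = records[records["phase"] == phase]
    if participant_id is None:
        ids = recs["participant_id"].unique() if "participant_id" in recs else [""]
        participant_id = str(ids[0]) if len(ids) else ""
    lure_conds = WM_LURE_CONDS if phase == "WM" else [Condition.NEW.value]
    false_old = recs[recs["condition"].isin(lure_conds) & _called_old(recs)]
    return BiasEstimate(
        participant_id=participant_id,
        phase=phase,
        n_false_old=len(false_old),
        n_same_color=int((false_old["response"] == Response.SS.value).sum()),
    )


def object_id_rates(records: pd.DataFrame, phase: str) -> dict[int, float]:
    """Raw per-set-size rate at which studied objects were called old
    (uncorrected for lure performance; includes novel-color probes)."""
    recs = records[(records["phase"] == phase) & records["condition"].isin(OLD_CONDS)]
    out: dict[int, float] = {}
    for s in (2, 3, 4):
        sub = recs[recs["set_size"] == s]
        out[s] = float(_called_old(sub).mean()) if len(sub) else float("nan")
    return out


# ---------------------------------------------------------------------------
# cohort-level scoring (vectorized wrappers over the per-participant ops)

def score_cohort(
    records: pd.DataFrame,
    pool_wm_lures: bool = False,
    binding_include_all: bool = False,
    adjust_mode: str = "k_floor",
) -> dict[str, pd.DataFrame]:
    """Score every participant; returns tidy frames keyed by estimate type.

    Keys: ``recognition`` (h, f, p, k per phase x set size), ``ratios``,
    ``binding``, ``bias``, ``object_id``, and a ``bookkeeping`` frame that
    conserves record counts through every filter.
    """
    groups = (
        records[["participant_id", "age_group"]].drop_duplicates()
        .set_index("participant_id")["age_group"]
        if "age_group" in records else pd.Series(dtype=object)
    )
    rec_rows, bind_rows, bias_rows, oid_rows = [], [], [], []
    for pid, df in records.groupby("participant_id", sort=True):
        age = groups.get(pid, "")
        for phase in ("WM", "LTM"):
            for s in (2, 3, 4):
                counts = tally_recognition(df, phase, s, pool_wm_lures=pool_wm_lures)
                raw = estimate_p(counts)
                p_adj, flag = adjust_estimate(raw, phase, s, mode=adjust_mode)
                row = dict(
                    participant_id=pid, age_group=age, phase=phase, set_size=s,
                    n_old=counts.n_old, n_old_called_old=counts.n_old_called_old,
                    n_new=counts.n_new, n_new_called_old=counts.n_new_called_old,
                    h=counts.h, f=counts.f, p_raw=raw, p=p_adj, adjusted=flag,
                    k=capacity_k(p_adj, s) if phase == "WM" else np.nan,
                )
                rec_rows.append(row)
            for cell in binding_cells(df, phase, include_all=binding_include_all,
                                      participant_id=str(pid)):
                bind_rows.append(
                    dict(
                        participant_id=pid, age_group=age, phase=phase,
                        set_size=cell.set_size, n_eligible=cell.n_eligible,
                        n_errors=cell.n_errors, error_rate=cell.error_rate,
                        excluded=cell.excluded,
                    )
                )
            be = bias_rates(df, phase, participant_id=str(pid))
            bias_rows.append(
                dict(participant_id=pid, age_group=age, phase=phase,
                     n_false_old=be.n_false_old, n_same_color=be.n_same_color,
                     rate=be.rate)
            )
            for s, rate in object_id_rates(df, phase).items():
                oid_rows.append(
                    dict(participant_id=pid, age_group=age, phase=phase,
                         set_size=s, rate=rate)
                )

    recognition = pd.DataFrame(rec_rows)
    wm = recognition[recognition["phase"] == "WM"][
        ["participant_id", "age_group", "set_size", "p", "k"]
    ].rename(columns={"p": "p_wm"})
    lt = recognition[recognition["phase"] == "LTM"][
        ["participant_id", "set_size", "p"]
    ].rename(columns={"p": "p_ltm"})
    ratios = wm.merge(lt, on=["participant_id", "set_size"])
    ratios["ratio"] = ratios["p_ltm"] / ratios["p_wm"]

    binding = pd.DataFrame(bind_rows)
    out = {
        "recognition": recognition,
        "ratios": ratios,
        "binding": binding,
        "bias": pd.DataFrame(bias_rows),
        "object_id": pd.DataFrame(oid_rows),
        "bookkeeping": _bookkeeping(records, binding),
    }
    return out


def _bookkeeping(records: pd.DataFrame, binding: pd.DataFrame) -> pd.DataFrame:
    """Filter accounting in the style of eligible-instance reporting."""
    n_binding_probes = int(records["condition"].isin(BINDING_CONDS).sum())
    elig = int(binding["n_eligible"].sum())
    ltm = binding[binding["phase"] == "LTM"]
    rows = [
        dict(stage="records_total", count=len(records)),
        dict(stage="binding_condition_probes", count=n_binding_probes),
        dict(stage="binding_eligible_trials", count=elig),
        dict(stage="binding_filtered_trials", count=n_binding_probes - elig),
        dict(stage="ltm_binding_instances", count=len(ltm)),
        dict(stage="ltm_binding_instances_excluded", count=int(ltm["excluded"].sum())),
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report tables

def table1_summary(scored: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Group x set-size means (SD) of p(WM), p(LTM), ratio, binding error
    rates, and capacity k, shaped like the published summary table."""
    rec, ratios, binding = scored["recognition"], scored["ratios"], scored["binding"]
    rows = []
    for (age, s), sub in ratios.groupby(["age_group", "set_size"], sort=True):
        wm_bind = binding[(binding["phase"] == "WM") & (binding["age_group"] == age)
                          & (binding["set_size"] == s) & (binding["n_eligible"] > 0)]
        lt_bind = binding[(binding["phase"] == "LTM") & (binding["age_group"] == age)
                          & (binding["set_size"] == s) & ~binding["excluded"]
                          & (binding["n_eligible"] > 0)]
        rows.append(
            dict(
                age_group=age, set_size=s,
                p_wm_mean=sub["p_wm"].mean(), p_wm_sd=sub["p_wm"].std(),
                p_ltm_mean=sub["p_ltm"].mean(), p_ltm_sd=sub["p_ltm"].std(),
                ratio_mean=sub["ratio"].mean(), ratio_sd=sub["ratio"].std(),
                wm_binding_err_mean=wm_bind["error_rate"].mean(),
                ltm_binding_err_mean=lt_bind["error_rate"].mean(),
                k_mean=sub["k"].mean(), k_sd=sub["k"].std(),
                n=len(sub),
            )
        )
    return pd.DataFrame(rows)


def table2_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Mean per-participant response frequencies on the binding-relevant
    trials (re-paired and intact), plus aggregate binding scores.

    Delayed-test intact rows exclude probes of objects re-used from WM
    probing, mirroring the contingent binding analysis.
    """
    rows = []
    for age, df in records.groupby("age_group", sort=True):
        n = df["participant_id"].nunique()
        for phase in ("WM", "LTM"):
            sub = df[df["phase"] == phase]
            for label, cond in (("repaired", Condition.SAME_DIFF_SWAP.value),
                                ("intact", Condition.SAME_SAME.value)):
                trials = sub[sub["condition"] == cond]
                if phase == "LTM":
                    trials = trials[~trials["was_wm_probe"].astype(bool)]
                freq = trials["response"].value_counts()
                f_ss = freq.get("SS", 0) / n
                f_sd = freq.get("SD", 0) / n
                f_do = freq.get("DO", 0) / n
                correct = f_sd if label == "repaired" else f_ss
                wrong = f_ss if label == "repaired" else f_sd
                rows.append(
                    dict(
                        age_group=age, phase=phase, trial_type=label,
                        freq_old_intact=round_half_up(f_ss, 2),
                        freq_diffcol=round_half_up(f_sd, 2),
                        freq_diffobj=round_half_up(f_do, 2),
                        binding_score=round_half_up(
                            binding_score_from_counts(correct, wrong), 2
                        ),
                    )
                )
    return pd.DataFrame(rows)
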