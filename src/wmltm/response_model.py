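"""Multinomial-processing-tree observer and cohort simulation.

The observer holds the probed object with probability ``min(k/S, 1)``.  A held
object is always called "old"; its color judgment depends on whether the
object-color binding survived (``b_wm``/``b_ltm``) or, for novel-color probes,
whether the extraneous color is detected (``d_novel``).  An object that is not
held is called "new" with probability ``1 - g_old``; otherwise the observer
guesses "old" and picks the same-color option with probability ``beta_same``.
Marginalized over the color branch this reduces to the classic guessing model
for old/new recognition: hit rate = p + (1 - p) * g.

For the delayed test the availability becomes ``min(k/S, 1) * tau_ltm``, the
binding survival ``b_ltm``, and the guess-old rate ``g_old_ltm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict

import numpy as np
import pandas as pd
from scipy import stats

from ._util import STREAM_PARTICIPANTS, _norm_seed, substream
from .task_design import (
    Condition,
    LTMDesign,
    NEW_OBJECT_CONDITIONS,
    Response,
    WMDesign,
    _generate_ltm,
    _generate_wm,
)

_PROB_FIELDS = (
    "g_old", "beta_same", "b_wm", "d_novel", "tau_ltm", "b_ltm", "g_old_ltm",
)


@dataclass(frozen=True)
class ParticipantParams:
    """Latent observer parameters; all but ``k_true`` are probabilities."""

    k_true: float      # capacity, items
    g_old: float       # guess-"old" rate when the object is not held (WM)
    beta_same: float   # P(color guess lands on "same color")
    b_wm: float        # P(binding retained | object held), WM probe
    d_novel: float     # P(novel probe color detected | object held)
    tau_ltm: float     # P(held object survives into the delayed test)
    b_ltm: float       # P(binding survives | object survived)
    g_old_ltm: float   # guess-"old" rate in the delayed test

    def __post_init__(self) -> None:
        if not self.k_true > 0:
            raise ValueError(f"k_true must be positive, got {self.k_true}")
        for name in _PROB_FIELDS:
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")
        if self.d_novel < self.b_wm:
            raise ValueError("d_novel must be >= b_wm (novelty detection can only help)")


def response_probabilities(
    condition: Condition,
    phase: str,
    set_size: int | None,
    params: ParticipantParams,
) -> np.ndarray:
    """Analytic (P_SS, P_SD, P_DO) for one probe type.

    ``set_size`` is the origin set size; it may be None only for NEW lures.
    """
    condition = Condition(condition)
    if phase not in ("WM", "LTM"):
        raise ValueError(f"phase must be 'WM' or 'LTM', got {phase!r}")
    if phase == "WM" and condition is Condition.NEW:
        raise ValueError("NEW lures occur only in the LTM test")
    beta = params.beta_same
    if phase == "WM":
        g, b = params.g_old, params.b_wm
    else:
        g, b = params.g_old_ltm, params.b_ltm

    if condition in NEW_OBJECT_CONDITIONS:
        p = 0.0
    else:
        if set_size is None:
            raise ValueError("old-object probes require a set size")
        p = min(params.k_true / set_size, 1.0)
        if phase == "LTM":
            p *= params.tau_ltm

    if condition is Condition.SAME_SAME:
        in_ss, in_sd = b + (1 - b) * beta, (1 - b) * (1 - beta)
    elif condition is Condition.SAME_DIFF_SWAP:
        in_ss, in_sd = (1 - b) * beta, b + (1 - b) * (1 - beta)
    elif condition is Condition.SAME_DIFF_NOVEL:
        d = params.d_novel
        in_ss, in_sd = (1 - d) * beta, d + (1 - d) * (1 - beta)
    else:  # lure: the in-memory branch is unreachable (p = 0)
        in_ss = in_sd = 0.0

    p_ss = p * in_ss + (1 - p) * g * beta
    p_sd = p * in_sd + (1 - p) * g * (1 - beta)
    p_do = (1 - p) * (1 - g)
    triple = np.array([p_ss, p_sd, p_do])
    if np.any(triple < -1e-12) or abs(triple.sum() - 1.0) > 1e-9:
        raise ValueError(f"corrupted parameters produced {triple}")
    return triple


@dataclass(frozen=True)
class AgeGroupProfile:
    """Cohort description: truncated-normal heterogeneity per parameter."""

    name: str
    n: int
    means: dict[str, float]
    sds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        missing = {f.name for f in fields(ParticipantParams)} - set(self.means)
        if missing:
            raise ValueError(f"profile {self.name!r} missing means for {sorted(missing)}")
        if any(sd < 0 for sd in self.sds.values()):
            raise ValueError("spreads must be >= 0")

    def sample_params(self, rng: np.random.Generator) -> ParticipantParams:
        out: dict[str, float] = {}
        for f in fields(ParticipantParams):
            mu = self.means[f.name]
            sd = self.sds.get(f.name, 0.0)
            lo, hi = (1e-6, np.inf) if f.name == "k_true" else (0.0, 1.0)
            if sd == 0:
                out[f.name] = float(np.clip(mu, lo, min(hi, 1e9)))
            else:
                a, b = (lo - mu) / sd, (hi - mu) / sd
                out[f.name] = float(
                    stats.truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng)
                )
        # sampled independently; restore the tree's ordering constraint
        out["d_novel"] = max(out["d_novel"], out["b_wm"])
        return ParticipantParams(**out)


def default_profiles() -> tuple[AgeGroupProfile, AgeGroupProfile, AgeGroupProfile]:
    """Three age-group cohorts calibrated to the published group patterns:

    capacity and binding retention increase with age, the guess-old rate in
    the delayed test rises with age (children favor "new" when unsure), and
    the same-color guess bias sits near .70 in every group.
    """
    common = dict(beta_same=0.70)
    sds = dict(
        k_true=0.0, g_old=0.08, beta_same=0.06, b_wm=0.08, d_novel=0.05,
        tau_ltm=0.10, b_ltm=0.08, g_old_ltm=0.08,
    )
    young = AgeGroupProfile(
        name="grade1-2", n=43,
        means=dict(k_true=2.0, g_old=0.30, b_wm=0.45, d_novel=0.80,
                   tau_ltm=0.45, b_ltm=0.55, g_old_ltm=0.13, **common),
        sds={**sds, "k_true": 0.55},
    )
    middle = AgeGroupProfile(
        name="grade5-7", n=39,
        means=dict(k_true=3.0, g_old=0.33, b_wm=0.65, d_novel=0.85,
                   tau_ltm=0.55, b_ltm=0.55, g_old_ltm=0.29, **common),
        sds={**sds, "k_true": 0.50},
    )
    adult = AgeGroupProfile(
        name="adult", n=42,
        means=dict(k_true=3.6, g_old=0.35, b_wm=0.75, d_novel=0.90,
                   tau_ltm=0.55, b_ltm=0.55, g_old_ltm=0.32, **common),
        sds={**sds, "k_true": 0.45},
    )
    return young, middle, adult


RECORD_COLUMNS = [
    "participant_id", "age_group", "phase", "probe_index", "set_size",
    "condition", "was_wm_probe", "response", "object_correct", "fully_correct",
]

_RESPONSES = np.array([Response.SS.value, Response.SD.value, Response.DO.value])


def _draw_responses(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Vectorized categorical draw; probs has shape (n, 3)."""
    u = rng.random(len(probs))
    cum = np.cumsum(probs, axis=1)
    idx = (u[:, None] > cum).sum(axis=1)
    return _RESPONSES[idx]


def simulate_participant(
    params: ParticipantParams,
    wm: WMDesign,
    ltm: LTMDesign,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Answer every probe of one session exactly once."""
    keys: list[tuple[str, Condition, int | None]] = []
    meta: list[tuple[str, int, int | None, str, bool, str]] = []
    for tr in wm.trials:
        keys.append(("WM", tr.probe_condition, tr.set_size))
        meta.append(("WM", tr.trial_index, tr.set_size, tr.probe_condition.value,
                     False, tr.correct_response.value))
    for pr in ltm.probes:
        keys.append(("LTM", pr.condition, pr.origin_set_size))
        meta.append(("LTM", pr.probe_index, pr.origin_set_size, pr.condition.value,
                     pr.was_wm_probe, pr.correct_response.value))

    cache: dict[tuple[str, Condition, int | None], np.ndarray] = {}
    probs = np.empty((len(keys), 3))
    for i, key in enumerate(keys):
        if key not in cache:
            cache[key] = response_probabilities(key[1], key[0], key[2], params)
        probs[i] = cache[key]
    resp = _draw_responses(rng, probs)

    cond = np.array([m[3] for m in meta])
    correct = np.array([m[5] for m in meta])
    old_object = ~np.isin(cond, [c.value for c in NEW_OBJECT_CONDITIONS])
    object_correct = np.where(old_object, resp != "DO", resp == "DO")
    return pd.DataFrame(
        {
            "phase": [m[0] for m in meta],
            "probe_index": [m[1] for m in meta],
            "set_size": pd.array([m[2] for m in meta], dtype="Int64"),
            "condition": cond,
            "was_wm_probe": [m[4] for m in meta],
            "response": resp,
            "object_correct": object_correct,
            "fully_correct": resp == correct,
        }
    )


def simulate_cohort(
    wm: WMDesign,
    ltm: LTMDesign,
    profile: AgeGroupProfile,
    seed: int,
) -> tuple[list[ParticipantParams], pd.DataFrame]:
    """Simulate one cohort; every participant gets a fresh design permutation.

    ``wm``/``ltm`` define the session structure being administered; each
    participant's own session is regenerated from the substream
    ``[seed, participants-stream, index, stage]`` so adding participants never
    perturbs earlier ones.  Returns the latent parameters (for recovery
    studies) and a long-format response frame.
    """
    all_params: list[ParticipantParams] = []
    frames: list[pd.DataFrame] = []
    for i in range(profile.n):
        rng_param = substream(seed, STREAM_PARTICIPANTS, i, 0)
        rng_design = substream(seed, STREAM_PARTICIPANTS, i, 1)
        rng_resp = substream(seed, STREAM_PARTICIPANTS, i, 2)
        params = profile.sample_params(rng_param)
        wm_i = _generate_wm(rng_design)
        ltm_i = _generate_ltm(wm_i, rng_design)
        df = simulate_participant(params, wm_i, ltm_i, rng_resp)
        df.insert(0, "age_group", profile.name)
        df.insert(0, "participant_id", f"{profile.name}_{i + 1:03d}")
        all_params.append(params)
        frames.append(df)
    records = pd.concat(frames, ignore_index=True)
    return all_params, records[RECORD_COLUMNS]


def params_frame(
    profiles_params: dict[str, list[ParticipantParams]]
) -> pd.DataFrame:
    """Latent parameters as a tidy frame (participant_id + all fields)."""
    rows = []
    for group, plist in profiles_params.items():
        for i, p in enumerate(plist):
            rows.append({"participant_id": f"{group}_{i + 1:03d}",
                         "age_group": group, **asdict(p)})
    return pd.DataFrame(rows)
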