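"""Seeded generation of the WM study/probe design and the delayed LTM test.

The WM session presents short sequences of uniquely identified items, each in
one of six colors, and probes a single object per trial with a three-way
response (same object-same color / same object-different color / different
object).  The LTM test later re-probes studied items (intact, re-paired with
another array color, or in a novel color) mixed with brand-new lures.

All structural counts are fixed; the generator only randomizes trial order,
item identity assignment, colors, and probed positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import STREAM_DESIGN, substream

COLORS: tuple[str, ...] = ("blue", "brown", "green", "indigo", "orange", "red")
N_COLORS = 6

#: trials per set size
WM_TRIAL_COUNTS: dict[int, int] = {2: 54, 3: 36, 4: 30}
N_WM_TRIALS = 120
N_STUDIED_ITEMS = 336          # sum of S over trials
N_WM_NOVEL_OBJECTS = 40        # different-object probe identities
N_LTM_NEW_OBJECTS = 48         # brand-new LTM lure identities

N_LTM_PROBES = 144
LTM_PER_SET_SIZE = 32          # studied probes per origin set size
LTM_CELL = 8                   # swap / novel / probed-same / unprobed-same


class Condition(str, Enum):
    SAME_SAME = "SAME_SAME"
    SAME_DIFF_SWAP = "SAME_DIFF_SWAP"
    SAME_DIFF_NOVEL = "SAME_DIFF_NOVEL"
    DIFF_OBJ_ARRAYCOLOR = "DIFF_OBJ_ARRAYCOLOR"
    DIFF_OBJ_NOVELCOLOR = "DIFF_OBJ_NOVELCOLOR"
    NEW = "NEW"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Response(str, Enum):
    SS = "SS"  # same object, same color
    SD = "SD"  # same object, different color
    DO = "DO"  # different object

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: conditions whose probe object was part of a study sequence
OLD_OBJECT_CONDITIONS = frozenset(
    {Condition.SAME_SAME, Condition.SAME_DIFF_SWAP, Condition.SAME_DIFF_NOVEL}
)
#: conditions whose probe object was never studied
NEW_OBJECT_CONDITIONS = frozenset(
    {Condition.DIFF_OBJ_ARRAYCOLOR, Condition.DIFF_OBJ_NOVELCOLOR, Condition.NEW}
)

CORRECT_RESPONSE: dict[Condition, Response] = {
    Condition.SAME_SAME: Response.SS,
    Condition.SAME_DIFF_SWAP: Response.SD,
    Condition.SAME_DIFF_NOVEL: Response.SD,
    Condition.DIFF_OBJ_ARRAYCOLOR: Response.DO,
    Condition.DIFF_OBJ_NOVELCOLOR: Response.DO,
    Condition.NEW: Response.DO,
}


@dataclass(frozen=True)
class StudyItem:
    item_id: int
    color: str
    position: int  # 1-based serial position within its trial


@dataclass(frozen=True)
class WMTrial:
    trial_index: int  # 1-based presentation order
    set_size: int
    items: tuple[StudyItem, ...]
    probe_object: int
    probe_color: str
    probe_condition: Condition
    correct_response: Response

    @property
    def colors(self) -> tuple[str, ...]:
        return tuple(it.color for it in self.items)

    @property
    def item_ids(self) -> tuple[int, ...]:
        return tuple(it.item_id for it in self.items)


@dataclass(frozen=True)
class WMDesign:
    trials: tuple[WMTrial, ...]
    color_count: int = N_COLORS

    @property
    def studied_ids(self) -> set[int]:
        return {it.item_id for tr in self.trials for it in tr.items}


@dataclass(frozen=True)
class LTMProbe:
    probe_index: int  # 1-based test order
    origin: str  # "STUDIED" | "NEW"
    origin_set_size: int | None
    condition: Condition
    was_wm_probe: bool
    probe_object: int
    probe_color: str
    correct_response: Response


@dataclass(frozen=True)
class LTMDesign:
    probes: tuple[LTMProbe, ...]


def _per_set_size_conditions(set_size: int) -> list[Condition]:
    """Fixed condition multiset for one set size (thirds, halved)."""
    n = WM_TRIAL_COUNTS[set_size]
    third = n // 3
    half = third // 2
    return (
        [Condition.SAME_SAME] * third
        + [Condition.SAME_DIFF_SWAP] * half
        + [Condition.SAME_DIFF_NOVEL] * half
        + [Condition.DIFF_OBJ_ARRAYCOLOR] * half
        + [Condition.DIFF_OBJ_NOVELCOLOR] * half
    )


def generate_wm_design(seed: int) -> WMDesign:
    """Generate the 120-trial WM session for one participant.

    Trial order, item-identity assignment, within-trial colors, and probed
    positions are all driven by ``seed``; the structural counts never vary.
    """
    rng = substream(seed, STREAM_DESIGN, 0)
    return _generate_wm(rng)


def _generate_wm(rng: np.random.Generator) -> WMDesign:
    specs: list[tuple[int, Condition]] = []
    for s in sorted(WM_TRIAL_COUNTS):
        specs.extend((s, c) for c in _per_set_size_conditions(s))
    order = rng.permutation(len(specs))
    specs = [specs[i] for i in order]

    studied_ids = [int(i) for i in rng.permutation(N_STUDIED_ITEMS) + 1]
    novel_ids = [int(i) for i in rng.permutation(N_WM_NOVEL_OBJECTS) + 1 + N_STUDIED_ITEMS]
    next_item = 0
    next_novel = 0

    trials: list[WMTrial] = []
    for idx, (s, cond) in enumerate(specs, start=1):
        color_idx = rng.permutation(N_COLORS)[:s]
        colors = [COLORS[i] for i in color_idx]
        items = tuple(
            StudyItem(item_id=studied_ids[next_item + p], color=colors[p], position=p + 1)
            for p in range(s)
        )
        next_item += s
        absent = [c for c in COLORS if c not in colors]

        if cond is Condition.SAME_SAME:
            pos = int(rng.integers(s))
            probe_object, probe_color = items[pos].item_id, items[pos].color
        elif cond is Condition.SAME_DIFF_SWAP:
            pos = int(rng.integers(s))
            others = [p for p in range(s) if p != pos]
            other = others[int(rng.integers(len(others)))]
            probe_object, probe_color = items[pos].item_id, items[other].color
        elif cond is Condition.SAME_DIFF_NOVEL:
            pos = int(rng.integers(s))
            probe_object = items[pos].item_id
            probe_color = absent[int(rng.integers(len(absent)))]
        elif cond is Condition.DIFF_OBJ_ARRAYCOLOR:
            probe_object = novel_ids[next_novel]
            next_novel += 1
            probe_color = colors[int(rng.integers(s))]
        else:  # DIFF_OBJ_NOVELCOLOR
            probe_object = novel_ids[next_novel]
            next_novel += 1
            probe_color = absent[int(rng.integers(len(absent)))]

        trials.append(
            WMTrial(
                trial_index=idx,
                set_size=s,
                items=items,
                probe_object=probe_object,
                probe_color=probe_color,
                probe_condition=cond,
                correct_response=CORRECT_RESPONSE[cond],
            )
        )
    return WMDesign(trials=tuple(trials))


def generate_ltm_design(wm: WMDesign, seed: int) -> LTMDesign:
    """Generate the 144-probe LTM test matched to a WM design.

    Per origin set size: 8 re-paired (swap), 8 novel-color, 8 intact probes of
    objects that served as WM probes, 8 intact probes of never-probed objects.
    Swap/novel/unprobed-intact objects are drawn from items never used as WM
    probes, spreading probes across distinct WM trials where possible.
    """
    rng = substream(seed, STREAM_DESIGN, 1)
    return _generate_ltm(wm, rng)


def _generate_ltm(wm: WMDesign, rng: np.random.Generator) -> LTMDesign:
    by_size: dict[int, list[WMTrial]] = {s: [] for s in WM_TRIAL_COUNTS}
    for tr in wm.trials:
        by_size.setdefault(tr.set_size, []).append(tr)

    wm_probed = {
        tr.probe_object
        for tr in wm.trials
        if tr.probe_condition in OLD_OBJECT_CONDITIONS
    }
    item_trial = {it.item_id: tr for tr in wm.trials for it in tr.items}

    probes: list[LTMProbe] = []

    def _studied_probe(item_id: int, cond: Condition, was_wm_probe: bool) -> LTMProbe:
        tr = item_trial[item_id]
        own_color = next(it.color for it in tr.items if it.item_id == item_id)
        if cond is Condition.SAME_SAME:
            color = own_color
        elif cond is Condition.SAME_DIFF_SWAP:
            pool = [c for c in tr.colors if c != own_color]
            color = pool[int(rng.integers(len(pool)))]
        else:  # SAME_DIFF_NOVEL
            pool = [c for c in COLORS if c not in tr.colors]
            color = pool[int(rng.integers(len(pool)))]
        return LTMProbe(
            probe_index=0,
            origin="STUDIED",
            origin_set_size=tr.set_size,
            condition=cond,
            was_wm_probe=was_wm_probe,
            probe_object=item_id,
            probe_color=color,
            correct_response=CORRECT_RESPONSE[cond],
        )

    for s in sorted(WM_TRIAL_COUNTS):
        trials = by_size[s]
        ss_trials = [t for t in trials if t.probe_condition is Condition.SAME_SAME]
        if len(ss_trials) < LTM_CELL:
            raise ValueError(
                f"set size {s}: only {len(ss_trials)} intact-probe WM trials, need {LTM_CELL}"
            )
        pick = rng.permutation(len(ss_trials))[:LTM_CELL]
        probed_same_trials = [ss_trials[i] for i in pick]
        for tr in probed_same_trials:
            probes.append(_studied_probe(tr.probe_object, Condition.SAME_SAME, True))

        # Remaining 24 probes come from never-WM-probed items, at most one per
        # WM trial where the trial budget allows, overflowing onto used trials.
        used = {tr.trial_index for tr in probed_same_trials}
        candidates: list[int] = []
        first_pass = [t for t in trials if t.trial_index not in used]
        order = rng.permutation(len(first_pass))
        for i in order:
            tr = first_pass[i]
            free = [it.item_id for it in tr.items if it.item_id not in wm_probed]
            if free:
                candidates.append(free[int(rng.integers(len(free)))])
        need = 3 * LTM_CELL
        if len(candidates) < need:
            taken = set(candidates)
            overflow = [t for t in trials if t.trial_index in used]
            order = rng.permutation(len(overflow))
            for i in order:
                tr = overflow[i]
                free = [
                    it.item_id
                    for it in tr.items
                    if it.item_id not in wm_probed and it.item_id not in taken
                ]
                if free:
                    pickd = free[int(rng.integers(len(free)))]
                    candidates.append(pickd)
                    taken.add(pickd)
                if len(candidates) >= need:
                    break
        if len(candidates) < need:
            raise ValueError(
                f"set size {s}: only {len(candidates)} eligible unprobed items, need {need}"
            )
        chosen = [candidates[i] for i in rng.permutation(len(candidates))[:need]]
        cells = (
            [Condition.SAME_DIFF_SWAP] * LTM_CELL
            + [Condition.SAME_DIFF_NOVEL] * LTM_CELL
            + [Condition.SAME_SAME] * LTM_CELL
        )
        for item_id, cond in zip(chosen, cells):
            probes.append(_studied_probe(item_id, cond, False))

    new_ids = rng.permutation(N_LTM_NEW_OBJECTS) + 1 + N_STUDIED_ITEMS + N_WM_NOVEL_OBJECTS
    for oid in new_ids:
        probes.append(
            LTMProbe(
                probe_index=0,
                origin="NEW",
                origin_set_size=None,
                condition=Condition.NEW,
                was_wm_probe=False,
                probe_object=int(oid),
                probe_color=COLORS[int(rng.integers(N_COLORS))],
                correct_response=Response.DO,
            )
        )

    order = rng.permutation(len(probes))
    final = [
        LTMProbe(**{**asdict(probes[i]), "probe_index": rank + 1,
                    "condition": probes[i].condition,
                    "correct_response": probes[i].correct_response})
        for rank, i in enumerate(order)
    ]
    return LTMDesign(probes=tuple(final))


# ---------------------------------------------------------------------------
# validation

def validate_design(wm: WMDesign, ltm: LTMDesign | None = None) -> list[str]:
    """Check every structural invariant; return human-readable violations."""
    v: list[str] = []
    trials = wm.trials
    if len(trials) != N_WM_TRIALS:
        v.append(f"trial count: expected {N_WM_TRIALS}, got {len(trials)}")
    size_counts: dict[int, int] = {}
    cond_counts: dict[Condition, int] = {}
    studied: list[int] = []
    wm_probe_objects: set[int] = set()
    for tr in trials:
        size_counts[tr.set_size] = size_counts.get(tr.set_size, 0) + 1
        cond_counts[tr.probe_condition] = cond_counts.get(tr.probe_condition, 0) + 1
        if len(tr.items) != tr.set_size:
            v.append(f"trial {tr.trial_index}: {len(tr.items)} items != set size {tr.set_size}")
        if len(set(tr.colors)) != len(tr.items):
            v.append(f"trial {tr.trial_index}: repeated colors within trial")
        if [it.position for it in tr.items] != list(range(1, tr.set_size + 1)):
            v.append(f"trial {tr.trial_index}: bad serial positions")
        studied.extend(tr.item_ids)
        c = tr.probe_condition
        if tr.correct_response is not CORRECT_RESPONSE[c]:
            v.append(f"trial {tr.trial_index}: wrong correct_response for {c.value}")
        if c in OLD_OBJECT_CONDITIONS:
            wm_probe_objects.add(tr.probe_object)
            if tr.probe_object not in tr.item_ids:
                v.append(f"trial {tr.trial_index}: old-object probe not in array")
            else:
                own = next(it.color for it in tr.items if it.item_id == tr.probe_object)
                if c is Condition.SAME_SAME and tr.probe_color != own:
                    v.append(f"trial {tr.trial_index}: intact probe not in original color")
                if c is Condition.SAME_DIFF_SWAP and not (
                    tr.probe_color != own and tr.probe_color in tr.colors
                ):
                    v.append(f"trial {tr.trial_index}: swap probe color not another array color")
                if c is Condition.SAME_DIFF_NOVEL and tr.probe_color in tr.colors:
                    v.append(f"trial {tr.trial_index}: novel-color probe wears an array color")
        else:
            if c is Condition.DIFF_OBJ_ARRAYCOLOR and tr.probe_color not in tr.colors:
                v.append(f"trial {tr.trial_index}: array-color lure in non-array color")
            if c is Condition.DIFF_OBJ_NOVELCOLOR and tr.probe_color in tr.colors:
                v.append(f"trial {tr.trial_index}: novel-color lure in array color")

    for s, n in WM_TRIAL_COUNTS.items():
        if size_counts.get(s, 0) != n:
            v.append(f"set size {s}: expected {n} trials, got {size_counts.get(s, 0)}")
    expected_conds = {
        Condition.SAME_SAME: 40,
        Condition.SAME_DIFF_SWAP: 20,
        Condition.SAME_DIFF_NOVEL: 20,
        Condition.DIFF_OBJ_ARRAYCOLOR: 20,
        Condition.DIFF_OBJ_NOVELCOLOR: 20,
    }
    for c, n in expected_conds.items():
        if cond_counts.get(c, 0) != n:
            v.append(f"condition {c.value}: expected {n} trials, got {cond_counts.get(c, 0)}")
    if len(set(studied)) != len(studied):
        v.append("duplicated studied item id")
    if len(set(studied)) != N_STUDIED_ITEMS:
        v.append(f"studied items: expected {N_STUDIED_ITEMS}, got {len(set(studied))}")
    lure_objects = {
        tr.probe_object for tr in trials if tr.probe_condition in NEW_OBJECT_CONDITIONS
    }
    if len(lure_objects) != N_WM_NOVEL_OBJECTS:
        v.append(f"novel probe objects: expected {N_WM_NOVEL_OBJECTS}, got {len(lure_objects)}")
    if lure_objects & set(studied):
        v.append("a different-object probe id is also a studied id")

    if ltm is None:
        return v

    studied_set = set(studied)
    item_trial = {it.item_id: tr for tr in trials for it in tr.items}
    if len(ltm.probes) != N_LTM_PROBES:
        v.append(f"LTM probe count: expected {N_LTM_PROBES}, got {len(ltm.probes)}")
    new_count = 0
    cell: dict[tuple[int, Condition, bool], int] = {}
    for pr in ltm.probes:
        if pr.condition is Condition.NEW:
            new_count += 1
            if pr.probe_object in studied_set or pr.probe_object in lure_objects:
                v.append(f"LTM probe {pr.probe_index}: NEW object was seen before")
            continue
        if pr.probe_object not in studied_set:
            v.append(f"LTM probe {pr.probe_index}: studied probe object never studied")
            continue
        tr = item_trial[pr.probe_object]
        if pr.origin_set_size != tr.set_size:
            v.append(f"LTM probe {pr.probe_index}: wrong origin set size")
        own = next(it.color for it in tr.items if it.item_id == pr.probe_object)
        if pr.condition is Condition.SAME_SAME and pr.probe_color != own:
            v.append(f"LTM probe {pr.probe_index}: intact probe not in original color")
        if pr.condition is Condition.SAME_DIFF_SWAP and not (
            pr.probe_color != own and pr.probe_color in tr.colors
        ):
            v.append(f"LTM probe {pr.probe_index}: swap color not another array color")
        if pr.condition is Condition.SAME_DIFF_NOVEL and pr.probe_color in tr.colors:
            v.append(f"LTM probe {pr.probe_index}: novel color present in array")
        if pr.was_wm_probe:
            if pr.condition is not Condition.SAME_SAME:
                v.append(f"LTM probe {pr.probe_index}: was_wm_probe on non-intact probe")
            if pr.probe_object not in wm_probe_objects:
                v.append(f"LTM probe {pr.probe_index}: flagged as WM probe but never probed")
        elif pr.probe_object in wm_probe_objects:
            v.append(f"LTM probe {pr.probe_index}: WM-probed object without flag")
        key = (tr.set_size, pr.condition, pr.was_wm_probe)
        cell[key] = cell.get(key, 0) + 1
    if new_count != N_LTM_NEW_OBJECTS:
        v.append(f"LTM NEW probes: expected {N_LTM_NEW_OBJECTS}, got {new_count}")
    for s in WM_TRIAL_COUNTS:
        for cond, flag in (
            (Condition.SAME_DIFF_SWAP, False),
            (Condition.SAME_DIFF_NOVEL, False),
            (Condition.SAME_SAME, True),
            (Condition.SAME_SAME, False),
        ):
            got = cell.get((s, cond, flag), 0)
            if got != LTM_CELL:
                v.append(
                    f"LTM cell set size {s} / {cond.value} / was_wm_probe={flag}: "
                    f"expected {LTM_CELL}, got {got}"
                )
    return v


# ---------------------------------------------------------------------------
# serialization

def wm_design_frame(wm: WMDesign) -> pd.DataFrame:
    """Long frame: one row per studied item plus one probe row per trial."""
    rows = []
    for tr in wm.trials:
        for it in tr.items:
            rows.append(
                dict(
                    trial_index=tr.trial_index, set_size=tr.set_size, row_type="item",
                    position=it.position, item_id=it.item_id, color=it.color,
                    probe_condition="", correct_response="",
                )
            )
        rows.append(
            dict(
                trial_index=tr.trial_index, set_size=tr.set_size, row_type="probe",
                position=0, item_id=tr.probe_object, color=tr.probe_color,
                probe_condition=tr.probe_condition.value,
                correct_response=tr.correct_response.value,
            )
        )
    return pd.DataFrame(rows)


def ltm_design_frame(ltm: LTMDesign) -> pd.DataFrame:
    rows = [
        dict(
            probe_index=pr.probe_index, origin=pr.origin,
            origin_set_size="" if pr.origin_set_size is None else pr.origin_set_size,
            condition=pr.condition.value, was_wm_probe=pr.was_wm_probe,
            probe_object=pr.probe_object, probe_color=pr.probe_color,
            correct_response=pr.correct_response.value,
        )
        for pr in ltm.probes
    ]
    return pd.DataFrame(rows)


def design_to_json(wm: WMDesign, ltm: LTMDesign) -> str:
    payload = {
        "color_count": wm.color_count,
        "wm_trials": [
            {
                "trial_index": tr.trial_index,
                "set_size": tr.set_size,
                "items": [asdict(it) for it in tr.items],
                "probe_object": tr.probe_object,
                "probe_color": tr.probe_color,
                "probe_condition": tr.probe_condition.value,
                "correct_response": tr.correct_response.value,
            }
            for tr in wm.trials
        ],
        "ltm_probes": [
            {
                "probe_index": pr.probe_index,
                "origin": pr.origin,
                "origin_set_size": pr.origin_set_size,
                "condition": pr.condition.value,
                "was_wm_probe": pr.was_wm_probe,
                "probe_object": pr.probe_object,
                "probe_color": pr.probe_color,
                "correct_response": pr.correct_response.value,
            }
            for pr in ltm.probes
        ],
    }
    return json.dumps(payload, indent=1)


def relabel_colors(wm: WMDesign, mapping: dict[str, str]) -> WMDesign:
    """Apply a color permutation to a WM design (used for invariance checks)."""
    if sorted(mapping) != sorted(COLORS) or sorted(mapping.values()) != sorted(COLORS):
        raise ValueError("mapping must be a permutation of the six colors")
    trials = []
    for tr in wm.trials:
        items = tuple(
            StudyItem(it.item_id, mapping[it.color], it.position) for it in tr.items
        )
        trials.append(
            WMTrial(
                trial_index=tr.trial_index, set_size=tr.set_size, items=items,
                probe_object=tr.probe_object, probe_color=mapping[tr.probe_color],
                probe_condition=tr.probe_condition, correct_response=tr.correct_response,
            )
        )
    return WMDesign(trials=tuple(trials), color_count=wm.color_count)
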