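"""Novel-object-recognition scoring and visit-epoch construction.

The discrimination index is

    DI = (time on novel - time on familiar) / total exploration time

so DI is in [-1, 1], 0 means no preference and positive values indicate
novelty preference.  Because several neural estimators are sensitive to
the analysis window length, visits are concatenated until the
accumulated time reaches a 5 s target, truncating the final contributing
visit at the threshold.  Familiarization sessions are valid only when
total object exploration reaches 10 s; memory acquisition contrasts the
first versus the last 5 s of accumulated visit time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

from .core import Epoch, EpochSet

__all__ = [
    "VisitRecord",
    "MemoryScore",
    "discrimination_index",
    "concatenate_visits",
    "split_early_late",
    "label_visit_epochs",
    "passes_baseline_screen",
    "visits_from_events",
]

TARGET_EPOCH_S = 5.0
MIN_FAMILIARIZATION_S = 10.0
BASELINE_DI_CUTOFF = 0.2


@dataclass(frozen=True)
class VisitRecord:
    """One timestamped object visit."""

    object: str  # novel / familiar (or left / right during familiarization)
    start_s: float
    end_s: float
    phase: str = ""  # familiarization / STM / LTM

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError("visit must have positive duration")

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


def _check_sorted_nonoverlap(visits: Sequence[VisitRecord]) -> None:
    for a, b in zip(visits, visits[1:]):
        if b.start_s < a.start_s:
            raise ValueError("visits must be ordered in time")
        if b.start_s < a.end_s:
            raise ValueError("visits overlap")


def visits_from_events(events: pd.DataFrame, phase: str = "") -> list[VisitRecord]:
    """Visit records from an event table with onset_s/offset_s/label columns."""
    return [
        VisitRecord(object=str(r.label), start_s=float(r.onset_s), end_s=float(r.offset_s), phase=phase)
        for r in events.itertuples()
    ]


@dataclass
class MemoryScore:
    di: float
    total_exploration_s: float
    n_visits: dict[str, int]
    time_per_object: dict[str, float]
    valid: bool


def discrimination_index(
    visits: Sequence[VisitRecord],
    *,
    novel_label: str = "novel",
    familiar_label: str = "familiar",
) -> MemoryScore:
    """Discrimination index of a test session.

    Requires at least one visit to each object class and non-zero total
    exploration.
    """
    _check_sorted_nonoverlap(sorted(visits, key=lambda v: v.start_s))
    t_nov = sum(v.duration for v in visits if v.object == novel_label)
    t_fam = sum(v.duration for v in visits if v.object == familiar_label)
    n_nov = sum(1 for v in visits if v.object == novel_label)
    n_fam = sum(1 for v in visits if v.object == familiar_label)
    if n_nov == 0 or n_fam == 0:
        raise ValueError("DI requires at least one visit to each object class")
    total = t_nov + t_fam
    if total <= 0:
        raise ValueError("zero total exploration time")
    return MemoryScore(
        di=(t_nov - t_fam) / total,
        total_exploration_s=total,
        n_visits={novel_label: n_nov, familiar_label: n_fam},
        time_per_object={novel_label: t_nov, familiar_label: t_fam},
        valid=total >= MIN_FAMILIARIZATION_S,
    )


def concatenate_visits(
    visits: Sequence[VisitRecord],
    target_s: float = TARGET_EPOCH_S,
    order: Literal["first", "last"] = "first",
    *,
    truncate: bool = True,
    label: str | None = None,
) -> tuple[EpochSet, dict]:
    """Accumulate visits until the total reaches ``target_s``.

    ``order="first"`` accumulates from the start of the session,
    ``order="last"`` backward from the final visit.  With ``truncate``
    (default) the last contributing visit is cut so the accumulated time
    equals ``target_s`` exactly (its tail for order="first", its head for
    order="last").  If less than ``target_s`` is available all visits are
    returned and the result is flagged ``short``.
    """
    vs = sorted(visits, key=lambda v: v.start_s)
    _check_sorted_nonoverlap(vs)
    if order == "last":
        seq: Iterable[VisitRecord] = reversed(vs)
    elif order == "first":
        seq = vs
    else:
        raise ValueError("order must be 'first' or 'last'")
    picked: list[Epoch] = []
    acc = 0.0
    n_used = 0
    for v in seq:
        lab = label or v.object
        remaining = target_s - acc
        if remaining <= 1e-12:
            break
        n_used += 1
        if v.duration <= remaining + 1e-12 or not truncate:
            picked.append(Epoch(v.start_s, v.end_s, lab))
            acc += v.duration
        elif order == "first":
            picked.append(Epoch(v.start_s, v.start_s + remaining, lab))
            acc = target_s
        else:
            picked.append(Epoch(v.end_s - remaining, v.end_s, lab))
            acc = target_s
    short = acc < target_s - 1e-12
    info = {"accumulated_s": acc, "n_visits_used": n_used, "short": short, "order": order}
    return EpochSet(sorted(picked, key=lambda e: e.start)), info


def split_early_late(
    familiarization_visits: Sequence[VisitRecord],
    target_s: float = TARGET_EPOCH_S,
    *,
    min_total_s: float = MIN_FAMILIARIZATION_S,
) -> tuple[EpochSet, EpochSet, dict]:
    """Early vs late accumulated visit time during familiarization.

    Objects are pooled regardless of arm.  Early concatenates ``target_s``
    of visit time from the session start, late concatenates backward from
    the final visit; with total exploration >= 2 * target_s the two
    partitions are disjoint.  Familiarization with less than
    ``min_total_s`` of exploration is invalid and rejected.
    """
    vs = sorted(familiarization_visits, key=lambda v: v.start_s)
    total = sum(v.duration for v in vs)
    if total < min_total_s - 1e-12:
        raise ValueError(
            f"invalid familiarization: {total:g} s of exploration, need >= {min_total_s:g} s"
        )
    early, info_e = concatenate_visits(vs, target_s, order="first", label="early")
    late, info_l = concatenate_visits(vs, target_s, order="last", label="late")
    return early, late, {"early": info_e, "late": info_l, "total_s": total}


def label_visit_epochs(
    visits: Sequence[VisitRecord],
    phase: Literal["STM", "LTM"],
    target_s: float = TARGET_EPOCH_S,
    *,
    objects: tuple[str, str] = ("novel", "familiar"),
) -> tuple[EpochSet, dict]:
    """One concatenated ``target_s`` epoch per object class in a test.

    Epochs are tagged ``{phase}:{object}``; a missing object class is
    omitted with a warning, an under-filled class is flagged short.
    """
    if phase not in ("STM", "LTM"):
        raise ValueError("phase must be 'STM' or 'LTM'")
    all_eps: list[Epoch] = []
    info: dict = {}
    for obj in objects:
        ov = [v for v in visits if v.object == obj]
        if not ov:
            warnings.warn(f"no {obj!r} visits in {phase}; epoch omitted", stacklevel=2)
            continue
        eps, inf = concatenate_visits(ov, target_s, order="first", label=f"{phase}:{obj}")
        all_eps.extend(eps)
        info[obj] = inf
    return EpochSet(sorted(all_eps, key=lambda e: e.start)), info


def passes_baseline_screen(baseline_score: MemoryScore, cutoff: float = BASELINE_DI_CUTOFF) -> bool:
    """Inclusion screen: baseline discrimination index above ``cutoff``."""
    return baseline_score.di > cutoff
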