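"""Percent-rescue scoring, rescue categories, dysregulation scores and
shared-rescue set analysis.

Percent rescue of a unit (gene or skipped-exon event) in one patient is

    100 * (pre - post) / (pre - control_reference)

on the PSI scale for events and on the log2FC-vs-control scale for genes
(so the gene control reference is 0). A value of 100 means the defect moved
exactly to the control level; above 100 it overshot; negative values mean it
moved away from controls. Categories:

    rescued      10 < r < 110
    overrescued  r >= 110
    misrescued   r < -10
    unchanged    -10 <= r <= 10

Dysregulation scores summarize a subject's global defect as the mean
absolute deviation from controls over the units significant pre-training;
the post score reuses exactly the same unit set.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import ValidationError

logger = logging.getLogger("dmrescue")

CATEGORIES = ("rescued", "overrescued", "misrescued", "unchanged")

#: denominator guard: |pre - control_ref| below this is undefined rescue
DENOM_EPS = 1e-12


class UndefinedRescueError(ValueError):
    """pre equals the control reference; percent rescue is undefined."""


def percent_rescue(pre_value: float, post_value: float,
                   control_ref: float, eps: float = DENOM_EPS) -> float:
    """100 * (pre - post) / (pre - control_ref).

    Raises :class:`UndefinedRescueError` when the pre-training deviation from
    the control reference is below ``eps`` (the unit was not dysregulated, so
    'rescue' has no meaning).
    """
    denom = pre_value - control_ref
    if abs(denom) < eps:
        raise UndefinedRescueError(
            f"pre value {pre_value!r} equals control reference {control_ref!r}")
    return 100.0 * (pre_value - post_value) / denom


def classify_rescue(percent: float) -> str:
    """Map a finite percent-rescue value to its category (see module docs)."""
    if not math.isfinite(percent):
        raise ValidationError(f"percent rescue must be finite, got {percent!r}")
    if percent >= 110.0:
        return "overrescued"
    if percent > 10.0:
        return "rescued"
    if percent < -10.0:
        return "misrescued"
    return "unchanged"


def rescue_records(pre: Mapping[str, float], post: Mapping[str, float],
                   control_ref: Mapping[str, float] | float,
                   significant: Iterable[str],
                   subject_id: str, modality: str) -> pd.DataFrame:
    """Build per-unit rescue records for one subject.

    ``pre``/``post`` map unit_id to the subject's pre/post values (PSI for
    events, log2FC-vs-control for genes); ``control_ref`` is the per-unit
    control reference or a scalar (0 for genes). Units whose pre value is
    missing or whose denominator is below the guard are excluded; exclusion
    counts are logged. Returns columns: unit_id, subject_id, modality,
    percent_rescue, category.
    """
    if modality not in ("gene", "event"):
        raise ValidationError(f"modality must be 'gene' or 'event', got {modality!r}")
    rows = []
    n_undefined = n_missing = 0
    for unit in significant:
        pre_v = pre.get(unit)
        post_v = post.get(unit)
        if pre_v is None or post_v is None or not (
                math.isfinite(pre_v) and math.isfinite(post_v)):
            n_missing += 1
            continue
        ref = control_ref if isinstance(control_ref, (int, float)) \
            else control_ref.get(unit)
        if ref is None or not math.isfinite(ref):
            n_missing += 1
            continue
        try:
            r = percent_rescue(pre_v, post_v, float(ref))
        except UndefinedRescueError:
            n_undefined += 1
            continue
        rows.append((unit, subject_id, modality, r, classify_rescue(r)))
    if n_undefined or n_missing:
        logger.info("rescue_records[%s/%s]: excluded %d undefined-denominator "
                    "and %d missing-value unit(s)", subject_id, modality,
                    n_undefined, n_missing)
    df = pd.DataFrame(rows, columns=["unit_id", "subject_id", "modality",
                                     "percent_rescue", "category"])
    df.attrs["n_undefined"] = n_undefined
    df.attrs["n_missing"] = n_missing
    return df


def dysregulation_score(deviations: Sequence[float]) -> float:
    """Mean absolute deviation from controls over a fixed unit set."""
    arr = np.asarray(list(deviations), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValidationError("dysregulation score undefined for an empty unit set")
    return float(np.mean(np.abs(arr)))


def percent_units_rescued(records: pd.DataFrame,
                          include_overrescued: bool = False) -> float:
    """Percentage of a subject's defined units in the rescued category.

    Overrescued units count only with ``include_overrescued=True`` (the
    categories are reported separately; the splicing-vs-clinical comparison
    optionally pools them).
    """
    n = len(records)
    if n == 0:
        raise ValidationError("no defined rescue records")
    cats = {"rescued", "overrescued"} if include_overrescued else {"rescued"}
    return 100.0 * records["category"].isin(cats).sum() / n


def mean_percent_rescue(records: pd.DataFrame) -> float:
    """Average percent rescue over a subject's defined units."""
    if len(records) == 0:
        raise ValidationError("no defined rescue records")
    return float(records["percent_rescue"].mean())


# ---------------------------------------------------------------------------
# shared-rescue overlaps (upset semantics)
# ---------------------------------------------------------------------------

def shared_rescue_overlaps(rescued_sets: Mapping[str, set]) -> dict:
    """Exact set-intersection tabulation across subjects.

    For each subject subset that owns at least one event, count the events
    rescued in exactly that subset (upset semantics). Returns a dict with:

    * ``exact`` — DataFrame (combo: '+'.joined sorted subject ids, k, count)
    * ``per_k`` — events rescued in exactly k subjects: total events and the
      number of distinct populated combos
    * ``unique`` — per subject: set size, events unique to that subject, and
      the unique percentage
    """
    subjects = sorted(rescued_sets)
    if len(subjects) < 2:
        raise ValidationError("overlap analysis needs >= 2 subjects")
    membership: dict[str, tuple] = {}
    for s in subjects:
        for ev in rescued_sets[s]:
            membership.setdefault(ev, ())
    for ev in membership:
        membership[ev] = tuple(s for s in subjects if ev in rescued_sets[s])
    combo_counts: dict[tuple, int] = {}
    for combo in membership.values():
        combo_counts[combo] = combo_counts.get(combo, 0) + 1
    exact = pd.DataFrame(
        [{"combo": "+".join(c), "k": len(c), "exact_count": n}
         for c, n in sorted(combo_counts.items())])
    per_k = (exact.groupby("k")
             .agg(total_events=("exact_count", "sum"),
                  n_combos=("exact_count", "size"))
             .reset_index()) if len(exact) else pd.DataFrame(
        columns=["k", "total_events", "n_combos"])
    uniq_rows = []
    for s in subjects:
        size = len(rescued_sets[s])
        unique = combo_counts.get((s,), 0)
        uniq_rows.append({"subject_id": s, "n_rescued": size,
                          "n_unique": unique,
                          "pct_unique": 100.0 * unique / size if size else np.nan})
    return {"exact": exact, "per_k": per_k, "unique": pd.DataFrame(uniq_rows)}


def shared_between_any_k(overlaps: dict, k: int) -> int:
    """Total events rescued in exactly k subjects (0 when none)."""
    per_k = overlaps["per_k"]
    row = per_k.loc[per_k["k"] == k, "total_events"]
    return int(row.iloc[0]) if len(row) else 0


# ---------------------------------------------------------------------------
# panel classification
# ---------------------------------------------------------------------------

PANEL_STATES = ("no_reads", "not_significant", "rescued", "not_rescued")


def panel_classify(panel: Sequence[str],
                   records: pd.DataFrame,
                   significant: set[str],
                   pre_support_ok: Mapping[str, bool],
                   post_support_ok: Mapping[str, bool]) -> pd.Series:
    """Classify a biomarker event panel for one subject.

    State per panel event: ``no_reads`` if the event is absent from the PSI
    universe or lacks read support pre or post; ``not_significant`` if not
    significantly misspliced pre-training; otherwise ``rescued`` when its
    category is rescued or overrescued (partial or full rescue), else
    ``not_rescued``.
    """
    by_unit = records.set_index("unit_id") if len(records) else pd.DataFrame()
    states = {}
    for ev in panel:
        if ev not in pre_support_ok:
            logger.warning("panel_classify: event %r absent from PSI universe", ev)
            states[ev] = "no_reads"
            continue
        if not (pre_support_ok.get(ev, False) and post_support_ok.get(ev, False)):
            states[ev] = "no_reads"
            continue
        if ev not in significant:
            states[ev] = "not_significant"
            continue
        if len(by_unit) and ev in by_unit.index:
            cat = by_unit.loc[ev, "category"]
            states[ev] = "rescued" if cat in ("rescued", "overrescued") \
                else "not_rescued"
        else:
            # significant but rescue undefined (denominator guard)
            states[ev] = "not_significant"
    return pd.Series(states, name="state")
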