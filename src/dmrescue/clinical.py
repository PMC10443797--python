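"""Clinical change metrics and molecular-clinical correlation.

Clinical tests are summarized per subject as percent change,
100 * (post - pre) / pre, and screened against the minimal detectable
change, MDC = 1.96 * SEMT * sqrt(2), where SEMT (standard error of
measurement) derives from the cohort's baseline SD and the test's
test-retest ICC. Two SEMT conventions circulate: the standard psychometric
form SD * sqrt(1 - ICC) (the default here) and a linear form SD * (1 - ICC);
both are provided.

Molecular-clinical association uses Spearman correlation (average-rank
transform, two-sided t approximation) and, to control for the age gap
between patients and controls, a first-order partial Spearman correlation

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) (1 - r_yz^2))

computed on ranks, with a t approximation on n - 3 degrees of freedom.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import ClinicalRaw, ValidationError

logger = logging.getLogger("dmrescue")

#: the four 1-RM strength exercises averaged into the clinical outcome
RM_TESTS = ("leg_extension", "leg_press", "hip_abduction", "squat")


class DegenerateCorrelationError(ValueError):
    """Correlation undefined (zero rank variance or perfectly confounded)."""


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    controlled_for: str | None = None


# ---------------------------------------------------------------------------
# change metrics
# ---------------------------------------------------------------------------

def percent_change(pre: float, post: float) -> float:
    """100 * (post - pre) / pre."""
    if pre == 0:
        raise ValidationError("percent change undefined for pre value 0")
    return 100.0 * (post - pre) / pre


def semt(sd_baseline: float, icc: float, variant: str = "sqrt") -> float:
    """Standard error of measurement from baseline SD and ICC.

    variant='sqrt': SD * sqrt(1 - ICC) (standard); variant='linear':
    SD * (1 - ICC).
    """
    if sd_baseline < 0:
        raise ValidationError("sd_baseline must be >= 0")
    if not 0 <= icc <= 1:
        raise ValidationError(f"ICC must be in [0,1], got {icc}")
    if variant == "sqrt":
        return sd_baseline * math.sqrt(1.0 - icc)
    if variant == "linear":
        return sd_baseline * (1.0 - icc)
    raise ValidationError(f"variant must be 'sqrt' or 'linear', got {variant!r}")


def mdc(semt_value: float) -> float:
    """Minimal detectable change: 1.96 * SEMT * sqrt(2)."""
    if semt_value < 0:
        raise ValidationError("SEMT must be >= 0")
    return 1.96 * semt_value * math.sqrt(2.0)


def meaningful_change(pre: float, post: float, mdc_value: float) -> bool:
    """True iff the raw-unit change strictly exceeds the MDC."""
    return abs(post - pre) > mdc_value


def build_clinical_table(rows: Sequence[ClinicalRaw],
                         icc_by_test: Mapping[str, float] | None = None,
                         semt_variant: str = "sqrt") -> pd.DataFrame:
    """Per subject per test: pre, post, percent change, SEMT, MDC, meaningful.

    SEMT uses the SD of the cohort's pre values per test; tests without an
    ICC get NaN SEMT/MDC and a missing meaningful flag.
    """
    df = pd.DataFrame([{"subject_id": r.subject_id, "test_name": r.test_name,
                        "pre": r.pre_value, "post": r.post_value}
                       for r in rows])
    if df.empty:
        raise ValidationError("no clinical rows")
    if df.duplicated(["subject_id", "test_name"]).any():
        raise ValidationError("duplicate (subject, test) clinical rows")
    df["percent_change"] = [percent_change(p, q)
                            for p, q in zip(df["pre"], df["post"])]
    sd_baseline = df.groupby("test_name")["pre"].std(ddof=1)
    semt_vals, mdc_vals, meaningful = [], [], []
    for _, r in df.iterrows():
        icc = (icc_by_test or {}).get(r["test_name"])
        if icc is None or np.isnan(sd_baseline[r["test_name"]]):
            semt_vals.append(np.nan)
            mdc_vals.append(np.nan)
            meaningful.append(pd.NA)
        else:
            s = semt(float(sd_baseline[r["test_name"]]), icc, semt_variant)
            m = mdc(s)
            semt_vals.append(s)
            mdc_vals.append(m)
            meaningful.append(meaningful_change(r["pre"], r["post"], m))
    df["semt"] = semt_vals
    df["mdc"] = mdc_vals
    df["meaningful"] = meaningful
    return df


def average_1rm_change(percent_changes: Mapping[str, float],
                       tests: Sequence[str] = RM_TESTS) -> float:
    """Mean percent change across the configured 1-RM tests."""
    missing = [t for t in tests if t not in percent_changes]
    if missing:
        raise ValidationError(f"missing 1-RM test(s): {missing}")
    return float(np.mean([percent_changes[t] for t in tests]))


def per_subject_1rm_change(clin_table: pd.DataFrame,
                           tests: Sequence[str] = RM_TESTS) -> pd.Series:
    """Average 1-RM percent change per subject from a clinical table."""
    out = {}
    for subj, grp in clin_table.groupby("subject_id"):
        changes = dict(zip(grp["test_name"], grp["percent_change"]))
        out[subj] = average_1rm_change(changes, tests)
    return pd.Series(out).sort_index()


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def _ranks(x: Sequence[float]) -> np.ndarray:
    return stats.rankdata(np.asarray(x, dtype=float), method="average")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0:
        raise DegenerateCorrelationError("zero variance in ranks")
    return float(a @ b) / denom


def _t_p_value(rho: float, df: int) -> float:
    if df <= 0:
        return float("nan")
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt(df / (1.0 - rho * rho))
    return 2.0 * float(stats.t.sf(abs(t), df))


def spearman(x: Sequence[float], y: Sequence[float],
             p_mode: str = "t") -> CorrelationResult:
    """Spearman correlation: Pearson on average ranks.

    p via the two-sided t approximation with n-2 df, or exact enumeration of
    all permutations for ``p_mode='permutation'`` (n <= 10).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValidationError("spearman needs n >= 3")
    rx, ry = _ranks(x), _ranks(y)
    rho = _pearson(rx, ry)
    if p_mode == "t":
        p = _t_p_value(rho, n - 2)
    elif p_mode == "permutation":
        if n > 10:
            raise ValidationError("exact permutation p limited to n <= 10")
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_pearson(rx, np.asarray(perm))) >= abs(rho) - 1e-12:
                count += 1
        p = count / total
    else:
        raise ValidationError(f"unknown p_mode {p_mode!r}")
    return CorrelationResult(rho, p, n)


def partial_spearman(x: Sequence[float], y: Sequence[float],
                     z: Sequence[float]) -> CorrelationResult:
    """First-order partial Spearman correlation of x and y controlling z."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape):
        raise ValidationError("x, y, z must have equal length")
    n = len(x)
    if n < 4:
        raise ValidationError("partial spearman needs n >= 4")
    rx, ry, rz = _ranks(x), _ranks(y), _ranks(z)
    if np.all(rz == rz[0]):
        raise DegenerateCorrelationError("control variable has zero variance")
    r_xy = _pearson(rx, ry)
    r_xz = _pearson(rx, rz)
    r_yz = _pearson(ry, rz)
    if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
        raise DegenerateCorrelationError(
            "control variable perfectly correlated with an input")
    rho = (r_xy - r_xz * r_yz) / math.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))
    rho = min(1.0, max(-1.0, rho))
    return CorrelationResult(rho, _t_p_value(rho, n - 3), n,
                             controlled_for="z")


def correlate_rescue_with_clinical(
        pct_rescued: Mapping[str, float],
        clinical_change: Mapping[str, float],
        ages: Mapping[str, float] | None = None) -> dict[str, CorrelationResult]:
    """Spearman (and age-controlled partial Spearman) of %units rescued vs
    clinical improvement over the subjects present in both inputs."""
    subjects = sorted(set(pct_rescued) & set(clinical_change))
    if len(subjects) < 4:
        raise ValidationError(
            f"need >= 4 subjects with both metrics, got {len(subjects)}")
    x = [pct_rescued[s] for s in subjects]
    y = [clinical_change[s] for s in subjects]
    out = {"spearman": spearman(x, y)}
    if ages is not None:
        with_age = [s for s in subjects if s in ages]
        if len(with_age) < 4:
            logger.warning("correlate_rescue_with_clinical: fewer than 4 "
                           "subjects with ages; partial correlation omitted")
        else:
            try:
                res = partial_spearman([pct_rescued[s] for s in with_age],
                                       [clinical_change[s] for s in with_age],
                                       [ages[s] for s in with_age])
            except DegenerateCorrelationError as exc:
                logger.warning("age-controlled correlation omitted: %s", exc)
            else:
                out["partial_age"] = CorrelationResult(
                    res.rho, res.p_value, res.n, controlled_for="age")
    return out


# ---------------------------------------------------------------------------
# grouped descending overlap
# ---------------------------------------------------------------------------

def grouped_descending_overlap(
        subjects_ordered: Sequence[str],
        rescued_gene_sets: Mapping[str, set]) -> dict:
    """Cumulative intersection of rescued-gene sets in clinical order.

    Intersect the top subject's set with the next, then the next, until the
    running intersection is empty. ``steps`` holds the intersections of the
    top 2, top 3, ... subjects; ``terminal`` is the last non-empty running
    set (which may be the top subject's own set, depth 1) and ``depth`` the
    number of subjects it spans (0 when the top set is already empty).
    """
    steps: list[set] = []
    current: set | None = None
    terminal: set = set()
    depth = 0
    for i, subj in enumerate(subjects_ordered):
        s = set(rescued_gene_sets.get(subj, set()))
        current = s if current is None else current & s
        if i > 0:
            steps.append(set(current))
        if current:
            terminal, depth = set(current), i + 1
        else:
            break
    return {"steps": steps, "terminal": terminal, "depth": depth}
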