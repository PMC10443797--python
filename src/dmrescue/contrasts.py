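"""Per-individual and grouped contrasts versus controls.

The pipeline's downstream statistics consume effect/p/FDR tables. For real
data those tables come from dedicated count-model and splicing engines and
are read unchanged (``method="external"``). For the synthetic path this
module provides documented naive estimators: length-normalized PSI, a
CPM-or-median-ratio log2 fold change, and a Welch/z + Benjamini-Hochberg
significance surrogate. An individual patient contributes a single pre (or
post) sample, so individual-vs-controls significance borrows the control
group's dispersion: the patient value is z-scored against the control mean
and SD.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_model import ContrastTable, CountMatrix, PsiMatrix, ValidationError

logger = logging.getLogger("dmrescue")


@dataclass(frozen=True)
class Thresholds:
    """Significance cutoffs; all comparisons downstream are strict.

    Genes pass with |log2FC| > lfc_min and p < deg_p_max; events with
    |dPSI| > dpsi_min, FDR < splice_fdr_max and, when set, p < splice_p_max.
    """

    lfc_min: float
    deg_p_max: float
    dpsi_min: float
    splice_fdr_max: float
    splice_p_max: float | None = None
    min_gene_count: int = 10
    min_event_reads: int = 5

    def __post_init__(self) -> None:
        for name in ("lfc_min", "deg_p_max", "dpsi_min", "splice_fdr_max"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name} must be positive")
        if self.splice_p_max is not None and self.splice_p_max <= 0:
            raise ValidationError("splice_p_max must be positive when set")


#: cutoffs of the strength-training and (reanalyzed) cycling-training studies
PRESETS: dict[str, Thresholds] = {
    "strength": Thresholds(lfc_min=2.0, deg_p_max=0.05, dpsi_min=0.2,
                           splice_fdr_max=0.05),
    "cycling": Thresholds(lfc_min=1.5, deg_p_max=0.005, dpsi_min=0.05,
                          splice_fdr_max=0.05, splice_p_max=0.0002),
}


def get_thresholds(preset: str, **overrides) -> Thresholds:
    if preset not in PRESETS:
        raise ValidationError(f"unknown preset {preset!r}; choose from {list(PRESETS)}")
    th = PRESETS[preset]
    return replace(th, **overrides) if overrides else th


# ---------------------------------------------------------------------------
# naive estimators (synthetic path)
# ---------------------------------------------------------------------------

def estimate_psi(inclusion_reads: float, skipping_reads: float,
                 inc_eff_len: float, skip_eff_len: float) -> float:
    """Length-normalized percent spliced in.

    PSI = (I/lI) / (I/lI + S/lS); NaN (missing, not 0) when no reads at all.
    """
    if inc_eff_len <= 0 or skip_eff_len <= 0:
        raise ValidationError("effective lengths must be > 0")
    if inclusion_reads < 0 or skipping_reads < 0:
        raise ValidationError("read counts must be >= 0")
    if inclusion_reads + skipping_reads == 0:
        return float("nan")
    inc = inclusion_reads / inc_eff_len
    skp = skipping_reads / skip_eff_len
    return inc / (inc + skp)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million per sample."""
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValidationError("sample with zero total counts")
    return counts / totals * 1e6


def median_ratio_norm(counts: pd.DataFrame) -> pd.DataFrame:
    """Median-of-ratios normalized counts (composition-robust size factors).

    Size factor per sample = median over reference genes of
    count / geometric-mean(count across samples); reference genes are those
    with positive counts in every sample. Falls back to CPM scaling if no
    such gene exists.
    """
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        return cpm(counts)
    ref = counts.loc[positive].to_numpy(dtype=float)
    log_geo = np.mean(np.log(ref), axis=1)
    factors = np.exp(np.median(np.log(ref) - log_geo[:, None], axis=0))
    return counts / factors


_NORMALIZERS = {"cpm": cpm, "median_ratio": median_ratio_norm}


def normalized_log_expression(counts: CountMatrix | pd.DataFrame,
                              pseudocount: float = 0.5,
                              normalization: str = "cpm") -> pd.DataFrame:
    """log2(normalized count + pseudocount) per gene per sample."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if normalization not in _NORMALIZERS:
        raise ValidationError(f"unknown normalization {normalization!r}")
    return np.log2(_NORMALIZERS[normalization](df) + pseudocount)


def estimate_log2fc(counts: CountMatrix | pd.DataFrame,
                    samples_a: list[str], samples_b: list[str],
                    pseudocount: float = 0.5,
                    contrast_label: str = "a_vs_b",
                    normalization: str = "cpm") -> ContrastTable:
    """Naive log2 fold change of group a over group b on normalized counts.

    effect = log2((mean_a + pseudocount) / (mean_b + pseudocount)); p and FDR
    are left NaN for :func:`attach_significance` to fill.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if not samples_a or not samples_b:
        raise ValidationError("both groups must contain at least one sample")
    for s in list(samples_a) + list(samples_b):
        if s not in df.columns:
            raise ValidationError(f"sample {s!r} not in count matrix")
    norm = _NORMALIZERS[normalization](df)
    mean_a = norm[list(samples_a)].mean(axis=1)
    mean_b = norm[list(samples_b)].mean(axis=1)
    effect = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    table = pd.DataFrame({
        "unit_id": df.index, "effect": effect.to_numpy(),
        "p_value": np.nan, "fdr": np.nan, "contrast_label": contrast_label,
    })
    return ContrastTable(table.reset_index(drop=True))


def delta_psi_contrast(psi: PsiMatrix | pd.DataFrame,
                       samples_a: list[str], samples_b: list[str],
                       contrast_label: str = "a_vs_b") -> ContrastTable:
    """Mean PSI difference (group a minus group b) per event; NaN-aware."""
    df = psi.psi if isinstance(psi, PsiMatrix) else psi
    if not samples_a or not samples_b:
        raise ValidationError("both groups must contain at least one sample")
    effect = df[list(samples_a)].mean(axis=1) - df[list(samples_b)].mean(axis=1)
    table = pd.DataFrame({
        "unit_id": df.index, "effect": effect.to_numpy(),
        "p_value": np.nan, "fdr": np.nan, "contrast_label": contrast_label,
    })
    return ContrastTable(table.reset_index(drop=True))


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------

def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (NaN-preserving)."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def _nanvar_safe(x: np.ndarray) -> np.ndarray:
    """Row-wise sample variance (ddof=1); NaN where fewer than 2 values."""
    n = np.sum(~np.isnan(x), axis=1)
    out = np.full(x.shape[0], np.nan)
    ok = n >= 2
    if ok.any():
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[ok] = np.nanvar(x[ok], axis=1, ddof=1)
    return out


def attach_significance(table: ContrastTable,
                        values_a: pd.DataFrame | None = None,
                        values_b: pd.DataFrame | None = None,
                        method: str = "external",
                        sd_floor: float = 0.0) -> ContrastTable:
    """Fill p and FDR columns of a contrast table.

    ``external``: the table must already carry p/fdr and passes through
    unchanged. ``welch_bh``: two-sided Welch t per unit on the per-sample
    values (group a vs group b), or — when group a is a single sample — a
    z-score of that value against the control mean/SD; BH correction across
    units. ``sd_floor`` bounds the control-side SD away from zero; with
    sd_floor=0, zero-variance units are untestable and excluded with a
    warning.
    """
    if method == "external":
        t = table.table
        if t["p_value"].isna().any() or t["fdr"].isna().any():
            raise ValidationError("method='external' requires p and fdr present")
        return table
    if method != "welch_bh":
        raise ValidationError(f"unknown significance method {method!r}")
    if values_a is None or values_b is None:
        raise ValidationError("welch_bh requires per-sample values for both groups")
    t = table.table.copy()
    a = values_a.reindex(t["unit_id"]).to_numpy(dtype=float)
    b = values_b.reindex(t["unit_id"]).to_numpy(dtype=float)
    nb = np.sum(~np.isnan(b), axis=1)
    mb = np.nanmean(b, axis=1)
    vb = _nanvar_safe(b)
    vb = np.maximum(vb, sd_floor ** 2)
    na = np.sum(~np.isnan(a), axis=1)
    p = np.full(len(t), np.nan)
    untestable = np.zeros(len(t), dtype=bool)
    single = na == 1
    if a.shape[1] == 1 or single.any():
        xa = np.nanmean(a, axis=1)
        sdb = np.sqrt(vb)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (xa - mb) / sdb
        pz = 2.0 * stats.norm.sf(np.abs(z))
        use = single & (nb >= 2)
        p[use & (sdb > 0)] = pz[use & (sdb > 0)]
        untestable |= use & (sdb == 0)
    multi = na >= 2
    if multi.any():
        ma = np.nanmean(a, axis=1)
        va = _nanvar_safe(a)
        va = np.maximum(va, sd_floor ** 2)
        se2 = va / np.maximum(na, 1) + vb / np.maximum(nb, 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = (ma - mb) / np.sqrt(se2)
            df = se2 ** 2 / (
                (va / na) ** 2 / np.maximum(na - 1, 1)
                + (vb / nb) ** 2 / np.maximum(nb - 1, 1))
        pt = 2.0 * stats.t.sf(np.abs(tstat), df)
        ok = multi & (nb >= 2) & (se2 > 0)
        p[ok] = pt[ok]
        untestable |= multi & (se2 == 0)
    if untestable.any():
        bad = t.loc[untestable, "unit_id"].tolist()
        logger.warning("attach_significance: %d unit(s) untestable "
                       "(zero variance), excluded: %s%s", len(bad), bad[:5],
                       "..." if len(bad) > 5 else "")
        t = t.loc[~untestable].reset_index(drop=True)
        p = p[~untestable]
    t["p_value"] = p
    t["fdr"] = benjamini_hochberg(p)
    return ContrastTable(t)


def filter_significant(table: ContrastTable, th: Thresholds,
                       modality: str) -> set[str]:
    """Units passing the modality's strict significance cutoffs.

    Genes: |effect| > lfc_min and p < deg_p_max. Events: |effect| > dpsi_min,
    fdr < splice_fdr_max and (p < splice_p_max when configured).
    """
    t = table.table
    if modality == "gene":
        needed = ["effect", "p_value"]
    elif modality == "event":
        needed = ["effect", "fdr"] + (["p_value"] if th.splice_p_max is not None
                                      else [])
    else:
        raise ValidationError(f"modality must be 'gene' or 'event', got {modality!r}")
    for col in needed:
        missing = t.loc[t[col].isna(), "unit_id"]
        if len(missing):
            raise ValidationError(
                f"missing {col} for unit(s) {missing.tolist()[:5]}")
    if modality == "gene":
        keep = (t["effect"].abs() > th.lfc_min) & (t["p_value"] < th.deg_p_max)
    else:
        keep = (t["effect"].abs() > th.dpsi_min) & (t["fdr"] < th.splice_fdr_max)
        if th.splice_p_max is not None:
            keep &= t["p_value"] < th.splice_p_max
    return set(t.loc[keep, "unit_id"])


def delta_log2fc(pre_vs_ctrl: ContrastTable,
                 post_vs_ctrl: ContrastTable,
                 label: str = "delta") -> pd.DataFrame:
    """Per-unit change in effect: post-vs-control minus pre-vs-control.

    Units present in only one table are excluded; their count is logged.
    Antisymmetric under swapping the two tables.
    """
    pre = pre_vs_ctrl.effects()
    post = post_vs_ctrl.effects()
    shared = pre.index.intersection(post.index)
    n_dropped = len(pre.index.symmetric_difference(post.index))
    if n_dropped:
        logger.warning("delta_log2fc: %d unit(s) present in only one table, "
                       "excluded", n_dropped)
    delta = (post.loc[shared] - pre.loc[shared])
    return pd.DataFrame({"unit_id": shared, "subject_id": label,
                         "delta_lfc": delta.to_numpy()}).reset_index(drop=True)


# ---------------------------------------------------------------------------
# raw-data filters
# ---------------------------------------------------------------------------

def filter_low_counts(counts: CountMatrix, min_count: int = 10,
                      mode: str = "every") -> CountMatrix:
    """Drop genes with < min_count counts in every sample (mode='every', the
    default literal reading) or in any sample (mode='any')."""
    df = counts.counts
    if mode == "every":
        keep = (df >= min_count).any(axis=1)
    elif mode == "any":
        keep = (df >= min_count).all(axis=1)
    else:
        raise ValidationError(f"mode must be 'every' or 'any', got {mode!r}")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_low_counts: dropped %d gene(s) below %d counts",
                    dropped, min_count)
    return CountMatrix(df.loc[keep])


def apply_support_filter(psi: PsiMatrix, min_reads: int = 5) -> PsiMatrix:
    """Set PSI cells with <= min_reads supporting reads to missing (NaN)."""
    if psi.support is None:
        return psi
    masked = psi.psi.where(psi.support > min_reads)
    n = int((psi.support.to_numpy() <= min_reads).sum())
    if n:
        logger.info("apply_support_filter: %d cell(s) set missing "
                    "(<= %d supporting reads)", n, min_reads)
    return PsiMatrix(masked, psi.support)
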