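"""Synthetic DM1 training-cohort generator with full ground truth.

Emulates the downstream structure of a strength-training transcriptome study:
unaffected controls sampled once, patients sampled before (pre) and after
(post) a training program. Patients carry planted expression and splicing
defects whose magnitude scales with a per-patient severity (the analogue of
the CTG repeat-length spectrum), and the training partially rescues each
defect toward control levels. Clinical one-repetition-maximum (1-RM) gains
are generated as a monotone function of each patient's mean expression rescue
mixed with noise, so the molecular-clinical correlation the analysis measures
has a known planted strength.

Generative model
----------------
* Gene counts: negative binomial with shared dispersion; per-sample library
  size factors drawn log-normally. A DM gene ``u`` in patient ``p`` has a
  pre-training log2 offset of ``sign_u * (2.5 + severity_p)`` plus a small
  per-(gene, patient) jitter.
* PSI: DM events are shifted from the control baseline toward 1 (inclusion
  events) or 0 (exclusion events) by ``0.3 + 0.3 * severity_p``, truncated to
  [0, 1]; measurement noise is additive Gaussian with truncation.
* Rescue: the post-training defect of unit ``u`` in patient ``p`` is
  ``pre + rho * (control_mean - pre)`` (PSI scale for events, log2 scale for
  genes) with per-unit rescue ``rho = fraction_p ** gamma_u``. The power-law
  form keeps the limits exact (fraction 0 -> no change, fraction 1 -> complete
  rescue for every unit) while spreading per-unit rescue within a patient.

Deterministic limit
-------------------
``noise_sd_psi = 0`` switches the whole generator to its noise-free limit:
PSI noise off, counts set to rounded expected values with unit library
factors (no negative-binomial sampling), clinical noise off, and per-unit
rescue exponents placed on an even grid that avoids the +10% rescue-category
boundary. In this limit the downstream complete-rescue / null identities hold
exactly, which is what makes every pipeline stage testable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import (
    ClinicalRaw,
    CountMatrix,
    EventAnnotation,
    PsiMatrix,
    SampleMeta,
    ValidationError,
    write_clinical_table,
    write_event_bed,
    write_fasta,
    write_sample_meta,
    write_wide_matrix,
)

YGCY_MOTIFS = ("TGCT", "TGCC", "CGCT", "CGCC")

#: per-unit rescue exponent ranges (log-uniform); genes are spread wide to
#: emulate the strong inter-individual heterogeneity of the expression
#: response, events narrower (splicing response is more uniform)
GENE_GAMMA_RANGE = (0.5, 7.0)
EVENT_GAMMA_RANGE = (0.5, 2.5)

#: guard band (rescue-fraction scale) kept free of gene rescue values around
#: the 10% category boundary in the deterministic limit, so that estimator
#: distortion (pseudocount, count rounding) cannot flip a category
_BOUNDARY_GUARD = (0.08, 0.12)

_RM_TESTS = ("leg_extension", "leg_press", "hip_abduction", "squat")
_RM_BASELINES = {"leg_extension": 40.0, "leg_press": 120.0,
                 "hip_abduction": 25.0, "squat": 50.0}
_OTHER_TESTS = {"knee_extensors": 120.0, "thirty_sec_sts": 10.0}


def _per_patient(value, n: int, default: tuple[float, float],
                 name: str) -> np.ndarray:
    """Broadcast a scalar / sequence / None to one value per patient."""
    if value is None:
        arr = np.linspace(default[0], default[1], n)
    else:
        arr = np.atleast_1d(np.asarray(value, dtype=float))
        if arr.size == 1:
            arr = np.repeat(arr, n)
        elif arr.size != n:
            raise ValidationError(
                f"{name}: expected scalar or length-{n} sequence, got {arr.size}")
    return arr


@dataclass
class SimParams:
    """Simulation parameters; per-patient fields accept a scalar or sequence.

    Defaults mirror the study design being emulated: 9 trained male patients,
    6 untrained controls, severity spanning the repeat-length spectrum,
    splicing rescue fractions around 0.7 (fairly uniform), expression rescue
    fractions spread 0.3-0.7 (heterogeneous), and a clinical link strength of
    0.8 (a strong but noisy molecular-clinical association).
    """

    n_controls: int = 6
    n_patients: int = 9
    n_genes: int = 1000
    n_events: int = 400
    severity: object = None  # default linspace(0.2, 0.95)
    rescue_fraction_expr: object = None  # default linspace(0.3, 0.7)
    rescue_fraction_splice: object = None  # default linspace(0.55, 0.85)
    noise_sd_psi: float = 0.03
    nb_dispersion: float = 0.1
    frac_dm_genes: float = 0.15
    frac_dm_events: float = 0.3
    clinical_link_strength: float = 0.8
    seed: int = 0

    def resolved(self) -> "_Resolved":
        if min(self.n_controls, self.n_patients, self.n_genes, self.n_events) < 1:
            raise ValidationError("n_controls/n_patients/n_genes/n_events must be >= 1")
        if self.noise_sd_psi < 0:
            raise ValidationError("noise_sd_psi must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be > 0")
        for name, v in (("frac_dm_genes", self.frac_dm_genes),
                        ("frac_dm_events", self.frac_dm_events),
                        ("clinical_link_strength", self.clinical_link_strength)):
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        n = self.n_patients
        sev = _per_patient(self.severity, n, (0.2, 0.95), "severity")
        f_expr = _per_patient(self.rescue_fraction_expr, n, (0.3, 0.7),
                              "rescue_fraction_expr")
        f_spl = _per_patient(self.rescue_fraction_splice, n, (0.55, 0.85),
                             "rescue_fraction_splice")
        for name, arr in (("severity", sev), ("rescue_fraction_expr", f_expr),
                          ("rescue_fraction_splice", f_spl)):
            if np.any((arr < 0) | (arr > 1)):
                raise ValidationError(f"{name} values must be in [0,1]")
        return _Resolved(self, sev, f_expr, f_spl)

    @property
    def deterministic(self) -> bool:
        """noise_sd_psi == 0 selects the fully noise-free generator limit."""
        return self.noise_sd_psi == 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("severity", "rescue_fraction_expr", "rescue_fraction_splice"):
            v = d[key]
            if isinstance(v, np.ndarray):
                d[key] = v.tolist()
        return d


@dataclass
class _Resolved:
    params: SimParams
    severity: np.ndarray
    f_expr: np.ndarray
    f_splice: np.ndarray


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort.

    ``true_effect_pre_*`` are the realized (post-truncation) pre-training
    deviations from the control baseline, per unit per patient;
    ``true_rescue_*`` the per-unit rescue fractions in [0, 1].
    """

    dm_gene_ids: list[str]
    dm_event_ids: list[str]
    event_direction: dict[str, str]  # inclusion | exclusion
    true_effect_pre_genes: pd.DataFrame  # genes x patients, log2 offsets
    true_effect_pre_events: pd.DataFrame  # events x patients, delta PSI
    true_rescue_genes: pd.DataFrame  # DM genes x patients
    true_rescue_events: pd.DataFrame  # DM events x patients
    clinical_true_gain: pd.Series  # percent 1-RM gain per patient
    params: dict = field(default_factory=dict)


def _gamma_values(n: int, rng: np.random.Generator, grange: tuple[float, float],
                  deterministic: bool,
                  guard_fractions: np.ndarray | None = None) -> np.ndarray:
    """Per-unit rescue exponents.

    Stochastic mode: i.i.d. log-uniform on ``grange``. Deterministic mode: an
    even log-spaced grid; when ``guard_fractions`` is given, grid points whose
    implied rescue ``f ** gamma`` would fall inside the category guard band for
    any patient fraction are shifted to the nearest allowed value, keeping the
    grid's coverage of every inter-patient threshold interval.
    """
    lo, hi = grange
    if not deterministic:
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    # forbidden gamma intervals (one per patient fraction strictly inside (0,1))
    bands: list[tuple[float, float]] = []
    if guard_fractions is not None:
        g_lo, g_hi = _BOUNDARY_GUARD
        for f in guard_fractions:
            if 0.0 < f < 1.0:
                a, b = np.log(g_hi) / np.log(f), np.log(g_lo) / np.log(f)
                bands.append((max(lo, a), min(hi, b)))
    bands.sort()
    grid = np.exp(np.linspace(np.log(lo), np.log(hi), n))
    if not bands:
        return grid
    out = grid.copy()
    for i, g in enumerate(grid):
        for a, b in bands:
            if a < g < b:
                # move to the nearer band edge (tiny offset keeps it outside)
                eps = 1e-9 * (b - a)
                out[i] = a - eps if (g - a) <= (b - g) else b + eps
                break
    return out


def simulate_cohort(params: SimParams) -> tuple[
        CountMatrix, PsiMatrix, list[SampleMeta], list[ClinicalRaw], SyntheticTruth]:
    """Simulate counts, PSI, metadata, clinical measures and ground truth."""
    res = params.resolved()
    det = params.deterministic
    ss = np.random.SeedSequence(params.seed)
    rng_gene, rng_event, rng_clin, rng_misc = (
        np.random.default_rng(s) for s in ss.spawn(4))

    n_pat, n_ctl = params.n_patients, params.n_controls
    patients = [f"P{i + 1:02d}" for i in range(n_pat)]
    controls = [f"C{i + 1:02d}" for i in range(n_ctl)]
    sample_ids = (controls
                  + [f"{p}_pre" for p in patients]
                  + [f"{p}_post" for p in patients])

    # ---- sample metadata (controls younger than patients, as in DM1 cohorts)
    if det:
        ctl_ages = np.linspace(26.0, 38.0, n_ctl)
        # interleave so age is not a monotone function of severity
        base = np.linspace(38.0, 58.0, n_pat)
        pat_ages = np.concatenate([base[::2], base[1::2][::-1]])
    else:
        ctl_ages = np.clip(rng_misc.normal(32, 6, n_ctl), 20, 60)
        pat_ages = np.clip(rng_misc.normal(48, 8, n_pat), 25, 70)
    meta = [SampleMeta(c, c, "control", "baseline", round(float(a), 1))
            for c, a in zip(controls, ctl_ages)]
    for p, a in zip(patients, pat_ages):
        meta.append(SampleMeta(f"{p}_pre", p, "patient", "pre", round(float(a), 1)))
        meta.append(SampleMeta(f"{p}_post", p, "patient", "post", round(float(a), 1)))

    # ---- gene expression -------------------------------------------------
    gene_ids = [f"G{i + 1:05d}" for i in range(params.n_genes)]
    n_dm_g = max(1, int(round(params.frac_dm_genes * params.n_genes)))
    dm_genes = gene_ids[:n_dm_g]  # ids are arbitrary labels; first block is DM
    baseline = np.exp(rng_gene.normal(np.log(400.0), 1.0, params.n_genes))
    baseline = np.clip(baseline, 100.0, 5e4)
    sign = np.where(rng_gene.random(n_dm_g) < 0.5, 1.0, -1.0)
    jitter = (np.zeros((n_dm_g, n_pat)) if det
              else rng_gene.normal(0.0, 0.25, (n_dm_g, n_pat)))
    offsets_pre = np.zeros((params.n_genes, n_pat))
    offsets_pre[:n_dm_g, :] = (sign[:, None]
                               * (2.5 + res.severity[None, :]) + jitter)

    gamma_g = _gamma_values(n_dm_g, rng_gene, GENE_GAMMA_RANGE, det,
                            guard_fractions=res.f_expr if det else None)
    rescue_g = np.power(res.f_expr[None, :], gamma_g[:, None])  # DM genes x pat
    offsets_post = offsets_pre.copy()
    offsets_post[:n_dm_g, :] = offsets_pre[:n_dm_g, :] * (1.0 - rescue_g)

    if det:
        libfac = np.ones(len(sample_ids))
    else:
        libfac = np.exp(rng_gene.normal(0.0, 0.15, len(sample_ids)))
    mu = np.empty((params.n_genes, len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        if sid in controls:
            off = 0.0
        else:
            p = sample_ids[j].rsplit("_", 1)[0]
            pi = patients.index(p)
            off = offsets_pre[:, pi] if sid.endswith("_pre") else offsets_post[:, pi]
        mu[:, j] = baseline * np.power(2.0, off) * libfac[j]
    if det:
        counts = np.round(mu)
    else:
        alpha = params.nb_dispersion
        counts = rng_gene.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))
    count_df = pd.DataFrame(counts.astype(np.int64), index=gene_ids,
                            columns=sample_ids)

    # ---- splicing --------------------------------------------------------
    event_ids = [f"SE{i + 1:05d}" for i in range(params.n_events)]
    n_dm_e = max(1, int(round(params.frac_dm_events * params.n_events)))
    dm_events = event_ids[:n_dm_e]
    direction = np.where(rng_event.random(n_dm_e) < 0.5, 1.0, -1.0)  # +1 incl
    psi0 = rng_event.uniform(0.05, 0.95, params.n_events)
    # DM baselines placed mid-range so the planted shift stays informative
    psi0[:n_dm_e] = np.where(direction > 0,
                             rng_event.uniform(0.15, 0.45, n_dm_e),
                             rng_event.uniform(0.55, 0.85, n_dm_e))
    # Which DM events are misspliced in which patient: a small "core" tier is
    # shared across most patients (the classic DM1 biomarker events), the
    # rest are idiosyncratic, emulating the heterogeneity of per-individual
    # significant-event sets. The deterministic limit activates everything.
    if det:
        active = np.ones((n_dm_e, n_pat), dtype=bool)
    else:
        n_core = int(round(0.2 * n_dm_e))
        p_active = np.where(np.arange(n_dm_e) < n_core, 0.85, 0.15)
        active = rng_event.random((n_dm_e, n_pat)) < p_active[:, None]
        active[rng_event.integers(0, n_dm_e, n_pat), np.arange(n_pat)] = True
    shift = np.zeros((params.n_events, n_pat))
    shift[:n_dm_e, :] = (direction[:, None]
                         * (0.3 + 0.3 * res.severity[None, :]) * active)
    psi_pre = np.clip(psi0[:, None] + shift, 0.0, 1.0)
    effect_pre_events = psi_pre - psi0[:, None]

    gamma_e = _gamma_values(n_dm_e, rng_event, EVENT_GAMMA_RANGE, det)
    rescue_e = np.power(res.f_splice[None, :], gamma_e[:, None])
    psi_post = psi_pre.copy()
    psi_post[:n_dm_e, :] = (psi_pre[:n_dm_e, :]
                            + rescue_e * (psi0[:n_dm_e, None] - psi_pre[:n_dm_e, :]))

    psi = np.empty((params.n_events, len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        if sid in controls:
            col = np.repeat(psi0[:, None], 1, axis=1)[:, 0]
        else:
            pi = patients.index(sid.rsplit("_", 1)[0])
            col = psi_pre[:, pi] if sid.endswith("_pre") else psi_post[:, pi]
        if not det:
            col = col + rng_event.normal(0.0, params.noise_sd_psi, params.n_events)
        psi[:, j] = np.clip(col, 0.0, 1.0)
    psi_df = pd.DataFrame(psi, index=event_ids, columns=sample_ids)

    if det:
        support = np.full(psi.shape, 60, dtype=np.int64)
    else:
        support = rng_event.poisson(60.0, psi.shape)
        low = rng_event.random(psi.shape) < 0.02  # sporadic low-coverage cells
        support[low] = rng_event.poisson(3.0, int(low.sum()))
    support_df = pd.DataFrame(support.astype(np.int64), index=event_ids,
                              columns=sample_ids)

    # ---- clinical: 1-RM gains linked to mean expression rescue ----------
    mean_rescue = rescue_g.mean(axis=0)  # per patient
    sd = mean_rescue.std()
    z = (mean_rescue - mean_rescue.mean()) / (sd if sd > 0 else 1.0)
    lam = params.clinical_link_strength
    eta = np.zeros(n_pat) if det else rng_clin.normal(0.0, 1.0, n_pat)
    gain = 80.0 + 45.0 * (lam * z + (1.0 - lam) * eta)
    clinical: list[ClinicalRaw] = []
    for pi, p in enumerate(patients):
        for test in _RM_TESTS:
            tj = 0.0 if det else rng_clin.normal(0.0, 6.0)
            pre = _RM_BASELINES[test] * (1.0 if det else
                                         np.exp(rng_clin.normal(0.0, 0.2)))
            post = pre * (1.0 + (gain[pi] + tj) / 100.0)
            clinical.append(ClinicalRaw(p, test, float(pre), float(post)))
        for test, base in _OTHER_TESTS.items():
            tj = 0.0 if det else rng_clin.normal(0.0, 3.0)
            pre = base * (1.0 if det else np.exp(rng_clin.normal(0.0, 0.15)))
            post = pre * (1.0 + (0.2 * gain[pi] + tj) / 100.0)
            clinical.append(ClinicalRaw(p, test, float(pre), float(post)))

    truth = SyntheticTruth(
        dm_gene_ids=list(dm_genes),
        dm_event_ids=list(dm_events),
        event_direction={e: ("inclusion" if d > 0 else "exclusion")
                         for e, d in zip(dm_events, direction)},
        true_effect_pre_genes=pd.DataFrame(offsets_pre, index=gene_ids,
                                           columns=patients),
        true_effect_pre_events=pd.DataFrame(effect_pre_events, index=event_ids,
                                            columns=patients),
        true_rescue_genes=pd.DataFrame(rescue_g, index=dm_genes, columns=patients),
        true_rescue_events=pd.DataFrame(rescue_e, index=dm_events, columns=patients),
        clinical_true_gain=pd.Series(gain, index=patients),
        params=params.to_dict(),
    )
    return (CountMatrix(count_df), PsiMatrix(psi_df, support_df), meta,
            clinical, truth)


# ---------------------------------------------------------------------------
# sequence fixtures for the motif analysis
# ---------------------------------------------------------------------------

def ygcy_window_probability(composition: Sequence[float]) -> float:
    """Probability that a 4-mer window of an i.i.d. sequence matches YGCY.

    ``composition`` is (pA, pC, pG, pT).
    """
    pa, pc, pg, pt = composition
    py = pc + pt
    return py * pg * pc * py


def _random_nt(rng: np.random.Generator, n: int,
               composition: Sequence[float]) -> np.ndarray:
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n,
                      p=np.asarray(composition, dtype=float))


def _plant_motifs(seq: np.ndarray, rng: np.random.Generator,
                  extra_density: float) -> None:
    """Overwrite Poisson-placed positions of ``seq`` with random YGCY 4-mers."""
    n = len(seq)
    if n < 4 or extra_density <= 0:
        return
    k = rng.poisson(extra_density * n)
    if k == 0:
        return
    positions = rng.integers(0, n - 3, size=k)
    for pos in positions:
        motif = YGCY_MOTIFS[rng.integers(0, 4)]
        seq[pos:pos + 4] = np.frombuffer(motif.encode(), dtype="S1")


_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.encode().translate(_COMPLEMENT)[::-1].decode()


def simulate_event_sequences(
        events: Sequence[EventAnnotation],
        directions: Mapping[str, str],
        flank: int = 250,
        density_ratio: float = 1.0,
        seed: int = 0,
        composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> dict[str, str]:
    """Generate one contig per event with direction-dependent YGCY planting.

    Regions are built transcript-relative (upstream | exon | downstream);
    inclusion-direction events receive extra YGCY motifs upstream and within
    the exon, exclusion-direction events downstream, at a Poisson rate chosen
    so the planted region's expected YGCY density is ``density_ratio`` times
    the background density of the stated mononucleotide composition. Events
    whose direction is not listed are background (no planting). The returned
    contigs are genome-strand sequences: for a '-' strand event the
    transcript-relative construct is reverse-complemented, so strand-aware
    extraction recovers the planted orientation.
    """
    if flank < 4 and flank != 0:
        raise ValidationError(f"flank must be 0 or >= 4 to fit a motif, got {flank}")
    if density_ratio <= 0:
        raise ValidationError("density_ratio must be > 0")
    base_density = ygcy_window_probability(composition)
    # an inserted 4-mer overwrites ~7 windows (each a background match with
    # prob base_density) while guaranteeing one; inflate the insertion rate
    # so the net planted density hits the target
    extra = (density_ratio - 1.0) * base_density / (1.0 - 7.0 * base_density)
    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    for ev in events:
        exon_len = ev.exon_end - ev.exon_start
        if ev.exon_start != flank:
            raise ValidationError(
                f"event {ev.event_id}: exon_start must equal flank ({flank}) "
                "for single-event contigs")
        up = _random_nt(rng, flank, composition)
        exon = _random_nt(rng, exon_len, composition)
        down = _random_nt(rng, flank, composition)
        direction = directions.get(ev.event_id, "background")
        if direction == "inclusion":
            _plant_motifs(up, rng, extra)
            _plant_motifs(exon, rng, extra)
        elif direction == "exclusion":
            _plant_motifs(down, rng, extra)
        transcript = b"".join(x.tobytes() for x in (up, exon, down)).decode()
        genome[ev.chrom] = (transcript if ev.strand == "+"
                            else reverse_complement(transcript))
    return genome


def make_motif_fixture(
        n_fg: int = 300,
        n_background: int = 1500,
        direction: str = "inclusion",
        exon_len: int = 150,
        flank: int = 250,
        density_ratio: float = 2.0,
        seed: int = 0,
        composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> tuple[list[EventAnnotation], dict[str, str], dict[str, str]]:
    """Self-contained BED+FASTA-shaped fixture for motif-enrichment tests.

    Returns (events, genome, directions); half the events sit on the '-'
    strand so strand handling is always exercised.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    events: list[EventAnnotation] = []
    directions: dict[str, str] = {}
    for i in range(n_fg + n_background):
        eid = f"mev{i + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        events.append(EventAnnotation(eid, f"ctg_{eid}", flank, flank + exon_len,
                                      strand))
        if i < n_fg:
            directions[eid] = direction
    genome = simulate_event_sequences(events, directions, flank=flank,
                                      density_ratio=density_ratio, seed=seed,
                                      composition=composition)
    return events, genome, directions


def simulate_cohort_event_annotations(
        event_ids: Sequence[str], exon_len: int = 150, flank: int = 250,
        seed: int = 0) -> list[EventAnnotation]:
    """Single-contig-per-event annotations for a simulated cohort's events."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    return [EventAnnotation(eid, f"ctg_{eid}", flank, flank + exon_len,
                            "+" if rng.random() < 0.5 else "-")
            for eid in event_ids]


# ---------------------------------------------------------------------------
# on-disk fixture
# ---------------------------------------------------------------------------

def write_cohort(out_dir: str | Path, params: SimParams,
                 flank: int = 250, exon_len: int = 150,
                 density_ratio: float = 2.0) -> dict:
    """Simulate a cohort and write every file the pipeline reads.

    Writes counts.tsv, psi.tsv, support.tsv, samples.tsv, clinical.tsv,
    events.bed, genome.fa and truth.json; returns a manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts, psi, meta, clinical, truth = simulate_cohort(params)
    write_wide_matrix(counts.counts, out / "counts.tsv", "gene_id")
    write_wide_matrix(psi.psi, out / "psi.tsv", "event_id")
    write_wide_matrix(psi.support, out / "support.tsv", "event_id")
    write_sample_meta(meta, out / "samples.tsv")
    write_clinical_table(clinical, out / "clinical.tsv")
    events = simulate_cohort_event_annotations(psi.event_ids, exon_len, flank,
                                               seed=params.seed)
    write_event_bed(events, out / "events.bed")
    genome = simulate_event_sequences(events, truth.event_direction, flank=flank,
                                      density_ratio=density_ratio,
                                      seed=params.seed)
    write_fasta(genome, out / "genome.fa")
    truth_json = {
        "dm_gene_ids": truth.dm_gene_ids,
        "dm_event_ids": truth.dm_event_ids,
        "event_direction": truth.event_direction,
        "true_rescue_genes": truth.true_rescue_genes.to_dict(),
        "true_rescue_events": truth.true_rescue_events.to_dict(),
        "clinical_true_gain": truth.clinical_true_gain.to_dict(),
        "params": truth.params,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=2)
        fh.write("\n")
    files = ["counts.tsv", "psi.tsv", "support.tsv", "samples.tsv",
             "clinical.tsv", "events.bed", "genome.fa", "truth.json"]
    return {"dir": str(out), "files": files}
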