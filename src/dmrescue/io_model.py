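"""Shared data model and on-disk formats.

Every table the pipeline touches is tab-delimited text with a header row;
sequences are FASTA, exon coordinates are BED6 (0-based, half-open — the
single coordinate convention used throughout the package). Readers validate
and reject rather than coerce: an out-of-range PSI or a malformed BED line is
an error naming the offending row, never a silent clamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("dmrescue")

#: significant digits used for all serialized floating-point values
FLOAT_DIGITS = 12
_FLOAT_FMT = f"%.{FLOAT_DIGITS}g"

VALID_GROUPS = ("control", "patient")
VALID_TIMEPOINTS = ("baseline", "pre", "post")
NUCLEOTIDES = frozenset("ACGTN")


class FormatError(ValueError):
    """A file does not conform to the documented layout."""


class ValidationError(ValueError):
    """Parsed content violates a data-model invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleMeta:
    """One sequenced sample in the three-arm design (control / pre / post)."""

    sample_id: str
    subject_id: str
    group: str  # control | patient
    timepoint: str  # baseline | pre | post
    age: float | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValidationError(
                f"sample {self.sample_id!r}: group {self.group!r} not in {VALID_GROUPS}")
        if self.timepoint not in VALID_TIMEPOINTS:
            raise ValidationError(
                f"sample {self.sample_id!r}: timepoint {self.timepoint!r} "
                f"not in {VALID_TIMEPOINTS}")
        if self.group == "control" and self.timepoint != "baseline":
            raise ValidationError(
                f"control sample {self.sample_id!r} must have timepoint 'baseline', "
                f"got {self.timepoint!r}")
        if self.group == "patient" and self.timepoint == "baseline":
            raise ValidationError(
                f"patient sample {self.sample_id!r} cannot have timepoint 'baseline'")


def validate_sample_set(samples: Sequence[SampleMeta]) -> None:
    """Enforce cohort-level invariants.

    sample_id unique; every patient subject has exactly one pre sample and at
    most one post sample.
    """
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate sample_id(s): {dupes}")
    by_subject: dict[str, list[SampleMeta]] = {}
    for s in samples:
        if s.group == "patient":
            by_subject.setdefault(s.subject_id, []).append(s)
    for subj, ss in by_subject.items():
        n_pre = sum(1 for s in ss if s.timepoint == "pre")
        n_post = sum(1 for s in ss if s.timepoint == "post")
        if n_pre != 1:
            raise ValidationError(
                f"patient subject {subj!r} has {n_pre} pre samples (need exactly 1)")
        if n_post > 1:
            raise ValidationError(
                f"patient subject {subj!r} has {n_post} post samples (at most 1)")


@dataclass
class CountMatrix:
    """Gene-level raw counts, genes x samples (non-negative integers)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise ValidationError("duplicate gene_id in count matrix")
        if c.columns.has_duplicates:
            raise ValidationError("duplicate sample_id in count matrix")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("count matrix contains non-numeric values")
        if np.any(arr < 0):
            raise ValidationError("count matrix contains negative values")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("count matrix contains non-integer values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class PsiMatrix:
    """Percent-spliced-in values, events x samples, in [0, 1].

    Missing cells (insufficient read support) are NaN, which is distinct from
    PSI = 0. ``support`` carries per-cell supporting-read counts when known.
    """

    psi: pd.DataFrame
    support: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        p = self.psi
        if p.index.has_duplicates:
            raise ValidationError("duplicate event_id in PSI matrix")
        arr = p.to_numpy(dtype=float)
        bad = np.argwhere((arr < 0) | (arr > 1))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"PSI out of [0,1]: event {p.index[i]!r}, sample {p.columns[j]!r}, "
                f"value {arr[i, j]!r}")
        if self.support is not None:
            s = self.support
            if list(s.index) != list(p.index) or list(s.columns) != list(p.columns):
                raise ValidationError("support table axes do not match PSI matrix")
            if np.any(s.to_numpy() < 0):
                raise ValidationError("negative support read count")

    @property
    def event_ids(self) -> list[str]:
        return list(self.psi.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.psi.columns)


#: canonical column order of a contrast table
CONTRAST_COLUMNS = ["unit_id", "effect", "p_value", "fdr", "contrast_label"]


@dataclass
class ContrastTable:
    """Per-unit effect (log2FC or ΔPSI) with significance vs a reference group."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CONTRAST_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"contrast table missing column(s): {missing}")
        t = self.table
        if t.duplicated(["unit_id", "contrast_label"]).any():
            raise ValidationError("duplicate (unit_id, contrast_label) rows")
        for col in ("p_value", "fdr"):
            vals = t[col].dropna()
            if ((vals < 0) | (vals > 1)).any():
                bad = t.loc[t.index[(t[col] < 0) | (t[col] > 1)], "unit_id"].iloc[0]
                raise ValidationError(f"{col} outside [0,1] for unit {bad!r}")

    @property
    def units(self) -> list[str]:
        return list(self.table["unit_id"])

    def effects(self) -> pd.Series:
        return self.table.set_index("unit_id")["effect"]


@dataclass(frozen=True)
class EventAnnotation:
    """A skipped-exon event: cassette-exon coordinates, 0-based half-open."""

    event_id: str
    chrom: str
    exon_start: int
    exon_end: int
    strand: str
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.exon_start >= self.exon_end:
            raise ValidationError(
                f"event {self.event_id!r}: exon_start {self.exon_start} >= "
                f"exon_end {self.exon_end}")
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"event {self.event_id!r}: strand {self.strand!r} must be '+' or '-' "
                "(strand is required to orient upstream/downstream flanks)")


@dataclass(frozen=True)
class ClinicalRaw:
    """Pre/post value of one clinical test for one subject (raw test units)."""

    subject_id: str
    test_name: str
    pre_value: float
    post_value: float


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_DEFAULT_EFFECT_COLUMNS = {
    "unit_id": "unit_id", "effect": "effect", "p_value": "p_value", "fdr": "fdr"}


def read_effect_table(path: str | Path, contrast_label: str,
                      columns: Mapping[str, str] | None = None) -> ContrastTable:
    """Read a per-unit effect table (log2FC or ΔPSI with p and FDR).

    ``columns`` maps canonical names (unit_id/effect/p_value/fdr) to the
    header names actually present in the file. Rows whose effect is not
    numeric are dropped with a logged warning.
    """
    colmap = dict(_DEFAULT_EFFECT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise FormatError(f"{path}: empty effect table")
    for canon, name in colmap.items():
        if name not in df.columns:
            raise FormatError(f"{path}: missing required column {name!r} ({canon})")
    out = pd.DataFrame({canon: df[name] for canon, name in colmap.items()})
    numeric = pd.to_numeric(out["effect"], errors="coerce")
    bad = numeric.isna() & out["effect"].notna() | out["effect"].isna()
    if bad.any():
        for uid in out.loc[bad, "unit_id"]:
            logger.warning("%s: dropping unit %r with non-numeric effect", path, uid)
    out = out.loc[~bad].copy()
    out["effect"] = pd.to_numeric(out["effect"])
    out["p_value"] = pd.to_numeric(out["p_value"], errors="coerce")
    out["fdr"] = pd.to_numeric(out["fdr"], errors="coerce")
    out["contrast_label"] = contrast_label
    return ContrastTable(out.reset_index(drop=True))


def _read_wide_matrix(path: str | Path, index_name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected '{index_name}' column plus sample columns")
    return df.set_index(df.columns[0]).rename_axis(index_name)


def read_psi_matrix(path: str | Path,
                    support_path: str | Path | None = None) -> PsiMatrix:
    """Read a wide PSI table (first column event_id). Empty / 'NA' cells are
    missing values; any numeric value outside [0,1] is an error."""
    psi = _read_wide_matrix(path, "event_id").astype(float)
    support = None
    if support_path is not None:
        support = _read_wide_matrix(support_path, "event_id")
    return PsiMatrix(psi, support)


def read_count_matrix(path: str | Path) -> CountMatrix:
    counts = _read_wide_matrix(path, "gene_id")
    return CountMatrix(counts)


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "subject_id", "group", "timepoint"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    samples = []
    for _, row in df.iterrows():
        age = float(row["age"]) if "age" in df.columns and pd.notna(row.get("age")) else None
        sex = row.get("sex") if "sex" in df.columns and pd.notna(row.get("sex")) else None
        samples.append(SampleMeta(row["sample_id"], row["subject_id"],
                                  row["group"], row["timepoint"], age, sex))
    validate_sample_set(samples)
    return samples


def read_clinical_table(path: str | Path) -> list[ClinicalRaw]:
    df = pd.read_csv(path, sep="\t")
    required = ["subject_id", "test_name", "pre_value", "post_value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return [ClinicalRaw(str(r.subject_id), str(r.test_name),
                        float(r.pre_value), float(r.post_value))
            for r in df.itertuples()]


def read_event_bed(path: str | Path) -> list[EventAnnotation]:
    """Read BED6 event annotations. The BED name field is the event_id; the
    score field is ignored; strand '.' is rejected (flank orientation is
    strand-dependent)."""
    events = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 BED fields, "
                                  f"got {len(fields)}")
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if strand == ".":
                raise ValidationError(
                    f"{path}:{lineno}: strand '.' not allowed — strand is required "
                    "to orient upstream/downstream flanks")
            try:
                events.append(EventAnnotation(name, chrom, start_i, end_i, strand))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return events


def read_region_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {header: uppercased sequence}, restricted to ACGTN.

    Headers are either event-region keys ('ev1|exon') or plain contig names;
    duplicate headers are an error.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValidationError(f"{path}: duplicate FASTA header {rec.id!r}")
        seq = str(rec.seq).upper()
        alien = set(seq) - NUCLEOTIDES
        if alien:
            raise ValidationError(
                f"{path}: sequence {rec.id!r} contains non-nucleotide "
                f"character(s) {sorted(alien)}")
        seqs[rec.id] = seq
    return seqs


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT, na_rep="NA")


def write_wide_matrix(df: pd.DataFrame, path: str | Path, index_name: str) -> None:
    out = df.copy()
    out.index.name = index_name
    write_tsv(out, path, index=True)


def write_sample_meta(samples: Sequence[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(s) for s in samples])
    write_tsv(df, path)


def write_clinical_table(rows: Sequence[ClinicalRaw], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    write_tsv(df, path)


def write_event_bed(events: Sequence[EventAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ev in events:
            fh.write(f"{ev.chrom}\t{ev.exon_start}\t{ev.exon_end}\t"
                     f"{ev.event_id}\t0\t{ev.strand}\n")


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def config_hash(config: Mapping) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(tables: Mapping[str, pd.DataFrame], out_dir: str | Path,
                 config: Mapping | None = None, seed: int | None = None,
                 extras: Mapping | None = None) -> dict:
    """Write one TSV per named table plus a JSON run summary; return the manifest.

    Numeric content is deterministic for fixed inputs; only the timestamp in
    the JSON summary varies between reruns.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc
    manifest: dict = {"tables": {}, "summary": "run_summary.json"}
    for name, df in tables.items():
        fname = f"{name}.tsv"
        write_tsv(df, out / fname)
        manifest["tables"][name] = fname
    summary = {
        "config_hash": config_hash(config or {}),
        "seed": seed,
        "n_tables": len(tables),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if extras:
        summary.update(extras)
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
        fh.write("\n")
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
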