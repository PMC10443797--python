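"""YGCY (MBNL-binding) motif enrichment around regulated exons.

MBNL proteins regulate cassette exons position-dependently through YGCY
tetramers (TGCT, TGCC, CGCT, CGCC; Y = pyrimidine): events aberrantly
included in DM1 tend to carry elevated YGCY density upstream of or within
the regulated exon, aberrantly excluded events downstream. This module
extracts strand-aware exon and flank sequences, counts overlapping YGCY
windows, selects composition-matched background events, and reports per
region x direction log2 density enrichment over the matched background.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import EventAnnotation, ValidationError
from .synthetic import reverse_complement

logger = logging.getLogger("dmrescue")

REGIONS = ("upstream", "exon", "downstream")
_YGCY_RE = re.compile(r"(?=[CT]GC[CT])")  # lookahead: overlapping windows count

#: pseudo-density added to both sides of the enrichment ratio, motifs per nt
DEFAULT_EPSILON = 0.5 / 1000.0  # 0.5 motifs per kb


def count_ygcy(seq: str) -> int:
    """Number of (possibly overlapping) 4-nt windows matching YGCY.

    Windows containing N never match; sequences shorter than 4 nt count 0.
    """
    return sum(1 for _ in _YGCY_RE.finditer(seq.upper()))


@dataclass
class RegionSeqs:
    """Transcript-relative sequences of one event: 5' flank, exon, 3' flank."""

    event_id: str
    upstream: str
    exon: str
    downstream: str
    direction: str = "background"  # inclusion | exclusion | background
    truncated: bool = False

    def concatenated(self) -> str:
        return self.upstream + self.exon + self.downstream


def extract_regions(event: EventAnnotation, genome, flank: int = 250) -> RegionSeqs:
    """Extract exon and flanks from a genome mapping, strand-aware.

    For '+' strand: upstream = [start-flank, start), downstream =
    [end, end+flank). For '-' strand all three sequences are
    reverse-complemented and the flank labels swapped, so "upstream" is
    always 5' of the exon on the coding strand. Flanks running off a contig
    end are truncated and flagged.
    """
    if flank < 0:
        raise ValidationError("flank must be >= 0")
    contig = genome[event.chrom] if not hasattr(genome, "get") \
        else genome.get(event.chrom)
    if contig is None:
        raise ValidationError(f"contig {event.chrom!r} not in genome")
    contig = str(contig)
    n = len(contig)
    if event.exon_start < 0 or event.exon_end > n:
        raise ValidationError(
            f"event {event.event_id!r}: exon [{event.exon_start},{event.exon_end}) "
            f"outside contig {event.chrom!r} (length {n})")
    left_start = max(0, event.exon_start - flank)
    right_end = min(n, event.exon_end + flank)
    truncated = (left_start > event.exon_start - flank) or \
                (right_end < event.exon_end + flank)
    left = contig[left_start:event.exon_start]
    exon = contig[event.exon_start:event.exon_end]
    right = contig[event.exon_end:right_end]
    if event.strand == "+":
        up, ex, down = left, exon, right
    else:
        up = reverse_complement(right)
        ex = reverse_complement(exon)
        down = reverse_complement(left)
    return RegionSeqs(event.event_id, up.upper(), ex.upper(), down.upper(),
                      truncated=truncated)


def mononucleotide_frequencies(seq: str) -> np.ndarray:
    """(fA, fC, fG, fT) of a sequence, ignoring N."""
    counts = np.array([seq.count(b) for b in "ACGT"], dtype=float)
    total = counts.sum()
    if total == 0:
        return np.full(4, 0.25)
    return counts / total


def match_background(fg: list[RegionSeqs], pool: list[RegionSeqs],
                     k: int = 5, seed: int = 0) -> list[list[RegionSeqs]]:
    """Per foreground event, its k composition-nearest background events.

    Distance is Euclidean on mononucleotide frequency vectors of the
    concatenated exon+flank sequence. Ties are broken by a seeded shuffle of
    the pool followed by a stable sort, then stable event-id order within
    equal shuffled positions. Selection is without replacement within one
    foreground event's set and with replacement across foreground events.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if len(pool) < k:
        raise ValidationError(f"background pool ({len(pool)}) smaller than k={k}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    shuffled = [pool[i] for i in order]
    pool_freqs = np.array([mononucleotide_frequencies(r.concatenated())
                           for r in shuffled])
    out = []
    for region in fg:
        f = mononucleotide_frequencies(region.concatenated())
        d = np.linalg.norm(pool_freqs - f, axis=1)
        idx = np.argsort(d, kind="stable")[:k]
        out.append([shuffled[i] for i in idx])
    return out


def _stratum_density(regions: list[RegionSeqs], attr: str) -> tuple[float, int]:
    total_nt = sum(len(getattr(r, attr)) for r in regions)
    total_motifs = sum(count_ygcy(getattr(r, attr)) for r in regions)
    return (total_motifs / total_nt if total_nt else np.nan), total_nt


def motif_enrichment(fg: list[RegionSeqs],
                     bg_sets: list[list[RegionSeqs]],
                     epsilon: float = DEFAULT_EPSILON) -> pd.DataFrame:
    """log2 YGCY density enrichment per region per direction stratum.

    Foreground events are partitioned by their ``direction``; per region the
    foreground density (total motifs / total nt across the stratum) is
    compared with the density across the pooled matched backgrounds (with
    multiplicity), and log2((fg + eps) / (bg + eps)) reported. Empty
    direction strata are omitted with a warning.
    """
    if len(fg) != len(bg_sets):
        raise ValidationError("one background set per foreground event required")
    rows = []
    for direction in ("inclusion", "exclusion"):
        sel = [i for i, r in enumerate(fg) if r.direction == direction]
        if not sel:
            logger.warning("motif_enrichment: no %s-direction events, "
                           "stratum omitted", direction)
            continue
        fg_regions = [fg[i] for i in sel]
        bg_regions = [b for i in sel for b in bg_sets[i]]
        for region in REGIONS:
            fg_d, fg_nt = _stratum_density(fg_regions, region)
            bg_d, bg_nt = _stratum_density(bg_regions, region)
            log2e = float(np.log2((fg_d + epsilon) / (bg_d + epsilon)))
            rows.append({"region": region, "direction": direction,
                         "fg_density": fg_d, "bg_density": bg_d,
                         "fg_nt": fg_nt, "bg_nt": bg_nt,
                         "log2_enrichment": log2e})
    return pd.DataFrame(rows, columns=["region", "direction", "fg_density",
                                       "bg_density", "fg_nt", "bg_nt",
                                       "log2_enrichment"])


def enrichment_analysis(events: list[EventAnnotation], genome,
                        directions: dict[str, str],
                        flank: int = 250, k: int = 5, seed: int = 0,
                        epsilon: float = DEFAULT_EPSILON) -> pd.DataFrame:
    """End-to-end: extract regions, match backgrounds, compute enrichment.

    ``directions`` maps significantly misregulated event ids to
    'inclusion'/'exclusion'; all other events form the background pool
    (detected but not misregulated in the same assay universe).
    """
    regions = []
    for ev in events:
        r = extract_regions(ev, genome, flank)
        r.direction = directions.get(ev.event_id, "background")
        regions.append(r)
    fg = [r for r in regions if r.direction != "background"]
    pool = [r for r in regions if r.direction == "background"]
    if not fg:
        logger.warning("enrichment_analysis: no misregulated events; "
                       "empty result")
        return motif_enrichment([], [])
    bg_sets = match_background(fg, pool, k=k, seed=seed)
    return motif_enrichment(fg, bg_sets, epsilon=epsilon)
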