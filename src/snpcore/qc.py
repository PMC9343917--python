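"""Marker-level QC filtering and annotation.

Filtering mirrors the usual GBS pipeline thresholds for an inbred diversity
panel: markers are retained when the minor allele frequency is strictly above
``min_maf``, the missing-call fraction strictly below ``max_missing`` and,
when a read-depth matrix is present, per-call depth lies inside
``[min_depth, max_depth]`` for the required fraction of called entries.

Annotation assigns each marker one genomic-context class with precedence
CDS > UTR > intron > upstream/downstream > intergenic, and classifies coding
substitutions as synonymous or non-synonymous by codon translation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .errors import FormatError, UndefinedValueError, ValidationError
from .model import AnnotationClass, Call, GenotypeMatrix, MarkerRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for marker retention.

    MAF and missingness inequalities are strict (MAF > ``min_maf``, missing <
    ``max_missing``); depth bounds are inclusive. ``min_depth_fraction`` is
    the fraction of *called* entries whose depth must lie in bounds when a
    depth matrix exists (1.0 = every called entry).
    """

    min_maf: float = 0.05
    max_missing: float = 0.30
    min_depth: int = 3
    max_depth: int = 190
    min_depth_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValidationError(f"min_maf {self.min_maf} outside [0, 0.5]")
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValidationError(f"max_missing {self.max_missing} outside [0, 1]")
        if self.min_depth > self.max_depth:
            raise ValidationError("min_depth > max_depth")
        if not 0.0 <= self.min_depth_fraction <= 1.0:
            raise ValidationError("min_depth_fraction outside [0, 1]")


def missing_rate(gm: GenotypeMatrix, marker_id: str) -> float:
    """Fraction of cultivars with a missing call at the marker."""
    col = gm.column(marker_id)
    return float((col == Call.MISSING).sum() / gm.n_cultivars)


def allele_counts(gm: GenotypeMatrix, marker_id: str) -> tuple[int, int]:
    """(allele1, allele2) counts from called genotypes; HET adds one of each."""
    col = gm.column(marker_id)
    n_hom1 = int((col == Call.HOM1).sum())
    n_hom2 = int((col == Call.HOM2).sum())
    n_het = int((col == Call.HET).sum())
    return 2 * n_hom1 + n_het, 2 * n_hom2 + n_het


def allele_frequencies(gm: GenotypeMatrix, marker_id: str) -> tuple[float, float]:
    """(allele1, allele2) frequencies among called genotypes."""
    c1, c2 = allele_counts(gm, marker_id)
    total = c1 + c2
    if total == 0:
        raise UndefinedValueError(f"marker {marker_id}: no called genotypes")
    return c1 / total, c2 / total


def minor_allele_frequency(gm: GenotypeMatrix, marker_id: str) -> float:
    """min(p, 1 - p) over called genotypes at the marker."""
    p, q = allele_frequencies(gm, marker_id)
    return min(p, q)


def _depth_ok(gm: GenotypeMatrix, j: int, cfg: FilterConfig) -> bool:
    if gm.depth is None:
        return True
    called = gm.calls[:, j] != Call.MISSING
    if not called.any():
        return True
    d = gm.depth[called, j]
    in_bounds = (d >= cfg.min_depth) & (d <= cfg.max_depth)
    return bool(in_bounds.mean() >= cfg.min_depth_fraction)


def apply_filters(
    gm: GenotypeMatrix, cfg: FilterConfig = FilterConfig()
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Retain markers passing all QC rules; report each marker's fate.

    Rules are evaluated in order missing -> MAF -> depth, and a dropped
    marker records the first rule it failed. An all-missing marker that
    survives the missingness rule fails the MAF rule (its MAF is undefined).
    """
    kept_ids: list[str] = []
    rows = []
    for j, m in enumerate(gm.markers):
        miss = missing_rate(gm, m.marker_id)
        try:
            maf = minor_allele_frequency(gm, m.marker_id)
        except UndefinedValueError:
            maf = np.nan
        depth_ok = _depth_ok(gm, j, cfg)
        fail = ""
        if not miss < cfg.max_missing:
            fail = "missing"
        elif not (np.isfinite(maf) and maf > cfg.min_maf):
            fail = "maf"
        elif not depth_ok:
            fail = "depth"
        else:
            kept_ids.append(m.marker_id)
        rows.append(
            {
                "marker_id": m.marker_id,
                "kept": fail == "",
                "first_fail_rule": fail,
                "maf": maf,
                "missing": miss,
                "depth_ok": depth_ok,
            }
        )
    report = pd.DataFrame(rows)
    return gm.subset_markers(kept_ids), report


# -- substitution classes --------------------------------------------------

_TRANSITION_PAIRS = ({"A", "G"}, {"C", "T"})


def substitution_type(allele1: str, allele2: str) -> str:
    """``transition`` (A<->G, C<->T) or ``transversion`` (any purine/pyrimidine mix)."""
    a, b = allele1.upper(), allele2.upper()
    if a not in "ACGT" or b not in "ACGT" or len(a) != 1 or len(b) != 1:
        raise ValidationError(f"alleles must be single nucleotides, got {allele1}/{allele2}")
    if a == b:
        raise ValidationError("alleles must differ")
    return "transition" if {a, b} in _TRANSITION_PAIRS else "transversion"


def tstv_ratio(markers: Iterable[MarkerRecord]) -> float:
    """Transitions-to-transversions ratio over a marker list."""
    n_ts = n_tv = 0
    for m in markers:
        if substitution_type(m.allele1, m.allele2) == "transition":
            n_ts += 1
        else:
            n_tv += 1
    if n_tv == 0:
        raise UndefinedValueError("no transversion markers; Ts/Tv undefined")
    return n_ts / n_tv


# -- genomic-context annotation --------------------------------------------


@dataclass
class AnnotationIntervals:
    """Per-chromosome 1-based inclusive interval sets for genomic context.

    ``genes`` carries (start, end, strand); CDS intervals carry strand and
    phase. Upstream/downstream spans extend ``updown_bp`` beyond the gene
    boundaries on the strand-appropriate side (1 kb by default — a
    conventional promoter-proximal window).
    """

    genes: dict[str, IntervalTree] = field(default_factory=dict)
    cds: dict[str, IntervalTree] = field(default_factory=dict)
    utr: dict[str, IntervalTree] = field(default_factory=dict)
    intron: dict[str, IntervalTree] = field(default_factory=dict)
    upstream: dict[str, IntervalTree] = field(default_factory=dict)
    downstream: dict[str, IntervalTree] = field(default_factory=dict)
    updown_bp: int = 1000

    @staticmethod
    def _add(trees: dict[str, IntervalTree], chrom: str, start: int, end: int, data=None):
        if start > end:
            return
        # intervaltree uses half-open ends; inputs are 1-based inclusive
        trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, data)

    @classmethod
    def from_gff3(cls, path: str | Path, updown_bp: int = 1000) -> "AnnotationIntervals":
        """Build interval sets from a GFF3-like TSV.

        ``gene``, ``CDS``, UTR (``five_prime_UTR``/``three_prime_UTR``/
        ``UTR``) and ``intron`` features are used; other types are ignored.
        Upstream/downstream spans are derived from gene boundaries.
        """
        ann = cls(updown_bp=updown_bp)
        with open(path, encoding="utf-8") as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 8:
                    raise FormatError(f"{path}: line {ln}: expected >= 8 GFF columns")
                chrom, _, ftype, start_s, end_s, _, strand, phase_s = parts[:8]
                start, end = int(start_s), int(end_s)
                if ftype == "gene":
                    ann.add_gene(chrom, start, end, strand if strand in "+-" else "+")
                elif ftype == "CDS":
                    phase = int(phase_s) if phase_s in "012" else 0
                    cls._add(ann.cds, chrom, start, end, (strand, phase))
                elif ftype in ("five_prime_UTR", "three_prime_UTR", "UTR"):
                    cls._add(ann.utr, chrom, start, end)
                elif ftype == "intron":
                    cls._add(ann.intron, chrom, start, end)
        return ann

    def add_gene(self, chrom: str, start: int, end: int, strand: str = "+") -> None:
        self._add(self.genes, chrom, start, end, strand)
        d = self.updown_bp
        if strand == "-":
            up = (end + 1, end + d)
            down = (max(1, start - d), start - 1)
        else:
            up = (max(1, start - d), start - 1)
            down = (end + 1, end + d)
        self._add(self.upstream, chrom, *up)
        self._add(self.downstream, chrom, *down)

    def chromosomes(self) -> set[str]:
        return set(self.genes) | set(self.cds) | set(self.utr) | set(self.intron)

    def _hit(self, trees: dict[str, IntervalTree], chrom: str, pos: int) -> bool:
        t = trees.get(chrom)
        return bool(t is not None and t.overlaps_point(pos))


def classify_location(marker: MarkerRecord, ann: AnnotationIntervals) -> AnnotationClass:
    """Genomic-context class of a marker position.

    Precedence: CDS > UTR > intron (a gene position outside CDS/UTR counts
    as intronic when no explicit intron interval covers it) > upstream /
    downstream (both -> up_downstream) > intergenic. Unknown chromosomes
    classify as intergenic with a warning.
    """
    chrom, pos = marker.chromosome, marker.position
    if chrom not in ann.chromosomes() and chrom not in ann.upstream:
        log.warning("marker %s: chromosome %s absent from annotation", marker.marker_id, chrom)
        return AnnotationClass.INTERGENIC
    if ann._hit(ann.cds, chrom, pos):
        return AnnotationClass.CDS
    if ann._hit(ann.utr, chrom, pos):
        return AnnotationClass.UTR
    if ann._hit(ann.intron, chrom, pos) or ann._hit(ann.genes, chrom, pos):
        return AnnotationClass.INTRON
    up = ann._hit(ann.upstream, chrom, pos)
    down = ann._hit(ann.downstream, chrom, pos)
    if up and down:
        return AnnotationClass.UP_DOWNSTREAM
    if up:
        return AnnotationClass.UPSTREAM
    if down:
        return AnnotationClass.DOWNSTREAM
    return AnnotationClass.INTERGENIC


# -- coding effect ---------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def coding_effect(
    marker: MarkerRecord,
    cds_sequence: str,
    cds_start: int,
    strand: str = "+",
    phase: int = 0,
) -> str:
    """``synonymous`` or ``nonsynonymous`` effect of the allele substitution.

    ``cds_sequence`` is the forward-strand genomic sequence of the CDS
    interval starting at 1-based ``cds_start``; on the minus strand the
    coding sequence is its reverse complement. ``phase`` bases are discarded
    from the coding 5' end before framing into codons. Both alleles are
    substituted into the affected codon and translated with the standard
    genetic code; a substitution creating a stop codon counts as
    nonsynonymous.
    """
    seq = cds_sequence.upper()
    if set(seq) - set("ACGT"):
        raise ValidationError("ambiguous base in CDS sequence")
    if strand not in "+-":
        raise ValidationError(f"invalid strand {strand!r}")
    if phase not in (0, 1, 2):
        raise ValidationError(f"invalid phase {phase!r}")
    cds_end = cds_start + len(seq) - 1
    pos = marker.position
    if not cds_start <= pos <= cds_end:
        raise ValidationError(
            f"marker {marker.marker_id} at {pos} outside CDS [{cds_start}, {cds_end}]"
        )
    if strand == "+":
        coding = seq
        off = pos - cds_start
        a1, a2 = marker.allele1, marker.allele2
    else:
        coding = seq[::-1].translate(_COMPLEMENT)
        off = cds_end - pos
        a1 = marker.allele1.translate(_COMPLEMENT)
        a2 = marker.allele2.translate(_COMPLEMENT)
    idx = off - phase
    if idx < 0:
        raise ValidationError("marker lies in the phase-trimmed overhang of the CDS")
    codon_start = (idx // 3) * 3 + phase
    within = idx % 3
    codon = coding[codon_start : codon_start + 3]
    if len(codon) < 3:
        raise ValidationError("CDS truncated before the end of the affected codon")
    codon1 = codon[:within] + a1 + codon[within + 1 :]
    codon2 = codon[:within] + a2 + codon[within + 1 :]
    aa1 = str(Seq(codon1).translate())
    aa2 = str(Seq(codon2).translate())
    return "synonymous" if aa1 == aa2 else "nonsynonymous"


def annotate_markers(
    gm_or_markers, ann: AnnotationIntervals
) -> list[AnnotationClass]:
    """Classify every marker; returns classes in marker order."""
    markers = getattr(gm_or_markers, "markers", gm_or_markers)
    return [classify_location(m, ann) for m in markers]
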