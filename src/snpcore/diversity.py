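"""Per-marker diversity statistics.

The central statistic is the polymorphic information content

    PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2,

where the ``p_i`` are allele frequencies at the locus. For a biallelic SNP
with frequencies (p, q) this reduces to ``1 - (p^2 + q^2) - 2 p^2 q^2`` and is
bounded by 0.375, attained at p = 0.5. Expected heterozygosity (gene
diversity) is ``He = 1 - sum_i p_i^2``, so PIC = He - 2 p^2 q^2 for a
biallelic locus and PIC < He whenever the locus is polymorphic.

Allele frequencies are estimated from called genotypes only, with residual
heterozygous calls contributing one copy of each allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedValueError, ValidationError
from .model import Call, GenotypeMatrix
from .qc import allele_frequencies, minor_allele_frequency

_FREQ_SUM_TOL = 1e-9


@dataclass(frozen=True)
class AlleleFrequencySpectrum:
    """Allele frequencies p_1..p_n at one locus (n = 2 for a SNP panel)."""

    frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        freqs = tuple(float(p) for p in self.frequencies)
        object.__setattr__(self, "frequencies", freqs)
        if any(p < 0 or p > 1 for p in freqs):
            raise ValidationError(f"allele frequencies outside [0, 1]: {freqs}")
        if not math.isclose(sum(freqs), 1.0, abs_tol=_FREQ_SUM_TOL, rel_tol=0.0):
            raise ValidationError(f"allele frequencies sum to {sum(freqs)}, not 1")


def _freqs(afs) -> tuple[float, ...]:
    if isinstance(afs, AlleleFrequencySpectrum):
        return afs.frequencies
    return AlleleFrequencySpectrum(tuple(afs)).frequencies


def pic(afs) -> float:
    """Polymorphic information content of an allele-frequency spectrum."""
    p = _freqs(afs)
    sq = [x * x for x in p]
    cross = sum(
        2.0 * sq[i] * sq[j] for i in range(len(p) - 1) for j in range(i + 1, len(p))
    )
    return 1.0 - sum(sq) - cross


def pic_biallelic(maf: float) -> float:
    """PIC of a biallelic locus given its minor allele frequency."""
    if not 0.0 <= maf <= 0.5:
        raise ValidationError(f"MAF {maf} outside [0, 0.5]")
    return pic((maf, 1.0 - maf))


def expected_heterozygosity(afs) -> float:
    """Gene diversity He = 1 - sum_i p_i^2."""
    p = _freqs(afs)
    return 1.0 - sum(x * x for x in p)


def observed_heterozygosity(gm: GenotypeMatrix, marker_id: str) -> float:
    """Fraction of called genotypes that are heterozygous at the marker."""
    col = gm.column(marker_id)
    n_called = int((col != Call.MISSING).sum())
    if n_called == 0:
        raise UndefinedValueError(f"marker {marker_id}: no called genotypes")
    return float((col == Call.HET).sum() / n_called)


def round_half_up(x: float, digits: int = 2) -> float:
    """Decimal half-up rounding, matching how report tables are printed."""
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{digits}"), rounding=ROUND_HALF_UP))


@dataclass
class MarkerStats:
    """Realised per-marker diversity statistics (full precision)."""

    marker_id: str
    maf: float
    pic: float
    expected_heterozygosity: float
    observed_heterozygosity: float
    n_called: int
    n_missing: int


@dataclass
class PanelDiversity:
    """Per-marker stats plus panel-level means and ranges."""

    per_marker: list[MarkerStats]
    panel: dict

    def to_frame(self, gm: Optional[GenotypeMatrix] = None) -> pd.DataFrame:
        rows = []
        for s in self.per_marker:
            row = {
                "marker_id": s.marker_id,
                "maf": s.maf,
                "pic": s.pic,
                "he": s.expected_heterozygosity,
                "ho": s.observed_heterozygosity,
                "n_called": s.n_called,
                "n_missing": s.n_missing,
            }
            if gm is not None:
                m = gm.marker(s.marker_id)
                row.update(
                    chromosome=m.chromosome,
                    position=m.position,
                    alleles=f"{m.allele1}/{m.allele2}",
                )
            rows.append(row)
        return pd.DataFrame(rows)


def _summary(values: Sequence[float]) -> dict:
    arr = np.asarray(values, dtype=float)
    return {
        "mean": float(arr.mean()),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "mean_rounded": round_half_up(float(arr.mean())),
        "min_rounded": round_half_up(float(arr.min())),
        "max_rounded": round_half_up(float(arr.max())),
    }


def marker_summary(gm: GenotypeMatrix) -> PanelDiversity:
    """Compute MAF, PIC, He and Ho for every marker plus panel summaries.

    Markers with no called genotype are reported with NaN statistics and
    excluded from the panel means/ranges. Rounded values in the panel block
    use half-up 2-decimal rounding as printed in report tables; the
    per-marker records keep full precision.
    """
    stats: list[MarkerStats] = []
    for m in gm.markers:
        col = gm.column(m.marker_id)
        n_called = int((col != Call.MISSING).sum())
        n_missing = gm.n_cultivars - n_called
        if n_called == 0:
            stats.append(
                MarkerStats(m.marker_id, np.nan, np.nan, np.nan, np.nan, 0, n_missing)
            )
            continue
        p, q = allele_frequencies(gm, m.marker_id)
        stats.append(
            MarkerStats(
                marker_id=m.marker_id,
                maf=min(p, q),
                pic=pic((p, q)),
                expected_heterozygosity=expected_heterozygosity((p, q)),
                observed_heterozygosity=observed_heterozygosity(gm, m.marker_id),
                n_called=n_called,
                n_missing=n_missing,
            )
        )
    usable = [s for s in stats if s.n_called > 0]
    if usable:
        panel = {
            "n_markers": len(stats),
            "n_markers_called": len(usable),
            "maf": _summary([s.maf for s in usable]),
            "pic": _summary([s.pic for s in usable]),
            "he": _summary([s.expected_heterozygosity for s in usable]),
            "ho": _summary([s.observed_heterozygosity for s in usable]),
            "pooled_observed_heterozygosity": float(
                sum(s.observed_heterozygosity * s.n_called for s in usable)
                / sum(s.n_called for s in usable)
            ),
        }
    else:
        panel = {"n_markers": len(stats), "n_markers_called": 0}
    return PanelDiversity(per_marker=stats, panel=panel)
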