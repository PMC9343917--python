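"""Genotype data model for inbred cultivar panels.

A panel is a cultivars x markers matrix of biallelic SNP calls. Every call is
one of four states: homozygous for the first allele (``HOM1``), homozygous for
the second allele (``HOM2``), heterozygous (``HET``) or ``MISSING``. ``HOM1``
refers to the marker's ``allele1`` as listed in the marker metadata, which for
endpoint-PCR genotyping platforms (Fluidigm-style "XX"/"YY"/"XY" calls) is not
necessarily the reference allele of any genome assembly.

Calls are stored as a compact ``int8`` array; the :class:`Call` enum gives the
codes meaning. ``encode_binary`` expands each marker into two allele-presence
columns (the 1/0 allelic matrix used for Jaccard-based clustering), with
``NaN`` as the explicit missing code.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ValidationError

log = logging.getLogger(__name__)

VALID_NUCLEOTIDES = frozenset("ACGT")


class Call(enum.IntEnum):
    """Genotype call codes as stored in :attr:`GenotypeMatrix.calls`."""

    MISSING = -1
    HOM1 = 0
    HET = 1
    HOM2 = 2


class AnnotationClass(str, enum.Enum):
    """Genomic context of a marker.

    ``CDS`` is the generic coding class used when the synonymous /
    non-synonymous effect has not been resolved (interval containment alone
    cannot decide it); :func:`snpcore.qc.coding_effect` refines it.
    """

    CDS = "CDS"
    CDS_SYNONYMOUS = "CDS_synonymous"
    CDS_NONSYNONYMOUS = "CDS_nonsynonymous"
    UTR = "UTR"
    INTRON = "intron"
    INTERGENIC = "intergenic"
    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"
    UP_DOWNSTREAM = "up_downstream"
    UNKNOWN = "unknown"


class HorticulturalType(str, enum.Enum):
    """Lettuce horticultural types used for panel metadata."""

    COS = "Cos"
    ICEBERG = "Iceberg"
    FRISEE_D_AMERIQUE = "FriseeDAmerique"
    BUTTERHEAD = "Butterhead"
    LOLLO = "Lollo"
    MULTI_DIVIDED = "MultiDivided"
    OAKLEAF = "Oakleaf"
    UNKNOWN = "Unknown"


#: Fluidigm-style allele call labels and their genotype codes. "XX" is the
#: allele1 homozygote, "YY" the allele2 homozygote, "XY" the heterozygote.
FLUIDIGM_TO_CALL = {
    "XX": Call.HOM1,
    "YY": Call.HOM2,
    "XY": Call.HET,
    "NoCall": Call.MISSING,
    "No Call": Call.MISSING,
}

CALL_TO_FLUIDIGM = {
    Call.HOM1: "XX",
    Call.HOM2: "YY",
    Call.HET: "XY",
    Call.MISSING: "NoCall",
}

#: Missing-data tokens normalised at parse time.
MISSING_TOKENS = frozenset({"NA", "./.", ".|.", "NoCall", "No Call", ""})


class HetPolicy(str, enum.Enum):
    """Policies for recoding residual heterozygous calls in an inbred panel."""

    KEEP = "keep"
    TO_MISSING = "to_missing"
    TO_MAJOR_HOM = "to_major_hom"


@dataclass
class MarkerRecord:
    """Metadata for one biallelic SNP marker.

    ``maf`` / ``pic`` hold externally supplied (e.g. published) values and may
    be absent; realised statistics are always recomputed from the calls.
    """

    marker_id: str
    chromosome: str
    position: int
    allele1: str
    allele2: str
    annotation_class: AnnotationClass = AnnotationClass.UNKNOWN
    maf: Optional[float] = None
    pic: Optional[float] = None

    def __post_init__(self) -> None:
        self.allele1 = self.allele1.upper()
        self.allele2 = self.allele2.upper()
        if isinstance(self.annotation_class, str) and not isinstance(
            self.annotation_class, AnnotationClass
        ):
            self.annotation_class = AnnotationClass(self.annotation_class)
        if self.allele1 not in VALID_NUCLEOTIDES or self.allele2 not in VALID_NUCLEOTIDES:
            raise ValidationError(
                f"marker {self.marker_id}: alleles must be A/C/G/T, "
                f"got {self.allele1}/{self.allele2}"
            )
        if self.allele1 == self.allele2:
            raise ValidationError(f"marker {self.marker_id}: alleles must differ")
        if self.position < 1:
            raise ValidationError(
                f"marker {self.marker_id}: position must be >= 1 (1-based coordinates)"
            )
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValidationError(f"marker {self.marker_id}: MAF {self.maf} outside [0, 0.5]")


@dataclass
class CultivarRecord:
    """One cultivar (accession) in the panel."""

    cultivar_id: str
    horticultural_type: HorticulturalType = HorticulturalType.UNKNOWN
    origin: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.horticultural_type, str) and not isinstance(
            self.horticultural_type, HorticulturalType
        ):
            self.horticultural_type = HorticulturalType(self.horticultural_type)


@dataclass
class GenotypeMatrix:
    """Cultivars x markers matrix of biallelic SNP calls.

    ``calls[i, j]`` is the :class:`Call` code of cultivar ``i`` at marker
    ``j``. ``depth`` optionally carries per-call read depths of the same
    shape.
    """

    cultivars: list[CultivarRecord]
    markers: list[MarkerRecord]
    calls: np.ndarray
    depth: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.cultivars), len(self.markers)):
            raise ValidationError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.cultivars)} cultivars, {len(self.markers)} markers)"
            )
        valid = np.isin(self.calls, [c.value for c in Call])
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ValidationError(f"invalid call codes {bad.tolist()}")
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if self.depth.shape != self.calls.shape:
                raise ValidationError("depth shape differs from calls shape")
            if (self.depth < 0).any():
                raise ValidationError("negative read depths")
        for name, ids in (
            ("cultivar", [c.cultivar_id for c in self.cultivars]),
            ("marker", [m.marker_id for m in self.markers]),
        ):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise ValidationError(f"duplicate {name} ids: {dupes}")
        self._marker_index = {m.marker_id: j for j, m in enumerate(self.markers)}
        self._cultivar_index = {c.cultivar_id: i for i, c in enumerate(self.cultivars)}

    # -- basic accessors ---------------------------------------------------

    @property
    def n_cultivars(self) -> int:
        return len(self.cultivars)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def cultivar_ids(self) -> list[str]:
        return [c.cultivar_id for c in self.cultivars]

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def marker_index(self, marker_id: str) -> int:
        try:
            return self._marker_index[marker_id]
        except KeyError:
            raise ValidationError(f"unknown marker id {marker_id!r}") from None

    def cultivar_index(self, cultivar_id: str) -> int:
        try:
            return self._cultivar_index[cultivar_id]
        except KeyError:
            raise ValidationError(f"unknown cultivar id {cultivar_id!r}") from None

    def column(self, marker_id: str) -> np.ndarray:
        return self.calls[:, self.marker_index(marker_id)]

    def row(self, cultivar_id: str) -> np.ndarray:
        return self.calls[self.cultivar_index(cultivar_id), :]

    def marker(self, marker_id: str) -> MarkerRecord:
        return self.markers[self.marker_index(marker_id)]

    # -- subsetting --------------------------------------------------------

    def subset_markers(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        """New matrix restricted to ``marker_ids``, in the given order."""
        idx = [self.marker_index(m) for m in marker_ids]
        return GenotypeMatrix(
            cultivars=list(self.cultivars),
            markers=[self.markers[j] for j in idx],
            calls=self.calls[:, idx].copy(),
            depth=None if self.depth is None else self.depth[:, idx].copy(),
        )

    def subset_cultivars(self, cultivar_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.cultivar_index(c) for c in cultivar_ids]
        return GenotypeMatrix(
            cultivars=[self.cultivars[i] for i in idx],
            markers=list(self.markers),
            calls=self.calls[idx, :].copy(),
            depth=None if self.depth is None else self.depth[idx, :].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            cultivars=list(self.cultivars),
            markers=list(self.markers),
            calls=self.calls.copy(),
            depth=None if self.depth is None else self.depth.copy(),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        """Identity of ids, marker coordinates and calls (depth ignored)."""
        return (
            self.cultivar_ids == other.cultivar_ids
            and self.marker_ids == other.marker_ids
            and [(m.chromosome, m.position) for m in self.markers]
            == [(m.chromosome, m.position) for m in other.markers]
            and np.array_equal(self.calls, other.calls)
        )


def encode_binary(gm: GenotypeMatrix) -> np.ndarray:
    """Expand each marker into two allele-presence columns.

    Column ``2j`` flags presence of marker ``j``'s allele1, column ``2j + 1``
    presence of allele2: HOM1 -> (1, 0), HOM2 -> (0, 1), HET -> (1, 1).
    Missing calls become ``NaN`` in both columns, an explicit code distinct
    from 0 so that absence of an allele is never confused with no data.
    """
    out = np.full((gm.n_cultivars, 2 * gm.n_markers), np.nan)
    calls = gm.calls
    a1 = out[:, 0::2]
    a2 = out[:, 1::2]
    a1[calls == Call.HOM1] = 1.0
    a2[calls == Call.HOM1] = 0.0
    a1[calls == Call.HOM2] = 0.0
    a2[calls == Call.HOM2] = 1.0
    a1[calls == Call.HET] = 1.0
    a2[calls == Call.HET] = 1.0
    return out


def decode_binary(binary: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_binary` (NaN pairs decode to MISSING)."""
    if binary.shape[1] % 2:
        raise ValidationError("binary matrix must have an even number of columns")
    a1 = binary[:, 0::2]
    a2 = binary[:, 1::2]
    calls = np.full(a1.shape, Call.MISSING.value, dtype=np.int8)
    calls[(a1 == 1) & (a2 == 0)] = Call.HOM1
    calls[(a1 == 0) & (a2 == 1)] = Call.HOM2
    calls[(a1 == 1) & (a2 == 1)] = Call.HET
    return calls


def major_homozygote(column: np.ndarray) -> Call:
    """The more frequent homozygote class in a call column (ties -> HOM1)."""
    n1 = int((column == Call.HOM1).sum())
    n2 = int((column == Call.HOM2).sum())
    if n1 == n2:
        log.debug("homozygote tie (%d vs %d); defaulting to HOM1", n1, n2)
        return Call.HOM1
    return Call.HOM1 if n1 > n2 else Call.HOM2


def recode_heterozygotes(
    gm: GenotypeMatrix, policy: HetPolicy | str = HetPolicy.KEEP
) -> GenotypeMatrix:
    """Recode residual heterozygous calls in a principally inbred panel.

    ``keep`` is the identity; ``to_missing`` masks every HET; ``to_major_hom``
    replaces each HET by the homozygote class more frequent at that marker
    (tie -> HOM1, logged). HOM1/HOM2/MISSING entries are never touched.
    """
    policy = HetPolicy(policy)
    if policy is HetPolicy.KEEP:
        return gm.copy()
    out = gm.copy()
    het = out.calls == Call.HET
    if policy is HetPolicy.TO_MISSING:
        out.calls[het] = Call.MISSING
        return out
    for j in range(out.n_markers):
        col = het[:, j]
        if col.any():
            out.calls[col, j] = major_homozygote(gm.calls[:, j])
    return out
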