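"""Readers and writers for genotype matrices, marker metadata and panels.

Supported on-disk forms:

* plain genotype TSV — header row names markers, first column names
  cultivars, cells are ``0``/``1``/``2`` (allele1-homozygote / heterozygote /
  allele2-homozygote) or a missing token;
* Fluidigm-style call tables (TSV or CSV) with ``XX``/``YY``/``XY``/
  ``No Call`` cells;
* minimal VCF v4.2 with a GT FORMAT field (read through cyvcf2);
* marker metadata TSV (marker_id, chromosome, position, allele1, allele2,
  location[, maf, pic]);
* one-marker-per-line panel files.

Missing tokens ``NA``, ``./.``, ``NoCall``, ``No Call`` and the empty string
are normalised at parse time.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ValidationError
from .model import (
    CALL_TO_FLUIDIGM,
    FLUIDIGM_TO_CALL,
    MISSING_TOKENS,
    AnnotationClass,
    Call,
    CultivarRecord,
    GenotypeMatrix,
    MarkerRecord,
)

log = logging.getLogger(__name__)

_MATRIX_TO_CALL = {"0": Call.HOM1, "1": Call.HET, "2": Call.HOM2}
_CALL_TO_MATRIX = {Call.HOM1: "0", Call.HET: "1", Call.HOM2: "2", Call.MISSING: "NA"}


def _placeholder_markers(names: Sequence[str]) -> list[MarkerRecord]:
    # Genotype tables carry no coordinates; synthesise minimal metadata that
    # downstream joins can overwrite via attach_markers().
    return [
        MarkerRecord(marker_id=n, chromosome="un", position=j + 1, allele1="A", allele2="C")
        for j, n in enumerate(names)
    ]


def _delimiter_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_genotype_tsv(
    path: str | Path,
    dialect: str = "matrix",
    markers: Optional[Sequence[MarkerRecord]] = None,
) -> GenotypeMatrix:
    """Read a genotype table (``matrix`` or ``fluidigm`` dialect).

    When ``markers`` is given, metadata records are matched to the header by
    marker id; otherwise placeholder records are synthesised.
    """
    path = Path(path)
    if dialect not in ("matrix", "fluidigm"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    token_map = dict(_MATRIX_TO_CALL) if dialect == "matrix" else dict(FLUIDIGM_TO_CALL)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter=_delimiter_for(path)))
    if not rows:
        raise ParseError(f"{path}: empty file")
    header = rows[0]
    if len(header) < 2:
        raise ParseError(f"{path}: line 1: header names no markers")
    marker_names = [h.strip() for h in header[1:]]
    if len(set(marker_names)) != len(marker_names):
        raise ValidationError(f"{path}: duplicate marker ids in header")
    cultivar_ids: list[str] = []
    calls = np.full((len(rows) - 1, len(marker_names)), Call.MISSING.value, dtype=np.int8)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ParseError(
                f"{path}: line {i}: expected {len(header)} fields, got {len(row)}"
            )
        cid = row[0].strip()
        if cid in cultivar_ids:
            raise ValidationError(f"{path}: line {i}: duplicate cultivar id {cid!r}")
        cultivar_ids.append(cid)
        for j, tok in enumerate(row[1:]):
            tok = tok.strip()
            if tok in MISSING_TOKENS:
                continue
            try:
                calls[i - 2, j] = token_map[tok]
            except KeyError:
                raise ParseError(
                    f"{path}: line {i}: unknown genotype token {tok!r} "
                    f"for dialect {dialect!r}"
                ) from None
    if markers is not None:
        by_id = {m.marker_id: m for m in markers}
        try:
            marker_records = [by_id[n] for n in marker_names]
        except KeyError as e:
            raise ValidationError(f"{path}: header marker {e} absent from metadata") from None
    else:
        marker_records = _placeholder_markers(marker_names)
    return GenotypeMatrix(
        cultivars=[CultivarRecord(cultivar_id=c) for c in cultivar_ids],
        markers=marker_records,
        calls=calls,
    )


def write_genotype_tsv(gm: GenotypeMatrix, path: str | Path, dialect: str = "matrix") -> None:
    """Write a genotype table in the ``matrix`` or ``fluidigm`` dialect."""
    path = Path(path)
    if dialect == "matrix":
        call_map = _CALL_TO_MATRIX
    elif dialect == "fluidigm":
        call_map = CALL_TO_FLUIDIGM
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")
    delim = _delimiter_for(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delim, lineterminator="\n")
        w.writerow(["cultivar_id", *gm.marker_ids])
        for i, cid in enumerate(gm.cultivar_ids):
            w.writerow([cid, *(call_map[Call(v)] for v in gm.calls[i])])


def attach_markers(gm: GenotypeMatrix, markers: Sequence[MarkerRecord]) -> GenotypeMatrix:
    """Replace placeholder marker metadata by matching records on marker id."""
    by_id = {m.marker_id: m for m in markers}
    try:
        records = [by_id[n] for n in gm.marker_ids]
    except KeyError as e:
        raise ValidationError(f"marker {e} absent from metadata") from None
    return GenotypeMatrix(
        cultivars=list(gm.cultivars), markers=records, calls=gm.calls.copy(), depth=gm.depth
    )


# -- marker metadata ------------------------------------------------------


def read_marker_table(path: str | Path) -> list[MarkerRecord]:
    """Read marker metadata TSV (marker_id, chromosome, position, alleles...)."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = {"marker_id", "chromosome", "position", "allele1", "allele2"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            MarkerRecord(
                marker_id=str(row.marker_id),
                chromosome=str(row.chromosome),
                position=int(row.position),
                allele1=str(row.allele1),
                allele2=str(row.allele2),
                annotation_class=AnnotationClass(getattr(row, "location", "unknown")),
                maf=None if pd.isna(getattr(row, "maf", np.nan)) else float(row.maf),
                pic=None if pd.isna(getattr(row, "pic", np.nan)) else float(row.pic),
            )
        )
    return records


def write_marker_table(markers: Sequence[MarkerRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "marker_id": [m.marker_id for m in markers],
            "chromosome": [m.chromosome for m in markers],
            "position": [m.position for m in markers],
            "allele1": [m.allele1 for m in markers],
            "allele2": [m.allele2 for m in markers],
            "location": [m.annotation_class.value for m in markers],
            "maf": [m.maf for m in markers],
            "pic": [m.pic for m in markers],
        }
    ).to_csv(path, sep="\t", index=False)


# -- minimal VCF -----------------------------------------------------------


@dataclass
class VcfReadReport:
    """Counts of records excluded while reading a VCF."""

    n_kept: int = 0
    n_multiallelic: int = 0
    n_non_snp: int = 0

    @property
    def n_skipped(self) -> int:
        return self.n_multiallelic + self.n_non_snp


def read_vcf_minimal(path: str | Path, with_report: bool = False):
    """Read a GT-only VCF into a :class:`GenotypeMatrix`.

    REF maps to allele1 and ALT to allele2, so 0/0 -> HOM1, 1/1 -> HOM2,
    0/1 or 1/0 (phased or not) -> HET and ./. -> MISSING. Multiallelic and
    non-SNP (indel) records are skipped with a warning and counted in the
    report. Positions stay 1-based as in the VCF.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no samples")
    report = VcfReadReport()
    markers: list[MarkerRecord] = []
    columns: list[np.ndarray] = []
    first = True
    for v in vcf:
        if first:
            if "GT" not in (v.FORMAT or []):
                raise FormatError(f"{path}: records carry no GT field")
            first = False
        if len(v.ALT) != 1:
            report.n_multiallelic += 1
            log.warning("%s:%s skipped: multiallelic", v.CHROM, v.POS)
            continue
        ref, alt = v.REF.upper(), v.ALT[0].upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
            report.n_non_snp += 1
            log.warning("%s:%s skipped: not a SNP (%s>%s)", v.CHROM, v.POS, ref, alt)
            continue
        col = np.full(len(samples), Call.MISSING.value, dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                continue
            col[i] = Call.HOM1 if a + b == 0 else (Call.HOM2 if a + b == 2 else Call.HET)
        markers.append(
            MarkerRecord(
                marker_id=v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}",
                chromosome=v.CHROM,
                position=v.POS,
                allele1=ref,
                allele2=alt,
            )
        )
        columns.append(col)
        report.n_kept += 1
    calls = (
        np.column_stack(columns)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(
        cultivars=[CultivarRecord(cultivar_id=s) for s in samples],
        markers=markers,
        calls=calls,
    )
    return (gm, report) if with_report else gm


_GT_STRINGS = {Call.HOM1: "0/0", Call.HET: "0/1", Call.HOM2: "1/1", Call.MISSING: "./."}


def write_vcf_minimal(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a GT-only VCF v4.2 (allele1 as REF, allele2 as ALT)."""
    path = Path(path)
    chroms = list(dict.fromkeys(m.chromosome for m in gm.markers))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=snpcore\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.cultivar_ids) + "\n")
        order = sorted(
            range(gm.n_markers),
            key=lambda j: (chroms.index(gm.markers[j].chromosome), gm.markers[j].position),
        )
        for j in order:
            m = gm.markers[j]
            gts = "\t".join(_GT_STRINGS[Call(v)] for v in gm.calls[:, j])
            fh.write(
                f"{m.chromosome}\t{m.position}\t{m.marker_id}\t{m.allele1}\t{m.allele2}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


# -- panels ----------------------------------------------------------------


def read_panel(path: str | Path) -> list[str]:
    """Read a one-marker-id-per-line panel file (blank lines, '#' comments ignored)."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_panel(marker_ids: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(marker_ids) + "\n", encoding="utf-8")
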