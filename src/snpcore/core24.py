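"""Published 24-marker lettuce core panel metadata.

Marker ids, chromosome, 1-based position, allele pair, genomic-context class
and the published minor-allele-frequency / PIC values of the 24 core SNP
markers developed for Korean commercial lettuce cultivar identification.
MAF/PIC are as printed (2 decimals); realised statistics on any genotype
matrix are always recomputed from the calls.
"""

from __future__ import annotations

from .model import AnnotationClass, MarkerRecord

_ROWS = [
    # (id, chrom, position, allele1, allele2, location, maf, pic)
    ("SNP001", "chr1", 11945871, "A", "G", "CDS", 0.49, 0.37),
    ("SNP002", "chr1", 13440345, "G", "C", "CDS", 0.48, 0.37),
    ("SNP005", "chr1", 44033573, "C", "T", "intron", 0.22, 0.28),
    ("SNP010", "chr1", 69220682, "C", "A", "CDS", 0.26, 0.31),
    ("SNP025", "chr2", 91614666, "T", "C", "CDS", 0.22, 0.28),
    ("SNP038", "chr2", 117891323, "C", "T", "intergenic", 0.44, 0.37),
    ("SNP057", "chr3", 68819733, "G", "T", "CDS", 0.42, 0.37),
    ("SNP063", "chr3", 144267704, "A", "G", "intergenic", 0.21, 0.28),
    ("SNP079", "chr4", 226988250, "G", "A", "CDS", 0.49, 0.37),
    ("SNP082", "chr5", 8785574, "A", "G", "intergenic", 0.16, 0.23),
    ("SNP084", "chr5", 36437007, "C", "T", "intron", 0.43, 0.37),
    ("SNP120", "chr5", 284742114, "C", "T", "CDS", 0.32, 0.34),
    ("SNP133", "chr7", 112702864, "T", "G", "CDS", 0.39, 0.36),
    ("SNP135", "chr7", 133109575, "C", "A", "UTR", 0.42, 0.37),
    ("SNP139", "chr8", 32465725, "G", "A", "CDS", 0.45, 0.37),
    ("SNP140", "chr8", 32465762, "A", "G", "CDS", 0.45, 0.37),
    ("SNP141", "chr8", 32467169, "G", "A", "CDS", 0.18, 0.26),
    ("SNP147", "chr8", 76000585, "C", "T", "CDS", 0.40, 0.37),
    ("SNP148", "chr8", 78404531, "C", "T", "CDS", 0.32, 0.34),
    ("SNP158", "chr8", 208004895, "C", "T", "CDS", 0.25, 0.31),
    ("SNP166", "chr9", 32125232, "A", "G", "CDS", 0.36, 0.36),
    ("SNP177", "chr9", 77623861, "G", "A", "CDS", 0.36, 0.36),
    ("SNP180", "chr9", 133535460, "G", "A", "CDS", 0.26, 0.31),
    ("SNP181", "chr9", 135041719, "C", "T", "CDS", 0.26, 0.31),
]


def core24_markers() -> list[MarkerRecord]:
    """Fresh :class:`MarkerRecord` objects for the published core-24 panel."""
    return [
        MarkerRecord(
            marker_id=mid,
            chromosome=chrom,
            position=pos,
            allele1=a1,
            allele2=a2,
            annotation_class=AnnotationClass(loc),
            maf=maf,
            pic=pic,
        )
        for mid, chrom, pos, a1, a2, loc, maf, pic in _ROWS
    ]


#: Published per-marker minor allele frequencies, in panel order.
CORE24_MAFS = tuple(r[6] for r in _ROWS)

#: Published per-marker PIC values, in panel order.
CORE24_PICS = tuple(r[7] for r in _ROWS)
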