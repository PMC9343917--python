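"""Synthetic inbred-cultivar panel generator.

The generator emulates the statistical structure of a selfing-crop diversity
panel genotyped on a biallelic SNP assay: mostly homozygous cultivars drawn
from a few subpopulations, with residual heterozygous calls and missing data
as thin independent noise layers on top.

Population structure follows the Balding–Nichols model: each marker has an
ancestral allele frequency p drawn uniformly from the ancestral MAF range,
and each subpopulation draws its own frequency from
``Beta(p (1 - F) / F, (1 - p)(1 - F) / F)`` with F the fixation index
(FST). Cultivars are fully homozygous draws from their subpopulation
frequency — heterozygosity enters only as planted noise, matching a
principally self-pollinated crop. Planted duplicate groups copy a
progenitor's full profile *before* noise, providing ground truth for the
unique-profile discrimination rule.

All randomness flows through one explicit seed; no global RNG state is
touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core24 import core24_markers
from .errors import ValidationError
from .model import Call, CultivarRecord, GenotypeMatrix, MarkerRecord

_NUCS = np.array(list("ACGT"))


@dataclass
class PanelSpec:
    """Study conditions for one synthetic panel.

    Defaults mirror a ~95-cultivar commercial lettuce panel: three
    subpopulations, nine chromosomes, biallelic markers with ancestral MAF in
    [0.05, 0.50], a residual heterozygous-call rate of 0.25% and a low
    missing-call rate well under the 30% QC ceiling.
    """

    n_subpops: int = 3
    cultivars_per_subpop: Sequence[int] = (32, 32, 31)
    n_markers: int = 500
    n_chromosomes: int = 9
    fst: float = 0.2
    ancestral_maf_range: tuple[float, float] = (0.05, 0.50)
    residual_het_rate: float = 0.0025
    missing_rate: float = 0.02
    duplicate_groups: Sequence[tuple[int, int]] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cultivars_per_subpop) != self.n_subpops:
            raise ValidationError(
                f"cultivars_per_subpop has {len(self.cultivars_per_subpop)} entries "
                f"for {self.n_subpops} subpopulations"
            )
        if not 0.0 < self.fst < 1.0:
            raise ValidationError("fst must be in (0, 1)")
        for name in ("residual_het_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValidationError(f"{name} must be in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValidationError("ancestral_maf_range must satisfy 0 < lo <= hi <= 0.5")
        for sp, size in self.duplicate_groups:
            if not 0 <= sp < self.n_subpops:
                raise ValidationError(f"duplicate group references subpopulation {sp}")
            if size < 2:
                raise ValidationError("duplicate groups must have size >= 2")

    @property
    def n_cultivars(self) -> int:
        return int(sum(self.cultivars_per_subpop))


@dataclass
class PanelTruth:
    """Latent quantities behind a generated panel."""

    ancestral_freq: np.ndarray  # (n_markers,) allele2 frequency
    subpop_freq: np.ndarray  # (n_subpops, n_markers) allele2 frequency
    subpop_of: list[int]  # per cultivar
    duplicate_groups: list[list[str]]
    het_mask: np.ndarray  # planted heterozygous calls
    missing_mask: np.ndarray  # planted missing calls

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "ancestral_freq": self.ancestral_freq.tolist(),
                    "subpop_freq": self.subpop_freq.tolist(),
                    "subpop_of": self.subpop_of,
                    "duplicate_groups": self.duplicate_groups,
                    "n_planted_het": int(self.het_mask.sum()),
                    "n_planted_missing": int(self.missing_mask.sum()),
                },
                indent=2,
            ),
            encoding="utf-8",
        )


def _random_markers(spec: PanelSpec, rng: np.random.Generator) -> list[MarkerRecord]:
    markers = []
    per_chrom = np.array_split(np.arange(spec.n_markers), spec.n_chromosomes)
    mid = 0
    for c, idx in enumerate(per_chrom, start=1):
        k = len(idx)
        if k == 0:
            continue
        # uniform positions without replacement, sorted; spacing realism
        # (and linkage) is deliberately not modelled
        positions = np.sort(rng.choice(np.arange(1, 10_000_000), size=k, replace=False))
        for pos in positions:
            mid += 1
            a1, a2 = rng.choice(4, size=2, replace=False)
            markers.append(
                MarkerRecord(
                    marker_id=f"M{mid:04d}",
                    chromosome=f"chr{c}",
                    position=int(pos),
                    allele1=str(_NUCS[a1]),
                    allele2=str(_NUCS[a2]),
                )
            )
    return markers


def generate_panel(spec: PanelSpec) -> tuple[GenotypeMatrix, PanelTruth]:
    """Generate one synthetic panel and its ground truth.

    Order of construction: subpopulation frequencies, fully homozygous
    cultivar draws, duplicate-group profile copies, then planted HET and
    MISSING noise (a call drawn for both becomes MISSING).
    """
    rng = np.random.default_rng(spec.seed)
    n_c, n_m, n_s = spec.n_cultivars, spec.n_markers, spec.n_subpops

    lo, hi = spec.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=n_m)
    f = spec.fst
    a = p_anc * (1 - f) / f
    b = (1 - p_anc) * (1 - f) / f
    subpop_freq = rng.beta(a, b, size=(n_s, n_m))

    subpop_of: list[int] = []
    for s, k in enumerate(spec.cultivars_per_subpop):
        subpop_of.extend([s] * int(k))

    calls = np.empty((n_c, n_m), dtype=np.int8)
    for i, s in enumerate(subpop_of):
        hom2 = rng.random(n_m) < subpop_freq[s]
        calls[i] = np.where(hom2, Call.HOM2.value, Call.HOM1.value)

    cultivar_ids = [f"LS{i + 1:03d}" for i in range(n_c)]

    # plant duplicate groups: copy a progenitor's profile before noise
    members_by_subpop: dict[int, list[int]] = {}
    for i, s in enumerate(subpop_of):
        members_by_subpop.setdefault(s, []).append(i)
    used: set[int] = set()
    duplicate_groups: list[list[str]] = []
    for sp, size in spec.duplicate_groups:
        avail = [i for i in members_by_subpop[sp] if i not in used]
        if len(avail) < size:
            raise ValidationError(
                f"subpopulation {sp} has {len(avail)} unused cultivars, "
                f"cannot plant a duplicate group of {size}"
            )
        group = avail[:size]
        used.update(group)
        for i in group[1:]:
            calls[i] = calls[group[0]]
        duplicate_groups.append([cultivar_ids[i] for i in group])

    het_mask = rng.random((n_c, n_m)) < spec.residual_het_rate
    missing_mask = rng.random((n_c, n_m)) < spec.missing_rate
    het_mask &= ~missing_mask
    calls[het_mask] = Call.HET.value
    calls[missing_mask] = Call.MISSING.value

    gm = GenotypeMatrix(
        cultivars=[CultivarRecord(cultivar_id=c) for c in cultivar_ids],
        markers=_random_markers(spec, rng),
        calls=calls,
    )
    truth = PanelTruth(
        ancestral_freq=p_anc,
        subpop_freq=subpop_freq,
        subpop_of=subpop_of,
        duplicate_groups=duplicate_groups,
        het_mask=het_mask,
        missing_mask=missing_mask,
    )
    return gm, truth


def fixture_table4(n_cultivars: int = 95, seed: int = 0) -> GenotypeMatrix:
    """Genotype matrix realising the published core-24 panel's MAFs.

    Marker metadata is the published core-24 panel. For each marker the
    number of allele2 (minor) homozygotes is the published MAF times
    ``n_cultivars`` rounded to the nearest achievable count — all calls are
    homozygous, matching an inbred panel — and the genotype-to-cultivar
    assignment is shuffled by the seed. With the default ``n_cultivars=95``
    the realised MAFs reproduce the published values to within 1/190.
    """
    if n_cultivars < 2:
        raise ValidationError("need at least 2 cultivars")
    rng = np.random.default_rng(seed)
    markers = core24_markers()
    calls = np.empty((n_cultivars, len(markers)), dtype=np.int8)
    for j, m in enumerate(markers):
        k = int(round(m.maf * n_cultivars))
        col = np.full(n_cultivars, Call.HOM1.value, dtype=np.int8)
        col[:k] = Call.HOM2.value
        rng.shuffle(col)
        calls[:, j] = col
    return GenotypeMatrix(
        cultivars=[CultivarRecord(cultivar_id=f"LS{i + 1:03d}") for i in range(n_cultivars)],
        markers=markers,
        calls=calls,
    )
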