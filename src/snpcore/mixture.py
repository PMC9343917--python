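"""Simulated equal-mass DNA mixtures for heterozygote validation.

Mixing equal amounts of DNA from two fully homozygous cultivars should
produce a heterozygous call exactly at the loci where the parents carry
opposite homozygotes (the *informative* loci). The simulation scores how
often that expectation is met when each informative locus can independently
fail and be miscalled as a homozygote — the kind of shortfall that in real
assays comes from technical limitations, incomplete fixation of cultivars or
seed-purity problems. Pooled heterozygote concordance therefore converges to
``1 - assay_failure_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .model import Call, GenotypeMatrix

_EXPECTED = {
    frozenset((Call.HOM1, Call.HOM2)): Call.HET,
}


def expected_mixture_call(call_a: Call | int, call_b: Call | int) -> Call:
    """Expected genotype of an equal-mass mixture of two samples.

    Opposite homozygotes yield HET; identical calls yield themselves; any
    heterozygous parent yields HET; a missing parent propagates MISSING.
    The operation is commutative.
    """
    a, b = Call(call_a), Call(call_b)
    if Call.MISSING in (a, b):
        return Call.MISSING
    if Call.HET in (a, b):
        return Call.HET
    if a == b:
        return a
    return Call.HET


@dataclass
class MixtureResult:
    """Heterozygote concordance for one mixed cultivar pair."""

    pair: tuple[str, str]
    expected_calls: np.ndarray
    observed_calls: np.ndarray
    n_informative: int
    n_het_called: int

    @property
    def het_concordance(self) -> Optional[float]:
        """HET calls over informative loci; None when no locus is informative."""
        if self.n_informative == 0:
            return None
        return self.n_het_called / self.n_informative


def simulate_mixture_experiment(
    gm: GenotypeMatrix,
    pairs: Sequence[tuple[str, str]],
    panel: Optional[Sequence[str]] = None,
    assay_failure_rate: float = 0.0,
    seed: Optional[int] = None,
) -> list[MixtureResult]:
    """Simulate mixture genotyping for a list of cultivar pairs.

    Informative loci (parents opposite homozygotes, both called) are
    miscalled as a random parental homozygote with probability
    ``assay_failure_rate``, independently per locus (seeded).
    """
    if not pairs:
        raise ValidationError("empty pairs list")
    if not 0.0 <= assay_failure_rate < 1.0:
        raise ValidationError("assay_failure_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    sub = gm if panel is None else gm.subset_markers(panel)
    results = []
    for a, b in pairs:
        ca = sub.calls[sub.cultivar_index(a)]
        cb = sub.calls[sub.cultivar_index(b)]
        expected = np.array(
            [expected_mixture_call(x, y).value for x, y in zip(ca, cb)], dtype=np.int8
        )
        informative = ((ca == Call.HOM1) & (cb == Call.HOM2)) | (
            (ca == Call.HOM2) & (cb == Call.HOM1)
        )
        observed = expected.copy()
        fail = informative & (rng.random(len(expected)) < assay_failure_rate)
        if fail.any():
            # a failed assay reports one of the parental homozygotes at random
            hom = np.where(rng.random(len(expected)) < 0.5, Call.HOM1, Call.HOM2)
            observed[fail] = hom[fail]
        n_informative = int(informative.sum())
        n_het_called = int((observed[informative] == Call.HET).sum())
        results.append(
            MixtureResult(
                pair=(a, b),
                expected_calls=expected,
                observed_calls=observed,
                n_informative=n_informative,
                n_het_called=n_het_called,
            )
        )
    return results


def pooled_het_concordance(results: Sequence[MixtureResult]) -> Optional[float]:
    """Heterozygote concordance pooled over all informative loci of all pairs."""
    n_inf = sum(r.n_informative for r in results)
    if n_inf == 0:
        return None
    return sum(r.n_het_called for r in results) / n_inf


def mixture_report_frame(results: Sequence[MixtureResult]):
    import pandas as pd

    return pd.DataFrame(
        {
            "cultivar_a": [r.pair[0] for r in results],
            "cultivar_b": [r.pair[1] for r in results],
            "n_informative": [r.n_informative for r in results],
            "n_het_called": [r.n_het_called for r in results],
            "het_concordance": [r.het_concordance for r in results],
        }
    )
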