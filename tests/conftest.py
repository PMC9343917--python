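import numpy as np
import pytest

from snpcore import (
    Call,
    CultivarRecord,
    GenotypeMatrix,
    MarkerRecord,
    PanelSpec,
    generate_panel,
)

M = Call.MISSING.value
H1 = Call.HOM1.value
H2 = Call.HOM2.value
HT = Call.HET.value


def make_matrix(calls, marker_meta=None, cultivar_ids=None, depth=None):
    """Build a GenotypeMatrix from a nested list of call codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n_c, n_m = calls.shape
    if marker_meta is None:
        marker_meta = [(f"M{j+1:03d}", "chr1", 1000 * (j + 1), "A", "G") for j in range(n_m)]
    markers = [
        MarkerRecord(marker_id=mid, chromosome=c, position=p, allele1=a1, allele2=a2)
        for mid, c, p, a1, a2 in marker_meta
    ]
    if cultivar_ids is None:
        cultivar_ids = [f"LS{i+1:03d}" for i in range(n_c)]
    return GenotypeMatrix(
        cultivars=[CultivarRecord(cultivar_id=c) for c in cultivar_ids],
        markers=markers,
        calls=calls,
        depth=depth,
    )


@pytest.fixture(scope="session")
def synth_panel():
    """A seeded 95-cultivar / 500-marker panel with light noise."""
    spec = PanelSpec(seed=7)
    gm, truth = generate_panel(spec)
    return gm, truth, spec


@pytest.fixture(scope="session")
def clean_panel_with_duplicates():
    """Noise-free panel with planted duplicate groups (planted-truth oracle)."""
    spec = PanelSpec(
        seed=11,
        n_markers=294,
        residual_het_rate=0.0,
        missing_rate=0.0,
        duplicate_groups=((0, 4), (1, 3), (1, 2), (2, 2)),
    )
    gm, truth = generate_panel(spec)
    return gm, truth, spec
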