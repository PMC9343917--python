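"""Cultivar distinguishability and core-panel selection.

Two cultivars are *separated* by a panel when at least ``min_diff`` loci are
called in both and carry different genotypes; loci missing in either cultivar
are ignored. A cultivar is *identified* when its multilocus profile is shared
by no other cultivar under that rule — the operational meaning of "this panel
distinguishes N of the M cultivars" in DUS-style fingerprinting.

Because missingness can make "not separated" non-transitive (a ~ b and b ~ c
while a and c differ), duplicate groups are the connected components of the
not-separated graph: a conservative merge for reference-variety screening,
logged whenever the relation is genuinely non-transitive.

Panel selection offers two strategies: ``pic_rank`` (highest PIC first, with
optional round-robin chromosome balancing and a minimum physical spacing) and
``set_cover`` (greedy cover of not-yet-separated cultivar pairs).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConstraintError, UndefinedValueError, ValidationError
from .model import Call, GenotypeMatrix
from .qc import allele_frequencies

log = logging.getLogger(__name__)


@dataclass
class SeparationResult:
    """Outcome of applying the unique-profile rule to a panel."""

    panel: list[str]
    n_cultivars: int
    n_identified: int
    identification_rate: float
    duplicate_groups: list[list[str]]
    n_separated_pairs: int
    n_incomparable_pairs: int

    def to_dict(self) -> dict:
        return {
            "panel_size": len(self.panel),
            "panel": self.panel,
            "n_cultivars": self.n_cultivars,
            "n_identified": self.n_identified,
            "identification_rate": self.identification_rate,
            "duplicate_groups": self.duplicate_groups,
            "n_separated_pairs": self.n_separated_pairs,
            "n_incomparable_pairs": self.n_incomparable_pairs,
        }


@dataclass
class PanelSelection:
    """Nested core panels with per-size separation results."""

    strategy: str
    sizes: list[int]
    panels: dict[int, list[str]]
    results: dict[int, SeparationResult]

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "sizes": self.sizes,
            "panels": {str(k): v for k, v in self.panels.items()},
            "results": {str(k): v.to_dict() for k, v in self.results.items()},
        }


def _panel_calls(gm: GenotypeMatrix, panel: Optional[Sequence[str]]) -> np.ndarray:
    if panel is None:
        return gm.calls
    if len(panel) == 0:
        raise ValidationError("empty marker panel")
    idx = [gm.marker_index(m) for m in panel]
    return gm.calls[:, idx]


def _diff_count(calls: np.ndarray, i: int, j: int) -> int:
    a, b = calls[i], calls[j]
    both = (a != Call.MISSING) & (b != Call.MISSING)
    return int(((a != b) & both).sum())


def pair_separated(
    gm: GenotypeMatrix,
    cultivar_a: str,
    cultivar_b: str,
    panel: Optional[Sequence[str]] = None,
    min_diff: int = 1,
) -> bool:
    """True iff >= ``min_diff`` mutually called panel loci differ."""
    if min_diff < 1:
        raise ValidationError("min_diff must be >= 1")
    calls = _panel_calls(gm, panel)
    return (
        _diff_count(calls, gm.cultivar_index(cultivar_a), gm.cultivar_index(cultivar_b))
        >= min_diff
    )


def _pairwise_diff_matrix(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(diff_counts, comparable_counts) over all cultivar pairs."""
    n = calls.shape[0]
    called = calls != Call.MISSING
    diffs = np.zeros((n, n), dtype=np.int32)
    comp = np.zeros((n, n), dtype=np.int32)
    for i in range(n):
        both = called[i] & called
        diffs[i] = ((calls[i] != calls) & both).sum(axis=1)
        comp[i] = both.sum(axis=1)
    return diffs, comp


def separation_summary(
    gm: GenotypeMatrix, panel: Optional[Sequence[str]] = None, min_diff: int = 1
) -> SeparationResult:
    """Unique-profile identification summary for a panel.

    Duplicate groups are connected components of the not-separated graph;
    cultivars in singleton components are counted as identified.
    """
    if min_diff < 1:
        raise ValidationError("min_diff must be >= 1")
    calls = _panel_calls(gm, panel)
    n = gm.n_cultivars
    diffs, comp = _pairwise_diff_matrix(calls)
    separated = diffs >= min_diff
    np.fill_diagonal(separated, True)
    # union-find over the not-separated relation
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    n_separated_pairs = 0
    n_incomparable_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            if comp[i, j] == 0:
                n_incomparable_pairs += 1
            if separated[i, j]:
                n_separated_pairs += 1
            else:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups_idx: dict[int, list[int]] = {}
    for i in range(n):
        groups_idx.setdefault(find(i), []).append(i)
    ids = gm.cultivar_ids
    duplicate_groups = []
    for members in groups_idx.values():
        if len(members) < 2:
            continue
        if any(
            separated[a, b] for a, b in itertools.combinations(members, 2)
        ):
            log.warning(
                "not-separated relation is non-transitive within group %s; "
                "merged by transitive closure",
                [ids[m] for m in members],
            )
        duplicate_groups.append(sorted(ids[m] for m in members))
    duplicate_groups.sort()
    n_identified = n - sum(len(g) for g in duplicate_groups)
    return SeparationResult(
        panel=list(panel) if panel is not None else list(gm.marker_ids),
        n_cultivars=n,
        n_identified=n_identified,
        identification_rate=n_identified / n if n else 0.0,
        duplicate_groups=duplicate_groups,
        n_separated_pairs=n_separated_pairs,
        n_incomparable_pairs=n_incomparable_pairs,
    )


# -- PIC-ranked selection --------------------------------------------------


def _marker_pic(gm: GenotypeMatrix) -> np.ndarray:
    from .diversity import pic as _pic

    out = np.zeros(gm.n_markers)
    for j, m in enumerate(gm.markers):
        try:
            out[j] = _pic(allele_frequencies(gm, m.marker_id))
        except UndefinedValueError:
            out[j] = -1.0  # all-missing markers rank last
    return out


def _chrom_order(gm: GenotypeMatrix) -> dict[str, int]:
    order: dict[str, int] = {}
    for m in gm.markers:
        order.setdefault(m.chromosome, len(order))
    return order


def _spacing_ok(
    gm: GenotypeMatrix, j: int, chosen: list[int], min_spacing_bp: int
) -> bool:
    if min_spacing_bp <= 0:
        return True
    mj = gm.markers[j]
    for k in chosen:
        mk = gm.markers[k]
        if mk.chromosome == mj.chromosome and abs(mk.position - mj.position) < min_spacing_bp:
            return False
    return True


def select_pic_rank(
    gm: GenotypeMatrix,
    size: int,
    balance_chromosomes: bool = True,
    min_spacing_bp: int = 0,
) -> list[str]:
    """Select ``size`` markers by descending PIC.

    With chromosome balancing, chromosomes are visited round-robin in
    metadata order and each contributes its best remaining marker per round;
    a ``min_spacing_bp`` floor skips markers too close to an already chosen
    marker on the same chromosome. Ties break by (chromosome order,
    position, marker id).
    """
    if size > gm.n_markers:
        raise ConstraintError(f"requested {size} markers but only {gm.n_markers} available")
    if size < 1:
        raise ValidationError("size must be >= 1")
    pic_vals = _marker_pic(gm)
    corder = _chrom_order(gm)

    def sort_key(j: int):
        m = gm.markers[j]
        return (-pic_vals[j], corder[m.chromosome], m.position, m.marker_id)

    chosen: list[int] = []
    if not balance_chromosomes:
        for j in sorted(range(gm.n_markers), key=sort_key):
            if _spacing_ok(gm, j, chosen, min_spacing_bp):
                chosen.append(j)
                if len(chosen) == size:
                    break
    else:
        queues: dict[str, list[int]] = {c: [] for c in corder}
        for j in sorted(range(gm.n_markers), key=sort_key):
            queues[gm.markers[j].chromosome].append(j)
        active = [c for c in corder if queues[c]]
        while len(chosen) < size and active:
            progressed = False
            for c in list(active):
                if len(chosen) == size:
                    break
                q = queues[c]
                while q:
                    j = q.pop(0)
                    if _spacing_ok(gm, j, chosen, min_spacing_bp):
                        chosen.append(j)
                        progressed = True
                        break
                if not q:
                    active.remove(c)
            if not progressed and len(chosen) < size:
                break
    if len(chosen) < size:
        raise ConstraintError(
            f"only {len(chosen)} of {size} markers selectable under "
            f"min_spacing_bp={min_spacing_bp}"
        )
    return [gm.markers[j].marker_id for j in chosen]


# -- greedy set cover ------------------------------------------------------


def select_set_cover(
    gm: GenotypeMatrix, target_size: Optional[int] = None
) -> list[str]:
    """Greedy panel covering cultivar-pair separations.

    Repeatedly adds the marker separating the most not-yet-separated
    comparable pairs (ties -> higher PIC, then chromosome order, position,
    id). With ``target_size`` None, stops once every pair separable by any
    single marker is covered — the same pairs the full panel separates under
    the one-locus rule.
    """
    n = gm.n_cultivars
    pairs = list(itertools.combinations(range(n), 2))
    called = gm.calls != Call.MISSING
    # coverage[j, p]: marker j separates pair p
    cover = np.zeros((gm.n_markers, len(pairs)), dtype=bool)
    for p, (i, k) in enumerate(pairs):
        both = called[i] & called[k]
        cover[:, p] = (gm.calls[i] != gm.calls[k]) & both
    pic_vals = _marker_pic(gm)
    corder = _chrom_order(gm)
    uncovered = cover.any(axis=0)
    chosen: list[int] = []
    available = set(range(gm.n_markers))
    while available:
        if target_size is not None and len(chosen) >= target_size:
            break
        if target_size is None and not uncovered.any():
            break
        gains = {j: int((cover[j] & uncovered).sum()) for j in available}
        best = min(
            available,
            key=lambda j: (
                -gains[j],
                -pic_vals[j],
                corder[gm.markers[j].chromosome],
                gm.markers[j].position,
                gm.markers[j].marker_id,
            ),
        )
        if target_size is None and gains[best] == 0:
            break
        chosen.append(best)
        available.remove(best)
        uncovered &= ~cover[best]
    return [gm.markers[j].marker_id for j in chosen]


# -- nested panels ---------------------------------------------------------

DEFAULT_NESTED_SIZES = (192, 96, 48, 24, 18, 12, 9, 6)


def nested_panels(
    gm: GenotypeMatrix,
    strategy: str = "pic_rank",
    sizes: Sequence[int] = DEFAULT_NESTED_SIZES,
    min_diff: int = 1,
    **strategy_kwargs,
) -> PanelSelection:
    """Select nested core panels of decreasing sizes.

    The largest panel is selected from the full matrix; each smaller panel is
    selected by re-running the strategy restricted to the next larger panel,
    which guarantees nesting by construction. A per-size
    :class:`SeparationResult` is attached.
    """
    sizes = list(sizes)
    if sizes != sorted(sizes, reverse=True) or len(set(sizes)) != len(sizes):
        raise ValidationError("sizes must be strictly decreasing")
    if sizes and sizes[0] > gm.n_markers:
        raise ConstraintError(
            f"largest panel size {sizes[0]} exceeds marker count {gm.n_markers}"
        )
    if strategy not in ("pic_rank", "set_cover"):
        raise ValidationError(f"unknown strategy {strategy!r}")
    panels: dict[int, list[str]] = {}
    results: dict[int, SeparationResult] = {}
    current = gm
    for size in sizes:
        if strategy == "pic_rank":
            panel = select_pic_rank(current, size, **strategy_kwargs)
        else:
            panel = select_set_cover(current, target_size=size)
        panels[size] = panel
        results[size] = separation_summary(gm, panel, min_diff=min_diff)
        current = gm.subset_markers(panel)
    return PanelSelection(strategy=strategy, sizes=sizes, panels=panels, results=results)


# -- reference-variety suggestion ------------------------------------------


def suggest_reference_varieties(
    gm: GenotypeMatrix,
    query_cultivar: str,
    panel: Optional[Sequence[str]] = None,
    k: int = 5,
) -> list[tuple[str, float]]:
    """Rank candidate reference varieties by genetic similarity to a query.

    Similarity is 1 minus the simple-matching distance over mutually called
    panel loci. Cultivars sharing no called locus with the query are
    excluded. Ties rank by cultivar id.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    calls = _panel_calls(gm, panel)
    qi = gm.cultivar_index(query_cultivar)
    q = calls[qi]
    if not (q != Call.MISSING).any():
        raise UndefinedValueError(f"query {query_cultivar} has no called panel loci")
    out = []
    for i, cid in enumerate(gm.cultivar_ids):
        if i == qi:
            continue
        both = (q != Call.MISSING) & (calls[i] != Call.MISSING)
        n_both = int(both.sum())
        if n_both == 0:
            continue
        n_diff = int(((q != calls[i]) & both).sum())
        out.append((cid, 1.0 - n_diff / n_both))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out[:k]
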