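"""End-to-end pipeline orchestration.

Stage order follows the analysis it automates: QC filtering -> diversity
statistics -> nested core-panel selection -> discrimination -> clustering
(tree + PCA) -> optional mixture validation. Every run writes a manifest
recording inputs, the configuration hash, the seed and package versions, so
reruns with identical config and inputs produce byte-identical
(non-timestamped) outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__ as _pkg_version
from .discrimination import nested_panels, separation_summary
from .diversity import marker_summary
from .errors import PipelineError, ValidationError
from .io import (
    read_genotype_tsv,
    read_marker_table,
    attach_markers,
    write_genotype_tsv,
    write_marker_table,
    write_panel,
)
from .mixture import mixture_report_frame, pooled_het_concordance, simulate_mixture_experiment
from .model import GenotypeMatrix, HetPolicy, recode_heterozygotes
from .phylo import (
    jaccard_distance_matrix,
    neighbor_joining,
    pca,
    simple_matching_distance_matrix,
    to_newick,
)
from .qc import FilterConfig, apply_filters
from .simulate import PanelSpec, generate_panel

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one of ``genotypes`` (path to a genotype table) or ``synthetic``
    (a :class:`PanelSpec`) must be provided.
    """

    out_dir: str | Path
    genotypes: Optional[str | Path] = None
    dialect: str = "matrix"
    markers: Optional[str | Path] = None
    synthetic: Optional[PanelSpec] = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    het_policy: HetPolicy = HetPolicy.KEEP
    strategy: str = "pic_rank"
    sizes: Sequence[int] = (24, 18, 12)
    min_diff: int = 1
    distance: str = "jaccard"
    run_tree: bool = True
    run_pca: bool = True
    n_mixture_pairs: int = 0
    assay_failure_rate: float = 0.0
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.genotypes is None) == (self.synthetic is None):
            raise ValidationError("provide exactly one of genotypes / synthetic")
        if self.genotypes is not None and not Path(self.genotypes).exists():
            raise ValidationError(f"genotype file not found: {self.genotypes}")
        if self.markers is not None and not Path(self.markers).exists():
            raise ValidationError(f"marker metadata file not found: {self.markers}")
        if self.distance not in ("jaccard", "simple_matching"):
            raise ValidationError(f"unknown distance {self.distance!r}")

    def to_dict(self) -> dict:
        # out_dir is where the run lands, not part of what it computes; it is
        # omitted so reruns into different directories hash identically
        d = dataclasses.asdict(self)
        del d["out_dir"]
        if self.genotypes is not None:
            d["genotypes"] = str(self.genotypes)
        if self.markers is not None:
            d["markers"] = str(self.markers)
        d["het_policy"] = HetPolicy(self.het_policy).value
        d["sizes"] = list(self.sizes)
        if self.synthetic is not None:
            d["synthetic"]["cultivars_per_subpop"] = list(
                self.synthetic.cultivars_per_subpop
            )
            d["synthetic"]["duplicate_groups"] = [
                list(g) for g in self.synthetic.duplicate_groups
            ]
        return d


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_input(cfg: PipelineConfig) -> GenotypeMatrix:
    if cfg.synthetic is not None:
        gm, _truth = generate_panel(cfg.synthetic)
        return gm
    gm = read_genotype_tsv(cfg.genotypes, dialect=cfg.dialect)
    if cfg.markers is not None:
        gm = attach_markers(gm, read_marker_table(cfg.markers))
    return gm


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns the manifest dict (also written to disk)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "versions": {"snpcore": _pkg_version, "numpy": np.__version__},
        "stages": [],
        "status": "incomplete",
    }
    stage = "load"
    try:
        gm = _load_input(cfg)
        if cfg.synthetic is not None:
            write_genotype_tsv(gm, out / "genotypes.tsv")
            write_marker_table(gm.markers, out / "markers.tsv")
        manifest["n_cultivars"] = gm.n_cultivars
        manifest["n_markers_input"] = gm.n_markers

        stage = "qc"
        gm = recode_heterozygotes(gm, cfg.het_policy)
        gm, report = apply_filters(gm, cfg.filter)
        report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        manifest["n_markers_retained"] = gm.n_markers
        manifest["stages"].append("qc")

        stage = "stats"
        div = marker_summary(gm)
        div.to_frame(gm).to_csv(out / "marker_stats.tsv", sep="\t", index=False)
        (out / "panel_summary.json").write_text(
            json.dumps(div.panel, indent=2), encoding="utf-8"
        )
        manifest["stages"].append("stats")

        stage = "select"
        selection = nested_panels(
            gm, strategy=cfg.strategy, sizes=list(cfg.sizes), min_diff=cfg.min_diff
        )
        for size, panel in selection.panels.items():
            write_panel(panel, out / f"panel_{size}.txt")
        (out / "selection.json").write_text(
            json.dumps(selection.to_dict(), indent=2), encoding="utf-8"
        )
        manifest["stages"].append("select")

        stage = "discriminate"
        full = separation_summary(gm, min_diff=cfg.min_diff)
        (out / "separation_full.json").write_text(
            json.dumps(full.to_dict(), indent=2), encoding="utf-8"
        )
        manifest["identification_rate_full"] = full.identification_rate
        manifest["identification_rate_by_size"] = {
            str(s): r.identification_rate for s, r in selection.results.items()
        }
        manifest["stages"].append("discriminate")

        if cfg.run_tree:
            stage = "tree"
            dm = (
                jaccard_distance_matrix(gm)
                if cfg.distance == "jaccard"
                else simple_matching_distance_matrix(gm)
            )
            np.savetxt(
                out / "distances.tsv",
                dm.data,
                delimiter="\t",
                header="\t".join(dm.ids),
                comments="",
            )
            tree = neighbor_joining(dm)
            (out / "tree.nwk").write_text(to_newick(tree), encoding="utf-8")
            manifest["stages"].append("tree")

        if cfg.run_pca:
            stage = "pca"
            res = pca(gm, n_components=2)
            res.coordinates.to_csv(out / "pca_coordinates.tsv", sep="\t")
            (out / "pca_variance.json").write_text(
                json.dumps(
                    {"explained_variance_ratio": res.explained_variance_ratio.tolist()},
                    indent=2,
                ),
                encoding="utf-8",
            )
            manifest["stages"].append("pca")

        if cfg.n_mixture_pairs > 0:
            stage = "mixture"
            rng = np.random.default_rng(cfg.seed)
            ids = gm.cultivar_ids
            pairs = []
            for _ in range(cfg.n_mixture_pairs):
                i, j = rng.choice(len(ids), size=2, replace=False)
                pairs.append((ids[i], ids[j]))
            smallest = selection.panels[min(selection.panels)] if selection.panels else None
            results = simulate_mixture_experiment(
                gm,
                pairs,
                panel=smallest,
                assay_failure_rate=cfg.assay_failure_rate,
                seed=cfg.seed,
            )
            mixture_report_frame(results).to_csv(
                out / "mixture_report.tsv", sep="\t", index=False
            )
            pooled = pooled_het_concordance(results)
            (out / "mixture_summary.json").write_text(
                json.dumps({"pooled_het_concordance": pooled}, indent=2),
                encoding="utf-8",
            )
            manifest["stages"].append("mixture")
    except Exception as e:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
        raise PipelineError(f"stage {stage!r} failed: {e}") from e
    manifest["status"] = "complete"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest
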