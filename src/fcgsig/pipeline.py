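"""End-to-end orchestration on synthetic data: simulate -> differential
expression -> region decomposition -> cohort projection -> enrichment ->
clinical association -> clustering, with a JSON run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import io
from . import venn
from .de import hyperoxia_contrasts
from .enrichment import gsea_preranked, nes_matrix, rank_from_contrast
from .projection import (clinical_association, cluster,
                         intersignature_correlation, score_all,
                         zscore_matrix)
from .simulate import (SimConfig, default_effects, simulate_cohort,
                       simulate_gene_sets, simulate_murine_counts)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "fcgsig_run"
    seed: int = 0
    n_genes: int = 2000
    n_per_group: int = 3
    timepoint: str = "P5"
    fdr_deg: float = 0.05
    lfc_min: float = 1.0
    fdr_gsea: float = 0.25
    n_perm: int = 200
    n_gene_sets: int = 30
    cohort_n_per_sex: int = 60
    cohort_loading: float = 2.0
    normalize_scores: bool = False
    overlap_denominator: str = "union"
    require_concordance: bool = True
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("fdr_deg", "fdr_gsea"):
            value = getattr(self, name)
            if not (0 < value <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        unknown = {k: v for k, v in data.items() if k not in known}
        if unknown:
            kwargs.setdefault("extra", {}).update(unknown)
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run the full synthetic pipeline; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage_times: dict[str, float] = {}

    def tick(stage: str) -> None:
        stage_times[stage] = round(time.time() - t0, 3)
        logger.info("stage %s done at %.1fs", stage, stage_times[stage])

    sim = SimConfig(n_genes=config.n_genes, n_per_group=config.n_per_group,
                    seed=config.seed)
    effects = default_effects(sim)
    study = simulate_murine_counts(sim, effects)
    io.write_counts_tsv(study.counts, out / "counts.tsv")
    io.write_sample_sheet(study.design, out / "sample_sheet.tsv")
    io.write_annotation(study.annotation, out / "gene_annotation.tsv")
    tick("simulate")

    contrasts = hyperoxia_contrasts(study, config.timepoint,
                                    fdr_max=config.fdr_deg,
                                    lfc_min=config.lfc_min)
    gmt_sets: dict[str, tuple[str, ...]] = {}
    for genotype, result in contrasts.items():
        io.write_deg_table(result.table, out / f"deg_{result.name}.tsv")
        io.write_signature_tsv(result.signature,
                               out / f"signature_{result.name}.tsv")
        gmt_sets.update(io.signature_to_gmt_sets(result.signature))
    if gmt_sets:
        io.write_gmt(gmt_sets, out / "signatures.gmt")
    tick("deg")

    decomposition = venn.decompose(
        contrasts["XXF"].signature, contrasts["XXM"].signature,
        contrasts["XYF"].signature, contrasts["XYM"].signature,
        require_concordance=config.require_concordance)
    (out / "venn_summary.json").write_text(
        json.dumps(decomposition.to_summary(), indent=2))
    tick("decompose")

    signatures = [c.signature for c in contrasts.values()
                  if len(c.signature)]
    if not signatures:
        raise RuntimeError("stage project: all hyperoxia signatures are "
                           "empty; nothing to project")
    cohort = simulate_cohort(sim, signatures[0], config.cohort_loading,
                             sex_specific=True,
                             n_per_sex=config.cohort_n_per_sex,
                             seed=config.seed)
    cohort.expression.round(6).to_csv(out / "cohort_expression.tsv",
                                      sep="\t")
    io.write_clinical_csv(cohort.clinical, out / "cohort_clinical.csv")
    z = zscore_matrix(cohort.expression)
    scores = score_all(z, signatures, normalize=config.normalize_scores)
    scores.scores.round(6).to_csv(out / "score_matrix.tsv", sep="\t")
    tick("project")

    if scores.scores.shape[0] >= 2:
        corr = intersignature_correlation(scores)
        corr.round(6).to_csv(out / "intersignature_correlation.tsv",
                             sep="\t")
        tree = cluster(corr, mode="correlation")
        io.write_newick(tree.to_newick(), out / "signature_dendrogram.nwk")
    tick("cluster")

    collection = simulate_gene_sets(sim, effects, config.n_gene_sets,
                                    seed=config.seed)
    io.write_gmt(collection, out / "gene_sets.gmt")
    enrichments = {}
    for genotype, result in contrasts.items():
        ranked = rank_from_contrast(result.table)
        enr = gsea_preranked(ranked, collection, n_perm=config.n_perm,
                             seed=config.seed)
        enr.round(6).to_csv(out / f"gsea_{result.name}.tsv", sep="\t")
        enrichments[result.name] = enr
    mat = nes_matrix(enrichments, fdr_max=config.fdr_gsea)
    mat.round(6).to_csv(out / "nes_matrix.tsv", sep="\t")
    tick("gsea")

    assoc = clinical_association(scores, cohort.clinical,
                                 stratify_by_sex=True)
    assoc.round(6).to_csv(out / "clinical_association.tsv", sep="\t",
                          index=False)
    tick("associate")

    digests = {p.name: _sha256(p) for p in sorted(out.iterdir())
               if p.is_file() and p.name != "manifest.json"}
    from . import __version__
    manifest = {
        "package_version": __version__,
        "config": {k: v for k, v in asdict(config).items() if k != "extra"},
        "stage_seconds": stage_times,
        "output_digests": digests,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
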