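"""Recovery and calibration experiments used by the acceptance checks.

Each function regenerates its inputs from a seed, runs the pipeline piece
under study and returns the measured quantity, so results are reproducible
and computed from scratch on every call.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .anova import three_way_anova
from .de import chromosome_tally, hyperoxia_contrasts
from .enrichment import RankedList, gsea_preranked
from .projection import (clinical_association, cluster, score_all,
                         intersignature_correlation, zscore_matrix)
from .simulate import (PlantedEffects, SimConfig, default_effects,
                       gene_universe, simulate_cohort, simulate_murine_counts)
from .de import Signature
from .venn import decompose

GENOTYPE_ORDER = ("XXF", "XXM", "XYF", "XYM")


def null_fdp(n_reps: int = 20, n_genes: int = 2000, n_per_group: int = 3,
             fdr_max: float = 0.05, seed: int = 0) -> float:
    """Mean false discovery proportion over null-simulation contrasts."""
    fdps = []
    for rep in range(n_reps):
        cfg = SimConfig(n_genes=n_genes, n_per_group=n_per_group,
                        timepoints=("P5",), seed=seed + rep)
        study = simulate_murine_counts(cfg, PlantedEffects.null())
        for result in hyperoxia_contrasts(study, "P5").values():
            called = int((result.table["q"] <= fdr_max).sum())
            fdps.append(called / max(called, 1))
    return float(np.mean(fdps))


def planted_recovery(seed: int = 0, n_genes: int = 2000) -> dict:
    """Core-gene sensitivity per genotype, region-E sensitivity and the
    Y-chromosome DEG count of the hyperoxia response."""
    cfg = SimConfig(n_genes=n_genes, timepoints=("P5",), seed=seed)
    effects = default_effects(cfg)
    study = simulate_murine_counts(cfg, effects)
    contrasts = hyperoxia_contrasts(study, "P5")
    core = set(effects.core)

    sensitivity = {}
    y_degs = 0
    for genotype, result in contrasts.items():
        sig = result.signature
        sensitivity[genotype] = len(core & (sig.up | sig.down)) / len(core)
        tally = chromosome_tally(sig, study.annotation)
        y_degs += int(tally["Y"].sum())

    decomposition = decompose(*(contrasts[g].signature
                                for g in GENOTYPE_ORDER))
    region_e = set(decomposition.regions["E"])
    return {
        "sensitivity": sensitivity,
        "min_sensitivity": min(sensitivity.values()),
        "region_e_sensitivity": len(core & region_e) / len(core),
        "y_degs": y_degs,
    }


def cluster_recovery_fraction(n_seeds: int = 20, n_genes: int = 1500,
                              seed: int = 0) -> float:
    """Fraction of seeds in which the XX hyperoxia signatures merge at a
    smaller cophenetic height with each other than either does with XYM
    (simulations plant the XX-attenuated chromosomal interaction only)."""
    hits = 0
    for rep in range(n_seeds):
        cfg = SimConfig(n_genes=n_genes, timepoints=("P21",),
                        seed=seed + rep)
        effects = default_effects(cfg, include_gonadal=False)
        study = simulate_murine_counts(cfg, effects)
        contrasts = hyperoxia_contrasts(study, "P21")
        signatures = [contrasts[g].signature for g in GENOTYPE_ORDER]

        probe = Signature("probe", frozenset(list(gene_universe(cfg).index)
                                             [:1]), frozenset())
        cohort = simulate_cohort(cfg, probe, loading=0.0, n_per_sex=40,
                                 seed=seed + rep)
        z = zscore_matrix(cohort.expression)
        scores = score_all(z, signatures)
        corr = intersignature_correlation(scores)
        tree = cluster(corr)

        coph = squareform(hierarchy.cophenet(tree.linkage))
        pos = {label: i for i, label in enumerate(tree.labels)}
        names = {g: contrasts[g].signature.name for g in GENOTYPE_ORDER}
        if not all(names[g] in pos for g in ("XXF", "XXM", "XYM")):
            continue
        d_xx = coph[pos[names["XXF"]], pos[names["XXM"]]]
        d_f_m = coph[pos[names["XXF"]], pos[names["XYM"]]]
        d_m_m = coph[pos[names["XXM"]], pos[names["XYM"]]]
        hits += d_xx < min(d_f_m, d_m_m)
    return hits / n_seeds


def gsea_null_pvalues(n_sets: int = 200, n_genes: int = 2000,
                      n_perm: int = 1000, seed: int = 0) -> np.ndarray:
    """Nominal p-values of random sets under a random ranking."""
    rng = np.random.default_rng(seed)
    metric = np.sort(rng.normal(size=n_genes))[::-1]
    ranked = RankedList(genes=tuple(f"g{i}" for i in range(n_genes)),
                        metric=metric)
    sets = {
        f"r{i}": tuple(rng.choice(ranked.genes,
                                  int(rng.integers(10, 101)),
                                  replace=False))
        for i in range(n_sets)
    }
    result = gsea_preranked(ranked, sets, n_perm=n_perm, seed=seed + 1)
    return result["p"].to_numpy()


def gsea_planted_detection(n_seeds: int = 20, n_genes: int = 2000,
                           n_perm: int = 1000, seed: int = 0) -> float:
    """Fraction of seeds where a set planted at the top of the ranking
    attains NES > 0 with q < 0.25."""
    hits = 0
    for rep in range(n_seeds):
        rng = np.random.default_rng(seed + rep)
        metric = np.sort(rng.normal(size=n_genes))[::-1]
        ranked = RankedList(genes=tuple(f"g{i}" for i in range(n_genes)),
                            metric=metric)
        sets = {"planted": tuple(ranked.genes[:40])}
        for i in range(15):
            sets[f"rand{i}"] = tuple(
                rng.choice(ranked.genes, int(rng.integers(15, 60)),
                           replace=False))
        result = gsea_preranked(ranked, sets, n_perm=n_perm, seed=seed + rep)
        row = result.loc["planted"]
        hits += (row["nes"] > 0) and (row["q"] < 0.25)
    return hits / n_seeds


def clinical_detection_fraction(n_seeds: int = 20, n_per_sex: int = 60,
                                loading: float = 2.0, n_genes: int = 2000,
                                seed: int = 0) -> float:
    """Fraction of seeds detecting the planted female-stratum signature-BPD
    anticorrelation at r < 0, p < 0.05."""
    hits = 0
    for rep in range(n_seeds):
        cfg = SimConfig(n_genes=n_genes, seed=seed + rep)
        genes = list(gene_universe(cfg).index)
        sig = Signature("planted", frozenset(genes[:30]),
                        frozenset(genes[30:60]))
        cohort = simulate_cohort(cfg, sig, loading, sex_specific=True,
                                 n_per_sex=n_per_sex, seed=seed + rep)
        z = zscore_matrix(cohort.expression)
        scores = score_all(z, [sig])
        assoc = clinical_association(scores, cohort.clinical)
        cell = assoc[(assoc["variable"] == "bpd_status")
                     & (assoc["stratum"] == "F")]
        r, p = cell["r"].iloc[0], cell["p"].iloc[0]
        hits += (r < 0) and (p < 0.05)
    return hits / n_seeds


def anova_null_pvalues(n_reps: int = 500, n_per_cell: int = 6,
                       seed: int = 0) -> pd.DataFrame:
    """Per-term p-values over replicated null 2x2x2 simulations."""
    rng = np.random.default_rng(seed)
    rows = []
    for t in ("RA", "O2"):
        for c in ("XX", "XY"):
            for g in ("F", "M"):
                rows += [{"treatment": t, "chromosomal_sex": c,
                          "gonadal_sex": g}] * n_per_cell
    factors = pd.DataFrame(rows)
    records = []
    for _ in range(n_reps):
        values = rng.normal(size=len(factors))
        table = three_way_anova(values, factors)
        records.append(table["p"].drop("Residual"))
    return pd.DataFrame(records).reset_index(drop=True)
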