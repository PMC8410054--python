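"""Synthetic data generators for the factorial sex-genotype design.

Produces murine-like negative-binomial count studies over the four core
genotypes (XXF, XXM, XYF, XYM) crossed with treatment (RA / O2) and
timepoint, human-like expression cohorts with clinical covariates, and
gene-set collections — all with recorded planted truth so downstream
recovery can be tested.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GENOTYPES = ("XXF", "XXM", "XYF", "XYM")

#: genotype -> (chromosomal_sex, gonadal_sex)
GENOTYPE_FACTORS = {
    "XXF": ("XX", "F"),
    "XXM": ("XX", "M"),
    "XYF": ("XY", "F"),
    "XYM": ("XY", "M"),
}

TREATMENTS = ("RA", "O2")

#: floor NB mean standing in for "not expressed" (avoids all-zero rows)
OFF_MEAN = 0.01

#: ordered BPD severity grades and the latent-severity cut points between them
BPD_GRADES = ("none", "mild", "moderate", "severe")
BPD_THRESHOLDS = (0.0, 0.7, 1.3)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic factorial count study."""

    n_genes: int = 2000
    n_per_group: int = 3
    timepoints: tuple[str, ...] = ("P5", "P21")
    frac_x: float = 0.08
    frac_y: float = 0.02
    baseline_log2_range: tuple[float, float] = (4.0, 10.0)
    dispersion_mean: float = 0.03
    dispersion_log_sd: float = 0.5
    library_size_log_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_per_group <= 0:
            raise ValueError("n_genes and n_per_group must be positive")
        if not self.timepoints:
            raise ValueError("at least one timepoint is required")
        if not (0 <= self.frac_x and 0 <= self.frac_y):
            raise ValueError("chromosome fractions must be non-negative")
        if self.frac_x + self.frac_y >= 1:
            raise ValueError("frac_x + frac_y must be < 1")
        lo, hi = self.baseline_log2_range
        if hi < lo:
            raise ValueError("baseline_log2_range must be (low, high)")
        if self.dispersion_mean <= 0:
            raise ValueError("dispersion_mean must be positive")


@dataclass(frozen=True)
class PlantedEffects:
    """Ground-truth effects injected into a simulated study.

    ``core`` genes respond to treatment in every genotype; ``xx_protective``
    genes carry a chromosomal-sex x treatment interaction (full effect in XY,
    attenuated in XX); ``gonadal_modulated`` genes respond more strongly in
    gonadal males. ``x_escapees`` get a baseline shift in XX samples and
    ``y_only`` genes are silenced in XX samples. Marker genes mimic
    Xist (XX-only), Sry (gonadal-male-only) and Uty (XY-only) expression.
    """

    core: Mapping[str, float] = field(default_factory=dict)
    xx_protective: Mapping[str, float] = field(default_factory=dict)
    gonadal_modulated: Mapping[str, float] = field(default_factory=dict)
    x_escapees: frozenset = frozenset()
    y_only: frozenset = frozenset()
    markers: Mapping[str, str] = field(default_factory=dict)
    xx_attenuation: float = 0.25
    gonadal_attenuation: float = 0.25
    escape_shift: float = 0.585

    def named_sets(self) -> dict[str, frozenset]:
        return {
            "core": frozenset(self.core),
            "xx_protective": frozenset(self.xx_protective),
            "gonadal_modulated": frozenset(self.gonadal_modulated),
            "x_escapees": frozenset(self.x_escapees),
            "y_only": frozenset(self.y_only),
            "markers": frozenset(self.markers.values()),
        }

    def validate(self, annotation: pd.Series | None = None) -> None:
        sets = self.named_sets()
        names = list(sets)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                overlap = sets[a] & sets[b]
                if overlap:
                    raise ValueError(
                        f"planted sets {a!r} and {b!r} overlap: "
                        f"{sorted(overlap)[:5]}"
                    )
        if annotation is not None:
            universe = set(annotation.index)
            for name, genes in sets.items():
                missing = genes - universe
                if missing:
                    raise ValueError(
                        f"planted set {name!r} has genes outside the "
                        f"universe: {sorted(missing)[:5]}"
                    )
            x_genes = set(annotation.index[annotation == "X"])
            y_genes = set(annotation.index[annotation == "Y"])
            if not sets["x_escapees"] <= x_genes:
                raise ValueError("x_escapees must be X-chromosome genes")
            if not sets["y_only"] <= y_genes:
                raise ValueError("y_only must be Y-chromosome genes")

    @classmethod
    def null(cls) -> "PlantedEffects":
        """No planted effects at all (pure noise study)."""
        return cls()


def gene_universe(config: SimConfig) -> pd.Series:
    """Deterministic gene ids and chromosome assignment (A/X/Y).

    The assignment depends only on ``config`` (via its seed), so a study and
    a cohort built from the same config share one gene universe.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    n_x = int(round(config.frac_x * config.n_genes))
    n_y = int(round(config.frac_y * config.n_genes))
    chrom = np.array(["A"] * config.n_genes, dtype=object)
    picked = rng.choice(config.n_genes, size=n_x + n_y, replace=False)
    chrom[picked[:n_x]] = "X"
    chrom[picked[n_x:]] = "Y"
    return pd.Series(chrom, index=pd.Index(genes, name="gene_id"),
                     name="chromosome")


def default_effects(
    config: SimConfig,
    n_core: int = 150,
    beta_core: float = 2.0,
    n_xx_protective: int = 60,
    beta_xx: float = 2.0,
    n_gonadal: int = 60,
    beta_gonadal: float = 2.0,
    n_escapees: int = 12,
    n_y_only: int = 4,
    include_gonadal: bool = True,
) -> PlantedEffects:
    """Default planted truth drawn deterministically from the gene universe.

    Treatment-responsive sets are drawn from autosomes only, so the planted
    hyperoxia response carries no Y-chromosome genes by construction.
    """
    annotation = gene_universe(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    autosomal = list(annotation.index[annotation == "A"])
    x_genes = list(annotation.index[annotation == "X"])
    y_genes = list(annotation.index[annotation == "Y"])

    n_gon = n_gonadal if include_gonadal else 0
    need = n_core + n_xx_protective + n_gon + 3  # +1 autosomal Sry marker
    if need > len(autosomal):
        raise ValueError("not enough autosomal genes for requested effects")
    if n_escapees + 1 > len(x_genes):
        raise ValueError("not enough X genes for escapees plus Xist marker")
    if n_y_only + 1 > len(y_genes):
        raise ValueError("not enough Y genes for y_only plus Uty marker")

    auto = rng.permutation(autosomal)
    xs = rng.permutation(x_genes)
    ys = rng.permutation(y_genes)

    def signed(genes: Sequence[str], beta: float) -> dict[str, float]:
        half = len(genes) // 2
        return {g: (beta if i < half else -beta)
                for i, g in enumerate(genes)}

    core = signed(auto[:n_core], beta_core)
    pos = n_core
    xx_prot = signed(auto[pos:pos + n_xx_protective], beta_xx)
    pos += n_xx_protective
    gonadal = signed(auto[pos:pos + n_gon], beta_gonadal)
    pos += n_gon
    markers = {
        "xist_like": xs[n_escapees],
        "sry_like": auto[pos],
        "uty_like": ys[n_y_only],
    }
    effects = PlantedEffects(
        core=core,
        xx_protective=xx_prot,
        gonadal_modulated=gonadal,
        x_escapees=frozenset(xs[:n_escapees]),
        y_only=frozenset(ys[:n_y_only]),
        markers=markers,
    )
    effects.validate(annotation)
    return effects


@dataclass
class FactorialStudy:
    """A count matrix plus its factorial design and gene annotation."""

    counts: pd.DataFrame          # genes x samples, non-negative ints
    design: pd.DataFrame          # sample_id-indexed factor table
    annotation: pd.Series         # gene -> chromosome in {A, X, Y}
    truth: PlantedEffects | None = None

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.design.index):
            raise ValueError("counts columns must match design rows")
        if not self.counts.index.equals(self.annotation.index):
            raise ValueError("counts rows must match gene annotation")
        required = {"genotype", "chromosomal_sex", "gonadal_sex",
                    "treatment", "timepoint"}
        missing = required - set(self.design.columns)
        if missing:
            raise ValueError(f"design is missing factors: {sorted(missing)}")
        for sid, row in self.design.iterrows():
            expect = GENOTYPE_FACTORS[row["genotype"]]
            if (row["chromosomal_sex"], row["gonadal_sex"]) != expect:
                raise ValueError(
                    f"sample {sid}: genotype {row['genotype']} inconsistent "
                    f"with ({row['chromosomal_sex']}, {row['gonadal_sex']})"
                )
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def samples(self, **criteria: str) -> list[str]:
        """Sample ids matching all given factor=level criteria."""
        mask = pd.Series(True, index=self.design.index)
        for factor, level in criteria.items():
            mask &= self.design[factor] == level
        return list(self.design.index[mask])


def _build_design(config: SimConfig) -> pd.DataFrame:
    rows = []
    for tp in config.timepoints:
        for genotype in GENOTYPES:
            for treatment in TREATMENTS:
                for rep in range(1, config.n_per_group + 1):
                    chrom_sex, gonadal_sex = GENOTYPE_FACTORS[genotype]
                    sid = f"{genotype}_{treatment}_{tp}_r{rep}"
                    rows.append({
                        "sample_id": sid,
                        "genotype": genotype,
                        "chromosomal_sex": chrom_sex,
                        "gonadal_sex": gonadal_sex,
                        "treatment": treatment,
                        "timepoint": tp,
                    })
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_murine_counts(
    config: SimConfig,
    effects: PlantedEffects | None = None,
) -> FactorialStudy:
    """Draw a factorial NB count study with the given planted effects.

    Per-element mean is ``s_j * 2**eta_gj`` where ``eta`` stacks the baseline
    with each planted term matching the sample's factors; the NB variance is
    ``m + phi * m**2`` with a lognormal ``phi`` across genes.
    """
    if effects is None:
        effects = default_effects(config)
    annotation = gene_universe(config)
    effects.validate(annotation)
    design = _build_design(config)
    genes = annotation.index
    n_genes, n_samples = len(genes), len(design)

    root = np.random.SeedSequence([config.seed, 303])
    g_rng, s_rng, c_rng = map(np.random.default_rng, root.spawn(3))

    lo, hi = config.baseline_log2_range
    baseline = g_rng.uniform(lo, hi, size=n_genes)
    phi = np.exp(g_rng.normal(np.log(config.dispersion_mean),
                              config.dispersion_log_sd, size=n_genes))
    lib = np.exp(s_rng.normal(0.0, config.library_size_log_sd,
                              size=n_samples))
    lib /= np.exp(np.mean(np.log(lib)))  # geometric mean 1

    gene_pos = {g: i for i, g in enumerate(genes)}
    is_xx = (design["chromosomal_sex"] == "XX").to_numpy()
    is_gm = (design["gonadal_sex"] == "M").to_numpy()
    is_o2 = (design["treatment"] == "O2").to_numpy()

    eta = np.tile(baseline[:, None], (1, n_samples))

    # guarantee marker genes have a clearly nonzero on-state
    for gene in effects.markers.values():
        eta[gene_pos[gene], :] = np.maximum(eta[gene_pos[gene], :], 8.0)

    for gene, beta in effects.core.items():
        eta[gene_pos[gene], is_o2] += beta
    for gene, beta in effects.xx_protective.items():
        i = gene_pos[gene]
        eta[i, is_o2 & ~is_xx] += beta
        eta[i, is_o2 & is_xx] += beta * effects.xx_attenuation
    for gene, beta in effects.gonadal_modulated.items():
        i = gene_pos[gene]
        eta[i, is_o2 & is_gm] += beta
        eta[i, is_o2 & ~is_gm] += beta * effects.gonadal_attenuation
    for gene in effects.x_escapees:
        eta[gene_pos[gene], is_xx] += effects.escape_shift

    mean = lib[None, :] * np.exp2(eta)

    # silenced states: forced to a floor mean rather than exactly zero
    for gene in effects.y_only:
        mean[gene_pos[gene], is_xx] = OFF_MEAN
    if "xist_like" in effects.markers:
        mean[gene_pos[effects.markers["xist_like"]], ~is_xx] = OFF_MEAN
    if "sry_like" in effects.markers:
        mean[gene_pos[effects.markers["sry_like"]], ~is_gm] = OFF_MEAN
    if "uty_like" in effects.markers:
        mean[gene_pos[effects.markers["uty_like"]], is_xx] = OFF_MEAN

    r = 1.0 / phi
    p = r[:, None] / (r[:, None] + mean)
    counts = c_rng.negative_binomial(r[:, None], p)

    counts_df = pd.DataFrame(counts, index=genes, columns=design.index)
    return FactorialStudy(counts=counts_df, design=design,
                          annotation=annotation, truth=effects)


@dataclass
class Cohort:
    """External expression cohort with a clinical table and optional truth."""

    expression: pd.DataFrame      # genes x subjects
    clinical: pd.DataFrame        # subject-indexed
    truth: dict | None = None

    def __post_init__(self) -> None:
        if not self.expression.columns.equals(self.clinical.index):
            raise ValueError("clinical rows must match expression columns")
        if self.clinical["sex"].isna().any():
            raise ValueError("sex must be recorded for every subject")
        bad = set(self.clinical["bpd_status"]) - set(BPD_GRADES)
        if bad:
            raise ValueError(f"unknown BPD grades: {sorted(bad)}")


def _bpd_grade(u: np.ndarray) -> np.ndarray:
    grade = np.zeros(len(u), dtype=int)
    for threshold in BPD_THRESHOLDS:
        grade += u > threshold
    return np.array(BPD_GRADES, dtype=object)[grade]


def simulate_cohort(
    config: SimConfig,
    protect_signature,
    loading: float,
    sex_specific: bool = True,
    n_per_sex: int = 60,
    seed: int | None = None,
    flip_prob: float = 0.05,
) -> Cohort:
    """Draw a human-like cohort with a planted signature-severity link.

    A latent severity ``u ~ N(0,1)`` drives the clinical covariates; in the
    targeted stratum (females when ``sex_specific``) the signature's genes get
    expression ``-loading * u * direction + noise`` so the summed Z-score of
    the signature anticorrelates with BPD severity there.
    """
    if not np.isfinite(loading):
        raise ValueError("loading must be finite")
    up = frozenset(protect_signature.up)
    down = frozenset(protect_signature.down)
    if not (up or down):
        raise ValueError("signature must be non-empty")

    annotation = gene_universe(config)
    universe = set(annotation.index)
    missing = (up | down) - universe
    if missing:
        raise ValueError(
            f"signature genes outside the cohort gene universe: "
            f"{sorted(missing)}"
        )

    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))

    n = 2 * n_per_sex
    subjects = pd.Index([f"h{i:04d}" for i in range(n)], name="subject_id")
    sex = np.array(["F"] * n_per_sex + ["M"] * n_per_sex, dtype=object)
    u = rng.normal(0.0, 1.0, size=n)

    gestational_age = np.clip(28.0 - 2.5 * u + rng.normal(0, 1.5, n),
                              23.0, 36.0)
    birth_weight = np.clip(1100.0 - 250.0 * u + rng.normal(0, 150.0, n),
                           400.0, None)
    o2 = (u > 0.2).astype(int)
    flips = rng.random(n) < flip_prob
    o2[flips] = 1 - o2[flips]

    clinical = pd.DataFrame({
        "sex": sex,
        "gestational_age": np.round(gestational_age, 1),
        "birth_weight": np.round(birth_weight, 0),
        "bpd_status": _bpd_grade(u),
        "o2_at_28d": np.where(o2 == 1, "yes", "no"),
    }, index=subjects)

    expr = rng.normal(0.0, 1.0, size=(config.n_genes, n))
    target = np.ones(n, dtype=bool) if not sex_specific else (sex == "F")
    gene_pos = {g: i for i, g in enumerate(annotation.index)}
    for gene in up:
        expr[gene_pos[gene], target] += -loading * u[target]
    for gene in down:
        expr[gene_pos[gene], target] += loading * u[target]

    expression = pd.DataFrame(expr, index=annotation.index, columns=subjects)
    truth = {
        "loading": loading,
        "latent_severity": pd.Series(u, index=subjects),
        "target_stratum": "F" if sex_specific else "all",
        "signature": protect_signature.name,
    }
    return Cohort(expression=expression, clinical=clinical, truth=truth)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions and enrichment truth."""

    sets: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)
    truth: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicates")


def simulate_gene_sets(
    config: SimConfig,
    effects: PlantedEffects,
    n_sets: int,
    set_size_range: tuple[int, int] = (15, 60),
    enriched_fraction: float = 0.2,
    planted_purity: float = 0.8,
    seed: int | None = None,
) -> GeneSetCollection:
    """Random gene sets, some enriched for planted core-response genes."""
    if n_sets <= 0:
        raise ValueError("n_sets must be positive")
    lo, hi = set_size_range
    if lo < 1 or hi < lo:
        raise ValueError("set_size_range must be (low, high) with low >= 1")
    if hi > config.n_genes:
        raise ValueError("set sizes cannot exceed the gene universe")

    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    universe = np.array(list(gene_universe(config).index))
    core_up = sorted(g for g, b in effects.core.items() if b > 0)
    core_down = sorted(g for g, b in effects.core.items() if b < 0)

    n_enriched = int(round(enriched_fraction * n_sets))
    if not (core_up or core_down):
        n_enriched = 0

    sets: dict[str, tuple[str, ...]] = {}
    truth: dict[str, bool] = {}
    descriptions: dict[str, str] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        name = f"SET_{i:03d}"
        if i < n_enriched:
            pool = core_up if (i % 2 == 0 and core_up) else core_down
            n_planted = min(len(pool), max(1, int(round(planted_purity
                                                        * size))))
            planted = rng.choice(pool, size=n_planted, replace=False)
            rest = rng.choice(
                np.setdiff1d(universe, planted, assume_unique=False),
                size=size - n_planted, replace=False)
            genes = tuple(np.concatenate([planted, rest]))
            truth[name] = True
            descriptions[name] = "planted-enriched"
        else:
            genes = tuple(rng.choice(universe, size=size, replace=False))
            truth[name] = False
            descriptions[name] = "random"
        sets[name] = genes
    return GeneSetCollection(sets=sets, descriptions=descriptions,
                             truth=truth)
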