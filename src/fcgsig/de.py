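"""Normalization, moderated two-group testing and directional signatures.

The test is a variance-moderated pooled t: per-gene pooled variances are
shrunk toward their across-gene mean with a fixed prior df, which stabilizes
the tiny group sizes (n=3) typical of the factorial design. At prior df 0 it
reduces exactly to the classical pooled two-sample t-test.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GENOTYPES, FactorialStudy

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Signature:
    """A named directional DEG set from one contrast."""

    name: str
    up: frozenset
    down: frozenset
    fdr_max: float = 0.05
    lfc_min: float = 1.0

    def __post_init__(self) -> None:
        overlap = self.up & self.down
        if overlap:
            raise ValueError(f"up/down overlap in {self.name!r}: "
                             f"{sorted(overlap)[:5]}")

    def __len__(self) -> int:
        return len(self.up) + len(self.down)

    def directions(self) -> dict[str, str]:
        d = {g: "up" for g in self.up}
        d.update({g: "down" for g in self.down})
        return d


@dataclass
class NormalizedExpression:
    """log2-normalized values with the size factors that produced them."""

    values: pd.DataFrame
    size_factors: pd.Series


@dataclass
class ContrastResult:
    """DEG table plus the thresholded signature for one contrast."""

    name: str
    table: pd.DataFrame
    signature: Signature


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors; library-size fallback when no gene
    is positive in every sample."""
    mat = counts.to_numpy(dtype=float)
    if mat.sum() == 0:
        raise ValueError("cannot normalize an all-zero count matrix")
    eligible = (mat > 0).all(axis=1)
    if eligible.any():
        sub = mat[eligible]
        log_geomean = np.mean(np.log(sub), axis=1)
        ratios = np.log(sub) - log_geomean[:, None]
        s = np.exp(np.median(ratios, axis=0))
    else:
        logger.warning("no gene positive in all samples; falling back to "
                       "library-size ratios")
        libs = mat.sum(axis=0)
        if (libs == 0).any():
            raise ValueError("sample with zero total counts")
        s = libs / np.exp(np.mean(np.log(libs)))
    return pd.Series(s, index=counts.columns, name="size_factor")


def log_normalize(counts: pd.DataFrame,
                  s: pd.Series | None = None) -> NormalizedExpression:
    """``log2(count / size_factor + 1)``; zeros stay exactly 0."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    if s is None:
        s = size_factors(counts)
    values = np.log2(counts.div(s, axis=1) + 1.0)
    return NormalizedExpression(values=values, size_factors=s)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def moderated_two_group_test(
    expr: NormalizedExpression | pd.DataFrame,
    group_a,
    group_b,
    d0: float = 4.0,
) -> pd.DataFrame:
    """Moderated pooled t-test per gene, B versus A (log2FC = mean_B - mean_A).

    Pooled per-gene variance ``s2`` (df = nA+nB-2) is shrunk toward the
    across-gene mean prior ``s0^2`` with prior df ``d0``; p-values use a
    t distribution with ``d0 + df`` degrees of freedom, BH-adjusted to q.
    """
    values = expr.values if isinstance(expr, NormalizedExpression) else expr
    group_a, group_b = list(group_a), list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if d0 < 0:
        raise ValueError("prior df must be non-negative")

    a = values[group_a].to_numpy(dtype=float)
    b = values[group_b].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    df = na + nb - 2

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) \
        + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df
    s0_sq = float(s2.mean())
    if s0_sq == 0:
        warnings.warn("all genes have zero pooled variance", stacklevel=2)
    s2_tilde = (d0 * s0_sq + df * s2) / (d0 + df)

    lfc = mean_b - mean_a
    denom = np.sqrt(s2_tilde * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, lfc / np.where(denom > 0, denom, 1.0),
                     np.where(lfc == 0, 0.0, np.inf * np.sign(lfc)))
    df_total = d0 + df
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    q = bh_adjust(p)

    return pd.DataFrame({
        "log2FC": lfc,
        "t": t,
        "df": float(df),
        "d0": float(d0),
        "p": p,
        "q": q,
        "mean_a": mean_a,
        "mean_b": mean_b,
    }, index=values.index)


def call_degs(table: pd.DataFrame, fdr_max: float = 0.05,
              lfc_min: float = 1.0, name: str = "contrast") -> Signature:
    """Threshold a DEG table into a directional signature."""
    if fdr_max <= 0 or lfc_min < 0:
        raise ValueError("thresholds must be positive")
    sig_mask = table["q"] <= fdr_max
    up = frozenset(table.index[sig_mask & (table["log2FC"] >= lfc_min)])
    down = frozenset(table.index[sig_mask & (table["log2FC"] <= -lfc_min)])
    return Signature(name=name, up=up, down=down,
                     fdr_max=fdr_max, lfc_min=lfc_min)


def filter_low_counts(counts: pd.DataFrame, min_count: int = 5,
                      min_samples: int = 2) -> pd.DataFrame:
    """Keep genes with >= min_count counts in >= min_samples samples."""
    keep = (counts >= min_count).sum(axis=1) >= min_samples
    return counts.loc[keep]


def _contrast(study: FactorialStudy, samples_a, samples_b, name: str,
              fdr_max: float, lfc_min: float, d0: float,
              min_count: int, min_samples: int) -> ContrastResult:
    counts = study.counts[list(samples_a) + list(samples_b)]
    counts = filter_low_counts(counts, min_count, min_samples)
    norm = log_normalize(counts)
    table = moderated_two_group_test(norm, samples_a, samples_b, d0=d0)
    sig = call_degs(table, fdr_max=fdr_max, lfc_min=lfc_min, name=name)
    return ContrastResult(name=name, table=table, signature=sig)


def hyperoxia_contrasts(
    study: FactorialStudy,
    timepoint: str,
    fdr_max: float = 0.05,
    lfc_min: float = 1.0,
    d0: float = 4.0,
    min_count: int = 5,
    min_samples: int = 2,
) -> dict[str, ContrastResult]:
    """O2-vs-RA contrast within each genotype at one timepoint.

    Returns one ContrastResult per genotype; log2FC is O2 minus RA.
    """
    out: dict[str, ContrastResult] = {}
    for genotype in GENOTYPES:
        ra = study.samples(genotype=genotype, treatment="RA",
                           timepoint=timepoint)
        o2 = study.samples(genotype=genotype, treatment="O2",
                           timepoint=timepoint)
        if len(ra) < 2 or len(o2) < 2:
            raise ValueError(
                f"design cell ({genotype}, {timepoint}) has too few samples "
                f"(RA={len(ra)}, O2={len(o2)})"
            )
        name = f"{genotype}_O2_vs_RA_{timepoint}"
        out[genotype] = _contrast(study, ra, o2, name, fdr_max, lfc_min,
                                  d0, min_count, min_samples)
    return out


def genotype_contrast(
    study: FactorialStudy,
    genotype_a: str,
    genotype_b: str,
    condition: str,
    timepoint: str,
    fdr_max: float = 0.05,
    lfc_min: float = 1.0,
    d0: float = 4.0,
    min_count: int = 5,
    min_samples: int = 2,
) -> ContrastResult:
    """One genotype-vs-genotype contrast within a condition (B minus A)."""
    if genotype_a == genotype_b:
        raise ValueError(f"self-contrast {genotype_a} vs itself is not "
                         "meaningful")
    a = study.samples(genotype=genotype_a, treatment=condition,
                      timepoint=timepoint)
    b = study.samples(genotype=genotype_b, treatment=condition,
                      timepoint=timepoint)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"design cell empty or too small for "
            f"({genotype_a}|{genotype_b}, {condition}, {timepoint})"
        )
    name = f"{genotype_b}_vs_{genotype_a}_{condition}_{timepoint}"
    return _contrast(study, a, b, name, fdr_max, lfc_min, d0,
                     min_count, min_samples)


def intergenotype_contrasts(
    study: FactorialStudy,
    condition: str,
    timepoint: str,
    **kwargs,
) -> dict[tuple[str, str], ContrastResult]:
    """All six pairwise genotype contrasts within one condition."""
    if condition not in ("RA", "O2"):
        raise ValueError(f"unknown condition {condition!r}")
    out = {}
    for ga, gb in itertools.combinations(GENOTYPES, 2):
        out[(ga, gb)] = genotype_contrast(study, ga, gb, condition,
                                          timepoint, **kwargs)
    return out


def chromosome_tally(sig: Signature, annotation: pd.Series) -> pd.DataFrame:
    """Direction x chromosome (A/X/Y) counts for a signature."""
    unannotated = (sig.up | sig.down) - set(annotation.index)
    if unannotated:
        raise ValueError(f"unannotated genes in signature: "
                         f"{sorted(unannotated)[:10]}")
    tally = pd.DataFrame(0, index=["up", "down"], columns=["A", "X", "Y"])
    for genes, direction in ((sig.up, "up"), (sig.down, "down")):
        for gene in genes:
            tally.loc[direction, annotation[gene]] += 1
    return tally
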