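"""Preranked gene-set enrichment: weighted-KS enrichment scores, a
gene-sampling permutation null for NES / nominal p / FDR q, NES-matrix
masking, pathway overlap and the cross-species discordance rule."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GeneSetCollection


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by decreasing ranking metric (ties broken by gene id)."""

    genes: tuple[str, ...]
    metric: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.metric):
            raise ValueError("genes and metric lengths differ")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids in ranked list")
        if not np.isfinite(self.metric).all():
            raise ValueError("ranking metric must be finite")
        diffs = np.diff(self.metric)
        if (diffs > 0).any():
            raise ValueError("metric must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)


def rank_from_contrast(table: pd.DataFrame, metric: str = "t") -> RankedList:
    """Ranked list from a DEG table, sorted by the signed statistic."""
    if table.index.duplicated().any():
        dupes = table.index[table.index.duplicated()].tolist()
        raise ValueError(f"duplicate gene ids: {dupes[:5]}")
    values = table[metric]
    order = sorted(table.index, key=lambda g: (-values[g], g))
    return RankedList(genes=tuple(order),
                      metric=values[order].to_numpy(dtype=float))


def enrichment_score(ranked: RankedList, gene_set,
                     weight: float = 1.0) -> tuple[float, np.ndarray]:
    """Weighted-KS enrichment score and the full running sum.

    Hits add ``|r|^weight / N_R``; misses subtract ``1/(N - N_H)``. The ES is
    the running-sum value of maximum absolute deviation from zero (signed).
    """
    gene_set = set(gene_set)
    n = len(ranked)
    hits = np.fromiter((g in gene_set for g in ranked.genes), dtype=bool,
                       count=n)
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if n_hits == n:
        raise ValueError("gene set covers the whole ranked universe")

    w = np.abs(ranked.metric) ** weight
    n_r = w[hits].sum()
    steps = np.where(hits,
                     (w / n_r) if n_r > 0 else (1.0 / n_hits),
                     -1.0 / (n - n_hits))
    if n_r == 0:  # all hit metrics are zero: fall back to equal hit weight
        steps = np.where(hits, 1.0 / n_hits, -1.0 / (n - n_hits))
    running = np.cumsum(steps)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), running


def _es_from_positions(pos: np.ndarray, absw: np.ndarray, n: int
                       ) -> np.ndarray:
    """Vectorized ES for many same-size sets given sorted hit positions.

    ``pos``: (n_sets, k) sorted hit indices; ``absw``: |metric|^weight over
    the whole ranked list. Evaluates the running sum only at its candidate
    extrema (just before and just after every hit)."""
    n_sets, k = pos.shape
    w = absw[pos]
    n_r = w.sum(axis=1, keepdims=True)
    cumw = np.cumsum(w, axis=1)
    # rows with all-zero hit weights fall back to equal hit steps
    with np.errstate(invalid="ignore", divide="ignore"):
        cumw = np.where(n_r > 0, cumw / n_r,
                        np.arange(1, k + 1, dtype=float) / k)
    pen = 1.0 / (n - k)
    misses_before = (pos - np.arange(k)) * pen
    after = cumw - misses_before
    before = np.concatenate(
        [np.zeros((n_sets, 1)), cumw[:, :-1]], axis=1) - misses_before
    candidates = np.concatenate([after, before], axis=1)
    idx = np.argmax(np.abs(candidates), axis=1)
    return candidates[np.arange(n_sets), idx]


def _null_es(absw: np.ndarray, k: int, n_perm: int,
             rng: np.random.Generator) -> np.ndarray:
    n = len(absw)
    pos = np.empty((n_perm, k), dtype=np.int64)
    for i in range(n_perm):
        pos[i] = rng.choice(n, size=k, replace=False)
    pos.sort(axis=1)
    return _es_from_positions(pos, absw, n)


def gsea_preranked(
    ranked: RankedList,
    collection: GeneSetCollection | dict,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Preranked GSEA over a gene-set collection.

    The null is gene-sampling: for each set size, ``n_perm`` random same-size
    sets are scored. NES divides ES by the mean same-sign |null ES| of its
    size class; nominal p compares against same-sign nulls; FDR q follows the
    pooled normalized-null procedure.
    """
    sets = collection.sets if isinstance(collection, GeneSetCollection) \
        else collection
    universe = set(ranked.genes)
    filtered: dict[str, list[str]] = {}
    for name, genes in sets.items():
        present = sorted(set(genes) & universe)
        if min_size <= len(present) <= max_size and len(present) < len(ranked):
            filtered[name] = present
    if not filtered:
        raise ValueError("no gene set survives the size filter")

    absw = np.abs(ranked.metric) ** weight
    rng = np.random.default_rng(seed)

    # one shared null ES distribution per distinct set size
    sizes = sorted({len(g) for g in filtered.values()})
    null_es = {k: _null_es(absw, k, n_perm, rng) for k in sizes}
    null_means = {}
    for k, es in null_es.items():
        pos_mean = es[es > 0].mean() if (es > 0).any() else np.nan
        neg_mean = np.abs(es[es < 0]).mean() if (es < 0).any() else np.nan
        null_means[k] = (pos_mean, neg_mean)

    # pooled normalized null for the FDR step
    null_nes_pool = []
    for k, es in null_es.items():
        pos_mean, neg_mean = null_means[k]
        nes = np.where(es >= 0,
                       es / pos_mean if np.isfinite(pos_mean) else np.nan,
                       es / neg_mean if np.isfinite(neg_mean) else np.nan)
        null_nes_pool.append(nes[np.isfinite(nes)])
    null_nes_pool = np.concatenate(null_nes_pool)

    rows = []
    gene_index = {g: i for i, g in enumerate(ranked.genes)}
    for name, genes in filtered.items():
        es, running = enrichment_score(ranked, genes, weight=weight)
        k = len(genes)
        nulls = null_es[k]
        pos_mean, neg_mean = null_means[k]
        if es >= 0:
            same = nulls[nulls >= 0]
            p = (1 + int((same >= es).sum())) / (1 + len(same))
            nes = es / pos_mean if np.isfinite(pos_mean) else np.nan
            peak = int(np.argmax(running))
            leading = [g for g in genes if gene_index[g] <= peak]
        else:
            same = nulls[nulls < 0]
            p = (1 + int((same <= es).sum())) / (1 + len(same))
            nes = es / neg_mean if np.isfinite(neg_mean) else np.nan
            trough = int(np.argmin(running))
            leading = [g for g in genes if gene_index[g] >= trough]
        rows.append({"set": name, "size": k, "es": es, "nes": nes,
                     "p": p, "leading_edge": ",".join(sorted(leading))})

    result = pd.DataFrame(rows).set_index("set")

    obs = result["nes"].to_numpy()
    q = np.full(len(obs), np.nan)
    pos_null = null_nes_pool[null_nes_pool >= 0]
    neg_null = null_nes_pool[null_nes_pool < 0]
    n_obs_pos = int((obs >= 0).sum())
    n_obs_neg = int((obs < 0).sum())
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            q[i] = 1.0
            continue
        if nes >= 0:
            num = ((pos_null >= nes).sum() / len(pos_null)
                   if len(pos_null) else 1.0)
            den = (obs[obs >= 0] >= nes).sum() / n_obs_pos
        else:
            num = ((neg_null <= nes).sum() / len(neg_null)
                   if len(neg_null) else 1.0)
            den = (obs[obs < 0] <= nes).sum() / n_obs_neg
        q[i] = min(1.0, num / den) if den > 0 else 1.0
    result["q"] = q
    return result[["size", "es", "nes", "p", "q", "leading_edge"]]


def nes_matrix(results: dict[str, pd.DataFrame],
               fdr_max: float = 0.25) -> pd.DataFrame:
    """Responses x gene sets matrix of NES, zeroed where q >= fdr_max."""
    all_sets = sorted(set().union(*(r.index for r in results.values())))
    mat = pd.DataFrame(0.0, index=sorted(results),
                       columns=pd.Index(all_sets, name="set"))
    for response, table in results.items():
        significant = table.index[table["q"] < fdr_max]
        mat.loc[response, significant] = table.loc[significant, "nes"]
    return mat


def pathway_overlap(pathway_sets: dict[str, set],
                    denominator: str = "union") -> pd.DataFrame:
    """Pairwise overlap counts and percentages between pathway label sets."""
    names = sorted(pathway_sets)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sa, sb = set(pathway_sets[a]), set(pathway_sets[b])
            inter = len(sa & sb)
            if denominator == "union":
                denom = len(sa | sb)
            elif denominator == "smaller":
                denom = min(len(sa), len(sb))
            else:
                raise ValueError(f"unknown denominator {denominator!r}")
            pct = 100.0 * inter / denom if denom else 0.0
            rows.append({"set_a": a, "set_b": b, "intersection": inter,
                         "denominator": denom, "percent": pct})
    return pd.DataFrame(rows)


def discordant_pathways(
    human: pd.DataFrame,
    xxf: pd.DataFrame,
    xxm: pd.DataFrame,
    xyf: pd.DataFrame,
    xym: pd.DataFrame,
    fdr_max: float = 0.25,
) -> list[str]:
    """Pathways induced in the human response but suppressed in the three
    feminized murine responses, and in XYM either induced or not
    significantly modulated."""
    shared = human.index
    for other in (xxf, xxm, xyf, xym):
        shared = shared.intersection(other.index)

    selected = []
    for pathway in shared:
        h = human.loc[pathway]
        if not (h["nes"] > 0 and h["q"] < fdr_max):
            continue
        feminized_down = all(
            t.loc[pathway, "nes"] < 0 and t.loc[pathway, "q"] < fdr_max
            for t in (xxf, xxm, xyf)
        )
        if not feminized_down:
            continue
        m = xym.loc[pathway]
        xym_ok = (m["nes"] > 0 and m["q"] < fdr_max) or m["q"] >= fdr_max
        if xym_ok:
            selected.append(pathway)
    return sorted(selected)
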