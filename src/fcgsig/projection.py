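"""Summed Z-score projection of signatures onto an expression cohort,
with intersignature correlation, UPGMA clustering and sex-stratified
clinical association."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .de import Signature
from .simulate import BPD_GRADES

logger = logging.getLogger(__name__)

CLINICAL_VARIABLES = ("gestational_age", "birth_weight", "bpd_status",
                      "o2_at_28d")


@dataclass
class ScoreMatrix:
    """Signatures x subjects summed Z-scores with per-signature coverage."""

    scores: pd.DataFrame
    coverage: pd.Series

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("score matrix contains non-finite entries")
        cov = self.coverage.to_numpy()
        if ((cov < 0) | (cov > 1)).any():
            raise ValueError("coverage must lie in [0, 1]")


@dataclass
class LinkageTree:
    """Average-linkage dendrogram with Newick serialization."""

    labels: list[str]
    linkage: np.ndarray

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.labels[i] for i in order]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return render(tree, tree.dist) + ";"


def zscore_matrix(expression: pd.DataFrame) -> pd.DataFrame:
    """Across-subject z-scores per gene (ddof=1); constant genes dropped."""
    if expression.shape[1] < 3:
        raise ValueError("need at least 3 subjects to z-score")
    sd = expression.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.info("excluding %d zero-variance genes", int(constant.sum()))
    kept = expression.loc[~constant]
    return kept.sub(kept.mean(axis=1), axis=0).div(sd[~constant], axis=0)


def summed_zscore(z: pd.DataFrame, sig: Signature,
                  normalize: bool = False) -> tuple[pd.Series, float]:
    """Per-subject score: sum of z over up-genes minus sum over down-genes.

    Missing signature genes are dropped; returns (scores, coverage) where
    coverage is the fraction of signature genes found in the cohort.
    """
    present = set(z.index)
    up = sorted(sig.up & present)
    down = sorted(sig.down & present)
    total = len(sig.up) + len(sig.down)
    if total == 0:
        raise ValueError(f"signature {sig.name!r} is empty")
    found = len(up) + len(down)
    if found == 0:
        raise ValueError(f"signature {sig.name!r} has zero coverage in "
                         "the cohort")
    coverage = found / total
    if coverage < 0.5:
        logger.warning("signature %s coverage is only %.2f", sig.name,
                       coverage)
    scores = z.loc[up].sum(axis=0) - z.loc[down].sum(axis=0)
    if normalize:
        scores = scores / found
    scores.name = sig.name
    return scores, coverage


def score_all(z: pd.DataFrame, signatures,
              normalize: bool = False) -> ScoreMatrix:
    """Score every signature; zero-coverage signatures are skipped with a
    warning rather than aborting the whole projection."""
    rows, covs, names = [], [], []
    for sig in signatures:
        try:
            scores, coverage = summed_zscore(z, sig, normalize=normalize)
        except ValueError as exc:
            logger.warning("skipping signature %s: %s", sig.name, exc)
            continue
        rows.append(scores)
        covs.append(coverage)
        names.append(sig.name)
    if not rows:
        raise ValueError("no signature had nonzero coverage")
    scores = pd.DataFrame(rows, index=pd.Index(names, name="signature"))
    coverage = pd.Series(covs, index=scores.index, name="coverage")
    return ScoreMatrix(scores=scores, coverage=coverage)


def intersignature_correlation(scores: ScoreMatrix | pd.DataFrame
                               ) -> pd.DataFrame:
    """Pearson correlation between signature score rows across subjects.

    Constant rows yield NaN (flagged missing, not zero)."""
    mat = scores.scores if isinstance(scores, ScoreMatrix) else scores
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 signatures")
    if mat.shape[1] < 3:
        raise ValueError("need at least 3 subjects")
    corr = mat.T.corr(method="pearson")
    np.fill_diagonal(corr.to_numpy(), 1.0)
    constant = mat.std(axis=1, ddof=0) == 0
    corr.loc[constant, :] = np.nan
    corr.loc[:, constant] = np.nan
    return corr


def cluster(matrix: pd.DataFrame, mode: str = "correlation") -> LinkageTree:
    """UPGMA clustering on distance 1 - Pearson r.

    ``mode='correlation'``: input is a square symmetric correlation matrix.
    ``mode='nes'``: input rows are responses; row-wise Pearson correlation is
    computed first. Labels are sorted lexicographically before linkage so
    ties break deterministically.
    """
    if mode == "correlation":
        if matrix.shape[0] != matrix.shape[1]:
            raise ValueError("correlation input must be square")
        arr = matrix.to_numpy(dtype=float)
        if not np.allclose(arr, arr.T, atol=1e-8, equal_nan=True):
            raise ValueError("correlation input must be symmetric")
        corr = matrix
    elif mode == "nes":
        corr = matrix.T.corr(method="pearson")
    else:
        raise ValueError(f"unknown mode {mode!r}")

    labels = sorted(str(x) for x in corr.index)
    corr = corr.loc[labels, labels]
    dist = 1.0 - corr.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = squareform(dist, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    return LinkageTree(labels=labels, linkage=linkage)


def _encode_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Numeric encoding: BPD grade 0-3 ordinal, oxygen-at-28d 0/1."""
    encoded = pd.DataFrame(index=clinical.index)
    encoded["gestational_age"] = clinical["gestational_age"].astype(float)
    encoded["birth_weight"] = clinical["birth_weight"].astype(float)
    grade_code = {g: i for i, g in enumerate(BPD_GRADES)}
    encoded["bpd_status"] = clinical["bpd_status"].map(grade_code)
    encoded["o2_at_28d"] = clinical["o2_at_28d"].map({"no": 0, "yes": 1})
    if encoded.isna().any().any():
        bad = encoded.columns[encoded.isna().any()].tolist()
        raise ValueError(f"clinical variables failed to encode: {bad}")
    return encoded


def clinical_association(
    scores: ScoreMatrix | pd.DataFrame,
    clinical: pd.DataFrame,
    stratify_by_sex: bool = True,
) -> pd.DataFrame:
    """Pearson association of each signature score with each clinical
    variable, overall and per sex stratum.

    Returns a tidy frame (signature, variable, stratum, r, p, n); strata
    with fewer than 3 subjects are reported with missing r and p.
    """
    mat = scores.scores if isinstance(scores, ScoreMatrix) else scores
    encoded = _encode_clinical(clinical)
    strata = {"all": pd.Series(True, index=clinical.index)}
    if stratify_by_sex:
        for sex in ("F", "M"):
            strata[sex] = clinical["sex"] == sex

    rows = []
    for sig_name, score_row in mat.iterrows():
        for variable in CLINICAL_VARIABLES:
            for stratum, mask in strata.items():
                idx = clinical.index[mask]
                x = score_row[idx].to_numpy(dtype=float)
                y = encoded.loc[idx, variable].to_numpy(dtype=float)
                n = len(idx)
                if n < 3 or np.std(x) == 0 or np.std(y) == 0:
                    r, p = np.nan, np.nan
                else:
                    r, p = stats.pearsonr(x, y)
                rows.append({"signature": sig_name, "variable": variable,
                             "stratum": stratum, "r": r, "p": p, "n": n})
    return pd.DataFrame(rows)
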