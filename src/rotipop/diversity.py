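"""Alpha and beta diversity of OTU tables.

Alpha metrics (per sample): Good's coverage ``1 - F1/N``, Shannon entropy
in nats, bias-corrected Chao1 richness and Faith's phylogenetic diversity
(root-inclusive).  Beta side: Bray-Curtis dissimilarity, non-metric
multidimensional scaling (SMACOF majorization with isotonic regression on
dissimilarity ranks, Kruskal stress-1 reported) and the ANOSIM permutation
test on ranked dissimilarities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import TreeNode
from skbio.diversity import alpha as _skbio_alpha
from sklearn.manifold import smacof

__all__ = [
    "goods_coverage",
    "shannon",
    "chao1",
    "faith_pd",
    "alpha_table",
    "bray_curtis",
    "nmds",
    "NmdsResult",
    "anosim",
]


def _counts(sample) -> np.ndarray:
    c = np.asarray(sample)
    if c.ndim != 1:
        raise ValueError("expected a 1-D vector of counts")
    if np.any(c < 0):
        raise ValueError("negative counts")
    return c


def goods_coverage(sample) -> float:
    """Good's coverage 1 - F1/N (F1 = singleton OTUs, N = total reads)."""
    c = _counts(sample)
    if c.sum() == 0:
        raise ValueError("empty sample")
    return float(_skbio_alpha.goods_coverage(c.astype(int)))


def shannon(sample) -> float:
    """Shannon entropy over nonzero proportions, natural log."""
    c = _counts(sample)
    if c.sum() == 0:
        raise ValueError("empty sample")
    return float(_skbio_alpha.shannon(c, base=np.e))


def chao1(sample) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1))."""
    c = _counts(sample).astype(int)
    if c.sum() == 0:
        raise ValueError("empty sample")
    return float(_skbio_alpha.chao1(c, bias_corrected=True))


def faith_pd(sample, otu_ids, tree: TreeNode) -> float:
    """Faith's PD: branch length of the minimal root-connecting subtree.

    ``sample`` is aligned with ``otu_ids``; every observed OTU must be a
    tip of ``tree``.
    """
    c = _counts(sample)
    otu_ids = list(otu_ids)
    if len(otu_ids) != c.size:
        raise ValueError("otu_ids length does not match counts")
    observed = [o for o, v in zip(otu_ids, c) if v > 0]
    tips = {t.name for t in tree.tips()}
    missing = [o for o in observed if o not in tips]
    if missing:
        raise ValueError(f"OTUs absent from tree: {missing[:10]}")
    return float(_skbio_alpha.faith_pd(c.astype(int), taxa=otu_ids, tree=tree))


def alpha_table(table, tree: TreeNode | None = None) -> pd.DataFrame:
    """Per-sample coverage, Shannon, Chao1 (and PD when a tree is given)."""
    rows = {}
    for sid in table.sample_ids:
        c = table.counts.loc[sid].to_numpy()
        row = {
            "coverage": goods_coverage(c),
            "shannon": shannon(c),
            "chao1": chao1(c),
        }
        if tree is not None:
            row["pd"] = faith_pd(c, table.otu_ids, tree)
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def bray_curtis(counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity, 1 - 2 sum(min) / (sum_u + sum_v)."""
    if counts.shape[0] < 2:
        raise ValueError("need at least two samples")
    arr = counts.to_numpy(dtype=float)
    if np.any(arr.sum(axis=1) == 0):
        bad = list(counts.index[arr.sum(axis=1) == 0])
        raise ValueError(f"all-zero sample(s): {bad}")
    d = squareform(pdist(arr, metric="braycurtis"))
    return pd.DataFrame(d, index=counts.index, columns=counts.index)


@dataclass(frozen=True)
class NmdsResult:
    coordinates: pd.DataFrame
    stress: float  # Kruskal stress-1
    converged: bool


def nmds(
    dist: pd.DataFrame,
    dims: int = 2,
    n_starts: int = 8,
    max_iter: int = 300,
    seed: int = 0,
) -> NmdsResult:
    """Non-metric MDS by SMACOF majorization with isotonic regression.

    Runs ``n_starts`` random initializations and keeps the configuration
    with the lowest Kruskal stress-1.  A stress above 0.2 is flagged as
    non-converged (the embedding is still returned).
    """
    d = np.asarray(dist, dtype=float)
    if d.shape[0] < dims + 1:
        raise ValueError("need at least dims + 1 samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords, stress = smacof(
            d,
            metric=False,
            n_components=dims,
            n_init=n_starts,
            max_iter=max_iter,
            random_state=np.random.RandomState(seed),
            eps=1e-9,
            normalized_stress=True,
        )
    cols = [f"nmds{i + 1}" for i in range(dims)]
    frame = pd.DataFrame(coords, index=dist.index, columns=cols)
    return NmdsResult(coordinates=frame, stress=float(stress), converged=stress <= 0.2)


def _anosim_r(within: np.ndarray, ranks: np.ndarray, denom: float) -> float:
    return (ranks[~within].mean() - ranks[within].mean()) / denom


def anosim(dist: pd.DataFrame, labels, n_perm: int = 999, seed: int = 0) -> dict:
    """ANOSIM R with an add-one permutation p-value.

    R = (mean between-group rank - mean within-group rank) / (M/2) over the
    M = n(n-1)/2 ranked dissimilarities; group labels are permuted
    ``n_perm`` times and p = (1 + #{R_perm >= R_obs}) / (n_perm + 1).
    """
    labels = np.asarray(list(labels))
    n = labels.size
    if n != dist.shape[0]:
        raise ValueError("labels length does not match distance matrix")
    _, counts = np.unique(labels, return_counts=True)
    if len(counts) < 2 or np.any(counts < 2):
        raise ValueError("need >= 2 groups with >= 2 members each")
    d = np.asarray(dist, dtype=float)
    iu, ju = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu, ju])
    m = ranks.size
    denom = m / 2.0
    within = labels[iu] == labels[ju]
    r_obs = _anosim_r(within, ranks, denom)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        w = perm[iu] == perm[ju]
        if _anosim_r(w, ranks, denom) >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return {"R": float(r_obs), "p": float(p), "n_perm": n_perm}
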