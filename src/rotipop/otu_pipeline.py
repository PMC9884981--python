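"""OTU-table hygiene and accounting.

The cleaning order mirrors standard amplicon practice: drop OTUs whose
lineage contains a chloroplast token, drop singletons (total count of 1
across all samples), then rarefy every sample to a common depth (the
minimum sample total unless an explicit depth is given).  Downstream
helpers cover relative-abundance filtering, Venn partitioning of OTU
presence across groups, and taxonomy aggregation at a named rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import DataIntegrityError

__all__ = [
    "OtuTable",
    "RANKS",
    "remove_chloroplast",
    "remove_singletons",
    "rarefy",
    "abundance_filter",
    "venn_partition",
    "shared_fraction",
    "aggregate_taxonomy",
    "top_k_taxa",
]

RANKS = ["domain", "phylum", "class", "order", "family", "genus", "species"]
_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}


@dataclass(frozen=True)
class OtuTable:
    """Samples x OTUs integer counts with taxonomy and sample metadata.

    ``counts`` is indexed by sample id with one column per OTU;
    ``taxonomy`` maps OTU id to a 7-rank semicolon-delimited lineage;
    ``metadata`` is indexed by sample id with at least ``group``, ``stage``
    and ``replicate`` columns for the study design.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if arr.size and (np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer)):
            if not np.allclose(arr, np.round(arr)) or np.any(arr < 0):
                raise DataIntegrityError("counts must be non-negative integers")
            object.__setattr__(self, "counts", self.counts.round().astype(int))
        missing_tax = set(self.counts.columns) - set(self.taxonomy.index)
        if missing_tax:
            raise DataIntegrityError(f"OTUs without taxonomy: {sorted(missing_tax)[:5]}")
        if set(self.counts.index) != set(self.metadata.index):
            raise DataIntegrityError("sample ids of counts and metadata differ")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)

    def select_otus(self, keep) -> "OtuTable":
        keep = list(keep)
        return OtuTable(
            counts=self.counts[keep],
            taxonomy=self.taxonomy.loc[keep],
            metadata=self.metadata,
        )

    def select_samples(self, keep) -> "OtuTable":
        keep = list(keep)
        return OtuTable(
            counts=self.counts.loc[keep],
            taxonomy=self.taxonomy,
            metadata=self.metadata.loc[keep],
        )


def remove_chloroplast(
    table: OtuTable, tokens: tuple[str, ...] = ("chloroplast",)
) -> tuple[OtuTable, list[str]]:
    """Drop OTUs whose lineage contains any token (case-insensitive, any rank).

    Returns the cleaned table and the list of removed OTU ids.
    """
    low_tokens = tuple(t.lower() for t in tokens)
    removed = [
        otu
        for otu in table.otu_ids
        if any(tok in str(table.taxonomy.loc[otu]).lower() for tok in low_tokens)
    ]
    keep = [o for o in table.otu_ids if o not in set(removed)]
    return table.select_otus(keep), removed


def remove_singletons(table: OtuTable) -> tuple[OtuTable, list[str]]:
    """Drop OTUs whose total count across all samples equals 1."""
    totals = table.counts.sum(axis=0)
    removed = list(totals.index[totals == 1])
    keep = [o for o in table.otu_ids if totals[o] != 1]
    return table.select_otus(keep), removed


def rarefy(table: OtuTable, depth: int | None = None, seed: int = 0) -> OtuTable:
    """Subsample every sample without replacement to a common depth.

    ``depth=None`` uses the minimum sample total (so no sample is dropped);
    with an explicit depth, samples below it are dropped with a warning.
    Subsampling is a multivariate hypergeometric draw per sample.
    """
    totals = table.sample_totals
    if depth is None:
        depth = int(totals.min())
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    keep_samples = list(totals.index[totals >= depth])
    dropped = sorted(set(table.sample_ids) - set(keep_samples))
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below depth {depth}: {dropped[:5]}",
            stacklevel=2,
        )
        if not keep_samples:
            raise ValueError("no sample reaches the requested depth")
    sub = table.select_samples(keep_samples)
    rng = np.random.default_rng(seed)
    out = np.empty(sub.counts.shape, dtype=int)
    for i, (_, row) in enumerate(sub.counts.iterrows()):
        counts = row.to_numpy()
        if counts.sum() == depth:
            out[i] = counts
        else:
            out[i] = rng.multivariate_hypergeometric(counts, depth)
    return OtuTable(
        counts=pd.DataFrame(out, index=sub.counts.index, columns=sub.counts.columns),
        taxonomy=sub.taxonomy,
        metadata=sub.metadata,
    )


def abundance_filter(
    table: OtuTable,
    threshold: float = 0.01,
    mode: str = "any-sample",
    strict: bool = True,
) -> OtuTable:
    """Keep OTUs whose relative abundance exceeds ``threshold``.

    ``mode='any-sample'`` keeps an OTU if it exceeds the threshold in at
    least one sample; ``mode='mean'`` uses the mean relative abundance over
    samples.  ``strict=True`` means strictly greater than.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    rel = table.relative_abundance()
    if mode == "any-sample":
        stat = rel.max(axis=0)
    elif mode == "mean":
        stat = rel.mean(axis=0)
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    mask = stat > threshold if strict else stat >= threshold
    return table.select_otus(list(stat.index[mask]))


def venn_partition(table: OtuTable, by: str = "group") -> dict[frozenset, int]:
    """Count OTUs in every presence/absence region across 2-3 group levels.

    Presence in a level means a nonzero total count over that level's
    samples.  Keys are frozensets of level labels (the region where an OTU
    is present in exactly those levels); OTUs absent everywhere are not
    counted, so the region counts sum to the number of OTUs present in at
    least one level.
    """
    if by not in table.metadata.columns:
        raise KeyError(f"metadata has no column {by!r}")
    levels = sorted(table.metadata[by].unique().tolist())
    if not 2 <= len(levels) <= 3:
        raise ValueError(f"venn_partition supports 2-3 levels, got {len(levels)}")
    presence = {}
    for lvl in levels:
        samples = table.metadata.index[table.metadata[by] == lvl]
        presence[lvl] = table.counts.loc[samples].sum(axis=0) > 0
    regions: dict[frozenset, int] = {}
    for k in range(1, len(levels) + 1):
        for combo in combinations(levels, k):
            inside = np.logical_and.reduce([presence[l].to_numpy() for l in combo])
            outside = [presence[l].to_numpy() for l in levels if l not in combo]
            if outside:
                inside = inside & ~np.logical_or.reduce(outside)
            regions[frozenset(combo)] = int(inside.sum())
    return regions


def shared_fraction(shared: int, total: int) -> float:
    """Percentage of OTUs shared by all groups, to two decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= shared <= total:
        raise ValueError("need 0 <= shared <= total")
    return round(100.0 * shared / total, 2)


def _parse_rank(lineage: str, rank: str) -> str:
    """Label at a rank, falling back to 'unclassified <nearest parent>'."""
    idx = _RANK_INDEX[rank]
    parts = [p.strip() for p in str(lineage).split(";")]
    labels = []
    for p in parts:
        lab = p.split("__", 1)[1] if "__" in p else p
        labels.append(lab.strip())
    label = labels[idx] if idx < len(labels) else ""
    if label and label.lower() not in ("unclassified", "uncultured"):
        return label
    for j in range(idx - 1, -1, -1):
        if j < len(labels) and labels[j] and labels[j].lower() not in (
            "unclassified",
            "uncultured",
        ):
            return f"unclassified {labels[j]}"
    return "unclassified"


def aggregate_taxonomy(table: OtuTable, rank: str) -> pd.DataFrame:
    """Sum counts over OTUs sharing the label at ``rank``.

    Returns a samples x taxa frame; lineages unresolved at the rank
    aggregate under ``unclassified <nearest classified parent>`` so that
    per-sample totals are conserved.
    """
    if rank not in _RANK_INDEX:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labels = table.taxonomy.loc[table.otu_ids].map(lambda s: _parse_rank(s, rank))
    agg = table.counts.T.groupby(labels.values).sum().T
    return agg


def top_k_taxa(aggregated: pd.DataFrame, k: int = 50) -> list[str]:
    """Top-k taxa by mean relative abundance; ties break lexicographically."""
    totals = aggregated.sum(axis=1)
    rel = aggregated.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    mean_rel = rel.mean(axis=0)
    order = sorted(mean_rel.index, key=lambda t: (-mean_rel[t], t))
    return order[: min(k, len(order))]
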