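"""Readers and writers for the package's plain-text formats.

Cohort and density tables are tidy CSV; OTU tables use the classic
QIIME-like TSV dialect (rows are OTUs, first column ``#OTU ID``, one
column per sample, final ``taxonomy`` column) with sample metadata in a
separate TSV; trees are Newick; nested results are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .demography import CohortTable, DensityTable
from .otu_pipeline import OtuTable

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "read_density_csv",
    "write_density_csv",
    "read_otu_tsv",
    "write_otu_tsv",
    "read_tree",
    "write_tree",
    "write_json",
    "read_json",
]


def read_cohort_csv(path, interval: float = 8.0) -> CohortTable:
    return CohortTable(pd.read_csv(path), interval=interval)


def write_cohort_csv(cohort: CohortTable, path) -> None:
    cohort.data.to_csv(path, index=False)


def read_density_csv(path, n0: float = 2.0) -> DensityTable:
    return DensityTable(pd.read_csv(path), n0=n0)


def write_density_csv(density: DensityTable, path) -> None:
    density.data.to_csv(path, index=False)


def read_otu_tsv(table_path, metadata_path) -> OtuTable:
    """Read the OTUs x samples TSV dialect plus a sample metadata TSV."""
    raw = pd.read_csv(table_path, sep="\t", index_col=0)
    if "taxonomy" not in raw.columns:
        raise ValueError("OTU table must have a trailing 'taxonomy' column")
    taxonomy = raw["taxonomy"]
    counts = raw.drop(columns=["taxonomy"]).T.astype(int)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    return OtuTable(counts=counts, taxonomy=taxonomy, metadata=metadata)


def write_otu_tsv(table: OtuTable, table_path, metadata_path=None) -> None:
    out = table.counts.T.copy()
    out.insert(len(out.columns), "taxonomy", table.taxonomy.loc[out.index])
    out.index.name = "#OTU ID"
    out.to_csv(table_path, sep="\t")
    if metadata_path is not None:
        meta = table.metadata.copy()
        meta.index.name = "sample_id"
        meta.to_csv(metadata_path, sep="\t")


def read_tree(path) -> TreeNode:
    return TreeNode.read(str(path))


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path))


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
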