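"""Expression-based validation of a gene signature.

Samples are clustered by agglomerative hierarchical clustering on the
euclidean distances computed over the signature genes' expression
intensities.  If the signature captures disease biology, the resulting
clusters should separate samples with different clinical attributes; the
association is summarized per cluster and tested (Fisher exact or a one-way
F-test on a binary indicator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import f_oneway, fisher_exact

logger = logging.getLogger(__name__)

LINKAGE_METHODS = ("single", "complete", "average", "ward")


@dataclass
class ExpressionDataset:
    """Expression matrix (genes x samples) plus a clinical attribute table.

    ``expression`` rows are gene ids, columns sample ids; ``clinical`` is
    indexed by sample id with one column per attribute.  Clinical sample ids
    must be a subset of expression sample ids; entries must be finite.
    """

    expression: pd.DataFrame
    clinical: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.expression.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.expression.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        if not np.isfinite(self.expression.to_numpy(dtype=float)).all():
            raise ValueError("non-finite expression values")
        if len(self.clinical):
            missing = set(self.clinical.index) - set(self.expression.columns)
            if missing:
                raise ValueError(
                    f"clinical samples absent from expression: {sorted(missing)[:3]}"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.expression.index)


@dataclass
class ClusterAssignment:
    """Sample -> cluster label in {1..k} from hierarchical clustering."""

    assignment: dict[str, int]
    k: int
    linkage: str
    distance: str = "euclidean"

    def members(self, label: int) -> list[str]:
        return [s for s, c in self.assignment.items() if c == label]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column gene id, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip().str.upper()
    return df


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a samples x attributes TSV (first column sample id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g", lineterminator="\n")


def subset_expression(
    data: ExpressionDataset, genes: Iterable[str]
) -> ExpressionDataset:
    """Restrict the matrix rows to the signature genes present in it.

    Missing genes are logged; fewer than 2 matches is an error since no
    meaningful distance can be computed.
    """
    wanted = [g.strip().upper() for g in genes]
    present = [g for g in wanted if g in data.expression.index]
    missing = len(wanted) - len(present)
    if missing:
        logger.info("subset_expression: %d signature genes absent from matrix", missing)
    if len(present) < 2:
        raise ValueError(
            f"only {len(present)} signature gene(s) found in the expression "
            "matrix; need at least 2"
        )
    return ExpressionDataset(
        expression=data.expression.loc[present], clinical=data.clinical
    )


def zscore_genes(data: ExpressionDataset) -> ExpressionDataset:
    """Per-gene standardization (optional; clustering defaults to raw values)."""
    x = data.expression
    sd = x.std(axis=1, ddof=0).replace(0.0, 1.0)
    return ExpressionDataset(
        expression=x.sub(x.mean(axis=1), axis=0).div(sd, axis=0),
        clinical=data.clinical,
    )


def cluster_samples(
    data: ExpressionDataset, k: int = 2, linkage_method: str = "average"
) -> ClusterAssignment:
    """Hierarchical clustering of samples on euclidean expression distance.

    The dendrogram is cut to exactly ``k`` clusters.  SciPy's agglomerative
    merge order is deterministic for a given input order, with equal-distance
    merges resolved by the lowest original index pair.  Cluster labels are
    renumbered 1..k by first appearance in sample order.
    """
    if linkage_method not in LINKAGE_METHODS:
        raise ValueError(f"linkage must be one of {LINKAGE_METHODS}")
    samples = data.samples
    if k < 1 or k > len(samples):
        raise ValueError(f"k={k} outside 1..{len(samples)} samples")
    x = data.expression.to_numpy(dtype=float).T  # samples x genes
    z = linkage(pdist(x, metric="euclidean"), method=linkage_method)
    raw = fcluster(z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    assignment = {s: relabel[lab] for s, lab in zip(samples, raw)}
    got = len(set(assignment.values()))
    if got != k:
        raise RuntimeError(f"dendrogram cut produced {got} clusters, wanted {k}")
    return ClusterAssignment(assignment=assignment, k=k, linkage=linkage_method)


def cluster_clinical_summary(
    assign: ClusterAssignment,
    data: ExpressionDataset,
    numeric_attrs: Sequence[str],
) -> pd.DataFrame:
    """Per-cluster arithmetic mean of each numeric clinical attribute.

    Missing values are excluded attribute-wise; the table carries matching
    ``n_<attr>`` count columns.  Requesting an absent attribute raises with
    the available column names.
    """
    avail = list(data.clinical.columns)
    absent = [a for a in numeric_attrs if a not in avail]
    if absent:
        raise KeyError(f"attributes {absent} not in clinical table; available: {avail}")
    rows = []
    for label in range(1, assign.k + 1):
        members = [s for s in assign.members(label) if s in data.clinical.index]
        sub = data.clinical.loc[members, list(numeric_attrs)].apply(
            pd.to_numeric, errors="coerce"
        )
        row: dict[str, float | int] = {"cluster": label, "n_samples": len(members)}
        for attr in numeric_attrs:
            vals = sub[attr].dropna()
            row[attr] = float(vals.mean()) if len(vals) else float("nan")
            row[f"n_{attr}"] = int(len(vals))
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")


@dataclass(frozen=True)
class AssociationResult:
    p: float
    table: tuple[tuple[int, int], tuple[int, int]]
    method: str
    n_excluded: int


def cluster_association(
    assign: ClusterAssignment,
    binary_attribute: Mapping[str, int | float],
    method: str = "fisher",
    min_coverage: float = 0.9,
) -> AssociationResult:
    """Association between a 2-cluster assignment and a 0/1 attribute.

    ``fisher``: two-sided exact test on the 2x2 contingency table
    (clusters x attribute).  ``anova``: one-way F-test comparing the 0/1
    indicator between the two clusters.  Samples with a missing attribute
    are excluded (logged); coverage below ``min_coverage`` is an error, as
    is a cluster left with no annotated sample.
    """
    if assign.k != 2:
        raise ValueError("association test requires exactly 2 clusters")
    if method not in ("fisher", "anova"):
        raise ValueError(f"unknown method {method!r}")
    values: dict[str, int] = {}
    n_excluded = 0
    for s in assign.assignment:
        v = binary_attribute.get(s)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            n_excluded += 1
            continue
        if v not in (0, 1):
            raise ValueError(f"attribute for {s!r} is {v!r}, expected 0/1")
        values[s] = int(v)
    n_total = len(assign.assignment)
    if n_excluded:
        logger.info("association: %d/%d samples lack the attribute", n_excluded, n_total)
    if n_total and len(values) < min_coverage * n_total:
        raise ValueError(
            f"attribute defined for {len(values)}/{n_total} samples, below "
            f"the {min_coverage:.0%} coverage requirement"
        )
    table = [[0, 0], [0, 0]]
    for s, v in values.items():
        table[assign.assignment[s] - 1][1 - v] += 1  # col 0: positives
    if any(sum(r) == 0 for r in table):
        raise ValueError("a cluster has no sample with the attribute defined")
    if method == "fisher":
        p = float(fisher_exact(table, alternative="two-sided")[1])
    else:
        groups = [
            [v for s, v in values.items() if assign.assignment[s] == lab]
            for lab in (1, 2)
        ]
        if all(len(set(g)) == 1 for g in groups) and groups[0][0] == groups[1][0]:
            p = 1.0  # constant indicator: no variance to test
        else:
            p = float(f_oneway(*groups)[1])
    return AssociationResult(
        p=p,
        table=((table[0][0], table[0][1]), (table[1][0], table[1][1])),
        method=method,
        n_excluded=n_excluded,
    )


def dichotomize(
    attribute: Mapping[str, float], threshold: float = 2000.0
) -> dict[str, int]:
    """Threshold a numeric attribute into 0/1 (1 when value > threshold).

    The default of 2000 days suits time-to-event attributes such as time to
    distant metastasis; missing values propagate as missing.
    """
    out: dict[str, int] = {}
    for s, v in attribute.items():
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        out[s] = int(float(v) > threshold)
    return out
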