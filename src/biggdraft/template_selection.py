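"""COG-profile template selection: which organisms are metabolically closest?

Per-organism COG annotations (protein -> COG -> functional category) are
reduced to the METABOLISM general category, turned into a binary
presence/absence matrix (rows = organisms, columns = COG ids), and compared
with a pairwise distance (Jaccard by default, Hamming by flag).  The k
organisms closest to the query organism supply the template models.  A PCA
view of the profiles (zero-variance columns dropped, z-scored, first two
components) supports visual inspection of metabolic-function variability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.feature_selection import VarianceThreshold
from sklearn.preprocessing import StandardScaler

__all__ = [
    "METABOLISM_CATEGORIES",
    "CogAnnotation",
    "read_cog_tsv",
    "build_profile_matrix",
    "metabolic_distance",
    "top_k_closest",
    "PcaResult",
    "pca_profiles",
    "plot_scores",
]

#: COG functional-category letters grouped under METABOLISM:
#: C energy, G carbohydrates, E amino acids, F nucleotides, H coenzymes,
#: I lipids, P inorganic ions, Q secondary metabolites.
METABOLISM_CATEGORIES = frozenset("CGEFHIPQ")


@dataclass
class CogAnnotation:
    """COG annotation rows for one organism: (protein_id, cog_id, category)."""

    organism: str
    rows: List[Tuple[str, str, str]] = field(default_factory=list)

    def metabolic_cogs(self) -> set:
        """COG ids whose category letters intersect METABOLISM (a protein may
        carry a multi-letter category such as ``EG``)."""
        return {
            cog
            for _, cog, category in self.rows
            if set(category) & METABOLISM_CATEGORIES
        }


def read_cog_tsv(path: Union[str, Path], organism: Optional[str] = None) -> CogAnnotation:
    """Read a COG annotation TSV: protein_id, cog_id, category[, evalue].

    A header row starting with ``protein_id`` is skipped; the organism name
    defaults to the file stem.
    """
    path = Path(path)
    organism = organism or path.stem.removesuffix(".tsv")
    rows: List[Tuple[str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() == "protein_id":
                continue
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            rows.append((fields[0], fields[1], fields[2]))
    return CogAnnotation(organism=organism, rows=rows)


def build_profile_matrix(annotations: Sequence[CogAnnotation]) -> pd.DataFrame:
    """Binary presence/absence matrix of metabolic COGs.

    Rows are organisms (input order), columns the sorted union of metabolic
    COG ids; an entry is 1 iff the organism has at least one protein
    annotated with that COG.  An organism with no metabolic COGs is retained
    as an all-zero row with a warning.
    """
    if len(annotations) < 2:
        raise ValueError("need at least two organisms to build a profile matrix")
    organisms = [a.organism for a in annotations]
    if len(set(organisms)) != len(organisms):
        raise ValueError("duplicate organism names in annotations")
    per_org = {a.organism: a.metabolic_cogs() for a in annotations}
    for org, cogs in per_org.items():
        if not cogs:
            warnings.warn(f"organism {org!r} has no metabolic COGs", stacklevel=2)
    columns = sorted(set().union(*per_org.values())) if any(per_org.values()) else []
    data = np.zeros((len(organisms), len(columns)), dtype=np.int8)
    col_index = {c: j for j, c in enumerate(columns)}
    for i, org in enumerate(organisms):
        for cog in per_org[org]:
            data[i, col_index[cog]] = 1
    return pd.DataFrame(data, index=organisms, columns=columns)


def metabolic_distance(matrix: pd.DataFrame, metric: str = "jaccard") -> pd.DataFrame:
    """Symmetric pairwise distance matrix over binary COG profiles.

    ``jaccard`` (default): 1 - |A & B| / |A | B|, with the distance between
    two empty profiles defined as 0 (with a warning).  ``hamming``: fraction
    of columns at which the profiles differ.
    """
    values = matrix.to_numpy(dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least two organisms")
    if metric == "jaccard":
        inter = values @ values.T
        sizes = values.sum(axis=1)
        union = sizes[:, None] + sizes[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = 1.0 - np.divide(
                inter, union, out=np.ones_like(inter), where=union > 0
            )
        if np.any(union == 0):
            warnings.warn(
                "distance between all-zero profiles defined as 0", stacklevel=2
            )
            dist[union == 0] = 0.0
    elif metric == "hamming":
        if values.shape[1] == 0:
            dist = np.zeros((n, n))
        else:
            diff = values[:, None, :] != values[None, :, :]
            dist = diff.mean(axis=2)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=matrix.index, columns=matrix.index)


def top_k_closest(
    distances: pd.DataFrame, target_organism: str, k: int = 3
) -> List[str]:
    """The k organisms with smallest distance to the target (excluded),
    ties broken lexicographically."""
    if target_organism not in distances.index:
        raise KeyError(f"target organism {target_organism!r} not in distance matrix")
    others = [o for o in distances.index if o != target_organism]
    if k >= len(distances.index):
        raise ValueError(
            f"k={k} but only {len(others)} other organisms are available"
        )
    ranked = sorted(others, key=lambda o: (distances.at[target_organism, o], o))
    return ranked[:k]


@dataclass
class PcaResult:
    """PCA scores (rows aligned with the input matrix) plus the explained
    variance fraction of each returned component."""

    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    components: np.ndarray
    feature_names: List[str]


def pca_profiles(
    matrix: pd.DataFrame,
    variance_threshold: float = 0.0,
    standardize: bool = True,
    n_components: int = 2,
) -> PcaResult:
    """PCA of a binary profile matrix, the standard preprocessing applied.

    Columns with variance <= ``variance_threshold`` (default: exactly zero
    variance) are dropped, the remainder z-scored, and principal components
    extracted with a deterministic full SVD.  Component signs are
    canonicalized so the largest-magnitude loading of each component is
    positive, making scores reproducible across runs and platforms.
    """
    if matrix.shape[0] < 3:
        raise ValueError("PCA requires at least three rows")
    values = matrix.to_numpy(dtype=float)
    selector = VarianceThreshold(threshold=variance_threshold)
    try:
        reduced = selector.fit_transform(values)
    except ValueError as exc:
        raise ValueError("all columns are below the variance threshold") from exc
    if reduced.shape[1] == 0:
        raise ValueError("all columns are below the variance threshold")
    kept = [c for c, keep in zip(matrix.columns, selector.get_support()) if keep]
    if standardize:
        reduced = StandardScaler().fit_transform(reduced)
    n_components = min(n_components, reduced.shape[0], reduced.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(reduced)
    components = pca.components_.copy()
    for i in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] *= -1.0
            scores[:, i] *= -1.0
    return PcaResult(
        scores=pd.DataFrame(
            scores,
            index=matrix.index,
            columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
        ),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        components=components,
        feature_names=list(kept),
    )


def plot_scores(
    result: PcaResult,
    path: Union[str, Path],
    color_by: Optional[Dict[str, str]] = None,
) -> None:
    """Scatter of PC1 vs PC2 with row labels; written as SVG/PNG by suffix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    scores = result.scores
    groups: Dict[str, List[str]] = {}
    for label in scores.index:
        groups.setdefault((color_by or {}).get(label, "model"), []).append(label)
    for group, labels in sorted(groups.items()):
        sub = scores.loc[labels]
        ax.scatter(sub["PC1"], sub["PC2"], label=group, s=30)
        for label in labels:
            ax.annotate(label, (scores.at[label, "PC1"], scores.at[label, "PC2"]),
                        fontsize=7, xytext=(3, 3), textcoords="offset points")
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0] * 100:.1f}% variance)")
    if len(evr) > 1:
        ax.set_ylabel(f"PC2 ({evr[1] * 100:.1f}% variance)")
    if color_by:
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
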