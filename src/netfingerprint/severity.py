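"""PC1 drinking-severity index.

The behavioral target of the whole pipeline: the first principal component
of a battery of intrinsically associated alcohol-consumption measures,
computed on the correlation matrix (i.e., after z-scoring each measure).
Under the correlation-matrix convention the variance explained is exactly
``100 * eigenvalue / n_measures``; a battery whose PC1 eigenvalue is 7.42
over 15 measures therefore explains 49.47% of the variance.

Measures whose direction is protective (e.g., abstinence counts) are
sign-flipped before PCA, and the component is oriented so that it
correlates non-negatively with a named anchor measure (by default the
first column), making higher scores mean more severe drinking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError

__all__ = ["MeasureTable", "SeverityIndex", "compute_severity_pc1", "read_measure_table"]

log = logging.getLogger(__name__)


@dataclass
class MeasureTable:
    """A subjects x measures battery with flip/anchor metadata.

    ``flip_set`` names measures whose sign is inverted before PCA;
    ``anchor`` names the measure used to orient PC1 (non-negative
    correlation). Subjects with any missing measure are dropped at
    construction and recorded in ``excluded_subjects``.
    """

    data: pd.DataFrame
    flip_set: frozenset[str] = frozenset()
    anchor: str | None = None
    excluded_subjects: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.data.shape[1] < 2:
            raise ParameterError("need at least 2 measures")
        missing_names = sorted(set(self.flip_set) - set(self.data.columns))
        if missing_names:
            raise ParameterError(f"flip_set names unknown measures: {missing_names}")
        if self.anchor is not None and self.anchor not in self.data.columns:
            raise ParameterError(f"anchor {self.anchor!r} not among measures")
        bad = self.data.index[self.data.isna().any(axis=1)]
        if len(bad):
            log.info("excluding %d subjects with missing measures", len(bad))
            self.excluded_subjects = tuple(bad)
            self.data = self.data.drop(index=bad)

    @property
    def processed(self) -> pd.DataFrame:
        """Measures after sign flipping."""
        out = self.data.copy()
        for name in self.flip_set:
            out[name] = -out[name]
        return out


@dataclass
class SeverityIndex:
    """PC1 of the drinking battery.

    ``scores`` are standardized (mean 0, SD 1) per-subject severity values;
    ``eigenvalue`` is the leading eigenvalue of the measure correlation
    matrix; ``variance_explained`` is ``100 * eigenvalue / n_measures``;
    ``loadings`` are the component loadings (eigenvector scaled by the
    square root of the eigenvalue).
    """

    scores: pd.Series
    eigenvalue: float
    variance_explained: float
    loadings: pd.Series

    def to_tsv(self, path: str | Path) -> None:
        frame = self.scores.rename("pc1").to_frame()
        frame.to_csv(path, sep="\t")

    def summary(self) -> str:
        lines = [
            f"PC1 eigenvalue      : {self.eigenvalue:.4f}",
            f"variance explained  : {self.variance_explained:.2f}%",
            "loadings:",
        ]
        lines += [f"  {name:<14s} {v:+.3f}" for name, v in self.loadings.items()]
        return "\n".join(lines)


def compute_severity_pc1(
    table: MeasureTable | pd.DataFrame,
    flip: Sequence[str] = (),
    anchor: str | None = None,
) -> SeverityIndex:
    """Correlation-matrix PCA of the (sign-flipped) battery; return PC1.

    Each measure is z-scored, the sample correlation matrix is
    eigendecomposed, and subjects are projected onto the leading
    eigenvector. The projection is standardized to unit variance and
    oriented so its correlation with the anchor measure (after flipping)
    is non-negative.

    Raises
    ------
    DataError
        On missing values (listing offending subjects) or a constant
        measure column (naming it).
    """
    if not isinstance(table, MeasureTable):
        table = MeasureTable(
            pd.DataFrame(table), flip_set=frozenset(flip), anchor=anchor
        )
    data = table.processed
    if data.shape[0] < 3:
        raise DataError(f"need at least 3 subjects, got {data.shape[0]}")
    na_rows = data.index[data.isna().any(axis=1)]
    if len(na_rows):
        raise DataError(f"missing values for subjects: {list(na_rows)}")

    x = data.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    constant = [c for c, s in zip(data.columns, sd) if s == 0.0]
    if constant:
        raise DataError(f"constant measure column(s): {constant}")
    z = (x - x.mean(axis=0)) / sd

    corr = (z.T @ z) / (x.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    eigenvalue = float(eigvals[-1])
    vec = eigvecs[:, -1]

    raw = z @ vec
    anchor_name = table.anchor or data.columns[0]
    orient = float(np.dot(raw - raw.mean(), data[anchor_name] - data[anchor_name].mean()))
    if orient < 0:
        vec = -vec
        raw = -raw
    scores = raw / raw.std(ddof=1)

    m = data.shape[1]
    return SeverityIndex(
        scores=pd.Series(scores, index=data.index, name="pc1"),
        eigenvalue=eigenvalue,
        variance_explained=100.0 * eigenvalue / m,
        loadings=pd.Series(vec * np.sqrt(eigenvalue), index=data.columns, name="loading"),
    )


def read_measure_table(
    path: str | Path,
    flip: Sequence[str] = (),
    anchor: str | None = None,
    drop_columns: Sequence[str] = ("age", "sex"),
) -> MeasureTable:
    """Load a ``behavior.tsv``-style file into a :class:`MeasureTable`.

    Covariate columns (by default ``age`` and ``sex``) are dropped if
    present so the file written by the simulator round-trips.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    keep = [c for c in df.columns if c not in set(drop_columns)]
    return MeasureTable(df[keep], flip_set=frozenset(flip), anchor=anchor)
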