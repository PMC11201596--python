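"""Molecular profiling of regional effect maps.

A regional GLM produces an unthresholded T map of the severity association
per brain region (adjusting for age and sex), and that map is spatially
correlated — Pearson, across gray-matter regions, white matter and CSF
excluded — with region-keyed receptor/transporter density maps rescaled to
[0, 100]. A map is flagged when its parametric two-tailed p falls below
alpha; an optional Benjamini-Hochberg correction across maps is available
but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError

__all__ = [
    "RegionalTMap",
    "ReceptorAtlas",
    "SpatialCorrResult",
    "parcel_glm_tmap",
    "rescale_map",
    "spatial_correlation",
    "read_receptor_atlas",
    "read_tmap",
]


@dataclass
class RegionalTMap:
    """Region-keyed T statistics for one contrast (unthresholded)."""

    values: pd.Series
    contrast: str = ""
    df: int | None = None
    perfect_fit_regions: tuple = ()

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise DataError(f"duplicate region labels in T map: {dupes}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise DataError("T map contains non-finite values")

    def to_tsv(self, path: str | Path) -> None:
        self.values.rename("T").to_frame().to_csv(path, sep="\t", index_label="region")


@dataclass
class ReceptorAtlas:
    """Region-keyed receptor/transporter density maps, rescaled to [0, 100]."""

    maps: pd.DataFrame
    tissue_class: pd.Series
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.maps.columns.has_duplicates:
            dupes = self.maps.columns[self.maps.columns.duplicated()].tolist()
            raise ParameterError(f"duplicate map names: {dupes}")
        missing = self.maps.index.difference(self.tissue_class.index)
        if len(missing):
            raise DataError(f"regions without tissue class: {list(missing)}")

    @property
    def map_names(self) -> list[str]:
        return list(self.maps.columns)

    def gray_regions(self, exclude_classes: Sequence[str] = ("white", "csf")) -> pd.Index:
        tc = self.tissue_class.reindex(self.maps.index)
        return self.maps.index[~tc.isin(set(exclude_classes))]

    def to_tsv(self, path: str | Path) -> None:
        out = self.maps.copy()
        out.insert(0, "tissue_class", self.tissue_class.reindex(out.index))
        out.to_csv(path, sep="\t", index_label="region")


@dataclass
class SpatialCorrResult:
    """Per-map spatial correlation with the T map."""

    table: pd.DataFrame  # map, r, p, n, flagged
    alpha: float
    correction: str | None = None

    @property
    def flagged(self) -> list[str]:
        return self.table.index[self.table["flagged"]].tolist()

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="map")


def parcel_glm_tmap(
    regional_contrasts: pd.DataFrame,
    severity,
    covariates: pd.DataFrame,
    contrast_name: str = "",
) -> RegionalTMap:
    """Region-wise OLS of task contrast on severity, adjusting age and sex.

    For each region, the contrast values across subjects are regressed on
    ``[intercept, severity, age, sex]``; the returned T statistic is the
    severity coefficient over its standard error, with ``n - 4`` residual
    degrees of freedom. Regions fit perfectly (zero residual variance) get
    a large finite T of sign matching the coefficient and are listed in
    ``perfect_fit_regions``.
    """
    y = np.asarray(regional_contrasts, dtype=float)
    n, n_regions = y.shape
    sev = np.asarray(severity, dtype=float)
    if sev.shape != (n,):
        raise DataError(f"severity has shape {sev.shape}, expected ({n},)")
    cov = np.column_stack(
        [np.asarray(covariates["age"], float), np.asarray(covariates["sex"], float)]
    )
    if cov.shape[0] != n:
        raise DataError("covariates not aligned with contrasts")
    x = np.column_stack([np.ones(n), sev, cov])
    p = x.shape[1]
    if n < p + 1:
        raise DataError(f"need at least {p + 1} subjects, got {n}")
    if np.linalg.matrix_rank(x) < p:
        raise DataError("rank-deficient design (collinear severity/covariates)")

    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)  # p x regions
    resid = y - x @ beta
    df = n - p
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df
    scale = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))

    b_sev = beta[1]
    tiny = np.finfo(float).eps * np.abs(y).max() ** 2 * n
    perfect = sigma2 <= tiny
    with np.errstate(divide="ignore", invalid="ignore"):
        t = b_sev / scale
    t[perfect] = np.sign(b_sev[perfect]) * 1e6

    regions = regional_contrasts.columns
    return RegionalTMap(
        values=pd.Series(t, index=regions, name="T"),
        contrast=contrast_name,
        df=df,
        perfect_fit_regions=tuple(regions[perfect]),
    )


def rescale_map(values: pd.Series) -> pd.Series:
    """Affine rescale to min 0, max 100 (order preserving)."""
    v = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(v), np.nanmax(v)
    if not hi > lo:
        raise DataError("cannot rescale a constant map")
    # divide first: the extreme points land on exactly 0 and 100
    out = (v - lo) / (hi - lo) * 100.0
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return pd.Series(out)


def spatial_correlation(
    tmap: RegionalTMap,
    atlas: ReceptorAtlas,
    exclude_classes: Sequence[str] = ("white", "csf"),
    alpha: float = 0.05,
    correction: str | None = None,
    min_regions: int = 10,
) -> SpatialCorrResult:
    """Pearson correlation of the T map with each receptor map.

    Regions are matched by label (order-independent); tissue classes in
    ``exclude_classes`` are dropped before correlation. Each map gets a
    two-tailed parametric p; maps with p < alpha are flagged.
    ``correction="fdr"`` applies Benjamini-Hochberg across maps first.
    """
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha must lie in (0, 1), got {alpha}")
    if correction not in (None, "fdr"):
        raise ParameterError(f"unknown correction {correction!r}")
    usable = atlas.gray_regions(exclude_classes)

    rows = []
    for name in atlas.map_names:
        col = atlas.maps[name].reindex(usable).dropna()
        shared = tmap.values.index.intersection(col.index)
        if len(shared) < min_regions:
            raise DataError(
                f"map {name!r}: only {len(shared)} usable shared regions "
                f"(need {min_regions})"
            )
        r, p = stats.pearsonr(
            tmap.values.reindex(shared).to_numpy(dtype=float),
            col.reindex(shared).to_numpy(dtype=float),
        )
        rows.append({"map": name, "r": float(r), "p": float(p), "n": len(shared)})

    table = pd.DataFrame(rows).set_index("map")
    pvals = table["p"].to_numpy()
    if correction == "fdr":
        pvals = stats.false_discovery_control(pvals, method="bh")
        table["p_corrected"] = pvals
    table["flagged"] = pvals < alpha
    return SpatialCorrResult(table=table, alpha=alpha, correction=correction)


def read_receptor_atlas(path: str | Path) -> ReceptorAtlas:
    """Load ``receptors.tsv``: region, tissue_class, one column per map."""
    df = pd.read_csv(path, sep="\t", index_col="region")
    if "tissue_class" not in df.columns:
        raise DataError("receptors table needs a 'tissue_class' column")
    tissue = df["tissue_class"]
    return ReceptorAtlas(maps=df.drop(columns="tissue_class"), tissue_class=tissue)


def read_tmap(path: str | Path, contrast: str = "") -> RegionalTMap:
    """Load ``tmap.tsv``: region, T."""
    df = pd.read_csv(path, sep="\t", index_col="region")
    return RegionalTMap(values=df.iloc[:, 0].rename("T"), contrast=contrast)
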