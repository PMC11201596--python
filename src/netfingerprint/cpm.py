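"""Connectome-based predictive modeling (CPM).

The protocol: within each training fold, correlate every connectivity edge
with the behavioral score (partial Pearson correlation controlling age and
sex), keep edges passing a p threshold split by correlation sign into a
positive and a negative network, summarize each subject by the summed edge
strength over each network, fit an ordinary least-squares model of behavior
on the strengths, and predict the held-out subjects. Model performance is
the Pearson correlation between cross-validated predictions and observed
scores; significance comes from re-running the whole procedure on permuted
behavior labels.

Edge selection is strictly training-fold-internal — held-out subjects never
influence the mask — and the positive and negative networks are disjoint by
construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError

__all__ = [
    "EdgeMask",
    "CPMResult",
    "PermutationResult",
    "edge_behavior_correlation",
    "select_edges",
    "network_strength",
    "fit_predict",
    "permutation_test",
]

log = logging.getLogger(__name__)

Edge = tuple[int, int]


@dataclass(frozen=True)
class EdgeMask:
    """Disjoint signed sets of unordered node pairs.

    ``positive`` edges correlate positively with behavior, ``negative``
    edges negatively. Pairs are stored as (i, j) with i < j.
    """

    positive: frozenset[Edge] = frozenset()
    negative: frozenset[Edge] = frozenset()

    def __post_init__(self) -> None:
        for name, edges in (("positive", self.positive), ("negative", self.negative)):
            for i, j in edges:
                if i == j:
                    raise ParameterError(f"{name} mask contains self-pair ({i}, {j})")
                if i > j:
                    raise ParameterError(
                        f"{name} mask pair ({i}, {j}) not in canonical (i < j) order"
                    )
        overlap = self.positive & self.negative
        if overlap:
            raise ParameterError(
                f"positive and negative masks overlap: {sorted(overlap)}"
            )

    @classmethod
    def from_edges(cls, positive: Sequence[Edge] = (), negative: Sequence[Edge] = ()):
        canon = lambda es: frozenset((min(i, j), max(i, j)) for i, j in es)
        return cls(positive=canon(positive), negative=canon(negative))

    @property
    def n_edges(self) -> int:
        return len(self.positive) + len(self.negative)

    def write(self, path_pos: str | Path, path_neg: str | Path) -> None:
        for path, edges in ((path_pos, self.positive), (path_neg, self.negative)):
            lines = ["# node_i\tnode_j (0-based)"]
            lines += [f"{i}\t{j}" for i, j in sorted(edges)]
            Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path_pos: str | Path, path_neg: str | Path) -> "EdgeMask":
        def load(path):
            edges = []
            for line in Path(path).read_text().splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                i, j = line.split("\t")
                edges.append((int(i), int(j)))
            return edges

        return cls.from_edges(load(path_pos), load(path_neg))


@dataclass
class CPMResult:
    """Cross-validated CPM output.

    ``r`` is the Pearson correlation of predicted vs observed behavior
    (mean over repeats for repeated k-fold; per-repeat values are kept in
    ``r_per_repeat``). ``p`` is filled in by :func:`permutation_test`.
    ``consensus_mask`` contains edges selected in at least
    ``consensus_fraction`` of all folds.
    """

    observed: pd.Series
    predicted: pd.Series
    r: float
    scheme: str
    k: int | None
    repeats: int
    p_threshold: float
    network: str
    seed: int | None
    fold_masks: list[EdgeMask] = field(default_factory=list)
    consensus_mask: EdgeMask = field(default_factory=EdgeMask)
    consensus_fraction: float = 1.0
    r_per_repeat: np.ndarray = field(default_factory=lambda: np.zeros(0))
    degenerate_folds: int = 0
    p: float | None = None
    n_permutations: int | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.observed)

    def to_jsonable(self) -> dict:
        return {
            "r": float(self.r),
            "p": None if self.p is None else float(self.p),
            "n_permutations": self.n_permutations,
            "scheme": self.scheme,
            "k": self.k,
            "repeats": self.repeats,
            "p_threshold": self.p_threshold,
            "network": self.network,
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "r_per_repeat": [float(x) for x in self.r_per_repeat],
            "consensus_fraction": self.consensus_fraction,
            "consensus_positive": sorted(map(list, self.consensus_mask.positive)),
            "consensus_negative": sorted(map(list, self.consensus_mask.negative)),
            "degenerate_folds": self.degenerate_folds,
        }


@dataclass
class PermutationResult:
    p: float
    r_observed: float
    r_permuted: np.ndarray
    n_permutations: int


# ---------------------------------------------------------------------------
# internals


def _stack_edges(matrices) -> tuple[np.ndarray, int, tuple[np.ndarray, np.ndarray]]:
    """(n_subjects, n_nodes, n_nodes) -> (n_subjects, n_edges) upper triangle."""
    arr = np.asarray(
        [m.values if hasattr(m, "values") and not isinstance(m, np.ndarray) else m
         for m in matrices],
        dtype=float,
    )
    if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
        raise DataError(f"expected stacked square matrices, got shape {arr.shape}")
    n_nodes = arr.shape[1]
    iu = np.triu_indices(n_nodes, k=1)
    return arr[:, iu[0], iu[1]], n_nodes, iu


def _as_covariate_array(covariates, n: int) -> np.ndarray | None:
    if covariates is None:
        return None
    if isinstance(covariates, pd.DataFrame):
        x = covariates.to_numpy(dtype=float)
    else:
        x = np.asarray(covariates, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
    if x.shape[0] != n:
        raise DataError(f"covariates have {x.shape[0]} rows, expected {n}")
    if np.isnan(x).any():
        raise DataError("covariates contain missing values")
    return x


def _partial_corr_columns(
    e: np.ndarray, y: np.ndarray, x: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, int]:
    """Partial Pearson r of each column of ``e`` with ``y`` given ``x``.

    Returns (r, p, df) with df = n - 2 - q; constant columns give NaN.
    Residualization uses a QR projection, equivalent to
    residualize-then-correlate.
    """
    n = e.shape[0]
    q = 0 if x is None else x.shape[1]
    z = np.ones((n, 1)) if x is None else np.column_stack([np.ones(n), x])
    qmat, _ = np.linalg.qr(z)
    e_r = e - qmat @ (qmat.T @ e)
    y_r = y - qmat @ (qmat.T @ y)

    e_norm = np.linalg.norm(e_r, axis=0)
    y_norm = np.linalg.norm(y_r)
    if y_norm == 0.0:
        raise DataError("behavior is constant after covariate adjustment")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (e_r.T @ y_r) / (e_norm * y_norm)
    r[e_norm == 0.0] = np.nan
    r = np.clip(r, -1.0, 1.0)

    df = n - 2 - q
    if df < 1:
        raise DataError(f"too few subjects ({n}) for {q} covariates")
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return r, p, df


def _residualized_behavior_corr(
    e: np.ndarray, y: np.ndarray, x: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, int]:
    """Simple correlation of edges with covariate-residualized behavior."""
    n = e.shape[0]
    if x is not None:
        z = np.column_stack([np.ones(n), x])
        beta, *_ = np.linalg.lstsq(z, y, rcond=None)
        y = y - z @ beta
    return _partial_corr_columns(e, y, None)


_METHODS = {"partial": _partial_corr_columns, "residualized": _residualized_behavior_corr}


# ---------------------------------------------------------------------------
# public operations


def edge_behavior_correlation(
    matrices,
    behavior,
    covariates=None,
    method: str = "partial",
) -> pd.DataFrame:
    """Per-edge association between connectivity and behavior.

    For every upper-triangle edge, the partial Pearson correlation between
    the edge values and the behavior across subjects, controlling the
    covariates, with a two-tailed p from the t transform on ``n - 2 - q``
    degrees of freedom. ``method="residualized"`` instead correlates raw
    edge values with covariate-residualized behavior.

    Returns a DataFrame with columns ``i, j, r, p, df, constant`` (constant
    edges are flagged and carry NaN statistics).
    """
    if method not in _METHODS:
        raise ParameterError(f"unknown method {method!r}; use 'partial' or 'residualized'")
    e, _, iu = _stack_edges(matrices)
    n = e.shape[0]
    if n < 10:
        raise DataError(f"need at least 10 subjects, got {n}")
    y = np.asarray(behavior, dtype=float)
    if y.shape != (n,):
        raise DataError(f"behavior has shape {y.shape}, expected ({n},)")
    if np.ptp(y) == 0.0:
        raise DataError("behavior is constant")
    x = _as_covariate_array(covariates, n)
    q = 0 if x is None else x.shape[1]
    if n < q + 3:
        raise DataError(f"need at least covariates + 3 = {q + 3} subjects, got {n}")

    r, p, df = _METHODS[method](e, y, x)
    return pd.DataFrame(
        {
            "i": iu[0],
            "j": iu[1],
            "r": r,
            "p": p,
            "df": df,
            "constant": np.isnan(r),
        }
    )


def select_edges(edge_stats: pd.DataFrame, p_threshold: float = 0.01) -> EdgeMask:
    """Threshold the per-edge statistics into a signed mask."""
    if not 0.0 < p_threshold <= 1.0:
        raise ParameterError(f"p_threshold must lie in (0, 1], got {p_threshold}")
    ok = edge_stats["p"].to_numpy() < p_threshold if p_threshold < 1.0 else np.isfinite(
        edge_stats["r"].to_numpy()
    )
    r = edge_stats["r"].to_numpy()
    ii = edge_stats["i"].to_numpy()
    jj = edge_stats["j"].to_numpy()
    pos = frozenset(
        (int(a), int(b)) for a, b in zip(ii[ok & (r > 0)], jj[ok & (r > 0)])
    )
    neg = frozenset(
        (int(a), int(b)) for a, b in zip(ii[ok & (r < 0)], jj[ok & (r < 0)])
    )
    return EdgeMask(positive=pos, negative=neg)


def network_strength(matrix, mask: EdgeMask) -> tuple[float, float]:
    """Summed edge values over the positive and negative networks."""
    m = matrix.values if hasattr(matrix, "values") and not isinstance(matrix, np.ndarray) else matrix
    m = np.asarray(m, dtype=float)
    n = m.shape[0]
    for i, j in list(mask.positive) + list(mask.negative):
        if j >= n:
            raise ParameterError(f"mask edge ({i}, {j}) outside {n}-node matrix")
    pos = float(sum(m[i, j] for i, j in mask.positive))
    neg = float(sum(m[i, j] for i, j in mask.negative))
    return pos, neg


def _folds(n: int, scheme: str, k: int | None, rng: np.random.Generator):
    if scheme == "loocv":
        for i in range(n):
            test = np.array([i])
            train = np.delete(np.arange(n), i)
            yield train, test
    elif scheme == "kfold":
        order = rng.permutation(n)
        for part in np.array_split(order, k):
            test = np.sort(part)
            train = np.setdiff1d(np.arange(n), test)
            yield train, test
    else:  # pragma: no cover - validated upstream
        raise ParameterError(f"unknown scheme {scheme!r}")


def _select_columns(
    e_train: np.ndarray, y_train: np.ndarray, x_train, method: str, p_threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    r, p, _ = _METHODS[method](e_train, y_train, x_train)
    ok = p < p_threshold
    pos_cols = np.flatnonzero(ok & (r > 0))
    neg_cols = np.flatnonzero(ok & (r < 0))
    return pos_cols, neg_cols


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r, defined as 0.0 when either side is constant."""
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def fit_predict(
    matrices,
    behavior,
    covariates=None,
    *,
    scheme: str = "loocv",
    k: int = 5,
    repeats: int = 1,
    p_threshold: float = 0.01,
    network: str = "combined",
    method: str = "partial",
    consensus_fraction: float = 1.0,
    seed: int | None = None,
) -> CPMResult:
    """Cross-validated CPM prediction of behavior from connectivity.

    Per fold: edges are selected on training subjects only, an OLS model of
    behavior on network strength (one predictor for ``network="positive"``
    or ``"negative"``, two for ``"combined"``) is fit on the training fold,
    and the held-out subjects are predicted. ``r`` is the Pearson
    correlation of predictions with observations over all subjects; for
    repeated k-fold it is the mean over repeats.

    A training fold whose strengths are constant (e.g., no edges selected)
    falls back to an intercept-only model and is counted in
    ``degenerate_folds``.
    """
    if scheme not in ("loocv", "kfold"):
        raise ParameterError(f"scheme must be 'loocv' or 'kfold', got {scheme!r}")
    if scheme == "kfold" and k < 2:
        raise ParameterError(f"k must be at least 2, got {k}")
    if network not in ("positive", "negative", "combined"):
        raise ParameterError(f"unknown network {network!r}")
    if not 0.0 < consensus_fraction <= 1.0:
        raise ParameterError("consensus_fraction must lie in (0, 1]")
    if method not in _METHODS:
        raise ParameterError(f"unknown method {method!r}")

    e, _, iu = _stack_edges(matrices)
    n = e.shape[0]
    y = np.asarray(behavior, dtype=float)
    index = behavior.index if isinstance(behavior, pd.Series) else pd.RangeIndex(n)
    if y.shape != (n,):
        raise DataError(f"behavior has shape {y.shape}, expected ({n},)")
    if np.ptp(y) == 0.0:
        raise DataError("behavior is constant")
    x = _as_covariate_array(covariates, n)

    rng = np.random.default_rng(seed)
    n_repeats = 1 if scheme == "loocv" else repeats
    if scheme == "loocv" and repeats != 1:
        log.info("LOOCV is deterministic; ignoring repeats=%d", repeats)

    r_per_repeat = np.empty(n_repeats)
    first_predictions: np.ndarray | None = None
    fold_masks: list[EdgeMask] = []
    pos_counts: dict[Edge, int] = {}
    neg_counts: dict[Edge, int] = {}
    n_folds_total = 0
    degenerate = 0

    for rep in range(n_repeats):
        preds = np.empty(n)
        for train, test in _folds(n, scheme, k, rng):
            x_train = None if x is None else x[train]
            pos_cols, neg_cols = _select_columns(
                e[train], y[train], x_train, method, p_threshold
            )
            mask = EdgeMask(
                positive=frozenset(
                    (int(iu[0][c]), int(iu[1][c])) for c in pos_cols
                ),
                negative=frozenset(
                    (int(iu[0][c]), int(iu[1][c])) for c in neg_cols
                ),
            )
            fold_masks.append(mask)
            n_folds_total += 1
            for edge in mask.positive:
                pos_counts[edge] = pos_counts.get(edge, 0) + 1
            for edge in mask.negative:
                neg_counts[edge] = neg_counts.get(edge, 0) + 1

            predictors = []
            if network in ("positive", "combined"):
                predictors.append(e[:, pos_cols].sum(axis=1))
            if network in ("negative", "combined"):
                predictors.append(e[:, neg_cols].sum(axis=1))
            s = np.column_stack(predictors)
            usable = [c for c in range(s.shape[1]) if np.ptp(s[train, c]) > 0.0]
            if not usable:
                degenerate += 1
                log.warning("degenerate training fold: intercept-only prediction")
                preds[test] = y[train].mean()
                continue
            design = np.column_stack([np.ones(n), s[:, usable]])
            beta, *_ = np.linalg.lstsq(design[train], y[train], rcond=None)
            preds[test] = design[test] @ beta

        r_per_repeat[rep] = _safe_pearson(preds, y)
        if first_predictions is None:
            first_predictions = preds.copy()

    need = int(np.ceil(consensus_fraction * n_folds_total))
    consensus = EdgeMask(
        positive=frozenset(e_ for e_, c in pos_counts.items() if c >= need),
        negative=frozenset(
            e_ for e_, c in neg_counts.items()
            if c >= need and e_ not in pos_counts
        ),
    )

    return CPMResult(
        observed=pd.Series(y, index=index, name="observed"),
        predicted=pd.Series(first_predictions, index=index, name="predicted"),
        r=float(r_per_repeat.mean()),
        scheme=scheme,
        k=k if scheme == "kfold" else None,
        repeats=n_repeats,
        p_threshold=p_threshold,
        network=network,
        seed=seed,
        fold_masks=fold_masks,
        consensus_mask=consensus,
        consensus_fraction=consensus_fraction,
        r_per_repeat=r_per_repeat,
        degenerate_folds=degenerate,
    )


def permutation_test(
    matrices,
    behavior,
    covariates=None,
    *,
    n_perm: int = 1000,
    seed: int | None = None,
    result: CPMResult | None = None,
    **cpm_kwargs,
) -> PermutationResult:
    """Permutation significance of the cross-validated prediction r.

    Behavior labels are permuted across subjects while covariates stay
    bound to their subjects, the full cross-validation (selection included)
    is re-run per permutation, and

        p = (1 + #{r_perm >= r_obs}) / (1 + n_perm).

    Pass ``result`` to reuse an already-computed observed fit (it must come
    from the same data and settings); its ``p`` and ``n_permutations``
    fields are filled in.
    """
    if n_perm < 1:
        raise ParameterError(f"n_perm must be at least 1, got {n_perm}")
    ss = np.random.SeedSequence(seed)
    cv_seed, perm_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))

    y = np.asarray(behavior, dtype=float)
    if result is None:
        result = fit_predict(
            matrices, behavior, covariates, seed=cv_seed, **cpm_kwargs
        )
    r_obs = result.r

    kwargs = dict(cpm_kwargs)
    kwargs.setdefault("scheme", result.scheme)
    if result.k is not None:
        kwargs.setdefault("k", result.k)
    kwargs.setdefault("repeats", result.repeats)
    kwargs.setdefault("p_threshold", result.p_threshold)
    kwargs.setdefault("network", result.network)

    rng = np.random.default_rng(perm_seed)
    r_perm = np.empty(n_perm)
    for b in range(n_perm):
        y_b = y[rng.permutation(len(y))]
        res_b = fit_predict(
            matrices, y_b, covariates,
            seed=int(rng.integers(0, 2**31)), **kwargs,
        )
        r_perm[b] = res_b.r

    p = (1.0 + float(np.sum(r_perm >= r_obs))) / (1.0 + n_perm)
    result.p = p
    result.n_permutations = n_perm
    return PermutationResult(
        p=p, r_observed=r_obs, r_permuted=r_perm, n_permutations=n_perm
    )
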