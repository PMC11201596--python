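"""Synthetic cohorts with known ground truth.

Everything downstream of this module (severity PCA, connectivity, CPM,
anatomy, molecular correlation) is validated against cohorts generated here,
where the latent drinking severity, the behavior-coupled edges, and the
receptor-map associations are all planted and therefore recoverable.

The generator emulates the statistical structure of a large task-fMRI
cohort: a 15-measure drinking battery with a single dominant factor, age
that differs by sex, block-structured node time courses whose planted edge
correlations shift linearly with severity, and region-keyed receptor /
transporter density maps with chosen spatial associations to a target
effect map.

Deliberate simplifications (see docs/methods.md): frame noise is i.i.d.
Gaussian with no temporal autocorrelation, severity enters edge strength
linearly, and no hemodynamics or motion are modeled.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, SimulationError

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_behavior",
    "simulate_timeseries",
    "simulate_cohort",
    "simulate_receptor_atlas",
    "simulate_regional_contrasts",
    "make_positive_definite",
    "synthetic_atlas_annotation",
    "write_cohort",
    "RECEPTOR_MAP_NAMES",
]

#: The 27 receptor / transporter systems covered by the molecular stage.
RECEPTOR_MAP_NAMES: tuple[str, ...] = (
    "5-HT1a_1", "5-HT1a_2", "5-HT1b_1", "5-HT1b_2", "5-HT2a_1", "5-HT2a_2",
    "5-HT4", "CB1", "D1", "D2_1", "D2_2", "FDOPA", "GABAa_1", "GABAa_2",
    "MOR_1", "MOR_2", "mGluR5_1", "mGluR5_2", "mGluR5_3", "DAT", "NAT",
    "SERT_1", "SERT_2", "SERT_3", "VAChT_1", "VAChT_2", "VAChT_3",
)

Edge = tuple[int, int]


def _normalize_edges(edges: Sequence[Edge], n_nodes: int, what: str) -> list[Edge]:
    out: list[Edge] = []
    for e in edges:
        i, j = int(e[0]), int(e[1])
        if i == j:
            raise ParameterError(f"{what}: self-pair ({i}, {j}) is not an edge")
        if not (0 <= i < n_nodes and 0 <= j < n_nodes):
            raise ParameterError(
                f"{what}: edge ({i}, {j}) outside node range [0, {n_nodes})"
            )
        out.append((min(i, j), max(i, j)))
    if len(set(out)) != len(out):
        raise ParameterError(f"{what}: duplicate edges after canonical ordering")
    return out


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Defaults describe the study conditions the package targets: a
    ~10^2-10^3-subject cohort, a 15-measure battery with one dominant
    component explaining about half the variance, and block-structured
    task time series for reward and punishment conditions.

    Parameters
    ----------
    n_subjects : cohort size.
    n_nodes : number of atlas nodes (the real atlas has 268; tests use
        fewer to keep matrices small).
    frames_per_block, n_blocks_per_condition : block structure; total
        frames per condition is their product.
    n_measures : size of the drinking battery (default 15).
    factor_loading : loading of every measure on the latent severity
        factor, in [0, 1]. The default 0.677 puts the first principal
        component's variance share at (1 + 14*lambda^2)/15 ~ 49.5%.
    n_flipped_measures : how many measures are generated with inverted
        sign (severity-protective direction), to exercise the flip rule.
    planted_pos_edges / planted_neg_edges : node pairs whose correlation
        shifts by +/- effect_size per SD of latent severity.
    effect_size : maximum mean |correlation shift| per unit severity.
    base_connectivity : correlation of planted edges at severity 0.
    noise_sd : SD of the i.i.d. measurement noise on behavior measures.
    seed : default random seed for all stages of this cohort.
    """

    n_subjects: int = 500
    n_nodes: int = 60
    frames_per_block: int = 75
    n_blocks_per_condition: int = 4
    n_measures: int = 15
    factor_loading: float = 0.677
    n_flipped_measures: int = 3
    planted_pos_edges: tuple[Edge, ...] = ()
    planted_neg_edges: tuple[Edge, ...] = ()
    effect_size: float = 0.0
    base_connectivity: float = 0.2
    noise_sd: float = 1.0
    conditions: tuple[str, ...] = ("reward", "punishment")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be positive")
        if self.n_nodes < 2:
            raise ParameterError("n_nodes must be at least 2")
        if self.n_measures < 2:
            raise ParameterError("n_measures must be at least 2")
        if not 0.0 <= self.factor_loading <= 1.0:
            raise ParameterError(
                f"factor_loading must lie in [0, 1], got {self.factor_loading}"
            )
        if not 0 <= self.n_flipped_measures <= self.n_measures:
            raise ParameterError("n_flipped_measures outside [0, n_measures]")
        pos = _normalize_edges(self.planted_pos_edges, self.n_nodes, "planted_pos_edges")
        neg = _normalize_edges(self.planted_neg_edges, self.n_nodes, "planted_neg_edges")
        if set(pos) & set(neg):
            raise ParameterError(
                f"planted positive and negative edges overlap: {sorted(set(pos) & set(neg))}"
            )
        object.__setattr__(self, "planted_pos_edges", tuple(pos))
        object.__setattr__(self, "planted_neg_edges", tuple(neg))
        if not -1.0 < self.base_connectivity < 1.0:
            raise ParameterError("base_connectivity must lie in (-1, 1)")
        # 3-SD safety margin: planted correlations stay inside (-1, 1) for
        # severities up to |z| = 3.
        reach = abs(self.base_connectivity) + 3.0 * abs(self.effect_size)
        if (pos or neg) and reach >= 1.0:
            raise ParameterError(
                "planted correlations can leave (-1, 1): "
                f"|base| + 3*|effect| = {reach:.3f} >= 1"
            )

    @property
    def frames_per_condition(self) -> int:
        return self.frames_per_block * self.n_blocks_per_condition

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted_pos_edges"] = [list(e) for e in self.planted_pos_edges]
        d["planted_neg_edges"] = [list(e) for e in self.planted_neg_edges]
        d["conditions"] = list(self.conditions)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        for key in ("planted_pos_edges", "planted_neg_edges"):
            if key in d:
                d[key] = tuple(tuple(e) for e in d[key])
        if "conditions" in d:
            d["conditions"] = tuple(d["conditions"])
        return cls(**d)


@dataclass
class GroundTruth:
    """What was planted, for downstream recovery checks."""

    latent_severity: np.ndarray | None = None
    flipped_measures: tuple[str, ...] = ()
    planted_pos_edges: tuple[Edge, ...] = ()
    planted_neg_edges: tuple[Edge, ...] = ()
    edge_effect_sizes: dict[Edge, float] = field(default_factory=dict)
    planted_receptor_r: dict[str, float] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "latent_severity": None
            if self.latent_severity is None
            else [float(x) for x in self.latent_severity],
            "flipped_measures": list(self.flipped_measures),
            "planted_pos_edges": [list(e) for e in self.planted_pos_edges],
            "planted_neg_edges": [list(e) for e in self.planted_neg_edges],
            "edge_effect_sizes": {
                f"{i}-{j}": float(v) for (i, j), v in self.edge_effect_sizes.items()
            },
            "planted_receptor_r": {k: float(v) for k, v in self.planted_receptor_r.items()},
        }


# ---------------------------------------------------------------------------
# behavior battery


def simulate_behavior(
    config: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw a one-factor drinking battery plus age/sex covariates.

    Each measure j is ``lambda * latent + sqrt(1 - lambda^2) * eps_j`` with
    i.i.d. standard-normal noise, so the population correlation matrix is
    compound-symmetric with off-diagonal lambda^2 and its leading eigenvalue
    is ``1 + (m - 1) * lambda^2``. The first ``n_flipped_measures`` columns
    are sign-inverted to mimic severity-protective items. Age is normal with
    a sex-shifted mean (men 27.9 +/- 3.6 y, women 29.6 +/- 3.6 y).

    Returns
    -------
    (measures, covariates, truth) where ``measures`` is subjects x m,
    ``covariates`` has ``age`` and ``sex`` (0 = male, 1 = female), and
    ``truth`` carries the latent severity.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, m, lam = config.n_subjects, config.n_measures, config.factor_loading

    latent = rng.standard_normal(n)
    eps = rng.standard_normal((n, m))
    raw = lam * latent[:, None] + np.sqrt(1.0 - lam**2) * eps
    names = [f"measure_{j + 1:02d}" for j in range(m)]
    flipped = tuple(names[: config.n_flipped_measures])
    signs = np.ones(m)
    signs[: config.n_flipped_measures] = -1.0
    measures = pd.DataFrame(raw * signs, columns=names)
    measures.index = [f"sub-{i + 1:04d}" for i in range(n)]
    measures.index.name = "subject"

    sex = rng.integers(0, 2, size=n)  # 0 = male, 1 = female
    age = np.where(sex == 0, rng.normal(27.9, 3.6, n), rng.normal(29.6, 3.6, n))
    covariates = pd.DataFrame({"age": age, "sex": sex}, index=measures.index)

    truth = GroundTruth(
        latent_severity=latent,
        flipped_measures=flipped,
        planted_pos_edges=config.planted_pos_edges,
        planted_neg_edges=config.planted_neg_edges,
    )
    return measures, covariates, truth


# ---------------------------------------------------------------------------
# positive-definite repair


def make_positive_definite(
    matrix: np.ndarray, floor: float = 1e-6
) -> np.ndarray:
    """Repair a symmetric matrix to a valid correlation matrix.

    Eigenvalues are clipped at ``floor``, the matrix is reassembled and
    rescaled to unit diagonal. A matrix that is already positive definite
    with unit diagonal is returned unchanged (as a copy).
    """
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ParameterError(f"expected a square matrix, got shape {a.shape}")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ParameterError("matrix is not symmetric")
    w, v = np.linalg.eigh(a)
    if w[0] >= floor and np.allclose(np.diag(a), 1.0, atol=1e-12):
        return a.copy()
    # alternate eigenvalue clipping with unit-diagonal rescaling: the
    # rescale can push the smallest eigenvalue back under the floor, so
    # iterate until both constraints hold
    out = a
    for _ in range(100):
        w, v = np.linalg.eigh(out)
        if w[0] >= floor * (1.0 - 1e-9):
            break
        w = np.clip(w, floor, None)
        out = (v * w) @ v.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        out = (out + out.T) / 2.0
        np.fill_diagonal(out, 1.0)
    return out.copy()


# ---------------------------------------------------------------------------
# time series


def _subject_correlation(
    config: SimulationConfig, severity: float, repair_tol: float = 0.05
) -> np.ndarray:
    c = np.eye(config.n_nodes)
    planted = [(e, +1.0) for e in config.planted_pos_edges] + [
        (e, -1.0) for e in config.planted_neg_edges
    ]
    for (i, j), sign in planted:
        val = config.base_connectivity + sign * config.effect_size * severity
        val = float(np.clip(val, -0.999, 0.999))
        c[i, j] = c[j, i] = val
    repaired = make_positive_definite(c)
    delta = np.abs(repaired - c)
    if delta.max() > repair_tol:
        bad = np.argwhere(delta > repair_tol)
        edges = sorted({(min(i, j), max(i, j)) for i, j in bad if i != j})
        raise SimulationError(
            "planted correlation matrix not repairable within "
            f"{repair_tol}: offending edges {edges}"
        )
    return repaired


def simulate_timeseries(
    config: SimulationConfig,
    latent_severity: np.ndarray,
    seed: int | None = None,
) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Draw per-subject, per-condition node time courses.

    For subject i the frames are i.i.d. draws from a zero-mean multivariate
    normal whose correlation matrix is the identity except at planted edges,
    which sit at ``base_connectivity + sign * effect_size * severity_i``
    (positive-list edges strengthen with severity, negative-list edges
    weaken). The matrix is repaired to positive definite by eigenvalue
    clipping when planting makes it indefinite.

    Returns a dict mapping condition name to an array of shape
    ``(n_subjects, frames_per_condition, n_nodes)`` plus the ground truth.
    """
    if config.frames_per_block < 1 or config.n_blocks_per_condition < 1:
        raise ParameterError(
            "frames_per_block and n_blocks_per_condition must be positive"
        )
    severity = np.asarray(latent_severity, dtype=float)
    if severity.shape != (config.n_subjects,):
        raise ParameterError(
            f"latent_severity has length {severity.size}, expected {config.n_subjects}"
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, nodes, frames = config.n_subjects, config.n_nodes, config.frames_per_condition
    planted = config.planted_pos_edges or config.planted_neg_edges

    out: dict[str, np.ndarray] = {}
    for condition in config.conditions:
        data = np.empty((n, frames, nodes))
        for i in range(n):
            z = rng.standard_normal((frames, nodes))
            if planted and condition != "fixation":
                corr = _subject_correlation(config, severity[i])
                chol = np.linalg.cholesky(corr)
                data[i] = z @ chol.T
            else:
                # identity correlation: the draw itself
                data[i] = z
        out[condition] = data

    effects = {e: config.effect_size for e in config.planted_pos_edges}
    effects.update({e: -config.effect_size for e in config.planted_neg_edges})
    truth = GroundTruth(
        latent_severity=severity,
        planted_pos_edges=config.planted_pos_edges,
        planted_neg_edges=config.planted_neg_edges,
        edge_effect_sizes=effects,
    )
    return out, truth


def simulate_cohort(
    config: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, np.ndarray], GroundTruth]:
    """Behavior battery + covariates + time series from one seed."""
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    s_beh, s_ts = root.spawn(2)
    measures, covariates, truth = simulate_behavior(
        config, seed=int(s_beh.generate_state(1)[0] % 2**31)
    )
    series, ts_truth = simulate_timeseries(
        config, truth.latent_severity, seed=int(s_ts.generate_state(1)[0] % 2**31)
    )
    truth.edge_effect_sizes = ts_truth.edge_effect_sizes
    return measures, covariates, series, truth


# ---------------------------------------------------------------------------
# receptor atlases and regional maps


def simulate_receptor_atlas(
    n_regions: int,
    map_names: Sequence[str] = RECEPTOR_MAP_NAMES,
    planted: Mapping[str, float] | None = None,
    seed: int | None = None,
    n_white: int = 0,
    n_csf: int = 0,
    sample_exact: bool = False,
):
    """Build a synthetic region-keyed receptor atlas plus target effect map.

    A target regional map (standard normal across gray-matter regions) plays
    the role of the severity T map. Each named receptor/transporter system
    gets a map constructed as ``r * target + sqrt(1 - r^2) * noise`` with
    ``r`` taken from ``planted`` (0 when absent), then linearly rescaled to
    [0, 100]. With ``sample_exact=True`` the noise is orthogonalized to the
    target in-sample, so the realized gray-matter spatial correlation equals
    the planted value exactly rather than in expectation.

    ``n_white`` / ``n_csf`` extra regions are appended with independent
    values and tissue-class labels ``white`` / ``csf``; the molecular stage
    excludes them.

    Returns ``(atlas, tmap, truth)`` where ``atlas`` is a
    :class:`~netfingerprint.molecular.ReceptorAtlas`, ``tmap`` a
    :class:`~netfingerprint.molecular.RegionalTMap` over gray regions, and
    ``truth`` records the planted correlations.
    """
    from .molecular import ReceptorAtlas, RegionalTMap, rescale_map

    if n_regions < 10:
        raise ParameterError("n_regions must be at least 10")
    names = list(map_names)
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ParameterError(f"duplicate map names: {dupes}")
    planted = dict(planted or {})
    unknown = sorted(set(planted) - set(names))
    if unknown:
        raise ParameterError(f"planted associations for unknown maps: {unknown}")
    for name, r in planted.items():
        if not -1.0 < float(r) < 1.0:
            raise ParameterError(f"planted r for {name} must satisfy |r| < 1, got {r}")

    rng = np.random.default_rng(seed)
    gray = [f"GM_{i + 1:03d}" for i in range(n_regions)]
    white = [f"WM_{i + 1:03d}" for i in range(n_white)]
    csf = [f"CSF_{i + 1:03d}" for i in range(n_csf)]
    regions = gray + white + csf
    tissue = pd.Series(
        ["gray"] * n_regions + ["white"] * n_white + ["csf"] * n_csf,
        index=regions,
        name="tissue_class",
    )

    t_gray = rng.standard_normal(n_regions)
    t_std = (t_gray - t_gray.mean()) / t_gray.std(ddof=0)

    cols = {}
    for name in names:
        r = float(planted.get(name, 0.0))
        eps = rng.standard_normal(n_regions)
        if sample_exact:
            # project out the target, then standardize: realized sample
            # correlation with the target is exactly r
            eps = eps - (eps @ t_std) / (t_std @ t_std) * t_std
            eps = eps - eps.mean()
            eps = eps / eps.std(ddof=0)
        vals = r * t_std + np.sqrt(1.0 - r**2) * eps
        full = np.concatenate([vals, rng.standard_normal(n_white + n_csf)])
        cols[name] = rescale_map(pd.Series(full, index=regions))

    maps = pd.DataFrame(cols, index=pd.Index(regions, name="region"))
    atlas = ReceptorAtlas(
        maps=maps,
        tissue_class=tissue,
        provenance={n: "synthetic stand-in map" for n in names},
    )
    tmap = RegionalTMap(
        values=pd.Series(t_gray, index=pd.Index(gray, name="region"), name="T"),
        contrast="synthetic-target",
        df=None,
    )
    truth = GroundTruth(planted_receptor_r={n: float(planted.get(n, 0.0)) for n in names})
    return atlas, tmap, truth


def simulate_regional_contrasts(
    region_pattern: pd.Series,
    severity: np.ndarray,
    covariates: pd.DataFrame,
    effect_scale: float = 0.3,
    noise_sd: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-subject regional task-contrast values with a planted severity slope.

    Region j of subject i is ``effect_scale * pattern_j * severity_i`` plus
    small age/sex nuisance terms and Gaussian noise, so a regional GLM of
    contrast on severity (adjusting for age and sex) recovers a T map
    spatially proportional to ``region_pattern``.
    """
    rng = np.random.default_rng(seed)
    sev = np.asarray(severity, dtype=float)
    pattern = np.asarray(region_pattern, dtype=float)
    n, p = sev.size, pattern.size
    age = np.asarray(covariates["age"], dtype=float)
    sex = np.asarray(covariates["sex"], dtype=float)
    age_z = (age - age.mean()) / age.std(ddof=0)
    nuisance = 0.1 * age_z[:, None] + 0.1 * (sex - sex.mean())[:, None]
    data = (
        effect_scale * np.outer(sev, pattern)
        + nuisance * np.ones((1, p))
        + rng.normal(0.0, noise_sd, size=(n, p))
    )
    return pd.DataFrame(data, index=covariates.index, columns=region_pattern.index)


# ---------------------------------------------------------------------------
# atlas annotation fixture

MACRO_REGIONS = (
    "prefrontal", "motor", "insula", "parietal", "temporal",
    "occipital", "limbic", "cerebellar", "subcortical", "brainstem",
)

CANONICAL_NETWORKS = ("MF", "FP", "DMN", "Mot", "VI", "VII", "Vas", "SAL", "SC", "CBL")


def synthetic_atlas_annotation(n_nodes: int = 268, seed: int = 0) -> pd.DataFrame:
    """A synthetic node annotation table in the style of a 268-node atlas.

    Assigns every node a macro-region, one of the ten canonical networks,
    a hemisphere, and rough coordinates. The assignment is arbitrary but
    deterministic; it is a stand-in for a real atlas annotation, which the
    loader in :mod:`netfingerprint.anatomy` accepts in the same format.
    """
    rng = np.random.default_rng(seed)
    macro = rng.choice(MACRO_REGIONS, size=n_nodes)
    network = rng.choice(CANONICAL_NETWORKS, size=n_nodes)
    # guarantee all ten networks appear when there is room
    if n_nodes >= len(CANONICAL_NETWORKS):
        network[: len(CANONICAL_NETWORKS)] = CANONICAL_NETWORKS
    hemi = np.where(np.arange(n_nodes) % 2 == 0, "L", "R")
    coords = rng.integers(-70, 71, size=(n_nodes, 3))
    return pd.DataFrame(
        {
            "node": np.arange(n_nodes),
            "macro_region": macro,
            "network": network,
            "hemisphere": hemi,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
        }
    ).set_index("node")


# ---------------------------------------------------------------------------
# cohort writer


def write_cohort(
    out_dir: str | Path,
    config: SimulationConfig,
    seed: int | None = None,
    include_receptors: bool = True,
    planted_receptor_r: Mapping[str, float] | None = None,
) -> Path:
    """Generate a cohort and write it as plain-text files.

    Layout: ``behavior.tsv`` (measures + age + sex), ``timeseries/
    <subject>_<condition>.tsv`` (frames x nodes), ``atlas.tsv``,
    ``receptors.tsv`` + ``tmap.tsv`` (optional), ``ground_truth.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    measures, covariates, series, truth = simulate_cohort(config, seed=seed)

    behavior = measures.join(covariates)
    behavior.to_csv(out / "behavior.tsv", sep="\t")

    ts_dir = out / "timeseries"
    ts_dir.mkdir(exist_ok=True)
    for condition, data in series.items():
        for i, subject in enumerate(measures.index):
            np.savetxt(ts_dir / f"{subject}_{condition}.tsv", data[i], delimiter="\t")

    synthetic_atlas_annotation(config.n_nodes, seed=config.seed).to_csv(
        out / "atlas.tsv", sep="\t"
    )

    truth_doc = truth.to_jsonable()
    if include_receptors:
        atlas, tmap, rec_truth = simulate_receptor_atlas(
            n_regions=119,
            planted=planted_receptor_r,
            seed=config.seed if seed is None else seed,
            n_white=4,
            n_csf=2,
        )
        atlas.to_tsv(out / "receptors.tsv")
        tmap.to_tsv(out / "tmap.tsv")
        truth_doc["planted_receptor_r"] = rec_truth.to_jsonable()["planted_receptor_r"]

    truth_doc["config"] = config.to_dict()
    (out / "ground_truth.json").write_text(json.dumps(truth_doc, indent=2))
    return out
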