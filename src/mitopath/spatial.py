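"""Spatial autocorrelation of per-residue pathogenicity scores.

Global autocorrelation is Moran's I,

    I = (N / sum_ij w_ij) * sum_ij w_ij (y_i - ybar)(y_j - ybar) / sum_i (y_i - ybar)^2,

with w_ij measuring residue proximity: either a quadratic distance decay
(w_ij = d_ij^-2, prioritizing short-range structure) or a binary cutoff
matrix (1 - eps within radius r, eps outside, eps = 1e-6 keeping rows
normalizable). The weight matrix is row-normalized and then renormalized so
all entries sum to 1, after which I reduces to Z'WZ with Z the standardized
(population SD) scores. Significance comes from score permutations; the null
expectation is E[I] = -1/(N-1).

LISA decomposes I into per-site contributions l = Z o (WZ) with sum(l) = I;
each site's permutation p-value is corrected across sites by
Benjamini-Hochberg, and significant high-scoring runs are reported as
high-risk regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from mitopath.datamodel import ResidueSite
from mitopath.ensemble import BaggedEnsemble

_PERM_BATCH = 512


@dataclass
class ResidueField:
    """Per-residue CA coordinates and aggregated scores."""

    sites: list[ResidueSite]

    def __post_init__(self) -> None:
        keys = [s.site_key for s in self.sites]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (complex, chain, residue) sites")

    @property
    def coords(self) -> np.ndarray:
        return np.array([s.ca_coord for s in self.sites], dtype=float)

    @property
    def scores(self) -> np.ndarray:
        return np.array(
            [np.nan if s.mean_score is None else s.mean_score for s in self.sites]
        )

    def __len__(self) -> int:
        return len(self.sites)

    def by_complex(self) -> dict[str, "ResidueField"]:
        out: dict[str, list[ResidueSite]] = {}
        for s in self.sites:
            out.setdefault(s.complex_id, []).append(s)
        return {cid: ResidueField(sites) for cid, sites in out.items()}


def residue_mean_scores(
    variant_scores: Mapping[str, float],
    residue_map: Mapping[str, ResidueSite],
) -> ResidueField:
    """Average variant scores by residue: one value per spatial point.

    Variants without a mapped residue are ignored (their count is implicit in
    the inputs); residues with no scored variant are excluded.
    """
    per_site: dict[tuple, list[float]] = {}
    site_by_key: dict[tuple, ResidueSite] = {}
    for vid, score in variant_scores.items():
        site = residue_map.get(vid)
        if site is None:
            continue
        per_site.setdefault(site.site_key, []).append(float(score))
        site_by_key[site.site_key] = site
    sites = []
    for key, scores in per_site.items():
        s = site_by_key[key]
        sites.append(
            ResidueSite(s.complex_id, s.chain, s.residue_index, s.ca_coord,
                        mean_score=float(np.mean(scores)))
        )
    sites.sort(key=lambda s: s.site_key)
    return ResidueField(sites)


def drop_spatial_learners(ensemble: BaggedEnsemble) -> BaggedEnsemble:
    """Remove base learners trained on any spatial (X/Y/Z) feature.

    Used before spatial autocorrelation so positional features cannot induce
    trivial autocorrelation. Spatial features are those carried in the
    training table's spatial flags; here they are identified by the
    ensemble's feature roster intersected with the conventional coordinate
    names unless flags were recorded at fit time.
    """
    spatial = set(ensemble.spatial_flags) or {"X", "Y", "Z"}
    survivors = [
        lr for lr in ensemble.learners if not (set(lr.feature_subset) & spatial)
    ]
    if not survivors:
        raise ValueError("every base learner uses a spatial feature; nothing survives")
    return BaggedEnsemble(
        learners=survivors,
        training_ids=ensemble.training_ids,
        feature_names=ensemble.feature_names,
        hyperparams=ensemble.hyperparams,
        rng_seed=ensemble.rng_seed,
        spatial_flags=ensemble.spatial_flags,
    )


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------

@dataclass
class SpatialWeights:
    kind: str                      # "quadratic_decay" | "binary_cutoff"
    matrix: np.ndarray             # normalized: zero diagonal, sums to 1
    cutoff: float | None = None
    eps: float = 1e-6


def build_weights(
    sites: ResidueField | np.ndarray,
    kind: str = "quadratic_decay",
    r: float | None = None,
    eps: float = 1e-6,
) -> SpatialWeights:
    """Proximity weight matrix over residue sites.

    quadratic_decay: w_ij = d_ij^-2. binary_cutoff: w_ij = 1-eps within
    radius ``r`` and eps outside. Rows are normalized to sum 1, then the
    whole matrix is renormalized so its total is 1. Coincident sites (zero
    distance) are fatal.
    """
    coords = sites.coords if isinstance(sites, ResidueField) else np.asarray(sites, float)
    n = len(coords)
    if n < 2:
        raise ValueError("need at least two sites")
    d = squareform(pdist(coords))
    off = ~np.eye(n, dtype=bool)
    if (d[off] == 0).any():
        i, j = np.argwhere((d == 0) & off)[0]
        raise ValueError(f"coincident sites {i} and {j}: zero distance")
    if kind == "quadratic_decay":
        with np.errstate(divide="ignore"):
            w = np.where(off, d, np.inf) ** -2.0
    elif kind == "binary_cutoff":
        if r is None or r <= 0:
            raise ValueError("binary_cutoff requires a positive radius r")
        w = np.where(d <= r, 1.0 - eps, eps)
        np.fill_diagonal(w, 0.0)
    else:
        raise ValueError(f"unknown weight kind {kind!r}")
    w = w / w.sum(axis=1, keepdims=True)  # row-normalize
    w = w / w.sum()                       # renormalize: total weight 1
    return SpatialWeights(kind=kind, matrix=w, cutoff=r, eps=eps)


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

@dataclass
class MoranResult:
    I: float
    expected: float
    p_value: float
    n_sites: int
    n_permutations: int
    seed: int


def _standardize(y: np.ndarray) -> np.ndarray:
    sd = y.std()  # population SD
    if sd == 0:
        raise ValueError("score variance is zero; Moran's I undefined")
    return (y - y.mean()) / sd


def _permuted_I(z: np.ndarray, w: np.ndarray, n_perm: int, rng) -> np.ndarray:
    out = np.empty(n_perm)
    n = len(z)
    for start in range(0, n_perm, _PERM_BATCH):
        batch = min(_PERM_BATCH, n_perm - start)
        zp = np.empty((batch, n))
        for b in range(batch):
            zp[b] = z[rng.permutation(n)]
        out[start:start + batch] = np.einsum("bi,ij,bj->b", zp, w, zp, optimize=True)
    return out


def morans_I(
    field: ResidueField | np.ndarray,
    weights: SpatialWeights,
    n_perm: int = 10_000,
    seed: int = 0,
) -> MoranResult:
    """Global Moran's I with a one-sided (greater) permutation p-value.

    The p-value uses the add-one estimator (1 + #{I_perm >= I_obs}) /
    (1 + n_perm), never exactly zero.
    """
    y = field.scores if isinstance(field, ResidueField) else np.asarray(field, float)
    z = _standardize(y)
    w = weights.matrix
    i_obs = float(z @ w @ z)
    n = len(z)
    rng = np.random.default_rng(seed)
    if n_perm > 0:
        perms = _permuted_I(z, w, n_perm, rng)
        p = float((1 + (perms >= i_obs).sum()) / (1 + n_perm))
    else:
        p = float("nan")
    return MoranResult(
        I=i_obs, expected=-1.0 / (n - 1), p_value=p,
        n_sites=n, n_permutations=n_perm, seed=seed,
    )


def cutoff_scan(
    field: ResidueField | np.ndarray,
    radii: Sequence[float],
    n_perm: int = 1000,
    seed: int = 0,
    coords: np.ndarray | None = None,
) -> tuple[dict[float, MoranResult], float]:
    """Binary-cutoff Moran's I over a ladder of radii; reports the argmax radius."""
    radii = list(radii)
    if any(r <= 0 for r in radii) or sorted(radii) != radii:
        raise ValueError("radii must be positive and sorted ascending")
    if isinstance(field, ResidueField):
        pts = field.coords
    else:
        if coords is None:
            raise ValueError("coords required when field is a raw score array")
        pts = coords
    results = {}
    for r in radii:
        w = build_weights(pts if not isinstance(field, ResidueField) else field,
                          "binary_cutoff", r=r)
        results[r] = morans_I(field, w, n_perm=n_perm, seed=seed)
    best = max(results, key=lambda r: results[r].I)
    return results, best


# ---------------------------------------------------------------------------
# LISA
# ---------------------------------------------------------------------------

@dataclass
class LISAResult:
    local_i: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    alpha: float
    n_permutations: int
    seed: int

    @property
    def significant(self) -> np.ndarray:
        return self.q_values < self.alpha


def lisa(
    field: ResidueField | np.ndarray,
    weights: SpatialWeights,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.01,
) -> LISAResult:
    """Local indicators of spatial association with BH-corrected p-values.

    l_i = z_i * (Wz)_i; the vector sums to the global I. Each site's
    one-sided p-value compares its observed l_i with its own distribution
    under total score permutation; Benjamini-Hochberg controls the FDR
    across sites (by convention within one protein complex: pass per-complex
    fields for complex-wise correction).
    """
    y = field.scores if isinstance(field, ResidueField) else np.asarray(field, float)
    z = _standardize(y)
    w = weights.matrix
    l_obs = z * (w @ z)
    n = len(z)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(n, dtype=int)
    for start in range(0, n_perm, _PERM_BATCH):
        batch = min(_PERM_BATCH, n_perm - start)
        zp = np.empty((batch, n))
        for b in range(batch):
            zp[b] = z[rng.permutation(n)]
        l_perm = zp * (zp @ w.T)
        exceed += (l_perm >= l_obs[np.newaxis, :]).sum(axis=0)
    p = (1 + exceed) / (1 + n_perm)
    q = multipletests(p, method="fdr_bh")[1]
    q = np.maximum(q, p)  # BH never reports below the raw p-value
    return LISAResult(
        local_i=l_obs, p_values=p, q_values=q, alpha=alpha,
        n_permutations=n_perm, seed=seed,
    )


# ---------------------------------------------------------------------------
# region calling
# ---------------------------------------------------------------------------

def call_regions(
    field: ResidueField,
    threshold: float,
    significant: np.ndarray | None = None,
) -> pd.DataFrame:
    """Label residues high/low risk and emit contiguous runs per chain.

    A residue is high_risk iff its mean score >= threshold. When a LISA
    significance mask is given, each run also reports how many of its
    residues are significant. Returns columns: complex, chain, start, end,
    label, n_residues, n_significant.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    sig = (
        np.zeros(len(field), dtype=bool) if significant is None
        else np.asarray(significant, dtype=bool)
    )
    rows = []
    sites = sorted(range(len(field)), key=lambda i: field.sites[i].site_key)
    run = None
    for i in sites:
        s = field.sites[i]
        label = "high_risk" if s.mean_score >= threshold else "low_risk"
        if (
            run is not None
            and run["complex"] == s.complex_id
            and run["chain"] == s.chain
            and run["label"] == label
            and s.residue_index == run["end"] + 1
        ):
            run["end"] = s.residue_index
            run["n_residues"] += 1
            run["n_significant"] += int(sig[i])
        else:
            if run is not None:
                rows.append(run)
            run = {
                "complex": s.complex_id, "chain": s.chain,
                "start": s.residue_index, "end": s.residue_index,
                "label": label, "n_residues": 1, "n_significant": int(sig[i]),
            }
    if run is not None:
        rows.append(run)
    return pd.DataFrame(rows)
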