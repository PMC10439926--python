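"""Seeded generators for synthetic feature tables and toy protein structures.

The feature-table generator emulates the shape of the curated mtDNA
missense training corpus: ~1874 variants with ~7.5% pathogenic, 22 named
features mixing class-informative signals, pure noise and three spatial
coordinates, and sparse per-feature MCAR missingness (0.2-1%). The toy
structure generator produces ideal alpha-helical (or linear) CA traces
carrying a spatially smooth score field with known ground truth, so the
autocorrelation statistics can be validated without downloading real
structures. All generators are pure functions of their spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mitopath.datamodel import FeatureGroup, FeatureTable, LabeledDataset, ResidueSite
from mitopath.spatial import ResidueField

SPATIAL_NAMES = ("X", "Y", "Z")


@dataclass(frozen=True)
class SynthTableSpec:
    """Recipe for a synthetic labeled feature table.

    Defaults mirror the real training corpus: 1874 variants, 140 of them
    pathogenic, 22 features of which 5 are informative (class-conditional
    Gaussians separated by ``effect_size`` population SDs, sharing a latent
    factor with loading ``latent_rho``), 14 are class-independent noise, and
    3 are spatial coordinates taken from a toy helix. Per-feature MCAR
    missing rates are drawn uniformly from ``missing_rate_range``.
    """

    n_variants: int = 1874
    positive_fraction: float = 140 / 1874
    n_informative: int = 5
    n_noise: int = 14
    n_spatial: int = 3
    effect_size: float = 1.5
    latent_rho: float = 0.3
    missing_rate_range: tuple[float, float] = (0.002, 0.01)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must lie in (0, 1)")
        if self.n_spatial not in (0, 3):
            raise ValueError("n_spatial must be 0 or 3 (X, Y, Z)")

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_noise + self.n_spatial


@dataclass(frozen=True)
class ToyStructureSpec:
    """Recipe for a toy structure with a smooth per-residue score field.

    geometry 'helix' uses ideal alpha-helix parameters (rise 1.5 A per
    residue, 100 degrees per turn step, radius 2.3 A); 'line' spaces CAs
    3.8 A apart on a straight line. score_field 'ramp' is a logistic ramp
    along the sequence with smoothness length ``smoothness``; 'patch' is a
    Gaussian bump of that width centered mid-chain. Gaussian noise with SD
    ``noise_sd`` is added and the result clipped to [0, 1].
    """

    n_residues: int = 100
    geometry: str = "helix"         # "helix" | "line"
    score_field: str = "ramp"       # "ramp" | "patch"
    smoothness: float = 10.0        # residues
    noise_sd: float = 0.02
    complex_id: str = "toy"
    chain: str = "A"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 10:
            raise ValueError("need at least 10 residues")
        if self.smoothness <= 0:
            raise ValueError("smoothness length must be positive")


def gen_toy_structure(spec: ToyStructureSpec) -> tuple[ResidueField, np.ndarray]:
    """Generate a toy CA trace with a smooth score field.

    Returns the residue field and the ground-truth high-risk mask (noise-free
    smooth field >= 0.5).
    """
    rng = np.random.default_rng(spec.seed)
    i = np.arange(spec.n_residues)
    if spec.geometry == "helix":
        theta = np.deg2rad(100.0) * i
        coords = np.column_stack(
            [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i]
        )
    elif spec.geometry == "line":
        coords = np.column_stack([3.8 * i, np.zeros_like(i), np.zeros_like(i)])
    else:
        raise ValueError(f"unknown geometry {spec.geometry!r}")

    mid = spec.n_residues / 2.0
    if spec.score_field == "ramp":
        smooth = 1.0 / (1.0 + np.exp(-(i - mid) / spec.smoothness))
    elif spec.score_field == "patch":
        smooth = 0.15 + 0.7 * np.exp(-((i - mid) ** 2) / (2.0 * spec.smoothness**2))
    else:
        raise ValueError(f"unknown score_field {spec.score_field!r}")
    scores = np.clip(smooth + rng.normal(0.0, spec.noise_sd, spec.n_residues), 0.0, 1.0)

    sites = [
        ResidueSite(spec.complex_id, spec.chain, int(idx) + 1,
                    tuple(coords[idx]), mean_score=float(scores[idx]))
        for idx in i
    ]
    return ResidueField(sites), smooth >= 0.5


def gen_feature_table(spec: SynthTableSpec) -> LabeledDataset:
    """Generate a labeled synthetic feature table per the spec.

    The positive count is the exact rounded allocation (140 at the default
    shape); labels are shuffled over rows. Informative feature f for variant
    i is effect_size*y_i + sqrt(latent_rho)*g_i + sqrt(1-latent_rho)*e_if
    with a shared latent factor g inducing inter-feature correlation. Noise
    features are standard normal regardless of class. Spatial coordinates
    are CA positions of a toy helix, class-independent.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_variants
    n_pos = int(round(spec.positive_fraction * n))
    y = np.zeros(n, dtype=int)
    y[rng.choice(n, n_pos, replace=False)] = 1

    cols: dict[str, np.ndarray] = {}
    groups: dict[str, FeatureGroup] = {}
    latent = rng.normal(size=n)
    lam = math.sqrt(spec.latent_rho)
    res = math.sqrt(max(0.0, 1.0 - spec.latent_rho))
    for f in range(spec.n_informative):
        name = f"cons_{f}" if f < 2 else f"pred_{f - 2}"
        cols[name] = spec.effect_size * y + lam * latent + res * rng.normal(size=n)
        groups[name] = FeatureGroup.evolutionary if f < 2 else FeatureGroup.predictor
    for f in range(spec.n_noise):
        name = f"noise_{f}"
        cols[name] = rng.normal(size=n)
        groups[name] = FeatureGroup.predictor
    if spec.n_spatial:
        helix, _ = gen_toy_structure(
            ToyStructureSpec(n_residues=max(10, n // 4), seed=spec.seed + 1)
        )
        coords = helix.coords
        pick = rng.integers(0, len(coords), n)
        for axis, name in enumerate(SPATIAL_NAMES):
            cols[name] = coords[pick, axis]
            groups[name] = FeatureGroup.structural

    ids = [f"v{i:05d}" for i in range(n)]
    df = pd.DataFrame(cols, index=ids)

    lo, hi = spec.missing_rate_range
    rates = rng.uniform(lo, hi, df.shape[1])
    mask = rng.random(df.shape) < rates[np.newaxis, :]
    df = df.mask(pd.DataFrame(mask, index=df.index, columns=df.columns))

    table = FeatureTable(df, groups, SPATIAL_NAMES if spec.n_spatial else ())
    return LabeledDataset(table, pd.Series(y, index=ids))
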