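"""Bayesian calibration of raw ensemble scores.

Class-conditional score densities P(y|C=1) and P(y|C=0) are approximated by
Beta distributions fitted by maximum likelihood: the pathogenic density to
out-of-bag scores of known pathogenic training variants, the benign density
to scores of an independent benign reference set (out-of-bag scores replacing
any overlap with the training set). With a prior P(C=1) = 0.1 the posterior

    P(C=1|y) = f1(y) pi / (f1(y) pi + f0(y) (1 - pi))

maps a raw score y to a pathogenicity probability, which is binned into five
clinical classes: benign (P <= 0.001), likely benign (0.001 < P <= 0.1), VUS
(0.1 < P < 0.9), likely pathogenic (0.9 <= P < 0.99), pathogenic (P >= 0.99).
Because the posterior is (checked to be) monotone in the score, each
posterior cutpoint inverts to a score threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import betaln

DEFAULT_PRIOR = 0.1
CLASS_CUTPOINTS = (0.001, 0.1, 0.9, 0.99)
CLASS_NAMES = ("benign", "likely_benign", "VUS", "likely_pathogenic", "pathogenic")
DEFAULT_CLIP = 1e-6


@dataclass
class BetaFit:
    """A maximum-likelihood Beta density fitted to scores in (0, 1)."""

    alpha: float
    beta: float
    nll: float
    n: int
    clip: float = DEFAULT_CLIP

    def pdf(self, y: np.ndarray | float) -> np.ndarray | float:
        y = np.clip(y, self.clip, 1.0 - self.clip)
        return stats.beta.pdf(y, self.alpha, self.beta)


def fit_beta(scores: Sequence[float], clip: float = DEFAULT_CLIP) -> BetaFit:
    """Fit Beta(alpha, beta) by minimizing the negative log-likelihood.

    Scores are clipped into [clip, 1-clip] first (Beta densities diverge at
    the boundary). Initialization is method-of-moments; the optimizer runs to
    tolerance 1e-8 in the log-parameters. Needs at least 10 scores and
    positive variance.
    """
    x = np.clip(np.asarray(scores, dtype=float), clip, 1.0 - clip)
    if len(x) < 10:
        raise ValueError(f"need >= 10 scores to fit a Beta density, got {len(x)}")
    if np.ptp(x) == 0.0:
        raise ValueError(
            "all scores identical after clipping; a Beta density is degenerate "
            "here — check that the score source actually varies"
        )
    m, v = float(x.mean()), float(x.var())
    # method of moments: alpha+beta = m(1-m)/v - 1
    common = max(m * (1.0 - m) / v - 1.0, 1e-3)
    a0, b0 = max(m * common, 1e-3), max((1.0 - m) * common, 1e-3)

    log_x, log_1mx = np.log(x).sum(), np.log1p(-x).sum()
    n = len(x)

    def nll(theta):
        a, b = np.exp(theta)
        return -((a - 1.0) * log_x + (b - 1.0) * log_1mx - n * betaln(a, b))

    res = optimize.minimize(
        nll, x0=np.log([a0, b0]), method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000},
    )
    a, b = np.exp(res.x)
    return BetaFit(alpha=float(a), beta=float(b), nll=float(res.fun), n=n, clip=clip)


@dataclass
class CalibrationModel:
    """Two fitted Beta densities plus a pathogenicity prior."""

    beta_pathogenic: BetaFit
    beta_benign: BetaFit
    prior: float = DEFAULT_PRIOR
    cutpoints: tuple[float, ...] = CLASS_CUTPOINTS
    clip: float = DEFAULT_CLIP

    def __post_init__(self) -> None:
        if not 0.0 <= self.prior <= 1.0:
            raise ValueError("prior must lie in [0, 1]")
        if list(self.cutpoints) != sorted(self.cutpoints):
            raise ValueError("class cutpoints must be strictly increasing")

    def to_json(self, path: str | Path, thresholds: dict | None = None) -> None:
        payload = {
            "format_version": 1,
            "alpha_pathogenic": self.beta_pathogenic.alpha,
            "beta_pathogenic": self.beta_pathogenic.beta,
            "alpha_benign": self.beta_benign.alpha,
            "beta_benign": self.beta_benign.beta,
            "prior": self.prior,
            "cutpoints": list(self.cutpoints),
            "clip": self.clip,
        }
        if thresholds is not None:
            payload["score_thresholds"] = thresholds
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        d = json.loads(Path(path).read_text())
        return cls(
            BetaFit(d["alpha_pathogenic"], d["beta_pathogenic"], float("nan"), 0, d["clip"]),
            BetaFit(d["alpha_benign"], d["beta_benign"], float("nan"), 0, d["clip"]),
            prior=d["prior"],
            cutpoints=tuple(d["cutpoints"]),
            clip=d["clip"],
        )


def fit_calibration(
    pathogenic_oob_scores: Sequence[float],
    benign_reference_scores: Sequence[float],
    prior: float = DEFAULT_PRIOR,
    clip: float = DEFAULT_CLIP,
) -> CalibrationModel:
    """Fit both class-conditional Beta densities and assemble the model."""
    return CalibrationModel(
        beta_pathogenic=fit_beta(pathogenic_oob_scores, clip),
        beta_benign=fit_beta(benign_reference_scores, clip),
        prior=prior,
        clip=clip,
    )


def posterior(model: CalibrationModel, y: np.ndarray | float) -> np.ndarray | float:
    """Posterior pathogenicity probability P(C=1 | score)."""
    f1 = model.beta_pathogenic.pdf(y)
    f0 = model.beta_benign.pdf(y)
    pi = model.prior
    num = f1 * pi
    den = num + f0 * (1.0 - pi)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), pi)
    return float(out) if np.isscalar(y) else out


def classify(p: float, cutpoints: tuple[float, ...] = CLASS_CUTPOINTS) -> str:
    """Five-class clinical label from a posterior probability."""
    c1, c2, c3, c4 = cutpoints
    if p <= c1:
        return "benign"
    if p <= c2:
        return "likely_benign"
    if p < c3:
        return "VUS"
    if p < c4:
        return "likely_pathogenic"
    return "pathogenic"


def score_thresholds(
    model: CalibrationModel,
    grid_size: int = 10_000,
    tol: float = 1e-6,
) -> dict[float, float | None]:
    """Invert the posterior: score threshold per posterior cutpoint.

    The posterior is evaluated on a dense score grid and checked for
    monotonicity (two arbitrary Beta fits need not give a monotone likelihood
    ratio; a non-monotone posterior is fatal rather than silently inverted).
    Each cutpoint's threshold is the smallest score whose posterior reaches
    it, refined by bisection to ``tol``. A cutpoint the posterior never
    attains maps to None.
    """
    grid = np.linspace(model.clip, 1.0 - model.clip, grid_size)
    post = posterior(model, grid)
    diffs = np.diff(post)
    if (diffs < -1e-9).any():
        worst = int(np.argmin(diffs))
        raise ValueError(
            "posterior is not monotone non-decreasing in the score "
            f"(drops by {-diffs[worst]:.3g} near score {grid[worst]:.4f}); "
            "the fitted Beta densities do not support threshold inversion"
        )
    out: dict[float, float | None] = {}
    for cut in model.cutpoints:
        above = post >= cut
        if not above.any():
            out[cut] = None
            continue
        hi_i = int(above.argmax())
        if hi_i == 0:
            out[cut] = float(grid[0])
            continue
        lo, hi = float(grid[hi_i - 1]), float(grid[hi_i])
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if posterior(model, mid) >= cut:
                hi = mid
            else:
                lo = mid
        out[cut] = hi
    return out
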