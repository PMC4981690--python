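"""The β screening statistic for inter-class score separation.

Profile HMM scores alone do not disambiguate closely related subclasses:
a secreted class-B endoglucanase and a class-C enzyme (class B plus a
C-terminal CBM49) score similarly against all class profiles.  The β
statistic quantifies how well-spaced the three class score groups are.

Each class contributes a two-member group: its 1D-side mean and its
3D-side mean (τ = 2 in every mode).  For a pair of groups i, j the
modified Z-score term is

    α_ij = τ² (μ_i − μ_j)² / (100 (σ_i² + σ_j²))

with μ the intra-group mean and σ² the intra-group population variance,
and

    β = α₁₂ + α₂₃ + α₁₃

(the halved symmetric 3×3 double sum; group 1↔A, 2↔B, 3↔C).  Large β means
the class evidence is well separated, and pairwise mean differences ΔHMM
with their median gauge the absolute spacing in bits.  Sequences are
partitioned at β thresholds 2.777 / 1.00, with high-confidence use also
requiring median ΔHMM ≥ 200 bits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .profiles import CLASSES, ClassMeanTriple

#: maps group indices 1, 2, 3 to subclasses
GROUP_INDEX = {1: "A", 2: "B", 3: "C"}
PAIRS = ((1, 2), (2, 3), (1, 3))


@dataclass(frozen=True)
class GroupStats:
    """Mean/variance summary of one two-member score group."""

    mu: float
    sigma2: float
    tau: int
    members: tuple

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("variance cannot be negative")


@dataclass(frozen=True)
class AlphaTriple:
    """The three pairwise α terms with diagnostic inter-group z-scores."""

    a12: float
    a23: float
    a13: float
    z12: float = 0.0
    z23: float = 0.0
    z13: float = 0.0
    saturated: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.a12, self.a23, self.a13], dtype=float)


@dataclass(frozen=True)
class ScreenConfig:
    """Partition thresholds on β and the spacing floor on median ΔHMM."""

    beta_hi: float = 2.777
    beta_lo: float = 1.00
    delta_min: float = 200.0

    def __post_init__(self) -> None:
        if not self.beta_lo < self.beta_hi:
            raise ValueError("need beta_lo < beta_hi")
        if self.delta_min < 0:
            raise ValueError("delta_min must be >= 0")


@dataclass
class BetaResult:
    """β, the pairwise ΔHMM spacings, and the screening partition."""

    beta: float
    alphas: AlphaTriple
    deltas: tuple  # (|A-B|, |B-C|, |A-C|) in bits
    median_delta: float
    partition: Optional[str] = None
    well_spaced: Optional[bool] = None


def group_stats(members: Sequence[float]) -> GroupStats:
    """Population mean/variance of a two-member group (τ = 2)."""
    if len(members) != 2:
        raise ValueError(f"a group has exactly two members, got {len(members)}")
    a, b = (float(x) for x in members)
    if not (math.isfinite(a) and math.isfinite(b)):
        raise ValueError("group members must be finite")
    mu = (a + b) / 2.0
    sigma2 = ((a - mu) ** 2 + (b - mu) ** 2) / 2.0
    return GroupStats(mu, sigma2, 2, (a, b))


def alpha(gi: GroupStats, gj: GroupStats, formula: str = "standard",
          eps: float = 1e-9) -> tuple:
    """One α term between two groups; returns ``(alpha, z, saturated)``.

    The default form is α = τ²(μ_i−μ_j)²/(100(σ_i²+σ_j²)), which is
    symmetric, invariant under affine rescaling of the raw scores, and
    inversely proportional to the mean within-group variance.  When both
    variances vanish while the means differ, the denominator is floored
    at ``eps`` and the saturation flag is set instead of crashing.

    ``formula="alt"`` evaluates the alternative parenthesization
    (|μ_i−μ_j|/100)·(|μ_i−μ_j|/(σ_i²+σ_j²/τ)²) for sensitivity checks;
    it is not affine invariant and is never the default.
    """
    if gi.tau != 2 or gj.tau != 2:
        raise ValueError("alpha is defined for two-member groups (tau = 2)")
    d = abs(gi.mu - gj.mu)
    pooled = gi.sigma2 + gj.sigma2
    saturated = False
    if d > 0 and pooled < eps:
        pooled = eps
        saturated = True
    tau = 2
    if d == 0:
        a = 0.0
    elif formula == "standard":
        a = (d * d * tau * tau) / (100.0 * pooled)
    elif formula == "alt":
        denom = (gi.sigma2 + gj.sigma2 / tau) ** 2
        denom = max(denom, eps)
        a = (d / 100.0) * (d / denom)
    else:
        raise ValueError(f"unknown formula {formula!r}")
    z = 0.0 if d == 0 else (gi.mu - gj.mu) / math.sqrt(max(pooled / tau, eps / tau))
    return a, z, saturated


def alpha_triple(side_means: Mapping[str, Sequence[float]],
                 formula: str = "standard", eps: float = 1e-9) -> AlphaTriple:
    """α₁₂/α₂₃/α₁₃ from the per-class (1D-side, 3D-side) mean pairs."""
    groups = {idx: group_stats(side_means[cls]) for idx, cls in GROUP_INDEX.items()}
    vals = {}
    zs = {}
    saturated = False
    for i, j in PAIRS:
        a, z, sat = alpha(groups[i], groups[j], formula=formula, eps=eps)
        vals[(i, j)] = a
        zs[(i, j)] = z
        saturated = saturated or sat
    return AlphaTriple(vals[(1, 2)], vals[(2, 3)], vals[(1, 3)],
                       zs[(1, 2)], zs[(2, 3)], zs[(1, 3)], saturated)


def beta(at: AlphaTriple) -> float:
    """β: the halved symmetric double sum, i.e. α₁₂ + α₂₃ + α₁₃."""
    return at.a12 + at.a23 + at.a13


def delta_hmm(triple: ClassMeanTriple) -> tuple:
    """Absolute pairwise class-mean differences and their median.

    Returns ``((|A−B|, |B−C|, |A−C|), median)`` where the median of three
    values is the middle order statistic.
    """
    d = triple.as_dict()
    deltas = (abs(d["A"] - d["B"]), abs(d["B"] - d["C"]), abs(d["A"] - d["C"]))
    return deltas, float(sorted(deltas)[1])


def screen(br: BetaResult, cfg: Optional[ScreenConfig] = None) -> BetaResult:
    """Attach the partition label and the spacing flag to a BetaResult.

    ``AA`` (pass): β > beta_hi; ``AB`` (intermediate): beta_lo ≤ β ≤
    beta_hi; ``AC`` (fail): β < beta_lo.  ``well_spaced`` additionally
    requires median ΔHMM ≥ delta_min and is the criterion for
    high-confidence downstream use.
    """
    cfg = cfg or ScreenConfig()
    if br.beta > cfg.beta_hi:
        br.partition = "AA"
    elif br.beta >= cfg.beta_lo:
        br.partition = "AB"
    else:
        br.partition = "AC"
    br.well_spaced = bool(br.partition == "AA" and br.median_delta >= cfg.delta_min)
    return br


def beta_result(triple: ClassMeanTriple, cfg: Optional[ScreenConfig] = None,
                formula: str = "standard") -> BetaResult:
    """Full β computation for one sequence's class-mean triple."""
    at = alpha_triple(triple.side_means, formula=formula)
    deltas, med = delta_hmm(triple)
    br = BetaResult(beta(at), at, deltas, med)
    return screen(br, cfg)


def beta_table(triples: Mapping[str, ClassMeanTriple],
               cfg: Optional[ScreenConfig] = None,
               formula: str = "standard") -> pd.DataFrame:
    """Tabulate β results for many sequences (one row per sequence)."""
    rows = []
    for sid, triple in triples.items():
        br = beta_result(triple, cfg, formula=formula)
        d = triple.as_dict()
        rows.append({
            "seq_id": sid,
            "hmm_a": d["A"], "hmm_b": d["B"], "hmm_c": d["C"],
            "a12": br.alphas.a12, "a23": br.alphas.a23, "a13": br.alphas.a13,
            "beta": br.beta,
            "d_ab": br.deltas[0], "d_bc": br.deltas[1], "d_ac": br.deltas[2],
            "median_delta": br.median_delta,
            "partition": br.partition,
            "well_spaced": br.well_spaced,
        })
    return pd.DataFrame(rows).set_index("seq_id") if rows else pd.DataFrame(
        columns=["hmm_a", "hmm_b", "hmm_c", "a12", "a23", "a13", "beta",
                 "d_ab", "d_bc", "d_ac", "median_delta", "partition",
                 "well_spaced"])
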