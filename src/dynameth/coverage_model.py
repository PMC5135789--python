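"""Poisson (Lander-Waterman) coverage-requirement model for cohort design.

Per-base sequencing depth is modelled as Poisson with rate lambda. For a
cohort of N samples the model finds the smallest lambda such that a CpG is
covered with at least ``k`` reads in a required fraction ``f`` of samples
jointly with probability ``p_success``:

    [P(Poisson(lambda) >= k)]^ceil(f*N) >= p_success

The required lambda converts to a raw per-sample read count by scaling
with the target size, dividing by the read length, and inflating for PCR
duplicates and off-target reads:

    reads = lambda * L / read_len / ((1 - dup_rate) * (1 - offtarget_rate))

The joint (tail-power) reading above is the default; an alternative
binomial-over-samples reading (at least ceil(f*N) of N samples succeed)
is available via ``mode="binomial"`` but yields lower estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import binom, poisson

from .errors import ValidationError

__all__ = [
    "CoverageModelParams",
    "CoverageEstimate",
    "poisson_tail",
    "min_lambda",
    "reads_required",
    "coverage_curve",
    "targeted_params",
    "wgbs_params",
]

BISECT_TOL = 1e-6
BISECT_HI = 1e4


@dataclass
class CoverageModelParams:
    """Inputs of the multi-sample coverage model.

    k: required per-CpG depth; p_success: joint success probability;
    sample_frac: fraction of the N samples that must reach depth k;
    target_bp: captured/effective genome size; read_len in bases;
    dup_rate / offtarget_rate: fractions of reads lost to PCR duplicates
    and off-target mapping.
    """

    n_samples: int
    target_bp: float
    k: int = 30
    p_success: float = 0.95
    sample_frac: float = 0.8
    read_len: int = 100
    dup_rate: float = 0.0
    offtarget_rate: float = 0.0

    def __post_init__(self):
        if self.k < 0:
            raise ValidationError("required depth k must be >= 0")
        if not 0 < self.p_success < 1:
            raise ValidationError("p_success must be in (0, 1)")
        if not 0 < self.sample_frac <= 1:
            raise ValidationError("sample_frac must be in (0, 1]")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if self.target_bp <= 0 or self.read_len <= 0:
            raise ValidationError("target_bp and read_len must be positive")
        if not (0 <= self.dup_rate < 1 and 0 <= self.offtarget_rate < 1):
            raise ValidationError("dup/offtarget rates must be in [0, 1)")

    @property
    def n_required(self) -> int:
        return math.ceil(self.sample_frac * self.n_samples)


@dataclass
class CoverageEstimate:
    lambda_required: float
    reads_required: float


def poisson_tail(k: int, lam: float) -> float:
    """Upper tail P(X >= k) for X ~ Poisson(lam)."""
    if k < 0 or lam < 0:
        raise ValidationError("poisson_tail needs k >= 0 and lam >= 0")
    if k == 0:
        return 1.0
    return float(poisson.sf(k - 1, lam))


def _success_prob(lam: float, params: CoverageModelParams, mode: str) -> float:
    tail = poisson_tail(params.k, lam)
    if mode == "joint":
        return tail ** params.n_required
    if mode == "binomial":
        # P(at least n_required of n_samples reach depth k)
        return float(binom.sf(params.n_required - 1, params.n_samples, tail))
    raise ValidationError(f"unknown coverage model mode {mode!r}")


def min_lambda(params: CoverageModelParams, mode: str = "joint",
               tol: float = BISECT_TOL) -> float:
    """Smallest Poisson rate meeting the cohort coverage requirement.

    Found by bisection to absolute tolerance ``tol``; monotone
    non-decreasing in k, N and p_success.
    """
    if params.k == 0:
        return 0.0
    lo, hi = 0.0, float(params.k + 10)
    while _success_prob(hi, params, mode) < params.p_success:
        hi *= 2
        if hi > BISECT_HI:
            raise ValidationError("coverage requirement unattainable in bracket")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _success_prob(mid, params, mode) >= params.p_success:
            hi = mid
        else:
            lo = mid
    return hi


def reads_required(lambda_required: float, params: CoverageModelParams) -> float:
    """Raw reads per sample for a given per-base depth requirement."""
    eff = (1.0 - params.dup_rate) * (1.0 - params.offtarget_rate)
    return lambda_required * params.target_bp / params.read_len / eff


def estimate(params: CoverageModelParams, mode: str = "joint") -> CoverageEstimate:
    lam = min_lambda(params, mode)
    return CoverageEstimate(lam, reads_required(lam, params))


def targeted_params(n_samples: int, target_bp: float = 9.0e7,
                    dup_rate: float = 0.10, offtarget_rate: float = 0.30,
                    **kw) -> CoverageModelParams:
    """Default parameterization of the targeted (capture) design."""
    return CoverageModelParams(n_samples=n_samples, target_bp=target_bp,
                               dup_rate=dup_rate, offtarget_rate=offtarget_rate,
                               **kw)


def wgbs_params(n_samples: int, target_bp: float = 2.7e9,
                dup_rate: float = 0.20, offtarget_rate: float = 0.0,
                **kw) -> CoverageModelParams:
    """Default parameterization of whole-genome bisulfite sequencing."""
    return CoverageModelParams(n_samples=n_samples, target_bp=target_bp,
                               dup_rate=dup_rate, offtarget_rate=offtarget_rate,
                               **kw)


def coverage_curve(targeted: CoverageModelParams, wgbs: CoverageModelParams,
                   n_range: Iterable[int], mode: str = "joint") -> pd.DataFrame:
    """Per-N lambda and read requirements for the two designs.

    Returns a table with columns N, lambda_targeted, reads_targeted,
    lambda_wgbs, reads_wgbs; reads are monotone non-decreasing in N.
    """
    rows = []
    for n in n_range:
        t = estimate(replace(targeted, n_samples=n), mode)
        w = estimate(replace(wgbs, n_samples=n), mode)
        rows.append({"N": n,
                     "lambda_targeted": t.lambda_required,
                     "reads_targeted": t.reads_required,
                     "lambda_wgbs": w.lambda_required,
                     "reads_wgbs": w.reads_required})
    return pd.DataFrame(rows)
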