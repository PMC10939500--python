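"""Poisson quantification of droplet-digital PCR (ddPCR).

A duplex assay partitions a reaction into ``D`` droplets; two fluorescent
probes (FAM, HEX) each mark one allele of a heterozygous SNP. By Poisson
occupancy the mean template copies per droplet for a channel with ``k``
positive droplets is

    lambda = -ln(1 - k / D),

and the allelic fraction is lambda_FAM / (lambda_FAM + lambda_HEX).
Confidence intervals come from first-order (delta-method) propagation of
the binomial sampling variance of each positive proportion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .exceptions import InvalidParameterError, SaturationError

__all__ = [
    "DropletCounts",
    "AllelicResult",
    "poisson_lambda",
    "lambda_variance",
    "allelic_fraction",
    "expression_change",
]


@dataclass(frozen=True)
class DropletCounts:
    droplets: int
    fam_positive: int
    hex_positive: int

    def __post_init__(self) -> None:
        if self.droplets < 1:
            raise InvalidParameterError("droplets must be >= 1")
        for name in ("fam_positive", "hex_positive"):
            k = getattr(self, name)
            if not 0 <= k <= self.droplets:
                raise InvalidParameterError(
                    f"{name}={k} outside [0, droplets={self.droplets}]"
                )


@dataclass(frozen=True)
class AllelicResult:
    lambda_fam: float
    lambda_hex: float
    fraction_fam: float
    ci_low: float
    ci_high: float

    @property
    def ratio(self) -> float:
        """FAM:HEX concentration ratio."""
        return self.lambda_fam / self.lambda_hex


def poisson_lambda(droplets: int, positives: int) -> float:
    """Mean template copies per droplet from the positive-droplet count."""
    if positives > droplets:
        raise InvalidParameterError(
            f"positives={positives} exceeds droplets={droplets}"
        )
    if positives < 0:
        raise InvalidParameterError("positives must be >= 0")
    if positives == droplets:
        raise SaturationError(
            "all droplets positive: concentration is unbounded; dilute and rerun"
        )
    return -math.log1p(-positives / droplets)


def lambda_variance(droplets: int, positives: int) -> float:
    """Delta-method variance of the lambda estimate.

    Var(p_hat) = p(1-p)/D and d(lambda)/dp = 1/(1-p), so
    Var(lambda_hat) ~= p / (D (1-p)).
    """
    p = positives / droplets
    return p / (droplets * (1.0 - p))


def allelic_fraction(counts: DropletCounts, coverage: float = 0.95) -> AllelicResult:
    """Fraction of template assigned to the FAM allele, with a CI.

    The CI propagates the per-channel binomial variance through the Poisson
    transform and the ratio f = l1/(l1+l2):
    Var(f) ~= (l2^2 Var(l1) + l1^2 Var(l2)) / (l1+l2)^4.
    """
    if counts.fam_positive == 0 and counts.hex_positive == 0:
        raise InvalidParameterError("no positive droplets in either channel")
    l1 = poisson_lambda(counts.droplets, counts.fam_positive)
    l2 = poisson_lambda(counts.droplets, counts.hex_positive)
    total = l1 + l2
    f = l1 / total
    v1 = lambda_variance(counts.droplets, counts.fam_positive)
    v2 = lambda_variance(counts.droplets, counts.hex_positive)
    var_f = (l2 * l2 * v1 + l1 * l1 * v2) / total**4
    z = norm.ppf(0.5 + coverage / 2.0)
    half = z * math.sqrt(var_f)
    return AllelicResult(
        lambda_fam=l1,
        lambda_hex=l2,
        fraction_fam=f,
        ci_low=max(0.0, f - half),
        ci_high=min(1.0, f + half),
    )


def expression_change(edited: AllelicResult, control: AllelicResult) -> float:
    """Percent decrease of the edited (FAM) allele relative to the other,
    calibrated against a genomic-DNA control assayed with the same probes.

    Returns 100 * (1 - (ratio_edited / ratio_control)); positive values
    mean the edited allele is expressed less than the calibration predicts,
    e.g. +50 is a twofold (50%) reduction.
    """
    if edited.lambda_hex <= 0 or control.lambda_hex <= 0 or control.lambda_fam <= 0:
        raise InvalidParameterError("zero concentration in a ratio denominator")
    return 100.0 * (1.0 - edited.ratio / control.ratio)
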