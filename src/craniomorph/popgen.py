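"""Single-SNP population differentiation (fixation index, F_ST).

Both estimators take per-population frequencies of one designated allele.
F_ST is 0 when the subpopulations carry identical allelic content and 1
when alternate alleles are fixed in each.

``hudson_fst`` is the two-population Hudson form without finite-sample
correction — at reference-panel sample sizes (hundreds to thousands of
chromosomes per population) the order-1/n correction terms are negligible.
``wright_fst`` is the classical heterozygosity partition (H_T - H_S)/H_T.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError

__all__ = ["hudson_fst", "wright_fst", "pairwise_fst_matrix", "PopAlleleTable"]


class PopAlleleTable(dict):
    """population label -> frequency of the designated allele in [0, 1]."""

    def __init__(self, freqs: Mapping[str, float]):
        for pop, p in freqs.items():
            _check_freq(p, pop)
        super().__init__(freqs)


def _check_freq(p: float, label: str = "p") -> float:
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise InvalidParameterError(f"allele frequency {label}={p} outside [0, 1]")
    return p


def hudson_fst(p1: float, p2: float) -> float:
    """Hudson's pairwise F_ST: (p1-p2)^2 / (p1(1-p2) + p2(1-p1))."""
    p1, p2 = _check_freq(p1, "p1"), _check_freq(p2, "p2")
    denom = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    if denom == 0.0:
        raise InvalidParameterError(
            "F_ST undefined: both populations fixed for the same allele"
        )
    return (p1 - p2) ** 2 / denom


def wright_fst(p1: float, p2: float, weights: Sequence[float] = (0.5, 0.5)) -> float:
    """Heterozygosity-partition F_ST, (H_T - H_S) / H_T, with population
    weights (e.g. relative sample sizes) summing to 1."""
    p1, p2 = _check_freq(p1, "p1"), _check_freq(p2, "p2")
    w = np.asarray(weights, dtype=float)
    if w.shape != (2,) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise InvalidParameterError("weights must be two non-negatives summing to 1")
    p_bar = w[0] * p1 + w[1] * p2
    h_t = 2.0 * p_bar * (1.0 - p_bar)
    if h_t == 0.0:
        raise InvalidParameterError("F_ST undefined: total heterozygosity is zero")
    h_s = w[0] * 2.0 * p1 * (1.0 - p1) + w[1] * 2.0 * p2 * (1.0 - p2)
    return (h_t - h_s) / h_t


def pairwise_fst_matrix(table: Mapping[str, float], estimator: str = "hudson") -> pd.DataFrame:
    """Symmetric matrix of pairwise F_ST over all populations (diagonal 0)."""
    pops = list(table)
    if len(pops) < 2:
        raise InvalidParameterError("need at least 2 populations")
    fn = {"hudson": hudson_fst, "wright": wright_fst}.get(estimator)
    if fn is None:
        raise InvalidParameterError(f"unknown estimator {estimator!r}")
    out = np.zeros((len(pops), len(pops)))
    for i, a in enumerate(pops):
        for j in range(i + 1, len(pops)):
            val = fn(table[a], table[pops[j]])
            out[i, j] = out[j, i] = val
    return pd.DataFrame(out, index=pops, columns=pops)
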