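"""Discrete entropy functionals used as tissue-age statistics.

Three measures of disorder are provided:

* ``discrete_entropy`` — the statistical (Shannon/Boltzmann) entropy
  ``-sum_i p_i log_b p_i`` of a density or probability vector;
* ``kl_divergence`` — the Kullback–Leibler relative entropy
  ``D(p||q) = sum_x p(x) log_b(p(x)/q(x))`` between a young baseline density
  p(x) and an aged density q(x), the central age statistic of the package;
* ``combinatorial_entropy`` — ``ln W`` with multiplicity
  ``W = N! / prod_i n_i!``, the configurational disorder of occupation
  numbers, which grows as cooperative order between tissue parts decays.

Conventions: ``0 * log 0 = 0`` throughout.  The KL log base defaults to 10 so
that a density ratio of 1e9 — the mammalian lifetime-to-metabolic-time
invariant — contributes 9 to a single-compartment raw term.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence, Union

import numpy as np
from scipy.special import gammaln, xlogy

from .errors import InvalidDistributionError, ParameterError, ShapeError, SupportError
from .profiles import CountVector, DensityProfile, ProfileLike, as_density_values

logger = logging.getLogger(__name__)

__all__ = [
    "discrete_entropy",
    "kl_divergence",
    "combinatorial_entropy",
    "deviation_from_unity",
]

_NORM_TOL = 1e-9


def _check_base(base: float) -> float:
    if not (base > 1):
        raise ParameterError(f"log base must exceed 1, got {base}")
    return math.log(base)


def discrete_entropy(p: ProfileLike, base: float = math.e,
                     normalize: bool = True) -> float:
    """Statistical entropy ``-sum_i p_i log_base p_i``.

    Parameters
    ----------
    p
        Density profile or non-negative sequence.
    base
        Logarithm base (> 1); natural log by default.
    normalize
        If true, rescale ``p`` to unit mass first.  If false, ``p`` must
        already sum to 1 within 1e-9.

    Returns
    -------
    float
        Entropy in ``log_base`` units; lies in ``[0, log_base(n)]`` for a
        normalized length-``n`` input.
    """
    ln_base = _check_base(base)
    values = as_density_values(p)
    total = float(values.sum())
    if total <= 0:
        raise InvalidDistributionError("all-zero input has no entropy")
    if normalize:
        values = values / total
    elif abs(total - 1.0) > _NORM_TOL:
        raise InvalidDistributionError(
            f"input sums to {total!r}, not 1; pass normalize=True to rescale"
        )
    return float(-np.sum(xlogy(values, values)) / ln_base)


def kl_divergence(p: ProfileLike, q: ProfileLike, base: float = 10.0,
                  mode: str = "normalized", floor: float | None = None) -> float:
    """Kullback–Leibler divergence ``sum_x p(x) log_base(p(x)/q(x))``.

    ``p`` is the baseline (young) density, ``q`` the aged one.

    Parameters
    ----------
    mode
        ``"normalized"`` — both vectors are rescaled to unit mass first; the
        result is then >= 0, and 0 iff p == q elementwise.  ``"raw"`` — the
        literal sum over the unnormalized densities (may be negative); this
        is the reading under which a single compartment with density ratio
        1e9 contributes log10 = 9.
    floor
        Positive clamp applied to both vectors before the ratio (default:
        the profiles' own floor, else 1e-12).  Pass ``floor=0`` to disable
        clamping, in which case a vanishing ``q`` under positive ``p`` raises
        :class:`SupportError`.
    """
    ln_base = _check_base(base)
    if mode not in ("normalized", "raw"):
        raise ParameterError(f"mode must be 'normalized' or 'raw', got {mode!r}")
    if floor is None:
        floor = max(
            p.floor if isinstance(p, DensityProfile) else 0.0,
            q.floor if isinstance(q, DensityProfile) else 0.0,
        ) or 1e-12
    pv = as_density_values(p).astype(float)
    qv = as_density_values(q).astype(float)
    if pv.shape != qv.shape:
        raise ShapeError(f"p has {pv.size} compartments, q has {qv.size}")
    if floor > 0:
        if np.any(pv < floor) or np.any(qv < floor):
            logger.warning("clamping densities below floor %g before KL ratio", floor)
        pv = np.maximum(pv, floor)
        qv = np.maximum(qv, floor)
    else:
        bad = (qv == 0) & (pv > 0)
        if np.any(bad):
            idx = int(np.argmax(bad))
            raise SupportError(
                f"q vanishes at compartment {idx} where p = {pv[idx]}",
                compartment=idx,
            )
    if mode == "normalized":
        ps, qs = pv.sum(), qv.sum()
        if ps <= 0 or qs <= 0:
            raise InvalidDistributionError("cannot normalize an all-zero density")
        pv, qv = pv / ps, qv / qs
    # xlogy handles p_i = 0 terms; q_i > 0 is guaranteed above
    return float(np.sum(xlogy(pv, pv / qv)) / ln_base)


def combinatorial_entropy(c: Union[CountVector, Sequence[int]]) -> float:
    """Logarithm of the multinomial multiplicity, ``ln(N! / prod_i n_i!)``.

    Computed through log-gamma, so large totals never overflow.  Zero when a
    single cell holds everything; maximal at equal occupation.  Natural-log
    units.
    """
    if not isinstance(c, CountVector):
        c = CountVector(np.asarray(c))
    if c.total < 1:
        raise InvalidDistributionError("total count must be at least 1")
    n = c.counts.astype(float)
    return float(gammaln(c.total + 1.0) - np.sum(gammaln(n + 1.0)))


def deviation_from_unity(series: Sequence[float]) -> np.ndarray:
    """Elementwise ``|D_t - 1|`` of a KL trajectory.

    The distance of the relative entropy from the unit level; plotted against
    iteration count it trends upward as the tissue ages.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise InvalidDistributionError("series must be a non-empty 1-D sequence")
    return np.abs(arr - 1.0)
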