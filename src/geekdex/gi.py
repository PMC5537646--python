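"""Geek-index (GI) construction.

The GI is a composite of three child-level measures collected at age 12:
non-verbal IQ (Raven's Standard Progressive Matrices), social aloofness
(CAST social subscale) and restricted/repetitive behaviours (CAST RRB
subscale).  The composite multiplies the IQ score by the sum of the two
CAST subscales, after two transforms:

* very high RRB scores are folded down so that the highest GI values
  correspond to *midrange* RRB — a child with clinically extreme RRB is
  not the intended "geek" phenotype;
* every subscale is shifted by +1 before multiplication, so a true score
  of 0 maps to 1 and no child's GI can be zeroed out by a single zero
  subscale.

Three variants are provided: ``default`` (shift + RRB fold), ``raw_rrb``
(no fold) and ``standardized`` (scale-normalized subscales, composite
z-scored against the cohort).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError

#: inclusive score ranges of the three subscales (configurable in the
#: synthetic generator; these are the package defaults)
IQ_RANGE = (0, 60)
SOCIAL_RANGE = (0, 13)
RRB_RANGE = (0, 13)

_VARIANT_NAMES = ("default", "standardized", "raw_rrb")


@dataclass(frozen=True)
class GIVariant:
    """How the GI composite is computed.

    Parameters
    ----------
    name:
        ``default``, ``standardized`` or ``raw_rrb``.
    rrb_fold_threshold:
        RRB score tau above which scores are folded down; the recoded
        score peaks at tau ("midrange" of the 0-13 scale by default).
    rrb_fold_slope:
        Slope of the fold above tau: recoded = tau - slope * (score - tau),
        floored at 0.
    """

    name: str = "default"
    rrb_fold_threshold: float = 7.0
    rrb_fold_slope: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in _VARIANT_NAMES:
            raise DomainError(f"unknown GI variant {self.name!r}; expected one of {_VARIANT_NAMES}")
        if not (RRB_RANGE[0] <= self.rrb_fold_threshold <= RRB_RANGE[1]):
            raise DomainError("rrb_fold_threshold must lie within the RRB scale range")
        if self.rrb_fold_slope < 0:
            raise DomainError("rrb_fold_slope must be >= 0")


DEFAULT_VARIANT = GIVariant("default")
STANDARDIZED_VARIANT = GIVariant("standardized")
RAW_RRB_VARIANT = GIVariant("raw_rrb")

VARIANTS = {
    "default": DEFAULT_VARIANT,
    "standardized": STANDARDIZED_VARIANT,
    "raw_rrb": RAW_RRB_VARIANT,
}


@dataclass(frozen=True)
class GeekIndex:
    """A single child's GI value together with the variant that produced it."""

    value: float
    variant: GIVariant

    def __post_init__(self) -> None:
        if self.variant.name == "default" and not self.value > 0:
            raise DomainError("default-variant GI must be strictly positive")


def _check_range(x, lo, hi, what: str):
    arr = np.asarray(x, dtype=float)
    if np.any(np.isnan(arr)):
        raise DomainError(f"{what} contains NaN")
    if np.any(arr < lo) or np.any(arr > hi):
        raise DomainError(f"{what} outside scale range [{lo}, {hi}]")
    return arr


def shift_transform(score):
    """Shift a subscale by +1 so that a true score of 0 maps to 1.

    Guards the multiplicative composite against zeroing-out: without the
    shift every child scoring 0 on any one subscale would get GI = 0.
    """
    arr = np.asarray(score, dtype=float)
    if np.any(arr < 0):
        raise DomainError("shift_transform requires non-negative scores")
    out = arr + 1.0
    return out.item() if np.isscalar(score) or np.ndim(score) == 0 else out


def recode_rrb(raw_rrb, variant: GIVariant = DEFAULT_VARIANT, scale_max: float = RRB_RANGE[1]):
    """Fold down high RRB scores so the composite peaks at midrange RRB.

    Identity below the fold threshold tau; above tau a tent-map descent
    ``tau - slope * (score - tau)``, floored at 0.  The ``raw_rrb``
    variant returns the input unchanged.
    """
    arr = _check_range(raw_rrb, 0, scale_max, "RRB score")
    if variant.name == "raw_rrb":
        out = arr.copy()
    else:
        tau = variant.rrb_fold_threshold
        s = variant.rrb_fold_slope
        out = np.where(arr <= tau, arr, np.maximum(tau - s * (arr - tau), 0.0))
    return out.item() if np.ndim(raw_rrb) == 0 else out


def compute_gi(nonverbal, social, rrb, variant: GIVariant = DEFAULT_VARIANT):
    """Compute the GI composite from the three subscales.

    ``default`` / ``raw_rrb``:
        GI = shift(nonverbal) * (shift(social) + shift(recode(rrb)))

    ``standardized``:
        each subscale (RRB after recoding) is divided by its sample
        standard deviation, combined with the same product structure, and
        the composite is z-scored.  Centering the subscales themselves is
        deliberately avoided: a product of mean-centered scores loads on
        second moments rather than on the shared trait and would not rank-
        track the other variants.  Requires array input (n >= 2).

    Scalars in, scalar out; arrays in, array out (order-preserving).
    """
    scalar = np.ndim(nonverbal) == 0
    nv = _check_range(nonverbal, *IQ_RANGE, what="non-verbal IQ score")
    so = _check_range(social, *SOCIAL_RANGE, what="CAST social score")
    rr = np.asarray(recode_rrb(rrb, variant), dtype=float)

    if variant.name == "standardized":
        if scalar or nv.size < 2:
            raise DomainError("standardized variant needs a cohort (>= 2 children) to normalize against")
        sds = [np.std(v, ddof=1) for v in (nv, so, rr)]
        if any(s == 0 for s in sds):
            raise DomainError("standardized variant undefined for a constant subscale")
        comp = (nv / sds[0]) * (so / sds[1] + rr / sds[2])
        sd_c = np.std(comp, ddof=1)
        if sd_c == 0:
            raise DomainError("standardized variant undefined: composite is constant")
        out = (comp - np.mean(comp)) / sd_c
        return out
    out = (nv + 1.0) * ((so + 1.0) + (rr + 1.0))
    return float(out) if scalar else out


def gi_for_cohort(cohort, variant: GIVariant = DEFAULT_VARIANT) -> pd.Series:
    """One GI value per child, aligned with the cohort's row order.

    ``cohort`` is a per-child DataFrame with ``nonverbal_iq``,
    ``cast_social`` and ``cast_rrb`` columns, or a collection of
    :class:`~geekdex.synth.TwinPair` (converted internally).
    """
    if not isinstance(cohort, pd.DataFrame):
        from .synth import cohort_to_frame

        cohort = cohort_to_frame(cohort)
    if len(cohort) == 0:
        return pd.Series([], dtype=float, name=f"gi_{variant.name}")
    vals = compute_gi(
        cohort["nonverbal_iq"].to_numpy(),
        cohort["cast_social"].to_numpy(),
        cohort["cast_rrb"].to_numpy(),
        variant,
    )
    return pd.Series(vals, index=cohort.index, name=f"gi_{variant.name}")


def score_cohort(cohort: pd.DataFrame, variants=("default", "standardized", "raw_rrb")) -> pd.DataFrame:
    """Return a copy of the cohort augmented with ``gi_<variant>`` columns."""
    out = cohort.copy()
    for name in variants:
        v = VARIANTS[name] if isinstance(name, str) else name
        col = "gi_rawrrb" if v.name == "raw_rrb" else f"gi_{v.name}"
        out[col] = gi_for_cohort(cohort, v)
    return out
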