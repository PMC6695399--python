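"""Chip normalization: signal flooring, percentile shift, exosome mass correction.

The normalization model is the one used by single-channel array suites
(GeneSpring-style): raw linear signals are floored at a small positive value,
log2-transformed, and each chip is shifted so that its Pth percentile of log2
signal is zero (P = 75 for mRNA chips, 99 for miRNA chips).  Exosomal miRNA
chips are additionally rescaled to a common loaded-RNA mass (1 ng equivalent)
before flooring, via per-sample multiplicative factors.

No per-feature baseline (median) centering is performed anywhere in this
module; chips are only made comparable to each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ConfigError, ExpressionMatrix, StateError


@dataclass
class NormalizationSpec:
    """Parameters of the floor + percentile-shift normalization for one assay.

    ``percentile`` is 75 for mRNA and 99 for miRNA chips by convention.
    ``mass_correction_factors`` maps sample name -> linear factor
    (1 ng / loaded mass in ng); absent means no correction.
    ``linear_variant`` switches the percentile shift to multiplicative
    rescaling on the linear scale instead of subtraction on log2.
    ``mass_correct_after_shift`` applies the mass correction after (rather
    than before) flooring and percentile shift.
    """

    floor_value: float = 1.0
    percentile: float = 75.0
    mass_correction_factors: dict[str, float] | None = None
    linear_variant: bool = False
    mass_correct_after_shift: bool = False

    def __post_init__(self) -> None:
        if self.floor_value <= 0:
            raise ConfigError("floor_value must be > 0")
        if not (0 < self.percentile <= 100):
            raise ConfigError("percentile must be in (0, 100]")
        if self.mass_correction_factors is not None:
            for name, f in self.mass_correction_factors.items():
                if f <= 0:
                    raise ConfigError(f"mass-correction factor for {name!r} must be > 0")


def floor_signals(matrix: ExpressionMatrix, floor_value: float = 1.0) -> ExpressionMatrix:
    """Replace every linear-scale signal below ``floor_value`` by ``floor_value``."""
    if matrix.is_log2:
        raise StateError("floor_signals expects linear-scale signals, got log2")
    if floor_value <= 0:
        raise ConfigError("floor_value must be > 0")
    return matrix.with_signals(matrix.signals.clip(lower=floor_value))


def percentile_shift(matrix: ExpressionMatrix, percentile: float, *, linear: bool = False) -> ExpressionMatrix:
    """Normalize each chip to its Pth percentile.

    Default behaviour: log2-transform the (floored, positive) signals and
    subtract each chip's Pth percentile of log2 signal from that chip, so the
    Pth percentile of every output chip is exactly 0 and the output is flagged
    ``is_log2``.  Percentiles interpolate linearly between closest ranks.

    With ``linear=True`` each chip is instead divided by its linear-scale Pth
    percentile before the log2 transform (agrees with the default exactly when
    the percentile falls on an exact rank, and closely otherwise — the rank
    interpolation happens on a different scale).
    """
    if matrix.is_log2:
        raise StateError("percentile_shift expects linear-scale signals, got log2")
    if matrix.normalized:
        raise StateError("matrix is already normalized; refusing to double-normalize")
    if not (0 < percentile <= 100):
        raise ConfigError("percentile must be in (0, 100]")
    values = matrix.signals.to_numpy(dtype=float)
    if (values <= 0).any():
        raise StateError("percentile_shift requires strictly positive signals (floor first)")
    if linear:
        pctl = np.percentile(values, percentile, axis=0)
        out = np.log2(values / pctl)
    else:
        logv = np.log2(values)
        pctl = np.percentile(logv, percentile, axis=0)
        out = logv - pctl
    shifted = pd.DataFrame(out, index=matrix.signals.index, columns=matrix.signals.columns)
    return matrix.with_signals(shifted, is_log2=True, normalized=True)


def mass_correct(matrix: ExpressionMatrix, factors: dict[str, float]) -> ExpressionMatrix:
    """Multiply each sample's signals by its per-sample mass factor.

    The factor for a sample loaded with m ng of RNA is 1/m, bringing all
    chips to a 1 ng equivalent.  Applied on the linear scale.
    """
    if matrix.is_log2:
        raise StateError("mass_correct expects linear-scale signals, got log2")
    names = matrix.sample_names()
    missing = [n for n in names if n not in factors]
    extra = [n for n in factors if n not in names]
    if missing or extra:
        raise ConfigError(
            f"mass-correction factors do not match samples (missing {missing}, extra {extra})"
        )
    for name, f in factors.items():
        if f <= 0:
            raise ConfigError(f"mass-correction factor for {name!r} must be > 0")
    scaled = matrix.signals * pd.Series({n: float(factors[n]) for n in names})
    return matrix.with_signals(scaled)


def normalize_chips(matrix: ExpressionMatrix, spec: NormalizationSpec) -> ExpressionMatrix:
    """Full per-assay normalization: (mass-correct) -> floor -> percentile shift."""
    out = matrix
    factors = spec.mass_correction_factors
    if factors is not None and not spec.mass_correct_after_shift:
        out = mass_correct(out, factors)
    out = floor_signals(out, spec.floor_value)
    out = percentile_shift(out, spec.percentile, linear=spec.linear_variant)
    if factors is not None and spec.mass_correct_after_shift:
        # on log2 scale the linear factor becomes an additive offset
        offset = pd.Series({n: np.log2(float(factors[n])) for n in out.sample_names()})
        out = out.with_signals(out.signals + offset)
    return out
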