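"""Model-performance statistics: MRD, GMFE, effect ratios, fold criteria
and ratio-dependent prediction acceptance limits."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PredictionObservationSet",
    "RatioPair",
    "mrd",
    "gmfe",
    "effect_ratio",
    "guest_limits",
    "fraction_within_fold",
]

log = logging.getLogger(__name__)


@dataclass
class PredictionObservationSet:
    """Paired predicted/observed values (concentrations or AUC/Cmax)."""

    predicted: np.ndarray
    observed: np.ndarray
    analyte: str = ""
    scenario: str = ""
    lloq: float | None = None
    n_excluded: int = field(default=0, init=False)

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.observed = np.asarray(self.observed, dtype=float)
        if self.predicted.shape != self.observed.shape:
            raise ValueError("predicted and observed must have equal length")
        if self.lloq is not None:
            keep = self.observed > self.lloq
            self.n_excluded = int((~keep).sum())
            if self.n_excluded:
                log.info(
                    "%s/%s: excluded %d observations at or below LLOQ",
                    self.analyte,
                    self.scenario,
                    self.n_excluded,
                )
            self.predicted = self.predicted[keep]
            self.observed = self.observed[keep]

    @property
    def n(self) -> int:
        return int(self.predicted.size)

    def _validate_positive(self) -> None:
        if self.n == 0:
            raise ValueError("empty prediction/observation set")
        if np.any(self.observed <= 0) or np.any(self.predicted <= 0):
            raise ValueError("log-based metrics require strictly positive values")


def mrd(pairs: PredictionObservationSet) -> float:
    """Mean relative deviation: 10 ** sqrt(mean of squared log10 residuals)."""
    pairs._validate_positive()
    resid = np.log10(pairs.predicted) - np.log10(pairs.observed)
    return float(10.0 ** np.sqrt(np.mean(resid**2)))


def gmfe(pairs: PredictionObservationSet) -> float:
    """Geometric mean fold error: 10 ** mean(|log10(pred/obs)|)."""
    pairs._validate_positive()
    return float(10.0 ** np.mean(np.abs(np.log10(pairs.predicted / pairs.observed))))


@dataclass(frozen=True)
class RatioPair:
    """Effect metric over its control (NM for DGI; same-AS no-perpetrator
    metric for DD(G)I)."""

    effect: float
    control: float

    def __post_init__(self) -> None:
        if self.control <= 0:
            raise ValueError("control metric must be > 0")
        if self.effect < 0:
            raise ValueError("effect metric must be >= 0")


def effect_ratio(pair: RatioPair) -> float:
    return pair.effect / pair.control


def guest_limits(observed_ratio: float, variability: float = 1.25) -> tuple[float, float]:
    """Ratio-dependent acceptance bounds on predicted/observed interaction
    ratios: with R = max(r, 1/r), upper = (variability + 2(R-1)) / R and
    lower = 1/upper.  Symmetric in r <-> 1/r and equal to (1/v, v) at r=1.
    """
    if observed_ratio <= 0:
        raise ValueError("observed ratio must be > 0")
    if variability < 1:
        raise ValueError("variability factor must be >= 1")
    r = max(observed_ratio, 1.0 / observed_ratio)
    upper = (variability + 2.0 * (r - 1.0)) / r
    return 1.0 / upper, upper


def fraction_within_fold(pairs: PredictionObservationSet, fold: float = 2.0) -> float:
    """Share of pairs with 1/fold <= predicted/observed <= fold (boundary
    inclusive)."""
    if fold <= 1:
        raise ValueError("fold must be > 1")
    pairs._validate_positive()
    ratio = pairs.predicted / pairs.observed
    within = (ratio >= 1.0 / fold) & (ratio <= fold)
    return float(within.mean())
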