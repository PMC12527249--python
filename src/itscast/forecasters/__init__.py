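"""Interchangeable forecaster families behind one fit/predict contract."""

from .base import BaseForecaster, ForecastFitError, clone
from .arima import ArimaForecaster
from .nnar import NnarForecaster
from .hybrid import HybridForecaster
from .structural import StructuralTrendSeasonal

FAMILIES = ("arima", "nnar", "hybrid")

_REGISTRY = {
    "arima": ArimaForecaster,
    "nnar": NnarForecaster,
    "hybrid": HybridForecaster,
}


def make_forecaster(family: str, **params) -> BaseForecaster:
    """Instantiate a forecaster family by tag with estimator parameters."""
    try:
        cls = _REGISTRY[family]
    except KeyError:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}") from None
    return cls(**params)


__all__ = [
    "BaseForecaster",
    "ForecastFitError",
    "ArimaForecaster",
    "NnarForecaster",
    "HybridForecaster",
    "StructuralTrendSeasonal",
    "make_forecaster",
    "clone",
    "FAMILIES",
]
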