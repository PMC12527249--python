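"""Typed hyperparameter configurations and the tuning boxes they live in.

Each dataclass validates its fields against the search box used for
space-filling hyperparameter sampling (the ranges explored by the study
design); ``to_estimator`` resolves a configuration into a forecaster
estimator.  Estimators themselves accept values outside the boxes (useful
for desk-scale runs); only these config types enforce the ranges.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

from .arima import ArimaForecaster
from .hybrid import HybridForecaster
from .nnar import NnarForecaster

__all__ = ["ArimaConfig", "NnarConfig", "HybridConfig", "SEARCH_SPACES", "config_class"]


def _check(name, value, lo, hi):
    if not (lo <= value <= hi):
        raise ValueError(f"{name}={value} outside tuning range [{lo}, {hi}]")


@dataclass
class ArimaConfig:
    p: int = 1
    q: int = 1
    d: int = 0
    P: int = 0
    Q: int = 0
    D: int = 0
    seasonal_period: int = 7
    fourier_K: int = 3

    def __post_init__(self):
        _check("p", self.p, 1, 3)
        _check("q", self.q, 1, 3)
        _check("d", self.d, 0, 2)
        _check("P", self.P, 0, 3)
        _check("Q", self.Q, 0, 3)
        _check("D", self.D, 0, 1)

    def to_estimator(self, random_state: int = 0) -> ArimaForecaster:
        return ArimaForecaster(**asdict(self))


@dataclass
class NnarConfig:
    p_lags: int = 1
    P_seasonal: int = 1
    hidden_units: int = 10
    n_networks: int = 40
    decay: float = 0.01
    epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        _check("p_lags", self.p_lags, 1, 6)
        _check("P_seasonal", self.P_seasonal, 1, 4)
        _check("hidden_units", self.hidden_units, 8, 20)
        _check("n_networks", self.n_networks, 40, 100)
        _check("decay", self.decay, 0.01, 0.1)
        _check("epochs", self.epochs, 50, 200)

    def to_estimator(self, random_state: int | None = None) -> NnarForecaster:
        params = asdict(self)
        seed = params.pop("seed")
        return NnarForecaster(
            random_state=seed if random_state is None else random_state, **params
        )


@dataclass
class HybridConfig:
    changepoint_range: float = 0.6
    cp_prior: float = 0.05
    seas_prior: float = 1.0
    yearly_K: int = 3
    mtry: int = 10
    min_n: int = 2
    depth: int = 8
    learning_rate: float = 0.05
    gamma: float = 1e-6
    early_stop: int = 20
    n_trees_max: int = 300
    seed: int = 0

    def __post_init__(self):
        _check("changepoint_range", self.changepoint_range, 0.4, 0.8)
        _check("cp_prior", self.cp_prior, 0.01, 0.5)
        _check("seas_prior", self.seas_prior, 0.1, 2.0)
        _check("mtry", self.mtry, 4, 25)
        _check("min_n", self.min_n, 1, 12)
        _check("depth", self.depth, 8, 20)
        _check("learning_rate", self.learning_rate, 0.001, 0.1)
        _check("gamma", self.gamma, 1e-12, 1e2)
        _check("early_stop", self.early_stop, 10, 30)

    def to_estimator(self, random_state: int | None = None) -> HybridForecaster:
        params = asdict(self)
        seed = params.pop("seed")
        return HybridForecaster(
            random_state=seed if random_state is None else random_state, **params
        )


#: per-family sampling boxes: name -> (low, high, kind) with kind in
#: {"int", "float", "logfloat"}
SEARCH_SPACES = {
    "arima": {
        "p": (1, 3, "int"),
        "q": (1, 3, "int"),
        "d": (0, 2, "int"),
        "P": (0, 3, "int"),
        "Q": (0, 3, "int"),
        "D": (0, 1, "int"),
    },
    "nnar": {
        "p_lags": (1, 6, "int"),
        "P_seasonal": (1, 4, "int"),
        "hidden_units": (8, 20, "int"),
        "n_networks": (40, 100, "int"),
        "decay": (0.01, 0.1, "float"),
        "epochs": (50, 200, "int"),
    },
    "hybrid": {
        "changepoint_range": (0.4, 0.8, "float"),
        "cp_prior": (0.01, 0.5, "float"),
        "seas_prior": (0.1, 2.0, "float"),
        "mtry": (4, 25, "int"),
        "min_n": (1, 12, "int"),
        "depth": (8, 20, "int"),
        "learning_rate": (0.001, 0.1, "float"),
        "gamma": (1e-12, 1e2, "logfloat"),
        "early_stop": (10, 30, "int"),
    },
}

_CONFIG_CLASSES = {"arima": ArimaConfig, "nnar": NnarConfig, "hybrid": HybridConfig}


def config_class(family: str):
    try:
        return _CONFIG_CLASSES[family]
    except KeyError:
        raise ValueError(f"unknown family {family!r}") from None
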