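"""JSON persistence for fitted distance-distribution models.

Normal and exponential fits round-trip through their parameters alone;
the data-driven families (ECDF, KDE) store the fitted data vector so the
reloaded model is bit-identical to the original fit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import distfit
from .distfit import (ECDFFit, ExponentialFit, FittedDistribution, KDEFit,
                      NormalFit)

FORMAT = "premirdist-model/1"


def save_model(fit: FittedDistribution, path: str | Path) -> None:
    state: dict = {
        "format": FORMAT,
        "family": fit.family,
        "data_n": fit.data_n,
        "data_min": fit.data_min,
        "data_max": fit.data_max,
    }
    if isinstance(fit, NormalFit):
        state["mu"] = fit.mu
        state["sigma"] = fit.sigma
    elif isinstance(fit, ExponentialFit):
        state["mean"] = fit.mean
    elif isinstance(fit, ECDFFit):
        state["values"] = [float(v) for v in fit._sorted]
    elif isinstance(fit, KDEFit):
        state["bandwidth"] = fit.bandwidth
        state["values"] = [float(v) for v in fit._data]
    else:  # pragma: no cover - future families
        raise TypeError(f"cannot serialize {type(fit).__name__}")
    Path(path).write_text(json.dumps(state) + "\n")


def load_model(path: str | Path) -> FittedDistribution:
    state = json.loads(Path(path).read_text())
    if state.get("format") != FORMAT:
        raise ValueError(f"{path}: not a {FORMAT} file")
    family = state["family"]
    if family == "normal":
        fit = object.__new__(NormalFit)
        fit.data_n = state["data_n"]
        fit.data_min = state["data_min"]
        fit.data_max = state["data_max"]
        fit.mu = state["mu"]
        fit.sigma = state["sigma"]
        fit.degenerate = fit.sigma == 0.0
        if not fit.degenerate:
            from scipy import stats
            fit._frozen = stats.norm(loc=fit.mu, scale=fit.sigma)
        return fit
    if family == "exponential":
        fit = object.__new__(ExponentialFit)
        fit.data_n = state["data_n"]
        fit.data_min = state["data_min"]
        fit.data_max = state["data_max"]
        fit.mean = state["mean"]
        from scipy import stats
        fit._frozen = stats.expon(scale=fit.mean)
        return fit
    values = np.asarray(state["values"], dtype=float)
    if family == "ecdf":
        return distfit.fit_ecdf(values)
    if family == "kde":
        return distfit.fit_kde(values, bandwidth=state["bandwidth"])
    raise ValueError(f"unknown family {family!r} in {path}")
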