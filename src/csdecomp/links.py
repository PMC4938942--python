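"""Link functions for binary-outcome models.

Each link provides the response function F (probability given the linear
predictor), its density f = F', and the density derivative f' needed by
delta-method standard errors for average marginal effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import special, stats

VALID_LINKS = ("probit", "logit", "identity")


@dataclass(frozen=True)
class Link:
    name: str
    cdf: Callable[[np.ndarray], np.ndarray]
    pdf: Callable[[np.ndarray], np.ndarray]
    dpdf: Callable[[np.ndarray], np.ndarray] = field(repr=False, default=None)


def _probit_dpdf(z):
    return -z * stats.norm.pdf(z)


def _logit_pdf(z):
    p = special.expit(z)
    return p * (1.0 - p)


def _logit_dpdf(z):
    p = special.expit(z)
    return p * (1.0 - p) * (1.0 - 2.0 * p)


_LINKS = {
    "probit": Link("probit", stats.norm.cdf, stats.norm.pdf, _probit_dpdf),
    "logit": Link("logit", special.expit, _logit_pdf, _logit_dpdf),
    "identity": Link(
        "identity",
        lambda z: np.asarray(z, dtype=float),
        lambda z: np.ones_like(np.asarray(z, dtype=float)),
        lambda z: np.zeros_like(np.asarray(z, dtype=float)),
    ),
}


def get_link(name: str) -> Link:
    try:
        return _LINKS[name]
    except KeyError:
        raise ValueError(
            f"unknown link {name!r}; expected one of {VALID_LINKS}"
        ) from None
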