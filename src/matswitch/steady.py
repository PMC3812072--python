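"""Analytic oracle: the 4-state chain of a random descendant lineage.

Follow a uniformly random daughter at every division.  The lineage moves
between four states (Pu, Ps, Mu, Ms) — allele × imprint — with
transition probabilities derived from the division rules: from an
unimprinted state the lineage becomes imprinted with probability beta/2
(the lagging daughter is picked half the time); from an imprinted state
it switches allele with probability ``s_eff * h / 2`` where ``h`` is the
heterologous fraction of completed attempts for that cell type.

Under neutral synchronous growth the expected allele composition of the
population follows this chain, so its stationary distribution is the
population oracle.  When both effective switching rates are positive the
stationary P fraction has the closed form ``h_M / (h_M + h_P)`` —
independent of beta and s, which scale both fluxes equally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .choice import ChoiceParams, heterologous_fraction
from .region import Allele, RegionConfig

__all__ = [
    "STATE_ORDER",
    "SteadyResult",
    "build_transition_matrix",
    "stationary_distribution",
    "steady_fraction_P",
    "project_fractions",
]

STATE_ORDER = ("Pu", "Ps", "Mu", "Ms")
_CLOSED_FORM_TOL = 1e-10


def switching_rates(config: RegionConfig, params: ChoiceParams) -> tuple:
    """Effective per-division switching rates (h_P, h_M) of the leading daughter.

    ``h_P`` is the probability that an imprinted P cell's leading daughter
    is M (and symmetrically for ``h_M``), i.e. attempt success times the
    heterologous fraction of the donor distribution.
    """
    s = params.s_eff(config)
    return (
        s * heterologous_fraction(Allele.P, config, params),
        s * heterologous_fraction(Allele.M, config, params),
    )


def build_transition_matrix(config: RegionConfig, params: ChoiceParams) -> np.ndarray:
    """Row-stochastic 4×4 matrix over (Pu, Ps, Mu, Ms) for a random daughter."""
    beta = params.imprint_efficiency
    h_P, h_M = switching_rates(config, params)

    T = np.zeros((4, 4))
    # Pu: lagging (1/2) imprinted w.p. beta; leading (1/2) stays Pu
    T[0, 1] = beta / 2.0
    T[0, 0] = 1.0 - beta / 2.0
    # Ps: lagging keeps Ps w.p. beta/2; leading switches to Mu w.p. h_P/2
    T[1, 1] = beta / 2.0
    T[1, 2] = h_P / 2.0
    T[1, 0] = 1.0 - beta / 2.0 - h_P / 2.0
    # mirror rows for M
    T[2, 3] = beta / 2.0
    T[2, 2] = 1.0 - beta / 2.0
    T[3, 3] = beta / 2.0
    T[3, 0] = h_M / 2.0
    T[3, 2] = 1.0 - beta / 2.0 - h_M / 2.0

    assert np.allclose(T.sum(axis=1), 1.0, atol=1e-12)
    return T


def stationary_distribution(matrix: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Stationary vector of a row-stochastic matrix via the linear system.

    Solves pi (T - I) = 0 with the normalization sum(pi) = 1; falls back
    to power iteration if the system is ill-conditioned.
    """
    k = matrix.shape[0]
    A = np.vstack([(matrix.T - np.eye(k)), np.ones((1, k))])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.any(pi < -1e-9) or abs(pi.sum() - 1.0) > 1e-9:
        pi = np.full(k, 1.0 / k)
        for _ in range(200_000):
            nxt = pi @ matrix
            if np.max(np.abs(nxt - pi)) < tol:
                pi = nxt
                break
            pi = nxt
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


@dataclass(frozen=True)
class SteadyResult:
    """Long-run allele composition of a random lineage.

    ``flag`` is ``"unique"`` when both switching rates are positive (a
    unique stationary distribution exists), ``"absorbing_P"`` /
    ``"absorbing_M"`` for one-way switching, or ``"founder_dependent"``
    when no switching occurs at all (``fraction_P`` is then None).
    """

    fraction_P: Optional[float]
    flag: str
    stationary: Optional[np.ndarray] = None
    h_P: float = 0.0
    h_M: float = 0.0

    def to_dict(self) -> dict:
        return {
            "fraction_P": self.fraction_P,
            "flag": self.flag,
            "stationary": None if self.stationary is None else
                dict(zip(STATE_ORDER, (float(x) for x in self.stationary))),
            "h_P": self.h_P,
            "h_M": self.h_M,
        }


def steady_fraction_P(config: RegionConfig, params: ChoiceParams) -> SteadyResult:
    """Stationary P fraction, cross-validated against the closed form.

    With both rates positive the stationary vector of the transition
    matrix is computed and checked against ``h_M / (h_M + h_P)`` to
    1e-10; a discrepancy would indicate an internal inconsistency and
    raises.
    """
    h_P, h_M = switching_rates(config, params)
    beta = params.imprint_efficiency

    if h_P > 0.0 and h_M > 0.0 and beta > 0.0:
        T = build_transition_matrix(config, params)
        pi = stationary_distribution(T)
        frac = float(pi[0] + pi[1])
        closed = h_M / (h_M + h_P)
        if abs(frac - closed) > _CLOSED_FORM_TOL:
            raise AssertionError(
                f"stationary vector ({frac}) disagrees with closed form ({closed})"
            )
        return SteadyResult(closed, "unique", pi, h_P, h_M)
    if h_P > 0.0 and h_M == 0.0 and beta > 0.0:
        pi = np.array([0.0, 0.0, 1.0 - beta / 2.0, beta / 2.0])
        return SteadyResult(0.0, "absorbing_M", pi, h_P, h_M)
    if h_M > 0.0 and h_P == 0.0 and beta > 0.0:
        pi = np.array([1.0 - beta / 2.0, beta / 2.0, 0.0, 0.0])
        return SteadyResult(1.0, "absorbing_P", pi, h_P, h_M)
    return SteadyResult(None, "founder_dependent", None, h_P, h_M)


def project_fractions(
    matrix: np.ndarray, initial: np.ndarray, t: int
) -> np.ndarray:
    """P-fraction trajectory of the lineage chain over generations 0..t."""
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (4,):
        raise ValueError("initial distribution must have 4 entries (Pu, Ps, Mu, Ms)")
    if abs(initial.sum() - 1.0) > 1e-9 or np.any(initial < 0):
        raise ValueError("initial distribution must be a probability vector")
    if t < 0:
        raise ValueError("t must be nonnegative")
    out = np.empty(t + 1)
    pi = initial.copy()
    out[0] = pi[0] + pi[1]
    for i in range(1, t + 1):
        pi = pi @ matrix
        out[i] = pi[0] + pi[1]
    return out
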