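"""Donor-choice models: which silent cassette converts *mat1*.

Two mechanistic models are implemented.

**Competition model** (the default): the SRE2 and SRE3 recombination
enhancers compete to capture the recombinogenic end generated at *mat1*,
each promoting conversion by its adjacent cassette.  The relative
activity of each enhancer depends on the cell type (P or M) and on the
chromatin state (Swi6 present or absent): Swi6 tilts the competition
toward SRE2 in M cells, while SRE3 wins in P cells and in swi6Δ cells.
The probability that the mat2-adjacent enhancer wins is simply
``w2 / (w2 + w3)`` with weights read from a table.

**2004 spreading model**: an earlier alternative in which the Swi2/Swi5
recombination-promoting complex (RPC) enters the region at SRE3, stays
there in P cells (favoring the SRE3-adjacent cassette) and spreads to
mat2 in M cells via Swi6 (favoring mat2).  When SRE3 is absent, or RPC is
absent, mat2 is preferred by default.  The rule picks its preferred donor
with probability ``q`` (the spreading-preference strength).

Default weights: in swi6+ cells P cells use SRE3 at 0.8 and err onto SRE2
at 0.2 of attempted switches, M cells use SRE2 at 0.9 and err onto SRE3
at 0.1.  The swi6Δ column (SRE3 0.85 / SRE2 0.15 in both cell types) is a
calibrated constant chosen so the wild-type architecture without Swi6
settles near 15% P cells, matching the observed strong M bias; it is not
a measured quantity.  Enhancer-less slots retain a small residual weight
(0.02) because enhancer-deletion strains still switch, albeit very
inefficiently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, Union

from .region import Allele, Enhancer, RegionConfig, is_heterologous

__all__ = [
    "ChoiceParams",
    "DonorDistribution",
    "DegenerateConfigError",
    "default_weights",
    "default_params",
    "perfect_directionality_params",
    "params_from_error_rates",
    "swap_cell_columns",
    "donor_distribution",
    "donor_distribution_2004",
    "donor_distribution_for",
    "heterologous_fraction",
    "heterologous_rate",
]

# weight table keys: (enhancer, cell allele, swi6_present)
WeightTable = Dict[tuple, float]


class DegenerateConfigError(ValueError):
    """Both candidate donors have zero weight for the requesting cell."""


def default_weights() -> WeightTable:
    """The default enhancer-activity table (relative weights, not rates)."""
    w: WeightTable = {}
    swi6 = {  # (enhancer, cell) -> weight with Swi6 present
        (Enhancer.SRE3, Allele.P): 0.8,
        (Enhancer.SRE2, Allele.P): 0.2,
        (Enhancer.SRE2, Allele.M): 0.9,
        (Enhancer.SRE3, Allele.M): 0.1,
    }
    swi6del = {  # calibrated: SRE3 outcompetes SRE2 without Swi6
        (Enhancer.SRE3, Allele.P): 0.85,
        (Enhancer.SRE2, Allele.P): 0.15,
        (Enhancer.SRE3, Allele.M): 0.85,
        (Enhancer.SRE2, Allele.M): 0.15,
    }
    for (enh, cell), val in swi6.items():
        w[(enh, cell, True)] = val
    for (enh, cell), val in swi6del.items():
        w[(enh, cell, False)] = val
    for cell in Allele:
        for chromatin in (True, False):
            w[(Enhancer.NONE, cell, chromatin)] = 0.02
    return w


@dataclass(frozen=True)
class ChoiceParams:
    """Parameters of the donor-choice and switching machinery.

    Attributes
    ----------
    weights
        Relative enhancer activity, keyed by (enhancer, cell type,
        swi6_present).  Nonnegative; only ratios matter within a cell
        type/chromatin combination.
    attempt_success
        Compound probability ``s`` that an imprinted division completes a
        conversion attempt (default 0.85, placing the compound switching
        probability of the switchable lineage in the observed 80–90% band).
    rpc_loss_success
        Replacement for ``s`` when the Swi2/Swi5 complex is absent
        (swi2Δ/swi5Δ strains); conversions still initiate but almost
        always fail (default 0.02).
    imprint_efficiency
        Probability ``beta`` that the lagging-strand daughter acquires
        the imprint (default 1.0).
    model_variant
        ``"competition"`` or ``"spreading2004"``.
    spreading_preference
        Strength ``q`` with which the 2004 model's rule picks its
        preferred donor (default 0.9).
    lethal_on_failure
        If True, a failed conversion attempt kills the leading-strand
        daughter instead of healing it (default False).
    """

    weights: WeightTable = field(default_factory=default_weights)
    attempt_success: float = 0.85
    rpc_loss_success: float = 0.02
    imprint_efficiency: float = 1.0
    model_variant: str = "competition"
    spreading_preference: float = 0.9
    lethal_on_failure: bool = False

    def __post_init__(self) -> None:
        for key, val in self.weights.items():
            if val < 0:
                raise ValueError(f"negative weight {val} for {key}")
        for name in ("attempt_success", "rpc_loss_success", "imprint_efficiency",
                     "spreading_preference"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")
        if self.model_variant not in ("competition", "spreading2004"):
            raise ValueError(
                f"unknown model_variant {self.model_variant!r}; "
                "expected 'competition' or 'spreading2004'"
            )

    def weight(self, enhancer: Enhancer, cell: Allele, swi6_present: bool) -> float:
        return self.weights[(enhancer, cell, bool(swi6_present))]

    def s_eff(self, config: RegionConfig) -> float:
        """Attempt-success probability effective in this genotype."""
        return self.attempt_success if config.rpc_present else self.rpc_loss_success

    # -- serialization ---------------------------------------------------

    def weights_to_json(self) -> str:
        """Weight table as nested JSON: enhancer → cell → chromatin → weight."""
        nested: dict = {}
        for (enh, cell, chromatin), val in self.weights.items():
            col = "swi6+" if chromatin else "swi6del"
            nested.setdefault(enh.value, {}).setdefault(cell.value, {})[col] = val
        return json.dumps(nested, sort_keys=True)

    @staticmethod
    def weights_from_json(s: str) -> WeightTable:
        nested = json.loads(s)
        w: WeightTable = {}
        for enh_name, by_cell in nested.items():
            for cell_name, by_col in by_cell.items():
                for col, val in by_col.items():
                    if col not in ("swi6+", "swi6del"):
                        raise ValueError(f"unknown chromatin column {col!r}")
                    w[(Enhancer(enh_name), Allele(cell_name), col == "swi6+")] = float(val)
        return w

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": json.loads(self.weights_to_json()),
                "attempt_success": self.attempt_success,
                "rpc_loss_success": self.rpc_loss_success,
                "imprint_efficiency": self.imprint_efficiency,
                "model_variant": self.model_variant,
                "spreading_preference": self.spreading_preference,
                "lethal_on_failure": self.lethal_on_failure,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, s: str) -> "ChoiceParams":
        d = json.loads(s)
        weights = cls.weights_from_json(json.dumps(d.pop("weights")))
        return cls(weights=weights, **d)


def default_params(**overrides) -> ChoiceParams:
    """Default parameter set; keyword overrides applied on top."""
    return replace(ChoiceParams(), **overrides) if overrides else ChoiceParams()


def perfect_directionality_params(**overrides) -> ChoiceParams:
    """Deterministic error-free parameters (beta=1, s=1, zero error rates).

    P cells always pick the SRE3-adjacent slot, M cells always SRE2; used
    for the structural pedigree rules (one-in-four, recurrent switching).
    """
    kw = dict(attempt_success=1.0, imprint_efficiency=1.0)
    kw.update(overrides)
    return params_from_error_rates(0.0, 0.0, **kw)


def params_from_error_rates(
    e_P: float,
    e_M: float,
    swi6_present: bool = True,
    base: ChoiceParams = None,
    **overrides,
) -> ChoiceParams:
    """Parametrize the weight table by the two directionality error rates.

    ``e_P`` is the probability a P cell's attempt engages SRE2 (its
    'wrong' enhancer) and ``e_M`` the probability an M cell engages SRE3.
    The four weights of the chromatin column selected by ``swi6_present``
    are set to (e_P, 1−e_P, e_M, 1−e_M); the other column is untouched.
    """
    if not (0.0 <= e_P <= 1.0 and 0.0 <= e_M <= 1.0):
        raise ValueError("error rates must lie in [0, 1]")
    params = base if base is not None else ChoiceParams()
    w = dict(params.weights)
    w[(Enhancer.SRE2, Allele.P, swi6_present)] = e_P
    w[(Enhancer.SRE3, Allele.P, swi6_present)] = 1.0 - e_P
    w[(Enhancer.SRE3, Allele.M, swi6_present)] = e_M
    w[(Enhancer.SRE2, Allele.M, swi6_present)] = 1.0 - e_M
    return replace(params, weights=w, **overrides)


def swap_cell_columns(params: ChoiceParams) -> ChoiceParams:
    """Exchange the P and M columns of the weight table (symmetry tool)."""
    w = {
        (enh, cell.other(), chromatin): val
        for (enh, cell, chromatin), val in params.weights.items()
    }
    return replace(params, weights=w)


@dataclass(frozen=True)
class DonorDistribution:
    """Probability over the two donors, conditional on an attempt."""

    p_mat2: float
    p_mat3: float

    def __post_init__(self) -> None:
        if abs(self.p_mat2 + self.p_mat3 - 1.0) > 1e-12:
            raise ValueError("donor probabilities must sum to 1")


def _cell(value: Union[str, Allele]) -> Allele:
    return value if isinstance(value, Allele) else Allele(str(value).upper())


def donor_distribution(
    cell: Union[str, Allele], config: RegionConfig, params: ChoiceParams
) -> DonorDistribution:
    """Competition model: normalized enhancer weights of the two slots."""
    cell = _cell(cell)
    w2 = params.weight(config.mat2.enhancer, cell, config.swi6_present)
    w3 = params.weight(config.mat3.enhancer, cell, config.swi6_present)
    total = w2 + w3
    if total <= 0.0:
        raise DegenerateConfigError(
            f"both donor weights are zero for cell type {cell.value} "
            f"(mat2 {config.mat2.enhancer.value}, mat3 {config.mat3.enhancer.value})"
        )
    return DonorDistribution(p_mat2=w2 / total, p_mat3=w3 / total)


def donor_distribution_2004(
    cell: Union[str, Allele], config: RegionConfig, params: ChoiceParams
) -> DonorDistribution:
    """2004 spreading model: preferred donor chosen with probability q.

    mat2 is preferred when SRE3 is absent, when RPC is absent, or in M
    cells with Swi6 (RPC spreads from SRE3 to mat2).  Otherwise RPC stays
    at SRE3 and the SRE3-carrying slot is preferred — in P cells, and
    (since spreading requires Swi6) also in swi6Δ M cells.  With SRE3 on
    both slots the mat3 copy is taken as the nucleation site.
    """
    cell = _cell(cell)
    q = params.spreading_preference
    sre3_at_mat2 = config.mat2.enhancer is Enhancer.SRE3
    sre3_at_mat3 = config.mat3.enhancer is Enhancer.SRE3
    sre3_present = sre3_at_mat2 or sre3_at_mat3
    if (
        not sre3_present
        or not config.rpc_present
        or (cell is Allele.M and config.swi6_present)
    ):
        preferred_mat2 = True
    else:
        # RPC localized at SRE3: prefer the slot carrying it
        preferred_mat2 = sre3_at_mat2 and not sre3_at_mat3
    p2 = q if preferred_mat2 else 1.0 - q
    return DonorDistribution(p_mat2=p2, p_mat3=1.0 - p2)


def donor_distribution_for(
    cell: Union[str, Allele], config: RegionConfig, params: ChoiceParams
) -> DonorDistribution:
    """Dispatch on ``params.model_variant``."""
    if params.model_variant == "spreading2004":
        return donor_distribution_2004(cell, config, params)
    return donor_distribution(cell, config, params)


def heterologous_fraction(
    cell: Union[str, Allele], config: RegionConfig, params: ChoiceParams
) -> float:
    """Probability that a *completed* attempt is heterologous (switches)."""
    cell = _cell(cell)
    dist = donor_distribution_for(cell, config, params)
    h = 0.0
    for p, slot in ((dist.p_mat2, config.mat2), (dist.p_mat3, config.mat3)):
        if is_heterologous(cell, slot):
            h += p
    return h


def heterologous_rate(
    cell: Union[str, Allele], config: RegionConfig, params: ChoiceParams
) -> float:
    """Per-attempt probability that the leading-strand daughter switches.

    Equals ``s_eff * sum over slots of p(slot) * [slot heterologous]``,
    where ``s_eff`` is ``attempt_success`` or, in RPC-less genotypes,
    ``rpc_loss_success``.
    """
    return params.s_eff(config) * heterologous_fraction(cell, config, params)
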