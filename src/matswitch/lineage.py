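"""Replication-coupled switching: pedigrees and growing cultures.

Each division produces two daughters distinguished by which strand of
*mat1* they inherit.  The lagging-strand daughter keeps the parental
allele and acquires the strand-specific imprint with probability ``beta``
— it founds (or continues) the switchable lineage.  The leading-strand
daughter of an *imprinted* parent carries a broken/recombinogenic *mat1*:
with probability ``s_eff`` the conversion completes using a donor drawn
from the donor-choice model, and the daughter's allele becomes the donor
slot's content (a homologous donor leaves the type unchanged — a futile
switch).  Failed attempts heal without conversion by default.  Either
way the leading daughter is born unimprinted.

These rules reproduce the two classical pedigree facts: exactly one of
the four granddaughters of a newly switched (unimprinted) cell switches,
and the switchable lineage switches recurrently at every division.

Cultures are simulated with synchronous generations and a carrying
capacity: every cell divides, then the population is uniformly
subsampled without replacement back down to the capacity
(Wright–Fisher-like).  Because cells in a given state are exchangeable,
the population update is performed on the four state counts with exact
binomial/multinomial draws — distributionally identical to dividing each
cell individually, at O(1) cost per generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .choice import ChoiceParams, donor_distribution_for, heterologous_fraction
from .region import Allele, RegionConfig

__all__ = [
    "CellState",
    "PedigreeNode",
    "Trajectory",
    "divide",
    "enumerate_pedigree",
    "count_switched_granddaughters",
    "simulate_culture",
    "imprinted_fraction",
]

MAX_PEDIGREE_DEPTH = 20
STATE_ORDER = ("Pu", "Ps", "Mu", "Ms")


@dataclass(frozen=True)
class CellState:
    """One cell: its *mat1* allele and whether *mat1* is imprinted."""

    allele: Allele
    imprinted: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.allele, Allele):
            object.__setattr__(self, "allele", Allele(str(self.allele).upper()))

    @property
    def label(self) -> str:
        """Short state name: Pu, Ps, Mu or Ms (u=unswitchable, s=switchable)."""
        return self.allele.value + ("s" if self.imprinted else "u")

    @classmethod
    def from_label(cls, label: str) -> "CellState":
        label = str(label).strip()
        if len(label) != 2 or label[0].upper() not in "PM" or label[1].lower() not in "us":
            raise ValueError(f"unknown cell-state label {label!r}; expected Pu/Ps/Mu/Ms")
        return cls(Allele(label[0].upper()), imprinted=label[1].lower() == "s")


@dataclass
class PedigreeNode:
    """Binary pedigree node; internal nodes have one lagging and one leading child."""

    state: CellState
    lagging: Optional["PedigreeNode"] = None
    leading: Optional["PedigreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.lagging is None and self.leading is None

    def leaves(self) -> list:
        if self.is_leaf:
            return [self]
        return self.lagging.leaves() + self.leading.leaves()

    def to_dict(self) -> dict:
        d: dict = {"state": self.state.label}
        if not self.is_leaf:
            d["lagging"] = self.lagging.to_dict()
            d["leading"] = self.leading.to_dict()
        return d


def _bernoulli(p: float, rng: Optional[np.random.Generator]) -> bool:
    """Draw a coin; without an rng only forced (0/1) probabilities are legal."""
    if rng is None:
        if p not in (0.0, 1.0):
            raise ValueError(
                f"deterministic mode requires probability 0 or 1, got {p}; "
                "pass an rng/seed for stochastic divisions"
            )
        return bool(p)
    return rng.random() < p


def divide(
    cell: CellState,
    config: RegionConfig,
    params: ChoiceParams,
    rng: Optional[np.random.Generator] = None,
):
    """One division: returns ``(lagging_daughter, leading_daughter)``.

    ``rng=None`` selects deterministic mode, valid only when beta, s_eff
    and the donor draw are all forced to 0 or 1.  With
    ``lethal_on_failure`` set, a failed attempt returns ``None`` for the
    leading daughter.
    """
    beta = params.imprint_efficiency
    lagging = CellState(cell.allele, imprinted=_bernoulli(beta, rng))
    if not cell.imprinted:
        return lagging, CellState(cell.allele, imprinted=False)
    if _bernoulli(params.s_eff(config), rng):
        dist = donor_distribution_for(cell.allele, config, params)
        donor = config.mat2 if _bernoulli(dist.p_mat2, rng) else config.mat3
        return lagging, CellState(donor.content, imprinted=False)
    if params.lethal_on_failure:
        return lagging, None
    return lagging, CellState(cell.allele, imprinted=False)


def enumerate_pedigree(
    founder: CellState,
    depth: int,
    config: RegionConfig,
    params: ChoiceParams,
    seed: Optional[int] = None,
) -> PedigreeNode:
    """Full binary pedigree of ``depth`` generations from ``founder``.

    ``seed=None`` requires deterministic (0/1-forced) parameters.
    """
    if depth < 0:
        raise ValueError("depth must be nonnegative")
    if depth > MAX_PEDIGREE_DEPTH:
        raise ValueError(
            f"depth {depth} exceeds the pedigree guard ({MAX_PEDIGREE_DEPTH}); "
            "use simulate_culture for large populations"
        )
    rng = None if seed is None else np.random.default_rng(seed)

    def grow(state: CellState, remaining: int) -> PedigreeNode:
        node = PedigreeNode(state)
        if remaining == 0:
            return node
        lag, lead = divide(state, config, params, rng)
        node.lagging = grow(lag, remaining - 1)
        if lead is None:  # lethal failure truncates the branch
            node.leading = PedigreeNode(CellState(state.allele, False))
        else:
            node.leading = grow(lead, remaining - 1)
        return node

    return grow(founder, depth)


def count_switched_granddaughters(
    founder: CellState,
    config: RegionConfig,
    params: ChoiceParams,
    seed: Optional[int] = None,
) -> int:
    """Number of the four depth-2 descendants whose allele differs from the founder's."""
    tree = enumerate_pedigree(founder, 2, config, params, seed=seed)
    return sum(leaf.state.allele is not founder.allele for leaf in tree.leaves())


@dataclass
class Trajectory:
    """Per-generation counts of the four cell states in one culture."""

    counts: pd.DataFrame  # columns: generation, Pu, Ps, Mu, Ms, fraction_P
    seed: Optional[int] = None
    provenance: dict = field(default_factory=dict)

    @property
    def generations(self) -> int:
        return int(self.counts["generation"].iloc[-1])

    @property
    def fraction_P(self) -> pd.Series:
        return self.counts["fraction_P"]

    @property
    def final_fraction_P(self) -> float:
        return float(self.counts["fraction_P"].iloc[-1])

    def final_counts(self) -> np.ndarray:
        return self.counts.iloc[-1][list(STATE_ORDER)].to_numpy(dtype=np.int64)

    def to_csv(self, path_or_buf=None):
        return self.counts.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "Trajectory":
        df = pd.read_csv(path_or_buf)
        missing = {"generation", *STATE_ORDER} - set(df.columns)
        if missing:
            raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
        if "fraction_P" not in df.columns:
            df["fraction_P"] = (df["Pu"] + df["Ps"]) / df[list(STATE_ORDER)].sum(axis=1)
        return cls(counts=df)


def _finalize_trajectory(rows, seed, provenance) -> Trajectory:
    df = pd.DataFrame(rows, columns=["generation", *STATE_ORDER])
    total = df[list(STATE_ORDER)].sum(axis=1)
    df["fraction_P"] = (df["Pu"] + df["Ps"]) / total.where(total > 0, other=np.nan)
    return Trajectory(counts=df, seed=seed, provenance=provenance)


def simulate_culture(
    founder: Union[CellState, str],
    config: RegionConfig,
    params: ChoiceParams,
    generations: int,
    capacity: int = 10_000,
    seed: Optional[int] = None,
) -> Trajectory:
    """Grow a culture from a single founder under synchronous divisions.

    Every generation each cell divides (population exactly doubles unless
    ``lethal_on_failure`` removes failed leading daughters); if the
    population exceeds ``capacity`` it is subsampled uniformly without
    replacement back to ``capacity``.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if capacity < 100:
        raise ValueError("capacity must be >= 100")
    if isinstance(founder, str):
        founder = CellState.from_label(founder)
    rng = np.random.default_rng(seed)

    beta = params.imprint_efficiency
    s_eff = params.s_eff(config)
    h = {a: heterologous_fraction(a, config, params) for a in Allele}

    # state vector n = [Pu, Ps, Mu, Ms]
    n = np.zeros(4, dtype=np.int64)
    n[STATE_ORDER.index(founder.label)] = 1
    rows = [(0, *n)]

    for gen in range(1, generations + 1):
        nPu, nPs, nMu, nMs = (int(x) for x in n)
        new = np.zeros(4, dtype=np.int64)

        # lagging daughters: parental allele, imprinted w.p. beta
        for allele_count, iu, is_ in ((nPu + nPs, 0, 1), (nMu + nMs, 2, 3)):
            imprinted = rng.binomial(allele_count, beta)
            new[is_] += imprinted
            new[iu] += allele_count - imprinted
        # leading daughters of unimprinted parents: unchanged, unimprinted
        new[0] += nPu
        new[2] += nMu
        # leading daughters of imprinted parents
        for count, allele, iu_self, iu_other in ((nPs, Allele.P, 0, 2), (nMs, Allele.M, 2, 0)):
            if count == 0:
                continue
            p_switch = s_eff * h[allele]
            p_futile = s_eff * (1.0 - h[allele])
            switched, futile, failed = rng.multinomial(
                count, [p_switch, p_futile, 1.0 - p_switch - p_futile]
            )
            new[iu_other] += switched
            new[iu_self] += futile
            if not params.lethal_on_failure:
                new[iu_self] += failed

        if new.sum() > capacity:
            new = rng.multivariate_hypergeometric(new, capacity).astype(np.int64)
        n = new
        rows.append((gen, *n))
        if n.sum() == 0:  # possible only with lethal_on_failure
            break

    provenance = {
        "config": config.to_json(),
        "params": params.to_json(),
        "founder": founder.label,
        "capacity": capacity,
    }
    return _finalize_trajectory(rows, seed, provenance)


def imprinted_fraction(trajectory: Trajectory, burn_in: int = 0) -> float:
    """Mean fraction of imprinted (switchable) cells over generations > burn_in."""
    df = trajectory.counts
    post = df[df["generation"] > burn_in]
    if post.empty:
        raise ValueError("trajectory has no generations beyond the burn-in")
    total = post[list(STATE_ORDER)].sum(axis=1)
    return float(((post["Ps"] + post["Ms"]) / total).mean())


def plot_trajectory(trajectory: Trajectory, ax=None):
    """Plot P/(P+M) against generation (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(trajectory.counts["generation"], trajectory.counts["fraction_P"])
    ax.set_xlabel("generation")
    ax.set_ylabel("P / (P + M)")
    ax.set_ylim(0, 1)
    return ax
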