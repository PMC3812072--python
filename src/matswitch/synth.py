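"""Synthetic replicate-culture observations.

Emulates the three statistical readouts used to phenotype switching
strains, without any wet-lab data:

* **microscopy** — per-culture cell-type counts from a dual fluorescent
  reporter; each replicate's P-cell count is Binomial(n_cells, f_true).
* **southern** — per-culture band-intensity pairs from a blot probing
  the *mat1* content; each intensity carries independent multiplicative
  lognormal noise (default CV 0.15, an invented measurement-error scale:
  none is reported for the original quantifications), so the ratio
  estimator I_P/(I_P+I_M) is median-unbiased for f_true.
* **variegated cultures** — low-switching genotypes (RPC loss) founded by
  single cells of random type; founder effects produce culture-to-culture
  bimodality (dispersion far above binomial), the hallmark of iodine
  staining at colony junctions.

Defaults of nine replicates and 500 counted cells mirror the
nine-independent-culture panels and microscopy tallies of the study
design being emulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .choice import ChoiceParams
from .lineage import CellState, simulate_culture
from .region import Allele, RegionConfig

__all__ = [
    "ObservationSet",
    "SchemaError",
    "sample_microscopy",
    "sample_southern",
    "sample_variegated_cultures",
    "write_observations",
    "read_observations",
]

CSV_COLUMNS = ["strain", "method", "replicate", "n_cells", "x_P", "intensity_P", "intensity_M"]
METHODS = ("microscopy", "southern")


class SchemaError(ValueError):
    """Malformed observation table or CSV file."""


@dataclass
class ObservationSet:
    """Replicate per-culture measurements for one strain.

    ``data`` holds one row per replicate culture with columns
    ``replicate`` plus either (``n_cells``, ``x_P``) for microscopy or
    (``intensity_P``, ``intensity_M``) for southern.  ``provenance``
    records the true generating parameters (synthetic files only).
    """

    strain: str
    method: str
    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise SchemaError(f"unknown method {self.method!r}; expected one of {METHODS}")
        df = self.data
        if self.method == "microscopy":
            for col in ("n_cells", "x_P"):
                if col not in df.columns:
                    raise SchemaError(f"microscopy observations require column {col!r}")
            bad = df.index[(df["x_P"] < 0) | (df["x_P"] > df["n_cells"])]
            if len(bad):
                raise SchemaError(f"x_P outside [0, n_cells] in replicate row {bad[0]}")
        else:
            for col in ("intensity_P", "intensity_M"):
                if col not in df.columns:
                    raise SchemaError(f"southern observations require column {col!r}")
            bad = df.index[(df["intensity_P"] <= 0) | (df["intensity_M"] <= 0)]
            if len(bad):
                raise SchemaError(f"non-positive intensity in replicate row {bad[0]}")

    @property
    def n_replicates(self) -> int:
        return len(self.data)

    def fractions(self) -> np.ndarray:
        """Per-replicate P fractions."""
        if self.method == "microscopy":
            return (self.data["x_P"] / self.data["n_cells"]).to_numpy(dtype=float)
        ip = self.data["intensity_P"].to_numpy(dtype=float)
        im = self.data["intensity_M"].to_numpy(dtype=float)
        return ip / (ip + im)


def sample_microscopy(
    f_true: float,
    n_rep: int = 9,
    n_cells: int = 500,
    seed: Optional[int] = None,
    strain: str = "synthetic",
) -> ObservationSet:
    """Independent Binomial(n_cells, f_true) P-cell counts per replicate."""
    if not 0.0 <= f_true <= 1.0:
        raise ValueError(f"f_true={f_true} outside [0, 1]")
    if n_rep < 1 or n_cells < 1:
        raise ValueError("n_rep and n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.binomial(n_cells, f_true, size=n_rep)
    df = pd.DataFrame(
        {"replicate": np.arange(1, n_rep + 1), "n_cells": n_cells, "x_P": x}
    )
    return ObservationSet(
        strain=strain,
        method="microscopy",
        data=df,
        provenance={"f_true": f_true, "n_cells": n_cells, "seed": seed},
    )


def sample_southern(
    f_true: float,
    n_rep: int = 9,
    noise_cv: float = 0.15,
    seed: Optional[int] = None,
    strain: str = "synthetic",
    intensity_floor: float = 1e-6,
) -> ObservationSet:
    """Band-intensity pairs with multiplicative lognormal noise.

    ``intensity_P = max(f_true, floor) * exp(eps1)`` and likewise for M,
    with eps ~ Normal(0, sigma) and sigma chosen so each intensity's
    coefficient of variation equals ``noise_cv``.
    """
    if noise_cv <= 0:
        raise ValueError("noise_cv must be positive")
    if not 0.0 <= f_true <= 1.0:
        raise ValueError(f"f_true={f_true} outside [0, 1]")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    sigma = np.sqrt(np.log1p(noise_cv**2))
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, sigma, size=(n_rep, 2))
    ip = max(f_true, intensity_floor) * np.exp(eps[:, 0])
    im = max(1.0 - f_true, intensity_floor) * np.exp(eps[:, 1])
    df = pd.DataFrame(
        {"replicate": np.arange(1, n_rep + 1), "intensity_P": ip, "intensity_M": im}
    )
    return ObservationSet(
        strain=strain,
        method="southern",
        data=df,
        provenance={"f_true": f_true, "noise_cv": noise_cv, "seed": seed},
    )


def sample_variegated_cultures(
    config: RegionConfig,
    params: ChoiceParams,
    n_rep: int = 9,
    generations: int = 30,
    capacity: int = 10_000,
    n_cells: int = 500,
    seed: Optional[int] = None,
    strain: str = "synthetic",
) -> ObservationSet:
    """Replicate cultures founded by single cells of random type.

    Each replicate simulates a growing culture (fair-coin founder,
    unimprinted) and then counts ``n_cells`` cells sampled without
    replacement at the final generation, as microscopy would.  With a
    low-switching genotype the replicate fractions are bimodal near 0
    and 1 (founder effects); with efficient switching they cluster at
    the steady state.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_rep + 1):
        founder = CellState(Allele.P if rng.random() < 0.5 else Allele.M, imprinted=False)
        traj = simulate_culture(
            founder, config, params, generations=generations, capacity=capacity,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        pu, ps, mu, ms = (int(v) for v in traj.final_counts())
        n_p, total = pu + ps, pu + ps + mu + ms
        k = min(n_cells, total)
        x = int(rng.hypergeometric(n_p, total - n_p, k)) if k > 0 else 0
        rows.append((rep, k, x))
    df = pd.DataFrame(rows, columns=["replicate", "n_cells", "x_P"])
    return ObservationSet(
        strain=strain,
        method="microscopy",
        data=df,
        provenance={
            "generator": "variegated_cultures",
            "config": config.to_json(),
            "params": params.to_json(),
            "generations": generations,
            "capacity": capacity,
            "seed": seed,
        },
    )


def write_observations(obs: ObservationSet, path) -> None:
    """Lossless CSV with a commented header carrying method and provenance."""
    df = obs.data.copy()
    df.insert(0, "strain", obs.strain)
    df.insert(1, "method", obs.method)
    for col in CSV_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    df = df[CSV_COLUMNS]
    with open(path, "w") as fh:
        fh.write(f"# matswitch observations v1\n")
        fh.write(f"# method: {obs.method}\n")
        fh.write(f"# provenance: {json.dumps(obs.provenance, sort_keys=True)}\n")
        df.to_csv(fh, index=False)


def read_observations(path) -> ObservationSet:
    """Parse a CSV written by :func:`write_observations` (or hand-made)."""
    provenance: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body_start = i + 1
            stripped = line.lstrip("#").strip()
            if stripped.startswith("provenance:"):
                try:
                    provenance = json.loads(stripped.split(":", 1)[1].strip())
                except json.JSONDecodeError as exc:
                    raise SchemaError(f"unparseable provenance header: {exc}") from None
        else:
            break
    from io import StringIO

    try:
        df = pd.read_csv(StringIO("".join(lines[body_start:])))
    except Exception as exc:
        raise SchemaError(f"unparseable observation CSV: {exc}") from None
    for col in ("strain", "method", "replicate"):
        if col not in df.columns:
            raise SchemaError(f"observation CSV missing required column {col!r}")
    methods = df["method"].dropna().unique()
    strains = df["strain"].dropna().unique()
    if len(methods) != 1 or len(strains) != 1:
        raise SchemaError("observation CSV must contain a single strain and method")
    method, strain = str(methods[0]), str(strains[0])
    if method == "microscopy":
        for col in ("n_cells", "x_P"):
            if col not in df.columns or df[col].isna().any():
                raise SchemaError(f"microscopy CSV missing values in column {col!r}")
        data = df[["replicate", "n_cells", "x_P"]].astype(
            {"replicate": int, "n_cells": int, "x_P": int}
        )
    elif method == "southern":
        for col in ("intensity_P", "intensity_M"):
            if col not in df.columns or df[col].isna().any():
                raise SchemaError(f"southern CSV missing values in column {col!r}")
        data = df[["replicate", "intensity_P", "intensity_M"]].astype(
            {"replicate": int, "intensity_P": float, "intensity_M": float}
        )
    else:
        raise SchemaError(f"unknown method {method!r} in observation CSV")
    return ObservationSet(
        strain=strain, method=method, data=data.reset_index(drop=True), provenance=provenance
    )
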