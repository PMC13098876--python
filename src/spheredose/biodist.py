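"""Ex-vivo biodistribution handling.

Reads per-organ %IA/g tables (percent injected activity per gram, already
decay-corrected to injection time by the gamma-counting workflow),
aggregates replicates into mean ± SEM uptake series, converts Bi-213
gamma counts to Ac-225 activity under secular equilibrium, and scales
reference mouse organ masses to a subject's body mass.

Input convention: %IA/g values are decay-corrected to injection time.
Physical decay is re-applied downstream when the time-activity curve is
built — supplying non-corrected values would double-count decay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .nuclides import DecayChainSpec, NuclideRecord, build_chain, get_nuclide

__all__ = [
    "BiodistSample",
    "UptakeSeries",
    "OrganMassModel",
    "read_biodistribution",
    "decay_correct",
    "ac225_from_bi213",
    "aggregate",
    "load_organ_mass_table",
    "allometric_organ_mass",
]

REQUIRED_COLUMNS = ("organ", "time_h", "pia_per_g", "replicate")


@dataclass(frozen=True)
class BiodistSample:
    """One decay-corrected %IA/g measurement for one organ and animal."""

    organ: str
    t_h: float
    pia_per_g: float
    replicate: str

    def __post_init__(self):
        if not self.organ:
            raise ValueError("organ name must be non-empty")
        if self.t_h < 0:
            raise ValueError(f"t_h must be >= 0, got {self.t_h}")
        if self.pia_per_g < 0:
            raise ValueError(f"pia_per_g must be >= 0, got {self.pia_per_g}")


@dataclass(frozen=True)
class UptakeSeries:
    """Replicate-aggregated uptake for one organ: mean ± SEM per timepoint."""

    organ: str
    times_h: tuple[float, ...]
    mean_pia_per_g: tuple[float, ...]
    sem: tuple[float, ...]
    n: tuple[int, ...]

    def __post_init__(self):
        if not all(b > a for a, b in zip(self.times_h, self.times_h[1:])):
            raise ValueError("times must be strictly increasing")
        lengths = {len(self.times_h), len(self.mean_pia_per_g), len(self.sem), len(self.n)}
        if len(lengths) != 1:
            raise ValueError("field lengths differ")
        for k, s in zip(self.n, self.sem):
            if k < 1:
                raise ValueError("n must be >= 1")
            if k == 1 and s != 0:
                raise ValueError("sem must be 0 for single replicates")


@dataclass(frozen=True)
class OrganMassModel:
    """Reference organ mass and the body mass it was measured at."""

    organ: str
    reference_mass_g: float
    reference_body_mass_g: float

    def __post_init__(self):
        if self.reference_mass_g <= 0 or self.reference_body_mass_g <= 0:
            raise ValueError("masses must be > 0")

    def scaled_mass_g(self, body_mass_g: float) -> float:
        if body_mass_g <= 0:
            raise ValueError("body mass must be > 0")
        return self.reference_mass_g * body_mass_g / self.reference_body_mass_g


class BiodistSchemaError(ValueError):
    """Malformed biodistribution CSV (missing column or bad row)."""


def read_biodistribution(path: str | Path) -> list[BiodistSample]:
    """Read and validate a biodistribution CSV.

    Expected header: ``organ,time_h,pia_per_g,replicate`` (extra columns
    pass through unused).  Rows with blank organs or negative values are
    rejected with their row numbers.
    """
    df = pd.read_csv(path, dtype={"replicate": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise BiodistSchemaError(f"{path}: missing required column(s) {missing}")

    samples: list[BiodistSample] = []
    bad_rows: list[str] = []
    for idx, row in df.iterrows():
        lineno = idx + 2  # header is line 1
        try:
            t_h = float(row["time_h"])
            pia = float(row["pia_per_g"])
            organ = str(row["organ"]).strip()
            if organ in ("", "nan"):
                raise ValueError("blank organ")
            samples.append(
                BiodistSample(organ=organ, t_h=t_h, pia_per_g=pia, replicate=str(row["replicate"]))
            )
        except (TypeError, ValueError) as exc:
            bad_rows.append(f"line {lineno}: {exc}")
    if bad_rows:
        raise BiodistSchemaError(f"{path}: invalid rows:\n" + "\n".join(bad_rows))
    return samples


def write_biodistribution(samples: list[BiodistSample], path: str | Path) -> None:
    """Write samples in the same CSV dialect :func:`read_biodistribution` reads."""
    df = pd.DataFrame(
        {
            "organ": [s.organ for s in samples],
            "time_h": [s.t_h for s in samples],
            "pia_per_g": [s.pia_per_g for s in samples],
            "replicate": [s.replicate for s in samples],
        }
    )
    df.to_csv(path, index=False)


def decay_correct(count_rate: float, elapsed_s: float, nuclide: NuclideRecord) -> float:
    """Correct a count rate back to a reference time ``elapsed_s`` earlier.

    Multiplies by exp(+λ·elapsed): measuring one half-life after the
    reference doubles the corrected rate.
    """
    if elapsed_s < 0:
        raise ValueError("elapsed_s must be >= 0 (reference precedes measurement)")
    return count_rate * math.exp(nuclide.decay_constant * elapsed_s)


def ac225_from_bi213(
    bi213_activity_bq: float,
    wait_time_s: float,
    min_halflives: float = 10.0,
    chain: DecayChainSpec | None = None,
) -> float:
    """Infer Ac-225 activity from a Bi-213 measurement at secular equilibrium.

    Samples stored long enough (``min_halflives`` Bi-213 half-lives,
    default 10) reach secular equilibrium, where A(Bi-213) =
    A(Ac-225) × cumulative branching (≈ 1 for the Ac-225 chain).
    """
    bi213 = get_nuclide("Bi-213")
    required_s = min_halflives * bi213.half_life_s
    if wait_time_s < required_s:
        raise ValueError(
            f"equilibrium not reached: waited {wait_time_s:.0f} s, "
            f"need >= {required_s:.0f} s ({min_halflives:g} Bi-213 half-lives)"
        )
    if chain is None:
        chain = build_chain("Ac-225")
    branching = chain.cumulative_branching("Bi-213")
    return bi213_activity_bq / branching


def aggregate(samples: list[BiodistSample]) -> dict[str, UptakeSeries]:
    """Mean and SEM of %IA/g per (organ, timepoint), keyed by organ.

    Duplicate replicate ids at one timepoint are treated as distinct
    samples (merged files are averaged, never dropped).
    """
    if not samples:
        return {}
    df = pd.DataFrame(
        {"organ": [s.organ for s in samples], "t": [s.t_h for s in samples], "v": [s.pia_per_g for s in samples]}
    )
    out: dict[str, UptakeSeries] = {}
    for organ, grp in df.groupby("organ", sort=True):
        stats = (
            grp.groupby("t")["v"]
            .agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
            .sort_index()
        )
        sem = np.where(stats["n"] > 1, stats["sd"] / np.sqrt(stats["n"]), 0.0)
        out[organ] = UptakeSeries(
            organ=organ,
            times_h=tuple(float(t) for t in stats.index),
            mean_pia_per_g=tuple(float(m) for m in stats["mean"]),
            sem=tuple(float(s) for s in sem),
            n=tuple(int(k) for k in stats["n"]),
        )
    return out


def load_organ_mass_table(path: str | Path | None = None) -> dict[str, OrganMassModel]:
    """Load the reference mouse organ-mass table (package fixture by default)."""
    if path is None:
        with resources.files("spheredose.data").joinpath("mouse_organ_masses.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    return {
        r.organ: OrganMassModel(r.organ, float(r.reference_mass_g), float(r.reference_body_mass_g))
        for r in df.itertuples()
    }


def allometric_organ_mass(
    organ: str,
    body_mass_g: float,
    reference_table: dict[str, OrganMassModel] | None = None,
    exponent: float = 1.0,
) -> float:
    """Organ mass at a given body mass by proportional allometric scaling.

    mass = reference_mass × (body/reference_body)^exponent, exponent 1 by
    default.  Tumors are never in the reference table — tumor mass is
    always supplied directly by the caller.
    """
    if body_mass_g <= 0:
        raise ValueError("body_mass_g must be > 0")
    table = reference_table if reference_table is not None else load_organ_mass_table()
    if organ not in table:
        raise KeyError(
            f"unknown organ {organ!r}; known organs: {sorted(table)} "
            "(tumor masses are supplied by the caller, not scaled)"
        )
    ref = table[organ]
    return ref.reference_mass_g * (body_mass_g / ref.reference_body_mass_g) ** exponent
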