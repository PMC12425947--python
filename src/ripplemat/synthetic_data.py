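"""Seeded synthetic inputs: community tables and ripple geometry ensembles.

The community generator draws sample compositions from Dirichlet
distributions around packaged mean vectors that reproduce the relative
abundances observed at a shallow-water vent field: a storm-succession
time series (Arcobacter-dominated calm-sea white mat collapsing to a
Sulfurimonas- then Sulfurovum-dominated community) and a trough→crest
mat-colour gradient across a single sand ripple (Cyanobacteria rising,
Sulfurimonas falling).  Taxa not reported for a condition carry the
pooled 'other' remainder, preserving closure without inventing values.

All randomness flows from a single integer seed through one
numpy.random.Generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd

from .geometry import RippleGeometry

META_COLS = ("sample_id", "scenario", "condition", "position")

_STORM_MEANS = {
    "pre_storm": {"Arcobacter": 0.783, "Sulfurimonas": 0.163, "unclassified": 0.025},
    "day_plus_1": {"Sulfurimonas": 0.591, "Arcobacter": 0.344, "Cyanobacteria": 0.016},
    "day_plus_3": {"Sulfurovum": 0.362, "Sulfurimonas": 0.225,
                   "Campylobacteraceae": 0.220, "unclassified": 0.138,
                   "Arcobacter": 0.052},
}

_RIPPLE_MEANS = {
    "yellow": {"Cyanobacteria": 0.266, "Sulfurimonas": 0.353},
    "light_brown": {"Cyanobacteria": 0.260, "Sulfurimonas": 0.181},
    "brown": {"Cyanobacteria": 0.576, "Sulfurimonas": 0.081},
}

#: trough→crest ordinal of the mat-colour conditions
_RIPPLE_POSITIONS = {"yellow": 0, "light_brown": 1, "brown": 2}


@dataclass
class ScenarioSpec:
    """A set of per-condition mean compositions plus a Dirichlet noise level.

    concentration is the Dirichlet concentration (inverse noise): draws have
    mean equal to the mean vector and variance m_i(1-m_i)/(concentration+1).
    """

    name: str
    mean_vectors: dict  # condition -> {taxon: mean}
    concentration: float = 50.0
    n_replicates: int = 5
    seed: int = 0
    positions: dict = dfield(default_factory=dict)  # condition -> ordinal

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        closed = {}
        for cond, mv in self.mean_vectors.items():
            if any(v < 0 for v in mv.values()):
                raise ValueError(f"negative mean abundance in condition {cond!r}")
            total = float(sum(mv.values()))
            if total > 1.0 + 1e-9:
                raise ValueError(f"means of condition {cond!r} sum to {total} > 1")
            mv = dict(mv)
            mv["other"] = mv.get("other", 0.0) + max(0.0, 1.0 - total)
            closed[cond] = mv
        self.mean_vectors = closed

    @property
    def taxa(self) -> list[str]:
        names: list[str] = []
        for mv in self.mean_vectors.values():
            for t in mv:
                if t not in names:
                    names.append(t)
        return names


def builtin_scenario(name: str, concentration: float = 50.0,
                     n_replicates: int = 5, seed: int = 0) -> ScenarioSpec:
    """Packaged scenarios: 'storm_timeseries' or 'ripple_gradient'."""
    if name == "storm_timeseries":
        return ScenarioSpec(name=name, mean_vectors=_STORM_MEANS,
                            concentration=concentration,
                            n_replicates=n_replicates, seed=seed)
    if name == "ripple_gradient":
        return ScenarioSpec(name=name, mean_vectors=_RIPPLE_MEANS,
                            concentration=concentration,
                            n_replicates=n_replicates, seed=seed,
                            positions=dict(_RIPPLE_POSITIONS))
    raise ValueError(
        f"unknown scenario {name!r}; available: storm_timeseries, ripple_gradient"
    )


def generate_community_table(spec: ScenarioSpec) -> pd.DataFrame:
    """Sample×taxon relative-abundance table with metadata columns.

    Rows are Dirichlet(concentration × mean) draws per condition; rows sum
    to 1 exactly up to round-off.  Taxa with zero mean in a condition are
    exactly zero in its draws.  Deterministic for a fixed spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    taxa = spec.taxa
    rows = []
    for cond, mv in spec.mean_vectors.items():
        means = np.array([mv.get(t, 0.0) for t in taxa])
        pos = spec.positions.get(cond, np.nan)
        alive = means > 0
        alpha = spec.concentration * means[alive]
        for r in range(spec.n_replicates):
            draw = np.zeros(len(taxa))
            draw[alive] = rng.dirichlet(alpha)
            rows.append({"sample_id": f"{cond}_{r}", "scenario": spec.name,
                         "condition": cond, "position": pos,
                         **dict(zip(taxa, draw))})
    return pd.DataFrame(rows)


def generate_ripple_ensemble(
    n: int,
    wavelength_range: tuple[float, float] = (0.15, 0.20),
    height_fraction: float = 0.115,
    asymmetry: float = 0.5,
    bed_depth_m: float = 0.02,
    seed: int = 0,
) -> list[RippleGeometry]:
    """n ripple geometries with wavelengths uniform over the field-observed
    crest-to-crest range (default 15–20 cm) and height a fixed fraction of
    wavelength; seeded and reproducible."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = wavelength_range
    if not 0 < lo < hi:
        raise ValueError(f"invalid wavelength range ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    lam = rng.uniform(lo, hi, size=n)
    return [
        RippleGeometry(wavelength_m=float(w), height_m=float(height_fraction * w),
                       asymmetry=asymmetry, bed_depth_m=bed_depth_m)
        for w in lam
    ]


def write_table_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
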