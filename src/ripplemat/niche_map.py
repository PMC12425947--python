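"""Redox niche mapping along the ripple surface.

Maps steady O2/H2S exposure at the sediment–water interface to an ordered
set of mat classes (white < yellow < light_brown < brown, the oxygenation
axis observed on vent-field sand ripples: white in the reduced trough,
brown at the oxygenated crest) and quantifies agreement between a
predicted zonation and a community table with trough→crest sample
positions via sign-adjusted Spearman rank correlation of indicator taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import PorosityField
from .scalar_transport import ScalarField

MAT_CLASSES = ("white", "yellow", "light_brown", "brown")

#: indicator taxa and the expected sign of their trough→crest abundance trend:
#: Cyanobacteria (oxygenic phototrophs) increase toward the crest, the sulfur
#: oxidizer Sulfurimonas tracks the reduced fluids and decreases.
DEFAULT_INDICATOR_TAXA = {"Cyanobacteria": +1, "Sulfurimonas": -1}


@dataclass(frozen=True)
class NicheThresholds:
    """Two ascending cut points per scalar split exposures into tertile
    classes; class_map sends (O2 tertile, H2S tertile) to a mat class and
    must be monotone: more O2 never lowers the class, more H2S never
    raises it."""

    o2_levels: tuple[float, float]
    h2s_levels: tuple[float, float]
    class_map: dict = dfield(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("o2", self.o2_levels), ("h2s", self.h2s_levels)):
            if not lo < hi:
                raise ValueError(f"{name} cut points must ascend: got ({lo}, {hi})")
        if not self.class_map:
            object.__setattr__(self, "class_map", _default_class_map())
        self._check_monotone()

    def _check_monotone(self) -> None:
        rank = {c: i for i, c in enumerate(MAT_CLASSES)}
        for to2 in range(3):
            for th in range(3):
                here = rank[self.class_map[(to2, th)]]
                if to2 < 2 and rank[self.class_map[(to2 + 1, th)]] < here:
                    raise ValueError("class_map not monotone in O2 tertile")
                if th < 2 and rank[self.class_map[(to2, th + 1)]] > here:
                    raise ValueError("class_map not monotone in H2S tertile")


def _default_class_map() -> dict:
    """score = O2 tertile + (2 - H2S tertile) in 0..4 → four ordered classes;
    (low O2, high H2S) → white, (high O2, low H2S) → brown."""
    out = {}
    for to2 in range(3):
        for th in range(3):
            score = to2 + (2 - th)
            cls = ("white", "white", "yellow", "light_brown", "brown")[score]
            out[(to2, th)] = cls
    return out


def tertile_thresholds(o2: np.ndarray, h2s: np.ndarray) -> NicheThresholds:
    """Scale-free thresholds from a run's own exposure distribution."""
    o = tuple(np.quantile(np.asarray(o2, float), [1 / 3, 2 / 3]))
    h = tuple(np.quantile(np.asarray(h2s, float), [1 / 3, 2 / 3]))
    # degenerate (constant-field) distributions: widen symbolically
    if o[0] >= o[1]:
        o = (o[0] - 0.5, o[0] + 0.5)
    if h[0] >= h[1]:
        h = (h[0] - 0.5, h[0] + 0.5)
    return NicheThresholds(o2_levels=o, h2s_levels=h)


def _tertile(v: float, levels: tuple[float, float]) -> int:
    return int(v > levels[0]) + int(v > levels[1])


def classify_mat(o2: float, h2s: float, thresholds: NicheThresholds) -> str:
    """Mat class for one surface exposure pair."""
    if not (np.isfinite(o2) and np.isfinite(h2s)):
        raise ValueError(f"non-finite exposure: o2={o2}, h2s={h2s}")
    return thresholds.class_map[
        (_tertile(o2, thresholds.o2_levels), _tertile(h2s, thresholds.h2s_levels))
    ]


@dataclass
class ZonationProfile:
    columns: np.ndarray  # interface column x-indices
    positions: np.ndarray  # ordinal: 0 = trough ... max = crest
    classes: list[str]
    exposures: pd.DataFrame  # per column: O2, H2S, T (when present)

    def to_frame(self) -> pd.DataFrame:
        df = self.exposures.copy()
        df.insert(0, "x", self.columns)
        df.insert(1, "position", self.positions)
        df["mat_class"] = self.classes
        return df


def surface_exposures(
    scalars: list[ScalarField], geometry: PorosityField
) -> pd.DataFrame:
    """Scalar values at the first water cell above the bed, per column —
    the exposure a surface-attached mat experiences."""
    ny = scalars[0].C.shape[0] if scalars else 0
    cols = np.arange(geometry.shape[1])
    first_fluid = np.clip(geometry.bed_profile + 1, 0, ny - 1)
    data = {s.name: s.C[first_fluid, cols] for s in scalars}
    return pd.DataFrame(data)


def zonation_profile(
    scalars: list[ScalarField],
    geometry: PorosityField,
    thresholds: NicheThresholds | None = None,
) -> ZonationProfile:
    """Classify every interface column, ordered trough→crest by bed height.

    With thresholds=None, tertiles of the run's own O2/H2S exposure
    distributions are used (scale-free default).
    """
    expo = surface_exposures(scalars, geometry)
    if "O2" not in expo or "H2S" not in expo:
        raise ValueError("zonation needs scalars named 'O2' and 'H2S'")
    if thresholds is None:
        thresholds = tertile_thresholds(expo["O2"].to_numpy(), expo["H2S"].to_numpy())
    bp = geometry.bed_profile
    positions = (bp - bp.min()).astype(int)
    classes = [
        classify_mat(o, h, thresholds)
        for o, h in zip(expo["O2"], expo["H2S"])
    ]
    return ZonationProfile(columns=np.arange(len(bp)), positions=positions,
                           classes=classes, exposures=expo)


def zonation_agreement(
    table: pd.DataFrame,
    indicator_taxa: dict | None = None,
    position_col: str = "position",
) -> float:
    """Sign-adjusted mean Spearman correlation between sample position
    (trough→crest ordinal) and indicator-taxon relative abundance.

    +1 means every indicator follows its expected gradient (phototrophs up,
    sulfur oxidizers down toward the crest); -1 a perfect reversal.  Ties
    get midranks.  Taxa absent from the table are skipped; at least one
    must be present.
    """
    if indicator_taxa is None:
        indicator_taxa = DEFAULT_INDICATOR_TAXA
    if position_col not in table.columns:
        raise ValueError(f"table lacks a {position_col!r} column")
    pos = table[position_col].to_numpy(dtype=float)
    if len(pos) < 3:
        raise ValueError("need at least 3 positioned samples for a rank correlation")
    vals = []
    for taxon, sign in indicator_taxa.items():
        if taxon not in table.columns:
            continue
        ab = table[taxon].to_numpy(dtype=float)
        if np.all(ab == ab[0]) or np.all(pos == pos[0]):
            continue  # correlation undefined on a constant vector
        rho = stats.spearmanr(pos, ab).statistic
        vals.append(np.sign(sign) * rho)
    if not vals:
        raise ValueError("no usable indicator taxa found in table")
    return float(np.mean(vals))
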