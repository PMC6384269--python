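"""Region-level bookkeeping: the 43-region atlas, regional mean
extraction, volume normalization, percent volume change, and the
percent-decline summary of the longitudinal rate-constant tables.

The bundled atlas merges the automated-anatomical-labelling parcellation
into 43 named regions grouped by lobe (15 frontal, 9 temporal, 6
parietal, 6 occipital, 4 insula/cingulate, 3 central).  Two frontal
regions share the printed label "Orbital superior frontal" (they are
distinct subdivisions); the fixture keeps both with a disambiguating
suffix.  The bundled reference tables hold group-level visit means (T0,
T2, T4), pooled SEM, mixed-model fixed-effect slope and p-value for each
region, one table per tracer.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "RegionAtlas",
    "load_atlas",
    "load_reference_table",
    "extract_regional_means",
    "normalize_volume",
    "pbvc",
    "percent_decline_summary",
    "DeclineSummary",
]

LOBE_GROUPS = ("frontal", "temporal", "parietal", "occipital", "insula_cingulate", "central")


@dataclass(frozen=True)
class Region:
    id: int
    name: str
    lobe_group: str


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered collection of named brain regions."""

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("region ids must be unique")
        bad = {r.lobe_group for r in self.regions} - set(LOBE_GROUPS)
        if bad:
            raise ValueError(f"unknown lobe groups: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.regions)

    def name_of(self, region_id: int) -> str:
        for r in self.regions:
            if r.id == region_id:
                return r.name
        raise KeyError(region_id)

    def id_of(self, name: str) -> int:
        for r in self.regions:
            if r.name == name:
                return r.id
        raise KeyError(name)

    @property
    def ids(self) -> list[int]:
        return [r.id for r in self.regions]

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "name": self.names, "lobe_group": [r.lobe_group for r in self.regions]}
        )


def _data_path(fname: str):
    return resources.files("brainfuel").joinpath("data", fname)


def load_atlas() -> RegionAtlas:
    """The bundled 43-region atlas."""
    df = pd.read_csv(_data_path("aal43_atlas.tsv"), sep="\t")
    return RegionAtlas(tuple(Region(int(r.id), r.name, r.lobe_group) for r in df.itertuples()))


def load_reference_table(tracer: str = "glucose") -> pd.DataFrame:
    """Bundled longitudinal regional rate-constant summary for a tracer.

    Columns: region, T0, T2, T4, SEM, fixed_effect (annual slope,
    min^-1/yr), p_value.  One row per atlas region.
    """
    fname = {"glucose": "kglc_longitudinal.tsv", "acac": "kacac_longitudinal.tsv"}.get(tracer)
    if fname is None:
        raise ValueError(f"unknown tracer {tracer!r}")
    return pd.read_csv(_data_path(fname), sep="\t")


def extract_regional_means(image: np.ndarray, label_volume: np.ndarray, atlas: RegionAtlas | None = None) -> pd.DataFrame:
    """Arithmetic mean of ``image`` over each labelled region.

    NaN voxels (e.g. flagged missing by partial-volume correction) are
    ignored.  Regions present in the atlas but empty in the label volume
    (or all-NaN) get a flagged row with a NaN mean, never a silent drop.
    """
    image = np.asarray(image, dtype=float)
    label_volume = np.asarray(label_volume)
    if image.shape != label_volume.shape:
        raise ValueError("image grid does not match label volume")
    ids = atlas.ids if atlas is not None else [int(i) for i in np.unique(label_volume) if i != 0]
    rows = []
    for rid in ids:
        mask = label_volume == rid
        vals = image[mask]
        vals = vals[np.isfinite(vals)]
        n = int(vals.size)
        rows.append(
            dict(
                region_id=rid,
                region=atlas.name_of(rid) if atlas is not None else str(rid),
                mean=float(vals.mean()) if n else np.nan,
                n_voxels=n,
                flagged=n == 0,
            )
        )
    return pd.DataFrame(rows)


def normalize_volume(region_volume: float, icv: float) -> float:
    """Region volume as a fraction of intracranial volume."""
    if icv <= 0:
        raise ValueError("intracranial volume must be positive")
    return region_volume / icv


def pbvc(volume_t0: float, volume_t1: float) -> float:
    """Percent brain volume change between two timepoints.

    Atrophy appears as a negative value; its magnitude is -PBVC.
    """
    if volume_t0 <= 0:
        raise ValueError("baseline volume must be positive")
    return 100.0 * (volume_t1 - volume_t0) / volume_t0


@dataclass(frozen=True)
class DeclineSummary:
    """Per-region 4-year percent declines among significant regions.

    ``min_decline_pct``/``max_decline_pct`` are rounded to the nearest
    integer percent (half away from zero); the annualized range divides
    by the follow-up span and rounds to one decimal.
    """

    per_region: pd.DataFrame
    min_decline_pct: int
    max_decline_pct: int
    annualized_min_pct: float
    annualized_max_pct: float


def _round_half_away(x: float, decimals: int = 0) -> float:
    scale = 10.0**decimals
    return np.sign(x) * np.floor(np.abs(x) * scale + 0.5) / scale


def percent_decline_summary(
    table: pd.DataFrame,
    alpha: float = 0.05,
    followup_years: float = 4.0,
) -> DeclineSummary:
    """Summarize the longitudinal decline of regions with p <= alpha.

    For each significant region the decline is 100*(T0 - T4)/T0 over the
    follow-up; the summary reports the per-region values together with
    the rounded (min, max) percent range and the annualized range.
    """
    required = {"region", "T0", "T4", "p_value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if table[["T0", "T4", "p_value"]].isna().any().any():
        raise ValueError("reference table has missing cells")
    sig = table[table["p_value"] <= alpha].copy()
    if sig.empty:
        raise ValueError(f"no regions significant at alpha={alpha}")
    sig["decline_pct"] = 100.0 * (sig["T0"] - sig["T4"]) / sig["T0"]
    sig["annual_decline_pct"] = sig["decline_pct"] / followup_years
    return DeclineSummary(
        per_region=sig[["region", "T0", "T4", "p_value", "decline_pct", "annual_decline_pct"]].reset_index(drop=True),
        min_decline_pct=int(_round_half_away(sig["decline_pct"].min())),
        max_decline_pct=int(_round_half_away(sig["decline_pct"].max())),
        annualized_min_pct=float(_round_half_away(sig["annual_decline_pct"].min(), 1)),
        annualized_max_pct=float(_round_half_away(sig["annual_decline_pct"].max(), 1)),
    )
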