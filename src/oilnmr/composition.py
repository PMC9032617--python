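"""Fatty-acid composition and viscosity utilities.

The package ships a reference table of GC-FID fatty-acid percentages (plus
rheometer viscosity) for four commercial avocado-oil brands and one brand
each of soybean, corn and rapeseed oil. These compositions explain the
relaxometry differences the classifier exploits: avocado and rapeseed oil
are MUFA-dominated while soybean and corn oil are PUFA-dominated, and
viscosity tracks MUFA content positively and PUFA content negatively.

``ND`` (not detected) entries are treated as exactly zero. Printed category
rows in such tables occasionally disagree with the sum of their components
(the bundled corn-oil MUFA row is one such case); this module always reports
sums recomputed from the individual acids and flags discrepancies instead of
silently trusting or correcting the printed rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .classification import PrincipalComponents, UnitVarianceScaler

__all__ = [
    "FattyAcidProfile",
    "SFA_ACIDS",
    "MUFA_ACIDS",
    "PUFA_ACIDS",
    "load_reference_profiles",
    "category_sums",
    "unsaturation_ordering",
    "viscosity_correlation",
    "composition_pca",
    "compare_printed_categories",
]

#: Saturated acids: no double bond.
SFA_ACIDS = frozenset({"C14:0", "C16:0", "C18:0", "C20:0", "C22:0", "C24:0"})
#: Monounsaturated acids: exactly one double bond.
MUFA_ACIDS = frozenset({"C16:1", "C18:1n9c", "C20:1", "C24:1n9"})
#: Polyunsaturated acids: two or more double bonds.
PUFA_ACIDS = frozenset({"C18:2n6c", "C18:3n6", "C18:3n3", "C20:2", "C20:3n3", "C20:5n3"})

_KNOWN = SFA_ACIDS | MUFA_ACIDS | PUFA_ACIDS


@dataclass(frozen=True)
class FattyAcidProfile:
    """Relative fatty-acid percentages and viscosity of one oil."""

    name: str
    percentages: dict[str, float]
    viscosity: float
    origin: str = ""
    oil_type: str = ""

    def __post_init__(self) -> None:
        for acid, value in self.percentages.items():
            if value < 0:
                raise ValueError(f"negative percentage for {acid} in {self.name}")


def load_reference_profiles(path: str | Path | None = None) -> list[FattyAcidProfile]:
    """Load the bundled (or a user-supplied) composition table.

    Expected layout: first column ``row`` naming fatty acids plus
    ``oil_type``, ``origin`` and ``viscosity_mPa_s`` rows; remaining columns
    are oils. ``ND`` means not detected and is read as 0.
    """
    if path is None:
        source = resources.files("oilnmr.data") / "fatty_acid_composition.csv"
        table = pd.read_csv(source, index_col=0, keep_default_na=False)  # type: ignore[arg-type]
    else:
        table = pd.read_csv(path, index_col=0, keep_default_na=False)
    profiles = []
    acid_rows = [r for r in table.index if r in _KNOWN]
    for oil in table.columns:
        pct = {acid: (0.0 if table.loc[acid, oil] == "ND" else float(table.loc[acid, oil]))
               for acid in acid_rows}
        profiles.append(FattyAcidProfile(
            name=oil,
            percentages=pct,
            viscosity=float(table.loc["viscosity_mPa_s", oil]),
            origin=str(table.loc["origin", oil]) if "origin" in table.index else "",
            oil_type=str(table.loc["oil_type", oil]) if "oil_type" in table.index else "",
        ))
    return profiles


def category_sums(profile: FattyAcidProfile) -> tuple[float, float, float]:
    """(SFA, MUFA, PUFA) percentages, summed from the individual acids."""
    sfa = mufa = pufa = 0.0
    for acid, value in profile.percentages.items():
        if acid in SFA_ACIDS:
            sfa += value
        elif acid in MUFA_ACIDS:
            mufa += value
        elif acid in PUFA_ACIDS:
            pufa += value
        else:
            raise ValueError(f"unknown fatty acid {acid!r} in profile {profile.name}")
    return (sfa, mufa, pufa)


def unsaturation_ordering(profiles: list[FattyAcidProfile], tie_tol: float = 1e-9) -> dict[str, str]:
    """Descending ordering of the three category sums per oil.

    Returns e.g. ``{"AO-1": "MUFA > PUFA > SFA"}``; exact ties are reported
    with ``=``.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    out = {}
    for p in profiles:
        sums = dict(zip(("SFA", "MUFA", "PUFA"), category_sums(p)))
        ordered = sorted(sums, key=lambda k: sums[k], reverse=True)
        parts = [ordered[0]]
        for prev, cur in zip(ordered, ordered[1:]):
            sep = " = " if abs(sums[prev] - sums[cur]) <= tie_tol else " > "
            parts.append(sep + cur)
        out[p.name] = "".join(parts)
    return out


def viscosity_correlation(profiles: list[FattyAcidProfile]) -> tuple[float, float]:
    """Pearson correlations of viscosity with MUFA and with PUFA across oils."""
    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles for a correlation")
    visc = np.array([p.viscosity for p in profiles])
    cats = np.array([category_sums(p) for p in profiles])
    mufa, pufa = cats[:, 1], cats[:, 2]
    if np.std(visc) == 0 or np.std(mufa) == 0 or np.std(pufa) == 0:
        raise ValueError("zero variance; correlation undefined")
    r_mufa = float(np.corrcoef(visc, mufa)[0, 1])
    r_pufa = float(np.corrcoef(visc, pufa)[0, 1])
    return r_mufa, r_pufa


def composition_pca(profiles: list[FattyAcidProfile], n_components: int = 2) -> PrincipalComponents:
    """UV-scaled PCA of the individual-acid percentages plus viscosity.

    Acids that are zero in every profile are dropped (constant columns carry
    no variance to scale).
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles for a PCA")
    acids = sorted({a for p in profiles for a in p.percentages})
    data = pd.DataFrame(
        [{**{a: p.percentages.get(a, 0.0) for a in acids}, "viscosity": p.viscosity}
         for p in profiles],
        index=[p.name for p in profiles],
    )
    data = data.loc[:, data.std(ddof=1) > 0]
    scaled = UnitVarianceScaler().fit(data).transform(data)
    return PrincipalComponents(n_components=n_components).fit(scaled)


def compare_printed_categories(path: str | Path | None = None,
                               flag_tol: float = 0.05) -> pd.DataFrame:
    """Recompute SFA/MUFA/PUFA from individual acids and compare to the
    printed category rows of the table, flagging discrepancies above
    ``flag_tol`` percentage points."""
    if path is None:
        source = resources.files("oilnmr.data") / "fatty_acid_composition.csv"
        table = pd.read_csv(source, index_col=0, keep_default_na=False)  # type: ignore[arg-type]
    else:
        table = pd.read_csv(path, index_col=0, keep_default_na=False)
    profiles = load_reference_profiles(path)
    rows = []
    for p in profiles:
        computed = dict(zip(("SFA", "MUFA", "PUFA"), category_sums(p)))
        for cat, value in computed.items():
            printed_row = f"{cat}_printed"
            printed = float(table.loc[printed_row, p.name]) if printed_row in table.index else np.nan
            rows.append({
                "oil": p.name, "category": cat,
                "computed": round(value, 10), "printed": printed,
                "discrepancy": abs(value - printed) if np.isfinite(printed) else np.nan,
                "flagged": bool(np.isfinite(printed) and abs(value - printed) > flag_tol),
            })
    return pd.DataFrame(rows)
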