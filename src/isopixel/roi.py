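"""ROI-level isotope quantification and bulk-scale enrichment arithmetic.

Per-ROI compositions use the ratio-of-sums estimator: species intensities
are averaged over the ROI's pixels first and the isotope-fraction formulas
are applied to the averages. This matches how average secondary-ion signal
intensities per region are used for ROI isotope compositions, is additive
under ROI merges, and weighs pixels by their ion yield. The mean-of-ratios
alternative is exposed separately for cross-checks only.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .constants import ATOMIC_MASS, MOLAR_MASS_15N, MOLAR_MASS_N
from .stack_io import ControlReference, FormatError, IonCountStack, ROISet

__all__ = [
    "roi_composition",
    "roi_composition_mean_of_ratios",
    "tissue_summary",
    "mixing_fraction",
    "solution_molarity",
    "excess_15n_mass",
    "isotope_weighted_molar_mass",
]

_RATIO_SPECIES = ("12C12C", "13C12C", "12C14N", "12C15N")


def _roi_sums(canvas: IonCountStack, rois: ROISet) -> pd.DataFrame:
    rois.validate()
    if rois.labels.shape != canvas.shape:
        raise ValueError(
            f"ROI label image {rois.labels.shape} does not lie on canvas {canvas.shape}"
        )
    ids = rois.ids
    out = pd.DataFrame({"id": ids})
    out["n_px"] = ndimage.sum_labels(np.ones(canvas.shape), rois.labels, ids).astype(int)
    for sp in canvas.species:
        out[f"sum_{sp}"] = ndimage.sum_labels(
            canvas.counts[sp].astype(np.float64), rois.labels, ids
        )
    return out


def roi_composition(
    canvas: IonCountStack,
    rois: ROISet,
    control: ControlReference | None = None,
) -> pd.DataFrame:
    """Per-ROI isotope composition table (ratio-of-sums estimator).

    Columns: id, tissue, compartment, n_px, mean_<species>, at13c_pct,
    at15n_pct, total_cn_mean, and ape13c_pct/ape15n_pct when a control is
    given.
    """
    canvas.require(*_RATIO_SPECIES)
    sums = _roi_sums(canvas, rois)
    tab = rois.annotations.merge(sums, on="id").sort_values("id").reset_index(drop=True)
    if (tab["n_px"] < 1).any():
        empty = tab.loc[tab["n_px"] < 1, "id"].tolist()
        raise FormatError(f"empty ROIs: {empty}")
    for sp in canvas.species:
        tab[f"mean_{sp}"] = tab[f"sum_{sp}"] / tab["n_px"]
    a = tab["sum_13C12C"]
    b = tab["sum_12C12C"]
    n15 = tab["sum_12C15N"]
    n14 = tab["sum_12C14N"]
    with np.errstate(divide="ignore", invalid="ignore"):
        tab["at13c_pct"] = 100.0 * a / (2.0 * b + a)
        tab["at15n_pct"] = 100.0 * n15 / (n15 + n14)
        r = a / (2.0 * b)
        tab["total_cn_mean"] = (n14 + n15) * (1.0 + r) / tab["n_px"]
    if control is not None:
        tab["ape13c_pct"] = [
            row.at13c_pct - control.at_pct("13C", row.tissue, row.compartment)
            for row in tab.itertuples()
        ]
        tab["ape15n_pct"] = [
            row.at15n_pct - control.at_pct("15N", row.tissue, row.compartment)
            for row in tab.itertuples()
        ]
    return tab.drop(columns=[f"sum_{sp}" for sp in canvas.species])


def roi_composition_mean_of_ratios(canvas: IonCountStack, rois: ROISet) -> pd.DataFrame:
    """Per-ROI at% as the mean of per-pixel ratios (cross-check estimator).

    Pixels with zero denominator are excluded per ROI. Kept separate from
    :func:`roi_composition` on purpose; the two estimators differ on
    heterogeneous ROIs.
    """
    canvas.require(*_RATIO_SPECIES)
    rois.validate()
    ids = rois.ids
    a = canvas.counts["13C12C"].astype(np.float64)
    b = canvas.counts["12C12C"].astype(np.float64)
    n15 = canvas.counts["12C15N"].astype(np.float64)
    n14 = canvas.counts["12C14N"].astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        r13 = np.where(2 * b + a > 0, 100.0 * a / (2 * b + a), np.nan)
        r15 = np.where(n15 + n14 > 0, 100.0 * n15 / (n15 + n14), np.nan)
    out = pd.DataFrame({"id": ids})
    for col, img in (("at13c_pct", r13), ("at15n_pct", r15)):
        vals = []
        for i in ids:
            px = img[rois.labels == i]
            px = px[np.isfinite(px)]
            vals.append(px.mean() if px.size else np.nan)
        out[col] = vals
    return out.merge(rois.annotations, on="id")


def tissue_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Group a ROI table into per tissue x compartment summary rows.

    For each group and each of at13c_pct/at15n_pct: n, mean, RSD (sample
    SD / mean; 0 for single-ROI groups), min, max — mirroring the layout of
    a per-tissue isotope signature table. A resin/background tissue, when
    present in the table, summarizes like any other.
    """
    if table.empty:
        raise ValueError("empty ROI table")
    rows = []
    for (tis, comp), grp in table.groupby(["tissue", "compartment"], sort=True):
        row = {"tissue": tis, "compartment": comp, "n": len(grp)}
        for ch, col in (("at13c", "at13c_pct"), ("at15n", "at15n_pct")):
            v = grp[col].to_numpy(dtype=float)
            mean = v.mean()
            sd = v.std(ddof=1) if v.size > 1 else 0.0
            row[f"{ch}_mean"] = mean
            row[f"{ch}_rsd"] = sd / mean if mean != 0 else 0.0
            row[f"{ch}_min"] = v.min()
            row[f"{ch}_max"] = v.max()
        rows.append(row)
    cols = ["tissue", "compartment", "n",
            "at13c_mean", "at13c_rsd", "at13c_min", "at13c_max",
            "at15n_mean", "at15n_rsd", "at15n_min", "at15n_max"]
    return pd.DataFrame(rows)[cols]


def mixing_fraction(observed_at_pct: float, source_at_pct: float, natural_at_pct: float) -> float:
    """Two-pool mixing: fraction of the element replaced by the labelled source.

    f = (observed - natural) / (source - natural), clamped to [0, 1] with a
    warning when the observed value lies outside the two end members.
    """
    if source_at_pct == natural_at_pct:
        raise ValueError("source and natural at% are equal; mixing fraction undefined")
    f = (observed_at_pct - natural_at_pct) / (source_at_pct - natural_at_pct)
    if not (0.0 <= f <= 1.0):
        warnings.warn(
            f"observed at% {observed_at_pct} outside [natural, source]; clamping", stacklevel=2
        )
        f = min(max(f, 0.0), 1.0)
    return f


def _parse_formula(formula: str) -> list[tuple[str, int, str | None]]:
    """Parse e.g. '15NH4Cl' into [(element, count, isotope-or-None), ...]."""
    import re

    tokens = re.findall(r"(\d+)?([A-Z][a-z]?)(\d*)", formula)
    out = []
    consumed = ""
    for iso, elem, count in tokens:
        if not elem:
            continue
        consumed += f"{iso}{elem}{count}"
        out.append((elem, int(count) if count else 1, f"{iso}{elem}" if iso else None))
    if consumed != formula:
        raise ValueError(f"cannot parse formula {formula!r}")
    if not out:
        raise ValueError(f"cannot parse formula {formula!r}")
    return out


def isotope_weighted_molar_mass(
    formula: str, label_at_pct: float = 0.0, label_element: str = "N"
) -> float:
    """Molar mass with the label element's mass weighted by enrichment.

    Atoms of ``label_element`` (or written with an explicit isotope prefix,
    e.g. '15N') weigh ``label_at_pct``% heavy isotope, the rest light.
    """
    if not (0.0 <= label_at_pct <= 100.0):
        raise ValueError("label at% must be in [0, 100]")
    heavy = {"N": ("15N", "14N"), "C": ("13C", "12C")}
    mass = 0.0
    for elem, count, iso in _parse_formula(formula):
        if elem == label_element:
            h, l = heavy[label_element]
            f = label_at_pct / 100.0
            mass += count * (f * ATOMIC_MASS[h] + (1 - f) * ATOMIC_MASS[l])
        elif iso is not None:
            mass += count * ATOMIC_MASS[iso]
        else:
            if elem not in ATOMIC_MASS:
                raise ValueError(f"unknown element {elem!r} in formula {formula!r}")
            mass += count * ATOMIC_MASS[elem]
    return mass


def solution_molarity(
    mass_conc_mg_per_l: float,
    formula: str | None = None,
    label_at_pct: float = 0.0,
    label_element: str = "N",
    molar_mass: float | None = None,
    n_label_atoms: int | None = None,
) -> float:
    """Millimolar concentration of the label element in a labelling solution.

    Either give a chemical ``formula`` (isotope-weighted molar mass computed
    from standard atomic masses) or an assumed ``molar_mass`` with
    ``n_label_atoms`` per molecule (e.g. an amino-acid mixture at an assumed
    mean molar mass).
    """
    if mass_conc_mg_per_l < 0:
        raise ValueError("mass concentration must be >= 0")
    if formula is not None:
        m = isotope_weighted_molar_mass(formula, label_at_pct, label_element)
        n_atoms = sum(
            count for elem, count, iso in _parse_formula(formula)
            if elem == label_element
        )
        if n_atoms == 0:
            raise ValueError(f"formula {formula!r} contains no {label_element}")
    else:
        if molar_mass is None or n_label_atoms is None:
            raise ValueError("give either formula or (molar_mass, n_label_atoms)")
        m, n_atoms = molar_mass, n_label_atoms
    return mass_conc_mg_per_l / m * n_atoms


def excess_15n_mass(
    ape15n_pct: float, total_n_mass_ug: float, convention: str = "atomic"
) -> dict:
    """Mass of excess 15N in a pool of total nitrogen.

    ``atomic`` convention converts the N pool to moles at the mean molar
    mass of nitrogen and weighs the excess atoms at the 15N mass
    (mass * APE/100 * 15.0001/14.007); ``mass`` applies APE directly to the
    N mass. The convention used is recorded in the result.
    """
    if ape15n_pct < 0 or total_n_mass_ug < 0:
        raise ValueError("inputs must be >= 0")
    if convention == "atomic":
        value = total_n_mass_ug * (ape15n_pct / 100.0) * (MOLAR_MASS_15N / MOLAR_MASS_N)
    elif convention == "mass":
        value = total_n_mass_ug * (ape15n_pct / 100.0)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return {"excess_15n_ug": value, "convention": convention}
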