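"""Per-pixel isotope-fraction maps from secondary-ion counts.

The carbon isotope fraction is inferred from the diatomic C2- species by the
pairing formula

    at%13C = 100 * 13C12C / (2 * 12C12C + 13C12C),

exact when atoms pair independently (13C13C is not detected in this
configuration), and the nitrogen fraction from the CN- species by

    at%15N = 100 * 12C15N / (12C15N + 12C14N).

The structural CN- signal is corrected for the dual labelling,

    total CN = (12C14N + 12C15N) * (1 + R),   R = 13C12C / (2 * 12C12C),

so that strongly 13C-labelled structures are not dimmed. Atom percent excess
(APE) is the sample at% minus the at% of the unlabelled control.

Pixels whose ratio denominator falls below a count threshold are masked
invalid rather than imputed; standard errors come from first-order (delta
method) propagation of independent Poisson counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stack_io import ControlReference, IonCountStack

__all__ = [
    "AtomFractionMap",
    "IsotopePairMap",
    "carbon_atom_fraction",
    "nitrogen_atom_fraction",
    "total_cn_signal",
    "ape",
    "ratio_uncertainty",
    "compute_isotope_pair_map",
]

#: Default minimum denominator counts for a pixel to be considered valid.
DEFAULT_MIN_COUNTS = 10


@dataclass
class AtomFractionMap:
    """One isotope-fraction image with its uncertainty and validity mask.

    ``at_pct`` and ``se_pct`` are NaN on invalid pixels.
    """

    at_pct: np.ndarray
    se_pct: np.ndarray
    valid: np.ndarray
    channel: str  # "13C" or "15N"


@dataclass
class IsotopePairMap:
    """Joint per-pixel carbon/nitrogen composition of one stack."""

    at13c: AtomFractionMap
    at15n: AtomFractionMap
    total_cn: np.ndarray
    cn_valid: np.ndarray
    ape13c_pct: np.ndarray | None = None
    ape15n_pct: np.ndarray | None = None
    control: ControlReference | None = None


def _ratio_map(num: np.ndarray, den: np.ndarray, min_counts: int) -> tuple[np.ndarray, np.ndarray]:
    valid = den >= min_counts
    at = np.full(num.shape, np.nan)
    np.divide(100.0 * num, den, out=at, where=valid)
    return at, valid


def carbon_atom_fraction(stack: IonCountStack, min_counts: int = DEFAULT_MIN_COUNTS) -> AtomFractionMap:
    """at%13C image from the C2- pairing formula, with delta-method SE."""
    stack.require("13C12C", "12C12C")
    a = stack.counts["13C12C"].astype(np.float64)
    b = stack.counts["12C12C"].astype(np.float64)
    at, valid = _ratio_map(a, 2.0 * b + a, min_counts)
    se = ratio_uncertainty(stack, "13C", min_counts=min_counts)
    return AtomFractionMap(at_pct=at, se_pct=se, valid=valid, channel="13C")


def nitrogen_atom_fraction(stack: IonCountStack, min_counts: int = DEFAULT_MIN_COUNTS) -> AtomFractionMap:
    """at%15N image from the CN- species ratio, with delta-method SE."""
    stack.require("12C15N", "12C14N")
    a = stack.counts["12C15N"].astype(np.float64)
    b = stack.counts["12C14N"].astype(np.float64)
    at, valid = _ratio_map(a, a + b, min_counts)
    se = ratio_uncertainty(stack, "15N", min_counts=min_counts)
    return AtomFractionMap(at_pct=at, se_pct=se, valid=valid, channel="15N")


def total_cn_signal(stack: IonCountStack) -> tuple[np.ndarray, np.ndarray]:
    """Dual-label-corrected structural CN- signal (counts) and validity mask.

    Pixels with zero 12C12C counts (R undefined) are masked.
    """
    stack.require("12C14N", "12C15N", "13C12C", "12C12C")
    n14 = stack.counts["12C14N"].astype(np.float64)
    n15 = stack.counts["12C15N"].astype(np.float64)
    a = stack.counts["13C12C"].astype(np.float64)
    b = stack.counts["12C12C"].astype(np.float64)
    valid = b > 0
    r = np.zeros_like(b)
    np.divide(a, 2.0 * b, out=r, where=valid)
    total = np.where(valid, (n14 + n15) * (1.0 + r), np.nan)
    return total, valid


def ratio_uncertainty(stack: IonCountStack, channel: str, min_counts: int = DEFAULT_MIN_COUNTS) -> np.ndarray:
    """Per-pixel SE (at% units) of the isotope-fraction estimate.

    First-order propagation treating each species count as an independent
    Poisson variate; NaN where the denominator is below ``min_counts``.
    """
    if channel == "13C":
        stack.require("13C12C", "12C12C")
        a = stack.counts["13C12C"].astype(np.float64)
        b = stack.counts["12C12C"].astype(np.float64)
        den = 2.0 * b + a
        valid = den >= min_counts
        # f = a/(a+2b): df/da = 2b/den^2, df/db = -2a/den^2
        with np.errstate(divide="ignore", invalid="ignore"):
            var = (4.0 * b**2 * a + 4.0 * a**2 * b) / den**4
    elif channel == "15N":
        stack.require("12C15N", "12C14N")
        a = stack.counts["12C15N"].astype(np.float64)
        b = stack.counts["12C14N"].astype(np.float64)
        den = a + b
        valid = den >= min_counts
        with np.errstate(divide="ignore", invalid="ignore"):
            var = a * b / den**3
    else:
        raise ValueError(f"unknown channel {channel!r}")
    se = np.full(a.shape, np.nan)
    np.sqrt(var, out=se, where=valid)
    return 100.0 * np.where(valid, se, np.nan)


def ape(
    at_pct: np.ndarray | float,
    control: ControlReference,
    channel: str,
    tissue: str | None = None,
    compartment: str | None = None,
):
    """Atom percent excess: sample at% minus control at% (signed, unclamped)."""
    base = control.at_pct(channel, tissue=tissue, compartment=compartment)
    return np.asarray(at_pct) - base if isinstance(at_pct, np.ndarray) else at_pct - base


def compute_isotope_pair_map(
    stack: IonCountStack,
    control: ControlReference | None = None,
    min_counts: int = DEFAULT_MIN_COUNTS,
) -> IsotopePairMap:
    """Full per-pixel composition of one stack; APE maps when a control is given."""
    c = carbon_atom_fraction(stack, min_counts=min_counts)
    n = nitrogen_atom_fraction(stack, min_counts=min_counts)
    total, cn_valid = total_cn_signal(stack)
    out = IsotopePairMap(at13c=c, at15n=n, total_cn=total, cn_valid=cn_valid, control=control)
    if control is not None:
        out.ape13c_pct = ape(c.at_pct, control, "13C")
        out.ape15n_pct = ape(n.at_pct, control, "15N")
    return out
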