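"""Ion-count stacks, ROI sets and control references, with file round trips.

An acquisition tile is stored as a multi-page 32-bit unsigned TIFF (one page
per secondary-ion species, fixed page order) plus a JSON sidecar carrying the
species map and acquisition metadata. ROI sets are a 16-bit label TIFF plus
an annotation CSV. Control references are plain CSV. All writers sort keys
and fix endianness so identical inputs produce byte-identical files.

Coordinates are 0-based, row-major, origin top-left, pixel-centred; stage
offsets are micrometres and convert to pixels through the pixel size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .constants import (
    COMPARTMENTS_EXTENDED,
    SPECIES,
    TISSUES_EXTENDED,
)

__all__ = [
    "IonCountStack",
    "ROISet",
    "ControlReference",
    "FormatError",
    "read_ion_stack",
    "write_ion_stack",
    "read_roi_set",
    "write_roi_set",
    "load_control_reference",
    "write_control_reference",
]


class FormatError(ValueError):
    """A file or in-memory object violates the ion-stack/ROI/control schema."""


@dataclass
class IonCountStack:
    """Per-species count images for one acquisition tile (or a canvas).

    Parameters
    ----------
    counts
        Mapping of species key (see :data:`isopixel.constants.SPECIES`) to a
        2-D non-negative integer array of accumulated ion counts.
    pixel_size_um
        Lateral pixel size in micrometres per pixel.
    dwell_ms
        Total per-pixel dwell time in milliseconds (summed over planes).
    planes
        Number of accumulated acquisition planes.
    stage_offset_um
        Stage position of the tile origin on the sample, micrometres (y, x).
    pre_sputtered
        Whether the field was pre-sputtered before this acquisition (the
        remedy for the N2-adsorption bias in re-measured areas).
    order_index
        Position of this tile in the acquisition sequence (0-based).
    """

    counts: dict[str, np.ndarray]
    pixel_size_um: float
    dwell_ms: float = 13.5
    planes: int = 1
    stage_offset_um: tuple[float, float] = (0.0, 0.0)
    pre_sputtered: bool = False
    order_index: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.counts.values())).shape

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.counts)

    def validate(self) -> None:
        if not self.counts:
            raise FormatError("stack has no species images")
        shape = None
        for sp, img in self.counts.items():
            img = np.asarray(img)
            if img.ndim != 2:
                raise FormatError(f"species {sp}: image must be 2-D")
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise FormatError(
                    f"species {sp}: shape {img.shape} != {shape} (dimension mismatch)"
                )
            if not np.issubdtype(img.dtype, np.integer):
                if not np.allclose(img, np.round(img)):
                    raise FormatError(f"species {sp}: non-integer pixel values")
            if img.min() < 0:
                raise FormatError(f"species {sp}: negative counts")
            self.counts[sp] = img.astype(np.uint32)
        if self.pixel_size_um <= 0:
            raise FormatError("pixel_size_um must be > 0")
        if self.dwell_ms < 0:
            raise FormatError("dwell_ms must be >= 0")

    def require(self, *species: str) -> None:
        missing = [sp for sp in species if sp not in self.counts]
        if missing:
            raise FormatError("species missing: " + ", ".join(missing))

    def copy(self) -> "IonCountStack":
        return replace(self, counts={k: v.copy() for k, v in self.counts.items()})


def write_ion_stack(stack: IonCountStack, path: str | Path) -> Path:
    """Write *stack* as multi-page TIFF + JSON sidecar; returns the TIFF path."""
    stack.validate()
    path = Path(path)
    order = [sp for sp in SPECIES if sp in stack.counts]
    order += [sp for sp in stack.counts if sp not in order]
    pages = np.stack([stack.counts[sp].astype("<u4") for sp in order])
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "pages": {str(i): sp for i, sp in enumerate(order)},
        "pixel_size_um": stack.pixel_size_um,
        "dwell_ms": stack.dwell_ms,
        "planes": stack.planes,
        "stage_offset_um": list(stack.stage_offset_um),
        "pre_sputtered": stack.pre_sputtered,
        "order_index": stack.order_index,
    }
    path.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True) + "\n"
    )
    return path


def read_ion_stack(path: str | Path, required_species: tuple[str, ...] = SPECIES) -> IonCountStack:
    """Read a stack written by :func:`write_ion_stack`.

    Raises :class:`FormatError` when the sidecar is missing a species in
    *required_species* (pass ``()`` to accept any subset).
    """
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    page_map = {int(k): v for k, v in meta["pages"].items()}
    counts = {page_map[i]: np.asarray(pages[i]) for i in sorted(page_map)}
    missing = [sp for sp in required_species if sp not in counts]
    if missing:
        raise FormatError("species missing: " + ", ".join(missing))
    return IonCountStack(
        counts=counts,
        pixel_size_um=float(meta["pixel_size_um"]),
        dwell_ms=float(meta["dwell_ms"]),
        planes=int(meta["planes"]),
        stage_offset_um=tuple(meta["stage_offset_um"]),
        pre_sputtered=bool(meta["pre_sputtered"]),
        order_index=int(meta["order_index"]),
    )


@dataclass
class ROISet:
    """Annotated pixel regions on a mosaic canvas.

    ``labels`` holds positive integer ROI ids (0 = unassigned);
    ``annotations`` maps each id to a tissue class and compartment.
    """

    labels: np.ndarray
    annotations: pd.DataFrame  # columns: id, tissue, compartment

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.validate()

    def validate(self) -> None:
        if self.labels.ndim != 2:
            raise FormatError("ROI label image must be 2-D")
        if self.labels.min() < 0:
            raise FormatError("ROI labels must be non-negative")
        ann = self.annotations
        for col in ("id", "tissue", "compartment"):
            if col not in ann.columns:
                raise FormatError(f"annotation table missing column {col!r}")
        if ann["id"].duplicated().any():
            dup = sorted(ann.loc[ann["id"].duplicated(), "id"].unique().tolist())
            raise FormatError(f"duplicate ROI ids in annotations: {dup}")
        bad_t = sorted(set(ann["tissue"]) - set(TISSUES_EXTENDED))
        if bad_t:
            raise FormatError(
                f"unknown tissue codes {bad_t}; allowed: {list(TISSUES_EXTENDED)}"
            )
        bad_c = sorted(set(ann["compartment"]) - set(COMPARTMENTS_EXTENDED))
        if bad_c:
            raise FormatError(
                f"unknown compartment codes {bad_c}; allowed: {list(COMPARTMENTS_EXTENDED)}"
            )
        image_ids = set(np.unique(self.labels).tolist()) - {0}
        table_ids = set(int(i) for i in ann["id"])
        only_img = sorted(image_ids - table_ids)
        only_tab = sorted(table_ids - image_ids)
        if only_img or only_tab:
            raise FormatError(
                f"ROI id mismatch: in image only {only_img}, in table only {only_tab}"
            )

    @property
    def ids(self) -> np.ndarray:
        return np.sort(self.annotations["id"].to_numpy())


def write_roi_set(rois: ROISet, label_path: str | Path, annotation_path: str | Path) -> None:
    rois.validate()
    if rois.labels.max() > np.iinfo(np.uint16).max:
        raise FormatError("ROI ids exceed 16-bit label range")
    tifffile.imwrite(Path(label_path), rois.labels.astype("<u2"), photometric="minisblack")
    ann = rois.annotations.sort_values("id")[["id", "tissue", "compartment"]]
    ann.to_csv(Path(annotation_path), index=False)


def read_roi_set(label_path: str | Path, annotation_path: str | Path) -> ROISet:
    labels = np.asarray(tifffile.imread(Path(label_path)))
    ann = pd.read_csv(Path(annotation_path))
    return ROISet(labels=labels, annotations=ann)


@dataclass
class ControlReference:
    """Isotope fractions of the unlabelled control, the APE baseline.

    Global means are mandatory; per tissue x compartment overrides are
    optional and fall back to the global values.
    """

    at13c_pct: float
    at15n_pct: float
    rsd13c: float = 0.0
    rsd15n: float = 0.0
    n: int = 1
    per_group: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v, name in ((self.at13c_pct, "at13c_pct"), (self.at15n_pct, "at15n_pct")):
            _check_atpct(v, name)
        for key, (c, nn) in self.per_group.items():
            _check_atpct(c, f"per_group{key} at13c")
            _check_atpct(nn, f"per_group{key} at15n")
        if self.n < 1:
            raise FormatError("control n must be >= 1")

    def at_pct(self, channel: str, tissue: str | None = None, compartment: str | None = None) -> float:
        """Control at% for ``channel`` in {'13C','15N'}, with group fallback."""
        if channel not in ("13C", "15N"):
            raise ValueError(f"unknown channel {channel!r}")
        idx = 0 if channel == "13C" else 1
        if tissue is not None:
            key = (tissue, compartment if compartment is not None else "none")
            if key in self.per_group:
                return self.per_group[key][idx]
            # tissue-level override with unspecified compartment
            key2 = (tissue, "none")
            if key2 in self.per_group:
                return self.per_group[key2][idx]
        return self.at13c_pct if idx == 0 else self.at15n_pct


def _check_atpct(v: float, name: str) -> None:
    if not (0.0 < v < 100.0):
        raise FormatError(f"{name}={v} outside (0, 100) at%")


def write_control_reference(ref: ControlReference, path: str | Path) -> None:
    rows = [
        {
            "tissue": "global",
            "compartment": "none",
            "at13c_pct": ref.at13c_pct,
            "at15n_pct": ref.at15n_pct,
            "rsd13c": ref.rsd13c,
            "rsd15n": ref.rsd15n,
            "n": ref.n,
        }
    ]
    for (tis, comp), (c, nn) in sorted(ref.per_group.items()):
        rows.append(
            {
                "tissue": tis,
                "compartment": comp,
                "at13c_pct": c,
                "at15n_pct": nn,
                "rsd13c": "",
                "rsd15n": "",
                "n": "",
            }
        )
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def load_control_reference(path: str | Path) -> ControlReference:
    """Load a control reference from CSV (columns tissue, compartment,
    at13c_pct, at15n_pct, optional rsd/n; a ``tissue == 'global'`` row is
    required and supplies the fallback values)."""
    df = pd.read_csv(Path(path))
    for col in ("tissue", "at13c_pct", "at15n_pct"):
        if col not in df.columns:
            raise FormatError(f"control file missing column {col!r}")
    if "compartment" not in df.columns:
        df["compartment"] = "none"
    df["compartment"] = df["compartment"].fillna("none")
    glob = df[df["tissue"] == "global"]
    if len(glob) != 1:
        raise FormatError("control file must contain exactly one 'global' row")
    g = glob.iloc[0]
    per_group = {}
    for _, r in df[df["tissue"] != "global"].iterrows():
        per_group[(str(r["tissue"]), str(r["compartment"]))] = (
            float(r["at13c_pct"]),
            float(r["at15n_pct"]),
        )
    return ControlReference(
        at13c_pct=float(g["at13c_pct"]),
        at15n_pct=float(g["at15n_pct"]),
        rsd13c=float(g.get("rsd13c", 0.0) or 0.0),
        rsd15n=float(g.get("rsd15n", 0.0) or 0.0),
        n=int(g.get("n", 1) or 1),
        per_group=per_group,
    )
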