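"""Read and write DICOM RT Structure Set files.

Structures are stored as stacks of closed planar polygons in patient
millimetre coordinates.  Writing supports a configurable number of decimal
places in the DecimalString coordinate rendering, emulating the varying
precision used by different export systems; reading preserves contour and
vertex order exactly and applies no cleaning.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import _dicom
from ._dicom import Dataset
from .errors import RTSSDataError, RTSSFormatError
from .model import CLOSED_PLANAR, ImageGrid, PlanarContour, Structure

RTSS_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"

DEFAULT_DECIMAL_PLACES = 6
_DS_MAX_BYTES = 16  # DICOM DecimalString length limit

# tags
_SOP_CLASS = (0x0008, 0x0016)
_SOP_INSTANCE = (0x0008, 0x0018)
_MODALITY = (0x0008, 0x0060)
_FOR_UID = (0x0020, 0x0052)
_REF_FOR_SEQ = (0x3006, 0x0010)
_SSROI_SEQ = (0x3006, 0x0020)
_ROI_NUMBER = (0x3006, 0x0022)
_ROI_REF_FOR = (0x3006, 0x0024)
_ROI_NAME = (0x3006, 0x0026)
_ROI_GEN_ALG = (0x3006, 0x0036)
_ROI_CONTOUR_SEQ = (0x3006, 0x0039)
_ROI_DISPLAY_COLOR = (0x3006, 0x002A)
_CONTOUR_SEQ = (0x3006, 0x0040)
_GEOMETRIC_TYPE = (0x3006, 0x0042)
_N_POINTS = (0x3006, 0x0046)
_CONTOUR_DATA = (0x3006, 0x0050)
_REF_ROI_NUMBER = (0x3006, 0x0084)


def format_decimal(value: float, decimal_places: int) -> str:
    """Render one coordinate as a DICOM DecimalString.

    Rounded to ``decimal_places``, trailing zeros stripped.  Raises
    :class:`RTSSFormatError` when the rendering exceeds the 16-byte DS
    limit.
    """
    s = f"{value:.{decimal_places}f}"
    if "." in s:
        s = s.rstrip("0").rstrip(".")
    if s in ("-0", ""):
        s = "0"
    if len(s) > _DS_MAX_BYTES:
        raise RTSSFormatError(
            f"coordinate {value!r} renders to {len(s)} bytes at "
            f"{decimal_places} decimal places (DICOM DS limit is 16); "
            "use fewer decimal places"
        )
    return s


def write_rtss(
    structures: list[Structure],
    grid: ImageGrid | None,
    path,
    decimal_places: int = DEFAULT_DECIMAL_PLACES,
) -> None:
    """Write structures as a minimal valid RT Structure Set.

    Coordinates are rounded to ``decimal_places``; a subsequent
    :func:`read_rtss` reproduces every vertex within
    ``0.5 * 10**-decimal_places`` mm per coordinate.
    """
    if not 1 <= decimal_places <= 10:
        raise ValueError("decimal_places must be in [1, 10]")
    if grid is not None:
        for s in structures:
            grid.check_contains(s)

    for_uid = next(
        (s.frame_of_reference for s in structures if s.frame_of_reference), _dicom.new_uid()
    )
    sop_instance = _dicom.new_uid()

    ds = Dataset()
    ds.put_text(_SOP_CLASS, "UI", RTSS_SOP_CLASS)
    ds.put_text(_SOP_INSTANCE, "UI", sop_instance)
    ds.put_text((0x0008, 0x0020), "DA", "")
    ds.put_text((0x0008, 0x0030), "TM", "")
    ds.put_text((0x0008, 0x0050), "SH", "")
    ds.put_text(_MODALITY, "CS", "RTSTRUCT")
    ds.put_text((0x0008, 0x0070), "LO", "rtssqc")
    ds.put_text((0x0008, 0x0090), "PN", "")
    ds.put_text((0x0010, 0x0010), "PN", "Synthetic^Phantom")
    ds.put_text((0x0010, 0x0020), "LO", "RTSSQC")
    ds.put_text((0x0010, 0x0030), "DA", "")
    ds.put_text((0x0010, 0x0040), "CS", "O")
    ds.put_text((0x0020, 0x000D), "UI", _dicom.new_uid())
    ds.put_text((0x0020, 0x000E), "UI", _dicom.new_uid())
    ds.put_text((0x0020, 0x0010), "SH", "")
    ds.put_text((0x0020, 0x0011), "IS", "1")
    ds.put_text((0x3006, 0x0002), "SH", "RTSSQC")
    ds.put_text((0x3006, 0x0008), "DA", "")
    ds.put_text((0x3006, 0x0009), "TM", "")

    ref_for = Dataset()
    ref_for.put_text(_FOR_UID, "UI", for_uid)
    ds.put_sequence(_REF_FOR_SEQ, [ref_for])

    roi_items, contour_items, obs_items = [], [], []
    for number, s in enumerate(structures, start=1):
        roi = Dataset()
        roi.put_text(_ROI_NUMBER, "IS", str(number))
        roi.put_text(_ROI_REF_FOR, "UI", s.frame_of_reference or for_uid)
        roi.put_text(_ROI_NAME, "LO", s.name)
        roi.put_text(_ROI_GEN_ALG, "CS", "AUTOMATIC")
        roi_items.append(roi)

        contours = []
        for c in s.contours:
            if c.geometric_type != CLOSED_PLANAR:
                raise RTSSDataError(
                    f"structure {s.name!r}: unsupported geometric type "
                    f"{c.geometric_type!r} (only CLOSED_PLANAR is supported)"
                )
            item = Dataset()
            item.put_text(_GEOMETRIC_TYPE, "CS", CLOSED_PLANAR)
            item.put_text(_N_POINTS, "IS", str(c.n_vertices))
            triplets = c.points3d().ravel()
            item.put_text(
                _CONTOUR_DATA,
                "DS",
                "\\".join(format_decimal(v, decimal_places) for v in triplets),
            )
            contours.append(item)
        rc = Dataset()
        rc.put_text(_ROI_DISPLAY_COLOR, "IS", "255\\0\\0")
        rc.put_sequence(_CONTOUR_SEQ, contours)
        rc.put_text(_REF_ROI_NUMBER, "IS", str(number))
        contour_items.append(rc)

        obs = Dataset()
        obs.put_text((0x3006, 0x0082), "IS", str(number))
        obs.put_text(_REF_ROI_NUMBER, "IS", str(number))
        obs.put_text((0x3006, 0x00A4), "CS", "ORGAN")
        obs.put_text((0x3006, 0x00A6), "PN", "")
        obs_items.append(obs)

    ds.put_sequence(_SSROI_SEQ, roi_items)
    ds.put_sequence(_ROI_CONTOUR_SEQ, contour_items)
    ds.put_sequence((0x3006, 0x0080), obs_items)

    _dicom.write_file(path, ds, RTSS_SOP_CLASS, sop_instance)


def read_rtss(path, z_tol: float = 1e-3) -> list[Structure]:
    """Read an RT Structure Set into the polygon-stack model.

    One :class:`Structure` per ROI, in structure-set order; contour order
    and vertex order are preserved exactly and no cleaning is applied.
    A contour whose z varies by more than ``z_tol`` mm is rejected as
    non-planar.
    """
    try:
        ds = _dicom.read_file(path)
    except _dicom.DicomFormatError as exc:
        raise RTSSFormatError(str(exc)) from exc

    modality = ds.text(_MODALITY, "")
    sop = ds.text(_SOP_CLASS, "")
    if modality != "RTSTRUCT" and sop != RTSS_SOP_CLASS:
        raise RTSSFormatError(f"not an RT Structure Set (modality {modality!r})")

    roi_seq = ds.sequence(_SSROI_SEQ)
    contour_seq = ds.sequence(_ROI_CONTOUR_SEQ)
    if roi_seq is None:
        raise RTSSFormatError("missing StructureSetROISequence (3006,0020)")
    if contour_seq is None:
        raise RTSSFormatError("missing ROIContourSequence (3006,0039)")

    names: dict[str, str] = {}
    fors: dict[str, str] = {}
    order: list[str] = []
    for roi in roi_seq:
        number = roi.text(_ROI_NUMBER, "")
        names[number] = roi.text(_ROI_NAME, "") or f"ROI-{number}"
        fors[number] = roi.text(_ROI_REF_FOR, "") or ""
        order.append(number)

    by_number: dict[str, Structure] = {
        n: Structure(name=names[n], contours=[], frame_of_reference=fors[n]) for n in order
    }
    for rc in contour_seq:
        number = rc.text(_REF_ROI_NUMBER, "")
        if number not in by_number:
            raise RTSSFormatError(f"ROIContourSequence references unknown ROI {number!r}")
        target = by_number[number]
        for item in rc.sequence(_CONTOUR_SEQ) or []:
            gtype = item.text(_GEOMETRIC_TYPE, "")
            if gtype != CLOSED_PLANAR:
                raise RTSSDataError(
                    f"ROI {target.name!r}: unsupported contour geometric type "
                    f"{gtype!r} (only CLOSED_PLANAR is supported)"
                )
            values = item.texts(_CONTOUR_DATA)
            if not values or len(values) % 3:
                raise RTSSFormatError(
                    f"ROI {target.name!r}: contour data is not a list of (x,y,z) triplets"
                )
            pts = np.array([float(v) for v in values]).reshape(-1, 3)
            zspread = float(pts[:, 2].max() - pts[:, 2].min())
            if zspread > z_tol:
                raise RTSSDataError(
                    f"ROI {target.name!r}: non-planar contour (z varies by {zspread:.6g} mm)"
                )
            target.contours.append(PlanarContour(pts[:, :2], float(pts[0, 2]), gtype))

    return [by_number[n] for n in order]


# ---------------------------------------------------------------------------
# grid sidecar (for structure sets without a referenced image series)
# ---------------------------------------------------------------------------

def grid_sidecar_path(rtss_path) -> Path:
    return Path(str(rtss_path) + ".grid.json")


def write_grid_sidecar(grid: ImageGrid, rtss_path) -> Path:
    p = grid_sidecar_path(rtss_path)
    p.write_text(json.dumps(grid.to_dict(), indent=2) + "\n")
    return p


def read_grid_sidecar(rtss_path) -> ImageGrid:
    p = grid_sidecar_path(rtss_path)
    if not p.exists():
        raise RTSSFormatError(f"no grid sidecar found at {p}")
    return ImageGrid.from_dict(json.loads(p.read_text()))
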