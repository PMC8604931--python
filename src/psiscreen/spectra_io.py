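"""Reading, writing and binning of spectra.

The central container is :class:`SpectraMatrix`: rows are individual spectra,
columns an ordered m/z grid, with a replicate map (``subject_of``) recording
which spectra come from the same subject and an optional subject-level class
map (``class_of``).  Raw centroided peak lists (from CSV-exported scans or
mzML files) are placed on a common grid with :func:`bin_peaklists`; matrices
round-trip through a plain CSV dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "PeakList",
    "SpectraMatrix",
    "read_matrix_csv",
    "write_matrix_csv",
    "read_mzml",
    "bin_peaklists",
    "average_replicates",
]


@dataclass
class PeakList:
    """A single centroided spectrum: m/z positions and ion counts.

    ``polarity`` records the acquisition mode ("positive" or "negative");
    nothing downstream computes with it, it is carried as metadata.
    """

    mz: np.ndarray
    intensity: np.ndarray
    polarity: str = "negative"
    source_id: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise FormatError("peak list arrays must be one-dimensional")
        if self.mz.size != self.intensity.size:
            raise FormatError(
                f"peak list {self.source_id!r}: mz and intensity lengths differ "
                f"({self.mz.size} vs {self.intensity.size})"
            )
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise FormatError(f"peak list {self.source_id!r}: mz not strictly ascending")
        if np.any(self.intensity < 0):
            raise FormatError(f"peak list {self.source_id!r}: negative intensity")
        if self.polarity not in ("positive", "negative"):
            raise FormatError(f"unknown polarity {self.polarity!r}")

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())


@dataclass
class SpectraMatrix:
    """Sample x m/z intensity matrix with replicate and class structure."""

    X: np.ndarray
    mz_axis: np.ndarray
    spectrum_ids: list[str]
    subject_of: dict[str, str]
    class_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.mz_axis = np.asarray(self.mz_axis, dtype=float)
        self.spectrum_ids = list(self.spectrum_ids)
        if self.X.ndim != 2:
            raise FormatError("X must be 2-D (spectra x variables)")
        if self.mz_axis.ndim != 1 or self.mz_axis.size != self.X.shape[1]:
            raise FormatError("mz_axis length must equal number of columns")
        if self.mz_axis.size > 1 and np.any(np.diff(self.mz_axis) <= 0):
            raise FormatError("mz_axis must be strictly ascending")
        if len(self.spectrum_ids) != self.X.shape[0]:
            raise FormatError("spectrum_ids length must equal number of rows")
        if len(set(self.spectrum_ids)) != len(self.spectrum_ids):
            raise FormatError("spectrum ids must be unique")
        missing = [s for s in self.spectrum_ids if s not in self.subject_of]
        if missing:
            raise ConsistencyError(f"spectra without subject mapping: {missing[:5]}")
        if self.class_of is not None:
            unknown = [s for s in self.subjects if s not in self.class_of]
            if unknown:
                raise ConsistencyError(f"subjects without class label: {unknown[:5]}")

    # -- shape & structure ------------------------------------------------
    @property
    def n_spectra(self) -> int:
        return self.X.shape[0]

    @property
    def n_variables(self) -> int:
        return self.X.shape[1]

    @property
    def subjects(self) -> list[str]:
        """Unique subject ids in order of first appearance."""
        seen: dict[str, None] = {}
        for sid in self.spectrum_ids:
            seen.setdefault(self.subject_of[sid], None)
        return list(seen)

    def labels(self) -> np.ndarray:
        """Per-spectrum class labels (requires ``class_of``)."""
        if self.class_of is None:
            raise ConsistencyError("matrix has no class labels")
        return np.array(
            [self.class_of[self.subject_of[sid]] for sid in self.spectrum_ids]
        )

    def classes(self) -> list[str]:
        if self.class_of is None:
            raise ConsistencyError("matrix has no class labels")
        return sorted(set(self.class_of.values()))

    def subject_ids_per_row(self) -> np.ndarray:
        return np.array([self.subject_of[sid] for sid in self.spectrum_ids])

    def column_index(self, mz: float) -> int:
        """Index of the grid column whose label equals ``mz`` (exact match)."""
        hits = np.flatnonzero(np.isclose(self.mz_axis, mz, rtol=0, atol=1e-9))
        if hits.size != 1:
            raise KeyError(f"m/z {mz} not on the grid")
        return int(hits[0])

    def subset(self, rows: Sequence[int]) -> "SpectraMatrix":
        rows = np.asarray(rows, dtype=int)
        ids = [self.spectrum_ids[i] for i in rows]
        sub = {sid: self.subject_of[sid] for sid in ids}
        cls = None
        if self.class_of is not None:
            keep = {sub[sid] for sid in ids}
            cls = {s: c for s, c in self.class_of.items() if s in keep}
        return SpectraMatrix(self.X[rows], self.mz_axis.copy(), ids, sub, cls)

    def with_class_of(self, class_of: dict[str, str]) -> "SpectraMatrix":
        return replace(self, X=self.X.copy(), class_of=dict(class_of))


# -- CSV dialect -----------------------------------------------------------
# Header: first field is an id column label, remaining fields are m/z values.
# One row per spectrum, first field the spectrum id.  Label CSV: subject,class.


def read_matrix_csv(
    path: str | Path,
    label_path: str | Path | None = None,
    subject_path: str | Path | None = None,
) -> SpectraMatrix:
    """Read a spectra matrix from CSV, optionally with labels and replicate map.

    The header row carries the m/z values; columns are reordered ascending if
    needed.  Missing cells are an error, never silently zero.  Without a
    replicate map each spectrum is its own subject.
    """
    try:
        frame = pd.read_csv(path, index_col=0, header=0,
                            float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed CSV ({exc})") from exc
    try:
        mz = np.array([float(c) for c in frame.columns])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric m/z header") from exc
    values = frame.to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = frame.index[np.isnan(values).any(axis=1)][:5].tolist()
        raise FormatError(f"{path}: missing cells in rows {bad}")
    order = np.argsort(mz, kind="stable")
    mz = mz[order]
    values = values[:, order]
    ids = [str(i) for i in frame.index]

    subject_of = {sid: sid for sid in ids}
    if subject_path is not None:
        rep = pd.read_csv(subject_path, header=0)
        if rep.shape[1] < 2:
            raise FormatError(f"{subject_path}: expected spectrum_id,subject_id columns")
        mapping = dict(zip(rep.iloc[:, 0].astype(str), rep.iloc[:, 1].astype(str)))
        unknown = [sid for sid in mapping if sid not in subject_of]
        if unknown:
            raise ConsistencyError(
                f"{subject_path}: replicate map references unknown spectra {unknown[:5]}"
            )
        subject_of.update(mapping)

    class_of = None
    if label_path is not None:
        lab = pd.read_csv(label_path, header=0)
        if lab.shape[1] < 2:
            raise FormatError(f"{label_path}: expected subject_id,class columns")
        class_of = dict(zip(lab.iloc[:, 0].astype(str), lab.iloc[:, 1].astype(str)))
        known = set(subject_of.values())
        unknown = [s for s in class_of if s not in known]
        if unknown:
            raise ConsistencyError(
                f"{label_path}: labels reference unknown subjects {unknown[:5]}"
            )
    return SpectraMatrix(values, mz, ids, subject_of, class_of)


def write_matrix_csv(
    m: SpectraMatrix,
    path: str | Path,
    label_path: str | Path | None = None,
    subject_path: str | Path | None = None,
) -> None:
    """Write a matrix (and optionally labels / replicate map) in the CSV dialect."""
    frame = pd.DataFrame(m.X, index=pd.Index(m.spectrum_ids, name="spectrum_id"),
                         columns=[repr(float(v)) for v in m.mz_axis])
    frame.to_csv(path)
    if label_path is not None:
        if m.class_of is None:
            raise ConsistencyError("matrix has no class labels to write")
        pd.DataFrame(
            {"subject_id": list(m.class_of), "class": list(m.class_of.values())}
        ).to_csv(label_path, index=False)
    if subject_path is not None:
        pd.DataFrame(
            {"spectrum_id": m.spectrum_ids,
             "subject_id": [m.subject_of[s] for s in m.spectrum_ids]}
        ).to_csv(subject_path, index=False)


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"


def _decode_binary_array(elem) -> np.ndarray:
    import base64
    import zlib

    dtype = np.float64
    compressed = False
    for cv in elem.iter(f"{_MZML_NS}cvParam"):
        name = cv.get("name", "")
        if name == "32-bit float":
            dtype = np.float32
        elif name == "zlib compression":
            compressed = True
    binary = elem.find(f"{_MZML_NS}binary")
    raw = base64.b64decode((binary.text or "").strip())
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path) -> list[PeakList]:
    """Read centroided scans from an mzML file as peak lists.

    A direct XML reader (64/32-bit float arrays, optional zlib compression).
    Profile-mode scans are rejected: binning assumes centroided data.
    """
    from lxml import etree

    out: list[PeakList] = []
    tree = etree.parse(str(path))
    for spec in tree.iter(f"{_MZML_NS}spectrum"):
        names = {cv.get("name", "") for cv in spec.iter(f"{_MZML_NS}cvParam")}
        if "profile spectrum" in names:
            raise FormatError(
                f"{path}: scan {spec.get('id')} is profile mode; "
                "only centroided scans are supported"
            )
        polarity = "negative" if "negative scan" in names else "positive"
        mz = inten = None
        for arr in spec.iter(f"{_MZML_NS}binaryDataArray"):
            arr_names = {cv.get("name", "") for cv in arr.iter(f"{_MZML_NS}cvParam")}
            if "m/z array" in arr_names:
                mz = _decode_binary_array(arr)
            elif "intensity array" in arr_names:
                inten = _decode_binary_array(arr)
        if mz is None or inten is None:
            raise FormatError(f"{path}: scan {spec.get('id')} lacks m/z or "
                              "intensity arrays")
        order = np.argsort(mz, kind="stable")
        out.append(PeakList(mz[order], inten[order], polarity=polarity,
                            source_id=str(spec.get("id", len(out)))))
    return out


def bin_peaklists(
    peaklists: Sequence[PeakList],
    mz_min: float = 50.0,
    mz_max: float = 1000.0,
    bin_width: float = 1.0,
    spectrum_ids: Sequence[str] | None = None,
    subject_of: dict[str, str] | None = None,
    class_of: dict[str, str] | None = None,
) -> SpectraMatrix:
    """Sum peak intensities into half-open bins [mz_min + k*w, mz_min + (k+1)*w).

    Peaks at or above the upper edge of the last bin are dropped and counted in
    the log.  On a unit-width grid starting at an integer, columns are labelled
    by the integer lower edge (so a peak at 118.3 lands in variable "118"),
    matching the unit-resolution variable convention of ion-trap data;
    otherwise labels are bin centers.
    """
    if mz_max <= mz_min:
        raise ValueError(f"mz_max ({mz_max}) must exceed mz_min ({mz_min})")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.floor((mz_max - mz_min) / bin_width + 1e-9))
    if n_bins < 1:
        raise ValueError("grid is empty: bin_width exceeds the m/z range")
    upper = mz_min + n_bins * bin_width
    if bin_width == 1.0 and abs(mz_min - round(mz_min)) < 1e-9:
        axis = round(mz_min) + np.arange(n_bins, dtype=float)
    else:
        axis = mz_min + (np.arange(n_bins) + 0.5) * bin_width

    X = np.zeros((len(peaklists), n_bins))
    n_dropped = 0
    dropped_intensity = 0.0
    for i, pl in enumerate(peaklists):
        if pl.mz.size == 0:
            continue
        k = np.floor((pl.mz - mz_min) / bin_width).astype(int)
        in_range = (pl.mz >= mz_min) & (pl.mz < upper)
        n_dropped += int((~in_range).sum())
        dropped_intensity += float(pl.intensity[~in_range].sum())
        X[i] = np.bincount(k[in_range], weights=pl.intensity[in_range],
                           minlength=n_bins)
    if n_dropped:
        logger.info(
            "bin_peaklists: dropped %d peaks outside [%g, %g) "
            "(total intensity %.6g)", n_dropped, mz_min, upper, dropped_intensity
        )
    if spectrum_ids is None:
        spectrum_ids = [pl.source_id or f"spectrum_{i}" for i, pl in enumerate(peaklists)]
    if subject_of is None:
        subject_of = {sid: sid for sid in spectrum_ids}
    return SpectraMatrix(X, axis, list(spectrum_ids), dict(subject_of), class_of)


def average_replicates(m: SpectraMatrix) -> SpectraMatrix:
    """Collapse replicate spectra to one arithmetic-mean row per subject.

    Output rows follow the subjects' order of first appearance and the
    replicate map becomes the identity.
    """
    subjects = m.subjects
    rows = np.empty((len(subjects), m.n_variables))
    per_row_subject = m.subject_ids_per_row()
    for i, subj in enumerate(subjects):
        rows[i] = m.X[per_row_subject == subj].mean(axis=0)
    cls = None
    if m.class_of is not None:
        cls = {s: m.class_of[s] for s in subjects}
    return SpectraMatrix(rows, m.mz_axis.copy(), list(subjects),
                         {s: s for s in subjects}, cls)
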