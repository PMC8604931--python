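"""Match selected m/z variables to candidate metabolites in a local table.

Queries are compared with the expected adduct m/z of each compound
(M+H: monoisotopic mass + 1.007276 Da; M-H: mass - 1.007276 Da) under an
absolute tolerance.  The table is user-supplied CSV — no live database
queries.  A small bundled demo table (synthetic extract of literature
monoisotopic masses, documentation use only) ships with the package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

PROTON_MASS = 1.007276  # Da

__all__ = ["CompoundTable", "read_compound_table", "demo_compound_table",
           "annotate_mz", "PROTON_MASS"]


@dataclass
class CompoundTable:
    """Local compound catalogue: name, monoisotopic mass (Da), compound class."""

    frame: pd.DataFrame  # columns: name, monoisotopic_mass, class

    def __post_init__(self) -> None:
        required = {"name", "monoisotopic_mass", "class"}
        if not required.issubset(self.frame.columns):
            raise FormatError(
                f"compound table needs columns {sorted(required)}, "
                f"got {list(self.frame.columns)}"
            )
        if self.frame["name"].duplicated().any():
            dup = self.frame["name"][self.frame["name"].duplicated()].tolist()
            raise FormatError(f"duplicate compound names: {dup[:5]}")
        if (self.frame["monoisotopic_mass"] <= 0).any():
            raise FormatError("monoisotopic masses must be positive")

    def __len__(self) -> int:
        return len(self.frame)


def read_compound_table(path: str | Path) -> CompoundTable:
    return CompoundTable(pd.read_csv(path))


def demo_compound_table() -> CompoundTable:
    """Tiny bundled table for documentation examples (not a real database)."""
    with resources.files("psiscreen.data").joinpath("demo_compounds.csv").open() as fh:
        return CompoundTable(pd.read_csv(fh))


@dataclass
class AnnotationReport:
    """Hits per query plus the queries that matched nothing."""

    hits: pd.DataFrame  # query_mz, name, expected_mz, error, class
    unmatched: list[float]
    adduct: str
    tol: float


def annotate_mz(
    mz_values,
    table: CompoundTable,
    adduct: str = "M+H",
    tol: float = 0.01,
) -> AnnotationReport:
    """All compounds whose adduct m/z lies within ``tol`` of each query.

    Unit-resolution queries (all integral) against a sub-0.5 Th tolerance are
    unlikely to match by construction; a warning flags that mismatch of
    precisions rather than silently returning an empty report.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if adduct == "M+H":
        shift = PROTON_MASS
    elif adduct in ("M-H", "M−H"):
        shift = -PROTON_MASS
    else:
        raise ValueError(f"unknown adduct {adduct!r}; use 'M+H' or 'M-H'")
    queries = [float(v) for v in np.atleast_1d(np.asarray(mz_values, dtype=float))]
    if queries and tol < 0.5 and all(abs(q - round(q)) < 1e-9 for q in queries):
        warnings.warn(
            "queries are unit-resolution integers but the tolerance is "
            f"{tol} Th; matches will be rare — consider a wider tolerance "
            "or centroided query masses"
        )
    expected = table.frame["monoisotopic_mass"].to_numpy(dtype=float) + shift
    records = []
    unmatched = []
    for q in queries:
        err = expected - q
        hit_rows = np.flatnonzero(np.abs(err) <= tol + 1e-12)
        if hit_rows.size == 0:
            unmatched.append(q)
            continue
        for i in hit_rows:
            records.append({
                "query_mz": q,
                "name": table.frame["name"].iloc[i],
                "expected_mz": expected[i],
                "error": float(err[i]),
                "class": table.frame["class"].iloc[i],
            })
    hits = pd.DataFrame.from_records(
        records, columns=["query_mz", "name", "expected_mz", "error", "class"]
    )
    return AnnotationReport(hits, unmatched, adduct, tol)
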