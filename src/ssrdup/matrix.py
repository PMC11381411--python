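"""Binary SSR band matrices and their on-disk form.

A band matrix records, for every accession (genebank entry) and every amplified
SSR fragment, whether the fragment was observed (``present``), not observed
(``absent``), or could not be interpreted (``missing``).  Dominant presence /
absence scoring sidesteps allele-dosage calling in autotetraploid crops such as
potato: each fragment is a column, regardless of which alleles at a locus
produced it.

Cells are stored as a compact ``int8`` array with codes ``1`` (present), ``0``
(absent) and ``-1`` (missing).  Files are plain CSV/TSV: first column the
accession id, remaining columns one per fragment, cells written with
configurable tokens (``1`` / ``0`` / ``?`` by default; ``NA`` and the empty
string are also read as missing).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PRESENT: int = 1
ABSENT: int = 0
MISSING: int = -1

CLONAL_TYPES = ("landrace", "improved variety", "breeding line", "unknown")


class BandMatrixError(ValueError):
    """Raised for malformed band-matrix files or inconsistent matrices."""


@dataclass(frozen=True)
class Dialect:
    """Token conventions of a band-matrix file.

    Parameters
    ----------
    sep
        Column separator ("," for CSV, "\\t" for TSV).
    present, absent
        Tokens read/written for the two scored states.
    missing
        Tokens accepted as missing on read; the first is used on write.
    """

    sep: str = ","
    present: str = "1"
    absent: str = "0"
    missing: tuple[str, ...] = ("?", "NA", "")


@dataclass(frozen=True)
class AccessionRecord:
    """Passport metadata for one accession."""

    accession_id: str
    name: str = ""
    collection: str = ""
    country: str = ""
    clonal_type: str = "unknown"

    def __post_init__(self) -> None:
        if not self.accession_id:
            raise BandMatrixError("accession_id must be non-empty")
        if self.clonal_type not in CLONAL_TYPES:
            raise BandMatrixError(
                f"clonal_type {self.clonal_type!r} not in {CLONAL_TYPES}"
            )


@dataclass
class ValidationReport:
    """Matrix-level summary counts plus human-readable problems."""

    n_accessions: int
    n_fragments: int
    n_missing_cells: int
    n_polymorphic: int
    n_monomorphic: int
    problems: list[str] = field(default_factory=list)


class BandMatrix:
    """Accessions x fragments matrix of dominant band scores.

    Parameters
    ----------
    accession_ids
        Ordered unique row identifiers.
    fragment_ids
        Ordered unique column identifiers.  By convention
        ``"<marker>_<size>"`` when the amplifying marker and fragment size
        are known.
    cells
        ``(n_accessions, n_fragments)`` array of codes in
        ``{PRESENT, ABSENT, MISSING}``.
    loci
        Optional per-fragment locus/marker label (same length as
        ``fragment_ids``).  Only the simulator and reports use the grouping;
        distances are computed per band.
    """

    def __init__(
        self,
        accession_ids: Sequence[str],
        fragment_ids: Sequence[str],
        cells: np.ndarray,
        loci: Sequence[str] | None = None,
    ) -> None:
        self.accession_ids = list(accession_ids)
        self.fragment_ids = list(fragment_ids)
        self.cells = np.asarray(cells, dtype=np.int8)
        self.loci = list(loci) if loci is not None else None
        self._check()

    def _check(self) -> None:
        n, m = len(self.accession_ids), len(self.fragment_ids)
        if n < 2:
            raise BandMatrixError("a band matrix needs at least 2 accessions")
        if m < 1:
            raise BandMatrixError("a band matrix needs at least 1 fragment")
        if len(set(self.accession_ids)) != n:
            dupes = _duplicates(self.accession_ids)
            raise BandMatrixError(f"duplicated accession ids: {dupes}")
        if len(set(self.fragment_ids)) != m:
            dupes = _duplicates(self.fragment_ids)
            raise BandMatrixError(f"duplicated fragment ids: {dupes}")
        if self.cells.shape != (n, m):
            raise BandMatrixError(
                f"cell array shape {self.cells.shape} != ({n}, {m})"
            )
        bad = ~np.isin(self.cells, (PRESENT, ABSENT, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise BandMatrixError(
                f"invalid cell code {int(self.cells[i, j])} at "
                f"({self.accession_ids[i]}, {self.fragment_ids[j]})"
            )
        if self.loci is not None and len(self.loci) != m:
            raise BandMatrixError("loci must have one label per fragment")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BandMatrix):
            return NotImplemented
        return (
            self.accession_ids == other.accession_ids
            and self.fragment_ids == other.fragment_ids
            and np.array_equal(self.cells, other.cells)
        )

    def subset_fragments(self, index: Sequence[int]) -> "BandMatrix":
        """Matrix restricted to (or resampled over) the given column indices."""
        index = list(index)
        frag = [f"{self.fragment_ids[j]}#{k}" for k, j in enumerate(index)]
        return BandMatrix(self.accession_ids, frag, self.cells[:, index])

    def to_frame(self, dialect: Dialect = Dialect()) -> pd.DataFrame:
        """Token DataFrame (index = accession ids) as written to disk."""
        tokens = np.empty(self.cells.shape, dtype=object)
        tokens[self.cells == PRESENT] = dialect.present
        tokens[self.cells == ABSENT] = dialect.absent
        tokens[self.cells == MISSING] = dialect.missing[0]
        return pd.DataFrame(
            tokens, index=self.accession_ids, columns=self.fragment_ids
        )


def _duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for x in items:
        if x in seen and x not in out:
            out.append(x)
        seen.add(x)
    return out


def read_band_matrix(path: str | Path, dialect: Dialect = Dialect()) -> BandMatrix:
    """Parse a band-matrix file.

    The first header field names the id column and is ignored; every other
    header field is a fragment id.  Cell tokens outside the dialect raise a
    parse error naming the offending row and column; rows of the wrong length
    raise a parse error naming the row.
    """
    text = Path(path).read_text()
    return _parse_band_matrix(text, dialect, source=str(path))


def _parse_band_matrix(text: str, dialect: Dialect, source: str = "<string>") -> BandMatrix:
    reader = csv.reader(io.StringIO(text), delimiter=dialect.sep)
    rows = [row for row in reader if row and any(tok.strip() for tok in row)]
    if len(rows) < 2:
        raise BandMatrixError(f"{source}: need a header and at least one data row")
    header = [tok.strip() for tok in rows[0]]
    fragment_ids = header[1:]
    width = len(header)

    decode = {dialect.present: PRESENT, dialect.absent: ABSENT}
    for tok in dialect.missing:
        decode[tok] = MISSING

    accession_ids: list[str] = []
    cells = np.empty((len(rows) - 1, len(fragment_ids)), dtype=np.int8)
    for r, row in enumerate(rows[1:], start=2):
        # Trailing empty field from a trailing separator is tolerated.
        if len(row) == width + 1 and row[-1].strip() == "":
            row = row[:-1]
        if len(row) != width:
            raise BandMatrixError(
                f"{source}: row {r} has {len(row)} fields, expected {width}"
            )
        accession_ids.append(row[0].strip())
        for c, tok in enumerate(row[1:]):
            tok = tok.strip()
            try:
                cells[r - 2, c] = decode[tok]
            except KeyError:
                raise BandMatrixError(
                    f"{source}: unknown token {tok!r} at row {r}, "
                    f"column {fragment_ids[c]!r}"
                ) from None
    return BandMatrix(accession_ids, fragment_ids, cells)


def write_band_matrix(
    m: BandMatrix, path: str | Path, dialect: Dialect = Dialect()
) -> None:
    """Write ``m`` so that :func:`read_band_matrix` round-trips it exactly."""
    frame = m.to_frame(dialect)
    frame.to_csv(path, sep=dialect.sep, index_label="accession_id")


def validate_matrix(m: BandMatrix) -> ValidationReport:
    """Summarise a matrix: missingness and the polymorphic/monomorphic split.

    A fragment is *polymorphic* when its non-missing cells include both the
    present and the absent state; otherwise (all equal, or all missing) it is
    monomorphic.  The two counts always partition the fragments.
    """
    present = m.cells == PRESENT
    absent = m.cells == ABSENT
    poly = present.any(axis=0) & absent.any(axis=0)
    n_poly = int(poly.sum())
    report = ValidationReport(
        n_accessions=m.n_accessions,
        n_fragments=m.n_fragments,
        n_missing_cells=int((m.cells == MISSING).sum()),
        n_polymorphic=n_poly,
        n_monomorphic=m.n_fragments - n_poly,
    )
    all_missing_rows = np.nonzero((m.cells == MISSING).all(axis=1))[0]
    for i in all_missing_rows:
        report.problems.append(f"accession {m.accession_ids[i]} is entirely missing")
    all_missing_cols = np.nonzero((m.cells == MISSING).all(axis=0))[0]
    for j in all_missing_cols:
        report.problems.append(f"fragment {m.fragment_ids[j]} is entirely missing")
    return report


def read_metadata(path: str | Path) -> dict[str, AccessionRecord]:
    """Read the passport sidecar CSV keyed by accession_id."""
    frame = pd.read_csv(path, dtype=str).fillna("")
    required = {"accession_id"}
    if not required <= set(frame.columns):
        raise BandMatrixError(f"metadata file must have columns {sorted(required)}")
    records: dict[str, AccessionRecord] = {}
    for row in frame.itertuples(index=False):
        rec = AccessionRecord(
            accession_id=row.accession_id,
            name=getattr(row, "name", "") or "",
            collection=getattr(row, "collection", "") or "",
            country=getattr(row, "country", "") or "",
            clonal_type=getattr(row, "clonal_type", "") or "unknown",
        )
        if rec.accession_id in records:
            raise BandMatrixError(f"duplicated metadata for {rec.accession_id}")
        records[rec.accession_id] = rec
    return records


def write_metadata(
    records: Mapping[str, AccessionRecord], path: str | Path
) -> None:
    frame = pd.DataFrame(
        [
            {
                "accession_id": r.accession_id,
                "name": r.name,
                "collection": r.collection,
                "country": r.country,
                "clonal_type": r.clonal_type,
            }
            for r in records.values()
        ]
    )
    frame.to_csv(path, index=False)
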