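"""Domain types, dataset validation and report (de)serialization.

The pipeline's unit of data is a :class:`PairedSample`: one subject measured
for serum 25-hydroxyvitamin D by two assays — a chemiluminescence immunoassay
(CLIA) and liquid chromatography–tandem mass spectrometry (LC-MS/MS) — plus
age and sex.  The inter-method difference ``diff = lcms - clia`` is always
recomputed on load and never trusted from a file.

Reports produced by the analysis stages serialize to a single hierarchical
interchange format (JSON) with a schema-version field, so saved fuzzy models
remain loadable across package versions.
"""

from __future__ import annotations

import enum
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Iterable, Mapping

import pandas as pd

from .exceptions import SchemaError, ValidationError

SCHEMA_VERSION = 1
PACKAGE_VERSION = "0.1.0"

FIELDS = ("sample_id", "age", "sex", "clia", "lcms")


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


#: case-insensitive aliases accepted for the sex column
DEFAULT_SEX_ALIASES: dict[str, Sex] = {
    "male": Sex.male, "m": Sex.male, "0": Sex.male,
    "female": Sex.female, "f": Sex.female, "1": Sex.female,
}


@dataclass(frozen=True)
class SexEncoding:
    """Numeric coding used when sex enters a numeric model matrix.

    The source data carry sex as a category; any model that needs a number
    goes through this mapping.  Predictions must be invariant to the choice
    (e.g. swapping 0/1), which the fuzzy-model tests verify.
    """

    male_code: float = 0.0
    female_code: float = 1.0

    def __post_init__(self) -> None:
        if self.male_code == self.female_code:
            raise ValidationError("male_code and female_code must differ")

    def encode(self, sex: Sex) -> float:
        return self.female_code if sex is Sex.female else self.male_code


@dataclass(frozen=True)
class PairedSample:
    """One subject: demographics plus both assay results (ng/mL)."""

    sample_id: str
    age: float
    sex: Sex
    clia: float
    lcms: float
    diff: float = field(init=False)

    def __post_init__(self) -> None:
        problems = []
        if not (0 < self.age < 120) or not math.isfinite(self.age):
            problems.append(f"age {self.age!r} outside (0, 120)")
        for name in ("clia", "lcms"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                problems.append(f"{name} {v!r} not a finite non-negative value")
        if problems:
            raise ValidationError(
                f"invalid sample {self.sample_id!r}", diagnostics=problems
            )
        object.__setattr__(self, "diff", self.lcms - self.clia)


@dataclass(frozen=True)
class Dataset:
    """Ordered, id-unique collection of paired samples."""

    samples: tuple[PairedSample, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def diffs(self) -> list[float]:
        return [s.diff for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "age": [s.age for s in self.samples],
                "sex": [s.sex.value for s in self.samples],
                "clia": [s.clia for s in self.samples],
                "lcms": [s.lcms for s in self.samples],
                "diff": [s.diff for s in self.samples],
            }
        )


def _resolve_sex(raw: Any, aliases: Mapping[str, Sex]) -> Sex:
    key = str(raw).strip().lower()
    # numeric spellings like "1.0" reduce to their integer alias
    if key.endswith(".0"):
        key = key[:-2]
    if key not in aliases:
        raise ValueError(f"unrecognized sex value {raw!r}")
    return aliases[key]


def read_dataset(
    path: str | Path,
    col_map: Mapping[str, str] | None = None,
    sex_aliases: Mapping[str, Sex] | None = None,
    provenance: str | None = None,
) -> Dataset:
    """Read a delimited table (CSV or TSV, sniffed) of paired samples.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    col_map
        Maps the canonical field names (``sample_id, age, sex, clia, lcms``)
        to the file's column headers; identity by default.
    sex_aliases
        Case-insensitive spellings accepted for the sex column
        (default: male/m/0 and female/f/1).

    Raises
    ------
    SchemaError
        A mapped column is absent from the header.
    ValidationError
        One or more rows fail validation; diagnostics carry 1-based line
        numbers (header = line 1).
    """
    path = Path(path)
    col_map = dict(col_map or {})
    aliases = dict(sex_aliases or DEFAULT_SEX_ALIASES)
    table = pd.read_csv(path, sep=None, engine="python", dtype=str,
                        skipinitialspace=True)

    columns = {}
    for canon in FIELDS:
        source = col_map.get(canon, canon)
        if source not in table.columns:
            raise SchemaError(
                f"required column {source!r} (for field {canon!r}) "
                f"not in header {list(table.columns)}"
            )
        columns[canon] = source

    samples: list[PairedSample] = []
    diagnostics: list[str] = []
    for idx, row in table.iterrows():
        line = idx + 2  # header occupies line 1
        try:
            sex = _resolve_sex(row[columns["sex"]], aliases)
            sample = PairedSample(
                sample_id=str(row[columns["sample_id"]]).strip(),
                age=float(row[columns["age"]]),
                sex=sex,
                clia=float(row[columns["clia"]]),
                lcms=float(row[columns["lcms"]]),
            )
        except ValidationError as exc:
            diagnostics.extend(f"line {line}: {d}" for d in exc.diagnostics)
        except (TypeError, ValueError) as exc:
            diagnostics.append(f"line {line}: {exc}")
        else:
            samples.append(sample)
    if diagnostics:
        raise ValidationError(f"{len(diagnostics)} invalid row(s) in {path}",
                              diagnostics=diagnostics)
    return Dataset(samples=tuple(samples), provenance=provenance or str(path))


def write_dataset(data: Dataset, path: str | Path) -> None:
    """Write a dataset as a CSV with the canonical column names."""
    data.to_frame().to_csv(path, index=False)


def file_checksum(path: str | Path) -> str:
    """SHA-256 of a file, for run manifests."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# report serialization
# ---------------------------------------------------------------------------

_REPORT_REGISTRY: dict[str, Callable[[dict], Any]] = {}


def register_report(kind: str):
    """Class decorator registering a result type for report round-trips.

    The class must provide ``to_dict()`` and a classmethod ``from_dict``.
    """

    def deco(cls):
        cls.report_kind = kind
        _REPORT_REGISTRY[kind] = cls.from_dict
        return cls

    return deco


def _assert_finite(obj: Any, trail: str = "report") -> None:
    if isinstance(obj, float) and not math.isfinite(obj):
        raise ValidationError(f"non-finite value at {trail}: {obj!r}")
    elif isinstance(obj, dict):
        for k, v in obj.items():
            _assert_finite(v, f"{trail}.{k}")
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            _assert_finite(v, f"{trail}[{i}]")


def write_report(report: Any, path: str | Path,
                 source_checksum: str | None = None) -> None:
    """Serialize a result object to a JSON report file.

    Refuses reports containing non-finite numbers: NaN/inf almost always
    signal an upstream degeneracy that should be handled, not archived.
    """
    kind = getattr(report, "report_kind", None)
    if kind is None or not hasattr(report, "to_dict"):
        raise ValidationError(
            f"object of type {type(report).__name__} is not a serializable report"
        )
    payload = report.to_dict()
    _assert_finite(payload)
    envelope = {
        "schema_version": SCHEMA_VERSION,
        "package_version": PACKAGE_VERSION,
        "kind": kind,
        "source_checksum": source_checksum,
        "payload": payload,
    }
    with open(path, "w") as fh:
        json.dump(envelope, fh, indent=2, allow_nan=False)
        fh.write("\n")


def read_report(path: str | Path) -> Any:
    """Inverse of :func:`write_report`; returns the original result object."""
    # result modules self-register on import
    from . import agreement, fcm, fis, validation  # noqa: F401

    with open(path) as fh:
        envelope = json.load(fh)
    kind = envelope.get("kind")
    if kind not in _REPORT_REGISTRY:
        raise ValidationError(f"unknown report kind {kind!r} in {path}")
    return _REPORT_REGISTRY[kind](envelope["payload"])


def dataset_from_rows(rows: Iterable[tuple], provenance: str = "") -> Dataset:
    """Build a dataset from (sample_id, age, sex, clia, lcms) tuples."""
    samples = tuple(
        PairedSample(str(sid), float(age),
                     sex if isinstance(sex, Sex) else Sex(str(sex)),
                     float(clia), float(lcms))
        for sid, age, sex, clia, lcms in rows
    )
    return Dataset(samples=samples, provenance=provenance)
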