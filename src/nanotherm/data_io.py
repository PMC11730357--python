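"""Reading, validating and de-duplicating labeled thermostability datasets.

A labeled dataset is a table with columns ``id``, ``sequence``, ``tm``,
``method`` (and optionally ``aligned``, ``source``). Apparent melting
temperatures are in degrees Celsius; the loader enforces a physical
plausibility band of 15-110 degC. Sequences may additionally carry a
149-column alignment on the fixed antibody numbering scheme; degapping the
alignment must reproduce the raw sequence.

When the same sequence has been measured more than once (a frequent situation
when aggregating literature data measured with different techniques), a single
record is retained per sequence according to an ordered preference over
experimental methods, by default nanoDSF > DSF > DSC > CD > other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ConfigError, DatasetError, FormatError
from .scales import AA20, AHO_LENGTH, ALPHABET, GAP
from .templates import GERMLINE_TEMPLATES

#: canonical experimental-method labels
METHODS: tuple[str, ...] = ("nanoDSF", "DSF", "DSC", "CD", "other")

#: default duplicate-resolution preference (most consistent technique first)
DEFAULT_PREFERENCE: tuple[str, ...] = METHODS

#: physical plausibility band for apparent melting temperatures (degC)
TM_MIN, TM_MAX = 15.0, 110.0

_METHOD_ALIASES = {
    "nanodsf": "nanoDSF",
    "nano-dsf": "nanoDSF",
    "dsf": "DSF",
    "sypro-orange dsf": "DSF",
    "dsc": "DSC",
    "cd": "CD",
    "other": "other",
    "others": "other",
}


def normalize_method(raw: str) -> tuple[str, bool]:
    """Map a free-text method string onto the canonical labels.

    Returns ``(label, known)`` where ``known`` is False when the string was
    not recognized and fell back to ``"other"``.
    """
    key = str(raw).strip().lower()
    if key in _METHOD_ALIASES:
        return _METHOD_ALIASES[key], True
    return "other", False


@dataclass
class ThermoRecord:
    """One labeled nanobody measurement."""

    id: str
    sequence: str
    tm: float
    method: str = "other"
    source: str = ""
    aligned: str | None = None
    cluster: int | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            self.method, _ = normalize_method(self.method)
        if not (TM_MIN <= self.tm <= TM_MAX):
            raise DatasetError(
                f"record {self.id!r}: tm={self.tm} degC outside the "
                f"plausibility band [{TM_MIN}, {TM_MAX}]"
            )
        if any(aa not in AA20 for aa in self.sequence):
            bad = next(aa for aa in self.sequence if aa not in AA20)
            raise DatasetError(f"record {self.id!r}: invalid residue {bad!r}")
        if self.aligned is not None:
            validate_aligned(self.aligned)
            if self.aligned.replace(GAP, "") != self.sequence:
                raise AlignmentError(
                    f"record {self.id!r}: degapped alignment does not "
                    "reproduce the sequence"
                )


@dataclass
class Dataset:
    """Ordered collection of :class:`ThermoRecord` with provenance text."""

    records: list[ThermoRecord] = field(default_factory=list)
    provenance: str = ""
    n_unknown_methods: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def aligned(self) -> list[str]:
        missing = [r.id for r in self.records if r.aligned is None]
        if missing:
            raise AlignmentError(f"records without alignment: {missing[:5]}")
        return [r.aligned for r in self.records]  # type: ignore[misc]

    @property
    def tms(self) -> np.ndarray:
        return np.array([r.tm for r in self.records], dtype=float)

    @property
    def methods(self) -> list[str]:
        return [r.method for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sequence": self.sequences,
                "aligned": [r.aligned or "" for r in self.records],
                "tm": self.tms,
                "method": self.methods,
                "source": [r.source for r in self.records],
                "cluster": [r.cluster if r.cluster is not None else -1
                            for r in self.records],
            }
        )


_MANDATORY = ("id", "sequence", "tm", "method")


def read_thermo_table(path: str | Path, dialect: str | None = None) -> Dataset:
    """Read a labeled thermostability table (CSV, TSV or XLSX).

    Column headers are matched case-insensitively; ``id``, ``sequence``,
    ``tm`` and ``method`` are mandatory, ``aligned``/``source``/``cluster``
    optional. Unknown method strings are normalized to ``"other"``; the count
    of such rows is stored on ``Dataset.n_unknown_methods`` and warned about.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if dialect is None:
        suffix = path.suffix.lower()
        dialect = {".csv": "csv", ".tsv": "tsv", ".xlsx": "xlsx"}.get(suffix, "csv")
    if dialect == "xlsx":
        df = pd.read_excel(path)
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
    elif dialect == "csv":
        df = pd.read_csv(path)
    else:
        raise ConfigError(f"unknown dialect {dialect!r}")

    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in _MANDATORY:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path.name}")
    if len(df) == 0:
        raise DatasetError(f"empty table: {path.name}")

    records: list[ThermoRecord] = []
    n_unknown = 0
    for i, row in df.iterrows():
        try:
            tm = float(row["tm"])
        except (TypeError, ValueError) as exc:
            raise DatasetError(f"row {i}: non-numeric tm {row['tm']!r}") from exc
        method, known = normalize_method(row["method"])
        if not known:
            n_unknown += 1
        aligned = None
        if "aligned" in df.columns:
            val = row["aligned"]
            if isinstance(val, str) and val.strip():
                aligned = val.strip()
        cluster = None
        if "cluster" in df.columns and not pd.isna(row["cluster"]):
            c = int(row["cluster"])
            cluster = c if c >= 0 else None
        records.append(
            ThermoRecord(
                id=str(row["id"]).strip(),
                sequence=str(row["sequence"]).strip().upper(),
                tm=tm,
                method=method,
                source=str(row.get("source", "") or ""),
                aligned=aligned,
                cluster=cluster,
            )
        )
    if n_unknown:
        warnings.warn(f"{n_unknown} rows had unrecognized method strings "
                      "(mapped to 'other')", stacklevel=2)
    return Dataset(records=records, provenance=str(path),
                   n_unknown_methods=n_unknown)


def write_thermo_table(ds: Dataset, path: str | Path) -> None:
    """Write a dataset as TSV (the normalized interchange format)."""
    ds.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read prediction-only sequences from FASTA as ``(id, sequence)`` pairs."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


@dataclass
class DuplicateGroup:
    sequence: str
    kept_id: str
    member_ids: list[str]
    tms: list[float]
    pairwise_abs_diffs: list[float]


@dataclass
class DuplicateReport:
    groups: list[DuplicateGroup]

    @property
    def mean_pairwise_abs_diff(self) -> float:
        diffs = [d for g in self.groups for d in g.pairwise_abs_diffs]
        return float(np.mean(diffs)) if diffs else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sequence": [g.sequence for g in self.groups],
                "kept_id": [g.kept_id for g in self.groups],
                "n_members": [len(g.member_ids) for g in self.groups],
                "member_ids": [",".join(g.member_ids) for g in self.groups],
                "tms": [",".join(f"{t:.2f}" for t in g.tms) for g in self.groups],
                "mean_abs_diff": [float(np.mean(g.pairwise_abs_diffs))
                                  for g in self.groups],
            }
        )


def resolve_duplicates(
    ds: Dataset,
    preference: Sequence[str] = DEFAULT_PREFERENCE,
    source_preference: Sequence[str] | None = None,
) -> tuple[Dataset, DuplicateReport]:
    """Collapse repeated measurements of the same sequence to one record.

    Within each duplicate group the retained record is the one whose method
    ranks earliest in ``preference``; ties within the same method are broken
    by ``source_preference`` (an ordered list of source strings), then by
    input order. The report lists each group together with its pairwise
    absolute Tm differences.
    """
    if not preference:
        raise ConfigError("empty method preference list")
    pref_rank = {m: i for i, m in enumerate(preference)}
    src_rank = ({s: i for i, s in enumerate(source_preference)}
                if source_preference else {})

    by_seq: dict[str, list[tuple[int, ThermoRecord]]] = {}
    for i, rec in enumerate(ds.records):
        by_seq.setdefault(rec.sequence, []).append((i, rec))

    kept: list[tuple[int, ThermoRecord]] = []
    groups: list[DuplicateGroup] = []
    for seq, members in by_seq.items():
        if len(members) == 1:
            kept.append(members[0])
            continue
        best = min(
            members,
            key=lambda item: (
                pref_rank.get(item[1].method, len(preference)),
                src_rank.get(item[1].source, len(src_rank)),
                item[0],
            ),
        )
        kept.append(best)
        tms = [rec.tm for _, rec in members]
        diffs = [abs(tms[a] - tms[b])
                 for a in range(len(tms)) for b in range(a + 1, len(tms))]
        groups.append(
            DuplicateGroup(
                sequence=seq,
                kept_id=best[1].id,
                member_ids=[rec.id for _, rec in members],
                tms=tms,
                pairwise_abs_diffs=diffs,
            )
        )
    kept.sort(key=lambda item: item[0])
    out = Dataset(
        records=[rec for _, rec in kept],
        provenance=ds.provenance + " | duplicates resolved",
        n_unknown_methods=ds.n_unknown_methods,
    )
    return out, DuplicateReport(groups=groups)


def validate_aligned(aligned: str) -> list[int]:
    """Validate a 149-column alignment; return the gap positions (0-based).

    Raises :class:`AlignmentError` stating the observed length on a length
    mismatch, or naming the offending character and position on an invalid
    symbol.
    """
    if len(aligned) != AHO_LENGTH:
        raise AlignmentError(
            f"aligned sequence has length {len(aligned)}, expected {AHO_LENGTH}"
        )
    gaps = []
    for i, ch in enumerate(aligned):
        if ch not in ALPHABET:
            raise AlignmentError(f"invalid character {ch!r} at position {i}")
        if ch == GAP:
            gaps.append(i)
    return gaps


class NumberingBackend(Protocol):
    """Adapter interface for external antibody-numbering tools."""

    def align(self, sequence: str) -> str:  # pragma: no cover - protocol
        """Return a 149-column alignment of ``sequence`` or raise
        :class:`AlignmentError`."""
        ...


class TemplateAligner:
    """Fallback numbering backend: thread a sequence onto bundled templates.

    A query is placed on the gap pattern of every stored template whose
    residue count matches the query length; the threading with the highest
    identity to its template is returned, provided it exceeds
    ``min_identity``. Sufficient for template-derived sequences (fixtures and
    simulations); real repertoire data should use a dedicated numbering tool
    through the same adapter interface.
    """

    def __init__(self, templates: dict[str, str] | None = None,
                 min_identity: float = 0.5) -> None:
        self.templates = dict(templates or GERMLINE_TEMPLATES)
        self.min_identity = min_identity

    def align(self, sequence: str) -> str:
        best: tuple[float, str] | None = None
        for name, tmpl in self.templates.items():
            residues = [i for i, ch in enumerate(tmpl) if ch != GAP]
            if len(residues) != len(sequence):
                continue
            threaded = [GAP] * len(tmpl)
            matches = 0
            for aa, pos in zip(sequence, residues):
                threaded[pos] = aa
                if aa == tmpl[pos]:
                    matches += 1
            identity = matches / len(residues)
            if best is None or identity > best[0]:
                best = (identity, "".join(threaded))
        if best is None or best[0] < self.min_identity:
            raise AlignmentError(
                f"sequence of {len(sequence)} residues could not be placed on "
                "any stored template"
            )
        return best[1]


def number_sequence(sequence: str, backend: NumberingBackend | None = None) -> str:
    """Place a raw sequence on the 149-position scheme.

    An input that already is a valid 149-column alignment is passed through
    unchanged. Otherwise the numbering ``backend`` (default: the bundled
    :class:`TemplateAligner`) produces the alignment, which is validated and
    checked to degap back to the input.
    """
    if len(sequence) == AHO_LENGTH and GAP in sequence:
        validate_aligned(sequence)
        return sequence
    backend = backend or TemplateAligner()
    aligned = backend.align(sequence)
    validate_aligned(aligned)
    if aligned.replace(GAP, "") != sequence:
        raise AlignmentError("backend alignment does not degap to the input")
    return aligned


def align_dataset(ds: Dataset, backend: NumberingBackend | None = None) -> Dataset:
    """Fill missing alignments; drop (with a warning) unalignable records."""
    backend = backend or TemplateAligner()
    out: list[ThermoRecord] = []
    dropped: list[str] = []
    for rec in ds.records:
        if rec.aligned is not None:
            out.append(rec)
            continue
        try:
            aligned = number_sequence(rec.sequence, backend)
        except AlignmentError:
            dropped.append(rec.id)
            continue
        out.append(replace(rec, aligned=aligned))
    if dropped:
        warnings.warn(f"dropped {len(dropped)} unalignable sequences: "
                      f"{dropped[:5]}", stacklevel=2)
    return Dataset(records=out, provenance=ds.provenance,
                   n_unknown_methods=ds.n_unknown_methods)
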