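"""Readers and writers for the tabular formats the tool touches.

Four external formats are handled, all plain TSV (UTF-8, ``#`` comment
lines ignored):

* STRING ``protein.actions`` interaction dumps (columns ``item_id_a``,
  ``item_id_b``, ``mode``, ``action``, ``is_directional``, ``a_is_acting``,
  ``score``);
* identifier alias tables (STRING ``aliases`` dumps or generic two-column
  external-to-canonical mappings);
* deregulated-protein (DP) lists, one identifier per row with an optional
  p-value column;
* reference disease-candidate exports (identifier + inference score, the
  shape produced by CTDbase queries).

Confidence scores are normalized to STRING's integer 0-999 scale on read,
whatever dialect the file uses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import EmptySeedError, FormatError

SCORE_MAX = 999

_TRUE = {"t", "true", "1", "yes"}
_FALSE = {"f", "false", "0", "no", ""}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RawInteraction:
    """One row of a ``protein.actions`` file, score on the 0-999 scale.

    ``a_is_acting`` may be ``None`` when the file carries no acting-protein
    annotation; downstream orientation then defaults to source -> target.
    """

    source_id: str
    target_id: str
    is_directional: bool
    a_is_acting: bool | None
    score: int
    mode: str = ""
    action: str = ""

    def __post_init__(self) -> None:
        if not self.source_id or not self.target_id:
            raise FormatError("interaction with empty protein identifier")
        if not 0 <= self.score <= SCORE_MAX:
            raise FormatError(
                f"score {self.score} outside the 0-{SCORE_MAX} scale"
            )


@dataclass(frozen=True)
class IdMapping:
    """Many-to-one map from external identifiers to canonical node ids.

    Canonical identifiers resolve to themselves, so applying the mapping is
    idempotent. ``IdMapping.identity()`` builds a pass-through mapping for
    inputs that already use canonical identifiers.
    """

    table: Mapping[str, str] = field(default_factory=dict)
    passthrough: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "_canonical", frozenset(self.table.values()))

    @classmethod
    def identity(cls) -> "IdMapping":
        return cls(table={}, passthrough=True)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "IdMapping":
        table: dict[str, str] = {}
        for external, canonical in pairs:
            prev = table.get(external)
            if prev is not None and prev != canonical:
                raise FormatError(
                    f"identifier {external!r} maps to both {prev!r} "
                    f"and {canonical!r}"
                )
            table[external] = canonical
        return cls(table=table)

    def resolve(self, identifier: str) -> str | None:
        """Canonical id for ``identifier``, or None when unmappable."""
        if self.passthrough:
            return identifier
        hit = self.table.get(identifier)
        if hit is not None:
            return hit
        if identifier in self._canonical:  # already canonical: idempotence
            return identifier
        return None


@dataclass(frozen=True)
class DPSet:
    """The seed set of deregulated proteins for one proteomic dataset."""

    dataset_name: str
    members: frozenset[str]
    pvalues: Mapping[str, float] | None = None
    unmapped: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.members:
            raise EmptySeedError(
                f"dataset {self.dataset_name!r} has no mappable "
                "deregulated protein"
            )
        if self.pvalues:
            bad = {m: p for m, p in self.pvalues.items() if not 0 < p <= 1}
            if bad:
                raise FormatError(f"p-values outside (0, 1]: {bad}")


@dataclass(frozen=True)
class ReferenceCandidates:
    """A disease's reference candidates, descending by inference score."""

    disease_name: str
    entries: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        scores = [s for _, s in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise FormatError(
                f"reference list {self.disease_name!r} not sorted by "
                "descending inference score"
            )

    @property
    def members(self) -> frozenset[str]:
        return frozenset(ident for ident, _ in self.entries)


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(
            path, sep="\t", comment="#", dtype=str,
            skip_blank_lines=True, encoding="utf-8",
        )
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: file holds no table") from exc


def _parse_bool(value: str | float, column: str, line: int) -> bool:
    text = "" if pd.isna(value) else str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise FormatError(f"line {line}: cannot parse {column}={value!r} as boolean")


def _normalize_scores(raw: pd.Series, dialect: str) -> list[int]:
    """Normalize a score column to integers on the 0-999 scale.

    ``dialect`` is ``"int"`` (already 0-999), ``"real"`` (0-1 probabilities)
    or ``"auto"`` (real iff every value is <= 1).
    """
    numeric = pd.to_numeric(raw, errors="coerce")
    if numeric.isna().any():
        line = int(numeric.index[numeric.isna()][0]) + 2  # header + 1-based
        raise FormatError(f"line {line}: unparseable score {raw[line - 2]!r}")
    if dialect == "auto":
        dialect = "real" if float(numeric.max()) <= 1.0 else "int"
    if dialect == "real":
        numeric = (numeric * 1000).round().clip(upper=SCORE_MAX)
    elif dialect != "int":
        raise ValueError(f"unknown score dialect {dialect!r}")
    return [int(v) for v in numeric]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_string_actions(path, dialect: str = "auto") -> list[RawInteraction]:
    """Parse a STRING ``protein.actions`` TSV into interaction records.

    Parameters
    ----------
    path
        Path to the (uncompressed) TSV file.
    dialect
        Score-scale flag: ``"int"``, ``"real"`` or ``"auto"``.
    """
    frame = _read_tsv(path)
    required = ["item_id_a", "item_id_b", "is_directional", "score"]
    for column in required:
        if column not in frame.columns:
            raise FormatError(f"{path}: missing required column {column!r}")
    has_acting = "a_is_acting" in frame.columns
    scores = _normalize_scores(frame["score"], dialect)

    records: list[RawInteraction] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        line = i + 2
        a = "" if pd.isna(row.item_id_a) else str(row.item_id_a).strip()
        b = "" if pd.isna(row.item_id_b) else str(row.item_id_b).strip()
        if not a or not b:
            raise FormatError(f"line {line}: empty protein identifier")
        acting = (
            _parse_bool(row.a_is_acting, "a_is_acting", line)
            if has_acting else None
        )
        records.append(RawInteraction(
            source_id=a,
            target_id=b,
            is_directional=_parse_bool(row.is_directional, "is_directional", line),
            a_is_acting=acting,
            score=scores[i],
            mode=str(getattr(row, "mode", "") or ""),
            action=str(getattr(row, "action", "") or ""),
        ))
    return records


def write_string_actions(interactions: Sequence[RawInteraction], path) -> None:
    """Write interactions back to the ``protein.actions`` TSV layout."""
    def flag(value: bool | None) -> str:
        return "f" if value is None else ("t" if value else "f")

    frame = pd.DataFrame({
        "item_id_a": [r.source_id for r in interactions],
        "item_id_b": [r.target_id for r in interactions],
        "mode": [r.mode for r in interactions],
        "action": [r.action for r in interactions],
        "is_directional": [flag(r.is_directional) for r in interactions],
        "a_is_acting": [flag(r.a_is_acting) for r in interactions],
        "score": [r.score for r in interactions],
    })
    frame.to_csv(path, sep="\t", index=False)


def read_id_mapping(path) -> IdMapping:
    """Read an alias table into an :class:`IdMapping`.

    Accepts either a STRING ``aliases`` dump (canonical id first, alias
    second) or a generic two-column ``external<TAB>canonical`` table. The
    STRING layout is recognized by an ``alias`` column in the header.
    """
    frame = _read_tsv(path)
    columns = [c.lstrip("#").strip() for c in frame.columns]
    frame.columns = columns
    if "alias" in columns:
        canonical_col = columns[0]
        pairs = zip(frame["alias"].astype(str), frame[canonical_col].astype(str))
    else:
        if len(columns) < 2:
            raise FormatError(f"{path}: mapping needs two columns")
        pairs = zip(frame[columns[0]].astype(str), frame[columns[1]].astype(str))
    return IdMapping.from_pairs(pairs)


def read_dp_list(path, mapping: IdMapping | None = None,
                 dataset_name: str | None = None) -> DPSet:
    """Read a deregulated-protein list and translate it to canonical ids.

    Unmapped identifiers are collected in ``DPSet.unmapped`` rather than
    silently dropped; duplicates are counted once. A file in which no
    identifier maps at all raises :class:`EmptySeedError`.
    """
    mapping = mapping or IdMapping.identity()
    frame = _read_tsv(path)
    if "id" not in frame.columns:
        # headerless: first column is the identifier, optional second p-value
        frame = pd.read_csv(path, sep="\t", comment="#", dtype=str, header=None)
        frame.columns = ["id", "pvalue"][: len(frame.columns)]

    members: set[str] = set()
    pvalues: dict[str, float] = {}
    unmapped: list[str] = []
    has_pvalue = "pvalue" in frame.columns
    for row in frame.itertuples(index=False):
        ident = str(row.id).strip()
        if not ident or ident.lower() == "nan":
            continue
        canonical = mapping.resolve(ident)
        if canonical is None:
            if ident not in unmapped:
                unmapped.append(ident)
            continue
        members.add(canonical)
        if has_pvalue and not pd.isna(row.pvalue):
            pvalues[canonical] = float(row.pvalue)

    name = dataset_name or str(path)
    if not members:
        raise EmptySeedError(f"{path}: no identifier could be mapped")
    return DPSet(
        dataset_name=name,
        members=frozenset(members),
        pvalues=pvalues or None,
        unmapped=tuple(unmapped),
    )


def read_reference_candidates(path, top_n: int = 500,
                              disease_name: str | None = None
                              ) -> ReferenceCandidates:
    """Read a CTDbase-style export and keep the ``top_n`` best-scored rows.

    Rows are sorted by descending inference score with ties broken by their
    stable input order. Fewer rows than ``top_n`` triggers a warning and
    returns everything.
    """
    frame = _read_tsv(path)
    if "id" not in frame.columns or "inference_score" not in frame.columns:
        raise FormatError(
            f"{path}: reference list needs 'id' and 'inference_score' columns"
        )
    scores = pd.to_numeric(frame["inference_score"], errors="coerce")
    if scores.isna().any():
        line = int(scores.index[scores.isna()][0]) + 2
        raise FormatError(f"line {line}: unparseable inference score")
    order = scores.sort_values(ascending=False, kind="stable").index
    entries = [
        (str(frame.loc[i, "id"]).strip(), float(scores.loc[i])) for i in order
    ]
    if len(entries) < top_n:
        warnings.warn(
            f"{path}: only {len(entries)} candidates available "
            f"(requested top {top_n})", stacklevel=2,
        )
    return ReferenceCandidates(
        disease_name=disease_name or str(path),
        entries=tuple(entries[:top_n]),
    )


def write_dp_list(dps: DPSet, path) -> None:
    rows = sorted(dps.members)
    frame = pd.DataFrame({"id": rows})
    if dps.pvalues:
        frame["pvalue"] = [dps.pvalues.get(m, "") for m in rows]
    frame.to_csv(path, sep="\t", index=False)


def write_reference_candidates(ref: ReferenceCandidates, path) -> None:
    pd.DataFrame(ref.entries, columns=["id", "inference_score"]).to_csv(
        path, sep="\t", index=False
    )
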