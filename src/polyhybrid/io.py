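"""Cross-string grammar, trait tables, parameter files and reports.

Cross strings name a genotype class over single-character line labels:
``"A"`` a parental line, ``"A×B"`` an F1, ``"AB.self"`` a selfed-F1 F2
and ``"AB×AC"`` / ``"AB×CD"`` F2 crosses between F1s (with or without a
shared parent).  ``"×"``, ``"x"`` and ``"*"`` are accepted as the cross
separator; the canonical form uses ``"×"`` with labels sorted within and
across sides.  The side written first is the dam (seed parent) — kept as
written so maternal effects can be modelled — while identity is unordered.

Trait tables are RFC-4180 CSV with columns ``cross, ploidy, generation,
replicate, value`` (``replicate`` may be empty for mean-only tables; for
selfing series ``generation`` counts selfing generations since the F1,
for multi-generation panels it is 0/1/2 for parent/F1/F2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .theory import LandscapeParams

__all__ = [
    "CrossString",
    "CrossParseError",
    "CrossTableError",
    "parse_cross",
    "read_cross_table",
    "write_cross_table",
    "write_report",
    "load_params",
    "dump_params",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "1.0"
_SEPARATORS = ("×", "x", "*")
_SELF_SUFFIX = ".self"


class CrossParseError(ValueError):
    """Malformed or unknown cross string."""


class CrossTableError(ValueError):
    """One or more invalid rows in a cross table."""

    def __init__(self, message, errors):
        super().__init__(message)
        self.errors = errors  # list of (row_number, message)


@dataclass(frozen=True)
class CrossString:
    """A parsed cross: dam side, sire side and generation tag.

    ``kind`` is one of ``parent``, ``F1``, ``F2-self``, ``F2-cross``.
    ``dam`` is the left (seed-parent) side as written; ``canonical``
    gives the order-independent form.
    """

    dam: tuple
    sire: tuple  # empty tuple for a parent
    kind: str

    @property
    def lines(self) -> tuple:
        return tuple(sorted(set(self.dam) | set(self.sire)))

    @property
    def n_parents(self) -> int:
        return len(self.lines)

    @property
    def is_f2(self) -> bool:
        return self.kind.startswith("F2")

    @property
    def canonical(self) -> str:
        dam = "".join(sorted(self.dam))
        sire = "".join(sorted(self.sire))
        if self.kind == "parent":
            return dam
        if self.kind == "F2-self" or (self.kind == "F2-cross" and dam == sire):
            return f"{dam}{_SELF_SUFFIX}"
        a, b = sorted([dam, sire])
        return f"{a}×{b}"

    def h_vector(self, labels) -> np.ndarray:
        """Expected hybrid indices over `labels`: each side contributes
        half the genome, split evenly over the lines it names."""
        labels = list(labels)
        h = np.zeros(len(labels))
        sides = [self.dam] if not self.sire else [self.dam, self.sire]
        for side in sides:
            for l in side:
                h[labels.index(l)] += 1.0 / (len(sides) * len(side))
        return h

    def __str__(self) -> str:
        return self.canonical


def _split_labels(part: str, s: str, offset: int):
    labels = []
    for i, ch in enumerate(part):
        if not (ch.isalnum() and ch == ch.upper()):
            raise CrossParseError(
                f"invalid label character {ch!r} at position {offset + i} in {s!r}; "
                "labels are single upper-case letters or digits"
            )
        labels.append(ch)
    if len(set(labels)) != len(labels):
        raise CrossParseError(f"repeated label within one side of {s!r}")
    return tuple(labels)


def parse_cross(s: str, known_labels=None) -> CrossString:
    """Parse a cross string; see the module docstring for the grammar."""
    if not isinstance(s, str) or not s.strip():
        raise CrossParseError(f"empty or non-string cross: {s!r}")
    text = s.strip()
    selfed = text.endswith(_SELF_SUFFIX)
    if selfed:
        text = text[: -len(_SELF_SUFFIX)]
    sep_at = [(i, ch) for i, ch in enumerate(text) if ch in _SEPARATORS]
    if len(sep_at) > 1:
        raise CrossParseError(
            f"multiple cross separators in {s!r} (positions "
            f"{[i for i, _ in sep_at]})"
        )
    if selfed and sep_at:
        raise CrossParseError(f"{s!r} mixes '.self' with a cross separator")

    if selfed:
        dam = _split_labels(text, s, 0)
        if len(dam) != 2:
            raise CrossParseError(
                f"{s!r}: '.self' expects a two-line F1 such as 'AB.self'"
            )
        parsed = CrossString(dam=dam, sire=dam, kind="F2-self")
    elif sep_at:
        i, _ = sep_at[0]
        left, right = text[:i], text[i + 1 :]
        if not left or not right:
            raise CrossParseError(f"missing side at position {i} in {s!r}")
        dam = _split_labels(left, s, 0)
        sire = _split_labels(right, s, i + 1)
        if len(dam) != len(sire):
            raise CrossParseError(
                f"{s!r} crosses sides of different generations "
                f"({len(dam)} vs {len(sire)} lines); backcrosses are not supported"
            )
        if len(dam) == 1:
            if dam == sire:
                raise CrossParseError(
                    f"{s!r} selfs a parental line; write the line name alone"
                )
            parsed = CrossString(dam=dam, sire=sire, kind="F1")
        elif len(dam) == 2:
            kind = "F2-self" if set(dam) == set(sire) else "F2-cross"
            parsed = CrossString(dam=dam, sire=sire, kind=kind)
        else:
            raise CrossParseError(
                f"{s!r}: sides may name one line (F1 cross) or two (F2 cross)"
            )
    else:
        dam = _split_labels(text, s, 0)
        if len(dam) != 1:
            raise CrossParseError(
                f"{s!r}: a bare side must name a single parental line"
            )
        parsed = CrossString(dam=dam, sire=(), kind="parent")

    if known_labels is not None:
        unknown = sorted(set(parsed.lines) - set(known_labels))
        if unknown:
            raise CrossParseError(
                f"unknown line label(s) {unknown} in {s!r}; declared lines are "
                f"{sorted(known_labels)}"
            )
    return parsed


_REQUIRED_COLUMNS = ("cross", "ploidy", "generation", "value")


def read_cross_table(path, known_labels=None) -> pd.DataFrame:
    """Read and validate a long-format trait table.

    Returns the table with a parsed ``P`` column added.  All row-level
    problems are collected and raised together as :class:`CrossTableError`
    naming the offending rows.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CrossTableError(
            f"missing required column(s) {missing}; found {list(df.columns)}",
            errors=[(None, f"missing columns {missing}")],
        )
    if "replicate" not in df.columns:
        df["replicate"] = np.nan
    errors = []
    P = np.zeros(len(df), dtype=int)
    for idx, row in df.iterrows():
        rowno = idx + 2  # header is line 1
        try:
            P[idx] = parse_cross(str(row["cross"]), known_labels).n_parents
        except CrossParseError as exc:
            errors.append((rowno, str(exc)))
            continue
        k = row["ploidy"]
        if not float(k).is_integer() or int(k) < 2 or int(k) % 2:
            errors.append((rowno, f"ploidy {k!r} is not an even integer >= 2"))
        g = row["generation"]
        if pd.isna(g) or float(g) < 0:
            errors.append((rowno, f"generation {g!r} is negative or missing"))
    if errors:
        head = "; ".join(f"row {r}: {m}" for r, m in errors[:5])
        more = f" (+{len(errors) - 5} more)" if len(errors) > 5 else ""
        raise CrossTableError(
            f"{len(errors)} invalid row(s) in cross table: {head}{more}",
            errors=errors,
        )
    df = df.copy()
    df["ploidy"] = df["ploidy"].astype(int)
    df["generation"] = df["generation"].astype(int)
    df["value"] = df["value"].astype(float)
    df["P"] = P
    return df


def write_cross_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("cross", "ploidy", "generation", "P", "replicate", "value") if c in df.columns]
    df.to_csv(path, index=False, columns=cols)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Fraction):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.Series,)):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (set, tuple)):
        return list(obj)
    raise TypeError(f"cannot serialise {type(obj).__name__} to JSON")


def write_report(report: dict, path) -> None:
    """Serialise an analysis report as JSON with a schema version."""
    payload = {"schema_version": SCHEMA_VERSION, **report}
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")


def load_params(path) -> LandscapeParams:
    """Load landscape parameters from a YAML file.

    Expected keys: ``labels`` (list), ``w`` (scalar or mapping label ->
    value), ``M`` and ``I`` (mappings ``"A-B" -> value`` for the upper
    triangle, or a scalar applied to all pairs).
    """
    data = yaml.safe_load(Path(path).read_text())
    labels = tuple(str(l) for l in data["labels"])
    P = len(labels)

    w_raw = data.get("w", 0.0)
    if isinstance(w_raw, dict):
        w = np.array([float(w_raw[l]) for l in labels])
    else:
        w = np.full(P, float(w_raw))

    def matrix(key):
        raw = data.get(key, 0.0)
        mat = np.zeros((P, P))
        if isinstance(raw, dict):
            for pair, val in raw.items():
                a, _, b = str(pair).partition("-")
                i, j = labels.index(a), labels.index(b)
                mat[i, j] = mat[j, i] = float(val)
        else:
            mat[:] = float(raw)
            np.fill_diagonal(mat, 0.0)
        return mat

    return LandscapeParams(
        labels=labels, parent_fitness=w, masking=matrix("M"), epistasis=matrix("I")
    )


def dump_params(params: LandscapeParams, path) -> None:
    labels = list(params.labels)
    iu = zip(*np.triu_indices(params.n_parents, 1))
    pairs = [(labels[i], labels[j]) for i, j in iu]
    data = {
        "labels": labels,
        "w": {l: float(v) for l, v in zip(labels, params.parent_fitness)},
        "M": {
            f"{a}-{b}": float(params.masking[labels.index(a), labels.index(b)])
            for a, b in pairs
        },
        "I": {
            f"{a}-{b}": float(params.epistasis[labels.index(a), labels.index(b)])
            for a, b in pairs
        },
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
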