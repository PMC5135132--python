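"""PHYLIP distance-matrix and control-file I/O.

The analysis consumes a single pairwise evolutionary-distance matrix covering
the sequences of *all* libraries, plus a small key=value control file that
assigns sequences to libraries and sets run parameters.  Both the classic
square (full) PHYLIP dialect and the lower-triangular dialect are supported;
labels are whitespace-delimited and may be any length (strict 10-character
PHYLIP fields also parse, as long as labels contain no whitespace).

Control-file grammar (one ``key = value`` per line, ``#`` comments allowed)::

    matrix        = path/to/distances.phylip
    libraries     = SW, MS, CS, FS        # optional names; default lib1..libL
    sizes         = 80, 80, 80, 80        # contiguous blocks in matrix order
    members_SW    = seq1, seq2, ...       # alternative: explicit label lists
    permutations  = 999
    seed          = 42
    alpha         = 0.05
    rmax          = 1.0

Exactly one of ``sizes`` / ``members_*`` must be given.  Unknown keys produce
a warning, not an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DistanceMatrix",
    "LibraryPartition",
    "RunConfig",
    "PhylipParseError",
    "MatrixValidationError",
    "PartitionError",
    "ControlFileError",
    "read_phylip_distances",
    "write_phylip_distances",
    "read_control",
    "bind_partition",
]

#: asymmetry below this is float noise from upstream writers and is averaged
#: away; anything larger is a hard error.
ASYMMETRY_TOL = 1e-8


class PhylipParseError(ValueError):
    """Malformed PHYLIP distance-matrix file."""


class MatrixValidationError(ValueError):
    """Parsed matrix violates distance-matrix invariants."""


class PartitionError(ValueError):
    """Library partition inconsistent with the distance matrix."""


class ControlFileError(ValueError):
    """Malformed control file."""


@dataclass(frozen=True)
class DistanceMatrix:
    """A labeled symmetric matrix of pairwise evolutionary distances.

    Distances are on the substitutions-per-site scale; ``d[i, j]`` is the
    distance between sequences ``labels[i]`` and ``labels[j]``.
    """

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise MatrixValidationError("duplicate sequence labels")
        if d.shape != (n, n):
            raise MatrixValidationError(
                f"matrix shape {d.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(d)):
            raise MatrixValidationError("non-finite distance entry")
        if np.any(d < 0):
            raise MatrixValidationError("negative distance entry")
        asym = np.max(np.abs(d - d.T)) if n else 0.0
        if asym > ASYMMETRY_TOL:
            raise MatrixValidationError(
                f"matrix asymmetric beyond tolerance ({asym:.3g} > {ASYMMETRY_TOL:g})"
            )
        d = (d + d.T) / 2.0
        if np.any(np.abs(np.diag(d)) > ASYMMETRY_TOL):
            raise MatrixValidationError("nonzero diagonal entry")
        np.fill_diagonal(d, 0.0)
        d.flags.writeable = False
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, labels: Iterable[str]) -> np.ndarray:
        """Row indices of the given labels, in the given order."""
        pos = {lab: i for i, lab in enumerate(self.labels)}
        try:
            return np.array([pos[lab] for lab in labels], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - message formatting
            raise PartitionError(f"label {exc.args[0]!r} not in matrix") from None

    def submatrix(self, labels: Sequence[str]) -> np.ndarray:
        idx = self.index(labels)
        return self.d[np.ix_(idx, idx)]


@dataclass(frozen=True)
class LibraryPartition:
    """Assignment of the matrix's sequence labels to named libraries."""

    libraries: tuple[tuple[str, tuple[str, ...]], ...]

    @property
    def n_libraries(self) -> int:
        return len(self.libraries)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.libraries)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(members) for _, members in self.libraries)

    def members(self, name: str) -> tuple[str, ...]:
        for lib, mem in self.libraries:
            if lib == name:
                return mem
        raise KeyError(name)

    def pairs(self) -> list[tuple[str, str]]:
        """All unordered library pairs, in partition order."""
        names = self.names
        return [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]


@dataclass
class RunConfig:
    """Parameter settings for one analysis run (the control file in memory)."""

    matrix_path: str | None = None
    library_names: tuple[str, ...] = ()
    sizes: tuple[int, ...] | None = None
    members: dict[str, tuple[str, ...]] = field(default_factory=dict)
    permutations: int = 999
    seed: int | None = None
    alpha: float = 0.05
    r_max: float = 1.0

    def __post_init__(self) -> None:
        if self.permutations < 0:
            raise ControlFileError("permutations must be >= 0")
        if not (0.0 < self.alpha < 1.0):
            raise ControlFileError("alpha must be in (0, 1)")
        if self.r_max <= 0:
            raise ControlFileError("rmax must be positive")


# ---------------------------------------------------------------------------
# PHYLIP parsing


def _tokenize(path: str | Path) -> tuple[int, list[list[str]]]:
    lines = Path(path).read_text().splitlines()
    rows: list[list[str]] = []
    n: int | None = None
    for line in lines:
        toks = line.split()
        if not toks:
            continue
        if n is None:
            try:
                n = int(toks[0])
            except ValueError:
                raise PhylipParseError(
                    f"first token {toks[0]!r} is not a sequence count"
                ) from None
            if len(toks) > 1:
                rows.append(toks[1:])
            continue
        rows.append(toks)
    if n is None:
        raise PhylipParseError("empty file: no sequence count found")
    return n, rows


def _floats(tokens: Sequence[str], row_label: str) -> list[float]:
    out = []
    for t in tokens:
        try:
            out.append(float(t))
        except ValueError:
            raise PhylipParseError(
                f"row {row_label!r}: non-numeric entry {t!r}"
            ) from None
    return out


def _parse_rows_auto(n: int, lines: list[list[str]]) -> tuple[list[str], list[list[float]]]:
    """One taxon per physical line; dialect inferred later from row lengths."""
    if len(lines) != n:
        raise PhylipParseError(
            f"header declares {n} sequences but file has {len(lines)} data rows"
            + (f" (first surplus row starts with {lines[n][0]!r})" if len(lines) > n else "")
        )
    labels = [row[0] for row in lines]
    values = [_floats(row[1:], row[0]) for row in lines]
    return labels, values


def _parse_rows_stream(
    n: int, lines: list[list[str]], counts: Sequence[int]
) -> tuple[list[str], list[list[float]]]:
    """Known per-row value counts; rows may wrap over physical lines."""
    stream = [t for row in lines for t in row]
    labels, values = [], []
    pos = 0
    for i, want in enumerate(counts):
        if pos >= len(stream):
            raise PhylipParseError(f"file ends before row {i + 1} of {n}")
        label = stream[pos]
        pos += 1
        chunk = stream[pos : pos + want]
        if len(chunk) < want:
            raise PhylipParseError(
                f"row {label!r}: expected {want} distances, found {len(chunk)}"
            )
        values.append(_floats(chunk, label))
        labels.append(label)
        pos += want
    if pos != len(stream):
        raise PhylipParseError(f"{len(stream) - pos} unexpected trailing tokens")
    return labels, values


def read_phylip_distances(
    path: str | Path, dialect: str = "auto"
) -> DistanceMatrix:
    """Read a PHYLIP distance matrix (square or lower-triangular).

    Parameters
    ----------
    path
        File whose first non-blank token is the sequence count ``N``, followed
        by one labeled row per sequence.
    dialect
        ``"square"`` (N values per row), ``"lower_triangular"`` (row *i* has
        *i* values, optionally including a zero diagonal), or ``"auto"``
        (inferred from row lengths; requires one taxon per line).  The
        explicit dialects also accept rows wrapped over several lines.
    """
    if dialect not in ("auto", "square", "lower_triangular"):
        raise ValueError(f"unknown dialect {dialect!r}")
    n, lines = _tokenize(path)
    if n < 1:
        raise PhylipParseError(f"sequence count must be >= 1, got {n}")

    if dialect == "square":
        labels, values = _parse_rows_stream(n, lines, [n] * n)
    elif dialect == "lower_triangular":
        try:
            labels, values = _parse_rows_stream(n, lines, list(range(n)))
        except PhylipParseError:
            # lower-triangular with explicit zero diagonal
            labels, values = _parse_rows_stream(n, lines, list(range(1, n + 1)))
    else:
        labels, values = _parse_rows_auto(n, lines)

    lens = [len(v) for v in values]
    if lens == [n] * n:
        d = np.array(values, dtype=float)
    elif lens == list(range(n)) or lens == list(range(1, n + 1)):
        d = np.zeros((n, n))
        for i, row in enumerate(values):
            took = row[:i]  # drop any explicit diagonal term
            d[i, : len(took)] = took
        d = d + d.T
    else:
        bad = next(i for i, ln in enumerate(lens) if ln not in (n, i, i + 1))
        raise PhylipParseError(
            f"row {labels[bad]!r} has {lens[bad]} distances; expected {n} "
            f"(square) or {bad} (lower-triangular)"
        )
    try:
        return DistanceMatrix(tuple(labels), d)
    except MatrixValidationError as exc:
        raise MatrixValidationError(f"{path}: {exc}") from None


def write_phylip_distances(
    m: DistanceMatrix, path: str | Path, dialect: str = "square"
) -> None:
    """Write a distance matrix in PHYLIP format.

    Labels of 10 characters or fewer are padded to the classic fixed-width
    field; longer labels are written whitespace-delimited (relaxed dialect),
    which round-trips through :func:`read_phylip_distances` either way.
    """
    if dialect not in ("square", "lower_triangular"):
        raise ValueError(f"unknown dialect {dialect!r}")
    pad = max((len(lab) for lab in m.labels), default=0) <= 10
    with open(path, "w") as fh:
        fh.write(f"{m.n:5d}\n")
        for i, lab in enumerate(m.labels):
            row = m.d[i, : i if dialect == "lower_triangular" else m.n]
            name = f"{lab:<10s}" if pad else lab
            vals = " ".join(f"{v:.12g}" for v in row)
            fh.write(f"{name}  {vals}".rstrip() + "\n")


# ---------------------------------------------------------------------------
# Control file


_KNOWN_KEYS = {"matrix", "libraries", "sizes", "permutations", "seed", "alpha", "rmax"}


def _split_list(value: str) -> list[str]:
    parts = [p.strip() for p in value.replace(",", " ").split()]
    return [p for p in parts if p]


def read_control(path: str | Path) -> RunConfig:
    """Parse a key=value control file into a :class:`RunConfig`."""
    cfg: dict[str, object] = {}
    members: dict[str, tuple[str, ...]] = {}
    names: tuple[str, ...] = ()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ControlFileError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip().lower(), value.strip()
        if key == "matrix":
            cfg["matrix_path"] = value
        elif key == "libraries":
            names = tuple(_split_list(value))
        elif key == "sizes":
            try:
                cfg["sizes"] = tuple(int(x) for x in _split_list(value))
            except ValueError:
                raise ControlFileError(f"{path}:{lineno}: non-integer size") from None
        elif key == "permutations":
            cfg["permutations"] = int(value)
        elif key == "seed":
            cfg["seed"] = int(value)
        elif key == "alpha":
            cfg["alpha"] = float(value)
        elif key == "rmax":
            cfg["r_max"] = float(value)
        elif key.startswith("members_"):
            members[key[len("members_") :]] = tuple(_split_list(value))
        else:
            warnings.warn(f"{path}:{lineno}: unknown control key {key!r}", stacklevel=2)
    if members and "sizes" in cfg:
        raise ControlFileError("give either sizes= or members_* lines, not both")
    if members:
        if names:
            missing = set(names) - set(members)
            if missing:
                raise ControlFileError(f"libraries named but no members_ line: {sorted(missing)}")
            members = {name: members[name] for name in names}
        names = tuple(members)
    elif "sizes" in cfg and not names:
        names = tuple(f"lib{i + 1}" for i in range(len(cfg["sizes"])))  # type: ignore[arg-type]
    if names and "sizes" in cfg and len(names) != len(cfg["sizes"]):  # type: ignore[arg-type]
        raise ControlFileError("libraries= and sizes= have different lengths")
    return RunConfig(library_names=names, members=members, **cfg)  # type: ignore[arg-type]


def bind_partition(m: DistanceMatrix, cfg: RunConfig) -> LibraryPartition:
    """Resolve a config's partition description against a concrete matrix.

    Block sizes are taken over consecutive matrix rows in order; explicit
    member lists are matched by label.  Every sequence in the matrix must be
    assigned to exactly one library.
    """
    if cfg.members:
        libs = []
        seen: set[str] = set()
        label_set = set(m.labels)
        for name in cfg.library_names or tuple(cfg.members):
            mem = cfg.members[name]
            if not mem:
                raise PartitionError(f"library {name!r} is empty")
            for lab in mem:
                if lab in seen:
                    raise PartitionError(f"label {lab!r} assigned to two libraries")
                if lab not in label_set:
                    raise PartitionError(f"label {lab!r} not present in matrix")
                seen.add(lab)
            libs.append((name, tuple(mem)))
        if seen != label_set:
            missing = sorted(label_set - seen)[:5]
            raise PartitionError(
                f"{len(label_set) - len(seen)} matrix sequences unassigned "
                f"(e.g. {missing})"
            )
        return LibraryPartition(tuple(libs))
    if cfg.sizes is None:
        raise PartitionError("config specifies neither sizes nor member lists")
    if any(s <= 0 for s in cfg.sizes):
        raise PartitionError("library sizes must be positive")
    if sum(cfg.sizes) != m.n:
        raise PartitionError(
            f"sizes sum to {sum(cfg.sizes)} but matrix has {m.n} sequences"
        )
    names = cfg.library_names or tuple(f"lib{i + 1}" for i in range(len(cfg.sizes)))
    libs, start = [], 0
    for name, size in zip(names, cfg.sizes):
        libs.append((name, tuple(m.labels[start : start + size])))
        start += size
    return LibraryPartition(tuple(libs))
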