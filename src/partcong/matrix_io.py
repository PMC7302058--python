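"""Discrete morphological character matrices: containers, NEXUS I/O, and
dataset curation (taxon filtering by missing data, removal of
parsimony-uninformative characters, between-matrix overlap screening).

Cells are one of observed (a nonempty set of integer state codes; a
multi-state set records polymorphism/uncertainty), missing ("?") or
inapplicable ("-").  Missing and inapplicable are distinct in storage, so
completeness filters can count both, but they are scored identically (fully
ambiguous) by the parsimony machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import dendropy

OBSERVED, MISSING, INAPPLICABLE = 0, 1, 2
_KIND_NAMES = {OBSERVED: "observed", MISSING: "missing", INAPPLICABLE: "inapplicable"}

CRANIO = "craniodental"
POST = "postcranial"
OTHER = "other"


class NexusParseError(ValueError):
    pass


class MatrixValidationError(ValueError):
    pass


@dataclass(frozen=True)
class CellState:
    kind: str                      # "observed" | "missing" | "inapplicable"
    states: frozenset = frozenset()

    def __post_init__(self):
        if self.kind == "observed" and not self.states:
            raise MatrixValidationError("observed cell must carry states")
        if self.kind != "observed" and self.states:
            raise MatrixValidationError(f"{self.kind} cell cannot carry states")


class CharacterMatrix:
    """Taxa x categorical characters with named character sets.

    Internally cells are a ``uint32`` bitmask array (observed state sets;
    zero for missing/inapplicable) plus a parallel kind array.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        masks: np.ndarray,
        kinds: np.ndarray,
        alphabet: int = 10,
        charsets: Mapping[str, Iterable[int]] | None = None,
        char_labels: Sequence[str] | None = None,
    ):
        self.taxa = tuple(taxa)
        if len(set(self.taxa)) != len(self.taxa):
            raise MatrixValidationError("duplicate taxon labels")
        self.masks = np.asarray(masks, dtype=np.uint32)
        self.kinds = np.asarray(kinds, dtype=np.int8)
        if self.masks.shape != (len(self.taxa), self.masks.shape[1]):
            raise MatrixValidationError("masks shape mismatch")
        if self.kinds.shape != self.masks.shape:
            raise MatrixValidationError("kinds shape mismatch")
        if alphabet < 1 or alphabet > 32:
            raise MatrixValidationError("alphabet size must be in 1..32")
        self.alphabet = int(alphabet)
        top = self.masks.max(initial=np.uint32(0))
        if int(top) >> self.alphabet:
            raise MatrixValidationError("observed state code exceeds alphabet")
        if np.any((self.kinds == OBSERVED) & (self.masks == 0)):
            raise MatrixValidationError("observed cell with empty state set")
        if np.any((self.kinds != OBSERVED) & (self.masks != 0)):
            raise MatrixValidationError("missing/inapplicable cell with states")
        self.charsets = {
            str(k): tuple(sorted(int(i) for i in v)) for k, v in (charsets or {}).items()
        }
        for name, idx in self.charsets.items():
            if idx and (idx[0] < 0 or idx[-1] >= self.n_chars):
                raise MatrixValidationError(f"charset {name!r} out of range")
        if char_labels is None:
            char_labels = [f"char_{i + 1}" for i in range(self.n_chars)]
        self.char_labels = tuple(char_labels)
        if len(self.char_labels) != self.n_chars:
            raise MatrixValidationError("char_labels length mismatch")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return self.masks.shape[1]

    def cell(self, taxon: str, char: int) -> CellState:
        t = self.taxa.index(taxon)
        kind = int(self.kinds[t, char])
        if kind == OBSERVED:
            m = int(self.masks[t, char])
            states = frozenset(i for i in range(self.alphabet) if m >> i & 1)
            return CellState("observed", states)
        return CellState(_KIND_NAMES[kind])

    def scoring_masks(self, chars: Sequence[int] | None = None) -> np.ndarray:
        """State-set masks for parsimony: missing/inapplicable become the
        full alphabet (fully ambiguous, never forcing steps)."""
        full = np.uint32((1 << self.alphabet) - 1)
        m = self.masks if chars is None else self.masks[:, list(chars)]
        k = self.kinds if chars is None else self.kinds[:, list(chars)]
        return np.where(k == OBSERVED, m, full).astype(np.uint32)

    def unscored_fraction(self, taxon_index: int, chars: Sequence[int]) -> float:
        """Fraction of `chars` that are missing or inapplicable for a taxon."""
        if not len(chars):
            return 0.0
        k = self.kinds[taxon_index, list(chars)]
        return float(np.mean(k != OBSERVED))

    def subset(self, taxa: Sequence[str] | None = None, chars: Sequence[int] | None = None) -> "CharacterMatrix":
        trows = range(self.n_taxa) if taxa is None else [self.taxa.index(t) for t in taxa]
        ccols = list(range(self.n_chars)) if chars is None else list(chars)
        cmap = {c: i for i, c in enumerate(ccols)}
        charsets = {
            name: [cmap[c] for c in idx if c in cmap]
            for name, idx in self.charsets.items()
        }
        charsets = {k: v for k, v in charsets.items() if v}
        return CharacterMatrix(
            [self.taxa[t] for t in trows],
            self.masks[np.ix_(list(trows), ccols)],
            self.kinds[np.ix_(list(trows), ccols)],
            alphabet=self.alphabet,
            charsets=charsets,
            char_labels=[self.char_labels[c] for c in ccols],
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CharacterMatrix)
            and self.taxa == other.taxa
            and self.alphabet == other.alphabet
            and np.array_equal(self.masks, other.masks)
            and np.array_equal(self.kinds, other.kinds)
            and self.charsets == other.charsets
        )

    def __repr__(self) -> str:
        return f"CharacterMatrix({self.n_taxa} taxa x {self.n_chars} chars)"


@dataclass(frozen=True)
class PartitionScheme:
    """Per-character labels: craniodental, postcranial, or other (excluded)."""

    labels: tuple

    def __post_init__(self):
        bad = set(self.labels) - {CRANIO, POST, OTHER}
        if bad:
            raise MatrixValidationError(f"unknown partition labels: {bad}")

    def _indices(self, label: str) -> tuple:
        return tuple(i for i, l in enumerate(self.labels) if l == label)

    @property
    def cranio(self) -> tuple:
        return self._indices(CRANIO)

    @property
    def post(self) -> tuple:
        return self._indices(POST)

    @property
    def other(self) -> tuple:
        return self._indices(OTHER)

    @property
    def analysed(self) -> tuple:
        """Characters that enter any test (both partitions, no 'other')."""
        return tuple(sorted(self.cranio + self.post))

    def swapped(self) -> "PartitionScheme":
        flip = {CRANIO: POST, POST: CRANIO, OTHER: OTHER}
        return PartitionScheme(tuple(flip[l] for l in self.labels))

    def subset(self, chars: Sequence[int]) -> "PartitionScheme":
        return PartitionScheme(tuple(self.labels[c] for c in chars))


@dataclass
class CurationReport:
    threshold: float
    removed_taxa: dict = field(default_factory=dict)     # taxon -> {partition: fraction}
    removed_characters: dict = field(default_factory=dict)  # index -> reason

    @property
    def n_taxa_removed(self) -> int:
        return len(self.removed_taxa)

    def to_frame(self):
        import pandas as pd
        rows = [
            {"item": t, "kind": "taxon",
             "cranio_unscored": fr.get(CRANIO, float("nan")),
             "post_unscored": fr.get(POST, float("nan"))}
            for t, fr in self.removed_taxa.items()
        ] + [
            {"item": str(c), "kind": "character", "reason": r}
            for c, r in self.removed_characters.items()
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NEXUS I/O


def read_nexus(path) -> CharacterMatrix:
    """Read a STANDARD-datatype NEXUS matrix (with optional SETS block)."""
    try:
        ds = dendropy.DataSet.get(path=str(path), schema="nexus")
    except dendropy.utility.error.DataParseError as exc:  # pragma: no cover
        raise NexusParseError(str(exc)) from exc
    if not ds.char_matrices:
        raise NexusParseError("no CHARACTERS/DATA block found")
    dm = ds.char_matrices[0]
    sa = dm.default_state_alphabet
    symbols = [
        s.symbol for s in sa.fundamental_state_iter()
        if s.symbol not in ("-", "?")
    ]
    code = {sym: i for i, sym in enumerate(symbols)}
    taxa = [t.label for t in dm.taxon_namespace]
    n_chars = max(len(dm[t]) for t in dm.taxon_namespace)
    masks = np.zeros((len(taxa), n_chars), np.uint32)
    kinds = np.zeros((len(taxa), n_chars), np.int8)
    for ti, t in enumerate(dm.taxon_namespace):
        row = dm[t]
        if len(row) != n_chars:
            raise NexusParseError(f"ragged row for taxon {t.label!r}")
        for ci, cell in enumerate(row):
            sym = cell.symbol
            if sym == "?":
                kinds[ti, ci] = MISSING
                continue
            if sym == "-":
                kinds[ti, ci] = INAPPLICABLE
                continue
            states = [s.symbol for s in cell.fundamental_states if s.symbol != "-"]
            if not states:
                kinds[ti, ci] = INAPPLICABLE
                continue
            m = 0
            for s in states:
                if s not in code:
                    raise NexusParseError(
                        f"state symbol {s!r} not in declared symbols")
                m |= 1 << code[s]
            masks[ti, ci] = m
    charsets = {
        name: sorted(sub.character_indices)
        for name, sub in dm.character_subsets.items()
    }
    return CharacterMatrix(
        taxa, masks, kinds, alphabet=max(len(symbols), 2), charsets=charsets
    )


def write_nexus(matrix: CharacterMatrix, path) -> str:
    """Write a matrix as STANDARD NEXUS (MISSING=?, GAP=-), polymorphism as
    {..}; CHARSETs go to a SETS block."""
    symbols = "0123456789ABCDEFGHIJKLMNOPQRSTUV"[: matrix.alphabet]
    lines = ["#NEXUS", "", "BEGIN DATA;"]
    lines.append(f"  DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_chars};")
    lines.append(
        f'  FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;'
    )
    lines.append("  MATRIX")
    width = max(len(t) for t in matrix.taxa) + 2
    for ti, taxon in enumerate(matrix.taxa):
        cells = []
        for ci in range(matrix.n_chars):
            kind = matrix.kinds[ti, ci]
            if kind == MISSING:
                cells.append("?")
            elif kind == INAPPLICABLE:
                cells.append("-")
            else:
                m = int(matrix.masks[ti, ci])
                ss = [symbols[i] for i in range(matrix.alphabet) if m >> i & 1]
                cells.append(ss[0] if len(ss) == 1 else "{" + "".join(ss) + "}")
        label = _nexus_label(taxon)
        lines.append(f"    {label:<{width}}{''.join(cells)}")
    lines.append("  ;")
    lines.append("END;")
    if matrix.charsets:
        lines.append("")
        lines.append("BEGIN SETS;")
        for name, idx in matrix.charsets.items():
            lines.append(f"  CHARSET {name} = {_ranges_1based(idx)};")
        lines.append("END;")
    text = "\n".join(lines) + "\n"
    with open(path, "w") as fh:
        fh.write(text)
    return str(path)


def _nexus_label(label: str) -> str:
    if all(ch.isalnum() or ch in "_." for ch in label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _ranges_1based(idx: Sequence[int]) -> str:
    out = []
    run = [idx[0], idx[0]]
    for i in idx[1:]:
        if i == run[1] + 1:
            run[1] = i
        else:
            out.append(run)
            run = [i, i]
    out.append(run)
    return " ".join(
        f"{a + 1}" if a == b else f"{a + 1}-{b + 1}" for a, b in out
    )


# ---------------------------------------------------------------------------
# Partitions and curation


def build_partition_scheme(matrix: CharacterMatrix, cranio_set, post_set) -> PartitionScheme:
    """Label characters craniodental/postcranial from charset names or index
    sets; everything unlisted is 'other' and excluded from all tests."""
    cr = _resolve_charset(matrix, cranio_set)
    po = _resolve_charset(matrix, post_set)
    if cr & po:
        raise MatrixValidationError(
            f"craniodental and postcranial sets overlap: {sorted(cr & po)}")
    labels = []
    for i in range(matrix.n_chars):
        labels.append(CRANIO if i in cr else POST if i in po else OTHER)
    return PartitionScheme(tuple(labels))


def _resolve_charset(matrix: CharacterMatrix, spec) -> set:
    if isinstance(spec, str):
        if spec not in matrix.charsets:
            raise MatrixValidationError(f"no charset named {spec!r}")
        return set(matrix.charsets[spec])
    idx = set(int(i) for i in spec)
    if idx and (min(idx) < 0 or max(idx) >= matrix.n_chars):
        raise MatrixValidationError("character index out of range")
    return idx


def matrix_overlap(m1: CharacterMatrix, m2: CharacterMatrix, char_map: Mapping[int, int] | None = None) -> float:
    """Cells in common between two matrices as a percentage of the smaller.

    Shared cells are shared-taxon x shared-character positions, regardless
    of the scored states.  Character identity comes from `char_map`
    (m1 index -> m2 index) or, by default, exact character-label match.
    """
    shared_taxa = set(m1.taxa) & set(m2.taxa)
    if char_map is None:
        lab2 = set(m2.char_labels)
        n_shared_chars = sum(1 for l in m1.char_labels if l in lab2)
    else:
        n_shared_chars = len(char_map)
    smaller = min(m1.n_taxa * m1.n_chars, m2.n_taxa * m2.n_chars)
    if smaller == 0:
        return 0.0
    return 100.0 * len(shared_taxa) * n_shared_chars / smaller


def is_informative(matrix: CharacterMatrix, char: int) -> bool:
    """Parsimony-informative: at least two states each observed as a fixed
    (singleton) score in at least two taxa."""
    col_m = matrix.masks[:, char]
    col_k = matrix.kinds[:, char]
    counts = {}
    for m, k in zip(col_m, col_k):
        if k == OBSERVED and int(m).bit_count() == 1:
            counts[int(m)] = counts.get(int(m), 0) + 1
    return sum(1 for c in counts.values() if c >= 2) >= 2


def is_variable(matrix: CharacterMatrix, char: int) -> bool:
    """At least two distinct fixed (singleton) observed states."""
    col_m = matrix.masks[:, char]
    col_k = matrix.kinds[:, char]
    states = {
        int(m) for m, k in zip(col_m, col_k)
        if k == OBSERVED and int(m).bit_count() == 1
    }
    return len(states) >= 2


def _newly_degraded(before: CharacterMatrix, after: CharacterMatrix, char: int) -> bool:
    """Did taxon removal render the character uninformative or invariant?"""
    return (
        (is_informative(before, char) and not is_informative(after, char))
        or (is_variable(before, char) and not is_variable(after, char))
    )


def remove_uninformative(
    matrix: CharacterMatrix,
    mode: str = "all",
    reference: CharacterMatrix | None = None,
) -> CharacterMatrix:
    """Strip parsimony-uninformative (incl. invariant) characters.

    mode="all" removes every uninformative character; mode="newly-only"
    removes only characters rendered uninformative or newly invariant
    relative to `reference` (the pre-curation matrix).
    """
    if mode not in ("all", "newly-only"):
        raise ValueError("mode must be 'all' or 'newly-only'")
    if mode == "newly-only" and reference is None:
        raise ValueError("mode='newly-only' requires a reference matrix")
    keep = []
    for c in range(matrix.n_chars):
        if mode == "all":
            if is_informative(matrix, c):
                keep.append(c)
        else:
            if not _newly_degraded(reference, matrix, c):
                keep.append(c)
    return matrix.subset(chars=keep)


def curate_matrix(
    matrix: CharacterMatrix,
    scheme: PartitionScheme,
    threshold: float = 0.40,
    iterate: bool = False,
):
    """Single-pass curation: drop taxa whose missing+inapplicable fraction
    exceeds `threshold` within either analysis partition, then drop
    characters rendered uninformative/invariant by those deletions.

    Returns (curated_matrix, curated_scheme, CurationReport).
    """
    if len(scheme.labels) != matrix.n_chars:
        raise MatrixValidationError("scheme does not cover the matrix")
    report = CurationReport(threshold=threshold)
    cur, sch = matrix, scheme
    while True:
        removed = []
        for ti, taxon in enumerate(cur.taxa):
            fr_c = cur.unscored_fraction(ti, sch.cranio)
            fr_p = cur.unscored_fraction(ti, sch.post)
            if fr_c > threshold or fr_p > threshold:
                removed.append(taxon)
                report.removed_taxa[taxon] = {CRANIO: fr_c, POST: fr_p}
        if removed:
            keep_taxa = [t for t in cur.taxa if t not in removed]
            if not keep_taxa:
                raise MatrixValidationError(
                    "curation removed every taxon; threshold too strict")
            trimmed = cur.subset(taxa=keep_taxa)
        else:
            trimmed = cur
        # characters newly rendered uninformative/invariant by the deletions
        drop = [
            c for c in range(trimmed.n_chars)
            if _newly_degraded(cur, trimmed, c)
        ]
        for c in drop:
            report.removed_characters[trimmed.char_labels[c]] = (
                "rendered uninformative by taxon removal")
        keep_chars = [c for c in range(trimmed.n_chars) if c not in set(drop)]
        nxt = trimmed.subset(chars=keep_chars)
        nxt_scheme = sch.subset(keep_chars)
        if not iterate or (not removed and not drop):
            return nxt, nxt_scheme, report
        if cur.n_taxa == nxt.n_taxa and cur.n_chars == nxt.n_chars:
            return nxt, nxt_scheme, report
        cur, sch = nxt, nxt_scheme
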