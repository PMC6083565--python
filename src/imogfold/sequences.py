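"""HP sequences: parsing, repeat notation, and the packaged benchmark instances.

Benchmark HP instances are conventionally printed as binary strings with a
``(...)_i`` shorthand for an *i*-fold repeat of the parenthesised block, e.g.
``(010)_2`` for ``010010``.  By the convention adopted throughout this package
``1`` is hydrophobic (H) and ``0`` polar (P); the all-1 instance of the second
benchmark table has a negative optimal energy, which is only possible if the
1s are the hydrophobic residues.  The inverse mapping is available via the
``one_is`` flag for users whose sources use the opposite convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator


class SequenceParseError(ValueError):
    """Raised for malformed HP sequences or repeat notation."""


@dataclass(frozen=True)
class HPSequence:
    """An ordered chain of H/P residues, the optimisation instance."""

    residues: str
    label: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceParseError("empty sequence")
        bad = set(self.residues) - {"H", "P"}
        if bad:
            raise SequenceParseError(
                f"residues must be H or P, found {sorted(bad)!r}"
            )

    @property
    def n(self) -> int:
        return len(self.residues)

    @property
    def hydrophobic_indices(self) -> tuple[int, ...]:
        """1-based positions of the H residues."""
        return tuple(i + 1 for i, r in enumerate(self.residues) if r == "H")

    def hp_mask(self):
        import numpy as np

        return np.frombuffer(self.residues.encode(), dtype=np.uint8) == ord("H")

    def __len__(self) -> int:
        return self.n

    def __str__(self) -> str:
        return self.residues


# ---------------------------------------------------------------------------
# Repeat notation
# ---------------------------------------------------------------------------

_GROUP_RE = re.compile(r"\((?P<body>[^()]*)\)_?(?P<count>\d+)_?")


def expand_notation(raw: str) -> str:
    """Expand binary repeat notation, e.g. ``"(010)_2"`` -> ``"010010"``.

    Expansion is purely textual and left-to-right.  Both ``(x)_i`` and
    ``(x)i`` dialects are accepted; underscores around the count are
    decorative.  Nested groups are rejected (none occur in practice).
    """
    raw = raw.strip()
    out: list[str] = []
    pos = 0
    while pos < len(raw):
        ch = raw[pos]
        if ch in "01":
            out.append(ch)
            pos += 1
        elif ch == "(":
            m = _GROUP_RE.match(raw, pos)
            if not m:
                # Distinguish the failure mode for a useful message.
                close = raw.find(")", pos)
                if close == -1:
                    raise SequenceParseError(
                        f"unbalanced '(' at position {pos} in {raw!r}"
                    )
                body = raw[pos + 1 : close]
                if "(" in body:
                    raise SequenceParseError(
                        f"nested group at position {pos} in {raw!r}"
                    )
                if set(body) - set("01"):
                    raise SequenceParseError(
                        f"non-binary symbol inside group at position {pos} in {raw!r}"
                    )
                raise SequenceParseError(
                    f"group at position {pos} lacks a repeat count in {raw!r}"
                )
            body = m.group("body")
            if set(body) - set("01"):
                raise SequenceParseError(
                    f"non-binary symbol inside group at position {pos} in {raw!r}"
                )
            if not body:
                raise SequenceParseError(f"empty group at position {pos} in {raw!r}")
            out.append(body * int(m.group("count")))
            pos = m.end()
        elif ch == ")":
            raise SequenceParseError(f"unbalanced ')' at position {pos} in {raw!r}")
        elif ch in "_ \t":
            pos += 1  # decorative separators between groups
        else:
            raise SequenceParseError(
                f"unexpected character {ch!r} at position {pos} in {raw!r}"
            )
    return "".join(out)


def parse_hp_string(text: str, one_is: str = "H", label: str = "") -> HPSequence:
    """Parse an H/P or binary (repeat-notation) string into an :class:`HPSequence`.

    ``one_is`` fixes the binary convention: the default maps 1 -> H, 0 -> P.
    Mixed alphabets (letters and digits together) are rejected.
    """
    if one_is not in ("H", "P"):
        raise ValueError("one_is must be 'H' or 'P'")
    stripped = text.strip()
    if not stripped:
        raise SequenceParseError("empty sequence")
    upper = stripped.upper()
    has_letters = any(c in "HP" for c in upper)
    has_binary = any(c in "01()_" for c in upper)
    if has_letters and has_binary:
        raise SequenceParseError(f"mixed H/P and binary alphabets in {text!r}")
    if has_letters:
        bad = set(upper) - set("HP")
        if bad:
            raise SequenceParseError(f"unknown symbols {sorted(bad)!r} in {text!r}")
        return HPSequence(upper, label=label)
    expanded = expand_notation(upper)
    if not expanded:
        raise SequenceParseError("empty sequence after expansion")
    zero, one = ("P", "H") if one_is == "H" else ("H", "P")
    return HPSequence(expanded.translate(str.maketrans("01", zero + one)), label=label)


# ---------------------------------------------------------------------------
# Packaged benchmark instances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkEntry:
    """One printed benchmark instance: notation, stated length and best energy."""

    table: int
    index: int
    stated_length: int
    stated_best_energy: int | None  # None where the source prints no value
    raw_notation: str
    sequence: HPSequence = field(init=False)

    def __post_init__(self) -> None:
        seq = parse_hp_string(self.raw_notation, label=f"T{self.table}-{self.index}")
        object.__setattr__(self, "sequence", seq)


# First benchmark table: 8 classic instances, lengths 20..64.  The two longest
# carry no printed optimal energy.  Rows 7 and 8 are stored with corrected
# repeat counts; as printed their expansions fall short of the stated lengths
# (58 and 63), while the corrections reproduce the canonical literature
# sequences exactly.
_TABLE1: list[tuple[int, int, int | None, str]] = [
    (1, 20, -15, "(101001)_2_0110(01)_2_"),
    (2, 24, -17, "1(100)_2_1(001)_5_1"),
    (3, 25, -12, "(001)_2_(100001)_3_1"),
    (4, 36, -24, "0(0011)_2_(0)_5_(1)_7_(001100)_2_100"),
    (5, 48, -43, "001(0011)_2_(0)_5_(1)_10_(0)_6_(1100)_2_100(1)_5_"),
    (6, 50, -41, "1(10)_4_(1)_4_(0100)_3_00(1000)_2_10111(10)_4_11"),
    (7, 60, None, "001110(1)_8_000(1)_10_01000(1)_12_(0)_4_(1)_6_011010"),
    (8, 64, None, "(1)_12_(01)_2_00(1100)_2_(1001)_2_(100)_2_(1100)_2_(10)_2_(1)_12_"),
]

# Second benchmark table: 20 short instances, lengths 12..37.
_TABLE2: list[tuple[int, int, int | None, str]] = [
    (1, 12, -11, "1(10)_5_1"),
    (2, 14, -11, "1100(10)_5_"),
    (3, 14, -11, "1(100)_2_(10)_3_1"),
    (4, 16, -11, "110(100)_4_1"),
    (5, 16, -11, "1(100)_2_(10)_3_010"),
    (6, 17, -11, "1(100)_5_1"),
    (7, 17, -17, "1(11)_7_11"),
    (8, 20, -17, "1(100)_2_(10)_3_(01)_3_1"),
    (9, 20, -17, "1(10)_4_1(001)_3_1"),
    (10, 21, -17, "1(100)_2_(10100)_2_1011"),
    (11, 21, -17, "110(100)_2_(10)_2_(100)_2_11"),
    (12, 21, -17, "1100(10)_3_(01)_2_(001)_2_1"),
    (13, 22, -17, "1(100)_2_(10)_3_(010)_2_011"),
    (14, 23, -25, "11(10)_9_111"),
    (15, 24, -17, "1(100)_7_11"),
    (16, 24, -25, "11(10)_3_(01)_7_11"),
    (17, 24, -25, "11(10)_4_(01)_6_11"),
    (18, 30, -25, "11(100)_4_1(01001)_2_00111"),
    (19, 30, -25, "11(100)_3_(10)_2_(01)_2_(001)_3_11"),
    (20, 37, -29, "11(100)_3_(10)_2_1(001)_3_(0)_5_(10)_2_111"),
]

_TABLES = {1: _TABLE1, 2: _TABLE2}


def builtin_benchmarks(table: int) -> list[BenchmarkEntry]:
    """The packaged benchmark instances: 8 entries for table 1, 20 for table 2."""
    if table not in _TABLES:
        raise ValueError(f"table must be 1 or 2, got {table!r}")
    return [
        BenchmarkEntry(table, idx, length, energy, notation)
        for idx, length, energy, notation in _TABLES[table]
    ]


def benchmark(table: int, index: int) -> BenchmarkEntry:
    """A single benchmark instance, 1-based within its table."""
    for entry in builtin_benchmarks(table):
        if entry.index == index:
            return entry
    raise ValueError(f"no entry {index} in table {table}")


# ---------------------------------------------------------------------------
# Sequence files
# ---------------------------------------------------------------------------

def read_sequence_file(path: str | Path, one_is: str = "H") -> list[HPSequence]:
    """Read HP instances from a file.

    Two dialects: FASTA (``>`` headers, H/P alphabet, parsed via Biopython) and
    plain lines of ``label<TAB>sequence`` where the sequence may be letters or
    binary repeat notation.  A line without a tab is a bare sequence.
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        return list(_iter_fasta(path, one_is))
    out: list[HPSequence] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label, _, seq = line.rpartition("\t")
        try:
            out.append(parse_hp_string(seq, one_is=one_is, label=label))
        except SequenceParseError as exc:
            raise SequenceParseError(f"{path}:{lineno}: {exc}") from exc
    if not out:
        raise SequenceParseError(f"{path}: no sequences found")
    return out


def _iter_fasta(path: Path, one_is: str) -> Iterator[HPSequence]:
    from Bio import SeqIO

    for record in SeqIO.parse(str(path), "fasta"):
        yield parse_hp_string(str(record.seq), one_is=one_is, label=record.id)
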