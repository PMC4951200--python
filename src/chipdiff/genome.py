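"""Genome coordinate space.

A :class:`GenomeTable` is an ordered chromosome -> length map read from a
UCSC ``chrom.sizes`` file (two tab-separated columns: name, length).  Its
order is stable and defines the ordering of every downstream output
(coverage tracks, window tilings, region calls).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator


@dataclass(frozen=True)
class GenomeTable:
    """Ordered map of chromosome names to lengths (bp).

    Parameters
    ----------
    entries
        Sequence of ``(name, length)`` pairs.  Names must be unique and
        lengths strictly positive.
    """

    entries: tuple[tuple[str, int], ...]
    _lengths: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        entries = tuple((str(n), int(l)) for n, l in self.entries)
        object.__setattr__(self, "entries", entries)
        lengths: dict[str, int] = {}
        for name, length in entries:
            if name in lengths:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            if length <= 0:
                raise ValueError(
                    f"chromosome {name!r} has non-positive length {length}"
                )
            lengths[name] = length
        object.__setattr__(self, "_lengths", lengths)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.entries)

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome: {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    def __contains__(self, chrom: object) -> bool:
        return chrom in self._lengths

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.entries)

    @classmethod
    def from_entries(cls, entries: Iterable[tuple[str, int]]) -> "GenomeTable":
        return cls(tuple(entries))

    def to_file(self, path: str | Path) -> None:
        """Write as chrom.sizes (TSV: name, length), preserving order."""
        with open(path, "w") as fh:
            for name, length in self.entries:
                fh.write(f"{name}\t{length}\n")


def read_genome_table(path: str | Path) -> GenomeTable:
    """Parse a ``chrom.sizes`` file into a :class:`GenomeTable`.

    Each non-empty line must be ``name<TAB>length`` with a strictly
    positive integer length.  File order is preserved.  An empty file
    yields an empty table (downstream operations on it return empty
    results).

    Raises
    ------
    ValueError
        On a duplicate chromosome name (naming the duplicate) or a
        malformed / non-positive length (naming the line number).
    """
    entries: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'name<TAB>length', got {line!r}"
                )
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer chromosome length {fields[1]!r}"
                ) from None
            if length <= 0:
                raise ValueError(
                    f"{path}:{lineno}: non-positive chromosome length {length}"
                )
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome name {name!r}")
            seen.add(name)
            entries.append((name, length))
    return GenomeTable(tuple(entries))
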