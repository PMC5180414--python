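"""Two-step dictionary search: a binary index over sorted key-coordinate
text databases.

A database is tab-delimited text, column 1 = key (any string, typically a
chromosome/contig), column 2 = integer coordinate, sorted by key then
coordinate. Lines are split per key into bins of ``bin_size`` lines
(default 10). The index records, per bin, the first coordinate and the byte
offset of the bin start; a key directory maps key names to their bin
arrays. A query locates the candidate bin by binary search in the directory
(step one), seeks there, and reads forward sequentially (step two), so the
cost is bounded by two random accesses plus a bounded sequential scan.

The on-disk index is a versioned little-endian sidecar file ``<db>.tds``.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from bisect import bisect_left
from pathlib import Path

from .errors import InvalidIntervalError, SortOrderError

MAGIC = b"TDS1"
DEFAULT_BIN_SIZE = 10


@dataclass
class TdsIndex:
    """In-memory form of the binary index.

    ``bins[key]`` is a pair of parallel lists: first coordinate of each bin
    and byte offset of each bin start, both strictly increasing in offset.
    """

    bin_size: int = DEFAULT_BIN_SIZE
    bins: dict[str, tuple[list[int], list[int]]] = field(default_factory=dict)

    # -- construction ------------------------------------------------------

    @classmethod
    def build(cls, db_path: str | Path, bin_size: int = DEFAULT_BIN_SIZE) -> "TdsIndex":
        """Index a sorted database file.

        Raises :class:`SortOrderError` (naming the offending line) when keys
        reappear after an intervening key or coordinates decrease within a
        key. An empty file yields an empty index.
        """
        if bin_size < 1:
            raise ValueError(f"bin_size must be >= 1, got {bin_size}")
        index = cls(bin_size=bin_size)
        seen_done: set[str] = set()
        cur_key: str | None = None
        cur_coord: int | None = None
        lines_in_bin = 0
        with open(db_path, "rb") as fh:
            lineno = 0
            while True:
                offset = fh.tell()
                raw = fh.readline()
                if not raw:
                    break
                lineno += 1
                key, coord = _parse_key_coord(raw, lineno)
                if key != cur_key:
                    if key in seen_done:
                        raise SortOrderError(
                            f"key {key!r} reappears after other keys", lineno
                        )
                    if cur_key is not None:
                        seen_done.add(cur_key)
                    cur_key, cur_coord = key, None
                    index.bins[key] = ([], [])
                    lines_in_bin = 0
                elif cur_coord is not None and coord < cur_coord:
                    raise SortOrderError(
                        f"coordinate {coord} < {cur_coord} within key {key!r}", lineno
                    )
                cur_coord = coord
                if lines_in_bin == 0:
                    firsts, offsets = index.bins[key]
                    firsts.append(coord)
                    offsets.append(offset)
                lines_in_bin = (lines_in_bin + 1) % bin_size
        return index

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            fh.write(MAGIC)
            fh.write(struct.pack("<II", self.bin_size, len(self.bins)))
            for key, (firsts, offsets) in self.bins.items():
                kb = key.encode()
                fh.write(struct.pack("<HQ", len(kb), len(firsts)))
                fh.write(kb)
                for c, o in zip(firsts, offsets):
                    fh.write(struct.pack("<qQ", c, o))

    @classmethod
    def load(cls, path: str | Path) -> "TdsIndex":
        with open(path, "rb") as fh:
            if fh.read(4) != MAGIC:
                raise ValueError(f"{path}: not a TDS index file")
            bin_size, n_keys = struct.unpack("<II", fh.read(8))
            index = cls(bin_size=bin_size)
            for _ in range(n_keys):
                klen, nbins = struct.unpack("<HQ", fh.read(10))
                key = fh.read(klen).decode()
                firsts: list[int] = []
                offsets: list[int] = []
                for _ in range(nbins):
                    c, o = struct.unpack("<qQ", fh.read(16))
                    firsts.append(c)
                    offsets.append(o)
                index.bins[key] = (firsts, offsets)
        return index

    def n_bins(self, key: str) -> int:
        return len(self.bins[key][0]) if key in self.bins else 0


def _parse_key_coord(raw: bytes, lineno: int) -> tuple[str, int]:
    parts = raw.rstrip(b"\r\n").split(b"\t")
    if len(parts) < 2:
        raise SortOrderError("fewer than 2 tab-delimited columns", lineno)
    try:
        coord = int(parts[1])
    except ValueError:
        raise SortOrderError(f"non-integer coordinate {parts[1]!r}", lineno)
    return parts[0].decode(), coord


class TdsDatabase:
    """A sorted text database plus its TDS index, with the query path.

    The sidecar ``<db>.tds`` is built on first use when absent.
    """

    def __init__(self, db_path: str | Path, bin_size: int = DEFAULT_BIN_SIZE):
        self.db_path = Path(db_path)
        self.index_path = Path(str(db_path) + ".tds")
        if self.index_path.exists():
            self.index = TdsIndex.load(self.index_path)
        else:
            self.index = TdsIndex.build(self.db_path, bin_size=bin_size)
            self.index.save(self.index_path)

    def query(self, key: str, start: int, end: int | None = None) -> list[str]:
        """Return database lines with the given key and coordinate in
        ``[start, end]`` (inclusive), in file order.

        Unknown keys return an empty list; ``start > end`` is an error.
        """
        if end is None:
            end = start
        if start > end:
            raise InvalidIntervalError(f"start ({start}) > end ({end})")
        if key not in self.index.bins:
            return []
        firsts, offsets = self.index.bins[key]
        # scan from the bin before the first bin whose first coordinate
        # reaches start: duplicates of start may spill into the previous bin
        bin_i = max(bisect_left(firsts, start) - 1, 0)
        out: list[str] = []
        with open(self.db_path, "rb") as fh:
            fh.seek(offsets[bin_i])
            while True:
                raw = fh.readline()
                if not raw:
                    break
                k, coord = _parse_key_coord(raw, -1)
                if k != key or coord > end:
                    break
                if coord >= start:
                    out.append(raw.rstrip(b"\r\n").decode())
        return out
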