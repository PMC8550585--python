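"""Fixed-row-width table store with batch-granular dirty tracking.

The central data layout of this package: a 2D table whose rows all occupy
the same amount of memory regardless of how many items they actually hold,
plus a secondary vector with the current length of every row.  Because the
capacity is allocated once and never grows, localized edits (a cut severing
a few element-node links) touch a handful of rows in place instead of
shifting a packed ragged array.

Rows are grouped into contiguous *batches*, the unit of dirty tracking and
of mirror copying: a host-to-device mirror only needs to receive the dirty
batches, not the whole table.  A :class:`TransferLedger` accounts, frame by
frame, for the bytes such a mirror would receive under batched transfer
versus a full-table copy, so the transfer saving of the layout can be
quantified without any accelerator hardware.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import RowOverflowError, SoftcutError

#: Bytes used per entry of the row-length vector (int32 on the mirror).
ROW_LENGTH_BYTES = 4


@dataclass(frozen=True)
class TransferRecord:
    """One flush of one table in one frame."""

    frame: int
    table: str
    bytes_batched: int
    bytes_full: int
    n_dirty_batches: int


class TransferLedger:
    """Accumulates per-frame transfer records for a set of tables."""

    def __init__(self) -> None:
        self.records: list[TransferRecord] = []

    def record(self, rec: TransferRecord) -> None:
        self.records.append(rec)

    # -- queries ---------------------------------------------------------

    def frames(self) -> list[int]:
        """Sorted distinct frames with at least one record."""
        return sorted({r.frame for r in self.records})

    def frames_with_edits(self) -> list[int]:
        """Sorted distinct frames in which any table had a dirty batch."""
        return sorted({r.frame for r in self.records if r.n_dirty_batches > 0})

    def reduction(
        self,
        frames: Iterable[int] | None = None,
        table: str | None = None,
    ) -> float:
        """Transfer reduction ``1 - sum(batched) / sum(full)`` over ``frames``.

        ``frames=None`` means every recorded frame.  Raises
        :class:`SoftcutError` when the selection is empty.
        """
        frame_set = None if frames is None else set(frames)
        sel = [
            r
            for r in self.records
            if (frame_set is None or r.frame in frame_set)
            and (table is None or r.table == table)
        ]
        if not sel:
            raise SoftcutError("reduction over an empty frame/table selection")
        full = sum(r.bytes_full for r in sel)
        if full == 0:
            raise SoftcutError("selected tables have zero size")
        batched = sum(r.bytes_batched for r in sel)
        return 1.0 - batched / full

    def table_names(self) -> list[str]:
        return sorted({r.table for r in self.records})

    def reduction_report(
        self, frames: Iterable[int] | None = None
    ) -> dict[str, float]:
        """Per-table and aggregate reduction over a frame range.

        Returns a mapping ``{table_name: reduction, ..., "aggregate": r}``.
        """
        if frames is not None:
            frames = list(frames)
            if not frames:
                raise SoftcutError("empty frame range")
        out = {name: self.reduction(frames, name) for name in self.table_names()}
        out["aggregate"] = self.reduction(frames)
        return out

    # -- CSV dump --------------------------------------------------------

    CSV_FIELDS = ("frame", "table_name", "bytes_batched", "bytes_full", "n_dirty_batches")

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(self.CSV_FIELDS)
            for r in self.records:
                w.writerow((r.frame, r.table, r.bytes_batched, r.bytes_full, r.n_dirty_batches))

    @classmethod
    def from_csv(cls, path) -> "TransferLedger":
        ledger = cls()
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            for row in reader:
                ledger.record(
                    TransferRecord(
                        frame=int(row["frame"]),
                        table=row["table_name"],
                        bytes_batched=int(row["bytes_batched"]),
                        bytes_full=int(row["bytes_full"]),
                        n_dirty_batches=int(row["n_dirty_batches"]),
                    )
                )
        return ledger


class FixedWidthTable:
    """Pre-allocated 2D table with fixed row capacity and batch dirty flags.

    Parameters
    ----------
    n_rows, max_row_width:
        Capacity, fixed for the lifetime of the table.  No operation grows
        either dimension.
    dtype:
        NumPy dtype of one item.  May be a structured dtype (e.g. a
        node-index/weight pair for the surface mapping).
    item_shape:
        Trailing shape of one item, e.g. ``(3,)`` for gradient vectors.
    item_bytes:
        Modeled payload size of one item on the mirror.  Defaults to the
        in-memory itemsize times the item count.
    batch_size:
        Rows per transfer batch; the unit of dirty tracking.
    batched:
        When False, any edit marks the whole table for transfer (the
        no-batching reference policy used for comparison runs).
    name, ledger:
        Optional identification and accounting hookup; ``flush(frame=...)``
        appends a :class:`TransferRecord` when a ledger is attached.
    """

    def __init__(
        self,
        n_rows: int,
        max_row_width: int,
        dtype=np.float64,
        item_shape: tuple[int, ...] = (),
        item_bytes: int | None = None,
        batch_size: int = 64,
        batched: bool = True,
        name: str = "table",
        ledger: TransferLedger | None = None,
    ) -> None:
        if n_rows < 1 or max_row_width < 1 or batch_size < 1:
            raise SoftcutError("n_rows, max_row_width and batch_size must be >= 1")
        if batch_size > n_rows:
            raise SoftcutError("batch_size may not exceed n_rows")
        dtype = np.dtype(dtype)
        if item_bytes is None:
            item_bytes = int(dtype.itemsize * np.prod(item_shape, dtype=int)) if item_shape else dtype.itemsize
        if item_bytes < 1:
            raise SoftcutError("item_bytes must be >= 1")
        self.n_rows = int(n_rows)
        self.max_row_width = int(max_row_width)
        self.item_bytes = int(item_bytes)
        self.batch_size = int(batch_size)
        self.batched = bool(batched)
        self.name = name
        self.ledger = ledger
        self.payload = np.zeros((n_rows, max_row_width) + tuple(item_shape), dtype=dtype)
        self.row_lengths = np.zeros(n_rows, dtype=np.int32)
        self.dirty = np.zeros(self.n_batches, dtype=bool)

    # -- geometry --------------------------------------------------------

    @property
    def n_batches(self) -> int:
        return -(-self.n_rows // self.batch_size)

    def batch_of_row(self, row: int) -> int:
        return row // self.batch_size

    def batch_rows(self, batch: int) -> slice:
        lo = batch * self.batch_size
        return slice(lo, min(lo + self.batch_size, self.n_rows))

    def batch_bytes(self, batch: int) -> int:
        """Mirror bytes for one batch: payload slots plus row-length slice."""
        rows = self.batch_rows(batch)
        n = rows.stop - rows.start
        return n * (self.max_row_width * self.item_bytes + ROW_LENGTH_BYTES)

    @property
    def bytes_full(self) -> int:
        return self.n_rows * (self.max_row_width * self.item_bytes + ROW_LENGTH_BYTES)

    # -- access ----------------------------------------------------------

    def write_row(self, row: int, items: Sequence | np.ndarray) -> None:
        """Replace a row's content and length; marks the row's batch dirty.

        Unused trailing slots are zero-filled so serialization is
        reproducible; consumers must still honor ``row_lengths``.  Raises
        :class:`RowOverflowError` (table unchanged) when ``items`` exceeds
        the fixed row capacity.
        """
        if not 0 <= row < self.n_rows:
            raise IndexError(f"row {row} out of range [0, {self.n_rows})")
        items = np.asarray(items, dtype=self.payload.dtype)
        n = items.shape[0] if items.ndim else int(items.size > 0)
        if n > self.max_row_width:
            raise RowOverflowError(
                f"table {self.name!r}: row {row} would hold {n} items, "
                f"max_row_width is {self.max_row_width}",
                row_index=row,
            )
        self.payload[row, :n] = items
        self.payload[row, n:] = np.zeros((), dtype=self.payload.dtype)
        self.row_lengths[row] = n
        self.dirty[self.batch_of_row(row)] = True

    def read_row(self, row: int) -> np.ndarray:
        """Copy of the occupied slots of a row."""
        return self.payload[row, : self.row_lengths[row]].copy()

    # -- transfer --------------------------------------------------------

    def flush(self, frame: int | None = None) -> list[tuple[int, int]]:
        """Return the transfer plan for dirty batches and clear the flags.

        The plan is a list of ``(batch_index, byte_count)``; after a flush a
        mirror that copies exactly those batches sees the current payload
        and row lengths of every flushed row.  With batching disabled any
        edit transfers the full table.  When a ledger is attached and
        ``frame`` is given, the flush is recorded against that frame.
        """
        dirty_idx = np.flatnonzero(self.dirty)
        if self.batched:
            plan = [(int(b), self.batch_bytes(int(b))) for b in dirty_idx]
        elif len(dirty_idx) > 0:
            plan = [(b, self.batch_bytes(b)) for b in range(self.n_batches)]
        else:
            plan = []
        self.dirty[:] = False
        if self.ledger is not None and frame is not None:
            self.ledger.record(
                TransferRecord(
                    frame=frame,
                    table=self.name,
                    bytes_batched=sum(b for _, b in plan),
                    bytes_full=self.bytes_full,
                    n_dirty_batches=len(dirty_idx),
                )
            )
        return plan


class TableMirror:
    """Host-memory stand-in for a device-side copy of a table.

    ``sync`` applies a flush plan by copying only the planned batches from
    the source.  After every flush the mirror must equal the source on all
    rows — the mirror-equivalence contract of batched transfer.
    """

    def __init__(self, table: FixedWidthTable) -> None:
        self.table = table
        self.payload = table.payload.copy()
        self.row_lengths = table.row_lengths.copy()

    def sync(self, plan: Iterable[tuple[int, int]]) -> int:
        """Copy the batches named in ``plan``; returns bytes copied."""
        total = 0
        for batch, nbytes in plan:
            rows = self.table.batch_rows(batch)
            self.payload[rows] = self.table.payload[rows]
            self.row_lengths[rows] = self.table.row_lengths[rows]
            total += nbytes
        return total

    def equals_source(self) -> bool:
        return bool(
            np.array_equal(self.payload, self.table.payload)
            and np.array_equal(self.row_lengths, self.table.row_lengths)
        )
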