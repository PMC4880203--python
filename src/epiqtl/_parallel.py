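"""Worker-count-invariant parallel mapping with static chunking.

Work items (kinship cell blocks, marker indices, pair indices) are split
into contiguous chunks whose sizes differ by at most one, mirroring the
``m/p`` allocation arithmetic of a static scheduler.  Because every item is
computed independently and results are reassembled in submission order, the
gathered output is bit-for-bit identical for any worker count.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["chunk_items", "parallel_map"]


def chunk_items(n_items: int, p: int) -> list[np.ndarray]:
    """Partition ``range(n_items)`` into ``min(p, n_items)`` contiguous chunks."""
    if p < 1:
        raise ValueError("worker count must be >= 1")
    p = min(p, max(n_items, 1))
    return [c for c in np.array_split(np.arange(n_items), p) if c.size]


def _apply_chunk(fn: Callable, items: Sequence) -> list:
    out = []
    for it in items:
        try:
            out.append(fn(it))
        except Exception as exc:
            raise RuntimeError(f"worker failed on item {it!r}: {exc}") from exc
    return out


def parallel_map(items: Sequence, fn: Callable, workers: int = 1) -> list:
    """Apply ``fn`` to every item, optionally across worker processes.

    Results are returned in input order regardless of ``workers``.
    """
    items = list(items)
    if workers < 1:
        raise ValueError("worker count must be >= 1")
    if workers == 1 or len(items) <= 1:
        return _apply_chunk(fn, items)
    from joblib import Parallel, delayed

    chunks = chunk_items(len(items), workers)
    parts = Parallel(n_jobs=min(workers, len(chunks)))(
        delayed(_apply_chunk)(fn, [items[i] for i in c]) for c in chunks
    )
    return [r for part in parts for r in part]
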