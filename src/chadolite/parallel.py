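"""Order-preserving parallel staging for loaders.

Parsing/staging of records may fan out over a thread pool, but results are
returned in input order and all store writes stay on the calling thread, so
the final store state is identical for any worker count.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from typing import Callable, Iterable, Sequence, TypeVar

T = TypeVar("T")
R = TypeVar("R")


def parallel_map(fn: Callable[[T], R], items: Sequence[T],
                 threads: int = 1) -> list[R]:
    """Map ``fn`` over ``items``, optionally on ``threads`` workers.

    Results come back in input order regardless of completion order.
    """
    items = list(items)
    if threads <= 1 or len(items) < 2:
        return [fn(item) for item in items]
    with ThreadPoolExecutor(max_workers=threads) as pool:
        return list(pool.map(fn, items))
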