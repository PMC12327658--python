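"""Balanced incomplete block designs for best-worst scaling questionnaires.

A BWS questionnaire shows each respondent a sequence of choice sets
(blocks), each a size-``k`` subset of the ``v`` items under study.  For the
item utilities to be estimated with equal precision, the design should be a
balanced incomplete block design (BIBD): every item appears in the same
number of sets (``r``) and every unordered pair of items co-occurs in the
same number of sets (``lambda``).  The classical construction used here
develops a *difference set* — a ``k``-subset of the integers mod ``v`` whose
pairwise differences hit every nonzero residue exactly ``lambda`` times —
into ``v`` blocks by cyclic shifting.  For the 15-item layout with 15 sets
of 7 options this yields the (v, b, k, r, lambda) = (15, 15, 7, 7, 3)
design in which every item appears 7 times and every pair co-occurs 3
times.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import pandas as pd

__all__ = [
    "ItemSet",
    "BWSDesign",
    "BalanceReport",
    "DesignError",
    "find_difference_set",
    "develop_design",
    "check_balance",
    "make_bibd_design",
    "read_design_csv",
    "write_design_csv",
]


class DesignError(ValueError):
    """Raised for invalid design parameters or malformed designs."""


@dataclass(frozen=True)
class ItemSet:
    """The universe of choice options.

    Parameters
    ----------
    items
        Ordered, unique item labels.  Best-worst scaling needs at least
        three options so that a best and a worst choice are informative.
    """

    items: tuple[str, ...]

    def __init__(self, items: Sequence[str]):
        items = tuple(str(x) for x in items)
        if len(items) < 3:
            raise DesignError("an item set needs at least 3 items")
        if len(set(items)) != len(items):
            dupes = [x for x, c in Counter(items).items() if c > 1]
            raise DesignError(f"duplicate item labels: {dupes}")
        object.__setattr__(self, "items", items)

    @property
    def v(self) -> int:
        return len(self.items)

    def index(self, label: str) -> int:
        try:
            return self.items.index(label)
        except ValueError:
            raise DesignError(f"unknown item label: {label!r}") from None

    def __len__(self) -> int:
        return self.v

    def __iter__(self):
        return iter(self.items)


@dataclass(frozen=True)
class BWSDesign:
    """A block design: ``b`` choice sets, each an ordered list of ``k``
    distinct item indices into ``item_set``.

    Within a block an item may appear only once; all blocks share the same
    size ``k`` with 3 <= k <= v.
    """

    item_set: ItemSet
    blocks: tuple[tuple[int, ...], ...]

    def __init__(self, item_set: ItemSet, blocks: Sequence[Sequence[int]]):
        blocks = tuple(tuple(int(i) for i in blk) for blk in blocks)
        if not blocks:
            raise DesignError("a design needs at least one block")
        k = len(blocks[0])
        v = item_set.v
        if not 3 <= k <= v:
            raise DesignError(f"block size {k} outside [3, v={v}]")
        for j, blk in enumerate(blocks):
            if len(blk) != k:
                raise DesignError(f"block {j} has size {len(blk)}, expected {k}")
            if len(set(blk)) != k:
                raise DesignError(f"block {j} repeats an item")
            for i in blk:
                if not 0 <= i < v:
                    raise DesignError(f"block {j}: item index {i} outside [0, {v})")
        object.__setattr__(self, "item_set", item_set)
        object.__setattr__(self, "blocks", blocks)

    @property
    def v(self) -> int:
        return self.item_set.v

    @property
    def b(self) -> int:
        return len(self.blocks)

    @property
    def k(self) -> int:
        return len(self.blocks[0])

    def block_labels(self, j: int) -> tuple[str, ...]:
        """Item labels of block ``j`` (0-based) in presentation order."""
        return tuple(self.item_set.items[i] for i in self.blocks[j])


@dataclass(frozen=True)
class BalanceReport:
    """Exact replication and pair co-occurrence counts of a design."""

    v: int
    b: int
    k: int
    replication: tuple[int, ...]
    lambda_pair: dict = field(repr=False)
    r: int | None
    lam: int | None
    is_bibd: bool

    def __str__(self) -> str:  # pragma: no cover - display helper
        head = f"BalanceReport(v={self.v}, b={self.b}, k={self.k}, "
        if self.is_bibd:
            return head + f"r={self.r}, lambda={self.lam}, BIBD)"
        return head + "not balanced)"


def find_difference_set(v: int, k: int, lam: int) -> frozenset[int]:
    """Find a (v, k, lam) difference set in the integers mod ``v``.

    Returns the lexicographically smallest ``k``-subset containing 0 whose
    multiset of ordered differences covers every nonzero residue exactly
    ``lam`` times.  Deterministic: the same parameters always yield the
    same set.

    Raises
    ------
    DesignError
        If the counting identity lam*(v-1) = k*(k-1) fails, or no
        difference set with these parameters exists.
    """
    if v < 3:
        raise DesignError("v must be >= 3")
    if not 2 <= k < v:
        raise DesignError("need 2 <= k < v")
    if lam * (v - 1) != k * (k - 1):
        raise DesignError(
            f"no (v={v}, k={k}, lambda={lam}) difference set: "
            f"{lam}*{v - 1} != {k}*{k - 1}"
        )
    # WLOG a difference set can be shifted to contain 0; combinations() is
    # lexicographic so the first hit is the smallest such set.
    for rest in combinations(range(1, v), k - 1):
        cand = (0,) + rest
        counts = Counter((x - y) % v for x in cand for y in cand if x != y)
        if all(counts[d] == lam for d in range(1, v)):
            return frozenset(cand)
    raise DesignError(f"no (v={v}, k={k}, lambda={lam}) difference set exists")


def develop_design(diff_set: frozenset[int] | Sequence[int], v: int,
                   item_set: ItemSet) -> BWSDesign:
    """Develop a difference set into a cyclic design with ``v`` blocks.

    Block ``j`` is ``{(d + j) mod v for d in diff_set}`` with items in
    cyclic-shift order.  The result is a BIBD with r = k and
    lambda = k(k-1)/(v-1).
    """
    if item_set.v != v:
        raise DesignError(
            f"item set has {item_set.v} items but the modulus is {v}")
    base = sorted(int(d) for d in diff_set)
    if any(not 0 <= d < v for d in base):
        raise DesignError("difference-set residues must lie in [0, v)")
    blocks = [tuple((d + j) % v for d in base) for j in range(v)]
    return BWSDesign(item_set, blocks)


def check_balance(design: BWSDesign) -> BalanceReport:
    """Count item replications and pair co-occurrences by enumeration."""
    v, b, k = design.v, design.b, design.k
    rep = [0] * v
    pair: Counter = Counter()
    for blk in design.blocks:
        for i in blk:
            rep[i] += 1
        for i, j in combinations(sorted(blk), 2):
            pair[(i, j)] += 1
    all_pairs = {p: pair.get(p, 0) for p in combinations(range(v), 2)}
    rep_vals = set(rep)
    lam_vals = set(all_pairs.values())
    r = rep[0] if len(rep_vals) == 1 else None
    lam = next(iter(lam_vals)) if len(lam_vals) == 1 else None
    return BalanceReport(
        v=v, b=b, k=k,
        replication=tuple(rep),
        lambda_pair=all_pairs,
        r=r, lam=lam,
        is_bibd=(r is not None and lam is not None),
    )


def make_bibd_design(item_set: ItemSet, n_sets: int, set_size: int) -> BWSDesign:
    """Build a cyclic BIBD with ``n_sets`` blocks of ``set_size`` options.

    Currently supports the symmetric case n_sets == v, where a difference
    set exists; lambda is inferred from the counting identity.
    """
    v = item_set.v
    if n_sets != v:
        raise DesignError(
            "cyclic difference-set construction requires n_sets == number "
            f"of items (got {n_sets} sets for {v} items)")
    num = set_size * (set_size - 1)
    if num % (v - 1):
        raise DesignError(
            f"no balanced design: k(k-1)={num} not divisible by v-1={v - 1}")
    lam = num // (v - 1)
    ds = find_difference_set(v, set_size, lam)
    return develop_design(ds, v, item_set)


def write_design_csv(design: BWSDesign, path) -> None:
    """Write a design as CSV with header ``block,position,item``.

    Blocks and positions are numbered from 1; items are written as labels.
    """
    rows = [
        {"block": j + 1, "position": p + 1, "item": design.item_set.items[i]}
        for j, blk in enumerate(design.blocks)
        for p, i in enumerate(blk)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_design_csv(path, item_set: ItemSet | None = None) -> BWSDesign:
    """Read a ``block,position,item`` CSV back into a :class:`BWSDesign`.

    If ``item_set`` is omitted, the items are taken to be the labels seen
    in the file, ordered by first appearance.
    """
    df = pd.read_csv(path, dtype={"item": str})
    missing = {"block", "position", "item"} - set(df.columns)
    if missing:
        raise DesignError(f"design CSV missing columns: {sorted(missing)}")
    if item_set is None:
        seen: dict[str, None] = {}
        for label in df["item"]:
            seen.setdefault(label, None)
        item_set = ItemSet(list(seen))
    blocks = []
    for _, grp in df.sort_values(["block", "position"]).groupby("block", sort=True):
        blocks.append([item_set.index(label) for label in grp["item"]])
    return BWSDesign(item_set, blocks)
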