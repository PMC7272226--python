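"""Kinship and inbreeding coefficients from explicit pedigrees.

Wright's path-counting definition: the inbreeding coefficient ``F`` of
an individual is the probability that its two alleles at a locus are
identical by descent, obtained by summing ``(1/2)**(n1 + n2 + 1)`` over
all distinct ancestral paths connecting the parents through a common
ancestor (``n1``/``n2`` = path lengths to that ancestor).  The recursive
kinship formulation implemented here is algebraically identical and
handles arbitrary pedigrees:

    phi(a, a) = (1 + F_a) / 2
    phi(a, b) = (phi(father_a, b) + phi(mother_a, b)) / 2

with founders mutually unrelated and the recursion always descending
through the individual furthest from the founders.  ``F`` of a child is
the kinship of its parents.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Hashable, Optional


class Pedigree:
    """A pedigree as a child -> (father, mother) mapping.

    Founders are individuals without registered parents.  Individuals
    may be added in any order as long as the graph is acyclic.
    """

    def __init__(self) -> None:
        self._parents: dict[Hashable, tuple[Optional[Hashable], Optional[Hashable]]] = {}

    def add(
        self,
        child: Hashable,
        father: Optional[Hashable] = None,
        mother: Optional[Hashable] = None,
    ) -> None:
        if child in self._parents:
            raise ValueError(f"individual {child!r} already in pedigree")
        self._parents[child] = (father, mother)

    def parents(self, individual: Hashable):
        return self._parents.get(individual, (None, None))

    def __len__(self) -> int:
        return len(self._parents)

    def __contains__(self, individual: Hashable) -> bool:
        return individual in self._parents

    def _depth(self, individual: Hashable, _seen: frozenset = frozenset()) -> int:
        if individual in _seen:
            raise ValueError("pedigree contains a cycle")
        father, mother = self.parents(individual)
        seen = _seen | {individual}
        depths = [self._depth(p, seen) for p in (father, mother) if p is not None]
        return 1 + max(depths, default=-1)

    def kinship(self, a: Hashable, b: Hashable) -> float:
        """Kinship coefficient phi(a, b)."""

        @lru_cache(maxsize=None)
        def phi(x: Hashable, y: Hashable) -> float:
            if x == y:
                fx, mx = self.parents(x)
                f_x = 0.0 if fx is None or mx is None else phi(*_ordered(fx, mx))
                return 0.5 * (1.0 + f_x)
            # Recurse through the individual furthest from the founders
            # so every step strictly reduces total depth.
            if self._depth(x) < self._depth(y):
                x, y = y, x
            fx, mx = self.parents(x)
            if fx is None or mx is None:
                return 0.0  # founder unrelated to everyone else
            return 0.5 * (phi(*_ordered(fx, y)) + phi(*_ordered(mx, y)))

        def _ordered(x, y):
            # canonicalise the argument pair for the cache
            sx, sy = sorted((str(x), str(y)))
            return (x, y) if (str(x), str(y)) == (sx, sy) else (y, x)

        return phi(*_ordered(a, b))

    def inbreeding(self, individual: Hashable) -> float:
        """Inbreeding coefficient F of ``individual`` (kinship of its parents)."""
        father, mother = self.parents(individual)
        if father is None or mother is None:
            return 0.0
        return self.kinship(father, mother)


def cousin_mating_pedigree(degree: int = 2) -> tuple[Pedigree, Hashable]:
    """Pedigree in which two ``degree``-th cousins have a child.

    ``degree=1`` gives first cousins (child ``F`` = 1/16), ``degree=2``
    second cousins (child ``F`` = 1/64), and so on.  Returns the
    pedigree and the identifier of the offspring.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    ped = Pedigree()
    # shared ancestral couple
    ped.add("A0")
    ped.add("B0")
    # two sibling lines descending from the shared couple
    left, right = "L0", "R0"
    ped.add(left, "A0", "B0")
    ped.add(right, "A0", "B0")
    for g in range(1, degree + 1):
        for side, prev in (("L", left), ("R", right)):
            spouse = f"{side}S{g}"
            ped.add(spouse)
            ped.add(f"{side}{g}", prev, spouse)
        left, right = f"L{g}", f"R{g}"
    ped.add("child", left, right)
    return ped, "child"


def second_cousin_inbreeding() -> float:
    """``F`` for the offspring of second cousins, by path counting (1/64)."""
    ped, child = cousin_mating_pedigree(degree=2)
    return ped.inbreeding(child)
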