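"""Direction-consistent convergent expression calls.

A gene is *shared* for a focal species if it is a DEG with the same
direction versus EVERY background species (intersection over comparisons;
``min_support`` relaxes to at least k of N comparisons). Convergent genes
are the per-direction intersections of the two focal species' shared sets,
computed against the same background.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError

__all__ = ["ConvergenceResult", "shared_degs", "convergent_genes"]


@dataclass
class ConvergenceResult:
    tissue: str
    shared_up_focal1: set[str]
    shared_down_focal1: set[str]
    shared_up_focal2: set[str]
    shared_down_focal2: set[str]
    convergent_up: set[str]
    convergent_down: set[str]

    def summary(self) -> dict[str, int]:
        return {
            "shared_up_focal1": len(self.shared_up_focal1),
            "shared_down_focal1": len(self.shared_down_focal1),
            "shared_up_focal2": len(self.shared_up_focal2),
            "shared_down_focal2": len(self.shared_down_focal2),
            "convergent_up": len(self.convergent_up),
            "convergent_down": len(self.convergent_down),
        }


def shared_degs(
    comparisons: dict[str, set[str]],
    background: list[str] | None = None,
    min_support: int | None = None,
) -> set[str]:
    """Genes significant in the same direction versus every background species.

    ``comparisons`` maps background species id -> the DEG set (one direction)
    from the focal-vs-that-species comparison. ``background`` lists the
    species that must be covered; omitting one is a configuration error.
    """
    if background is not None:
        missing = [sp for sp in background if sp not in comparisons]
        if missing:
            raise ConfigurationError(f"missing comparisons for background: {missing}")
        sets = [comparisons[sp] for sp in background]
    else:
        sets = list(comparisons.values())
    if not sets:
        raise ConfigurationError("no comparisons supplied")
    k = len(sets) if min_support is None else min_support
    if not (1 <= k <= len(sets)):
        raise ConfigurationError(
            f"min_support {k} out of range for {len(sets)} comparisons"
        )
    if k == len(sets):
        return set.intersection(*sets)
    support: dict[str, int] = {}
    for s in sets:
        for g in s:
            support[g] = support.get(g, 0) + 1
    return {g for g, n in support.items() if n >= k}


def convergent_genes(
    shared_up_focal1: set[str],
    shared_down_focal1: set[str],
    shared_up_focal2: set[str],
    shared_down_focal2: set[str],
    tissue: str = "",
) -> ConvergenceResult:
    """Per-direction intersection of the two focal species' shared DEG sets."""
    return ConvergenceResult(
        tissue=tissue,
        shared_up_focal1=set(shared_up_focal1),
        shared_down_focal1=set(shared_down_focal1),
        shared_up_focal2=set(shared_up_focal2),
        shared_down_focal2=set(shared_down_focal2),
        convergent_up=set(shared_up_focal1) & set(shared_up_focal2),
        convergent_down=set(shared_down_focal1) & set(shared_down_focal2),
    )
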