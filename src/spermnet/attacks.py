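"""Node-deletion experiments: targeted hub removal vs random failure.

Scale-free signaling maps are robust to random node loss but fragile to
the loss of their hubs; these experiments operationalize the "collapse"
of a network after hub deletion as weak-component fragmentation, measured
by the component count and the giant-component fraction of the surviving
nodes.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .network import SignalingNetwork, remove_nodes, weak_components
from .topology import TopologySummary, rank_hubs, summarize_topology

__all__ = [
    "AttackResult",
    "AttackComparison",
    "targeted_attack",
    "random_attack",
    "compare_attacks",
]


@dataclass(frozen=True)
class AttackResult:
    """State of a network after one node-deletion experiment."""

    strategy: str  # "targeted" | "random"
    removed: tuple[str, ...]
    network: SignalingNetwork
    post_summary: TopologySummary | None
    n_components: int
    giant_fraction: float
    seed: int | None = None


def _fragmentation(net: SignalingNetwork) -> tuple[int, float]:
    comps = weak_components(net)
    if not comps:
        return 0, 0.0
    return len(comps), len(comps[0]) / net.n_nodes


def _result(
    strategy: str,
    net: SignalingNetwork,
    removed: Sequence[str],
    *,
    summarize: bool,
    seed: int | None = None,
) -> AttackResult:
    after = remove_nodes(net, removed) if removed else net
    n_comp, giant = _fragmentation(after)
    return AttackResult(
        strategy=strategy,
        removed=tuple(removed),
        network=after,
        post_summary=summarize_topology(after) if summarize else None,
        n_components=n_comp,
        giant_fraction=giant,
        seed=seed,
    )


def targeted_attack(
    net: SignalingNetwork,
    n_remove: int | None = None,
    labels: Iterable[str] | None = None,
    *,
    summarize: bool = True,
) -> AttackResult:
    """Remove the most linked nodes (or an explicit label set).

    ``n_remove`` takes the top of the total-degree hub ranking; ``labels``
    names the nodes directly (e.g. the calcium hub plus the ATP-ADP
    system).  Deterministic.
    """
    if (n_remove is None) == (labels is None):
        raise ValueError("specify exactly one of n_remove or labels")
    if labels is not None:
        removed = list(labels)
    else:
        if n_remove < 0 or n_remove >= net.n_nodes:
            raise ValueError("n_remove must be in [0, n_nodes)")
        removed = [v for v, _ in rank_hubs(net, top_n=n_remove)] if n_remove else []
    return _result("targeted", net, removed, summarize=summarize)


def random_attack(
    net: SignalingNetwork,
    n_remove: int,
    seed: int,
    n_reps: int = 1,
    *,
    summarize: bool = True,
) -> list[AttackResult]:
    """Remove ``n_remove`` uniformly chosen distinct nodes, ``n_reps`` times.

    Each repetition uses a sub-seed derived from ``seed`` so the whole
    experiment is reproducible and repetitions are independent.
    """
    if n_remove >= net.n_nodes:
        raise ValueError(f"n_remove={n_remove} must be < node count {net.n_nodes}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels = net.sorted_nodes()
    root = np.random.default_rng(seed)
    sub_seeds = root.integers(0, 2**31 - 1, size=n_reps)
    results = []
    for rep_seed in sub_seeds:
        rng = np.random.default_rng(int(rep_seed))
        removed = [labels[i] for i in rng.choice(len(labels), size=n_remove, replace=False)]
        results.append(_result("random", net, removed, summarize=summarize, seed=int(rep_seed)))
    return results


@dataclass(frozen=True)
class AttackComparison:
    """Targeted-vs-random asymmetry statistics for one network."""

    targeted: AttackResult
    random_results: tuple[AttackResult, ...]
    random_mean_giant: float
    random_sd_giant: float
    fraction_targeted_below_random: float

    @property
    def asymmetry(self) -> float:
        """Random-minus-targeted gap in giant-component fraction."""
        return self.random_mean_giant - self.targeted.giant_fraction


def compare_attacks(
    net: SignalingNetwork,
    n_remove: int,
    n_reps: int,
    seed: int,
    *,
    summarize: bool = False,
) -> AttackComparison:
    """Run both strategies with the same removal budget and contrast them."""
    targeted = targeted_attack(net, n_remove=n_remove, summarize=summarize)
    randoms = random_attack(net, n_remove, seed, n_reps, summarize=summarize)
    giants = np.array([r.giant_fraction for r in randoms])
    return AttackComparison(
        targeted=targeted,
        random_results=tuple(randoms),
        random_mean_giant=float(giants.mean()),
        random_sd_giant=float(giants.std(ddof=1)) if len(giants) > 1 else 0.0,
        fraction_targeted_below_random=float(
            np.mean(targeted.giant_fraction < giants)
        ),
    )
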