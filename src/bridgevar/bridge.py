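"""Bridge effects: summed lag-2 indirect effects through a candidate node.

A candidate bridge node funnels activity between the depression and anxiety
clusters via two-step paths ``i -> bridge -> j``.  A path qualifies when it
begins and ends at different non-bridge nodes and crosses between clusters:
the origin must be readable as one cluster and the destination as the
other.  Overlapping items (members of both clusters) can take either role,
so the only excluded pairs are those whose endpoints are single-cluster
items of the same cluster.  With 3 pure depression, 2 pure anxiety and 2
overlapping items this yields 22 paths for an overlapping bridge, 24 for a
pure anxiety bridge and 26 for a pure depression bridge.

The bridge effect is the sum over qualifying pairs of
``phi[bridge <- i] * phi[j <- bridge]``, evaluated at every retained MCMC
draw so the statistic has a full posterior; the mean bridge effect divides
by the path count so nodes with different counts can be ranked together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import ItemCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "BridgePathSet",
    "BridgeEffectSummary",
    "GroupDifference",
    "enumerate_bridge_paths",
    "bridge_effect_draws",
    "summarize_effect",
    "compare_groups",
    "rank_bridges",
]


@dataclass(frozen=True)
class BridgePathSet:
    """Qualifying ordered (origin, destination) pairs for one bridge node."""

    bridge: str
    pairs: tuple

    @property
    def count(self) -> int:
        return len(self.pairs)


def _pair_qualifies(m_i: frozenset, m_j: frozenset) -> bool:
    """True when some cluster reading of i differs from some reading of j."""
    for x in m_i:
        for y in m_j:
            if x != y:
                return True
    return False


def enumerate_bridge_paths(bridge: str, catalog: ItemCatalog) -> BridgePathSet:
    """All qualifying ordered (i, j) pairs for paths ``i -> bridge -> j``.

    Pairs must satisfy ``i != j``, neither equal to the bridge, and must
    cross clusters in at least one reading; each ordered pair appears
    exactly once regardless of how many cluster readings support it.
    """
    bridge_item = catalog[bridge]  # raises KeyError on unknown code
    pairs = []
    for it_i in catalog:
        if it_i.code == bridge_item.code:
            continue
        for it_j in catalog:
            if it_j.code == bridge_item.code or it_j.code == it_i.code:
                continue
            if _pair_qualifies(it_i.membership, it_j.membership):
                pairs.append((it_i.code, it_j.code))
    return BridgePathSet(bridge=bridge_item.code, pairs=tuple(pairs))


def bridge_effect_draws(phi_draws: np.ndarray, path_set: BridgePathSet,
                        catalog: ItemCatalog) -> np.ndarray:
    """Per-draw bridge effect: sum over pairs of the in-edge/out-edge product.

    ``phi_draws`` is (n_draws, p, p) with ``phi[to, from]``.
    """
    phi_draws = np.asarray(phi_draws, dtype=float)
    p = len(catalog)
    if phi_draws.ndim != 3 or phi_draws.shape[1:] != (p, p):
        raise ValueError(f"phi_draws must be (n_draws, {p}, {p}); "
                         f"got {phi_draws.shape}")
    b = catalog.index(path_set.bridge)
    i_idx = np.array([catalog.index(i) for i, _ in path_set.pairs])
    j_idx = np.array([catalog.index(j) for _, j in path_set.pairs])
    into = phi_draws[:, b, i_idx]      # phi[bridge <- i]
    out = phi_draws[:, j_idx, b]       # phi[j <- bridge]
    return (into * out).sum(axis=1)


@dataclass
class BridgeEffectSummary:
    """Posterior summary of one bridge effect (and its per-path mean)."""

    bridge: str
    group: str
    draws: np.ndarray
    count: int

    @property
    def mean(self) -> float:
        return float(self.draws.mean())

    @property
    def ci95(self) -> tuple:
        return (float(np.quantile(self.draws, 0.025)),
                float(np.quantile(self.draws, 0.975)))

    @property
    def p_one_tailed(self) -> float:
        le = float(np.mean(self.draws <= 0))
        ge = float(np.mean(self.draws >= 0))
        return min(le, ge)

    @property
    def p_two_tailed(self) -> float:
        return min(1.0, 2.0 * self.p_one_tailed)

    @property
    def significant(self) -> bool:
        lo, hi = self.ci95
        return lo > 0 or hi < 0

    @property
    def mean_effect_draws(self) -> np.ndarray:
        """Drawwise bridge effect divided by the number of contributing paths."""
        return self.draws / self.count

    @property
    def mean_effect(self) -> float:
        return float(self.mean_effect_draws.mean())

    @property
    def mean_effect_ci95(self) -> tuple:
        lo, hi = self.ci95
        return (lo / self.count, hi / self.count)

    def as_row(self) -> dict:
        lo, hi = self.ci95
        mlo, mhi = self.mean_effect_ci95
        return {"bridge": self.bridge, "group": self.group, "count": self.count,
                "mean": self.mean, "lo": lo, "hi": hi,
                "p_one_tailed": self.p_one_tailed,
                "p_two_tailed": self.p_two_tailed,
                "significant": self.significant,
                "mean_effect": self.mean_effect,
                "mean_effect_lo": mlo, "mean_effect_hi": mhi}


def summarize_effect(draws: np.ndarray, count: int, bridge: str = "",
                     group: str = "") -> BridgeEffectSummary:
    """Wrap a per-draw bridge-effect vector in its posterior summary."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty draw vector")
    return BridgeEffectSummary(bridge=bridge, group=group, draws=draws, count=count)


@dataclass
class GroupDifference:
    """Drawwise difference of one bridge effect between two groups."""

    bridge: str
    group_a: str
    group_b: str
    draws: np.ndarray      # aligned (chain, iteration) a - b

    @property
    def mean(self) -> float:
        return float(self.draws.mean())

    @property
    def ci95(self) -> tuple:
        return (float(np.quantile(self.draws, 0.025)),
                float(np.quantile(self.draws, 0.975)))

    @property
    def p_one_tailed(self) -> float:
        le = float(np.mean(self.draws <= 0))
        ge = float(np.mean(self.draws >= 0))
        return min(le, ge)

    @property
    def p_two_tailed(self) -> float:
        return min(1.0, 2.0 * self.p_one_tailed)

    @property
    def significant(self) -> bool:
        lo, hi = self.ci95
        return lo > 0 or hi < 0

    def as_row(self) -> dict:
        lo, hi = self.ci95
        return {"bridge": self.bridge, "group_a": self.group_a,
                "group_b": self.group_b, "mean": self.mean, "lo": lo, "hi": hi,
                "p_one_tailed": self.p_one_tailed,
                "p_two_tailed": self.p_two_tailed,
                "significant": self.significant}


def compare_groups(summary_a: BridgeEffectSummary,
                   summary_b: BridgeEffectSummary) -> GroupDifference:
    """Drawwise a - b difference; draws must align on (chain, iteration).

    Group matrices composed from shared fixed-effect draws align
    automatically.
    """
    if summary_a.draws.shape != summary_b.draws.shape:
        raise ValueError("draw vectors have unequal length; cannot align")
    if summary_a.bridge != summary_b.bridge:
        raise ValueError("summaries refer to different bridge nodes")
    return GroupDifference(bridge=summary_a.bridge, group_a=summary_a.group,
                           group_b=summary_b.group,
                           draws=summary_a.draws - summary_b.draws)


def rank_bridges(summaries: list, catalog: ItemCatalog) -> pd.DataFrame:
    """Rank candidate bridges of one group by mean bridge effect.

    The top node is the highest posterior-mean *mean* bridge effect (bridge
    effect per contributing path); every other node gets a drawwise
    ``top - node`` difference and is flagged when that difference's 95% CI
    excludes zero.  Ties at the top are broken by catalog order (logged).
    """
    groups = {s.group for s in summaries}
    if len(groups) != 1:
        raise ValueError(f"summaries must come from a single group, got {groups}")
    by_code = {s.bridge: s for s in summaries}
    means = {code: by_code[code].mean_effect for code in by_code}
    best_val = max(means.values())
    best_candidates = [c for c in catalog.codes if c in means and means[c] == best_val]
    if len(best_candidates) > 1:
        logger.warning("tie for best bridge (%s); keeping catalog order",
                       best_candidates)
    best = best_candidates[0]
    rows = []
    for s in sorted(summaries, key=lambda s: -s.mean_effect):
        if s.bridge == best:
            diff_mean, lo, hi, flag = 0.0, 0.0, 0.0, False
        else:
            d = by_code[best].mean_effect_draws - s.mean_effect_draws
            diff_mean = float(d.mean())
            lo, hi = float(np.quantile(d, 0.025)), float(np.quantile(d, 0.975))
            flag = bool(lo > 0 or hi < 0)
        row = s.as_row()
        row.update({"rank": len(rows) + 1, "is_best": s.bridge == best,
                    "diff_from_best": diff_mean, "diff_lo": lo, "diff_hi": hi,
                    "differs_from_best": flag})
        rows.append(row)
    return pd.DataFrame(rows)
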