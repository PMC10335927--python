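"""Positional Burrows-Wheeler transforms over the panel and state selection.

Two builders produce positional prefix arrays: :func:`build_full_pbwt`
updates the array at every site (the brute-force oracle) while
:func:`build_sparse_pbwt` updates, between adjacent common sites, only the
haplotypes carrying at least one minor allele in the interval and splices
the reordered subsequence behind the untouched block.  Both agree exactly
at every common site.

:func:`select_states` picks up to K conditioning haplotypes for a target by
neighbor lookup in the prefix arrays at spaced checkpoints, complemented by
carrier sharing at confidently-called rare alleles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel_store import CARRIER_LIST, HaplotypePanel

__all__ = [
    "PbwtCheckpoints",
    "ConditioningSet",
    "build_full_pbwt",
    "build_sparse_pbwt",
    "select_states",
]


@dataclass
class PbwtCheckpoints:
    """Positional prefix arrays materialized at selected sites."""

    checkpoint_sites: np.ndarray  # site indices, ascending
    prefix_arrays: list  # one permutation of 0..n_hap-1 per checkpoint

    def array_at(self, site: int) -> np.ndarray:
        i = int(np.searchsorted(self.checkpoint_sites, site))
        if i >= len(self.checkpoint_sites) or self.checkpoint_sites[i] != site:
            raise KeyError(f"no checkpoint at site {site}")
        return self.prefix_arrays[i]


@dataclass
class ConditioningSet:
    """Up to K reference haplotypes forming the HMM state space."""

    target_id: int
    window_id: int
    hap_indices: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.hap_indices = np.asarray(self.hap_indices, dtype=np.int64)
        if len(np.unique(self.hap_indices)) != len(self.hap_indices):
            raise ValueError("conditioning haplotype indices must be distinct")
        if len(self.hap_indices) > self.K:
            raise ValueError("conditioning set exceeds capacity K")


def _partition(order: np.ndarray, minor: np.ndarray) -> np.ndarray:
    """Stable partition: non-minor haplotypes first, minor carriers after."""
    m = minor[order]
    return np.concatenate((order[~m], order[m]))


def build_full_pbwt(panel: HaplotypePanel) -> PbwtCheckpoints:
    """Standard PBWT update at every site; serves as the exact oracle."""
    order = np.arange(panel.n_hap, dtype=np.int64)
    sites = np.arange(panel.n_site, dtype=np.int64)
    arrays = []
    for s in range(panel.n_site):
        order = _partition(order, panel.minor_mask(s))
        arrays.append(order.copy())
    return PbwtCheckpoints(checkpoint_sites=sites, prefix_arrays=arrays)


def _apply_rare_interval(
    panel: HaplotypePanel, order: np.ndarray, rare_sites: list[int]
) -> np.ndarray:
    """Run the small PBWT over the carriers of an all-rare interval and
    splice its prefix array behind the block of untouched haplotypes."""
    in_sub = np.zeros(panel.n_hap, dtype=bool)
    for s in rare_sites:
        in_sub[panel.columns[s].carriers] = True
    if not in_sub.any():
        return order
    sub = order[in_sub[order]]
    mask = np.zeros(panel.n_hap, dtype=bool)
    for s in rare_sites:
        carriers = panel.columns[s].carriers
        mask[carriers] = True
        sub = _partition(sub, mask)
        mask[carriers] = False
    return np.concatenate((order[~in_sub[order]], sub))


def build_sparse_pbwt(panel: HaplotypePanel) -> PbwtCheckpoints:
    """Prefix arrays at common sites only, via small PBWTs over rare-interval
    carriers; equals :func:`build_full_pbwt` at every common site."""
    order = np.arange(panel.n_hap, dtype=np.int64)
    cp_sites: list[int] = []
    arrays = []
    pending: list[int] = []
    for s in range(panel.n_site):
        if panel.is_common(s):
            if pending:
                order = _apply_rare_interval(panel, order, pending)
                pending = []
            order = _partition(order, panel.minor_mask(s))
            cp_sites.append(s)
            arrays.append(order.copy())
        else:
            pending.append(s)
    # trailing rare sites never precede a checkpoint; nothing to record
    return PbwtCheckpoints(
        checkpoint_sites=np.asarray(cp_sites, dtype=np.int64), prefix_arrays=arrays
    )


# ---------------------------------------------------------------------------
# Conditioning-state selection
# ---------------------------------------------------------------------------


def _insertion_position(
    minorized: np.ndarray,
    target_minor: np.ndarray,
    order: np.ndarray,
    site: int,
    lo_site: int,
) -> int:
    """Position at which the target's reversed minorized prefix (sites
    ``site`` down to ``lo_site``) inserts into the PBWT order."""

    def le_target(hap: int) -> bool:
        # True if panel hap sorts at-or-before the target
        col = minorized[lo_site : site + 1, hap]
        tgt = target_minor[lo_site : site + 1]
        diff = np.flatnonzero(col != tgt)
        if diff.size == 0:
            return True
        s = diff[-1]  # most significant differing site (reversed prefix)
        return col[s] < tgt[s]

    lo, hi = 0, len(order)
    while lo < hi:
        mid = (lo + hi) // 2
        if le_target(int(order[mid])):
            lo = mid + 1
        else:
            hi = mid
    return lo


def select_states(
    checkpoints: PbwtCheckpoints,
    panel: HaplotypePanel,
    target_haps,
    target_rare_calls=(),
    K: int = 2000,
    interval_cm: float = 0.1,
    neighbors: int = 4,
    target_id: int = 0,
    window_id: int = 0,
    window: tuple[int, int] | None = None,
) -> ConditioningSet:
    """Select up to K conditioning haplotypes for one target.

    Parameters
    ----------
    target_haps:
        Current diplotype estimate: two full-length ALT-indicator vectors.
    target_rare_calls:
        Site indices at which the target confidently carries the panel's
        minor allele; every panel carrier of those alleles is added.
    interval_cm:
        Minimum genetic spacing between checkpoints used for neighbor
        lookup (0.1 cM by default).
    neighbors:
        Number of neighbors taken on each side of the target's position.
    """
    if K < 2:
        raise ValueError(f"state capacity K={K} is not a valid configuration")
    n_hap = panel.n_hap
    all_haps = np.arange(n_hap, dtype=np.int64)
    if K >= n_hap:
        return ConditioningSet(target_id, window_id, all_haps, K)

    lo_site, hi_site = (0, panel.n_site) if window is None else window
    cp_sites = np.asarray(checkpoints.checkpoint_sites)
    in_win = (cp_sites >= lo_site) & (cp_sites < hi_site)
    cp_idx = np.flatnonzero(in_win)

    # greedily keep checkpoints spaced >= interval_cm apart
    cms = panel.cm_positions
    spaced: list[int] = []
    last_cm = -np.inf
    for i in cp_idx:
        c = cms[cp_sites[i]]
        if c - last_cm >= interval_cm:
            spaced.append(int(i))
            last_cm = c
    if cp_idx.size and (not spaced or spaced[-1] != int(cp_idx[-1])):
        spaced.append(int(cp_idx[-1]))

    minorized = panel.minorized()
    flip = np.asarray(
        [0 if c.minor_is_alt else 1 for c in panel.columns], dtype=np.uint8
    )
    counts = np.zeros(n_hap, dtype=np.int64)
    recency = np.full(n_hap, -1, dtype=np.int64)
    tick = 0
    for hap_vec in target_haps:
        tgt_minor = np.asarray(hap_vec, dtype=np.uint8) ^ flip
        for i in spaced:
            site = int(cp_sites[i])
            order = checkpoints.prefix_arrays[i]
            pos = _insertion_position(minorized, tgt_minor, order, site, lo_site)
            a = max(0, pos - neighbors)
            b = min(n_hap, pos + neighbors)
            picked = order[a:b]
            counts[picked] += 1
            recency[picked] = tick
            tick += 1
    for s in target_rare_calls:
        col = panel.columns[s]
        if col.encoding == CARRIER_LIST and col.carriers is not None:
            counts[col.carriers] += 1
            recency[col.carriers] = tick
            tick += 1

    selected = np.flatnonzero(counts > 0)
    if selected.size > K:
        # keep by descending selection count, ties by lower haplotype index
        ranked = selected[np.lexsort((selected, -counts[selected]))]
        selected = np.sort(ranked[:K])
    return ConditioningSet(target_id, window_id, selected.astype(np.int64), K)
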