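"""Haploid Li & Stephens forward-backward restricted to polymorphic sites.

The conditioning haplotypes form the HMM states.  Within the custom panel
most rare variants are monomorphic; their emissions are state-independent,
so the forward-backward recursion is run only over the polymorphic sites,
with the transition probability adjusted to the genetic distance between
consecutive polymorphic sites.  Monomorphic-site posteriors come from the
emission alone.  Running the dense recursion over every site yields the
same posteriors, which is the correctness argument for the skip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .panel_store import HaplotypePanel
from .sparse_pbwt import ConditioningSet

__all__ = [
    "HmmParams",
    "CustomPanel",
    "AllelePosteriors",
    "build_custom_panel",
    "transition_prob",
    "forward_backward",
    "impute_monomorphic",
    "impute_all",
]


@dataclass
class HmmParams:
    """Copying-model parameters: effective population size and copy error."""

    ne: float = 15000.0
    err: float = 1e-4

    def __post_init__(self) -> None:
        if self.ne <= 0:
            raise ValueError("ne must be positive")
        if not (0.0 < self.err < 0.5):
            raise ValueError("err must be in (0, 0.5)")


@dataclass
class CustomPanel:
    """The K conditioning haplotypes decoded over one site window."""

    hap_indices: np.ndarray  # panel haplotype ids, len K
    alleles: np.ndarray  # (K, M) ALT indicators
    site_indices: np.ndarray  # absolute panel site indices, len M
    cm: np.ndarray  # genetic positions, len M
    poly_sites: np.ndarray  # window-relative indices polymorphic among the K
    mono_allele: np.ndarray  # (M,) fixed allele; meaningful at mono sites

    @property
    def K(self) -> int:
        return self.alleles.shape[0]

    @property
    def M(self) -> int:
        return self.alleles.shape[1]

    @property
    def mono_sites(self) -> np.ndarray:
        mask = np.ones(self.M, dtype=bool)
        mask[self.poly_sites] = False
        return np.flatnonzero(mask)


@dataclass
class AllelePosteriors:
    """Posterior probability of carrying ALT, per covered site."""

    site_indices: np.ndarray  # window-relative
    p1: np.ndarray


def build_custom_panel(
    panel: HaplotypePanel,
    cset: ConditioningSet,
    window: tuple[int, int] | None = None,
    site_indices: np.ndarray | None = None,
) -> CustomPanel:
    """Decode the conditioning haplotypes and classify poly/mono sites."""
    if len(cset.hap_indices) == 0:
        raise ValueError("empty conditioning set")
    if site_indices is None:
        lo, hi = (0, panel.n_site) if window is None else window
        if hi <= lo:
            raise ValueError(f"empty site window [{lo}, {hi})")
        site_indices = np.arange(lo, hi, dtype=np.int64)
    else:
        site_indices = np.asarray(site_indices, dtype=np.int64)
        if site_indices.size == 0:
            raise ValueError("empty site window")
    alleles = panel.dense()[site_indices][:, cset.hap_indices].T.copy()
    k = alleles.shape[0]
    counts = alleles.sum(axis=0)
    poly = np.flatnonzero((counts >= 1) & (counts <= k - 1))
    mono_allele = (counts == k).astype(np.uint8)
    cm = panel.cm_positions[site_indices]
    return CustomPanel(
        hap_indices=np.asarray(cset.hap_indices, dtype=np.int64),
        alleles=alleles.astype(np.uint8),
        site_indices=site_indices,
        cm=cm,
        poly_sites=poly,
        mono_allele=mono_allele,
    )


def transition_prob(d_cm: float, params: HmmParams, K: int) -> float:
    """Switch probability over a genetic distance of ``d_cm``.

    rho = 1 - exp(-0.04 * ne * d_cm / K).  Copying stays on the same state
    with probability (1 - rho) + rho/K and moves to each other state with
    probability rho/K, so consecutive gaps with no intervening emission
    compose to the single-gap value at the summed distance.
    """
    if np.any(np.asarray(d_cm) < 0):
        raise ValueError("genetic distance must be non-negative")
    return 1.0 - np.exp(-0.04 * params.ne * np.asarray(d_cm, dtype=np.float64) / K)


def _check_hl(hl: np.ndarray) -> np.ndarray:
    hl = np.asarray(hl, dtype=np.float64)
    bad = np.flatnonzero(hl.sum(axis=1) <= 0)
    if bad.size:
        raise ValueError(f"all-zero haploid likelihood at window site {int(bad[0])}")
    return hl


def _fb_numpy(
    A: np.ndarray,
    hl: np.ndarray,
    rho: np.ndarray,
    err: float,
    return_gamma: bool = False,
):
    """Scalar-reference forward-backward kernel (vectorized over states).

    A: (K, P) alleles, hl: (P, 2), rho: (P-1,).  Returns p1 over the P sites.
    """
    K, P = A.shape
    p_alt = err + (1.0 - 2.0 * err) * A  # P(emit ALT | state), (K, P)
    e = hl[:, 0] * (1.0 - p_alt) + hl[:, 1] * p_alt  # (K, P)
    F = np.empty((K, P))
    f = e[:, 0] / K
    f = f / f.sum()
    F[:, 0] = f
    for p in range(1, P):
        f = e[:, p] * ((1.0 - rho[p - 1]) * f + rho[p - 1] / K)
        f = f / f.sum()
        F[:, p] = f
    B = np.empty((K, P))
    b = np.full(K, 1.0 / K)
    B[:, P - 1] = b
    for p in range(P - 2, -1, -1):
        w = e[:, p + 1] * b
        b = (1.0 - rho[p]) * w + (rho[p] / K) * w.sum()
        b = b / b.sum()
        B[:, p] = b
    g = F * B
    g = g / g.sum(axis=0)
    p1 = (g * hl[:, 1] * p_alt / e).sum(axis=0)
    if return_gamma:
        return p1, g
    return p1


@njit(cache=True)
def _fb_numba(A, hl, rho, err):  # pragma: no cover - exercised via wrapper
    K, P = A.shape
    F = np.empty((K, P))
    B = np.empty((K, P))
    e = np.empty((K, P))
    for p in range(P):
        for k in range(K):
            pa = err + (1.0 - 2.0 * err) * A[k, p]
            e[k, p] = hl[p, 0] * (1.0 - pa) + hl[p, 1] * pa
    s = 0.0
    for k in range(K):
        F[k, 0] = e[k, 0]
        s += F[k, 0]
    for k in range(K):
        F[k, 0] /= s
    for p in range(1, P):
        r = rho[p - 1]
        s = 0.0
        for k in range(K):
            F[k, p] = e[k, p] * ((1.0 - r) * F[k, p - 1] + r / K)
            s += F[k, p]
        for k in range(K):
            F[k, p] /= s
    for k in range(K):
        B[k, P - 1] = 1.0 / K
    for p in range(P - 2, -1, -1):
        r = rho[p]
        wsum = 0.0
        for k in range(K):
            wsum += e[k, p + 1] * B[k, p + 1]
        s = 0.0
        for k in range(K):
            B[k, p] = (1.0 - r) * e[k, p + 1] * B[k, p + 1] + (r / K) * wsum
            s += B[k, p]
        for k in range(K):
            B[k, p] /= s
    out = np.empty(P)
    for p in range(P):
        gs = 0.0
        for k in range(K):
            gs += F[k, p] * B[k, p]
        acc = 0.0
        for k in range(K):
            pa = err + (1.0 - 2.0 * err) * A[k, p]
            acc += (F[k, p] * B[k, p] / gs) * hl[p, 1] * pa / e[k, p]
        out[p] = acc
    return out


def forward_backward(
    cpanel: CustomPanel,
    hl: np.ndarray,
    params: HmmParams,
    kernel: str = "numba",
) -> AllelePosteriors:
    """Allele posteriors at the polymorphic sites of the custom panel.

    ``hl`` is an (M, 2) array of haploid likelihoods over all window sites;
    only the rows at ``poly_sites`` are used.
    """
    hl = _check_hl(hl)
    poly = cpanel.poly_sites
    if poly.size == 0:
        return AllelePosteriors(poly, np.empty(0))
    A = np.ascontiguousarray(cpanel.alleles[:, poly], dtype=np.float64)
    hlp = np.ascontiguousarray(hl[poly])
    d = np.diff(cpanel.cm[poly])
    rho = np.asarray(transition_prob(d, params, cpanel.K), dtype=np.float64)
    if kernel == "numba":
        p1 = _fb_numba(A, hlp, rho, params.err)
    else:
        p1 = _fb_numpy(A, hlp, rho, params.err)
    return AllelePosteriors(poly, p1)


def impute_monomorphic(
    cpanel: CustomPanel, hl: np.ndarray, params: HmmParams
) -> AllelePosteriors:
    """Emission-only posteriors at sites monomorphic among the K states.

    All states carry the same allele a, so the state posterior is
    irrelevant: p(a) ~ hl(a) * (1 - err), p(1 - a) ~ hl(1 - a) * err.
    """
    hl = _check_hl(hl)
    mono = cpanel.mono_sites
    if mono.size == 0:
        return AllelePosteriors(mono, np.empty(0))
    a = cpanel.mono_allele[mono].astype(np.int64)
    hl_a = hl[mono, a]
    hl_o = hl[mono, 1 - a]
    pa = hl_a * (1.0 - params.err)
    po = hl_o * params.err
    p_alt_is_a = pa / (pa + po)
    p1 = np.where(a == 1, p_alt_is_a, 1.0 - p_alt_is_a)
    return AllelePosteriors(mono, p1)


def impute_all(
    cpanel: CustomPanel, hl: np.ndarray, params: HmmParams, kernel: str = "numba"
) -> np.ndarray:
    """Full-window ALT posteriors: forward-backward at poly sites merged
    with emission-only posteriors at mono sites."""
    out = np.empty(cpanel.M)
    fb = forward_backward(cpanel, hl, params, kernel=kernel)
    out[fb.site_indices] = fb.p1
    mono = impute_monomorphic(cpanel, hl, params)
    out[mono.site_indices] = mono.p1
    return out
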