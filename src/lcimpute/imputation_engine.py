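"""Gibbs-sampler imputation engine.

Each target sample is imputed independently: an initialization pass builds
a first diplotype from rare-variant calls and two consecutive haploid
imputation steps, then burn-in and main Gibbs iterations alternate haploid
imputation and phasing, re-selecting conditioning states from the current
diplotype each round.  Genotype posteriors are averaged over the main
iterations only.

All random draws are counter-based: a uniform stream is derived from
(seed, sample, iteration, haplotype) and indexed by absolute site index,
so identical inputs give identical output regardless of windowing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ls_hmm import CustomPanel, HmmParams, build_custom_panel, impute_all
from .panel_store import CARRIER_LIST, HaplotypePanel
from .sparse_pbwt import PbwtCheckpoints, select_states

__all__ = [
    "Diplotype",
    "GibbsSchedule",
    "PosteriorRecord",
    "haploid_likelihoods",
    "initialize_diplotype",
    "gibbs_run",
    "impute_onto_scaffold",
]

_RARE_CALL_THRESHOLD = 0.99


@dataclass
class Diplotype:
    """Ordered pair of allele vectors over the window sites."""

    hap1: np.ndarray
    hap2: np.ndarray

    def genotypes(self) -> np.ndarray:
        return self.hap1.astype(np.int64) + self.hap2.astype(np.int64)


@dataclass
class GibbsSchedule:
    n_burnin: int = 5
    n_main: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_main < 1:
            raise ValueError("schedule requires n_main >= 1")
        if self.n_burnin < 0:
            raise ValueError("n_burnin must be non-negative")


@dataclass
class PosteriorRecord:
    """Per-site genotype posteriors, dosages and phased best-guess calls."""

    site_indices: np.ndarray  # absolute panel site indices
    gp: np.ndarray  # (M, 3) posteriors over {RR, RA, AA}, rows sum to 1
    ds: np.ndarray  # (M,) dosage = gp_RA + 2 gp_AA
    gt: np.ndarray  # (M, 2) phased best-guess alleles


def haploid_likelihoods(gl: np.ndarray, other_hap_allele) -> np.ndarray:
    """Condition the diploid GL triplets on the other haplotype's allele.

    other = 0 gives (l0, l1) ~ (L_RR, L_RA); other = 1 gives (L_RA, L_AA).
    Rows are normalized to max 1.
    """
    gl = np.atleast_2d(np.asarray(gl, dtype=np.float64))
    other = np.broadcast_to(
        np.asarray(other_hap_allele, dtype=np.int64), gl.shape[:1]
    )
    rows = np.arange(gl.shape[0])
    out = np.stack((gl[rows, other], gl[rows, other + 1]), axis=1)
    mx = out.max(axis=1)
    bad = np.flatnonzero(mx <= 0)
    if bad.size:
        raise ValueError(
            f"degenerate genotype likelihoods at window site {int(bad[0])}"
        )
    return out / mx[:, None]


def _uniforms(seed: int, sample_id: int, iteration: int, hap: int, n: int) -> np.ndarray:
    """Counter-based uniforms: a pure function of the identifying tuple."""
    ss = np.random.SeedSequence(
        entropy=int(seed), spawn_key=(int(sample_id), int(iteration) + 16, int(hap))
    )
    return np.random.Generator(np.random.Philox(ss)).random(n)


def _window(panel: HaplotypePanel, window) -> tuple[int, int]:
    lo, hi = (0, panel.n_site) if window is None else window
    if hi <= lo:
        raise ValueError(f"no sites in window [{lo}, {hi})")
    return lo, hi


def _panel_alt_freqs(panel: HaplotypePanel, lo: int, hi: int) -> np.ndarray:
    af = np.asarray(
        [s.alt_count for s in panel.sites[lo:hi]], dtype=np.float64
    ) / max(panel.n_hap, 1)
    return np.clip(af, 1.0 / (2 * panel.n_hap + 2), 1.0 - 1.0 / (2 * panel.n_hap + 2))


def _genotype_posterior_hwe(gl: np.ndarray, af: np.ndarray) -> np.ndarray:
    prior = np.stack(((1 - af) ** 2, 2 * af * (1 - af), af**2), axis=1)
    post = gl * prior
    return post / post.sum(axis=1, keepdims=True)


def _rare_calls(panel: HaplotypePanel, gl: np.ndarray, lo: int, hi: int) -> list[int]:
    """Sites where the target confidently carries the panel's minor allele."""
    af = _panel_alt_freqs(panel, lo, hi)
    post = _genotype_posterior_hwe(gl, af)
    calls: list[int] = []
    for w, s in enumerate(range(lo, hi)):
        col = panel.columns[s]
        if col.encoding != CARRIER_LIST or len(col.carriers) == 0:
            continue
        if col.minor_is_alt:
            p_carry = post[w, 1] + post[w, 2]
        else:
            p_carry = post[w, 0] + post[w, 1]
        if p_carry > _RARE_CALL_THRESHOLD:
            calls.append(s)
    return calls


def _full_length(panel: HaplotypePanel, lo: int, hi: int, values: np.ndarray) -> np.ndarray:
    out = np.zeros(panel.n_site, dtype=np.uint8)
    out[lo:hi] = values
    return out


def _select(panel, checkpoints, hap1w, hap2w, rare_calls, K, lo, hi, sample_id):
    return select_states(
        checkpoints,
        panel,
        (
            _full_length(panel, lo, hi, hap1w),
            _full_length(panel, lo, hi, hap2w),
        ),
        target_rare_calls=rare_calls,
        K=K,
        target_id=sample_id,
        window=(lo, hi),
    )


def _couple_posteriors(p1a: np.ndarray, p1b: np.ndarray, gl: np.ndarray) -> np.ndarray:
    """Genotype posterior from two haploid ALT posteriors, renormalized
    against the input genotype likelihoods."""
    a = np.clip(p1a, 1e-12, 1 - 1e-12)
    b = np.clip(p1b, 1e-12, 1 - 1e-12)
    g = np.stack(((1 - a) * (1 - b), a * (1 - b) + (1 - a) * b, a * b), axis=1)
    weighted = g * gl
    tot = weighted.sum(axis=1, keepdims=True)
    flat = tot[:, 0] <= 0
    if np.any(flat):  # degenerate gl/posterior conflict: drop the gl weight
        weighted[flat] = g[flat]
        tot = weighted.sum(axis=1, keepdims=True)
    return weighted / tot


def initialize_diplotype(
    gl_sample: np.ndarray,
    panel: HaplotypePanel,
    checkpoints: PbwtCheckpoints,
    K: int = 2000,
    params: HmmParams | None = None,
    seed: int = 0,
    sample_id: int = 0,
    window: tuple[int, int] | None = None,
    kernel: str = "numba",
) -> Diplotype:
    """Initial diplotype: rare-sharing state selection from a frequency-prior
    haplotype sketch, then two consecutive haploid imputation steps."""
    params = params or HmmParams()
    lo, hi = _window(panel, window)
    gl = np.asarray(gl_sample, dtype=np.float64)
    af = _panel_alt_freqs(panel, lo, hi)
    post = _genotype_posterior_hwe(gl, af)
    p_hap_alt = post[:, 1] / 2 + post[:, 2]
    sketch = (p_hap_alt > 0.5).astype(np.uint8)
    rare_calls = _rare_calls(panel, gl, lo, hi)
    cset = _select(
        panel, checkpoints, sketch, sketch, rare_calls, K, lo, hi, sample_id
    )
    cpanel = build_custom_panel(panel, cset, window=(lo, hi))
    # step 1: other haplotype integrated out under the gl-weighted prior
    hl_a = np.stack(
        (
            gl[:, 0] * (1 - af) + gl[:, 1] * af,
            gl[:, 1] * (1 - af) + gl[:, 2] * af,
        ),
        axis=1,
    )
    hl_a = hl_a / hl_a.max(axis=1, keepdims=True)
    p1a = impute_all(cpanel, hl_a, params, kernel=kernel)
    u = _uniforms(seed, sample_id, 0, 0, panel.n_site)[lo:hi]
    hap1 = (u < p1a).astype(np.uint8)
    # step 2: conditional on the first haplotype
    hl_b = haploid_likelihoods(gl, hap1)
    p1b = impute_all(cpanel, hl_b, params, kernel=kernel)
    u = _uniforms(seed, sample_id, 0, 1, panel.n_site)[lo:hi]
    hap2 = (u < p1b).astype(np.uint8)
    return Diplotype(hap1, hap2)


def _phased_best_guess(
    gp: np.ndarray, hap1: np.ndarray, hap2: np.ndarray, p1a: np.ndarray, p1b: np.ndarray
) -> np.ndarray:
    """Phased GT: the final sampled diplotype, switched to the gp argmax
    genotype where inconsistent (het orientation from the haploid posteriors)."""
    gt = np.stack((hap1, hap2), axis=1).astype(np.int8)
    gstar = gp.argmax(axis=1)
    bad = np.flatnonzero(gt.sum(axis=1) != gstar)
    for i in bad:
        if gstar[i] == 0:
            gt[i] = (0, 0)
        elif gstar[i] == 2:
            gt[i] = (1, 1)
        else:
            gt[i] = (1, 0) if p1a[i] >= p1b[i] else (0, 1)
    return gt


def gibbs_run(
    gl_sample: np.ndarray,
    panel: HaplotypePanel,
    checkpoints: PbwtCheckpoints,
    schedule: GibbsSchedule | None = None,
    K: int = 2000,
    params: HmmParams | None = None,
    sample_id: int = 0,
    window: tuple[int, int] | None = None,
    kernel: str = "numba",
) -> PosteriorRecord:
    """Burn-in + main Gibbs iterations for one sample over one window."""
    schedule = schedule or GibbsSchedule()
    params = params or HmmParams()
    lo, hi = _window(panel, window)
    gl = np.asarray(gl_sample, dtype=np.float64)
    if gl.shape != (hi - lo, 3):
        raise ValueError(f"gl shape {gl.shape} does not match window ({hi - lo}, 3)")
    seed = schedule.seed
    dip = initialize_diplotype(
        gl, panel, checkpoints, K=K, params=params, seed=seed,
        sample_id=sample_id, window=(lo, hi), kernel=kernel,
    )
    hap1, hap2 = dip.hap1, dip.hap2
    rare_calls = _rare_calls(panel, gl, lo, hi)
    acc = np.zeros((hi - lo, 3))
    prev_haps: np.ndarray | None = None
    cpanel: CustomPanel | None = None
    p1a = p1b = None
    for it in range(schedule.n_burnin + schedule.n_main):
        cset = _select(
            panel, checkpoints, hap1, hap2, rare_calls, K, lo, hi, sample_id
        )
        if prev_haps is None or not np.array_equal(cset.hap_indices, prev_haps):
            cpanel = build_custom_panel(panel, cset, window=(lo, hi))
            prev_haps = cset.hap_indices
        p1a = impute_all(cpanel, haploid_likelihoods(gl, hap2), params, kernel=kernel)
        u = _uniforms(seed, sample_id, it + 1, 0, panel.n_site)[lo:hi]
        hap1 = (u < p1a).astype(np.uint8)
        p1b = impute_all(cpanel, haploid_likelihoods(gl, hap1), params, kernel=kernel)
        u = _uniforms(seed, sample_id, it + 1, 1, panel.n_site)[lo:hi]
        hap2 = (u < p1b).astype(np.uint8)
        if it >= schedule.n_burnin:
            acc += _couple_posteriors(p1a, p1b, gl)
    gp = acc / schedule.n_main
    gp = gp / gp.sum(axis=1, keepdims=True)
    ds = gp[:, 1] + 2 * gp[:, 2]
    gt = _phased_best_guess(gp, hap1, hap2, p1a, p1b)
    return PosteriorRecord(
        site_indices=np.arange(lo, hi, dtype=np.int64), gp=gp, ds=ds, gt=gt
    )


def impute_onto_scaffold(
    scaffold: Diplotype,
    scaffold_sites: np.ndarray,
    extra_sites: np.ndarray,
    extra_gl: np.ndarray,
    panel: HaplotypePanel,
    checkpoints: PbwtCheckpoints,
    K: int = 2000,
    params: HmmParams | None = None,
    sample_id: int = 0,
    kernel: str = "numba",
) -> tuple[PosteriorRecord, list[int]]:
    """Impute extra sites (indels / low-quality variants) into a phased
    high-quality SNP scaffold.

    Scaffold alleles are treated as error-free haploid observations; extra
    sites interleave positionally and get posteriors from the copying model
    plus their own genotype likelihoods.  Extra sites outside the scaffold
    span are rejected per site and returned separately.
    """
    params = params or HmmParams()
    scaffold_sites = np.asarray(scaffold_sites, dtype=np.int64)
    extra_sites = np.asarray(extra_sites, dtype=np.int64)
    extra_gl = np.atleast_2d(np.asarray(extra_gl, dtype=np.float64))
    if extra_sites.size == 0:
        empty = np.empty(0, dtype=np.int64)
        return (
            PosteriorRecord(empty, np.empty((0, 3)), np.empty(0), np.empty((0, 2), dtype=np.int8)),
            [],
        )
    if scaffold_sites.size == 0:
        raise ValueError("scaffold covers no sites")
    inside = (
        (extra_sites > scaffold_sites[0])
        & (extra_sites < scaffold_sites[-1])
        & ~np.isin(extra_sites, scaffold_sites)
    )
    rejected = [int(s) for s in extra_sites[~inside]]
    extra_sites = extra_sites[inside]
    extra_gl = extra_gl[inside]
    if extra_sites.size == 0:
        empty = np.empty(0, dtype=np.int64)
        return (
            PosteriorRecord(empty, np.empty((0, 3)), np.empty(0), np.empty((0, 2), dtype=np.int8)),
            rejected,
        )

    union = np.union1d(scaffold_sites, extra_sites)
    is_scaffold = np.isin(union, scaffold_sites)
    extra_pos = np.flatnonzero(~is_scaffold)
    scaf_pos = np.flatnonzero(is_scaffold)

    h1_full = np.zeros(panel.n_site, dtype=np.uint8)
    h2_full = np.zeros(panel.n_site, dtype=np.uint8)
    h1_full[scaffold_sites] = scaffold.hap1
    h2_full[scaffold_sites] = scaffold.hap2
    cset = select_states(
        checkpoints,
        panel,
        (h1_full, h2_full),
        K=K,
        target_id=sample_id,
        window=(int(union[0]), int(union[-1]) + 1),
    )
    cpanel = build_custom_panel(panel, cset, site_indices=union)

    af = np.asarray([panel.alt_freq(int(s)) for s in extra_sites])
    af = np.clip(af, 1e-6, 1 - 1e-6)
    one_hot = np.asarray([[1.0, 0.0], [0.0, 1.0]])

    hl_a = np.empty((union.size, 2))
    hl_a[scaf_pos] = one_hot[scaffold.hap1]
    marg = np.stack(
        (
            extra_gl[:, 0] * (1 - af) + extra_gl[:, 1] * af,
            extra_gl[:, 1] * (1 - af) + extra_gl[:, 2] * af,
        ),
        axis=1,
    )
    hl_a[extra_pos] = marg / marg.max(axis=1, keepdims=True)
    p1a = impute_all(cpanel, hl_a, params, kernel=kernel)
    hap_a_extra = (p1a[extra_pos] > 0.5).astype(np.uint8)

    hl_b = np.empty((union.size, 2))
    hl_b[scaf_pos] = one_hot[scaffold.hap2]
    hl_b[extra_pos] = haploid_likelihoods(extra_gl, hap_a_extra)
    p1b = impute_all(cpanel, hl_b, params, kernel=kernel)

    pa, pb = p1a[extra_pos], p1b[extra_pos]
    gp = _couple_posteriors(pa, pb, extra_gl)
    ds = gp[:, 1] + 2 * gp[:, 2]
    gt = _phased_best_guess(
        gp, (pa > 0.5).astype(np.uint8), (pb > 0.5).astype(np.uint8), pa, pb
    )
    return PosteriorRecord(site_indices=extra_sites, gp=gp, ds=ds, gt=gt), rejected
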