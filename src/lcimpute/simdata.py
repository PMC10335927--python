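"""Synthetic panels, mosaic targets and low-coverage pileups.

The built-in generator draws site minor-allele frequencies from a
rare-heavy power-law spectrum and assigns carriers through a slowly
drifting hidden ordering, which induces local linkage disequilibrium.
Targets are mosaics of panel haplotypes with Poisson-distributed switch
points, so the copying model can in principle recover them.  Reads are
Poisson-depth base calls with per-base error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glcaller import ALT_BASE, OTHER_BASE, REF_BASE, SitePileup
from .imputation_engine import Diplotype
from .panel_store import (
    DEFAULT_MAF_THRESHOLD,
    GeneticMap,
    HaplotypePanel,
    VariantSite,
    annotate_cm,
    build_sparse_panel,
)

__all__ = ["SimConfig", "simulate_panel", "simulate_target", "simulate_reads"]

_NUC = ("A", "C", "G", "T")


@dataclass
class SimConfig:
    seed: int
    n_hap: int = 200
    n_site: int = 1000
    region_bp: int = 1_000_000
    sfs_alpha: float = 1.0
    mosaic_switch_per_cm: float = 1.0
    coverage: float = 1.0
    base_err: float = 0.002
    maf_threshold: float = DEFAULT_MAF_THRESHOLD
    rate_cm_per_mb: float = 1.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.n_hap % 2:
            raise ValueError("n_hap must be even: haplotypes come in pairs")
        for name in ("n_hap", "region_bp", "sfs_alpha", "rate_cm_per_mb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_site < 0 or self.coverage < 0 or self.base_err < 0:
            raise ValueError("n_site, coverage and base_err must be non-negative")


def _rng(cfg: SimConfig, *stream) -> np.random.Generator:
    return np.random.Generator(
        np.random.Philox(np.random.SeedSequence(entropy=cfg.seed, spawn_key=stream))
    )


def simulate_panel(cfg: SimConfig) -> tuple[HaplotypePanel, GeneticMap]:
    """Phased biallelic panel with a power-law SFS and local LD, plus a
    uniform genetic map."""
    rng = _rng(cfg, 0)
    gmap = GeneticMap.uniform(cfg.region_bp, cfg.rate_cm_per_mb)
    if cfg.n_site == 0:
        return HaplotypePanel([], cfg.n_hap, [], cfg.maf_threshold), gmap
    positions = np.sort(
        rng.choice(cfg.region_bp, size=cfg.n_site, replace=False)
    ).astype(np.int64)

    # minor-allele counts ~ k^(-alpha) on 1..n_hap/2
    ks = np.arange(1, cfg.n_hap // 2 + 1, dtype=np.float64)
    pk = ks ** (-cfg.sfs_alpha)
    pk /= pk.sum()
    counts = rng.choice(len(ks), size=cfg.n_site, p=pk) + 1

    hidden = rng.permutation(cfg.n_hap)
    r = 0
    dense = np.zeros((cfg.n_site, cfg.n_hap), dtype=np.uint8)
    sites: list[VariantSite] = []
    for s in range(cfg.n_site):
        if rng.random() < 0.05:
            r = int(rng.integers(cfg.n_hap))
        else:
            r = int((r + rng.integers(-2, 3)) % cfg.n_hap)
        if rng.random() < 0.02:
            i = int(rng.integers(cfg.n_hap - 1))
            hidden[i], hidden[i + 1] = hidden[i + 1], hidden[i]
        carriers = hidden[(r + np.arange(counts[s])) % cfg.n_hap]
        dense[s, carriers] = 1
        ref, alt = rng.choice(4, size=2, replace=False)
        sites.append(
            VariantSite(chrom="1", pos_bp=int(positions[s]), ref=_NUC[ref], alt=_NUC[alt])
        )
    panel = build_sparse_panel(dense, cfg.maf_threshold, sites=sites)
    annotate_cm(panel, gmap)
    return panel, gmap


def simulate_target(
    panel: HaplotypePanel, gmap: GeneticMap, cfg: SimConfig, instance: int = 0
) -> tuple[Diplotype, np.ndarray]:
    """Mosaic diplotype copied from panel haplotypes.

    Each target haplotype copies a panel haplotype, switching source at
    Poisson(mosaic_switch_per_cm x length_cm) genetic positions, with a
    per-site copy error of ``base_err``.  Returns the diplotype and the
    (2, n_site) copy-path record of source haplotype indices.
    """
    if panel.n_site == 0 or panel.n_hap == 0:
        raise ValueError("cannot simulate a target from an empty panel")
    rng = _rng(cfg, 1, instance)
    cm = panel.cm_positions
    length_cm = max(float(cm[-1] - cm[0]), 0.0)
    dense = panel.dense()
    haps = []
    paths = []
    for _ in range(2):
        n_switch = rng.poisson(cfg.mosaic_switch_per_cm * length_cm)
        cuts = np.sort(rng.uniform(cm[0], cm[-1], size=n_switch))
        seg = np.searchsorted(cuts, cm, side="right")
        sources = rng.integers(panel.n_hap, size=n_switch + 1)
        path = sources[seg]
        alleles = dense[np.arange(panel.n_site), path].astype(np.uint8)
        if cfg.base_err > 0:
            flip = rng.random(panel.n_site) < cfg.base_err
            alleles = alleles ^ flip.astype(np.uint8)
        haps.append(alleles)
        paths.append(path)
    return Diplotype(hap1=haps[0], hap2=haps[1]), np.asarray(paths)


def simulate_reads(
    diplotype: Diplotype, coverage: float, base_err: float, seed: int
) -> list[SitePileup]:
    """Poisson-depth pileups: each read samples one haplotype uniformly and
    miscalls to a uniformly chosen wrong base with probability base_err."""
    if coverage < 0:
        raise ValueError("coverage must be non-negative")
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    m = len(diplotype.hap1)
    depths = rng.poisson(coverage, size=m)
    total = int(depths.sum())
    site_of = np.repeat(np.arange(m), depths)
    which = rng.integers(2, size=total)
    alleles = np.where(which == 0, diplotype.hap1[site_of], diplotype.hap2[site_of])
    true_base = np.where(alleles == 1, ALT_BASE, REF_BASE).astype(np.int8)
    err_mask = rng.random(total) < base_err
    # a wrong base is uniform over the 3 non-true bases; exactly one of them
    # is the opposite panel allele, the other two are "other"
    pick = rng.integers(3, size=total)
    wrong = np.where(
        pick == 0, (1 - alleles).astype(np.int8) * (ALT_BASE - REF_BASE) + REF_BASE,
        OTHER_BASE,
    ).astype(np.int8)
    bases = np.where(err_mask, wrong, true_base).astype(np.int8)
    err_rec = max(base_err, 1e-4)  # quality cap keeps error probs positive
    out: list[SitePileup] = []
    bounds = np.concatenate(([0], np.cumsum(depths)))
    for s in range(m):
        a, b = bounds[s], bounds[s + 1]
        if a == b:
            out.append(SitePileup())
        else:
            out.append(
                SitePileup(
                    bases=bases[a:b].copy(),
                    error_probs=np.full(b - a, err_rec),
                )
            )
    return out
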