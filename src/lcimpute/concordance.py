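"""Streaming concordance between imputed calls and truth.

Dosage pairs are pooled per frequency bin and summarized by a single
squared Pearson correlation per bin; best-guess genotypes feed the
non-reference discordance rate NRD = mismatches / (mismatches + het
matches + hom-alt matches), with NRC = 1 - NRD.  Accumulation is
streaming (sufficient statistics only) and order-independent.
"""

from __future__ import annotations

import numpy as np

__all__ = ["FrequencyBins", "ConcordanceAccumulator", "default_maf_edges"]


def default_maf_edges(n_hap: int | None = None) -> np.ndarray:
    """Default bin edges over MAF: allele-count boundaries {1, 2, 5} while
    below MAF 0.001 (panel-size permitting), then fixed MAF boundaries."""
    maf_part = [0.001, 0.002, 0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5]
    edges = [0.0]
    if n_hap:
        for ac in (1, 2, 5):
            f = ac / n_hap
            if f < maf_part[0]:
                edges.append(f)
    edges.extend(maf_part)
    return np.asarray(edges)


class FrequencyBins:
    """Ordered MAF bin edges partitioning (0, 0.5]; bin i is (e_i, e_{i+1}]."""

    def __init__(self, edges) -> None:
        edges = np.asarray(edges, dtype=np.float64)
        if edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if edges[0] < 0 or edges[-1] != 0.5:
            raise ValueError("bins must partition (0, 0.5]")
        self.edges = edges

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    def assign(self, maf):
        """Bin index per MAF value; -1 for values outside (0, 0.5]."""
        maf = np.asarray(maf, dtype=np.float64)
        idx = np.searchsorted(self.edges, maf, side="left") - 1
        idx = np.where((maf <= self.edges[0]) | (maf > 0.5), -1, idx)
        return idx if idx.ndim else int(idx)

    def label(self, i: int) -> str:
        return f"({self.edges[i]:g},{self.edges[i + 1]:g}]"


class ConcordanceAccumulator:
    """Streaming sufficient statistics per frequency bin.

    x is the truth dosage, y the imputed dosage; genotype match counts are
    kept for {RR, RA, AA} plus a single mismatch counter.
    """

    def __init__(self, bins: FrequencyBins) -> None:
        self.bins = bins
        n = bins.n_bins
        self.n = np.zeros(n, dtype=np.int64)
        self.sx = np.zeros(n)
        self.sy = np.zeros(n)
        self.sxx = np.zeros(n)
        self.syy = np.zeros(n)
        self.sxy = np.zeros(n)
        self.match_rr = np.zeros(n, dtype=np.int64)
        self.match_ra = np.zeros(n, dtype=np.int64)
        self.match_aa = np.zeros(n, dtype=np.int64)
        self.mismatch = np.zeros(n, dtype=np.int64)
        self.n_variants = np.zeros(n, dtype=np.int64)

    def accumulate(self, bin_id, truth_dosage, imputed_dosage, truth_gt, imputed_gt):
        """Add genotype pairs (vectorized; scalars accepted)."""
        b = np.atleast_1d(np.asarray(bin_id, dtype=np.int64))
        x = np.atleast_1d(np.asarray(truth_dosage, dtype=np.float64))
        y = np.atleast_1d(np.asarray(imputed_dosage, dtype=np.float64))
        tg = np.atleast_1d(np.asarray(truth_gt, dtype=np.int64))
        ig = np.atleast_1d(np.asarray(imputed_gt, dtype=np.int64))
        if np.any((b < 0) | (b >= self.bins.n_bins)):
            raise ValueError("unknown frequency bin")
        if np.any((x < 0) | (x > 2) | (y < 0) | (y > 2)):
            raise ValueError("dosages must lie in [0, 2]")
        np.add.at(self.n, b, 1)
        np.add.at(self.sx, b, x)
        np.add.at(self.sy, b, y)
        np.add.at(self.sxx, b, x * x)
        np.add.at(self.syy, b, y * y)
        np.add.at(self.sxy, b, x * y)
        same = tg == ig
        np.add.at(self.match_rr, b[same & (tg == 0)], 1)
        np.add.at(self.match_ra, b[same & (tg == 1)], 1)
        np.add.at(self.match_aa, b[same & (tg == 2)], 1)
        np.add.at(self.mismatch, b[~same], 1)
        return self

    def count_variant(self, bin_id) -> None:
        np.add.at(self.n_variants, np.atleast_1d(np.asarray(bin_id)), 1)

    def pearson_r2(self, bin_id: int) -> float | None:
        """Pooled squared Pearson correlation for one bin; None when
        undefined (n < 2 or zero variance in either vector)."""
        n = self.n[bin_id]
        if n < 2:
            return None
        vx = n * self.sxx[bin_id] - self.sx[bin_id] ** 2
        vy = n * self.syy[bin_id] - self.sy[bin_id] ** 2
        if vx <= 0 or vy <= 0:
            return None
        cov = n * self.sxy[bin_id] - self.sx[bin_id] * self.sy[bin_id]
        return float(cov * cov / (vx * vy))

    def nrd(self, bin_id: int | None = None) -> float | None:
        """Non-reference discordance (overall, or for one bin); None when
        the denominator is zero.  Hom-ref matches never enter."""
        sel = slice(None) if bin_id is None else slice(bin_id, bin_id + 1)
        mm = int(self.mismatch[sel].sum())
        denom = mm + int(self.match_ra[sel].sum()) + int(self.match_aa[sel].sum())
        if denom == 0:
            return None
        return mm / denom

    def nrc(self, bin_id: int | None = None) -> float | None:
        d = self.nrd(bin_id)
        return None if d is None else 1.0 - d

    def table(self) -> list[dict]:
        rows = []
        for i in range(self.bins.n_bins):
            rows.append(
                {
                    "bin": self.bins.label(i),
                    "n_variants": int(self.n_variants[i]),
                    "n_genotypes": int(self.n[i]),
                    "r2": self.pearson_r2(i),
                    "nrd": self.nrd(i),
                    "nrc": self.nrc(i),
                }
            )
        return rows


def accumulate(acc, bin_id, truth_dosage, imputed_dosage, truth_gt, imputed_gt):
    """Functional alias for :meth:`ConcordanceAccumulator.accumulate`."""
    return acc.accumulate(bin_id, truth_dosage, imputed_dosage, truth_gt, imputed_gt)
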