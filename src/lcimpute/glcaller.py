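"""Genotype likelihoods from base-call pileups.

Standard biallelic caller: a read matching an allele contributes 1 - e,
each of the three mismatching bases contributes e/3, and a heterozygous
genotype samples its two alleles with equal probability.  Bases that are
neither ref nor alt contribute e/3 under both alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "REF_BASE",
    "ALT_BASE",
    "OTHER_BASE",
    "SitePileup",
    "compute_gl",
    "compute_gl_matrix",
    "phred_to_error",
    "write_text_pileup",
    "read_text_pileup",
]

REF_BASE = 0
ALT_BASE = 1
OTHER_BASE = 2

QUALITY_FLOOR = 5  # phred
QUALITY_CAP = 40


@dataclass
class SitePileup:
    """Base observations overlapping one site."""

    bases: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))
    error_probs: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def depth(self) -> int:
        return len(self.bases)


def phred_to_error(q, floor: int = QUALITY_FLOOR, cap: int = QUALITY_CAP):
    """Phred quality to error probability, clamped to [floor, cap]."""
    q = np.clip(np.asarray(q, dtype=np.float64), floor, cap)
    return 10.0 ** (-q / 10.0)


def compute_gl(pileup_site: SitePileup) -> np.ndarray:
    """Linear, max-normalized (L_RR, L_RA, L_AA) for one site.

    A site with no reads is uninformative: (1, 1, 1).
    """
    bases = np.asarray(pileup_site.bases, dtype=np.int8)
    e = np.asarray(pileup_site.error_probs, dtype=np.float64)
    if bases.size == 0:
        return np.ones(3)
    if np.any((e <= 0) | (e > 0.75)):
        raise ValueError("read error probabilities must lie in (0, 0.75]")
    p_ref = np.where(bases == REF_BASE, 1.0 - e, e / 3.0)
    p_alt = np.where(bases == ALT_BASE, 1.0 - e, e / 3.0)
    # log-domain products to stay finite at high depth
    gl = np.asarray(
        [
            np.exp(np.log(p_ref).sum()),
            np.exp(np.log(0.5 * p_ref + 0.5 * p_alt).sum()),
            np.exp(np.log(p_alt).sum()),
        ]
    )
    return gl / gl.max()


def compute_gl_matrix(pileup: list[SitePileup]) -> np.ndarray:
    """(n_site, 3) likelihood matrix for one sample's pileups."""
    return np.asarray([compute_gl(p) for p in pileup])


# ---------------------------------------------------------------------------
# Simple text pileup format: one line per site,
#   CHROM  POS(1-based)  REF  ALT  BASES  QUALS(phred+33)
# "." in the BASES/QUALS columns marks a site with no reads.
# ---------------------------------------------------------------------------


def write_text_pileup(path, sites, pileup: list[SitePileup]) -> None:
    with open(path, "w") as fh:
        fh.write("#CHROM\tPOS\tREF\tALT\tBASES\tQUALS\n")
        for site, p in zip(sites, pileup):
            if p.depth == 0:
                fh.write(f"{site.chrom}\t{site.pos_bp + 1}\t{site.ref}\t{site.alt}\t.\t.\n")
                continue
            chars = []
            for b in p.bases:
                chars.append(site.ref if b == REF_BASE else site.alt if b == ALT_BASE else "N")
            quals = "".join(
                chr(int(round(-10 * np.log10(e))) + 33) for e in p.error_probs
            )
            fh.write(
                f"{site.chrom}\t{site.pos_bp + 1}\t{site.ref}\t{site.alt}\t"
                f"{''.join(chars)}\t{quals}\n"
            )


def read_text_pileup(path) -> list[SitePileup]:
    out: list[SitePileup] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            _, _, ref, alt, bases_s, quals_s = line.rstrip("\n").split("\t")
            if bases_s == ".":
                out.append(SitePileup())
                continue
            codes = np.asarray(
                [
                    REF_BASE if c == ref else ALT_BASE if c == alt else OTHER_BASE
                    for c in bases_s
                ],
                dtype=np.int8,
            )
            errs = phred_to_error([ord(c) - 33 for c in quals_s])
            out.append(SitePileup(bases=codes, error_probs=np.atleast_1d(errs)))
    return out
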